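>S288c
MMNVANLLLISVYLNVGMQYRDYTIRLDPICDLSGTQGPHFPPSSGGTGHKHVNRWMYPR
GLHYYTVGIVPCNPMSLYWRFWAEKSTENGRFTPTLIQITRRL
>hom01
MMLVANLLNIMVYDNAGMHYRMYTI-LDPY-GLSGTQGPHDPPSSFGPSHKHVNRREYPR
GVHLYYVKEVCCNP-LLCWRAWAEKSTSNGRETNT-VQITRRL
>hom02
G-NVANRLLKQVWLNEGMLYLDYTRILDPICDLSYT-VGHTPPSSGGYGIKHVNRMDY-R
GLHY-TVGIVMCNDMSLYWRF-WDKRTEN-RFTCTLTCRTKRL
>hom03
HMNVNNLLGISV-LNVGM-YRDDTHALDPICDLSGCQGPHFD-SSGYTGHSHVNRWMYKR
GYHHAMVG-VPCNIMS-YQR-ILEESPEN-SFT-TLIQITCRL
>hom04
MMA-AWLLFTSP--WRWLQYRDVTIALHPICDLAHFQGPHFPGSYGGDNMKGVNRWSCPR
HPHYYTVGIVPCNPVWLWNRFWGE-STRNWWFTPT-MQITRSL
>hom05
VVNFARLQRLQVRLWVY-VYYDNTYHL-FNCKLSGTEGPHFPPQQGYTGHKHV--FDYPR
G-HYYTVC-GW-GPSSLLWKPWAEKIIVFGNFTPLLTCI-YR-
>hom06
MMNVANPLLPSVYLQVGMQY-TWTIKCDPIPQLNGTQCPHMPPSSGCTGHKHV-CWMYPR
GTHYYTMGELPHLPNSLYWRFIY-KSEENGRF-FTQIQITRHL
>hom07
MLN-ANMLLPSVALNVGPQYKEYTVYAHIDCD-TGTQ-DHYDPS-GKTEL-QVNP-RYVR
GLHYYTIGINPINPMSTAYRFWAEKAAEN-RFTSTLIQITRYL
>hom08
MMIRDNVLWASVKGNVGMQV-DYTI-LDPKCCLSG-QSDHFPPSSGGTFHKHGTIWMSPR
GFHFPTVKIVPDNCDSDYWRDWANKMTEN-RFSPYLIQITLRS
>hom09
DMNTNNLLRASVYLR-GMQYFTYYIRLDPICDCSGTQGPHFPESTGGTKTGHVNRHMYPR
GLCYYWVGIVPCNMMSFYWRKKPEKSG-NGAFTPTLIQIDVRL
>hom10
MFNVDDLSL-SSSLDVG--YRDRNIRYDPHCDLRHTQGGHFPPSSSGTGVTHVNRVMYPR
GNHECTVGIVICNRMTLYQRFWATKHTEN-RFMNTLIQIRRRL
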