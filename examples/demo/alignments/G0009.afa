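>S288c
MMSLPLPRSSNSYAAGMVDECLTLILEGYQTGNSSGSWFSEILVEKLREVQRCRGVYTGA
GETLNQITSRNRTSLGYTAQASHQEVGYSPRLMDGFPTELPH
>hom01
MMSLPLPRS-NSYAAWMVDECLTLILAMRQPGM-SG-WFVEILVEKLREVQGCRGVYLEA
GETLNQMGSRNINSLGYTAQA-HQES-YSP-LDDYFPTELWS
>hom02
MMSLPKPRRSNTYGAGMQEE-IPLELEEYQTG-SSLTK-SEHLVCTLREVQRCRGVYTEM
G-TLQWTTSHNRTSLGYTAQHSHQ-MGYSPSLMDYNPTHLPI
>hom03
MDSLRSPRSHNSYAAGM-DECIILILSW-QTMNGSGSWFSEQLVEKVRSV-RMQGVYTGP
GETLNQIF--NRTSLHVTEQLSHQEVGYTHRLYVGIPT-LPH
>hom04
KMSTLLPRS-NSYAAGHVDECLTIILERYQEGNSSGRWFSTIIFEKLVEWQRCRGVDSMA
GE-LNQITSRLRMSRGYTAQ--RQEAGDEPGLMD-FCTCEPH
>hom05
MHSLPSPRSRNSYAAGQVDECLPLITYGYQTGVSPQSW-T-RLTEKTDE--RCQGVYTGA
SPTLNQ-TSRNRTSLTYVNQASHFETGQSKRIMDKFPTELPH
>hom06
MMSLGFPRSSNEYMYSMVDECLRLILEGEATGNSSGSIFMWIIVESLFEVSWLRGVNTGW
GEIRRQITSRERTYL-LWAQ--HQARGYSPRLSDGPPDEGPH
>hom07
MMSLPLPRPLI-YAAGMVPECLTLKLTGDVTPVGSGAWESEIHVEKWR-SQPCEGVYYGA
-ESL-V-DSRNL-SLGDTAQP-HKEVGYSPRLMDDAPTMLPP
>hom08
MMWL-LPRSQNSTAAGMV-VCVTRILEGIQSGNINGSWFSEALEEKCREH-H-RGG-TGA
GETGNFIHSRNRTETGYTYTAAHWEVNYSSRFMDGFPHNLPH
>hom09
CWSLPLEFSSNS-AVGMVDKCRLLLLW-YQMGNNSGSWFSQWLRPKLRECGRP-GIYGGA
RETLNQITSRNRA-LGYGAAAHHGEVGYSP-LMDGFTV-LPH
>hom10
LMMEPQPRSPFSYNAGMVDECLTLILEGYQTGRSSGLAFTEILVEKLREHQRCRGK-YPH
GET-NQITSRNRTRFGFTTQASIQSVAYSNRLMDFFPTKLPL
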