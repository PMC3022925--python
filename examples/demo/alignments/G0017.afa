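>S288c
MASTMCDSLYRGLLLFLLLSEVASTRHFVFEVSMLTFRTRRITVNRRVYCNLVASPRIPV
SPRKRCTDLAFFEEPAFQRRPTLTCAPYCQPSRAANRP
>hom01
CASTACDSCYSGGLPKLL-SEVASTCHFVFKV-DLMFRTKRIMDSR-VYHVLRASPVIGV
SPSKRCTFLAFFENKAEMHRPTFTCEPYR-PSRQANRP
>hom02
MAS-DCDSLYRGYLTFYGLWNVA-TDCSVFEASMLTMRTRRITVNRRVGCNLVAAPWIYV
SP-KRCTDFAQFEE-AFQRRPFLWCAPYCQISRAANRP
>hom03
MLSTMLESLYRTCLLFLLLSEFASHRHAVAWVSMCTHR-DRITVNYRVYCTLV-SIVIPV
SPRT-CADNAFFEEYDFQARP-LTCAPYCPPSFAANRP
>hom04
HASTMERLLYHGLLL-LLLSEQASTRSFPRTCGMLTFRTR--TVNRQVAYLLVCSPIIPV
SPAKRCTDEANCPEPAFQHRPTLQCGPYCQPSRDANRP
>hom05
MAQTMCDSKYRML--FELLSERQSTRHTVSPVSMCEIRTRRIS-ERGVYQNPVASPRIPW
EPYHA-ADLQFFELPAFQGRPTLTCSNYCQPTRWACKP
>hom06
KASPLCDSRYRGLLLFLALSEVASTRHFVFEVS-KVFRQRRITMWRRVP-NSV-SPMR-V
HPRKRMTVLAAFR-SAFGRRPTLTHAPY-QPIRAA--P
>hom07
MAFTMCDSLYRPLWLFLHPQEVDSVAHFVF-VSMLTFRLRRQTVWHRVYS-LVAS-RIPM
S-RKRVGDLAFFEPPKVQR-P-LTCAPY-HPCIHADMP
>hom08
MCFTCKRWLYRGLLRFLLLSEIAHDGAFVFEWAMLRFRTRRWCVNGRVYTNLVQSWR-PV
QYTKRCPDCAMFEE-AEQRRPT-TQAYYCQLIRACCKP
>hom09
MAEWSCRSLYRGKQLFLLLSEM-WVPRFIMEVSMLTFMWIMICVGRRTYCKLVGKQRIPY
SPFKRCTENLFIVEPAFER-PEWWCAPYCQGSRA-FRW
>hom10
MASAL-DLDYSGLLHFLLLSPWASTREFWFEV-MLTFHTRRITVIRRGYCNLVAEPRIPV
-PKKRCTDLAFF-ESIF-LRPTLT-GPMCQPSRAANRP
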