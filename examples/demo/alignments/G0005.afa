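>S288c
MEDRFCTPESLHPASCWKIAMRRSLRTAWWLTPWRCSRAAVSADGHGTLARCIAGDDSQV
NQAFPAQPM
>hom01
MECRFCTPESCHPASCE-VAMRISLGL--GPTPWRCSHAAVSADG-ETLARPVAGDDSQM
NQAFMAQPM
>hom02
YEDRFCTPPSLHWIM-WKIAMRESLRKAWW-TAWRDSRAA-SADTKTTLATCIAGDDSQV
SQAFPAQ-M
>hom03
MEIRFCTP-HLHPIECQKIAMRPIVRTAFPLTPQRCSRQAVSADEYG-LARCIAWDDRQV
NQAFPQQPW
>hom04
MHDAGCLVESLHD-CCEWISMRGSHRTWWW-TEWRCSRAKKSADGHGTLARLG-GDQYYV
NNAFGAQCM
>hom05
VEKRHCCQESQHQAPCWKDAMAFS-RT-WWLEAWFFSRAAVSADMHIALKRCLSGDDSQ-
NQA-PKQPM
>hom06
MEARVCTMNSLHPDSVWKIRNRRLLVTAWWLTPWRHSKAAFSAPGHGTEARCIAGDDSNV
EQAFLAQPM
>hom07
MEDRFC-PE-IHPASCWKIAMNGWLRTLWWLTPWLNSCA-VAAPGHITLARCI-ADDSQV
NQ-APKLPM
>hom08
VIDRFVTPESLH-ASYWSGAMRRSDRT-WFLIFVNCSAADVKAREHGVL-R-IAGDWE-N
NS-FPAQFM
>hom09
M-DRFMMPESLH-AVEPKIAMRRSH-TAWWLPPWVCARMAVSAIGHGKLARCIAYDMSQV
SQA-PAKPC
>hom10
AEDRFCEDEPLHPA-NWKIDSRRSQW-AWTETGWRC-MCAVSVDGHGTVRRCIAGDDSQV
NQAFGRVPM
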