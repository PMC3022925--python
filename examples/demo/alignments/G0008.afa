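>S288c
MKGCCTGAEVGSAPSTLQNNFSQTRIHMHLSSTSGRTRLQPLRWPDMPRTIGGSSTPSPY
RRVTRDPCGPVLSHPHQT
>hom01
HMGGCTHAYVGSAP-TLQNCASQQRIHAHLSSTSGRKSLQPDRWYDMGAAIGGSSLASPM
R-VNRYPCGPSLQMPFQT
>hom02
MYSCCTEAVYGSSPMTLQNKFSSVRIHMH-SHTSKCTALQPLRWPDMIRTIGG-KHWNPY
LAN-FDPC-PVLNTEE-N
>hom03
KKGCCTGASVGSATSMLWNNWIQ-RHHHHLT-TS-RTCWQWLRWPSMG-TITCSSTPSYY
Q-PTRDPCGPVLSHPNQV
>hom04
MKSCCE-YEFGSAPSYLQNNMRQLQIHMHLSSTSGRCML-PTRLPDIPRTKW-S-TCSPD
DLVTRAPCGPVLTHPDLL
>hom05
MTGVCTGAGFGSAPSALQQNFENRRIHTQLSSDSGR-RLQPLIWPDMPCTIFGSSTDSP-
RRVTRHPNWPPLSH-HQT
>hom06
MKGCGV-REVG-ANKTLQPNFSQTRIHWS-ACTSLFTR-DPLRWPMAPRTIGE-SSPLPY
DRPFRDPCLYQLSHPHQT
>hom07
WHGLCTEAEVGSM-LWLQNDF-QMRLSMT-SSTLGRTTFQLLVFDDMERNIKESSTPSPY
RDVTRG-CFRVLMHN-QM
>hom08
MFSVC-AATV-SAPSTL-NNFSHTRSYMGWSYTSLRTPLWPL-WPDIFRTIHGSSCPSPD
RHVERDPCGPVESHPHQT
>hom09
KLG-GTGAEHGYWPSTGWNRYSQTVKH-HWSSFSGRSRVQPLDWP-KFRTF-PSS-PTPY
TR-S-DPT-PELEHPMQT
>hom10
MVGCGTLADSGKAWSTLVQNFSTTCIHGHLSSTSQRTRLQPLRWPDFYRTICGSSTPGHD
RLVTADPTGPWLSHPWQN
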