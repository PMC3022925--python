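>S288c
MYVGTSTRHDLSIRAPAIGGVRTRNGLPPVLQRHWVRKEGGDHVDRGVYITKRHKLVLQR
>hom01
MYVGTSTRHVLEVRAPAIG-FLTRNGLP-VSQRHWVR-EGGDH-DWCSDITKRHQTVSQR
>hom02
MYVGASTEHDLHIRADETGGWATRDGFPAVKQSEWVRKFGRDYVTRGVYITTRHKLVLSR
>hom03
MYF-TSTRHDTSERPPAIGDLRLR-GLYQVLNRHWVRKEGVDHVDRGRHI-KRHKKVLQR
>hom04
MYVRTSTREDYSIRSPAIICVW-RNYLPPVLQRHWVMEEG-D-VFLGVYITKRHALVLQV
>hom05
W-VKTSCKHDLSIRASDIGGVRTRMGKPPPLQRYWAPKEQ-QHCVKGVYITKRHKLTLQR
>hom06
-YVGYQTRFDLQ-RAPAI-DVPTRNGEPSVPQRHWCRKEGGDHVDIK-YITKRHATTLQR
>hom07
MYV-MDTRQWLTIRAGA-IGVRTRNS-PPVLQHHWVPKEGGDNVDMG-YVYCRHKLVMQI
>hom08
SFVGTSTRHPRSPRAPA-GDKRTRNGAHGVLQRDWVRKQGGR-VDSGVYITKWHKLVLQR
>hom09
MNVGTS-RHDLSIRAPAIGGIRLQNGGPPVLWRHYVYKEGGD-NDR-Y-ITL-HKLVLCN
>hom10
ADVCTSGRELLSIQAPAIGGVRTRMGWPPVLQRHSVTGE-GDIVNEGVFNTKRHKSVLNK
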