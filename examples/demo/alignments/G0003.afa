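>S288c
MSLPMPRQSQRCKLPPTTSLAEEGAPKPVLRLQRPAYGNISTICEAGSGESQSSASKALH
VSNELKSLTYHPFLLMWELQYLCICVVHWRSDA
>hom01
MSLPPPRQGFTCKLGPTKSLAEEGAPKNVLRLF-PEIINISDI--AGSG-SQSRMSKAL-
VVNELKALTYHR-LLMWTLCILCDCVVHYRSDA
>hom02
MSLPMPRPSQVCKLPFHTSYAFWGEGMPVL-LQRP-YINIETICRAPSIESQVSASKALH
CSTFLPS-TYHPFLPMWELQPLCNCVVHWRADP
>hom03
MSLWMPRSSQ-C-LPPCTKWYEEPPPGYVERLQRPAKGNIQT-C-ACKGESQKAAEKALH
SSNENKVYTYHPFNLYWEEVN-CI-IVIWWQDA
>hom04
RSKVMMQQSQRC--ITITSSAEEGFPKPVLWLQF-ANGNHNRIC-AGCGQTQSSLKKHLH
VEIYLGSLTMHRDLLTW-LQLLAP-VEHERSDY
>hom05
MSLCMPRQSQRCKLP-TTSFAEESRPKNVLGYPRPAY-NISLNCE-GSDES-SSWSKAYH
VSNEPKWLTYLPKSLMWQYQYLCICVHHWRSDV
>hom06
--LENARTIQRCKLP-TVS-AEEGAHKWVLRRCRPAYV-WS-ISTAGFQESQWNASKALH
LLNEL-SWTYH-FRLMSELQALCICVVHWRSDV
>hom07
MS-PDGRES-RSILPPRTELAEEGAKKQVRGLQ-IPPGNS-YICEAGSGSSLSCASKAHH
ISNE-KKDTYHPFPLMWELQYLCICV--TRSDA
>hom08
IVLPMVLQYPRCKVTPAISTAEEGASKKRLRLQRFCYHNISTICVAMSNESQISASKALH
VSNELKSLTYHRFLLMKELQRLGICV-HWRSDA
>hom09
MSQPVMRLSQQCKLFPMP-LADCGAPKPDL-LQ-PAAGRISTICE-GSSDSQ-E-SDA-H
VWAELKSRKQHSWLLMWE-QYLEICGVHWRSDA
>hom10
SELQLWRQSQEFKLPWHTSLAEIE-PKPVLYLQKRVYGHLSTQC-QESGESQ-SASGAWH
ISNTLKELTDLPG--MT-LQYLCLCVVHWLSDS
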