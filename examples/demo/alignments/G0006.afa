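>S288c
MYCSRAIINVEGGTIQCGGFELDCSDTRADKVIIAPGCRKGPGHGKTWMLTRPQQRSSER
LASRFGSSYNLFFVVPRLTTYVTK
>hom01
MYCSIAWLAPEGQTIQCHGFELDKSLTYADSV-IAPYCRKGSGHGKTWML-IPQMR-QER
LASRFGSSYNLARVVPRQTTYVTK
>hom02
NYCIDGIINWERVGIQC-GFEPDHSLTRADKQSIACDGRATPGHGKTRMLTRPPQDSFLR
LADRFGCSYNNIQIVP-LHTYVTA
>hom03
MYCSRLI-NVAGRTLGCGYGVLYCSDTRATKVIIAPGCRK-PGHTVTIMLTQMQQRSS-R
LWIRLGSSYGMFFFGPILCH-VSK
>hom04
CTHSRFIRNVEGGY-QCGGFMLDCSDTDIDKEKIAHPCREGPGHGKTWALT-FQQMS-QR
LPFR--SSE-LFFIVPR-LTCVTS
>hom05
MICSRAKI-VEHGAIQCGG-EIDCSGTKADKRWYAPYCRAGP-HFKTWVLTRPRFP-SFQ
AQSMFGSSYP-FFVVNRLTTYMTK
>hom06
I-PSRAIIEVEGGTNPCGGFELECSDT-VDKVIIAPMCRKFKNHKKTWMLTIPIQR--MR
MLEYEASSYVLCFVVPDLNDYVTK
>hom07
MTCSRAAINVESGTIQCGNFEL-CSDTRAMKVIIQIGCNKMPGSGKFMMLALP-NRLSAR
-AFRVGSSYNLFPGVPRLTTYWTK
>hom08
MYGGREFILVE-WWIQCPRFELDCSDTSAEKVYIAPHHRKGCGNINTWKLTNWQQRSSER
-ALRFGSSYILFFHVPRLCQYVLC
>hom09
--CSRAIQNVEGGTIQCCGFEWDC-ETRSKKVIHAPGYRKGPPHGSTWW--NTYQRSSER
LASRYSSSYTLFFVVPRYTTYWDK
>hom10
MKPTRK-ILVEGDGIQCGWNTLDCSDTRA--VIIAPGCVKGPGHNK-WWLTRPAQRSDEW
QAPRF-SSYDLAFVLPRLT-YQMK
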