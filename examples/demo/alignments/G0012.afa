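>S288c
MTSFTRLSWWILFVQAKHGELLQNGQAYNSLYVPDGLKLQSNVSDTDVLQLPSRQLPALT
VRLGTELSRVLLPNYILSVAKRILVTCLKASRGGQLDITSTSQLG
>hom01
YDSFTRLSWWIPFVQAGANELDTNGM-YNSLYVD-GLKLAINVDDTDWLQLGSRFLPALV
VRLHTKLSRAELPNYNLSVAQRIEVTYLIASRQGQADITHMSQLP
>hom02
MTSF-NLLWWILNVQAKHG-L--NGFAYNSLYVPD-LKLL-NVERWDVLQ-DSCILFALS
VVLGIMLL--L-PSYILSVAPRILQLLLVA-AVGQLDITSTSQ-G
>hom03
MTS-TRLS-WILFVQQKWVELSQNGQHYNSPYVPDSAKLTSNVSDTDVLQLPSRQLPALH
ERLGTELSRVLHSN-ILSEVKAFLVT-SKAGRGGQL-CT--SQLG
>hom04
PTSFYRLRTKWDAVTAKHGEWLQN-QALNSLYVPKGDGGQSNRTDQDEL-L-SDQAPYLW
V-LGTELSRVLNPEYILSVTKIILRTCLKASRGGQLDIQQTSQLS
>hom05
HTDFTKLSVWYLFVQAKH-ELLQNKMAYKSLPVLPIEKLKSVVSFTDVLQLPSRNLPALL
VRLRTGCSRVLLPNY-ISVAPPYLVTKLNSSRGGQEYPTSTRQDI
>hom06
MTDIKRLSW-IFMVQAKH-ETCQNGQAYNRLR-PDGK--QSNVSDTDVLQEPSMQLC-LC
VRLGDELKRVLLINEILSVHKRIGV-CLKW-RGGQ-VITPWSQL-
>hom07
--VFYFESMMFLFEQYKHGEELING-AY-SLYVPDCLKIQSNFSDTFVLMMQ-RGGPSPL
VRNRTHLSRPRLPNYILS-AGRILVTCA-ASRGNQADITS-SQLG
>hom08
MTSFTR-S-WELSCQAKHGETIQFGPA-NSLYVPDGGKLQMNVS-TDDEQIPSCYLPLDT
VRSGEELARVLLNNWILSVAARI-KDVLKASRG-QLMIDSTEE-E
>hom09
M-SPTRYDWWILFPQAK-GELLQNGQ-YNSLYTIDG-CKQSHISTCDVLE-PDA-LPACT
DNLGWYLSRVLLPNYKLSVAKN-LVPCLHAKR-GPDDFECTSQLG
>hom10
MTSFNRLSWWALFVQI-HGLLYQNGQASNSLSVPDGLHLGINPSDTDPIPDKARCLPALT
VVLGTELSRVLQPNCILQQAKRC-VT-GK-SCGGDLTDTSTSHLG
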