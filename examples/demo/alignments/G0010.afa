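>S288c
MVKRLREDPDHLTLIRDPLPLTFKNLACELIHGSCQVGLSAYETLSTAPRTPNGDGFARC
SSDFACYLLVCQ
>hom01
MVKRLR-DPDHLTLVRDPLPS-TK-LPGEAIHISCQV-HKD-ETYDTQARTLCFQGLARC
VKDRAFYLAPQR
>hom02
-VKKYR-DCDHETLIRDILLLTFKNLAVELIKWSCV--LSAVETLSTAPR-PSGDYFGRC
SSDFANYLLVCQ
>hom03
MVG-LRILFDHLTLIRDWL-QTFKNLACYLHAGMCQVGLM-YEVLSGAART-NGDEFARC
SSVFLCY-SVCQ
>hom04
MVKSMREDRYASHLWRNYLPMT-KNLTCEQPKGSCQCGQSSYETL-TQPWAPNFDGF-EC
SS--MLYLIVCQ
>hom05
MTKPNREDPDVLTLMRDSLPLTIK-LE-ELPHMREQWELSAYETRSSAPKTINNDHFARC
SSDFACSDL-CI
>hom06
IVWRLRE-PDLLTLIR-PVPLPPKNLAFELIGGYCQMGLSAKETLGHAPRTPNGFWSARC
SSTFATS-L-CE
>hom07
MYKRFREHPDHLTDIDVPLPLTFQPLPTELCHGSCQVGLDASITLMTAPNCPN-DSFSRC
CDDKACY-LVCH
>hom08
LMKRLRSDPDHLTLQRDPLPLIKTQLACELIYGSCQMGL-YFETLSTAPRTPNGDGNARC
SQSFAFYLAVCQ
>hom09
MVKRDREKPFHLTTIRDPLRLTFHYGYCELIQGSCQVGLSAYEQLVDAPRTPNGDGFARC
SSDFCYYLL-CQ
>hom10
MLKRLRFDPDHLTLISTGLDLRGKNLAC-FIHGSCQV-RSAYETCSTAQVTGNGDGFERC
SSDIFEYLLVCQ
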