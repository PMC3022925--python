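>S288c
MLRLFTDHVLTGGRYLPRWRRSRRIKGSSNVRITMLAADCPLISSYRYLGYWRNPKYMTE
PKIGPFASMRAPHTCHIEVRQSLKTGLQKSLRDETRVENCAAGLVSFCLI
>hom01
VLRLFTCHNPTGGRYSPRWRRSRRI-GSKNVRHTMLAADCTLFSSYR-LVYWRHPKYMTN
PKIGPRESMRAPHTCHIEVRQSLKTQLEKSERDEHRNENCAAICA-FSLY
>hom02
MLRQFTDHVWMGGRYLP--DRSRRIKGCSNVNIQMWPADC-LTSCLDYLQYMR-PKYMEE
YKIAPWASMTATHTCGLEVLKSLNTKLQSALREET-TIKCVAGNTMFCPG
>hom03
MWRLFRSHVLTGGRCLPWPRRSYRIKGSNNPRETMLAADCTLISSY-KLGYKRYWKYMTE
PAI-PFMSMRWLIACHIEVRQSLKCILQTSLREETRVENCALYLLSFCLI
>hom04
WLRTFVDDP-T--RYLPRWCRSIQIKGSSCVRITMLAADCPLISSSRYLGIWRNPKYMFE
HKMGPTASM-APHTCHPE-R-SLKTV-QKCLRDETRVENC-AGLVSWCLI
>hom05
SFNF-T-HNLTLGLI-PYWRHSTRSKESHN-VIRHLAAACFGIS-YRDLGQERNPKMKTE
PKIGPMAEHRAP-TCHIEDFDSLKT-LDKSLRDETRVENCGWGLVSFCNR
>hom06
MARLFY-QYLT-CRMLH-WKYQERIKESRNVQIRALAADSP-ISSYRYLRYWRNSKY-TE
IKIG-FASMR-PA-CHNEVRQ-LKHGKQGSTRCYTRDENCIAGNVSVRQV
>hom07
MLRTPTDHV-TR-RYLMVWRRG-RIKGTLPHRSTMLAAQCKLISSYR-LGYDREPKYMT-
-KI-FFCSMAAECTCHIE-RPWHKEGYQKSKWDEQNVENKIAGFVSFCLI
>hom08
-LKLFTDRPLTGMPYLPRYRRSRDMTGSSTVW-THTAMKQPSISSYRQLGNIRNPKYMTE
PAIGHFASMRAF-TCDIESRQ-LKTGLHKSLRDETRVNFCLAGLVSFCLI
>hom09
MRCLLTDWDGQHGRVLPRWRRSRRIMGS-NVRDTMPAADCPLIASACVYGKWRNPYYMWE
PKISPFASMQKQHACDIECRCQDSTLLGKS-RDATRVGTMAAGLVSDWLI
>hom10
DSYMFE-HVLTDGRYLPRWRRSRRITGGSPVKITMR-ADKPCGSS-RYLGPWRNPKNATE
PLHGPFASFGYPHTCHIEVLQSLKTGLQKS-RLETRIENCAAGHVSFCLI
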