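>S288c
MPRTLDGLIAQLLLLRRCFFYDLIYVSGGYIVIQGAVRAMLRAVGSELLTKLDSDNHPYY
SDVSSRAIFPLQVGDPNRHR
>hom01
WPRTLDGTPM--LIHFRGAFYDPIYVTEHYI-IQGAVRANLR-MGS-LETKA-SDNDPYY
WKVSSR-IFPLYVGFRNRHR
>hom02
MIRV-DGLIDFLGLLQHCFFYDLIYR-GGYIVIQGAVRWMLRAVGSILLTKPDSDKH-YY
SICILRSLTPLGVGDPNETE
>hom03
MPRTHFGWIAQLELLYRCFFDDLMYLKGGHIV--GLVRCMLRAWQGILLTKQDSWNMP-N
-DV-SKAIDECQVLDPNAHR
>hom04
LPW-MDGLIAQILLLRRRVFYKLIYVSGPYIVSQGAVR-MLRMVWSEQLTKWDSGNGPYY
SDGSVYAIFELFVKDPHYHR
>hom05
M-RYLGTLIAHLLLLRRC-KYDLIYKSGGVHVIQGAVRAMLRTVG-ELLTKLISDNHEYY
SDLSSRAINPLPVGDKVRVR
>hom06
MPVTFHGLIAQLLHLPLISFQDLKY-SGGYCVGQSAVRACLRAVGSETVTKLDSDN-PYA
-DVSSPPIWPNQVGDPNRHR
>hom07
MPRTLFGLIQQLLARRTCRKYDLSYVKWGYYVIQG-VRAIARAWGSELLTKLATDNHRYG
DDHSSRAIFPLQVGDPNQP-
>hom08
RPATLD-LRFQMLC-RRHL-YDLISVSGGYIVIQGFVRAMLCQVGVSLVTFLSSDYHPHY
QDVSSHAIFNLQVFGYNR-R
>hom09
MPRTLDGLI-EALLLRRCCTYCWIFGSVGAICIQGA-HIILQAVYVILLT-LDSDNTPYY
SDVYSTAIFPLQVVDPKRHR
>hom10
MPFTLLGLRAQQLLFRRCKFYDLIYVSGTYIVNQGRHRACQFAVVSGLLTKLCSDQ-PYY
VQVSSRYIFPLQV-DPERHF
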