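>S288c
MHPPRAPVPVILSGSQSPLESNVAVKIPHLSLPDSEYEEITRLLRLACAFDASVLLSTLG
GLSRLSKYLSFVLWR
>hom01
EHKPRAPVGVKLSGMQSPLESPIAN-IHHLALPYSEQEEIFILLRLACH-WPSELLSTLG
YLSRLSKYLPF--QR
>hom02
MEPPEAPVPVI-SGYASWLEAHEANKEPSLSLPDR-YEEHTRLL-CACY-DASV-LSTLG
TLHELEKYLSFDDWR
>hom03
-HPPRA-VMVI-SQ-PSPLG-NDIVKIPFLSLPDKEGGEITRLL-LAYAFDASVWLSTLG
GC-R-AKYLSCVYWR
>hom04
MAPPRKPMPVRHE-SQSLLESTMRTKIPH-S-FLHEYEE-TYLLRLSCAFAAQFLLST-G
GLSRLNMYLGFVLWR
>hom05
MHP-RA-LSVILSGFRSPLSSHVFVKI-HGSIGDS-SEEITRL-RLACAFDAMVQKMTKG
GLSTKEHYDSFGLGH
>hom06
MQPP-EGVPVILSGDQSPLESNVAHKIPDLSLPDWPTI--VWLFNLACAFDASVYLSTPG
GLSLLPKYLSDHLDC
>hom07
MHPP-RPVPDYLSG-QSGLESNV-WKIPHLSLGDSEYEEFHRLLVYACAFGGSGGLSTLH
GLSRLSKYLSFVWS-
>hom08
MHPPRAFVPVI-SGSRSPLESNGTVKFPHLH--DSEYEEITRLLRLAFAQDASRLLSKLG
G-SRLSYYCSF-LWR
>hom09
MKPPRAPVAVLLSIL-PALESRVAVKI-H-SLGGTEYQEITRLLRLSHADDATVLNPT-T
GI-RSLK-LYFVHVR
>hom10
MHPP-APVPVHLQGSQVKMLSSV-VKIPHK--PYLEYEEITRLLPLACAFDSNLLGSCCG
HLSRLSPYLVFVLWR
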