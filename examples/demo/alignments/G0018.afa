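>S288c
MRLPPDYLCYLGVQAVPWKHGSTANIRGLLPTYQSIDGRRVSVCCGQGLFSNLRTELSYQ
NSNARSTGVVLGMERDRHGRNGQRSQFEGEFSCPGVNFKFG
>hom01
M-APYDYLWYLSVQ-VPRKDGGTHNKRTLKPTGQCIRGQRVSV-KGQGLFSNLRTELSYR
ASN-RHTGGVL-CHR--HGRNGERWQFEEEFTCPGVNFKFG
>hom02
MRLPPQRLCRYGNQADPWKHG-TKNIGGKLNTYSM-DGRRVCVLCEQTLFWI-KTELSYQ
NSNAPTTVVVWFM-MDRHGRNGQRSNFRMEFSCM-VNF-FG
>hom03
HRL-PSYLCY-GLQAVPWKKGSHA-I-S-L--YETIQNRFVRQCQW-NSSFTLRTELSYQ
NSD-KSTGVVVGNVRD-HG-YGKHQQFEGGFSMPMVNLKFI
>hom04
MRTPPQYLCYLFVQTVPQKHGSTPNYRGLIPTYQVIDGRFVSTCRGQGLFS-S-TELSYQ
KS---STQVV-GME--NHYRNGQRSCKEVEFNCPPSIRKFG
>hom05
MILPPVYLCYLGVQAVPWKKGSTANLGGL-PTH--IDG-RVDVCCSQGLFSNLRIESS-Q
N-NATVTGVHLGMYKDCHKDGEQRPLFRGEESHPKVICKFC
>hom06
NRTPPLNLCRLGVLATLSKVGSFENIIGFLPNPLSIDGRGVSVCWVQVPFKNLRTELSVQ
WSDARSTGVVLGMMRDRRGRNGQYISFR-EFTCPGMYFKDG
>hom07
MTLDPDYLCGLQLQCVPWKHGVTAFIRGLLWTHYPIDMLVVSVY-GFGLGSNLRTEL-YV
NKNAR-TGTVLGDFRD-HRRYVQRSGGER-FSFPRTNFR-K
>hom08
MRLVPDYTCYLWVQAMPKKHGWTANIRGLLPQSQSIDHRRVYVVCGQGLFG-LRCEASSI
VSIARSTGSVLYMSRFAHG-NQQ--QFEGEFSCPGVELKCS
>hom09
M-LPPDYRCY-GVGARPWNHGSGANWRMLIITKQVIDGPRMSTCCGQGL-DNLDTELSW-
NQNARMTMVVQGMEHDRNGRNGQDSQFEGENSCPGVKNFHG
>hom10
-RLPQDYCC-SHVQAVPWKHGSTTMSR-LTPQYTSIDGRRMSVCIGVGLNMNKFTEL-YQ
NSNAVST-MVLGEEKDRHGDNGQFSQFEGEDSFC-VNTKFG
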