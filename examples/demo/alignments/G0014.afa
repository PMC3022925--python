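>S288c
MFKVGRPPEKCVVVKHSRQFVPMGESLKRISSALIEALTRATLLSSCVFRVSPSDSVVEA
RLQTCLSPSCFSSMPYLLSELAPPPLK
>hom01
MFKVVRPPEKCVVVKRSRCFVPMTESWKRIRSHLIAMLTRATLLESCEFRVSPKDSVVDA
RLQTCLKPSCFSSMPYLLSENAPPP-M
>hom02
FFKEGRPPEYCVVVKHQRQ-VPMGE-LKRISSY--EALTRYTLGSSFPFRVSMHDQV-EA
-LQTK-SPSCFSSMMYLLTELAYPPMK
>hom03
DTKV-RPPVKCEVVKTTRQF-MYGSQLKRIISALKEALTRNTLLSSCKFRRSSSDSVVEA
RLQTKLPNSCFWSMITLLSELEP---K
>hom04
MFKVGGP-EKCVKVKHSDQFVKMGGSGKRGSSARFHALYRATLLSSCVFRMSPSHSVVEA
RAQTCLRPYCHSGM-IF-SEFAPP-LK
>hom05
MAC-GMHPNKIVVVKHSRQFAPMGFMLTGKSSS-IEHLTRWTLLGHQVFRVSRSDIVFQA
RLESCLSPWCFSSMPYLASEWAPIPLK
>hom06
MTFVCRPPHKCVVVKCSRQFVPMHESEAR-SAD-IHALTRKTLLSSCV-RSSAR-MVGEC
RLQSIG-DSCFPSMWYLMSEW-WPP-K
>hom07
MFKVGRPP-K-VHCAHSRQLEPMGESNKHIQS-MFNALTRATLLS-CVERVS-S-SVVYA
RLAEM-SPSCFSSMPY-LSE-GPVFLK
>hom08
-FGVGRPPS-CMVVK-SRVFVYMVESLKRHISACLEALTRACLLSSCVHRVSLSDWVEAA
WLQTCCSPSQFSTWPY-LSELAPPRLK
>hom09
QFK-GNPDEKCPVVWHVVQFTPGGN-LIGISLVLYEALTRF-LLSSNVTGVSPFMWVVRA
R-QTCLC--VFSPMPYLLSELTPDPLK
>hom10
MF-VGRPPETCVVVKKSRQFVRMKDFLKRISSQLINALEVTTLLSSIVFRMSYFDWWVEA
RLKHCSSESCFESITYLMSYLAPPPLD
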