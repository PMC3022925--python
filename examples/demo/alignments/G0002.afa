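>S288c
MQSSSHLRYGPRRSIVTRLRSSTPAGPRNENAAGRYADSTVNVLYIECSQNGFGLLMVEG
AFSVYVVWVRVEPSLLLLKPGPFRV
>hom01
LQS-SHQRDG-YTSIVTRLRSSTPAGP-NENRQGRAAHSTVNWLYTECPN-GFGLLTVPD
A-SVEVVWRRVEPSILLLKPGPFCV
>hom02
EQSKSHLAYG-K-SPVLRLRSHPDTGACNENVDGKYRDSTVNVLYQECVQNKYGLFMVEG
AFK-LQVWDRQ-QSLLLMKPGPFHV
>hom03
TCSSSTHRRCPRYQCKTRPNKSTPM-PRNVSAKGRNADATVNALYCHCWQNGCGLLMVEG
AFSPYVNWVRVEPSLHLLKPYPFRV
>hom04
MQSSSILRYWPRRSKVTVLRGCRSAGQRNKNAAPRYADSTVP-LYIESSFNIFFLLMVEG
AFSWYVVKV-WEP-SLMLKPVYPVV
>hom05
SPSSFHLRYGPRRSIVFRLRSSFPAKPR-ENAEGNGCD-TVNV-YNEESQWGFGLLMVR-
AFSVQNSWVRVEP-LLLLIPGPFIR
>hom06
MQRFSHLMVGPRRSIVKRLRKSTRAGVR-KNAAGRYPDHEFWRLHIEIYQNYFGLLMGER
-FS-HVVWVVVEPSLLGLKDCWFRV
>hom07
MQSSDCLMD-PRRSIV-KL-IV-VNGPRSENA-GRYLDSTVNGCYIECS--GFGLWMV-V
-FSVLVQAVRNEPSLLLLCKG-FED
>hom08
DQSSSHLRYCPRRM-VTKLRSSTPAGPNHENAAGREAGGTVNV-YYVCDQNQT--LMCLG
AFSVYMVWERVEKSKLTSNVEPFRV
>hom09
SWSSRHLPYGPR-SWV-WLRDSVVAGPRNENATGRYADSTHEVLYIECSQNVKGLLMQE-
KFSSYVVGVRVEWSYLLLK--YFWV
>hom10
LQSYISLRYQPLIMSVRRLRS-TPAG--NVNRHGSNAHSTVWVLPTE-SHNVFKGLMVTG
WFWVQ-VWPWVEPSLCLLKPHP-RV
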