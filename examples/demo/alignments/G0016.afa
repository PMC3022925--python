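>S288c
MPANGLYFRSFKTSAKVSPLNRCRSEHTAWCPCVTTGTSWSTDAPRTQNGSTVVQVCPYS
DELPVEKHGQWMVTDDTCSNTHRLWDETIDVLGTSNLTRSMDPHNLGRCIHLINASG
>hom01
FPAHNTYFRSFKTRYEVSPLNRCVSEFTAMCWC-MTITSGARDAMRVQNGSTVLKVCFQS
MSDPVEKHGQWNPVDDCDSN-MRSWDETISTFVTSNLTVSMDPH-KGRCIHLINASG
>hom02
MTANGLPVESEKYSAKCSTQERCRMHHTADCWCMYTGTSWSTDAERTK-GATVVSVVPMI
-ILPDYPHRQWKVTDDTCSQTQAVWKCQIWHLPISLLTRCMDTHNLGPCIHLI-ASA
>hom03
MPAGGLYFNSFKTS-KVSPLNRCRSEHTASCPYRTTGTS-CADAY-TQNLATVV-VLPYS
DELPVKKRGQWMNTDDTCCNTHWLWKETIDVLGTSVLTRSGDP-NLGRCIKLI-ASG
>hom04
DIVHALYFRSFKNS-DVTPYMRCRSVHTAL-PCFTLGTSMGVDAIVYSNPSTV-QVCPYW
-ELKTMDHGQWMKTDWT-GE-NRLWTPFIDVLGTSNLVKSMDPHNLGR-LHLAHQSW
>hom05
MFAQGLYFTCFKQINKVS-LNRVRSEHRGWMPCVTTGG-W-TEYPGTWNGSTKVQNCP-S
NPLPVEKHKQWIVVDDTCSVTHRLQKGNIDVLG-SMRYRSMDPTDE-R-IHLIHWSG
>hom06
MPANGLYFRMFKTEAKERPLNRCRSEH-AGA--VDTQTCWSQHAVITQTMSHVVQFCPYF
LWLMVETMGQCMYCPATCSNTHFLIDETIDCLGTSNFTASWDPHRLDRCIHQ-NASG
>hom07
MPDISLYFRSFLTSQKVSKLNT-RSECTAWAPCVTLC-SWST-APRTQNMSTQCQVKPNS
DELPKEKHGQLMETDDTCNNTHRLW-EAIQVLGTGNLTRSPRPWNLGR-ILNE-DDG
>hom08
MPQGGL-FRSDKTSACVSPDNRDRWIHTALCPCHTC-TSW-TDAPKTQVDSTV-QTCPMH
DEEPVEKTGQW-VTDDTCSNT-RLW-YGIDV-GASCLTRHMMPQNLGRCINLKNASE
>hom09
MPAPNWHFRSFKPYAKFSNLNLCR-EHTAWHPCVTPGSSWSMGAPRTQLGSTPVQVKYYS
DQN-LF-HGQWMESWD-CSHTHRLWDE-IDWLNTSNLHRSMDPHYEGRCI-LKNASG
>hom10
DNANGLYFWSFKTSAYSSKLNRCASEHTAWCPCVTCGESWPTDAPRTKNGSTVVQEEKLS
DELIVSK-G-WMYRDDTCSNHPRPNDHTIDVLIT-NTTRRSD-HCLGRCIHLINASG
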