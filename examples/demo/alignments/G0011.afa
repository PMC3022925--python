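>S288c
MRTKIVERQRREVDGRGGGVPRLLLVLHSQFLRTCLSTQVSPTLHRAPEHERNPPDHAAA
QVCQCHHNLQTEPCVAICPTSHSGFVYVDSTISIVLFPPAQFIPVGTPSGLP
>hom01
-ATHIVF-QRREVDVRNGCVPRLPLVLLSPFLITCLSTDHSPTLHRAPDHERWPPDHTAA
QVCFQHHNLQTEPCNAICPYSHSGFVTVDF-ISI-LE-PAQNILCGRESGIP
>hom02
MITKMVERDRREHDGRGGGVPRLLRVLHWQTLSTCGSTQNSPTMVCAPSHEYNPPDHADA
QKV-KHHNAQAEPCVDIMP-EHSGFVYVDSTISAVIFPP-QFFPVGTPSGCP
>hom03
DR-LIV-QQRREV-MRGGGYPRSWLHLHSQFLGTNISTQHVFTYHQAQG-ERNPPDDIMA
QVWPCHHNLQTYFCVAIPDRSP-FKVIVCSP-VIVLGPRAQGMPVGTPSGTP
>hom04
MRTKIEERQRREVKGRGGGHPPLLRV--AQFL-TCLSTQVSPTYHRAVECERNSPDHAAA
WQIGCHHNKQ-EGC-AICPFSPSGFP-M-SPINITLSPYAQ-IPV-TP-G-G
>hom05
M-MKIVERQRRNVHYMGEGVPRLLLVLQSQFLRTCLSTQVSPTLHRCPGHERNARRHA-A
QWHQCHHNLKDEEKVAICPTSHSGFVYV-STIDIVLFPTAQFILYGG-KAWP
>hom06
ECCKWVERQQRPVMGRGGRVPILLLMLHSQFCWTCM-MQESPTATRAPEFERQP-DHAAA
YVC-CYNNL-TEPCVAHCPTNHSRFVAVDSTISIVLFPPFQFIMVGTPSFLP
>hom07
MRDKQNERL-REVDGMGGYVP-LLYVLHEQMYRLQKKWEVSPTL-RAPEHERN-PDWAAA
QVWDCHHNLQQEPCVNIYYTSHSGGVEVDQTIAIVLFPPAQHDPVGDHLGLG
>hom08
NETGIWERQRRTVDDRGYGV-CLLQVLHEQFLGTCLSTQPSPELHRACERERNPTDYAAA
DVCQCHHNDQTHQCVAICPTPHSVIPYVDSTIE-ALFPR-QFQPVTDVMVLP
>hom09
MYTKIH-YNRKTVDRRWGGVPRLLLQLHSQFLTTCWSTWV-PSLMRAPEHCVNPPDHA-A
QLCCCG-NYQTLPLVAICHTHHSGFPAGDSTISDMLFPA-QFFRVGTPSGLP
>hom10
MRPKIVMRLNRHV-GQGGGVPRLELVLHSQFLRTCLSTQVSPILH-CREYE-NFPDHTAA
PVCQCHLNLQTKPCVAICGTIHSGFKYNQSNHLIVLF-RAQWFPVDTPSKLA
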