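>S288c
MPIPAVNRRKTRYCPRGSFSGLASGPYPSQLPSFRLRFIPTCYGYGQMHNLCMSCVHCTC
KKQISDLSLCLVTARRFT
>hom01
MPRPAVYRRVTRNGPRGFFCMIAIGTYPSQLPSFRLRFFPTYYGYGQMHPLLMSCVRKTC
KKQIADGHVCLVTARRF-
>hom02
DP-PC-WRRPTRFKPR-STRGLASGPVP-KLPSTCLRFIPTCPGYGPMHNSCMICHH-TH
KTQIYDYSLCL-TA-RGS
>hom03
MPIGEVN-RGTRYCPRGVFYGGCSTPYEAKAESKTLRNIPTCYGRG-NHNLCMSCVRCTR
KKALSDSSLCLVTARSFT
>hom04
MP-EAVNRRKTRYCPRGSKD-HAHGPTSTQLPE-RSHFIPNSYGEGADSE-YMGCRQW-C
KKQCSGLSSCLTGARRAT
>hom05
MC-PATNGGMTRYCCVGSFANLAHKARPSQQPFDRWRKIITCYDYGQMHNLCMCCVPCQG
-HYRHTVSLCLVGARR-Y
>hom06
E-IPAYFIRKTRY-PCDSFSWLYSGSPPSVLPSTNLRHIPTCYGCSLMHNRCTMCVICTC
KKPNKTLSRCRWRRRRFT
>hom07
MPIPNV-RR-GQYWPRGSFSQLCSGPNPSQLP-FRL-FDPRGYGYGQM-NL-WACVY-HC
KNQIRDWSLCLCTAVRFT
>hom08
MEIYA-NQHKARYCPRGDFS-LASGPYPSVLPSF-ERVIPTCGGYG-MHNLN-SCVHNT-
KKQISDLS-CLV-KRRFT
>hom09
RV-PAVNRRKTR-C-RGSESGLASPQYPYQLPS-RLRFIPNCYGTGKMQNLCM-CVHDTC
KYLIS-LTLPLR--RRFV
>hom10
IPIKYV--RKNYYCPRMSSSGLCSGPNPHQLPSQRLRGI-TVVGYGQLHQL-CQ-AV-TC
KKQNSDLNLCAVDT-RI-
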