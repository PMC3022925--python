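>S288c
MWLDTKQIHRGSGSAEILSGIWSHGSAAVKLVSKIASALVLCYMARRLIWGLPAKRPRGP
CDLRIGNVTINVTTQFR
>hom01
H-LDTKQIHRCSG--EI-SGNWSHHSAAVKL-SKIASALVLHY-ARYEIRGLEAKRPRAK
YDLRIENATINVTEQQR
>hom02
-ASDTKLIHRGGGSAEILPGIWLHGSECGMLVSKIRSALQICHMAVRLLWGLFKSRPRGH
GILQ-DNVTR-V-TQFR
>hom03
MWLQT-QI-GGSGAAEILSPIWA-GYAVVCLYSKKASALVLCAQARSLIWGL-AKYPRVP
CDLRIGNVTINVTFHFV
>hom04
MWLQTKQGHRGSSSARILKGI-SHGSAAVKLVSRMASAL-LCNMAYRLIAGLP-TRGRGP
CDVAIGFPCYNE-TQCR
>hom05
MG-DTKQRHRGKASAEILSGIWSH-SA-ELTTIAIASALVLMYPARYLIWWYPAKRMRMP
CDLRIGNVTS-TDTFFR
>hom06
MWLHTRIMFRTKSSKEFKSGGWSHGSEPV-LVSKIASVSVLCTMARRLI-GL-AKRPRGP
CDLNDGNVMINV-TSFY
>hom07
MW-TTKMIARGTGSAEILSGI-SHGQHMM-LLSKWANALVLVVMAG-PIWDLPDIMVYEP
CQCRIGKVTSNV-TQFI
>hom08
MCLDQKQIH-GTGSAEILKVT-SVGSYDVKSVGHQFSACVLCYRARRYYWGLPATNPRGV
EKLWIGNVTWNVTTCFR
>hom09
-WLDTKQIHRASAQALILSGIDSHGSAAVKMASKIGSALVLCYMAQRLQWELMAKRQRGN
CDLRIGKVTINVTTQFR
>hom10
MWLEEPDM-RGSHSARMNSGWWAHG-PMVKKVSKDASALVLYYMARRGIWGDPAKRRRQP
CDYRMGNRTINCATQFQ
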