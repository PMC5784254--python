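>ac_synthetic_01
EHEKRQYTPSSRKDTSRAACGRSQAWDPSRPSNWQNEARRWYPPYYSPPE
>ac_synthetic_02
AWSDRQYPDSSRKTTSRASCGDQQCWDPGRYSNWQPNGRTWCPPENSWQE
>ac_synthetic_03
AWEDRQYPDSSRKWTSRASCYDSQAWDPWRY-NWQNNGA--DPPQPDPPW
>ac_synthetic_04
AWEDRQY-DSSDPWTSRYACGDSQ-WDQSRYSNWQNNGRTWEWPQNSPHE
>ac_synthetic_05
AQEDRQPSDSSPKWTSRTACHDSQAWEPSRYSNWQQNGRSWEPPQNSPPE
>ac_synthetic_06
AWHWPQYPDSSRKETSRAACGDSQAWDPSRNSNWHNNGATWEPPQNEPPE
>ac_synthetic_07
AWEDRQYPDSYRKWTSRACCGDSQAWDYSRYSNWANNGRTWEPPQGSPNE
>ac_synthetic_08
AYERAQYPDSSRKWTSRAACGNSQPCDP-RYSNWQNNGRTKENPWNSPPE
>ac_synthetic_09
WWEDPQWPDSSNKWTSRAACGDSQAWDSSRYSNWQNN-R-DEPPQNSPPE
>ac_synthetic_10
DREDRQYN-SSSKTTSRAA-GRSH-WDPSRQSNWYNNGAKWEPPQNSPPE
>ac_synthetic_11
AWESRQYPTSSRDWTSRKATGDSQAWDAQSYSNWQNNCRTWCPPQNSPPE
>ac_synthetic_12
AWEDRQDPDSSRKDTSTADCGPSCAWDPSNYSNWQNNGRWWSPPQNSPPE
>ac_synthetic_13
AQEDRQKPDSSRPWTSAAACG-SQARCPSRYSNWQNNGRTREPPQDSPPE
>ac_synthetic_14
APYDRQTPDSSRKEPSRWAGGDAQAWDPSRYPNWQNNGRTWEPPWNSPPE
>ac_synthetic_15
-WEDRQ-PD-SRKWWSRAYCGDSQAWDPSRYSNWWNNTRKWEPPQNSPPE
>ac_synthetic_16
AWRYRQAHDSSRD-NSRAACGSTQYWDWSRHNPWGYNAREWEPSSASPQA
>ac_synthetic_17
AWEQKQYPPDSRKWTSNAACGDGYAWPPSYCYNWQENRPTWEPPQNSPPC
>ac_synthetic_18
AWYKRQYPDSSRKWTSRNACGDSSAWDPSGYSNWQGNGRTWEPPQNSPQE
>ac_synthetic_19
WWEDRQCPDSSRKWTSRAACGDCQAWDPSRYGNWQNKGRQWEGPQNSPPE
>ac_synthetic_20
AWCDRQYCTQSRKWTSQAACGDSQAWDPSRCSNNQNNGRT-EPPQNSPP-
>ac_synthetic_21
AWEDRQACRSSRKWTSRAACGDSQARDPYEYTGWQNNGDGTEPPQNQPPH
>ac_synthetic_22
KWEDRQGPDSSRAATSRAAKGDAQAWDPSRGRNQRSTGYTWEPPQNCPPE
>ac_synthetic_23
QWDDRQ-HDSS-HWTNRAADGAPQAWDPSRPSNQQNNKRTDEPPQDKPQE
>ac_synthetic_24
K-EDDEYWRSSRKWTSRAWCWDSQERDPSRRYNWQNNGRTWEPPQESGYE
>ac_synthetic_25
PWE-RQYPDSSRKTTSYAACGDSASWDPSRYSNWQNRGRTWEDWQNSSSE
>ac_synthetic_26
AQE-RQYYDGSRKWTHRAACGDSQNWDPSRYSNWQNTGRTHEPPANSPPE
>ac_synthetic_27
TNEDCQWPDSERKWTSRAWWNCSQAWDPSRYSNWQNCGRTWKPPQNSPPE
>ac_synthetic_28
CWQDRQYPDSSRKWTSRAACPDSQAHDPSRYSNWQNNGRTWEPCNNSPPE
>ac_synthetic_29
DWQDAQYPDSSREWTSRTA-GDSYAHEPYAYSSQQNSGREWEPPGNSPPE
>ac_synthetic_30
W-E-DDDYDSARKWCSRRACGDSQPWDW-RNSSGQ-NWRTWEPNQNSPPE
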