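>pde_synthetic_01
CTCDKNKDAYDDHAEACDNCNQYATWYNWWKDES-AKNGQDETNKDGAYE
>pde_synthetic_02
CTCDSNTDAYPDHAEDCDNCQQYATWYNWEKDASHASNGEAETNNDTGYE
>pde_synthetic_03
CECDSNKDPYPDHAEYTDNCNRYHTWYNWWKDESHAWNGE-ETYNDTDHW
>pde_synthetic_04
CTCDSNKDKETDHAEYEDNCNTDATWYNWWKDESHASNGEDETNNDTDYE
>pde_synthetic_05
CTCDNNKSAEPDHTEYADNKNQYATWQNWWKDEEHASNSEGETNNWTDPE
>pde_synthetic_06
YTCDSNHPA-PYQAEYCDPCNQYAEWYNWRKDDSHASNGEPETDNDTDYE
>pde_synthetic_07
CTCDSNKDDCPDHAEYCWGCNQYRTWDNDWKDESH-SNGEDETNNDTDYE
>pde_synthetic_08
CTCDHNKDGYPDHAEYCDNSNQYATWYNS-KCESHATNGDDETNNYTDYE
>pde_synthetic_09
CTCDSNADAYPDHAEYTRNCNQYATWPPWWKQESHATNGEDATNSDPDYH
>pde_synthetic_10
CTCDSNKDTEPDH-TYCNNCNQYRTWYTWWKDESHARNGKPEPNYDCDYE
>pde_synthetic_11
CTCDSNKRAYPDHAEYCDRCNQYANW-NHWKDRCSASNGPCETNNDTDEW
>pde_synthetic_12
QTCDSNKDAYPDHYEPYDNCNQYPT-YEWWKDES-ASN-EDETNNDTDYW
>pde_synthetic_13
CTCDSGHDAYPDHAEYCDACNQYATWYNDWSDTSHASNGEDECNA-TDYE
>pde_synthetic_14
CTCQSNYDAYPDQAEYCDACNQYETW-NWWKDESHCSWGEDETNNDYDYE
>pde_synthetic_15
CHQDANKNAY-DHGEYCDNGNQYATWYNWWKDESHASNGEDEQNNDDDYE
>pde_synthetic_16
CNNDSNKDKYPDHS-YCDHANQYATWYNWWKDCSHAHNGEDTTNCDTDYE
>pde_synthetic_17
DTNDDNKDAYPCHAKYCDNCNQYATWYNPWKDESHASNYEAETNHDTDYE
>pde_synthetic_18
CTKPSNKDACPDCAEYCDNC-QYANWYN-WKDPSHASNGEDETYNDCDYE
>pde_synthetic_19
CTCDSNKDAYPDHAEYCDNCNPYAQWDNWWKDESPAS-GEDETPNDTDCE
>pde_synthetic_20
CTNDSYKDAYPDHAEYCDNCNQYATWYNWRKDESHASHGEDETNNDKDYE
>pde_synthetic_21
-TCDSNKDAYPDHAGYTDNCNQHASWYNWWQDECHTWNGEDETNNDTDYE
>pde_synthetic_22
CTCDSNKDACPNHEEYCDNCNWYATDNNWEKNESHASNGEDETNQDTDY-
>pde_synthetic_23
NSCDSNKDAYWNSAEYCDNCKQYATWYNWWKDKPHWSNGEDETNNDRQYE
>pde_synthetic_24
CTCDSNWPPYPDHAEYADNCQQYTTWYNWCKAESHASNGEDETGDDTGY-
>pde_synthetic_25
CTCCSNKDQYPQPCEYCDNCYQYAQNYNWWKDCSHASN-EDE-NNNTDYS
>pde_synthetic_26
CTKNSNKDA-PDWAEYYDNCNCYATWYNTWKQEKHASNGEAEQNNDTNYE
>pde_synthetic_27
NTCDRNKDWYPSHAEYDDNCNPYPTKYNWWKWEPHESWGEDETNNDTDYE
>pde_synthetic_28
CA-ESNKDAYNDHAEYCDT-NQ-ATWYHWWKDTSHASNGEDEGNADTDSE
>pde_synthetic_29
YTCDGNKDAYWDHKEYCQCCNQRATYYNWWKDESHASNGEQETTDDTDYE
>pde_synthetic_30
CTCGSWKDAYPCHAEECDNCNQYATWYNWWKDES-ACNRWDETNNDDDYE
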