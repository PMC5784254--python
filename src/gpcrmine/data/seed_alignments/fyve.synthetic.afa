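>fyve_synthetic_01
WAQTTAWSSSKNSTARKWQQNECPHRCPGGGGSSGQDGES
>fyve_synthetic_02
WAQEPN-SSSKNYAARKWQQTESPHSCPGGGRSGGTDGES
>fyve_synthetic_03
WADDSNYSSS-NSTYNEWPQWECPHSRPGGKGSGGGDGES
>fyve_synthetic_04
WAQDDNSSSSCNSYARKWQY-ECPHSCPGGGGHGGQGGES
>fyve_synthetic_05
WAQDSKWSSSKNSWARKWQAWE-PHHCPGGGGSGGQDQES
>fyve_synthetic_06
WNQDPNYSSSKNSTARK-QQNECPHSCPGGGGSGGQDGES
>fyve_synthetic_07
WAQ-PNWSGSKESS-RKWQPWEPNPPCPGGGGSQGQDGEG
>fyve_synthetic_08
WA-DYNWSSSKNSTARSWQQWEKPQ-CPDTGGSGGQGGES
>fyve_synthetic_09
CEQDPNNSSSKNSTADKWQQWYCPNSCPGGNGSG-QPGSN
>fyve_synthetic_10
WAQKPTWSSQKASTARKKQQWECPHSCPGGGGSGGQDGES
>fyve_synthetic_11
WAQTPNRSSSKESTARKWQQWEPQHSCQGGGCSGGQDGES
>fyve_synthetic_12
TAQDPNWSSSKNWNARKDQQWEC-HSCPEG-GSGGQNHEW
>fyve_synthetic_13
W-QDPCKSDSKYSTARKWQQHECPHSCPGGGGNEGQWPES
>fyve_synthetic_14
WAEDPNWKSSKNSTARSWQQW-KPHSCWGGGGSPGQDGES
>fyve_synthetic_15
WAQPPNWSPKKNSTARKWQYR-CPHSPPGGGGSAGQDAES
>fyve_synthetic_16
WPQDPNWGSSKNSTARKWQRWECPHSCPQGGGSGGQDSES
>fyve_synthetic_17
HAQGPTWYSSTNG-WRAAQYWECPPPCP-GGGSG-QDGES
>fyve_synthetic_18
WAQHPNGSSSKNSTARTWQQWECPHSCPGGGGSHGCDGES
>fyve_synthetic_19
WAQ-E-WSSSKNSHAR-WQKWECPKSCPGGGGSTGQQGES
>fyve_synthetic_20
CAQHPNWGSSYT-TCRKWQQRECWHSKWHGGGSGGQDWRS
>fyve_synthetic_21
WAQDPWWSSSKNSTARKWQQWECPESTQG-GGSGHQDGE-
>fyve_synthetic_22
WAQDPNWSSSKNSTARKWQCWECPHSCPSGGGS-SDDGES
>fyve_synthetic_23
TRQTPNWGHSKNS-ARKWQQWGCPHSDPGGGGSGNQDGRS
>fyve_synthetic_24
DAQDPRWRSSKNYTARKWQQWPCPKSCDGQHGWGGQDGES
>fyve_synthetic_25
WAQDPNWSSSKNSTARKWQQWECPHSCPGHGGWGGQDGEQ
>fyve_synthetic_26
WAQDP-WSSSPNSDARGWRQWECPHDCPGGGGHGGQEGES
>fyve_synthetic_27
WARDPNWSSSKNSWKRDWQTWECPRSCCGGGGSGGQNGES
>fyve_synthetic_28
WWNDPN-SSSGNSHARCWQQWECNHSCPG--GSGGQDGES
>fyve_synthetic_29
WA-DPNWSSAKNSCARKKQGWECPHSCPGG-GSGGQDGES
>fyve_synthetic_30
-AQAPHWSSSKNSTARKNDQWECPHQCPGGGGSGAQDGES
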