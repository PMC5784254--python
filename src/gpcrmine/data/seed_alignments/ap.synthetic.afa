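>ap_synthetic_01
S-GYSWQQDAGWEAKNTHCGNNYGTASTQDSDGQAHPCSTDHRKGAGKQQKTDRK
>ap_synthetic_02
AQ-QKWQQDAGAHQQQRCCKNNYGTA-TQDSSGQGHPCSTDQRKGNGKQ-PEDRK
>ap_synthetic_03
SPGQKWQSDAKWEQPNRHCKNNYGTSGTW-SSGQTHPCWTDTRPGNGKQQPKWRK
>ap_synthetic_04
SPGQKWQQ-AGWEAPN-HCKNNEGTNKTAGSWGQAHQHSTDPRKGNGKQQPTDRK
>ap_synthetic_05
SPGQKWQQD-GWEQPNNH-TNNNGTAKTQDSSAQSHPCSAQPRKGNGKQW-TDRK
>ap_synthetic_06
SPGQKWQQDAGWEQPNRHCK-NYGTAKTQDSSGQAHDPSTDPRKGNGNQQPTDQK
>ap_synthetic_07
NPGKYWQTDNGWPGPNQHCKNGYGTAKTQDESRQAHPDKTHPREGNG-QHPTYRK
>ap_synthetic_08
SPGQKWQQDAGWEQPNTHCKRHYGTHR-Q-SSGQAHPCSTDPRKGNGKQQPGDRK
>ap_synthetic_09
SPWQKNQQDAGWEQPNRNCKNNYGTAKYQYSSGQAHPCSTDPHKGKGKQQPCDRK
>ap_synthetic_10
QPGKKWQQDAGW-QPNRHCWNNEGTDKTQDSSGQAHPGWTDPRKGNGKQQP-W-K
>ap_synthetic_11
SPGQ-WRQDAGWEQPNRSCENNYGTHSTCDSSNDHHPCSTDPRKGNGAQQPTDRK
>ap_synthetic_12
SPRQWWQQDAQWEQPNHHCCNNYGTAKTDDSSGSPKPCCTDPRKGNGDQQPT-RS
>ap_synthetic_13
SGGQTWQADYCWEQPNHHCKNHYCTARTQDSGGQSHPCSRDPRKGNPKQQPTDRK
>ap_synthetic_14
SHGCKWQQRAGW-QCNRHCKNNYGTCKTQDSSQAGHPAQTWPRKGNGKQQRTDRY
>ap_synthetic_15
SRGQKWQQDAGWEQSNRHCKNYYGTNKTQDRAGQAHPCSTD-RKGNWKQQPTDRK
>ap_synthetic_16
SPGQKWQRDAGWEPPNPHCKAPYGTAKTHDSSGS-HP-STDPRKGNKKHQPTDRK
>ap_synthetic_17
SPGHKWQQHQGREQWNRHCYNNDGTAKTQWSSGQAPPCSTDPTKGDGKQQPTDRK
>ap_synthetic_18
-PGQKWQQDAGWEQP-RHCKNNSGTGHTQDSSEQRHPCSTQPRKGN-KQQHTDRY
>ap_synthetic_19
SPGQKDQQWSGWWQPNRHGKNNYGTAKTQDSSGQAHPCSTNPRKGKGKPQPTDRK
>ap_synthetic_20
SPGQKYQGPAGWEQPPRRC-NNDGQASTQDSSGWAWPCSADQRQGQGYQRGTDRK
>ap_synthetic_21
SPGNKWQQDHGWNQPN-NCKNNYGTAETDDSPGA-HPCSTDPRKGNGKQQPTDRK
>ap_synthetic_22
PCGQKWQQDAGWEQPD-KCKNNYGTKKTQDSSYRTHPCSTDSRQGNGKQQPTDRK
>ap_synthetic_23
SPGEKWQQDAGWEQTNRHCKNNCGTGKTCDHSGQAHPCS-DPRKGNGKQQATDRK
>ap_synthetic_24
SPGQKWQQDAGWEQPNR-CKNHKYTAKTQQ-SGQAHPCSTDPRAGNGSQQPTDTK
>ap_synthetic_25
PPEQKWQQCPGWKQCNRHCKN-KGTAGTGDSSYQAHPCSTDCRKGNGKQQPTDRQ
>ap_synthetic_26
SPCRYRQQDAGWEAPNRHCKNNYDTACTQDSSNQWHCCRTGPRYGNGKCQPTDRK
>ap_synthetic_27
SDGQKWQQDAGKEQPWRHWKNYYGT-ATQDSSCQAKQCSTWPRKGQGTQQPTD-K
>ap_synthetic_28
SPGQK-QQDAGWEQRNRHCKWNYGTEKTCDSQGQAHPCSTHTQRHNGKQQPTDDK
>ap_synthetic_29
SPGQKWQQRAGWEQPNRHCKCNYGTAKTQDNSGQDHPCSTDPRYGNNKKQPTDRK
>ap_synthetic_30
SPGQKWCQDAGWEEPWRHCKNNYGTAKTQDRSGQAHPCSTDPHKGNGKQHPTDRP
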