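>dep_synthetic_01
HQPHCCANYNAKRTHDEGDKKPHDPNPRERDPTSNSAHWR
>dep_synthetic_02
NTPHCCATYRAKKTEDPCDGPPHDPNKDWCHPTSNSRHSR
>dep_synthetic_03
NTPHCCRNYRATRTEDPEDKCPNDPNHDWCHPTSNSAHWR
>dep_synthetic_04
STPHCCANKRAKRTADKCDKCEHDPNCDWCHQTSNSAHYR
>dep_synthetic_05
DTPHCCNNYY-KRT-DPCDSKPHDPNNDWCHYTSNSCHHG
>dep_synthetic_06
NTPNCCARYRAKRTGDPRDKCPHDPDPDQCHPTEDSAHWR
>dep_synthetic_07
NEPHCCANSRQKRTGDPCDKCPQDPNPDWQ-PTQNSAEWR
>dep_synthetic_08
NTAGCDANYRA-RTGDPCDKCPHDPNKEWCHP-SNRAHWR
>dep_synthetic_09
NTPECCANYRAKRTGDPCDKSNHSPNDGWCHWTSNSAHWR
>dep_synthetic_10
NK-HCCANHREKGTDDGCDDCPHWWEPDWCAPTSN-AHWQ
>dep_synthetic_11
NSPHRCANYRSRRTGDPCDKCPHDPNPDWSHPTQRSAHWR
>dep_synthetic_12
NTPGCCANYRAKRTKDWCPKQPCDPNPPWCEQTSCSAHWE
>dep_synthetic_13
NTPHCCANDTAKRTPCYCDKCGHDANPDWCHPTCNSAHWR
>dep_synthetic_14
GQPHCCANYQAKRTGHPCDKCPGDPNPDWCHYTSNSAHWR
>dep_synthetic_15
NTPHCYANYRAKRTGDPCDKTPHDPNPEWWHPE-NSAHGR
>dep_synthetic_16
CQPHCEANYRAQETGDPEDKCPHD-NPDWCHQTSNSAHWH
>dep_synthetic_17
NTPHCKANWRAKRTHDPTDKCPGDPNPDWCHKTENSAHWR
>dep_synthetic_18
NTPHCHANWRA-ST-SPCGKCDHDPNPDWCKPTSNSGNWR
>dep_synthetic_19
TTPWCCANYCAKRPNDCTDKCPHDPNPSWKHSTSNSAHWR
>dep_synthetic_20
CGPHCCAN-RAKRTGDPCDKTQHCKNPDWCHPTSNYAHWR
>dep_synthetic_21
NTGHCCAPY-AKRTCDPCCKCPHKPNPDRCHPTSNSATWR
>dep_synthetic_22
NTPHCCARYQSKRTGDPRDKCPHYPNPDWEHPRSNDAHWR
>dep_synthetic_23
NTPHC-SNYRK-RTGDPCDKNPHDTNPDWCHPTSNSAHWR
>dep_synthetic_24
NTWHCNACYHAKRS-YPCDKCPHDPNPDWCHDTSNSAHQR
>dep_synthetic_25
NTPPHCNNKRAKRTGDPCDKWRHHPNPDWTHPWSNSPHER
>dep_synthetic_26
NTPHCCATYREKRTGDPCDKC-HDPPPDWCHPDSNSAHWP
>dep_synthetic_27
NTPHCEANYRAKQTKDQCDKCPHDPNPDWCHPTSNSDNWR
>dep_synthetic_28
NTPHCCANGRAKRTGD-CSKCAPDPNPDWCHP-SNSAHWR
>dep_synthetic_29
NTPDCCSNYRAKHTGYPCDKCHHCSTPDWAHCTSNSAWWR
>dep_synthetic_30
NTPHCCRN-RAKR-GSPCDACPHDP-PDWCHPHSNNASWR
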