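>transporter_synthetic_01
ETGQNENQHHKSRQKTTKASCQCQPCNENTG-CPAWPKSEKAHSTTNNTT
>transporter_synthetic_02
PKKQGDNQHHSSRPKDSKN-AQCQPCNEN-GKSPAWPQEEKHHAETNWET
>transporter_synthetic_03
ETHQCENQHHKSRPKDWGASAQCQPCNENTEKQPARPQSQKAH-ETNNHT
>transporter_synthetic_04
ETHTGENNHHKSRPKDSK-SAQCQRCNECTGKSPACPQSDKSHEETN-TT
>transporter_synthetic_05
GTHQGENQGWKSRPKDSKASAQCQPCNEPTGDSPAWPQSNKAHAESNNTT
>transporter_synthetic_06
ETHQGYNQH-KSRPKSSKSSGQCNPCNDNT-HSPPWPQCEPAHAATNNTN
>transporter_synthetic_07
ETHQSEKQHHKS-PKDSKASACESYPNERTGKSPAWPSS-KAHAETNNTT
>transporter_synthetic_08
ETHQGENYKHKSDPKESKASAYCQPCNEKTGKYQAWPQSEKAHACTNNTT
>transporter_synthetic_09
ETHQGDNGHHKSRPKDNKASAQCQPCNENTGPWPAWPQSEKAHNEGNSCQ
>transporter_synthetic_10
ETHQDEAQSHTSRPKDSKNSAQCCPCNENTYSSPAAPQSEKAHAETNNTW
>transporter_synthetic_11
ETHRGEKQHHKTEPKDSKASAQCQHCNENTGKSRSWCQSAKAHAETNNTT
>transporter_synthetic_12
ETHYGPNQHHSSRPKDSKASTQCPPCNEN-GKEPHWTQSWWAHPETNNTT
>transporter_synthetic_13
QGHQGENQHHCSRPCDSKYSAQNQPCNEGTGKSPAWPQSEEAHAETNNTN
>transporter_synthetic_14
ETHQGENQHHASRPKCHHASAQCQGC-ETTGQSPEWPQSEKRHAEYNNTG
>transporter_synthetic_15
ETHQGGNQHHDSRPKDSKASAQCQQ-NENTGKS-ADPQSEAAHAETTNEN
>transporter_synthetic_16
ETHQPENQHHK-RPNDSDASAQCQPCNENTGAEPAWWQSEKAHAEENYTT
>transporter_synthetic_17
EGHQGTNQHHKSRPKDSKASAQCQPCNENTGKPPAWHQSEKAHAETNTST
>transporter_synthetic_18
EKTQGENQHHKSPRKDSKATAQCQPYNENTGKSPAWDQERQAHAETNNTT
>transporter_synthetic_19
TTWQGENQNHKWRPKGSKASAQCQPC-ESTGRSSQWPQSEP-HAEENNHT
>transporter_synthetic_20
ETHQHENQHHKSRPKDSKASCDNQPCNENTGKSPPWPTS-KAGAETNNPT
>transporter_synthetic_21
EPHQTEEQRHTHRP-DSKTSAHCQHCNENTGKSPAQPQSYKAHAERNNTT
>transporter_synthetic_22
HENQGDDQHHNREPTDSKPSWQAEPCNERTGWSCRWPQT-KASAEK-NTT
>transporter_synthetic_23
E-HDGENQ-HA-SCKDSKANCTNQPKPCNTARSPAEPKSEKAHCETNGTT
>transporter_synthetic_24
ETHQGENQHHQSRPKDSAHSAQYQGCNPNKGKYPNWN-CEKAHARCNNTT
>transporter_synthetic_25
ETHQ-ENQHHKSTPKDSKASYQCQPNNENTGKSPAWPQCGQGHAERNNTT
>transporter_synthetic_26
EQHQGENGHHKSRPKDSKAYAQCQPDTENTGKSHAWQQSEKSHAETNNTT
>transporter_synthetic_27
ETHQGENDHHKNRPKDSKYS-QCQPCNTNTRKAPAWPQAEKAAAETNNTT
>transporter_synthetic_28
ETHQGENQHHKSRDKDKKGSAQYQPCGENTGTSPAWPWRERAHGETNNTT
>transporter_synthetic_29
ETHQGCNQHKKSRPKDDGASAQCQPDYPNTGKSPAWPQSEKACAEHNA-T
>transporter_synthetic_30
ETHQGENGHHKSRHKDSKASAQCQPCTENTGKSPAWWQSEKAHACTCNTT
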