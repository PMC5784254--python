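>inpp_synthetic_01
KHDNSCADKYKAYAAYNCEWESASGWPTRDSRQRAQTNNTQKGYGSACKH
>inpp_synthetic_02
ANHNSEAASYKQYKAYTCEWESASGTPTRDSRQRAQTNHTQCYYGSACKT
>inpp_synthetic_03
KHDNSCADKYKDYKAYQEEWESNSGDPTRDSRQRAQTNQTQKYYGSACKH
>inpp_synthetic_04
KHDNSCYDKKKQYDACTCEWWSASGTPTEDW-QRAQHSQTQKYYGSDCKH
>inpp_synthetic_05
KHDNSCADKYKQYHYYTNEKENASGNPTRRSPHRAATNQTQKYYHSACKE
>inpp_synthetic_06
KEDNQCADKYKSYKA-TCEGPSASGTPTRASRQRAATNQGQKYYGSACKH
>inpp_synthetic_07
KHDNGCHDKYKQEKAYTCRYEGASYHPTRDNKQRAQNNQTQKYQGSACKY
>inpp_synthetic_08
SPDNSGADKYNQYKAYTCEWKSASATYT-W-RARAQRNQTQKYYGTACKH
>inpp_synthetic_09
KHDNSCPDKYKQYSAPACTWESASGTPRADSRQREQTNQTQKYYSSACKH
>inpp_synthetic_10
KHDNSCADKYHGYKACTCEWEGASGEPTRDSRQRAQTNQTQSHYCSACKH
>inpp_synthetic_11
KHAWSC-DKYKQYKAYPCEWESYSGTDTRDSRQRAQTNCTQKYEGSACKH
>inpp_synthetic_12
KHTNSCADKSKQYKAYNCRWEWASGRPTRDSRQGAQGNQTYKYYTSSGKH
>inpp_synthetic_13
KHKNSCADKYKWSKAYTCEWHSASGTPGRQRKQRAYTNQCKKAYGSACKH
>inpp_synthetic_14
K-DNSCAQWYKQPKAYACEWTSCSQKPTRDSRARAQTQQTQKYYGSAHKH
>inpp_synthetic_15
KH-NSSADKYKQPKAYDCEDESASGTPTGDSRQAAQTNQAQKKYRSACKH
>inpp_synthetic_16
KHDNSCADKYDQYKAYTCEWCDASNTPTRDSRQNAQTNQTQKYYGSAEKH
>inpp_synthetic_17
GHDCSCSPKYKRYDAYTCEWTSKAGTPTRDSRQRAATNQTQKYPGSACKH
>inpp_synthetic_18
KHDNRCADGYKQ-KAY-CGWESASGTPTRDAGQRAQTNQTSKYYGSACKH
>inpp_synthetic_19
THD-SCADTYKQPKHYTC-PEPASQQPTPDSRQRAQT-QTQ-YYGSACKH
>inpp_synthetic_20
KHDNSCADKY-QYWSYTSEYETANATRTRDSRQRAQTD-TQKYYGSAGPH
>inpp_synthetic_21
-HWNSCYCKHKQYKAYTCENENAQETPTRTSRQRASRNQTQTYYGSACKN
>inpp_synthetic_22
KHDNSCPDKYKQCKAYTCEWESAS-TPT-DNR-RAQREQHPKYGGSWHKG
>inpp_synthetic_23
KHDRSCADKYKQHCSYTCEPESASHTGTRDSHQRAATNQTQQYYNSACKH
>inpp_synthetic_24
KHDRSCARKYKAYGNYTCEKESSNGCPTRDSKARAQTNQTQKY-GSACKH
>inpp_synthetic_25
SHDNSCASKAKCYKAYKCEAQSAKGTQTRDSRQAAQTNQTTKYYGSADKH
>inpp_synthetic_26
KHGNSNADKQKQSEAYTCNHESASHTPTRDSWQRAQNNKGQKYYGETCKH
>inpp_synthetic_27
KHDNSCADNQKKDKAYTPEWESASGTPTSDSRQRHQRNQTQKY-GS-AKH
>inpp_synthetic_28
KHDNSCADKPKQYKGYNCEWEQDSGTPTNDCR-RAQTNQAQKDYGSACKH
>inpp_synthetic_29
PHDTSCADASKQYYACECRWESAEATPTRDSRQRA-TNPTQEYYGSHCKH
>inpp_synthetic_30
KHR-SCADKYKQNKAYTCG-ESYSGTP-RDSRQTAQTNQYQKDYASACKH
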