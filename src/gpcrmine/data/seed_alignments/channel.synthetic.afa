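>channel_synthetic_01
DRNQGHDWDGEGCPYRGAYKYEHHHQQRKWKGDKCTSYPSDSYYDGSYDT
>channel_synthetic_02
DRNQGQD-CGEGHGYRGAYYYEAHHQQHNWKGYPCRSYPHRSYYDGSYDT
>channel_synthetic_03
DRNQGS-WCGYQHGYPTAYYYEAHHQQRHWYGYPCTSDPHKSYCDGSYDT
>channel_synthetic_04
DRNQGHDWCGEGCGYWGAYYYEAHHQQRKWKGSPCR-YWHASYYDGSQDT
>channel_synthetic_05
GRPQRHDWCGEGHEY-GAYYEEAHHQQRKWKDYKCTS-PHGSYYDGSYPT
>channel_synthetic_06
DRNQGHDKCGEGHGYRNAYYYEAHHQQRDWKGYPCTSYPHDSYYDWHYDT
>channel_synthetic_07
DRNQGHDWHGQGHGYRGAAYYEAHHQQRKWKGYPRTSYPHDSYYNGSYET
>channel_synthetic_08
DRNQGHDWNG-GRETRRAYQYECHHQWRKWKGYPHTSYPHQSYYPGSYDT
>channel_synthetic_09
NRNQGHDWCGEGHGYEGYYYYHKTHQQPKYKGYPCESY-HDSYYDGRYDT
>channel_synthetic_10
DRNQHYDW-WEGHPYRQACYYEADHQQRKWKGYPDTSYPHTSYYDGSYDT
>channel_synthetic_11
NQNQGHGCCGEGHGYDGAWYYKAQHQQTKWKEYPC-RYPHDSYYDGQYDT
>channel_synthetic_12
DRNQGHDWCTRGHGYSGAYQTNAHHHRDKWKGYPCTSPDH-SAEDGSYDT
>channel_synthetic_13
DRNQGHDWCPE-HGYRGAYYY-AHHQQRKWK-YPCTSYPYDSYYDGSYDT
>channel_synthetic_14
ERN-GKDWCGEGHGERGAWYYEAHHQQRKWKCYPCTS-PHDSHYSTKYDT
>channel_synthetic_15
DRNQGYDWCGEGHGPCGA-YYEAHHSQRKWKCYPRDSYPHDSYYDCSADT
>channel_synthetic_16
CRNQGHDWCNEGHGYRGAYYYEAHHAQQYWK-YTCWSYPHDSTYDASNDP
>channel_synthetic_17
KRNQGHDWCGEKHGYEGEYYYGAHH-QRKWKNDQGTSYNHDKYYDGSYDP
>channel_synthetic_18
DRNQGDDWWGEGSGYRGRYYAEYHRQQRKDKGYHCTSYCHDSYYCGSYDC
>channel_synthetic_19
DRNQGHDWCGEPHGYRCAYYY-AHGQQRKWQGYPCTSYPHDSYYDGSYDT
>channel_synthetic_20
HRNQGHDWCGEGHAGQGAYY-EAHHQQRAWQRYPCTSYPRDEYRDGSYDT
>channel_synthetic_21
DNNQGHDWCGWGHGPRGAYYYQNQEQDRK-KGGPCDSYPHDSYYDGSYDT
>channel_synthetic_22
DRWQTHDKRKWEHNYRPAYYYTAHHQQHDEKGYPCTSYPHDSTYDRSDDT
>channel_synthetic_23
DRTQGHDWCGEGHGYRGAYYYEAHHQQYKKKGYPCNDYPHDSPYDGSYDT
>channel_synthetic_24
DRNQGHDWCYECHGYRGAYPYHAHHTQR-WKGYNCTSYPQDSYYDGSYDT
>channel_synthetic_25
DRNCYHDWNGEGHGYRGAYYYEDHHQQRCWKGYPCTSYAHDSYYDGSYDW
>channel_synthetic_26
DRNQDHDWCGSGAQYWGAYYYEAHHQQAKWKGYPCTSYPHDSYYDGDYET
>channel_synthetic_27
DRNQGHDWCGEGHGYRGAYYYEAPHQQRKWKDTPCTSYPHDSYTDGSY-R
>channel_synthetic_28
QRNQGHDWCPEGHGYRGAYYYGAHHQQAKKKGYPDHCYPHDSCYDGSYDC
>channel_synthetic_29
DR-QKHD-CKEGHGSRARYCQEAHH-QRKWA-YPCGSTPHDSYQDGS-TT
>channel_synthetic_30
DNNQGHDWCQEGNGYRGAYYSEAHHQQRQWKGSPCTSCPHDHKRDASTTT
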