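>tkl_synthetic_01
GACDPHAGPHWPTWGKGQASWYA-EQARCDRWCKQQKPEPDTCNAYEKTA
>tkl_synthetic_02
GACDAHAGPHHTTWGKGQASRSASNSQ-GP-PYKQQKPEPDTCNAYCKTA
>tkl_synthetic_03
GACDAHAGPHDPTWYKGQASRSAPEWKNCDRCYKKQKPEDDTCNAYCKTA
>tkl_synthetic_04
GAPDNAAGPHHPTTGAEQATRSATEQKNCRRWYTQQKPESDTANAYHKTC
>tkl_synthetic_05
GACPAHASPHHPEWGKGQASR-ATE--NCDKYYAQYKKEPDTCNAYCKTA
>tkl_synthetic_06
GACCAEAGAHHPTWGKPQASRSATENKRCTRPYKQQKPE-DTHNAYCWTA
>tkl_synthetic_07
GACDAHAETHYPTWGKGQPSA-ATEPKNCDRWYTK-KPEPDRCNAY-YTA
>tkl_synthetic_08
G-CDAHAGPHHPHWGKGSA-RAATECKSCDRWYWYQKPEPDTCNNYWKTA
>tkl_synthetic_09
GYCDHHAGPHHPAWGKGQASRSATDQKNCDRWYKQQKPEPDTANASCKCW
>tkl_synthetic_10
GARDAHANPHKKTWGKGQASCSATGQKNRDRNYKQQK-ERDTCPAPCKTA
>tkl_synthetic_11
GACQAHACPHH-TWGKSQAHRSASET-NCDRWYKQQKKETDTCNRYDK-A
>tkl_synthetic_12
RACDAHAGPHHPTWTKGQASRSATEQKYCDRWCKQGKPETSTCNAYHYTA
>tkl_synthetic_13
GACQAHAGPHHCTWGKGQASCSATNQKNPDRWY-QQK-EKR-ENHYCKSA
>tkl_synthetic_14
GACDAR-EPHHPTWGKGDANRSATEQKNCDRA-KHQKPNPDTCN-YCKTA
>tkl_synthetic_15
GACDGHAGPHHPYGGKTSASRSASEQK-CDRWYGSQKPEPDTCRTYQATA
>tkl_synthetic_16
GACDARAGGHHPQWATGQAWRTATEQKNCDREEKQKKPECDTCNAYQS-A
>tkl_synthetic_17
SACTAHARPHHPTWGEGQASRAPTEQKNCDRTYKQQKKEPDGCND-CSTA
>tkl_synthetic_18
GAYQAHAKPHHPTWGKGQASRSATEQKNCDRSYKQQKPEPDTCNAYC-TA
>tkl_synthetic_19
GACDAHAKPHHPTHYKGQDSRSATEQKNCDRWWKQQKPPDDTCNAYSKTA
>tkl_synthetic_20
GAGDAHAYHHHKTWPKGQASRSKTEQKNCDRYYNNSDPEGDTCNCYCKTA
>tkl_synthetic_21
GACDAHAKPHHPTDGKGQASNSATEQKNCDRWYKQQHPEPDTCNAYCKTT
>tkl_synthetic_22
GDCDSHACPHHPPWNKGQASRSATEQKNCDRWYKQQSPEP-TCNAYCKTA
>tkl_synthetic_23
GARDNHAGPHHPTEGKG-ASRSAWEQNNCDRWYKQQKPEPATCNQYCNGA
>tkl_synthetic_24
EACDAHAGPHHPTWGKGQCSRNASEDNNCDRWYTQQKPEPDTCNAGCETA
>tkl_synthetic_25
GACDAHYGPHHPTWGKGQASRSATEQKWCDRWYDEQKTEPGTCNAYCKTA
>tkl_synthetic_26
GACDAHAGPHHPTWDKGQASASATTKKNCDRWYKQQKPEPDTCNARCKTQ
>tkl_synthetic_27
GAETAQAGPHHPTAGKGQPSRS-TEQKNCDRWCKQQKPEPENNNEPEATA
>tkl_synthetic_28
CACQAHRGPHHPTA-KTQASTSATNPKNCDSAYKSAKPEPDNCNKYCCPA
>tkl_synthetic_29
GATDAHAYPHH-TWGKGQASRSATEQKNSDSAYKQQKPEPDTCNAYSKTN
>tkl_synthetic_30
GACDAHA-PHHDTWGKGQASRSKTEQKNCDRWYSQQKPEPDTCEAYCKTG
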