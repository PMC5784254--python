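>pipk_synthetic_01
P-NHRKENDLGKSHSQWKARNTPAHSHPMDYSLKYGWYEHQNNDNKKKAPGERQWTCRHH
>pipk_synthetic_02
PQNHRKENDLGKSGSQWKARNNCPHSHPMDYSLKYGTYEHENNDPGKKAHGERQWTTRNH
>pipk_synthetic_03
PQSHRKENDLGKSGSPWKARDYYPHSHSMDYSLHYGNYNHSWNDNKKKSHG-RQWTTRNH
>pipk_synthetic_04
PQNHRHENDLGHSGSQSKDRNNCQWSHPMDYSLKYGKYYHWWNDNKKKAHGDDQWTTRNH
>pipk_synthetic_05
PQNHRKENDLGGSGSQWKARNNCPHSHPMDYSLKYGWYQHRWTHNKKKAHREWYWTTAND
>pipk_synthetic_06
PTSHRKTNDLGKSGSQEKARNDCPGSHPMDYSLKCTWYEHCWNDNWKKAHGERQWQTSNH
>pipk_synthetic_07
PQNKRKENDLGKSDSQTKQRNNCPHSDHMDYSLKYGWYEHEWNDNKKKAHGERQWTTRNH
>pipk_synthetic_08
PQNHRKENDLGKSGSQWK-RNNCPYSH-MDYSLKYGWYEHETHDNKNKAHGERDPETRNH
>pipk_synthetic_09
PQNHRKENDLGKSGSQWKTPTNCPHD-DMDYSLKSGWYEYEWYDNQCKAGGERWDATRNC
>pipk_synthetic_10
PQNYRKENDLGKSGSQWAERNNPEHSHPMDYSLKYGPYEHEWNDNPKKAHGERQWTTRNH
>pipk_synthetic_11
PQNHRKENDLGKSGSQWSRNNNCPHCWPMDYSPKYGWYTHEWNRNKKKRHGERHWTTRNH
>pipk_synthetic_12
PQPHS-ENDLGKSGSQRKARYRRPYSH-MDYSLKYGWYEHEWNDNKKKA-GERQEDTGNH
>pipk_synthetic_13
PQNHRKENDLGKSPSQWKARNNCPH-HPMDYSLKYESYEKEWNDNKKKAHGERQWTTRNC
>pipk_synthetic_14
PQNHRKKNDLGKSGSPWKERNNCPHDHYMDYSLHDWSCEHEWNEPTKKAHGRSQWTTRNH
>pipk_synthetic_15
PENHRKENDLGKSGSQWTARNNCPHSHQMDYSLKYGWGEHWWNDNKKKYHGERQSTT-NH
>pipk_synthetic_16
PQNHRKENDLGKSGSQWKTRNNCPTSHPMDYSLKYGCYEHEWNDNKKKAHGSRQWTTRNY
>pipk_synthetic_17
PQRHRYENDLGKSGSQWKARNNCPHSHPMDYSL--GWYEHEWNDNKKKAHGERQATERNY
>pipk_synthetic_18
PQNHRKDNDLGKSGSQWKARNNCNHSGPMDYSLKDGRYGHEWNDNYKKAHGERQWTTRNG
>pipk_synthetic_19
PQNHRCEHDLGKSGYQWKARNNCPHSHPMDYSLKYGWYEREADDNRKKSKH-RQWTNKNH
>pipk_synthetic_20
PQNHRNENDLGKS-SQWKCRNNCPHGHPMDYSLKYGW-EHYWNDHKQKAHGERAWTGRNH
>pipk_synthetic_21
PNNHRKENDLGKSGSQWKARNNCPHSHPMDYSLAQGWYEHEWNDNKKKA-GQRQWTTRNH
>pipk_synthetic_22
PQNHRKENDLGKSYSQWKARNECPHSHCMDYELKYDW-YKEWNDNKKKAHGER-WDTRNH
>pipk_synthetic_23
EQYDRWEQDLGKSGSHWKARNNCPHSAPMDYSLKYGP-EHEWNDHKKKAHGERQWTTRNH
>pipk_synthetic_24
GQSHRKKNDLGKSGSQYKAENNCPHSHPMDYSLQQGWQEHEWNDNKKKAHKERQWWYRNS
>pipk_synthetic_25
PPNHRKENDLGKSGSQWCARNNCPHSHPMDYSLKYGWY-HEWNDN-KKAHGRRQWTSRNH
>pipk_synthetic_26
PQRHRKENDLGKSGYQWK-RNNCSHSHPMDYSLKYGWYEQC-N-NSKKANRERQNT-ATH
>pipk_synthetic_27
PW-HRKENDLGKSGSQ-KRRNNCPHYHPMDYSLKYAWYEHEWDGNEKKGHGEREWTPRNH
>pipk_synthetic_28
PQNHCKENDLGKSSSQKKARNNCPHSHGMDYSLKYGWYEHEWNDNKKKAHGERQWTTRNH
>pipk_synthetic_29
PQNHRKTNDLGKSGSQWKADNDCPHSHPMDYSLKYGSYEHEWNDNKKKAHGNRQWTTRNH
>pipk_synthetic_30
PQNPRHENDLGKSGSQW-ARNNCPHSHPMDYSL-YGWYETEHNRNKKKHHGYRWWTTRNH
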