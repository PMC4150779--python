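>SYNT0001.1 SYNT_ETS
A  [ 80  8 82  6  4 90 92  6  8  8 ]
C  [  6  6  6  4  3  3  3  4  6  8 ]
G  [  8 78  8 86 90  4  3 86  8 74 ]
T  [  6  8  4  4  3  3  2  4 78 10 ]
>SYNT0002.1 SYNT_REL
A  [  4  3  2 86  6  4  5  4  6  5 ]
C  [  5  4  4  5 82  6  5  6 80 82 ]
G  [ 85 88 90  5  4  5  4  4  6  7 ]
T  [  6  5  4  4  8 85 86 86  8  6 ]
>SYNT0003.1 SYNT_DECOY
A  [  8 78  6  8 70  8 10 74  8 10 ]
C  [ 74  8  8 72 10  8  8  8  8 66 ]
G  [ 10  6 76 10 10  8 72 10  8 14 ]
T  [  8  8 10 10 10 76 10  8 76 10 ]
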