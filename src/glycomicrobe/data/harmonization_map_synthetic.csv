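original_peak,harmonized_gp
P1,GP1
P2,GP2
P3,GP3
P4,GP4
P5,GP4
P6,GP5
P7,GP6
P8,GP7
P9,GP8
P10,GP9
P11,GP10
P12,GP10
P13,GP11
P14,GP12
P15,GP13
P16,GP14
P17,GP15
P18,GP16
P19,GP17
P20,GP18
P21,GP19
P22,GP19
P23,GP20
P24,GP21
P25,GP22
P26,GP23
P27,GP24
P28,GP25
P29,GP26
P30,GP27
P31,GP28
P32,GP29
P33,GP30
P34,GP31
P35,GP32
P36,GP33
P37,GP34
P38,GP35
P39,GP36
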