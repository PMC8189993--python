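species_code,size,reach,rel_reach,hardness,grip,food_size,grab,stuffing
T40,Large,Long Range,Close to,Hard,Feeble effort,Small food,Little chunks,Tiny mouthfulls
KL,Large,Long Range,Close to,Hard,Powerful grip,Big food,Major grab,Well stuffed
T7,Large,Long Range,Close to,Soft,Feeble effort,Small food,Little chunks,Tiny mouthfulls
T62,Large,Long Range,Well away,Hard,Powerful grip,Big food,Major grab,Tiny mouthfulls
T38,Large,Long Range,Well away,Hard,Powerful grip,Big food,Major grab,Tiny mouthfulls
A10b,Large,Long Range,Well away,Hard,Powerful grip,Big food,Major grab,Well stuffed
T66,Large,Long Range,Well away,Hard,Powerful grip,Big food,Major grab,Well stuffed
T8,Large,Long Range,Well away,Soft,Feeble effort,Big food,Major grab,Tiny mouthfulls
A1,Large,Short distance,Close to,Soft,Feeble effort,Small food,Little chunks,Tiny mouthfulls
T89,Large,Short distance,Close to,Soft,Feeble effort,Small food,Little chunks,Tiny mouthfulls
T17,Large,Short distance,Close to,Soft,Feeble effort,Small food,Little chunks,Tiny mouthfulls
T21,Large,Short distance,Close to,Soft,Feeble effort,Small food,Little chunks,Tiny mouthfulls
LA1,Small,Long Range,Well away,Hard,Powerful grip,Big food,Major grab,Tiny mouthfulls
AL2,Small,Long Range,Well away,Hard,Powerful grip,Big food,Major grab,Well stuffed
A15,Small,Long Range,Well away,Soft,Feeble effort,Big food,Major grab,Well stuffed
AC204,Small,Short distance,Close to,Soft,Feeble effort,Small food,Little chunks,Tiny mouthfulls
F1,Small,Short distance,Close to,Soft,Feeble effort,Small food,Little chunks,Tiny mouthfulls
T6,Small,Short distance,Close to,Soft,Feeble effort,Small food,Little chunks,Tiny mouthfulls
T9,Small,Short distance,Close to,Soft,Feeble effort,Small food,Little chunks,Tiny mouthfulls
T87,Small,Short distance,Close to,Soft,Feeble effort,Small food,Little chunks,Tiny mouthfulls
T90,Small,Short distance,Close to,Soft,Feeble effort,Small food,Little chunks,Tiny mouthfulls
A17,Small,Short distance,Close to,Soft,Feeble effort,Small food,Little chunks,Well stuffed
T34,Small,Short distance,Well away,Soft,Feeble effort,Small food,Little chunks,Tiny mouthfulls
T32,Small,Short distance,Well away,Soft,Feeble effort,Small food,Little chunks,Tiny mouthfulls
T44,Small,Short distance,Well away,Soft,Feeble effort,Small food,Little chunks,Tiny mouthfulls
A4,Small,Short distance,Well away,Soft,Feeble effort,Small food,Major grab,Tiny mouthfulls
T13,Small,Short distance,Well away,Soft,Feeble effort,Small food,Major grab,Tiny mouthfulls
T11,Small,Short distance,Well away,Soft,Feeble effort,Small food,Major grab,Tiny mouthfulls
C3,Large,Long Range,Close to,Hard,Feeble effort,Big food,Little chunks,Tiny mouthfulls
TH4,Large,Long Range,Close to,Hard,Feeble effort,Big food,Little chunks,Tiny mouthfulls
R2,Large,Long Range,Close to,Hard,Powerful grip,Big food,Little chunks,Tiny mouthfulls
R1,Large,Long Range,Close to,Hard,Powerful grip,Big food,Little chunks,Well stuffed
TH3,Large,Short distance,Close to,Hard,Powerful grip,Small food,Little chunks,Tiny mouthfulls
C10,Large,Short distance,Close to,Soft,Feeble effort,Small food,Little chunks,Tiny mouthfulls
C5,Small,Short distance,Close to,Soft,Feeble effort,Small food,Little chunks,Tiny mouthfulls
L3,Large,Long Range,Close to,Soft,Feeble effort,Small food,Little chunks,Tiny mouthfulls
L1,Small,Short distance,Close to,Soft,Feeble effort,Small food,Little chunks,Tiny mouthfulls
S5,Small,Short distance,Close to,Soft,Feeble effort,Small food,Little chunks,Tiny mouthfulls
G3,Small,Long Range,Well away,Hard,Powerful grip,Big food,Major grab,Well stuffed
CH1,Small,Long Range,Well away,Hard,Powerful grip,Big food,Major grab,Well stuffed
G6,Large,Long Range,Close to,Hard,Powerful grip,Big food,Major grab,Well stuffed
G5,Small,Long Range,Well away,Hard,Powerful grip,Big food,Major grab,Well stuffed
Ca4,Small,Short distance,Close to,Soft,Feeble effort,Small food,Major grab,Well stuffed
CV1(66),Small,Short distance,Close to,Soft,Feeble effort,Small food,Little chunks,Tiny mouthfulls
D4,Small,Short distance,Well away,Hard,Powerful grip,Big food,Major grab,Well stuffed
D5,Small,Short distance,Well away,Soft,Powerful grip,Small food,Major grab,Well stuffed
D3,Small,Short distance,Well away,Soft,Powerful grip,Small food,Major grab,Well stuffed
Typical,Small,Short distance,Close to,Soft,Feeble effort,Small food,Little chunks,Tiny mouthfulls
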