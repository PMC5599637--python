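name,full_name,rrt,target_ion,qualifier_ions
Nonadecane,Nonadecane (internal standard),1.000,57,268;71;85
EME,Ecgonine methylester,0.711,82,83;96;271
EC,Ecgonine,0.793,96,82;97;83
TROPA,Tropacocaine,1.035,124,245;82;94
BENZO,Benzoylecgonine,1.229,240,82;361;256
NOR,Norcocaine,1.243,240,346;179;140
CIS,Cis-cinnamoylcocaine,1.285,82,182;96;329
TRANS,Trans-cinnamoylcocaine,1.376,82,182;96;329
TMC,"3,4,5-Trimethoxycocaine",1.630,182,82;94;393
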