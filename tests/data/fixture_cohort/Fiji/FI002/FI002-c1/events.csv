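clip_id,t_s,channel,state
FI002-c1-k01,0.000,OBJECT,Nothing
FI002-c1-k01,0.000,LOCATION,PorchHome
FI002-c1-k01,0.000,CONTEXT,NoRisk
FI002-c1-k01,182.503,OBJECT,OwnSkin
FI002-c1-k01,183.667,OBJECT,Nothing
FI002-c1-k02,0.000,OBJECT,Nothing
FI002-c1-k02,0.000,LOCATION,PorchHome
FI002-c1-k02,0.000,CONTEXT,NoRisk
FI002-c1-k02,75.891,OBJECT,OwnSkin
FI002-c1-k02,78.320,OBJECT,Nothing
FI002-c1-k03,0.000,OBJECT,Nothing
FI002-c1-k03,0.000,LOCATION,PorchHome
FI002-c1-k03,0.000,CONTEXT,NoRisk
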