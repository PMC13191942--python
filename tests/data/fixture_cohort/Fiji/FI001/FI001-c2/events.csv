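clip_id,t_s,channel,state
FI001-c2-k01,0.000,OBJECT,Nothing
FI001-c2-k01,0.000,LOCATION,IndoorHome
FI001-c2-k01,0.000,CONTEXT,NoRisk
FI001-c2-k01,0.641,OBJECT,Wall
FI001-c2-k01,1.549,OBJECT,Nothing
FI001-c2-k01,20.399,CONTEXT,AroundAnimal
FI001-c2-k01,33.196,CONTEXT,NoRisk
FI001-c2-k01,184.878,OBJECT,BenchtopSurface
FI001-c2-k01,186.305,OBJECT,Nothing
FI001-c2-k01,200.175,OBJECT,FishMeatEgg
FI001-c2-k01,202.687,OBJECT,Nothing
FI001-c2-k01,224.957,OBJECT,Rice
FI001-c2-k01,227.379,OBJECT,Nothing
FI001-c2-k01,227.380,OBJECT,OwnSkin
FI001-c2-k01,229.942,OBJECT,Nothing
FI001-c2-k02,0.000,OBJECT,Nothing
FI001-c2-k02,0.000,LOCATION,IndoorHome
FI001-c2-k02,0.000,CONTEXT,NoRisk
FI001-c2-k02,56.159,OBJECT,OtherFood
FI001-c2-k02,56.954,OBJECT,Nothing
FI001-c2-k02,113.576,OBJECT,Ball
FI001-c2-k02,114.144,OBJECT,Nothing
FI001-c2-k02,114.145,OBJECT,Wood
FI001-c2-k02,117.923,OBJECT,Nothing
FI001-c2-k02,161.869,OBJECT,OwnSkin
FI001-c2-k02,165.997,OBJECT,Nothing
FI001-c2-k03,0.000,OBJECT,Nothing
FI001-c2-k03,0.000,LOCATION,IndoorHome
FI001-c2-k03,0.000,CONTEXT,NoRisk
FI001-c2-k03,42.063,OBJECT,OwnSkin
FI001-c2-k03,43.587,OBJECT,Nothing
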