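clip_id,t_s,channel,state
FI003-c1-k01,0.000,OBJECT,Nothing
FI003-c1-k01,0.000,LOCATION,OutdoorCommunal
FI003-c1-k01,0.000,CONTEXT,NoRisk
FI003-c1-k01,42.098,OBJECT,OwnHand
FI003-c1-k01,43.928,OBJECT,Nothing
FI003-c1-k01,52.445,OBJECT,DryFood
FI003-c1-k01,57.530,OBJECT,Nothing
FI003-c1-k01,64.025,LOCATION,OutsideHome
FI003-c1-k01,77.068,OBJECT,OwnSkin
FI003-c1-k01,80.461,OBJECT,Nothing
FI003-c1-k01,104.591,LOCATION,PorchHome
FI003-c1-k01,119.725,OBJECT,FishMeatEgg
FI003-c1-k01,123.286,OBJECT,Nothing
FI003-c1-k01,129.552,OBJECT,Ball
FI003-c1-k01,130.308,OBJECT,Nothing
FI003-c1-k01,187.213,OBJECT,FruitVegetable
FI003-c1-k01,190.054,OBJECT,Nothing
FI003-c1-k01,191.395,OBJECT,PlantFiberMat
FI003-c1-k01,198.940,OBJECT,Nothing
FI003-c1-k01,203.124,OBJECT,OwnHand
FI003-c1-k01,205.094,OBJECT,Nothing
FI003-c1-k02,0.000,OBJECT,Nothing
FI003-c1-k02,0.000,LOCATION,PorchHome
FI003-c1-k02,0.000,CONTEXT,NoRisk
FI003-c1-k02,55.973,OBJECT,DrinkingWater
FI003-c1-k02,56.520,OBJECT,Nothing
FI003-c1-k02,64.000,OBJECT,PlantFiberMat
FI003-c1-k02,69.401,OBJECT,Nothing
FI003-c1-k02,75.270,OBJECT,FruitVegetable
FI003-c1-k02,81.087,OBJECT,Nothing
FI003-c1-k02,115.254,OBJECT,OwnHand
FI003-c1-k02,116.823,OBJECT,Nothing
FI003-c1-k02,116.824,OBJECT,Metal
FI003-c1-k02,119.759,OBJECT,Nothing
FI003-c1-k02,127.378,OBJECT,LiquidFood
FI003-c1-k02,128.566,OBJECT,Nothing
FI003-c1-k02,137.416,OBJECT,OtherMixedObject
FI003-c1-k02,138.273,OBJECT,Nothing
FI003-c1-k02,191.129,OBJECT,LiquidFood
FI003-c1-k02,201.789,OBJECT,Nothing
FI003-c1-k03,0.000,OBJECT,Nothing
FI003-c1-k03,0.000,LOCATION,PorchHome
FI003-c1-k03,0.000,CONTEXT,NoRisk
FI003-c1-k03,3.818,OBJECT,Wood
FI003-c1-k03,6.119,OBJECT,Nothing
FI003-c1-k03,33.134,OBJECT,OtherMixedObject
FI003-c1-k03,35.108,OBJECT,Nothing
FI003-c1-k03,42.497,OBJECT,OtherPeoplesMouth
FI003-c1-k03,43.415,OBJECT,Nothing
FI003-c1-k03,44.851,OBJECT,FishMeatEgg
FI003-c1-k03,46.135,OBJECT,Nothing
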