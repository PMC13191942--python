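clip_id,t_s,channel,state
IN002-c2-k01,0.000,OBJECT,Nothing
IN002-c2-k01,0.000,LOCATION,PorchHome
IN002-c2-k01,0.000,CONTEXT,NoRisk
IN002-c2-k01,84.396,OBJECT,DrinkingWater
IN002-c2-k01,85.524,OBJECT,Nothing
IN002-c2-k01,90.676,OBJECT,BenchtopSurface
IN002-c2-k01,91.222,OBJECT,Nothing
IN002-c2-k01,116.355,OBJECT,DryFood
IN002-c2-k01,119.160,OBJECT,Nothing
IN002-c2-k01,147.195,OBJECT,OwnHand
IN002-c2-k01,147.991,OBJECT,Nothing
IN002-c2-k01,225.281,OBJECT,FishMeatEgg
IN002-c2-k01,225.739,OBJECT,Nothing
IN002-c2-k01,225.903,OBJECT,Rice
IN002-c2-k01,227.743,OBJECT,Nothing
IN002-c2-k02,0.000,OBJECT,Nothing
IN002-c2-k02,0.000,LOCATION,PorchHome
IN002-c2-k02,0.000,CONTEXT,NoRisk
IN002-c2-k02,17.842,OBJECT,PlantFiberMat
IN002-c2-k02,18.907,OBJECT,Nothing
IN002-c2-k02,18.908,OBJECT,OwnSkin
IN002-c2-k02,21.015,OBJECT,Nothing
IN002-c2-k02,149.512,OBJECT,OtherPeoplesMouth
IN002-c2-k02,151.680,OBJECT,Nothing
IN002-c2-k02,178.980,OBJECT,OwnSkin
IN002-c2-k02,182.014,OBJECT,Nothing
IN002-c2-k02,203.991,OBJECT,OwnHand
IN002-c2-k02,205.074,OBJECT,Nothing
IN002-c2-k02,205.075,OBJECT,OtherFood
IN002-c2-k02,206.721,OBJECT,Nothing
IN002-c2-k03,0.000,OBJECT,Nothing
IN002-c2-k03,0.000,LOCATION,PorchHome
IN002-c2-k03,0.000,CONTEXT,NoRisk
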