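clip_id,t_s,channel,state
IN001-c2-k01,0.000,OBJECT,Nothing
IN001-c2-k01,0.000,LOCATION,OutsideHome
IN001-c2-k01,0.000,CONTEXT,NoRisk
IN001-c2-k01,6.009,OBJECT,Metal
IN001-c2-k01,9.427,OBJECT,Nothing
IN001-c2-k01,72.208,OBJECT,OwnSkin
IN001-c2-k01,73.232,OBJECT,Nothing
IN001-c2-k01,158.610,OBJECT,OwnSkin
IN001-c2-k01,162.041,OBJECT,Nothing
IN001-c2-k01,187.651,OBJECT,Wood
IN001-c2-k01,189.548,OBJECT,Nothing
IN001-c2-k01,212.964,OBJECT,FishMeatEgg
IN001-c2-k01,215.290,OBJECT,Nothing
IN001-c2-k02,0.000,OBJECT,Nothing
IN001-c2-k02,0.000,LOCATION,OutsideHome
IN001-c2-k02,0.000,CONTEXT,NoRisk
IN001-c2-k02,75.684,OBJECT,OwnSkin
IN001-c2-k02,77.764,OBJECT,Nothing
IN001-c2-k02,86.443,OBJECT,PhoneTablet
IN001-c2-k02,94.528,OBJECT,Nothing
IN001-c2-k02,189.064,OBJECT,Ball
IN001-c2-k02,190.554,OBJECT,Nothing
IN001-c2-k02,190.731,OBJECT,FruitVegetable
IN001-c2-k02,191.374,OBJECT,Nothing
IN001-c2-k02,215.492,OBJECT,OtherMixedObject
IN001-c2-k02,219.483,OBJECT,Nothing
IN001-c2-k02,228.118,OBJECT,OwnSkin
IN001-c2-k02,230.124,OBJECT,NotInView
IN001-c2-k03,0.000,OBJECT,NotInView
IN001-c2-k03,0.000,LOCATION,OutsideHome
IN001-c2-k03,0.000,CONTEXT,NoRisk
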