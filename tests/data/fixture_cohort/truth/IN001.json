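{"child_id": "IN001", "params": {"hours": 0.15, "campaigns": [2], "target_outdoor_fraction": 0.9133092799329939, "child_rate_factor": 0.9716408783934679, "group_factors": {"high_risk": 0.0025352926376142814}, "context_exposure": {"Handwashing": true, "Eating": true, "EnvironmentalWater": true, "AroundAnimal": true, "AroundFeces": false}, "configured_any_rate": 73.70000000000002}, "observed_s": 540.0, "not_in_view_s": 69.876, "n_contacts": 11, "contacts": [{"object": "Metal", "group": "fomite", "onset_s": 6.009, "end_s": 9.427, "location": "OutsideHome", "context": "NoRisk"}, {"object": "OwnSkin", "group": "own_hand_skin", "onset_s": 72.208, "end_s": 73.232, "location": "OutsideHome", "context": "NoRisk"}, {"object": "OwnSkin", "group": "own_hand_skin", "onset_s": 158.61, "end_s": 162.041, "location": "OutsideHome", "context": "NoRisk"}, {"object": "Wood", "group": "fomite", "onset_s": 187.651, "end_s": 189.548, "location": "OutsideHome", "context": "NoRisk"}, {"object": "FishMeatEgg", "group": "food", "onset_s": 212.964, "end_s": 215.29, "location": "OutsideHome", "context": "NoRisk"}, {"object": "OwnSkin", "group": "own_hand_skin", "onset_s": 315.684, "end_s": 317.764, "location": "OutsideHome", "context": "NoRisk"}, {"object": "PhoneTablet", "group": "fomite", "onset_s": 326.443, "end_s": 334.528, "location": "OutsideHome", "context": "NoRisk"}, {"object": "Ball", "group": "fomite", "onset_s": 429.064, "end_s": 430.554, "location": "OutsideHome", "context": "NoRisk"}, {"object": "FruitVegetable", "group": "food", "onset_s": 430.731, "end_s": 431.374, "location": "OutsideHome", "context": "NoRisk"}, {"object": "OtherMixedObject", "group": "fomite", "onset_s": 455.492, "end_s": 459.483, "location": "OutsideHome", "context": "NoRisk"}, {"object": "OwnSkin", "group": "own_hand_skin", "onset_s": 468.118, "end_s": 470.124, "location": "OutsideHome", "context": "NoRisk"}], "intervals": {"OBJECT": [[0.0, 6.009, "Nothing"], [6.009, 9.427, "Metal"], [9.427, 72.208, "Nothing"], [72.208, 73.232, "OwnSkin"], [73.232, 158.61, "Nothing"], [158.61, 162.041, "OwnSkin"], [162.041, 187.651, "Nothing"], [187.651, 189.548, "Wood"], [189.548, 212.964, "Nothing"], [212.964, 215.29, "FishMeatEgg"], [215.29, 315.684, "Nothing"], [315.684, 317.764, "OwnSkin"], [317.764, 326.443, "Nothing"], [326.443, 334.528, "PhoneTablet"], [334.528, 429.064, "Nothing"], [429.064, 430.554, "Ball"], [430.554, 430.731, "Nothing"], [430.731, 431.374, "FruitVegetable"], [431.374, 455.492, "Nothing"], [455.492, 459.483, "OtherMixedObject"], [459.483, 468.118, "Nothing"], [468.118, 470.124, "OwnSkin"], [470.124, 540.0, "NotInView"]], "LOCATION": [[0.0, 540.0, "OutsideHome"]], "CONTEXT": [[0.0, 540.0, "NoRisk"]]}}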