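{"child_id": "FI003", "params": {"hours": 0.15, "campaigns": [1], "target_outdoor_fraction": 0.744604241731171, "child_rate_factor": 1.24852973734939, "group_factors": {"high_risk": 0.3242986029568844}, "context_exposure": {"Handwashing": true, "Eating": true, "EnvironmentalWater": false, "AroundAnimal": true, "AroundFeces": false}, "configured_any_rate": 71.6}, "observed_s": 540.0, "not_in_view_s": 0, "n_contacts": 20, "contacts": [{"object": "OwnHand", "group": "own_hand_skin", "onset_s": 42.098, "end_s": 43.928, "location": "OutdoorCommunal", "context": "NoRisk"}, {"object": "DryFood", "group": "food", "onset_s": 52.445, "end_s": 57.53, "location": "OutdoorCommunal", "context": "NoRisk"}, {"object": "OwnSkin", "group": "own_hand_skin", "onset_s": 77.068, "end_s": 80.461, "location": "OutsideHome", "context": "NoRisk"}, {"object": "FishMeatEgg", "group": "food", "onset_s": 119.725, "end_s": 123.286, "location": "PorchHome", "context": "NoRisk"}, {"object": "Ball", "group": "fomite", "onset_s": 129.552, "end_s": 130.308, "location": "PorchHome", "context": "NoRisk"}, {"object": "FruitVegetable", "group": "food", "onset_s": 187.213, "end_s": 190.054, "location": "PorchHome", "context": "NoRisk"}, {"object": "PlantFiberMat", "group": "fomite", "onset_s": 191.395, "end_s": 198.94, "location": "PorchHome", "context": "NoRisk"}, {"object": "OwnHand", "group": "own_hand_skin", "onset_s": 203.124, "end_s": 205.094, "location": "PorchHome", "context": "NoRisk"}, {"object": "DrinkingWater", "group": "food", "onset_s": 295.973, "end_s": 296.52, "location": "PorchHome", "context": "NoRisk"}, {"object": "PlantFiberMat", "group": "fomite", "onset_s": 304.0, "end_s": 309.401, "location": "PorchHome", "context": "NoRisk"}, {"object": "FruitVegetable", "group": "food", "onset_s": 315.27, "end_s": 321.087, "location": "PorchHome", "context": "NoRisk"}, {"object": "OwnHand", "group": "own_hand_skin", "onset_s": 355.254, "end_s": 356.823, "location": "PorchHome", "context": "NoRisk"}, {"object": "Metal", "group": "fomite", "onset_s": 356.824, "end_s": 359.759, "location": "PorchHome", "context": "NoRisk"}, {"object": "LiquidFood", "group": "food", "onset_s": 367.378, "end_s": 368.566, "location": "PorchHome", "context": "NoRisk"}, {"object": "OtherMixedObject", "group": "fomite", "onset_s": 377.416, "end_s": 378.273, "location": "PorchHome", "context": "NoRisk"}, {"object": "LiquidFood", "group": "food", "onset_s": 431.129, "end_s": 441.789, "location": "PorchHome", "context": "NoRisk"}, {"object": "Wood", "group": "fomite", "onset_s": 483.818, "end_s": 486.119, "location": "PorchHome", "context": "NoRisk"}, {"object": "OtherMixedObject", "group": "fomite", "onset_s": 513.134, "end_s": 515.108, "location": "PorchHome", "context": "NoRisk"}, {"object": "OtherPeoplesMouth", "group": "other_hand_skin", "onset_s": 522.497, "end_s": 523.415, "location": "PorchHome", "context": "NoRisk"}, {"object": "FishMeatEgg", "group": "food", "onset_s": 524.851, "end_s": 526.135, "location": "PorchHome", "context": "NoRisk"}], "intervals": {"OBJECT": [[0.0, 42.098, "Nothing"], [42.098, 43.928, "OwnHand"], [43.928, 52.445, "Nothing"], [52.445, 57.53, "DryFood"], [57.53, 77.068, "Nothing"], [77.068, 80.461, "OwnSkin"], [80.461, 119.725, "Nothing"], [119.725, 123.286, "FishMeatEgg"], [123.286, 129.552, "Nothing"], [129.552, 130.308, "Ball"], [130.308, 187.213, "Nothing"], [187.213, 190.054, "FruitVegetable"], [190.054, 191.395, "Nothing"], [191.395, 198.94, "PlantFiberMat"], [198.94, 203.124, "Nothing"], [203.124, 205.094, "OwnHand"], [205.094, 295.973, "Nothing"], [295.973, 296.52, "DrinkingWater"], [296.52, 304.0, "Nothing"], [304.0, 309.401, "PlantFiberMat"], [309.401, 315.27, "Nothing"], [315.27, 321.087, "FruitVegetable"], [321.087, 355.254, "Nothing"], [355.254, 356.823, "OwnHand"], [356.823, 356.824, "Nothing"], [356.824, 359.759, "Metal"], [359.759, 367.378, "Nothing"], [367.378, 368.566, "LiquidFood"], [368.566, 377.416, "Nothing"], [377.416, 378.273, "OtherMixedObject"], [378.273, 431.129, "Nothing"], [431.129, 441.789, "LiquidFood"], [441.789, 483.818, "Nothing"], [483.818, 486.119, "Wood"], [486.119, 513.134, "Nothing"], [513.134, 515.108, "OtherMixedObject"], [515.108, 522.497, "Nothing"], [522.497, 523.415, "OtherPeoplesMouth"], [523.415, 524.851, "Nothing"], [524.851, 526.135, "FishMeatEgg"], [526.135, 540.0, "Nothing"]], "LOCATION": [[0.0, 64.025, "OutdoorCommunal"], [64.025, 104.591, "OutsideHome"], [104.591, 540.0, "PorchHome"]], "CONTEXT": [[0.0, 540.0, "NoRisk"]]}}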