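{"child_id": "IN002", "params": {"hours": 0.15, "campaigns": [2], "target_outdoor_fraction": 0.4820671430627474, "child_rate_factor": 0.9852790005778304, "group_factors": {"high_risk": 0.06647918624570355}, "context_exposure": {"Handwashing": true, "Eating": true, "EnvironmentalWater": true, "AroundAnimal": true, "AroundFeces": false}, "configured_any_rate": 73.70000000000002}, "observed_s": 540.0, "not_in_view_s": 0, "n_contacts": 12, "contacts": [{"object": "DrinkingWater", "group": "food", "onset_s": 84.396, "end_s": 85.524, "location": "PorchHome", "context": "NoRisk"}, {"object": "BenchtopSurface", "group": "fomite", "onset_s": 90.676, "end_s": 91.222, "location": "PorchHome", "context": "NoRisk"}, {"object": "DryFood", "group": "food", "onset_s": 116.355, "end_s": 119.16, "location": "PorchHome", "context": "NoRisk"}, {"object": "OwnHand", "group": "own_hand_skin", "onset_s": 147.195, "end_s": 147.991, "location": "PorchHome", "context": "NoRisk"}, {"object": "FishMeatEgg", "group": "food", "onset_s": 225.281, "end_s": 225.739, "location": "PorchHome", "context": "NoRisk"}, {"object": "Rice", "group": "food", "onset_s": 225.903, "end_s": 227.743, "location": "PorchHome", "context": "NoRisk"}, {"object": "PlantFiberMat", "group": "fomite", "onset_s": 257.842, "end_s": 258.907, "location": "PorchHome", "context": "NoRisk"}, {"object": "OwnSkin", "group": "own_hand_skin", "onset_s": 258.908, "end_s": 261.015, "location": "PorchHome", "context": "NoRisk"}, {"object": "OtherPeoplesMouth", "group": "other_hand_skin", "onset_s": 389.512, "end_s": 391.68, "location": "PorchHome", "context": "NoRisk"}, {"object": "OwnSkin", "group": "own_hand_skin", "onset_s": 418.98, "end_s": 422.014, "location": "PorchHome", "context": "NoRisk"}, {"object": "OwnHand", "group": "own_hand_skin", "onset_s": 443.991, "end_s": 445.074, "location": "PorchHome", "context": "NoRisk"}, {"object": "OtherFood", "group": "food", "onset_s": 445.075, "end_s": 446.721, "location": "PorchHome", "context": "NoRisk"}], "intervals": {"OBJECT": [[0.0, 84.396, "Nothing"], [84.396, 85.524, "DrinkingWater"], [85.524, 90.676, "Nothing"], [90.676, 91.222, "BenchtopSurface"], [91.222, 116.355, "Nothing"], [116.355, 119.16, "DryFood"], [119.16, 147.195, "Nothing"], [147.195, 147.991, "OwnHand"], [147.991, 225.281, "Nothing"], [225.281, 225.739, "FishMeatEgg"], [225.739, 225.903, "Nothing"], [225.903, 227.743, "Rice"], [227.743, 257.842, "Nothing"], [257.842, 258.907, "PlantFiberMat"], [258.907, 258.908, "Nothing"], [258.908, 261.015, "OwnSkin"], [261.015, 389.512, "Nothing"], [389.512, 391.68, "OtherPeoplesMouth"], [391.68, 418.98, "Nothing"], [418.98, 422.014, "OwnSkin"], [422.014, 443.991, "Nothing"], [443.991, 445.074, "OwnHand"], [445.074, 445.075, "Nothing"], [445.075, 446.721, "OtherFood"], [446.721, 540.0, "Nothing"]], "LOCATION": [[0.0, 540.0, "PorchHome"]], "CONTEXT": [[0.0, 540.0, "NoRisk"]]}}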