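{"child_id": "FI002", "params": {"hours": 0.15, "campaigns": [1], "target_outdoor_fraction": 0.5495238203391586, "child_rate_factor": 0.38982535939812446, "group_factors": {"high_risk": 1.5739959985573628}, "context_exposure": {"Handwashing": true, "Eating": true, "EnvironmentalWater": false, "AroundAnimal": true, "AroundFeces": false}, "configured_any_rate": 71.6}, "observed_s": 540.0, "not_in_view_s": 0, "n_contacts": 2, "contacts": [{"object": "OwnSkin", "group": "own_hand_skin", "onset_s": 182.503, "end_s": 183.667, "location": "PorchHome", "context": "NoRisk"}, {"object": "OwnSkin", "group": "own_hand_skin", "onset_s": 315.891, "end_s": 318.32, "location": "PorchHome", "context": "NoRisk"}], "intervals": {"OBJECT": [[0.0, 182.503, "Nothing"], [182.503, 183.667, "OwnSkin"], [183.667, 315.891, "Nothing"], [315.891, 318.32, "OwnSkin"], [318.32, 540.0, "Nothing"]], "LOCATION": [[0.0, 540.0, "PorchHome"]], "CONTEXT": [[0.0, 540.0, "NoRisk"]]}}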