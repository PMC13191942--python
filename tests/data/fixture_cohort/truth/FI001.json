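{"child_id": "FI001", "params": {"hours": 0.15, "campaigns": [2], "target_outdoor_fraction": 0.21083385882638822, "child_rate_factor": 0.4505636669725507, "group_factors": {"high_risk": 0.03666995557620792}, "context_exposure": {"Handwashing": true, "Eating": true, "EnvironmentalWater": false, "AroundAnimal": true, "AroundFeces": true}, "configured_any_rate": 71.6}, "observed_s": 540.0, "not_in_view_s": 0, "n_contacts": 10, "contacts": [{"object": "Wall", "group": "fomite", "onset_s": 0.641, "end_s": 1.549, "location": "IndoorHome", "context": "NoRisk"}, {"object": "BenchtopSurface", "group": "fomite", "onset_s": 184.878, "end_s": 186.305, "location": "IndoorHome", "context": "NoRisk"}, {"object": "FishMeatEgg", "group": "food", "onset_s": 200.175, "end_s": 202.687, "location": "IndoorHome", "context": "NoRisk"}, {"object": "Rice", "group": "food", "onset_s": 224.957, "end_s": 227.379, "location": "IndoorHome", "context": "NoRisk"}, {"object": "OwnSkin", "group": "own_hand_skin", "onset_s": 227.38, "end_s": 229.942, "location": "IndoorHome", "context": "NoRisk"}, {"object": "OtherFood", "group": "food", "onset_s": 296.159, "end_s": 296.954, "location": "IndoorHome", "context": "NoRisk"}, {"object": "Ball", "group": "fomite", "onset_s": 353.576, "end_s": 354.144, "location": "IndoorHome", "context": "NoRisk"}, {"object": "Wood", "group": "fomite", "onset_s": 354.145, "end_s": 357.923, "location": "IndoorHome", "context": "NoRisk"}, {"object": "OwnSkin", "group": "own_hand_skin", "onset_s": 401.869, "end_s": 405.997, "location": "IndoorHome", "context": "NoRisk"}, {"object": "OwnSkin", "group": "own_hand_skin", "onset_s": 522.063, "end_s": 523.587, "location": "IndoorHome", "context": "NoRisk"}], "intervals": {"OBJECT": [[0.0, 0.641, "Nothing"], [0.641, 1.549, "Wall"], [1.549, 184.878, "Nothing"], [184.878, 186.305, "BenchtopSurface"], [186.305, 200.175, "Nothing"], [200.175, 202.687, "FishMeatEgg"], [202.687, 224.957, "Nothing"], [224.957, 227.379, "Rice"], [227.379, 227.38, "Nothing"], [227.38, 229.942, "OwnSkin"], [229.942, 296.159, "Nothing"], [296.159, 296.954, "OtherFood"], [296.954, 353.576, "Nothing"], [353.576, 354.144, "Ball"], [354.144, 354.145, "Nothing"], [354.145, 357.923, "Wood"], [357.923, 401.869, "Nothing"], [401.869, 405.997, "OwnSkin"], [405.997, 522.063, "Nothing"], [522.063, 523.587, "OwnSkin"], [523.587, 540.0, "Nothing"]], "LOCATION": [[0.0, 540.0, "IndoorHome"]], "CONTEXT": [[0.0, 20.399, "NoRisk"], [20.399, 33.196, "AroundAnimal"], [33.196, 540.0, "NoRisk"]]}}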