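{
  "seed": 0,
  "arms": [
    {
      "country": "Fiji",
      "n_children": 3
    },
    {
      "country": "Indonesia",
      "n_children": 2
    }
  ],
  "children": [
    {
      "child_id": "FI001",
      "country": "Fiji",
      "sessions": 1
    },
    {
      "child_id": "FI002",
      "country": "Fiji",
      "sessions": 1
    },
    {
      "child_id": "FI003",
      "country": "Fiji",
      "sessions": 1
    },
    {
      "child_id": "IN001",
      "country": "Indonesia",
      "sessions": 1
    },
    {
      "child_id": "IN002",
      "country": "Indonesia",
      "sessions": 1
    }
  ]
}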