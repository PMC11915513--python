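{
  "k": 2,
  "name": "heuristic_k2_p4",
  "p": 4,
  "searches": [
    {
      "L": [
        0,
        0,
        0,
        2
      ],
      "U": [
        0,
        1,
        2,
        2
      ],
      "pi": [
        0,
        1,
        2,
        3
      ]
    },
    {
      "L": [
        0,
        0,
        1,
        1
      ],
      "U": [
        0,
        1,
        1,
        2
      ],
      "pi": [
        1,
        2,
        3,
        0
      ]
    },
    {
      "L": [
        0,
        0,
        0,
        0
      ],
      "U": [
        0,
        0,
        2,
        2
      ],
      "pi": [
        2,
        3,
        1,
        0
      ]
    }
  ]
}
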