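{
  "k": 3,
  "name": "heuristic_k3_p5",
  "p": 5,
  "searches": [
    {
      "L": [
        0,
        0,
        0,
        0,
        3
      ],
      "U": [
        0,
        2,
        2,
        3,
        3
      ],
      "pi": [
        0,
        1,
        2,
        3,
        4
      ]
    },
    {
      "L": [
        0,
        0,
        0,
        2,
        2
      ],
      "U": [
        0,
        1,
        2,
        2,
        3
      ],
      "pi": [
        1,
        2,
        3,
        4,
        0
      ]
    },
    {
      "L": [
        0,
        0,
        1,
        1,
        1
      ],
      "U": [
        0,
        1,
        1,
        2,
        3
      ],
      "pi": [
        2,
        3,
        4,
        1,
        0
      ]
    },
    {
      "L": [
        0,
        0,
        0,
        0,
        0
      ],
      "U": [
        0,
        0,
        3,
        3,
        3
      ],
      "pi": [
        3,
        4,
        2,
        1,
        0
      ]
    }
  ]
}
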