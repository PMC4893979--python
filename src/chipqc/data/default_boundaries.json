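{
  "cuts": {
    "10.0": [
      21.999894820121373,
      35.62292017170172,
      52.359249999999996
    ],
    "2.5": [
      13.352303769847332,
      17.772693954227634,
      18.24665285646593
    ],
    "5.0": [
      17.588412107651582,
      19.35291286554333,
      30.255499999999998
    ]
  },
  "provenance": "quartiles of 72 simulated datasets (sharp/broad x depths x enrichments, grading fraction 0.5)"
}
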