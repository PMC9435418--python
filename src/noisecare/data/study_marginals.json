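{
 "n": 209,
 "variables": {
  "exposure": {
   "states": [
    "low",
    "moderate",
    "high"
   ],
   "counts": [
    47,
    126,
    36
   ],
   "means": [
    48.8,
    54.92,
    61.75
   ],
   "sds": [
    1.84,
    1.69,
    1.53
   ]
  },
  "sensitivity": {
   "states": [
    "low",
    "moderate",
    "high"
   ],
   "counts": [
    59,
    93,
    57
   ],
   "means": [
    34.98,
    60.08,
    82.17
   ],
   "sds": [
    7.62,
    6.1,
    5.81
   ]
  },
  "annoyance": {
   "states": [
    "low",
    "moderate",
    "high"
   ],
   "counts": [
    61,
    104,
    44
   ],
   "means": [
    32.95,
    58.75,
    88.63
   ],
   "sds": [
    8.23,
    7.96,
    15.18
   ]
  },
  "quality": {
   "states": [
    "undesirable",
    "partly_desirable",
    "desirable"
   ],
   "counts": [
    19,
    97,
    93
   ],
   "means": [
    119.52,
    175.83,
    214.32
   ],
   "sds": [
    5.31,
    18.78,
    14.29
   ]
  },
  "psychosocial": {
   "states": [
    "undesirable",
    "partly_desirable",
    "desirable"
   ],
   "counts": [
    24,
    116,
    69
   ],
   "means": [
    47.16,
    73.16,
    92.18
   ],
   "sds": [
    8.2,
    6.81,
    5.94
   ]
  },
  "communicational": {
   "states": [
    "undesirable",
    "partly_desirable",
    "desirable"
   ],
   "counts": [
    21,
    101,
    87
   ],
   "means": [
    24.95,
    36.37,
    46.29
   ],
   "sds": [
    1.96,
    3.32,
    2.66
   ]
  },
  "physical": {
   "states": [
    "undesirable",
    "partly_desirable",
    "desirable"
   ],
   "counts": [
    30,
    74,
    105
   ],
   "means": [
    43.46,
    65.41,
    84.0
   ],
   "sds": [
    5.17,
    5.49,
    6.62
   ]
  }
 }
}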