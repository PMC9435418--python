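{
 "variables": [
  {
   "name": "exposure",
   "states": [
    "low",
    "moderate",
    "high"
   ]
  },
  {
   "name": "sensitivity",
   "states": [
    "low",
    "moderate",
    "high"
   ]
  },
  {
   "name": "annoyance",
   "states": [
    "low",
    "moderate",
    "high"
   ]
  },
  {
   "name": "quality",
   "states": [
    "undesirable",
    "partly_desirable",
    "desirable"
   ]
  }
 ],
 "cpts": [
  {
   "child": "exposure",
   "parents": [],
   "rows": [
    {
     "given": [],
     "probs": [
      0.22488038277511962,
      0.6028708133971292,
      0.1722488038277512
     ]
    }
   ]
  },
  {
   "child": "sensitivity",
   "parents": [],
   "rows": [
    {
     "given": [],
     "probs": [
      0.2822966507177033,
      0.4449760765550239,
      0.2727272727272727
     ]
    }
   ]
  },
  {
   "child": "annoyance",
   "parents": [],
   "rows": [
    {
     "given": [],
     "probs": [
      0.291866028708134,
      0.49760765550239233,
      0.21052631578947367
     ]
    }
   ]
  },
  {
   "child": "quality",
   "parents": [
    "exposure",
    "sensitivity",
    "annoyance"
   ],
   "rows": [
    {
     "given": [
      "low",
      "low",
      "low"
     ],
     "probs": [
      0.037,
      0.333,
      0.63
     ]
    },
    {
     "given": [
      "low",
      "low",
      "moderate"
     ],
     "probs": [
      0.333,
      0.333,
      0.334
     ]
    },
    {
     "given": [
      "low",
      "low",
      "high"
     ],
     "probs": [
      0.333,
      0.333,
      0.334
     ]
    },
    {
     "given": [
      "low",
      "moderate",
      "low"
     ],
     "probs": [
      0.167,
      0.083,
      0.75
     ]
    },
    {
     "given": [
      "low",
      "moderate",
      "moderate"
     ],
     "probs": [
      0.5,
      0.333,
      0.167
     ]
    },
    {
     "given": [
      "low",
      "moderate",
      "high"
     ],
     "probs": [
      0.333,
      0.333,
      0.334
     ]
    },
    {
     "given": [
      "low",
      "high",
      "low"
     ],
     "probs": [
      1.0,
      0.0,
      0.0
     ]
    },
    {
     "given": [
      "low",
      "high",
      "moderate"
     ],
     "probs": [
      0.0,
      1.0,
      0.0
     ]
    },
    {
     "given": [
      "low",
      "high",
      "high"
     ],
     "probs": [
      0.333,
      0.333,
      0.334
     ]
    },
    {
     "given": [
      "moderate",
      "low",
      "low"
     ],
     "probs": [
      0.0,
      0.231,
      0.769
     ]
    },
    {
     "given": [
      "moderate",
      "low",
      "moderate"
     ],
     "probs": [
      0.118,
      0.353,
      0.529
     ]
    },
    {
     "given": [
      "moderate",
      "low",
      "high"
     ],
     "probs": [
      0.333,
      0.333,
      0.334
     ]
    },
    {
     "given": [
      "moderate",
      "moderate",
      "low"
     ],
     "probs": [
      0.0,
      0.2,
      0.8
     ]
    },
    {
     "given": [
      "moderate",
      "moderate",
      "moderate"
     ],
     "probs": [
      0.038,
      0.481,
      0.481
     ]
    },
    {
     "given": [
      "moderate",
      "moderate",
      "high"
     ],
     "probs": [
      0.333,
      0.333,
      0.334
     ]
    },
    {
     "given": [
      "moderate",
      "high",
      "low"
     ],
     "probs": [
      0.5,
      0.5,
      0.0
     ]
    },
    {
     "given": [
      "moderate",
      "high",
      "moderate"
     ],
     "probs": [
      0.136,
      0.409,
      0.455
     ]
    },
    {
     "given": [
      "moderate",
      "high",
      "high"
     ],
     "probs": [
      0.0,
      0.833,
      0.167
     ]
    },
    {
     "given": [
      "high",
      "low",
      "low"
     ],
     "probs": [
      0.333,
      0.333,
      0.334
     ]
    },
    {
     "given": [
      "high",
      "low",
      "moderate"
     ],
     "probs": [
      0.0,
      1.0,
      0.0
     ]
    },
    {
     "given": [
      "high",
      "low",
      "high"
     ],
     "probs": [
      0.333,
      0.333,
      0.334
     ]
    },
    {
     "given": [
      "high",
      "moderate",
      "low"
     ],
     "probs": [
      0.0,
      1.0,
      0.0
     ]
    },
    {
     "given": [
      "high",
      "moderate",
      "moderate"
     ],
     "probs": [
      0.0,
      1.0,
      0.0
     ]
    },
    {
     "given": [
      "high",
      "moderate",
      "high"
     ],
     "probs": [
      0.27272727272727276,
      0.4545454545454546,
      0.2727272727272727
     ]
    },
    {
     "given": [
      "high",
      "high",
      "low"
     ],
     "probs": [
      0.333,
      0.333,
      0.334
     ]
    },
    {
     "given": [
      "high",
      "high",
      "moderate"
     ],
     "probs": [
      0.0,
      0.0,
      1.0
     ]
    },
    {
     "given": [
      "high",
      "high",
      "high"
     ],
     "probs": [
      0.111,
      0.889,
      0.0
     ]
    }
   ]
  }
 ]
}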