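{
 "artery_layers": {
  "ogden": {
   "adventitia": {
    "alpha": [
     24.61,
     25.0,
     23.9
    ],
    "d1": 3.92,
    "mu": [
     -1.99,
     1.2,
     0.81
    ]
   },
   "intima": {
    "alpha": [
     24.43,
     25.0,
     23.24
    ],
    "d1": 0.85,
    "mu": [
     -5.7,
     3.58,
     2.17
    ]
   },
   "media": {
    "alpha": [
     21.71,
     22.0,
     21.2
    ],
    "d1": 4.11,
    "mu": [
     -1.84,
     1.12,
     0.73
    ]
   }
  },
  "polynomial": {
   "adventitia": {
    "c01": 0.202,
    "c02": 1.34,
    "c10": -0.189,
    "c11": -1.38,
    "c20": 0.459
   },
   "intima": {
    "c01": 0.223,
    "c02": 2.67,
    "c10": -0.204,
    "c11": -3.71,
    "c20": 1.37
   },
   "media": {
    "c01": 0.128,
    "c02": 0.569,
    "c10": -0.117,
    "c11": -0.672,
    "c20": 0.224
   }
  },
  "reduced_polynomial": {
   "adventitia": {
    "c": [
     0.00827,
     0.012,
     0.52,
     -5.63,
     21.44,
     0.0
    ]
   },
   "intima": {
    "c": [
     0.00679,
     0.54,
     -1.11,
     10.65,
     -7.27,
     1.63
    ]
   },
   "media": {
    "c": [
     0.00652,
     0.0489,
     0.00926,
     0.76,
     -0.43,
     0.0869
    ]
   }
  }
 },
 "compositions": [
  "P9G1-A-C",
  "P9G1-A-NC",
  "P9G1-B-C",
  "P9G1-B-NC"
 ],
 "cryogel_density_kg_m3": {
  "P9G1-A-C": [
   1080.0,
   36.0
  ],
  "P9G1-A-NC": [
   1190.0,
   19.0
  ],
  "P9G1-B-C": [
   1070.0,
   37.0
  ],
  "P9G1-B-NC": [
   1120.0,
   38.0
  ]
 },
 "cryogel_ogden": {
  "P9G1-A-C": {
   "alpha1": [
    7.116,
    0.528
   ],
   "mu0": [
    0.157,
    0.016
   ],
   "mu1": [
    0.0444,
    0.006
   ],
   "r2": [
    0.9994,
    0.0004
   ]
  },
  "P9G1-A-NC": {
   "alpha1": [
    6.553,
    0.276
   ],
   "mu0": [
    0.122,
    0.012
   ],
   "mu1": [
    0.0374,
    0.0042
   ],
   "r2": [
    0.9988,
    0.0008
   ]
  },
  "P9G1-B-C": {
   "alpha1": [
    7.765,
    0.493
   ],
   "mu0": [
    0.107,
    0.009
   ],
   "mu1": [
    0.0276,
    0.001
   ],
   "r2": [
    0.9994,
    0.0003
   ]
  },
  "P9G1-B-NC": {
   "alpha1": [
    7.311,
    0.581
   ],
   "mu0": [
    0.083,
    0.011
   ],
   "mu1": [
    0.0227,
    0.0025
   ],
   "r2": [
    0.9988,
    0.0008
   ]
  }
 },
 "cryogel_yeoh": {
  "P9G1-A-C": {
   "c10": [
    0.0205,
    0.0035
   ],
   "c20": [
    0.0015,
    0.0028
   ],
   "c30": [
    0.0042,
    0.0017
   ],
   "mu0": [
    0.041,
    0.007
   ],
   "r2": [
    0.9994,
    0.0008
   ]
  },
  "P9G1-A-NC": {
   "c10": [
    0.018,
    0.0024
   ],
   "c20": [
    -0.0015,
    0.0019
   ],
   "c30": [
    0.0044,
    0.0012
   ],
   "mu0": [
    0.036,
    0.0049
   ],
   "r2": [
    0.9984,
    0.0009
   ]
  },
  "P9G1-B-C": {
   "c10": [
    0.0126,
    0.0006
   ],
   "c20": [
    0.0015,
    0.0014
   ],
   "c30": [
    0.0032,
    0.0006
   ],
   "mu0": [
    0.0252,
    0.0012
   ],
   "r2": [
    0.9997,
    0.0002
   ]
  },
  "P9G1-B-NC": {
   "c10": [
    0.0108,
    0.0014
   ],
   "c20": [
    -0.0007,
    0.0007
   ],
   "c30": [
    0.0033,
    0.0009
   ],
   "mu0": [
    0.0217,
    0.0027
   ],
   "r2": [
    0.9985,
    0.0007
   ]
  }
 },
 "graft_layups": {
  "PG-1": {
   "adventitia": "P9G1-A-C",
   "intima": "P9G1-A-C",
   "media": "P9G1-B-NC"
  },
  "PG-2": {
   "adventitia": "P9G1-A-NC",
   "intima": "P9G1-A-C",
   "media": "P9G1-B-NC"
  },
  "PG-3": {
   "adventitia": "P9G1-B-C",
   "intima": "P9G1-A-C",
   "media": "P9G1-B-NC"
  },
  "PG-4": {
   "adventitia": "P9G1-B-NC",
   "intima": "P9G1-A-C",
   "media": "P9G1-B-NC"
  }
 },
 "layer_thicknesses_mm": [
  0.23,
  0.3,
  0.34
 ],
 "pressure": {
  "diastolic_mmHg": 80.0,
  "mmHg_to_MPa": 0.000133322,
  "systolic_mmHg": 120.0
 },
 "soft_tissue": {
  "E_MPa": 0.05,
  "nu": 0.49
 }
}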