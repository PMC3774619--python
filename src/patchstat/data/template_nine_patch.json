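{
 "name": "nine-patch",
 "block_size": 25.0,
 "patches": [
  {
   "category": "A",
   "vertices": [
    [
     0.0,
     0.0
    ],
    [
     0.3333333333333333,
     0.0
    ],
    [
     0.3333333333333333,
     0.3333333333333333
    ],
    [
     0.0,
     0.3333333333333333
    ]
   ]
  },
  {
   "category": "B",
   "vertices": [
    [
     0.0,
     0.3333333333333333
    ],
    [
     0.3333333333333333,
     0.3333333333333333
    ],
    [
     0.3333333333333333,
     0.6666666666666666
    ],
    [
     0.0,
     0.6666666666666666
    ]
   ]
  },
  {
   "category": "A",
   "vertices": [
    [
     0.0,
     0.6666666666666666
    ],
    [
     0.3333333333333333,
     0.6666666666666666
    ],
    [
     0.3333333333333333,
     1.0
    ],
    [
     0.0,
     1.0
    ]
   ]
  },
  {
   "category": "B",
   "vertices": [
    [
     0.3333333333333333,
     0.0
    ],
    [
     0.6666666666666666,
     0.0
    ],
    [
     0.6666666666666666,
     0.3333333333333333
    ],
    [
     0.3333333333333333,
     0.3333333333333333
    ]
   ]
  },
  {
   "category": "A",
   "vertices": [
    [
     0.3333333333333333,
     0.3333333333333333
    ],
    [
     0.6666666666666666,
     0.3333333333333333
    ],
    [
     0.6666666666666666,
     0.6666666666666666
    ],
    [
     0.3333333333333333,
     0.6666666666666666
    ]
   ]
  },
  {
   "category": "B",
   "vertices": [
    [
     0.3333333333333333,
     0.6666666666666666
    ],
    [
     0.6666666666666666,
     0.6666666666666666
    ],
    [
     0.6666666666666666,
     1.0
    ],
    [
     0.3333333333333333,
     1.0
    ]
   ]
  },
  {
   "category": "A",
   "vertices": [
    [
     0.6666666666666666,
     0.0
    ],
    [
     1.0,
     0.0
    ],
    [
     1.0,
     0.3333333333333333
    ],
    [
     0.6666666666666666,
     0.3333333333333333
    ]
   ]
  },
  {
   "category": "B",
   "vertices": [
    [
     0.6666666666666666,
     0.3333333333333333
    ],
    [
     1.0,
     0.3333333333333333
    ],
    [
     1.0,
     0.6666666666666666
    ],
    [
     0.6666666666666666,
     0.6666666666666666
    ]
   ]
  },
  {
   "category": "A",
   "vertices": [
    [
     0.6666666666666666,
     0.6666666666666666
    ],
    [
     1.0,
     0.6666666666666666
    ],
    [
     1.0,
     1.0
    ],
    [
     0.6666666666666666,
     1.0
    ]
   ]
  }
 ]
}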