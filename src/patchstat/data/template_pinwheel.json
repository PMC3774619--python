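{
 "name": "pinwheel",
 "block_size": 25.0,
 "patches": [
  {
   "category": "blade",
   "vertices": [
    [
     0,
     0
    ],
    [
     0.5,
     0
    ],
    [
     0.5,
     0.5
    ]
   ]
  },
  {
   "category": "ground",
   "vertices": [
    [
     0,
     0
    ],
    [
     0.5,
     0.5
    ],
    [
     0,
     0.5
    ]
   ]
  },
  {
   "category": "blade",
   "vertices": [
    [
     0.5,
     0
    ],
    [
     1,
     0
    ],
    [
     0.5,
     0.5
    ]
   ]
  },
  {
   "category": "ground",
   "vertices": [
    [
     1,
     0
    ],
    [
     1,
     0.5
    ],
    [
     0.5,
     0.5
    ]
   ]
  },
  {
   "category": "blade",
   "vertices": [
    [
     1,
     0.5
    ],
    [
     1,
     1
    ],
    [
     0.5,
     0.5
    ]
   ]
  },
  {
   "category": "ground",
   "vertices": [
    [
     1,
     1
    ],
    [
     0.5,
     1
    ],
    [
     0.5,
     0.5
    ]
   ]
  },
  {
   "category": "blade",
   "vertices": [
    [
     0.5,
     1
    ],
    [
     0,
     1
    ],
    [
     0.5,
     0.5
    ]
   ]
  },
  {
   "category": "ground",
   "vertices": [
    [
     0,
     1
    ],
    [
     0,
     0.5
    ],
    [
     0.5,
     0.5
    ]
   ]
  }
 ]
}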