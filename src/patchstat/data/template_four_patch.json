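{
 "name": "four-patch",
 "block_size": 25.0,
 "patches": [
  {
   "category": "A",
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
    ],
    [
     0,
     0.5
    ]
   ]
  },
  {
   "category": "B",
   "vertices": [
    [
     0.5,
     0
    ],
    [
     1.0,
     0
    ],
    [
     1.0,
     0.5
    ],
    [
     0.5,
     0.5
    ]
   ]
  },
  {
   "category": "B",
   "vertices": [
    [
     0,
     0.5
    ],
    [
     0.5,
     0.5
    ],
    [
     0.5,
     1.0
    ],
    [
     0,
     1.0
    ]
   ]
  },
  {
   "category": "A",
   "vertices": [
    [
     0.5,
     0.5
    ],
    [
     1.0,
     0.5
    ],
    [
     1.0,
     1.0
    ],
    [
     0.5,
     1.0
    ]
   ]
  }
 ]
}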