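{
 "name": "double-four-patch",
 "block_size": 25.0,
 "patches": [
  {
   "category": "plain",
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
   "category": "plain",
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
   "category": "small",
   "vertices": [
    [
     0.0,
     0.0
    ],
    [
     0.25,
     0.0
    ],
    [
     0.25,
     0.25
    ],
    [
     0.0,
     0.25
    ]
   ]
  },
  {
   "category": "small",
   "vertices": [
    [
     0.0,
     0.25
    ],
    [
     0.25,
     0.25
    ],
    [
     0.25,
     0.5
    ],
    [
     0.0,
     0.5
    ]
   ]
  },
  {
   "category": "small",
   "vertices": [
    [
     0.25,
     0.0
    ],
    [
     0.5,
     0.0
    ],
    [
     0.5,
     0.25
    ],
    [
     0.25,
     0.25
    ]
   ]
  },
  {
   "category": "small",
   "vertices": [
    [
     0.25,
     0.25
    ],
    [
     0.5,
     0.25
    ],
    [
     0.5,
     0.5
    ],
    [
     0.25,
     0.5
    ]
   ]
  },
  {
   "category": "small",
   "vertices": [
    [
     0.5,
     0.5
    ],
    [
     0.75,
     0.5
    ],
    [
     0.75,
     0.75
    ],
    [
     0.5,
     0.75
    ]
   ]
  },
  {
   "category": "small",
   "vertices": [
    [
     0.5,
     0.75
    ],
    [
     0.75,
     0.75
    ],
    [
     0.75,
     1.0
    ],
    [
     0.5,
     1.0
    ]
   ]
  },
  {
   "category": "small",
   "vertices": [
    [
     0.75,
     0.5
    ],
    [
     1.0,
     0.5
    ],
    [
     1.0,
     0.75
    ],
    [
     0.75,
     0.75
    ]
   ]
  },
  {
   "category": "small",
   "vertices": [
    [
     0.75,
     0.75
    ],
    [
     1.0,
     0.75
    ],
    [
     1.0,
     1.0
    ],
    [
     0.75,
     1.0
    ]
   ]
  }
 ]
}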