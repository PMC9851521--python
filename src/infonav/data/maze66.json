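{
 "nodes": [
  {
   "id": 0,
   "x": 0,
   "y": 0,
   "landmark": true,
   "name": "A"
  },
  {
   "id": 1,
   "x": 1,
   "y": 0,
   "landmark": false,
   "name": ""
  },
  {
   "id": 2,
   "x": 2,
   "y": 0,
   "landmark": false,
   "name": ""
  },
  {
   "id": 3,
   "x": 3,
   "y": 0,
   "landmark": true,
   "name": "B"
  },
  {
   "id": 4,
   "x": 4,
   "y": 0,
   "landmark": false,
   "name": ""
  },
  {
   "id": 5,
   "x": 5,
   "y": 0,
   "landmark": false,
   "name": ""
  },
  {
   "id": 6,
   "x": 6,
   "y": 0,
   "landmark": false,
   "name": ""
  },
  {
   "id": 7,
   "x": 7,
   "y": 0,
   "landmark": true,
   "name": "C"
  },
  {
   "id": 8,
   "x": 8,
   "y": 0,
   "landmark": false,
   "name": ""
  },
  {
   "id": 9,
   "x": 9,
   "y": 0,
   "landmark": false,
   "name": ""
  },
  {
   "id": 10,
   "x": 10,
   "y": 0,
   "landmark": false,
   "name": ""
  },
  {
   "id": 11,
   "x": 11,
   "y": 0,
   "landmark": true,
   "name": "D"
  },
  {
   "id": 12,
   "x": 12,
   "y": 0,
   "landmark": false,
   "name": ""
  },
  {
   "id": 13,
   "x": 13,
   "y": 0,
   "landmark": false,
   "name": ""
  },
  {
   "id": 14,
   "x": 14,
   "y": 0,
   "landmark": true,
   "name": "E"
  },
  {
   "id": 15,
   "x": 0,
   "y": 1,
   "landmark": false,
   "name": ""
  },
  {
   "id": 16,
   "x": 5,
   "y": 1,
   "landmark": false,
   "name": ""
  },
  {
   "id": 17,
   "x": 10,
   "y": 1,
   "landmark": false,
   "name": ""
  },
  {
   "id": 18,
   "x": 14,
   "y": 1,
   "landmark": false,
   "name": ""
  },
  {
   "id": 19,
   "x": 0,
   "y": 2,
   "landmark": true,
   "name": "L"
  },
  {
   "id": 20,
   "x": 5,
   "y": 2,
   "landmark": false,
   "name": ""
  },
  {
   "id": 21,
   "x": 10,
   "y": 2,
   "landmark": false,
   "name": ""
  },
  {
   "id": 22,
   "x": 14,
   "y": 2,
   "landmark": false,
   "name": ""
  },
  {
   "id": 23,
   "x": 0,
   "y": 3,
   "landmark": false,
   "name": ""
  },
  {
   "id": 24,
   "x": 5,
   "y": 3,
   "landmark": false,
   "name": ""
  },
  {
   "id": 25,
   "x": 10,
   "y": 3,
   "landmark": false,
   "name": ""
  },
  {
   "id": 26,
   "x": 14,
   "y": 3,
   "landmark": false,
   "name": ""
  },
  {
   "id": 27,
   "x": 0,
   "y": 4,
   "landmark": false,
   "name": ""
  },
  {
   "id": 28,
   "x": 1,
   "y": 4,
   "landmark": false,
   "name": ""
  },
  {
   "id": 29,
   "x": 2,
   "y": 4,
   "landmark": false,
   "name": ""
  },
  {
   "id": 30,
   "x": 3,
   "y": 4,
   "landmark": false,
   "name": ""
  },
  {
   "id": 31,
   "x": 4,
   "y": 4,
   "landmark": false,
   "name": ""
  },
  {
   "id": 32,
   "x": 5,
   "y": 4,
   "landmark": false,
   "name": ""
  },
  {
   "id": 33,
   "x": 7,
   "y": 4,
   "landmark": false,
   "name": ""
  },
  {
   "id": 34,
   "x": 10,
   "y": 4,
   "landmark": false,
   "name": ""
  },
  {
   "id": 35,
   "x": 14,
   "y": 4,
   "landmark": true,
   "name": "F"
  },
  {
   "id": 36,
   "x": 0,
   "y": 5,
   "landmark": false,
   "name": ""
  },
  {
   "id": 37,
   "x": 5,
   "y": 5,
   "landmark": false,
   "name": ""
  },
  {
   "id": 38,
   "x": 7,
   "y": 5,
   "landmark": false,
   "name": ""
  },
  {
   "id": 39,
   "x": 10,
   "y": 5,
   "landmark": false,
   "name": ""
  },
  {
   "id": 40,
   "x": 14,
   "y": 5,
   "landmark": false,
   "name": ""
  },
  {
   "id": 41,
   "x": 0,
   "y": 6,
   "landmark": true,
   "name": "K"
  },
  {
   "id": 42,
   "x": 5,
   "y": 6,
   "landmark": false,
   "name": ""
  },
  {
   "id": 43,
   "x": 7,
   "y": 6,
   "landmark": false,
   "name": ""
  },
  {
   "id": 44,
   "x": 10,
   "y": 6,
   "landmark": false,
   "name": ""
  },
  {
   "id": 45,
   "x": 14,
   "y": 6,
   "landmark": false,
   "name": ""
  },
  {
   "id": 46,
   "x": 0,
   "y": 7,
   "landmark": false,
   "name": ""
  },
  {
   "id": 47,
   "x": 5,
   "y": 7,
   "landmark": false,
   "name": ""
  },
  {
   "id": 48,
   "x": 7,
   "y": 7,
   "landmark": false,
   "name": ""
  },
  {
   "id": 49,
   "x": 10,
   "y": 7,
   "landmark": false,
   "name": ""
  },
  {
   "id": 50,
   "x": 14,
   "y": 7,
   "landmark": false,
   "name": ""
  },
  {
   "id": 51,
   "x": 0,
   "y": 8,
   "landmark": true,
   "name": "J"
  },
  {
   "id": 52,
   "x": 1,
   "y": 8,
   "landmark": false,
   "name": ""
  },
  {
   "id": 53,
   "x": 2,
   "y": 8,
   "landmark": false,
   "name": ""
  },
  {
   "id": 54,
   "x": 3,
   "y": 8,
   "landmark": true,
   "name": "I"
  },
  {
   "id": 55,
   "x": 4,
   "y": 8,
   "landmark": false,
   "name": ""
  },
  {
   "id": 56,
   "x": 5,
   "y": 8,
   "landmark": false,
   "name": ""
  },
  {
   "id": 57,
   "x": 6,
   "y": 8,
   "landmark": false,
   "name": ""
  },
  {
   "id": 58,
   "x": 7,
   "y": 8,
   "landmark": false,
   "name": ""
  },
  {
   "id": 59,
   "x": 8,
   "y": 8,
   "landmark": false,
   "name": ""
  },
  {
   "id": 60,
   "x": 9,
   "y": 8,
   "landmark": false,
   "name": ""
  },
  {
   "id": 61,
   "x": 10,
   "y": 8,
   "landmark": false,
   "name": ""
  },
  {
   "id": 62,
   "x": 11,
   "y": 8,
   "landmark": true,
   "name": "H"
  },
  {
   "id": 63,
   "x": 12,
   "y": 8,
   "landmark": false,
   "name": ""
  },
  {
   "id": 64,
   "x": 13,
   "y": 8,
   "landmark": false,
   "name": ""
  },
  {
   "id": 65,
   "x": 14,
   "y": 8,
   "landmark": true,
   "name": "G"
  }
 ],
 "edges": [
  [
   0,
   1,
   "E"
  ],
  [
   0,
   15,
   "N"
  ],
  [
   1,
   2,
   "E"
  ],
  [
   2,
   3,
   "E"
  ],
  [
   3,
   4,
   "E"
  ],
  [
   4,
   5,
   "E"
  ],
  [
   5,
   6,
   "E"
  ],
  [
   5,
   16,
   "N"
  ],
  [
   6,
   7,
   "E"
  ],
  [
   7,
   8,
   "E"
  ],
  [
   8,
   9,
   "E"
  ],
  [
   9,
   10,
   "E"
  ],
  [
   10,
   11,
   "E"
  ],
  [
   10,
   17,
   "N"
  ],
  [
   11,
   12,
   "E"
  ],
  [
   12,
   13,
   "E"
  ],
  [
   13,
   14,
   "E"
  ],
  [
   14,
   18,
   "N"
  ],
  [
   15,
   19,
   "N"
  ],
  [
   16,
   20,
   "N"
  ],
  [
   17,
   21,
   "N"
  ],
  [
   18,
   22,
   "N"
  ],
  [
   19,
   23,
   "N"
  ],
  [
   20,
   24,
   "N"
  ],
  [
   21,
   25,
   "N"
  ],
  [
   22,
   26,
   "N"
  ],
  [
   23,
   27,
   "N"
  ],
  [
   24,
   32,
   "N"
  ],
  [
   25,
   34,
   "N"
  ],
  [
   26,
   35,
   "N"
  ],
  [
   27,
   28,
   "E"
  ],
  [
   27,
   36,
   "N"
  ],
  [
   28,
   29,
   "E"
  ],
  [
   29,
   30,
   "E"
  ],
  [
   30,
   31,
   "E"
  ],
  [
   32,
   37,
   "N"
  ],
  [
   33,
   38,
   "N"
  ],
  [
   34,
   39,
   "N"
  ],
  [
   35,
   40,
   "N"
  ],
  [
   36,
   41,
   "N"
  ],
  [
   37,
   42,
   "N"
  ],
  [
   38,
   43,
   "N"
  ],
  [
   39,
   44,
   "N"
  ],
  [
   40,
   45,
   "N"
  ],
  [
   41,
   46,
   "N"
  ],
  [
   42,
   47,
   "N"
  ],
  [
   43,
   48,
   "N"
  ],
  [
   44,
   49,
   "N"
  ],
  [
   45,
   50,
   "N"
  ],
  [
   46,
   51,
   "N"
  ],
  [
   47,
   56,
   "N"
  ],
  [
   48,
   58,
   "N"
  ],
  [
   49,
   61,
   "N"
  ],
  [
   50,
   65,
   "N"
  ],
  [
   51,
   52,
   "E"
  ],
  [
   52,
   53,
   "E"
  ],
  [
   53,
   54,
   "E"
  ],
  [
   54,
   55,
   "E"
  ],
  [
   55,
   56,
   "E"
  ],
  [
   56,
   57,
   "E"
  ],
  [
   57,
   58,
   "E"
  ],
  [
   58,
   59,
   "E"
  ],
  [
   59,
   60,
   "E"
  ],
  [
   60,
   61,
   "E"
  ],
  [
   61,
   62,
   "E"
  ],
  [
   62,
   63,
   "E"
  ],
  [
   63,
   64,
   "E"
  ],
  [
   64,
   65,
   "E"
  ]
 ],
 "metadata": {
  "default_route": [
   0,
   1,
   2,
   3,
   4,
   5,
   6,
   7,
   8,
   9,
   10,
   11,
   12,
   13,
   14,
   18,
   22,
   26,
   35,
   40,
   45,
   50,
   65,
   64,
   63,
   62,
   61,
   60,
   59,
   58,
   57,
   56,
   55,
   54,
   53,
   52,
   51,
   46,
   41,
   36,
   27,
   23,
   19,
   15,
   0
  ]
 }
}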