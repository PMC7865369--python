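{
 "points": [
  [
   -0.52,
   -0.38
  ],
  [
   -0.346667,
   -0.435556
  ],
  [
   -0.173333,
   -0.468889
  ],
  [
   0.0,
   -0.48
  ],
  [
   0.173333,
   -0.468889
  ],
  [
   0.346667,
   -0.435556
  ],
  [
   0.52,
   -0.38
  ],
  [
   -0.62,
   -0.29
  ],
  [
   -0.465,
   -0.31625
  ],
  [
   -0.31,
   -0.335
  ],
  [
   -0.155,
   -0.34625
  ],
  [
   0.0,
   -0.35
  ],
  [
   0.155,
   -0.34625
  ],
  [
   0.31,
   -0.335
  ],
  [
   0.465,
   -0.31625
  ],
  [
   0.62,
   -0.29
  ],
  [
   -0.68,
   -0.18
  ],
  [
   -0.453333,
   -0.202222
  ],
  [
   -0.226667,
   -0.215556
  ],
  [
   0.0,
   -0.22
  ],
  [
   0.226667,
   -0.215556
  ],
  [
   0.453333,
   -0.202222
  ],
  [
   0.68,
   -0.18
  ],
  [
   -0.72,
   -0.06
  ],
  [
   -0.576,
   -0.0672
  ],
  [
   -0.432,
   -0.0728
  ],
  [
   -0.288,
   -0.0768
  ],
  [
   -0.144,
   -0.0792
  ],
  [
   0.0,
   -0.08
  ],
  [
   0.144,
   -0.0792
  ],
  [
   0.288,
   -0.0768
  ],
  [
   0.432,
   -0.0728
  ],
  [
   0.576,
   -0.0672
  ],
  [
   0.72,
   -0.06
  ],
  [
   -0.7,
   0.1
  ],
  [
   -0.56,
   0.1
  ],
  [
   -0.42,
   0.1
  ],
  [
   -0.28,
   0.1
  ],
  [
   -0.14,
   0.1
  ],
  [
   0.0,
   0.1
  ],
  [
   0.14,
   0.1
  ],
  [
   0.28,
   0.1
  ],
  [
   0.42,
   0.1
  ],
  [
   0.56,
   0.1
  ],
  [
   0.7,
   0.1
  ],
  [
   -0.58,
   0.26
  ],
  [
   -0.464,
   0.2672
  ],
  [
   -0.348,
   0.2728
  ],
  [
   -0.232,
   0.2768
  ],
  [
   -0.116,
   0.2792
  ],
  [
   0.0,
   0.28
  ],
  [
   0.116,
   0.2792
  ],
  [
   0.232,
   0.2768
  ],
  [
   0.348,
   0.2728
  ],
  [
   0.464,
   0.2672
  ],
  [
   0.58,
   0.26
  ],
  [
   -0.34,
   0.38
  ],
  [
   -0.17,
   0.425
  ],
  [
   0.0,
   0.44
  ],
  [
   0.17,
   0.425
  ],
  [
   0.34,
   0.38
  ],
  [
   -0.33,
   -0.250926
  ],
  [
   -0.487111,
   -0.114074
  ],
  [
   -0.391111,
   -0.117274
  ],
  [
   -0.322667,
   -0.164859
  ],
  [
   -0.219556,
   -0.123852
  ],
  [
   -0.38,
   -0.016533
  ],
  [
   0.33,
   -0.250926
  ],
  [
   0.487111,
   -0.114074
  ],
  [
   0.391111,
   -0.117274
  ],
  [
   0.322667,
   -0.164859
  ],
  [
   0.219556,
   -0.123852
  ],
  [
   0.38,
   -0.016533
  ],
  [
   -0.162667,
   0.218667
  ],
  [
   -0.172667,
   0.327
  ],
  [
   -0.095333,
   0.3814
  ],
  [
   -0.038667,
   0.333067
  ],
  [
   0.162667,
   0.218667
  ],
  [
   0.172667,
   0.327
  ],
  [
   0.095333,
   0.3814
  ],
  [
   0.038667,
   0.333067
  ]
 ],
 "triangles": [
  [
   0,
   8,
   7
  ],
  [
   1,
   8,
   0
  ],
  [
   1,
   9,
   8
  ],
  [
   2,
   9,
   1
  ],
  [
   2,
   10,
   9
  ],
  [
   3,
   10,
   2
  ],
  [
   3,
   11,
   10
  ],
  [
   3,
   11,
   12
  ],
  [
   3,
   12,
   4
  ],
  [
   4,
   12,
   13
  ],
  [
   4,
   13,
   5
  ],
  [
   5,
   13,
   14
  ],
  [
   5,
   14,
   6
  ],
  [
   6,
   14,
   15
  ],
  [
   7,
   17,
   16
  ],
  [
   8,
   17,
   7
  ],
  [
   9,
   17,
   8
  ],
  [
   9,
   18,
   17
  ],
  [
   10,
   18,
   9
  ],
  [
   10,
   19,
   18
  ],
  [
   11,
   19,
   10
  ],
  [
   11,
   19,
   12
  ],
  [
   12,
   19,
   20
  ],
  [
   12,
   20,
   13
  ],
  [
   13,
   20,
   21
  ],
  [
   13,
   21,
   14
  ],
  [
   14,
   21,
   15
  ],
  [
   15,
   21,
   22
  ],
  [
   16,
   24,
   23
  ],
  [
   17,
   24,
   16
  ],
  [
   17,
   25,
   24
  ],
  [
   17,
   26,
   25
  ],
  [
   18,
   26,
   17
  ],
  [
   18,
   27,
   26
  ],
  [
   19,
   27,
   18
  ],
  [
   19,
   28,
   27
  ],
  [
   19,
   28,
   29
  ],
  [
   19,
   29,
   20
  ],
  [
   20,
   29,
   30
  ],
  [
   20,
   30,
   21
  ],
  [
   21,
   30,
   31
  ],
  [
   21,
   31,
   32
  ],
  [
   21,
   32,
   22
  ],
  [
   22,
   32,
   33
  ],
  [
   24,
   34,
   23
  ],
  [
   24,
   35,
   34
  ],
  [
   25,
   35,
   24
  ],
  [
   25,
   36,
   35
  ],
  [
   26,
   36,
   25
  ],
  [
   26,
   37,
   36
  ],
  [
   27,
   37,
   26
  ],
  [
   27,
   38,
   37
  ],
  [
   28,
   38,
   27
  ],
  [
   28,
   39,
   38
  ],
  [
   28,
   39,
   40
  ],
  [
   28,
   40,
   29
  ],
  [
   29,
   40,
   41
  ],
  [
   29,
   41,
   30
  ],
  [
   30,
   41,
   42
  ],
  [
   30,
   42,
   31
  ],
  [
   31,
   42,
   43
  ],
  [
   31,
   43,
   32
  ],
  [
   32,
   43,
   44
  ],
  [
   32,
   44,
   33
  ],
  [
   35,
   45,
   34
  ],
  [
   35,
   46,
   45
  ],
  [
   36,
   46,
   35
  ],
  [
   36,
   47,
   46
  ],
  [
   37,
   47,
   36
  ],
  [
   37,
   48,
   47
  ],
  [
   38,
   48,
   37
  ],
  [
   38,
   49,
   48
  ],
  [
   39,
   49,
   38
  ],
  [
   39,
   50,
   49
  ],
  [
   39,
   50,
   51
  ],
  [
   39,
   51,
   40
  ],
  [
   40,
   51,
   52
  ],
  [
   40,
   52,
   41
  ],
  [
   41,
   52,
   53
  ],
  [
   41,
   53,
   42
  ],
  [
   42,
   53,
   54
  ],
  [
   42,
   54,
   43
  ],
  [
   43,
   54,
   55
  ],
  [
   43,
   55,
   44
  ],
  [
   46,
   56,
   45
  ],
  [
   47,
   56,
   46
  ],
  [
   48,
   56,
   47
  ],
  [
   48,
   57,
   56
  ],
  [
   49,
   57,
   48
  ],
  [
   49,
   58,
   57
  ],
  [
   50,
   58,
   49
  ],
  [
   50,
   58,
   51
  ],
  [
   51,
   58,
   59
  ],
  [
   51,
   59,
   52
  ],
  [
   52,
   59,
   60
  ],
  [
   52,
   60,
   53
  ],
  [
   53,
   60,
   54
  ],
  [
   54,
   60,
   55
  ]
 ],
 "landmark_mirror": [
  6,
  5,
  4,
  3,
  2,
  1,
  0,
  15,
  14,
  13,
  12,
  11,
  10,
  9,
  8,
  7,
  22,
  21,
  20,
  19,
  18,
  17,
  16,
  33,
  32,
  31,
  30,
  29,
  28,
  27,
  26,
  25,
  24,
  23,
  44,
  43,
  42,
  41,
  40,
  39,
  38,
  37,
  36,
  35,
  34,
  55,
  54,
  53,
  52,
  51,
  50,
  49,
  48,
  47,
  46,
  45,
  60,
  59,
  58,
  57,
  56,
  67,
  68,
  69,
  70,
  71,
  72,
  61,
  62,
  63,
  64,
  65,
  66,
  77,
  78,
  79,
  80,
  73,
  74,
  75,
  76
 ],
 "region_mirror": [
  13,
  12,
  11,
  10,
  9,
  8,
  7,
  6,
  5,
  4,
  3,
  2,
  1,
  0,
  27,
  26,
  25,
  24,
  23,
  22,
  21,
  20,
  19,
  18,
  17,
  16,
  15,
  14,
  43,
  42,
  41,
  40,
  39,
  38,
  37,
  36,
  35,
  34,
  33,
  32,
  31,
  30,
  29,
  28,
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
  50,
  49,
  48,
  47,
  46,
  45,
  44,
  83,
  82,
  81,
  80,
  79,
  78,
  77,
  76,
  75,
  74,
  73,
  72,
  71,
  70,
  69,
  68,
  67,
  66,
  65,
  64,
  97,
  96,
  95,
  94,
  93,
  92,
  91,
  90,
  89,
  88,
  87,
  86,
  85,
  84
 ],
 "meta_regions": {
  "forehead": [
   [
    6,
    7
   ],
   [
    5,
    8
   ],
   [
    4,
    9
   ],
   [
    19,
    22
   ]
  ],
  "nose_bridge": [
   [
    35,
    36
   ],
   [
    53,
    54
   ]
  ],
  "mid_cheek": [
   [
    45,
    62
   ],
   [
    46,
    61
   ],
   [
    47,
    60
   ],
   [
    48,
    59
   ]
  ],
  "nasolabial_fold": [
   [
    67,
    80
   ],
   [
    68,
    79
   ],
   [
    69,
    78
   ]
  ],
  "upper_perioral": [
   [
    71,
    76
   ],
   [
    72,
    75
   ],
   [
    73,
    74
   ]
  ],
  "chin": [
   [
    90,
    91
   ],
   [
    89,
    92
   ],
   [
    88,
    93
   ]
  ]
 },
 "reference_region": 20
}
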