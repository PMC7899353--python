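# Scoring tables for the CAPL-2 batch scorer.
#
# Units:
#   pacer.conversion_15m_to_20m : 15-metre laps -> 20-metre-equivalent laps
#   plank.seconds_per_point     : seconds of hold per point (capped at max_score)
#   camsa.time_bins             : right-closed trial-time intervals (seconds) -> points
#   steps.score_lower_edges     : minimum step average (steps/day) earning score i+1
#   steps.min_daily/max_daily   : daily step-count validity bounds (steps)
#   steps.min_wear_hours        : minimum pedometer wear time (decimal hours)
#   self_report.map             : active days (0-7) -> points (0-5)
#   csappa.points               : response (1-4) -> points, "normal" orientation;
#                                 "reversed" items score points[5 - response]
#   breq.points                 : response (1-5) -> points
#
# Entries marked PROVISIONAL reconstruct manual-only tables: they honour the
# documented score ranges and monotonicity but are not transcriptions.
# Override any value by passing a copy of this file with --config / config=.

pacer:
  laps_per_point: 5
  max_score: 10
  valid_lap_range: [1, 229]
  # PROVISIONAL distance-equivalent lookup (kept as an explicit table
  # because the shuttle-run stage structure need not be linear).
  conversion_15m_to_20m:
    1: 1
    2: 1
    3: 2
    4: 3
    5: 3
    6: 4
    7: 5
    8: 6
    9: 6
    10: 7
    11: 8
    12: 9
    13: 9
    14: 10
    15: 11
    16: 12
    17: 12
    18: 13
    19: 14
    20: 15
    21: 15
    22: 16
    23: 17
    24: 18
    25: 18
    26: 19
    27: 20
    28: 21
    29: 21
    30: 22
    31: 23
    32: 24
    33: 24
    34: 25
    35: 26
    36: 27
    37: 27
    38: 28
    39: 29
    40: 30
    41: 30
    42: 31
    43: 32
    44: 33
    45: 33
    46: 34
    47: 35
    48: 36
    49: 36
    50: 37
    51: 38
    52: 39
    53: 39
    54: 40
    55: 41
    56: 42
    57: 42
    58: 43
    59: 44
    60: 45
    61: 45
    62: 46
    63: 47
    64: 48
    65: 48
    66: 49
    67: 50
    68: 51
    69: 51
    70: 52
    71: 53
    72: 54
    73: 54
    74: 55
    75: 56
    76: 57
    77: 57
    78: 58
    79: 59
    80: 60
    81: 60
    82: 61
    83: 62
    84: 63
    85: 63
    86: 64
    87: 65
    88: 66
    89: 66
    90: 67
    91: 68
    92: 69
    93: 69
    94: 70
    95: 71
    96: 72
    97: 72
    98: 73
    99: 74
    100: 75
    101: 75
    102: 76
    103: 77
    104: 78
    105: 78
    106: 79
    107: 80
    108: 81
    109: 81
    110: 82
    111: 83
    112: 84
    113: 84
    114: 85
    115: 86
    116: 87
    117: 87
    118: 88
    119: 89
    120: 90
    121: 90
    122: 91
    123: 92
    124: 93
    125: 93
    126: 94
    127: 95
    128: 96
    129: 96
    130: 97
    131: 98
    132: 99
    133: 99
    134: 100
    135: 101
    136: 102
    137: 102
    138: 103
    139: 104
    140: 105
    141: 105
    142: 106
    143: 107
    144: 108
    145: 108
    146: 109
    147: 110
    148: 111
    149: 111
    150: 112
    151: 113
    152: 114
    153: 114
    154: 115
    155: 116
    156: 117
    157: 117
    158: 118
    159: 119
    160: 120
    161: 120
    162: 121
    163: 122
    164: 123
    165: 123
    166: 124
    167: 125
    168: 126
    169: 126
    170: 127
    171: 128
    172: 129
    173: 129
    174: 130
    175: 131
    176: 132
    177: 132
    178: 133
    179: 134
    180: 135
    181: 135
    182: 136
    183: 137
    184: 138
    185: 138
    186: 139
    187: 140
    188: 141
    189: 141
    190: 142
    191: 143
    192: 144
    193: 144
    194: 145
    195: 146
    196: 147
    197: 147
    198: 148
    199: 149
    200: 150
    201: 150
    202: 151
    203: 152
    204: 153
    205: 153
    206: 154
    207: 155
    208: 156
    209: 156
    210: 157
    211: 158
    212: 159
    213: 159
    214: 160
    215: 161
    216: 162
    217: 162
    218: 163
    219: 164
    220: 165
    221: 165
    222: 166
    223: 167
    224: 168
    225: 168
    226: 169
    227: 170
    228: 171
    229: 171
    230: 172
    231: 173
    232: 174
    233: 174
    234: 175
    235: 176
    236: 177
    237: 177
    238: 178
    239: 179
    240: 180
    241: 180
    242: 181
    243: 182
    244: 183
    245: 183
    246: 184
    247: 185
    248: 186
    249: 186
    250: 187
    251: 188
    252: 189
    253: 189
    254: 190
    255: 191
    256: 192
    257: 192
    258: 193
    259: 194
    260: 195
    261: 195
    262: 196
    263: 197
    264: 198
    265: 198
    266: 199
    267: 200
    268: 201
    269: 201
    270: 202
    271: 203
    272: 204
    273: 204
    274: 205
    275: 206
    276: 207
    277: 207
    278: 208
    279: 209
    280: 210
    281: 210
    282: 211
    283: 212
    284: 213
    285: 213
    286: 214
    287: 215
    288: 216
    289: 216
    290: 217
    291: 218
    292: 219
    293: 219
    294: 220
    295: 221
    296: 222
    297: 222
    298: 223
    299: 224
    300: 225
    301: 225
    302: 226
    303: 227
    304: 228
    305: 228
    306: 229

plank:
  # PROVISIONAL: one point per 12 seconds held, capped at 10.
  seconds_per_point: 12
  max_score: 10

camsa:
  skill_range: [0, 14]
  divisor: 2.8
  slowest_score: 1
  # PROVISIONAL right-closed bins: a trial at or under max_seconds earns score.
  time_bins:
    - {max_seconds: 14, score: 14}
    - {max_seconds: 16, score: 13}
    - {max_seconds: 18, score: 12}
    - {max_seconds: 20, score: 11}
    - {max_seconds: 22, score: 10}
    - {max_seconds: 24, score: 9}
    - {max_seconds: 26, score: 8}
    - {max_seconds: 28, score: 7}
    - {max_seconds: 30, score: 6}
    - {max_seconds: 32, score: 5}
    - {max_seconds: 34, score: 4}
    - {max_seconds: 36, score: 3}
    - {max_seconds: 38, score: 2}

steps:
  # PROVISIONAL validity bounds and score table.
  min_daily: 1000
  max_daily: 30000
  min_wear_hours: 10.0
  # score_lower_edges[i] is the minimum step average earning score i+1;
  # averages below the first edge score 0, at/above the last edge score 25.
  score_lower_edges:
    - 5500
    - 6000
    - 6500
    - 7000
    - 7500
    - 8000
    - 8500
    - 9000
    - 9500
    - 10000
    - 10500
    - 11000
    - 11500
    - 12000
    - 12500
    - 13000
    - 13500
    - 14000
    - 14500
    - 15000
    - 15500
    - 16000
    - 16500
    - 17000
    - 17500

self_report:
  map: {0: 0, 1: 1, 2: 2, 3: 3, 4: 4, 5: 5, 6: 5, 7: 5}

csappa:
  points: {1: 0.6, 2: 1.2, 3: 1.8, 4: 2.5}
  # PROVISIONAL per-item orientation (which end of the response scale earns
  # the most points); the questionnaire alternates item polarity.
  orientation:
    csappa1: reversed
    csappa2: normal
    csappa3: normal
    csappa4: reversed
    csappa5: reversed
    csappa6: normal

breq:
  points: {1: 0.5, 2: 1.0, 3: 1.5, 4: 2.0, 5: 2.5}

knowledge:
  # String matching is exact (after trimming outer whitespace) by default.
  case_sensitive: true
  answer_keys:
    pa_guideline:
      code: 3
      strings: ["60 minutes or 1 hour"]
    crf_means:
      code: 2
      strings: ["How well the heart can pump blood and the lungs can provide oxygen"]
    ms_means:
      code: 1
      strings: ["How well the muscles can push, pull or stretch"]
    sports_skill:
      code: 4
      strings: ["Watch a video, take a lesson or have a coach teach you how to kick and catch"]
  # PROVISIONAL accepted words for the six story blanks (1 point each).
  fill_blank_keys:
    pa_is: ["fun"]
    pa_is_also: ["important"]
    improve: ["endurance"]
    increase: ["strength"]
    when_cooling_down: ["stretches"]
    heart_rate: ["decreases"]

interpretation:
  # Raw-vs-derived column fed to the normative lookup, per protocol.  The
  # plank lookup is keyed on hold time in seconds; all others on scores.
  inputs:
    pacer: pacer_score
    steps: step_average
    plank: plank_time
    camsa: camsa_score
    pc: pc_score
    db: db_score
    mc: mc_score
    ku: ku_score
    capl: capl_score
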