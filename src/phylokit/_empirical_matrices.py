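"""Published empirical amino-acid replacement model data.

Lower-triangle exchangeabilities (column-major: (2,1),(3,1)...(20,1),
(3,2)...(20,19)) and equilibrium frequencies for the classical empirical
models: Dayhoff (Dayhoff, Schwartz & Orcutt 1978), JTT (Jones, Taylor &
Thornton 1992), mtREV24 (Adachi & Hasegawa 1996), LG (Le & Gascuel 2008)
and WAG (Whelan & Goldman 2001).  Residues are in the conventional
ARNDCQEGHILKMFPSTWYV order.
"""

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

DAYHOFF_RATES = [
    27, 98, 120, 36, 89, 198, 240, 23,
    65, 41, 26, 72, 18, 250, 409, 371,
    0, 24, 208, 32, 0, 23, 246, 1,
    9, 240, 64, 15, 464, 90, 14, 103,
    154, 26, 201, 8, 24, 905, 0, 103,
    148, 139, 535, 77, 34, 318, 1, 14,
    42, 495, 229, 23, 95, 15, 0, 134,
    1153, 125, 86, 24, 0, 71, 0, 0,
    13, 95, 66, 0, 0, 18, 0, 0,
    11, 28, 44, 0, 0, 0, 0, 19,
    161, 16, 0, 96, 49, 716, 28, 606,
    18, 73, 153, 114, 0, 153, 56, 53,
    0, 0, 35, 81, 43, 61, 11, 83,
    30, 0, 51, 79, 34, 0, 22, 37,
    10, 0, 7, 27, 17, 15, 34, 234,
    30, 0, 0, 54, 7, 44, 26, 0,
    48, 94, 35, 22, 27, 127, 44, 257,
    46, 336, 196, 12, 24, 192, 0, 37,
    889, 18, 527, 157, 32, 17, 33, 46,
    28, 175, 243, 0, 33, 96, 136, 0,
    13, 10, 92, 17, 62, 104, 0, 0,
    258, 11, 46, 13, 76, 698, 12, 245,
    78, 0, 0, 48, 550, 75, 34, 30,
    0, 42, 157, 61, 0, 28,
]
DAYHOFF_FREQS = [
    0.08712691287, 0.0409039591, 0.04043195957, 0.04687195313, 0.03347396653,
    0.03825496175, 0.04952995047, 0.08861191139, 0.03361796638, 0.03688596311,
    0.08535691464, 0.08048191952, 0.01475298525, 0.03977196023, 0.05067994932,
    0.06957693042, 0.05854194146, 0.01049398951, 0.02991597008, 0.06471793528,
]

JTT_RATES = [
    58, 54, 81, 56, 57, 105, 179, 27,
    36, 30, 35, 54, 15, 194, 378, 475,
    9, 11, 298, 45, 16, 113, 310, 29,
    137, 328, 22, 38, 646, 44, 5, 74,
    101, 64, 126, 20, 17, 528, 34, 86,
    58, 81, 391, 47, 12, 263, 30, 10,
    15, 503, 232, 8, 70, 16, 10, 49,
    767, 130, 112, 11, 7, 26, 15, 4,
    15, 59, 38, 4, 46, 31, 9, 5,
    59, 69, 17, 23, 7, 31, 78, 14,
    223, 42, 115, 209, 62, 323, 26, 597,
    9, 72, 292, 43, 4, 164, 53, 51,
    18, 24, 20, 119, 26, 12, 9, 181,
    18, 5, 18, 30, 32, 10, 7, 45,
    23, 6, 6, 27, 14, 5, 24, 201,
    33, 55, 8, 47, 16, 56, 45, 33,
    40, 115, 73, 46, 8, 573, 11, 229,
    21, 479, 89, 10, 40, 245, 9, 32,
    961, 14, 388, 248, 102, 59, 25, 52,
    24, 180, 65, 4, 21, 47, 103, 10,
    8, 14, 43, 16, 29, 226, 24, 18,
    323, 17, 92, 12, 53, 536, 62, 285,
    118, 6, 10, 23, 477, 35, 63, 38,
    12, 21, 112, 71, 25, 16,
]
JTT_FREQS = [
    0.07674792325, 0.05169094831, 0.04264495736, 0.05154394846, 0.0198029802,
    0.04075195925, 0.06182993817, 0.07315192685, 0.02294397706, 0.05376094624,
    0.0919039081, 0.05867594132, 0.02382597617, 0.04012595987, 0.0509009491,
    0.06876493124, 0.05856494144, 0.01426098574, 0.0321019679, 0.066004934,
]

MTREV_RATES = [
    23.18, 26.95, 17.67, 59.93, 1.9, 9.77, 120.71, 13.9,
    96.49, 25.46, 8.36, 141.88, 6.37, 54.31, 387.86, 480.72,
    1.9, 6.48, 195.06, 13.24, 1.9, 103.33, 220.99, 1.9,
    23.03, 165.23, 1.9, 15.58, 141.4, 1.9, 4.69, 23.64,
    6.04, 2.08, 21.95, 1.9, 7.64, 794.38, 58.94, 173.56,
    63.05, 53.3, 496.13, 27.1, 15.16, 608.7, 65.41, 15.2,
    73.31, 494.39, 238.46, 10.68, 191.36, 1.9, 1.9, 55.28,
    583.55, 56.77, 113.99, 4.34, 1.9, 2.31, 1.9, 4.98,
    13.43, 69.02, 28.01, 19.86, 21.21, 1.9, 75.24, 1.9,
    30.71, 141.49, 62.73, 25.65, 1.9, 6.18, 70.8, 31.26,
    277.05, 179.97, 33.6, 254.77, 1.9, 313.56, 6.75, 582.4,
    8.34, 39.7, 465.58, 47.37, 19.11, 137.29, 54.11, 94.93,
    1.9, 38.82, 19, 28.28, 49.12, 3.31, 1.9, 313.86,
    1.9, 2.67, 12.83, 54.71, 14.82, 1.9, 13.12, 21.14,
    1.9, 5.98, 2.41, 22.73, 1.9, 1.9, 1.9, 125.93,
    11.17, 10.92, 3.21, 2.53, 12.26, 11.49, 127.67, 11.97,
    48.16, 60.97, 77.46, 44.78, 7.08, 670.14, 1.9, 329.09,
    19.57, 517.98, 84.67, 20.63, 47.7, 368.43, 1.9, 25.01,
    1222.94, 14.88, 537.53, 216.06, 40.1, 73.61, 126.4, 32.44,
    44.15, 91.67, 91.37, 6.44, 50.1, 105.79, 136.33, 24,
    51.17, 1.9, 90.82, 18.84, 111.16, 528.17, 21.71, 39.96,
    387.54, 17.31, 64.29, 33.85, 7.84, 465.58, 6.35, 169.9,
    128.22, 4.21, 16.21, 8.23, 597.21, 38.58, 64.92, 1.9,
    9.99, 38.73, 204.54, 26.25, 5.37, 1.9,
]
MTREV_FREQS = [
    0.072, 0.019, 0.039, 0.019, 0.006,
    0.025, 0.024, 0.056, 0.028, 0.088,
    0.169, 0.023, 0.054, 0.061, 0.054,
    0.072, 0.086, 0.029, 0.033, 0.043,
]

LG_RATES = [
    0.425093, 0.276818, 0.395144, 2.489084, 0.969894, 1.038545, 2.06604, 0.358858,
    0.14983, 0.395337, 0.536518, 1.124035, 0.253701, 1.177651, 4.727182, 2.139501,
    0.180717, 0.218959, 2.54787, 0.751878, 0.123954, 0.534551, 2.807908, 0.36397,
    0.390192, 2.426601, 0.126991, 0.301848, 6.326067, 0.484133, 0.052722, 0.332533,
    0.858151, 0.578987, 0.593607, 0.31444, 0.170887, 5.076149, 0.528768, 1.695752,
    0.541712, 1.437645, 4.509238, 0.191503, 0.068427, 2.145078, 0.371004, 0.089525,
    0.161787, 4.008358, 2.000679, 0.045376, 0.612025, 0.083688, 0.062556, 0.523386,
    5.24387, 0.844926, 0.927114, 0.01069, 0.015076, 0.282959, 0.025548, 0.017416,
    0.394456, 1.240275, 0.42586, 0.02989, 0.135107, 0.037967, 0.084808, 0.003499,
    0.569265, 0.640543, 0.320627, 0.594007, 0.013266, 0.89368, 1.105251, 0.075382,
    2.784478, 1.14348, 0.670128, 1.165532, 1.959291, 4.128591, 0.267959, 4.813505,
    0.072854, 0.582457, 3.234294, 1.672569, 0.035855, 0.624294, 1.223828, 1.080136,
    0.236199, 0.257336, 0.210332, 0.348847, 0.423881, 0.044265, 0.069673, 1.807177,
    0.173735, 0.018811, 0.419409, 0.611973, 0.604545, 0.077852, 0.120037, 0.245034,
    0.311484, 0.008705, 0.044261, 0.296636, 0.139538, 0.089586, 0.196961, 1.73999,
    0.129836, 0.268491, 0.054679, 0.076701, 0.108882, 0.366317, 0.697264, 0.442472,
    0.682139, 0.508851, 0.990012, 0.584262, 0.597054, 5.306834, 0.119013, 4.145067,
    0.159069, 4.273607, 1.112727, 0.078281, 0.064105, 1.033739, 0.11166, 0.232523,
    10.649107, 0.1375, 6.312358, 2.592692, 0.24906, 0.182287, 0.302936, 0.619632,
    0.299648, 1.702745, 0.656604, 0.023918, 0.390322, 0.748683, 1.136863, 0.049906,
    0.131932, 0.185202, 1.798853, 0.099849, 0.34696, 2.020366, 0.696175, 0.481306,
    1.898718, 0.094464, 0.361819, 0.165001, 2.457121, 7.803902, 0.654683, 1.338132,
    0.571468, 0.095131, 0.089613, 0.296501, 6.472279, 0.248862, 0.400547, 0.098369,
    0.140825, 0.245841, 2.188158, 3.151815, 0.18951, 0.249313,
]
LG_FREQS = [
    0.07906592093, 0.05594094406, 0.04197695802, 0.05305194695, 0.01293698706,
    0.04076695923, 0.07158592841, 0.05733694266, 0.02235497765, 0.06215693784,
    0.09908090092, 0.0645999354, 0.02295097705, 0.0423019577, 0.04403995596,
    0.0611969388, 0.05328694671, 0.01206598793, 0.03415496585, 0.06914693085,
]

WAG_RATES = [
    0.551571, 0.509848, 0.738998, 1.02704, 0.908598, 1.58285, 1.41672, 0.316954,
    0.193335, 0.397915, 0.906265, 0.893496, 0.210494, 1.43855, 3.37079, 2.12111,
    0.113133, 0.240735, 2.00601, 0.635346, 0.147304, 0.528191, 3.0355, 0.439157,
    0.584665, 2.13715, 0.186979, 0.497671, 5.35142, 0.683162, 0.102711, 0.679489,
    1.22419, 0.554413, 1.16392, 0.381533, 0.251849, 5.42942, 0.265256, 1.54364,
    0.947198, 1.12556, 3.95629, 0.554236, 0.131528, 3.01201, 0.198221, 0.0961621,
    0.195081, 3.97423, 2.03006, 0.0719167, 1.086, 0.196246, 0.0302949, 0.616783,
    6.17416, 0.865584, 0.930676, 0.039437, 0.0848047, 0.479855, 0.103754, 0.0467304,
    0.423984, 1.07176, 0.374866, 0.129767, 0.325711, 0.152335, 0.0988179, 0.021352,
    0.306674, 0.248972, 0.170135, 0.384287, 0.0740339, 0.390482, 0.39802, 0.109404,
    1.40766, 0.512984, 0.71707, 0.543833, 1.00214, 5.46947, 0.330052, 4.29411,
    0.113917, 0.869489, 3.8949, 1.54526, 0.0999208, 0.933372, 1.02887, 0.857928,
    0.215737, 0.22771, 0.301281, 0.567717, 0.570025, 0.127395, 0.154263, 2.58443,
    0.315124, 0.0811339, 0.682355, 0.704939, 0.822765, 0.156557, 0.196303, 0.588731,
    0.24941, 0.0304501, 0.0613037, 0.373558, 0.1741, 0.049931, 0.24357, 1.34182,
    0.225833, 0.336983, 0.103604, 0.187247, 0.13819, 0.499462, 0.890432, 0.404141,
    0.679371, 0.696198, 0.740169, 0.473307, 0.262569, 3.87344, 0.118358, 3.17097,
    0.323832, 4.25746, 1.05947, 0.0999288, 0.31944, 1.45816, 0.212483, 0.42017,
    7.8213, 0.257555, 4.85402, 2.11517, 0.415844, 0.344739, 0.326622, 0.665309,
    0.398618, 1.80034, 0.934276, 0.088836, 0.556896, 0.96713, 1.38698, 0.137505,
    0.133264, 0.305434, 1.19063, 0.171329, 0.493905, 1.51612, 0.515706, 0.428437,
    2.05845, 0.161444, 0.545931, 0.171903, 1.52964, 6.45428, 0.649892, 1.61328,
    0.795384, 0.139405, 0.216046, 0.314887, 4.37802, 0.523742, 0.786993, 0.232739,
    0.110864, 0.291148, 1.38823, 2.48539, 0.365369, 0.31473,
]
WAG_FREQS = [
    0.08662790866, 0.0439720044, 0.03908940391, 0.0570451057, 0.01930780193,
    0.03672810367, 0.05805890581, 0.08325180833, 0.02443130244, 0.04846600485,
    0.08620900862, 0.0620286062, 0.01950270195, 0.03843190384, 0.04576310458,
    0.06951790695, 0.0610127061, 0.01438590144, 0.03527420353, 0.07089560709,
]

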