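{
"FP1": 0,
"FPZ": 0,
"FP2": 0,
"AF3": 0,
"AF4": 0,
"F7": 1,
"F5": 1,
"F3": 1,
"F1": 1,
"FZ": 2,
"F2": 3,
"F4": 3,
"F6": 3,
"F8": 3,
"FT7": 4,
"FC5": 4,
"FC3": 4,
"FC1": 4,
"FCZ": 5,
"FC2": 6,
"FC4": 6,
"FC6": 6,
"FT8": 6,
"T7": 7,
"C5": 7,
"C3": 7,
"C1": 7,
"CZ": 8,
"C2": 9,
"C4": 9,
"C6": 9,
"T8": 9,
"TP7": 10,
"CP5": 10,
"CP3": 10,
"CP1": 10,
"CPZ": 11,
"CP2": 12,
"CP4": 12,
"CP6": 12,
"TP8": 12,
"P7": 13,
"P5": 13,
"P3": 13,
"P1": 13,
"PZ": 14,
"P2": 15,
"P4": 15,
"P6": 15,
"P8": 15,
"PO7": 16,
"PO5": 16,
"PO3": 16,
"POZ": 16,
"PO4": 16,
"PO6": 16,
"PO8": 16,
"CB1": 16,
"O1": 16,
"OZ": 16,
"O2": 16,
"CB2": 16
}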