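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
"FZ": 1,
"F2": 2,
"F4": 2,
"F6": 2,
"F8": 2,
"FT7": 3,
"FC5": 5,
"FC3": 5,
"FC1": 5,
"FCZ": 5,
"FC2": 5,
"FC4": 5,
"FC6": 5,
"FT8": 4,
"T7": 3,
"C5": 5,
"C3": 5,
"C1": 5,
"CZ": 5,
"C2": 5,
"C4": 5,
"C6": 5,
"T8": 4,
"TP7": 3,
"CP5": 6,
"CP3": 6,
"CP1": 6,
"CPZ": 6,
"CP2": 6,
"CP4": 6,
"CP6": 6,
"TP8": 4,
"P7": 7,
"P5": 7,
"P3": 7,
"P1": 7,
"PZ": 7,
"P2": 8,
"P4": 8,
"P6": 8,
"P8": 8,
"PO7": 9,
"PO5": 9,
"PO3": 9,
"POZ": 9,
"PO4": 9,
"PO6": 9,
"PO8": 9,
"CB1": 9,
"O1": 9,
"OZ": 9,
"O2": 9,
"CB2": 9
}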