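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
"F2": 1,
"F4": 1,
"F6": 1,
"F8": 1,
"FT7": 2,
"FC5": 2,
"FC3": 2,
"FC1": 2,
"FCZ": 2,
"FC2": 2,
"FC4": 2,
"FC6": 2,
"FT8": 2,
"T7": 3,
"C5": 3,
"C3": 3,
"C1": 3,
"CZ": 3,
"C2": 3,
"C4": 3,
"C6": 3,
"T8": 3,
"TP7": 4,
"CP5": 4,
"CP3": 4,
"CP1": 4,
"CPZ": 4,
"CP2": 4,
"CP4": 4,
"CP6": 4,
"TP8": 4,
"P7": 5,
"P5": 5,
"P3": 5,
"P1": 5,
"PZ": 5,
"P2": 5,
"P4": 5,
"P6": 5,
"P8": 5,
"PO7": 6,
"PO5": 6,
"PO3": 6,
"POZ": 6,
"PO4": 6,
"PO6": 6,
"PO8": 6,
"CB1": 6,
"O1": 6,
"OZ": 6,
"O2": 6,
"CB2": 6
}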