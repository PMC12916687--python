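{
"FP1": 0,
"FPZ": 0,
"FP2": 0,
"F7": 1,
"F3": 1,
"FZ": 1,
"F4": 1,
"F8": 1,
"FC5": 2,
"FC1": 2,
"FC2": 2,
"FC6": 2,
"T7": 3,
"C3": 3,
"CZ": 3,
"C4": 3,
"T8": 3,
"CP5": 4,
"CP1": 4,
"CP2": 4,
"CP6": 4,
"P7": 5,
"P3": 5,
"PZ": 5,
"P4": 5,
"P8": 5,
"PO5": 6,
"PO3": 6,
"POZ": 6,
"PO4": 6,
"PO6": 6,
"OZ": 6
}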