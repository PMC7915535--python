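{
  "grid_rows": 10,
  "grid_cols": 9,
  "placement": {
    "F3": [0, 2], "F1": [0, 3], "Fz": [0, 4], "F2": [0, 5], "F4": [0, 6],
    "FFC5": [1, 1], "FFC3": [1, 2], "FFC1": [1, 3], "FFC2": [1, 5], "FFC4": [1, 6], "FFC6": [1, 7],
    "FC5": [2, 1], "FC3": [2, 2], "FC1": [2, 3], "FCz": [2, 4], "FC2": [2, 5], "FC4": [2, 6], "FC6": [2, 7],
    "FTT7": [3, 0], "FCC5": [3, 1], "FCC3": [3, 2], "FCC1": [3, 3], "FCC2": [3, 5], "FCC4": [3, 6], "FCC6": [3, 7], "FTT8": [3, 8],
    "C5": [4, 1], "C3": [4, 2], "C1": [4, 3], "Cz": [4, 4], "C2": [4, 5], "C4": [4, 6], "C6": [4, 7],
    "TTP7": [5, 0], "CCP5": [5, 1], "CCP3": [5, 2], "CCP1": [5, 3], "CCP2": [5, 5], "CCP4": [5, 6], "CCP6": [5, 7], "TTP8": [5, 8],
    "CP5": [6, 1], "CP3": [6, 2], "CP1": [6, 3], "CPz": [6, 4], "CP2": [6, 5], "CP4": [6, 6], "CP6": [6, 7],
    "CPP5": [7, 1], "CPP3": [7, 2], "CPP1": [7, 3], "CPP2": [7, 5], "CPP4": [7, 6], "CPP6": [7, 7],
    "P3": [8, 2], "P1": [8, 3], "Pz": [8, 4], "P2": [8, 5], "P4": [8, 6],
    "PPO1": [9, 3], "PPO2": [9, 5]
  }
}
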