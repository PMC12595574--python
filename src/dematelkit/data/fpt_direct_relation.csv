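,F1,F2,F3,F4,F5,F6,F7,F8,F9,F10,F11,F12,F13,F14,F15
F1,0.00,2.26,2.37,2.32,2.42,2.11,1.79,1.89,2.11,1.84,2.11,1.89,1.95,2.16,1.89
F2,2.53,0.00,2.68,2.63,2.42,1.84,1.74,1.74,1.74,1.84,1.58,1.53,1.58,1.84,1.47
F3,2.42,2.21,0.00,2.53,2.68,2.05,2.05,2.26,2.05,1.89,1.95,1.63,1.79,1.89,1.74
F4,2.53,2.21,2.68,0.00,2.79,2.26,2.00,1.95,2.00,1.89,1.63,1.58,1.47,1.95,1.68
F5,2.16,2.11,2.32,2.53,0.00,2.84,2.63,2.47,2.26,2.11,1.89,1.68,1.89,1.89,1.89
F6,2.84,2.53,2.68,2.84,2.74,0.00,2.74,2.42,2.26,2.26,1.89,2.05,2.11,2.05,2.05
F7,2.84,2.32,2.74,2.68,2.42,2.42,0.00,2.32,2.37,2.26,1.95,1.95,1.95,1.95,1.95
F8,2.11,1.89,1.95,1.95,2.89,2.58,2.58,0.00,2.47,2.37,2.26,1.95,1.95,1.89,2.11
F9,2.16,2.05,2.32,2.00,2.42,2.32,2.68,2.79,0.00,2.37,2.32,2.05,1.89,1.79,2.16
F10,2.21,2.05,2.21,2.42,2.47,2.37,2.68,2.63,2.74,0.00,2.68,2.63,2.68,2.37,2.63
F11,2.42,2.00,2.21,2.16,2.53,2.42,2.53,2.84,2.58,2.47,0.00,2.63,2.53,2.32,2.42
F12,2.16,2.11,2.05,2.16,1.84,2.05,2.37,2.11,2.32,2.37,2.37,0.00,2.58,2.21,2.58
F13,2.42,2.05,2.32,2.42,2.32,2.32,2.63,2.32,2.32,2.26,2.37,2.26,0.00,2.05,2.32
F14,2.47,2.26,2.32,2.53,2.53,2.21,1.95,1.68,1.84,2.21,2.21,2.05,2.21,0.00,2.11
F15,1.95,1.68,2.00,2.26,2.11,2.21,2.47,2.26,2.63,2.79,2.37,2.37,2.26,2.05,0.00
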