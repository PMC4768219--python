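>kb_canonical kb_canonical
A [ 0.010 0.010 0.010 0.485 0.250 0.250 0.015 0.015 0.010 0.010 ]
C [ 0.010 0.010 0.010 0.015 0.250 0.250 0.485 0.485 0.970 0.970 ]
G [ 0.970 0.970 0.970 0.485 0.250 0.250 0.015 0.015 0.010 0.010 ]
T [ 0.010 0.010 0.010 0.015 0.250 0.250 0.485 0.485 0.010 0.010 ]
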