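# Michael-acceptor warhead patterns, one per line: pattern_id <TAB> SMARTS
# SMARTS atom order: beta carbon (thiol attack site), alpha carbon, EWG anchor atom.
# Patterns are tried in file order; the first match at a given beta carbon wins.
acrylamide	[CH2]=[CH1][CX3](=O)[NX3]
acrylate_ester	[CH2]=[CH1][CX3](=O)[OX2][#6]
enone	[CH2]=[CH1][CX3](=O)[#6]
vinyl_sulfone	[CH2]=[CH1][SX4](=O)(=O)[#6]
vinyl_sulfonate	[CH2]=[CH1][SX4](=O)(=O)[OX2][#6]
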