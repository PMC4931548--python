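# Strained-ring and non-endogenous bonding patterns (illustrative starter set).
C1=CC1            # cyclopropene
O1C=C1            # oxirene
C1=CC=C1          # cyclobutadiene
C=C=C             # cumulated diene
[OX2][OX2]        # peroxide linkage
[NX3][NX3][NX3]   # triamine chain
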