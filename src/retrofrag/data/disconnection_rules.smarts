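# Retrosynthetic disconnection rules.
# One rule per line: <name> <SMARTS>; the bond between the atoms tagged :1
# and :2 is the candidate disconnection. Acyclic bonds only (!@) — ring
# disconnections are not single-step fragment couplings.
acyclic_C_N_single   [#6:1]-!@[#7:2]
acyclic_C_O_single   [#6:1]-!@[#8:2]
acyclic_C_S_single   [#6:1]-!@[#16:2]
amide                [C:1](=O)-!@[#7:2]
ester                [C:1](=O)-!@[O:2][#6]
ether                [#6:1]-!@[O:2]-!@[#6]
sulfonamide          [S:1](=O)(=O)-!@[#7:2]
acyclic_C_C_double   [#6:1]=!@[#6:2]
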