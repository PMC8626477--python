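"""Per-column conservation of a reference residue in a large alignment.

Simulates a 2460-sequence alignment in which one column (an arginine)
is conserved with probability 0.76 and the rest are invariant, then maps
the reference position to its alignment column and reports frequencies.
"""

from corescaffold import conservation_table, simulate_alignment

reference = "MARKS"
profile = [1.0, 1.0, 0.76, 1.0, 1.0]  # position 3 is the variable Arg
msa = simulate_alignment(reference, 2460, profile, seed=5)

table = conservation_table(msa, positions=[2, 3, 4])
print(table.to_string(index=False))
# the planted 76%-conserved arginine is recovered within binomial noise;
# fully conserved positions report 100%.
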