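"""Candidate tryptic cleavage sites of an arbitrary protein sequence.

Trypsin cleaves after Lys or Arg unless the next residue is Pro; the
annotation returns the 1-based P1 positions of candidate bonds.
"""

from pepdemask import annotate_cleavage_sites

fragment = "LIVTQTMKGLDIQKVAGTWYSLAMAASDISLLDAQSAPLR"  # beta-LG 1-40
sites = annotate_cleavage_sites(fragment)
print("sequence:", fragment)
print("candidate P1 positions:", sites)
for p in sites:
    print(f"  bond {p}: {fragment[p - 1]}-{fragment[p]}")
print("Positions 8 and 14 match the first two sites of the packaged")
print("beta-LG map; Lys/Arg followed by Pro would have been skipped.")
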