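"""Combinatorial codebooks: pairing N dyes yields (N²−N)/2 codewords.

Builds the 10-plex codebook (5 dyes → 10 pair codewords) and prints each
target's expected spectral channels and 4D phasor signature — the centroid
the classifier expects for equal-photon dye pairs.
"""

from phasorplex import build_codebook, expected_signature, n_pairs
from phasorplex.simulate import default_panel

for n in (3, 5, 12):
    print(f"{n} fluorophores -> {n_pairs(n)} pair codewords")

panel = default_panel(5)
codebook = build_codebook(panel, [f"gene{i}" for i in range(10)])
print("\ntarget  dyes                 channels  lifetime centroid (g, s)")
for target, cw in codebook.codewords.items():
    chans, sig = expected_signature(cw, codebook, rep_frequency=78e6)
    print(
        f"{target:7s} {'+'.join(cw):20s} {sorted(chans)!s:9s} "
        f"({sig[2]:.3f}, {sig[3]:.3f})"
    )
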