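"""Extract an end-motif profile from fragments on a reference genome.

Builds a small synthetic reference with fragments whose 5'-end 4-mers
follow a known distribution, extracts the 256-motif profile, and shows
how closely the extracted frequencies match the generating ones.
"""

import tempfile

import numpy as np
import pyfaidx

from emdeepsd import MOTIFS, build_profile, load_fragments, simulate_fragments

rng = np.random.RandomState(0)
target = rng.dirichlet(np.full(256, 1.0))  # generating motif distribution

with tempfile.TemporaryDirectory() as tmp:
    fasta, bed = simulate_fragments(target, n_fragments=20_000, seed=1,
                                    out_dir=tmp)
    fragments = load_fragments(bed, max_insert=600)
    profile = build_profile(fragments, pyfaidx.Fasta(str(fasta)), "demo")

tv = 0.5 * np.abs(profile.frequencies - target).sum()
print(f"fragments used: {len(fragments)}")
print(f"total motif counts (2 per fragment): {profile.counts.sum()}")
print(f"most frequent extracted motif: "
      f"{MOTIFS[int(np.argmax(profile.frequencies))]}")
print(f"total-variation distance to generating distribution: {tv:.4f}")
print("A small TV distance means the extractor recovers the motif "
      "distribution the fragments were planted with.")
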