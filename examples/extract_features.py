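"""Compute the 39-descriptor feature vector for a few proteins.

Builds a tiny synthetic family, takes its seed as the consensus region and
prints selected descriptors for one member and one unrelated decoy.
"""

import numpy as np

from protclass import FEATURE_NAMES, FamilySpec, extract_features, generate_decoys, generate_family
from protclass.synthetic import random_protein

seed_seq = random_protein(np.random.default_rng(1), 120)
member = generate_family(FamilySpec(seed_seq, 1, 0.1, rng_seed=2))[0]
decoy = generate_decoys(1, (120, 120), rng_seed=3)[0]

for rec in (member, decoy):
    fv = extract_features(rec, consensus=seed_seq)
    print(f"\n{rec.id}  (length {fv.length})")
    print(f"  selfalign vs consensus : {fv.selfalign_consensus:.3f}")
    print(f"  global identity        : {fv.global_identity:.3f}")
    print(f"  pI / charge at pH 7.2  : {fv.pI:.2f} / {fv.charge:+.2f}")
    print(f"  nominal mass (Da)      : {fv.nominal_mass}")
    print(f"  GRAVY / instability    : {fv.gravy:+.3f} / {fv.instability:.1f}")
    print(f"  entropy / energy       : {fv.entropy:.3f} bits / {fv.energy:.4f}")

print(
    "\nThe family member aligns closely to the consensus (selfalign near 1)\n"
    "while the random decoy does not; the remaining descriptors are\n"
    "composition and physicochemical summaries used by the classifier.\n"
    f"Full vector: {len(FEATURE_NAMES)} named values."
)
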