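"""Derive a conserved-domain pattern from a family alignment and match it.

A synthetic family carries an invariant 24-residue core (think active-site
conservation).  The refined pattern recovers that core as a short motif;
family members match it, random decoys essentially never do.
"""

import numpy as np

from protclass import (
    FamilySpec,
    consensus_from_msa,
    derive_pattern,
    generate_decoys,
    generate_family,
    match_pattern,
    pattern_random_probability,
)
from protclass.synthetic import random_protein, star_align

seed_seq = random_protein(np.random.default_rng(4), 120)
spec = FamilySpec(seed_seq, 20, 0.10, rng_seed=5, conserved_region=(40, 64))
family = generate_family(spec)
msa = star_align(seed_seq, family)

profile = consensus_from_msa(msa)
pattern = derive_pattern(msa, min_conservation=0.95, refine=True)
print("consensus length :", len(profile.consensus))
print("pattern          :", pattern.to_text())
print(f"random-match prob: {pattern_random_probability(pattern):.3e}")

members_hit = sum(bool(match_pattern(pattern, m.sequence)) for m in family)
decoys = generate_decoys(200, (100, 140), rng_seed=6)
decoys_hit = sum(bool(match_pattern(pattern, d.sequence)) for d in decoys)
print(f"family members matching: {members_hit}/{len(family)}")
print(f"decoys matching        : {decoys_hit}/{len(decoys)}")
print(
    "\nThe motif covers the conserved core, so it separates the family from\n"
    "background sequence with a random-occurrence probability far below one\n"
    "expected hit per proteome."
)
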