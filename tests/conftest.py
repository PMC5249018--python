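import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from protclass.motif import consensus_from_msa, derive_pattern
from protclass.synthetic import FamilySpec, make_benchmark, random_protein

AA3 = "ACD"  # small alphabet for exhaustive/randomized cross-checks


def family_spec(i: int, n_members: int = 50, mutation_rate: float = 0.10,
                length: int = 120) -> FamilySpec:
    """Deterministic family recipe: random seed sequence with a conserved
    24-residue core (positions 40-64) mutated nowhere."""
    seed_seq = random_protein(np.random.default_rng(101 + i), length)
    return FamilySpec(seed_seq, n_members, mutation_rate, rng_seed=211 + i,
                      conserved_region=(40, 64), name=f"fam{i + 1}")


@pytest.fixture(scope="session")
def nif_benchmark():
    """Six families of 50 members (10% divergence) plus 300 decoys —
    the multiclass recovery setting."""
    return make_benchmark([family_spec(i) for i in range(6)], 300,
                          rng_seed=999, decoy_length_range=(100, 140))


@pytest.fixture(scope="session")
def binary_pool():
    """One family plus distant relatives (50% divergence, no conserved core)
    and random decoys: the binary discovery setting.

    Returns (records, truth, consensus, refined pattern).
    """
    spec = family_spec(0)
    bench = make_benchmark([spec], 80, rng_seed=555)
    relatives = FamilySpec(spec.seed_sequence, 40, 0.5, rng_seed=777,
                           name="relative")
    from protclass.synthetic import generate_family

    records = list(bench.records) + generate_family(relatives)
    truth = dict(bench.truth)
    truth.update({r.id: 0 for r in records if r.id.startswith("relative")})
    consensus = consensus_from_msa(bench.msas[0]).consensus
    pattern = derive_pattern(bench.msas[0], 0.95, refine=True)
    return records, truth, consensus, pattern
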