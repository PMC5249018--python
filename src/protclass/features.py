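"""The 39 sequence descriptors: composition, consensus-alignment scores and
physicochemical properties.

Three categories make up the fixed-order feature vector:

1. composition — the 20 residue fractions (alphabetical), 5 functional-group
   fractions and the sequence length;
2. consensus alignment — the self-normalized global alignment similarity to
   the family consensus plus global/local identity and positive fractions;
3. physicochemical — isoelectric point, net charge at pH 7.2, nominal mass,
   aromaticity, instability index, GRAVY, and the co-occurrence entropy and
   energy texture statistics.

Aromaticity, GRAVY and the instability index follow the standard Lobry,
Kyte–Doolittle and Guruprasad definitions (delegated to Biopython's
ProtParam).  pI and charge use a Henderson–Hasselbalch model over the
ionizable groups with a pinned, configurable pK table.  Nominal mass is the
integer residue-mass sum plus 18 for one water.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .align import DEFAULT_SCORING, ScoringConfig, global_align, local_align, selfalign
from .io import CANONICAL_AA, ProteinRecord

logger = logging.getLogger(__name__)

# Five functional groups (may overlap: Y is both polar and aromatic; each
# group contributes its own fraction).
FUNCTIONAL_GROUPS: dict[str, frozenset[str]] = {
    "positive": frozenset("KRH"),
    "negative": frozenset("DE"),
    "polar": frozenset("STNQCY"),
    "nonpolar": frozenset("GAVLIPM"),
    "aromatic": frozenset("FWY"),
}
GROUP_ORDER = ("positive", "negative", "polar", "nonpolar", "aromatic")

# EMBOSS-style pK set; configurable via the pk_table arguments below.
DEFAULT_PK: dict[str, float] = {
    "Nterm": 8.6, "Cterm": 3.6,
    "K": 10.8, "R": 12.5, "H": 6.5,
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
}
_POSITIVE_GROUPS = ("Nterm", "K", "R", "H")
_NEGATIVE_GROUPS = ("Cterm", "D", "E", "C", "Y")

# Integer nominal residue masses; free peptide = sum + 18 (one water).
NOMINAL_RESIDUE_MASS: dict[str, int] = {
    "G": 57, "A": 71, "S": 87, "P": 97, "V": 99, "T": 101, "C": 103,
    "L": 113, "I": 113, "N": 114, "D": 115, "Q": 128, "K": 128, "E": 129,
    "M": 131, "H": 137, "F": 147, "R": 156, "Y": 163, "W": 186,
}

WATER_NOMINAL_MASS = 18

#: Instability indices above this flag a protein as unstable (short half-life).
INSTABILITY_THRESHOLD = 40.0

#: Default pH for the net-charge feature (typical intracellular pH).
DEFAULT_PH = 7.2

COOC_WINDOW = 9  # 3x3 co-occurrence grid consumes 9 consecutive residues


def _require_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty sequence")


def aa_composition(sequence: str) -> tuple[np.ndarray, np.ndarray, int]:
    """(20 residue fractions, 5 functional-group fractions, length)."""
    _require_sequence(sequence)
    counts = Counter(sequence)
    n = len(sequence)
    comp = np.array([counts.get(aa, 0) / n for aa in CANONICAL_AA])
    groups = np.array([
        sum(counts.get(aa, 0) for aa in FUNCTIONAL_GROUPS[g]) / n
        for g in GROUP_ORDER
    ])
    return comp, groups, n


def aromaticity(sequence: str) -> float:
    """Relative frequency of Phe + Trp + Tyr."""
    _require_sequence(sequence)
    return ProteinAnalysis(sequence).aromaticity()


def gravy(sequence: str) -> float:
    """Grand average of Kyte–Doolittle hydropathy (positive = hydrophobic)."""
    _require_sequence(sequence)
    return ProteinAnalysis(sequence).gravy()


def instability_index(sequence: str) -> float:
    """Guruprasad dipeptide-weight instability index; > 40 = unstable."""
    if len(sequence) < 2:
        raise ValueError("instability index needs at least 2 residues")
    return ProteinAnalysis(sequence).instability_index()


def is_unstable(sequence: str) -> bool:
    return instability_index(sequence) > INSTABILITY_THRESHOLD


def net_charge(
    sequence: str,
    pH: float = DEFAULT_PH,
    pk_table: Mapping[str, float] = DEFAULT_PK,
) -> float:
    """Henderson–Hasselbalch net charge at the given pH.

    Positive groups (N-terminus, K, R, H) each contribute
    ``1/(1+10^(pH-pK))``; negative groups (C-terminus, D, E, C, Y) each
    contribute ``-1/(1+10^(pK-pH))``.  Strictly decreasing in pH.
    """
    _require_sequence(sequence)
    counts = Counter(sequence)
    charge = 0.0
    for group in _POSITIVE_GROUPS:
        n = 1 if group == "Nterm" else counts.get(group, 0)
        if n:
            charge += n / (1.0 + 10.0 ** (pH - pk_table[group]))
    for group in _NEGATIVE_GROUPS:
        n = 1 if group == "Cterm" else counts.get(group, 0)
        if n:
            charge -= n / (1.0 + 10.0 ** (pk_table[group] - pH))
    return charge


def isoelectric_point(
    sequence: str,
    pk_table: Mapping[str, float] = DEFAULT_PK,
    tol: float = 1e-4,
) -> float:
    """pH where the net charge crosses zero, by bisection on [0, 14].

    The charge is strictly decreasing in pH, positive at pH 0 and negative at
    pH 14 for any sequence under the default table, so the crossing is unique.
    """
    _require_sequence(sequence)
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, pk_table) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def nominal_mass(sequence: str) -> int:
    """Integer nominal mass of the free peptide (residue sum + water)."""
    _require_sequence(sequence)
    return sum(NOMINAL_RESIDUE_MASS[aa] for aa in sequence) + WATER_NOMINAL_MASS


def cooccurrence_entropy_energy(sequence: str) -> tuple[float, float]:
    """Texture statistics of the residue-pair co-occurrence distribution.

    A window of 9 consecutive residues slides along the sequence (step 1).
    Each window is reversed (read right-to-left) and filled row-major into a
    3×3 grid; every horizontally adjacent grid pair increments a 20×20
    ordered-pair count.  Counts are normalized to probabilities p, then

        energy  = Σ p²          (uniformity; 1 for a degenerate distribution)
        entropy = −Σ p log₂ p   (disorder, bits; 0 for a degenerate one)

    Sequences shorter than 9 residues yield (0, 0) with a logged warning so
    genome-wide scans never abort.
    """
    _require_sequence(sequence)
    if len(sequence) < COOC_WINDOW:
        logger.warning(
            "sequence of length %d < %d: co-occurrence entropy/energy set to 0",
            len(sequence), COOC_WINDOW,
        )
        return 0.0, 0.0
    counts: Counter[tuple[str, str]] = Counter()
    for start in range(len(sequence) - COOC_WINDOW + 1):
        grid = sequence[start:start + COOC_WINDOW][::-1]
        for row in range(3):
            for col in range(2):
                i = 3 * row + col
                counts[(grid[i], grid[i + 1])] += 1
    total = sum(counts.values())
    entropy = 0.0
    energy = 0.0
    for c in counts.values():
        p = c / total
        energy += p * p
        entropy -= p * math.log2(p)
    return entropy, energy


# ---------------------------------------------------------------------------
# Feature vector assembly

FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"frac_{aa}" for aa in CANONICAL_AA)
    + tuple(f"grp_{g}" for g in GROUP_ORDER)
    + (
        "length",
        "selfalign_consensus",
        "global_identity",
        "global_positive",
        "local_identity",
        "local_positive",
        "pI",
        "charge",
        "nominal_mass",
        "aromaticity",
        "instability",
        "gravy",
        "entropy",
        "energy",
    )
)
N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 39


@dataclass(frozen=True)
class FeatureVector:
    """The 39 descriptors of one protein, in the documented fixed order."""

    aa_comp: np.ndarray            # 20 fractions, alphabetical residue order
    group_counts: np.ndarray       # 5 functional-group fractions
    length: int
    selfalign_consensus: float
    global_identity: float
    global_positive: float
    local_identity: float
    local_positive: float
    pI: float
    charge: float
    nominal_mass: int
    aromaticity: float
    instability: float
    gravy: float
    entropy: float
    energy: float

    def to_array(self) -> np.ndarray:
        return np.concatenate([
            self.aa_comp,
            self.group_counts,
            np.array([
                self.length,
                self.selfalign_consensus,
                self.global_identity,
                self.global_positive,
                self.local_identity,
                self.local_positive,
                self.pI,
                self.charge,
                self.nominal_mass,
                self.aromaticity,
                self.instability,
                self.gravy,
                self.entropy,
                self.energy,
            ]),
        ])


def extract_features(
    record: ProteinRecord,
    consensus: str,
    scoring: ScoringConfig = DEFAULT_SCORING,
    pH: float = DEFAULT_PH,
) -> FeatureVector:
    """Compute the full 39-feature vector for one sanitized record.

    Alignment-derived features are taken against ``consensus`` (the family
    consensus region).
    """
    if not consensus:
        raise ValueError("consensus must be non-empty")
    seq = record.sequence
    comp, groups, length = aa_composition(seq)
    g = global_align(seq, consensus, scoring)
    l = local_align(seq, consensus, scoring)
    entropy, energy = cooccurrence_entropy_energy(seq)
    return FeatureVector(
        aa_comp=comp,
        group_counts=groups,
        length=length,
        selfalign_consensus=selfalign(seq, consensus, scoring),
        global_identity=g.identity,
        global_positive=g.positive,
        local_identity=l.identity,
        local_positive=l.positive,
        pI=isoelectric_point(seq),
        charge=net_charge(seq, pH),
        nominal_mass=nominal_mass(seq),
        aromaticity=aromaticity(seq),
        instability=instability_index(seq) if length >= 2 else 0.0,
        gravy=gravy(seq),
        entropy=entropy,
        energy=energy,
    )


def feature_matrix(
    records: Sequence[ProteinRecord],
    consensus: str,
    scoring: ScoringConfig = DEFAULT_SCORING,
    pH: float = DEFAULT_PH,
) -> pd.DataFrame:
    """Feature table: one row per record (indexed by id), 39 named columns."""
    rows = [extract_features(r, consensus, scoring, pH).to_array() for r in records]
    return pd.DataFrame(rows, index=[r.id for r in records], columns=list(FEATURE_NAMES))
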