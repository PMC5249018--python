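"""Synthetic protein families and decoys for end-to-end testing.

Families are grown from a seed sequence by i.i.d. per-residue substitution
(uniform over the 19 alternatives) and optional indels.  An optional
*conserved region* of the seed is exempt from mutation, emulating the
active-site-style conservation that makes short conserved domains
discoverable in real families; outside it divergence is uniform.  Decoys are
i.i.d. residue strings with a configurable composition.

All randomness flows from explicit integer seeds; no global RNG state is
touched, so every generated benchmark is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .align import DEFAULT_SCORING, ScoringConfig, global_align
from .io import CANONICAL_AA, GAP, Msa, ProteinRecord, write_fasta, write_msa

_AA = np.array(list(CANONICAL_AA))


@dataclass(frozen=True)
class FamilySpec:
    """Recipe for one synthetic protein family.

    ``conserved_region`` is an optional half-open (start, end) slice of the
    seed within which substitutions and indels are suppressed.
    """

    seed_sequence: str
    n_members: int
    mutation_rate: float
    indel_rate: float = 0.0
    rng_seed: int = 0
    conserved_region: tuple[int, int] | None = None
    name: str = "fam"

    def __post_init__(self) -> None:
        if len(self.seed_sequence) < 10:
            raise ValueError("seed_sequence must have at least 10 residues")
        if not (0 <= self.mutation_rate < 1 and 0 <= self.indel_rate < 1):
            raise ValueError("rates must lie in [0, 1)")
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if self.conserved_region is not None:
            s, e = self.conserved_region
            if not (0 <= s < e <= len(self.seed_sequence)):
                raise ValueError("conserved_region out of bounds")


def random_protein(rng: np.random.Generator, length: int,
                   composition: Sequence[float] | None = None) -> str:
    p = None
    if composition is not None:
        p = np.asarray(composition, dtype=float)
        if p.shape != (20,) or p.sum() <= 0 or (p < 0).any():
            raise ValueError("composition must be 20 non-negative fractions")
        p = p / p.sum()
    return "".join(rng.choice(_AA, size=length, p=p))


def _mutate(rng: np.random.Generator, spec: FamilySpec) -> str:
    seed = spec.seed_sequence
    cons = spec.conserved_region
    out: list[str] = []
    for i, aa in enumerate(seed):
        protected = cons is not None and cons[0] <= i < cons[1]
        if not protected and spec.indel_rate and rng.random() < spec.indel_rate / 2:
            continue  # deletion
        if not protected and rng.random() < spec.mutation_rate:
            alternatives = [c for c in CANONICAL_AA if c != aa]
            out.append(alternatives[rng.integers(19)])
        else:
            out.append(aa)
        if not protected and spec.indel_rate and rng.random() < spec.indel_rate / 2:
            out.append(_AA[rng.integers(20)])  # insertion after position i
    return "".join(out)


def generate_family(spec: FamilySpec) -> list[ProteinRecord]:
    """Generate ``spec.n_members`` mutated copies of the seed (deterministic
    for a given ``spec.rng_seed``)."""
    rng = np.random.default_rng(spec.rng_seed)
    records = []
    for i in range(spec.n_members):
        records.append(ProteinRecord(
            id=f"{spec.name}_m{i:04d}",
            sequence=_mutate(rng, spec),
            description=f"synthetic family member (mutation_rate={spec.mutation_rate})",
        ))
    return records


def generate_decoys(
    n: int,
    length_range: tuple[int, int],
    composition: Sequence[float] | None = None,
    rng_seed: int = 0,
    name: str = "decoy",
) -> list[ProteinRecord]:
    """i.i.d. random proteins; lengths uniform over the inclusive range."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = length_range
    if lo > hi or lo < 1:
        raise ValueError("invalid length_range")
    rng = np.random.default_rng(rng_seed)
    return [
        ProteinRecord(
            id=f"{name}_{i:04d}",
            sequence=random_protein(rng, int(rng.integers(lo, hi + 1)), composition),
            description="synthetic decoy",
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Star alignment of family members against the seed (gapped via the align
# module) — enough to build a family MSA without a full progressive aligner.


def star_align(seed: str, sequences: Sequence[ProteinRecord],
               scoring: ScoringConfig = DEFAULT_SCORING) -> Msa:
    """Align every sequence to the seed and merge on seed coordinates
    ("once a gap, always a gap"); insertions relative to the seed are padded
    with gaps across the other rows."""
    L = len(seed)
    # per record: residue (or gap) at each seed position, plus insertions
    # keyed by the seed position they precede (L = after the last).
    aligned_rows: list[tuple[list[str], dict[int, str]]] = []
    for rec in sequences:
        aln = global_align(rec.sequence, seed, scoring)
        at_pos = [GAP] * L
        inserts: dict[int, str] = {}
        seed_i = 0
        for mem_c, seed_c in zip(aln.aligned_a, aln.aligned_b):
            if seed_c == GAP:
                inserts[seed_i] = inserts.get(seed_i, "") + mem_c
            else:
                at_pos[seed_i] = mem_c
                seed_i += 1
        aligned_rows.append((at_pos, inserts))
    max_insert = [0] * (L + 1)
    for _, inserts in aligned_rows:
        for j, ins in inserts.items():
            max_insert[j] = max(max_insert[j], len(ins))
    out_records = []
    for rec, (at_pos, inserts) in zip(sequences, aligned_rows):
        parts: list[str] = []
        for j in range(L + 1):
            if max_insert[j]:
                ins = inserts.get(j, "")
                parts.append(ins.ljust(max_insert[j], GAP))
            if j < L:
                parts.append(at_pos[j])
        out_records.append(ProteinRecord(rec.id, "".join(parts), rec.description))
    return Msa(tuple(out_records))


@dataclass(frozen=True)
class Benchmark:
    """A labeled candidate pool plus per-family MSAs for motif derivation."""

    records: tuple[ProteinRecord, ...]
    truth: dict[str, int]                  # record id -> 0 (decoy) or 1..k
    label_semantics: dict[int, str]
    msas: tuple[Msa, ...]                  # one per family, spec order
    specs: tuple[FamilySpec, ...]


def make_benchmark(
    family_specs: Sequence[FamilySpec],
    n_decoys: int,
    rng_seed: int = 0,
    msa_subsample: int = 20,
    decoy_length_range: tuple[int, int] | None = None,
    scoring: ScoringConfig = DEFAULT_SCORING,
) -> Benchmark:
    """Mix family members (labels 1..k in spec order) with decoys (label 0)
    and build a star-aligned MSA from the first ``msa_subsample`` members of
    each family."""
    if not family_specs:
        raise ValueError("at least one family is required")
    records: list[ProteinRecord] = []
    truth: dict[str, int] = {}
    msas: list[Msa] = []
    semantics: dict[int, str] = {0: "decoy"}
    for label, spec in enumerate(family_specs, start=1):
        members = generate_family(spec)
        records.extend(members)
        truth.update({m.id: label for m in members})
        semantics[label] = spec.name
        msas.append(star_align(spec.seed_sequence,
                               members[: min(msa_subsample, len(members))],
                               scoring))
    if decoy_length_range is None:
        lengths = [len(s.seed_sequence) for s in family_specs]
        decoy_length_range = (min(lengths), max(max(lengths), min(lengths) + 1))
    if n_decoys > 0:
        decoys = generate_decoys(n_decoys, decoy_length_range, rng_seed=rng_seed)
        records.extend(decoys)
        truth.update({d.id: 0 for d in decoys})
    return Benchmark(tuple(records), truth, semantics, tuple(msas),
                     tuple(family_specs))


def write_benchmark(benchmark: Benchmark, out_dir: str | Path) -> dict[str, Path]:
    """Write pool FASTA, truth TSV and per-family aligned FASTA files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"pool": out / "pool.fasta", "truth": out / "truth.tsv"}
    write_fasta(benchmark.records, paths["pool"])
    pd.DataFrame(
        [(r.id, benchmark.truth[r.id]) for r in benchmark.records],
        columns=["id", "label"],
    ).to_csv(paths["truth"], sep="\t", index=False)
    for i, msa in enumerate(benchmark.msas, start=1):
        p = out / f"family{i}_msa.fasta"
        write_msa(msa, p)
        paths[f"msa_{i}"] = p
    return paths
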