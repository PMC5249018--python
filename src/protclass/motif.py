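"""Consensus regions and PROSITE-style conserved-domain patterns.

A consensus region summarizes an MSA column-wise by majority residue.  A
conserved-domain pattern is an ordered motif of fixed residues, residue
classes ``[AC]``, exclusions ``{AC}`` and bounded wildcards ``x(m,n)``; a
protein *has* the domain iff the pattern matches anywhere in its sequence.

``derive_pattern`` is a transparent, conservative stand-in for a motif
discovery tool: gap-poor columns become fixed/class elements built from the
residues actually observed, runs of gap-rich columns become bounded
wildcards.  With ``refine=True`` only the longest contiguous run of
well-conserved element columns is kept, yielding the short, highly specific
motifs conserved domains are in practice (active-site style conservation).

Matching compiles the pattern to a regular expression, so matches are the
leftmost non-overlapping ones under greedy wildcard expansion.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable

from .io import CANONICAL_AA, GAP, Msa

ALPHABET_SIZE = 20


class PatternSyntaxError(ValueError):
    """Malformed PROSITE-style pattern text."""


@dataclass(frozen=True)
class ConsensusProfile:
    """Majority-residue consensus of an MSA over its gap-poor columns."""

    consensus: str
    column_conservation: tuple[float, ...]  # majority fraction per retained column
    n_sequences: int


@dataclass(frozen=True)
class PatternElement:
    """One motif position: fixed residue, class, exclusion or wildcard.

    ``residues`` is None for wildcards.  ``min_repeat``/``max_repeat`` give
    the repetition range (1, 1 for unrepeated elements).
    """

    kind: str  # "fixed" | "class" | "excluded" | "wildcard"
    residues: frozenset[str] | None
    min_repeat: int = 1
    max_repeat: int = 1

    def __post_init__(self) -> None:
        if self.min_repeat > self.max_repeat:
            raise PatternSyntaxError(
                f"repeat range ({self.min_repeat},{self.max_repeat}) has min > max"
            )
        if self.kind in ("class", "excluded") and not self.residues:
            raise PatternSyntaxError("residue class must be non-empty")

    def to_text(self) -> str:
        if self.kind == "fixed":
            body = next(iter(self.residues))
        elif self.kind == "class":
            body = "[" + "".join(sorted(self.residues)) + "]"
        elif self.kind == "excluded":
            body = "{" + "".join(sorted(self.residues)) + "}"
        else:
            body = "x"
        if (self.min_repeat, self.max_repeat) == (1, 1):
            return body
        if self.min_repeat == self.max_repeat:
            return f"{body}({self.min_repeat})"
        return f"{body}({self.min_repeat},{self.max_repeat})"

    def to_regex(self) -> str:
        if self.kind == "fixed":
            body = next(iter(self.residues))
        elif self.kind == "class":
            body = "[" + "".join(sorted(self.residues)) + "]"
        elif self.kind == "excluded":
            body = "[^" + "".join(sorted(self.residues)) + "]"
        else:
            body = "."
        if (self.min_repeat, self.max_repeat) == (1, 1):
            return body
        if self.min_repeat == self.max_repeat:
            return f"{body}{{{self.min_repeat}}}"
        return f"{body}{{{self.min_repeat},{self.max_repeat}}}"


@dataclass(frozen=True)
class PrositePattern:
    elements: tuple[PatternElement, ...]

    def __post_init__(self) -> None:
        if not self.elements:
            raise PatternSyntaxError("pattern must have at least one element")

    def to_text(self) -> str:
        return "-".join(e.to_text() for e in self.elements)

    def to_regex(self) -> str:
        return "".join(e.to_regex() for e in self.elements)


_TOKEN_RE = re.compile(
    r"^(?:(?P<fixed>[A-Z])|\[(?P<cls>[A-Z]+)\]|\{(?P<exc>[A-Z]+)\}|(?P<wild>x))"
    r"(?:\((?P<min>\d+)(?:,(?P<max>\d+))?\))?$"
)


def _check_residues(letters: str, pos: int) -> frozenset[str]:
    bad = sorted(set(letters) - set(CANONICAL_AA))
    if bad:
        raise PatternSyntaxError(
            f"element {pos}: non-canonical residue letter(s) {bad}"
        )
    return frozenset(letters)


def parse_pattern(text: str) -> PrositePattern:
    """Parse PROSITE-style pattern text (elements joined by '-').

    Grammar per element: a residue letter, ``[CLASS]``, ``{EXCLUDED}`` or
    ``x``, optionally followed by ``(n)`` or ``(m,n)``.  A trailing '.' is
    tolerated.  Errors report the 1-based element position.
    """
    text = text.strip().rstrip(".")
    if not text:
        raise PatternSyntaxError("empty pattern")
    elements: list[PatternElement] = []
    for pos, token in enumerate(text.split("-"), start=1):
        m = _TOKEN_RE.match(token.strip())
        if m is None:
            raise PatternSyntaxError(f"element {pos}: cannot parse '{token}'")
        lo = int(m.group("min")) if m.group("min") else 1
        hi = int(m.group("max")) if m.group("max") else lo
        if lo > hi:
            raise PatternSyntaxError(
                f"element {pos}: repeat range ({lo},{hi}) has min > max"
            )
        if m.group("fixed"):
            elem = PatternElement("fixed", _check_residues(m.group("fixed"), pos), lo, hi)
        elif m.group("cls"):
            elem = PatternElement("class", _check_residues(m.group("cls"), pos), lo, hi)
        elif m.group("exc"):
            elem = PatternElement("excluded", _check_residues(m.group("exc"), pos), lo, hi)
        else:
            elem = PatternElement("wildcard", None, lo, hi)
        elements.append(elem)
    return PrositePattern(tuple(elements))


def match_pattern(pattern: PrositePattern, sequence: str) -> list[tuple[int, int]]:
    """All leftmost non-overlapping matches as half-open (start, end) pairs."""
    return [m.span() for m in re.finditer(pattern.to_regex(), sequence)]


def has_domain(pattern: PrositePattern, sequence: str) -> bool:
    return re.search(pattern.to_regex(), sequence) is not None


def pattern_random_probability(pattern: PrositePattern) -> float:
    """Probability that a fixed window matches under i.i.d. uniform residues.

    Per element the single-position probability is |allowed|/20 (wildcards:
    1).  Variable repeats contribute their most permissive expansion, i.e.
    the minimum repeat count of a restrictive element.
    """
    prob = 1.0
    for e in pattern.elements:
        if e.kind == "wildcard":
            continue
        if e.kind == "excluded":
            p = (ALPHABET_SIZE - len(e.residues)) / ALPHABET_SIZE
        else:
            p = len(e.residues) / ALPHABET_SIZE
        prob *= p ** e.min_repeat
    return prob


# ---------------------------------------------------------------------------
# Derivation from an MSA


def _column_counts(msa: Msa, j: int) -> Counter[str]:
    return Counter(ch for ch in msa.column(j) if ch != GAP)


def consensus_from_msa(msa: Msa) -> ConsensusProfile:
    """Majority-residue consensus over columns with ≤ 50 % gaps.

    Per retained column the majority residue (ties broken alphabetically)
    becomes the consensus letter; conservation is majority count over
    non-gap count.  Raises ``ValueError`` when every column is gap-rich.
    """
    n = len(msa)
    letters: list[str] = []
    conservation: list[float] = []
    for j in range(msa.width):
        counts = _column_counts(msa, j)
        non_gap = sum(counts.values())
        if non_gap / n <= 0.5:  # strictly more than 50% gaps -> dropped
            continue
        best = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        letters.append(best[0])
        conservation.append(best[1] / non_gap)
    if not letters:
        raise ValueError("all alignment columns are gap-rich; no consensus")
    return ConsensusProfile("".join(letters), tuple(conservation), n)


def derive_pattern(
    msa: Msa,
    min_conservation: float = 0.9,
    refine: bool = False,
) -> PrositePattern:
    """Derive a conserved-domain pattern from an MSA.

    A column whose non-gap fraction is ≥ ``min_conservation`` emits a fixed
    residue (single residue observed) or a class of all observed residues.
    Maximal runs of remaining columns emit one bounded wildcard ``x(m,n)``
    where m/n are the per-row non-gap run lengths; leading and trailing
    wildcard runs are trimmed.

    With ``refine=True`` only the longest contiguous run of element columns
    whose *majority* conservation is ≥ ``min_conservation`` is kept — a
    short, specific motif rather than a whole-sequence pattern.

    Raises ``ValueError`` when no column qualifies (suggesting a lower
    threshold).
    """
    n = len(msa)
    # Classify columns: element (set of observed residues) or wildcard (None)
    column_sets: list[frozenset[str] | None] = []
    majority: list[float] = []
    for j in range(msa.width):
        counts = _column_counts(msa, j)
        non_gap = sum(counts.values())
        if non_gap and non_gap / n >= min_conservation:
            column_sets.append(frozenset(counts))
            majority.append(max(counts.values()) / non_gap)
        else:
            column_sets.append(None)
            majority.append(0.0)
    element_cols = [j for j, s in enumerate(column_sets) if s is not None]
    if not element_cols:
        raise ValueError(
            "no alignment column qualifies as a pattern element; "
            f"try a threshold below {min_conservation}"
        )

    if refine:
        keep = [
            s is not None and majority[j] >= min_conservation
            for j, s in enumerate(column_sets)
        ]
        best_start = best_len = 0
        j = 0
        while j < msa.width:
            if keep[j]:
                k = j
                while k < msa.width and keep[k]:
                    k += 1
                if k - j > best_len:
                    best_start, best_len = j, k - j
                j = k
            else:
                j += 1
        if best_len == 0:
            raise ValueError(
                "no well-conserved column run found for refinement; "
                f"try a threshold below {min_conservation}"
            )
        columns = range(best_start, best_start + best_len)
        return PrositePattern(tuple(
            _element_from_set(column_sets[j]) for j in columns
        ))

    # Full span: elements interleaved with bounded wildcards
    elements: list[PatternElement] = []
    j = 0
    while j < msa.width:
        if column_sets[j] is not None:
            elements.append(_element_from_set(column_sets[j]))
            j += 1
        else:
            k = j
            while k < msa.width and column_sets[k] is None:
                k += 1
            if elements:  # leading wildcard run trimmed
                run_lengths = [
                    sum(1 for c in rec.sequence[j:k] if c != GAP)
                    for rec in msa.records
                ]
                lo, hi = min(run_lengths), max(run_lengths)
                if hi > 0 and k < msa.width:  # trailing run trimmed too
                    elements.append(PatternElement("wildcard", None, lo, hi))
            j = k
    return PrositePattern(tuple(elements))


def _element_from_set(residues: frozenset[str]) -> PatternElement:
    if len(residues) == 1:
        return PatternElement("fixed", residues)
    return PatternElement("class", residues)
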