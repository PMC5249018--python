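"""Gene co-occurrence correlation and neighborhood analysis.

Presence calls are boolean per (genome, gene label).  The Pearson
correlation of two 0/1 presence columns equals the phi coefficient of their
2×2 contingency table; p-values come from the t distribution with n−2
degrees of freedom.  Neighborhood scans count gene labels within ±window
*genes* (order indices, same replicon) of every focal-gene locus.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneLocus

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenePresenceTable:
    """Genomes × gene-labels boolean matrix."""

    presence: pd.DataFrame  # index: genome ids, columns: gene labels, dtype bool

    @property
    def genomes(self) -> list[str]:
        return list(self.presence.index)

    @property
    def genes(self) -> list[str]:
        return list(self.presence.columns)


def build_presence_table(
    loci: Sequence[GeneLocus], gene_set: Sequence[str]
) -> GenePresenceTable:
    """presence[g, j] is True iff genome g carries ≥1 locus labeled gene_set[j].

    Genomes appear in order of first occurrence in ``loci``.
    """
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    genomes: list[str] = []
    seen: set[str] = set()
    for locus in loci:
        if locus.genome_id not in seen:
            seen.add(locus.genome_id)
            genomes.append(locus.genome_id)
    df = pd.DataFrame(False, index=genomes, columns=list(gene_set), dtype=bool)
    wanted = set(gene_set)
    for locus in loci:
        if locus.gene_label in wanted:
            df.loc[locus.genome_id, locus.gene_label] = True
    return GenePresenceTable(df)


def pearson_cooccurrence(
    table: GenePresenceTable,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r (phi) of presence columns, with two-sided p-values.

    Requires ≥3 genomes.  Pairs involving a constant column are reported as
    NaN with a warning (r is undefined there).  Diagonal r is 1, p is 0.
    """
    df = table.presence.astype(float)
    n = len(df)
    if n < 3:
        raise ValueError("correlation needs at least 3 genomes")
    genes = table.genes
    constant = [g for g in genes if df[g].nunique() <= 1]
    if constant:
        logger.warning(
            "constant presence column(s) %s: correlations reported as NaN",
            constant,
        )
    r = pd.DataFrame(np.nan, index=genes, columns=genes)
    p = pd.DataFrame(np.nan, index=genes, columns=genes)
    for i, gi in enumerate(genes):
        r.loc[gi, gi] = 1.0
        p.loc[gi, gi] = 0.0
        for gj in genes[i + 1:]:
            if gi in constant or gj in constant:
                continue
            res = stats.pearsonr(df[gi], df[gj])
            r.loc[gi, gj] = r.loc[gj, gi] = res.statistic
            p.loc[gi, gj] = p.loc[gj, gi] = res.pvalue
    return r, p


def neighborhood_scan(
    loci: Sequence[GeneLocus], focal: str, window: int = 5
) -> dict[str, int]:
    """Counts of each gene label within ±window genes of every focal locus.

    One count per (focal locus, neighbor locus) pair — a genome with two
    focal copies contributes from both.  Windows never cross replicon
    boundaries and truncate at replicon ends.
    """
    by_replicon: dict[tuple[str, str], list[GeneLocus]] = defaultdict(list)
    for locus in loci:
        by_replicon[(locus.genome_id, locus.replicon_id)].append(locus)
    counts: Counter[str] = Counter()
    n_focal = 0
    for group in by_replicon.values():
        focal_loci = [g for g in group if g.gene_label == focal]
        n_focal += len(focal_loci)
        for f in focal_loci:
            for g in group:
                delta = g.order_index - f.order_index
                if delta != 0 and abs(delta) <= window:
                    counts[g.gene_label] += 1
    if n_focal == 0:
        logger.warning("focal gene label '%s' not found in any replicon", focal)
    return dict(counts)
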