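"""Rank comparison of effluent abundance against a consensus plasma proteome.

Effluent proteins quantified by Top3 are mapped onto a reference table of
mean plasma concentrations.  On the shared set, each protein gets a
relative abundance rank in each list (rank / list length, rank 1 = most
abundant); the difference of relative ranks measures over- or
underrepresentation in effluent relative to plasma, and the n most
extreme proteins in each direction are selected for downstream
enrichment analysis.  Relative ranks are used because the two lists have
different lengths; raw-rank mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from pdeproteome.abundance import Top3Abundance

__all__ = [
    "RankComparison",
    "map_to_reference",
    "abundance_correlation",
    "compare_ranks",
    "select_rank_extremes",
]


@dataclass(frozen=True)
class RankComparison:
    accession: str
    pde_rank: float
    plasma_rank: float
    relative_rank_delta: float  # pde relative rank - plasma relative rank


def map_to_reference(
    pde: Sequence[Top3Abundance], ref: Mapping[str, float]
) -> tuple[set[str], set[str], set[str]]:
    """Partition accessions into (shared, effluent-only, reference-only)."""
    pde_acc = {a.reporter for a in pde}
    ref_acc = set(ref)
    return pde_acc & ref_acc, pde_acc - ref_acc, ref_acc - pde_acc


def abundance_correlation(
    shared_abundance: Mapping[str, float], ref: Mapping[str, float]
) -> float:
    """Pearson r between log10 effluent abundance and log10 plasma conc."""
    accs = sorted(set(shared_abundance) & set(ref))
    if len(accs) < 3:
        raise ValueError("need at least 3 shared proteins for a correlation")
    x = np.log10([shared_abundance[a] for a in accs])
    y = np.log10([ref[a] for a in accs])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, _ = stats.pearsonr(x, y)
    return float(r)


def compare_ranks(
    pde: Sequence[Top3Abundance],
    ref: Mapping[str, float],
    mode: Literal["relative", "raw"] = "relative",
) -> list[RankComparison]:
    """Rank each full list (ties averaged) and compare on the shared set.

    Ranks are computed over the *entire* effluent list and the *entire*
    reference list; proteins absent from the reference are excluded from
    the comparison (they have no plasma rank).
    """
    pde_series = pd.Series({a.reporter: a.abundance for a in pde}, dtype=float)
    ref_series = pd.Series(dict(ref), dtype=float)
    pde_rank = pde_series.rank(ascending=False, method="average")
    ref_rank = ref_series.rank(ascending=False, method="average")
    shared = sorted(set(pde_rank.index) & set(ref_rank.index))
    n_pde, n_ref = len(pde_rank), len(ref_rank)
    out = []
    for acc in shared:
        pr, rr = float(pde_rank[acc]), float(ref_rank[acc])
        if mode == "relative":
            delta = pr / n_pde - rr / n_ref
        elif mode == "raw":
            delta = pr - rr
        else:
            raise ValueError(f"unknown rank mode {mode!r}")
        out.append(
            RankComparison(
                accession=acc, pde_rank=pr, plasma_rank=rr, relative_rank_delta=delta
            )
        )
    return out


def select_rank_extremes(
    comparisons: Sequence[RankComparison], n_each: int = 100
) -> tuple[set[str], set[str]]:
    """The n most over- and underrepresented proteins in effluent.

    A negative delta means the protein ranks better (more abundant) in
    effluent than in plasma.  Ties break lexicographically by accession,
    so the selection is deterministic.
    """
    if n_each < 0:
        raise ValueError("n_each must be >= 0")
    if 2 * n_each > len(comparisons):
        raise ValueError(
            f"cannot select 2x{n_each} extremes from {len(comparisons)} shared proteins"
        )
    by_delta = sorted(comparisons, key=lambda c: (c.relative_rank_delta, c.accession))
    higher = {c.accession for c in by_delta[:n_each]}
    by_delta_desc = sorted(
        comparisons, key=lambda c: (-c.relative_rank_delta, c.accession)
    )
    lower = {c.accession for c in by_delta_desc[:n_each]}
    return higher, lower
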