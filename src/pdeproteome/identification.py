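"""Dual-engine tiered PSM validation, protein grouping and decoy FDR.

Protein identifications from two search engines (score scales are not
comparable across engines) are validated with a three-threshold scheme:

* a protein with >= 2 unique peptides scoring above ``T1`` is accepted, or
* a protein with a single peptide scoring above ``T2`` is accepted;
* for accepted proteins, additional peptides scoring above ``T3`` are kept.

Unique here means the peptide's PSMs name exactly one protein.  Spectra
assigned different peptides by the two engines are spectral conflicts and
are discarded from both engines' evidence.  Accepted proteins are then
grouped by shared validated peptides (connected components of the
peptide-sharing graph) and each group is represented by one reporter
accession.  Running the identical procedure on PSMs searched against a
reversed database yields the decoy counts for FDR estimation.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PSMRecord",
    "ValidationThresholds",
    "ProteinGroup",
    "FDRReport",
    "CalibrationUnavailableError",
    "UndefinedFDRError",
    "recalibrate_masses",
    "validate_proteins",
    "estimate_fdr",
    "filter_keratins",
    "merge_isoforms",
]


class CalibrationUnavailableError(ValueError):
    """No high-confidence PSMs are available for mass recalibration."""


class UndefinedFDRError(ZeroDivisionError):
    """FDR is undefined because the target count is zero."""


@dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum match from one search engine.

    ``theoretical_mz`` accompanies the measured precursor m/z so that the
    recalibration step needs no sequence chemistry.
    """

    spectrum_id: str
    peptide: str
    proteins: tuple[str, ...]
    engine: str
    score: float
    retention_time: float
    precursor_mz: float
    is_decoy: bool = False
    theoretical_mz: float | None = None

    def __post_init__(self) -> None:
        if not self.proteins:
            raise ValueError("PSMRecord requires at least one protein accession")
        if not np.isfinite(self.score):
            raise ValueError("PSM score must be finite")
        if self.retention_time < 0:
            raise ValueError("retention time must be >= 0")


@dataclass(frozen=True)
class ValidationThresholds:
    """Score tiers for one engine; must satisfy T3 <= T1 <= T2."""

    T1: float
    T2: float
    T3: float

    def __post_init__(self) -> None:
        if not (self.T3 <= self.T1 <= self.T2):
            raise ValueError(f"thresholds must satisfy T3 <= T1 <= T2, got {self}")


#: Published tier values for the two engines.
MASCOT_THRESHOLDS = ValidationThresholds(T1=16.0, T2=40.0, T3=10.0)
PHENYX_THRESHOLDS = ValidationThresholds(T1=5.5, T2=9.5, T3=3.5)
DEFAULT_THRESHOLDS: dict[str, ValidationThresholds] = {
    "mascot": MASCOT_THRESHOLDS,
    "phenyx": PHENYX_THRESHOLDS,
}


@dataclass
class ProteinGroup:
    reporter: str
    members: frozenset[str]
    peptides: frozenset[str]
    unique_peptides: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.reporter not in self.members:
            raise ValueError("group reporter must be one of its members")
        if not self.unique_peptides <= self.peptides:
            raise ValueError("unique peptides must be a subset of the peptide set")


@dataclass(frozen=True)
class FDRReport:
    peptide_fdr: float
    protein_group_fdr: float
    n_target_peptides: int
    n_decoy_peptides: int
    n_target_groups: int
    n_decoy_groups: int


def _ppm_offset(psm: PSMRecord) -> float:
    if psm.theoretical_mz is None or psm.theoretical_mz <= 0:
        raise ValueError(f"PSM {psm.spectrum_id} lacks a theoretical m/z")
    return (psm.precursor_mz - psm.theoretical_mz) / psm.theoretical_mz * 1e6


def recalibrate_masses(
    psms: Sequence[PSMRecord], high_conf_score: float
) -> list[PSMRecord]:
    """Remove the median ppm mass offset of high-confidence PSMs.

    The offset of each PSM scoring >= ``high_conf_score`` relative to its
    theoretical mass is computed in ppm; the median offset is subtracted
    from every precursor m/z.  Raises
    :class:`CalibrationUnavailableError` when no PSM reaches the
    high-confidence score.
    """
    high_conf = [p for p in psms if p.score >= high_conf_score]
    if not high_conf:
        raise CalibrationUnavailableError(
            f"no PSM with score >= {high_conf_score}; cannot recalibrate"
        )
    median_ppm = float(np.median([_ppm_offset(p) for p in high_conf]))
    factor = 1.0 + median_ppm * 1e-6
    return [replace(p, precursor_mz=p.precursor_mz / factor) for p in psms]


def discard_spectral_conflicts(
    psms_by_engine: Mapping[str, Sequence[PSMRecord]],
) -> dict[str, list[PSMRecord]]:
    """Drop spectra assigned different peptides by different engines.

    A conflicting spectrum is removed from every engine's evidence.
    """
    peptide_by_spectrum: dict[str, set[str]] = defaultdict(set)
    for psms in psms_by_engine.values():
        for p in psms:
            peptide_by_spectrum[p.spectrum_id].add(p.peptide)
    conflicted = {sid for sid, peps in peptide_by_spectrum.items() if len(peps) > 1}
    return {
        engine: [p for p in psms if p.spectrum_id not in conflicted]
        for engine, psms in psms_by_engine.items()
    }


def _validated_peptides_one_engine(
    psms: Sequence[PSMRecord], thr: ValidationThresholds, strict: bool
) -> dict[str, set[str]]:
    """Apply the T1/T2 tiers then the T3 augmentation for one engine.

    Returns accepted protein -> validated peptide set.  ``strict`` selects
    ``>`` (default) versus ``>=`` for all three tiers.
    """

    def above(score: float, t: float) -> bool:
        return score > t if strict else score >= t

    # Best score per (protein, peptide) and the protein list per peptide.
    best: dict[tuple[str, str], float] = {}
    peptide_proteins: dict[str, set[str]] = defaultdict(set)
    for p in psms:
        peptide_proteins[p.peptide].update(p.proteins)
        for acc in p.proteins:
            key = (acc, p.peptide)
            if key not in best or p.score > best[key]:
                best[key] = p.score

    by_protein: dict[str, dict[str, float]] = defaultdict(dict)
    for (acc, pep), score in best.items():
        by_protein[acc][pep] = score

    accepted: dict[str, set[str]] = {}
    for acc, pep_scores in by_protein.items():
        unique_above_t1 = [
            pep
            for pep, s in pep_scores.items()
            if above(s, thr.T1) and len(peptide_proteins[pep]) == 1
        ]
        any_above_t2 = any(above(s, thr.T2) for s in pep_scores.values())
        if len(unique_above_t1) >= 2 or any_above_t2:
            accepted[acc] = {pep for pep, s in pep_scores.items() if above(s, thr.T3)}
    return accepted


def group_by_shared_peptides(
    protein_peptides: Mapping[str, set[str]],
) -> list[ProteinGroup]:
    """Union proteins sharing any validated peptide into groups.

    Connected components of the bipartite protein-peptide graph, found by
    union-find over proteins.  The reporter is the lexicographically
    smallest accession among members with the most unique peptides.
    """
    parent: dict[str, str] = {acc: acc for acc in protein_peptides}

    def find(a: str) -> str:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    by_peptide: dict[str, list[str]] = defaultdict(list)
    for acc, peps in protein_peptides.items():
        for pep in peps:
            by_peptide[pep].append(acc)
    for accs in by_peptide.values():
        for other in accs[1:]:
            union(accs[0], other)

    components: dict[str, set[str]] = defaultdict(set)
    for acc in protein_peptides:
        components[find(acc)].add(acc)

    groups: list[ProteinGroup] = []
    for members in components.values():
        peptides = set().union(*(protein_peptides[m] for m in members))
        groups.append(_make_group(members, peptides, protein_peptides))
    groups.sort(key=lambda g: g.reporter)
    return _recompute_unique_peptides(groups)


def _make_group(
    members: set[str],
    peptides: set[str],
    protein_peptides: Mapping[str, set[str]],
) -> ProteinGroup:
    n_shared: dict[str, int] = defaultdict(int)
    for pep in peptides:
        owners = [m for m in members if pep in protein_peptides.get(m, ())]
        if len(owners) == 1:
            n_shared[owners[0]] += 1
    best_count = max((n_shared.get(m, 0) for m in members), default=0)
    reporter = min(m for m in members if n_shared.get(m, 0) == best_count)
    return ProteinGroup(
        reporter=reporter, members=frozenset(members), peptides=frozenset(peptides)
    )


def _recompute_unique_peptides(groups: list[ProteinGroup]) -> list[ProteinGroup]:
    """unique_peptides = peptides occurring in exactly one group's set."""
    count: dict[str, int] = defaultdict(int)
    for g in groups:
        for pep in g.peptides:
            count[pep] += 1
    return [
        ProteinGroup(
            reporter=g.reporter,
            members=g.members,
            peptides=g.peptides,
            unique_peptides=frozenset(p for p in g.peptides if count[p] == 1),
        )
        for g in groups
    ]


def validate_proteins(
    psms_by_engine: Mapping[str, Sequence[PSMRecord]],
    thresholds: Mapping[str, ValidationThresholds] | None = None,
    *,
    strict: bool = True,
    discard_conflicts: bool = True,
) -> list[ProteinGroup]:
    """Full validation: tiers per engine, conflict removal, grouping.

    Parameters
    ----------
    psms_by_engine
        Engine label -> PSM list (one search, target or decoy).
    thresholds
        Engine label -> :class:`ValidationThresholds`; defaults to the
        published Mascot/Phenyx tiers for those engine labels.
    strict
        Apply every tier as a strict inequality (default) or as ``>=``.
    """
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    missing = set(psms_by_engine) - set(thresholds)
    if missing:
        raise ValueError(f"no validation thresholds for engine(s): {sorted(missing)}")

    if discard_conflicts:
        psms_by_engine = discard_spectral_conflicts(psms_by_engine)

    merged: dict[str, set[str]] = defaultdict(set)
    for engine, psms in psms_by_engine.items():
        accepted = _validated_peptides_one_engine(psms, thresholds[engine], strict)
        for acc, peps in accepted.items():
            merged[acc] |= peps
    return group_by_shared_peptides(merged)


def estimate_fdr(
    target_groups: Sequence[ProteinGroup],
    decoy_groups: Sequence[ProteinGroup],
) -> FDRReport:
    """Decoy-based FDR: decoy count over target count, peptides and groups.

    Both group lists must come from the identical validation procedure,
    run once on the target search and once on the reversed-database
    search.
    """
    n_target_peptides = len({p for g in target_groups for p in g.peptides})
    n_decoy_peptides = len({p for g in decoy_groups for p in g.peptides})
    n_target_groups = len(target_groups)
    n_decoy_groups = len(decoy_groups)
    if n_target_groups == 0 or n_target_peptides == 0:
        raise UndefinedFDRError("FDR undefined: no validated target identifications")
    return FDRReport(
        peptide_fdr=n_decoy_peptides / n_target_peptides,
        protein_group_fdr=n_decoy_groups / n_target_groups,
        n_target_peptides=n_target_peptides,
        n_decoy_peptides=n_decoy_peptides,
        n_target_groups=n_target_groups,
        n_decoy_groups=n_decoy_groups,
    )


def filter_keratins(
    groups: Iterable[ProteinGroup], names: Mapping[str, str]
) -> list[ProteinGroup]:
    """Drop keratin groups whose description mentions hair or cuticular.

    Cytoskeletal keratins are retained: they mark mesothelial cells and
    are biologically meaningful in dialysis effluent.  Only descriptions
    that are keratins *and* contain "hair" or "cuticular"
    (case-insensitive) are excluded.
    """
    kept = []
    for g in groups:
        desc = names.get(g.reporter, "").lower()
        if "keratin" in desc and ("hair" in desc or "cuticular" in desc):
            continue
        kept.append(g)
    return kept


def _base_accession(acc: str) -> str:
    head, sep, tail = acc.rpartition("-")
    if sep and tail.isdigit():
        return head
    return acc


def merge_isoforms(groups: Sequence[ProteinGroup]) -> list[ProteinGroup]:
    """Merge groups whose reporters differ only by an isoform suffix.

    Accessions follow the ``accession-N`` convention.  Peptide and member
    sets are unioned and unique peptides recomputed over the merged
    grouping.
    """
    buckets: dict[str, list[ProteinGroup]] = defaultdict(list)
    for g in groups:
        buckets[_base_accession(g.reporter)].append(g)

    merged: list[ProteinGroup] = []
    for gs in buckets.values():
        if len(gs) == 1:
            merged.append(gs[0])
            continue
        members = frozenset().union(*(g.members for g in gs))
        peptides = frozenset().union(*(g.peptides for g in gs))
        reporter = min(g.reporter for g in gs)
        merged.append(ProteinGroup(reporter=reporter, members=members, peptides=peptides))
    merged.sort(key=lambda g: g.reporter)
    return _recompute_unique_peptides(merged)
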