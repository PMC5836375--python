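"""Modified Top3 label-free abundance from extracted ion chromatograms.

Top3 estimates a protein's abundance as the mean area of its three most
intense peptides.  Standard peak integration considers only the local
chromatographic peak around a single PSM; when a peptide has several
PSMs spread over elution time this can truncate the true signal.  The
modified rule therefore computes, for any peptide with >= 2 PSMs, both

* ``A_S`` — the area of the single contiguous peak containing the
  highest-apex PSM (local integration), and
* ``A_0f`` — the area under the whole chromatogram from the earliest PSM
  retention time ``T_0`` to the latest ``T_f``,

and takes the larger of the two as the peptide area.  A single-PSM
peptide keeps the local area ``A_S``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PeptideArea",
    "Top3Abundance",
    "integrate_peptide_area",
    "top3",
    "top3_per_group",
    "rank_abundances",
]


@dataclass(frozen=True)
class PeptideArea:
    """Resolved integration of one peptide's chromatogram.

    ``A_0f`` is NaN for single-PSM peptides (not computed).
    """

    peptide: str
    A_S: float
    A_0f: float
    T_0: float
    T_f: float
    area: float


@dataclass(frozen=True)
class Top3Abundance:
    reporter: str
    abundance: float
    n_peptides_used: int


def _local_peak_bounds(
    intensity: np.ndarray, apex_idx: int, frac_of_apex: float
) -> tuple[int, int]:
    """Expand from the apex to the nearest valley below ``frac * apex``.

    A valley is a local minimum of the sampled trace; the boundary is the
    first one whose intensity falls below the apex fraction, or the trace
    end.
    """
    threshold = frac_of_apex * intensity[apex_idx]
    lo = apex_idx
    while lo > 0:
        if (
            intensity[lo] <= threshold
            and intensity[lo] <= intensity[lo - 1]
            and (lo == apex_idx or intensity[lo] <= intensity[lo + 1])
        ):
            break
        lo -= 1
    hi = apex_idx
    n = len(intensity)
    while hi < n - 1:
        if (
            intensity[hi] <= threshold
            and intensity[hi] <= intensity[hi + 1]
            and (hi == apex_idx or intensity[hi] <= intensity[hi - 1])
        ):
            break
        hi += 1
    return lo, hi


def _apex_index(intensity: np.ndarray, start_idx: int) -> int:
    """Hill-climb from a grid index to the local maximum of its peak."""
    i = start_idx
    n = len(intensity)
    while i > 0 and intensity[i - 1] > intensity[i]:
        i -= 1
    while i < n - 1 and intensity[i + 1] > intensity[i]:
        i += 1
    return i


def _area_between(times: np.ndarray, intensity: np.ndarray, t0: float, t1: float) -> float:
    """Trapezoidal area over [t0, t1] with linear interpolation at the ends."""
    if t1 <= t0:
        return 0.0
    grid = times[(times > t0) & (times < t1)]
    ts = np.concatenate(([t0], grid, [t1]))
    ys = np.interp(ts, times, intensity)
    return float(np.trapezoid(ys, ts))


def integrate_peptide_area(
    trace: tuple[np.ndarray, np.ndarray],
    psm_times: Sequence[float],
    peptide: str = "",
    frac_of_apex: float = 0.05,
) -> PeptideArea:
    """Integrate one peptide's XIC using the A_S / A_0f rule.

    Parameters
    ----------
    trace
        ``(times, intensities)`` arrays; times strictly increasing.
    psm_times
        Retention times (min) of the peptide's PSMs; all must lie within
        the trace span.
    frac_of_apex
        Valley threshold, as a fraction of the apex intensity, that ends
        the local peak region for ``A_S``.
    """
    times = np.asarray(trace[0], dtype=float)
    intensity = np.asarray(trace[1], dtype=float)
    if times.size == 0 or times.size != intensity.size:
        raise ValueError("trace must have matching, non-empty time/intensity arrays")
    if np.any(np.diff(times) <= 0):
        raise ValueError("trace times must be strictly increasing")
    psm_times = sorted(float(t) for t in psm_times)
    if not psm_times:
        raise ValueError("at least one PSM retention time is required")
    if psm_times[0] < times[0] or psm_times[-1] > times[-1]:
        raise ValueError("PSM retention time outside the trace span")

    # A_S: local peak around the PSM whose peak apex is highest.
    apex_indices = [
        _apex_index(intensity, int(np.argmin(np.abs(times - t)))) for t in psm_times
    ]
    best_apex = max(apex_indices, key=lambda i: intensity[i])
    lo, hi = _local_peak_bounds(intensity, best_apex, frac_of_apex)
    a_s = float(np.trapezoid(intensity[lo : hi + 1], times[lo : hi + 1]))

    t_0, t_f = psm_times[0], psm_times[-1]
    if len(psm_times) >= 2:
        a_0f = _area_between(times, intensity, t_0, t_f)
        area = max(a_s, a_0f)
    else:
        a_0f = float("nan")
        area = a_s
    return PeptideArea(peptide=peptide, A_S=a_s, A_0f=a_0f, T_0=t_0, T_f=t_f, area=area)


def top3(areas: Sequence[PeptideArea], reporter: str = "") -> Top3Abundance:
    """Mean of the up-to-three largest resolved peptide areas."""
    if not areas:
        raise ValueError("top3 requires at least one peptide area")
    largest = sorted((a.area for a in areas), reverse=True)[:3]
    return Top3Abundance(
        reporter=reporter,
        abundance=float(np.mean(largest)),
        n_peptides_used=len(largest),
    )


def top3_per_group(
    group_peptides: Mapping[str, set[str]],
    areas: Mapping[str, PeptideArea],
) -> list[Top3Abundance]:
    """Top3 for each protein group from its peptides' resolved areas.

    ``group_peptides`` maps a group reporter to the peptide set to
    quantify with (all validated peptides, or only unique ones).
    Groups with no integrated peptide are omitted.
    """
    out = []
    for reporter in sorted(group_peptides):
        peptide_areas = [
            areas[p] for p in group_peptides[reporter] if p in areas
        ]
        if peptide_areas:
            out.append(top3(peptide_areas, reporter=reporter))
    return out


def rank_abundances(abundances: Sequence[Top3Abundance]) -> dict[str, float]:
    """Descending abundance ranks (1 = most abundant), average rank on ties."""
    if not abundances:
        return {}
    s = pd.Series(
        {a.reporter: a.abundance for a in abundances}, dtype=float
    )
    ranks = s.rank(ascending=False, method="average")
    return {str(k): float(v) for k, v in ranks.items()}
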