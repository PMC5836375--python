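"""TMT 6-plex reporter processing and paired differential analysis.

Reporter ions are extracted from MS2 peak lists within a narrow m/z
window (default +/- 0.005 Th), corrected for isotopic label impurities by
solving the impurity mixing system, and normalised so that all six
channel totals within a run are equal.  Because both treatments of each
patient sit in the same run (cross-over design, three patients per
6-plex), protein ratios are formed per patient from unique-peptide
reporter intensities and tested against no change with a one-sample,
one-sided t-test over patients.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from pdeproteome.identification import ProteinGroup
from pdeproteome.study_design import StudyDesign

__all__ = [
    "ReporterSpectrum",
    "ImpurityMatrix",
    "PatientRatio",
    "DifferentialResult",
    "DEFAULT_REPORTER_MZ",
    "extract_reporters",
    "correct_impurities",
    "normalize_channels",
    "protein_patient_ratio",
    "patient_ratios",
    "differential_test",
    "stable_protein_subset",
]

#: Monoisotopic reporter m/z of the six TMT 6-plex channels (126..131).
DEFAULT_REPORTER_MZ = np.array(
    [126.127726, 127.131081, 128.134436, 129.137790, 130.141145, 131.138180]
)

N_CHANNELS = 6


@dataclass
class ReporterSpectrum:
    """Reporter intensities of one MS2 spectrum (one peptide, one run)."""

    spectrum_id: str
    peptide: str
    channel_intensity: np.ndarray
    run: str

    def __post_init__(self) -> None:
        self.channel_intensity = np.asarray(self.channel_intensity, dtype=float)
        if self.channel_intensity.shape != (N_CHANNELS,):
            raise ValueError("exactly 6 reporter channels required")
        if not np.all(np.isfinite(self.channel_intensity)):
            raise ValueError("reporter intensities must be finite")


@dataclass(frozen=True)
class ImpurityMatrix:
    """Column-stochastic mixing matrix of the isotopic label impurities.

    Column ``j`` gives the distribution of label ``j``'s signal over the
    six observed channels; columns sum to <= 1 (signal lost outside the
    six windows is allowed) and the diagonal dominates.
    """

    M: np.ndarray

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        if M.shape != (N_CHANNELS, N_CHANNELS):
            raise ValueError("impurity matrix must be 6x6")
        if np.any(M < 0) or np.any(M.sum(axis=0) > 1.0 + 1e-6):
            raise ValueError("impurity columns must be proportions summing to <= 1")
        if np.any(np.diag(M) < M.sum(axis=0) - np.diag(M)):
            raise ValueError("impurity matrix must be diagonally dominant")
        object.__setattr__(self, "M", M)

    @classmethod
    def identity(cls) -> "ImpurityMatrix":
        return cls(np.eye(N_CHANNELS))

    @classmethod
    def nearest_neighbor(cls, minus1: float = 0.02, plus1: float = 0.04) -> "ImpurityMatrix":
        """Typical label sheet: a few percent spill into adjacent channels."""
        M = np.eye(N_CHANNELS) * (1.0 - minus1 - plus1)
        for j in range(N_CHANNELS):
            if j > 0:
                M[j - 1, j] += minus1
            if j < N_CHANNELS - 1:
                M[j + 1, j] += plus1
        return cls(M)


@dataclass(frozen=True)
class PatientRatio:
    """One protein's treated-vs-control log ratio for one patient."""

    reporter: str
    patient: str
    log_ratio: float
    n_peptide_obs: int


@dataclass(frozen=True)
class DifferentialResult:
    reporter: str
    n_ratios: int
    mean_log_ratio: float
    p_value: float
    significant: bool
    passes_fc: bool


def extract_reporters(
    peaks: Sequence[tuple[float, float]],
    expected_mz: np.ndarray | None = None,
    tolerance: float = 0.005,
) -> np.ndarray:
    """Sum peak intensities within +/- tolerance of each reporter m/z.

    Channels with no peak in the window report 0.  Raises if the
    extraction windows of two channels overlap.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    mz = DEFAULT_REPORTER_MZ if expected_mz is None else np.asarray(expected_mz, float)
    if mz.shape != (N_CHANNELS,):
        raise ValueError("expected_mz must have 6 entries")
    order = np.sort(mz)
    if np.any(np.diff(order) < 2 * tolerance):
        raise ValueError("reporter extraction windows overlap; reduce tolerance")
    out = np.zeros(N_CHANNELS)
    for peak_mz, intensity in peaks:
        d = np.abs(mz - peak_mz)
        j = int(np.argmin(d))
        if d[j] <= tolerance:
            out[j] += intensity
    return out


def correct_impurities(
    v: np.ndarray, M: ImpurityMatrix
) -> tuple[np.ndarray, int]:
    """Invert the impurity mixing: solve M x = v, clip negatives to 0.

    Returns the corrected 6-vector and the number of clipped channels.
    """
    v = np.asarray(v, dtype=float)
    if v.shape != (N_CHANNELS,):
        raise ValueError("reporter vector must have 6 channels")
    x = np.linalg.solve(M.M, v)
    n_clipped = int(np.sum(x < 0))
    return np.clip(x, 0.0, None), n_clipped


def normalize_channels(
    run_spectra: Sequence[ReporterSpectrum],
) -> list[ReporterSpectrum]:
    """Rescale channels so all six totals equal the mean original total.

    Operates within one run (all spectra must share a run id).  A channel
    whose total is zero cannot be normalised and raises.
    """
    runs = {s.run for s in run_spectra}
    if len(runs) > 1:
        raise ValueError("normalize_channels operates on a single run")
    totals = np.sum([s.channel_intensity for s in run_spectra], axis=0)
    if np.any(totals <= 0):
        raise ValueError(f"degenerate channel totals {totals}; cannot normalize")
    scale = totals.mean() / totals
    return [
        replace(s, channel_intensity=s.channel_intensity * scale)
        for s in run_spectra
    ]


def _patient_channels(
    design: StudyDesign, patient: str
) -> tuple[str, int, int]:
    """(run, control channel, treated channel) for one patient."""
    run = design.primary_run(patient)
    control = treated = None
    for (r, ch), cell in design.channel_assignment.items():
        if r != run or cell.patient != patient or cell.is_replicate:
            continue
        if cell.treatment == "control":
            control = ch
        elif cell.treatment == "alagln":
            treated = ch
    if control is None or treated is None:
        raise KeyError(f"patient {patient} lacks both treatments in run {run}")
    return run, control, treated


def protein_patient_ratio(
    group: ProteinGroup,
    spectra: Sequence[ReporterSpectrum],
    design: StudyDesign,
    patient: str,
    *,
    estimator: Literal["sum", "median"] = "sum",
    log_base: float = 2.0,
) -> PatientRatio | None:
    """Treated/control log ratio of one protein for one patient.

    Only spectra of the group's unique peptides in the patient's run are
    used.  ``sum`` (default) takes the log ratio of summed reporter
    intensities; ``median`` takes the median of per-spectrum log ratios.
    Returns ``None`` when no unique-peptide spectrum or a zero
    denominator makes the ratio undefined.
    """
    run, ch_control, ch_treated = _patient_channels(design, patient)
    # peptides iterate in sorted order so float summation is reproducible
    if isinstance(spectra, Mapping):  # pre-built peptide index for one run
        obs = [
            s for pep in sorted(group.unique_peptides) for s in spectra.get(pep, ())
        ]
    else:
        obs = [
            s
            for s in spectra
            if s.run == run and s.peptide in group.unique_peptides
        ]
    if not obs:
        return None
    log = math.log2 if log_base == 2.0 else lambda x: math.log(x, log_base)
    if estimator == "sum":
        num = sum(s.channel_intensity[ch_treated] for s in obs)
        den = sum(s.channel_intensity[ch_control] for s in obs)
        if den <= 0 or num <= 0:
            return None
        value = log(num / den)
    elif estimator == "median":
        ratios = [
            log(s.channel_intensity[ch_treated] / s.channel_intensity[ch_control])
            for s in obs
            if s.channel_intensity[ch_control] > 0 and s.channel_intensity[ch_treated] > 0
        ]
        if not ratios:
            return None
        value = float(np.median(ratios))
    else:
        raise ValueError(f"unknown ratio estimator {estimator!r}")
    return PatientRatio(
        reporter=group.reporter, patient=patient, log_ratio=value, n_peptide_obs=len(obs)
    )


def patient_ratios(
    groups: Iterable[ProteinGroup],
    spectra: Sequence[ReporterSpectrum],
    design: StudyDesign,
    **kwargs,
) -> dict[str, list[PatientRatio]]:
    """Per-patient ratios for every group; reporter -> ratio list."""
    by_run: dict[str, dict[str, list[ReporterSpectrum]]] = defaultdict(
        lambda: defaultdict(list)
    )
    for s in spectra:
        by_run[s.run][s.peptide].append(s)
    out: dict[str, list[PatientRatio]] = {}
    for group in groups:
        ratios = []
        for patient in design.patients():
            run = design.primary_run(patient)
            r = protein_patient_ratio(group, by_run.get(run, {}), design, patient, **kwargs)
            if r is not None:
                ratios.append(r)
        if ratios:
            out[group.reporter] = ratios
    return out


def _one_sided_p(values: np.ndarray) -> float:
    """One-sided one-sample t-test p against 0, side chosen by the mean."""
    mean = values.mean()
    sd = values.std(ddof=1)
    if sd == 0:
        return 0.5 if mean == 0 else 0.0
    t, p_two = stats.ttest_1samp(values, 0.0)
    return float(p_two) / 2.0


def differential_test(
    ratios: Mapping[str, Sequence[PatientRatio]],
    min_ratios: int = 3,
    alpha: float = 0.05,
    fc_cutoff: float = 1.2,
    *,
    calibrated: bool = True,
) -> list[DifferentialResult]:
    """Per-protein one-sided t-test of patient log ratios against 0.

    The reported ``p_value`` is the one-sided p in the direction of the
    sample mean (half the two-sided p).  Because that direction is chosen
    from the data, flagging at the nominal ``alpha`` would double the
    realised type-I rate; with ``calibrated=True`` (default) a protein is
    significant when the directional p is below ``alpha / 2`` — i.e. the
    two-sided p is below ``alpha`` — keeping the error rate over both
    directions at ``alpha``.  ``calibrated=False`` compares the
    directional p to ``alpha`` literally.

    Proteins with fewer than ``min_ratios`` patient ratios are reported
    as untested (``p_value`` NaN, not significant).  ``passes_fc`` marks
    a mean fold change beyond ``fc_cutoff`` in either direction.
    """
    if min_ratios < 2:
        raise ValueError("min_ratios must be >= 2")
    log_cut = math.log2(fc_cutoff)
    threshold = alpha / 2 if calibrated else alpha
    results = []
    for reporter in sorted(ratios):
        values = np.array([r.log_ratio for r in ratios[reporter]])
        mean = float(values.mean())
        if len(values) < min_ratios:
            results.append(
                DifferentialResult(reporter, len(values), mean, float("nan"), False, False)
            )
            continue
        p = _one_sided_p(values)
        results.append(
            DifferentialResult(
                reporter=reporter,
                n_ratios=len(values),
                mean_log_ratio=mean,
                p_value=p,
                significant=p < threshold,
                passes_fc=abs(mean) > log_cut,
            )
        )
    return results


def stable_protein_subset(
    ratios: Mapping[str, Sequence[PatientRatio]], min_patients: int = 17
) -> set[str]:
    """Reporters with a ratio in at least ``min_patients`` patients."""
    return {
        reporter
        for reporter, rs in ratios.items()
        if len({r.patient for r in rs}) >= min_patients
    }
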