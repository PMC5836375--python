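"""Synthetic inputs with the statistical structure the analysis assumes.

The generators emulate the downstream-facing properties of a
CPLL-equalised effluent proteome measured by 2D-LC-MS with TMT 6-plex
labelling:

* a log-normal protein abundance spread whose upper range is occupied by
  plasma proteins (with overlap), and a consensus plasma concentration
  correlated with effluent abundance at a configurable level;
* PSM lists per search engine, with engine-specific score scales, decoy
  matches against a reversed database, and a matching rate of incorrect
  target matches so that decoy counting can be checked against the truth;
* extracted ion chromatograms whose peak areas scale linearly with true
  abundance;
* reporter intensity tables following a paired cross-over design
  (treated channel multiplied by ``2**effect``), with multiplicative
  log-normal noise and optional isotopic-impurity mixing that the
  correction step can round-trip.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from pdeproteome.identification import PSMRecord
from pdeproteome.study_design import StudyDesign, make_crossover_design
from pdeproteome.tmt_quant import ImpurityMatrix, ReporterSpectrum

__all__ = [
    "GroundTruth",
    "generate_ground_truth",
    "generate_psms",
    "generate_xics",
    "generate_tmt_experiment",
    "generate_annotation_db",
    "make_crossover_design",
    "ENGINE_SCORE_PARAMS",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Per-engine score distributions (normal location/scale); the two scales
#: differ roughly threefold, like the two engines' validation tiers.
ENGINE_SCORE_PARAMS: dict[str, dict[str, float]] = {
    "mascot": {"target_loc": 32.0, "target_scale": 9.0, "decoy_loc": 8.0, "decoy_scale": 4.0},
    "phenyx": {"target_loc": 11.0, "target_scale": 3.0, "decoy_loc": 2.5, "decoy_scale": 1.3},
}


@dataclass(frozen=True)
class Protein:
    accession: str
    entry_name: str
    true_abundance: float
    is_plasma: bool
    is_keratin_excludable: bool
    description: str


@dataclass
class GroundTruth:
    """Simulated proteome with known abundances, effects and annotations."""

    proteins: list[Protein]
    peptide_map: dict[str, list[str]]
    effect_map: dict[str, float]
    plasma_concentration: dict[str, float]

    #: peptide -> accessions carrying it (inverse of peptide_map)
    protein_of_peptide: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.protein_of_peptide:
            inv: dict[str, list[str]] = {}
            for acc, peps in self.peptide_map.items():
                for pep in peps:
                    inv.setdefault(pep, []).append(acc)
            self.protein_of_peptide = inv

    @property
    def accessions(self) -> list[str]:
        return [p.accession for p in self.proteins]

    @property
    def abundance(self) -> dict[str, float]:
        return {p.accession: p.true_abundance for p in self.proteins}

    @property
    def descriptions(self) -> dict[str, str]:
        return {p.accession: p.description for p in self.proteins}

    @property
    def all_peptides(self) -> set[str]:
        return {pep for peps in self.peptide_map.values() for pep in peps}


def _random_peptides(rng: np.random.Generator, n: int) -> list[str]:
    """Unique random tryptic-looking sequences (8-14 residues + K/R)."""
    out: set[str] = set()
    while len(out) < n:
        length = int(rng.integers(8, 15))
        body = "".join(rng.choice(AMINO_ACIDS, size=length))
        out.add(body + str(rng.choice(["K", "R"])))
    return sorted(out)


def generate_ground_truth(
    n_proteins: int = 600,
    plasma_fraction: float = 0.3,
    seed: int = 0,
    *,
    plasma_correlation: float = 0.6,
    effect_fraction: float = 0.1,
    effect_size: float = 0.5,
    peptides_per_protein: tuple[int, int] = (3, 9),
    shared_peptide_fraction: float = 0.05,
    n_keratins: int = 4,
) -> GroundTruth:
    """Simulate the proteome a CPLL-equalised effluent sample draws from.

    Abundances are log-normal (log10 sd ~0.8, a compressed plasma-like
    spread); the plasma subset sits one decade higher on average but
    overlaps the cellular proteins.  Plasma concentrations correlate with
    log abundance at ``plasma_correlation`` (a knob, not an assertion
    about real effluent).  Exactly ``round(effect_fraction * n)``
    proteins receive a true AlaGln log2 effect of +/- ``effect_size``
    (half up, half down); all others are null.
    """
    if n_proteins < 10:
        raise ValueError("n_proteins must be >= 10")
    if not 0.0 <= plasma_fraction <= 1.0:
        raise ValueError("plasma_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)

    n_plasma = int(round(n_proteins * plasma_fraction))
    is_plasma = np.zeros(n_proteins, dtype=bool)
    is_plasma[rng.choice(n_proteins, size=n_plasma, replace=False)] = True

    log_ab = rng.normal(5.0, 0.8, size=n_proteins)
    log_ab[is_plasma] += 1.0  # plasma subset occupies the upper decade, overlapping

    # concentrations exist only for the plasma subset, so the correlation
    # knob is defined (and standardised) within that subset
    rho = plasma_correlation
    if n_plasma >= 2:
        mu, sd = log_ab[is_plasma].mean(), log_ab[is_plasma].std()
    else:
        mu, sd = log_ab.mean(), max(log_ab.std(), 1e-12)
    z = (log_ab - mu) / max(sd, 1e-12)
    log_conc = rho * z + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal(size=n_proteins)

    proteins: list[Protein] = []
    keratin_idx = set(rng.choice(n_proteins, size=min(2 * n_keratins, n_proteins), replace=False))
    keratin_idx = sorted(keratin_idx)
    excludable = set(keratin_idx[:n_keratins])
    for i in range(n_proteins):
        acc = f"P{i + 10000:05d}"
        if i in excludable:
            desc = f"Keratin, type I cuticular Ha{i}"
            name = f"KRTC{i}_HUMAN"
        elif i in keratin_idx:
            desc = f"Keratin, type II cytoskeletal {i}"
            name = f"KRT{i}_HUMAN"
        else:
            desc = f"Synthetic effluent protein {i}"
            name = f"SYN{i}_HUMAN"
        proteins.append(
            Protein(
                accession=acc,
                entry_name=name,
                true_abundance=float(10.0 ** log_ab[i]),
                is_plasma=bool(is_plasma[i]),
                is_keratin_excludable=(i in excludable),
                description=desc,
            )
        )

    n_pep = rng.integers(peptides_per_protein[0], peptides_per_protein[1] + 1, size=n_proteins)
    pool = _random_peptides(rng, int(n_pep.sum()))
    rng.shuffle(pool)
    peptide_map: dict[str, list[str]] = {}
    cursor = 0
    for p, k in zip(proteins, n_pep):
        peptide_map[p.accession] = pool[cursor : cursor + int(k)]
        cursor += int(k)

    # A small fraction of peptides is shared by a second protein, so that
    # grouping and peptide uniqueness are exercised.
    n_shared = int(round(shared_peptide_fraction * len(pool)))
    for pep in rng.choice(pool, size=n_shared, replace=False):
        other = proteins[int(rng.integers(n_proteins))].accession
        if pep not in peptide_map[other]:
            peptide_map[other].append(str(pep))

    n_effect = int(round(effect_fraction * n_proteins))
    effect_map = {p.accession: 0.0 for p in proteins}
    hit = rng.choice(n_proteins, size=n_effect, replace=False)
    for j, i in enumerate(hit):
        effect_map[proteins[i].accession] = effect_size if j % 2 == 0 else -effect_size

    plasma_concentration = {
        proteins[i].accession: float(10.0 ** (1.5 + log_conc[i]))
        for i in range(n_proteins)
        if is_plasma[i]
    }
    return GroundTruth(
        proteins=proteins,
        peptide_map=peptide_map,
        effect_map=effect_map,
        plasma_concentration=plasma_concentration,
    )


def generate_psms(
    truth: GroundTruth,
    engine: str = "mascot",
    n_spectra: int = 4000,
    decoy_fraction: float = 0.3,
    seed: int = 0,
    *,
    ppm_shift: float = 4.0,
    rt_span: tuple[float, float] = (5.0, 60.0),
    rt_jitter: float = 0.05,
    database_size_factor: int = 15,
    score_params: dict[str, float] | None = None,
) -> list[PSMRecord]:
    """Simulate one engine's search of target + reversed databases.

    Each spectrum is a correct target match with probability
    ``1 - decoy_fraction``; otherwise it is a random match that hits the
    reversed (decoy) half of the concatenated database with probability
    1/2 and the target half with probability 1/2.  The searched database
    is ``database_size_factor`` times larger than the truly present
    proteome (a sequence collection always dwarfs one sample's
    detectable proteins), so random target matches mostly land on absent
    proteins — exactly mirroring the all-absent reversed half, which is
    what makes decoy counting estimate the false target matches
    one-to-one.  Scores come from engine-specific target/decoy normals;
    retention times are per-peptide with small jitter so that abundant
    peptides accumulate multiple PSMs; measured precursor m/z carries a
    uniform ``ppm_shift`` miscalibration relative to the theoretical m/z.
    """
    if engine not in ENGINE_SCORE_PARAMS:
        raise ValueError(f"unknown engine {engine!r}; known: {sorted(ENGINE_SCORE_PARAMS)}")
    if not 0.0 <= decoy_fraction <= 1.0:
        raise ValueError("decoy_fraction must be in [0, 1]")
    params = score_params or ENGINE_SCORE_PARAMS[engine]
    rng = np.random.default_rng(seed)

    peptides = sorted(truth.all_peptides)
    abund = truth.abundance
    weights = np.array(
        [sum(abund[a] for a in truth.protein_of_peptide[p]) for p in peptides]
    )
    weights = np.sqrt(weights)
    weights /= weights.sum()

    rt_base = {p: float(rng.uniform(*rt_span)) for p in peptides}
    mz_theo = {p: float(rng.uniform(400.0, 1200.0)) for p in peptides}

    if database_size_factor < 1:
        raise ValueError("database_size_factor must be >= 1")
    n_present = len(truth.accessions)
    n_database = n_present * database_size_factor

    records: list[PSMRecord] = []
    kind = rng.random(n_spectra)
    random_match = kind < decoy_fraction
    decoy_side = rng.random(n_spectra) < 0.5
    target_choice = rng.choice(len(peptides), size=n_spectra, p=weights)
    # random matches are database lookups, blind to abundance: a protein
    # slot is drawn uniformly from the searched database, identically for
    # the target and the reversed half
    random_slot = rng.integers(n_database, size=n_spectra)
    novel_counter = 0
    for i in range(n_spectra):
        sid = f"{engine}.{i:06d}"
        if not random_match[i]:
            pep = peptides[target_choice[i]]
            prots = tuple(sorted(truth.protein_of_peptide[pep]))
            score = float(rng.normal(params["target_loc"], params["target_scale"]))
            is_decoy = False
            rt = rt_base[pep] + float(rng.normal(0.0, rt_jitter))
            theo = mz_theo[pep]
        else:
            score = float(rng.normal(params["decoy_loc"], params["decoy_scale"]))
            rt = float(rng.uniform(*rt_span))
            theo = float(rng.uniform(400.0, 1200.0))
            slot = int(random_slot[i])
            if slot < n_present:
                src = truth.accessions[slot]
                src_pep = str(rng.choice(truth.peptide_map[src]))
                accs: tuple[str, ...] = tuple(
                    sorted(truth.protein_of_peptide[src_pep])
                )
                pep = src_pep[::-1]  # reversed sequence of a real peptide
            else:
                # an absent database protein with a sequence of its own
                accs = (f"DBP{slot:06d}",)
                pep = "".join(rng.choice(AMINO_ACIDS, size=11)) + "K"
            novel_counter += 1
            if decoy_side[i]:
                prots = tuple("DECOY_" + a for a in accs)
                is_decoy = True
            else:
                if slot < n_present:
                    # an incorrect peptide attributed to a present protein
                    pep = (
                        "".join(rng.choice(AMINO_ACIDS, size=10))
                        + f"X{seed}X{novel_counter}"
                    )
                prots = accs
                is_decoy = False
        mz = theo * (1.0 + (ppm_shift + float(rng.normal(0.0, 0.3))) * 1e-6)
        records.append(
            PSMRecord(
                spectrum_id=sid,
                peptide=pep,
                proteins=prots,
                engine=engine,
                score=score,
                retention_time=max(rt, 0.0),
                precursor_mz=mz,
                is_decoy=is_decoy,
                theoretical_mz=theo,
            )
        )
    return records


def generate_xics(
    truth: GroundTruth,
    psms: Sequence[PSMRecord],
    seed: int = 0,
    *,
    grid_step: float = 0.01,
    peak_sigma: float = 0.08,
    pad: float = 1.0,
    height_cv: float = 0.0,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-peptide chromatograms: one Gaussian peak near each PSM.

    Peak area is proportional to the summed true abundance of the
    peptide's proteins (times an optional log-normal factor of
    coefficient of variation ``height_cv``).  The time grid is uniform
    (``grid_step`` minutes) and strictly increasing.
    """
    rng = np.random.default_rng(seed)
    times_by_peptide: dict[str, list[float]] = {}
    for p in psms:
        if p.is_decoy:
            continue
        times_by_peptide.setdefault(p.peptide, []).append(p.retention_time)

    abund = truth.abundance
    sigma_ln = np.sqrt(np.log1p(height_cv**2)) if height_cv > 0 else 0.0
    traces: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for pep in sorted(times_by_peptide):
        rts = sorted(times_by_peptide[pep])
        base = sum(abund[a] for a in truth.protein_of_peptide.get(pep, []))
        if base == 0:
            continue
        t = np.arange(rts[0] - pad, rts[-1] + pad + grid_step, grid_step)
        y = np.zeros_like(t)
        for rt in rts:
            factor = float(np.exp(rng.normal(0.0, sigma_ln))) if sigma_ln else 1.0
            height = base * factor / (peak_sigma * np.sqrt(2 * np.pi))
            y += height * np.exp(-0.5 * ((t - rt) / peak_sigma) ** 2)
        traces[pep] = (t, y)
    return traces


def generate_tmt_experiment(
    truth: GroundTruth,
    design: StudyDesign,
    noise_cv: float = 0.1,
    seed: int = 0,
    *,
    impurity: ImpurityMatrix | None = None,
    detection_probability: float = 0.9,
) -> list[ReporterSpectrum]:
    """Reporter intensity tables for every run of a cross-over design.

    For each run, each peptide of each protein yields one MS2 spectrum
    with probability ``detection_probability``.  The channel intensity is

        ``true_abundance * 2**effect[if treated] * lognormal(noise_cv)``

    scaled by a per-spectrum ionisation factor common to all channels
    (it cancels in within-spectrum ratios).  When an ``impurity`` matrix
    is given the true channel vector is mixed by it, so the correction
    step can be round-tripped.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2)) if noise_cv > 0 else 0.0
    abund = truth.abundance

    peptides = sorted(truth.all_peptides)
    spectra: list[ReporterSpectrum] = []
    counter = 0
    for run in design.runs:
        cells = design.cells_in_run(run)
        for pep in peptides:
            owners = truth.protein_of_peptide[pep]
            base_control = sum(abund[a] for a in owners)
            # a shared peptide's treated signal mixes its owners' effects
            base_treated = sum(
                abund[a] * 2.0 ** truth.effect_map[a] for a in owners
            )
            if rng.random() > detection_probability:
                continue
            ionization = float(rng.lognormal(0.0, 0.3))
            v = np.zeros(6)
            for ch, cell in cells.items():
                level = base_treated if cell.treatment == "alagln" else base_control
                noise = float(np.exp(rng.normal(0.0, sigma))) if sigma else 1.0
                v[ch] = level * ionization * noise
            if impurity is not None:
                v = impurity.M @ v
            counter += 1
            spectra.append(
                ReporterSpectrum(
                    spectrum_id=f"tmt.{run}.{counter:06d}",
                    peptide=pep,
                    channel_intensity=v,
                    run=run,
                )
            )
    return spectra


def generate_annotation_db(
    accessions: Sequence[str],
    seed: int = 0,
    *,
    n_leaf_terms: int = 30,
    n_mid_terms: int = 5,
    term_size_range: tuple[int, int] = (10, 80),
    reference_size: int | None = None,
    spike_members: set[str] | None = None,
):
    """A three-level term DAG with random memberships and an optional spike.

    Leaf terms draw random member sets from ``accessions``; each leaf has
    one mid-level parent and all mids share a single root, so true-path
    propagation and most-specific-term reduction are exercised.  When
    ``spike_members`` is given, an extra leaf term ``GO:SPIKE`` carries
    exactly those members: a candidate list oversampling them is then
    enriched for that term by construction.
    """
    from pdeproteome.enrichment import AnnotationDB

    rng = np.random.default_rng(seed)
    accessions = list(accessions)
    lo, hi = term_size_range
    if hi > len(accessions):
        hi = len(accessions)
        lo = min(lo, hi)

    terms: dict[str, tuple[str, set[str]]] = {"GO:ROOT": ("biological process", set())}
    parents: dict[str, set[str]] = {}
    mids = [f"GO:M{i:03d}" for i in range(n_mid_terms)]
    for m in mids:
        terms[m] = (f"mid-level process {m}", set())
        parents[m] = {"GO:ROOT"}
    for i in range(n_leaf_terms):
        term = f"GO:L{i:03d}"
        size = int(rng.integers(lo, hi + 1))
        members = set(rng.choice(accessions, size=size, replace=False))
        terms[term] = (f"leaf process {i}", members)
        parents[term] = {str(rng.choice(mids))}
    if spike_members is not None:
        terms["GO:SPIKE"] = ("spiked enriched process", set(spike_members))
        parents["GO:SPIKE"] = {str(rng.choice(mids))}
    return AnnotationDB(
        terms=terms,
        parents=parents,
        reference_size=reference_size or len(accessions),
    )
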