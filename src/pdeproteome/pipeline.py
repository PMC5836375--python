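"""End-to-end orchestration: identify -> quantify -> differential -> compare -> enrich.

``run_full`` executes the five analysis stages on synthetic inputs (or on
tables supplied through the configured paths), writing each stage's
output as flat TSV/JSON into a run directory together with a summary
report of the counts at every gate and SHA-256 checksums of every file,
so a rerun with the same configuration and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from pdeproteome import abundance as ab
from pdeproteome import enrichment as en
from pdeproteome import io as pio
from pdeproteome import plasma_compare as pc
from pdeproteome import synthetic_data as synth
from pdeproteome import tmt_quant as tq
from pdeproteome.identification import (
    DEFAULT_THRESHOLDS,
    estimate_fdr,
    filter_keratins,
    merge_isoforms,
    validate_proteins,
)
from pdeproteome.study_design import make_crossover_design

__all__ = ["PipelineConfig", "run_full", "summarize_identifications"]


@dataclass
class PipelineConfig:
    """Knobs of a full synthetic run; defaults are the study conditions.

    20 patients in a two-period cross-over, 7 TMT 6-plex runs, two search
    engines with the published score tiers, candidate cutoffs FC > 1.2
    and p < 0.05 with 3..20 ratios per protein, 100 rank extremes per
    direction, and a 17-of-20-patients rule for the stably abundant
    subset.
    """

    seed: int = 0
    n_proteins: int = 600
    plasma_fraction: float = 0.3
    plasma_correlation: float = 0.6
    effect_fraction: float = 0.1
    effect_size: float = 0.5
    n_spectra_per_engine: int = 4000
    decoy_fraction: float = 0.3
    n_patients: int = 20
    noise_cv: float = 0.1
    alpha: float = 0.05
    fc_cutoff: float = 1.2
    min_ratios: int = 3
    max_ratios: int = 20
    n_extremes: int = 100
    min_patients_stable: int = 17
    min_observed: int = 1
    top3_unique_only: bool = False

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def summarize_identifications(
    per_run_reporters: Mapping[str, set[str]],
) -> dict:
    """Per-run counts plus the cumulative union curve in run order."""
    if not per_run_reporters:
        raise ValueError("at least one run is required")
    runs = list(per_run_reporters)
    per_run = {run: len(per_run_reporters[run]) for run in runs}
    seen: set[str] = set()
    cumulative = []
    for run in runs:
        seen |= per_run_reporters[run]
        cumulative.append(len(seen))
    return {"per_run": per_run, "cumulative": cumulative, "total": len(seen)}


def run_full(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage on synthetic data and write a run directory.

    Returns the summary dictionary (also written as ``summary.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    seeds = np.random.SeedSequence(config.seed).generate_state(8) % (2**31)
    summary: dict = {"seed": config.seed, "stage_seeds": [int(s) for s in seeds]}

    # ---- synthesis -------------------------------------------------------
    truth = synth.generate_ground_truth(
        n_proteins=config.n_proteins,
        plasma_fraction=config.plasma_fraction,
        seed=int(seeds[0]),
        plasma_correlation=config.plasma_correlation,
        effect_fraction=config.effect_fraction,
        effect_size=config.effect_size,
    )
    design = make_crossover_design(config.n_patients)
    design.to_yaml(out / "design.yaml")

    psms = {}
    for i, engine in enumerate(("mascot", "phenyx")):
        psms[engine] = synth.generate_psms(
            truth,
            engine=engine,
            n_spectra=config.n_spectra_per_engine,
            decoy_fraction=config.decoy_fraction,
            seed=int(seeds[1 + i]),
        )
        pio.write_psms(psms[engine], out / f"psms_{engine}.tsv")

    # ---- stage 1: identification ----------------------------------------
    targets = {e: [p for p in ps if not p.is_decoy] for e, ps in psms.items()}
    decoys = {e: [p for p in ps if p.is_decoy] for e, ps in psms.items()}
    target_groups = validate_proteins(targets, DEFAULT_THRESHOLDS)
    decoy_groups = validate_proteins(decoys, DEFAULT_THRESHOLDS)
    fdr = estimate_fdr(target_groups, decoy_groups)
    target_groups = merge_isoforms(
        filter_keratins(target_groups, truth.descriptions)
    )
    pio.write_groups(target_groups, out / "protein_groups.tsv")
    (out / "fdr_report.json").write_text(json.dumps(asdict(fdr), indent=2))
    summary["identification"] = {
        "n_groups": len(target_groups),
        "peptide_fdr": fdr.peptide_fdr,
        "protein_group_fdr": fdr.protein_group_fdr,
    }

    # ---- stage 2: Top3 abundance ----------------------------------------
    all_target_psms = [p for ps in targets.values() for p in ps]
    traces = synth.generate_xics(truth, all_target_psms, seed=int(seeds[3]))
    pio.write_xics(traces, out / "xics.tsv")
    psm_times: dict[str, list[float]] = {}
    for p in all_target_psms:
        psm_times.setdefault(p.peptide, []).append(p.retention_time)
    areas = {
        pep: ab.integrate_peptide_area(traces[pep], psm_times[pep], peptide=pep)
        for pep in traces
    }
    group_peptides = {
        g.reporter: set(g.unique_peptides if config.top3_unique_only else g.peptides)
        for g in target_groups
    }
    abundances = ab.top3_per_group(group_peptides, areas)
    pio.write_abundances(abundances, out / "abundance_top3.tsv")
    summary["abundance"] = {"n_quantified": len(abundances)}

    # ---- stage 3: TMT differential --------------------------------------
    spectra = synth.generate_tmt_experiment(
        truth, design, noise_cv=config.noise_cv, seed=int(seeds[4])
    )
    normalized = [
        s
        for run in design.runs
        for s in tq.normalize_channels([x for x in spectra if x.run == run])
    ]
    pio.write_reporters(normalized, out / "reporters.tsv")
    ratios = tq.patient_ratios(target_groups, normalized, design)
    results = tq.differential_test(
        ratios,
        min_ratios=config.min_ratios,
        alpha=config.alpha,
        fc_cutoff=config.fc_cutoff,
    )
    _write_differential(results, out / "differential.tsv")
    candidates = {
        r.reporter for r in results if r.significant and r.passes_fc
    }
    stable = tq.stable_protein_subset(ratios, config.min_patients_stable)
    summary["differential"] = {
        "n_tested": sum(1 for r in results if r.n_ratios >= config.min_ratios),
        "n_significant": sum(1 for r in results if r.significant),
        "n_candidates": len(candidates),
        "n_increased": sum(
            1 for r in results if r.reporter in candidates and r.mean_log_ratio > 0
        ),
        "n_decreased": sum(
            1 for r in results if r.reporter in candidates and r.mean_log_ratio < 0
        ),
        "n_stable": len(stable),
    }

    # ---- stage 4: plasma comparison -------------------------------------
    ref = truth.plasma_concentration
    pio.write_reference(ref, out / "plasma_reference.tsv")
    shared, pde_only, ref_only = pc.map_to_reference(abundances, ref)
    abundance_map = {a.reporter: a.abundance for a in abundances}
    r = pc.abundance_correlation(
        {a: abundance_map[a] for a in shared}, ref
    )
    comparisons = pc.compare_ranks(abundances, ref)
    n_each = min(config.n_extremes, len(comparisons) // 2)
    higher, lower = pc.select_rank_extremes(comparisons, n_each)
    summary["plasma_compare"] = {
        "n_shared": len(shared),
        "n_pde_only": len(pde_only),
        "n_ref_only": len(ref_only),
        "pearson_r_log": r,
        "n_each_extreme": n_each,
    }

    # ---- stage 5: enrichment --------------------------------------------
    rng = np.random.default_rng(int(seeds[5]))
    spike = set(
        rng.choice(sorted(higher), size=min(30, len(higher)), replace=False)
    ) if higher else None
    db = synth.generate_annotation_db(
        truth.accessions, seed=int(seeds[6]), spike_members=spike
    )
    db.to_tables(out / "annotations.tsv", out / "term_parents.tsv")
    tested = en.overrepresentation_test(higher, db, min_observed=config.min_observed)
    tested = en.bonferroni(tested, alpha=config.alpha)
    significant = {t.term for t in tested if t.significant}
    specific = en.most_specific_terms(significant, db)
    _write_enrichment(tested, specific, out / "enrichment.tsv")
    summary["enrichment"] = {
        "n_tested": len(tested),
        "n_significant": len(significant),
        "n_most_specific": len(specific),
    }

    per_run_reporters: dict[str, set[str]] = {}
    peptide_to_group = {
        pep: g.reporter for g in target_groups for pep in g.peptides
    }
    for run in design.runs:
        per_run_reporters[run] = {
            peptide_to_group[s.peptide]
            for s in normalized
            if s.run == run and s.peptide in peptide_to_group
        }
    summary["runs"] = summarize_identifications(per_run_reporters)

    checksums = {
        f.name: _sha256(f) for f in sorted(out.iterdir()) if f.name != "summary.json"
    }
    summary["checksums"] = checksums
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def _write_differential(results: Sequence[tq.DifferentialResult], path: Path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "reporter": [r.reporter for r in results],
            "n_ratios": [r.n_ratios for r in results],
            "mean_log2_ratio": [r.mean_log_ratio for r in results],
            "p_value": [r.p_value for r in results],
            "significant": [int(r.significant) for r in results],
            "passes_fc": [int(r.passes_fc) for r in results],
        }
    ).to_csv(path, sep="\t", index=False)


def _write_enrichment(
    results: Sequence[en.EnrichmentResult], specific: set[str], path: Path
) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "term": [r.term for r in results],
            "name": [r.name for r in results],
            "K": [r.K for r in results],
            "n": [r.n for r in results],
            "observed": [r.observed for r in results],
            "expected": [round(r.expected, 2) for r in results],
            "fold_enrichment": [round(r.fold, 2) for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_bonferroni": [r.p_corrected for r in results],
            "significant": [int(r.significant) for r in results],
            "most_specific": [int(r.term in specific) for r in results],
        }
    ).to_csv(path, sep="\t", index=False)
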