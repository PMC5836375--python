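"""Flat-file round trips for every stage's inputs and outputs.

All tables are plain TSV with documented headers so any single stage can
be run and inspected in isolation: PSM lists per engine, long-format
XIC traces, reporter intensity tables, protein groups, abundance tables
and the plasma reference.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from pdeproteome.abundance import Top3Abundance
from pdeproteome.identification import ProteinGroup, PSMRecord
from pdeproteome.tmt_quant import ReporterSpectrum

PROTEIN_SEP = ";"


def psms_to_frame(psms: Sequence[PSMRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "spectrum_id": [p.spectrum_id for p in psms],
            "peptide": [p.peptide for p in psms],
            "proteins": [PROTEIN_SEP.join(p.proteins) for p in psms],
            "engine": [p.engine for p in psms],
            "score": [p.score for p in psms],
            "retention_time": [p.retention_time for p in psms],
            "precursor_mz": [p.precursor_mz for p in psms],
            "theoretical_mz": [p.theoretical_mz for p in psms],
            "is_decoy": [int(p.is_decoy) for p in psms],
        }
    )


def frame_to_psms(df: pd.DataFrame) -> list[PSMRecord]:
    return [
        PSMRecord(
            spectrum_id=str(row.spectrum_id),
            peptide=str(row.peptide),
            proteins=tuple(str(row.proteins).split(PROTEIN_SEP)),
            engine=str(row.engine),
            score=float(row.score),
            retention_time=float(row.retention_time),
            precursor_mz=float(row.precursor_mz),
            is_decoy=bool(int(row.is_decoy)),
            theoretical_mz=None if pd.isna(row.theoretical_mz) else float(row.theoretical_mz),
        )
        for row in df.itertuples(index=False)
    ]


def write_psms(psms: Sequence[PSMRecord], path: str | Path) -> None:
    # %.17g keeps scores and masses exact through a write/read cycle
    psms_to_frame(psms).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_psms(path: str | Path) -> list[PSMRecord]:
    return frame_to_psms(pd.read_csv(path, sep="\t", float_precision="round_trip"))


def write_xics(
    traces: Mapping[str, tuple[np.ndarray, np.ndarray]], path: str | Path
) -> None:
    """Long format: one (peptide, time, intensity) row per sample point."""
    frames = [
        pd.DataFrame({"peptide": pep, "time": t, "intensity": y})
        for pep, (t, y) in sorted(traces.items())
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_xics(path: str | Path) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return {
        str(pep): (g["time"].to_numpy(), g["intensity"].to_numpy())
        for pep, g in df.groupby("peptide", sort=True)
    }


def write_reporters(spectra: Sequence[ReporterSpectrum], path: str | Path) -> None:
    rows = []
    for s in spectra:
        row = {"spectrum_id": s.spectrum_id, "peptide": s.peptide, "run": s.run}
        for ch in range(6):
            row[f"channel_{ch}"] = s.channel_intensity[ch]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_reporters(path: str | Path) -> list[ReporterSpectrum]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    chans = [f"channel_{ch}" for ch in range(6)]
    return [
        ReporterSpectrum(
            spectrum_id=str(row.spectrum_id),
            peptide=str(row.peptide),
            channel_intensity=np.array([getattr(row, c) for c in chans], dtype=float),
            run=str(row.run),
        )
        for row in df.itertuples(index=False)
    ]


def write_groups(groups: Sequence[ProteinGroup], path: str | Path) -> None:
    pd.DataFrame(
        {
            "reporter": [g.reporter for g in groups],
            "members": [PROTEIN_SEP.join(sorted(g.members)) for g in groups],
            "peptides": [PROTEIN_SEP.join(sorted(g.peptides)) for g in groups],
            "unique_peptides": [
                PROTEIN_SEP.join(sorted(g.unique_peptides)) for g in groups
            ],
            "n_peptides": [len(g.peptides) for g in groups],
            "n_unique": [len(g.unique_peptides) for g in groups],
        }
    ).to_csv(path, sep="\t", index=False)


def read_groups(path: str | Path) -> list[ProteinGroup]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, float_precision="round_trip")

    def split(s: str) -> frozenset[str]:
        return frozenset(x for x in str(s).split(PROTEIN_SEP) if x)

    return [
        ProteinGroup(
            reporter=str(row.reporter),
            members=split(row.members),
            peptides=split(row.peptides),
            unique_peptides=split(row.unique_peptides),
        )
        for row in df.itertuples(index=False)
    ]


def write_abundances(abundances: Sequence[Top3Abundance], path: str | Path) -> None:
    from pdeproteome.abundance import rank_abundances

    ranks = rank_abundances(abundances)
    pd.DataFrame(
        {
            "reporter": [a.reporter for a in abundances],
            "abundance": [a.abundance for a in abundances],
            "n_peptides_used": [a.n_peptides_used for a in abundances],
            "rank": [ranks[a.reporter] for a in abundances],
        }
    ).to_csv(path, sep="\t", index=False)


def read_abundances(path: str | Path) -> list[Top3Abundance]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        Top3Abundance(
            reporter=str(r.reporter),
            abundance=float(r.abundance),
            n_peptides_used=int(r.n_peptides_used),
        )
        for r in df.itertuples(index=False)
    ]


def write_reference(ref: Mapping[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"accession": list(ref), "mean_concentration": list(ref.values())}
    ).to_csv(path, sep="\t", index=False)


def read_reference(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return dict(zip(df["accession"].astype(str), df["mean_concentration"].astype(float)))
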