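"""Cross-over study design: mapping of TMT runs and channels to patients.

Each patient contributes two effluent samples — one dwell with standard
dialysis fluid (control) and one with AlaGln-supplemented fluid — and
both sit in the same 6-plex run so ratios are formed within a run.  The
default layout mirrors a 20-patient trial in 7 runs: runs 1-6 carry three
patients each (6 channels), run 7 carries the last two patients plus two
replicate channels that re-measure an earlier patient as an internal
quality control.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["ChannelCell", "StudyDesign", "make_crossover_design"]

TREATMENTS = ("control", "alagln")


@dataclass(frozen=True)
class ChannelCell:
    patient: str
    treatment: str
    is_replicate: bool = False

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}")


@dataclass
class StudyDesign:
    """Channels are indexed 0..5, corresponding to reporters 126..131."""

    runs: list[str]
    channel_assignment: dict[tuple[str, int], ChannelCell]

    def __post_init__(self) -> None:
        per_run: dict[str, int] = {}
        seen: dict[str, dict[str, str]] = {}
        for (run, ch), cell in self.channel_assignment.items():
            if run not in self.runs:
                raise ValueError(f"assignment references unknown run {run}")
            if not 0 <= ch <= 5:
                raise ValueError("channel index must be in 0..5")
            per_run[run] = per_run.get(run, 0) + 1
            if cell.is_replicate:
                continue
            runs_for = seen.setdefault(cell.patient, {})
            if cell.treatment in runs_for and runs_for[cell.treatment] != run:
                raise ValueError(
                    f"patient {cell.patient} has {cell.treatment} in two runs"
                )
            runs_for[cell.treatment] = run
        for patient, treatments in seen.items():
            if set(treatments) != set(TREATMENTS):
                raise ValueError(f"patient {patient} lacks one treatment")
            if len(set(treatments.values())) != 1:
                raise ValueError(f"patient {patient} split across runs")

    def patients(self) -> list[str]:
        """Patients with a primary (non-replicate) sample pair, sorted."""
        return sorted(
            {
                c.patient
                for c in self.channel_assignment.values()
                if not c.is_replicate
            }
        )

    def primary_run(self, patient: str) -> str:
        for (run, _), cell in self.channel_assignment.items():
            if cell.patient == patient and not cell.is_replicate:
                return run
        raise KeyError(f"unknown patient {patient}")

    def cells_in_run(self, run: str) -> dict[int, ChannelCell]:
        return {
            ch: cell
            for (r, ch), cell in self.channel_assignment.items()
            if r == run
        }

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "runs": list(self.runs),
            "channels": [
                {
                    "run": run,
                    "channel": ch,
                    "patient": cell.patient,
                    "treatment": cell.treatment,
                    "replicate": cell.is_replicate,
                }
                for (run, ch), cell in sorted(self.channel_assignment.items())
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyDesign":
        doc = yaml.safe_load(Path(path).read_text())
        assignment = {
            (row["run"], int(row["channel"])): ChannelCell(
                patient=row["patient"],
                treatment=row["treatment"],
                is_replicate=bool(row.get("replicate", False)),
            )
            for row in doc["channels"]
        }
        return cls(runs=list(doc["runs"]), channel_assignment=assignment)


def make_crossover_design(n_patients: int = 20, patients_per_run: int = 3) -> StudyDesign:
    """Default 7-run layout for 20 patients with two QC replicate channels.

    Patients are packed three per run (control/treated in adjacent
    channels).  When the last run is not full, its spare channels repeat
    the first patient's pair as replicates.
    """
    if n_patients < 1:
        raise ValueError("need at least one patient")
    patients = [f"patient{i + 1:02d}" for i in range(n_patients)]
    runs: list[str] = []
    assignment: dict[tuple[str, int], ChannelCell] = {}
    for start in range(0, n_patients, patients_per_run):
        run = f"run{len(runs) + 1}"
        runs.append(run)
        chunk = patients[start : start + patients_per_run]
        ch = 0
        for patient in chunk:
            assignment[(run, ch)] = ChannelCell(patient, "control")
            assignment[(run, ch + 1)] = ChannelCell(patient, "alagln")
            ch += 2
        # spare channels: replicate the first patient as internal QC
        while ch + 1 < 6 and len(chunk) < patients_per_run:
            assignment[(run, ch)] = ChannelCell(patients[0], "control", is_replicate=True)
            assignment[(run, ch + 1)] = ChannelCell(patients[0], "alagln", is_replicate=True)
            ch += 2
    return StudyDesign(runs=runs, channel_assignment=assignment)
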