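"""Shared tabular dataset container and plain-text IO.

A :class:`RelocationDataset` bundles the tables every pipeline stage
consumes: the long design table (one row per trial x face), a trial-level
table with per-trial eye-tracker calibration fields, the touch-response
table, and the fixation report.  Simulated datasets additionally carry a
ground-truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

__all__ = ["RelocationDataset", "SchemaError"]

TRIAL_KEY = ["participant_id", "trial_id"]

#: Calibration fields required on the trial table for exclusion handling.
CALIBRATION_COLUMNS = ["mean_calib_deg", "max_point_calib_deg", "precheck_deg"]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


def require_columns(df: pd.DataFrame, columns, table: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table is missing columns: {missing}")


@dataclass
class RelocationDataset:
    """All tables for one (real or simulated) relocation experiment.

    Attributes
    ----------
    design
        Long design table, one row per trial x face (shared across
        participants).
    trials
        One row per participant x trial: condition columns plus the
        calibration-error fields used by the exclusion rules.
    responses
        One final touch coordinate per participant x trial.
    fixations
        Parsed fixation report: per-fixation start/end times (ms, relative
        to encoding onset) and gaze coordinates (deg).
    truth
        Simulation-only ground truth (latent mixture branch, generative
        binding probability, recency flag); ``None`` for real data.
    """

    design: pd.DataFrame
    trials: pd.DataFrame
    responses: pd.DataFrame
    fixations: pd.DataFrame
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        require_columns(self.design, ["trial_id", "face_slot", "center_x_deg",
                                      "center_y_deg", "is_test_face"], "design")
        require_columns(self.trials, TRIAL_KEY, "trials")
        require_columns(self.responses, TRIAL_KEY + ["x_deg", "y_deg"],
                        "responses")
        require_columns(self.fixations, TRIAL_KEY + ["start_ms", "end_ms",
                                                     "x_deg", "y_deg"],
                        "fixations")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def subset(self, keep: pd.DataFrame) -> "RelocationDataset":
        """Restrict all participant x trial keyed tables to ``keep`` keys."""
        keys = keep[TRIAL_KEY].drop_duplicates()

        def _filter(df: pd.DataFrame | None) -> pd.DataFrame | None:
            if df is None:
                return None
            return df.merge(keys, on=TRIAL_KEY, how="inner")

        return replace(self, trials=_filter(self.trials),
                       responses=_filter(self.responses),
                       fixations=_filter(self.fixations),
                       truth=_filter(self.truth))

    def write(self, out_dir: str | Path) -> None:
        """Write all tables as CSV (fixations as TSV, fixation-report style)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.design.to_csv(out / "design.csv", index=False)
        self.trials.to_csv(out / "trials.csv", index=False)
        self.responses.to_csv(out / "responses.csv", index=False)
        self.fixations.to_csv(out / "fixations.tsv", sep="\t", index=False)
        if self.truth is not None:
            self.truth.to_csv(out / "truth.csv", index=False)

    @classmethod
    def read(cls, in_dir: str | Path) -> "RelocationDataset":
        src = Path(in_dir)
        truth_path = src / "truth.csv"
        return cls(
            design=pd.read_csv(src / "design.csv"),
            trials=pd.read_csv(src / "trials.csv"),
            responses=pd.read_csv(src / "responses.csv"),
            fixations=pd.read_csv(src / "fixations.tsv", sep="\t"),
            truth=pd.read_csv(truth_path) if truth_path.exists() else None,
        )
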