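"""Exclusion rules, safe-area accuracy, precision and swap-error scoring.

A relocation is *correct* when it lands within the 7-deg safe area of the
tested face's original center (inclusive boundary).  Incorrect responses
landing inside another encoded face's safe area are *swap* (mis-binding)
errors; everything else is a *random* error.  Because the minimum pairwise
center distance at encoding (14 deg) is exactly twice the safe radius, safe
areas never overlap and the classification is unambiguous except on the
measure-zero tangent point (resolved by a deterministic tie-break).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (CALIBRATION_COLUMNS, TRIAL_KEY, RelocationDataset,
                   SchemaError, require_columns)
from .design import TrialDesign
from .simulate import TouchResponse

__all__ = [
    "ExclusionThresholds",
    "ExclusionReport",
    "ScoredTrial",
    "apply_exclusions",
    "score_trial",
    "score_dataset",
    "summarize_performance",
]


@dataclass(frozen=True)
class ExclusionThresholds:
    """Trial-exclusion thresholds (all in degrees of visual angle).

    Trials are discarded when the average nine-point calibration error is at
    or above ``max_mean_calib_deg``, any single calibration point errs by
    ``max_point_calib_deg`` or more, the pre-trial check errs by
    ``max_precheck_deg`` or more, the trial-initial fixation falls outside
    ``start_fixation_radius_deg`` of the screen center, or the test face was
    never fixated during encoding.
    """

    max_mean_calib_deg: float = 0.5
    max_point_calib_deg: float = 1.0
    max_precheck_deg: float = 1.0
    start_fixation_radius_deg: float = 7.0

    def __post_init__(self) -> None:
        for name in ("max_mean_calib_deg", "max_point_calib_deg",
                     "max_precheck_deg", "start_fixation_radius_deg"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class ExclusionStep:
    rule: str
    n_before: int
    n_removed: int

    @property
    def pct_of_remaining(self) -> float:
        return 100.0 * self.n_removed / self.n_before if self.n_before else 0.0


@dataclass
class ExclusionReport:
    """Per-rule removal counts with sequential denominators.

    Percentages are relative to the data remaining when each rule was
    applied, matching how eye-tracking exclusions are conventionally
    reported.
    """

    steps: list[ExclusionStep] = field(default_factory=list)
    n_total: int = 0

    @property
    def n_removed(self) -> int:
        return sum(s.n_removed for s in self.steps)

    @property
    def pct_total(self) -> float:
        return 100.0 * self.n_removed / self.n_total if self.n_total else 0.0

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_removed": self.n_removed,
            "pct_total": self.pct_total,
            "steps": [{"rule": s.rule, "n_before": s.n_before,
                       "n_removed": s.n_removed,
                       "pct_of_remaining": s.pct_of_remaining}
                      for s in self.steps],
        }


def apply_exclusions(dataset: RelocationDataset,
                     thresholds: ExclusionThresholds = ExclusionThresholds(),
                     roi_margin_deg: float = 0.5
                     ) -> tuple[RelocationDataset, ExclusionReport]:
    """Apply the four trial-exclusion rules in order and report removals.

    Rules (sequential, each evaluated on the trials surviving the previous
    one): (1) calibration error, (2) pre-trial check error, (3) initial
    fixation outside the central region, (4) test face never fixated during
    encoding.  Threshold comparisons for rules 1-2 are inclusive (``>=``).
    """
    trials = dataset.trials
    require_columns(trials, CALIBRATION_COLUMNS, "trials")
    if "encoding_duration_s" not in trials.columns:
        raise SchemaError("trials table is missing encoding_duration_s")
    report = ExclusionReport(n_total=len(trials))

    def _drop(mask_excluded: pd.Series, rule: str,
              remaining: pd.DataFrame) -> pd.DataFrame:
        report.steps.append(ExclusionStep(rule, len(remaining),
                                          int(mask_excluded.sum())))
        return remaining.loc[~mask_excluded]

    rem = trials
    bad = ((rem["mean_calib_deg"] >= thresholds.max_mean_calib_deg)
           | (rem["max_point_calib_deg"] >= thresholds.max_point_calib_deg))
    rem = _drop(bad, "calibration", rem)

    bad = rem["precheck_deg"] >= thresholds.max_precheck_deg
    rem = _drop(bad, "precheck", rem)

    fx = dataset.fixations.sort_values(TRIAL_KEY + ["start_ms"])
    first = fx.groupby(TRIAL_KEY, as_index=False).first()
    first["start_dist"] = np.hypot(first["x_deg"], first["y_deg"])
    rem = rem.merge(first[TRIAL_KEY + ["start_dist"]], on=TRIAL_KEY, how="left")
    bad = rem["start_dist"] > thresholds.start_fixation_radius_deg
    bad = bad.fillna(False)
    rem = _drop(bad, "start_fixation", rem).drop(columns=["start_dist"])

    # rule 4: any encoding-window fixation inside the test-face ROI (+margin)
    test_faces = dataset.design.loc[dataset.design["is_test_face"],
                                    ["trial_id", "center_x_deg", "center_y_deg",
                                     "half_width_deg", "half_height_deg"]]
    fx = dataset.fixations.merge(test_faces, on="trial_id", how="left")
    enc = rem[TRIAL_KEY + ["encoding_duration_s"]]
    fx = fx.merge(enc, on=TRIAL_KEY, how="inner")
    in_window = ((fx["end_ms"] > 0)
                 & (fx["start_ms"] < fx["encoding_duration_s"] * 1000.0))
    on_test = (in_window
               & (np.abs(fx["x_deg"] - fx["center_x_deg"])
                  <= fx["half_width_deg"] + roi_margin_deg)
               & (np.abs(fx["y_deg"] - fx["center_y_deg"])
                  <= fx["half_height_deg"] + roi_margin_deg))
    hit = fx.loc[on_test, TRIAL_KEY].drop_duplicates()
    hit["__hit"] = True
    rem = rem.merge(hit, on=TRIAL_KEY, how="left")
    bad = rem["__hit"].isna()
    rem = _drop(bad, "test_face_unfixated", rem).drop(columns=["__hit"])

    return dataset.subset(rem), report


@dataclass(frozen=True)
class ScoredTrial:
    """Accuracy, precision and error classification of one trial."""

    trial_id: str
    correct: bool
    distance_deg: float
    log_distance: float  # ln of distance; NaN when distance == 0
    error_type: str  # correct | swap | random
    swap_slot: int | None = None
    swap_distance_deg: float | None = None


def score_trial(trial: TrialDesign, response: TouchResponse,
                safe_radius_deg: float = 7.0) -> ScoredTrial:
    """Score one relocation against its trial's encoded placements.

    The boundary is inclusive: a response exactly at the safe radius counts
    as inside.  On the (measure-zero) tangent point equidistant from two
    centers, the test face wins if it is one of them, otherwise the lowest
    face slot.
    """
    if trial.trial_id != response.trial_id:
        raise ValueError("trial and response must share trial_id")
    target = trial.test_placement
    d_target = math.hypot(response.x_deg - target.center_x_deg,
                          response.y_deg - target.center_y_deg)
    log_d = math.log(d_target) if d_target > 0 else math.nan
    if d_target <= safe_radius_deg:
        return ScoredTrial(trial.trial_id, True, d_target, log_d, "correct")
    best_slot, best_d = None, math.inf
    for p in trial.placements:
        if p.face_slot == trial.test_slot:
            continue
        d = math.hypot(response.x_deg - p.center_x_deg,
                       response.y_deg - p.center_y_deg)
        if d <= safe_radius_deg and d < best_d:
            best_slot, best_d = p.face_slot, d
    if best_slot is not None:
        return ScoredTrial(trial.trial_id, False, d_target, log_d, "swap",
                           best_slot, best_d)
    return ScoredTrial(trial.trial_id, False, d_target, log_d, "random")


def score_dataset(dataset: RelocationDataset,
                  safe_radius_deg: float = 7.0) -> pd.DataFrame:
    """Vectorized scoring of every response in a dataset.

    Returns one row per participant x trial with condition columns,
    ``correct``, ``distance_deg``, ``log_distance``, ``error_type``,
    ``swap_slot``, ``swap_distance_deg`` and the nearest-face accuracy
    variant ``nearest_is_target`` (correctness defined without the safe-area
    radius, purely by which original center is closest).
    """
    design = dataset.design
    wide = design.pivot_table(index="trial_id", columns="face_slot",
                              values=["center_x_deg", "center_y_deg"])
    trial_ids = wide.index.to_numpy()
    slots = sorted(design["face_slot"].unique())
    cx = wide["center_x_deg"].reindex(columns=slots).to_numpy()
    cy = wide["center_y_deg"].reindex(columns=slots).to_numpy()
    test_slot = (design.loc[design["is_test_face"]]
                 .set_index("trial_id")["face_slot"].reindex(wide.index)
                 .to_numpy())

    resp = dataset.responses.merge(
        pd.DataFrame({"trial_id": trial_ids,
                      "__row": np.arange(len(trial_ids))}),
        on="trial_id", how="left")
    rows = resp["__row"].to_numpy()
    dx = resp["x_deg"].to_numpy()[:, None] - cx[rows]
    dy = resp["y_deg"].to_numpy()[:, None] - cy[rows]
    dist = np.hypot(dx, dy)  # (n_resp, n_slots) with NaN for absent slots
    slot_arr = np.asarray(slots)
    tgt_col = np.searchsorted(slot_arr, test_slot[rows])
    d_target = dist[np.arange(len(resp)), tgt_col]

    correct = d_target <= safe_radius_deg
    non_target = dist.copy()
    non_target[np.arange(len(resp)), tgt_col] = np.nan
    with np.errstate(invalid="ignore"):
        within = non_target <= safe_radius_deg
    within[np.isnan(non_target)] = False
    any_swap = within.any(axis=1)
    masked = np.where(within, non_target, np.inf)
    nearest_col = masked.argmin(axis=1)
    swap_slot = np.where(~correct & any_swap, slot_arr[nearest_col], -1)
    swap_dist = np.where(~correct & any_swap,
                         masked[np.arange(len(resp)), nearest_col], np.nan)
    error_type = np.where(correct, "correct",
                          np.where(any_swap, "swap", "random"))
    with np.errstate(divide="ignore"):
        log_d = np.where(d_target > 0, np.log(np.maximum(d_target, 1e-300)),
                         np.nan)
    nearest_is_target = (np.nanargmin(
        np.where(np.isnan(dist), np.inf, dist), axis=1) == tgt_col)

    scored = resp[TRIAL_KEY].copy()
    scored["correct"] = correct
    scored["distance_deg"] = d_target
    scored["log_distance"] = log_d
    scored["error_type"] = error_type
    scored["swap_slot"] = swap_slot
    scored["swap_distance_deg"] = swap_dist
    scored["nearest_is_target"] = nearest_is_target
    cond_cols = [c for c in ("experiment", "load", "emotion", "maintenance_s")
                 if c in dataset.trials.columns]
    scored = scored.merge(dataset.trials[TRIAL_KEY + cond_cols], on=TRIAL_KEY,
                          how="left")
    return scored


def _mean_log_distance(d: np.ndarray) -> float:
    """Natural-log mean with zeros replaced by half the smallest positive d."""
    d = np.asarray(d, dtype=float)
    d = d[np.isfinite(d)]
    if len(d) == 0:
        return math.nan
    pos = d[d > 0]
    if len(pos) == 0:
        return math.nan
    floor = pos.min() / 2.0
    return float(np.log(np.where(d > 0, d, floor)).mean())


def summarize_performance(scored: pd.DataFrame,
                          by: list[str] | None = None,
                          sigma_hat: float | None = None,
                          safe_radius_deg: float = 7.0,
                          area: tuple[float, float] | None = None,
                          use_nearest: bool = False) -> pd.DataFrame:
    """Aggregate scored trials into per-condition performance summaries.

    Per group: accuracy (mean correct), mean/SE of relocation distance among
    correct trials (raw and natural-log), swap share of errors, swap-error
    precision and counts.  With ``use_nearest`` accuracy is the nearest-face
    variant (no safe-area constraint).  When ``sigma_hat`` is supplied the
    raw category proportions are corrected into generative mixture-weight
    estimates via the closed-form Gaussian capture probability (see
    :func:`facereloc.stats.recover_mixture`); otherwise raw proportions are
    reported.
    """
    acc_col = "nearest_is_target" if use_nearest else "correct"
    groups = scored.groupby(by, dropna=False) if by else [((), scored)]
    rows = []
    for key, grp in groups:
        if by and not isinstance(key, tuple):
            key = (key,)
        n = len(grp)
        corr = grp.loc[grp["error_type"] == "correct", "distance_deg"].to_numpy()
        n_swap = int((grp["error_type"] == "swap").sum())
        n_random = int((grp["error_type"] == "random").sum())
        n_err = n_swap + n_random
        row = dict(zip(by or [], key))
        row.update({
            "n_trials": n,
            "n_correct": int(len(corr)),
            "n_swap": n_swap,
            "n_random": n_random,
            "accuracy": float(grp[acc_col].mean()) if n else math.nan,
            "mean_distance_deg": float(corr.mean()) if len(corr) else math.nan,
            "se_distance_deg": (float(corr.std(ddof=1) / math.sqrt(len(corr)))
                                if len(corr) > 1 else math.nan),
            "mean_log_distance": _mean_log_distance(corr),
            "swap_share": n_swap / n_err if n_err else math.nan,
            "mean_swap_distance_deg": (
                float(grp["swap_distance_deg"].dropna().mean())
                if n_swap else math.nan),
            "is_empty": n == 0,
        })
        if sigma_hat is not None and n > 0:
            from .stats import recover_mixture
            k = int(round(float(grp["load"].mean()))) if "load" in grp else 4
            est = recover_mixture(
                {"correct": int((grp["error_type"] == "correct").sum()),
                 "swap": n_swap, "random": n_random},
                sigma_hat=sigma_hat, safe_radius_deg=safe_radius_deg,
                area=area, n_faces=k)
            row.update({"p_target_hat": est.p_target,
                        "p_swap_hat": est.p_swap,
                        "p_uniform_hat": est.p_uniform})
        rows.append(row)
    return pd.DataFrame(rows)
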