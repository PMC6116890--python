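"""Generative model for relocation responses and encoding scanpaths.

Responses follow a three-component mixture that mirrors how the scoring
stage classifies trials.  With probability

``p_bind = logistic(beta0 + beta_emotion * 1[happy] + beta_load * (load - 2)
+ beta_mi * ln(maintenance_s) + (beta_recency
+ beta_emotion_x_recency * 1[happy]) * 1[exited_last])``

the identity-location binding survives and the touch lands at the target
center plus isotropic Gaussian noise; otherwise the error is a *swap*
(a uniformly chosen non-target center plus noise) with probability
``p_swap_given_error``, or a uniform draw over the presentation area.

Scanpaths emulate a parsed fixation report: faces are visited in random
order with Poisson-distributed revisits, each visit comprising 1-3
log-normal fixations, truncated at encoding offset.  The recency flag fed
into the response model is *computed from the simulated scanpath*, so
exit-order effects downstream are reproducible by construction.

All default parameter values are artifact calibration choices (aggregate
accuracy ~0.73-0.85, swap share of errors ~0.8-0.9, mean fixation ~310 ms,
mean visit ~620 ms); they are not empirical estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import RelocationDataset
from .design import PRESENTATION_AREA_DEG, TrialDesign, design_to_frame

__all__ = [
    "ScanpathParams",
    "SimParams",
    "TouchResponse",
    "FixationRecord",
    "bind_probability",
    "simulate_response",
    "simulate_scanpath",
    "simulate_dataset",
]


@dataclass(frozen=True)
class ScanpathParams:
    """Parameters of the synthetic encoding scanpath and exclusion events.

    ``mean_fix_ms``/``sdlog_fix`` define a log-normal fixation-duration law
    (the mean is the arithmetic mean of the law).  ``revisit_rate`` is the
    Poisson mean of extra visits per face.  The three exclusion-event rates
    default to the per-rule data-loss levels typical of a well-calibrated
    eye-tracking session (fractions of trials, not percentages).
    """

    mean_fix_ms: float = 310.0
    sdlog_fix: float = 0.3
    revisit_rate: float = 0.8
    p_skip_face: float = 0.02
    p_calib_fail: float = 0.007
    p_precheck_fail: float = 0.014
    p_center_violation: float = 0.023
    saccade_gap_ms: float = 30.0

    def __post_init__(self) -> None:
        for name in ("revisit_rate", "p_skip_face", "p_calib_fail",
                     "p_precheck_fail", "p_center_violation"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p_skip_face", "p_calib_fail", "p_precheck_fail",
                     "p_center_violation"):
            if getattr(self, name) > 1:
                raise ValueError(f"{name} must be <= 1")
        if self.mean_fix_ms <= 0:
            raise ValueError("mean_fix_ms must be > 0")

    @property
    def mulog_fix(self) -> float:
        """Log-normal mu giving arithmetic mean ``mean_fix_ms``."""
        return math.log(self.mean_fix_ms) - self.sdlog_fix ** 2 / 2.0


@dataclass(frozen=True)
class SimParams:
    """Generative mixture and scanpath parameters.

    Logit-scale coefficients act on the binding probability; load is
    centered at 2 faces and maintenance enters as log-seconds, so ``beta0``
    is the binding logit for an angry load-2 trial at a 1-s interval whose
    test face was not the last exited.
    """

    beta0: float = 1.4
    beta_emotion: float = 0.25
    beta_load: float = -0.35
    beta_mi: float = -0.27
    beta_recency: float = 0.5
    beta_emotion_x_recency: float = 0.25
    sigma_target_deg: float = 2.0
    sigma_swap_deg: float = 2.5
    p_swap_given_error: float = 0.85
    gaze: ScanpathParams = field(default_factory=ScanpathParams)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_swap_given_error <= 1.0:
            raise ValueError("p_swap_given_error must be in [0, 1]")
        if self.sigma_target_deg < 0 or self.sigma_swap_deg < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass(frozen=True)
class TouchResponse:
    """Final relocation coordinate for one trial (with latent ground truth)."""

    trial_id: str
    x_deg: float
    y_deg: float
    latent_component: str = ""  # target | swap | uniform (simulation only)
    swap_slot: int | None = None


@dataclass(frozen=True)
class FixationRecord:
    """One parsed fixation, times in ms relative to encoding onset."""

    trial_id: str
    start_ms: float
    end_ms: float
    x_deg: float
    y_deg: float

    def __post_init__(self) -> None:
        if not self.end_ms > self.start_ms:
            raise ValueError("fixation must have positive duration")


def bind_probability(trial: TrialDesign, exited_last: bool,
                     params: SimParams) -> float:
    """Probability the identity-location binding survives to retrieval."""
    happy = 1.0 if trial.emotion == "happy" else 0.0
    last = 1.0 if exited_last else 0.0
    logit = (params.beta0
             + params.beta_emotion * happy
             + params.beta_load * (trial.load - 2)
             + params.beta_mi * math.log(trial.maintenance_s)
             + (params.beta_recency
                + params.beta_emotion_x_recency * happy) * last)
    # numerically stable logistic
    if logit >= 0:
        return 1.0 / (1.0 + math.exp(-logit))
    e = math.exp(logit)
    return e / (1.0 + e)


def _clip_to_area(x: float, y: float,
                  area: tuple[float, float]) -> tuple[float, float]:
    w, h = area
    return (min(max(x, -w / 2), w / 2), min(max(y, -h / 2), h / 2))


def simulate_response(trial: TrialDesign, exited_last: bool,
                      params: SimParams,
                      rng: np.random.Generator | int | None = None,
                      area: tuple[float, float] = PRESENTATION_AREA_DEG
                      ) -> TouchResponse:
    """Draw one relocation touch from the three-component mixture.

    Out-of-area draws are clipped to the presentation area rather than
    resampled so the mixture weights are preserved exactly.  Load-1 trials
    have no non-target faces, so their errors are always uniform.
    """
    if not trial.placements:
        raise ValueError("trial must have at least one placement")
    rng = np.random.default_rng(rng)
    p_bind = bind_probability(trial, exited_last, params)
    target = trial.test_placement
    if rng.random() < p_bind:
        x = target.center_x_deg + rng.normal(0.0, params.sigma_target_deg)
        y = target.center_y_deg + rng.normal(0.0, params.sigma_target_deg)
        x, y = _clip_to_area(x, y, area)
        return TouchResponse(trial.trial_id, x, y, "target")
    if trial.load > 1 and rng.random() < params.p_swap_given_error:
        others = [p for p in trial.placements if p.face_slot != trial.test_slot]
        chosen = others[rng.integers(len(others))]
        x = chosen.center_x_deg + rng.normal(0.0, params.sigma_swap_deg)
        y = chosen.center_y_deg + rng.normal(0.0, params.sigma_swap_deg)
        x, y = _clip_to_area(x, y, area)
        return TouchResponse(trial.trial_id, x, y, "swap", chosen.face_slot)
    w, h = area
    x = rng.uniform(-w / 2, w / 2)
    y = rng.uniform(-h / 2, h / 2)
    return TouchResponse(trial.trial_id, x, y, "uniform")


def _visit_sequence(n_faces: int, params: ScanpathParams,
                    rng: np.random.Generator) -> list[int]:
    """Random visit order: one first pass plus shuffled Poisson revisits."""
    faces = list(range(n_faces))
    if n_faces > 1 and params.p_skip_face > 0 and rng.random() < params.p_skip_face:
        faces.pop(rng.integers(n_faces))
    first_pass = rng.permutation(faces).tolist()
    extras: list[int] = []
    for f in faces:
        extras.extend([f] * int(rng.poisson(params.revisit_rate)))
    rng.shuffle(extras)
    seq = first_pass + extras
    # adjacent duplicates would merge into a single visit; collapse them
    collapsed = [seq[0]]
    for f in seq[1:]:
        if f != collapsed[-1]:
            collapsed.append(f)
    return collapsed


def simulate_scanpath(trial: TrialDesign, params: ScanpathParams,
                      rng: np.random.Generator | int | None = None
                      ) -> list[FixationRecord]:
    """Simulate the encoding scanpath as a list of fixation records.

    Gaze points are uniform inside the visited face's bounding rectangle;
    the sequence is truncated at encoding offset (the final fixation is
    clipped there), so all fixations lie within ``[0, encoding_duration]``.
    """
    if trial.encoding_duration_s <= 0:
        raise ValueError("encoding duration must be > 0")
    rng = np.random.default_rng(rng)
    enc_ms = trial.encoding_duration_s * 1000.0
    seq = _visit_sequence(len(trial.placements), params, rng)
    records: list[FixationRecord] = []
    t = float(rng.uniform(0.0, 50.0))  # first saccade lands shortly after onset
    mu = params.mulog_fix
    for face in seq:
        p = trial.placements[face]
        n_fix = int(rng.integers(1, 4))
        durs = rng.lognormal(mu, params.sdlog_fix, size=n_fix)
        xs = p.center_x_deg + rng.uniform(-p.half_width_deg, p.half_width_deg,
                                          size=n_fix)
        ys = p.center_y_deg + rng.uniform(-p.half_height_deg, p.half_height_deg,
                                          size=n_fix)
        for d, x, y in zip(durs, xs, ys):
            if t >= enc_ms - 1.0:
                return records
            end = min(t + float(d), enc_ms)
            records.append(FixationRecord(trial.trial_id, t, end,
                                          float(x), float(y)))
            t = end + params.saccade_gap_ms
    return records


def _exited_last(seq_records: list[FixationRecord], trial: TrialDesign,
                 roi_margin_deg: float = 0.5) -> bool:
    """Whether the test face holds the final visit of the scanpath."""
    if trial.load < 2 or not seq_records:
        return False
    last = seq_records[-1]
    p = trial.test_placement
    return (abs(last.x_deg - p.center_x_deg) <= p.half_width_deg + roi_margin_deg
            and abs(last.y_deg - p.center_y_deg) <= p.half_height_deg + roi_margin_deg)


def simulate_dataset(design: Sequence[TrialDesign], n_participants: int,
                     params: SimParams | None = None,
                     rng: np.random.Generator | int | None = None,
                     area: tuple[float, float] = PRESENTATION_AREA_DEG
                     ) -> RelocationDataset:
    """Simulate a full dataset: one response + scanpath per participant x trial.

    Per-trial calibration-error fields are drawn so that a configured
    fraction of trials violates each exclusion rule; a pre-trial central
    fixation (negative start time) carries the start-fixation check.  The
    ground-truth table records the latent mixture branch, the generative
    binding probability and the recency flag for every trial.
    """
    if not design:
        raise ValueError("design must be non-empty")
    params = params or SimParams()
    rng = np.random.default_rng(rng)
    g = params.gaze

    trial_rows, resp_rows, fix_rows, truth_rows = [], [], [], []
    for pi in range(n_participants):
        pid = f"p{pi:03d}"
        n = len(design)
        # calibration fields, vectorized per participant
        mean_calib = np.minimum(np.abs(rng.normal(0.25, 0.08, n)), 0.45)
        max_point = np.minimum(mean_calib * rng.uniform(1.2, 1.8, n), 0.95)
        calib_fail = rng.random(n) < g.p_calib_fail
        mean_calib[calib_fail] = rng.uniform(0.5, 0.9, calib_fail.sum())
        max_point[calib_fail] = rng.uniform(1.0, 1.8, calib_fail.sum())
        precheck = np.minimum(np.abs(rng.normal(0.3, 0.15, n)), 0.95)
        pre_fail = rng.random(n) < g.p_precheck_fail
        precheck[pre_fail] = rng.uniform(1.0, 2.0, pre_fail.sum())
        start_r = np.minimum(np.abs(rng.normal(1.0, 0.5, n)), 6.5)
        center_fail = rng.random(n) < g.p_center_violation
        start_r[center_fail] = rng.uniform(7.5, 12.0, center_fail.sum())
        start_phi = rng.uniform(0.0, 2 * np.pi, n)

        for ti, trial in enumerate(design):
            path = simulate_scanpath(trial, g, rng)
            last = _exited_last(path, trial)
            resp = simulate_response(trial, last, params, rng, area)
            trial_rows.append((pid, trial.trial_id, trial.experiment,
                               trial.load, trial.emotion, trial.maintenance_s,
                               trial.encoding_duration_s, trial.test_slot,
                               mean_calib[ti], max_point[ti], precheck[ti]))
            resp_rows.append((pid, trial.trial_id, resp.x_deg, resp.y_deg))
            sx = start_r[ti] * math.cos(start_phi[ti])
            sy = start_r[ti] * math.sin(start_phi[ti])
            fix_rows.append((pid, trial.trial_id, 0, -450.0, -50.0, sx, sy))
            for k, rec in enumerate(path, start=1):
                fix_rows.append((pid, trial.trial_id, k, rec.start_ms,
                                 rec.end_ms, rec.x_deg, rec.y_deg))
            truth_rows.append((pid, trial.trial_id, resp.latent_component,
                               bind_probability(trial, last, params), last,
                               resp.swap_slot))

    trials = pd.DataFrame(trial_rows, columns=[
        "participant_id", "trial_id", "experiment", "load", "emotion",
        "maintenance_s", "encoding_duration_s", "test_slot",
        "mean_calib_deg", "max_point_calib_deg", "precheck_deg"])
    responses = pd.DataFrame(resp_rows, columns=[
        "participant_id", "trial_id", "x_deg", "y_deg"])
    fixations = pd.DataFrame(fix_rows, columns=[
        "participant_id", "trial_id", "fix_index", "start_ms", "end_ms",
        "x_deg", "y_deg"])
    truth = pd.DataFrame(truth_rows, columns=[
        "participant_id", "trial_id", "latent_component", "p_bind",
        "exited_last", "swap_slot"])
    return RelocationDataset(design=design_to_frame(design), trials=trials,
                             responses=responses, fixations=fixations,
                             truth=truth)
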