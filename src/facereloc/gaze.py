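"""Fixation-to-ROI assignment and oculomotor measures.

A face's ROI is the smallest axis-aligned rectangle enclosing its oval,
expanded by a margin (default 0.5 deg) on all sides; a fixation belongs to a
face when its gaze point falls inside the expanded rectangle (inclusive).
A *visit* (entry) is a maximal run of consecutive fixations on the same
face.  Selection order ranks faces by the start of their first visit,
exit order by the end of their last visit; trials in which not every face
was fixated, or every face received only a single visit (selection and exit
orders then coincide), are flagged unusable for order analyses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import TRIAL_KEY, RelocationDataset
from .design import FacePlacement
from .simulate import FixationRecord

__all__ = [
    "GazeMeasures",
    "OrderValidity",
    "GazeOrderAssociation",
    "assign_fixations_to_rois",
    "compute_gaze_measures",
    "compute_orders",
    "kendall_tau",
    "gaze_table",
]

#: Off-face fixations shorter than this do not terminate a visit run.
MICRO_GAP_MS = 80.0


@dataclass(frozen=True)
class GazeMeasures:
    """Per-face oculomotor summary for one trial."""

    face_slot: int
    total_fix_ms: float
    mean_fix_ms: float
    mean_visit_ms: float
    n_visits: int
    selection_rank: int | None = None
    exit_rank: int | None = None


@dataclass(frozen=True)
class OrderValidity:
    """Usability flags for selection/exit order analyses."""

    all_faces_fixated: bool
    single_entry_per_face: bool

    @property
    def usable_for_order_analysis(self) -> bool:
        return self.all_faces_fixated and not self.single_entry_per_face


@dataclass(frozen=True)
class GazeOrderAssociation:
    """Kendall rank correlation between two order variables."""

    tau: float
    p_value: float
    n: int


def assign_fixations_to_rois(fixations: Sequence[FixationRecord] | pd.DataFrame,
                             placements: Sequence[FacePlacement],
                             margin_deg: float = 0.5) -> pd.DataFrame:
    """Label each fixation with the face ROI containing it (-1 = none).

    Under the default layout constraints expanded ROIs cannot overlap; if a
    custom configuration makes them overlap, a warning is issued and ties
    are broken by nearest face center.
    """
    if not placements:
        raise ValueError("placements must be non-empty")
    if isinstance(fixations, pd.DataFrame):
        df = fixations.copy()
    else:
        df = pd.DataFrame([{
            "trial_id": f.trial_id, "start_ms": f.start_ms, "end_ms": f.end_ms,
            "x_deg": f.x_deg, "y_deg": f.y_deg} for f in fixations])
    cx = np.array([p.center_x_deg for p in placements])
    cy = np.array([p.center_y_deg for p in placements])
    hw = np.array([p.half_width_deg + margin_deg for p in placements])
    hh = np.array([p.half_height_deg + margin_deg for p in placements])
    slots = np.array([p.face_slot for p in placements])

    x = df["x_deg"].to_numpy()[:, None]
    y = df["y_deg"].to_numpy()[:, None]
    inside = (np.abs(x - cx) <= hw) & (np.abs(y - cy) <= hh)
    n_hits = inside.sum(axis=1)
    if (n_hits > 1).any():
        warnings.warn("expanded ROIs overlap; breaking ties by nearest center",
                      stacklevel=2)
    dist = np.hypot(x - cx, y - cy)
    dist[~inside] = np.inf
    label = np.where(n_hits > 0, slots[dist.argmin(axis=1)], -1)
    df["face_slot"] = label
    return df


def _segment_visits(labels: np.ndarray, durations: np.ndarray,
                    micro_gap_ms: float = MICRO_GAP_MS) -> np.ndarray:
    """Visit id per fixation (-1 for off-face fixations).

    Off-face fixations shorter than ``micro_gap_ms`` are transparent: they
    neither belong to a visit nor terminate the surrounding run.
    """
    visit = np.full(len(labels), -1, dtype=int)
    current_face = None
    vid = -1
    for i, (lab, dur) in enumerate(zip(labels, durations)):
        if lab < 0:
            if dur >= micro_gap_ms:
                current_face = None
            continue
        if lab != current_face:
            vid += 1
            current_face = lab
        visit[i] = vid
    return visit


def compute_gaze_measures(labeled: pd.DataFrame,
                          display_window: tuple[float, float],
                          micro_gap_ms: float = MICRO_GAP_MS
                          ) -> list[GazeMeasures]:
    """Per-face fixation and visit statistics for one trial.

    ``total_fix_ms`` sums every on-face fixation; fixations starting before
    display onset or ending after display offset are excluded from
    ``mean_fix_ms``, and visits containing such fixations are excluded from
    ``mean_visit_ms``.  Faces never fixated are omitted.
    """
    df = labeled.sort_values("start_ms")
    labels = df["face_slot"].to_numpy()
    dur = (df["end_ms"] - df["start_ms"]).to_numpy(dtype=float)
    onset, offset = display_window
    in_window = ((df["start_ms"].to_numpy() >= onset)
                 & (df["end_ms"].to_numpy() <= offset))
    visit = _segment_visits(labels, dur, micro_gap_ms)

    out = []
    for face in sorted(set(labels[labels >= 0])):
        on = labels == face
        vids = np.unique(visit[on])
        visit_ok = [v for v in vids
                    if in_window[(visit == v)].all()]
        visit_durs = [dur[visit == v].sum() for v in visit_ok]
        fix_in = on & in_window
        out.append(GazeMeasures(
            face_slot=int(face),
            total_fix_ms=float(dur[on].sum()),
            mean_fix_ms=(float(dur[fix_in].mean()) if fix_in.any()
                         else math.nan),
            mean_visit_ms=(float(np.mean(visit_durs)) if visit_durs
                           else math.nan),
            n_visits=int(len(vids)),
        ))
    return out


def compute_orders(labeled: pd.DataFrame, test_slot: int, n_faces: int,
                   micro_gap_ms: float = MICRO_GAP_MS
                   ) -> tuple[dict[int, tuple[int, int]], OrderValidity]:
    """Selection and exit ranks per face, plus order-validity flags.

    Selection rank orders faces by the start time of their first visit, exit
    rank by the end time of their last visit; ties (identical timestamps)
    break by face slot.  All fixations count toward orders, including those
    straddling the display window.
    """
    if n_faces < 2:
        raise ValueError("order analysis requires at least 2 faces")
    df = labeled.sort_values("start_ms")
    labels = df["face_slot"].to_numpy()
    starts = df["start_ms"].to_numpy(dtype=float)
    ends = df["end_ms"].to_numpy(dtype=float)
    dur = ends - starts
    visit = _segment_visits(labels, dur, micro_gap_ms)

    faces = sorted(set(labels[labels >= 0]))
    first_start = {f: starts[labels == f].min() for f in faces}
    last_end = {f: ends[labels == f].max() for f in faces}
    n_visits = {f: len(np.unique(visit[labels == f])) for f in faces}

    sel_order = sorted(faces, key=lambda f: (first_start[f], f))
    exit_order = sorted(faces, key=lambda f: (last_end[f], f))
    ranks = {f: (sel_order.index(f) + 1, exit_order.index(f) + 1)
             for f in faces}
    validity = OrderValidity(
        all_faces_fixated=len(faces) == n_faces,
        single_entry_per_face=all(v == 1 for v in n_visits.values()),
    )
    return ranks, validity


def kendall_tau(selection_ranks: Sequence[float],
                exit_ranks: Sequence[float]) -> GazeOrderAssociation:
    """Kendall tau-b between paired per-trial order values.

    Uses the tie-corrected tau-b statistic with a two-sided p-value from the
    normal approximation; for fewer than 10 untied pairs the exact null
    distribution is used instead.
    """
    x = np.asarray(selection_ranks, dtype=float)
    y = np.asarray(exit_ranks, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired sequences must have equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 pairs for a rank correlation")
    has_ties = (len(np.unique(x)) < len(x)) or (len(np.unique(y)) < len(y))
    method = "exact" if (len(x) < 10 and not has_ties) else "asymptotic"
    res = sps.kendalltau(x, y, method=method)
    return GazeOrderAssociation(tau=float(res.statistic),
                                p_value=float(res.pvalue), n=len(x))


def gaze_table(dataset: RelocationDataset, margin_deg: float = 0.5,
               micro_gap_ms: float = MICRO_GAP_MS) -> pd.DataFrame:
    """Per participant x trial x face oculomotor measures for a dataset.

    Vectorized over the whole fixation table.  Returns one row per fixated
    face with total/mean fixation time, mean visit duration, visit count,
    selection and exit ranks, the order-validity flags, and for the tested
    face the ``exited_last`` recency indicator.
    """
    design = dataset.design
    rois = design[["trial_id", "face_slot", "center_x_deg", "center_y_deg",
                   "half_width_deg", "half_height_deg"]].rename(
        columns={"face_slot": "roi_slot"})
    rois = rois.assign(half_width_deg=rois["half_width_deg"] + margin_deg,
                       half_height_deg=rois["half_height_deg"] + margin_deg)

    fx = dataset.fixations.merge(rois, on="trial_id", how="left")
    inside = ((np.abs(fx["x_deg"] - fx["center_x_deg"]) <= fx["half_width_deg"])
              & (np.abs(fx["y_deg"] - fx["center_y_deg"])
                 <= fx["half_height_deg"]))
    fx = fx.loc[:, TRIAL_KEY + ["start_ms", "end_ms"]].assign(
        hit_slot=np.where(inside, fx["roi_slot"], -1))
    # collapse the per-ROI rows back to one row per fixation
    agg = (fx.groupby(TRIAL_KEY + ["start_ms", "end_ms"], sort=False)
           ["hit_slot"].max().reset_index())
    agg = agg.sort_values(TRIAL_KEY + ["start_ms"], kind="mergesort")

    labels = agg["hit_slot"].to_numpy(dtype=int)
    dur = (agg["end_ms"] - agg["start_ms"]).to_numpy(dtype=float)
    key_codes = pd.factorize(
        agg["participant_id"].astype(str) + "\x00" + agg["trial_id"].astype(str)
    )[0]
    new_key = np.empty(len(agg), dtype=bool)
    new_key[0] = True
    new_key[1:] = key_codes[1:] != key_codes[:-1]

    # visit segmentation with micro-gap tolerance, vectorized across trials
    visit = np.full(len(agg), -1, dtype=int)
    current = -2  # face of the open run; -2 = none
    vid = -1
    for i in range(len(agg)):
        if new_key[i]:
            current = -2
        lab = labels[i]
        if lab < 0:
            if dur[i] >= micro_gap_ms:
                current = -2
            continue
        if lab != current:
            vid += 1
            current = lab
        visit[i] = vid

    agg["face_slot"] = labels
    agg["dur_ms"] = dur
    agg["visit_id"] = visit
    on = agg.loc[agg["face_slot"] >= 0].copy()
    enc = dataset.trials.set_index(TRIAL_KEY)["encoding_duration_s"] * 1000.0
    on["offset_ms"] = enc.reindex(
        pd.MultiIndex.from_frame(on[TRIAL_KEY])).to_numpy()
    on["in_window"] = (on["start_ms"] >= 0) & (on["end_ms"] <= on["offset_ms"])

    visits = on.groupby(["visit_id"], sort=False).agg(
        participant_id=("participant_id", "first"),
        trial_id=("trial_id", "first"),
        face_slot=("face_slot", "first"),
        v_start=("start_ms", "min"),
        v_end=("end_ms", "max"),
        v_dur=("dur_ms", "sum"),
        v_in_window=("in_window", "all"),
    ).reset_index()

    per_face = on.groupby(TRIAL_KEY + ["face_slot"], sort=False).agg(
        total_fix_ms=("dur_ms", "sum"),
        n_fix=("dur_ms", "size"),
    ).reset_index()
    mean_fix = (on.loc[on["in_window"]]
                .groupby(TRIAL_KEY + ["face_slot"], sort=False)["dur_ms"]
                .mean().rename("mean_fix_ms").reset_index())
    vstats = visits.groupby(TRIAL_KEY + ["face_slot"], sort=False).agg(
        n_visits=("visit_id", "size"),
        first_visit_start=("v_start", "min"),
        last_visit_end=("v_end", "max"),
    ).reset_index()
    mean_visit = (visits.loc[visits["v_in_window"]]
                  .groupby(TRIAL_KEY + ["face_slot"], sort=False)["v_dur"]
                  .mean().rename("mean_visit_ms").reset_index())

    out = (per_face.merge(mean_fix, on=TRIAL_KEY + ["face_slot"], how="left")
           .merge(vstats, on=TRIAL_KEY + ["face_slot"], how="left")
           .merge(mean_visit, on=TRIAL_KEY + ["face_slot"], how="left"))

    out = out.sort_values(TRIAL_KEY + ["first_visit_start", "face_slot"],
                          kind="mergesort")
    out["selection_rank"] = out.groupby(TRIAL_KEY, sort=False).cumcount() + 1
    out = out.sort_values(TRIAL_KEY + ["last_visit_end", "face_slot"],
                          kind="mergesort")
    out["exit_rank"] = out.groupby(TRIAL_KEY, sort=False).cumcount() + 1

    grp = out.groupby(TRIAL_KEY, sort=False)
    n_fixated = grp["face_slot"].transform("size")
    out["n_faces_fixated"] = n_fixated
    load = dataset.trials.set_index(TRIAL_KEY)["load"]
    out["n_faces"] = load.reindex(
        pd.MultiIndex.from_frame(out[TRIAL_KEY])).to_numpy()
    out["all_faces_fixated"] = out["n_faces_fixated"] == out["n_faces"]
    out["single_entry_per_face"] = grp["n_visits"].transform(
        lambda v: (v == 1).all())
    out["usable_for_order_analysis"] = (out["all_faces_fixated"]
                                        & ~out["single_entry_per_face"])
    test_slot = dataset.trials.set_index(TRIAL_KEY)["test_slot"]
    out["is_test_face"] = out["face_slot"] == test_slot.reindex(
        pd.MultiIndex.from_frame(out[TRIAL_KEY])).to_numpy()
    # recency is only defined for multi-face displays
    out["exited_last"] = (out["is_test_face"] & (out["n_faces"] >= 2)
                          & (out["exit_rank"] == out["n_faces_fixated"]))
    return out.sort_values(TRIAL_KEY + ["face_slot"]).reset_index(drop=True)
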