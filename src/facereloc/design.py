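"""Constrained random layouts and counterbalanced trial designs.

The relocation task presents 1-4 expressive faces at pseudorandom screen
positions inside a central presentation area, subject to two geometric rules:

* the *edge* of every face must be at least 7 deg of visual angle from the
  screen center (so the centrally shown test face never overlaps an encoded
  location), and
* the *centers* of any two faces must be at least 14 deg apart, which both
  prevents crowding and guarantees that the 7-deg "safe areas" used by the
  scoring stage never overlap.

Layouts are drawn by uniform rejection sampling; trial lists are built per
condition cell (load x emotion for Experiment 1, maintenance interval x
emotion for Experiment 2) with identity assignment balanced by round-robin
and the test-face side of screen counterbalanced within participant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InfeasibleConstraintsError",
    "DesignConfigError",
    "LayoutConstraintSet",
    "FacePlacement",
    "TrialDesign",
    "ExperimentConfig",
    "DEFAULT_CONSTRAINTS",
    "FACE_HALF_WIDTH_DEG",
    "FACE_HALF_HEIGHT_DEG",
    "edge_clearance_deg",
    "sample_layout",
    "mirror_layout",
    "build_design",
    "design_to_frame",
    "trials_frame",
]

# Face stimuli subtend an oval of 3.70 x 5.19 deg (100 x 140 px); the printed
# degree values are taken as authoritative over the cm re-conversion.
FACE_HALF_WIDTH_DEG = 1.85
FACE_HALF_HEIGHT_DEG = 2.595

#: Central presentation area (1120 x 706 px) in degrees of visual angle.
PRESENTATION_AREA_DEG = (42.53, 26.81)


class InfeasibleConstraintsError(RuntimeError):
    """Layout constraints could not be satisfied by rejection sampling."""


class DesignConfigError(ValueError):
    """Experiment configuration cannot be counterbalanced as requested."""


@dataclass(frozen=True)
class LayoutConstraintSet:
    """Geometric constraints for encoding-display face placement.

    ``min_center_to_screen_center_deg`` applies to the face *edge* (bounding
    ellipse), not its center.  ``safe_radius_deg`` is half the minimum
    pairwise center distance, so safe areas are disjoint by construction.
    """

    min_center_to_screen_center_deg: float = 7.0
    min_pairwise_center_deg: float = 14.0
    presentation_area_deg: tuple[float, float] = PRESENTATION_AREA_DEG
    safe_radius_deg: float = 7.0

    def __post_init__(self) -> None:
        if self.safe_radius_deg != self.min_pairwise_center_deg / 2.0:
            raise ValueError(
                "safe_radius_deg must equal min_pairwise_center_deg / 2")
        w, h = self.presentation_area_deg
        if w <= 0 or h <= 0:
            raise ValueError("presentation area must be positive")


DEFAULT_CONSTRAINTS = LayoutConstraintSet()


@dataclass(frozen=True)
class FacePlacement:
    """One face's position and identity within an encoding display."""

    face_slot: int
    center_x_deg: float
    center_y_deg: float
    half_width_deg: float = FACE_HALF_WIDTH_DEG
    half_height_deg: float = FACE_HALF_HEIGHT_DEG
    identity_id: str = ""
    expression: str = "neutral"

    def __post_init__(self) -> None:
        if self.half_width_deg <= 0 or self.half_height_deg <= 0:
            raise ValueError("face half-extents must be > 0")


@dataclass(frozen=True)
class TrialDesign:
    """A single trial: condition, timing, placements and tested face."""

    trial_id: str
    experiment: int
    load: int
    emotion: str
    maintenance_s: float
    placements: tuple[FacePlacement, ...]
    test_slot: int
    version_id: str = "v00"
    mirrored: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.test_slot < len(self.placements):
            raise ValueError("test_slot must index an existing placement")
        if self.load != len(self.placements):
            raise ValueError("load must equal the number of placements")

    @property
    def encoding_duration_s(self) -> float:
        """Encoding display duration: 1.5 s per face."""
        return 1.5 * self.load

    @property
    def test_placement(self) -> FacePlacement:
        return self.placements[self.test_slot]


def edge_clearance_deg(x: float, y: float,
                       half_width_deg: float = FACE_HALF_WIDTH_DEG,
                       half_height_deg: float = FACE_HALF_HEIGHT_DEG) -> float:
    """Distance from the screen center to the face's bounding-ellipse edge.

    The ellipse radius is evaluated along the line connecting the screen
    center to the face center; the clearance is the center distance minus
    that radius (negative if the ellipse covers the screen center).
    """
    d = math.hypot(x, y)
    if d == 0.0:
        return -min(half_width_deg, half_height_deg)
    a, b = half_width_deg, half_height_deg
    r_edge = a * b * d / math.hypot(b * x, a * y)
    return d - r_edge


def _center_bounds(constraints: LayoutConstraintSet,
                   half_width: float, half_height: float) -> tuple[float, float]:
    w, h = constraints.presentation_area_deg
    xmax = w / 2.0 - half_width
    ymax = h / 2.0 - half_height
    if xmax <= 0 or ymax <= 0:
        raise InfeasibleConstraintsError(
            "face does not fit inside the presentation area")
    return xmax, ymax


def sample_layout(n_faces: int,
                  constraints: LayoutConstraintSet = DEFAULT_CONSTRAINTS,
                  rng: np.random.Generator | int | None = None,
                  half_width_deg: float = FACE_HALF_WIDTH_DEG,
                  half_height_deg: float = FACE_HALF_HEIGHT_DEG,
                  max_attempts: int = 10_000) -> list[FacePlacement]:
    """Draw a constraint-satisfying random layout of ``n_faces`` placements.

    Centers are drawn uniformly over the presentation area (shrunk so the
    whole face fits) and accepted if the edge rule and all pairwise distance
    rules hold; a stuck partial layout is restarted.  Deterministic given a
    seeded generator.

    Raises
    ------
    InfeasibleConstraintsError
        If ``max_attempts`` draws do not yield a valid layout; the message
        names the most frequently violated rule.
    """
    if not 1 <= n_faces <= 4:
        raise ValueError("n_faces must be between 1 and 4")
    rng = np.random.default_rng(rng)
    xmax, ymax = _center_bounds(constraints, half_width_deg, half_height_deg)
    if (n_faces >= 2
            and constraints.min_pairwise_center_deg > math.hypot(2 * xmax, 2 * ymax)):
        raise InfeasibleConstraintsError(
            f"min pairwise center distance {constraints.min_pairwise_center_deg} deg "
            f"exceeds the presentation-area diagonal available to face centers "
            f"({math.hypot(2 * xmax, 2 * ymax):.2f} deg): pairwise rule infeasible")

    centers: list[tuple[float, float]] = []
    violations = {"edge": 0, "pairwise": 0}
    stuck = 0
    for _ in range(max_attempts):
        x = rng.uniform(-xmax, xmax)
        y = rng.uniform(-ymax, ymax)
        if (edge_clearance_deg(x, y, half_width_deg, half_height_deg)
                < constraints.min_center_to_screen_center_deg):
            violations["edge"] += 1
            continue
        if any(math.hypot(x - cx, y - cy) < constraints.min_pairwise_center_deg
               for cx, cy in centers):
            violations["pairwise"] += 1
            stuck += 1
            if stuck >= 500:  # partial layout blocks the rest: restart
                centers.clear()
                stuck = 0
            continue
        centers.append((x, y))
        stuck = 0
        if len(centers) == n_faces:
            return [FacePlacement(face_slot=i, center_x_deg=cx, center_y_deg=cy,
                                  half_width_deg=half_width_deg,
                                  half_height_deg=half_height_deg)
                    for i, (cx, cy) in enumerate(centers)]
    worst = max(violations, key=violations.get)
    rule = ("edge-to-screen-center minimum distance" if worst == "edge"
            else "pairwise center minimum distance")
    raise InfeasibleConstraintsError(
        f"no valid {n_faces}-face layout in {max_attempts} attempts; "
        f"most violated rule: {rule}")


def mirror_layout(placements: Sequence[FacePlacement]) -> list[FacePlacement]:
    """Left/right reversal of a layout: negate x, preserve everything else."""
    return [replace(p, center_x_deg=-p.center_x_deg) for p in placements]


@dataclass(frozen=True)
class ExperimentConfig:
    """Factor structure of one experiment version.

    Experiment 1 crosses memory load (1-4 faces) with emotion at a fixed 1-s
    maintenance interval; Experiment 2 fixes load at 4 and crosses
    maintenance interval (1/3/6 s) with emotion.  ``reps_per_cell`` trials
    are generated per condition cell (default 32, giving the canonical 256
    and 192 trial totals).
    """

    experiment: int
    loads: tuple[int, ...] = (1, 2, 3, 4)
    maintenance_s: tuple[float, ...] = (1.0,)
    emotions: tuple[str, ...] = ("angry", "happy")
    reps_per_cell: int = 32
    n_identities: int = 8
    version_id: str = "v00"
    mirrored: bool = False
    constraints: LayoutConstraintSet = field(default_factory=LayoutConstraintSet)

    @classmethod
    def experiment_1(cls, reps_per_cell: int = 32, **kwargs) -> "ExperimentConfig":
        return cls(experiment=1, loads=(1, 2, 3, 4), maintenance_s=(1.0,),
                   reps_per_cell=reps_per_cell, **kwargs)

    @classmethod
    def experiment_2(cls, reps_per_cell: int = 32, **kwargs) -> "ExperimentConfig":
        return cls(experiment=2, loads=(4,), maintenance_s=(1.0, 3.0, 6.0),
                   reps_per_cell=reps_per_cell, **kwargs)

    @property
    def cells(self) -> list[tuple[int, float, str]]:
        return [(load, mi, emo)
                for load in self.loads
                for mi in self.maintenance_s
                for emo in self.emotions]

    @property
    def n_trials(self) -> int:
        return len(self.cells) * self.reps_per_cell


def build_design(config: ExperimentConfig,
                 rng: np.random.Generator | int | None = None
                 ) -> list[TrialDesign]:
    """Generate the full within-participant trial list for one version.

    Per condition cell, identity assignment uses a least-used round-robin so
    appearance counts per identity differ by at most one, and the side of
    screen the tested face occupies is counterbalanced (half left, half
    right, mirroring the sampled layout when needed).  Trial order is
    randomized across cells.  With ``config.mirrored`` the entire design is
    left/right reversed after generation, so trial *k* of a mirrored version
    matches trial *k* of the unmirrored version up to x negation.
    """
    if config.reps_per_cell % 2 != 0:
        raise DesignConfigError(
            "reps_per_cell must be even to counterbalance test-face side "
            f"(got {config.reps_per_cell})")
    rng = np.random.default_rng(rng)
    identities = [f"id{i:02d}" for i in range(config.n_identities)]

    trials: list[TrialDesign] = []
    for load, mi, emo in config.cells:
        if load > config.n_identities:
            raise DesignConfigError("load exceeds the number of identities")
        appear = dict.fromkeys(identities, 0)
        tested = dict.fromkeys(identities, 0)
        half = config.reps_per_cell // 2
        sides = rng.permutation(["L"] * half + ["R"] * half)
        for rep in range(config.reps_per_cell):
            placements = sample_layout(load, config.constraints, rng)
            # counterbalance which screen half holds the to-be-tested face
            side = sides[rep]
            want = (lambda x: x < 0) if side == "L" else (lambda x: x > 0)
            slots = [p.face_slot for p in placements if want(p.center_x_deg)]
            if not slots:
                placements = mirror_layout(placements)
                slots = [p.face_slot for p in placements if want(p.center_x_deg)]
            test_slot = int(rng.choice(slots))
            # least-used round-robin keeps per-cell appearance counts within 1
            order = rng.permutation(config.n_identities).tolist()
            chosen = sorted(order, key=lambda i: appear[identities[i]])[:load]
            chosen_ids = [identities[i] for i in chosen]
            test_identity = min(chosen_ids, key=lambda n: tested[n])
            others = [n for n in chosen_ids if n != test_identity]
            rng.shuffle(others)
            assignment: dict[int, str] = {test_slot: test_identity}
            free = [p.face_slot for p in placements if p.face_slot != test_slot]
            for slot, name in zip(free, others):
                assignment[slot] = name
            for name in chosen_ids:
                appear[name] += 1
            tested[test_identity] += 1
            placements = tuple(
                replace(p, identity_id=assignment[p.face_slot], expression=emo)
                for p in placements)
            trials.append(TrialDesign(
                trial_id="", experiment=config.experiment, load=load,
                emotion=emo, maintenance_s=mi, placements=placements,
                test_slot=test_slot, version_id=config.version_id,
                mirrored=config.mirrored))

    order = rng.permutation(len(trials))
    out: list[TrialDesign] = []
    for k, idx in enumerate(order):
        t = trials[idx]
        placements = t.placements
        if config.mirrored:
            placements = tuple(mirror_layout(placements))
        out.append(replace(t, trial_id=f"{config.version_id}-t{k:03d}",
                           placements=placements))
    return out


def design_to_frame(trials: Sequence[TrialDesign]) -> pd.DataFrame:
    """Long design table: one row per trial x face."""
    rows = []
    for t in trials:
        for p in t.placements:
            rows.append({
                "trial_id": t.trial_id,
                "experiment": t.experiment,
                "version_id": t.version_id,
                "mirrored": t.mirrored,
                "load": t.load,
                "emotion": t.emotion,
                "maintenance_s": t.maintenance_s,
                "encoding_duration_s": t.encoding_duration_s,
                "face_slot": p.face_slot,
                "identity_id": p.identity_id,
                "expression": p.expression,
                "center_x_deg": p.center_x_deg,
                "center_y_deg": p.center_y_deg,
                "half_width_deg": p.half_width_deg,
                "half_height_deg": p.half_height_deg,
                "is_test_face": p.face_slot == t.test_slot,
            })
    return pd.DataFrame(rows)


def trials_frame(trials: Sequence[TrialDesign]) -> pd.DataFrame:
    """Trial-level table (one row per trial)."""
    return pd.DataFrame([{
        "trial_id": t.trial_id,
        "experiment": t.experiment,
        "version_id": t.version_id,
        "mirrored": t.mirrored,
        "load": t.load,
        "emotion": t.emotion,
        "maintenance_s": t.maintenance_s,
        "encoding_duration_s": t.encoding_duration_s,
        "test_slot": t.test_slot,
    } for t in trials])


def frame_to_trials(design: pd.DataFrame) -> list[TrialDesign]:
    """Rebuild ``TrialDesign`` objects from a long design table."""
    trials = []
    for trial_id, grp in design.groupby("trial_id", sort=False):
        grp = grp.sort_values("face_slot")
        placements = tuple(FacePlacement(
            face_slot=int(r.face_slot), center_x_deg=float(r.center_x_deg),
            center_y_deg=float(r.center_y_deg),
            half_width_deg=float(r.half_width_deg),
            half_height_deg=float(r.half_height_deg),
            identity_id=str(r.identity_id), expression=str(r.expression),
        ) for r in grp.itertuples())
        test_slot = int(grp.loc[grp.is_test_face, "face_slot"].iloc[0])
        first = grp.iloc[0]
        trials.append(TrialDesign(
            trial_id=str(trial_id), experiment=int(first.experiment),
            load=int(first.load), emotion=str(first.emotion),
            maintenance_s=float(first.maintenance_s), placements=placements,
            test_slot=test_slot, version_id=str(first.version_id),
            mirrored=bool(first.mirrored)))
    return trials


def min_pairwise_distance(placements: Sequence[FacePlacement]) -> float:
    """Smallest center-to-center distance in a layout (inf for one face)."""
    if len(placements) < 2:
        return math.inf
    return min(math.hypot(a.center_x_deg - b.center_x_deg,
                          a.center_y_deg - b.center_y_deg)
               for a, b in combinations(placements, 2))
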