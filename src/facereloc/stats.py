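"""Contrast coding, mixed-effects modelling and permutation inference.

The analysis contract is lme4-style: binomial outcomes (accuracy, swap
indicator) and gaussian outcomes (log precision, log durations) are fit with
participant and trial-item random effects, uncorrelated intercepts and
slopes, and a stepwise simplification ladder applied on non-convergence
(highest-order slopes dropped first, trial terms simplified before
participant terms; the most complex converging model is reported).

Gaussian models use :class:`statsmodels` ``MixedLM``; binomial models use
the variational-Bayes ``BinomialBayesMixedGLM``, whose posterior means and
SDs are reported as coefficients and standard errors.  The terminal ladder
rung is a fixed-effects GLM/OLS with participant-clustered robust standard
errors.  A self-contained within-participant sign-flip permutation test is
provided as a backend-free alternative for two-level factors.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats as sps

from .design import PRESENTATION_AREA_DEG

__all__ = [
    "ContrastScheme",
    "ModelFit",
    "MixtureEstimate",
    "PermutationResult",
    "DegenerateDataError",
    "UnidentifiableError",
    "code_contrasts",
    "fit_mixed_model",
    "permutation_inference",
    "recover_mixture",
    "capture_probability",
    "estimate_sigma",
]


class DegenerateDataError(ValueError):
    """Outcome carries no information (constant, or too few groups)."""


class UnidentifiableError(ValueError):
    """Mixture correction is unidentifiable (capture probability ~ 0)."""


# ---------------------------------------------------------------------------
# contrast coding


@dataclass(frozen=True)
class ContrastScheme:
    """A centered factor coding: ``levels`` x (``levels`` - 1) matrix.

    ``sliding`` (repeated / backward-difference) coding estimates adjacent
    level-mean differences; ``simple`` coding compares each level against
    the first (reference) level.  Columns of either matrix sum to zero.
    """

    kind: str
    levels: tuple
    matrix: np.ndarray
    column_names: tuple[str, ...]

    def expand(self, values: pd.Series | np.ndarray) -> pd.DataFrame:
        """Map a factor column to its numeric contrast columns."""
        idx = {lv: i for i, lv in enumerate(self.levels)}
        rows = np.asarray([idx[v] for v in np.asarray(values)])
        return pd.DataFrame(self.matrix[rows], columns=list(self.column_names))


def code_contrasts(levels, kind: str = "sliding") -> ContrastScheme:
    """Build a sliding or simple contrast scheme for ordered factor levels."""
    levels = tuple(levels)
    k = len(levels)
    if k < 2:
        raise ValueError("need at least 2 levels")
    if len(set(levels)) != k:
        raise ValueError("duplicate levels")
    mat = np.zeros((k, k - 1))
    names = []
    if kind == "sliding":
        for j in range(1, k):
            mat[:j, j - 1] = -(k - j) / k
            mat[j:, j - 1] = j / k
            names.append(f"{levels[j]}-{levels[j - 1]}")
    elif kind == "simple":
        for j in range(1, k):
            mat[:, j - 1] = -1.0 / k
            mat[j, j - 1] = (k - 1.0) / k
            names.append(f"{levels[j]}-{levels[0]}")
    else:
        raise ValueError(f"unknown contrast kind {kind!r}")
    return ContrastScheme(kind, levels, mat, tuple(names))


# ---------------------------------------------------------------------------
# model fitting


@dataclass
class ModelFit:
    """Tidy fitted-model summary: per-term beta, SE, z/t and p."""

    terms: list[str]
    beta: dict[str, float]
    se: dict[str, float]
    stat: dict[str, float]
    p_value: dict[str, float]
    family: str
    random_structure: str
    converged: bool
    simplification_steps: list[str] = field(default_factory=list)
    backend: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms,
            "beta": [self.beta[t] for t in self.terms],
            "se": [self.se[t] for t in self.terms],
            "stat": [self.stat[t] for t in self.terms],
            "p_value": [self.p_value[t] for t in self.terms],
        })


def _safe_name(name: str) -> str:
    return re.sub(r"\W", "_", name)


def _expand_term(data: pd.DataFrame, term: str,
                 contrasts: dict[str, ContrastScheme]) -> pd.DataFrame:
    """Numeric columns for one fixed term (``a`` or interaction ``a:b``)."""
    parts = term.split(":")
    pieces: list[pd.DataFrame] = []
    for part in parts:
        if part not in data.columns:
            raise KeyError(f"unknown fixed term component {part!r}")
        col = data[part]
        if part in contrasts:
            scheme = contrasts[part]
        elif (col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype)
              or col.dtype == bool):
            scheme = code_contrasts(sorted(pd.unique(col)), "sliding")
        else:
            pieces.append(pd.DataFrame({part: col.to_numpy(dtype=float)},
                                       index=col.index))
            continue
        exp = scheme.expand(col)
        exp.columns = [f"{part}[{c}]" for c in exp.columns]
        pieces.append(exp.set_index(col.index))
    out = pieces[0]
    for nxt in pieces[1:]:
        prod = {}
        for a in out.columns:
            for b in nxt.columns:
                prod[f"{a}:{b}"] = out[a].to_numpy() * nxt[b].to_numpy()
        out = pd.DataFrame(prod, index=out.index)
    return out


def _ladder(random: dict[str, list[str]]) -> list[dict[str, list[str]]]:
    """Simplification sequence: trial slopes, participant slopes (highest
    order first), then trial intercept, participant intercept, then none."""
    rungs = [dict((g, list(t)) for g, t in random.items())]

    def _drop_next(spec):
        spec = {g: list(t) for g, t in spec.items()}
        order = list(spec)  # trial-like groups are simplified first if
        order.sort(key=lambda g: 0 if "trial" in g.lower() else 1)
        for g in order:  # slopes first
            slopes = [t for t in spec[g] if t != "1"]
            if slopes:
                spec[g] = [t for t in spec[g] if t != slopes[-1]]
                return spec, f"dropped random slope {slopes[-1]!r} for {g}"
        for g in order:  # then intercepts
            if "1" in spec[g]:
                spec[g] = []
                return spec, f"dropped random intercept for {g}"
        return None, None

    steps = []
    spec = rungs[0]
    while True:
        spec, msg = _drop_next(spec)
        if spec is None:
            break
        rungs.append(spec)
        steps.append(msg)
    return rungs, steps


def _describe(random: dict[str, list[str]]) -> str:
    parts = []
    for g, terms in random.items():
        if terms:
            parts.append(f"{g}: ({' + '.join(terms)})")
    return "; ".join(parts) if parts else "none (fixed effects only)"


def _fit_once(endog: np.ndarray, X: pd.DataFrame, data: pd.DataFrame,
              random: dict[str, list[str]], family: str,
              contrasts: dict[str, ContrastScheme]):
    """Fit one ladder rung; raise on any convergence problem."""
    frame = X.copy()
    frame["_y"] = endog
    for g in random:
        frame[g] = data[g].to_numpy()
    fixed_cols = list(X.columns)
    rhs = " + ".join(fixed_cols) if fixed_cols else "1"
    formula = f"_y ~ {rhs}"

    vc: dict[str, str] = {}
    for g, terms in random.items():
        for t in terms:
            if t == "1":
                vc[f"{_safe_name(g)}_icpt"] = f"0 + C({g})"
            else:
                if t not in frame.columns:
                    raise KeyError(f"random slope {t!r} is not a fixed column")
                vc[f"{_safe_name(g)}_{_safe_name(t)}"] = f"0 + C({g}):{t}"

    # singular (boundary) fits still count as converged, as in lme4 practice;
    # true optimizer failure is surfaced via the converged flag / finite SEs
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if not vc:
            cluster_col = next((g for g in random if "participant" in g),
                               next(iter(random), None)) if random else None
            groups = (pd.factorize(data[cluster_col])[0]
                      if cluster_col else None)
            exog = sm.add_constant(X.to_numpy(dtype=float)) \
                if fixed_cols else np.ones((len(endog), 1))
            if family == "binomial":
                model = sm.GLM(endog, exog, family=sm.families.Binomial())
            else:
                model = sm.OLS(endog, exog)
            if groups is not None:
                res = model.fit(cov_type="cluster", cov_kwds={"groups": groups})
            else:
                res = model.fit()
            params = np.asarray(res.params)
            bse = np.asarray(res.bse)
            names = ["Intercept"] + fixed_cols
            backend = "GLM-cluster" if family == "binomial" else "OLS-cluster"
        elif family == "gaussian":
            frame["_one"] = 1
            model = sm.MixedLM.from_formula(formula, groups="_one",
                                            re_formula="0", vc_formula=vc,
                                            data=frame)
            res = model.fit(reml=True, method="lbfgs", maxiter=200)
            if not res.converged:
                raise RuntimeError("MixedLM did not converge")
            params = np.asarray(res.fe_params)
            bse = np.asarray(res.bse_fe)
            names = list(res.model.exog_names)
            backend = "MixedLM"
        else:
            from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM
            model = BinomialBayesMixedGLM.from_formula(formula, vc, frame)
            res = model.fit_vb()
            k = model.k_fep
            params = np.asarray(res.fe_mean)
            bse = np.asarray(res.fe_sd)
            names = list(model.exog_names[:k])
            backend = "BinomialBayesMixedGLM-VB"
    if not (np.all(np.isfinite(params)) and np.all(np.isfinite(bse))
            and np.all(bse > 0)):
        raise RuntimeError("non-finite estimates or standard errors")
    return names, params, bse, backend


def fit_mixed_model(data: pd.DataFrame, outcome: str,
                    fixed: list[str],
                    random: dict[str, list[str]] | None = None,
                    family: str | None = None,
                    contrasts: dict[str, ContrastScheme] | None = None
                    ) -> ModelFit:
    """Fit a (generalized) linear mixed model with a simplification ladder.

    Parameters
    ----------
    data
        Long table with one row per trial; must contain the outcome, every
        fixed-term column and every random-grouping column.
    outcome
        Column name; binary outcomes get a binomial family, otherwise
        gaussian (override with ``family``).
    fixed
        Fixed-effect terms; categorical columns are expanded with sliding
        contrasts unless ``contrasts`` provides a scheme; ``"a:b"`` denotes
        an interaction.
    random
        Mapping of grouping column to random terms, e.g.
        ``{"participant_id": ["1", "emotion"], "trial_id": ["1"]}`` for
        uncorrelated intercepts and slopes.  Defaults to intercepts for
        ``participant_id`` and ``trial_id`` when present.
    """
    contrasts = contrasts or {}
    if random is None:
        random = {g: ["1"] for g in ("participant_id", "trial_id")
                  if g in data.columns}
    y = data[outcome].to_numpy()
    if np.unique(y[np.isfinite(y.astype(float))]).size < 2:
        raise DegenerateDataError(f"outcome {outcome!r} is constant")
    if family is None:
        vals = np.unique(y[~pd.isna(y)])
        family = "binomial" if set(np.asarray(vals, dtype=float)) <= {0.0, 1.0} \
            else "gaussian"
    keep = ~pd.isna(data[outcome])
    data = data.loc[keep].reset_index(drop=True)
    y = data[outcome].to_numpy(dtype=float)

    pieces = [_expand_term(data, t, contrasts) for t in fixed]
    X = pd.concat(pieces, axis=1) if pieces else pd.DataFrame(index=data.index)
    X.columns = [_safe_name(c) for c in X.columns]
    display = {}
    for piece in pieces:
        for c in piece.columns:
            display[_safe_name(c)] = c

    # random slopes are named by fixed term; map them to expanded columns
    random_expanded: dict[str, list[str]] = {}
    for g, terms in random.items():
        cols = []
        for t in terms:
            if t == "1":
                cols.append("1")
            else:
                exp = [_safe_name(c) for c in _expand_term(data, t, contrasts)]
                cols.extend(exp)
        random_expanded[g] = cols

    rungs, step_msgs = _ladder(random_expanded)
    steps_taken: list[str] = []
    last_err: Exception | None = None
    for i, rung in enumerate(rungs):
        try:
            names, params, bse, backend = _fit_once(y, X, data, rung, family,
                                                    contrasts)
        except Exception as err:  # noqa: BLE001 - ladder catches fit failures
            last_err = err
            if i < len(step_msgs):
                steps_taken.append(f"{step_msgs[i]} ({err})")
            continue
        pretty = [display.get(n, n) for n in names]
        stat = params / bse
        if family == "binomial" or backend != "MixedLM":
            p = 2.0 * sps.norm.sf(np.abs(stat))
        else:
            p = 2.0 * sps.norm.sf(np.abs(stat))
        return ModelFit(
            terms=pretty,
            beta=dict(zip(pretty, params.astype(float))),
            se=dict(zip(pretty, bse.astype(float))),
            stat=dict(zip(pretty, stat.astype(float))),
            p_value=dict(zip(pretty, p.astype(float))),
            family=family,
            random_structure=_describe(rung),
            converged=True,
            simplification_steps=steps_taken,
            backend=backend,
        )
    raise RuntimeError(f"no model converged, last error: {last_err}")


# ---------------------------------------------------------------------------
# permutation inference


@dataclass(frozen=True)
class PermutationResult:
    """Within-participant sign-flip permutation test result."""

    observed: float
    p_value: float
    n_perm: int
    n_participants: int


def permutation_inference(data: pd.DataFrame, outcome: str, factor: str,
                          n_perm: int = 1000,
                          rng: np.random.Generator | int | None = None,
                          levels: tuple | None = None) -> PermutationResult:
    """Paired sign-flip permutation test for a two-level within factor.

    The statistic is the mean over participants of the participant-level
    difference in mean outcome between the two factor levels.  The null is
    built by randomly flipping the sign of each participant's difference;
    the two-sided p-value is ``(1 + #{|null| >= |obs|}) / (1 + n_perm)``.
    """
    rng = np.random.default_rng(rng)
    if levels is None:
        levels = tuple(sorted(pd.unique(data[factor])))
    if len(levels) != 2:
        raise ValueError("permutation test requires exactly 2 factor levels")
    cell = (data.pivot_table(index="participant_id", columns=factor,
                             values=outcome, aggfunc="mean")
            .reindex(columns=list(levels)).dropna())
    if len(cell) < 2:
        raise DegenerateDataError("need at least 2 participants")
    diffs = (cell[levels[1]] - cell[levels[0]]).to_numpy()
    obs = float(diffs.mean())
    signs = rng.choice([-1.0, 1.0], size=(n_perm, len(diffs)))
    null = (signs * diffs).mean(axis=1)
    p = (1.0 + np.sum(np.abs(null) >= abs(obs) - 1e-12)) / (1.0 + n_perm)
    return PermutationResult(observed=obs, p_value=float(p), n_perm=n_perm,
                             n_participants=len(diffs))


# ---------------------------------------------------------------------------
# mixture recovery


def capture_probability(sigma_deg: float, safe_radius_deg: float = 7.0) -> float:
    """Mass of an isotropic bivariate Gaussian within ``safe_radius_deg``."""
    if sigma_deg < 0:
        raise ValueError("sigma must be >= 0")
    if sigma_deg == 0:
        return 1.0
    return 1.0 - math.exp(-safe_radius_deg ** 2 / (2.0 * sigma_deg ** 2))


@dataclass(frozen=True)
class MixtureEstimate:
    """Estimated generative mixture weights (sum to 1)."""

    p_target: float
    p_swap: float
    p_uniform: float


def recover_mixture(counts: dict[str, int] | pd.Series,
                    sigma_hat: float,
                    safe_radius_deg: float = 7.0,
                    area: tuple[float, float] | None = None,
                    n_faces: int = 4) -> MixtureEstimate:
    """Invert observed correct/swap/random proportions to mixture weights.

    The observed category probabilities are a known linear mixing of the
    generative weights: a target (or swap) draw is captured by its safe area
    with probability ``c = 1 - exp(-r^2 / (2 sigma^2))``, while a uniform
    draw leaks into each safe area with probability ``a = pi r^2 / A``
    (``A`` = presentation-area size).  Solving the 3 x 3 linear system (2 x 2
    for single-face displays, which admit no swaps) and renormalizing yields
    the weight estimates.
    """
    area = area or PRESENTATION_AREA_DEG
    c = capture_probability(sigma_hat, safe_radius_deg)
    if c < 1e-12:
        raise UnidentifiableError("capture probability is ~0; sigma too large")
    a = math.pi * safe_radius_deg ** 2 / (area[0] * area[1])
    n_corr = float(counts["correct"])
    n_swap = float(counts.get("swap", 0) if hasattr(counts, "get")
                   else counts["swap"])
    n_rand = float(counts["random"])
    total = n_corr + n_swap + n_rand
    if total == 0:
        raise DegenerateDataError("no scored trials")
    q = np.array([n_corr, n_swap, n_rand]) / total
    if n_faces < 2:
        m = np.array([[c, a], [1.0 - c, 1.0 - a]])
        w = np.linalg.solve(m, np.array([q[0], q[2]]))
        w = np.clip(w, 0.0, None)
        w = w / w.sum()
        return MixtureEstimate(float(w[0]), 0.0, float(w[1]))
    m = np.array([
        [c, 0.0, a],
        [0.0, c, (n_faces - 1) * a],
        [1.0 - c, 1.0 - c, 1.0 - n_faces * a],
    ])
    w = np.linalg.solve(m, q)
    w = np.clip(w, 0.0, None)
    s = w.sum()
    if s == 0:
        raise DegenerateDataError("mixture inversion degenerate")
    w = w / s
    return MixtureEstimate(float(w[0]), float(w[1]), float(w[2]))


def estimate_sigma(distances, safe_radius_deg: float = 7.0) -> float:
    """MLE of the target relocation noise SD from correct-trial distances.

    Models distances inside the safe area as a mixture of a radius-truncated
    Rayleigh (the isotropic Gaussian target component, scale ``sigma``) and
    a uniform-over-disc contaminant (uniform touches that happen to land in
    the safe area); returns the fitted ``sigma``.
    """
    d = np.asarray(distances, dtype=float)
    d = d[(d > 0) & (d <= safe_radius_deg)]
    if len(d) < 10:
        raise DegenerateDataError("need >= 10 positive distances")
    r = safe_radius_deg

    def nll(theta):
        log_sigma, logit_w = theta
        s = math.exp(log_sigma)
        w = 1.0 / (1.0 + math.exp(-logit_w))
        trunc = 1.0 - math.exp(-r ** 2 / (2.0 * s ** 2))
        f_t = d / s ** 2 * np.exp(-d ** 2 / (2.0 * s ** 2)) / trunc
        f_u = 2.0 * d / r ** 2
        return -np.log(w * f_t + (1.0 - w) * f_u + 1e-300).sum()

    start = np.array([math.log(max(np.sqrt(np.mean(d ** 2) / 2.0), 1e-3)), 2.0])
    res = optimize.minimize(nll, start, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8,
                                     "maxiter": 2000})
    return float(math.exp(res.x[0]))
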