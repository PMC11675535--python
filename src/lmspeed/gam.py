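"""Penalized additive models and AIC-based candidate comparison.

Three families of Gaussian additive candidates describe how response
properties change with stimulus speed:

* normalized directional response ``rn``:
  ``rn ~ (1|cell)``, ``rn ~ s(log2(speed))``, ``rn ~ s(log2(speed)) + (1|cell)``
* log2 time-to-peak ``log2_timep``: the two models above plus
  ``shape + s(log2(speed) * shape)`` with and without ``(1|cell)``
* phase peak activity ``activityp``:
  ``(1|cell)``, ``phase + s(log2(speed) * phase)``, and both together

``s`` is a penalized cubic B-spline smooth (basis dimension 10,
second-order difference penalty, sum-to-zero constrained against the
intercept, with a second shrinkage penalty on the penalty null space so a
spurious smooth can vanish entirely); ``(1|cell)`` is a random intercept
implemented as ridge-penalized group dummies -- the standard
random-effect basis of the additive framework.  Smoothing and ridge
parameters maximize the profiled Gaussian marginal likelihood, and
candidates are compared by marginal AIC with a delta-AIC < 2 parsimony
rule.  Model ranks, not absolute AIC values, are the meaningful output:
different penalized-regression backends produce different absolute
numbers for the same data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import null_space
from scipy.optimize import minimize

__all__ = [
    "ModelSpec",
    "FittedCandidate",
    "FitReport",
    "FAMILIES",
    "candidate_specs",
    "fit_candidates",
    "predict_curve",
    "simulate_candidate_data",
]

BASIS_DIM = 10
LOG_LAMBDA_BOUNDS = (-8.0, 12.0)  # searched on log10 scale


# ---------------------------------------------------------------------------
# design-matrix terms


class _SmoothTerm:
    """Centered cubic B-spline smooth of one covariate (P-spline penalty)."""

    def __init__(self, x: np.ndarray, k: int = BASIS_DIM):
        x = np.asarray(x, dtype=float)
        self.lo, self.hi = float(x.min()), float(x.max())
        if self.hi <= self.lo:
            raise ValueError("smooth covariate is constant")
        interior = np.linspace(self.lo, self.hi, k - 2)[1:-1]
        self.knots = np.concatenate(
            [[self.lo] * 4, interior, [self.hi] * 4]
        )
        B = self._raw(x)
        # sum-to-zero constraint: project out the direction confounded with
        # the intercept, leaving k-1 identifiable columns
        constraint = B.sum(axis=0, keepdims=True)
        self.Z = null_space(constraint)
        D = np.diff(np.eye(k), n=2, axis=0)
        self.S = self.Z.T @ (D.T @ D) @ self.Z
        # double-penalty shrinkage: a separate ridge on the penalty null
        # space (the leftover linear trend) lets a spurious smooth shrink
        # to zero entirely instead of keeping an unpenalized straight line
        N = null_space(self.S)
        self.S_null = N @ N.T

    def _raw(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self.lo, self.hi)
        return BSpline.design_matrix(x, self.knots, 3).toarray()

    def build(self, x: np.ndarray) -> np.ndarray:
        return self._raw(x) @ self.Z

    @property
    def width(self) -> int:
        return self.Z.shape[1]


class _RandomTerm:
    """Ridge-penalized group indicators: a random intercept per level."""

    def __init__(self, groups: Sequence):
        self.levels = sorted(set(groups))

    def build(self, groups: Sequence) -> np.ndarray:
        index = {g: i for i, g in enumerate(self.levels)}
        X = np.zeros((len(groups), len(self.levels)))
        for row, g in enumerate(groups):
            if g in index:  # unseen levels predict at the population mean
                X[row, index[g]] = 1.0
        return X

    @property
    def S(self) -> np.ndarray:
        return np.eye(len(self.levels))

    @property
    def width(self) -> int:
        return len(self.levels)


class _FactorTerm:
    """Unpenalized treatment-coded dummies (first level is reference)."""

    def __init__(self, values: Sequence):
        self.levels = sorted(set(values))

    def build(self, values: Sequence) -> np.ndarray:
        X = np.zeros((len(values), len(self.levels) - 1))
        index = {g: i for i, g in enumerate(self.levels)}
        for row, g in enumerate(values):
            i = index[g]
            if i > 0:
                X[row, i - 1] = 1.0
        return X

    @property
    def width(self) -> int:
        return len(self.levels) - 1


class _SmoothByTerm:
    """One centered smooth per factor level, sharing a single penalty."""

    def __init__(self, x: np.ndarray, values: Sequence, k: int = BASIS_DIM):
        self.smooth = _SmoothTerm(np.asarray(x, dtype=float), k=k)
        self.levels = sorted(set(values))

    def build(self, x: np.ndarray, values: Sequence) -> np.ndarray:
        base = self.smooth.build(x)
        blocks = []
        values = np.asarray(values)
        for level in self.levels:
            mask = (values == level).astype(float)[:, None]
            blocks.append(base * mask)
        return np.hstack(blocks)

    def _blockdiag(self, block: np.ndarray) -> np.ndarray:
        out = np.zeros((self.width, self.width))
        w = self.smooth.width
        for i in range(len(self.levels)):
            out[i * w : (i + 1) * w, i * w : (i + 1) * w] = block
        return out

    @property
    def S(self) -> np.ndarray:
        return self._blockdiag(self.smooth.S)

    @property
    def S_null(self) -> np.ndarray:
        return self._blockdiag(self.smooth.S_null)

    @property
    def width(self) -> int:
        return self.smooth.width * len(self.levels)


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class ModelSpec:
    """One candidate: response, additive terms, and a formula string."""

    response: str
    formula: str
    smooth: bool = False  # s(log2(speed))
    random_cell: bool = False  # (1|cell)
    factor: Optional[str] = None  # "shape" or "phase" main effect
    smooth_by: Optional[str] = None  # per-level smooths of log2(speed)


def _specs_rn() -> List[ModelSpec]:
    r = "rn"
    return [
        ModelSpec(r, "rn ~ (1|cell)", random_cell=True),
        ModelSpec(r, "rn ~ s(log2(speed))", smooth=True),
        ModelSpec(r, "rn ~ s(log2(speed)) + (1|cell)", smooth=True, random_cell=True),
    ]


def _specs_timep() -> List[ModelSpec]:
    r = "log2_timep"
    return [
        ModelSpec(r, "log2(timep) ~ (1|cell)", random_cell=True),
        ModelSpec(r, "log2(timep) ~ s(log2(speed))", smooth=True),
        ModelSpec(r, "log2(timep) ~ s(log2(speed)) + (1|cell)", smooth=True,
                  random_cell=True),
        ModelSpec(r, "log2(timep) ~ shape + s(log2(speed) * shape)",
                  factor="shape", smooth_by="shape"),
        ModelSpec(r, "log2(timep) ~ shape + s(log2(speed) * shape) + (1|cell)",
                  factor="shape", smooth_by="shape", random_cell=True),
    ]


def _specs_activityp() -> List[ModelSpec]:
    r = "activityp"
    return [
        ModelSpec(r, "activityp ~ (1|cell)", random_cell=True),
        ModelSpec(r, "activityp ~ phase + s(log2(speed) * phase)",
                  factor="phase", smooth_by="phase"),
        ModelSpec(r, "activityp ~ phase + s(log2(speed) * phase) + (1|cell)",
                  factor="phase", smooth_by="phase", random_cell=True),
    ]


FAMILIES: Dict[str, List[ModelSpec]] = {
    "rn": _specs_rn(),
    "timep": _specs_timep(),
    "activityp": _specs_activityp(),
}


def candidate_specs(family: str) -> List[ModelSpec]:
    try:
        return list(FAMILIES[family])
    except KeyError:
        raise KeyError(f"unknown family {family!r}; expected one of {sorted(FAMILIES)}")


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FittedCandidate:
    spec: ModelSpec
    beta: np.ndarray
    terms: dict
    lambdas: Dict[str, float]
    edf: float
    rss: float
    n: int
    r2: float
    rmse: float
    sigma: float
    aic: float
    residuals: np.ndarray
    cov: np.ndarray  # (X'X + S)^-1 * sigma^2
    x_range: Tuple[float, float]
    degenerate: bool = False


def _assemble(spec: ModelSpec, data: pd.DataFrame, terms: dict):
    """Design matrix, penalty blocks and column offsets for one candidate."""
    n = len(data)
    cols = [np.ones((n, 1))]
    penalized: List[Tuple[slice, np.ndarray, str]] = []
    offset = 1
    x = data["log2_speed"].to_numpy(dtype=float)
    if spec.factor is not None:
        X = terms["factor"].build(data[spec.factor])
        cols.append(X)
        offset += X.shape[1]
    if spec.smooth:
        X = terms["smooth"].build(x)
        sl = slice(offset, offset + X.shape[1])
        cols.append(X)
        penalized.append((sl, terms["smooth"].S, "smooth"))
        penalized.append((sl, terms["smooth"].S_null, "smooth_null"))
        offset += X.shape[1]
    if spec.smooth_by is not None:
        X = terms["smooth_by"].build(x, data[spec.smooth_by])
        sl = slice(offset, offset + X.shape[1])
        cols.append(X)
        penalized.append((sl, terms["smooth_by"].S, "smooth_by"))
        penalized.append((sl, terms["smooth_by"].S_null, "smooth_by_null"))
        offset += X.shape[1]
    if spec.random_cell:
        X = terms["random"].build(data["cell"])
        cols.append(X)
        penalized.append((slice(offset, offset + X.shape[1]), terms["random"].S, "random"))
        offset += X.shape[1]
    return np.hstack(cols), penalized


def _penalty_matrix(p: int, penalized, log10_lambdas) -> np.ndarray:
    S = np.zeros((p, p))
    for (sl, block, _), ll in zip(penalized, log10_lambdas):
        lam = 10.0 ** float(np.clip(ll, *LOG_LAMBDA_BOUNDS))
        S[sl, sl] += lam * block
    return S


def _solve(XtX, Xty, S):
    A = XtX + S
    try:
        beta = np.linalg.solve(A, Xty)
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        Ainv = np.linalg.pinv(A)
        beta = Ainv @ Xty
    return beta, Ainv


def _fit_one(spec: ModelSpec, data: pd.DataFrame, terms: dict) -> FittedCandidate:
    """Fit one candidate: penalties by marginal likelihood, marginal AIC.

    Penalized blocks (smooths, random intercepts) are treated as Gaussian
    random effects with variance sigma^2 / lambda; lambdas maximize the
    profiled marginal likelihood, which -- unlike GCV -- does not let a
    spurious nuisance term lower the criterion by absorbing noise.  The
    reported AIC is the marginal -2 log ML plus twice the parameter count
    (unpenalized coefficients, one variance parameter per penalty, and the
    residual variance).
    """
    y = data[spec.response].to_numpy(dtype=float)
    n = len(y)
    X, penalized = _assemble(spec, data, terms)
    p = X.shape[1]
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    pen_idx = sorted({i for sl, _, _ in penalized for i in range(p)[sl]})
    gram_zz = XtX[np.ix_(pen_idx, pen_idx)]

    def minus2_logml(log10_lambdas) -> float:
        S = _penalty_matrix(p, penalized, log10_lambdas)
        beta, _ = _solve(XtX, Xty, S)
        rss = max(yty - 2 * beta @ Xty + beta @ XtX @ beta, 1e-300)
        deviance = rss + float(beta @ S @ beta)
        if pen_idx:
            psi = S[np.ix_(pen_idx, pen_idx)]
            sign1, ld_post = np.linalg.slogdet(gram_zz + psi)
            sign2, ld_prior = np.linalg.slogdet(psi)
            if sign1 <= 0 or sign2 <= 0:
                return np.inf
        else:
            ld_post = ld_prior = 0.0
        sigma2 = deviance / n
        return n * math.log(2 * math.pi * sigma2) + n + ld_post - ld_prior

    if penalized:
        starts = [np.zeros(len(penalized)), np.full(len(penalized), 4.0)]
        fits = [
            minimize(minus2_logml, x0, method="Nelder-Mead",
                     options={"xatol": 1e-3, "fatol": 1e-8, "maxiter": 600})
            for x0 in starts
        ]
        best = min(fits, key=lambda f: f.fun)
        log10_lambdas = best.x
        m2ll = float(best.fun)
    else:
        log10_lambdas = np.array([])
        m2ll = float(minus2_logml(log10_lambdas))

    S = _penalty_matrix(p, penalized, log10_lambdas)
    beta, Ainv = _solve(XtX, Xty, S)
    fitted = X @ beta
    residuals = y - fitted
    rss = float(residuals @ residuals)
    edf = float(np.trace(Ainv @ XtX))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = max(0.0, 1.0 - rss / tss) if tss > 0 else 0.0
    rmse = math.sqrt(rss / n)
    resid_df = max(n - edf, 1e-6)
    sigma = math.sqrt(rss / resid_df)
    n_fixed = p - len(pen_idx)
    aic = m2ll + 2.0 * (n_fixed + len(penalized) + 1.0)
    degenerate = bool(resid_df < 1 or not np.isfinite(aic))
    if degenerate:
        warnings.warn(f"degenerate fit for {spec.formula!r}", stacklevel=2)
    lambdas = {
        name: 10.0 ** float(np.clip(ll, *LOG_LAMBDA_BOUNDS))
        for (_, _, name), ll in zip(penalized, log10_lambdas)
    }
    x = data["log2_speed"].to_numpy(dtype=float)
    return FittedCandidate(
        spec=spec, beta=beta, terms=terms, lambdas=lambdas, edf=edf, rss=rss,
        n=n, r2=r2, rmse=rmse, sigma=sigma, aic=aic, residuals=residuals,
        cov=Ainv * sigma**2, x_range=(float(x.min()), float(x.max())),
        degenerate=degenerate,
    )


@dataclass
class FitReport:
    family: str
    candidates: List[FittedCandidate]

    # candidates within this many AIC units of the minimum are treated as
    # equivalently supported, and the simplest of them is preferred (the
    # usual delta-AIC < 2 parsimony convention)
    AIC_EQUIVALENCE = 2.0

    @property
    def selected(self) -> FittedCandidate:
        aics = np.array([c.aic for c in self.candidates])
        return self.candidates[int(np.argmax(aics <= aics.min() + self.AIC_EQUIVALENCE))]

    def table(self) -> pd.DataFrame:
        best = self.selected
        rows = []
        for c in self.candidates:
            rows.append({
                "formula": c.spec.formula,
                "r2": round(c.r2, 4),
                "rmse": round(c.rmse, 4),
                "sigma": round(c.sigma, 4),
                "aic": round(c.aic, 2),
                "edf": round(c.edf, 2),
                "selected": c is best,
                "degenerate": c.degenerate,
            })
        return pd.DataFrame(rows)


def fit_candidates(data: pd.DataFrame, family: str) -> FitReport:
    """Fit every candidate of a family on the identical data subset.

    ``data`` needs columns ``log2_speed``, ``cell``, the family's response
    (``rn``, ``log2_timep`` or ``activityp``) and, where used, ``shape`` or
    ``phase``.  Rows with shape "unmodulated" are dropped for families with
    a shape term so that all candidates see the same rows.  Fits are exact
    re-runs: the same data give identical AIC values.
    """
    specs = candidate_specs(family)
    needed = {"log2_speed", "cell", specs[0].response}
    for spec in specs:
        needed |= {c for c in (spec.factor, spec.smooth_by) if c}
    missing = needed - set(data.columns)
    if missing:
        raise KeyError(f"data is missing columns {sorted(missing)}")
    data = data.dropna(subset=sorted(needed)).copy()
    if any(spec.factor == "shape" or spec.smooth_by == "shape" for spec in specs):
        data = data[data["shape"] != "unmodulated"]
    for col in ("shape", "phase"):
        if col in needed:
            counts = data[col].value_counts()
            thin = counts[counts < 3]
            if len(thin):
                warnings.warn(
                    f"factor {col!r} has levels with <3 observations: "
                    f"{dict(thin)}", stacklevel=2,
                )
    x = data["log2_speed"].to_numpy(dtype=float)
    terms: dict = {"random": _RandomTerm(data["cell"])}
    if any(s.smooth for s in specs):
        terms["smooth"] = _SmoothTerm(x)
    for spec in specs:
        if spec.factor:
            terms["factor"] = _FactorTerm(data[spec.factor])
        if spec.smooth_by:
            terms["smooth_by"] = _SmoothByTerm(x, data[spec.smooth_by])
    return FitReport(family=family, candidates=[_fit_one(s, data, terms) for s in specs])


def predict_curve(
    fitted: FittedCandidate,
    speed_grid: Sequence[float],
    level: Optional[str] = None,
) -> pd.DataFrame:
    """Population-level predictions with 95% intervals on a speed grid.

    Random intercepts are set to zero (the population mean); for models
    with a factor, ``level`` picks the level (default: reference level).
    Grid points beyond the fitted speed range are flagged as extrapolated.
    """
    spec = fitted.spec
    grid = np.asarray(speed_grid, dtype=float)
    x = np.log2(grid)
    frame = pd.DataFrame({"log2_speed": x})
    frame["cell"] = "__population__"  # unseen level -> zero random effect
    factor_col = spec.factor or spec.smooth_by
    if factor_col is not None:
        levels = fitted.terms["smooth_by" if spec.smooth_by else "factor"].levels
        frame[factor_col] = level if level is not None else levels[0]
        if frame[factor_col].iloc[0] not in levels:
            raise KeyError(f"unknown level {level!r} for factor {factor_col!r}")
    X, _ = _assemble(spec, frame, fitted.terms)
    mean = X @ fitted.beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, fitted.cov, X), 0.0))
    lo, hi = fitted.x_range
    return pd.DataFrame({
        "speed": grid,
        "mean": mean,
        "lower": mean - 1.96 * se,
        "upper": mean + 1.96 * se,
        "extrapolated": (x < lo) | (x > hi),
    })


# ---------------------------------------------------------------------------
# generative forms for selection-sanity experiments


def simulate_candidate_data(
    family: str,
    candidate_index: int,
    n: int = 500,
    n_cells: int = 50,
    seed: int = 0,
    noise_sd: float = 0.3,
    cell_sd: float = 0.6,
) -> pd.DataFrame:
    """Draw data from one candidate's own generative form.

    Speeds are sampled log-uniformly over 2-1,024 deg/s; cells are assigned
    cyclically; smooth effects are sinusoids of log2 speed with per-level
    amplitude, phase and offset for smooth-by-factor candidates.  Used to
    check that AIC recovers the generating candidate.
    """
    spec = candidate_specs(family)[candidate_index]
    rng = np.random.default_rng(seed)
    x = rng.uniform(1.0, 10.0, n)  # log2 of speed
    cells = np.array([f"c{i % n_cells:02d}" for i in range(n)])
    factor_col = spec.factor or spec.smooth_by
    data = pd.DataFrame({"log2_speed": x, "cell": cells})
    y = np.zeros(n)
    if factor_col is not None:
        levels = ("directional", "bidirectional", "omnidirectional") \
            if factor_col == "shape" else ("IT", "TR", "SS")
        values = np.array([levels[i % len(levels)] for i in range(n)])
        rng.shuffle(values)
        data[factor_col] = values
        amp = {lv: a for lv, a in zip(levels, (1.0, 0.5, 1.2))}
        phase = {lv: p for lv, p in zip(levels, (0.0, 1.5, 3.0))}
        offset = {lv: o for lv, o in zip(levels, (0.0, 0.8, -0.8))}
        for lv in levels:
            mask = values == lv
            y[mask] += offset[lv] + amp[lv] * np.sin(0.8 * x[mask] + phase[lv])
    elif spec.smooth:
        y += 0.9 * np.sin(0.8 * x)
    if spec.random_cell:
        effects = rng.normal(0.0, cell_sd, n_cells)
        index = {f"c{i:02d}": i for i in range(n_cells)}
        y += np.array([effects[index[c]] for c in cells])
    y += rng.normal(0.0, noise_sd, n)
    data[spec.response] = y
    if factor_col is None and any(
        s.factor or s.smooth_by for s in candidate_specs(family)
    ):
        # other candidates in the family still need the factor column
        col = "shape" if family == "timep" else "phase"
        levels = ("directional", "bidirectional", "omnidirectional") \
            if col == "shape" else ("IT", "TR", "SS")
        data[col] = np.array([levels[i % len(levels)] for i in range(n)])
    return data
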