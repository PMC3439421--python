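"""Maximum-entropy presence–background niche model.

The model is the classic Gibbs formulation: over the background cells
x_1..x_n the fitted density is

    q(x) = exp(Σ_j λ_j f_j(x)) / Z,      Z = Σ_i exp(Σ_j λ_j f_j(x_i)),

where the f_j are feature transforms of the covariates (linear, quadratic
and hinge, each affinely rescaled to [0, 1] on the background range).  The
weights minimize the L1-regularized negative mean presence log-density

    L(λ) = −(1/m) Σ_presences log q(x_p) + Σ_j β_j |λ_j|,

with per-feature penalties β_j = reg_multiplier · σ̂_j / √m (σ̂_j the
background standard deviation of feature j).  Equivalently: the maximum-
entropy distribution over the background whose feature expectations match
the presence sample means to within β_j.

Optimization is cyclic coordinate descent with soft-thresholding and
backtracking; the run is declared converged when the penalized objective
decreases by less than ``convergence_tol`` over a full cycle (default
1e-6, default iteration cap 500).

For display the raw density is passed through the logistic transform

    p(x) = τ e^H q(x) / (1 + τ e^H q(x)),

with H the entropy of the fitted background distribution and τ the assumed
prevalence of a "typical" presence site (default 0.5).  The transform is
strictly increasing in q, so cell rankings are identical on either scale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .environment import EnvStack, GridSpec
from .exceptions import FitError, ProjectionError

__all__ = [
    "FeatureBasis",
    "MaxentModel",
    "SuitabilitySurface",
    "build_features",
    "design_matrix",
    "maxent_objective",
    "fit_maxent",
    "project",
    "max_probability",
]

log = logging.getLogger(__name__)

#: floor for the background feature standard deviation entering β_j
SIGMA_FLOOR = 1e-3
#: floor for the coordinate-wise curvature estimate
HESSIAN_FLOOR = 1e-8


@dataclass(frozen=True)
class FeatureBasis:
    """One feature transform of one covariate.

    ``scale_min``/``scale_max`` are the background range of the covariate
    and anchor the affine rescaling to [0, 1]; hinge features additionally
    carry a knot inside that range and a direction.
    """

    kind: str  # "linear" | "quadratic" | "hinge"
    covariate: str
    scale_min: float
    scale_max: float
    knot: float | None = None
    direction: str | None = None  # "forward" | "reverse" (hinge only)

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "quadratic", "hinge"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "hinge":
            if self.knot is None or self.direction not in ("forward", "reverse"):
                raise ValueError("hinge features need a knot and a direction")
            if not self.is_degenerate and not (self.scale_min < self.knot < self.scale_max):
                raise ValueError("hinge knot must lie strictly inside the background range")
        elif self.knot is not None:
            raise ValueError("non-hinge features carry no knot")

    @property
    def is_degenerate(self) -> bool:
        """True for features built on a constant covariate (excluded from fits)."""
        return not self.scale_max > self.scale_min

    def evaluate(self, v: np.ndarray) -> np.ndarray:
        """Evaluate the feature on raw covariate values (vectorized)."""
        v = np.asarray(v, dtype=float)
        if self.is_degenerate:
            return np.zeros_like(v)
        if self.kind == "linear":
            return (v - self.scale_min) / (self.scale_max - self.scale_min)
        if self.kind == "quadratic":
            u = (v - self.scale_min) / (self.scale_max - self.scale_min)
            return u * u
        if self.direction == "forward":
            return np.maximum(0.0, (v - self.knot) / (self.scale_max - self.knot))
        return np.maximum(0.0, (self.knot - v) / (self.knot - self.scale_min))

    def label(self) -> str:
        if self.kind == "hinge":
            return f"hinge_{self.direction}({self.covariate}@{self.knot:g})"
        return f"{self.kind}({self.covariate})"


def build_features(
    stack: EnvStack,
    use_linear: bool = True,
    use_quadratic: bool = True,
    use_hinge: bool = True,
    hinge_knots: int = 10,
) -> list[FeatureBasis]:
    """Construct the feature basis from a training stack.

    Per covariate: one linear, one quadratic and ``2·hinge_knots`` hinge
    features (forward and reverse at equally spaced interior knots of the
    background range), as enabled.  Constant covariates yield degenerate
    features that are kept in the list but excluded from fitting.
    """
    if not (use_linear or use_quadratic or use_hinge):
        raise ValueError("at least one feature class must be enabled")
    features: list[FeatureBasis] = []
    for i, name in enumerate(stack.layer_names):
        vals = stack.values[i, stack.valid_mask]
        lo, hi = float(np.min(vals)), float(np.max(vals))
        if not hi > lo:
            log.warning("covariate %r is constant on the training region; "
                        "its features are degenerate and will not be fitted", name)
            if use_linear:
                features.append(FeatureBasis("linear", name, lo, hi))
            if use_quadratic:
                features.append(FeatureBasis("quadratic", name, lo, hi))
            continue
        if use_linear:
            features.append(FeatureBasis("linear", name, lo, hi))
        if use_quadratic:
            features.append(FeatureBasis("quadratic", name, lo, hi))
        if use_hinge:
            knots = lo + (hi - lo) * np.arange(1, hinge_knots + 1) / (hinge_knots + 1)
            for k in knots:
                features.append(
                    FeatureBasis("hinge", name, lo, hi, knot=float(k), direction="forward")
                )
                features.append(
                    FeatureBasis("hinge", name, lo, hi, knot=float(k), direction="reverse")
                )
    return features


def design_matrix(features: list[FeatureBasis], table: pd.DataFrame) -> np.ndarray:
    """Feature matrix (n_rows × n_features) from a covariate table."""
    cols = []
    for feat in features:
        if feat.covariate not in table.columns:
            raise ProjectionError(f"covariate table lacks layer {feat.covariate!r}")
        cols.append(feat.evaluate(table[feat.covariate].to_numpy(dtype=float)))
    return np.column_stack(cols) if cols else np.empty((len(table), 0))


def maxent_objective(
    lam: np.ndarray, X_presence: np.ndarray, X_background: np.ndarray, beta: np.ndarray
) -> float:
    """Penalized objective L(λ) — exposed for tests and brute-force oracles."""
    s_bg = X_background @ lam
    log_z = logsumexp(s_bg)
    nll = -float(np.mean(X_presence @ lam)) + float(log_z)
    return nll + float(np.abs(lam) @ beta)


@dataclass
class MaxentModel:
    """A fitted maximum-entropy model."""

    features: list[FeatureBasis]
    weights: np.ndarray
    reg_weights: np.ndarray
    log_normalizer: float
    entropy: float
    tau: float = 0.5
    converged: bool = False
    iterations_used: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.reg_weights = np.asarray(self.reg_weights, dtype=float)
        if not (len(self.features) == self.weights.size == self.reg_weights.size):
            raise ValueError("features, weights and reg_weights must align")
        if self.entropy < 0:
            raise ValueError("entropy of a discrete distribution cannot be negative")

    # -- evaluation helpers -------------------------------------------------
    def covariate_ranges(self) -> dict[str, tuple[float, float]]:
        """Background range of each covariate the model uses (for clamping)."""
        out: dict[str, tuple[float, float]] = {}
        for feat in self.features:
            lo, hi = out.get(feat.covariate, (np.inf, -np.inf))
            out[feat.covariate] = (min(lo, feat.scale_min), max(hi, feat.scale_max))
        return out

    def linear_score(self, table: pd.DataFrame) -> np.ndarray:
        """Σ_j λ_j f_j(x) for each row of a covariate table."""
        return design_matrix(self.features, table) @ self.weights

    def raw_density(self, table: pd.DataFrame) -> np.ndarray:
        """q(x) renormalized over the rows of ``table``."""
        s = self.linear_score(table)
        return np.exp(s - logsumexp(s))

    def logistic_from_raw(self, q: np.ndarray) -> np.ndarray:
        """Logistic suitability p = τ e^H q / (1 + τ e^H q)."""
        r = self.tau * np.exp(self.entropy) * np.asarray(q, dtype=float)
        return r / (1.0 + r)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": "sdmsense-maxent-1",
            "tau": self.tau,
            "log_normalizer": self.log_normalizer,
            "entropy": self.entropy,
            "converged": self.converged,
            "iterations_used": self.iterations_used,
            "features": [
                {
                    "kind": f.kind,
                    "covariate": f.covariate,
                    "scale_min": f.scale_min,
                    "scale_max": f.scale_max,
                    "knot": f.knot,
                    "direction": f.direction,
                    "weight": w,
                    "reg_weight": b,
                }
                for f, w, b in zip(self.features, self.weights, self.reg_weights)
            ],
        }

    def save(self, path) -> None:
        """Write a flat text description that round-trips bit-exactly."""
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "MaxentModel":
        with open(path) as fh:
            d = json.load(fh)
        feats, w, b = [], [], []
        for row in d["features"]:
            feats.append(
                FeatureBasis(
                    row["kind"], row["covariate"], row["scale_min"], row["scale_max"],
                    knot=row["knot"], direction=row["direction"],
                )
            )
            w.append(row["weight"])
            b.append(row["reg_weight"])
        return cls(
            features=feats,
            weights=np.array(w),
            reg_weights=np.array(b),
            log_normalizer=d["log_normalizer"],
            entropy=d["entropy"],
            tau=d["tau"],
            converged=d["converged"],
            iterations_used=d["iterations_used"],
        )


def fit_maxent(
    presence_covs: pd.DataFrame,
    background_covs: pd.DataFrame,
    features: list[FeatureBasis],
    reg_multiplier: float = 1.0,
    convergence_tol: float = 1e-6,
    max_iterations: int = 500,
    tau: float = 0.5,
    seed: int = 0,
) -> MaxentModel:
    """Fit the Gibbs density by L1-penalized coordinate descent.

    ``seed`` is accepted for interface symmetry with the stochastic stages
    of the pipeline; the optimizer itself is deterministic (zero
    initialization, fixed cycling order).
    """
    active = [f for f in features if not f.is_degenerate]
    if not active:
        raise FitError("no active (non-degenerate) features to fit")
    if len(presence_covs) < 1:
        raise FitError("at least one presence row is required")
    if len(background_covs) < 2:
        raise FitError("at least two background rows are required")

    X_pr = design_matrix(active, presence_covs)
    X_bg = design_matrix(active, background_covs)
    if not (np.all(np.isfinite(X_pr)) and np.all(np.isfinite(X_bg))):
        raise FitError("non-finite covariate values in presence or background table")

    m = X_pr.shape[0]
    n = X_bg.shape[0]
    n_feat = len(active)
    pbar = X_pr.mean(axis=0)
    sigma = np.maximum(X_bg.std(axis=0), SIGMA_FLOOR)
    beta = reg_multiplier * sigma / np.sqrt(m)

    lam = np.zeros(n_feat)
    s = np.zeros(n)  # X_bg @ lam, maintained incrementally
    cols = [np.ascontiguousarray(X_bg[:, j]) for j in range(n_feat)]
    # shifted exponentials e = exp(s - shift) maintained across updates so a
    # coordinate step costs O(n) raw numpy ops with no logsumexp overhead
    shift = 0.0
    e = np.exp(s - shift)
    z_sum = float(e.sum())
    log_z = shift + np.log(z_sum)
    lin = 0.0  # pbar @ lam
    pen = 0.0  # beta @ |lam|
    obj = -lin + log_z + pen

    converged = False
    iterations = 0
    for cycle in range(max_iterations):
        # refresh the shift once per cycle to keep the exponentials in range
        shift = float(s.max())
        e = np.exp(s - shift)
        z_sum = float(e.sum())
        log_z = shift + np.log(z_sum)
        obj_start = obj
        for j in range(n_feat):
            col = cols[j]
            ef = float(e @ col) / z_sum
            ef2 = float(e @ (col * col)) / z_sum
            grad = ef - pbar[j]
            hess = max(ef2 - ef * ef, HESSIAN_FLOOR)
            z = lam[j] - grad / hess
            lam_new = np.sign(z) * max(abs(z) - beta[j] / hess, 0.0)
            step = lam_new - lam[j]
            if step == 0.0:
                continue
            # backtracking on the penalized objective
            for _ in range(30):
                cand = lam[j] + step
                with np.errstate(over="ignore", invalid="ignore"):
                    e_try = e * np.exp(step * col)
                    z_try = float(e_try.sum())
                if not np.isfinite(z_try) or z_try <= 0.0:
                    step *= 0.5  # overshot into overflow; shrink and retry
                    continue
                log_z_try = shift + np.log(z_try)
                pen_try = pen - beta[j] * abs(lam[j]) + beta[j] * abs(cand)
                lin_try = lin + pbar[j] * step
                obj_try = -lin_try + log_z_try + pen_try
                if obj_try <= obj + 1e-15:
                    lam[j] = cand
                    s += step * col
                    e = e_try
                    z_sum = z_try
                    log_z = log_z_try
                    lin = lin_try
                    pen = pen_try
                    obj = obj_try
                    break
                step *= 0.5
        iterations = cycle + 1
        if obj_start - obj < convergence_tol:
            converged = True
            break

    w = np.exp(s - log_z)
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = float(-np.sum(np.where(w > 0, w * np.log(w), 0.0)))
    entropy = max(entropy, 0.0)

    weights = np.zeros(len(features))
    regs = np.zeros(len(features))
    pos = 0
    for i, f in enumerate(features):
        if f.is_degenerate:
            continue
        weights[i] = lam[pos]
        regs[i] = beta[pos]
        pos += 1

    if not converged:
        log.warning("coordinate descent hit the iteration cap (%d) before the "
                    "objective stabilized", max_iterations)
    return MaxentModel(
        features=list(features),
        weights=weights,
        reg_weights=regs,
        log_normalizer=float(log_z),
        entropy=entropy,
        tau=tau,
        converged=converged,
        iterations_used=iterations,
    )


@dataclass
class SuitabilitySurface:
    """A continuous 0–1 suitability map plus its maximum and clamping flags."""

    grid: GridSpec
    probability: np.ndarray  # (n_rows, n_cols), NaN outside valid cells
    valid_mask: np.ndarray
    max_probability: float
    clamped_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        vals = self.probability[self.valid_mask]
        if vals.size and not ((vals >= 0).all() and (vals <= 1).all()):
            raise ValueError("suitability values must lie in [0, 1]")

    def scores_at(self, points) -> np.ndarray:
        """Suitability at the cells containing each (x, y) point (NaN if invalid)."""
        pts = np.asarray(list(points), dtype=float).reshape(-1, 2)
        row, col = self.grid.cell_of(pts[:, 0], pts[:, 1])
        ok = (
            (row >= 0) & (row < self.grid.n_rows) & (col >= 0) & (col < self.grid.n_cols)
        )
        r = np.clip(row, 0, self.grid.n_rows - 1)
        c = np.clip(col, 0, self.grid.n_cols - 1)
        out = np.where(ok, self.probability[r, c], np.nan)
        return out


def project(model: MaxentModel, stack: EnvStack, clamp: bool = True) -> SuitabilitySurface:
    """Project a fitted model onto a covariate stack.

    Projected cells are scored on the training scale — q(x) = exp(Σ λ_j
    f_j(x) − log Z_train) with the normalizer learned during fitting — so
    logistic values are comparable across projection regions of different
    sizes, and a model trained on a well-matched restricted region shows
    the higher, more peaked probabilities it earned there.  (A per-region
    renormalized density is available via :meth:`MaxentModel.raw_density`.)
    With ``clamp`` set, covariates are clipped to their training background
    range and cells where clipping occurred are flagged.
    """
    missing = [c for c in model.covariate_ranges() if c not in stack.layer_names]
    if missing:
        raise ProjectionError(f"projection stack lacks covariate layer(s) {missing}")

    table = stack.valid_table()
    clamped_rows = np.zeros(len(table), dtype=bool)
    if clamp:
        for cov, (lo, hi) in model.covariate_ranges().items():
            vals = table[cov].to_numpy(dtype=float)
            outside = (vals < lo) | (vals > hi)
            clamped_rows |= outside
            table[cov] = np.clip(vals, lo, hi)

    q = np.exp(model.linear_score(table) - model.log_normalizer)
    p = model.logistic_from_raw(q)

    prob = np.full(stack.grid.shape, np.nan)
    rr = table["row"].to_numpy()
    cc = table["col"].to_numpy()
    prob[rr, cc] = p
    clamped = np.zeros(stack.grid.shape, dtype=bool)
    clamped[rr, cc] = clamped_rows
    return SuitabilitySurface(
        grid=stack.grid,
        probability=prob,
        valid_mask=stack.valid_mask.copy(),
        max_probability=float(np.max(p)),
        clamped_mask=clamped,
    )


def max_probability(surface: SuitabilitySurface) -> float:
    """Maximum of the logistic surface over valid cells."""
    vals = surface.probability[surface.valid_mask]
    if vals.size == 0:
        raise ValueError("surface has no valid cells")
    return float(np.max(vals))
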