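"""GBLUP: REML variance components, breeding-value solutions, holdout prediction.

Model: y = X beta + u + e with u ~ N(0, sigma2_g G) and e ~ N(0, sigma2_e I).
Writing V = sigma2 (h2 G + (1 - h2) I), a single eigendecomposition of G
rotates the model to independent observations, after which the restricted
likelihood is profiled down to a 1-D function of h2 and maximized by bounded
Brent search on [0, 1]; boundary solutions are permitted.  Binary and
ordinal responses are fitted on their observed numeric scale (linear model),
so their continuous genomic predictions can be thresholded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .grm import Grm

_W_FLOOR = 1e-12


class SingularDesignError(ValueError):
    """Raised when the fixed-effect design matrix is rank deficient."""


@dataclass
class MixedModelSpec:
    """Response name plus the ordered fixed-effect list (intercept implicit)."""

    response: str
    fixed_effects: list = field(default_factory=list)


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    pseudo_h2: float
    log_reml: float
    at_boundary: bool = False

    def __post_init__(self) -> None:
        if self.sigma2_g < 0 or self.sigma2_e < 0:
            raise ValueError("variance components must be nonnegative")
        if not 0.0 <= self.pseudo_h2 <= 1.0:
            raise ValueError("pseudo_h2 must lie in [0, 1]")


@dataclass
class GblupFit:
    spec: MixedModelSpec
    vc: VarianceComponents
    beta: np.ndarray
    beta_names: list
    gebv: np.ndarray
    fitted: np.ndarray
    ids: list


def build_design(pheno: pd.DataFrame, fixed_effects: list[str]):
    """Assemble the fixed-effect design matrix.

    ``birth_year`` is expanded to categorical indicators with the first level
    dropped; every other named effect is taken as a numeric column.  The
    intercept is always included.  Raises :class:`SingularDesignError` naming
    the collinear columns if the result is rank deficient.
    """
    n = len(pheno)
    cols = [np.ones(n)]
    names = ["intercept"]
    for eff in fixed_effects:
        if eff == "intercept":
            continue
        if eff == "birth_year":
            dummies = pd.get_dummies(pheno["birth_year"].astype(int), prefix="birth_year",
                                     drop_first=True, dtype=float)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy())
                names.append(str(c))
        else:
            if eff not in pheno.columns:
                raise KeyError(f"fixed effect {eff!r} not in phenotype table")
            v = pd.to_numeric(pheno[eff], errors="raise").to_numpy(dtype=float)
            if np.any(np.isnan(v)):
                raise ValueError(f"fixed effect {eff!r} contains missing values")
            cols.append(v)
            names.append(eff)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns greedily
        bad = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            trial = kept + [j]
            if np.linalg.matrix_rank(X[:, trial]) < len(trial):
                bad.append(names[j])
            else:
                kept.append(j)
        raise SingularDesignError(f"collinear fixed-effect columns: {bad}")
    return X, names


def _prepare_rotation(grm: Grm):
    """Eigendecompose G (ridge-repaired if needed); returns (d, U)."""
    vals, vecs = grm.eigendecomposition()
    if vals.min() < 0:
        ridge = 1e-6 * np.mean(np.diag(grm.matrix))
        vals = vals + ridge
        vals = np.clip(vals, 0.0, None)
    return vals, vecs


def _profile_neg_reml(h2: float, ystar: np.ndarray, Xstar: np.ndarray, d: np.ndarray):
    """Negative restricted log-likelihood profiled over beta and total sigma2."""
    n, p = Xstar.shape
    w = np.maximum(h2 * d + (1.0 - h2), _W_FLOOR)
    Xw = Xstar / w[:, None]
    XtWX = Xstar.T @ Xw
    XtWy = Xw.T @ ystar
    sign, logdet_xtwx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf, None, None
    beta = np.linalg.solve(XtWX, XtWy)
    r = ystar - Xstar @ beta
    rss = float(r @ (r / w))
    if rss <= 0:
        rss = _W_FLOOR
    sigma2 = rss / (n - p)
    neg = 0.5 * ((n - p) * np.log(2 * np.pi * sigma2) + np.log(w).sum()
                 + logdet_xtwx + (n - p))
    return neg, sigma2, beta


def reml_fit(y: np.ndarray, X: np.ndarray, grm: Grm, h2_tol: float = 1e-8) -> VarianceComponents:
    """Estimate (sigma2_g, sigma2_e) by REML via eigen-rotation of G.

    A coarse grid on h2 locates the basin, Brent search refines it, and the
    h2 = 0 and h2 = 1 boundaries are checked explicitly.
    """
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("response length does not match design rows")
    if n < p + 2:
        raise ValueError(f"need n >= p + 2 observations (n={n}, p={p})")
    d, U = _prepare_rotation(grm)
    ystar = U.T @ y
    Xstar = U.T @ X

    def obj(h2: float) -> float:
        return _profile_neg_reml(h2, ystar, Xstar, d)[0]

    grid = np.linspace(0.0, 1.0, 21)
    grid_vals = np.array([obj(h) for h in grid])
    j = int(np.argmin(grid_vals))
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, len(grid) - 1)]
    if hi - lo < 1e-12:
        best_h2 = grid[j]
    else:
        res = minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                              options={"xatol": h2_tol})
        best_h2 = float(res.x)
        if obj(best_h2) > grid_vals[j]:
            best_h2 = float(grid[j])
    # explicit boundary check
    for b in (0.0, 1.0):
        if obj(b) < obj(best_h2):
            best_h2 = b
    neg, sigma2, _beta = _profile_neg_reml(best_h2, ystar, Xstar, d)
    h2 = min(max(best_h2, 0.0), 1.0)
    at_boundary = h2 < h2_tol or h2 > 1.0 - h2_tol
    return VarianceComponents(sigma2_g=sigma2 * h2, sigma2_e=sigma2 * (1.0 - h2),
                              pseudo_h2=h2, log_reml=-neg, at_boundary=at_boundary)


def solve_blup(y: np.ndarray, X: np.ndarray, grm: Grm, vc: VarianceComponents,
               spec: MixedModelSpec | None = None,
               beta_names: list | None = None) -> GblupFit:
    """GLS fixed effects and BLUP breeding values at the given components.

    beta = (X' V^-1 X)^-1 X' V^-1 y and u = sigma2_g G V^-1 (y - X beta),
    evaluated through the eigenbasis of G so V is diagonal.
    """
    y = np.asarray(y, dtype=float)
    d, U = _prepare_rotation(grm)
    w = vc.sigma2_g * d + vc.sigma2_e
    if np.min(w) < _W_FLOOR:  # V numerically singular: ridge and continue
        w = w + max(_W_FLOOR, 1e-8 * max(vc.sigma2_g + vc.sigma2_e, 1.0))
    ystar = U.T @ y
    Xstar = U.T @ X
    Xw = Xstar / w[:, None]
    beta = np.linalg.solve(Xstar.T @ Xw, Xw.T @ ystar)
    rstar = ystar - Xstar @ beta
    # u = sigma2_g G V^-1 r = sigma2_g U diag(d / w) U' r
    gebv = vc.sigma2_g * (U @ (d * (rstar / w)))
    fitted = X @ beta + gebv
    return GblupFit(spec=spec or MixedModelSpec(response="y"), vc=vc,
                    beta=beta, beta_names=beta_names or [f"b{j}" for j in range(X.shape[1])],
                    gebv=gebv, fitted=fitted, ids=list(grm.ids))


def fit_gblup(pheno: pd.DataFrame, grm: Grm, response: str,
              fixed_effects: list[str] | None = None) -> GblupFit:
    """Convenience wrapper: align phenotypes to the GRM, REML, then BLUP."""
    fixed_effects = [] if fixed_effects is None else list(fixed_effects)
    sub = pheno.loc[grm.ids]
    y = pd.to_numeric(sub[response], errors="raise").to_numpy(dtype=float)
    X, names = build_design(sub, fixed_effects)
    vc = reml_fit(y, X, grm)
    return solve_blup(y, X, grm, vc,
                      spec=MixedModelSpec(response=response, fixed_effects=fixed_effects),
                      beta_names=names)


def predict_holdout(fit_train: GblupFit, grm_full: Grm, test_ids: list[str],
                    X_test: np.ndarray):
    """Predict breeding values and phenotypes for held-out individuals.

    u_test = G_test,train G_train,train^-1 u_train (conditional expectation,
    ridge-stabilized); predicted phenotype = X_test beta + u_test.
    Test ids must be disjoint from the training ids.
    """
    train_ids = fit_train.ids
    overlap = set(test_ids) & set(train_ids)
    if overlap:
        raise ValueError(f"test ids overlap training ids: {sorted(overlap)[:5]}")
    known = set(grm_full.ids)
    unknown = [s for s in list(test_ids) + list(train_ids) if s not in known]
    if unknown:
        raise KeyError(f"ids missing from GRM: {unknown[:5]}")
    G_tt = grm_full.block(train_ids, train_ids)
    G_st = grm_full.block(test_ids, train_ids)
    ridge = 1e-8 * max(np.mean(np.diag(G_tt)), 1.0)
    u_test = G_st @ np.linalg.solve(G_tt + ridge * np.eye(len(train_ids)), fit_train.gebv)
    y_pred = X_test @ fit_train.beta + u_test
    return y_pred, u_test
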