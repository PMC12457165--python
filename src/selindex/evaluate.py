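"""Cross-validated evaluation of genomic predictions.

Five-fold cross-validation with the metric battery matched to trait type:
MCC and AUROC for binary traits, Kendall's tau-b and Spearman's rho for
ordinal traits, Pearson's R and NMSE for continuous traits.  Pooled metrics
are computed on the concatenated out-of-fold predictions; per-fold values
are reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gblup import MixedModelSpec, build_design, predict_holdout, reml_fit, solve_blup
from .grm import Grm, compute_pcs


@dataclass
class FoldPlan:
    k: int
    assignments: dict  # id -> fold index
    seed: int

    def fold_ids(self, fold: int) -> list:
        return [s for s, f in self.assignments.items() if f == fold]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class TraitReport:
    trait: str
    kind: str
    pseudo_h2: float
    pooled: dict = field(default_factory=dict)
    per_fold: list = field(default_factory=list)
    predictions: pd.DataFrame | None = None


def make_folds(ids: list, k: int = 5, seed: int = 0) -> FoldPlan:
    """Uniform random partition into k folds with sizes differing by <= 1."""
    ids = list(ids)
    if k < 2 or k > len(ids):
        raise ValueError(f"k must be in [2, n]; got k={k}, n={len(ids)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    assignments = {}
    for fold, chunk in enumerate(np.array_split(perm, k)):
        for i in chunk:
            assignments[ids[i]] = fold
    return FoldPlan(k=k, assignments=assignments, seed=seed)


def confusion(pred_class: np.ndarray, obs: np.ndarray) -> ConfusionCounts:
    pred_class = np.asarray(pred_class).astype(int)
    obs = np.asarray(obs).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((pred_class == 1) & (obs == 1))),
        fp=int(np.sum((pred_class == 1) & (obs == 0))),
        tn=int(np.sum((pred_class == 0) & (obs == 0))),
        fn=int(np.sum((pred_class == 0) & (obs == 1))),
    )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0
    (the degenerate one-class-prediction case)."""
    num = c.tp * c.tn - c.fp * c.fn
    den = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if den == 0:
        return 0.0
    return num / math.sqrt(den)


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUROC with ties credited one half.

    Undefined (nan) when either class is absent.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def kendall_tau(pred: np.ndarray, obs: np.ndarray) -> float:
    """Kendall's tau-b (tie-corrected)."""
    res = stats.kendalltau(pred, obs)
    return float(res.statistic)


def spearman_rho(pred: np.ndarray, obs: np.ndarray) -> float:
    """Spearman correlation with average-rank ties."""
    res = stats.spearmanr(pred, obs)
    return float(res.statistic)


def pearson_r(pred: np.ndarray, obs: np.ndarray) -> float:
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if np.std(pred) == 0 or np.std(obs) == 0:
        return float("nan")
    return float(stats.pearsonr(pred, obs).statistic)


def nmse(pred: np.ndarray, obs: np.ndarray) -> float:
    """Mean squared error over the population (divide-by-n) variance of obs,
    so a constant-at-the-mean predictor scores exactly 1; nan when the
    observations have zero variance."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    var = float(np.mean((obs - obs.mean()) ** 2))
    if var == 0:
        return float("nan")
    return float(np.mean((pred - obs) ** 2) / var)


def classify_prediction(pred: np.ndarray, kind: str, n_classes: int | None = None) -> np.ndarray:
    """Threshold continuous genomic predictions to classes.

    Binary: class 1 iff prediction >= 0.5.  Ordinal: round to the nearest
    valid class and clip to [0, n_classes - 1].
    """
    pred = np.asarray(pred, dtype=float)
    if kind == "binary":
        return (pred >= 0.5).astype(int)
    if kind == "ordinal":
        hi = (n_classes - 1) if n_classes else int(np.nanmax(pred).round())
        return np.clip(np.rint(pred), 0, hi).astype(int)
    raise ValueError(f"classification undefined for kind {kind!r}")


def metrics_for_kind(pred: np.ndarray, obs: np.ndarray, kind: str,
                     n_classes: int | None = None) -> dict:
    """The trait-type-appropriate metric subset (other cells stay absent)."""
    out: dict = {}
    if kind == "binary":
        out["mcc"] = mcc(confusion(classify_prediction(pred, "binary"), obs))
        out["auroc"] = auroc(pred, obs)
    elif kind == "ordinal":
        out["kendall_tau"] = kendall_tau(pred, obs)
        out["spearman_rho"] = spearman_rho(pred, obs)
    elif kind == "continuous":
        out["pearson_r"] = pearson_r(pred, obs)
        out["nmse"] = nmse(pred, obs)
    else:
        raise ValueError(f"unknown trait kind {kind!r}")
    return out


def _design_for_fold(X_full: np.ndarray, names: list, rows: np.ndarray):
    """Drop columns constant within the training rows (e.g. a birth-year level
    absent from the fold) and return the retained column index."""
    Xt = X_full[rows]
    keep = [0] + [j for j in range(1, X_full.shape[1]) if np.ptp(Xt[:, j]) > 0]
    return keep


def evaluate_trait(trait: str, pheno: pd.DataFrame, grm: Grm, kind: str,
                   fixed_effects: list[str] | None = None,
                   folds: FoldPlan | None = None, k: int = 5, seed: int = 0,
                   n_classes: int | None = None) -> TraitReport:
    """Cross-validated GBLUP evaluation of one trait.

    Per fold: REML + BLUP on the training individuals, conditional-expectation
    prediction for the held-out fold, metrics by trait kind.  Pseudo-
    heritability comes from a full-data fit.  ``pheno`` must be indexed by id
    and cover every id in ``grm``.
    """
    fixed_effects = ["birth_year", "pc1", "pc2", "pc3"] if fixed_effects is None else list(fixed_effects)
    sub = pheno.loc[grm.ids].copy()
    if any(e.startswith("pc") for e in fixed_effects) and "pc1" not in sub.columns:
        pcs = compute_pcs(grm, max(int(e[2:]) for e in fixed_effects if e.startswith("pc")))
        for j in range(pcs.shape[1]):
            sub[f"pc{j + 1}"] = pcs[:, j]
    y = pd.to_numeric(sub[trait], errors="raise").to_numpy(dtype=float)
    X_full, names = build_design(sub, fixed_effects)
    folds = make_folds(grm.ids, k=k, seed=seed) if folds is None else folds

    vc_full = reml_fit(y, X_full, grm)
    if kind == "ordinal" and n_classes is None:
        n_classes = int(np.nanmax(y)) + 1

    id_pos = {s: i for i, s in enumerate(grm.ids)}
    oof_pred = np.full(len(y), np.nan)
    oof_gebv = np.full(len(y), np.nan)
    per_fold = []
    for fold in range(folds.k):
        test_ids = [s for s in grm.ids if folds.assignments[s] == fold]
        train_ids = [s for s in grm.ids if folds.assignments[s] != fold]
        tr = np.array([id_pos[s] for s in train_ids])
        te = np.array([id_pos[s] for s in test_ids])
        keep = _design_for_fold(X_full, names, tr)
        Xtr, Xte = X_full[np.ix_(tr, keep)], X_full[np.ix_(te, keep)]
        grm_tr = grm.subset(train_ids)
        vc = reml_fit(y[tr], Xtr, grm_tr)
        fit = solve_blup(y[tr], Xtr, grm_tr, vc,
                         spec=MixedModelSpec(response=trait, fixed_effects=fixed_effects),
                         beta_names=[names[j] for j in keep])
        y_pred, u_test = predict_holdout(fit, grm, test_ids, Xte)
        oof_pred[te] = y_pred
        oof_gebv[te] = u_test
        fm = metrics_for_kind(y_pred, y[te], kind, n_classes=n_classes)
        fm["fold"] = fold
        fm["n_test"] = len(te)
        per_fold.append(fm)

    pooled = metrics_for_kind(oof_pred, y, kind, n_classes=n_classes)
    preds = pd.DataFrame({"id": grm.ids, "observed": y, "predicted": oof_pred,
                          "gebv": oof_gebv,
                          "fold": [folds.assignments[s] for s in grm.ids]}).set_index("id")
    return TraitReport(trait=trait, kind=kind, pseudo_h2=vc_full.pseudo_h2,
                       pooled=pooled, per_fold=per_fold, predictions=preds)


def evaluate_success_with_fixed_effect(extra_fixed: str | list[str] | None, pheno: pd.DataFrame,
                                       grm: Grm, fixed_effects: list[str] | None = None,
                                       folds: FoldPlan | None = None, k: int = 5,
                                       seed: int = 0, response: str = "success") -> TraitReport:
    """Evaluate the binary success outcome with index scores appended to the
    fixed-effect design (scores observed for all individuals, including the
    held-out fold).

    Parental-score effects are defined only for dogs whose sire and dam both
    carry records; rows where an extra fixed effect is missing are excluded,
    so e.g. parent_total_score automatically restricts the run to the trio
    subset (the GRM and any provided fold plan are subset to match).
    """
    base = ["birth_year", "pc1", "pc2", "pc3"] if fixed_effects is None else list(fixed_effects)
    extras = []
    if extra_fixed:
        extras = [extra_fixed] if isinstance(extra_fixed, str) else list(extra_fixed)
        base = base + extras
    if extras:
        sub = pheno.loc[grm.ids]
        complete = ~sub[extras].isna().any(axis=1)
        if not complete.all():
            keep = [s for s, ok in zip(grm.ids, complete) if ok]
            grm = grm.subset(keep)
            pheno = pheno.loc[keep]
            if folds is not None:
                folds = FoldPlan(k=folds.k, seed=folds.seed,
                                 assignments={s: f for s, f in folds.assignments.items()
                                              if s in set(keep)})
    return evaluate_trait(response, pheno, grm, kind="binary", fixed_effects=base,
                          folds=folds, k=k, seed=seed)


def report_frame(reports: list) -> pd.DataFrame:
    """Assemble per-trait reports into the standard wide table (one row per
    trait; metric cells blank where the trait type does not define them)."""
    rows = []
    for r in reports:
        row = {"trait": r.trait, "pseudo_h2": r.pseudo_h2}
        for m in ("mcc", "auroc", "kendall_tau", "spearman_rho", "pearson_r", "nmse"):
            row[m] = r.pooled.get(m, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
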