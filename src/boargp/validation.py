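"""Phenotype adjustment, k-fold cross-validation and accuracy comparison.

Accuracy of (G)EBV is measured as R = r(EBV, y_adj) / sqrt(h2), where y_adj
is the phenotype adjusted for the random day-of-analysis effect using the
full-data fit, and h2 excludes the day variance (consistently with the
adjustment).  Prediction bias is the slope of the regression of y_adj on
EBV, with slope 1 indicating no bias.  Two methods' accuracies are compared
with the Hotelling-Williams test for dependent correlations sharing one
variable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .kinship import RelationshipMatrix
from .mixedmodel import (
    BlupSolution,
    ModelSpec,
    VarianceComponents,
    heritability,
    solve_blup,
)

__all__ = [
    "CvResult",
    "CorrelationComparison",
    "adjust_phenotypes",
    "kfold_split",
    "cross_validate",
    "accuracy_from_r",
    "pooled_metrics",
    "hotelling_williams",
    "compare_cv",
]


@dataclass
class CvResult:
    trait: str
    method: str  # "pblup" or "gblup"
    fold_of_animal: dict
    r_ebv_yadj: float
    accuracy: float
    beta: float
    h2: float
    n_pooled: int
    per_fold: pd.DataFrame = field(repr=False)
    pooled: pd.DataFrame = field(repr=False)  # animal, ebv, y_adj, fold


@dataclass
class CorrelationComparison:
    r13: float
    r23: float
    r12: float
    n: int
    t_statistic: float
    p_value: float


def adjust_phenotypes(
    pheno: pd.DataFrame, spec: ModelSpec, solution: BlupSolution
) -> pd.Series:
    """y_adj = y - mu_hat - day BLUP of the record's day (full-data fit)."""
    df = pheno.loc[pheno[spec.trait].notna()]
    y = df[spec.trait].to_numpy(dtype=float)
    if spec.include_day and solution.day_levels.size:
        lookup = {lvl: b for lvl, b in zip(solution.day_levels, solution.day_blups)}
        days = df[spec.day_col].to_numpy()
        unknown = [d for d in pd.unique(days) if d not in lookup]
        if unknown:
            raise ValueError(f"records with unknown day level: {unknown[:5]}")
        day_adj = np.array([lookup[d] for d in days])
    else:
        day_adj = 0.0
    return pd.Series(
        y - solution.mu_hat - day_adj,
        index=df[spec.animal_col].astype(str),
        name=f"{spec.trait}_adj",
    )


def kfold_split(animal_ids, k: int = 5, seed: int = 0) -> np.ndarray:
    """Random partition into k folds with sizes differing by at most one."""
    if k <= 1:
        raise ValueError("k must be at least 2")
    ids = np.asarray(animal_ids)
    n = ids.size
    if n < k:
        raise ValueError(f"cannot split {n} animals into {k} folds")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=np.intp)
    for f, chunk in enumerate(np.array_split(perm, k)):
        folds[chunk] = f
    return folds


def cross_validate(
    pheno: pd.DataFrame,
    spec: ModelSpec,
    K: RelationshipMatrix,
    vc: VarianceComponents,
    folds: np.ndarray | None = None,
    k: int = 5,
    seed: int = 0,
    y_adj: pd.Series | None = None,
    blend_weight: float | None = None,
    full_solution: BlupSolution | None = None,
) -> CvResult:
    """Masked k-fold cross-validation of (G)EBV predictions.

    Per fold, the validation animals' records are dropped from the data and
    the BLUP system is re-solved with the full-data variance components;
    their (G)EBVs then derive purely from relationships.  Validation
    predictions are pooled across folds before computing r, the accuracy
    R = r / sqrt(h2), and the bias slope beta of y_adj regressed on EBV.
    """
    df = pheno.loc[pheno[spec.trait].notna()]
    animals = df[spec.animal_col].astype(str).to_numpy(dtype=object)
    if full_solution is None:
        full_solution = solve_blup(pheno, spec, K, vc, blend_weight=blend_weight)
    if y_adj is None:
        y_adj = adjust_phenotypes(pheno, spec, full_solution)
    if folds is None:
        folds = kfold_split(animals, k=k, seed=seed)
    folds = np.asarray(folds)
    if folds.size != animals.size:
        raise ValueError("fold assignment length does not match phenotyped animals")

    a_index = {a: i for i, a in enumerate(K.animal_ids)}
    rows = []
    fold_stats = []
    for f in np.unique(folds):
        val_animals = animals[folds == f]
        train = df.loc[~np.isin(animals, val_animals)]
        sol = solve_blup(train, spec, K, vc, blend_weight=blend_weight)
        idx = np.array([a_index[a] for a in val_animals])
        ebv_val = sol.u_hat[idx]
        yv = y_adj.loc[val_animals].to_numpy()
        if np.var(yv) <= 0:
            warnings.warn(f"fold {f}: zero variance of adjusted phenotype; skipped")
            continue
        for a, e, yy in zip(val_animals, ebv_val, yv):
            rows.append((a, e, yy, int(f)))
        r_f = float(np.corrcoef(ebv_val, yv)[0, 1])
        fold_stats.append((int(f), len(val_animals), r_f))

    pooled = pd.DataFrame(rows, columns=["animal", "ebv", "y_adj", "fold"])
    h2 = heritability(vc)
    r, acc, beta = pooled_metrics(
        pooled["ebv"].to_numpy(), pooled["y_adj"].to_numpy(), h2
    )
    return CvResult(
        trait=spec.trait,
        method="gblup" if K.kind == "genomic_G" else "pblup",
        fold_of_animal=dict(zip(animals, folds.tolist())),
        r_ebv_yadj=r,
        accuracy=acc,
        beta=beta,
        h2=h2,
        n_pooled=len(pooled),
        per_fold=pd.DataFrame(fold_stats, columns=["fold", "n_validation", "r"]),
        pooled=pooled,
    )


def pooled_metrics(ebv: np.ndarray, y_adj: np.ndarray, h2: float):
    """(r, accuracy, beta) of pooled validation predictions.

    r is the Pearson correlation of EBV with y_adj, accuracy is r/sqrt(h2),
    and beta is the slope of y_adj regressed on EBV (1 = unbiased).
    """
    r = float(np.corrcoef(ebv, y_adj)[0, 1])
    beta = float(np.polyfit(ebv, y_adj, 1)[0])
    return r, accuracy_from_r(r, h2), beta


def accuracy_from_r(r: float, h2: float) -> float:
    """Accuracy R = r / sqrt(h2) of EBV against day-adjusted phenotypes."""
    if not (0.0 < h2 <= 1.0):
        raise ValueError("h2 must lie in (0, 1]")
    return r / np.sqrt(h2)


def hotelling_williams(r13: float, r23: float, r12: float, n: int) -> CorrelationComparison:
    """Williams' t-test for two dependent correlations sharing variable 3.

    Here variables 1 and 2 are the two methods' EBVs and variable 3 the
    adjusted phenotype.  The statistic is referred to a t distribution with
    n - 3 degrees of freedom (two-sided).
    """
    if n <= 3:
        raise ValueError("need n > 3")
    for name, r in (("r13", r13), ("r23", r23), ("r12", r12)):
        if not (-1.0 < r < 1.0):
            raise ValueError(f"{name} must lie strictly in (-1, 1)")
    detR = 1.0 - r13**2 - r23**2 - r12**2 + 2.0 * r13 * r23 * r12
    if detR <= 0:
        raise ValueError("degenerate correlation matrix (|R| <= 0)")
    rbar = 0.5 * (r13 + r23)
    denom = 2.0 * ((n - 1) / (n - 3)) * detR + rbar**2 * (1.0 - r12) ** 3
    t = (r13 - r23) * np.sqrt((n - 1) * (1.0 + r12) / denom)
    p = 2.0 * scipy.stats.t.sf(abs(t), df=n - 3)
    return CorrelationComparison(r13, r23, r12, n, float(t), float(p))


def compare_cv(cv1: CvResult, cv2: CvResult, n: int | None = None) -> CorrelationComparison:
    """Hotelling-Williams comparison of two CV runs on the same animals.

    r12 is computed from the two methods' pooled EBVs; n defaults to the
    number of pooled validation animals.
    """
    m = cv1.pooled.merge(cv2.pooled, on="animal", suffixes=("_1", "_2"))
    if len(m) == 0:
        raise ValueError("no shared animals between the two CV runs")
    r12 = float(np.corrcoef(m["ebv_1"], m["ebv_2"])[0, 1])
    if n is None:
        n = len(m)
    return hotelling_williams(cv1.r_ebv_yadj, cv2.r_ebv_yadj, r12, n)
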