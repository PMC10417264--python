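"""REML variance components and BLUP solving for the univariate animal model.

The model is  y = 1*mu + X*b + W*a + e  with b a random day-of-analysis
effect (b ~ N(0, I*sigma2_day)), a the additive genetic effect
(a ~ N(0, K*sigma2_a) with K either the pedigree A or the genomic G matrix)
and e ~ N(0, I*sigma2_e).  The same solver serves pedigree-based BLUP and
GBLUP; only the relationship matrix changes.

Variance components are estimated by AI-REML (average-information
Newton updates) with EM-REML fallback steps whenever an AI update proposes a
non-positive component; EM alone is also available.  Both are written in
terms of the projection matrix P = V^-1 - V^-1 1 (1'V^-1 1)^-1 1'V^-1,
which is affordable at the scale this package targets (a few thousand
records).

Heritability is reported as sigma2_a / (sigma2_a + sigma2_e), i.e. on the
day-adjusted scale; including the day variance in the denominator is
available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .kinship import KinshipInverse, RelationshipMatrix, blend_and_invert

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "BlupSolution",
    "build_design",
    "assemble_mme",
    "reml_estimate",
    "solve_blup",
    "heritability",
]


@dataclass
class ModelSpec:
    """Trait and factor columns of the animal model."""

    trait: str
    animal_col: str = "animal"
    day_col: str = "day"
    include_day: bool = True


@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_day: float
    sigma2_e: float
    h2: float = None
    se_h2: float | None = None
    converged: bool = True
    n_iterations: int = 0
    method: str = "ai"
    loglik: float | None = None

    def __post_init__(self) -> None:
        if min(self.sigma2_a, self.sigma2_day, self.sigma2_e) < 0:
            raise ValueError("variance components must be non-negative")
        if self.h2 is None:
            self.h2 = heritability(self)
        if not (0.0 <= self.h2 <= 1.0):
            raise ValueError("h2 outside [0, 1]")


@dataclass
class BlupSolution:
    """Solutions of the mixed-model equations plus prediction-error variances."""

    animal_ids: np.ndarray
    mu_hat: float
    day_levels: np.ndarray
    day_blups: np.ndarray
    u_hat: np.ndarray
    pev: np.ndarray
    reliability: np.ndarray
    pev_matrix: np.ndarray = field(repr=False)
    kind: str = "pedigree_A"
    blend_weight: float = 0.0
    vc: VarianceComponents | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal": [str(a) for a in self.animal_ids],
                "ebv": self.u_hat,
                "pev": self.pev,
                "reliability": self.reliability,
            }
        )


def heritability(vc: VarianceComponents, include_day: bool = False) -> float:
    """h2 = sigma2_a / (sigma2_a + sigma2_e), optionally adding sigma2_day."""
    denom = vc.sigma2_a + vc.sigma2_e + (vc.sigma2_day if include_day else 0.0)
    if denom <= 0:
        raise ValueError("heritability undefined: all variance components are zero")
    return vc.sigma2_a / denom


def heritability_se(vc: VarianceComponents, ai_inverse: np.ndarray) -> float:
    """Delta-method SE of h2 from the inverse AI matrix (order a, day, e)."""
    a, e = vc.sigma2_a, vc.sigma2_e
    denom = (a + e) ** 2
    grad = np.array([e / denom, 0.0, -a / denom])
    return float(np.sqrt(grad @ ai_inverse @ grad))


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def build_design(pheno: pd.DataFrame, spec: ModelSpec, K: RelationshipMatrix):
    """Extract y, the day incidence X and the animal incidence W.

    Records with a missing trait value are dropped.  Every phenotyped animal
    must be present in the relationship matrix; unphenotyped animals in K
    keep zero columns in W and are predicted through relationships alone.
    """
    df = pheno.loc[pheno[spec.trait].notna()]
    if len(df) == 0:
        raise ValueError(f"no records with non-missing {spec.trait!r}")
    y = df[spec.trait].to_numpy(dtype=float)
    animals = df[spec.animal_col].astype(str).to_numpy(dtype=object)
    a_idx = K.index_of(animals)  # raises for phenotyped animals absent from K
    n = len(df)
    W = np.zeros((n, K.n_animals))
    W[np.arange(n), a_idx] = 1.0

    if spec.include_day:
        if spec.day_col not in df.columns:
            raise ValueError(f"day column {spec.day_col!r} absent from phenotypes")
        if df[spec.day_col].isna().any():
            bad = df.loc[df[spec.day_col].isna(), spec.animal_col].tolist()[:5]
            raise ValueError(f"records with unknown day level: {bad}")
        day_levels, day_codes = np.unique(df[spec.day_col].to_numpy(), return_inverse=True)
        X = np.zeros((n, day_levels.size))
        X[np.arange(n), day_codes] = 1.0
    else:
        day_levels = np.array([])
        X = np.zeros((n, 0))
    return y, X, W, day_levels, a_idx


def assemble_mme(
    y: np.ndarray,
    X: np.ndarray,
    W: np.ndarray,
    Kinv: KinshipInverse,
    vc: VarianceComponents,
):
    """Henderson's mixed-model equations for (mu, day BLUPs, animal BLUPs).

    The day block carries the ratio lambda_day = sigma2_e / sigma2_day and
    the animal block lambda_a * K^-1 with lambda_a = sigma2_e / sigma2_a.
    Returns ``(LHS, RHS, slices)`` with named index slices per block.
    """
    n, d = X.shape
    q = W.shape[1]
    if vc.sigma2_a <= 0:
        raise ValueError("sigma2_a must be positive to fit an animal effect")
    use_day = d > 0
    if use_day and vc.sigma2_day <= 0:
        warnings.warn(
            "sigma2_day is zero; dropping the day block from the equations",
            stacklevel=2,
        )
        use_day = False
        X = np.zeros((n, 0))
        d = 0
    lam_a = vc.sigma2_e / vc.sigma2_a
    ones = np.ones((n, 1))
    blocks = [ones, X, W] if use_day else [ones, W]
    M = np.concatenate(blocks, axis=1)
    LHS = M.T @ M
    RHS = M.T @ y
    if use_day:
        lam_day = vc.sigma2_e / vc.sigma2_day
        sl_mu = slice(0, 1)
        sl_day = slice(1, 1 + d)
        sl_a = slice(1 + d, 1 + d + q)
        LHS[sl_day, sl_day] += lam_day * np.eye(d)
    else:
        sl_mu = slice(0, 1)
        sl_day = slice(1, 1)
        sl_a = slice(1, 1 + q)
    LHS[sl_a, sl_a] += lam_a * Kinv.values
    return LHS, RHS, {"mu": sl_mu, "day": sl_day, "animal": sl_a}


def solve_blup(
    pheno: pd.DataFrame,
    spec: ModelSpec,
    K: RelationshipMatrix,
    vc: VarianceComponents,
    blend_weight: float | None = None,
) -> BlupSolution:
    """Solve the mixed-model equations and extract PEV and reliability.

    PEV comes from the animal block of the inverse coefficient matrix
    (times sigma2_e); reliability is 1 - PEV / (sigma2_a * K_ii), with K the
    blended matrix actually inverted.  The full animal block of the inverse
    is kept: it is what SNP-effect standard errors need downstream.
    """
    if blend_weight is None:
        blend_weight = 0.01 if K.kind == "genomic_G" else 0.0
    y, X, W, day_levels, _ = build_design(pheno, spec, K)
    Kinv = blend_and_invert(K, blend_weight)
    LHS, RHS, sl = assemble_mme(y, X, W, Kinv, vc)
    try:
        c, low = scipy.linalg.cho_factor(LHS)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "mixed-model equations are singular (animal block likely rank"
            " deficient); increase the blend weight"
        ) from exc
    Cinv = scipy.linalg.cho_solve((c, low), np.eye(LHS.shape[0]))
    sol = Cinv @ RHS

    q = K.n_animals
    Kb_diag = (1.0 - blend_weight) * np.diag(K.values) + blend_weight
    pev_matrix = vc.sigma2_e * Cinv[sl["animal"], sl["animal"]]
    pev = np.diag(pev_matrix).copy()
    denom = vc.sigma2_a * Kb_diag
    reliability = np.clip(1.0 - pev / denom, 0.0, 1.0)
    n_day = sl["day"].stop - sl["day"].start
    return BlupSolution(
        animal_ids=K.animal_ids.copy(),
        mu_hat=float(sol[sl["mu"]][0]),
        day_levels=day_levels if n_day else np.array([]),
        day_blups=sol[sl["day"]].copy(),
        u_hat=sol[sl["animal"]].copy(),
        pev=pev,
        reliability=reliability,
        pev_matrix=pev_matrix,
        kind=K.kind,
        blend_weight=blend_weight,
        vc=vc,
    )


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

def _reml_quantities(theta, parts, y, ones):
    """P-matrix quantities shared by the EM and AI updates.

    For each variance component i (``parts[i]`` is V_i = dV/dtheta_i, with
    ``None`` standing for the identity of the residual) this computes
    tr(P V_i), r_i = V_i P y and w_i = P r_i, from which the REML score is
    score_i = -0.5 * (tr(P V_i) - y'P V_i P y)  and the average-information
    matrix is AI_ij = 0.5 * r_i' w_j.
    """
    n = y.size
    V = theta[0] * parts[0] + theta[2] * np.eye(n)
    if parts[1] is not None:
        V = V + theta[1] * parts[1]
    c, low = scipy.linalg.cho_factor(V)
    logdet_V = 2.0 * np.sum(np.log(np.diag(c)))
    Vinv = scipy.linalg.cho_solve((c, low), np.eye(n))
    Vinv1 = Vinv @ ones
    s = float(ones @ Vinv1)
    P = Vinv - np.outer(Vinv1, Vinv1) / s
    Py = P @ y
    logL = -0.5 * (logdet_V + np.log(s) + float(y @ Py))

    traces = np.full(3, np.nan)
    rs: list = [None, None, None]
    ws: list = [None, None, None]
    for i, Vi in enumerate(parts[:2]):
        if Vi is None:
            continue
        traces[i] = np.sum(P * Vi)  # tr(P V_i) for symmetric V_i
        rs[i] = Vi @ Py
        ws[i] = P @ rs[i]
    traces[2] = np.trace(P)  # residual: V_e = I
    rs[2] = Py
    ws[2] = P @ Py
    return logL, traces, rs, ws


def reml_estimate(
    pheno: pd.DataFrame,
    spec: ModelSpec,
    K: RelationshipMatrix,
    method: str = "ai",
    tol: float = 1e-8,
    max_iter: int = 500,
    start: tuple | None = None,
) -> VarianceComponents:
    """Estimate (sigma2_a, sigma2_day, sigma2_e) by AI- or EM-REML.

    Starting values default to an equal split of the sample phenotypic
    variance.  Components are floored at 1e-8 times the phenotypic variance;
    an AI update proposing a non-positive component falls back to an EM step
    for that iteration.  Non-convergence returns the last iterate with
    ``converged=False`` and a warning rather than raising.  When
    ``method='ai'`` the SE of h2 is attached via the delta method on the
    inverse AI matrix.
    """
    if method not in ("ai", "em"):
        raise ValueError(f"unknown REML method: {method!r}")
    y, X, W, _, _ = build_design(pheno, spec, K)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 records to separate the components")
    var_y = y.var(ddof=1)
    if var_y <= 0:
        raise ValueError("phenotype has zero variance; REML is degenerate")
    floor = 1e-8 * var_y

    use_day = X.shape[1] > 0
    Va = W @ K.values @ W.T
    Vday = X @ X.T if use_day else None
    parts = [Va, Vday, None]  # None = identity (residual)
    ones = np.ones(n)
    q_levels = np.array([K.n_animals, X.shape[1] if use_day else 1, n], dtype=float)
    active = [0, 1, 2] if use_day else [0, 2]

    if start is not None:
        theta = np.array(
            [start[0], start[1] if use_day else 0.0, start[2]], dtype=float
        )
    else:
        theta = np.full(3, var_y / len(active))
        if not use_day:
            theta[1] = 0.0

    def em_step(theta, traces, quads):
        new = theta.copy()
        for i in active:
            new[i] = theta[i] + theta[i] ** 2 * (quads[i] - traces[i]) / q_levels[i]
        return new

    converged = False
    logL = -np.inf
    ai_inv_full = None
    it = 0
    for it in range(1, max_iter + 1):
        logL, traces, rs, ws = _reml_quantities(theta, parts, y, ones)
        # y' P V_i P y = r_i' P y with Py = rs[2]
        quads = np.array(
            [float(rs[i] @ rs[2]) if rs[i] is not None else np.nan for i in range(3)]
        )

        if method == "ai":
            k = len(active)
            AI = np.empty((k, k))
            for ii, i in enumerate(active):
                for jj, j in enumerate(active):
                    AI[ii, jj] = 0.5 * float(rs[i] @ ws[j])
            AI = 0.5 * (AI + AI.T)
            score = np.array([-0.5 * (traces[i] - quads[i]) for i in active])
            try:
                if np.linalg.cond(AI) > 1e10:
                    raise np.linalg.LinAlgError("AI matrix ill-conditioned")
                delta = np.linalg.solve(AI, score)
                proposal = theta.copy()
                proposal[active] = theta[active] + delta
            except np.linalg.LinAlgError:
                proposal = np.full(3, -1.0)
            if np.all(proposal[active] > 0):
                new = proposal
                ai_inv_full = _embed_ai_inverse(AI, active)
            else:
                new = em_step(theta, traces, quads)
        else:
            new = em_step(theta, traces, quads)

        new[active] = np.maximum(new[active], floor)
        rel_change = np.max(
            np.abs(new[active] - theta[active]) / np.maximum(theta[active], floor)
        )
        theta = new
        if rel_change < tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"REML did not converge in {max_iter} iterations "
            f"(last relative change {rel_change:.2e})",
            stacklevel=2,
        )

    vc = VarianceComponents(
        sigma2_a=float(theta[0]),
        sigma2_day=float(theta[1]),
        sigma2_e=float(theta[2]),
        converged=converged,
        n_iterations=it,
        method=method,
        loglik=float(logL),
    )
    if method == "ai" and ai_inv_full is not None:
        vc.se_h2 = heritability_se(vc, ai_inv_full)
    return vc


def _embed_ai_inverse(AI: np.ndarray, active: list) -> np.ndarray:
    """Inverse AI matrix embedded into the full 3x3 (a, day, e) order."""
    inv = np.linalg.inv(AI)
    full = np.zeros((3, 3))
    for ii, i in enumerate(active):
        for jj, j in enumerate(active):
            full[i, j] = inv[ii, jj]
    return full
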