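"""Single-trait animal model: REML variance components and BLUP.

The model is

    y = X b + Z_h h + Z_a a + Z_d d + e

with fixed effects b (age-at-first-foaling class and the inbreeding
covariate), random herd (environmental unit x birth year, identity
covariance, variance s2_h), random additive genetic effects (pedigree
covariance A, variance s2_a), random dominance effects (covariance D,
variance s2_d) and residual (identity, s2_e).  Phenotypic variance is the
sum of the four components and h2 = s2_a / s2_p.

Estimation works on the marginal covariance of the phenotyped mares,

    V = S s2_h + A_m s2_a + D_m s2_d + I s2_e,

where A_m and D_m are the relationship matrices restricted to phenotyped
mares and S the herd-block indicator product.  This is exactly equivalent
to REML on the full mixed-model equations (Gaussian marginalization over
unphenotyped levels) and keeps the per-iteration cost at one n x n
factorization.  Updates are EM steps in the V-parameterization with an
average-information (AI) acceleration step that is only accepted when it
does not decrease the restricted log-likelihood, so logL is non-decreasing
over the whole iteration history.

BLUP solutions for *all* pedigree animals (including unphenotyped
ancestors) come from Henderson's mixed-model equations built sparsely with
A^{-1}; dominance levels are the phenotyped mares (marginal-equivalent for
the remaining effects).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as la
import scipy.sparse as sp

from .kinship import KinshipMatrices

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "reml_estimate",
    "heritability",
    "se_heritability",
    "build_mme",
    "solve_blup",
]


@dataclass
class ModelSpec:
    """Which terms enter the animal model (fixed part: intercept + AF + F)."""

    include_herd: bool = True
    include_additive: bool = True
    include_dominance: bool = True
    use_af: bool = True
    use_inbreeding: bool = True


@dataclass
class VarianceComponents:
    var_herd: float
    var_additive: float
    var_dominance: float
    var_residual: float
    logL: float = np.nan
    aic: float = np.nan
    converged: bool = False
    n_iterations: int = 0
    se_h2: float = np.nan
    logL_history: list = field(default_factory=list)
    cov_components: np.ndarray | None = None   # sampling cov, order = component_names
    component_names: tuple = ()

    @property
    def var_phenotypic(self) -> float:
        return self.var_herd + self.var_additive + self.var_dominance + self.var_residual

    @property
    def h2(self) -> float:
        vp = self.var_phenotypic
        return self.var_additive / vp if vp > 0 else 0.0

    @property
    def dominance_ratio(self) -> float:
        vp = self.var_phenotypic
        return self.var_dominance / vp if vp > 0 else 0.0


def _fixed_design(ph: pd.DataFrame, model: ModelSpec) -> np.ndarray:
    n = len(ph)
    cols = [np.ones(n)]
    if model.use_af and "af_class" in ph and ph["af_class"].nunique() > 1:
        cols.append((ph["af_class"].to_numpy() == 4).astype(float))
    if model.use_inbreeding and "F" in ph and np.ptp(ph["F"].to_numpy()) > 0:
        cols.append(ph["F"].to_numpy(float))
    return np.column_stack(cols)


def _herd_codes(ph: pd.DataFrame) -> tuple[np.ndarray, list]:
    eu_by = list(zip(ph["eu_id"].astype(int), ph["birth_year"].astype(int)))
    levels = sorted(set(eu_by))
    lut = {lv: i for i, lv in enumerate(levels)}
    return np.array([lut[x] for x in eu_by]), levels


@dataclass
class _Design:
    y: np.ndarray
    X: np.ndarray
    parts: list            # (name, dense n x n covariance structure, q for EM)
    h_codes: np.ndarray | None
    h_levels: list
    m_idx: np.ndarray      # row of each mare in the pedigree/A
    A_m: np.ndarray | None
    D_m: np.ndarray | None


def _build_design(
    ph: pd.DataFrame,
    kinship: KinshipMatrices,
    model: ModelSpec,
    trait: str,
    D_m: np.ndarray | None = None,
) -> _Design:
    missing = [m for m in ph["mare_id"] if m not in kinship.index]
    if missing:
        raise ValueError(f"phenotyped mares not in pedigree: {missing[:5]}")
    y = ph[trait].to_numpy(float)
    n = len(y)
    X = _fixed_design(ph, model)
    m_idx = np.array([kinship.index[m] for m in ph["mare_id"]], dtype=int)
    parts = []
    h_codes, h_levels = (None, [])
    if model.include_herd:
        h_codes, h_levels = _herd_codes(ph)
        S = (h_codes[:, None] == h_codes[None, :]).astype(float)
        parts.append(("herd", S, len(h_levels)))
    A_m = None
    if model.include_additive:
        A_m = kinship.A[np.ix_(m_idx, m_idx)]
        parts.append(("additive", A_m, n))
    if model.include_dominance:
        if D_m is None:
            D_m = kinship.subset_D(ph["mare_id"].to_numpy())
        parts.append(("dominance", D_m, n))
    parts.append(("residual", np.eye(n), n))
    return _Design(y, X, parts, h_codes, h_levels, m_idx, A_m, D_m)


def _logL_and_P(theta, des: _Design):
    n = len(des.y)
    V = np.zeros((n, n))
    for th, (_, M, _) in zip(theta, des.parts):
        V += th * M
    c, low = la.cho_factor(V, lower=True, check_finite=False)
    logdetV = 2.0 * np.sum(np.log(np.diag(c)))
    Vinv = la.cho_solve((c, low), np.eye(n), check_finite=False)
    W = Vinv @ des.X
    XtVX = des.X.T @ W
    cx = la.cho_factor(XtVX, check_finite=False)
    logdetX = 2.0 * np.sum(np.log(np.diag(cx[0])))
    P = Vinv - W @ la.cho_solve(cx, W.T, check_finite=False)
    Py = P @ des.y
    p = des.X.shape[1]
    logL = -0.5 * (
        logdetV + logdetX + float(des.y @ Py) + (n - p) * np.log(2.0 * np.pi)
    )
    return logL, P, Py


def reml_estimate(
    phenotypes: pd.DataFrame,
    kinship: KinshipMatrices,
    model: ModelSpec | None = None,
    trait: str = "value",
    init: dict | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    D_m: np.ndarray | None = None,
    n_em_warmup: int = 2,
    callback=None,
) -> VarianceComponents:
    """Estimate variance components by EM-REML with AI acceleration.

    ``phenotypes`` needs columns ``mare_id``, the trait column, ``af_class``,
    ``F``, ``eu_id``, ``birth_year``.  ``init`` optionally maps component
    names (herd/additive/dominance/residual) to starting variances (> 0).
    Components are floored at 1e-8 of the phenotypic variance; convergence
    is a maximum relative parameter change below ``tol``.
    """
    model = model or ModelSpec()
    des = _build_design(phenotypes, kinship, model, trait, D_m)
    names = [name for name, _, _ in des.parts]
    vy = float(np.var(des.y, ddof=1))
    if vy == 0.0:
        raise ValueError("phenotypes are constant; variance components undefined")
    default_frac = {"herd": 0.05, "additive": 0.30, "dominance": 0.10, "residual": 0.55}
    theta = np.array(
        [
            (init[name] if init and name in init else default_frac[name] * vy)
            for name in names
        ]
    )
    if np.any(theta <= 0):
        raise ValueError("initial variances must be > 0")
    floor = 1e-8 * vy
    qs = np.array([q for _, _, q in des.parts], float)

    history: list[float] = []
    converged = False
    logL, P, Py = _logL_and_P(theta, des)
    history.append(logL)
    it = 0
    AI = None
    for it in range(1, max_iter + 1):
        trPV = np.array([float(np.sum(P * M)) for _, M, _ in des.parts])
        u = [M @ Py for _, M, _ in des.parts]           # V_i P y
        yPVPy = np.array([float(Py @ ui) for ui in u])
        grad = 0.5 * (yPVPy - trPV)
        Pu = [P @ ui for ui in u]
        k = len(theta)
        AI = np.empty((k, k))
        for i in range(k):
            for j in range(i, k):
                AI[i, j] = AI[j, i] = 0.5 * float(u[i] @ Pu[j])

        theta_em = theta + (theta**2 / qs) * (yPVPy - trPV)
        theta_em = np.maximum(theta_em, floor)

        accepted = None
        full_ai = False
        step_kind = "EM"
        if it > n_em_warmup:
            # AI (Newton) step on the active components; components parked
            # at the floor with a negative gradient are left there so they
            # cannot corrupt the system.  The pseudo-inverse tolerates the
            # near-singular AI matrix of a weakly identified dominance/
            # residual split.  The step is clipped at the variance floor
            # and backtracked on a likelihood decrease before falling back
            # to the (monotone) EM update.
            active = (theta > 10 * floor) | (grad > 0)
            step = np.zeros(k)
            if active.any():
                sub = np.ix_(active, active)
                step[active] = (
                    np.linalg.pinv(AI[sub], rcond=1e-10, hermitian=True)
                    @ grad[active]
                )
            for frac in (1.0, 0.5, 0.25, 0.1, 0.05, 0.02):
                cand = np.maximum(theta + frac * step, floor)
                logL_ai, P_ai, Py_ai = _logL_and_P(cand, des)
                if logL_ai >= logL - 1e-8:
                    accepted = (cand, logL_ai, P_ai, Py_ai)
                    full_ai = frac == 1.0
                    step_kind = f"AI{frac}"
                    break
        if accepted is None:
            logL_new, P_new, Py_new = _logL_and_P(theta_em, des)
            accepted = (theta_em, logL_new, P_new, Py_new)

        new_theta, new_logL, P, Py = accepted
        if callback is not None:
            callback(it, step_kind, new_theta, new_logL, grad)
        rel = np.max(np.abs(new_theta - theta) / np.maximum(theta, floor))
        dlogL = new_logL - logL
        theta, logL = new_theta, new_logL
        history.append(logL)
        # parameter stability, or a flat likelihood at a full Newton step
        # (dominance/residual can form a near-ridge when D is close to
        # identity, where parameters drift while logL is maximal)
        if rel < tol or (full_ai and 0 <= dlogL < 1e-9 * max(abs(logL), 1.0)):
            converged = True
            break

    comp = dict(zip(names, theta))
    vc = VarianceComponents(
        var_herd=comp.get("herd", 0.0),
        var_additive=comp.get("additive", 0.0),
        var_dominance=comp.get("dominance", 0.0),
        var_residual=comp["residual"],
        logL=logL,
        converged=converged,
        n_iterations=it,
        logL_history=history,
        component_names=tuple(names),
    )
    vc.aic = -2.0 * logL + 2.0 * len(names)
    try:
        vc.cov_components = la.inv(AI)
    except (la.LinAlgError, TypeError):
        vc.cov_components = None
    vc.se_h2 = se_heritability(vc)
    return vc


def heritability(vc: VarianceComponents) -> float:
    """Narrow-sense heritability: additive over total phenotypic variance."""
    if vc.var_phenotypic <= 0:
        raise ValueError("phenotypic variance must be > 0")
    return vc.h2


def se_heritability(vc: VarianceComponents, cov: np.ndarray | None = None) -> float:
    """Delta-method standard error of h2 = s2_a / s2_p.

    Uses the sampling (co)variances of the variance components:
    ``se = h2 * sqrt(Var(s2_a)/s2_a^2 + Var(s2_p)/s2_p^2
                     - 2 Cov(s2_a, s2_p)/(s2_a s2_p))``.
    Returns 0 when the additive variance or all sampling variances are zero.
    """
    if cov is None:
        cov = vc.cov_components
    sa, sp_ = vc.var_additive, vc.var_phenotypic
    if sa == 0.0 or sp_ <= 0.0:
        return 0.0
    if cov is None:
        return np.nan
    names = list(vc.component_names)
    if "additive" not in names:
        return 0.0
    ia = names.index("additive")
    var_a = cov[ia, ia]
    var_p = float(np.sum(cov))
    cov_ap = float(np.sum(cov[ia, :]))
    arg = var_a / sa**2 + var_p / sp_**2 - 2.0 * cov_ap / (sa * sp_)
    return vc.h2 * np.sqrt(max(arg, 0.0))


_LAMBDA_CAP = 1e12


def build_mme(
    phenotypes: pd.DataFrame,
    kinship: KinshipMatrices,
    vc: VarianceComponents,
    model: ModelSpec | None = None,
    trait: str = "value",
    D_m: np.ndarray | None = None,
):
    """Henderson mixed-model equations as a sparse symmetric system.

    Random-effect blocks carry the variance ratios lambda = s2_e / s2_u on
    their covariance-inverse structure (identity for herd, A^{-1} over the
    whole pedigree for additive, D_m^{-1} over phenotyped mares for
    dominance).  Returns ``(C, rhs, layout)`` where layout maps block names
    to column slices plus level identifiers.
    """
    model = model or ModelSpec()
    des = _build_design(phenotypes, kinship, model, trait, D_m)
    n = len(des.y)
    blocks = [sp.csr_matrix(des.X)]
    layout = {"fixed": slice(0, des.X.shape[1])}
    offset = des.X.shape[1]
    if model.include_herd:
        q = len(des.h_levels)
        Zh = sp.coo_matrix(
            (np.ones(n), (np.arange(n), des.h_codes)), shape=(n, q)
        ).tocsr()
        blocks.append(Zh)
        layout["herd"] = slice(offset, offset + q)
        layout["herd_levels"] = des.h_levels
        offset += q
    if model.include_additive:
        n_ped = len(kinship.ids)
        Za = sp.coo_matrix(
            (np.ones(n), (np.arange(n), des.m_idx)), shape=(n, n_ped)
        ).tocsr()
        blocks.append(Za)
        layout["additive"] = slice(offset, offset + n_ped)
        layout["animal_ids"] = kinship.ids
        offset += n_ped
    if model.include_dominance:
        Zd = sp.identity(n, format="csr")
        blocks.append(Zd)
        layout["dominance"] = slice(offset, offset + n)
        offset += n

    Z = sp.hstack(blocks, format="csr")
    rhs = Z.T @ des.y

    def lam(s2_u):
        return min(vc.var_residual / max(s2_u, 1e-300), _LAMBDA_CAP)

    gblocks = [sp.csr_matrix((des.X.shape[1], des.X.shape[1]))]
    if model.include_herd:
        q = len(des.h_levels)
        gblocks.append(lam(vc.var_herd) * sp.identity(q, format="csr"))
    if model.include_additive:
        gblocks.append(lam(vc.var_additive) * kinship.A_inv)
    if model.include_dominance:
        gblocks.append(sp.csr_matrix(lam(vc.var_dominance) * la.inv(des.D_m)))
    C = (Z.T @ Z + sp.block_diag(gblocks, format="csr")).tocsr()
    layout["n_equations"] = offset
    layout["mare_ids"] = phenotypes["mare_id"].to_numpy()
    return C, rhs, layout


def solve_blup(
    phenotypes: pd.DataFrame,
    kinship: KinshipMatrices,
    vc: VarianceComponents,
    model: ModelSpec | None = None,
    trait: str = "value",
    D_m: np.ndarray | None = None,
    dense_cutoff: int = 20000,
) -> dict:
    """Solve the MME; EBVs cover every pedigree animal.

    Returns a dict with ``beta`` (fixed-effect solutions), ``ebv``
    (pd.Series over all pedigree animals), ``herd`` and ``dominance``
    solutions, and the relative residual norm of the solved system.
    """
    model = model or ModelSpec()
    C, rhs, layout = build_mme(phenotypes, kinship, vc, model, trait, D_m)
    dim = layout["n_equations"]
    if dim <= dense_cutoff:
        Cd = C.toarray()
        sol = la.solve(Cd, rhs, assume_a="sym")
    else:
        sol = sp.linalg.spsolve(C.tocsc(), rhs)
    resid = float(np.linalg.norm(C @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300))
    if resid > 1e-6:
        raise RuntimeError(f"MME solve failed: relative residual {resid:.2e}")
    out = {"beta": sol[layout["fixed"]], "residual_norm": resid, "layout": layout}
    if model.include_herd:
        out["herd"] = dict(zip(layout["herd_levels"], sol[layout["herd"]]))
    if model.include_additive:
        out["ebv"] = pd.Series(sol[layout["additive"]], index=layout["animal_ids"])
    if model.include_dominance:
        out["dominance"] = pd.Series(sol[layout["dominance"]], index=layout["mare_ids"])
    return out
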