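"""Projection of foal production to the 6-season endpoint and LFR traits.

Two projection methods, both trained on complete (6-season) careers and
applied to mares with k = 3, 4 or 5 registered seasons:

* ``coefficients`` — additive two-factor fixed-effects fit of the foal
  count at season 6 on the foal-count class after k seasons plus the
  age-at-first-foaling (AF) class; predictions are the fitted cell values.
* ``equations`` — least-squares regression of the foal count at season 6
  on the numeric foal count after k seasons plus an AF contrast.

Predictions are kept fractional and clamped to ``[foals_after(k), 6]``.
The lifetime foaling rate is ``LFR = foals6 / 6``; the arcsine expression
is ``arcsin(p)`` in radians (``arcsin(sqrt(p))`` available via a flag).

Validation statistics compare actual and predicted foal counts:
``PSB = 100 * (y-yhat)'(y-yhat) / y'y``, ``MAD = mean |y-yhat|`` and
``SDR = sd(y-yhat)`` (n-1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .studbook import MareCareer

__all__ = [
    "ProjectionFit",
    "ValidationStats",
    "fit_projection",
    "project_foals",
    "compute_lfr",
    "arcsine_transform",
    "validation_stats",
    "validate_projection",
    "assemble_phenotypes",
    "TRAITS",
]

TRAITS = ("lfr_c", "lfr_e", "arcsine_c", "arcsine_e")


@dataclass
class ProjectionFit:
    """Trained predictor of foals at season 6 from a k-season career."""

    method: str                         # 'coefficients' | 'equations'
    k: int
    intercept: float = 0.0
    slope: float = 0.0                  # equations: coefficient on foals_after(k)
    af4: float = 0.0                    # contrast of AF class 4 vs 3
    class_effects: dict = field(default_factory=dict)  # coefficients: foal-class -> effect
    fallback: tuple = (0.0, 0.0)        # (intercept, slope) over class effects
    n_training: int = 0

    def predict_raw(self, foals_k: int, af_class: int) -> float:
        af_term = self.af4 if af_class == 4 else 0.0
        if self.method == "equations":
            return self.intercept + self.slope * foals_k + af_term
        if foals_k in self.class_effects:
            return self.intercept + self.class_effects[foals_k] + af_term
        b0, b1 = self.fallback
        return b0 + b1 * foals_k + af_term


@dataclass
class ValidationStats:
    psb: float
    mad: float
    sdr: float
    k: int = 0
    method: str = ""


def _design(foals_k, af, method: str, k: int):
    n = len(foals_k)
    af4 = (np.asarray(af) == 4).astype(float)
    two_classes = 0 < af4.sum() < n
    if method == "equations":
        cols = [np.ones(n), np.asarray(foals_k, float)]
        if two_classes:
            cols.append(af4)
        return np.column_stack(cols), two_classes, None
    levels = sorted(set(int(v) for v in foals_k))
    cols = [np.ones(n)]
    for lev in levels[1:]:                       # first level absorbed in intercept
        cols.append((np.asarray(foals_k) == lev).astype(float))
    if two_classes:
        cols.append(af4)
    return np.column_stack(cols), two_classes, levels


def fit_projection(training: list[MareCareer], method: str, k: int) -> ProjectionFit:
    """Fit a projection of foals at season 6 from the first k seasons."""
    if method not in ("coefficients", "equations"):
        raise ValueError(f"unknown method {method!r}")
    if k not in (3, 4, 5):
        raise ValueError("k must be in {3, 4, 5}")
    short = [c for c in training if c.n_seasons < 6]
    if short:
        raise ValueError(f"{len(short)} training careers have fewer than 6 seasons")
    y = np.array([c.foals_after(6) for c in training], float)
    fk = np.array([c.foals_after(k) for c in training], float)
    af = np.array([c.af_class for c in training])

    X, two_classes, levels = _design(fk, af, method, k)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)

    fit = ProjectionFit(method=method, k=k, n_training=len(y))
    if method == "equations":
        fit.intercept, fit.slope = beta[0], beta[1]
        fit.af4 = beta[2] if two_classes else 0.0
    else:
        fit.intercept = beta[0]
        effects = {levels[0]: 0.0}
        for i, lev in enumerate(levels[1:]):
            effects[lev] = beta[1 + i]
        fit.class_effects = effects
        fit.af4 = beta[1 + len(levels) - 1] if two_classes else 0.0
        # linear fallback across observed class effects, for unseen classes
        xs = np.array(sorted(effects), float)
        ys = np.array([fit.intercept + effects[x] for x in sorted(effects)])
        if len(xs) > 1:
            b1, b0 = np.polyfit(xs, ys, 1)
        else:
            b0, b1 = ys[0], 0.0
        fit.fallback = (b0, b1)
    return fit


def project_foals(career: MareCareer, fit: ProjectionFit) -> float:
    """Predicted (fractional) foals at season 6, clamped to [foals_k, 6]."""
    if career.n_seasons != fit.k:
        raise ValueError(
            f"career has {career.n_seasons} seasons but fit horizon is {fit.k}"
        )
    fk = career.foals_after(fit.k)
    pred = fit.predict_raw(fk, career.af_class)
    return float(np.clip(pred, fk, 6.0))


def compute_lfr(foals6) -> np.ndarray | float:
    """Lifetime foaling rate: foals at season 6 divided by 6 opportunities."""
    arr = np.asarray(foals6, float)
    if np.any(arr < 0) or np.any(arr > 6):
        raise ValueError("foals6 must lie in [0, 6]")
    out = arr / 6.0
    return float(out) if np.isscalar(foals6) else out


def arcsine_transform(lfr, sqrt_variant: bool = False):
    """arcsin(p) in radians (or arcsin(sqrt(p)) when sqrt_variant)."""
    arr = np.asarray(lfr, float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("lfr must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr)) if sqrt_variant else np.arcsin(arr)
    return float(out) if np.isscalar(lfr) else out


def validation_stats(actual, predicted, k: int = 0, method: str = "") -> ValidationStats:
    """PSB, MAD and SDR of predicted vs actual foal counts."""
    y = np.asarray(actual, float)
    yhat = np.asarray(predicted, float)
    if y.shape != yhat.shape or y.size == 0:
        raise ValueError("actual and predicted must be equal-length and non-empty")
    denom = float(y @ y)
    if denom == 0.0:
        raise ValueError("PSB undefined: actuals are all zero")
    r = y - yhat
    psb = 100.0 * float(r @ r) / denom
    mad = float(np.mean(np.abs(r)))
    sdr = float(np.std(r, ddof=1)) if y.size > 1 else 0.0
    return ValidationStats(psb=psb, mad=mad, sdr=sdr, k=k, method=method)


def validate_projection(
    complete: list[MareCareer],
    rng: np.random.Generator,
    holdout_fraction: float = 0.5,
) -> pd.DataFrame:
    """Out-of-sample predictive ability of both methods at k = 3, 4, 5.

    Complete careers are split once into a fit set and a holdout set; for
    each horizon the projections are trained on the fit set and scored on
    the holdout's actual foal counts.  Returns a tidy frame with columns
    method, k, psb, mad, sdr.
    """
    idx = rng.permutation(len(complete))
    n_hold = int(round(holdout_fraction * len(complete)))
    hold = [complete[i] for i in idx[:n_hold]]
    fit_set = [complete[i] for i in idx[n_hold:]]
    if not hold or not fit_set:
        raise ValueError("not enough complete careers to split")
    rows = []
    for method in ("coefficients", "equations"):
        for k in (3, 4, 5):
            fit = fit_projection(fit_set, method, k)
            truncated = [
                MareCareer(
                    c.mare_id, c.birth_year, c.eu_id, c.af_class, c.events[:k], k
                )
                for c in hold
            ]
            yhat = [project_foals(t, fit) for t in truncated]
            y = [c.foals_after(6) for c in hold]
            st = validation_stats(y, yhat, k=k, method=method)
            rows.append(
                {"method": method, "k": k, "psb": st.psb, "mad": st.mad, "sdr": st.sdr}
            )
    return pd.DataFrame(rows)


def assemble_phenotypes(
    careers: list[MareCareer],
    fits: dict,
    inbreeding: pd.Series | None = None,
    sqrt_variant: bool = False,
) -> pd.DataFrame:
    """Build the four LFR trait expressions for every mare with >= 3 seasons.

    ``fits`` maps ``(method, k)`` -> ProjectionFit for method in
    {'coefficients', 'equations'} and k in {3, 4, 5}.  Mares with 6
    registered seasons use their actual foal count (source 'actual'); the
    rest are projected with the fit matching their season count (source
    'projected').  Returns one row per mare with columns ``lfr_c``,
    ``lfr_e``, ``arcsine_c``, ``arcsine_e``, fixed effects and metadata.
    """
    rows = []
    seen = set()
    for c in careers:
        if c.mare_id in seen:
            raise ValueError(f"mare {c.mare_id} appears twice")
        seen.add(c.mare_id)
        if c.n_seasons >= 6:
            foals_c = foals_e = float(c.foals_after(6))
            source = "actual"
        elif c.n_seasons >= 3:
            k = c.n_seasons
            foals_c = project_foals(c, fits[("coefficients", k)])
            foals_e = project_foals(c, fits[("equations", k)])
            source = "projected"
        else:
            raise ValueError(f"mare {c.mare_id} has fewer than 3 seasons")
        lfr_c = compute_lfr(foals_c)
        lfr_e = compute_lfr(foals_e)
        rows.append(
            {
                "mare_id": c.mare_id,
                "lfr_c": lfr_c,
                "lfr_e": lfr_e,
                "arcsine_c": arcsine_transform(lfr_c, sqrt_variant),
                "arcsine_e": arcsine_transform(lfr_e, sqrt_variant),
                "source": source,
                "af_class": c.af_class,
                "eu_id": c.eu_id,
                "birth_year": c.birth_year,
                "F": 0.0,
            }
        )
    df = pd.DataFrame(rows)
    if inbreeding is not None:
        df["F"] = inbreeding.reindex(df["mare_id"]).fillna(0.0).to_numpy()
    return df
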