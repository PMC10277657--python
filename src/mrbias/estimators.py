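"""Summary-data Mendelian randomisation estimators and diagnostics.

All estimators operate on a :class:`~mrbias.gwas_io.HarmonisedSet` of L
instruments with exposure effects ``bx`` (se ``sx``) and outcome effects
``by`` (se ``sy``).  The inverse-variance-weighted (IVW) estimate is the
slope of the weighted regression of ``by`` on ``bx`` through the origin with
weights 1/sy^2; its default standard error uses multiplicative random
effects, i.e. the fixed-effect se inflated by sqrt(max(1, Q/(L-1))) where Q
is Cochran's heterogeneity statistic.  MR-Egger frees the intercept (a test
of directional pleiotropy) and the weighted median is consistent when
instruments carrying at least half the weight are valid.

Wald-ratio variances are first order (exposure-side uncertainty ignored) —
adequate for strong instruments, and flagged as a limitation when mean F is
low, as in reverse-direction "no relevance" analyses.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import stats as _st

from .gwas_io import HarmonisedSet

#: 95% normal quantile used for all confidence intervals.
Z95 = 1.959964


class InsufficientInstrumentsError(ValueError):
    pass


@dataclass
class MREstimate:
    """A causal-effect estimate from one method on one instrument set."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    scale: str
    odds_ratio: float | None = None  # exp(beta) when the outcome is binary

    def to_dict(self) -> dict:
        return {
            "method": self.method, "beta": self.beta, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "pvalue": self.pvalue, "n_snps": self.n_snps, "scale": self.scale,
            "odds_ratio": self.odds_ratio,
        }


@dataclass
class PleiotropyDiagnostics:
    Q: float
    Q_df: int
    Q_pvalue: float
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pvalue: float | None = None

    def to_dict(self) -> dict:
        return {
            "Q": self.Q, "Q_df": self.Q_df, "Q_pvalue": self.Q_pvalue,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_se": self.egger_intercept_se,
            "egger_intercept_pvalue": self.egger_intercept_pvalue,
        }


@dataclass
class InstrumentStrength:
    F: np.ndarray = field(repr=False)
    mean_F: float = float("nan")
    total_R2: float | None = None


class DifferenceTest(NamedTuple):
    delta: float
    z: float
    pvalue: float


def _finish(method: str, beta: float, se: float, n_snps: int,
            h: HarmonisedSet) -> MREstimate:
    p = float(2.0 * _st.norm.sf(abs(beta) / se)) if se > 0 else float("nan")
    return MREstimate(
        method=method, beta=float(beta), se=float(se),
        ci_low=float(beta - Z95 * se), ci_high=float(beta + Z95 * se),
        pvalue=p, n_snps=int(n_snps), scale=h.scale,
        odds_ratio=float(np.exp(beta)) if h.outcome_type == "binary" else None,
    )


def wald_ratio(bx: float, se_x: float, by: float, se_y: float) -> tuple[float, float]:
    """Single-instrument ratio estimate: (by/bx, |se_y/bx|), first order."""
    if bx == 0:
        raise ZeroDivisionError("exposure effect is zero; Wald ratio undefined")
    return by / bx, abs(se_y / bx)


def ivw(h: HarmonisedSet, random_effects: bool = True
        ) -> tuple[MREstimate, PleiotropyDiagnostics]:
    """IVW estimate with fixed-effect or multiplicative-random-effects se.

    The random-effects inflation factor is floored at 1, so the MRE se is
    never smaller than the fixed-effect se and the two coincide whenever
    Q/(L-1) <= 1.
    """
    L = len(h)
    if L < 1:
        raise InsufficientInstrumentsError("IVW needs at least one instrument")
    bx, by, sy = h.beta_exposure, h.beta_outcome, h.se_outcome
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    if denom == 0:
        raise ZeroDivisionError("all exposure effects are zero")
    beta = float(np.sum(w * bx * by)) / denom
    se_fixed = denom ** -0.5
    Q = float(np.sum(w * (by - beta * bx) ** 2))
    df = L - 1
    Q_p = float(_st.chi2.sf(Q, df)) if df > 0 else float("nan")
    scale_fac = np.sqrt(max(1.0, Q / df)) if (random_effects and df > 0) else 1.0
    est = _finish("ivw_mre" if random_effects else "ivw_fe",
                  beta, se_fixed * scale_fac, L, h)
    return est, PleiotropyDiagnostics(Q=Q, Q_df=df, Q_pvalue=Q_p)


def mr_egger(h: HarmonisedSet, fit_intercept: bool = True
             ) -> tuple[MREstimate, PleiotropyDiagnostics]:
    """MR-Egger: weighted regression with a free intercept.

    Instruments are first oriented so every exposure effect is positive
    (rows with bx<0 have both effects negated; bx==0 rows are dropped).
    Slope and intercept standard errors are inflated multiplicatively by
    sqrt(max(1, Q/(L-2))).  With ``fit_intercept=False`` the fit reduces
    algebraically to fixed-effect IVW (debugging identity).
    """
    keep = h.beta_exposure != 0
    bx = np.abs(h.beta_exposure[keep])
    flip = np.sign(h.beta_exposure[keep])
    by = h.beta_outcome[keep] * flip
    sy = h.se_outcome[keep]
    L = int(keep.sum())
    if L < 3:
        raise InsufficientInstrumentsError("MR-Egger needs at least 3 instruments")
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(L), bx]) if fit_intercept else bx[:, None]
    XtW = X.T * w
    cov = np.linalg.inv(XtW @ X)
    coef = cov @ (XtW @ by)
    resid = by - X @ coef
    Q = float(np.sum(w * resid**2))
    df = L - X.shape[1]
    scale_fac = np.sqrt(max(1.0, Q / df)) if df > 0 else 1.0
    ses = np.sqrt(np.diag(cov)) * scale_fac
    if fit_intercept:
        intercept, slope = coef
        se_int, se_slope = ses
        int_p = float(2.0 * _st.norm.sf(abs(intercept) / se_int))
        diag = PleiotropyDiagnostics(
            Q=Q, Q_df=df, Q_pvalue=float(_st.chi2.sf(Q, df)),
            egger_intercept=float(intercept), egger_intercept_se=float(se_int),
            egger_intercept_pvalue=int_p)
    else:
        slope, se_slope = coef[0], ses[0]
        diag = PleiotropyDiagnostics(Q=Q, Q_df=df,
                                     Q_pvalue=float(_st.chi2.sf(Q, df)))
    return _finish("egger", slope, se_slope, L, h), diag


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, v))


def weighted_median(h: HarmonisedSet, n_boot: int = 1000, seed: int | None = None
                    ) -> MREstimate:
    """Weighted-median estimate with a parametric-bootstrap standard error.

    Ratio-level inverse-variance weights (first order: bx^2/sy^2) define the
    standardised cumulative weight s_i = (sum_{j<=i} w_j - w_i/2) / sum w;
    the estimate interpolates the ordered ratios at s = 0.5.  The bootstrap
    redraws (bx, by) from their sampling normals ``n_boot`` times; ``seed``
    is required for reproducibility.
    """
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed")
    L = len(h)
    if L < 3:
        raise InsufficientInstrumentsError("weighted median needs >= 3 instruments")
    bx, sx = h.beta_exposure, h.se_exposure
    by, sy = h.beta_outcome, h.se_outcome
    if np.any(bx == 0):
        raise ZeroDivisionError("zero exposure effect in weighted median input")
    ratios = by / bx
    weights = bx**2 / sy**2
    beta = _weighted_median(ratios, weights)

    rng = np.random.default_rng(seed)
    bx_b = bx + sx * rng.standard_normal((n_boot, L))
    by_b = by + sy * rng.standard_normal((n_boot, L))
    bx_b[bx_b == 0] = np.finfo(float).tiny
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = _weighted_median(by_b[i] / bx_b[i], bx_b[i] ** 2 / sy**2)
    se = float(np.std(boots, ddof=1))
    return _finish("weighted_median", beta, se, L, h)


def instrument_strength(h: HarmonisedSet) -> InstrumentStrength:
    """Per-variant F statistics and variance explained.

    F_j = (bx_j/sx_j)^2; for a standardised quantitative exposure the
    per-variant variance explained is R2_j = 2*eaf_j*(1-eaf_j)*bx_j^2 and
    total_R2 sums it over variants with a known frequency (None when no
    frequency is available).
    """
    F = (h.beta_exposure / h.se_exposure) ** 2
    eaf = h.eaf_exposure
    have = np.isfinite(eaf)
    if have.any():
        r2 = 2.0 * eaf[have] * (1.0 - eaf[have]) * h.beta_exposure[have] ** 2
        total = float(np.sum(r2))
    else:
        total = None
    return InstrumentStrength(F=F, mean_F=float(np.mean(F)), total_R2=total)


def estimate_difference(e1: MREstimate, e2: MREstimate) -> DifferenceTest:
    """Two-sided z test of beta1 - beta2, treating the estimates as
    independent (approximate when the underlying samples share controls)."""
    if e1.scale != e2.scale:
        raise ValueError(f"estimates on different scales: {e1.scale} vs {e2.scale}")
    delta = e1.beta - e2.beta
    se = np.sqrt(e1.se**2 + e2.se**2)
    z = delta / se
    return DifferenceTest(delta=float(delta), z=float(z),
                          pvalue=float(2.0 * _st.norm.sf(abs(z))))
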