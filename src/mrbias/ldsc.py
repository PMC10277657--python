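"""Heritability and cross-trait genetic correlation by LD score regression.

Under a polygenic model the expected association chi-square of variant j is
E[chi2_j] = 1 + N*h2*l_j/M, where l_j is the variant's LD score and M the
number of reference variants; regressing chi2 on N*l/M therefore estimates
the (observed-scale) SNP heritability h2 as the slope, while the intercept
absorbs confounding inflation.  The cross-trait analogue regresses the
z-score product z1*z2 on sqrt(N1*N2)*l/M to estimate the genetic covariance,
and the genetic correlation is rg = gcov/sqrt(h2_1*h2_2).  Standard errors
come from a delete-one block jackknife over contiguous variant blocks.

A screen of |rg| between a disease GWAS and candidate predictors of
selection (education, smoking, income analogues) flags outcome definitions
whose summary statistics may be picking up who gets tested rather than the
disease itself — with the caveat that a true causal path produces rg too.

When every supplied LD score is identical (e.g. the unlinked-variant
simulator, where l_j = 1 for all j), a free intercept is unidentifiable;
the fit then constrains the chi-square intercept to 1 and the cross-trait
intercept to 0, which is exact for non-overlapping samples with no
confounding inflation.  The result records which mode was used.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _st

from .gwas_io import SummaryStats, _COMPLEMENT

#: reporting window for rg: sampling noise can push the point estimate
#: outside [-1, 1]; values beyond +-1.25 are clipped and flagged.
RG_REPORT_LIMIT = 1.25


class InsufficientVariantsError(ValueError):
    """Too few overlapping variants to attempt LD score regression."""


@dataclass
class LDScoreTable:
    """Per-variant LD scores plus the reference panel size M."""

    scores: pd.DataFrame  # columns: variant_id, ld_score
    M: int

    def __post_init__(self) -> None:
        need = {"variant_id", "ld_score"}
        if not need.issubset(self.scores.columns):
            raise ValueError(f"LD score table needs columns {sorted(need)}")
        if (self.scores["ld_score"] < 0).any():
            raise ValueError("negative LD scores")
        if self.M < len(self.scores):
            raise ValueError("M smaller than the number of scored variants")


def read_ld_scores(path, M: int | None = None) -> LDScoreTable:
    df = pd.read_csv(path, sep="\t")
    return LDScoreTable(scores=df[["variant_id", "ld_score"]], M=M or len(df))


def write_ld_scores(table: LDScoreTable, path) -> None:
    table.scores.to_csv(path, sep="\t", index=False)


@dataclass
class H2Result:
    h2: float
    intercept: float
    h2_se: float
    n_variants: int
    mode: str  # "free" | "constrained"


@dataclass
class GeneticCorrelation:
    rg: float | None
    rg_se: float | None
    rg_pvalue: float | None
    h2_trait1: float
    h2_trait2: float
    gcov: float | None
    intercept1: float
    intercept2: float
    gcov_intercept: float | None
    n_variants: int
    out_of_range: bool = False
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "rg": self.rg, "rg_se": self.rg_se, "rg_pvalue": self.rg_pvalue,
            "h2_trait1": self.h2_trait1, "h2_trait2": self.h2_trait2,
            "gcov": self.gcov, "intercept1": self.intercept1,
            "intercept2": self.intercept2, "gcov_intercept": self.gcov_intercept,
            "n_variants": self.n_variants, "out_of_range": self.out_of_range,
            "note": self.note,
        }


def default_n_blocks(n: int) -> int:
    """200 equal-count blocks, fewer for small variant sets."""
    b = 200 if n >= 2000 else max(20, n // 10)
    return int(np.clip(b, 2, n))


class _BlockedFit:
    """Weighted line fit y ~ x with delete-one-block jackknife replicates.

    ``constrain`` fixes the intercept at the given value; otherwise both
    slope and intercept are free.  All quantities are closed forms in the
    per-block weighted sums, so block deletion is O(1).
    """

    def __init__(self, x, y, w, n_blocks: int, constrain: float | None = None):
        x = np.asarray(x, float); y = np.asarray(y, float)
        w = np.asarray(w, float)
        n = len(x)
        self.constrain = constrain
        edges = np.linspace(0, n, n_blocks + 1).astype(int)
        sums = np.empty((n_blocks, 5))
        for b in range(n_blocks):
            s = slice(edges[b], edges[b + 1])
            ws, xs, ys = w[s], x[s], y[s]
            sums[b] = [ws.sum(), (ws * xs).sum(), (ws * ys).sum(),
                       (ws * xs * xs).sum(), (ws * xs * ys).sum()]
        self.block_sums = sums
        self.totals = sums.sum(axis=0)

    @staticmethod
    def _solve(t, constrain):
        Sw, Sx, Sy, Sxx, Sxy = np.moveaxis(np.atleast_2d(t), -1, 0)
        if constrain is None:
            det = Sw * Sxx - Sx**2
            slope = (Sw * Sxy - Sx * Sy) / det
            intercept = (Sy - slope * Sx) / Sw
        else:
            slope = (Sxy - constrain * Sx) / Sxx
            intercept = np.full_like(slope, constrain)
        return slope, intercept

    def fit(self) -> tuple[float, float]:
        s, i = self._solve(self.totals, self.constrain)
        return float(s[0]), float(i[0])

    def jackknife_slopes(self) -> np.ndarray:
        return self._solve(self.totals - self.block_sums, self.constrain)[0]


def _jackknife_se(reps: np.ndarray) -> float:
    reps = reps[np.isfinite(reps)]
    B = len(reps)
    if B < 2:
        return float("nan")
    return float(np.sqrt((B - 1) / B * np.sum((reps - reps.mean()) ** 2)))


def _merge_ld(stats: SummaryStats, ld: LDScoreTable) -> pd.DataFrame:
    df = stats.data.merge(ld.scores, on="variant_id")
    if df["n"].isna().any():
        raise ValueError(f"per-variant n required for LDSC ({stats.trait_name})")
    return df


def _is_constant(ell: np.ndarray) -> bool:
    return float(np.std(ell)) <= 1e-9 * max(1.0, float(np.mean(np.abs(ell))))


def _h2_components(chi2, N, ell, M, n_blocks):
    """Two-step-weighted h2 fit; returns (fit object, h2, intercept, mode)."""
    x = N * ell / M
    constrained = _is_constant(ell)
    constrain = 1.0 if constrained else None
    step1 = _BlockedFit(x, chi2, np.ones_like(x), n_blocks, constrain)
    h2_0, _ = step1.fit()
    w = 1.0 / (1.0 + N * max(h2_0, 0.0) * ell / M) ** 2
    fit = _BlockedFit(x, chi2, w, n_blocks, constrain)
    h2, intercept = fit.fit()
    return fit, h2, intercept, ("constrained" if constrained else "free")


def fit_h2(stats: SummaryStats, ld: LDScoreTable, min_variants: int = 50,
           n_blocks: int | None = None) -> H2Result:
    """Univariate LD score regression.

    Two-step weighting: an unweighted pass estimates h2, then weights
    1/(1 + N*h2*l/M)^2 down-weight high-LD variants in the final fit.

    Raises
    ------
    InsufficientVariantsError
        with fewer than ``min_variants`` overlapping variants — heritability
        (and hence any genetic correlation) cannot be estimated.
    """
    df = _merge_ld(stats, ld)
    n = len(df)
    if n < min_variants:
        raise InsufficientVariantsError(
            f"{stats.trait_name}: {n} variants overlap the LD score table "
            f"(<{min_variants}); h2 cannot be estimated")
    n_blocks = n_blocks or default_n_blocks(n)
    z = df["beta"].to_numpy(float) / df["se"].to_numpy(float)
    fit, h2, intercept, mode = _h2_components(
        z**2, df["n"].to_numpy(float), df["ld_score"].to_numpy(float),
        ld.M, n_blocks)
    return H2Result(h2=h2, intercept=intercept,
                    h2_se=_jackknife_se(fit.jackknife_slopes()),
                    n_variants=n, mode=mode)


def _align_z2(df: pd.DataFrame) -> pd.DataFrame:
    """Flip trait-2 z where its effect allele is trait 1's other allele
    (directly or after strand complement); drop irreconcilable variants."""
    ea1, oa1 = df["effect_allele_1"], df["other_allele_1"]
    ea2, oa2 = df["effect_allele_2"], df["other_allele_2"]
    cea2 = ea2.map(_COMPLEMENT)
    coa2 = oa2.map(_COMPLEMENT)
    same = ((ea2 == ea1) & (oa2 == oa1)) | ((cea2 == ea1) & (coa2 == oa1))
    swap = ((ea2 == oa1) & (oa2 == ea1)) | ((cea2 == oa1) & (coa2 == ea1))
    df = df[same | swap].copy()
    df["sign2"] = np.where(same[same | swap], 1.0, -1.0)
    return df


def fit_rg(stats1: SummaryStats, stats2: SummaryStats, ld: LDScoreTable,
           min_variants: int = 50, n_blocks: int | None = None
           ) -> GeneticCorrelation:
    """Cross-trait LD score regression.

    Returns rg with a block-jackknife standard error and normal p value.
    When either trait's h2 estimate is non-positive rg is undefined and
    reported missing (the "NA" behaviour for traits with too little
    heritable signal).  rg is z-based, so rescaling one trait's betas and
    ses jointly leaves it unchanged.
    """
    d1 = _merge_ld(stats1, ld).set_index("variant_id")
    d2 = _merge_ld(stats2, ld).set_index("variant_id")
    common = d1.index.intersection(d2.index)
    df = d1.loc[common].join(d2.loc[common], lsuffix="_1", rsuffix="_2")
    df["ld_score"] = df["ld_score_1"]
    df = _align_z2(df.reset_index())
    n = len(df)
    if n < min_variants:
        raise InsufficientVariantsError(
            f"{n} shared variants (<{min_variants}); rg cannot be estimated")
    n_blocks = n_blocks or default_n_blocks(n)

    ell = df["ld_score"].to_numpy(float)
    N1 = df["n_1"].to_numpy(float)
    N2 = df["n_2"].to_numpy(float)
    z1 = df["beta_1"].to_numpy(float) / df["se_1"].to_numpy(float)
    z2 = df["sign2"].to_numpy(float) * df["beta_2"].to_numpy(float) \
        / df["se_2"].to_numpy(float)

    fit1, h2_1, int1, mode = _h2_components(z1**2, N1, ell, ld.M, n_blocks)
    fit2, h2_2, int2, _ = _h2_components(z2**2, N2, ell, ld.M, n_blocks)

    # rg is undefined when either heritability is non-positive or not
    # distinguishable from zero (small-heritability "NA" behaviour)
    se1 = _jackknife_se(fit1.jackknife_slopes())
    se2 = _jackknife_se(fit2.jackknife_slopes())
    if (h2_1 <= 0 or h2_2 <= 0
            or (np.isfinite(se1) and h2_1 < 2.0 * se1)
            or (np.isfinite(se2) and h2_2 < 2.0 * se2)):
        return GeneticCorrelation(
            rg=None, rg_se=None, rg_pvalue=None, h2_trait1=h2_1, h2_trait2=h2_2,
            gcov=None, intercept1=int1, intercept2=int2, gcov_intercept=None,
            n_variants=n,
            note="small or non-positive h2; rg undefined (NA)")

    x = np.sqrt(N1 * N2) * ell / ld.M
    w = 1.0 / ((1.0 + N1 * h2_1 * ell / ld.M) * (1.0 + N2 * h2_2 * ell / ld.M))
    constrain = 0.0 if _is_constant(ell) else None
    fitx = _BlockedFit(x, z1 * z2, w, n_blocks, constrain)
    gcov, gint = fitx.fit()
    rg = gcov / np.sqrt(h2_1 * h2_2)

    # jackknife the full pipeline: h2s and gcov per deleted block
    h2_1b = fit1.jackknife_slopes()
    h2_2b = fit2.jackknife_slopes()
    gcov_b = fitx.jackknife_slopes()
    with np.errstate(invalid="ignore"):
        rg_b = gcov_b / np.sqrt(h2_1b * h2_2b)
    se = _jackknife_se(rg_b)
    p = float(2.0 * _st.norm.sf(abs(rg) / se)) if se and np.isfinite(se) else None

    out_of_range = bool(abs(rg) > RG_REPORT_LIMIT)
    rg_rep = float(np.clip(rg, -RG_REPORT_LIMIT, RG_REPORT_LIMIT))
    return GeneticCorrelation(
        rg=rg_rep, rg_se=se, rg_pvalue=p, h2_trait1=h2_1, h2_trait2=h2_2,
        gcov=float(gcov), intercept1=int1, intercept2=int2,
        gcov_intercept=float(gint), n_variants=n, out_of_range=out_of_range,
        note=f"intercepts {mode}")


def rg_matrix(outcome_stats: dict[str, SummaryStats],
              predictor_stats: dict[str, SummaryStats],
              ld: LDScoreTable, min_variants: int = 50) -> pd.DataFrame:
    """Genetic-correlation matrix (outcome definitions x predictors),
    rendered with NA where rg is undefined or h2 too small."""
    rows = []
    for oname, ostats in outcome_stats.items():
        row: dict[str, object] = {"outcome": oname}
        for pname, pstats in predictor_stats.items():
            try:
                gc = fit_rg(ostats, pstats, ld, min_variants=min_variants)
            except InsufficientVariantsError:
                gc = None
            if gc is None or gc.rg is None:
                row[f"rg_{pname}"] = np.nan
                row[f"se_{pname}"] = np.nan
                row[f"p_{pname}"] = np.nan
            else:
                row[f"rg_{pname}"] = gc.rg
                row[f"se_{pname}"] = gc.rg_se
                row[f"p_{pname}"] = gc.rg_pvalue
        rows.append(row)
    return pd.DataFrame(rows)
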