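"""Multivariable Mendelian randomisation (MVMR).

MVMR regresses the outcome associations jointly on several exposures'
association coefficients, so each coefficient is that exposure's direct
effect conditional on the others — the summary-data analogue of adjusting a
regression for covariables.  Here it serves to adjust an exposure-outcome
effect for genetically instrumented predictors of selection (education,
smoking, income analogues): if the adjusted estimate attenuates, part of the
unadjusted signal flowed through the selection predictor.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .estimators import (MREstimate, PleiotropyDiagnostics, Z95,
                         DifferenceTest, estimate_difference,
                         InsufficientInstrumentsError)
from .gwas_io import (SummaryStats, SummaryStatsError, _harmonise_pair,
                      PALINDROME_EAF_WINDOW)


class RankDeficientError(ValueError):
    """Exposure-effect matrix is (near) collinear; carries the condition number."""

    def __init__(self, cond: float):
        super().__init__(f"exposure matrix is rank deficient "
                         f"(condition number {cond:.3g})")
        self.condition_number = cond


@dataclass
class MultiExposureSet:
    """Union instrument set for k >= 2 exposures, aligned to common alleles."""

    variant_ids: np.ndarray
    beta_exposures: np.ndarray = field(repr=False)  # L x k
    se_exposures: np.ndarray = field(repr=False)
    beta_outcome: np.ndarray = field(repr=False)
    se_outcome: np.ndarray = field(repr=False)
    exposure_names: list[str] = field(default_factory=list)
    outcome_name: str = "outcome"
    outcome_type: str = "binary"
    exposure_types: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beta_exposures = np.atleast_2d(np.asarray(self.beta_exposures, float))
        self.se_exposures = np.atleast_2d(np.asarray(self.se_exposures, float))
        L, k = self.beta_exposures.shape
        if len(self.variant_ids) != L or len(self.beta_outcome) != L:
            raise ValueError("inconsistent lengths in MultiExposureSet")
        if not self.exposure_names:
            self.exposure_names = [f"exposure{i+1}" for i in range(k)]

    @property
    def k(self) -> int:
        return self.beta_exposures.shape[1]

    def __len__(self) -> int:
        return self.beta_exposures.shape[0]

    def scale(self, exposure_idx: int) -> str:
        etype = (self.exposure_types[exposure_idx]
                 if self.exposure_types else "quantitative")
        return f"{self.outcome_type}~{etype}"


def build_multi_exposure(exposures: Sequence[SummaryStats],
                         outcome: SummaryStats,
                         instrument_ids: Sequence[str],
                         palindrome_eaf_window: float = PALINDROME_EAF_WINDOW
                         ) -> MultiExposureSet:
    """Assemble a MultiExposureSet on a union instrument list.

    Every exposure and the outcome must report each instrument; the first
    exposure's effect allele defines the orientation.  Variants missing from
    any set, or dropped during harmonisation, are excluded.
    """
    primary = exposures[0]
    ids = [v for v in instrument_ids if v in set(primary.data["variant_id"])]
    prim_df = primary.data[primary.data["variant_id"].isin(ids)]
    if prim_df.empty:
        raise SummaryStatsError("no instruments present in the primary exposure")

    aligned: list[pd.DataFrame] = []
    for other in list(exposures[1:]) + [outcome]:
        kept, _ = _harmonise_pair(prim_df, other.data, palindrome_eaf_window)
        aligned.append(kept.set_index("variant_id"))

    common = set(prim_df["variant_id"])
    for kept in aligned:
        common &= set(kept.index)
    if not common:
        raise SummaryStatsError("empty intersection across exposures and outcome")
    order = [v for v in prim_df["variant_id"] if v in common]

    prim_df = prim_df.set_index("variant_id").loc[order]
    bX = [prim_df["beta"].to_numpy(float)]
    sX = [prim_df["se"].to_numpy(float)]
    for kept in aligned[:-1]:
        bX.append(kept.loc[order, "beta_o"].to_numpy(float))
        sX.append(kept.loc[order, "se_o"].to_numpy(float))
    out_kept = aligned[-1]
    return MultiExposureSet(
        variant_ids=np.array(order),
        beta_exposures=np.column_stack(bX),
        se_exposures=np.column_stack(sX),
        beta_outcome=out_kept.loc[order, "beta_o"].to_numpy(float),
        se_outcome=out_kept.loc[order, "se_o"].to_numpy(float),
        exposure_names=[e.trait_name for e in exposures],
        outcome_name=outcome.trait_name,
        outcome_type=outcome.trait_type,
        exposure_types=[e.trait_type for e in exposures],
    )


def mvmr_ivw(m: MultiExposureSet, cond_limit: float = 1e8
             ) -> tuple[dict[str, MREstimate], PleiotropyDiagnostics]:
    """Weighted multiple regression of outcome on all exposure columns.

    No intercept; weights 1/se_outcome^2; standard errors inflated
    multiplicatively by sqrt(max(1, Q/(L-k))).  With k=1 this reduces
    exactly to the univariable IVW estimate.
    """
    L, k = len(m), m.k
    if L <= k:
        raise InsufficientInstrumentsError(f"need more instruments ({L}) than "
                                           f"exposures ({k})")
    w = 1.0 / m.se_outcome**2
    X = m.beta_exposures
    sw = np.sqrt(w)
    cond = float(np.linalg.cond(X * sw[:, None]))
    if not np.isfinite(cond) or cond > cond_limit:
        raise RankDeficientError(cond)
    XtW = X.T * w
    cov = np.linalg.inv(XtW @ X)
    coef = cov @ (XtW @ m.beta_outcome)
    resid = m.beta_outcome - X @ coef
    Q = float(np.sum(w * resid**2))
    df = L - k
    scale_fac = np.sqrt(max(1.0, Q / df))
    ses = np.sqrt(np.diag(cov)) * scale_fac

    estimates: dict[str, MREstimate] = {}
    for i, name in enumerate(m.exposure_names):
        b, s = float(coef[i]), float(ses[i])
        estimates[name] = MREstimate(
            method="mvmr_ivw", beta=b, se=s,
            ci_low=b - Z95 * s, ci_high=b + Z95 * s,
            pvalue=float(2.0 * _st.norm.sf(abs(b) / s)),
            n_snps=L, scale=m.scale(i),
            odds_ratio=float(np.exp(b)) if m.outcome_type == "binary" else None)
    diag = PleiotropyDiagnostics(Q=Q, Q_df=df,
                                 Q_pvalue=float(_st.chi2.sf(Q, df)))
    return estimates, diag


def adjustment_compare(unadjusted: MREstimate,
                       adjusted: Mapping[str, MREstimate],
                       pct_threshold: float = 0.20,
                       p_threshold: float = 0.05) -> pd.DataFrame:
    """Attenuation table: unadjusted vs each covariable-adjusted estimate.

    Percent change is on the log-effect scale, (b_adj - b_unadj)/b_unadj.
    The qualitative flag is ``consistent`` unless the change exceeds
    ``pct_threshold`` in magnitude AND the independent-samples difference
    test has p < ``p_threshold`` (both required, so noise alone is not
    flagged); attenuated means the adjusted effect moved toward the null.
    """
    rows = []
    for cov_name, adj in adjusted.items():
        diff: DifferenceTest = estimate_difference(adj, unadjusted)
        if unadjusted.beta != 0:
            pct = (adj.beta - unadjusted.beta) / unadjusted.beta
        else:
            pct = float("inf") if adj.beta != 0 else 0.0
        if abs(pct) > pct_threshold and diff.pvalue < p_threshold:
            flag = "attenuated" if abs(adj.beta) < abs(unadjusted.beta) else "amplified"
        else:
            flag = "consistent"
        rows.append({
            "covariable": cov_name,
            "beta_unadjusted": unadjusted.beta, "beta_adjusted": adj.beta,
            "delta_beta": adj.beta - unadjusted.beta,
            "pct_change_log": pct, "z": diff.z, "pvalue": diff.pvalue,
            "flag": flag,
        })
    return pd.DataFrame(rows)
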