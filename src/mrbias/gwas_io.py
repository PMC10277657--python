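"""Reading, validation and harmonisation of GWAS summary statistics.

The canonical per-variant record carries the fields every downstream step
needs: identifiers and coordinates, the effect/other allele pair, the
effect-allele frequency, the association coefficient (SD units for
quantitative traits, log-odds for binary traits) with its standard error and
two-sided p value, and sample sizes.  Files in other dialects are mapped onto
this layout with a ``column_map``.

Harmonisation aligns an outcome file's effects to the exposure's effect
allele, resolving strand flips by complementing alleles and palindromic
(A/T, C/G) variants by effect-allele-frequency concordance.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

log = logging.getLogger(__name__)

CANONICAL_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n", "n_cases", "n_controls",
]
REQUIRED_COLUMNS = ["variant_id", "effect_allele", "other_allele", "beta", "se"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
VALID_ALLELES = frozenset(_COMPLEMENT)

#: default half-width of the allele-frequency window around 0.5 inside which a
#: palindromic variant's strand cannot be resolved from frequencies.
PALINDROME_EAF_WINDOW = 0.08


class SummaryStatsError(ValueError):
    """Malformed or unusable summary statistics input."""


class NoInstrumentsError(SummaryStatsError):
    """No variant passed the instrument-selection threshold.

    Signalled distinctly so callers can relax the p-value threshold (the
    conventional fallback when a disease GWAS has few genome-wide hits).
    """


@dataclass
class SummaryStats:
    """One trait's per-variant GWAS association results.

    ``data`` holds the canonical columns (missing ones are added as NA);
    variant ids must be unique.
    """

    trait_name: str
    trait_type: str  # "quantitative" | "binary"
    data: pd.DataFrame
    release_tag: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise SummaryStatsError(
                f"trait_type must be quantitative|binary, got {self.trait_type!r}")
        df = self.data
        for col in CANONICAL_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df = df[CANONICAL_COLUMNS].reset_index(drop=True)
        if df["variant_id"].duplicated().any():
            dupes = df.loc[df["variant_id"].duplicated(), "variant_id"].head(3).tolist()
            raise SummaryStatsError(f"duplicate variant ids, e.g. {dupes}")
        self.data = df

    @property
    def n_variants(self) -> int:
        return len(self.data)

    def subset(self, mask_or_ids) -> "SummaryStats":
        """Return a copy restricted to a boolean mask or an id collection."""
        df = self.data
        if isinstance(mask_or_ids, (pd.Series, np.ndarray)) and getattr(
                mask_or_ids, "dtype", None) == bool:
            out = df.loc[np.asarray(mask_or_ids)]
        else:
            out = df[df["variant_id"].isin(list(mask_or_ids))]
        return replace(self, data=out.reset_index(drop=True).copy())


def _recompute_pvalue(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    z = np.abs(beta / se)
    return np.clip(2.0 * _st.norm.sf(z), 5e-324, 1.0)


def read_summary_stats(path, *, column_map: Mapping[str, str] | None = None,
                       trait_name: str = "trait",
                       trait_type: str = "quantitative",
                       release_tag: str = "", sep: str | None = None,
                       provenance: str = "") -> SummaryStats:
    """Read a delimited summary-statistics file into a validated SummaryStats.

    Parameters
    ----------
    column_map
        Mapping canonical-name -> file-column-name for any column whose header
        differs from the canonical one.  Required fields: variant_id,
        effect_allele, other_allele, beta, se.
    sep
        Field separator; sniffed from the file when omitted.

    Rows failing validation (non-positive or non-finite se, identical or
    non-ACGT alleles, non-finite beta) are dropped and counted in the log.
    Missing or out-of-range p values are recomputed from 2*Phi(-|beta/se|).
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    except (OSError, pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise SummaryStatsError(f"cannot read summary stats from {path}: {exc}") from exc

    if column_map:
        rename = {src: canon for canon, src in column_map.items() if src in raw.columns}
        missing_src = [src for src in column_map.values() if src not in raw.columns]
        if missing_src:
            raise SummaryStatsError(
                f"column_map names columns absent from {path.name}: {missing_src}")
        raw = raw.rename(columns=rename)

    absent = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if absent:
        raise SummaryStatsError(f"required columns missing from {path.name}: {absent}")

    df = raw.copy()
    for col in ("eaf", "beta", "se", "pvalue", "pos", "n", "n_cases", "n_controls"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    df["variant_id"] = df["variant_id"].astype(str)
    if "chrom" in df.columns:
        df["chrom"] = df["chrom"].astype(str)

    n_in = len(df)
    ok = (
        np.isfinite(df["beta"]) & np.isfinite(df["se"]) & (df["se"] > 0)
        & df["effect_allele"].isin(VALID_ALLELES)
        & df["other_allele"].isin(VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
    )
    dropped = int(n_in - ok.sum())
    if dropped:
        log.info("read_summary_stats(%s): dropped %d/%d invalid rows",
                 path.name, dropped, n_in)
    df = df.loc[ok].reset_index(drop=True)
    if df.empty:
        raise SummaryStatsError(f"no valid rows in {path}")

    # out-of-(0,1] frequencies are unusable but not fatal
    if "eaf" in df.columns:
        bad_eaf = ~((df["eaf"] > 0) & (df["eaf"] < 1))
        df.loc[bad_eaf, "eaf"] = np.nan

    if "pvalue" not in df.columns:
        df["pvalue"] = np.nan
    bad_p = ~((df["pvalue"] > 0) & (df["pvalue"] <= 1))
    if bad_p.any():
        df.loc[bad_p, "pvalue"] = _recompute_pvalue(
            df.loc[bad_p, "beta"].to_numpy(), df.loc[bad_p, "se"].to_numpy())

    stats = SummaryStats(trait_name=trait_name, trait_type=trait_type,
                         data=df, release_tag=release_tag,
                         provenance=provenance or f"read from {path.name}; "
                                                  f"{dropped} rows dropped")
    return stats


def write_summary_stats(stats: SummaryStats, path) -> None:
    """Write the canonical tab-delimited layout (NA for missing values)."""
    stats.data[CANONICAL_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


def select_instruments(stats: SummaryStats, p_threshold: float = 5e-8,
                       prune_window_bp: int = 250_000) -> SummaryStats:
    """Select instruments: p-value filter plus greedy distance pruning.

    Within each chromosome the smallest-p variant is kept and any other
    selected variant within ``prune_window_bp`` of a kept one is removed
    (a desk-scale stand-in for LD clumping).  Output ordered by (chrom, pos).

    Raises
    ------
    NoInstrumentsError
        when nothing passes, so callers can retry with a relaxed threshold.
    """
    if not (0 < p_threshold < 1):
        raise ValueError("p_threshold must be in (0,1)")
    if prune_window_bp < 0:
        raise ValueError("prune_window_bp must be >= 0")
    df = stats.data
    hits = df[df["pvalue"] < p_threshold]
    if hits.empty:
        raise NoInstrumentsError(
            f"no variants of {stats.trait_name} below p<{p_threshold:g}")
    keep_idx: list[int] = []
    for _, grp in hits.groupby(hits["chrom"].astype(str), sort=True):
        kept_pos: list[float] = []
        for idx in grp.sort_values("pvalue", kind="stable").index:
            pos = grp.at[idx, "pos"]
            if np.isnan(pos):
                keep_idx.append(idx)  # unknown position: its own locus
                continue
            if all(abs(pos - kp) > prune_window_bp for kp in kept_pos):
                keep_idx.append(idx)
                kept_pos.append(pos)
    out = hits.loc[sorted(keep_idx)].sort_values(
        ["chrom", "pos"], kind="stable").reset_index(drop=True)
    return replace(stats, data=out.copy(),
                   provenance=f"{stats.provenance}; instruments p<{p_threshold:g}, "
                              f"prune {prune_window_bp}bp")


@dataclass
class HarmonisedSet:
    """Exposure and outcome effects aligned to the exposure's effect allele.

    Only retained (kept/flipped) variants appear in the estimation vectors;
    ``flags`` records the action taken for every shared variant.
    """

    variant_ids: np.ndarray
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    eaf_exposure: np.ndarray
    flags: pd.DataFrame = field(repr=False)
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    exposure_type: str = "quantitative"
    outcome_type: str = "binary"

    def __post_init__(self) -> None:
        L = len(self.variant_ids)
        for name in ("beta_exposure", "se_exposure", "beta_outcome",
                     "se_outcome", "eaf_exposure"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape[0] != L:
                raise ValueError(f"{name} length {arr.shape[0]} != {L}")
            setattr(self, name, arr)

    def __len__(self) -> int:
        return len(self.variant_ids)

    @property
    def scale(self) -> str:
        return f"{self.outcome_type}~{self.exposure_type}"


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def _harmonise_pair(exp_df: pd.DataFrame, out_df: pd.DataFrame,
                    palindrome_eaf_window: float) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (aligned merged frame of retained variants, full flags frame)."""
    merged = exp_df.merge(out_df, on="variant_id", suffixes=("_e", "_o"))
    if merged.empty:
        raise SummaryStatsError("no shared variants between exposure and outcome")
    w = palindrome_eaf_window
    actions: list[str] = []
    signs: list[int] = []
    for row in merged.itertuples(index=False):
        ea_e, oa_e = row.effect_allele_e, row.other_allele_e
        ea_o, oa_o = row.effect_allele_o, row.other_allele_o
        if _is_palindromic(ea_e, oa_e):
            # outcome alleles of a palindromic variant are the same pair on
            # either strand; resolve orientation from allele frequencies
            if {ea_o, oa_o} != {ea_e, oa_e}:
                actions.append("dropped_mismatch"); signs.append(0)
                continue
            eaf_e, eaf_o = row.eaf_e, row.eaf_o
            if not (np.isfinite(eaf_e) and np.isfinite(eaf_o)):
                actions.append("dropped_palindromic"); signs.append(0)
                continue
            if abs(eaf_e - 0.5) < w or abs(eaf_o - 0.5) < w:
                actions.append("dropped_palindromic"); signs.append(0)
                continue
            base = 1 if ea_o == ea_e else -1
            eaf_aligned = eaf_o if base == 1 else 1.0 - eaf_o
            if abs(eaf_aligned - eaf_e) <= abs(eaf_aligned - (1.0 - eaf_e)):
                sign = base
            else:  # strand flip: frequencies match the mirrored allele
                sign = -base
            actions.append("kept" if sign == 1 else "flipped")
            signs.append(sign)
            continue
        # non-palindromic: direct match, swap, then complemented strand
        pairs = [(ea_o, oa_o), (_COMPLEMENT.get(ea_o), _COMPLEMENT.get(oa_o))]
        sign = 0
        for a, b in pairs:
            if (a, b) == (ea_e, oa_e):
                sign = 1
                break
            if (a, b) == (oa_e, ea_e):
                sign = -1
                break
        if sign == 0:
            actions.append("dropped_mismatch")
        else:
            actions.append("kept" if sign == 1 else "flipped")
        signs.append(sign)

    merged = merged.assign(action=actions, sign=signs)
    flags = merged[["variant_id", "action"]].copy()
    kept = merged[merged["sign"] != 0].copy()
    kept["beta_o"] = kept["beta_o"] * kept["sign"]
    flip = kept["sign"] == -1
    kept.loc[flip, "eaf_o"] = 1.0 - kept.loc[flip, "eaf_o"]
    return kept, flags


def harmonise(exposure: SummaryStats,
              outcomes: SummaryStats | Sequence[SummaryStats],
              palindrome_eaf_window: float = PALINDROME_EAF_WINDOW):
    """Align one or more outcome SummaryStats to the exposure's effect alleles.

    With a single outcome a :class:`HarmonisedSet` is returned.  With several,
    the retained variants are intersected across all outcomes and a list of
    HarmonisedSets (in input order, all on the same variants) is returned.
    """
    single = isinstance(outcomes, SummaryStats)
    outcome_list = [outcomes] if single else list(outcomes)
    pair_results = []
    for out in outcome_list:
        kept, flags = _harmonise_pair(exposure.data, out.data, palindrome_eaf_window)
        pair_results.append((out, kept, flags))

    common = set(pair_results[0][1]["variant_id"])
    for _, kept, _ in pair_results[1:]:
        common &= set(kept["variant_id"])
    if not common:
        raise SummaryStatsError("empty intersection of harmonised variants")

    sets = []
    for out, kept, flags in pair_results:
        kept = kept[kept["variant_id"].isin(common)].reset_index(drop=True)
        sets.append(HarmonisedSet(
            variant_ids=kept["variant_id"].to_numpy(),
            beta_exposure=kept["beta_e"].to_numpy(float),
            se_exposure=kept["se_e"].to_numpy(float),
            beta_outcome=kept["beta_o"].to_numpy(float),
            se_outcome=kept["se_o"].to_numpy(float),
            eaf_exposure=kept["eaf_e"].to_numpy(float),
            flags=flags,
            exposure_name=exposure.trait_name,
            outcome_name=out.trait_name,
            exposure_type=exposure.trait_type,
            outcome_type=out.trait_type,
        ))
    return sets[0] if single else sets
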