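"""The five-approach framework for probing selection and misclassification
bias in summary-data MR, and the structured report it produces.

The approaches, run over a set of case/control definitions ("schemes") and
data releases:

1. *Definition comparison* — consistency of the causal estimate across
   different case/control definitions; divergence of a scheme from the
   precision-weighted consensus suggests the definition-specific bias
   (population controls -> misclassification; tested controls -> selection).
2. *No-relevance control* — MR in the reverse direction, with the disease as
   exposure and a pre-existing trait as outcome, where no true causal effect
   is possible; a non-null estimate indicates selection, misclassification
   or pleiotropy.
3. *Genetic-correlation screen* — LD score regression of each disease GWAS
   against candidate predictors of selection; strong rg suggests the GWAS
   partly captures who gets tested (though a true causal path produces rg
   too).
4. *MVMR adjustment* — re-estimation adjusting for each genetically
   instrumented selection predictor; attenuation suggests bias through that
   predictor (or a mediating path).
5. *Comparison over time* — forward and reverse estimates per data release;
   a reverse signal confined to early, more selective releases points at
   selection.

All thresholds are qualitative decisions, exposed in
:class:`FrameworkConfig` and recorded in the report.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import estimators as est
from .estimators import MREstimate
from .gwas_io import (NoInstrumentsError, SummaryStats, SummaryStatsError,
                      harmonise, select_instruments)
from .ldsc import (InsufficientVariantsError, LDScoreTable, fit_rg)
from .mvmr import adjustment_compare, build_multi_exposure, mvmr_ivw
from .simulate import (SCHEMES, ScenarioConfig, constant_ld_table,
                       simulate_study)

#: fixed caveat attached to definition-comparison flags: comparing or
#: stratifying on sub-groups (e.g. the tested) itself conditions on a
#: collider and can induce the very bias being probed.
STRATIFICATION_CAVEAT = (
    "Comparing or stratifying on subgroups (for example, restricting to "
    "tested individuals) conditions on a potential collider and can itself "
    "induce bias; divergence between definitions is a prompt for "
    "investigation, not proof of which definition is unbiased.")

SHARED_CONTROLS_CAVEAT = (
    "Difference tests treat estimates as independent; definitions sharing "
    "controls make these tests approximate (conservative or "
    "anticonservative).")

GC_TRUE_PATH_CAVEAT = (
    "A genetic correlation with a predictor of selection can also arise "
    "from a true causal path between the predictor and the disease; the "
    "screen cannot distinguish the two by itself.")


@dataclass
class FrameworkConfig:
    """Decision thresholds and analysis settings (all config-exposed).

    The underlying literature is qualitative about what difference "counts";
    these defaults flag only changes that are both material (>20% on the
    log-effect scale) and statistically supported.
    """

    seed: int = 0
    p_instruments: float = 5e-8
    p_relaxed: float = 5e-6
    prune_window_bp: int = 250_000
    diff_p_threshold: float = 0.05
    diff_pct_threshold: float = 0.20
    rg_threshold: float = 0.2
    rg_p_threshold: float = 0.05
    min_cases: int = 500
    wm_n_boot: int = 1000


class NotEstimable(Exception):
    """An approach cannot be run for a scheme (no data / no instruments)."""


# --------------------------------------------------------------------------
# single-pair MR runs

def run_estimator_suite(h, seed: int, n_boot: int = 1000) -> dict:
    """IVW (multiplicative random effects), MR-Egger and weighted median on
    one harmonised set, with instrument-strength diagnostics."""
    out: dict[str, object] = {}
    ivw_est, ivw_diag = est.ivw(h, random_effects=True)
    out["ivw_mre"] = ivw_est.to_dict()
    strength = est.instrument_strength(h)
    out["diagnostics"] = ivw_diag.to_dict()
    out["mean_F"] = strength.mean_F
    out["total_R2"] = strength.total_R2
    out["n_snps"] = len(h)
    if len(h) >= 3:
        egger_est, egger_diag = est.mr_egger(h)
        out["egger"] = egger_est.to_dict()
        out["egger_diagnostics"] = egger_diag.to_dict()
        wm = est.weighted_median(h, n_boot=n_boot, seed=seed)
        out["weighted_median"] = wm.to_dict()
    return out


def forward_mr(exposure_stats: SummaryStats, outcome_stats: SummaryStats,
               fw: FrameworkConfig) -> dict:
    """Exposure -> disease MR for one scheme (full estimator suite)."""
    instruments = select_instruments(exposure_stats, fw.p_instruments,
                                     fw.prune_window_bp)
    h = harmonise(instruments, outcome_stats)
    return run_estimator_suite(h, seed=fw.seed, n_boot=fw.wm_n_boot)


def reverse_mr(disease_stats: SummaryStats, trait_stats: SummaryStats,
               fw: FrameworkConfig) -> dict:
    """Disease -> pre-existing-trait MR (the no-relevance direction).

    Instrument selection first tries the genome-wide threshold, then the
    relaxed threshold (used when a disease GWAS has few or no genome-wide
    hits); the threshold actually used is recorded.
    """
    try:
        instruments = select_instruments(disease_stats, fw.p_instruments,
                                         fw.prune_window_bp)
        threshold = fw.p_instruments
    except NoInstrumentsError:
        instruments = select_instruments(disease_stats, fw.p_relaxed,
                                         fw.prune_window_bp)
        threshold = fw.p_relaxed
    h = harmonise(instruments, trait_stats)
    out = run_estimator_suite(h, seed=fw.seed, n_boot=fw.wm_n_boot)
    out["p_threshold_used"] = threshold
    return out


def _mre(d: Mapping) -> MREstimate:
    return MREstimate(**{k: d[k] for k in (
        "method", "beta", "se", "ci_low", "ci_high", "pvalue", "n_snps",
        "scale", "odds_ratio")})


# --------------------------------------------------------------------------
# the five approaches

def compare_definitions(estimates: Mapping[str, MREstimate],
                        fw: FrameworkConfig) -> dict:
    """Pairwise and against-consensus comparison of scheme estimates.

    The consensus is the precision-weighted mean of all scheme estimates on
    the shared scale; a scheme is flagged when it differs from the consensus
    by more than the percent threshold on the log scale with difference-test
    p below threshold.
    """
    names = sorted(estimates)
    if len(names) < 2:
        return {"applicable": False, "reason": "fewer than two estimates"}
    scale = estimates[names[0]].scale
    usable = [n for n in names if estimates[n].scale == scale]
    w = np.array([1.0 / estimates[n].se**2 for n in usable])
    b = np.array([estimates[n].beta for n in usable])
    pooled_beta = float(np.sum(w * b) / np.sum(w))
    pooled = MREstimate(method="pooled", beta=pooled_beta,
                        se=float(np.sum(w) ** -0.5),
                        ci_low=float("nan"), ci_high=float("nan"),
                        pvalue=float("nan"), n_snps=0, scale=scale)

    pairwise = []
    for i, a in enumerate(usable):
        for bname in usable[i + 1:]:
            d = est.estimate_difference(estimates[a], estimates[bname])
            pairwise.append({"scheme_a": a, "scheme_b": bname,
                             "delta": d.delta, "z": d.z, "pvalue": d.pvalue})

    per_scheme = {}
    flagged = []
    for n in usable:
        d = est.estimate_difference(estimates[n], pooled)
        pct = ((estimates[n].beta - pooled_beta) / pooled_beta
               if pooled_beta != 0 else float("inf"))
        flag = bool(abs(pct) > fw.diff_pct_threshold
                    and d.pvalue < fw.diff_p_threshold)
        note = SCHEMES[n].bias_note if n in SCHEMES else ""
        per_scheme[n] = {"beta": estimates[n].beta, "se": estimates[n].se,
                         "pct_vs_pooled": pct, "pvalue_vs_pooled": d.pvalue,
                         "flag": flag, "bias_hypothesis": note}
        if flag:
            flagged.append(n)
    return {"applicable": True, "pooled_beta": pooled_beta,
            "pairwise": pairwise, "per_scheme": per_scheme,
            "flagged": flagged,
            "caveats": [STRATIFICATION_CAVEAT, SHARED_CONTROLS_CAVEAT]}


def no_relevance(outcome_stats: Mapping[str, SummaryStats | None],
                 trait_stats: SummaryStats, fw: FrameworkConfig) -> dict:
    """Reverse-direction (disease -> pre-existing trait) run per scheme.

    Flags a scheme when its reverse IVW 95% CI excludes zero — under the
    no-relevance assumption any signal reflects bias.  Records instrument
    count and mean F (ratios from weak disease instruments are noisier, and
    the first-order Wald variance understates this)."""
    per_scheme = {}
    flagged = []
    for name in sorted(outcome_stats):
        stats = outcome_stats[name]
        if stats is None:
            per_scheme[name] = {"estimable": False,
                                "reason": "no case/control GWAS"}
            continue
        try:
            res = reverse_mr(stats, trait_stats, fw)
        except (NoInstrumentsError, SummaryStatsError) as exc:
            per_scheme[name] = {"estimable": False, "reason": str(exc)}
            continue
        ivw_d = res["ivw_mre"]
        flag = bool(ivw_d["ci_low"] > 0 or ivw_d["ci_high"] < 0)
        per_scheme[name] = {
            "estimable": True, "ivw": ivw_d, "flag": flag,
            "n_instruments": res["n_snps"], "mean_F": res["mean_F"],
            "p_threshold_used": res["p_threshold_used"],
        }
        if flag:
            flagged.append(name)
    return {"applicable": True, "per_scheme": per_scheme, "flagged": flagged,
            "note": ("reverse estimates are on the SD-of-trait per log-odds "
                     "scale; a CI excluding zero indicates selection, "
                     "misclassification or pleiotropy in the forward "
                     "analysis")}


def gc_screen(outcome_stats: Mapping[str, SummaryStats | None],
              predictor_stats: Mapping[str, SummaryStats],
              ld: LDScoreTable, fw: FrameworkConfig) -> dict:
    """Genetic correlation of each scheme GWAS with each selection
    predictor; |rg| above threshold with small p raises the flag."""
    table = {}
    flagged = []
    for name in sorted(outcome_stats):
        stats = outcome_stats[name]
        row = {}
        if stats is None:
            table[name] = {"estimable": False}
            continue
        any_flag = False
        for pname in sorted(predictor_stats):
            try:
                gc = fit_rg(stats, predictor_stats[pname], ld)
            except InsufficientVariantsError as exc:
                row[pname] = {"rg": None, "note": str(exc)}
                continue
            if gc.rg is None:
                row[pname] = {"rg": None, "note": gc.note}
                continue
            f = bool(abs(gc.rg) > fw.rg_threshold
                     and gc.rg_pvalue is not None
                     and gc.rg_pvalue < fw.rg_p_threshold)
            row[pname] = {"rg": gc.rg, "se": gc.rg_se, "pvalue": gc.rg_pvalue,
                          "flag": f}
            any_flag = any_flag or f
        table[name] = {"estimable": True, "predictors": row, "flag": any_flag}
        if any_flag:
            flagged.append(name)
    return {"applicable": True, "table": table, "flagged": flagged,
            "caveats": [GC_TRUE_PATH_CAVEAT]}


def mvmr_adjustment(exposure_stats: SummaryStats,
                    predictor_stats: Mapping[str, SummaryStats],
                    outcome_stats: SummaryStats,
                    unadjusted: MREstimate, fw: FrameworkConfig) -> dict:
    """Adjust the exposure-outcome effect for each selection predictor,
    one at a time, and tabulate attenuation."""
    adjusted: dict[str, MREstimate] = {}
    details = {}
    for pname in sorted(predictor_stats):
        pstats = predictor_stats[pname]
        try:
            exp_ids = select_instruments(exposure_stats, fw.p_instruments,
                                         fw.prune_window_bp)
            try:
                pred_ids = select_instruments(pstats, fw.p_instruments,
                                              fw.prune_window_bp)
                union = list(dict.fromkeys(
                    list(exp_ids.data["variant_id"])
                    + list(pred_ids.data["variant_id"])))
            except NoInstrumentsError:
                union = list(exp_ids.data["variant_id"])
            mset = build_multi_exposure([exposure_stats, pstats],
                                        outcome_stats, union)
            estimates, diag = mvmr_ivw(mset)
            adjusted[pname] = estimates[exposure_stats.trait_name]
            details[pname] = {
                "estimate": estimates[exposure_stats.trait_name].to_dict(),
                "covariable_estimate": estimates[pstats.trait_name].to_dict(),
                "Q": diag.Q, "Q_df": diag.Q_df, "n_instruments": len(mset)}
        except (SummaryStatsError, NoInstrumentsError, ValueError) as exc:
            details[pname] = {"estimable": False, "reason": str(exc)}
    if not adjusted:
        return {"applicable": False, "reason": "no adjustment estimable",
                "details": details}
    table = adjustment_compare(unadjusted, adjusted,
                               pct_threshold=fw.diff_pct_threshold,
                               p_threshold=fw.diff_p_threshold)
    flagged_covars = sorted(table.loc[table["flag"] != "consistent",
                                      "covariable"].tolist())
    return {"applicable": True,
            "table": table.to_dict(orient="records"),
            "details": details, "flagged_covariables": flagged_covars,
            "note": ("per-exposure marginal mean F overstates conditional "
                     "instrument strength; attenuation can also reflect "
                     "adjustment for a mediator")}


def time_compare(forward: Mapping[str, Mapping[str, MREstimate | None]],
                 reverse: Mapping[str, Mapping[str, dict | None]],
                 release_order: Sequence[str], fw: FrameworkConfig) -> dict:
    """Forward and reverse estimates per release, with consecutive-release
    difference tests; a release whose reverse CI excludes zero is flagged
    (selective-testing signature of early releases)."""
    if len(release_order) < 2:
        return {"applicable": False, "reason": "single release"}
    per_scheme: dict[str, dict] = {}
    flagged: list[str] = []
    scheme_names = sorted({s for rel in forward.values() for s in rel})
    for name in scheme_names:
        series = []
        for rel in release_order:
            f = forward.get(rel, {}).get(name)
            r = reverse.get(rel, {}).get(name)
            entry = {"release": rel,
                     "forward": f.to_dict() if f is not None else None}
            if r is not None and r.get("estimable", True):
                ivw_d = r.get("ivw") or r.get("ivw_mre") or r
                entry["reverse_beta"] = ivw_d["beta"]
                entry["reverse_ci"] = [ivw_d["ci_low"], ivw_d["ci_high"]]
                entry["reverse_flag"] = bool(
                    ivw_d["ci_low"] > 0 or ivw_d["ci_high"] < 0)
            else:
                entry["reverse_flag"] = None
            series.append(entry)
        diffs = []
        for prev, cur in zip(series, series[1:]):
            if prev["forward"] is None or cur["forward"] is None:
                continue
            d = est.estimate_difference(_mre(cur["forward"]),
                                        _mre(prev["forward"]))
            diffs.append({"from": prev["release"], "to": cur["release"],
                          "delta": d.delta, "z": d.z, "pvalue": d.pvalue})
        flagged_rel = [e["release"] for e in series if e["reverse_flag"]]
        per_scheme[name] = {"series": series, "consecutive_diffs": diffs,
                            "flagged_releases": flagged_rel}
        if flagged_rel:
            flagged.append(name)
    return {"applicable": True, "per_scheme": per_scheme, "flagged": flagged,
            "note": ("drifting forward estimates with overlapping CIs are "
                     "consistent with changing power; a reverse signal at a "
                     "selective release indicates selection bias")}


# --------------------------------------------------------------------------
# report assembly

@dataclass
class BiasReport:
    """Merged result of the five approaches with per-scheme overall flags."""

    scenario: str
    seed: int
    thresholds: dict
    sections: dict
    overall: dict
    counts: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=2,
                          allow_nan=True)

    def to_markdown(self) -> str:
        lines = [f"# Bias-assessment report — scenario {self.scenario}",
                 f"seed: {self.seed}", "", "## Overall per-scheme flags", ""]
        for scheme in sorted(self.overall):
            o = self.overall[scheme]
            lines.append(f"- **{scheme}**: {o['flag']}")
            for ev in o["evidence"]:
                lines.append(f"  - {ev}")
        lines += ["", "## Decision thresholds", ""]
        for k in sorted(self.thresholds):
            lines.append(f"- {k}: {self.thresholds[k]}")
        for sec in sorted(self.sections):
            lines += ["", f"## Section: {sec}", "",
                      "```json",
                      json.dumps(self.sections[sec], sort_keys=True, indent=1),
                      "```"]
        return "\n".join(lines) + "\n"


def assemble_report(sections: Mapping[str, dict], counts: Mapping[str, dict],
                    fw: FrameworkConfig, scenario: str = "custom") -> BiasReport:
    """Merge section flags into per-scheme overall flags.

    Precedence (highest wins): underpowered (fewer than ``min_cases`` cases,
    or nothing estimable) > possible_misclassification (definition
    divergence of a population-control scheme) > possible_selection_bias
    (no-relevance, genetic-correlation or time-comparison flag, or
    definition divergence of a tested-control scheme) > no_evidence_of_bias.
    The precedence is a reporting choice; all evidence lines are retained.
    """
    defs = sections.get("definitions_comparison", {})
    norel = sections.get("no_relevance", {})
    gc = sections.get("genetic_correlation_screen", {})
    timec = sections.get("time_comparison", {})

    scheme_names = sorted(set(counts)
                          | set(defs.get("per_scheme", {}))
                          | set(norel.get("per_scheme", {})))
    overall = {}
    for name in scheme_names:
        evidence = []
        cnt = counts.get(name, {})
        n_cases = cnt.get("cases")
        underpowered = False
        if n_cases is not None and n_cases < fw.min_cases:
            underpowered = True
            evidence.append(f"only {n_cases} cases (<{fw.min_cases})")
        nr = norel.get("per_scheme", {}).get(name)
        if nr is not None and not nr.get("estimable", True):
            underpowered = True
            evidence.append(f"no-relevance not estimable: {nr.get('reason')}")

        mis = False
        selection = False
        if name in defs.get("flagged", []):
            note = defs["per_scheme"][name].get("bias_hypothesis", "")
            pop = name in SCHEMES and SCHEMES[name].population_controls
            evidence.append(f"estimate diverges from pooled definitions "
                            f"({'population controls' if pop else 'tested controls'}): {note}")
            if pop:
                mis = True
            else:
                selection = True
        if nr is not None and nr.get("flag"):
            selection = True
            evidence.append("no-relevance (reverse) IVW CI excludes 0")
        if name in gc.get("flagged", []):
            selection = True
            evidence.append("genetic correlation with selection predictor(s) "
                            f"above |rg|>{fw.rg_threshold}")
        if name in timec.get("flagged", []):
            selection = True
            rels = timec["per_scheme"][name]["flagged_releases"]
            evidence.append(f"reverse signal at release(s) {rels}")

        if underpowered:
            flag = "underpowered"
        elif mis:
            flag = "possible_misclassification"
        elif selection:
            flag = "possible_selection_bias"
        else:
            flag = "no_evidence_of_bias"
        overall[name] = {"flag": flag, "evidence": evidence}

    return BiasReport(scenario=scenario, seed=fw.seed,
                      thresholds=dataclasses.asdict(fw),
                      sections=dict(sections), overall=overall,
                      counts={k: dict(v) for k, v in counts.items()})


# --------------------------------------------------------------------------
# end-to-end simulated-study pipeline

def run_study_framework(cfg: ScenarioConfig, fw: FrameworkConfig | None = None,
                        schemes: Sequence[str] | None = None) -> BiasReport:
    """Simulate a study under a scenario and run all five approaches.

    Deterministic: identical scenario, framework config and seed produce a
    byte-identical JSON report.
    """
    fw = fw or FrameworkConfig(seed=cfg.seed)
    study = simulate_study(cfg, seed=fw.seed, schemes=schemes)
    last = study.release_tags[-1]
    ld = constant_ld_table(study.panel)

    forward: dict[str, dict[str, MREstimate | None]] = {}
    forward_full: dict[str, dict] = {}
    reverse: dict[str, dict[str, dict | None]] = {}
    for rel in study.release_tags:
        forward[rel] = {}
        reverse[rel] = {}
        for name in sorted(study.outcomes[rel]):
            stats = study.outcomes[rel][name]
            if stats is None:
                forward[rel][name] = None
                reverse[rel][name] = {"estimable": False,
                                      "reason": "no case/control GWAS"}
                continue
            try:
                res = forward_mr(study.exposure_stats, stats, fw)
                forward[rel][name] = _mre(res["ivw_mre"])
                if rel == last:
                    forward_full[name] = res
            except (NoInstrumentsError, SummaryStatsError) as exc:
                forward[rel][name] = None
                if rel == last:
                    forward_full[name] = {"estimable": False,
                                          "reason": str(exc)}
            try:
                rres = reverse_mr(stats, study.exposure_stats, fw)
                rres["estimable"] = True
                reverse[rel][name] = rres
            except (NoInstrumentsError, SummaryStatsError) as exc:
                reverse[rel][name] = {"estimable": False, "reason": str(exc)}

    last_estimates = {n: e for n, e in forward[last].items() if e is not None}
    predictors = {"sep_trait": study.sep_stats}
    sections = {
        "definitions_comparison": compare_definitions(last_estimates, fw),
        "no_relevance": no_relevance(study.outcomes[last],
                                     study.exposure_stats, fw),
        "genetic_correlation_screen": gc_screen(study.outcomes[last],
                                                predictors, ld, fw),
        "time_comparison": time_compare(forward, reverse,
                                        study.release_tags, fw),
    }
    # MVMR adjustment of the main (C2-style) analysis where available
    main_scheme = "C2" if "C2" in last_estimates else (
        sorted(last_estimates)[0] if last_estimates else None)
    if main_scheme is not None and study.outcomes[last][main_scheme] is not None:
        sections["mvmr_adjustment"] = mvmr_adjustment(
            study.exposure_stats, predictors,
            study.outcomes[last][main_scheme],
            last_estimates[main_scheme], fw)
        sections["mvmr_adjustment"]["scheme"] = main_scheme
    else:
        sections["mvmr_adjustment"] = {"applicable": False,
                                       "reason": "main scheme not estimable"}
    # serialisable copies of the estimator tables (analysis panels)
    sections["estimates"] = {
        "forward_latest": {n: (e.to_dict() if e is not None else None)
                           for n, e in forward[last].items()},
        "forward_suite_latest": forward_full,
    }
    return assemble_report(sections, study.truth.counts[last], fw,
                           scenario=cfg.name)
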