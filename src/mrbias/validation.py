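"""Simulation-based validation harnesses for the estimators and the
bias-assessment framework.

Each replicate function simulates a fresh two-sample study under a scenario
and returns the quantities a calibration or power property needs; the batch
runners aggregate replicates with seeds derived deterministically from one
base seed.  These harnesses back both the test suite and the acceptance
script, so the numbers they report are always recomputed from scratch.
"""
from __future__ import annotations

import numpy as np

from . import estimators as est
from .framework import FrameworkConfig, forward_mr, reverse_mr
from .gwas_io import NoInstrumentsError, SummaryStatsError, select_instruments
from .ldsc import fit_rg
from .mvmr import build_multi_exposure, mvmr_ivw
from .simulate import (ScenarioConfig, apply_scheme, draw_tested, gwas,
                       simulate_cohort, simulate_ldsc_sumstats, simulate_panel,
                       simulate_study)


def _rep_seed(base_seed: int, rep: int) -> int:
    # fixed-offset derivation keeps every per-replicate seed below 2**31
    return (int(base_seed) * 1_000_003 + rep * 7919 + 17) % (2**31 - 1)


def _estimand(cfg: ScenarioConfig, scheme: str, base_seed: int) -> float:
    """Scheme-level estimand oracle at the panel's realised genetic
    variances (deterministic given the base seed)."""
    from .simulate import _derived_rng, scheme_estimand
    panel = simulate_panel(cfg, _derived_rng(_rep_seed(base_seed, 0), 11))
    return scheme_estimand(cfg, scheme, n=400_000,
                           seed=_rep_seed(base_seed, 10**6),
                           panel_variances={
                               "sep_genetic": panel.var_sep_gen,
                               "exposure_genetic": panel.var_exp_gen,
                               "disease_genetic": panel.var_dis_gen})


def forward_reverse_replicate(cfg: ScenarioConfig, seed: int,
                              scheme: str = "C2",
                              fw: FrameworkConfig | None = None) -> dict:
    """One replicate of the forward (exposure->disease) and reverse
    (no-relevance) analyses for one scheme."""
    fw = fw or FrameworkConfig(seed=seed)
    study = simulate_study(cfg, seed=seed, schemes=[scheme])
    stats = study.outcomes[study.release_tags[-1]][scheme]
    out: dict[str, object] = {"seed": seed}
    if stats is None:
        out["estimable"] = False
        return out
    fres = forward_mr(study.exposure_stats, stats, fw)
    out["forward_beta"] = fres["ivw_mre"]["beta"]
    out["forward_se"] = fres["ivw_mre"]["se"]
    out["egger_intercept"] = (fres.get("egger_diagnostics") or {}).get(
        "egger_intercept")
    out["mean_F"] = fres["mean_F"]
    out["total_R2"] = fres["total_R2"]
    try:
        rres = reverse_mr(stats, study.exposure_stats, fw)
        ivw_d = rres["ivw_mre"]
        out["reverse_beta"] = ivw_d["beta"]
        out["reverse_ci"] = (ivw_d["ci_low"], ivw_d["ci_high"])
        out["reverse_covers_zero"] = bool(
            ivw_d["ci_low"] <= 0.0 <= ivw_d["ci_high"])
        out["reverse_flag"] = not out["reverse_covers_zero"]
        out["reverse_n_instruments"] = rres["n_snps"]
    except (NoInstrumentsError, SummaryStatsError):
        out["reverse_flag"] = None
    out["estimable"] = True
    return out


def calibration_batch(cfg: ScenarioConfig, n_reps: int, base_seed: int,
                      scheme: str = "C2") -> dict:
    """Replicated S0-style calibration: forward IVW bias against the marginal
    log-OR estimand, reverse-CI coverage of zero, Egger intercept."""
    from .simulate import marginal_log_or
    fbetas, intercepts, covers, flags = [], [], [], []
    panel_vars = None
    for r in range(n_reps):
        rep = forward_reverse_replicate(cfg, _rep_seed(base_seed, r), scheme)
        if not rep["estimable"]:
            continue
        fbetas.append(rep["forward_beta"])
        if rep.get("egger_intercept") is not None:
            intercepts.append(rep["egger_intercept"])
        if rep.get("reverse_flag") is not None:
            covers.append(rep["reverse_covers_zero"])
            flags.append(rep["reverse_flag"])
    # estimand: scheme-level log-OR per SD of exposure-specific genetic
    # shift (selection/misclassification of the scheme included), evaluated
    # at the generator's realised genetic variances
    truth = _estimand(cfg, scheme, base_seed)
    fbetas = np.asarray(fbetas)
    return {
        "n_reps": len(fbetas),
        "theta": cfg.theta,
        "estimand": truth,
        "forward_mean": float(np.mean(fbetas)),
        "forward_bias": float(np.mean(fbetas) - truth),
        "forward_mc_se": float(np.std(fbetas, ddof=1) / np.sqrt(len(fbetas))),
        "egger_intercept_mean": float(np.mean(intercepts)) if intercepts else None,
        "egger_intercept_mc_se": (float(np.std(intercepts, ddof=1)
                                        / np.sqrt(len(intercepts)))
                                  if len(intercepts) > 1 else None),
        "reverse_coverage": float(np.mean(covers)) if covers else None,
        "reverse_flag_rate": float(np.mean(flags)) if flags else None,
    }


def no_relevance_flag_rate(cfg: ScenarioConfig, n_reps: int, base_seed: int,
                           scheme: str = "C2") -> dict:
    """Fraction of replicates in which the no-relevance flag fires."""
    flags = []
    for r in range(n_reps):
        rep = forward_reverse_replicate(cfg, _rep_seed(base_seed, r), scheme)
        if rep.get("reverse_flag") is not None:
            flags.append(rep["reverse_flag"])
    return {"n_reps": len(flags),
            "flag_rate": float(np.mean(flags)) if flags else None}


def misclassification_replicate(cfg: ScenarioConfig, seed: int,
                                levels: list[float] | None = None,
                                pop_scheme: str = "C2",
                                tested_scheme: str = "C1",
                                fw: FrameworkConfig | None = None) -> dict:
    """One replicate of the contamination experiment.

    The outcome cohort is drawn once; the testing flag is re-drawn at each
    testing-policy intercept in ``levels`` (lower intercept => more infected
    individuals untested => more contaminated population controls).  Returns
    the population-control |log-OR| per level plus the tested-control
    estimate at the least-contaminated level.
    """
    fw = fw or FrameworkConfig(seed=seed)
    levels = levels if levels is not None else cfg.contamination_levels
    if not levels:
        raise ValueError("no contamination levels configured")
    from .simulate import _derived_rng
    panel = simulate_panel(cfg, _derived_rng(seed, 11))
    exp_cohort = simulate_cohort(cfg, _derived_rng(seed, 13), panel)
    out_cohort = simulate_cohort(cfg, _derived_rng(seed, 17), panel)
    exposure_stats = gwas(exp_cohort, "exposure")
    instruments = select_instruments(exposure_stats, fw.p_instruments,
                                     fw.prune_window_bp)

    def _ivw_for(labels) -> float:
        stats = gwas(out_cohort, labels, trait_name="case_status")
        from .gwas_io import harmonise
        h = harmonise(instruments, stats)
        return est.ivw(h)[0].beta

    rng_test = _derived_rng(seed, 23)
    pop_betas = []
    tested_beta = None
    contamination = []
    for i, c0 in enumerate(levels):
        out_cohort.tested = draw_tested(
            out_cohort, cfg, rng_test, c0_per_era=np.full(len(cfg.releases), c0))
        labels_pop, _ = apply_scheme(out_cohort, pop_scheme)
        pop_betas.append(_ivw_for(labels_pop))
        inf = out_cohort.infected
        contamination.append(float(np.mean(~out_cohort.tested[inf])))
        if i == 0:
            labels_tested, _ = apply_scheme(out_cohort, tested_scheme)
            tested_beta = _ivw_for(labels_tested)
    return {"levels": list(levels), "contamination_fraction": contamination,
            "pop_abs_betas": [abs(b) for b in pop_betas],
            "tested_abs_beta": abs(tested_beta)}


def misclassification_batch(cfg: ScenarioConfig, n_reps: int,
                            base_seed: int) -> dict:
    """Fraction of replicates with strictly decreasing population-control
    |log-OR| across contamination levels, all below the tested-control
    estimate."""
    mono, below, both = [], [], []
    for r in range(n_reps):
        rep = misclassification_replicate(cfg, _rep_seed(base_seed, r))
        b = rep["pop_abs_betas"]
        is_mono = all(x > y for x, y in zip(b, b[1:]))
        is_below = all(x < rep["tested_abs_beta"] for x in b)
        mono.append(is_mono)
        below.append(is_below)
        both.append(is_mono and is_below)
    return {"n_reps": n_reps,
            "monotone_rate": float(np.mean(mono)),
            "below_tested_rate": float(np.mean(below)),
            "signature_rate": float(np.mean(both))}


def mvmr_replicate(cfg: ScenarioConfig, seed: int, scheme: str = "C2",
                   fw: FrameworkConfig | None = None) -> dict:
    """One replicate of the SEP-adjustment experiment: univariable IVW vs
    the MVMR exposure coefficient adjusted for the SEP trait."""
    fw = fw or FrameworkConfig(seed=seed)
    study = simulate_study(cfg, seed=seed, schemes=[scheme])
    outcome = study.outcomes[study.release_tags[-1]][scheme]
    exp_hits = select_instruments(study.exposure_stats, fw.p_instruments,
                                  fw.prune_window_bp)
    from .gwas_io import harmonise
    h = harmonise(exp_hits, outcome)
    unadj = est.ivw(h)[0]
    try:
        sep_hits = select_instruments(study.sep_stats, fw.p_instruments,
                                      fw.prune_window_bp)
        union = list(dict.fromkeys(list(exp_hits.data["variant_id"])
                                   + list(sep_hits.data["variant_id"])))
    except NoInstrumentsError:
        union = list(exp_hits.data["variant_id"])
    mset = build_multi_exposure([study.exposure_stats, study.sep_stats],
                                outcome, union)
    adj = mvmr_ivw(mset)[0][study.exposure_stats.trait_name]
    return {"unadjusted_beta": unadj.beta, "adjusted_beta": adj.beta}


def mvmr_recovery_batch(cfg: ScenarioConfig, n_reps: int, base_seed: int,
                        scheme: str = "C2") -> dict:
    """Fraction of replicates where adjustment moves the estimate strictly
    closer to the scheme-level estimand (brute-force oracle)."""
    truth = _estimand(cfg, scheme, base_seed)
    closer, unadj, adj = [], [], []
    for r in range(n_reps):
        rep = mvmr_replicate(cfg, _rep_seed(base_seed, r), scheme)
        unadj.append(rep["unadjusted_beta"])
        adj.append(rep["adjusted_beta"])
        closer.append(abs(rep["adjusted_beta"] - truth)
                      < abs(rep["unadjusted_beta"] - truth))
    return {"n_reps": n_reps, "truth_estimand": truth,
            "unadjusted_mean": float(np.mean(unadj)),
            "adjusted_mean": float(np.mean(adj)),
            "recovery_rate": float(np.mean(closer))}


def ldsc_recovery_batch(h2_1: float, h2_2: float, rg: float, M: int,
                        N1: int, N2: int, n_reps: int, base_seed: int) -> dict:
    """Replicated rg recovery from the direct summary-level generator."""
    within, rgs, ses = [], [], []
    for r in range(n_reps):
        s1, s2, ld = simulate_ldsc_sumstats(h2_1, h2_2, rg, M, N1, N2,
                                            seed=_rep_seed(base_seed, r))
        gc = fit_rg(s1, s2, ld)
        rgs.append(gc.rg)
        ses.append(gc.rg_se)
        within.append(abs(gc.rg - rg) <= 2.0 * gc.rg_se)
    return {"n_reps": n_reps, "true_rg": rg,
            "rg_mean": float(np.mean(rgs)),
            "rg_se_mean": float(np.mean(ses)),
            "within_2se_rate": float(np.mean(within))}
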