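"""Synthetic cohort -> GWAS generator with selection and misclassification.

The generator produces individual-level cohorts with the causal structure of
an infectious-disease MR study: unlinked biallelic variants; a heritable
socioeconomic-position (SEP) trait; a standardised quantitative exposure
(BMI analogue) with its own variants plus an optional SEP effect; infection,
hospitalisation and severity flags driven by exposure and SEP on the
logistic-liability scale; and a testing flag whose probability can depend on
SEP, exposure, symptom severity and a per-release policy intercept.  Only
infected-and-tested individuals are laboratory-confirmed, so case/control
definitions built on confirmation inherit selection bias, and "population
control" definitions label infected-but-untested individuals as controls —
the misclassification mechanism.

Seven case/control definitions mirror the COVID-19 HGI-style scheme families
(severity vs tested controls, severity vs population, hospitalisation
variants, test-positivity variants, symptom-predicted), and cumulative
releases with era-specific testing policies emulate GWAS releases over time.
Every simulated dataset carries a TruthRecord with the generating
parameters, realised counts and the expected bias direction per scheme.

Variants are simulated unlinked, so distance pruning is a no-op and LD score
regression on these GWAS uses constant LD scores (see :mod:`mrbias.ldsc`);
a separate direct summary-level generator with explicit, variable LD scores
(:func:`simulate_ldsc_sumstats`) validates the LDSC estimator independently
of the cohort path.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .gwas_io import SummaryStats
from .ldsc import LDScoreTable

_ALLELE_CYCLE = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]  # non-palindromic


class DegenerateScenarioError(ValueError):
    """A simulated flag has prevalence 0 or 1; names the offending coefficient."""


# --------------------------------------------------------------------------
# configuration

@dataclass
class ReleaseSpec:
    """One cumulative data release: recruitment fraction and testing policy."""

    tag: str
    fraction: float  # cumulative fraction of the cohort recruited by this release
    c0: float        # testing intercept for individuals recruited in this era


@dataclass
class ScenarioConfig:
    """All knobs of the cohort generator.

    Effect-size units: exposure and SEP are standardised (SD=1); theta and
    theta_sev are log-odds of infection / severity per SD exposure; the c_*
    coefficients are log-odds of being tested per unit of their argument.
    """

    name: str = "custom"
    seed: int = 0
    n: int = 20_000
    m: int = 100
    maf_range: tuple[float, float] = (0.10, 0.50)
    # genetic architecture (disjoint variant blocks; remainder null)
    n_exposure_variants: int = 50
    exposure_effect_range: tuple[float, float] = (0.07, 0.30)
    n_sep_variants: int = 20
    sep_effect_range: tuple[float, float] = (0.12, 0.22)
    n_disease_variants: int = 10
    disease_effect_range: tuple[float, float] = (0.20, 0.35)
    # structural coefficients
    delta_sep_exposure: float = 0.0   # SEP -> exposure (SD per SD)
    theta: float = 0.3                # exposure -> infection liability
    theta_sev: float = 0.3            # exposure -> hospitalisation/severity
    a0: float = -1.0                  # infection intercept
    a_sep: float = 0.0                # SEP -> infection
    b0: float = -1.0                  # hospitalisation (among infected) intercept
    b_sep: float = 0.0
    d0: float = -1.0                  # severe (among hospitalised) intercept
    # selection into testing
    c_sep: float = 0.0
    c_exposure: float = 0.0
    c_severity: float = 0.0
    releases: list[ReleaseSpec] = field(
        default_factory=lambda: [ReleaseSpec("r6", 1.0, 3.0)])
    # horizontal pleiotropy: direct infection effects of exposure variants
    pleiotropy_frac: float = 0.0
    pleiotropy_effect: float = 0.0
    pleiotropy_mode: str = "balanced"  # balanced | directional
    # symptom-predicted classifier (D1 family)
    d1_sensitivity: float = 0.75
    d1_specificity: float = 0.95
    # GWAS filters
    min_minor_count: int = 5
    # optional testing-intercept grid for misclassification experiments
    contamination_levels: list[float] | None = None

    def __post_init__(self) -> None:
        total = (self.n_exposure_variants + self.n_sep_variants
                 + self.n_disease_variants)
        if total > self.m:
            raise ValueError(f"variant blocks ({total}) exceed m={self.m}")
        if not self.releases:
            raise ValueError("at least one release is required")
        self.releases = [r if isinstance(r, ReleaseSpec) else ReleaseSpec(**r)
                         for r in self.releases]
        fracs = [r.fraction for r in self.releases]
        if any(f <= 0 or f > 1 for f in fracs) or fracs != sorted(fracs):
            raise ValueError("release fractions must be increasing in (0,1]")
        if abs(fracs[-1] - 1.0) > 1e-9:
            raise ValueError("final release fraction must be 1.0")
        for frac_name in ("d1_sensitivity", "d1_specificity",
                          "pleiotropy_frac"):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{frac_name} must be in [0,1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["releases"] = [dataclasses.asdict(r) for r in self.releases]
        d["maf_range"] = list(self.maf_range)
        for k in ("exposure_effect_range", "sep_effect_range",
                  "disease_effect_range"):
            d[k] = list(getattr(self, k))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        d.pop("kind", None)
        for k in ("maf_range", "exposure_effect_range", "sep_effect_range",
                  "disease_effect_range"):
            if k in d:
                d[k] = tuple(d[k])
        if "contamination_levels" in d and d["contamination_levels"] is not None:
            d["contamination_levels"] = list(d["contamination_levels"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class LdscScenario:
    """Parameters of the direct summary-level LDSC generator."""

    name: str = "ldsc"
    h2_trait1: float = 0.5
    h2_trait2: float = 0.4
    rg: float = 0.3
    M: int = 5000
    N1: int = 50_000
    N2: int = 50_000


def load_scenario(name_or_path) -> ScenarioConfig | LdscScenario:
    """Load a packaged scenario (S0..S5) or a user YAML file."""
    p = Path(str(name_or_path))
    if p.exists():
        with open(p) as fh:
            d = yaml.safe_load(fh)
    else:
        ref = resources.files("mrbias.scenarios").joinpath(f"{name_or_path}.yaml")
        if not ref.is_file():
            raise FileNotFoundError(f"unknown scenario {name_or_path!r}")
        d = yaml.safe_load(ref.read_text())
    if d.get("kind") == "ldsc_summary":
        d = {k: v for k, v in d.items() if k != "kind"}
        return LdscScenario(**d)
    return ScenarioConfig.from_dict(d)


# --------------------------------------------------------------------------
# variant panel and cohort

@dataclass
class VariantPanel:
    """Shared genome: variant metadata and true per-variant effects."""

    variant_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    maf: np.ndarray
    gamma: np.ndarray          # exposure effects (SD per effect allele)
    alpha: np.ndarray          # SEP effects
    beta_disease: np.ndarray   # direct infection-liability effects

    @property
    def m(self) -> int:
        return len(self.variant_id)

    @property
    def var_g(self) -> np.ndarray:
        return 2.0 * self.maf * (1.0 - self.maf)

    @property
    def var_sep_gen(self) -> float:
        return float(np.sum(self.var_g * self.alpha**2))

    @property
    def var_exp_gen(self) -> float:
        return float(np.sum(self.var_g * self.gamma**2))

    @property
    def var_dis_gen(self) -> float:
        return float(np.sum(self.var_g * self.beta_disease**2))


def simulate_panel(cfg: ScenarioConfig, rng: np.random.Generator) -> VariantPanel:
    m = cfg.m
    maf = rng.uniform(*cfg.maf_range, size=m)
    lo, hi = cfg.exposure_effect_range
    gamma = np.zeros(m)
    alpha = np.zeros(m)
    beta_dis = np.zeros(m)
    i0 = cfg.n_exposure_variants
    i1 = i0 + cfg.n_sep_variants
    i2 = i1 + cfg.n_disease_variants
    gamma[:i0] = rng.uniform(lo, hi, i0) * rng.choice([-1.0, 1.0], i0)
    lo, hi = cfg.sep_effect_range
    alpha[i0:i1] = rng.uniform(lo, hi, i1 - i0) * rng.choice([-1.0, 1.0], i1 - i0)
    lo, hi = cfg.disease_effect_range
    beta_dis[i1:i2] = rng.uniform(lo, hi, i2 - i1) * rng.choice([-1.0, 1.0], i2 - i1)
    # horizontal pleiotropy: direct disease effects of some exposure variants
    n_pleio = int(round(cfg.pleiotropy_frac * cfg.n_exposure_variants))
    if n_pleio and cfg.pleiotropy_effect:
        idx = rng.choice(i0, size=n_pleio, replace=False)
        if cfg.pleiotropy_mode == "directional":
            signs = np.ones(n_pleio)
        else:
            signs = rng.choice([-1.0, 1.0], n_pleio)
        beta_dis[idx] += signs * cfg.pleiotropy_effect

    chrom = np.array([str(i % 22 + 1) for i in range(m)])
    pos = np.array([(i // 22 + 1) * 10_000_000 for i in range(m)], dtype=int)
    ea = np.array([_ALLELE_CYCLE[i % 4][0] for i in range(m)])
    oa = np.array([_ALLELE_CYCLE[i % 4][1] for i in range(m)])
    ids = np.array([f"rs{i+1}" for i in range(m)])
    return VariantPanel(variant_id=ids, chrom=chrom, pos=pos, effect_allele=ea,
                        other_allele=oa, maf=maf, gamma=gamma, alpha=alpha,
                        beta_disease=beta_dis)


@dataclass
class Cohort:
    """One simulated sample: genotypes plus all phenotype and status flags."""

    panel: VariantPanel
    genotypes: np.ndarray = field(repr=False)  # n x m int8
    sep: np.ndarray = field(repr=False)
    exposure: np.ndarray = field(repr=False)
    infected: np.ndarray = field(repr=False)
    hospitalised: np.ndarray = field(repr=False)
    severe: np.ndarray = field(repr=False)
    severity_score: np.ndarray = field(repr=False)  # 0..3
    tested: np.ndarray = field(repr=False)
    d1_positive: np.ndarray = field(repr=False)
    era: np.ndarray = field(repr=False)  # release-era index per individual

    @property
    def n(self) -> int:
        return len(self.exposure)


def _check_prevalence(flag: np.ndarray, coefficient: str) -> None:
    p = float(np.mean(flag))
    if p in (0.0, 1.0):
        raise DegenerateScenarioError(
            f"degenerate prevalence {p:.0f} — adjust coefficient {coefficient!r}")


def _draw_genotypes(rng, maf, n):
    m = len(maf)
    return ((rng.random((n, m)) < maf).view(np.int8)
            + (rng.random((n, m)) < maf).view(np.int8))


def draw_tested(cohort: Cohort, cfg: ScenarioConfig,
                rng: np.random.Generator,
                c0_per_era: np.ndarray | None = None) -> np.ndarray:
    """Draw the tested flag given the rest of the cohort (used for the main
    draw and for re-drawing under alternative testing policies)."""
    if c0_per_era is None:
        c0_per_era = np.array([r.c0 for r in cfg.releases])
    lin = (c0_per_era[cohort.era] + cfg.c_sep * cohort.sep
           + cfg.c_exposure * cohort.exposure
           + cfg.c_severity * cohort.severity_score)
    return rng.random(cohort.n) < expit(lin)


def simulate_cohort(cfg: ScenarioConfig, rng: np.random.Generator,
                    panel: VariantPanel | None = None) -> Cohort:
    """Draw one cohort under the scenario's structural model.

    Genotypes are Binomial(2, maf) and independent across variants; SEP and
    the exposure are standardised to approximately unit variance by setting
    the noise variance to the remainder after the genetic (and SEP)
    contributions.  severe => hospitalised => infected by construction.
    """
    if panel is None:
        panel = simulate_panel(cfg, rng)
    n = cfg.n
    G = _draw_genotypes(rng, panel.maf, n)
    Gc = G - 2.0 * panel.maf  # centred dosages for phenotype construction

    sep_noise_var = max(0.05, 1.0 - panel.var_sep_gen)
    sep = Gc @ panel.alpha + rng.standard_normal(n) * np.sqrt(sep_noise_var)

    delta = cfg.delta_sep_exposure
    exp_noise_var = max(0.05, 1.0 - panel.var_exp_gen - delta**2)
    exposure = (Gc @ panel.gamma + delta * sep
                + rng.standard_normal(n) * np.sqrt(exp_noise_var))

    lin_inf = (cfg.a0 + cfg.theta * exposure + cfg.a_sep * sep
               + Gc @ panel.beta_disease)
    infected = rng.random(n) < expit(lin_inf)
    _check_prevalence(infected, "a0")

    lin_sev = cfg.theta_sev * exposure + cfg.b_sep * sep
    hospitalised = infected & (rng.random(n) < expit(cfg.b0 + lin_sev))
    severe = hospitalised & (rng.random(n) < expit(cfg.d0 + lin_sev))
    severity_score = (infected.astype(np.int8) + hospitalised.astype(np.int8)
                      + severe.astype(np.int8))

    fracs = np.array([r.fraction for r in cfg.releases])
    era = np.searchsorted(fracs, (np.arange(n) + 0.5) / n)

    d1_rand = rng.random(n)
    d1_positive = np.where(infected, d1_rand < cfg.d1_sensitivity,
                           d1_rand < 1.0 - cfg.d1_specificity)

    cohort = Cohort(panel=panel, genotypes=G, sep=sep, exposure=exposure,
                    infected=infected, hospitalised=hospitalised,
                    severe=severe, severity_score=severity_score,
                    tested=np.zeros(n, bool), d1_positive=d1_positive, era=era)
    cohort.tested = draw_tested(cohort, cfg, rng)
    _check_prevalence(cohort.tested, "c0")
    return cohort


# --------------------------------------------------------------------------
# case/control schemes

@dataclass(frozen=True)
class Scheme:
    """A case/control definition: predicates over cohort status flags.

    Individuals matching neither predicate are excluded.  Population-control
    schemes define controls as anyone who is not a case, which labels
    infected-but-untested individuals as controls (misclassification).
    """

    name: str
    case: Callable
    control: Callable
    population_controls: bool
    bias_note: str


def _confirmed(c) -> np.ndarray:
    return c.infected & c.tested


SCHEMES: dict[str, Scheme] = {
    "A1": Scheme(
        "A1",
        case=lambda c: _confirmed(c) & c.severe,
        control=lambda c: _confirmed(c) & ~c.hospitalised,
        population_controls=False,
        bias_note=("sample conditional on confirmed infection and on hospital "
                   "admission: collider selection when testing/diagnosis is "
                   "predicted by other traits; typically the smallest sample")),
    "A2": Scheme(
        "A2",
        case=lambda c: _confirmed(c) & c.severe,
        control=lambda c: ~(_confirmed(c) & c.severe),
        population_controls=True,
        bias_note=("population controls include infected-but-untested "
                   "individuals (misclassification); case status still "
                   "conditional on testing (selection)")),
    "B1": Scheme(
        "B1",
        case=lambda c: _confirmed(c) & c.hospitalised,
        control=lambda c: _confirmed(c) & ~c.hospitalised,
        population_controls=False,
        bias_note=("both groups conditional on confirmed infection: collider "
                   "selection through predictors of testing and admission")),
    "B2": Scheme(
        "B2",
        case=lambda c: _confirmed(c) & c.hospitalised,
        control=lambda c: ~(_confirmed(c) & c.hospitalised),
        population_controls=True,
        bias_note=("population controls include untested infected individuals "
                   "(misclassification of cases as controls)")),
    "C1": Scheme(
        "C1",
        case=lambda c: _confirmed(c),
        control=lambda c: c.tested & ~c.infected,
        population_controls=False,
        bias_note=("sample conditional on being tested: collider selection "
                   "when testing is predicted by exposure, severity or SEP")),
    "C2": Scheme(
        "C2",
        case=lambda c: _confirmed(c),
        control=lambda c: ~_confirmed(c),
        population_controls=True,
        bias_note=("controls are anyone not a confirmed case, including "
                   "untested infected individuals (misclassification)")),
    "D1": Scheme(
        "D1",
        case=lambda c: c.d1_positive,
        control=lambda c: ~c.d1_positive,
        population_controls=True,
        bias_note=("symptom-predicted status: misreporting in both groups "
                   "(imperfect sensitivity/specificity) and unknown infection "
                   "status")),
}


def apply_scheme(cohort: Cohort, scheme: Scheme | str,
                 mask: np.ndarray | None = None
                 ) -> tuple[np.ndarray, dict[str, int]]:
    """Label a cohort (or a sub-sample mask) under one scheme.

    Returns labels (1 case, 0 control, -1 excluded) over the full cohort,
    with everyone outside ``mask`` excluded, plus realised counts.
    """
    if isinstance(scheme, str):
        scheme = SCHEMES[scheme]
    cases = scheme.case(cohort)
    controls = scheme.control(cohort) & ~cases
    labels = np.full(cohort.n, -1, dtype=np.int8)
    labels[controls] = 0
    labels[cases] = 1
    if mask is not None:
        labels[~mask] = -1
    counts = {"cases": int(np.sum(labels == 1)),
              "controls": int(np.sum(labels == 0)),
              "excluded": int(np.sum(labels == -1))}
    return labels, counts


# --------------------------------------------------------------------------
# per-variant association scans

def _linear_scan(G: np.ndarray, y: np.ndarray):
    """Closed-form per-variant simple linear regression (vectorised)."""
    n = len(y)
    Gf = G.astype(float)
    gm = Gf.mean(axis=0)
    yc = y - y.mean()
    Sgg = np.einsum("ij,ij->j", Gf, Gf) - n * gm**2
    Sgy = Gf.T @ yc
    Syy = float(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = Sgy / Sgg
        # tiny floor keeps se > 0 when the phenotype is an exact function of
        # the dosage (perfect-fit edge case)
        sigma2 = np.maximum(Syy - beta * Sgy, 1e-24) / (n - 2)
        se = np.sqrt(sigma2 / Sgg)
    return beta, se


def _logistic_scan(G: np.ndarray, y: np.ndarray, max_iter: int = 40,
                   tol: float = 1e-8):
    """Per-variant ML logistic regression (intercept + dosage), vectorised
    Newton-Raphson across variants.  Returns beta, se, converged mask."""
    n, m = G.shape
    Gf = G.astype(float)
    G2 = Gf * Gf
    ybar = float(np.mean(y))
    a = np.full(m, logit(min(max(ybar, 1e-10), 1 - 1e-10)))
    b = np.zeros(m)
    active = np.ones(m, bool)
    yv = y.astype(float)[:, None]
    det = np.ones(m)
    h00 = np.ones(m)
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        eta = a[idx] + Gf[:, idx] * b[idx]
        p = expit(eta)
        W = p * (1.0 - p) + 1e-12
        r = yv - p
        g0 = r.sum(axis=0)
        g1 = np.einsum("ij,ij->j", Gf[:, idx], r)
        h00_i = W.sum(axis=0)
        h01 = np.einsum("ij,ij->j", Gf[:, idx], W)
        h11 = np.einsum("ij,ij->j", G2[:, idx], W)
        det_i = h00_i * h11 - h01**2
        det[idx] = det_i
        h00[idx] = h00_i
        with np.errstate(divide="ignore", invalid="ignore"):
            da = (h11 * g0 - h01 * g1) / det_i
            db = (h00_i * g1 - h01 * g0) / det_i
        da = np.clip(da, -4, 4)
        db = np.clip(db, -4, 4)
        a[idx] += da
        b[idx] += db
        still = (np.maximum(np.abs(da), np.abs(db)) > tol) & (np.abs(b[idx]) < 15)
        active[idx] = still
    converged = ~active & (np.abs(b) < 12) & (det > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(h00 / det)
    return b, se, converged & np.isfinite(se)


def _panel_frame(panel: VariantPanel, keep: np.ndarray, beta, se, eaf,
                 n: int, n_cases=None, n_controls=None) -> pd.DataFrame:
    from scipy import stats as _st
    z = np.abs(beta[keep] / se[keep])
    return pd.DataFrame({
        "variant_id": panel.variant_id[keep],
        "chrom": panel.chrom[keep],
        "pos": panel.pos[keep],
        "effect_allele": panel.effect_allele[keep],
        "other_allele": panel.other_allele[keep],
        "eaf": eaf[keep],
        "beta": beta[keep],
        "se": se[keep],
        "pvalue": np.clip(2.0 * _st.norm.sf(z), 5e-324, 1.0),
        "n": n,
        "n_cases": n_cases if n_cases is not None else np.nan,
        "n_controls": n_controls if n_controls is not None else np.nan,
    })


def gwas(cohort: Cohort, phenotype, trait_name: str | None = None,
         release_tag: str = "", mask: np.ndarray | None = None,
         min_minor_count: int = 5) -> SummaryStats:
    """Per-variant GWAS of a quantitative phenotype or case/control labels.

    ``phenotype`` is "exposure", "sep", a float array (simple linear
    regression), or an int label array with -1 meaning excluded (ML logistic
    regression).  Variants that are monomorphic, have fewer than
    ``min_minor_count`` minor-allele carriers in the analysed sample, or fail
    to converge (separation) are dropped.
    """
    panel = cohort.panel
    if isinstance(phenotype, str):
        y = {"exposure": cohort.exposure, "sep": cohort.sep}[phenotype]
        trait_name = trait_name or phenotype
        binary = False
        labels = None
    else:
        arr = np.asarray(phenotype)
        binary = np.issubdtype(arr.dtype, np.integer) or arr.dtype == bool
        if binary:
            labels = arr.astype(np.int8)
            y = None
        else:
            y = arr.astype(float)
            labels = None
        trait_name = trait_name or ("case_status" if binary else "trait")

    row_mask = np.ones(cohort.n, bool) if mask is None else np.asarray(mask, bool)
    if binary:
        row_mask = row_mask & (labels >= 0)
    G = cohort.genotypes[row_mask]
    n = int(row_mask.sum())
    if n < 10:
        raise DegenerateScenarioError(f"only {n} analysable individuals")

    alt = G.sum(axis=0)
    mac = np.minimum(alt, 2 * n - alt)
    keep = mac >= min_minor_count
    eaf = alt / (2.0 * n)

    if binary:
        yb = labels[row_mask]
        beta, se, ok = _logistic_scan(G, yb)
        keep = keep & ok
        n_cases = int(np.sum(yb == 1))
        n_controls = int(np.sum(yb == 0))
        df = _panel_frame(panel, keep, beta, se, eaf, n, n_cases, n_controls)
        ttype = "binary"
    else:
        beta, se, = _linear_scan(G, y[row_mask])
        keep = keep & np.isfinite(se) & (se > 0)
        df = _panel_frame(panel, keep, beta, se, eaf, n)
        ttype = "quantitative"
    return SummaryStats(trait_name=trait_name, trait_type=ttype, data=df,
                        release_tag=release_tag,
                        provenance=f"simulated GWAS ({ttype}), n={n}")


# --------------------------------------------------------------------------
# study-level orchestration

@dataclass
class TruthRecord:
    """Ground truth serialised alongside every simulated dataset."""

    config: dict
    theta: float
    theta_sev: float
    counts: dict            # release -> scheme -> counts
    bias_notes: dict        # scheme -> expected-bias annotation
    panel_variances: dict
    theta_marginal: float | None = None

    def to_json(self, path=None) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


@dataclass
class StudyData:
    """Two-sample study: an unselected exposure-cohort GWAS plus per-scheme,
    per-release case/control GWAS from an independent outcome cohort."""

    exposure_stats: SummaryStats
    sep_stats: SummaryStats
    outcomes: dict  # release tag -> scheme name -> SummaryStats
    panel: VariantPanel
    truth: TruthRecord
    release_tags: list[str]


def _derived_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), stream]))


def simulate_releases(cfg: ScenarioConfig, cohort: Cohort,
                      schemes: Sequence[str] | None = None
                      ) -> tuple[dict, dict]:
    """GWAS per scheme for each cumulative release of the outcome cohort."""
    schemes = list(schemes) if schemes else list(SCHEMES)
    outcomes: dict[str, dict[str, SummaryStats]] = {}
    counts: dict[str, dict[str, dict]] = {}
    for r_idx, rel in enumerate(cfg.releases):
        mask = cohort.era <= r_idx
        outcomes[rel.tag] = {}
        counts[rel.tag] = {}
        for name in schemes:
            labels, cnt = apply_scheme(cohort, name, mask=mask)
            counts[rel.tag][name] = cnt
            if cnt["cases"] == 0 or cnt["controls"] == 0:
                outcomes[rel.tag][name] = None  # not estimable
                continue
            outcomes[rel.tag][name] = gwas(
                cohort, labels, trait_name=f"covid_{name}", release_tag=rel.tag,
                min_minor_count=cfg.min_minor_count)
    return outcomes, counts


def simulate_study(cfg: ScenarioConfig, seed: int | None = None,
                   schemes: Sequence[str] | None = None) -> StudyData:
    """Simulate the full two-sample study for a scenario.

    The exposure cohort (pre-pandemic, unselected) yields the quantitative
    exposure and SEP-trait GWAS; an independent outcome cohort yields the
    case/control GWAS per scheme per release.  All randomness derives from
    ``seed`` (default: the scenario's own seed).
    """
    seed = cfg.seed if seed is None else seed
    panel = simulate_panel(cfg, _derived_rng(seed, 11))
    exp_cohort = simulate_cohort(cfg, _derived_rng(seed, 13), panel)
    out_cohort = simulate_cohort(cfg, _derived_rng(seed, 17), panel)

    exposure_stats = gwas(exp_cohort, "exposure", trait_name="exposure",
                          min_minor_count=cfg.min_minor_count)
    sep_stats = gwas(exp_cohort, "sep", trait_name="sep_trait",
                     min_minor_count=cfg.min_minor_count)
    outcomes, counts = simulate_releases(cfg, out_cohort, schemes)

    truth = TruthRecord(
        config=cfg.to_dict(), theta=cfg.theta, theta_sev=cfg.theta_sev,
        counts=counts,
        bias_notes={name: SCHEMES[name].bias_note for name in
                    (schemes or SCHEMES)},
        panel_variances={"sep_genetic": panel.var_sep_gen,
                         "exposure_genetic": panel.var_exp_gen,
                         "disease_genetic": panel.var_dis_gen})
    return StudyData(exposure_stats=exposure_stats, sep_stats=sep_stats,
                     outcomes=outcomes, panel=panel, truth=truth,
                     release_tags=[r.tag for r in cfg.releases])


def write_study(study: StudyData, outdir) -> None:
    """Write the study as canonical TSVs (<run>/<release>/<scheme>.tsv),
    the exposure/SEP GWAS, a constant LD-score table and the TruthRecord."""
    from .gwas_io import write_summary_stats
    from .ldsc import write_ld_scores
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_summary_stats(study.exposure_stats, outdir / "exposure.tsv")
    write_summary_stats(study.sep_stats, outdir / "sep_trait.tsv")
    for rel, by_scheme in study.outcomes.items():
        rdir = outdir / rel
        rdir.mkdir(exist_ok=True)
        for name, stats in by_scheme.items():
            if stats is not None:
                write_summary_stats(stats, rdir / f"{name}.tsv")
    write_ld_scores(constant_ld_table(study.panel), outdir / "ld_scores.tsv")
    study.truth.to_json(outdir / "truth.json")


def constant_ld_table(panel: VariantPanel) -> LDScoreTable:
    """LD scores for the unlinked design: l_j = 1, M = m."""
    return LDScoreTable(
        scores=pd.DataFrame({"variant_id": panel.variant_id,
                             "ld_score": np.ones(panel.m)}),
        M=panel.m)


# --------------------------------------------------------------------------
# estimand oracles (phenotype-only Monte Carlo, no genotypes)

@dataclass
class _PhenotypeDraw:
    sep: np.ndarray
    exposure: np.ndarray
    infected: np.ndarray
    hospitalised: np.ndarray
    severe: np.ndarray
    severity_score: np.ndarray
    tested: np.ndarray
    d1_positive: np.ndarray
    era: np.ndarray

    @property
    def n(self) -> int:
        return len(self.exposure)


def _phenotypes_only(cfg: ScenarioConfig, n: int, rng: np.random.Generator,
                     panel_variances: dict | None = None) -> _PhenotypeDraw:
    """Draw phenotypes with genetic contributions folded into normal noise.

    Valid because genotypes enter the structural model only through the SEP,
    exposure and disease-liability sums, which are approximately normal.
    """
    pv = panel_variances or {}
    v_sep = float(pv.get("sep_genetic", 0.0))
    v_exp = float(pv.get("exposure_genetic", 0.0))
    v_dis = float(pv.get("disease_genetic", 0.0))
    sep = rng.standard_normal(n) * np.sqrt(v_sep + max(0.05, 1.0 - v_sep))
    delta = cfg.delta_sep_exposure
    exposure = (rng.standard_normal(n) * np.sqrt(
        v_exp + max(0.05, 1.0 - v_exp - delta**2)) + delta * sep)
    lin = (cfg.a0 + cfg.theta * exposure + cfg.a_sep * sep
           + rng.standard_normal(n) * np.sqrt(v_dis))
    infected = rng.random(n) < expit(lin)
    lin_sev = cfg.theta_sev * exposure + cfg.b_sep * sep
    hospitalised = infected & (rng.random(n) < expit(cfg.b0 + lin_sev))
    severe = hospitalised & (rng.random(n) < expit(cfg.d0 + lin_sev))
    score = (infected.astype(np.int8) + hospitalised.astype(np.int8)
             + severe.astype(np.int8))
    fracs = np.array([r.fraction for r in cfg.releases])
    era = np.searchsorted(fracs, (np.arange(n) + 0.5) / n)
    c0 = np.array([r.c0 for r in cfg.releases])
    tested = rng.random(n) < expit(c0[era] + cfg.c_sep * sep
                                   + cfg.c_exposure * exposure
                                   + cfg.c_severity * score)
    d1r = rng.random(n)
    d1 = np.where(infected, d1r < cfg.d1_sensitivity,
                  d1r < 1.0 - cfg.d1_specificity)
    return _PhenotypeDraw(sep=sep, exposure=exposure, infected=infected,
                          hospitalised=hospitalised, severe=severe,
                          severity_score=score, tested=tested, d1_positive=d1,
                          era=era)


def _logistic_slope(x: np.ndarray, y: np.ndarray) -> float:
    b, se, ok = _logistic_scan(x[:, None], y.astype(np.int8))
    if not ok[0]:
        raise RuntimeError("oracle logistic fit failed")
    return float(b[0])


def _scheme_mass(cfg: ScenarioConfig, scheme_name: str, x, sep, dis, era_c0
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Per-individual case and control probabilities under one scheme.

    Given the covariates, every status flag is a product of conditionally
    independent Bernoullis, so the scheme's case/control probabilities have
    closed forms over the four severity states (not infected; infected not
    admitted; admitted not severe; severe) and the state-dependent testing
    probability."""
    p_inf = expit(cfg.a0 + cfg.theta * x + cfg.a_sep * sep + dis)
    lin_sev = cfg.theta_sev * x + cfg.b_sep * sep
    p_h = expit(cfg.b0 + lin_sev)
    p_s = expit(cfg.d0 + lin_sev)
    s = [1.0 - p_inf,
         p_inf * (1.0 - p_h),
         p_inf * p_h * (1.0 - p_s),
         p_inf * p_h * p_s]
    t_base = era_c0 + cfg.c_sep * sep + cfg.c_exposure * x
    t = [expit(t_base + cfg.c_severity * k) for k in range(4)]
    confirmed = s[1] * t[1] + s[2] * t[2] + s[3] * t[3]
    if scheme_name == "infection":  # no-scheme reference: infected vs not
        return p_inf, 1.0 - p_inf
    if scheme_name == "A1":
        return s[3] * t[3], s[1] * t[1]
    if scheme_name == "A2":
        case = s[3] * t[3]
        return case, 1.0 - case
    if scheme_name == "B1":
        return s[2] * t[2] + s[3] * t[3], s[1] * t[1]
    if scheme_name == "B2":
        case = s[2] * t[2] + s[3] * t[3]
        return case, 1.0 - case
    if scheme_name == "C1":
        return confirmed, s[0] * t[0]
    if scheme_name == "C2":
        return confirmed, 1.0 - confirmed
    if scheme_name == "D1":
        case = cfg.d1_sensitivity * p_inf + (1.0 - cfg.d1_specificity) * (1.0 - p_inf)
        return case, 1.0 - case
    raise KeyError(scheme_name)


def scheme_estimand(cfg: ScenarioConfig, scheme: str = "infection",
                    n: int = 400_000, seed: int = 0,
                    panel_variances: dict | None = None,
                    h: float = 0.02) -> float:
    """Brute-force estimand oracle: the population log-odds of case (versus
    control) per SD of an exposure-specific genetic shift, under a scheme's
    selection and misclassification rules.

    A variant affecting only the exposure shifts it additively; the estimand
    a valid MR instrument targets is therefore the derivative of the
    population case/control log odds with respect to such a shift,
    marginalised over everything else.  Computed by central finite
    difference on the closed-form per-individual scheme probabilities over
    a Monte-Carlo covariate draw — deterministic given the draw, so the
    only noise is covariate sampling.
    """
    pv = panel_variances or {}
    v_sep = float(pv.get("sep_genetic", 0.0))
    v_exp = float(pv.get("exposure_genetic", 0.0))
    v_dis = float(pv.get("disease_genetic", 0.0))
    rng = np.random.default_rng(seed)
    sep = rng.standard_normal(n) * np.sqrt(v_sep + max(0.05, 1.0 - v_sep))
    delta = cfg.delta_sep_exposure
    x = (rng.standard_normal(n)
         * np.sqrt(v_exp + max(0.05, 1.0 - v_exp - delta**2)) + delta * sep)
    dis = rng.standard_normal(n) * np.sqrt(v_dis)
    fracs = np.array([r.fraction for r in cfg.releases])
    era = np.searchsorted(fracs, (np.arange(n) + 0.5) / n)
    era_c0 = np.array([r.c0 for r in cfg.releases])[era]

    def logodds(shift: float) -> float:
        case, ctrl = _scheme_mass(cfg, scheme, x + shift, sep, dis, era_c0)
        return float(np.log(np.mean(case)) - np.log(np.mean(ctrl)))

    return (logodds(+h) - logodds(-h)) / (2.0 * h)


def marginal_log_or(cfg: ScenarioConfig, n: int = 400_000, seed: int = 0,
                    panel_variances: dict | None = None) -> float:
    """Marginal log-odds of infection per SD of exposure-specific genetic
    shift — the estimand a valid summary-data MR with a logistic-GWAS
    outcome targets in the absence of selection and misclassification
    (smaller in magnitude than the conditional liability coefficient theta
    because of non-collapsibility)."""
    return scheme_estimand(cfg, "infection", n=n, seed=seed,
                           panel_variances=panel_variances)


def scheme_log_or(cfg: ScenarioConfig, scheme: Scheme | str,
                  n: int = 1_000_000, seed: int = 0,
                  panel_variances: dict | None = None) -> float:
    """Brute-force Monte-Carlo estimand: the log-odds of case status per SD
    exposure in the population actually analysed under a scheme (after
    selection and misclassification).  The reference against which the
    direction and size of scheme-level bias is judged."""
    if isinstance(scheme, str):
        scheme = SCHEMES[scheme]
    ph = _phenotypes_only(cfg, n, np.random.default_rng(seed), panel_variances)
    cases = scheme.case(ph)
    controls = scheme.control(ph) & ~cases
    keep = cases | controls
    return _logistic_slope(ph.exposure[keep], cases[keep].astype(np.int8))


# --------------------------------------------------------------------------
# direct summary-level LDSC generator

def simulate_ldsc_sumstats(h2_1: float, h2_2: float, rg: float, M: int,
                           N1: int, N2: int, seed: int,
                           ld_shape: float = 2.0, ld_scale: float = 20.0
                           ) -> tuple[SummaryStats, SummaryStats, LDScoreTable]:
    """Generate two traits' summary statistics directly at the z-score level.

    Per-variant true effects are bivariate normal with per-variant variance
    h2*l_j/M and cross-covariance rg*sqrt(h2_1*h2_2)*l_j/M; observed
    z = sqrt(N)*effect + independent standard normal noise (non-overlapping
    samples).  LD scores are Gamma(shape, scale) draws — a stand-in for a
    real reference's l distribution.
    """
    if not -1.0 <= rg <= 1.0:
        raise ValueError("rg must be in [-1,1]")
    rng = np.random.default_rng(seed)
    ell = rng.gamma(ld_shape, ld_scale, size=M)
    u = rng.standard_normal(M)
    v = rng.standard_normal(M)
    s1 = np.sqrt(np.maximum(h2_1, 0.0) * ell / M)
    s2 = np.sqrt(np.maximum(h2_2, 0.0) * ell / M)
    eta1 = s1 * u
    eta2 = s2 * (rg * u + np.sqrt(max(0.0, 1.0 - rg**2)) * v)
    z1 = np.sqrt(N1) * eta1 + rng.standard_normal(M)
    z2 = np.sqrt(N2) * eta2 + rng.standard_normal(M)

    ids = np.array([f"snp{i+1}" for i in range(M)])
    ea = np.array([_ALLELE_CYCLE[i % 4][0] for i in range(M)])
    oa = np.array([_ALLELE_CYCLE[i % 4][1] for i in range(M)])
    maf = rng.uniform(0.05, 0.5, M)

    def _stats(z, N, name):
        se = np.full(M, 1.0 / np.sqrt(N))
        from scipy import stats as _st
        df = pd.DataFrame({
            "variant_id": ids,
            "chrom": np.array([str(i % 22 + 1) for i in range(M)]),
            "pos": np.arange(1, M + 1) * 100_000,
            "effect_allele": ea, "other_allele": oa, "eaf": maf,
            "beta": z * se, "se": se,
            "pvalue": np.clip(2.0 * _st.norm.sf(np.abs(z)), 5e-324, 1.0),
            "n": N, "n_cases": np.nan, "n_controls": np.nan})
        return SummaryStats(trait_name=name, trait_type="quantitative",
                            data=df, provenance="direct summary-level simulation")

    ld = LDScoreTable(scores=pd.DataFrame({"variant_id": ids, "ld_score": ell}),
                      M=M)
    return _stats(z1, N1, "trait1"), _stats(z2, N2, "trait2"), ld
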