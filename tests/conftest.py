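import numpy as np
import pandas as pd
import pytest

from mrbias.gwas_io import HarmonisedSet, SummaryStats


def make_sumstats(rows, trait_name="trait", trait_type="quantitative",
                  release_tag=""):
    """Build a SummaryStats from a list of dicts with canonical keys."""
    return SummaryStats(trait_name=trait_name, trait_type=trait_type,
                        data=pd.DataFrame(rows), release_tag=release_tag)


def make_harmonised(bx, by, se_y, se_x=None, eaf=None, outcome_type="binary"):
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    se_y = np.asarray(se_y, float) if np.ndim(se_y) else np.full_like(bx, se_y)
    se_x = (np.asarray(se_x, float) if se_x is not None
            else np.full_like(bx, 0.01))
    eaf = (np.asarray(eaf, float) if eaf is not None
           else np.full_like(bx, np.nan))
    ids = np.array([f"rs{i+1}" for i in range(len(bx))])
    flags = pd.DataFrame({"variant_id": ids, "action": "kept"})
    return HarmonisedSet(variant_ids=ids, beta_exposure=bx, se_exposure=se_x,
                         beta_outcome=by, se_outcome=se_y,
                         eaf_exposure=eaf, flags=flags,
                         outcome_type=outcome_type)


@pytest.fixture
def toy_harmonised():
    """Three clean instruments, by = 0.5*bx exactly plus intercept 0.02."""
    return make_harmonised([0.1, 0.2, 0.3], [0.07, 0.12, 0.17], 0.01)


@pytest.fixture(scope="session")
def small_cfg():
    """A fast cohort scenario for unit tests (not the packaged study size)."""
    from mrbias.simulate import ScenarioConfig
    return ScenarioConfig(name="unit", n=4000, m=60, n_exposure_variants=25,
                          n_sep_variants=10, n_disease_variants=8)
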