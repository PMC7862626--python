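import numpy as np
import pytest

import medchain as mc
from medchain.mr import run_gene_mr


@pytest.fixture(scope="session")
def small_cohort():
    """A moderate cohort reused across read-only tests."""
    cohort, annotation, truth = mc.gen_cohort(mc.CohortSimConfig(n=1500, seed=42))
    return cohort, annotation, truth


@pytest.fixture(scope="session")
def null_mr_run():
    """1000 genes simulated under a zero causal effect, all estimators run.

    Shared between the type-I-error checks of the generator and the
    false-call-rate check of the triple-concordance rule.
    """
    tables, _ = mc.gen_two_sample_gwas(
        mc.GwasSimConfig(n_genes=1000, theta=0.0, seed=11)
    )
    estimates = run_gene_mr(tables, seed=11, n_boot=200)
    return estimates


@pytest.fixture(scope="session")
def balanced_pleiotropy_intercepts():
    """Egger intercepts across 500 genes simulated with balanced pleiotropy."""
    cfg = mc.GwasSimConfig(n_genes=500, theta=0.1, pleiotropy_mode="balanced",
                           pleiotropy_sd=0.01, seed=21)
    tables, _ = mc.gen_two_sample_gwas(cfg)
    intercepts = []
    for t in tables.values():
        try:
            pruned, _ = mc.select_instruments(t)
        except mc.NotEnoughInstruments:
            continue
        intercepts.append(mc.egger_regression(pruned).egger_intercept)
    return np.array(intercepts)


def confounder_matrix(data):
    from medchain.pipeline import _confounder_matrix

    return _confounder_matrix(data)
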