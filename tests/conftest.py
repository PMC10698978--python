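"""Shared fixtures: the attack panel, engines, a trained sieve classifier,
and pedigree cohorts. Session-scoped because the attack panel and the
classifier are reused across many tests."""

from __future__ import annotations

import numpy as np
import pytest

from haploleak.attack import train_match_classifier
from haploleak.engine import EngineParams, ImputationEngine
from haploleak.fixtures import attack_config_for, attack_panel, combined_cohort, pedigree_founders
from haploleak.kinship import cohort_sk_matrix
from haploleak.linking import fit_sk_likelihoods


@pytest.fixture(scope="session")
def panel():
    """The 200 x 20k attack panel at its frozen study conditions."""
    return attack_panel(seed=1)


@pytest.fixture(scope="session")
def attack_cfg(panel):
    return attack_config_for(panel)


@pytest.fixture(scope="session")
def engine(panel):
    return ImputationEngine(panel)


@pytest.fixture(scope="session")
def discrete_engine(panel):
    return ImputationEngine(panel, EngineParams(output_mode="discrete"))


@pytest.fixture(scope="session")
def classifier(engine, attack_cfg):
    """The sieve random forest, trained once on the attack panel."""
    return train_match_classifier(engine, attack_cfg, n_per_class=100, seed=5)


@pytest.fixture(scope="session")
def founders():
    """Multi-chromosome founder haplotypes for pedigree cohorts."""
    return pedigree_founders(seed=1, n_hap=800, n_chrom=4, n_var=1500)


@pytest.fixture(scope="session")
def sk_likelihoods(founders):
    """Chunk-level SK likelihoods fit on a held-out labelled cohort."""
    cohort = combined_cohort(founders, [1, 2, 3, 4, 5, "unrelated"], 12, seed=101)
    sk = cohort_sk_matrix(cohort)
    by_deg = {"1": [], "2": [], "3+": [], "unrelated": []}
    for p, d in enumerate(cohort.degrees):
        rows = (sk.hap_id == 2 * p) | (sk.hap_id == 2 * p + 1)
        key = "unrelated" if d == "unrelated" else ("3+" if int(d) >= 3 else str(d))
        by_deg[key].append(sk.values[rows, p])
    by_deg = {k: np.concatenate(v) for k, v in by_deg.items()}
    return fit_sk_likelihoods(by_deg, mode="chunk")
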