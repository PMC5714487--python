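import warnings

import numpy as np
import pandas as pd
import pytest

import beanqtl as bq
from beanqtl import simdata

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_map():
    return simdata.simulate_map(3, 15, 60.0, 11)


@pytest.fixture(scope="session")
def small_geno(small_map):
    return simdata.simulate_ril_genotypes(small_map, 120, 12)


@pytest.fixture(scope="session")
def paper_map():
    """11-chromosome map at roughly one marker per 1.85 cM."""
    return simdata.simulate_map(11, 47, 85.0, 1)


@pytest.fixture(scope="session")
def paper_geno(paper_map):
    return simdata.simulate_ril_genotypes(paper_map, 188, 2)


@pytest.fixture(scope="session")
def paper_truth(paper_map):
    truth, qtl_table = simdata.default_truth_model(paper_map, residual_sd=2.5)
    return truth, qtl_table


@pytest.fixture(scope="session")
def paper_weather():
    return {
        p.site: simdata.simulate_site_weather(p, 500 + i)
        for i, p in enumerate(simdata.default_site_profiles())
    }


@pytest.fixture(scope="session")
def paper_records(paper_geno, paper_truth, paper_weather):
    """Line x site TF records for a 188-line, 5-site trial, residual 2.5 d."""
    truth, _ = paper_truth
    records, rec = simdata.simulate_line_site_tf(truth, paper_geno, paper_weather, 7)
    return records[records["converged"]].reset_index(drop=True), rec


@pytest.fixture(scope="session")
def small_trial():
    """Compact plot-level trial (60 lines, 2 sites, 2 reps) for the spatial
    and multi-site models."""
    lm = simdata.simulate_map(3, 12, 60.0, 21)
    geno = simdata.simulate_ril_genotypes(lm, 60, 22)
    markers = lm.markers
    truth = simdata.TruthModel(
        intercept=44.18,
        centering={"DAY": 12.37, "Tmin": 16.128},
        ec_main={"DAY": 4.03, "Tmin": -0.61},
        qtl_main={markers[3]: -2.0, markers[15]: 1.2},
        qtl_ec={(markers[3], "Tmin"): -0.25},
        residual_sd=1.0,
        line_sd=1.5,
    )
    sites = simdata.default_site_profiles()[:2]
    plots, rec = simdata.simulate_trial(lm, geno, truth, sites, n_reps=2, seed=23)
    return lm, geno, truth, plots, rec
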