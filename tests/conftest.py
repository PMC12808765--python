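import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from grsig import simulate


@pytest.fixture(scope="session")
def small_counts():
    """A reduced Dex time-course (800 genes, 20 per planted class)."""
    cfg = simulate.SimCountConfig(
        n_genes=800,
        class_sizes={c: 20 for c in simulate.PLANTED_CLASSES},
        seed=11,
    )
    counts, samples, truth = simulate.simulate_counts(cfg)
    return cfg, counts, samples, truth


@pytest.fixture(scope="session")
def default_counts():
    """The full default design (5,000 genes, 60 per class, effect 3)."""
    cfg = simulate.SimCountConfig(seed=1)
    return (cfg,) + simulate.simulate_counts(cfg)


@pytest.fixture(scope="session")
def cohort_default():
    cfg = simulate.SimCohortConfig(seed=3)
    cohort, truth = simulate.simulate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def toy_genome():
    cfg = simulate.SimPeakConfig(seed=2)
    genes, peaks, truth = simulate.simulate_genome_and_peaks(cfg)
    return cfg, genes, peaks, truth


@pytest.fixture(scope="session")
def tmt_default():
    cfg = simulate.SimTmtConfig(seed=4)
    psms, channels, truth = simulate.simulate_reporter(cfg)
    return cfg, psms, channels, truth


def dex_vs_vehicle_groups(samples: pd.DataFrame, model: str, timepoint: str):
    sel = (samples["model"] == model) & (samples["timepoint"] == timepoint)
    ga = list(samples.loc[sel & (samples["treatment"] == "dex"), "sample_id"])
    gb = list(samples.loc[sel & (samples["treatment"] == "vehicle"), "sample_id"])
    return ga, gb
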