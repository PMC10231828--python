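import numpy as np
import pandas as pd
import pytest

from otoscape import assignment as asg
from otoscape import baseline as bl
from otoscape import ensemble as ens
from otoscape import isoscape as iso
from otoscape import synthetic as syn


@pytest.fixture(scope="session")
def scfg():
    return syn.SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def baseline_ds(scfg):
    """Balanced, standardized synthetic baseline."""
    raw = syn.gen_baseline(scfg)
    eligible = bl.filter_baseline(raw)
    return bl.standardize(bl.oversample_balance(eligible, seed=11))


@pytest.fixture(scope="session")
def masks(scfg):
    return syn.gen_masks(scfg)


@pytest.fixture(scope="session")
def mixing_lines(scfg, masks):
    return syn.default_mixing_lines(scfg, masks)


@pytest.fixture(scope="session")
def ocean(scfg, masks):
    return syn.gen_ocean(scfg, 2013, masks)


@pytest.fixture(scope="session")
def southern_iso(scfg, masks, mixing_lines, ocean):
    T, S = ocean
    return iso.build_isoscape(T, S, 2013, "southern", mixing_lines,
                              iso.FractionationModel(),
                              masks["southern"], masks["shelf"])


@pytest.fixture(scope="session")
def variance_model():
    return asg.VarianceModel()


@pytest.fixture(scope="session")
def small_ensemble(baseline_ds):
    """Fast three-member ensemble shared across tests."""
    model, reports = ens.fit_ensemble(
        baseline_ds, names=["LDA", "kNN", "RF", "NULL"], top_k=3, seed=5)
    return model, reports


def tiny_records(n_per=10, year_classes=(2000, 2001), seed=0,
                 offset=(1.0, 1.0)):
    """Hand-rolled two-contingent records for arithmetic-level tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for yc in year_classes:
        for cont, sign in (("northern", -1.0), ("southern", 1.0)):
            for k in range(n_per):
                rows.append({
                    "fish_id": f"{yc}{cont[0]}{k}",
                    "d18o": sign * offset[0] / 2 + rng.normal(0, 0.3),
                    "d13c": -sign * offset[1] / 2 + rng.normal(0, 0.3),
                    "year_class": yc, "age": 1, "contingent": cont,
                })
    return pd.DataFrame(rows)
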