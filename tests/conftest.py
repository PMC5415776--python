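import numpy as np
import pandas as pd
import pytest

from methpanel import synthetic_data as sd
from methpanel.data_model import BetaMatrix, SampleSheet


@pytest.fixture(scope="session")
def cohort():
    """Small paired cohort with 10 planted markers, a SNP probe and a
    trait tracking probe cg00000000."""
    cfg = sd.SimConfig(
        n_individuals=15,
        n_probes=400,
        n_discriminating=10,
        seed=11,
        snp_probe=sd.SnpProbeSpec(allele_freq=0.3),
        trait_specs=(sd.TraitSpec("hdl", "cg00000000", 0.9),),
    )
    return sd.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def marker_cohort(cohort):
    """Cohort with one probe overwritten as a perfectly separating marker."""
    disc = cohort.truth.loc[cohort.truth["discriminating"], "probe_id"]
    marker = disc.iloc[0]
    beta = sd.inject_perfect_marker(
        cohort.beta, cohort.sheet, marker, low=0.34, high=0.97, rng=7
    )
    return beta, cohort.sheet, marker


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_sheet(n_individuals, timepoints=("before", "after"), drop=()):
    """Build a sample sheet; ``drop`` removes (individual_idx, tissue,
    timepoint) entries to create incomplete pairs."""
    rows = []
    for i in range(n_individuals):
        ind = f"I{i:03d}"
        for tissue in ("AB", "OM"):
            for tp in timepoints:
                if (i, tissue, tp) in drop:
                    continue
                rows.append((f"{ind}_{tissue}_{tp}", ind, tissue, tp))
    return SampleSheet(
        pd.DataFrame(rows, columns=["sample_id", "individual_id", "tissue", "timepoint"])
    )


def make_matrix(values, probe_ids=None, sample_ids=None):
    arr = np.asarray(values, dtype=float)
    probe_ids = probe_ids or [f"cg{i:08d}" for i in range(arr.shape[0])]
    sample_ids = sample_ids or [f"S{j}" for j in range(arr.shape[1])]
    return BetaMatrix(pd.DataFrame(arr, index=probe_ids, columns=sample_ids))
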