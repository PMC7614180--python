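import numpy as np
import pandas as pd
import pytest

import stockid as s
from stockid.matrix import LOCUS_COLUMNS, GenotypeMatrix


def make_matrix(dosages, quals=None, chroms=None, positions=None, sample_ids=None):
    """Handmade GenotypeMatrix from a 2-D list (np.nan = missing)."""
    d = np.asarray(dosages, dtype=float)
    n, L = d.shape
    loci = pd.DataFrame(
        {
            "locus_id": [f"L{j}" for j in range(L)],
            "chrom": chroms if chroms is not None else ["chr1"] * L,
            "pos": positions if positions is not None else list(range(1, L + 1)),
            "ref": "A",
            "alt": "G",
            "qual": quals if quals is not None else [50.0] * L,
        }
    )[LOCUS_COLUMNS]
    ids = sample_ids if sample_ids is not None else [f"S{i}" for i in range(n)]
    return GenotypeMatrix(ids, loci, d)


def random_matrix(rng, n_samples, n_loci, missing=0.0):
    p = rng.uniform(0.1, 0.9, size=n_loci)
    d = rng.binomial(2, p, size=(n_samples, n_loci)).astype(float)
    if missing:
        d[rng.random(d.shape) < missing] = np.nan
    return make_matrix(d)


def two_pop_sim(F, n1, n2, n_loci, seed, maf_range=(0.1, 0.5)):
    cfg = s.SimulationConfig(
        pop_names=["A", "B"],
        sample_sizes=[n1, n2],
        terminal_drift={"A": F, "B": F},
        n_background_loci=n_loci,
        maf_range=maf_range,
        seed=seed,
    )
    gm, truth = s.simulate_baseline(cfg)
    pop_map = dict(zip(truth.samples["sample_id"], truth.samples["true_population"]))
    return gm, truth, pop_map


@pytest.fixture(scope="session")
def herring_sim():
    """Four-population baseline matched to the published panel F_ST pattern."""
    cfg = s.herring_panel_config(seed=1)
    gm, truth = s.simulate_baseline(cfg)
    pop_map = dict(zip(truth.samples["sample_id"], truth.samples["true_population"]))
    return gm, truth, pop_map


@pytest.fixture(scope="session")
def herring_replicate_runs(herring_sim):
    """Replicate admixture-EM likelihood table on the matched 4-pop baseline."""
    gm, _, _ = herring_sim
    return s.replicate_likelihood_table(gm, k_range=(1, 8), n_runs=10, base_seed=7)
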