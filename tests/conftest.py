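import numpy as np
import pandas as pd
import pytest

import hostpref as hp


def make_assoc(y, T, level="97", otus=None, hosts=None):
    """AssociationMatrix from plain arrays."""
    y = np.asarray(y, dtype=int)
    otus = otus or [f"f{i}" for i in range(y.shape[0])]
    hosts = hosts or [f"p{j}" for j in range(y.shape[1])]
    return hp.AssociationMatrix(
        y=pd.DataFrame(y, index=otus, columns=hosts),
        T=pd.Series(np.asarray(T, dtype=int), index=hosts),
        level=level,
    )


def make_distance(values, labels=None, kind="generic"):
    v = np.asarray(values, dtype=float)
    labels = labels or [f"l{i}" for i in range(v.shape[0])]
    return hp.DistanceMatrix(pd.DataFrame(v, index=labels, columns=labels), kind=kind)


def random_distance(n, rng, labels=None, kind="generic"):
    v = rng.uniform(size=(n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return make_distance(v, labels=labels, kind=kind)


@pytest.fixture(scope="session")
def small_pipeline():
    """A small but non-degenerate synthetic dataset run through rarefaction."""
    cfg = hp.SimulationConfig(
        n_samples=200,
        n_plant_otus=(12, 8, 4, 2),
        n_fungal_otus=60,
        depth_distribution=(np.log(300.0), 0.7, 1),
        rng_seed=11,
    )
    hosts, coords = hp.generate_hosts(cfg)
    counts, truth = hp.generate_counts(cfg, hosts, coords)
    rarefied, dropped = hp.rarefy(counts, depth=100, seed=11)
    occ = hp.to_presence_absence(rarefied)
    return {
        "config": cfg,
        "hosts": hosts,
        "coords": coords,
        "counts": counts,
        "truth": truth,
        "rarefied": rarefied,
        "dropped": dropped,
        "occ": occ,
    }
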