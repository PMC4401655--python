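"""Replication scenarios: canned synthetic study designs with known truth.

Each function builds one self-contained experiment used to validate the
estimators — a calibration dataset with no preference, a recovery dataset
with host-exclusive fungi, a scale-detection dataset where preference
lives at a coarse host-clustering level, and a dipterocarp-contrast
dataset where only ECM fungi track host genetic distance.  They are used
by the test-suite and the reproduction script, and are convenient starting
points for power analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import community as comm
from .containers import AssociationMatrix, level_column
from .matrices import build_association, rarefy, to_presence_absence
from .preference import HostPreferenceModel
from .simulate import SimulationConfig, generate_counts, generate_host_distances, generate_hosts, preference_for_level


def null_association(
    n_otus: int = 200, n_hosts: int = 4, n_i: int = 20, t_per_host: int = 50,
    seed: int = 0,
) -> AssociationMatrix:
    """Preference-free association counts: y_i ~ Multinomial(N_i, T/sum T).

    Balanced hosts by default; every credible interval that excludes zero
    on this data is a false positive.
    """
    rng = np.random.default_rng([seed, 31])
    T = pd.Series([t_per_host] * n_hosts, index=[f"h{j}" for j in range(n_hosts)])
    p = T.to_numpy() / T.sum()
    y = rng.multinomial(n_i, p, size=n_otus)
    return AssociationMatrix(
        y=pd.DataFrame(y, index=[f"null{i}" for i in range(n_otus)], columns=T.index),
        T=T, level="97",
    )


def exclusive_association(
    n_reps: int = 100, n_hosts: int = 4, n_i: int = 20, t_per_host: int = 50,
    seed: int = 0,
):
    """Host-exclusive fungi: each replicate OTU has all N_i occurrences on one
    (randomly chosen) host.  Returns (AssociationMatrix, target host index)."""
    rng = np.random.default_rng([seed, 37])
    T = pd.Series([t_per_host] * n_hosts, index=[f"h{j}" for j in range(n_hosts)])
    targets = rng.integers(0, n_hosts, size=n_reps)
    y = np.zeros((n_reps, n_hosts), dtype=int)
    y[np.arange(n_reps), targets] = n_i
    assoc = AssociationMatrix(
        y=pd.DataFrame(y, index=[f"excl{i}" for i in range(n_reps)], columns=T.index),
        T=T, level="97",
    )
    return assoc, targets


def level_preference_replicate(
    seed: int,
    preference_level: str = "98",
    n_samples: int = 240,
    n_plant_otus: tuple = (24, 12, 6, 3),
    n_fungal_otus: int = 40,
    n_preferring: int = 10,
    strength: float = 8.0,
    draws: int = 1000,
):
    """One scale-detection replicate: some fungi prefer a whole cluster at
    `preference_level` rather than a single finest-level host.

    Returns mean D-hat-max of the preferring OTUs at the finest level and at
    the preference level: preference at a coarse taxonomic grain should be
    more visible when hosts are clustered at that grain.
    """
    cfg = SimulationConfig(
        n_samples=n_samples, n_plant_otus=n_plant_otus, n_fungal_otus=n_fungal_otus,
        depth_distribution=(np.log(300.0), 0.7, 1), rng_seed=seed,
    )
    hosts, coords = generate_hosts(cfg)
    cfg.preference_matrix = preference_for_level(
        cfg, hosts, otu_rows=range(n_preferring), level=preference_level,
        strength=strength,
    )
    counts, _ = generate_counts(cfg, hosts, coords)
    rarefied, _ = rarefy(counts, depth=100, seed=seed)
    occ = to_presence_absence(rarefied)
    focal = [f"F{k:04d}" for k in range(1, n_preferring + 1)]
    out = {}
    for lv in ("99.8", preference_level):
        res = HostPreferenceModel.from_occurrence(occ, hosts, lv, min_occurrence=5).fit(
            draws=draws, seed=seed
        )
        dm = res.dmax()["d_max"]
        out[lv] = float(dm.reindex([f for f in focal if f in dm.index]).mean())
    return out["99.8"], out[preference_level]


def ecm_dipterocarp_replicate(
    seed: int,
    n_samples: int = 300,
    n_plant_otus: tuple = (30, 15, 8, 4),
    n_fungal_otus: int = 300,
    n_ecm: int = 60,
    strength: float = 20.0,
    n_null: int = 199,
    n_perm: int = 99,
):
    """One dipterocarp-contrast replicate.

    ECM fungi (spread over the abundance ranks) each prefer one dipterocarp
    host cluster at the 98% level; all other fungi are host-indifferent, so
    only the ECM community within dipterocarps should track host genetic
    distance.  Returns (Mantel r in the dipterocarp dataset, Mantel r in the
    non-dipterocarp dataset) for the ECM OTU subset.
    """
    cfg = SimulationConfig(
        n_samples=n_samples, n_plant_otus=n_plant_otus, n_fungal_otus=n_fungal_otus,
        depth_distribution=(np.log(300.0), 0.7, 1), fungal_abundance_decay=0.99,
        dipterocarp_fraction=0.5, rng_seed=seed,
    )
    hosts, coords = generate_hosts(cfg)
    rng = np.random.default_rng([seed, 99])
    rep = hosts.table.drop_duplicates(subset=level_column("99.8")).set_index(
        level_column("99.8")
    )
    dip_clusters = sorted(rep.loc[rep["is_dipterocarp"], level_column("98")].unique())
    ecm_rows = list(range(0, n_fungal_otus, n_fungal_otus // n_ecm))[:n_ecm]
    cfg.preference_matrix = preference_for_level(
        cfg, hosts, ecm_rows, "98",
        target_clusters=rng.choice(dip_clusters, size=len(ecm_rows)),
        strength=strength,
    )
    counts, _ = generate_counts(cfg, hosts, coords)
    rarefied, _ = rarefy(counts, depth=100, seed=seed)
    occ = to_presence_absence(rarefied)
    dip, nondip = comm.split_by_host(occ, hosts)
    gdist = generate_host_distances(hosts, cfg)
    ecm_ids = [f"F{k + 1:04d}" for k in ecm_rows]

    rs = {}
    for name, subset in (("dip", dip), ("nondip", nondip)):
        sub = subset.subset_otus(ecm_ids)
        units = comm.group_by_plant_otu(sub, hosts, "99.8")
        units = units.loc[units.sum(axis=1) > 0]
        cd = comm.raup_crick(units, n_null=n_null, seed=seed)
        labels = [l for l in cd.labels if l in gdist.labels]
        rs[name] = comm.mantel(
            cd.reindex(labels), gdist.reindex(labels), n_perm=n_perm, seed=seed
        ).r
    return rs["dip"], rs["nondip"]
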