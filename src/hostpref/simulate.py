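"""Synthetic root-sample communities with known host-preference structure.

The generator emulates the processed data of a transect survey of
root-associated fungi: one root sample per metre along a linear transect,
host plants clustered into nested OTU partitions at four sequence-similarity
cutoffs, and a long-tailed fungal OTU table whose per-sample sequencing
depth varies around the 100-read rarefaction threshold.  Because every
fungal OTU's true colonization weights per host are recorded, downstream
estimates (D-hat, Mantel r, ...) can be checked against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import LEVELS, CountMatrix, DistanceMatrix, HostAssignment, level_column
from .errors import ValidationError

#: distance assigned to a pair of finest-level plant OTUs by the coarsest
#: level at which they share a cluster (keys: level or "none" = never merge).
#: Values are on the 1 - similarity scale of the clustering cutoffs.
TIER_DISTANCES: dict[str, float] = {"99.8": 0.0, "99": 0.01, "98": 0.02, "97": 0.03, "none": 0.05}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    Defaults match the study design the package targets: 600 samples at
    1-m intervals, ~150 finest-level host OTUs in nested partitions, ~1700
    fungal OTUs with geometric-series base abundance, and lognormal read
    depths placing roughly a fifth of samples below the 100-read
    rarefaction threshold.
    """

    n_samples: int = 600
    #: plant OTU counts per level, finest (99.8%) to coarsest (97%)
    n_plant_otus: tuple[int, int, int, int] = (150, 100, 60, 30)
    n_fungal_otus: int = 1700
    #: lognormal depth law: (mean of log reads, sd of log reads, floor)
    depth_distribution: tuple[float, float, int] = (np.log(250.0), 1.0, 1)
    #: per fungal OTU, relative colonization weight per finest-level plant
    #: OTU; None = all-equal rows (the null of no host preference)
    preference_matrix: np.ndarray | None = None
    #: exponential range (metres) of per-OTU spatial clustering; 0 = none
    spatial_aggregation: float = 0.0
    #: amplitude of the spatial odds multiplier when aggregation is on
    spatial_amplitude: float = 3.0
    #: geometric decay of host OTU sample frequencies; 1.0 = uniform hosts
    host_abundance_decay: float = 0.98
    #: geometric decay of fungal base abundances (long-tailed ranks)
    fungal_abundance_decay: float = 0.995
    #: fraction of coarsest-level host clusters flagged dipterocarp
    dipterocarp_fraction: float = 0.4
    #: within-tier multiplicative jitter of host genetic distances
    distance_jitter: float = 0.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0 or self.n_fungal_otus <= 0:
            raise ValidationError("n_samples and n_fungal_otus must be positive")
        if len(self.n_plant_otus) != len(LEVELS):
            raise ValidationError(f"n_plant_otus must give one count per level {LEVELS}")
        if any(a < b for a, b in zip(self.n_plant_otus, self.n_plant_otus[1:])):
            raise ValidationError("n_plant_otus must be non-increasing fine -> coarse")
        if self.n_plant_otus[0] > self.n_samples:
            raise ValidationError(
                f"cannot realize {self.n_plant_otus[0]} plant OTUs with "
                f"{self.n_samples} samples"
            )
        if self.preference_matrix is not None:
            pm = np.asarray(self.preference_matrix, dtype=float)
            if pm.shape != (self.n_fungal_otus, self.n_plant_otus[0]):
                raise ValidationError(
                    "preference_matrix must be n_fungal_otus x finest n_plant_otus"
                )
            if (pm < 0).any() or (pm.sum(axis=1) <= 0).any():
                raise ValidationError("preference rows must be non-negative, not all zero")

    def preferences(self) -> np.ndarray:
        if self.preference_matrix is None:
            return np.ones((self.n_fungal_otus, self.n_plant_otus[0]))
        return np.asarray(self.preference_matrix, dtype=float)


@dataclass
class GroundTruth:
    """Everything needed to score recovery of the simulated structure."""

    true_preference_matrix: np.ndarray  # fungal x finest plant OTUs
    host_labels: pd.Series  # sample -> finest plant OTU
    coordinates: pd.Series  # sample -> metres along transect
    #: per fungal OTU, expected read-allocation probability per finest host
    expected_marginals: pd.DataFrame
    depths: pd.Series = field(default=None)

    def __post_init__(self):
        if not self.host_labels.index.equals(self.coordinates.index):
            raise ValidationError("host labels and coordinates cover different samples")
        coords = self.coordinates.to_numpy(dtype=float)
        if not (np.diff(coords) > 0).all():
            raise ValidationError("coordinates must be strictly increasing")


def _plant_otu_ids(n: int) -> list[str]:
    return [f"P{k:03d}" for k in range(1, n + 1)]


def _fungal_otu_ids(n: int) -> list[str]:
    return [f"F{k:04d}" for k in range(1, n + 1)]


def _nested_partition(counts: tuple[int, ...]) -> list[np.ndarray]:
    """Map finest-level OTU index -> cluster index at each coarser level.

    Each coarser level merges contiguous blocks of the previous level's
    clusters, so the partitions form a chain-nested hierarchy (as
    sequence clustering at decreasing similarity cutoffs does).
    """
    fine = counts[0]
    maps = [np.arange(fine)]
    prev_map, prev_count = maps[0], fine
    for c in counts[1:]:
        block = np.minimum((np.arange(prev_count) * c) // prev_count, c - 1)
        prev_map = block[prev_map]
        maps.append(prev_map)
        prev_count = c
    return maps


def generate_hosts(config: SimulationConfig) -> tuple[HostAssignment, pd.Series]:
    """Draw a host plant OTU for every sampling position on the transect.

    Returns the host table (labels at all four levels, family and
    dipterocarp flags) and the sample coordinates in metres.
    """
    config.validate()
    rng = np.random.default_rng([config.rng_seed, 1])
    n_fine = config.n_plant_otus[0]
    fine_ids = _plant_otu_ids(n_fine)

    # geometric-series host frequencies (decay 1.0 -> uniform); shuffle the
    # rank order so dominance is not tied to the nesting layout
    ranks = config.host_abundance_decay ** np.arange(n_fine)
    order = rng.permutation(n_fine)
    freqs = ranks[order]
    freqs = freqs / freqs.sum()

    # guarantee every fine OTU occurs at least once, then fill multinomially
    labels_idx = np.concatenate(
        [np.arange(n_fine), rng.choice(n_fine, size=config.n_samples - n_fine, p=freqs)]
    )
    labels_idx = labels_idx[rng.permutation(config.n_samples)]

    maps = _nested_partition(config.n_plant_otus)
    sample_ids = [f"S{k:04d}" for k in range(1, config.n_samples + 1)]
    table = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    for lv, mapping, count in zip(LEVELS, maps, config.n_plant_otus):
        ids = [f"P{lv}_{c:03d}" for c in range(1, count + 1)] if lv != LEVELS[0] else fine_ids
        table[level_column(lv)] = [ids[mapping[i]] for i in labels_idx]

    # family / dipterocarp flags live on the coarsest clusters so that all
    # members of a 97% cluster share a family
    n_coarse = config.n_plant_otus[-1]
    n_dip = max(1, int(round(config.dipterocarp_fraction * n_coarse)))
    dip_clusters = set(rng.choice(n_coarse, size=n_dip, replace=False).tolist())
    other_families = ["Burseraceae", "Euphorbiaceae", "Myristicaceae", "Clusiaceae", "Myrtaceae"]
    family_of_cluster = {
        c: ("Dipterocarpaceae" if c in dip_clusters else other_families[c % len(other_families)])
        for c in range(n_coarse)
    }
    coarse_idx = maps[-1][labels_idx]
    table["family"] = [family_of_cluster[c] for c in coarse_idx]
    table["is_dipterocarp"] = table["family"] == "Dipterocarpaceae"

    coordinates = pd.Series(
        np.arange(config.n_samples, dtype=float), index=table.index, name="position_m"
    )
    return HostAssignment(table), coordinates


def generate_counts(
    config: SimulationConfig, hosts: HostAssignment, coordinates: pd.Series | None = None
) -> tuple[CountMatrix, GroundTruth]:
    """Simulate the sample x fungal OTU read-count table.

    Per sample, a depth is drawn from the lognormal depth law and reads are
    allocated multinomially with probability proportional to
    (base abundance x preference weight for the sample's host x spatial
    kernel at the sample's position).
    """
    config.validate()
    rng = np.random.default_rng([config.rng_seed, 2])
    n_s, n_f = config.n_samples, config.n_fungal_otus
    if len(hosts.sample_ids) != n_s:
        raise ValidationError("host table does not match config.n_samples")
    if coordinates is None:
        coordinates = pd.Series(np.arange(n_s, dtype=float), index=hosts.sample_ids)

    fine_ids = hosts.plant_otus(LEVELS[0])
    fine_index = {lab: k for k, lab in enumerate(_plant_otu_ids(config.n_plant_otus[0]))}
    host_idx = hosts.labels(LEVELS[0]).map(fine_index).to_numpy()

    base = config.fungal_abundance_decay ** np.arange(n_f)  # long-tailed ranks
    pref = config.preferences()

    # spatial kernel: odds multiplier 1 + A * exp(-|x - centre| / range)
    positions = coordinates.to_numpy(dtype=float)
    if config.spatial_aggregation > 0:
        centres = rng.uniform(positions.min(), positions.max(), size=n_f)
        kernel = 1.0 + config.spatial_amplitude * np.exp(
            -np.abs(positions[None, :] - centres[:, None]) / config.spatial_aggregation
        )  # fungal x sample
    else:
        kernel = np.ones((1, n_s))

    mu, sigma, floor = config.depth_distribution
    depths = np.maximum(np.round(rng.lognormal(mu, sigma, size=n_s)).astype(int), int(floor))

    counts = np.zeros((n_s, n_f), dtype=np.int64)
    for s in range(n_s):
        w = base * pref[:, host_idx[s]] * (kernel[:, s] if kernel.shape[0] > 1 else kernel[0, s])
        total = w.sum()
        if total <= 0:
            raise ValidationError(
                f"zero total colonization weight for sample {hosts.sample_ids[s]!r}"
            )
        counts[s] = rng.multinomial(depths[s], w / total)

    cm = CountMatrix(
        pd.DataFrame(counts, index=hosts.sample_ids, columns=_fungal_otu_ids(n_f)),
        state="raw",
    )
    # expected read-allocation probability per host, spatial kernel marginalised out
    exp_w = base[:, None] * pref  # fungal x fine hosts
    exp_p = exp_w / exp_w.sum(axis=0, keepdims=True)
    marginals = pd.DataFrame(
        exp_p, index=cm.otu_ids, columns=_plant_otu_ids(config.n_plant_otus[0])
    )
    truth = GroundTruth(
        true_preference_matrix=pref,
        host_labels=hosts.labels(LEVELS[0]).copy(),
        coordinates=pd.Series(positions, index=hosts.sample_ids),
        expected_marginals=marginals,
        depths=pd.Series(depths, index=hosts.sample_ids),
    )
    del fine_ids
    return cm, truth


def generate_host_distances(
    hosts: HostAssignment, config: SimulationConfig
) -> DistanceMatrix:
    """Host genetic distances consistent with the nested OTU partitions.

    Two finest-level plant OTUs are assigned the tier distance of the
    coarsest-grained level at which they first share a cluster; OTUs never
    sharing a cluster get the beyond-97% tier.  With zero jitter the result
    is an ultrametric by construction; jitter perturbs distances
    multiplicatively within a tier (kept small enough to preserve the
    tier ordering).
    """
    rng = np.random.default_rng([config.rng_seed, 3])
    fine = hosts.table[level_column(LEVELS[0])]
    # one representative row per finest OTU
    rep = hosts.table.drop_duplicates(subset=level_column(LEVELS[0])).set_index(
        level_column(LEVELS[0])
    )
    labels = sorted(rep.index)
    n = len(labels)
    d = np.zeros((n, n))
    tier_of_pair = np.full((n, n), TIER_DISTANCES["none"])
    for lv in reversed(LEVELS[1:]):  # coarsest first so finer levels overwrite
        lab = rep.loc[labels, level_column(lv)].to_numpy()
        same = lab[:, None] == lab[None, :]
        tier_of_pair[same] = TIER_DISTANCES[lv]
    np.fill_diagonal(tier_of_pair, 0.0)
    d = tier_of_pair
    if config.distance_jitter > 0:
        jit = np.clip(config.distance_jitter, 0.0, 0.45)
        factors = rng.uniform(1 - jit, 1 + jit, size=(n, n))
        factors = np.triu(factors, 1)
        factors = factors + factors.T
        d = d * np.where(factors > 0, factors, 1.0)
        np.fill_diagonal(d, 0.0)
    idx = pd.Index(labels, name="plant_otu")
    return DistanceMatrix(pd.DataFrame(d, index=idx, columns=idx), kind="genetic")


def preference_for_level(
    config: SimulationConfig,
    hosts: HostAssignment,
    otu_rows,
    level,
    target_clusters=None,
    strength: float = 10.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Build a preference matrix encoding preference at a chosen cutoff level.

    Each listed fungal OTU row gets weight `strength` for every finest-level
    host inside one cluster at `level` (a random cluster per OTU unless
    `target_clusters` pins them) and weight 1 elsewhere.  Used to simulate
    e.g. genus-level rather than species-level preference.
    """
    if rng is None:
        rng = np.random.default_rng([config.rng_seed, 4])
    pref = np.ones((config.n_fungal_otus, config.n_plant_otus[0]))
    rep = hosts.table.drop_duplicates(subset=level_column(LEVELS[0])).set_index(
        level_column(LEVELS[0])
    )
    fine_ids = _plant_otu_ids(config.n_plant_otus[0])
    level_labels = rep.reindex(fine_ids)[level_column(level)]
    clusters = sorted(level_labels.dropna().unique())
    otu_rows = list(otu_rows)
    if target_clusters is None:
        target_clusters = rng.choice(clusters, size=len(otu_rows))
    for row, cluster in zip(otu_rows, np.asarray(target_clusters)):
        member = (level_labels == cluster).to_numpy()
        pref[row, member] = strength
    return pref


def write_dataset(path_prefix, counts: CountMatrix, hosts: HostAssignment,
                  coordinates: pd.Series, distances: DistanceMatrix,
                  truth: GroundTruth) -> dict:
    """Write the full synthetic dataset as the TSV formats the readers consume."""
    from . import io as hio

    paths = {
        "counts": f"{path_prefix}_counts.tsv",
        "hosts": f"{path_prefix}_hosts.tsv",
        "coords": f"{path_prefix}_coords.tsv",
        "distances": f"{path_prefix}_gdist.tsv",
        "truth": f"{path_prefix}_truth.tsv",
    }
    hio.write_count_matrix(counts, paths["counts"])
    hio.write_hosts(hosts, paths["hosts"])
    coordinates.rename("position_m").to_frame().to_csv(paths["coords"], sep="\t")
    hio.write_distance(distances, paths["distances"])
    truth.expected_marginals.to_csv(paths["truth"], sep="\t")
    return paths
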