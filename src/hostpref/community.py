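"""Null-model beta-diversity and distance-matrix machinery: Raup-Crick
dissimilarity, Mantel and partial Mantel permutation tests, Moran's I
spatial autocorrelation, and the dipterocarp / non-dipterocarp split."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import DistanceMatrix, HostAssignment, OccurrenceMatrix, level_column
from .errors import ValidationError

__all__ = [
    "MantelResult",
    "group_by_plant_otu",
    "raup_crick",
    "mantel",
    "partial_mantel",
    "morans_i",
    "split_by_host",
    "unit_geographic_distances",
]


@dataclass
class MantelResult:
    """Outcome of a (partial) Mantel permutation test."""

    r: float
    p: float
    n_perm: int
    alternative: str = "greater"
    control: str | None = None


def split_by_host(occ: OccurrenceMatrix, hosts: HostAssignment):
    """Split an occurrence matrix into dipterocarp and non-dipterocarp parts."""
    shared = occ.sample_ids.intersection(hosts.sample_ids)
    if len(shared) < len(occ.sample_ids):
        missing = occ.sample_ids.difference(hosts.sample_ids)[0]
        raise ValidationError(f"sample {missing!r} has no host assignment")
    is_dip = hosts.table.loc[occ.sample_ids, "is_dipterocarp"].astype(bool).to_numpy()
    if is_dip.all() or (~is_dip).all():
        raise ValidationError("one host group is empty; cannot split")
    return (
        OccurrenceMatrix(occ.data.loc[is_dip].copy()),
        OccurrenceMatrix(occ.data.loc[~is_dip].copy()),
    )


def group_by_plant_otu(occ: OccurrenceMatrix, hosts: HostAssignment, level) -> pd.DataFrame:
    """Pool sample occurrences into one binary row per plant OTU at `level`.

    A fungal OTU is present in a unit if it occurs in any of the unit's
    samples.  Units (plant OTUs) with no fungal occurrences are kept; the
    Raup-Crick null requires every unit to retain >= 1 OTU, checked there.
    """
    labels = hosts.table.loc[occ.sample_ids, level_column(level)]
    pooled = (occ.data.groupby(labels.to_numpy()).sum() > 0).astype(np.int8)
    return pooled.sort_index()


def raup_crick(
    units: pd.DataFrame,
    n_null: int = 999,
    seed: int = 0,
    frequencies: np.ndarray | None = None,
) -> DistanceMatrix:
    """Raup-Crick null-model dissimilarity between community units.

    For each pair of units, `n_null` pairs of null communities are drawn:
    each null community keeps the unit's observed richness and samples
    OTUs without replacement with probability proportional to each OTU's
    occurrence frequency across all units (an explicit frequency vector
    over the columns may be supplied instead, e.g. a uniform pool).  The
    dissimilarity is

        [#{null shared > observed shared} + 0.5 * #{ties}] / n_null,

    so pairs sharing more OTUs than the null expects score below 0.5 and
    pairs sharing fewer score above 0.5.  Values lie in [0, 1].
    """
    if units.shape[0] < 2:
        raise ValidationError("Raup-Crick needs >= 2 community units")
    mat = units.to_numpy(dtype=bool)
    n_units, n_otus = mat.shape
    richness = mat.sum(axis=1)
    if (richness < 1).any():
        bad = units.index[int(np.argmin(richness))]
        raise ValidationError(f"unit {bad!r} contains no OTU")
    if frequencies is None:
        freq = mat.sum(axis=0).astype(float)
    else:
        freq = np.asarray(frequencies, dtype=float)
        if freq.shape != (n_otus,) or (freq < 0).any():
            raise ValidationError("frequencies must be a non-negative vector over the OTU pool")
    pool = int(np.count_nonzero(freq > 0))
    if (richness > pool).any():
        bad = units.index[int(np.argmax(richness > pool))]
        raise ValidationError(
            f"unit {bad!r} richness {richness.max()} exceeds the null pool of {pool} OTUs"
        )
    with np.errstate(divide="ignore"):
        log_freq = np.where(freq > 0, np.log(np.where(freq > 0, freq, 1.0)), -np.inf)

    rng = np.random.default_rng(seed)
    # weighted sampling without replacement via Gumbel top-k, one block per unit
    nulls = np.empty((n_units, n_null, n_otus), dtype=bool)
    for u in range(n_units):
        keys = log_freq[None, :] + rng.gumbel(size=(n_null, n_otus))
        top = np.argpartition(-keys, richness[u] - 1, axis=1)[:, : richness[u]]
        block = np.zeros((n_null, n_otus), dtype=bool)
        np.put_along_axis(block, top, True, axis=1)
        nulls[u] = block

    d = np.zeros((n_units, n_units))
    for a in range(n_units):
        for b in range(a + 1, n_units):
            obs = int(np.count_nonzero(mat[a] & mat[b]))
            null_shared = np.count_nonzero(nulls[a] & nulls[b], axis=1)
            score = (np.count_nonzero(null_shared > obs)
                     + 0.5 * np.count_nonzero(null_shared == obs)) / n_null
            d[a, b] = d[b, a] = score
    return DistanceMatrix(
        pd.DataFrame(d, index=units.index, columns=units.index), kind="community"
    )


def _condensed_entries(values: np.ndarray) -> np.ndarray:
    return values[np.tril_indices_from(values, k=-1)]


def _rank_rows(x: np.ndarray) -> np.ndarray:
    """Midrank each row of a 2-D array (vectorised rankdata)."""
    return sps.rankdata(x, axis=-1)


def _pearson_rows(rx: np.ndarray, ry: np.ndarray) -> np.ndarray:
    rx = rx - rx.mean(axis=-1, keepdims=True)
    ry = ry - ry.mean(axis=-1, keepdims=True)
    num = (rx * ry).sum(axis=-1)
    den = np.sqrt((rx**2).sum(axis=-1) * (ry**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def _check_mantel_inputs(*mats: DistanceMatrix):
    labels = mats[0].labels
    out = []
    for m in mats:
        m = m.reindex(labels)
        tri = m.condensed()
        if np.allclose(tri, tri[0]):
            raise ValidationError(
                f"distance matrix ({m.kind}) has a constant lower triangle; "
                "rank correlation is undefined"
            )
        out.append(m)
    if len(labels) < 4:
        raise ValidationError("Mantel tests need >= 4 labels")
    return out


def _permuted_triangles(values: np.ndarray, perms: np.ndarray) -> np.ndarray:
    iu, ju = np.tril_indices(values.shape[0], k=-1)
    return values[perms[:, iu], perms[:, ju]]


def _perm_pvalue(stat_obs: float, stat_perm: np.ndarray, alternative: str) -> float:
    n_perm = stat_perm.size
    if alternative == "greater":
        exceed = np.count_nonzero(stat_perm >= stat_obs - 1e-12)
    elif alternative == "two-sided":
        exceed = np.count_nonzero(np.abs(stat_perm) >= abs(stat_obs) - 1e-12)
    else:
        raise ValidationError(f"unknown alternative {alternative!r}")
    return (1 + exceed) / (1 + n_perm)


def _permutations(n: int, n_perm: int, rng) -> np.ndarray:
    return np.array([rng.permutation(n) for _ in range(n_perm)])


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 9999,
    seed: int = 0,
    alternative: str = "greater",
    exact: bool = False,
) -> MantelResult:
    """Mantel test: Spearman correlation of two distance matrices.

    r is the Spearman correlation of the lower-triangle entries;
    significance comes from `n_perm` simultaneous row/column label
    permutations of d2, with the add-one permutation p-value
    (1 + #{r_perm >= r_obs}) / (1 + n_perm) for the default one-sided
    (positive association) alternative.  With ``exact=True`` all n!
    relabelings are enumerated instead and p = #{r_perm >= r_obs} / n!
    (the identity is among the relabelings, so p >= 1/n!).
    """
    d1, d2 = _check_mantel_inputs(d1, d2)
    x = _condensed_entries(d1.data.to_numpy(dtype=float))
    v2 = d2.data.to_numpy(dtype=float)
    rx = sps.rankdata(x)
    r_obs = float(_pearson_rows(rx, sps.rankdata(_condensed_entries(v2))))

    n = len(d1.labels)
    if exact:
        from itertools import permutations as iperm
        from math import factorial

        if factorial(n) > 50_000:
            raise ValidationError("exact Mantel enumeration is limited to small n")
        perms = np.array(list(iperm(range(n))))
        ry = _rank_rows(_permuted_triangles(v2, perms))
        r_perm = _pearson_rows(rx[None, :], ry)
        if alternative == "greater":
            p = float(np.mean(r_perm >= r_obs - 1e-12))
        else:
            p = float(np.mean(np.abs(r_perm) >= abs(r_obs) - 1e-12))
        return MantelResult(r=r_obs, p=p, n_perm=len(perms), alternative=alternative)

    rng = np.random.default_rng(seed)
    perms = _permutations(n, n_perm, rng)
    ry = _rank_rows(_permuted_triangles(v2, perms))
    r_perm = _pearson_rows(rx[None, :], ry)
    return MantelResult(
        r=r_obs, p=_perm_pvalue(r_obs, r_perm, alternative),
        n_perm=n_perm, alternative=alternative,
    )


def _partial_r(r12, r13, r23) -> float:
    den = (1 - r13**2) * (1 - r23**2)
    return (r12 - r13 * r23) / np.sqrt(den)


def partial_mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    d_control: DistanceMatrix,
    n_perm: int = 9999,
    seed: int = 0,
    alternative: str = "greater",
) -> MantelResult:
    """Partial Mantel test of d1 vs d2 controlling for d_control.

    The statistic is the first-order partial Spearman correlation
    r12.3 = (r12 - r13 r23) / sqrt((1-r13^2)(1-r23^2)); significance by
    permuting d1's labels and recomputing the partial statistic.
    """
    d1, d2, d3 = _check_mantel_inputs(d1, d2, d_control)
    v1 = d1.data.to_numpy(dtype=float)
    r2 = sps.rankdata(_condensed_entries(d2.data.to_numpy(dtype=float)))
    r3 = sps.rankdata(_condensed_entries(d3.data.to_numpy(dtype=float)))
    r1 = sps.rankdata(_condensed_entries(v1))

    r12 = float(_pearson_rows(r1, r2))
    r13 = float(_pearson_rows(r1, r3))
    r23 = float(_pearson_rows(r2, r3))
    if min(1 - abs(r13), 1 - abs(r23)) < 1e-10:
        raise ValidationError("degenerate control: |r| = 1 with the control matrix")
    r_obs = _partial_r(r12, r13, r23)

    rng = np.random.default_rng(seed)
    perms = _permutations(len(d1.labels), n_perm, rng)
    r1p = _rank_rows(_permuted_triangles(v1, perms))
    r12p = _pearson_rows(r1p, r2[None, :])
    r13p = _pearson_rows(r1p, r3[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        r_perm = (r12p - r13p * r23) / np.sqrt((1 - r13p**2) * (1 - r23**2))
    return MantelResult(
        r=float(r_obs), p=_perm_pvalue(float(r_obs), r_perm, alternative),
        n_perm=n_perm, alternative=alternative, control=d_control.kind,
    )


def morans_i(values, coordinates, weights: np.ndarray | None = None) -> dict:
    """Moran's I spatial autocorrelation with inverse-distance weights.

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 with centred values z,
    w_ij = 1 / |x_i - x_j| (w_ii = 0) unless a weight matrix is supplied.
    E[I] = -1/(n-1); the two-sided p uses the normal approximation with
    the randomization variance.
    """
    z = np.asarray(values, dtype=float)
    x = np.asarray(coordinates, dtype=float)
    n = z.size
    if n < 4:
        raise ValidationError("Moran's I needs >= 4 samples")
    if np.allclose(z, z[0]):
        raise ValidationError("Moran's I undefined for constant values")
    if weights is None:
        diff = np.abs(x[:, None] - x[None, :])
        off = ~np.eye(n, dtype=bool)
        if (diff[off] == 0).any():
            i, j = np.argwhere((diff == 0) & off)[0]
            raise ValidationError(f"duplicate coordinates for samples {i} and {j}")
        w = np.zeros((n, n))
        w[off] = 1.0 / diff[off]
    else:
        w = np.asarray(weights, dtype=float)

    z = z - z.mean()
    s0 = w.sum()
    i_stat = (n / s0) * float(z @ w @ z) / float(z @ z)
    e_i = -1.0 / (n - 1)

    # randomization variance (standard S1/S2/b2 formula)
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    b2 = n * (z**4).sum() / (z**2).sum() ** 2
    var = (
        n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2)
        - b2 * ((n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2)
    ) / ((n - 1) * (n - 2) * (n - 3) * s0**2) - e_i**2
    sd = float(np.sqrt(max(var, 0.0)))
    p = 2.0 * float(sps.norm.sf(abs(i_stat - e_i) / sd)) if sd > 0 else 1.0
    return {"I": float(i_stat), "expected": e_i, "sd": sd, "p": min(p, 1.0)}


def unit_geographic_distances(
    hosts: HostAssignment, coordinates: pd.Series, level, sample_ids=None
) -> DistanceMatrix:
    """Pairwise |difference of mean transect position| between plant OTUs.

    The community units of the Mantel analyses are plant OTUs, so their
    geographic separation is summarized by the mean position of each
    unit's samples.
    """
    table = hosts.table if sample_ids is None else hosts.table.loc[list(sample_ids)]
    coords = coordinates.loc[table.index]
    centre = coords.groupby(table[level_column(level)].to_numpy()).mean().sort_index()
    v = np.abs(centre.to_numpy()[:, None] - centre.to_numpy()[None, :])
    np.fill_diagonal(v, 0.0)
    idx = pd.Index(centre.index, name="plant_otu")
    return DistanceMatrix(pd.DataFrame(v, index=idx, columns=idx), kind="geographic")
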