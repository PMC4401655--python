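"""Rarefaction, presence/absence conversion, plant x fungal association
matrices, and sample-based OTU accumulation curves."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import AssociationMatrix, CountMatrix, HostAssignment, OccurrenceMatrix, level_column
from .errors import StateError, ValidationError

DEFAULT_DEPTH = 100


def rarefy(counts: CountMatrix, depth: int = DEFAULT_DEPTH, seed: int = 0):
    """Subsample every sample's reads to `depth` without replacement.

    Samples whose total is below `depth` are removed and returned in the
    dropped list; samples at exactly `depth` are kept unchanged.  Each
    sample uses an independent RNG stream derived from (seed, row index),
    so a single sample can be re-rarefied in isolation and reproduced.

    Returns (rarefied CountMatrix, list of dropped sample ids).
    """
    if depth <= 0:
        raise ValidationError(f"rarefaction depth must be positive, got {depth}")
    if counts.state != "raw":
        raise StateError("rarefy expects a raw count matrix")
    data = counts.data
    totals = data.sum(axis=1).to_numpy()
    keep = totals >= depth
    dropped = list(data.index[~keep])

    rows = []
    kept_ids = []
    values = data.to_numpy()
    for pos in np.flatnonzero(keep):
        row = values[pos]
        if totals[pos] == depth:
            rows.append(row.copy())
        else:
            rng = np.random.default_rng([seed, int(pos)])
            rows.append(rng.multivariate_hypergeometric(row, depth))
        kept_ids.append(data.index[pos])
    rarefied = pd.DataFrame(
        np.asarray(rows, dtype=np.int64).reshape(len(rows), data.shape[1]),
        index=pd.Index(kept_ids, name=data.index.name),
        columns=data.columns,
    )
    return CountMatrix(rarefied, state="rarefied", depth=depth), dropped


def to_presence_absence(counts: CountMatrix) -> OccurrenceMatrix:
    """Binary presence/absence from a rarefied count matrix.

    Fungal OTU columns that are all-zero after rarefaction are dropped
    from the matrix and recorded in ``empty_otus``.
    """
    if counts.state != "rarefied":
        raise StateError("presence/absence conversion requires a rarefied matrix")
    binary = (counts.data > 0).astype(np.int8)
    empty = list(binary.columns[binary.sum(axis=0) == 0])
    return OccurrenceMatrix(binary.drop(columns=empty), empty_otus=empty)


def build_association(
    occ: OccurrenceMatrix, hosts: HostAssignment, level
) -> AssociationMatrix:
    """Plant-taxon x fungal-OTU association counts at one cutoff level.

    y[i, j] = number of samples assigned to plant OTU j (at `level`) in
    which fungal OTU i is present.  Fungal OTUs observed in no retained
    sample are dropped.
    """
    col = level_column(level)
    missing = occ.sample_ids.difference(hosts.sample_ids)
    if len(missing):
        raise ValidationError(f"sample {missing[0]!r} has no host assignment")
    labels = hosts.table.loc[occ.sample_ids, col]
    if labels.isna().any():
        bad = labels.index[labels.isna()][0]
        raise ValidationError(f"sample {bad!r} has no host label at level {level}")
    grouped = occ.data.groupby(labels.to_numpy()).sum()  # plant OTU x fungal OTU
    T = labels.value_counts().sort_index()
    y = grouped.T  # fungal rows x plant columns
    y = y.loc[y.sum(axis=1) > 0]
    y = y[T.index]
    return AssociationMatrix(y=y, T=T, level=str(level))


def _exact_expected_richness(m: np.ndarray, M: int, t: np.ndarray) -> np.ndarray:
    """E[S(t)] = sum_k (1 - C(M - m_k, t) / C(M, t)), vectorised over t."""
    # log C(M - m, t) - log C(M, t), with C(a, t) = 0 when a < t
    a = (M - m)[:, None].astype(float)  # OTUs x 1
    tt = t[None, :].astype(float)
    with np.errstate(invalid="ignore"):
        log_ratio = (
            gammaln(a + 1) - gammaln(a - tt + 1) - (gammaln(M + 1) - gammaln(M - tt + 1))
        )
    q = np.where(a >= tt, np.exp(log_ratio), 0.0)  # P(OTU absent from t samples)
    return (1.0 - q).sum(axis=0), q


def accumulation_curve(
    occ: OccurrenceMatrix,
    subset=None,
    method: str = "exact",
    n_perm: int = 100,
    seed: int = 0,
    t_values=None,
) -> pd.DataFrame:
    """Sample-based OTU accumulation curve with 95% confidence band.

    exact: hypergeometric expectation of richness after t samples, with the
    analytic standard deviation from pairwise joint absence probabilities.
    random: mean and sd of richness over `n_perm` random sample orderings.
    CI = mean +/- 1.96 * sd in both methods.

    `subset` restricts the curve to a set of OTU ids (e.g. a taxonomy
    filter); `t_values` defaults to 1..M.
    """
    data = occ.data if subset is None else occ.data[[o for o in occ.data.columns if o in set(subset)]]
    M = data.shape[0]
    if M < 1:
        raise ValidationError("accumulation curve needs at least one sample")
    if t_values is None:
        t_values = np.arange(1, M + 1)
    t_values = np.asarray(t_values, dtype=int)
    if (t_values < 1).any() or (t_values > M).any():
        raise ValidationError(f"t must lie in 1..{M}")

    values = data.to_numpy()
    m = values.sum(axis=0)  # samples containing each OTU
    m = m[m > 0]

    if method == "exact":
        mean, q = _exact_expected_richness(m, M, t_values)
        # Var(S) = sum_{k,l} (q_kl - q_k q_l) with q_kl = P(both k and l absent)
        present = values[:, values.sum(axis=0) > 0]
        co = present.T @ present  # co-occurrence counts
        u = m[:, None] + m[None, :] - co  # |A_k union A_l|
        a = (M - u)[None, :, :].astype(float)
        tt = t_values[:, None, None].astype(float)
        with np.errstate(invalid="ignore"):
            log_ratio = (
                gammaln(a + 1) - gammaln(a - tt + 1)
                - (gammaln(M + 1) - gammaln(M - tt + 1))
            )
        q_joint = np.where(a >= tt, np.exp(log_ratio), 0.0)  # t x K x K
        var = (q_joint - q.T[:, :, None] * q.T[:, None, :]).sum(axis=(1, 2))
        sd = np.sqrt(np.maximum(var, 0.0))
    elif method == "random":
        rng = np.random.default_rng(seed)
        richness = np.empty((n_perm, len(t_values)))
        for p in range(n_perm):
            order = rng.permutation(M)
            seen = np.cumsum(values[order], axis=0) > 0
            s_of_t = seen.sum(axis=1)
            richness[p] = s_of_t[t_values - 1]
        mean = richness.mean(axis=0)
        sd = richness.std(axis=0, ddof=1) if n_perm > 1 else np.zeros(len(t_values))
    else:
        raise ValidationError(f"unknown accumulation method {method!r}")

    return pd.DataFrame(
        {
            "t": t_values,
            "richness": mean,
            "sd": sd,
            "ci_lo": mean - 1.96 * sd,
            "ci_hi": mean + 1.96 * sd,
        }
    )
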