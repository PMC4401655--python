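"""Bayesian Dirichlet-multinomial host-preference model.

For each fungal OTU i, the counts of samples in which it occurs across
plant OTUs, ``y_i = (y_i1, ..., y_iJ)``, are modelled as multinomial with
composition ``pi_i`` and total ``N_i``.  The Dirichlet prior

    alpha_ij = T_j * N_i / sum_j T_j

places the prior mean at the host sample shares ``T_j / sum T_j``, i.e.
the association frequencies expected if fungi colonized hosts at random
with probability proportional to sampling effort.  Host preference is
quantified per posterior draw by the normalized deviation

    Dbar_ij = (pi_ij - E[pi_ij]) / ||pi_i - E[pi_i]||_2,

which sums to zero and has unit L2 norm across hosts, so each component
lies in [-1, 1]: positive values mean the fungus occurs on that host more
often than random host selection predicts.  The posterior mean of Dbar is
D-hat; its maximum over hosts (D-hat-max) summarizes how sharply the OTU
prefers its best host, and comparing D-hat-max across host clustering
levels locates the taxonomic grain of the preference.

The model is conjugate, so the default fit draws directly from the exact
Dirichlet posterior ``Dir(alpha_i + y_i)``.  A Metropolis-within-Gibbs
MCMC mode (random-walk on the log of the latent gamma variables whose
normalization is the Dirichlet) is provided as an independent route with
burn-in, thinning, multiple chains and Gelman-Rubin diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .containers import AssociationMatrix
from .errors import ConvergenceError, ValidationError
from .stats import compact_letter_display, holm_adjust, wilcoxon_signed_rank

__all__ = [
    "compute_alpha",
    "compute_D",
    "compute_Dmax",
    "gelman_rubin",
    "compare_Dmax_levels",
    "HostPreferenceModel",
    "HostPreferenceResults",
]

_NORM_TOL = 1e-12  # draws whose deviation vector is numerically zero are rejected


def compute_alpha(assoc: AssociationMatrix) -> pd.DataFrame:
    """Dirichlet prior parameters alpha_ij = T_j * N_i / sum_j T_j.

    Row sums equal N_i, and the prior mean T_j / sum T_j is the random
    host-selection expectation, identical for every fungal OTU.
    """
    if assoc.J < 2:
        raise ValidationError("preference undefined for a single host taxon")
    T = assoc.T.to_numpy(dtype=float)
    N = assoc.N.to_numpy(dtype=float)
    if (N < 1).any():
        raise ValidationError("every modelled fungal OTU needs N_i >= 1")
    alpha = np.outer(N, T / T.sum())
    return pd.DataFrame(alpha, index=assoc.fungal_otus, columns=assoc.plant_otus)


def _draw_conjugate(post_alpha: np.ndarray, draws: int, rng: np.random.Generator) -> np.ndarray:
    """Exact posterior draws, shape (draws, n_otus, J)."""
    g = rng.gamma(shape=post_alpha[None, :, :], size=(draws, *post_alpha.shape))
    return g / g.sum(axis=2, keepdims=True)


def _gibbs_chains(
    post_alpha: np.ndarray,
    iterations: int,
    chains: int,
    burn_in: int,
    thin: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Metropolis-within-Gibbs sampler on the gamma representation.

    pi_i = g_i / sum(g_i) with g_ij ~ Gamma(alpha_ij + y_ij).  Each scalar
    w = log g is updated by a random-walk Metropolis step against the
    target density exp(a*w - e^w); normalizing the g's yields Dirichlet
    draws.  Burn-in counts raw iterations before thinning.

    Returns per-chain retained pi draws, shape (chains, kept, n_otus, J).
    """
    if iterations <= 0 or burn_in < 0 or thin <= 0:
        raise ValidationError("iterations, thin must be positive; burn_in non-negative")
    if burn_in >= iterations:
        raise ValidationError("burn_in must be smaller than iterations")
    a = post_alpha
    kept = (iterations - burn_in) // thin
    if kept < 1:
        raise ValidationError("no draws retained; reduce burn_in or thin")
    step = 2.4 / np.sqrt(np.maximum(a, 0.5))  # RW scale ~ posterior sd of log g
    out = np.empty((chains, kept, *a.shape))
    for c in range(chains):
        # overdispersed starts around the conditional mode log(a)
        w = np.log(a) + rng.normal(scale=1.0, size=a.shape) + (c - (chains - 1) / 2)
        k = 0
        for it in range(iterations):
            prop = w + step * rng.normal(size=a.shape)
            log_acc = a * (prop - w) - (np.exp(prop) - np.exp(w))
            accept = np.log(rng.uniform(size=a.shape)) < log_acc
            w = np.where(accept, prop, w)
            if it >= burn_in and (it - burn_in) % thin == 0 and k < kept:
                g = np.exp(w)
                out[c, k] = g / g.sum(axis=1, keepdims=True)
                k += 1
    return out


def compute_D(pi_draws: np.ndarray, expected_pi: np.ndarray, max_reject_frac: float = 0.01):
    """Per-draw normalized deviations Dbar and their summaries.

    Parameters
    ----------
    pi_draws : (draws, n_otus, J) posterior composition draws.
    expected_pi : (J,) random host-selection expectation T_j / sum T_j.

    Draws whose deviation vector has an effectively zero norm cannot be
    normalized and are rejected (per OTU); more than `max_reject_frac`
    rejected draws for any OTU raises.

    Returns a dict with Dbar draws (rejected -> NaN), D_hat, the 95%/99%
    equal-tailed credible intervals, significance flags, and the per-OTU
    rejected-draw counts.
    """
    dev = pi_draws - expected_pi[None, None, :]
    norm = np.linalg.norm(dev, axis=2)  # draws x n_otus
    ok = norm > _NORM_TOL
    n_rejected = (~ok).sum(axis=0)
    n_draws = pi_draws.shape[0]
    if (n_rejected > max_reject_frac * n_draws).any():
        raise ConvergenceError(
            f"more than {max_reject_frac:.0%} of draws had degenerate deviation vectors"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        dbar = dev / norm[:, :, None]
    dbar[~ok] = np.nan

    d_hat = np.nanmean(dbar, axis=0)
    q = np.nanquantile(dbar, [0.025, 0.975, 0.005, 0.995], axis=0)
    ci95 = (q[0], q[1])
    ci99 = (q[2], q[3])
    return {
        "dbar": dbar,
        "d_hat": d_hat,
        "ci95_lo": ci95[0],
        "ci95_hi": ci95[1],
        "ci99_lo": ci99[0],
        "ci99_hi": ci99[1],
        "sig95": (ci95[0] > 0) | (ci95[1] < 0),
        "sig99": (ci99[0] > 0) | (ci99[1] < 0),
        "n_rejected": n_rejected,
    }


def compute_Dmax(d_hat: pd.DataFrame) -> pd.DataFrame:
    """Per-OTU signed maximum of D-hat over hosts.

    The summary follows the printed definition max_j D-hat_ij (a signed
    max, not max |D-hat|); rows where the two disagree — i.e. where the
    largest-magnitude deviation is negative — are flagged instead of
    silently reinterpreted.
    """
    d_max = d_hat.max(axis=1)
    abs_differs = ~np.isclose(d_max, d_hat.abs().max(axis=1))
    return pd.DataFrame({"d_max": d_max, "abs_max_differs": abs_differs})


def gelman_rubin(chain_draws: np.ndarray) -> np.ndarray:
    """Potential scale reduction factor per parameter.

    chain_draws : (chains, n, ...) array of retained draws.
    R-hat = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain
    variance and B the between-chain variance of chain means (times n).
    """
    chain_draws = np.asarray(chain_draws, dtype=float)
    if chain_draws.ndim < 2 or chain_draws.shape[0] < 2:
        raise ValidationError("gelman_rubin needs >= 2 chains")
    n = chain_draws.shape[1]
    if n < 10:
        raise ValidationError("gelman_rubin needs chains of length >= 10")
    means = chain_draws.mean(axis=1)  # chains x ...
    W = chain_draws.var(axis=1, ddof=1).mean(axis=0)
    B = n * means.var(axis=0, ddof=1)
    if np.all(W == 0):
        raise ConvergenceError("zero within-chain variance in all chains")
    with np.errstate(divide="ignore", invalid="ignore"):
        var_hat = (n - 1) / n * W + B / n
        rhat = np.sqrt(var_hat / W)
    return rhat


def compare_Dmax_levels(dmax_table: pd.DataFrame, alpha: float = 0.05):
    """Pairwise Wilcoxon signed-rank comparison of D-hat-max across levels.

    `dmax_table` has one row per fungal OTU and one column per host
    clustering level.  All level pairs are tested two-sided on the paired
    values, Holm-corrected across the pairs; the compact letter display
    assigns shared letters to levels that do not differ significantly.

    Returns (pairs DataFrame, {level: letters}).
    """
    levels = list(dmax_table.columns)
    if len(dmax_table) < 6:
        raise ValidationError("need >= 6 OTUs for the cross-level comparison")
    if dmax_table.isna().any().any():
        raise ValidationError("D-hat-max table must cover the same OTU set at every level")
    rows = []
    for a, b in combinations(levels, 2):
        x, y = dmax_table[a].to_numpy(), dmax_table[b].to_numpy()
        if np.all(x == y):
            warnings.warn(f"all paired differences are zero for levels {a} vs {b}")
            p = 1.0
        else:
            p = wilcoxon_signed_rank(x, y)
        rows.append({"level_a": a, "level_b": b, "p": p})
    pairs = pd.DataFrame(rows)
    pairs["holm_p"] = holm_adjust(pairs["p"].to_numpy())
    pairs["significant"] = pairs["holm_p"] < alpha
    sig_map = {
        (r.level_a, r.level_b): bool(r.significant) for r in pairs.itertuples()
    }
    letters = compact_letter_display(levels, sig_map)
    return pairs, letters


# ---------------------------------------------------------------------------
# model / results objects


class HostPreferenceModel:
    """Dirichlet-multinomial host-preference model for one association matrix.

    Parameters
    ----------
    assoc : AssociationMatrix
        Plant-taxon x fungal-OTU association counts at one cutoff level.
    min_occurrence : int
        Only fungal OTUs occurring in at least this many samples
        (N_i >= min_occurrence) are modelled; rare OTUs carry too little
        information for the deviation statistic.
    """

    def __init__(self, assoc: AssociationMatrix, min_occurrence: int = 5):
        keep = assoc.N >= min_occurrence
        if not keep.any():
            raise ValidationError("no fungal OTU passes the minimum-occurrence filter")
        self.assoc = AssociationMatrix(
            y=assoc.y.loc[keep], T=assoc.T.copy(), level=assoc.level
        )
        self.alpha = compute_alpha(self.assoc)
        self.expected_pi = (self.assoc.T / self.assoc.T.sum()).to_numpy(dtype=float)

    @classmethod
    def from_occurrence(cls, occ, hosts, level, min_occurrence: int = 5):
        """Convenience constructor from a sample-level occurrence matrix."""
        from .matrices import build_association

        return cls(build_association(occ, hosts, level), min_occurrence=min_occurrence)

    def fit(
        self,
        mode: str = "conjugate",
        draws: int = 5000,
        chains: int = 3,
        iterations: int = 100_000,
        burn_in: int = 40_000,
        thin: int = 20,
        seed: int = 0,
        chunk_size: int = 64,
        keep_draws: bool = False,
    ) -> "HostPreferenceResults":
        """Sample the posterior and summarize the preference statistics.

        conjugate : direct draws from the exact Dirichlet posterior
            (`draws` per OTU).
        gibbs : `chains` Metropolis-within-Gibbs chains of `iterations` raw
            iterations each; `burn_in` raw iterations are discarded before
            thinning every `thin`-th draw.  Gelman-Rubin diagnostics are
            computed per pi parameter.

        OTUs are processed in chunks of `chunk_size` to bound memory.
        """
        if mode not in ("conjugate", "gibbs"):
            raise ValidationError(f"unknown sampling mode {mode!r}")
        if mode == "conjugate" and draws <= 0:
            raise ValidationError("draws must be positive")
        rng = np.random.default_rng([seed, 17])

        y = self.assoc.y.to_numpy(dtype=float)
        post_alpha_all = self.alpha.to_numpy() + y
        n_otus = post_alpha_all.shape[0]

        blocks = {k: [] for k in (
            "d_hat", "ci95_lo", "ci95_hi", "ci99_lo", "ci99_hi", "sig95", "sig99",
            "n_rejected",
        )}
        rhat_blocks = []
        dbar_blocks = [] if keep_draws else None

        for start in range(0, n_otus, chunk_size):
            pa = post_alpha_all[start : start + chunk_size]
            if mode == "conjugate":
                pi = _draw_conjugate(pa, draws, rng)
            else:
                per_chain = _gibbs_chains(pa, iterations, chains, burn_in, thin, rng)
                rhat_blocks.append(gelman_rubin(per_chain))
                pi = per_chain.reshape(-1, *pa.shape)
            summ = compute_D(pi, self.expected_pi)
            for k in blocks:
                blocks[k].append(summ[k])
            if keep_draws:
                dbar_blocks.append(summ["dbar"])

        idx, cols = self.assoc.fungal_otus, self.assoc.plant_otus

        def frame(key, dtype=float):
            return pd.DataFrame(np.vstack(blocks[key]).astype(dtype), index=idx, columns=cols)

        n_draws_used = draws if mode == "conjugate" else chains * ((iterations - burn_in) // thin)
        return HostPreferenceResults(
            model=self,
            d_hat=frame("d_hat"),
            ci95_lo=frame("ci95_lo"),
            ci95_hi=frame("ci95_hi"),
            ci99_lo=frame("ci99_lo"),
            ci99_hi=frame("ci99_hi"),
            sig95=frame("sig95", bool),
            sig99=frame("sig99", bool),
            n_rejected=pd.Series(np.concatenate(blocks["n_rejected"]), index=idx),
            rhat=(
                pd.DataFrame(np.vstack(rhat_blocks), index=idx, columns=cols)
                if rhat_blocks
                else None
            ),
            dbar_draws=(np.concatenate(dbar_blocks, axis=1) if keep_draws else None),
            mode=mode,
            n_draws=n_draws_used,
            chains=chains if mode == "gibbs" else 1,
            burn_in=burn_in if mode == "gibbs" else 0,
            thin=thin if mode == "gibbs" else 1,
            seed=seed,
        )


@dataclass
class HostPreferenceResults:
    """Posterior summaries of the host-preference statistics at one level."""

    model: HostPreferenceModel
    d_hat: pd.DataFrame
    ci95_lo: pd.DataFrame
    ci95_hi: pd.DataFrame
    ci99_lo: pd.DataFrame
    ci99_hi: pd.DataFrame
    sig95: pd.DataFrame
    sig99: pd.DataFrame
    n_rejected: pd.Series
    rhat: pd.DataFrame | None
    dbar_draws: np.ndarray | None
    mode: str
    n_draws: int
    chains: int
    burn_in: int
    thin: int
    seed: int
    _dmax: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def level(self) -> str:
        return self.model.assoc.level

    def dmax(self) -> pd.DataFrame:
        """Per-OTU signed max of D-hat over hosts (with the |max| flag)."""
        if self._dmax is None:
            self._dmax = compute_Dmax(self.d_hat)
        return self._dmax

    def summary(self) -> pd.DataFrame:
        """Tidy per-(OTU, host) table: D-hat, credible intervals, flags.

        The `flag` column mirrors the figure convention: '*' when the 99%
        interval excludes 0, '+' when only the 95% interval does.
        """
        long = self.d_hat.stack().rename("d_hat").reset_index()
        long.columns = ["otu", "host", "d_hat"]
        for name, df in (
            ("ci95_lo", self.ci95_lo), ("ci95_hi", self.ci95_hi),
            ("ci99_lo", self.ci99_lo), ("ci99_hi", self.ci99_hi),
        ):
            long[name] = df.stack().to_numpy()
        s95 = self.sig95.stack().to_numpy()
        s99 = self.sig99.stack().to_numpy()
        long["flag"] = np.where(s99, "*", np.where(s95, "+", ""))
        if self.rhat is not None:
            long["rhat"] = self.rhat.stack().to_numpy()
        return long

    def max_rhat(self) -> float | None:
        return None if self.rhat is None else float(self.rhat.to_numpy().max())
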