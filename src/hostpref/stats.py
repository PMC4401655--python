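"""Shared statistical primitives: Fisher's exact test, Holm correction,
exact Wilcoxon signed-rank enumeration, and compact letter displays.

These are the small frequentist tools used by the reporting layers
(taxon frequency tables, cross-level comparisons); the Bayesian machinery
lives in :mod:`hostpref.preference`.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "fisher_exact_two_sided",
    "holm_adjust",
    "wilcoxon_signed_rank",
    "compact_letter_display",
    "round_half_away",
]


def round_half_away(x, decimals: int = 1):
    """Round half away from zero (the convention of most report tables).

    numpy rounds half to even; report percentages such as 12.75 -> 12.8
    require the away-from-zero rule.
    """
    x = np.asarray(x, dtype=float)
    factor = 10.0**decimals
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return out if out.ndim else float(out)


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    The two-sided p is the sum of hypergeometric probabilities of all
    tables with the same margins that are at most as probable as the
    observed one (R's convention).
    """
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("fisher_exact_two_sided expects a non-negative 2x2 table")
    return float(sps.fisher_exact(table, alternative="two-sided")[1])


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues.copy()
    return multipletests(pvalues, method="holm")[1]


def _exact_signed_rank_p(ranks: np.ndarray, w_obs: float) -> float:
    """Two-sided p by enumeration of all 2^n sign assignments.

    `ranks` are the midranks of the non-zero |differences|; W+ is the sum
    of ranks with positive sign.  p = 2 * min(P(W+ <= w), P(W+ >= w)),
    capped at 1.  Valid with tied ranks, where the large-sample and
    scipy exact paths are not.
    """
    n = ranks.size
    # all 2^n subsets, vectorised; n is capped by the caller
    masks = np.array(list(itertools.product((0.0, 1.0), repeat=n)))
    w_all = masks @ ranks
    p_le = np.mean(w_all <= w_obs + 1e-12)
    p_ge = np.mean(w_all >= w_obs - 1e-12)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(x, y, exact_max_n: int = 16) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are discarded (the classic Wilcoxon treatment).  For
    up to `exact_max_n` non-zero pairs the null distribution is enumerated
    over all sign assignments (correct under ties); larger samples use the
    normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if d.size <= exact_max_n:
        return _exact_signed_rank_p(ranks, w_pos)
    res = sps.wilcoxon(d, alternative="two-sided", method="approx")
    return float(res.pvalue)


def compact_letter_display(labels, pair_significant) -> dict:
    """Assign letters so that groups NOT significantly different share one.

    Parameters
    ----------
    labels : sequence of group names.
    pair_significant : mapping (a, b) -> bool for each unordered pair.

    Letters correspond to the maximal cliques of the "not significantly
    different" graph, enumerated exhaustively (group counts here are tiny:
    four clustering levels).
    """
    labels = list(labels)
    k = len(labels)
    if k > 16:
        raise ValueError("compact_letter_display enumerates subsets; too many groups")
    adj = {(a, b): not pair_significant.get((a, b), pair_significant.get((b, a), False))
           for a in labels for b in labels if a != b}

    cliques: list[set] = []
    for mask in range(1, 2**k):
        members = {labels[i] for i in range(k) if mask >> i & 1}
        if all(adj[(a, b)] for a in members for b in members if a != b):
            cliques.append(members)
    cliques = [c for c in cliques if not any(c < other for other in cliques)]
    cliques.sort(key=lambda c: sorted(labels.index(m) for m in c))
    letters = {lab: "" for lab in labels}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for letter, c in zip(alphabet, cliques):
        for lab in labels:
            if lab in c:
                letters[lab] += letter
    if k and any(not v for v in letters.values()):  # pragma: no cover - defensive
        raise RuntimeError("letter display failed to cover all groups")
    return letters
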