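"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's vectorized code paths: frequencies
are counted with nested loops, E_p with an explicit (residue, window)
double loop, and the separability ceiling with a closed-form binomial
calculation.  Frozen statistical bounds quoted in the tests were produced
with the Monte-Carlo helpers here (replicate counts noted at the call
sites); they are re-frozen rather than re-run so the suite stays fast.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binom

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def brute_frequency(sequences: list[str], aa: str, position: int,
                    pseudocount: float = 0.0) -> float:
    """Frequency of ``aa`` at 1-based ``position`` by explicit counting."""
    count = 0
    for seq in sequences:
        if seq[position - 1] == aa:
            count += 1
    return (count + pseudocount) / (len(sequences) + 20 * pseudocount)


def brute_bfe(seq: str, pos_seqs: list[str], neg_seqs: list[str]) -> np.ndarray:
    """Bi-profile encoding via nested-loop counting (no pseudocount)."""
    L = len(seq)
    vec = np.empty(2 * L)
    for j in range(1, L + 1):
        vec[j - 1] = brute_frequency(pos_seqs, seq[j - 1], j)
        vec[L + j - 1] = brute_frequency(neg_seqs, seq[j - 1], j)
    return vec


def brute_ep(window_scores: np.ndarray, L: int, w: int) -> np.ndarray:
    """Per-residue window-score sums by looping over every (residue, window)
    pair; interior residues only, NaN elsewhere."""
    ep = np.full(L, np.nan)
    for i in range(1, L + 1):  # residue, 1-based
        n_cover, total = 0, 0.0
        for s in range(1, L - w + 2):  # window start
            if s <= i <= s + w - 1:
                n_cover += 1
                total += window_scores[s - 1]
        if n_cover == w:
            ep[i - 1] = total
    return ep


def bayes_optimal_auroc(r: float, n_enriched: int, L: int = 20) -> float:
    """Separability ceiling for ``n_enriched`` residues enriched r-fold at
    every position over a uniform background.

    The log-likelihood ratio is monotone in the count k of enriched
    residues in the peptide, k ~ Binomial(L, p) with class-specific p, so
    AUROC follows in closed form from the two binomials.
    """
    Z = (20 - n_enriched + n_enriched * r) / 20
    p_pos = n_enriched * (r / 20) / Z
    p_neg = n_enriched / 20
    ks = np.arange(L + 1)
    P = binom.pmf(ks, L, p_pos)
    Q = binom.pmf(ks, L, p_neg)
    cumQ = np.cumsum(Q)
    auc = 0.0
    for k in ks:
        auc += P[k] * ((cumQ[k - 1] if k > 0 else 0.0) + 0.5 * Q[k])
    return float(auc)


def mc_interval(statistic, n_replicates: int, seed: int,
                q: tuple[float, float] = (2.5, 97.5)) -> tuple[float, float]:
    """Sampling interval of ``statistic(seed_i)`` over seeded replicates."""
    rng = np.random.default_rng(seed)
    vals = [statistic(int(rng.integers(2 ** 31))) for _ in range(n_replicates)]
    lo, hi = np.percentile(vals, q)
    return float(lo), float(hi)
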