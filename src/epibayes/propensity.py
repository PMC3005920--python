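"""Relative position-specific amino-acid propensities (P_x).

The propensity of amino acid *a* at peptide position *j* is the ratio of its
frequency of occurrence at position *j* in the epitope pool to its frequency
at the same position in the non-epitope pool:

    P_x(a, j) = f_pos(a, j) / f_neg(a, j)

Frequencies are estimated per position with an optional Laplace pseudocount:

    f(a, j) = (count(a, j) + c) / (n + 20 c)

P_x > 1 marks enrichment in epitopes, P_x < 1 depletion.  Averaging P_x over
all positions gives a per-amino-acid propensity scale; the per-position
standard deviation of the 20 P_x values measures how strongly position-specific
the residue preferences are (a dispersion profile that separates real
epitope/non-epitope contrasts from same-distribution control splits).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets_io import AA_INDEX, AMINO_ACIDS, NonstandardPolicy, PeptidePool

N_AA = 20


@dataclass(frozen=True)
class PositionProfile:
    """20 x L matrix of per-position amino-acid frequencies.

    Rows follow the fixed alphabetical order ``ACDEFGHIKLMNPQRSTVWY``.
    Without a pseudocount each column sums to 1 exactly (standard residues).
    """

    values: np.ndarray  # shape (20, L)
    n_sequences: int
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.values.setflags(write=False)

    @property
    def length(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class PropensityTable:
    """20 x L matrix of P_x ratios; NaN marks 0/0 (undefined) entries."""

    values: np.ndarray  # shape (20, L)
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.values.setflags(write=False)

    @property
    def length(self) -> int:
        return self.values.shape[1]

    def mean_defined(self) -> float:
        """Mean over entries where P_x is defined."""
        return float(np.nanmean(self.values))


def count_matrix(pool: PeptidePool) -> np.ndarray:
    """Raw 20 x L occurrence counts; non-standard residues contribute 1/20
    to every row of their column (the uniform-mapping policy)."""
    L = pool.length
    counts = np.zeros((N_AA, L))
    for pep in pool:
        for j, ch in enumerate(pep.sequence):
            idx = AA_INDEX.get(ch)
            if idx is None:
                counts[:, j] += 1.0 / N_AA
            else:
                counts[idx, j] += 1.0
    return counts


def compute_position_profile(pool: PeptidePool,
                             pseudocount: float = 0.0) -> PositionProfile:
    """Estimate per-position amino-acid frequencies from a pool.

    Entry (a, j) = (count of a at position j + pseudocount) /
    (pool size + 20 * pseudocount).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    counts = count_matrix(pool)
    n = len(pool)
    freqs = (counts + pseudocount) / (n + N_AA * pseudocount)
    return PositionProfile(freqs, n_sequences=n, pseudocount=pseudocount)


def compute_px(pos_pool: PeptidePool, neg_pool: PeptidePool,
               pseudocount: float = 1.0) -> PropensityTable:
    """Compute the 20 x L table of relative propensities P_x.

    Both frequency profiles use the same pseudocount.  With pseudocount 0,
    a 0/0 cell is undefined and stored as NaN; a positive frequency over a
    zero denominator raises, since the ratio is infinite — rerun with a
    positive pseudocount.
    """
    if pos_pool.length != neg_pool.length:
        raise ValueError(
            f"pool length mismatch: {pos_pool.length} vs {neg_pool.length}")
    pos = compute_position_profile(pos_pool, pseudocount).values
    neg = compute_position_profile(neg_pool, pseudocount).values
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = pos / neg
    if pseudocount == 0:
        infinite = (neg == 0) & (pos > 0)
        if infinite.any():
            a, j = np.argwhere(infinite)[0]
            raise ValueError(
                f"P_x({AMINO_ACIDS[a]}, {j + 1}) has zero non-epitope frequency "
                "but non-zero epitope frequency; use a positive pseudocount"
            )
        ratio[(neg == 0) & (pos == 0)] = np.nan
    return PropensityTable(ratio, pseudocount=pseudocount)


def average_px(table: PropensityTable) -> pd.Series:
    """Per-amino-acid average of P_x across all positions.

    NaN (undefined) cells are excluded from the average of their row.
    """
    with np.errstate(invalid="ignore"):
        means = np.nanmean(table.values, axis=1)
    return pd.Series(means, index=list(AMINO_ACIDS), name="average_px")


def positionwise_px_sd(table: PropensityTable) -> pd.Series:
    """Per-position standard deviation of the 20 amino-acid P_x values.

    Population form (divide by the number of defined residues): the 20 amino
    acids are the complete set, not a sample.
    """
    with np.errstate(invalid="ignore"):
        sds = np.nanstd(table.values, axis=0, ddof=0)
    return pd.Series(sds, index=np.arange(1, table.length + 1), name="px_sd")


def _matrix_frame(values: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(values, index=list(AMINO_ACIDS),
                        columns=np.arange(1, values.shape[1] + 1))


def export_heatmap_table(table: PropensityTable | PositionProfile,
                         path: str | Path) -> None:
    """Write a 20-row x L-column TSV (amino-acid row labels, 1-based
    position column headers, 4-decimal values) — the heat-map table."""
    if table.values.size == 0:
        raise ValueError("cannot export an empty table")
    df = _matrix_frame(table.values)
    df.to_csv(path, sep="\t", float_format="%.4f", index_label="aa")


def read_heatmap_table(path: str | Path) -> pd.DataFrame:
    """Read back a heat-map TSV as a DataFrame (amino acid x position)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def export_average_table(tables: dict[str, PropensityTable],
                         path: str | Path) -> None:
    """Per-amino-acid average-P_x table, one column per labeled dataset."""
    df = pd.DataFrame({name: average_px(t) for name, t in tables.items()})
    df.to_csv(path, sep="\t", float_format="%.4f", index_label="aa")
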