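"""Peptide feature encodings: simple binary and bi-profile Bayes (BFE).

Simple binary encoding represents each residue as a 20-dimensional one-hot
block, so a length-L peptide becomes a 20*L vector with exactly L ones.  The
block layout is reverse-alphabetical: alanine is ``[0,...,0,1]`` (the 1 in
the last coordinate), cysteine ``[0,...,0,1,0]``, and so on.  The layout is
irrelevant to the classifier but fixed for bit-exact reproducibility.

Bi-profile Bayes feature extraction (BFE) encodes a peptide against a pair
of position-specific frequency profiles — one estimated from the epitope
(positive) training pool, one from the non-epitope (negative) pool.  Element
j of the feature vector is the positive-profile frequency of the peptide's
residue at position j; element L+j is the negative-profile frequency of the
same residue.  A length-L peptide thus becomes a 2*L vector of frequencies
in [0, 1] carrying its likeness to each class at every position.  Profiles
must be estimated from training data only; encoding never mutates them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datasets_io import AA_INDEX, Peptide, PeptidePool
from .propensity import (N_AA, PositionProfile, compute_position_profile,
                         read_heatmap_table, export_heatmap_table)


@dataclass(frozen=True)
class BFEProfilePair:
    """Positive (epitope) and negative (non-epitope) position profiles,
    estimated from the training split only."""

    positive: PositionProfile
    negative: PositionProfile

    def __post_init__(self) -> None:
        if self.positive.length != self.negative.length:
            raise ValueError("profile length mismatch: "
                             f"{self.positive.length} vs {self.negative.length}")

    @property
    def length(self) -> int:
        return self.positive.length


def _residue_column(profile_values: np.ndarray, ch: str, j: int) -> float:
    idx = AA_INDEX.get(ch)
    if idx is None:
        # uniform-mapping policy: a non-standard residue reads as the
        # column's mean frequency (1/20 of its mass)
        return float(profile_values[:, j].mean())
    return float(profile_values[idx, j])


def encode_binary(peptide: Peptide | str) -> np.ndarray:
    """One-hot encode a peptide into a 20*L vector.

    Residue blocks are reverse-alphabetical (alanine's 1 is the last
    coordinate of its block).  Non-standard residues under the
    uniform-mapping policy get a constant 1/20 block.
    """
    seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
    L = len(seq)
    vec = np.zeros(N_AA * L)
    for i, ch in enumerate(seq):
        idx = AA_INDEX.get(ch)
        if idx is None:
            vec[i * N_AA:(i + 1) * N_AA] = 1.0 / N_AA
        else:
            vec[i * N_AA + (N_AA - 1 - idx)] = 1.0
    return vec


def build_bfe_profiles(pos_pool: PeptidePool, neg_pool: PeptidePool,
                       pseudocount: float = 0.0) -> BFEProfilePair:
    """Estimate the positive/negative profile pair from training pools.

    The default pseudocount is 0 (raw occurrence frequencies); Laplace
    smoothing is available through the knob.
    """
    if pos_pool.length != neg_pool.length:
        raise ValueError(
            f"pool length mismatch: {pos_pool.length} vs {neg_pool.length}")
    return BFEProfilePair(
        positive=compute_position_profile(pos_pool, pseudocount),
        negative=compute_position_profile(neg_pool, pseudocount),
    )


def encode_bfe(peptide: Peptide | str, profiles: BFEProfilePair) -> np.ndarray:
    """Encode a peptide as a 2*L bi-profile frequency vector."""
    seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
    L = profiles.length
    if len(seq) != L:
        raise ValueError(f"peptide length {len(seq)} != profile length {L}")
    vec = np.empty(2 * L)
    pos, neg = profiles.positive.values, profiles.negative.values
    for j, ch in enumerate(seq):
        vec[j] = _residue_column(pos, ch, j)
        vec[L + j] = _residue_column(neg, ch, j)
    return vec


def encode_pool(pool: PeptidePool, scheme: str,
                profiles: BFEProfilePair | None = None) -> np.ndarray:
    """Encode every peptide of a pool into a feature matrix (n x d)."""
    if scheme == "binary":
        return np.array([encode_binary(p) for p in pool])
    if scheme == "bfe":
        if profiles is None:
            raise ValueError("BFE encoding requires a profile pair")
        return np.array([encode_bfe(p, profiles) for p in pool])
    raise ValueError(f"unknown encoding scheme {scheme!r}")


def save_profiles(profiles: BFEProfilePair, directory: str | Path) -> None:
    """Serialize profiles as two heat-map TSVs plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    export_heatmap_table(profiles.positive, directory / "profile_positive.tsv")
    export_heatmap_table(profiles.negative, directory / "profile_negative.tsv")
    meta = {
        "length": profiles.length,
        "n_positive": profiles.positive.n_sequences,
        "n_negative": profiles.negative.n_sequences,
        "pseudocount": profiles.positive.pseudocount,
    }
    (directory / "profiles.json").write_text(json.dumps(meta, indent=2))


def load_profiles(directory: str | Path) -> BFEProfilePair:
    directory = Path(directory)
    meta = json.loads((directory / "profiles.json").read_text())
    pos = read_heatmap_table(directory / "profile_positive.tsv").to_numpy()
    neg = read_heatmap_table(directory / "profile_negative.tsv").to_numpy()
    return BFEProfilePair(
        positive=PositionProfile(pos, meta["n_positive"], meta["pseudocount"]),
        negative=PositionProfile(neg, meta["n_negative"], meta["pseudocount"]),
    )
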