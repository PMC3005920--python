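"""Whole-antigen scanning: per-residue epitope propensity (E_p).

An antigen of length L is scanned with a sliding window of width w (default
20, the classifier's peptide length), giving L-w+1 windows at 1-based starts
1..L-w+1.  Each window is scored by the trained SVM, and the residue epitope
propensity of residue i is the additive sum of the decision scores of all
windows containing i:

    E_p(i) = sum_{s : s <= i <= s+w-1} score(window at s)

Interior residues (positions w .. L-w+1) are covered by exactly w windows;
these are the scored range by default, keeping E_p magnitudes comparable
across positions.  Terminal residues, covered by fewer windows, are reported
as unscored unless partial sums are requested.  The sign rule E_p > 0 calls
a residue an epitope; E_p <= 0 a non-epitope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import TrainedModel, predict
from .datasets_io import AnnotatedAntigen, Peptide, PeptidePool

CALL_EPITOPE = "epitope"
CALL_NON_EPITOPE = "non-epitope"
CALL_UNSCORED = "unscored"


@dataclass
class ResidueTrack:
    """Per-residue E_p scores and calls along one antigen.

    ``ep`` has one entry per residue; NaN marks unscored positions (termini
    not covered by a full complement of windows).
    """

    antigen_id: str
    ep: np.ndarray
    calls: list[str]

    def scored_positions(self) -> np.ndarray:
        """1-based positions with a defined E_p."""
        return np.flatnonzero(~np.isnan(self.ep)) + 1

    def to_frame(self, sequence: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame({
            "antigen_id": self.antigen_id,
            "position": np.arange(1, len(self.ep) + 1),
            "ep": self.ep,
            "call": self.calls,
        })
        if sequence is not None:
            df.insert(2, "residue", list(sequence))
        return df


def sliding_windows(antigen: AnnotatedAntigen, w: int = 20) -> list[tuple[int, str]]:
    """Enumerate (1-based start, subsequence) windows at step 1."""
    L = len(antigen)
    if L < w:
        raise ValueError(
            f"antigen {antigen.id!r} of length {L} is shorter than window {w}")
    return [(s, antigen.sequence[s - 1:s - 1 + w]) for s in range(1, L - w + 2)]


def compute_ep(window_scores: np.ndarray, L: int, w: int = 20,
               termini: str = "unscored") -> np.ndarray:
    """Integrate per-window scores into per-residue E_p sums.

    ``window_scores`` has one entry per window from :func:`sliding_windows`.
    ``termini="unscored"`` (default) defines E_p only on the interior
    positions w..L-w+1 (full window coverage); ``termini="partial"`` also
    reports the partial sums at the termini.  An antigen with L < 2w-1 has
    an empty interior and yields an all-NaN track with a warning.
    """
    scores = np.asarray(window_scores, dtype=float)
    n_windows = L - w + 1
    if scores.shape != (n_windows,):
        raise ValueError(
            f"expected {n_windows} window scores for L={L}, w={w}; "
            f"got {scores.shape}")
    # full convolution: entry i-1 sums scores[s-1] over starts s covering i
    ep = np.convolve(scores, np.ones(w), mode="full")
    if termini == "partial":
        return ep
    if termini != "unscored":
        raise ValueError("termini must be 'unscored' or 'partial'")
    interior = np.full(L, np.nan)
    lo, hi = w, L - w + 1  # 1-based inclusive interior
    if lo > hi:
        warnings.warn(
            f"antigen of length {L} has no residue covered by {w} full "
            f"windows (needs L >= {2 * w - 1}); all residues unscored")
    else:
        interior[lo - 1:hi] = ep[lo - 1:hi]
    return interior


def call_epitopes(ep: np.ndarray) -> list[str]:
    """Apply the sign rule: E_p > 0 epitope, E_p <= 0 non-epitope,
    NaN unscored."""
    calls = []
    for v in ep:
        if np.isnan(v):
            calls.append(CALL_UNSCORED)
        elif v > 0:
            calls.append(CALL_EPITOPE)
        else:
            calls.append(CALL_NON_EPITOPE)
    return calls


def scan_antigen(model: TrainedModel, antigen: AnnotatedAntigen,
                 w: int | None = None, termini: str = "unscored") -> ResidueTrack:
    """Score an antigen end to end: windows -> SVM scores -> E_p -> calls."""
    w = w or model.peptide_length
    if w != model.peptide_length:
        raise ValueError(
            f"window {w} != model peptide length {model.peptide_length}")
    windows = sliding_windows(antigen, w)
    pool = PeptidePool([Peptide(seq) for _, seq in windows])
    scores, _ = predict(model, pool)
    ep = compute_ep(scores, len(antigen), w, termini=termini)
    return ResidueTrack(antigen.id, ep, call_epitopes(ep))


def score_antigen(track: ResidueTrack, mask: list[bool] | None) -> dict:
    """Benchmark calls against the annotation mask over scored residues.

    Residues with E_p > 0 and annotated epitope are TP; E_p <= 0 and not
    annotated are TN; the off-diagonal counts give FP/FN.  Accuracy is the
    percentage of scored residues called correctly.  Mean E_p over annotated
    epitope vs non-epitope residues is reported alongside (NaN when a group
    is empty).
    """
    if mask is None:
        raise ValueError("antigen has no epitope annotation mask")
    if len(mask) != len(track.ep):
        raise ValueError("mask length does not match track length")
    mask_arr = np.asarray(mask, dtype=bool)
    scored = ~np.isnan(track.ep)
    ep = track.ep[scored]
    truth = mask_arr[scored]
    pred = ep > 0
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    tn = int(np.sum(~pred & ~truth))
    fn = int(np.sum(~pred & truth))
    n = len(ep)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_pos = float(np.mean(ep[truth])) if truth.any() else float("nan")
        mean_neg = float(np.mean(ep[~truth])) if (~truth).any() else float("nan")
    return {
        "antigen_id": track.antigen_id,
        "n_scored": n,
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "accuracy": 100.0 * (tp + tn) / n if n else float("nan"),
        "mean_ep_epitope": mean_pos,
        "mean_ep_non_epitope": mean_neg,
    }
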