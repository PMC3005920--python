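"""Readers, writers and validation for peptide pools, antigens and annotations.

File formats
------------
* Peptide pools: plain text, one peptide per line; blank lines and lines
  starting with ``#`` are ignored.  Files carry no header and no labels —
  the class label comes from which file (or flag) the pool is loaded under.
* Antigens: standard FASTA.
* Epitope annotations: TSV with columns ``antigen_id``, ``start``, ``end``.
  Coordinates are 1-based and inclusive at both ends, matching the
  residue-position convention of the immunology literature.
* Reports: TSV with a ``#``-prefixed comment header recording parameters.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO

#: The 20 standard amino acids, fixed alphabetical order used for every
#: matrix row layout in this package.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Ambiguity/non-standard codes that are rejected by default.
NONSTANDARD = set("BJOUXZ*")

Label = Literal["positive", "negative", "unlabeled"]

NonstandardPolicy = Literal["reject", "uniform"]


class SequenceError(ValueError):
    """A sequence violates the validation contract."""


def validate_sequence(seq: str, policy: NonstandardPolicy = "reject",
                      context: str = "sequence") -> str:
    """Upper-case and validate an amino-acid sequence.

    With ``policy="reject"`` (default) any character outside the 20 standard
    one-letter codes raises :class:`SequenceError`.  With ``policy="uniform"``
    non-standard codes are retained; downstream profile computations spread
    their contribution uniformly (1/20) over the standard residues — they are
    never silently dropped.
    """
    seq = seq.strip().upper()
    if not seq:
        raise SequenceError(f"empty {context}")
    for pos, ch in enumerate(seq, start=1):
        if ch in AA_INDEX:
            continue
        if policy == "uniform" and (ch in NONSTANDARD or ch.isalpha()):
            continue
        raise SequenceError(
            f"non-standard residue {ch!r} at position {pos} in {context}; "
            "use the uniform-mapping policy to accept it"
        )
    return seq


@dataclass(frozen=True)
class Peptide:
    """A fixed-length peptide with a class label."""

    sequence: str
    label: Label = "unlabeled"

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PeptidePool:
    """An ordered, non-empty collection of equal-length peptides."""

    peptides: list[Peptide]

    def __post_init__(self) -> None:
        if not self.peptides:
            raise SequenceError("peptide pool is empty")
        L = len(self.peptides[0])
        for i, p in enumerate(self.peptides, start=1):
            if len(p) != L:
                raise SequenceError(
                    f"inconsistent peptide length at entry {i}: "
                    f"expected {L}, got {len(p)}"
                )

    @property
    def length(self) -> int:
        """Common peptide length L."""
        return len(self.peptides[0])

    @property
    def sequences(self) -> list[str]:
        return [p.sequence for p in self.peptides]

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self):
        return iter(self.peptides)


@dataclass
class AnnotatedAntigen:
    """An antigen sequence with an optional per-residue epitope mask.

    ``epitope_mask[i]`` is True when residue ``i+1`` (1-based) lies inside an
    annotated epitope.  The mask, when present, has exactly one entry per
    residue.
    """

    id: str
    sequence: str
    epitope_mask: list[bool] | None = None

    def __post_init__(self) -> None:
        if self.epitope_mask is not None and len(self.epitope_mask) != len(self.sequence):
            raise SequenceError(
                f"antigen {self.id!r}: mask length {len(self.epitope_mask)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def read_peptide_file(path: str | Path, label: Label = "unlabeled",
                      policy: NonstandardPolicy = "reject") -> PeptidePool:
    """Read a one-peptide-per-line file into a validated :class:`PeptidePool`.

    Blank lines and ``#`` comments are skipped.  All peptides must share one
    length; the error for a violation names the offending line.
    """
    path = Path(path)
    peptides: list[Peptide] = []
    expected_len: int | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            seq = validate_sequence(line, policy, context=f"{path.name} line {lineno}")
            if expected_len is None:
                expected_len = len(seq)
            elif len(seq) != expected_len:
                raise SequenceError(
                    f"inconsistent peptide length at line {lineno} of {path.name}: "
                    f"expected {expected_len}, got {len(seq)}"
                )
            peptides.append(Peptide(seq, label))
    if not peptides:
        raise SequenceError(f"no peptides found in {path}")
    return PeptidePool(peptides)


def write_peptide_file(pool: PeptidePool, path: str | Path,
                       header: str | None = None) -> None:
    """Write a pool one peptide per line, with an optional ``#`` header."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for p in pool:
            fh.write(p.sequence + "\n")


def read_antigen_fasta(path: str | Path,
                       policy: NonstandardPolicy = "reject") -> list[AnnotatedAntigen]:
    """Read antigen sequences from FASTA; masks are left absent.

    Raises on an empty file and on duplicated record IDs.
    """
    path = Path(path)
    antigens: list[AnnotatedAntigen] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicated antigen ID {rec.id!r} in {path.name}")
        seen.add(rec.id)
        seq = validate_sequence(str(rec.seq), policy, context=f"antigen {rec.id!r}")
        antigens.append(AnnotatedAntigen(rec.id, seq))
    if not antigens:
        raise SequenceError(f"no FASTA records found in {path}")
    return antigens


def write_antigen_fasta(antigens: Sequence[AnnotatedAntigen], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ant in antigens:
            fh.write(f">{ant.id}\n")
            for i in range(0, len(ant.sequence), 60):
                fh.write(ant.sequence[i:i + 60] + "\n")


def read_epitope_annotations(path: str | Path,
                             antigens: Sequence[AnnotatedAntigen]) -> list[AnnotatedAntigen]:
    """Attach per-residue epitope masks from an interval TSV.

    The file has columns ``antigen_id``, ``start``, ``end`` (1-based,
    inclusive).  Every listed antigen gets a mask that is True inside its
    intervals and False elsewhere; antigens without intervals get an
    all-False mask.  Intervals outside the sequence bounds or naming an
    unknown antigen raise :class:`SequenceError`.
    """
    path = Path(path)
    by_id = {a.id: a for a in antigens}
    masks = {a.id: [False] * len(a) for a in antigens}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise SequenceError(
                    f"{path.name} line {lineno}: expected antigen_id, start, end")
            aid, start_s, end_s = parts[0], parts[1], parts[2]
            if aid not in by_id:
                raise SequenceError(f"{path.name} line {lineno}: unknown antigen {aid!r}")
            start, end = int(start_s), int(end_s)
            L = len(by_id[aid])
            if not (1 <= start <= end <= L):
                raise SequenceError(
                    f"{path.name} line {lineno}: interval ({start}, {end}) outside "
                    f"antigen {aid!r} of length {L}"
                )
            for i in range(start - 1, end):
                masks[aid][i] = True
    return [AnnotatedAntigen(a.id, a.sequence, masks[a.id]) for a in antigens]


def write_epitope_annotations(antigens: Sequence[AnnotatedAntigen],
                              path: str | Path) -> None:
    """Write masks back out as 1-based inclusive intervals (TSV)."""
    with open(path, "w") as fh:
        fh.write("# antigen_id\tstart\tend (1-based, inclusive)\n")
        for ant in antigens:
            if ant.epitope_mask is None:
                continue
            start = None
            for i, flag in enumerate(ant.epitope_mask):
                if flag and start is None:
                    start = i + 1
                elif not flag and start is not None:
                    fh.write(f"{ant.id}\t{start}\t{i}\n")
                    start = None
            if start is not None:
                fh.write(f"{ant.id}\t{start}\t{len(ant)}\n")


def write_report(df, path: str | Path, params: dict | None = None) -> None:
    """Write a DataFrame as TSV with a ``#`` comment header of parameters."""
    buf = io.StringIO()
    if params:
        for k, v in params.items():
            buf.write(f"# {k}: {v}\n")
    df.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())
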