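"""Core containers shared across the toolkit.

The unit of analysis is an annotated mitochondrial genome: one circular
~14.9 kb sequence stored linearized at the control-region start, plus a
typed, stranded feature table (13 protein-coding genes, 22 tRNAs, 2 rRNAs
and the control region).  Alignments are named, equal-length rows over
``{A,C,G,T,N,-}``; coordinates are 0-based half-open throughout the
in-memory API.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

DNA_ALPHABET = frozenset("ACGTN")
ALIGNED_ALPHABET = frozenset("ACGTN-")

#: translation applied to every incoming sequence: case fold and RNA -> DNA
_NORMALIZE = str.maketrans("acgtunU", "ACGTTNT")

_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")

FEATURE_KINDS = ("PCG", "tRNA", "rRNA", "control")


class FormatError(ValueError):
    """Malformed input: bad characters, bad coordinates, bad structure."""


def normalize_sequence(seq: str, *, aligned: bool = False, context: str = "") -> str:
    """Upper-case a nucleotide string, map U->T, and validate its alphabet.

    Raises :class:`FormatError` naming the first offending position.
    """
    if not seq:
        raise FormatError(f"empty sequence{' in ' + context if context else ''}")
    out = seq.translate(_NORMALIZE)
    allowed = ALIGNED_ALPHABET if aligned else DNA_ALPHABET
    for i, ch in enumerate(out):
        if ch not in allowed:
            where = f" in {context}" if context else ""
            raise FormatError(
                f"invalid character {ch!r} at offset {i}{where} "
                f"(allowed: {''.join(sorted(allowed))})"
            )
    return out


def revcomp(seq: str) -> str:
    """Reverse complement; N and '-' are self-complementary."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over ``{A,C,G,T,N}`` (plus ``-`` if aligned)."""

    id: str
    sequence: str
    aligned: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        object.__setattr__(
            self,
            "sequence",
            normalize_sequence(self.sequence, aligned=self.aligned, context=self.id),
        )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FeatureRecord:
    """A stranded gene feature in 0-based half-open coordinates.

    ``kind`` is one of PCG / tRNA / rRNA / control; ``strand`` is '+' for the
    heavy strand and '-' for the light strand.
    """

    gene_name: str
    kind: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise FormatError(
                f"unknown feature kind {self.kind!r} for {self.gene_name}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"feature {self.gene_name} must be stranded '+' or '-', "
                f"got {self.strand!r}"
            )
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"feature {self.gene_name}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedMitogenome:
    """One mitogenome sequence with its gene features."""

    record: SequenceRecord
    features: list[FeatureRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.record)
        for f in self.features:
            if f.end > n:
                raise FormatError(
                    f"feature {f.gene_name} [{f.start},{f.end}) exceeds "
                    f"genome length {n}"
                )

    @property
    def id(self) -> str:
        return self.record.id

    @property
    def sequence(self) -> str:
        return self.record.sequence

    def __len__(self) -> int:
        return len(self.record)

    def features_of_kind(self, kind: str) -> list[FeatureRecord]:
        return [f for f in self.features if f.kind == kind]

    def gene_sequence(self, feature: FeatureRecord) -> str:
        """Coding-strand sequence of a feature (light-strand genes are
        reverse-complemented)."""
        sub = self.sequence[feature.start : feature.end]
        return revcomp(sub) if feature.strand == "-" else sub

    def counts_by_kind(self) -> dict[str, int]:
        out = {k: 0 for k in FEATURE_KINDS}
        for f in self.features:
            out[f.kind] += 1
        return out


class Alignment:
    """Named equal-length rows over ``{A,C,G,T,N,-}``.

    Rows are stored as a byte matrix so column operations vectorize.
    """

    def __init__(self, records: Iterable[SequenceRecord | tuple[str, str]]):
        recs: list[SequenceRecord] = []
        for r in records:
            if isinstance(r, SequenceRecord):
                recs.append(
                    r if r.aligned else SequenceRecord(r.id, r.sequence, aligned=True)
                )
            else:
                name, seq = r
                recs.append(SequenceRecord(name, seq, aligned=True))
        if not recs:
            raise FormatError("alignment needs at least one row")
        lengths = {len(r) for r in recs}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment: row lengths {sorted(lengths)}")
        names = [r.id for r in recs]
        if len(set(names)) != len(names):
            raise FormatError("duplicate row names in alignment")
        self.names: list[str] = names
        self.matrix: np.ndarray = np.frombuffer(
            "".join(r.sequence for r in recs).encode("ascii"), dtype="S1"
        ).reshape(len(recs), -1)

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]

    def row(self, name_or_index: str | int) -> str:
        i = (
            name_or_index
            if isinstance(name_or_index, int)
            else self.names.index(name_or_index)
        )
        return self.matrix[i].tobytes().decode("ascii")

    def records(self) -> Iterator[SequenceRecord]:
        for name in self.names:
            yield SequenceRecord(name, self.row(name), aligned=True)

    def window(self, start: int, end: int) -> "Alignment":
        sub = Alignment.__new__(Alignment)
        sub.names = list(self.names)
        sub.matrix = self.matrix[:, start:end]
        return sub

    def subset(self, names: Sequence[str]) -> "Alignment":
        missing = [n for n in names if n not in self.names]
        if missing:
            raise KeyError(f"taxa not in alignment: {missing}")
        idx = [self.names.index(n) for n in names]
        sub = Alignment.__new__(Alignment)
        sub.names = list(names)
        sub.matrix = self.matrix[idx]
        return sub

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Alignment)
            and self.names == other.names
            and self.matrix.shape == other.matrix.shape
            and bool((self.matrix == other.matrix).all())
        )
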