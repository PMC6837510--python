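"""Majority-threshold consensus over multiple assemblies of one mitogenome.

Per-coverage assemblies of the same genome are aligned; each column is
resolved to the nucleotide reaching a representation threshold (default
60%), computed over *all* rows so that masked (N) or gapped rows count
against resolution.  Gaps can neither win a column nor appear in the
consensus: a column where no nucleotide reaches the threshold yields 'N',
and a column of only gaps/N is dropped.  A threshold above 0.5 makes the
winner unique whenever one exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import Alignment, FormatError, SequenceRecord

_NUCS = (b"A", b"C", b"G", b"T")
DROP = "drop"


@dataclass(frozen=True)
class ConsensusParams:
    threshold: float = 0.60
    min_rows: int = 2

    def __post_init__(self) -> None:
        if not (0.5 < self.threshold <= 1.0):
            raise FormatError(
                f"threshold must be in (0.5, 1], got {self.threshold} "
                "(<= 0.5 would allow ties)"
            )
        if self.min_rows < 2:
            raise FormatError(f"min_rows must be >= 2, got {self.min_rows}")


@dataclass
class ColumnCall:
    column: int
    symbol: str            # A/C/G/T, 'N', or DROP
    winning_fraction: float
    n_informative: int     # rows carrying a real nucleotide


@dataclass
class ConsensusReport:
    consensus: SequenceRecord
    columns: list[ColumnCall] = field(default_factory=list)
    resolved: int = 0
    set_to_n: int = 0
    dropped: int = 0

    @property
    def alignment_length(self) -> int:
        return self.resolved + self.set_to_n + self.dropped


def consensus_column(symbols: Sequence[str], params: ConsensusParams = ConsensusParams()) -> str:
    """Resolve one alignment column to a symbol, 'N', or the drop marker.

    Fractions are computed over all rows (N and '-' count in the
    denominator); only A/C/G/T can win.
    """
    if len(symbols) < params.min_rows:
        raise FormatError(
            f"column has {len(symbols)} rows, need >= {params.min_rows}"
        )
    symbols = [s.upper() for s in symbols]
    bad = [s for s in symbols if s not in "ACGTN-"]
    if bad:
        raise FormatError(f"invalid column symbols: {bad}")
    n = len(symbols)
    informative = [s for s in symbols if s in "ACGT"]
    if not informative:
        return DROP
    best, best_count = None, 0
    for nuc in "ACGT":
        c = symbols.count(nuc)
        if c > best_count:
            best, best_count = nuc, c
    if best_count / n >= params.threshold:
        return best
    return "N"


def build_consensus(
    alignment: Alignment,
    params: ConsensusParams = ConsensusParams(),
    *,
    name: str = "consensus",
) -> ConsensusReport:
    """Apply :func:`consensus_column` to every column, left to right."""
    if alignment.n_rows < params.min_rows:
        raise FormatError(
            f"alignment has {alignment.n_rows} rows, need >= {params.min_rows}"
        )
    m = alignment.matrix
    n_rows = alignment.n_rows
    calls: list[ColumnCall] = []
    out: list[str] = []
    resolved = set_to_n = dropped = 0
    counts = {nuc: (m == nuc).sum(axis=0) for nuc in _NUCS}
    count_mat = np.vstack([counts[nuc] for nuc in _NUCS])  # 4 x L
    informative = count_mat.sum(axis=0)
    winner_idx = count_mat.argmax(axis=0)
    winner_count = count_mat.max(axis=0)
    for c in range(alignment.n_cols):
        if informative[c] == 0:
            calls.append(ColumnCall(c, DROP, 0.0, 0))
            dropped += 1
            continue
        frac = winner_count[c] / n_rows
        if frac >= params.threshold:
            sym = _NUCS[winner_idx[c]].decode("ascii")
            out.append(sym)
            resolved += 1
        else:
            sym = "N"
            out.append("N")
            set_to_n += 1
        calls.append(ColumnCall(c, sym, float(frac), int(informative[c])))
    if not out:
        raise FormatError("every column dropped: no consensus sequence")
    return ConsensusReport(
        consensus=SequenceRecord(name, "".join(out)),
        columns=calls,
        resolved=resolved,
        set_to_n=set_to_n,
        dropped=dropped,
    )
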