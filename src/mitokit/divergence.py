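"""Pairwise and group-mean p-distances, sliding-window divergence profiles
and alignment site classification.

The p-distance is the proportion of differing nucleotides among compared
positions, with pairwise deletion: for each sequence pair only the positions
where either member carries N or '-' are excluded.  Group means average the
per-pair p over all C(n,2) pairs, each pair keeping its own denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import Alignment, FormatError

_MISSING = (b"N", b"-")


@dataclass(frozen=True)
class DivergenceEstimate:
    """A p-distance with its raw counts."""

    label: str
    p: float
    differences: float
    sites_compared: float


@dataclass(frozen=True)
class WindowProfileParams:
    """Sliding-window geometry: consecutive windows share ``overlap`` bp,
    so the step is ``window - overlap`` (500/100 -> step 400 by default).
    ``slide_by_overlap=True`` selects the alternative reading in which the
    window advances by ``overlap`` bp each step."""

    window: int = 500
    overlap: int = 100
    slide_by_overlap: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.overlap < self.window):
            raise FormatError(
                f"need 0 <= overlap < window, got overlap={self.overlap} "
                f"window={self.window}"
            )

    @property
    def step(self) -> int:
        return self.overlap if self.slide_by_overlap else self.window - self.overlap


@dataclass(frozen=True)
class WindowEstimate:
    start: int
    end: int
    group: str
    p: float
    sites_compared: float


@dataclass(frozen=True)
class SiteClassCounts:
    """Column classification of an alignment.

    Columns containing any gap or N are 'unclassified'; the remainder are
    conserved (one state), parsimony-informative (>=2 states each in >=2
    rows), singleton (exactly one row differs from a single shared state),
    or other-variable.
    """

    total: int
    conserved: int
    parsimony_informative: int
    singleton: int
    other_variable: int
    unclassified: int

    def __post_init__(self) -> None:
        parts = (
            self.conserved
            + self.parsimony_informative
            + self.singleton
            + self.other_variable
            + self.unclassified
        )
        if parts != self.total:
            raise ValueError(f"site classes sum to {parts}, expected {self.total}")


def _row_bytes(row: str | np.ndarray) -> np.ndarray:
    if isinstance(row, np.ndarray):
        return row
    return np.frombuffer(str(row).encode("ascii"), dtype="S1")


def p_distance(row_a: str | np.ndarray, row_b: str | np.ndarray, *, label: str = "") -> DivergenceEstimate:
    """p-distance between two equal-length rows under pairwise deletion."""
    a, b = _row_bytes(row_a), _row_bytes(row_b)
    if a.shape != b.shape:
        raise FormatError(f"rows differ in length: {a.size} vs {b.size}")
    ok = ~(np.isin(a, _MISSING) | np.isin(b, _MISSING))
    sites = int(ok.sum())
    if sites == 0:
        raise FormatError(
            f"no comparable sites between rows{' ' + label if label else ''}"
        )
    diffs = int((a[ok] != b[ok]).sum())
    return DivergenceEstimate(label, diffs / sites, diffs, sites)


def group_mean_p(alignment: Alignment, taxa: Sequence[str] | None = None, *, label: str = "") -> DivergenceEstimate:
    """Mean pairwise p over all C(n,2) pairs of ``taxa`` (default: all rows).

    Each pair keeps its own pairwise-deletion denominator; the reported
    differences and sites_compared are per-pair means.
    """
    names = list(taxa) if taxa is not None else list(alignment.names)
    if len(names) < 2:
        raise FormatError("group mean p-distance needs at least 2 taxa")
    sub = alignment.subset(names)
    ps, diffs, sites = [], [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            try:
                est = p_distance(sub.matrix[i], sub.matrix[j])
            except FormatError as exc:
                raise FormatError(
                    f"pair ({names[i]}, {names[j]}): {exc}"
                ) from exc
            ps.append(est.p)
            diffs.append(est.differences)
            sites.append(est.sites_compared)
    n = len(ps)
    return DivergenceEstimate(
        label or "+".join(names),
        sum(ps) / n,
        sum(diffs) / n,
        sum(sites) / n,
    )


def window_spans(length: int, params: WindowProfileParams) -> list[tuple[int, int]]:
    """Window start/end spans: full windows every ``step`` bp from 0, plus a
    final truncated window iff its length is at least window/2."""
    if length < params.window:
        raise FormatError(
            f"alignment length {length} shorter than window {params.window}"
        )
    spans: list[tuple[int, int]] = []
    start = 0
    while start + params.window <= length:
        spans.append((start, start + params.window))
        start += params.step
    if start < length and (length - start) >= params.window / 2:
        spans.append((start, length))
    return spans


def window_profile(
    alignment: Alignment,
    groups: Mapping[str, Sequence[str]] | None = None,
    params: WindowProfileParams = WindowProfileParams(),
) -> list[WindowEstimate]:
    """Windowed group-mean p-distance profiles over identical windows.

    ``groups`` maps a profile label to its taxa; by default one profile
    ("all") over every row.  A window where some pair has no comparable
    sites reports NaN for that group.
    """
    if groups is None:
        groups = {"all": list(alignment.names)}
    out: list[WindowEstimate] = []
    for start, end in window_spans(alignment.n_cols, params):
        win = alignment.window(start, end)
        for label, taxa in groups.items():
            try:
                est = group_mean_p(win, list(taxa))
                out.append(WindowEstimate(start, end, label, est.p, est.sites_compared))
            except FormatError:
                out.append(WindowEstimate(start, end, label, float("nan"), 0))
    return out


def pairwise_matrix(alignment: Alignment):
    """Symmetric matrix of pairwise p-distances as a pandas DataFrame."""
    import pandas as pd

    if alignment.n_rows < 2:
        raise FormatError("pairwise matrix needs at least 2 rows")
    n = alignment.n_rows
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            est = p_distance(
                alignment.matrix[i],
                alignment.matrix[j],
                label=f"{alignment.names[i]}-{alignment.names[j]}",
            )
            mat[i, j] = mat[j, i] = est.p
    return pd.DataFrame(mat, index=alignment.names, columns=alignment.names)


def classify_sites(alignment: Alignment) -> SiteClassCounts:
    """Classify every alignment column; needs >= 4 rows for
    parsimony-informativeness to be meaningful."""
    if alignment.n_rows < 4:
        raise FormatError(
            f"site classification needs >= 4 rows, got {alignment.n_rows}"
        )
    m = alignment.matrix
    total = m.shape[1]
    has_missing = np.isin(m, _MISSING).any(axis=0)
    conserved = informative = singleton = other = 0
    unclassified = int(has_missing.sum())
    for c in np.nonzero(~has_missing)[0]:
        col = m[:, c]
        states, counts = np.unique(col, return_counts=True)
        if len(states) == 1:
            conserved += 1
        elif (counts >= 2).sum() >= 2:
            informative += 1
        elif len(states) == 2 and counts.min() == 1:
            singleton += 1
        else:
            other += 1
    return SiteClassCounts(
        total=total,
        conserved=conserved,
        parsimony_informative=informative,
        singleton=singleton,
        other_variable=other,
        unclassified=unclassified,
    )
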