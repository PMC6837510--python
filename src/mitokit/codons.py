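"""Genetic-code services, codon degeneracy, four-fold-site extraction and
Nei–Gojobori (1986) counting of synonymous and non-synonymous substitutions.

The default genetic code is NCBI translation table 5 (invertebrate
mitochondrial): ATA encodes Met, TGA encodes Trp, and AGA/AGG encode Ser,
leaving TAA/TAG as the only stops.  The NG86 estimator counts potential
synonymous (S) and non-synonymous (N) sites per codon, averages observed
differences over all minimal mutational pathways between differing codons
(pathways through stop codons excluded), and applies the Jukes–Cantor
correction d = -(3/4)·ln(1 - (4/3)p) to the resulting proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

from Bio.Data import CodonTable

from .core import Alignment, FormatError

_BASES = "ACGT"


def jc_correct(p: float) -> float:
    """Jukes–Cantor multiple-hit correction d = -(3/4)·ln(1 - (4/3)p).

    Defined for p in [0, 0.75); p at or beyond 3/4 is saturated.
    """
    if p < 0:
        raise ValueError(f"proportion must be non-negative, got {p}")
    if p >= 0.75:
        raise ValueError(f"p = {p} is saturated (>= 3/4): JC correction undefined")
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


class GeneticCode:
    """A 64-codon translation table with an explicit stop set."""

    def __init__(self, table_id: int = 5):
        table = CodonTable.unambiguous_dna_by_id[table_id]
        self.table_id = table_id
        self.name = table.names[0]
        self._aa: dict[str, str] = dict(table.forward_table)
        for stop in table.stop_codons:
            self._aa[stop] = "*"
        self.stop_codons = frozenset(table.stop_codons)
        if len(self._aa) != 64:
            raise ValueError(f"incomplete codon table {table_id}")

    def amino_acid(self, codon: str) -> str:
        """One-letter amino acid for a codon; '*' for stop, 'X' if ambiguous."""
        codon = codon.upper()
        if any(b not in _BASES for b in codon) or len(codon) != 3:
            return "X"
        return self._aa[codon]

    def is_stop(self, codon: str) -> bool:
        return codon.upper() in self.stop_codons

    def __repr__(self) -> str:
        return f"GeneticCode(table_id={self.table_id})"


#: invertebrate mitochondrial code, the toolkit-wide default
INVERTEBRATE_MITO = GeneticCode(5)
STANDARD_CODE = GeneticCode(1)


def translate(cds: str, code: GeneticCode = INVERTEBRATE_MITO) -> str:
    """Translate an in-frame coding sequence; stops render '*', ambiguous
    codons (containing N or '-') render 'X'."""
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise FormatError(f"coding sequence length {len(cds)} not divisible by 3")
    return "".join(code.amino_acid(cds[i : i + 3]) for i in range(0, len(cds), 3))


def degeneracy_class(
    codon: str, position: int, code: GeneticCode = INVERTEBRATE_MITO
) -> int:
    """Number of nucleotides at ``position`` (1-based, others held fixed)
    yielding the same amino acid as the codon itself — 1, 2, 3 or 4."""
    codon = codon.upper()
    if position not in (1, 2, 3):
        raise ValueError(f"codon position must be 1, 2 or 3, got {position}")
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise FormatError(f"cannot classify degeneracy of codon {codon!r}")
    aa = code.amino_acid(codon)
    i = position - 1
    return sum(
        1
        for b in _BASES
        if code.amino_acid(codon[:i] + b + codon[i + 1 :]) == aa
    )


def extract_fourfold(
    alignment: Alignment, code: GeneticCode = INVERTEBRATE_MITO
) -> Alignment:
    """Extract third-codon-position columns that are four-fold degenerate in
    every taxon.

    A column is kept iff, at that codon, every row (i) is free of N/'-',
    (ii) has degeneracy 4 at the third position, and (iii) all rows agree at
    the first two codon positions.  Extraction is conservative on purpose:
    sites kept are putatively neutral in all taxa simultaneously.
    """
    if alignment.n_cols % 3 != 0:
        raise FormatError(
            f"alignment length {alignment.n_cols} not divisible by 3"
        )
    rows = [alignment.row(i) for i in range(alignment.n_rows)]
    kept: list[int] = []
    for c in range(0, alignment.n_cols, 3):
        codons = [r[c : c + 3] for r in rows]
        if any(ch not in _BASES for cod in codons for ch in cod):
            continue
        if any(cod[:2] != codons[0][:2] for cod in codons[1:]):
            continue
        if all(degeneracy_class(cod, 3, code) == 4 for cod in codons):
            kept.append(c + 2)
    sub = Alignment.__new__(Alignment)
    sub.names = list(alignment.names)
    sub.matrix = alignment.matrix[:, kept]
    return sub


# ---------------------------------------------------------------------------
# Nei–Gojobori counting
# ---------------------------------------------------------------------------

@dataclass
class DnDsEstimate:
    """Per-gene (or per-pair) NG86 estimate of dN, dS and their ratio."""

    gene: str
    dN: float
    dS: float
    pN: float
    pS: float
    S: float
    N: float
    Sd: float
    Nd: float
    codons_compared: int
    skipped_codons: int = 0
    saturated: bool = False
    pairs_used: int = 1
    pairs_excluded_saturated: int = 0

    @property
    def omega(self) -> float:
        """dN/dS; NaN when dS is zero or saturated."""
        if self.saturated or self.dS != self.dS or self.dS == 0.0:
            return float("nan")
        return self.dN / self.dS


def _potential_sites(codon: str, code: GeneticCode) -> float:
    """NG86 potential synonymous sites in one codon: at each position the
    fraction of the three possible changes that are synonymous (changes to
    or from stop codons are never synonymous)."""
    aa = code.amino_acid(codon)
    s = 0.0
    for i in range(3):
        for b in _BASES:
            if b == codon[i]:
                continue
            mutant = codon[:i] + b + codon[i + 1 :]
            if code.amino_acid(mutant) == aa and not code.is_stop(mutant):
                s += 1.0 / 3.0
    return s


def _pathway_counts(
    codon_a: str, codon_b: str, code: GeneticCode
) -> tuple[float, float] | None:
    """Average (synonymous, non-synonymous) difference counts over all
    minimal mutational pathways between two codons, excluding pathways that
    pass through a stop codon.  Returns None if no stop-free pathway exists.
    """
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return (0.0, 0.0)
    syn_total = 0.0
    non_total = 0.0
    n_paths = 0
    for order in permutations(diff_positions):
        current = codon_a
        steps: list[tuple[str, str]] = []
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if code.is_stop(nxt) and nxt != codon_b:
                blocked = True
                break
            steps.append((current, nxt))
            current = nxt
        if blocked:
            continue
        n_paths += 1
        for before, after in steps:
            if code.amino_acid(before) == code.amino_acid(after):
                syn_total += 1.0
            else:
                non_total += 1.0
    if n_paths == 0:
        return None
    return syn_total / n_paths, non_total / n_paths


def ng86_pair(
    cds_a: str,
    cds_b: str,
    code: GeneticCode = INVERTEBRATE_MITO,
    *,
    gene: str = "",
) -> DnDsEstimate:
    """Nei–Gojobori dN/dS between two in-frame coding sequences.

    Codons containing N or '-' in either sequence are skipped pairwise, as
    are stop codons and codon pairs whose every minimal pathway crosses a
    stop.  ``saturated`` is set (and the corresponding distance is NaN) when
    pS or pN reaches the Jukes–Cantor domain bound of 3/4.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) != len(cds_b):
        raise FormatError(
            f"coding sequences differ in length: {len(cds_a)} vs {len(cds_b)}"
        )
    if len(cds_a) % 3 != 0:
        raise FormatError(f"length {len(cds_a)} not divisible by 3")
    S_a = S_b = 0.0
    Sd = Nd = 0.0
    compared = skipped = 0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        if any(ch not in _BASES for ch in ca + cb):
            skipped += 1
            continue
        if code.is_stop(ca) or code.is_stop(cb):
            skipped += 1
            continue
        counts = _pathway_counts(ca, cb, code)
        if counts is None:
            skipped += 1
            continue
        compared += 1
        S_a += _potential_sites(ca, code)
        S_b += _potential_sites(cb, code)
        Sd += counts[0]
        Nd += counts[1]
    if compared == 0:
        raise FormatError("no comparable codons between the two sequences")
    S = 0.5 * (S_a + S_b)
    N = 3.0 * compared - S
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    saturated = pS >= 0.75 or pN >= 0.75
    dS = float("nan") if pS >= 0.75 else jc_correct(pS)
    dN = float("nan") if pN >= 0.75 else jc_correct(pN)
    return DnDsEstimate(
        gene=gene,
        dN=dN,
        dS=dS,
        pN=pN,
        pS=pS,
        S=S,
        N=N,
        Sd=Sd,
        Nd=Nd,
        codons_compared=compared,
        skipped_codons=skipped,
        saturated=saturated,
    )


def gene_dnds(
    alignment: Alignment,
    code: GeneticCode = INVERTEBRATE_MITO,
    *,
    gene: str = "",
) -> DnDsEstimate:
    """Group NG86 estimate for one gene: the mean over all pairwise
    estimates, with ω taken as mean dN / mean dS.

    Pairs with saturated dS are excluded from the mean; the exclusion count
    is reported.  All pairs saturated is an error.
    """
    if alignment.n_rows < 2:
        raise FormatError("gene alignment needs at least 2 taxa")
    pair_estimates: list[DnDsEstimate] = []
    excluded = 0
    for i in range(alignment.n_rows):
        for j in range(i + 1, alignment.n_rows):
            est = ng86_pair(alignment.row(i), alignment.row(j), code, gene=gene)
            if est.saturated:
                excluded += 1
            else:
                pair_estimates.append(est)
    if not pair_estimates:
        raise FormatError(
            f"all {excluded} pairwise comparisons for {gene or 'gene'} are "
            "saturated (pS or pN >= 3/4); dN/dS undefined"
        )
    k = len(pair_estimates)

    def mean(attr: str) -> float:
        return sum(getattr(e, attr) for e in pair_estimates) / k

    return DnDsEstimate(
        gene=gene,
        dN=mean("dN"),
        dS=mean("dS"),
        pN=mean("pN"),
        pS=mean("pS"),
        S=mean("S"),
        N=mean("N"),
        Sd=mean("Sd"),
        Nd=mean("Nd"),
        codons_compared=round(mean("codons_compared")),
        skipped_codons=round(mean("skipped_codons")),
        saturated=False,
        pairs_used=k,
        pairs_excluded_saturated=excluded,
    )
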