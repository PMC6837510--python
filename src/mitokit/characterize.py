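"""Composition summaries and codon-usage statistics for annotated
mitogenomes.

Covers the three descriptive layers routinely tabulated for new mitogenome
assemblies: whole-genome element composition (GC%, N%, and the share of the
genome covered by PCGs, tRNAs, rRNAs and intergenic spacers), base
composition of the concatenated protein-coding genes on the coding strand,
and per-gene codon usage with RSCU and an explicit codon-usage bias index.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .codons import INVERTEBRATE_MITO, GeneticCode
from .core import AnnotatedMitogenome, FormatError


@dataclass(frozen=True)
class CompositionSummary:
    """Element composition of one genome, percentages of total length
    rounded to 2 decimals."""

    total_length: int
    gc_percent: float
    n_percent: float
    intergenic_percent: float
    trna_percent: float
    pcg_percent: float
    rrna_percent: float


def composition_summary(genome: AnnotatedMitogenome) -> CompositionSummary:
    """Table of element composition.

    Element percentages come from annotated spans; a position covered by
    two overlapping genes counts toward each class once.  Intergenic is
    everything covered by no gene feature and not control region.
    """
    if not genome.features:
        raise FormatError(f"genome {genome.id} has no annotations")
    n = len(genome)
    seq = np.frombuffer(genome.sequence.encode("ascii"), dtype="S1")
    gc = int(np.isin(seq, (b"G", b"C")).sum())
    ncount = int((seq == b"N").sum())
    masks = {k: np.zeros(n, dtype=bool) for k in ("PCG", "tRNA", "rRNA", "control")}
    covered = np.zeros(n, dtype=bool)
    for f in genome.features:
        masks[f.kind][f.start : f.end] = True
        covered[f.start : f.end] = True
    intergenic = int((~covered).sum())

    def pct(x: int) -> float:
        return round(100.0 * x / n, 2)

    return CompositionSummary(
        total_length=n,
        gc_percent=pct(gc),
        n_percent=pct(ncount),
        intergenic_percent=pct(intergenic),
        trna_percent=pct(int(masks["tRNA"].sum())),
        pcg_percent=pct(int(masks["PCG"].sum())),
        rrna_percent=pct(int(masks["rRNA"].sum())),
    )


def pcg_base_composition(
    genomes: AnnotatedMitogenome | list[AnnotatedMitogenome],
) -> dict[str, float]:
    """Base percentages over concatenated PCGs, coding-strand oriented
    (light-strand genes reverse-complemented first).  N excluded from the
    denominator; A+C+G+T sum to 100."""
    if isinstance(genomes, AnnotatedMitogenome):
        genomes = [genomes]
    counts = Counter()
    for g in genomes:
        pcgs = g.features_of_kind("PCG")
        if not pcgs:
            raise FormatError(f"genome {g.id} has no PCG annotations")
        for f in pcgs:
            counts.update(g.gene_sequence(f))
    total = sum(counts[b] for b in "ACGT")
    if total == 0:
        raise FormatError("no unambiguous PCG nucleotides")
    return {b: 100.0 * counts[b] / total for b in "ACGT"}


@dataclass
class GeneCodonUsage:
    gene: str
    counts: dict[str, int]
    rscu: dict[str, float]
    bias: float
    skipped_codons: int = 0

    def top_codons(self, n: int = 3) -> list[str]:
        """Most frequent codons, count-descending, alphabetical tie-break."""
        return [
            c for c, _ in sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ][:n]


@dataclass
class CodonUsageTable:
    per_gene: dict[str, GeneCodonUsage] = field(default_factory=dict)
    pooled: GeneCodonUsage | None = None


def _families(code: GeneticCode) -> dict[str, list[str]]:
    """Synonymous codon families (stops excluded), keyed by amino acid."""
    fams: dict[str, list[str]] = {}
    for b1 in "TCAG":
        for b2 in "TCAG":
            for b3 in "TCAG":
                codon = b1 + b2 + b3
                aa = code.amino_acid(codon)
                if aa == "*":
                    continue
                fams.setdefault(aa, []).append(codon)
    return fams


def _usage_stats(
    gene: str, counts: Counter, code: GeneticCode, skipped: int
) -> GeneCodonUsage:
    fams = _families(code)
    total = sum(counts.values())
    rscu: dict[str, float] = {}
    bias = 0.0
    for aa, family in fams.items():
        fam_total = sum(counts[c] for c in family)
        k = len(family)
        if fam_total == 0:
            continue
        for c in family:
            rscu[c] = counts[c] / (fam_total / k)
        if k > 1:
            share = fam_total / total
            dev = sum(abs(counts[c] / fam_total - 1.0 / k) for c in family)
            bias += share * dev / (2.0 * (1.0 - 1.0 / k))
    return GeneCodonUsage(
        gene=gene,
        counts={c: counts[c] for c in sorted(counts)},
        rscu=rscu,
        bias=bias,
        skipped_codons=skipped,
    )


def _count_codons(
    gene: str, cds: str, code: GeneticCode
) -> tuple[Counter, int]:
    if len(cds) % 3 != 0:
        # tolerate an abbreviated terminal stop (completed by
        # polyadenylation in vivo) by trimming 1-2 trailing nt
        trim = len(cds) % 3
        warnings.warn(
            f"gene {gene}: trimming {trim} trailing nt (abbreviated stop)",
            stacklevel=3,
        )
        cds = cds[: len(cds) - trim]
    counts: Counter = Counter()
    skipped = 0
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and code.is_stop(codons[-1]):
        codons = codons[:-1]  # terminal stop excluded from usage
    for codon in codons:
        if any(ch not in "ACGT" for ch in codon):
            skipped += 1
        elif code.is_stop(codon):
            skipped += 1  # internal stop: never counted as usage
        else:
            counts[codon] += 1
    return counts, skipped


def codon_usage(
    genes: dict[str, str],
    code: GeneticCode = INVERTEBRATE_MITO,
    *,
    strict_frame: bool = True,
) -> CodonUsageTable:
    """Codon usage per gene and pooled, from coding-strand sequences.

    RSCU(c) = observed(c) / (family total / family size).  The bias index
    B in [0,1] is the usage-share-weighted mean absolute deviation of
    within-family frequencies from uniform, normalized so B=0 iff every used
    family is uniform and B=1 iff every family uses a single codon.
    Codons containing N/'-' are skipped and tallied.
    """
    if not genes:
        raise FormatError("no genes given")
    table = CodonUsageTable()
    pooled: Counter = Counter()
    pooled_skipped = 0
    for gene, cds in genes.items():
        if strict_frame and len(cds) % 3 != 0:
            raise FormatError(
                f"gene {gene}: length {len(cds)} not divisible by 3"
            )
        counts, skipped = _count_codons(gene, cds.upper(), code)
        table.per_gene[gene] = _usage_stats(gene, counts, code, skipped)
        pooled.update(counts)
        pooled_skipped += skipped
    table.pooled = _usage_stats("pooled", pooled, code, pooled_skipped)
    return table


def to_rna(codon: str) -> str:
    """Display helper: DNA codon -> RNA codon (TTA -> UUA)."""
    return codon.replace("T", "U")
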