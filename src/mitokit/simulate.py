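"""Synthetic mitogenome clades: build an annotated AT-rich ancestor, evolve
it along a dated tree under a strict clock with per-gene purifying
selection, and emit noisy per-coverage assembly replicates.

The generator emulates the organisation of cactophilic *Drosophila*
mitogenomes: a ~14.9 kb circular genome (stored linearized at the
control-region start) carrying 37 genes — 13 protein-coding genes, 22
tRNAs and 2 rRNAs, 23 features on the heavy (+) strand and 14 on the light
(-) strand — at ~76.5% A+T.  Substitutions are proposed per site under
Jukes–Cantor with probability p = (3/4)(1 - exp(-(4/3) d)) for a branch of
neutral expected divergence d = rate x duration; inside PCGs, proposals
that change the encoded amino acid are accepted with probability
omega(gene), silent changes are always accepted, and changes creating
internal stop codons are rejected.  Selection is therefore pure
omega-thinning of non-synonymous proposals, which keeps the closed-form JC
oracle exact at four-fold degenerate sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .codons import INVERTEBRATE_MITO, GeneticCode
from .core import (
    AnnotatedMitogenome,
    FeatureRecord,
    FormatError,
    SequenceRecord,
    revcomp,
)
from .dating import Chronogram
from . import io as mio

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_BASE_INDEX = {b"A": 0, b"C": 1, b"G": 2, b"T": 3}

#: default chronogram (ages in years): ingroup crown 2.11 Myr,
#: buzzatii/koepferae split 1.5 Myr, koepferae strains 0.31 Myr,
#: borborema/seriema 0.05 Myr, antonietae clade 0.95 Myr, outgroup 10.63 Myr.
DEFAULT_CHRONOGRAM_NEWICK = (
    "(Dmoj:10630000,"
    "((Dbuz:1500000,(DkoeA:310000,DkoeB:310000):1190000):610000,"
    "(Dato:950000,(Dbrb:50000,Dsei:50000):900000):1160000):8520000);"
)

#: ingroup-only variant (6 tips, crown 2.11 Myr)
INGROUP_CHRONOGRAM_NEWICK = (
    "((Dbuz:1500000,(DkoeA:310000,DkoeB:310000):1190000):610000,"
    "(Dato:950000,(Dbrb:50000,Dsei:50000):900000):1160000);"
)

#: per-gene dN/dS under purifying selection (buzzatii-cluster-like defaults)
DEFAULT_OMEGA = {
    "ATP6": 0.005,
    "ATP8": 0.060,
    "CytB": 0.005,
    "COI": 0.003,
    "COII": 0.005,
    "COIII": 0.006,
    "ND1": 0.003,
    "ND2": 0.036,
    "ND3": 0.009,
    "ND4L": 0.008,
    "ND4": 0.011,
    "ND5": 0.007,
    "ND6": 0.012,
}

#: (name, kind, length, strand) in mitogenome order, control region first
#: (the genome is linearized at the control-region start); gene order and
#: strand assignment follow the conserved Drosophila arrangement.
DEFAULT_ARCHITECTURE: tuple[tuple[str, str, int, str], ...] = (
    ("control_region", "control", 120, "+"),
    ("trnI", "tRNA", 66, "+"),
    ("trnQ", "tRNA", 66, "-"),
    ("trnM", "tRNA", 66, "+"),
    ("ND2", "PCG", 1005, "+"),
    ("trnW", "tRNA", 66, "+"),
    ("trnC", "tRNA", 66, "-"),
    ("trnY", "tRNA", 66, "-"),
    ("COI", "PCG", 1500, "+"),
    ("trnL2", "tRNA", 66, "+"),
    ("COII", "PCG", 687, "+"),
    ("trnK", "tRNA", 66, "+"),
    ("trnD", "tRNA", 66, "+"),
    ("ATP8", "PCG", 162, "+"),
    ("ATP6", "PCG", 678, "+"),
    ("COIII", "PCG", 789, "+"),
    ("trnG", "tRNA", 66, "+"),
    ("ND3", "PCG", 354, "+"),
    ("trnA", "tRNA", 66, "+"),
    ("trnR", "tRNA", 66, "+"),
    ("trnN", "tRNA", 66, "+"),
    ("trnS1", "tRNA", 66, "+"),
    ("trnE", "tRNA", 66, "+"),
    ("trnF", "tRNA", 66, "-"),
    ("ND5", "PCG", 1665, "-"),
    ("trnH", "tRNA", 66, "-"),
    ("ND4", "PCG", 1320, "-"),
    ("ND4L", "PCG", 294, "-"),
    ("trnT", "tRNA", 66, "+"),
    ("trnP", "tRNA", 66, "-"),
    ("ND6", "PCG", 525, "+"),
    ("CytB", "PCG", 1125, "+"),
    ("trnS2", "tRNA", 66, "+"),
    ("ND1", "PCG", 939, "-"),
    ("trnL1", "tRNA", 66, "-"),
    ("rrnL", "rRNA", 1326, "-"),
    ("trnV", "tRNA", 66, "-"),
    ("rrnS", "rRNA", 789, "-"),
)

#: short intergenic spacers inserted after these genes (bp); totals 160
DEFAULT_SPACERS: dict[str, int] = {
    "trnQ": 20,
    "trnY": 20,
    "trnK": 20,
    "trnE": 20,
    "trnH": 20,
    "trnT": 20,
    "CytB": 20,
    "trnL1": 20,
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the clade simulator; defaults are the study conditions."""

    seed: int = 0
    genome_length_target: int = 14900
    at_fraction: float = 0.765
    gene_architecture: tuple[tuple[str, str, int, str], ...] = DEFAULT_ARCHITECTURE
    spacers: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SPACERS))
    clock_rate_per_year: float = 6.2e-7
    omega_per_gene: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OMEGA)
    )
    codon_position_rate_multipliers: tuple[float, float, float] = (1.0, 1.0, 1.0)
    code: GeneticCode = INVERTEBRATE_MITO

    def __post_init__(self) -> None:
        if not (0.0 < self.at_fraction < 1.0):
            raise FormatError(f"at_fraction must be in (0,1), got {self.at_fraction}")
        counts = {"PCG": 0, "tRNA": 0, "rRNA": 0, "control": 0}
        strands = {"+": 0, "-": 0}
        for name, kind, length, strand in self.gene_architecture:
            if kind not in counts:
                raise FormatError(f"unknown kind {kind!r} for {name}")
            counts[kind] += 1
            if kind != "control":
                strands[strand] += 1
            if kind == "PCG" and length % 3 != 0:
                raise FormatError(f"PCG {name} length {length} not divisible by 3")
        if (counts["PCG"], counts["tRNA"], counts["rRNA"], counts["control"]) != (
            13,
            22,
            2,
            1,
        ):
            raise FormatError(
                f"architecture must carry 13 PCG + 22 tRNA + 2 rRNA + 1 control, "
                f"got {counts}"
            )
        if (strands["+"], strands["-"]) != (23, 14):
            raise FormatError(
                f"architecture must place 23 genes on '+' and 14 on '-', "
                f"got {strands}"
            )
        for gene, w in self.omega_per_gene.items():
            if not (0.0 <= w <= 1.0):
                raise FormatError(f"omega for {gene} must be in [0,1], got {w}")
        total = sum(l for _, _, l, _ in self.gene_architecture) + sum(
            self.spacers.values()
        )
        if total > 1.01 * self.genome_length_target:
            raise FormatError(
                f"architecture total {total} bp exceeds genome_length_target "
                f"{self.genome_length_target} by more than 1%"
            )
        if abs(total - self.genome_length_target) > 0.01 * self.genome_length_target:
            raise FormatError(
                f"architecture total {total} bp more than 1% away from target "
                f"{self.genome_length_target}"
            )
        if len(self.codon_position_rate_multipliers) != 3 or any(
            m < 0 for m in self.codon_position_rate_multipliers
        ):
            raise FormatError("codon_position_rate_multipliers: three reals >= 0")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated clade."""

    chronogram: Chronogram
    omega_per_gene: dict[str, float]
    seed: int
    substitutions_per_branch: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# ancestor construction
# ---------------------------------------------------------------------------

def _base_probs(at_fraction: float) -> np.ndarray:
    return np.array(
        [
            at_fraction / 2,       # A
            (1 - at_fraction) / 2, # C
            (1 - at_fraction) / 2, # G
            at_fraction / 2,       # T
        ]
    )


def _random_bases(rng: np.random.Generator, n: int, probs: np.ndarray) -> str:
    idx = rng.choice(4, size=n, p=probs)
    return _BASES[idx].tobytes().decode("ascii")


def _random_orf(
    rng: np.random.Generator, n_codons: int, probs: np.ndarray, code: GeneticCode
) -> str:
    """ATG start, stop-free interior codons sampled with per-base AT bias,
    complete TAA terminal stop."""
    codons = [
        b1 + b2 + b3
        for b1 in "ACGT"
        for b2 in "ACGT"
        for b3 in "ACGT"
        if not code.is_stop(b1 + b2 + b3)
    ]
    base_p = {b: probs[_BASE_INDEX[b.encode()]] for b in "ACGT"}
    weights = np.array([base_p[c[0]] * base_p[c[1]] * base_p[c[2]] for c in codons])
    weights /= weights.sum()
    interior = rng.choice(len(codons), size=n_codons - 2, p=weights)
    return "ATG" + "".join(codons[i] for i in interior) + "TAA"


def build_ancestor(config: SimulationConfig) -> AnnotatedMitogenome:
    """Deterministically (per seed) generate the annotated ancestral genome."""
    rng = np.random.default_rng([config.seed, 0])
    probs = _base_probs(config.at_fraction)
    parts: list[str] = []
    features: list[FeatureRecord] = []
    pos = 0
    for name, kind, length, strand in config.gene_architecture:
        if kind == "PCG":
            cds = _random_orf(rng, length // 3, probs, config.code)
            seg = revcomp(cds) if strand == "-" else cds
        else:
            seg = _random_bases(rng, length, probs)
        parts.append(seg)
        features.append(FeatureRecord(name, kind, strand, pos, pos + length))
        pos += length
        spacer = config.spacers.get(name, 0)
        if spacer:
            parts.append(_random_bases(rng, spacer, probs))
            pos += spacer
    genome = AnnotatedMitogenome(
        SequenceRecord("ancestor", "".join(parts)), features
    )
    return genome


# ---------------------------------------------------------------------------
# evolution along a chronogram
# ---------------------------------------------------------------------------

def _jc_p(d: float) -> float:
    return 0.75 * (1.0 - np.exp(-(4.0 / 3.0) * d))


def _evolve_neutral(rng: np.random.Generator, seq: str, d: float) -> tuple[str, int]:
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1").copy()
    p = _jc_p(d)
    hits = np.nonzero(rng.random(arr.size) < p)[0]
    for i in hits:
        cur = _BASE_INDEX[arr[i]]
        arr[i] = _BASES[(cur + 1 + rng.integers(3)) % 4]
    return arr.tobytes().decode("ascii"), len(hits)


def _evolve_pcg(
    rng: np.random.Generator,
    cds: str,
    d: float,
    omega: float,
    multipliers: tuple[float, float, float],
    code: GeneticCode,
) -> tuple[str, int]:
    """Evolve one coding-strand CDS over a branch of neutral divergence d.

    Proposals are drawn per site under JC at d times the codon-position
    multiplier and then filtered: silent -> accepted, amino-acid-changing ->
    accepted with probability omega, internal stop -> rejected.  Multiple
    hits in one codon are resolved left to right against the current state.
    """
    arr = np.frombuffer(cds.encode("ascii"), dtype="S1").copy()
    n = arr.size
    pos_mult = np.tile(np.asarray(multipliers), n // 3)
    p = _jc_p(d * pos_mult)
    hits = np.nonzero(rng.random(n) < p)[0]
    accepted = 0
    last_codon_start = n - 3
    for i in hits:
        cur = _BASE_INDEX[arr[i]]
        new_base = _BASES[(cur + 1 + rng.integers(3)) % 4]
        c0 = (i // 3) * 3
        old_codon = arr[c0 : c0 + 3].tobytes().decode("ascii")
        new_codon = (
            old_codon[: i - c0] + new_base.decode("ascii") + old_codon[i - c0 + 1 :]
        )
        if code.is_stop(new_codon) and c0 != last_codon_start:
            continue  # internal stop: rejected
        if code.amino_acid(new_codon) == code.amino_acid(old_codon):
            arr[i] = new_base
            accepted += 1
        elif rng.random() < omega:
            arr[i] = new_base
            accepted += 1
    return arr.tobytes().decode("ascii"), accepted


def _evolve_genome(
    rng: np.random.Generator,
    genome: AnnotatedMitogenome,
    d: float,
    config: SimulationConfig,
) -> tuple[AnnotatedMitogenome, int]:
    """One branch: evolve every segment (features and intergenic spans)."""
    seq = genome.sequence
    out = list(seq)
    subs = 0
    covered = np.zeros(len(seq), dtype=bool)
    for f in genome.features:
        covered[f.start : f.end] = True
        segment = genome.gene_sequence(f)  # coding-strand oriented
        if f.kind == "PCG":
            omega = config.omega_per_gene.get(f.gene_name, 0.0)
            evolved, k = _evolve_pcg(
                rng,
                segment,
                d,
                omega,
                config.codon_position_rate_multipliers,
                config.code,
            )
        else:
            evolved, k = _evolve_neutral(rng, segment, d)
        subs += k
        stored = revcomp(evolved) if f.strand == "-" else evolved
        out[f.start : f.end] = stored
    # intergenic spans evolve neutrally
    gaps = np.nonzero(~covered)[0]
    if gaps.size:
        inter = "".join(seq[i] for i in gaps)
        evolved, k = _evolve_neutral(rng, inter, d)
        subs += k
        for j, i in enumerate(gaps):
            out[i] = evolved[j]
    return (
        AnnotatedMitogenome(
            SequenceRecord(genome.id, "".join(out)), list(genome.features)
        ),
        subs,
    )


def evolve_clade(
    ancestor: AnnotatedMitogenome,
    chronogram: Chronogram,
    config: SimulationConfig,
) -> tuple[list[AnnotatedMitogenome], SimulationTruth]:
    """Evolve the ancestor along the chronogram; returns the tip genomes (in
    chronogram tip order) and the simulation truth.

    Deterministic given ``config.seed``: a single random stream is consumed
    in pre-order branch order.
    """
    tips = chronogram.tip_names
    if len(tips) < 2:
        raise FormatError("chronogram must have at least 2 tips")
    if chronogram.root_age < 0:
        raise FormatError("negative ages")
    rng = np.random.default_rng([config.seed, 1])
    rate = config.clock_rate_per_year
    seq_at: dict = {chronogram.tree.seed_node: ancestor}
    subs_per_branch: dict[str, int] = {}
    node_index = 0
    for node in chronogram.tree.preorder_node_iter():
        if node is chronogram.tree.seed_node:
            continue
        parent_genome = seq_at[node.parent_node]
        duration = node.parent_node.age - node.age
        if duration < -1e-9 * max(chronogram.root_age, 1.0):
            raise FormatError("child older than parent in chronogram")
        d = rate * max(duration, 0.0)
        evolved, subs = _evolve_genome(rng, parent_genome, d, config)
        if node.is_leaf():
            label = node.taxon.label
            evolved = AnnotatedMitogenome(
                SequenceRecord(label, evolved.sequence), list(evolved.features)
            )
        else:
            node_index += 1
            label = f"node{node_index}"
        subs_per_branch[label] = subs
        seq_at[node] = evolved
    genomes = {
        leaf.taxon.label: seq_at[leaf] for leaf in chronogram.tree.leaf_node_iter()
    }
    truth = SimulationTruth(
        chronogram=chronogram,
        omega_per_gene=dict(config.omega_per_gene),
        seed=config.seed,
        substitutions_per_branch=subs_per_branch,
    )
    return [genomes[t] for t in tips], truth


def default_chronogram() -> Chronogram:
    return Chronogram.from_newick(DEFAULT_CHRONOGRAM_NEWICK)


def ingroup_chronogram() -> Chronogram:
    return Chronogram.from_newick(INGROUP_CHRONOGRAM_NEWICK)


# ---------------------------------------------------------------------------
# alignment builders (simulator output shares coordinates, so no aligner)
# ---------------------------------------------------------------------------

def pcg_alignment(
    genomes: Sequence[AnnotatedMitogenome], gene: str | None = None
) -> "Alignment":
    """Codon-aligned coding-strand alignment of one PCG (or of all PCGs
    concatenated in genome order) across genomes with shared annotations."""
    from .core import Alignment

    rows = []
    for g in genomes:
        feats = g.features_of_kind("PCG")
        if gene is not None:
            feats = [f for f in feats if f.gene_name == gene]
            if not feats:
                raise FormatError(f"gene {gene!r} not annotated in {g.id}")
        rows.append((g.id, "".join(g.gene_sequence(f) for f in feats)))
    return Alignment(rows)


def genome_alignment(genomes: Sequence[AnnotatedMitogenome]) -> "Alignment":
    """Whole-genome alignment of simulator tips (shared coordinates)."""
    from .core import Alignment

    return Alignment([(g.id, g.sequence) for g in genomes])


def single_gene_ancestor(
    n_codons: int,
    seed: int,
    *,
    gene: str = "GENE",
    at_fraction: float = 0.765,
    code: GeneticCode = INVERTEBRATE_MITO,
) -> AnnotatedMitogenome:
    """A genome consisting of one heavy-strand PCG: an ATG-initiated,
    stop-free ORF with a complete terminal stop.  The substrate for
    selection-recovery experiments on a single gene."""
    rng = np.random.default_rng([seed, 4])
    cds = _random_orf(rng, n_codons, _base_probs(at_fraction), code)
    feature = FeatureRecord(gene, "PCG", "+", 0, 3 * n_codons)
    return AnnotatedMitogenome(SequenceRecord("ancestor", cds), [feature])


#: four-fold codon families without synonymous first-position escapes:
#: any first- or second-position change is non-synonymous, so under
#: omega=0 only third positions evolve and they are exactly iid JC.
_SAFE_FOURFOLD_PREFIXES = ("GG", "GC", "GT", "CC", "AC", "TC")


def neutral_fourfold_ancestor(
    n_codons: int, seed: int, *, at_fraction: float = 0.765
) -> AnnotatedMitogenome:
    """A single-PCG genome built only from four-fold degenerate codons
    (Gly/Ala/Val/Pro/Thr/Ser families), the calibration substrate for
    clock and topology checks: with omega=0 every third position is a
    four-fold site evolving neutrally."""
    rng = np.random.default_rng([seed, 3])
    prefixes = rng.choice(len(_SAFE_FOURFOLD_PREFIXES), size=n_codons)
    thirds = rng.choice(4, size=n_codons, p=_base_probs(at_fraction))
    seq = "".join(
        _SAFE_FOURFOLD_PREFIXES[p] + _BASES[t].decode("ascii")
        for p, t in zip(prefixes, thirds)
    )
    feature = FeatureRecord("FF4", "PCG", "+", 0, 3 * n_codons)
    return AnnotatedMitogenome(SequenceRecord("ancestor", seq), [feature])


# ---------------------------------------------------------------------------
# assembly corruption
# ---------------------------------------------------------------------------

def corrupt_assemblies(
    genome: AnnotatedMitogenome | SequenceRecord,
    n_replicates: int,
    error_rate: float,
    mask_intervals: Sequence[Sequence[tuple[int, int]]] | None,
    seed: int,
) -> list[SequenceRecord]:
    """Noisy per-coverage assembly replicates of one genome.

    Each replicate carries independent per-site substitution errors at
    ``error_rate`` plus its masked intervals replaced by N (emulating
    low-read-representation regions).  Deterministic given ``seed``.
    """
    record = genome.record if isinstance(genome, AnnotatedMitogenome) else genome
    if n_replicates < 2:
        raise FormatError(f"need >= 2 replicates, got {n_replicates}")
    if not (0.0 <= error_rate <= 0.05):
        raise FormatError(f"error_rate must be in [0, 0.05], got {error_rate}")
    n = len(record)
    if mask_intervals is None:
        mask_intervals = [[] for _ in range(n_replicates)]
    if len(mask_intervals) != n_replicates:
        raise FormatError(
            f"mask_intervals must list one set of ranges per replicate "
            f"({n_replicates}), got {len(mask_intervals)}"
        )
    for rep, ranges in enumerate(mask_intervals):
        for start, end in ranges:
            if not (0 <= start < end <= n):
                raise FormatError(
                    f"mask [{start},{end}) out of bounds for replicate {rep} "
                    f"(genome length {n})"
                )
    rng = np.random.default_rng([seed, 2])
    out: list[SequenceRecord] = []
    base = np.frombuffer(record.sequence.encode("ascii"), dtype="S1")
    for rep in range(n_replicates):
        arr = base.copy()
        if error_rate > 0:
            hits = np.nonzero(rng.random(n) < error_rate)[0]
            for i in hits:
                if arr[i] in _BASE_INDEX:
                    cur = _BASE_INDEX[arr[i]]
                    arr[i] = _BASES[(cur + 1 + rng.integers(3)) % 4]
        for start, end in mask_intervals[rep]:
            arr[start:end] = b"N"
        out.append(
            SequenceRecord(f"{record.id}_rep{rep + 1}", arr.tobytes().decode("ascii"))
        )
    return out


# ---------------------------------------------------------------------------
# bundle output
# ---------------------------------------------------------------------------

def write_bundle(
    out_dir: str | Path,
    tips: list[AnnotatedMitogenome],
    truth: SimulationTruth,
) -> None:
    """Write tips.fasta, features.gff3, truth.nwk (branch lengths in Myr)
    and truth.tsv into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mio.write_fasta([t.record for t in tips], out / "tips.fasta")
    mio.write_features(tips[0].features, out / "features.gff3", seqid=tips[0].id)
    (out / "truth.nwk").write_text(
        truth.chronogram.to_newick(units_in_years=1e6) + "\n"
    )
    rows = [("seed", truth.seed)]
    rows += [(f"omega:{g}", w) for g, w in sorted(truth.omega_per_gene.items())]
    rows += [
        (f"substitutions:{b}", k)
        for b, k in sorted(truth.substitutions_per_branch.items())
    ]
    mio.write_tsv(rows, ("key", "value"), out / "truth.tsv")
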