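# Methods

`mitokit` re-implements, as a tested library, the desk-scale core of a
comparative mitogenomics study of a closely related clade of cactophilic
*Drosophila* (the *D. buzzatii* cluster and its *repleta*-group outgroup):
assembly consensus calling, genome characterization, divergence profiling,
per-gene dN/dS, four-fold degenerate site extraction and strict-clock
divergence dating.  Because such analyses normally start from sequencing
data, the package carries a synthetic clade generator whose defaults encode
the study conditions, so every downstream stage can be exercised — and its
statistical behavior quantified — without any external data.

## The synthetic clade generator

**What it emulates.**  A circular, AT-rich (~76.5% A+T) mitogenome of
~14.9 kb stored linearized at the control-region start, carrying 37 genes
(13 protein-coding genes, 22 tRNAs, 2 rRNAs) plus a short control region, in
the conserved *Drosophila* order and orientation: 23 features on the heavy
(+) strand and 14 on the light (−) strand.  PCG lengths are realistic,
divisible by three, and each gene is an ATG-initiated stop-free open reading
frame under the invertebrate mitochondrial code (NCBI table 5: ATA→Met,
TGA→Trp, AGA/AGG→Ser) with a complete TAA terminal stop.  The default
architecture totals 14,890 bp, inside the 14,885–14,904 bp range typical of
the clade's assemblies.

**Evolution model.**  Sequences evolve along a dated tree (chronogram, node
ages in years) under a strict molecular clock.  For a branch of duration
Δt years the neutral expected divergence is d = μ·Δt with
μ = 6.2×10⁻⁷ substitutions/site/year by default (an empirical *Drosophila*
mtDNA rate; sd 1.89×10⁻⁷).  Per site, one substitution is proposed with the
Jukes–Cantor probability p = (3/4)(1 − e^(−(4/3)d)), the replacement drawn
uniformly from the three alternatives.  Because the per-branch proposal is
exactly the JC transition kernel, the composition of proposals along any
root-to-tip path is again JC — realized p-distances at neutral sites follow
the closed form exactly, which is what the calibration tests exploit.

Selection inside PCGs is ω-thinning: a proposal that changes the encoded
amino acid is accepted with probability ω(gene); silent proposals are always
accepted; proposals creating internal stop codons are always rejected
(lethality).  Default ω values per gene span 0.003–0.060, the purifying
range observed for mitochondrial PCGs in the clade (ATP8 0.060 and ND2
0.036 at the permissive end, COI 0.003 at the most constrained).  Codon
position rate multipliers exist as a knob but default to (1,1,1): observed
among-position rate variation then emerges from ω-thinning alone, keeping
the neutral-site oracle exact.

**Default chronogram.**  Six ingroup tips and one outgroup with the
published age structure: ingroup crown 2.11 Myr; *buzzatii*–*koepferae*
split 1.5 Myr; *koepferae* A/B strains 0.31 Myr; *borborema*–*seriema*
0.05 Myr; outgroup split 10.63 Myr.  The age of the
(*antonietae*,(*borborema*,*seriema*)) clade is not printed anywhere; it is
set to 0.95 Myr, consistent with the statement that this radiation is
younger than 1 Myr.  All ages are overridable; `Chronogram.scaled()` yields
shallower or deeper variants.

**Two limitations worth knowing.**

1. *One proposal per site per branch.*  At most one change per site per
   branch can occur.  Neutral marginals are still exactly JC (the proposal
   *is* the JC kernel), but the realized non-synonymous divergence on a
   branch is ω·p(d) rather than ω·d: at deep branches (d ≳ 0.5) p(d) < d,
   so NG86 ω estimates from deep pairs are attenuated by a factor
   ≈ p(d)/d (≈ 0.47 at d = 1.3).  ω-recovery checks therefore run at
   moderate divergence (total d ≈ 0.1), where the attenuation is a few
   percent; the acceptance script's per-gene ω values from the half-depth
   clade are reported as computed, attenuation included, and preserve the
   gene ranking.
2. *Stop-avoidance is absolute.*  Non-synonymous proposals into TAA/TAG are
   rejected regardless of ω.  Under AT-rich composition these are a
   non-negligible share of non-synonymous mutation opportunities, so the
   realized non-synonymous flux sits slightly below ω × neutral even at
   shallow depth.  This is why ω recovery is assessed with a sign test
   (estimates scatter on both sides of truth relative to replicate noise)
   rather than a mean ± 2 SE band.

A related consequence of the equal-exchange (JC) proposal: base
composition is not stationary at the ancestral AT fraction.  Neutral sites
drift toward the uniform (25% each) equilibrium, noticeably so on the deep
outgroup branch (GC of the simulated outgroup tip rises to ~35% from the
ancestral ~23.5%).  Real mitogenomes hold their AT bias through mutational
bias, which the simulator deliberately omits to keep the closed-form
oracle exact; composition-sensitive comparisons should therefore use the
ancestor or shallow tips.

What passing the simulator-based tests does **not** show: performance on
real data with indels, rearrangements, sequencing chimeras, among-site rate
heterogeneity beyond codon structure, base-compositional non-stationarity,
or tRNA/rRNA structural constraints.  The generator produces none of these.

## Assembly consensus

Per-coverage assemblies of one genome, pre-aligned, are merged column by
column.  The winning nucleotide must reach a representation threshold
τ (default 0.60) computed over **all** rows — N and '-' count in the
denominator, so heavily masked columns honestly fail and emit N.  Gaps can
neither win nor appear in output; columns of only gaps/N are dropped.
τ > 0.5 is enforced, which makes the winner unique whenever one exists and
removes tie-breaking entirely.  What a real pipeline emits when no
nucleotide reaches 60% is undocumented; emitting N is this package's
explicit choice.

## Divergence statistics

The p-distance divides nucleotide differences by nucleotides compared, with
pairwise deletion (only positions missing in that specific pair are
dropped).  Group means average per-pair p over all C(n,2) pairs, each pair
keeping its own denominator.  Windowed profiles default to 500 bp windows
sharing 100 bp with their successor (step 400); the caption-ambiguous
alternative reading (advance by 100 bp) is one flag away
(`slide_by_overlap`).  A truncated terminal window is kept iff it is at
least half a window long.  Site classification (conserved /
parsimony-informative / singleton / other-variable) follows the standard
definitions; any column containing a gap or N is counted as
"unclassified" rather than silently folded into a class — which is also why
published class counts need not sum to the printed alignment length.

## Codon statistics and dN/dS

Degeneracy of a codon position is the number of nucleotides there (others
held fixed) preserving the amino acid.  Four-fold site extraction is
deliberately strict: a third-position column is kept only if every taxon
has a gap-free codon with degeneracy 4 **and** all taxa agree at the first
two codon positions — sites kept are putatively neutral in all taxa
simultaneously.  Whether published pipelines demand the cross-taxon
conservation condition is usually unstated; the stricter rule is documented
here and loses only a modest fraction of sites at these depths.

dN/dS uses Nei–Gojobori (1986) counting: potential synonymous sites per
codon are the per-position fractions of synonymous single-nucleotide
changes (changes to stops count as non-synonymous); observed differences
are averaged over all minimal mutational pathways between differing codons,
excluding pathways through stop codons; pS = Sd/S and pN = Nd/N receive the
JC correction d = −(3/4)·ln(1 − (4/3)p), undefined (flagged saturated) at
p ≥ 3/4.  A group estimate is the mean of pairwise estimates with
saturated pairs excluded (count reported) and ω taken as mean dN / mean dS,
which stays defined when individual pairs have dS = 0.  NG86-with-JC is a
counting stand-in for maximum-likelihood codon models; published ML values
are comparators for magnitude and gene ranking, not exact targets.

## Dating

Distances are JC-corrected p-distances at extracted four-fold sites;
saturated pairs abort dating rather than being clamped.  Topology comes
from neighbor joining (rooted at the midpoint of the declared outgroup's
branch) — plumbing, not a contribution; the package uses scikit-bio's NJ.

`StrictClockModel.fit()` estimates node ages by least squares: under a
strict clock E[d_ij] = 2μ·t_MRCA(i,j), so each internal node's
unconstrained height is half the mean distance over the tip pairs it
separates.  Age monotonicity (child ≤ parent) is enforced by agglomerative
pooling of violating nodes into their parent block (pair-count-weighted
means), the tree-order analogue of pool-adjacent-violators.  Uncalibrated,
ages are heights divided by μ; with a root calibration the root is fixed,
ages scale proportionally, and the implied rate is reported instead
(`mu_estimated`).  The fit is deterministic, always ultrametric, exactly
scale-equivariant, and a fixed point under refitting its own distances.
It replaces Bayesian MCMC dating: point estimates only, no credible
intervals, no birth–death prior, no relaxed clocks.

Note the published inputs are mutually inconsistent under d = 2μt (the
printed rate, the printed whole-genome p-distances and the printed ages
cannot all hold simultaneously); the rate is therefore treated as a free
parameter with the printed default, and recovery is always judged against
simulation truth, never against published posterior ages.

## Problem sizes used in the checks

Chosen from the binomial error of a p-distance estimate, before running the
corresponding tests:

- **Clock calibration**: two-tip clades at T ∈ {0.05, 0.31, 0.95, 2.11}
  Myr on a 6,000-codon neutral four-fold gene; at the deepest T the
  expected p is 0.727, still inside the JC domain, and the extracted sites
  are exactly i.i.d. Bernoulli, so a 3-SE band is exact.  The calibration
  gene uses only four-fold families without synonymous first-position
  escapes (Gly/Ala/Val/Pro/Thr/Ser-TCN; no Leu-CTN, no Arg-CGN) so that
  with ω = 0 the first two codon positions are frozen and extraction keeps
  every codon.
- **Age recovery**: 12,000-codon neutral gene — the youngest node
  (0.05 Myr, a single tip pair) has relative age error ≈ 3.5%, making a
  10% band meaningful; at genome scale (~1,000 four-fold sites) that node
  is statistically unresolvable at 10% and crown-depth pairs (p ≈ 0.73)
  occasionally cross the saturation bound outright.
- **Split recovery**: 6,000-codon neutral gene; the internal edge
  separating the two ingroup clades is ≈ 1.1 substitutions/site long
  against distance noise of ≈ 0.2.
- **ω recovery**: 1,500-codon genes at total divergence 0.1, twenty
  replicates per ω ∈ {0, 0.05, 0.5}.

All tests and the acceptance script are seeded and deterministic.
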