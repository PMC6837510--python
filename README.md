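# mitokit

Comparative mitogenomics at desk scale, for people studying closely related
animal clades through their mitochondrial genomes — the analysis path that
runs from multiple per-coverage assemblies of a ~14.9 kb mitogenome to
divergence times, entirely as a tested, reusable Python library.

The package covers, stage by stage:

- **Consensus calling** — merge aligned per-coverage assemblies of one
  genome at a representation threshold τ (default 60%), gaps disallowed.
- **Characterization** — element composition (GC%, N%, PCG/tRNA/rRNA/
  intergenic shares), PCG base composition on the coding strand, codon
  usage with RSCU and an explicit bias index B ∈ [0, 1].
- **Divergence** — p-distances (pairwise deletion), group means, sliding-
  window profiles (500 bp / 100 bp overlap by default), pairwise matrices
  and site classification (conserved / parsimony-informative / singleton).
- **Molecular evolution** — invertebrate mitochondrial genetic code
  (table 5), codon degeneracy, four-fold degenerate third-position site
  extraction, and Nei–Gojobori (1986) dN/dS with Jukes–Cantor correction:
  pS = Sd/S, pN = Nd/N, d = −(3/4)·ln(1 − (4/3)p), ω = dN/dS.
- **Dating** — neighbor-joining topology plumbing plus a strict-clock
  least-squares fit: node ages minimize Σ (d_ij − 2μ·t_MRCA(i,j))² under
  age monotonicity, with μ = 6.2×10⁻⁷ substitutions/site/year by default,
  or the root fixed at a calibration age with μ re-estimated.
- **Simulation** — an annotated AT-rich ancestor (37 genes in the
  conserved *Drosophila* arrangement) evolved along a dated tree under
  ω-thinned purifying selection, plus noisy masked assembly replicates, so
  every stage above is exercisable and calibratable without downloads.

The dating stage is organised statsmodels-style: `StrictClockModel(...)`
is built from a topology and a distance matrix, `fit()` returns a
`StrictClockResults` carrying the chronogram, the rate, residual
diagnostics and a `summary()` table.

## Worked example

```python
import mitokit as mk

cfg = mk.SimulationConfig(seed=1)
ancestor = mk.build_ancestor(cfg)
tips, truth = mk.evolve_clade(ancestor, mk.default_chronogram(), cfg)

aln = mk.genome_alignment(tips)
print(mk.p_distance(aln.row("Dbrb"), aln.row("Dsei")).p)    # 0.02653
print(mk.p_distance(aln.row("DkoeA"), aln.row("DkoeB")).p)  # 0.12243

counts = mk.classify_sites(aln)
# conserved 7301, parsimony-informative 5710, singletons 1252
ingroup = [t for t in tips if t.id != "Dmoj"]
ff = mk.extract_fourfold(mk.pcg_alignment(ingroup))
print(ff.n_cols)                                            # 977
```

The two p-distances show the clade's age structure directly: the
*borborema*–*seriema* pair (50 kyr split) is an order of magnitude less
diverged than the two *koepferae* strains would be at crown depths, and the
six ingroup protein-coding gene sets still share 977 four-fold degenerate
third positions — the putatively neutral sites that feed dating.

Dating those sites with the strict clock (here on a neutral 12,000-codon
simulation so the truth is known — crown 2.11 Myr, splits at 1.5, 0.95,
0.31 and 0.05 Myr):

```text
Strict-clock least-squares dating
================================================
taxa:                6
rate (subst/site/yr): 6.2e-07  [fixed]
root age (yr):       2,096,499
residual SS:         9.155e-02
constraint poolings: 0

node ages (years):
       2,096,499  (Dato,Dbrb,Dbuz,DkoeA,DkoeB,Dsei)
       1,511,106  (Dbuz,DkoeA,DkoeB)
         952,324  (Dato,Dbrb,Dsei)
         303,726  (DkoeA,DkoeB)
          52,481  (Dbrb,Dsei)
```

Every fitted age lands within a few percent of its true value.

A CLI mirrors the stages for shell use:

```bash
mitokit simulate --seed 1 --out bundle/
mitokit consensus --in assemblies.fasta --threshold 0.60 --out cons.fasta
mitokit windows --aln aln.fasta --window 500 --overlap 100 --out profile.tsv
mitokit dnds --aln gene.fasta --code 5 --out dnds.tsv
mitokit date --aln fourfold.fasta --outgroup Dmoj --rate 6.2e-7 --out chronogram.nwk
```

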