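"""Simulator contracts: ancestor architecture, determinism, clock behavior
of the evolution engine, and assembly corruption."""

import math

import numpy as np
import pytest

import mitokit as mk
from mitokit.core import FormatError
from mitokit.simulate import (
    DEFAULT_ARCHITECTURE,
    SimulationConfig,
    neutral_fourfold_ancestor,
    single_gene_ancestor,
)


class TestConfig:
    def test_default_architecture_counts(self, default_config):
        kinds = {}
        strands = {"+": 0, "-": 0}
        for name, kind, length, strand in default_config.gene_architecture:
            kinds[kind] = kinds.get(kind, 0) + 1
            if kind != "control":
                strands[strand] += 1
        assert kinds == {"control": 1, "PCG": 13, "tRNA": 22, "rRNA": 2}
        assert strands == {"+": 23, "-": 14}

    def test_oversized_architecture_rejected(self):
        arch = tuple(
            (n, k, l * 2, s) for n, k, l, s in DEFAULT_ARCHITECTURE
        )
        with pytest.raises(FormatError):
            SimulationConfig(gene_architecture=arch)

    def test_omega_out_of_range_rejected(self):
        with pytest.raises(FormatError):
            SimulationConfig(omega_per_gene={"ND2": 1.5})


class TestAncestor:
    def test_feature_counts(self, ancestor):
        assert ancestor.counts_by_kind() == {
            "PCG": 13,
            "tRNA": 22,
            "rRNA": 2,
            "control": 1,
        }

    def test_total_length_in_published_range(self, ancestor):
        assert 14885 <= len(ancestor) <= 14904

    def test_at_fraction_within_two_points(self, ancestor, default_config):
        seq = ancestor.sequence
        at = (seq.count("A") + seq.count("T")) / len(seq)
        assert abs(at - default_config.at_fraction) <= 0.02

    def test_every_pcg_is_clean_orf(self, ancestor):
        for f in ancestor.features_of_kind("PCG"):
            aa = mk.translate(ancestor.gene_sequence(f))
            assert aa[-1] == "*"
            assert "*" not in aa[:-1]

    def test_features_non_overlapping(self, ancestor):
        spans = sorted((f.start, f.end) for f in ancestor.features)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_determinism(self, default_config):
        a = mk.build_ancestor(default_config)
        b = mk.build_ancestor(default_config)
        assert a.sequence == b.sequence
        assert a.features == b.features

    def test_seed_changes_sequence(self, default_config, ancestor):
        other = mk.build_ancestor(SimulationConfig(seed=2))
        assert other.sequence != ancestor.sequence


class TestEvolve:
    def test_zero_durations_identity(self, ancestor, default_config):
        chron = mk.Chronogram.from_newick("(A:0,B:0);")
        tips, truth = mk.evolve_clade(ancestor, chron, default_config)
        for t in tips:
            assert t.sequence == ancestor.sequence
        assert all(v == 0 for v in truth.substitutions_per_branch.values())

    def test_omega_zero_freezes_proteins(self):
        cfg = SimulationConfig(seed=5, omega_per_gene={"GENE": 0.0})
        anc = single_gene_ancestor(400, seed=5)
        chron = mk.Chronogram.from_newick("(A:2000000,(B:500000,C:500000):1500000);")
        tips, _ = mk.evolve_clade(anc, chron, cfg)
        proteins = {
            mk.translate(t.gene_sequence(t.features[0])) for t in tips
        }
        assert len(proteins) == 1

    def test_annotations_carried_over(self, clade, ancestor):
        tips, _ = clade
        for t in tips:
            assert t.features == ancestor.features

    def test_determinism(self, ancestor, default_config):
        chron = mk.ingroup_chronogram()
        t1, _ = mk.evolve_clade(ancestor, chron, default_config)
        t2, _ = mk.evolve_clade(ancestor, chron, default_config)
        assert [x.sequence for x in t1] == [x.sequence for x in t2]

    def test_too_few_tips_rejected(self, ancestor, default_config):
        chron = mk.Chronogram.from_newick("(A:1);")
        with pytest.raises(FormatError):
            mk.evolve_clade(ancestor, chron, default_config)

    def test_fourfold_divergence_matches_jc_closed_form(self):
        """Two tips at 0.5 Myr: realized 4-fold p-distance within 3
        binomial SE of (3/4)(1 - exp(-(4/3)*2*mu*T))."""
        T = 0.5e6
        mu = 6.2e-7
        cfg = SimulationConfig(seed=42, omega_per_gene={"FF4": 0.0})
        anc = neutral_fourfold_ancestor(4000, seed=42)
        chron = mk.Chronogram.from_newick(f"(A:{T},B:{T});")
        tips, _ = mk.evolve_clade(anc, chron, cfg)
        sites = mk.extract_fourfold(mk.pcg_alignment(tips))
        est = mk.p_distance(sites.row("A"), sites.row("B"))
        p_expected = 0.75 * (1 - math.exp(-(4 / 3) * 2 * mu * T))
        se = math.sqrt(p_expected * (1 - p_expected) / est.sites_compared)
        assert abs(est.p - p_expected) <= 3 * se

    def test_clock_linearity(self):
        """Doubling all ages doubles expected realized neutral divergence
        (JC-transformed), over 20 replicate simulations."""
        mu = 6.2e-7
        T = 0.25e6
        d1, d2 = [], []
        for rep in range(20):
            anc = neutral_fourfold_ancestor(800, seed=900 + rep)
            for depth, out in ((T, d1), (2 * T, d2)):
                cfg = SimulationConfig(seed=900 + rep, omega_per_gene={"FF4": 0.0})
                chron = mk.Chronogram.from_newick(f"(A:{depth},B:{depth});")
                tips, _ = mk.evolve_clade(anc, chron, cfg)
                sites = mk.extract_fourfold(mk.pcg_alignment(tips))
                p = mk.p_distance(sites.row("A"), sites.row("B")).p
                out.append(mk.jc_correct(p))
        ratio = np.mean(d2) / np.mean(d1)
        # 2 mu T = 0.31 per branch at the deeper depth: ratio should be ~2
        assert ratio == pytest.approx(2.0, rel=0.15)

    def test_architecture_conservation_under_purifying_selection(self, clade):
        """Evolved tips still translate cleanly for omega <= 0.1."""
        tips, _ = clade
        for t in tips:
            for f in t.features_of_kind("PCG"):
                aa = mk.translate(t.gene_sequence(f))
                assert "*" not in aa[:-1]


class TestCorruptAssemblies:
    def test_no_error_no_mask_identity(self, ancestor):
        reps = mk.corrupt_assemblies(ancestor, 3, 0.0, None, seed=1)
        assert all(r.sequence == ancestor.sequence for r in reps)

    def test_mask_applied_to_right_replicate(self, ancestor):
        masks = [[], [(100, 200)], []]
        reps = mk.corrupt_assemblies(ancestor, 3, 0.0, masks, seed=1)
        assert set(reps[1].sequence[100:200]) == {"N"}
        assert reps[0].sequence == ancestor.sequence
        assert reps[2].sequence == ancestor.sequence

    def test_error_count_binomial(self, ancestor):
        rate = 0.01
        reps = mk.corrupt_assemblies(ancestor, 5, rate, None, seed=3)
        n = len(ancestor)
        expected = rate * n
        se = math.sqrt(n * rate * (1 - rate))
        for r in reps:
            mism = sum(1 for a, b in zip(r.sequence, ancestor.sequence) if a != b)
            assert abs(mism - expected) <= 3 * se

    def test_determinism(self, ancestor):
        a = mk.corrupt_assemblies(ancestor, 2, 0.01, None, seed=9)
        b = mk.corrupt_assemblies(ancestor, 2, 0.01, None, seed=9)
        assert [r.sequence for r in a] == [r.sequence for r in b]

    def test_out_of_bounds_mask_rejected(self, ancestor):
        with pytest.raises(FormatError):
            mk.corrupt_assemblies(ancestor, 2, 0.0, [[(0, 10)], [(0, 10**6)]], seed=1)

    def test_replicate_and_rate_bounds(self, ancestor):
        with pytest.raises(FormatError):
            mk.corrupt_assemblies(ancestor, 1, 0.0, None, seed=1)
        with pytest.raises(FormatError):
            mk.corrupt_assemblies(ancestor, 2, 0.5, None, seed=1)


class TestBundle(object):
    def test_bundle_round_trips(self, tmp_path, clade):
        tips, truth = clade
        mk.write_bundle(tmp_path, tips, truth)
        from mitokit import io as mio

        recs = mio.read_fasta(tmp_path / "tips.fasta")
        assert [r.id for r in recs] == [t.id for t in tips]
        feats = mio.read_features(tmp_path / "features.gff3")
        assert feats == tips[0].features
        chron = mk.Chronogram.from_newick(
            (tmp_path / "truth.nwk").read_text(), units_in_years=1e6
        )
        assert chron.root_age == pytest.approx(truth.chronogram.root_age, rel=1e-6)
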