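"""JC correction, NJ topology plumbing and the strict-clock least-squares
fit."""

import math

import dendropy
import numpy as np
import pandas as pd
import pytest

import mitokit as mk
from mitokit.core import FormatError
from mitokit.dating import ClockModel, StrictClockModel, nj_topology

import oracles


class TestJcCorrect:
    def test_zero(self):
        assert mk.jc_correct(0.0) == 0.0

    def test_known_value(self):
        assert mk.jc_correct(0.1) == pytest.approx(
            -0.75 * math.log(1 - 0.4 / 3), rel=1e-12
        )
        assert mk.jc_correct(0.1) == pytest.approx(0.1073256, abs=1e-6)

    def test_d_at_least_p(self):
        for p in np.linspace(0.0, 0.7, 20):
            assert mk.jc_correct(p) >= p

    def test_saturation_bound(self):
        with pytest.raises(ValueError):
            mk.jc_correct(0.75)


def _dist_df(labels, fn):
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = fn(labels[i], labels[j])
    return pd.DataFrame(m, index=labels, columns=labels)


def _splits(tree):
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and not node.is_leaf():
            out.add(frozenset(l.taxon.label for l in node.leaf_iter()))
    return out


class TestNjTopology:
    def test_two_taxa_cherry(self):
        df = _dist_df(["A", "B"], lambda a, b: 0.2)
        tree = nj_topology(df)
        assert sorted(l.taxon.label for l in tree.leaf_node_iter()) == ["A", "B"]

    def test_additive_quartet_recovers_generating_topology(self):
        # tree ((A,B),(C,D)) with internal branch 0.3
        patristic = {
            ("A", "B"): 0.2,
            ("A", "C"): 0.8,
            ("A", "D"): 0.9,
            ("B", "C"): 0.8,
            ("B", "D"): 0.9,
            ("C", "D"): 0.3,
        }

        def fn(a, b):
            return patristic.get((a, b), patristic.get((b, a)))

        labels = ["A", "B", "C", "D"]
        df = _dist_df(labels, fn)
        # oracle: best pairing by the four-point condition
        assert oracles.best_quartet_topology(patristic, labels) == frozenset({"A", "B"})
        tree = nj_topology(df, outgroup="D")
        assert frozenset({"A", "B"}) in _splits(tree)

    def test_asymmetric_matrix_rejected(self):
        df = _dist_df(["A", "B", "C"], lambda a, b: 0.1)
        df.iloc[0, 1] = 0.5
        with pytest.raises(FormatError):
            nj_topology(df)

    def test_outgroup_rooting(self):
        df = _dist_df(
            ["A", "B", "C", "O"],
            lambda a, b: 0.1 if {a, b} == {"A", "B"} else (1.0 if "O" in (a, b) else 0.4),
        )
        tree = nj_topology(df, outgroup="O")
        root_children = tree.seed_node.child_nodes()
        labels = [
            {l.taxon.label for l in c.leaf_iter()} for c in root_children
        ]
        assert {"O"} in labels


class TestStrictClock:
    def test_two_taxon_analytic_age(self):
        """age = d / (2 mu), exact."""
        mu = 6.2e-7
        d = 0.062
        df = _dist_df(["A", "B"], lambda a, b: d)
        topo = nj_topology(df)
        res = StrictClockModel(topo, df, ClockModel(rate=mu)).fit()
        assert res.chronogram.root_age == pytest.approx(d / (2 * mu), rel=1e-15)
        assert res.chronogram.root_age == pytest.approx(50_000.0)

    def _ultrametric_case(self):
        ages = {"AB": 1.0e6, "ABC": 3.0e6}
        mu = 6.2e-7

        def fn(a, b):
            t = ages["AB"] if {a, b} == {"A", "B"} else ages["ABC"]
            return 2 * mu * t

        df = _dist_df(["A", "B", "C"], fn)
        topo = dendropy.Tree.get(data="((A,B),C);", schema="newick",
                                 suppress_internal_node_taxa=True)
        return df, topo, ages, mu

    def test_perfect_input_zero_residual(self):
        df, topo, ages, mu = self._ultrametric_case()
        res = StrictClockModel(topo, df, ClockModel(rate=mu)).fit()
        assert res.rss == pytest.approx(0.0, abs=1e-20)
        fitted = res.node_ages()
        assert fitted[frozenset({"A", "B"})] == pytest.approx(ages["AB"])
        assert fitted[frozenset({"A", "B", "C"})] == pytest.approx(ages["ABC"])

    def test_scale_equivariance(self):
        df, topo, _, mu = self._ultrametric_case()
        res1 = StrictClockModel(topo, df, ClockModel(rate=mu)).fit()
        res2 = StrictClockModel(topo, df * 3.0, ClockModel(rate=mu)).fit()
        for k, v in res1.node_ages().items():
            assert res2.node_ages()[k] == pytest.approx(3.0 * v)

    def test_fit_is_ultrametric_and_fixed_point(self):
        """Refitting distances derived from a fitted chronogram reproduces
        it exactly."""
        rng = np.random.default_rng(3)
        labels = ["A", "B", "C", "D"]
        df = _dist_df(labels, lambda a, b: 0.2 + 0.3 * rng.random())
        df = (df + df.T) / 2
        topo = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick",
                                 suppress_internal_node_taxa=True)
        mu = 6.2e-7
        res = StrictClockModel(topo, df, ClockModel(rate=mu)).fit()
        chron = res.chronogram  # construction itself validates ultrametricity
        df2 = _dist_df(labels, lambda a, b: 2 * mu * chron.mrca_age(a, b))
        res2 = StrictClockModel(topo, df2, ClockModel(rate=mu)).fit()
        for k, v in res.node_ages().items():
            assert res2.node_ages()[k] == pytest.approx(v, rel=1e-9)

    def test_monotonicity_constraint_pools_violators(self):
        """A child whose raw mean distance exceeds its parent's is pooled
        to the parent age rather than inverting the order."""
        # (A,B) cherry more divergent than the root pairs
        def fn(a, b):
            if {a, b} == {"A", "B"}:
                return 1.0
            return 0.4

        df = _dist_df(["A", "B", "C"], fn)
        topo = dendropy.Tree.get(data="((A,B),C);", schema="newick",
                                 suppress_internal_node_taxa=True)
        res = StrictClockModel(topo, df, ClockModel(rate=1.0)).fit()
        ages = res.node_ages()
        assert ages[frozenset({"A", "B"})] <= ages[frozenset({"A", "B", "C"})]
        assert res.pooled_nodes >= 1

    def test_calibrated_mode_matches_uncalibrated_at_consistent_root(self):
        df, topo, ages, mu = self._ultrametric_case()
        free = StrictClockModel(topo, df, ClockModel(rate=mu)).fit()
        cal = StrictClockModel(
            topo, df, ClockModel(rate=mu, root_calibration_age=free.chronogram.root_age)
        ).fit()
        assert cal.mu_used == pytest.approx(mu)
        for k, v in free.node_ages().items():
            assert cal.node_ages()[k] == pytest.approx(v)

    def test_calibrated_mode_reestimates_rate(self):
        df, topo, ages, mu = self._ultrametric_case()
        res = StrictClockModel(
            topo, df, ClockModel(rate=mu, root_calibration_age=2 * ages["ABC"])
        ).fit()
        assert res.mu_estimated
        assert res.mu_used == pytest.approx(mu / 2)
        assert res.chronogram.root_age == pytest.approx(2 * ages["ABC"])

    def test_summary_mentions_rate_and_root(self):
        df, topo, _, mu = self._ultrametric_case()
        res = StrictClockModel(topo, df, ClockModel(rate=mu)).fit()
        text = res.summary()
        assert "rate" in text and "root age" in text


class TestFourfoldDistanceMatrix:
    def test_saturated_pair_listed(self):
        # all sites differ -> p = 1 at the single 4-fold site column set
        aln = mk.Alignment([("a", "GGAGGA"), ("b", "GGCGGC")])
        with pytest.raises(FormatError, match="a-b"):
            mk.fourfold_distance_matrix(aln)

    def test_simulated_clade_distances_are_reasonable(self, ancestor, default_config):
        # half-depth clade keeps every pair safely inside the JC domain
        chron = mk.ingroup_chronogram().scaled(0.5)
        tips, _ = mk.evolve_clade(ancestor, chron, default_config)
        aln = mk.pcg_alignment(tips)
        dm = mk.fourfold_distance_matrix(aln)
        # sisters are closest
        assert dm.loc["Dbrb", "Dsei"] == dm.drop("Dbrb").min()["Dbrb"] == \
            dm.loc["Dsei", "Dbrb"]
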