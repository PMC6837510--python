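"""Distance-based topology plumbing and simplified strict-clock dating.

Divergence times are estimated from Jukes–Cantor-corrected distances at
four-fold degenerate third codon positions (putatively neutral sites).
Under a strict clock with rate mu substitutions/site/year, the expected
corrected distance between two taxa whose most recent common ancestor has
age t is d = 2*mu*t.  :class:`StrictClockModel` fits node ages by least
squares subject to the age-monotonicity constraint (child younger than
parent, enforced by agglomerative pooling), either converting heights with
a fixed rate or, when a root calibration age is supplied, fixing the root
and re-estimating the rate as a by-product.

This is a deterministic stand-in for Bayesian relaxed/strict-clock MCMC
dating: point estimates only, no credible intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .codons import extract_fourfold, jc_correct
from .core import Alignment, FormatError
from .divergence import p_distance

__all__ = [
    "jc_correct",
    "ClockModel",
    "Chronogram",
    "nj_topology",
    "fourfold_distance_matrix",
    "StrictClockModel",
    "StrictClockResults",
]

#: published strict-clock prior for Drosophila mitochondrial DNA
DEFAULT_CLOCK_RATE = 6.2e-7          # substitutions / site / year
DEFAULT_CLOCK_RATE_SD = 1.89e-7
DEFAULT_ROOT_AGE = 11.3e6            # years
DEFAULT_ROOT_CI = (9.34e6, 13.0e6)


@dataclass(frozen=True)
class ClockModel:
    """Strict molecular clock: one rate for every branch.

    ``root_calibration_age`` is optional; when set, the fit fixes the root
    at that age and reports the implied rate instead of using ``rate``.
    """

    rate: float = DEFAULT_CLOCK_RATE
    rate_sd: float = DEFAULT_CLOCK_RATE_SD
    root_calibration_age: float | None = None
    root_ci: tuple[float, float] = DEFAULT_ROOT_CI

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError(f"clock rate must be positive, got {self.rate}")
        if self.root_calibration_age is not None and self.root_calibration_age <= 0:
            raise ValueError("root calibration age must be positive")


class Chronogram:
    """Rooted tree whose node heights are ages in years; tips at age 0.

    Wraps a dendropy tree whose branch lengths are durations in years; every
    node carries an ``age`` attribute.  Construction validates
    ultrametricity to 1e-6 relative tolerance and age monotonicity.
    """

    def __init__(self, tree: dendropy.Tree):
        tree.is_rooted = True
        self.tree = tree
        self._assign_ages()

    def _assign_ages(self) -> None:
        # depth from root, then age = root_depth_max - depth
        root = self.tree.seed_node
        depths: dict[dendropy.Node, float] = {root: 0.0}
        for node in self.tree.preorder_node_iter():
            if node is root:
                continue
            bl = node.edge.length
            if bl is None:
                raise FormatError("chronogram requires branch lengths (years)")
            if bl < 0:
                raise FormatError(f"negative branch length {bl}")
            depths[node] = depths[node.parent_node] + bl
        tip_depths = [depths[leaf] for leaf in self.tree.leaf_node_iter()]
        root_age = max(tip_depths)
        tol = 1e-6 * max(root_age, 1.0)
        for leaf, d in zip(self.tree.leaf_node_iter(), tip_depths):
            if abs(d - root_age) > tol:
                raise FormatError(
                    f"tree is not ultrametric: tip {leaf.taxon.label} at depth "
                    f"{d}, root age {root_age}"
                )
        for node in self.tree.preorder_node_iter():
            node.age = root_age - depths[node]
        for leaf in self.tree.leaf_node_iter():
            leaf.age = 0.0

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, *, units_in_years: float = 1.0) -> "Chronogram":
        """Parse Newick whose branch lengths are durations; ``units_in_years``
        rescales (e.g. 1e6 for branch lengths in Myr)."""
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
        if units_in_years != 1.0:
            for edge in tree.preorder_edge_iter():
                if edge.length is not None:
                    edge.length *= units_in_years
        return cls(tree)

    # -- accessors ---------------------------------------------------------

    @property
    def root_age(self) -> float:
        return self.tree.seed_node.age

    @property
    def tip_names(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def node_ages(self) -> dict[frozenset[str], float]:
        """Map from the tip-set under each internal node to its age."""
        out: dict[frozenset[str], float] = {}
        for node in self.tree.preorder_internal_node_iter():
            tips = frozenset(l.taxon.label for l in node.leaf_iter())
            out[tips] = node.age
        return out

    def mrca_age(self, a: str, b: str) -> float:
        mrca = self.tree.mrca(taxon_labels=[a, b])
        return mrca.age

    def scaled(self, factor: float) -> "Chronogram":
        tree = self.tree.clone(depth=1)
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= factor
        return Chronogram(tree)

    def to_newick(self, *, units_in_years: float = 1.0) -> str:
        tree = self.tree.clone(depth=1)
        if units_in_years != 1.0:
            for edge in tree.preorder_edge_iter():
                if edge.length is not None:
                    edge.length /= units_in_years
        return tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".10g",
        ).strip()

    def __repr__(self) -> str:
        return (
            f"Chronogram({len(self.tip_names)} tips, root age "
            f"{self.root_age:.4g} yr)"
        )


# ---------------------------------------------------------------------------
# distance matrices and NJ topology
# ---------------------------------------------------------------------------

def fourfold_distance_matrix(alignment: Alignment, *, already_fourfold: bool = False) -> pd.DataFrame:
    """JC-corrected pairwise distance matrix at four-fold degenerate sites.

    ``alignment`` is an in-frame PCG alignment (or, with
    ``already_fourfold``, a pre-extracted site matrix).  Saturated pairs
    (p >= 3/4) abort with an error listing them.
    """
    sites = alignment if already_fourfold else extract_fourfold(alignment)
    if sites.n_cols == 0:
        raise FormatError("no four-fold degenerate sites to compare")
    n = sites.n_rows
    mat = np.zeros((n, n))
    saturated: list[str] = []
    for i in range(n):
        for j in range(i + 1, n):
            p = p_distance(sites.matrix[i], sites.matrix[j]).p
            if p >= 0.75:
                saturated.append(f"{sites.names[i]}-{sites.names[j]} (p={p:.3f})")
                continue
            mat[i, j] = mat[j, i] = jc_correct(p)
    if saturated:
        raise FormatError(
            "saturated pairs (p >= 3/4), JC distance undefined: "
            + ", ".join(saturated)
        )
    return pd.DataFrame(mat, index=sites.names, columns=sites.names)


def nj_topology(
    distance_matrix: pd.DataFrame, outgroup: str | None = None
) -> dendropy.Tree:
    """Neighbor-joining tree from a symmetric distance matrix, optionally
    rooted at the midpoint of the outgroup's branch."""
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj

    values = np.asarray(distance_matrix, dtype=float)
    ids = [str(x) for x in distance_matrix.index]
    if values.shape[0] != values.shape[1]:
        raise FormatError("distance matrix must be square")
    if not np.allclose(values, values.T):
        raise FormatError("distance matrix must be symmetric")
    if not np.allclose(np.diag(values), 0.0):
        raise FormatError("distance matrix diagonal must be zero")
    if len(ids) < 2:
        raise FormatError("need at least 2 taxa")
    if len(ids) == 2:
        d = values[0, 1]
        newick = f"({ids[0]}:{d / 2},{ids[1]}:{d / 2});"
        tree = dendropy.Tree.get(data=newick, schema="newick")
        tree.is_rooted = True
        return tree
    sk_tree = skbio_nj(SkbioDM(values, ids))
    newick = str(sk_tree.write([], format="newick")[0])
    tree = dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=True
    )
    if outgroup is not None:
        leaf = None
        for l in tree.leaf_node_iter():
            if l.taxon.label == outgroup:
                leaf = l
                break
        if leaf is None:
            raise FormatError(f"outgroup {outgroup!r} not in tree")
        edge = leaf.edge
        half = (edge.length or 0.0) / 2.0
        tree.reroot_at_edge(edge, length1=half, length2=half)
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# strict-clock least-squares fit
# ---------------------------------------------------------------------------

@dataclass
class StrictClockResults:
    """Fit output: the dated tree, the rate actually used (or implied), and
    residual diagnostics."""

    chronogram: Chronogram
    clock: ClockModel
    mu_used: float
    mu_estimated: bool
    node_heights: dict[frozenset[str], float]  # divergence units (d/2)
    residuals: pd.DataFrame = field(repr=False)
    rss: float = 0.0
    pooled_nodes: int = 0

    def node_ages(self) -> dict[frozenset[str], float]:
        return self.chronogram.node_ages()

    def summary(self) -> str:
        lines = [
            "Strict-clock least-squares dating",
            "=" * 48,
            f"taxa:                {len(self.chronogram.tip_names)}",
            f"rate (subst/site/yr): {self.mu_used:.4g}"
            + ("  [re-estimated from root calibration]" if self.mu_estimated else "  [fixed]"),
            f"root age (yr):       {self.chronogram.root_age:,.0f}",
            f"residual SS:         {self.rss:.3e}",
            f"constraint poolings: {self.pooled_nodes}",
            "",
            "node ages (years):",
        ]
        for tips, age in sorted(
            self.chronogram.node_ages().items(), key=lambda kv: -kv[1]
        ):
            label = ",".join(sorted(tips))
            if len(label) > 46:
                label = label[:43] + "..."
            lines.append(f"  {age:>14,.0f}  ({label})")
        return "\n".join(lines)


class StrictClockModel:
    """Least-squares strict-clock dating of a rooted topology.

    Parameters
    ----------
    topology : dendropy.Tree
        Rooted tree (e.g. from :func:`nj_topology`); branch lengths ignored.
    distances : pandas.DataFrame
        Symmetric JC-corrected distance matrix over the topology's tips.
    clock : ClockModel
        Rate, and optionally a root calibration age.

    Node ages minimize sum over tip pairs of (d_ij - 2*mu*t_mrca(i,j))^2
    subject to child age <= parent age, solved by pooling adjacent violators
    (each pooled block takes its pair-weighted mean height).
    """

    def __init__(
        self,
        topology: dendropy.Tree,
        distances: pd.DataFrame,
        clock: ClockModel = ClockModel(),
    ):
        self.topology = topology
        self.clock = clock
        tips = sorted(l.taxon.label for l in topology.leaf_node_iter())
        if len(tips) < 2:
            raise FormatError("dating needs at least 2 taxa")
        missing = [t for t in tips if t not in distances.index]
        if missing:
            raise FormatError(f"taxa missing from distance matrix: {missing}")
        self.distances = distances.loc[tips, tips].astype(float)
        values = self.distances.to_numpy()
        if not np.allclose(values, values.T):
            raise FormatError("distance matrix must be symmetric")

    @classmethod
    def from_alignment(
        cls,
        alignment: Alignment,
        *,
        outgroup: str,
        clock: ClockModel = ClockModel(),
        already_fourfold: bool = False,
    ) -> "StrictClockModel":
        """Convenience constructor: four-fold distances + NJ rooting in one
        step from an in-frame PCG alignment."""
        dm = fourfold_distance_matrix(alignment, already_fourfold=already_fourfold)
        topo = nj_topology(dm, outgroup=outgroup)
        return cls(topo, dm, clock)

    # -- fitting -----------------------------------------------------------

    def fit(self) -> StrictClockResults:
        topo = self.topology.clone(depth=1)
        d = self.distances

        # per internal node: pairs whose MRCA it is, and their mean d/2
        internal: list[dendropy.Node] = list(topo.preorder_internal_node_iter())
        pairs_of: dict[dendropy.Node, list[tuple[str, str]]] = {v: [] for v in internal}
        for v in internal:
            children = v.child_nodes()
            clades = [
                [l.taxon.label for l in c.leaf_iter()] if not c.is_leaf() else [c.taxon.label]
                for c in children
            ]
            for a in range(len(clades)):
                for b in range(a + 1, len(clades)):
                    for ta in clades[a]:
                        for tb in clades[b]:
                            pairs_of[v].append((ta, tb))

        # agglomerative pooling: block per node, merge upward on violation
        block_of = {v: v for v in internal}
        block_sum = {
            v: sum(d.at[a, b] / 2.0 for a, b in pairs_of[v]) for v in internal
        }
        block_w = {v: len(pairs_of[v]) for v in internal}
        parent_of = {v: v.parent_node for v in internal}

        def find(v):
            while block_of[v] is not v:
                block_of[v] = block_of[block_of[v]]
                v = block_of[v]
            return v

        pooled = 0
        changed = True
        while changed:
            changed = False
            for v in internal:
                if v is topo.seed_node:
                    continue
                bv, bp = find(v), find(parent_of[v])
                if bv is bp:
                    continue
                hv = block_sum[bv] / block_w[bv]
                hp = block_sum[bp] / block_w[bp]
                if hv > hp + 1e-15:
                    block_of[bv] = bp
                    block_sum[bp] += block_sum[bv]
                    block_w[bp] += block_w[bv]
                    pooled += 1
                    changed = True

        heights = {v: block_sum[find(v)] / block_w[find(v)] for v in internal}
        root = topo.seed_node
        h_root = heights[root]
        if h_root <= 0:
            raise FormatError(
                "infeasible fit: root height is not positive "
                "(all distances zero?)"
            )

        if self.clock.root_calibration_age is not None:
            root_age = self.clock.root_calibration_age
            mu = h_root / root_age
            ages = {v: root_age * heights[v] / h_root for v in internal}
            mu_estimated = True
        else:
            mu = self.clock.rate
            ages = {v: heights[v] / mu for v in internal}
            mu_estimated = False

        # branch lengths in years from fitted ages
        for v in internal:
            for child in v.child_nodes():
                child_age = ages.get(child, 0.0)
                child.edge.length = max(ages[v] - child_age, 0.0)
        root.edge.length = None

        chron = Chronogram(topo)

        rows = []
        rss = 0.0
        names = list(d.index)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                t = chron.mrca_age(a, b)
                fitted = 2.0 * mu * t
                resid = d.at[a, b] - fitted
                rss += resid * resid
                rows.append((a, b, d.at[a, b], fitted, resid))
        residuals = pd.DataFrame(
            rows, columns=["taxon_a", "taxon_b", "observed", "fitted", "residual"]
        )
        node_heights = {}
        for v in internal:
            tipset = frozenset(l.taxon.label for l in v.leaf_iter())
            node_heights[tipset] = heights[v]
        return StrictClockResults(
            chronogram=chron,
            clock=self.clock,
            mu_used=mu,
            mu_estimated=mu_estimated,
            node_heights=node_heights,
            residuals=residuals,
            rss=rss,
            pooled_nodes=pooled,
        )
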