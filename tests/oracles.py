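"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written position-by-position / by exhaustive enumeration,
deliberately sharing no code with the package internals.
"""

from __future__ import annotations

from itertools import permutations

BASES = "ACGT"
MISSING = set("N-")


# -- p-distance --------------------------------------------------------------

def p_distance_scan(a: str, b: str) -> tuple[int, int]:
    """(differences, sites_compared) by a per-position scan with pairwise
    deletion."""
    diffs = sites = 0
    for x, y in zip(a, b):
        if x in MISSING or y in MISSING:
            continue
        sites += 1
        if x != y:
            diffs += 1
    return diffs, sites


# -- site classification -----------------------------------------------------

def classify_column(column: str) -> str:
    if any(ch in MISSING for ch in column):
        return "unclassified"
    states = {}
    for ch in column:
        states[ch] = states.get(ch, 0) + 1
    if len(states) == 1:
        return "conserved"
    if sum(1 for c in states.values() if c >= 2) >= 2:
        return "parsimony_informative"
    if len(states) == 2 and min(states.values()) == 1:
        return "singleton"
    return "other_variable"


def classify_alignment(rows: list[str]) -> dict[str, int]:
    out = {
        "conserved": 0,
        "parsimony_informative": 0,
        "singleton": 0,
        "other_variable": 0,
        "unclassified": 0,
    }
    for c in range(len(rows[0])):
        out[classify_column("".join(r[c] for r in rows))] += 1
    return out


# -- genetic code / degeneracy ----------------------------------------------

def degeneracy_enumerate(codon: str, position: int, aa_of) -> int:
    """Count bases at `position` (1-based) giving the same amino acid,
    using the supplied codon->aa function."""
    i = position - 1
    target = aa_of(codon)
    return sum(
        1 for b in BASES if aa_of(codon[:i] + b + codon[i + 1 :]) == target
    )


# -- NG86 --------------------------------------------------------------------

def ng86_sites_codon(codon: str, aa_of, stops: set[str]) -> float:
    """Potential synonymous sites in one codon (changes to stops count as
    non-synonymous)."""
    s = 0.0
    for i in range(3):
        for b in BASES:
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1 :]
            if mut not in stops and aa_of(mut) == aa_of(codon):
                s += 1 / 3
    return s


def ng86_pathways_codon(
    ca: str, cb: str, aa_of, stops: set[str]
) -> tuple[float, float] | None:
    """(syn, nonsyn) observed differences averaged over stop-free minimal
    pathways, or None when every pathway is blocked."""
    positions = [i for i in range(3) if ca[i] != cb[i]]
    if not positions:
        return 0.0, 0.0
    path_counts = []
    for order in permutations(positions):
        cur = ca
        syn = non = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in stops:
                ok = False
                break
            if aa_of(nxt) == aa_of(cur):
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            path_counts.append((syn, non))
    if not path_counts:
        return None
    n = len(path_counts)
    return (
        sum(s for s, _ in path_counts) / n,
        sum(m for _, m in path_counts) / n,
    )


def ng86_pair_oracle(
    cds_a: str, cds_b: str, aa_of, stops: set[str]
) -> dict[str, float]:
    """Full NG86 counting (S, N, Sd, Nd, codons) by per-codon enumeration."""
    S_a = S_b = Sd = Nd = 0.0
    compared = 0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        if any(ch not in BASES for ch in ca + cb):
            continue
        if ca in stops or cb in stops:
            continue
        counts = ng86_pathways_codon(ca, cb, aa_of, stops)
        if counts is None:
            continue
        compared += 1
        S_a += ng86_sites_codon(ca, aa_of, stops)
        S_b += ng86_sites_codon(cb, aa_of, stops)
        Sd += counts[0]
        Nd += counts[1]
    S = 0.5 * (S_a + S_b)
    return {
        "S": S,
        "N": 3.0 * compared - S,
        "Sd": Sd,
        "Nd": Nd,
        "codons": compared,
    }


# -- least-squares topology check -------------------------------------------

def best_quartet_topology(d: dict[tuple[str, str], float], taxa: list[str]) -> frozenset:
    """Of the three unrooted 4-taxon topologies, the one with the smallest
    least-squares additive fit; returned as the sister pair containing
    taxa[0].  Uses the four-point condition on path lengths."""
    a, b, c, e = taxa

    def dd(x, y):
        return d[(x, y)] if (x, y) in d else d[(y, x)]

    # sum of distances across each pairing
    pairings = {
        frozenset({a, b}): dd(a, b) + dd(c, e),
        frozenset({a, c}): dd(a, c) + dd(b, e),
        frozenset({a, e}): dd(a, e) + dd(b, c),
    }
    return min(pairings, key=pairings.get)
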