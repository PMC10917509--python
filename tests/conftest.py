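import numpy as np
import pytest

from prdm9kit.alleles import (
    CANONICAL_UNIT_NT,
    NucleotideAllele,
    RepeatUnit,
    ZnfArrayAllele,
    build_array,
)
from prdm9kit.simulate import SimulationConfig, simulate_allele_family


@pytest.fixture(scope="session")
def canonical_allele() -> NucleotideAllele:
    return NucleotideAllele("canon", CANONICAL_UNIT_NT * 3)


@pytest.fixture(scope="session")
def family():
    """One default-condition simulated allele family."""
    return simulate_allele_family(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def family_arrays(family):
    return family.arrays()


def toy_array(name: str, units: list[str]) -> ZnfArrayAllele:
    """Array over arbitrary (multiple-of-3) unit strings, bypassing biology."""
    ru = [RepeatUnit(index=i, nt=u, aa="", complete=True) for i, u in enumerate(units)]
    return ZnfArrayAllele(
        allele=NucleotideAllele(name, "".join(units)),
        units=ru,
        contacts=["---"] * len(units),
        kept_mask=[True] * len(units),
    )


def brute_force_distance(A, B, w) -> float:
    """Exhaustive minimum over all monotone edit scripts (test oracle).

    Independent of the DP: recursion enumerates every script; unit
    substitution cost recomputed here with a plain Hamming/Levenshtein;
    owner-relative slippage rule re-derived from scratch.
    """
    ua = [u.nt for u in A.kept_units()]
    ub = [u.nt for u in B.kept_units()]

    def lev(x, y):
        prev = list(range(len(y) + 1))
        for i, cx in enumerate(x, 1):
            cur = [i]
            for j, cy in enumerate(y, 1):
                cur.append(
                    min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (cx != cy))
                )
            prev = cur
        return prev[-1]

    def sub(x, y):
        if len(x) == len(y):
            return w.w_mut * sum(a != b for a, b in zip(x, y))
        return w.w_mut * lev(x, y)

    def gap(units, i):
        for j in (i - 1, i + 1):
            if 0 <= j < len(units) and len(units[j]) == len(units[i]):
                mism = sum(a != b for a, b in zip(units[i], units[j]))
                if mism <= w.slippage_max_mismatch:
                    return w.w_slippage
        return w.w_indel

    from functools import lru_cache

    @lru_cache(maxsize=None)
    def rec(i, j):
        if i == len(ua) and j == len(ub):
            return 0.0
        best = float("inf")
        if i < len(ua):
            best = min(best, rec(i + 1, j) + gap(tuple(ua), i))
        if j < len(ub):
            best = min(best, rec(i, j + 1) + gap(tuple(ub), j))
        if i < len(ua) and j < len(ub):
            best = min(best, rec(i + 1, j + 1) + sub(ua[i], ub[j]))
        return best

    return rec(0, 0)


def random_toy_pair(rng: np.random.Generator, alphabet="AC", max_units=4):
    """Random pair of small arrays over a 2-letter toy unit alphabet."""
    def mk(name):
        n = int(rng.integers(1, max_units + 1))
        units = [
            "".join(rng.choice(list(alphabet), size=3)) for _ in range(n)
        ]
        return toy_array(name, units)

    return mk("A"), mk("B")


def random_additive_matrix(rng: np.random.Generator, n_taxa: int):
    """Random binary tree with branch lengths >= 0.1 and its path metric."""
    import dendropy

    tns = dendropy.TaxonNamespace()
    nodes = [dendropy.Node(taxon=tns.new_taxon(f"t{i}")) for i in range(n_taxa)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for k in (j, i):
            child = nodes.pop(k)
            parent.add_child(child)
            child.edge.length = float(rng.uniform(0.1, 2.0))
        nodes.append(parent)
    root = dendropy.Node()
    for child in nodes:
        root.add_child(child)
        child.edge.length = float(rng.uniform(0.1, 2.0))
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    pdm = tree.phylogenetic_distance_matrix()
    labels = [f"t{i}" for i in range(n_taxa)]
    D = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            D[i, j] = D[j, i] = pdm.patristic_distance(
                tns.get_taxon(labels[i]), tns.get_taxon(labels[j])
            )
    return labels, D, tree
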