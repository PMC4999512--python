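"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import stats

from coopcare.data import SpeciesRecord
from coopcare.phylo import Phylogeny, read_newick


# ---------------------------------------------------------------------------
# independent oracles (deliberately brute-force; never share code paths with
# the implementation they check)
# ---------------------------------------------------------------------------

def enumerate_signed_rank_p(values, mu: float = 0.5) -> float:
    """Exact one-tailed signed-rank p by enumerating all 2^n sign patterns."""
    d = np.asarray(values, dtype=float) - mu
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    n = d.size
    hits = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if w >= w_obs - 1e-12:
            hits += 1
    return hits / 2.0**n


def vcv_by_path_enumeration(tree: Phylogeny) -> tuple[list[str], np.ndarray]:
    """Unnormalized covariance via explicit root-to-tip edge-path sums.

    For each pair of tips the covariance is the summed length of the edges
    their root paths share, found by set intersection on edge identities.
    """
    dtree = tree.tree
    paths: dict[str, dict[int, float]] = {}
    for leaf in dtree.leaf_node_iter():
        node, path = leaf, {}
        while node.parent_node is not None:
            path[id(node.edge)] = node.edge.length
            node = node.parent_node
        paths[leaf.taxon.label.replace(" ", "_")] = path
    taxa = sorted(paths)
    n = len(taxa)
    C = np.zeros((n, n))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            shared = set(paths[a]) & set(paths[b])
            C[i, j] = sum(paths[a][e] for e in shared)
    return taxa, C


def gls_by_explicit_inverse(y, X, V) -> np.ndarray:
    """Textbook GLS coefficients through explicit matrix inverses."""
    Vi = np.linalg.inv(V)
    return np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

WORKED_NEWICK = "((A:1,B:1):1,C:2);"


@pytest.fixture
def worked_tree() -> Phylogeny:
    """Three-taxon tree whose covariance is hand-enumerable."""
    return read_newick(WORKED_NEWICK)[0]


def make_record(species_id: str = "sp", **kw) -> SpeciesRecord:
    """A valid species record with overridable fields."""
    defaults = dict(effort_pct=50.0, kinship_r=0.3, sexratio_pct_male=60.0,
                    group_size=3.5, pct_nests_helped=40.0, quality=2,
                    epp_rate=5.0)
    defaults.update(kw)
    return SpeciesRecord(species_id=species_id, **defaults)


@pytest.fixture
def record_factory():
    return make_record
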