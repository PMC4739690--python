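import numpy as np
import pytest

from rhinopath import (
    CATEGORIES,
    PathologyCategory,
    SpecimenRecord,
    TaxonProfile,
    TimeTree,
    read_newick,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20160203)


def make_record(taxon="T", element="femur", count=1, row=None, **ranks):
    """Record with ranks given as keyword args, e.g. exostoses=2."""
    return SpecimenRecord(
        specimen_id="X-1",
        taxon=taxon,
        element=element,
        count=count,
        ranks={PathologyCategory(k): v for k, v in ranks.items()},
        row=row,
    )


def uniform_record(taxon="T", rank=1, count=1, element="femur"):
    """Record with the same rank in all seven categories."""
    return SpecimenRecord(
        specimen_id="X-1",
        taxon=taxon,
        element=element,
        count=count,
        ranks={c: rank for c in CATEGORIES},
    )


def profile(taxon, fad, lad, mass=100.0, nisp=10, mni=3, extant=None):
    return TaxonProfile(
        taxon=taxon,
        mass_kg=mass,
        fad_ma=fad,
        lad_ma=lad,
        nisp=nisp,
        mni=mni,
        extant=(lad == 0) if extant is None else extant,
    )


@pytest.fixture
def three_tip_timetree():
    """((A:1,B:1):1,C:2); with branch durations as written."""
    return TimeTree(read_newick("((A:1,B:1):1,C:2);"))


def random_timetree(rng, n_tips, min_len=0.1, max_len=3.0):
    """Random dichotomous topology with uniform positive branch durations."""
    from rhinopath.synth import random_topology

    labels = [f"t{i}" for i in range(n_tips)]
    tree = random_topology(labels, rng)
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = float(rng.uniform(min_len, max_len))
    return TimeTree(tree)


def brownian_covariance(timetree):
    """V[i,j] = shared root-to-MRCA branch duration; the BM tip covariance."""
    tips = list(timetree.tree.leaf_node_iter())
    paths = []
    for leaf in tips:
        nodes = []
        nd = leaf
        while nd.parent_node is not None:
            nodes.append(nd)
            nd = nd.parent_node
        paths.append(set(nodes))
    n = len(tips)
    V = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            shared = paths[i] & paths[j]
            V[i, j] = sum(nd.edge.length for nd in shared)
    labels = [leaf.taxon.label for leaf in tips]
    return labels, V


def gls_slope(timetree, x_map, y_map):
    """GLS slope of y on x under the Brownian covariance (with intercept)."""
    labels, V = brownian_covariance(timetree)
    x = np.array([x_map[t] for t in labels])
    y = np.array([y_map[t] for t in labels])
    X = np.column_stack([np.ones_like(x), x])
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    return float(beta[1])
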