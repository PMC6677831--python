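"""Shared fixtures: toy structures and the expensive simulation experiments.

The discrimination and tree-recovery experiments are session-scoped so the
module-level property tests and the acceptance tests evaluate the same run.
"""

import numpy as np
import pytest

from oligodeer.classifier import classify
from oligodeer.deer_inverse import invert_trace
from oligodeer.phylo import distance_matrix, neighbor_joining
from oligodeer.synthetic_data import (
    ToyBundleSpec,
    evolve_sequences,
    make_deer_dataset,
    make_toy_bundle,
    random_additive_tree,
    ring_deer_spec,
)

RING_RADII = {3: 21.36, 5: 15.31, 6: 16.0}


@pytest.fixture(scope="session")
def toy_bundle():
    return make_toy_bundle(ToyBundleSpec(seed=0))


@pytest.fixture(scope="session")
def toy_bundle_flipped():
    return make_toy_bundle(ToyBundleSpec(loop_tip="flipped", seed=0))


@pytest.fixture(scope="session")
def toy_bundle_xr_like():
    """Extended helices + flipped loop + aromatic triad (XR-type features)."""
    return make_toy_bundle(
        ToyBundleSpec(loop_tip="flipped", extend_helices=True,
                      aromatic_triad=True, seed=0)
    )


@pytest.fixture(scope="session")
def discrimination_results():
    """Simulate -> invert -> classify for each oligomer over 20 noise seeds.

    Returns {n: number of seeds in which the true n won}.
    """
    wins = {}
    for n, radius in RING_RADII.items():
        wins[n] = 0
        for seed in range(1, 21):
            trace, _ = make_deer_dataset(ring_deer_spec(n, radius, seed=seed))
            result = invert_trace(trace)
            report = classify([p.position for p in result["peaks"]])
            if report.winner.n == n:
                wins[n] += 1
    return wins


@pytest.fixture(scope="session")
def nj_topology_recovery():
    """NJ recovery of a 6-taxon generating topology from evolved families.

    Returns the number of seeds (of 20) with Robertson-Foulds distance 0.
    """
    import dendropy

    correct = 0
    for seed in range(1, 21):
        tree = random_additive_tree(6, seed=seed, min_branch=0.05, max_branch=0.4)
        aln = evolve_sequences(tree, root_length=5000, seed=seed + 1000)
        inferred = neighbor_joining(distance_matrix(aln), aln.names)
        # compare unrooted topologies on a common taxon namespace
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=tree.as_string(schema="newick"),
                               schema="newick", taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=inferred.as_string(schema="newick"),
                               schema="newick", taxon_namespace=tns)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        rf = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
        if rf == 0:
            correct += 1
    return correct


def brute_force_min_rmsd(a, b, axis_step_deg=2.0, angle_step_deg=2.0):
    """Grid-search oracle for the least-RMSD rigid superposition.

    Scans rotations on an axis-angle grid (Fibonacci hemisphere of axes at
    ~axis_step spacing, full angle sweep) with the optimal translation
    applied analytically (centroid match). Independent of the SVD route.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    step = np.deg2rad(axis_step_deg)
    n_axes = int(np.ceil(2 * np.pi / step**2))
    i = np.arange(n_axes)
    z = (i + 0.5) / n_axes
    phi = np.pi * (1 + 5**0.5) * i
    axes = np.column_stack([
        np.sqrt(1 - z**2) * np.cos(phi),
        np.sqrt(1 - z**2) * np.sin(phi),
        z,
    ])
    angles = np.deg2rad(np.arange(angle_step_deg, 360.0, angle_step_deg))
    best = np.inf
    for ax in np.array_split(axes, max(1, n_axes // 64)):
        k = np.zeros((len(ax), 3, 3))
        k[:, 0, 1] = -ax[:, 2]
        k[:, 0, 2] = ax[:, 1]
        k[:, 1, 0] = ax[:, 2]
        k[:, 1, 2] = -ax[:, 0]
        k[:, 2, 0] = -ax[:, 1]
        k[:, 2, 1] = ax[:, 0]
        k2 = k @ k
        for th in angles:
            rot = np.eye(3) + np.sin(th) * k + (1 - np.cos(th)) * k2
            moved = np.einsum("bij,nj->bni", rot, ac)
            rmsd = np.sqrt(np.mean(np.sum((moved - bc) ** 2, axis=2), axis=1))
            best = min(best, float(rmsd.min()))
    return best
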