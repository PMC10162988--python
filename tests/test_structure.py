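"""Distances, ordination, differentiation and the QC dendrogram."""

import numpy as np
import pandas as pd
import pytest

from popcons.dataset import MISSING
from popcons.io import split_by_locality
from popcons.simulate import (
    LineageSpec,
    LocalitySpec,
    SimConfig,
    simulate_hierarchical_dataset,
)
from popcons.structure import (
    cophenetic_distances,
    pairwise_fst,
    pcoa,
    prevosti_distance,
    upgma_dendrogram,
)

from conftest import hwe_population, make_ds


# --------------------------------------------------------------- Prevosti

def test_prevosti_handworked_values():
    ds = make_ds([[0, 0], [2, 2]])  # identical genotypes
    assert prevosti_distance(ds).iloc[0, 1] == 0.0
    opp = make_ds([[0, 2], [2, 0]])  # opposite homozygotes everywhere
    assert prevosti_distance(opp).iloc[0, 1] == 1.0
    single = make_ds([[0, 1]])  # AA vs AB: 0.5 * (|1-0.5| + |0-0.5|)
    assert prevosti_distance(single).iloc[0, 1] == pytest.approx(0.5)


def test_prevosti_metric_properties():
    rng = np.random.default_rng(0)
    for _ in range(5):
        ds = make_ds(rng.integers(0, 3, size=(40, 8)))
        d = prevosti_distance(ds).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert (d >= 0).all() and (d <= 1).all()
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


def test_prevosti_pairwise_complete_over_missing():
    ds = make_ds([[0, 2], [MISSING, 1], [2, 2]])
    # only loci 0 and 2 are co-called: (1 + 0) / 2
    assert prevosti_distance(ds).iloc[0, 1] == pytest.approx(0.5)


# ------------------------------------------------------------------- PCoA

def test_pcoa_recovers_line_and_pairs():
    x = np.array([0.0, 1.0, 3.0, 7.0])
    d = pd.DataFrame(np.abs(x[:, None] - x[None, :]))
    res = pcoa(d, n_axes=2)
    assert res.percent_variance[0] == pytest.approx(100.0, abs=1e-9)
    # two tight well-separated pairs: first axis dominates
    pts = np.array([[0, 0], [0.05, 0], [10, 0.1], [10.05, 0.05]])
    d2 = pd.DataFrame(np.linalg.norm(pts[:, None] - pts[None, :], axis=-1))
    res2 = pcoa(d2)
    assert res2.percent_variance[0] > 90
    axis1 = res2.coordinates.iloc[:, 0].to_numpy()
    assert (axis1[:2] < axis1[2:].min()).all() or (axis1[:2] > axis1[2:].max()).all()


def test_pcoa_recovers_plane_configuration_up_to_rotation():
    from scipy.linalg import orthogonal_procrustes

    rng = np.random.default_rng(1)
    pts = rng.normal(size=(12, 2))
    pts -= pts.mean(axis=0)
    d = pd.DataFrame(np.linalg.norm(pts[:, None] - pts[None, :], axis=-1))
    res = pcoa(d, n_axes=2)
    coords = res.coordinates.to_numpy()
    rot, _ = orthogonal_procrustes(coords, pts)
    assert np.abs(coords @ rot - pts).max() < 1e-6


def test_pcoa_identical_samples_and_cross_check():
    ds = make_ds([[0, 0, 2], [1, 1, 0], [2, 2, 1]])
    res = pcoa(prevosti_distance(ds))
    np.testing.assert_allclose(
        res.coordinates.iloc[0].to_numpy(), res.coordinates.iloc[1].to_numpy(), atol=1e-6
    )
    # independent cross-check against scikit-bio on a Euclidean matrix
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(2)
    pts = rng.normal(size=(10, 3))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    ours = pcoa(pd.DataFrame(d), n_axes=3)
    theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d))
    np.testing.assert_allclose(
        ours.percent_variance[:3],
        100 * theirs.proportion_explained.to_numpy()[:3],
        atol=1e-6,
    )
    np.testing.assert_allclose(
        np.abs(ours.coordinates.to_numpy()),
        np.abs(theirs.samples.to_numpy()[:, :3]),
        atol=1e-6,
    )


# -------------------------------------------------------------------- FST

def _wc_theta_oracle(pop_counts_a, pop_counts_b):
    """Literal scalar transcription of the two-population Weir-Cockerham
    variance components; input = per-locus (n, p, h_obs) tuples."""
    suma = sumabc = 0.0
    r = 2
    for (n1, p1, h1), (n2, p2, h2) in zip(pop_counts_a, pop_counts_b):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2
        suma += a
        sumabc += a + b + c
    return suma / sumabc


def test_wc_theta_matches_independent_oracle():
    """Multi-locus theta equals the textbook variance-component formulas."""
    # 3-locus toy with explicit genotype columns
    pop1 = make_ds(
        [[0, 1, 1, 2, 2], [0, 0, 1, 1, 1], [2, 2, 1, 0, 1]], localities=["a"] * 5
    )
    pop2 = make_ds([[0, 0, 0, 1], [2, 2, 1, 1], [0, 1, 0, 0]], localities=["b"] * 4)
    res = pairwise_fst({"a": pop1, "b": pop2}, n_bootstrap=0)

    def stats(ds):
        out = []
        for i in range(ds.n_loci):
            x = ds.dosages[i]
            n = len(x)
            out.append((n, x.sum() / (2 * n), np.mean(x == 1)))
        return out

    oracle = _wc_theta_oracle(stats(pop1), stats(pop2))
    assert res.theta.loc["a", "b"] == pytest.approx(oracle, abs=1e-12)


def test_fst_fixed_difference_is_one():
    pop1 = make_ds(np.zeros((20, 6), dtype=np.int8), localities=["a"] * 6)
    pop2 = make_ds(np.full((20, 6), 2, dtype=np.int8), localities=["b"] * 6)
    res = pairwise_fst({"a": pop1, "b": pop2}, n_bootstrap=200, seed=1)
    assert res.theta.loc["a", "b"] == pytest.approx(1.0)
    assert res.p_values.loc["a", "b"] < 0.01


def test_fst_null_two_halves_of_one_population():
    thetas = []
    for seed in range(20):
        ds = hwe_population(40, 3000, seed=seed)
        half = ["a"] * 20 + ["b"] * 20
        ds2 = make_ds(ds.dosages, localities=half)
        pops = split_by_locality(ds2, 2)
        thetas.append(float(pairwise_fst(pops, n_bootstrap=0).theta.loc["a", "b"]))
    inside = [(-0.02 <= t <= 0.02) for t in thetas]
    assert np.mean(inside) >= 0.95


def test_fst_invariant_to_allele_labels_and_population_order():
    ds, _ = simulate_hierarchical_dataset(
        SimConfig(
            n_loci=500,
            lineages=[LineageSpec("l", 0.1)],
            localities=[LocalitySpec("a", "l", 0.1, 10), LocalitySpec("b", "l", 0.1, 12)],
            missing_rate=0.02,
            seed=3,
        )
    )
    pops = split_by_locality(ds, 2)
    base = pairwise_fst(pops, n_bootstrap=0).theta.loc["a", "b"]
    # flip ref/alt labels at a subset of loci
    flipped = {}
    for name, pop in pops.items():
        dos = pop.dosages.copy()
        rows = np.arange(0, dos.shape[0], 2)
        called = dos[rows] != MISSING
        dos[rows] = np.where(called, 2 - dos[rows], MISSING)
        flipped[name] = make_ds(dos, localities=[name] * pop.n_samples)
    assert pairwise_fst(flipped, n_bootstrap=0).theta.loc["a", "b"] == pytest.approx(
        base, abs=1e-12
    )
    reordered = {"b": pops["b"], "a": pops["a"]}
    assert pairwise_fst(reordered, n_bootstrap=0).theta.loc["b", "a"] == pytest.approx(
        base, abs=1e-12
    )


def test_hierarchical_fst_pattern_between_exceeds_within():
    hits = 0
    for seed in range(20):
        cfg = SimConfig(
            n_loci=1500,
            lineages=[LineageSpec("l1", 0.15), LineageSpec("l2", 0.15)],
            localities=[
                LocalitySpec("a1", "l1", 0.03, 12),
                LocalitySpec("a2", "l1", 0.03, 12),
                LocalitySpec("b1", "l2", 0.03, 12),
                LocalitySpec("b2", "l2", 0.03, 12),
            ],
            missing_rate=0.0,
            seed=seed,
        )
        ds, _ = simulate_hierarchical_dataset(cfg)
        theta = pairwise_fst(split_by_locality(ds, 2), n_bootstrap=0).theta
        within = max(theta.loc["a1", "a2"], theta.loc["b1", "b2"])
        between = min(
            theta.loc[x, y] for x in ("a1", "a2") for y in ("b1", "b2")
        )
        hits += between > within
    assert hits >= 19


# ------------------------------------------------------------------ UPGMA

def test_upgma_topologies():
    d = pd.DataFrame(
        [[0, 0.1, 0.5], [0.1, 0, 0.5], [0.5, 0.5, 0]],
        index=["s1", "s2", "s3"],
        columns=["s1", "s2", "s3"],
    )
    import re

    nwk = upgma_dendrogram(d)
    # s1 and s2 form the cherry; s3 joins outside it
    assert re.search(r"\(s[12]:[^()]*,s[12]:[^()]*\)", nwk)
    # duplicate pair in a noisy background forms a cherry
    rng = np.random.default_rng(4)
    ds = make_ds(np.column_stack([c := rng.integers(0, 3, 50), c, rng.integers(0, 3, (50, 4))]))
    nwk2 = upgma_dendrogram(prevosti_distance(ds))
    assert "(S0:0,S1:0)" in nwk2 or "(S1:0,S0:0)" in nwk2


def test_upgma_exact_on_ultrametric_input():
    labels = list("abcd")
    d = pd.DataFrame(
        [
            [0.0, 0.2, 0.8, 0.8],
            [0.2, 0.0, 0.8, 0.8],
            [0.8, 0.8, 0.0, 0.3],
            [0.8, 0.8, 0.3, 0.0],
        ],
        index=labels,
        columns=labels,
    )
    coph = cophenetic_distances(dist=d)
    np.testing.assert_allclose(coph.to_numpy(), d.to_numpy(), atol=1e-9)
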