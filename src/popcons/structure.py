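"""Genetic distances, ordination and differentiation.

* Prevosti distance between individuals: half the mean absolute difference
  in within-individual allele frequencies over co-called loci (for biallelic
  dosages this is ``|x_i - x_j| / 2`` averaged over loci).
* Classical principal-coordinate analysis of that distance matrix, with
  percent variance per axis relative to the sum of positive eigenvalues.
* Pairwise Weir–Cockerham theta (F_ST) between populations, aggregated as a
  ratio of sums of the among/total variance components over loci, with
  locus-bootstrap significance.
* UPGMA dendrogram (Newick) used for the technical-replicate sanity check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .dataset import DatasetError, GenotypeDataset


def prevosti_distance(ds: GenotypeDataset) -> pd.DataFrame:
    """Sample-by-sample Prevosti distance matrix (entries in [0, 1]).

    Pairs with no co-called locus get NaN.
    """
    if ds.n_samples < 2:
        raise DatasetError("need >= 2 samples")
    called = ds.called.astype(np.float64)
    x = np.where(ds.called, ds.dosages, 0).astype(np.float64)
    n = ds.n_samples
    dist = np.zeros((n, n))
    # |x_i - x_j| / 2 averaged over co-called loci
    for i in range(n):
        diff = np.abs(x[:, i : i + 1] - x[:, i:]) / 2.0
        ok = called[:, i : i + 1] * called[:, i:]
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(ok.sum(axis=0) > 0, (diff * ok).sum(axis=0) / ok.sum(axis=0), np.nan)
        dist[i, i:] = d
        dist[i:, i] = d
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=ds.sample_ids, columns=ds.sample_ids)


@dataclass
class PcoaResult:
    """Principal-coordinate scores and per-axis percent variance."""

    coordinates: pd.DataFrame  # samples x axes
    percent_variance: np.ndarray
    eigenvalues: np.ndarray


def pcoa(dist: pd.DataFrame, n_axes: int = 2) -> PcoaResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    The squared-distance matrix is double-centred, eigendecomposed, and
    coordinates scaled by the square root of each (non-negative) eigenvalue.
    Percent variance per axis is its eigenvalue over the sum of positive
    eigenvalues.
    """
    d = np.asarray(dist, dtype=float)
    if np.isnan(d).any():
        raise DatasetError("distance matrix has undefined entries")
    if not np.allclose(d, d.T):
        raise DatasetError("distance matrix must be symmetric")
    if np.allclose(d, 0):
        raise DatasetError("all-zero distance matrix")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos_sum = eigvals[eigvals > 0].sum()
    n_axes = min(n_axes, n)
    coords = eigvecs[:, :n_axes] * np.sqrt(np.maximum(eigvals[:n_axes], 0.0))
    percent = 100.0 * np.maximum(eigvals[:n_axes], 0.0) / pos_sum
    labels = list(dist.index) if isinstance(dist, pd.DataFrame) else list(range(n))
    return PcoaResult(
        coordinates=pd.DataFrame(
            coords, index=labels, columns=[f"PCo{k + 1}" for k in range(n_axes)]
        ),
        percent_variance=percent,
        eigenvalues=eigvals,
    )


def _wc_components(
    pop_a: GenotypeDataset, pop_b: GenotypeDataset
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus Weir–Cockerham among-population (a) and total (a+b+c)
    variance components for two populations; NaN where undefined."""
    r = 2.0
    stats = []
    for pop in (pop_a, pop_b):
        called = pop.called
        n = called.sum(axis=1).astype(float)
        alt = np.where(called, pop.dosages, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / np.maximum(2 * n, 1), np.nan)
            h = np.where(n > 0, (pop.dosages == 1).sum(axis=1) / np.maximum(n, 1), np.nan)
        stats.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = stats
    valid = (n1 >= 1) & (n2 >= 1) & (n1 + n2 > 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = (n1 + n2) / r
        n_c = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (n1 + n2)
        inner = p_bar * (1 - p_bar) - ((r - 1) / r) * s2
        a = (n_bar / n_c) * (s2 - (inner - h_bar / 4) / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (inner - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar)
        c = h_bar / 2
        total = a + b + c
    a = np.where(valid & (n_c > 0), a, np.nan)
    total = np.where(valid & (n_c > 0), total, np.nan)
    return a, total


@dataclass
class FstResult:
    """Pairwise multi-locus Weir–Cockerham theta and bootstrap p-values."""

    theta: pd.DataFrame
    p_values: pd.DataFrame
    n_bootstrap: int

    def to_table(self) -> pd.DataFrame:
        """Lower triangle theta, upper triangle p-values (presentation form)."""
        out = self.theta.copy()
        names = list(out.index)
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if j > i:
                    out.loc[a, b] = self.p_values.loc[a, b]
                elif j == i:
                    out.loc[a, b] = 0.0
        return out


def pairwise_fst(
    populations: dict[str, GenotypeDataset],
    n_bootstrap: int = 1000,
    seed: int = 0,
    alternative: str = "theta_le_zero",
) -> FstResult:
    """Pairwise Weir–Cockerham theta with locus-bootstrap significance.

    Theta per pair is the ratio of sums over loci of the among-population
    variance component to the total. Significance: loci are resampled with
    replacement ``n_bootstrap`` times and the one-sided p-value is the
    fraction of replicates with theta <= 0 (``alternative="ci_excludes_zero"``
    instead reports twice the smaller tail of the replicate distribution
    around zero).
    """
    names = list(populations)
    for name, pop in populations.items():
        if pop.n_samples < 2:
            raise DatasetError(f"population {name}: needs >= 2 samples for FST")
    k = len(names)
    theta = np.zeros((k, k))
    pvals = np.zeros((k, k))
    rng = np.random.default_rng(seed)
    for i in range(k):
        for j in range(i + 1, k):
            a, total = _wc_components(populations[names[i]], populations[names[j]])
            ok = np.isfinite(a) & np.isfinite(total)
            a, total = a[ok], total[ok]
            if a.size == 0:
                raise DatasetError(f"no usable loci for pair {names[i]}/{names[j]}")
            t = a.sum() / total.sum()
            theta[i, j] = theta[j, i] = t
            if n_bootstrap > 0:
                idx = rng.integers(a.size, size=(n_bootstrap, a.size))
                with np.errstate(invalid="ignore", divide="ignore"):
                    reps = a[idx].sum(axis=1) / total[idx].sum(axis=1)
                if alternative == "ci_excludes_zero":
                    lower = np.mean(reps <= 0)
                    p = min(1.0, 2 * min(lower, 1 - lower))
                else:
                    p = float(np.mean(reps <= 0))
                pvals[i, j] = pvals[j, i] = p
    return FstResult(
        theta=pd.DataFrame(theta, index=names, columns=names),
        p_values=pd.DataFrame(pvals, index=names, columns=names),
        n_bootstrap=n_bootstrap,
    )


def upgma_dendrogram(dist: pd.DataFrame) -> str:
    """Average-linkage (UPGMA) tree of a distance matrix, as Newick text."""
    d = np.asarray(dist, dtype=float)
    if np.isnan(d).any():
        raise DatasetError("distance matrix has undefined entries")
    labels = [str(x) for x in dist.index]
    linkage = hierarchy.average(squareform(d, checks=False))
    root = hierarchy.to_tree(linkage)

    def newick(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = node.get_left(), node.get_right()
        bl_l = node.dist / 2 - (left.dist / 2 if not left.is_leaf() else 0)
        bl_r = node.dist / 2 - (right.dist / 2 if not right.is_leaf() else 0)
        return f"({newick(left)}:{bl_l:.6g},{newick(right)}:{bl_r:.6g})"

    return newick(root) + ";"


def cophenetic_distances(newick: str | None = None, dist: pd.DataFrame | None = None):
    """Cophenetic distance matrix of the UPGMA tree built from ``dist``."""
    if dist is None:
        raise DatasetError("dist is required")
    d = np.asarray(dist, dtype=float)
    linkage = hierarchy.average(squareform(d, checks=False))
    coph = hierarchy.cophenet(linkage)
    return pd.DataFrame(squareform(coph), index=dist.index, columns=dist.columns)
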