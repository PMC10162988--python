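"""Effective-population-size trajectories from LD decay with distance.

Under drift-recombination equilibrium the expected squared correlation
between loci at recombination fraction c is approximately
``E[r2] = 1 / (alpha + 4 Ne c)`` (alpha = 2.2 with the mutation-rate
modifier; alpha = 1 without), and pairs at recombination fraction c reflect
the effective size roughly ``t = 1 / (2c)`` generations ago. Binning locus
pairs by c and inverting the relationship per bin therefore traces recent Ne
through time:

``Ne(bin) = (1 / (4 f(c_mean))) * (1 / mean_adj_r2 - alpha)``, f(c) = c.

Sampled r2 is inflated by finite sample size; the unphased-genotype
correction subtracts 1/n (n = co-called individuals of a pair) before
binning. Physical distance maps to c through a uniform recombination rate
(default 1 cM/Mb). Uncertainty comes from an individual-dropout bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import MISSING, DatasetError, GenotypeDataset

DEFAULT_ALPHA = 2.2  # Sved & Feldman mutation-rate modifier; 1.0 = drift only
DEFAULT_BIN_RANGE = (0.0005, 0.25)
DEFAULT_N_BINS = 8


def pairwise_ld(
    ds_pop: GenotypeDataset,
    maf: float = 0.05,
    recomb_rate_per_bp: float = 1e-8,
    c_max: float = 0.25,
    min_callrate: float = 0.5,
) -> pd.DataFrame:
    """All same-scaffold locus-pair (c, adjusted r2) values for one population.

    Loci are pre-filtered to within-population MAF >= ``maf`` and call rate
    >= ``min_callrate``. For each retained same-scaffold pair with
    recombination fraction ``c = bp_distance * recomb_rate_per_bp <= c_max``,
    r2 is the squared Pearson correlation of dosages over co-called samples
    and the returned value is ``r2 - 1/n`` (n = co-called individuals).
    """
    freq = ds_pop.allele_frequencies()
    callrate = ds_pop.called.mean(axis=1)
    with np.errstate(invalid="ignore"):
        keep = (
            np.isfinite(freq)
            & (np.minimum(freq, 1 - freq) >= maf)
            & (callrate >= min_callrate)
        )
    idx = np.nonzero(keep)[0]
    if idx.size < 2:
        raise DatasetError("fewer than 2 loci pass the MAF/call-rate filters")
    sub = ds_pop.take_loci(idx)
    out_c: list[np.ndarray] = []
    out_r2: list[np.ndarray] = []
    out_n: list[np.ndarray] = []
    scaffolds: dict[str, list[int]] = {}
    for i, loc in enumerate(sub.loci):
        scaffolds.setdefault(loc.scaffold, []).append(i)
    for rows in scaffolds.values():
        if len(rows) < 2:
            continue
        rows_arr = np.array(rows)
        pos = np.array([sub.loci[i].position for i in rows], dtype=np.int64)
        block = sub.dosages[rows_arr, :]
        called = block != MISSING
        fully_called = bool(called.all())
        if fully_called:
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = np.corrcoef(block.astype(float))
        for a in range(len(rows)):
            dist_bp = pos[a + 1 :] - pos[a]
            c = dist_bp * recomb_rate_per_bp
            ok = c <= c_max
            if not ok.any():
                continue
            bs = np.nonzero(ok)[0] + a + 1
            if fully_called:
                r2 = corr[a, bs] ** 2
                n_pair = np.full(bs.size, block.shape[1], dtype=float)
            else:
                r2 = np.empty(bs.size)
                n_pair = np.empty(bs.size)
                for k, b in enumerate(bs):
                    shared = called[a] & called[b]
                    n_pair[k] = shared.sum()
                    if n_pair[k] < 2:
                        r2[k] = np.nan
                        continue
                    xa = block[a, shared].astype(float)
                    xb = block[b, shared].astype(float)
                    if xa.std() == 0 or xb.std() == 0:
                        r2[k] = np.nan
                    else:
                        r2[k] = np.corrcoef(xa, xb)[0, 1] ** 2
            out_c.append(c[ok])
            out_r2.append(r2 - 1.0 / n_pair)
            out_n.append(n_pair)
    if not out_c:
        raise DatasetError("no locus pairs within c_max on any scaffold")
    table = pd.DataFrame(
        {
            "c": np.concatenate(out_c),
            "r2_adj": np.concatenate(out_r2),
            "n_pair": np.concatenate(out_n),
        }
    )
    return table.dropna(subset=["r2_adj"]).reset_index(drop=True)


@dataclass
class NeTrajectory:
    """Binned Ne-through-time estimates for one population."""

    population: str
    table: pd.DataFrame  # columns: c_mean, t_generations, t_years, mean_r2_adj, n_pairs, Ne
    replicates: list[pd.DataFrame] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    def envelope(self) -> pd.DataFrame:
        """Per-bin min/median/max Ne over bootstrap replicates."""
        if not self.replicates:
            raise DatasetError("no bootstrap replicates")
        merged = pd.concat(
            [rep.assign(rep=k) for k, rep in enumerate(self.replicates)], ignore_index=True
        )
        agg = merged.groupby("bin")["Ne"].agg(["min", "median", "max"])
        return self.table.set_index("bin").join(agg, how="left").reset_index()


def _log_bins(low: float, high: float, n_bins: int) -> np.ndarray:
    return np.geomspace(low, high, n_bins + 1)


def estimate_trajectory(
    pairs: pd.DataFrame,
    bins: np.ndarray | None = None,
    alpha: float = DEFAULT_ALPHA,
    min_pairs: int = 50,
    population: str = "",
) -> NeTrajectory:
    """Invert binned mean adjusted r2 to an Ne point estimate per bin.

    Bins with fewer than ``min_pairs`` pairs are merged with their right
    neighbour; bins whose implied Ne is non-positive (mean adjusted
    r2 >= 1/alpha) are dropped.
    """
    if bins is None:
        bins = _log_bins(*DEFAULT_BIN_RANGE, DEFAULT_N_BINS)
    bins = np.asarray(bins, dtype=float)
    c = pairs["c"].to_numpy()
    r2 = pairs["r2_adj"].to_numpy()
    which = np.digitize(c, bins) - 1
    members: list[np.ndarray] = []
    for b in range(len(bins) - 1):
        members.append(np.nonzero(which == b)[0])
    # merge thin bins rightward
    merged: list[np.ndarray] = []
    carry = np.array([], dtype=int)
    for m in members:
        cur = np.concatenate([carry, m])
        if cur.size >= min_pairs:
            merged.append(cur)
            carry = np.array([], dtype=int)
        else:
            carry = cur
    if carry.size:
        if merged:
            merged[-1] = np.concatenate([merged[-1], carry])
        elif carry.size >= 2:
            merged.append(carry)
    if not merged:
        raise DatasetError("no bin reaches min_pairs")
    rows = []
    for k, m in enumerate(merged):
        c_mean = float(np.mean(c[m]))
        r2_mean = float(np.mean(r2[m]))
        if r2_mean <= 0:
            continue
        ne = (1.0 / (4.0 * c_mean)) * (1.0 / r2_mean - alpha)
        if ne < 1e-6:
            continue  # LD at/below the alpha floor carries no Ne signal
        rows.append(
            {
                "bin": k,
                "c_mean": c_mean,
                "t_generations": 1.0 / (2.0 * c_mean),
                "t_years": np.nan,
                "mean_r2_adj": r2_mean,
                "n_pairs": int(m.size),
                "Ne": ne,
            }
        )
    if not rows:
        raise DatasetError("every bin was dropped (no positive Ne estimate)")
    return NeTrajectory(
        population=population,
        table=pd.DataFrame(rows),
        parameters={"alpha": alpha, "min_pairs": min_pairs, "bins": bins.tolist()},
    )


def scale_to_years(traj: NeTrajectory, generation_time: float = 1.95) -> NeTrajectory:
    """Convert bin ages from generations to years in place and return traj."""
    if generation_time <= 0:
        raise DatasetError("generation_time must be positive")
    traj.table["t_years"] = traj.table["t_generations"] * generation_time
    for rep in traj.replicates:
        rep["t_years"] = rep["t_generations"] * generation_time
    traj.parameters["generation_time"] = generation_time
    return traj


def ld_ne_trajectory(
    ds_pop: GenotypeDataset,
    population: str = "",
    maf: float = 0.05,
    recomb_rate_per_bp: float = 1e-8,
    c_max: float = 0.25,
    alpha: float = DEFAULT_ALPHA,
    min_pairs: int = 50,
    bins: np.ndarray | None = None,
    generation_time: float = 1.95,
) -> NeTrajectory:
    """Point-estimate trajectory for one population (LD scan + inversion)."""
    pairs = pairwise_ld(ds_pop, maf=maf, recomb_rate_per_bp=recomb_rate_per_bp, c_max=c_max)
    traj = estimate_trajectory(
        pairs, bins=bins, alpha=alpha, min_pairs=min_pairs, population=population
    )
    return scale_to_years(traj, generation_time)


def bootstrap_trajectory(
    ds_pop: GenotypeDataset,
    population: str = "",
    drop_frac: float = 0.1,
    reps: int = 10,
    seed: int = 0,
    **kwargs,
) -> NeTrajectory:
    """Individual-dropout bootstrap around the point-estimate trajectory.

    Each replicate removes ``max(1, round(drop_frac * n))`` individuals at
    random (none when drop_frac = 0) and re-estimates; the replicate tables
    are attached to the returned trajectory.
    """
    import math

    n = ds_pop.n_samples
    n_drop = 0 if drop_frac == 0 else max(1, int(round(drop_frac * n)))
    if math.ceil((1 - drop_frac) * n) < 5:
        raise DatasetError(
            f"population too small to bootstrap: ceil((1-{drop_frac})*n) must be >= 5, n={n}"
        )
    traj = ld_ne_trajectory(ds_pop, population=population, **kwargs)
    rng = np.random.default_rng(seed)
    for _ in range(reps):
        keep = np.sort(rng.choice(n, size=n - n_drop, replace=False)) if n_drop else np.arange(n)
        sub = ds_pop.take_samples(keep)
        rep = ld_ne_trajectory(sub, population=population, **kwargs)
        traj.replicates.append(rep.table)
    traj.parameters.update({"drop_frac": drop_frac, "reps": reps, "seed": seed})
    return traj
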