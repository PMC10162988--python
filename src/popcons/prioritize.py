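"""Allele-based conservation prioritisation of populations.

Two complementary views of how much each population matters for the species'
genomic diversity:

* Leave-one-out contributions to rarefied allelic richness (AR). AR at a
  locus is the expected number of alleles in a random draw of g gene copies
  (hypergeometric rarefaction, default g = 10), which removes the
  sample-size dependence of raw allele counts. Pooling all populations
  gives AR(t); removing population i gives AR(-i); the contribution of i is
  ``(AR(t) - AR(-i)) / (AR(t) - 1)``, normalising the loss by the
  polymorphic excess above the monomorphic floor of 1.
* Resampled maximum-coverage selection. Treating each allele as a feature
  and each population as a unit of cost 1, the optimal set of populations of
  a given budget maximises the number of alleles present in at least one
  chosen population. Drawing a fixed number of individuals per population
  per iteration removes sample-size advantage; tallies over iterations show
  how stable each optimum is.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .dataset import DatasetError, GenotypeDataset


def _log_comb(n: np.ndarray, g: int) -> np.ndarray:
    return gammaln(n + 1) - gammaln(g + 1) - gammaln(n - g + 1)


def rarefaction_curve(alt: np.ndarray, copies: np.ndarray, g: int) -> np.ndarray:
    """Per-locus rarefied allele count at g gene copies.

    ``AR_g = sum_a [1 - C(N - N_a, g) / C(N, g)]`` over the two alleles with
    copy counts ``N_a`` of ``N = copies`` total. Loci with fewer than g
    called copies return NaN.
    """
    alt = np.asarray(alt, dtype=float)
    copies = np.asarray(copies, dtype=float)
    ar = np.full(alt.shape, np.nan)
    ok = copies >= g
    log_cn = _log_comb(copies[ok], g)
    total = np.zeros(ok.sum())
    for count in (alt[ok], copies[ok] - alt[ok]):
        rest = copies[ok] - count
        miss_prob = np.where(rest >= g, np.exp(_log_comb(np.maximum(rest, g), g) - log_cn), 0.0)
        # allele absent from the population contributes 0, not 1
        total += np.where(count > 0, 1.0 - miss_prob, 0.0)
    ar[ok] = total
    return ar


def rarefied_allelic_richness(
    populations: dict[str, GenotypeDataset], g: int = 10
) -> pd.DataFrame:
    """Mean and SD over loci of rarefied allelic richness per population.

    Loci with fewer than g called gene copies in any population are excluded
    (the count is reported), so every population is rarefied on the same
    locus set.
    """
    if g < 2:
        raise DatasetError("g must be >= 2")
    counts = {}
    eligible = None
    for name, pop in populations.items():
        alt, copies = pop.alt_counts()
        counts[name] = (alt, copies)
        mask = copies >= g
        eligible = mask if eligible is None else (eligible & mask)
    if eligible is None or not eligible.any():
        raise DatasetError(f"no locus has >= {g} called gene copies in every population")
    rows = []
    for name, (alt, copies) in counts.items():
        ar = rarefaction_curve(alt[eligible], copies[eligible], g)
        rows.append(
            {
                "population": name,
                "mean_AR": float(np.nanmean(ar)),
                "SD_AR": float(np.nanstd(ar, ddof=1)),
                "n_loci": int(eligible.sum()),
            }
        )
    return pd.DataFrame(rows).set_index("population")


@dataclass
class ARResult:
    """Pooled rarefied allelic richness and leave-one-out contributions."""

    per_population: pd.DataFrame  # mean_AR, SD_AR
    ar_total: float
    ar_minus: dict[str, float]
    contribution: dict[str, float]
    g: int

    def to_frame(self) -> pd.DataFrame:
        out = self.per_population.copy()
        out["AR_minus_i"] = pd.Series(self.ar_minus)
        out["contribution"] = pd.Series(self.contribution)
        return out


def loo_contribution(
    populations: dict[str, GenotypeDataset],
    g: int = 10,
    normalisation: str = "monomorphic_floor",
) -> ARResult:
    """Leave-one-out contribution of each population to pooled rarefied AR.

    AR(t) treats all genotyped individuals as one collection; AR(-i) removes
    population i. The default contribution is
    ``(AR(t) - AR(-i)) / (AR(t) - 1)``; ``normalisation="total"`` divides by
    AR(t) instead. The locus set is fixed to loci with >= g called copies in
    every leave-one-out pool, so all AR values are comparable.
    """
    names = list(populations)
    if len(names) < 2:
        raise DatasetError("need >= 2 populations")
    per_pop = {name: populations[name].alt_counts() for name in names}

    def pool(exclude: str | None) -> tuple[np.ndarray, np.ndarray]:
        keys = [n for n in names if n != exclude]
        alt = np.sum([per_pop[k][0] for k in keys], axis=0)
        copies = np.sum([per_pop[k][1] for k in keys], axis=0)
        return alt, copies

    counts = {"__total__": pool(None)}
    for name in names:
        counts[name] = pool(name)
    eligible = None
    for alt, copies in counts.values():
        mask = copies >= g
        eligible = mask if eligible is None else (eligible & mask)
    if not eligible.any():
        raise DatasetError(f"no locus has >= {g} called copies in every leave-one-out pool")

    def mean_ar(key: str) -> float:
        alt, copies = counts[key]
        return float(np.nanmean(rarefaction_curve(alt[eligible], copies[eligible], g)))

    ar_total = mean_ar("__total__")
    if ar_total <= 1.0:
        raise DatasetError("pooled dataset is monomorphic; contributions undefined")
    denom = (ar_total - 1.0) if normalisation == "monomorphic_floor" else ar_total
    ar_minus = {name: mean_ar(name) for name in names}
    contribution = {name: (ar_total - ar_minus[name]) / denom for name in names}
    return ARResult(
        per_population=rarefied_allelic_richness(populations, g=g),
        ar_total=ar_total,
        ar_minus=ar_minus,
        contribution=contribution,
        g=g,
    )


@dataclass
class CoverageSolution:
    """Optimal population subsets for one budget of the max-coverage problem."""

    budget: int
    chosen_sets: list[tuple[str, ...]]  # all tied optima
    alleles_covered: int
    total_alleles: int
    tally: dict[tuple[str, ...], float] = field(default_factory=dict)
    mean_proportion: float = np.nan
    mean_ar_union: float = np.nan

    @property
    def proportion_of_total(self) -> float:
        return self.alleles_covered / self.total_alleles if self.total_alleles else np.nan


def max_coverage_exact(
    incidence: pd.DataFrame, budget: int, max_exhaustive: int = 20
) -> CoverageSolution:
    """Exhaustively optimal subset(s) of populations covering most alleles.

    ``incidence`` is an allele-by-population boolean matrix (an allele is
    covered when present in at least one chosen population). All tied optima
    are returned. Instances with more than ``max_exhaustive`` populations
    fall back to greedy forward selection.
    """
    if incidence.size == 0:
        raise DatasetError("empty incidence matrix")
    pops = list(incidence.columns)
    if not (1 <= budget <= len(pops)):
        raise DatasetError(f"budget must be in [1, {len(pops)}]")
    mat = incidence.to_numpy(dtype=bool)
    total = int(mat.any(axis=1).sum())
    if len(pops) <= max_exhaustive:
        best_sets: list[tuple[str, ...]] = []
        best = -1
        for combo in itertools.combinations(range(len(pops)), budget):
            covered = int(mat[:, combo].any(axis=1).sum())
            if covered > best:
                best, best_sets = covered, [tuple(pops[i] for i in combo)]
            elif covered == best:
                best_sets.append(tuple(pops[i] for i in combo))
    else:  # greedy fallback, logged approximation
        chosen: list[int] = []
        covered_mask = np.zeros(mat.shape[0], dtype=bool)
        for _ in range(budget):
            gains = [
                (mat[:, j] & ~covered_mask).sum() if j not in chosen else -1
                for j in range(len(pops))
            ]
            j = int(np.argmax(gains))
            chosen.append(j)
            covered_mask |= mat[:, j]
        best = int(covered_mask.sum())
        best_sets = [tuple(pops[i] for i in sorted(chosen))]
    return CoverageSolution(
        budget=budget, chosen_sets=best_sets, alleles_covered=best, total_alleles=total
    )


def _incidence_from_draw(draws: dict[str, GenotypeDataset]) -> pd.DataFrame:
    """Allele-by-population presence matrix from drawn samples.

    Each biallelic locus contributes two allele features (ref, alt); an
    allele is present in a population when its observed copy count among the
    drawn individuals is > 0.
    """
    cols = {}
    for name, pop in draws.items():
        alt, copies = pop.alt_counts()
        ref = copies - alt
        cols[name] = np.concatenate([ref > 0, alt > 0])
    first = next(iter(draws.values()))
    index = [f"{lid}:ref" for lid in first.locus_ids] + [
        f"{lid}:alt" for lid in first.locus_ids
    ]
    return pd.DataFrame(cols, index=index)


def prioritize_resampled(
    populations: dict[str, GenotypeDataset],
    n_per_pop: int = 4,
    reps: int = 100,
    budgets: tuple[int, ...] = (1, 2, 3, 4),
    g: int = 10,
    seed: int = 0,
) -> dict[int, CoverageSolution]:
    """Resampled maximum-coverage prioritisation across budgets.

    Per iteration, ``n_per_pop`` individuals are drawn per population without
    replacement, the allele incidence matrix is rebuilt from the draw, and
    the exact max-coverage optimum is found per budget. Ties split an
    iteration's tally weight equally so per-budget tallies sum to ``reps``.
    Coverage proportions are relative to the iteration's own total observed
    allele count; AR of the union of chosen populations' drawn samples is
    rarefied at g.
    """
    names = list(populations)
    for name, pop in populations.items():
        if pop.n_samples < n_per_pop:
            raise DatasetError(f"population {name}: fewer than {n_per_pop} samples")
    rng = np.random.default_rng(seed)
    tallies: dict[int, dict[tuple[str, ...], float]] = {b: {} for b in budgets}
    proportions: dict[int, list[float]] = {b: [] for b in budgets}
    ar_unions: dict[int, list[float]] = {b: [] for b in budgets}
    covered_counts: dict[int, list[int]] = {b: [] for b in budgets}
    totals: list[int] = []
    for _ in range(reps):
        draws = {
            name: pop.take_samples(
                np.sort(rng.choice(pop.n_samples, size=n_per_pop, replace=False))
            )
            for name, pop in populations.items()
        }
        incidence = _incidence_from_draw(draws)
        totals.append(int(incidence.to_numpy().any(axis=1).sum()))
        for b in budgets:
            sol = max_coverage_exact(incidence, b)
            weight = 1.0 / len(sol.chosen_sets)
            for s in sol.chosen_sets:
                key = tuple(sorted(s))
                tallies[b][key] = tallies[b].get(key, 0.0) + weight
            proportions[b].append(sol.proportion_of_total)
            covered_counts[b].append(sol.alleles_covered)
            rep_set = sol.chosen_sets[0]
            union_counts = [draws[n].alt_counts() for n in rep_set]
            alt = np.sum([c[0] for c in union_counts], axis=0)
            copies = np.sum([c[1] for c in union_counts], axis=0)
            # a small union cannot be rarefied to g copies; cap at its size
            g_union = min(g, 2 * n_per_pop * b)
            ar = rarefaction_curve(alt, copies, g_union)
            ar_unions[b].append(float(np.nanmean(ar)))
    out: dict[int, CoverageSolution] = {}
    for b in budgets:
        out[b] = CoverageSolution(
            budget=b,
            chosen_sets=sorted(tallies[b], key=tallies[b].get, reverse=True),
            alleles_covered=int(round(float(np.mean(covered_counts[b])))),
            total_alleles=int(round(float(np.mean(totals)))),
            tally=dict(sorted(tallies[b].items(), key=lambda kv: -kv[1])),
            mean_proportion=float(np.mean(proportions[b])),
            mean_ar_union=float(np.mean(ar_unions[b])),
        )
    return out


def coverage_table(solutions: dict[int, CoverageSolution]) -> pd.DataFrame:
    """Flat per-budget, per-configuration summary of a resampled run."""
    rows = []
    for b, sol in solutions.items():
        for subset, weight in sol.tally.items():
            rows.append(
                {
                    "budget": b,
                    "configuration": "+".join(subset),
                    "tally": weight,
                    "mean_proportion_of_alleles": sol.mean_proportion,
                    "mean_AR_conserved": sol.mean_ar_union,
                }
            )
    return pd.DataFrame(rows)
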