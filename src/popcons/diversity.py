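"""Per-population diversity accounting.

For each population the module reports, averaged over SNP loci with standard
errors: observed allele count A, effective allele number A_E = 1 / sum(p_a^2),
observed heterozygosity H_O, expected heterozygosity H_E with Nei's unbiased
small-sample factor 2n/(2n - 1), and the fixation index
F_IS = 1 - H_O / H_E averaged over polymorphic loci. SNP-panel
heterozygosities are conditioned on variant sites and therefore inflated by
ascertainment; :func:`autosomal_heterozygosity` removes that bias by spreading
the heterozygosity over all callable sites (variant plus invariant), the
scale on which per-site diversity is conventionally reported (x1000 for
display).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataset import DatasetError, GenotypeDataset


def _locus_stats(pop: GenotypeDataset, unbiased: bool = True):
    """Per-locus n_called, p-hat, A, A_E, H_O, H_E within one population."""
    called = pop.called
    n_called = called.sum(axis=1)
    alt = np.where(called, pop.dosages, 0).sum(axis=1)
    copies = 2 * n_called
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(copies > 0, alt / np.maximum(copies, 1), np.nan)
        het = (pop.dosages == 1).sum(axis=1)
        h_o = np.where(n_called > 0, het / np.maximum(n_called, 1), np.nan)
    a = np.where((alt > 0) & (alt < copies), 2.0, 1.0)
    a[copies == 0] = np.nan
    homozygosity = p**2 + (1 - p) ** 2
    a_e = 1.0 / homozygosity
    h_e = 2 * p * (1 - p)
    if unbiased:
        with np.errstate(invalid="ignore", divide="ignore"):
            h_e = h_e * copies / np.maximum(copies - 1, 1)
        h_e[copies < 2] = np.nan
    return n_called, p, a, a_e, h_o, h_e


def _mean_se(x: np.ndarray) -> tuple[float, float]:
    x = x[np.isfinite(x)]
    if x.size == 0:
        return np.nan, np.nan
    se = float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else np.nan
    return float(np.mean(x)), se


def allele_frequencies(
    ds: GenotypeDataset, populations: dict[str, GenotypeDataset]
) -> pd.DataFrame:
    """Per-population per-locus alt-allele frequency and called copy count.

    Frequencies are over called gene copies only; loci with no called copy in
    a population are NaN.
    """
    frames = {}
    for name, pop in populations.items():
        alt, copies = pop.alt_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(copies > 0, alt / np.maximum(copies, 1), np.nan)
        frames[(name, "freq")] = freq
        frames[(name, "copies")] = copies
    out = pd.DataFrame(frames, index=ds.locus_ids)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["population", "stat"])
    return out


def per_population_diversity(
    populations: dict[str, GenotypeDataset],
    unbiased: bool = True,
    fis_per_locus: bool = True,
) -> pd.DataFrame:
    """Mean SNP diversity metrics (with SEs over loci) for each population.

    ``unbiased`` applies Nei's 2n/(2n-1) small-sample factor to H_E.
    ``fis_per_locus`` averages 1 - H_O/H_E over polymorphic loci; when False
    the ratio-of-means form 1 - mean(H_O)/mean(H_E) is used instead.
    """
    rows = []
    for name, pop in populations.items():
        if pop.n_samples < 2:
            raise DatasetError(f"population {name}: needs >= 2 samples")
        n_called, _, a, a_e, h_o, h_e = _locus_stats(pop, unbiased=unbiased)
        if not (n_called >= 2).any():
            raise DatasetError(f"population {name}: fewer than 2 called samples at all loci")
        a_mean, a_se = _mean_se(a)
        ae_mean, ae_se = _mean_se(a_e)
        he_mean, he_se = _mean_se(h_e)
        ho_mean, ho_se = _mean_se(h_o)
        poly = np.isfinite(h_e) & (h_e > 0) & np.isfinite(h_o)
        if fis_per_locus:
            fis = 1.0 - h_o[poly] / h_e[poly]
            fis_mean, fis_se = _mean_se(fis)
        else:
            fis_mean = 1.0 - np.nanmean(h_o[poly]) / np.nanmean(h_e[poly])
            fis_se = np.nan
        rows.append(
            {
                "population": name,
                "n": pop.n_samples,
                "A": a_mean,
                "A_SE": a_se,
                "A_E": ae_mean,
                "A_E_SE": ae_se,
                "H_E": he_mean,
                "H_E_SE": he_se,
                "H_O": ho_mean,
                "H_O_SE": ho_se,
                "F_IS": fis_mean,
                "F_IS_SE": fis_se,
            }
        )
    return pd.DataFrame(rows).set_index("population")


def autosomal_heterozygosity(
    populations: dict[str, GenotypeDataset],
    callable_sites: int | dict[str, int],
    unbiased: bool = True,
    display_scale: float = 1.0,
) -> pd.DataFrame:
    """Observed/expected per-site heterozygosity over all callable sites.

    ``callable_sites`` is the number of genotyped nucleotide positions
    (variant + invariant) per population, or one global count. Invariant
    sites contribute zero heterozygosity but enter the denominator, removing
    the ascertainment bias of SNP-only panels. Set ``display_scale=1000``
    for the conventional x1000 display scale.
    """
    rows = []
    for name, pop in populations.items():
        sites = callable_sites[name] if isinstance(callable_sites, dict) else callable_sites
        if sites < pop.n_loci:
            raise DatasetError(
                f"population {name}: callable_sites ({sites}) < variant loci ({pop.n_loci})"
            )
        called = pop.called
        n_called_entries = int(called.sum())
        n_het = int((pop.dosages == 1).sum())
        # invariant sites are taken as called in every sample
        total_obs = pop.n_samples * sites - (pop.n_loci * pop.n_samples - n_called_entries)
        h_o_auto = n_het / total_obs if total_obs > 0 else np.nan
        _, _, _, _, _, h_e = _locus_stats(pop, unbiased=unbiased)
        per_site = np.zeros(sites)
        finite = h_e[np.isfinite(h_e)]
        per_site[: finite.size] = finite
        h_e_auto = float(np.mean(per_site))
        se = float(np.std(per_site, ddof=1) / np.sqrt(sites)) if sites > 1 else np.nan
        rows.append(
            {
                "population": name,
                "callable_sites": sites,
                "H_O_auto": h_o_auto * display_scale,
                "H_E_auto": h_e_auto * display_scale,
                "H_E_auto_SE": se * display_scale,
            }
        )
    return pd.DataFrame(rows).set_index("population")


def diversity_table(
    populations: dict[str, GenotypeDataset],
    callable_sites: int | dict[str, int] | None = None,
    unbiased: bool = True,
) -> pd.DataFrame:
    """Combined per-population diversity table (SNP metrics, optionally
    autosomal heterozygosities on the x1000 display scale)."""
    table = per_population_diversity(populations, unbiased=unbiased)
    if callable_sites is not None:
        auto = autosomal_heterozygosity(
            populations, callable_sites, unbiased=unbiased, display_scale=1000.0
        )
        table = table.join(auto[["H_E_auto", "H_O_auto"]])
    return table
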