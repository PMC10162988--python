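"""Post-genotyping quality-control cascade.

Stages, in the order they are applied by :func:`run_qc_cascade`:

1. locus call-rate (drop loci genotyped in < 90% of samples),
2. minor allele count (drop loci with MAC < 3),
3. excess observed heterozygosity (drop loci with H_O > 0.6, a signature of
   erroneously merged paralogous reads),
4. removal of close relatives (within-locality allele-matching kinship
   beta > 0.25),
5. LD pruning (|r| > 0.5 within 100 kb sliding windows),
6. sample missingness (drop samples missing > 25% of calls),
7. technical-replicate concordance check and removal.

Removal conditions are strict inequalities throughout. Pairwise statistics
use pairwise-complete observations; nothing is imputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import MISSING, DatasetError, GenotypeDataset


@dataclass
class FilterStage:
    name: str
    n_loci_before: int
    n_loci_after: int
    n_samples_before: int
    n_samples_after: int
    parameters: dict
    removed_ids: list[str]


@dataclass
class FilterReport:
    """Ordered record of what each QC stage removed."""

    stages: list[FilterStage] = field(default_factory=list)

    def add(self, stage: FilterStage) -> None:
        self.stages.append(stage)

    def extend(self, other: "FilterReport") -> None:
        self.stages.extend(other.stages)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "filter": [s.name for s in self.stages],
                "n_loci_before": [s.n_loci_before for s in self.stages],
                "n_loci_after": [s.n_loci_after for s in self.stages],
                "n_samples_before": [s.n_samples_before for s in self.stages],
                "n_samples_after": [s.n_samples_after for s in self.stages],
                "parameters": [json.dumps(s.parameters) for s in self.stages],
                "n_removed": [len(s.removed_ids) for s in self.stages],
            }
        )

    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "filter": s.name,
                "n_loci_before": s.n_loci_before,
                "n_loci_after": s.n_loci_after,
                "n_samples_before": s.n_samples_before,
                "n_samples_after": s.n_samples_after,
                "parameters": s.parameters,
                "removed_ids": s.removed_ids,
            }
            for s in self.stages
        ]
        Path(path).write_text(json.dumps(payload, indent=2))


def _locus_stage(
    ds: GenotypeDataset, keep: np.ndarray, name: str, params: dict
) -> tuple[GenotypeDataset, FilterReport]:
    removed = [ds.loci[i].locus_id for i in np.nonzero(~keep)[0]]
    out = ds.take_loci(np.nonzero(keep)[0])
    report = FilterReport(
        [
            FilterStage(
                name,
                ds.n_loci,
                out.n_loci,
                ds.n_samples,
                out.n_samples,
                params,
                removed,
            )
        ]
    )
    if out.n_loci == 0:
        raise DatasetError(f"{name}: all loci removed")
    return out, report


def filter_locus_callrate(
    ds: GenotypeDataset, min_prop: float = 0.90
) -> tuple[GenotypeDataset, FilterReport]:
    """Drop loci whose called fraction across samples is below ``min_prop``."""
    if not (0 < min_prop <= 1):
        raise DatasetError("min_prop must be in (0, 1]")
    callrate = ds.called.mean(axis=1)
    return _locus_stage(ds, callrate >= min_prop, "locus_callrate", {"min_prop": min_prop})


def filter_mac(ds: GenotypeDataset, min_mac: int = 3) -> tuple[GenotypeDataset, FilterReport]:
    """Drop loci whose minor-allele copy count over called genotypes is below ``min_mac``."""
    if min_mac < 0:
        raise DatasetError("min_mac must be >= 0")
    alt, copies = ds.alt_counts()
    minor = np.minimum(alt, copies - alt)
    return _locus_stage(ds, minor >= min_mac, "minor_allele_count", {"min_mac": min_mac})


def filter_excess_het(
    ds: GenotypeDataset, max_ho: float = 0.6
) -> tuple[GenotypeDataset, FilterReport]:
    """Drop loci with observed heterozygosity strictly above ``max_ho``."""
    if not (0 < max_ho <= 1):
        raise DatasetError("max_ho must be in (0, 1]")
    called = ds.called.sum(axis=1)
    hets = (ds.dosages == 1).sum(axis=1)
    with np.errstate(invalid="ignore"):
        ho = np.where(called > 0, hets / np.maximum(called, 1), 0.0)
    return _locus_stage(ds, ho <= max_ho, "excess_heterozygosity", {"max_ho": max_ho})


def kinship_matrix(ds: GenotypeDataset) -> pd.DataFrame:
    """Allele-matching (beta) kinship estimates for every sample pair.

    Per pair the mean over co-called loci of the allele-matching probability
    ``(x_i x_j + (2 - x_i)(2 - x_j)) / 4`` is computed, then centred on the
    mean matching over all distinct pairs M_B:
    ``beta = (M - M_B) / (1 - M_B)``. The diagonal holds within-individual
    matching treated the same way. Pairs with no co-called locus are NaN.
    """
    if ds.n_samples < 2:
        raise DatasetError("kinship requires >= 2 samples")
    called = ds.called.astype(np.float64)
    x = np.where(ds.called, ds.dosages, 0).astype(np.float64)
    s1 = x.T @ x
    a = x.T @ called  # a[i, j] = sum of x_i over loci co-called with j
    n_shared = called.T @ called
    with np.errstate(invalid="ignore", divide="ignore"):
        m = (2 * s1 - 2 * a - 2 * a.T + 4 * n_shared) / (4 * n_shared)
    m[n_shared == 0] = np.nan
    iu = np.triu_indices(ds.n_samples, k=1)
    m_b = np.nanmean(m[iu])
    beta = (m - m_b) / (1 - m_b)
    return pd.DataFrame(beta, index=ds.sample_ids, columns=ds.sample_ids)


def remove_related(
    ds: GenotypeDataset, threshold: float = 0.25, scope: str = "within-locality"
) -> tuple[GenotypeDataset, FilterReport]:
    """Greedily remove one member of each overly related pair.

    While any pair (within the same locality under the default scope) has
    kinship beta strictly above ``threshold``, the member with more missing
    data is removed (tie: the later sample in column order). Under the
    default scope the beta reference M_B is the mean matching among pairs of
    the same locality, so population structure does not masquerade as
    relatedness. Declared technical-replicate pairs are exempt: they are
    handled by the replicate-concordance stage, not as biological relatives.
    """
    n = ds.n_samples
    beta = np.full((n, n), np.nan)
    if scope == "within-locality":
        for idx in ds.localities().values():
            if len(idx) < 2:
                continue
            sub = kinship_matrix(ds.take_samples(idx)).to_numpy()
            for a, i in enumerate(idx):
                for b, j in enumerate(idx):
                    beta[i, j] = sub[a, b]
    else:
        beta = kinship_matrix(ds).to_numpy()
    miss = ds.sample_missingness()
    locality = [s.locality for s in ds.samples]
    ids = ds.sample_ids
    replicate_pair = {
        frozenset((s.sample_id, s.replicate_of)) for s in ds.samples if s.replicate_of
    }
    active = np.ones(n, dtype=bool)
    removed: list[int] = []
    while True:
        worst = None
        worst_val = threshold
        for i in range(n):
            if not active[i]:
                continue
            for j in range(i + 1, n):
                if not active[j]:
                    continue
                if scope == "within-locality" and locality[i] != locality[j]:
                    continue
                if frozenset((ids[i], ids[j])) in replicate_pair:
                    continue
                b = beta[i, j]
                if np.isfinite(b) and b > worst_val:
                    worst_val = b
                    worst = (i, j)
        if worst is None:
            break
        i, j = worst
        drop = j if (miss[j] >= miss[i]) else i
        active[drop] = False
        removed.append(drop)
    removed_ids = [ds.sample_ids[k] for k in removed]
    out = ds.take_samples(np.nonzero(active)[0])
    report = FilterReport(
        [
            FilterStage(
                "kinship_removal",
                ds.n_loci,
                out.n_loci,
                ds.n_samples,
                out.n_samples,
                {"threshold": threshold, "scope": scope},
                removed_ids,
            )
        ]
    )
    return out, report


def _pairwise_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r of two dosage vectors over co-called samples (NaN if undefined)."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return np.nan
    xv, yv = x[ok].astype(float), y[ok].astype(float)
    if xv.std() == 0 or yv.std() == 0:
        return np.nan
    return float(np.corrcoef(xv, yv)[0, 1])


def ld_prune(
    ds: GenotypeDataset,
    max_corr: float = 0.5,
    window_bp: int = 100_000,
    squared: bool = False,
) -> tuple[GenotypeDataset, FilterReport]:
    """Sliding-window LD pruning keeping the earlier locus of each pair.

    Loci are scanned in genomic order per scaffold; a locus is removed when
    its dosage correlation with any *kept* earlier locus within ``window_bp``
    strictly exceeds ``max_corr``. The statistic is |Pearson r| by default
    (``squared=True`` thresholds r² instead).
    """
    order = sorted(range(ds.n_loci), key=lambda i: (ds.loci[i].scaffold, ds.loci[i].position))
    kept_by_scaffold: dict[str, list[int]] = {}
    keep = np.zeros(ds.n_loci, dtype=bool)
    for i in order:
        loc = ds.loci[i]
        kept = kept_by_scaffold.setdefault(loc.scaffold, [])
        violated = False
        for j in reversed(kept):
            if loc.position - ds.loci[j].position > window_bp:
                break
            r = _pairwise_r(ds.dosages[i], ds.dosages[j])
            if np.isnan(r):
                continue
            stat = r * r if squared else abs(r)
            if stat > max_corr:
                violated = True
                break
        if not violated:
            keep[i] = True
            kept.append(i)
    return _locus_stage(
        ds, keep, "ld_prune", {"max_corr": max_corr, "window_bp": window_bp, "squared": squared}
    )


def filter_sample_missingness(
    ds: GenotypeDataset, max_miss: float = 0.25
) -> tuple[GenotypeDataset, FilterReport]:
    """Drop samples missing strictly more than ``max_miss`` of genotype calls."""
    if not (0 < max_miss < 1):
        raise DatasetError("max_miss must be in (0, 1)")
    miss = ds.sample_missingness()
    keep = miss <= max_miss
    if not keep.any():
        raise DatasetError("sample_missingness: all samples removed")
    removed = [ds.sample_ids[j] for j in np.nonzero(~keep)[0]]
    out = ds.take_samples(np.nonzero(keep)[0])
    report = FilterReport(
        [
            FilterStage(
                "sample_missingness",
                ds.n_loci,
                out.n_loci,
                ds.n_samples,
                out.n_samples,
                {"max_miss": max_miss},
                removed,
            )
        ]
    )
    return out, report


def replicate_concordance(ds: GenotypeDataset) -> pd.DataFrame:
    """Concordance and nearest-neighbour check for technical-replicate pairs.

    Per pair: the fraction of co-called loci with identical dosage, and
    whether each member's nearest neighbour by Prevosti distance is its
    partner (the dendrogram sanity check for replicate pairing).
    """
    from .structure import prevosti_distance

    pairs = [(s.replicate_of, s.sample_id) for s in ds.samples if s.replicate_of]
    if not pairs:
        raise DatasetError("no replicate pairs in dataset")
    ids = ds.sample_ids
    dist = prevosti_distance(ds).to_numpy()
    rows = []
    for src, rep in pairs:
        if src not in ids:
            raise DatasetError(f"replicate {rep} points at absent sample {src}")
        a, b = ids.index(src), ids.index(rep)
        ok = (ds.dosages[:, a] != MISSING) & (ds.dosages[:, b] != MISSING)
        conc = float(np.mean(ds.dosages[ok, a] == ds.dosages[ok, b])) if ok.any() else np.nan
        d = dist.copy()
        np.fill_diagonal(d, np.inf)
        nn_a = int(np.nanargmin(np.where(np.isnan(d[a]), np.inf, d[a])))
        nn_b = int(np.nanargmin(np.where(np.isnan(d[b]), np.inf, d[b])))
        rows.append(
            {
                "sample": src,
                "replicate": rep,
                "concordance": conc,
                "nearest_neighbour_pass": bool(nn_a == b and nn_b == a),
            }
        )
    return pd.DataFrame(rows)


def remove_replicates(ds: GenotypeDataset) -> tuple[GenotypeDataset, FilterReport]:
    """Drop technical-replicate columns (samples with ``replicate_of`` set)."""
    removed = [s.sample_id for s in ds.samples if s.replicate_of]
    out = ds.drop_samples(removed)
    report = FilterReport(
        [
            FilterStage(
                "replicate_removal",
                ds.n_loci,
                out.n_loci,
                ds.n_samples,
                out.n_samples,
                {},
                removed,
            )
        ]
    )
    return out, report


def run_qc_cascade(
    ds: GenotypeDataset,
    min_callrate: float = 0.90,
    min_mac: int = 3,
    max_ho: float = 0.6,
    kinship_threshold: float = 0.25,
    ld_max_corr: float = 0.5,
    ld_window_bp: int = 100_000,
    max_sample_missingness: float = 0.25,
    drop_replicates: bool = True,
    max_rounds: int = 5,
) -> tuple[GenotypeDataset, FilterReport]:
    """Apply the full QC cascade in its canonical order.

    Sample removals (relatives, high-missingness samples, replicates) can
    push a handful of loci back below the call-rate or MAC thresholds, so
    the cascade is repeated until the dataset is a fixed point (at most
    ``max_rounds`` passes; two nearly always suffice). The final matrix
    therefore satisfies every threshold jointly and re-running the cascade
    changes nothing.
    """
    report = FilterReport()
    for _ in range(max_rounds):
        shape_before = (ds.n_loci, ds.n_samples)
        ds, r = filter_locus_callrate(ds, min_callrate)
        report.extend(r)
        ds, r = filter_mac(ds, min_mac)
        report.extend(r)
        ds, r = filter_excess_het(ds, max_ho)
        report.extend(r)
        ds, r = remove_related(ds, kinship_threshold)
        report.extend(r)
        ds, r = ld_prune(ds, ld_max_corr, ld_window_bp)
        report.extend(r)
        ds, r = filter_sample_missingness(ds, max_sample_missingness)
        report.extend(r)
        if drop_replicates and any(s.replicate_of for s in ds.samples):
            ds, r = remove_replicates(ds)
            report.extend(r)
        if (ds.n_loci, ds.n_samples) == shape_before:
            break
    return ds, report
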