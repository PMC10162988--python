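"""Core genotype container shared by every stage of the pipeline.

A :class:`GenotypeDataset` holds a biallelic locus-by-sample dosage matrix
(counts of the alternate allele, 0/1/2, with ``MISSING = -1``) together with
locus records (scaffold, 1-based position, REF/ALT alleles) and sample
records (id, locality, optional coordinates and technical-replicate links).
All downstream statistics are allele-label symmetric, so which allele the
dosage counts is arbitrary but fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Sentinel dosage for an uncalled genotype.
MISSING: int = -1

_VALID_CODES = frozenset({0, 1, 2, MISSING})


class DatasetError(ValueError):
    """Raised for structurally invalid genotype datasets or inputs."""


@dataclass(frozen=True)
class LocusRecord:
    """One biallelic SNP: identifier, genomic placement and alleles."""

    locus_id: str
    scaffold: str
    position: int  # 1-based, as in VCF
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise DatasetError(f"locus {self.locus_id}: position must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise DatasetError(f"locus {self.locus_id}: ref == alt ({self.ref_allele})")


@dataclass(frozen=True)
class SampleRecord:
    """One diploid individual with its sampling locality.

    ``replicate_of`` links a technical replicate to its source sample; empty
    string means the sample is not a replicate.
    """

    sample_id: str
    locality: str
    latitude: float | None = None
    longitude: float | None = None
    replicate_of: str = ""


@dataclass
class GenotypeDataset:
    """Biallelic SNP-by-sample dosage matrix with locus and sample metadata.

    Parameters
    ----------
    loci
        Ordered locus records; ids must be unique.
    samples
        Ordered sample records; ids must be unique, and any ``replicate_of``
        must name another sample in the dataset.
    dosages
        ``(n_loci, n_samples)`` integer matrix with entries in
        ``{0, 1, 2, MISSING}`` counting copies of the alternate allele.
    """

    loci: list[LocusRecord]
    samples: list[SampleRecord]
    dosages: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.loci), len(self.samples)):
            raise DatasetError(
                f"dosage shape {self.dosages.shape} != "
                f"({len(self.loci)} loci, {len(self.samples)} samples)"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DatasetError(
                f"invalid dosage code {self.dosages[i, j]} at locus row {i}, sample column {j}"
            )
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise DatasetError("duplicate sample ids")
        lids = [l.locus_id for l in self.loci]
        if len(set(lids)) != len(lids):
            raise DatasetError("duplicate locus ids")
        known = set(ids)
        for s in self.samples:
            if s.replicate_of and s.replicate_of not in known:
                raise DatasetError(
                    f"sample {s.sample_id}: replicate_of {s.replicate_of!r} not in dataset"
                )

    # ------------------------------------------------------------------ views

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    @property
    def called(self) -> np.ndarray:
        """Boolean mask of called genotypes, same shape as ``dosages``."""
        return self.dosages != MISSING

    def missing_fraction(self) -> float:
        """Overall fraction of uncalled genotype entries."""
        return float(np.mean(self.dosages == MISSING))

    def sample_missingness(self) -> np.ndarray:
        """Per-sample fraction of uncalled loci."""
        return np.mean(self.dosages == MISSING, axis=0)

    def locus_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus_id": [l.locus_id for l in self.loci],
                "scaffold": [l.scaffold for l in self.loci],
                "position": [l.position for l in self.loci],
                "ref": [l.ref_allele for l in self.loci],
                "alt": [l.alt_allele for l in self.loci],
            }
        )

    def sample_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "locality": [s.locality for s in self.samples],
                "latitude": [s.latitude for s in self.samples],
                "longitude": [s.longitude for s in self.samples],
                "replicate_of": [s.replicate_of for s in self.samples],
            }
        )

    def localities(self) -> dict[str, list[int]]:
        """Mapping locality -> column indices, in first-seen order."""
        out: dict[str, list[int]] = {}
        for j, s in enumerate(self.samples):
            out.setdefault(s.locality, []).append(j)
        return out

    # -------------------------------------------------------------- subsetting

    def take_loci(self, index: Iterable[int] | np.ndarray) -> "GenotypeDataset":
        idx = np.asarray(list(index), dtype=int)
        return GenotypeDataset(
            loci=[self.loci[i] for i in idx],
            samples=list(self.samples),
            dosages=self.dosages[idx, :] if idx.size else np.empty((0, self.n_samples), np.int8),
        )

    def take_samples(self, index: Iterable[int] | np.ndarray) -> "GenotypeDataset":
        idx = np.asarray(list(index), dtype=int)
        samples = [self.samples[j] for j in idx]
        kept = {s.sample_id for s in samples}
        # replicate links pointing outside the subset are severed
        samples = [
            s if (not s.replicate_of or s.replicate_of in kept)
            else SampleRecord(s.sample_id, s.locality, s.latitude, s.longitude, "")
            for s in samples
        ]
        return GenotypeDataset(
            loci=list(self.loci),
            samples=samples,
            dosages=self.dosages[:, idx] if idx.size else np.empty((self.n_loci, 0), np.int8),
        )

    def drop_samples(self, sample_ids: Iterable[str]) -> "GenotypeDataset":
        drop = set(sample_ids)
        keep = [j for j, s in enumerate(self.samples) if s.sample_id not in drop]
        return self.take_samples(keep)

    def subset_locality(self, locality: str) -> "GenotypeDataset":
        idx = [j for j, s in enumerate(self.samples) if s.locality == locality]
        if not idx:
            raise DatasetError(f"no samples from locality {locality!r}")
        return self.take_samples(idx)

    # ------------------------------------------------------------- frequencies

    def alt_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-locus (alt allele copies, called gene copies) over all samples."""
        called = self.called
        alt = np.where(called, self.dosages, 0).sum(axis=1)
        copies = 2 * called.sum(axis=1)
        return alt.astype(np.int64), copies.astype(np.int64)

    def allele_frequencies(self) -> np.ndarray:
        """Per-locus alternate-allele frequency; NaN where no copy is called."""
        alt, copies = self.alt_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(copies > 0, alt / np.maximum(copies, 1), np.nan)


def concatenate_samples(datasets: Iterable[GenotypeDataset]) -> GenotypeDataset:
    """Column-bind datasets sharing an identical locus list."""
    dss = list(datasets)
    if not dss:
        raise DatasetError("nothing to concatenate")
    first = dss[0]
    for ds in dss[1:]:
        if ds.locus_ids != first.locus_ids:
            raise DatasetError("datasets do not share a locus list")
    return GenotypeDataset(
        loci=list(first.loci),
        samples=[s for ds in dss for s in ds.samples],
        dosages=np.concatenate([ds.dosages for ds in dss], axis=1),
    )
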