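"""Reading and writing genotype matrices and sample metadata.

Two interchangeable on-disk representations are supported:

* VCF (v4.x with GT fields), read through :mod:`cyvcf2`; only biallelic SNP
  records are retained and diploid GT calls are mapped to alt-allele dosages.
* A delimited genotype table (rows = loci, columns = samples) paired with a
  sample-metadata table. Dosage codes are ``0/1/2``; empty cells or ``NA``
  mean missing.

Both round-trip losslessly through :class:`~popcons.dataset.GenotypeDataset`.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import MISSING, DatasetError, GenotypeDataset, LocusRecord, SampleRecord

logger = logging.getLogger(__name__)

_SNP_ALLELES = {"A", "C", "G", "T"}


def _read_metadata(metadata_path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(metadata_path).endswith((".tsv", ".txt")) else None
    meta = pd.read_csv(metadata_path, sep=sep, engine="python", dtype={"sample_id": str})
    required = {"sample_id", "locality"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise DatasetError(f"metadata missing columns: {sorted(missing_cols)}")
    for col in ("latitude", "longitude", "replicate_of"):
        if col not in meta.columns:
            meta[col] = np.nan if col != "replicate_of" else ""
    meta["replicate_of"] = meta["replicate_of"].fillna("").astype(str)
    return meta


def _sample_records(sample_ids: list[str], meta: pd.DataFrame | None) -> list[SampleRecord]:
    if meta is None:
        return [SampleRecord(sid, locality="unknown") for sid in sample_ids]
    meta = meta.set_index("sample_id")
    absent = [sid for sid in sample_ids if sid not in meta.index]
    if absent:
        raise DatasetError(f"samples missing from metadata: {absent}")
    extra = sorted(set(meta.index) - set(sample_ids))
    if extra:
        warnings.warn(
            f"{len(extra)} metadata sample(s) absent from genotype matrix ignored: {extra}",
            stacklevel=3,
        )
    records = []
    present = set(sample_ids)
    for sid in sample_ids:
        row = meta.loc[sid]
        rep = row["replicate_of"] if row["replicate_of"] in present else ""
        records.append(
            SampleRecord(
                sample_id=sid,
                locality=str(row["locality"]),
                latitude=None if pd.isna(row["latitude"]) else float(row["latitude"]),
                longitude=None if pd.isna(row["longitude"]) else float(row["longitude"]),
                replicate_of=rep,
            )
        )
    return records


def read_vcf(path: str | Path, metadata_path: str | Path | None = None) -> GenotypeDataset:
    """Read a VCF into a :class:`GenotypeDataset`.

    Only biallelic SNP records are kept (multiallelic or indel records are
    dropped with a logged count). Diploid GT values map to dosages 0/1/2;
    any GT containing a missing allele maps to :data:`MISSING`. If
    ``metadata_path`` is given, sample localities and replicate links are
    attached; otherwise every sample gets locality ``"unknown"``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    loci: list[LocusRecord] = []
    rows: list[np.ndarray] = []
    n_dropped = 0
    for var in vcf:
        alts = var.ALT
        if len(alts) != 1 or len(var.REF) != 1 or len(alts[0]) != 1:
            n_dropped += 1
            continue
        if var.REF not in _SNP_ALLELES or alts[0] not in _SNP_ALLELES:
            n_dropped += 1
            continue
        row = np.full(len(sample_ids), MISSING, dtype=np.int8)
        for j, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                continue
            row[j] = a + b
        locus_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        loci.append(LocusRecord(locus_id, var.CHROM, var.POS, var.REF, alts[0]))
        rows.append(row)
    vcf.close()
    if n_dropped:
        logger.info("read_vcf: dropped %d non-biallelic-SNP record(s)", n_dropped)
    if not loci:
        raise DatasetError(f"{path}: no biallelic SNP records")
    meta = _read_metadata(metadata_path) if metadata_path is not None else None
    return GenotypeDataset(
        loci=loci,
        samples=_sample_records(sample_ids, meta),
        dosages=np.vstack(rows),
    )


def write_vcf(ds: GenotypeDataset, path: str | Path) -> None:
    """Write the dataset as a minimal VCF 4.2 text file (GT only)."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        scaffolds = sorted({l.scaffold for l in ds.loci})
        for sc in scaffolds:
            fh.write(f"##contig=<ID={sc}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ds.sample_ids)
            + "\n"
        )
        for i, loc in enumerate(ds.loci):
            gts = "\t".join(gt_map[int(x)] for x in ds.dosages[i])
            fh.write(
                f"{loc.scaffold}\t{loc.position}\t{loc.locus_id}\t"
                f"{loc.ref_allele}\t{loc.alt_allele}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_genotype_table(path: str | Path, metadata_path: str | Path) -> GenotypeDataset:
    """Read a delimited dosage table plus metadata into a dataset.

    The table carries columns ``locus_id, scaffold, position, ref, alt``
    followed by one column per sample with codes 0/1/2 (empty or NA =
    missing). Every sample column must have a metadata row; metadata rows
    for samples absent from the table are ignored with a warning.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else None
    table = pd.read_csv(path, sep=sep, engine="python", dtype={"locus_id": str})
    fixed = ["locus_id", "scaffold", "position", "ref", "alt"]
    missing_cols = [c for c in fixed if c not in table.columns]
    if missing_cols:
        raise DatasetError(f"genotype table missing columns: {missing_cols}")
    sample_ids = [c for c in table.columns if c not in fixed]
    if not sample_ids:
        raise DatasetError("genotype table has no sample columns")
    loci = [
        LocusRecord(str(r.locus_id), str(r.scaffold), int(r.position), str(r.ref), str(r.alt))
        for r in table.itertuples()
    ]
    dosages = np.full((len(loci), len(sample_ids)), MISSING, dtype=np.int8)
    for j, sid in enumerate(sample_ids):
        col = table[sid]
        for i, val in enumerate(col):
            if pd.isna(val) or val == "":
                continue
            try:
                code = int(val)
            except (TypeError, ValueError):
                raise DatasetError(
                    f"unparseable dosage {val!r} at locus {loci[i].locus_id}, sample {sid}"
                ) from None
            if code not in (0, 1, 2):
                raise DatasetError(
                    f"invalid dosage {code} at locus {loci[i].locus_id}, sample {sid}"
                )
            dosages[i, j] = code
    meta = _read_metadata(metadata_path)
    return GenotypeDataset(loci=loci, samples=_sample_records(sample_ids, meta), dosages=dosages)


def write_genotype_table(
    ds: GenotypeDataset, path: str | Path, metadata_path: str | Path
) -> None:
    """Write the dataset as a TSV dosage table and a TSV metadata table."""
    frame = ds.locus_frame()
    for j, sid in enumerate(ds.sample_ids):
        col = ds.dosages[:, j].astype(object)
        col[col == MISSING] = ""
        frame[sid] = col
    frame.to_csv(path, sep="\t", index=False)
    ds.sample_frame().to_csv(metadata_path, sep="\t", index=False)


def split_by_locality(ds: GenotypeDataset, min_n: int = 1) -> dict[str, GenotypeDataset]:
    """Per-locality views of the dataset, restricted to localities with at
    least ``min_n`` samples. The locus list is shared across views."""
    if min_n < 1:
        raise DatasetError("min_n must be >= 1")
    out: dict[str, GenotypeDataset] = {}
    for loc, idx in ds.localities().items():
        if len(idx) >= min_n:
            out[loc] = ds.take_samples(idx)
    if not out:
        warnings.warn(f"no locality has >= {min_n} samples", stacklevel=2)
    return out
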