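"""Shared fixtures and small dataset builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from popcons.dataset import GenotypeDataset, LocusRecord, SampleRecord


def make_ds(
    dosages,
    localities=None,
    positions=None,
    scaffolds=None,
    replicate_of=None,
) -> GenotypeDataset:
    """Hand-build a dataset from a dosage matrix (rows = loci)."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_loci, n_samples = dosages.shape
    localities = localities or ["pop1"] * n_samples
    positions = positions if positions is not None else [1000 * (i + 1) for i in range(n_loci)]
    scaffolds = scaffolds or ["chr1"] * n_loci
    replicate_of = replicate_of or [""] * n_samples
    loci = [
        LocusRecord(f"L{i}", scaffolds[i], int(positions[i]), "A", "G") for i in range(n_loci)
    ]
    samples = [
        SampleRecord(f"S{j}", localities[j], replicate_of=replicate_of[j])
        for j in range(n_samples)
    ]
    return GenotypeDataset(loci=loci, samples=samples, dosages=dosages)


def hwe_population(n_samples: int, n_loci: int, seed: int, locality: str = "pop1",
                   freq_range=(0.1, 0.9)) -> GenotypeDataset:
    """One panmictic Hardy-Weinberg population with uniform allele frequencies."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(*freq_range, size=n_loci)
    dosages = rng.binomial(2, p[:, None], size=(n_loci, n_samples)).astype(np.int8)
    return make_ds(dosages, localities=[locality] * n_samples)


@pytest.fixture(scope="session")
def study_populations():
    """QC-filtered per-locality views of the four-population study fixture."""
    import popcons as pc

    cfg = pc.study_design_config(n_loci=1500, seed=0)
    ds, _ = pc.simulate_hierarchical_dataset(cfg)
    filtered, _ = pc.run_qc_cascade(ds)
    return pc.split_by_locality(filtered, 5)
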