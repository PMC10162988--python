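"""Synthetic genotype data with controllable population structure.

Two generators are provided:

* :func:`simulate_hierarchical_dataset` draws locality allele frequencies
  under a two-level Balding–Nichols hierarchy (lineages within the species,
  localities within lineages) and genotypes as binomial draws. Under this
  model the expected Weir–Cockerham differentiation between localities is
  approximately the compounded drift parameter F, which gives closed-form
  checks for the downstream estimators.
* :func:`simulate_wright_fisher_ld` runs a discrete-generation Wright–Fisher
  population with crossover recombination, producing the LD-versus-distance
  structure that the effective-population-size estimator inverts.

Both are deterministic under a fixed seed and emit ordinary
:class:`~popcons.dataset.GenotypeDataset` objects, so every downstream stage
can be exercised without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import MISSING, DatasetError, GenotypeDataset, LocusRecord, SampleRecord


@dataclass(frozen=True)
class LineageSpec:
    lineage_id: str
    f_lineage: float  # Balding-Nichols drift from the ancestral pool


@dataclass(frozen=True)
class LocalitySpec:
    locality_id: str
    lineage_id: str
    f_local: float  # drift of the locality from its lineage
    n_samples: int


@dataclass
class SimConfig:
    """Parameters of the hierarchical genotype simulation."""

    n_loci: int
    lineages: list[LineageSpec]
    localities: list[LocalitySpec]
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.025
    n_relative_pairs: int = 0
    n_replicate_pairs: int = 0
    locus_spacing_bp: int = 20_000
    loci_per_scaffold: int = 250
    #: lineage_id -> fraction of loci polymorphic ONLY in that lineage
    #: (post-split mutations; the allele is absent from all other lineages)
    private_fractions: dict[str, float] | None = None
    private_freq_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        raw = dict(raw)
        raw["lineages"] = [LineageSpec(**d) for d in raw.get("lineages", [])]
        raw["localities"] = [LocalitySpec(**d) for d in raw.get("localities", [])]
        for key in ("ancestral_freq_range", "private_freq_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(open(path)))

    def validate(self) -> None:
        if self.n_loci < 1:
            raise DatasetError("n_loci must be >= 1")
        lo, hi = self.ancestral_freq_range
        if not (0 < lo < hi < 1):
            raise DatasetError("ancestral_freq_range must satisfy 0 < low < high < 1")
        if not (0 <= self.missing_rate < 1):
            raise DatasetError("missing_rate must be in [0, 1)")
        lineage_ids = {l.lineage_id for l in self.lineages}
        if len(lineage_ids) != len(self.lineages):
            raise DatasetError("duplicate lineage ids")
        for spec in self.lineages:
            if not (0 < spec.f_lineage < 1):
                raise DatasetError(f"lineage {spec.lineage_id}: F must be in (0, 1)")
        for spec in self.localities:
            if spec.lineage_id not in lineage_ids:
                raise DatasetError(f"locality {spec.locality_id}: unknown lineage")
            if not (0 < spec.f_local < 1):
                raise DatasetError(f"locality {spec.locality_id}: F must be in (0, 1)")
            if spec.n_samples < 1:
                raise DatasetError(f"locality {spec.locality_id}: n_samples must be >= 1")
        if self.private_fractions:
            unknown = set(self.private_fractions) - lineage_ids
            if unknown:
                raise DatasetError(f"private_fractions for unknown lineages: {sorted(unknown)}")
            if sum(self.private_fractions.values()) >= 1:
                raise DatasetError("private_fractions must sum to < 1")


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated dataset."""

    ancestral_freqs: np.ndarray
    lineage_freqs: dict[str, np.ndarray]
    locality_freqs: dict[str, np.ndarray]
    f_lineage: dict[str, float]
    f_local: dict[str, float]
    relative_pairs: list[tuple[str, str, str]] = field(default_factory=list)  # parent_a, parent_b, child
    replicate_pairs: list[tuple[str, str]] = field(default_factory=list)  # source, replicate


_BN_IDENTITY_F = 1e-9  # below this, drift is treated as zero (identity draw)


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """Draw descendant frequencies Beta(p(1-F)/F, (1-p)(1-F)/F) around p."""
    if f < _BN_IDENTITY_F:
        return p.copy()
    scale = (1.0 - f) / f
    return rng.beta(np.maximum(p * scale, 1e-12), np.maximum((1.0 - p) * scale, 1e-12))


def _make_loci(n_loci: int, spacing: int, per_scaffold: int) -> list[LocusRecord]:
    loci = []
    for i in range(n_loci):
        sc, k = divmod(i, per_scaffold)
        loci.append(
            LocusRecord(f"L{i:06d}", f"scaffold_{sc + 1}", (k + 1) * spacing, "A", "G")
        )
    return loci


def simulate_hierarchical_dataset(config: SimConfig) -> tuple[GenotypeDataset, SimTruth]:
    """Simulate a structured SNP dataset under the two-level drift model.

    Per locus an ancestral frequency is drawn uniform on
    ``ancestral_freq_range``; each lineage drifts from it by Balding–Nichols
    with its F, each locality drifts from its lineage likewise, and diploid
    genotypes are binomial(2, locality frequency). A configurable fraction
    of loci per lineage is instead lineage-private (a post-split mutation):
    the alternate allele segregates only in that lineage, at a frequency
    drawn uniform on ``private_freq_range``, and is absent elsewhere.
    Relative pairs (one Mendelian offspring of two random same-locality
    parents), technical replicate pairs, and random missingness are then
    layered on per the config. Loci monomorphic in the realised sample are
    retained.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    p_anc = rng.uniform(*config.ancestral_freq_range, size=config.n_loci)

    # assign lineage-private loci, zeroing the ancestral allele elsewhere
    private_owner = np.full(config.n_loci, "", dtype=object)
    if config.private_fractions:
        perm = rng.permutation(config.n_loci)
        start = 0
        for lineage_id, frac in config.private_fractions.items():
            k = int(round(frac * config.n_loci))
            private_owner[perm[start : start + k]] = lineage_id
            start += k
        p_anc[private_owner != ""] = 0.0

    lineage_freqs = {}
    for spec in config.lineages:
        q = _balding_nichols(rng, p_anc, spec.f_lineage)
        own = private_owner == spec.lineage_id
        if own.any():
            q[own] = rng.uniform(*config.private_freq_range, size=int(own.sum()))
        q[(private_owner != "") & ~own] = 0.0
        lineage_freqs[spec.lineage_id] = q
    f_lineage = {spec.lineage_id: spec.f_lineage for spec in config.lineages}

    locality_freqs: dict[str, np.ndarray] = {}
    samples: list[SampleRecord] = []
    columns: list[np.ndarray] = []
    for spec in config.localities:
        q = _balding_nichols(rng, lineage_freqs[spec.lineage_id], spec.f_local)
        locality_freqs[spec.locality_id] = q
        geno = rng.binomial(2, q[:, None], size=(config.n_loci, spec.n_samples))
        columns.append(geno.astype(np.int8))
        samples.extend(
            SampleRecord(f"{spec.locality_id}_{k + 1:02d}", spec.locality_id)
            for k in range(spec.n_samples)
        )

    ds = GenotypeDataset(
        loci=_make_loci(config.n_loci, config.locus_spacing_bp, config.loci_per_scaffold),
        samples=samples,
        dosages=np.concatenate(columns, axis=1),
    )
    truth = SimTruth(
        ancestral_freqs=p_anc,
        lineage_freqs=lineage_freqs,
        locality_freqs=locality_freqs,
        f_lineage=f_lineage,
        f_local={spec.locality_id: spec.f_local for spec in config.localities},
    )

    if config.n_relative_pairs:
        eligible = [s for s in config.localities if s.n_samples >= 2]
        pairs = []
        for k in range(config.n_relative_pairs):
            spec = eligible[k % len(eligible)]
            a, b = rng.choice(spec.n_samples, size=2, replace=False) + 1
            pairs.append(
                (f"{spec.locality_id}_{a:02d}", f"{spec.locality_id}_{b:02d}", spec.locality_id)
            )
        ds, truth = inject_relatives(ds, truth, pairs, seed=int(rng.integers(2**31)))
    if config.n_replicate_pairs:
        sources = rng.choice(ds.n_samples, size=config.n_replicate_pairs, replace=False)
        ds, truth = inject_replicates(
            ds, truth, [ds.sample_ids[j] for j in sources]
        )
    if config.missing_rate > 0:
        ds = add_missingness(ds, config.missing_rate, seed=int(rng.integers(2**31)))
    return ds, truth


def inject_relatives(
    ds: GenotypeDataset,
    truth: SimTruth,
    pairs: list[tuple[str, str, str]],
    seed: int = 0,
) -> tuple[GenotypeDataset, SimTruth]:
    """Append one Mendelian offspring per (parent_a, parent_b, locality) pair.

    At each locus the offspring receives one allele drawn from each parent's
    genotype; a missing parent genotype propagates MISSING.
    """
    rng = np.random.default_rng(seed)
    ids = ds.sample_ids
    samples = list(ds.samples)
    cols = [ds.dosages]
    for k, (pa, pb, locality) in enumerate(pairs):
        try:
            ja, jb = ids.index(pa), ids.index(pb)
        except ValueError as exc:
            raise DatasetError(f"unknown parent in pair {k}: {exc}") from None
        for j in (ja, jb):
            if ds.samples[j].locality != locality:
                raise DatasetError(
                    f"parent {ds.samples[j].sample_id} not in locality {locality}"
                )
        xa = ds.dosages[:, ja].astype(float)
        xb = ds.dosages[:, jb].astype(float)
        child = (
            rng.binomial(1, np.clip(xa, 0, 2) / 2.0)
            + rng.binomial(1, np.clip(xb, 0, 2) / 2.0)
        ).astype(np.int8)
        child[(ds.dosages[:, ja] == MISSING) | (ds.dosages[:, jb] == MISSING)] = MISSING
        child_id = f"{locality}_off{k + 1}"
        samples.append(SampleRecord(child_id, locality))
        cols.append(child[:, None])
        truth.relative_pairs.append((pa, pb, child_id))
    out = GenotypeDataset(loci=list(ds.loci), samples=samples, dosages=np.concatenate(cols, axis=1))
    return out, truth


def inject_replicates(
    ds: GenotypeDataset, truth: SimTruth, source_ids: list[str]
) -> tuple[GenotypeDataset, SimTruth]:
    """Append an exact technical-replicate column per source sample."""
    ids = ds.sample_ids
    samples = list(ds.samples)
    cols = [ds.dosages]
    for sid in source_ids:
        try:
            j = ids.index(sid)
        except ValueError:
            raise DatasetError(f"unknown sample {sid!r}") from None
        src = ds.samples[j]
        rep_id = f"{sid}_rep"
        samples.append(
            SampleRecord(rep_id, src.locality, src.latitude, src.longitude, replicate_of=sid)
        )
        cols.append(ds.dosages[:, j][:, None])
        truth.replicate_pairs.append((sid, rep_id))
    out = GenotypeDataset(loci=list(ds.loci), samples=samples, dosages=np.concatenate(cols, axis=1))
    return out, truth


def add_missingness(ds: GenotypeDataset, rate: float, seed: int = 0) -> GenotypeDataset:
    """Independently blank each called genotype with the given probability."""
    if not (0 <= rate < 1):
        raise DatasetError("rate must be in [0, 1)")
    if rate == 0:
        return ds
    rng = np.random.default_rng(seed)
    dosages = ds.dosages.copy()
    mask = (rng.random(dosages.shape) < rate) & (dosages != MISSING)
    dosages[mask] = MISSING
    return GenotypeDataset(loci=list(ds.loci), samples=list(ds.samples), dosages=dosages)


def simulate_wright_fisher_ld(
    ne: int,
    n_generations: int,
    chrom_length: int = 5_000_000,
    recomb_rate: float = 1e-8,
    n_chromosomes: int = 5,
    sample_n: int = 30,
    n_loci_per_chrom: int = 80,
    seed: int = 0,
) -> GenotypeDataset:
    """Forward Wright–Fisher simulation with crossover recombination.

    Each chromosome carries ``n_loci_per_chrom`` evenly spaced biallelic loci
    initialised i.i.d. at frequency 0.5 across ``2*ne`` haplotypes. Each
    generation, every one of the ``ne`` diploid offspring draws two random
    parents; each parent transmits a gamete built with a Poisson number of
    crossovers (rate ``recomb_rate`` per bp). The final generation is
    sampled without replacement and returned unphased.
    """
    if ne < 2:
        raise DatasetError("ne must be >= 2")
    if n_generations < 1:
        raise DatasetError("n_generations must be >= 1")
    if sample_n > ne:
        raise DatasetError(f"sample_n ({sample_n}) exceeds ne ({ne})")
    rng = np.random.default_rng(seed)
    positions = np.linspace(1, chrom_length, n_loci_per_chrom).astype(np.int64)
    morgans = recomb_rate * chrom_length

    loci: list[LocusRecord] = []
    blocks: list[np.ndarray] = []
    for c in range(n_chromosomes):
        hap = (rng.random((2 * ne, n_loci_per_chrom)) < 0.5)
        for _ in range(n_generations):
            parents = rng.integers(ne, size=(ne, 2))
            nxo = rng.poisson(morgans, size=2 * ne)
            start = rng.integers(2, size=2 * ne)
            new = np.empty_like(hap)
            for g in range(2 * ne):
                pa = parents[g // 2, g % 2]
                h0, h1 = hap[2 * pa], hap[2 * pa + 1]
                if nxo[g] == 0:
                    new[g] = h1 if start[g] else h0
                else:
                    xo = np.sort(rng.integers(1, chrom_length, size=nxo[g]))
                    which = (start[g] + np.searchsorted(xo, positions)) % 2
                    new[g] = np.where(which == 0, h0, h1)
            hap = new
        chosen = rng.choice(ne, size=sample_n, replace=False)
        geno = (hap[2 * chosen] + hap[2 * chosen + 1]).astype(np.int8)
        blocks.append(geno.T)  # loci x samples
        loci.extend(
            LocusRecord(f"wf_c{c + 1}_l{i:04d}", f"wf_chrom_{c + 1}", int(pos), "A", "G")
            for i, pos in enumerate(positions)
        )
    samples = [SampleRecord(f"wf_{k + 1:03d}", "wf_population") for k in range(sample_n)]
    return GenotypeDataset(loci=loci, samples=samples, dosages=np.concatenate(blocks, axis=0))


def study_design_config(
    n_loci: int = 3000,
    missing_rate: float = 0.025,
    seed: int = 0,
    n_relative_pairs: int = 1,
    n_replicate_pairs: int = 2,
) -> SimConfig:
    """Four-population sampling design used as the bundled test fixture.

    It mirrors a range-wide rodent survey: two similar high-diversity
    mainland localities in one lineage (n = 14 and 8), one strongly drifted
    offshore-island lineage rich in private alleles (n = 14), and one
    low-diversity peripheral lineage (n = 5), with ~2.5% missingness, one
    close-relative pair and two technical replicates. Lineage-private
    variant classes (post-split mutations) give the island its uniqueness
    and keep the two mainland localities mutually redundant: 14% of loci are
    island-private, 5% mainland-private (shared by both central localities)
    and 4% peripheral-private.
    """
    return SimConfig(
        n_loci=n_loci,
        lineages=[
            LineageSpec("mainland", 0.05),
            LineageSpec("island", 0.45),
            LineageSpec("peripheral", 0.30),
        ],
        localities=[
            LocalitySpec("CentralA", "mainland", 0.03, 14),
            LocalitySpec("CentralB", "mainland", 0.03, 8),
            LocalitySpec("Island", "island", 0.05, 14),
            LocalitySpec("Peripheral", "peripheral", 0.25, 5),
        ],
        private_fractions={"island": 0.14, "mainland": 0.05, "peripheral": 0.04},
        missing_rate=missing_rate,
        n_relative_pairs=n_relative_pairs,
        n_replicate_pairs=n_replicate_pairs,
        seed=seed,
    )
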