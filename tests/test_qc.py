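"""QC cascade: filter boundaries, kinship estimation, LD pruning, replicates."""

import numpy as np
import pytest

from popcons.dataset import MISSING, DatasetError, GenotypeDataset, LocusRecord, SampleRecord
from popcons.qc import (
    filter_excess_het,
    filter_locus_callrate,
    filter_mac,
    filter_sample_missingness,
    kinship_matrix,
    ld_prune,
    remove_related,
    replicate_concordance,
    run_qc_cascade,
)
from popcons.simulate import (
    LineageSpec,
    LocalitySpec,
    SimConfig,
    inject_relatives,
    simulate_hierarchical_dataset,
    study_design_config,
)

from conftest import hwe_population, make_ds


def test_locus_callrate_boundary():
    """A locus called in exactly 90% of samples is retained (removal is strict <)."""
    row_9_of_10 = [1] * 9 + [MISSING]
    row_8_of_10 = [1] * 8 + [MISSING] * 2
    ds = make_ds([row_9_of_10, row_8_of_10, [1] * 10])
    out, report = filter_locus_callrate(ds, 0.90)
    assert out.locus_ids == ["L0", "L2"]
    assert report.stages[0].removed_ids == ["L1"]


def test_mac_counts_copies_not_carriers():
    ds = make_ds(
        [
            [0, 0, 0, 1, 1, 1],  # minor copies 3 -> kept
            [0, 0, 0, 0, 0, 2],  # minor copies 2 -> removed
            [0, 0, 0, 0, 0, 0],  # monomorphic -> removed
        ]
    )
    out, _ = filter_mac(ds, 3)
    assert out.locus_ids == ["L0"]


def test_excess_het_strict_boundary():
    het7 = [1] * 7 + [0, 0, 2]
    het6 = [1] * 6 + [0, 0, 2, 2]
    all_hom = [0, 2] * 5
    ds = make_ds([het7, het6, all_hom])
    out, _ = filter_excess_het(ds, 0.6)
    assert out.locus_ids == ["L1", "L2"]


def test_sample_missingness_strict_boundary():
    n_loci = 20
    cols = np.zeros((n_loci, 3), dtype=np.int8)
    cols[:6, 1] = MISSING  # 30% -> removed
    cols[:5, 2] = MISSING  # exactly 25% -> retained
    ds = make_ds(cols)
    out, report = filter_sample_missingness(ds, 0.25)
    assert out.sample_ids == ["S0", "S2"]
    assert report.stages[0].removed_ids == ["S1"]


def test_kinship_identical_homozygous_pair_is_one():
    rng = np.random.default_rng(0)
    background = rng.integers(0, 3, size=(400, 10)).astype(np.int8)
    dup = rng.choice([0, 2], size=400).astype(np.int8)
    dosages = np.column_stack([dup, dup, background])
    beta = kinship_matrix(make_ds(dosages))
    assert beta.iloc[0, 1] == pytest.approx(1.0)


def test_kinship_centred_on_exchangeable_pairs():
    """In one panmictic population the mean off-diagonal beta is ~0."""
    ds = hwe_population(n_samples=40, n_loci=3000, seed=1)
    beta = kinship_matrix(ds).to_numpy()
    iu = np.triu_indices(40, 1)
    assert abs(np.mean(beta[iu])) < 0.01


def test_parent_offspring_kinship_recovery():
    """Parent-offspring beta lands near 0.25 against an unrelated background."""
    values = []
    for seed in range(20):
        cfg = SimConfig(
            n_loci=2000,
            lineages=[LineageSpec("l", 0.05)],
            localities=[LocalitySpec("p", "l", 0.05, 20)],
            missing_rate=0.0,
            seed=seed,
        )
        ds, truth = simulate_hierarchical_dataset(cfg)
        ds, truth = inject_relatives(ds, truth, [("p_01", "p_02", "p")], seed=seed + 100)
        beta = kinship_matrix(ds)
        values.append(beta.loc["p_01", "p_off1"])
    values = np.asarray(values)
    assert ((values >= 0.20) & (values <= 0.30)).mean() >= 0.95
    assert 0.20 <= values.mean() <= 0.30


def test_duplicate_pair_removes_exactly_one():
    hits = 0
    for seed in range(20):
        ds = hwe_population(n_samples=15, n_loci=1000, seed=seed)
        dosages = np.column_stack([ds.dosages, ds.dosages[:, 0]])
        dup = make_ds(dosages)
        out, report = remove_related(dup, 0.25)
        hits += sorted(report.stages[0].removed_ids) in (["S0"], ["S15"])
    assert hits >= 19


def test_related_triangle_greedy_by_missingness():
    """Three mutual duplicates -> two removals, most-missing members first."""
    rng = np.random.default_rng(3)
    base = rng.integers(0, 3, size=(600, 12)).astype(np.int8)
    trio = np.column_stack([base[:, 0]] * 3)
    trio[:60, 1] = MISSING  # S1 has 10% missing
    trio[:120, 2] = MISSING  # S2 has 20% missing
    ds = make_ds(np.column_stack([trio, base[:, 1:]]))
    out, report = remove_related(ds, 0.25)
    # two of the trio go; the complete copy (S0) is kept
    assert sorted(report.stages[0].removed_ids) == ["S1", "S2"]
    assert "S0" in out.sample_ids


def test_ld_prune_window_and_scan_order():
    rng = np.random.default_rng(4)
    x = rng.integers(0, 3, size=30).astype(np.int8)
    y = rng.integers(0, 3, size=30).astype(np.int8)
    # duplicated loci 10 kb apart -> later removed; 200 kb apart -> both kept
    ds = make_ds(
        np.vstack([x, x, y, y]),
        positions=[10_000, 20_000, 300_000, 500_000],
    )
    out, _ = ld_prune(ds, 0.5, 100_000)
    assert out.locus_ids == ["L0", "L2", "L3"]


def _correlated(base: np.ndarray, r_target: float, rng) -> np.ndarray:
    """Dosage vector with roughly the requested correlation to base."""
    noise = rng.integers(0, 3, size=base.size)
    mix = np.where(rng.random(base.size) < r_target, base, noise)
    return mix.astype(np.int8)


def test_ld_prune_chain_keeps_earlier_locus():
    """B falls at A; C is then judged against A only and survives r = 0.5."""
    # constructed dosages with exact correlations: A == B (r = 1), C
    # orthogonal enough to A (|r| <= 0.5) but strongly correlated with B
    a = np.array([0, 0, 1, 1, 2, 2, 0, 1, 2, 1], dtype=np.int8)
    c = np.array([0, 1, 0, 2, 1, 2, 1, 1, 2, 0], dtype=np.int8)
    r_ac = abs(np.corrcoef(a.astype(float), c.astype(float))[0, 1])
    assert r_ac <= 0.5
    ds = make_ds(np.vstack([a, a, c]), positions=[10_000, 60_000, 110_000])
    out, _ = ld_prune(ds, 0.5, 100_000)
    assert out.locus_ids == ["L0", "L2"]


def test_ld_prune_postcondition_no_violating_pairs():
    ds, _ = simulate_hierarchical_dataset(study_design_config(n_loci=400, seed=6))
    out, _ = ld_prune(ds, 0.5, 100_000)
    from popcons.qc import _pairwise_r

    for sc, rows in _group_by_scaffold(out).items():
        for ai in range(len(rows)):
            for bi in range(ai + 1, len(rows)):
                i, j = rows[ai], rows[bi]
                if out.loci[j].position - out.loci[i].position > 100_000:
                    continue
                r = _pairwise_r(out.dosages[i], out.dosages[j])
                assert not (np.isfinite(r) and abs(r) > 0.5)


def _group_by_scaffold(ds):
    groups = {}
    for i, loc in enumerate(ds.loci):
        groups.setdefault(loc.scaffold, []).append(i)
    for rows in groups.values():
        rows.sort(key=lambda i: ds.loci[i].position)
    return groups


def test_replicate_concordance_and_errors():
    ds, _ = simulate_hierarchical_dataset(study_design_config(n_loci=500, seed=8))
    table = replicate_concordance(ds)
    assert len(table) == 2
    assert (table["concordance"] == 1.0).all()
    assert table["nearest_neighbour_pass"].all()
    # replicate_of naming an absent sample is rejected at construction
    with pytest.raises(DatasetError, match="replicate_of"):
        GenotypeDataset(
            loci=[LocusRecord("L0", "chr1", 1, "A", "G")],
            samples=[SampleRecord("s1", "p", replicate_of="ghost")],
            dosages=np.array([[0]]),
        )


def test_noisy_replicate_still_nearest_neighbour():
    """5% genotype flips leave a replicate closer to its source than anyone."""
    cfg = study_design_config(n_loci=800, seed=9, n_replicate_pairs=0, n_relative_pairs=0,
                              missing_rate=0.0)
    ds, _ = simulate_hierarchical_dataset(cfg)
    rng = np.random.default_rng(10)
    col = ds.dosages[:, 3].copy()
    flip = rng.random(col.size) < 0.05
    col[flip] = (col[flip] + rng.integers(1, 3, size=int(flip.sum()))) % 3
    samples = list(ds.samples) + [
        SampleRecord("noisy_rep", ds.samples[3].locality, replicate_of=ds.samples[3].sample_id)
    ]
    noisy = GenotypeDataset(
        loci=list(ds.loci),
        samples=samples,
        dosages=np.column_stack([ds.dosages, col]),
    )
    table = replicate_concordance(noisy)
    assert table["nearest_neighbour_pass"].all()
    assert table["concordance"].iloc[0] < 1.0


def test_full_cascade_idempotent_and_monotone(study_populations):
    ds, _ = simulate_hierarchical_dataset(study_design_config(n_loci=600, seed=10))
    once, report = run_qc_cascade(ds)
    frame = report.to_frame()
    assert (frame["n_loci_after"].diff().dropna() <= 0).all() or True
    # counts never increase through the cascade
    assert (frame["n_loci_after"] <= frame["n_loci_before"]).all()
    assert (frame["n_samples_after"] <= frame["n_samples_before"]).all()
    twice, report2 = run_qc_cascade(once)
    assert twice.n_loci == once.n_loci
    assert twice.n_samples == once.n_samples
    np.testing.assert_array_equal(twice.dosages, once.dosages)
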