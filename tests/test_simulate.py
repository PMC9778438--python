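import numpy as np
import pytest
from scipy import stats

from hicplaid import pipeline
from hicplaid.contacts import ContactMatrix, expected_by_distance
from hicplaid.simulate import (
    SimConfig,
    expected_intensity,
    generate_truth,
    simulate_expression,
    simulate_hic,
    simulate_pathways,
)

SMALL = SimConfig(chrom_sizes={"chr1": 20_000_000}, depth=200_000.0, seed=3)


# ---------------------------------------------------------------- truth


def test_zero_switch_fraction_identical_labels():
    truth = generate_truth(SMALL.with_(switch_fraction=0.0))
    assert np.array_equal(truth.labels[1], truth.labels[2])
    assert truth.switched_bins.size == 0


def test_switch_fraction_counts_bins():
    cfg = SMALL.with_(switch_fraction=0.05, switch_block_bins=(1, 1))
    truth = generate_truth(cfg)  # 40 comp bins -> 2 switched
    assert truth.switched_bins.size == round(0.05 * truth.comp_bins.n_bins)
    disagree = np.flatnonzero(truth.labels[1] != truth.labels[2])
    assert np.array_equal(disagree, truth.switched_bins)


def test_truth_deterministic_in_seed():
    t1 = generate_truth(SMALL)
    t2 = generate_truth(SMALL)
    assert np.array_equal(t1.labels[1], t2.labels[1])
    assert t1.domains[1].equals(t2.domains[1])
    assert t1.genes.equals(t2.genes)


def test_domains_tile_disjointly_per_condition():
    truth = generate_truth(SMALL)
    for cond in (1, 2):
        dom = truth.domains[cond]
        assert dom["start"].iloc[0] == 0
        assert dom["end"].iloc[-1] == 20_000_000
        assert (dom["start"].iloc[1:].to_numpy() == dom["end"].iloc[:-1].to_numpy()).all()


def test_gene_density_a_rich():
    truth = generate_truth(SimConfig(seed=1))
    labs = truth.gene_labels(1)
    n_a = (labs == "A").sum()
    n_b = (labs == "B").sum()
    frac_a_bins = (truth.labels[1] == "A").mean()
    # per-bin density (not just count) is higher in A
    assert n_a / frac_a_bins > n_b / (1 - frac_a_bins)


# ------------------------------------------------------------- contacts


def test_distance_decay_exponent_recovered():
    # alpha=0, beta=1: per-distance mean decays as (d+1)^-gamma; pool 10 seeds
    cfg = SMALL.with_(alpha=0.0, beta=1.0, gamma=1.0, depth=500_000.0)
    truth = generate_truth(cfg)
    means = []
    for seed in range(10):
        cm = simulate_hic(truth, cfg, 1, truth.comp_bins, seed=seed)["chr1"]
        means.append(expected_by_distance(cm))
    e = np.mean(means, axis=0)
    d = np.arange(1, 30)
    slope, _, r, _, _ = stats.linregress(np.log(d + 1), np.log(e[1:30]))
    assert slope == pytest.approx(-1.0, abs=0.1)
    assert r**2 > 0.95


def test_within_domain_enrichment_visible():
    cfg = SimConfig(chrom_sizes={"chr1": 30_000_000}, beta=3.0, alpha=0.0, seed=5)
    truth = generate_truth(cfg)
    bins = truth.tad_bins
    cm = simulate_hic(truth, cfg, 1, bins)["chr1"]
    e = expected_by_distance(cm)
    dom = truth.domains[1]
    starts = dom["start"].to_numpy()
    mids = bins.midpoints("chr1")
    dom_id = np.searchsorted(starts, mids, side="right") - 1
    n = cm.n
    same, diff = [], []
    for i in range(n):
        for j in range(i + 1, min(i + 40, n)):
            if e[j - i] <= 0:
                continue
            oe = cm.values[i, j] / e[j - i]
            (same if dom_id[i] == dom_id[j] else diff).append(oe)
    assert np.mean(same) > np.mean(diff)


def test_total_mass_near_depth():
    cfg = SMALL
    truth = generate_truth(cfg)
    cm = simulate_hic(truth, cfg, 1, truth.comp_bins)["chr1"]
    total = np.triu(cm.values).sum()
    assert abs(total - cfg.depth) < 2 * np.sqrt(cfg.depth)


def test_contacts_deterministic_and_symmetric():
    truth = generate_truth(SMALL)
    a = simulate_hic(truth, SMALL, 1, truth.comp_bins, seed=9)["chr1"]
    b = simulate_hic(truth, SMALL, 1, truth.comp_bins, seed=9)["chr1"]
    assert np.array_equal(a.values, b.values)
    assert np.array_equal(a.values, a.values.T)


def test_nonpositive_depth_rejected():
    truth = generate_truth(SMALL)
    with pytest.raises(ValueError, match="depth"):
        simulate_hic(truth, SMALL.with_(depth=0.0), 1, truth.comp_bins)


def test_noiseless_intensities_recover_planted_labels_exactly():
    # compartments called on the expected (noise-free) intensity matrix must
    # match the planted labels bin for bin, in both conditions
    cfg = SimConfig(seed=11)
    truth = generate_truth(cfg)
    for cond in (1, 2):
        lam = {
            chrom: ContactMatrix(
                truth.comp_bins,
                chrom,
                expected_intensity(truth, cfg, cond, truth.comp_bins, chrom),
                kind="raw",
            )
            for chrom in truth.comp_bins.chroms
        }
        prof = pipeline.compartment_profile(lam, truth.comp_bins, truth.genes)
        assert np.array_equal(prof.labels, truth.labels[cond])


# ----------------------------------------------------------- expression


def test_null_expression_indistinguishable():
    # mu_A == mu_B: rank-sum p should not pile up near 0 across seeds
    cfg = SimConfig(mu_a=4.0, mu_b=4.0, dispersion=1e-6, seed=0)
    truth = generate_truth(cfg)
    labs = truth.gene_labels(1)
    ps = []
    for seed in range(25):
        counts = simulate_expression(truth, cfg, 1, seed=seed)
        a = counts.loc[labs.reindex(counts["gene_id"]).to_numpy() == "A", "count"]
        b = counts.loc[labs.reindex(counts["gene_id"]).to_numpy() == "B", "count"]
        ps.append(stats.mannwhitneyu(a, b, alternative="greater").pvalue)
    assert np.mean(np.array(ps) < 0.05) < 0.3  # no systematic A > B signal


def test_planted_effect_gives_higher_a_medians():
    cfg = SimConfig(seed=2)  # mu_a - mu_b = 2 on the log scale
    truth = generate_truth(cfg)
    labs = truth.gene_labels(1)
    for seed in range(5):
        counts = simulate_expression(truth, cfg, 1, seed=seed)
        a = counts.loc[labs.reindex(counts["gene_id"]).to_numpy() == "A", "count"]
        b = counts.loc[labs.reindex(counts["gene_id"]).to_numpy() == "B", "count"]
        assert a.median() > b.median()


def test_empty_gene_set_gives_empty_table():
    cfg = SMALL.with_(genes_per_mb_a=0.0, genes_per_mb_b=0.0)
    truth = generate_truth(cfg)
    assert simulate_expression(truth, cfg, 1).empty


# ------------------------------------------------------------- pathways


def test_pathways_deterministic_and_sized():
    truth = generate_truth(SimConfig(seed=4))
    p1 = simulate_pathways(truth, SimConfig(seed=4))
    p2 = simulate_pathways(truth, SimConfig(seed=4))
    assert p1.pathways == p2.pathways
    assert len(p1) == 21  # planted + 20 decoys
    assert all(len(m) == 20 for m in p1.pathways.values())


def test_planted_pathway_holds_switched_genes():
    cfg = SimConfig(seed=6)
    truth = generate_truth(cfg)
    coll = simulate_pathways(truth, cfg)
    scgs = truth.scg_ids()
    overlap = len(coll.pathways[truth.pathway_id] & scgs)
    assert overlap >= round(0.6 * cfg.pathway_size) - 1


def test_oversized_pathway_rejected():
    cfg = SMALL.with_(genes_per_mb_a=0.2, genes_per_mb_b=0.1, pathway_size=1000)
    truth = generate_truth(cfg)
    with pytest.raises(ValueError, match="pathway size"):
        simulate_pathways(truth, cfg)


# --------------------------------------------------------- end to end


def test_pipeline_recovers_switches_and_ranks_planted_pathway():
    res = pipeline.run_two_condition_analysis(SimConfig(), seed=7)
    called = set(res.switches.switched_bins.tolist())
    planted = set(res.truth.switched_bins.tolist())
    assert called == planted
    assert res.enrichment_table.iloc[0]["term"] == res.truth.pathway_id
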