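import numpy as np
import pandas as pd
import pytest

from hicplaid import bin_genome
from hicplaid.tads import (
    DiHmm,
    DiTrack,
    _di_formula,
    call_tads,
    directionality_index,
    fit_di_hmm,
    tad_summary,
    tss_profile,
)

from conftest import make_matrix, symmetric_counts

RES = 40_000


def make_track(di, resolution=RES, chrom="c"):
    bins = bin_genome({chrom: len(di) * resolution}, resolution)
    return DiTrack(bins, np.asarray(di, dtype=float), 2_000_000, np.zeros(len(di), bool))


def states_hmm(states):
    s = np.array(list(states), dtype="<U1")
    return DiHmm(
        means=np.array([-1.0, 0.0, 1.0]),
        variances=np.ones(3),
        transmat=np.eye(3),
        startprob=np.ones(3) / 3,
        states=s,
        converged=True,
    )


# ------------------------------------------------------------------- DI


def test_di_zero_when_balanced():
    assert _di_formula(np.array([10.0]), np.array([10.0]))[0] == 0.0


def test_di_hand_value_and_antisymmetry():
    # A=10, B=40: E=25, (A-E)^2/E + (B-E)^2/E = 9 + 9 = 18, downstream-biased
    assert _di_formula(np.array([10.0]), np.array([40.0]))[0] == pytest.approx(18.0)
    assert _di_formula(np.array([40.0]), np.array([10.0]))[0] == pytest.approx(-18.0)


def test_di_matches_brute_force_window_oracle(rng):
    n, w = 30, 5
    v = symmetric_counts(rng, n)
    cm = make_matrix(v, resolution=RES, chrom="c")
    track = directionality_index({"c": cm}, cm.bins, window=w * RES)
    for i in range(n):
        a = sum(v[i, j] for j in range(max(0, i - w), i))
        b = sum(v[i, j] for j in range(i + 1, min(n, i + w + 1)))
        e = (a + b) / 2
        if a + b == 0 or a == b:
            expect = 0.0
        else:
            expect = np.sign(b - a) * ((a - e) ** 2 / e + (b - e) ** 2 / e)
        assert track.di[i] == pytest.approx(expect)
    # edge flags where the window is truncated
    assert track.edge[:w].all() and track.edge[-w:].all()
    assert not track.edge[w:-w].any()


def test_di_reversal_antisymmetry(rng):
    n, w = 24, 4
    v = symmetric_counts(rng, n)
    cm = make_matrix(v, resolution=RES)
    fwd = directionality_index({"chrA": cm}, cm.bins, window=w * RES)
    rcm = make_matrix(v[::-1, ::-1], resolution=RES)
    rev = directionality_index({"chrA": rcm}, rcm.bins, window=w * RES)
    interior = slice(w, n - w)
    assert np.allclose(fwd.di[interior], -rev.di[::-1][interior])


def test_di_homogeneous_degree_one(rng):
    v = symmetric_counts(rng, 20)
    cm1 = make_matrix(v, resolution=RES)
    cm2 = make_matrix(2 * v, resolution=RES)
    t1 = directionality_index({"chrA": cm1}, cm1.bins, window=3 * RES)
    t2 = directionality_index({"chrA": cm2}, cm2.bins, window=3 * RES)
    assert np.allclose(t2.di, 2 * t1.di)


def test_window_smaller_than_resolution_rejected(bins5):
    with pytest.raises(ValueError, match="window"):
        directionality_index({}, bins5, window=1)


# ------------------------------------------------------------------ HMM


def test_hmm_decodes_planted_runs():
    rng = np.random.default_rng(0)
    di = np.concatenate([np.full(60, 10.0), np.full(60, -10.0)])
    di += rng.normal(0, 0.1, size=di.size)
    hmm = fit_di_hmm(make_track(di), seed=0)
    assert (hmm.states[:60] == "D").all()
    assert (hmm.states[60:] == "U").all()


def test_all_zero_di_gives_single_none_state():
    hmm = fit_di_hmm(make_track(np.zeros(100)), seed=0)
    assert (hmm.states == "N").all()


def test_decoded_path_beats_random_paths():
    # Monte-Carlo optimality: Viterbi path likelihood >= 1000 random paths
    rng = np.random.default_rng(1)
    di = np.concatenate(
        [np.full(40, 8.0), np.full(30, 0.0), np.full(40, -8.0)]
    ) + rng.normal(0, 0.5, size=110)
    hmm = fit_di_hmm(make_track(di), seed=1)

    def path_logprob(states_idx):
        lp = np.log(hmm.startprob[states_idx[0]] + 1e-300)
        for a, b in zip(states_idx[:-1], states_idx[1:]):
            lp += np.log(hmm.transmat[a, b] + 1e-300)
        mu = hmm.model.means_.ravel()[states_idx]
        var = hmm.model.covars_.ravel()[states_idx]
        lp += np.sum(-0.5 * (np.log(2 * np.pi * var) + (di - mu) ** 2 / var))
        return lp

    letter_to_model = {}
    order = np.argsort(hmm.model.means_.ravel())
    for model_idx, letter in zip(order, "UND"):
        letter_to_model[letter] = model_idx
    decoded = np.array([letter_to_model[s] for s in hmm.states])
    lp_decoded = path_logprob(decoded)
    for _ in range(1000):
        random_path = rng.integers(0, 3, size=di.size)
        assert path_logprob(random_path) <= lp_decoded + 1e-9


def test_canonical_state_order():
    rng = np.random.default_rng(2)
    di = rng.choice([-5.0, 0.0, 5.0], size=200) + rng.normal(0, 0.3, 200)
    hmm = fit_di_hmm(make_track(di), seed=2)
    assert hmm.means[0] < hmm.means[1] < hmm.means[2]


def test_too_few_bins_rejected():
    with pytest.raises(ValueError, match="50"):
        fit_di_hmm(make_track(np.zeros(10)), seed=0)


# ------------------------------------------------------------ TAD calls


def test_down_up_motif_spans_whole_path():
    tads = call_tads(states_hmm("DDDNNUUU"), bin_genome({"c": 8 * RES}, RES))
    assert len(tads.domains) == 1
    d = tads.domains.iloc[0]
    assert (d["start"], d["end"]) == (0, 8 * RES)


def test_all_none_path_yields_no_domains():
    tads = call_tads(states_hmm("NNNNNNNN"), bin_genome({"c": 8 * RES}, RES))
    assert tads.domains.empty
    with pytest.warns(UserWarning):
        assert tad_summary(tads)["count"] == 0


def test_gap_classification_400kb_rule():
    # two domains separated by 5 bins (200 kb <= 400 kb): boundary
    path = "DDUU" + "N" * 5 + "DDUU"
    tads = call_tads(states_hmm(path), bin_genome({"c": 13 * RES}, RES))
    assert len(tads.domains) == 2
    assert tads.gaps.iloc[0]["kind"] == "boundary"
    # separated by 11 bins (440 kb > 400 kb): unorganized
    path = "DDUU" + "N" * 11 + "DDUU"
    tads = call_tads(states_hmm(path), bin_genome({"c": 19 * RES}, RES))
    assert tads.gaps.iloc[0]["kind"] == "unorganized"


def test_gap_of_exactly_400kb_is_boundary():
    path = "DDUU" + "N" * 10 + "DDUU"  # 10 * 40 kb = 400 kb
    tads = call_tads(states_hmm(path), bin_genome({"c": 18 * RES}, RES))
    assert tads.gaps.iloc[0]["length"] == 400_000
    assert tads.gaps.iloc[0]["kind"] == "boundary"


def test_boundary_center_is_gap_midpoint():
    path = "DDUU" + "NN" + "DDUU"
    tads = call_tads(states_hmm(path), bin_genome({"c": 10 * RES}, RES))
    gap = tads.gaps.iloc[0]
    assert gap["center"] == (gap["start"] + gap["end"]) // 2


def test_unclosed_motif_yields_no_domain():
    tads = call_tads(states_hmm("NNDDDNNN"), bin_genome({"c": 8 * RES}, RES))
    assert tads.domains.empty


# ------------------------------------------------------------- summary


def test_median_of_three_domains():
    from hicplaid.tads import TadSet

    domains = pd.DataFrame(
        {
            "chrom": ["c"] * 3,
            "start": [0, 1_500_000, 4_000_000],
            "end": [1_000_000, 3_500_000, 7_000_000],  # sizes 1, 2, 3 Mb
        }
    )
    gaps = pd.DataFrame(columns=["chrom", "start", "end", "length", "kind", "center"])
    s = tad_summary(TadSet(domains, gaps))
    assert s["median_size"] == pytest.approx(2_000_000)
    assert s["count"] == 3


def test_summary_matches_sort_oracle(rng):
    sizes = rng.integers(1, 100, size=11) * 10_000
    starts = np.cumsum(np.concatenate([[0], sizes[:-1] + 50_000]))
    domains = pd.DataFrame(
        {"chrom": "c", "start": starts, "end": starts + sizes}
    )
    from hicplaid.tads import TadSet

    s = tad_summary(TadSet(domains, pd.DataFrame(columns=["chrom", "start", "end", "length", "kind", "center"])))
    assert s["median_size"] == sorted(sizes)[5]
    assert s["count"] == 11


# --------------------------------------------------------- TSS profile


def test_single_tss_lands_in_downstream_window():
    boundaries = pd.DataFrame({"chrom": ["c"], "center": [1_000_000]})
    tss = pd.DataFrame({"chrom": ["c"], "pos": [1_005_000]})
    prof = tss_profile(boundaries, tss, window_bp=10_000, span_bp=50_000)
    hit = prof.loc[prof["count"] > 0]
    assert len(hit) == 1
    assert hit.iloc[0]["offset_bp"] == 0
    assert hit.iloc[0]["count"] == 1


def test_no_tss_gives_zero_profile():
    boundaries = pd.DataFrame({"chrom": ["c"], "center": [500_000]})
    tss = pd.DataFrame({"chrom": [], "pos": []})
    prof = tss_profile(boundaries, tss)
    assert (prof["count"] == 0).all()


def test_planted_boundary_enrichment_recovered(rng):
    centers = np.arange(1, 6) * 2_000_000
    boundaries = pd.DataFrame({"chrom": "c", "center": centers})
    near = np.concatenate([c + rng.integers(-50_000, 50_000, 40) for c in centers])
    far = rng.integers(0, 12_000_000, 100)
    tss = pd.DataFrame({"chrom": "c", "pos": np.concatenate([near, far])})
    prof = tss_profile(boundaries, tss, window_bp=10_000, span_bp=500_000)
    offsets = prof["offset_bp"].to_numpy()
    central = prof.loc[np.abs(offsets + 5_000) <= 50_000, "count"]
    flank = prof.loc[np.abs(offsets) > 250_000, "count"]
    assert central.mean() > 2 * flank.mean()
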