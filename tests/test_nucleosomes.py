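"""Occupancy tracks, the simplified caller, distance histograms, TSS
metaplots and NDR metrics — unit oracles plus simulation recovery."""

import collections

import numpy as np
import pytest

import chromdev as cd
from chromdev.nucleosomes import (
    DOUBLET,
    MAIN_PEAK,
    MAIN_WITH_SHOULDER,
    SHOULDER,
    CallerParams,
    candidate_peaks,
)


# ---------------------------------------------------------------------------
# occupancy
# ---------------------------------------------------------------------------

def test_single_fragment_coverage():
    track = cd.occupancy_from_fragments(
        [cd.FragmentRecord("c1", 0, 147)], "c1", 300, mode="footprint_coverage"
    )
    assert track.values[:147].tolist() == [1.0] * 147
    assert track.values[147:].sum() == 0


def test_coverage_sum_conservation_and_brute_force():
    """Track sum equals total fragment length; per-base values match a
    brute-force counter on a 10 kb random fragment set."""
    rng = np.random.default_rng(0)
    frags = [
        cd.FragmentRecord("c1", int(s), int(s + l))
        for s, l in zip(rng.integers(0, 9800, 400), rng.integers(50, 200, 400))
    ]
    frags = [f for f in frags if f.end <= 10_000]
    track = cd.occupancy_from_fragments(frags, "c1", 10_000)
    assert track.values.sum() == sum(f.length for f in frags)
    brute = np.zeros(10_000)
    for f in frags:
        for b in range(f.start, f.end):
            brute[b] += 1
    np.testing.assert_array_equal(track.values, brute)


def test_midpoint_mode_counts_midpoints():
    frags = [cd.FragmentRecord("c1", 0, 100), cd.FragmentRecord("c1", 10, 110)]
    track = cd.occupancy_from_fragments(frags, "c1", 200, mode="midpoint")
    assert track.values[50] == 1 and track.values[60] == 1
    assert track.values.sum() == 2


def test_out_of_bounds_fragments_clipped_with_count():
    frags = [cd.FragmentRecord("c1", 90, 160)]
    track = cd.occupancy_from_fragments(frags, "c1", 100)
    assert track.n_clipped == 1
    assert track.values[90:].tolist() == [1.0] * 10


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def test_smoothing_delta_peak_and_constant():
    delta = np.zeros(501)
    delta[250] = 1.0
    sm = cd.smooth_track(cd.OccupancyTrack("c1", delta, mode="midpoint"))
    assert np.argmax(sm.values) == 250
    assert sm.mode == "smoothed_midpoint_density"
    const = cd.smooth_track(cd.OccupancyTrack("c1", np.full(300, 2.0)))
    np.testing.assert_allclose(const.values, 2.0)


def test_smoothing_conserves_mass():
    rng = np.random.default_rng(1)
    values = rng.poisson(3.0, size=2000).astype(float)
    sm = cd.smooth_track(cd.OccupancyTrack("c1", values), sigma_bp=25)
    assert sm.values.sum() == pytest.approx(values.sum(), rel=1e-6)


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def smoothed_deltas(positions, n, sigma=20.0, weights=None):
    v = np.zeros(n)
    for i, p in enumerate(positions):
        v[p] = weights[i] if weights else 1.0
    return cd.smooth_track(cd.OccupancyTrack("c1", v, mode="midpoint"), sigma_bp=sigma)


def test_isolated_peaks_recovered_exactly():
    track = smoothed_deltas([100, 280, 460], 600)
    calls = cd.call_nucleosomes(track)
    assert [c.dyad for c in calls] == [100, 280, 460]
    assert all(c.category == MAIN_PEAK for c in calls)


def test_close_peaks_merge_to_doublet():
    track = smoothed_deltas([200, 260], 500)
    calls = cd.call_nucleosomes(track)
    assert len(calls) == 1
    assert calls[0].category == DOUBLET
    assert abs(calls[0].dyad - 230) <= 2  # weighted centre of equal peaks


def test_shoulder_labelling():
    track = smoothed_deltas([200, 330], 600, weights=[1.0, 0.55])
    calls = cd.call_nucleosomes(track)
    cats = [c.category for c in calls]
    assert cats == [MAIN_WITH_SHOULDER, SHOULDER]


def test_all_zero_track_gives_no_calls():
    assert cd.call_nucleosomes(cd.OccupancyTrack("c1", np.zeros(500))) == []


def test_candidate_peaks_match_brute_force_maxima():
    """On short random smoothed tracks, candidate peaks equal brute-force
    local-maxima enumeration above the same floor."""
    rng = np.random.default_rng(2)
    params = CallerParams()
    for _ in range(20):
        raw = np.zeros(2000)
        raw[rng.integers(0, 2000, size=12)] = rng.integers(5, 40, size=12)
        v = cd.smooth_track(cd.OccupancyTrack("c1", raw, mode="midpoint")).values
        peaks, floor = candidate_peaks(v, params)
        brute = [
            i for i in range(1, len(v) - 1)
            if v[i] > v[i - 1] and v[i] > v[i + 1] and v[i] >= floor
        ]
        assert peaks.tolist() == brute


def test_caller_recovers_simulated_dyads(mnase_pipeline):
    """On phased arrays with 10 bp jitter and 30 fragments per nucleosome,
    at least 90% of true dyads are matched by a call within 20 bp."""
    dyads = mnase_pipeline["true_dyads"]
    by_contig = collections.defaultdict(list)
    for c in mnase_pipeline["calls"]:
        by_contig[c.contig].append(c.dyad)
    by_contig = {k: np.array(sorted(v)) for k, v in by_contig.items()}
    matched = sum(
        1
        for r in dyads.itertuples(index=False)
        if r.contig in by_contig and np.abs(by_contig[r.contig] - r.dyad).min() <= 20
    )
    assert matched / len(dyads) >= 0.90


# ---------------------------------------------------------------------------
# distance histogram
# ---------------------------------------------------------------------------

def mk_call(contig, dyad, category=MAIN_PEAK):
    return cd.NucleosomeCall(contig, dyad, dyad - 73, dyad + 74, category, 1.0)


def test_distances_arithmetic_and_mode():
    hist = cd.adjacent_distances([mk_call("c1", d) for d in (100, 280, 460)])
    assert hist.distances.tolist() == [180, 180]
    assert hist.mode == 180.0
    assert hist.total == 2


def test_no_cross_contig_pairs():
    calls = [mk_call("c1", 100), mk_call("c2", 400)]
    assert cd.adjacent_distances(calls).total == 0


def test_mainpeak_filter_drops_then_pairs():
    calls = [
        mk_call("c1", 100),
        mk_call("c1", 250, SHOULDER),
        mk_call("c1", 460),
    ]
    hist = cd.adjacent_distances(calls, category_filter="mainpeak")
    assert hist.distances.tolist() == [360]


def test_mode_tie_breaks_to_smaller_distance():
    calls = [mk_call("c1", d) for d in (0, 100, 300)]  # distances 100, 200
    assert cd.adjacent_distances(calls).mode == 100.0


def test_histogram_total_count_invariant(mnase_pipeline):
    """Total histogram count = Σ over contigs (n_retained − 1)."""
    calls = mnase_pipeline["calls"]
    hist = cd.adjacent_distances(calls, category_filter="mainpeak")
    per_contig = collections.Counter(
        c.contig for c in calls if c.category == MAIN_PEAK
    )
    expected = sum(n - 1 for n in per_contig.values() if n > 1)
    assert hist.total == expected


def test_empty_histogram_mode_absent():
    hist = cd.adjacent_distances([mk_call("c1", 100)])
    assert hist.mode is None


# ---------------------------------------------------------------------------
# metaplots and NDR
# ---------------------------------------------------------------------------

def test_metaplot_normalises_each_gene_to_one():
    values = np.zeros(4000)
    values[2100:2300] = 4.0  # window max 4 → normalized max 1
    tracks = {"c1": cd.OccupancyTrack("c1", values)}
    genes = [cd.GeneRecord("g1", "c1", 2000, 3000, "+")]
    mp = cd.tss_metaplot(tracks, genes, {"g1": "high"})
    assert mp.class_means["high"].max() == pytest.approx(1.0)
    assert np.all(mp.class_means["high"] >= 0) and np.all(mp.class_means["high"] <= 1)


def test_metaplot_minus_strand_mirrors_plus():
    rng = np.random.default_rng(3)
    values = rng.random(6000)
    tracks = {"c1": cd.OccupancyTrack("c1", values)}
    plus = [cd.GeneRecord("g1", "c1", 2500, 3500, "+")]
    mirrored = {"c1": cd.OccupancyTrack("c1", values[::-1].copy())}
    minus = [cd.GeneRecord("g1", "c1", 6000 - 3500, 6000 - 2500, "-")]
    mp_plus = cd.tss_metaplot(tracks, plus, {"g1": "x"})
    mp_minus = cd.tss_metaplot(mirrored, minus, {"g1": "x"})
    np.testing.assert_allclose(mp_plus.class_means["x"], mp_minus.class_means["x"])


def test_metaplot_excludes_out_of_window_and_zero_genes():
    tracks = {"c1": cd.OccupancyTrack("c1", np.zeros(3000))}
    genes = [
        cd.GeneRecord("edge", "c1", 100, 700, "+"),  # window leaves contig
        cd.GeneRecord("zero", "c1", 1500, 2000, "+"),  # all-zero window
    ]
    mp = cd.tss_metaplot(tracks, genes, {"edge": "a", "zero": "a"})
    assert mp.n_excluded == 2
    assert mp.n_genes == {}


def test_ndr_toy_profile_minimum():
    positions = -1000 + 10.0 * (np.arange(200) + 0.5)
    profile = np.ones(200)
    dip_bin = int(np.argmin(np.abs(positions - (-100))))
    profile[dip_bin - 2 : dip_bin + 3] = [0.8, 0.4, 0.2, 0.4, 0.8]  # V shape
    mp = cd.MetaplotMatrix(positions, {"x": profile}, {"x": 10}, 0)
    m = cd.ndr_metrics(mp, "x")
    assert m.min_pos == pytest.approx(positions[dip_bin])
    assert m.width == pytest.approx(30.0)  # bins below 0.5 x flank max


def test_ndr_flat_profile_zero_width():
    positions = -1000 + 10.0 * (np.arange(200) + 0.5)
    mp = cd.MetaplotMatrix(positions, {"x": np.ones(200)}, {"x": 5}, 0)
    assert cd.ndr_metrics(mp, "x").width == 0.0


def test_simulated_ndr_upstream_of_tss_and_monotone(mnase_pipeline):
    """Class-average minimum lies upstream of the TSS, and the measured NDR
    width increases with the simulated class width (high 300 > low 120)."""
    cfg = mnase_pipeline["config"]
    ann = mnase_pipeline["annotation"]
    # balanced explicit classes: half low, half high
    classes = {
        g.gene_id: ("low" if i % 2 else "high") for i, g in enumerate(ann.genes)
    }
    frags, _ = cd.simulate_mnase_fragments(ann, cfg, "wt", classes)
    tracks = {
        c.name: cd.occupancy_from_fragments(frags, c.name, c.length)
        for c in ann.contigs if not c.is_control
    }
    mp = cd.tss_metaplot(tracks, ann.genes, classes)
    low = cd.ndr_metrics(mp, "low")
    high = cd.ndr_metrics(mp, "high")
    assert low.min_pos < 0 and high.min_pos < 0
    assert high.width > low.width


def test_wild_type_like_equivalence_across_seeds():
    """Two datasets simulated from identical nucleosome parameters but
    different seeds give distance-histogram modes within one bin and
    metaplots differing by < 0.05 everywhere (the mutant's chromatin is
    wild-type-like)."""
    modes, metaplots = [], []
    for seed in (11, 12):
        cfg = cd.isolated_array_config(seed=seed, n_genes=260)
        classes = None  # derive inside pipelines
        hist = cd.nucleosome_spacing_pipeline(cfg, category_filter="mainpeak")
        modes.append(hist.mode)
        ann = cd.build_genome(cfg)
        all_high = {g.gene_id: "high" for g in ann.genes}
        mp = cd.tss_metaplot_pipeline(cfg, classes=all_high)
        metaplots.append(mp.class_means["high"])
    assert abs(modes[0] - modes[1]) <= 5.0
    assert np.max(np.abs(metaplots[0] - metaplots[1])) < 0.05
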