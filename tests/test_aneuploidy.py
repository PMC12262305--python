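import numpy as np
import pandas as pd
import pytest

from stic_atlas import aneuploidy as an
from stic_atlas.synthetic import LocusCounts, ReferencePanel, generate_dna_sample


def _lc(counts, loci=None, sample_id="s"):
    counts = np.asarray(counts)
    if loci is None:
        loci = pd.DataFrame(
            {"locus_id": [f"L{i}" for i in range(len(counts))],
             "chrom": "1", "pos0": np.arange(len(counts)) * 1000}
        )
    return LocusCounts(sample_id, loci, counts)


# ---------------------------------------------------------------------------
# normalisation and panel matching
# ---------------------------------------------------------------------------

def test_normalize_loci_examples():
    np.testing.assert_allclose(an.normalize_loci(_lc([2, 2, 2, 2])), 0.25)
    f1 = an.normalize_loci(_lc([3, 1, 6]))
    f2 = an.normalize_loci(_lc([30, 10, 60]))
    np.testing.assert_allclose(f1, f2)
    rng = np.random.default_rng(0)
    f = an.normalize_loci(_lc(rng.integers(1, 100, 50)))
    assert f.sum() == pytest.approx(1.0, abs=1e-12)


def test_match_reference_selects_exact_copy_first(dna_world):
    panel = dna_world["panel"]
    sample = panel.member(13)
    matched = an.match_reference(sample, panel, n_match=7)
    assert matched.member_ids[0] == panel.member_ids[13]


def test_match_reference_equals_brute_force(dna_world):
    g, loci, w, panel = (dna_world["genome"], dna_world["loci"],
                         dna_world["weights"], dna_world["panel"])
    s = generate_dna_sample("probe", loci, w, g, [], 300_000,
                            np.random.SeedSequence(987))
    matched = an.match_reference(s, panel, n_match=7)
    frac = an.normalize_loci(s)
    dists = [np.linalg.norm(panel.fractions()[i] - frac) for i in range(panel.size)]
    expected = [panel.member_ids[i] for i in np.argsort(dists, kind="stable")[:7]]
    assert matched.member_ids == expected


def test_match_reference_preconditions(dna_world):
    panel = dna_world["panel"]
    s = panel.member(0)
    with pytest.raises(ValueError, match="exceed"):
        an.match_reference(s, panel, n_match=30)
    other = _lc(np.ones(10, dtype=int), sample_id="odd")
    with pytest.raises(ValueError, match="locus mismatch"):
        an.match_reference(other, panel)


# ---------------------------------------------------------------------------
# arm Z-scores
# ---------------------------------------------------------------------------

def _toy_panel_on(genome, per_arm_counts, n_members=8, jitter=None):
    """Panel with one locus per scoreable arm and fixed per-member counts."""
    arms = genome.scoreable_arms()
    loci = pd.DataFrame(
        {"locus_id": [f"L{i}" for i in range(len(arms))],
         "chrom": [a.chrom for a in arms],
         "pos0": [a.start for a in arms]}
    )
    counts = np.tile(per_arm_counts, (n_members, 1)).astype(int)
    if jitter is not None:
        counts = counts + jitter
    return loci, ReferencePanel(loci, counts, [f"R{i}" for i in range(n_members)])


def test_sample_identical_to_panel_scores_zero(genome):
    loci, panel = _toy_panel_on(genome, np.full(39, 100))
    jit = np.zeros((8, 39), dtype=int)
    jit[:4, 0] = 1
    jit[4:, 0] = -1  # give arm 0 nonzero panel SD so z is defined there
    loci, panel = _toy_panel_on(genome, np.full(39, 100), jitter=jit)
    s = LocusCounts("s", loci, panel.counts[0])
    prof = an.arm_zscores(s, panel, genome)
    assert (prof.table.loc[prof.table["sigma"] > 0, "call"] == "neutral").all()


def test_arm_at_mu_plus_6_sigma_is_called_gain(genome):
    rng = np.random.default_rng(1)
    base = np.full(39, 1000)
    jitter = rng.integers(-30, 31, size=(8, 39))
    loci, panel = _toy_panel_on(genome, base, jitter=jitter)
    arm_fracs = panel.fractions()  # members x arms (one locus per arm)
    mu = arm_fracs.mean(axis=0)
    sigma = arm_fracs.std(axis=0, ddof=1)
    # construct a sample whose arm-0 fraction sits exactly at mu + 6 sigma
    target = mu.copy()
    target[0] = mu[0] + 6 * sigma[0]
    target /= target.sum()
    total = 10_000_000
    counts = np.round(target * total).astype(int)
    s = LocusCounts("s", loci, counts)
    prof = an.arm_zscores(s, panel, genome)
    # renormalisation of the constructed sample keeps z near (not exactly) 6
    arm0 = prof.table.index[0]
    assert prof.table.loc[arm0, "z"] == pytest.approx(6.0, rel=0.05)
    assert prof.table.loc[arm0, "call"] == "gain"


def test_zero_sigma_arm_flagged_neutral(genome):
    loci, panel = _toy_panel_on(genome, np.full(39, 100))
    counts = np.full(39, 100)
    counts[0] = 500
    s = LocusCounts("s", loci, counts)
    with pytest.warns(UserWarning, match="zero panel SD"):
        prof = an.arm_zscores(s, panel, genome)
    assert (prof.table["call"] == "neutral").all()
    assert prof.warnings_


def test_simulated_single_arm_loss_detected(dna_world):
    """A log2 -1 single-arm loss is called on that arm and nowhere else."""
    g, loci, w, panel = (dna_world["genome"], dna_world["loci"],
                         dna_world["weights"], dna_world["panel"])
    hits = clean = 0
    n = 20
    for i, seed in enumerate(np.random.SeedSequence(55).spawn(n)):
        s = generate_dna_sample(f"L{i}", loci, w, g, [("9q", -1.0)], 300_000, seed)
        prof = an.arm_zscores(s, an.match_reference(s, panel), g)
        hits += prof.table.loc["9q", "call"] == "loss"
        others = prof.table.drop(index="9q")
        clean += (others["call"] == "neutral").all()
    assert hits >= int(0.95 * n)
    assert clean >= int(0.9 * n)


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def test_bins_zero_when_sample_equals_panel_mean(dna_world):
    g, panel = dna_world["genome"], dna_world["panel"]
    mean_counts = panel.counts.mean(axis=0)
    s = LocusCounts("avg", panel.loci, np.round(mean_counts).astype(int))
    bins = an.bin_log2_ratios(s, panel, g)
    vals = bins["log2"].dropna()
    assert np.abs(vals).median() < 0.1


def test_bin_with_doubled_fraction_near_one():
    loci = pd.DataFrame(
        {"locus_id": [f"L{i}" for i in range(100)],
         "chrom": "1", "pos0": np.arange(100) * 40_000}
    )
    base = np.full(100, 1000)
    panel = ReferencePanel(loci, np.tile(base, (8, 1)), [f"R{i}" for i in range(8)])
    counts = base.copy()
    counts[0] *= 2  # bin 0 holds exactly locus 0 (two loci per 50-kb bin? 40kb spacing)
    s = LocusCounts("s", loci, counts)
    from stic_atlas.genome import toy_genome

    bins = an.bin_log2_ratios(s, panel, toy_genome(), pseudo=1e-6)
    first = bins.dropna(subset=["log2"]).iloc[0]
    # bin 0 covers loci 0 (doubled) and 1: ratio (2+1)/2 before renormalisation
    assert first["log2"] == pytest.approx(np.log2(3 / 2), abs=0.02)


def test_pseudocount_shrinks_ratios_toward_zero(dna_world):
    g, loci, w, panel = (dna_world["genome"], dna_world["loci"],
                         dna_world["weights"], dna_world["panel"])
    s = generate_dna_sample("p", loci, w, g, [("4q", 0.8)], 300_000,
                            np.random.SeedSequence(3))
    small = an.bin_log2_ratios(s, panel, g, pseudo=0.5)["log2"]
    large = an.bin_log2_ratios(s, panel, g, pseudo=50.0)["log2"]
    ok = small.notna() & large.notna()
    assert (np.abs(large[ok]) <= np.abs(small[ok]) + 1e-12).all()


# ---------------------------------------------------------------------------
# CBS
# ---------------------------------------------------------------------------

def _bins_from(x, chrom="1", bin_bp=50_000):
    n = len(x)
    return pd.DataFrame(
        {"chrom": chrom, "start": np.arange(n) * bin_bp,
         "end": (np.arange(n) + 1) * bin_bp, "n_loci": 1, "log2": x}
    )


def test_cbs_noiseless_step_found_exactly():
    x = np.concatenate([np.zeros(100), np.ones(100)])
    seg = an.cbs_segment(_bins_from(x), seed=0)
    assert len(seg) == 2
    assert seg["start"].tolist() == [0, 100 * 50_000]
    np.testing.assert_allclose(seg["seg_log2"], [0.0, 1.0])


def test_cbs_constant_signal_single_segment():
    seg = an.cbs_segment(_bins_from(np.full(150, 0.3)), seed=0)
    assert len(seg) == 1
    assert seg.iloc[0]["n_bins"] == 150


def test_cbs_segments_partition_bins_and_means_match():
    rng = np.random.default_rng(9)
    x = np.concatenate([rng.normal(0, 0.2, 80), rng.normal(0.8, 0.2, 60),
                        rng.normal(-0.6, 0.2, 60)])
    bins = _bins_from(x)
    seg = an.cbs_segment(bins, seed=1)
    assert seg["n_bins"].sum() == len(x)
    for _, row in seg.iterrows():
        member = bins[(bins["start"] >= row["start"]) & (bins["end"] <= row["end"])]
        assert row["seg_log2"] == pytest.approx(member["log2"].mean(), abs=1e-9)


def test_cbs_noisy_step_breakpoint_accuracy():
    hits = 0
    n = 20
    for i in range(n):
        rng = np.random.default_rng(300 + i)
        x = np.concatenate([np.zeros(100), np.full(100, 0.58)]) + rng.normal(0, 0.2, 200)
        seg = an.cbs_segment(_bins_from(x), seed=i)
        bps = seg["start"].to_numpy()[1:] // 50_000
        hits += any(abs(int(bp) - 100) <= 2 for bp in bps)
    assert hits >= 18


def test_cbs_skips_all_missing_chromosome():
    bins = _bins_from(np.full(20, np.nan))
    assert len(an.cbs_segment(bins, seed=0)) == 0


# ---------------------------------------------------------------------------
# focal calls and aneuploidy index
# ---------------------------------------------------------------------------

def test_focal_call_rules(genome):
    band = genome.band_by_name("19q12")
    arm = genome.arm_by_name("19q")
    whole_arm = pd.DataFrame(
        [{"chrom": "19", "start": arm.start, "end": arm.end,
          "n_bins": 120, "seg_log2": 0.6}]
    )
    calls = an.call_focal_amplifications(whole_arm, genome)
    assert not calls["19q12"]["called"]  # not sub-chromosomal

    focal = pd.DataFrame(
        [{"chrom": "19", "start": band["start"], "end": band["start"] + 1_000_000,
          "n_bins": 20, "seg_log2": 0.5}]
    )
    calls = an.call_focal_amplifications(focal, genome)
    assert calls["19q12"]["called"]
    assert calls["19q12"]["seg_log2"] == pytest.approx(0.5)

    weak = focal.assign(seg_log2=0.2)
    assert not an.call_focal_amplifications(weak, genome)["19q12"]["called"]

    with pytest.raises(KeyError, match="unknown cytoband"):
        an.call_focal_amplifications(focal, genome, targets=["99z99"])


def test_aneuploidy_index_arithmetic():
    flat = _bins_from(np.zeros(100))
    seg_flat = an.cbs_segment(flat, seed=0)
    assert an.aneuploidy_index(flat, seg_flat) == 0

    x = np.zeros(100)
    x[10:50] = 0.5
    bins = _bins_from(x)
    segs = pd.DataFrame(
        [{"chrom": "1", "start": 0, "end": 500_000, "n_bins": 10, "seg_log2": 0.0},
         {"chrom": "1", "start": 500_000, "end": 2_500_000, "n_bins": 40,
          "seg_log2": 0.5},
         {"chrom": "1", "start": 2_500_000, "end": 5_000_000, "n_bins": 50,
          "seg_log2": 0.0}]
    )
    assert an.aneuploidy_index(bins, segs) == 40 * 50_000


def test_aneuploidy_index_threshold_monotone():
    rng = np.random.default_rng(11)
    x = rng.normal(0, 0.4, 200)
    bins = _bins_from(x)
    lo = an.aneuploidy_index(bins, None, log2_gain=0.25, log2_loss=-0.25, level="bin")
    hi = an.aneuploidy_index(bins, None, log2_gain=0.3, log2_loss=-0.3, level="bin")
    assert hi <= lo


def test_whole_genome_gain_fills_index():
    """Bins uniformly at log2 0.58 count every binned base pair."""
    bins = _bins_from(np.full(200, 0.58))
    segs = an.cbs_segment(bins, seed=0)
    assert an.aneuploidy_index(bins, segs) == int((bins["end"] - bins["start"]).sum())
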