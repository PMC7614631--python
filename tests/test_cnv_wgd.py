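"""Coverage segmentation, WGD calling/dating, LoY, recurrence, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from devilclones.cnv_wgd import (
    arm_event_enrichment,
    call_wgd,
    date_wgd,
    detect_loy,
    gain_loss_depth,
    gene_deletion_screen,
    modal_cn,
    recurrence_map,
    segment_coverage,
)
from devilclones.trees import CloneTree


def _bins(depths, chrom="chr1", bin_size=1000):
    return pd.DataFrame({
        "chrom": chrom,
        "start": np.arange(len(depths)) * bin_size,
        "depth": depths,
    })


def _star_tree(labels):
    parent = {i + 1: 0 for i in range(len(labels))}
    dates = {i + 1: 2015.0 for i in range(len(labels))}
    return CloneTree(parent, dates, {i + 1: s for i, s in enumerate(labels)})


class TestSegmentation:
    def test_flat_depth_single_segment_at_ploidy(self):
        segs = segment_coverage(_bins(np.ones(500)), purity=1.0, ploidy=2)
        assert len(segs) == 1
        assert segs[0].cn == 2
        assert segs[0].n_bins == 500

    def test_noiseless_step_breakpoint_within_one_bin(self):
        y = np.concatenate([np.ones(500), np.full(500, 1.5)])
        segs = segment_coverage(_bins(y), purity=1.0, ploidy=2)
        assert [s.cn for s in segs] == [2, 3]
        assert abs(segs[0].end - 500_000) <= 1000

    def test_noisy_step_recovered(self):
        rng = np.random.default_rng(5)
        y = np.concatenate([np.ones(600), np.full(400, 0.5)]) + rng.normal(0, 0.05, 1000)
        segs = segment_coverage(_bins(y), purity=1.0, ploidy=2)
        assert [s.cn for s in segs] == [2, 1]
        assert abs(segs[0].end - 600_000) <= 3000

    def test_all_zero_coverage_errors(self):
        with pytest.raises(ValueError):
            segment_coverage(_bins(np.zeros(100)))

    def test_segments_tile_chromosome(self):
        rng = np.random.default_rng(8)
        y = np.concatenate([np.ones(300), np.full(200, 1.5), np.ones(300)])
        y += rng.normal(0, 0.04, len(y))
        segs = segment_coverage(_bins(y), purity=1.0, ploidy=2)
        assert segs[0].start == 0
        assert segs[-1].end == len(y) * 1000
        for a, b in zip(segs[:-1], segs[1:]):
            assert a.end == b.start

    def test_purity_correction(self):
        # CN 3 at purity 0.8 on diploid baseline: depth (0.8*3+0.4)/2 = 1.4
        y = np.concatenate([np.ones(500), np.full(500, 1.4)])
        segs = segment_coverage(_bins(y), purity=0.8, ploidy=2)
        assert [s.cn for s in segs] == [2, 3]


class TestGeneDeletionScreen:
    ANN = pd.DataFrame({
        "gene_id": ["MMR1", "OTHER1"],
        "chrom": ["chr1", "chr1"],
        "start": [250_000, 700_000],
        "end": [253_000, 703_000],
        "strand": ["+", "+"],
    })

    def test_no_submodal_segments_empty(self):
        segs = segment_coverage(_bins(np.ones(1000)), purity=1.0, ploidy=2)
        assert gene_deletion_screen(segs, self.ANN).empty

    def test_planted_focal_deletion_hits_one_gene(self):
        """A focal single-copy loss over an MMR gene is found, focally."""
        y = np.ones(1000)
        y[240:260] = 0.5
        segs = segment_coverage(_bins(y), purity=1.0, ploidy=2)
        hits = gene_deletion_screen(segs, self.ANN)
        assert list(hits.gene_id) == ["MMR1"]
        assert bool(hits.iloc[0].focal) and not bool(hits.iloc[0].homozygous)

    def test_homozygous_deletion_flagged(self):
        y = np.ones(1000)
        y[240:260] = 0.0
        segs = segment_coverage(_bins(y), purity=1.0, ploidy=2)
        hits = gene_deletion_screen(segs, self.ANN)
        assert bool(hits.iloc[0].homozygous)


class TestWgd:
    def _tetra_sample(self, purity, n_var=600, seed=0):
        rng = np.random.default_rng(seed)
        denom = 4 * purity + 2 * (1 - purity)
        m2, m1 = 2 * purity / denom, purity / denom
        ps = np.array([m2] * (n_var // 2) + [m1] * (n_var // 2))
        dp = rng.poisson(80, len(ps))
        alt = rng.binomial(dp, ps)
        return alt / np.maximum(dp, 1)

    def test_diploid_not_flagged(self):
        segs = segment_coverage(_bins(np.ones(800)), purity=1.0, ploidy=2)
        vafs = np.random.default_rng(1).normal(0.5, 0.05, 500)
        assert not call_wgd(segs, vafs, 1.0).tetraploid

    def test_tetraploid_pure_flagged_with_modes(self):
        segs = segment_coverage(_bins(np.ones(800)), purity=1.0, ploidy=4)
        call = call_wgd(segs, self._tetra_sample(1.0), 1.0)
        assert call.modal_cn == 4 and call.tetraploid
        assert call.vaf_modes == pytest.approx((0.5, 0.25))

    def test_tetraploid_purity_08_modes(self):
        segs = segment_coverage(_bins(np.ones(800)), purity=0.8, ploidy=4)
        call = call_wgd(segs, self._tetra_sample(0.8, seed=2), 0.8)
        assert call.tetraploid
        assert call.vaf_modes == pytest.approx((0.4444, 0.2222), abs=1e-3)

    def test_date_wgd_zero_post_count_is_sampling_date(self):
        d, _ = date_wgd(100, 0, rate=496.3, sampling_date=2017.5)
        assert d == 2017.5

    def test_date_wgd_arithmetic(self):
        # 1985 post-WGD mutations at kappa*r = 2 x 496.3 is exactly 2 years
        d, _ = date_wgd(5000, 1985, rate=496.3, sampling_date=2017.0, kappa=2.0)
        assert 2017.0 - d == pytest.approx(1985 / (2 * 496.3))
        assert 2017.0 - d == pytest.approx(2.0, abs=2e-3)

    def test_planted_wgd_dates_recovered(self, dft2_small=None):
        """Round trip: simulate tetraploid mixtures at known WGD dates and
        recover them within +/- 0.5 years at ~80x."""
        rng = np.random.default_rng(9)
        r = 496.3
        recovered = []
        for true_elapsed in (1.0, 1.8, 4.0, 7.0):
            sampling = 2017.0
            post = rng.poisson(2 * r * true_elapsed)
            d, ival = date_wgd(4000, post, rate=r, sampling_date=sampling,
                               rate_interval=(436.0, 556.5))
            recovered.append(sampling - d - true_elapsed)
            assert ival[0] <= d <= ival[1]
        assert np.max(np.abs(recovered)) < 0.5


class TestLoY:
    def test_expected_ratio_no_loss(self):
        y = _bins(np.full(200, 0.5), chrom="chrY")
        a = _bins(np.ones(2000))
        assert not detect_loy(y, a, purity=1.0, founder_sex="male")

    def test_zero_y_coverage_is_loss(self):
        y = _bins(np.full(200, 0.01), chrom="chrY")
        a = _bins(np.ones(2000))
        assert detect_loy(y, a, purity=1.0, founder_sex="male")

    def test_female_founder_refused(self):
        y = _bins(np.full(200, 0.5), chrom="chrY")
        with pytest.raises(ValueError):
            detect_loy(y, y, purity=1.0, founder_sex="female")

    def test_five_planted_losses_map_to_five_origins(self):
        """Five LoY events, one at a clade stem shared by the whole clade."""
        from devilclones.phylo_clock import map_event_to_tree

        # tree: one 6-tip clade + 14 loose tips
        parent, dates, labels = {1: 0}, {0: 2014.0, 1: 2015.0}, {}
        nxt = 2
        for i in range(6):
            parent[nxt] = 1
            dates[nxt] = 2017.0
            labels[nxt] = f"c{i}"
            nxt += 1
        for i in range(14):
            parent[nxt] = 0
            dates[nxt] = 2017.0
            labels[nxt] = f"s{i}"
            nxt += 1
        t = CloneTree(parent, dates, labels)
        carriers = {f"c{i}" for i in range(6)} | {"s0", "s3", "s7", "s11"}
        origins = map_event_to_tree(t, carriers, polarity="loss")
        assert len(origins) == 5
        assert 1 in origins  # the clade stem


class TestRecurrence:
    def test_sister_tips_share_one_occurrence(self):
        """The same CNV in two sister tips deduplicates to depth 1."""
        parent = {1: 0, 2: 1, 3: 1, 4: 0}
        t = CloneTree(parent, {2: 2015.0, 3: 2015.0, 4: 2015.0},
                      {2: "A", 3: "B", 4: "C"})
        seg = lambda cn: [  # noqa: E731
            type("S", (), {"chrom": "chr1", "start": 100_000, "end": 200_000,
                           "cn": cn, "n_bins": 100, "mean_depth": 1.0})(),
            type("S", (), {"chrom": "chr1", "start": 0, "end": 100_000,
                           "cn": 2, "n_bins": 100, "mean_depth": 1.0})(),
            type("S", (), {"chrom": "chr1", "start": 200_000, "end": 1_000_000,
                           "cn": 2, "n_bins": 800, "mean_depth": 1.0})(),
        ]
        events, _ = recurrence_map({"A": seg(3), "B": seg(3), "C": seg(2)}, t)
        assert len(events) == 1
        assert events.iloc[0].n_origins == 1 and events.iloc[0].n_carriers == 2

    def test_unrelated_carriers_two_occurrences(self):
        parent = {1: 0, 2: 1, 3: 1, 4: 0, 5: 0}
        t = CloneTree(parent, {2: 2015.0, 3: 2015.0, 4: 2015.0, 5: 2015.0},
                      {2: "A", 3: "B", 4: "C", 5: "D"})
        mk = lambda cn: [  # noqa: E731
            type("S", (), {"chrom": "chr1", "start": 100_000, "end": 200_000,
                           "cn": cn, "n_bins": 100, "mean_depth": 1.0})(),
            type("S", (), {"chrom": "chr1", "start": 200_000, "end": 2_000_000,
                           "cn": 2, "n_bins": 1800, "mean_depth": 1.0})(),
        ]
        events, _ = recurrence_map({"A": mk(3), "B": mk(2), "C": mk(3), "D": mk(2)}, t)
        assert events.iloc[0].n_origins == 2
        track = gain_loss_depth(events, {"chr1": 2_000_000})["chr1"]
        peak = track.gain_depth.max()
        assert peak == 2  # depth equals deduplicated origin count

    def test_depth_conservation(self):
        """Sum of track depth changes equals total deduplicated origins."""
        parent = {1: 0, 2: 1, 3: 1, 4: 0, 5: 0}
        t = CloneTree(parent, {2: 2015.0, 3: 2015.0, 4: 2015.0, 5: 2015.0},
                      {2: "A", 3: "B", 4: "C", 5: "D"})
        rng = np.random.default_rng(3)
        samples = {}
        for s in "ABCD":
            segs = []
            pos = 0
            for _ in range(3):
                ln = int(rng.integers(100, 400)) * 1000
                cn = int(rng.choice([1, 2, 3]))
                segs.append(type("S", (), {"chrom": "chr1", "start": pos,
                                           "end": pos + ln, "cn": cn,
                                           "n_bins": ln // 1000,
                                           "mean_depth": 1.0})())
                pos += ln
            segs.append(type("S", (), {"chrom": "chr1", "start": pos,
                                       "end": 2_000_000, "cn": 2,
                                       "n_bins": (2_000_000 - pos) // 1000,
                                       "mean_depth": 1.0})())
            samples[s] = segs
        events, _ = recurrence_map(samples, t, sample_modal={s: 2 for s in "ABCD"})
        assert len(events) == events.groupby(["cnv_id", "origin_branch"]).ngroups


class TestArmEnrichment:
    def test_equal_frequencies_p_one(self):
        t = np.array([True] * 10 + [False] * 10)
        e = np.array(([True] * 5 + [False] * 5) * 2)
        p, _ = arm_event_enrichment(t, e)
        assert p == pytest.approx(1.0)

    def test_perfect_separation_matches_hypergeom(self):
        """[[10,0],[0,10]] p equals the hypergeometric enumeration."""
        t = np.array([True] * 10 + [False] * 10)
        e = np.array([True] * 10 + [False] * 10)
        p, table = arm_event_enrichment(t, e)
        # exact two-sided Fisher p by enumerating the hypergeometric support
        rv = hypergeom(20, 10, 10)
        p0 = rv.pmf(10)
        p_exact = sum(rv.pmf(k) for k in range(0, 11) if rv.pmf(k) <= p0 * (1 + 1e-9))
        assert p == pytest.approx(p_exact, rel=1e-6)

    def test_planted_enrichment_detected(self):
        """Tetraploids with 4x the arm-event probability yield p < 0.01 in
        the majority of scaled replicates (19 vs 100 design)."""
        rng = np.random.default_rng(21)
        wins = 0
        for _ in range(30):
            tet = np.array([True] * 19 + [False] * 100)
            pe = np.where(tet, 0.8, 0.2)
            ev = rng.random(len(tet)) < pe
            try:
                p, _ = arm_event_enrichment(tet, ev)
            except ValueError:
                continue
            wins += p < 0.01
        assert wins > 15

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            arm_event_enrichment(np.array([True, True]), np.array([True, False]))
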