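"""Spectra, NNLS signature fitting, burden regressions, ratios, outliers."""

import numpy as np
import pandas as pd
import pytest

from devilclones.rates import (
    burden_regression,
    detect_rate_shift,
    flag_hypermutators,
    rate_ratio,
)
from devilclones.signatures import (
    ID_CHANNELS,
    SBS_CHANNELS,
    ReferenceSignatures,
    Spectrum,
    build_spectrum,
    fit_signatures,
    indel_channel,
    sbs_channel,
)
from devilclones.simcohort import dft1_config, simulate_mutations, simulate_transmission_tree


def _clock_rates(sub):
    return {"substitution": sub, "indel": 0.0, "line1_insertion": 0.0,
            "rearrangement_event": 0.0, "cnv_event": 0.0}


class TestSpectrum:
    def test_purine_reference_reverse_complemented(self):
        # G>A with reference triplet 5'-CGT-3' maps to C>T at 5'-ACG-3'
        assert sbs_channel("G", "A", "CGT") == "A[C>T]G"

    def test_pyrimidine_reference_kept(self):
        assert sbs_channel("C", "T", "ACG") == "A[C>T]G"

    def test_empty_input_all_zero(self):
        v = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "var_class", "context"])
        sbs, ind = build_spectrum(v)
        assert sbs.total == 0 and ind.total == 0

    def test_channel_totals_match_bruteforce_loop(self, small_genome):
        """Spectrum built from the genome equals a per-variant classification
        loop done independently here."""
        cfg = dft1_config(
            n_tumours=3, sampling_window=(1990.0, 1992.0),
            rates={"substitution": 800.0, "indel": 300.0, "line1_insertion": 0,
                   "rearrangement_event": 0, "cnv_event": 0},
        )
        t = simulate_transmission_tree(cfg, np.random.default_rng(4))
        variants, _ = simulate_mutations(t, cfg, small_genome, np.random.default_rng(4))
        sbs, ind = build_spectrum(variants, genome=small_genome)
        # independent loop using only genome primitives
        exp_sbs = {c: 0 for c in SBS_CHANNELS}
        exp_ind = {c: 0 for c in ID_CHANNELS}
        for row in variants.itertuples(index=False):
            if row.var_class == "substitution":
                trip = small_genome.triplet(row.chrom, int(row.pos))
                exp_sbs[sbs_channel(row.ref, row.alt, trip)] += 1
            elif row.var_class == "indel":
                ins = len(row.alt) > len(row.ref)
                base = row.alt[-1] if ins else row.ref[-1]
                run = small_genome.homopolymer_run(row.chrom, int(row.pos) + 1)
                exp_ind[indel_channel("ins" if ins else "del", base, run)] += 1
        assert sbs.counts.to_dict() == exp_sbs
        assert ind.counts.to_dict() == exp_ind
        # simulator's own channel labels agree with genome-derived ones
        subs = variants[variants.var_class == "substitution"]
        trips = [small_genome.triplet(r.chrom, int(r.pos)) for r in subs.itertuples()]
        recomputed = [sbs_channel(r.ref, r.alt, tr)
                      for r, tr in zip(subs.itertuples(), trips)]
        assert recomputed == list(subs.context)


class TestFitSignatures:
    def test_pure_signature_recovered_exactly(self):
        refs = ReferenceSignatures.load_sbs()
        spec = Spectrum(refs.matrix["SBS1"] * 1000.0)
        fit = fit_signatures(spec, refs)
        assert fit.exposures["SBS1"] == pytest.approx(1000.0, abs=0.01)
        assert fit.exposures["SBS5"] == pytest.approx(0.0, abs=1e-6)
        assert fit.residual_norm == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("mix", [(0.66, 0.34), (0.47, 0.53)])
    def test_indel_mixture_proportions_recovered(self, mix):
        """ID1:ID2 mixtures recovered within +/- 5 points."""
        refs = ReferenceSignatures.load_indel().subset(["ID1", "ID2"])
        rng = np.random.default_rng(17)
        probs = refs.matrix.to_numpy() @ np.array(mix)
        counts = rng.multinomial(3000, probs)
        fit = fit_signatures(Spectrum(pd.Series(counts, index=ID_CHANNELS)), refs)
        props = fit.proportions()
        assert props["ID1"] == pytest.approx(mix[0], abs=0.05)
        assert props["ID2"] == pytest.approx(mix[1], abs=0.05)

    def test_degenerate_signatures_flagged(self):
        refs = ReferenceSignatures.load_sbs()
        dup = refs.matrix[["SBS1"]].copy()
        dup["SBS1b"] = dup["SBS1"]
        from devilclones.signatures import ReferenceSignatures as RS

        spec = Spectrum((refs.matrix["SBS1"] * 500).round().astype(int))
        with pytest.warns(UserWarning, match="non-identifiable"):
            fit = fit_signatures(spec, RS(dup))
        assert not fit.identifiable

    def test_nonnegative_exposures(self):
        refs = ReferenceSignatures.load_sbs()
        rng = np.random.default_rng(3)
        spec = Spectrum(pd.Series(rng.integers(0, 50, len(SBS_CHANNELS)),
                                  index=SBS_CHANNELS))
        fit = fit_signatures(spec, refs)
        assert (fit.exposures >= 0).all()


class TestBurdenRegression:
    def test_exact_line(self):
        fit = burden_regression([0.0, 150.0, 300.0], [2000.0, 2001.0, 2002.0])
        assert fit.slope == pytest.approx(150.0)
        assert fit.p_value < 1e-6

    def test_constant_burden_not_significant(self):
        fit = burden_regression([100, 101, 99, 100, 100],
                                [2000, 2001, 2002, 2003, 2004])
        assert abs(fit.slope) < 1.0
        assert not fit.significant

    def test_identical_dates_error(self):
        with pytest.raises(ValueError):
            burden_regression([1, 2, 3], [2000, 2000, 2000])

    def test_dft2_design_ci_coverage(self):
        """Slope CI covers the true 496.3/yr in >= 90/100 DFT2-like
        replicates (41 tumours, 2014-2018)."""
        from devilclones.simcohort import dft2_config

        hits = 0
        for rep in range(100):
            cfg = dft2_config(
                rates=_clock_rates(496.3) | {"substitution": 496.3}, seed=3000 + rep
            )
            t = simulate_transmission_tree(cfg, np.random.default_rng(3000 + rep))
            _, truth = simulate_mutations(t, cfg, None, np.random.default_rng(4000 + rep))
            burdens = [truth.tip_burdens[t.labels[n]]["substitution"] for n in t.tips()]
            dates = [t.dates[n] for n in t.tips()]
            fit = burden_regression(burdens, dates)
            lo, hi = fit.slope_interval
            hits += lo <= 496.3 <= hi
        assert hits >= 90

    def test_f_test_type_i_error_controlled(self):
        """Date-independent Poisson noise triggers the F-test at ~5%."""
        rng = np.random.default_rng(9)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            dates = rng.uniform(2003, 2018, size=20)
            burdens = rng.poisson(3000, size=20)
            rejections += burden_regression(burdens, dates).p_value < 0.05
        rate = rejections / n_rep
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep)


class TestRateRatio:
    def _fit(self, slope, se, n=40):
        rng = np.random.default_rng(1)
        dates = np.linspace(2000, 2010, n)
        return burden_regression(slope * (dates - 1990) + rng.normal(0, 1, n), dates)

    def test_published_point_ratios(self):
        """Printed DFT1/DFT2 regression slopes give ratios 3.041 and 3.182."""
        assert 496.3 / 163.2 == pytest.approx(3.041, abs=5e-4)
        assert 479.2 / 150.6 == pytest.approx(3.182, abs=5e-4)

    def test_equal_rates_ratio_one_and_reciprocity(self):
        a = self._fit(100.0, 1.0)
        b = self._fit(250.0, 1.0)
        assert rate_ratio(a, a).ratio == pytest.approx(1.0)
        ab, ba = rate_ratio(a, b), rate_ratio(b, a)
        assert ab.ratio * ba.ratio == pytest.approx(1.0)

    def test_nonsignificant_rate_suppressed(self):
        good = self._fit(100.0, 1.0)
        flat = burden_regression([100, 101, 99, 100], [2000, 2001, 2002, 2003])
        assert rate_ratio(flat, good).ratio is None

    def test_delta_interval_matches_monte_carlo_oracle(self):
        """Delta-method CI endpoints within 2% of a 1e5-draw Monte-Carlo
        propagation with the same normal slope errors."""
        a = burden_regression(
            163.2 * (np.linspace(2003, 2018, 63) - 1986)
            + np.random.default_rng(5).normal(0, 400, 63),
            np.linspace(2003, 2018, 63),
        )
        b = burden_regression(
            496.3 * (np.linspace(2014, 2018, 41) - 2011)
            + np.random.default_rng(6).normal(0, 300, 41),
            np.linspace(2014, 2018, 41),
        )
        rr = rate_ratio(a, b)
        rng = np.random.default_rng(7)
        draws_a = rng.normal(a.slope, a.slope_se, 100_000)
        draws_b = rng.normal(b.slope, b.slope_se, 100_000)
        mc = draws_b / draws_a
        mc_lo, mc_hi = np.quantile(mc, [0.025, 0.975])
        assert rr.interval_delta[0] == pytest.approx(mc_lo, rel=0.02)
        assert rr.interval_delta[1] == pytest.approx(mc_hi, rel=0.02)


class TestRateShift:
    def _cohort(self, seed, offset=0.0, n=40):
        cfg = dft1_config(n_tumours=n, rates=_clock_rates(202.0), seed=seed)
        t = simulate_transmission_tree(cfg, np.random.default_rng(seed))
        _, truth = simulate_mutations(t, cfg, None, np.random.default_rng(seed + 1))
        burdens = {t.labels[n_]: float(truth.tip_burdens[t.labels[n_]]["substitution"])
                   for n_ in t.tips()}
        dates = {t.labels[n_]: t.dates[n_] for n_ in t.tips()}
        target = None
        if offset:
            sets = t.tipsets()
            cands = [n_ for n_ in t.nodes
                     if n_ != t.root and not t.is_tip(n_)
                     and 10 <= len(sets[n_]) <= n - 10]
            target = max(cands, key=lambda n_: len(sets[n_]))
            for s in sets[target]:
                burdens[s] = max(0.0, burdens[s] + offset)
        return t, burdens, dates, target

    def test_null_burdens_controlled(self):
        """Burdens that depend only on date (no clade effect) stay below
        q < 0.05 on >= 95/100 replicates."""
        rng = np.random.default_rng(11)
        clean = 0
        for rep in range(100):
            t, _, dates, _ = self._cohort(5000 + rep)
            burdens = {s: float(rng.poisson(202.0 * (d - 1986.0)))
                       for s, d in dates.items()}
            rep_df = detect_rate_shift(t, burdens, dates)
            clean += not rep_df["significant"].any() if len(rep_df) else True
        assert clean >= 95

    def test_planted_deficit_recovered(self):
        """A planted -1200 clade offset is flagged and sized within 20%."""
        found = []
        for seed in (61, 62, 63):
            t, burdens, dates, target = self._cohort(seed, offset=-1200.0)
            df = detect_rate_shift(t, burdens, dates)
            hit = df[df.branch == target].iloc[0]
            assert hit.q < 0.05
            found.append(hit.offset)
        assert np.mean(found) == pytest.approx(-1200.0, rel=0.2)


class TestHypermutators:
    def test_points_on_line_unflagged(self):
        dates = {f"s{i}": 2000.0 + i for i in range(8)}
        burdens = {s: 100.0 * (d - 1995.0) for s, d in dates.items()}
        rep = flag_hypermutators(burdens, dates)
        assert not rep.flagged.any()

    def test_planted_outlier_fold_recovered(self):
        """A 6x substitution outlier flags with fold-excess ~ 6."""
        rng = np.random.default_rng(13)
        dates = {f"s{i}": float(d) for i, d in enumerate(np.linspace(2003, 2018, 30))}
        burdens = {s: float(rng.poisson(200.0 * (d - 1986.0)))
                   for s, d in dates.items()}
        victim = "s15"
        burdens[victim] *= 6.0
        rep = flag_hypermutators(burdens, dates).set_index("sample")
        assert rep.loc[victim, "flagged"]
        assert rep.loc[victim, "fold_excess"] == pytest.approx(6.0, rel=0.1)
        assert rep.flagged.sum() == 1

    def test_flags_monotone_in_threshold(self):
        rng = np.random.default_rng(14)
        dates = {f"s{i}": float(d) for i, d in enumerate(np.linspace(2003, 2018, 25))}
        burdens = {s: float(rng.poisson(200.0 * (d - 1986.0)) * rng.choice([1, 2, 5]))
                   for s, d in dates.items()}
        counts = [flag_hypermutators(burdens, dates, threshold=th).flagged.sum()
                  for th in (1.5, 2.0, 3.0, 5.0, 8.0)]
        assert all(b >= a for a, b in zip(counts[1:], counts))
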