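"""Impact classification, expected-count enumeration, per-gene dN/dS tests."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from devilclones.selection import (
    IMPACT_CLASSES,
    classify_impact,
    expected_counts,
    gene_dnds_test,
)
from devilclones.signatures import SBS_CHANNELS, sbs_channel
from devilclones.simcohort.genome import SyntheticGenome


def _toy_genome(seed=3, n_genes=5):
    g = SyntheticGenome.generate(120_000, n_genes=n_genes, n_l1=2, seed=seed)
    return g


def _gene(genome, i=0):
    return genome.genes.iloc[i]


class TestClassifyImpact:
    def test_synonymous_leu_to_leu(self, small_genome):
        g = _gene(small_genome)
        # find a position whose mutation is synonymous, by construction
        cds = small_genome.cds_sequence(g)
        for cpos in range(2, len(cds), 3):  # third codon positions
            codon = cds[cpos - 2 : cpos + 1]
            for alt_cds in "ACGT":
                if alt_cds == cds[cpos]:
                    continue
                mutated = codon[:2] + alt_cds
                if str(Seq(codon).translate()) == str(Seq(mutated).translate()):
                    if g.strand == "+":
                        pos = g.start + cpos + 1
                        ref, alt = cds[cpos], alt_cds
                    else:
                        pos = g.end - cpos
                        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                        ref, alt = comp[cds[cpos]], comp[alt_cds]
                    impact = classify_impact(g.chrom, pos, ref, alt, g, small_genome)
                    assert impact == "synonymous"
                    return
        pytest.fail("no synonymous site found in first gene")

    def test_stop_gain_is_nonsense(self):
        # hand-built gene: TGG (Trp) -> TGA (stop) at codon 2
        seq = np.array([_b for _b in map("ACGT".index, "A" * 10 + "ATGTGGAAATAA" + "A" * 10)],
                       dtype=np.uint8)
        genome = SyntheticGenome(
            {"chr1": len(seq)}, {"chr1": seq},
            pd.DataFrame([("G1", "chr1", 10, 22, "+")],
                         columns=["gene_id", "chrom", "start", "end", "strand"]),
            pd.DataFrame(columns=["element_id", "chrom", "start", "end", "strand"]),
        )
        g = genome.genes.iloc[0]
        assert classify_impact("chr1", 16, "G", "A", g, genome) == "nonsense"

    def test_one_bp_deletion_is_frameshift(self, small_genome):
        g = _gene(small_genome)
        pos = g.start + 5
        ref = small_genome.base(g.chrom, pos) + small_genome.base(g.chrom, pos + 1)
        impact = classify_impact(g.chrom, pos, ref, ref[0], g, small_genome)
        assert impact == "frameshift"

    def test_bad_cds_length_errors(self, small_genome):
        g = _gene(small_genome).copy()
        g.end = g.end + 1
        with pytest.raises(ValueError, match="divisible"):
            classify_impact(g.chrom, g.start + 2, "A", "T", g, small_genome)


class TestExpectedCounts:
    def _uniform_variants(self, genome, n=4000, seed=5, only_synonymous=False):
        """Substitutions placed uniformly over coding base pairs."""
        rng = np.random.default_rng(seed)
        rows = []
        genes = list(genome.genes.itertuples(index=False))
        lens = np.array([g.end - g.start for g in genes], dtype=float)
        probs = lens / lens.sum()
        while len(rows) < n:
            g = genes[rng.choice(len(genes), p=probs)]
            pos = int(rng.integers(g.start + 1, g.end + 1))
            if pos < 2 or pos > genome.chrom_lengths[g.chrom] - 1:
                continue
            ref = genome.base(g.chrom, pos)
            alt = rng.choice([b for b in "ACGT" if b != ref])
            if only_synonymous:
                gs = pd.Series(g._asdict())
                if classify_impact(g.chrom, pos, ref, alt, gs, genome) != "synonymous":
                    continue
            rows.append((g.chrom, pos, ref, alt, "substitution"))
        return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "var_class"])

    def test_expected_equals_bruteforce_enumeration(self):
        """Expected counts equal an exhaustive CDS x 3-alt enumeration done
        independently on a 5-gene toy genome."""
        genome = _toy_genome()
        variants = self._uniform_variants(genome, n=3000)
        ic = expected_counts(variants, genome.genes, genome, min_synonymous=1)

        # independent oracle: loop every CDS site x alt, classify, sum rates
        chan_idx = {c: i for i, c in enumerate(SBS_CHANNELS)}
        opp = np.zeros(len(SBS_CHANNELS))
        per_gene = {}
        for g in genome.genes.itertuples(index=False):
            gs = pd.Series(g._asdict())
            site_list = []
            for p0 in range(g.start, g.end):
                pos = p0 + 1
                trip = genome.triplet(g.chrom, pos)
                for alt in "ACGT":
                    if alt == trip[1]:
                        continue
                    imp = classify_impact(g.chrom, pos, trip[1], alt, gs, genome)
                    ch = chan_idx[sbs_channel(trip[1], alt, trip)]
                    site_list.append((ch, imp))
                    if imp == "synonymous":
                        opp[ch] += 1
            per_gene[g.gene_id] = site_list
        obs_syn_ch = np.zeros(len(SBS_CHANNELS))
        for row in variants.itertuples(index=False):
            g = genome.genes[genome.genes.chrom == row.chrom]
            g = g[(g.start < row.pos) & (row.pos <= g.end)]
            if len(g) != 1:
                continue
            gs = g.iloc[0]
            if classify_impact(row.chrom, row.pos, row.ref, row.alt, gs, genome) == "synonymous":
                obs_syn_ch[chan_idx[sbs_channel(
                    row.ref, row.alt, genome.triplet(row.chrom, row.pos))]] += 1
        # same shrinkage estimator, on independently enumerated opportunities
        n_syn = obs_syn_ch.sum()
        u0 = n_syn / opp.sum()
        a = 2.0 * len(SBS_CHANNELS) / max(n_syn, 1.0)
        rate = np.where(opp > 0,
                        (obs_syn_ch + a * u0 * opp) / ((1 + a) * np.maximum(opp, 1)),
                        u0)
        for gid, sites in per_gene.items():
            for cls in ("synonymous", "missense", "nonsense"):
                manual = sum(rate[ch] for ch, imp in sites if imp == cls)
                assert ic.expected.loc[gid, cls] == pytest.approx(manual, abs=1e-9)

    def test_synonymous_conservation(self):
        genome = _toy_genome(seed=9)
        variants = self._uniform_variants(genome, n=2000, seed=11)
        ic = expected_counts(variants, genome.genes, genome, min_synonymous=1)
        assert ic.expected["synonymous"].sum() == pytest.approx(
            ic.observed["synonymous"].sum()
        )

    def test_zero_synonymous_errors(self):
        genome = _toy_genome()
        v = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "var_class"])
        with pytest.raises(ValueError, match="synonymous"):
            expected_counts(v, genome.genes, genome)


class TestGeneDnDsTest:
    def test_obs_equals_exp_gives_lrt_zero_p_one(self):
        genome = _toy_genome()
        variants = TestExpectedCounts()._uniform_variants(genome, n=3000)
        ic = expected_counts(variants, genome.genes, genome, min_synonymous=1)
        ic.observed["missense"] = ic.expected["missense"].round().astype(int)
        ic.observed["nonsense"] = 0
        ic.expected["nonsense"] = 0.0
        ic.observed["frameshift"] = 0
        ic.expected["frameshift"] = 0.0
        res = gene_dnds_test(ic)
        mis = res.per_gene[res.per_gene["class"] == "missense"]
        # rounding causes at-most-one-mutation discrepancies; p stays high
        assert (mis.p > 0.2).all()

    def test_neutral_simulation_calibrated(self):
        """Uniform mutagenesis: the global omega CI covers 1 and the
        per-gene global (all protein-altering) test stays below q < 0.05 in
        >= 95/100 replicates."""
        genome = _toy_genome(seed=13, n_genes=30)
        helper = TestExpectedCounts()
        clean = 0
        covers = 0
        for rep in range(100):
            variants = helper._uniform_variants(genome, n=3000, seed=200 + rep)
            ic = expected_counts(variants, genome.genes, genome, min_synonymous=1)
            res = gene_dnds_test(ic)
            pg = res.per_gene
            clean += not ((pg["class"] == "global") & (pg.q < 0.05)).any()
            lo, hi = res.global_omega.loc["global", ["lo", "hi"]]
            covers += lo <= 1.0 <= hi
        assert clean >= 95
        assert covers >= 90

    def test_planted_truncations_reach_q_below_half_percent(self):
        """Six truncating mutations against expectation < 0.5 give the
        repeated-truncation signal at q < 0.005."""
        genome = _toy_genome(seed=17)
        helper = TestExpectedCounts()
        # sparse synonymous-only background keeps the truncating
        # expectation below 0.5
        variants = helper._uniform_variants(genome, n=10, seed=33,
                                            only_synonymous=True)
        target = genome.genes.iloc[2]
        gs = target
        planted = []
        for p0 in range(gs.start, gs.end):
            pos = p0 + 1
            trip = genome.triplet(gs.chrom, pos)
            for alt in "ACGT":
                if alt == trip[1]:
                    continue
                if classify_impact(gs.chrom, pos, trip[1], alt, gs, genome) == "nonsense":
                    planted.append((gs.chrom, pos, trip[1], alt, "substitution"))
                if len(planted) == 6:
                    break
            if len(planted) == 6:
                break
        variants = pd.concat(
            [variants, pd.DataFrame(planted, columns=variants.columns)],
            ignore_index=True,
        )
        ic = expected_counts(variants, genome.genes, genome, min_synonymous=1)
        res = gene_dnds_test(ic)
        row = res.per_gene[(res.per_gene.gene == gs.gene_id)
                           & (res.per_gene["class"] == "truncating")].iloc[0]
        assert row.q < 0.005

    def test_q_monotone_in_p(self):
        genome = _toy_genome(seed=19)
        helper = TestExpectedCounts()
        variants = helper._uniform_variants(genome, n=2500, seed=55)
        ic = expected_counts(variants, genome.genes, genome, min_synonymous=1)
        res = gene_dnds_test(ic)
        for cls in ("missense", "truncating", "global"):
            sub = res.per_gene[res.per_gene["class"] == cls].sort_values("p")
            assert (np.diff(sub.q) >= -1e-12).all()
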