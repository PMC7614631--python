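"""End-to-end cohort assembly: genome, tree, mutations, germline and bulk
read counts, with coverage-bin emulation for copy-number analyses."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from devilclones.simcohort.bulk import make_bulk_sample
from devilclones.simcohort.config import CohortConfig
from devilclones.simcohort.genome import SyntheticGenome
from devilclones.simcohort.germline import GermlinePopulation
from devilclones.simcohort.mutations import TruthTable, simulate_mutations
from devilclones.simcohort.tree import simulate_transmission_tree
from devilclones.trees import CloneTree

__all__ = ["Cohort", "simulate_cohort"]


def _descendant_tips(tree: CloneTree, node: int) -> set[int]:
    out, stack = set(), [node]
    while stack:
        n = stack.pop()
        if tree.is_tip(n):
            out.add(n)
        stack.extend(tree.children[n])
    return out


@dataclass
class Cohort:
    """A simulated cohort with full ground truth."""

    config: CohortConfig
    genome: SyntheticGenome
    tree: CloneTree
    variants: pd.DataFrame
    truth: TruthTable
    germline: GermlinePopulation
    metadata: pd.DataFrame  # sample_id, clone, sampling_date, host_id, purity, ploidy
    allele_counts: dict[str, pd.DataFrame] = field(default_factory=dict)

    # ------------------------------------------------------------ accessors
    @property
    def samples(self) -> list[str]:
        return list(self.metadata["sample_id"])

    def tip_of(self, sample: str) -> int:
        for node, label in self.tree.labels.items():
            if label == sample:
                return node
        raise KeyError(sample)

    def path_vids(self, sample: str) -> list[int]:
        tip = self.tip_of(sample)
        vids: list[int] = []
        for node in self.tree.path_to_root(tip):
            vids.extend(self.tree.branch_variants.get(node, []))
        return vids

    def sample_cn_profile(self, sample: str) -> pd.DataFrame:
        """True integer copy-number segments for one tumour (truth channel).

        Base state is the tumour ploidy on autosomes; chromosome X carries
        ploidy copies for a female founder and ploidy/2 for a male founder,
        which also contributes ploidy/2 Y copies unless lost (LoY).  CNV
        event deltas on the root-to-tip path are applied on top.
        """
        tip = self.tip_of(sample)
        ploidy = int(self.truth.ploidy[sample])
        path = set(self.tree.path_to_root(tip))
        male = self.config.founder_sex == "male"
        loy = any(b in path for b in self.truth.loy_branches)
        base: dict[str, float] = {}
        for chrom in self.genome.chromosomes:
            if chrom == "chrY":
                base[chrom] = 0 if (not male or loy) else ploidy / 2
            elif chrom == "chrX":
                base[chrom] = ploidy / 2 if male else ploidy
            else:
                base[chrom] = ploidy
        events = [e for e in self.truth.cnv_events if e["branch"] in path]
        rows = []
        for chrom in self.genome.chromosomes:
            clen = self.genome.chrom_lengths[chrom]
            bounds = {0, clen}
            for e in events:
                if e["chrom"] == chrom:
                    bounds |= {e["start"], e["end"]}
            edges = sorted(bounds)
            for s, e_ in zip(edges[:-1], edges[1:]):
                cn = base[chrom] + sum(
                    ev["delta"]
                    for ev in events
                    if ev["chrom"] == chrom and ev["start"] <= s and ev["end"] >= e_
                )
                rows.append((chrom, s, e_, max(0.0, cn)))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "cn"])

    def coverage_bins(
        self,
        sample: str,
        bin_size: int = 1000,
        noise_sd: float = 0.05,
        rng: np.random.Generator | int | None = None,
    ) -> pd.DataFrame:
        """Normalised binned read coverage for one tumour.

        Depth 1.0 corresponds to the sample's average (ploidy-level) state;
        tumour copy-number changes shift it according to purity.
        """
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        purity = float(self.truth.purity[sample])
        ploidy = int(self.truth.ploidy[sample])
        profile = self.sample_cn_profile(sample)
        denom = purity * ploidy + 2 * (1 - purity)
        rows = []
        for chrom in self.genome.chromosomes:
            clen = self.genome.chrom_lengths[chrom]
            starts = np.arange(0, clen - bin_size + 1, bin_size)
            cn = np.full(len(starts), float(ploidy))
            sub = profile[profile.chrom == chrom]
            for seg in sub.itertuples(index=False):
                mask = (starts >= seg.start) & (starts + bin_size <= seg.end)
                cn[mask] = seg.cn
            # host cells contribute two copies of autosomes/X, none of Y
            host_copies = 0.0 if chrom == "chrY" else 2.0
            expected = (purity * cn + host_copies * (1 - purity)) / denom
            depth = np.maximum(0.0, rng.normal(expected, noise_sd))
            for s, d in zip(starts, depth):
                rows.append((chrom, int(s), float(d)))
        return pd.DataFrame(rows, columns=["chrom", "start", "depth"])


def _site_key(df: pd.DataFrame) -> pd.Series:
    return (
        df["chrom"].astype(str) + ":" + df["pos"].astype(str) + ":"
        + df["ref"].astype(str) + ":" + df["alt"].astype(str)
    )


def _matrices_from_counts(
    counts: dict[str, pd.DataFrame]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    alt_cols, dp_cols = {}, {}
    for sample, df in counts.items():
        keyed = df.assign(_key=_site_key(df)).set_index("_key")
        keyed = keyed[~keyed.index.duplicated()]
        alt_cols[sample] = keyed["alt_reads"]
        dp_cols[sample] = keyed["depth"]
    alt = pd.DataFrame(alt_cols).fillna(0).astype(int)
    dp = pd.DataFrame(dp_cols).reindex(alt.index).fillna(0).astype(int)
    return alt, dp


# Cohort accessors for the somatic-filter stage ---------------------------


def tumour_allele_matrices(cohort: "Cohort") -> tuple[pd.DataFrame, pd.DataFrame]:
    """(alt, depth) frames, variants x tumour samples, keyed chrom:pos:ref:alt.

    Sites a tumour does not carry get depth drawn at the cohort mean with
    zero alt reads (the sequenced tumour covers them; they are just not
    mutated there).
    """
    alt, dp = _matrices_from_counts(cohort.allele_counts)
    rng = np.random.default_rng(cohort.config.seed + 97)
    missing = dp.to_numpy() == 0
    dp_fill = rng.poisson(cohort.config.depth_mean, size=missing.sum())
    arr = dp.to_numpy()
    arr[missing] = dp_fill
    return alt, pd.DataFrame(arr, index=dp.index, columns=dp.columns)


def normal_allele_matrices(
    cohort: "Cohort", site_index: pd.Index
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(alt, depth) frames for the panel normals over the given sites.

    Normals carry their simulated genotypes at germline sites and reference
    alleles everywhere else.
    """
    rng = np.random.default_rng(cohort.config.seed + 131)
    germ = cohort.germline
    gkey = (
        germ.sites["chrom"].astype(str) + ":" + germ.sites["pos"].astype(str)
        + ":" + germ.sites["ref"] + ":" + germ.sites["alt"]
    )
    site_to_col = {k: i for i, k in enumerate(gkey)}
    rows_vaf = np.zeros((len(site_index), len(germ.sample_ids)))
    for r, key in enumerate(site_index):
        c = site_to_col.get(key)
        if c is not None:
            geno = germ.genotypes[:, c]
            rows_vaf[r] = np.where(geno == 2, 1.0, np.where(geno == 1, 0.5, 0.0))
    dp = rng.poisson(cohort.config.depth_mean, size=rows_vaf.shape)
    alt = rng.binomial(dp, rows_vaf)
    return (
        pd.DataFrame(alt, index=site_index, columns=germ.sample_ids),
        pd.DataFrame(dp, index=site_index, columns=germ.sample_ids),
    )


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Simulate a full cohort: reference genome, transmission tree, somatic
    variants of all classes, germline population, purities and per-sample
    bulk allele counts.  Deterministic given ``config.seed``."""
    ss = np.random.SeedSequence(config.seed)
    rng_genome, rng_tree, rng_mut, rng_germ, rng_bulk = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    scale = config.genome_scale
    n_l1 = config.n_l1_elements or max(6, int(round(1948 * scale)))
    genome = SyntheticGenome.generate(
        config.scaled_genome_bp, n_genes=config.n_genes, n_l1=n_l1, seed=rng_genome
    )
    tree = simulate_transmission_tree(config, rng_tree)
    variants, truth = simulate_mutations(tree, config, genome, rng_mut)
    germ = GermlinePopulation.generate(
        genome, config.heterozygosity_per_kb, config.n_normals, rng_germ
    )

    tips = tree.tips()
    labels = [tree.labels[t] for t in tips]
    p_lo, p_hi = config.purity_range
    purities = rng_bulk.uniform(p_lo, p_hi, size=len(tips))
    wgd_tipsets = {
        e["branch"]: _descendant_tips(tree, e["branch"]) for e in truth.wgd_events
    }
    meta_rows = []
    founder_het = germ.founder_het_sites()
    allele_counts: dict[str, pd.DataFrame] = {}
    sub = config.subclone_spec
    for i, (tip, label) in enumerate(zip(tips, labels)):
        purity = float(purities[i])
        wgd_here = [e for e in truth.wgd_events if tip in wgd_tipsets[e["branch"]]]
        ploidy = 4 if wgd_here else 2
        truth.purity[label] = purity
        truth.ploidy[label] = ploidy

        vids = set()
        for node in tree.path_to_root(tip):
            vids.update(tree.branch_variants.get(node, []))
        df = variants[variants.vid.isin(vids)].copy() if len(variants) else variants.copy()
        df["is_germline"] = False
        df["component"] = 0
        df["tumour_cn"] = float(ploidy)
        df["multiplicity"] = 1.0
        if wgd_here:
            year = min(e["year"] for e in wgd_here)
            df.loc[df.time < year, "multiplicity"] = 2.0
        mix = None
        if sub is not None and sub.tumour == label:
            partner_label = sub.partner or _sister_label(tree, tip)
            partner_tip = next(n for n, l in tree.labels.items() if l == partner_label)
            own = set(df.vid)
            partner = set()
            for node in tree.path_to_root(partner_tip):
                partner.update(tree.branch_variants.get(node, []))
            shared = own & partner
            extra = variants[variants.vid.isin(partner - own)].copy()
            extra["is_germline"] = False
            extra["tumour_cn"] = float(ploidy)
            extra["multiplicity"] = 1.0
            extra["component"] = 2
            df["component"] = np.where(df.vid.isin(shared), 0, 1)
            df = pd.concat([df, extra], ignore_index=True)
            mix = tuple(sub.fractions)
            truth.subclone_fractions[label] = list(sub.fractions)
        if len(founder_het):
            germ_df = founder_het.assign(
                vid=-1, var_class="germline", context="", branch=-1, time=np.nan,
                l1_source="", is_germline=True, component=0,
                tumour_cn=2.0, multiplicity=1.0,
            )[df.columns.intersection(
                ["chrom", "pos", "ref", "alt", "vid", "var_class", "context",
                 "branch", "time", "l1_source", "is_germline", "component",
                 "tumour_cn", "multiplicity"]
            )]
            df = pd.concat([df, germ_df], ignore_index=True)
        counts = make_bulk_sample(
            df, purity, config.depth_mean, subclone_mix=mix, rng=rng_bulk
        )
        allele_counts[label] = counts
        meta_rows.append(
            (label, config.clone_label, float(tree.dates[tip]), f"H{i:03d}",
             purity, ploidy)
        )

    metadata = pd.DataFrame(
        meta_rows,
        columns=["sample_id", "clone", "sampling_date", "host_id", "purity", "ploidy"],
    )
    return Cohort(config, genome, tree, variants, truth, germ, metadata, allele_counts)


def _sister_label(tree: CloneTree, tip: int) -> str:
    """Label of the nearest tip that is not ``tip`` itself."""
    parent = tree.parent[tip]
    candidates = _descendant_tips(tree, parent) - {tip}
    while not candidates:
        parent = tree.parent[parent]
        candidates = _descendant_tips(tree, parent) - {tip}
    best = min(candidates, key=lambda n: tree.depth(n))
    return tree.labels[best]
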