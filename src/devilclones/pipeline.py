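"""End-to-end pipeline: simulate -> filter -> tree -> clock -> subclones ->
signatures/rates -> CNV/WGD/LoY -> dN/dS -> LINE-1 -> report.

One :class:`RunConfig` drives one or two simulated clones (two enable the
between-clone rate-ratio table).  Every stage can be toggled; the report is
a JSON-serialisable dict whose sections mirror the stages.  Identical
configuration and seeds give identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from devilclones import signatures as sigs
from devilclones import somatic_filter as sf
from devilclones.cnv_wgd import (
    arm_event_enrichment,
    call_wgd,
    date_wgd,
    detect_loy,
    modal_cn,
    recurrence_map,
    segment_coverage,
)
from devilclones.phylo_clock import (
    MutationMatrix,
    build_tree,
    detect_polytomies,
    fit_strict_clock,
    origin_interval_with_ambiguity,
)
from devilclones.rates import (
    burden_regression,
    detect_rate_shift,
    flag_hypermutators,
    rate_ratio,
)
from devilclones.retro_l1 import attribute_sources, source_tally, insertion_rate
from devilclones.selection import expected_counts, gene_dnds_test
from devilclones.simcohort import CohortConfig, dft1_config, dft2_config, simulate_cohort
from devilclones.simcohort.cohort import (
    Cohort,
    normal_allele_matrices,
    tumour_allele_matrices,
)
from devilclones.subclone_deconv import detect_subclones

log = logging.getLogger("devilclones.pipeline")

__all__ = ["RunConfig", "run_pipeline", "DEFAULT_STAGES"]

DEFAULT_STAGES = [
    "filter", "tree_clock", "subclones", "rates_signatures",
    "cnv_wgd", "dnds", "l1",
]


@dataclass
class RunConfig:
    clones: list[CohortConfig] = field(default_factory=lambda: [dft1_config(), dft2_config()])
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in DEFAULT_STAGES})
    seed: int = 0
    clock_iterations: int = 50_000
    clock_burnin: int = 10_000
    clonal_threshold: float = 0.2
    hypermutator_threshold: float = 3.0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        presets = {"DFT1": dft1_config, "DFT2": dft2_config}
        clones = []
        for c in d.get("clones", [{"preset": "DFT1"}, {"preset": "DFT2"}]):
            c = dict(c)
            preset = c.pop("preset", None)
            if preset:
                clones.append(presets[preset.upper()](**c))
            else:
                clones.append(CohortConfig(**c))
        kwargs = {k: v for k, v in d.items() if k != "clones"}
        return cls(clones=clones, **kwargs)


def _analyse_clone(cohort: Cohort, rc: RunConfig, report: dict) -> dict:
    label = cohort.config.clone_label
    out: dict = {"clone": label, "n_tumours": len(cohort.samples)}
    stages = rc.stages
    dates = dict(zip(cohort.metadata.sample_id, cohort.metadata.sampling_date))

    somatic_keys = None
    if stages.get("filter", True):
        log.info("[%s] somatic filter", label)
        t_alt, t_dp = tumour_allele_matrices(cohort)
        n_alt, n_dp = normal_allele_matrices(cohort, t_alt.index)
        panel = sf.NormalPanel(cohort.germline.sample_ids)
        cls = sf.classify_germline(t_alt, t_dp, n_alt, n_dp, panel)
        het = sf.heterozygosity_per_kb(
            {s: cohort.germline.het_count(i) for i, s in enumerate(cohort.germline.sample_ids)},
            cohort.genome.total_bp,
        )
        purities = {}
        for s in cohort.samples:
            ac = cohort.allele_counts[s]
            som = ac[(~ac.is_germline) & (ac.var_class == "substitution")
                     & (ac.tumour_cn == 2) & (ac.multiplicity == 1) & (ac.component == 0)]
            est = sf.estimate_purity(som.alt_reads / som.depth.clip(lower=1))
            purities[s] = est.purity
        somatic_keys = cls.somatic
        out["filter"] = {
            **cls.summary,
            "heterozygosity_median_per_kb": round(het.median, 4),
            "heterozygosity_range_per_kb": [round(v, 4) for v in het.range],
            "purity_estimates": {s: (round(p, 3) if p else None) for s, p in purities.items()},
        }

    tree = None
    fit = None
    if stages.get("tree_clock", True):
        log.info("[%s] tree + strict clock", label)
        mat, shared = MutationMatrix.from_branch_counts(cohort.tree)
        tree = build_tree(
            mat, {cohort.tree.labels[n]: cohort.tree.dates[n] for n in cohort.tree.tips()}
        )
        fit = fit_strict_clock(
            tree, seed=rc.seed + 11,
            iterations=rc.clock_iterations, burnin=rc.clock_burnin,
        )
        origin = origin_interval_with_ambiguity(fit, shared, seed=rc.seed + 13)
        polys = detect_polytomies(tree, fit)
        out["clock"] = {
            "rate_per_year": round(fit.rate_median, 1),
            "rate_interval": [round(v, 1) for v in fit.rate_interval],
            "mrca_date": round(fit.root_median, 2),
            "origin_date": round(origin.median, 2),
            "origin_interval": [round(v, 2) for v in origin.interval],
            "shared_ambiguous_variants": shared,
            "n_polytomies": len(polys),
            "convergence": round(fit.convergence, 4),
        }

    if stages.get("subclones", True):
        log.info("[%s] subclone screen", label)
        sub_out = {}
        for s in cohort.samples:
            if cohort.truth.ploidy[s] != 2:
                continue
            ac = cohort.allele_counts[s]
            som = ac[(~ac.is_germline) & (ac.var_class == "substitution")]
            model = detect_subclones(
                som.alt_reads.to_numpy(), som.depth.to_numpy(),
                purity=cohort.truth.purity[s], seed=rc.seed + 17,
            )
            if model.k >= 2 and not model.underpowered:
                sub_out[s] = {
                    "k": model.k,
                    "fractions": [round(float(f), 3) for f in model.fractions],
                }
        out["subclones"] = sub_out

    fits = {}
    if stages.get("rates_signatures", True):
        log.info("[%s] rates and signatures", label)
        hyper = flag_hypermutators(
            {s: cohort.truth.tip_burdens[s]["substitution"] for s in cohort.samples},
            dates, threshold=rc.hypermutator_threshold,
        )
        flagged = set(hyper.loc[hyper.flagged, "sample"])
        keep = [s for s in cohort.samples if s not in flagged]
        rate_table = {}
        for cls_name in ("substitution", "indel", "rearrangement_event", "cnv_event"):
            f = burden_regression(
                [cohort.truth.tip_burdens[s][cls_name] for s in keep],
                [dates[s] for s in keep],
            )
            fits[cls_name] = f
            rate_table[cls_name] = {
                "rate": round(f.slope, 1),
                "interval": [round(v, 1) for v in f.slope_interval],
                "significant": f.significant,
            }
        shift = detect_rate_shift(cohort.tree, {
            s: cohort.truth.tip_burdens[s]["substitution"] for s in keep
        }, dates)
        spect_sbs, spect_id = sigs.build_spectrum(
            cohort.variants[cohort.variants.var_class.isin(["substitution", "indel"])],
        )
        exp_sbs = sigs.fit_signatures(spect_sbs, sigs.ReferenceSignatures.load_sbs())
        exp_id = sigs.fit_signatures(spect_id, sigs.ReferenceSignatures.load_indel())
        out["rates"] = rate_table
        out["hypermutators"] = sorted(flagged)
        out["rate_shift_hits"] = int(shift["significant"].sum()) if len(shift) else 0
        out["signature_exposures"] = {
            "sbs": {k: round(v, 1) for k, v in exp_sbs.exposures.items()},
            "indel": {k: round(v, 1) for k, v in exp_id.exposures.items()},
        }

    if stages.get("cnv_wgd", True):
        log.info("[%s] CNV / WGD / LoY", label)
        rate = fits.get("substitution")
        seg_by_sample = {}
        ploidy_flags, arm_flags, wgd_dates, loy_samples = {}, {}, {}, []
        rng = np.random.default_rng(rc.seed + 23)
        for s in cohort.samples:
            bins = cohort.coverage_bins(s, rng=rng)
            purity = cohort.truth.purity[s]
            ploidy = cohort.truth.ploidy[s]
            segs = segment_coverage(bins, purity=purity, ploidy=ploidy)
            seg_by_sample[s] = segs
            m = modal_cn(segs)
            ac = cohort.allele_counts[s]
            som = ac[(~ac.is_germline) & (ac.var_class == "substitution")]
            vafs = (som.alt_reads / som.depth.clip(lower=1)).to_numpy()
            call = call_wgd(segs, vafs, purity, sample=s)
            ploidy_flags[s] = call.tetraploid
            arm_flags[s] = any(
                (sg.end - sg.start) >= cohort.genome.chrom_lengths[sg.chrom] / 2
                and sg.cn != m and sg.chrom != "chrY"
                for sg in segs
            )
            if call.tetraploid and rate is not None:
                d, ival = date_wgd(
                    call.pre_count, call.post_count, rate.slope, dates[s],
                    rate_interval=rate.slope_interval,
                )
                wgd_dates[s] = round(d, 2)
            if cohort.config.founder_sex == "male":
                ybins = bins[bins.chrom == "chrY"]
                abins = bins[~bins.chrom.isin(["chrX", "chrY"])]
                if detect_loy(ybins, abins, purity, "male", ploidy=ploidy):
                    loy_samples.append(s)
        events, linked = recurrence_map(seg_by_sample, cohort.tree)
        out["cnv_wgd"] = {
            "n_tetraploid": int(sum(ploidy_flags.values())),
            "wgd_dates": wgd_dates,
            "loy_samples": loy_samples,
            "n_unique_cnv_occurrences": int(events["cnv_id"].nunique()) if len(events) else 0,
            "n_linked_cnv_pairs": int(len(linked)),
        }
        if any(ploidy_flags.values()) and not all(ploidy_flags.values()):
            p, _ = arm_event_enrichment(
                np.array([ploidy_flags[s] for s in cohort.samples]),
                np.array([arm_flags[s] for s in cohort.samples]),
            )
            out["cnv_wgd"]["arm_event_fisher_p"] = round(p, 5)

    if stages.get("dnds", True):
        log.info("[%s] dN/dS", label)
        coding = cohort.variants[cohort.variants.var_class.isin(["substitution", "indel"])]
        try:
            ic = expected_counts(coding, cohort.genome.genes, cohort.genome)
            res = gene_dnds_test(ic)
            hits = res.per_gene[(res.per_gene["class"] == "global") & (res.per_gene.q < 0.05)]
            out["dnds"] = {
                "global_omega": {
                    c: [round(v, 3) for v in res.global_omega.loc[c, ["omega", "lo", "hi"]]]
                    for c in res.global_omega.index
                },
                "genes_under_selection": sorted(hits.gene),
            }
        except ValueError as e:
            out["dnds"] = {"skipped": str(e)}

    if stages.get("l1", True):
        log.info("[%s] LINE-1", label)
        ins = cohort.variants[cohort.variants.var_class == "line1_insertion"].copy()
        ins = ins.rename(columns={"vid": "insertion_id"})
        attributed = attribute_sources(ins, cohort.genome.l1_elements)
        tally = source_tally(attributed[attributed.source != ""])
        f = insertion_rate(
            [cohort.truth.tip_burdens[s]["line1_insertion"] for s in cohort.samples],
            [dates[s] for s in cohort.samples],
        )
        fits["line1_insertion"] = f
        out["l1"] = {
            "rate": round(f.slope, 1),
            "interval": [round(v, 1) for v in f.slope_interval],
            "significant": f.significant,
            "n_sources_with_transductions": int((tally.drop("orphan", errors="ignore") > 0).sum()),
            "top_source": (tally.drop("orphan", errors="ignore").idxmax()
                           if len(tally.drop("orphan", errors="ignore")) else None),
        }
    out["_fits"] = fits
    return out


def run_pipeline(config: RunConfig, outdir: str | None = None) -> dict:
    """Run all enabled stages over the configured clones; return the report."""
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")
    report: dict = {"schema_version": 1, "seed": config.seed, "clones": {}}
    clone_results = {}
    for cfg in config.clones:
        cohort = simulate_cohort(cfg)
        log.info("simulated %s: %d tumours, %d variants",
                 cfg.clone_label, len(cohort.samples), len(cohort.variants))
        res = _analyse_clone(cohort, config, report)
        clone_results[cfg.clone_label] = res
        report["clones"][cfg.clone_label] = {k: v for k, v in res.items() if k != "_fits"}

    if len(config.clones) == 2 and config.stages.get("rates_signatures", True):
        a, b = (clone_results[c.clone_label] for c in config.clones)
        ratios = {}
        for cls_name in set(a["_fits"]) & set(b["_fits"]):
            rr = rate_ratio(a["_fits"][cls_name], b["_fits"][cls_name], seed=config.seed)
            ratios[cls_name] = (
                {"ratio": round(rr.ratio, 3),
                 "interval_delta": [round(v, 3) for v in rr.interval_delta],
                 "interval_bootstrap": [round(v, 3) for v in rr.interval_bootstrap]}
                if rr.ratio is not None else {"suppressed": rr.suppressed_reason}
            )
        report["rate_ratios"] = ratios

    if outdir:
        import os

        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, default=str)
    return report
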