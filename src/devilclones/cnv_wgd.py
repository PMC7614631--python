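"""Copy-number segmentation, WGD detection and dating, LoY, recurrence maps.

Coverage is consumed as normalised depth in fixed-size bins (BED-style
0-based half-open coordinates).  Segmentation is least-squares binary
segmentation: recursively split at the point maximising the between-segment
SSE reduction, with a minimum segment of 10 bins, stopping when the
improvement falls below 3 x sigma^2 x log n (noise variance estimated from
successive bin differences).  Integer copy number is the purity-corrected
depth ratio rounded at the sample's ploidy baseline.

Tetraploidy is called when the base-pair-weighted modal copy number is 4
and the clonal VAF distribution in CN=4 regions is bimodal at the two
multiplicity modes m x purity / (4 x purity + 2 x (1 - purity)), m = 1, 2.
WGD events are dated by counting substitutions before (multiplicity 2) and
after (multiplicity 1) duplication: elapsed = post_count / (kappa x rate),
with kappa = 2 by default since post-WGD accrual scales with DNA content
(kappa = 1 also supported; outputs are labelled).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from devilclones.trees import CloneTree
from devilclones.phylo_clock import map_event_to_tree

__all__ = [
    "CNSegment",
    "segment_coverage",
    "gene_deletion_screen",
    "PloidyCall",
    "call_wgd",
    "date_wgd",
    "detect_loy",
    "recurrence_map",
    "arm_event_enrichment",
]


@dataclass
class CNSegment:
    chrom: str
    start: int  # 0-based half-open
    end: int
    cn: int
    n_bins: int
    mean_depth: float


def _best_split(y: np.ndarray, min_bins: int) -> tuple[int, float]:
    """Index and SSE reduction of the best binary split of y."""
    n = len(y)
    if n < 2 * min_bins:
        return -1, 0.0
    csum = np.cumsum(y)
    csq = np.cumsum(y * y)
    total_sse = csq[-1] - csum[-1] ** 2 / n
    ks = np.arange(min_bins, n - min_bins + 1)
    left_n = ks
    right_n = n - ks
    left_sum = csum[ks - 1]
    right_sum = csum[-1] - left_sum
    sse = (
        (csq[ks - 1] - left_sum**2 / left_n)
        + ((csq[-1] - csq[ks - 1]) - right_sum**2 / right_n)
    )
    i = int(np.argmin(sse))
    return int(ks[i]), float(total_sse - sse[i])


def segment_coverage(
    bins: pd.DataFrame,
    purity: float = 1.0,
    ploidy: int = 2,
    bin_size: int = 1000,
    min_bins: int = 10,
    penalty_factor: float = 3.0,
) -> list[CNSegment]:
    """Segment normalised binned coverage into integer copy-number segments.

    ``bins`` columns: chrom, start, depth (normalised so 1.0 = the sample's
    average, i.e. the ploidy state at its purity).
    """
    if not len(bins) or not np.any(bins["depth"].to_numpy() > 0):
        raise ValueError("all-zero coverage: cannot segment")
    segments: list[CNSegment] = []
    denom = purity * ploidy + 2.0 * (1.0 - purity)
    for chrom, sub in bins.groupby("chrom", sort=False):
        y = sub["depth"].to_numpy(float)
        starts = sub["start"].to_numpy(int)
        sigma2 = np.median(np.abs(np.diff(y))) ** 2 / (0.6745**2 * 2) if len(y) > 1 else 0.0
        penalty = penalty_factor * max(sigma2, 1e-8) * np.log(max(len(y), 2))
        pieces: list[tuple[int, int]] = []
        stack = [(0, len(y))]
        while stack:
            a, b = stack.pop()
            k, gain = _best_split(y[a:b], min_bins)
            if k > 0 and gain > penalty:
                stack.append((a, a + k))
                stack.append((a + k, b))
            else:
                pieces.append((a, b))
        for a, b in sorted(pieces):
            mean_depth = float(y[a:b].mean())
            # host cells contribute 2 copies (none for chrY)
            host = 0.0 if chrom == "chrY" else 2.0
            cn = (mean_depth * denom - host * (1.0 - purity)) / purity
            segments.append(
                CNSegment(
                    chrom=str(chrom),
                    start=int(starts[a]),
                    end=int(starts[b - 1]) + bin_size,
                    cn=max(0, int(round(cn))),
                    n_bins=b - a,
                    mean_depth=mean_depth,
                )
            )
    return segments


def modal_cn(segments: list[CNSegment]) -> int:
    """Base-pair-weighted modal copy number (autosomes only)."""
    weights: dict[int, int] = {}
    for s in segments:
        if s.chrom in ("chrX", "chrY"):
            continue
        weights[s.cn] = weights.get(s.cn, 0) + (s.end - s.start)
    return max(weights, key=weights.get)


def gene_deletion_screen(
    segments: list[CNSegment],
    annotation: pd.DataFrame,
    gene_list: list[str] | None = None,
    sample_modal_cn: int | None = None,
    focal_max_bp: int = 10_000_000,
) -> pd.DataFrame:
    """Genes whose CDS overlaps a segment below the sample's modal CN.

    Homozygous deletions (CN 0) are flagged distinctly; events shorter than
    ``focal_max_bp`` are labelled focal, larger ones arm-scale.
    """
    modal = sample_modal_cn if sample_modal_cn is not None else modal_cn(segments)
    genes = annotation if gene_list is None else annotation[
        annotation["gene_id"].isin(gene_list)
    ]
    rows = []
    for g in genes.itertuples(index=False):
        for s in segments:
            if s.chrom == g.chrom and s.start < g.end and s.end > g.start and s.cn < modal:
                rows.append(
                    (g.gene_id, s.chrom, s.start, s.end, s.cn,
                     s.cn == 0, (s.end - s.start) < focal_max_bp)
                )
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "cn",
                       "homozygous", "focal"],
    )


@dataclass
class PloidyCall:
    sample: str
    modal_cn: int
    tetraploid: bool
    vaf_modes: tuple[float, float] | None = None  # (multiplicity 2, 1)
    wgd_date: float | None = None
    wgd_interval: tuple[float, float] | None = None
    pre_count: int | None = None
    post_count: int | None = None


def call_wgd(
    segments: list[CNSegment],
    vafs: np.ndarray,
    purity: float,
    sample: str = "",
    min_variants: int = 200,
    min_mode_fraction: float = 0.15,
    mode_tolerance: float = 0.06,
) -> PloidyCall:
    """Tetraploidy call: modal CN 4 plus a bimodal clonal VAF distribution
    in CN=4 regions at the two multiplicity modes."""
    m = modal_cn(segments)
    call = PloidyCall(sample=sample, modal_cn=m, tetraploid=False)
    if m != 4 or len(vafs) < min_variants:
        return call
    denom = 4.0 * purity + 2.0 * (1.0 - purity)
    mode2 = 2.0 * purity / denom
    mode1 = 1.0 * purity / denom
    v = np.asarray(vafs, dtype=float)
    assign2 = np.abs(v - mode2) < np.abs(v - mode1)
    f2 = assign2.mean()
    centred2 = np.abs(v[assign2].mean() - mode2) < mode_tolerance if assign2.any() else False
    centred1 = np.abs(v[~assign2].mean() - mode1) < mode_tolerance if (~assign2).any() else False
    if min_mode_fraction <= f2 <= 1 - min_mode_fraction and centred1 and centred2:
        call.tetraploid = True
        call.vaf_modes = (float(mode2), float(mode1))
        call.pre_count = int(assign2.sum())
        call.post_count = int((~assign2).sum())
    return call


def date_wgd(
    pre_count: int,
    post_count: int,
    rate: float,
    sampling_date: float,
    rate_interval: tuple[float, float] | None = None,
    kappa: float = 2.0,
    genome_fraction: float = 1.0,
) -> tuple[float, tuple[float, float]]:
    """Date a whole-genome duplication from post-duplication mutations.

    ``post_count`` mutations (multiplicity 1, scaled to genome-wide
    equivalents via ``genome_fraction``) accumulated at kappa x rate after
    doubling: elapsed = post / (kappa x rate).  The interval combines the
    exact Poisson interval on the count with the rate's interval.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    post_gw = post_count / genome_fraction
    elapsed = post_gw / (kappa * rate)
    lo_c = stats.chi2.ppf(0.025, 2 * post_gw) / 2 if post_gw > 0 else 0.0
    hi_c = stats.chi2.ppf(0.975, 2 * (post_gw + 1)) / 2
    r_lo, r_hi = rate_interval if rate_interval else (rate, rate)
    lo_e = lo_c / (kappa * r_hi)
    hi_e = hi_c / (kappa * r_lo)
    if pre_count + post_count > 0 and post_gw > (pre_count + post_count) * 2:
        import warnings

        warnings.warn("post-WGD count exceeds total lineage expectation")
    return sampling_date - elapsed, (sampling_date - hi_e, sampling_date - lo_e)


def detect_loy(
    chry_bins: pd.DataFrame,
    autosome_bins: pd.DataFrame,
    purity: float,
    founder_sex: str,
    ploidy: int = 2,
    host_y_copies: float = 0.0,
    loss_ratio: float = 0.5,
) -> bool:
    """Loss-of-Y call from the chrY/autosome depth ratio.

    The expected ratio with Y present is the Y-copy expectation (one Y per
    tumour genome at ploidy scaling, plus any male-host contamination)
    against the autosomal baseline; observed below ``loss_ratio`` x expected
    flags LoY.  Refuses a female founder (no Y baseline exists).
    """
    if founder_sex != "male":
        raise ValueError("LoY detection requires a male clone founder")
    y_depth = float(chry_bins["depth"].mean())
    a_depth = float(autosome_bins["depth"].mean())
    denom = purity * ploidy + 2.0 * (1.0 - purity)
    expected = (purity * (ploidy / 2.0) + host_y_copies * (1.0 - purity)) / denom
    observed = y_depth / a_depth
    return observed < loss_ratio * expected


def recurrence_map(
    sample_segments: dict[str, list[CNSegment]],
    tree: CloneTree,
    sample_modal: dict[str, int] | None = None,
    bin_size: int = 1000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort CNV recurrence map with phylogenetic deduplication.

    CNVs are matched across samples when their boundaries agree within one
    bin and their direction (gain/loss versus the sample's modal CN)
    matches; each matched set is deduplicated to its parsimony origins on
    the tree, so a mitotically inherited CNV counts once.  Returns
    (events, linked) where ``events`` has one row per unique occurrence
    (origin) and ``linked`` reports CNV pairs with identical carrier sets.
    """
    raw = []
    for sample, segs in sample_segments.items():
        modal = (
            sample_modal[sample] if sample_modal else modal_cn(segs)
        )
        for s in segs:
            if s.chrom in ("chrY",):
                continue
            if s.cn != modal:
                raw.append(
                    (sample, s.chrom, s.start, s.end,
                     "gain" if s.cn > modal else "loss")
                )
    df = pd.DataFrame(raw, columns=["sample", "chrom", "start", "end", "direction"])
    groups: list[dict] = []
    for (chrom, direction), sub in df.groupby(["chrom", "direction"], sort=False):
        sub = sub.sort_values(["start", "end"])
        for row in sub.itertuples(index=False):
            placed = False
            for g in groups:
                if (
                    g["chrom"] == chrom
                    and g["direction"] == direction
                    and abs(g["start"] - row.start) <= bin_size
                    and abs(g["end"] - row.end) <= bin_size
                ):
                    g["carriers"].add(row.sample)
                    placed = True
                    break
            if not placed:
                groups.append(
                    {"chrom": chrom, "start": row.start, "end": row.end,
                     "direction": direction, "carriers": {row.sample}}
                )
    rows = []
    for gi, g in enumerate(groups):
        origins = map_event_to_tree(tree, g["carriers"], polarity="gain")
        for o in origins:
            rows.append(
                (gi, g["chrom"], g["start"], g["end"], g["direction"],
                 len(g["carriers"]), o, len(origins))
            )
    events = pd.DataFrame(
        rows, columns=["cnv_id", "chrom", "start", "end", "direction",
                       "n_carriers", "origin_branch", "n_origins"],
    )
    linked_rows = []
    carrier_sets = [frozenset(g["carriers"]) for g in groups]
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            if len(carrier_sets[i]) >= 2 and carrier_sets[i] == carrier_sets[j]:
                origins = map_event_to_tree(tree, set(carrier_sets[i]), "gain")
                linked_rows.append((i, j, len(carrier_sets[i]), len(origins) == 1))
    linked = pd.DataFrame(
        linked_rows, columns=["cnv_a", "cnv_b", "n_carriers", "clade_consistent"]
    )
    return events, linked


def gain_loss_depth(
    events: pd.DataFrame, chrom_lengths: dict[str, int], bin_size: int = 1000
) -> dict[str, pd.DataFrame]:
    """Per-base gain/loss depth tracks from deduplicated recurrence events."""
    tracks = {}
    for chrom, clen in chrom_lengths.items():
        nbins = clen // bin_size + 1
        gain = np.zeros(nbins)
        loss = np.zeros(nbins)
        sub = events[events["chrom"] == chrom]
        for row in sub.itertuples(index=False):
            a, b = row.start // bin_size, min(nbins, row.end // bin_size + 1)
            (gain if row.direction == "gain" else loss)[a:b] += 1
        tracks[chrom] = pd.DataFrame(
            {"bin_start": np.arange(nbins) * bin_size, "gain_depth": gain,
             "loss_depth": loss}
        )
    return tracks


def arm_event_enrichment(
    tetraploid: np.ndarray, has_arm_event: np.ndarray
) -> tuple[float, np.ndarray]:
    """Fisher's exact test of arm-scale event frequency by ploidy class."""
    t = np.asarray(tetraploid, bool)
    e = np.asarray(has_arm_event, bool)
    if t.all() or (~t).all():
        raise ValueError("need tumours in both ploidy classes")
    table = np.array(
        [[(t & e).sum(), (t & ~e).sum()], [(~t & e).sum(), (~t & ~e).sum()]]
    )
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p), table
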