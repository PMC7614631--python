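"""Context-aware dN/dS with per-gene likelihood-ratio tests.

A deliberately reduced dNdScv-style model: mutation rates per 96-channel
trinucleotide context are estimated from synonymous sites genome-wide
(pooled across the clone), expected counts per gene and impact class follow
by summing context rates over every possible coding change, and each gene is
tested for excess missense, truncating (nonsense + frameshift) and overall
protein-altering mutations by a Poisson likelihood-ratio test with
Benjamini-Hochberg correction.  The negative-binomial covariate shrinkage of
the full dNdScv method is intentionally omitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats
from statsmodels.stats.multitest import multipletests

from devilclones.signatures import SBS_CHANNELS, sbs_channel
from devilclones.simcohort.genome import SyntheticGenome

__all__ = [
    "classify_impact",
    "ImpactCounts",
    "expected_counts",
    "DnDsResult",
    "gene_dnds_test",
]

IMPACT_CLASSES = ["synonymous", "missense", "nonsense", "frameshift", "inframe"]
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# standard genetic code, expanded once from Biopython's translator
_CODON_AA = {
    a + b + c: str(Seq(a + b + c).translate())
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
}


def classify_impact(
    chrom: str, pos: int, ref: str, alt: str, gene: pd.Series, genome: SyntheticGenome
) -> str:
    """Impact class of a variant overlapping a CDS (standard genetic code).

    Substitutions are classified by codon translation; indels by frame
    (length % 3).  ``pos`` is 1-based; gene coordinates 0-based half-open.
    """
    if (gene.end - gene.start) % 3 != 0:
        raise ValueError(f"CDS length of {gene.gene_id} not divisible by 3")
    if chrom != gene.chrom or not (gene.start < pos <= gene.end):
        raise ValueError("variant does not overlap the CDS")
    if len(ref) != len(alt):
        indel_len = abs(len(ref) - len(alt))
        return "frameshift" if indel_len % 3 else "inframe"
    cds = genome.cds_sequence(gene)
    p0 = pos - 1
    if gene.strand == "+":
        cpos = p0 - gene.start
        base = alt
    else:
        cpos = gene.end - 1 - p0
        base = _COMP[alt]
    codon_i, within = divmod(cpos, 3)
    codon = cds[codon_i * 3 : codon_i * 3 + 3]
    mutated = codon[:within] + base + codon[within + 1 :]
    aa_ref = _CODON_AA[codon]
    aa_alt = _CODON_AA[mutated]
    if aa_alt == aa_ref:
        return "synonymous"
    if aa_alt == "*":
        return "nonsense"
    return "missense"  # includes stop-loss, counted with missense


@dataclass
class ImpactCounts:
    observed: pd.DataFrame  # genes x impact classes
    expected: pd.DataFrame
    context_rates: pd.Series  # per 96-channel mutation rate
    n_synonymous: int


def _site_enumeration(gene: pd.Series, genome: SyntheticGenome):
    """(channel index, impact class index) for every CDS site x alt base.

    Cached on the genome object: the enumeration depends only on the gene
    model and the reference sequence.
    """
    cache = genome.__dict__.setdefault("_enum_cache", {})
    key = (gene.gene_id, gene.start, gene.end, gene.strand)
    if key in cache:
        return cache[key]
    chans, classes = [], []
    chan_idx = {c: i for i, c in enumerate(SBS_CHANNELS)}
    cls_idx = {c: i for i, c in enumerate(IMPACT_CLASSES)}
    for p0 in range(gene.start, gene.end):
        pos = p0 + 1
        if pos < 2 or pos > genome.chrom_lengths[gene.chrom] - 1:
            continue
        trip = genome.triplet(gene.chrom, pos)
        ref = trip[1]
        for alt in "ACGT":
            if alt == ref:
                continue
            impact = classify_impact(gene.chrom, pos, ref, alt, gene, genome)
            chans.append(chan_idx[sbs_channel(ref, alt, trip)])
            classes.append(cls_idx[impact])
    cache[key] = (np.array(chans), np.array(classes))
    return cache[key]


def expected_counts(
    variants: pd.DataFrame,
    annotation: pd.DataFrame,
    genome: SyntheticGenome,
    callable_bp: int | None = None,
    min_synonymous: int = 100,
) -> ImpactCounts:
    """Observed and expected per-gene impact counts.

    Substitution expectations come from per-context rates fitted to
    synonymous sites genome-wide, so expected synonymous totals equal the
    observed ones by construction.  Indel (frameshift) expectation is
    proportional to CDS length times the cohort indel rate per base.
    """
    callable_bp = callable_bp or genome.total_bp
    genes = list(annotation.itertuples(index=False))
    enum = {g.gene_id: _site_enumeration(pd.Series(g._asdict()), genome) for g in genes}

    obs = pd.DataFrame(0, index=[g.gene_id for g in genes], columns=IMPACT_CLASSES)
    obs_syn_ch = np.zeros(len(SBS_CHANNELS))
    chan_idx = {c: i for i, c in enumerate(SBS_CHANNELS)}
    by_chrom = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for row in variants.itertuples(index=False):
        for g in by_chrom.get(row.chrom, []):
            if not (g.start < row.pos <= g.end):
                continue
            gene = pd.Series(g._asdict())
            if row.var_class == "substitution":
                impact = classify_impact(row.chrom, int(row.pos), row.ref, row.alt, gene, genome)
                obs.loc[g.gene_id, impact] += 1
                if impact == "synonymous":
                    trip = genome.triplet(row.chrom, int(row.pos))
                    obs_syn_ch[chan_idx[sbs_channel(row.ref, row.alt, trip)]] += 1
            elif row.var_class == "indel":
                impact = classify_impact(row.chrom, int(row.pos), row.ref, row.alt, gene, genome)
                obs.loc[g.gene_id, impact] += 1

    n_syn = int(obs["synonymous"].sum())
    if n_syn == 0:
        raise ValueError("no synonymous mutations observed: context rates undefined")
    if n_syn < min_synonymous:
        import warnings

        warnings.warn(f"only {n_syn} synonymous mutations: dN/dS is underpowered")

    syn_opp_ch = np.zeros(len(SBS_CHANNELS))
    for g in genes:
        chans, classes = enum[g.gene_id]
        syn_mask = classes == IMPACT_CLASSES.index("synonymous")
        np.add.at(syn_opp_ch, chans[syn_mask], 1)
    # Per-channel rates shrunk toward the global synonymous rate: with few
    # synonymous observations per channel the raw ratio obs/opportunity is
    # far too noisy and would distort non-synonymous expectations.  The
    # shrinkage weight a ~ 2 pseudo-mutations per channel vanishes as data
    # grow, and total expected synonymous counts still equal observed ones.
    opp_total = syn_opp_ch.sum()
    u0 = n_syn / opp_total
    a = 2.0 * len(SBS_CHANNELS) / max(n_syn, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate_ch = np.where(
            syn_opp_ch > 0,
            (obs_syn_ch + a * u0 * syn_opp_ch) / ((1.0 + a) * np.maximum(syn_opp_ch, 1)),
            u0,  # channels never synonymous anywhere fall back to the global rate
        )

    exp = pd.DataFrame(0.0, index=obs.index, columns=IMPACT_CLASSES)
    for g in genes:
        chans, classes = enum[g.gene_id]
        for ci, cls in enumerate(IMPACT_CLASSES[:3]):  # substitution classes
            mask = classes == ci
            exp.loc[g.gene_id, cls] = rate_ch[chans[mask]].sum()
    # indel expectation: CDS length x cohort indel rate per base
    n_indels = int((variants["var_class"] == "indel").sum())
    for g in genes:
        cds_len = g.end - g.start
        exp.loc[g.gene_id, "frameshift"] = n_indels * cds_len / callable_bp
        exp.loc[g.gene_id, "inframe"] = 0.0
    return ImpactCounts(obs, exp, pd.Series(rate_ch, index=SBS_CHANNELS), n_syn)


@dataclass
class DnDsResult:
    global_omega: pd.DataFrame  # class -> omega, lo, hi
    per_gene: pd.DataFrame  # gene, class, obs, exp, lrt, p, q


def _poisson_lrt(obs: float, exp: float) -> float:
    if exp <= 0:
        return 0.0 if obs == 0 else np.inf
    if obs == 0:
        return 2.0 * exp
    return 2.0 * (obs * np.log(obs / exp) - (obs - exp))


def _binomial_share_lrt(n: float, total: float, share: float) -> float:
    """LRT of gene count n against Binomial(total, share).

    Conditioning on the cohort total cancels the (noisy) global mutation
    rate, so per-gene tests stay calibrated even when the context rates are
    estimated from modest synonymous counts.
    """
    if total <= 0 or share <= 0:
        return 0.0 if n == 0 else np.inf
    if share >= 1:
        return 0.0
    e = total * share
    rest = total - n
    e_rest = total * (1 - share)
    lrt = 0.0
    lrt += n * np.log(n / e) if n > 0 else 0.0
    lrt += rest * np.log(rest / e_rest) if rest > 0 else 0.0
    return 2.0 * lrt


def _ratio_ci(n: float, s: float, rho: float) -> tuple[float, float]:
    """95% CI for omega = (n / s) / rho from two Poisson counts.

    Uses the exact conditional-binomial construction for the rate ratio of
    independent Poisson counts: n | n + s is binomial, so both sampling
    noises propagate into the interval.
    """
    if s <= 0 or rho <= 0:
        return (np.nan, np.nan)
    p_lo = stats.beta.ppf(0.025, n, s + 1) if n > 0 else 0.0
    p_hi = stats.beta.ppf(0.975, n + 1, s)
    return (float(p_lo / (1 - p_lo) / rho), float(p_hi / (1 - p_hi) / rho))


def gene_dnds_test(
    counts: ImpactCounts, test_all_genes: bool = False
) -> DnDsResult:
    """Per-gene Poisson LRTs for excess missense / truncating / all
    protein-altering mutations, BH-corrected over tested genes, plus global
    omega per class with exact Poisson confidence intervals."""
    obs, exp = counts.observed, counts.expected
    tests = {
        "missense": (obs["missense"], exp["missense"]),
        "truncating": (
            obs["nonsense"] + obs["frameshift"],
            exp["nonsense"] + exp["frameshift"],
        ),
        "global": (
            obs["missense"] + obs["nonsense"] + obs["frameshift"],
            exp["missense"] + exp["nonsense"] + exp["frameshift"],
        ),
    }
    rows = []
    for cls, (o, e) in tests.items():
        total_o, total_e = float(o.sum()), float(e.sum())
        for gene in obs.index:
            if not test_all_genes and tests["global"][0][gene] == 0:
                continue
            share = float(e[gene]) / total_e if total_e > 0 else 0.0
            lrt = _binomial_share_lrt(float(o[gene]), total_o, share)
            p = float(stats.chi2.sf(lrt, 1)) if np.isfinite(lrt) else 0.0
            rows.append((gene, cls, float(o[gene]), float(e[gene]), float(lrt), p))
    per_gene = pd.DataFrame(rows, columns=["gene", "class", "obs", "exp", "lrt", "p"])
    per_gene["q"] = 1.0
    for cls in tests:
        mask = per_gene["class"] == cls
        if mask.any():
            per_gene.loc[mask, "q"] = multipletests(per_gene.loc[mask, "p"], method="fdr_bh")[1]
    grows = []
    s_tot = float(obs["synonymous"].sum())
    for cls, (o, e) in tests.items():
        n_tot, e_tot = float(o.sum()), float(e.sum())
        if e_tot > 0 and s_tot > 0:
            rho = e_tot / s_tot  # expected nonsyn-to-syn opportunity ratio
            lo, hi = _ratio_ci(n_tot, s_tot, rho)
            grows.append((cls, n_tot / e_tot, lo, hi))
        else:
            grows.append((cls, np.nan, np.nan, np.nan))
    global_omega = pd.DataFrame(
        grows, columns=["class", "omega", "lo", "hi"]
    ).set_index("class")
    return DnDsResult(global_omega, per_gene)
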