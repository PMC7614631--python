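# Methods

This note documents the models, estimators and numerical choices behind
`devilclones`, what the synthetic cohorts do and do not emulate, and the
package's known limitations.

## Synthetic cohorts (`simcohort`)

**Transmission tree.** The clone genealogy is a constant-rate birth (Yule)
process started from one lineage at the configured origin year, with
complete sampling: every lineage extant at the start of the sampling window
receives exactly one tip whose sampling date is drawn uniformly within the
window. The birth rate defaults to 1.5 splits/lineage/year, a sub-yearly
transmission generation time consistent with the rapid early
diversification documented for these clones; it is a configurable modelling
choice, not an inference. All n−1 splits are constrained to predate the
sampling window (inter-split intervals are rescaled if the Yule draw
overruns, preserving relative spacing). An optional multifurcation
probability merges a new split into its parent node, producing true
polytomies — the genealogical signature of one donor infecting several
recipients. The edge from the origin to the first split is the clone stem;
its mutations are shared by every sampled tumour and are exactly the
variants whose somatic/germline status is ambiguous downstream.

**Mutation clocks.** Each class (substitution, indel, LINE-1 insertion,
rearrangement event, CNV event) accrues per branch as
Poisson(rate × duration), with genome-per-year rates defaulting to the
published DFT1/DFT2 regression values. The genome is scaled by 1/300
(~10 Mb of the 2,983,750,195 bp callable genome) so cohorts simulate in
seconds; rates stay genome-wide, so burdens are directly interpretable.
The reference sequence is a first-order Markov chain with same-base
persistence 0.35 — an i.i.d. sequence badly underrepresents the homopolymer
tracts that host slippage indels, while the Markov genome carries a
realistic run-length spectrum at uniform base composition.

**Signatures.** Substitution channels are drawn from the configured
SBS1/SBS5 mixture (DFT1 ≈ 8%/92%, DFT2 ≈ 3%/97%, the proportions implied by
the per-signature rates), indel channels from the ID1/ID2 mixture (66/34
and 47/53). The packaged signature profiles are stylized synthetic
stand-ins (SBS1: C>T at CpG; SBS5: flat with mild T>C; SBS6: C>T-rich
mismatch-repair profile; ID1/ID2: 1-bp T/A insertions/deletions at
homopolymer runs ≥5; ID7: deletion-heavy MMR profile) shipped as flat TSVs
and shared between simulator and fitter. A hypermutator branch multiplies
substitution and indel rates (defaults 6× and 10×) from that branch onward
and draws the excess from the extra MMR-style signatures.

**Bulk sampling.** Per-variant depth is Poisson(depth_mean, default 83);
alt reads are Binomial(depth, VAF) with
VAF = purity·multiplicity·cell_fraction / (purity·CN_tumour + 2(1−purity)).
Germline heterozygous sites are emitted at VAF 0.5 regardless of purity.
Purity is uniform on the configured range (default 0.75–1).

**Germline model.** Polymorphic sites carry frequencies ~ Uniform(0.1,
0.5); genotypes are Hardy-Weinberg with a lognormal per-sample
heterozygosity factor (sd 0.12, median 1) that spreads per-sample rates
around the configured 0.132 het/kb median, emulating the observed
population range without modelling population structure. The site count is
chosen so the cohort median matches the configured rate.

**What the simulator does not emulate.** Read-level artefacts (mapping
error, strand bias, contamination), epidemiological realism (host death,
R0, spatial structure), pretransmission intervals, sequence context beyond
first-order composition, transcriptional-strand effects, and WGD-doubled
CNV dosage. Tests passing on these cohorts demonstrate estimator
correctness under the generating model, not robustness to real-data
artefacts.

## Somatic filtering

A variant is germline iff any panel normal shows ≥2 supporting reads at
depth ≥10 (thresholds configurable; matched-host subtraction, when host
links exist, applies first but the union rule is identical). Variants
present in all tumours of a clone and absent from all normals form the
clone-shared ambiguous bin. Purity = min(1, 2 × median VAF) over ≥50
clonal variants in copy-neutral diploid regions.

## Tree building and clock dating

Greedy perfect phylogeny: patterns ordered by sharing count (ties by
genomic order), accepted when laminar with the accepted family, conflicts
parked and later counted on each Camin-Sokal origin branch. This is exact
for clonal somatic variants under infinite sites; conflict fractions above
20% trigger a threshold warning.

The strict clock is sampled by Metropolis-Hastings over (rate, internal
node dates) with branch likelihood Poisson(count | r·duration), a uniform
rate prior on (0, 10 × max tip burden / sampling span) and uniform
order-constrained date priors. Defaults: 50,000 sweeps, 10,000 burn-in,
thinning 10; one sweep = one rate update, one scale move and one update per
internal node. Two mixing devices matter: per-node step sizes initialised
from local Fisher information and adapted during burn-in toward 44%
acceptance, and a likelihood-preserving scale move that stretches all
internal dates about the latest tip while scaling the rate inversely (with
the s^(n−1) Jacobian), which decorrelates the rate/timescale mode. On
3-tip trees the sampler matches brute-force grid integration; convergence
is reported as the split-half relative difference of the rate median.

Origin dating extends the root rootward by f × shared/r with
f ~ Uniform(0,1) over the posterior draws; the prior on f is this
package's choice and is flagged in the output. Because the truly somatic
stem variants have f = 1, the posterior median origin carries a rootward
bias of about half the stem length (~0.3 yr at the default birth rate);
the posterior interval covers the true origin.

Polytomy detection collapses internal branches shorter than ε (default
0.25 yr, posterior-median durations) and reports multifurcations of
out-degree ≥3.

## Subclone deconvolution

Binomial mixtures over (alt, depth) for k = 1..3, EM with 10 seeded
restarts, BIC selection with 2k−1 parameters; component VAF p maps to cell
fraction 2p/purity; a component with fraction ≥0.95 is labelled clonal.
Variants below depth 20 are excluded; fewer than 100 usable variants
returns k=1 with an underpowered flag. Ties in posterior assignment go to
the larger-fraction component. At ~80x the minimum reliably detectable
subclone fraction is ≈0.1. Placement attaches a pseudo-sample at the
branch maximising (shared path variants − missing path variants), with
branches within one variant of the optimum co-reported as ambiguous.

## Rates, ratios, shifts

Burden-vs-date fits are unweighted OLS with free intercept; slope CIs are
t-based and the F-test for a nonzero slope gates significance (α = 0.05,
non-significant classes reported "n.s." and excluded from ratios). Rate
ratios carry a first-order delta-method CI and a 10⁴-draw parametric
bootstrap CI side by side — the published ratio intervals are not exactly
reproducible by the delta method applied to printed slope CIs, so both are
reported. Phylogenetic non-independence of tumours is ignored (documented
limitation): in particular, clade-offset scans (`detect_rate_shift`, OLS of
burden ~ date + clade indicator per internal branch with ≥4 tips inside and
outside, BH across branches) treat tumours as independent, so shared-branch
Poisson noise inflates type-I error relative to a date-only null;
calibration holds when burdens depend on date alone. Hypermutators are
flagged by leave-one-out fold-excess ≥3 (default).

## Copy number, WGD, LoY

Least-squares binary segmentation: recursive best split by SSE reduction,
minimum segment 10 bins, stop when the gain is below 3σ²·log n with σ
estimated from successive bin differences. Integer CN is the
purity-corrected depth ratio rounded at the ploidy baseline. Tetraploidy
requires bp-weighted modal CN 4 plus a bimodal clonal VAF distribution at
the multiplicity modes m·purity/(4·purity+2(1−purity)) (each mode holding
≥15% of variants within 0.06 of its expectation). WGD dates are
sampling_date − post_count/(κ·r) with κ = 2 by default (post-doubling
accrual scales with DNA content; κ = 1 supported and labelled), with the
exact Poisson interval on the count combined with the rate CI. LoY is an
observed chrY/autosome depth ratio below half its expectation given purity,
ploidy and male-host contamination. Recurrent CNVs match across samples at
±1 bin with equal direction, deduplicate to parsimony origins (mitotically
inherited events count once), and pairs with identical multi-sample carrier
sets are reported as linked.

## dN/dS ("dNdScv-lite")

Impact classes by codon translation (standard code; stop-loss counted with
missense; CDS-length-divisibility enforced). Mutation rates per 96-channel
context are estimated from synonymous sites genome-wide with shrinkage
toward the global synonymous rate (pseudo-weight ≈2 mutations per channel,
vanishing as synonymous counts grow; channels with no synonymous
opportunity anywhere fall back to the global rate). The shrinkage preserves
the identity Σ expected synonymous = observed synonymous. Expected counts
per gene and class sum context rates over every possible coding change;
frameshift expectation is CDS length × cohort indel rate per base.
Per-gene tests condition on the cohort total — gene count vs
Binomial(total, expected share) by LRT — which cancels global-rate noise
and keeps small-cohort calibration; BH correction runs within each class
over genes with ≥1 protein-altering mutation (a flag widens this to all
genes). The global ω CI uses the exact conditional-binomial construction
for a ratio of Poisson counts, so both sampling noises propagate. The
negative-binomial covariate shrinkage of the full dNdScv is deliberately
omitted; with per-context rates pooled across the clone this is a
reduced, but calibrated, analogue.

## LINE-1 attribution

An insertion carrying a 3' transduction is attributed to the annotated
full-length element whose 3' end lies within 10 kb (default) upstream of
the transduced segment on the correct strand; nearest wins, ties are
flagged, unmatched transductions are orphans. Activity per source per
branch uses gain parsimony on the carrier sets.

## Problem sizes

Tests and the acceptance script run cohorts of 8–63 tumours on 1/300 to
1/2000 genome scales, chosen so the full suite and the acceptance run each
complete in minutes on a single core while keeping every estimator in its
operating regime (hundreds of variants per mixture fit, tens of thousands
of substitutions per clock fit, ≥10 tumours per clade scan).
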