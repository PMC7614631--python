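"""Per-branch mutation simulation on a dated transmission tree.

Counts for every mutation class are drawn Poisson(rate x branch duration);
substitution channels follow the configured SBS mixture and indel channels
the ID mixture; positions are placed uniformly over the scaled callable
genome without collision (context-matched for substitutions, homopolymer-run
matched for indels).  A hypermutator branch multiplies the substitution and
indel rates from that branch onward and contributes the excess from an extra
mismatch-repair-style signature.  WGD, LoY and CNV events are recorded as
truth and expressed later when bulk samples are drawn.

When no genome is supplied the simulator runs in burden-only mode: branch
counts and the truth table are produced without individual variant records,
which is all the rate-recovery and clock analyses need.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from devilclones.signatures import ReferenceSignatures, SBS_CHANNELS, ID_CHANNELS
from devilclones.simcohort.config import CohortConfig
from devilclones.simcohort.genome import SyntheticGenome
from devilclones.trees import CloneTree

__all__ = ["TruthTable", "simulate_mutations"]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class TruthTable:
    """Ground truth emitted alongside every simulated cohort."""

    branch_counts: dict[int, dict[str, int]] = field(default_factory=dict)
    tip_burdens: dict[str, dict[str, int]] = field(default_factory=dict)
    purity: dict[str, float] = field(default_factory=dict)
    ploidy: dict[str, int] = field(default_factory=dict)
    subclone_fractions: dict[str, list[float]] = field(default_factory=dict)
    wgd_events: list[dict] = field(default_factory=list)
    loy_branches: list[int] = field(default_factory=list)
    l1_attribution: dict[int, str] = field(default_factory=dict)
    cnv_events: list[dict] = field(default_factory=list)
    rearrangements: list[dict] = field(default_factory=list)
    hypermutator_branch: int | None = None

    def audit_conservation(self, tree: CloneTree) -> bool:
        """Check tip burden == sum of ancestral branch counts, per class."""
        for tip in tree.tips():
            label = tree.labels[tip]
            for cls, total in self.tip_burdens[label].items():
                if tree.total_count(tip, cls) != total:
                    return False
        return True

    def to_json(self) -> str:
        def _default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))

        payload = {
            "branch_counts": {str(k): v for k, v in self.branch_counts.items()},
            "tip_burdens": self.tip_burdens,
            "purity": self.purity,
            "ploidy": self.ploidy,
            "subclone_fractions": self.subclone_fractions,
            "wgd_events": self.wgd_events,
            "loy_branches": self.loy_branches,
            "l1_attribution": {str(k): v for k, v in self.l1_attribution.items()},
            "cnv_events": self.cnv_events,
            "rearrangements": self.rearrangements,
            "hypermutator_branch": self.hypermutator_branch,
        }
        return json.dumps(payload, indent=2, default=_default)


class _SitePool:
    """Collision-free draws from pre-shuffled position pools."""

    def __init__(self, index: dict, rng: np.random.Generator) -> None:
        self.pools = {}
        self.ptr = {}
        self.rng = rng
        self.index = index

    def draw(self, key) -> int:
        if key not in self.pools:
            arr = self.index.get(key)
            if arr is None or len(arr) == 0:
                raise RuntimeError(f"no genome sites available for {key}; widen genome")
            self.pools[key] = self.rng.permutation(arr)
            self.ptr[key] = 0
        i = self.ptr[key]
        if i >= len(self.pools[key]):
            raise RuntimeError(f"exhausted genome sites for {key}; widen genome")
        self.ptr[key] = i + 1
        return int(self.pools[key][i])


def _hyper_descendants(tree: CloneTree, branch: int) -> set[int]:
    out, stack = set(), [branch]
    while stack:
        n = stack.pop()
        out.add(n)
        stack.extend(tree.children[n])
    return out


def simulate_mutations(
    tree: CloneTree,
    config: CohortConfig,
    genome: SyntheticGenome | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame | None, TruthTable]:
    """Draw per-branch mutations of every class; return (variants, truth).

    ``variants`` is None in burden-only mode (``genome=None``).  Branch
    counts are stored on ``tree.branch_counts`` in both modes.
    """
    for cls in ("substitution", "indel", "line1_insertion", "rearrangement_event", "cnv_event"):
        if cls not in config.rates:
            raise ValueError(f"rate for class {cls} not configured")
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    truth = TruthTable()
    hyper = config.hypermutator_spec
    hyper_nodes: set[int] = set()
    if hyper is not None:
        hyper_nodes = _hyper_descendants(tree, hyper.branch)
        truth.hypermutator_branch = hyper.branch

    sbs_refs = ReferenceSignatures.load_sbs()
    id_refs = ReferenceSignatures.load_indel()
    p_sbs = sbs_refs.mixture(config.signature_mix) if config.signature_mix else None
    p_id = id_refs.mixture(config.indel_signature_mix) if config.indel_signature_mix else None
    if hyper is not None:
        m_s, m_i = hyper.substitution_multiplier, hyper.indel_multiplier
        extra_s = sbs_refs.mixture({hyper.extra_sbs_signature: 1.0})
        extra_i = id_refs.mixture({hyper.extra_id_signature: 1.0})
        p_sbs_hyper = p_sbs / m_s + extra_s * (1 - 1 / m_s) if p_sbs is not None else extra_s
        p_id_hyper = p_id / m_i + extra_i * (1 - 1 / m_i) if p_id is not None else extra_i

    ctx_pool = run_pool = None
    if genome is not None:
        ctx_pool = _SitePool(genome.context_site_index(), rng)
        run_pool = _SitePool(genome.run_site_index(), rng)
        chrom_names = genome.chromosomes
        chrom_p = np.array([genome.chrom_lengths[c] for c in chrom_names], dtype=float)
        chrom_p /= chrom_p.sum()
        used_uniform: set[tuple[str, int]] = set()

    records: list[tuple] = []
    vid = 0
    l1_weights = None
    if genome is not None and len(genome.l1_elements):
        if config.l1_source_spec:
            ids = list(genome.l1_elements.element_id)
            w = np.zeros(len(ids))
            for elem, weight in config.l1_source_spec:
                w[ids.index(elem)] = weight
        else:
            w = np.ones(len(genome.l1_elements))
        l1_weights = w / w.sum()

    for node in tree.preorder():
        if node == tree.root:
            continue
        dur = tree.branch_duration(node)
        if dur < 0:
            raise ValueError(f"negative branch duration at node {node}")
        is_hyper = node in hyper_nodes
        rates = dict(config.rates)
        if is_hyper and hyper is not None:
            rates["substitution"] *= hyper.substitution_multiplier
            rates["indel"] *= hyper.indel_multiplier
        counts = {
            cls: int(rng.poisson(rates[cls] * dur)) for cls in rates
        }
        tree.branch_counts[node] = dict(counts)
        truth.branch_counts[node] = dict(counts)
        if genome is None:
            continue

        t0 = tree.dates[tree.parent[node]]
        branch_vids: list[int] = []

        # ---- substitutions: channel-first placement on matching contexts
        n_sub = counts["substitution"]
        if n_sub:
            probs = p_sbs_hyper if (is_hyper and hyper is not None) else p_sbs
            chan_counts = rng.multinomial(n_sub, probs)
            for ci in np.flatnonzero(chan_counts):
                channel = SBS_CHANNELS[ci]
                five, rest = channel[0], channel[2:]
                pyr_ref, pyr_alt, three = rest[0], rest[2], rest[4]
                ctx = five + pyr_ref + three
                for _ in range(int(chan_counts[ci])):
                    chrom, pos = genome.decode_site(ctx_pool.draw(ctx))
                    ref = genome.base(chrom, pos)
                    alt = pyr_alt if ref == pyr_ref else _COMP[pyr_alt]
                    records.append(
                        (vid, chrom, pos, ref, alt, "substitution", channel,
                         node, float(rng.uniform(t0, tree.dates[node])), "",
                         "", np.nan, np.nan)
                    )
                    branch_vids.append(vid)
                    vid += 1

        # ---- indels: channel-first placement on homopolymer runs
        n_ind = counts["indel"]
        if n_ind:
            probs = p_id_hyper if (is_hyper and hyper is not None) else p_id
            chan_counts = rng.multinomial(n_ind, probs)
            for ci in np.flatnonzero(chan_counts):
                channel = ID_CHANNELS[ci]
                op, base, rb = channel.split("_")
                for _ in range(int(chan_counts[ci])):
                    chrom, run_start = genome.decode_site(run_pool.draw((base, rb)))
                    pos = run_start - 1  # VCF anchor base before the run
                    anchor = genome.base(chrom, pos)
                    if op == "ins":
                        ref, alt = anchor, anchor + base
                    else:
                        ref, alt = anchor + base, anchor
                    records.append(
                        (vid, chrom, pos, ref, alt, "indel", channel,
                         node, float(rng.uniform(t0, tree.dates[node])), "",
                         "", np.nan, np.nan)
                    )
                    branch_vids.append(vid)
                    vid += 1

        # ---- LINE-1 insertions with optional 3' transductions
        n_l1 = counts["line1_insertion"]
        for _ in range(int(n_l1)):
            while True:
                chrom = chrom_names[rng.choice(len(chrom_names), p=chrom_p)]
                pos = int(rng.integers(2, genome.chrom_lengths[chrom] - 1))
                if (chrom, pos) not in used_uniform:
                    used_uniform.add((chrom, pos))
                    break
            source = ""
            td_chrom, td_start, td_end = "", np.nan, np.nan
            if l1_weights is not None:
                elem = genome.l1_elements.iloc[int(rng.choice(len(l1_weights), p=l1_weights))]
                source = str(elem.element_id)
                truth.l1_attribution[vid] = source
                if rng.random() < config.l1_transduction_prob:
                    # unique sequence downstream of the source 3' end
                    offset = int(rng.integers(20, 2000))
                    td_len = int(rng.integers(200, 3000))
                    clen = genome.chrom_lengths[elem.chrom]
                    td_chrom = str(elem.chrom)
                    if elem.strand == "+":
                        td_start = min(elem.end + offset, clen - 1)
                        td_end = min(td_start + td_len, clen)
                    else:
                        td_end = max(elem.start - offset, 1)
                        td_start = max(td_end - td_len, 0)
            records.append(
                (vid, chrom, pos, genome.base(chrom, pos), "<INS:L1>",
                 "line1_insertion", "", node,
                 float(rng.uniform(t0, tree.dates[node])), source,
                 td_chrom, td_start, td_end)
            )
            branch_vids.append(vid)
            vid += 1

        # ---- structural classes: recorded as truth event tables
        for _ in range(int(counts["rearrangement_event"])):
            chrom = chrom_names[rng.choice(len(chrom_names), p=chrom_p)]
            truth.rearrangements.append(
                {"branch": node, "chrom": chrom,
                 "pos": int(rng.integers(1, genome.chrom_lengths[chrom]))}
            )
        for _ in range(int(counts["cnv_event"])):
            chrom = chrom_names[rng.choice(len(chrom_names), p=chrom_p)]
            clen = genome.chrom_lengths[chrom]
            if rng.random() < 0.2:  # arm-scale event
                start, end = (0, clen // 2) if rng.random() < 0.5 else (clen // 2, clen)
            else:
                length = int(10 ** rng.uniform(3.7, 5.0))
                start = int(rng.integers(0, max(1, clen - length)))
                end = min(clen, start + length)
            truth.cnv_events.append(
                {"branch": node, "chrom": chrom, "start": int(start),
                 "end": int(end), "delta": int(1 if rng.random() < 0.5 else -1)}
            )
        tree.branch_variants[node] = branch_vids

    for branch, year in config.wgd_specs:
        truth.wgd_events.append({"branch": int(branch), "year": float(year)})
    truth.loy_branches = [int(b) for b in config.loy_specs]

    for tip in tree.tips():
        label = tree.labels[tip]
        truth.tip_burdens[label] = {
            cls: tree.total_count(tip, cls) for cls in config.rates
        }

    if genome is None:
        return None, truth
    variants = pd.DataFrame(
        records,
        columns=["vid", "chrom", "pos", "ref", "alt", "var_class", "context",
                 "branch", "time", "l1_source", "td_chrom", "td_start", "td_end"],
    )
    return variants, truth
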