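"""Clone phylogeny construction and strict-molecular-clock dating.

Tree building uses greedy perfect phylogeny, which is valid for clonal
somatic variants under the infinite-sites assumption: variants are ordered
by sharing count, each variant's carrier set is accepted if it nests with
the sets accepted so far, and the rare conflicting variants are assigned
afterwards by irreversible-gain parsimony.

Dating is a Metropolis-Hastings sampler over the clock rate r (mutations
per genome per year) and the internal node dates, with per-branch likelihood
Poisson(count | r x duration), a uniform rate prior on (0, 10 x max tip
burden / sampling span) and uniform node-date priors subject to parent <=
child.  Tip sampling dates are fixed data.  Origin-date uncertainty from
clone-shared variants of ambiguous somatic/germline status is propagated by
placing a Uniform(0,1) prior on their somatic fraction f and extending the
root rootward by f x shared_count / r.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from devilclones.trees import CloneTree

__all__ = [
    "MutationMatrix",
    "build_tree",
    "ClockFit",
    "fit_strict_clock",
    "OriginEstimate",
    "origin_interval_with_ambiguity",
    "detect_polytomies",
    "map_event_to_tree",
    "poisson_clock_loglik",
]


# --------------------------------------------------------------------------
# Mutation matrix
# --------------------------------------------------------------------------


@dataclass
class MutationMatrix:
    """Binary sample x variant presence, compressed to sharing patterns.

    Each distinct carrier set (pattern) keeps its total variant count and
    the ids of the variants showing it.
    """

    samples: list[str]
    patterns: list[frozenset[str]]
    weights: np.ndarray
    vids: list[list]

    @classmethod
    def from_presence(cls, presence: pd.DataFrame) -> "MutationMatrix":
        """From a samples x variants boolean frame (columns = variant ids)."""
        arr = presence.to_numpy(bool)
        if arr.ndim != 2:
            raise ValueError("presence must be 2-D (samples x variants)")
        if (arr.sum(axis=0) == 0).any():
            raise ValueError("all-zero variant columns are not allowed")
        samples = list(presence.index)
        groups: dict[frozenset, list] = {}
        for j, col in enumerate(presence.columns):
            pat = frozenset(np.array(samples)[arr[:, j]])
            groups.setdefault(pat, []).append(col)
        patterns = list(groups)
        weights = np.array([len(groups[p]) for p in patterns])
        return cls(samples, patterns, weights, [groups[p] for p in patterns])

    @classmethod
    def from_vaf(
        cls,
        alt: pd.DataFrame,
        dp: pd.DataFrame,
        purity: dict[str, float] | None = None,
        clonal_threshold: float = 0.2,
    ) -> "MutationMatrix":
        """Presence := VAF >= clonal_threshold at purity-adjusted scale."""
        vaf = alt / dp.replace(0, np.nan)
        thresh = pd.Series(
            {s: clonal_threshold * (purity.get(s, 1.0) if purity else 1.0)
             for s in alt.columns}
        )
        presence = (vaf >= thresh).fillna(False)
        presence = presence.loc[presence.any(axis=1)]
        return cls.from_presence(presence.T)

    @classmethod
    def from_branch_counts(
        cls, tree: CloneTree, count_class: str = "substitution"
    ) -> tuple["MutationMatrix", int]:
        """Patterns from a simulated tree's branch counts (truth channel).

        Variants on the clone stem are shared by every tumour and absent
        from normals; they are returned separately as ``shared_count``, the
        clone-shared ambiguous bin.
        """
        tipsets = tree.tipsets()
        all_tips = tipsets[tree.root]
        samples = sorted(all_tips)
        patterns, weights, vids = [], [], []
        shared = 0
        for node in tree.nodes:
            if node == tree.root:
                continue
            w = tree.branch_counts.get(node, {}).get(count_class, 0)
            if w == 0:
                continue
            pat = tipsets[node]
            if pat == all_tips:
                shared += w
                continue
            patterns.append(pat)
            weights.append(w)
            vids.append(list(tree.branch_variants.get(node, [])))
        return cls(samples, patterns, np.array(weights), vids), shared

    @property
    def total_variants(self) -> int:
        return int(self.weights.sum())


# --------------------------------------------------------------------------
# Greedy perfect phylogeny
# --------------------------------------------------------------------------


def _laminar_compatible(s: frozenset, family: list[frozenset]) -> bool:
    return all(s <= a or a <= s or not (s & a) for a in family)


def build_tree(
    matrix: MutationMatrix,
    tip_dates: dict[str, float] | None = None,
    conflict_warn_fraction: float = 0.2,
) -> CloneTree:
    """Greedy perfect-phylogeny construction from a mutation matrix.

    Deterministic: patterns are processed by descending sharing count with
    ties broken by input (genomic) order.  Branch counts land under the
    ``substitution`` class; parked conflicting patterns are mapped by
    Camin-Sokal parsimony and counted on each origin branch.
    """
    if len(matrix.samples) < 3:
        raise ValueError("need at least 3 samples to build a tree")
    order = sorted(range(len(matrix.patterns)), key=lambda i: (-len(matrix.patterns[i]), i))
    accepted: dict[frozenset, tuple[int, list]] = {}
    parked: list[int] = []
    family: list[frozenset] = []
    for i in order:
        pat = matrix.patterns[i]
        if pat in accepted:
            w, v = accepted[pat]
            accepted[pat] = (w + int(matrix.weights[i]), v + list(matrix.vids[i]))
        elif _laminar_compatible(pat, family):
            accepted[pat] = (int(matrix.weights[i]), list(matrix.vids[i]))
            family.append(pat)
        else:
            parked.append(i)

    parked_weight = int(matrix.weights[parked].sum()) if parked else 0
    if matrix.total_variants and parked_weight / matrix.total_variants > conflict_warn_fraction:
        warnings.warn(
            f"{parked_weight}/{matrix.total_variants} variants conflict with the "
            "greedy perfect phylogeny; the clonal-presence threshold is likely wrong"
        )

    # node set: root (all samples), accepted clusters, singleton tips
    full = frozenset(matrix.samples)
    clusters = {full} | set(accepted) | {frozenset([s]) for s in matrix.samples}
    clusters.discard(frozenset())
    ordered = sorted(clusters, key=lambda c: (-len(c), sorted(c)))
    ids = {c: i for i, c in enumerate(ordered)}
    parent: dict[int, int] = {}
    for c in ordered:
        if c == full:
            continue
        best = None
        for cand in ordered:
            if c < cand and (best is None or len(cand) < len(best)):
                best = cand
        parent[ids[c]] = ids[best]
    labels = {ids[frozenset([s])]: s for s in matrix.samples}
    dates = {}
    if tip_dates:
        for s in matrix.samples:
            dates[ids[frozenset([s])]] = tip_dates[s]
    tree = CloneTree(parent, dates, labels)
    for c, (w, v) in accepted.items():
        tree.branch_counts[ids[c]] = {"substitution": w}
        tree.branch_variants[ids[c]] = v

    # parsimony assignment of parked patterns: one count per origin branch
    if parked:
        tipsets = tree.tipsets()
        for i in parked:
            for node in _gain_origins(tree, tipsets, matrix.patterns[i]):
                bc = tree.branch_counts.setdefault(node, {})
                bc["substitution"] = bc.get("substitution", 0) + int(matrix.weights[i])
                tree.branch_variants.setdefault(node, []).extend(matrix.vids[i])
    return tree


def _gain_origins(
    tree: CloneTree, tipsets: dict[int, frozenset], carriers: frozenset
) -> list[int]:
    """Maximal clades wholly inside the carrier set (Camin-Sokal origins)."""
    origins = []
    stack = [tree.root]
    while stack:
        n = stack.pop()
        if tipsets[n] <= carriers:
            origins.append(n)
        else:
            stack.extend(tree.children[n])
    return origins


def map_event_to_tree(
    tree: CloneTree, carriers: set[str], polarity: str = "gain"
) -> list[int]:
    """Minimum independent origins of an irreversible gain (or loss) whose
    carrier tips are given; returns the originating branch nodes."""
    if not carriers:
        raise ValueError("carrier set must be non-empty")
    if polarity not in ("gain", "loss"):
        raise ValueError("polarity must be 'gain' or 'loss'")
    tipsets = tree.tipsets()
    unknown = carriers - set(tipsets[tree.root])
    if unknown:
        raise KeyError(f"carriers not in tree: {sorted(unknown)}")
    return _gain_origins(tree, tipsets, frozenset(carriers))


# --------------------------------------------------------------------------
# Strict clock MCMC
# --------------------------------------------------------------------------


def poisson_clock_loglik(counts: np.ndarray, durations: np.ndarray, rate: float) -> float:
    """Log-likelihood (up to the count-factorial constant) of branch counts
    under a strict clock."""
    counts = np.asarray(counts, float)
    durations = np.asarray(durations, float)
    if rate <= 0 or np.any(durations < 0):
        return -np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(counts > 0, counts * np.log(rate * durations), 0.0)
    if np.any(np.isinf(terms) | np.isnan(terms)):
        return -np.inf
    return float(terms.sum() - rate * durations.sum())


@dataclass
class ClockFit:
    rate_median: float
    rate_interval: tuple[float, float]
    node_dates: dict[int, tuple[float, float, float]]  # node -> (median, lo, hi)
    root_samples: np.ndarray
    rate_samples: np.ndarray
    settings: dict
    convergence: float  # split-half relative difference in the rate median
    tree: CloneTree = field(repr=False, default=None)

    @property
    def root_median(self) -> float:
        return float(np.median(self.root_samples))

    @property
    def root_interval(self) -> tuple[float, float]:
        lo, hi = np.quantile(self.root_samples, [0.025, 0.975])
        return float(lo), float(hi)


def fit_strict_clock(
    tree: CloneTree,
    seed: int = 0,
    iterations: int = 50_000,
    burnin: int = 10_000,
    thin: int = 10,
    node_step: float = 0.5,
    count_class: str | None = "substitution",
) -> ClockFit:
    """Metropolis-Hastings strict-clock fit on a tree with dated tips.

    One iteration is a full sweep: a rate update followed by one update of
    every internal node date.  Posterior medians and central 95% intervals
    are reported for the rate and every node date.
    """
    rng = np.random.default_rng(seed)
    tips = tree.tips()
    tip_dates = {n: tree.dates[n] for n in tips}
    if len(set(round(d, 9) for d in tip_dates.values())) < 2:
        raise ValueError("all tips share one date: clock rate unidentifiable")

    nodes = tree.nodes
    internal = [n for n in nodes if not tree.is_tip(n)]
    idx = {n: i for i, n in enumerate(nodes)}
    parent_idx = {idx[n]: idx[tree.parent[n]] for n in nodes if n != tree.root}
    children_idx = {idx[n]: [idx[c] for c in tree.children[n]] for n in nodes}

    def branch_count(n: int) -> float:
        bc = tree.branch_counts.get(n, {})
        if count_class is None:
            return float(sum(bc.values()))
        return float(bc.get(count_class, 0))

    counts = np.array([0.0 if n == tree.root else branch_count(n) for n in nodes])
    dates = np.full(len(nodes), np.nan)
    for n in tips:
        dates[idx[n]] = tip_dates[n]

    span = max(tip_dates.values()) - min(tip_dates.values())
    burdens = [sum(counts[idx[m]] for m in tree.path_to_root(n) if m != tree.root) for n in tips]
    max_burden = max(max(burdens), 1.0)
    r_max = 10.0 * max_burden / span
    r = max_burden / max(span, 1e-9) / 2 + 1e-6

    # clock-consistent initialisation, children before parents
    for n in tree.postorder():
        if tree.is_tip(n):
            continue
        i = idx[n]
        dates[i] = min(dates[c] - max(counts[c] / r, 1e-4) for c in children_idx[i])

    child_counts = counts  # alias: counts are indexed by child node
    internal_idx = np.array([idx[n] for n in internal])
    root_i = idx[tree.root]
    c_tot = float(counts.sum())

    def total_duration() -> float:
        return float(sum(dates[i] - dates[parent_idx[i]] for i in parent_idx))

    d_tot = total_duration()
    r_step = max(r * 0.05, 1e-6)
    n_samples = max(0, (iterations - burnin)) // thin
    rate_out = np.empty(n_samples)
    date_out = np.empty((n_samples, len(internal_idx)))
    k = 0
    log, exp = math.log, math.exp
    n_int = len(internal_idx)
    int_list = [int(i) for i in internal_idx]
    has_parent = [i in parent_idx for i in int_list]
    par_of = [parent_idx.get(i, -1) for i in int_list]
    kids_of = [children_idx[i] for i in int_list]
    c_above_of = [float(child_counts[i]) for i in int_list]
    kid_counts_of = [[float(child_counts[c]) for c in kids] for kids in kids_of]

    # per-node step sizes from local Fisher information, adapted in burn-in
    steps = np.empty(n_int)
    for j in range(n_int):
        inv = sum(1.0 / max(c, 0.5) for c in kid_counts_of[j])
        if has_parent[j]:
            inv += 1.0 / max(c_above_of[j], 0.5)
        steps[j] = min(node_step, 2.4 / (r * math.sqrt(max(inv, 1e-12))) if inv else node_step)
    acc = np.zeros(n_int)
    tries = np.zeros(n_int)

    parent_edges = list(parent_idx.items())
    edge_child = np.array([c for c, _ in parent_edges])
    edge_parent = np.array([p for _, p in parent_edges])
    edge_counts = child_counts[edge_child]
    latest_tip = max(tip_dates.values())

    def full_ll(rate: float) -> float:
        d = dates[edge_child] - dates[edge_parent]
        if rate <= 0 or np.any(d < 0):
            return -np.inf
        with np.errstate(divide="ignore"):
            terms = np.where(edge_counts > 0, edge_counts * np.log(rate * d), 0.0)
        if np.any(np.isinf(terms)):
            return -np.inf
        return float(terms.sum() - rate * d.sum())

    for it in range(iterations):
        noise = rng.normal(0.0, 1.0, size=n_int)
        us = rng.random(n_int + 3)
        # scale move: stretch internal dates about the latest tip, rate
        # scaled inversely -- decorrelates the rate/timescale mode
        s = exp(rng.normal(0.0, 0.03))
        r_new = r / s
        if 0 < r_new < r_max:
            old = dates[internal_idx].copy()
            old_ll = full_ll(r)
            dates[internal_idx] = latest_tip - (latest_tip - old) * s
            dll = full_ll(r_new) - old_ll + (n_int - 1) * log(s)
            if dll >= 0 or us[n_int + 2] < exp(dll):
                r = r_new
                d_tot = total_duration()
            else:
                dates[internal_idx] = old
        # rate update: O(1) given count and duration totals
        r_new = r + rng.normal(0.0, r_step)
        if 0 < r_new < r_max:
            dll = c_tot * log(r_new / r) - (r_new - r) * d_tot
            if dll >= 0 or us[n_int] < exp(dll):
                r = r_new
        # node-date sweep (fixed scan order; a valid MH scan scheme)
        for j in range(n_int):
            i = int_list[j]
            cur = dates[i]
            x = cur + noise[j] * steps[j]
            tries[j] += 1
            lo = dates[par_of[j]] if has_parent[j] else -math.inf
            kids = kids_of[j]
            hi = min(dates[c] for c in kids)
            if not (lo < x < hi):
                continue
            delta = x - cur
            dll = 0.0
            if has_parent[j]:
                c_above = c_above_of[j]
                if c_above > 0.0:
                    dll += c_above * (log(x - lo) - log(cur - lo))
                dll -= r * delta
            for c, cc in zip(kids, kid_counts_of[j]):
                if cc > 0.0:
                    dll += cc * (log(dates[c] - x) - log(dates[c] - cur))
                dll += r * delta
            if dll >= 0 or us[j] < exp(dll):
                dates[i] = x
                acc[j] += 1
                d_tot += delta * (1 - len(kids)) if has_parent[j] else -delta * len(kids)
        if it < burnin and it > 0 and it % 200 == 0:
            rate_acc = np.divide(acc, np.maximum(tries, 1))
            steps *= np.exp(np.clip(rate_acc - 0.44, -0.5, 0.5))
            steps = np.clip(steps, 1e-4, 10.0)
            acc[:] = 0
            tries[:] = 0
        if it >= burnin and (it - burnin) % thin == 0 and k < n_samples:
            rate_out[k] = r
            date_out[k] = dates[internal_idx]
            k += 1

    rate_out, date_out = rate_out[:k], date_out[:k]
    half = k // 2
    conv = abs(np.median(rate_out[:half]) - np.median(rate_out[half:])) / max(
        np.median(rate_out), 1e-12
    )
    node_summ = {}
    for j, i in enumerate(internal_idx):
        med = float(np.median(date_out[:, j]))
        lo_, hi_ = np.quantile(date_out[:, j], [0.025, 0.975])
        node_summ[nodes[i]] = (med, float(lo_), float(hi_))
    for n in tips:
        node_summ[n] = (tip_dates[n], tip_dates[n], tip_dates[n])
    lo_r, hi_r = np.quantile(rate_out, [0.025, 0.975])
    root_pos = list(internal_idx).index(root_i)
    return ClockFit(
        rate_median=float(np.median(rate_out)),
        rate_interval=(float(lo_r), float(hi_r)),
        node_dates=node_summ,
        root_samples=date_out[:, root_pos].copy(),
        rate_samples=rate_out.copy(),
        settings={
            "iterations": iterations, "burnin": burnin, "thin": thin,
            "seed": seed, "rate_prior_max": r_max,
        },
        convergence=float(conv),
        tree=tree,
    )


# --------------------------------------------------------------------------
# Origin interval with somatic/germline ambiguity
# --------------------------------------------------------------------------


@dataclass
class OriginEstimate:
    median: float
    interval: tuple[float, float]
    samples: np.ndarray
    shared_count: int
    somatic_fraction_prior: str = "Uniform(0,1)"


def origin_interval_with_ambiguity(
    fit: ClockFit, shared_count: int, seed: int = 0,
    somatic_fraction: float | None = None,
) -> OriginEstimate:
    """Clone origin date integrating over the somatic fraction f of the
    clone-shared ambiguous variants: origin = root - f x shared / r, with
    f ~ Uniform(0,1) unless fixed explicitly."""
    if shared_count < 0:
        raise ValueError("shared_count must be >= 0")
    rng = np.random.default_rng(seed)
    if somatic_fraction is None:
        f = rng.uniform(0.0, 1.0, size=len(fit.root_samples))
    else:
        f = np.full(len(fit.root_samples), float(somatic_fraction))
    samples = fit.root_samples - f * shared_count / fit.rate_samples
    lo, hi = np.quantile(samples, [0.025, 0.975])
    return OriginEstimate(
        float(np.median(samples)), (float(lo), float(hi)), samples, int(shared_count)
    )


# --------------------------------------------------------------------------
# Polytomy detection
# --------------------------------------------------------------------------


def detect_polytomies(
    tree: CloneTree, fit: ClockFit | None = None, epsilon_years: float = 0.25
) -> list[dict]:
    """Collapse internal branches shorter than epsilon (posterior-median
    durations when a fit is given) and report resulting multifurcations:
    out-degree >= 3 flags candidate superspreading events."""
    node_date = (
        {n: fit.node_dates[n][0] for n in tree.nodes} if fit is not None else dict(tree.dates)
    )
    work = tree.copy()
    if epsilon_years > 0:
        merged = True
        while merged:
            merged = False
            for n in list(work.nodes):
                if n == work.root or work.is_tip(n) or n not in work.parent:
                    continue
                dur = node_date[n] - node_date[work.parent[n]]
                if dur < epsilon_years:
                    p = work.parent[n]
                    for c in work.children[n]:
                        work.parent[c] = p
                        work.children[p].append(c)
                    work.children[p].remove(n)
                    del work.parent[n], work.children[n]
                    merged = True
                    break
    report = []
    for n in work.nodes:
        deg = len(work.children[n])
        if deg >= 3:
            report.append({"node": n, "out_degree": deg, "date": node_date.get(n)})
    return report
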