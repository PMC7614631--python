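"""Transmission-tree simulation.

The clone genealogy is a constant-rate birth (Yule) process started from a
single lineage at the origin year, with complete sampling: every lineage
extant at the start of the sampling window receives exactly one tip, sampled
at a date drawn uniformly within the window (the sampling design of the real
cohorts is unknown; uniform dates are a configurable default, not an
inference).  All n-1 splits are constrained to predate the sampling window;
if the Yule draw overruns, inter-split intervals are rescaled to fit, which
preserves their relative spacing.

An optional multifurcation probability lets a splitting lineage add the new
daughter to its parent node instead of creating a fresh bifurcation,
producing true polytomies — the genealogical signature of one donor
transmitting to several recipients.
"""

from __future__ import annotations

import numpy as np

from devilclones.simcohort.config import CohortConfig
from devilclones.trees import CloneTree

__all__ = ["simulate_transmission_tree"]


def simulate_transmission_tree(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> CloneTree:
    """Simulate a rooted, dated clone genealogy with ``n_tumours`` tips.

    The root node sits at ``origin_year``; the edge from the root to the
    first split is the clone stem, whose mutations are shared by every
    sampled tumour.  Deterministic given ``config.seed`` (or an explicit
    ``rng``).
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_tumours
    lo, hi = config.sampling_window

    # Yule split times: 1 -> n lineages, waiting time Exp(k * birth_rate)
    ks = np.arange(1, n)
    waits = rng.exponential(1.0 / (ks * config.birth_rate))
    split_times = config.origin_year + np.cumsum(waits)
    horizon = lo - 1e-3 * (lo - config.origin_year)
    if split_times[-1] > horizon:
        scale = (horizon - config.origin_year) / (split_times[-1] - config.origin_year)
        split_times = config.origin_year + (split_times - config.origin_year) * scale

    parent: dict[int, int] = {}
    dates: dict[int, float] = {0: config.origin_year}
    next_id = 1
    lineages = [0]  # node each growing lineage currently hangs from
    for s in split_times:
        idx = int(rng.integers(len(lineages)))
        head = lineages[idx]
        if (
            config.multifurcation_prob > 0
            and head != 0
            and rng.random() < config.multifurcation_prob
        ):
            # attach the new daughter to the existing split: a polytomy
            lineages.append(head)
            continue
        node = next_id
        next_id += 1
        parent[node] = head
        dates[node] = float(s)
        lineages[idx] = node
        lineages.append(node)

    tip_dates = rng.uniform(lo, hi, size=len(lineages))
    labels: dict[int, str] = {}
    order = rng.permutation(len(lineages))
    for i, lineage_idx in enumerate(order):
        node = next_id
        next_id += 1
        parent[node] = lineages[lineage_idx]
        dates[node] = float(tip_dates[i])
        labels[node] = f"{config.clone_label}_T{i:03d}"

    tree = CloneTree(parent, dates, labels)
    assert tree.n_tips() == n
    return tree
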