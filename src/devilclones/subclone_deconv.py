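"""Subclone detection, isolation and phylogenetic placement.

Bulk tumours are screened for subclonal cell populations by fitting binomial
mixtures to somatic variant allele counts in copy-neutral regions: a
component at cell fraction phi contributes heterozygous variants at expected
VAF = purity x phi / 2.  Model order k = 1..k_max is selected by BIC, with a
clonal component (phi ~ 1) always permitted.  Detected subclones are
computationally isolated by maximum-posterior assignment and placed on the
clone phylogeny as pseudo-samples at the branch sharing the most
branch-defining variants.

At ~80x bulk depth the minimum reliably detectable subclone fraction is
about 0.1; bulk sequencing captures only clonal mutations or those in
sizeable subclones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from devilclones.trees import CloneTree

__all__ = [
    "SubcloneModel",
    "detect_subclones",
    "split_subclones",
    "place_on_tree",
]


@dataclass
class SubcloneModel:
    k: int
    fractions: np.ndarray  # cell fractions, descending
    weights: np.ndarray  # mixture weights (variant proportions)
    posteriors: np.ndarray  # n_variants x k assignment posteriors
    log_likelihood: float
    bic: float
    scores: dict[int, tuple[float, float]]  # k -> (loglik, bic)
    purity: float
    underpowered: bool = False
    clonal_component: int | None = None  # index of the phi ~ 1 component

    @property
    def subclonal_fractions(self) -> np.ndarray:
        """Cell fractions of non-clonal components (descending)."""
        if self.clonal_component is None:
            return self.fractions
        return np.delete(self.fractions, self.clonal_component)


def _em_binomial_mixture(
    alt: np.ndarray,
    dp: np.ndarray,
    k: int,
    rng: np.random.Generator,
    restarts: int,
    max_p: float,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Best-of-restarts EM fit; returns (loglik, p, weights, posteriors)."""
    n = len(alt)
    best = (-np.inf, None, None, None)
    for _ in range(restarts):
        p = np.sort(rng.uniform(0.02, max_p, size=k))[::-1]
        w = np.full(k, 1.0 / k)
        prev = -np.inf
        for _ in range(max_iter):
            logpmf = binom.logpmf(alt[:, None], dp[:, None], p[None, :])
            logw = np.log(np.maximum(w, 1e-300))
            joint = logpmf + logw
            m = joint.max(axis=1, keepdims=True)
            lse = m[:, 0] + np.log(np.exp(joint - m).sum(axis=1))
            ll = float(lse.sum())
            gamma = np.exp(joint - lse[:, None])
            w = gamma.mean(axis=0)
            p = (gamma * alt[:, None]).sum(axis=0) / np.maximum(
                (gamma * dp[:, None]).sum(axis=0), 1e-12
            )
            p = np.clip(p, 1e-6, max_p)
            if abs(ll - prev) < tol * max(1.0, abs(ll)):
                break
            prev = ll
        if ll > best[0]:
            best = (ll, p.copy(), w.copy(), gamma.copy())
    return best


def detect_subclones(
    alt_reads: np.ndarray,
    depth: np.ndarray,
    purity: float = 1.0,
    k_max: int = 3,
    seed: int = 0,
    restarts: int = 10,
    min_variants: int = 100,
    min_depth: int = 20,
) -> SubcloneModel:
    """Binomial-mixture deconvolution of one tumour's somatic VAFs.

    Only variants at depth >= ``min_depth`` (assumed copy-neutral diploid)
    enter the fit.  Returns the BIC-best model; an underpowered sample gets
    k = 1 with a flag.  Deterministic given ``seed``.
    """
    alt = np.asarray(alt_reads, dtype=float)
    dp = np.asarray(depth, dtype=float)
    keep = dp >= min_depth
    alt, dp = alt[keep], dp[keep]
    max_p = max(purity / 2.0, 1e-3)
    if len(alt) < min_variants:
        p_hat = alt.sum() / max(dp.sum(), 1.0)
        frac = np.array([min(1.0, 2.0 * p_hat / purity)])
        return SubcloneModel(
            1, frac, np.ones(1), np.ones((len(alt), 1)), float("nan"),
            float("nan"), {}, purity, underpowered=True,
            clonal_component=0 if frac[0] >= 0.95 else None,
        )
    rng = np.random.default_rng(seed)
    scores: dict[int, tuple[float, float]] = {}
    fits = {}
    n = len(alt)
    for k in range(1, k_max + 1):
        ll, p, w, gamma = _em_binomial_mixture(alt, dp, k, rng, restarts, max_p)
        n_params = 2 * k - 1  # k success probs + (k-1) weights
        bic = -2.0 * ll + n_params * np.log(n)
        scores[k] = (ll, float(bic))
        fits[k] = (ll, p, w, gamma)
    k_best = min(scores, key=lambda k: scores[k][1])
    ll, p, w, gamma = fits[k_best]
    order = np.argsort(p)[::-1]
    p, w, gamma = p[order], w[order], gamma[:, order]
    fractions = np.clip(2.0 * p / purity, 1e-6, 1.0)
    clonal = int(np.argmax(fractions)) if fractions.max() >= 0.95 else None
    return SubcloneModel(
        k_best, fractions, w, gamma, ll, scores[k_best][1], scores, purity,
        clonal_component=clonal,
    )


def split_subclones(
    model: SubcloneModel, variant_ids: list
) -> dict[int, list]:
    """Assign each variant to its maximum-posterior component.

    Ties go to the larger-fraction component (lower index after the
    descending sort), a documented deterministic tie-break.  Returns
    component index -> variant ids.
    """
    if model.k < 2:
        raise ValueError("need k >= 2 components to split")
    if len(variant_ids) != len(model.posteriors):
        raise ValueError("variant_ids must match the fitted variants")
    # argmax returns the first (larger-fraction) component on exact ties
    comp = np.argmax(model.posteriors, axis=1)
    out: dict[int, list] = {j: [] for j in range(model.k)}
    for vid, c in zip(variant_ids, comp):
        out[int(c)].append(vid)
    return out


@dataclass
class Attachment:
    branch: int
    score: int
    sister_tips: frozenset[str]
    ambiguous_with: list[int] = field(default_factory=list)


def place_on_tree(
    subclone_variants: set,
    tree: CloneTree,
    ambiguity_margin: int = 1,
) -> Attachment:
    """Attach a pseudo-sample to the branch maximising shared-variant
    compatibility: count of branch-path-defining variants present, minus
    those absent.  Branches within ``ambiguity_margin`` of the best score
    are co-reported."""
    path_vars: dict[int, set] = {}
    scores: dict[int, int] = {}
    for node in tree.preorder():
        if node == tree.root:
            path_vars[node] = set(tree.branch_variants.get(node, []))
        else:
            path_vars[node] = path_vars[tree.parent[node]] | set(
                tree.branch_variants.get(node, [])
            )
        pv = path_vars[node]
        scores[node] = len(subclone_variants & pv) - len(pv - subclone_variants)
    best = max(scores, key=lambda n: (scores[n], -tree.depth(n)))
    near = [
        n for n in scores
        if n != best and scores[best] - scores[n] <= ambiguity_margin
    ]
    return Attachment(
        branch=best,
        score=scores[best],
        sister_tips=tree.clade_tipset(best),
        ambiguous_with=sorted(near),
    )
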