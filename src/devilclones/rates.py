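"""Mutation-rate regressions, rate ratios, clade rate shifts, hypermutators.

Per-class mutation rates are the slopes of ordinary least-squares
regressions of per-tumour mutation burden against sampling date (decimal
years), reported with t-based 95% confidence intervals and the F-test for a
non-zero slope; classes failing the F-test are labelled not significant and
excluded from ratio formation.  Rate ratios carry first-order delta-method
intervals with a parametric-bootstrap interval co-reported, because the two
can differ when slope CIs are wide.  Regressions are unweighted and ignore
phylogenetic non-independence of tumours, a documented limitation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from devilclones.trees import CloneTree

__all__ = [
    "RateFit",
    "burden_regression",
    "RateRatio",
    "rate_ratio",
    "detect_rate_shift",
    "flag_hypermutators",
]

ALPHA = 0.05


@dataclass
class RateFit:
    slope: float  # mutations / genome / year
    intercept: float
    slope_se: float
    slope_interval: tuple[float, float]
    p_value: float  # F-test for slope != 0
    n: int
    residuals: np.ndarray = field(repr=False)
    dates: np.ndarray = field(repr=False)
    burdens: np.ndarray = field(repr=False)

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA

    @property
    def label(self) -> str:
        return f"{self.slope:.1f}" if self.significant else "n.s."


def burden_regression(burdens, dates) -> RateFit:
    """OLS of mutation burden on sampling date; slope is the clock rate."""
    y = np.asarray(burdens, dtype=float)
    x = np.asarray(dates, dtype=float)
    if len(y) != len(x):
        raise ValueError("burdens and dates must align")
    if len(y) < 3:
        raise ValueError("need at least 3 samples")
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct sampling dates")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=ALPHA)
    return RateFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        slope_se=float(model.bse[1]),
        slope_interval=(float(ci[1][0]), float(ci[1][1])),
        p_value=float(model.f_pvalue),
        n=len(y),
        residuals=np.asarray(model.resid),
        dates=x,
        burdens=y,
    )


@dataclass
class RateRatio:
    ratio: float | None
    interval_delta: tuple[float, float] | None
    interval_bootstrap: tuple[float, float] | None
    suppressed_reason: str | None = None


def rate_ratio(
    fit_a: RateFit, fit_b: RateFit, n_boot: int = 10_000, seed: int = 0
) -> RateRatio:
    """Ratio slope_b / slope_a with delta-method and bootstrap intervals.

    Suppressed (as in published rate tables) when either slope fails its
    F-test or is non-positive.
    """
    if not fit_a.significant or not fit_b.significant:
        return RateRatio(None, None, None, "non-significant slope")
    if fit_a.slope <= 0 or fit_b.slope <= 0:
        return RateRatio(None, None, None, "non-positive slope")
    r = fit_b.slope / fit_a.slope
    se = r * np.sqrt(
        (fit_a.slope_se / fit_a.slope) ** 2 + (fit_b.slope_se / fit_b.slope) ** 2
    )
    delta = (r - 1.959963985 * se, r + 1.959963985 * se)
    rng = np.random.default_rng(seed)
    a = rng.normal(fit_a.slope, fit_a.slope_se, size=n_boot)
    b = rng.normal(fit_b.slope, fit_b.slope_se, size=n_boot)
    ok = a > 0
    lo, hi = np.quantile(b[ok] / a[ok], [0.025, 0.975])
    return RateRatio(float(r), (float(delta[0]), float(delta[1])), (float(lo), float(hi)))


def detect_rate_shift(
    tree: CloneTree,
    burdens: dict[str, float],
    dates: dict[str, float],
    min_descendants: int = 4,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-clade burden-offset scan.

    For every internal branch with >= ``min_descendants`` descendant tips
    (and at least ``min_descendants`` outside tips), fit
    burden ~ date + I(descendant); the indicator coefficient estimates the
    clade's genome-wide mutation offset (negative = deficit).  Per-clade and
    background slopes are fitted separately; p-values are Benjamini-Hochberg
    corrected across branches.
    """
    samples = [s for s in burdens if s in dates]
    y = np.array([burdens[s] for s in samples], dtype=float)
    x = np.array([dates[s] for s in samples], dtype=float)
    tipsets = tree.tipsets()
    all_tips = set(samples)
    rows = []
    for node in tree.nodes:
        if node == tree.root or tree.is_tip(node):
            continue
        clade = set(tipsets[node]) & all_tips
        if len(clade) < min_descendants or len(all_tips - clade) < min_descendants:
            continue
        ind = np.array([1.0 if s in clade else 0.0 for s in samples])
        X = sm.add_constant(np.column_stack([x, ind]))
        model = sm.OLS(y, X).fit()
        offset = float(model.params[2])
        p = float(model.pvalues[2])
        in_mask = ind == 1
        slope_in = slope_out = (np.nan, np.nan, np.nan)
        for mask, store in ((in_mask, "in"), (~in_mask, "out")):
            if mask.sum() >= 3 and len(np.unique(x[mask])) >= 2:
                f = burden_regression(y[mask], x[mask])
                val = (f.slope, *f.slope_interval)
            else:
                val = (np.nan, np.nan, np.nan)
            if store == "in":
                slope_in = val
            else:
                slope_out = val
        rows.append(
            (node, len(clade), offset, p, *slope_in, *slope_out)
        )
    df = pd.DataFrame(
        rows,
        columns=["branch", "n_tips", "offset", "p",
                 "clade_slope", "clade_slope_lo", "clade_slope_hi",
                 "background_slope", "background_slope_lo", "background_slope_hi"],
    )
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
        df["significant"] = df["q"] < q_threshold
        df = df.sort_values("q").reset_index(drop=True)
    else:
        df["q"] = []
        df["significant"] = []
    return df


def flag_hypermutators(
    burdens: dict[str, float],
    dates: dict[str, float],
    threshold: float = 3.0,
) -> pd.DataFrame:
    """Leave-one-out burden-outlier scan.

    Each sample is compared with the prediction of the regression fitted to
    all other samples; fold-excess >= ``threshold`` flags a hypermutator.
    """
    samples = sorted(s for s in burdens if s in dates)
    rows = []
    for s in samples:
        rest = [t for t in samples if t != s]
        fit = burden_regression(
            [burdens[t] for t in rest], [dates[t] for t in rest]
        )
        pred = fit.intercept + fit.slope * dates[s]
        fold = burdens[s] / pred if pred > 0 else np.inf
        rows.append((s, burdens[s], pred, fold, fold >= threshold))
    return pd.DataFrame(
        rows, columns=["sample", "burden", "expected", "fold_excess", "flagged"]
    )
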