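"""Germline/somatic variant classification against a panel of normals.

A variant is germline iff it is present in any panel normal, where presence
means at least ``min_alt_reads`` supporting reads at ``min_depth`` total
depth.  When a tumour has a matched host normal, matched-host subtraction is
applied first and the panel subtraction afterwards; the germline rule is the
union of both.  Variants shared by all tumours of a clone yet absent from
every normal cannot be assigned confidently — those clone-shared, ambiguous
variants are kept in a separate bin consumed by the clock module when it
propagates origin-date uncertainty.

Also provides cohort germline heterozygosity (sites per kilobase) and a
median-VAF purity estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NormalPanel",
    "GermlineClassification",
    "classify_germline",
    "heterozygosity_per_kb",
    "HeterozygosityReport",
    "estimate_purity",
    "PurityEstimate",
]


@dataclass
class NormalPanel:
    """Panel of normal devil genomes, optionally host-matched to tumours."""

    normal_ids: list[str]
    host_links: dict[str, str] = field(default_factory=dict)  # tumour -> normal

    def validate(self, tumour_ids: list[str]) -> None:
        if not self.normal_ids:
            raise ValueError("cannot classify variants with an empty normal panel")
        overlap = set(self.normal_ids) & set(tumour_ids)
        if overlap:
            raise ValueError(f"panel must be disjoint from tumours: {sorted(overlap)}")
        for t, n in self.host_links.items():
            if n not in self.normal_ids:
                raise ValueError(f"matched host {n} for {t} not in panel")


@dataclass
class GermlineClassification:
    somatic: pd.Index
    germline: pd.Index
    ambiguous: pd.Index
    matched_host_hits: int = 0

    @property
    def summary(self) -> dict[str, int]:
        return {
            "n_somatic": len(self.somatic),
            "n_germline": len(self.germline),
            "n_ambiguous": len(self.ambiguous),
            "matched_host_hits": self.matched_host_hits,
        }


def _presence(alt: pd.DataFrame, dp: pd.DataFrame, min_alt: int, min_depth: int) -> pd.DataFrame:
    return (alt >= min_alt) & (dp >= min_depth)


def classify_germline(
    tumour_alt: pd.DataFrame,
    tumour_dp: pd.DataFrame,
    normal_alt: pd.DataFrame,
    normal_dp: pd.DataFrame,
    panel: NormalPanel,
    min_alt_reads: int = 2,
    min_depth: int = 10,
    clone_shared_ambiguous: bool = True,
) -> GermlineClassification:
    """Partition variants (rows) into somatic / germline / ambiguous sets.

    All four frames are variants x samples; the variant index must agree.
    The three output sets are disjoint and their union is the input.
    """
    panel.validate(list(tumour_alt.columns))
    normal_alt = normal_alt[panel.normal_ids]
    normal_dp = normal_dp[panel.normal_ids]
    in_normal = _presence(normal_alt, normal_dp, min_alt_reads, min_depth)

    matched_hits = 0
    if panel.host_links:
        matched_cols = sorted(set(panel.host_links.values()))
        matched_hits = int(in_normal[matched_cols].any(axis=1).sum())
    germline_mask = in_normal.any(axis=1)

    ambiguous_mask = pd.Series(False, index=tumour_alt.index)
    if clone_shared_ambiguous:
        in_tumour = _presence(tumour_alt, tumour_dp, min_alt_reads, min_depth)
        ambiguous_mask = in_tumour.all(axis=1) & ~germline_mask

    somatic_mask = ~germline_mask & ~ambiguous_mask
    return GermlineClassification(
        somatic=tumour_alt.index[somatic_mask],
        germline=tumour_alt.index[germline_mask],
        ambiguous=tumour_alt.index[ambiguous_mask],
        matched_host_hits=matched_hits,
    )


@dataclass
class HeterozygosityReport:
    per_sample: pd.Series  # heterozygous sites per kb
    median: float
    range: tuple[float, float]


def heterozygosity_per_kb(
    het_site_counts: dict[str, int] | pd.Series, callable_genome: int
) -> HeterozygosityReport:
    """Heterozygous sites per kilobase per sample, with cohort median/range."""
    if callable_genome <= 0:
        raise ValueError("callable_genome must be > 0")
    counts = pd.Series(het_site_counts, dtype=float)
    rates = counts * 1000.0 / callable_genome
    if len(rates) == 0:
        return HeterozygosityReport(rates, float("nan"), (float("nan"), float("nan")))
    return HeterozygosityReport(
        rates, float(rates.median()), (float(rates.min()), float(rates.max()))
    )


@dataclass
class PurityEstimate:
    purity: float | None
    n_variants: int
    flagged: bool

    def __float__(self) -> float:
        if self.purity is None:
            raise ValueError("purity undefined (underpowered sample)")
        return self.purity


def estimate_purity(
    vafs: np.ndarray | pd.Series,
    diploid_mask: np.ndarray | None = None,
    min_variants: int = 50,
) -> PurityEstimate:
    """Purity = min(1, 2 x median VAF) over clonal variants in diploid
    copy-neutral regions; flagged (purity None) when underpowered."""
    v = np.asarray(vafs, dtype=float)
    if diploid_mask is not None:
        v = v[np.asarray(diploid_mask, dtype=bool)]
    v = v[~np.isnan(v)]
    if len(v) < min_variants:
        return PurityEstimate(None, len(v), True)
    return PurityEstimate(float(min(1.0, 2.0 * np.median(v))), len(v), False)
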