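"""Bulk-sequencing read-count emulation.

Per-variant total depth is Poisson(depth_mean) and alt reads are
Binomial(depth, expected VAF) with

    VAF = purity x multiplicity x cell_fraction
          / (purity x tumour_copies + 2 x (1 - purity)),

the standard purity/copy-number model for a bulk tumour.  Germline
heterozygous sites are emitted at VAF 0.5 irrespective of purity, since host
and tumour cells share the germline genotype.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["expected_vaf", "make_bulk_sample"]


def expected_vaf(
    purity: float,
    multiplicity: np.ndarray | float = 1.0,
    cell_fraction: np.ndarray | float = 1.0,
    tumour_cn: np.ndarray | float = 2.0,
) -> np.ndarray | float:
    return purity * np.asarray(multiplicity) * np.asarray(cell_fraction) / (
        purity * np.asarray(tumour_cn) + 2.0 * (1.0 - purity)
    )


def make_bulk_sample(
    variants: pd.DataFrame,
    purity: float,
    depth_mean: float,
    subclone_mix: tuple[float, ...] | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Emulate bulk allele counts for one tumour.

    ``variants`` may carry optional columns ``cell_fraction`` (default 1),
    ``multiplicity`` (default 1), ``tumour_cn`` (default 2), ``is_germline``
    (default False) and, when ``subclone_mix`` is given, a ``component``
    column (0 = clonal, 1..k = subclone-private) mapped onto the mixture
    fractions.  Returns a copy with ``depth`` and ``alt_reads`` columns.
    """
    if depth_mean <= 0:
        raise ValueError("depth_mean must be > 0")
    if not (0 < purity <= 1):
        raise ValueError("purity must be in (0, 1]")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    out = variants.copy()
    n = len(out)
    cf = out["cell_fraction"].to_numpy(float) if "cell_fraction" in out else np.ones(n)
    if subclone_mix is not None:
        if abs(sum(subclone_mix) - 1.0) > 1e-6:
            raise ValueError("subclone fractions must sum to 1")
        comp = out["component"].to_numpy(int)
        fracs = np.concatenate([[1.0], np.asarray(subclone_mix, float)])
        cf = fracs[comp]
    mult = out["multiplicity"].to_numpy(float) if "multiplicity" in out else np.ones(n)
    cn = out["tumour_cn"].to_numpy(float) if "tumour_cn" in out else np.full(n, 2.0)
    vaf = np.asarray(expected_vaf(purity, mult, cf, cn), dtype=float)
    if "is_germline" in out:
        vaf = np.where(out["is_germline"].to_numpy(bool), 0.5, vaf)
    vaf = np.clip(vaf, 0.0, 1.0)
    depth = rng.poisson(depth_mean, size=n)
    alt = rng.binomial(depth, vaf)
    out["depth"] = depth
    out["alt_reads"] = alt
    return out
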