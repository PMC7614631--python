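"""Germline population model.

Polymorphic sites carry population allele frequencies drawn Uniform(0.1,
0.5); genotypes follow Hardy-Weinberg proportions with a mild per-sample
heterozygosity factor (lognormal, median 1) that spreads per-sample rates
around the configured median, emulating population structure without
modelling it.  The number of sites is chosen so the median per-sample
heterozygosity matches the configured rate per kilobase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from devilclones.simcohort.genome import SyntheticGenome

__all__ = ["GermlinePopulation"]

_F_LO, _F_HI = 0.1, 0.5
# E[2f(1-f)] for f ~ Uniform(0.1, 0.5)
_MEAN_HET = 2 * ((_F_HI**2 - _F_LO**2) / 2 - (_F_HI**3 - _F_LO**3) / 3) / (_F_HI - _F_LO)
_ALT = {"A": "G", "C": "T", "G": "A", "T": "C"}  # transitions, for determinism


@dataclass
class GermlinePopulation:
    sites: pd.DataFrame  # chrom, pos (1-based), ref, alt, freq
    genotypes: np.ndarray  # (n_samples, n_sites) in {0,1,2}
    sample_ids: list[str]
    founder: np.ndarray  # founder devil genotype vector

    @classmethod
    def generate(
        cls,
        genome: SyntheticGenome,
        het_rate_per_kb: float,
        n_normals: int,
        rng: np.random.Generator,
        sample_spread: float = 0.12,
    ) -> "GermlinePopulation":
        total_bp = genome.total_bp
        n_sites = max(1, int(round(het_rate_per_kb / 1000.0 * total_bp / _MEAN_HET)))
        chroms = genome.chromosomes
        lens = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
        probs = lens / lens.sum()
        seen: set[tuple[int, int]] = set()
        rows = []
        while len(rows) < n_sites:
            ci = int(rng.choice(len(chroms), p=probs))
            pos = int(rng.integers(2, genome.chrom_lengths[chroms[ci]] - 1))
            if (ci, pos) in seen:
                continue
            seen.add((ci, pos))
            ref = genome.base(chroms[ci], pos)
            rows.append((chroms[ci], pos, ref, _ALT[ref], float(rng.uniform(_F_LO, _F_HI))))
        sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "freq"])
        f = sites["freq"].to_numpy()
        factors = np.exp(rng.normal(0.0, sample_spread, size=n_normals + 1))
        genos = np.zeros((n_normals + 1, len(sites)), dtype=np.int8)
        for i, m in enumerate(factors):
            p_het = np.clip(2 * f * (1 - f) * m, 0, 0.75)
            p_hom = f**2
            u = rng.random(len(sites))
            genos[i] = np.where(u < p_hom, 2, np.where(u < p_hom + p_het, 1, 0))
        sample_ids = [f"N{i:03d}" for i in range(n_normals)]
        return cls(sites, genos[1:], sample_ids, genos[0])

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def het_count(self, sample_index: int) -> int:
        return int((self.genotypes[sample_index] == 1).sum())

    def founder_het_sites(self) -> pd.DataFrame:
        """Sites at which the clone founder was heterozygous."""
        return self.sites[self.founder == 1].reset_index(drop=True)
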