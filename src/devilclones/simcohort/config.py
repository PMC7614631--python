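"""Cohort configuration.

Default per-class clock rates are the published DFT1/DFT2 regression rates
(mutations per genome per year); the callable genome defaults to
2,983,750,195 bp, scaled down by ``genome_scale`` (default 1/300, ~10 Mb) so
cohorts simulate in seconds while all rates stay interpretable genome-wide.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

__all__ = ["CohortConfig", "dft1_config", "dft2_config", "CALLABLE_GENOME_BP"]

CALLABLE_GENOME_BP = 2_983_750_195

MUTATION_CLASSES = [
    "substitution",
    "indel",
    "line1_insertion",
    "rearrangement_event",
    "cnv_event",
]


@dataclass
class HypermutatorSpec:
    """A branch from which substitution/indel rates are multiplied and an
    extra signature (mismatch-repair style) contributes the excess."""

    branch: int
    substitution_multiplier: float = 6.0
    indel_multiplier: float = 10.0
    extra_sbs_signature: str = "SBS6"
    extra_id_signature: str = "ID7"


@dataclass
class SubcloneSpec:
    """One tumour is produced as a mixture of its own lineage and a partner
    lineage's cells at the given fractions (fractions sum to 1)."""

    tumour: str
    fractions: tuple[float, ...] = (0.6, 0.4)
    partner: str | None = None  # default: phylogenetic sister tip


@dataclass
class CohortConfig:
    clone_label: str = "DFT1"
    origin_year: float = 1986.0
    n_tumours: int = 63
    sampling_window: tuple[float, float] = (2003.0, 2018.0)
    rates: dict[str, float] = field(
        default_factory=lambda: {
            "substitution": 163.2,
            "indel": 22.2,
            "line1_insertion": 0.0,
            "rearrangement_event": 1.1,
            "cnv_event": 0.7,
        }
    )
    signature_mix: dict[str, float] = field(
        default_factory=lambda: {"SBS1": 0.08, "SBS5": 0.92}
    )
    indel_signature_mix: dict[str, float] = field(
        default_factory=lambda: {"ID1": 0.66, "ID2": 0.34}
    )
    depth_mean: float = 83.0
    purity_range: tuple[float, float] = (0.75, 1.0)
    callable_genome: int = CALLABLE_GENOME_BP
    genome_scale: float = 1.0 / 300.0
    heterozygosity_per_kb: float = 0.132
    n_normals: int = 20
    birth_rate: float = 1.5  # transmission (lineage splitting) rate per year
    multifurcation_prob: float = 0.0
    founder_sex: str = "female"
    n_genes: int = 40
    n_l1_elements: int | None = None  # default: 1948 scaled by genome_scale
    l1_transduction_prob: float = 0.5
    hypermutator_spec: HypermutatorSpec | None = None
    wgd_specs: list[tuple[int, float]] = field(default_factory=list)
    loy_specs: list[int] = field(default_factory=list)
    subclone_spec: SubcloneSpec | None = None
    l1_source_spec: list[tuple[str, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_tumours < 2:
            raise ValueError("n_tumours must be >= 2")
        lo, hi = self.sampling_window
        if lo <= self.origin_year:
            raise ValueError(
                f"sampling window {self.sampling_window} must lie strictly "
                f"after the origin year {self.origin_year}"
            )
        if hi < lo:
            raise ValueError("sampling window must be ordered")
        for cls, rate in self.rates.items():
            if rate < 0:
                raise ValueError(f"rate for {cls} must be >= 0")
        for mix, fam in (
            (self.signature_mix, "substitution"),
            (self.indel_signature_mix, "indel"),
        ):
            if mix and abs(sum(mix.values()) - 1.0) > 1e-6:
                raise ValueError(f"{fam} signature weights must sum to 1")
        if self.subclone_spec is not None:
            if abs(sum(self.subclone_spec.fractions) - 1.0) > 1e-6:
                raise ValueError("subclone fractions must sum to 1")
        p_lo, p_hi = self.purity_range
        if not (0 <= p_lo <= p_hi <= 1):
            raise ValueError("purity_range must be within [0, 1]")

    @property
    def scaled_genome_bp(self) -> int:
        return int(round(self.callable_genome * self.genome_scale))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


def dft1_config(**overrides) -> CohortConfig:
    """DFT1-like defaults: origin 1986, 63 tumours sampled 2003-2018,
    published DFT1 regression rates and signature proportions."""
    base = dict(
        clone_label="DFT1",
        origin_year=1986.0,
        n_tumours=63,
        sampling_window=(2003.0, 2018.0),
        rates={
            "substitution": 163.2,
            "indel": 22.2,
            "line1_insertion": 0.0,
            "rearrangement_event": 1.1,
            "cnv_event": 0.7,
        },
        signature_mix={"SBS1": 0.08, "SBS5": 0.92},
        indel_signature_mix={"ID1": 0.66, "ID2": 0.34},
        founder_sex="female",
    )
    base.update(overrides)
    return CohortConfig(**base)


def dft2_config(**overrides) -> CohortConfig:
    """DFT2-like defaults: origin 2011, 41 tumours sampled 2014-2018,
    published DFT2 regression rates; male founder (carries chromosome Y)."""
    base = dict(
        clone_label="DFT2",
        origin_year=2011.0,
        n_tumours=41,
        sampling_window=(2014.0, 2018.0),
        rates={
            "substitution": 496.3,
            "indel": 86.5,
            "line1_insertion": 24.1,
            "rearrangement_event": 3.6,
            "cnv_event": 5.6,
        },
        signature_mix={"SBS1": 0.034, "SBS5": 0.966},
        indel_signature_mix={"ID1": 0.47, "ID2": 0.53},
        founder_sex="male",
    )
    base.update(overrides)
    return CohortConfig(**base)
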