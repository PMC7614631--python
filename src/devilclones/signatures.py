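"""Mutational spectra and signature fitting.

Substitutions are classified on the 96-channel scheme: six pyrimidine-strand
base changes (C>A, C>G, C>T, T>A, T>C, T>G) by 16 flanking-base contexts.
Substitutions whose reference base is a purine are reverse-complemented onto
the pyrimidine strand before classification.

Indels use a reduced 24-channel scheme: (insertion | deletion) x inserted or
deleted base (A, C, G, T) x homopolymer run-length bin (1, 2-4, >=5).  In this
scheme ID1 is a 1-bp T/A insertion at runs >=5 and ID2 the matching deletion;
this is sufficient to express the ID1/ID2/ID7 contrasts the analyses need
without the full COSMIC ID83 classification.

The packaged reference profiles (``devilclones/data/*.synthetic.tsv``) are
stylized synthetic stand-ins for the COSMIC signatures they are named after:
SBS1 concentrates on C>T at CpG, SBS5 is flat with a mild T>C excess, SBS6
is a C>T-rich mismatch-repair-deficiency profile, and ID1/ID2/ID7 follow the
channel definitions above.  Exposure fitting is non-negative least squares on
channel proportions with a sparsity refit pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "SBS_CHANNELS",
    "ID_CHANNELS",
    "sbs_channel",
    "indel_channel",
    "ReferenceSignatures",
    "Spectrum",
    "build_spectrum",
    "fit_signatures",
    "fit_exposure_table",
]

SUB_CLASSES = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
BASES = "ACGT"
SBS_CHANNELS: list[str] = [
    f"{f}[{s}]{t}" for s in SUB_CLASSES for f in BASES for t in BASES
]
ID_OPS = ["ins", "del"]
ID_RUN_BINS = ["1", "2-4", "5+"]
ID_CHANNELS: list[str] = [
    f"{op}_{b}_{r}" for op in ID_OPS for b in BASES for r in ID_RUN_BINS
]

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def sbs_channel(ref: str, alt: str, triplet: str) -> str:
    """96-channel label for a substitution given its reference triplet.

    ``triplet`` is the reference 5'-3' trinucleotide centred on the mutated
    base.  Purine references are reverse-complemented to the pyrimidine
    strand, the field's standard convention.
    """
    if triplet[1] != ref:
        raise ValueError(f"triplet {triplet} does not centre on ref {ref}")
    if ref in "AG":
        triplet = _revcomp(triplet)
        ref, alt = _revcomp(ref), _revcomp(alt)
    return f"{triplet[0]}[{ref}>{alt}]{triplet[2]}"


def run_bin(run_length: int) -> str:
    if run_length >= 5:
        return "5+"
    if run_length >= 2:
        return "2-4"
    return "1"


def indel_channel(op: str, base: str, run_length: int) -> str:
    """Reduced 24-channel label for a 1-bp indel at a homopolymer run."""
    if op not in ID_OPS:
        raise ValueError(f"op must be one of {ID_OPS}")
    return f"{op}_{base}_{run_bin(run_length)}"


@dataclass
class ReferenceSignatures:
    """Signature id -> channel probability vectors (each summing to 1)."""

    matrix: pd.DataFrame  # channels x signatures

    @classmethod
    def load_sbs(cls) -> "ReferenceSignatures":
        return cls._load("signatures_sbs96.synthetic.tsv", SBS_CHANNELS)

    @classmethod
    def load_indel(cls) -> "ReferenceSignatures":
        return cls._load("signatures_id24.synthetic.tsv", ID_CHANNELS)

    @classmethod
    def _load(cls, name: str, channels: list[str]) -> "ReferenceSignatures":
        with resources.files("devilclones.data").joinpath(name).open() as fh:
            mat = pd.read_csv(fh, sep="\t", index_col=0)
        mat = mat.loc[channels]
        if not np.allclose(mat.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError(f"signature columns in {name} must sum to 1")
        return cls(mat)

    @property
    def names(self) -> list[str]:
        return list(self.matrix.columns)

    def subset(self, names: list[str]) -> "ReferenceSignatures":
        return ReferenceSignatures(self.matrix[list(names)])

    def mixture(self, weights: dict[str, float]) -> np.ndarray:
        """Channel probabilities of a weighted signature mixture."""
        w = pd.Series(weights, dtype=float)
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")
        return (self.matrix[w.index].to_numpy() @ w.to_numpy()).ravel()


@dataclass
class Spectrum:
    """Observed counts per mutation channel for one sample or cohort."""

    counts: pd.Series  # indexed by channel

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def proportions(self) -> pd.Series:
        tot = self.counts.sum()
        return self.counts / tot if tot else self.counts.astype(float)


def build_spectrum(variants: pd.DataFrame, genome=None) -> tuple[Spectrum, Spectrum]:
    """Build substitution (96) and indel (24) spectra from a variant table.

    Channels are recomputed from the reference ``genome`` when given
    (columns required: chrom, pos [1-based], ref, alt, var_class); otherwise
    the table's precomputed ``context`` column is used.
    """
    sbs = pd.Series(0, index=SBS_CHANNELS, dtype=int)
    ind = pd.Series(0, index=ID_CHANNELS, dtype=int)
    for row in variants.itertuples(index=False):
        if row.var_class == "substitution":
            if genome is not None:
                trip = genome.triplet(row.chrom, int(row.pos))
                ch = sbs_channel(row.ref, row.alt, trip)
            else:
                ch = row.context
            sbs[ch] += 1
        elif row.var_class == "indel":
            if genome is not None:
                ins = len(row.alt) > len(row.ref)
                base = (row.alt[-1] if ins else row.ref[-1])
                run = genome.homopolymer_run(row.chrom, int(row.pos) + 1)
                # an insertion extends the run it joins; count the existing run
                ch = indel_channel("ins" if ins else "del", base, run)
            else:
                ch = row.context
            ind[ch] += 1
    return Spectrum(sbs), Spectrum(ind)


@dataclass
class ExposureFit:
    """NNLS signature exposures for one spectrum, in mutation counts."""

    exposures: pd.Series
    residual_norm: float
    identifiable: bool = True

    def proportions(self) -> pd.Series:
        tot = self.exposures.sum()
        return self.exposures / tot if tot else self.exposures


def fit_signatures(
    spectrum: Spectrum,
    refs: ReferenceSignatures,
    sparsity_threshold: float = 0.01,
) -> ExposureFit:
    """Decompose a spectrum into reference-signature exposures by NNLS.

    Exposures are fitted on channel proportions, rescaled to mutation counts,
    and signatures contributing less than ``sparsity_threshold`` of the burden
    are zeroed and the remainder refitted.
    """
    if refs.matrix.shape[1] < 1:
        raise ValueError("need at least one reference signature")
    a = refs.matrix.to_numpy()
    corr = np.corrcoef(a.T)
    identifiable = True
    if a.shape[1] > 1 and np.any(np.triu(corr, 1) > 0.999):
        warnings.warn("near-identical reference signatures: exposures non-identifiable")
        identifiable = False
    total = float(spectrum.counts.sum())
    if total == 0:
        zeros = pd.Series(0.0, index=refs.names)
        return ExposureFit(zeros, 0.0, identifiable)
    b = spectrum.proportions().to_numpy()
    x, rnorm = nnls(a, b)
    # sparsity pass: drop trace exposures and refit the survivors
    keep = x >= sparsity_threshold
    if keep.any() and not keep.all():
        x2 = np.zeros_like(x)
        x2[keep], rnorm = nnls(a[:, keep], b)
        x = x2
    exposures = pd.Series(x * total, index=refs.names)
    return ExposureFit(exposures, float(rnorm * total), identifiable)


def fit_exposure_table(
    spectra: dict[str, Spectrum], refs: ReferenceSignatures
) -> pd.DataFrame:
    """Per-sample exposure table (samples x signatures, plus residual)."""
    rows = {}
    for sample, spec in spectra.items():
        fit = fit_signatures(spec, refs)
        rows[sample] = fit.exposures.to_dict() | {"residual": fit.residual_norm}
    return pd.DataFrame.from_dict(rows, orient="index")
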