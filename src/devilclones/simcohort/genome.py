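"""Synthetic reference genome: sequence, gene models and LINE-1 annotation.

The genome mimics a chromosome-level marsupial assembly at desk scale: six
autosome-equivalents plus X and Y whose lengths sum to the scaled callable
genome, random sequence, non-overlapping single-interval CDS gene models
(lengths divisible by 3) and full-length LINE-1 source-element coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SyntheticGenome"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_DECODE = np.array(list("ACGT"))

# fractional chromosome sizes (autosomes 1-6, X, Y)
_CHROM_FRACTIONS = {
    "chr1": 0.24,
    "chr2": 0.19,
    "chr3": 0.16,
    "chr4": 0.14,
    "chr5": 0.12,
    "chr6": 0.08,
    "chrX": 0.06,
    "chrY": 0.01,
}


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


@dataclass
class SyntheticGenome:
    chrom_lengths: dict[str, int]
    seq: dict[str, np.ndarray]  # uint8 base codes per chromosome
    genes: pd.DataFrame  # gene_id, chrom, start, end, strand (0-based half-open)
    l1_elements: pd.DataFrame  # element_id, chrom, start, end, strand
    _ctx_index: dict | None = field(default=None, repr=False)
    _run_index: dict | None = field(default=None, repr=False)

    # ------------------------------------------------------------- creation
    @classmethod
    def generate(
        cls,
        total_bp: int,
        n_genes: int = 40,
        n_l1: int = 7,
        seed: int | np.random.Generator = 0,
    ) -> "SyntheticGenome":
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        lengths = {
            c: max(2000, int(round(f * total_bp))) for c, f in _CHROM_FRACTIONS.items()
        }
        seq = {c: cls._markov_sequence(n, rng) for c, n in lengths.items()}
        genes = cls._place_genes(lengths, n_genes, rng)
        l1 = cls._place_l1(lengths, n_l1, rng)
        return cls(lengths, seq, genes, l1)

    @staticmethod
    def _markov_sequence(
        n: int, rng: np.random.Generator, persistence: float = 0.35
    ) -> np.ndarray:
        """First-order Markov sequence with same-base persistence.

        Mammalian genomes are rich in homopolymer tracts; an i.i.d. sequence
        badly underrepresents the runs that host slippage indels.  Runs have
        geometric lengths (mean 1/(1-persistence)) and successive run bases
        are uniform over the other three bases, keeping composition uniform.
        """
        mean_run = 1.0 / (1.0 - persistence)
        n_runs = int(n / mean_run * 1.1) + 16
        lens = rng.geometric(1.0 - persistence, size=n_runs)
        steps = rng.integers(1, 4, size=n_runs)  # never repeat the last base
        bases = (np.cumsum(steps) + rng.integers(0, 4)) % 4
        seq = np.repeat(bases.astype(np.uint8), lens)
        while len(seq) < n:
            extra = rng.integers(0, 4, size=n - len(seq), dtype=np.uint8)
            seq = np.concatenate([seq, extra])
        return seq[:n]

    @staticmethod
    def _place_genes(lengths: dict[str, int], n_genes: int, rng) -> pd.DataFrame:
        autosomes = [c for c in lengths if c not in ("chrX", "chrY")]
        rows = []
        per_chrom = int(np.ceil(n_genes / len(autosomes)))
        gid = 0
        for chrom in autosomes:
            clen = lengths[chrom]
            slot = clen // (per_chrom + 1)
            for i in range(per_chrom):
                if gid >= n_genes:
                    break
                cds_len = 3 * int(rng.integers(100, 501))  # 300-1500 bp
                start = (i + 1) * slot - cds_len // 2
                start = int(np.clip(start, 1, clen - cds_len - 1))
                strand = "+" if rng.random() < 0.5 else "-"
                rows.append((f"GENE{gid:04d}", chrom, start, start + cds_len, strand))
                gid += 1
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])

    @staticmethod
    def _place_l1(lengths: dict[str, int], n_l1: int, rng) -> pd.DataFrame:
        # full-length elements ~6 kb, placed on autosomes away from edges
        autosomes = [c for c in lengths if c not in ("chrX", "chrY")]
        rows = []
        for i in range(n_l1):
            chrom = autosomes[i % len(autosomes)]
            clen = lengths[chrom]
            elem_len = 6000 if clen > 40000 else max(200, clen // 20)
            # deterministic spacing with jitter keeps elements non-overlapping
            slot = clen // (n_l1 // len(autosomes) + 2)
            start = (i // len(autosomes) + 1) * slot + int(rng.integers(0, slot // 4 + 1))
            start = int(np.clip(start, 1000, clen - elem_len - 20000))
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"L1_{i:03d}", chrom, start, start + elem_len, strand))
        return pd.DataFrame(
            rows, columns=["element_id", "chrom", "start", "end", "strand"]
        )

    # -------------------------------------------------------------- queries
    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def total_bp(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    def base(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        self._check(chrom, pos)
        return str(_DECODE[self.seq[chrom][pos - 1]])

    def triplet(self, chrom: str, pos: int) -> str:
        """Reference 5'-3' trinucleotide centred on a 1-based position."""
        self._check(chrom, pos)
        if pos < 2 or pos > self.chrom_lengths[chrom] - 1:
            raise ValueError(f"position {chrom}:{pos} too close to chromosome end")
        codes = self.seq[chrom][pos - 2 : pos + 1]
        return "".join(_DECODE[codes])

    def seq_str(self, chrom: str, start: int, end: int) -> str:
        """Sequence of the 0-based half-open interval [start, end)."""
        return "".join(_DECODE[self.seq[chrom][start:end]])

    def homopolymer_run(self, chrom: str, pos: int) -> int:
        """Length of the maximal homopolymer run containing the 1-based
        position."""
        self._check(chrom, pos)
        s = self.seq[chrom]
        i = pos - 1
        b = s[i]
        left = i
        while left > 0 and s[left - 1] == b:
            left -= 1
        right = i
        n = len(s)
        while right < n - 1 and s[right + 1] == b:
            right += 1
        return right - left + 1

    def cds_sequence(self, gene: pd.Series) -> str:
        key = (gene.gene_id, gene.start, gene.end, gene.strand)
        cache = self.__dict__.setdefault("_cds_cache", {})
        if key not in cache:
            codes = self.seq[gene.chrom][gene.start : gene.end]
            if gene.strand == "-":
                codes = _revcomp_codes(codes)
            cache[key] = "".join(_DECODE[codes])
        return cache[key]

    def _check(self, chrom: str, pos: int) -> None:
        if chrom not in self.chrom_lengths:
            raise KeyError(f"unknown chromosome {chrom}")
        if not (1 <= pos <= self.chrom_lengths[chrom]):
            raise IndexError(f"position {chrom}:{pos} outside reference")

    # ----------------------------------------------- mutation-site indexing
    def context_site_index(self) -> dict[str, np.ndarray]:
        """Positions indexed by pyrimidine-strand trinucleotide context.

        Returns a mapping 3-mer (centre C or T on the pyrimidine strand) ->
        array of encoded global sites.  Purine-centred positions are indexed
        under their reverse-complement context.
        """
        if self._ctx_index is None:
            index: dict[str, list] = {}
            for ci, chrom in enumerate(self.chromosomes):
                s = self.seq[chrom].astype(np.int64)
                if len(s) < 3:
                    continue
                f, m, t = s[:-2], s[1:-1], s[2:]
                pyr = (m == 1) | (m == 3)
                cf = np.where(pyr, f, 3 - t)
                cm = np.where(pyr, m, 3 - m)
                ct = np.where(pyr, t, 3 - f)
                code = cf * 4 + ct + np.where(cm == 3, 16, 0)
                pos1 = np.arange(2, len(s))  # 1-based centre positions
                for k in range(32):
                    mask = code == k
                    if mask.any():
                        ctx = _DECODE[k % 16 // 4] + ("T" if k >= 16 else "C") + _DECODE[k % 4]
                        index.setdefault(ctx, []).append(
                            (np.int64(ci) << 34) + pos1[mask]
                        )
            self._ctx_index = {
                k: np.concatenate(v) for k, v in index.items()
            }
        return self._ctx_index

    def run_site_index(self) -> dict[tuple[str, str], np.ndarray]:
        """Positions indexed by (run base, run-length bin) for indel placement.

        Each homopolymer run contributes its first position only, so an indel
        channel draw picks a distinct run.
        """
        if self._run_index is None:
            from devilclones.signatures import run_bin

            index: dict[tuple[str, str], list] = {}
            for ci, chrom in enumerate(self.chromosomes):
                s = self.seq[chrom]
                if len(s) < 3:
                    continue
                change = np.flatnonzero(np.diff(s)) + 1
                starts = np.concatenate([[0], change])
                ends = np.concatenate([change, [len(s)]])
                run_len = ends - starts
                run_base = s[starts]
                # skip runs at chromosome edges
                ok = (starts > 0) & (ends < len(s))
                for b in range(4):
                    for rb, (lo, hi) in (("1", (1, 2)), ("2-4", (2, 5)), ("5+", (5, 10**9))):
                        mask = ok & (run_base == b) & (run_len >= lo) & (run_len < hi)
                        if mask.any():
                            key = (str(_DECODE[b]), rb)
                            index.setdefault(key, []).append(
                                (np.int64(ci) << 34) + starts[mask] + 1
                            )
            self._run_index = {k: np.concatenate(v) for k, v in index.items()}
        return self._run_index

    def decode_site(self, gpos: int) -> tuple[str, int]:
        """Decode an encoded global site into (chrom, 1-based position)."""
        return self.chromosomes[int(gpos) >> 34], int(gpos) & ((1 << 34) - 1)
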