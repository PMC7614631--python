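"""Cohort serialization: FASTA, GFF3, per-sample VCF 4.2, metadata TSV,
newick truth tree and JSON truth table.  VCF output is plain text with
FORMAT AD,DP and INFO CLASS/CTX; files written here are readable by pysam
(symbolic LINE-1 insertion alleles included)."""

from __future__ import annotations

import os

import pandas as pd

from devilclones.simcohort.cohort import Cohort

__all__ = ["write_cohort", "read_vcf_variants"]

_FASTA_WIDTH = 80


def write_fasta(cohort: Cohort, path: str) -> None:
    with open(path, "w") as fh:
        for chrom in cohort.genome.chromosomes:
            fh.write(f">{chrom}\n")
            seq = cohort.genome.seq_str(chrom, 0, cohort.genome.chrom_lengths[chrom])
            for i in range(0, len(seq), _FASTA_WIDTH):
                fh.write(seq[i : i + _FASTA_WIDTH] + "\n")


def write_gff3(cohort: Cohort, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in cohort.genome.genes.itertuples(index=False):
            attrs = f"ID={g.gene_id};biotype=protein_coding"
            fh.write(
                f"{g.chrom}\tsimcohort\tCDS\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t0\t{attrs}\n"
            )
        for e in cohort.genome.l1_elements.itertuples(index=False):
            attrs = f"ID={e.element_id};repeat_family=LINE-1;full_length=true"
            fh.write(
                f"{e.chrom}\tsimcohort\tmobile_genetic_element\t{e.start + 1}\t{e.end}\t.\t{e.strand}\t.\t{attrs}\n"
            )


def _vcf_header(cohort: Cohort, sample: str) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=devilclones-simcohort"]
    for chrom in cohort.genome.chromosomes:
        lines.append(f"##contig=<ID={chrom},length={cohort.genome.chrom_lengths[chrom]}>")
    lines += [
        '##ALT=<ID=INS:L1,Description="LINE-1 insertion">',
        '##INFO=<ID=CLASS,Number=1,Type=String,Description="Mutation class">',
        '##INFO=<ID=CTX,Number=1,Type=String,Description="Trinucleotide or indel channel">',
        '##INFO=<ID=AMBIG,Number=0,Type=Flag,Description="Clone-shared, somatic/germline-ambiguous">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}",
    ]
    return "\n".join(lines) + "\n"


def write_sample_vcf(cohort: Cohort, sample: str, path: str) -> None:
    counts = cohort.allele_counts[sample]
    order = {c: i for i, c in enumerate(cohort.genome.chromosomes)}
    counts = counts.sort_values(["chrom", "pos"], key=lambda s: s.map(order) if s.name == "chrom" else s)
    with open(path, "w") as fh:
        fh.write(_vcf_header(cohort, sample))
        for row in counts.itertuples(index=False):
            alt = row.alt if row.alt != "<INS:L1>" else "<INS:L1>"
            cls = "germline" if row.is_germline else row.var_class
            info = f"CLASS={cls}"
            if getattr(row, "context", ""):
                info += f";CTX={row.context}"
            ref_reads = int(row.depth) - int(row.alt_reads)
            fh.write(
                f"{row.chrom}\t{row.pos}\t{'.' if row.vid < 0 else 'v' + str(row.vid)}\t"
                f"{row.ref}\t{alt}\t.\tPASS\t{info}\tAD:DP\t"
                f"{ref_reads},{int(row.alt_reads)}:{int(row.depth)}\n"
            )


def read_vcf_variants(path: str) -> pd.DataFrame:
    """Read a VCF written by this package back into a variant table."""
    import pysam

    rows = []
    with pysam.VariantFile(path) as vf:
        sample = list(vf.header.samples)[0]
        for rec in vf:
            ad = rec.samples[sample]["AD"]
            rows.append(
                (rec.chrom, rec.pos, rec.ref, rec.alts[0],
                 rec.info.get("CLASS", ""), rec.info.get("CTX", ""),
                 int(ad[1]), int(rec.samples[sample]["DP"]))
            )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "var_class", "context",
                       "alt_reads", "depth"]
    )


def write_cohort(cohort: Cohort, outdir: str) -> None:
    """Write the full external representation of a simulated cohort."""
    os.makedirs(outdir, exist_ok=True)
    write_fasta(cohort, os.path.join(outdir, "reference.fa"))
    write_gff3(cohort, os.path.join(outdir, "annotation.gff3"))
    cohort.metadata.to_csv(os.path.join(outdir, "metadata.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "truth_tree.nwk"), "w") as fh:
        fh.write(cohort.tree.newick(branch_units="years") + "\n")
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        fh.write(cohort.truth.to_json())
    vcf_dir = os.path.join(outdir, "vcf")
    os.makedirs(vcf_dir, exist_ok=True)
    for sample in cohort.samples:
        write_sample_vcf(cohort, sample, os.path.join(vcf_dir, f"{sample}.vcf"))
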