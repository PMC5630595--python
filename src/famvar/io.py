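"""Readers and writers for the pipeline's file formats.

Variant tables travel as a minimal protein-space VCF (CHROM = protein id,
POS = 1-based residue index, REF/ALT = amino-acid letters or the class
markers ``*`` / ``fs``, consequence in INFO/CSQ, diploid GT per sample) or
as an equivalent wide TSV. Family alignments are aligned FASTA in the
profile convention: match columns uppercase, deletions ``-``, insertion
residues lowercase; headers carry the domain bounds as ``>protein/start-end``.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from famvar.containers import (
    CONSEQUENCES,
    DomainInstance,
    FamilyAlignment,
    VariantRecord,
    VariantTable,
)


class ParseError(ValueError):
    """Raised for malformed input rows; carries file and line context."""


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

def write_vcf(table: VariantTable, path: str | Path) -> None:
    path = Path(path)
    proteins = sorted({v.protein for v in table.variants})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CSQ,Number=1,Type=String,'
                 'Description="Consequence class">\n')
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        for p in proteins:
            fh.write(f"##contig=<ID={p}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
                "INFO", "FORMAT"] + table.individuals
        fh.write("\t".join(cols) + "\n")
        gt_strings = np.array(["0|0", "0|1", "1|1"])
        for v in table.variants:
            gts = gt_strings[v.allele_counts]
            row = [v.protein, str(v.position), ".", v.ref_residue,
                   v.alt_residue, ".", ".",
                   f"CSQ={v.consequence};GENE={v.protein}", "GT", *gts]
            fh.write("\t".join(row) + "\n")


def read_vcf(path: str | Path) -> VariantTable:
    path = Path(path)
    with pysam.VariantFile(str(path)) as vf:
        individuals = list(vf.header.samples)
        variants: list[VariantRecord] = []
        for rec in vf:
            csq = rec.info.get("CSQ")
            if csq not in CONSEQUENCES:
                raise ParseError(
                    f"{path}:{rec.chrom}:{rec.pos}: unknown consequence {csq!r}"
                )
            counts = np.zeros(len(individuals), dtype=np.int8)
            for j, sample in enumerate(rec.samples.values()):
                gt = sample["GT"]
                if gt is None or len(gt) != 2 or None in gt:
                    raise ParseError(
                        f"{path}:{rec.chrom}:{rec.pos}: sample "
                        f"{individuals[j]} has non-diploid GT {gt!r}"
                    )
                counts[j] = sum(gt)
            variants.append(
                VariantRecord(rec.chrom, rec.pos, rec.ref, rec.alts[0],
                              str(csq), counts)
            )
    return VariantTable(variants, individuals)


_TSV_FIXED = ["protein", "position", "ref", "alt", "consequence"]


def write_variants_tsv(table: VariantTable, path: str | Path) -> None:
    df = table.to_dataframe(genotypes=True)
    df.to_csv(path, sep="\t", index=False)


def read_variants_tsv(path: str | Path) -> VariantTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"protein": str})
    missing = [c for c in _TSV_FIXED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    individuals = [c for c in df.columns if c not in _TSV_FIXED]
    variants = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        if row["consequence"] not in CONSEQUENCES:
            raise ParseError(
                f"{path}:{line}: unknown consequence {row['consequence']!r}"
            )
        counts = row[individuals].to_numpy(dtype=np.int64)
        if counts.size and (counts.min() < 0 or counts.max() > 2):
            raise ParseError(f"{path}:{line}: allele counts outside {{0,1,2}}")
        variants.append(
            VariantRecord(row["protein"], int(row["position"]), row["ref"],
                          row["alt"], row["consequence"],
                          counts.astype(np.int8))
        )
    return VariantTable(variants, individuals)


def read_variants(path: str | Path, format: str = "vcf") -> VariantTable:
    """Dispatch on ``format`` in {"vcf", "tsv"}."""
    if format == "vcf":
        return read_vcf(path)
    if format == "tsv":
        return read_variants_tsv(path)
    raise ValueError(f"unknown variant format {format!r}")


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def _aligned_row(inst: DomainInstance, sequence: str, model_length: int) -> str:
    row: list[str] = []
    expected = 1
    for pos in range(inst.start, inst.end + 1):
        col = inst.column_map.get(pos)
        if col is None:
            row.append(sequence[pos - 1].lower())
        else:
            while expected < col:
                row.append("-")
                expected += 1
            row.append(sequence[pos - 1].upper())
            expected = col + 1
    while expected <= model_length:
        row.append("-")
        expected += 1
    return "".join(row)


def write_alignment_fasta(fa: FamilyAlignment, sequences: dict[str, str],
                          path: str | Path) -> None:
    with open(path, "w") as fh:
        for inst in fa.members:
            row = _aligned_row(inst, sequences[inst.protein], fa.model_length)
            fh.write(f">{inst.protein}/{inst.start}-{inst.end}\n{row}\n")


_HEADER_RE = re.compile(r"^(?P<protein>.+)/(?P<start>\d+)-(?P<end>\d+)$")


def _parse_aligned_row(name: str, row: str, family: str) -> DomainInstance:
    m = _HEADER_RE.match(name)
    if not m:
        raise ParseError(f"alignment header {name!r} is not protein/start-end")
    start = int(m.group("start"))
    pos, col = start, 0
    column_map: dict[int, int] = {}
    for ch in row:
        if ch in "-.":
            col += 1
        elif ch.islower():
            pos += 1
        else:
            col += 1
            column_map[pos] = col
            pos += 1
    return DomainInstance(family, m.group("protein"), start,
                          int(m.group("end")), column_map)


def read_alignment_fasta(path: str | Path, family: str) -> FamilyAlignment:
    """Aligned FASTA in profile convention back to a FamilyAlignment."""
    from Bio import SeqIO

    members = []
    model_length = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        row = str(rec.seq)
        n_cols = sum(1 for ch in row if ch in "-." or ch.isupper())
        model_length = max(model_length, n_cols)
        members.append(_parse_aligned_row(rec.id, row, family))
    return FamilyAlignment(family, model_length, members)


def read_alignment_stockholm(path: str | Path, family: str) -> FamilyAlignment:
    from Bio import AlignIO

    aln = AlignIO.read(str(path), "stockholm")
    members = []
    model_length = 0
    for rec in aln:
        row = str(rec.seq)
        n_cols = sum(1 for ch in row if ch in "-." or ch.isupper())
        model_length = max(model_length, n_cols)
        members.append(_parse_aligned_row(rec.id, row, family))
    return FamilyAlignment(family, model_length, members)


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# cohort and screen tables
# ---------------------------------------------------------------------------

def write_cohort_tsv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"individual": str})


def write_screen_tsv(screen: pd.DataFrame, path: str | Path) -> None:
    screen.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_screen_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
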