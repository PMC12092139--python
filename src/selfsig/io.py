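"""Readers and writers for the pipeline's text dialects.

Formats:

* SSR genotype CSV — header ``sample,population,species,<locus>_a,<locus>_b,...``
  with integer allele sizes; 0 or empty codes a missing allele copy.
* SNP long TSV — ``sample  species  population  snp_id  locus_id
  pos_in_locus  gt`` with gt in {0,1,2} or '.' for missing; positions are
  1-based (VCF convention).
* minimal VCF — biallelic records, GT subfield only; CHROM is the locus
  group, POS the within-locus order; phased '|' and unphased '/' separators
  are equivalent.  Species/population labels come from an optional sample
  table.
* variant TSV — ``sample  species  transcript_id  transcript_len_bp  snv_id
  effect  score`` with empty fields for transcript rows without SNVs.
* Newick trees via dendropy.

All writers emit stable column order and fixed float formatting so output
is deterministic.
"""

from __future__ import annotations

import csv
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .popgen_ssr import SSRGenotypeTable
from .snp_pipeline import SNPMatrix
from .snv_metrics import COLUMNS as VARIANT_COLUMNS
from .snv_metrics import VariantTable

__all__ = [
    "ParseError",
    "read_ssr_csv",
    "write_ssr_csv",
    "read_snp_tsv",
    "write_snp_tsv",
    "read_snp_vcf",
    "write_snp_vcf",
    "read_variant_tsv",
    "write_variant_tsv",
    "read_newick",
    "write_newick",
]


class ParseError(ValueError):
    """Malformed input; carries the 1-based line number where found."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        where = f" (line {line})" if line is not None else ""
        super().__init__(f"{message}{where}")


# ---------------------------------------------------------------- SSR CSV


def _parse_allele(tok: str, line: int) -> int:
    tok = tok.strip()
    if tok == "":
        return 0
    try:
        v = int(tok)
    except ValueError:
        raise ParseError(f"allele size is not an integer: {tok!r}", line) from None
    if v < 0:
        raise ParseError(f"negative allele size: {v}", line)
    return v


def read_ssr_csv(path: str | Path) -> SSRGenotypeTable:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty file", 1) from None
        if header[:3] != ["sample", "population", "species"]:
            raise ParseError(
                "header must start with 'sample,population,species'", 1
            )
        allele_cols = header[3:]
        if len(allele_cols) % 2 != 0:
            raise ParseError("odd number of allele columns", 1)
        loci = []
        for i in range(0, len(allele_cols), 2):
            a, b = allele_cols[i], allele_cols[i + 1]
            if not (a.endswith("_a") and b.endswith("_b") and a[:-2] == b[:-2]):
                raise ParseError(f"allele columns must pair as <locus>_a,<locus>_b; got {a},{b}", 1)
            loci.append(a[:-2])
        samples, pops, spps, rows = [], [], [], []
        for ln, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"expected {len(header)} fields, got {len(row)}", ln
                )
            samples.append(row[0])
            pops.append(row[1])
            spps.append(row[2])
            rows.append([_parse_allele(t, ln) for t in row[3:]])
        if len(set(samples)) != len(samples):
            dup = sorted({s for s in samples if samples.count(s) > 1})
            raise ParseError(f"duplicate sample ids: {dup}")
        alleles = np.array(rows, dtype=np.int64).reshape(len(samples), len(loci), 2)
        return SSRGenotypeTable(
            samples=samples,
            population=np.array(pops, dtype=object),
            species=np.array(spps, dtype=object),
            loci=loci,
            alleles=alleles,
        )


def write_ssr_csv(table: SSRGenotypeTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        cols = ["sample", "population", "species"]
        for loc in table.loci:
            cols += [f"{loc}_a", f"{loc}_b"]
        w.writerow(cols)
        for i, s in enumerate(table.samples):
            row = [s, table.population[i], table.species[i]]
            row += [int(x) for x in table.alleles[i].reshape(-1)]
            w.writerow(row)


# ---------------------------------------------------------------- SNP TSV

_SNP_COLS = ["sample", "species", "population", "snp_id", "locus_id", "pos_in_locus", "gt"]


def _parse_gt_code(tok: str, line: int) -> int:
    tok = tok.strip()
    if tok in (".", "", "-1"):
        return -1
    if tok in ("0", "1", "2"):
        return int(tok)
    raise ParseError(f"genotype code must be 0/1/2 or '.', got {tok!r}", line)


def read_snp_tsv(path: str | Path) -> SNPMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _SNP_COLS:
            raise ParseError(f"header must be {_SNP_COLS}", 1)
        records = []
        for ln, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != len(_SNP_COLS):
                raise ParseError(f"expected {len(_SNP_COLS)} fields, got {len(parts)}", ln)
            try:
                pos = int(parts[5])
            except ValueError:
                raise ParseError(f"pos_in_locus not an integer: {parts[5]!r}", ln) from None
            records.append(
                (parts[0], parts[1], parts[2], parts[3], parts[4], pos,
                 _parse_gt_code(parts[6], ln))
            )
    if not records:
        raise ParseError("no data rows")
    df = pd.DataFrame(records, columns=_SNP_COLS)
    samples = list(pd.unique(df["sample"]))
    snp_meta = df.drop_duplicates("snp_id")[["snp_id", "locus_id", "pos_in_locus"]]
    snp_ids = list(snp_meta["snp_id"])
    gt = df.pivot_table(
        index="sample", columns="snp_id", values="gt", aggfunc="first", fill_value=-1
    ).reindex(index=samples, columns=snp_ids)
    sample_meta = df.drop_duplicates("sample").set_index("sample")
    return SNPMatrix(
        samples=samples,
        species=sample_meta.loc[samples, "species"].to_numpy(dtype=object),
        population=sample_meta.loc[samples, "population"].to_numpy(dtype=object),
        snp_ids=snp_ids,
        locus_ids=snp_meta["locus_id"].to_numpy(dtype=object),
        pos_in_locus=snp_meta["pos_in_locus"].to_numpy(),
        genotypes=gt.to_numpy(dtype=np.int8, na_value=-1),
    )


def write_snp_tsv(m: SNPMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_SNP_COLS) + "\n")
        for i, s in enumerate(m.samples):
            for j, snp in enumerate(m.snp_ids):
                gt = int(m.genotypes[i, j])
                fh.write(
                    "\t".join(
                        [s, str(m.species[i]), str(m.population[i]), snp,
                         str(m.locus_ids[j]), str(int(m.pos_in_locus[j])),
                         "." if gt == -1 else str(gt)]
                    )
                    + "\n"
                )


# ------------------------------------------------------------ minimal VCF


def read_snp_vcf(
    path: str | Path, sample_info: pd.DataFrame | None = None
) -> tuple[SNPMatrix, int]:
    """Read a minimal VCF into an SNPMatrix.

    Only biallelic SNP records are accepted; multiallelic records are
    skipped and counted (the count is returned alongside the matrix).
    CHROM becomes the locus group and POS the within-locus order.
    ``sample_info``, if given, is indexed by sample with ``species`` and
    ``population`` columns; otherwise both labels default to 'unknown'.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, locus_ids, pos, rows = [], [], [], []
    n_multiallelic = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multiallelic += 1
            continue
        gts = rec.genotype.array()
        codes = np.full(len(samples), -1, dtype=np.int8)
        alleles = gts[:, :2]
        called = ~(alleles < 0).any(axis=1)
        codes[called] = alleles[called].sum(axis=1)
        snp_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        locus_ids.append(rec.CHROM)
        pos.append(rec.POS)
        rows.append(codes)
    if not rows:
        raise ParseError("no biallelic records in VCF")
    g = np.stack(rows, axis=1)
    if sample_info is not None:
        species = sample_info.loc[samples, "species"].to_numpy(dtype=object)
        population = sample_info.loc[samples, "population"].to_numpy(dtype=object)
    else:
        species = np.array(["unknown"] * len(samples), dtype=object)
        population = species.copy()
    return (
        SNPMatrix(
            samples=samples,
            species=species,
            population=population,
            snp_ids=snp_ids,
            locus_ids=np.array(locus_ids, dtype=object),
            pos_in_locus=np.array(pos),
            genotypes=g,
        ),
        n_multiallelic,
    )


def write_snp_vcf(m: SNPMatrix, path: str | Path) -> None:
    """Write a minimal GT-only VCF (REF/ALT are placeholder A/T)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for loc in pd.unique(pd.Series(m.locus_ids)):
            fh.write(f"##contig=<ID={loc}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(m.samples)
            + "\n"
        )
        gt_str = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
        for j, snp in enumerate(m.snp_ids):
            fields = [
                str(m.locus_ids[j]), str(int(m.pos_in_locus[j])), snp,
                "A", "T", ".", "PASS", ".", "GT",
            ]
            fields += [gt_str[int(m.genotypes[i, j])] for i in range(m.n_samples)]
            fh.write("\t".join(fields) + "\n")


# ------------------------------------------------------------ variant TSV


def read_variant_tsv(path: str | Path) -> VariantTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != VARIANT_COLUMNS:
            raise ParseError(f"header must be {VARIANT_COLUMNS}", 1)
        rows = []
        for ln, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != len(VARIANT_COLUMNS):
                raise ParseError(
                    f"expected {len(VARIANT_COLUMNS)} fields, got {len(parts)}", ln
                )
            sample, species, tid, length, snv_id, effect, score = parts
            try:
                length_bp = int(length)
            except ValueError:
                raise ParseError(f"transcript_len_bp not an integer: {length!r}", ln) from None
            if effect not in ("", "synonymous", "nonsynonymous"):
                raise ParseError(f"unknown effect class {effect!r}", ln)
            if score:
                try:
                    score_val = float(score)
                except ValueError:
                    raise ParseError(f"score not a number: {score!r}", ln) from None
            else:
                score_val = np.nan
            rows.append(
                (sample, species, tid, length_bp,
                 snv_id or None, effect or None, score_val)
            )
    if not rows:
        raise ParseError("no data rows")
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    return VariantTable(df)


def write_variant_tsv(v: VariantTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(VARIANT_COLUMNS) + "\n")
        for _, r in v.df.iterrows():
            score = "" if pd.isna(r["score"]) else f"{r['score']:.6g}"
            fh.write(
                "\t".join(
                    [str(r["sample"]), str(r["species"]), str(r["transcript_id"]),
                     str(int(r["transcript_len_bp"])),
                     "" if pd.isna(r["snv_id"]) or r["snv_id"] is None else str(r["snv_id"]),
                     "" if pd.isna(r["effect"]) or r["effect"] is None else str(r["effect"]),
                     score]
                )
                + "\n"
            )


# ----------------------------------------------------------------- trees


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_newick(tree, path: str | Path) -> None:
    """Write a dendropy Tree or an :class:`~selfsig.trees.UnrootedTree`."""
    with open(path, "w") as fh:
        if isinstance(tree, dendropy.Tree):
            fh.write(tree.as_string(schema="newick"))
        else:
            fh.write(tree.newick() + "\n")
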