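"""Readers and writers for the plain-text formats the pipeline consumes."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_table_tsv",
    "write_table_tsv",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_gmt",
    "write_gmt",
    "write_vcf",
    "read_vcf_dosages",
    "write_json",
    "read_json",
]


def read_expression_tsv(path) -> pd.DataFrame:
    """Probesets x samples matrix; first column holds probeset ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    return df


def write_expression_tsv(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="probeset_id")


def read_table_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path) -> pd.DataFrame:
    """SNPs x samples dosage matrix; NA marks missing calls."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    return df.astype(float)


def write_dosage_tsv(geno: pd.DataFrame, path) -> None:
    geno.to_csv(path, sep="\t", index_label="snp_id", na_rep="NA")


def read_gmt(path) -> dict:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(gene_sets: dict, path) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, name] + sorted(genes)) + "\n")


def write_vcf(geno: pd.DataFrame, snp_annot: pd.DataFrame, path) -> None:
    """Plain-text VCF 4.2 with GT calls; the minor allele is ALT."""
    annot = snp_annot.set_index("snp_id").loc[geno.index]
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.columns)
            + "\n"
        )
        for snp in geno.index:
            row = annot.loc[snp]
            calls = [gt_map.get(v, "./.") for v in geno.loc[snp]]
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{snp}\t{row.get('ref', 'A')}\t"
                f"{row.get('alt', 'G')}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_vcf_dosages(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse GT calls from a plain-text VCF into (dosages, SNP annotation)."""
    samples, rows, meta = None, [], []
    for line in Path(path).read_text().splitlines():
        if line.startswith("##") or not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if line.startswith("#CHROM"):
            samples = fields[9:]
            continue
        chrom, pos, snp_id, ref, alt = fields[:5]
        fmt = fields[8].split(":")
        gt_i = fmt.index("GT")
        doses = []
        for call in fields[9:]:
            gt = call.split(":")[gt_i].replace("|", "/")
            if "." in gt:
                doses.append(np.nan)
            else:
                doses.append(float(sum(int(a) for a in gt.split("/"))))
        rows.append(doses)
        meta.append((snp_id, chrom, int(pos), ref, alt))
    annot = pd.DataFrame(meta, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    geno = pd.DataFrame(rows, index=annot["snp_id"].to_list(), columns=samples)
    return geno, annot


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (pd.Series,)):
            return o.to_dict()
        raise TypeError(f"cannot serialize {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default))


def read_json(path):
    return json.loads(Path(path).read_text())
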