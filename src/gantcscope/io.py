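"""Readers and writers for the on-disk formats.

FASTA goes through Biopython, GFF3 reading through gffutils (in-memory
sqlite db). Kinetics tables are TSV with header
``contig  position0  strand  ipd_ratio  coverage`` (0-based forward
coordinates, strand +/-); a converter from PacBio modifications.csv-style
1-based ``tpl``/numeric-strand tables is provided. All numeric TSV output
is written with 6 significant digits so repeated runs diff byte-identically.
"""

from __future__ import annotations

import os

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import GenomeRecord, make_feature_table

FLOAT_FORMAT = "%.6g"

KINETICS_HEADER = ["contig", "position0", "strand", "ipd_ratio", "coverage"]

# GFF3 feature type <-> internal feature class
_TYPE_TO_CLASS = {
    "CDS": "protein_coding",
    "gene": "protein_coding",
    "mRNA": "protein_coding",
    "rRNA": "rna",
    "tRNA": "rna",
    "ncRNA": "rna",
    "tmRNA": "rna",
}
_CLASS_TO_TYPE = {"protein_coding": "CDS", "rna": "rRNA", "other": "region"}


def read_fasta(path, circular: bool = True) -> GenomeRecord:
    """First record of a FASTA file as a GenomeRecord."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return GenomeRecord(record.id, str(record.seq).upper(), circular=circular)


def write_fasta(genome: GenomeRecord, path) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.contig_id, description="")
    SeqIO.write([rec], str(path), "fasta")


def read_gff3(path) -> pd.DataFrame:
    """Feature table from GFF3 (1-based inclusive -> 0-based half-open)."""
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.all_features():
        kind = _TYPE_TO_CLASS.get(feat.featuretype, "other")
        fid = feat.attributes.get("ID", [feat.id])[0]
        rows.append(
            {
                "feature_id": fid,
                "contig": feat.seqid,
                "start": feat.start - 1,
                "end": feat.end,
                "strand": feat.strand if feat.strand in "+-" else "+",
                "kind": kind,
            }
        )
    return make_feature_table(rows)


def write_gff3(features: pd.DataFrame, path, contig_lengths: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if contig_lengths:
            for contig, length in contig_lengths.items():
                fh.write(f"##sequence-region {contig} 1 {length}\n")
        for row in features.itertuples(index=False):
            ftype = _CLASS_TO_TYPE.get(row.kind, "region")
            fh.write(
                "\t".join(
                    [
                        row.contig, "gantcscope", ftype,
                        str(row.start + 1), str(row.end), ".", row.strand, ".",
                        f"ID={row.feature_id}",
                    ]
                )
                + "\n"
            )


def read_kinetics(path) -> pd.DataFrame:
    """Kinetics TSV -> internal observation table (position, 0-based)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in KINETICS_HEADER if c not in df.columns]
    if missing:
        raise ValueError(
            f"malformed kinetics file {os.fspath(path)!r}: missing column(s) {missing}"
        )
    out = df.rename(columns={"position0": "position"})
    bad = set(out["strand"].unique()) - {"+", "-"}
    if bad:
        raise ValueError(
            f"malformed kinetics file {os.fspath(path)!r}: bad strand values {sorted(bad)!r}"
        )
    return out[["contig", "position", "strand", "ipd_ratio", "coverage"]]


def write_kinetics(obs: pd.DataFrame, path) -> None:
    out = obs.rename(columns={"position": "position0"})[KINETICS_HEADER]
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def convert_pacbio_kinetics(df: pd.DataFrame, contig: str | None = None) -> pd.DataFrame:
    """PacBio modifications-style table -> internal observation table.

    Expects 1-based ``tpl`` positions and numeric ``strand`` (0 = forward,
    1 = reverse) plus ``ipdRatio`` and ``coverage`` columns, as written by
    the standard base-modification pipeline.
    """
    required = {"tpl", "strand", "ipdRatio", "coverage"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"PacBio kinetics table missing columns: {sorted(missing)}")
    out = pd.DataFrame(
        {
            "contig": df["refName"] if "refName" in df.columns else contig,
            "position": df["tpl"].astype(int) - 1,
            "strand": np.where(df["strand"].astype(int) == 0, "+", "-"),
            "ipd_ratio": df["ipdRatio"].astype(float),
            "coverage": df["coverage"].astype(int),
        }
    )
    if out["contig"].isna().any():
        raise ValueError("no refName column; pass contig= explicitly")
    return out


def read_expression_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_gene_stats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log_ratio", "p_adj"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene stats table missing columns: {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_catalog(path) -> dict[str, set]:
    """Gene-set catalog TSV (`set_name<TAB>gene_id`) -> dict of sets."""
    df = pd.read_csv(path, sep="\t")
    if not {"set_name", "gene_id"} <= set(df.columns):
        raise ValueError("catalog must have columns set_name and gene_id")
    return {name: set(sub["gene_id"]) for name, sub in df.groupby("set_name")}


def write_catalog(catalog: dict[str, set], path) -> None:
    rows = [
        {"set_name": name, "gene_id": gid}
        for name in sorted(catalog)
        for gid in sorted(catalog[name])
    ]
    pd.DataFrame(rows, columns=["set_name", "gene_id"]).to_csv(path, sep="\t", index=False)


def read_panel(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0).astype(bool)


def read_config(path) -> dict:
    """Flat key = value config file; '#' starts a comment."""
    config = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{os.fspath(path)}:{lineno}: expected key = value")
            key, value = (part.strip() for part in line.split("=", 1))
            config[key] = value
    return config


def write_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        for key in config:
            fh.write(f"{key} = {config[key]}\n")
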