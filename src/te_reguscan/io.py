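"""Readers and writers for the plain-text interchange formats.

All genomic coordinates are 0-based half-open (BED native); no other
coordinate dialect is used anywhere in the package.

Canonical in-memory containers are :class:`pandas.DataFrame` objects with
fixed column names:

* TE annotation (BED6+4): ``chrom, start, end, family, te_class, age_class,
  copy_id, fragment_index, strand``
* peaks (BED4): ``chrom, start, end, name``
* pcHiC links (7-column BEDPE): ``chromA, startA, endA, chromB, startB,
  endB, gene``
* expression matrix: genes x taxa TSV, index column ``gene``
* DE table: ``gene, log2FC, pvalue, padj``
* reporter plates CSV: ``construct, cell_type, treatment, replicate,
  firefly, renilla``
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

TE_COLUMNS = [
    "chrom",
    "start",
    "end",
    "family",
    "te_class",
    "age_class",
    "copy_id",
    "fragment_index",
    "strand",
]
PEAK_COLUMNS = ["chrom", "start", "end", "name"]
LINK_COLUMNS = ["chromA", "startA", "endA", "chromB", "startB", "endB", "gene"]
PLATE_COLUMNS = ["construct", "cell_type", "treatment", "replicate", "firefly", "renilla"]


def _read_table(path, names=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", header=None, names=names)


def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED4/BED6+ into a peak DataFrame (extra columns kept).

    Lines starting with ``#`` are skipped. A missing name column is filled
    with ``peak_<i>``.
    """
    df = _read_table(path)
    ncol = df.shape[1]
    if ncol < 3:
        raise ValueError(f"{path}: BED needs >=3 columns, got {ncol}")
    names = PEAK_COLUMNS[: min(ncol, 4)]
    extra = [f"col{i}" for i in range(len(names), ncol)]
    df.columns = names + extra
    if "name" not in df.columns:
        df["name"] = [f"peak_{i}" for i in range(len(df))]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed(df: pd.DataFrame, path, columns=None) -> None:
    cols = columns or [c for c in PEAK_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def read_te_bed(path) -> pd.DataFrame:
    """Read the BED6+4 TE annotation written by :func:`write_te_bed`."""
    df = _read_table(path)
    if df.shape[1] != 10:
        raise ValueError(f"{path}: TE BED6+4 needs 10 columns, got {df.shape[1]}")
    df.columns = [
        "chrom", "start", "end", "family", "score", "strand",
        "te_class", "age_class", "copy_id", "fragment_index",
    ]
    out = df[TE_COLUMNS].copy()
    out["start"] = out["start"].astype(int)
    out["end"] = out["end"].astype(int)
    return out


def write_te_bed(tes: pd.DataFrame, path) -> None:
    """Write TEs as BED6+4: name=family, score=copy_id, then class/age/copy/fragment."""
    out = pd.DataFrame(
        {
            "chrom": tes["chrom"],
            "start": tes["start"],
            "end": tes["end"],
            "name": tes["family"],
            "score": tes["copy_id"],
            "strand": tes.get("strand", "."),
            "te_class": tes["te_class"],
            "age_class": tes["age_class"],
            "copy_id": tes["copy_id"],
            "fragment_index": tes["fragment_index"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(path) -> pd.DataFrame:
    df = _read_table(path, names=LINK_COLUMNS)
    for c in ("startA", "endA", "startB", "endB"):
        df[c] = df[c].astype(int)
    return df


def write_bedpe(links: pd.DataFrame, path) -> None:
    links.to_csv(path, sep="\t", header=False, index=False, columns=LINK_COLUMNS)


def read_expression_matrix(path) -> pd.DataFrame:
    """Gene x taxon TPM matrix; first column is the gene id."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_matrix(tpm: pd.DataFrame, path) -> None:
    tpm.to_csv(path, sep="\t", index_label="gene")


def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"gene", "log2FC"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: DE table missing columns {sorted(missing)}")
    return df


def write_de_table(de: pd.DataFrame, path) -> None:
    de.to_csv(path, sep="\t", index=False)


def read_plates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: plate CSV missing columns {sorted(missing)}")
    return df


def write_plates(wells: pd.DataFrame, path) -> None:
    wells.to_csv(path, index=False, columns=PLATE_COLUMNS)


def read_chrom_sizes(path) -> dict:
    df = _read_table(path, names=["chrom", "length"])
    return dict(zip(df["chrom"], df["length"].astype(int)))


def write_chrom_sizes(sizes: dict, path) -> None:
    pd.DataFrame(sizes.items(), columns=["chrom", "length"]).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_gmt(path) -> dict:
    """GMT pathway file: name, description, then tab-separated gene ids."""
    pathways = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line with <3 fields: {line[:80]!r}")
        pathways[parts[0]] = set(parts[2:])
    return pathways


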