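"""Readers and writers for the concrete on-disk formats the tool touches.

Formats: phASER ``phaser_gene_ae`` per-sample TSVs (or a combined long table
with a ``sample`` column); GTEx-style wide gene x sample matrices with
``a|b`` cells; newline-delimited gene lists and GTF/GFF3 gene records for
the FDR gene universe; the V^G reference TSV this tool both writes and
consumes; and outlier-test result TSVs.  Writers emit deterministic column
order and LF line endings with a row-count checksum header; readers validate
strictly and name the offending column/cell/line on error.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GeneUniverse, HaplotypeCountMatrix

__all__ = [
    "read_phaser_gene_ae",
    "read_wide_matrix",
    "write_wide_matrix",
    "read_gene_universe",
    "read_vg_table",
    "write_vg_table",
]

PHASER_REQUIRED = ["name", "contig", "start", "stop", "aCount", "bCount"]
_CHECKSUM_RE = re.compile(r"^#\s*nrows=(\d+)\s*$")


def _strip(ids: pd.Index | pd.Series) -> pd.Index | pd.Series:
    return ids.str.replace(r"\.\d+$", "", regex=True)


def read_phaser_gene_ae(paths, sample_ids=None, strip_versions: bool = False) -> HaplotypeCountMatrix:
    """Read phaser_gene_ae-style TSVs into a count matrix.

    ``paths`` is one file per sample (sample ids default to file stems) or a
    single combined long table containing a ``sample`` column.  Required
    columns: name, contig, start, stop, aCount, bCount.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    paths = [Path(p) for p in paths]
    frames = []
    for i, path in enumerate(paths):
        df = pd.read_csv(path, sep="\t", comment="#")
        missing = [c for c in PHASER_REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns: {missing}")
        if (df["aCount"] < 0).any() or (df["bCount"] < 0).any():
            raise ValueError(f"{path}: negative haplotype counts")
        if "sample" not in df.columns:
            sid = sample_ids[i] if sample_ids else path.stem
            df = df.assign(sample=sid)
        frames.append(df[["name", "sample", "aCount", "bCount"]])
    long = pd.concat(frames, ignore_index=True)
    dup = long.duplicated(["name", "sample"])
    if dup.any():
        first = long.loc[dup, ["name", "sample"]].iloc[0]
        raise ValueError(f"duplicate (gene, sample) record: {tuple(first)}")
    a = long.pivot(index="name", columns="sample", values="aCount")
    b = long.pivot(index="name", columns="sample", values="bCount")
    a.index.name = b.index.name = "gene_id"
    a.columns.name = b.columns.name = "sample_id"
    if strip_versions:
        a.index = _strip(a.index)
        b.index = _strip(b.index)
    return HaplotypeCountMatrix(a.astype(float), b.astype(float))


def write_wide_matrix(matrix: HaplotypeCountMatrix, path) -> None:
    """Write a gene x sample matrix with ``a|b`` cells (empty = missing)."""
    a, b = matrix.a, matrix.b
    cells = np.where(
        np.isnan(a.to_numpy()),
        "",
        np.char.add(
            np.char.add(np.nan_to_num(a.to_numpy()).astype(int).astype(str), "|"),
            np.nan_to_num(b.to_numpy()).astype(int).astype(str),
        ),
    )
    out = pd.DataFrame(cells, index=a.index, columns=a.columns)
    with open(path, "w", newline="\n") as fh:
        fh.write(f"# nrows={out.shape[0]}\n")
        out.to_csv(fh, sep="\t", index_label="gene_id", lineterminator="\n")


def read_wide_matrix(path, strip_versions: bool = False) -> HaplotypeCountMatrix:
    """Read a wide ``a|b`` matrix written by :func:`write_wide_matrix` (or a
    foreign file without the checksum header)."""
    path = Path(path)
    expected = None
    with open(path) as fh:
        first = fh.readline()
    if (m := _CHECKSUM_RE.match(first.strip())) is not None:
        expected = int(m.group(1))
    raw = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str, keep_default_na=False)
    if expected is not None and raw.shape[0] != expected:
        raise ValueError(f"{path}: expected {expected} rows per header checksum, found {raw.shape[0]}")
    a = np.full(raw.shape, np.nan)
    b = np.full(raw.shape, np.nan)
    values = raw.to_numpy()
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = values[i, j].strip()
            if not cell:
                continue
            parts = cell.split("|")
            if len(parts) != 2 or not parts[0].strip().isdigit() or not parts[1].strip().isdigit():
                raise ValueError(
                    f"{path}: malformed cell {cell!r} at gene {raw.index[i]!r}, sample {raw.columns[j]!r}"
                )
            a[i, j] = int(parts[0])
            b[i, j] = int(parts[1])
    index = pd.Index(raw.index, name="gene_id")
    if strip_versions:
        index = _strip(index)
    cols = pd.Index(raw.columns, name="sample_id")
    return HaplotypeCountMatrix(
        pd.DataFrame(a, index=index, columns=cols), pd.DataFrame(b, index=index, columns=cols)
    )


_GTF_GENE_ID_RE = re.compile(r'gene_id "([^"]+)"')
_GTF_GENE_TYPE_RE = re.compile(r'gene_(?:type|biotype) "([^"]+)"')


def read_gene_universe(path, biotypes: set | None = None, strip_versions: bool = False) -> GeneUniverse:
    """Read an FDR gene universe from a newline-delimited gene list or a
    GTF/GFF3 annotation (gene records only, filtered to ``biotypes``)."""
    path = Path(path)
    text = path.read_text()
    is_gtf = any(
        line and not line.startswith("#") and len(line.split("\t")) >= 9
        for line in text.splitlines()[:50]
    )
    ids: list[str] = []
    bio: dict[str, str] = {}
    if is_gtf:
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}: unparseable annotation line {lineno}")
            if fields[2] != "gene":
                continue
            gid_m = _GTF_GENE_ID_RE.search(fields[8])
            if gid_m is None:
                raise ValueError(f"{path}: line {lineno}: gene record without gene_id")
            gid = gid_m.group(1)
            type_m = _GTF_GENE_TYPE_RE.search(fields[8])
            gtype = type_m.group(1) if type_m else ""
            if biotypes is not None and gtype not in biotypes:
                continue
            ids.append(gid)
            bio[gid] = gtype
    else:
        ids = [line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")]
    if strip_versions:
        ids = [re.sub(r"\.\d+$", "", g) for g in ids]
        bio = {re.sub(r"\.\d+$", "", g): t for g, t in bio.items()}
    return GeneUniverse(gene_ids=set(ids), biotypes=bio)


VG_COLUMNS = ["gene_id", "sd_g", "vg", "ci_low", "ci_high", "n_used", "converged"]


def write_vg_table(estimates: pd.DataFrame, path) -> None:
    """Write the V^G reference interchange TSV (deterministic column order)."""
    cols = [c for c in VG_COLUMNS if c in estimates.columns]
    with open(path, "w", newline="\n") as fh:
        fh.write(f"# nrows={len(estimates)}\n")
        estimates[cols].to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_vg_table(path, vg_convention: str = "sd") -> pd.DataFrame:
    """Read a V^G reference table.

    ``vg_convention`` names the scale of the stored dispersion column for
    legacy two-column (gene, Vg) tables: ``sd`` (the native convention — the
    SD of the latent log allelic fold change), ``variance`` (sd_g^2), or
    ``half_variance`` (sd_g^2 / 2).  The returned frame always carries the
    native ``sd_g`` column.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    df = pd.read_csv(path, sep="\t", comment="#")
    if (m := _CHECKSUM_RE.match(first.strip())) is not None and len(df) != int(m.group(1)):
        raise ValueError(f"{path}: expected {m.group(1)} rows per header checksum, found {len(df)}")
    if "sd_g" not in df.columns:
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected at least (gene, Vg) columns")
        df = df.rename(columns={df.columns[0]: "gene_id", df.columns[1]: "raw_vg"})
        if vg_convention == "sd":
            df["sd_g"] = df["raw_vg"].astype(float)
        elif vg_convention == "variance":
            df["sd_g"] = np.sqrt(df["raw_vg"].astype(float))
        elif vg_convention == "half_variance":
            df["sd_g"] = np.sqrt(2.0 * df["raw_vg"].astype(float))
        else:
            raise ValueError(f"unknown vg convention {vg_convention!r}")
    return df
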