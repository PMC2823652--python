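"""Readers and writers for the tab-delimited formats the pipeline touches.

PCL (Stanford Microarray Database dialect)
    Header row ``ID  NAME  GWEIGHT  <sample ids...>``, optional EWEIGHT
    row, one row per probe.  Values are log2(sample/reference) ratios
    stored as-is; empty cells are missing.  GWEIGHT/EWEIGHT are written
    for compatibility but ignored numerically.  NAME packs
    ``gene_symbol|unigene_id`` (the bar and unigene part optional).
    Sample annotations (cell type, treatment, pair id) travel in an
    optional companion TSV since PCL has no room for them.

CDT/GTR/ATR (Eisen clustering ecosystem)
    ``write_cdt_gtr`` emits the matrix reordered by the dendrogram leaf
    orders plus the gene (.gtr) and array (.atr) node files, readable by
    standard TreeView implementations.

Clinical tables, signature lists and term->gene maps are plain TSVs with
documented headers (see README).
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    AnnotationSet,
    ClinicalTable,
    Dendrogram,
    ExpressionMatrix,
    GeneSignature,
    ValidationError,
)

logger = logging.getLogger(__name__)

_SAMPLES_SUFFIX = ".samples.tsv"


# ----------------------------------------------------------------- PCL
def read_pcl(path: str | Path, samples_path: str | Path | None = None) -> ExpressionMatrix:
    """Read a PCL expression matrix.

    If ``samples_path`` is omitted, a companion ``<stem>.samples.tsv``
    next to the PCL is used when present; otherwise sample annotations
    default to blank/``n/a``.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise ValidationError(f"{path}: empty PCL file")
    header = rows[0]
    if len(header) < 4 or header[0].upper() not in ("ID", "YORF", "UID", "CLID"):
        raise ValidationError(
            f"{path}: PCL header must start with ID, NAME, GWEIGHT then sample ids"
        )
    sample_ids = header[3:]
    body = rows[1:]
    if body and body[0] and body[0][0].upper() == "EWEIGHT":
        body = body[1:]

    probe_ids: list[str] = []
    symbols: list[str] = []
    unigenes: list[str] = []
    values = np.full((len(body), len(sample_ids)), np.nan)
    for i, row in enumerate(body):
        if not row or not any(cell.strip() for cell in row):
            raise ValidationError(f"{path}: blank data row {i + 2}")
        row = row + [""] * (3 + len(sample_ids) - len(row))
        probe_ids.append(row[0].strip())
        name = row[1].strip()
        sym, _, uni = name.partition("|")
        symbols.append(sym.strip().upper())
        unigenes.append(uni.strip())
        for j, cell in enumerate(row[3 : 3 + len(sample_ids)]):
            cell = cell.strip()
            if cell == "":
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValidationError(
                    f"{path}: non-numeric cell at row {i + 2}, column {sample_ids[j]}: {cell!r}"
                ) from None

    dupes = pd.Series(probe_ids)
    dupes = sorted(dupes[dupes.duplicated()].unique())
    if dupes:
        raise ValidationError(f"{path}: duplicate probe ids: {', '.join(dupes)}")

    samples = _read_samples_table(path, samples_path, sample_ids)
    features = pd.DataFrame(
        {"probe_id": probe_ids, "gene_symbol": symbols, "unigene_id": unigenes}
    )
    return ExpressionMatrix(values, features, samples)


def _read_samples_table(
    pcl_path: Path, samples_path: str | Path | None, sample_ids: list[str]
) -> pd.DataFrame:
    if samples_path is None:
        candidate = pcl_path.with_suffix(_SAMPLES_SUFFIX)
        samples_path = candidate if candidate.exists() else None
    if samples_path is None:
        return pd.DataFrame({"sample_id": sample_ids})
    # keep_default_na: the treatment label "n/a" is literal, not missing
    tab = pd.read_csv(
        samples_path, sep="\t", dtype=str, keep_default_na=False
    ).fillna("")
    if "sample_id" not in tab.columns:
        raise ValidationError(f"{samples_path}: missing column 'sample_id'")
    tab = tab.set_index("sample_id", drop=False)
    missing = [s for s in sample_ids if s not in tab.index]
    if missing:
        raise ValidationError(
            f"{samples_path}: no annotation for samples {missing}"
        )
    return tab.loc[sample_ids].reset_index(drop=True)


def write_pcl(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write PCL plus the ``<stem>.samples.tsv`` companion annotation."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["ID", "NAME", "GWEIGHT"] + matrix.sample_ids)
        w.writerow(["EWEIGHT", "", ""] + ["1"] * matrix.n_samples)
        for i in range(matrix.n_genes):
            feat = matrix.features.iloc[i]
            name = feat["gene_symbol"]
            if feat["unigene_id"]:
                name = f"{name}|{feat['unigene_id']}"
            cells = [
                "" if np.isnan(v) else repr(float(v)) for v in matrix.values[i]
            ]
            w.writerow([feat["probe_id"], name, "1"] + cells)
    matrix.samples.to_csv(path.with_suffix(_SAMPLES_SUFFIX), sep="\t", index=False)


# ------------------------------------------------------------ CDT/GTR
def _node_names(prefix: str, dend: Dendrogram) -> tuple[list[str], list[str]]:
    leaves = [f"{prefix}{i}X" for i in range(dend.n_leaves)]
    nodes = [f"NODE{prefix[0]}{j + 1}X" for j in range(len(dend.merges))]
    return leaves, nodes


def _write_tree_file(path: Path, prefix: str, dend: Dendrogram) -> list[str]:
    """Write a GTR/ATR node file; returns per-leaf node ids (GID/AID)."""
    leaf_ids, node_ids = _node_names(prefix, dend)
    n = dend.n_leaves
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for j, (left, right, height, _) in enumerate(dend.merges):
            lid = leaf_ids[left] if left < n else node_ids[left - n]
            rid = leaf_ids[right] if right < n else node_ids[right - n]
            # TreeView stores similarity (correlation), not distance.
            w.writerow([node_ids[j], lid, rid, repr(1.0 - height)])
    return leaf_ids


def write_cdt_gtr(
    matrix: ExpressionMatrix,
    gene_tree: Dendrogram,
    sample_tree: Dendrogram | None,
    path_stem: str | Path,
) -> dict[str, Path]:
    """Emit .cdt (+ .gtr, .atr) files in dendrogram leaf order."""
    stem = Path(path_stem)
    if sorted(gene_tree.labels) != sorted(matrix.probe_ids):
        raise ValidationError("gene tree leaves do not match matrix rows")
    if sample_tree is not None and sorted(sample_tree.labels) != sorted(
        matrix.sample_ids
    ):
        raise ValidationError("sample tree leaves do not match matrix columns")

    row_pos = {p: i for i, p in enumerate(matrix.probe_ids)}
    gene_order = [row_pos[gene_tree.labels[i]] for i in gene_tree.leaf_order()]
    if sample_tree is not None:
        col_pos = {s: j for j, s in enumerate(matrix.sample_ids)}
        col_order = [
            col_pos[sample_tree.labels[j]] for j in sample_tree.leaf_order()
        ]
    else:
        col_order = list(range(matrix.n_samples))

    out: dict[str, Path] = {}
    gtr_path = stem.with_suffix(".gtr")
    gene_leaf_ids = _write_tree_file(gtr_path, "GENE", gene_tree)
    out["gtr"] = gtr_path
    aid_for_col: list[str] | None = None
    if sample_tree is not None:
        atr_path = stem.with_suffix(".atr")
        arry_leaf_ids = _write_tree_file(atr_path, "ARRY", sample_tree)
        out["atr"] = atr_path
        leaf_seq = sample_tree.leaf_order()
        aid_for_col = [arry_leaf_ids[j] for j in leaf_seq]

    gid_for_row = [
        gene_leaf_ids[i] for i in gene_tree.leaf_order()
    ]
    cdt_path = stem.with_suffix(".cdt")
    ordered_samples = [matrix.sample_ids[j] for j in col_order]
    with open(cdt_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["GID", "ID", "NAME", "GWEIGHT"] + ordered_samples)
        if aid_for_col is not None:
            w.writerow(["AID", "", "", ""] + aid_for_col)
        w.writerow(["EWEIGHT", "", "", ""] + ["1"] * len(ordered_samples))
        for gid, i in zip(gid_for_row, gene_order):
            feat = matrix.features.iloc[i]
            name = feat["gene_symbol"]
            if feat["unigene_id"]:
                name = f"{name}|{feat['unigene_id']}"
            cells = [
                "" if np.isnan(matrix.values[i, j]) else repr(float(matrix.values[i, j]))
                for j in col_order
            ]
            w.writerow([gid, feat["probe_id"], name, "1"] + cells)
    out["cdt"] = cdt_path
    return out


# ----------------------------------------------------------- clinical
def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV: sample_id, time, event [, endpoint_label,
    covariates...]."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing mandatory column '{col}'")
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------- signature
def read_signature(path: str | Path, name: str | None = None) -> GeneSignature:
    """Read a signature TSV with columns gene [, direction]; header
    metadata lines ``# name: ...`` / ``# direction: ...`` /
    ``# provenance: ...`` are honoured."""
    path = Path(path)
    meta = {"name": name or path.stem, "direction": "up", "provenance": ""}
    genes: list[str] = []
    with open(path, encoding="utf-8") as fh:
        header_seen = False
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition(":")
                key = key.strip().lower()
                if key in meta and val.strip():
                    meta[key] = val.strip()
                continue
            if not header_seen:
                header_seen = True
                if line.split("\t")[0].strip().lower() == "gene":
                    continue
            genes.append(line.split("\t")[0].strip())
    if name is not None:
        meta["name"] = name
    return GeneSignature(
        meta["name"], genes, direction=meta["direction"], provenance=meta["provenance"]
    )


def write_signature(sig: GeneSignature, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# name: {sig.name}\n")
        fh.write(f"# direction: {sig.direction}\n")
        if sig.provenance:
            fh.write(f"# provenance: {sig.provenance}\n")
        fh.write("gene\n")
        for g in sig.genes:
            fh.write(f"{g}\n")


# ----------------------------------------------------------- term map
def read_term_map(path: str | Path) -> AnnotationSet:
    """Read a pre-propagated term->gene TSV (columns term, gene).

    The declared background is the union of all listed genes; supply
    extra background-only genes as rows with term ``BACKGROUND``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("term", "gene"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing mandatory column '{col}'")
    term_map: dict[str, set[str]] = {}
    background: set[str] = set()
    for term, gene in zip(df["term"], df["gene"]):
        gene = gene.strip().upper()
        if not gene:
            continue
        background.add(gene)
        if term.strip().upper() == "BACKGROUND":
            continue
        term_map.setdefault(term.strip(), set()).add(gene)
    return AnnotationSet(term_map, background)


def write_term_map(annot: AnnotationSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term\tgene\n")
        for term in sorted(annot.term_to_genes):
            for gene in sorted(annot.term_to_genes[term]):
                fh.write(f"{term}\t{gene}\n")
        annotated = set().union(*annot.term_to_genes.values())
        for gene in sorted(annot.background - annotated):
            fh.write(f"BACKGROUND\t{gene}\n")
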