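"""Readers and writers for the pipeline's tab-separated interchange formats.

Counts TSV layout: four key columns (chrom, pos, strand, context) followed by
two columns per sample, ``<sample>.M`` and ``<sample>.U``.  Missing cells are
empty fields.  All writers emit an optional leading ``#`` comment line
recording the resolved config hash and seed; readers skip comment lines.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .types import (
    ELEMENT_CLASSES,
    KEY_COLUMNS,
    IntervalSet,
    MethylCounts,
    PanelAnnotation,
    ValidationError,
    validate_sample_sheet,
)


def _meta_line(meta: Mapping[str, object] | None) -> str | None:
    if not meta:
        return None
    return "# " + " ".join(f"{k}={v}" for k, v in meta.items())


def write_table(df: pd.DataFrame, path, meta: Mapping[str, object] | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        line = _meta_line(meta)
        if line:
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_counts(path) -> MethylCounts:
    """Read a counts TSV into a :class:`MethylCounts`."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = [c for c in KEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: counts table lacks columns {missing}")
    value_cols = [c for c in df.columns if c not in KEY_COLUMNS]
    samples: list[str] = []
    for c in value_cols:
        if c.endswith(".M"):
            samples.append(c[:-2])
        elif not c.endswith(".U"):
            raise ValidationError(f"{path}: unexpected column {c!r}")
    for s in samples:
        if f"{s}.U" not in df.columns:
            raise ValidationError(f"{path}: sample {s!r} lacks a U column")
    M = df[[f"{s}.M" for s in samples]].to_numpy(dtype=float)
    U = df[[f"{s}.U" for s in samples]].to_numpy(dtype=float)
    # a cell is missing when either member of the pair is absent
    nan = np.isnan(M) | np.isnan(U)
    M[nan] = np.nan
    U[nan] = np.nan
    frac = np.concatenate([M[~np.isnan(M)], U[~np.isnan(U)]])
    if frac.size and np.any(frac != np.round(frac)):
        raise ValidationError(f"{path}: non-integer read counts")
    return MethylCounts(df[KEY_COLUMNS], samples, M, U)


def write_counts(counts: MethylCounts, path,
                 meta: Mapping[str, object] | None = None) -> None:
    df = counts.keys.copy()
    for j, s in enumerate(counts.samples):
        df[f"{s}.M"] = counts.M[:, j]
        df[f"{s}.U"] = counts.U[:, j]
    path = Path(path)
    with open(path, "w") as fh:
        line = _meta_line(meta)
        if line:
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.0f")


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, comment="#")
    return validate_sample_sheet(sheet)


def write_sample_sheet(sheet: pd.DataFrame, path,
                       meta: Mapping[str, object] | None = None) -> None:
    with open(path, "w") as fh:
        line = _meta_line(meta)
        if line:
            fh.write(line + "\n")
        sheet.to_csv(fh, index=False)


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file (0-based half-open); returns chrom/start/end[/name]."""
    rows = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw or raw.startswith(("#", "track", "browser")):
                continue
            parts = raw.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{ln}: BED line with < 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValidationError(f"{path}:{ln}: non-integer coordinate") from exc
            if end <= start:
                raise ValidationError(f"{path}:{ln}: end <= start")
            rows.append((parts[0], start, end, parts[3] if len(parts) > 3 else ""))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def read_annotation(genes_path, elements_path=None, mask_path=None) -> PanelAnnotation:
    """Assemble a :class:`PanelAnnotation` from a gene TSV plus BED files.

    The elements BED uses column 4 for the element class; unknown classes are
    rejected.  The SNP mask is BED3.
    """
    genes = pd.read_csv(genes_path, sep="\t", comment="#", dtype={"chrom": str})
    need = {"gene_id", "chrom", "tss", "strand", "window_bp"}
    missing = need - set(genes.columns)
    if missing:
        raise ValidationError(f"{genes_path}: gene table lacks {sorted(missing)}")
    if "pathways" not in genes.columns:
        genes["pathways"] = ""
    genes["pathways"] = genes["pathways"].fillna("")

    elements: dict[str, IntervalSet] = {}
    if elements_path is not None:
        bed = read_bed(elements_path)
        bad = set(bed["name"]) - ELEMENT_CLASSES
        if bad:
            raise ValidationError(f"{elements_path}: unknown element class(es) {sorted(bad)}")
        for cls, sub in bed.groupby("name", sort=True):
            elements[str(cls)] = IntervalSet(sub[["chrom", "start", "end"]])

    mask = None
    if mask_path is not None:
        mask = IntervalSet(read_bed(mask_path)[["chrom", "start", "end"]])
    return PanelAnnotation(genes=genes, elements=elements, snp_mask=mask)


def write_annotation(annotation: PanelAnnotation, genes_path,
                     elements_path=None, mask_path=None) -> None:
    genes = annotation.genes.copy()
    genes["pathways"] = genes["pathways"].map(lambda ps: ",".join(sorted(ps)))
    genes.to_csv(genes_path, sep="\t", index=False)
    if elements_path is not None:
        with open(elements_path, "w") as fh:
            for cls in sorted(annotation.elements):
                for _, row in annotation.elements[cls].intervals.iterrows():
                    fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\t{cls}\n")
    if mask_path is not None:
        with open(mask_path, "w") as fh:
            if annotation.snp_mask is not None:
                for _, row in annotation.snp_mask.intervals.iterrows():
                    fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\n")
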