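"""Core domain containers for targeted bisulfite-panel methylation analysis.

The panel is described at three levels:

* cytosines — keyed by (chrom, pos, strand, context) with ``pos`` 1-based and
  context ``CpG`` or ``CpH``;
* samples — rows of a sample sheet carrying the modelling covariates
  (diagnosis group, age, sex, postmortem interval, batch, replicate group);
* annotation — panel genes (TSS, probe window, pathway memberships) plus
  genomic-element and SNP-mask interval sets in BED convention
  (0-based, half-open).

Coordinate convention: interval inputs are BED 0-based half-open; cytosine
positions are 1-based.  A cytosine at 1-based position ``p`` lies inside
``[start, end)`` iff ``start < p <= end``.  Conversion happens only here.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

KEY_COLUMNS = ["chrom", "pos", "strand", "context"]
CONTEXTS = frozenset({"CpG", "CpH"})
STRANDS = frozenset({"+", "-"})

#: closed set of pathway labels of the autophagy-lysosomal panel
PATHWAYS = frozenset(
    {"autophagy", "CMA", "lysosome", "macroautophagy", "selective_autophagy"}
)

#: genomic element classes recognised by the annotation reader
ELEMENT_CLASSES = frozenset(
    {
        "promoter", "1to5kb", "5UTR", "exon", "intron", "3UTR", "intergenic",
        "cgi", "shore", "shelf", "open_sea",
        "active_promoter", "active_enhancer", "poised_enhancer",
    }
)


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


def validate_keys(keys: pd.DataFrame) -> pd.DataFrame:
    """Validate a cytosine key table (chrom, pos, strand, context)."""
    missing = [c for c in KEY_COLUMNS if c not in keys.columns]
    if missing:
        raise ValidationError(f"key table lacks columns {missing}")
    keys = keys.reset_index(drop=True)
    if (keys["pos"] < 1).any():
        raise ValidationError("cytosine positions must be >= 1 (1-based)")
    bad_strand = set(keys["strand"]) - STRANDS
    if bad_strand:
        raise ValidationError(f"unknown strand value(s) {sorted(bad_strand)}")
    bad_ctx = set(keys["context"]) - CONTEXTS
    if bad_ctx:
        raise ValidationError(f"unknown context value(s) {sorted(bad_ctx)}")
    dup = keys.duplicated(subset=KEY_COLUMNS)
    if dup.any():
        first = keys.loc[dup.idxmax(), KEY_COLUMNS].tolist()
        raise ValidationError(f"duplicate cytosine key {first}")
    return keys


@dataclass
class MethylCounts:
    """Paired methylated/unmethylated read-count matrices, cytosines x samples.

    ``M`` and ``U`` are float arrays with ``NaN`` marking absent cells; both
    matrices are missing at exactly the same cells.  Coverage is ``M + U``.
    """

    keys: pd.DataFrame
    samples: list[str]
    M: np.ndarray
    U: np.ndarray

    def __post_init__(self) -> None:
        self.keys = validate_keys(self.keys)
        self.samples = list(self.samples)
        self.M = np.asarray(self.M, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        shape = (len(self.keys), len(self.samples))
        if self.M.shape != shape or self.U.shape != shape:
            raise ValidationError(
                f"count matrices must have shape {shape}, "
                f"got M{self.M.shape} U{self.U.shape}"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample ids")
        if not np.array_equal(np.isnan(self.M), np.isnan(self.U)):
            raise ValidationError("M and U must be missing at the same cells")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.M, initial=0) < 0 or np.nanmin(self.U, initial=0) < 0:
                raise ValidationError("counts must be non-negative")

    @property
    def n_sites(self) -> int:
        return len(self.keys)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def coverage(self) -> np.ndarray:
        return self.M + self.U

    def beta(self, min_coverage: int = 1) -> "BetaMatrix":
        """Beta values B = M / (M + U) where coverage >= ``min_coverage``."""
        cov = self.coverage
        with np.errstate(invalid="ignore", divide="ignore"):
            B = np.where(cov >= max(min_coverage, 1), self.M / cov, np.nan)
        return BetaMatrix(self.keys, self.samples, B)

    def subset_sites(self, mask: np.ndarray) -> "MethylCounts":
        mask = np.asarray(mask)
        return MethylCounts(
            self.keys.loc[mask].reset_index(drop=True),
            self.samples, self.M[mask], self.U[mask],
        )

    def subset_samples(self, keep: Iterable[str]) -> "MethylCounts":
        keep = list(keep)
        idx = [self.samples.index(s) for s in keep]
        return MethylCounts(self.keys, keep, self.M[:, idx], self.U[:, idx])


@dataclass
class BetaMatrix:
    """Methylation fractions in [0, 1]; NaN marks missing calls."""

    keys: pd.DataFrame
    samples: list[str]
    B: np.ndarray

    def __post_init__(self) -> None:
        self.keys = validate_keys(self.keys)
        self.samples = list(self.samples)
        self.B = np.asarray(self.B, dtype=float)
        if self.B.shape != (len(self.keys), len(self.samples)):
            raise ValidationError("beta matrix shape mismatch")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.B, initial=0) < 0 or np.nanmax(self.B, initial=1) > 1:
                raise ValidationError("beta values must lie in [0, 1]")

    def subset_sites(self, mask: np.ndarray) -> "BetaMatrix":
        mask = np.asarray(mask)
        return BetaMatrix(
            self.keys.loc[mask].reset_index(drop=True), self.samples, self.B[mask]
        )

    def subset_samples(self, keep: Iterable[str]) -> "BetaMatrix":
        keep = list(keep)
        idx = [self.samples.index(s) for s in keep]
        return BetaMatrix(self.keys, keep, self.B[:, idx])


REQUIRED_SHEET_COLUMNS = ["sample_id", "group"]


def validate_sample_sheet(sheet: pd.DataFrame,
                          samples: Iterable[str] | None = None) -> pd.DataFrame:
    """Validate the per-sample covariate table.

    Required columns: sample_id, group (case/control).  Optional: age, sex,
    pmi, batch, replicate_group, plus arbitrary numeric extras.
    """
    missing = [c for c in REQUIRED_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValidationError(f"sample sheet lacks columns {missing}")
    sheet = sheet.reset_index(drop=True)
    if sheet["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in sample sheet")
    bad = set(sheet["group"]) - {"case", "control"}
    if bad:
        raise ValidationError(f"unknown group label(s) {sorted(bad)}")
    if "age" in sheet.columns and (sheet["age"].dropna() < 0).any():
        raise ValidationError("ages must be non-negative")
    if samples is not None:
        want = list(samples)
        have = set(sheet["sample_id"])
        absent = [s for s in want if s not in have]
        if absent:
            raise ValidationError(f"samples missing from sheet: {absent[:5]}")
        sheet = (
            sheet.set_index("sample_id").loc[want].reset_index()
        )
    return sheet


class IntervalSet:
    """Union-membership queries over BED-style (0-based, half-open) intervals.

    Overlapping intervals of the same class are retained; membership is the
    union.  Queries accept 1-based cytosine positions.
    """

    def __init__(self, intervals: pd.DataFrame):
        if len(intervals) and (intervals["end"] <= intervals["start"]).any():
            raise ValidationError("interval with end <= start")
        if len(intervals) and (intervals["start"] < 0).any():
            raise ValidationError("negative interval start")
        self.intervals = (
            intervals.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
        )
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in self.intervals.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy(dtype=np.int64)
            ends = np.maximum.accumulate(sub["end"].to_numpy(dtype=np.int64))
            self._by_chrom[str(chrom)] = (starts, ends)

    def __len__(self) -> int:
        return len(self.intervals)

    def contains(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Membership of 1-based positions in the interval union."""
        chrom = np.asarray(chrom)
        pos0 = np.asarray(pos, dtype=np.int64) - 1  # to 0-based
        out = np.zeros(len(pos0), dtype=bool)
        for c, (starts, cummax_end) in self._by_chrom.items():
            sel = chrom == c
            if not sel.any():
                continue
            idx = np.searchsorted(starts, pos0[sel], side="right")
            hit = idx > 0
            hit[hit] = cummax_end[idx[hit] - 1] > pos0[sel][hit]
            out[sel] = hit
        return out


@dataclass
class PanelAnnotation:
    """Panel genes plus genomic-element and SNP-mask interval sets.

    ``genes`` columns: gene_id, chrom, tss (1-based), strand, window_bp,
    pathways (frozenset drawn from :data:`PATHWAYS`), gwas_flag.
    """

    genes: pd.DataFrame
    elements: dict[str, IntervalSet] = field(default_factory=dict)
    snp_mask: IntervalSet | None = None

    def __post_init__(self) -> None:
        g = self.genes.reset_index(drop=True)
        if g["gene_id"].duplicated().any():
            raise ValidationError("duplicate gene_id in panel annotation")
        if (g["tss"] < 1).any():
            raise ValidationError("gene TSS must be 1-based (>= 1)")
        norm = []
        for p in g["pathways"]:
            ps = frozenset(p) if not isinstance(p, str) else frozenset(
                x for x in p.split(",") if x
            )
            bad = ps - PATHWAYS
            if bad:
                raise ValidationError(f"unknown pathway label(s) {sorted(bad)}")
            norm.append(ps)
        g = g.assign(pathways=norm)
        if "gwas_flag" not in g.columns:
            g["gwas_flag"] = False
        if "window_bp" not in g.columns:
            g["window_bp"] = 0
        self.genes = g

    def pathway_genes(self, pathway: str) -> list[str]:
        if pathway not in PATHWAYS:
            raise ValidationError(f"unknown pathway {pathway!r}")
        sel = self.genes["pathways"].map(lambda ps: pathway in ps)
        return self.genes.loc[sel, "gene_id"].tolist()

    def assign_genes(self, keys: pd.DataFrame) -> pd.Series:
        """Assign each cytosine to the nearest panel-gene TSS among genes whose
        probe window contains the site; ties break lexicographically by
        gene_id.  Unassigned sites get NA."""
        out = pd.Series(pd.NA, index=keys.index, dtype="object")
        best_dist = np.full(len(keys), np.inf)
        genes = self.genes.sort_values("gene_id")
        pos = keys["pos"].to_numpy(dtype=np.int64)
        chrom = keys["chrom"].to_numpy()
        for _, g in genes.iterrows():
            dist = np.abs(pos - int(g["tss"]))
            inside = (chrom == g["chrom"]) & (dist <= int(g["window_bp"]))
            better = inside & (dist < best_dist)  # strict: lexicographic ties
            best_dist[better] = dist[better]
            out.iloc[np.flatnonzero(better)] = g["gene_id"]
        return out

    def nearest_tss_distance(self, keys: pd.DataFrame) -> tuple[np.ndarray, pd.Series]:
        """Unsigned distance to the nearest panel-gene TSS (no window limit),
        with the nearest gene's id (lexicographic tie-break)."""
        pos = keys["pos"].to_numpy(dtype=np.int64)
        chrom = keys["chrom"].to_numpy()
        dist = np.full(len(keys), np.inf)
        gene = pd.Series(pd.NA, index=keys.index, dtype="object")
        for _, g in self.genes.sort_values("gene_id").iterrows():
            d = np.where(chrom == g["chrom"], np.abs(pos - int(g["tss"])), np.inf)
            better = d < dist
            dist[better] = d[better]
            gene.iloc[np.flatnonzero(better)] = g["gene_id"]
        return dist, gene


@dataclass
class Config:
    """Pipeline thresholds; defaults are the panel-analysis conventions.

    shrink_factor is the m-value shrinkage f; datasets containing CpH sites
    use ``shrink_factor_cph`` instead.
    """

    min_coverage: int = 30
    min_call_rate: float = 0.7
    stable_fraction: float = 0.5
    outlier_sd: float = 3.0
    replicate_min_r: float = 0.9
    shrink_factor: float = 1000.0
    shrink_factor_cph: float = 2000.0
    sv_var_threshold: float = 0.05
    irls_max_iter: int = 100
    fdr_q: float = 0.05
    tss_bin_bp: int = 20000
    normalize: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_coverage", "outlier_sd", "replicate_min_r",
                     "shrink_factor", "shrink_factor_cph", "irls_max_iter",
                     "tss_bin_bp"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        for name in ("min_call_rate", "stable_fraction", "fdr_q"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must be in (0, 1)")
        if not 0 < self.sv_var_threshold <= 1:
            raise ValidationError("sv_var_threshold must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config key(s) {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def resolved(self) -> Mapping[str, object]:
        return dataclasses.asdict(self)
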