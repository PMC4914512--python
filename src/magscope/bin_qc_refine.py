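"""Bin extraction, essential-gene QC, %GC diagnostics, coverage refinement.

Chunks selected by 2D polygon are promoted to whole contigs, bins are
scored for completeness (distinct single-copy families present) and
contamination (families in multiple copies), gene-wise %GC distributions
are compared, and contigs with outlying mean fold-coverage (|modified
Z-score| > 3.5) are excluded in a single refinement pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import wasserstein_distance
from shapely.geometry import Polygon as ShapelyPolygon

from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    InvalidPolygonError,
    MissingDataError,
)

OUTLIER_THRESHOLD = 3.5
MAD_CONSISTENCY = 0.6745
MEANAD_CONSISTENCY = 1.253314
N_ESSENTIAL_FAMILIES = 107


@dataclass(frozen=True)
class PolygonSelection:
    """A closed, simple 2D polygon given as an ordered vertex list."""

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        object.__setattr__(self, "vertices", verts)
        if len(verts) < 3:
            raise InvalidPolygonError("polygon needs >= 3 vertices")
        shp = ShapelyPolygon(verts)
        if not shp.is_valid or shp.area == 0:
            raise InvalidPolygonError("polygon is self-intersecting or degenerate")


@dataclass
class EssentialGeneReport:
    n_families_present: int
    n_families_multicopy: int
    family_copy_counts: dict[str, int] = field(default_factory=dict)
    n_families_total: int = N_ESSENTIAL_FAMILIES

    def __post_init__(self) -> None:
        if not (self.n_families_multicopy <= self.n_families_present
                <= self.n_families_total):
            raise ValueError("inconsistent essential-gene counts")


@dataclass
class Bin:
    bin_id: str
    contig_ids: list[str]
    provenance: str  # polygon | beacon | mgs-refined
    embedding_run_id: str | None = None
    qc: EssentialGeneReport | None = None

    def __post_init__(self) -> None:
        if len(set(self.contig_ids)) != len(self.contig_ids):
            raise ValueError("duplicate contig ids in bin")
        if self.provenance not in ("polygon", "beacon", "mgs-refined"):
            raise ValueError(f"unknown provenance {self.provenance!r}")


# ---------------------------------------------------------------------------
# polygon selection
# ---------------------------------------------------------------------------

def _on_segment(px, py, x1, y1, x2, y2, eps=1e-12) -> bool:
    cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
    if abs(cross) > eps * max(1.0, abs(x2 - x1), abs(y2 - y1)):
        return False
    return (min(x1, x2) - eps <= px <= max(x1, x2) + eps
            and min(y1, y2) - eps <= py <= max(y1, y2) + eps)


def point_in_polygon(x: float, y: float, polygon: PolygonSelection) -> bool:
    """Even-odd (ray casting) membership; boundary points count as inside."""
    verts = polygon.vertices
    n = len(verts)
    inside = False
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if _on_segment(x, y, x1, y1, x2, y2):
            return True
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside


def points_in_polygon(points: pd.DataFrame, polygon: PolygonSelection) -> list[str]:
    """Chunk ids of embedding points falling inside the polygon.

    ``points`` must carry chunk_id, x, y columns (or a chunk_id index).
    """
    frame = points.reset_index() if "chunk_id" not in points.columns else points
    selected = [
        str(row.chunk_id)
        for row in frame.itertuples(index=False)
        if point_in_polygon(float(row.x), float(row.y), polygon)
    ]
    return selected


def chunks_to_contigs(
    selected_chunk_ids: list[str],
    chunk_map: pd.DataFrame,
    rule: str = "majority",
) -> list[str]:
    """Promote chunk-level selections to whole contigs.

    "majority": a contig is included iff strictly more than half of its
    chunks were selected (exactly half is excluded). "length_majority":
    the same with chunks weighted by length, so a short unselected tail
    chunk cannot veto its contig. "any": one selected chunk suffices.
    """
    if rule not in ("majority", "length_majority", "any"):
        raise InvalidParameterError(f"unknown rule {rule!r}")
    known = set(chunk_map["chunk_id"])
    missing = set(selected_chunk_ids) - known
    if missing:
        raise MissingDataError(f"chunks absent from map: {sorted(missing)[:5]}")
    selected = set(selected_chunk_ids)
    contigs = []
    for contig, grp in chunk_map.groupby("parent_contig", sort=True):
        in_sel = grp["chunk_id"].isin(selected)
        if rule == "any":
            if in_sel.any():
                contigs.append(str(contig))
        elif rule == "length_majority":
            spans = (grp["end"] - grp["start"]).to_numpy(dtype=float)
            if 2 * spans[in_sel.to_numpy()].sum() > spans.sum():
                contigs.append(str(contig))
        else:
            if 2 * int(in_sel.sum()) > len(grp):
                contigs.append(str(contig))
    return contigs


# ---------------------------------------------------------------------------
# essential-gene QC
# ---------------------------------------------------------------------------

def completeness_contamination(
    bin_contigs: list[str],
    marker_hits: pd.DataFrame,
    gene_to_contig: dict[str, str],
    n_families_total: int = N_ESSENTIAL_FAMILIES,
) -> EssentialGeneReport:
    """Count essential families present / in multiple copies on bin contigs.

    ``marker_hits`` maps gene_id to family_id; genes are located via
    ``gene_to_contig``. Completeness is the number of distinct families
    with at least one copy; contamination the number with at least two.
    """
    contig_set = set(bin_contigs)
    counts: dict[str, int] = {}
    for row in marker_hits.itertuples(index=False):
        contig = gene_to_contig.get(row.gene_id)
        if contig in contig_set:
            counts[row.family_id] = counts.get(row.family_id, 0) + 1
    present = len(counts)
    multi = sum(1 for v in counts.values() if v >= 2)
    return EssentialGeneReport(present, multi, counts, n_families_total)


# ---------------------------------------------------------------------------
# %GC diagnostics
# ---------------------------------------------------------------------------

def gc_per_sequence(sequences: dict[str, str]) -> pd.Series:
    """Percent GC per sequence, ambiguous bases excluded from the denominator.

    Sequences with no unambiguous base are reported as NaN.
    """
    values = {}
    for name, seq in sequences.items():
        s = seq.upper()
        gc = s.count("G") + s.count("C")
        denom = gc + s.count("A") + s.count("T")
        values[name] = 100.0 * gc / denom if denom else np.nan
    return pd.Series(values, name="gc_percent")


def gc_distribution_compare(values_a, values_b) -> dict[str, float]:
    """Summaries + earth-mover distance between two %GC distributions."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 5 or b.size < 5:
        raise InsufficientDataError("need >= 5 values per distribution")
    q1a, q3a = np.percentile(a, [25, 75])
    q1b, q3b = np.percentile(b, [25, 75])
    return {
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "iqr_a": float(q3a - q1a),
        "iqr_b": float(q3b - q1b),
        "emd": float(wasserstein_distance(a, b)),
    }


# ---------------------------------------------------------------------------
# coverage-outlier refinement
# ---------------------------------------------------------------------------

def modified_zscore(values) -> np.ndarray:
    """Robust outlier scores: 0.6745 * (x - median) / MAD.

    If the median absolute deviation is zero the mean absolute deviation
    fallback (x - median) / (1.253314 * MeanAD) is used; if both are zero
    all scores are zero.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("need >= 3 values for modified Z-scores")
    med = np.median(x)
    absdev = np.abs(x - med)
    mad = np.median(absdev)
    if mad > 0:
        return MAD_CONSISTENCY * (x - med) / mad
    meanad = absdev.mean()
    if meanad > 0:
        return (x - med) / (MEANAD_CONSISTENCY * meanad)
    return np.zeros_like(x)


def coverage_outlier_filter(
    bin_contigs: list[str],
    contig_coverage: dict[str, float] | pd.Series,
    threshold: float = OUTLIER_THRESHOLD,
) -> tuple[list[str], list[str], pd.Series]:
    """Single-pass exclusion of contigs with |modified Z| strictly > threshold.

    Both coverage tails are removed; a score of exactly ``threshold`` is
    kept. Returns (kept, discarded, scores). Re-running on the kept set may
    flag further contigs; per the single refine-then-reassemble semantics
    only one pass is performed.
    """
    cov = pd.Series(contig_coverage)
    missing = [c for c in bin_contigs if c not in cov.index]
    if missing:
        raise MissingDataError(f"no coverage for contigs: {missing[:5]}")
    values = cov.loc[bin_contigs].to_numpy(dtype=float)
    scores = pd.Series(modified_zscore(values), index=bin_contigs, name="modified_z")
    outlier = scores.abs() > threshold
    kept = [c for c in bin_contigs if not outlier[c]]
    discarded = [c for c in bin_contigs if outlier[c]]
    return kept, discarded, scores


def contig_mean_coverage(
    depth: pd.DataFrame,
    contig_lengths: dict[str, int] | None = None,
) -> pd.Series:
    """Length-weighted mean depth per contig from windowed depth records.

    ``depth`` columns: contig, start, end, depth (0-based half-open
    windows, the dialect of common per-base depth tools). When
    ``contig_lengths`` is given, positions without records count as zero
    and unknown contigs in the depth table are fatal; otherwise the
    largest end coordinate seen is used as the contig length.
    """
    required = {"contig", "start", "end", "depth"}
    if not required.issubset(depth.columns):
        raise InvalidParameterError(f"depth table needs columns {sorted(required)}")
    if contig_lengths is not None:
        unknown = set(depth["contig"]) - set(contig_lengths)
        if unknown:
            raise MissingDataError(f"unknown contigs in depth file: {sorted(unknown)[:5]}")
    means = {}
    for contig, grp in depth.groupby("contig", sort=True):
        spans = (grp["end"] - grp["start"]).to_numpy(dtype=float)
        if (spans <= 0).any():
            raise InvalidParameterError(f"non-positive window on contig {contig}")
        total = float((spans * grp["depth"].to_numpy(dtype=float)).sum())
        if contig_lengths is not None:
            length = float(contig_lengths[str(contig)])
        else:
            length = float(grp["end"].max())
        means[str(contig)] = total / length
    if contig_lengths is not None:
        for contig in contig_lengths:
            means.setdefault(contig, 0.0)
    return pd.Series(means, name="mean_coverage").sort_index()


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def bin_qc_row(
    bin_: Bin,
    contig_sequences: dict[str, str],
    n_discarded: int = 0,
) -> dict:
    """One QC-report row (sizes, %GC median/IQR, essential-gene counts)."""
    seqs = {c: contig_sequences[c] for c in bin_.contig_ids}
    gc = gc_per_sequence(seqs).dropna()
    q1, q3 = (np.percentile(gc, [25, 75]) if len(gc) else (np.nan, np.nan))
    return {
        "bin_id": bin_.bin_id,
        "provenance": bin_.provenance,
        "n_contigs": len(bin_.contig_ids),
        "total_bp": sum(len(s) for s in seqs.values()),
        "gc_median": float(np.median(gc)) if len(gc) else np.nan,
        "gc_iqr": float(q3 - q1),
        "completeness": bin_.qc.n_families_present if bin_.qc else np.nan,
        "contamination": bin_.qc.n_families_multicopy if bin_.qc else np.nan,
        "n_discarded_outliers": n_discarded,
    }
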