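"""End-to-end orchestration of the two recovery approaches.

Approach 1 ("canopy_refine"): filter the gene catalog, canopy-cluster gene
abundance profiles, call MGS, embed the best sample's contigs, select the
MGS cluster with a polygon, and refine by coverage outliers.

Approach 2 ("targeted"): select taxon-specific marker genes, group them,
rank samples by marker coverage, highlight beacon contigs in the
embedding, select the surrounding cluster, and refine.

The manual polygon-drawing step is replaced by polygon files; when none
are supplied, scaffolding helpers derive a selection automatically (convex
hull of labelled points for Approach 1, density cluster around the beacon
for Approach 2). These helpers stand in for human cluster selection in
automated runs and make no scientific claim.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from sklearn.cluster import HDBSCAN

from . import bin_qc_refine as qc
from . import canopy_mgs as cm
from . import signature_embedding as se
from . import targeted_recovery as tr
from .errors import InvalidParameterError, MissingDataError
from .synthetic_community import Community

_KNOWN_KEYS = None  # populated after RunConfig definition


@dataclass
class RunConfig:
    """All parameters of a pipeline run; unknown keys are rejected."""

    approach: str = "canopy_refine"  # canopy_refine | targeted
    input_dir: str | None = None
    out_dir: str | None = None
    seed: int = 0
    # canopy stage
    min_gene_length: int = 100
    min_gene_cov: float = 2.0
    max_canopy_dist: float = 0.1
    max_close_dist: float = 0.4
    max_merge_dist: float = 0.1
    min_step_dist: float = 0.005
    stop_fraction: float = 1.0
    min_genes: int = 700
    # embedding stage
    min_contig_length: int = 1_000
    chunk_size: int = 5_000
    # fold tail chunks shorter than min_contig_length into their neighbor;
    # short tails embed noisily and make whole-contig promotion flaky
    merge_tail: bool = True
    k: int = 5
    pca_dims: int = 50
    perplexity: float = 30.0
    # targeted stage
    target_taxon: str = "Cyanobacteria"
    min_confidence: float = 0.75
    # refinement
    outlier_threshold: float = 3.5
    # length-weighted majority: a short tail chunk falling outside the
    # selection cannot veto an otherwise fully selected contig
    promotion_rule: str = "length_majority"
    n_families_total: int = 107
    # polygon files per bin id; empty -> automatic scaffolding selection
    polygons: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.approach not in ("canopy_refine", "targeted"):
            raise InvalidParameterError(f"unknown approach {self.approach!r}")

    @classmethod
    def from_mapping(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        return cls.from_mapping(raw)


# ---------------------------------------------------------------------------
# polygon scaffolding (stand-ins for manual selection)
# ---------------------------------------------------------------------------

def convex_hull_polygon(points_xy: np.ndarray, pad: float = 0.05) -> qc.PolygonSelection:
    """Convex hull of a point set, padded outward from the centroid.

    Test/automation scaffolding for the manual polygon-drawing step.
    """
    pts = np.asarray(points_xy, dtype=float)
    uniq = np.unique(pts, axis=0)
    if len(uniq) < 3:
        # degenerate cloud: padded bounding box
        lo = pts.min(axis=0) - 1e-3
        hi = pts.max(axis=0) + 1e-3
        span = np.maximum(hi - lo, 1e-3)
        lo, hi = lo - pad * span, hi + pad * span
        verts = [(lo[0], lo[1]), (hi[0], lo[1]), (hi[0], hi[1]), (lo[0], hi[1])]
        return qc.PolygonSelection(tuple(verts))
    hull = ConvexHull(uniq)
    verts = uniq[hull.vertices]
    centroid = verts.mean(axis=0)
    padded = centroid + (verts - centroid) * (1.0 + pad)
    return qc.PolygonSelection(tuple(map(tuple, padded)))


def polygon_around_points(
    coords: pd.DataFrame, chunk_ids: list[str], pad: float = 0.05
) -> qc.PolygonSelection:
    """Hull polygon around the embedding points of the given chunks."""
    pts = coords.loc[coords.index.intersection(chunk_ids), ["x", "y"]].to_numpy()
    if len(pts) == 0:
        raise MissingDataError("no embedding points for the requested chunks")
    return convex_hull_polygon(pts, pad)


def polygon_around_beacon(
    coords: pd.DataFrame,
    beacon_chunk_ids: list[str],
    pad: float = 0.05,
    min_cluster_size: int = 5,
) -> qc.PolygonSelection:
    """Select the density cluster containing the beacon chunks.

    Hierarchical density clustering (no fixed scale parameter) emulates
    the visual selection of the cluster around a beacon contig. Falls back
    to a hull around the beacon points themselves if density clustering
    leaves them unassigned.
    """
    X = coords[["x", "y"]].to_numpy()
    labels = HDBSCAN(min_cluster_size=min_cluster_size, copy=True).fit_predict(X)

    beacon_pos = [coords.index.get_loc(c) for c in beacon_chunk_ids if c in coords.index]
    if not beacon_pos:
        raise MissingDataError("beacon chunks absent from embedding")
    # a beacon contig's chunks may straddle several density sub-clusters;
    # the selection covers every cluster holding one of them
    beacon_labels = {int(labels[i]) for i in beacon_pos if labels[i] != -1}
    if beacon_labels:
        member_pts = X[np.isin(labels, sorted(beacon_labels))]
    else:
        member_pts = X[beacon_pos]
    return convex_hull_polygon(member_pts, pad)


# ---------------------------------------------------------------------------
# shared embedding stage
# ---------------------------------------------------------------------------

def _embed_community(community: Community, cfg: RunConfig):
    contigs = {c.contig_id: c.sequence for c in community.contigs}
    chunks = se.filter_and_chunk(contigs, cfg.min_contig_length, cfg.chunk_size,
                                 merge_tail=cfg.merge_tail)
    matrix = se.signature_matrix(chunks, k=cfg.k)
    coords = se.embed_signatures(matrix, pca_dims=cfg.pca_dims,
                                 perplexity=cfg.perplexity, seed=cfg.seed)
    run_id = f"embed-k{cfg.k}-seed{cfg.seed}"
    return chunks, se.chunk_map_frame(chunks), coords, run_id


def _refine_bin(
    bin_id: str,
    provenance: str,
    contig_ids: list[str],
    community: Community,
    sample: str,
    cfg: RunConfig,
    run_id: str,
) -> tuple[qc.Bin, dict]:
    coverage = community.contig_coverage[sample]
    skipped_refinement = len(contig_ids) < 3  # robust scores need >= 3 values
    if skipped_refinement:
        kept, discarded = list(contig_ids), []
    else:
        kept, discarded, scores = qc.coverage_outlier_filter(
            contig_ids, coverage, cfg.outlier_threshold)
    report_bin = qc.Bin(bin_id, kept, provenance, embedding_run_id=run_id)
    if community.marker_hits is not None:
        report_bin.qc = qc.completeness_contamination(
            kept, community.marker_hits, community.gene_to_contig,
            cfg.n_families_total)
    row = qc.bin_qc_row(report_bin,
                        {c.contig_id: c.sequence for c in community.contigs},
                        n_discarded=len(discarded))
    row.update({"sample": sample, "n_selected_contigs": len(contig_ids)})
    if skipped_refinement:
        row["refinement_skipped"] = "fewer than 3 contigs"
    return report_bin, row


def _load_polygon(path: str | Path) -> qc.PolygonSelection:
    raw = json.loads(Path(path).read_text())
    return qc.PolygonSelection(tuple(map(tuple, raw["vertices"])))


# ---------------------------------------------------------------------------
# approach 1
# ---------------------------------------------------------------------------

def run_approach1(community: Community, cfg: RunConfig) -> tuple[list[qc.Bin], dict]:
    """Canopy clustering -> MGS -> embedding -> polygon -> refinement."""
    t0 = time.time()
    report: dict = {"approach": "canopy_refine", "stages": {}, "bins": []}

    profiles = cm.filter_gene_catalog(
        community.gene_coverage, community.gene_lengths,
        cfg.min_gene_length, cfg.min_gene_cov)
    profiles, zero_var = cm.split_zero_variance(profiles)
    report["stages"]["catalog"] = {
        "genes_in": int(len(community.gene_coverage)),
        "genes_kept": int(len(profiles)),
        "zero_variance_excluded": len(zero_var),
    }

    canopies = cm.canopy_cluster(
        profiles,
        max_canopy_dist=cfg.max_canopy_dist, max_close_dist=cfg.max_close_dist,
        max_merge_dist=cfg.max_merge_dist, min_step_dist=cfg.min_step_dist,
        stop_fraction=cfg.stop_fraction)
    mgs_list = cm.call_mgs(canopies, cfg.min_genes)
    report["stages"]["canopy"] = {"n_canopies": len(canopies), "n_mgs": len(mgs_list)}

    bins: list[qc.Bin] = []
    if not mgs_list:
        report["wall_time_s"] = round(time.time() - t0, 3)
        return bins, report

    chunks, chunk_map, coords, run_id = _embed_community(community, cfg)
    report["stages"]["embedding"] = {"n_chunks": len(chunks), "run_id": run_id}
    chunks_by_contig: dict[str, list[str]] = {}
    for c in chunks:
        chunks_by_contig.setdefault(c.parent_contig, []).append(c.chunk_id)

    points_tables = {}
    for mgs in mgs_list:
        sample = cm.best_sample_for_mgs(mgs, community.gene_coverage)
        flagged, unplaced = cm.mgs_to_contig_labels(mgs, community.gene_to_contig)
        labels = {contig: mgs.mgs_id for contig in flagged}
        points = se.points_frame(chunks, coords, labels=labels,
                                 coverage=dict(community.contig_coverage[sample]))
        points_tables[mgs.mgs_id] = points

        if mgs.mgs_id in cfg.polygons:
            polygon = _load_polygon(cfg.polygons[mgs.mgs_id])
        else:
            labelled_chunks = [cid for contig in flagged
                               for cid in chunks_by_contig.get(contig, [])]
            polygon = polygon_around_points(coords, labelled_chunks)

        selected = qc.points_in_polygon(points, polygon)
        contig_ids = qc.chunks_to_contigs(selected, chunk_map, cfg.promotion_rule)
        bin_, row = _refine_bin(mgs.mgs_id, "mgs-refined", contig_ids,
                                community, sample, cfg, run_id)
        row["n_unplaced_genes"] = len(unplaced)
        bins.append(bin_)
        report["bins"].append(row)

    report["wall_time_s"] = round(time.time() - t0, 3)
    if cfg.out_dir:
        _persist(cfg, report, bins, points_tables, chunk_map, community)
    return bins, report


# ---------------------------------------------------------------------------
# approach 2
# ---------------------------------------------------------------------------

def run_approach2(community: Community, cfg: RunConfig) -> tuple[list[qc.Bin], dict]:
    """Marker selection -> CLSGs -> beacon-guided selection -> refinement."""
    t0 = time.time()
    report: dict = {"approach": "targeted", "stages": {}, "bins": []}
    if community.taxonomy is None:
        raise MissingDataError("community carries no taxon annotations")

    candidates = tr.select_marker_candidates(
        community.taxonomy, cfg.target_taxon, cfg.min_confidence)
    report["stages"]["marker_selection"] = {"n_candidates": len(candidates)}
    if not candidates:
        report["note"] = "no target population detected"
        report["wall_time_s"] = round(time.time() - t0, 3)
        return [], report

    meta = pd.DataFrame(
        [(g.gene_id, int(g.has_start), int(g.has_stop)) for g in community.genes],
        columns=["gene_id", "has_start", "has_stop"])
    complete = tr.drop_partial_genes(candidates, meta)
    report["stages"]["partial_filter"] = {"kept": len(complete),
                                          "dropped": len(candidates) - len(complete)}
    if not complete:
        report["note"] = "no target population detected"
        report["wall_time_s"] = round(time.time() - t0, 3)
        return [], report

    seqs = {g.gene_id: g.sequence for g in community.genes if g.gene_id in set(complete)}
    groups = tr.build_marker_groups(seqs, community.gene_coverage)
    report["stages"]["marker_groups"] = {
        "n_groups": len(groups),
        "groups": [{"clsg_id": g.clsg_id, "n_members": len(g.member_gene_ids),
                    "max_coverage": g.max_coverage} for g in groups]}

    chunks, chunk_map, coords, run_id = _embed_community(community, cfg)
    report["stages"]["embedding"] = {"n_chunks": len(chunks), "run_id": run_id}
    chunks_by_contig: dict[str, list[str]] = {}
    for c in chunks:
        chunks_by_contig.setdefault(c.parent_contig, []).append(c.chunk_id)

    bins: list[qc.Bin] = []
    points_tables = {}
    for group in groups:
        ranking = tr.rank_samples_by_marker(group)
        if not ranking:
            report["bins"].append({"bin_id": group.clsg_id,
                                   "note": "all-zero marker coverage"})
            continue
        sample = ranking[0]
        beacons, unmapped = tr.locate_beacon_contigs(group, community.gene_to_contig)
        points = se.points_frame(chunks, coords, markers=beacons,
                                 coverage=dict(community.contig_coverage[sample]))
        points_tables[group.clsg_id] = points

        if group.clsg_id in cfg.polygons:
            polygon = _load_polygon(cfg.polygons[group.clsg_id])
        else:
            beacon_chunks = [cid for contig in beacons
                             for cid in chunks_by_contig.get(contig, [])]
            polygon = polygon_around_beacon(coords, beacon_chunks)

        selected = qc.points_in_polygon(points, polygon)
        contig_ids = qc.chunks_to_contigs(selected, chunk_map, cfg.promotion_rule)
        bin_, row = _refine_bin(group.clsg_id, "beacon", contig_ids,
                                community, sample, cfg, run_id)
        row["sample_ranking"] = ranking[:10]
        row["n_unmapped_marker_genes"] = len(unmapped)
        if community.contig_coverage[sample].loc[bin_.contig_ids].mean() < 10:
            row["low_coverage_warning"] = True  # completeness likely reduced
        bins.append(bin_)
        report["bins"].append(row)

    report["wall_time_s"] = round(time.time() - t0, 3)
    if cfg.out_dir:
        _persist(cfg, report, bins, points_tables, chunk_map, community)
    return bins, report


def run(community: Community, cfg: RunConfig) -> tuple[list[qc.Bin], dict]:
    if cfg.approach == "canopy_refine":
        return run_approach1(community, cfg)
    return run_approach2(community, cfg)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def _hash_frame(frame: pd.DataFrame) -> str:
    return hashlib.sha256(frame.to_csv().encode()).hexdigest()[:16]


def _persist(cfg: RunConfig, report: dict, bins, points_tables, chunk_map,
             community: Community | None = None) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for bin_id, points in points_tables.items():
        se.write_points(points, out / f"points_{bin_id}.tsv")
    chunk_map.to_csv(out / "chunk_map.tsv", sep="\t", index=False)
    for b in bins:
        pd.Series(b.contig_ids, name="contig_id").to_csv(
            out / f"bin_{b.bin_id}.contigs.tsv", sep="\t", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    from . import __version__
    manifest = {"config": asdict(cfg), "bins": [b.bin_id for b in bins],
                "version": __version__}
    if community is not None:
        manifest["input_hashes"] = {
            "gene_coverage": _hash_frame(community.gene_coverage),
            "contig_coverage": _hash_frame(community.contig_coverage),
        }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
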