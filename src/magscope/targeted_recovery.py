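"""Targeted, marker-gene-guided population recovery.

Selects taxon-specific marker genes by annotation confidence, drops
incomplete gene predictions, clusters the survivors into marker sequence
groups (95% identity over 50% of the shorter sequence), ranks samples by
the representative gene's fold-coverage, and flags the contigs carrying
group members as "beacon contigs" for highlighting in the 2D embedding.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .errors import MissingDataError
from .sequence_clustering import MARKER_GROUP_PARAMS, IdentityParams, greedy_cluster


@dataclass
class MarkerSequenceGroup:
    clsg_id: str
    member_gene_ids: list[str]
    representative_id: str
    sample_coverage: pd.Series  # per-sample fold-coverage of the representative

    @property
    def max_coverage(self) -> float:
        return float(self.sample_coverage.max()) if len(self.sample_coverage) else 0.0


# ---------------------------------------------------------------------------
# marker selection
# ---------------------------------------------------------------------------

def normalize_confidence(values: pd.Series) -> pd.Series:
    """Accept confidences on either a 0-1 or 0-100 scale.

    Any value above 1 flips the whole column to percent interpretation.
    """
    v = values.astype(float)
    if (v > 1).any():
        return v / 100.0
    return v


def select_marker_candidates(
    annotations: pd.DataFrame,
    target_taxon: str,
    min_confidence: float = 0.75,
) -> list[str]:
    """Genes annotated to the target taxon at or above the confidence cutoff.

    ``annotations`` columns: gene_id, taxon, confidence. The taxon match is
    a substring test on the taxon path; the confidence boundary is
    inclusive.
    """
    conf = normalize_confidence(annotations["confidence"])
    hit = annotations["taxon"].astype(str).str.contains(target_taxon, regex=False)
    keep = annotations.loc[hit & (conf >= min_confidence), "gene_id"]
    return sorted(map(str, keep))


def most_common_marker_family(
    annotations: pd.DataFrame,
    target_taxon: str,
    family_column: str = "marker_family",
    min_confidence: float = 0.75,
) -> str | None:
    """Pick the qualifying marker family with the most annotated genes.

    Generalises the choice of a single marker gene type: among genes passing
    the taxon/confidence filter, returns the most frequent value of
    ``family_column`` (ties by name), or None when nothing qualifies.
    """
    if family_column not in annotations.columns:
        raise MissingDataError(f"annotations lack a {family_column!r} column")
    keep = set(select_marker_candidates(annotations, target_taxon, min_confidence))
    sub = annotations[annotations["gene_id"].astype(str).isin(keep)]
    if sub.empty:
        return None
    counts = sub[family_column].value_counts()
    best = counts.max()
    return sorted(counts.index[counts == best])[0]


def drop_partial_genes(gene_ids: list[str], meta: pd.DataFrame) -> list[str]:
    """Keep only genes whose prediction has both a start and a stop codon.

    ``meta`` columns: gene_id, has_start, has_stop (truthy flags). A gene
    missing from the table is fatal.
    """
    table = meta.set_index(meta["gene_id"].astype(str))
    missing = [g for g in gene_ids if g not in table.index]
    if missing:
        raise MissingDataError(f"genes missing from prediction meta: {missing[:5]}")
    kept = []
    for gid in gene_ids:
        row = table.loc[gid]
        if bool(row["has_start"]) and bool(row["has_stop"]):
            kept.append(gid)
    return kept


_PARTIAL_RE = re.compile(r"partial=([01])([01])")


def parse_partial_flag(header: str) -> tuple[bool, bool]:
    """Map the ``partial=XY`` gene-predictor header dialect to flags.

    X (5' edge) and Y (3' edge) are '1' when the gene runs off the contig
    edge; '0' means the corresponding codon is present. Returns
    (has_start, has_stop). Headers without the tag are treated as complete.
    """
    m = _PARTIAL_RE.search(header)
    if m is None:
        return True, True
    return m.group(1) == "0", m.group(2) == "0"


# ---------------------------------------------------------------------------
# marker groups
# ---------------------------------------------------------------------------

def build_marker_groups(
    gene_sequences: dict[str, str],
    gene_coverage: pd.DataFrame,
    params: IdentityParams = MARKER_GROUP_PARAMS,
) -> list[MarkerSequenceGroup]:
    """Cluster marker genes and number groups by descending peak coverage.

    Delegates to greedy identity clustering (default 0.95 identity over
    0.5 of the shorter sequence). Groups are numbered CLSG01, CLSG02, ...
    by descending maximum per-sample fold-coverage of their representative
    gene (ties by representative id).
    """
    if not gene_sequences:
        return []
    clusters = greedy_cluster(gene_sequences, params)
    groups = []
    for cluster in clusters:
        rep = cluster.representative_id
        if rep in gene_coverage.index:
            cov = gene_coverage.loc[rep]
        else:
            cov = pd.Series(0.0, index=gene_coverage.columns)
        groups.append((rep, sorted(cluster.member_ids), cov))
    groups.sort(key=lambda t: (-float(t[2].max()) if len(t[2]) else 0.0, t[0]))
    return [
        MarkerSequenceGroup(f"CLSG{i + 1:02d}", members, rep, cov)
        for i, (rep, members, cov) in enumerate(groups)
    ]


def rank_samples_by_marker(group: MarkerSequenceGroup) -> list[str]:
    """Samples by descending representative coverage (ties by sample id).

    The first element is the sample chosen for visualization/recovery.
    All-zero coverage yields an empty ranking.
    """
    cov = group.sample_coverage
    if len(cov) == 0 or (cov == 0).all():
        return []
    order = sorted(cov.index, key=lambda s: (-float(cov[s]), s))
    return [str(s) for s in order]


def locate_beacon_contigs(
    group: MarkerSequenceGroup,
    gene_to_contig: dict[str, str],
) -> tuple[set[str], list[str]]:
    """Contigs carrying any group member gene (the beacons), plus unmapped genes."""
    beacons: set[str] = set()
    unmapped: list[str] = []
    for gid in group.member_gene_ids:
        contig = gene_to_contig.get(gid)
        if contig is None:
            unmapped.append(gid)
        else:
            beacons.add(contig)
    return beacons, unmapped


def groups_frame(groups: list[MarkerSequenceGroup]) -> pd.DataFrame:
    rows = [(g.clsg_id, member, g.representative_id)
            for g in groups for member in g.member_gene_ids]
    return pd.DataFrame(rows, columns=["clsg_id", "member", "representative"])


def sample_ranking_frame(group: MarkerSequenceGroup, top_n: int = 10) -> pd.DataFrame:
    """Rank-abundance table of the top samples for one group."""
    ranking = rank_samples_by_marker(group)[:top_n]
    return pd.DataFrame(
        [(group.clsg_id, rank + 1, sample, float(group.sample_coverage[sample]))
         for rank, sample in enumerate(ranking)],
        columns=["clsg_id", "rank", "sample", "fold_coverage"],
    )
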