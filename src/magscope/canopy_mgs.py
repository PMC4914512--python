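"""Co-abundance canopy clustering of gene abundance profiles and MGS calling.

Genes whose per-sample fold-coverage co-varies across samples are gathered
into canopies under a Pearson-correlation distance; canopies with at least
``min_genes`` members (700 by default) are promoted to metagenomic species
(MGS). Clustering parameters default to: max_canopy_dist 0.1,
max_close_dist 0.4, max_merge_dist 0.1, min_step_dist 0.005,
stop_fraction 1.

The seeding order is deterministic (descending total coverage, ties by
gene id) so results are exactly reproducible; a random seeding order is
available behind a flag. Correlation is computed on raw fold-coverages;
zero-variance profiles must be removed first (see
:func:`split_zero_variance`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UndefinedCorrelationError

MAX_RECENTER_ITERATIONS = 10  # safety bound on the gather/recenter loop


@dataclass
class Canopy:
    canopy_id: str
    center: np.ndarray
    members: list[str]
    close_members: list[str]

    def __post_init__(self) -> None:
        missing = set(self.members) - set(self.close_members)
        if missing:
            raise ValueError(f"members not within close_members: {sorted(missing)[:5]}")


@dataclass
class MGS:
    mgs_id: str
    member_gene_ids: list[str]
    source_canopy_ids: list[str] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return len(self.member_gene_ids)


# ---------------------------------------------------------------------------
# catalog filtering
# ---------------------------------------------------------------------------

def filter_gene_catalog(
    profiles: pd.DataFrame,
    gene_lengths: pd.Series,
    min_length: int = 100,
    min_cov: float = 2.0,
    min_samples_at_cov: int = 1,
) -> pd.DataFrame:
    """Drop genes shorter than ``min_length`` or never reaching ``min_cov``.

    A gene is preserved if its fold-coverage is at least ``min_cov`` in at
    least ``min_samples_at_cov`` samples.
    """
    lengths = gene_lengths.reindex(profiles.index)
    keep_len = lengths >= min_length
    keep_cov = (profiles >= min_cov).sum(axis=1) >= min_samples_at_cov
    return profiles.loc[keep_len & keep_cov]


def split_zero_variance(profiles: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Separate profiles with zero variance (correlation undefined)."""
    variances = profiles.var(axis=1, ddof=0)
    bad = profiles.index[variances == 0].tolist()
    return profiles.drop(index=bad), bad


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def pearson_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - Pearson correlation; in [0, 2]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise UndefinedCorrelationError("need >= 3 samples")
    if a.std() == 0 or b.std() == 0:
        raise UndefinedCorrelationError("zero-variance profile")
    r = np.corrcoef(a, b)[0, 1]
    return float(1.0 - r)


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    """Center rows and scale to unit norm so correlation is a dot product."""
    centered = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    if (norms == 0).any():
        raise UndefinedCorrelationError("zero-variance profile present")
    return centered / norms


def _distances_to(Z: np.ndarray, center: np.ndarray) -> np.ndarray:
    c = center - center.mean()
    norm = np.linalg.norm(c)
    if norm == 0:
        raise UndefinedCorrelationError("zero-variance center")
    return 1.0 - Z @ (c / norm)


# ---------------------------------------------------------------------------
# canopy clustering
# ---------------------------------------------------------------------------

def canopy_cluster(
    profiles: pd.DataFrame,
    max_canopy_dist: float = 0.1,
    max_close_dist: float = 0.4,
    max_merge_dist: float = 0.1,
    min_step_dist: float = 0.005,
    stop_fraction: float = 1.0,
    seed: int | None = None,
    random_order: bool = False,
    center_statistic: str = "median",
) -> list[Canopy]:
    """Cluster gene abundance profiles into canopies.

    Genes are visited as seed origins in deterministic order (descending
    total coverage, ties by gene id); already-assigned genes are skipped.
    A canopy gathers all unassigned genes within ``max_canopy_dist`` of the
    origin profile, recomputes its center as the element-wise median (or
    mean) of member profiles, and repeats gather/recenter until the center
    moves less than ``min_step_dist`` or ``MAX_RECENTER_ITERATIONS`` passes.
    ``close_members`` are all genes within ``max_close_dist`` of the final
    center. Seeding stops once the assigned fraction reaches
    ``stop_fraction``. Finally, canopies whose centers lie within
    ``max_merge_dist`` are merged by single linkage; members are unioned
    and the center recomputed once.
    """
    if profiles.empty:
        return []
    if center_statistic not in ("median", "mean"):
        raise ValueError("center_statistic must be 'median' or 'mean'")

    X = profiles.to_numpy(dtype=float)
    ids = np.array(profiles.index)
    Z = _standardize_rows(X)
    n = len(ids)

    if random_order:
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
    else:
        totals = X.sum(axis=1)
        order = np.lexsort((ids, -totals))

    center_fn = np.median if center_statistic == "median" else np.mean
    assigned = np.zeros(n, dtype=bool)
    raw: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []  # (center, member_idx, close_idx)

    for origin in order:
        if assigned.sum() / n >= stop_fraction and raw:
            break
        if assigned[origin]:
            continue
        center = X[origin].astype(float)
        members = np.array([origin])
        for _ in range(MAX_RECENTER_ITERATIONS):
            dists = _distances_to(Z, center)
            candidates = np.where((dists <= max_canopy_dist) & ~assigned)[0]
            if candidates.size == 0:
                candidates = np.array([origin])
            members = candidates
            new_center = center_fn(X[members], axis=0)
            if new_center.std() == 0:
                break
            if pearson_distance(new_center, center) < min_step_dist:
                center = new_center
                break
            center = new_center
        dists = _distances_to(Z, center)
        close = np.where(dists <= max_close_dist)[0]
        close = np.union1d(close, members)  # members are close by construction
        assigned[members] = True
        raw.append((center, members, close))

    merged = _merge_canopies(raw, X, max_merge_dist, max_close_dist, Z, center_fn)
    canopies = []
    for i, (center, members, close) in enumerate(merged):
        canopies.append(Canopy(
            canopy_id=f"canopy{i:05d}",
            center=center,
            members=sorted(ids[members]),
            close_members=sorted(ids[close]),
        ))
    return canopies


def _merge_canopies(raw, X, max_merge_dist, max_close_dist, Z, center_fn):
    """Single-linkage merge of canopies whose centers are within threshold."""
    k = len(raw)
    if k <= 1:
        return raw
    parent = list(range(k))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    centers = [c for c, _, _ in raw]
    for i in range(k):
        for j in range(i + 1, k):
            try:
                d = pearson_distance(centers[i], centers[j])
            except UndefinedCorrelationError:
                continue
            if d <= max_merge_dist:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(k):
        groups.setdefault(find(i), []).append(i)

    out = []
    # keep deterministic output order: by first constituent canopy index
    for root in sorted(groups, key=lambda r: min(groups[r])):
        idxs = groups[root]
        if len(idxs) == 1:
            out.append(raw[idxs[0]])
            continue
        members = np.unique(np.concatenate([raw[i][1] for i in idxs]))
        center = center_fn(X[members], axis=0)
        if center.std() > 0:
            close = np.where(_distances_to(Z, center) <= max_close_dist)[0]
            close = np.union1d(close, members)
        else:
            close = np.unique(np.concatenate([raw[i][2] for i in idxs]))
        out.append((center, members, close))
    return out


# ---------------------------------------------------------------------------
# MGS calling and helpers
# ---------------------------------------------------------------------------

def call_mgs(canopies: list[Canopy], min_genes: int = 700) -> list[MGS]:
    """Promote canopies with at least ``min_genes`` members to MGS."""
    qualifying = [c for c in canopies if len(c.members) >= min_genes]
    qualifying.sort(key=lambda c: (-len(c.members), c.canopy_id))
    return [MGS(f"MGS{i:05d}", list(c.members), [c.canopy_id])
            for i, c in enumerate(qualifying)]


def mgs_to_contig_labels(
    mgs: MGS, gene_to_contig: dict[str, str]
) -> tuple[set[str], list[str]]:
    """Contigs encoding at least one MGS gene, plus genes without a mapping."""
    flagged: set[str] = set()
    unplaced: list[str] = []
    for gid in mgs.member_gene_ids:
        contig = gene_to_contig.get(gid)
        if contig is None:
            unplaced.append(gid)
        else:
            flagged.add(contig)
    return flagged, unplaced


def best_sample_for_mgs(mgs: MGS, coverage: pd.DataFrame) -> str:
    """Sample with the highest mean coverage of the MGS genes (ties: id order)."""
    sub = coverage.loc[coverage.index.intersection(mgs.member_gene_ids)]
    means = sub.mean(axis=0)
    best = means.max()
    return sorted(means.index[means == best])[0]


def canopy_assignments_frame(canopies: list[Canopy]) -> pd.DataFrame:
    rows = []
    for c in canopies:
        member_set = set(c.members)
        for gid in c.close_members:
            rows.append((gid, c.canopy_id, int(gid not in member_set)))
    return pd.DataFrame(rows, columns=["gene_id", "canopy_id", "is_close_only"])


def mgs_summary_frame(mgs_list: list[MGS], coverage: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for m in mgs_list:
        sub = coverage.loc[coverage.index.intersection(m.member_gene_ids)]
        row = {"mgs_id": m.mgs_id, "n_genes": m.n_genes}
        row.update({f"mean_cov_{s}": v for s, v in sub.mean(axis=0).items()})
        rows.append(row)
    return pd.DataFrame(rows)
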