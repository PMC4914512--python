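"""Chunking, canonical k-mer signatures, and 2D embedding of contigs.

Contigs below a minimum length are dropped; longer contigs are cut into
fixed-size chunks so that well-assembled genomes do not collapse into a
handful of points. Each chunk gets a canonical (reverse-complement merged)
k-mer frequency signature, a centered log-ratio transform, and a 2D
Barnes-Hut t-SNE embedding after a linear (PCA) pre-reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .errors import (
    DegenerateInputError,
    InvalidParameterError,
    SequenceLengthError,
    TooFewPointsError,
)

ALPHA_MIN = 0.05

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


@dataclass(frozen=True)
class Chunk:
    chunk_id: str
    parent_contig: str
    start: int        # 0-based offset on the parent contig
    length: int
    sequence: str

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class SignatureMatrix:
    """CLR-transformed canonical k-mer signatures, one row per chunk."""

    ids: list[str]
    kmers: list[str]
    values: np.ndarray  # (n_chunks, n_canonical_kmers)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.ids), len(self.kmers)):
            raise InvalidParameterError("signature matrix shape mismatch")


@dataclass
class EmbeddingPoint:
    chunk_id: str
    x: float
    y: float
    label: str | None = None
    is_marker: bool = False
    alpha: float = 1.0


# ---------------------------------------------------------------------------
# chunking
# ---------------------------------------------------------------------------

def filter_and_chunk(
    contigs: dict[str, str],
    min_length: int = 1_000,
    chunk_size: int = 5_000,
    merge_tail: bool = False,
) -> list[Chunk]:
    """Drop short contigs and cut the rest into fixed-size chunks.

    A contig shorter than ``min_length`` is omitted. A contig of at most
    ``chunk_size`` is emitted whole. Longer contigs are cut left-to-right
    into ``chunk_size`` pieces as long as the remainder is at least
    ``chunk_size``; the entire remainder then becomes the final chunk. This
    literal rule can emit a very short tail (a 5,001 nt contig yields
    chunks of 5,000 and 1 nt); ``merge_tail=True`` folds tails shorter
    than ``min_length`` into the previous chunk instead.
    """
    chunks: list[Chunk] = []
    for contig_id, seq in contigs.items():
        n = len(seq)
        if n < min_length:
            continue
        if n <= chunk_size:
            chunks.append(Chunk(f"{contig_id}|0", contig_id, 0, n, seq))
            continue
        pos = 0
        parts: list[tuple[int, int]] = []
        while n - pos >= chunk_size:
            parts.append((pos, chunk_size))
            pos += chunk_size
        if pos < n:
            parts.append((pos, n - pos))
        if merge_tail and len(parts) > 1 and parts[-1][1] < min_length:
            tail = parts.pop()
            prev = parts.pop()
            parts.append((prev[0], prev[1] + tail[1]))
        for start, length in parts:
            chunks.append(Chunk(f"{contig_id}|{start}", contig_id, start, length,
                                seq[start:start + length]))
    return chunks


def chunk_map_frame(chunks: list[Chunk]) -> pd.DataFrame:
    """BED-like table (parent, start, end, chunk_id; 0-based half-open)."""
    return pd.DataFrame(
        [(c.parent_contig, c.start, c.end, c.chunk_id) for c in chunks],
        columns=["parent_contig", "start", "end", "chunk_id"],
    )


# ---------------------------------------------------------------------------
# k-mer signatures
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _canonical_table(k: int) -> tuple[np.ndarray, list[str]]:
    """Map each of the 4^k k-mer codes to a canonical column index.

    A k-mer is pooled with its reverse complement under the
    lexicographically smaller of the two.
    """
    n = 4 ** k
    codes = np.arange(n)
    digits = np.empty((k, n), dtype=np.int64)
    tmp = codes.copy()
    for i in range(k - 1, -1, -1):
        digits[i] = tmp % 4
        tmp //= 4
    rc_digits = 3 - digits[::-1]
    rc = np.zeros(n, dtype=np.int64)
    for i in range(k):
        rc = rc * 4 + rc_digits[i]
    canon_code = np.minimum(codes, rc)
    uniq = np.unique(canon_code)
    col = np.searchsorted(uniq, canon_code)
    bases = "ACGT"
    kmers = []
    for code in uniq:
        s, c = [], int(code)
        for _ in range(k):
            s.append(bases[c % 4])
            c //= 4
        kmers.append("".join(reversed(s)))
    return col, kmers


def canonical_kmers(k: int) -> list[str]:
    """Sorted canonical k-mer vocabulary for the given k."""
    return list(_canonical_table(k)[1])


def kmer_frequencies(sequence: str, k: int = 5, canonical: bool = True) -> np.ndarray:
    """Relative frequencies of (canonical) k-mers over sliding windows.

    Windows containing non-ACGT characters are skipped; counts are
    normalised to sum to one.
    """
    if len(sequence) < k:
        raise SequenceLengthError(f"sequence length {len(sequence)} < k={k}")
    arr = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    windows = sliding_window_view(arr, k)
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        raise DegenerateInputError("no unambiguous k-mer window in sequence")
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = windows[valid] @ powers
    if canonical:
        col, kmers = _canonical_table(k)
        counts = np.bincount(col[codes], minlength=len(kmers)).astype(float)
    else:
        counts = np.bincount(codes, minlength=4 ** k).astype(float)
    return counts / counts.sum()


def clr_transform(freq_vector: np.ndarray, pseudo_fraction: float = 0.65) -> np.ndarray:
    """Centered log-ratio transform with multiplicative zero replacement.

    Zeros become ``pseudo_fraction`` times the smallest nonzero component;
    the vector is renormalised and each component replaced by
    log(component) minus the mean of logs, so the output sums to zero.
    """
    v = np.asarray(freq_vector, dtype=float)
    if (v < 0).any():
        raise InvalidParameterError("frequency vector must be non-negative")
    if not v.any():
        raise DegenerateInputError("all-zero frequency vector")
    v = v / v.sum()
    zero = v == 0
    if zero.any():
        v = v.copy()
        v[zero] = pseudo_fraction * v[~zero].min()
        v = v / v.sum()
    logs = np.log(v)
    return logs - logs.mean()


def signature_matrix(
    chunks: list[Chunk],
    k: int = 5,
    canonical: bool = True,
    pseudo_fraction: float = 0.65,
) -> SignatureMatrix:
    """Build the CLR-transformed signature matrix for a chunk set."""
    rows = [clr_transform(kmer_frequencies(c.sequence, k, canonical), pseudo_fraction)
            for c in chunks]
    kmers = canonical_kmers(k) if canonical else ["".join(p) for p in product("ACGT", repeat=k)]
    return SignatureMatrix([c.chunk_id for c in chunks], kmers,
                           np.vstack(rows) if rows else np.empty((0, len(kmers))))


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------

def embed_signatures(
    matrix: SignatureMatrix,
    pca_dims: int = 50,
    perplexity: float = 30.0,
    seed: int = 0,
    n_iter: int = 1_000,
) -> pd.DataFrame:
    """2D Barnes-Hut t-SNE of the signature matrix after PCA pre-reduction.

    Perplexity is auto-lowered to floor((rows - 1) / 3) when the input is
    too small for the requested value. Deterministic for a given seed.
    Returns a frame indexed by chunk_id with columns x, y.
    """
    n = len(matrix.ids)
    if n < 4:
        raise TooFewPointsError(f"need >= 4 points to embed, got {n}")
    max_perp = (n - 1) // 3
    perplexity = float(min(perplexity, max_perp))
    X = matrix.values
    dims = min(pca_dims, X.shape[1], n)
    X = PCA(n_components=dims, random_state=seed).fit_transform(X)
    ts = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        random_state=seed,
        max_iter=max(n_iter, 250),
        method="barnes_hut",
    )
    coords = ts.fit_transform(X)
    return pd.DataFrame(coords, index=pd.Index(matrix.ids, name="chunk_id"),
                        columns=["x", "y"])


def coverage_alpha(fold_coverage: np.ndarray, alpha_min: float = ALPHA_MIN) -> np.ndarray:
    """Opaqueness from coverage: ln(1 + c) scaled by the set maximum.

    alpha = clip(ln(1 + c) / ln(1 + max c), alpha_min, 1]; all-zero
    coverage yields alpha_min everywhere.
    """
    c = np.asarray(fold_coverage, dtype=float)
    if (c < 0).any():
        raise InvalidParameterError("coverage must be non-negative")
    cmax = c.max() if c.size else 0.0
    if cmax == 0:
        return np.full(c.shape, alpha_min)
    alpha = np.log1p(c) / np.log1p(cmax)
    return np.clip(alpha, alpha_min, 1.0)


def points_frame(
    chunks: list[Chunk],
    coords: pd.DataFrame,
    labels: dict[str, str] | None = None,
    markers: set[str] | None = None,
    coverage: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Assemble the points table written by the embed stage.

    ``labels`` and ``markers`` are keyed by parent contig id; ``coverage``
    holds per-contig fold-coverage used for point opaqueness.
    """
    labels = labels or {}
    markers = markers or set()
    rows = []
    for c in chunks:
        rows.append({
            "chunk_id": c.chunk_id,
            "parent_contig": c.parent_contig,
            "x": float(coords.loc[c.chunk_id, "x"]),
            "y": float(coords.loc[c.chunk_id, "y"]),
            "label": labels.get(c.parent_contig, ""),
            "is_marker": int(c.parent_contig in markers),
        })
    frame = pd.DataFrame(rows)
    if coverage is not None:
        cov = np.array([coverage.get(c.parent_contig, 0.0) for c in chunks])
        frame["alpha"] = coverage_alpha(cov)
    else:
        frame["alpha"] = 1.0
    return frame


def write_points(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")


def plot_points(frame: pd.DataFrame, path: str | Path) -> None:
    """Optional scatter plot of an embedding (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 7))
    for label, sub in frame.groupby(frame["label"].replace("", "unlabelled")):
        ax.scatter(sub["x"], sub["y"], s=12, alpha=0.6, label=str(label))
    stars = frame[frame["is_marker"] == 1]
    if len(stars):
        ax.scatter(stars["x"], stars["y"], marker="*", s=220, c="black")
    ax.legend(fontsize=7)
    fig.savefig(path, dpi=150)
    plt.close(fig)
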