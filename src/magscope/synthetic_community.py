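"""Ground-truthed synthetic multi-genome communities.

Generates genomes with distinct base composition, fragments them into
contigs, tiles genes along each genome, and simulates per-gene and
per-contig fold-coverage across samples with within-genome co-abundance.
Single-copy marker families, taxon annotations and near-duplicate gene
copies can be planted so that every downstream stage of the toolkit can be
scored against known truth.

All randomness flows through :func:`numpy.random.default_rng` seeded
explicitly; every operation is bit-reproducible for a given seed.
Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

_BASES = np.array(["A", "C", "G", "T"])


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeModel:
    """Parameters of one synthetic genome."""

    genome_id: str
    gc_target: float
    length: int
    n_genes: int
    is_target_taxon: bool = False

    def __post_init__(self) -> None:
        if self.length < 10_000:
            raise InvalidParameterError(f"genome length must be >= 10000, got {self.length}")
        if not 0.2 <= self.gc_target <= 0.8:
            raise InvalidParameterError(f"gc_target must be in [0.2, 0.8], got {self.gc_target}")
        if self.n_genes < 1:
            raise InvalidParameterError("n_genes must be >= 1")


@dataclass(frozen=True)
class CommunitySpec:
    """Full description of a synthetic community simulation."""

    genomes: tuple[GenomeModel, ...]
    n_samples: int
    abundance_log_mean: float = 2.5
    abundance_log_sd: float = 1.0
    gene_noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "genomes", tuple(self.genomes))
        if self.n_samples < 2:
            raise InvalidParameterError("n_samples must be >= 2")
        if self.gene_noise_cv < 0:
            raise InvalidParameterError("gene_noise_cv must be >= 0")
        if len(self.genomes) < 1:
            raise InvalidParameterError("at least one genome required")

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i:02d}" for i in range(self.n_samples)]


@dataclass
class Contig:
    contig_id: str
    genome_id: str
    start: int  # 0-based, on the source genome
    end: int    # half-open
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Gene:
    gene_id: str
    genome_id: str
    start: int
    end: int
    sequence: str
    contig_id: str | None = None
    strand: str = "+"
    has_start: bool = True
    has_stop: bool = True

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GroundTruth:
    """Planted truth used for scoring downstream stages."""

    contig_to_genome: dict[str, str] = field(default_factory=dict)
    gene_to_genome: dict[str, str] = field(default_factory=dict)
    marker_placements: dict[str, str] = field(default_factory=dict)
    duplicate_pairs: list[tuple[str, str, float]] = field(default_factory=list)


@dataclass
class Community:
    """A fully realised synthetic community plus its ground truth."""

    spec: CommunitySpec
    genome_sequences: dict[str, str]
    contigs: list[Contig]
    genes: list[Gene]
    gene_coverage: pd.DataFrame      # gene_id x sample
    contig_coverage: pd.DataFrame    # contig_id x sample
    abundance: pd.DataFrame          # genome_id x sample
    truth: GroundTruth
    marker_hits: pd.DataFrame | None = None     # gene_id, family_id
    taxonomy: pd.DataFrame | None = None        # gene_id, taxon, confidence

    @property
    def gene_to_contig(self) -> dict[str, str]:
        return {g.gene_id: g.contig_id for g in self.genes if g.contig_id is not None}

    @property
    def gene_lengths(self) -> pd.Series:
        return pd.Series({g.gene_id: g.length for g in self.genes}, name="length")

    def contigs_of_genome(self, genome_id: str) -> list[str]:
        return [c.contig_id for c in self.contigs if c.genome_id == genome_id]


# ---------------------------------------------------------------------------
# sequence-level operations
# ---------------------------------------------------------------------------

def generate_genome_sequence(gc_target: float, length: int, seed: int) -> str:
    """Draw an i.i.d. base sequence with expected GC content ``gc_target``.

    P(G) = P(C) = gc_target / 2 and P(A) = P(T) = (1 - gc_target) / 2.
    An order-0 model is sufficient for composition-based separability;
    higher-order chains would slot in here if ever needed.
    """
    if not 0.0 < gc_target < 1.0:
        raise InvalidParameterError(f"gc_target must be in (0, 1), got {gc_target}")
    if length < 1:
        raise InvalidParameterError("length must be positive")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_target) / 2.0
    gc = gc_target / 2.0
    idx = rng.choice(4, size=length, p=[at, gc, gc, at])
    return "".join(_BASES[idx])


def fragment_into_contigs(
    sequence: str,
    mean_len: int,
    min_len: int,
    seed: int,
    *,
    genome_id: str = "genome",
    lognormal_sigma: float = 0.5,
) -> list[Contig]:
    """Tile a genome left-to-right into non-overlapping contigs.

    Contig lengths are lognormal with mean ~``mean_len``, truncated below
    at ``min_len``; the final remainder (shorter than ``min_len``) is
    appended to the last contig so lengths always sum to the genome length.
    """
    if min_len < 500:
        raise InvalidParameterError("min_len must be >= 500")
    if mean_len < min_len:
        raise InvalidParameterError("mean_len must be >= min_len")
    rng = np.random.default_rng(seed)
    total = len(sequence)
    if total <= min_len:
        return [Contig(f"{genome_id}_c0000", genome_id, 0, total, sequence)]

    mu = np.log(mean_len) - lognormal_sigma**2 / 2.0
    bounds: list[int] = []
    pos = 0
    while total - pos > min_len:
        draw = int(round(rng.lognormal(mu, lognormal_sigma)))
        length = max(min_len, draw)
        if total - pos - length <= min_len:
            length = total - pos  # absorb the remainder
        bounds.append(length)
        pos += length
    if pos < total:  # leftover shorter than min_len -> extend last contig
        bounds[-1] += total - pos

    contigs = []
    start = 0
    for i, length in enumerate(bounds):
        contigs.append(
            Contig(f"{genome_id}_c{i:04d}", genome_id, start, start + length,
                   sequence[start:start + length])
        )
        start += length
    return contigs


def _tile_genes(genome: GenomeModel, sequence: str) -> list[Gene]:
    # genes tiled end-to-end; trailing residue left intergenic
    glen = len(sequence) // genome.n_genes
    genes = []
    for i in range(genome.n_genes):
        s, e = i * glen, (i + 1) * glen
        genes.append(Gene(f"{genome.genome_id}_g{i:04d}", genome.genome_id, s, e,
                          sequence[s:e]))
    return genes


def _assign_genes_to_contigs(genes: list[Gene], contigs: list[Contig]) -> None:
    """Place each gene on the contig containing its midpoint."""
    edges = np.array([c.end for c in contigs])
    for g in genes:
        mid = (g.start + g.end) // 2
        idx = int(np.searchsorted(edges, mid, side="right"))
        g.contig_id = contigs[min(idx, len(contigs) - 1)].contig_id


# ---------------------------------------------------------------------------
# coverage simulation
# ---------------------------------------------------------------------------

def simulate_abundances(spec: CommunitySpec, rng: np.random.Generator) -> pd.DataFrame:
    """Per genome-sample lognormal abundances, independent across samples."""
    a = rng.lognormal(spec.abundance_log_mean, spec.abundance_log_sd,
                      size=(len(spec.genomes), spec.n_samples))
    return pd.DataFrame(a, index=[g.genome_id for g in spec.genomes],
                        columns=spec.sample_ids)


def _noisy_rows(base: np.ndarray, cv: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """n rows of base * max(0, 1 + eps), eps ~ Normal(0, cv)."""
    if cv == 0:
        return np.tile(base, (n, 1))
    eps = rng.normal(0.0, cv, size=(n, base.size))
    return base * np.maximum(0.0, 1.0 + eps)


def simulate_gene_coverages(
    spec: CommunitySpec,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the gene x sample fold-coverage table alone.

    Gene coverage is the genome-sample abundance scaled by multiplicative
    gene noise truncated at zero, so genes of one genome co-vary across
    samples while genomes stay independent.
    """
    rng = np.random.default_rng(spec.seed)
    abundance = simulate_abundances(spec, rng)
    truth = GroundTruth()
    rows, ids = [], []
    for genome in spec.genomes:
        base = abundance.loc[genome.genome_id].to_numpy()
        rows.append(_noisy_rows(base, spec.gene_noise_cv, genome.n_genes, rng))
        for i in range(genome.n_genes):
            gid = f"{genome.genome_id}_g{i:04d}"
            ids.append(gid)
            truth.gene_to_genome[gid] = genome.genome_id
    table = pd.DataFrame(np.vstack(rows), index=ids, columns=spec.sample_ids)
    table.index.name = "gene_id"
    return table, truth


def simulate_community(
    spec: CommunitySpec,
    *,
    mean_contig_len: int = 5_000,
    min_contig_len: int = 500,
) -> Community:
    """Realise genomes, contigs, genes and coverages for ``spec``."""
    rng = np.random.default_rng(spec.seed)
    abundance = simulate_abundances(spec, rng)
    truth = GroundTruth()

    genome_sequences: dict[str, str] = {}
    contigs: list[Contig] = []
    genes: list[Gene] = []
    gene_rows, gene_ids = [], []
    contig_rows, contig_ids = [], []

    for genome in spec.genomes:
        seq_seed = int(rng.integers(0, 2**31))
        frag_seed = int(rng.integers(0, 2**31))
        seq = generate_genome_sequence(genome.gc_target, genome.length, seq_seed)
        genome_sequences[genome.genome_id] = seq

        g_contigs = fragment_into_contigs(seq, mean_contig_len, min_contig_len,
                                          frag_seed, genome_id=genome.genome_id)
        g_genes = _tile_genes(genome, seq)
        _assign_genes_to_contigs(g_genes, g_contigs)
        contigs.extend(g_contigs)
        genes.extend(g_genes)

        base = abundance.loc[genome.genome_id].to_numpy()
        gene_rows.append(_noisy_rows(base, spec.gene_noise_cv, len(g_genes), rng))
        contig_rows.append(_noisy_rows(base, spec.gene_noise_cv, len(g_contigs), rng))
        for g in g_genes:
            gene_ids.append(g.gene_id)
            truth.gene_to_genome[g.gene_id] = genome.genome_id
        for c in g_contigs:
            contig_ids.append(c.contig_id)
            truth.contig_to_genome[c.contig_id] = genome.genome_id

    gene_coverage = pd.DataFrame(np.vstack(gene_rows), index=gene_ids,
                                 columns=spec.sample_ids)
    gene_coverage.index.name = "gene_id"
    contig_coverage = pd.DataFrame(np.vstack(contig_rows), index=contig_ids,
                                   columns=spec.sample_ids)
    contig_coverage.index.name = "contig_id"

    return Community(spec, genome_sequences, contigs, genes,
                     gene_coverage, contig_coverage, abundance, truth)


# ---------------------------------------------------------------------------
# planting: markers, duplicates, taxonomy, partial genes
# ---------------------------------------------------------------------------

def plant_marker_families(
    truth: GroundTruth,
    n_families: int = 107,
    contamination_copies: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Label single-copy marker families on the planted genes.

    Each genome receives one gene per family for ``n_families`` families
    (shared family ids across genomes, so a bin merging two genomes shows
    every family in two copies). ``contamination_copies`` extra copies of
    distinct families are planted on the first genome, each labelled on a
    previously unlabelled gene, raising that genome's multicopy count by
    exactly that amount. Updates ``truth.marker_placements`` in place and
    returns the hit table (gene_id, family_id).
    """
    rng = np.random.default_rng(seed)
    genomes: dict[str, list[str]] = {}
    for gid, genome in truth.gene_to_genome.items():
        genomes.setdefault(genome, []).append(gid)
    for genome, gids in genomes.items():
        need = n_families + (contamination_copies if genome == sorted(genomes)[0] else 0)
        if len(gids) < need:
            raise InvalidParameterError(
                f"genome {genome} has {len(gids)} genes, needs >= {need}")

    families = [f"fam{i:03d}" for i in range(n_families)]
    records: list[tuple[str, str]] = []
    for genome in sorted(genomes):
        gids = sorted(genomes[genome])
        picked = rng.choice(len(gids), size=n_families, replace=False)
        for fam, i in zip(families, picked):
            records.append((gids[i], fam))
            truth.marker_placements[gids[i]] = fam
        if genome == sorted(genomes)[0] and contamination_copies > 0:
            if contamination_copies > n_families:
                raise InvalidParameterError(
                    "contamination_copies cannot exceed n_families")
            unlabeled = [g for g in gids if g not in truth.marker_placements]
            if len(unlabeled) < contamination_copies:
                raise InvalidParameterError("too few unlabeled genes for contamination")
            for j in range(contamination_copies):
                records.append((unlabeled[j], families[j]))
                truth.marker_placements[unlabeled[j]] = families[j]
    table = pd.DataFrame(records, columns=["gene_id", "family_id"])
    return table


def plant_near_duplicates(
    genes: dict[str, str],
    identity_target: float,
    n_pairs: int,
    seed: int = 0,
) -> tuple[dict[str, str], list[tuple[str, str, float]]]:
    """Create mutated copies of ``n_pairs`` genes at a planted identity.

    Each copy differs from its source by ``round(len * (1 - identity))``
    point substitutions at uniformly chosen distinct positions.
    """
    if not 0 < identity_target <= 1:
        raise InvalidParameterError("identity_target must be in (0, 1]")
    if identity_target < 0.5:
        raise InvalidParameterError("identity_target < 0.5 is outside the tool's range")
    if n_pairs > len(genes):
        raise InvalidParameterError("n_pairs exceeds number of genes")
    rng = np.random.default_rng(seed)
    ids = sorted(genes)
    chosen = rng.choice(len(ids), size=n_pairs, replace=False)
    dups: dict[str, str] = {}
    pairs: list[tuple[str, str, float]] = []
    for i in chosen:
        src_id = ids[int(i)]
        seq = list(genes[src_id])
        n_sub = int(round(len(seq) * (1.0 - identity_target)))
        if n_sub > 0:
            positions = rng.choice(len(seq), size=n_sub, replace=False)
            for p in positions:
                alt = [b for b in "ACGT" if b != seq[p]]
                seq[p] = alt[int(rng.integers(0, 3))]
        dup_id = f"{src_id}_dup"
        dups[dup_id] = "".join(seq)
        pairs.append((src_id, dup_id, identity_target))
    return dups, pairs


def annotate_taxa(
    community: Community,
    target_taxon: str = "Cyanobacteria",
    n_marker_genes: int = 5,
    confidence: float = 0.9,
    seed: int = 0,
    background_taxa: tuple[str, ...] = ("Firmicutes", "Bacteroidetes", "Proteobacteria"),
) -> pd.DataFrame:
    """Attach per-gene taxon annotations with confidences.

    The first ``n_marker_genes`` genes of every ``is_target_taxon`` genome
    are labelled ``target_taxon`` at the given confidence; one extra target
    gene gets a sub-threshold confidence (0.5) to exercise the filter.
    Background genes receive rotating background taxa at confidence 0.8.
    The table is stored on ``community.taxonomy`` and returned.
    """
    rng = np.random.default_rng(seed)
    records = []
    for genome in community.spec.genomes:
        gids = sorted(g.gene_id for g in community.genes
                      if g.genome_id == genome.genome_id)
        if genome.is_target_taxon:
            for gid in gids[:n_marker_genes]:
                records.append((gid, target_taxon, confidence))
            if len(gids) > n_marker_genes:
                records.append((gids[n_marker_genes], target_taxon, 0.5))
            rest = gids[n_marker_genes + 1:]
        else:
            rest = gids
        for gid in rest:
            taxon = background_taxa[int(rng.integers(0, len(background_taxa)))]
            records.append((gid, taxon, 0.8))
    table = pd.DataFrame(records, columns=["gene_id", "taxon", "confidence"])
    community.taxonomy = table
    return table


def mark_partial_genes(community: Community, gene_ids: list[str]) -> None:
    """Flag listed genes as lacking a stop codon (incomplete predictions)."""
    wanted = set(gene_ids)
    for g in community.genes:
        if g.gene_id in wanted:
            g.has_stop = False


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_fasta(path: Path, records: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def write_community(community: Community, outdir: str | Path) -> Path:
    """Persist a community as plain-text FASTA/TSV plus a JSON sidecar."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    write_fasta(out / "contigs.fasta", {c.contig_id: c.sequence for c in community.contigs})
    write_fasta(out / "genes.fasta", {g.gene_id: g.sequence for g in community.genes})

    cov = community.gene_coverage.copy()
    cov.insert(0, "length", community.gene_lengths.reindex(cov.index))
    cov.to_csv(out / "gene_coverage.tsv", sep="\t")
    community.contig_coverage.to_csv(out / "contig_coverage.tsv", sep="\t")

    meta = pd.DataFrame(
        [(g.gene_id, g.contig_id, g.start, g.end, g.strand,
          int(g.has_start), int(g.has_stop), g.genome_id) for g in community.genes],
        columns=["gene_id", "contig_id", "start", "end", "strand",
                 "has_start", "has_stop", "genome_id"],
    )
    meta.to_csv(out / "gene_meta.tsv", sep="\t", index=False)

    pd.DataFrame(sorted(community.truth.contig_to_genome.items()),
                 columns=["contig_id", "genome_id"]).to_csv(
        out / "contig_truth.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(community.truth.gene_to_genome.items()),
                 columns=["gene_id", "genome_id"]).to_csv(
        out / "gene_truth.tsv", sep="\t", index=False)

    if community.marker_hits is not None:
        community.marker_hits.to_csv(out / "marker_hits.tsv", sep="\t", index=False)
    if community.taxonomy is not None:
        community.taxonomy.to_csv(out / "taxonomy.tsv", sep="\t", index=False)

    sidecar = {
        "seed": community.spec.seed,
        "n_samples": community.spec.n_samples,
        "abundance_log_mean": community.spec.abundance_log_mean,
        "abundance_log_sd": community.spec.abundance_log_sd,
        "gene_noise_cv": community.spec.gene_noise_cv,
        "genomes": [
            {"genome_id": g.genome_id, "gc_target": g.gc_target, "length": g.length,
             "n_genes": g.n_genes, "is_target_taxon": g.is_target_taxon}
            for g in community.spec.genomes
        ],
    }
    with open(out / "community.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return out


def _read_fasta(path: Path) -> dict[str, str]:
    records: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                records[name] = []
            else:
                records[name].append(line)
    return {k: "".join(v) for k, v in records.items()}


def load_community(indir: str | Path) -> Community:
    """Reload a community persisted by :func:`write_community`.

    Also accepts equivalently formatted real data directories; the genome
    sequences themselves are not round-tripped (downstream stages never
    need them).
    """
    indir = Path(indir)
    spec = spec_from_json(indir / "community.json")
    contig_seqs = _read_fasta(indir / "contigs.fasta")
    gene_seqs = _read_fasta(indir / "genes.fasta")

    contig_truth = pd.read_csv(indir / "contig_truth.tsv", sep="\t")
    gene_truth = pd.read_csv(indir / "gene_truth.tsv", sep="\t")
    truth = GroundTruth(
        contig_to_genome=dict(zip(contig_truth["contig_id"], contig_truth["genome_id"])),
        gene_to_genome=dict(zip(gene_truth["gene_id"], gene_truth["genome_id"])),
    )

    meta = pd.read_csv(indir / "gene_meta.tsv", sep="\t")
    genes = [
        Gene(r.gene_id, r.genome_id, int(r.start), int(r.end),
             gene_seqs[r.gene_id], contig_id=r.contig_id, strand=r.strand,
             has_start=bool(r.has_start), has_stop=bool(r.has_stop))
        for r in meta.itertuples(index=False)
    ]
    contigs = [
        Contig(cid, truth.contig_to_genome.get(cid, ""), 0, len(seq), seq)
        for cid, seq in contig_seqs.items()
    ]

    gene_cov = pd.read_csv(indir / "gene_coverage.tsv", sep="\t", index_col=0)
    gene_cov = gene_cov.drop(columns=["length"], errors="ignore")
    contig_cov = pd.read_csv(indir / "contig_coverage.tsv", sep="\t", index_col=0)

    community = Community(spec, {}, contigs, genes, gene_cov, contig_cov,
                          pd.DataFrame(), truth)
    markers = indir / "marker_hits.tsv"
    if markers.exists():
        community.marker_hits = pd.read_csv(markers, sep="\t")
        community.truth.marker_placements = dict(
            zip(community.marker_hits["gene_id"], community.marker_hits["family_id"]))
    taxonomy = indir / "taxonomy.tsv"
    if taxonomy.exists():
        community.taxonomy = pd.read_csv(taxonomy, sep="\t")
    return community


def spec_from_json(path: str | Path) -> CommunitySpec:
    """Load a CommunitySpec from the JSON sidecar / config format."""
    with open(path) as fh:
        raw = json.load(fh)
    genomes = tuple(GenomeModel(**g) for g in raw.pop("genomes"))
    return CommunitySpec(genomes=genomes, **raw)
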