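"""Shared-strain detection across draft genomes via ANI graph components.

Draft genomes (metagenome-assembled bins) pass a completeness /
contamination gate, then every retained pair receives an average
nucleotide identity (ANI): the shorter genome is cut into fixed-length
fragments, each fragment is placed on the other genome by exact shared
k-mer anchors and scored by gap-free extension, and the ANI is the mean
identity of fragments mapping at or above the identity floor. Pairs whose
alignment covers less than half the mean genome length or falls below 99%
identity are discarded; the surviving edges are grouped into connected
components, which are the candidate shared strains, and reported with the
suit sites where their members were assembled.

The estimator is substitution-oriented (gap-free extension, no indel
handling); it is calibrated against planted substitution divergence, not
against rearranged or indel-rich genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DraftGenome", "AniParams", "AniEdge", "StrainComponent",
    "qc_gate", "ani_pair", "all_pairs_ani", "filter_edges",
    "strain_components", "write_genomes", "read_genomes",
]

_CODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
    _CODE[b + 32] = i  # lowercase

_SENTINEL = np.uint64(0xFFFFFFFFFFFFFFFF)


@dataclass
class DraftGenome:
    """A binned draft genome with assembly QC metadata."""

    genome_id: str
    sample_id: str
    contigs: list
    completeness: float | None = None
    contamination: float | None = None

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)

    def codes(self) -> np.ndarray:
        """Concatenated 2-bit base codes; contigs separated by sentinels."""
        parts = []
        sep = np.full(32, 4, dtype=np.uint8)
        for i, c in enumerate(self.contigs):
            if i:
                parts.append(sep)
            parts.append(_CODE[np.frombuffer(c.encode("ascii"), dtype=np.uint8)])
        return np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)


@dataclass(frozen=True)
class AniParams:
    fragment_len: int = 1000
    k: int = 16
    min_frag_identity: float = 0.80
    anchor_stride: int = 64


@dataclass(frozen=True)
class AniEdge:
    genome_a: str
    genome_b: str
    ani: float                 # percent identity over mapped fragments
    aligned_fraction: float    # mapped bases / mean(total lengths)
    n_fragments_mapped: int


def qc_gate(genomes, min_completeness: float = 50.0,
            max_contamination: float = 20.0) -> tuple[list, list]:
    """Drop genomes below 50% complete or above 20% contaminated.

    Boundaries are inclusive for retention ("less than" / "more than" are
    strict discards). Returns (retained, rejection log).
    """
    retained, rejected = [], []
    for g in genomes:
        if g.completeness is None or g.contamination is None:
            raise ValueError(f"genome {g.genome_id}: missing completeness/contamination")
        if g.completeness < min_completeness:
            rejected.append((g.genome_id, f"completeness {g.completeness:.1f} < {min_completeness}"))
        elif g.contamination > max_contamination:
            rejected.append((g.genome_id, f"contamination {g.contamination:.1f} > {max_contamination}"))
        else:
            retained.append(g)
    return retained, rejected


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Rolling 2-bit k-mer codes; windows containing non-ACGT -> sentinel."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        out = (out << np.uint64(2)) | codes[j:j + n].astype(np.uint64)
    bad = (codes > 3).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(bad)])
    invalid = (cs[k:] - cs[:-k]) > 0
    out[invalid] = _SENTINEL
    return out


class _RefIndex:
    """Sorted k-mer index of a reference genome for anchor lookups."""

    def __init__(self, codes: np.ndarray, k: int):
        self.codes = codes
        kmers = _kmer_codes(codes, k)
        order = np.argsort(kmers, kind="stable")
        self.sorted_kmers = kmers[order]
        self.positions = order.astype(np.int64)

    def lookup(self, queries: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """First reference position of each query k-mer (-1 if absent)."""
        idx = np.searchsorted(self.sorted_kmers, queries)
        ok = (idx < self.sorted_kmers.size)
        ok[ok] &= self.sorted_kmers[idx[ok]] == queries[ok]
        ok &= queries != _SENTINEL
        pos = np.full(queries.size, -1, dtype=np.int64)
        pos[ok] = self.positions[idx[ok]]
        return pos, ok


def _map_fragments(q_codes: np.ndarray, ref: _RefIndex, params: AniParams,
                   q_kmers: np.ndarray | None = None) -> tuple[np.ndarray, int]:
    """Place non-overlapping query fragments on the reference.

    Returns (identities of mapped fragments, number of fragments cut).
    """
    flen, k, stride = params.fragment_len, params.k, params.anchor_stride
    n_frag = q_codes.size // flen
    if n_frag == 0:
        return np.empty(0), 0
    if q_kmers is None:
        q_kmers = _kmer_codes(q_codes, k)
    offs = np.arange(0, flen - k + 1, stride)
    starts = np.arange(n_frag) * flen
    qpos = (starts[:, None] + offs[None, :]).ravel()
    pos, ok = ref.lookup(q_kmers[qpos])

    r_codes = ref.codes
    idents = []
    n_anchors = offs.size
    for f in range(n_frag):
        sl = slice(f * n_anchors, (f + 1) * n_anchors)
        hit = ok[sl]
        if not hit.any():
            continue
        diags = pos[sl][hit] - (qpos[sl][hit] - starts[f])
        vals, cnts = np.unique(diags, return_counts=True)
        rstart = int(vals[np.argmax(cnts)])
        if rstart < 0 or rstart + flen > r_codes.size:
            continue
        frag = q_codes[starts[f]:starts[f] + flen]
        ref_win = r_codes[rstart:rstart + flen]
        ident = float(np.mean((frag == ref_win) & (frag < 4)))
        if ident >= params.min_frag_identity:
            idents.append(ident)
    return np.asarray(idents), n_frag


def ani_pair(g1: DraftGenome, g2: DraftGenome,
             params: AniParams = AniParams(),
             _index_cache: dict | None = None) -> AniEdge:
    """Fragment-mapping ANI between two draft genomes.

    The shorter genome is always the query, so the estimate is symmetric
    by construction. An unalignable pair yields ani = 0 with zero mapped
    fragments.
    """
    if g1.total_length < params.fragment_len or g2.total_length < params.fragment_len:
        raise ValueError("both genomes must be at least one fragment long")
    # shorter genome queries the longer; deterministic tie-break by id
    if (g1.total_length, g1.genome_id) <= (g2.total_length, g2.genome_id):
        q, r = g1, g2
    else:
        q, r = g2, g1
    if _index_cache is not None and r.genome_id in _index_cache:
        ref = _index_cache[r.genome_id]
    else:
        ref = _RefIndex(r.codes(), params.k)
        if _index_cache is not None:
            _index_cache[r.genome_id] = ref
    idents, _ = _map_fragments(q.codes(), ref, params)
    mean_len = 0.5 * (g1.total_length + g2.total_length)
    if idents.size == 0:
        return AniEdge(g1.genome_id, g2.genome_id, 0.0, 0.0, 0)
    return AniEdge(
        genome_a=g1.genome_id, genome_b=g2.genome_id,
        ani=float(100.0 * idents.mean()),
        aligned_fraction=float(idents.size * params.fragment_len / mean_len),
        n_fragments_mapped=int(idents.size))


def all_pairs_ani(genomes, params: AniParams = AniParams()) -> list:
    """ANI edges for every unordered genome pair.

    Per-genome code arrays, query k-mer streams and reference indexes are
    computed once and shared across pairs, so the all-vs-all cost is
    dominated by anchor lookups rather than re-encoding.
    """
    ordered = sorted(genomes, key=lambda g: (g.total_length, g.genome_id))
    for g in ordered:
        if g.total_length < params.fragment_len:
            raise ValueError(
                f"genome {g.genome_id} is shorter than one fragment")
    codes = {g.genome_id: g.codes() for g in ordered}
    indexes = {g.genome_id: _RefIndex(codes[g.genome_id], params.k)
               for g in ordered}
    edges = []
    for i, q in enumerate(ordered):
        q_codes = codes[q.genome_id]
        q_kmers = _kmer_codes(q_codes, params.k)
        for r in ordered[i + 1:]:
            idents, _ = _map_fragments(q_codes, indexes[r.genome_id],
                                       params, q_kmers=q_kmers)
            mean_len = 0.5 * (q.total_length + r.total_length)
            if idents.size == 0:
                edges.append(AniEdge(q.genome_id, r.genome_id, 0.0, 0.0, 0))
            else:
                edges.append(AniEdge(
                    q.genome_id, r.genome_id,
                    ani=float(100.0 * idents.mean()),
                    aligned_fraction=float(idents.size * params.fragment_len / mean_len),
                    n_fragments_mapped=int(idents.size)))
    return edges


def filter_edges(edges, min_ani: float = 99.0, min_coverage: float = 0.5) -> list:
    """Keep near-identical pairs: ani >= min_ani and coverage >= min_coverage.

    Boundaries are inclusive — only alignments strictly below either
    threshold are discarded.
    """
    return [e for e in edges
            if e.aligned_fraction >= min_coverage and e.ani >= min_ani]


@dataclass
class StrainComponent:
    members: list                  # genome ids
    sites: list                    # (set_id, side, component) per member
    fully_connected: bool
    spans_multiple_samples: bool
    in_control: bool


def strain_components(genomes, edges, metadata: pd.DataFrame | None = None) -> list:
    """Connected components of the filtered identity graph.

    Every retained genome is a node, so singletons appear as single-member
    components. A component is fully connected when every member pair has
    a surviving edge; sites come from sample metadata when provided, and
    components touching a control sample are flagged.
    """
    import networkx as nx

    by_id = {g.genome_id: g for g in genomes}
    graph = nx.Graph()
    graph.add_nodes_from(by_id)
    for e in edges:
        if e.genome_a not in by_id or e.genome_b not in by_id:
            raise ValueError(f"edge references unknown genome: {e.genome_a}/{e.genome_b}")
        graph.add_edge(e.genome_a, e.genome_b)

    out = []
    for comp in sorted(nx.connected_components(graph), key=lambda c: (-len(c), sorted(c))):
        members = sorted(comp)
        n = len(members)
        full = graph.subgraph(comp).number_of_edges() == n * (n - 1) // 2
        sites, in_control = [], False
        for gid in members:
            sid = by_id[gid].sample_id
            if metadata is not None and sid in metadata.index:
                row = metadata.loc[sid]
                sites.append((row["set_id"], row["side"], row["component"]))
                in_control = in_control or row["component"] == "CONTROL"
            else:
                sites.append((None, None, None))
        samples = {by_id[g].sample_id for g in members}
        out.append(StrainComponent(
            members=members, sites=sites, fully_connected=full,
            spans_multiple_samples=len(samples) > 1, in_control=in_control))
    return out


# ---------------------------------------------------------------------------
# FASTA IO (one multi-FASTA per draft genome, headers sample|bin|contig)


def write_genomes(genomes, outdir) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for g in genomes:
        records = [
            SeqRecord(Seq(c), id=f"{g.genome_id}|contig_{i}", description="")
            for i, c in enumerate(g.contigs)
        ]
        fname = g.genome_id.replace("|", "__") + ".fasta"
        seqio_write(records, outdir / fname, "fasta")


def read_genomes(indir, qc_table: pd.DataFrame | None = None) -> list:
    """Load one DraftGenome per FASTA file; QC values from a metadata table
    indexed by genome_id (columns completeness, contamination)."""
    from Bio.SeqIO import parse as seqio_parse

    genomes = []
    for path in sorted(Path(indir).glob("*.fasta")):
        contigs, gid, sample = [], None, None
        for rec in seqio_parse(path, "fasta"):
            parts = rec.id.split("|")
            sample = parts[0]
            gid = "|".join(parts[:2]) if len(parts) >= 2 else rec.id
            contigs.append(str(rec.seq))
        comp = cont = None
        if qc_table is not None and gid in qc_table.index:
            comp = float(qc_table.loc[gid, "completeness"])
            cont = float(qc_table.loc[gid, "contamination"])
        genomes.append(DraftGenome(genome_id=gid, sample_id=sample,
                                   contigs=contigs, completeness=comp,
                                   contamination=cont))
    return genomes
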