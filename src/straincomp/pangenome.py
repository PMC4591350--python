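"""Pan-genome partitioning, annotation-category summaries and pathway
completeness.

CDS protein products from all genomes are clustered into putative
ortholog groups by single-linkage over pairwise global-alignment
identity (50% identity over 50% of the shorter sequence by default,
common pan-genome practice).  Clusters are then dropped into Venn cells
according to the set of genomes they touch: the cell containing every
genome is the core genome; singleton cells are strain-unique genes.

Pathway completeness asks, for a list of pathway definitions (sets of
required EC numbers), what share of pathways have all of their enzymes
in a genome's annotated EC set, and what share are at most one enzyme
short — the latter always includes the former.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Sequence, Set, Tuple

import networkx as nx
import pandas as pd
from Bio import Align

from .annotation import CdsRecord

__all__ = [
    "ProteinRecord",
    "OrthologCluster",
    "VennPartition",
    "PathwayDefinition",
    "cluster_cds",
    "venn_partition",
    "category_summary",
    "pathway_completeness",
    "read_pathways",
]


@dataclass(frozen=True)
class ProteinRecord:
    genome_id: str
    cds_id: str
    sequence: str


@dataclass
class OrthologCluster:
    cluster_id: str
    members: List[Tuple[str, str]]  # (genome_id, cds_id)

    @property
    def genomes(self) -> FrozenSet[str]:
        return frozenset(g for g, _ in self.members)


@dataclass
class PathwayDefinition:
    pathway_id: str
    required_enzymes: Set[str]

    def __post_init__(self):
        if not self.required_enzymes:
            raise ValueError(f"pathway {self.pathway_id!r} has no required enzymes")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


def _pair_identity(aligner: Align.PairwiseAligner, a: str, b: str) -> Tuple[float, float]:
    """(identity over aligned columns, coverage of shorter sequence)."""
    aln = aligner.align(a, b)[0]
    identical = 0
    aligned_cols = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        aligned_cols += a1 - a0
        sub_a, sub_b = a[a0:a1], b[b0:b1]
        identical += sum(x == y for x, y in zip(sub_a, sub_b))
    shorter = min(len(a), len(b))
    if shorter == 0 or aligned_cols == 0:
        return 0.0, 0.0
    return identical / aligned_cols, aligned_cols / shorter


def _kmer_candidates(proteins: Sequence[ProteinRecord], k: int = 5) -> Set[Tuple[int, int]]:
    by_kmer: Dict[str, List[int]] = defaultdict(list)
    for idx, rec in enumerate(proteins):
        seen = set()
        seq = rec.sequence
        for i in range(max(len(seq) - k + 1, 0)):
            seen.add(seq[i : i + k])
        if not seen and seq:  # shorter than k: index the whole sequence
            seen.add(seq)
        for km in seen:
            by_kmer[km].append(idx)
    pairs: Set[Tuple[int, int]] = set()
    for idxs in by_kmer.values():
        for i, a in enumerate(idxs):
            for b in idxs[i + 1 :]:
                pairs.add((a, b))
    return pairs


def cluster_cds(
    proteins: Sequence[ProteinRecord],
    min_identity: float = 0.5,
    min_coverage: float = 0.5,
) -> List[OrthologCluster]:
    """Single-linkage ortholog clusters over pairwise protein identity.

    A shared-k-mer prefilter limits exact global alignment to plausible
    pairs; any pair with no 5-mer in common cannot reach 50% identity
    over half the shorter sequence for realistic protein lengths.
    Cluster ids are deterministic: the lexicographically smallest
    ``genome_id:cds_id`` among members.
    """
    if not proteins:
        return []
    aligner = _make_aligner()
    graph = nx.Graph()
    graph.add_nodes_from(range(len(proteins)))
    for a, b in sorted(_kmer_candidates(proteins)):
        ident, cov = _pair_identity(aligner, proteins[a].sequence, proteins[b].sequence)
        if ident >= min_identity and cov >= min_coverage:
            graph.add_edge(a, b)
    clusters = []
    for comp in nx.connected_components(graph):
        members = sorted((proteins[i].genome_id, proteins[i].cds_id) for i in comp)
        cid = f"{members[0][0]}:{members[0][1]}"
        clusters.append(OrthologCluster(cid, members))
    clusters.sort(key=lambda c: c.cluster_id)
    return clusters


@dataclass
class VennPartition:
    genome_ids: List[str]
    cell_counts: Dict[Tuple[str, ...], int] = field(default_factory=dict)

    @property
    def core_count(self) -> int:
        return self.cell_counts.get(tuple(sorted(self.genome_ids)), 0)

    def unique_count(self, genome_id: str) -> int:
        return self.cell_counts.get((genome_id,), 0)

    @property
    def n_clusters(self) -> int:
        return sum(self.cell_counts.values())

    def to_json_dict(self) -> Dict[str, int]:
        return {",".join(cell): n for cell, n in sorted(self.cell_counts.items())}


def venn_partition(
    clusters: Iterable[OrthologCluster], genome_ids: Sequence[str]
) -> VennPartition:
    """Assign each cluster to the Venn cell of genomes it is found in."""
    known = set(genome_ids)
    counts: Dict[Tuple[str, ...], int] = defaultdict(int)
    for cluster in clusters:
        extra = cluster.genomes - known
        if extra:
            raise KeyError(f"cluster {cluster.cluster_id} references unknown genomes {extra}")
        cell = tuple(sorted(cluster.genomes))
        counts[cell] += 1
    return VennPartition(list(genome_ids), dict(counts))


def category_summary(cds: Iterable[CdsRecord]) -> pd.Series:
    """Counts per functional category; 'Total' sums categorized CDSs only."""
    counts: Dict[str, int] = defaultdict(int)
    for rec in cds:
        if rec.category:
            counts[rec.category] += 1
    series = pd.Series(dict(sorted(counts.items())), dtype=int)
    series["Total"] = int(series.sum()) if len(series) else 0
    return series


def pathway_completeness(
    pathways: Sequence[PathwayDefinition], annotated_ecs: Set[str]
) -> Tuple[float, float]:
    """(fraction of pathways fully annotated, fraction missing at most one).

    The second fraction includes complete pathways, so it is never
    smaller than the first.
    """
    if not pathways:
        raise ValueError("pathway list is empty")
    complete = 0
    near = 0
    for pw in pathways:
        missing = len(pw.required_enzymes - annotated_ecs)
        if missing == 0:
            complete += 1
        if missing <= 1:
            near += 1
    n = len(pathways)
    return complete / n, near / n


def read_pathways(path) -> List[PathwayDefinition]:
    """Pathway definitions as TSV: ``pathway_id<TAB>EC,EC,...``."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            ecs = {e.strip() for e in parts[1].split(",") if e.strip()}
            out.append(PathwayDefinition(parts[0], ecs))
    return out
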