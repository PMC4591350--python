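"""Pairwise local-alignment segments: readers, writers and a desk-scale
anchor aligner.

Segments connect an interval on a *query* genome to an interval on a
*target* genome.  Two on-disk dialects are supported:

* ``tsv`` -- nine tab-separated columns
  ``qgenome qreplicon qstart qend tgenome treplicon tstart tend strand``
  with an optional tenth column carrying fractional identity;
* ``maf`` -- UCSC MAF ``a``/``s`` blocks where the ``s`` source field is
  ``<genome>.<replicon>``.  Minus-strand MAF coordinates (counted from the
  sequence end) are converted to forward-strand half-open intervals on
  reading.  The alignment text column is not retained; ``write_segments``
  emits ``*`` as a placeholder.

The built-in :func:`anchor_align` finds exact k-mer matches on both
strands and chains colinear matches on the same diagonal, so synthetic
genomes can be compared without an external aligner.  It makes no claim
of parity with production aligners; it exists so that planted, verbatim
shared blocks are recovered deterministically.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Tuple

from .genome import Genome

__all__ = [
    "AlignmentSegment",
    "read_segments",
    "write_segments",
    "anchor_align",
    "filter_segments",
    "transpose_segments",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignmentSegment:
    query_genome: str
    query_replicon: str
    q_start: int  # 0-based half-open
    q_end: int
    target_genome: str
    target_replicon: str
    t_start: int
    t_end: int
    strand: str  # '+' or '-'
    identity: Optional[float] = None

    def __post_init__(self):
        if not (0 <= self.q_start < self.q_end):
            raise ValueError(f"bad query interval [{self.q_start},{self.q_end})")
        if not (0 <= self.t_start < self.t_end):
            raise ValueError(f"bad target interval [{self.t_start},{self.t_end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def query_length(self) -> int:
        return self.q_end - self.q_start


def transpose_segments(segments: List[AlignmentSegment]) -> List[AlignmentSegment]:
    """Swap query and target sides of every segment."""
    return [
        AlignmentSegment(
            s.target_genome, s.target_replicon, s.t_start, s.t_end,
            s.query_genome, s.query_replicon, s.q_start, s.q_end,
            s.strand, s.identity,
        )
        for s in segments
    ]


# ---------------------------------------------------------------- TSV dialect


def _read_tsv(path) -> List[AlignmentSegment]:
    out: List[AlignmentSegment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) not in (9, 10):
                raise ValueError(f"{path}:{lineno}: expected 9 or 10 columns, got {len(f)}")
            try:
                seg = AlignmentSegment(
                    f[0], f[1], int(f[2]), int(f[3]),
                    f[4], f[5], int(f[6]), int(f[7]), f[8],
                    float(f[9]) if len(f) == 10 else None,
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            out.append(seg)
    return out


def _write_tsv(segments: List[AlignmentSegment], path) -> None:
    with open(path, "w") as fh:
        for s in segments:
            row = [
                s.query_genome, s.query_replicon, str(s.q_start), str(s.q_end),
                s.target_genome, s.target_replicon, str(s.t_start), str(s.t_end),
                s.strand,
            ]
            if s.identity is not None:
                row.append(f"{s.identity:.6g}")
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------- MAF dialect


def _parse_src(src: str, path, lineno: int) -> Tuple[str, str]:
    if "." not in src:
        raise ValueError(f"{path}:{lineno}: MAF src {src!r} lacks '<genome>.<replicon>'")
    genome, replicon = src.split(".", 1)
    return genome, replicon


def _read_maf(path) -> List[AlignmentSegment]:
    out: List[AlignmentSegment] = []
    s_lines: List[Tuple[int, List[str]]] = []

    def flush(block_end_line: int) -> None:
        if not s_lines:
            return
        if len(s_lines) != 2:
            raise ValueError(
                f"{path}:{block_end_line}: MAF block has {len(s_lines)} 's' lines, expected 2"
            )
        sides = []
        for lineno, f in s_lines:
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: malformed 's' line")
            genome, replicon = _parse_src(f[1], path, lineno)
            start, size, strand, src_size = int(f[2]), int(f[3]), f[4], int(f[5])
            if strand == "-":
                fwd_start = src_size - start - size
            else:
                fwd_start = start
            if fwd_start < 0 or fwd_start + size > src_size:
                raise ValueError(
                    f"{path}:{lineno}: interval [{fwd_start},{fwd_start + size}) "
                    f"outside sequence of size {src_size}"
                )
            sides.append((genome, replicon, fwd_start, fwd_start + size, strand))
        (qg, qr, qs, qe, qstrand), (tg, tr, ts, te, tstrand) = sides
        strand = "+" if qstrand == tstrand else "-"
        out.append(AlignmentSegment(qg, qr, qs, qe, tg, tr, ts, te, strand))
        s_lines.clear()

    with open(path) as fh:
        lineno = 0
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("a"):
                flush(lineno)
            elif line.startswith("s"):
                s_lines.append((lineno, line.split()))
            elif line.strip() == "" or line.startswith("#"):
                continue
        flush(lineno)
    return out


def _write_maf(segments: List[AlignmentSegment], path) -> None:
    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        for s in segments:
            qlen = s.q_end - s.q_start
            tlen = s.t_end - s.t_start
            fh.write("a\n")
            fh.write(
                f"s {s.query_genome}.{s.query_replicon} {s.q_start} {qlen} + "
                f"{s.q_end} *\n"
            )
            if s.strand == "-":
                # minimal valid srcSize: the interval's own end
                fh.write(
                    f"s {s.target_genome}.{s.target_replicon} 0 {tlen} - {s.t_end} *\n"
                )
            else:
                fh.write(
                    f"s {s.target_genome}.{s.target_replicon} {s.t_start} {tlen} + "
                    f"{s.t_end} *\n"
                )
            fh.write("\n")


def read_segments(path, format: str = "tsv") -> List[AlignmentSegment]:
    if format == "tsv":
        return _read_tsv(path)
    if format == "maf":
        return _read_maf(path)
    raise ValueError(f"unknown segment format {format!r}")


def write_segments(segments: List[AlignmentSegment], path, format: str = "tsv") -> None:
    if format == "tsv":
        _write_tsv(segments, path)
    elif format == "maf":
        _write_maf(segments, path)
    else:
        raise ValueError(f"unknown segment format {format!r}")


# ------------------------------------------------------------ anchor aligner


def _kmer_index(seq: str, k: int) -> Dict[str, List[int]]:
    index: Dict[str, List[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            index[kmer].append(i)
    return index


def _chain_diagonal(positions: List[int], k: int, max_gap: int) -> List[Tuple[int, int]]:
    """Chain sorted match start positions on one diagonal into runs.

    Returns half-open query intervals [first, last + k)."""
    chains = []
    start = prev = positions[0]
    for p in positions[1:]:
        if p - prev <= max_gap + k:
            prev = p
        else:
            chains.append((start, prev + k))
            start = prev = p
    chains.append((start, prev + k))
    return chains


def anchor_align(
    genome_a: Genome,
    genome_b: Genome,
    k: int = 15,
    max_gap: int = 100,
    min_chain: int = 300,
) -> List[AlignmentSegment]:
    """Exact k-mer anchor alignment of two genomes, both strands.

    Matches on the same (target replicon, strand, diagonal) are chained
    when consecutive anchors are within ``max_gap`` bp; chains spanning at
    least ``min_chain`` query bp become segments with identity 1.0.
    """
    if k < 8:
        raise ValueError(f"seed length k must be >= 8, got {k}")
    shortest = min(
        min(genome_a.replicon_lengths.values()), min(genome_b.replicon_lengths.values())
    )
    if k > shortest:
        raise ValueError(f"k={k} exceeds shortest replicon length {shortest}")

    indexes = {rep: _kmer_index(seq.upper(), k) for rep, seq in genome_b.replicons.items()}
    segments: List[AlignmentSegment] = []

    for q_rep in genome_a.replicon_order:
        q_seq = genome_a.replicons[q_rep].upper()
        for strand in "+-":
            scan = q_seq if strand == "+" else _revcomp(q_seq)
            L = len(scan)
            # (target replicon, diagonal) -> list of scan-coordinate starts
            hits: Dict[Tuple[str, int], List[int]] = defaultdict(list)
            for i in range(L - k + 1):
                kmer = scan[i : i + k]
                if "N" in kmer:
                    continue
                for t_rep, index in indexes.items():
                    for j in index.get(kmer, ()):
                        hits[(t_rep, i - j)].append(i)
            for (t_rep, diag) in sorted(hits):
                positions = sorted(set(hits[(t_rep, diag)]))
                for s, e in _chain_diagonal(positions, k, max_gap):
                    if e - s < min_chain:
                        continue
                    ts, te = s - diag, e - diag
                    if strand == "+":
                        qs, qe = s, e
                    else:
                        qs, qe = L - e, L - s
                    segments.append(
                        AlignmentSegment(
                            genome_a.genome_id, q_rep, qs, qe,
                            genome_b.genome_id, t_rep, ts, te,
                            strand, 1.0,
                        )
                    )
    segments.sort(
        key=lambda s: (
            genome_a.replicon_order.index(s.query_replicon),
            s.q_start, s.q_end, s.target_replicon, s.t_start, s.strand,
        )
    )
    return segments


def filter_segments(
    segments: List[AlignmentSegment], min_len: int = 300
) -> List[AlignmentSegment]:
    """Keep segments whose query interval spans at least ``min_len`` bp."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    return [s for s in segments if s.query_length >= min_len]
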