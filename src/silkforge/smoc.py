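"""Seed-and-extend reconstruction of repetitive silk genes from short reads.

The procedure mirrors targeted curation of spidroin loci: a de Bruijn graph
of the short reads is materialized as unitigs, the conserved N/C-terminal
domains are located on those unitigs by six-frame protein homology search,
and each terminal-domain seed is extended base by base.  At every step the
terminal k-mer of the growing consensus (a deliberately large "anchor"
k-mer) is matched exactly against the reads; the bases the matching reads
contribute immediately past the anchor form one position-weight-matrix
column, and the consensus advances only while the column is deep enough and
near-unanimous.  Extension halts when the consensus runs into the tandem
repeat array (detected by trailing-window autocorrelation), when read
support fails, or at a length cap.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Seq import Seq
from Bio.Align import substitution_matrices

from .simgen import ReadSet, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "DeBruijnGraph", "Seed", "AssemblyCandidate",
    "build_debruijn", "extract_unitigs", "find_terminal_seeds",
    "extend_seed", "detect_repeat_boundary",
]


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class DeBruijnGraph:
    k: int
    nodes: dict[str, int]                       # canonical k-mer -> coverage
    edges: dict[tuple[tuple[str, str], tuple[str, str]], int] = field(default_factory=dict)


@dataclass
class Seed:
    contig_id: str
    contig_seq: str
    hit_start: int        # forward-strand, 0-based half-open
    hit_end: int
    strand: str           # "+" / "-"
    frame: int            # 0|1|2 on the stranded sequence
    domain_kind: str      # "N" | "C"
    domain_name: str
    score: float


@dataclass
class AssemblyCandidate:
    name: str
    consensus: str
    seed: Seed
    # aligned with consensus; None over the seed-derived prefix/suffix
    per_column_support: list[tuple[int, float] | None]
    boundary_pos: int | None
    halted_reason: str    # repeat_boundary | no_support | max_length
    direction: str        # "3p" | "5p"


def build_debruijn(reads: ReadSet | list, k: int, min_count: int = 1) -> DeBruijnGraph:
    """Count canonical k-mers (and (k-1)-overlap edges) from reads.

    k must be odd so no k-mer is its own reverse complement; k-mers
    containing N are skipped; nodes below ``min_count`` are dropped.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd (even k admits palindromic k-mers)")
    nodes: Counter = Counter()
    edges: Counter = Counter()
    seqs = [r.seq for r in reads]

    def oriented(km: str) -> tuple[str, str]:
        c = canonical(km)
        return (c, "+" if km == c else "-")

    for seq in seqs:
        n = len(seq)
        prev = None
        for i in range(n - k + 1):
            km = seq[i:i + k]
            if "N" in km:
                prev = None
                continue
            nodes[canonical(km)] += 1
            cur = oriented(km)
            if prev is not None:
                e = (prev, cur)
                erc = ((cur[0], "-" if cur[1] == "+" else "+"),
                       (prev[0], "-" if prev[1] == "+" else "+"))
                edges[min(e, erc)] += 1
            prev = cur
    kept = {km: c for km, c in nodes.items() if c >= min_count}
    kept_edges = {e: m for e, m in edges.items()
                  if e[0][0] in kept and e[1][0] in kept}
    return DeBruijnGraph(k=k, nodes=kept, edges=kept_edges)


def _succ(graph: DeBruijnGraph, seq: str) -> list[str]:
    out = []
    suf = seq[1:]
    for b in "ACGT":
        nxt = suf + b
        if canonical(nxt) in graph.nodes:
            out.append(nxt)
    return out


def _pred(graph: DeBruijnGraph, seq: str) -> list[str]:
    return [revcomp(s) for s in _succ(graph, revcomp(seq))]


def extract_unitigs(graph: DeBruijnGraph) -> list[str]:
    """Maximal non-branching paths, each reported once in canonical
    orientation, sorted by (length desc, lexicographic)."""
    visited: set[str] = set()
    unitigs: list[str] = []
    for start in sorted(graph.nodes):
        if start in visited:
            continue
        # walk backward to the start of the non-branching path
        seq = start
        path = [start]
        cur = start
        while True:
            preds = _pred(graph, cur)
            if len(preds) != 1:
                break
            p = preds[0]
            if len(_succ(graph, p)) != 1 or canonical(p) in (canonical(x) for x in path):
                break
            cur = p
            path.append(p)
        path.reverse()  # now path[0] is the leftmost oriented k-mer
        cur = path[-1]
        while True:
            succs = _succ(graph, cur)
            if len(succs) != 1:
                break
            s = succs[0]
            if len(_pred(graph, s)) != 1 or canonical(s) in (canonical(x) for x in path):
                break
            cur = s
            path.append(s)
        seq = path[0] + "".join(p[-1] for p in path[1:])
        for p in path:
            visited.add(canonical(p))
        rc = revcomp(seq)
        unitigs.append(seq if seq <= rc else rc)
    return sorted(set(unitigs), key=lambda s: (-len(s), s))


def _local_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -10.0
    a.extend_gap_score = -1.0
    a.mode = "local"
    return a


def _domain_kind(name: str) -> str:
    if name.upper().endswith("NTD") or "_N" in name.upper():
        return "N"
    if name.upper().endswith("CTD") or "_C" in name.upper():
        return "C"
    return "?"


def find_terminal_seeds(contigs: list[str], domains: list[tuple[str, str]],
                        min_score: float) -> list[Seed]:
    """Locate terminal-domain homologies on contigs by six-frame local
    alignment (BLOSUM62, affine gaps); coordinates on the forward strand."""
    if not domains:
        raise ValueError("no reference terminal domains supplied")
    aligner = _local_aligner()
    seeds: list[Seed] = []
    for ci, contig in enumerate(contigs):
        if len(contig) < 3:
            logger.warning("skipping contig %d: shorter than 3 nt", ci)
            continue
        cid = f"utg{ci}"
        for strand in "+-":
            nt = contig if strand == "+" else revcomp(contig)
            for frame in range(3):
                trimmed = nt[frame:frame + 3 * ((len(nt) - frame) // 3)]
                if not trimmed:
                    continue
                prot = str(Seq(trimmed).translate()).replace("*", "X")
                for dname, dseq in domains:
                    score = aligner.score(prot, dseq)
                    if score < min_score:
                        continue
                    aln = aligner.align(prot, dseq)[0]
                    t = aln.aligned[0]
                    aa_start, aa_end = int(t[0][0]), int(t[-1][1])
                    s_nt = frame + 3 * aa_start
                    e_nt = frame + 3 * aa_end
                    if strand == "-":
                        s_nt, e_nt = len(contig) - e_nt, len(contig) - s_nt
                    seeds.append(Seed(
                        contig_id=cid, contig_seq=contig,
                        hit_start=s_nt, hit_end=e_nt, strand=strand,
                        frame=frame, domain_kind=_domain_kind(dname),
                        domain_name=dname, score=float(score)))
    seeds.sort(key=lambda s: (-s.score, s.contig_id, s.hit_start))
    return seeds


def detect_repeat_boundary(consensus: str, window: int, period_max: int,
                           min_fraction: float = 0.9) -> int | None:
    """Smallest position p whose length-``window`` suffix-side window is
    tandem-periodic: some period q <= period_max matches >= ``min_fraction``
    of positions under the lag-q autocorrelation test."""
    if window < 2 * period_max:
        raise ValueError("window must be >= 2 * period_max")
    n = len(consensus)
    if n < window:
        return None
    s = np.frombuffer(consensus.encode(), dtype=np.uint8)
    n_p = n - window + 1
    ok = np.zeros(n_p, dtype=bool)
    for q in range(1, period_max + 1):
        eq = (s[:-q] == s[q:]).astype(np.int32)
        c = np.concatenate([[0], np.cumsum(eq)])
        span = window - q
        # fraction of matching positions in [p, p + window - q)
        fr = (c[span:span + n_p] - c[:n_p]) / span
        ok |= fr >= min_fraction
        if ok[0]:
            return 0
    hits = np.flatnonzero(ok)
    return int(hits[0]) if hits.size else None


class _AnchorIndex:
    """Exact k-mer lookup over both orientations of a read set."""

    def __init__(self, reads, k: int):
        self.k = k
        self.seqs: list[str] = []
        self.index: dict[str, list[tuple[int, int]]] = {}
        for r in reads:
            for seq in (r.seq, revcomp(r.seq)):
                si = len(self.seqs)
                self.seqs.append(seq)
                for i in range(len(seq) - k + 1):
                    km = seq[i:i + k]
                    if "N" not in km:
                        self.index.setdefault(km, []).append((si, i))

    def next_bases(self, anchor: str) -> list[str]:
        out = []
        for si, i in self.index.get(anchor, ()):
            j = i + self.k
            seq = self.seqs[si]
            if j < len(seq):
                out.append(seq[j])
        return out


def extend_seed(seed: Seed, reads: ReadSet, anchor_k: int = 51,
                min_depth: int = 5, min_frac: float = 0.8,
                max_len: int = 20000, direction: str = "3p",
                boundary_window: int = 300, boundary_period_max: int = 150,
                name: str | None = None,
                _index: "_AnchorIndex | None" = None) -> AssemblyCandidate:
    """PWM extension of a terminal-domain seed until the repeat array.

    The consensus is kept in gene orientation (the seed's strand applied);
    ``direction='3p'`` grows rightward (an N-terminal seed toward the
    repeats), ``'5p'`` leftward (a C-terminal seed).  Each appended column
    requires depth >= ``min_depth`` and a majority base frequency >=
    ``min_frac``; a tie between two bases halts with ``no_support``.
    """
    if direction not in ("3p", "5p"):
        raise ValueError("direction must be '3p' or '5p'")
    init = seed.contig_seq[seed.hit_start:seed.hit_end]
    if seed.strand == "-":
        init = revcomp(init)
    # work in an orientation where growth is always rightward
    work = init if direction == "3p" else revcomp(init)
    seed_len = len(work)
    idx = _index if _index is not None else _AnchorIndex(reads, anchor_k)
    support: list[tuple[int, float]] = []
    halted = "max_length"
    boundary_work: int | None = None
    appended_since_check = 0
    while len(work) < max_len:
        anchor = work[-anchor_k:]
        if len(anchor) < anchor_k:
            halted = "no_support"
            break
        bases = idx.next_bases(anchor)
        depth = len(bases)
        if depth < min_depth:
            halted = "no_support"
            break
        counts = Counter(bases)
        ranked = counts.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            halted = "no_support"  # tie: curation favours precision
            break
        base, cnt = ranked[0]
        frac = cnt / depth
        if frac < min_frac:
            halted = "no_support"
            break
        work += base
        support.append((depth, frac))
        appended_since_check += 1
        if appended_since_check >= 25:
            appended_since_check = 0
            b = detect_repeat_boundary(work, boundary_window, boundary_period_max)
            if b is not None:
                halted = "repeat_boundary"
                boundary_work = b
                break
    else:
        halted = "max_length"
    if halted in ("no_support", "max_length") and boundary_work is None:
        b = detect_repeat_boundary(work, boundary_window, boundary_period_max) \
            if len(work) >= boundary_window else None
        if b is not None:
            halted = "repeat_boundary"
            boundary_work = b

    if direction == "3p":
        consensus = work
        per_col: list[tuple[int, float] | None] = (
            [None] * seed_len + support)
        boundary = boundary_work
    else:
        consensus = revcomp(work)
        per_col = list(reversed(support)) + [None] * seed_len
        boundary = None if boundary_work is None else len(work) - boundary_work
    return AssemblyCandidate(
        name=name or f"{seed.domain_name}_{direction}",
        consensus=consensus, seed=seed, per_column_support=per_col,
        boundary_pos=boundary, halted_reason=halted, direction=direction)
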