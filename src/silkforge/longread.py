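"""Long-read confirmation of candidate gene architecture.

Because a spidroin's repeat array is far longer than any short read, the
array's unit count can only be trusted when the whole locus — both terminal
candidates and the repeats between them — is contained in one long read.
This module provides a minimal trusted-k-mer error-correction stage for the
long reads, maps assembled candidates onto them (shared-k-mer prescreen
plus edlib infix alignment), and counts repeat units between the mapped
termini by greedy left-to-right tiling.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import edlib

from .simgen import Read, ReadSet, revcomp
from .smoc import AssemblyCandidate

__all__ = [
    "LongReadSupport", "correct_long_reads", "map_candidate",
    "count_repeat_units", "modal_repeat_count",
]


@dataclass
class LongReadSupport:
    read_id: str
    candidate_name: str
    read_start: int      # 0-based half-open on the long read
    read_end: int
    strand: str
    identity: float
    full_length: bool = False


def _trusted_spectrum(short: ReadSet | list, k: int, min_count: int) -> set[str]:
    counts: Counter = Counter()
    for r in short:
        seq = r.seq
        for i in range(len(seq) - k + 1):
            km = seq[i:i + k]
            if "N" not in km:
                counts[min(km, revcomp(km))] += 1
    return {km for km, c in counts.items() if c >= min_count}


def correct_long_reads(long: ReadSet, short: ReadSet, k: int = 17,
                       min_count: int = 2) -> ReadSet:
    """Trusted-k-mer single-substitution repair of long reads.

    A base whose covering k-mers are absent from the short-read spectrum is
    replaced by the unique alternative base that makes every covering k-mer
    trusted; if zero or more than one alternative works, the base is left
    unchanged.  Output read count equals input.
    """
    trusted = _trusted_spectrum(short, k, min_count)

    def kmer_ok(seq: list[str], s: int) -> bool:
        km = "".join(seq[s:s + k])
        return "N" not in km and min(km, revcomp(km)) in trusted

    out_reads = []
    for r in long:
        seq = list(r.seq)
        n = len(seq)
        if n < k:
            out_reads.append(Read(id=r.id, seq=r.seq, qual="I" * n, mate=r.mate))
            continue
        # untrusted flags per k-mer start, updated locally after each repair
        bad = [not kmer_ok(seq, s) for s in range(n - k + 1)]
        for i in range(n):
            lo, hi = max(0, i - k + 1), min(i, n - k)
            if not any(bad[lo:hi + 1]):
                continue
            orig = seq[i]
            fixes = []
            for b in "ACGT":
                if b == orig:
                    continue
                seq[i] = b
                if all(kmer_ok(seq, s) for s in range(lo, hi + 1)):
                    fixes.append(b)
            seq[i] = fixes[0] if len(fixes) == 1 else orig
            if len(fixes) == 1:
                for s in range(lo, hi + 1):
                    bad[s] = not kmer_ok(seq, s)
        fixed = "".join(seq)
        out_reads.append(Read(id=r.id, seq=fixed,
                              qual="I" * len(fixed), mate=r.mate))
    return ReadSet(reads=out_reads, platform="long",
                   source_truth=dict(long.source_truth))


def _shared_kmers(a: str, b_kmers: set[str], k: int) -> int:
    n = 0
    for i in range(0, len(a) - k + 1, k):
        if a[i:i + k] in b_kmers:
            n += 1
    return n


def map_candidate(candidate: AssemblyCandidate | str, long: ReadSet,
                  seed_k: int = 15, min_identity: float = 0.8,
                  name: str | None = None) -> list[LongReadSupport]:
    """Locate a candidate consensus within individual long reads.

    Reads sharing no ``seed_k``-mer with the candidate are skipped; the
    rest are aligned with an infix (semi-global) edit-distance alignment,
    and supports with identity >= ``min_identity`` are returned with
    forward-strand coordinates on the read.
    """
    if isinstance(candidate, AssemblyCandidate):
        query, cname = candidate.consensus, candidate.name
    else:
        query, cname = candidate, (name or "candidate")
    if len(query) < seed_k:
        raise ValueError("candidate shorter than seed_k")
    qkmers = {query[i:i + seed_k] for i in range(len(query) - seed_k + 1)}
    supports = []
    for r in long:
        for strand in "+-":
            seq = r.seq if strand == "+" else revcomp(r.seq)
            if _shared_kmers(seq, qkmers, seed_k) == 0:
                continue
            res = edlib.align(query, seq, mode="HW", task="locations")
            if res["editDistance"] < 0 or not res["locations"]:
                continue
            start, end = res["locations"][0]
            end += 1  # edlib end is inclusive
            aln_len = max(len(query), end - start)
            identity = 1.0 - res["editDistance"] / aln_len
            if identity < min_identity:
                continue
            if strand == "-":
                start, end = len(seq) - end, len(seq) - start
            supports.append(LongReadSupport(
                read_id=r.id, candidate_name=cname,
                read_start=start, read_end=end,
                strand=strand, identity=identity))
            break  # best strand wins; a read supports a candidate once
    return supports


def flag_full_length(n_supports: list[LongReadSupport],
                     c_supports: list[LongReadSupport]) -> list[tuple[LongReadSupport, LongReadSupport]]:
    """Mark supports whose N- and C-candidates lie on the same read in
    consistent orientation and order; returns the (N, C) pairs."""
    by_read = {s.read_id: s for s in n_supports}
    pairs = []
    for cs in c_supports:
        ns = by_read.get(cs.read_id)
        if ns is None or ns.strand != cs.strand:
            continue
        if ns.strand == "+":
            ordered = ns.read_end <= cs.read_start + 1
        else:
            ordered = cs.read_end <= ns.read_start + 1
        if ordered:
            ns.full_length = cs.full_length = True
            pairs.append((ns, cs))
    return pairs


def count_repeat_units(read_segment: str, unit: str,
                       min_identity: float = 0.8) -> int:
    """Greedy non-overlapping left-to-right tiling of a segment by a
    repeat unit; each tile must align at identity >= ``min_identity``."""
    if len(unit) < 20:
        raise ValueError("unit must be >= 20 nt")
    max_d = int((1.0 - min_identity) * len(unit))
    pos, count = 0, 0
    n = len(read_segment)
    win = int(len(unit) * 1.3)
    while pos + int(len(unit) * min_identity) <= n:
        window = read_segment[pos:pos + win]
        res = edlib.align(unit, window, mode="SHW", task="locations", k=max_d)
        if res["editDistance"] >= 0 and res["locations"]:
            end = res["locations"][0][1] + 1
            count += 1
            pos += max(end, 1)
        else:
            pos += 1
    return count


def modal_repeat_count(pairs: list[tuple[LongReadSupport, LongReadSupport]],
                       long: ReadSet, unit: str,
                       min_identity: float = 0.75) -> int | None:
    """Modal repeat-unit count over full-length (N,C) support pairs."""
    reads = {r.id: r for r in long}
    counts = []
    for ns, cs in pairs:
        seq = reads[ns.read_id].seq
        if ns.strand == "-":
            seq = revcomp(seq)
            n_end = len(seq) - ns.read_start
            c_start = len(seq) - cs.read_end
        else:
            n_end, c_start = ns.read_end, cs.read_start
        if c_start <= n_end:
            continue
        counts.append(count_repeat_units(seq[n_end:c_start], unit, min_identity))
    if not counts:
        return None
    return Counter(counts).most_common(1)[0][0]
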