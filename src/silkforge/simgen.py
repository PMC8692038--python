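"""Synthetic spidroin gene models and sequencing-read simulation.

Every downstream stage of the toolkit (assembly, long-read confirmation,
cataloguing, phylogeny, profiling) is exercisable on the output of this
module without any external data.  A gene model is the canonical spidroin
architecture: a conserved N-terminal domain, a long array of nucleotide-
identical repeat units built from a family's motif grammar, and a conserved
C-terminal domain.  Reads emulate Illumina-like short reads (uniform
substitution errors) and Nanopore-like long reads (gamma-distributed
lengths, mixed substitution/indel errors).

Coordinates are 0-based half-open throughout; strands are '+'/'-'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

from . import _domains
from .catalogue import (MotifGrammar, RepeatUnit, classify_tail, grammar_for,
                        load_grammars)

__all__ = [
    "SpidroinGeneModel", "Read", "ReadSet",
    "build_gene", "simulate_short_reads", "simulate_long_reads",
    "reverse_translate", "revcomp",
]

_COMP = str.maketrans("ACGTN", "TGCAN")

# codons per amino acid, standard table 1
_CODONS: dict[str, list[str]] = {}
for _codon, _aa in unambiguous_dna_by_id[1].forward_table.items():
    _CODONS.setdefault(_aa, []).append(_codon)
for _aa in _CODONS:
    _CODONS[_aa].sort()


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class Read:
    id: str
    seq: str
    qual: str | None = None
    mate: str | None = None


@dataclass
class ReadSet:
    reads: list[Read]
    platform: str  # "short" | "long"
    # read id -> (origin start, origin end, strand) on the source sequence
    source_truth: dict[str, tuple[int, int, str]] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.reads)

    def __len__(self):
        return len(self.reads)


@dataclass
class SpidroinGeneModel:
    name: str
    family: str
    ntd: str
    repeats: list[RepeatUnit]
    ctd: str
    cds_nt: str

    @property
    def protein(self) -> str:
        return self.ntd + "".join(u.aa_seq for u in self.repeats) + self.ctd

    def validate(self) -> None:
        if len(self.cds_nt) % 3:
            raise ValueError("cds length not divisible by 3")
        aa = str(Seq(self.cds_nt).translate())
        if "*" in aa:
            raise ValueError("internal stop codon in cds")
        if aa != self.protein:
            raise ValueError("cds translation does not match domain architecture")


def reverse_translate(aa_seq: str, rng: np.random.Generator) -> str:
    """Back-translate, choosing uniformly among synonymous codons."""
    return "".join(
        _CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in aa_seq
    )


_FILLER = "GSQYLP"  # glycine/serine-rich spacer residues; no alanine runs


def _make_tail(grammar: MotifGrammar, rng: np.random.Generator) -> str:
    if grammar.tail_rule == "none":
        return ""
    if grammar.tail_rule == "poly_A":
        if grammar.tail_motifs and rng.random() < 0.5:
            return grammar.tail_motifs[rng.integers(len(grammar.tail_motifs))]
        return "A" * int(rng.integers(5, 9))
    if grammar.tail_rule == "poly_GA":
        return "GA" * int(rng.integers(3, 6))
    # poly_X
    if grammar.tail_motifs:
        return grammar.tail_motifs[rng.integers(len(grammar.tail_motifs))]
    return "".join("SVITL"[rng.integers(5)] for _ in range(8))


def _foreign_core_hit(seq: str, grammar: MotifGrammar,
                      grammars: list[MotifGrammar]) -> bool:
    for g in grammars:
        if g.family == grammar.family:
            continue
        for m in g.core_motifs:
            if m not in grammar.core_motifs and m in seq:
                return True
    return False


def _make_unit(grammar: MotifGrammar, repeat_len_aa: int,
               rng: np.random.Generator,
               grammars: list[MotifGrammar]) -> RepeatUnit:
    longest = max(len(m) for m in grammar.core_motifs)
    if repeat_len_aa < longest:
        raise ValueError(
            f"repeat_len_aa={repeat_len_aa} shorter than longest grammar "
            f"motif ({longest} aa)")
    for _attempt in range(200):
        tail = _make_tail(grammar, rng)
        budget = max(repeat_len_aa - len(tail), longest)
        core = []
        while sum(map(len, core)) < budget:
            motif = grammar.core_motifs[rng.integers(len(grammar.core_motifs))]
            spacer = "".join(_FILLER[rng.integers(len(_FILLER))]
                             for _ in range(rng.integers(0, 3)))
            core.append(motif + spacer)
        body = "".join(core)
        # trim spacer overhang but never cut into the final core motif
        first = grammar.core_motifs[0]
        body = body[:budget]
        if not any(m in body for m in grammar.core_motifs):
            body = first + body[len(first):budget]
        seq = body + tail
        if "AAAA" in body and grammar.tail_rule != "poly_A":
            continue
        if grammar.tail_rule == "none" and "AAAA" in seq:
            continue
        if _foreign_core_hit(seq, grammar, grammars):
            continue
        kind, tseq = classify_tail(seq, grammar.tail_motifs)
        return RepeatUnit(aa_seq=seq, tail_kind=kind, tail_seq=tseq)
    raise RuntimeError("could not build a grammar-consistent repeat unit")


def build_gene(grammar: MotifGrammar | str, n_repeats: int, repeat_len_aa: int,
               seed: int, name: str | None = None) -> SpidroinGeneModel:
    """Build a synthetic spidroin gene from a motif grammar.

    The repeat array is a tandem amplification: one unit is constructed to
    satisfy the grammar (>=1 core motif, the grammar's tail rule) and then
    replicated at the nucleotide level, emulating the near-identity of real
    spidroin repeats.  Deterministic for a fixed seed.
    """
    grammars = load_grammars()
    if isinstance(grammar, str):
        grammar = grammar_for(grammar, grammars)
    if n_repeats < 0:
        raise ValueError("n_repeats must be nonnegative")
    rng = np.random.default_rng(seed)
    ntd = _domains.NTD[grammar.family]
    ctd = _domains.CTD[grammar.family]
    if n_repeats:
        unit = _make_unit(grammar, repeat_len_aa, rng, grammars)
        unit_nt = reverse_translate(unit.aa_seq, rng)
        units = [RepeatUnit(aa_seq=unit.aa_seq, tail_kind=unit.tail_kind,
                            tail_seq=unit.tail_seq) for _ in range(n_repeats)]
    else:
        units, unit_nt = [], ""
    cds = (reverse_translate(ntd, rng) + unit_nt * n_repeats
           + reverse_translate(ctd, rng))
    gene = SpidroinGeneModel(
        name=name or f"{grammar.family}_synthetic",
        family=grammar.family, ntd=ntd, repeats=units, ctd=ctd, cds_nt=cds)
    gene.validate()
    return gene


def _add_substitutions(seq: str, err_rate: float,
                       rng: np.random.Generator) -> str:
    if err_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.size) < err_rate)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hit:
        choices = bases[bases != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode()


def simulate_short_reads(source: str, coverage: float, read_len: int,
                         err_rate: float = 0.0, paired: bool = False,
                         insert_mean: int = 300, seed: int = 0) -> ReadSet:
    """Simulate Illumina-like reads with i.i.d. substitution errors.

    Read count is round(coverage * len(source) / read_len); pairs count as
    two reads.  Every read's origin interval and strand are recorded in
    ``source_truth``.
    """
    if read_len > len(source):
        raise ValueError("read_len exceeds source length")
    rng = np.random.default_rng(seed)
    n_reads = int(round(coverage * len(source) / read_len))
    reads: list[Read] = []
    truth: dict[str, tuple[int, int, str]] = {}

    def emit(idx: str, start: int, strand: str, mate: str | None) -> None:
        sub = source[start:start + read_len]
        if strand == "-":
            sub = revcomp(sub)
        sub = _add_substitutions(sub, err_rate, rng)
        reads.append(Read(id=idx, seq=sub, qual="I" * read_len, mate=mate))
        truth[idx] = (start, start + read_len, strand)

    if paired:
        n_pairs = n_reads // 2
        sd = 0.1 * insert_mean
        for p in range(n_pairs):
            insert = int(np.clip(round(rng.normal(insert_mean, sd)),
                                 read_len, len(source)))
            fstart = int(rng.integers(0, len(source) - insert + 1))
            a, b = f"sr{p}/1", f"sr{p}/2"
            emit(a, fstart, "+", b)
            emit(b, fstart + insert - read_len, "-", a)
    else:
        for i in range(n_reads):
            start = int(rng.integers(0, len(source) - read_len + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            emit(f"sr{i}", start, strand, None)
    return ReadSet(reads=reads, platform="short", source_truth=truth)


def simulate_long_reads(source: str, coverage: float, mean_len: int,
                        err_rate: float = 0.0, seed: int = 0) -> ReadSet:
    """Simulate Nanopore-like long reads.

    Lengths are gamma(shape=2) with the requested mean, truncated to the
    source length; reads are drawn until total bases reach
    coverage * len(source).  Errors split 60% substitutions, 20%
    insertions, 20% deletions of ``err_rate``.
    """
    if mean_len < 500:
        raise ValueError("mean_len must be >= 500")
    rng = np.random.default_rng(seed)
    target = coverage * len(source)
    total = 0
    reads: list[Read] = []
    truth: dict[str, tuple[int, int, str]] = {}
    i = 0
    while total < target:
        length = int(min(len(source), max(200, rng.gamma(2.0, mean_len / 2.0))))
        start = int(rng.integers(0, len(source) - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        sub = source[start:start + length]
        if strand == "-":
            sub = revcomp(sub)
        seq = _apply_long_errors(sub, err_rate, rng)
        rid = f"lr{i}"
        reads.append(Read(id=rid, seq=seq, qual="I" * len(seq)))
        truth[rid] = (start, start + length, strand)
        total += length
        i += 1
    return ReadSet(reads=reads, platform="long", source_truth=truth)


def _apply_long_errors(seq: str, err_rate: float,
                       rng: np.random.Generator) -> str:
    if err_rate <= 0:
        return seq
    p_sub, p_ins, p_del = 0.6 * err_rate, 0.2 * err_rate, 0.2 * err_rate
    out = []
    bases = "ACGT"
    for ch in seq:
        r = rng.random()
        if r < p_del:
            continue
        if r < p_del + p_sub:
            alt = bases[rng.integers(4)]
            while alt == ch:
                alt = bases[rng.integers(4)]
            out.append(alt)
        else:
            out.append(ch)
        if rng.random() < p_ins:
            out.append(bases[rng.integers(4)])
    return "".join(out)
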