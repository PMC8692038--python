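"""Repeat-unit decomposition, motif scanning and spidroin family classification.

Spidroins are architecturally an N-terminal domain, a long array of near-
identical repeat units, and a C-terminal domain.  Families (MaSp1-5,
MiSp1B/C/D, Flag) are diagnosed by the short amino-acid motifs of their
repeat units and by the kind of "tail" ending each unit: the classic
beta-sheet-forming poly-alanine tail, a poly-GA tail, or its replacement by
other neutral residues (S, V, I, T, L) -- the poly-X tail seen in the bark
spiders' MaSp4 and MiSp1C.  The packaged grammar lives in
``data/grammar.tsv``; motifs not explicitly reported for *Caerostris*
(the MiSp and Flag cores) are reconstructed stand-ins and marked as such
in the table's notes column.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from . import _domains

AA20 = set("ACDEFGHIKLMNPQRSTVWY")
POLY_X_ALPHABET = set("SVITLA")  # 'A' allowed but never as a run of >=4

FAMILY_ORDER = [
    "MaSp1", "MaSp2", "MaSp3", "MaSp4", "MaSp5",
    "MiSp1B", "MiSp1C", "MiSp1D", "Flag",
]

_POLY_GA_RE = re.compile(r"(?:GA){3,}$")
_POLY_A_RE = re.compile(r"A{4,}$")


@dataclass
class RepeatUnit:
    """One repeat unit of a spidroin repetitive domain."""

    aa_seq: str
    motif_hits: list[tuple[str, int]] = field(default_factory=list)
    tail_kind: str = "none"  # poly_A | poly_GA | poly_X | none
    tail_seq: str = ""

    def __post_init__(self):
        if self.tail_kind not in ("poly_A", "poly_GA", "poly_X", "none"):
            raise ValueError(f"unknown tail_kind {self.tail_kind!r}")


@dataclass
class MotifGrammar:
    """Family-diagnostic repeat motifs and tail rule for one spidroin family."""

    family: str
    clade: str
    core_motifs: list[str]
    tail_rule: str  # poly_A | poly_GA | poly_X | none
    tail_motifs: list[str] = field(default_factory=list)
    notes: str = ""


@dataclass
class CompositionReport:
    fractions: dict[str, float]
    cys_fraction: float
    gly_fraction: float
    pro_fraction: float
    is_crp: bool
    length_aa: int


def load_grammars(path: str | Path | None = None) -> list[MotifGrammar]:
    """Load the packaged (or a user-supplied) grammar table."""
    if path is None:
        text = (resources.files("silkforge") / "data" / "grammar.tsv").read_text()
    else:
        text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    out = []
    for ln in lines[1:]:
        row = dict(zip(header, ln.split("\t")))
        out.append(MotifGrammar(
            family=row["family"],
            clade=row["clade"],
            core_motifs=[m for m in row["core_motifs"].split(",") if m],
            tail_rule=row["tail_rule"],
            tail_motifs=[m for m in row.get("tail_motifs", "").split(",") if m],
            notes=row.get("notes", ""),
        ))
    return out


def grammar_for(family: str, grammars: list[MotifGrammar] | None = None) -> MotifGrammar:
    grammars = grammars if grammars is not None else load_grammars()
    for g in grammars:
        if g.family == family:
            return g
    valid = [g.family for g in grammars]
    raise ValueError(f"unknown family label {family!r}; valid labels: {valid}")


def _find_all(hay: str, needle: str) -> list[int]:
    hits, i = [], hay.find(needle)
    while i != -1:
        hits.append(i)
        i = hay.find(needle, i + 1)
    return hits


def classify_tail(aa_seq: str, tail_motifs: list[str] = ()) -> tuple[str, str]:
    """Determine the tail kind and tail sequence of a repeat unit.

    Explicit tail motifs (e.g. VSVVSTTVS, SSSVAISL) are matched as suffixes
    first; otherwise a >=3x tandem GA suffix is poly_GA, a run of >=4 A is
    poly_A, and a suffix of >=6 neutral residues (S,V,I,T,L, with A allowed
    only in runs <4) is poly_X.
    """
    for m in tail_motifs:
        if aa_seq.endswith(m):
            kind = "poly_A" if "AAAA" in m else "poly_X"
            return kind, m
    m = _POLY_GA_RE.search(aa_seq)
    if m:
        return "poly_GA", m.group(0)
    m = _POLY_A_RE.search(aa_seq)
    if m:
        return "poly_A", m.group(0)
    # maximal neutral-residue suffix
    i = len(aa_seq)
    while i > 0 and aa_seq[i - 1] in POLY_X_ALPHABET:
        i -= 1
    suffix = aa_seq[i:]
    if len(suffix) >= 6 and not re.search(r"A{4}", suffix):
        return "poly_X", suffix
    return "none", ""


def scan_motifs(unit: RepeatUnit, grammar: MotifGrammar) -> RepeatUnit:
    """Annotate a repeat unit with exact core/tail motif hits and its tail kind."""
    hits: list[tuple[str, int]] = []
    for motif in list(grammar.core_motifs) + list(grammar.tail_motifs):
        for off in _find_all(unit.aa_seq, motif):
            hits.append((motif, off))
    kind, tail = classify_tail(unit.aa_seq, grammar.tail_motifs)
    return RepeatUnit(aa_seq=unit.aa_seq, motif_hits=sorted(hits, key=lambda h: (h[1], h[0])),
                      tail_kind=kind, tail_seq=tail)


def _rolling_mean(m: np.ndarray, w: int) -> np.ndarray:
    c = np.concatenate([[0.0], np.cumsum(m)])
    return (c[w:] - c[:-w]) / w


def _lag_scores(seq: str, period_min: int, period_max: int) -> dict[int, float]:
    """Per-lag self-similarity: the best local (windowed) match fraction,
    so short repetitive spans are not washed out by long unique flanks."""
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = {}
    for q in range(period_min, min(period_max, len(seq) - 1) + 1):
        m = (s[:-q] == s[q:]).astype(float)
        w = min(max(2 * q, 20), m.size)
        if w < 1:
            continue
        out[q] = float(_rolling_mean(m, w).max())
    return out


def decompose_repeats(protein: str, period_min: int = 4, period_max: int = 200,
                      min_fraction: float = 0.5) -> list[RepeatUnit]:
    """Segment a protein's repetitive span into tandem repeat units.

    The dominant period is the smallest lag whose windowed self-match score
    is within 5% of the best over [period_min, period_max]; the repetitive
    span is the maximal region where a rolling window of one period keeps
    a self-match fraction >= 0.7.  Non-repetitive proteins (no lag scores
    >= ``min_fraction``) yield an empty list.
    """
    if len(protein) < 2 * period_min:
        raise ValueError("protein shorter than twice the minimum period")
    scores = _lag_scores(protein, period_min, period_max)
    if not scores:
        return []
    best = max(scores.values())
    if best < min_fraction:
        return []
    q = min(k for k, v in scores.items() if v >= best - 0.05)
    s = np.frombuffer(protein.encode(), dtype=np.uint8)
    m = (s[:-q] == s[q:]).astype(float)
    if m.size < q:
        return []
    roll = _rolling_mean(m, q)  # roll[i] = mean(m[i:i+q])
    good = np.flatnonzero(roll >= 0.7)
    if good.size == 0:
        return []
    start, stop = int(good[0]), int(good[-1]) + 2 * q
    stop = min(stop, len(protein))
    # snap the start past flank residues the 0.7 window tolerance let in
    while start < m.size and not m[start]:
        start += 1
    n_units = (stop - start) // q
    if n_units < 2:
        return []
    return [RepeatUnit(aa_seq=protein[start + k * q: start + (k + 1) * q])
            for k in range(n_units)]


_ACCEPTED_TAILS = {
    "poly_A": {"poly_A"},
    "poly_GA": {"poly_GA"},
    "poly_X": {"poly_X"},
    "none": {"none"},
}


def _tail_agrees(unit: RepeatUnit, grammar: MotifGrammar) -> bool:
    if unit.tail_seq and unit.tail_seq in grammar.tail_motifs:
        return True
    return unit.tail_kind in _ACCEPTED_TAILS[grammar.tail_rule]


def classify_family(units: list[RepeatUnit], ntd_assignment: str | None = None,
                    grammars: list[MotifGrammar] | None = None,
                    ) -> tuple[str, dict]:
    """Assign a spidroin family label from repeat-unit motif content.

    Score per family = fraction of units containing >=1 core motif, plus a
    0.5 bonus weighted by the fraction of units whose tail satisfies the
    family's tail rule.  Nomenclature favours repeat content: when an
    N-terminal-domain clade assignment conflicts with the motif winner
    (e.g. a MaSp4-like repeat array on a MaSp2-clade NTD is *not* a
    conflict, since MaSp4 belongs to the MaSp2 clade), the motif winner is
    returned with ``conflict=True`` in the breakdown.
    """
    grammars = grammars if grammars is not None else load_grammars()
    order = {g.family: i for i, g in enumerate(grammars)}
    if not units:
        return "other", {"scores": {g.family: 0.0 for g in grammars}, "conflict": False}
    scores = {}
    for g in grammars:
        annotated = [scan_motifs(u, g) for u in units]
        core_frac = sum(
            1 for u in annotated if any(h[0] in g.core_motifs for h in u.motif_hits)
        ) / len(units)
        tail_frac = sum(1 for u in annotated if _tail_agrees(u, g)) / len(units)
        scores[g.family] = core_frac + 0.5 * tail_frac
    winner = min(scores, key=lambda f: (-scores[f], order[f]))
    g = grammar_for(winner, grammars)
    conflict = ntd_assignment is not None and ntd_assignment != g.clade
    return winner, {"scores": scores, "conflict": conflict, "clade": g.clade}


def classify_family_rotation_invariant(units: list[RepeatUnit],
                                       ntd_assignment: str | None = None,
                                       grammars: list[MotifGrammar] | None = None,
                                       ) -> tuple[str, dict]:
    """Classify repeat units whose phase within the tandem period is unknown.

    Units recovered by period detection start at an arbitrary offset within
    the repeat, so the diagnostic tail may sit mid-unit.  All cyclic
    rotations of the unit set are scored and the best-scoring rotation's
    verdict returned (ties broken by the smallest rotation).
    """
    grammars = grammars if grammars is not None else load_grammars()
    if not units:
        return classify_family(units, ntd_assignment, grammars)
    q = len(units[0].aa_seq)
    best = None
    for r in range(q):
        rotated = [RepeatUnit(aa_seq=u.aa_seq[r:] + u.aa_seq[:r]) for u in units]
        label, info = classify_family(rotated, ntd_assignment, grammars)
        key = (info["scores"].get(label, 0.0), -r)
        if best is None or key > best[0]:
            best = (key, label, info)
    return best[1], best[2]


def composition_stats(protein: str, crp_threshold: float = 0.05) -> CompositionReport:
    """Exact amino-acid composition with a cysteine-rich-protein (CRP) flag."""
    if not protein:
        raise ValueError("empty sequence")
    bad = set(protein) - AA20
    if bad:
        raise ValueError(f"unknown residue symbol(s): {sorted(bad)}")
    n = len(protein)
    counts = Counter(protein)
    fractions = {aa: counts.get(aa, 0) / n for aa in sorted(AA20) if counts.get(aa, 0)}
    cys = counts.get("C", 0) / n
    return CompositionReport(
        fractions=fractions,
        cys_fraction=cys,
        gly_fraction=counts.get("G", 0) / n,
        pro_fraction=counts.get("P", 0) / n,
        is_crp=cys >= crp_threshold,
        length_aa=n,
    )


def _protein_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -10.0
    a.extend_gap_score = -1.0
    a.mode = "global"
    return a


def assign_ntd_clade(ntd_protein: str) -> str:
    """Assign an N-terminal domain to its closest packaged clade template."""
    aligner = _protein_aligner()
    best, best_score = None, -np.inf
    for clade in sorted(set(_domains.FAMILY_CLADE.values())):
        fam = next(f for f, c in _domains.FAMILY_CLADE.items() if c == clade)
        score = aligner.score(ntd_protein, _domains.NTD[fam])
        if score > best_score:
            best, best_score = clade, score
    return best


def spice_candidates(proteome_shares: dict[str, float], tpm: dict[str, float],
                     spidroin_ids: set[str], tpm_floor: float = 1.0,
                     top_n: int = 4) -> list[str]:
    """Designate SpiCEs: the top non-spidroin proteins by proteome share
    whose mRNA expression clears the TPM floor."""
    ranked = sorted(
        (p for p, s in proteome_shares.items()
         if p not in spidroin_ids and tpm.get(p, 0.0) > tpm_floor),
        key=lambda p: (-proteome_shares[p], p),
    )
    return ranked[:top_n]
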