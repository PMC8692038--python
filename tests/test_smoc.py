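"""de Bruijn seeding, terminal-domain homology search, and PWM extension."""

import numpy as np
import pytest

import edlib
from silkforge import _domains
from silkforge.simgen import (Read, build_gene, reverse_translate, revcomp,
                              simulate_short_reads)
from silkforge.smoc import (Seed, build_debruijn, detect_repeat_boundary,
                            extend_seed, extract_unitigs, find_terminal_seeds)


def _rand_nt(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), n))


class TestDeBruijn:
    def test_toy_read_canonical_counts(self):
        # ACGTT: k-mers ACG, CGT, GTT; CGT canonicalizes to ACG (its
        # reverse complement), GTT to AAC
        g = build_debruijn([Read("r", "ACGTT")], 3, 1)
        assert g.nodes == {"ACG": 2, "AAC": 1}

    def test_reverse_complement_read_doubles_counts(self):
        src = _rand_nt(40, 3)
        one = build_debruijn([Read("r", src)], 7, 1)
        both = build_debruijn([Read("r", src), Read("rc", revcomp(src))], 7, 1)
        assert set(one.nodes) == set(both.nodes)
        assert all(both.nodes[k] == 2 * one.nodes[k] for k in one.nodes)

    def test_even_k_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            build_debruijn([Read("r", "ACGTACGT")], 4, 1)

    def test_min_count_filters_nodes(self):
        g = build_debruijn([Read("r", "ACGTTACGTT")], 5, 2)
        g1 = build_debruijn([Read("r", "ACGTTACGTT")], 5, 1)
        assert set(g.nodes) <= set(g1.nodes)

    def test_kmers_with_n_skipped(self):
        g = build_debruijn([Read("r", "ACGNTACGT")], 3, 1)
        assert not any("N" in k for k in g.nodes)


class TestUnitigs:
    def test_linear_path_single_contig(self):
        src = _rand_nt(40, 3)  # no internal k-mer/revcomp collisions at k=7
        g = build_debruijn([Read("r", src)], 7, 1)
        u = extract_unitigs(g)
        assert len(u) == 1
        assert u[0] in (src, revcomp(src))

    def test_branch_node_splits_into_three_contigs(self):
        rng = np.random.default_rng(4)
        core = "".join(rng.choice(list("ACGT"), 14))
        a = "".join(rng.choice(list("ACGT"), 12)) + core
        b = "".join(rng.choice(list("ACGT"), 12)) + core
        g = build_debruijn([Read("a", a), Read("b", b)], 7, 1)
        assert len(extract_unitigs(g)) == 3

    def test_empty_graph_gives_empty_list(self):
        g = build_debruijn([Read("r", "ACGTACGTA")], 5, 99)
        assert extract_unitigs(g) == []

    def test_simulated_coverage_reconstructs_unique_source(self):
        src = _rand_nt(5000, 8)
        reads = simulate_short_reads(src, 30, 150, 0.005, seed=9)
        contigs = extract_unitigs(build_debruijn(reads, 31, 3))
        best = max(contigs, key=len)
        assert len(best) >= 0.99 * len(src)
        ident = max(1 - edlib.align(c, src, mode="HW")["editDistance"] / len(c)
                    for c in (best, revcomp(best)))
        assert ident >= 0.999


@pytest.fixture(scope="module")
def ntd_contig():
    rng = np.random.default_rng(5)
    nt = reverse_translate(_domains.NTD["MaSp1"], rng)
    return _rand_nt(90, 6) + nt + _rand_nt(90, 7)


class TestTerminalSeeds:
    def test_exact_backtranslation_reaches_self_score(self, ntd_contig):
        from silkforge.smoc import _local_aligner
        domains = [("MaSp1_NTD", _domains.NTD["MaSp1"])]
        seeds = find_terminal_seeds([ntd_contig], domains, min_score=100)
        top = seeds[0]
        self_score = _local_aligner().score(_domains.NTD["MaSp1"],
                                            _domains.NTD["MaSp1"])
        assert top.score == self_score
        assert top.strand == "+" and top.frame == 0
        assert top.domain_kind == "N"
        assert (top.hit_start, top.hit_end) == (90, 90 + 450)

    def test_reverse_complement_contig_maps_back_to_forward(self, ntd_contig):
        domains = [("MaSp1_NTD", _domains.NTD["MaSp1"])]
        fwd = find_terminal_seeds([ntd_contig], domains, 100)[0]
        rev = find_terminal_seeds([revcomp(ntd_contig)], domains, 100)[0]
        assert rev.score == fwd.score
        assert rev.strand == "-"
        # re-extract: the reverse-complemented hit equals the forward hit
        sub = rev.contig_seq[rev.hit_start:rev.hit_end]
        assert revcomp(sub) == ntd_contig[fwd.hit_start:fwd.hit_end]

    def test_random_contigs_produce_no_seeds_at_half_self_score(self):
        from silkforge.smoc import _local_aligner
        domains = [(f"{f}_NTD", _domains.NTD[f]) for f in ("MaSp1", "MaSp5")]
        floor = min(_local_aligner().score(s, s) for _, s in domains) / 2
        contigs = [_rand_nt(1000, 100 + i) for i in range(40)]
        assert find_terminal_seeds(contigs, domains, floor) == []


class TestRepeatBoundary:
    def test_junction_located_within_tolerance(self):
        rng = np.random.default_rng(5)
        uniq = "".join(rng.choice(list("ACGT"), 600))
        unit = "".join(rng.choice(list("ACGT"), 30))
        b = detect_repeat_boundary(uniq + unit * 6, window=60, period_max=30)
        assert b is not None and abs(b - 600) <= 30

    def test_random_sequence_has_no_boundary(self):
        for s in range(50):
            seq = _rand_nt(2000, 200 + s)
            assert detect_repeat_boundary(seq, 60, 30) is None

    def test_all_repeat_input_boundary_zero(self):
        unit = _rand_nt(30, 9)
        assert detect_repeat_boundary(unit * 6, 60, 30) == 0

    def test_window_precondition(self):
        with pytest.raises(ValueError):
            detect_repeat_boundary("ACGT" * 100, 50, 30)


def _truth_seed(src, end=300, strand="+"):
    if strand == "+":
        return Seed("c", src[:end], 0, end, "+", 0, "N", "toy", 0.0)
    return Seed("c", revcomp(src[:end]), 0, end, "-", 0, "N", "toy", 0.0)


@pytest.fixture(scope="module")
def repeat_locus():
    rng = np.random.default_rng(10)
    uniq = "".join(rng.choice(list("ACGT"), 600))
    unit = "".join(rng.choice(list("ACGT"), 90))
    return uniq + unit * 8


class TestExtension:
    def test_error_free_extension_reaches_repeat_boundary(self, repeat_locus):
        src = repeat_locus
        reads = simulate_short_reads(src, 40, 150, 0.0, seed=11)
        cand = extend_seed(_truth_seed(src), reads, anchor_k=51,
                           min_depth=5, min_frac=0.8, direction="3p",
                           boundary_window=200, boundary_period_max=100)
        assert cand.halted_reason == "repeat_boundary"
        assert cand.consensus == src[:len(cand.consensus)]
        assert abs(cand.boundary_pos - 600) <= 51

    def test_pwm_columns_respect_thresholds(self, repeat_locus):
        reads = simulate_short_reads(repeat_locus, 40, 150, 0.0, seed=11)
        cand = extend_seed(_truth_seed(repeat_locus), reads, anchor_k=51,
                           min_depth=5, min_frac=0.8, direction="3p",
                           boundary_window=200, boundary_period_max=100)
        cols = [c for c in cand.per_column_support if c is not None]
        assert cols, "extension appended no columns"
        assert all(d >= 5 and f >= 0.8 for d, f in cols)

    def test_orientation_symmetric_consensus(self, repeat_locus):
        reads = simulate_short_reads(repeat_locus, 40, 150, 0.0, seed=11)
        kw = dict(boundary_window=200, boundary_period_max=100)
        fwd = extend_seed(_truth_seed(repeat_locus, strand="+"), reads, **kw)
        rev = extend_seed(_truth_seed(repeat_locus, strand="-"), reads, **kw)
        assert fwd.consensus == rev.consensus

    def test_noisy_reads_keep_consensus_identity(self, repeat_locus):
        reads = simulate_short_reads(repeat_locus, 50, 150, 0.01, seed=12)
        cand = extend_seed(_truth_seed(repeat_locus), reads, anchor_k=51,
                           min_depth=10, min_frac=0.8, direction="3p",
                           boundary_window=200, boundary_period_max=100)
        span = len(cand.consensus)
        truth = repeat_locus[:span]
        dist = edlib.align(cand.consensus, truth, mode="NW")["editDistance"]
        assert 1 - dist / span >= 0.999

    def test_coverage_gap_halts_with_no_support(self):
        src = _rand_nt(2400, 12)
        reads = simulate_short_reads(src[:1200], 40, 150, 0.0, seed=13)
        cand = extend_seed(_truth_seed(src), reads, direction="3p")
        assert cand.halted_reason == "no_support"
        assert len(cand.consensus) <= 1200

    def test_absent_anchor_leaves_seed_only(self):
        src = _rand_nt(1000, 14)
        other = simulate_short_reads(_rand_nt(1000, 15), 30, 150, 0.0, seed=16)
        cand = extend_seed(_truth_seed(src), other, direction="3p")
        assert cand.halted_reason == "no_support"
        assert cand.consensus == src[:300]


def test_end_to_end_recovery_zero_error(masp4_gene, masp4_short_reads):
    """Error-free 50x reads: seeds from both termini extend to the repeat
    array and reproduce the gene sequence exactly over their spans."""
    from silkforge.pipeline import reference_domains
    src = masp4_gene.cds_nt
    contigs = extract_unitigs(build_debruijn(masp4_short_reads, 31, 2))
    seeds = find_terminal_seeds(contigs, reference_domains(), 150)
    nseed = next(s for s in seeds if s.domain_kind == "N")
    cseed = next(s for s in seeds if s.domain_kind == "C")
    ncand = extend_seed(nseed, masp4_short_reads, direction="3p")
    ccand = extend_seed(cseed, masp4_short_reads, direction="5p")
    for cand in (ncand, ccand):
        assert cand.halted_reason == "repeat_boundary"
        assert cand.consensus in src  # 100% identity over the span
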