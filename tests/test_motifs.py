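"""PWM prediction, assembly, comparison, scanning and overlap counting."""

import numpy as np
import pytest

from prdm9kit.motifs import (
    ArrayPWM,
    FingerSpecificity,
    GenomicHit,
    assemble_array_pwm,
    compare_motifs,
    intersect_hits,
    overlap_matrix,
    predict_finger_pfm,
    pwm_for_allele,
    read_bed,
    read_jaspar,
    read_meme,
    reverse_complement_pwm,
    scan_sequences,
    score_threshold_from_pvalue,
    write_bed,
    write_jaspar,
    write_meme,
)


def dirichlet_pwm(name: str, width: int, seed: int) -> ArrayPWM:
    rng = np.random.default_rng(seed)
    return ArrayPWM(name=name, matrix=rng.dirichlet(np.ones(4), size=width).T)


class TestFingerPfm:
    def test_columns_stochastic_and_deterministic(self):
        f1 = predict_finger_pfm("TDK")
        f2 = predict_finger_pfm("TDK")
        assert np.allclose(f1.pfm.sum(axis=0), 1.0)
        assert np.array_equal(f1.pfm, f2.pfm)

    def test_external_matrix_passthrough(self):
        mat = np.array(
            [[0.7, 0.1, 0.25], [0.1, 0.7, 0.25], [0.1, 0.1, 0.25], [0.1, 0.1, 0.25]]
        )
        f = predict_finger_pfm("ASQ", predictor={"ASQ": mat})
        assert np.array_equal(f.pfm, mat)

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            predict_finger_pfm("TDX")

    def test_documented_preferences(self):
        # Arg prefers G; uniform column for residues without a preference
        f = predict_finger_pfm("RGA")
        assert f.pfm[:, 0].argmax() == 2  # G row
        assert np.allclose(f.pfm[:, 1], 0.25)


class TestAssembly:
    def test_width_is_three_per_finger(self):
        fingers = [predict_finger_pfm("TDK") for _ in range(5)]
        pwm = assemble_array_pwm("x", fingers)
        assert pwm.width == 15

    def test_single_finger_reverse_complement(self):
        # consensus ACG per column order -> assembled consensus CGT
        mat = np.array(
            [[0.9, 0.1, 0.0], [0.05, 0.8, 0.0], [0.03, 0.05, 0.9], [0.02, 0.05, 0.1]]
        )
        pwm = assemble_array_pwm("f", [FingerSpecificity("AAA", mat)])
        assert pwm.consensus() == "CGT"

    def test_reverse_complement_is_involution(self):
        fingers = [predict_finger_pfm(c) for c in ("TDK", "ASQ", "RRR")]
        concat = np.hstack([f.pfm for f in fingers])
        pwm = assemble_array_pwm("x", fingers)
        assert np.allclose(reverse_complement_pwm(pwm.matrix), concat)

    def test_empty_finger_list_errors(self):
        with pytest.raises(ValueError, match="empty"):
            assemble_array_pwm("x", [])


class TestCompare:
    def test_self_comparison_minimal_p(self):
        pwm = dirichlet_pwm("m", 12, seed=1)
        s = compare_motifs(pwm, pwm, n_shuffles=200, seed=3)
        assert s.best_offset == 0 and s.best_orientation == "+"
        assert s.p_value == pytest.approx(1 / 201)

    def test_too_narrow_motifs_no_similarity(self):
        a = dirichlet_pwm("a", 5, seed=2)
        b = dirichlet_pwm("b", 5, seed=3)
        s = compare_motifs(a, b, n_shuffles=200, seed=0, min_overlap=6)
        assert s.no_similarity
        assert s.neg_log10_p is None

    def test_seeded_determinism(self):
        a = dirichlet_pwm("a", 9, seed=4)
        b = dirichlet_pwm("b", 12, seed=5)
        s1 = compare_motifs(a, b, n_shuffles=300, seed=11)
        s2 = compare_motifs(a, b, n_shuffles=300, seed=11)
        assert s1 == s2

    def test_reverse_complement_detected(self):
        a = dirichlet_pwm("a", 10, seed=6)
        rc = ArrayPWM(name="rc", matrix=reverse_complement_pwm(a.matrix))
        s = compare_motifs(a, rc, n_shuffles=200, seed=0)
        assert s.best_orientation == "-"
        assert s.p_value == pytest.approx(1 / 201)

    def test_few_shuffles_rejected(self):
        a = dirichlet_pwm("a", 9, seed=7)
        with pytest.raises(ValueError, match="100"):
            compare_motifs(a, a, n_shuffles=50)


class TestThreshold:
    def test_p_one_returns_minimum_score(self):
        pwm = dirichlet_pwm("m", 6, seed=8)
        lo = pwm.log_odds()
        assert score_threshold_from_pvalue(pwm, 1.0) == pytest.approx(
            np.round(lo.min(axis=0).sum(), 3), abs=2e-3
        )

    def test_uniform_pwm_threshold_zero(self):
        pwm = ArrayPWM(name="u", matrix=np.full((4, 6), 0.25))
        assert score_threshold_from_pvalue(pwm, 0.5) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("p", [1e-3, 1e-4])
    def test_monte_carlo_calibration(self, p):
        """Empirical single-strand hit rate matches the requested p (3 SE)."""
        pwm = dirichlet_pwm("m", 12, seed=3)
        thr = score_threshold_from_pvalue(pwm, p)
        rng = np.random.default_rng(12345)
        n = 400_000
        seq = "".join(rng.choice(list("ACGT"), size=n + pwm.width - 1))
        hits = scan_sequences(pwm, {"c": seq}, thr)
        plus = sum(1 for h in hits if h.strand == "+")
        se = (n * p * (1 - p)) ** 0.5
        assert abs(plus - n * p) <= 3 * se


class TestScan:
    def test_planted_consensus_found_on_both_strands(self):
        pwm = dirichlet_pwm("m", 12, seed=9)
        cons = pwm.consensus()
        comp = str.maketrans("ACGT", "TGCA")
        rng = np.random.default_rng(0)
        bg = "".join(rng.choice(list("ACGT"), size=500))
        seq = bg[:100] + cons + bg[100:300] + cons.translate(comp)[::-1] + bg[300:]
        hits = scan_sequences(pwm, {"chr1": seq}, pwm.max_score() - 1e-6)
        coords = {(h.start, h.strand) for h in hits}
        assert (100, "+") in coords
        assert (312, "-") in coords  # 100 + 12 + 200-nt spacer

    def test_non_reversed_assembly_finds_opposite_strand(self):
        """The reverse-complement assembly convention flips the hit strand."""
        from prdm9kit.motifs import FingerSpecificity, assemble_array_pwm

        rng = np.random.default_rng(10)
        fingers = [
            FingerSpecificity("AAA", rng.dirichlet(np.ones(4) / 2, size=3).T)
            for _ in range(4)
        ]
        assembled = assemble_array_pwm("fwd", fingers)
        plain = ArrayPWM(
            name="plain", matrix=np.hstack([f.pfm for f in fingers])
        )
        site = assembled.consensus()
        bg = "".join(rng.choice(list("ACGT"), size=400))
        seq = bg[:200] + site + bg[200:]
        hits_a = scan_sequences(assembled, {"c": seq}, assembled.max_score() - 1e-6)
        hits_p = scan_sequences(plain, {"c": seq}, plain.max_score() - 1e-6)
        assert any(h.start == 200 and h.strand == "+" for h in hits_a)
        assert any(h.start == 200 and h.strand == "-" for h in hits_p)

    def test_empty_fasta_errors(self):
        with pytest.raises(ValueError, match="no sequences"):
            scan_sequences(dirichlet_pwm("m", 6, seed=1), {}, 0.0)

    def test_ambiguous_windows_skipped(self):
        pwm = dirichlet_pwm("m", 6, seed=11)
        seq = "ACGTAC" + "N" + "ACGTACGT"
        hits = scan_sequences(pwm, {"c": seq}, -1e9)
        for h in hits:
            assert "N" not in seq[h.start : h.end]


def hit(chrom, s, e, strand="+", name="x"):
    return GenomicHit(chrom, s, e, strand, 1.0, name)


class TestIntersect:
    def test_identical_disjoint_sets(self):
        a = [hit("c", 0, 10), hit("c", 20, 30), hit("c", 40, 50)]
        s = intersect_hits(a, list(a))
        assert s.n_pairs == 3
        assert s.jaccard == pytest.approx(1.0)

    def test_disjoint_sets(self):
        a = [hit("c", 0, 10)]
        b = [hit("c", 10, 20)]  # half-open: no shared base
        s = intersect_hits(a, b)
        assert s.n_pairs == 0
        assert s.jaccard == 0.0

    def test_one_bp_overlap_counts(self):
        s = intersect_hits([hit("c", 0, 18)], [hit("c", 17, 35)])
        assert s.n_pairs == 1

    def test_strand_agnostic_and_cross_chromosome(self):
        a = [hit("c1", 0, 10, "+"), hit("c2", 0, 10, "+")]
        b = [hit("c1", 5, 15, "-")]
        assert intersect_hits(a, b).n_pairs == 1

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(314)
        for _ in range(200):
            def rand_set():
                n = int(rng.integers(0, 20))
                out = []
                for _ in range(n):
                    s = int(rng.integers(0, 200))
                    w = int(rng.integers(1, 30))
                    out.append(hit(f"c{rng.integers(2)}", s, s + w))
                return out

            a, b = rand_set(), rand_set()
            expected = sum(
                1
                for x in a
                for y in b
                if x.chrom == y.chrom and min(x.end, y.end) > max(x.start, y.start)
            )
            assert intersect_hits(a, b).n_pairs == expected


class TestOverlapMatrix:
    def test_identical_sets_all_ones(self):
        a = [hit("c", 0, 10), hit("c", 50, 60)]
        counts, jac = overlap_matrix({"x": a, "y": list(a)})
        assert np.all(jac.values == 1.0)
        assert counts.loc["x", "y"] == 2

    def test_empty_set_zero_row(self):
        a = [hit("c", 0, 10)]
        counts, jac = overlap_matrix({"x": a, "empty": []})
        assert counts.loc["x", "empty"] == 0
        assert jac.loc["empty", "empty"] == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(9)
        sets = {}
        for name in "abc":
            sets[name] = [
                hit("c", int(s), int(s) + 10)
                for s in rng.integers(0, 300, size=8)
            ]
        counts, jac = overlap_matrix(sets)
        assert np.array_equal(counts.values, counts.values.T)
        assert np.allclose(jac.values, jac.values.T)


class TestIO:
    def test_bed_roundtrip(self, tmp_path):
        hits = [
            GenomicHit("chr1", 5, 17, "+", 8.123, "m1"),
            GenomicHit("chr2", 0, 12, "-", -1.5, "m2"),
        ]
        p = tmp_path / "h.bed"
        write_bed(hits, p)
        back = read_bed(p)
        assert [(h.chrom, h.start, h.end, h.strand, h.motif) for h in back] == [
            (h.chrom, h.start, h.end, h.strand, h.motif) for h in hits
        ]
        assert back[0].score == pytest.approx(8.12, abs=0.01)

    def test_meme_roundtrip(self, tmp_path, family_arrays):
        pwms = [pwm_for_allele(a) for a in family_arrays[:3]]
        p = tmp_path / "m.meme"
        write_meme(pwms, p)
        back = read_meme(p)
        assert [b.name for b in back] == [q.name for q in pwms]
        for b, q in zip(back, pwms):
            assert np.allclose(b.matrix, q.matrix, atol=1e-5)

    def test_jaspar_roundtrip(self, tmp_path):
        pwms = [dirichlet_pwm("a", 6, 1), dirichlet_pwm("b", 9, 2)]
        p = tmp_path / "m.jaspar"
        write_jaspar(pwms, p)
        back = read_jaspar(p)
        assert [b.name for b in back] == ["a", "b"]
        for b, q in zip(back, pwms):
            assert np.allclose(b.matrix, q.matrix, atol=1e-3)
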