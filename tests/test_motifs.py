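import itertools

import numpy as np
import pytest

from oracles import classify_rule_table, pwm_null_tail_enum
from somitime import (
    Pwm,
    candidate_enrichment,
    classify_pathway_motif,
    make_promoters,
    match_to_reference,
    pwm_similarity,
    read_meme,
    scan_promoters,
    write_meme,
)
from somitime.motifs import (
    estimate_background,
    genes_with_motif,
    integer_log_odds,
    score_distribution,
    score_threshold,
)

A1_CONSENSUS = "CGGGCGGCCAGGGGGGGGGGGGGCGGGGGCGGGGG"


def noisy_copy(pwm, name, sd, seed):
    rng = np.random.default_rng(seed)
    probs = np.clip(pwm.probs + rng.normal(0, sd, pwm.probs.shape), 1e-3, None)
    probs /= probs.sum(axis=1, keepdims=True)
    return Pwm(name, probs)


@pytest.fixture(scope="module")
def a1():
    return Pwm.from_consensus("A1", A1_CONSENSUS)


class TestSimilarity:
    def test_self_similarity(self, a1):
        sim = pwm_similarity(a1, a1)
        assert sim.best_r == pytest.approx(1.0, abs=1e-12)
        assert sim.overlap_fraction == 1.0
        assert sim.offset == 0
        assert sim.meets_overlap

    def test_shift_overlap_arithmetic(self, rng):
        probs = rng.dirichlet(np.ones(4), size=20)
        a = Pwm("a", probs)
        shifted = Pwm("b", np.vstack([probs[3:], probs[:3]]))
        sim = pwm_similarity(a, shifted, overlap_min=0.5)
        assert sim.offset == 3
        assert sim.overlap_fraction == pytest.approx((20 - 3) / 20)
        assert sim.best_r > 0.9

    def test_random_pwms_rarely_similar(self):
        rng = np.random.default_rng(0)
        high = 0
        for _ in range(200):
            a = Pwm("a", rng.dirichlet(np.ones(4), size=20))
            b = Pwm("b", rng.dirichlet(np.ones(4), size=20))
            if abs(pwm_similarity(a, b).best_r) >= 0.6:
                high += 1
        assert high <= 10  # >=95% of draws below the similarity gate

    def test_symmetry(self, rng, a1):
        other = noisy_copy(a1, "x", 0.2, 1)
        assert pwm_similarity(a1, other).best_r == pytest.approx(
            pwm_similarity(other, a1).best_r, abs=1e-9
        )


class TestMatchToReference:
    def test_pathway_fixtures_map_to_a1(self, a1):
        refs = [a1, Pwm.from_consensus("A4", "A" * 23 + "CCAACA")]
        for seed, name in enumerate(["W2", "N1", "F1"]):
            motif = noisy_copy(a1, name, 0.08, seed)
            ref, sim = match_to_reference(motif, refs)
            assert ref is not None and ref.name == "A1"
            assert sim.best_r > 0.6

    def test_orthogonal_motif_matches_nothing(self, a1):
        att = Pwm.from_consensus("x", "ATATATATATATATATATAT")
        ref, _ = match_to_reference(att, [a1])
        assert ref is None

    def test_overlap_gate_rejects_short_alignment(self, rng):
        # construct b as a 8-column copy of a 20-column motif: max overlap 40%
        probs = rng.dirichlet(np.ones(4), size=20)
        a = Pwm("a", probs)
        b = Pwm("b", probs[:8])
        sim = pwm_similarity(a, b, overlap_min=0.6)
        # alignment meeting the 60% floor cannot use the perfect 8-col match
        ref, _ = match_to_reference(b, [a])
        assert sim.overlap_fraction >= 0.6 or not sim.meets_overlap
        # the perfect short alignment alone must not produce a match
        assert ref is None or sim.meets_overlap


class TestScan:
    def test_planted_consensus_found_at_300(self, a1):
        promoters, _ = make_promoters(
            5, length=2000, gc=0.4, planted={2: [(300, A1_CONSENSUS)]}, seed=1
        )
        hits = scan_promoters(a1, promoters, score_p_max=1e-6)
        hit_rows = hits[hits["gene"] == "gene0002"]
        assert ((hit_rows["position"] == 300) & (hit_rows["strand"] == "+")).any()

    def test_no_hits_in_hostile_background(self):
        gc_rich = Pwm.from_consensus("g", "GCGCGCGCGCGC")
        promoters = {"a": "A" * 500}
        hits = scan_promoters(gc_rich, promoters, background=np.full(4, 0.25))
        assert len(hits) == 0

    def test_strand_consistency_under_reverse_complement(self, a1):
        promoters, _ = make_promoters(
            1, length=800, gc=0.5, planted={0: [(100, A1_CONSENSUS)]}, seed=5
        )
        seq = promoters["gene0000"]
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[b] for b in reversed(seq))
        bg = np.full(4, 0.25)
        fwd = scan_promoters(a1, {"x": seq}, 1e-6, background=bg)
        rev = scan_promoters(a1, {"x": rc}, 1e-6, background=bg)
        W = a1.width
        L = len(seq)
        mapped = sorted(
            (L - W - pos, {"+": "-", "-": "+"}[strand])
            for pos, strand in zip(rev["position"], rev["strand"])
        )
        assert mapped == sorted(zip(fwd["position"], fwd["strand"]))

    def test_null_distribution_sums_to_one_and_matches_enumeration(self):
        rng = np.random.default_rng(4)
        for W in (5, 7):
            pwm = Pwm("w", rng.dirichlet(np.full(4, 0.6), size=W))
            bg = np.array([0.3, 0.2, 0.2, 0.3])
            mat = integer_log_odds(pwm, bg)
            offset, dist = score_distribution(mat, bg)
            assert dist.sum() == pytest.approx(1.0, abs=1e-9)
            # pick an attainable site-level p ceiling for this width
            min_tail = np.cumsum(dist[::-1]).min()
            p_max = min(1e-2, 4 * float(min_tail))
            thr = score_threshold(mat, bg, p_max)
            tail = dist[thr - offset :].sum()
            assert tail == pytest.approx(
                pwm_null_tail_enum(mat, bg, thr), abs=1e-12
            )
            assert tail <= p_max


class TestClassification:
    @pytest.mark.parametrize(
        "fracs,label",
        [
            ((0.70, 0.10, 0.10), "one-pathway"),
            ((0.65, 0.62, 0.15), "two-pathway"),
            ((0.61, 0.60, 0.60), "three-pathway"),
            ((0.70, 0.30, 0.10), "unclassified"),
            ((0.50, 0.10, 0.10), "unclassified"),
        ],
    )
    def test_stated_rules(self, fracs, label):
        w, n, f = fracs
        out = classify_pathway_motif({"Wnt": w, "Notch": n, "Fgf": f})
        assert out.label == label

    def test_full_grid_matches_rule_oracle(self):
        grid = np.round(np.arange(0, 1.01, 0.1), 10)
        for w, n, f in itertools.product(grid, repeat=3):
            got = classify_pathway_motif({"Wnt": w, "Notch": n, "Fgf": f}).label
            assert got == classify_rule_table(w, n, f)

    def test_scale_free(self):
        # classification depends only on fractions, by construction of its
        # inputs; identical fractions from different set sizes agree
        a = classify_pathway_motif({"Wnt": 6 / 10, "Notch": 1 / 10, "Fgf": 0.0})
        b = classify_pathway_motif({"Wnt": 60 / 100, "Notch": 10 / 100, "Fgf": 0.0})
        assert a.label == b.label == "one-pathway"


class TestCandidateEnrichment:
    def test_planted_counts(self, a1):
        planted = {i: [(300, A1_CONSENSUS)] for i in range(80)}
        promoters, _ = make_promoters(100, length=1200, gc=0.4, planted=planted, seed=2)
        report = candidate_enrichment(list(promoters), [a1], promoters, 1e-6)
        assert report["per_motif"]["A1"]["count"] == 80
        assert report["n_with_any_motif"] == 80

    def test_empty_reference(self, a1):
        promoters, _ = make_promoters(5, length=300, seed=0)
        report = candidate_enrichment(list(promoters), [], promoters)
        assert report["n_with_any_motif"] == 0

    def test_disjoint_plants_union(self):
        m1 = "GGGGGCCCCCGGGGGCCCCC"
        m2 = "TTTTTAAAAATTTTTAAAAA"
        planted = {i: [(50, m1)] for i in range(40)}
        planted.update({i: [(50, m2)] for i in range(40, 80)})
        promoters, _ = make_promoters(100, length=600, gc=0.5, planted=planted, seed=9)
        pwms = [Pwm.from_consensus("m1", m1), Pwm.from_consensus("m2", m2)]
        report = candidate_enrichment(list(promoters), pwms, promoters, 1e-7)
        assert report["per_motif"]["m1"]["count"] == 40
        assert report["per_motif"]["m2"]["count"] == 40
        assert report["n_with_any_motif"] == 80

    def test_missing_promoters_reported(self, a1):
        promoters, _ = make_promoters(3, length=300, seed=0)
        report = candidate_enrichment(
            list(promoters) + ["absent_gene"], [a1], promoters
        )
        assert report["missing_promoters"] == ["absent_gene"]
        assert report["n_candidates_scanned"] == 3


class TestMemeIO:
    def test_roundtrip(self, tmp_path, rng, a1):
        motifs = [a1, Pwm("r", rng.dirichlet(np.ones(4), size=9))]
        path = tmp_path / "motifs.meme"
        write_meme(motifs, path)
        back = read_meme(path)
        assert [m.name for m in back] == ["A1", "r"]
        for orig, rec in zip(motifs, back):
            np.testing.assert_allclose(orig.probs, rec.probs, atol=1e-6)
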