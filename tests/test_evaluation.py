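"""F-score arithmetic, gene matching rules, operon and antisense stats."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from strandscan.evaluation import (
    GeneRecord,
    antisense_stats,
    compare_operons,
    evaluate,
    f_score,
    match_genes,
)


class TestFScore:
    @pytest.mark.parametrize("sn,pr,expected", [
        (87.01, 97.82, 92.10),
        (97.51, 98.05, 97.78),
        (96.54, 98.11, 97.32),
        (88.57, 96.32, 92.28),
        (100.0, 100.0, 100.0),
        (0.0, 55.0, 0.0),
        (0.0, 0.0, 0.0),
    ])
    def test_values(self, sn, pr, expected):
        assert round(f_score(sn, pr), 2) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            f_score(-1, 50)
        with pytest.raises(ValueError):
            f_score(50, 101)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(min_value=0.01, max_value=100),
           st.floats(min_value=0.01, max_value=100))
    def test_symmetric_harmonic_mean_bounds(self, a, b):
        f = f_score(a, b)
        assert f == pytest.approx(f_score(b, a))
        assert min(a, b) - 1e-9 <= f <= (a + b) / 2 + 1e-9
        assert f_score(a, a) == pytest.approx(a)


def rec(tid, s, e, strand="+"):
    return GeneRecord(tid, s, e, strand)


class TestMatchGenes:
    def test_identical_prediction_matches_both_modes(self):
        for mode in ("complete", "overlap80"):
            m = match_genes([rec("t", 30, 330)], [rec("t", 30, 330)],
                            {"t": 400}, mode)
            assert (m.tp, m.fp, m.fn, m.excluded) == (1, 0, 0, 0)

    def test_eighty_percent_cover_in_frame(self):
        # prediction covers the 3'-most 80% in frame: a hit at overlap80;
        # under 'complete' it is neither TP nor FP (it still clears the 80%
        # bar), so the gene counts as FN only
        ann = [rec("t", 0, 300)]
        pred = [rec("t", 60, 300)]
        m80 = match_genes(pred, ann, {"t": 400}, "overlap80")
        assert (m80.tp, m80.fp, m80.fn) == (1, 0, 0)
        mc = match_genes(pred, ann, {"t": 400}, "complete")
        assert (mc.tp, mc.fp, mc.fn) == (0, 0, 1)

    def test_out_of_frame_overlap_is_false_positive(self):
        m = match_genes([rec("t", 61, 301)], [rec("t", 0, 300)],
                        {"t": 400}, "overlap80")
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    def test_wrong_strand_is_false_positive(self):
        m = match_genes([rec("t", 0, 300, "-")], [rec("t", 0, 300, "+")],
                        {"t": 400}, "overlap80")
        assert (m.tp, m.fp) == (0, 1)

    def test_partial_five_prime_prediction_excluded(self):
        # transcript truncates the gene's 5' end (annotation start < 0);
        # the prediction keeps the in-frame stop but starts mid-gene
        ann = [rec("t", -90, 300)]
        pred = [rec("t", 30, 300)]
        m = match_genes(pred, ann, {"t": 400}, "overlap80")
        assert (m.tp, m.fp, m.fn, m.excluded) == (0, 0, 0, 1)
        assert m.annotated_covered == 0

    def test_partial_five_prime_antisense_excluded(self):
        # antisense gene truncated on its 5' side = annotation end > length
        ann = [rec("t", 100, 520, "-")]
        pred = [rec("t", 100, 400, "-")]
        m = match_genes(pred, ann, {"t": 450}, "overlap80")
        assert (m.excluded, m.fp) == (1, 0)

    def test_matches_exhaustive_interval_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            L = 3000
            anns = []
            for i in range(int(rng.integers(1, 6))):
                s = int(rng.integers(0, L - 400))
                e = s + 3 * int(rng.integers(50, 120))
                anns.append(rec("t", s, e))
            preds = []
            for i in range(int(rng.integers(0, 6))):
                a = anns[int(rng.integers(0, len(anns)))]
                jitter = 3 * int(rng.integers(-20, 20))
                preds.append(rec("t", max(0, a.start + jitter), a.end))
            m = match_genes(preds, anns, {"t": L}, "overlap80")
            # independent nested-loop re-derivation
            tp = 0
            for a in anns:
                ok = False
                for p in preds:
                    shared = min(p.end, a.end) - max(p.start, a.start)
                    if (shared > 0 and (p.start - a.start) % 3 == 0
                            and shared / (a.end - a.start) >= 0.8):
                        ok = True
                tp += ok
            assert m.tp == tp
            assert m.fn == len(anns) - tp


class TestEvaluate:
    def test_perfect_predictions(self):
        anns = [rec("t", 0, 300), rec("t", 400, 700)]
        reports = evaluate(list(anns), anns, {"t": 800})
        for r in reports.values():
            assert (r.sn, r.pr, r.f) == (100.0, 100.0, 100.0)

    def test_sensitivity_arithmetic_at_scale(self):
        # 1889 of 2171 covered genes matched -> Sn 87.01%
        anns = [rec(f"t{i}", 0, 300) for i in range(2171)]
        preds = [rec(f"t{i}", 0, 300) for i in range(1889)]
        lengths = {f"t{i}": 300 for i in range(2171)}
        r = evaluate(preds, anns, lengths)["complete"]
        assert round(r.sn, 2) == 87.01

    def test_precision_uses_shared_fp_set(self):
        # one exact hit, one 80% in-frame hit, one miss: the 80% hit is not
        # an FP under 'complete', so Pr_complete = 1/2, not 1/3
        anns = [rec("t", 0, 300), rec("t", 400, 700), rec("t", 800, 1100)]
        preds = [rec("t", 0, 300), rec("t", 460, 700),
                 rec("t", 1200, 1500)]
        r = evaluate(preds, anns, {"t": 1600})
        assert (r["overlap80"].tp, r["overlap80"].fp) == (2, 1)
        assert r["overlap80"].pr == pytest.approx(100 * 2 / 3)
        assert (r["complete"].tp, r["complete"].fp) == (1, 1)
        assert r["complete"].pr == pytest.approx(50.0)

    def test_no_predictions_flags_precision(self):
        r = evaluate([], [rec("t", 0, 300)], {"t": 400})
        assert not r["complete"].pr_defined
        assert r["complete"].pr == 0.0

    def test_random_predictions_score_poorly(self):
        rng = np.random.default_rng(23)
        anns = [rec(f"t{i}", 300, 900) for i in range(40)]
        preds = [rec(f"t{i}", int(rng.integers(0, 1200)) * 3 % 1500,
                     1500 + 300) for i in range(40)]
        lengths = {f"t{i}": 2000 for i in range(40)}
        r = evaluate(preds, anns, lengths)["overlap80"]
        assert r.f < 50.0


class TestOperons:
    def test_identical_operon_complete_and_matched(self):
        known = [[(0, 300), (320, 620)]]
        c = compare_operons(known, known)
        assert (c.n_complete, c.n_matched_80) == (1, 1)
        assert (c.n_contained, c.n_spanning) == (0, 0)

    def test_prediction_spanning_two_known_operons(self):
        # a predicted operon bridging two known ones across a 92-nt gap
        known = [[(0, 300), (305, 605)], [(697, 1000), (1005, 1300)]]
        pred = [[(305, 605), (697, 1000)]]
        c = compare_operons(pred, known)
        assert c.n_spanning == 1
        assert c.n_complete == 0

    def test_contained_three_of_four_genes(self):
        known = [[(0, 300), (310, 610), (620, 920), (930, 1230)]]
        pred = [[(310, 610), (620, 920), (930, 1230)]]
        c = compare_operons(pred, known)
        assert (c.n_matched_80, c.n_contained, c.n_complete) == (1, 1, 0)

    def test_invariants_hold(self):
        known = [[(0, 300), (320, 620)], [(700, 1000)]]
        preds = [[(0, 300), (320, 620)], [(320, 620)], [(100, 700)]]
        c = compare_operons(preds, known)
        assert c.n_complete <= c.n_matched_80 <= c.n_predicted
        assert c.n_contained + c.n_spanning <= c.n_predicted - c.n_complete

    def test_overlapping_genes_rejected(self):
        with pytest.raises(ValueError):
            compare_operons([[(0, 300), (200, 500)]], [[(0, 300)]])


class TestAntisenseStats:
    def test_hand_classified_cases(self):
        genes = [(1000, 1600, "+"), (2000, 2600, "+"), (3000, 3600, "-"),
                 (5000, 5300, "+")]
        cases = [
            ((1300, 1700, "-"), "partial_single_opposite"),  # half of gene 1
            ((900, 1700, "-"), "contains_gene"),             # full gene 1
            ((1300, 2300, "-"), "other"),          # two opposite genes
            ((3200, 3700, "+"), "partial_single_opposite"),
            ((3200, 3700, "-"), "other"),          # same-strand overlap
            ((4000, 4500, "-"), "other"),          # no gene at all
            ((4900, 5400, "-"), "contains_gene"),
            ((2500, 2700, "-"), "partial_single_opposite"),
            ((2000, 2600, "-"), "contains_gene"),  # exact containment
            ((100, 400, "+"), "other"),
        ]
        counts = antisense_stats([c[0] for c in cases], genes)
        expect = {"partial_single_opposite": 0, "contains_gene": 0,
                  "other": 0}
        for _, label in cases:
            expect[label] += 1
        assert counts == expect
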