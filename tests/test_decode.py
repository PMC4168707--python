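"""Viterbi decoding, gene extraction, classification, end-to-end driver."""

import filecmp

import numpy as np
import pytest

import strandscan as ss
from strandscan.decode import (
    ANTISENSE_CODING,
    SENSE_CODING,
    Transcript,
    classify_transcript,
    extract_genes,
    predict,
    viterbi,
)
from strandscan.model import reverse_complement, mirror_parameters
from strandscan.simulate import simulate_transcription
from conftest import brute_force_score, build_path, random_parameters, random_seq


class TestViterbi:
    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            k = int(rng.integers(0, 3))
            p = random_parameters(rng, k=k)
            L = int(rng.integers(4, 13))
            seq = "".join(rng.choice(list("ACGTN"), size=L,
                                     p=[.24, .24, .24, .24, .04]))
            path = viterbi(seq, p)
            assert path.score == pytest.approx(brute_force_score(seq, p),
                                               abs=1e-9)

    def test_all_n_sequence_default_transitions(self):
        # emissions cancel (uniform 1/4 for N everywhere): the best path is
        # decided by transitions alone and stays in the sense UTR
        p = ss.ModelParameters.default()
        path = viterbi("N" * 30, p)
        assert set(path.states) == {"UTR_S"}
        expected = np.log(0.5) + 29 * np.log(0.98) + 30 * np.log(0.25)
        assert path.score == pytest.approx(expected)

    def test_invalid_symbol_rejected(self):
        with pytest.raises(ValueError, match="invalid symbols"):
            viterbi("ACGU" * 10, ss.ModelParameters.uniform())

    def test_per_base_score_bounded_by_best_emission(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            p = random_parameters(rng, k=1)
            best = max(
                max(float(np.max(v)) for v in p.utr_emission.values()),
                max(float(np.max(vec)) for t in
                    list(p.match_sense.values())
                    + list(p.match_antisense.values())
                    for vec in t.values()),
                max(p.start_codon_probs.values()) ** (1 / 3),
                max(p.stop_codon_probs.values()) ** (1 / 3),
            )
            seq = random_seq(rng, int(rng.integers(30, 120)))
            path = viterbi(seq, p)
            assert path.score / len(seq) <= np.log(best) + 1e-9

    def test_planted_orf_recovered(self, benchmark):
        truth, lib = benchmark["truth"], benchmark["library"]
        tr = next(t for t in benchmark["transcripts"]
                  if t.provenance["kind"] == "sense")
        params = ss.select_parameters(tr.gc, lib)
        path = viterbi(tr, params)
        genes = extract_genes(path, tr, params).genes
        expected = [(f.start, f.end) for f in benchmark["projected"]
                    if f.seqid == tr.id]
        assert [(g.start, g.end) for g in genes] == sorted(expected)
        for g in genes:
            assert path.states[g.start] == "START_S"
            assert path.states[g.end - 1] == "STOP_S"
            assert set(path.states[g.start + 3:g.end - 3]) <= set(
                ("M1", "M2", "M3", "M4", "M5", "M6"))


class TestExtraction:
    def test_all_utr_path_is_empty(self):
        rng = np.random.default_rng(0)
        path = build_path([("UTR", 200)])
        tr = Transcript("t", random_seq(rng, 200))
        assert extract_genes(path, tr).genes == []

    @pytest.mark.parametrize("body_nt,kept", [(111, False), (114, True)])
    def test_min_length_threshold_inclusive_120(self, body_nt, kept):
        # ORF length includes start and stop codons: 117 nt dropped, 120 kept
        rng = np.random.default_rng(1)
        path = build_path([("UTR", 30), ("GENE", body_nt), ("UTR", 30)])
        tr = Transcript("t", random_seq(rng, len(path.states)))
        res = extract_genes(path, tr, min_gene_length=120)
        if kept:
            assert [(g.start, g.end) for g in res.genes] == [(30, 30 + body_nt + 6)]
            assert res.n_dropped_short == 0
        else:
            assert res.genes == []
            assert res.n_dropped_short == 1

    def test_two_orf_operon_path(self):
        rng = np.random.default_rng(2)
        path = build_path([("UTR", 10), ("GENE", 120), ("UTR", 25),
                           ("GENE", 150), ("UTR", 10)])
        tr = Transcript("t", random_seq(rng, len(path.states)))
        genes = extract_genes(path, tr).genes
        assert len(genes) == 2
        (a, b) = genes
        assert a.end <= b.start
        assert all(g.length % 3 == 0 for g in genes)
        assert all(g.frame == g.start % 3 for g in genes)
        assert all(g.has_start and g.has_stop for g in genes)

    def test_antisense_coordinates_and_sequence(self):
        rng = np.random.default_rng(3)
        path = build_path([("UTR", 15), ("AGENE", 120), ("UTR", 15)])
        labels = list(path.states)
        # replace flanking UTR_S labels with the antisense UTRs the topology
        # would actually produce
        from strandscan.decode import DP_INDEX
        for i in range(15):
            labels[i] = "UTR3_A"
            path.dp_states[i] = DP_INDEX["UTR3_A"]
            labels[-1 - i] = "UTR5_A"
            path.dp_states[-1 - i] = DP_INDEX["UTR5_A"]
        path = type(path)(states=tuple(labels), score=0.0,
                          dp_states=path.dp_states)
        tr = Transcript("t", random_seq(rng, len(labels)))
        genes = extract_genes(path, tr).genes
        assert len(genes) == 1
        g = genes[0]
        assert g.strand == "antisense"
        assert (g.start, g.end) == (15, 15 + 126)
        assert g.nucleotide == reverse_complement(tr.sequence[g.start:g.end])

    def test_path_length_mismatch_raises(self):
        path = build_path([("UTR", 10)])
        with pytest.raises(ValueError):
            extract_genes(path, Transcript("t", "ACGT" * 100))


class TestClassification:
    def _gene(self, strand):
        return ss.GeneCall(transcript_id="t", start=0, end=126, strand=strand,
                           has_start=True, has_stop=True, frame=0, score=1.0)

    def test_no_calls_is_noncoding(self):
        ann = classify_transcript(Transcript("t", "ACGT" * 40), [])
        assert ann.verdict == "sense_noncoding"

    def test_single_antisense_call(self):
        ann = classify_transcript(Transcript("t", "ACGT" * 40),
                                  [self._gene("antisense")])
        assert ann.verdict == "antisense"

    def test_multiple_sense_calls_is_operon(self):
        ann = classify_transcript(Transcript("t", "ACGT" * 80),
                                  [self._gene("sense"), self._gene("sense")])
        assert ann.verdict == "sense_coding"
        assert len(ann.genes) == 2

    def test_mixed_strand_calls_raise(self):
        with pytest.raises(RuntimeError):
            classify_transcript(Transcript("t", "ACGT" * 40),
                                [self._gene("sense"), self._gene("antisense")])


class TestMirrorConsistency:
    def test_sense_genes_map_to_antisense_on_reverse_complement(
            self, benchmark):
        # with mirrored parameters, symmetric initiation and the
        # single-antisense restriction disabled, genes predicted on T and on
        # revcomp(T) correspond at mirrored coordinates with equal scores
        from strandscan.simulate import (GeneratorConfig, generate_genome,
                                         training_corpus_from_truth)
        from conftest import TRAIN_SEEDS

        truths = [generate_genome(GeneratorConfig(seed=s,
                                                  genome_length=60_000))
                  for s in TRAIN_SEEDS]
        lib = ss.train(training_corpus_from_truth(truths),
                       restrict_antisense=False)
        params = ss.select_parameters(0.5, lib)
        params.transition["IDLE"] = {"UTR_S": 0.5, "UTR3_A": 0.5}
        params = mirror_parameters(params)

        checked = 0
        for tr in benchmark["transcripts"]:
            if tr.provenance["kind"] != "sense" or len(tr) > 2500:
                continue
            fwd = extract_genes(viterbi(tr, params), tr, params,
                                max_antisense=None)
            rc = Transcript("rc", reverse_complement(tr.sequence))
            rev = extract_genes(viterbi(rc, params), rc, params,
                                max_antisense=None)
            L = len(tr)
            sense_f = sorted((g.start, g.end, round(g.score, 6))
                             for g in fwd.genes if g.strand == "sense")
            anti_r = sorted((L - g.end, L - g.start, round(g.score, 6))
                            for g in rev.genes if g.strand == "antisense")
            assert sense_f == anti_r
            checked += 1
            if checked >= 5:
                break
        assert checked == 5


class TestPredictDriver:
    def test_deterministic_outputs(self, tmp_path, benchmark):
        transcripts = benchmark["transcripts"][:8]
        for d in ("run1", "run2"):
            predict(transcripts, benchmark["library"], tmp_path / d)
        cmp = filecmp.dircmp(tmp_path / "run1", tmp_path / "run2")
        assert not cmp.diff_files
        assert set(cmp.common) >= {"genes.gff3", "genes.faa", "genes.fna",
                                   "transcripts.tsv", "genes_partial.gff3"}

    def test_empty_input(self, tmp_path):
        out = predict([], ss.ModelParameters.uniform(), tmp_path / "empty")
        assert out == []
        assert (tmp_path / "empty" / "genes.gff3").exists()

    def test_short_transcripts_skipped(self):
        out = predict([("tiny", "ACGT" * 10)], ss.ModelParameters.uniform())
        assert out == []

    def test_frame_closure_on_benchmark(self, benchmark):
        # every complete call starts with a configured start codon, ends with
        # a configured stop codon, and has length divisible by 3
        params = benchmark["library"].bins[50]
        assert benchmark["predicted"], "benchmark produced no gene calls"
        for g in benchmark["predicted"]:
            assert g.length % 3 == 0
            assert g.nucleotide[:3] in params.start_codons
            assert g.nucleotide[-3:] in params.stop_codons
            aa = g.protein
            assert "*" not in aa

    def test_antisense_transcripts_never_yield_sense_calls(self, benchmark):
        kinds = {t.id: t.provenance["kind"] for t in benchmark["transcripts"]}
        for ann in benchmark["annotations"]:
            if kinds[ann.transcript_id] == "antisense":
                assert all(g.strand == "antisense" for g in ann.genes)
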