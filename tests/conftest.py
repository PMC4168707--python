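import numpy as np
import pytest

import strandscan as ss
from strandscan.decode import (
    DP_INDEX,
    N_DP,
    StatePath,
    build_emission_matrix,
    build_transition_matrix,
)
from strandscan.simulate import (
    GeneratorConfig,
    generate_genome,
    project_annotations,
    simulate_transcription,
    training_corpus_from_truth,
)


# ----------------------------------------------------------------------
# shared helpers

def random_parameters(rng, k=1, restrict_antisense=True):
    """Fully random valid parameters on the fixed topology (toy models for
    oracle comparisons; sense and antisense halves independently random)."""
    p = ss.ModelParameters.uniform(k=k, restrict_antisense=restrict_antisense)
    for row in p.transition.values():
        probs = rng.dirichlet([1.0] * len(row))
        for key, v in zip(sorted(row), probs):
            row[key] = float(v)
    for table in list(p.match_sense.values()) + \
            list(p.match_antisense.values()):
        for c in table:
            table[c] = rng.dirichlet([1.0] * 4)
    for s in p.utr_emission:
        p.utr_emission[s] = rng.dirichlet([1.0] * 4)
    sc = rng.dirichlet([1.0] * len(p.start_codons))
    p.start_codon_probs = {c: float(v) for c, v in zip(p.start_codons, sc)}
    st = rng.dirichlet([1.0] * len(p.stop_codons))
    p.stop_codon_probs = {c: float(v) for c, v in zip(p.stop_codons, st)}
    return p


def brute_force_score(seq, params):
    """Exhaustive maximum over all topology-valid state paths (depth-first
    enumeration); independent of the Viterbi recursion."""
    init, T = build_transition_matrix(params)
    E = build_emission_matrix(seq, params)
    L = len(seq)
    succ = [np.nonzero(np.isfinite(T[s]))[0] for s in range(N_DP)]
    best = [float("-inf")]

    def dfs(t, s, score):
        score = score + E[t, s]
        if t == L - 1:
            if score > best[0]:
                best[0] = score
            return
        for d in succ[s]:
            dfs(t + 1, d, score + T[s, d])

    for s in np.nonzero(np.isfinite(init))[0]:
        dfs(0, s, init[s])
    return best[0]


_M_CYCLE = ("M1", "M2", "M3", "M4", "M5", "M6")
_MA_CYCLE = ("M1A", "M2A", "M3A", "M4A", "M5A", "M6A")


def build_path(segments):
    """Synthesize a topology-shaped StatePath from a segment plan.

    Segments: ("UTR", n), ("GENE", body_nt) for a complete sense ORF, or
    ("AGENE", body_nt) for a complete antisense ORF (body_nt multiple of 3).
    """
    labels, dp = [], []

    def sig(name):
        for ph in range(3):
            labels.append(name)
            dp.append(DP_INDEX[f"{name}/{ph}"])

    for kind, n in segments:
        if kind == "UTR":
            labels.extend(["UTR_S"] * n)
            dp.extend([DP_INDEX["UTR_S"]] * n)
        elif kind == "GENE":
            sig("START_S")
            for i in range(n):
                labels.append(_M_CYCLE[i % 6])
                dp.append(DP_INDEX[_M_CYCLE[i % 6]])
            sig("STOP_S")
        elif kind == "AGENE":
            sig("STOP_A")
            for i in range(n):
                labels.append(_MA_CYCLE[i % 6])
                dp.append(DP_INDEX[_MA_CYCLE[i % 6]])
            sig("START_A")
        else:
            raise ValueError(kind)
    return StatePath(states=tuple(labels), score=0.0,
                     dp_states=np.array(dp, dtype=np.int64))


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# ----------------------------------------------------------------------
# session-scoped synthetic benchmark: train on one genome set, test on a
# disjoint one generated with the same codon-bias model

TRAIN_SEEDS = (11, 12)
TEST_SEED = 99


@pytest.fixture(scope="session")
def trained_library():
    truths = [generate_genome(GeneratorConfig(seed=s, genome_length=60_000))
              for s in TRAIN_SEEDS]
    return ss.train(training_corpus_from_truth(truths))


@pytest.fixture(scope="session")
def benchmark(trained_library):
    truth = generate_genome(GeneratorConfig(seed=TEST_SEED,
                                            genome_length=120_000))
    transcripts = simulate_transcription(truth)
    annotations = ss.predict(transcripts, trained_library)
    return {
        "truth": truth,
        "transcripts": transcripts,
        "by_id": {t.id: t for t in transcripts},
        "annotations": annotations,
        "predicted": [g for a in annotations for g in a.genes],
        "projected": project_annotations(truth, transcripts),
        "lengths": {t.id: len(t) for t in transcripts},
        "library": trained_library,
    }
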