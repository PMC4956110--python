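"""Syntax estimation, sub-state HMM construction, and Viterbi decoders."""

import itertools

import numpy as np
import pytest

from songscribe.annotations import Note
from songscribe.syntax import (
    DegenerateEmissionsError,
    DegeneratePriorError,
    InvalidPathError,
    StatePath,
    SyntaxModel,
    UnknownClassError,
    build_substate_hmm,
    convert_posterior_to_emission,
    decode_frame_sequence,
    decode_interval_sequence,
    fit_syntax_model,
    path_to_annotation,
    sample_sequences,
)


class TestSyntaxEstimation:
    def test_single_sequence_smoothing_worked_example(self):
        m = fit_syntax_model(["AABAAB"], alpha=0.5)
        a, b = m.class_index("A"), m.class_index("B")
        # P0(B|AA) = 1, so P(B|AA) = (1 + 0.5) / (1 + 2*0.5) = 0.75
        assert m.trans[a, a, b] == pytest.approx(0.75)
        assert m.trans[a, a, a] == pytest.approx(0.25)

    def test_large_alpha_tends_to_uniform(self):
        m = fit_syntax_model(["AABAAB"], alpha=1e6)
        assert np.allclose(m.trans, 0.5, atol=1e-5)

    def test_context_vectors_sum_to_one(self, rng):
        seqs = ["".join(rng.choice(list("abc"), size=10)) for _ in range(5)]
        for alpha in (0.0, 0.01, 1.0):
            m = fit_syntax_model(seqs, alpha)
            assert np.allclose(m.trans.sum(axis=2), 1.0, atol=1e-9)

    def test_unseen_contexts_are_uniform(self):
        m = fit_syntax_model(["AAAA"], alpha=0.0, classes=["A", "B"])
        b = m.class_index("B")
        assert np.allclose(m.trans[b, b], 0.5)

    def test_smoothing_monotone_toward_uniform(self):
        probs = []
        for alpha in (0.0, 0.01, 0.1, 1.0, 10.0):
            m = fit_syntax_model(["AABAAB"], alpha)
            a, b = m.class_index("A"), m.class_index("B")
            probs.append(m.trans[a, a, b])
        assert probs == sorted(probs, reverse=True)
        assert probs[0] == 1.0 and probs[-1] > 0.5

    def test_unknown_label_rejected(self):
        with pytest.raises(UnknownClassError):
            fit_syntax_model(["ABX"], 0.1, classes=["A", "B"])

    def test_recovery_from_sampled_sequences(self):
        """Transition probabilities of a known 4-class second-order syntax are
        recovered from 5000 simulated notes within sampling error."""
        from songscribe.synthetic import cyclic_syntax

        true = cyclic_syntax(list("wxyz"), p_main=0.95, p_alt=0.05)
        rng = np.random.default_rng(0)
        seqs = sample_sequences(true, 1, (5000, 5000), rng)
        est = fit_syntax_model(seqs, alpha=0.0, classes=true.classes)
        # compare contexts with enough visits for +/-0.03 to be meaningful
        counts = np.zeros((4, 4))
        idx = [true.class_index(c) for c in seqs[0]]
        for x, y in zip(idx, idx[1:]):
            counts[x, y] += 1
        dev = np.abs(est.trans - true.trans).max(axis=2)
        assert counts.max() >= 50
        assert dev[counts >= 50].max() <= 0.03


class TestSubstateHMM:
    @pytest.fixture(scope="class")
    def model(self):
        rng = np.random.default_rng(4)
        return SyntaxModel(["A", "B"], 0.0, rng.dirichlet(np.ones(2), size=(2, 2)))

    def test_rows_sum_to_one(self, model):
        hmm = build_substate_hmm(model)
        a = hmm.transition_matrix()
        assert np.allclose(a.sum(axis=1), 1.0, atol=1e-9)

    def test_printed_transition_formulas(self, model):
        n = 2
        hmm = build_substate_hmm(model)
        a = hmm.transition_matrix()
        i1 = hmm.state_index(("A", "B", 1))
        i2 = hmm.state_index(("A", "B", 2))
        i3 = hmm.state_index(("A", "B", 3))
        isil = hmm.state_index(("A", "B", "s"))
        assert a[i1, i1] == a[i1, i2] == 0.5
        assert a[i3, i3] == a[i3, isil] == pytest.approx(1 / (n + 2))
        x, b = model.class_index("A"), model.class_index("B")
        for z, zc in enumerate(model.classes):
            j = hmm.state_index(("B", zc, 1))
            assert a[i3, j] == pytest.approx(n / (n + 2) * model.trans[x, b, z])
            assert a[isil, j] == pytest.approx(n / (n + 1) * model.trans[x, b, z])
        assert a[isil, isil] == pytest.approx(1 / (n + 1))

    def test_left_to_right_structural_zeros(self, model):
        hmm = build_substate_hmm(model)
        a = hmm.transition_matrix()
        assert a[hmm.state_index(("A", "B", 2)), hmm.state_index(("A", "B", 1))] == 0
        assert a[hmm.state_index(("A", "B", 3)), hmm.state_index(("A", "B", 2))] == 0
        assert a[hmm.state_index(("A", "B", "s")), hmm.state_index(("A", "B", 3))] == 0

    def test_emission_mapping(self, model):
        hmm = build_substate_hmm(model)
        n = model.n
        assert hmm.emission_class[hmm.state_index(("A", "B", 2))] == 3 * 1 + 1
        assert hmm.emission_class[hmm.state_index(("A", "B", "s"))] == 3 * n

    def test_class_label_colliding_with_sentinel_rejected(self):
        m = SyntaxModel(["<e>", "B"], 0.0, np.full((2, 2, 2), 0.5))
        with pytest.raises(ValueError):
            build_substate_hmm(m)


class TestBayesConversion:
    def test_uniform_priors_rescale_only(self):
        scores = np.array([[0.8, 0.3], [0.2, 0.7]])
        out = convert_posterior_to_emission(scores, np.array([0.5, 0.5]))
        assert np.allclose(out, 2 * scores)

    def test_ratio_example(self):
        out = convert_posterior_to_emission(np.array([[0.8], [0.2]]), np.array([0.5, 0.5]))
        assert np.allclose(out[:, 0], [1.6, 0.4])

    def test_disabled_returns_posterior(self):
        scores = np.array([[0.8], [0.2]])
        assert np.array_equal(convert_posterior_to_emission(scores, np.array([0.5, 0.5]),
                                                            enabled=False), scores)

    def test_zero_prior_rejected(self):
        with pytest.raises(DegeneratePriorError):
            convert_posterior_to_emission(np.array([[1.0], [0.0]]), np.array([1.0, 0.0]))


def brute_interval(model, scores):
    n, m = model.n, len(scores)
    best, best_s = None, -np.inf
    for labels in itertools.product(range(n), repeat=m):
        s = 0.0
        for t, z in enumerate(labels):
            p = 1.0 / n if t < 2 else model.trans[labels[t - 2], labels[t - 1], z]
            if p == 0:
                s = -np.inf
                break
            s += np.log(p) + np.log(scores[t][z])
        if s > best_s + 1e-12:
            best_s, best = s, labels
    return [model.classes[i] for i in best]


class TestIntervalDecoder:
    def test_uniform_syntax_reduces_to_argmax(self):
        m = SyntaxModel(["A", "B"], 0.0, np.full((2, 2, 2), 0.5))
        scores = [np.array(v) for v in ([0.9, 0.1], [0.4, 0.6], [0.2, 0.8])]
        assert decode_interval_sequence(m, scores) == ["A", "B", "B"]

    def test_empty_input(self):
        m = SyntaxModel(["A", "B"], 0.0, np.full((2, 2, 2), 0.5))
        assert decode_interval_sequence(m, []) == []

    def test_matches_bruteforce_enumeration(self, rng):
        for _ in range(40):
            n = int(rng.integers(2, 4))
            m_len = int(rng.integers(1, 9))
            classes = [chr(65 + i) for i in range(n)]
            model = SyntaxModel(classes, 0.0, rng.dirichlet(np.ones(n), size=(n, n)))
            scores = list(rng.dirichlet(np.ones(n), size=m_len))
            assert decode_interval_sequence(model, scores) == brute_interval(model, scores)

    def test_syntax_overrides_weak_local_evidence(self):
        """An interval whose local argmax violates a near-deterministic rule
        is corrected when the syntax log-odds beat the emission log-odds."""
        trans = np.full((2, 2, 2), 0.5)
        trans[0, 0] = [0.999, 0.001]  # after A A, almost surely A again
        model = SyntaxModel(["A", "B"], 0.0, trans)
        scores = [np.array([0.9, 0.1]), np.array([0.9, 0.1]), np.array([0.45, 0.55])]
        got = decode_interval_sequence(model, scores)
        assert got == ["A", "A", "A"] == brute_interval(model, scores)


def brute_frame(hmm, emissions):
    logb = np.log(np.maximum(emissions, 1e-300))[hmm.emission_class]
    a = hmm.transition_matrix()
    loga = np.where(a > 0, np.log(np.maximum(a, 1e-300)), -np.inf)
    t_total = emissions.shape[1]
    best, best_s = None, -np.inf

    def rec(path, score):
        nonlocal best, best_s
        t = len(path)
        if t == t_total:
            if score > best_s + 1e-12:
                best_s, best = score, list(path)
            return
        for s in range(hmm.n_states):
            lp = hmm.log_init[s] if t == 0 else loga[path[-1], s]
            if lp == -np.inf:
                continue
            rec(path + [s], score + lp + logb[s, t])

    rec([], 0.0)
    return best, best_s


class TestFrameDecoder:
    @pytest.fixture(scope="class")
    def hmm(self):
        rng = np.random.default_rng(11)
        model = SyntaxModel(["A", "B"], 0.0, rng.dirichlet(np.ones(2), size=(2, 2)))
        return build_substate_hmm(model)

    def test_matches_bruteforce_enumeration(self, hmm, rng):
        for _ in range(8):
            t = int(rng.integers(3, 7))
            em = rng.dirichlet(np.ones(7), size=t).T
            path = decode_frame_sequence(hmm, em)
            bpath, bs = brute_frame(hmm, em)
            assert list(path.states) == bpath
            assert path.log_score == pytest.approx(bs)

    def test_onehot_legal_path_is_recovered(self, hmm):
        seq = [("<e>", "<e>", "s"), ("<e>", "A", 1), ("<e>", "A", 2),
               ("<e>", "A", 3), ("<e>", "A", "s")]
        em = np.full((7, len(seq)), 1e-12)
        for t, s in enumerate(seq):
            em[hmm.emission_class[hmm.state_index(s)], t] = 1.0
        path = decode_frame_sequence(hmm, em)
        assert [hmm.states[i] for i in path.states] == seq

    def test_short_subdivision_burst_cannot_split_a_note(self, hmm):
        """A 1-frame burst of sub-division-1 evidence inside a note does not
        create a boundary: 2 -> 1 transitions are structurally forbidden."""
        # emissions strongly favor A1 A2 [A1-burst] A2 A3
        classes = {("A", k): 3 * 0 + (k - 1) for k in (1, 2, 3)}
        em = np.full((7, 5), 1e-6)
        for t, k in enumerate([1, 2, 1, 2, 3]):
            em[classes[("A", k)], t] = 1.0
        ann = path_to_annotation(decode_frame_sequence(hmm, em))
        assert len(ann.notes) == 1

    def test_degenerate_emissions_rejected(self, hmm):
        em = np.zeros((7, 3))
        with pytest.raises(DegenerateEmissionsError):
            decode_frame_sequence(hmm, em)

    def test_minimum_note_duration_is_three_frames(self, hmm, rng):
        """Every completed decoded note spans at least 3 frames (one per
        sub-state); only a note truncated by the end of the sequence may be
        shorter, because decoding may stop in any state."""
        for _ in range(5):
            em = rng.dirichlet(np.ones(7), size=30).T
            ann = path_to_annotation(decode_frame_sequence(hmm, em))
            for note in ann.notes:
                if note.offset < ann.timeline_length:
                    assert note.duration >= 3


class TestPathToAnnotation:
    @pytest.fixture(scope="class")
    def hmm(self):
        model = SyntaxModel(["A", "B"], 0.0, np.full((2, 2, 2), 0.5))
        return build_substate_hmm(model)

    def _path(self, hmm, seq):
        return StatePath(np.array([hmm.state_index(s) for s in seq]), 0.0, hmm)

    def test_single_note_with_silence(self, hmm):
        seq = [("<e>", "<e>", "s")] * 2 + [("<e>", "A", 1)] * 2 + \
              [("<e>", "A", 2)] + [("<e>", "A", 3)] * 2 + [("<e>", "A", "s")]
        ann = path_to_annotation(self._path(hmm, seq))
        assert [(n.onset, n.offset, n.label) for n in ann.notes] == [(2, 7, "A")]

    def test_repetition_without_gap_splits_at_3_to_1(self, hmm):
        seq = [("<e>", "A", 1), ("<e>", "A", 2), ("<e>", "A", 3),
               ("A", "A", 1), ("A", "A", 2), ("A", "A", 3)]
        ann = path_to_annotation(self._path(hmm, seq))
        assert [(n.onset, n.offset) for n in ann.notes] == [(0, 3), (3, 6)]

    def test_all_silence_is_empty(self, hmm):
        ann = path_to_annotation(self._path(hmm, [("<e>", "<e>", "s")] * 5))
        assert len(ann.notes) == 0

    def test_illegal_transition_rejected(self, hmm):
        seq = [("<e>", "A", 2), ("<e>", "A", 1)]
        path = StatePath(np.array([hmm.state_index(s) for s in seq]), 0.0, hmm)
        with pytest.raises(InvalidPathError):
            path_to_annotation(path)
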