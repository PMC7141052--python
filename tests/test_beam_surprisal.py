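"""Beam search, prefix probabilities, and surprisal arithmetic."""

import math

import numpy as np
import pytest

from gazeparse.beam_surprisal import (
    advance,
    beam_parse,
    prefix_probability,
    surprisal_from_alphas,
    surprisal_series,
)
from gazeparse.transition_model import transition_probs
from gazeparse.transition_system import apply, initial_state, legal_transitions


def enumerate_prefix_probs(sentence, model):
    """Independent breadth-first enumeration of *all* partial parses.

    Recomputes the per-word prefix probabilities without any of the beam
    machinery: plain frontier expansion with explicit probability products,
    no pruning, no log-space bookkeeping.
    """
    n = len(sentence)
    frontier = [(initial_state(n), 1.0)]
    alphas = []
    for target in range(2, n + 2):
        arrived = []
        work = list(frontier)
        while work:
            state, prob = work.pop()
            legal = legal_transitions(state, n)
            if not legal:
                continue  # dead state: its mass is simply lost
            masked, _ = transition_probs(model, state, sentence)
            for t, p in masked.items():
                if p == 0.0:
                    continue
                child = apply(state, t, n)
                entry = (child, prob * p)
                if child.buffer_pos == target:
                    arrived.append(entry)
                else:
                    work.append(entry)
        alphas.append(sum(p for _, p in arrived))
        frontier = arrived
    return alphas


class TestSurprisalArithmetic:
    def test_published_worked_example_reproduced(self):
        """A five-word copular sentence's printed per-word prefix
        probabilities must yield its printed surprisal column (natural
        log), within the rounding of the printed probabilities."""
        alphas = [1, 0.99997, 0.9985, 0.3134, 0.2713]
        expected = [0.00000, 0.00003, 0.00148, 1.15865, 0.14419]
        got = surprisal_from_alphas(alphas)
        assert np.allclose(got, expected, atol=2e-4)

    def test_natural_log_not_other_bases(self):
        got = surprisal_from_alphas([1, 0.9985, 0.3134])[-1]
        assert abs(got - 1.15865) < 2e-4          # ln
        assert abs(got - 1.6717) > 0.1            # log2 would give this
        assert abs(got - 0.50325) > 0.1           # log10 would give this

    def test_zero_alpha_gives_infinity(self):
        got = surprisal_from_alphas([1.0, 0.5, 0.0])
        assert got[-1] == math.inf

    def test_increasing_alpha_rejected(self):
        with pytest.raises(ValueError):
            surprisal_from_alphas([0.5, 0.9])


class TestPrefixProbability:
    def test_empty_set_is_zero(self):
        assert prefix_probability([]) == 0.0

    def test_sums_state_probabilities(self):
        n = 3
        s1 = apply(initial_state(n), list(legal_transitions(initial_state(n), n))[0], n)
        from dataclasses import replace

        states = [replace(s1, logprob=math.log(p)) for p in (0.5, 0.3, 0.1)]
        assert prefix_probability(states) == pytest.approx(0.9)


class TestBeam:
    def test_first_word_surprisal_is_zero_with_wide_beam(
        self, toy_treebank, trained_model
    ):
        """Only SHIFT and RIGHTARC are reachable at word 1, and their
        renormalized probabilities sum to one, so nothing is lost."""
        for sent in toy_treebank[:5]:
            prof = surprisal_series(sent, trained_model, k=50)
            assert prof.surprisal[0] <= 1e-12

    def test_k1_is_greedy_one_state_per_word(self, toy_treebank, trained_model):
        parse = beam_parse(toy_treebank[0], trained_model, k=1)
        assert all(len(states) == 1 for states in parse.states_per_word)

    def test_k1_surprisal_matches_best_chain_probability(
        self, toy_treebank, trained_model
    ):
        """At k=1 the surprisal of word i is minus the log-probability of
        the most probable transition chain consuming it, found here by
        brute-force enumeration of all chains from the retained state."""
        sent = toy_treebank[2]
        n = len(sent)
        state = initial_state(n)
        expected = []
        for target in range(2, n + 2):
            # enumerate every chain from `state` to the next word position
            best = None
            work = [(state, 1.0)]
            while work:
                cur, prob = work.pop()
                masked, _ = transition_probs(trained_model, cur, sent)
                for t, p in masked.items():
                    if p == 0.0:
                        continue
                    child = apply(cur, t, n)
                    if child.buffer_pos == target:
                        if best is None or prob * p > best[1]:
                            best = (child, prob * p)
                    else:
                        work.append((child, prob * p))
            state, chain_prob = best
            expected.append(-math.log(chain_prob))
        prof = surprisal_series(sent, trained_model, k=1)
        assert np.allclose(prof.surprisal, expected, atol=1e-9)

    def test_beam_equals_exhaustive_enumeration_without_pruning(
        self, toy_treebank, trained_model
    ):
        """k=∞ beam prefix probabilities match a brute-force breadth-first
        enumeration of every partial parse, to double precision."""
        five_worders = [s for s in toy_treebank if len(s) == 5][:5]
        assert five_worders
        for sent in five_worders:
            expected = enumerate_prefix_probs(sent, trained_model)
            prof = surprisal_series(sent, trained_model, k=None)
            assert np.allclose(prof.alphas, expected, rtol=0, atol=1e-12)

    def test_alpha_monotonically_non_increasing(self, toy_treebank, trained_model):
        # unpruned runs enumerate every partial parse, which grows
        # exponentially with length: keep k=None to short sentences
        short = [s for s in toy_treebank if len(s) <= 6][:6]
        for sent in short:
            for k in (1, 3, None):
                prof = surprisal_series(sent, trained_model, k)
                alphas = (1.0,) + prof.alphas
                assert all(
                    b <= a + 1e-12 for a, b in zip(alphas, alphas[1:])
                )

    def test_k_monotonicity_of_prefix_probabilities(
        self, toy_treebank, trained_model
    ):
        """A wider beam can only retain more mass at every word."""
        for sent in [s for s in toy_treebank if len(s) <= 6][:5]:
            profiles = [
                surprisal_series(sent, trained_model, k).alphas
                for k in (1, 2, 3, 5, 10, None)
            ]
            for narrow, wide in zip(profiles, profiles[1:]):
                assert all(a <= b + 1e-12 for a, b in zip(narrow, wide))

    def test_surprisal_telescopes_to_total_logprob(
        self, toy_treebank, trained_model
    ):
        """Σ_i s_i = −ln α_n in every configuration."""
        for sent in toy_treebank[:10]:
            ks = (1, 2, 10, None) if len(sent) <= 6 else (1, 2, 10)
            for k in ks:
                prof = surprisal_series(sent, trained_model, k)
                assert sum(prof.surprisal) == pytest.approx(
                    -math.log(prof.alphas[-1]), abs=1e-9
                )

    def test_no_pruning_means_zero_surprisal_everywhere(
        self, toy_treebank, trained_model
    ):
        """SHIFT is always legal while the buffer is nonempty, so no state
        dies before the end of the sentence; with k=∞ the renormalized
        distributions conserve all mass and surprisal vanishes."""
        for sent in [s for s in toy_treebank if len(s) <= 6][:6]:
            prof = surprisal_series(sent, trained_model, k=None)
            assert all(s <= 1e-9 for s in prof.surprisal)
            assert all(d <= 1e-12 for d in prof.dropped_mass)

    def test_state_logprob_is_sum_of_transition_logs(
        self, toy_treebank, trained_model
    ):
        """State probability = product of its transition probabilities."""
        sent = toy_treebank[1]
        n = len(sent)
        parse = beam_parse(sent, trained_model, k=5)
        for state in parse.states_per_word[-1]:
            acc = 0.0
            cur = initial_state(n)
            for t in state.history:
                masked, _ = transition_probs(trained_model, cur, sent)
                acc += math.log(masked[t])
                cur = apply(cur, t, n)
            assert state.logprob == pytest.approx(acc, abs=1e-9)

    def test_beam_boundary_tie_break_is_deterministic(
        self, toy_treebank, trained_model
    ):
        sent = toy_treebank[0]
        a = beam_parse(sent, trained_model, k=3)
        b = beam_parse(sent, trained_model, k=3)
        for sa, sb in zip(a.states_per_word, b.states_per_word):
            assert [s.history_key for s in sa] == [s.history_key for s in sb]

    def test_advance_requires_consistent_positions(self, toy_treebank, trained_model):
        sent = toy_treebank[0]
        n = len(sent)
        s0 = initial_state(n)
        s1 = apply(s0, list(legal_transitions(s0, n))[0], n)
        with pytest.raises(ValueError, match="mixed"):
            advance([s0, s1], trained_model, sent, 5)
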