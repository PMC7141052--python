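"""DLT storage/integration costs and ACT-R retrieval cost."""

import math

import numpy as np
import pytest

from gazeparse.beam_surprisal import beam_parse
from gazeparse.corpus_io import Sentence, Token
from gazeparse.memory_metrics import (
    RetrievalParams,
    association_strength,
    base_activation,
    integration_cost,
    predictor_table,
    retrieval_cost_per_word,
    retrieval_costs_beam,
    storage_cost,
)
from gazeparse.transition_system import Transition, oracle

S, L, R, D = (Transition.SHIFT, Transition.LEFTARC, Transition.RIGHTARC,
              Transition.REDUCE)


def tok(i, form, cpos, pos, head, **feats):
    return Token(index=i, form=form, lemma=form, cpos=cpos, pos=pos,
                 feats=feats, head=head)


@pytest.fixture
def preverbal_argument_sentence():
    """Head-final clause with three case-marked preverbal arguments, a
    negation, a verb and an auxiliary — the classic storage-cost
    configuration where a verb is predicted from the first argument on."""
    return Sentence(id="ex4", tokens=(
        tok(1, "deepika", "N", "NNP", 9),
        tok(2, "ko", "P", "PSP", 1, case="acc"),
        tok(3, "shaam", "N", "NN", 9),
        tok(4, "se", "P", "PSP", 3, case="ins"),
        tok(5, "abhay", "N", "NNP", 9),
        tok(6, "ne", "P", "PSP", 5, case="erg"),
        tok(7, "fona", "N", "NN", 9),
        tok(8, "nahi", "R", "NEG", 9),
        tok(9, "kiyaa", "V", "VM", 0, tam="past"),
        tok(10, "hai", "V", "VAUX", 9, tam="prs"),
    ))


class TestStorageCost:
    def test_worked_example(self, preverbal_argument_sentence):
        """One verb is predicted at the first case-marked argument; the
        prediction persists across further arguments and discharges at the
        verb."""
        sc = storage_cost(preverbal_argument_sentence)
        assert sc[1] == 1            # at "deepika ko"
        assert sc[:2] == [1, 1]
        # constant across the preverbal arguments
        assert sc[2:8] == [1] * 6
        assert sc[8] == 0            # at the verb
        assert sc[9] == 0

    def test_single_word_sentence(self):
        assert storage_cost(Sentence(id="s", tokens=(tok(1, "x", "V", "VM", 0),))) == [0]

    def test_zero_at_final_word_of_head_final_sentences(self, toy_treebank):
        for sent in toy_treebank:
            assert storage_cost(sent)[-1] == 0

    def test_counts_distinct_future_heads(self):
        # two nouns awaiting two different future heads (noun 2 and verb 4)
        sent = Sentence(id="s", tokens=(
            tok(1, "a", "N", "NN", 2),
            tok(2, "b", "N", "NN", 4),
            tok(3, "c", "N", "NN", 4),
            tok(4, "v", "V", "VM", 0),
        ))
        assert storage_cost(sent) == [1, 1, 1, 0]


class TestIntegrationCost:
    def test_adjacent_dependency_costs_nothing(self):
        sent = Sentence(id="s", tokens=(
            tok(1, "a", "N", "NN", 2), tok(2, "v", "V", "VM", 0)))
        assert integration_cost(sent) == [0, 0]

    def test_referents_between_arc_members_are_counted(self):
        # dependent at 1, head at 4; a noun at 2 and a postposition at 3
        sent = Sentence(id="s", tokens=(
            tok(1, "a", "N", "NN", 4),
            tok(2, "b", "N", "NN", 4),
            tok(3, "p", "P", "PSP", 2),
            tok(4, "v", "V", "VM", 0),
        ))
        ic = integration_cost(sent)
        # at the verb: arc 1->4 crosses the noun at 2 (1 referent), the
        # postposition does not count; arc 2->4 crosses nothing relevant
        assert ic[3] >= 1
        assert ic == [0, 0, 0, 1]

    def test_words_completing_no_dependency_cost_zero(self, toy_treebank):
        for sent in toy_treebank[:10]:
            ic = integration_cost(sent)
            completions = {max(t.head, t.index) for t in sent if t.head != 0}
            for i in range(1, len(sent) + 1):
                if i not in completions:
                    assert ic[i - 1] == 0


class TestActivation:
    def test_unit_lag_gives_zero_base_activation(self):
        assert base_activation([0.0], now=1.0, d=0.5) == pytest.approx(0.0)

    def test_two_event_base_activation(self):
        # events 1 s and 4 s ago: ln(1^-0.5 + 4^-0.5) = ln(1.5)
        got = base_activation([3.0, 0.0], now=4.0, d=0.5)
        assert got == pytest.approx(math.log(1.5), abs=1e-12)

    def test_decay_is_monotone_without_new_retrievals(self):
        acts = [base_activation([0.0], now=t, d=0.5) for t in (1.0, 2.0, 5.0, 10.0)]
        assert all(b < a for a, b in zip(acts, acts[1:]))

    def test_never_encoded_chunk_errors(self):
        with pytest.raises(ValueError):
            base_activation([], now=1.0, d=0.5)

    def test_fan_one_gives_ceiling_strength(self):
        s, fan = association_strength("NN", ["NN", "VM"], s_max=1.5)
        assert fan == 1 and s == pytest.approx(1.5)

    def test_fan_four(self):
        s, fan = association_strength("NN", ["NN"] * 4, s_max=1.5)
        assert fan == 4
        assert s == pytest.approx(1.5 - math.log(4), abs=1e-12)
        assert s == pytest.approx(0.1137, abs=1e-4)

    def test_doubling_fan_costs_ln2(self):
        s2, _ = association_strength("NN", ["NN"] * 2)
        s4, _ = association_strength("NN", ["NN"] * 4)
        assert s2 - s4 == pytest.approx(math.log(2), abs=1e-12)

    def test_unmatched_cue_contributes_zero(self):
        assert association_strength("JJ", ["NN", "VM"]) == (0.0, 0)


class TestRetrievalSimulation:
    def test_shift_only_word_costs_production_plus_reading(self):
        sent = Sentence(id="s", tokens=(
            tok(1, "a", "N", "NN", 2), tok(2, "v", "V", "VM", 0)))
        total, ret = retrieval_cost_per_word((S,), sent)
        assert total[0] == pytest.approx(51.0)
        assert ret[0] == 0.0

    def test_arc_word_costs_two_productions_reading_and_latency(self):
        sent = Sentence(id="s", tokens=(
            tok(1, "a", "N", "NN", 2), tok(2, "v", "V", "VM", 0)))
        total, ret = retrieval_cost_per_word((S, L), sent)
        # word 2's LEFTARC: two productions + retrieval of the noun chunk
        assert ret[1] > 0
        assert total[1] == pytest.approx(100.0 + ret[1])  # reading not yet paid
        params = RetrievalParams()
        # closed form: the noun was encoded once, fan 1 among {root, noun}
        lag = (2 * params.production_ms + params.reading_ms) / 1000.0
        b = math.log(lag ** -params.d)
        expected = 1000.0 * params.f * math.exp(-(b + params.w * 1.5))
        assert ret[1] == pytest.approx(expected, abs=1e-9)

    def test_latency_decreases_with_activation_over_grid(self):
        params = RetrievalParams()
        lat = [1000.0 * params.f * math.exp(-a) for a in np.linspace(-1, 3, 20)]
        assert all(b < a for a, b in zip(lat, lat[1:]))

    def test_oracle_log_accrues_monotone_clock(self, toy_treebank):
        for sent in toy_treebank[:5]:
            total, ret = retrieval_cost_per_word(oracle(sent), sent)
            assert all(t >= 0 for t in total)
            assert all(r >= 0 for r in ret)
            # every word costs at least one production + reading
            assert all(t >= 51.0 - 1e-9 for t in total)

    def test_beam_aggregation_is_probability_weighted(
        self, toy_treebank, trained_model
    ):
        sent = toy_treebank[0]
        parse = beam_parse(sent, trained_model, k=3)
        total, ret = retrieval_costs_beam(parse)
        assert len(total) == len(sent)
        assert all(np.isfinite(total))
        # weighted mean lies within the per-state range at each word
        for i, states in enumerate(parse.states_per_word, start=1):
            per_state = [
                retrieval_cost_per_word(s.history, sent)[0][i - 1]
                for s in states
            ]
            assert min(per_state) - 1e-9 <= total[i - 1] <= max(per_state) + 1e-9

    def test_integration_and_retrieval_costs_correlate_positively(
        self, toy_treebank, trained_model
    ):
        """Both formalize retrieval at the integration site, so they should
        agree in sign on head-final synthetic treebanks."""
        table = predictor_table(toy_treebank[:30], trained_model, k=3)
        r = np.corrcoef(table["integration_cost"], table["retrieval_latency_ms"])[0, 1]
        assert r > 0


class TestPredictorTable:
    def test_shape_and_ranges(self, toy_treebank, trained_model):
        table = predictor_table(toy_treebank[:5], trained_model, k=3)
        assert len(table) == sum(len(s) for s in toy_treebank[:5])
        assert (table["storage_cost"] >= 0).all()
        assert (table["integration_cost"] >= 0).all()
        assert (table["retrieval_cost_ms"] >= 0).all()
        assert (table["surprisal"].dropna() >= 0).all()
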