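"""Word-synchronous top-k beam search, prefix probabilities, and surprisal.

For each word position i the parser maintains the set of partial parses
(states) that have consumed exactly words 1..i.  Advancing from i to i+1
applies every legal transition to every state, closing over the
non-consuming transitions (LEFTARC, REDUCE) until all surviving states have
consumed word i+1, then keeps only the k most probable states.  Because
LEFTARC and REDUCE strictly shrink the stack, these closure chains always
terminate without an explicit cap.

The prefix probability α_i is the summed probability of the retained states
at word i; surprisal is the natural-log ratio of successive prefix
probabilities, s_i = ln(α_{i-1}/α_i) with α_0 = 1.  Since transition
distributions are renormalized over the legal transitions, probability mass
is lost only to beam pruning (and, at the end of the sentence, to states
that cannot be completed), and Σ s_i = −ln α_n exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from dataclasses import replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .corpus_io import Sentence
from .transition_model import TransitionModel, transition_probs
from .transition_system import ParserState, Transition, apply, initial_state

__all__ = [
    "SurprisalProfile",
    "BeamParse",
    "advance",
    "prefix_probability",
    "surprisal_from_alphas",
    "surprisal_series",
    "beam_parse",
]

DEFAULT_K = 10
K_SWEEP = (1, 2, 3, 4, 5, 10, 15, 20, 25)


@dataclass(frozen=True)
class SurprisalProfile:
    """Per-word prefix probabilities and surprisal for one sentence.

    ``alphas[i-1]`` is α_i for word i (α_0 = 1 is implicit); surprisal is in
    nats.  ``dropped_mass[i-1]`` is the probability mass removed at word i by
    pruning and dead states.  When every state dies at some word, surprisal
    from that word on is ``inf`` and ``failed`` is set; downstream analyses
    exclude such sentences.
    """

    sentence_id: str
    alphas: tuple[float, ...]
    surprisal: tuple[float, ...]
    k: Optional[int]
    dropped_mass: tuple[float, ...]
    failed: bool = False

    def __len__(self) -> int:
        return len(self.alphas)


@dataclass
class BeamParse:
    """Full beam-search record: states per word plus the surprisal profile.

    ``states_per_word[i-1]`` holds the retained states after consuming word
    i, sorted most probable first.  ``final_states`` are the states after the
    end-of-sentence REDUCE closure (no word index is assigned to it, so it
    contributes no surprisal), flagged complete when every word is headed and
    the stack is reduced to the root.
    """

    sentence: Sentence
    profile: SurprisalProfile
    states_per_word: list[list[ParserState]] = field(default_factory=list)
    final_states: list[ParserState] = field(default_factory=list)

    def best_parse(self) -> Optional[ParserState]:
        """Most probable complete final state, if any."""
        n = len(self.sentence)
        complete = [s for s in self.final_states if s.is_complete(n)]
        if not complete:
            return None
        return max(complete, key=lambda s: s.logprob)


def _sort_key(state: ParserState):
    # descending probability, then lexicographic history for deterministic
    # tie-breaks at the beam boundary
    return (-state.logprob, state.history_key)


def advance(
    states: Sequence[ParserState],
    model: TransitionModel,
    sentence: Sentence,
    k: Optional[int],
) -> tuple[list[ParserState], float]:
    """One word-synchronous beam step.

    Takes the states that have consumed word i (all sharing a buffer
    position) and returns ``(survivors, dropped_mass)`` where the survivors
    have consumed word i+1, are sorted by probability with deterministic
    tie-breaking, and are truncated to the ``k`` most probable
    (``k=None`` disables pruning).  Dead states en route are dropped and
    their mass accounted to ``dropped_mass``, as is the mass of pruned
    states.
    """
    if not states:
        raise ValueError("advance called with no live states")
    positions = {s.buffer_pos for s in states}
    if len(positions) != 1:
        raise ValueError(f"states at mixed buffer positions: {sorted(positions)}")
    n = len(sentence)
    target = positions.pop() + 1

    arrived: list[ParserState] = []
    dead_logmass: list[float] = []
    frontier = list(states)
    while frontier:
        nxt: list[ParserState] = []
        for state in frontier:
            try:
                masked, _ = transition_probs(model, state, sentence)
            except Exception as exc:
                from .transition_model import DeadStateError

                if isinstance(exc, DeadStateError):
                    dead_logmass.append(state.logprob)
                    continue
                raise
            for t, p in sorted(masked.items(), key=lambda kv: kv[0].value):
                if p <= 0.0:
                    continue  # zero-probability branch carries no mass
                child = apply(state, t, n)
                child = replace(child, logprob=state.logprob + math.log(p))
                if child.buffer_pos == target:
                    arrived.append(child)
                else:
                    nxt.append(child)
        frontier = nxt

    arrived.sort(key=_sort_key)
    dropped = 0.0
    if dead_logmass:
        dropped += float(np.exp(logsumexp(dead_logmass)))
    if k is not None and len(arrived) > k:
        pruned = arrived[k:]
        arrived = arrived[:k]
        dropped += float(
            np.exp(logsumexp([s.logprob for s in pruned]))
        )
    return arrived, dropped


def prefix_probability(states: Sequence[ParserState]) -> float:
    """α = summed probability of the states at a common word index."""
    if not states:
        return 0.0
    if len({s.buffer_pos for s in states}) != 1:
        raise ValueError("prefix probability over states at mixed word indices")
    return float(np.exp(logsumexp([s.logprob for s in states])))


def surprisal_from_alphas(alphas: Sequence[float]) -> list[float]:
    """Surprisal series from a prefix-probability series, s_i = ln(α_{i-1}/α_i).

    ``alphas`` excludes α_0 = 1.  α_i = 0 yields ``inf`` for that word and
    every later word until (if ever) α becomes 0/0, which stays ``inf``.
    """
    out: list[float] = []
    prev = 1.0
    for a in alphas:
        if a < 0 or a > prev + 1e-12:
            raise ValueError(f"prefix probabilities must be non-increasing in [0,1]: {a} after {prev}")
        out.append(math.inf if a == 0.0 else math.log(prev / a))
        prev = a
    return out


def beam_parse(
    sentence: Sentence, model: TransitionModel, k: Optional[int] = DEFAULT_K
) -> BeamParse:
    """Run the word-synchronous beam over a whole sentence.

    After the last word the REDUCE closure is run to termination to flag
    complete parses, but it is assigned no word index: the profile has
    exactly n surprisal values.
    """
    n = len(sentence)
    states: list[ParserState] = [initial_state(n)]
    alphas: list[float] = []
    log_alphas: list[float] = []
    dropped: list[float] = []
    prev_log_alpha = 0.0
    failed = False
    per_word: list[list[ParserState]] = []

    for i in range(1, n + 1):
        if states:
            states, d = advance(states, model, sentence, k)
        else:
            d = 0.0
        per_word.append(states)
        dropped.append(d)
        if states:
            log_alpha = float(logsumexp([s.logprob for s in states]))
        else:
            log_alpha = -math.inf
            failed = True
        alphas.append(float(np.exp(log_alpha)))
        log_alphas.append(log_alpha)

    surprisal = []
    prev = 0.0
    for la in log_alphas:
        # clamp float round-off: alpha can exceed its predecessor by ~1e-16
        s = math.inf if la == -math.inf else max(prev - la, 0.0)
        surprisal.append(s)
        prev = la

    # end-of-sentence closure: REDUCE chains only (buffer exhausted)
    final: list[ParserState] = []
    frontier = list(states)
    while frontier:
        nxt = []
        for state in frontier:
            from .transition_system import legal_transitions

            legal = legal_transitions(state, n)
            if not legal:
                final.append(state)
                continue
            try:
                masked, _ = transition_probs(model, state, sentence)
            except Exception:
                final.append(state)
                continue
            for t, p in masked.items():
                if p <= 0.0:
                    continue
                child = apply(state, t, n)
                child = replace(child, logprob=state.logprob + math.log(p))
                nxt.append(child)
        frontier = nxt
    final.sort(key=_sort_key)

    profile = SurprisalProfile(
        sentence_id=sentence.id,
        alphas=tuple(alphas),
        surprisal=tuple(surprisal),
        k=k,
        dropped_mass=tuple(dropped),
        failed=failed,
    )
    return BeamParse(
        sentence=sentence,
        profile=profile,
        states_per_word=per_word,
        final_states=final,
    )


def surprisal_series(
    sentence: Sentence, model: TransitionModel, k: Optional[int] = DEFAULT_K
) -> SurprisalProfile:
    """Per-word surprisal for one sentence (see :func:`beam_parse`)."""
    return beam_parse(sentence, model, k).profile
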