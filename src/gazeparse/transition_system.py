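"""Arc-eager transition system for unlabeled dependency parsing.

The machine has four transitions — SHIFT, LEFTARC, RIGHTARC, REDUCE — over a
state of (stack, buffer position, arc set).  The virtual root, index 0, sits
at the bottom of the stack from initialization, so exactly two transitions
(SHIFT, RIGHTARC) are legal at the first word of every sentence.  A state
with no legal transition is a *dead* state; beam search drops it.

States are immutable: :func:`apply` returns a new state, so one state can be
extended along several beam branches safely.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional

from .corpus_io import Sentence

__all__ = [
    "Transition",
    "ParserState",
    "IllegalTransition",
    "NonProjectiveError",
    "initial_state",
    "legal_transitions",
    "apply",
    "oracle",
    "replay",
]


class Transition(enum.Enum):
    SHIFT = "S"
    LEFTARC = "L"
    RIGHTARC = "R"
    REDUCE = "D"

    def consumes(self) -> bool:
        """Whether this transition advances the buffer position."""
        return self in (Transition.SHIFT, Transition.RIGHTARC)


class IllegalTransition(ValueError):
    """A transition was applied whose precondition does not hold."""


class NonProjectiveError(ValueError):
    """The oracle was asked for a sentence it cannot derive."""


@dataclass(frozen=True)
class ParserState:
    """One partial parse: stack, buffer position, arcs, log-probability.

    ``buffer_pos`` is the 1-based index of the next unconsumed word
    (n+1 when the buffer is exhausted).  ``arcs`` are (head, dependent)
    pairs; ``head_of`` caches the dependent->head map for O(1) legality
    checks.  ``history`` is the full transition sequence from the initial
    state, and ``logprob`` the running sum of log transition probabilities.
    """

    stack: tuple[int, ...]
    buffer_pos: int
    arcs: frozenset[tuple[int, int]]
    head_of: dict[int, int] = field(default_factory=dict, compare=False)
    logprob: float = 0.0
    history: tuple[Transition, ...] = ()

    @property
    def history_key(self) -> str:
        """Deterministic tie-break key: the history as a letter string."""
        return "".join(t.value for t in self.history)

    def is_complete(self, n: int) -> bool:
        """Every word headed and the stack reduced back to the root."""
        return (
            self.buffer_pos == n + 1
            and len(self.arcs) == n
            and self.stack == (0,)
        )


def initial_state(n: int) -> ParserState:
    """Root on the stack, buffer at word 1, empty arc set."""
    if n < 1:
        raise ValueError("sentence length must be >= 1")
    return ParserState(stack=(0,), buffer_pos=1, arcs=frozenset())


def legal_transitions(state: ParserState, n: int) -> set[Transition]:
    """Exactly the transitions whose preconditions hold in ``state``.

    SHIFT and RIGHTARC need a nonempty buffer; LEFTARC additionally needs a
    non-root, still-headless stack top; REDUCE needs a stack top that already
    has a head.  The returned set may be empty (a dead state).
    """
    legal: set[Transition] = set()
    buffer_nonempty = state.buffer_pos <= n
    top: Optional[int] = state.stack[-1] if state.stack else None
    if buffer_nonempty:
        legal.add(Transition.SHIFT)
        if top is not None:
            legal.add(Transition.RIGHTARC)
        if top is not None and top != 0 and top not in state.head_of:
            legal.add(Transition.LEFTARC)
    if top is not None and top != 0 and top in state.head_of:
        legal.add(Transition.REDUCE)
    return legal


def apply(state: ParserState, t: Transition, n: int) -> ParserState:
    """Pure transition application; raises :class:`IllegalTransition`."""
    legal = legal_transitions(state, n)
    if t not in legal:
        raise IllegalTransition(
            f"{t.name} illegal in state (stack={state.stack}, "
            f"buffer_pos={state.buffer_pos}, n={n}); legal: "
            f"{sorted(x.name for x in legal)}"
        )
    b = state.buffer_pos
    history = state.history + (t,)
    if t is Transition.SHIFT:
        return replace(
            state, stack=state.stack + (b,), buffer_pos=b + 1, history=history
        )
    if t is Transition.RIGHTARC:
        head = state.stack[-1]
        return replace(
            state,
            stack=state.stack + (b,),
            buffer_pos=b + 1,
            arcs=state.arcs | {(head, b)},
            head_of={**state.head_of, b: head},
            history=history,
        )
    if t is Transition.LEFTARC:
        dep = state.stack[-1]
        return replace(
            state,
            stack=state.stack[:-1],
            arcs=state.arcs | {(b, dep)},
            head_of={**state.head_of, dep: b},
            history=history,
        )
    # REDUCE
    return replace(state, stack=state.stack[:-1], history=history)


def oracle(sentence: Sentence) -> tuple[Transition, ...]:
    """Gold transition sequence for a projective sentence.

    The standard arc-eager oracle: attach eagerly when the gold arc joins the
    stack top and the buffer front, REDUCE when the stack top is finished and
    buried material still needs the buffer front, otherwise SHIFT.  Replaying
    the sequence reproduces the gold arc set exactly and ends with the stack
    reduced to the root.

    Raises :class:`NonProjectiveError` for non-projective sentences (callers
    decide whether to skip them).
    """
    if not sentence.projective:
        raise NonProjectiveError(
            f"sentence {sentence.id!r} is non-projective; no arc-eager derivation"
        )
    heads = (None,) + sentence.heads()  # heads[i] = gold head of word i
    n = len(sentence)
    deps_of: dict[int, list[int]] = {}
    for d in range(1, n + 1):
        deps_of.setdefault(heads[d], []).append(d)

    state = initial_state(n)
    seq: list[Transition] = []

    def emit(t: Transition) -> None:
        nonlocal state
        seq.append(t)
        state = apply(state, t, n)

    while state.buffer_pos <= n:
        b = state.buffer_pos
        top = state.stack[-1]
        if top != 0 and heads[top] == b and top not in state.head_of:
            emit(Transition.LEFTARC)
        elif heads[b] == top:
            emit(Transition.RIGHTARC)
        elif top in state.head_of and _needs_reduce(state, b, heads, deps_of):
            emit(Transition.REDUCE)
        else:
            emit(Transition.SHIFT)
    while state.stack[-1] != 0:
        emit(Transition.REDUCE)
    if state.arcs != sentence.arcs():  # pragma: no cover - guarded by projectivity
        raise NonProjectiveError(
            f"oracle failed to derive gold tree for sentence {sentence.id!r}"
        )
    return tuple(seq)


def _needs_reduce(state, b, heads, deps_of) -> bool:
    """True if material below the stack top still links to the buffer front."""
    top = state.stack[-1]
    if heads[b] < top:
        return True
    return any(d < top and d not in state.head_of for d in deps_of.get(b, ()))


def replay(
    sentence_length: int, transitions: tuple[Transition, ...]
) -> ParserState:
    """Apply a transition sequence from the initial state; raises if illegal."""
    state = initial_state(sentence_length)
    for t in transitions:
        state = apply(state, t, sentence_length)
    return state


def format_transition_log(history: tuple[Transition, ...]) -> str:
    """One transition name per line — the text form the retrieval-cost
    module's inputs can be stored in."""
    return "\n".join(t.name for t in history)


def parse_transition_log(text: str) -> tuple[Transition, ...]:
    """Inverse of :func:`format_transition_log`; blank lines are ignored."""
    return tuple(
        Transition[line.strip()] for line in text.splitlines() if line.strip()
    )
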