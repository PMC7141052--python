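"""Working-memory and prediction cost metrics.

Three families of sentence-level predictors:

* **Storage cost** (dependency locality theory): at word i, the number of
  distinct upcoming heads predicted by the words read so far — formally, the
  count of positions h > i that are the gold head of at least one word at a
  position ≤ i.  This is an algorithmic proxy for what is traditionally
  annotated by hand; it is 1 across the preverbal arguments of a head-final
  clause and drops to 0 at the verb.
* **Integration cost** (DLT): at the word completing a dependency, the
  number of discourse-referent words (by default nouns and verbs, selected
  by coarse POS) strictly between the two arc members, summed over all
  dependencies whose rightmost member is that word.  Arcs from the virtual
  root carry no integration cost.
* **Cue-based retrieval cost** (ACT-R): each dependency arc formed by the
  parser retrieves the stack-resident arc member from memory.  A chunk's
  activation is A = B + Σ_j W_j·S_ji, with base activation
  B = ln(Σ_j (now − t_j)^{−d}) over its creation/retrieval timestamps and
  associative strength S = S_max − ln(fan) for the single part-of-speech
  cue, where fan counts the chunks sharing that POS.  Retrieval latency is
  F·exp(−A).  Productions cost 50 ms (two per arc, one per SHIFT, one per
  REDUCE) and reading a word 1 ms.  Per-word costs across a beam are the
  probability-weighted mean over the surviving states at that word.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .beam_surprisal import BeamParse, beam_parse
from .corpus_io import Sentence
from .transition_model import TransitionModel
from .transition_system import Transition

__all__ = [
    "RetrievalParams",
    "storage_cost",
    "integration_cost",
    "base_activation",
    "association_strength",
    "retrieval_cost_per_word",
    "retrieval_costs_beam",
    "predictor_table",
    "DEFAULT_REFERENT_CLASSES",
]

#: coarse POS categories treated as introducing discourse referents
DEFAULT_REFERENT_CLASSES = frozenset({"N", "V"})

ROOT_CUE = "<root>"


@dataclass(frozen=True)
class RetrievalParams:
    """ACT-R retrieval parameters.

    ``s_max`` — associative strength ceiling (1.5).
    ``d`` — base-level decay exponent (canonical 0.5; config-overridable).
    ``f`` — latency scaling factor in seconds (assumption: 1.0).
    ``production_ms`` — fixed cost per production firing (50 ms).
    ``reading_ms`` — cost of reading a word (1 ms).
    ``w`` — weight of the single POS retrieval cue (1.0).
    """

    s_max: float = 1.5
    d: float = 0.5
    f: float = 1.0
    production_ms: float = 50.0
    reading_ms: float = 1.0
    w: float = 1.0

    def __post_init__(self) -> None:
        if self.s_max <= 0 or self.d <= 0 or self.f <= 0:
            raise ValueError("s_max, d and f must all be positive")


# ---------------------------------------------------------------------------
# DLT costs (gold-tree based)


def storage_cost(sentence: Sentence) -> list[int]:
    """Per-word count of distinct predicted upcoming heads.

    SC(i) = |{h > i : some word at position ≤ i has gold head h}|.  Constant
    across successive preverbal arguments sharing one verb, 0 once the verb
    arrives, always 0 at the last word of a head-final clause.
    """
    heads = sentence.heads()
    n = len(sentence)
    out = []
    for i in range(1, n + 1):
        future_heads = {heads[d - 1] for d in range(1, i + 1) if heads[d - 1] > i}
        out.append(len(future_heads))
    return out


def integration_cost(
    sentence: Sentence,
    referent_classes: frozenset[str] = DEFAULT_REFERENT_CLASSES,
) -> list[int]:
    """Per-word DLT integration cost from the gold tree.

    Each dependency contributes, at its rightmost member, the number of
    discourse-referent words (coarse POS in ``referent_classes``) strictly
    between head and dependent.  Words completing no dependency score 0.
    """
    n = len(sentence)
    out = [0] * n
    for tok in sentence:
        h = tok.head
        if h == 0:
            continue
        lo, hi = min(h, tok.index), max(h, tok.index)
        between = sum(
            1 for j in range(lo + 1, hi)
            if sentence[j - 1].cpos in referent_classes
        )
        out[hi - 1] += between
    return out


# ---------------------------------------------------------------------------
# ACT-R activation


def base_activation(timestamps: Sequence[float], now: float, d: float) -> float:
    """B = ln( Σ_j (now − t_j)^(−d) ) over creation/retrieval times."""
    if not timestamps:
        raise ValueError("chunk was never encoded: no timestamps")
    lags = [now - t for t in timestamps]
    if any(lag <= 0 for lag in lags):
        raise ValueError(f"non-positive lag in {lags}; now={now}")
    return math.log(sum(lag ** (-d) for lag in lags))


def association_strength(
    cue_value: str, chunk_cues: Sequence[str], s_max: float = 1.5
) -> tuple[float, int]:
    """(S_ji, fan) for one cue: S = S_max − ln(fan).

    fan counts the memory chunks sharing the cue's value.  A cue matching no
    chunk has no defined association and contributes 0.
    """
    fan = sum(1 for c in chunk_cues if c == cue_value)
    if fan == 0:
        return 0.0, 0
    return s_max - math.log(fan), fan


# ---------------------------------------------------------------------------
# retrieval simulation over a transition log


@dataclass
class _Chunk:
    pos: str
    timestamps: list[float] = field(default_factory=list)


def retrieval_cost_per_word(
    history: Sequence[Transition],
    sentence: Sentence,
    params: RetrievalParams = RetrievalParams(),
) -> tuple[list[float], list[float]]:
    """Simulate one transition log on the ACT-R clock.

    Returns ``(total_ms, retrieval_ms)`` per word: the total cost accrued
    while the word was the buffer front (productions + retrieval latencies +
    reading cost) and its pure retrieval-latency component.  The clock
    starts at 0 for each sentence; timestamps are kept in seconds.  Each
    transition is attributed to the word at the buffer front when it was
    applied; anything after the last word is consumed (end-of-sentence
    REDUCE closure) is not attributed to any word.
    """
    n = len(sentence)
    total = [0.0] * n
    retrieval = [0.0] * n
    clock = 0.0  # seconds
    chunks: dict[int, _Chunk] = {0: _Chunk(pos=ROOT_CUE, timestamps=[0.0])}
    stack = [0]
    buffer_pos = 1

    def retrieve(idx: int) -> float:
        chunk = chunks[idx]
        if clock <= max(chunk.timestamps):
            raise ValueError("clock did not advance before retrieval")
        b = base_activation(chunk.timestamps, clock, params.d)
        cues = [c.pos for c in chunks.values()]
        s, fan = association_strength(chunk.pos, cues, params.s_max)
        a = b + params.w * s
        return 1000.0 * params.f * math.exp(-a)

    for t in history:
        word = buffer_pos if buffer_pos <= n else None
        cost = 0.0
        ret_ms = 0.0
        if t is Transition.SHIFT:
            cost += params.production_ms
            clock += params.production_ms / 1000.0
            chunks[buffer_pos] = _Chunk(
                pos=sentence[buffer_pos - 1].pos, timestamps=[clock]
            )
            stack.append(buffer_pos)
            buffer_pos += 1
            cost += params.reading_ms
            clock += params.reading_ms / 1000.0
        elif t is Transition.RIGHTARC:
            cost += 2 * params.production_ms
            clock += 2 * params.production_ms / 1000.0
            ret_ms = retrieve(stack[-1])
            cost += ret_ms
            clock += ret_ms / 1000.0
            chunks[stack[-1]].timestamps.append(clock)
            chunks[buffer_pos] = _Chunk(
                pos=sentence[buffer_pos - 1].pos, timestamps=[clock]
            )
            stack.append(buffer_pos)
            buffer_pos += 1
            cost += params.reading_ms
            clock += params.reading_ms / 1000.0
        elif t is Transition.LEFTARC:
            cost += 2 * params.production_ms
            clock += 2 * params.production_ms / 1000.0
            ret_ms = retrieve(stack[-1])
            cost += ret_ms
            clock += ret_ms / 1000.0
            chunks[stack[-1]].timestamps.append(clock)
            stack.pop()
        else:  # REDUCE: a production that forms no arc
            cost += params.production_ms
            clock += params.production_ms / 1000.0
            stack.pop()
        if word is not None:
            total[word - 1] += cost
            retrieval[word - 1] += ret_ms
    return total, retrieval


def retrieval_costs_beam(
    parse: BeamParse, params: RetrievalParams = RetrievalParams()
) -> tuple[list[float], list[float]]:
    """Probability-weighted mean per-word retrieval cost across the beam.

    For each word i, every state surviving in the beam at i contributes the
    cost it accrued at word i, weighted by its probability renormalized over
    the beam.  Words where the beam is empty get NaN.
    """
    n = len(parse.sentence)
    total = [math.nan] * n
    retrieval = [math.nan] * n
    for i, states in enumerate(parse.states_per_word, start=1):
        if not states:
            continue
        logps = np.array([s.logprob for s in states])
        weights = np.exp(logps - logps.max())
        weights /= weights.sum()
        t_acc = 0.0
        r_acc = 0.0
        for w, state in zip(weights, states):
            per_total, per_ret = retrieval_cost_per_word(
                state.history, parse.sentence, params
            )
            t_acc += w * per_total[i - 1]
            r_acc += w * per_ret[i - 1]
        total[i - 1] = t_acc
        retrieval[i - 1] = r_acc
    return total, retrieval


# ---------------------------------------------------------------------------
# predictor table


def predictor_table(
    sentences: Sequence[Sentence],
    model: TransitionModel,
    k: Optional[int] = 10,
    params: RetrievalParams = RetrievalParams(),
    referent_classes: frozenset[str] = DEFAULT_REFERENT_CLASSES,
) -> pd.DataFrame:
    """Per-(sentence, word) predictor table.

    Columns: ``sentence, word, form, storage_cost, integration_cost,
    retrieval_cost_ms, retrieval_latency_ms, surprisal, alpha``.  Sentences
    the beam cannot parse (all states dead) get NaN surprisal columns and a
    ``failed`` flag; downstream analysis excludes them.
    """
    rows = []
    for sent in sentences:
        parse = beam_parse(sent, model, k)
        sc = storage_cost(sent)
        ic = integration_cost(sent, referent_classes)
        total, ret = retrieval_costs_beam(parse, params)
        prof = parse.profile
        for i, tok in enumerate(sent, start=1):
            s = prof.surprisal[i - 1]
            rows.append(
                {
                    "sentence": sent.id,
                    "word": i,
                    "form": tok.form,
                    "storage_cost": sc[i - 1],
                    "integration_cost": ic[i - 1],
                    "retrieval_cost_ms": total[i - 1],
                    "retrieval_latency_ms": ret[i - 1],
                    "surprisal": math.nan if math.isinf(s) else s,
                    "alpha": prof.alphas[i - 1],
                    "failed": prof.failed,
                }
            )
    return pd.DataFrame(rows)
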