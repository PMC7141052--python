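"""Synthetic fixtures: a case-marked SOV toy treebank, simulated reading
times with known effect structure, and constructive fixation sequences.

The toy grammar is head-final with postposed case clitics, echoing the
dependency statistics of Hindi-like treebanks that make storage cost
non-trivial: preverbal argument NPs (optionally with genitive modifiers and
adjectives) predict an upcoming verb, case clitics attach to the preceding
nominal, and an optional auxiliary follows the verb.  All generated trees
are projective and single-rooted, morphology (case, tense-aspect-modality,
chunk id, gender) is populated so the rich feature templates are exercised,
and generation is deterministic given a seed.

Reading times are generated from exactly the model the analysis stage
assumes: per measure, log-duration is a linear function of the scaled
predictors plus crossed subject/item intercepts, per-predictor subject/item
slopes, and Gaussian noise, exponentiated to ms; a configurable fraction of
words is skipped (all three measures 0 ms).  Random effects and residuals
are shared across the three measures (a slow reader is slow on every
measure), which keeps every marginal measure exactly log-linear while
guaranteeing FPRT ≤ TFT and FPRT ≤ RPD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .corpus_io import FixationSequence, GazeRecord, Sentence, Token

__all__ = [
    "GrammarConfig",
    "RTConfig",
    "gen_treebank",
    "word_predictors",
    "gen_reading_times",
    "gen_fixations",
    "gen_random_fixations",
    "InfeasibleMeasures",
]


# ---------------------------------------------------------------------------
# toy grammar

_NOUNS = [
    "raam", "siitaa", "mohan", "kitaab", "ghar", "gaaRii", "laRkaa",
    "laRkii", "phal", "paanii", "shahar", "chiTThii", "darvaazaa", "baccaa",
]
_VERBS = ["gayaa", "aayaa", "paRhaa", "dekhaa", "kiyaa", "bolaa", "likhaa", "khaayaa"]
_AUX = ["hai", "thaa", "thii"]
_CLITICS = [("ne", "erg"), ("ko", "acc"), ("se", "ins"), ("mein", "loc"), ("par", "loc")]
_GEN_CLITIC = ("kaa", "gen")
_ADVERBS = ["jaldii", "kal", "dhiire"]
_ADJECTIVES = ["baRaa", "chhoTaa", "sundar", "puraanaa"]

_VOWELS = set("aeiou")


def _syllables(form: str) -> int:
    """Crude vowel-group count; the real quantity is an opaque input."""
    count = 0
    prev = False
    for ch in form:
        isv = ch in _VOWELS
        if isv and not prev:
            count += 1
        prev = isv
    return max(count, 1)


@dataclass(frozen=True)
class GrammarConfig:
    """Shape of the toy treebank.

    ``n_sentences`` sentences with 1..``max_nps`` preverbal argument NPs,
    optional genitive modifiers, adjectives, adverbs and auxiliaries; the
    probabilities below control the expansion choices.
    """

    n_sentences: int = 200
    max_nps: int = 3
    p_genitive: float = 0.2
    p_adjective: float = 0.2
    p_clitic: float = 0.7
    p_adverb: float = 0.25
    p_aux: float = 0.4
    #: a locative NP followed by another noun modifies that noun (instead of
    #: the verb) with this probability — genuine attachment ambiguity, so
    #: prefix probabilities divide over competing analyses and the beam
    #: width matters
    p_np_attach: float = 0.35


def _noun_token(rng, index: int, head: int, chunk: str, case: Optional[str]) -> Token:
    form = _NOUNS[rng.integers(len(_NOUNS))]
    feats = {"case": case or "0", "gen": "m" if rng.random() < 0.5 else "f",
             "chunk": chunk}
    return Token(index=index, form=form, lemma=form, cpos="N", pos="NN",
                 feats=feats, head=head, deprel="arg")


def gen_treebank(
    config: GrammarConfig = GrammarConfig(), seed: int = 0
) -> list[Sentence]:
    """Generate a deterministic projective SOV treebank."""
    rng = np.random.default_rng(seed)
    sentences = []
    for s in range(config.n_sentences):
        sentences.append(_gen_sentence(rng, f"syn{s + 1}", config))
    return sentences


def _gen_sentence(rng, sid: str, cfg: GrammarConfig) -> Sentence:
    # plan: [NP ...] [adverb] verb [aux]; build token plans with
    # placeholder heads, then resolve the verb position.
    plan: list[dict] = []  # each: kind, form..., head: int | "verb" | "next_noun"
    n_nps = int(rng.integers(1, cfg.max_nps + 1))
    chunk_no = 0
    for _ in range(n_nps):
        chunk_no += 1
        chunk = f"NP{chunk_no}"
        if rng.random() < cfg.p_genitive:
            # genitive modifier: gnoun kaa, attached to the following noun
            plan.append({"kind": "noun", "head": "next_noun", "chunk": chunk,
                         "case": _GEN_CLITIC[1]})
            plan.append({"kind": "clitic", "form": _GEN_CLITIC[0],
                         "case": _GEN_CLITIC[1], "head": "prev", "chunk": chunk})
        if rng.random() < cfg.p_adjective:
            plan.append({"kind": "adj", "head": "next_noun", "chunk": chunk})
        clitic: Optional[tuple[str, str]] = None
        if rng.random() < cfg.p_clitic:
            clitic = _CLITICS[rng.integers(len(_CLITICS))]
        # locative NPs that are not sentence-final may modify the next noun
        noun_head = "verb"
        is_last_np = chunk_no == n_nps
        if (clitic is not None and clitic[1] == "loc" and not is_last_np
                and rng.random() < cfg.p_np_attach):
            noun_head = "next_noun"
        plan.append({"kind": "noun", "head": noun_head, "chunk": chunk,
                     "case": None})
        if clitic is not None:
            form, case = clitic
            plan.append({"kind": "clitic", "form": form, "case": case,
                         "head": "prev", "chunk": chunk})
    if rng.random() < cfg.p_adverb:
        plan.append({"kind": "adv", "head": "verb", "chunk": "ADVP"})
    verb_pos = len(plan) + 1
    plan.append({"kind": "verb", "head": 0, "chunk": "VGF"})
    if rng.random() < cfg.p_aux:
        plan.append({"kind": "aux", "head": "verb", "chunk": "VGF"})

    # resolve heads
    tokens: list[Token] = []
    next_noun_at: dict[int, int] = {}
    noun_positions = [i + 1 for i, p in enumerate(plan) if p["kind"] == "noun"]
    for i, p in enumerate(plan):
        pos1 = i + 1
        if p["head"] == "next_noun":
            later = [np_ for np_ in noun_positions if np_ > pos1]
            head = later[0]
        elif p["head"] == "verb":
            head = verb_pos
        elif p["head"] == "prev":
            head = pos1 - 1
            # clitic attaches to the preceding nominal, skipping nothing:
            # it always directly follows its noun in the plan
        else:
            head = p["head"]
        next_noun_at[pos1] = head
    for i, p in enumerate(plan):
        pos1 = i + 1
        head = next_noun_at[pos1]
        kind = p["kind"]
        if kind == "noun":
            tokens.append(_noun_token(rng, pos1, head, p["chunk"], p["case"]))
        elif kind == "clitic":
            tokens.append(Token(index=pos1, form=p["form"], lemma=p["form"],
                                cpos="P", pos="PSP",
                                feats={"case": p["case"], "chunk": p["chunk"]},
                                head=head, deprel="lwg"))
        elif kind == "adj":
            form = _ADJECTIVES[rng.integers(len(_ADJECTIVES))]
            tokens.append(Token(index=pos1, form=form, lemma=form, cpos="J",
                                pos="JJ", feats={"chunk": p["chunk"]},
                                head=head, deprel="mod"))
        elif kind == "adv":
            form = _ADVERBS[rng.integers(len(_ADVERBS))]
            tokens.append(Token(index=pos1, form=form, lemma=form, cpos="R",
                                pos="RB", feats={"chunk": p["chunk"]},
                                head=head, deprel="adv"))
        elif kind == "verb":
            form = _VERBS[rng.integers(len(_VERBS))]
            tokens.append(Token(index=pos1, form=form, lemma=form, cpos="V",
                                pos="VM",
                                feats={"tam": "past", "chunk": p["chunk"]},
                                head=head, deprel="root"))
        else:  # aux
            form = _AUX[rng.integers(len(_AUX))]
            tokens.append(Token(index=pos1, form=form, lemma=form, cpos="V",
                                pos="VAUX",
                                feats={"tam": "prs", "chunk": p["chunk"]},
                                head=head, deprel="aux"))
    return Sentence(id=sid, tokens=tuple(tokens))


# ---------------------------------------------------------------------------
# word-level predictors

_UNIGRAM_RANK = {f: r for r, f in enumerate(
    _NOUNS + _VERBS + _AUX + [c for c, _ in _CLITICS] + [_GEN_CLITIC[0]]
    + _ADVERBS + _ADJECTIVES, start=1)}


def word_predictors(sentences: Sequence[Sentence]) -> pd.DataFrame:
    """Deterministic word-level predictor table for a toy treebank.

    Syllable length is counted from the form; complexity grows with word
    length; unigram log-frequency follows a Zipf-like rank over the lexicon;
    bigram log-frequency depends on the adjacent form pair.  These stand in
    for the externally computed predictors of a real corpus.
    """
    rows = []
    for sent in sentences:
        prev = "<s>"
        for tok in sent:
            rank = _UNIGRAM_RANK.get(tok.form, len(_UNIGRAM_RANK) + 1)
            pair_hash = (hash((prev, tok.form)) % 1000) / 1000.0
            rows.append({
                "sentence": sent.id,
                "word": tok.index,
                "complexity": len(tok.form) / 4.0,
                "syllables": _syllables(tok.form),
                "unigram": -math.log(rank + 1),
                "bigram": -math.log(rank + 1) - 2.0 + pair_hash,
            })
            prev = tok.form
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reading times

#: per-measure default effect sizes on log-ms, typical of naturalistic
#: reading corpora: strong length effect, facilitatory frequency effects,
#: small sentence-level effects.
DEFAULT_BETAS = {
    "fprt": {"syllables": 0.112, "bigram": -0.014, "unigram": -0.0003,
             "complexity": 0.003, "integration_cost": 0.004,
             "storage_cost": 0.003, "surprisal": 0.013},
    "rpd": {"syllables": 0.116, "bigram": -0.023, "unigram": -0.005,
            "complexity": 0.003, "integration_cost": 0.012,
            "storage_cost": -0.011, "surprisal": 0.002},
    "tft": {"syllables": 0.131, "bigram": -0.018, "unigram": -0.016,
            "complexity": 0.005, "integration_cost": 0.001,
            "storage_cost": 0.019, "surprisal": 0.005},
}

DEFAULT_INTERCEPTS = {"fprt": 5.50, "rpd": 5.65, "tft": 5.62}


@dataclass(frozen=True)
class RTConfig:
    """Reading-time simulation parameters.

    Log-scale standard deviations are typical of log reading times
    (residual ≈ 0.3, subject spread ≈ 0.1); the skip fraction of 0.25
    matches the roughly quarter of words recorded at 0 ms in eye-tracking
    corpora.
    """

    betas: dict = field(default_factory=lambda: {
        m: dict(v) for m, v in DEFAULT_BETAS.items()})
    intercepts: dict = field(default_factory=lambda: dict(DEFAULT_INTERCEPTS))
    n_subjects: int = 30
    subject_intercept_sd: float = 0.10
    item_intercept_sd: float = 0.05
    subject_slope_sd: float = 0.01
    item_slope_sd: float = 0.01
    residual_sd: float = 0.30
    zero_fraction: float = 0.25


def gen_reading_times(
    predictors: pd.DataFrame,
    config: RTConfig = RTConfig(),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate per-subject reading measures from a predictor table.

    ``predictors`` has one row per (sentence, word) with a column for every
    predictor named in ``config.betas``.  Returns ``(measures, truth)``:
    measures has one row per (subject, sentence, word) with ``fprt``,
    ``rpd``, ``tft`` in ms plus the word-level predictor columns; ``truth``
    records the coefficients and standard deviations actually used.
    Predictors are scaled (mean 0, sd 1) over the table before the betas
    apply, so the betas live on the same scale the analysis stage reports.
    """
    rng = np.random.default_rng(seed)
    measures = list(config.betas.keys())
    pred_names = sorted({p for m in measures for p in config.betas[m]})
    for p in pred_names:
        if p not in predictors.columns:
            raise ValueError(f"predictor table lacks column {p!r}")

    items = predictors["sentence"].astype(str).to_numpy()
    item_ids = sorted(set(items))
    n_items = len(item_ids)
    item_index = {s: i for i, s in enumerate(item_ids)}

    scaled = {}
    for p in pred_names:
        x = predictors[p].astype(float).to_numpy()
        sd = np.std(x, ddof=1)
        if sd == 0:
            raise ValueError(f"predictor {p!r} is constant; cannot scale")
        scaled[p] = (x - x.mean()) / sd

    n_sub = config.n_subjects
    u_sub = rng.normal(0, config.subject_intercept_sd, n_sub)
    u_item = rng.normal(0, config.item_intercept_sd, n_items)
    slope_sub = {p: rng.normal(0, config.subject_slope_sd, n_sub)
                 for p in pred_names}
    slope_item = {p: rng.normal(0, config.item_slope_sd, n_items)
                  for p in pred_names}

    n_words = len(predictors)
    frames = []
    for s in range(n_sub):
        eps = rng.normal(0, config.residual_sd, n_words)
        skip = rng.random(n_words) < config.zero_fraction
        item_idx = np.array([item_index[x] for x in items])
        re_part = u_sub[s] + u_item[item_idx] + eps
        for p in pred_names:
            re_part = re_part + (slope_sub[p][s] + slope_item[p][item_idx]) * scaled[p]
        block = {
            "subject": np.repeat(f"subj{s + 1:02d}", n_words),
            "sentence": items,
            "word": predictors["word"].to_numpy(),
        }
        values = {}
        for m in measures:
            eta = config.intercepts[m] + re_part
            for p, b in config.betas[m].items():
                eta = eta + b * scaled[p]
            values[m] = np.exp(eta)
        # a skipped word records 0 ms on every measure; guard the ordering
        # invariants against extreme predictor values
        if "fprt" in values:
            for m in ("rpd", "tft"):
                if m in values:
                    values[m] = np.maximum(values[m], values["fprt"])
        for m in measures:
            block[m] = np.where(skip, 0.0, np.round(values[m], 1))
        for p in ("complexity", "syllables", "unigram", "bigram"):
            if p in predictors.columns:
                block[p] = predictors[p].to_numpy()
        frames.append(pd.DataFrame(block))
    out = pd.concat(frames, ignore_index=True)
    truth = {
        "betas": {m: dict(config.betas[m]) for m in measures},
        "intercepts": dict(config.intercepts),
        "subject_intercept_sd": config.subject_intercept_sd,
        "item_intercept_sd": config.item_intercept_sd,
        "subject_slope_sd": config.subject_slope_sd,
        "item_slope_sd": config.item_slope_sd,
        "residual_sd": config.residual_sd,
        "zero_fraction": config.zero_fraction,
        "n_subjects": n_sub,
        "n_items": n_items,
    }
    return out, truth


# ---------------------------------------------------------------------------
# fixation sequences


class InfeasibleMeasures(ValueError):
    """No fixation sequence can realize the requested measure triples."""


def _reconstruct_trial(
    triples: list[tuple[float, float, float]]
) -> list[tuple[int, float]]:
    """Events realizing per-word (FPRT, RPD, TFT) for one trial.

    Feasibility follows from the measure definitions: every re-reading
    millisecond (TFT − FPRT) must be spent inside the regression window of
    some first-passed word at or to the right of it, every regression
    millisecond (RPD − FPRT) must be covered by re-reading supply at or to
    the left, the totals must balance exactly, and a regression needs some
    earlier word to land on.
    """
    n = len(triples)
    for w, (f, r, t) in enumerate(triples, start=1):
        if f < 0 or r < 0 or t < 0:
            raise InfeasibleMeasures(f"word {w}: negative measure")
        if t < f:
            raise InfeasibleMeasures(f"word {w}: TFT {t} < FPRT {f}")
        if f == 0 and r != 0:
            raise InfeasibleMeasures(
                f"word {w}: RPD {r} > 0 for a word with no first pass")
        if f > 0 and r < f:
            raise InfeasibleMeasures(f"word {w}: RPD {r} < FPRT {f}")
    first_passed = [w for w in range(1, n + 1) if triples[w - 1][0] > 0]
    if not first_passed:
        if any(t > 0 for _, _, t in triples):
            raise InfeasibleMeasures("fixation time with no first-passed word")
        return []
    m = first_passed[-1]
    supply = [triples[w - 1][2] - triples[w - 1][0] for w in range(1, n + 1)]
    if any(supply[w - 1] > 0 for w in range(m + 1, n + 1)):
        raise InfeasibleMeasures(
            "re-reading time on a word right of the last first-passed word")

    events: list[tuple[int, float]] = []
    for w in first_passed:
        f, r, _ = triples[w - 1]
        events.append((w, f))
        g = r - f
        if g <= 0:
            continue
        spends: list[tuple[int, float]] = []
        # earlier words first (nearest first), own re-reading last
        for j in range(w - 1, 0, -1):
            if g <= 0:
                break
            take = min(supply[j - 1], g)
            if take > 0:
                spends.append((j, take))
                supply[j - 1] -= take
                g -= take
        own = min(supply[w - 1], g)
        if g > 0 and not spends:
            raise InfeasibleMeasures(
                f"word {w}: regression time {g} with no earlier material to fixate")
        if own > 0:
            spends.append((w, own))
            supply[w - 1] -= own
            g -= own
        if g > 1e-9:
            raise InfeasibleMeasures(
                f"word {w}: regression time {g} exceeds available re-reading supply")
        events.extend(spends)
    leftover = sum(s for s in supply if s > 1e-9)
    if leftover > 1e-9:
        raise InfeasibleMeasures(
            f"re-reading supply of {leftover} ms cannot be placed in any "
            "regression window")
    return events


def gen_fixations(records: Sequence[GazeRecord]) -> list[FixationSequence]:
    """Constructive inverse of the gaze measures.

    Groups records by (subject, sentence) and builds, for each trial, a
    fixation sequence whose recomputed FPRT/RPD/TFT equal the given
    measures.  Raises :class:`InfeasibleMeasures` when no sequence exists.
    """
    trials: dict[tuple[str, str], dict[int, GazeRecord]] = {}
    for r in records:
        trials.setdefault((r.subject, r.sentence), {})[r.word] = r
    out = []
    for (subject, sentence), words in sorted(trials.items()):
        n = max(words)
        triples = []
        for w in range(1, n + 1):
            rec = words.get(w)
            if rec is None:
                triples.append((0.0, 0.0, 0.0))
            else:
                triples.append((rec.fprt_ms, rec.rpd_ms, rec.tft_ms))
        events = _reconstruct_trial(triples)
        if events:
            out.append(FixationSequence(subject=subject, sentence=sentence,
                                        events=tuple(events)))
    return out


def gen_random_fixations(
    rng: np.random.Generator,
    subject: str,
    sentence: str,
    n_words: int,
    p_skip: float = 0.25,
    p_refix: float = 0.15,
    p_regress: float = 0.2,
) -> FixationSequence:
    """A plausible random reading record: left-to-right sweep with skips,
    immediate re-fixations, and occasional regressions with re-reading."""
    events: list[tuple[int, float]] = []

    def dur() -> float:
        return float(int(rng.lognormal(5.2, 0.35)) + 30)

    visited: list[int] = []
    for w in range(1, n_words + 1):
        if rng.random() < p_skip:
            continue
        events.append((w, dur()))
        if rng.random() < p_refix:
            events.append((w, dur()))
        if visited and rng.random() < p_regress:
            back = visited[-int(rng.integers(1, min(3, len(visited)) + 1))]
            events.append((back, dur()))
            if rng.random() < 0.5:
                events.append((w, dur()))
        visited.append(w)
    return FixationSequence(subject=subject, sentence=sentence,
                            events=tuple(events))
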