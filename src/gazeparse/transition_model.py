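"""Feature extraction and the maximum-entropy transition classifier.

The feature set is the morphologically rich, strictly incremental template
inventory used for parsing a case-marked SOV language: FORM / LEMMA / POSTAG
/ CPOSTAG / morphological FEATS (gender-number-person excluded) / chunk id of
the top stack elements and the buffer front, structural neighbours
(head of Stack[0], linear predecessor of Stack[0], leftmost dependent of
Input[0]), and merge templates pairing stack-top and buffer-front columns.
A simpler POSTAG-merge-only set is available for comparison.

No template ever looks at a token beyond the buffer front, so the extracted
context is exactly what an incremental parser has seen.

The classifier is a multinomial logistic (MaxEnt) model with L2
regularization, trained on oracle transitions; at parse time its
probabilities are masked to the legal transitions of the current state and
renormalized, so the probabilities of all continuations of a live state sum
to one and surprisal measures only the mass lost to beam pruning and dead
states.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.feature_extraction import DictVectorizer
from sklearn.linear_model import LogisticRegression

from .corpus_io import MISSING, Sentence, Token
from .transition_system import ParserState, Transition, legal_transitions

__all__ = [
    "FeatureVector",
    "TransitionModel",
    "DeadStateError",
    "extract_features",
    "training_events",
    "train",
    "transition_probs",
]

NULL = "<null>"
ROOT = "<root>"

#: morphological feature keys excluded from FEATS templates (gender, number,
#: person); excluding them improves accuracy on this kind of treebank.
GNP_KEYS = frozenset({"gen", "num", "pers", "gender", "number", "person"})

#: feats key holding the chunk id.
CHUNK_KEY = "chunk"

DEFAULT_TRAIN_CONFIG = {
    "features": "rich",   # "rich" | "simple"
    "l2_c": 1.0,          # inverse L2 strength (sklearn C)
    "tol": 1e-6,
    "max_iter": 500,
    "holdout_fraction": 0.1,
}


@dataclass(frozen=True)
class FeatureVector:
    """The instantiated templates for one (state, sentence) pair.

    Every template is always present: absent context instantiates to an
    explicit ``<null>`` value rather than being omitted, so two states are
    distinguishable by *which* context they lack.
    """

    features: frozenset[str]

    def as_dict(self) -> dict[str, int]:
        return {f: 1 for f in self.features}


class DeadStateError(RuntimeError):
    """Raised when probabilities are requested for a state with no legal move."""


# ---------------------------------------------------------------------------
# template instantiation


def _column(tok: Optional[Token], column: str) -> str:
    """One column of a token; ``None`` context and root get placeholders."""
    if tok is None:
        return NULL
    if tok is ROOT_TOKEN:
        return ROOT
    if column == "FORM":
        return tok.form
    if column == "LEMMA":
        return tok.lemma
    if column == "POSTAG":
        return tok.pos
    if column == "CPOSTAG":
        return tok.cpos
    if column == "CHUNK":
        return tok.feats.get(CHUNK_KEY, MISSING)
    raise KeyError(column)


# sentinel standing for the virtual root on the stack
ROOT_TOKEN = Token(index=1, form=ROOT, lemma=ROOT, cpos=ROOT, pos=ROOT)


def _addressed_tokens(
    state: ParserState, sentence: Sentence
) -> dict[str, Optional[Token]]:
    """Resolve the template addresses to tokens (or None / root sentinel).

    Addresses: S0, S1, S2 (stack from the top), I0 (buffer front), headS0,
    predS0 (linear predecessor of S0), ldepI0 (leftmost dependent of the
    buffer front among the arcs built so far).
    """
    n = len(sentence)

    def tok(idx: Optional[int]) -> Optional[Token]:
        if idx is None:
            return None
        if idx == 0:
            return ROOT_TOKEN
        return sentence[idx - 1]

    stack = state.stack
    s0 = stack[-1] if len(stack) >= 1 else None
    s1 = stack[-2] if len(stack) >= 2 else None
    s2 = stack[-3] if len(stack) >= 3 else None
    i0 = state.buffer_pos if state.buffer_pos <= n else None

    head_s0 = state.head_of.get(s0) if s0 not in (None, 0) else None
    pred_s0 = s0 - 1 if s0 not in (None, 0) and s0 > 1 else None
    ldep_i0 = None
    if i0 is not None:
        deps = [d for (h, d) in state.arcs if h == i0]
        if deps:
            ldep_i0 = min(deps)
    return {
        "S0": tok(s0),
        "S1": tok(s1),
        "S2": tok(s2),
        "I0": tok(i0),
        "headS0": tok(head_s0),
        "predS0": tok(pred_s0),
        "ldepI0": tok(ldep_i0),
    }


def _feats_without_gnp(tok: Optional[Token]) -> list[str]:
    if tok is None:
        return [NULL]
    if tok is ROOT_TOKEN:
        return [ROOT]
    pairs = [
        f"{k}={v}" for k, v in tok.feats.items()
        if k not in GNP_KEYS and k != CHUNK_KEY
    ]
    return pairs if pairs else [NULL]


_RICH_SINGLE = [
    ("FORM", "S0"), ("FORM", "I0"),
    ("POSTAG", "S0"), ("POSTAG", "I0"),
    ("CHUNK", "S0"), ("CHUNK", "I0"),
    ("POSTAG", "S1"),
    ("POSTAG", "predS0"), ("POSTAG", "headS0"), ("POSTAG", "ldepI0"),
    ("CPOSTAG", "S0"), ("CPOSTAG", "I0"), ("CPOSTAG", "ldepI0"),
    ("FORM", "ldepI0"),
    ("LEMMA", "S0"), ("LEMMA", "I0"),
]

_RICH_MERGE = [
    ("CHUNK", ("S0", "I0")),
    ("CPOSTAG", ("S0", "I0")),
    ("POSTAG", ("S0", "I0")),
]

_SIMPLE_MERGE = [
    ("POSTAG", ("I0", "S0", "S1", "S2")),
    ("POSTAG", ("I0", "S0", "S1")),
    ("POSTAG", ("I0", "S0")),
]


def extract_features(
    state: ParserState, sentence: Sentence, features: str = "rich"
) -> FeatureVector:
    """Instantiate the template set for one state.

    ``features`` selects the rich morphological inventory (default) or the
    simple POSTAG-merge set. Deterministic: identical states yield identical
    vectors.
    """
    addr = _addressed_tokens(state, sentence)
    out: set[str] = set()
    if features == "rich":
        for value in _feats_without_gnp(addr["S0"]):
            out.add(f"split:FEATS:S0:{value}")
        for value in _feats_without_gnp(addr["I0"]):
            out.add(f"split:FEATS:I0:{value}")
        for column, where in _RICH_SINGLE:
            out.add(f"{column}:{where}:{_column(addr[where], column)}")
        for column, wheres in _RICH_MERGE:
            joined = "+".join(_column(addr[w], column) for w in wheres)
            out.add(f"merge:{column}:{'+'.join(wheres)}:{joined}")
    elif features == "simple":
        for column, wheres in _SIMPLE_MERGE:
            joined = "+".join(_column(addr[w], column) for w in wheres)
            out.add(f"merge:{column}:{'+'.join(wheres)}:{joined}")
    else:
        raise ValueError(f"unknown feature set {features!r} (rich|simple)")
    return FeatureVector(features=frozenset(out))


# ---------------------------------------------------------------------------
# model


@dataclass
class TransitionModel:
    """A trained MaxEnt transition classifier plus its feature vocabulary."""

    vectorizer: DictVectorizer
    classifier: LogisticRegression
    feature_set: str
    config: dict
    metadata: dict = field(default_factory=dict)

    #: index of each transition in the classifier's class order
    _class_index: dict[Transition, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._class_index = {
            Transition(c): i for i, c in enumerate(self.classifier.classes_)
        }

    # -- probabilities -----------------------------------------------------

    def raw_probs(self, fv: FeatureVector) -> dict[Transition, float]:
        """Unmasked softmax distribution over the trained transitions.

        Unknown features simply contribute no weight (they are absent from
        the vocabulary); transitions unseen in training have probability 0.
        """
        out = {t: 0.0 for t in Transition}
        if len(self.classifier.classes_) == 1:
            out[Transition(self.classifier.classes_[0])] = 1.0
            return out
        X = self.vectorizer.transform([fv.as_dict()])
        p = self.classifier.predict_proba(X)[0]
        for t, i in self._class_index.items():
            out[t] = float(p[i])
        return out

    # -- serialization -----------------------------------------------------

    FORMAT = "gazeparse-maxent/1"

    def save(self, path: str | Path) -> None:
        payload = {
            "format": self.FORMAT,
            "feature_set": self.feature_set,
            "config": self.config,
            "metadata": self.metadata,
            "classes": [c for c in self.classifier.classes_],
            "vocabulary": self.vectorizer.get_feature_names_out().tolist(),
            "coef": self.classifier.coef_.tolist(),
            "intercept": self.classifier.intercept_.tolist(),
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "TransitionModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("format") != cls.FORMAT:
            raise ValueError(
                f"unsupported model format {payload.get('format')!r}"
            )
        vec = DictVectorizer(sparse=True)
        vocab = payload["vocabulary"]
        vec.feature_names_ = list(vocab)
        vec.vocabulary_ = {f: i for i, f in enumerate(vocab)}
        clf = LogisticRegression()
        clf.classes_ = np.array(payload["classes"])
        clf.coef_ = np.array(payload["coef"])
        clf.intercept_ = np.array(payload["intercept"])
        return cls(
            vectorizer=vec,
            classifier=clf,
            feature_set=payload["feature_set"],
            config=payload["config"],
            metadata=payload["metadata"],
        )


def training_events(
    sentences: Sequence[Sentence], features: str = "rich"
) -> tuple[list[tuple[FeatureVector, Transition]], int]:
    """Oracle (features, transition) pairs from projective sentences.

    Non-projective sentences are skipped; the second return value counts
    them.
    """
    from .transition_system import NonProjectiveError, apply, initial_state, oracle

    events: list[tuple[FeatureVector, Transition]] = []
    skipped = 0
    for sent in sentences:
        try:
            seq = oracle(sent)
        except NonProjectiveError:
            skipped += 1
            continue
        n = len(sent)
        state = initial_state(n)
        for t in seq:
            events.append((extract_features(state, sent, features), t))
            state = apply(state, t, n)
    return events, skipped


def train(
    events: Sequence[tuple[FeatureVector, Transition]],
    config: Optional[dict] = None,
    seed: int = 0,
) -> TransitionModel:
    """Fit the multinomial logistic transition model.

    Deterministic given ``seed`` and ``config`` (lbfgs on a convex
    objective). Held-out per-transition accuracy is recorded in the model
    metadata when the event list is large enough to split.
    """
    if not events:
        raise ValueError("cannot train on an empty event list")
    cfg = {**DEFAULT_TRAIN_CONFIG, **(config or {})}
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(events))
    n_hold = int(len(events) * cfg["holdout_fraction"])
    # ensure every class appears in training even after the split
    hold_idx = set(order[:n_hold].tolist())
    train_idx = [i for i in range(len(events)) if i not in hold_idx]
    labels_all = {events[i][1] for i in range(len(events))}
    labels_train = {events[i][1] for i in train_idx}
    if labels_train != labels_all:
        train_idx = list(range(len(events)))
        hold_idx = set()

    vec = DictVectorizer(sparse=True)
    X = vec.fit_transform([events[i][0].as_dict() for i in train_idx])
    y = np.array([events[i][1].value for i in train_idx])
    clf = LogisticRegression(
        C=cfg["l2_c"],
        tol=cfg["tol"],
        max_iter=cfg["max_iter"],
        solver="lbfgs",
    )
    if len(np.unique(y)) == 1:
        # degenerate training set: a constant model putting all mass on
        # the single observed transition (the solver needs >= 2 classes)
        clf.classes_ = np.unique(y)
        clf.coef_ = np.zeros((1, X.shape[1]))
        clf.intercept_ = np.zeros(1)
    else:
        clf.fit(X, y)

    metadata = {"n_events": len(events), "seed": seed}
    if hold_idx:
        Xh = vec.transform([events[i][0].as_dict() for i in sorted(hold_idx)])
        yh = np.array([events[i][1].value for i in sorted(hold_idx)])
        pred = clf.predict(Xh)
        metadata["holdout_accuracy"] = float(np.mean(pred == yh))
        per_class = {}
        for label in np.unique(yh):
            mask = yh == label
            per_class[Transition(label).name] = float(
                np.mean(pred[mask] == label)
            )
        metadata["holdout_accuracy_per_transition"] = per_class
    return TransitionModel(
        vectorizer=vec,
        classifier=clf,
        feature_set="rich" if "features" not in cfg else cfg["features"],
        config=cfg,
        metadata=metadata,
    )


def transition_probs(
    model: TransitionModel, state: ParserState, sentence: Sentence
) -> tuple[dict[Transition, float], dict[Transition, float]]:
    """Legality-masked, renormalized transition distribution for a state.

    Returns ``(masked, unmasked)``. Masking zeroes illegal transitions and
    renormalizes the rest to sum to one, which preserves likelihood ratios
    among the legal transitions. Raises :class:`DeadStateError` for states
    with no legal transition so the beam can drop them.
    """
    legal = legal_transitions(state, len(sentence))
    if not legal:
        raise DeadStateError(
            f"no legal transition (stack={state.stack}, "
            f"buffer_pos={state.buffer_pos})"
        )
    fv = extract_features(state, sentence, model.feature_set)
    raw = model.raw_probs(fv)
    mass = sum(raw[t] for t in legal)
    if mass <= 0.0:
        # the trained classes carry no mass here; fall back to uniform
        masked = {t: 1.0 / len(legal) for t in legal}
    else:
        masked = {t: raw[t] / mass for t in legal}
    return masked, raw


def treebank_hash(sentences: Sequence[Sentence]) -> str:
    """Stable content hash used to stamp models with their training data."""
    h = hashlib.sha256()
    for sent in sentences:
        h.update(sent.id.encode())
        for tok in sent:
            h.update(
                f"{tok.index}|{tok.form}|{tok.pos}|{tok.head}".encode()
            )
    return h.hexdigest()[:16]
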