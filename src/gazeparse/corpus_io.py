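"""Readers and writers for the on-disk formats used throughout the toolkit.

Four dialects are defined here and nowhere else:

* **Treebank** — CoNLL-X tab-separated, ten columns per token line
  (``ID FORM LEMMA CPOSTAG POSTAG FEATS HEAD DEPREL PHEAD PDEPREL``), blank
  line between sentences, ``_`` for missing values, UTF-8.  An optional
  ``#<id>`` comment line before a sentence carries its identifier.
* **Measures** — per-word eye-tracking measure table, TSV with header
  ``subject sentence word fprt rpd tft complexity syllables unigram bigram``.
  Word-level predictors ride here rather than in the treebank because they
  are computed externally to the parser.
* **Fixations** — raw fixation logs, TSV with header
  ``subject sentence order word duration``.
* **Config** — YAML key/value files.

Malformed sentences, records, or event lists are rejected individually with
a diagnostic naming the offending line; reading never fails globally because
of one bad entry, and nothing is dropped silently.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterator, Sequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "Token",
    "Sentence",
    "GazeRecord",
    "FixationSequence",
    "Diagnostic",
    "ReadResult",
    "read_treebank",
    "write_treebank",
    "read_measures",
    "write_measures",
    "read_fixations",
    "write_fixations",
    "read_config",
    "is_projective",
]

MISSING = "_"

MEASURES_COLUMNS = [
    "subject", "sentence", "word", "fprt", "rpd", "tft",
    "complexity", "syllables", "unigram", "bigram",
]
FIXATIONS_COLUMNS = ["subject", "sentence", "order", "word", "duration"]


@dataclass(frozen=True)
class Token:
    """A dependency-annotated word.

    ``head`` uses 0 for the virtual root; ``index`` is 1-based. ``feats``
    holds the morphological key/value map (case marker, tense-aspect-modality,
    chunk id; gender/number/person may be present but are excludable by the
    feature extractor). The four word-level predictors are optional: they are
    supplied by the measures table, not the treebank.
    """

    index: int
    form: str
    lemma: str = MISSING
    cpos: str = MISSING
    pos: str = MISSING
    feats: dict[str, str] = field(default_factory=dict)
    head: int = 0
    deprel: str = MISSING
    syllable_length: Optional[int] = None
    word_complexity: Optional[float] = None
    unigram_logfreq: Optional[float] = None
    bigram_logfreq: Optional[float] = None

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"token index must be >= 1, got {self.index}")
        if self.head < 0:
            raise ValueError(f"head must be >= 0, got {self.head}")
        if self.head == self.index:
            raise ValueError(f"token {self.index} is its own head")

    def feats_string(self) -> str:
        if not self.feats:
            return MISSING
        return "|".join(f"{k}={v}" for k, v in self.feats.items())


@dataclass(frozen=True)
class Sentence:
    """An ordered, tree-checked list of tokens.

    Construction validates that indices are exactly 1..n, heads lie in 0..n,
    and the arcs form a single tree hanging off the virtual root 0 with
    exactly one root child. Projectivity is computed once and stored.
    """

    id: str
    tokens: tuple[Token, ...]
    projective: bool = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        n = len(self.tokens)
        if n == 0:
            raise ValueError(f"sentence {self.id!r}: no tokens")
        for i, tok in enumerate(self.tokens, start=1):
            if tok.index != i:
                raise ValueError(
                    f"sentence {self.id!r}: expected token index {i}, got {tok.index}"
                )
            if tok.head > n:
                raise ValueError(
                    f"sentence {self.id!r}: token {i} head {tok.head} out of range 0..{n}"
                )
        roots = [t.index for t in self.tokens if t.head == 0]
        if len(roots) != 1:
            raise ValueError(
                f"sentence {self.id!r}: expected exactly one root-attached token, "
                f"got {len(roots)}"
            )
        # cycle check: walk each token up to the root
        for tok in self.tokens:
            seen = set()
            cur = tok.index
            while cur != 0:
                if cur in seen:
                    raise ValueError(
                        f"sentence {self.id!r}: cycle through token {tok.index}"
                    )
                seen.add(cur)
                cur = self.tokens[cur - 1].head
        object.__setattr__(self, "projective", is_projective(self.heads()))

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self) -> Iterator[Token]:
        return iter(self.tokens)

    def __getitem__(self, i: int) -> Token:
        return self.tokens[i]

    def heads(self) -> tuple[int, ...]:
        """Gold head of word i at position i-1 (0 = virtual root)."""
        return tuple(t.head for t in self.tokens)

    def arcs(self) -> frozenset[tuple[int, int]]:
        """Gold arc set as (head, dependent) pairs, root arcs included."""
        return frozenset((t.head, t.index) for t in self.tokens)


def is_projective(heads: Sequence[int]) -> bool:
    """True iff no two arcs cross and every arc spans only descendants.

    ``heads[i-1]`` is the head of word i; the virtual root is 0 and its arc
    to the root word is included in the check (standard convention, so a
    non-final root word with dependents on both sides is still projective).
    """
    arcs = [(h, d) for d, h in enumerate(heads, start=1)]
    for h1, d1 in arcs:
        lo1, hi1 = min(h1, d1), max(h1, d1)
        for h2, d2 in arcs:
            lo2, hi2 = min(h2, d2), max(h2, d2)
            if lo1 < lo2 < hi1 < hi2 or lo2 < lo1 < hi2 < hi1:
                return False
    return True


@dataclass(frozen=True)
class GazeRecord:
    """Per-subject, per-word eye-tracking measures in milliseconds."""

    subject: str
    sentence: str
    word: int
    fprt_ms: float
    rpd_ms: float
    tft_ms: float
    complexity: Optional[float] = None
    syllables: Optional[int] = None
    unigram: Optional[float] = None
    bigram: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("fprt_ms", "rpd_ms", "tft_ms"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.fprt_ms > self.tft_ms:
            raise ValueError(
                f"fprt_ms {self.fprt_ms} exceeds tft_ms {self.tft_ms}"
            )
        if self.fprt_ms > 0 and self.rpd_ms > 0 and self.fprt_ms > self.rpd_ms:
            raise ValueError(
                f"fprt_ms {self.fprt_ms} exceeds rpd_ms {self.rpd_ms}"
            )


@dataclass(frozen=True)
class FixationSequence:
    """Ordered fixation events ``(word index, duration ms)`` for one trial."""

    subject: str
    sentence: str
    events: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(tuple(e) for e in self.events))
        for w, dur in self.events:
            if w < 1:
                raise ValueError(f"fixated word index must be >= 1, got {w}")
            if dur <= 0:
                raise ValueError(f"fixation duration must be > 0, got {dur}")


@dataclass(frozen=True)
class Diagnostic:
    """One rejected sentence/record with its location and reason."""

    line: int
    unit: str
    message: str

    def __str__(self) -> str:
        return f"line {self.line} [{self.unit}]: {self.message}"


class ReadResult(list):
    """A list of parsed units plus the diagnostics for rejected ones."""

    def __init__(self, items, diagnostics: list[Diagnostic]):
        super().__init__(items)
        self.diagnostics = diagnostics


# ---------------------------------------------------------------------------
# treebank


def _parse_feats(text: str) -> dict[str, str]:
    if text == MISSING or not text:
        return {}
    out: dict[str, str] = {}
    for part in text.split("|"):
        if "=" in part:
            k, v = part.split("=", 1)
        else:
            k, v = part, ""
        out[k] = v
    return out


def read_treebank(path: str | Path) -> ReadResult:
    """Read a CoNLL-X treebank; returns sentences plus per-sentence diagnostics.

    Cyclic, multi-rooted, or otherwise malformed sentences are rejected
    individually with the line number where they start; the rest of the file
    is still read.
    """
    sentences: list[Sentence] = []
    diagnostics: list[Diagnostic] = []
    block: list[tuple[int, str]] = []
    sent_id: Optional[str] = None
    auto_id = 0
    start_line = 1

    def flush() -> None:
        nonlocal block, sent_id, auto_id
        if not block:
            sent_id = None
            return
        auto_id += 1
        sid = sent_id if sent_id is not None else f"s{auto_id}"
        try:
            tokens = []
            for lineno, line in block:
                cols = line.split("\t")
                if len(cols) != 10:
                    raise ValueError(
                        f"line {lineno}: expected 10 columns, got {len(cols)}"
                    )
                tokens.append(
                    Token(
                        index=int(cols[0]),
                        form=cols[1],
                        lemma=cols[2],
                        cpos=cols[3],
                        pos=cols[4],
                        feats=_parse_feats(cols[5]),
                        head=int(cols[6]),
                        deprel=cols[7],
                    )
                )
            sentences.append(Sentence(id=sid, tokens=tuple(tokens)))
        except (ValueError, IndexError) as exc:
            diagnostics.append(Diagnostic(block[0][0], f"sentence {sid}", str(exc)))
        block = []
        sent_id = None

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                flush()
                continue
            if line.startswith("#"):
                sent_id = line[1:].strip()
                start_line = lineno
                continue
            if not block:
                start_line = lineno
            block.append((lineno, line))
        flush()
    return ReadResult(sentences, diagnostics)


def write_treebank(sentences: Sequence[Sentence], path: str | Path) -> None:
    """Write sentences in the CoNLL-X dialect, one ``#id`` comment each."""
    with open(path, "w", encoding="utf-8") as fh:
        for sent in sentences:
            fh.write(f"#{sent.id}\n")
            for tok in sent.tokens:
                cols = [
                    str(tok.index), tok.form, tok.lemma, tok.cpos, tok.pos,
                    tok.feats_string(), str(tok.head), tok.deprel,
                    MISSING, MISSING,
                ]
                fh.write("\t".join(cols) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# measures


def _opt_float(text: str) -> Optional[float]:
    return None if text == MISSING or text == "" else float(text)


def _opt_int(text: str) -> Optional[int]:
    return None if text == MISSING or text == "" else int(text)


def read_measures(path: str | Path) -> ReadResult:
    """Read the per-word measures TSV; bad records are rejected individually.

    Zero-millisecond measures are read as-is — the zero-removal the analysis
    stage performs is not this layer's business.
    """
    records: list[GazeRecord] = []
    diagnostics: list[Diagnostic] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != MEASURES_COLUMNS:
            raise ValueError(
                f"measures header mismatch: expected {MEASURES_COLUMNS}, got {header}"
            )
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            try:
                if len(cols) != len(MEASURES_COLUMNS):
                    raise ValueError(
                        f"expected {len(MEASURES_COLUMNS)} columns, got {len(cols)}"
                    )
                records.append(
                    GazeRecord(
                        subject=cols[0],
                        sentence=cols[1],
                        word=int(cols[2]),
                        fprt_ms=float(cols[3]),
                        rpd_ms=float(cols[4]),
                        tft_ms=float(cols[5]),
                        complexity=_opt_float(cols[6]),
                        syllables=_opt_int(cols[7]),
                        unigram=_opt_float(cols[8]),
                        bigram=_opt_float(cols[9]),
                    )
                )
            except ValueError as exc:
                diagnostics.append(Diagnostic(lineno, "measure record", str(exc)))
    return ReadResult(records, diagnostics)


def _fmt(value) -> str:
    if value is None:
        return MISSING
    if isinstance(value, float) and value == int(value):
        return str(int(value))
    return str(value)


def write_measures(records: Sequence[GazeRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(MEASURES_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.subject, r.sentence, str(r.word),
                        _fmt(r.fprt_ms), _fmt(r.rpd_ms), _fmt(r.tft_ms),
                        _fmt(r.complexity), _fmt(r.syllables),
                        _fmt(r.unigram), _fmt(r.bigram),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# fixations


def read_fixations(
    path: str | Path,
    sentence_lengths: Optional[dict[str, int]] = None,
) -> ReadResult:
    """Read raw fixation logs; a trial with any bad event is rejected whole.

    Events belonging to one (subject, sentence) trial are ordered by the
    ``order`` column. When ``sentence_lengths`` is given, trials containing a
    fixation on a word index beyond the sentence length are rejected.
    """
    diagnostics: list[Diagnostic] = []
    trials: dict[tuple[str, str], list[tuple[int, int, float, int]]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != FIXATIONS_COLUMNS:
            raise ValueError(
                f"fixations header mismatch: expected {FIXATIONS_COLUMNS}, got {header}"
            )
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            try:
                if len(cols) != len(FIXATIONS_COLUMNS):
                    raise ValueError(
                        f"expected {len(FIXATIONS_COLUMNS)} columns, got {len(cols)}"
                    )
                key = (cols[0], cols[1])
                trials.setdefault(key, []).append(
                    (int(cols[2]), int(cols[3]), float(cols[4]), lineno)
                )
            except ValueError as exc:
                diagnostics.append(Diagnostic(lineno, "fixation event", str(exc)))
    sequences: list[FixationSequence] = []
    for (subject, sentence), events in trials.items():
        events.sort(key=lambda e: e[0])
        try:
            if sentence_lengths is not None:
                n = sentence_lengths.get(sentence)
                if n is not None:
                    for _, w, _, lineno in events:
                        if w > n:
                            raise ValueError(
                                f"fixation on word {w} beyond sentence length {n}"
                            )
            sequences.append(
                FixationSequence(
                    subject=subject,
                    sentence=sentence,
                    events=tuple((w, dur) for _, w, dur, _ in events),
                )
            )
        except ValueError as exc:
            diagnostics.append(
                Diagnostic(events[0][3], f"trial {subject}/{sentence}", str(exc))
            )
    return ReadResult(sequences, diagnostics)


def write_fixations(sequences: Sequence[FixationSequence], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(FIXATIONS_COLUMNS) + "\n")
        for seq in sequences:
            for order, (word, dur) in enumerate(seq.events, start=1):
                fh.write(
                    "\t".join(
                        [seq.subject, seq.sentence, str(order), str(word), _fmt(dur)]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# config


def read_config(path: str | Path) -> dict:
    """Load a YAML key/value configuration file."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping, got {type(data).__name__}")
    return data
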