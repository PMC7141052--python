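"""Eye-movement reading measures computed from raw fixation sequences.

Definitions (per-word, per-trial, all in ms):

* **FPRT** (first-pass reading time / gaze duration): the sum of fixation
  durations on the word from its first fixation — provided the word was
  entered from the left, i.e. no word to its right had been fixated earlier
  in the trial — until the first fixation on any other word.  A word never
  first-pass-fixated scores 0, and re-fixations after leaving never re-open
  the first pass.
* **RPD** (regression-path duration / go-past time): the sum of *all*
  fixation durations (on the word and any earlier word, including returns to
  the word itself) from the word's first fixation until the gaze first lands
  right of the word.  Defined only for first-pass-entered words; otherwise 0.
  If the gaze never moves right of the word the window extends to the end of
  the trial.
* **TFT** (total fixation time): the sum of all fixations on the word in
  any pass.
"""

from __future__ import annotations

from typing import Sequence

from .corpus_io import FixationSequence, GazeRecord

__all__ = [
    "first_pass_reading_time",
    "regression_path_duration",
    "total_fixation_time",
    "measures_for_sequence",
    "records_from_fixations",
]


def _first_pass_entry(events, word: int) -> int | None:
    """Index of the word's first fixation if entered from the left, else None."""
    for i, (w, _) in enumerate(events):
        if w == word:
            return i
        if w > word:
            return None  # something right of the word was fixated first
    return None


def first_pass_reading_time(seq: FixationSequence, word: int) -> float:
    """FPRT(word) in ms; 0 when the word is never first-pass-fixated."""
    events = seq.events
    i0 = _first_pass_entry(events, word)
    if i0 is None:
        return 0.0
    total = 0.0
    for w, dur in events[i0:]:
        if w != word:
            break
        total += dur
    return total


def regression_path_duration(seq: FixationSequence, word: int) -> float:
    """RPD(word) in ms; 0 when the word has no first pass."""
    events = seq.events
    i0 = _first_pass_entry(events, word)
    if i0 is None:
        return 0.0
    total = 0.0
    for w, dur in events[i0:]:
        if w > word:
            break
        total += dur
    return total


def total_fixation_time(seq: FixationSequence, word: int) -> float:
    """TFT(word) in ms: all fixations on the word, any pass."""
    return float(sum(dur for w, dur in seq.events if w == word))


def measures_for_sequence(
    seq: FixationSequence, n_words: int
) -> list[tuple[float, float, float]]:
    """(FPRT, RPD, TFT) for words 1..n_words of one trial."""
    return [
        (
            first_pass_reading_time(seq, w),
            regression_path_duration(seq, w),
            total_fixation_time(seq, w),
        )
        for w in range(1, n_words + 1)
    ]


def records_from_fixations(
    sequences: Sequence[FixationSequence],
    sentence_lengths: dict[str, int],
) -> list[GazeRecord]:
    """Compute GazeRecords for every word of every trial."""
    records = []
    for seq in sequences:
        n = sentence_lengths[seq.sentence]
        for word, (fprt, rpd, tft) in enumerate(
            measures_for_sequence(seq, n), start=1
        ):
            records.append(
                GazeRecord(
                    subject=seq.subject,
                    sentence=seq.sentence,
                    word=word,
                    fprt_ms=fprt,
                    rpd_ms=rpd,
                    tft_ms=tft,
                )
            )
    return records
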