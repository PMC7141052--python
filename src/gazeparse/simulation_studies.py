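"""Reproducible end-to-end simulation studies.

Each study runs the full pipeline — synthetic treebank, oracle training,
beam surprisal, memory metrics, simulated reading times, crossed-effects
regression — at the scale of a typical eye-tracking corpus (30 subjects,
150 sentences, about a quarter of word tokens skipped):

* **parameter recovery**: reading times generated with known coefficients
  are refitted; a coefficient counts as recovered when the estimate falls
  within two standard errors of the truth.  The regression includes the
  random-slope structure the generator uses, so the standard errors are
  correctly calibrated.
* **null calibration**: with every coefficient (fixed and random slope)
  zero, the rate of |t| ≥ 2 among predictor terms estimates the
  false-positive rate of the significance convention.
* **measure dissociation**: a surprisal effect is injected only into
  first-pass reading time and a storage-cost effect only into total
  fixation time; the study asks how often each effect is detected in its
  own measure and how often it falsely appears in the other.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .analysis import ModelSpec, fit_lmm_many, prepare
from .memory_metrics import predictor_table
from .synthetic_data import (
    GrammarConfig,
    RTConfig,
    gen_reading_times,
    gen_treebank,
    word_predictors,
)
from .transition_model import TransitionModel, train, training_events

__all__ = [
    "build_corpus",
    "recovery_study",
    "null_study",
    "dissociation_study",
]

CORPUS_N_SENTENCES = 150
CORPUS_N_SUBJECTS = 30
DEFAULT_K = 10

STUDY_PREDICTORS = (
    "complexity", "unigram", "bigram", "syllables",
    "integration_cost", "storage_cost", "surprisal",
)


def build_corpus(
    seed: int,
    n_sentences: int = CORPUS_N_SENTENCES,
    k: int = DEFAULT_K,
) -> tuple[list, TransitionModel, pd.DataFrame]:
    """Treebank + trained parser + per-word predictor table.

    The predictor table joins the parser-derived sentence-level predictors
    (surprisal, storage, integration, retrieval) with the word-level ones
    (length, complexity, frequencies).
    """
    sentences = gen_treebank(GrammarConfig(n_sentences=n_sentences), seed=seed)
    events, _ = training_events(sentences)
    model = train(events, seed=seed)
    table = predictor_table(sentences, model, k)
    predictors = table.merge(word_predictors(sentences), on=["sentence", "word"])
    return sentences, model, predictors


def _study_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def recovery_study(
    predictors: pd.DataFrame,
    seed: int = 0,
    n_reps: int = 50,
    dependent: str = "fprt",
) -> dict:
    """Generate-and-refit with the default effect structure.

    Returns the pooled fraction of (coefficient, replication) pairs whose
    estimate lies within two standard errors of the generating value, the
    per-coefficient coverage, and the mean estimates.
    """
    cfg = RTConfig(n_subjects=CORPUS_N_SUBJECTS)
    spec = ModelSpec(dependent=dependent, predictors=STUDY_PREDICTORS,
                     slopes="all")
    tables = []
    truth = None
    for rep_seed in _study_seeds(seed, n_reps):
        measures, truth = gen_reading_times(predictors, cfg, seed=rep_seed)
        tables.append(prepare(measures, predictors, spec))
    results = fit_lmm_many(tables, spec)
    betas = truth["betas"][dependent]
    hits = {p: 0 for p in STUDY_PREDICTORS}
    estimates = {p: [] for p in STUDY_PREDICTORS}
    for res in results:
        for p in STUDY_PREDICTORS:
            row = res.coefficients.loc[p]
            estimates[p].append(float(row["estimate"]))
            if abs(row["estimate"] - betas.get(p, 0.0)) <= 2 * row["se"]:
                hits[p] += 1
    total = n_reps * len(STUDY_PREDICTORS)
    return {
        "n_reps": n_reps,
        "coverage": sum(hits.values()) / total,
        "per_predictor_coverage": {p: hits[p] / n_reps for p in hits},
        "mean_estimates": {p: float(np.mean(v)) for p, v in estimates.items()},
        "true_betas": dict(betas),
        "n_converged": sum(r.converged for r in results),
    }


def null_study(
    predictors: pd.DataFrame,
    seed: int = 0,
    n_reps: int = 50,
    dependent: str = "fprt",
) -> dict:
    """False-positive calibration with all predictor effects zero.

    The null removes the predictors' fixed *and* random-slope contributions
    (no effect in any form), keeping subject/item intercept variation and
    residual noise; the fit then uses crossed random intercepts, which is
    the matching structure.
    """
    cfg = RTConfig(
        betas={dependent: {p: 0.0 for p in STUDY_PREDICTORS}},
        n_subjects=CORPUS_N_SUBJECTS,
        subject_slope_sd=0.0,
        item_slope_sd=0.0,
    )
    spec = ModelSpec(dependent=dependent, predictors=STUDY_PREDICTORS,
                     slopes=())
    tables = []
    for rep_seed in _study_seeds(seed + 1, n_reps):
        measures, _ = gen_reading_times(predictors, cfg, seed=rep_seed)
        tables.append(prepare(measures, predictors, spec))
    results = fit_lmm_many(tables, spec)
    n_sig = 0
    for res in results:
        for p in STUDY_PREDICTORS:
            if abs(res.coefficients.loc[p, "t"]) >= 2.0:
                n_sig += 1
    total = n_reps * len(STUDY_PREDICTORS)
    return {
        "n_reps": n_reps,
        "false_positive_rate": n_sig / total,
        "n_tests": total,
        "n_converged": sum(r.converged for r in results),
    }


DISSOCIATION_BETAS = {
    # surprisal drives only the early measure, storage cost only the late
    # one; word length and bigram frequency act on both as in real corpora
    "fprt": {"surprisal": 0.013, "syllables": 0.112, "bigram": -0.014},
    "tft": {"storage_cost": 0.019, "syllables": 0.131, "bigram": -0.018},
}


def dissociation_study(
    predictors: pd.DataFrame,
    seed: int = 0,
    n_reps: int = 20,
) -> dict:
    """Early/late measure dissociation of the two prediction metrics.

    Returns, per replication averaged: how often surprisal is significant
    (positive, |t| ≥ 2) in the FPRT model and storage cost in the TFT
    model, and how often each incorrectly reaches significance in the other
    measure.
    """
    slope_preds = tuple(sorted({p for b in DISSOCIATION_BETAS.values() for p in b}))
    cfg = RTConfig(betas={m: dict(b) for m, b in DISSOCIATION_BETAS.items()},
                   n_subjects=CORPUS_N_SUBJECTS)
    specs = {
        m: ModelSpec(dependent=m, predictors=STUDY_PREDICTORS,
                     slopes=slope_preds)
        for m in ("fprt", "tft")
    }
    tables: dict[str, list[pd.DataFrame]] = {"fprt": [], "tft": []}
    for rep_seed in _study_seeds(seed + 2, n_reps):
        measures, _ = gen_reading_times(predictors, cfg, seed=rep_seed)
        for m in ("fprt", "tft"):
            tables[m].append(prepare(measures, predictors, specs[m]))
    results = {m: fit_lmm_many(tables[m], specs[m]) for m in ("fprt", "tft")}

    def sig(res, term, positive=True):
        row = res.coefficients.loc[term]
        ok = abs(row["t"]) >= 2.0
        return ok and (row["estimate"] > 0 if positive else True)

    surprisal_in_fprt = sum(sig(r, "surprisal") for r in results["fprt"])
    storage_in_tft = sum(sig(r, "storage_cost") for r in results["tft"])
    surprisal_in_tft = sum(sig(r, "surprisal", positive=False)
                           for r in results["tft"])
    storage_in_fprt = sum(sig(r, "storage_cost", positive=False)
                          for r in results["fprt"])
    both = sum(
        sig(a, "surprisal") and sig(b, "storage_cost")
        for a, b in zip(results["fprt"], results["tft"])
    )
    return {
        "n_reps": n_reps,
        "surprisal_detected_in_fprt": surprisal_in_fprt / n_reps,
        "storage_detected_in_tft": storage_in_tft / n_reps,
        "surprisal_spurious_in_tft": surprisal_in_tft / n_reps,
        "storage_spurious_in_fprt": storage_in_fprt / n_reps,
        "pattern_rate": both / n_reps,
    }
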