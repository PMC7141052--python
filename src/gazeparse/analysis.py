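"""Reading-time regression pipeline: scaling, filtering, crossed-effects LMMs.

The pipeline mirrors the standard treatment of eye-tracking corpus data:

1. join the per-word measure table with the predictor table;
2. drop data points recorded with 0 ms for the chosen measure (skipped
   words — typically around a quarter of the data);
3. log-transform the dependent measure (natural log);
4. center and scale every predictor to mean 0, sd 1;
5. fit a linear mixed model with crossed varying intercepts and varying
   slopes for subjects and for items (sentences), with no intercept-slope
   correlations, by REML;
6. report estimate, standard error and t per fixed effect, with |t| ≥ 2 as
   the significance convention.

For the retrieval-cost analysis, rows where the parser performed no
retrieval are dropped and integration cost is excluded (the two are
strongly correlated formalizations of the same retrieval event).

Fitting is delegated to lme4 through ``Rscript`` — the canonical
implementation of crossed random effects, and orders of magnitude faster
here than pure-Python alternatives; a statsmodels backend (random
intercepts only) is provided for cross-checking.  If the full random-slope
structure fails to converge, slopes are pruned in reverse predictor order
and the pruning is recorded on the result.
"""

from __future__ import annotations

import json
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .corpus_io import GazeRecord

__all__ = [
    "ModelSpec",
    "LmmResult",
    "ConvergenceError",
    "measures_frame",
    "scale_predictors",
    "prepare",
    "fit_lmm",
    "fit_lmm_many",
    "predictor_correlations",
]

MEASURE_COLUMNS = {"fprt": "fprt", "rpd": "rpd", "tft": "tft"}

DEFAULT_PREDICTORS = [
    "complexity", "unigram", "bigram", "syllables",
    "integration_cost", "storage_cost", "surprisal",
]

T_SIGNIFICANT = 2.0  # |t| >= 2 convention


class ConvergenceError(RuntimeError):
    """The mixed model failed to converge under every fallback structure."""


@dataclass(frozen=True)
class ModelSpec:
    """What to regress on what, and with which random-effect structure.

    ``dependent`` is one of ``fprt``/``rpd``/``tft`` (log-transformed before
    fitting).  ``predictors`` are fixed effects, scaled before fitting.
    ``slopes`` lists the predictors receiving by-subject and by-item random
    slopes (uncorrelated with the intercepts); ``"all"`` means every
    predictor.  ``retrieval_mode`` switches on the zero-retrieval exclusion
    and drops integration cost.
    """

    dependent: str = "fprt"
    predictors: tuple[str, ...] = tuple(DEFAULT_PREDICTORS)
    slopes: tuple[str, ...] | str = ()
    retrieval_mode: bool = False

    def __post_init__(self) -> None:
        if self.dependent not in MEASURE_COLUMNS:
            raise ValueError(
                f"dependent must be one of {sorted(MEASURE_COLUMNS)}, "
                f"got {self.dependent!r}"
            )
        object.__setattr__(self, "predictors", tuple(self.predictors))
        if self.slopes != "all":
            object.__setattr__(self, "slopes", tuple(self.slopes))

    def slope_predictors(self) -> tuple[str, ...]:
        return self.predictors if self.slopes == "all" else self.slopes


@dataclass
class LmmResult:
    """Fixed-effect table plus fitting diagnostics.

    ``coefficients`` is indexed by term with columns ``estimate``, ``se``,
    ``t`` and boolean ``significant`` (|t| ≥ 2).
    """

    coefficients: pd.DataFrame
    converged: bool
    formula: str
    pruned_slopes: list[str] = field(default_factory=list)
    messages: list[str] = field(default_factory=list)
    n_obs: int = 0


def measures_frame(records: Sequence[GazeRecord]) -> pd.DataFrame:
    """GazeRecords as a DataFrame with the measures-file columns."""
    return pd.DataFrame(
        {
            "subject": [r.subject for r in records],
            "sentence": [r.sentence for r in records],
            "word": [r.word for r in records],
            "fprt": [r.fprt_ms for r in records],
            "rpd": [r.rpd_ms for r in records],
            "tft": [r.tft_ms for r in records],
            "complexity": [r.complexity for r in records],
            "syllables": [r.syllables for r in records],
            "unigram": [r.unigram for r in records],
            "bigram": [r.bigram for r in records],
        }
    )


def scale_predictors(
    table: pd.DataFrame, columns: Sequence[str]
) -> pd.DataFrame:
    """Center each column on its mean and divide by its standard deviation.

    Idempotent up to floating error; a zero-variance column raises an error
    naming it.
    """
    out = table.copy()
    for col in columns:
        x = out[col].astype(float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"predictor {col!r} has zero variance; cannot scale")
        out[col] = (x - x.mean()) / sd
    return out


def prepare(
    measures: pd.DataFrame,
    predictors: pd.DataFrame,
    spec: ModelSpec,
) -> pd.DataFrame:
    """Join, filter and transform into a model-ready table.

    Inner-joins measures and predictors on (sentence, word) — the join loss
    and each filter count are recorded in ``DataFrame.attrs['filters']`` —
    then removes zero-ms rows for the chosen measure, log-transforms it into
    ``log_rt``, applies the retrieval exclusions when selected, and scales
    the predictors.
    """
    filters: dict[str, int] = {}
    dep = MEASURE_COLUMNS[spec.dependent]

    # the measures table is the canonical carrier of word-level predictors;
    # drop any duplicated non-key columns from the predictor side
    overlap = [
        c for c in predictors.columns
        if c in measures.columns and c not in ("sentence", "word")
    ]
    joined = measures.merge(
        predictors.drop(columns=overlap), on=["sentence", "word"], how="inner"
    )
    filters["join_loss"] = len(measures) - len(joined)

    if "failed" in joined.columns:
        bad = joined["failed"].astype(bool)
        filters["unparsable_sentences"] = int(bad.sum())
        joined = joined[~bad]

    nonzero = joined[dep] > 0
    filters["zero_measure"] = int((~nonzero).sum())
    joined = joined[nonzero].copy()

    if spec.retrieval_mode:
        if "retrieval_latency_ms" in joined.columns:
            has_ret = joined["retrieval_latency_ms"].fillna(0) > 0
            filters["zero_retrieval"] = int((~has_ret).sum())
            joined = joined[has_ret].copy()

    if joined.empty:
        raise ValueError(
            f"no data left after filtering ({filters}); cannot fit"
        )
    joined["log_rt"] = np.log(joined[dep].astype(float))
    joined = scale_predictors(joined, list(spec.predictors))
    joined.attrs["filters"] = filters
    return joined


# ---------------------------------------------------------------------------
# lme4 backend


_R_TEMPLATE = """
suppressMessages({library(lme4); library(jsonlite)})
args <- commandArgs(trailingOnly = TRUE)
d <- read.csv(args[1], stringsAsFactors = FALSE)
spec <- fromJSON(args[2], simplifyVector = FALSE)
formulas <- unlist(spec$formulas)
results <- list()
# replications share a design, so the previous solution's variance
# parameters are an excellent warm start for the next dataset
starts <- vector("list", length(formulas))
for (ds in unique(d$.dataset)) {
  sub <- d[d$.dataset == ds, ]
  sub$subject <- factor(sub$subject)
  sub$sentence <- factor(sub$sentence)
  fit <- NULL; used <- NA; msgs <- character(0); ok <- FALSE
  for (fi in seq_along(formulas)) {
    msgs <- character(0)
    m <- tryCatch(
      withCallingHandlers(
        lmer(as.formula(formulas[fi]), data = sub, REML = TRUE,
             start = starts[[fi]],
             control = lmerControl(calc.derivs = FALSE,
                                   optCtrl = list(xtol_abs = 1e-4,
                                                  ftol_abs = 1e-4))),
        warning = function(w) {
          msgs <<- c(msgs, conditionMessage(w)); invokeRestart("muffleWarning")
        }),
      error = function(e) { msgs <<- c(msgs, conditionMessage(e)); NULL })
    if (is.null(m)) next
    conv_fail <- any(grepl("failed to converge", msgs)) ||
      (!is.null(m@optinfo$conv$opt) && m@optinfo$conv$opt != 0)
    if (!conv_fail) {
      fit <- m; used <- fi; ok <- TRUE
      starts[[fi]] <- getME(m, "theta")
      break
    }
    if (is.null(fit)) { fit <- m; used <- fi }
  }
  if (is.null(fit)) {
    results[[as.character(ds)]] <- list(converged = FALSE, messages = msgs)
  } else {
    cf <- coef(summary(fit))
    results[[as.character(ds)]] <- list(
      converged = ok,
      formula_index = used,
      messages = msgs,
      terms = rownames(cf),
      estimate = unname(cf[, "Estimate"]),
      se = unname(cf[, "Std. Error"]),
      t = unname(cf[, "t value"])
    )
  }
}
cat(toJSON(results, digits = 12, auto_unbox = TRUE))
"""


def _formula_ladder(spec: ModelSpec) -> tuple[list[str], list[list[str]]]:
    """Full model first, then slope sets pruned in reverse predictor order."""
    fixed = " + ".join(spec.predictors) if spec.predictors else "1"
    slope_preds = list(spec.slope_predictors())
    ladder: list[str] = []
    pruned_sets: list[list[str]] = []
    for keep in range(len(slope_preds), -1, -1):
        kept = slope_preds[:keep]
        terms = [f"log_rt ~ {fixed}", "(1 | subject)", "(1 | sentence)"]
        for p in kept:
            terms.append(f"(0 + {p} | subject)")
            terms.append(f"(0 + {p} | sentence)")
        ladder.append(" + ".join(terms))
        pruned_sets.append(slope_preds[keep:])
    return ladder, pruned_sets


def fit_lmm_many(
    tables: Sequence[pd.DataFrame],
    spec: ModelSpec,
    backend: str = "lme4",
) -> list[LmmResult]:
    """Fit the same model specification on many prepared tables.

    The lme4 backend runs all fits in a single R process, which matters when
    simulation studies need dozens of replications.
    """
    if backend != "lme4":
        return [fit_lmm(t, spec, backend=backend) for t in tables]
    for t in tables:
        _check_table(t, spec)
    ladder, pruned_sets = _formula_ladder(spec)
    stacked = []
    for i, t in enumerate(tables):
        cols = ["log_rt", "subject", "sentence", *spec.predictors]
        sub = t[cols].copy()
        sub[".dataset"] = i
        stacked.append(sub)
    data = pd.concat(stacked, ignore_index=True)

    with tempfile.TemporaryDirectory(prefix="gazeparse_lmm_") as tmp:
        tmp = Path(tmp)
        data_path = tmp / "data.csv"
        spec_path = tmp / "spec.json"
        script_path = tmp / "fit.R"
        data.to_csv(data_path, index=False, float_format="%.8g")
        spec_path.write_text(json.dumps({"formulas": ladder}), encoding="utf-8")
        script_path.write_text(_R_TEMPLATE, encoding="utf-8")
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(script_path), str(data_path), str(spec_path)],
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0:
            raise RuntimeError(
                f"lme4 fitting failed (exit {proc.returncode}):\n{proc.stderr[-2000:]}"
            )
        payload = json.loads(proc.stdout)

    results: list[LmmResult] = []
    for i, t in enumerate(tables):
        entry = payload[str(i)]
        msgs = entry.get("messages", [])
        if isinstance(msgs, str):
            msgs = [msgs]
        if not entry.get("converged", False) and "terms" not in entry:
            raise ConvergenceError(
                f"dataset {i}: no mixed-model structure converged: {msgs}"
            )
        idx = entry["formula_index"] - 1
        terms = entry["terms"]
        if isinstance(terms, str):
            terms = [terms]
        coefs = pd.DataFrame(
            {
                "estimate": np.atleast_1d(entry["estimate"]).astype(float),
                "se": np.atleast_1d(entry["se"]).astype(float),
                "t": np.atleast_1d(entry["t"]).astype(float),
            },
            index=[term.replace("(Intercept)", "intercept") for term in terms],
        )
        coefs["significant"] = coefs["t"].abs() >= T_SIGNIFICANT
        results.append(
            LmmResult(
                coefficients=coefs,
                converged=bool(entry.get("converged", False)),
                formula=ladder[idx],
                pruned_slopes=pruned_sets[idx],
                messages=msgs,
                n_obs=len(t),
            )
        )
    return results


def _check_table(table: pd.DataFrame, spec: ModelSpec) -> None:
    for col in ("log_rt", "subject", "sentence", *spec.predictors):
        if col not in table.columns:
            raise ValueError(f"prepared table lacks column {col!r}")
    if table["subject"].nunique() < 2 or table["sentence"].nunique() < 2:
        raise ValueError("need at least 2 subjects and 2 items to fit an LMM")


def fit_lmm(
    table: pd.DataFrame, spec: ModelSpec, backend: str = "lme4"
) -> LmmResult:
    """Fit one crossed-random-effects model on a prepared table."""
    if backend == "lme4":
        return fit_lmm_many([table], spec, backend="lme4")[0]
    if backend == "statsmodels":
        return _fit_statsmodels(table, spec)
    raise ValueError(f"unknown backend {backend!r} (lme4|statsmodels)")


def _fit_statsmodels(table: pd.DataFrame, spec: ModelSpec) -> LmmResult:
    """Crossed random *intercepts* via statsmodels variance components.

    Cross-check backend: slower than lme4 and without random slopes, but an
    entirely independent implementation of the same model family.
    """
    import statsmodels.formula.api as smf

    _check_table(table, spec)
    if spec.slope_predictors():
        raise ValueError("the statsmodels backend fits random intercepts only")
    fixed = " + ".join(spec.predictors) if spec.predictors else "1"
    md = smf.mixedlm(
        f"log_rt ~ {fixed}",
        table,
        groups=np.ones(len(table)),
        vc_formula={"subject": "0 + C(subject)", "item": "0 + C(sentence)"},
        re_formula="0",
    )
    fit = md.fit(reml=True, method="lbfgs", maxiter=500)
    names = ["intercept" if n == "Intercept" else n for n in fit.fe_params.index]
    coefs = pd.DataFrame(
        {
            "estimate": fit.fe_params.values,
            "se": fit.bse_fe.values,
            "t": fit.fe_params.values / fit.bse_fe.values,
        },
        index=names,
    )
    coefs["significant"] = coefs["t"].abs() >= T_SIGNIFICANT
    return LmmResult(
        coefficients=coefs,
        converged=bool(fit.converged),
        formula=f"log_rt ~ {fixed} + (1|subject) + (1|sentence) [statsmodels]",
        n_obs=len(table),
    )


def predictor_correlations(
    table: pd.DataFrame, columns: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Pairwise Pearson correlations among predictors.

    Constant columns produce NaN entries (undefined correlation), flagged in
    ``attrs['constant_columns']``.
    """
    cols = list(columns) if columns is not None else DEFAULT_PREDICTORS
    if len(table) < 2:
        raise ValueError("need at least 2 rows for correlations")
    sub = table[cols].astype(float)
    corr = sub.corr(method="pearson")
    constant = [c for c in cols if sub[c].std(ddof=1) == 0]
    corr.attrs["constant_columns"] = constant
    return corr
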