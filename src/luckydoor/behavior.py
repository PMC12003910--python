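"""Behavioral statistics and group regression models.

Win-Stay is the headline metric: the proportion of wins on the rare-gain
(higher expected value) door that are followed by choosing that door again.
It is computed separately on the experimental block (where the doors differ
in expected value) and the baseline block (a control where they do not).
Gain frequency bias is the proportion of baseline-block trials on which the
frequent-gain (rare-loss) door was chosen.

Group models are linear regressions of a behavioral metric on group plus
demographic and mental-health covariates, fit by iteratively reweighted
least squares with a bisquare weight function to limit outlier influence;
continuous variables are z-scored so coefficients are standardized betas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .task_model import DeckLabel, TrialRecord

log = logging.getLogger(__name__)

#: Default model terms, matching the behavioral analysis covariate set.
DEFAULT_TERMS = ("group", "age", "gender", "ethnicity", "ses", "gad7", "phq9")

#: Conventional bisquare tuning constant (95% Gaussian efficiency).
BISQUARE_C = 4.685


def _validate_order(trials: Sequence[TrialRecord]) -> None:
    idx = [t.trial_index for t in trials]
    if idx != sorted(idx) or len(set(idx)) != len(idx):
        raise ValueError("trials must be ordered by trial_index without duplicates")


def win_stay(
    trials: Sequence[TrialRecord], target_deck: DeckLabel = "RareG"
) -> float | None:
    """Proportion of target-deck wins followed by staying with that deck.

    Numerator: trials t where choice(t) = target, outcome(t) > 0, and
    choice(t+1) = target. Denominator: trials t with a target-deck win and a
    following trial (final-trial wins are excluded; no follow-up exists).
    Returns None when the denominator is zero — no wins means the metric is
    undefined, not zero.
    """
    _validate_order(trials)
    num = den = 0
    for prev, nxt in zip(trials[:-1], trials[1:]):
        if prev.choice == target_deck and prev.is_win:
            den += 1
            if nxt.choice == target_deck:
                num += 1
    return num / den if den else None


def gain_frequency_bias(trials: Sequence[TrialRecord]) -> float:
    """Fraction of trials choosing the frequent-gain (RareL) door.

    Intended for the baseline block, where equal expected values isolate the
    bias toward frequent small gains.
    """
    if not trials:
        raise ValueError("empty trial list")
    _validate_order(trials)
    return sum(t.choice == "RareL" for t in trials) / len(trials)


def _records_from_frame(frame: pd.DataFrame) -> list[TrialRecord]:
    return [
        TrialRecord(int(r.trial), r.choice, int(r.outcome), int(r.cumulative))
        for r in frame.sort_values("trial").itertuples(index=False)
    ]


def compute_metrics(behavior: pd.DataFrame) -> pd.DataFrame:
    """Per-subject behavioral metrics from a tidy trial table.

    Expects columns (subject_id, block, trial, choice, outcome, cumulative)
    and returns one row per subject with win_stay_expt, win_stay_baseline
    (NaN where undefined) and gain_freq_bias (baseline-block RareL choice
    proportion).
    """
    rows = []
    for sid, sub in behavior.groupby("subject_id", sort=True):
        row: dict[str, object] = {"subject_id": sid}
        for block, col in (("experimental", "win_stay_expt"), ("baseline", "win_stay_baseline")):
            blk = sub[sub["block"] == block]
            if blk.empty:
                row[col] = np.nan
                continue
            ws = win_stay(_records_from_frame(blk))
            row[col] = np.nan if ws is None else ws
        base = sub[sub["block"] == "baseline"]
        row["gain_freq_bias"] = (
            gain_frequency_bias(_records_from_frame(base)) if not base.empty else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ModelResult:
    """Fitted model summary: per-term standardized effects plus model-level fit."""

    outcome: str
    terms: pd.DataFrame  # columns: term, beta, se, tstat, pvalue
    adj_r2: float
    fstat: float
    model_pvalue: float
    n_used: int
    n_dropped: int
    method: str = "robust-bisquare"

    def term(self, name: str) -> pd.Series:
        hit = self.terms[self.terms["term"] == name]
        if hit.empty:
            raise KeyError(f"no term {name!r}; have {list(self.terms['term'])}")
        return hit.iloc[0]

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "method": self.method,
            "adj_r2": float(self.adj_r2),
            "fstat": float(self.fstat),
            "model_pvalue": float(self.model_pvalue),
            "n_used": int(self.n_used),
            "n_dropped": int(self.n_dropped),
            "terms": self.terms.to_dict(orient="records"),
        }


_CATEGORICAL_REFERENCES = {
    "group": "non_exposed",
    "gender": "female",
    "ethnicity": "caucasian",
}


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    centered = x - x.mean()
    return centered / sd if sd > 0 else centered


def build_design(
    data: pd.DataFrame, terms: Sequence[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Design matrix with z-scored continuous terms and reference-coded
    categoricals (reference level dropped; named ``term[level]``)."""
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(data))}
    for term in terms:
        col = data[term]
        if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
            cols[term] = _zscore(col.to_numpy())
        else:
            levels = sorted(col.astype(str).unique())
            ref = _CATEGORICAL_REFERENCES.get(term)
            if ref in levels:
                levels.remove(ref)
                levels.insert(0, ref)
            for level in levels[1:]:
                cols[f"{term}[{level}]"] = (col.astype(str) == level).astype(float).to_numpy()
    X = pd.DataFrame(cols, index=data.index)
    return X, list(X.columns)


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify offending columns by incremental rank growth
        bad = []
        kept: list[int] = []
        for j in range(arr.shape[1]):
            trial = kept + [j]
            if np.linalg.matrix_rank(arr[:, trial]) == len(kept):
                bad.append(X.columns[j])
            else:
                kept.append(j)
        raise ValueError(f"rank-deficient design; collinear terms: {bad}")


def fit_group_model(
    metrics: pd.DataFrame,
    covariates: pd.DataFrame,
    outcome: str = "win_stay_expt",
    terms: Sequence[str] = DEFAULT_TERMS,
    robust: bool = True,
) -> ModelResult:
    """Regress a behavioral metric on group and covariates.

    The outcome and all continuous covariates are z-scored, so reported betas
    are standardized; categorical terms are reference-coded (reference group:
    non-exposed). The fit is iteratively reweighted least squares with
    bisquare weights (tuning constant 4.685); model-level adjusted R², F and
    p come from a weighted least-squares fit at the converged robust weights.
    Subjects with an undefined (NaN) outcome are dropped with a logged count.
    With ``robust=False`` an ordinary least-squares fit is returned.
    """
    data = metrics.merge(covariates, on="subject_id", validate="one_to_one")
    n_total = len(data)
    data = data.dropna(subset=[outcome, *terms])
    n_dropped = n_total - len(data)
    if n_dropped:
        log.warning("dropped %d subjects with undefined %s or covariates", n_dropped, outcome)
    if len(data) < 10:
        raise ValueError(f"need >= 10 complete cases, have {len(data)}")

    y = _zscore(data[outcome].to_numpy())
    X, _ = build_design(data, terms)
    result = robust_linear_fit(y, X, robust=robust)
    result.outcome = outcome
    result.n_dropped = n_dropped
    return result


def robust_linear_fit(
    y: np.ndarray, X: pd.DataFrame, robust: bool = True
) -> ModelResult:
    """IRLS fit with bisquare weights on a prepared design matrix.

    Per-term inference comes from the robust fit; model-level adjusted R², F
    and p come from a weighted least-squares fit at the converged robust
    weights. When the robust residual scale collapses (perfect fit) the
    routine falls back to ordinary least squares, which the IRLS solution
    equals when residuals vanish.
    """
    _check_rank(X)
    if robust:
        import warnings

        degenerate = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # zero-scale perfect fits fall back below
                fit = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=BISQUARE_C)).fit()
            degenerate = (
                not np.isfinite(fit.scale)
                or fit.scale < 1e-10
                or not np.all(np.isfinite(np.asarray(fit.bse)))
            )
        except Exception:
            degenerate = True
        if degenerate:
            fit = sm.OLS(y, X).fit()
            weights = np.ones(len(y))
            method = "ols-fallback"
        else:
            weights = np.asarray(fit.weights)
            method = "robust-bisquare"
    else:
        fit = sm.OLS(y, X).fit()
        weights = np.ones(len(y))
        method = "ols"

    terms_df = pd.DataFrame(
        {
            "term": X.columns,
            "beta": np.asarray(fit.params),
            "se": np.asarray(fit.bse),
            "tstat": np.asarray(fit.tvalues),
            "pvalue": np.asarray(fit.pvalues),
        }
    )
    wls = sm.WLS(y, X, weights=weights).fit()
    return ModelResult(
        outcome="y",
        terms=terms_df,
        adj_r2=float(wls.rsquared_adj),
        fstat=float(wls.fvalue),
        model_pvalue=float(wls.f_pvalue),
        n_used=len(y),
        n_dropped=0,
        method=method,
    )
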