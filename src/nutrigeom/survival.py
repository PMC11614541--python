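"""Proportional-hazards analysis of development and survival times.

Two Cox models are supported: time to adult eclosion (event = eclosion,
death treated as censoring at the death day) and survival time (event =
death).  Predictors are categorical P:C ratio and cellulose level with a
declared reference (3P:1C, low cellulose).  To let the cellulose effect vary
over early life, follow-up can be split into episodes at fixed cutpoints
(0-7, 7-14, 14-153 days) so cellulose gets one coefficient per interval.

Model selection follows an information-theoretic confidence-set procedure:
Akaike weights over the candidate set, retention at dAIC <= 4, then the
nesting rule (drop any retained model whose terms strictly contain those of a
retained model with lower AIC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

DEFAULT_CUTPOINTS = (7.0, 14.0, 153.0)
REF_PC = "3P:1C"
REF_CELLULOSE = "low"


def episode_split(
    subjects: pd.DataFrame, cutpoints: Sequence[float] = DEFAULT_CUTPOINTS
) -> pd.DataFrame:
    """Split each subject's follow-up into interval episodes.

    `subjects` columns: ``id, entry_day, exit_day, event`` plus any
    covariates.  Episodes are labelled by interval (e.g. ``"0-7"``); only the
    final episode carries the subject's event indicator.  Episode durations
    sum to the original follow-up.
    """
    cuts = list(cutpoints)
    if any(b <= a for a, b in zip(cuts, cuts[1:])):
        raise ValueError("cutpoints must be strictly increasing")
    if (subjects["exit_day"] > cuts[-1]).any():
        raise ValueError(f"exit_day beyond final cutpoint {cuts[-1]}")
    bounds = [0.0] + cuts
    labels = [f"{int(a)}-{int(b)}" for a, b in zip(bounds, bounds[1:])]
    rows = []
    covar_cols = [c for c in subjects.columns if c not in ("entry_day", "exit_day", "event")]
    for _, s in subjects.iterrows():
        entry, exit_, event = float(s["entry_day"]), float(s["exit_day"]), int(s["event"])
        if entry >= exit_:
            raise ValueError(f"subject {s.get('id')}: entry must precede exit")
        for (a, b), lab in zip(zip(bounds, bounds[1:]), labels):
            lo, hi = max(entry, a), min(exit_, b)
            if hi <= lo:
                continue
            last = hi == exit_
            row = {c: s[c] for c in covar_cols}
            row.update({"start": lo, "stop": hi, "event": event if last else 0,
                        "interval": lab})
            rows.append(row)
    return pd.DataFrame(rows)


def _design(df: pd.DataFrame, terms: Iterable[str],
            ref_pc: str = REF_PC, ref_cellulose: str = REF_CELLULOSE) -> pd.DataFrame:
    """Dummy-code categorical terms against their reference categories."""
    out = pd.DataFrame(index=df.index)
    terms = list(terms)
    if "pc" in terms:
        for lab in sorted(set(df["pc_label"]) - {ref_pc}):
            out[f"pc[{lab}]"] = (df["pc_label"] == lab).astype(float)
    if "cellulose" in terms:
        for lvl in [l for l in ("medium", "high", *sorted(set(df["cellulose_level"])))
                    if l != ref_cellulose]:
            col = f"cell[{lvl}]"
            if col not in out and (df["cellulose_level"] == lvl).any():
                out[col] = (df["cellulose_level"] == lvl).astype(float)
    if "pc:cellulose" in terms:
        for lab in sorted(set(df["pc_label"]) - {ref_pc}):
            for lvl in sorted(set(df["cellulose_level"]) - {ref_cellulose}):
                out[f"pc[{lab}]:cell[{lvl}]"] = (
                    (df["pc_label"] == lab) & (df["cellulose_level"] == lvl)
                ).astype(float)
    if "cellulose_by_interval" in terms:
        if "interval" not in df.columns:
            raise ValueError("cellulose_by_interval requires episode-split data "
                             "(run episode_split first)")
        for lab in sorted(set(df["interval"]), key=lambda s: float(s.split("-")[0])):
            for lvl in sorted(set(df["cellulose_level"]) - {ref_cellulose}):
                out[f"cell[{lvl}]@{lab}"] = (
                    (df["cellulose_level"] == lvl) & (df["interval"] == lab)
                ).astype(float)
    return out


class CoxModel(BaseEstimator):
    """Cox proportional-hazards fit with categorical diet terms.

    Parameters
    ----------
    terms : tuple of {"pc", "cellulose", "pc:cellulose", "cellulose_by_interval"}
        Predictor blocks.  ``cellulose_by_interval`` requires episode-split
        input and estimates one cellulose coefficient per time interval.
    ref_pc, ref_cellulose : str
        Reference categories (hazard ratio 1 by construction).

    Fitted attributes: ``params_`` (log hazard ratios), ``bse_``,
    ``hazard_ratios_``, ``log_likelihood_``, ``aic_``, ``k_``.
    Ties are handled with the Efron approximation.
    """

    def __init__(self, terms: tuple[str, ...] = ("pc", "cellulose"),
                 ref_pc: str = REF_PC, ref_cellulose: str = REF_CELLULOSE,
                 name: str | None = None):
        self.terms = terms
        self.ref_pc = ref_pc
        self.ref_cellulose = ref_cellulose
        self.name = name

    @property
    def term_set(self) -> frozenset:
        return frozenset(self.terms)

    def _prepare(self, df: pd.DataFrame) -> tuple[pd.DataFrame, bool]:
        episodic = "start" in df.columns and "stop" in df.columns
        X = _design(df, self.terms, self.ref_pc, self.ref_cellulose)
        dropped = [c for c in X.columns if X[c].nunique() <= 1]
        if dropped:
            warnings.warn(f"dropping constant term(s) {dropped} (rank deficiency)",
                          stacklevel=3)
            X = X.drop(columns=dropped)
        return X, episodic

    def fit(self, df: pd.DataFrame) -> "CoxModel":
        if int(df["event"].sum()) == 0:
            raise ValueError("no events in the data; the partial likelihood is empty")
        X, episodic = self._prepare(df)
        data = X.copy()
        data["event"] = df["event"].astype(int).values
        if episodic:
            data["id"] = df["id"].values
            data["start"] = df["start"].astype(float).values
            data["stop"] = df["stop"].astype(float).values
            fitter = CoxTimeVaryingFitter()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fitter.fit(data, id_col="id", event_col="event",
                           start_col="start", stop_col="stop")
        else:
            data["duration"] = (df["exit_day"] - df.get("entry_day", 0.0)).astype(float).values
            fitter = CoxPHFitter()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fitter.fit(data, duration_col="duration", event_col="event")
        self.fitter_ = fitter
        self.params_ = fitter.params_
        self.bse_ = fitter.standard_errors_
        self.hazard_ratios_ = np.exp(fitter.params_)
        self.log_likelihood_ = float(fitter.log_likelihood_)
        self.k_ = int(len(fitter.params_))
        self.aic_ = -2.0 * self.log_likelihood_ + 2.0 * self.k_
        self.n_ = int(df["id"].nunique() if "id" in df.columns else len(df))
        self.separation_flag_ = bool((self.bse_ > 10).any())
        if self.separation_flag_:
            warnings.warn("very large standard errors suggest separation "
                          "(a category with all-or-none events)", stacklevel=2)
        self._train_df = df
        return self

    def block_test(self, block: str) -> dict:
        """Likelihood-ratio chi-square for dropping one predictor block."""
        check_is_fitted(self, "params_")
        if block not in self.terms:
            raise ValueError(f"{block!r} is not a term of this model")
        reduced_terms = tuple(t for t in self.terms if t != block)
        full_ll, full_k = self.log_likelihood_, self.k_
        if reduced_terms:
            reduced = CoxModel(reduced_terms, self.ref_pc, self.ref_cellulose)
            reduced.fit(self._train_df)
            chi2 = 2.0 * (full_ll - reduced.log_likelihood_)
            dof = full_k - reduced.k_
        else:
            lrt = self.fitter_.log_likelihood_ratio_test()
            chi2, dof = float(lrt.test_statistic), full_k
        from scipy.stats import chi2 as chi2_dist
        return {"block": block, "chi2": chi2, "df": dof,
                "p": float(chi2_dist.sf(chi2, dof))}

    def summary(self) -> pd.DataFrame:
        check_is_fitted(self, "params_")
        return pd.DataFrame({
            "coef": self.params_, "se": self.bse_,
            "hazard_ratio": self.hazard_ratios_,
        })


def fit_cox(df: pd.DataFrame, terms: tuple[str, ...],
            ref_pc: str = REF_PC, ref_cellulose: str = REF_CELLULOSE) -> CoxModel:
    """Convenience wrapper: construct and fit a :class:`CoxModel`."""
    return CoxModel(terms=terms, ref_pc=ref_pc, ref_cellulose=ref_cellulose).fit(df)


@dataclass(frozen=True)
class HazardPercent:
    """A hazard ratio expressed the way results sections phrase it."""

    percent: float
    direction: str  # "less likely" | "higher risk" | "no difference"


def hr_to_percent(hr: float) -> HazardPercent:
    """Express a hazard ratio as a percent change statement.

    hr < 1 -> (1 - hr) x 100 "less likely"; hr > 1 -> (hr - 1) x 100
    "higher risk"; hr = 1 -> 0.
    """
    if hr <= 0:
        raise ValueError("hazard ratio must be positive")
    if hr < 1:
        return HazardPercent((1.0 - hr) * 100.0, "less likely")
    if hr > 1:
        return HazardPercent((hr - 1.0) * 100.0, "higher risk")
    return HazardPercent(0.0, "no difference")


@dataclass
class ConfidenceSet:
    """AIC confidence set over candidate models."""

    table: pd.DataFrame  # name, aic, k, delta_aic, weight, in_delta_set, retained
    retained: list[str]
    best: str


def aic_confidence_set(
    candidates: Sequence[CoxModel] | Sequence[dict], delta_max: float = 4.0
) -> ConfidenceSet:
    """Akaike weights, dAIC <= ``delta_max`` retention, then the nesting rule.

    Candidates may be fitted models (anything exposing ``aic_``, ``term_set``
    and optionally ``name``) or dicts with keys ``name, aic, terms``.
    Weights are normalized over the full candidate list; a retained model is
    dropped if its term set strictly contains that of another retained model
    with a lower AIC.
    """
    if len(candidates) == 0:
        raise ValueError("empty candidate list")
    rows = []
    for i, cand in enumerate(candidates):
        if isinstance(cand, dict):
            rows.append({"name": cand.get("name", f"m{i}"), "aic": float(cand["aic"]),
                         "terms": frozenset(cand["terms"]),
                         "k": cand.get("k", len(cand["terms"]))})
        else:
            rows.append({"name": cand.name or f"m{i}", "aic": float(cand.aic_),
                         "terms": cand.term_set, "k": cand.k_})
    tab = pd.DataFrame(rows)
    tab["delta_aic"] = tab["aic"] - tab["aic"].min()
    w = np.exp(-tab["delta_aic"] / 2.0)
    tab["weight"] = w / w.sum()
    tab["in_delta_set"] = tab["delta_aic"] <= delta_max
    pool = tab.index[tab["in_delta_set"]]
    retained_mask = tab["in_delta_set"].copy()
    for i in pool:
        for j in pool:
            if (tab.loc[j, "aic"] < tab.loc[i, "aic"]
                    and tab.loc[j, "terms"] < tab.loc[i, "terms"]):
                retained_mask.loc[i] = False
                break
    tab["retained"] = retained_mask
    tab = tab.sort_values("aic").reset_index(drop=True)
    retained = tab.loc[tab["retained"], "name"].tolist()
    return ConfidenceSet(table=tab, retained=retained, best=tab.loc[0, "name"])
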