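"""Propensity-score estimation, 1:1 nearest-neighbor matching and IPW.

The propensity score is the fitted probability of natalizumab (vs
fingolimod) from a logistic regression on six baseline covariates: age at
first MS claim, sex, region, time from first MS claim to first treatment,
first-line drug and time in first line.  Matching is greedy 1:1 nearest
neighbor without replacement over treated patients in seeded random
order, with a caliper of 0.1 on the raw PS scale (boundary inclusive).
IPW default is standard inverse-probability-of-treatment weighting (1/ps
for treated, 1/(1-ps) for controls, the ATE weight); a paper-literal mode
weighting everyone by 1/ps is kept for fidelity experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .common import ConfigError, get_logger
from .cohorts import CATEGORICAL_COVARIATES, CONTINUOUS_COVARIATES

log = get_logger(__name__)

PS_CLIP = 1e-6
DEFAULT_CALIPER = 0.1


@dataclass
class MatchedCohort:
    pairs: pd.DataFrame            # treated_id, control_id, ps_diff
    unmatched_treated: list = field(default_factory=list)
    unmatched_controls: list = field(default_factory=list)

    @property
    def patient_ids(self) -> np.ndarray:
        return np.concatenate([self.pairs["treated_id"].to_numpy(),
                               self.pairs["control_id"].to_numpy()])


def design_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """One-hot design with fixed (alphabetically first) reference levels.

    Zero-variance covariate columns are dropped (they are collinear with
    the intercept and would make the likelihood singular).
    """
    X = records[list(CONTINUOUS_COVARIATES)].astype(float).copy()
    for covar in CATEGORICAL_COVARIATES:
        levels = sorted(records[covar].astype(str).unique())
        for lv in levels[1:]:  # first level is the reference
            X[f"{covar}[{lv}]"] = (records[covar].astype(str) == lv).astype(float)
    X = X.loc[:, X.nunique() > 1]
    X.insert(0, "const", 1.0)
    return X


def fit_propensity(records: pd.DataFrame, treatment_col: str = "treatment",
                   penalized: bool = False) -> tuple[pd.DataFrame, dict]:
    """Fit the PS model and fill the ``ps`` column.

    ``records`` must contain the six covariates and a binary treatment
    column (1 = natalizumab).  Missing covariate values are an error
    listing the offending patients.  Fitted probabilities are clipped to
    (0, 1) at 1e-6.  On perfect separation the error suggests the
    penalized (ridge) fallback, available via ``penalized=True``.
    """
    cols = list(CONTINUOUS_COVARIATES) + list(CATEGORICAL_COVARIATES)
    missing = records[cols].isna().any(axis=1)
    if missing.any():
        ids = records.loc[missing, "patient_id"].tolist() if "patient_id" in records else \
            records.index[missing].tolist()
        raise ValueError(f"missing covariates for patients: {ids[:20]}"
                         + (" ..." if len(ids) > 20 else ""))
    y = records[treatment_col].astype(int).to_numpy()
    if len(np.unique(y)) < 2 or min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("need at least 2 patients in each treatment arm")
    X = design_matrix(records)

    if penalized:
        lr = LogisticRegression(penalty="l2", C=1e2, max_iter=2000)
        lr.fit(X.drop(columns="const"), y)
        ps = lr.predict_proba(X.drop(columns="const"))[:, 1]
        params = dict(zip(["const"] + list(X.columns[1:]),
                          np.concatenate([lr.intercept_, lr.coef_[0]])))
    else:
        import warnings

        try:
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, X).fit(disp=0, maxiter=500)
        except Exception as exc:  # PerfectSeparationError and kin
            raise ValueError(
                "propensity model failed (possible perfect separation); "
                "retry with penalized=True") from exc
        if not np.all(np.isfinite(res.params)):
            raise ValueError("propensity model diverged (possible perfect "
                             "separation); retry with penalized=True")
        ps = np.asarray(res.predict(X))
        params = dict(zip(X.columns, res.params))
    out = records.copy()
    out["ps"] = np.clip(ps, PS_CLIP, 1 - PS_CLIP)
    log.info("propensity model coefficients: %s",
             {k: round(v, 4) for k, v in params.items()})
    return out, params


def match_nearest(records: pd.DataFrame, caliper: float | None = DEFAULT_CALIPER,
                  seed: int = 0, treatment_col: str = "treatment",
                  id_col: str = "patient_id") -> MatchedCohort:
    """Greedy 1:1 nearest-neighbor matching without replacement.

    Treated patients are visited in seeded random order; each takes the
    unused control nearest in PS within the caliper (|delta ps| <=
    caliper, boundary inclusive; ``caliper=None`` disables it).  Ties are
    broken by stable control order.  Returns pairs and the unmatched
    patients of both arms; matching no one is a warning, not an error.
    """
    if records.empty or records[treatment_col].nunique() < 2:
        raise ConfigError("matching requires patients in both arms")
    treated = records[records[treatment_col] == 1]
    controls = records[records[treatment_col] == 0]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(treated))
    ctrl_ids = controls[id_col].to_numpy()
    ctrl_ps = controls["ps"].to_numpy()
    used = np.zeros(len(controls), dtype=bool)
    pairs = []
    for i in order:
        t_id = treated[id_col].iloc[i]
        t_ps = treated["ps"].iloc[i]
        d = np.abs(ctrl_ps - t_ps)
        d[used] = np.inf
        if caliper is not None:
            d[d > caliper + 1e-12] = np.inf
        j = int(np.argmin(d))  # argmin takes the first minimum: stable ties
        if not np.isfinite(d[j]):
            continue
        used[j] = True
        pairs.append((t_id, ctrl_ids[j], float(d[j])))
    pairs_df = pd.DataFrame(pairs, columns=["treated_id", "control_id", "ps_diff"])
    if not len(pairs_df):
        log.warning("no matched pairs within caliper %s", caliper)
    unmatched_t = [x for x in treated[id_col] if x not in set(pairs_df.get("treated_id", []))]
    unmatched_c = list(ctrl_ids[~used])
    return MatchedCohort(pairs=pairs_df, unmatched_treated=unmatched_t,
                         unmatched_controls=unmatched_c)


def compute_ipw(records: pd.DataFrame, mode: str = "standard",
                stabilized: bool = False,
                truncate_percentile: float | None = 99.0,
                treatment_col: str = "treatment") -> pd.DataFrame:
    """Fill the ``weight`` column from the fitted PS.

    mode "standard": 1/ps for treated, 1/(1-ps) for controls (ATE);
    mode "paper_literal": 1/ps for everyone.  Optionally stabilized by
    arm prevalence and truncated at a weight percentile (per arm pooled).
    """
    out = records.copy()
    t = out[treatment_col].astype(int).to_numpy()
    ps = out["ps"].to_numpy()
    if mode == "standard":
        w = np.where(t == 1, 1.0 / ps, 1.0 / (1.0 - ps))
    elif mode == "paper_literal":
        w = 1.0 / ps
    else:
        raise ConfigError(f"unknown IPW mode '{mode}'")
    if stabilized:
        prev = t.mean()
        w = np.where(t == 1, prev * w, (1 - prev) * w)
    if truncate_percentile is not None:
        cap = np.percentile(w, truncate_percentile)
        n_cap = int((w > cap).sum())
        if n_cap:
            log.info("truncating %d weights at the %.0fth percentile (%.3f)",
                     n_cap, truncate_percentile, cap)
        w = np.minimum(w, cap)
    out["weight"] = w
    return out


def standardized_mean_difference(x: np.ndarray, treated: np.ndarray,
                                 weights: np.ndarray | None = None) -> float:
    """|mean_t - mean_c| / sqrt((var_t + var_c)/2), weighted if given."""
    if weights is None:
        weights = np.ones(len(x))
    xt, wt = x[treated == 1], weights[treated == 1]
    xc, wc = x[treated == 0], weights[treated == 0]
    mt = np.average(xt, weights=wt)
    mc = np.average(xc, weights=wc)
    vt = np.average((xt - mt) ** 2, weights=wt)
    vc = np.average((xc - mc) ** 2, weights=wc)
    pooled = np.sqrt((vt + vc) / 2.0)
    if pooled == 0:
        return 0.0
    return float(abs(mt - mc) / pooled)


def balance_report(records: pd.DataFrame,
                   matched: MatchedCohort | None = None,
                   weighted: pd.DataFrame | None = None,
                   treatment_col: str = "treatment",
                   id_col: str = "patient_id") -> pd.DataFrame:
    """Pre/post-adjustment SMD per covariate (categoricals per level).

    Post-adjustment uses the matched subsample or the IPW weights,
    whichever is supplied; the SMD formula is identical pre and post.
    """
    def expand(df: pd.DataFrame) -> pd.DataFrame:
        cols = {c: df[c].astype(float).to_numpy() for c in CONTINUOUS_COVARIATES}
        for covar in CATEGORICAL_COVARIATES:
            for lv in sorted(records[covar].astype(str).unique()):
                cols[f"{covar}[{lv}]"] = (df[covar].astype(str) == lv).astype(float).to_numpy()
        return pd.DataFrame(cols, index=df.index)

    pre_X = expand(records)
    t_pre = records[treatment_col].astype(int).to_numpy()
    rows = []
    post_df, post_w = None, None
    if matched is not None and len(matched.pairs):
        post_df = records[records[id_col].isin(matched.patient_ids)]
        post_w = np.ones(len(post_df))
    elif weighted is not None:
        post_df = weighted
        post_w = weighted["weight"].to_numpy()
    post_X = expand(post_df) if post_df is not None else None
    t_post = (post_df[treatment_col].astype(int).to_numpy()
              if post_df is not None else None)
    for col in pre_X.columns:
        entry = {"covariate": col,
                 "smd_pre": standardized_mean_difference(
                     pre_X[col].to_numpy(), t_pre)}
        if post_X is not None:
            entry["smd_post"] = standardized_mean_difference(
                post_X[col].to_numpy(), t_post, post_w)
        else:
            entry["smd_post"] = np.nan
        # two-sample test on the (possibly adjusted) covariate, for tables
        entry["p_pre"] = _two_sample_p(pre_X[col].to_numpy(), t_pre)
        rows.append(entry)
    return pd.DataFrame(rows)


def _two_sample_p(x: np.ndarray, t: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return 1.0
    return float(stats.ttest_ind(x[t == 1], x[t == 0], equal_var=False).pvalue)
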