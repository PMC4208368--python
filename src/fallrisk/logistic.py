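"""Binary logistic regression of fall status on component scores.

The model is ``P(fall=1 | C) = 1 / (1 + exp(-(b0 + sum_i b_i C_i)))``, fit by
maximum likelihood (Newton/IRLS via statsmodels), with Wald coefficient
diagnostics, Nagelkerke R², a decile Hosmer–Lemeshow goodness-of-fit test,
p < 0.1 predictor selection and probability/class prediction. Classification
is in-sample (retrospective design); reports flag it as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as spstats

__all__ = [
    "LogisticModel",
    "fit_logistic",
    "wald_table",
    "nagelkerke_r2",
    "hosmer_lemeshow",
    "select_components",
    "predict",
]


@dataclass
class LogisticModel:
    predictors: list[str]
    beta: pd.Series  # includes "constant"
    se: pd.Series
    ll1: float  # fitted log-likelihood
    ll0: float  # null (intercept-only) log-likelihood
    n: int
    converged: bool
    separation_flag: bool = False
    labels: dict[str, str] = field(default_factory=dict)  # predictor -> label

    def to_dict(self) -> dict:
        tab = wald_table(self)
        return {
            "predictors": self.predictors,
            "labels": self.labels,
            "coefficients": {
                row.Index: dict(
                    beta=row.beta, se=row.se, wald=row.wald, p=row.p,
                    exp_beta=row.exp_beta,
                )
                for row in tab.itertuples()
            },
            "ll1": self.ll1,
            "ll0": self.ll0,
            "n": self.n,
            "converged": self.converged,
            "separation_flag": self.separation_flag,
            "nagelkerke_r2": nagelkerke_r2(self),
        }


def fit_logistic(scores: pd.DataFrame, labels: pd.Series | np.ndarray) -> LogisticModel:
    """Maximum-likelihood logistic fit of binary labels on score columns.

    Standard errors come from the inverse observed information. (Quasi-)
    separation is flagged on the result rather than silently accepted.
    """
    y = np.asarray(labels, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    x = scores.to_numpy(dtype=float)
    n, k = x.shape
    if n <= k + 1:
        raise ValueError(f"need n > n_predictors + 1 (n={n}, k={k})")
    exog = sm.add_constant(x, prepend=False)
    model = sm.Logit(y, exog)
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        try:
            res = model.fit(disp=0, maxiter=100, tol=1e-10)
        except Exception:
            separation = True
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(disp=0, method="bfgs", maxiter=500)
    if np.any(np.abs(res.params[:-1]) > 25):
        separation = True
    if separation:
        warnings.warn("possible (quasi-)separation: coefficient estimates diverge")
    names = list(scores.columns) + ["constant"]
    return LogisticModel(
        predictors=list(scores.columns),
        beta=pd.Series(res.params, index=names),
        se=pd.Series(res.bse, index=names),
        ll1=float(res.llf),
        ll0=float(res.llnull),
        n=n,
        converged=bool(res.mle_retvals.get("converged", True)),
        separation_flag=separation,
    )


def wald_table(model: LogisticModel) -> pd.DataFrame:
    """Coefficient table: beta, s.e., Wald = (beta/s.e.)^2, p (chi² df=1),
    exp(beta)."""
    wald = (model.beta / model.se) ** 2
    p = spstats.chi2.sf(wald, df=1)
    return pd.DataFrame(
        {
            "beta": model.beta,
            "se": model.se,
            "wald": wald,
            "p": pd.Series(p, index=model.beta.index),
            "exp_beta": np.exp(model.beta),
        }
    )


def nagelkerke_r2(model: LogisticModel) -> float:
    """Nagelkerke pseudo-R²: Cox–Snell normalized to a unit maximum."""
    n = model.n
    r2_cs = 1.0 - np.exp(2.0 * (model.ll0 - model.ll1) / n)
    denom = 1.0 - np.exp(2.0 * model.ll0 / n)
    return float(r2_cs / denom) if denom > 0 else 0.0


def hosmer_lemeshow(
    probabilities: np.ndarray,
    observed: np.ndarray,
    groups: int = 10,
) -> dict:
    """Decile-of-risk Hosmer–Lemeshow goodness-of-fit test.

    Subjects are sorted by predicted probability and split into ``groups``
    near-equal bins (ties kept together); the statistic sums
    (observed - expected)^2 / expected over bins and both outcome classes.
    Bins whose expected count in either class is zero are merged with a
    neighbour (df reduced accordingly, with a warning).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(observed, dtype=float)
    n = p.size
    if n < 2 * groups:
        raise ValueError(f"need at least {2 * groups} observations for {groups} groups")
    order = np.argsort(p, kind="stable")
    p, y = p[order], y[order]
    edges = [int(round(i * n / groups)) for i in range(groups + 1)]
    bins = []
    for a, b in zip(edges[:-1], edges[1:]):
        if a == b:
            continue
        # keep ties together: extend the bin while the boundary value repeats
        while b < n and b > a and p[b] == p[b - 1]:
            b += 1
        if bins and bins[-1][1] > a:
            a = bins[-1][1]
        if b > a:
            bins.append((a, b))
    rows = []
    for a, b in bins:
        rows.append(
            dict(
                n=b - a,
                observed=float(y[a:b].sum()),
                expected=float(p[a:b].sum()),
            )
        )
    # merge bins with a zero expected count in either class
    merged: list[dict] = []
    did_merge = False
    for row in rows:
        exp0 = row["n"] - row["expected"]
        if merged and (row["expected"] <= 0 or exp0 <= 0):
            did_merge = True
            top = merged[-1]
            top["n"] += row["n"]
            top["observed"] += row["observed"]
            top["expected"] += row["expected"]
        else:
            merged.append(dict(row))
    if did_merge:
        warnings.warn("Hosmer–Lemeshow: merged bins with zero expected counts")
    g = len(merged)
    chi2 = 0.0
    for row in merged:
        e1 = row["expected"]
        e0 = row["n"] - e1
        o1 = row["observed"]
        o0 = row["n"] - o1
        chi2 += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
    df = max(g - 2, 1)
    return {
        "chi2": float(chi2),
        "df": int(df),
        "p": float(spstats.chi2.sf(chi2, df)),
        "table": merged,
    }


def select_components(
    model: LogisticModel, scores: pd.DataFrame, labels, alpha: float = 0.1
) -> LogisticModel:
    """Retain predictors with Wald p < ``alpha`` and refit on that subset.

    Returns the refit model (intercept-only, with a warning, when nothing
    survives selection)."""
    tab = wald_table(model).drop(index="constant")
    keep = list(tab.index[tab["p"] < alpha])
    if not keep:
        warnings.warn("no predictors below the selection alpha; intercept-only model")
        empty = pd.DataFrame(index=scores.index)
        y = np.asarray(labels, dtype=float)
        b0 = float(np.log(y.mean() / (1 - y.mean()))) if 0 < y.mean() < 1 else 0.0
        ll0 = float(np.sum(y * np.log(y.mean()) + (1 - y) * np.log(1 - y.mean())))
        return LogisticModel(
            predictors=[],
            beta=pd.Series({"constant": b0}),
            se=pd.Series({"constant": float("nan")}),
            ll1=ll0,
            ll0=ll0,
            n=len(y),
            converged=True,
        )
    reduced = fit_logistic(scores[keep], labels)
    reduced.labels = {k: v for k, v in model.labels.items() if k in keep}
    return reduced


def predict(
    model: LogisticModel, scores: pd.DataFrame, threshold: float = 0.5
) -> tuple[pd.Series, pd.Series]:
    """Predicted fall probability and class (1 iff p >= threshold)."""
    missing = [c for c in model.predictors if c not in scores.columns]
    if missing:
        raise ValueError(f"missing predictor columns: {missing}")
    eta = np.full(len(scores), model.beta["constant"], dtype=float)
    for c in model.predictors:
        eta += model.beta[c] * scores[c].to_numpy(dtype=float)
    prob = 1.0 / (1.0 + np.exp(-eta))
    cls = (prob >= threshold).astype(int)
    return (
        pd.Series(prob, index=scores.index, name="probability"),
        pd.Series(cls, index=scores.index, name="predicted"),
    )
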