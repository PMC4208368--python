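"""Iterative factor reduction of the feature table.

The procedure standardizes all measures to Z-scores (missing values imputed
with the sample mean, i.e. zero), then repeats until stable:

1. compute per-measure sampling adequacy (MSA) and drop measures below 0.5
   (skipped while the correlation matrix is rank-deficient, see
   :func:`iterative_reduce`);
2. eigendecompose the correlation matrix, retain components with eigenvalue
   strictly greater than one (Kaiser criterion), rotate the retained loading
   block with normalized VARIMAX;
3. drop measures exhibiting complex structure — an absolute rotated loading
   above 0.4 on two or more components.

The final solution carries rotated loadings, communalities, variance
explained per component, the overall KMO and per-measure MSA, regression
component-score weights and a full iteration log.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ZTable",
    "FactorSolution",
    "standardize",
    "msa_kmo",
    "varimax",
    "extract_rotate",
    "complex_structure",
    "iterative_reduce",
    "component_scores",
]


@dataclass
class ZTable:
    """Standardized feature table plus its imputation mask."""

    values: pd.DataFrame  # subjects x measures, imputed (0 where missing)
    mask: pd.DataFrame  # True where the original value was missing

    @property
    def measures(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, keep: list[str]) -> "ZTable":
        return ZTable(values=self.values[keep], mask=self.mask[keep])


def standardize(table: pd.DataFrame) -> ZTable:
    """Z-score each column over its observed values; missing -> 0 (the mean).

    Constant columns (zero variance over observed entries) are rejected by
    name; columns need at least two observed values.
    """
    mask = table.isna()
    n_obs = (~mask).sum(axis=0)
    too_few = list(table.columns[n_obs < 2])
    if too_few:
        raise ValueError(f"measures with <2 observed values: {too_few}")
    means = table.mean(axis=0, skipna=True)
    sds = table.std(axis=0, ddof=1, skipna=True)
    constant = list(table.columns[sds <= 0])
    if constant:
        raise ValueError(f"constant measures cannot be standardized: {constant}")
    z = (table - means) / sds
    return ZTable(values=z.fillna(0.0), mask=mask)


def _correlation(z: ZTable) -> np.ndarray:
    """Correlation matrix of the imputed Z-table (imputed zeros included)."""
    x = z.values.to_numpy()
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(x, rowvar=False)
    return np.atleast_2d(r)


def _inverse_with_ridge(r: np.ndarray) -> tuple[np.ndarray, bool]:
    p = r.shape[0]
    try:
        cond = np.linalg.cond(r)
        if cond < 1e10:
            return np.linalg.inv(r), False
    except np.linalg.LinAlgError:
        pass
    lam = 1e-8 * np.trace(r) / p
    warnings.warn(
        f"correlation matrix singular/ill-conditioned; using ridge-"
        f"regularized inverse (lambda={lam:.3e})"
    )
    return np.linalg.inv(r + lam * np.eye(p)), True


def msa_kmo(z: ZTable | np.ndarray) -> tuple[pd.Series, float]:
    """Per-measure sampling adequacy and the overall KMO statistic.

    From the correlation matrix R and the anti-image partial correlations Q
    (off-diagonal elements of the scaled inverse, negated):
    ``MSA_j = sum_{i!=j} R_ij^2 / (sum R_ij^2 + sum Q_ij^2)`` and KMO is the
    same ratio over all pairs. Values below 0.5 mark measures sharing too
    little common variance for factoring.
    """
    if isinstance(z, ZTable):
        r = _correlation(z)
        names = z.measures
    else:
        r = np.asarray(z, dtype=float)
        names = [f"v{i}" for i in range(r.shape[0])]
    rinv, _ = _inverse_with_ridge(r)
    d = 1.0 / np.sqrt(np.diag(rinv))
    q = -rinv * np.outer(d, d)  # anti-image (partial) correlations
    np.fill_diagonal(q, 0.0)
    r_off = r - np.diag(np.diag(r))
    r2 = r_off**2
    q2 = q**2
    msa = r2.sum(axis=0) / (r2.sum(axis=0) + q2.sum(axis=0))
    kmo = r2.sum() / (r2.sum() + q2.sum())
    return pd.Series(msa, index=names, name="MSA"), float(kmo)


# ---------------------------------------------------------------------------
# VARIMAX


def varimax_criterion(lam: np.ndarray) -> float:
    """Raw VARIMAX criterion: summed column variances of squared loadings."""
    sq = lam**2
    p = lam.shape[0]
    return float(np.sum(sq**2) / p - np.sum((sq.sum(axis=0) / p) ** 2))


def varimax(
    loadings: np.ndarray,
    normalize: bool = True,
    tol: float = 1e-10,
    max_sweeps: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized (Kaiser-weighted) VARIMAX rotation by pairwise sweeps.

    Each planar rotation maximizes the criterion for its column pair in
    closed form, so the criterion is non-decreasing throughout. Returns the
    rotated loadings and the orthogonal rotation matrix.
    """
    lam = np.array(loadings, dtype=float)
    p, k = lam.shape
    rot = np.eye(k)
    if k < 2:
        return lam, rot
    if normalize:
        h = np.sqrt(np.sum(lam**2, axis=1))
        h = np.where(h > 0, h, 1.0)
        lam = lam / h[:, None]
    for _ in range(max_sweeps):
        before = varimax_criterion(lam)
        for a in range(k - 1):
            for b in range(a + 1, k):
                x, y = lam[:, a], lam[:, b]
                u = x**2 - y**2
                v = 2 * x * y
                num = 2 * (np.sum(u * v) - np.sum(u) * np.sum(v) / p)
                den = np.sum(u**2 - v**2) - (np.sum(u) ** 2 - np.sum(v) ** 2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-14:
                    continue
                c, s2 = np.cos(phi), np.sin(phi)
                g = np.array([[c, -s2], [s2, c]])
                lam[:, [a, b]] = lam[:, [a, b]] @ g
                rot[:, [a, b]] = rot[:, [a, b]] @ g
        if varimax_criterion(lam) - before < tol:
            break
    if normalize:
        lam = lam * h[:, None]
    return lam, rot


# ---------------------------------------------------------------------------
# extraction


@dataclass
class FactorSolution:
    measures: list[str]
    eigenvalues: np.ndarray  # retained pre-rotation eigenvalues
    loadings: pd.DataFrame  # measures x components, rotated
    communalities: pd.Series
    variance_explained: np.ndarray  # percent, per component (post-rotation)
    kmo: float = float("nan")
    msa: pd.Series | None = None
    score_weights: pd.DataFrame | None = None
    component_labels: list[str] = field(default_factory=list)
    iteration_log: list[dict] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def to_dict(self) -> dict:
        return {
            "measures": self.measures,
            "eigenvalues": [float(v) for v in self.eigenvalues],
            "components": list(self.loadings.columns),
            "component_labels": self.component_labels,
            "loadings": {
                c: [float(v) for v in self.loadings[c]] for c in self.loadings
            },
            "communalities": {k: float(v) for k, v in self.communalities.items()},
            "variance_explained_pct": [float(v) for v in self.variance_explained],
            "kmo": float(self.kmo),
            "msa": (
                {k: float(v) for k, v in self.msa.items()}
                if self.msa is not None
                else {}
            ),
            "score_weights": (
                {c: [float(v) for v in self.score_weights[c]] for c in self.score_weights}
                if self.score_weights is not None
                else None
            ),
            "iteration_log": self.iteration_log,
        }


def extract_rotate(z: ZTable, kaiser: float = 1.0) -> FactorSolution:
    """One extraction pass: eigendecomposition of the correlation matrix,
    Kaiser retention (eigenvalue strictly greater than ``kaiser``), normalized
    VARIMAX on the retained loading block.

    Sign convention: each rotated component's largest-magnitude loading is
    positive. Components are ordered by post-rotation variance explained,
    descending.
    """
    names = z.measures
    if len(names) < 2:
        raise ValueError("extraction requires at least 2 measures")
    r = _correlation(z)
    evals, evecs = np.linalg.eigh(r)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > kaiser
    if not keep.any():
        raise ValueError("no retainable components (all eigenvalues <= 1)")
    lam_unrot = evecs[:, keep] * np.sqrt(evals[keep])
    lam, _ = varimax(lam_unrot)
    # order by variance explained, fix signs
    var = np.sum(lam**2, axis=0)
    order = np.argsort(var)[::-1]
    lam = lam[:, order]
    var = var[order]
    for j in range(lam.shape[1]):
        if lam[np.argmax(np.abs(lam[:, j])), j] < 0:
            lam[:, j] = -lam[:, j]
    cols = [f"C{j + 1}" for j in range(lam.shape[1])]
    loadings = pd.DataFrame(lam, index=names, columns=cols)
    communalities = pd.Series(np.sum(lam**2, axis=1), index=names, name="communality")
    return FactorSolution(
        measures=list(names),
        eigenvalues=evals[keep],
        loadings=loadings,
        communalities=communalities,
        variance_explained=100.0 * var / len(names),
    )


def complex_structure(
    sol: FactorSolution, threshold: float = 0.4
) -> pd.DataFrame:
    """Measures loaded above ``threshold`` (absolute) by two or more
    components, with their loading rows."""
    hits = (sol.loadings.abs() > threshold).sum(axis=1) >= 2
    return sol.loadings.loc[hits]


def iterative_reduce(
    z: ZTable,
    msa_threshold: float = 0.5,
    loading_threshold: float = 0.4,
    kaiser: float = 1.0,
    max_iterations: int = 50,
) -> FactorSolution:
    """The full iterative pruning loop.

    Each iteration drops all measures with MSA below ``msa_threshold``, then
    re-extracts/rotates and drops all complex-structure measures; the loop
    ends at the first iteration that drops nothing. MSA pruning is suspended
    while the measure count approaches or exceeds the subject count (as in an
    80 x 92 starting table): the sample correlation matrix is then singular
    or near-singular and its anti-image partials are sampling artifacts that
    would flag almost every measure. Kaiser retention and complex-structure
    pruning shrink the measure set until MSA is well-posed (p <= 0.6 n).
    """
    current = z
    log: list[dict] = []
    n = z.values.shape[0]
    msa_max_p = int(0.6 * n)
    for it in range(1, max_iterations + 1):
        entry: dict = {"iteration": it, "n_measures": len(current.measures)}
        dropped_msa: list[str] = []
        if len(current.measures) <= msa_max_p:
            msa, kmo = msa_kmo(current)
            entry["kmo"] = float(kmo)
            dropped_msa = list(msa.index[msa < msa_threshold])
            if dropped_msa:
                keep = [m for m in current.measures if m not in dropped_msa]
                if len(keep) < 2:
                    raise ValueError("MSA pruning removed nearly all measures")
                current = current.subset(keep)
        else:
            entry["kmo"] = None
            entry["msa_skipped_rank_deficient"] = True
        sol = extract_rotate(current, kaiser=kaiser)
        cs = complex_structure(sol, threshold=loading_threshold)
        dropped_cs = list(cs.index)
        entry["dropped_msa"] = dropped_msa
        entry["dropped_complex"] = dropped_cs
        entry["n_components"] = sol.n_components
        log.append(entry)
        if not dropped_msa and not dropped_cs:
            msa, kmo = (
                msa_kmo(current)
                if len(current.measures) <= msa_max_p
                else (pd.Series(np.nan, index=current.measures), float("nan"))
            )
            sol.kmo = kmo
            sol.msa = msa
            sol.iteration_log = log
            sol.score_weights = _score_weights(current, sol)
            sol.component_labels = label_components(sol)
            return sol
        keep = [m for m in current.measures if m not in dropped_cs]
        if len(keep) < 2:
            raise ValueError("complex-structure pruning removed nearly all measures")
        current = current.subset(keep)
    raise RuntimeError(f"factor reduction did not converge in {max_iterations} iterations")


def _score_weights(z: ZTable, sol: FactorSolution) -> pd.DataFrame:
    r = _correlation(z)
    rinv, _ = _inverse_with_ridge(r)
    w = rinv @ sol.loadings.to_numpy()
    return pd.DataFrame(w, index=sol.measures, columns=sol.loadings.columns)


def component_scores(sol: FactorSolution, z: ZTable) -> pd.DataFrame:
    """Regression-method component scores: ``Z_retained @ (R^-1 Lambda)``."""
    if sol.score_weights is None:
        raise ValueError("solution has no score weights; run iterative_reduce")
    zr = z.values[sol.measures]
    scores = zr.to_numpy() @ sol.score_weights.to_numpy()
    return pd.DataFrame(scores, index=z.values.index, columns=sol.loadings.columns)


_DOMAIN_LABELS = [
    # (dominant measure domain, label)
    ("QS", "static balance"),
    ("QS_freq", "dynamic balance"),
    ("GA_mean_temporal", "temporal gait"),
    ("GA_mean_spatial", "spatial gait"),
    ("GA_var_temporal_R", "temporal variability, right"),
    ("GA_var_temporal_L", "temporal variability, left"),
    ("GA_var_spatial", "spatial variability"),
    ("GA_var_dst", "dynamic balance"),
]

_TEMPORAL = ("Str-T", "Stn-T", "Sw-T", "CAD")
_SPATIAL = ("Str-Len", "Stp-Len", "MaxFC", "MinFC", "SW")


def _measure_domain(measure: str) -> str:
    if ":" not in measure:
        return "other"
    domain, rest = measure.split(":", 1)
    if domain == "QS":
        # sway magnitude reflects static balance; sway frequency reflects the
        # speed of postural regulation (dynamic balance)
        return "QS_freq" if "FREQ" in rest else "QS"
    if domain == "FC":
        return "FC"
    stat = rest.split("-", 1)[0]
    side = rest.rsplit("-", 1)[-1]
    is_mean = stat == "Mn"
    if "DST" in rest and not is_mean:
        return "GA_var_dst"
    if any(m in rest for m in _TEMPORAL):
        if is_mean:
            return "GA_mean_temporal"
        return f"GA_var_temporal_{side}" if side in ("L", "R") else "GA_var_temporal"
    if any(m in rest for m in _SPATIAL):
        return "GA_mean_spatial" if is_mean else "GA_var_spatial"
    return "GA_other"


def label_components(sol: FactorSolution) -> list[str]:
    """Post hoc interpretive labels from each component's dominant measure
    domain; reported only, never used in computation."""
    labels = []
    for c in sol.loadings.columns:
        col = sol.loadings[c].abs()
        top = col[col > 0.4].index if (col > 0.4).any() else col.nlargest(3).index
        domains = pd.Series([_measure_domain(m) for m in top])
        dom = domains.mode().iloc[0]
        mapping = dict(_DOMAIN_LABELS)
        labels.append(mapping.get(dom, dom))
    return labels
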