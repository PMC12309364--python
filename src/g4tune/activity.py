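"""Feature-based linear modelling of G4 component activity.

Component activity is measured in relative expression units (REU): protein
output as a percentage of the unengineered-chassis control.  Activity is
modelled as an ordinary least-squares linear function of three sequence
features — G-tract length, G-tract number and mean loop length — fitted per
level (DNA or RNA).  The module also provides cross-context agreement
statistics (Pearson correlation, mean context shift), classification of
structure-acting versus merely insertional components, and a standardized-
residual outlier screen for paired panels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .motifs import Level

#: Observed activities run up to slightly above the control (107% was the
#: largest measured), so predictions are clipped to [0, 120].
REU_PREDICTION_BOUNDS = (0.0, 120.0)

#: Components whose expression reduction does not exceed this threshold are
#: indistinguishable from the generic insertional effect of a disabled
#: motif (5-20% reduction) and are not considered structure-acting.
STRUCTURE_THRESHOLD_REU = 20.0

FEATURE_NAMES = ("tract_length", "tract_count", "mean_loop_length")


@dataclass(frozen=True)
class Context:
    """Measurement context: cell host, molecular format, expression system."""

    cell_host: str = "CHO"
    format: str = "plasmid"
    system: str = "transient"

    _HOSTS = ("CHO", "HEK", "HepG2", "other")
    _FORMATS = ("plasmid", "mRNA")
    _SYSTEMS = ("transient", "stable")

    def __post_init__(self):
        if self.cell_host not in self._HOSTS:
            raise ValueError(f"cell_host must be one of {self._HOSTS}")
        if self.format not in self._FORMATS:
            raise ValueError(f"format must be one of {self._FORMATS}")
        if self.system not in self._SYSTEMS:
            raise ValueError(f"system must be one of {self._SYSTEMS}")


@dataclass(frozen=True)
class ActivityRecord:
    """One component's (measured or simulated) activity in one context."""

    component_label: str
    level: Level
    features: tuple  # (tract_length, tract_count, mean_loop_length)
    reu_mean: float
    reu_sd: float = 0.0
    n_replicates: int = 1
    context: Context = Context()

    def __post_init__(self):
        object.__setattr__(self, "level", Level(self.level))
        object.__setattr__(self, "features", tuple(float(x) for x in self.features))
        if len(self.features) != 3:
            raise ValueError("features must be (tract_length, tract_count, mean_loop_length)")
        if self.reu_mean < 0:
            raise ValueError("reu_mean must be >= 0")
        if self.reu_sd < 0:
            raise ValueError("reu_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class LinearActivityModel:
    """Fitted REU ~ intercept + b1*tract_length + b2*tract_count + b3*mean_loop."""

    level: Level
    intercept: float
    beta_tract_length: float
    beta_tract_count: float
    beta_loop_length: float
    r_squared: float
    f_pvalue: float
    n: int

    def __post_init__(self):
        object.__setattr__(self, "level", Level(self.level))
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("R^2 must lie in [0, 1]")

    @property
    def betas(self) -> tuple:
        return (self.beta_tract_length, self.beta_tract_count, self.beta_loop_length)


def _design_matrix(records: Sequence[ActivityRecord]) -> Tuple[np.ndarray, np.ndarray]:
    X = np.array([[1.0, *r.features] for r in records], dtype=float)
    y = np.array([r.reu_mean for r in records], dtype=float)
    return X, y


def _name_collinear_feature(X: np.ndarray) -> str:
    """Name a feature column whose removal restores full column rank."""
    base_rank = np.linalg.matrix_rank(X)
    for j in range(1, X.shape[1]):
        reduced = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(reduced) == base_rank:
            return FEATURE_NAMES[j - 1]
    return "unknown"


def fit_activity_model(records: Sequence[ActivityRecord], level) -> LinearActivityModel:
    """Fit the three-feature OLS activity model for one level.

    Solves the normal equations directly (X'X b = X'y) rather than wrapping
    a fitted-model object; reports R-squared and the overall F-test p-value.
    Raises on a rank-deficient design, naming a collinear feature.
    """
    level = Level(level)
    recs = [r for r in records if r.level is level]
    if len(recs) < 5:
        raise ValueError(
            f"need >= 5 records at level {level.value}, got {len(recs)}"
        )
    X, y = _design_matrix(recs)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "design matrix is rank-deficient; collinear feature: "
            + _name_collinear_feature(X)
        )
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("response has zero variance; nothing to model")
    r2 = 1.0 - sse / sst
    n, k = X.shape[0], X.shape[1] - 1
    df_resid = n - k - 1
    if sse <= 0 or df_resid <= 0 or r2 >= 1.0:
        f_p = 0.0
    else:
        f_stat = (r2 / k) / ((1.0 - r2) / df_resid)
        f_p = float(stats.f.sf(f_stat, k, df_resid))
    return LinearActivityModel(
        level=level,
        intercept=float(beta[0]),
        beta_tract_length=float(beta[1]),
        beta_tract_count=float(beta[2]),
        beta_loop_length=float(beta[3]),
        r_squared=min(max(r2, 0.0), 1.0),
        f_pvalue=f_p,
        n=n,
    )


def predict_reu(model: LinearActivityModel, features: Sequence[float]) -> float:
    """Linear prediction for a feature triple, clipped to [0, 120] REU."""
    if len(features) != 3:
        raise ValueError("features must be (tract_length, tract_count, mean_loop_length)")
    raw = model.intercept + float(np.dot(model.betas, np.asarray(features, dtype=float)))
    lo, hi = REU_PREDICTION_BOUNDS
    return min(max(raw, lo), hi)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Pearson product-moment correlation with two-sided t-transform p-value.

    Implemented from the definition; the p-value uses t = r*sqrt(n-2)/
    sqrt(1-r^2) with n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    xc, yc = x - x.mean(), y - y.mean()
    sx = float(np.sqrt(xc @ xc))
    sy = float(np.sqrt(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("constant input: correlation undefined")
    r = float((xc @ yc) / (sx * sy))
    r = min(max(r, -1.0), 1.0)
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return r, p


def classify_components(
    records: Sequence[ActivityRecord], threshold: float = STRUCTURE_THRESHOLD_REU
) -> Dict[str, List[ActivityRecord]]:
    """Partition components into structure-acting vs insertional-only.

    A component is structure-acting iff its expression reduction
    (100 - reu_mean) strictly exceeds ``threshold`` (default 20 REU, the
    upper edge of the generic insertional effect of disabled motifs).
    All records must share one context.
    """
    contexts = {r.context for r in records}
    if len(contexts) > 1:
        raise ValueError(f"records span multiple contexts: {sorted(map(str, contexts))}")
    out = {"structure_acting": [], "insertional_only": []}
    for r in records:
        key = "structure_acting" if (100.0 - r.reu_mean) > threshold else "insertional_only"
        out[key].append(r)
    return out


@dataclass(frozen=True)
class OutlierScreenResult:
    flags: tuple  # bool per point
    standardized_residuals: tuple
    r_before: float
    r_after: float  # correlation with flagged points excluded


def outlier_screen(
    observed: Sequence[float],
    reference: Sequence[float],
    z_threshold: float = 2.5,
) -> OutlierScreenResult:
    """Standardized-residual outlier screen on a paired panel.

    Fits observed ~ reference by simple linear regression, computes
    internally standardized residuals e_i / (s * sqrt(1 - h_ii)), and flags
    |z| > ``z_threshold``.  Returns the flags plus the Pearson r before and
    after excluding flagged points.
    """
    y = np.asarray(observed, dtype=float)
    x = np.asarray(reference, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("observed and reference must be equal-length 1-D series")
    n = y.size
    if n < 4:
        raise ValueError("need at least 4 paired points to screen outliers")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise ValueError("reference series is constant")
    slope = float(xc @ (y - y.mean())) / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    sse = float(resid @ resid)
    s2 = sse / (n - 2)
    leverage = 1.0 / n + xc**2 / sxx
    if s2 <= 0:
        z = np.zeros(n)
    else:
        z = resid / np.sqrt(s2 * (1.0 - leverage))
    flags = np.abs(z) > z_threshold
    r_before, _ = pearson_r(x, y)
    if flags.any() and (~flags).sum() >= 3:
        r_after, _ = pearson_r(x[~flags], y[~flags])
    else:
        r_after = r_before
    return OutlierScreenResult(
        flags=tuple(bool(f) for f in flags),
        standardized_residuals=tuple(float(v) for v in z),
        r_before=r_before,
        r_after=r_after,
    )


def context_shift(
    records_a: Sequence[ActivityRecord], records_b: Sequence[ActivityRecord]
) -> Tuple[float, float]:
    """Mean REU shift and Pearson r between two paired context panels.

    Records are paired by component label; returns
    (mean(REU_b - REU_a), pearson r of the paired REUs).
    """
    a = {r.component_label: r.reu_mean for r in records_a}
    b = {r.component_label: r.reu_mean for r in records_b}
    only_a = sorted(set(a) - set(b))
    only_b = sorted(set(b) - set(a))
    if only_a or only_b:
        raise ValueError(
            f"unpaired component labels: missing from B {only_a}, missing from A {only_b}"
        )
    labels = sorted(a)
    xs = [a[l] for l in labels]
    ys = [b[l] for l in labels]
    shift = float(np.mean(np.asarray(ys) - np.asarray(xs)))
    r, _ = pearson_r(xs, ys)
    return shift, r
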