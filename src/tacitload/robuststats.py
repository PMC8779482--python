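"""Inferential stage: one-way ANOVA with Tukey HSD, RANSAC outlier
rejection, and polynomial least-squares regression with fit statistics.

The ANOVA is the classical pooled between/within decomposition
(``F = MS_between / MS_within`` on ``(k - 1, N - k)`` degrees of freedom);
Tukey's honestly-significant-difference test uses the studentized-range
distribution with the pooled within-group mean square (Tukey–Kramer form
for unequal group sizes).  RANSAC fits exact two-point lines for a fixed
number of iterations and keeps the largest consensus set, which makes the
subsequent least-squares line robust to a small number of gross outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import InputError, ParameterError, TacitloadError

DEFAULT_ALPHA = 0.05


class DegenerateFitError(TacitloadError):
    """Model cannot be fitted (rank-deficient design or no consensus set)."""


@dataclass
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p: float
    group_means: dict

    def __str__(self) -> str:
        return f"F({self.df_between},{self.df_within}) = {self.f_stat:.4g}, p = {self.p:.4g}"


@dataclass
class TukeyResult:
    """One row per unordered group pair: mean diff, q statistic, adjusted p."""

    pairs: pd.DataFrame
    alpha: float = DEFAULT_ALPHA


@dataclass
class RansacConfig:
    min_samples: int = 2
    residual_threshold: float | None = None  # None: 2.5 x robust sigma (MAD)
    n_iterations: int = 2000
    seed: int = 0

    def validate(self) -> None:
        if self.min_samples != 2:
            raise ParameterError("line fitting uses exactly 2-point minimal samples")
        if self.n_iterations < 1:
            raise ParameterError("n_iterations must be >= 1")
        if self.residual_threshold is not None and self.residual_threshold < 0:
            raise ParameterError("residual_threshold must be >= 0")


@dataclass
class RegressionResult:
    """Least-squares polynomial fit; coefficients are intercept-first."""

    coefficients: np.ndarray
    r_squared: float
    f_stat: float
    p: float
    var_error: float
    inlier_mask: np.ndarray
    n_inliers: int
    degree: int
    stderr: np.ndarray = field(default_factory=lambda: np.array([]))

    def equation(self, x_name: str = "X", y_name: str = "Y") -> str:
        terms = [f"{self.coefficients[0]:.4f}"]
        for k, c in enumerate(self.coefficients[1:], start=1):
            power = x_name if k == 1 else f"{x_name}^{k}"
            terms.append(f"{'+' if c >= 0 else '-'} {abs(c):.4f}·{power}")
        return f"{y_name} = " + " ".join(terms)


def _group_arrays(values, groups) -> list[np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise InputError("values and groups must have the same length")
    if not np.all(np.isfinite(values)):
        raise InputError("values must be finite")
    labels = list(pd.unique(groups))
    arrays = [values[groups == lab] for lab in labels]
    return labels, arrays


def one_way_anova(values, groups) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA on pooled observations.

    Identical groups give ``F = 0, p = 1``; zero within-group variance with
    differing means gives the ``F = +inf`` sentinel with ``p = 0``.
    """
    labels, arrays = _group_arrays(values, groups)
    if len(arrays) < 2:
        raise ParameterError("ANOVA needs at least 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise ParameterError("every group needs at least 2 observations")
    n_total = sum(len(a) for a in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b = len(arrays) - 1
    df_w = n_total - len(arrays)
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0.0:
        f = 0.0 if ms_b == 0.0 else np.inf
        p = 1.0 if ms_b == 0.0 else 0.0
    else:
        f = ms_b / ms_w
        p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(
        f_stat=float(f), df_between=df_b, df_within=df_w, p=p,
        group_means={lab: float(a.mean()) for lab, a in zip(labels, arrays)},
    )


def tukey_hsd(values, groups, alpha: float = DEFAULT_ALPHA) -> TukeyResult:
    """Tukey(–Kramer) HSD pairwise comparisons with studentized-range p."""
    labels, arrays = _group_arrays(values, groups)
    if len(arrays) < 2:
        raise ParameterError("Tukey HSD needs at least 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise ParameterError("every group needs at least 2 observations")
    k = len(arrays)
    n_total = sum(len(a) for a in arrays)
    df_w = n_total - k
    ms_w = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df_w
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrays[i], arrays[j]
            diff = a.mean() - b.mean()
            se = np.sqrt(ms_w / 2.0 * (1.0 / len(a) + 1.0 / len(b)))
            if se == 0.0:
                q = 0.0 if diff == 0.0 else np.inf
                p = 1.0 if diff == 0.0 else 0.0
            else:
                q = abs(diff) / se
                p = float(stats.studentized_range.sf(q, k, df_w))
                p = min(max(p, 0.0), 1.0)
            rows.append(
                {
                    "group_a": labels[i], "group_b": labels[j],
                    "mean_diff": float(diff), "q": float(q), "p_adj": p,
                    "significant": p < alpha,
                }
            )
    return TukeyResult(pairs=pd.DataFrame(rows), alpha=alpha)


def _line_residuals(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residuals of the ordinary least-squares line through all points."""
    coef = np.polynomial.polynomial.polyfit(x, y, 1)
    return y - (coef[0] + coef[1] * x)


def ransac_line(x, y, config: RansacConfig | None = None) -> np.ndarray:
    """Largest-consensus inlier mask for a straight-line model.

    Each iteration fits the exact line through 2 random points and counts
    points within ``residual_threshold`` of it; the mask of the largest
    consensus set wins, ties resolved in favour of the earliest iteration.
    Raises :class:`DegenerateFitError` when no consensus set exceeds the
    minimal sample itself.
    """
    config = config or RansacConfig()
    config.validate()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise InputError("x and y must have the same length")
    if n < config.min_samples:
        raise ParameterError(f"need at least {config.min_samples} points, got {n}")
    threshold = config.residual_threshold
    if threshold is None:
        # robust scale of an initial all-points fit: 2.5 * 1.4826 * MAD,
        # i.e. ~2.5 sigma for Gaussian residuals, so genuine scatter is kept
        threshold = 2.5 * 1.4826 * float(np.median(np.abs(_line_residuals(x, y))))
    rng = np.random.default_rng(config.seed & 0x7FFFFFFF)
    iters = config.n_iterations
    i1 = rng.integers(0, n, size=iters)
    i2 = rng.integers(0, n - 1, size=iters)
    i2 = np.where(i2 >= i1, i2 + 1, i2)  # distinct second index, uniform
    dx = x[i2] - x[i1]
    valid = dx != 0
    slope = np.zeros(iters)
    slope[valid] = (y[i2] - y[i1])[valid] / dx[valid]
    intercept = y[i1] - slope * x[i1]
    resid = np.abs(y[None, :] - (intercept[:, None] + slope[:, None] * x[None, :]))
    counts = (resid <= threshold).sum(axis=1)
    counts[~valid] = -1
    best = int(np.argmax(counts))  # argmax returns the first maximum: earliest iteration
    if counts[best] < config.min_samples + 1:
        raise DegenerateFitError(
            f"no consensus set larger than the minimal sample "
            f"(best {counts[best]} of {n} points)"
        )
    return resid[best] <= threshold


def fit_polynomial(
    x, y, degree: int = 1, inlier_mask: np.ndarray | None = None
) -> RegressionResult:
    """Least-squares polynomial fit with R², regression F and residual variance.

    The fit runs on the masked subset when ``inlier_mask`` is given; the
    regression F statistic has ``(degree, n - degree - 1)`` degrees of
    freedom and ``var_error`` is the unbiased residual variance
    ``SSE / (n - degree - 1)``.
    """
    if degree not in (1, 2):
        raise ParameterError("degree must be 1 or 2")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be equal-length 1-d arrays")
    if inlier_mask is None:
        inlier_mask = np.ones(len(x), dtype=bool)
    inlier_mask = np.asarray(inlier_mask, dtype=bool)
    xs, ys = x[inlier_mask], y[inlier_mask]
    n = len(xs)
    if n < degree + 2:
        raise ParameterError(f"need at least degree + 2 = {degree + 2} points, got {n}")
    design = np.vander(xs, degree + 1, increasing=True)
    if np.linalg.matrix_rank(design) < degree + 1:
        raise DegenerateFitError("rank-deficient design (e.g. all x identical)")
    coef, *_ = np.linalg.lstsq(design, ys, rcond=None)
    fitted = design @ coef
    sse = float(np.sum((ys - fitted) ** 2))
    sst = float(np.sum((ys - ys.mean()) ** 2))
    ssr = max(sst - sse, 0.0)
    df_model, df_resid = degree, n - degree - 1
    var_error = sse / df_resid
    if sst == 0.0:
        r2 = 1.0 if sse == 0.0 else 0.0
    else:
        r2 = 1.0 - sse / sst
    if sse == 0.0:
        f = np.inf if ssr > 0 else 0.0
        p = 0.0 if ssr > 0 else 1.0
    else:
        f = (ssr / df_model) / (sse / df_resid)
        p = float(stats.f.sf(f, df_model, df_resid))
    # coefficient standard errors from (X'X)^-1 * var_error
    try:
        cov = np.linalg.inv(design.T @ design) * var_error
        stderr = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:  # pragma: no cover - rank checked above
        stderr = np.full(degree + 1, np.nan)
    return RegressionResult(
        coefficients=coef,
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        f_stat=float(f),
        p=p,
        var_error=float(var_error),
        inlier_mask=inlier_mask,
        n_inliers=int(inlier_mask.sum()),
        degree=degree,
        stderr=stderr,
    )


def robust_line_fit(x, y, config: RansacConfig | None = None) -> RegressionResult:
    """RANSAC inlier selection followed by least squares on the inliers."""
    mask = ransac_line(x, y, config)
    return fit_polynomial(x, y, degree=1, inlier_mask=mask)
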