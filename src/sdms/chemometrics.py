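"""Chemometric grouping of m/z measurands, calibration, and the TIA comparator.

Per-scan m/z values of one monitored peak often fall into several
statistically distinct subsets — tautomers or co-isolated species each
contribute their own cloud of measurands.  ``group_measurands`` partitions
the pooled values into such subsets and reports Shapiro-Wilk normality,
pairwise Welch t-tests, and a one-way ANOVA across the final groups.

``calibrate`` fits the linear calibration models ln[D''_SD] = f(conc.) or
D''_SD = f(conc.) by ordinary least squares, and ``tia_quantify`` implements
the classical comparator: Savitzky-Golay smoothing, endpoint-anchored linear
baseline correction, and trapezoidal integration of the residual peak area.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from scipy.signal import savgol_filter

from .errors import DegeneracyError, ValidationError


@dataclass
class MeasurandGroup:
    """A statistically homogeneous subset of per-scan m/z values."""

    label: str
    mz_values: np.ndarray
    mean_mz: float
    sd_mz: float
    n: int
    shapiro_W: float | None
    shapiro_p: float | None


@dataclass
class GroupingReport:
    groups: list[MeasurandGroup]
    pairwise_t: np.ndarray  # (k, k) t statistics, NaN on the diagonal
    pairwise_p: np.ndarray
    anova_F: float | None
    anova_p: float | None
    alpha: float

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def all_pairs_significant(self) -> bool:
        """True when every pair of groups differs at the report's alpha."""
        k = len(self.groups)
        return all(
            self.pairwise_p[i, j] < self.alpha for i in range(k) for j in range(i + 1, k)
        )


@dataclass
class CalibrationModel:
    transform: Literal["log_e", "identity"]
    slope: float
    slope_sd: float
    intercept: float
    intercept_sd: float
    pearson_r: float
    n_points: int
    concentration_units: str = "ng/mL"

    def predict(self, concentrations) -> np.ndarray:
        c = np.asarray(concentrations, dtype=float)
        y = self.intercept + self.slope * c
        return np.exp(y) if self.transform == "log_e" else y


@dataclass
class TIAResult:
    area: float
    baseline_intercept: float
    baseline_slope: float
    smoothing: tuple[int, int] | None


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test (3 <= n <= 5000, non-constant input)."""
    v = np.asarray(values, dtype=float)
    if not 3 <= v.size <= 5000:
        raise ValidationError(f"Shapiro-Wilk needs 3 <= n <= 5000, got n={v.size}")
    if np.ptp(v) == 0:
        raise ValidationError("Shapiro-Wilk undefined for a constant sample")
    res = stats.shapiro(v)
    return float(res.statistic), float(res.pvalue)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length, non-constant sequences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("pearson_r inputs must have equal length")
    if x.size < 3:
        raise ValidationError("pearson_r needs at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("pearson_r undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def _split_candidates(
    sorted_vals: np.ndarray, gap: float, max_components: int, seed: int
) -> list[np.ndarray]:
    """Candidate groups: gap pre-split, then per-block 1-D Gaussian mixtures.

    A plain gap split cannot separate overlapping m/z clouds (consecutive
    spacings in the valley between two clouds stay far below any sensible
    gap), so within each gap-delimited block the number of components is
    chosen by BIC over 1..max_components and values are hard-assigned to the
    most responsible component.  Components are returned in ascending order
    of mean.
    """
    from sklearn.mixture import GaussianMixture

    blocks = []
    start = 0
    diffs = np.diff(sorted_vals)
    for i, d in enumerate(diffs):
        if d > gap:
            blocks.append(sorted_vals[start : i + 1])
            start = i + 1
    blocks.append(sorted_vals[start:])

    groups: list[np.ndarray] = []
    for block in blocks:
        if block.size < 6 or np.ptp(block) == 0:
            groups.append(block)
            continue
        X = block.reshape(-1, 1)
        best_labels, best_bic = None, np.inf
        for k in range(1, min(max_components, block.size // 3) + 1):
            gm = GaussianMixture(n_components=k, n_init=3, random_state=seed)
            gm.fit(X)
            bic = gm.bic(X)
            if bic < best_bic - 1e-9:
                best_bic = bic
                best_labels = gm.predict(X)
        if best_labels is None or len(np.unique(best_labels)) == 1:
            groups.append(block)
        else:
            for lbl in np.unique(best_labels):
                member = block[best_labels == lbl]
                groups.append(member)
    groups.sort(key=lambda g: float(np.mean(g)))
    return groups


def group_measurands(
    mz_per_scan: Sequence[float],
    alpha: float = 0.05,
    gap: float = 0.2,
    seed: int = 0,
    max_components: int = 4,
) -> GroupingReport:
    """Partition pooled per-scan m/z values into statistically distinct groups.

    Candidate groups come from a gap pre-split (consecutive sorted spacings
    > ``gap``) refined by per-block Gaussian-mixture assignment; candidates
    whose Welch t-test p-value is >= ``alpha`` are merged (single linkage,
    iterated to a fixpoint).  The report carries the pairwise Welch matrix,
    a one-way ANOVA across the final groups, and per-group Shapiro-Wilk
    normality.  Every input value lands in exactly one group.
    """
    v = np.asarray(mz_per_scan, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 6:
        raise ValidationError("group_measurands needs at least 6 finite values")
    if not 0 < alpha <= 0.5:
        raise ValidationError("alpha must be in (0, 0.5]")
    sorted_vals = np.sort(v)
    members = _split_candidates(sorted_vals, gap, max_components, seed)

    # Groups below the testable size (n < 3) are absorbed into the candidate
    # with the nearest mean before any testing.
    while len(members) > 1 and min(m.size for m in members) < 3:
        i = min(range(len(members)), key=lambda i: members[i].size)
        small = members.pop(i)
        j = min(range(len(members)), key=lambda j: abs(members[j].mean() - small.mean()))
        members[j] = np.sort(np.concatenate([members[j], small]))

    # Merge phase: single-linkage union of pairs that are not distinguishable.
    merged = True
    while merged and len(members) > 1:
        merged = False
        for i, j in itertools.combinations(range(len(members)), 2):
            a, b = members[i], members[j]
            if a.size < 2 or b.size < 2 or (np.ptp(a) == 0 and np.ptp(b) == 0):
                p = 1.0 if abs(a.mean() - b.mean()) == 0 else 0.0
            else:
                p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            if not np.isfinite(p) or p >= alpha:
                members[i] = np.sort(np.concatenate([a, b]))
                del members[j]
                merged = True
                break
    members.sort(key=lambda g: float(np.mean(g)))

    k = len(members)
    t_mat = np.full((k, k), np.nan)
    p_mat = np.full((k, k), np.nan)
    for i, j in itertools.combinations(range(k), 2):
        res = stats.ttest_ind(members[i], members[j], equal_var=False)
        t_mat[i, j] = t_mat[j, i] = float(res.statistic)
        p_mat[i, j] = p_mat[j, i] = float(res.pvalue)

    if k >= 2:
        f_res = stats.f_oneway(*members)
        anova_F, anova_p = float(f_res.statistic), float(f_res.pvalue)
    else:
        anova_F = anova_p = None

    groups = []
    for i, m in enumerate(members):
        if 3 <= m.size <= 5000 and np.ptp(m) > 0:
            w, p_sw = shapiro_wilk(m)
        else:
            w = p_sw = None
        groups.append(
            MeasurandGroup(
                label=f"group_{i + 1}",
                mz_values=m,
                mean_mz=float(m.mean()),
                sd_mz=float(m.std(ddof=1)) if m.size > 1 else 0.0,
                n=int(m.size),
                shapiro_W=w,
                shapiro_p=p_sw,
            )
        )
    return GroupingReport(
        groups=groups, pairwise_t=t_mat, pairwise_p=p_mat, anova_F=anova_F, anova_p=anova_p,
        alpha=alpha,
    )


def calibrate(
    concentrations: Sequence[float],
    d_values: Sequence[float],
    transform: Literal["log_e", "identity"] = "log_e",
) -> CalibrationModel:
    """OLS calibration of (transformed) D''_SD against concentration.

    ``log_e`` fits ln[D''_SD] = intercept + slope * conc, the transform under
    which a log-linear variance law is exactly linear; ``identity`` fits the
    untransformed values.
    """
    c = np.asarray(concentrations, dtype=float)
    d = np.asarray(d_values, dtype=float)
    if c.size != d.size:
        raise ValidationError("concentrations and d_values lengths differ")
    if c.size < 3:
        raise ValidationError("calibration needs at least 3 points")
    if transform == "log_e":
        bad = np.nonzero(d <= 0)[0]
        if bad.size:
            raise ValidationError(
                f"log_e transform requires positive D values; offending point index {bad[0]}"
                f" (conc={c[bad[0]]:g}, D={d[bad[0]]:g})"
            )
        y = np.log(d)
    elif transform == "identity":
        y = d
    else:
        raise ValidationError(f"unknown transform {transform!r}")
    lr = stats.linregress(c, y)
    return CalibrationModel(
        transform=transform,
        slope=float(lr.slope),
        slope_sd=float(lr.stderr),
        intercept=float(lr.intercept),
        intercept_sd=float(lr.intercept_stderr),
        pearson_r=float(lr.rvalue),
        n_points=int(c.size),
    )


def tia_quantify(
    xs: Sequence[float],
    ys: Sequence[float],
    baseline: Literal["linear_endpoints", "none"] = "linear_endpoints",
    smoothing: tuple[int, int] | None = None,
) -> TIAResult:
    """Classical trapezoidal-integration quantification of one peak.

    Optional Savitzky-Golay smoothing ``(window, polyorder)`` with an odd
    window, optional linear baseline through the first and last (smoothed)
    points, then the trapezoidal integral of the non-negative residual.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.size != y.size:
        raise ValidationError("xs and ys lengths differ")
    if x.size < 5:
        raise ValidationError("tia_quantify needs at least 5 points")
    if np.any(np.diff(x) <= 0):
        raise ValidationError("xs must be strictly increasing")
    if smoothing is not None:
        window, poly = smoothing
        if window % 2 == 0:
            raise ValidationError("smoothing window must be odd")
        if window <= poly:
            raise ValidationError("smoothing window must exceed polyorder")
        y = savgol_filter(y, window, poly)
    if baseline == "linear_endpoints":
        slope = (y[-1] - y[0]) / (x[-1] - x[0])
        intercept = y[0] - slope * x[0]
    elif baseline == "none":
        slope = intercept = 0.0
    else:
        raise ValidationError(f"unknown baseline mode {baseline!r}")
    resid = np.clip(y - (intercept + slope * x), 0.0, None)
    area = float(np.trapezoid(resid, x))
    return TIAResult(
        area=area, baseline_intercept=float(intercept), baseline_slope=float(slope),
        smoothing=smoothing,
    )
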