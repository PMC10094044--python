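"""Stochastic-dynamic diffusion parameters from scan-level intensity noise.

The central quantity is the second-order stochastic-dynamic diffusion
parameter computed span-by-span from the population variance of the
per-scan intensity trace,

    D''_SD,i = 2.6388e-17 * ( <I^2> - <I>^2 ),      D''_SD,tot = sum_i D''_SD,i

with the companion first-order form

    D_SD,i = 1.3194e-17 * A_i * ( <I^2> - <I>^2 ) / <(I - <I>)^2>_fit ,

where A_i is the amplitude of a sine-squared ("SineSqr") model

    y(x) = y0 + A * sin^2( pi * (x - xc) / w )

fitted to the squared-deviation trace (I - <I>)^2 against scan time, and the
denominator is the time-average of the fitted curve over the span (see
``denominator`` below).  The two constants satisfy K2 = 2 * K1 exactly, which
ties the two forms together: when the fitted amplitude equals twice the mean
squared deviation of the fit, D and D'' coincide.

The same SineSqr fit supplies the amplitudes A_D and A_I of the
collision-energy profiles D''_SD = f(CE) and <I> = f(CE), from which the
theoretical mean total intensity of a fragment ion q is

    <I_TOT,q> = 0.5 * (A_I^q / A_D^q) * D''_SD,tot .

Units: the constants are applied verbatim to intensities in counts and the
result is labelled cm^2 s^-1; no unit conversion is attempted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress, pearsonr

from .errors import DegeneracyError, ValidationError
from .scan_io import IntensitySeries

#: first-order constant of the D_SD formula (cm^2 s^-1 per counts^2 ratio)
K1 = 1.3194e-17
#: second-order constant multiplying the intensity population variance
K2 = 2.6388e-17

# K2 = 2*K1 is the structural bridge between the two diffusion formulas.
assert K2 == 2.0 * K1


@dataclass(frozen=True)
class SpanSpec:
    """How to carve a series into scan-time spans.

    ``fixed_count`` chops the series into consecutive spans of
    ``span_length`` scans (a trailing remainder of >= 2 scans becomes its own
    span; a single leftover scan joins the previous span).  ``explicit``
    takes user-supplied half-open ``(start, end)`` positional boundaries.
    """

    mode: Literal["fixed_count", "explicit"] = "fixed_count"
    span_length: int = 5
    boundaries: tuple[tuple[int, int], ...] | None = None

    def resolve(self, n: int) -> list[tuple[int, int]]:
        if self.mode == "fixed_count":
            if self.span_length < 2:
                raise ValidationError("span_length must be >= 2")
            if n < 2:
                raise ValidationError("need at least 2 scans")
            spans = []
            start = 0
            while start < n:
                end = min(start + self.span_length, n)
                if n - end == 1:  # lone trailing scan: absorb it
                    end = n
                spans.append((start, end))
                start = end
            if spans and spans[-1][1] - spans[-1][0] < 2:
                last = spans.pop()
                prev = spans.pop()
                spans.append((prev[0], last[1]))
            return spans
        if self.mode == "explicit":
            if not self.boundaries:
                raise ValidationError("explicit mode requires boundaries")
            spans = [tuple(b) for b in self.boundaries]
            for s, e in spans:
                if not (0 <= s < e <= n):
                    raise ValidationError(f"span ({s}, {e}) outside series of length {n}")
                if e - s < 2:
                    raise ValidationError(f"span ({s}, {e}) covers fewer than 2 scans")
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 < e1:
                    raise ValidationError("spans must be non-overlapping and ordered")
            return spans
        raise ValidationError(f"unknown span mode {self.mode!r}")


@dataclass
class SineSqrFit:
    """Least-squares parameters of y0 + A*sin^2(pi*(x - xc)/w)."""

    amplitude_A: float
    center_xc: float
    width_w: float
    offset_y0: float
    rss: float
    degenerate: bool = False

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.offset_y0 + self.amplitude_A * np.sin(
            np.pi * (x - self.center_xc) / self.width_w
        ) ** 2


@dataclass
class DiffusionEstimate:
    span: tuple[int, int]
    mean_I: float
    var_I: float
    d_second: float
    d_first: float | None = None
    A_i: float | None = None


@dataclass
class DiffusionTotal:
    per_span: list[DiffusionEstimate]
    d_second_tot: float
    d_first_tot: float | None = None


@dataclass
class CEProfile:
    collision_energies: np.ndarray
    d_second_values: np.ndarray
    mean_intensities: np.ndarray
    fit_d: SineSqrFit
    fit_i: SineSqrFit
    theoretical_intensities: np.ndarray
    pearson_r: float


@dataclass
class CorrelationRecord:
    r: float
    slope: float
    intercept: float
    n: int


def population_variance(values: Sequence[float]) -> float:
    """<I^2> - <I>^2 with denominator n (population convention), clamped >= 0.

    Evaluated in the mathematically identical two-pass form
    mean((I - <I>)^2): the raw-moment difference cancels catastrophically for
    high-count intensity traces (mean ~1e5, sd ~1e2).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("population_variance of empty input")
    if not np.all(np.isfinite(v)):
        raise ValidationError("non-finite intensities")
    return max(float(np.var(v)), 0.0)


def d_sd_second(series: IntensitySeries, spans: SpanSpec = SpanSpec()) -> DiffusionTotal:
    """Second-order diffusion parameter per span and its total (additive)."""
    bounds = spans.resolve(len(series))
    per_span = []
    for s, e in bounds:
        seg = series.intensities[s:e]
        var = population_variance(seg)
        per_span.append(
            DiffusionEstimate(span=(s, e), mean_I=float(seg.mean()), var_I=var, d_second=K2 * var)
        )
    return DiffusionTotal(per_span=per_span, d_second_tot=sum(p.d_second for p in per_span))


# --- SineSqr fitting -------------------------------------------------------

def _sinesqr(params: np.ndarray, x: np.ndarray) -> np.ndarray:
    y0, a, xc, w = params
    return y0 + a * np.sin(np.pi * (x - xc) / w) ** 2


def _fft_start(x: np.ndarray, y: np.ndarray) -> np.ndarray | None:
    """Initial guess from the dominant Fourier mode on a uniform grid.

    sin^2(pi*(x-xc)/w) = 1/2 - cos(2*pi*(x-xc)/w)/2, so the dominant
    non-zero frequency f of y gives w = 1/f, and a linear fit of
    a + b*cos + c*sin recovers amplitude and phase in closed form.
    """
    n = x.size
    if n < 8:
        return None
    dx = np.diff(x)
    if dx.min() <= 0 or dx.max() / dx.min() > 1.001:
        return None
    freqs = np.fft.rfftfreq(n, d=dx.mean())
    spec = np.abs(np.fft.rfft(y - y.mean()))
    if spec.size < 2:
        return None
    k = 1 + int(np.argmax(spec[1:]))
    f = freqs[k]
    if f <= 0:
        return None
    w = 1.0 / f
    cos_t = np.cos(2 * np.pi * x / w)
    sin_t = np.sin(2 * np.pi * x / w)
    design = np.column_stack([np.ones(n), cos_t, sin_t])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    a0, b, c = coef
    amp = 2.0 * math.hypot(b, c)
    if amp == 0:
        return None
    xc = (w / (2 * np.pi)) * math.atan2(-c, -b)
    y0 = a0 - amp / 2.0
    return np.array([y0, amp, xc, w])


def fit_sinesqr(
    x: Sequence[float], y: Sequence[float], seed: int = 0, n_restarts: int = 10
) -> SineSqrFit:
    """Multi-start least-squares fit of the SineSqr model.

    Deterministic for a fixed seed: one spectral start, one coarse heuristic
    start, and ``n_restarts`` seeded random starts; the lowest-RSS solution
    wins.  A constant ordinate is degenerate and returns A = 0, y0 = mean(y)
    with the ``degenerate`` flag set.  The reported amplitude is always
    non-negative (a negative amplitude is folded into a half-period shift of
    the center).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y lengths differ")
    if x.size < 4:
        raise ValidationError("SineSqr fit needs at least 4 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite inputs to fit_sinesqr")

    span = float(x.max() - x.min())
    ptp = float(y.max() - y.min())
    if ptp == 0.0 or span == 0.0:
        return SineSqrFit(0.0, float(x[0]), max(span, 1.0), float(y.mean()), 0.0, degenerate=True)

    rng = np.random.default_rng(seed)
    starts = []
    fft_guess = _fft_start(x, y)
    if fft_guess is not None:
        starts.append(fft_guess)
    starts.append(np.array([y.min(), ptp, x[int(np.argmax(y))], 2.0 * span]))
    for _ in range(n_restarts):
        starts.append(
            np.array(
                [
                    y.min() + ptp * rng.uniform(-0.25, 0.25),
                    ptp * rng.uniform(0.5, 1.5),
                    rng.uniform(x.min(), x.max()),
                    span * rng.uniform(0.25, 4.0),
                ]
            )
        )

    lower = [-np.inf, -np.inf, -np.inf, span * 1e-3]
    upper = [np.inf, np.inf, np.inf, span * 1e3]
    best = None
    for p0 in starts:
        p0 = np.clip(p0, lower, upper)
        try:
            res = least_squares(
                lambda p: _sinesqr(p, x) - y, p0, bounds=(lower, upper), method="trf"
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise DegeneracyError("SineSqr fit failed from every start")

    y0, a, xc, w = best.x
    if a < 0:  # fold sign: y0 + a*sin^2 = (y0+a) + (-a)*sin^2 shifted by w/2
        y0, a, xc = y0 + a, -a, xc - w / 2.0
    rss = float(2.0 * best.cost)
    return SineSqrFit(float(a), float(xc), float(w), float(y0), rss)


def d_sd_first(
    series: IntensitySeries,
    spans: SpanSpec = SpanSpec(),
    seed: int = 0,
    denominator: Literal["fitted_msd", "sample_msd"] = "fitted_msd",
) -> DiffusionTotal:
    """First-order diffusion parameter D_SD per span and its total.

    Within each span the squared-deviation trace (I - <I>)^2 vs time is
    fitted with the SineSqr model, supplying the amplitude A_i.  The
    numerator variance is the raw population variance of the span; the
    denominator mean squared deviation is, by default, the time-average of
    the *fitted* curve over the span, so that fit error is what separates
    D_SD from D''_SD.  ``sample_msd`` uses the raw sample statistic instead,
    which makes the ratio identically 1 and D_SD = K1 * A_i.
    """
    bounds = spans.resolve(len(series))
    per_span = []
    for k, (s, e) in enumerate(bounds):
        t = series.times[s:e]
        seg = series.intensities[s:e]
        var = population_variance(seg)
        dev2 = (seg - seg.mean()) ** 2
        fit = fit_sinesqr(t, dev2, seed=seed + k) if len(t) >= 4 else None
        if fit is None or fit.degenerate:
            a_i = 0.0
            msd = var
        else:
            a_i = fit.amplitude_A
            msd = float(np.mean(fit(t))) if denominator == "fitted_msd" else var
        if msd <= 0.0:
            if a_i != 0.0:
                warnings.warn("degenerate SineSqr denominator; D_SD set to 0", stacklevel=2)
            d1 = 0.0
        else:
            d1 = K1 * a_i * var / msd
        per_span.append(
            DiffusionEstimate(
                span=(s, e),
                mean_I=float(seg.mean()),
                var_I=var,
                d_second=K2 * var,
                d_first=max(d1, 0.0),
                A_i=a_i,
            )
        )
    return DiffusionTotal(
        per_span=per_span,
        d_second_tot=sum(p.d_second for p in per_span),
        d_first_tot=sum(p.d_first for p in per_span),
    )


def d_prime_vs_dsecond(
    series_list: Sequence[IntensitySeries],
    spans: SpanSpec = SpanSpec(),
    seed: int = 0,
    denominator: Literal["fitted_msd", "sample_msd"] = "fitted_msd",
) -> CorrelationRecord:
    """Pearson correlation between per-series D_SD,tot and D''_SD,tot."""
    if len(series_list) < 3:
        raise ValidationError("need at least 3 series to correlate D' with D''")
    d1, d2 = [], []
    for k, series in enumerate(series_list):
        tot = d_sd_first(series, spans, seed=seed + 1000 * k, denominator=denominator)
        d1.append(tot.d_first_tot)
        d2.append(tot.d_second_tot)
    lr = linregress(d2, d1)
    return CorrelationRecord(
        r=float(lr.rvalue), slope=float(lr.slope), intercept=float(lr.intercept), n=len(d1)
    )


def eq4_profile(
    ce_points: Sequence[tuple[float, float, float]], seed: int = 0
) -> CEProfile:
    """Collision-energy intensity relation for one fragment ion.

    ``ce_points`` holds (CE, D''_SD,tot, <I>_exp) triples.  Both profiles are
    fitted with the SineSqr model against CE; the two amplitudes A_D and A_I
    convert each D''_SD,tot into a theoretical mean intensity
    0.5 * (A_I/A_D) * D''_SD,tot, reported together with the Pearson r
    between theoretical and experimental intensities.
    """
    pts = sorted(ce_points)
    if len(pts) < 4:
        raise ValidationError("eq4_profile needs at least 4 CE points")
    ce = np.array([p[0] for p in pts], dtype=float)
    d2 = np.array([p[1] for p in pts], dtype=float)
    mi = np.array([p[2] for p in pts], dtype=float)
    fit_d = fit_sinesqr(ce, d2, seed=seed)
    fit_i = fit_sinesqr(ce, mi, seed=seed + 1)
    if fit_d.amplitude_A == 0.0:
        raise DegeneracyError("A_D = 0: the CE intensity relation is undefined")
    theor = 0.5 * (fit_i.amplitude_A / fit_d.amplitude_A) * d2
    r = float(pearsonr(theor, mi).statistic)
    return CEProfile(
        collision_energies=ce,
        d_second_values=d2,
        mean_intensities=mi,
        fit_d=fit_d,
        fit_i=fit_i,
        theoretical_intensities=theor,
        pearson_r=r,
    )
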