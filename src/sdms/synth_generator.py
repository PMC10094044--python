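"""Seeded synthetic scan-series generators.

The generators emulate the statistical structure the stochastic-dynamic
method relies on — per-scan intensity fluctuation with a controlled
variance, overlapping Gaussian m/z clouds standing in for tautomer mixtures,
and a concentration-dependent intensity variance for calibration — so that
every stage of the pipeline is exercisable without instrument data.

The calibration scenario uses a log-linear variance law,

    ln var(I | conc) = a + b * conc ,

under which ln[D''_SD] = f(conc.) is exactly linear by construction: the
second-order diffusion parameter is proportional to the intensity variance,
so the log transform maps the law onto a straight line whose slope is b.
They do not emulate chromatographic peak shapes, ion suppression, or matrix
effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import ValidationError
from .scan_io import Scan, ScanSeries


@dataclass(frozen=True)
class SpeciesSpec:
    """One emitting ion species: an m/z cloud plus an intensity noise model.

    ``noise_model``: ``gaussian`` draws intensity base + N(0, gaussian_sd)
    clipped at zero; ``poisson`` draws Poisson(base_intensity).
    """

    mean_mz: float
    mz_sd: float = 0.0
    base_intensity: float = 1e5
    noise_model: Literal["gaussian", "poisson"] = "gaussian"
    gaussian_sd: float = 0.0
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.mz_sd < 0:
            raise ValidationError("mz_sd must be >= 0")
        if self.base_intensity < 0:
            raise ValidationError("base_intensity must be >= 0")
        if self.gaussian_sd < 0:
            raise ValidationError("gaussian_sd must be >= 0")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValidationError(f"unknown noise model {self.noise_model!r}")


@dataclass(frozen=True)
class CalibrationScenario:
    """Concentration grid plus the log-linear variance law that drives it.

    Defaults follow the calibration range of low-level biocide biomonitoring:
    concentrations 2-80 ng/mL, a base intensity high enough that gaussian
    clipping at zero is negligible, and a variance law spanning roughly six
    ln-units across the grid.
    """

    concentrations: tuple[float, ...] = (2.0, 6.0, 10.0, 20.0, 40.0, 80.0)
    log_var_intercept: float = 16.0  # a in ln var = a + b*conc
    log_var_slope: float = 0.08     # b, per ng/mL
    base_intensity: float = 1e6
    mean_mz: float = 212.209
    mz_sd: float = 0.03
    scans_per_level: int = 100
    dt: float = 0.01  # minutes
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.concentrations) == 0:
            raise ValidationError("concentration grid is empty")
        if self.scans_per_level < 2:
            raise ValidationError("scans_per_level must be >= 2")

    def variance_at(self, conc: float) -> float:
        return float(np.exp(self.log_var_intercept + self.log_var_slope * conc))


def simulate_srm(
    species: Sequence[SpeciesSpec],
    n_scans: int,
    dt: float = 0.01,
    seed: int = 0,
    segment_label: str = "synthetic",
    collision_energy: float | None = None,
) -> ScanSeries:
    """Simulate an SRM-style series: one centroid per species per scan.

    Per scan, each species emits m/z ~ Normal(mean_mz, mz_sd) and an
    intensity from its noise model (weighted by ``weight``).  Deterministic
    for a fixed seed.
    """
    if n_scans < 2:
        raise ValidationError("n_scans must be >= 2")
    if not species:
        raise ValidationError("need at least one species")
    if dt <= 0:
        raise ValidationError("dt must be > 0")
    rng = np.random.default_rng(seed)
    scans = []
    for i in range(n_scans):
        peaks = []
        for sp in species:
            mz = rng.normal(sp.mean_mz, sp.mz_sd) if sp.mz_sd > 0 else sp.mean_mz
            if sp.noise_model == "poisson":
                inten = float(rng.poisson(sp.base_intensity))
            else:
                inten = sp.base_intensity + (
                    rng.normal(0.0, sp.gaussian_sd) if sp.gaussian_sd > 0 else 0.0
                )
            peaks.append((mz, max(inten * sp.weight, 0.0)))
        scans.append(Scan(index=i, time=i * dt, peaks=tuple(peaks)))
    metadata = {"instrument_mode": "SRM"}
    if collision_energy is not None:
        metadata["collision_energy"] = collision_energy
    return ScanSeries(scans=scans, segment_label=segment_label, metadata=metadata)


def simulate_calibration(scenario: CalibrationScenario) -> dict[float, ScanSeries]:
    """One ScanSeries per concentration level under the scenario's variance law."""
    out: dict[float, ScanSeries] = {}
    for k, conc in enumerate(scenario.concentrations):
        sd = float(np.sqrt(scenario.variance_at(conc)))
        sp = SpeciesSpec(
            mean_mz=scenario.mean_mz,
            mz_sd=scenario.mz_sd,
            base_intensity=scenario.base_intensity,
            gaussian_sd=sd,
        )
        out[conc] = simulate_srm(
            [sp],
            n_scans=scenario.scans_per_level,
            dt=scenario.dt,
            seed=scenario.seed + 7919 * (k + 1),
            segment_label=f"calib_c{conc:g}",
        )
    return out
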