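"""Quantum-chemical diffusion parameter and structure-assignment correlation.

D_QC blends transition-state-theory ingredients: the ratio of the product of
ground-state vibrational wavenumbers to the product of transition-state
wavenumbers (one fewer mode — the reactive mode is gone), damped by an
Arrhenius factor in the activation enthalpy,

    D_QC = ( prod_i nu_i^0 / prod_i nu_i^s ) * exp( -dH‡ / (R * T) ) .

Frequency products over dozens of modes overflow double precision, so the
evaluation is carried out entirely in log space.  Wavenumbers are used as
given in cm^-1; their unit cancels in the ratio up to one leftover factor,
and no unit is attached to D_QC.

Structure assignment: for a set of ions with measured D''_SD values and one
or more candidate geometries each (tautomers), the candidate combination
whose D_QC values correlate best (highest |r|) with the measured D''_SD is
the assigned set of structures.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import linregress

from .errors import ValidationError

#: molar gas constant in hartree per kelvin (activation enthalpies in a.u.)
R_HARTREE_PER_K = 3.1668116e-6
#: molar gas constant in kJ per mol per kelvin
R_KJ_PER_MOL_K = 8.31446262e-3
#: one hartree in kJ/mol, for converting activation enthalpies between modes
HARTREE_IN_KJ_PER_MOL = 2625.49964

_GAS_CONSTANTS = {"hartree": R_HARTREE_PER_K, "kJ/mol": R_KJ_PER_MOL_K}


def kj_per_mol_to_hartree(value: float) -> float:
    """Convert an energy from kJ/mol to hartree (atomic units)."""
    return value / HARTREE_IN_KJ_PER_MOL


@dataclass
class QCIonModel:
    """Vibrational and energetic inputs for one candidate ion structure.

    ``ts_wavenumbers`` must hold exactly one mode fewer than
    ``gs_wavenumbers``; imaginary (non-positive) transition-state modes must
    be removed by the caller — they are rejected, never silently dropped.
    ``activation_enthalpy`` is interpreted in ``enthalpy_unit`` (default
    hartree, matching quantum-chemistry output).
    """

    label: str
    gs_wavenumbers: Sequence[float]
    ts_wavenumbers: Sequence[float]
    activation_enthalpy: float = 0.0
    temperature: float = 298.15
    enthalpy_unit: str = "hartree"

    def __post_init__(self) -> None:
        gs = np.asarray(self.gs_wavenumbers, dtype=float)
        ts = np.asarray(self.ts_wavenumbers, dtype=float)
        if gs.size == 0:
            raise ValidationError(f"{self.label}: empty ground-state frequency list")
        if ts.size != gs.size - 1:
            raise ValidationError(
                f"{self.label}: expected {gs.size - 1} transition-state wavenumbers, got {ts.size}"
            )
        if np.any(gs <= 0) or np.any(ts <= 0):
            raise ValidationError(f"{self.label}: wavenumbers must be > 0")
        if self.temperature <= 0:
            raise ValidationError(f"{self.label}: temperature must be > 0")
        if self.enthalpy_unit not in _GAS_CONSTANTS:
            raise ValidationError(
                f"{self.label}: enthalpy unit {self.enthalpy_unit!r} not in "
                f"{sorted(_GAS_CONSTANTS)}"
            )
        self.gs_wavenumbers = gs
        self.ts_wavenumbers = ts


@dataclass
class StructureCorrelation:
    ion_labels: list[str]
    d_second_values: np.ndarray
    d_qc_values: np.ndarray
    pearson_r: float
    slope: float
    slope_sd: float
    intercept: float
    intercept_sd: float


def d_qc(model: QCIonModel) -> float:
    """Evaluate D_QC wholly in log space (frequency products overflow)."""
    r = _GAS_CONSTANTS[model.enthalpy_unit]
    log_val = (
        float(np.sum(np.log(model.gs_wavenumbers)))
        - float(np.sum(np.log(model.ts_wavenumbers)))
        - model.activation_enthalpy / (r * model.temperature)
    )
    return math.exp(log_val)


def delta_d_qc(a: float, b: float) -> float:
    """Absolute difference |a - b| between two D_QC values."""
    if not (math.isfinite(a) and math.isfinite(b)):
        raise ValidationError("delta_d_qc requires finite inputs")
    return abs(a - b)


def correlate_structure(
    d_second: Sequence[float], d_qc_values: Sequence[float], labels: Sequence[str] | None = None
) -> StructureCorrelation:
    """Pearson correlation and fitted line of D''_SD against D_QC.

    |r| near 1 is the structure-confirmation criterion: the measured
    diffusion parameters of a consistent set of ions scale with their
    theoretical D_QC values.
    """
    d2 = np.asarray(d_second, dtype=float)
    dq = np.asarray(d_qc_values, dtype=float)
    if d2.size != dq.size:
        raise ValidationError("d_second and d_qc lists must have equal length")
    if d2.size < 3:
        raise ValidationError("correlate_structure needs at least 3 ions")
    if labels is None:
        labels = [f"ion_{i}" for i in range(d2.size)]
    elif len(labels) != d2.size:
        raise ValidationError("labels length mismatch")
    lr = linregress(dq, d2)
    return StructureCorrelation(
        ion_labels=list(labels),
        d_second_values=d2,
        d_qc_values=dq,
        pearson_r=float(lr.rvalue),
        slope=float(lr.slope),
        slope_sd=float(lr.stderr),
        intercept=float(lr.intercept),
        intercept_sd=float(lr.intercept_stderr),
    )


def assign_structures(
    d_second: Sequence[float],
    candidate_models: Mapping[str, Sequence[QCIonModel]],
    cap: int = 10**6,
) -> tuple[dict[str, QCIonModel], StructureCorrelation]:
    """Exhaustive search over candidate structures maximizing |r|.

    Every ion must offer at least one candidate.  The product space of
    candidate combinations is enumerated (refused above ``cap``); ties in
    |r| break deterministically toward earlier-listed candidates.
    """
    ions = list(candidate_models)
    if len(ions) != len(d_second):
        raise ValidationError("one measured D''_SD per ion is required")
    if len(ions) < 3:
        raise ValidationError("assign_structures needs at least 3 ions")
    for ion in ions:
        if len(candidate_models[ion]) == 0:
            raise ValidationError(f"ion {ion!r} has no candidate structures")
    space = 1
    for ion in ions:
        space *= len(candidate_models[ion])
        if space > cap:
            raise ValidationError(
                f"candidate product space exceeds cap {cap}; prune candidates per ion "
                "or raise the cap explicitly"
            )
    d_qc_cache = {ion: [d_qc(m) for m in candidate_models[ion]] for ion in ions}
    best_combo = None
    best_corr = None
    for combo in itertools.product(*(range(len(candidate_models[i])) for i in ions)):
        dq = [d_qc_cache[ion][c] for ion, c in zip(ions, combo)]
        if np.ptp(dq) == 0:
            continue
        corr = correlate_structure(d_second, dq, labels=ions)
        if best_corr is None or abs(corr.pearson_r) > abs(best_corr.pearson_r):
            best_corr = corr
            best_combo = combo
    if best_corr is None:
        raise ValidationError("no candidate combination yields a non-degenerate correlation")
    assignment = {
        ion: candidate_models[ion][c] for ion, c in zip(ions, best_combo)
    }
    return assignment, best_corr
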