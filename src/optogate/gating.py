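"""Dose-response and activation-curve fitting.

Turns idealization outputs (bright-state probabilities P_L1 per agonist
concentration) and electrophysiology tables into comparable activation
curves: linear subtraction of the dye-blink baseline, normalization to the
maximal response (F/F_max), Hill fits R = R_max c^n / (c^n + EC50^n), and
Boltzmann fits I = I_max / (1 + exp(-zF(V - V_0.5)/RT)) for conductance-
voltage data, plus a side-by-side comparison of optically and electrically
determined EC50 values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import lmfit

from .synth import FARADAY, GAS_CONSTANT, boltzmann_current

__all__ = [
    "BLINK_FRACTION",
    "DoseResponse",
    "GVModel",
    "ComparisonReport",
    "correct_blinking",
    "normalize",
    "fit_hill",
    "fit_boltzmann",
    "compare_optical_electrical",
    "read_dose_table",
    "read_gv_table",
]

#: Fraction of positive transitions shown by surface-deposited free dye;
#: subtracted linearly from raw P_L1 points as the blink baseline.
BLINK_FRACTION = 0.12


def correct_blinking(p_l1_raw, blink_fraction: float = BLINK_FRACTION):
    """Subtract the dye-blink baseline from raw P_L1, flooring at zero.

    Returns ``(corrected, floored)``; ``floored`` flags points clipped to
    zero (their raw value was below the baseline).  Accepts scalars or
    arrays.
    """
    p = np.asarray(p_l1_raw, dtype=float)
    if np.any((p < 0) | (p > 1)) or not 0 <= blink_fraction <= 1:
        raise ValueError("probabilities must be within [0, 1]")
    corrected = p - blink_fraction
    floored = corrected < 0
    corrected = np.where(floored, 0.0, corrected)
    if np.isscalar(p_l1_raw):
        return float(corrected), bool(floored)
    return corrected, floored


def normalize(values, reference_max: float):
    """Divide responses by the maximal response (F/F_max convention)."""
    if reference_max <= 0:
        raise ValueError("reference_max must be positive")
    return np.asarray(values, dtype=float) / reference_max


@dataclass
class DoseResponse:
    """Hill-fit summary of a dose-response series.

    ``responses`` keeps the series that was fitted; EC50 is in uM.  ``se``
    maps parameter name to standard error (may hold inf when the fit is
    unidentifiable, flagged by ``identifiable``).
    """

    concentrations: np.ndarray
    responses: np.ndarray
    ec50: float
    hill_n: float
    response_max: float
    se: dict[str, float] = field(default_factory=dict)
    identifiable: bool = True

    def predict(self, concentrations) -> np.ndarray:
        c = np.asarray(concentrations, dtype=float)
        cn = np.power(c, self.hill_n)
        return self.response_max * cn / (cn + self.ec50 ** self.hill_n)


def fit_hill(concentrations, responses, fix_hill_n: float | None = None,
             sem=None) -> DoseResponse:
    """Least-squares Hill fit R = R_max c^n / (c^n + EC50^n).

    Needs at least four distinct concentrations spanning the inflection.
    When per-point SEMs are given the fit is weighted by 1/SEM.  The Hill
    coefficient is fitted by default and can be fixed.  A saturating-only
    series (no information about EC50) yields ``identifiable=False`` with
    infinite EC50 standard error.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if np.unique(c).size < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if np.allclose(r, r[0]):
        raise ValueError("responses carry no dose dependence")
    weights = None
    if sem is not None:
        sem = np.asarray(sem, dtype=float)
        weights = 1.0 / np.where(sem > 0, sem, np.nanmin(sem[sem > 0]))

    pos = c[c > 0]
    params = lmfit.Parameters()
    params.add("rmax", value=float(r.max()), min=0.0)
    params.add("ec50", value=float(np.exp(np.mean(np.log(pos)))), min=1e-9)
    params.add("n", value=fix_hill_n if fix_hill_n is not None else 1.5,
               min=0.1, max=10.0, vary=fix_hill_n is None)

    def residual(p):
        cn = np.power(c, p["n"].value)
        model = p["rmax"].value * cn / (cn + p["ec50"].value ** p["n"].value)
        res = model - r
        return res * weights if weights is not None else res

    result = lmfit.minimize(residual, params, method="leastsq")
    if not result.success:
        raise RuntimeError("Hill fit did not converge")
    se = {}
    identifiable = result.errorbars
    for name in ("rmax", "ec50", "n"):
        par = result.params[name]
        se[name] = float(par.stderr) if (par.stderr is not None and identifiable) else np.inf
    return DoseResponse(
        concentrations=c, responses=r,
        ec50=float(result.params["ec50"].value),
        hill_n=float(result.params["n"].value),
        response_max=float(result.params["rmax"].value),
        se=se, identifiable=bool(identifiable and np.isfinite(se["ec50"])),
    )


@dataclass
class GVModel:
    """Boltzmann activation fit of a conductance/current-voltage relation."""

    v_half: float
    z_valence: float
    i_max: float
    se: dict[str, float] = field(default_factory=dict)
    faraday: float = FARADAY
    gas_const: float = GAS_CONSTANT
    temperature: float = 293.15

    def predict(self, voltages_mV) -> np.ndarray:
        return boltzmann_current(voltages_mV, self.v_half, self.z_valence,
                                 self.i_max, self.temperature)


def fit_boltzmann(voltages_mV, currents, temperature: float = 293.15) -> GVModel:
    """Fit I = I_max / (1 + exp(-zF(V - V_0.5)/RT)) to a G-V table.

    Voltages in mV.  Needs at least five voltages bracketing the midpoint; a
    flat relation (z -> 0) is rejected as unidentifiable.  V_0.5 and z are
    invariant under rescaling the current units.
    """
    v = np.asarray(voltages_mV, dtype=float)
    i = np.asarray(currents, dtype=float)
    if v.size < 5:
        raise ValueError("need at least 5 voltages")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    span = np.ptp(i)
    if span <= 0 or span < 1e-6 * np.max(np.abs(i), initial=1.0):
        raise ValueError("flat curve: Boltzmann parameters are unidentifiable")

    half = i.min() + span / 2
    v0 = float(v[np.argmin(np.abs(i - half))])
    params = lmfit.Parameters()
    params.add("v_half", value=v0)
    params.add("z", value=1.0, min=1e-3, max=50.0)
    params.add("i_max", value=float(i.max()))

    def residual(p):
        model = boltzmann_current(v, p["v_half"].value, p["z"].value,
                                  p["i_max"].value, temperature)
        return model - i

    result = lmfit.minimize(residual, params, method="leastsq")
    if not result.success:
        raise RuntimeError("Boltzmann fit did not converge")
    se = {}
    for name, key in (("v_half", "v_half"), ("z", "z_valence"), ("i_max", "i_max")):
        par = result.params[name]
        se[key] = float(par.stderr) if par.stderr is not None else np.inf
    return GVModel(v_half=float(result.params["v_half"].value),
                   z_valence=float(result.params["z"].value),
                   i_max=float(result.params["i_max"].value),
                   se=se, temperature=temperature)


@dataclass
class ComparisonReport:
    """Optical vs electrical EC50 comparison."""

    ec50_optical: float
    ec50_electrical: float
    ratio: float
    difference: float
    z_score: float
    mismatch: bool
    overlay: pd.DataFrame


def compare_optical_electrical(optical: DoseResponse,
                               electrical: DoseResponse,
                               n_grid: int = 50) -> ComparisonReport:
    """Compare EC50 values from the two arms and overlay their curves.

    ``ratio`` is optical/electrical, ``difference`` the absolute EC50
    difference (uM).
    The overlap test is a normal z-score from the fitted standard errors;
    ``mismatch`` flags disjoint 95% confidence intervals.  The overlay table
    tabulates both normalized curves on a shared log-spaced grid.
    """
    e1, e2 = optical.ec50, electrical.ec50
    s1 = optical.se.get("ec50", np.inf)
    s2 = electrical.se.get("ec50", np.inf)
    pooled = np.sqrt(s1 ** 2 + s2 ** 2)
    z = (e1 - e2) / pooled if np.isfinite(pooled) and pooled > 0 else 0.0
    lo1, hi1 = e1 - 1.96 * s1, e1 + 1.96 * s1
    lo2, hi2 = e2 - 1.96 * s2, e2 + 1.96 * s2
    mismatch = hi1 < lo2 or hi2 < lo1

    cmin = min(e1, e2) / 30
    cmax = max(e1, e2) * 30
    grid = np.geomspace(cmin, cmax, n_grid)
    overlay = pd.DataFrame({
        "concentration_uM": grid,
        "optical": optical.predict(grid) / optical.response_max,
        "electrical": electrical.predict(grid) / electrical.response_max,
    })
    return ComparisonReport(ec50_optical=e1, ec50_electrical=e2,
                            ratio=e1 / e2, difference=abs(e1 - e2), z_score=float(z),
                            mismatch=bool(mismatch), overlay=overlay)


def read_dose_table(path) -> pd.DataFrame:
    """Read a dose table CSV (concentration_uM, response[, sem, n])."""
    frame = pd.read_csv(path)
    if "concentration_uM" not in frame or "response" not in frame:
        raise ValueError("dose table needs concentration_uM and response columns")
    return frame


def read_gv_table(path) -> pd.DataFrame:
    """Read a G-V table CSV (voltage_mV, current)."""
    frame = pd.read_csv(path)
    if "voltage_mV" not in frame or "current" not in frame:
        raise ValueError("G-V table needs voltage_mV and current columns")
    return frame
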