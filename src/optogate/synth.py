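"""Synthetic inputs with the statistical structure the analysis assumes.

The generative picture is a single fluorescent spot on a cell membrane imaged
at 500 Hz: a channel gate modelled as a slow two-state telegraph whose opening
rate depends on agonist concentration through a Hill relation, multiplied per
fluorophore by a fast blinking telegraph and an irreversible photobleaching
survival indicator, summed over the fluorophores in the spot, time-averaged
over each camera exposure, and read out with additive Gaussian camera noise.

Also provided: Poisson photon-count frame stacks mimicking a 64x32 SPAD
imager, binomial subunit-labelling stoichiometry for tetramers under diluted
co-transfection, Boltzmann-activation current tables, dose-response series,
and toy pore structures with four planar side-chain groups in "horizontal
ring" (open) or "vertical" (closed) configuration plus placed waters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .trace import FluorescenceTrace
from .pore import PoreEnsemble

__all__ = [
    "EmitterModel",
    "TelegraphPath",
    "PoreFixture",
    "simulate_telegraph",
    "hill_open_rate",
    "simulate_emitter_trace",
    "simulate_photon_frames",
    "subunit_stoichiometry",
    "boltzmann_current",
    "simulate_gv_currents",
    "simulate_dose_series",
    "make_pore_fixture",
]

#: Gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.314
#: Faraday constant, C mol^-1.
FARADAY = 96485.0


@dataclass
class EmitterModel:
    """Generative parameters of one fluorescent spot.

    Rates are in s^-1, concentrations in uM, intensities in arbitrary camera
    units.  ``k_open_max`` is the dark->bright gating rate at saturating
    agonist; the agonist scales the opening rate only (the closing rate is
    concentration independent), which reproduces the observed lengthening of
    bright bursts with agonist.  Blinking is a fast two-state telegraph
    intrinsic to the dye; bleaching is a single irreversible step per
    fluorophore.

    Defaults describe a saturating-agonist bright dwell of ~156 ms
    (k_close = 6.41 s^-1), a mostly-emitting dye (~9% dark from blinking),
    bleaching within a minute of illumination, and a spot signal-to-noise
    ratio of 10.
    """

    k_open_max: float = 4.0
    k_close: float = 6.41
    ec50: float = 0.33
    hill_n: float = 2.0
    k_blink_off: float = 0.5
    k_blink_on: float = 5.0
    k_bleach: float = 0.05
    brightness: float = 10.0
    bg_mean: float = 100.0
    bg_sd: float = 1.0
    n_fluors: int = 1

    def __post_init__(self) -> None:
        rates = (self.k_open_max, self.k_close, self.k_blink_off,
                 self.k_blink_on, self.k_bleach)
        if any(r < 0 for r in rates):
            raise ValueError("rates must be non-negative")
        if self.ec50 <= 0 or self.hill_n <= 0:
            raise ValueError("ec50 and hill_n must be positive")
        if self.bg_sd <= 0:
            raise ValueError("bg_sd must be positive")
        if int(self.n_fluors) != self.n_fluors or self.n_fluors < 1:
            raise ValueError("n_fluors must be an integer >= 1")
        self.n_fluors = int(self.n_fluors)


@dataclass
class TelegraphPath:
    """Right-continuous piecewise-constant two-state path.

    ``switch_times`` are the transition instants (strictly increasing, within
    (0, duration)); ``states`` gives the state on each of the
    ``len(switch_times) + 1`` constant intervals and alternates between 0
    and 1.
    """

    switch_times: np.ndarray
    states: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        self.switch_times = np.asarray(self.switch_times, dtype=float)
        self.states = np.asarray(self.states, dtype=int)
        if self.states.size != self.switch_times.size + 1:
            raise ValueError("states must have one more entry than switch_times")
        if self.switch_times.size and (
            np.any(np.diff(self.switch_times) <= 0)
            or self.switch_times[0] <= 0
            or self.switch_times[-1] >= self.duration
        ):
            raise ValueError("switch_times must be strictly increasing within (0, duration)")
        if self.states.size > 1 and np.any(np.abs(np.diff(self.states)) != 1):
            raise ValueError("states must alternate")

    @property
    def breakpoints(self) -> np.ndarray:
        """Interval start times, beginning at 0."""
        return np.concatenate([[0.0], self.switch_times])

    def occupancy(self, state: int = 1) -> float:
        """Fraction of total time spent in ``state``."""
        edges = np.concatenate([self.breakpoints, [self.duration]])
        lengths = np.diff(edges)
        return float(lengths[self.states == state].sum() / self.duration)

    def dwell_times(self, state: int) -> np.ndarray:
        """Durations of all visits to ``state`` (boundary visits included)."""
        edges = np.concatenate([self.breakpoints, [self.duration]])
        lengths = np.diff(edges)
        return lengths[self.states == state]

    def value_at(self, t: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.breakpoints, np.asarray(t), side="right") - 1
        return self.states[idx]

    def bin_average(self, dt: float, n_bins: int | None = None) -> np.ndarray:
        """Time-average of the path over consecutive bins of width ``dt``.

        Models camera integration over each exposure.  Exact: uses the
        piecewise-linear cumulative integral of the step function.
        """
        if n_bins is None:
            n_bins = int(round(self.duration / dt))
        return _bin_average(self.breakpoints, self.states.astype(float),
                            self.duration, dt, n_bins)


def _bin_average(breaks: np.ndarray, values: np.ndarray, duration: float,
                 dt: float, n_bins: int) -> np.ndarray:
    """Average a piecewise-constant path over uniform bins (exact)."""
    t = np.concatenate([breaks, [duration]])
    seg = np.diff(t)
    cum = np.concatenate([[0.0], np.cumsum(values * seg)])
    edges = np.arange(n_bins + 1) * dt
    cum_at = np.interp(edges, t, cum)
    return np.diff(cum_at) / dt


def simulate_telegraph(k01: float, k10: float, duration: float,
                       seed: int | np.random.Generator) -> TelegraphPath:
    """Continuous-time two-state Markov chain with exponential holding times.

    ``k01`` is the 0->1 rate, ``k10`` the 1->0 rate.  The initial state is
    drawn from the stationary distribution P(1) = k01/(k01+k10).  With one
    rate zero the stationary distribution puts all mass on the absorbing
    state, so the path is constant.
    """
    if k01 < 0 or k10 < 0:
        raise ValueError("rates must be non-negative")
    if k01 == 0 and k10 == 0:
        raise ValueError("degenerate chain: both rates are zero")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)

    if k01 == 0 or k10 == 0:
        s0 = 0 if k01 == 0 else 1
        return TelegraphPath(np.empty(0), np.array([s0]), duration)

    s0 = int(rng.random() < k01 / (k01 + k10))
    mean_switch_rate = 2 * k01 * k10 / (k01 + k10)
    pieces: list[np.ndarray] = []
    t = 0.0
    total = 0
    while t < duration:
        n = max(64, int((duration - t) * mean_switch_rate * 1.2) + 16)
        parity = (s0 + total + np.arange(n)) % 2  # state during each dwell
        rates = np.where(parity == 1, k10, k01)
        times = t + np.cumsum(rng.exponential(1.0, n) / rates)
        m = int(np.searchsorted(times, duration))
        pieces.append(times[:m])
        total += m
        if m < n:
            break
        t = times[-1]

    switch_times = np.concatenate(pieces) if pieces else np.empty(0)
    states = (s0 + np.arange(total + 1)) % 2
    return TelegraphPath(switch_times=switch_times, states=states,
                         duration=duration)


def hill_open_rate(concentration, model: EmitterModel):
    """Agonist-dependent opening rate, k_open_max * c^n / (c^n + ec50^n).

    Zero at zero agonist and saturating at ``k_open_max``; the half-maximal
    concentration is ``model.ec50``.
    """
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    cn = np.power(c, model.hill_n)
    out = model.k_open_max * cn / (cn + model.ec50 ** model.hill_n)
    return float(out) if np.isscalar(concentration) else out


def _path_value_at(breaks: np.ndarray, values: np.ndarray, t: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(breaks, t, side="right") - 1
    return values[idx]


def simulate_emitter_trace(model: EmitterModel, concentration: float,
                           duration: float, dt: float,
                           seed: int | np.random.Generator) -> FluorescenceTrace:
    """Simulate one spot's 500 Hz-style intensity trace.

    Per fluorophore, intensity(t) = brightness * gate(t) * blink(t) *
    [t < t_bleach]; the gating telegraph is shared by the spot (it reports the
    channel), blinking and bleaching are independent per fluorophore.  Each
    sample is the time-average of the continuous path over its dt window
    (camera integration), plus Gaussian background noise.  Setting both blink
    rates (or both gating rates) to zero disables that process, leaving the
    corresponding factor at 1.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < 10 * dt:
        raise ValueError("duration must be at least 10*dt")
    rng = np.random.default_rng(seed)
    n_bins = int(round(duration / dt))
    duration = n_bins * dt

    k_open = hill_open_rate(concentration, model)
    if k_open == 0 and model.k_close == 0:
        gate = None  # gating disabled: channel treated as always bright
    else:
        gate = simulate_telegraph(k_open, model.k_close, duration, rng)

    total = np.zeros(n_bins)
    for _ in range(model.n_fluors):
        if model.k_blink_off == 0 and model.k_blink_on == 0:
            blink = None
        else:
            blink = simulate_telegraph(model.k_blink_on, model.k_blink_off,
                                       duration, rng)
        t_bleach = np.inf if model.k_bleach == 0 else rng.exponential(1.0 / model.k_bleach)

        breaks = [np.array([0.0])]
        if gate is not None:
            breaks.append(gate.switch_times)
        if blink is not None:
            breaks.append(blink.switch_times)
        if t_bleach < duration:
            breaks.append(np.array([t_bleach]))
        merged = np.unique(np.concatenate(breaks))
        value = np.ones(merged.size)
        if gate is not None:
            value = value * _path_value_at(gate.breakpoints, gate.states.astype(float), merged)
        if blink is not None:
            value = value * _path_value_at(blink.breakpoints, blink.states.astype(float), merged)
        if t_bleach < duration:
            value = value * (merged < t_bleach)
        total += _bin_average(merged, value, duration, dt, n_bins)

    values = model.brightness * total + rng.normal(model.bg_mean, model.bg_sd, n_bins)
    return FluorescenceTrace(values=values, dt=dt)


def simulate_photon_frames(lambda_bg: float, lambda_spot: float,
                           spot_pixels, shape: tuple[int, int] = (32, 64),
                           n_frames: int = 1000,
                           seed: int | np.random.Generator = 0) -> np.ndarray:
    """Poisson photon-count frame stack mimicking a 32x64 SPAD imager.

    Every pixel is an independent Poisson counter with rate ``lambda_bg``
    photons/frame; pixels listed in ``spot_pixels`` (iterable of (row, col))
    count at ``lambda_bg + lambda_spot``.  Returns an integer array of shape
    (n_frames, rows, cols).
    """
    if lambda_bg < 0 or lambda_spot < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    rate = np.full(shape, float(lambda_bg))
    for r, c in spot_pixels:
        if not (0 <= r < shape[0] and 0 <= c < shape[1]):
            raise ValueError(f"spot pixel {(r, c)} outside frame shape {shape}")
        rate[r, c] += lambda_spot
    return rng.poisson(rate, size=(n_frames,) + tuple(shape))


def subunit_stoichiometry(labeled_fraction: float) -> np.ndarray:
    """P(k labelled subunits), k = 0..4, for a tetramer.

    Under dilute co-transfection (e.g. 7:1 wild-type:tagged, labelled
    fraction 1/8) each of the four subunits is labelled independently, so the
    count is Binomial(4, labeled_fraction).
    """
    if not 0 <= labeled_fraction <= 1:
        raise ValueError("labeled_fraction must be in [0, 1]")
    return stats.binom.pmf(np.arange(5), 4, labeled_fraction)


def boltzmann_current(voltages_mV, v_half: float, z_valence: float,
                      i_max: float, temperature: float = 293.15) -> np.ndarray:
    """Noiseless Boltzmann activation curve I(V) = I_max/(1+exp(-zF(V-V0.5)/RT)).

    Voltages in mV; increases with V for z > 0 and passes through I_max/2 at
    ``v_half``.
    """
    v = np.asarray(voltages_mV, dtype=float)
    x = -z_valence * FARADAY * (v - v_half) * 1e-3 / (GAS_CONSTANT * temperature)
    return i_max / (1.0 + np.exp(x))


def simulate_gv_currents(voltages_mV, v_half: float = 100.0,
                         z_valence: float = 1.0, i_max: float = 1.0,
                         temperature: float = 293.15, noise_sd: float = 0.0,
                         seed: int | np.random.Generator = 0):
    """Voltage-current table: Boltzmann activation plus Gaussian noise.

    Default midpoint +100 mV at 20 C (293.15 K).  Returns a pandas DataFrame
    with columns ``voltage_mV`` and ``current``.
    """
    import pandas as pd

    if temperature <= 0:
        raise ValueError("temperature must be positive")
    rng = np.random.default_rng(seed)
    v = np.asarray(voltages_mV, dtype=float)
    i = boltzmann_current(v, v_half, z_valence, i_max, temperature)
    if noise_sd > 0:
        i = i + rng.normal(0.0, noise_sd, v.shape)
    return pd.DataFrame({"voltage_mV": v, "current": i})


def simulate_dose_series(concentrations, ec50: float = 0.33, hill_n: float = 2.0,
                         response_max: float = 0.5, baseline: float = 0.12,
                         noise_sd: float = 0.05,
                         seed: int | np.random.Generator = 0) -> np.ndarray:
    """Raw dose-response points: Hill curve + constant baseline + noise.

    Emulates an uncorrected P_L1 dose series whose constant offset is the dye
    blink contribution (default 0.12); downstream analysis subtracts the
    baseline, normalizes, and refits.
    """
    rng = np.random.default_rng(seed)
    c = np.asarray(concentrations, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    cn = np.power(c, hill_n)
    resp = response_max * cn / (cn + ec50 ** hill_n) + baseline
    if noise_sd > 0:
        resp = resp + rng.normal(0.0, noise_sd, c.shape)
    return resp


# ---------------------------------------------------------------------------
# Toy pore fixtures


@dataclass
class PoreFixture(PoreEnsemble):
    """A :class:`~optogate.pore.PoreEnsemble` built by :func:`make_pore_fixture`."""

    state_label: str = "open"


def make_pore_fixture(state_label: str = "open",
                      water_number_density: float = 0.0334,
                      n_frames: int = 1, seed: int | np.random.Generator = 0,
                      jitter_sd: float = 0.05) -> PoreFixture:
    """Toy pore: cylindrical wall, four planar side-chain groups, waters.

    Geometry (Angstrom): a z-axis cylinder of wall pseudo-atoms (centers at
    radius 5.5, vdW 1.5, so the accessible bore radius is 4.0) spanning z in
    [-10, 10]; four 3-atom planar "side-chain" groups (residue TYC, chains
    A-D) centred at z = 2.5, lying in the membrane plane for the open state
    ("horizontal ring") or in planes containing the pore axis for the closed
    state ("vertical").  The closed fixture adds a solid plug of atoms at
    z = 4 that occludes the bore above the groups.  Water oxygens (residue
    HOH) are placed uniformly at the requested number density (default bulk
    water, 0.0334 per cubic Angstrom) in accessible space by rejection
    sampling against atom vdW spheres; for the open state one on-axis water
    per 1 A slab is guaranteed so the water column is continuous by
    construction.  Additional frames jitter side-chain and water positions
    with Gaussian noise of ``jitter_sd``.
    """
    if state_label not in ("open", "closed"):
        raise ValueError(f"unknown state_label: {state_label!r}")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)

    z_lo, z_hi = -10.0, 10.0
    bore_radius = 4.0

    # cylindrical wall: rings of atoms, centers at radius 5.5, vdW 1.5
    wall_xyz = []
    ring_z = np.arange(z_lo, z_hi + 1e-9, 1.25)
    n_azim = 24
    for k, z in enumerate(ring_z):
        ang = 2 * np.pi * (np.arange(n_azim) + 0.5 * (k % 2)) / n_azim
        wall_xyz.append(np.stack([5.5 * np.cos(ang), 5.5 * np.sin(ang),
                                  np.full(n_azim, z)], axis=1))
    wall_xyz = np.concatenate(wall_xyz)

    # four planar side-chain groups at z ~= 2.5, chains A-D
    group_xyz = []
    group_chain: list[str] = []
    tri = np.array([[1.0, 0.0],
                    [-0.5, np.sqrt(3) / 2],
                    [-0.5, -np.sqrt(3) / 2]])  # unit triangle in plane coords
    for g, chain in enumerate("ABCD"):
        phi = g * np.pi / 2
        radial = np.array([np.cos(phi), np.sin(phi), 0.0])
        tangent = np.array([-np.sin(phi), np.cos(phi), 0.0])
        center = 4.5 * radial + np.array([0.0, 0.0, 2.5])
        if state_label == "open":
            # plane normal along z: ring parallel to the membrane plane
            e1, e2 = radial, tangent
        else:
            # plane contains the pore axis: normal is tangential
            e1, e2 = radial, np.array([0.0, 0.0, 1.0])
        pts = center + 1.2 * (tri[:, :1] * e1 + tri[:, 1:2] * e2)
        group_xyz.append(pts)
        group_chain += [chain] * 3
    group_xyz = np.concatenate(group_xyz)

    # closed state: solid plug occluding the bore at z = 4 (above the groups)
    plug_xyz = np.empty((0, 3))
    if state_label == "closed":
        g = np.arange(-4.2, 4.2 + 1e-9, 1.3)
        gx, gy = np.meshgrid(g, g)
        keep = gx ** 2 + gy ** 2 <= 4.6 ** 2
        plug_xyz = np.stack([gx[keep], gy[keep], np.full(int(keep.sum()), 4.0)],
                            axis=1)

    protein_xyz = np.concatenate([wall_xyz, group_xyz, plug_xyz])
    protein_radii = np.concatenate([
        np.full(len(wall_xyz), 1.5),
        np.full(len(group_xyz), 1.7),
        np.full(len(plug_xyz), 1.5),
    ])

    # waters: uniform candidates in the bore at the requested density, thinned
    # against vdW spheres -> uniform at that density within accessible space
    volume = np.pi * bore_radius ** 2 * (z_hi - z_lo)
    n_cand = rng.poisson(water_number_density * volume)
    rho = bore_radius * np.sqrt(rng.random(n_cand))
    ang = rng.uniform(0, 2 * np.pi, n_cand)
    wz = rng.uniform(z_lo, z_hi, n_cand)
    cand = np.stack([rho * np.cos(ang), rho * np.sin(ang), wz], axis=1)
    if n_cand:
        d2 = ((cand[:, None, :] - protein_xyz[None, :, :]) ** 2).sum(-1)
        waters = cand[np.all(d2 > protein_radii[None, :] ** 2, axis=1)]
    else:
        waters = np.empty((0, 3))
    if state_label == "open":
        # guarantee a continuous near-axis water column, one per 1 A slab
        # (a water far off-axis may fall outside a pore-radius boundary, so
        # the guarantee requires one within 1 A of the axis)
        slab_edges = np.arange(z_lo, z_hi - 1e-9, 1.0)
        for lo in slab_edges:
            in_slab = ((waters[:, 2] >= lo) & (waters[:, 2] < lo + 1.0)
                       & (np.hypot(waters[:, 0], waters[:, 1]) <= 1.0))
            if not np.any(in_slab):
                waters = np.vstack([waters, [0.0, 0.0, lo + 0.5]])
    n_waters = len(waters)

    n_groups = len(group_xyz)
    i_grp = len(wall_xyz)
    coords = np.empty((n_frames, len(protein_xyz) + n_waters, 3))
    for f in range(n_frames):
        frame_protein = protein_xyz.copy()
        frame_waters = waters.copy()
        if f > 0 and jitter_sd > 0:
            frame_protein[i_grp:i_grp + n_groups] += rng.normal(
                0.0, jitter_sd, (n_groups, 3))
            if n_waters:
                frame_waters = frame_waters + rng.normal(
                    0.0, jitter_sd, (n_waters, 3))
        coords[f, :len(protein_xyz)] = frame_protein
        coords[f, len(protein_xyz):] = frame_waters

    resnames = np.array(
        ["WAL"] * len(wall_xyz) + ["TYC"] * n_groups
        + ["PLG"] * len(plug_xyz) + ["HOH"] * n_waters)
    atomnames = np.array(
        ["C"] * len(wall_xyz) + ["CG"] * n_groups
        + ["C"] * len(plug_xyz) + ["O"] * n_waters)
    chains = np.array(
        ["W"] * len(wall_xyz) + group_chain + ["P"] * len(plug_xyz)
        + ["S"] * n_waters)
    resids = np.concatenate([
        np.repeat(1, len(wall_xyz)),
        np.repeat(np.arange(1, 5), 3),
        np.repeat(2, len(plug_xyz)),
        np.arange(100, 100 + n_waters),
    ]).astype(int)
    radii = np.concatenate([protein_radii, np.full(n_waters, 1.4)])

    return PoreFixture(
        coordinates=coords,
        resnames=resnames,
        atomnames=atomnames,
        chain_ids=chains,
        resids=resids,
        vdw_radii=radii,
        axis_origin=np.zeros(3),
        axis_direction=np.array([0.0, 0.0, 1.0]),
        state_label=state_label,
    )
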