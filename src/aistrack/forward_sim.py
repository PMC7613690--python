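"""Multi-compartment simulation and extracellular forward model.

Somatic current steps evoke action potentials in a compartmental cable model
with Hodgkin-Huxley-style channels (transient Na m^3 h, delayed-rectifier K
n^4, slow non-inactivating Kv7), integrated with a staggered implicit scheme
at a fixed time step (default 2^-5 ms, i.e. 32 kHz sampling).  Extracellular
potentials on the probe are the superposition of all compartments'
transmembrane currents in a homogeneous volume conductor: the line-source
approximation for cylindrical compartments and a point source for the
spherical soma.

Simulation families sweep soma jitter offsets, whole-neuron rotations about
the soma, and AIS positions.  Because rigid rotation/translation leaves the
intracellular solution unchanged, family runners solve the cable equations
once per AIS position and recompute only the electrode transfer matrix per
placement.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .morphology import (
    CM_UF_CM2,
    E_LEAK_MV,
    G_LEAK_S_CM2,
    RA_OHM_CM,
    DEFAULT_DENSITIES,
    ChannelDistribution,
    Morphology,
)
from .probe import Probe

DT_MS = 2.0**-5  # 32 kHz
V_INIT_MV = -75.0
AP_THRESHOLD_MV = 0.0
DEFAULT_SIGMA_S_M = 0.3
DEFAULT_OFFSETS = ((0.0, 0.0), (8.75, 0.0), (0.0, 8.75), (8.75, 8.75))


@dataclass
class SimulationConfig:
    """Grid and solver settings for a simulation family."""

    dt: float = DT_MS  # ms
    duration: float = 30.0  # ms
    stim_amplitude: float | None = None  # nA; None -> 1.5 x rheobase in [0.3, 2]
    stim_delay: float = 2.0  # ms
    stim_duration: float = 20.0  # ms
    soma_offsets: tuple = DEFAULT_OFFSETS  # um, in-plane jitter
    rotation_step_deg: float = 1.0
    ais_positions: tuple = tuple(range(5, 41))  # um
    conductivity_sigma: float = DEFAULT_SIGMA_S_M  # S/m
    seed: int = 0

    @classmethod
    def ball_and_stick_default(cls) -> "SimulationConfig":
        return cls()

    @classmethod
    def detailed_default(cls) -> "SimulationConfig":
        return cls(rotation_step_deg=5.0, ais_positions=tuple(range(5, 40, 2)))

    @classmethod
    def reduced(cls, rotation_step_deg=15.0, ais_positions=(5, 10, 15, 20, 25, 30, 35, 40),
                soma_offsets=((0.0, 0.0), (8.75, 8.75))) -> "SimulationConfig":
        """Desk-scale grid for tests and worked examples."""
        return cls(
            rotation_step_deg=rotation_step_deg,
            ais_positions=tuple(ais_positions),
            soma_offsets=tuple(soma_offsets),
        )

    @classmethod
    def kernel_reduced(cls) -> "SimulationConfig":
        """Desk-scale grid for kernel libraries: finer angles and AIS steps
        than :meth:`reduced` (position estimation needs the resolution), two
        jitter offsets."""
        return cls(
            rotation_step_deg=7.5,
            ais_positions=tuple(np.arange(5.0, 40.1, 2.5)),
            soma_offsets=((0.0, 0.0), (8.75, 8.75)),
        )

    @property
    def angles(self) -> np.ndarray:
        return np.arange(0.0, 360.0, self.rotation_step_deg)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration / self.dt)) + 1

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1000.0 / self.dt


def enumerate_grid(cfg: SimulationConfig):
    """Cartesian product of (soma offset, rotation angle, AIS position).

    Deterministic lexicographic order: offsets outermost, then angles, then
    AIS positions.
    """
    return list(
        itertools.product(
            [tuple(o) for o in cfg.soma_offsets],
            [float(a) for a in cfg.angles],
            [float(d) for d in cfg.ais_positions],
        )
    )


def rotate_and_place(m: Morphology, offset=(0.0, 0.0), theta_deg: float = 0.0) -> Morphology:
    """Rigidly rotate about the vertical axis through the soma center, then
    translate in-plane by ``offset``; z is unchanged."""
    out = m.copy()
    c = out.soma_center
    th = np.deg2rad(theta_deg)
    rot = np.array([[np.cos(th), -np.sin(th), 0.0], [np.sin(th), np.cos(th), 0.0], [0.0, 0.0, 1.0]])
    shift = np.array([offset[0], offset[1], 0.0])
    for sec in out.sections:
        sec.points = (sec.points - c) @ rot.T + c + shift
    out.soma_center = c + shift
    out.axon_orientation_deg = (out.axon_orientation_deg + theta_deg) % 360.0
    return out


# ---------------------------------------------------------------------------
# compartmentalization

@dataclass
class Compartments:
    """Flat compartment arrays derived from a morphology.

    Units: um for geometry, uS for conductances, nF for capacitance.
    """

    start: np.ndarray  # (n, 3)
    end: np.ndarray  # (n, 3)
    radius: np.ndarray  # (n,)
    length: np.ndarray  # (n,)
    area: np.ndarray  # (n,) um^2
    tag: list  # section tag per compartment
    parent: np.ndarray  # (n,) int, -1 for root
    g_axial: np.ndarray  # (n,) uS coupling to parent
    gbar: dict = field(default_factory=dict)  # channel -> (n,) uS
    c_m: np.ndarray | None = None  # (n,) nF
    e_na: float = 55.0
    e_k: float = -98.0
    soma_index: int = 0

    @property
    def n(self) -> int:
        return len(self.radius)

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.start + self.end)


def _half_axial_resistance_ohm(radius_um, length_um, is_sphere=False):
    if is_sphere:
        length_um = radius_um  # nominal core path through the sphere
    return RA_OHM_CM * (0.5 * length_um) / (np.pi * radius_um**2) * 1e4


def discretize(m: Morphology) -> Compartments:
    """Split each section into its ``n_segments`` equal-arclength compartments."""
    if m.biophysics is None:
        raise ValueError("assign biophysics before discretizing")
    dist = m.biophysics
    starts, ends, radii, lengths, areas, tags, parents = [], [], [], [], [], [], []
    sec_last_comp = {}

    for si, sec in enumerate(m.sections):
        if sec.tag == "soma":
            r = float(sec.radii[0])
            starts.append(sec.points[0])
            ends.append(sec.points[0])
            radii.append(r)
            lengths.append(2 * r)
            areas.append(4 * np.pi * r**2)  # equivalent-area sphere
            tags.append("soma")
            parents.append(-1)
            sec_last_comp[si] = len(radii) - 1
            continue
        nseg = sec.n_segments
        total = sec.length
        bounds = np.linspace(0.0, total, nseg + 1)
        seglens = np.linalg.norm(np.diff(sec.points, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seglens)])
        parent_comp = sec_last_comp.get(sec.parent, 0)
        for k in range(nseg):
            a, b = bounds[k], bounds[k + 1]
            pa, pb = sec.point_at(a), sec.point_at(b)
            r = float(np.interp(0.5 * (a + b), cum, sec.radii))
            L = b - a
            starts.append(pa)
            ends.append(pb)
            radii.append(r)
            lengths.append(L)
            areas.append(2 * np.pi * r * L)
            tags.append(sec.tag)
            parents.append(parent_comp)
            parent_comp = len(radii) - 1
        sec_last_comp[si] = parent_comp

    start = np.asarray(starts)
    end = np.asarray(ends)
    radius = np.asarray(radii)
    length = np.asarray(lengths)
    area = np.asarray(areas)
    parent = np.asarray(parents, dtype=int)
    n = len(radius)

    half_r = np.array(
        [
            _half_axial_resistance_ohm(radius[i], length[i], tags[i] == "soma")
            for i in range(n)
        ]
    )
    g_axial = np.zeros(n)
    for i in range(n):
        if parent[i] >= 0:
            g_axial[i] = 1e6 / (half_r[i] + half_r[parent[i]])  # uS

    # channel conductances: pS/um^2 * um^2 = pS; * 1e-6 -> uS
    gbar = {"na": np.zeros(n), "k": np.zeros(n), "kv7": np.zeros(n), "leak": np.zeros(n)}
    for i in range(n):
        dens = dist.densities.get(tags[i], DEFAULT_DENSITIES.get(tags[i], {}))
        gbar["na"][i] = dens.get("g_na", 0.0) * area[i] * 1e-6
        gbar["k"][i] = dens.get("g_k", 0.0) * area[i] * 1e-6
        gbar["kv7"][i] = dens.get("g_kv7", 0.0) * area[i] * 1e-6
        gbar["leak"][i] = G_LEAK_S_CM2 * 1e4 * area[i] * 1e-6  # S/cm^2 -> pS/um^2 = 1e4
    c_m = CM_UF_CM2 * area * 1e-5  # nF

    soma_index = tags.index("soma")
    return Compartments(
        start, end, radius, length, area, tags, parent, g_axial, gbar, c_m,
        e_na=dist.e_na, e_k=dist.e_k, soma_index=soma_index,
    )


def landmark_compartments(comps: Compartments, d_ais: float | None = None) -> dict:
    """Indices of reference compartments: soma, AIS midpoint, proximal
    dendrite (~35 um from the soma) and the axon just distal to the AIS."""
    tags = np.asarray(comps.tag)
    soma = comps.soma_index
    ais_ids = np.flatnonzero(tags == "ais")
    ais_mid = int(ais_ids[len(ais_ids) // 2])
    soma_pos = comps.center[soma]
    dend_ids = np.flatnonzero(tags == "dend")
    dend_d = np.linalg.norm(comps.center[dend_ids] - soma_pos, axis=1)
    dend70 = int(dend_ids[np.argmin(np.abs(dend_d - 35.0))])
    axon_ids = np.flatnonzero(tags == "axon")
    ais_end = comps.end[ais_ids[-1]]
    ax_d = np.linalg.norm(comps.center[axon_ids] - ais_end, axis=1)
    post_ais = axon_ids[
        np.linalg.norm(comps.center[axon_ids] - soma_pos, axis=1)
        > np.linalg.norm(ais_end - soma_pos)
        - 1.0
    ]
    axon_distal = int(post_ais[np.argmin(np.linalg.norm(comps.center[post_ais] - ais_end, axis=1) - 10.0)]) if len(post_ais) else int(axon_ids[np.argmin(ax_d)])
    return {"soma": soma, "ais_mid": ais_mid, "dend": dend70, "axon_distal": axon_distal}


# ---------------------------------------------------------------------------
# channel kinetics (rates in 1/ms, V in mV; suited to ~35 C cortical models)

def _vtrap(x, y):
    """x / (1 - exp(-x/y)) with the x -> 0 limit handled."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x / y) < 1e-6
    out = np.where(small, y * (1 + x / (2 * y)), x / (1 - np.exp(-np.where(small, 1.0, x) / y)))
    return np.where(small, y + x / 2, out)


def na_rates(v):
    # recovery from inactivation (alpha_h) is slowed on purpose: axonal Na
    # channels reprime over many ms, which limits step responses to one or
    # two APs instead of an unphysiological 300+ Hz burst
    am = 0.32 * _vtrap(v + 54.0, 4.0)
    bm = 0.28 * _vtrap(-(v + 27.0), 5.0)
    ah = 0.15 * 0.128 * np.exp(-(v + 50.0) / 18.0)
    bh = 4.0 / (1.0 + np.exp(-(v + 27.0) / 5.0))
    return am, bm, ah, bh


def k_rates(v):
    an = 0.032 * _vtrap(v + 52.0, 5.0)
    bn = 0.5 * np.exp(-(v + 57.0) / 40.0)
    return an, bn


def kv7_rates(v):
    winf = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    tauw = 100.0 / (3.3 * (np.exp((v + 35.0) / 20.0) + np.exp(-(v + 35.0) / 20.0)))
    return winf, tauw


# ---------------------------------------------------------------------------
# cable solver

@dataclass
class CableSolution:
    t: np.ndarray  # ms
    v: np.ndarray  # (n_comp, n_t) mV
    i_membrane: np.ndarray  # (n_comp, n_t) nA, capacitive + ionic
    i_stim: np.ndarray  # (n_t,) nA at the soma
    stim_amplitude: float
    spiked: bool
    comps: Compartments


def solve_cable(comps: Compartments, cfg: SimulationConfig, stim_amplitude: float) -> CableSolution:
    """Integrate the cable equations with a staggered implicit scheme.

    Gating variables advance by exponential integration at the current
    voltage; the voltage step then solves the backward-Euler linear system.
    Transmembrane current per compartment (capacitive + ionic) is recovered
    from Kirchhoff's law as net axial inflow plus stimulus, which conserves
    current to machine precision.
    """
    n = comps.n
    dt = cfg.dt
    nt = cfg.n_samples
    t = np.arange(nt) * dt

    parent = comps.parent
    ga = comps.g_axial
    # symmetric axial conductance matrix (dense; compartment counts are small)
    A_ax = np.zeros((n, n))
    for i in range(n):
        p = parent[i]
        if p >= 0:
            A_ax[i, p] += ga[i]
            A_ax[p, i] += ga[i]
    ax_diag = A_ax.sum(axis=1)

    v = np.full(n, V_INIT_MV)
    am, bm, ah, bh = na_rates(v)
    m_g = am / (am + bm)
    h_g = ah / (ah + bh)
    an, bn = k_rates(v)
    n_g = an / (an + bn)
    w_inf, _ = kv7_rates(v)
    w_g = w_inf.copy()

    gna, gk, gkv7, gleak = (comps.gbar[k] for k in ("na", "k", "kv7", "leak"))
    e_na, e_k, e_leak = comps.e_na, comps.e_k, E_LEAK_MV
    c_over_dt = comps.c_m / dt

    i_stim = np.zeros(nt)
    on = (t >= cfg.stim_delay) & (t < cfg.stim_delay + cfg.stim_duration)
    i_stim[on] = stim_amplitude
    stim_vec = np.zeros(n)

    V = np.empty((n, nt))
    IM = np.empty((n, nt))
    V[:, 0] = v
    IM[:, 0] = 0.0

    for k in range(1, nt):
        # gate update (exponential Euler at v_n)
        am, bm, ah, bh = na_rates(v)
        an, bn = k_rates(v)
        w_inf, w_tau = kv7_rates(v)
        for gate, a, b in ((0, am, bm), (1, ah, bh), (2, an, bn)):
            tau = 1.0 / (a + b)
            inf = a * tau
            if gate == 0:
                m_g = inf + (m_g - inf) * np.exp(-dt / tau)
            elif gate == 1:
                h_g = inf + (h_g - inf) * np.exp(-dt / tau)
            else:
                n_g = inf + (n_g - inf) * np.exp(-dt / tau)
        w_g = w_inf + (w_g - w_inf) * np.exp(-dt / w_tau)

        g_na_t = gna * m_g**3 * h_g
        g_k_t = gk * n_g**4
        g_kv7_t = gkv7 * w_g
        g_tot = g_na_t + g_k_t + g_kv7_t + gleak
        ge = g_na_t * e_na + (g_k_t + g_kv7_t) * e_k + gleak * e_leak

        stim_vec[comps.soma_index] = i_stim[k]
        # (C/dt + g_tot + ax_diag) v' - A_ax v' = C/dt v + ge + stim
        A = -A_ax.copy()
        np.fill_diagonal(A, c_over_dt + g_tot + ax_diag)
        rhs = c_over_dt * v + ge + stim_vec
        v_new = np.linalg.solve(A, rhs)

        # transmembrane (cap + ionic) current = axial inflow + stimulus
        IM[:, k] = A_ax @ v_new - ax_diag * v_new + stim_vec
        v = v_new
        V[:, k] = v

    spiked = bool(np.any(V > AP_THRESHOLD_MV))
    return CableSolution(t, V, IM, i_stim, stim_amplitude, spiked, comps)


def find_stimulus_amplitude(
    comps: Compartments, cfg: SimulationConfig, lo: float = 0.3, hi: float = 2.0,
    n_iter: int = 7, factor: float = 1.5,
) -> float:
    """1.5 x rheobase, with rheobase located by bisection within [lo, hi] nA.

    If even ``hi`` is subthreshold, returns ``hi``; the resulting simulation
    will carry the subthreshold flag.
    """
    if not solve_cable(comps, cfg, hi).spiked:
        return hi
    if solve_cable(comps, cfg, lo).spiked:
        rheo = lo
    else:
        a, b = lo, hi
        for _ in range(n_iter):
            mid = 0.5 * (a + b)
            if solve_cable(comps, cfg, mid).spiked:
                b = mid
            else:
                a = mid
        rheo = b
    return float(min(hi, factor * rheo))


# ---------------------------------------------------------------------------
# extracellular forward model

def transfer_matrix(comps: Compartments, probe: Probe, sigma_s_m: float = DEFAULT_SIGMA_S_M,
                    electrode_indices=None) -> np.ndarray:
    """Map compartment currents (nA) to electrode potentials (uV).

    Line-source approximation for cylindrical compartments, point source for
    the spherical soma, homogeneous medium of conductivity ``sigma_s_m``.
    """
    centers = probe.centers if electrode_indices is None else probe.centers[electrode_indices]
    scale = 1e3 / (4 * np.pi * sigma_s_m)  # uV per (nA / um)
    n_el = len(centers)
    T = np.empty((n_el, comps.n))

    a = comps.start  # (n, 3)
    b = comps.end
    axis = b - a
    L = comps.length
    is_point = L < 1e-9
    # cylindrical compartments
    cyl = ~is_point
    if np.any(cyl):
        ac, axc, Lc = a[cyl], axis[cyl], L[cyl]
        u = axc / Lc[:, None]
        diff = centers[:, None, :] - ac[None, :, :]  # (el, comp, 3)
        tproj = np.einsum("ecx,cx->ec", diff, u)  # longitudinal coord from start
        r2 = np.maximum(np.einsum("ecx,ecx->ec", diff, diff) - tproj**2, 0.0)
        r = np.sqrt(r2)
        r = np.maximum(r, comps.radius[cyl][None, :])  # clip inside the cable
        f = (np.arcsinh((Lc[None, :] - tproj) / r) + np.arcsinh(tproj / r)) / Lc[None, :]
        T[:, cyl] = scale * f
    if np.any(is_point):
        cpt = comps.center[is_point]
        d = np.linalg.norm(centers[:, None, :] - cpt[None, :, :], axis=2)
        d = np.maximum(d, comps.radius[is_point][None, :])
        T[:, is_point] = scale / d
    return T


# ---------------------------------------------------------------------------
# high-level simulation

@dataclass
class SimResult:
    extracellular: np.ndarray  # (n_electrodes, n_samples) uV
    electrode_indices: np.ndarray
    fs: float  # Hz
    metadata: dict
    v: np.ndarray | None = None  # intracellular (n_comp, n_samples) mV
    comps: Compartments | None = None


def simulate(
    m: Morphology,
    probe: Probe,
    cfg: SimulationConfig,
    offset=(0.0, 0.0),
    theta_deg: float = 0.0,
    electrode_indices=None,
    keep_intracellular: bool = True,
    stim_amplitude: float | None = None,
) -> SimResult:
    """Simulate one placement of a morphology on the probe.

    The morphology must carry biophysics.  If no stimulus amplitude is given
    (either here or in ``cfg``), 1.5 x rheobase is located by bisection.  A
    simulation that evokes no action potential is returned with
    ``metadata['subthreshold'] = True`` rather than raising.
    """
    placed = rotate_and_place(m, offset, theta_deg)
    comps = discretize(placed)
    amp = stim_amplitude if stim_amplitude is not None else cfg.stim_amplitude
    if amp is None:
        amp = find_stimulus_amplitude(comps, cfg)
    sol = solve_cable(comps, cfg, amp)
    if electrode_indices is None:
        electrode_indices = np.arange(probe.n_electrodes)
    T = transfer_matrix(comps, probe, cfg.conductivity_sigma, electrode_indices)
    extra = T @ sol.i_membrane
    meta = {
        "offset": tuple(offset),
        "theta_deg": float(theta_deg),
        "d_ais": m.d_ais,
        "stim_amplitude": float(amp),
        "subthreshold": not sol.spiked,
    }
    return SimResult(
        extracellular=extra,
        electrode_indices=np.asarray(electrode_indices),
        fs=cfg.fs,
        metadata=meta,
        v=sol.v if keep_intracellular else None,
        comps=comps,
    )


def _rotate_points(points, center, offset, theta_deg):
    th = np.deg2rad(theta_deg)
    rot = np.array([[np.cos(th), -np.sin(th), 0.0], [np.sin(th), np.cos(th), 0.0], [0.0, 0.0, 1.0]])
    shift = np.array([offset[0], offset[1], 0.0])
    return (points - center) @ rot.T + center + shift


def simulate_family(
    builder,
    probe: Probe,
    cfg: SimulationConfig,
    electrode_indices=None,
    progress=None,
):
    """Run the (offset, angle, AIS position) grid for one model family.

    ``builder(d_ais) -> Morphology`` must return a morphology with biophysics
    attached.  The cable equations are solved once per AIS position (rigid
    placement does not alter intracellular dynamics); each placement then only
    recomputes the electrode transfer matrix.  The stimulus amplitude is fixed
    per model at 1.5 x rheobase of the first AIS position.

    Yields ``SimResult`` without intracellular traces, in grid order
    (d_ais outer, then offset, then angle).
    """
    if electrode_indices is None:
        electrode_indices = np.arange(probe.n_electrodes)
    electrode_indices = np.asarray(electrode_indices)
    amp = cfg.stim_amplitude
    for d_ais in cfg.ais_positions:
        m = builder(float(d_ais))
        comps = discretize(m)
        if amp is None:
            amp = find_stimulus_amplitude(comps, cfg)
        sol = solve_cable(comps, cfg, amp)
        center = m.soma_center
        start0, end0 = comps.start.copy(), comps.end.copy()
        for offset in cfg.soma_offsets:
            for theta in cfg.angles:
                comps.start = _rotate_points(start0, center, offset, theta)
                comps.end = _rotate_points(end0, center, offset, theta)
                T = transfer_matrix(comps, probe, cfg.conductivity_sigma, electrode_indices)
                extra = T @ sol.i_membrane
                meta = {
                    "offset": tuple(offset),
                    "theta_deg": float(theta),
                    "d_ais": float(d_ais),
                    "stim_amplitude": float(amp),
                    "subthreshold": not sol.spiked,
                }
                yield SimResult(extra, electrode_indices, cfg.fs, meta)
                if progress is not None:
                    progress()
        comps.start, comps.end = start0, end0
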