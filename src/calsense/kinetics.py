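"""Agent-based forward model of microcolony growth with calcein-AM kinetics.

Cells in a monolayer microfluidic chamber take up the non-fluorescent
ester calcein-AM (CAM) from the perfusion medium, convert it to the
fluorescent polyanion calcein through intracellular esterases, and
secrete calcein through an energy-dependent transporter.  The model is a
minimal linear compartment system per cell:

    cam_in'  = uptake - conversion
    calcein' = conversion - efflux

with

    uptake      = area * sigma(s) * phi * max(1 - c/c_cap, 0)
                  * [ k_load * 1{carbon} * max(f_eq - f, 0)
                    + k_conv * (1 - energy) * max(f_max - f, 0) ]
    conversion  = k_cat * kappa * cam_in
    efflux      = k_eff_max * psi * energy * calcein

where ``s`` is the extracellular CAM concentration, ``sigma`` a
saturable Michaelis term normalised to 1 at the reference dose
(46.3 uM), ``c``/``f`` the intracellular CAM/calcein concentrations
(amount per area), ``phi``/``psi`` per-cell lognormal rate factors and
``kappa`` the esterase (conversion) capacity.  The two uptake routes
reflect the two observed regimes: a fast, product-inhibited loading
route active under feast (apparent constant ``k_load``, half-time
ln2/k_load ~ 10.6 min in naive cells) and a slow route that ramps in as
cellular energy falls under carbon starvation, producing the slow
famine-phase accumulation toward a high saturation level (apparent
constant ``k_conv``).  Efflux is gated by an energy state that relaxes
to 1 under carbon and decays exponentially without it, so carbon famine
shuts efflux off while iron famine leaves it running.

Growth is exponential in cell area at a medium/pH-dependent maximal
rate, with division at a noisy critical area.  Carbon famine halts
growth but still permits occasional reductive division (smaller
daughters); iron famine halts both.  Antibiotic pulses are modelled
phenomenologically: ampicillin arrests growth, raises the lysis hazard
and makes division asymmetric; chloramphenicol arrests growth and
erodes the conversion capacity while present.

All times are minutes internally; growth rates are reported in 1/h;
fluorescence amounts are arbitrary units (AU) times um^2, so
``calcein / area`` is the mean single-cell fluorescence in AU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .protocols import MediaPhase, MediaProtocol

__all__ = [
    "KineticParams",
    "Chamber",
    "CellState",
    "ColonyGroundTruth",
    "ExtracellularState",
    "step_cell_kinetics",
    "grow_and_divide",
    "update_extracellular",
    "simulate_colony",
    "surrogate_stoichiometry",
    "surrogate_to_cam",
]

# integer codes for per-cell fates (ground truth for phenotype benchmarks)
FATE_NORMAL = 0
FATE_DARK = 1            # no esterase activity, never grows: non-viable dark
FATE_DORMANT = 2         # fails to resume growth after famine, typical efflux
FATE_DORMANT_DELAYED = 3  # fails to resume growth, reduced efflux constant
FATE_DORMANT_LATE = 4    # fails to resume growth, efflux shuts down again late

FATE_NAMES = {
    FATE_NORMAL: "normal",
    FATE_DARK: "dark",
    FATE_DORMANT: "dormant_typical",
    FATE_DORMANT_DELAYED: "dormant_delayed_efflux",
    FATE_DORMANT_LATE: "dormant_late_increase",
}


@dataclass(frozen=True)
class KineticParams:
    """Rate constants and physiology of the per-cell kinetic model.

    The default calibration: ``k_load`` = ln2 / 10.6 min so that naive
    cells reach half of their loading plateau in ~10.6 min;
    ``k_conv`` = 0.0025 1/min for the famine-phase apparent conversion
    constant and ``k_eff_max`` = 0.005 1/min (= 2 x k_conv) for the
    feast-phase efflux constant; maximal growth rates in BHI of
    0.97 / 1.02 / 0.78 1/h at pH 7.0 / 7.4 / 6.6.
    """

    k_load: float = math.log(2.0) / 10.6     # 1/min, fast loading route
    k_conv: float = 0.0025                   # 1/min, famine conversion route
    k_eff_max: float = 0.005                 # 1/min, energy-gated efflux
    k_cat: float = 2.0                       # 1/min, esterase conversion of cam_in
    km_cam: float = 5.0                      # uM, saturation of uptake vs CAM dose
    cam_ref_um: float = 46.3                 # uM, reference dose (sigma == 1)
    cam_capacity: float = 1000.0             # AU, internal CAM pool ceiling
    f_eq: float = 430.0                      # AU, feast loading set-point
    f_max: float = 3000.0                    # AU, famine saturation level
    size_fluor_exp: float = 0.3              # set-point scaling with cell area
    ph_fluor_gain: float = 0.8               # f_eq increase per pH unit below 7
    mu_max_by_ph: tuple = ((6.6, 0.78), (7.0, 0.97), (7.4, 1.02))  # 1/h, BHI
    mu_cgxii: float = 0.60                   # 1/h, CGXII + 4% glucose
    mu_cv: float = 0.03                      # per-cell growth-rate CV
    energy_recovery: float = 0.5             # 1/min, energy rise under carbon
    energy_decay: float = 0.2                # 1/min, energy fall without carbon
    cell_cv: float = 0.15                    # lognormal CV of phi and psi
    division_area: float = 2.4               # um^2, mean critical area
    division_cv: float = 0.10                # CV of the critical area
    min_area: float = 0.8                    # um^2, floor for reductive division
    partition_cv: float = 0.05               # CV of amount partitioning at division
    division_asym_sd: float = 0.02           # sd of daughter area fraction
    lysis_rate: float = 0.005                # 1/h baseline lysis hazard
    famine_division_rate: float = 0.10       # 1/h reductive division under C famine
    growth_lag_seed: float = 30.0            # min, lag of freshly seeded founders
    growth_lag_refeed: float = 120.0         # min, lag after prolonged famine
    p_dark: float = 0.02                     # founder fraction without esterase
    p_dormant: float = 0.10                  # fraction failing to resume growth
    dormant_subtype_probs: tuple = (0.34, 0.33, 0.33)  # typical/delayed/late
    delayed_efflux_factor: float = 0.4       # psi multiplier of delayed subtype
    late_shutdown_delay: float = 180.0       # min after re-supply, late subtype
    amp_lysis_factor: float = 10.0
    amp_asym_factor: float = 3.0
    amp_psi_dispersion: float = 2.0          # extra lognormal CV factor on psi
    amp_arrest_extra: float = 120.0          # min of arrest beyond AMP exposure
    chl_conv_decay: float = 0.01             # 1/min kappa decay under CHL
    chl_arrest_extra: float = 60.0           # min of arrest beyond CHL exposure
    dt_int: float = 0.1                      # min, fixed RK4 integration step

    def __post_init__(self):
        for name in ("k_load", "k_conv", "k_eff_max", "k_cat", "km_cam",
                     "energy_recovery", "energy_decay", "lysis_rate",
                     "division_area"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def sigma(self, cam_uM) -> np.ndarray:
        """Saturable uptake factor, normalised to 1 at the reference dose."""
        s = np.asarray(cam_uM, dtype=float)
        ref = self.cam_ref_um / (self.km_cam + self.cam_ref_um)
        return (s / (self.km_cam + s)) / ref

    def f_eq_at_ph(self, ph: float) -> float:
        """Feast loading set-point; mildly elevated below pH 7."""
        return self.f_eq * (1.0 + self.ph_fluor_gain * max(0.0, 7.0 - ph))

    def mu_base(self, phase: MediaPhase) -> float:
        """Maximal growth rate (1/h) for a medium phase; zero without
        carbon or iron."""
        if not (phase.carbon_present and phase.iron_present):
            return 0.0
        if phase.medium == "bhi":
            phs = np.array([p for p, _ in self.mu_max_by_ph])
            mus = np.array([m for _, m in self.mu_max_by_ph])
            return float(mus[np.argmin(np.abs(phs - phase.ph))])
        return self.mu_cgxii


@dataclass(frozen=True)
class Chamber:
    """Monolayer cultivation chamber geometry (um).  The supply channel
    above the chamber has ten-fold fluid height, which scales its
    fluorescence signal per unit concentration."""

    width: float = 40.0
    height: float = 40.0
    fluid_height: float = 1.0
    channel_fluid_height: float = 10.0
    crowding_fraction: float = 0.8
    rod_width: float = 0.8
    contact_gap: float = 0.15

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def capacity_area(self) -> float:
        return self.crowding_fraction * self.area


@dataclass
class CellState:
    """Kinetic and geometric state of one cell at one instant."""

    cell_id: int
    parent_id: Optional[int]
    birth_time: float
    area: float                      # um^2
    cam_in: float = 0.0              # AU * um^2
    calcein: float = 0.0             # AU * um^2
    energy: float = 1.0              # in [0, 1]
    status: str = "alive"            # alive | lysed | arrested
    x: float = 0.0
    y: float = 0.0
    theta: float = 0.0
    conv_capacity: float = 1.0       # kappa, eroded by chloramphenicol
    cum_uptake: float = 0.0
    cum_efflux: float = 0.0
    cum_bleached: float = 0.0
    fate: int = FATE_NORMAL

    def __post_init__(self):
        if self.status == "alive" and self.area <= 0:
            raise ValueError("alive cell must have positive area")
        if self.cam_in < 0 or self.calcein < 0:
            raise ValueError("amounts must be >= 0")
        if not (0.0 <= self.energy <= 1.0):
            raise ValueError("energy must lie in [0, 1]")

    @property
    def mean_fluor(self) -> float:
        """Mean single-cell fluorescence (AU): calcein amount per area."""
        return self.calcein / self.area if self.area > 0 else 0.0


# ---------------------------------------------------------------------------
# vectorised kinetic core (single implementation used by both the scalar
# operation and the colony simulator)
# ---------------------------------------------------------------------------

def _kinetics_rhs(C, F, a, e, kappa, phi, psi, sigma_s, carbon, f_eq, p: KineticParams):
    f = F / a
    c = C / a
    room = np.maximum(1.0 - c / p.cam_capacity, 0.0)
    # larger cells carry disproportionately more esterase: their feast
    # set-point is mildly higher, reproducing the observed positive
    # area-fluorescence correlation in balanced growth
    f_eq_cell = f_eq * (a / p.division_area) ** p.size_fluor_exp
    u = sigma_s * phi * room * (
        p.k_load * carbon * np.maximum(f_eq_cell - f, 0.0)
        + p.k_conv * (1.0 - e) * np.maximum(p.f_max - f, 0.0)
    )
    U = a * u
    V = p.k_cat * kappa * C
    E = p.k_eff_max * psi * e * F
    return U - V, V - E, U, E


def _rk4_kinetics(C, F, cumU, cumE, e, energised, a, kappa, phi, psi,
                  sigma_s, carbon, f_eq, p: KineticParams, dt: float):
    """One fixed RK4 step of (cam_in, calcein, cum_uptake, cum_efflux,
    energy).

    Area and capacities are frozen within the step (they evolve on
    slower or piecewise schedules); the mass-balance identity
    cumU - cumE == cam_in + calcein is exact to rounding because the
    cumulative fluxes are integrated with the same tableau.
    ``energised`` selects per cell between energy recovery (carbon
    available and the cell still respiring) and exponential decay.
    """
    def rhs(Ci, Fi, ei):
        dC, dF, U, E = _kinetics_rhs(Ci, Fi, a, ei, kappa, phi, psi,
                                     sigma_s, carbon, f_eq, p)
        de = np.where(energised, p.energy_recovery * (1.0 - ei),
                      -p.energy_decay * ei)
        return dC, dF, U, E, de

    k1 = rhs(C, F, e)
    k2 = rhs(C + 0.5 * dt * k1[0], F + 0.5 * dt * k1[1], e + 0.5 * dt * k1[4])
    k3 = rhs(C + 0.5 * dt * k2[0], F + 0.5 * dt * k2[1], e + 0.5 * dt * k2[4])
    k4 = rhs(C + dt * k3[0], F + dt * k3[1], e + dt * k3[4])
    C = C + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
    F = F + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
    cumU = cumU + dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
    cumE = cumE + dt / 6.0 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
    e = e + dt / 6.0 * (k1[4] + 2 * k2[4] + 2 * k3[4] + k4[4])
    return (np.maximum(C, 0.0), np.maximum(F, 0.0), cumU, cumE,
            np.clip(e, 0.0, 1.0))


def step_cell_kinetics(state: CellState, params: KineticParams,
                       phase: MediaPhase, dt: float) -> CellState:
    """Advance one cell's uptake/conversion/efflux kinetics by ``dt``
    minutes under a fixed medium phase.  Growth and division are handled
    separately by :func:`grow_and_divide`.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if state.status != "alive":
        raise ValueError(f"cannot step a {state.status} cell")

    C = np.array([state.cam_in])
    F = np.array([state.calcein])
    cumU = np.array([state.cum_uptake])
    cumE = np.array([state.cum_efflux])
    a = np.array([state.area])
    kappa = np.array([state.conv_capacity])
    one = np.array([1.0])
    sigma_s = params.sigma(phase.cam_conc) * one
    f_eq = params.f_eq_at_ph(phase.ph)
    carbon = 1.0 if phase.carbon_present else 0.0
    e = state.energy

    n_sub = max(1, int(round(dt / params.dt_int)))
    h = dt / n_sub
    ev = np.array([float(state.energy)])
    energised = np.array([phase.carbon_present])
    for _ in range(n_sub):
        C, F, cumU, cumE, ev = _rk4_kinetics(
            C, F, cumU, cumE, ev, energised, a, kappa, one, one, sigma_s,
            carbon, f_eq, params, h)

    return replace(state, cam_in=float(C[0]), calcein=float(F[0]),
                   energy=float(ev[0]),
                   cum_uptake=float(cumU[0]), cum_efflux=float(cumE[0]))


def grow_and_divide(state: CellState, params: KineticParams, phase: MediaPhase,
                    dt: float, rng: np.random.Generator,
                    mu: Optional[float] = None,
                    division_threshold: Optional[float] = None,
                    allow_division: bool = True) -> "list[CellState]":
    """Grow one cell for ``dt`` minutes and split it if it crosses its
    critical division area.  Returns ``[cell]`` or ``[daughter1,
    daughter2]``.

    ``mu`` (1/h) defaults to the phase's maximal growth rate;
    ``division_threshold`` defaults to a fresh noisy draw around
    ``params.division_area``.  Amounts are partitioned proportionally to
    daughter areas with multiplicative partition noise; with
    ``partition_cv == 0`` the split conserves area, calcein and cam_in
    exactly.
    """
    if state.status != "alive":
        raise ValueError(f"cannot grow a {state.status} cell")
    if mu is None:
        mu = params.mu_base(phase)
    area = state.area * math.exp(mu / 60.0 * dt)
    cell = replace(state, area=area)
    if not allow_division or mu <= 0:
        return [cell]
    thr = division_threshold
    if thr is None:
        thr = params.division_area * math.exp(
            rng.normal(0.0, params.division_cv) - 0.5 * params.division_cv ** 2
        )
    if area < thr:
        return [cell]
    return divide_cell(cell, params, rng)


def divide_cell(cell: CellState, params: KineticParams, rng: np.random.Generator,
                asym_sd: Optional[float] = None,
                id_start: Optional[int] = None) -> "list[CellState]":
    """Split a cell into two daughters, conserving area and amounts."""
    if asym_sd is None:
        asym_sd = params.division_asym_sd
    pa = float(np.clip(rng.normal(0.5, asym_sd), 0.25, 0.75))
    if params.partition_cv > 0:
        pf = float(np.clip(pa * (1.0 + rng.normal(0.0, params.partition_cv)),
                           0.02, 0.98))
        pc = float(np.clip(pa * (1.0 + rng.normal(0.0, params.partition_cv)),
                           0.02, 0.98))
    else:
        pf = pc = pa
    i0 = id_start if id_start is not None else abs(hash((cell.cell_id, "d"))) % 10 ** 9
    w = 0.8
    half = max(cell.area / w / 4.0, w / 2.0)
    dx, dy = math.cos(cell.theta) * half, math.sin(cell.theta) * half
    kids = []
    for k, (frac_a, frac_f, frac_c, sgn) in enumerate(
            [(pa, pf, pc, -1.0), (1 - pa, 1 - pf, 1 - pc, 1.0)]):
        kids.append(replace(
            cell,
            cell_id=i0 + k,
            parent_id=cell.cell_id,
            birth_time=cell.birth_time,  # overwritten by the simulator
            area=cell.area * frac_a,
            cam_in=cell.cam_in * frac_c,
            calcein=cell.calcein * frac_f,
            cum_uptake=cell.cum_uptake * frac_f,
            cum_efflux=cell.cum_efflux * frac_f,
            cum_bleached=cell.cum_bleached * frac_f,
            x=cell.x + sgn * dx,
            y=cell.y + sgn * dy,
            theta=cell.theta + rng.normal(0.0, 0.1),
        ))
    return kids


# ---------------------------------------------------------------------------
# extracellular calcein at the three measurement sites
# ---------------------------------------------------------------------------

@dataclass
class ExtracellularState:
    """Calcein concentrations (AU per unit fluid height) at the chamber
    interior and the supply channel.  Measured *signals* scale with the
    local fluid height: 1 um inside the chamber, 10 um in the channel;
    the chamber entrance sees a mixing fraction of the interior."""

    conc_chamber: float = 0.0
    conc_channel: float = 0.0

    def signals(self, chamber: Chamber = Chamber(),
                entrance_mixing: float = 0.5) -> "dict[str, float]":
        return {
            "supply_channel": self.conc_channel * chamber.channel_fluid_height,
            "chamber_entrance": self.conc_chamber * entrance_mixing
            * chamber.fluid_height,
            "cell_proximity": self.conc_chamber * chamber.fluid_height,
        }


def update_extracellular(state: ExtracellularState, efflux_total: float,
                         dt: float, flow: float = 300.0,
                         n_upstream: int = 400,
                         chamber: Chamber = Chamber(),
                         washout_chamber: float = 0.02,
                         washout_channel: float = 0.5) -> ExtracellularState:
    """Advance the extracellular pools by ``dt`` minutes.

    Each site is a continuously stirred pool ``dC/dt = input - w * C``
    (exact exponential update, steady state input/w).  The chamber pool
    receives the colony's total efflux divided by the chamber fluid
    volume and exchanges diffusively with the channel (washout
    ``washout_chamber``); the supply channel integrates the efflux of
    ``n_upstream`` chambers into its ten-fold-height volume with a
    flow-driven washout.  Washouts scale linearly with the perfusion
    rate relative to the reference 300 nL/min.
    """
    if flow <= 0:
        raise ValueError(f"flow must be > 0, got {flow}")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    fscale = flow / 300.0
    v_ch = chamber.area * chamber.fluid_height
    v_sup = chamber.area * chamber.channel_fluid_height
    w1 = washout_chamber * fscale
    w2 = washout_channel * fscale

    def relax(conc, inp, w):
        if w <= 0:
            return conc + inp * dt
        decay = math.exp(-w * dt)
        return conc * decay + (inp / w) * (1.0 - decay)

    return ExtracellularState(
        conc_chamber=relax(state.conc_chamber, efflux_total / v_ch, w1),
        conc_channel=relax(state.conc_channel, n_upstream * efflux_total / v_sup, w2),
    )


# ---------------------------------------------------------------------------
# surrogate stoichiometry
# ---------------------------------------------------------------------------

def surrogate_stoichiometry(cam_uM: float) -> float:
    """Methyl methoxyacetate dose (uM) carrying the same molar amount of
    hydrolysable ester groups as ``cam_uM`` of CAM (3 mol per mol CAM)."""
    if cam_uM < 0:
        raise ValueError("CAM concentration must be >= 0")
    return 3.0 * cam_uM


def surrogate_to_cam(mma_uM: float) -> float:
    """Inverse of :func:`surrogate_stoichiometry`, reported to one
    decimal (e.g. 500 uM -> 166.7 uM CAM-equivalent)."""
    if mma_uM < 0:
        raise ValueError("surrogate concentration must be >= 0")
    return round(mma_uM / 3.0, 1)


# ---------------------------------------------------------------------------
# colony simulation
# ---------------------------------------------------------------------------

@dataclass
class ColonyGroundTruth:
    """Full ground truth of one simulated microcolony."""

    frames: "list[list[CellState]]"
    frame_times: "list[float]"
    extracellular: "list[dict]"          # per frame: site -> signal (AU)
    protocol: MediaProtocol
    seed: int
    params: KineticParams
    chamber: Chamber
    divisions: "list[tuple]" = field(default_factory=list)   # (t, parent, d1, d2)
    lysis_events: "list[tuple]" = field(default_factory=list)  # (t, cell_id)
    cell_fates: "dict[int, int]" = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for k, (t, cells) in enumerate(zip(self.frame_times, self.frames)):
            for c in cells:
                rows.append((k, t, c.cell_id, c.parent_id, c.area,
                             c.mean_fluor, c.cam_in, c.energy, c.status,
                             c.x, c.y, c.theta))
        return pd.DataFrame(rows, columns=[
            "frame", "t_min", "cell_id", "parent_id", "area_um2",
            "mean_fluor_au", "cam_in", "energy", "status", "x_um", "y_um",
            "theta"])

    def extracellular_dataframe(self) -> pd.DataFrame:
        rows = []
        for k, (t, sig) in enumerate(zip(self.frame_times, self.extracellular)):
            for site, v in sig.items():
                rows.append((k, t, site, v))
        return pd.DataFrame(rows, columns=["frame", "t_min", "site",
                                           "mean_fluor_au"])

    def colony_mean_fluor(self) -> np.ndarray:
        """Unweighted mean of single-cell mean fluorescence per frame
        (alive cells)."""
        out = []
        for cells in self.frames:
            vals = [c.mean_fluor for c in cells if c.status == "alive"]
            out.append(float(np.mean(vals)) if vals else np.nan)
        return np.asarray(out)

    def total_area(self) -> np.ndarray:
        return np.asarray([
            sum(c.area for c in cells if c.status == "alive")
            for cells in self.frames])


class _ColonyArrays:
    """Struct-of-arrays cell population used internally by
    :func:`simulate_colony`."""

    FIELDS = ("ids", "parent", "birth_t", "a", "C", "F", "e", "kappa", "phi",
              "psi", "mfac", "div_thr", "resume_t", "shutdown_t", "fate",
              "x", "y", "theta", "cumU", "cumE", "cumB")

    def __init__(self):
        for f in self.FIELDS:
            setattr(self, f, np.zeros(0))
        self.ids = np.zeros(0, dtype=np.int64)
        self.parent = np.zeros(0, dtype=np.int64)
        self.fate = np.zeros(0, dtype=np.int64)
        self.next_id = 1

    @property
    def n(self):
        return self.ids.size

    def append(self, **kw):
        for f in self.FIELDS:
            cur = getattr(self, f)
            val = np.asarray(kw[f], dtype=cur.dtype)
            setattr(self, f, np.concatenate([cur, np.atleast_1d(val)]))

    def drop(self, mask):
        keep = ~mask
        for f in self.FIELDS:
            setattr(self, f, getattr(self, f)[keep])


def _rod_length(area: float, width: float) -> float:
    """Spherocylinder length from area (circle-capped rectangle)."""
    cap = math.pi * width ** 2 / 4.0
    if area <= cap:
        return width
    return width + (area - cap) / width


def _relax_positions(pop: _ColonyArrays, chamber: Chamber,
                     iters: int = 60) -> None:
    """Resolve rod overlaps by pushing cell centres apart.

    Each rod is approximated by a short chain of circles along its axis;
    overlapping circles of different cells repel both centres.  Cells
    are kept inside the chamber walls."""
    from scipy.spatial import cKDTree

    n = pop.n
    if n == 0:
        return
    w = chamber.rod_width
    target = w + chamber.contact_gap
    lengths = np.array([_rod_length(a, w) for a in pop.a])
    half = np.maximum((lengths - w) / 2.0, 0.0)

    for _ in range(iters):
        # circle chains (spacing < half the rod width)
        ncirc = np.clip((half * 5.0 / w).astype(int) + 2, 1, 9)
        pts, owner = [], []
        for i in range(n):
            k = ncirc[i]
            offs = np.linspace(-half[i], half[i], k) if k > 1 else np.zeros(1)
            cx = pop.x[i] + offs * math.cos(pop.theta[i])
            cy = pop.y[i] + offs * math.sin(pop.theta[i])
            pts.append(np.column_stack([cx, cy]))
            owner.append(np.full(k, i))
        pts = np.concatenate(pts)
        owner = np.concatenate(owner)

        tree = cKDTree(pts)
        pairs = tree.query_pairs(target, output_type="ndarray")
        if pairs.size:
            oi, oj = owner[pairs[:, 0]], owner[pairs[:, 1]]
            diff = oi != oj
            pairs, oi, oj = pairs[diff], oi[diff], oj[diff]
        moved = False
        if pairs.size:
            d = pts[pairs[:, 1]] - pts[pairs[:, 0]]
            dist = np.linalg.norm(d, axis=1)
            dist = np.where(dist < 1e-9, 1e-9, dist)
            push = 0.5 * (target - dist) / dist
            vec = d * push[:, None]
            dx = np.zeros(n)
            dy = np.zeros(n)
            cnt = np.zeros(n)
            np.add.at(dx, oi, -vec[:, 0])
            np.add.at(dy, oi, -vec[:, 1])
            np.add.at(dx, oj, vec[:, 0])
            np.add.at(dy, oj, vec[:, 1])
            np.add.at(cnt, oi, 1.0)
            np.add.at(cnt, oj, 1.0)
            # average over contacts and cap the per-iteration step so
            # crowded colonies rearrange smoothly instead of jumping
            cnt = np.maximum(cnt, 1.0)
            dx /= cnt
            dy /= cnt
            step = np.hypot(dx, dy)
            cap = 0.12
            scale = np.where(step > cap, cap / np.maximum(step, 1e-12), 1.0)
            pop.x = pop.x + dx * scale
            pop.y = pop.y + dy * scale
            moved = True
        # chamber walls
        m = w / 2.0 + half * np.abs(np.cos(pop.theta))
        my = w / 2.0 + half * np.abs(np.sin(pop.theta))
        pop.x = np.clip(pop.x, m, chamber.width - m)
        pop.y = np.clip(pop.y, my, chamber.height - my)
        if not moved:
            break


def simulate_colony(n_founders: int, params: KineticParams,
                    protocol: MediaProtocol, seed: int,
                    chamber: Optional[Chamber] = None,
                    naive_founders: bool = False,
                    founder_fluor: Optional[float] = None,
                    record_interval: Optional[float] = None,
                    relax_geometry: bool = True) -> ColonyGroundTruth:
    """Simulate one microcolony under a scripted media protocol.

    Deterministic for fixed arguments and ``seed``.  Frames are recorded
    every ``record_interval`` minutes (default: the protocol's imaging
    frame interval).  ``naive_founders`` starts cells without any
    intracellular CAM or calcein (fresh seeding before CAM exposure);
    otherwise founders start near the feast loading steady state, or at
    ``founder_fluor`` AU if given.
    """
    if n_founders < 1:
        raise ValueError("n_founders must be >= 1")
    if chamber is None:
        chamber = Chamber()
    rng = np.random.default_rng(seed)
    p = params
    rec = record_interval if record_interval is not None else protocol.frame_interval
    dt = min(p.dt_int, rec)

    pop = _ColonyArrays()
    # founder initialisation
    f0_default = 0.8 * p.f_eq
    for _ in range(n_founders):
        a0 = p.division_area * 2.0 ** rng.uniform(-1.0, 0.0)
        phi = math.exp(rng.normal(0, p.cell_cv) - 0.5 * p.cell_cv ** 2)
        psi = math.exp(rng.normal(0, p.cell_cv) - 0.5 * p.cell_cv ** 2)
        mfac = math.exp(rng.normal(0, p.mu_cv) - 0.5 * p.mu_cv ** 2)
        dark = rng.random() < p.p_dark
        if naive_founders:
            f0 = 0.0
        elif founder_fluor is not None:
            f0 = founder_fluor * phi
        else:
            f0 = f0_default * phi
        founder_id = pop.next_id
        pop.next_id += 1
        pop.append(
            ids=founder_id, parent=-1, birth_t=protocol.start_time,
            a=a0, C=0.0, F=0.0 if dark else f0 * a0,
            e=0.8, kappa=0.0 if dark else 1.0, phi=0.0 if dark else phi,
            psi=psi, mfac=mfac,
            div_thr=p.division_area * math.exp(
                rng.normal(0, p.division_cv) - 0.5 * p.division_cv ** 2),
            resume_t=protocol.start_time + p.growth_lag_seed,
            shutdown_t=np.inf,
            fate=FATE_DARK if dark else FATE_NORMAL,
            x=rng.uniform(0.3, 0.7) * chamber.width,
            y=rng.uniform(0.3, 0.7) * chamber.height,
            theta=rng.uniform(0, math.pi),
            cumU=0.0, cumE=0.0, cumB=0.0,
        )
    fates = {int(i): int(f) for i, f in zip(pop.ids, pop.fate)}
    # founders start with their initial load already "taken up"
    pop.cumU = pop.F.copy()

    ec = ExtracellularState()
    frames: list[list[CellState]] = []
    frame_times: list[float] = []
    ec_frames: list[dict] = []
    divisions: list[tuple] = []
    lysis_events: list[tuple] = []
    newly_lysed: list[CellState] = []

    n_rec = int(math.floor(protocol.total_duration / rec + 1e-9)) + 1
    t = protocol.start_time
    last_relax = t
    prev_phase = protocol.phase_at(t)

    def record(t_now):
        if relax_geometry:
            _relax_positions(pop, chamber)
        cells = []
        for i in range(pop.n):
            cells.append(CellState(
                cell_id=int(pop.ids[i]), parent_id=(None if pop.parent[i] < 0
                                                    else int(pop.parent[i])),
                birth_time=float(pop.birth_t[i]), area=float(pop.a[i]),
                cam_in=float(pop.C[i]), calcein=float(pop.F[i]),
                energy=float(np.clip(pop.e[i], 0.0, 1.0)), status="alive",
                x=float(pop.x[i]), y=float(pop.y[i]), theta=float(pop.theta[i]),
                conv_capacity=float(pop.kappa[i]),
                cum_uptake=float(pop.cumU[i]), cum_efflux=float(pop.cumE[i]),
                cum_bleached=float(pop.cumB[i]), fate=int(pop.fate[i]),
            ))
        cells.extend(newly_lysed)
        newly_lysed.clear()
        frames.append(cells)
        frame_times.append(t_now)
        ec_frames.append(ec.signals(chamber))

    record(t)

    for k in range(1, n_rec):
        t_next = protocol.start_time + k * rec
        while t < t_next - 1e-9:
            h = min(dt, t_next - t)
            phase = protocol.phase_at(t)

            # phase-transition handling: famine -> feast backshift
            if (phase.carbon_present and not prev_phase.carbon_present):
                famine_span = t - _carbon_loss_time(protocol, t)
                lag = p.growth_lag_refeed if famine_span >= 120.0 else 0.0
                for i in range(pop.n):
                    if pop.fate[i] != FATE_NORMAL:
                        continue
                    r = rng.random()
                    if r < p.p_dormant:
                        sub = rng.random()
                        c0, c1, _ = p.dormant_subtype_probs
                        if sub < c0:
                            pop.fate[i] = FATE_DORMANT
                        elif sub < c0 + c1:
                            pop.fate[i] = FATE_DORMANT_DELAYED
                            pop.psi[i] *= p.delayed_efflux_factor
                        else:
                            pop.fate[i] = FATE_DORMANT_LATE
                            pop.shutdown_t[i] = t + p.late_shutdown_delay
                        pop.resume_t[i] = np.inf
                    else:
                        pop.resume_t[i] = max(pop.resume_t[i], t + lag)
                fates.update({int(i): int(f) for i, f in zip(pop.ids, pop.fate)})
            # antibiotic pulse onset
            if phase.antibiotic == "AMP" and prev_phase.antibiotic != "AMP":
                extra = math.sqrt(max(p.amp_psi_dispersion ** 2 - 1.0, 0.0)) * p.cell_cv
                pop.psi = pop.psi * np.exp(
                    rng.normal(0.0, extra, pop.n) - 0.5 * extra ** 2)
                pop.resume_t = np.maximum(
                    pop.resume_t, phase.end_time + p.amp_arrest_extra)
            if phase.antibiotic == "CHL" and prev_phase.antibiotic != "CHL":
                pop.resume_t = np.maximum(
                    pop.resume_t, phase.end_time + p.chl_arrest_extra)
            prev_phase = phase

            if pop.n:
                sigma_s = float(p.sigma(phase.cam_conc))
                f_eq = p.f_eq_at_ph(phase.ph)
                carbon = 1.0 if phase.carbon_present else 0.0
                psi_eff = np.where(t >= pop.shutdown_t, 0.0, pop.psi)
                # late-shutdown dormant cells de-energise even under
                # carbon (their efflux collapses and the starvation
                # conversion route re-opens, so fluorescence climbs
                # again)
                energised = phase.carbon_present & (t < pop.shutdown_t)
                pop.C, pop.F, pop.cumU, pop.cumE, pop.e = _rk4_kinetics(
                    pop.C, pop.F, pop.cumU, pop.cumE, pop.e, energised,
                    pop.a, pop.kappa, pop.phi, psi_eff, sigma_s, carbon,
                    f_eq, p, h)
                # conversion capacity under chloramphenicol
                if phase.antibiotic == "CHL":
                    pop.kappa = pop.kappa * math.exp(-p.chl_conv_decay * h)
                elif p.chl_conv_decay > 0:
                    full = pop.fate != FATE_DARK
                    pop.kappa = np.where(
                        full, 1.0 + (pop.kappa - 1.0) * math.exp(-p.chl_conv_decay * h),
                        pop.kappa)

                # growth
                mu = p.mu_base(phase)
                crowded = pop.a.sum() >= chamber.capacity_area
                arrest = phase.antibiotic in ("AMP", "CHL")
                if mu > 0 and not crowded and not arrest:
                    growing = (t >= pop.resume_t) & (pop.fate != FATE_DARK)
                    rate = mu / 60.0 * pop.mfac * growing
                    pop.a = pop.a * np.exp(rate * h)
                    # division at the critical area
                    ripe = np.nonzero(growing & (pop.a >= pop.div_thr))[0]
                    for i in ripe[::-1]:
                        _divide_index(pop, i, t + h, p, rng,
                                      asym_sd=p.division_asym_sd, divisions=divisions)
                elif not phase.carbon_present and phase.iron_present:
                    # reductive division under carbon famine
                    eligible = np.nonzero(
                        (pop.a >= 2.0 * p.min_area) & (pop.fate != FATE_DARK))[0]
                    if eligible.size:
                        pr = p.famine_division_rate / 60.0 * h
                        hits = eligible[rng.random(eligible.size) < pr]
                        for i in hits[::-1]:
                            _divide_index(pop, i, t + h, p, rng,
                                          asym_sd=p.division_asym_sd,
                                          divisions=divisions)

                # lysis
                lam = p.lysis_rate * (p.amp_lysis_factor
                                      if phase.antibiotic == "AMP" else 1.0)
                hit = rng.random(pop.n) < lam / 60.0 * h
                if hit.any():
                    for i in np.nonzero(hit)[0]:
                        lysis_events.append((t + h, int(pop.ids[i])))
                        newly_lysed.append(CellState(
                            cell_id=int(pop.ids[i]),
                            parent_id=(None if pop.parent[i] < 0
                                       else int(pop.parent[i])),
                            birth_time=float(pop.birth_t[i]),
                            area=float(pop.a[i]), cam_in=0.0, calcein=0.0,
                            energy=0.0, status="lysed",
                            x=float(pop.x[i]), y=float(pop.y[i]),
                            theta=float(pop.theta[i]), fate=int(pop.fate[i])))
                    pop.drop(hit)

                efflux_rate = float(np.sum(
                    p.k_eff_max * np.where(t >= pop.shutdown_t, 0.0, pop.psi)
                    * pop.e * pop.F)) if pop.n else 0.0
            else:
                efflux_rate = 0.0

            ec = update_extracellular(ec, efflux_rate, h, chamber=chamber)
            t += h
            # intermediate gentle relaxations keep crowded colonies
            # rearranging smoothly between recorded frames
            if relax_geometry and t - last_relax >= 2.0 - 1e-9:
                _relax_positions(pop, chamber, iters=25)
                last_relax = t
        record(t_next)
        t = t_next

    gt = ColonyGroundTruth(
        frames=frames, frame_times=frame_times, extracellular=ec_frames,
        protocol=protocol, seed=seed, params=params, chamber=chamber,
        divisions=divisions, lysis_events=lysis_events, cell_fates=fates)
    return gt


def _carbon_loss_time(protocol: MediaProtocol, t: float) -> float:
    """Start of the carbon-free span that ends at time ``t``."""
    loss = t
    for ph in reversed(protocol.phases):
        if ph.start_time >= t - 1e-9:
            continue
        if ph.carbon_present:
            break
        loss = ph.start_time
    return loss


def _divide_index(pop: _ColonyArrays, i: int, t: float, p: KineticParams,
                  rng: np.random.Generator, asym_sd: float,
                  divisions: "list[tuple]") -> None:
    pa = float(np.clip(rng.normal(0.5, asym_sd), 0.25, 0.75))
    if p.partition_cv > 0:
        pf = float(np.clip(pa * (1.0 + rng.normal(0.0, p.partition_cv)), 0.02, 0.98))
        pc = float(np.clip(pa * (1.0 + rng.normal(0.0, p.partition_cv)), 0.02, 0.98))
    else:
        pf = pc = pa
    w = 0.8
    length = _rod_length(pop.a[i], w)
    off = max((length - w) / 4.0, w / 4.0)
    ct, st = math.cos(pop.theta[i]), math.sin(pop.theta[i])
    parent_id = int(pop.ids[i])
    d1, d2 = pop.next_id, pop.next_id + 1
    pop.next_id += 2
    fracs = [(pa, pf, pc, -1.0, d1), (1 - pa, 1 - pf, 1 - pc, 1.0, d2)]
    base = {f: getattr(pop, f)[i] for f in pop.FIELDS}
    # remove parent, append daughters
    mask = np.zeros(pop.n, dtype=bool)
    mask[i] = True
    pop.drop(mask)
    for frac_a, frac_f, frac_c, sgn, did in fracs:
        thr = p.division_area * math.exp(
            rng.normal(0, p.division_cv) - 0.5 * p.division_cv ** 2)
        mfac = base["mfac"] * math.exp(rng.normal(0, p.mu_cv / 2.0))
        pop.append(
            ids=did, parent=parent_id, birth_t=t,
            a=base["a"] * frac_a, C=base["C"] * frac_c, F=base["F"] * frac_f,
            e=base["e"], kappa=base["kappa"], phi=base["phi"], psi=base["psi"],
            mfac=mfac, div_thr=thr, resume_t=base["resume_t"],
            shutdown_t=base["shutdown_t"], fate=base["fate"],
            x=base["x"] + sgn * off * ct, y=base["y"] + sgn * off * st,
            theta=base["theta"] + rng.normal(0.0, 0.08),
            cumU=base["cumU"] * frac_f, cumE=base["cumE"] * frac_f,
            cumB=base["cumB"] * frac_f,
        )
    divisions.append((t, parent_id, d1, d2))
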