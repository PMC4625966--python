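"""Perfusion media protocols for microfluidic single-cell cultivation.

A protocol is an ordered, contiguous sequence of perfusion phases.  Each
phase fixes the medium composition seen by every cell in the chamber:
carbon source (4 % w/v glucose), the iron chelator protocatechuate (PCA,
also a metabolizable carbon source), iron, the fluorogenic substrate
calcein-AM (CAM), an optional antibiotic pulse, and the medium pH.
Continuous perfusion (300 nL/min) is assumed to impose each phase
instantaneously and homogeneously on the chamber.

Presets encode the standard experimental designs: reference cultivations
in CGXII minimal medium or BHI complex medium at several pH values,
feast/famine shift experiments (carbon or iron withdrawal with later
re-supply), PCA omission, one-hour antibiotic pulses (ampicillin or
chloramphenicol) and CAM dose titrations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

__all__ = [
    "MediaPhase",
    "MediaProtocol",
    "make_protocol",
    "PRESET_NAMES",
]

#: Reference CAM dose in the perfusion medium (uM).
CAM_REFERENCE_UM = 46.3

#: Default imaging frame interval (minutes).
DEFAULT_FRAME_INTERVAL_MIN = 8.0


@dataclass(frozen=True)
class MediaPhase:
    """One perfusion phase of constant medium composition.

    Parameters
    ----------
    start_time : float
        Phase start, minutes from the beginning of the experiment.
    duration : float
        Phase length in minutes; must be positive.
    carbon_present : bool
        Whether the primary carbon source (glucose) is supplied.
    pca_present : bool
        Whether protocatechuate (iron chelator / auxiliary carbon) is
        supplied.
    iron_present : bool
        Whether iron is available to the cells.
    cam_conc : float
        Extracellular calcein-AM concentration in uM.
    antibiotic : str or None
        ``None``, ``"AMP"`` (ampicillin) or ``"CHL"`` (chloramphenicol).
    antibiotic_dose : float
        Dose in ug/mL (10 ug/mL in the standard pulse designs).
    ph : float
        Medium pH, restricted to [6.0, 9.0].
    medium : str
        ``"cgxii"`` (minimal) or ``"bhi"`` (complex); selects the growth
        physiology and the default growth-rate window downstream.
    """

    start_time: float
    duration: float
    carbon_present: bool = True
    pca_present: bool = True
    iron_present: bool = True
    cam_conc: float = CAM_REFERENCE_UM
    antibiotic: Optional[str] = None
    antibiotic_dose: float = 0.0
    ph: float = 7.0
    medium: str = "cgxii"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"phase duration must be > 0, got {self.duration}")
        if self.cam_conc < 0:
            raise ValueError(f"cam_conc must be >= 0, got {self.cam_conc}")
        if not (6.0 <= self.ph <= 9.0):
            raise ValueError(f"ph must lie in [6.0, 9.0], got {self.ph}")
        if self.antibiotic not in (None, "AMP", "CHL"):
            raise ValueError(f"unknown antibiotic {self.antibiotic!r}")
        if self.medium not in ("cgxii", "bhi"):
            raise ValueError(f"unknown medium {self.medium!r}")

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration


@dataclass(frozen=True)
class MediaProtocol:
    """Contiguous sequence of :class:`MediaPhase` plus the imaging cadence."""

    phases: tuple[MediaPhase, ...]
    frame_interval: float = DEFAULT_FRAME_INTERVAL_MIN

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("protocol needs at least one phase")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        object.__setattr__(self, "phases", tuple(self.phases))
        t = self.phases[0].start_time
        for ph in self.phases:
            if abs(ph.start_time - t) > 1e-9:
                raise ValueError(
                    f"phases must be contiguous: expected start {t}, got {ph.start_time}"
                )
            t = ph.end_time

    @property
    def start_time(self) -> float:
        return self.phases[0].start_time

    @property
    def total_duration(self) -> float:
        return self.phases[-1].end_time - self.phases[0].start_time

    @property
    def end_time(self) -> float:
        return self.phases[-1].end_time

    def phase_at(self, t: float) -> MediaPhase:
        """Phase active at time ``t`` (minutes); boundaries belong to the
        later phase, the final end time to the last phase."""
        if t < self.start_time - 1e-9 or t > self.end_time + 1e-9:
            raise ValueError(f"t={t} outside protocol [{self.start_time}, {self.end_time}]")
        for ph in self.phases:
            if t < ph.end_time - 1e-12:
                return ph
        return self.phases[-1]

    def frame_times(self) -> "list[float]":
        import numpy as np

        n = int(np.floor(self.total_duration / self.frame_interval)) + 1
        return [self.start_time + i * self.frame_interval for i in range(n)]


def _single_phase(duration: float, **kw) -> tuple[MediaPhase, ...]:
    return (MediaPhase(start_time=0.0, duration=duration, **kw),)


def _famine(kind: str, total: float = 1080.0, feast_end: float = 240.0,
            famine_end: float = 960.0, cam: float = CAM_REFERENCE_UM) -> tuple[MediaPhase, ...]:
    """Feast (4 h pre-cultivation), famine (12 h), feast restored."""
    if kind == "carbon":
        # CGXII - GLC - PCA: both carbon sources withdrawn, iron stays.
        starve = dict(carbon_present=False, pca_present=False, iron_present=True)
    elif kind == "iron":
        # iron and its chelator withdrawn; glucose stays.
        starve = dict(carbon_present=True, pca_present=False, iron_present=False)
    elif kind == "pca":
        starve = dict(carbon_present=True, pca_present=False, iron_present=True)
    else:  # pragma: no cover - internal
        raise ValueError(kind)
    return (
        MediaPhase(0.0, feast_end, cam_conc=cam),
        MediaPhase(feast_end, famine_end - feast_end, cam_conc=cam, **starve),
        MediaPhase(famine_end, total - famine_end, cam_conc=cam),
    )


def _antibiotic(drug: str, start: float = 120.0, dose: float = 10.0,
                total: float = 480.0, cam: float = CAM_REFERENCE_UM) -> tuple[MediaPhase, ...]:
    """Feast, exactly one hour of antibiotic exposure, feast recovery."""
    pulse = 60.0
    return (
        MediaPhase(0.0, start, cam_conc=cam),
        MediaPhase(start, pulse, cam_conc=cam, antibiotic=drug, antibiotic_dose=dose),
        MediaPhase(start + pulse, total - start - pulse, cam_conc=cam),
    )


PRESET_NAMES = (
    "reference_cgxii",
    "reference_bhi_ph66",
    "reference_bhi_ph70",
    "reference_bhi_ph74",
    "famine_carbon",
    "famine_iron",
    "omit_pca",
    "amp_pulse",
    "chl_pulse",
    "cam_titration",
)


def make_protocol(preset: str, **overrides) -> MediaProtocol:
    """Build a preset :class:`MediaProtocol`, optionally overridden.

    Recognised overrides: ``frame_interval``; ``duration`` (reference
    presets); ``start`` and ``dose`` (antibiotic pulses); ``cam_conc``
    (all presets; required positional meaning for ``cam_titration``);
    ``total``, ``feast_end``, ``famine_end`` (famine presets); plus any
    per-phase field applied uniformly via ``phase_overrides`` (a dict).
    """
    frame_interval = overrides.pop("frame_interval", DEFAULT_FRAME_INTERVAL_MIN)
    phase_overrides = overrides.pop("phase_overrides", None)
    cam = overrides.pop("cam_conc", CAM_REFERENCE_UM)

    if preset == "reference_cgxii":
        phases = _single_phase(overrides.pop("duration", 720.0), cam_conc=cam)
    elif preset in ("reference_bhi_ph66", "reference_bhi_ph70", "reference_bhi_ph74"):
        ph = {"66": 6.6, "70": 7.0, "74": 7.4}[preset[-2:]]
        phases = _single_phase(
            overrides.pop("duration", 300.0), cam_conc=cam, ph=ph, medium="bhi"
        )
    elif preset == "famine_carbon":
        phases = _famine("carbon", cam=cam, **{k: overrides.pop(k) for k in
                         ("total", "feast_end", "famine_end") if k in overrides})
    elif preset == "famine_iron":
        phases = _famine("iron", cam=cam, **{k: overrides.pop(k) for k in
                         ("total", "feast_end", "famine_end") if k in overrides})
    elif preset == "omit_pca":
        phases = _famine("pca", cam=cam, **{k: overrides.pop(k) for k in
                         ("total", "feast_end", "famine_end") if k in overrides})
    elif preset == "amp_pulse":
        phases = _antibiotic("AMP", start=overrides.pop("start", 120.0),
                             dose=overrides.pop("dose", 10.0),
                             total=overrides.pop("total", 480.0), cam=cam)
    elif preset == "chl_pulse":
        phases = _antibiotic("CHL", start=overrides.pop("start", 120.0),
                             dose=overrides.pop("dose", 10.0),
                             total=overrides.pop("total", 480.0), cam=cam)
    elif preset == "cam_titration":
        phases = _single_phase(overrides.pop("duration", 720.0), cam_conc=cam)
    else:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESET_NAMES}")

    if overrides:
        raise TypeError(f"unrecognised overrides for {preset!r}: {sorted(overrides)}")
    if phase_overrides:
        phases = tuple(replace(p, **phase_overrides) for p in phases)
    return MediaProtocol(phases=phases, frame_interval=frame_interval)
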