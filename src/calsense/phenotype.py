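"""Viability and dormancy phenotypes of tracked cells.

Every sufficiently long track receives exactly one primary label:

* ``growing`` — measurable area growth (or division) and fluorescence at
  or above the detection floor;
* ``non_growing_active`` — no area growth, but sustained calcein
  fluorescence: the cell still converts CAM, i.e. is metabolically
  active (dormant-like).  Cells whose fluorescence is strongly elevated
  over the colony median are additionally flagged;
* ``non_viable_lysed`` — an abrupt, permanent loss of fluorescence
  (lysis event);
* ``non_viable_dark`` — never fluorescent and never growing: no
  detectable esterase activity.

Cells observed across a famine-to-feast backshift are further
subtyped by their response to carbon re-supply: ``typical`` (efflux
resumes at the colony-typical rate), ``delayed_efflux`` (markedly
reduced efflux constant) or ``late_increase`` (fluorescence climbs
again hours after re-supply, i.e. efflux shuts down anew).

All thresholds are relative (colony medians, noise-based floors), since
absolute fluorescence units are instrument-specific.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .tracking import LineageForest, LineageNode
from .traces import fit_efflux_rate

__all__ = [
    "ClassificationThresholds",
    "PhenotypeLabel",
    "detect_lysis",
    "cell_growth_rate",
    "classify_cell",
    "subtype_post_resupply",
    "classify_forest",
]

PRIMARY_LABELS = ("growing", "non_growing_active", "non_viable_lysed",
                  "non_viable_dark")
SUBTYPES = ("typical", "delayed_efflux", "late_increase", "none")


@dataclass(frozen=True)
class ClassificationThresholds:
    """Relative thresholds separating the viability classes."""

    growth_eps: float = 0.05          # 1/h, below => non-growing
    fluor_floor: float = 30.0         # AU detection floor (~3 noise sd + bg margin)
    high_fluor_factor: float = 1.5    # multiple of colony median => "elevated"
    lysis_drop_frac: float = 0.5      # fractional one-frame loss
    resupply_lag: float = 120.0       # min of post-backshift coverage needed
    delayed_k_factor: float = 0.5     # fraction of colony-median efflux k

    def __post_init__(self):
        if not (0.0 < self.lysis_drop_frac <= 1.0):
            raise ValueError("lysis_drop_frac must lie in (0, 1]")
        for name in ("growth_eps", "fluor_floor", "high_fluor_factor",
                     "resupply_lag"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class PhenotypeLabel:
    label: str
    subtype: str = "none"
    elevated_fluor: bool = False
    event_time: Optional[float] = None     # lysis time (minutes) if lysed

    def __post_init__(self):
        if self.label not in PRIMARY_LABELS + ("unclassified",):
            raise ValueError(f"unknown label {self.label!r}")
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")


def detect_lysis(trace: np.ndarray,
                 thresholds: ClassificationThresholds = ClassificationThresholds()
                 ) -> Optional[int]:
    """Earliest frame index at which the fluorescence drops by at least
    ``lysis_drop_frac`` of the previous value and stays below the
    detection floor afterwards; ``None`` if no such event."""
    y = np.asarray(trace, dtype=float)
    if len(y) < 3:
        raise ValueError("trace must have at least 3 frames")
    for i in range(1, len(y)):
        if y[i - 1] <= 0:
            continue
        drop = (y[i - 1] - y[i]) / y[i - 1]
        if drop >= thresholds.lysis_drop_frac and \
                np.all(y[i:] < thresholds.fluor_floor):
            return i
    return None


def cell_growth_rate(node: LineageNode, window_frames: int = 10) -> float:
    """Per-cell area growth rate (1/h): log-slope of the single-cell
    area over the track (capped at ``window_frames`` intervals, matching
    the colony growth window)."""
    obs = node.observations
    n = min(len(obs), window_frames + 1)
    best = -np.inf
    for i in range(len(obs) - n + 1):
        sub = obs[i:i + n]
        th = np.array([o.t_min for o in sub]) / 60.0
        la = np.log(np.array([o.area for o in sub]))
        if np.ptp(th) == 0:
            continue
        best = max(best, stats.linregress(th, la).slope)
    return float(best)


def classify_cell(node: LineageNode,
                  thresholds: ClassificationThresholds = ClassificationThresholds(),
                  colony_median_fluor: Optional[float] = None,
                  growth_rate: Optional[float] = None) -> PhenotypeLabel:
    """Assign one primary viability label to a track.

    A track that divided is growing by definition; otherwise the area
    log-slope decides growth, and the fluorescence trace separates
    metabolically active from lysed and dark cells.
    """
    obs = node.observations
    if len(obs) < 3:
        return PhenotypeLabel(label="unclassified")
    fluor = np.array([o.mean_fluor for o in obs])
    t = np.array([o.t_min for o in obs])

    lysis = detect_lysis(fluor, thresholds)
    if lysis is not None:
        return PhenotypeLabel(label="non_viable_lysed",
                              event_time=float(t[lysis]))

    if growth_rate is None:
        growth_rate = cell_growth_rate(node)
    grows = node.end_reason == "divided" or growth_rate >= thresholds.growth_eps
    # sustained fluorescence: the trace spends most of its life above floor
    frac_bright = float(np.mean(fluor >= thresholds.fluor_floor))
    bright = frac_bright >= 0.5

    if grows and bright:
        return PhenotypeLabel(label="growing")
    if bright:
        elevated = False
        if colony_median_fluor is not None and colony_median_fluor > 0:
            elevated = (float(np.median(fluor))
                        >= thresholds.high_fluor_factor * colony_median_fluor)
        return PhenotypeLabel(label="non_growing_active",
                              elevated_fluor=elevated)
    if grows:
        # growing but dark is contradictory; growth wins over darkness
        return PhenotypeLabel(label="growing")
    return PhenotypeLabel(label="non_viable_dark")


def subtype_post_resupply(trace_t: np.ndarray, trace_fluor: np.ndarray,
                          backshift_time: float,
                          thresholds: ClassificationThresholds = ClassificationThresholds(),
                          colony_median_k: Optional[float] = None,
                          colony_median_fluor: Optional[float] = None) -> str:
    """Post-resupply subtype of a non-growing cell.

    ``delayed_efflux`` if the cell's fitted efflux constant after the
    backshift is below ``delayed_k_factor`` times the colony median;
    ``late_increase`` if the fluorescence climbs again beyond
    ``high_fluor_factor`` times the colony median after the resupply
    lag; else ``typical``.
    """
    t = np.asarray(trace_t, dtype=float)
    y = np.asarray(trace_fluor, dtype=float)
    after = t >= backshift_time - 1e-9
    if not after.any() or t[after][-1] - backshift_time < thresholds.resupply_lag:
        raise ValueError("insufficient post-backshift coverage")

    # late increase: the fluorescence climbs again well after re-supply,
    # judged against the cell's own post-backshift minimum
    late = t >= backshift_time + thresholds.resupply_lag
    if late.any():
        ta, ya = t[after], y[after]
        i_min = int(np.argmin(ya))
        post_min = float(ya[i_min])
        yl = y[late]
        tl = t[late]
        i_max = int(np.argmax(yl))
        if post_min > 0 and tl[i_max] > ta[i_min] and \
                float(yl[i_max]) >= thresholds.high_fluor_factor * post_min:
            return "late_increase"

    if colony_median_k is not None and colony_median_k > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_efflux_rate(t, y, backshift_time)
        if fit.k < thresholds.delayed_k_factor * colony_median_k:
            return "delayed_efflux"
    return "typical"


def classify_forest(forest: LineageForest,
                    thresholds: ClassificationThresholds = ClassificationThresholds(),
                    backshift_time: Optional[float] = None
                    ) -> "dict[int, PhenotypeLabel]":
    """Classify every track of a forest; tracks shorter than 3 frames
    come back unclassified.

    When ``backshift_time`` is given, non-growing tracks with enough
    post-backshift coverage are additionally subtyped against the
    colony-median efflux constant and fluorescence.
    """
    nodes = list(forest.index.values())
    all_fluor = [o.mean_fluor for nd in nodes for o in nd.observations]
    median_fluor = float(np.median(all_fluor)) if all_fluor else 0.0

    labels: dict[int, PhenotypeLabel] = {}
    for nd in nodes:
        labels[nd.track_id] = classify_cell(nd, thresholds, median_fluor)

    if backshift_time is None:
        return labels

    # colony-median efflux constant over tracks covering the backshift
    ks = []
    covered = []
    for nd in nodes:
        t = np.array([o.t_min for o in nd.observations])
        y = np.array([o.mean_fluor for o in nd.observations])
        if t[0] <= backshift_time and \
                t[-1] - backshift_time >= thresholds.resupply_lag:
            covered.append((nd, t, y))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ks.append(fit_efflux_rate(t, y, backshift_time).k)
            except (ValueError, RuntimeError):
                pass
    median_k = float(np.median(ks)) if ks else None

    for nd, t, y in covered:
        lab = labels[nd.track_id]
        if lab.label != "non_growing_active":
            continue
        try:
            sub = subtype_post_resupply(t, y, backshift_time, thresholds,
                                        colony_median_k=median_k,
                                        colony_median_fluor=median_fluor)
        except ValueError:
            continue
        labels[nd.track_id] = PhenotypeLabel(
            label=lab.label, subtype=sub, elevated_fluor=lab.elevated_fluor)
    return labels
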