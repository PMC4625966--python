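"""End-to-end orchestration: simulate -> render -> quantify -> track ->
analyze -> classify, as reproducible, fully persisted runs.

A run is described by a :class:`RunConfig` (protocol preset plus
parameter overrides, seeds, stages).  Every stage writes its outputs
under ``outdir/colony_<seed>/`` so any later stage can be re-run from
persisted intermediates; re-running the same config and seeds
reproduces the outputs exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import kinetics, imaging, quant, tracking, traces, phenotype
from .protocols import MediaProtocol, make_protocol

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "make_figures"]

log = logging.getLogger("calsense.pipeline")

STAGES = ("simulate", "render", "quantify", "track", "analyze", "classify")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    preset: str = "reference_cgxii"
    protocol_overrides: dict = field(default_factory=dict)
    kinetic_overrides: dict = field(default_factory=dict)
    imaging_overrides: dict = field(default_factory=dict)
    seeds: tuple = (1,)
    n_founders: int = 2
    outdir: str = "calsense_run"
    stages: tuple = STAGES
    bypass_ground_truth: bool = False
    naive_founders: bool = False

    def __post_init__(self):
        if not self.seeds:
            raise ValueError("seeds must be non-empty")
        idx = [STAGES.index(s) for s in self.stages]
        if idx != list(range(len(idx))):
            raise ValueError("stages must form a prefix chain of "
                             f"{STAGES}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "seeds" in data:
            data["seeds"] = tuple(data["seeds"])
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["seeds"] = list(self.seeds)
        d["stages"] = list(self.stages)
        return d

    def config_hash(self) -> str:
        """Hash of the scientific configuration (the output location
        does not affect results)."""
        d = self.to_dict()
        d.pop("outdir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def build_protocol(self) -> MediaProtocol:
        return make_protocol(self.preset, **self.protocol_overrides)

    def build_params(self) -> kinetics.KineticParams:
        return kinetics.KineticParams(**self.kinetic_overrides)

    def build_imaging(self) -> imaging.ImagingParams:
        return imaging.ImagingParams(**self.imaging_overrides)


@dataclass
class ReportBundle:
    """Aggregated per-colony results plus provenance."""

    config: RunConfig
    colonies: "dict[int, dict]"            # seed -> results
    provenance: dict

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o))

        return json.dumps({
            "config": self.config.to_dict(),
            "provenance": self.provenance,
            "colonies": {str(k): v for k, v in self.colonies.items()},
        }, indent=1, sort_keys=True, default=default)


def _carbon_shift_times(protocol: MediaProtocol):
    """(shift_time, backshift_time) of the first carbon-free span, or
    (None, None) for protocols without famine."""
    shift = backshift = None
    for ph in protocol.phases:
        if not ph.carbon_present and shift is None:
            shift = ph.start_time
        if shift is not None and ph.carbon_present and ph.start_time > shift:
            backshift = ph.start_time
            break
    if shift is not None and backshift is None:
        backshift = protocol.end_time
    return shift, backshift


def _analyze_colony(cell_table: pd.DataFrame, bg_table: Optional[pd.DataFrame],
                    protocol: MediaProtocol, fluor_floor: float,
                    im_params: Optional[imaging.ImagingParams] = None,
                    forest=None) -> dict:
    series = traces.colony_series(cell_table, bg_table, fluor_floor=fluor_floor)
    mean_fluor = series.mean_fluor
    if im_params is not None and im_params.bleach_frac_per_exposure > 0:
        # undo the calibrated exposure-coupled photobleaching before
        # fitting rate constants
        mean_fluor = traces.bleach_correct(
            mean_fluor, im_params.bleach_frac_per_exposure,
            im_params.exposure_every, background=im_params.background_au)
        series = traces.ColonySeries(
            t=series.t, sum_area=series.sum_area, mean_fluor=mean_fluor,
            cell_count=series.cell_count, extracellular=series.extracellular)
    medium = protocol.phases[0].medium
    window = traces.GROWTH_WINDOW_FRAMES.get(medium, 10)
    out: dict = {
        "t_min": series.t,
        "sum_area_um2": series.sum_area,
        "mean_fluor_au": series.mean_fluor,
        "cell_count": series.cell_count,
        "extracellular": series.extracellular,
    }
    if len(series.t) > window:
        growth = traces.apparent_growth_rate(series, window_frames=window)
        out["mu_app_per_h"] = growth.mu_app
        out["mu_max_per_h"] = growth.mu_max
        out["growth_window_frames"] = window
    shift, backshift = _carbon_shift_times(protocol)
    good = np.isfinite(series.mean_fluor)
    if shift is not None and backshift is not None and backshift > shift:
        conv = traces.fit_conversion_rate(series.t[good],
                                          series.mean_fluor[good],
                                          shift_time=shift,
                                          fit_span=backshift - shift)
        out["k_conv_per_min"] = conv.k
        out["k_conv_window"] = conv.fit_window
        if protocol.end_time - backshift >= 50.0 + protocol.frame_interval:
            bleach = (im_params.bleach_frac_per_exposure, im_params.exposure_every,
                      im_params.background_au) if im_params else (0.0, 1, 0.0)
            if forest is not None:
                tracks = [(np.array([o.frame for o in nd.observations]),
                           np.array([o.t_min for o in nd.observations]),
                           np.array([o.mean_fluor for o in nd.observations]))
                          for nd in forest.index.values()]
                try:
                    mk, _ = traces.per_cell_efflux_constant(
                        tracks, backshift, bleach_frac=bleach[0],
                        exposure_every=bleach[1], background=bleach[2])
                    out["k_eff_per_min"] = mk
                except ValueError:
                    forest = None
            if forest is None:
                eff = traces.fit_efflux_rate(series.t[good],
                                             series.mean_fluor[good],
                                             backshift_time=backshift)
                out["k_eff_per_min"] = eff.k
                out["k_eff_residual_au"] = eff.f_res
    if bg_table is not None and len(bg_table):
        prox = bg_table[bg_table["site"] == "cell_proximity"]["mean_fluor_au"]
        bright = cell_table[cell_table["mean_fluor_au"] >= fluor_floor]
        if len(bright) and len(prox):
            out["snr"] = traces.snr(bright["mean_fluor_au"], prox)
    return out


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the requested stage prefix for every seed.

    Returns a :class:`ReportBundle`; all intermediates and the final
    ``report.json`` are persisted under ``config.outdir``.
    """
    t_start = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    protocol = config.build_protocol()
    params = config.build_params()
    im_params = config.build_imaging()
    fluor_floor = im_params.background_au + 3.0 * im_params.noise_sd
    stages = set(config.stages)
    colonies: dict[int, dict] = {}

    for seed in config.seeds:
        cdir = outdir / f"colony_{seed}"
        cdir.mkdir(exist_ok=True)
        results: dict = {"seed": seed}
        colony = stack = cell_table = bg_table = forest = masks = None
        try:
            if "simulate" in stages:
                colony = kinetics.simulate_colony(
                    config.n_founders, params, protocol, seed=seed,
                    naive_founders=config.naive_founders)
                colony.to_dataframe().to_csv(cdir / "ground_truth.csv",
                                             index=False)
                colony.extracellular_dataframe().to_csv(
                    cdir / "extracellular.csv", index=False)
                log.info("colony %s: simulated %d frames", seed,
                         len(colony.frames))
            if "render" in stages:
                stack = imaging.render_stack(colony, im_params, seed=seed + 1)
                imaging.write_stack(stack, cdir / "stack")
                log.info("colony %s: rendered %d frames", seed, stack.n_frames)
            if "quantify" in stages:
                cell_table, bg_table, masks = quant.measure_stack(
                    stack, bypass_ground_truth=config.bypass_ground_truth,
                    return_masks=True)
                quant.write_table(cell_table, cdir / "observations.csv")
                quant.write_table(bg_table, cdir / "background.csv")
                log.info("colony %s: %d cell observations", seed,
                         len(cell_table))
            if "track" in stages:
                forest = tracking.track_observations(
                    cell_table, pixel_size=im_params.pixel_size,
                    n_frames=len(colony.frames) if colony else None,
                    masks=masks)
                tracking.export_lineage(forest, "newick",
                                        path=cdir / "lineage")
                tracking.export_lineage(forest, "tabular",
                                        path=cdir / "edges.csv")
            if "analyze" in stages:
                results.update(_analyze_colony(cell_table, bg_table, protocol,
                                               fluor_floor, im_params,
                                               forest=forest))
            if "classify" in stages:
                _, backshift = _carbon_shift_times(protocol)
                labels = phenotype.classify_forest(
                    forest, backshift_time=backshift)
                rows = [(tid, lab.label, lab.subtype, lab.elevated_fluor,
                         lab.event_time) for tid, lab in labels.items()]
                pheno = pd.DataFrame(rows, columns=[
                    "track_id", "label", "subtype", "elevated_fluor",
                    "event_time"])
                pheno.to_csv(cdir / "phenotypes.csv", index=False)
                counts = pheno["label"].value_counts().to_dict()
                results["phenotype_counts"] = counts
        except Exception as exc:
            raise RuntimeError(
                f"pipeline failed for seed {seed}: {exc}") from exc
        colonies[seed] = results

    log.info("pipeline finished in %.1f s", time.time() - t_start)
    bundle = ReportBundle(
        config=config, colonies=colonies,
        provenance={"config_hash": config.config_hash(),
                    "n_colonies": len(config.seeds)})
    (outdir / "report.json").write_text(bundle.to_json())
    return bundle


def make_figures(bundle: ReportBundle, outdir=None) -> "list[Path]":
    """Presentation plots: per-colony fluorescence traces, apparent
    growth rate, and cell-count series.  Returns the written files."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(outdir if outdir is not None else bundle.config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if not bundle.colonies:
        return written

    kinds = {
        "traces": ("t_min", "mean_fluor_au", "mean fluorescence (AU)"),
        "growth": (None, "mu_app_per_h", "apparent growth rate (1/h)"),
        "counts": ("t_min", "cell_count", "cell count"),
    }
    for kind, (xkey, ykey, ylabel) in kinds.items():
        fig, ax = plt.subplots(figsize=(5, 3.2))
        plotted = False
        for seed, res in bundle.colonies.items():
            if ykey not in res:
                continue
            y = np.asarray(res[ykey], dtype=float)
            x = (np.asarray(res[xkey], dtype=float)[: len(y)]
                 if xkey and xkey in res else np.arange(len(y)))
            ax.plot(x, y, label=f"seed {seed}", lw=1)
            plotted = True
        if not plotted:
            plt.close(fig)
            continue
        ax.set_xlabel("time (min)" if xkey else "window")
        ax.set_ylabel(ylabel)
        ax.legend(fontsize=6)
        fig.tight_layout()
        path = out / f"fig_{kind}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)
    return written
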