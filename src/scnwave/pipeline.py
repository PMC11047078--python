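"""End-to-end pipeline orchestration: simulate -> preprocess -> fit ->
cluster -> stats, with YAML config, logging and provenance.

A run is driven by a single config mapping (usually loaded from YAML).
Exactly one input source is given: ``synth`` (planted-parameter simulation)
or ``input`` (paths to a TIFF stack, its JSON sidecar and an optional tissue
mask). All stage outputs are plain CSV/JSON/TIFF/PNG files in the run
directory, and a provenance file echoes the config, seeds and package
version so any number in the outputs can be reproduced from it.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, circstats, cluster, rhythm, stack_io, synth, temp_response

__all__ = [
    "ConfigError",
    "StageError",
    "PipelineConfig",
    "validate_sidecar",
    "load_config",
    "run_pipeline",
]

log = logging.getLogger("scnwave")

ALL_STAGES = ("simulate", "preprocess", "rhythm", "cluster", "stats")


class ConfigError(ValueError):
    """Invalid configuration — refused before any computation."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


SIDECAR_SCHEMA = {
    "frame_interval_h": (int, float),
    "channel": str,
    "t0_h": (int, float),
    "temperature_epochs": list,
}


def validate_sidecar(meta: dict) -> list[str]:
    """Validate a stack-metadata sidecar against the expected schema.

    Returns a list of problems (empty = valid). ``frame_interval_h`` is
    required and positive; ``temperature_epochs`` entries need numeric
    start_h/end_h/temp_c.
    """
    problems: list[str] = []
    if "frame_interval_h" not in meta:
        problems.append("missing required key 'frame_interval_h'")
    for key, typ in SIDECAR_SCHEMA.items():
        if key in meta and not isinstance(meta[key], typ):
            problems.append(f"key '{key}' has type {type(meta[key]).__name__}")
    if isinstance(meta.get("frame_interval_h"), (int, float)) and meta["frame_interval_h"] <= 0:
        problems.append("'frame_interval_h' must be > 0")
    for i, ep in enumerate(meta.get("temperature_epochs", []) or []):
        if not isinstance(ep, dict):
            problems.append(f"temperature_epochs[{i}] is not a mapping")
            continue
        for k in ("start_h", "end_h", "temp_c"):
            if not isinstance(ep.get(k), (int, float)):
                problems.append(f"temperature_epochs[{i}] lacks numeric '{k}'")
    return problems


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see module docstring for the YAML
    layout; every field has the package default so a minimal config runs)."""

    synth: dict | None = None
    input: dict | None = None
    window_h: float = 24.5
    roi_size: int = 3
    retention_frac: float = 0.5
    normalization: str = "zscore"
    band_h: tuple[float, float] = rhythm.DEFAULT_BAND_H
    rae_threshold: float = rhythm.DEFAULT_RAE_THRESHOLD
    transient_skip_h: float = 12.0
    k: int = 5
    seed: int = 0
    n_init: int = 10
    temp_response_enabled: bool = True
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineConfig":
        if not isinstance(cfg, dict):
            raise ConfigError("config must be a mapping")
        if bool(cfg.get("synth")) == bool(cfg.get("input")):
            raise ConfigError("config needs exactly one of 'synth' or 'input'")
        det = cfg.get("detrend", {}) or {}
        rhy = cfg.get("rhythm", {}) or {}
        clu = cfg.get("cluster", {}) or {}
        tr = cfg.get("temp_response", {}) or {}
        pc = cls(
            synth=cfg.get("synth"),
            input=cfg.get("input"),
            window_h=float(det.get("window_h", 24.5)),
            roi_size=int(det.get("roi_size", 3)),
            retention_frac=float(det.get("retention_frac", 0.5)),
            normalization=str(clu.get("normalization", "zscore")),
            band_h=tuple(rhy.get("band_h", rhythm.DEFAULT_BAND_H)),
            rae_threshold=float(rhy.get("rae_threshold", rhythm.DEFAULT_RAE_THRESHOLD)),
            transient_skip_h=float(rhy.get("transient_skip_h", 12.0)),
            k=int(clu.get("k", 5)),
            seed=int(clu.get("seed", cfg.get("seed", 0))),
            n_init=int(clu.get("n_init", 10)),
            temp_response_enabled=bool(tr.get("enabled", True)),
            raw=cfg,
        )
        if pc.input is not None and "stack" not in pc.input:
            raise ConfigError("'input' config needs a 'stack' path")
        if pc.temp_response_enabled and pc.input is not None:
            sidecar = pc.input.get("sidecar")
            if sidecar is not None and Path(sidecar).exists():
                meta = json.loads(Path(sidecar).read_text())
                if not meta.get("temperature_epochs"):
                    raise ConfigError(
                        "temp_response requested but the sidecar carries no temperature_epochs"
                    )
        return pc


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh))


def _synth_params(cfg: dict) -> synth.SynthParams:
    cfg = dict(cfg)
    epochs = cfg.pop("temperature_epochs", None)
    if "grid_shape" in cfg:
        cfg["grid_shape"] = tuple(cfg["grid_shape"])
    if epochs:
        cfg["temperature_schedule"] = stack_io.TemperatureSchedule.from_dicts(epochs)
    try:
        return synth.SynthParams(**cfg)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid synth parameters: {exc}") from exc


def _fit_row(trace_id: str, epoch: Any, fit: rhythm.RhythmFit | None) -> dict:
    row = {"trace_id": trace_id, "epoch": epoch}
    if fit is None:
        row.update(
            period_h=np.nan, amplitude=np.nan, abs_phase_h=np.nan,
            circ_phase_h=np.nan, rae=np.nan, gof=np.nan, is_rhythmic=False,
        )
    else:
        row.update(fit.as_row())
    return row


def run_pipeline(
    config: PipelineConfig | dict,
    out_dir: str | Path,
    stages: tuple[str, ...] = ALL_STAGES,
) -> dict:
    """Run the requested stages and write all outputs under ``out_dir``.

    Returns a dict of in-memory results (per channel: whole-tissue fit,
    per-epoch fits, cluster result, wave vector, stats). A stage failure
    leaves completed-stage outputs in place, writes a FAILED marker naming
    the stage, and raises :class:`StageError`.
    """
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t_start = time.time()
    timings: dict[str, float] = {}
    results: dict[str, Any] = {"channels": {}}
    current_stage = "setup"
    try:
        # ------------------------------------------------------------ input
        channels: list[tuple[stack_io.FrameStack, stack_io.TemperatureSchedule | None]] = []
        mask = None
        gt = None
        if config.synth is not None and "simulate" in stages:
            current_stage = "simulate"
            t0 = time.time()
            params = _synth_params(config.synth)
            generated, gt = synth.generate_stack(params)
            stacks = generated if isinstance(generated, tuple) else (generated,)
            sim_dir = out / "sim"
            sim_dir.mkdir(exist_ok=True)
            for st in stacks:
                synth.write_stack(
                    st, sim_dir / f"{st.channel or 'stack'}.tif",
                    schedule=params.temperature_schedule, seed=params.seed,
                )
                channels.append((st, params.temperature_schedule))
            synth.write_ground_truth(gt, sim_dir)
            mask = gt.tissue_mask
            timings["simulate"] = time.time() - t0
            log.info("simulated %d channel(s), %d frames", len(stacks), stacks[0].n_frames)
        elif config.input is not None:
            current_stage = "load"
            st, schedule = stack_io.read_stack(
                config.input["stack"], config.input.get("sidecar")
            )
            channels.append((st, schedule))
            if config.input.get("mask"):
                mask = stack_io.read_mask(config.input["mask"])
            else:
                mask = np.ones(st.frame_shape, dtype=bool)
        if not channels:
            raise ConfigError("nothing to analyze: no synth stage requested and no input")

        whole_rows, epoch_rows, cluster_stat_rows, slope_rows = [], [], [], []
        whole_fits: dict[str, rhythm.RhythmFit] = {}

        for st, schedule in channels:
            ch = st.channel or "stack"
            ch_dir = out / ch
            ch_dir.mkdir(exist_ok=True)
            ch_res: dict[str, Any] = {}
            results["channels"][ch] = ch_res

            # ------------------------------------------------------- rhythm
            if "rhythm" in stages:
                current_stage = "rhythm"
                t0 = time.time()
                mean_trace = stack_io.extract_mean_trace(st, mask)
                fit = rhythm.fit_dominant_sinewave(
                    stack_io.cubic_detrend(mean_trace),
                    st.frame_interval_h, config.band_h, config.rae_threshold,
                )
                whole_fits[ch] = fit
                ch_res["whole_tissue_fit"] = fit
                whole_rows.append(_fit_row(ch, "all", fit))
                if schedule is not None and len(schedule) > 1:
                    efits = rhythm.fit_per_epoch(
                        mean_trace, st.frame_interval_h, schedule,
                        config.transient_skip_h, config.band_h, config.rae_threshold,
                    )
                    ch_res["per_epoch_fits"] = efits
                    for ef in efits:
                        epoch_rows.append(_fit_row(ch, ef.epoch_index, ef.fit))
                timings[f"rhythm/{ch}"] = time.time() - t0

            # --------------------------------------------------- preprocess
            rois = None
            if "preprocess" in stages or "cluster" in stages:
                current_stage = "preprocess"
                t0 = time.time()
                detrended = stack_io.moving_average_detrend(st, config.window_h)
                rois = stack_io.tile_rois(detrended, mask, config.roi_size, config.retention_frac)
                ch_res["rois"] = rois
                df = pd.DataFrame(rois.series)
                df.insert(0, "col", rois.roi_centers[:, 1])
                df.insert(0, "row", rois.roi_centers[:, 0])
                df.insert(0, "roi_id", np.arange(rois.n_roi))
                df.to_csv(ch_dir / "roi_series.csv", index=False)
                timings[f"preprocess/{ch}"] = time.time() - t0

            # ------------------------------------------------------ cluster
            if "cluster" in stages and rois is not None:
                current_stage = "cluster"
                t0 = time.time()
                norm = stack_io.normalize_series(rois.series, config.normalization)
                cres = cluster.kmeans_timeseries(
                    rois, k=config.k, seed=config.seed, n_init=config.n_init,
                    band_h=config.band_h, rae_threshold=config.rae_threshold,
                    series=norm.values,
                )
                ch_res["cluster"] = cres
                pd.DataFrame(
                    {
                        "roi_id": np.arange(rois.n_roi),
                        "row": rois.roi_centers[:, 0],
                        "col": rois.roi_centers[:, 1],
                        "cluster": cres.labels,
                        "is_NR": cres.is_nr[cres.labels],
                    }
                ).to_csv(ch_dir / "cluster_labels.csv", index=False)
                pd.DataFrame(
                    [
                        {
                            "cluster": c,
                            "size": int(cres.sizes[c]),
                            "com_row": cres.com[c, 0],
                            "com_col": cres.com[c, 1],
                            "is_NR": bool(cres.is_nr[c]),
                            **cres.fits[c].as_row(),
                        }
                        for c in range(cres.k)
                    ]
                ).to_csv(ch_dir / "cluster_stats.csv", index=False)
                phase_img, nr_mask = cluster.cluster_phase_map(cres, st.frame_shape)
                import tifffile

                tifffile.imwrite(ch_dir / "phase_map.tif", phase_img.astype(np.float32))
                _render_phase_map(phase_img, nr_mask, ch_dir / "phase_map.png")
                wv = cluster.wave_vector(cres)
                ch_res["wave_vector"] = wv
                (ch_dir / "wave_vector.json").write_text(
                    json.dumps(
                        {
                            "defined": wv.defined,
                            "angle_rad": wv.angle_rad,
                            "angle_deg": wv.angle_deg,
                            "r2": wv.r2,
                            "path": wv.path.tolist(),
                        },
                        allow_nan=True,
                    )
                )
                timings[f"cluster/{ch}"] = time.time() - t0

            # -------------------------------------------------------- stats
            if "stats" in stages:
                current_stage = "stats"
                t0 = time.time()
                if "cluster" in ch_res:
                    cres = ch_res["cluster"]
                    rhythmic_fits = [f for f in cres.fits if f.is_rhythmic]
                    stat = {"channel": ch, "n_rhythmic_clusters": len(rhythmic_fits)}
                    if rhythmic_fits:
                        sample = circstats.PhaseSample.from_hours(
                            [f.circ_phase_h for f in rhythmic_fits], period_h=24.0
                        )
                        stat["intercluster_circvar"] = circstats.circular_variance(sample)
                    if len(rhythmic_fits) >= 2:
                        mean_h, sd_h = circstats.period_dispersion(rhythmic_fits)
                        stat["period_mean_h"] = mean_h
                        stat["period_sd_h"] = sd_h
                    cluster_stat_rows.append(stat)
                    ch_res["stats"] = stat
                if config.temp_response_enabled and schedule is not None:
                    mean_trace = stack_io.extract_mean_trace(st, mask)
                    slopes = temp_response.epoch_slopes(
                        mean_trace, st.frame_interval_h, schedule
                    )
                    ch_res["epoch_slopes"] = slopes
                    for s in slopes:
                        slope_rows.append({"channel": ch, **asdict(s)})
                    if "per_epoch_fits" in ch_res:
                        try:
                            ch_res["delta_period_h"] = temp_response.delta_period(
                                ch_res["per_epoch_fits"]
                            )
                        except ValueError as exc:
                            log.info("delta_period skipped for %s: %s", ch, exc)
                timings[f"stats/{ch}"] = time.time() - t0

        # ---------------------------------------------------- cross-channel
        if len(whole_fits) == 2 and "rhythm" in stages:
            (ch_a, fit_a), (ch_b, fit_b) = whole_fits.items()
            if fit_a.is_rhythmic and fit_b.is_rhythmic:
                lag = rhythm.phase_offset(fit_a, fit_b)
                results["phase_offset_h"] = lag
                (out / "phase_offset.json").write_text(
                    json.dumps({"reporter_a": ch_a, "reporter_b": ch_b, "offset_h": lag})
                )

        if whole_rows or epoch_rows:
            pd.DataFrame(whole_rows + epoch_rows).to_csv(out / "rhythm_fits.csv", index=False)
        if cluster_stat_rows:
            pd.DataFrame(cluster_stat_rows).to_csv(out / "cluster_circstats.csv", index=False)
        if slope_rows:
            pd.DataFrame(slope_rows).to_csv(out / "epoch_slopes.csv", index=False)

        provenance = {
            "version": __version__,
            "config": config.raw,
            "seed": config.seed,
            "stages": list(stages),
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
            "elapsed_s": round(time.time() - t_start, 3),
        }
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
        return results
    except ConfigError:
        raise
    except Exception as exc:  # mark the failed stage, keep completed outputs
        (out / "FAILED").write_text(f"{current_stage}: {exc}\n")
        raise StageError(current_stage, str(exc)) from exc
    finally:
        log.removeHandler(handler)
        handler.close()


def _render_phase_map(phase_img: np.ndarray, nr_mask: np.ndarray, path: Path) -> None:
    """Diagnostic-grade phase-map rendering: phase color-coded, NR gray."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(phase_img, cmap="twilight", interpolation="nearest")
    overlay = np.zeros((*nr_mask.shape, 4))
    overlay[nr_mask] = (0.5, 0.5, 0.5, 1.0)
    ax.imshow(overlay, interpolation="nearest")
    fig.colorbar(im, ax=ax, label="peak phase (h)")
    ax.set_title("cluster phase map (gray = NR)")
    ax.set_axis_off()
    fig.savefig(path, dpi=100)
    plt.close(fig)
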