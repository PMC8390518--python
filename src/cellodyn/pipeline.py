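"""Pipeline orchestration: simulate -> (render/localize) -> segment -> fit -> report.

Each stage reads and writes only documented CSV/TIFF/JSON artifacts inside
the run directory, so stages are independently re-runnable; a manifest
records the seed, a config hash and per-stage row counts.  All randomness
funnels through one master seed; stage-local seeds are derived from it
deterministically.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from . import __version__
from .io import (
    Trajectory,
    read_trajectories,
    write_json,
    write_trajectories,
)
from .kinetics import (
    branching_fractions,
    build_report,
    collect_dwell_samples,
    derive_rates,
    fit_exponential_mle,
    report_to_markdown,
    report_to_tsv,
)
from .localize import correct_drift, link_spots, localize_stack
from .segment import (
    SegmentationParams,
    apply_filters,
    jumps_to_dataframe,
    molecules_to_dataframe,
    segment_trajectory,
    segments_to_dataframe,
)
from .sim import MovieSpec, SimConfig, render_movie, simulate_experiment

ALL_STAGES = ("simulate", "render", "localize", "segment", "fit", "report")
DEFAULT_STAGES = ("simulate", "segment", "fit", "report")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    stages: tuple[str, ...] = DEFAULT_STAGES
    sim: SimConfig = field(default_factory=SimConfig)
    movie: MovieSpec = field(default_factory=MovieSpec)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    boot_iterations: int = 1000
    static_pooling: str = "weighted"
    seed: int = 0
    trajectories_in: str | None = None
    localize_threshold: float = 60.0
    localize_window: int = 7
    link_max_step: float = 300.0
    link_max_gap: int = 1
    fiducial_min_amplitude: float | None = 1000.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        if d["sim"].get("drift") is not None:
            d["sim"]["drift"] = np.asarray(d["sim"]["drift"]).tolist()
        d["sim"].pop("_speed_params", None)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def derive_seed(master: int, stage: str) -> int:
    """Deterministic stage-local seed below 2^31."""
    import zlib

    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def _build_section(cls, data: dict, section: str, errors: list[str]):
    known = {f.name for f in dataclasses.fields(cls) if f.init}
    kwargs = {}
    for key, val in data.items():
        if key not in known:
            errors.append(f"{section}: unknown key '{key}'")
            continue
        kwargs[key] = val
    try:
        obj = cls(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"{section}: {exc}")
        return cls()
    try:
        obj.validate()
    except ValueError as exc:
        errors.append(f"{section}: {exc}")
    return obj


def validate_config(source: str | Path | dict | None) -> tuple[PipelineConfig, list[str]]:
    """Parse and schema-check a pipeline config (YAML/JSON path or dict).

    Unknown keys and out-of-range values produce itemized error messages;
    an empty file yields the full default configuration (whose thresholds
    are the standard analysis values: 10 nm static radius, 5 s segment
    minimum, 10 s event minimum, 500 s landing cutoff, 510 s maximum
    duration, 1000 bootstrap iterations, 66.0 nm pixels, 1 frame/s).
    """
    if source is None:
        data: dict = {}
    elif isinstance(source, dict):
        data = dict(source)
    else:
        text = Path(source).read_text()
        if not text.strip():
            data = {}
        else:
            import yaml

            loaded = yaml.safe_load(text)
            if loaded is None:
                data = {}
            elif not isinstance(loaded, dict):
                return PipelineConfig(), ["config root must be a mapping"]
            else:
                data = loaded

    errors: list[str] = []
    sections = {"sim": SimConfig, "movie": MovieSpec, "segmentation": SegmentationParams}
    top_known = set(sections) | {
        "stages", "boot_iterations", "static_pooling", "seed", "trajectories_in",
        "localize_threshold", "localize_window", "link_max_step", "link_max_gap",
        "fiducial_min_amplitude",
    }
    for key in data:
        if key not in top_known:
            errors.append(f"unknown key '{key}'")

    cfg = PipelineConfig(
        sim=_build_section(SimConfig, data.get("sim", {}) or {}, "sim", errors),
        movie=_build_section(MovieSpec, data.get("movie", {}) or {}, "movie", errors),
        segmentation=_build_section(
            SegmentationParams, data.get("segmentation", {}) or {}, "segmentation", errors
        ),
    )
    for key in ("boot_iterations", "static_pooling", "seed", "trajectories_in",
                "localize_threshold", "localize_window", "link_max_step", "link_max_gap",
                "fiducial_min_amplitude"):
        if key in data:
            setattr(cfg, key, data[key])
    if "stages" in data:
        stages = tuple(data["stages"])
        for st in stages:
            if st not in ALL_STAGES:
                errors.append(f"stages: unknown stage '{st}'")
        cfg.stages = stages
    if cfg.static_pooling not in ("weighted", "molecules_only", "segments_only"):
        errors.append("static_pooling must be weighted|molecules_only|segments_only")
    if cfg.boot_iterations < 1:
        errors.append("boot_iterations must be >= 1")
    return cfg, errors


def run_pipeline(config: PipelineConfig, outdir: str | Path, seed: int | None = None) -> Path:
    """Execute the enabled stages in order, writing artifacts to ``outdir``.

    On stage failure the manifest marks the failure point and partial
    artifacts are retained; a :class:`PipelineError` is raised.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config.seed = int(seed)
        config.sim.rng_seed = int(seed)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
        "status": "running",
    }
    write_json(config.to_dict(), outdir / "config.json")

    trajectories: list[Trajectory] | None = None
    truths = None
    segmented = None
    fits = None
    counts = None
    movie_length = config.sim.n_frames * config.sim.frame_interval

    def finish_stage(name: str, **info):
        manifest["stages"][name] = {"status": "ok", **info}
        write_json(manifest, outdir / "manifest.json")

    try:
        for stage in config.stages:
            if stage == "simulate":
                trajectories, truths = simulate_experiment(config.sim)
                write_trajectories(trajectories, outdir / "trajectories.csv")
                write_json([m.to_record() for m in truths], outdir / "ground_truth.json")
                finish_stage(stage, n_molecules=len(truths), n_trajectories=len(trajectories))
            elif stage == "render":
                if trajectories is None:
                    trajectories = read_trajectories(outdir / "trajectories.csv")
                rng = np.random.default_rng(derive_seed(config.seed, "render"))
                render_movie(
                    trajectories, config.movie, rng,
                    drift=config.sim.drift, path=outdir / "movie.tif",
                )
                write_json(
                    {"bead_positions_nm": [list(b) for b in config.movie.bead_positions]},
                    outdir / "beads.json",
                )
                finish_stage(stage, n_frames=config.movie.n_frames)
            elif stage == "localize":
                import tifffile

                stack = tifffile.imread(str(outdir / "movie.tif"))
                per_frame, diag = localize_stack(
                    stack,
                    intensity_threshold=config.localize_threshold,
                    window=config.localize_window,
                    pixel_size=config.movie.pixel_size,
                )
                tracks = link_spots(
                    per_frame,
                    max_step=config.link_max_step,
                    max_gap=config.link_max_gap,
                    fiducial_min_amplitude=config.fiducial_min_amplitude,
                )
                fiducials = [t for t in tracks if t.is_fiducial]
                if fiducials:
                    tracks, _ = correct_drift(tracks, fiducials, len(stack))
                trajectories = [
                    t.to_trajectory(config.sim.frame_interval)
                    for t in tracks
                    if not t.is_fiducial
                ]
                write_trajectories(trajectories, outdir / "trajectories_localized.csv")
                write_trajectories(
                    [t.to_trajectory(config.sim.frame_interval) for t in fiducials],
                    outdir / "fiducials.csv",
                )
                write_json(diag, outdir / "localize_diagnostics.json")
                finish_stage(stage, n_tracks=len(trajectories), n_fiducials=len(fiducials))
            elif stage == "segment":
                if trajectories is None:
                    src = config.trajectories_in or outdir / "trajectories.csv"
                    trajectories = read_trajectories(src)
                segmented_all = [
                    segment_trajectory(t, config.segmentation, movie_length)
                    for t in trajectories
                    if len(t) > 0
                ]
                segmented, filter_report = apply_filters(segmented_all, config.segmentation)
                segments_to_dataframe(segmented).to_csv(outdir / "segments.csv", index=False)
                jumps_to_dataframe(segmented).to_csv(outdir / "jumps.csv", index=False)
                molecules_to_dataframe(segmented).to_csv(outdir / "molecules.csv", index=False)
                write_json(dataclasses.asdict(filter_report), outdir / "filter_report.json")
                finish_stage(stage, n_retained=filter_report.n_retained,
                             n_input=filter_report.n_input)
            elif stage == "fit":
                if segmented is None:
                    raise PipelineError("fit stage requires the segment stage")
                samples = collect_dwell_samples(segmented, config.segmentation)
                rng = np.random.default_rng(derive_seed(config.seed, "fit"))
                fits = {}
                for label, sample in samples.items():
                    try:
                        fits[label] = fit_exponential_mle(
                            sample, boot_iterations=config.boot_iterations, seed=rng
                        )
                    except ValueError:
                        continue  # too few events for this label
                write_json(
                    {
                        lab: {
                            "tau_s": f.tau, "ci95": list(f.ci95), "n": f.n,
                            "boot_iterations": f.boot_iterations,
                            "t_min": f.t_min, "t_max": f.t_max,
                        }
                        for lab, f in fits.items()
                    },
                    outdir / "fits.json",
                )
                finish_stage(stage, n_fits=len(fits))
            elif stage == "report":
                if segmented is None or fits is None:
                    raise PipelineError("report stage requires segment and fit stages")
                counts = branching_fractions(segmented)
                rates = derive_rates(fits, counts, config.static_pooling)
                report = build_report(segmented, fits, counts, rates)
                write_json(report["rates"], outdir / "rates.json")
                write_json(report, outdir / "report.json")
                (outdir / "report.tsv").write_text(report_to_tsv(report))
                (outdir / "report.md").write_text(report_to_markdown(report))
                finish_stage(stage)
            else:
                raise PipelineError(f"unknown stage '{stage}'")
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failure_stage"] = stage
        manifest["error"] = str(exc)
        write_json(manifest, outdir / "manifest.json")
        raise

    manifest["status"] = "ok"
    write_json(manifest, outdir / "manifest.json")
    return outdir
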