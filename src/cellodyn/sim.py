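"""Synthetic-data generator for single-molecule cellulase tracking.

The generator realizes a three-state kinetic scheme for an exoglucanase
(e.g. *Tr*Cel7A) interacting with surface-immobilized cellulose.  A molecule
in solution lands on the substrate either in a *static* state (probability
``p_land_static``) or directly in a *processive* state.  While bound it
alternates between the two states; every exit from a bound state is a
first-order event, so dwell times are exponential and exit routes are chosen
with probability rate/total-rate:

* static state: total exit rate ``k_off_static + k_processive``; the
  molecule unbinds with probability ``k_off_static / total`` or starts a
  processive run otherwise.
* processive state: total exit rate ``k_off_processive + k_static``; the
  molecule unbinds or stalls back into the static state.

Processive motion is 1D along a fixed random heading per binding event (a
proxy for the cellulose strand being hydrolysed).  Per-segment speeds are
drawn from a truncated normal parameterized by its *post-truncation*
moments, so the configured mean/SD are the moments of the speeds the
experiment actually reports.  In ``runlength`` mode the processive dwell is
instead (sampled run length)/(sampled speed), with run lengths drawn as a
left-truncated exponential whose post-truncation mean is
``segment_length_mean``.

Rendering converts a state path into per-frame observed positions: constant
anchor during static dwells, linear advance during processive dwells,
instantaneous anchor displacements for jumps (brief unbinding/rebinding
events), plus shared stage drift and i.i.d. Gaussian localization noise.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .io import Trajectory

STATIC = "static"
PROCESSIVE = "processive"

_MAX_VISITS = 100_000


class SimulationError(ValueError):
    """Raised for configurations that cannot produce a terminating path."""


def truncnorm_from_moments(mean: float, sd: float, lower: float) -> tuple[float, float, float]:
    """Solve the underlying normal of a lower-truncated normal from its moments.

    Returns ``(alpha, mu, sigma)`` such that a normal(mu, sigma) truncated to
    ``[lower, inf)`` (standardized lower bound ``alpha``) has the requested
    post-truncation mean and SD.  Feasibility requires ``mean > lower`` and
    ``sd < mean - lower`` (the coefficient of variation of a lower-truncated
    normal about its bound is strictly below the exponential limit of 1).
    """
    if mean <= lower:
        raise ValueError("truncated mean must exceed the lower bound")
    if sd <= 0:
        raise ValueError("sd must be positive")
    excess = mean - lower
    target = excess / sd  # = (m(alpha) - alpha) / sqrt(v(alpha)), decreasing to 1
    if target <= 1.0:
        raise ValueError(
            "sd too large relative to (mean - lower) for a truncated normal"
        )

    def h(alpha: float) -> float:
        m, v = stats.truncnorm.stats(alpha, np.inf, moments="mv")
        return (float(m) - alpha) / math.sqrt(float(v)) - target

    alpha = optimize.brentq(h, -40.0, 80.0, xtol=1e-12)
    m, v = stats.truncnorm.stats(alpha, np.inf, moments="mv")
    sigma = sd / math.sqrt(float(v))
    mu = lower - alpha * sigma
    return float(alpha), float(mu), float(sigma)


@dataclass
class SimConfig:
    """Generator parameters; defaults are the study conditions.

    Rates are s^-1, lengths nm, speeds nm/s, times s.  ``drift`` is an
    optional per-frame ``(n_frames, 2)`` array of shared stage displacement
    in nm applied to every object.
    """

    k_off_static: float = 0.0106
    k_processive: float = 0.00064
    k_off_processive: float = 0.0113
    k_static: float = 0.0379
    p_land_static: float = 0.944
    speed_mean: float = 3.24
    speed_sd: float = 2.68
    speed_min: float = 0.5
    segment_length_mean: float = 38.6
    run_length_min: float = 10.0
    motion_mode: str = "duration"  # "duration" | "runlength"
    frame_interval: float = 1.0
    n_frames: int = 1000
    landing_window: float = 500.0
    localization_sd: float = 1.5
    jump_rate: float = 0.0008
    jump_distance_scale: float = 48.6
    jump_distance_max: float = 100.0
    drift: np.ndarray | None = None
    n_molecules: int = 1000
    rng_seed: int = 0
    field_size_nm: float = 5000.0

    _speed_params: tuple[float, float, float] | None = field(
        default=None, init=False, repr=False, compare=False
    )

    def validate(self) -> None:
        for name in ("k_off_static", "k_processive", "k_off_processive", "k_static",
                     "jump_rate", "localization_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.p_land_static <= 1.0:
            raise ValueError("p_land_static must be in [0, 1]")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.n_frames < 0 or self.n_molecules < 0:
            raise ValueError("n_frames and n_molecules must be >= 0")
        if self.motion_mode not in ("duration", "runlength"):
            raise ValueError("motion_mode must be 'duration' or 'runlength'")
        if self.motion_mode == "runlength" and self.segment_length_mean <= self.run_length_min:
            raise ValueError("segment_length_mean must exceed run_length_min")
        if self.drift is not None:
            d = np.asarray(self.drift, dtype=float)
            if d.shape != (self.n_frames, 2):
                raise ValueError("drift must have shape (n_frames, 2)")

    def speed_params(self) -> tuple[float, float, float]:
        """(alpha, mu, sigma) of the moment-matched truncated speed normal."""
        if self._speed_params is None:
            self._speed_params = truncnorm_from_moments(
                self.speed_mean, self.speed_sd, self.speed_min
            )
        return self._speed_params

    def draw_speed(self, rng: np.random.Generator, size: int | None = None):
        if self.speed_sd == 0:
            return self.speed_mean if size is None else np.full(size, self.speed_mean)
        alpha, mu, sigma = self.speed_params()
        out = stats.truncnorm.rvs(
            alpha, np.inf, loc=mu, scale=sigma, size=size or 1, random_state=rng
        )
        return float(out[0]) if size is None else out


@dataclass
class StateVisit:
    """One dwell in a bound state; speed/heading are 0 for static visits."""

    state: str
    dwell: float
    speed: float
    heading: float


@dataclass
class JumpTruth:
    """A true jump: instantaneous anchor displacement at `time` (s since landing)."""

    time: float
    distance: float
    dx: float
    dy: float


@dataclass
class GroundTruthMolecule:
    """True state path of one simulated molecule.

    ``frames``/``true_x``/``true_y`` (filled by :func:`render_positions`)
    give noise- and drift-free per-frame positions, jumps included; they are
    defined only between landing and unbinding.
    """

    molecule_id: int
    landing_time: float
    origin_x: float
    origin_y: float
    heading: float
    visits: list[StateVisit]
    jumps: list[JumpTruth]
    frames: np.ndarray | None = None
    true_x: np.ndarray | None = None
    true_y: np.ndarray | None = None

    @property
    def total_bound_duration(self) -> float:
        return float(sum(v.dwell for v in self.visits))

    @property
    def ever_processive(self) -> bool:
        return any(v.state == PROCESSIVE for v in self.visits)

    def state_sequence(self) -> list[tuple[str, float, float, float]]:
        return [(v.state, v.dwell, v.speed, v.heading) for v in self.visits]

    def to_record(self) -> dict:
        return {
            "molecule_id": self.molecule_id,
            "landing_time": self.landing_time,
            "origin_x": self.origin_x,
            "origin_y": self.origin_y,
            "heading": self.heading,
            "visits": [
                {"state": v.state, "dwell": v.dwell, "speed": v.speed, "heading": v.heading}
                for v in self.visits
            ],
            "jumps": [
                {"time": j.time, "distance": j.distance, "dx": j.dx, "dy": j.dy}
                for j in self.jumps
            ],
        }


def sample_state_path(
    config: SimConfig,
    rng: np.random.Generator,
    molecule_id: int = 0,
    landing_time: float = 0.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> GroundTruthMolecule:
    """Sample one molecule's bound-state path from the three-state scheme.

    The initial state is static with probability ``p_land_static``.  Each
    dwell is exponential in the state's total exit rate (in ``runlength``
    mode the processive dwell is length/speed instead); the exit route is
    chosen in proportion to the route rates.  Raises
    :class:`SimulationError` if a reachable state has no exit route.
    """
    config.validate()
    k_exit_static = config.k_off_static + config.k_processive
    k_exit_proc = config.k_off_processive + config.k_static
    heading = float(rng.uniform(0.0, 2.0 * math.pi))
    state = STATIC if rng.random() < config.p_land_static else PROCESSIVE
    visits: list[StateVisit] = []
    while True:
        if len(visits) >= _MAX_VISITS:
            raise SimulationError("state path did not terminate")
        if state == STATIC:
            if k_exit_static <= 0:
                raise SimulationError("static state is reachable but has no exit rate")
            dwell = float(rng.exponential(1.0 / k_exit_static))
            visits.append(StateVisit(STATIC, dwell, 0.0, 0.0))
            if rng.random() < config.k_processive / k_exit_static:
                state = PROCESSIVE
            else:
                break
        else:
            if k_exit_proc <= 0:
                raise SimulationError("processive state is reachable but has no exit route")
            speed = float(config.draw_speed(rng))
            if config.motion_mode == "duration":
                dwell = float(rng.exponential(1.0 / k_exit_proc))
            else:
                length = config.run_length_min + float(
                    rng.exponential(config.segment_length_mean - config.run_length_min)
                )
                dwell = length / speed
            visits.append(StateVisit(PROCESSIVE, dwell, speed, heading))
            if rng.random() < config.k_static / k_exit_proc:
                state = STATIC
            else:
                break

    total = sum(v.dwell for v in visits)
    jumps: list[JumpTruth] = []
    if config.jump_rate > 0 and total > 0:
        n_jumps = int(rng.poisson(config.jump_rate * total))
        for t_jump in np.sort(rng.uniform(0.0, total, size=n_jumps)):
            dist = float(rng.exponential(config.jump_distance_scale))
            while dist > config.jump_distance_max:
                dist = float(rng.exponential(config.jump_distance_scale))
            phi = float(rng.uniform(0.0, 2.0 * math.pi))
            jumps.append(JumpTruth(float(t_jump), dist, dist * math.cos(phi), dist * math.sin(phi)))

    return GroundTruthMolecule(
        molecule_id=molecule_id,
        landing_time=float(landing_time),
        origin_x=float(origin[0]),
        origin_y=float(origin[1]),
        heading=heading,
        visits=visits,
        jumps=jumps,
    )


def _true_positions(molecule: GroundTruthMolecule, tau: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free positions at times `tau` (seconds since landing)."""
    boundaries = np.cumsum([v.dwell for v in molecule.visits])
    starts = np.concatenate([[0.0], boundaries[:-1]])
    # cumulative displacement at the start of each visit
    sx, sy = molecule.origin_x, molecule.origin_y
    seg_x, seg_y = [], []
    for v in molecule.visits:
        seg_x.append(sx)
        seg_y.append(sy)
        if v.state == PROCESSIVE:
            sx += v.speed * v.dwell * math.cos(v.heading)
            sy += v.speed * v.dwell * math.sin(v.heading)
    idx = np.clip(np.searchsorted(boundaries, tau, side="right"), 0, len(molecule.visits) - 1)
    x = np.empty_like(tau)
    y = np.empty_like(tau)
    for i, (ti, vi) in enumerate(zip(tau, idx)):
        v = molecule.visits[vi]
        dt_in = ti - starts[vi]
        x[i] = seg_x[vi]
        y[i] = seg_y[vi]
        if v.state == PROCESSIVE:
            x[i] += v.speed * dt_in * math.cos(v.heading)
            y[i] += v.speed * dt_in * math.sin(v.heading)
    if molecule.jumps:
        jt = np.array([j.time for j in molecule.jumps])
        jx = np.cumsum([j.dx for j in molecule.jumps])
        jy = np.cumsum([j.dy for j in molecule.jumps])
        k = np.searchsorted(jt, tau, side="right")
        x += np.where(k > 0, jx[np.maximum(k - 1, 0)], 0.0)
        y += np.where(k > 0, jy[np.maximum(k - 1, 0)], 0.0)
    return x, y


def render_positions(
    molecule: GroundTruthMolecule,
    config: SimConfig,
    rng: np.random.Generator,
) -> Trajectory:
    """Render a state path into an observed trajectory.

    Positions are sampled at the global frame grid (``k * frame_interval``)
    for frames falling inside the bound interval; shared drift (if
    configured) and independent Gaussian localization noise of SD
    ``localization_sd`` are added per coordinate per frame.  Jump
    displacements are instantaneous, so they complete within one frame.
    """
    dt = config.frame_interval
    t_on = molecule.landing_time
    t_off = t_on + molecule.total_bound_duration
    k0 = int(math.ceil(t_on / dt - 1e-12))
    k1 = min(int(math.ceil(t_off / dt - 1e-12)), config.n_frames)
    frames = np.arange(k0, k1, dtype=int)
    tau = frames * dt - t_on
    x, y = _true_positions(molecule, tau.astype(float))
    molecule.frames = frames
    molecule.true_x = x.copy()
    molecule.true_y = y.copy()
    if config.drift is not None and len(frames):
        d = np.asarray(config.drift, dtype=float)
        x = x + d[frames, 0]
        y = y + d[frames, 1]
    if config.localization_sd > 0 and len(frames):
        x = x + rng.normal(0.0, config.localization_sd, size=len(frames))
        y = y + rng.normal(0.0, config.localization_sd, size=len(frames))
    return Trajectory(
        molecule_id=molecule.molecule_id,
        frames=frames,
        t=frames * dt,
        x=x,
        y=y,
        intensity=np.full(len(frames), 1000.0),
    )


def simulate_experiment(
    config: SimConfig,
) -> tuple[list[Trajectory], list[GroundTruthMolecule]]:
    """Simulate a full movie's worth of molecules.

    Landing times are uniform on ``[0, landing_window]``; trajectories are
    truncated at ``n_frames``.  Molecules whose bound interval covers no
    frame yield no trajectory but their ground truth is still returned.
    Fully reproducible from ``rng_seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    trajectories: list[Trajectory] = []
    truths: list[GroundTruthMolecule] = []
    lo = 0.1 * config.field_size_nm
    hi = 0.9 * config.field_size_nm
    for i in range(config.n_molecules):
        landing = float(rng.uniform(0.0, config.landing_window))
        origin = (float(rng.uniform(lo, hi)), float(rng.uniform(lo, hi)))
        mol = sample_state_path(config, rng, molecule_id=i, landing_time=landing, origin=origin)
        traj = render_positions(mol, config, rng)
        truths.append(mol)
        if len(traj):
            trajectories.append(traj)
    return trajectories, truths


@dataclass
class MovieSpec:
    """Parameters for rendering synthetic image stacks.

    ``field_size`` is the image side in pixels; positions are nm with the
    origin at the image corner.  Fiducial beads are present in every frame.
    """

    field_size: int = 64
    pixel_size: float = 66.0
    psf_sigma: float = 130.0
    emitter_photons: float = 16000.0  # calibrated for ~1.5 nm localization SD
    background: float = 20.0
    bead_positions: list[tuple[float, float]] = field(default_factory=list)
    bead_photons: float = 40000.0
    n_frames: int | None = None
    poisson_noise: bool = True

    def validate(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")


def _add_gaussian_spot(img: np.ndarray, x_px: float, y_px: float, sigma_px: float, photons: float) -> None:
    half = int(math.ceil(4.0 * sigma_px))
    cx, cy = int(round(x_px)), int(round(y_px))
    x0, x1 = max(cx - half, 0), min(cx + half + 1, img.shape[1])
    y0, y1 = max(cy - half, 0), min(cy + half + 1, img.shape[0])
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - x_px
    ys = np.arange(y0, y1) - y_px
    amp = photons / (2.0 * math.pi * sigma_px**2)
    img[y0:y1, x0:x1] += amp * np.exp(
        -(xs[None, :] ** 2 + ys[:, None] ** 2) / (2.0 * sigma_px**2)
    )


def render_movie(
    trajectories: Sequence[Trajectory],
    movie_spec: MovieSpec,
    rng: np.random.Generator,
    drift: np.ndarray | None = None,
    path: str | Path | None = None,
) -> np.ndarray:
    """Render trajectories and fiducial beads into a 16-bit image stack.

    Each frame is background + a symmetric 2D Gaussian per visible object,
    with Poisson counting noise.  Input trajectories are taken as drift-free
    true positions; the shared ``drift`` sequence is applied to emitters and
    beads alike.  Emitters outside the field are omitted from that frame
    with a warning.  If ``path`` is given the stack is written as a
    multi-page TIFF (one page per frame).
    """
    movie_spec.validate()
    if movie_spec.n_frames is not None:
        n_frames = movie_spec.n_frames
    elif trajectories:
        n_frames = int(max(t.frames[-1] for t in trajectories if len(t)) + 1)
    else:
        n_frames = 1
    size = movie_spec.field_size
    px = movie_spec.pixel_size
    sigma_px = movie_spec.psf_sigma / px
    extent = size * px
    stack = np.empty((n_frames, size, size), dtype=np.uint16)

    per_frame: dict[int, list[tuple[float, float]]] = {}
    warned = False
    for traj in trajectories:
        for f, x, y in zip(traj.frames, traj.x, traj.y):
            if f < 0 or f >= n_frames:
                continue
            per_frame.setdefault(int(f), []).append((x, y))

    for f in range(n_frames):
        img = np.full((size, size), float(movie_spec.background))
        dx, dy = (0.0, 0.0)
        if drift is not None:
            dx, dy = float(drift[f, 0]), float(drift[f, 1])
        for bx, by in movie_spec.bead_positions:
            _add_gaussian_spot(img, (bx + dx) / px, (by + dy) / px, sigma_px, movie_spec.bead_photons)
        for x, y in per_frame.get(f, []):
            xs, ys = x + dx, y + dy
            if not (0.0 <= xs < extent and 0.0 <= ys < extent):
                if not warned:
                    warnings.warn("emitter outside field; omitted from frame", stacklevel=2)
                    warned = True
                continue
            _add_gaussian_spot(img, xs / px, ys / px, sigma_px, movie_spec.emitter_photons)
        if movie_spec.poisson_noise:
            img = rng.poisson(img).astype(float)
        stack[f] = np.clip(np.round(img), 0, np.iinfo(np.uint16).max).astype(np.uint16)

    if path is not None:
        import tifffile

        tifffile.imwrite(str(path), stack, photometric="minisblack")
    return stack


def random_walk_drift(
    n_frames: int, step_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Cumulative 2D Gaussian random-walk drift, zero at frame 0 (nm)."""
    steps = rng.normal(0.0, step_sd, size=(n_frames, 2))
    steps[0] = 0.0
    return np.cumsum(steps, axis=0)
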