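"""Motion-state segmentation of single-particle trajectories.

Each bound trajectory is decomposed into *static* segments (the particle
stays within ``static_radius`` — default 10 nm — of its anchor), *processive*
segments (sustained displacement of at least ``static_radius`` lasting at
least ``min_processive_duration``), and *jump* events (displacements above
``jump_threshold`` completed within ``jump_max_frames`` frames, interpreted
as brief unbinding, diffusion through solution and rebinding within
``jump_search_radius`` of the previous anchor).

Jumps are detected on raw positions (so boxcar smoothing cannot dilute a
two-frame displacement) and removed by re-anchoring, so jump displacement
never contributes to segment displacement or run length.  Classification
then runs on boxcar-smoothed positions with an anchor-based changepoint
scan: a static segment holds while the smoothed position stays within
``static_radius`` of its anchor; an excursion beyond the radius opens a
candidate processive segment at the excursion onset, which closes when a
trailing ``close_window`` shows net displacement below ``close_radius``
(a noise-scaled stasis test).  The candidate is kept only if it satisfies
the operational definition (net displacement >= ``static_radius`` over
>= ``min_processive_duration``); otherwise its time is absorbed into the
surrounding static period.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import Trajectory
from .sim import PROCESSIVE, STATIC, GroundTruthMolecule


@dataclass
class SegmentationParams:
    """Thresholds of the operational static/processive/jump definitions.

    All lengths nm, times s.  ``close_window``/``close_radius`` and
    ``excursion_floor`` are changepoint-scan tuning parameters (stasis test
    and onset backtracking); the rest are the analysis definitions and
    inclusion filters.
    """

    static_radius: float = 10.0
    min_processive_duration: float = 5.0
    min_static_segment: float = 5.0
    min_total_duration: float = 10.0
    jump_threshold: float = 10.0
    jump_max_frames: int = 2
    jump_search_radius: float = 100.0
    boxcar_window: int = 5
    landing_cutoff: float = 500.0
    max_total_duration: float = 510.0
    static_fit_min: float = 5.0
    static_fit_max: float = 310.0
    close_window: float = 10.0
    close_radius: float = 4.0
    excursion_floor: float = 3.0
    stall_speed_max: float = 0.6
    jump_flank_max: float = 7.0
    static_criterion: str = "max_deviation"  # or "sd"
    velocity_estimator: str = "net"  # or "slope"

    def validate(self) -> None:
        positive = (
            "static_radius min_processive_duration min_static_segment "
            "min_total_duration jump_threshold jump_search_radius landing_cutoff "
            "max_total_duration static_fit_min static_fit_max close_window "
            "close_radius excursion_floor stall_speed_max jump_flank_max"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.jump_max_frames < 1:
            raise ValueError("jump_max_frames must be >= 1")
        if self.boxcar_window < 1 or self.boxcar_window % 2 == 0:
            raise ValueError("boxcar_window must be a positive odd integer")
        if self.static_fit_min >= self.static_fit_max:
            raise ValueError("static_fit_min must be < static_fit_max")
        if self.static_criterion not in ("max_deviation", "sd"):
            raise ValueError("static_criterion must be 'max_deviation' or 'sd'")
        if self.velocity_estimator not in ("net", "slope"):
            raise ValueError("velocity_estimator must be 'net' or 'slope'")


@dataclass
class Segment:
    kind: str  # "static" | "processive"
    t_start: float
    t_end: float
    duration: float
    net_displacement: float
    velocity: float | None
    terminal_fate: str  # "switch" | "unbind" | "censored" | "jump"
    start_idx: int
    end_idx: int


@dataclass
class JumpEvent:
    frame: int  # absolute arrival frame
    distance: float
    at_landing: bool
    arrival_idx: int = 0  # index within the track


@dataclass
class SegmentedTrajectory:
    molecule_id: int
    segments: list[Segment]
    jumps: list[JumpEvent]
    molecule_class: str  # "static_only" | "processive"
    total_bound_duration: float
    landing_time: float

    @property
    def has_jumps(self) -> bool:
        return len(self.jumps) > 0

    @property
    def first_segment_kind(self) -> str:
        return self.segments[0].kind if self.segments else STATIC


@dataclass
class FilterReport:
    n_input: int = 0
    n_retained: int = 0
    n_dropped_short: int = 0
    n_dropped_long: int = 0
    n_dropped_late_landing: int = 0


def smooth_positions(values: np.ndarray, window: int) -> np.ndarray:
    """Centered boxcar average; edges use shrinking (one-sided) windows."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("expected a 1D coordinate array")
    if len(values) < 1:
        raise ValueError("trajectory must contain at least 1 frame")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(values)])
    n = len(values)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi + 1 - lo)


def detect_jumps(
    traj: Trajectory, params: SegmentationParams
) -> tuple[list[JumpEvent], np.ndarray, list[tuple[int, int]]]:
    """Detect jumps on raw positions and re-anchor the trajectory.

    Returns ``(jumps, adjusted_xy, blocks)``: the jump events, the (n, 2)
    position array with every jump displacement subtracted from subsequent
    frames (so jumps cannot contribute to run lengths), and the jump-free
    index blocks the trajectory splits into.

    A candidate jump is a displacement above ``jump_threshold`` spanning at
    most ``jump_max_frames`` frames, landing within ``jump_search_radius``
    of the pre-jump position.  The displacement is measured between
    two-point position means on either side of the span, which halves the
    localization-noise contribution so that noise spikes during genuine
    motion rarely reach the threshold.  A jump also connects two
    *anchored* positions (unbind, diffuse, rebind), so both flanks must be
    quasi-static: the displacement over ``2 * jump_max_frames`` frames
    before departure and after arrival must each stay below
    ``jump_flank_max``.  Without these guards the onset of a fast
    processive run (>5 nm/s covers >10 nm in two frames) would be flagged
    as a jump and mid-run noise would shred moderate-speed segments.
    """
    n = len(traj)
    r = np.column_stack([traj.x, traj.y]).astype(float)
    frames = traj.frames
    jumps: list[JumpEvent] = []
    boundaries: list[int] = []
    i = 0
    while i < n - 1:
        hit = False
        for k in range(1, params.jump_max_frames + 1):
            j = i + k
            if j > n - 1:
                break
            span = int(frames[j] - frames[i])
            if span > params.jump_max_frames:
                break
            pre_mean = r[max(0, i - 1): i + 1].mean(axis=0)
            post_mean = r[j: min(n, j + 2)].mean(axis=0)
            d = float(np.hypot(*(post_mean - pre_mean)))
            if d <= params.jump_threshold or d > params.jump_search_radius:
                continue
            if j >= n - 1:
                continue  # no frame after arrival: re-association unverifiable
            flank = 2 * params.jump_max_frames
            pre = max(0, i - flank)
            post = min(n - 1, j + flank)
            d_pre = float(np.hypot(*(r[i] - r[pre])))
            d_post = float(np.hypot(*(r[post] - r[j])))
            if d_pre >= params.jump_flank_max or d_post >= params.jump_flank_max:
                continue
            vec = post_mean - pre_mean
            r[j:] -= vec
            r[i + 1: j] = r[i]  # in-flight frames held at the pre-jump anchor
            jumps.append(
                JumpEvent(
                    frame=int(frames[j]),
                    distance=d,
                    at_landing=i < params.jump_max_frames,
                    arrival_idx=j,
                )
            )
            boundaries.append(j)
            i = j
            hit = True
            break
        if not hit:
            i += 1
    blocks: list[tuple[int, int]] = []
    start = 0
    for b in boundaries:
        blocks.append((start, b - 1))
        start = b
    blocks.append((start, n - 1))
    return jumps, r, blocks


def _scan_block(
    s: np.ndarray, t: np.ndarray, a0: int, b0: int, params: SegmentationParams, dt: float
) -> list[tuple[str, int, int]]:
    """Anchor-based changepoint scan on smoothed positions over [a0, b0]."""
    out: list[tuple[str, int, int]] = []
    W = max(1, int(round(params.close_window / dt)))
    i = a0
    if b0 <= a0:
        return [(STATIC, a0, b0)]
    while i < b0:
        anchor = s[i]
        if params.static_criterion == "sd":
            # SD mode: hold while running positional SD about the anchor stays
            # below static_radius (a looser reading of the static definition).
            j = i
            while j + 1 <= b0:
                seg = s[i: j + 2]
                sd = float(np.sqrt(np.mean(np.sum((seg - seg.mean(axis=0)) ** 2, axis=1))))
                if sd > params.static_radius:
                    break
                j += 1
        else:
            j = i
            while j + 1 <= b0 and np.hypot(*(s[j + 1] - anchor)) <= params.static_radius:
                j += 1
        if j >= b0:
            out.append((STATIC, i, b0))
            return out
        c = j + 1  # first index beyond the radius
        # excursion onset: last index still at the anchor (within the floor).
        # If nothing returns to the floor (e.g. a sub-threshold jump shifted
        # the apparent anchor), fall back to the closest approach so that a
        # later noise spike cannot manufacture a long phantom excursion.
        e = None
        for m in range(c, i - 1, -1):
            if np.hypot(*(s[m] - anchor)) <= params.excursion_floor:
                e = m
                break
        anchored = e is not None
        if e is None:
            d_anchor = np.hypot(s[i:c + 1, 0] - anchor[0], s[i:c + 1, 1] - anchor[1])
            e = i + int(np.argmin(d_anchor))
        # A coherent excursion crosses the radius within the time the
        # slowest detectable mover needs; a crossing that takes longer is a
        # noise spike on a shifted apparent anchor (e.g. after a
        # sub-threshold jump), not motion.
        onset_cap = (
            params.static_radius / params.stall_speed_max / dt + params.boxcar_window
        )
        if c - e > onset_cap:
            q = max(e, i + 1)
            if q >= b0:
                out.append((STATIC, i, b0))
                return out
            out.append((STATIC, i, q))
            i = q
            continue
        # close when a trailing window shows stasis
        end = None
        t2 = max(c, e + W)
        while t2 <= b0:
            if np.hypot(*(s[t2] - s[t2 - W])) < params.close_radius:
                end = t2 - W
                break
            t2 += 1
        if end is None:
            # track ends mid-run: a short stall just before unbinding cannot
            # fill the stasis window, so certify it from the end-of-track
            # tail instead (all tail points near the final position, and the
            # fitted tail speed indistinguishable from zero — slow genuine
            # motion must not masquerade as a stall).
            W5 = max(1, int(round(params.min_static_segment / dt)))
            q = b0
            while q - 1 > e and np.hypot(*(s[q - 1] - s[b0])) < params.close_radius:
                q -= 1
            if b0 - q >= W5:
                tt = t[q: b0 + 1] - t[q]
                vx = np.polyfit(tt, s[q: b0 + 1, 0], 1)[0]
                vy = np.polyfit(tt, s[q: b0 + 1, 1], 1)[0]
                if math.hypot(vx, vy) < params.stall_speed_max:
                    end = q
        if end is None:
            end = b0
        end = max(end, c)
        duration = t[end] - t[e]
        # Validate against the anchor when the onset genuinely returned to
        # it; otherwise against displacement accrued from the onset, so an
        # anchor offset inherited from a sub-threshold jump cannot count
        # as motion.
        if anchored:
            run = float(np.hypot(*(s[end] - anchor)))
        else:
            run = float(np.hypot(*(s[end] - s[e])))
        if duration >= params.min_processive_duration and run >= params.static_radius:
            if e > i:
                out.append((STATIC, i, e))
            out.append((PROCESSIVE, e, end))
            i = end
            if end >= b0:
                return out
        else:
            q = max(e, i + 1)
            if q >= b0:
                out.append((STATIC, i, b0))
                return out
            out.append((STATIC, i, q))
            i = q
    if not out or out[-1][2] < b0:
        out.append((STATIC, out[-1][2] if out else a0, b0))
    return out


def _merge_segments(
    raw: list[tuple[str, int, int]], t: np.ndarray, params: SegmentationParams
) -> list[tuple[str, int, int]]:
    """Merge interior static slivers and fuse same-kind neighbours.

    A static interval shorter than ``min_static_segment`` *between two
    processive segments* is below the stall resolution and is absorbed
    into a single processive run.  Boundary slivers (at landing or just
    before unbinding) are kept as static: merging them would silently
    reassign the neighbouring processive segment's exit route.
    """
    segs = list(raw)
    # a sub-threshold leading static is onset-detection fuzz, not a dwell
    if (len(segs) > 1 and segs[0][0] == STATIC and segs[1][0] == PROCESSIVE
            and t[segs[0][2]] - t[segs[0][1]] < params.min_static_segment):
        segs[0:2] = [(PROCESSIVE, segs[0][1], segs[1][2])]
    changed = True
    while changed and len(segs) > 2:
        changed = False
        for k in range(1, len(segs) - 1):
            kind, a, b = segs[k]
            if kind != STATIC or t[b] - t[a] >= params.min_static_segment:
                continue
            if segs[k - 1][0] == PROCESSIVE and segs[k + 1][0] == PROCESSIVE:
                segs[k - 1: k + 2] = [(PROCESSIVE, segs[k - 1][1], segs[k + 1][2])]
                changed = True
                break
    # fuse runs of adjacent segments of the same kind
    fused: list[tuple[str, int, int]] = []
    for seg in segs:
        if fused and fused[-1][0] == seg[0]:
            fused[-1] = (seg[0], fused[-1][1], seg[2])
        else:
            fused.append(seg)
    return fused


def _slope_velocity(s: np.ndarray, t: np.ndarray, a: int, b: int) -> float:
    disp = s[a: b + 1] - s[a]
    direction = s[b] - s[a]
    norm = np.hypot(*direction)
    if norm == 0:
        return 0.0
    proj = disp @ (direction / norm)
    return float(np.polyfit(t[a: b + 1] - t[a], proj, 1)[0])


def segment_trajectory(
    traj: Trajectory,
    params: SegmentationParams | None = None,
    movie_length: float | None = None,
) -> SegmentedTrajectory:
    """Classify one trajectory into static/processive segments and jumps.

    Jumps are removed first (each jump also terminates the current
    segment); the changepoint scan then runs per jump-free block on
    boxcar-smoothed positions.  The final segment's fate is ``unbind``, or
    ``censored`` if the track is still present at ``movie_length``.
    """
    params = params or SegmentationParams()
    params.validate()
    n = len(traj)
    if n == 0:
        raise ValueError("cannot segment an empty trajectory")
    dt = float(np.median(np.diff(traj.t) / np.diff(traj.frames))) if n > 1 else 1.0
    jumps, r_adj, blocks = detect_jumps(traj, params)
    sx = smooth_positions(r_adj[:, 0], params.boxcar_window if n >= 1 else 1)
    sy = smooth_positions(r_adj[:, 1], params.boxcar_window)
    s = np.column_stack([sx, sy])
    t = traj.t

    idx_segments: list[tuple[str, int, int, bool]] = []  # (kind, a, b, ends_in_jump)
    for bi, (a0, b0) in enumerate(blocks):
        block_segs = _merge_segments(_scan_block(s, t, a0, b0, params, dt), t, params)
        last_in_block = len(block_segs) - 1
        for k, (kind, a, b) in enumerate(block_segs):
            idx_segments.append((kind, a, b, k == last_in_block and bi < len(blocks) - 1))

    censored = movie_length is not None and traj.t[-1] + 1.5 * dt >= movie_length
    segments: list[Segment] = []
    for k, (kind, a, b, ends_in_jump) in enumerate(idx_segments):
        duration = float(t[b] - t[a])
        if ends_in_jump:
            fate = "jump"
        elif k == len(idx_segments) - 1:
            fate = "censored" if censored else "unbind"
        else:
            fate = "switch"
        if kind == PROCESSIVE:
            # run length between anchor-refined endpoints: use the adjacent
            # static segment's mean position when available (unbiased by
            # onset/stop detection margins), else the raw boundary position.
            if k > 0 and idx_segments[k - 1][0] == STATIC and not idx_segments[k - 1][3]:
                pa, pb = idx_segments[k - 1][1], idx_segments[k - 1][2]
                start_ref = s[pa: pb + 1].mean(axis=0)
            else:
                start_ref = r_adj[a]
            if (k < len(idx_segments) - 1 and idx_segments[k + 1][0] == STATIC
                    and not ends_in_jump):
                na, nb = idx_segments[k + 1][1], idx_segments[k + 1][2]
                end_ref = s[na: nb + 1].mean(axis=0)
            else:
                end_ref = r_adj[b]
            run = float(np.hypot(*(np.asarray(end_ref) - np.asarray(start_ref))))
            if duration <= 0:
                raise ValueError("processive segment with zero duration")
            if params.velocity_estimator == "slope":
                velocity = _slope_velocity(s, t, a, b)
            else:
                velocity = float(np.hypot(*(r_adj[b] - r_adj[a]))) / duration
        else:
            run = float(np.hypot(*(s[b] - s[a])))
            velocity = None
        segments.append(
            Segment(
                kind=kind,
                t_start=float(t[a]),
                t_end=float(t[b]),
                duration=duration,
                net_displacement=run,
                velocity=velocity,
                terminal_fate=fate,
                start_idx=a,
                end_idx=b,
            )
        )

    mol_class = PROCESSIVE if any(sg.kind == PROCESSIVE for sg in segments) else "static_only"
    return SegmentedTrajectory(
        molecule_id=traj.molecule_id,
        segments=segments,
        jumps=jumps,
        molecule_class=mol_class,
        total_bound_duration=traj.bound_duration,
        landing_time=traj.landing_time,
    )


def segment_stats(seg: Segment) -> tuple[float | None, float, float]:
    """(velocity, run_length, duration) of a segment.

    Velocity is defined for processive segments only; zero-duration
    segments are an error.
    """
    if seg.duration <= 0:
        raise ValueError("segment has zero duration")
    if seg.kind == PROCESSIVE:
        velocity = seg.velocity if seg.velocity is not None else seg.net_displacement / seg.duration
    else:
        velocity = None
    return velocity, seg.net_displacement, seg.duration


def apply_filters(
    segmented: Sequence[SegmentedTrajectory], params: SegmentationParams | None = None
) -> tuple[list[SegmentedTrajectory], FilterReport]:
    """Apply the cohort inclusion filters.

    Drops molecules bound for less than ``min_total_duration``, bound for
    more than ``max_total_duration`` (potential irreversibly stuck
    outliers), or landing after ``landing_cutoff`` (to avoid premature
    truncation by the movie end).  Rule precedence for the report:
    short, long, late landing.
    """
    params = params or SegmentationParams()
    report = FilterReport(n_input=len(segmented))
    retained: list[SegmentedTrajectory] = []
    for st in segmented:
        if st.total_bound_duration < params.min_total_duration:
            report.n_dropped_short += 1
        elif st.total_bound_duration > params.max_total_duration:
            report.n_dropped_long += 1
        elif st.landing_time > params.landing_cutoff:
            report.n_dropped_late_landing += 1
        else:
            retained.append(st)
    report.n_retained = len(retained)
    return retained, report


@dataclass
class ExpectedSegment:
    kind: str
    duration: float
    run_length: float
    mean_speed: float


@dataclass
class ExpectedMolecule:
    """Detector-level expectation derived from a ground-truth state path.

    Applies the operational definitions (and the detector's resolution
    limits) to the true path: static interludes shorter than
    ``close_window`` are below the stasis-test resolution and merge into
    the surrounding run; processive visits qualify only with duration >=
    ``min_processive_duration`` and displacement >= ``static_radius``;
    leading/trailing static dwells below ``min_static_segment`` are
    absorbed.  This is the apples-to-apples reference for detector
    accuracy: molecules whose true motion falls below these operational
    thresholds are *expected* to read as static.
    """

    molecule_id: int
    segments: list[ExpectedSegment]
    molecule_class: str


def expected_from_truth(
    gt: GroundTruthMolecule,
    params: SegmentationParams | None = None,
    frame_interval: float = 1.0,
) -> ExpectedMolecule:
    params = params or SegmentationParams()
    items = [[v.state, v.dwell, v.speed * v.dwell if v.state == PROCESSIVE else 0.0, v.speed]
             for v in gt.visits]
    # merge static interludes below the stasis-test resolution
    merged = True
    while merged:
        merged = False
        for k in range(1, len(items) - 1):
            if (items[k][0] == STATIC and items[k][1] < params.close_window
                    and items[k - 1][0] == PROCESSIVE and items[k + 1][0] == PROCESSIVE):
                dur = items[k - 1][1] + items[k][1] + items[k + 1][1]
                run = items[k - 1][2] + items[k + 1][2]
                motion_dur = items[k - 1][1] + items[k + 1][1]
                speed = run / motion_dur if motion_dur > 0 else 0.0
                items[k - 1: k + 2] = [[PROCESSIVE, dur, run, speed]]
                merged = True
                break
    # boundary statics below min_static_segment cannot be certified as
    # dwells by the detector (onset fuzz at landing, too-short tail before
    # unbinding) and are absorbed into the adjacent processive run
    if (len(items) > 1 and items[0][0] == STATIC and items[1][0] == PROCESSIVE
            and items[0][1] < params.min_static_segment):
        items[1][1] += items[0][1]
        items = items[1:]
    if (len(items) > 1 and items[-1][0] == STATIC and items[-2][0] == PROCESSIVE
            and items[-1][1] < params.min_static_segment):
        items[-2][1] += items[-1][1]
        items = items[:-1]
    # demote sub-threshold processive visits to static time
    out: list[list] = []
    for st, dur, run, speed in items:
        detectable = (
            st == PROCESSIVE
            and dur >= params.min_processive_duration
            and run >= params.static_radius
            and speed >= params.stall_speed_max
        )
        if st == PROCESSIVE and not detectable:
            st, run, speed = STATIC, 0.0, 0.0
        if out and out[-1][0] == st == STATIC:
            out[-1][1] += dur
        else:
            out.append([st, dur, run, speed])
    segments = [ExpectedSegment(kind=a, duration=b, run_length=c, mean_speed=d)
                for a, b, c, d in out]
    mol_class = (
        PROCESSIVE if any(sg.kind == PROCESSIVE for sg in segments) else "static_only"
    )
    return ExpectedMolecule(molecule_id=gt.molecule_id, segments=segments, molecule_class=mol_class)


def expected_segmented(
    gt: GroundTruthMolecule,
    params: SegmentationParams | None = None,
    movie_length: float | None = None,
    frame_interval: float = 1.0,
) -> SegmentedTrajectory | None:
    """Ideal-detector segmentation of a ground-truth path.

    Converts :func:`expected_from_truth` output into a
    :class:`SegmentedTrajectory` with absolute times, movie-end censoring
    and terminal fates, so the downstream branching/fitting machinery can
    run on an oracle cohort exactly as on a detected one.  Returns ``None``
    for molecules bound for less than one frame.  Jumps are ignored (an
    ideal detector removes them exactly).
    """
    params = params or SegmentationParams()
    em = expected_from_truth(gt, params, frame_interval)
    t0 = gt.landing_time
    t_off = t0 + gt.total_bound_duration
    censored = movie_length is not None and t_off >= movie_length
    t_end_cap = min(t_off, movie_length) if movie_length is not None else t_off
    if t_end_cap - t0 < frame_interval:
        return None
    segments: list[Segment] = []
    t_cursor = t0
    for k, sg in enumerate(em.segments):
        seg_end = t_cursor + sg.duration
        truncated = seg_end >= t_end_cap
        seg_end = min(seg_end, t_end_cap)
        if seg_end <= t_cursor:
            break
        if truncated:
            fate = "censored" if censored else "unbind"
        elif k == len(em.segments) - 1:
            fate = "censored" if censored else "unbind"
        else:
            fate = "switch"
        duration = seg_end - t_cursor
        if sg.kind == PROCESSIVE:
            frac = duration / sg.duration if sg.duration > 0 else 1.0
            run = sg.run_length * frac
            velocity = sg.mean_speed
        else:
            run = 0.0
            velocity = None
        segments.append(
            Segment(
                kind=sg.kind,
                t_start=t_cursor,
                t_end=seg_end,
                duration=duration,
                net_displacement=run,
                velocity=velocity,
                terminal_fate=fate,
                start_idx=0,
                end_idx=0,
            )
        )
        t_cursor = seg_end
        if truncated:
            break
    if not segments:
        return None
    mol_class = (
        PROCESSIVE if any(sg.kind == PROCESSIVE for sg in segments) else "static_only"
    )
    return SegmentedTrajectory(
        molecule_id=gt.molecule_id,
        segments=segments,
        jumps=[],
        molecule_class=mol_class,
        total_bound_duration=t_end_cap - t0,
        landing_time=t0,
    )


def segments_to_dataframe(segmented: Sequence[SegmentedTrajectory]):
    import pandas as pd

    rows = []
    for st in segmented:
        for sg in st.segments:
            rows.append(
                {
                    "molecule_id": st.molecule_id,
                    "kind": sg.kind,
                    "t_start": sg.t_start,
                    "t_end": sg.t_end,
                    "duration_s": sg.duration,
                    "net_displacement_nm": sg.net_displacement,
                    "velocity_nm_s": sg.velocity if sg.velocity is not None else np.nan,
                    "terminal_fate": sg.terminal_fate,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "molecule_id", "kind", "t_start", "t_end", "duration_s",
            "net_displacement_nm", "velocity_nm_s", "terminal_fate",
        ],
    )


def jumps_to_dataframe(segmented: Sequence[SegmentedTrajectory]):
    import pandas as pd

    rows = []
    for st in segmented:
        for jp in st.jumps:
            rows.append(
                {
                    "molecule_id": st.molecule_id,
                    "frame": jp.frame,
                    "distance_nm": jp.distance,
                    "at_landing": jp.at_landing,
                }
            )
    return pd.DataFrame(rows, columns=["molecule_id", "frame", "distance_nm", "at_landing"])


def molecules_to_dataframe(segmented: Sequence[SegmentedTrajectory]):
    import pandas as pd

    rows = [
        {
            "molecule_id": st.molecule_id,
            "molecule_class": st.molecule_class,
            "landing_time_s": st.landing_time,
            "total_bound_duration_s": st.total_bound_duration,
            "n_segments": len(st.segments),
            "n_jumps": len(st.jumps),
            "first_segment_kind": st.first_segment_kind,
        }
        for st in segmented
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "molecule_id", "molecule_class", "landing_time_s",
            "total_bound_duration_s", "n_segments", "n_jumps", "first_segment_kind",
        ],
    )
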