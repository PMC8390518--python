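"""Sub-pixel spot localization, track linking and fiducial drift correction.

Spots are localized by nonlinear least-squares fits of a symmetric 2D
Gaussian plus constant offset to the point-spread function, linked
frame-to-frame by greedy nearest-neighbour assignment, and corrected for
stage drift by subtracting the mean displacement of fiducial beads.
Coordinates are continuous, origin at the image corner, x right / y down,
frames 0-based; sub-pixel centers are converted to nm via the pixel size.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize
from skimage.feature import peak_local_max

from .io import Trajectory

DEFAULT_PIXEL_SIZE = 66.0  # nm/pixel


class SpotFitError(RuntimeError):
    """A spot fit was rejected; the message states the reason."""


class DriftError(RuntimeError):
    """Drift correction requires at least one fiducial track."""


@dataclass
class SpotFit:
    frame: int
    x: float  # nm
    y: float  # nm
    sigma: float  # nm
    amplitude: float  # counts above offset
    offset: float  # counts
    fit_rss: float  # counts^2


@dataclass
class LinkedTrack:
    track_id: int
    spots: list[SpotFit] = field(default_factory=list)
    is_fiducial: bool = False

    @property
    def frames(self) -> np.ndarray:
        return np.array([s.frame for s in self.spots], dtype=int)

    @property
    def xy(self) -> np.ndarray:
        return np.array([[s.x, s.y] for s in self.spots], dtype=float)

    def to_trajectory(self, frame_interval: float = 1.0) -> Trajectory:
        f = self.frames
        xy = self.xy
        return Trajectory(
            molecule_id=self.track_id,
            frames=f,
            t=f * frame_interval,
            x=xy[:, 0],
            y=xy[:, 1],
            intensity=np.array([s.amplitude for s in self.spots]),
        )


def detect_spots(
    image: np.ndarray, intensity_threshold: float, min_separation: int = 3
) -> np.ndarray:
    """Candidate spot centers: local maxima above threshold, NMS-suppressed.

    Returns an (n, 2) array of (x, y) pixel coordinates (may be empty).
    """
    image = np.asarray(image, dtype=float)
    peaks = peak_local_max(
        image,
        min_distance=int(min_separation),
        threshold_abs=float(intensity_threshold),
        exclude_border=False,
    )
    if peaks.size == 0:
        return np.empty((0, 2))
    return peaks[:, ::-1].astype(float)  # (row, col) -> (x, y)


def _gaussian_model(params, xg, yg):
    amp, x0, y0, sigma, offset = params
    return offset + amp * np.exp(-((xg - x0) ** 2 + (yg - y0) ** 2) / (2.0 * sigma**2))


def fit_spot(
    image: np.ndarray,
    center_guess: Sequence[float],
    window: int = 7,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    frame: int = 0,
) -> SpotFit:
    """Least-squares fit of a symmetric 2D Gaussian + offset around a guess.

    ``center_guess`` is (x, y) in pixels; ``window`` is the half-width of
    the fit region, which must lie fully inside the image.  Raises
    :class:`SpotFitError` on non-convergence or non-positive amplitude.
    """
    image = np.asarray(image, dtype=float)
    cx, cy = int(round(center_guess[0])), int(round(center_guess[1]))
    if (cx - window < 0 or cy - window < 0
            or cx + window >= image.shape[1] or cy + window >= image.shape[0]):
        raise ValueError("fit window extends outside the image")
    sub = image[cy - window: cy + window + 1, cx - window: cx + window + 1]
    ys, xs = np.mgrid[cy - window: cy + window + 1, cx - window: cx + window + 1]
    offset0 = float(np.median(sub))
    amp0 = max(float(sub.max() - offset0), 1e-3)
    p0 = np.array([amp0, float(center_guess[0]), float(center_guess[1]), 1.5, offset0])

    def resid(p):
        return (_gaussian_model(p, xs, ys) - sub).ravel()

    res = optimize.least_squares(
        resid,
        p0,
        bounds=(
            [0.0, cx - window, cy - window, 0.3, -np.inf],
            [np.inf, cx + window, cy + window, float(2 * window), np.inf],
        ),
        method="trf",
        max_nfev=200,
    )
    if not res.success:
        raise SpotFitError("fit did not converge")
    amp, x0, y0, sigma, offset = res.x
    if amp <= 0:
        raise SpotFitError("non-positive amplitude")
    return SpotFit(
        frame=frame,
        x=float(x0 * pixel_size),
        y=float(y0 * pixel_size),
        sigma=float(sigma * pixel_size),
        amplitude=float(amp),
        offset=float(offset),
        fit_rss=float(np.sum(res.fun**2)),
    )


def localize_stack(
    stack: np.ndarray,
    intensity_threshold: float,
    min_separation: int = 3,
    window: int = 7,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
) -> tuple[list[list[SpotFit]], dict]:
    """Detect and fit spots in every frame of an image stack.

    Returns per-frame lists of accepted :class:`SpotFit` and a diagnostics
    dict with counts of detected/accepted/rejected spots.
    """
    per_frame: list[list[SpotFit]] = []
    n_detected = n_rejected = 0
    reasons: dict[str, int] = {}
    for f, img in enumerate(stack):
        fits: list[SpotFit] = []
        for x, y in detect_spots(img, intensity_threshold, min_separation):
            n_detected += 1
            try:
                fits.append(fit_spot(img, (x, y), window=window, pixel_size=pixel_size, frame=f))
            except (SpotFitError, ValueError) as exc:
                n_rejected += 1
                reasons[str(exc)] = reasons.get(str(exc), 0) + 1
        per_frame.append(fits)
    return per_frame, {
        "n_detected": n_detected,
        "n_accepted": n_detected - n_rejected,
        "n_rejected": n_rejected,
        "rejection_reasons": reasons,
    }


def link_spots(
    spots_by_frame: Sequence[Sequence[SpotFit]],
    max_step: float = 300.0,
    max_gap: int = 1,
    fiducial_min_coverage: float = 0.99,
    fiducial_min_amplitude: float | None = None,
) -> list[LinkedTrack]:
    """Greedy nearest-neighbour linking of per-frame spot fits.

    Candidate (track, spot) pairs within ``max_step`` nm (tracks may skip up
    to ``max_gap`` frames) are assigned in order of increasing distance,
    ties broken deterministically by lowest spot index then track id.
    Unlinked spots start new tracks.  Tracks present in at least
    ``fiducial_min_coverage`` of all frames (and, if
    ``fiducial_min_amplitude`` is set, at least that bright — beads far
    outshine single emitters) are flagged as fiducials.
    """
    n_frames = len(spots_by_frame)
    tracks: list[LinkedTrack] = []
    active: list[int] = []  # indices into tracks
    for f in range(n_frames):
        spots = list(spots_by_frame[f])
        active = [
            i for i in active if f - tracks[i].spots[-1].frame <= max_gap + 1
        ]
        pairs = []
        for ti in active:
            last = tracks[ti].spots[-1]
            for si, s in enumerate(spots):
                d = math.hypot(s.x - last.x, s.y - last.y)
                if d <= max_step:
                    pairs.append((d, si, ti))
        pairs.sort()
        used_spots: set[int] = set()
        used_tracks: set[int] = set()
        for d, si, ti in pairs:
            if si in used_spots or ti in used_tracks:
                continue
            tracks[ti].spots.append(spots[si])
            used_spots.add(si)
            used_tracks.add(ti)
        for si, s in enumerate(spots):
            if si not in used_spots:
                tracks.append(LinkedTrack(track_id=len(tracks), spots=[s]))
                active.append(len(tracks) - 1)
    for tr in tracks:
        tr.is_fiducial = len(tr.spots) >= fiducial_min_coverage * n_frames
        if tr.is_fiducial and fiducial_min_amplitude is not None:
            mean_amp = float(np.mean([s.amplitude for s in tr.spots]))
            tr.is_fiducial = mean_amp >= fiducial_min_amplitude
    return tracks


def estimate_drift(
    fiducial_tracks: Sequence[LinkedTrack], n_frames: int
) -> np.ndarray:
    """Per-frame drift (nm): mean fiducial displacement from frame 0.

    Gaps in a fiducial track are linearly interpolated.  Raises
    :class:`DriftError` if no fiducial is given.
    """
    if not fiducial_tracks:
        raise DriftError("drift correction requires at least one fiducial track")
    frames = np.arange(n_frames)
    disp = np.zeros((len(fiducial_tracks), n_frames, 2))
    for i, tr in enumerate(fiducial_tracks):
        f = tr.frames
        xy = tr.xy
        for c in range(2):
            disp[i, :, c] = np.interp(frames, f, xy[:, c] - xy[0, c])
    return disp.mean(axis=0)


def correct_drift(
    tracks: Sequence[LinkedTrack],
    fiducial_tracks: Sequence[LinkedTrack],
    n_frames: int,
) -> tuple[list[LinkedTrack], np.ndarray]:
    """Subtract fiducial-estimated drift from every track.

    Returns new tracks (fiducial residuals become ~0) and the drift array.
    """
    drift = estimate_drift(fiducial_tracks, n_frames)
    out: list[LinkedTrack] = []
    for tr in tracks:
        spots = [
            SpotFit(
                frame=s.frame,
                x=s.x - drift[s.frame, 0],
                y=s.y - drift[s.frame, 1],
                sigma=s.sigma,
                amplitude=s.amplitude,
                offset=s.offset,
                fit_rss=s.fit_rss,
            )
            for s in tr.spots
        ]
        out.append(LinkedTrack(track_id=tr.track_id, spots=spots, is_fiducial=tr.is_fiducial))
    return out, drift


def localization_precision_bound(
    psf_sigma: float, pixel_size: float, photons: float, background: float
) -> float:
    """Thompson-style localization precision (nm) for a 2D Gaussian PSF.

    sigma_loc^2 = (s^2 + a^2/12)/N + 8 pi s^4 b^2 / (a^2 N^2), with s the
    PSF sigma, a the pixel size, N the collected photons and b the
    background noise per pixel (counts).
    """
    s2 = psf_sigma**2 + pixel_size**2 / 12.0
    var = s2 / photons + 8.0 * math.pi * psf_sigma**4 * background**2 / (
        pixel_size**2 * photons**2
    )
    return math.sqrt(var)
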