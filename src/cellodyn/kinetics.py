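"""Dwell-time fitting and three-state rate derivation.

Under first-order kinetics every bound-state dwell is exponential, and the
observed time constant of a state equals the inverse of its *total* exit
rate.  Route rate constants follow by multiplying the exit rate with the
observed branching fraction of that route (the probability that exit takes
that route equals its rate over the total).  Concretely, with tau_p the
processive-segment time constant and f_off the fraction of processive
segments ending in unbinding:

    k_exit_processive = 1 / tau_p
    k_off_processive  = f_off * k_exit_processive
    k_static          = (1 - f_off) * k_exit_processive

and analogously for the static state, whose time constant pools the
binding durations of entirely static molecules with the dwell times of
static segments inside processive molecules.

Dwell samples are windowed by the analysis filters (events shorter than a
minimum are unclassifiable; very long ones are excluded as outliers), so
the time constant is the MLE of an exponential restricted to the window —
the memoryless shift ``tau = mean(durations) - t_min`` when there is no
upper edge, with the windowed-likelihood correction when there is.  95%
confidence intervals come from a seeded percentile bootstrap over
molecules.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .segment import PROCESSIVE, STATIC, SegmentationParams, SegmentedTrajectory

DWELL_LABELS = (
    "static_molecule",
    "static_pre",
    "static_post",
    "static_all",
    "processive",
    "processive_molecule",
    "jump_molecule",
)


@dataclass
class DwellSample:
    durations: np.ndarray
    t_min: float
    t_max: float
    label: str

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)


@dataclass
class ExpFit:
    tau: float
    ci95: tuple[float, float]
    n: int
    boot_iterations: int
    t_min: float = 0.0
    t_max: float = math.inf
    label: str = ""


@dataclass
class BranchingCounts:
    """Exit-route and landing-state counts from a segmented cohort."""

    n_processive_to_unbind: int = 0
    n_processive_to_static: int = 0
    n_static_to_unbind: int = 0
    n_static_to_processive: int = 0
    n_static_only_molecules: int = 0
    n_static_segments_of_processive: int = 0
    n_molecules: int = 0
    n_processive_molecules: int = 0
    n_processive_start_static: int = 0

    @property
    def frac_processive_unbind(self) -> float:
        tot = self.n_processive_to_unbind + self.n_processive_to_static
        return self.n_processive_to_unbind / tot if tot else math.nan

    @property
    def frac_static_to_processive(self) -> float:
        """Pooled over static-only molecules and static segments of processive ones."""
        tot = (self.n_static_only_molecules + self.n_static_to_unbind
               + self.n_static_to_processive)
        return self.n_static_to_processive / tot if tot else math.nan

    @property
    def frac_static_segments_to_processive(self) -> float:
        tot = self.n_static_to_unbind + self.n_static_to_processive
        return self.n_static_to_processive / tot if tot else math.nan

    @property
    def p_land_processive_obs(self) -> float:
        if not self.n_molecules:
            return math.nan
        frac_proc = self.n_processive_molecules / self.n_molecules
        if not self.n_processive_molecules:
            return 0.0
        start_static = self.n_processive_start_static / self.n_processive_molecules
        return frac_proc * (1.0 - start_static)

    @property
    def p_land_static_obs(self) -> float:
        if not self.n_molecules:
            return math.nan
        return 1.0 - self.p_land_processive_obs


@dataclass
class ThreeStateRates:
    """The six-parameter bound-state kinetic model.

    Exit rates decompose exactly into their route constants:
    ``k_off_processive + k_static == k_exit_processive`` and
    ``k_off_static + k_processive == k_exit_static``;
    ``p_land_static + p_land_processive == 1``.
    """

    k_exit_processive: float
    k_exit_static: float
    k_off_processive: float
    k_static: float
    k_off_static: float
    k_processive: float
    p_land_static: float
    p_land_processive: float

    def validate(self) -> None:
        if not math.isclose(self.k_off_processive + self.k_static,
                            self.k_exit_processive, rel_tol=1e-9, abs_tol=1e-15):
            raise ValueError("processive exit rate does not decompose")
        if not math.isclose(self.k_off_static + self.k_processive,
                            self.k_exit_static, rel_tol=1e-9, abs_tol=1e-15):
            raise ValueError("static exit rate does not decompose")
        if not math.isclose(self.p_land_static + self.p_land_processive, 1.0,
                            rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError("landing probabilities do not sum to 1")


def _windowed_exponential_mle(mean_shifted: float, window: float) -> float:
    """MLE time constant of an exponential observed on a window [0, T].

    Solves ``mean = tau - T/(exp(T/tau) - 1)``; as T -> inf this reduces to
    the memoryless shift ``tau = mean``.  Requires ``mean < T/2`` (otherwise
    the windowed sample is flatter than any exponential and no finite MLE
    exists).
    """
    if not math.isfinite(window):
        return mean_shifted
    if mean_shifted >= window / 2.0:
        raise ValueError(
            "windowed sample mean exceeds T/2; no finite exponential MLE"
        )

    def g(tau: float) -> float:
        z = window / tau
        if z > 700:
            corr = 0.0
        else:
            corr = window / math.expm1(z)
        return tau - corr - mean_shifted

    from scipy import optimize

    lo, hi = 1e-9, mean_shifted
    while g(hi) < 0:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError("windowed exponential MLE did not bracket")
    return float(optimize.brentq(g, lo, hi, xtol=1e-10, rtol=1e-12))


def fit_exponential_mle(
    sample: DwellSample,
    boot_iterations: int = 1000,
    seed: int | np.random.Generator = 0,
) -> ExpFit:
    """Windowed-exponential MLE with percentile-bootstrap 95% CI.

    Durations outside ``[t_min, t_max]`` are discarded (the analysis
    window) and the time constant is the MLE of an exponential truncated
    to that window.  With no upper window this is the memoryless shift
    ``tau = mean(durations) - t_min``; a finite upper window adds the
    standard windowed-likelihood correction (without it, discarding the
    long tail would bias tau low).  The bootstrap resamples the windowed
    durations (one entry per molecule or segment) with replacement.
    """
    d = sample.durations
    kept = d[(d >= sample.t_min) & (d <= sample.t_max)]
    if len(kept) < 2:
        raise ValueError(
            f"dwell sample '{sample.label}': fewer than 2 durations inside the window"
        )
    window = sample.t_max - sample.t_min
    tau = _windowed_exponential_mle(float(kept.mean()) - sample.t_min, window)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, len(kept), size=(boot_iterations, len(kept)))
    boot_means = kept[idx].mean(axis=1) - sample.t_min
    boots = np.empty(boot_iterations)
    for b, m in enumerate(boot_means):
        try:
            boots[b] = _windowed_exponential_mle(float(m), window)
        except ValueError:
            boots[b] = math.inf
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return ExpFit(
        tau=tau,
        ci95=(float(lo), float(hi)),
        n=int(len(kept)),
        boot_iterations=boot_iterations,
        t_min=sample.t_min,
        t_max=sample.t_max,
        label=sample.label,
    )


def collect_dwell_samples(
    segmented: Sequence[SegmentedTrajectory],
    params: SegmentationParams | None = None,
) -> dict[str, DwellSample]:
    """Build the labelled dwell samples the three-state analysis fits.

    Molecule-level binding durations are windowed by the inclusion filters
    (``min_total_duration`` to ``max_total_duration``); static/processive
    segment dwells by the segment fit window.  Censored segments (track
    still present at the movie end) are excluded, as are segments
    terminated by a jump (the jump interrupts the dwell measurement
    without revealing the exit route).
    """
    params = params or SegmentationParams()
    static_mol, proc_mol, jump_mol = [], [], []
    static_pre, static_post, static_all, proc_seg = [], [], [], []
    for st in segmented:
        if st.segments and st.segments[-1].terminal_fate == "censored":
            mol_censored = True
        else:
            mol_censored = False
        if not mol_censored:
            if st.molecule_class == "static_only":
                static_mol.append(st.total_bound_duration)
            else:
                proc_mol.append(st.total_bound_duration)
            if st.has_jumps:
                jump_mol.append(st.total_bound_duration)
        if st.molecule_class != PROCESSIVE:
            continue
        segs = st.segments
        for k, sg in enumerate(segs):
            if sg.terminal_fate in ("censored", "jump"):
                continue
            if sg.kind == PROCESSIVE:
                proc_seg.append(sg.duration)
            else:
                static_all.append(sg.duration)
                if k + 1 < len(segs) and segs[k + 1].kind == PROCESSIVE:
                    static_pre.append(sg.duration)
                if k > 0 and segs[k - 1].kind == PROCESSIVE:
                    static_post.append(sg.duration)
    w_mol = (params.min_total_duration, params.max_total_duration)
    w_seg = (params.static_fit_min, params.static_fit_max)
    return {
        "static_molecule": DwellSample(np.array(static_mol), *w_mol, "static_molecule"),
        "processive_molecule": DwellSample(np.array(proc_mol), *w_mol, "processive_molecule"),
        "jump_molecule": DwellSample(np.array(jump_mol), *w_mol, "jump_molecule"),
        "static_pre": DwellSample(np.array(static_pre), *w_seg, "static_pre"),
        "static_post": DwellSample(np.array(static_post), *w_seg, "static_post"),
        "static_all": DwellSample(np.array(static_all), *w_seg, "static_all"),
        "processive": DwellSample(
            np.array(proc_seg), params.min_processive_duration, params.static_fit_max,
            "processive",
        ),
    }


def branching_fractions(segmented: Sequence[SegmentedTrajectory]) -> BranchingCounts:
    """Count exit routes and landing states in a segmented cohort.

    Censored and jump-terminated segments carry no route information and
    are excluded from the route counts.
    """
    counts = BranchingCounts()
    for st in segmented:
        counts.n_molecules += 1
        if st.molecule_class == "static_only":
            last = st.segments[-1] if st.segments else None
            if last is not None and last.terminal_fate == "unbind":
                counts.n_static_only_molecules += 1
            continue
        counts.n_processive_molecules += 1
        if st.first_segment_kind == STATIC:
            counts.n_processive_start_static += 1
        segs = st.segments
        for k, sg in enumerate(segs):
            if sg.terminal_fate in ("censored", "jump"):
                continue
            if sg.kind == PROCESSIVE:
                if sg.terminal_fate == "unbind":
                    counts.n_processive_to_unbind += 1
                else:
                    counts.n_processive_to_static += 1
            else:
                counts.n_static_segments_of_processive += 1
                if sg.terminal_fate == "unbind":
                    counts.n_static_to_unbind += 1
                else:
                    counts.n_static_to_processive += 1
    return counts


def overall_static_landing(
    frac_static_only: float, frac_processive: float, frac_processive_start_static: float
) -> float:
    """Overall probability that a binding event enters the static state.

    Entirely static molecules land static by definition; processive
    molecules land static when their first segment is static.
    """
    return frac_static_only + frac_processive * frac_processive_start_static


def derive_rates(
    fits: Mapping[str, ExpFit],
    counts: BranchingCounts,
    static_pooling: str = "weighted",
) -> ThreeStateRates:
    """Derive the three-state rate constants from fitted dwells and counts.

    ``static_pooling`` selects the static time constant: ``weighted``
    (count-weighted mean of the static-molecule tau and the
    static-segment tau), ``molecules_only`` or ``segments_only``.  Route
    rates are branching fraction x exit rate, so the decomposition
    identities hold exactly by construction.
    """
    for label in ("processive",):
        if label not in fits:
            raise KeyError(f"missing dwell fit: '{label}'")
    tau_p = fits["processive"].tau
    if static_pooling == "weighted":
        need = [lab for lab in ("static_molecule", "static_all") if lab not in fits]
        if need:
            raise KeyError(f"missing dwell fit: '{need[0]}'")
        f1, f2 = fits["static_molecule"], fits["static_all"]
        tau_s = (f1.n * f1.tau + f2.n * f2.tau) / (f1.n + f2.n)
    elif static_pooling == "molecules_only":
        if "static_molecule" not in fits:
            raise KeyError("missing dwell fit: 'static_molecule'")
        tau_s = fits["static_molecule"].tau
    elif static_pooling == "segments_only":
        if "static_all" not in fits:
            raise KeyError("missing dwell fit: 'static_all'")
        tau_s = fits["static_all"].tau
    else:
        raise ValueError("static_pooling must be weighted|molecules_only|segments_only")

    k_exit_p = 1.0 / tau_p
    k_exit_s = 1.0 / tau_s
    f_off_p = counts.frac_processive_unbind
    f_sp = counts.frac_static_to_processive
    rates = ThreeStateRates(
        k_exit_processive=k_exit_p,
        k_exit_static=k_exit_s,
        k_off_processive=f_off_p * k_exit_p,
        k_static=(1.0 - f_off_p) * k_exit_p,
        k_off_static=(1.0 - f_sp) * k_exit_s,
        k_processive=f_sp * k_exit_s,
        p_land_static=counts.p_land_static_obs,
        p_land_processive=counts.p_land_processive_obs,
    )
    rates.validate()
    return rates


@dataclass
class ModelPredictions:
    """Closed-form observables of the embedded discrete chain."""

    p_enter_processive: float
    expected_processive_visits: float
    expected_static_visits: float
    mean_static_dwell: float
    mean_processive_dwell: float
    expected_bound_time_static: float
    expected_bound_time_processive: float
    expected_total_bound_time: float


def predict_observables(rates: ThreeStateRates) -> ModelPredictions:
    """Analytic predictions for the three-state chain.

    With q_sp = k_processive/k_exit_static the per-static-visit probability
    of switching to the processive state and q_ps = k_static/k_exit_processive
    the reverse, the chance a binding event ever moves processively is
    p_land_processive + p_land_static * q_sp, visit counts follow the
    geometric series of round trips, and expected bound times are visit
    counts times mean dwells.
    """
    if rates.k_exit_static <= 0 or rates.k_exit_processive <= 0:
        raise ValueError("exit rates must be positive")
    q_sp = rates.k_processive / rates.k_exit_static
    q_ps = rates.k_static / rates.k_exit_processive
    p_enter = rates.p_land_processive + rates.p_land_static * q_sp
    denom = 1.0 - q_sp * q_ps
    e_proc = p_enter / denom
    e_static = (rates.p_land_static + rates.p_land_processive * q_ps) / denom
    mean_s = 1.0 / rates.k_exit_static
    mean_p = 1.0 / rates.k_exit_processive
    return ModelPredictions(
        p_enter_processive=p_enter,
        expected_processive_visits=e_proc,
        expected_static_visits=e_static,
        mean_static_dwell=mean_s,
        mean_processive_dwell=mean_p,
        expected_bound_time_static=e_static * mean_s,
        expected_bound_time_processive=e_proc * mean_p,
        expected_total_bound_time=e_static * mean_s + e_proc * mean_p,
    )


def diffusion_length(diffusion_coefficient: float, time: float) -> float:
    """RMS 2D diffusion distance sqrt(<x^2>) with <x^2> = 4 D t."""
    return math.sqrt(4.0 * diffusion_coefficient * time)


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return math.nan, math.nan
    if arr.size == 1:
        return float(arr[0]), 0.0
    return float(arr.mean()), float(arr.std(ddof=1))


def build_report(
    segmented: Sequence[SegmentedTrajectory],
    fits: Mapping[str, ExpFit],
    counts: BranchingCounts,
    rates: ThreeStateRates,
) -> dict:
    """Assemble the cohort summary table (counts, percentages, dwell fits).

    Returns a plain dict (machine-readable; every value computed from the
    inputs).  Use :func:`report_to_markdown` for the human-readable view.
    """
    vel, run, dur = [], [], []
    dur_unbind, dur_static_end = [], []
    static_seg_unbind, static_seg_proc = [], []
    jump_distances = []
    n_jump_mol = 0
    n_immediate_proc_unbind = 0
    for st in segmented:
        if st.has_jumps:
            n_jump_mol += 1
        jump_distances.extend(j.distance for j in st.jumps)
        if (len(st.segments) == 1 and st.segments[0].kind == PROCESSIVE
                and st.segments[0].terminal_fate == "unbind"):
            n_immediate_proc_unbind += 1
        for k, sg in enumerate(st.segments):
            if sg.kind != PROCESSIVE:
                if sg.terminal_fate == "unbind":
                    static_seg_unbind.append(sg.duration)
                elif sg.terminal_fate == "switch":
                    static_seg_proc.append(sg.duration)
                continue
            vel.append(sg.velocity)
            run.append(sg.net_displacement)
            dur.append(sg.duration)
            if sg.terminal_fate == "unbind":
                dur_unbind.append(sg.duration)
            elif sg.terminal_fate == "switch":
                dur_static_end.append(sg.duration)

    n_mol = counts.n_molecules
    n_proc = counts.n_processive_molecules
    n_static_only = n_mol - n_proc

    def fit_entry(label):
        f = fits.get(label)
        if f is None:
            return None
        return {"tau_s": f.tau, "ci95_lo": f.ci95[0], "ci95_hi": f.ci95[1], "n": f.n}

    def ms(vals):
        m, s = _mean_sd(vals)
        return {"mean": m, "sd": s, "n": len(vals)}

    report = {
        "all_molecules": {
            "total_molecules": n_mol,
            "percent_entirely_static": 100.0 * n_static_only / n_mol if n_mol else math.nan,
            "binding_duration_static": fit_entry("static_molecule"),
            "percent_with_processive_segments": 100.0 * n_proc / n_mol if n_mol else math.nan,
            "binding_duration_processive": fit_entry("processive_molecule"),
            "percent_immediately_processive_and_unbind": (
                100.0 * n_immediate_proc_unbind / n_mol if n_mol else math.nan
            ),
        },
        "processive_molecules": {
            "percent_bound_into_processive_state": (
                100.0 * (1.0 - counts.n_processive_start_static / n_proc) if n_proc else math.nan
            ),
            "percent_bound_into_static_state": (
                100.0 * counts.n_processive_start_static / n_proc if n_proc else math.nan
            ),
            "n_processive_segments": len(dur),
            "duration_of_processive_segments": ms(dur),
            "velocity_nm_s": ms(vel),
            "run_length_nm": ms(run),
            "percent_processive_end_unbind": 100.0 * counts.frac_processive_unbind,
            "duration_processive_end_unbind": ms(dur_unbind),
            "percent_processive_end_static": 100.0 * (1 - counts.frac_processive_unbind),
            "duration_processive_end_static": ms(dur_static_end),
        },
        "static_segments_of_processive_molecules": {
            "n_static_segments": counts.n_static_segments_of_processive,
            "dwell_time": fit_entry("static_all"),
            "percent_static_end_unbind": 100.0 * (1 - counts.frac_static_segments_to_processive),
            "dwell_static_end_unbind": fit_entry("static_post"),
            "percent_static_end_processive": 100.0 * counts.frac_static_segments_to_processive,
            "dwell_static_end_processive": fit_entry("static_pre"),
        },
        "jumps": {
            "distance_nm": ms(jump_distances),
            "binding_duration_jump_molecules": fit_entry("jump_molecule"),
            "percent_molecules_with_jumps": 100.0 * n_jump_mol / n_mol if n_mol else math.nan,
        },
        "rates": {
            "k_exit_processive": rates.k_exit_processive,
            "k_exit_static": rates.k_exit_static,
            "k_off_processive": rates.k_off_processive,
            "k_static": rates.k_static,
            "k_off_static": rates.k_off_static,
            "k_processive": rates.k_processive,
            "p_land_static": rates.p_land_static,
            "p_land_processive": rates.p_land_processive,
        },
    }
    return report


def report_to_markdown(report: dict) -> str:
    lines = ["# Single-molecule cohort summary", ""]
    for section, rows in report.items():
        lines.append(f"## {section.replace('_', ' ')}")
        lines.append("")
        lines.append("| parameter | value |")
        lines.append("|---|---|")
        for key, val in rows.items():
            if isinstance(val, dict):
                if "tau_s" in val:
                    txt = f"{val['tau_s']:.1f} ({val['ci95_lo']:.1f}-{val['ci95_hi']:.1f}) s, n={val['n']}"
                else:
                    txt = f"{val['mean']:.3g} +/- {val['sd']:.3g} (n={val['n']})"
            elif val is None:
                txt = "n/a"
            elif isinstance(val, float):
                txt = f"{val:.4g}"
            else:
                txt = str(val)
            lines.append(f"| {key.replace('_', ' ')} | {txt} |")
        lines.append("")
    return "\n".join(lines)


def report_to_tsv(report: dict) -> str:
    lines = ["section\tparameter\tvalue"]
    for section, rows in report.items():
        for key, val in rows.items():
            if isinstance(val, dict):
                for sub, v in val.items():
                    lines.append(f"{section}\t{key}.{sub}\t{v}")
            else:
                lines.append(f"{section}\t{key}\t{val}")
    return "\n".join(lines) + "\n"
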