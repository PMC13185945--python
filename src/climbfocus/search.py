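"""Mountain-climbing autofocus controller with adaptive coarse-to-fine stepping.

The search proceeds in four stages:

1. *Direction determination* — acquire ``n_direction_points`` images stepping
   from the start position and fit a straight line to (z, sharpness); the sign
   of the fitted slope decides whether to keep climbing in the probe direction
   or reverse.
2. *Climb* — step the stage along the chosen direction.  After each
   acquisition the local slope of the sharpness curve is estimated by fitting
   a quadratic to the trailing ``fit_window`` samples ("first-step" fit).  When
   the slope magnitude stays below both a fixed threshold
   ``T_fix = T_pre * step_pre * 1e3`` and a dynamic threshold derived from the
   three preceding slopes for ``n_consecutive`` points in a row, the step size
   is halved (at most ``max_halvings`` times).  The climb terminates when the
   sharpness strictly decreases over ``n_consecutive`` consecutive steps.
3. *Focus prediction* — a degree-2 polynomial in the Legendre basis is fitted
   to the last ``fit_window`` samples ("second-step" fit); its vertex predicts
   the focus with sub-step precision.
4. *Error check* (optional) — the image at the fitted peak is compared, by
   NIQE score, with the acquired image of highest sharpness, and the
   lower-scoring (better) plane wins.

The fixed threshold detects the approach of a sharpness plateau on an absolute
scale set once per hardware configuration; the dynamic threshold requires the
slope magnitude to keep shrinking, which rejects plateaus far from the peak
where the curve is merely flat.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol, Sequence, runtime_checkable

import numpy as np

from .metrics import SharpnessSample, sharpness

__all__ = [
    "AutofocusConfig",
    "SearchEvent",
    "SearchTrace",
    "FocusResult",
    "FitPeak",
    "Microscope",
    "SearchRangeExceededError",
    "StageTravelError",
    "fixed_threshold",
    "dynamic_threshold",
    "determine_direction",
    "direction_two_point",
    "local_slope",
    "should_refine",
    "should_terminate",
    "fit_peak",
    "run_autofocus",
    "run_autofocus_fixed_sharpness",
]


class StageTravelError(RuntimeError):
    """Commanded stage position outside the hardware travel limits."""


class SearchRangeExceededError(RuntimeError):
    """Total traversed range exceeded ``max_range_um`` without bracketing a peak."""

    def __init__(self, message: str, trace: "SearchTrace"):
        super().__init__(message)
        self.trace = trace


@runtime_checkable
class Microscope(Protocol):
    """Minimal acquisition contract the controller drives.

    Adapters must move the stage to an absolute axial position in micrometres
    and return a 2-D grayscale intensity array on capture.  ``z_limits_um``
    reports the travel range; ``move_to`` must raise :class:`StageTravelError`
    outside it.
    """

    def move_to(self, z_um: float) -> None: ...

    def capture(self) -> np.ndarray: ...

    @property
    def z_limits_um(self) -> tuple[float, float]: ...


@dataclass
class AutofocusConfig:
    """User-facing autofocus parameters.

    ``step_pre_um`` (initial coarse step) and ``t_pre_per_um`` (pre-set slope
    threshold, 1/um) are the two parameters calibrated once per hardware
    setup; the rest default to the published procedure: 5 direction points,
    10-point fit windows, 3-consecutive rules, at most 2 halvings.
    """

    step_pre_um: float = 1.0
    t_pre_per_um: float = 3.0
    n_direction_points: int = 5
    fit_window: int = 10
    n_consecutive: int = 3
    max_halvings: int = 2
    max_range_um: float = 1000.0
    niqe_check: bool = False
    denoise: bool = True
    scan_sign: int = 1

    def __post_init__(self) -> None:
        if self.step_pre_um <= 0:
            raise ValueError("step_pre_um must be > 0")
        if self.t_pre_per_um < 0:
            raise ValueError("t_pre_per_um must be >= 0")
        if self.n_direction_points < 2:
            raise ValueError("n_direction_points must be >= 2")
        if self.fit_window < 3:
            raise ValueError("fit_window must be >= 3")
        if self.n_consecutive < 1:
            raise ValueError("n_consecutive must be >= 1")
        if self.max_halvings < 0:
            raise ValueError("max_halvings must be >= 0")
        if self.scan_sign not in (1, -1):
            raise ValueError("scan_sign must be +1 or -1")
        if self.max_range_um <= self.n_direction_points * self.step_pre_um:
            raise ValueError(
                "max_range_um must exceed n_direction_points * step_pre_um"
            )


@dataclass(frozen=True)
class SearchEvent:
    """Tagged event in the search trace (direction-decided, halved, ...)."""

    kind: str
    sample_index: int
    z_um: float
    info: Optional[float] = None


@dataclass
class SearchTrace:
    """Full acquisition history of one autofocus run."""

    samples: list = field(default_factory=list)
    step_history: list = field(default_factory=list)
    events: list = field(default_factory=list)
    direction: int = 0

    @property
    def z_positions(self) -> np.ndarray:
        return np.array([s.z_um for s in self.samples], dtype=float)

    @property
    def sharpness_values(self) -> np.ndarray:
        return np.array([s.sharpness for s in self.samples], dtype=float)

    def traversed_range_um(self) -> float:
        z = self.z_positions
        return float(z.max() - z.min()) if z.size else 0.0


@dataclass
class FocusResult:
    """Final predicted focus with provenance and the full climb trace."""

    z_focus_um: float
    source: str  # "fit_peak" | "measured_peak"
    fit_peak_z_um: Optional[float]
    best_measured_z_um: float
    trace: SearchTrace
    niqe_scores: Optional[tuple[float, float]] = None
    timing_s: Optional[dict] = None
    frames: Optional[list] = None  # captured images, aligned with trace.samples


# ---------------------------------------------------------------------------
# threshold and slope primitives
# ---------------------------------------------------------------------------


def fixed_threshold(t_pre_per_um: float, step_pre_um: float) -> float:
    """Fixed slope threshold ``T_fix = T_pre * step_pre * 1e3``.

    The 10^3 factor is part of the published unit convention and is applied
    literally; T_fix carries units of sharpness per micrometre.
    """
    if t_pre_per_um < 0 or step_pre_um < 0:
        raise ValueError("fixed_threshold arguments must be >= 0")
    return float(t_pre_per_um) * float(step_pre_um) * 1e3


def dynamic_threshold(last_three_slopes: Sequence[float]) -> float:
    """Dynamic slope threshold from the three preceding slope values.

    ``T_dyn = |S_avg + S_std|`` if ``S_avg < 0`` else ``|S_avg - S_std|``,
    with ``S_std`` the population (divisor-3) standard deviation, matching
    the population convention of the sharpness variance.
    """
    s = np.asarray(last_three_slopes, dtype=float)
    if s.shape != (3,):
        raise ValueError("dynamic_threshold requires exactly 3 slope values")
    s_avg = float(s.mean())
    s_std = float(s.std())  # population std, ddof=0
    if s_avg < 0:
        return abs(s_avg + s_std)
    return abs(s_avg - s_std)


def determine_direction(z_um: Sequence[float], values: Sequence[float]) -> int:
    """Search direction from a straight-line fit through the probe points.

    Returns +1 when the fitted slope is positive (sharpness increases along
    the probe direction: keep going), -1 otherwise (reverse).
    """
    z = np.asarray(z_um, dtype=float)
    s = np.asarray(values, dtype=float)
    if z.shape != s.shape or z.ndim != 1:
        raise ValueError("z and sharpness arrays must be 1-D and equal length")
    if np.unique(z).size < 2:
        raise ValueError("direction fit needs at least 2 distinct z positions")
    zc = z - z.mean()
    slope = float(np.dot(zc, s - s.mean()) / np.dot(zc, zc))
    return 1 if slope > 0 else -1


def direction_two_point(values: Sequence[float]) -> int:
    """Legacy two-point direction rule: sign of the first sharpness increment.

    Baseline comparator for the five-point linear fit; kept for benchmarking.
    """
    s = np.asarray(values, dtype=float)
    if s.size < 2:
        raise ValueError("two-point direction needs at least 2 values")
    return 1 if s[1] > s[0] else -1


def local_slope(z_um: Sequence[float], values: Sequence[float]) -> Optional[float]:
    """Slope of the sharpness curve at the latest position ("first-step" fit).

    Fits a least-squares quadratic to the trailing samples and evaluates its
    derivative at the most recent z.  Returns ``None`` (not ready) with fewer
    than 3 distinct z positions.
    """
    z = np.asarray(z_um, dtype=float)
    s = np.asarray(values, dtype=float)
    if np.unique(z).size < 3:
        return None
    z0 = z.mean()
    # centred fit for conditioning; the derivative is unaffected
    c = np.polynomial.polynomial.polyfit(z - z0, s, 2)
    return float(c[1] + 2.0 * c[2] * (z[-1] - z0))


def should_refine(
    slopes: Sequence[float],
    t_fix: float,
    n_consecutive: int = 3,
    start_index: int = 0,
) -> bool:
    """Halving criterion: both slope thresholds met for n consecutive points.

    For each of the last ``n_consecutive`` slope values the magnitude must be
    within ``t_fix`` *and* within the dynamic threshold computed from the three
    slopes preceding that point.  Points before ``start_index`` (slopes logged
    before the previous halving) cannot count towards the consecutive run,
    though they may still feed the dynamic threshold.
    """
    n = len(slopes)
    if n - n_consecutive < start_index or n < n_consecutive:
        return False
    for j in range(n - n_consecutive, n):
        if j < 3:
            return False  # dynamic threshold not ready for this point
        if abs(slopes[j]) > t_fix:
            return False
        if abs(slopes[j]) > dynamic_threshold(slopes[j - 3 : j]):
            return False
    return True


def should_terminate(values: Sequence[float], n_consecutive: int = 3) -> bool:
    """Stop rule: sharpness strictly decreased over the last n consecutive steps.

    Ties do not count as decreases, so noise plateaus cannot stop the climb.
    """
    s = list(values)
    if len(s) < n_consecutive + 1:
        return False
    tail = s[-(n_consecutive + 1) :]
    return all(tail[i] > tail[i + 1] for i in range(n_consecutive))


# ---------------------------------------------------------------------------
# second-step curve fit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitPeak:
    """Result of the second-step (Legendre-basis) quadratic fit."""

    z_peak_um: float
    coeffs: tuple  # monomial coefficients (c0, c1, c2) in z
    degenerate: bool


def fit_peak(z_um: Sequence[float], values: Sequence[float]) -> FitPeak:
    """Predict the focus as the vertex of a Legendre-basis quadratic fit.

    The samples' z range is mapped to [-1, 1] and a degree-2 polynomial in
    the Legendre basis is least-squares fitted (orthogonal bases keep the
    normal equations well conditioned).  The peak is the vertex of the
    equivalent monomial form.  The fit is flagged degenerate when the curve
    opens upward (no interior maximum), the system is rank-deficient, or the
    vertex falls outside the sampled range; the returned z is always clamped
    to the sampled range.
    """
    z = np.asarray(z_um, dtype=float)
    s = np.asarray(values, dtype=float)
    if z.size < 3:
        raise ValueError("fit_peak needs at least 3 samples")
    z_lo, z_hi = float(z.min()), float(z.max())
    if np.unique(z).size < 3:
        return FitPeak(z_peak_um=0.5 * (z_lo + z_hi), coeffs=(np.nan,) * 3, degenerate=True)
    series = np.polynomial.legendre.Legendre.fit(z, s, 2)
    poly = series.convert(kind=np.polynomial.polynomial.Polynomial)
    coef = np.zeros(3)
    coef[: poly.coef.size] = poly.coef
    c0, c1, c2 = (float(v) for v in coef)
    if c2 >= 0 or not np.isfinite(c2):
        return FitPeak(z_peak_um=0.5 * (z_lo + z_hi), coeffs=(c0, c1, c2), degenerate=True)
    vertex = -c1 / (2.0 * c2)
    degenerate = not (z_lo <= vertex <= z_hi)
    return FitPeak(
        z_peak_um=float(np.clip(vertex, z_lo, z_hi)),
        coeffs=(c0, c1, c2),
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# closed-loop controller
# ---------------------------------------------------------------------------


class _Timing:
    """Wall-clock breakdown: direction / capture / stage-move / algorithm."""

    def __init__(self) -> None:
        self.t = {"direction_s": 0.0, "capture_s": 0.0, "stage_move_s": 0.0,
                  "algorithm_s": 0.0}

    def add(self, key: str, dt: float) -> None:
        self.t[key] += dt

    def as_dict(self) -> dict:
        out = dict(self.t)
        out["total_s"] = sum(self.t.values())
        return out


def _slope_refine_rule(cfg: AutofocusConfig, t_fix: float) -> Callable:
    def rule(state: dict) -> bool:
        return should_refine(
            state["slopes"], t_fix, cfg.n_consecutive, state["refine_start"]
        )

    return rule


def run_autofocus(
    microscope: Microscope,
    start_z_um: float,
    config: Optional[AutofocusConfig] = None,
    niqe_model=None,
    keep_frames: bool = False,
) -> FocusResult:
    """Run the full adaptive mountain-climbing autofocus loop.

    Parameters
    ----------
    microscope:
        Any object satisfying the :class:`Microscope` protocol (virtual
        microscope, replayed TIFF stack, or hardware adapter).
    start_z_um:
        Axial position the search starts from.
    config:
        :class:`AutofocusConfig`; defaults are the published procedure.
    niqe_model:
        A trained :class:`climbfocus.niqe.NiqeModel`; when provided together
        with ``config.niqe_check`` the final plane is chosen by comparing the
        NIQE scores of the fitted-peak image and the best measured image.
    keep_frames:
        Retain every captured frame (needed for stack restoration).

    Raises
    ------
    SearchRangeExceededError
        when the traversal would exceed ``max_range_um`` (carries the trace).
    """
    cfg = config or AutofocusConfig()
    t_fix = fixed_threshold(cfg.t_pre_per_um, cfg.step_pre_um)
    return _run_loop(
        microscope, start_z_um, cfg,
        refine_rule=None,  # installed below once state exists
        t_fix=t_fix, niqe_model=niqe_model, keep_frames=keep_frames,
    )


def run_autofocus_fixed_sharpness(
    microscope: Microscope,
    start_z_um: float,
    config: Optional[AutofocusConfig] = None,
    sharpness_threshold: float = 2000.0,
    keep_frames: bool = False,
) -> FocusResult:
    """Baseline climber that halves the step once sharpness exceeds a preset value.

    This is the classical fixed-sharpness-threshold rule the slope-threshold
    method replaces: the step is halved whenever the latest sharpness value
    reaches ``sharpness_threshold``.  On fields of view whose peak sharpness
    never reaches the threshold it never refines; on bright fields it refines
    long before the peak.  Kept as a benchmark, not for production use.
    """
    cfg = config or AutofocusConfig()

    def rule(state: dict) -> bool:
        return state["climb_values"][-1] >= sharpness_threshold

    return _run_loop(
        microscope, start_z_um, cfg,
        refine_rule=rule, t_fix=None, niqe_model=None, keep_frames=keep_frames,
    )


def _run_loop(
    microscope: Microscope,
    start_z_um: float,
    cfg: AutofocusConfig,
    refine_rule: Optional[Callable],
    t_fix: Optional[float],
    niqe_model,
    keep_frames: bool,
) -> FocusResult:
    timing = _Timing()
    trace = SearchTrace()
    frames: list = []
    step = cfg.step_pre_um
    best = {"sharpness": -np.inf, "z": start_z_um, "image": None}
    z_seen_min = np.inf
    z_seen_max = -np.inf

    def acquire(z: float) -> SharpnessSample:
        nonlocal z_seen_min, z_seen_max
        t0 = time.perf_counter()
        microscope.move_to(z)
        t1 = time.perf_counter()
        img = microscope.capture()
        t2 = time.perf_counter()
        val = sharpness(img, denoise=cfg.denoise)
        t3 = time.perf_counter()
        timing.add("stage_move_s", t1 - t0)
        timing.add("capture_s", t2 - t1)
        timing.add("algorithm_s", t3 - t2)
        sample = SharpnessSample(z_um=z, sharpness=val)
        trace.samples.append(sample)
        trace.step_history.append(step)
        if keep_frames:
            frames.append(img)
        if val > best["sharpness"]:
            best.update(sharpness=val, z=z, image=img)
        z_seen_min = min(z_seen_min, z)
        z_seen_max = max(z_seen_max, z)
        return sample

    def guard_range(z_next: float) -> None:
        span = max(z_seen_max, z_next) - min(z_seen_min, z_next)
        if span > cfg.max_range_um:
            trace.events.append(
                SearchEvent("range-exceeded", len(trace.samples) - 1, z_next)
            )
            raise SearchRangeExceededError(
                f"traversed range {span:.3f} um exceeds max_range_um="
                f"{cfg.max_range_um:.3f}", trace
            )

    # --- stage 1: direction determination -------------------------------
    probe = []
    for i in range(cfg.n_direction_points):
        z = start_z_um + cfg.scan_sign * i * step
        guard_range(z)
        probe.append(acquire(z))
    t0 = time.perf_counter()
    rel = determine_direction([p.z_um for p in probe], [p.sharpness for p in probe])
    timing.add("direction_s", time.perf_counter() - t0)
    direction = cfg.scan_sign * rel
    trace.direction = direction
    trace.events.append(
        SearchEvent("direction-decided", len(trace.samples) - 1,
                    probe[-1].z_um, info=float(direction))
    )
    # On reversal the stage returns to the start and climbs the other way,
    # reusing only the start sample; forward probes are reused wholesale.
    climb = list(probe) if rel > 0 else [probe[0]]

    # --- stage 2: climb ---------------------------------------------------
    slopes: list[float] = []
    state = {"slopes": slopes, "refine_start": 0, "climb_values": None}
    if refine_rule is None:
        refine_rule = _slope_refine_rule(cfg, t_fix)

    def push_slope(upto: int) -> None:
        tail = climb[max(0, upto - cfg.fit_window) : upto]
        sl = local_slope([c.z_um for c in tail], [c.sharpness for c in tail])
        if sl is not None:
            slopes.append(sl)

    t0 = time.perf_counter()
    for k in range(3, len(climb) + 1):  # seed slopes from reused probe points
        push_slope(k)
    timing.add("algorithm_s", time.perf_counter() - t0)

    halvings = 0
    z_cur = climb[-1].z_um
    while True:
        z_next = z_cur + direction * step
        guard_range(z_next)
        s = acquire(z_next)
        climb.append(s)
        z_cur = z_next
        t0 = time.perf_counter()
        push_slope(len(climb))
        state["climb_values"] = [c.sharpness for c in climb]
        if halvings < cfg.max_halvings and refine_rule(state):
            step *= 0.5
            halvings += 1
            state["refine_start"] = len(slopes)
            trace.events.append(
                SearchEvent("halved" if halvings == 1 else "halved-again",
                            len(trace.samples) - 1, z_cur, info=step)
            )
        terminated = should_terminate(state["climb_values"], cfg.n_consecutive)
        timing.add("algorithm_s", time.perf_counter() - t0)
        if terminated:
            trace.events.append(
                SearchEvent("terminated", len(trace.samples) - 1, z_cur)
            )
            break

    # --- stage 3: second-step curve fit ----------------------------------
    # Fit the fit_window acquired points nearest (in z) to the best measured
    # sample.  On the forward single-pass these are the final fit_window
    # points; on the near-focus reversal path this keeps the direction probes
    # that bracket the peak instead of the receding downhill tail.
    z_best = best["z"]
    order = sorted(range(len(trace.samples)),
                   key=lambda i: abs(trace.samples[i].z_um - z_best))
    tail = [trace.samples[i] for i in sorted(order[: cfg.fit_window])]
    t0 = time.perf_counter()
    fit = fit_peak([c.z_um for c in tail], [c.sharpness for c in tail])
    timing.add("algorithm_s", time.perf_counter() - t0)
    trace.events.append(
        SearchEvent("fit-done", len(trace.samples) - 1, fit.z_peak_um,
                    info=0.0 if not fit.degenerate else 1.0)
    )

    # --- stage 4: final plane selection -----------------------------------
    niqe_scores = None
    if fit.degenerate:
        z_focus, source = best["z"], "measured_peak"
    elif cfg.niqe_check and niqe_model is not None:
        from .niqe import niqe_score, select_final_focus

        t0 = time.perf_counter()
        microscope.move_to(fit.z_peak_um)
        t1 = time.perf_counter()
        img_a = microscope.capture()
        t2 = time.perf_counter()
        timing.add("stage_move_s", t1 - t0)
        timing.add("capture_s", t2 - t1)
        t0 = time.perf_counter()
        z_focus, niqe_scores = select_final_focus(
            img_a, fit.z_peak_um, best["image"], best["z"], niqe_model
        )
        timing.add("algorithm_s", time.perf_counter() - t0)
        source = "fit_peak" if z_focus == fit.z_peak_um else "measured_peak"
        trace.events.append(
            SearchEvent("niqe-decided", len(trace.samples) - 1, z_focus)
        )
    else:
        z_focus, source = fit.z_peak_um, "fit_peak"

    return FocusResult(
        z_focus_um=float(z_focus),
        source=source,
        fit_peak_z_um=None if fit.degenerate else float(fit.z_peak_um),
        best_measured_z_um=float(best["z"]),
        trace=trace,
        niqe_scores=niqe_scores,
        timing_s=timing.as_dict(),
        frames=frames if keep_frames else None,
    )
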