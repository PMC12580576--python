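"""Response-level simulation of the eight motion-position illusion tasks.

Five illusions (flash-lag FLE, luminance flash-lag LUM-FLE, Fröhlich FE,
flash-drag FD, twinkle-goes TG) are measured with interleaved 1-up/1-down
adaptive staircases; three (flash-grab FG, motion-induced position shift
MIPS, flash-jump FJ) are adjustment/localization tasks.  The simulated
observer answers each staircase trial through a cumulative-normal
psychometric function with a lapse rate:

    P(respond "+1") = lapse/2 + (1 - lapse) * Phi((v - PSE) / sigma)

where the subjective PSE in screen coordinates is
``sign(direction) * true_magnitude + response_bias``.  A "+1" response
("presented value perceived above the PSE") moves the staircase value
down by the active step; the step size shrinks per the staircase's
reversal schedule.

Units: staircase values for FLE/FE live in degrees of polar angle (the
tasks rotate around fixation); the observer's true magnitude is stored
in arc-length dva and converted at the task radius (12.15 dva FLE,
10.5 dva FE).  LUM-FLE staircases run in % luminance contrast; FD and TG
in dva.  Adjustment tasks report directly in the illusion's native unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .cohort import ILLUSIONS, ObserverProfile

__all__ = [
    "StaircaseConfig",
    "StaircaseTrace",
    "AdjustmentTrialSet",
    "SessionResult",
    "respond",
    "staircase_step",
    "run_staircase",
    "run_illusion_session",
    "session_to_frame",
    "STAIRCASE_ILLUSIONS",
    "ADJUSTMENT_ILLUSIONS",
    "TASK_RADIUS",
]

STAIRCASE_ILLUSIONS = ("fle", "lum_fle", "fe", "fd", "tg")
ADJUSTMENT_ILLUSIONS = ("fg", "mips", "fj")

#: Rotation radius (dva) at which polar-angle staircase units are converted
#: to arc-length dva: flash radius for FLE, rod trailing edge for FE, target
#: radius for FG.
TASK_RADIUS = {"fle": 12.15, "fe": 10.5, "fg": 14.15}

#: Illusions whose staircase axis is polar angle rather than dva.
_POLAR = ("fle", "fe")

#: Direction labels and their screen-coordinate signs.
DIRECTIONS = {
    "fle": {"cw": 1.0, "ccw": -1.0},
    "lum_fle": {"increase": 1.0, "decrease": -1.0},
    "fe": {"cw": 1.0, "ccw": -1.0},
    "fd": {"down": 1.0, "up": -1.0},
    "tg": {"l2r": 1.0, "r2l": -1.0},
    "fg": {"cw": 1.0, "ccw": -1.0},
    "mips": {"pos": 1.0, "neg": -1.0},
    "fj": {"top_grow": 1.0, "bottom_grow": -1.0},
}

#: Contrast (% of full range) at which the LUM-FLE flash physically matches
#: the changing target at flash onset (80 cd/m^2 within the 22-132 range).
LUM_NEUTRAL = 47.3


@dataclass
class StaircaseConfig:
    illusion: str
    direction: str
    start_value: float
    n_trials: int
    step_schedule: list[tuple[int, float]]
    staircase_id: str = ""
    condition: str | None = None  # TG noise condition
    start_label: str = ""  # "ahead"/"behind" (or "high"/"low" for LUM-FLE)

    def __post_init__(self) -> None:
        if self.illusion not in STAIRCASE_ILLUSIONS:
            raise ValueError(f"unknown staircase illusion {self.illusion!r}")
        if self.direction not in DIRECTIONS[self.illusion]:
            raise ValueError(
                f"unknown direction {self.direction!r} for {self.illusion}"
            )
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        counts = [c for c, _ in self.step_schedule]
        steps = [s for _, s in self.step_schedule]
        if not self.step_schedule or counts[0] != 0:
            raise ValueError("step_schedule must start at reversal count 0")
        if any(s <= 0 for s in steps):
            raise ValueError("step sizes must be positive")
        if any(b <= a for a, b in zip(counts, counts[1:])):
            raise ValueError("schedule reversal counts must strictly increase")

    def step_for(self, n_reversals: int) -> float:
        step = self.step_schedule[0][1]
        for threshold, s in self.step_schedule:
            if n_reversals >= threshold:
                step = s
        return step


@dataclass
class StaircaseTrace:
    config: StaircaseConfig
    presented_value: np.ndarray
    response: np.ndarray  # +1 / -1
    is_reversal: np.ndarray  # bool
    step_used: np.ndarray
    final_value: float  # staircase position after the last update

    @property
    def n_trials(self) -> int:
        return len(self.presented_value)


@dataclass
class AdjustmentTrialSet:
    illusion: str
    trials: pd.DataFrame

    def __post_init__(self) -> None:
        if self.illusion not in ADJUSTMENT_ILLUSIONS:
            raise ValueError(f"unknown adjustment illusion {self.illusion!r}")


@dataclass
class SessionResult:
    observer_id: str
    illusion: str
    traces: list[StaircaseTrace] = field(default_factory=list)
    adjustment: AdjustmentTrialSet | None = None

    def to_frame(self, session: int = 1) -> pd.DataFrame:
        return session_to_frame(self, session=session)


# ---------------------------------------------------------------------------
# Observer model


def polar_from_arc(arc_dva: float, radius: float) -> float:
    """Arc-length dva -> degrees of polar angle at the given radius."""
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    return arc_dva / radius * 180.0 / np.pi


def _native_pse_sigma(
    profile: ObserverProfile, illusion: str, direction: str, condition: str | None
) -> tuple[float, float]:
    """Subjective PSE and slope in the staircase's native units."""
    m = profile.true_magnitude[illusion]
    b = profile.response_bias[illusion]
    sigma = profile.response_sigma[illusion]
    if illusion == "tg" and condition == "static":
        m = 0.0  # the TG shift only appears on dynamic-noise trials
    if illusion in _POLAR:
        r = TASK_RADIUS[illusion]
        m, b, sigma = (polar_from_arc(v, r) for v in (m, b, sigma))
    sign = DIRECTIONS[illusion][direction]
    pse = sign * m + b
    if illusion == "lum_fle":
        pse += LUM_NEUTRAL
    return pse, sigma


def respond_probability(
    profile: ObserverProfile,
    illusion: str,
    direction: str,
    presented_value: float,
    condition: str | None = None,
) -> float:
    """P(response = +1) for a staircase trial at the presented value."""
    if illusion not in STAIRCASE_ILLUSIONS:
        raise ValueError(f"unknown staircase illusion {illusion!r}")
    if direction not in DIRECTIONS[illusion]:
        raise ValueError(f"unknown direction {direction!r} for {illusion}")
    pse, sigma = _native_pse_sigma(profile, illusion, direction, condition)
    lapse = profile.lapse_rate
    return float(lapse / 2 + (1 - lapse) * ndtr((presented_value - pse) / sigma))


def respond(
    profile: ObserverProfile,
    illusion: str,
    direction: str,
    presented_value: float,
    rng: np.random.Generator,
    condition: str | None = None,
) -> int:
    """Draw a single ±1 judgement from the psychometric observer."""
    if not np.isfinite(presented_value):
        raise ValueError("presented_value must be finite")
    p = respond_probability(profile, illusion, direction, presented_value, condition)
    return 1 if rng.random() < p else -1


# ---------------------------------------------------------------------------
# Staircase mechanics


@dataclass
class _StaircaseState:
    config: StaircaseConfig
    value: float
    n_reversals: int = 0
    prev_response: int | None = None
    trials_done: int = 0

    @property
    def remaining(self) -> int:
        return self.config.n_trials - self.trials_done


def staircase_step(state: _StaircaseState, response: int) -> tuple[_StaircaseState, float]:
    """Apply one response: update reversal count, pick the active step,
    and move the staircase (a "+1" response moves the value down).

    Returns the updated state and the step size used.  The step-size
    change triggered by a threshold reversal applies from the move that
    follows that reversal (i.e., immediately after the response).
    """
    if state.remaining <= 0:
        raise ValueError("staircase has no remaining trials")
    if state.prev_response is not None and response != state.prev_response:
        state.n_reversals += 1
    step = state.config.step_for(state.n_reversals)
    state.value -= response * step
    state.prev_response = response
    state.trials_done += 1
    return state, step


def run_staircase(
    config: StaircaseConfig,
    profile: ObserverProfile,
    rng: np.random.Generator,
) -> StaircaseTrace:
    """Run one adaptive staircase to completion."""
    state = _StaircaseState(config=config, value=config.start_value)
    presented = np.empty(config.n_trials)
    responses = np.empty(config.n_trials, dtype=int)
    reversals = np.zeros(config.n_trials, dtype=bool)
    steps = np.empty(config.n_trials)
    for t in range(config.n_trials):
        presented[t] = state.value
        resp = respond(
            profile, config.illusion, config.direction, state.value, rng,
            condition=config.condition,
        )
        prev = state.prev_response
        state, step_used = staircase_step(state, resp)
        responses[t] = resp
        reversals[t] = prev is not None and resp != prev
        steps[t] = step_used
    return StaircaseTrace(
        config=config,
        presented_value=presented,
        response=responses,
        is_reversal=reversals,
        step_used=steps,
        final_value=state.value,
    )


# ---------------------------------------------------------------------------
# Session designs


#: Published staircase designs: (step schedule, start offset, trials/staircase).
STAIRCASE_DESIGNS: dict[str, dict] = {
    "fle": dict(step_schedule=[(0, 4.0), (3, 2.0)], start_value=28.0, n_trials=40),
    "fe": dict(
        step_schedule=[(0, 6.0), (1, 3.0), (2, 2.0), (3, 1.0)],
        start_value=45.0, n_trials=40,
    ),
    "fd": dict(step_schedule=[(0, 0.44), (4, 0.22)], start_value=3.52, n_trials=52),
    "tg": dict(step_schedule=[(0, 0.45)], start_value=4.52, n_trials=40),
    "lum_fle": dict(step_schedule=[(0, 5.0)], start_value=None, n_trials=40),
}


def _staircase_set(
    illusion: str, overrides: dict | None = None
) -> list[StaircaseConfig]:
    """The staircase battery for one illusion (published design by default)."""
    if illusion not in STAIRCASE_DESIGNS:
        raise ValueError(f"unknown staircase illusion {illusion!r}")
    design = dict(STAIRCASE_DESIGNS[illusion])
    if overrides:
        unknown = set(overrides) - set(design)
        if unknown:
            raise ValueError(f"unknown staircase fields for {illusion}: {unknown}")
        design.update(overrides)
    schedule = [tuple(pair) for pair in design["step_schedule"]]
    start = design["start_value"]
    n = design["n_trials"]

    configs = []
    conditions = ("dynamic", "static") if illusion == "tg" else (None,)
    for cond in conditions:
        for direction, dsign in DIRECTIONS[illusion].items():
            if illusion == "lum_fle":
                # absolute contrast starts: one above, one below the PSE
                pairs = [("high", 100.0), ("low", 10.0)]
            else:
                # start offset ahead of / behind the motion, in screen sign
                pairs = [("ahead", dsign * start), ("behind", -dsign * start)]
            for label, s0 in pairs:
                sid = "_".join(filter(None, [illusion, cond, direction, label]))
                configs.append(
                    StaircaseConfig(
                        illusion=illusion,
                        direction=direction,
                        start_value=s0,
                        n_trials=n,
                        step_schedule=schedule,
                        staircase_id=sid,
                        condition=cond,
                        start_label=label,
                    )
                )
    return configs


def _run_adjustment(
    illusion: str, profile: ObserverProfile, rng: np.random.Generator
) -> AdjustmentTrialSet:
    m = profile.true_magnitude[illusion]
    b = profile.response_bias[illusion]
    sigma = profile.response_sigma[illusion]
    rows = []
    if illusion == "mips":
        # 60 trials, 20 per starting offset; drift assignment random per trial.
        # Reported value: the top-bottom horizontal offset at subjective
        # alignment, i.e. twice the per-Gabor shift, plus bias and noise.
        start_labels = np.repeat(["aligned", "top_out", "top_in"], 20)
        rng.shuffle(start_labels)
        dirs = np.array(["pos", "neg"])[rng.integers(0, 2, size=60)]
        for t in range(60):
            dsign = DIRECTIONS["mips"][dirs[t]]
            rows.append(
                dict(
                    trial_index=t,
                    direction=dirs[t],
                    start_label=start_labels[t],
                    reported_value=dsign * 2 * m + b + rng.normal(0.0, sigma),
                    truth_value=0.0,
                    attention_check=False,
                    attention_passed=True,
                    valid=True,
                )
            )
    elif illusion == "fj":
        # 48 trials: 3 attention checks (every 15th), 45 experimental.
        # Reported value: height difference between target and reference bar
        # at the flash, twice the per-bar shift, signed by growth direction.
        n_top = 22 if rng.random() < 0.5 else 23
        dirs = np.array(["top_grow"] * n_top + ["bottom_grow"] * (45 - n_top))
        rng.shuffle(dirs)
        start_labels = np.repeat(["equal", "taller", "shorter"], 15)
        rng.shuffle(start_labels)
        check_positions = {14, 29, 44}  # every 15 trials
        exp_i = 0
        for t in range(48):
            if t in check_positions:
                rows.append(
                    dict(
                        trial_index=t,
                        direction="none",
                        start_label="check",
                        reported_value=np.nan,
                        truth_value=np.nan,
                        attention_check=True,
                        attention_passed=bool(
                            rng.random() >= profile.attention_fail_rate
                        ),
                        valid=True,
                    )
                )
                continue
            dsign = DIRECTIONS["fj"][dirs[exp_i]]
            rows.append(
                dict(
                    trial_index=t,
                    direction=dirs[exp_i],
                    start_label=start_labels[exp_i],
                    reported_value=dsign * 2 * m + b + rng.normal(0.0, sigma),
                    truth_value=0.0,
                    attention_check=False,
                    attention_passed=True,
                    valid=True,
                )
            )
            exp_i += 1
    elif illusion == "fg":
        # 200 trials: 30 per inducer duration (6 durations) + 20 catch.
        # Reported value: signed arc-length error (dva) of the clicked
        # position, positive in the reversal direction.
        durations = np.repeat([700, 800, 900, 1000, 1100, 1200], 30)
        dirs = np.array(["cw", "ccw"] * 90)
        order = rng.permutation(180)
        durations, dirs = durations[order], dirs[order]
        trials = [("target", d, dur) for d, dur in zip(dirs, durations)]
        trials += [("catch", "none", 0)] * 20
        order = rng.permutation(len(trials))
        for t, k in enumerate(order):
            kind, d, dur = trials[k]
            if kind == "catch":
                rows.append(
                    dict(
                        trial_index=t,
                        direction="none",
                        start_label=f"dur{dur}",
                        reported_value=np.nan,
                        truth_value=np.nan,
                        attention_check=True,
                        attention_passed=bool(
                            rng.random() >= profile.attention_fail_rate
                        ),
                        valid=True,
                    )
                )
                continue
            invalid = rng.random() < profile.invalid_response_rate
            dsign = DIRECTIONS["fg"][d]
            rows.append(
                dict(
                    trial_index=t,
                    direction=d,
                    start_label=f"dur{dur}",
                    reported_value=(
                        np.nan if invalid else dsign * m + b + rng.normal(0.0, sigma)
                    ),
                    truth_value=0.0,
                    attention_check=False,
                    attention_passed=True,
                    valid=not invalid,
                )
            )
    else:
        raise ValueError(f"unknown adjustment illusion {illusion!r}")
    return AdjustmentTrialSet(illusion=illusion, trials=pd.DataFrame(rows))


def run_illusion_session(
    illusion: str,
    profile: ObserverProfile,
    rng: np.random.Generator,
    staircase_overrides: dict | None = None,
) -> SessionResult:
    """Simulate one observer's full session for one illusion."""
    if illusion not in ILLUSIONS:
        raise ValueError(f"unknown illusion {illusion!r}; expected one of {ILLUSIONS}")
    result = SessionResult(observer_id=profile.observer_id, illusion=illusion)
    if illusion in STAIRCASE_ILLUSIONS:
        # Staircases are interleaved in the task but statistically
        # independent given the observer, so they are simulated in turn.
        for cfg in _staircase_set(illusion, staircase_overrides):
            result.traces.append(run_staircase(cfg, profile, rng))
    else:
        result.adjustment = _run_adjustment(illusion, profile, rng)
    return result


def session_to_frame(result: SessionResult, session: int = 1) -> pd.DataFrame:
    """Tidy one-row-per-trial table for a session (the CSV interface)."""
    frames = []
    for trace in result.traces:
        cfg = trace.config
        frames.append(
            pd.DataFrame(
                dict(
                    observer_id=result.observer_id,
                    illusion=result.illusion,
                    session=session,
                    staircase_id=cfg.staircase_id,
                    direction=cfg.direction,
                    condition=cfg.condition if cfg.condition else "",
                    start_label=cfg.start_label,
                    trial_index=np.arange(trace.n_trials),
                    presented_value=trace.presented_value,
                    response=trace.response,
                    reversal=trace.is_reversal,
                    step_used=trace.step_used,
                    final_value=trace.final_value,
                    reported_value=np.nan,
                    truth_value=np.nan,
                    attention_check=False,
                    attention_passed=True,
                    valid=True,
                )
            )
        )
    if result.adjustment is not None:
        t = result.adjustment.trials.copy()
        t.insert(0, "observer_id", result.observer_id)
        t.insert(1, "illusion", result.illusion)
        t.insert(2, "session", session)
        t.insert(3, "staircase_id", "")
        t["condition"] = ""
        t["presented_value"] = np.nan
        t["response"] = 0
        t["reversal"] = False
        t["step_used"] = np.nan
        t["final_value"] = np.nan
        frames.append(t)
    out = pd.concat(frames, ignore_index=True)
    cols = [
        "observer_id", "illusion", "session", "staircase_id", "direction",
        "condition", "start_label", "trial_index", "presented_value",
        "response", "reversal", "step_used", "final_value", "reported_value",
        "truth_value", "attention_check", "attention_passed", "valid",
    ]
    return out[cols]
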