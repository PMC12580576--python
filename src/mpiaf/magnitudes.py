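"""Behavioural pre-processing: PSEs, convergence checks, exclusions, magnitudes.

For the staircase illusions, a PSE per staircase is the mean presented
value over the final trials (20 for FLE, LUM-FLE and FD; 10 for FE and
TG, which leave fewer usable trials).  PSEs are averaged within each
motion direction, and the illusion magnitude is the half-difference of
the two direction PSEs — halving keeps the magnitude from being twice
its true size, and any direction-independent response bias cancels.

A staircase pair (one started above, one below the PSE) must converge:
the within-direction difference between the two staircases' PSEs (final
values for FD) may not exceed an illusion-specific threshold, printed in
the illusion's native unit (3.18 arc dva FLE, 30% contrast LUM-FLE,
8.25 arc dva FE, 3.5 dva FD, 1.48 dva TG).  Thresholds are exclusive:
only a strictly greater difference fails.  The Fröhlich task also drops
observers who pressed the same key on >= 80% of trials in two or more
staircases.  The adjustment tasks apply their own outlier and
attention/validity rules (MIPS >= 10 dva trial outliers; FJ 3-SD trial
outliers and the all-three-attention-checks exclusion; FG > 20%
attention-check failures or > 18 invalid responses).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ILLUSIONS
from .staircases import (
    ADJUSTMENT_ILLUSIONS,
    DIRECTIONS,
    STAIRCASE_ILLUSIONS,
    TASK_RADIUS,
    StaircaseTrace,
)

__all__ = [
    "ExclusionReason",
    "IllusionEstimate",
    "ConvergenceRule",
    "DEFAULT_RULES",
    "K_LAST",
    "pse_from_trace",
    "polar_to_arc",
    "illusion_magnitude",
    "check_convergence",
    "fe_same_key_exclusion",
    "mips_magnitude",
    "fj_magnitude",
    "fg_magnitude",
    "estimate_session",
    "estimate_all",
]


class ExclusionReason(str, enum.Enum):
    NONE = "none"
    STAIRCASE_NONCONVERGENCE = "staircase_nonconvergence"
    SAME_KEY = "same_key"
    ATTENTION_CHECK = "attention_check"
    INVALID_RESPONSES = "invalid_responses"


@dataclass
class IllusionEstimate:
    observer_id: str
    illusion: str
    magnitude: float  # NaN when excluded
    per_direction_pse: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    excluded: bool = False
    exclusion_reason: ExclusionReason = ExclusionReason.NONE
    n_trials_used: int = 0

    def __post_init__(self) -> None:
        if self.excluded and not np.isnan(self.magnitude):
            raise ValueError("excluded estimates must carry a missing magnitude")


@dataclass
class ConvergenceRule:
    illusion: str
    threshold: float  # native units; exclusive bound
    compare_on: str = "staircase_pse"  # or "final_value"

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("convergence threshold must be positive")
        if self.compare_on not in ("staircase_pse", "final_value"):
            raise ValueError(f"unknown compare_on {self.compare_on!r}")


#: Number of final trials averaged into each staircase PSE.
K_LAST = {"fle": 20, "lum_fle": 20, "fd": 20, "fe": 10, "tg": 10}

#: Published per-illusion convergence thresholds (native units).
DEFAULT_RULES = {
    "fle": ConvergenceRule("fle", 3.18),
    "lum_fle": ConvergenceRule("lum_fle", 30.0),
    "fe": ConvergenceRule("fe", 8.25),
    "fd": ConvergenceRule("fd", 3.5, compare_on="final_value"),
    "tg": ConvergenceRule("tg", 1.48),
}

_POLAR = ("fle", "fe")


def pse_from_trace(trace, k_last: int) -> float:
    """Mean presented value over the final ``k_last`` trials."""
    values = trace.presented_value if isinstance(trace, StaircaseTrace) else np.asarray(trace, float)
    if len(values) < k_last:
        raise ValueError(
            f"trace has {len(values)} trials; need at least {k_last} "
            f"({k_last - len(values)} short)"
        )
    return float(np.mean(values[-k_last:]))


def polar_to_arc(polar_deg: float, radius: float) -> float:
    """Degrees of polar angle -> arc-length degrees of visual angle."""
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    return radius * np.deg2rad(polar_deg)


def illusion_magnitude(pse_dir_pos: float, pse_dir_neg: float) -> float:
    """Half-difference of opposing-direction PSEs; NaN propagates."""
    return (pse_dir_pos - pse_dir_neg) / 2.0


# ---------------------------------------------------------------------------
# Staircase sessions (tidy trial-table interface)


def _staircase_stats(session: pd.DataFrame, illusion: str) -> pd.DataFrame:
    """Per-staircase PSE/final value, in the illusion's output units."""
    k = K_LAST[illusion]
    rows = []
    for sid, g in session.groupby("staircase_id", sort=True):
        g = g.sort_values("trial_index")
        pse = pse_from_trace(g["presented_value"].to_numpy(), k)
        final = float(g["final_value"].iloc[-1])
        if illusion in _POLAR:
            pse = polar_to_arc(pse, TASK_RADIUS[illusion])
            final = polar_to_arc(final, TASK_RADIUS[illusion])
        cond = g["condition"].iloc[0]
        rows.append(
            dict(
                staircase_id=sid,
                direction=g["direction"].iloc[0],
                condition="" if pd.isna(cond) else str(cond),
                pse=pse,
                final_value=final,
                n_trials=len(g),
            )
        )
    return pd.DataFrame(rows)


def check_convergence(session: pd.DataFrame, rule: ConvergenceRule) -> bool:
    """True iff every within-direction staircase pair agrees within the rule.

    For each (condition, direction) cell the absolute difference between the
    two opposite-start staircases — on PSEs, or final values for FD — must
    not strictly exceed the threshold.
    """
    stats = _staircase_stats(session, rule.illusion)
    col = "pse" if rule.compare_on == "staircase_pse" else "final_value"
    for _, g in stats.groupby(["condition", "direction"]):
        v = g[col].to_numpy()
        if len(v) != 2:
            raise ValueError(
                f"expected 2 staircases per direction, got {len(v)} for {rule.illusion}"
            )
        if abs(v[0] - v[1]) > rule.threshold:
            return False
    return True


def fe_same_key_exclusion(session: pd.DataFrame) -> bool:
    """True iff >= 2 staircases each show >= 80% identical responses."""
    n_flagged = 0
    for _, g in session.groupby("staircase_id"):
        resp = g["response"].to_numpy()
        frac_same = max(np.mean(resp == 1), np.mean(resp == -1))
        if frac_same >= 0.8:
            n_flagged += 1
    return n_flagged >= 2


def _staircase_estimate(
    observer_id: str, illusion: str, session: pd.DataFrame, rule: ConvergenceRule
) -> IllusionEstimate:
    converged = check_convergence(session, rule)
    same_key = illusion == "fe" and fe_same_key_exclusion(session)
    stats = _staircase_stats(session, illusion)
    # direction PSEs: average the staircase PSEs within each direction
    # (within condition for TG)
    dir_pse: dict[str, float] = {}
    for (cond, direction), g in stats.groupby(["condition", "direction"]):
        key = f"{cond}_{direction}" if cond else direction
        dir_pse[key] = float(g["pse"].mean())
    signs = DIRECTIONS[illusion]
    pos = next(d for d, s in signs.items() if s > 0)
    neg = next(d for d, s in signs.items() if s < 0)
    if illusion == "tg":
        mag = illusion_magnitude(
            dir_pse[f"dynamic_{pos}"], dir_pse[f"dynamic_{neg}"]
        ) - illusion_magnitude(dir_pse[f"static_{pos}"], dir_pse[f"static_{neg}"])
    else:
        mag = illusion_magnitude(dir_pse[pos], dir_pse[neg])
    excluded = (not converged) or same_key
    reason = ExclusionReason.NONE
    if same_key:
        reason = ExclusionReason.SAME_KEY
    elif not converged:
        reason = ExclusionReason.STAIRCASE_NONCONVERGENCE
    n_used = K_LAST[illusion] * len(stats)
    return IllusionEstimate(
        observer_id=observer_id,
        illusion=illusion,
        magnitude=np.nan if excluded else float(mag),
        per_direction_pse=dir_pse,
        converged=converged,
        excluded=excluded,
        exclusion_reason=reason,
        n_trials_used=0 if excluded else n_used,
    )


# ---------------------------------------------------------------------------
# Adjustment tasks


def _aligned_effects(trials: pd.DataFrame, illusion: str) -> np.ndarray:
    """Direction-aligned per-trial effects (positive = expected direction)."""
    signs = DIRECTIONS[illusion]
    d = trials["direction"].map(signs).to_numpy(dtype=float)
    return d * trials["reported_value"].to_numpy(dtype=float)


def mips_magnitude(trials: pd.DataFrame, observer_id: str = "") -> IllusionEstimate:
    """MIPS: drop >= 10 dva trial outliers, then half the mean aligned offset."""
    t = trials[~trials["attention_check"].astype(bool)]
    effects = _aligned_effects(t, "mips")
    keep = np.abs(effects) < 10.0  # the >= 10 dva bound itself is excluded
    effects = effects[keep]
    if len(effects) == 0:
        return IllusionEstimate(
            observer_id, "mips", np.nan, excluded=True,
            exclusion_reason=ExclusionReason.INVALID_RESPONSES,
        )
    return IllusionEstimate(
        observer_id, "mips", float(np.mean(effects) / 2.0),
        n_trials_used=int(keep.sum()),
    )


def fj_magnitude(trials: pd.DataFrame, observer_id: str = "") -> IllusionEstimate:
    """FJ: all-attention-checks-failed exclusion, 3-SD trial outliers, halve."""
    checks = trials[trials["attention_check"].astype(bool)]
    if len(checks) and not checks["attention_passed"].any():
        return IllusionEstimate(
            observer_id, "fj", np.nan, excluded=True,
            exclusion_reason=ExclusionReason.ATTENTION_CHECK,
        )
    t = trials[~trials["attention_check"].astype(bool)]
    effects = _aligned_effects(t, "fj")
    mu, sd = float(np.mean(effects)), float(np.std(effects, ddof=0))
    keep = np.abs(effects - mu) <= 3.0 * sd if sd > 0 else np.ones(len(effects), bool)
    effects = effects[keep]
    return IllusionEstimate(
        observer_id, "fj", float(np.mean(effects) / 2.0),
        n_trials_used=int(keep.sum()),
    )


def fg_magnitude(trials: pd.DataFrame, observer_id: str = "") -> IllusionEstimate:
    """FG: attention/validity exclusions, then within-then-across direction mean."""
    checks = trials[trials["attention_check"].astype(bool)]
    if len(checks) and (~checks["attention_passed"]).mean() > 0.20:
        return IllusionEstimate(
            observer_id, "fg", np.nan, excluded=True,
            exclusion_reason=ExclusionReason.ATTENTION_CHECK,
        )
    targets = trials[~trials["attention_check"].astype(bool)]
    n_invalid = int((~targets["valid"].astype(bool)).sum())
    if n_invalid > 18:  # more than 10% of the 180 target trials
        return IllusionEstimate(
            observer_id, "fg", np.nan, excluded=True,
            exclusion_reason=ExclusionReason.INVALID_RESPONSES,
        )
    valid = targets[targets["valid"].astype(bool)]
    per_dir = []
    for _, g in valid.groupby("direction"):
        per_dir.append(float(np.mean(_aligned_effects(g, "fg"))))
    return IllusionEstimate(
        observer_id, "fg", float(np.mean(per_dir)), n_trials_used=len(valid)
    )


# ---------------------------------------------------------------------------
# End-to-end


def estimate_session(
    session: pd.DataFrame, rules: dict[str, ConvergenceRule] | None = None
) -> IllusionEstimate:
    """Estimate one observer's illusion magnitude from one session's trials."""
    rules = rules or DEFAULT_RULES
    illusion = session["illusion"].iloc[0]
    observer_id = session["observer_id"].iloc[0]
    if illusion in STAIRCASE_ILLUSIONS:
        return _staircase_estimate(observer_id, illusion, session, rules[illusion])
    if illusion == "mips":
        return mips_magnitude(session, observer_id)
    if illusion == "fj":
        return fj_magnitude(session, observer_id)
    if illusion == "fg":
        return fg_magnitude(session, observer_id)
    raise ValueError(f"unknown illusion {illusion!r}")


def estimate_all(
    trials: pd.DataFrame, rules: dict[str, ConvergenceRule] | None = None
) -> pd.DataFrame:
    """Apply the per-illusion pipeline to a full trial table.

    Observers with two sessions get the mean of the two per-session
    magnitudes; if exactly one session survives its convergence and
    exclusion rules, that session alone is used; if neither survives,
    the magnitude is missing.
    """
    rows = []
    for (obs, illusion), g in trials.groupby(["observer_id", "illusion"], sort=True):
        per_session = [
            estimate_session(s, rules)
            for _, s in g.groupby("session", sort=True)
        ]
        ok = [e for e in per_session if not e.excluded]
        if ok:
            mag = float(np.mean([e.magnitude for e in ok]))
            excluded, reason = False, ExclusionReason.NONE
            n_used = sum(e.n_trials_used for e in ok)
        else:
            mag, excluded = np.nan, True
            reason = per_session[-1].exclusion_reason
            n_used = 0
        rows.append(
            dict(
                observer_id=obs,
                illusion=illusion,
                magnitude=mag,
                converged=all(e.converged for e in per_session),
                excluded=excluded,
                exclusion_reason=reason.value,
                n_sessions=len(per_session),
                n_sessions_used=len(ok),
                n_trials_used=n_used,
            )
        )
    return pd.DataFrame(rows)


def estimates_to_wide(estimates: pd.DataFrame) -> pd.DataFrame:
    """Observer x illusion magnitude table (columns in canonical order)."""
    wide = estimates.pivot(index="observer_id", columns="illusion", values="magnitude")
    cols = [il for il in ILLUSIONS if il in wide.columns]
    return wide[cols]


def exclusion_summary(estimates: pd.DataFrame) -> dict:
    """Tally of exclusions per illusion and reason (JSON-friendly)."""
    out: dict[str, dict[str, int]] = {}
    for il, g in estimates.groupby("illusion"):
        out[il] = {
            "n": int(len(g)),
            "n_excluded": int(g["excluded"].sum()),
            "reasons": {
                r: int((g.loc[g["excluded"], "exclusion_reason"] == r).sum())
                for r in g.loc[g["excluded"], "exclusion_reason"].unique()
            },
        }
    return out
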