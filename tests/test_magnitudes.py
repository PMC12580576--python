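"""PSE extraction, convergence/exclusion rules, and magnitude estimators.

Includes a brute-force oracle (explicit loops over the trial table) that
recomputes every PSE, convergence flag and magnitude and must agree with
the pipeline bit-for-bit.
"""

import numpy as np
import pandas as pd
import pytest

from mpiaf import cohort as ch
from mpiaf import magnitudes as mg
from mpiaf import staircases as sc
from mpiaf._seeds import substream


def _stair_frame(illusion, staircases, k_pad=0):
    """Build a session frame from {staircase_id: (direction, condition,
    presented_values, responses, final_value)}."""
    rows = []
    for sid, (direction, cond, values, responses, final) in staircases.items():
        for t, (v, r) in enumerate(zip(values, responses)):
            rows.append(
                dict(
                    observer_id="obsX", illusion=illusion, session=1,
                    staircase_id=sid, direction=direction, condition=cond,
                    start_label="", trial_index=t, presented_value=v,
                    response=r, reversal=False, step_used=np.nan,
                    final_value=final, reported_value=np.nan,
                    truth_value=np.nan, attention_check=False,
                    attention_passed=True, valid=True,
                )
            )
    return pd.DataFrame(rows)


def _const_fd_session(pse_by_staircase, finals=None):
    """FD session with constant staircases pinned at given values."""
    finals = finals or {}
    staircases = {}
    for sid, direction, v in pse_by_staircase:
        staircases[sid] = (
            direction, "", [v] * 20, [1, -1] * 10, finals.get(sid, v)
        )
    return _stair_frame("fd", staircases)


class TestPseFromTrace:
    def test_constant_tail_returns_it(self):
        assert mg.pse_from_trace(np.array([9.0] * 5 + [3.0] * 10), 10) == 3.0

    def test_arithmetic_series(self):
        assert mg.pse_from_trace(np.arange(1.0, 41.0), 10) == 35.5

    def test_final_trial_counts_per_illusion(self):
        assert mg.K_LAST == {"fle": 20, "lum_fle": 20, "fd": 20, "fe": 10, "tg": 10}

    def test_short_trace_names_deficit(self):
        with pytest.raises(ValueError, match="5"):
            mg.pse_from_trace(np.arange(15.0), 20)


class TestPolarToArc:
    @pytest.mark.parametrize(
        "polar,radius,expected",
        [(15, 12.15, 3.18), (45, 10.5, 8.25), (0, 5.0, 0.0)],
    )
    def test_printed_conversions(self, polar, radius, expected):
        assert round(mg.polar_to_arc(polar, radius), 2) == expected

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            mg.polar_to_arc(10, 0.0)


class TestIllusionMagnitude:
    def test_bias_cancels(self):
        m, b = 1.7, 0.4
        assert mg.illusion_magnitude(m + b, -m + b) == pytest.approx(m)

    def test_plain_values(self):
        assert mg.illusion_magnitude(2, -2) == 2
        assert mg.illusion_magnitude(0, 0) == 0

    def test_missing_propagates(self):
        assert np.isnan(mg.illusion_magnitude(np.nan, 1.0))


class TestConvergence:
    def test_identical_staircases_converge(self):
        session = _const_fd_session(
            [("a1", "down", 1.0), ("a2", "down", 1.0),
             ("b1", "up", -1.0), ("b2", "up", -1.0)]
        )
        assert mg.check_convergence(session, mg.DEFAULT_RULES["fd"])

    def test_threshold_is_exclusive(self):
        """A difference exactly at the printed bound still counts as converged."""
        for diff, expect in [(3.5, True), (3.51, False)]:
            session = _const_fd_session(
                [("a1", "down", 0.0), ("a2", "down", 0.0),
                 ("b1", "up", 0.0), ("b2", "up", 0.0)],
                finals={"a1": 0.0, "a2": diff, "b1": 0.0, "b2": 0.0},
            )
            assert mg.check_convergence(session, mg.DEFAULT_RULES["fd"]) is expect

    def test_fd_compares_final_values_not_pses(self):
        session = _const_fd_session(
            [("a1", "down", 10.0), ("a2", "down", 0.0),  # PSEs differ by 10
             ("b1", "up", 0.0), ("b2", "up", 0.0)],
            finals={"a1": 1.0, "a2": 1.0, "b1": 0.0, "b2": 0.0},
        )
        assert mg.check_convergence(session, mg.DEFAULT_RULES["fd"])

    def test_fle_threshold_in_arc_units(self):
        """A 3.2 dva arc split (> 3.18) between paired FLE staircases fails."""
        to_polar = lambda arc: arc / (12.15 * np.pi / 180)
        staircases = {
            "a1": ("cw", "", [to_polar(0.0)] * 40, [1, -1] * 20, 0.0),
            "a2": ("cw", "", [to_polar(3.2)] * 40, [1, -1] * 20, 0.0),
            "b1": ("ccw", "", [0.0] * 40, [1, -1] * 20, 0.0),
            "b2": ("ccw", "", [0.0] * 40, [1, -1] * 20, 0.0),
        }
        session = _stair_frame("fle", staircases)
        assert not mg.check_convergence(session, mg.DEFAULT_RULES["fle"])

    def test_tg_boundary_values(self):
        """A 1.48 dva TG split converges; 1.50 does not (threshold 1.48)."""
        for diff, expect in [(1.48, True), (1.50, False)]:
            staircases = {}
            for cond in ("dynamic", "static"):
                for d in ("l2r", "r2l"):
                    for j in (0, 1):
                        v = diff if (cond, d, j) == ("dynamic", "l2r", 1) else 0.0
                        staircases[f"{cond}_{d}_{j}"] = (
                            d, cond, [v] * 10, [1, -1] * 5, v
                        )
            session = _stair_frame("tg", staircases)
            assert mg.check_convergence(session, mg.DEFAULT_RULES["tg"]) is expect


class TestSameKeyRule:
    def _fe_session(self, response_sets):
        staircases = {
            f"s{i}": ("cw" if i < 2 else "ccw", "", [0.0] * 40, resp, 0.0)
            for i, resp in enumerate(response_sets)
        }
        return _stair_frame("fe", staircases)

    def test_single_repeating_staircase_not_excluded(self):
        mixed = [1, -1] * 20
        session = self._fe_session([[1] * 40, mixed, mixed, mixed])
        assert not mg.fe_same_key_exclusion(session)

    def test_two_staircases_at_exactly_eighty_percent_excluded(self):
        at_80 = [1] * 32 + [-1] * 8
        mixed = [1, -1] * 20
        session = self._fe_session([at_80, at_80, mixed, mixed])
        assert mg.fe_same_key_exclusion(session)

    def test_alternating_never_excluded(self):
        mixed = [1, -1] * 20
        session = self._fe_session([mixed] * 4)
        assert not mg.fe_same_key_exclusion(session)


def _adjustment_frame(illusion, rows):
    df = pd.DataFrame(rows)
    df.insert(0, "observer_id", "obsX")
    df.insert(1, "illusion", illusion)
    return df


class TestMips:
    def _trials(self, offsets, direction="pos"):
        return _adjustment_frame(
            "mips",
            [
                dict(trial_index=i, direction=direction, start_label="aligned",
                     reported_value=v, truth_value=0.0, attention_check=False,
                     attention_passed=True, valid=True)
                for i, v in enumerate(offsets)
            ],
        )

    def test_halving(self):
        est = mg.mips_magnitude(self._trials([2.0, 2.0, 2.0]))
        assert est.magnitude == pytest.approx(1.0)

    def test_outlier_dropped_then_halved(self):
        est = mg.mips_magnitude(self._trials([2.0, 2.0, 20.0]))
        assert est.magnitude == pytest.approx(1.0)
        assert est.n_trials_used == 2

    def test_boundary_offset_exactly_ten_excluded(self):
        est = mg.mips_magnitude(self._trials([10.0]))
        assert est.excluded and np.isnan(est.magnitude)


class TestFj:
    def _trials(self, effects, checks_passed=(True, True, True)):
        rows = [
            dict(trial_index=i, direction="top_grow", start_label="equal",
                 reported_value=v, truth_value=0.0, attention_check=False,
                 attention_passed=True, valid=True)
            for i, v in enumerate(effects)
        ]
        rows += [
            dict(trial_index=100 + j, direction="none", start_label="check",
                 reported_value=np.nan, truth_value=np.nan, attention_check=True,
                 attention_passed=ok, valid=True)
            for j, ok in enumerate(checks_passed)
        ]
        return _adjustment_frame("fj", rows)

    def test_all_attention_checks_failed_excludes(self):
        est = mg.fj_magnitude(self._trials([1.0] * 10, (False, False, False)))
        assert est.excluded
        assert est.exclusion_reason == mg.ExclusionReason.ATTENTION_CHECK

    def test_one_passed_check_retains(self):
        est = mg.fj_magnitude(self._trials([2.0] * 10, (False, True, False)))
        assert est.magnitude == pytest.approx(1.0)

    def test_three_sd_outlier_dropped(self):
        effects = [1.0] * 44
        rng = np.random.default_rng(0)
        effects = list(1.0 + 0.01 * rng.standard_normal(44))
        sd = np.std(effects)
        effects.append(1.0 + 10 * sd)
        est = mg.fj_magnitude(self._trials(effects))
        assert est.n_trials_used == 44

    def test_constant_effect_halved(self):
        est = mg.fj_magnitude(self._trials([2.4] * 45))
        assert est.magnitude == pytest.approx(1.2)


class TestFg:
    def _trials(self, cw_errors=(), ccw_errors=(), n_invalid=0, n_checks_failed=0):
        rows = []
        i = 0
        for d, errs in (("cw", cw_errors), ("ccw", ccw_errors)):
            sign = 1.0 if d == "cw" else -1.0
            for e in errs:
                rows.append(
                    dict(trial_index=i, direction=d, start_label="dur800",
                         reported_value=sign * e, truth_value=0.0,
                         attention_check=False, attention_passed=True, valid=True)
                )
                i += 1
        for _ in range(n_invalid):
            rows.append(
                dict(trial_index=i, direction="cw", start_label="dur800",
                     reported_value=np.nan, truth_value=0.0,
                     attention_check=False, attention_passed=True, valid=False)
            )
            i += 1
        for j in range(20):
            rows.append(
                dict(trial_index=i, direction="none", start_label="dur0",
                     reported_value=np.nan, truth_value=np.nan,
                     attention_check=True, attention_passed=j >= n_checks_failed,
                     valid=True)
            )
            i += 1
        return _adjustment_frame("fg", rows)

    def test_within_then_across_direction_average(self):
        est = mg.fg_magnitude(self._trials(cw_errors=[5.0] * 9, ccw_errors=[3.0] * 3))
        assert est.magnitude == pytest.approx(4.0)

    def test_perfect_reports_give_zero(self):
        est = mg.fg_magnitude(self._trials(cw_errors=[0.0] * 5, ccw_errors=[0.0] * 5))
        assert est.magnitude == 0.0

    def test_nineteen_invalid_responses_exclude(self):
        est = mg.fg_magnitude(
            self._trials(cw_errors=[1.0] * 80, ccw_errors=[1.0] * 81, n_invalid=19)
        )
        assert est.excluded
        assert est.exclusion_reason == mg.ExclusionReason.INVALID_RESPONSES

    def test_eighteen_invalid_responses_retained(self):
        est = mg.fg_magnitude(
            self._trials(cw_errors=[1.0] * 81, ccw_errors=[1.0] * 81, n_invalid=18)
        )
        assert not est.excluded

    def test_attention_failures_over_twenty_percent_exclude(self):
        est = mg.fg_magnitude(
            self._trials(cw_errors=[1.0] * 90, ccw_errors=[1.0] * 90,
                         n_checks_failed=5)
        )
        assert est.excluded
        assert est.exclusion_reason == mg.ExclusionReason.ATTENTION_CHECK


class TestEstimateAll:
    def _two_session_fd(self, mags, converged):
        """FD trial table with per-session pinned magnitudes."""
        frames = []
        for s, (m, ok) in enumerate(zip(mags, converged), start=1):
            finals = None if ok else {"a1": 0.0, "a2": 10.0, "b1": 0.0, "b2": 0.0}
            f = _const_fd_session(
                [("a1", "down", m), ("a2", "down", m),
                 ("b1", "up", -m), ("b2", "up", -m)],
                finals=finals,
            )
            f["session"] = s
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def test_two_converged_sessions_average(self):
        est = mg.estimate_all(self._two_session_fd([1.0, 2.0], [True, True]))
        assert est["magnitude"].iloc[0] == pytest.approx(1.5)
        assert est["n_sessions_used"].iloc[0] == 2

    def test_single_converged_session_fallback(self):
        est = mg.estimate_all(self._two_session_fd([1.0, 2.0], [False, True]))
        assert est["magnitude"].iloc[0] == pytest.approx(2.0)

    def test_no_converged_sessions_missing(self):
        est = mg.estimate_all(self._two_session_fd([1.0, 2.0], [False, False]))
        assert est["excluded"].iloc[0]
        assert np.isnan(est["magnitude"].iloc[0])
        assert est["exclusion_reason"].iloc[0] == "staircase_nonconvergence"


class TestBiasCancellation:
    def test_constant_shift_leaves_magnitude_unchanged(self, base_profile):
        rng = substream(31, "staircase")
        df = sc.run_illusion_session("fd", base_profile, rng).to_frame()
        est = mg.estimate_session(df)
        shifted = df.copy()
        shifted["presented_value"] += 0.9
        shifted["final_value"] += 0.9
        est2 = mg.estimate_session(shifted)
        assert est2.magnitude == pytest.approx(est.magnitude, abs=1e-12)


class TestMonotonicity:
    def test_larger_true_magnitude_larger_estimate(self, base_profile):
        """Doubling the latent magnitude does not reduce the mean estimate."""
        from dataclasses import replace

        means = []
        for scale in (1.0, 2.0):
            p = replace(
                base_profile,
                true_magnitude={
                    **base_profile.true_magnitude,
                    "fd": 0.4 * scale,
                },
            )
            rng = substream(32, "staircase")
            mags = []
            for _ in range(30):
                df = sc.run_illusion_session("fd", p, rng).to_frame()
                mags.append(mg.estimate_session(df).magnitude)
            means.append(np.mean(mags))
        assert means[1] >= means[0]


# ---------------------------------------------------------------------------
# Brute-force oracle equivalence


def _oracle_staircase(session, illusion):
    """Loop-based re-derivation of PSEs, convergence and magnitude."""
    rule = mg.DEFAULT_RULES[illusion]
    k = mg.K_LAST[illusion]
    per_stair = {}
    for sid in sorted(session["staircase_id"].unique()):
        g = session[session["staircase_id"] == sid].sort_values("trial_index")
        vals = list(g["presented_value"])[-k:]
        pse = float(np.mean(vals))
        final = float(g["final_value"].iloc[-1])
        if illusion in ("fle", "fe"):
            r = sc.TASK_RADIUS[illusion]
            pse = r * np.deg2rad(pse)
            final = r * np.deg2rad(final)
        cond = g["condition"].iloc[0]
        cond = "" if pd.isna(cond) else str(cond)
        per_stair[sid] = dict(
            pse=pse, final=final, direction=g["direction"].iloc[0], cond=cond
        )
    # convergence per (condition, direction) pair
    converged = True
    cells = {}
    for sid, info in per_stair.items():
        cells.setdefault((info["cond"], info["direction"]), []).append(
            info["pse"] if rule.compare_on == "staircase_pse" else info["final"]
        )
    for pair in cells.values():
        if abs(pair[0] - pair[1]) > rule.threshold:
            converged = False
    # direction PSEs and magnitude
    dir_vals = {}
    for sid in sorted(per_stair):
        info = per_stair[sid]
        dir_vals.setdefault((info["cond"], info["direction"]), []).append(info["pse"])
    dir_pse = {key: float(np.mean(v)) for key, v in dir_vals.items()}
    signs = sc.DIRECTIONS[illusion]
    pos = [d for d, s in signs.items() if s > 0][0]
    neg = [d for d, s in signs.items() if s < 0][0]
    if illusion == "tg":
        mag = (dir_pse[("dynamic", pos)] - dir_pse[("dynamic", neg)]) / 2 - (
            dir_pse[("static", pos)] - dir_pse[("static", neg)]
        ) / 2
    else:
        mag = (dir_pse[("", pos)] - dir_pse[("", neg)]) / 2
    same_key = False
    if illusion == "fe":
        n_rep = 0
        for sid in per_stair:
            g = session[session["staircase_id"] == sid]
            resp = list(g["response"])
            frac = max(resp.count(1) / len(resp), resp.count(-1) / len(resp))
            if frac >= 0.8:
                n_rep += 1
        same_key = n_rep >= 2
    excluded = (not converged) or same_key
    return mag, converged, excluded


def _oracle_adjustment(trials, illusion):
    signs = sc.DIRECTIONS[illusion]
    if illusion == "mips":
        effects = []
        for _, row in trials.iterrows():
            if row["attention_check"]:
                continue
            e = signs[row["direction"]] * row["reported_value"]
            if abs(e) < 10.0:
                effects.append(e)
        return float(np.mean(effects) / 2.0), True, False
    if illusion == "fj":
        checks = [r for _, r in trials.iterrows() if r["attention_check"]]
        if checks and not any(r["attention_passed"] for r in checks):
            return np.nan, True, True
        effects = [
            signs[r["direction"]] * r["reported_value"]
            for _, r in trials.iterrows()
            if not r["attention_check"]
        ]
        mu, sd = float(np.mean(effects)), float(np.std(effects))
        if sd > 0:
            effects = [e for e in effects if abs(e - mu) <= 3 * sd]
        return float(np.mean(effects) / 2.0), True, False
    if illusion == "fg":
        checks = [r for _, r in trials.iterrows() if r["attention_check"]]
        n_fail = sum(1 for r in checks if not r["attention_passed"])
        if checks and n_fail / len(checks) > 0.20:
            return np.nan, True, True
        targets = [r for _, r in trials.iterrows() if not r["attention_check"]]
        n_invalid = sum(1 for r in targets if not r["valid"])
        if n_invalid > 18:
            return np.nan, True, True
        by_dir = {}
        for r in targets:
            if r["valid"]:
                by_dir.setdefault(r["direction"], []).append(
                    signs[r["direction"]] * r["reported_value"]
                )
        per_dir = [float(np.mean(by_dir[d])) for d in sorted(by_dir)]
        return float(np.mean(per_dir)), True, False
    raise ValueError(illusion)


class TestOracleEquivalence:
    @pytest.mark.parametrize("illusion", ch.ILLUSIONS)
    def test_pipeline_matches_brute_force(self, illusion):
        """Loop-based recomputation agrees bit-for-bit on random sessions."""
        profiles = ch.make_cohort(
            ch.CohortSpec(
                n_observers=4, seed=41,
                attention_fail_rate=0.4, invalid_response_rate=0.12,
            )
        )
        for i, p in enumerate(profiles):
            rng = substream(42, "staircase", i)
            df = sc.run_illusion_session(illusion, p, rng).to_frame()
            est = mg.estimate_session(df)
            if illusion in sc.STAIRCASE_ILLUSIONS:
                mag, converged, excluded = _oracle_staircase(df, illusion)
                assert est.converged == converged
            else:
                mag, _, excluded = _oracle_adjustment(df, illusion)
            assert est.excluded == excluded
            if excluded:
                assert np.isnan(est.magnitude)
            else:
                assert est.magnitude == mag  # bit-exact
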