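"""Synthetic behavioral sessions for the probabilistic visual-search task.

Generates trial tables and millisecond gaze traces with the statistical
structure the analysis pipeline assumes, with recorded ground truth for
parameter-recovery tests:

* five interleaved environments with reward-target probabilities
  0/25/50/75/100%, ~25% single-fractal trials, a 5-s search limit with a
  0.75-s terminal fixation and 1-2 s inter-trial intervals;
* total search durations drawn from a truncated log-normal with a negative
  target-value effect and a positive environment-probability effect on the
  log scale, the condition effects loading on the environmental-fractal gaze
  component;
* a direct-saccade probability that decreases with environment probability
  on no-reward trials;
* search errors that hit the 5-s cap, repeated on the next trial.

The generator is schematic where realism does not matter for the analyses:
saccades have stereotyped kinematics (smooth-step trajectories chosen to
exceed the detection threshold) and fixational jitter is a small AR(1)
process, sufficient for dwell and saccade recovery but not a model of ocular
physiology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gaze_processing import TaskGeometry

__all__ = ["GeneratorParams", "GroundTruth", "generate_session",
           "generate_gaze_trace"]

#: A blank-screen location used for "other" gaze, at least one window radius
#: away from every object center.
_BLANK_SPOT = (0.0, -10.0)


@dataclass(frozen=True)
class GeneratorParams:
    """Tunable parameters of the synthetic-session generator.

    Duration effects are on the log scale (log seconds); probabilities are
    clipped to [0, 1] after the linear predictors are evaluated.
    """

    n_trials: int = 2000
    single_fraction: float = 0.25
    env_probs: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    # search-duration model: log T = baseline + value_effect * reward
    #   + prob_effect * p(reward) + single_offset * is_single + sigma * eps
    log_baseline: float = math.log(0.8)
    target_value_effect: float = -0.65
    env_prob_effect: float = 0.5
    single_log_offset: float = -0.8
    sigma_log: float = 0.45
    # baseline mean seconds of the non-environmental gaze components;
    # the environmental component takes the condition-driven remainder
    comp_start_s: float = 0.12
    comp_target_s: float = 0.10
    comp_other_s: float = 0.18
    comp_jitter_sigma: float = 0.3
    # direct-saccade probability (search trials)
    direct_intercept: float = 0.75
    direct_value_bonus: float = 0.1
    direct_noreward_env_slope: float = -0.4
    # search-error probability
    err_base: float = 0.02
    err_noreward_extra: float = 0.08
    # task timing (seconds)
    max_search_s: float = 5.0
    fix_hold_s: float = 0.75
    outcome_delay_s: float = 0.5
    iti_range: tuple[float, float] = (1.0, 2.0)
    pretrial_s: float = 1.5
    # gaze synthesis
    gaze_noise_sd: float = 0.15
    saccade_ms: int = 25
    blink_prob: float = 0.02

    def __post_init__(self):
        if not all(0.0 <= p <= 1.0 for p in self.env_probs):
            raise ValueError("env_probs must lie in [0, 1]")
        if not 0.0 <= self.single_fraction <= 1.0:
            raise ValueError("single_fraction must lie in [0, 1]")
        if self.max_search_s <= 0 or self.sigma_log < 0:
            raise ValueError("max_search_s must be > 0 and sigma_log >= 0")

    def replace(self, **changes) -> "GeneratorParams":
        return replace(self, **changes)

    def null(self) -> "GeneratorParams":
        """A null copy: no condition effects on any behavioral measure."""
        return self.replace(target_value_effect=0.0, env_prob_effect=0.0,
                            direct_value_bonus=0.0,
                            direct_noreward_env_slope=0.0,
                            err_noreward_extra=0.0)


@dataclass
class GroundTruth:
    """Injected parameters plus per-trial latent assignments."""

    params: GeneratorParams
    per_trial: pd.DataFrame  # true components, direct/error flags, plan info

    def expected_rrr(self) -> float:
        """Closed-form expectation of the reward-rate ratio.

        Mirrors the pipeline estimator on the generator's stationary trial
        distribution: error trials are repeated until correct, so each
        condition's presentation frequency is inflated by its expected
        attempt count ``1 / (1 - p_error)``. The 5-s truncation of correct
        durations is negligible at default parameters.
        """
        p = self.params
        iti = 0.5 * (p.iti_range[0] + p.iti_range[1])
        nonsearch = p.fix_hold_s + p.outcome_delay_s + iti
        cells = []
        for prob in p.env_probs:
            for v in (0, 1):
                w = (prob if v else 1.0 - prob) / len(p.env_probs)
                if w == 0:
                    continue
                pe0 = min(1.0, max(0.0, p.err_base
                                   + p.err_noreward_extra * (1 - v)))
                w = w / (1.0 - pe0)
                mu = (p.log_baseline + p.target_value_effect * v
                      + p.env_prob_effect * prob)
                mean_dur = math.exp(mu + 0.5 * p.sigma_log ** 2)
                p_err = min(1.0, max(0.0, p.err_base
                                     + p.err_noreward_extra * (1 - v)))
                cells.append((w, v, mean_dur, p_err))

        def rate(substitute: bool) -> float:
            # correct-trial mix is the actual one in both rates; the
            # counterfactual substitutes only the no-reward trials' mean
            # correct search duration and the error-per-correct ratio
            wc1 = sum(w * (1 - pe) for w, v, _, pe in cells if v == 1)
            mean_dur_1 = sum(w * (1 - pe) * d
                             for w, v, d, pe in cells if v == 1) / wc1
            err_1 = sum(w * pe for w, v, _, pe in cells if v == 1) / wc1
            p_corr = rew = t_corr = p_err_tot = 0.0
            for w, v, d, pe in cells:
                if substitute and v == 0:
                    d = mean_dur_1
                p_corr += w * (1 - pe)
                rew += w * (1 - pe) * v
                t_corr += w * (1 - pe) * (d + nonsearch)
                p_err_tot += w * pe
            e_rew = rew / p_corr
            e_t_corr = t_corr / p_corr
            err_per_corr = err_1 if substitute else p_err_tot / p_corr
            t_err = p.max_search_s + iti
            return e_rew / (e_t_corr + err_per_corr * t_err)

        return rate(False) / rate(True)


def _components(params, rng, total, direct, error):
    """Split one trial's search duration into gaze components (seconds)."""
    jit = rng.lognormal(mean=0.0, sigma=params.comp_jitter_sigma, size=3)
    d_start = params.comp_start_s * jit[0]
    d_target = params.comp_target_s * jit[1]
    d_other = params.comp_other_s * jit[2]
    if error:
        d_target = 0.0  # never acquired the target
    if direct:
        # straight to the target: no environmental fixations, surplus time
        # sits on the target (or wanders for error trials)
        d_env = 0.0
        base = d_start + d_target + d_other
        if base > total:
            scale = total / base
            d_start, d_target, d_other = (d_start * scale, d_target * scale,
                                          d_other * scale)
        elif error:
            d_other += total - base
        else:
            d_target += total - base
    else:
        base = d_start + d_target + d_other
        cap = 0.8 * total
        if base > cap:
            scale = cap / base
            d_start, d_target, d_other = (d_start * scale, d_target * scale,
                                          d_other * scale)
            base = cap
        d_env = total - base
    return d_start, d_env, d_target, d_other


def generate_session(
    params: GeneratorParams, seed, include_gaze: bool = True,
    session: str = "synthetic",
) -> tuple[pd.DataFrame, pd.DataFrame | None, GroundTruth]:
    """Generate one behavioral session.

    Returns ``(trial_table, gaze_table, ground_truth)``; ``gaze_table`` is
    None when ``include_gaze`` is False (trial-level analyses do not need
    traces, and skipping them makes large simulation studies cheap).
    Search-error trials are followed by a repeat of the same condition.
    """
    rng = np.random.default_rng(seed)
    geometry = TaskGeometry() if include_gaze else None
    n = params.n_trials
    trials = []
    latents = []
    gaze_frames = []
    t_cursor = 0.0
    repeat = None  # condition carried over after an error
    for i in range(n):
        if repeat is not None:
            task, env_i, value, loc = repeat
            is_repeat = True
        else:
            task = "single" if rng.random() < params.single_fraction \
                else "search"
            env_i = int(rng.integers(len(params.env_probs)))
            value = int(rng.random() < params.env_probs[env_i])
            loc = int(rng.integers(4))
            is_repeat = False
        prob = params.env_probs[env_i]

        mu = (params.log_baseline + params.target_value_effect * value
              + params.env_prob_effect * prob
              + (params.single_log_offset if task == "single" else 0.0))
        dur = float(np.exp(mu + params.sigma_log * rng.standard_normal()))
        p_err = min(1.0, max(0.0, params.err_base
                             + params.err_noreward_extra * (1 - value)))
        error = rng.random() < p_err
        if error:
            dur = params.max_search_s
        else:
            dur = min(dur, params.max_search_s - 0.05)

        if task == "single":
            direct = True
        else:
            p_direct = (params.direct_intercept
                        + params.direct_value_bonus * value
                        + params.direct_noreward_env_slope
                        * prob * (1 - value))
            direct = rng.random() < min(1.0, max(0.0, p_direct))
        d_start, d_env, d_target, d_other = _components(
            params, rng, dur, direct or task == "single", error)
        n_env_fix = (int(np.clip(d_env * 1000.0 // 150, 1, 6))
                     if (not direct and task == "search" and d_env > 0.001)
                     else 0)

        iti = float(rng.uniform(*params.iti_range))
        if error:
            post = params.max_search_s + iti
        else:
            post = dur + params.fix_hold_s + params.outcome_delay_s + iti
        search_start = t_cursor * 1000.0
        search_end = search_start + dur * 1000.0

        trials.append({
            "session": session, "trial_id": i, "task": task,
            "env": env_i + 1, "reward_probability": prob,
            "target_value": value, "target_location": loc,
            "search_start_ms": search_start, "search_end_ms": search_end,
            "outcome": "search_error" if error else "correct",
            "repeat_flag": int(is_repeat),
            "search_dur_s": dur,
            "post_array_s": post,
            "rewarded": int(value and not error),
            "novel_fractal_location": np.nan,
        })
        latents.append({
            "trial_id": i, "direct": bool(direct), "error": bool(error),
            "comp_start_s": d_start, "comp_environmental_s": d_env,
            "comp_target_s": d_target, "comp_other_s": d_other,
            "iti_s": iti, "n_env_fixations": n_env_fix,
        })
        if include_gaze and task == "search":
            plan = _fixation_plan(params, geometry, rng, loc, n_env_fix,
                                  error, d_start, d_env, d_target, d_other,
                                  dur)
            trace = generate_gaze_trace(plan, params, rng,
                                        t_offset_ms=search_start)
            trace.insert(0, "trial_id", i)
            gaze_frames.append(trace)
        t_cursor += post + params.pretrial_s
        repeat = (task, env_i, value, loc) if error else None

    trial_table = pd.DataFrame(trials)
    gaze_table = (pd.concat(gaze_frames, ignore_index=True)
                  if gaze_frames else None)
    truth = GroundTruth(params, pd.DataFrame(latents))
    return trial_table, gaze_table, truth


def _fixation_plan(params, geometry, rng, loc, n_env_fix, error,
                   d_start, d_env, d_target, d_other, total_s):
    """Fixation sequence (x, y, dwell_ms, label) realizing the components."""
    plan = [(0.0, 0.0, max(d_start, 0.03) * 1000.0, "start")]
    if d_other > 0.02:
        plan.append((*_BLANK_SPOT, d_other * 1000.0, "other"))
    if n_env_fix > 0:
        k = n_env_fix
        idx = rng.choice(12, size=k, replace=False)
        # half equal split, half Dirichlet: dwell variability without
        # starving any fixation below the 50-ms inspection criterion
        share = (0.5 / k + 0.5 * rng.dirichlet(np.full(k, 4.0))) \
            * d_env * 1000.0
        for j, fi in enumerate(idx):
            pos = geometry.environmental_positions[fi]
            plan.append((float(pos[0]), float(pos[1]),
                         float(share[j]), "environmental"))
    if not error and d_target > 0.001:
        tgt = geometry.target_positions[loc]
        plan.append((float(tgt[0]), float(tgt[1]),
                     d_target * 1000.0, "target"))
    # rescale dwells so dwell + saccade-transit time fills the search period
    n_sacc = len(plan) - 1
    budget = total_s * 1000.0 - n_sacc * params.saccade_ms
    dwell_sum = sum(p[2] for p in plan)
    if budget <= 0 or dwell_sum <= 0:
        return [(0.0, 0.0, max(total_s, 0.001) * 1000.0, "start")]
    scale = budget / dwell_sum
    return [(x, y, d * scale, lab) for x, y, d, lab in plan]


def generate_gaze_trace(
    plan, params: GeneratorParams, seed, t_offset_ms: float = 0.0
) -> pd.DataFrame:
    """Render a fixation plan as a 1-ms gaze trace.

    Fixations are stationary AR(1) jitter around each planned center (one
    per-fixation offset plus a slow wander far below the saccade-detection
    threshold after smoothing); transitions are smooth-step saccades of
    ``saccade_ms`` duration whose peak velocity exceeds the detection
    threshold for amplitudes above ~0.5 deg.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    xs, ys = [], []
    rho = 0.97
    sd = params.gaze_noise_sd

    def fixate(cx, cy, dwell_ms):
        m = max(int(round(dwell_ms)), 2)
        off = rng.normal(0.0, sd, size=2)
        steps = rng.normal(0.0, sd * math.sqrt(1 - rho * rho), size=(m, 2))
        wander = np.empty((m, 2))
        acc = rng.normal(0.0, sd, size=2) * 0.3
        for j in range(m):
            acc = rho * acc + steps[j]
            wander[j] = acc
        xs.append(cx + off[0] * 0.3 + wander[:, 0] * 0.3)
        ys.append(cy + off[1] * 0.3 + wander[:, 1] * 0.3)

    for j, (cx, cy, dwell, _lab) in enumerate(plan):
        if j > 0:
            px, py = plan[j - 1][0], plan[j - 1][1]
            u = np.arange(1, params.saccade_ms + 1) / params.saccade_ms
            h = 3 * u ** 2 - 2 * u ** 3  # smooth-step position profile
            xs.append(px + (cx - px) * h)
            ys.append(py + (cy - py) * h)
        fixate(cx, cy, dwell)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    t = np.arange(len(x), dtype=float) + t_offset_ms
    valid = np.ones(len(x), dtype=bool)
    if rng.random() < params.blink_prob and len(x) > 300:
        b0 = int(rng.integers(50, len(x) - 150))
        valid[b0:b0 + int(rng.integers(60, 120))] = False
    return pd.DataFrame({"t_ms": t, "x_deg": x, "y_deg": y, "valid": valid})
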