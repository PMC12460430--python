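"""Synthetic cohort generator with known ground truth.

Emulates the data shape of a mouse-tracked two-alternative forced-choice
study: participants with individual diffusion-model parameters (drawn from a
truncated trivariate normal), per-trial choices and RTs simulated from the
model, and cursor trajectories whose kinematics are coupled to the decision
process.  The motor model is this module's own construction — a generative
trajectory model chosen so that the qualitative couplings reported for real
cursor data hold and are individually switchable:

* lateral (x) velocity tracks the scaled evidence before the decision, plus
  smoothed noise and a slow idiosyncratic wobble — slow/noisy accumulation
  (low drift rate) yields a more complex x trace (raises sampleEnX);
* after the decision a ballistic launch to the chosen box follows, with a
  single velocity peak shortly after the decision: the peak comes later for
  longer decisions (threshold separation) and for larger non-decision times,
  and is lower for larger non-decision times (slower motor execution);
* post-decision motor jitter scales with non-decision time, planting the
  acceleration-sign-change coupling.

Trajectories are sampled at ~107 Hz; RT equals decision time + t0 and trials
exceeding the 2-s stimulus-phase limit are redrawn, mirroring the task's
time-out-and-restart rule.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import signal

from . import _wfpt
from .ddm import DDMParams, simulate
from .trajectories import Trajectory, TrialRecord, TrialSet

__all__ = ["MotorParams", "CohortConfig", "GroundTruth", "generate_cohort",
           "trajectory_from_decision", "write_cohort"]


@dataclass(frozen=True)
class MotorParams:
    """Tunables of the generative motor model (px, s, Hz units).

    The ``couple_*`` gains switch each planted cursor-DDM coupling off when
    set to 0, which the ablation tests use.
    """

    # vertical progress toward the response boxes: the travel distance is
    # fixed by the screen geometry, so the average pace scales inversely
    # with the trial duration (hover-response: arrive when deciding)
    y_distance: float = 800.0         # px vertical distance to the boxes
    y_distance_sd_log: float = 0.03   # participant reach/posture spread
    y_trial_jitter_sd_log: float = 0.08  # per-trial pace jitter
    y_pace_mod: float = 0.03          # slow sinusoidal pace modulation

    # pre-decision lateral movement
    evidence_gain: float = 70.0      # px/s at full scaled evidence
    evidence_gain_sd_log: float = 0.35
    track_tau: float = 0.6            # s, leaky integration of momentary
                                      # evidence the hand follows
    evidence_sat: float = 1.2         # tanh sharpness on the tracked signal
    lateral_noise_sd: float = 500.0   # px/s conflict jitter before smoothing
    noise_evidence_mod: float = 0.9   # share of noise amplitude gated off
                                      # once the tracked evidence commits
    undecided_gate: float = 0.5       # |tracked evidence| (SD units) below
                                      # which the conflict jitter is on
    conflict_v_gain: float = 0.6     # how strongly a participant's overall
                                      # difficulty (low drift) amplifies the
                                      # conflict jitter
    conflict_sd_log: float = 0.15     # idiosyncratic jitter-amplitude spread
    smooth_tau: float = 0.03          # s, arm-inertia low-pass
    wobble_amp: float = 150.0          # px/s slow idiosyncratic oscillation
    wobble_amp_sd_log: float = 0.5
    lateral_bias_sd: float = 80.0     # px/s participant-constant drift bias
    wobble_freq: Tuple[float, float] = (0.3, 1.2)  # Hz, per-trial uniform

    # post-decision ballistic segment
    encode_frac: float = 0.45          # share of t0 spent before evidence onset
    encode_frac_sd_log: float = 0.2  # participant spread (clipped 0.2-0.7)
    peak_frac: float = 0.7            # where in the movement the speed peaks
    peak_frac_sd_log: float = 0.25    # participant spread (clipped 0.25-0.8)
    beta_profile_b: float = 3.8       # right shape of the velocity profile
    move_time_sd_log: float = 0.1   # participant movement-duration style
    peak_speed_pow: float = 1.5       # launch-peak sensitivity to t0
    box_distance: float = 200.0       # px lateral distance to the box
    box_distance_jitter: float = 15.0  # per-trial px jitter
    hover_jitter_sd: float = 25.0     # px/s residual tremor while hovering

    # abortive early launches (changes of mind) decouple the velocity peak
    # from the final movement in a participant-specific way
    false_launch_prob: float = 0.15
    false_launch_prob_sd_log: float = 0.6
    false_launch_speed: float = 0.75  # relative to the trial's launch peak
    false_launch_speed_sd_log: float = 0.25
    false_launch_dur: float = 0.12    # s, out-and-back bump duration

    # post-decision speed jitter -> acceleration sign changes
    spike_prob: float = 0.35          # per-sample jitter probability
    spike_prob_sd_log: float = 0.6
    spike_amp: float = 0.06           # multiplicative speed jitter size

    # motor pauses (frozen cursor) before the decision
    pause_prob: float = 0.015
    pause_prob_sd_log: float = 0.7

    # coupling switches (1 = on, 0 = off)
    couple_evidence: float = 1.0      # evidence -> lateral wander (sampleEnX)
    couple_peak_time: float = 1.0     # decision/non-decision time -> peak lag
    couple_peak_speed: float = 1.0    # t0 -> peak velocity magnitude
    couple_jitter: float = 1.0        # t0 -> post-decision jitter amount


@dataclass(frozen=True)
class CohortConfig:
    """Study-scale defaults: 103 participants x 90 trials, 107 Hz, 2-s cap."""

    n_participants: int = 103
    n_trials: int = 90
    param_mean: Tuple[float, float, float] = (0.7, 2.0, 0.45)  # v, a, t0
    param_sd: Tuple[float, float, float] = (0.35, 0.25, 0.19)
    param_corr: Tuple[float, float, float] = (0.0, 0.0, 0.0)  # (va, vt0, at0)
    param_lo: Tuple[float, float, float] = (0.05, 0.8, 0.15)
    param_hi: Tuple[float, float, float] = (2.5, 3.5, 0.95)
    sampling_rate: float = 107.0
    rt_cap: float = 2.0
    ddm_dt: float = 1e-3
    motor: MotorParams = field(default_factory=MotorParams)

    def cov_matrix(self) -> np.ndarray:
        sd = np.asarray(self.param_sd)
        c_va, c_vt, c_at = self.param_corr
        corr = np.array([[1.0, c_va, c_vt], [c_va, 1.0, c_at], [c_vt, c_at, 1.0]])
        cov = corr * np.outer(sd, sd)
        if np.any(np.linalg.eigvalsh(cov) < -1e-12):
            raise ValueError("parameter covariance not positive semi-definite")
        return cov


@dataclass
class GroundTruth:
    """True participant parameters and per-trial decision variables.

    Regenerable bit-exactly from (CohortConfig, seed); evidence paths are not
    stored for that reason (re-simulate to obtain them).
    """

    participants: pd.DataFrame  # participant, v, a, t0 + motor latents
    trials: pd.DataFrame        # participant, trial, decision_time, choice, rt
    config: CohortConfig
    seed: int
    acceptance_rate: float      # of the truncated-normal rejection sampler


def _draw_participant_params(config: CohortConfig, rng: np.random.Generator
                             ) -> Tuple[np.ndarray, float]:
    mean = np.asarray(config.param_mean)
    cov = config.cov_matrix()
    lo = np.asarray(config.param_lo)
    hi = np.asarray(config.param_hi)
    need = config.n_participants
    out = np.empty((need, 3))
    filled = 0
    drawn = 0
    while filled < need:
        batch = rng.multivariate_normal(mean, cov, size=max(64, need))
        drawn += batch.shape[0]
        ok = np.all((batch >= lo) & (batch <= hi), axis=1)
        take = batch[ok][: need - filled]
        out[filled:filled + take.shape[0]] = take
        filled += take.shape[0]
        if drawn > 100 * need and filled / drawn < 0.01:
            raise ValueError(
                "truncated-normal acceptance below 1%: infeasible bounds"
            )
    return out, filled / drawn


def trajectory_from_decision(
    evidence: np.ndarray,
    decision_time: float,
    choice: bool,
    stimulus_dir: float,
    params: DDMParams,
    latents: Dict[str, float],
    motor: MotorParams,
    rng: np.random.Generator,
    sampling_rate: float = 107.0,
    ddm_dt: float = 1e-3,
    start_xy: Tuple[float, float] = (0.0, 0.0),
) -> Trajectory:
    """Render one trial's cursor path from its decision-process variables.

    ``evidence`` is the accumulator path on the simulator's time grid (from
    evidence onset); ``stimulus_dir`` is the screen direction (+1/-1) of the
    correct box; ``latents`` carries the participant's motor idiosyncrasies
    (keys y_speed, gain, wobble, move_fac, encode_frac, peak_frac, launch_p,
    launch_k, spike_p, pause_p; see :func:`_participant_latents`).
    """
    if decision_time <= 0:
        raise ValueError("decision time must be > 0")
    a, t0 = params.a, params.t0
    fs = sampling_rate
    delta = 1.0 / fs
    t_enc = latents["encode_frac"] * t0
    t_ball = (1.0 - latents["encode_frac"]) * t0
    rt = decision_time + t0
    n_samp = int(math.floor(rt * fs)) + 1
    t = np.arange(n_samp) * delta

    resp_dir = stimulus_dir if choice else -stimulus_dir
    dec_at = t_enc + decision_time

    pre = t < dec_at
    n_pre = int(pre.sum())

    # --- lateral command before the decision: the hand tracks a leaky
    # integral of the momentary evidence (recent percepts, not the total)
    vx = np.zeros(n_samp)
    tracked = np.zeros(n_pre)
    in_evidence = t[:n_pre] >= t_enc
    if np.any(in_evidence):
        idx = np.clip(((t[:n_pre][in_evidence] - t_enc) / ddm_dt).astype(int),
                      0, evidence.size - 1)
        ev = evidence[idx]
        ev = np.where(np.isnan(ev), a if choice else 0.0, ev)
        de_rate = np.diff(ev, prepend=ev[0] if ev.size else 0.0) / delta
        lam = math.exp(-delta / motor.track_tau)
        # stationary SD of the leaky integral of unit-diffusion increments;
        # start at the stationary law so short trials are not dominated by
        # the spin-up transient
        sd_leak = math.sqrt((1.0 - lam) / (1.0 + lam) / delta)
        accum0 = rng.normal(params.v, sd_leak)
        leak, _ = signal.lfilter(
            [1.0 - lam], [1.0, -lam], de_rate,
            zi=np.array([lam * accum0]),
        )
        tracked[in_evidence] = leak / sd_leak
    freq = rng.uniform(*motor.wobble_freq)
    phase = rng.uniform(0, 2 * np.pi)
    # response conflict: the hand jitters while the tracked evidence is
    # undecided (within the gate) and settles once it commits
    mod = motor.noise_evidence_mod
    if motor.couple_evidence:
        undecided = np.abs(tracked) < motor.undecided_gate
        noise_amp = (motor.lateral_noise_sd * latents["conflict"]
                     * ((1.0 - mod) + mod * undecided))
    else:
        noise_amp = motor.lateral_noise_sd * np.ones(n_pre)
    raw = (
        motor.couple_evidence * latents["gain"] * stimulus_dir
        * np.tanh(motor.evidence_sat * tracked)
        + noise_amp * rng.standard_normal(n_pre)
        + latents["bias"]
        + latents["wobble"] * np.sin(2 * np.pi * freq * t[:n_pre] + phase)
    )
    # arm inertia: exponential smoothing of the commanded lateral velocity
    alpha = delta / (motor.smooth_tau + delta)
    vx[:n_pre], _ = signal.lfilter(
        [alpha], [1.0, -(1.0 - alpha)], raw, zi=np.array([0.0])
    )

    # --- ballistic launch to the chosen box: a single-peaked (beta-shaped)
    # lateral velocity pulse whose duration scales with the non-decision
    # time (couple_peak_time) and whose height therefore falls with it
    # (couple_peak_speed); the peak sits at the participant's peak_frac
    move_fac = latents["move_fac"]
    t_move = (t_ball if motor.couple_peak_time else 0.27) * move_fac
    dist = motor.box_distance + rng.normal(0, motor.box_distance_jitter)
    post = ~pre
    t_move = max(t_move, 2 * delta)
    tau = (t[post] - dec_at) / t_move
    pf = latents["peak_frac"]
    be = motor.beta_profile_b
    al = (1.0 + pf * (be - 2.0)) / (1.0 - pf)  # beta mode at peak_frac
    # a hurried launch (small t0) is a sharper pulse, not a longer path:
    # the displacement stays the box distance while the peak rises
    if motor.couple_peak_speed:
        sharp = (0.27 / max(t_ball, 0.05)) ** (motor.peak_speed_pow - 1.0)
    else:
        sharp = 1.0
    sharp *= latents["vigor"]  # habitual punchiness of the launch
    al = 1.0 + sharp * (al - 1.0)
    be = 1.0 + sharp * (be - 1.0)
    log_norm = (math.lgamma(al) + math.lgamma(be) - math.lgamma(al + be))
    with np.errstate(divide="ignore"):
        log_prof = np.where(
            (tau > 0) & (tau < 1),
            (al - 1.0) * np.log(np.clip(tau, 1e-12, 1))
            + (be - 1.0) * np.log(np.clip(1 - tau, 1e-12, 1))
            - log_norm,
            -np.inf,
        )
    profile = np.exp(log_prof)
    vx[post] = resp_dir * dist * profile / t_move
    mode = (al - 1.0) / (al + be - 2.0)
    launch_peak = dist * math.exp(
        (al - 1.0) * math.log(max(mode, 1e-9))
        + (be - 1.0) * math.log(max(1 - mode, 1e-9)) - log_norm
    ) / t_move
    # reference peak of a typical (t_ball = 0.27 s) launch for this
    # participant: false-launch speed scales with habit, not with the
    # current trial's urgency
    t_move_ref = 0.27 * move_fac
    al0 = (1.0 + pf * (motor.beta_profile_b - 2.0)) / (1.0 - pf)
    mode0 = (al0 - 1.0) / (al0 + motor.beta_profile_b - 2.0)
    norm0 = (math.lgamma(al0) + math.lgamma(motor.beta_profile_b)
             - math.lgamma(al0 + motor.beta_profile_b))
    launch_peak_ref = motor.box_distance * math.exp(
        (al0 - 1.0) * math.log(max(mode0, 1e-9))
        + (motor.beta_profile_b - 1.0) * math.log(max(1 - mode0, 1e-9)) - norm0
    ) / t_move_ref
    hover = post.copy()
    hover[post] = tau >= 1.0

    # --- vertical progress; before the decision the hand keeps its overall
    # speed smooth (continuous-movement instruction), so lateral jitter
    # bends the path rather than modulating speed; stops once hovering
    # the preferred pace spreads the fixed vertical travel over the trial
    # and drifts smoothly (no white component: acceleration sign changes
    # should reflect jitter events, not numerical noise)
    f_pace = rng.uniform(0.3, 0.8)
    ph_pace = rng.uniform(0, 2 * np.pi)
    base_pace = (latents["y_dist"] / rt) * math.exp(
        rng.normal(0, motor.y_trial_jitter_sd_log)
    )
    v_target = base_pace * (
        1.0 + motor.y_pace_mod * np.sin(2 * np.pi * f_pace * t + ph_pace)
    )
    vy = v_target.copy()
    cap = 0.97 * v_target[:n_pre]
    vx[:n_pre] = cap * np.tanh(vx[:n_pre] / cap)
    vy[:n_pre] = np.sqrt(v_target[:n_pre] ** 2 - vx[:n_pre] ** 2)
    # after arriving, the cursor keeps its pace circling inside the box
    # (hover response with the continuous-movement instruction)
    n_hover = int(hover.sum())
    if n_hover:
        theta = (2 * np.pi * 2.5) * np.arange(n_hover) / fs + rng.uniform(0, 2 * np.pi)
        vx[hover] = v_target[hover] * np.sin(theta)
        vy[hover] = v_target[hover] * np.cos(theta)

    # --- abortive early launch: an out-and-back velocity spike during the
    # deliberation whose speed is a participant-specific fraction of the
    # final launch peak (may exceed it and claim the velocity maximum);
    # added after the pace compensation — a genuine speed burst
    if n_pre > 10 and rng.random() < latents["launch_p"]:
        t_f = rng.uniform(0.15, 0.7) * dec_at
        kappa = latents["launch_k"] * math.exp(
            rng.normal(0, motor.false_launch_speed_sd_log)
        )
        k0 = int(t_f / delta)
        k1 = min(n_pre, k0 + max(3, int(motor.false_launch_dur / delta)))
        span = np.arange(k1 - k0)
        bump = kappa * launch_peak_ref * np.sin(2 * np.pi * span / max(k1 - k0, 1))
        vx[k0:k1] += bump * (1.0 if rng.random() < 0.5 else -1.0)

    # --- post-decision speed jitter (acceleration sign changes)
    if motor.couple_jitter:
        spikes = rng.random(n_samp) < latents["spike_p"]
        spikes[:n_pre] = False
        spikes[hover] = False
        fac = 1.0 + motor.spike_amp * rng.standard_normal(n_samp)
        vx[spikes] *= fac[spikes]
        vy[spikes] *= fac[spikes]

    # --- motor pauses: frozen cursor samples before the decision
    paused = rng.random(n_samp) < latents["pause_p"]
    paused[~pre] = False
    vx[paused] = 0.0
    vy[paused] = 0.0

    dx = vx * delta
    dy = vy * delta
    dx[0] = 0.0
    dy[0] = 0.0
    x = start_xy[0] + np.cumsum(dx)
    y = start_xy[1] + np.cumsum(dy)
    return Trajectory(t=t, x=x, y=y)


def _participant_latents(motor: MotorParams, rng: np.random.Generator,
                         v: float, t0: float, v_mean: float, v_sd: float,
                         t0_mean: float, t0_sd: float) -> Dict[str, float]:
    z_t0 = (t0 - t0_mean) / t0_sd
    z_v = (v - v_mean) / v_sd
    return {
        "conflict": math.exp(
            -(motor.conflict_v_gain if motor.couple_evidence else 0.0) * z_v
            + rng.normal(0, motor.conflict_sd_log)
        ),
        "y_dist": motor.y_distance * math.exp(rng.normal(0, motor.y_distance_sd_log)),
        "gain": motor.evidence_gain * math.exp(rng.normal(0, motor.evidence_gain_sd_log)),
        "wobble": motor.wobble_amp * math.exp(rng.normal(0, motor.wobble_amp_sd_log)),
        "bias": rng.normal(0.0, motor.lateral_bias_sd),
        "move_fac": math.exp(rng.normal(0, motor.move_time_sd_log)),
        "vigor": math.exp(rng.normal(0, 0.35)),
        "encode_frac": float(np.clip(
            motor.encode_frac * math.exp(rng.normal(0, motor.encode_frac_sd_log)),
            0.15, 0.75,
        )),
        "peak_frac": float(np.clip(
            motor.peak_frac * math.exp(rng.normal(0, motor.peak_frac_sd_log)),
            0.2, 0.9,
        )),
        "launch_p": min(0.9, motor.false_launch_prob
                        * math.exp(rng.normal(0, motor.false_launch_prob_sd_log))),
        "launch_k": motor.false_launch_speed * math.exp(rng.normal(0, 0.25)),
        "spike_p": min(
            0.9,
            motor.spike_prob
            * math.exp(rng.normal(0, motor.spike_prob_sd_log))
            * (math.exp(0.1 * z_t0) if motor.couple_jitter else 1.0),
        ),
        "pause_p": motor.pause_prob * math.exp(rng.normal(0, motor.pause_prob_sd_log)),
    }


def generate_cohort(config: CohortConfig = CohortConfig(), seed: int = 0
                    ) -> Tuple[TrialSet, GroundTruth]:
    """Simulate a full cohort: parameters, choices/RTs, cursor trajectories."""
    rng = np.random.default_rng(seed)
    params_mat, acc_rate = _draw_participant_params(config, rng)
    t0_mean, t0_sd = config.param_mean[2], config.param_sd[2]
    motor = config.motor
    fs = config.sampling_rate

    trials: Dict[str, List[TrialRecord]] = {}
    p_rows, t_rows = [], []
    n = config.n_trials
    for i in range(config.n_participants):
        pid = f"p{i + 1:03d}"
        v, a, t0 = params_mat[i]
        params = DDMParams(v=float(v), a=float(a), t0=float(t0))
        lat = _participant_latents(motor, rng, float(v), float(t0),
                                   config.param_mean[0], config.param_sd[0],
                                   t0_mean, t0_sd)
        p_rows.append({"participant": pid, "v": v, "a": a, "t0": t0, **lat})

        # simulate trials, redrawing those beyond the stimulus-phase limit
        rts = np.empty(n)
        choices = np.empty(n, dtype=bool)
        paths = []
        filled = 0
        n_steps = int(math.ceil((config.rt_cap + 0.5) / config.ddm_dt))
        for _ in range(60):
            if filled >= n:
                break
            ch, dtm, pth = _wfpt.simulate_paths(
                params.v, params.a, params.zr, n, config.ddm_dt, n_steps,
                int(rng.integers(2**31)),
            )
            sim_rt = dtm + params.t0
            ok = np.flatnonzero(sim_rt <= config.rt_cap)
            take = ok[: n - filled]
            rts[filled:filled + take.size] = sim_rt[take]
            choices[filled:filled + take.size] = ch[take]
            for j in take:
                paths.append(pth[j])
            filled += take.size
        if filled < n:
            raise ValueError(
                f"participant {pid}: cannot draw {n} trials under the "
                f"{config.rt_cap}-s cap (params v={v:.2f}, a={a:.2f}, t0={t0:.2f})"
            )

        sides = np.array(["left", "right"])[
            rng.permutation(np.arange(n) % 2)
        ]
        recs = []
        for k in range(n):
            stim_dir = -1.0 if sides[k] == "left" else 1.0
            dec_time = rts[k] - t0
            traj = trajectory_from_decision(
                paths[k], dec_time, bool(choices[k]), stim_dir, params, lat,
                motor, rng, sampling_rate=fs, ddm_dt=config.ddm_dt,
                start_xy=(960.0 + rng.normal(0, 12.0), 150.0),
            )
            resp = sides[k] if choices[k] else ("right" if sides[k] == "left" else "left")
            recs.append(
                TrialRecord(
                    participant_id=pid, trial_index=k + 1,
                    stimulus_side=str(sides[k]), response_side=str(resp),
                    accuracy=int(choices[k]), rt=float(rts[k]), trajectory=traj,
                )
            )
            t_rows.append(
                {
                    "participant": pid, "trial": k + 1,
                    "decision_time": dec_time, "choice": bool(choices[k]),
                    "rt": float(rts[k]),
                }
            )
        trials[pid] = recs

    truth = GroundTruth(
        participants=pd.DataFrame(p_rows),
        trials=pd.DataFrame(t_rows),
        config=config,
        seed=seed,
        acceptance_rate=acc_rate,
    )
    return TrialSet(trials), truth


def write_cohort(trials: TrialSet, truth: GroundTruth, out_dir: str | Path) -> None:
    """Write traj.csv / trials.csv (loader schema) and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traj_df, trial_df = trials.to_frames()
    traj_df.to_csv(out / "traj.csv", index=False)
    trial_df.to_csv(out / "trials.csv", index=False)
    payload = {
        "seed": truth.seed,
        "acceptance_rate": truth.acceptance_rate,
        "config": {
            **{k: v for k, v in asdict(truth.config).items() if k != "motor"},
            "motor": asdict(truth.config.motor),
        },
        "participants": truth.participants.to_dict(orient="records"),
        "trials": truth.trials.to_dict(orient="records"),
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=1))
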