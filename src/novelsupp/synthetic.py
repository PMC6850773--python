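"""Synthetic VR sessions with ground-truth-coupled calcium fluorescence.

The generator emulates a head-fixed mouse running to alternating ends of a
180 cm linear VR track (7 min familiar / 14 min middle / 7 min familiar
epochs, behavior at 1 kHz, imaging at 5.2-7.8 Hz).  Per-cell fluorescence is
coupled to locomotion with a planted gain, sign and lag, and suppressed in the
middle epoch by a planted per-cell factor ``s_i``; the planted parameters are
returned as ground truth so downstream estimators can be validated by
parameter recovery.

Locomotion alternates between running bouts (clipped Ornstein-Uhlenbeck
forward speed) and rest bouts (mice are immobile roughly 45% of the time),
which also anchors the sliding-percentile baseline of downstream ΔF/F.  Task
proficiency (per epoch, in [0, 1]) controls goal-directedness: failure
(turn-around) probability, depth of the pre-reward slowdown, and the rate of
spurious licking all degrade as proficiency drops.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .behavior import BehaviorSession, FrameBehavior, downsample_behavior

try:  # pragma: no cover - numba is an optional accelerator
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f

        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


@dataclass
class SimConfig:
    """Parameters of a simulated session.

    Per-cell parameters (``suppression``, ``locomotion_gain``,
    ``locomotion_sign``, ``lag``, ``base``) may be given explicitly as arrays
    of length ``n_cells`` or left ``None`` to be drawn from the defaults:
    suppression ~ U[-0.2, 0.8], gain ~ U[1.0, 2.0] (peak locomotor
    modulation of 100-200% ΔF/F, typical of these interneurons), sign +1
    with probability 0.8 (locomotion-activated majority), lag ~ U[0, 1] s,
    baseline fluorescence ~ U[50, 200] au.  ``noise_sd`` is per-frame
    Gaussian noise as a fraction of baseline (0.02, a bright-soma SNR).
    ``seed`` fully determines all output.
    """

    epoch_durations: tuple = (420.0, 840.0, 420.0)
    track_length: float = 180.0
    frame_rate: float = 7.8
    behavior_rate: float = 1000.0
    n_cells: int = 20
    suppression: np.ndarray | None = None
    locomotion_gain: np.ndarray | None = None
    locomotion_sign: np.ndarray | None = None
    lag: np.ndarray | None = None
    base: np.ndarray | None = None
    bleach_tau: float | None = None
    noise_sd: float = 0.02
    proficiency: tuple = (0.9, 0.3, 0.9)
    task: str = "task"  # "task" (New middle epoch) or "no_task" (static screen)
    suppression_target: str = "activity"  # "activity" or "total"
    excess_variability: float = 0.3
    variability_tau: float = 0.5
    neuropil_coef: float = 0.0
    neuropil_scale: float = 0.5
    end_zone_cm: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if any(d <= 0 for d in self.epoch_durations):
            raise ValueError("epoch durations must be positive")
        if self.frame_rate > self.behavior_rate:
            raise ValueError("frame_rate must not exceed behavior_rate")
        if any(not 0 <= p <= 1 for p in self.proficiency):
            raise ValueError("proficiency must lie in [0, 1]")
        if self.task not in ("task", "no_task"):
            raise ValueError("task must be 'task' or 'no_task'")
        if self.suppression_target not in ("activity", "total"):
            raise ValueError("suppression_target must be 'activity' or 'total'")
        if self.suppression is not None:
            s = np.asarray(self.suppression, float)
            if np.any(s < -0.5) or np.any(s > 1.0):
                raise ValueError("suppression must lie in [-0.5, 1]")

    @property
    def epoch_names(self) -> tuple:
        middle = "NoTask" if self.task == "no_task" else "New"
        return ("Fam", middle, "FamPrime")

    def resolve_cells(self) -> dict:
        """Per-cell ground-truth parameters, drawing unspecified ones from the defaults."""
        rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), 1]))
        n = self.n_cells
        out = {}
        out["suppression"] = (
            np.asarray(self.suppression, float)
            if self.suppression is not None
            else rng.uniform(-0.2, 0.8, n)
        )
        out["gain"] = (
            np.asarray(self.locomotion_gain, float)
            if self.locomotion_gain is not None
            else rng.uniform(1.0, 2.0, n)
        )
        out["sign"] = (
            np.asarray(self.locomotion_sign, float)
            if self.locomotion_sign is not None
            else np.where(rng.random(n) < 0.8, 1.0, -1.0)
        )
        out["lag"] = np.asarray(self.lag, float) if self.lag is not None else rng.uniform(0.0, 1.0, n)
        if np.any(out["lag"] < 0) or np.any(out["lag"] > 2.0):
            raise ValueError("lag must lie in [0, 2] s")
        out["base"] = (
            np.asarray(self.base, float) if self.base is not None else rng.uniform(50.0, 200.0, n)
        )
        for k, v in out.items():
            if len(v) != n:
                raise ValueError(f"per-cell parameter {k} has wrong length")
        return out


@dataclass
class GroundTruth:
    """Planted per-cell parameters and the noiseless latent fluorescence."""

    suppression: np.ndarray
    gain: np.ndarray
    sign: np.ndarray
    lag: np.ndarray
    base: np.ndarray
    latent: np.ndarray  # cells x frames, noiseless
    drive: np.ndarray  # cells x frames, per-cell normalized activity drive


# ---------------------------------------------------------------------------
# kinematics


@njit(cache=True)
def _kinematics_loop(
    n,
    dt,
    ou_speed,
    run_speed,
    rot_noise,
    u_pool,
    epoch_code,
    prof_by_epoch,
    middle_is_task,
    track_length,
    end_zone,
    slow_zone,
    dwell_reward_n,
    dwell_turn_n,
    fail_scale,
    slow_depth_scale,
):
    pos = np.empty(n)
    fwd = np.empty(n)
    vr_v = np.empty(n)
    rot = np.empty(n)
    reward = np.zeros(n, np.uint8)
    entry = np.zeros(n, np.int8)  # +1 rewarded entry, -1 unrewarded entry

    p = track_length / 2.0
    heading = 1.0
    correct = 1.0
    ui = 0
    dwell = 0
    fail_armed = False
    fail_at = -1.0
    rot_state = 0.0
    rot_decay = np.exp(-dt / 0.7)
    frozen = -1.0  # NoTask frozen position (<0 means inactive)

    def _next_u(pool, i):
        return pool[i % pool.shape[0]], i + 1

    for t in range(n):
        ep = epoch_code[t]
        prof = prof_by_epoch[ep]
        task_now = (ep != 1) or middle_is_task
        if ep == 1 and not middle_is_task:
            if frozen < 0.0:
                frozen = p
            pos[t] = frozen
            fwd[t] = ou_speed[t]
            vr_v[t] = 0.0
            rot_state *= rot_decay
            rot[t] = rot_noise[t] + rot_state
            continue
        if frozen >= 0.0:
            # leaving NoTask: resume from frozen position, fresh trial
            p = frozen
            frozen = -1.0
            fail_armed = False

        if dwell > 0:
            dwell -= 1
            pos[t] = p
            fwd[t] = ou_speed[t] * 0.03
            vr_v[t] = 0.0
            rot_state *= rot_decay
            rot[t] = rot_noise[t] + rot_state
            continue

        # pre-reward slowdown when approaching the rewarded end; the final
        # goal-directed approach is not interrupted by rest bouts
        boundary = track_length - end_zone if heading > 0 else end_zone
        dist = (boundary - p) * heading
        g = 1.0
        v = ou_speed[t]
        if heading == correct and dist < slow_zone and dist > 0:
            depth = slow_depth_scale * prof
            g = 1.0 - depth * (1.0 - dist / slow_zone)
            v = run_speed[t]
        v = v * g
        newp = p + heading * v * dt
        if newp < 0.0:
            newp = 0.0
        if newp > track_length:
            newp = track_length

        # mid-track failure turn
        if fail_armed and heading == correct and (fail_at - newp) * heading <= 0.0:
            heading = -heading
            fail_armed = False
            rot_state = 12.0
            pos[t] = newp
            p = newp
            fwd[t] = v
            vr_v[t] = v
            rot[t] = rot_noise[t] + rot_state
            continue

        crossed = (newp - boundary) * heading >= 0.0 and (p - boundary) * heading < 0.0
        if crossed:
            if heading == correct:
                reward[t] = 1
                entry[t] = 1
                dwell = dwell_reward_n
                correct = -correct
                heading = -heading
            else:
                entry[t] = -1
                dwell = dwell_turn_n
                heading = -heading
            rot_state = 12.0
            # arm a possible failure for the next traversal
            u, ui = _next_u(u_pool, ui)
            if u < fail_scale * (1.0 - prof):
                u2, ui = _next_u(u_pool, ui)
                # turn-around point: between 25 and 85 cm short of the destination
                short = 25.0 + 60.0 * u2
                dest = track_length - end_zone if heading > 0 else end_zone
                fail_at = dest - heading * short
                fail_armed = (fail_at - newp) * heading > 0.0
            else:
                fail_armed = False
        pos[t] = newp
        p = newp
        fwd[t] = v
        vr_v[t] = v
        rot_state *= rot_decay
        rot[t] = rot_noise[t] + rot_state
    return pos, fwd, vr_v, rot, reward, entry


def _clipped_ou(rng, n, dt, mean, sd, tau):
    a = np.exp(-dt / tau)
    e = rng.normal(0.0, sd * np.sqrt(1.0 - a * a), n)
    x = lfilter([1.0], [1.0, -a], e)
    return np.clip(mean + x, 0.0, None)


def _rest_gate(rng, n, dt, mean_run_s=4.5, mean_rest_s=3.5, cv=0.15):
    """Binary run/rest gate: alternating bouts, ~45% of time at rest.

    Bout durations are mildly dispersed (truncated normal, CV ~0.25) so the
    realized rest fraction is stationary at the epoch scale — the regime in
    which epoch-ratio statistics such as the suppression index are well-posed.
    """
    gate = np.ones(n)
    t = 0
    running = True
    while t < n:
        mean = mean_run_s if running else mean_rest_s
        dur = max(0.5, rng.normal(mean, cv * mean))
        steps = max(1, int(round(dur / dt)))
        if not running:
            gate[t : t + steps] = 0.0
        t += steps
        running = not running
    return gate


def simulate_behavior(config: SimConfig) -> BehaviorSession:
    """Simulate VR alternation-task behavior at ``config.behavior_rate`` Hz."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    rate = config.behavior_rate
    dt = 1.0 / rate
    durs = config.epoch_durations
    n_per = [int(round(d * rate)) for d in durs]
    n = sum(n_per)
    epoch_code = np.repeat(np.arange(3, dtype=np.int64), n_per)

    # locomotion: OU running speed gated by run/rest bouts (~30% immobility),
    # with a small positive sensor floor while resting
    gate = _rest_gate(rng, n, dt)
    run_speed = _clipped_ou(rng, n, dt, mean=22.0, sd=6.0, tau=1.0)
    ou_speed = run_speed * gate + (1.0 - gate) * np.abs(rng.normal(0.0, 0.3, n))
    rot_noise = _clipped_ou(rng, n, dt, mean=2.0, sd=1.5, tau=1.0) * gate
    u_pool = rng.random(8192)

    pos, fwd, vr_v, rot, reward_flag, entry = _kinematics_loop(
        n,
        dt,
        ou_speed,
        run_speed,
        rot_noise,
        u_pool,
        epoch_code,
        np.asarray(config.proficiency, float),
        config.task == "task",
        config.track_length,
        config.end_zone_cm,
        30.0,
        int(round(1.5 * rate)),
        int(round(0.4 * rate)),
        0.55,
        0.7,
    )
    t = np.arange(n) * dt
    reward_times = t[reward_flag > 0]

    # licking: a bout near each reward plus spurious bouts at a rate that
    # rises as proficiency falls
    lick = np.zeros(n, np.uint8)

    def _add_bout(t0, n_events):
        gaps = rng.uniform(0.07, 0.12, n_events - 1) if n_events > 1 else np.empty(0)
        times = t0 + np.concatenate(([0.0], np.cumsum(gaps)))
        idx = np.round(times * rate).astype(np.int64)
        idx = idx[(idx >= 0) & (idx < n)]
        lick[idx] = 1

    for tr in reward_times:
        _add_bout(tr + rng.uniform(-0.2, 0.3), rng.integers(4, 8))
    for ep in range(3):
        prof = config.proficiency[ep]
        if ep == 1 and config.task == "no_task":
            prof = 1.0  # proficiency ignored; only baseline spurious licking
        lam = (0.5 + 4.0 * (1.0 - prof)) / 60.0  # bouts per second
        t0, t1 = np.cumsum([0] + n_per)[ep] * dt, np.cumsum([0] + n_per)[ep + 1] * dt
        n_spur = rng.poisson(lam * (t1 - t0))
        for ts in rng.uniform(t0, t1, n_spur):
            _add_bout(ts, rng.integers(2, 5))
    # licks at a fraction of unrewarded end-zone entries
    unrew_times = t[entry < 0]
    for te in unrew_times:
        if rng.random() < 0.1 + 0.5 * (1.0 - config.proficiency[epoch_code[int(te * rate)]]):
            _add_bout(te + rng.uniform(0.0, 0.8), rng.integers(2, 5))

    return BehaviorSession(
        t=t,
        position=pos,
        forward_speed=fwd,
        rot_speed=rot,
        vr_speed=vr_v,
        lick=lick,
        reward_times=reward_times,
        epoch=epoch_code,
        epoch_names=config.epoch_names,
        rate=rate,
        track_length=config.track_length,
        end_zone_cm=config.end_zone_cm,
    )


# ---------------------------------------------------------------------------
# fluorescence


def normalized_speed(speed: np.ndarray) -> np.ndarray:
    """Speed scaled to [0, 1] by its 95th percentile (clipped)."""
    q = np.percentile(speed, 95)
    if q <= 0:
        return np.zeros_like(speed)
    return np.clip(speed / q, 0.0, 1.0)


def _lagged(x: np.ndarray, lag_frames: int) -> np.ndarray:
    if lag_frames <= 0:
        return x
    out = np.empty_like(x)
    out[:lag_frames] = x[0]
    out[lag_frames:] = x[:-lag_frames]
    return out


def simulate_traces(
    behavior: BehaviorSession, config: SimConfig
) -> tuple[np.ndarray, np.ndarray, GroundTruth, FrameBehavior]:
    """Simulate raw per-cell fluorescence coupled to locomotion.

    Returns ``(raw, neuropil, truth, frame_behavior)``: ``raw`` is cells x
    frames fluorescence (latent + Gaussian noise, plus ``neuropil_coef`` times
    the shared neuropil trace if configured), ``neuropil`` the shared
    perisomatic trace, and ``truth`` the planted parameters with the noiseless
    latent.

    Each cell's latent is
    ``L_i(t) = base_i * B_i(t) * (1 + gain_i * r_i(t - lag_i) * (1 - s_i * 1[middle]))``
    in the default ``"activity"`` mode, where the drive ``r_i`` is the
    normalized ball speed for locomotion-activated cells (sign +1) and a
    rectified immobility signal for sign -1 cells: suppression scales only the
    behavior-driven component, leaving the quiescent baseline intact.  In
    ``"total"`` mode the whole latent is scaled:
    ``L_i = base_i * B_i * (1 + sign_i * gain_i * shat(t - lag_i)) * (1 - s_i * 1[middle])``.
    ``B_i(t) = exp(-t / bleach_tau)`` models photobleaching (1 if disabled).
    """
    if abs(behavior.duration - sum(config.epoch_durations)) > 1.0:
        raise ValueError("behavior and config have mismatched time bases")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2]))
    cells = config.resolve_cells()
    fb = downsample_behavior(behavior, config.frame_rate)
    shat = normalized_speed(fb.speed)
    n_frames = fb.n_frames
    mid = fb.epoch == 1
    tvec = np.arange(n_frames) / config.frame_rate
    bleach = np.exp(-tvec / config.bleach_tau) if config.bleach_tau else np.ones(n_frames)

    n_cells = config.n_cells
    latent = np.empty((n_cells, n_frames))
    drive = np.empty((n_cells, n_frames))
    for i in range(n_cells):
        lf = int(round(cells["lag"][i] * config.frame_rate))
        sh = _lagged(shat, lf)
        s_i = cells["suppression"][i]
        if config.suppression_target == "activity":
            r = sh if cells["sign"][i] > 0 else np.clip(1.0 - sh / 0.8, 0.0, 1.0)
            if config.excess_variability > 0:
                # physiological excess variability: lognormal gain fluctuation
                # (mean 1) with ~0.5 s correlation, independent across cells;
                # it gives ΔF/F its positive skew and caps model R^2 below 1
                a = np.exp(-1.0 / (config.variability_tau * config.frame_rate))
                eta = lfilter(
                    [1.0],
                    [1.0, -a],
                    rng.normal(0.0, config.excess_variability * np.sqrt(1 - a * a), n_frames),
                )
                r = r * np.exp(eta - config.excess_variability**2 / 2.0)
            drive[i] = r
            mod = 1.0 + cells["gain"][i] * r * np.where(mid, 1.0 - s_i, 1.0)
            latent[i] = cells["base"][i] * bleach * mod
        else:
            drive[i] = sh
            mod = 1.0 + cells["sign"][i] * cells["gain"][i] * sh
            latent[i] = cells["base"][i] * bleach * mod * np.where(mid, 1.0 - s_i, 1.0)

    noise = rng.normal(0.0, 1.0, latent.shape) * (config.noise_sd * cells["base"][:, None])
    neuropil_clean = config.neuropil_scale * latent.mean(axis=0)
    neuropil = neuropil_clean + rng.normal(
        0.0, config.noise_sd * max(neuropil_clean.mean(), 1e-12) * 0.3, n_frames
    )
    raw = latent + noise + config.neuropil_coef * neuropil_clean

    truth = GroundTruth(
        suppression=cells["suppression"],
        gain=cells["gain"],
        sign=cells["sign"],
        lag=cells["lag"],
        base=cells["base"],
        latent=latent,
        drive=drive,
    )
    return raw, neuropil, truth, fb


# ---------------------------------------------------------------------------
# movies


@dataclass
class MovieConfig:
    """Geometry and noise of the planted-somata movie generator.

    Defaults: 256 x 256 px sub-field at 1 um/px, 2-D Gaussian somata of
    sigma 3 um (ground-truth mask = 2-sigma disc, area ~113 um^2 > the 90 um^2
    detection floor), Poisson photon noise, optional known rigid shifts.
    """

    shape: tuple = (256, 256)
    px_size_um: float = 1.0
    soma_sigma_um: float = 3.0
    min_separation_um: float = 25.0
    background: float = 30.0
    poisson_noise: bool = True
    shifts: np.ndarray | None = None  # (frames, 2) integer (dy, dx)
    margin_px: int = 20


def plant_centroids(rng, n_cells, cfg: MovieConfig) -> np.ndarray:
    """Sample non-overlapping soma centroids; error if they cannot be placed."""
    pts: list = []
    lo, hiy, hix = cfg.margin_px, cfg.shape[0] - cfg.margin_px, cfg.shape[1] - cfg.margin_px
    for _ in range(20000):
        if len(pts) == n_cells:
            break
        cand = np.array([rng.uniform(lo, hiy), rng.uniform(lo, hix)])
        if all(np.hypot(*(cand - p)) * cfg.px_size_um >= cfg.min_separation_um for p in pts):
            pts.append(cand)
    if len(pts) < n_cells:
        raise ValueError("could not place somata without overlap; reduce n_cells or separation")
    return np.array(pts)


def simulate_movie(
    behavior: BehaviorSession, config: SimConfig, movie_cfg: MovieConfig | None = None
):
    """Render a planted-somata movie whose soma brightness follows simulate_traces.

    Returns ``(stack, planted, truth, fb)`` where ``planted`` is a dict with
    ground-truth ``centroids_px``, ``masks`` (2-sigma discs), ``areas_um2``
    and the applied per-frame ``shifts``.
    """
    movie_cfg = movie_cfg or MovieConfig()
    raw, neuropil, truth, fb = simulate_traces(behavior, config)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 3]))
    n_frames = fb.n_frames
    h, w = movie_cfg.shape
    cent = plant_centroids(rng, config.n_cells, movie_cfg)
    sig = movie_cfg.soma_sigma_um / movie_cfg.px_size_um

    yy, xx = np.mgrid[0:h, 0:w]
    profiles = np.empty((config.n_cells, h, w), np.float32)
    masks = []
    for i, (cy, cx) in enumerate(cent):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        profiles[i] = np.exp(-d2 / (2 * sig**2))
        masks.append(d2 <= (2 * sig) ** 2)
    areas = np.array([m.sum() * movie_cfg.px_size_um**2 for m in masks])

    shifts = movie_cfg.shifts
    if shifts is None:
        shifts = np.zeros((n_frames, 2), int)
    shifts = np.asarray(shifts)

    # soma brightness follows the noiseless latent (photon noise is added at
    # the pixel level); diffuse background carries the shared neuropil signal
    amp = truth.latent / np.maximum(truth.base[:, None], 1e-12)  # ~O(1)
    flat = profiles.reshape(config.n_cells, -1)
    stack = np.empty((n_frames, h, w), np.float32)
    brightness = truth.base[:, None] * amp  # == latent
    bg = movie_cfg.background * (neuropil / max(neuropil.mean(), 1e-12))
    for f in range(n_frames):
        frame = (brightness[:, f] @ flat).reshape(h, w) + bg[f]
        dy, dx = int(shifts[f, 0]), int(shifts[f, 1])
        if dy or dx:
            frame = np.roll(np.roll(frame, dy, axis=0), dx, axis=1)
        if movie_cfg.poisson_noise:
            frame = rng.poisson(np.clip(frame, 0, None)).astype(np.float32)
        stack[f] = frame

    planted = {
        "centroids_px": cent,
        "masks": masks,
        "areas_um2": areas,
        "shifts": shifts,
        "px_size_um": movie_cfg.px_size_um,
    }
    return stack, planted, truth, fb


def simulate_session(config: SimConfig):
    """Convenience wrapper: behavior plus traces for one session."""
    behavior = simulate_behavior(config)
    raw, neuropil, truth, fb = simulate_traces(behavior, config)
    return behavior, fb, raw, neuropil, truth
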