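"""Behavioral time series and task-performance metrics for VR alternation sessions.

A session is 1 kHz behavioral data (ball speeds, VR position, rewards, licks)
segmented into three contiguous epochs: a familiar environment (``Fam``), a
middle epoch (``New`` or ``NoTask``), and the same familiar environment again
(``FamPrime``).  Metrics here quantify task performance: reward rate,
anticipatory slowing before reward, licking structure, track occupancy and
trial failures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EPOCH_ORDER = ("Fam", "middle", "FamPrime")


@dataclass
class BehaviorSession:
    """Time-aligned behavioral series for one recording at ``rate`` Hz.

    Attributes
    ----------
    t : array of sample times in seconds.
    position : VR track position, cm in ``[0, track_length]``.
    forward_speed, rot_speed : forward / rotational ball speed components, cm/s.
    vr_speed : speed of motion through the virtual environment, cm/s
        (zero while the animal runs against a wall or the screen is static).
    lick : binary lick-sensor series (1 at lick events).
    reward_times : times of reward delivery, seconds.
    epoch : per-sample epoch code (0=Fam, 1=middle, 2=FamPrime).
    epoch_names : display name per epoch code, e.g. ("Fam", "New", "FamPrime").
    """

    t: np.ndarray
    position: np.ndarray
    forward_speed: np.ndarray
    rot_speed: np.ndarray
    vr_speed: np.ndarray
    lick: np.ndarray
    reward_times: np.ndarray
    epoch: np.ndarray
    epoch_names: tuple = ("Fam", "New", "FamPrime")
    rate: float = 1000.0
    track_length: float = 180.0
    end_zone_cm: float = 10.0

    def __post_init__(self):
        n = len(self.t)
        for name in ("position", "forward_speed", "rot_speed", "vr_speed", "lick", "epoch"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match t")
        if np.any(self.position < -1e-9) or np.any(self.position > self.track_length + 1e-9):
            raise ValueError("position outside [0, track_length]")
        if len(self.reward_times) and (
            self.reward_times.min() < self.t[0] or self.reward_times.max() > self.t[-1] + 1.0 / self.rate
        ):
            raise ValueError("reward_times outside session")
        # epochs must be contiguous and ordered
        codes = self.epoch[np.flatnonzero(np.diff(self.epoch)) ]
        if np.any(np.diff(self.epoch) < 0):
            raise ValueError("epochs must appear in order Fam, middle, FamPrime")

    @property
    def duration(self) -> float:
        return len(self.t) / self.rate

    def epoch_mask(self, name: str) -> np.ndarray:
        code = self.epoch_names.index(name)
        return self.epoch == code

    def epoch_bounds(self, name: str) -> tuple[float, float]:
        """(start, end) time of an epoch in seconds."""
        idx = np.flatnonzero(self.epoch_mask(name))
        if idx.size == 0:
            raise ValueError(f"epoch {name!r} not present")
        return self.t[idx[0]], self.t[idx[-1]] + 1.0 / self.rate


@dataclass
class FrameBehavior:
    """Behavior downsampled to the imaging frame clock.

    Continuous variables are means over each frame interval; rewards and licks
    are mapped to their containing frame (counts per frame).
    """

    t: np.ndarray
    position: np.ndarray
    forward_speed: np.ndarray
    rot_speed: np.ndarray
    vr_speed: np.ndarray
    reward: np.ndarray
    lick: np.ndarray
    epoch: np.ndarray
    epoch_names: tuple
    frame_rate: float
    track_length: float = 180.0

    @property
    def speed(self) -> np.ndarray:
        return compute_speed(self.forward_speed, self.rot_speed)

    @property
    def n_frames(self) -> int:
        return len(self.t)

    def epoch_mask(self, name: str) -> np.ndarray:
        return self.epoch == self.epoch_names.index(name)

    def regressors(self) -> dict:
        """Behavioral regressors used by the encoding model, keyed by name."""
        return {
            "forward_speed": self.forward_speed,
            "rot_speed": self.rot_speed,
            "reward": (self.reward > 0).astype(float),
            "vr_position": self.position,
            "vr_speed": self.vr_speed,
        }


@dataclass
class LickBout:
    """A run of lick events with inter-event gaps < 200 ms."""

    start: float
    end: float
    n_events: int

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("bout end before start")


def compute_speed(forward: np.ndarray, rot: np.ndarray) -> np.ndarray:
    """Total ball speed: Euclidean sum of forward and rotation components."""
    forward = np.asarray(forward, float)
    rot = np.asarray(rot, float)
    if forward.shape != rot.shape:
        raise ValueError("forward and rotation series must have equal length")
    return np.hypot(forward, rot)


def downsample_behavior(session: BehaviorSession, frame_rate: float) -> FrameBehavior:
    """Downsample 1 kHz behavior to the imaging frame rate.

    Continuous variables are averaged within each frame interval
    ``[i/frame_rate, (i+1)/frame_rate)``; reward and lick events are counted in
    their containing frame.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    if frame_rate > session.rate + 1e-9:
        raise ValueError("frame_rate must not exceed the behavior sampling rate")
    n_frames = int(np.floor(session.duration * frame_rate))
    idx = np.floor((session.t - session.t[0]) * frame_rate + 1e-9).astype(np.int64)
    keep = idx < n_frames
    idx = idx[keep]
    counts = np.bincount(idx, minlength=n_frames).astype(float)
    counts[counts == 0] = np.nan

    def mean_of(x):
        return np.bincount(idx, weights=x[keep], minlength=n_frames) / counts

    lick_counts = np.bincount(idx, weights=session.lick[keep].astype(float), minlength=n_frames)
    rtimes = session.reward_times - session.t[0]
    r_idx = np.floor(rtimes * frame_rate).astype(np.int64)
    r_idx = r_idx[(r_idx >= 0) & (r_idx < n_frames)]
    reward = np.bincount(r_idx, minlength=n_frames).astype(float)
    # epoch of the first behavior sample in each frame
    first = np.searchsorted(idx, np.arange(n_frames))
    first = np.minimum(first, len(idx) - 1)
    epoch_f = session.epoch[np.flatnonzero(keep)[first]]
    return FrameBehavior(
        t=(np.arange(n_frames) + 0.5) / frame_rate + session.t[0],
        position=mean_of(session.position),
        forward_speed=mean_of(session.forward_speed),
        rot_speed=mean_of(session.rot_speed),
        vr_speed=mean_of(session.vr_speed),
        reward=reward,
        lick=lick_counts,
        epoch=epoch_f,
        epoch_names=session.epoch_names,
        frame_rate=frame_rate,
        track_length=session.track_length,
    )


def rewards_per_min(session: BehaviorSession, epoch: str) -> float:
    """Reward rate within one epoch, rewards per minute."""
    t0, t1 = session.epoch_bounds(epoch)
    if t1 <= t0:
        raise ValueError("epoch has zero duration")
    n = np.count_nonzero((session.reward_times >= t0) & (session.reward_times < t1))
    return n / ((t1 - t0) / 60.0)


def normalize_to_famave(value_new: float, value_fam: float, value_famprime: float) -> float:
    """Ratio of a metric in the middle epoch to its mean over Fam and Fam'."""
    fam_ave = 0.5 * (value_fam + value_famprime)
    if fam_ave == 0:
        raise ZeroDivisionError("Fam_Ave is zero")
    return value_new / fam_ave


def pre_reward_deceleration(
    forward_speed: np.ndarray,
    reward_times: np.ndarray,
    rate: float,
    window_s: float = 3.0,
    t0: float = 0.0,
) -> float:
    """Mean forward-speed derivative in the ``window_s`` before each reward, cm/s^2.

    For each reward with a full pre-window the mean first derivative over
    ``[t_rew - window, t_rew)`` is taken; per-reward values are then averaged.
    Rewards without a full window are excluded.  Returns NaN when no reward
    qualifies.
    """
    n_win = int(round(window_s * rate))
    slopes = []
    dt = 1.0 / rate
    for tr in np.atleast_1d(reward_times):
        end = int(np.floor((tr - t0) * rate))
        start = end - n_win
        if start < 0 or end > len(forward_speed) or end - start < 2:
            continue
        seg = forward_speed[start:end]
        slopes.append((seg[-1] - seg[0]) / ((len(seg) - 1) * dt))
    return float(np.mean(slopes)) if slopes else float("nan")


def lick_event_times(lick_signal: np.ndarray, rate: float, t0: float = 0.0) -> np.ndarray:
    """Times of lick events (rising edges of the binary lick signal)."""
    sig = np.asarray(lick_signal) > 0
    edges = np.flatnonzero(sig & ~np.concatenate(([False], sig[:-1])))
    return t0 + edges / rate


def detect_lick_bouts(
    lick_signal: np.ndarray, rate: float, max_gap_s: float = 0.2, t0: float = 0.0
) -> list[LickBout]:
    """Merge lick events separated by gaps strictly below ``max_gap_s`` into bouts."""
    times = lick_event_times(lick_signal, rate, t0)
    if times.size == 0:
        return []
    split = np.flatnonzero(np.diff(times) >= max_gap_s)
    bouts = []
    start = 0
    for s in list(split) + [len(times) - 1]:
        seg = times[start : s + 1]
        bouts.append(LickBout(start=float(seg[0]), end=float(seg[-1]), n_events=len(seg)))
        start = s + 1
    return bouts


def lick_rate(bouts: list[LickBout], duration_s: float) -> float:
    """Lick-bout rate in bouts per minute."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    return len(bouts) / (duration_s / 60.0)


def correct_lick_fraction(
    bouts: list[LickBout], reward_times: np.ndarray, window_s: float = 0.5
) -> float:
    """Fraction of lick bouts starting within +/- ``window_s`` of any reward (inclusive)."""
    if not bouts:
        return float("nan")
    rt = np.atleast_1d(np.asarray(reward_times, float))
    if rt.size == 0:
        return 0.0
    hits = sum(1 for b in bouts if np.min(np.abs(rt - b.start)) <= window_s)
    return hits / len(bouts)


def endzone_entries(session: BehaviorSession, reward_window_s: float = 1.0):
    """Detect entries into either track end zone.

    Returns ``(times, rewarded)`` where ``rewarded[i]`` marks entries with a
    reward delivered within ``reward_window_s`` of the crossing.
    """
    lo = session.end_zone_cm
    hi = session.track_length - session.end_zone_cm
    inside = (session.position <= lo) | (session.position >= hi)
    enter = np.flatnonzero(inside & ~np.concatenate(([True], inside[:-1])))
    times = session.t[enter]
    rt = session.reward_times
    rewarded = np.array(
        [rt.size > 0 and np.min(np.abs(rt - tt)) <= reward_window_s for tt in times], bool
    )
    return times, rewarded


def unrewarded_endzone_lick_fraction(
    bouts: list[LickBout],
    entry_times: np.ndarray,
    rewarded: np.ndarray,
    window_s: float = 2.0,
) -> float:
    """Fraction of unrewarded end-zone entries followed by a lick bout.

    An entry counts as licked when some bout starts within
    ``[entry - 0.5 s, entry + window_s]``.
    """
    unrew = np.atleast_1d(entry_times)[~np.atleast_1d(rewarded)]
    if unrew.size == 0:
        return float("nan")
    starts = np.array([b.start for b in bouts]) if bouts else np.empty(0)
    licked = sum(
        1 for tt in unrew if starts.size and np.any((starts >= tt - 0.5) & (starts <= tt + window_s))
    )
    return licked / unrew.size


def occupancy_map(
    position: np.ndarray,
    rate: float,
    bin_cm: float = 20.0,
    track_length: float = 180.0,
) -> np.ndarray:
    """Time spent (seconds) in each ``bin_cm`` track bin; bins sum to the duration."""
    pos = np.asarray(position, float)
    if np.any(pos < -1e-9) or np.any(pos > track_length + 1e-9):
        raise ValueError("position outside track")
    n_bins = int(np.ceil(track_length / bin_cm))
    idx = np.minimum((pos / bin_cm).astype(int), n_bins - 1)
    return np.bincount(idx, minlength=n_bins) / rate


def trial_failure_location(
    session: BehaviorSession,
    min_sustain_s: float = 0.5,
    min_excursion_cm: float = 2.0,
) -> np.ndarray:
    """Distances (cm) from the destination end zone at which failed trials turn around.

    The destination alternates with each reward.  A turn-around is a sign
    reversal of track displacement sustained for at least ``min_sustain_s``
    and covering at least ``min_excursion_cm`` (to reject jitter), occurring
    before the destination end zone is reached.
    """
    rate = session.rate
    w = max(1, int(round(min_sustain_s * rate)))
    pos = session.position
    n = len(pos)
    # trial segmentation: destination flips after each reward
    bounds = [0] + [int(np.floor((tr - session.t[0]) * rate)) for tr in session.reward_times] + [n]
    # destination of first trial: the far end from the starting position side
    distances = []
    for k in range(len(bounds) - 1):
        a, b = bounds[k], bounds[k + 1]
        if b - a < 2 * w:
            continue
        if k == 0:
            # head toward whichever end is reached/approached first
            dest_sign = 1.0 if pos[min(b - 1, n - 1)] >= pos[a] else -1.0
        else:
            # previous reward was at one end; next destination is the other
            prev_end = pos[bounds[k] - 1] if bounds[k] > 0 else pos[a]
            dest_sign = -1.0 if prev_end > session.track_length / 2 else 1.0
        dest_boundary = (
            session.track_length - session.end_zone_cm if dest_sign > 0 else session.end_zone_cm
        )
        seg = pos[a:b]
        # displacement over the sustain window
        disp = seg[w:] - seg[:-w]
        toward = disp * dest_sign > min_excursion_cm
        away = disp * dest_sign < -min_excursion_cm
        reached = np.flatnonzero((seg - dest_boundary) * dest_sign >= 0)
        limit = reached[0] if reached.size else len(seg)
        state = 0  # 1 once moving toward destination
        for i in range(min(limit, len(disp))):
            if toward[i]:
                state = 1
            elif away[i] and state == 1:
                distances.append(abs(seg[i] - dest_boundary))
                state = 0
    return np.asarray(distances, float)
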