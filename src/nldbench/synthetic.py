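"""Synthetic task, kinematics, and neural-encoding generator.

Emulates a 2-DOF random-target finger task: on every trial a target is
drawn uniformly per finger group, the hand makes a smooth (minimum-jerk)
reach to it after a short reaction pause, and then holds inside the target
with small positional jitter.  The resulting velocity distribution is
peaked at zero with heavy tails — fast reaches embedded in long low-speed
holds — which is the qualitative behavioral signature the decoders are
judged on.

Neural features are produced by a per-channel tuning model mapping
kinematics (velocity, position, speed) through an optional nonlinearity to
nonnegative spiking-band-power, plus truncated Gaussian noise.  "Context
shifts" (spring load, wrist rotation) perturb the tuning parameters while
leaving kinematics untouched, emulating task manipulations that modulate
neural activity but not behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from nldbench.session import BinnedSession, Kinematics, TrialTable


# --------------------------------------------------------------------------
# Task configuration
# --------------------------------------------------------------------------


@dataclass
class TaskConfig:
    """Parameters of the simulated random-target task.

    Durations are in milliseconds; positions in "flex" units on [0, 1].
    """

    n_trials: int = 600
    n_dof: int = 2
    target_width: float = 0.15
    hold_time_ms: float = 750.0
    timeout_ms: float = 10_000.0
    bin_ms: float = 50.0
    seed: int = 0
    # Generator shape parameters (not part of the task geometry).
    reach_ms_range: tuple[float, float] = (400.0, 900.0)
    reaction_ms_range: tuple[float, float] = (150.0, 350.0)
    hold_jitter_sd: float = 0.004  # flex units per bin during holds
    failure_rate: float = 0.0

    def validate(self) -> None:
        if self.n_trials < 1:
            raise ValueError("TaskConfig.n_trials must be >= 1")
        if self.n_dof < 1:
            raise ValueError("TaskConfig.n_dof must be >= 1")
        if not (0.0 < self.target_width < 1.0):
            raise ValueError("TaskConfig.target_width must be in (0, 1)")
        if not (self.hold_time_ms < self.timeout_ms):
            raise ValueError("TaskConfig.hold_time_ms must be < timeout_ms")
        if self.bin_ms <= 0:
            raise ValueError("TaskConfig.bin_ms must be > 0")
        if not (0.0 <= self.failure_rate < 1.0):
            raise ValueError("TaskConfig.failure_rate must be in [0, 1)")


def _min_jerk(p0: np.ndarray, p1: np.ndarray, n_bins: int) -> np.ndarray:
    """Minimum-jerk position profile from p0 to p1 over n_bins bins.

    Returns an (n_bins, n_dof) array whose last row equals p1.
    """
    tau = np.arange(1, n_bins + 1) / n_bins
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    return p0[None, :] + s[:, None] * (p1 - p0)[None, :]


def generate_task_trials(
    config: TaskConfig, context: str = "normal"
) -> tuple[Kinematics, TrialTable]:
    """Simulate kinematics and the trial table for one block of trials.

    Each trial: reaction pause at the current posture, a minimum-jerk reach
    to an independently drawn uniform target per DOF, then an in-target
    hold with small jitter for the hold time.  Failed trials (drawn with
    ``config.failure_rate``) stall short of the target until the timeout.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    half = config.target_width / 2.0
    bin_s = config.bin_ms / 1000.0
    hold_bins = max(1, int(round(config.hold_time_ms / config.bin_ms)))
    timeout_bins = int(round(config.timeout_ms / config.bin_ms))

    pos_blocks: list[np.ndarray] = []
    records: list[dict] = []
    current = np.full(config.n_dof, 0.5)
    t = 0
    for _ in range(config.n_trials):
        target = rng.uniform(half, 1.0 - half, size=config.n_dof)
        react_bins = max(
            1, int(round(rng.uniform(*config.reaction_ms_range) / config.bin_ms))
        )
        reach_bins = max(
            2, int(round(rng.uniform(*config.reach_ms_range) / config.bin_ms))
        )
        failed = rng.uniform() < config.failure_rate

        react_jit = rng.normal(0.0, config.hold_jitter_sd, (react_bins, config.n_dof))
        block = [np.clip(current[None, :] + react_jit, 0.0, 1.0)]
        if failed:
            # Stall short of the target (miss by slightly more than the
            # half-width) and wander there until the timeout elapses.
            miss = target - np.sign(target - current + 1e-12) * (half * 2.5)
            miss = np.clip(miss, 0.0, 1.0)
            block.append(_min_jerk(current, miss, reach_bins))
            n_stall = max(1, timeout_bins - react_bins - reach_bins)
            jitter = rng.normal(0.0, config.hold_jitter_sd, (n_stall, config.n_dof))
            block.append(np.clip(miss[None, :] + jitter, 0.0, 1.0))
            endpoint = block[-1][-1]
        else:
            block.append(_min_jerk(current, target, reach_bins))
            jitter = rng.normal(0.0, config.hold_jitter_sd, (hold_bins, config.n_dof))
            # Keep the jittered hold inside the target window.
            held = np.clip(target[None, :] + jitter, target - half * 0.9, target + half * 0.9)
            block.append(np.clip(held, 0.0, 1.0))
            endpoint = block[-1][-1]

        block_arr = np.vstack(block)
        n = block_arr.shape[0]
        records.append(
            {
                "start_bin": t,
                "end_bin": t + n,
                "target_idx": target[0],
                "target_mrs": target[1] if config.n_dof > 1 else target[0],
                "target_width": config.target_width,
                "success": not failed,
                "context": context,
            }
        )
        pos_blocks.append(block_arr)
        current = endpoint
        t += n

    position = np.clip(np.vstack(pos_blocks), 0.0, 1.0)
    kin = Kinematics.from_position(position, bin_ms=config.bin_ms)
    return kin, TrialTable(pd.DataFrame.from_records(records))


# --------------------------------------------------------------------------
# Encoding model
# --------------------------------------------------------------------------

_LINKS = ("linear", "saturating", "quadratic")

#: Per-context tuning perturbations: (rotation angle of the velocity-weight
#: pair in radians, gain multiplier, baseline offset).  "normal" is the
#: identity by construction.
DEFAULT_CONTEXT_SHIFTS: dict[str, tuple[float, float, float]] = {
    "normal": (0.0, 1.0, 0.0),
    "spring": (0.5, 1.25, 2.0),
    "wrist": (0.8, 0.85, -1.5),
    "spring-wrist": (1.2, 1.35, 3.0),
}


@dataclass
class EncodingModel:
    """Ground-truth kinematics → expected-SBP tuning for each channel.

    The feature vector per bin is ``x = [v_idx, v_mrs, p_idx, p_mrs,
    |v_idx|, |v_mrs|]``.  Channel c has expected SBP
    ``b_c + gain_c * link(w_c · x)`` where the link is the identity
    ("linear"), a logistic saturation ("saturating"), or a quadratic
    expansion.  The logistic link saturates in both directions, so
    high-velocity tails are compressed in single-channel activity — the
    regime where affine decoders systematically under-predict speed.
    """

    baseline: np.ndarray  # (C,) nonnegative
    weights: np.ndarray  # (C, 6)
    gain: np.ndarray  # (C,) positive
    noise_sd: np.ndarray  # (C,) additive noise SD per channel
    nonlinearity: str = "saturating"
    context_shifts: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONTEXT_SHIFTS)
    )
    shift_magnitude: float = 1.0
    seed: int | None = None

    @property
    def n_channels(self) -> int:
        return self.baseline.shape[0]

    def known_contexts(self) -> list[str]:
        return list(self.context_shifts)

    def shifted_params(
        self, context: str
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(baseline, weights, gain) after applying the context shift."""
        if context not in self.context_shifts:
            raise ValueError(
                f"unknown context {context!r}; known contexts: "
                f"{sorted(self.context_shifts)}"
            )
        angle, gain_mult, offset = self.context_shifts[context]
        m = self.shift_magnitude
        angle = angle * m
        gain_mult = 1.0 + (gain_mult - 1.0) * m
        offset = offset * m
        w = self.weights.copy()
        c, s = np.cos(angle), np.sin(angle)
        wv = w[:, :2] @ np.array([[c, s], [-s, c]]).T
        w[:, :2] = wv
        baseline = np.maximum(self.baseline + offset, 0.0)
        return baseline, w, self.gain * gain_mult

    def expected_sbp(self, kin: Kinematics, context: str = "normal") -> np.ndarray:
        """Noise-free expected SBP, (T, C)."""
        baseline, w, gain = self.shifted_params(context)
        x = kinematic_features(kin)
        u = x @ w.T
        if self.nonlinearity == "linear":
            g = u
        elif self.nonlinearity == "saturating":
            with np.errstate(over="ignore"):
                g = 1.0 / (1.0 + np.exp(-u))  # logistic saturation
        elif self.nonlinearity == "quadratic":
            g = u + 0.25 * u**2
        else:  # pragma: no cover - guarded at construction
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")
        return baseline[None, :] + gain[None, :] * g


def kinematic_features(kin: Kinematics) -> np.ndarray:
    """Tuning features per bin: velocity, position, per-DOF speed."""
    return np.hstack([kin.velocity, kin.position, np.abs(kin.velocity)])


def generate_encoding_model(
    n_channels: int,
    nonlinearity: str = "saturating",
    seed: int = 0,
    noise_scale: float = 0.35,
    shift_magnitude: float = 1.0,
    context_shifts: dict[str, tuple[float, float, float]] | None = None,
) -> EncodingModel:
    """Draw random per-channel tuning parameters.

    With ``nonlinearity="linear"`` the kinematics → expected-SBP map is
    affine and baselines are inflated so the map stays nonnegative over the
    task's kinematic range, making ridge regression a near-optimal decoder
    (used as a control condition).  The noise SD per channel is
    ``noise_scale`` times the channel's (uninflated) baseline draw.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if nonlinearity not in _LINKS:
        raise ValueError(f"nonlinearity must be one of {_LINKS}")
    rng = np.random.default_rng(seed)
    baseline = rng.uniform(8.0, 25.0, n_channels)
    noise_sd = noise_scale * baseline
    # Velocity weights dominate; position and speed tuning are weaker.  The
    # saturating link gets steeper velocity tuning so single channels
    # genuinely saturate over the task's speed range.
    vel_sd = 0.9 if nonlinearity == "linear" else 2.5
    weights = np.hstack(
        [
            rng.normal(0.0, vel_sd, (n_channels, 2)),
            rng.normal(0.0, 0.35, (n_channels, 2)),
            rng.normal(0.0, 0.3, (n_channels, 2)),
        ]
    )
    gain = rng.uniform(8.0, 20.0, n_channels)
    if nonlinearity == "linear":
        # Worst-case |w·x| over |v| <= 6 flex/s, p in [0, 1]: guarantees a
        # nonnegative affine map without clipping.
        u_max = 6.0 * (
            np.abs(weights[:, 0]) + np.abs(weights[:, 1])
            + np.abs(weights[:, 4]) + np.abs(weights[:, 5])
        ) + np.abs(weights[:, 2]) + np.abs(weights[:, 3])
        baseline = gain * u_max * 1.05 + baseline
    shifts = dict(context_shifts) if context_shifts is not None else dict(
        DEFAULT_CONTEXT_SHIFTS
    )
    return EncodingModel(
        baseline=baseline,
        weights=weights,
        gain=gain,
        noise_sd=noise_sd,
        nonlinearity=nonlinearity,
        context_shifts=shifts,
        shift_magnitude=shift_magnitude,
        seed=seed,
    )


def encode_sbp(
    kin: Kinematics,
    model: EncodingModel,
    context: str = "normal",
    seed: int = 0,
) -> np.ndarray:
    """Noisy SBP features for the given kinematics under one context.

    ``sbp[t, c] = max(0, expected[t, c] + noise)`` with i.i.d. Gaussian
    noise of the model's per-channel SD per bin and channel.
    """
    expected = model.expected_sbp(kin, context=context)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, 1.0, expected.shape) * model.noise_sd[None, :]
    return np.maximum(expected + noise, 0.0)


# --------------------------------------------------------------------------
# Whole sessions
# --------------------------------------------------------------------------


def generate_session(
    task_config: TaskConfig,
    encoding_model: EncodingModel | None = None,
    contexts: list[tuple[str, int]] | None = None,
    seed: int | None = None,
    n_channels: int = 96,
    nonlinearity: str = "saturating",
) -> BinnedSession:
    """Generate a full binned session, optionally with context blocks.

    ``contexts`` is an ordered list of (label, n_trials) block definitions;
    when omitted a single "normal" block of ``task_config.n_trials`` is
    generated.  All randomness derives from ``seed`` (default: the task
    config's seed) through independent child streams per block.
    """
    if contexts is None:
        contexts = [("normal", task_config.n_trials)]
    for label, count in contexts:
        if count < 1:
            raise ValueError(f"context {label!r} must have >= 1 trials")
    root = task_config.seed if seed is None else seed
    ss = np.random.SeedSequence(root)
    children = ss.spawn(2 * len(contexts) + 1)
    if encoding_model is None:
        encoding_model = generate_encoding_model(
            n_channels,
            nonlinearity=nonlinearity,
            seed=int(children[-1].generate_state(1)[0] % (2**31)),
        )

    pos_parts: list[np.ndarray] = []
    sbp_parts: list[np.ndarray] = []
    trial_frames: list[pd.DataFrame] = []
    offset = 0
    for i, (label, count) in enumerate(contexts):
        block_cfg = TaskConfig(
            **{
                **task_config.__dict__,
                "n_trials": count,
                "seed": int(children[2 * i].generate_state(1)[0] % (2**31)),
            }
        )
        kin, trials = generate_task_trials(block_cfg, context=label)
        sbp = encode_sbp(
            kin,
            encoding_model,
            context=label,
            seed=int(children[2 * i + 1].generate_state(1)[0] % (2**31)),
        )
        frame = trials.frame.copy()
        frame["start_bin"] += offset
        frame["end_bin"] += offset
        offset += kin.n_bins
        pos_parts.append(kin.position)
        sbp_parts.append(sbp)
        trial_frames.append(frame)

    position = np.vstack(pos_parts)
    kin = Kinematics.from_position(position, bin_ms=task_config.bin_ms)
    trials = TrialTable(pd.concat(trial_frames, ignore_index=True))
    return BinnedSession(
        sbp=np.vstack(sbp_parts),
        kinematics=kin,
        trials=trials,
        metadata={
            "seed": root,
            "bin_ms": task_config.bin_ms,
            "nonlinearity": encoding_model.nonlinearity,
            "prebinned": 1,
        },
    )


# --------------------------------------------------------------------------
# Raw broadband fixture for the feature chain
# --------------------------------------------------------------------------


def generate_raw_segment(
    duration_s: float,
    fs: float,
    band_power_profile: dict,
    seed: int = 0,
) -> np.ndarray:
    """Band-limited Gaussian noise for validating the SBP feature chain.

    ``band_power_profile`` is ``{"band": (lo_hz, hi_hz), "power": var}``;
    zero power yields an all-zero signal.
    """
    if fs < 2000:
        raise ValueError("fs must be >= 2000 Hz")
    n = int(round(duration_s * fs))
    power = float(band_power_profile.get("power", 0.0))
    if power <= 0.0:
        return np.zeros(n)
    lo, hi = band_power_profile["band"]
    rng = np.random.default_rng(seed)
    white = rng.normal(0.0, 1.0, n)
    sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    sig = sosfiltfilt(sos, white)
    sig *= np.sqrt(power / max(np.var(sig), 1e-30))
    return sig
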