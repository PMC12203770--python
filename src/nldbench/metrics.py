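"""Evaluation metrics for offline decoder predictions and trial behavior.

Covers the standard offline suite — velocity MSE, high/low speed-regime
statistics, velocity-distribution KL divergence, across-instance prediction
deviation — and the trial-based metrics used for (simulated or replayed)
online blocks: time-to-target, orbiting time and rate, and Fitts-law
throughput.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

KL_EPS = 1e-9


# --------------------------------------------------------------------------
# Error and speed regimes
# --------------------------------------------------------------------------


def mse(pred: np.ndarray, true: np.ndarray) -> float:
    """Mean squared error over all bins and DOFs."""
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape:
        raise ValueError("prediction and truth shapes differ")
    return float(np.mean((pred - true) ** 2))


def group_mse(mses: np.ndarray) -> tuple[float, float]:
    """Mean and standard error across decoder instances of one type."""
    mses = np.asarray(mses, dtype=float)
    se = mses.std(ddof=1) / np.sqrt(len(mses)) if len(mses) > 1 else 0.0
    return float(mses.mean()), float(se)


def speed_regime_masks(
    true_velocities: np.ndarray, pct: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """High/low-speed masks over the pooled (bins x DOFs) speeds.

    Speed is |velocity| per DOF; the masks select pooled entries strictly
    above the (100 - pct)th and strictly below the pct-th percentile
    (linear-interpolation percentiles).  With constant speeds both masks
    are empty.
    """
    v = np.asarray(true_velocities, dtype=float)
    if v.size == 0:
        raise ValueError("empty velocities")
    speed = np.abs(v).ravel()
    hi = np.percentile(speed, 100.0 - pct)
    lo = np.percentile(speed, pct)
    return (speed > hi).reshape(v.shape), (speed < lo).reshape(v.shape)


def regime_stats(
    pred: np.ndarray, true: np.ndarray, mask: np.ndarray
) -> dict[str, float]:
    """Mean predicted/true speed and MSE restricted to one regime mask.

    The mask addresses pooled (bin, DOF) entries.  An empty mask yields
    NaNs (reported as missing).
    """
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if not mask.any():
        return {"mean_pred_speed": np.nan, "mean_true_speed": np.nan, "mse": np.nan}
    p = pred[mask]
    t = true[mask]
    return {
        "mean_pred_speed": float(np.abs(p).mean()),
        "mean_true_speed": float(np.abs(t).mean()),
        "mse": float(np.mean((p - t) ** 2)),
    }


def relative_difference(value: float, reference: float) -> float:
    """(value - reference) / reference, as used for decoder-vs-reference
    regime comparisons."""
    return (value - reference) / reference


# --------------------------------------------------------------------------
# Velocity distributions
# --------------------------------------------------------------------------


@dataclass
class VelocityPMF:
    edges: np.ndarray
    masses: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.edges) > 0):
            raise ValueError("edges must be strictly increasing")
        if abs(self.masses.sum() - 1.0) > 1e-12:
            raise ValueError("masses must sum to 1")


def histogram_edges(reference_velocities: np.ndarray, n_bins: int = 100) -> np.ndarray:
    """Shared histogram edges spanning the reference (hand-control)
    velocity range."""
    v = np.asarray(reference_velocities, dtype=float).ravel()
    lo, hi = v.min(), v.max()
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    return np.linspace(lo, hi, n_bins + 1)


def velocity_pmf(
    velocities: np.ndarray, edges: np.ndarray, source: str = ""
) -> VelocityPMF:
    """Empirical PMF of pooled (bins x DOFs) velocities on shared edges.

    Values outside the edge span are clipped into the end bins.
    """
    v = np.asarray(velocities, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty velocity input")
    edges = np.asarray(edges, dtype=float)
    clipped = np.clip(v, edges[0], edges[-1])
    counts, _ = np.histogram(clipped, bins=edges)
    return VelocityPMF(edges=edges, masses=counts / counts.sum(), source=source)


def kl_divergence(p: VelocityPMF, q: VelocityPMF) -> float:
    """KL(p || q) in nats with q floored at a small epsilon.

    Zero-mass p bins contribute nothing; q is floored at 1e-9 and
    renormalized so the divergence is finite for empirical histograms.
    """
    if p.edges.shape != q.edges.shape or not np.allclose(p.edges, q.edges):
        raise ValueError("PMFs must share identical edges")
    qm = np.maximum(q.masses, KL_EPS)
    qm = qm / qm.sum()
    mask = p.masses > 0
    return float(np.sum(p.masses[mask] * np.log(p.masses[mask] / qm[mask])))


# --------------------------------------------------------------------------
# Convergence consistency
# --------------------------------------------------------------------------


def median_prediction_deviation(prediction_sets: list[np.ndarray]) -> float:
    """Median over (time, DOF) of the across-instance sample SD.

    ``prediction_sets`` holds the aligned (N, 2) predictions of >= 2
    identically-trained instances of one decoder type.
    """
    if len(prediction_sets) < 2:
        raise ValueError("need at least 2 decoder instances")
    stack = np.stack([np.asarray(p, dtype=float) for p in prediction_sets])
    if any(p.shape != stack[0].shape for p in stack[1:]):
        raise ValueError("instances must be aligned")
    sd = stack.std(axis=0, ddof=1)
    return float(np.median(sd))


# --------------------------------------------------------------------------
# Trial metrics
# --------------------------------------------------------------------------


@dataclass
class TrialEvents:
    first_acquisition_bin: int | None
    final_acquisition_bin: int | None
    success: bool


def trial_events(
    positions: np.ndarray,
    target_centers: np.ndarray,
    target_width: float,
    hold_time_ms: float,
    bin_ms: float = 50.0,
    timeout_ms: float | None = None,
) -> TrialEvents:
    """Acquisition events for one trial.

    In-target means |position - center| <= width/2 on both DOFs (closed
    interval).  First acquisition is the first in-target bin; final
    acquisition is the start of the terminal in-target run that completes
    the hold; success requires the hold to finish before the timeout.
    """
    pos = np.asarray(positions, dtype=float)
    centers = np.asarray(target_centers, dtype=float)
    inside = (np.abs(pos - centers[None, :]) <= target_width / 2.0).all(axis=1)
    if not inside.any():
        return TrialEvents(None, None, False)
    first = int(np.argmax(inside))
    hold_bins = int(round(hold_time_ms / bin_ms))
    timeout_bins = (
        int(round(timeout_ms / bin_ms)) if timeout_ms is not None else len(inside)
    )
    # Scan in-target runs for the first that completes the hold.
    t = first
    n = len(inside)
    while t < n:
        if inside[t]:
            run_start = t
            while t < n and inside[t]:
                t += 1
            run_len = t - run_start
            if run_len >= hold_bins and run_start + hold_bins <= timeout_bins:
                return TrialEvents(first, run_start, True)
        else:
            t += 1
    return TrialEvents(first, None, False)


def trial_metrics(
    events: TrialEvents, bin_ms: float = 50.0
) -> dict[str, float | bool]:
    """Time-to-target and orbiting time for one trial, in ms."""
    if events.first_acquisition_bin is None:
        return {"tt_ms": np.nan, "ot_ms": np.nan, "acquired": False,
                "success": events.success}
    tt = events.first_acquisition_bin * bin_ms
    if events.final_acquisition_bin is None:
        ot = np.nan
    else:
        ot = (events.final_acquisition_bin - events.first_acquisition_bin) * bin_ms
    return {"tt_ms": tt, "ot_ms": ot, "acquired": True, "success": events.success}


def summarize_trials(per_trial: list[dict]) -> dict[str, float]:
    """Aggregate trial metrics the way online blocks are reported.

    Mean TT excludes zero-TT trials; orbiting rate is the fraction of
    trials with nonzero OT; mean OT uses nonzero OTs only.  Empty
    selections are reported as NaN.
    """
    tts = np.array([t["tt_ms"] for t in per_trial], dtype=float)
    ots = np.array([t["ot_ms"] for t in per_trial], dtype=float)
    nonzero_tt = tts[np.isfinite(tts) & (tts > 0)]
    finite_ot = ots[np.isfinite(ots)]
    nonzero_ot = finite_ot[finite_ot > 0]
    return {
        "mean_tt_ms": float(nonzero_tt.mean()) if len(nonzero_tt) else np.nan,
        "orbiting_rate": float((finite_ot > 0).mean()) if len(finite_ot) else np.nan,
        "mean_nonzero_ot_ms": float(nonzero_ot.mean()) if len(nonzero_ot) else np.nan,
        "success_rate": float(np.mean([t["success"] for t in per_trial])),
        "n_trials": len(per_trial),
    }


def fitts_throughput(
    start_positions: np.ndarray,
    target_centers: np.ndarray,
    target_widths: np.ndarray | float,
    acquisition_time_s: float,
) -> float:
    """Fitts-law throughput in bits/s.

    Index of difficulty sums log2(1 + D/W) over DOFs, with D the distance
    from the trial-start position to the target center and W the target
    width; throughput divides by the acquisition time.
    """
    if acquisition_time_s <= 0:
        raise ValueError("acquisition time must be > 0")
    d = np.abs(np.asarray(target_centers, dtype=float)
               - np.asarray(start_positions, dtype=float))
    w = np.broadcast_to(np.asarray(target_widths, dtype=float), d.shape)
    if np.any(w <= 0):
        raise ValueError("target width must be > 0")
    index_of_difficulty = np.sum(np.log2(1.0 + d / w))
    return float(index_of_difficulty / acquisition_time_s)
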