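"""Linear decoders: ridge regression and the dual-state movement/posture
decoder.

Ridge is the representative offline linear decoder (lambda 0.001 on
standardized features, bias unpenalized).  The dual-state decoder blends a
"movement" regression fit on high-speed bins with a "posture" regression
fit on low-speed bins, weighted by an LDA state classifier whose decision
threshold adapts online to maintain a target fast/slow classification
ratio (1:1 by default) over a sliding window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

DEFAULT_LAMBDA = 0.001

MODEL_SCHEMA_VERSION = 1


def _flatten(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x.reshape(x.shape[0], -1) if x.ndim > 2 else x


@dataclass
class RidgeModel:
    """Affine map from flattened feature windows to 2-DOF velocity."""

    weights: np.ndarray  # (D, 2)
    bias: np.ndarray  # (2,)
    lam: float
    x_mean: np.ndarray
    x_sd: np.ndarray

    def predict(self, windows: np.ndarray) -> np.ndarray:
        x = _flatten(windows)
        if x.shape[1] != self.weights.shape[0]:
            raise ValueError(
                f"window width {x.shape[1]} does not match training width "
                f"{self.weights.shape[0]}"
            )
        z = (x - self.x_mean) / self.x_sd
        return z @ self.weights + self.bias


def fit_ridge(
    windows: np.ndarray, velocities: np.ndarray, lam: float = DEFAULT_LAMBDA
) -> RidgeModel:
    """Closed-form ridge on standardized features with unpenalized bias.

    Solves ``min ||Y - ZW - b||^2 + lam * ||W||^2`` where Z are the
    z-scored features; the bias absorbs the target means exactly.
    """
    x = _flatten(windows)
    y = np.asarray(velocities, dtype=float)
    if x.shape[0] != y.shape[0] or x.shape[0] == 0:
        raise ValueError("windows and velocities must align and be nonempty")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    x_mean = x.mean(axis=0)
    x_sd = x.std(axis=0)
    x_sd = np.where(x_sd < 1e-12, 1.0, x_sd)
    z = (x - x_mean) / x_sd
    y_mean = y.mean(axis=0)
    yc = y - y_mean
    zc_mean = z.mean(axis=0)
    zc = z - zc_mean
    gram = zc.T @ zc + lam * np.eye(z.shape[1])
    try:
        w = np.linalg.solve(gram, zc.T @ yc)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular normal equations; use lam > 0"
        ) from err
    if lam == 0.0 and not np.all(np.isfinite(w)):
        raise np.linalg.LinAlgError("singular normal equations; use lam > 0")
    bias = y_mean - zc_mean @ w
    return RidgeModel(weights=w, bias=bias, lam=lam, x_mean=x_mean, x_sd=x_sd)


def predict_ridge(model: RidgeModel, windows: np.ndarray) -> np.ndarray:
    return model.predict(windows)


def save_ridge(model: RidgeModel, path, provenance: dict | None = None) -> None:
    """Serialize a ridge model to a single JSON file."""
    import json
    from pathlib import Path

    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "weights": model.weights.tolist(),
        "bias": model.bias.tolist(),
        "lam": model.lam,
        "x_mean": model.x_mean.tolist(),
        "x_sd": model.x_sd.tolist(),
        "provenance": provenance or {},
    }
    Path(path).write_text(json.dumps(payload))


def load_ridge(path) -> RidgeModel:
    import json
    from pathlib import Path

    payload = json.loads(Path(path).read_text())
    return RidgeModel(
        weights=np.array(payload["weights"]),
        bias=np.array(payload["bias"]),
        lam=payload["lam"],
        x_mean=np.array(payload["x_mean"]),
        x_sd=np.array(payload["x_sd"]),
    )


# --------------------------------------------------------------------------
# Dual-state decoder
# --------------------------------------------------------------------------


def speed_state_labels(
    velocities: np.ndarray, percentile: float = 50.0
) -> np.ndarray:
    """Boolean fast/slow labels from a pooled-speed percentile split.

    Speed is pooled across DOFs per bin as the mean |v|; bins above the
    given percentile (median by default) are labeled "movement" (True).
    """
    speed = np.abs(np.asarray(velocities, dtype=float)).mean(axis=1)
    return speed > np.percentile(speed, percentile)


@dataclass
class DualStateModel:
    movement: RidgeModel
    posture: RidgeModel
    lda: LinearDiscriminantAnalysis
    x_mean: np.ndarray
    x_sd: np.ndarray
    target_fast_fraction: float = 0.5
    window_bins: int = 100
    step_size: float = 0.01
    threshold: float = field(default=0.5)

    def posterior_fast(self, windows: np.ndarray) -> np.ndarray:
        z = (_flatten(windows) - self.x_mean) / self.x_sd
        return self.lda.predict_proba(z)[:, 1]


def fit_dual_state(
    windows: np.ndarray,
    velocities: np.ndarray,
    speed_labels: np.ndarray | None = None,
    lam: float = DEFAULT_LAMBDA,
    target_fast_fraction: float = 0.5,
) -> DualStateModel:
    """Fit movement/posture regressions on fast/slow bins plus an LDA state
    classifier on the same features."""
    x = _flatten(windows)
    y = np.asarray(velocities, dtype=float)
    if speed_labels is None:
        speed_labels = speed_state_labels(y)
    speed_labels = np.asarray(speed_labels, dtype=bool)
    if speed_labels.all() or (~speed_labels).all():
        raise ValueError("both movement and posture classes must be nonempty")
    movement = fit_ridge(x[speed_labels], y[speed_labels], lam=lam)
    posture = fit_ridge(x[~speed_labels], y[~speed_labels], lam=lam)
    x_mean = x.mean(axis=0)
    x_sd = x.std(axis=0)
    x_sd = np.where(x_sd < 1e-12, 1.0, x_sd)
    lda = LinearDiscriminantAnalysis()
    lda.fit((x - x_mean) / x_sd, speed_labels.astype(int))
    return DualStateModel(
        movement=movement,
        posture=posture,
        lda=lda,
        x_mean=x_mean,
        x_sd=x_sd,
        target_fast_fraction=target_fast_fraction,
    )


def predict_dual_state(
    model: DualStateModel,
    window_stream: np.ndarray,
    return_state: bool = False,
) -> np.ndarray | tuple[np.ndarray, dict]:
    """Stateful streaming prediction with the adaptive threshold.

    Per step the LDA posterior p is shifted against the current threshold
    (``p_fast = clip(p + 0.5 - threshold, 0, 1)``, the identity at
    threshold 0.5) and the output is the p_fast-weighted blend of the
    movement and posture regressions.  The threshold is nudged by an
    additive step toward making the sliding-window fraction of fast
    classifications (p > threshold) equal the target ratio.
    """
    posterior = model.posterior_fast(window_stream)
    pred_move = model.movement.predict(window_stream)
    pred_post = model.posture.predict(window_stream)

    threshold = model.threshold
    window: list[bool] = []
    p_fast_trace = np.empty_like(posterior)
    fast_trace = np.empty(posterior.shape[0], dtype=bool)
    thr_trace = np.empty_like(posterior)
    for t, p in enumerate(posterior):
        fast = bool(p > threshold)
        window.append(fast)
        if len(window) > model.window_bins:
            window.pop(0)
        p_fast = float(np.clip(p + (0.5 - threshold), 0.0, 1.0))
        p_fast_trace[t] = p_fast
        fast_trace[t] = fast
        thr_trace[t] = threshold
        frac = float(np.mean(window))
        threshold += model.step_size * (frac - model.target_fast_fraction)
        threshold = float(np.clip(threshold, 0.0, 1.0))

    out = p_fast_trace[:, None] * pred_move + (1.0 - p_fast_trace[:, None]) * pred_post
    if return_state:
        return out, {
            "p_fast": p_fast_trace,
            "fast": fast_trace,
            "threshold": thr_trace,
            "posterior": posterior,
        }
    return out
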