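"""Network decoders: the temporally-convolved feedforward network (TCN),
its regularization ablations, the LSTM, ReFIT recalibration, output
rescaling, and velocity redistribution.

The TCN applies a bank of time-wise convolutional filters to each SBP
channel independently across the 3-bin (150 ms) history window, then a
fully connected stack with optional batch normalization and dropout, and
a 2-unit linear output predicting normalized finger velocities.  Ablating
batchnorm and/or dropout gives the onlyDP / onlyBN / noBNDP variants.
Networks predict in normalized velocity space; two independent
single-weight/single-bias regressions (one per DOF) map predictions back
to flex/s.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from nldbench import nn


# --------------------------------------------------------------------------
# Configs
# --------------------------------------------------------------------------


@dataclass
class TCNConfig:
    n_channels: int = 96
    n_history: int = 2  # lookback bins; window = n_history + 1 bins
    n_filters: int = 16
    hidden: tuple[int, ...] = (256, 256)
    use_batchnorm: bool = True
    use_dropout: bool = True
    dropout: float = 0.5
    n_out: int = 2

    @property
    def window_bins(self) -> int:
        return self.n_history + 1


#: Named ablations of the TCN's regularization.
TCN_VARIANTS = {
    "tcn": dict(use_batchnorm=True, use_dropout=True),
    "onlybn": dict(use_batchnorm=True, use_dropout=False),
    "onlydp": dict(use_batchnorm=False, use_dropout=True),
    "nobndp": dict(use_batchnorm=False, use_dropout=False),
}


def variant_config(base: TCNConfig, variant: str) -> TCNConfig:
    if variant not in TCN_VARIANTS:
        raise ValueError(f"unknown TCN variant {variant!r}")
    return replace(base, **TCN_VARIANTS[variant])


@dataclass
class TrainConfig:
    lr: float = 1e-4
    weight_decay: float = 1e-2
    epochs: int | None = 10
    iterations: int | None = None
    batch_size: int = 32
    seed: int = 0
    redistribute: str | None = None  # None or "triangular"
    normalize_inputs: bool = False
    normalize_outputs: bool = True

    def __post_init__(self) -> None:
        if (self.epochs is None) == (self.iterations is None):
            raise ValueError("set exactly one of epochs/iterations")


#: Training budgets by variant: the ablated models without batchnorm get a
#: longer budget (80 epochs vs 10) because they train more slowly.
VARIANT_EPOCHS = {"tcn": 10, "onlybn": 10, "onlydp": 80, "nobndp": 80}
NORMALIZED_DATA_EPOCHS = 15


@dataclass
class LSTMConfig:
    n_channels: int = 96
    hidden_size: int = 300
    seq_len: int = 20
    bias_noise_sd: float = 0.1
    white_noise_sd: float = 0.2
    lr: float = 2e-4
    weight_decay: float = 0.003
    plateau_patience: int = 800
    plateau_steps: int = 2
    plateau_factor: float = 0.5
    epochs: int = 10
    batch_size: int = 512
    seed: int = 0


# --------------------------------------------------------------------------
# Output rescaling
# --------------------------------------------------------------------------


@dataclass
class OutputRescaler:
    """Two independent scalar affine maps, one per DOF."""

    weight: np.ndarray  # (2,)
    bias: np.ndarray  # (2,)

    def apply(self, preds: np.ndarray) -> np.ndarray:
        return preds * self.weight[None, :] + self.bias[None, :]


def fit_output_rescaler(
    normalized_preds: np.ndarray, true_velocities: np.ndarray
) -> OutputRescaler:
    """Per-DOF 1-D least squares mapping normalized predictions to flex/s."""
    p = np.asarray(normalized_preds, dtype=float)
    y = np.asarray(true_velocities, dtype=float)
    if p.shape != y.shape or p.shape[0] < 2:
        raise ValueError("need >= 2 aligned prediction/velocity rows per DOF")
    weight = np.empty(p.shape[1])
    bias = np.empty(p.shape[1])
    for d in range(p.shape[1]):
        var = np.var(p[:, d])
        if var < 1e-15:
            raise ValueError(f"zero-variance predictions in DOF {d}")
        weight[d] = np.cov(p[:, d], y[:, d], ddof=0)[0, 1] / var
        bias[d] = y[:, d].mean() - weight[d] * p[:, d].mean()
    return OutputRescaler(weight=weight, bias=bias)


# --------------------------------------------------------------------------
# TCN
# --------------------------------------------------------------------------


def build_tcn(config: TCNConfig, seed: int = 0) -> nn.Sequential:
    """Assemble the TCN: channel-wise temporal conv, FC stack, linear out."""
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = [
        nn.ChannelTemporalConv(config.window_bins, config.n_filters, rng)
    ]
    width = config.n_channels * config.n_filters
    if config.use_batchnorm:
        layers.append(nn.BatchNorm(width))
    layers.append(nn.ReLU())
    for h in config.hidden:
        layers.append(nn.Linear(width, h, rng))
        if config.use_batchnorm:
            layers.append(nn.BatchNorm(h))
        layers.append(nn.ReLU())
        if config.use_dropout:
            layers.append(nn.Dropout(config.dropout, rng))
        width = h
    layers.append(nn.Linear(width, config.n_out, rng))
    return nn.Sequential(layers)


class _Normalizer:
    def __init__(self, data: np.ndarray, enabled: bool = True):
        if enabled:
            self.mean = data.mean(axis=0)
            sd = data.std(axis=0)
            self.sd = np.where(sd < 1e-12, 1.0, sd)
        else:
            self.mean = np.zeros(data.shape[1:])
            self.sd = np.ones(data.shape[1:])

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.sd


@dataclass
class TrainedDecoder:
    """Uniform window -> flex/s velocity prediction contract."""

    kind: str
    net: object
    x_norm: _Normalizer
    rescaler: OutputRescaler
    loss_trace: list[float] = field(default_factory=list)
    config: object = None
    train_config: object = None
    iterations: int = 0

    def predict(self, windows: np.ndarray) -> np.ndarray:
        x = self.x_norm.apply(np.asarray(windows, dtype=float)).astype(nn.DTYPE)
        out = self.net.forward(x, training=False)
        return self.rescaler.apply(np.asarray(out, dtype=float))


def train_network(
    net: nn.Sequential,
    windows: np.ndarray,
    velocities: np.ndarray,
    train_config: TrainConfig,
    config: TCNConfig | None = None,
) -> TrainedDecoder:
    """Train a feedforward decoder to minimize velocity MSE with Adam.

    Targets are z-scored per DOF; predictions are mapped back to flex/s by
    a per-DOF output rescaler fit on the training set.  The per-epoch
    training loss trace (normalized-space MSE) is recorded.
    """
    x = np.asarray(windows, dtype=float)
    y = np.asarray(velocities, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("windows and velocities must align")
    rng = np.random.default_rng(train_config.seed)

    if train_config.redistribute == "triangular":
        idx = redistribute_velocities(
            np.arange(x.shape[0]), y, mode="triangular",
            seed=int(rng.integers(2**31)),
        )
        x, y = x[idx], y[idx]
    elif train_config.redistribute is not None:
        raise ValueError("redistribute must be None or 'triangular'")

    x_norm = _Normalizer(x, enabled=train_config.normalize_inputs)
    y_norm = _Normalizer(y, enabled=train_config.normalize_outputs)
    xs = x_norm.apply(x).astype(nn.DTYPE)
    ys = y_norm.apply(y).astype(nn.DTYPE)

    opt = nn.Adam(net.params, net.grads, lr=train_config.lr,
                  weight_decay=train_config.weight_decay)
    n = xs.shape[0]
    bs = min(train_config.batch_size, n)
    steps_per_epoch = max(1, n // bs)
    if train_config.epochs is not None:
        n_epochs = train_config.epochs
        max_iters = None
    else:
        max_iters = train_config.iterations
        n_epochs = int(np.ceil(max_iters / steps_per_epoch)) if max_iters else 0

    loss_trace: list[float] = []
    it = 0
    for _ in range(n_epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for s in range(steps_per_epoch):
            batch = order[s * bs : (s + 1) * bs]
            pred = net.forward(xs[batch], training=True)
            err = pred - ys[batch]
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at iteration {it}"
                )
            net.backward((2.0 / err.size * err).astype(nn.DTYPE))
            opt.step()
            epoch_losses.append(loss)
            it += 1
            if max_iters is not None and it >= max_iters:
                break
        loss_trace.append(float(np.mean(epoch_losses)))
        if max_iters is not None and it >= max_iters:
            break

    train_preds = _forward_in_chunks(net, xs)
    rescaler = fit_output_rescaler(train_preds, y)
    return TrainedDecoder(
        kind="tcn",
        net=net,
        x_norm=x_norm,
        rescaler=rescaler,
        loss_trace=loss_trace,
        config=config,
        train_config=train_config,
        iterations=it,
    )


def _forward_in_chunks(net, xs: np.ndarray, chunk: int = 4096) -> np.ndarray:
    outs = [
        np.asarray(net.forward(xs[i : i + chunk], training=False), dtype=float)
        for i in range(0, xs.shape[0], chunk)
    ]
    return np.vstack(outs)


def train_tcn(
    windows: np.ndarray,
    velocities: np.ndarray,
    config: TCNConfig | None = None,
    train_config: TrainConfig | None = None,
    seed: int = 0,
) -> TrainedDecoder:
    """Convenience wrapper: build and train a TCN (or ablated variant)."""
    config = config or TCNConfig(
        n_channels=np.asarray(windows).shape[1],
        n_history=np.asarray(windows).shape[2] - 1,
    )
    train_config = train_config or TrainConfig(seed=seed)
    net = build_tcn(config, seed=seed)
    dec = train_network(net, windows, velocities, train_config, config=config)
    return dec


# --------------------------------------------------------------------------
# LSTM
# --------------------------------------------------------------------------


def build_sequences(
    binned: np.ndarray,
    bins: np.ndarray,
    trial_starts: np.ndarray,
    seq_len: int = 20,
) -> np.ndarray:
    """Index matrix of within-trial sequences ending at each selected bin.

    ``trial_starts[k]`` is the first bin of the trial containing
    ``bins[k]``; sequences shorter than ``seq_len`` are padded at the front
    by repeating the trial's first bin, so sequences never cross a trial
    boundary.  Returns an (N, seq_len) int index array into ``binned``.
    """
    bins = np.asarray(bins, dtype=int)
    trial_starts = np.asarray(trial_starts, dtype=int)
    offsets = np.arange(-(seq_len - 1), 1)
    idx = bins[:, None] + offsets[None, :]
    return np.maximum(idx, trial_starts[:, None])


def train_lstm(
    binned: np.ndarray,
    bins: np.ndarray,
    velocities: np.ndarray,
    trial_starts: np.ndarray,
    config: LSTMConfig | None = None,
) -> TrainedDecoder:
    """Train the LSTM decoder on within-trial sequences.

    Inputs and targets are normalized for training; channel bias noise
    (SD 0.1) and white noise (SD 0.2) are injected per batch; loss is the
    MSE of the final sequence output; a plateau scheduler halves the
    learning rate after the configured patience, at most twice.
    """
    config = config or LSTMConfig(n_channels=binned.shape[1])
    y = np.asarray(velocities, dtype=float)
    seq_idx = build_sequences(binned, bins, trial_starts, config.seq_len)
    rng = np.random.default_rng(config.seed)

    x_norm = _Normalizer(binned[np.asarray(bins, dtype=int)])
    y_norm = _Normalizer(y)
    xs = x_norm.apply(binned).astype(nn.DTYPE)
    ys = y_norm.apply(y).astype(nn.DTYPE)

    net = nn.LSTM(config.n_channels, config.hidden_size, y.shape[1],
                  rng=np.random.default_rng(config.seed))
    opt = nn.Adam(net.params, net.grads, lr=config.lr,
                  weight_decay=config.weight_decay)

    n = seq_idx.shape[0]
    bs = min(config.batch_size, n)
    steps_per_epoch = max(1, n // bs)
    best = np.inf
    since_best = 0
    lr_steps = 0
    loss_trace: list[float] = []
    it = 0
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for s in range(steps_per_epoch):
            batch = order[s * bs : (s + 1) * bs]
            xb = xs[seq_idx[batch]]  # (B, T, C)
            xb = xb + rng.normal(
                0.0, config.bias_noise_sd, (xb.shape[0], 1, xb.shape[2])
            ).astype(nn.DTYPE)
            xb = xb + rng.normal(0.0, config.white_noise_sd, xb.shape).astype(
                nn.DTYPE
            )
            pred = net.forward(xb, training=True)
            err = pred - ys[batch]
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite LSTM training loss at iteration {it}"
                )
            net.backward((2.0 / err.size * err).astype(nn.DTYPE))
            opt.step()
            epoch_losses.append(loss)
            it += 1
            # Plateau scheduler on the running batch loss.
            if loss < best - 1e-6:
                best = loss
                since_best = 0
            else:
                since_best += 1
                if since_best >= config.plateau_patience and lr_steps < config.plateau_steps:
                    opt.lr *= config.plateau_factor
                    lr_steps += 1
                    since_best = 0
        loss_trace.append(float(np.mean(epoch_losses)))

    dec = TrainedDecoder(
        kind="lstm",
        net=net,
        x_norm=x_norm,
        rescaler=OutputRescaler(weight=np.ones(y.shape[1]), bias=np.zeros(y.shape[1])),
        loss_trace=loss_trace,
        config=config,
        iterations=it,
    )

    # Rescaler fit on training predictions (normalized space -> flex/s).
    train_preds = _predict_sequences(net, xs, seq_idx)
    dec.rescaler = fit_output_rescaler(train_preds, y)

    dec.predict_bins = lambda binned_new, bins_new, starts_new: _lstm_predict_bins(
        net, x_norm, dec.rescaler, config.seq_len, binned_new, bins_new, starts_new
    )
    return dec


def _lstm_predict_bins(net, x_norm, rescaler, seq_len, binned, bins, trial_starts):
    xs = x_norm.apply(np.asarray(binned, dtype=float)).astype(nn.DTYPE)
    sidx = build_sequences(binned, bins, trial_starts, seq_len)
    return rescaler.apply(_predict_sequences(net, xs, sidx))


def _predict_sequences(net: nn.LSTM, xs: np.ndarray, seq_idx: np.ndarray,
                       chunk: int = 2048) -> np.ndarray:
    outs = []
    for i in range(0, seq_idx.shape[0], chunk):
        outs.append(
            np.asarray(net.forward(xs[seq_idx[i : i + chunk]], training=False),
                       dtype=float)
        )
    return np.vstack(outs)


def lstm_param_count(n_in: int, n_hidden: int) -> int:
    """Recurrent-core parameter count: 4 * ((n_in + n_hidden) * n_hidden +
    n_hidden)."""
    return 4 * ((n_in + n_hidden) * n_hidden + n_hidden)


# --------------------------------------------------------------------------
# Checkpointing
# --------------------------------------------------------------------------

CHECKPOINT_SCHEMA_VERSION = 1


def save_decoder(dec: TrainedDecoder, path, provenance: dict | None = None) -> None:
    """Write a trained network decoder to a single HDF5 checkpoint.

    Stores architecture config, weights (and batchnorm running statistics),
    input-normalization constants, the output rescaler, and provenance.
    """
    import dataclasses
    import json

    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["schema_version"] = CHECKPOINT_SCHEMA_VERSION
        h5.attrs["kind"] = dec.kind
        h5.attrs["config"] = json.dumps(dataclasses.asdict(dec.config))
        h5.attrs["provenance"] = json.dumps(provenance or {})
        state = h5.create_group("state")
        for i, arr in enumerate(dec.net.state()):
            state.create_dataset(f"p{i:03d}", data=arr)
        h5.create_dataset("x_norm/mean", data=np.asarray(dec.x_norm.mean))
        h5.create_dataset("x_norm/sd", data=np.asarray(dec.x_norm.sd))
        h5.create_dataset("rescaler/weight", data=dec.rescaler.weight)
        h5.create_dataset("rescaler/bias", data=dec.rescaler.bias)
        h5.create_dataset("loss_trace", data=np.asarray(dec.loss_trace))


def load_decoder(path) -> TrainedDecoder:
    import json

    import h5py

    with h5py.File(path, "r") as h5:
        kind = h5.attrs["kind"]
        cfg_dict = json.loads(h5.attrs["config"])
        state = [
            h5["state"][k][()] for k in sorted(h5["state"].keys())
        ]
        mean = h5["x_norm/mean"][()]
        sd = h5["x_norm/sd"][()]
        rescaler = OutputRescaler(
            weight=h5["rescaler/weight"][()], bias=h5["rescaler/bias"][()]
        )
        loss_trace = list(h5["loss_trace"][()])

    norm = _Normalizer.__new__(_Normalizer)
    norm.mean, norm.sd = mean, sd
    if kind == "lstm":
        cfg_dict["hidden"] = cfg_dict.get("hidden_size", 300)
        config = LSTMConfig(**{
            k: v for k, v in cfg_dict.items() if k in LSTMConfig.__dataclass_fields__
        })
        net = nn.LSTM(config.n_channels, config.hidden_size, len(rescaler.weight),
                      rng=np.random.default_rng(0))
        net.load_state(state)
        net.w, net.u, net.b, net.w_out, net.b_out = net.params
        dec = TrainedDecoder(kind=kind, net=net, x_norm=norm, rescaler=rescaler,
                             loss_trace=loss_trace, config=config)
        dec.predict_bins = lambda binned, bins, starts: _lstm_predict_bins(
            net, norm, rescaler, config.seq_len, binned, bins, starts
        )
        return dec
    config = TCNConfig(**{
        k: (tuple(v) if k == "hidden" else v)
        for k, v in cfg_dict.items() if k in TCNConfig.__dataclass_fields__
    })
    net = build_tcn(config, seed=0)
    net.load_state(state)
    return TrainedDecoder(kind=kind, net=net, x_norm=norm, rescaler=rescaler,
                          loss_trace=loss_trace, config=config)


# --------------------------------------------------------------------------
# ReFIT recalibration
# --------------------------------------------------------------------------


def refit_relabel(
    pred_velocities: np.ndarray,
    positions: np.ndarray,
    target_centers: np.ndarray,
    target_widths: np.ndarray | float,
) -> np.ndarray:
    """Intention-estimation relabeling of recorded decode velocities.

    Per bin and DOF: outside the target, a velocity pointing away from the
    target center has its sign flipped (magnitude preserved); inside the
    target the velocity is set to zero; toward-target velocities are
    unchanged.
    """
    v = np.array(pred_velocities, dtype=float)
    pos = np.asarray(positions, dtype=float)
    centers = np.asarray(target_centers, dtype=float)
    half = np.asarray(target_widths, dtype=float) / 2.0
    inside = np.abs(pos - centers) <= half
    toward = centers - pos  # sign of the correct direction
    away = (~inside) & (v * toward < 0)
    v[away] *= -1.0
    v[inside] = 0.0
    return v


def refit_finetune(
    decoder: TrainedDecoder,
    windows: np.ndarray,
    velocities: np.ndarray,
    iterations: int = 500,
    lr: float = 2e-4,
    batch_size: int = 512,
    seed: int = 0,
) -> TrainedDecoder:
    """Fine-tune a trained TCN on relabeled data for a fixed number of
    optimizer iterations; all other hyperparameters are inherited."""
    tuned = copy.deepcopy(decoder)
    if iterations == 0:
        return tuned
    net = tuned.net
    x = tuned.x_norm.apply(np.asarray(windows, dtype=float)).astype(nn.DTYPE)
    # Fine-tuning targets in the network's normalized output space.
    y = (
        (np.asarray(velocities, dtype=float) - tuned.rescaler.bias[None, :])
        / tuned.rescaler.weight[None, :]
    ).astype(nn.DTYPE)
    wd = decoder.train_config.weight_decay if decoder.train_config else 1e-2
    opt = nn.Adam(net.params, net.grads, lr=lr, weight_decay=wd)
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    bs = min(batch_size, n)
    for it in range(iterations):
        batch = rng.integers(0, n, bs)
        pred = net.forward(x[batch], training=True)
        err = pred - y[batch]
        net.backward((2.0 / err.size * err).astype(nn.DTYPE))
        opt.step()
    tuned.iterations = iterations
    return tuned


# --------------------------------------------------------------------------
# Velocity redistribution
# --------------------------------------------------------------------------


def redistribute_velocities(
    rows: np.ndarray,
    velocities: np.ndarray,
    mode: str | None = "triangular",
    seed: int = 0,
    n_bins: int = 50,
) -> np.ndarray:
    """Importance-resample training rows toward a triangular speed density.

    The target density is triangular on [0, max speed] with its peak at
    half the maximum; rows are drawn with replacement with weights equal to
    the ratio of the target to the empirical speed density, preserving the
    training-set size.  Returns the resampled row indices.
    """
    rows = np.asarray(rows)
    if mode is None:
        return rows
    if mode != "triangular":
        raise ValueError("mode must be None or 'triangular'")
    v = np.asarray(velocities, dtype=float)
    speed = np.abs(v).mean(axis=1)
    smax = speed.max()
    if smax <= 0:
        return rows
    c = smax / 2.0
    # Triangular(0, c, smax) density.
    target = np.where(
        speed <= c,
        2.0 * speed / (smax * c),
        2.0 * (smax - speed) / (smax * (smax - c)),
    )
    hist, edges = np.histogram(speed, bins=n_bins, range=(0.0, smax), density=True)
    which = np.clip(np.searchsorted(edges, speed, side="right") - 1, 0, n_bins - 1)
    empirical = np.maximum(hist[which], 1e-12)
    weights = np.maximum(target, 1e-12) / empirical
    weights /= weights.sum()
    rng = np.random.default_rng(seed)
    return rows[rng.choice(len(rows), size=len(rows), replace=True, p=weights)]
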