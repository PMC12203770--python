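"""End-to-end offline experiment designs.

Three experiment kinds mirror the offline analyses the package exists for:

- ``decoder_comparison``: train instances of each roster decoder per fold,
  predict the holdout, and compare MSE / speed regimes / velocity-PMF KL
  divergence against ridge regression.
- ``stability_ablation``: train many instances of the TCN and its
  regularization ablations on identical data and measure performance and
  across-instance prediction deviation.
- ``context_generalization``: train on single-context, mixed, and full
  multi-context sets and test on every single-context holdout.

Each run is seeded per (fold, decoder, instance) so partial reruns are
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nldbench import decoders as dec
from nldbench import linear, metrics, stats
from nldbench.features import windows_for_bins
from nldbench.prep import (
    FoldSplit,
    make_folds,
    make_multi_context,
    trim_and_holdout,
)
from nldbench.session import BinnedSession
from nldbench.synthetic import TaskConfig, generate_encoding_model, generate_session

DEFAULT_ROSTER = ("rr", "ds", "tcn", "lstm")
N_HISTORY = 2


@dataclass
class ExperimentConfig:
    kind: str = "decoder_comparison"
    task: TaskConfig = field(default_factory=TaskConfig)
    n_channels: int = 96
    nonlinearity: str = "saturating"
    noise_scale: float = 0.35
    shift_magnitude: float = 1.0
    roster: tuple[str, ...] = DEFAULT_ROSTER
    instances: int = 5
    n_folds: int = 5
    folds_used: int | None = None  # restrict to the first k folds
    n_keep: int = 600
    n_holdout: int = 100
    seed: int = 0
    tcn_epochs: int | None = None  # None -> per-variant default
    lstm_epochs: int = 10
    contexts: tuple[str, ...] = ("normal", "spring", "wrist", "spring-wrist")

    def __post_init__(self) -> None:
        if not self.roster:
            raise ValueError("decoder roster must be nonempty")
        if self.instances < 1:
            raise ValueError("instances must be >= 1")


# --------------------------------------------------------------------------
# Training / prediction on sessions
# --------------------------------------------------------------------------


def _dataset(session: BinnedSession, trial_indices: np.ndarray):
    """(windows, velocities, bins, trial_starts) for a trial selection."""
    bins = session.trial_bins(trial_indices)
    windows, kept = windows_for_bins(session.sbp, bins, n_history=N_HISTORY)
    velocities = session.kinematics.velocity[kept]
    f = session.trials.frame
    starts = np.zeros(len(kept), dtype=int)
    tidx = session.trials.bin_trial_index(session.n_bins)
    starts = f.start_bin.to_numpy()[tidx[kept]]
    return windows, velocities, kept, starts


def train_decoder(
    kind: str,
    session: BinnedSession,
    trial_indices: np.ndarray,
    seed: int,
    config: ExperimentConfig | None = None,
):
    """Train one decoder instance of the given kind on the given trials."""
    windows, velocities, bins, starts = _dataset(session, trial_indices)
    if kind == "rr":
        return linear.fit_ridge(windows, velocities)
    if kind == "ds":
        return linear.fit_dual_state(windows, velocities)
    if kind.startswith("tcn"):
        variant = kind[4:] if "-" in kind else "tcn"
        base = dec.TCNConfig(n_channels=session.n_channels, n_history=N_HISTORY)
        tcn_cfg = dec.variant_config(base, variant)
        epochs = (
            config.tcn_epochs
            if config is not None and config.tcn_epochs is not None
            else dec.VARIANT_EPOCHS[variant]
        )
        tc = dec.TrainConfig(epochs=epochs, seed=seed)
        return dec.train_tcn(windows, velocities, config=tcn_cfg,
                             train_config=tc, seed=seed)
    if kind == "lstm":
        epochs = config.lstm_epochs if config is not None else 10
        cfg = dec.LSTMConfig(n_channels=session.n_channels, seed=seed,
                             epochs=epochs)
        return dec.train_lstm(session.sbp, bins, velocities, starts, config=cfg)
    raise ValueError(f"unknown decoder kind {kind!r}")


def predict_decoder(
    model, kind: str, session: BinnedSession, trial_indices: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(predictions, aligned true velocities) on the given trials."""
    windows, velocities, bins, starts = _dataset(session, trial_indices)
    if kind == "rr":
        return model.predict(windows), velocities
    if kind == "ds":
        return linear.predict_dual_state(model, windows), velocities
    if kind.startswith("tcn"):
        return model.predict(windows), velocities
    if kind == "lstm":
        return model.predict_bins(session.sbp, bins, starts), velocities
    raise ValueError(f"unknown decoder kind {kind!r}")


def _instance_seed(base: int, fold: int, kind: str, instance: int) -> int:
    h = np.random.SeedSequence(
        [base, fold, instance, abs(hash(kind)) % (2**31)]
    )
    return int(h.generate_state(1)[0] % (2**31))


# --------------------------------------------------------------------------
# Reports
# --------------------------------------------------------------------------


@dataclass
class MetricsReport:
    per_instance: pd.DataFrame
    summary: pd.DataFrame
    comparisons: pd.DataFrame | None = None
    predictions: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def save(self, prefix) -> None:
        self.per_instance.to_csv(f"{prefix}_instances.csv", index=False)
        self.summary.to_csv(f"{prefix}_summary.csv", index=False)
        if self.comparisons is not None:
            self.comparisons.to_csv(f"{prefix}_comparisons.csv", index=False)


def _session_for(config: ExperimentConfig, multi_context: bool) -> BinnedSession:
    model = generate_encoding_model(
        config.n_channels,
        nonlinearity=config.nonlinearity,
        seed=config.seed + 1,
        noise_scale=config.noise_scale,
        shift_magnitude=config.shift_magnitude,
    )
    contexts = (
        [(c, config.task.n_trials) for c in config.contexts]
        if multi_context
        else None
    )
    return generate_session(
        config.task, encoding_model=model, contexts=contexts, seed=config.seed
    )


# --------------------------------------------------------------------------
# Experiment 1: decoder comparison
# --------------------------------------------------------------------------


def run_decoder_comparison(
    config: ExperimentConfig, session: BinnedSession | None = None
) -> MetricsReport:
    """Train roster decoders per fold, test on the holdout, compare to RR."""
    if session is None:
        session = _session_for(config, multi_context=False)
    kept, holdout = trim_and_holdout(
        session.trials, n_keep=config.n_keep, n_holdout=config.n_holdout
    )
    split = make_folds(kept, seed=config.seed, n_folds=config.n_folds)
    folds = split.folds[: config.folds_used or config.n_folds]

    _, true_hold, hold_bins, _ = _dataset(session, holdout)
    edges = metrics.histogram_edges(true_hold)
    pmf_true = metrics.velocity_pmf(true_hold, edges, source="hand control")
    high_mask, low_mask = metrics.speed_regime_masks(true_hold)

    rows = []
    predictions: dict = {}
    for fold_id, fold in enumerate(folds):
        for kind in config.roster:
            for inst in range(config.instances):
                seed = _instance_seed(config.seed, fold_id, kind, inst)
                model = train_decoder(kind, session, fold["train"], seed, config)
                pred, true = predict_decoder(model, kind, session, holdout)
                predictions[(kind, fold_id, inst)] = pred
                hi = metrics.regime_stats(pred, true, high_mask)
                lo = metrics.regime_stats(pred, true, low_mask)
                pmf = metrics.velocity_pmf(pred, edges, source=kind)
                rows.append(
                    {
                        "decoder": kind,
                        "fold": fold_id,
                        "instance": inst,
                        "seed": seed,
                        "mse": metrics.mse(pred, true),
                        "high_mean_speed": hi["mean_pred_speed"],
                        "high_mse": hi["mse"],
                        "low_mean_speed": lo["mean_pred_speed"],
                        "low_mse": lo["mse"],
                        "kl_div": metrics.kl_divergence(pmf_true, pmf),
                    }
                )
    per_instance = pd.DataFrame(rows)
    summary = (
        per_instance.groupby("decoder")
        .agg(
            mse_mean=("mse", "mean"),
            mse_se=("mse", lambda s: s.std(ddof=1) / np.sqrt(len(s)) if len(s) > 1 else 0.0),
            high_mean_speed=("high_mean_speed", "mean"),
            low_mean_speed=("low_mean_speed", "mean"),
            kl_div_mean=("kl_div", "mean"),
        )
        .reset_index()
    )

    comparisons = None
    if "rr" in config.roster:
        ref = per_instance[per_instance.decoder == "rr"].sort_values(
            ["fold", "instance"]
        )
        comp_rows = []
        for kind in config.roster:
            if kind == "rr":
                continue
            other = per_instance[per_instance.decoder == kind].sort_values(
                ["fold", "instance"]
            )
            if len(other) != len(ref):
                continue
            res = stats.paired_ttest(
                other["mse"].to_numpy(), ref["mse"].to_numpy(), tail="less"
            )
            comp_rows.append(
                {
                    "decoder": kind,
                    "reference": "rr",
                    "metric": "mse",
                    "statistic": res.statistic,
                    "p": res.p_value,
                    "significant": res.significant,
                }
            )
        comparisons = pd.DataFrame(comp_rows)

    return MetricsReport(
        per_instance=per_instance,
        summary=summary,
        comparisons=comparisons,
        predictions=predictions,
        extras={
            "true_holdout": true_hold,
            "edges": edges,
            "high_mask": high_mask,
            "low_mask": low_mask,
        },
    )


# --------------------------------------------------------------------------
# Experiment 2: stability / regularization ablation
# --------------------------------------------------------------------------


def run_stability_ablation(
    config: ExperimentConfig,
    session: BinnedSession | None = None,
    variants: tuple[str, ...] = ("tcn", "tcn-onlybn", "tcn-onlydp", "tcn-nobndp"),
) -> MetricsReport:
    """Train many instances of each TCN variant on identical data."""
    bad = [v for v in variants if v.replace("tcn-", "tcn") not in
           ("tcn", "tcnonlybn", "tcnonlydp", "tcnnobndp")]
    if bad:
        raise ValueError(f"unknown variants: {bad}")
    if session is None:
        session = _session_for(config, multi_context=False)
    kept, holdout = trim_and_holdout(
        session.trials, n_keep=config.n_keep, n_holdout=config.n_holdout
    )
    split = make_folds(kept, seed=config.seed, n_folds=config.n_folds)
    train_trials = split.folds[0]["train"]

    _, true_hold, _, _ = _dataset(session, holdout)
    rows = []
    predictions: dict = {}
    loss_traces: dict = {}
    for kind in variants:
        for inst in range(config.instances):
            seed = _instance_seed(config.seed, 0, kind, inst)
            model = train_decoder(kind, session, train_trials, seed, config)
            pred, true = predict_decoder(model, kind, session, holdout)
            predictions[(kind, inst)] = pred
            loss_traces[(kind, inst)] = model.loss_trace
            rows.append(
                {
                    "decoder": kind,
                    "instance": inst,
                    "seed": seed,
                    "mse": metrics.mse(pred, true),
                }
            )
    per_instance = pd.DataFrame(rows)
    summary_rows = []
    for kind in variants:
        sub = per_instance[per_instance.decoder == kind]
        deviation = metrics.median_prediction_deviation(
            [predictions[(kind, i)] for i in range(config.instances)]
        ) if config.instances >= 2 else np.nan
        summary_rows.append(
            {
                "decoder": kind,
                "mse_mean": sub["mse"].mean(),
                "mse_sd": sub["mse"].std(ddof=1) if len(sub) > 1 else 0.0,
                "median_prediction_deviation": deviation,
            }
        )
    return MetricsReport(
        per_instance=per_instance,
        summary=pd.DataFrame(summary_rows),
        predictions=predictions,
        extras={"loss_traces": loss_traces, "true_holdout": true_hold},
    )


# --------------------------------------------------------------------------
# Experiment 3: context generalization
# --------------------------------------------------------------------------


def run_context_generalization(
    config: ExperimentConfig, session: BinnedSession | None = None
) -> MetricsReport:
    """Train on single-, mixed-, and full-context sets; test on every
    single-context holdout; group by prediction type."""
    if session is None:
        session = _session_for(config, multi_context=True)
    contexts = list(config.contexts)
    if len(session.contexts) < len(contexts):
        raise ValueError("session does not contain all required contexts")

    f = session.trials.frame
    folds_by_context: dict[str, FoldSplit] = {}
    holdout_by_context: dict[str, np.ndarray] = {}
    for ctx in contexts:
        candidates = np.flatnonzero(
            (f.context.to_numpy() == ctx) & f.success.to_numpy()
        )
        kept, holdout = trim_and_holdout(
            candidates, n_keep=config.n_keep, n_holdout=config.n_holdout
        )
        split = make_folds(kept, seed=config.seed + hash(ctx) % 1000,
                           n_folds=config.n_folds)
        split.holdout = holdout
        folds_by_context[ctx] = split
        holdout_by_context[ctx] = holdout

    fold_ids = range(config.folds_used or config.n_folds)
    sources = contexts + ["mixed", "full"]
    rows = []
    for fold_id in fold_ids:
        train_sets = {}
        for ctx in contexts:
            train_sets[ctx] = folds_by_context[ctx].folds[fold_id]["train"]
        for kind_set in ("mixed", "full"):
            mc = make_multi_context(
                folds_by_context, fold_id, kind_set, required_contexts=contexts
            )
            train_sets[kind_set] = np.sort(
                np.concatenate(list(mc.trials_by_context.values()))
            )
        for kind in config.roster:
            for source in sources:
                for inst in range(config.instances):
                    seed = _instance_seed(
                        config.seed, fold_id, f"{kind}:{source}", inst
                    )
                    model = train_decoder(
                        kind, session, train_sets[source], seed, config
                    )
                    for test_ctx in contexts:
                        pred, true = predict_decoder(
                            model, kind, session, holdout_by_context[test_ctx]
                        )
                        if source == test_ctx:
                            group = "on-context"
                        elif source in ("mixed", "full"):
                            group = f"{source}-context"
                        else:
                            group = "off-context"
                        rows.append(
                            {
                                "decoder": kind,
                                "fold": fold_id,
                                "instance": inst,
                                "train_source": source,
                                "test_context": test_ctx,
                                "group": group,
                                "mse": metrics.mse(pred, true),
                            }
                        )
    per_instance = pd.DataFrame(rows)
    summary = (
        per_instance.groupby(["decoder", "group"])["mse"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"mean": "mse_mean", "std": "mse_sd", "count": "n"})
    )
    return MetricsReport(per_instance=per_instance, summary=summary)


def run_experiment(config: ExperimentConfig, **kwargs) -> MetricsReport:
    runners = {
        "decoder_comparison": run_decoder_comparison,
        "stability_ablation": run_stability_ablation,
        "context_generalization": run_context_generalization,
    }
    if config.kind not in runners:
        raise ValueError(f"unknown experiment kind {config.kind!r}")
    return runners[config.kind](config, **kwargs)
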