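"""Trial-level dataset preparation: trimming, holdout, folds, multi-context.

The offline protocol: unsuccessful trials are removed, the session is
trimmed to its middle 600 trials, the final 100 (in original order) are
held out for testing, and the remaining 500 are shuffled once and split
into five 100-trial blocks, giving five ~400-trial training folds each
with a 100-trial validation block.  Shuffling is always at the trial
level — bins within a trial stay contiguous so feature windows never mix
trials.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from nldbench.session import TrialTable


@dataclass
class FoldSplit:
    """Holdout plus five train/validation partitions of one trial block."""

    holdout: np.ndarray  # trial indices, original order
    folds: list[dict]  # [{"train": idx, "validation": idx}, ...]
    seed: int
    provenance: dict = field(default_factory=dict)

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "holdout": self.holdout.tolist(),
            "folds": [
                {"train": f["train"].tolist(), "validation": f["validation"].tolist()}
                for f in self.folds
            ],
            "seed": self.seed,
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "FoldSplit":
        payload = json.loads(Path(path).read_text())
        return cls(
            holdout=np.array(payload["holdout"], dtype=int),
            folds=[
                {
                    "train": np.array(f["train"], dtype=int),
                    "validation": np.array(f["validation"], dtype=int),
                }
                for f in payload["folds"]
            ],
            seed=payload["seed"],
            provenance=payload.get("provenance", {}),
        )


@dataclass
class MultiContextSet:
    """A "mixed" or "full" multi-context training set."""

    kind: str  # "mixed" | "full"
    fold_id: int
    trials_by_context: dict[str, np.ndarray]

    @property
    def all_trials(self) -> dict[str, np.ndarray]:
        return self.trials_by_context

    @property
    def total_trials(self) -> int:
        return sum(len(v) for v in self.trials_by_context.values())


def trim_and_holdout(
    trials: TrialTable | np.ndarray,
    n_keep: int = 600,
    n_holdout: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Remove failures, trim to the middle ``n_keep`` trials, hold out the last
    ``n_holdout``.

    Returns ``(kept, holdout)`` where ``kept`` is the first
    ``n_keep - n_holdout`` trimmed trials and ``holdout`` the final
    ``n_holdout``, all as original trial indices in original order.
    """
    if isinstance(trials, TrialTable):
        success = trials["success"].to_numpy().astype(bool)
        candidates = np.flatnonzero(success)
    else:
        candidates = np.asarray(trials, dtype=int)
    n = len(candidates)
    if n < n_keep:
        raise ValueError(
            f"need at least {n_keep} successful trials, found {n}"
        )
    lead = (n - n_keep) // 2
    middle = candidates[lead : lead + n_keep]
    return middle[: n_keep - n_holdout], middle[n_keep - n_holdout :]


def make_folds(kept: np.ndarray, seed: int, n_folds: int = 5) -> FoldSplit:
    """Shuffle once and partition into equal blocks; fold i validates on
    block i and trains on the remaining blocks."""
    kept = np.asarray(kept, dtype=int)
    if len(kept) % n_folds != 0:
        raise ValueError(
            f"trial count {len(kept)} not divisible into {n_folds} folds"
        )
    rng = np.random.default_rng(seed)
    shuffled = kept[rng.permutation(len(kept))]
    blocks = np.split(shuffled, n_folds)
    folds = []
    for i in range(n_folds):
        train = np.concatenate([blocks[j] for j in range(n_folds) if j != i])
        folds.append({"train": train, "validation": blocks[i]})
    return FoldSplit(holdout=np.empty(0, dtype=int), folds=folds, seed=seed)


def prepare_session_folds(
    trials: TrialTable,
    seed: int,
    n_keep: int = 600,
    n_holdout: int = 100,
    n_folds: int = 5,
) -> FoldSplit:
    """Full protocol: trim, hold out, shuffle, five-fold split."""
    kept, holdout = trim_and_holdout(trials, n_keep=n_keep, n_holdout=n_holdout)
    split = make_folds(kept, seed=seed, n_folds=n_folds)
    split.holdout = holdout
    return split


def make_multi_context(
    folds_by_context: dict[str, FoldSplit],
    fold_id: int,
    kind: str,
    required_contexts: list[str] | None = None,
) -> MultiContextSet:
    """Build a "full" (all four training sets) or "mixed" (25% of each,
    sampled sequentially) multi-context training set for one fold."""
    if kind not in ("mixed", "full"):
        raise ValueError("kind must be 'mixed' or 'full'")
    contexts = required_contexts or list(folds_by_context)
    for ctx in contexts:
        if ctx not in folds_by_context:
            raise ValueError(f"missing context {ctx!r}")
    trials_by_context: dict[str, np.ndarray] = {}
    for pos, ctx in enumerate(contexts):
        train = folds_by_context[ctx].folds[fold_id]["train"]
        if kind == "full":
            trials_by_context[ctx] = train
        else:
            # Training sets are already shuffled, so a sequential slice is a
            # random quarter: the first 25% of the first context, the next
            # 25% of the second, and so on.
            quarter = len(train) // len(contexts)
            start = pos * quarter
            trials_by_context[ctx] = train[start : start + quarter]
    return MultiContextSet(kind=kind, fold_id=fold_id, trials_by_context=trials_by_context)


def prepare_trial_block(
    block: np.ndarray,
    middle_100: bool = False,
    n_exclude: int = 5,
    n_middle: int = 100,
) -> np.ndarray:
    """Filter one contiguous block of trials before trial-metric analysis.

    The first ``n_exclude`` trials are dropped (familiarization); in
    middle-100 mode the centered middle ``n_middle`` of the block are kept
    (never re-including excluded leading trials), or all remaining trials
    when fewer than ``n_middle`` remain.
    """
    block = np.asarray(block, dtype=int)
    if len(block) <= n_exclude:
        warnings.warn(
            f"block of {len(block)} trials shorter than the {n_exclude}-trial "
            "exclusion; returning empty selection",
            stacklevel=2,
        )
        return np.empty(0, dtype=int)
    remaining = block[n_exclude:]
    if not middle_100 or len(remaining) <= n_middle:
        return remaining
    lead = max(n_exclude, (len(block) - n_middle) // 2)
    return block[lead : lead + n_middle]
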