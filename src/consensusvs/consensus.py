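"""Probability-averaging consensus over trained classifiers.

The consensus score CS of a compound is the arithmetic mean of the
probability scores PS emitted by the member models; CS >= 0.5 predicts
active.  Utilities here enumerate all member combinations of a model pool
(all subsets of size >= 2) and sweep classification thresholds on the CS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from .modeling import EvaluationReport, TrainedClassifier, evaluate


class ConsensusError(ValueError):
    pass


def consensus_score(ps: Sequence[float]) -> float:
    """Arithmetic mean of >= 2 probability scores, each in [0, 1]."""
    ps = list(ps)
    if len(ps) < 2:
        raise ConsensusError("consensus requires at least 2 probability scores")
    arr = np.asarray(ps, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ConsensusError("probability scores must lie in [0, 1]")
    return float(arr.mean())


@dataclass(frozen=True)
class ConsensusPrediction:
    compound_id: str
    member_ps: tuple[float, ...]
    cs: float
    label: str  # active | inactive

    @classmethod
    def from_ps(cls, compound_id: str, member_ps: Sequence[float]):
        cs = consensus_score(member_ps)
        return cls(
            compound_id=compound_id,
            member_ps=tuple(float(p) for p in member_ps),
            cs=cs,
            label="active" if cs >= 0.5 else "inactive",
        )


@dataclass
class ConsensusModel:
    """A set of >= 2 trained classifiers combined by PS averaging."""

    members: list[TrainedClassifier] = field(default_factory=list)

    def __post_init__(self):
        if len(self.members) < 2:
            raise ConsensusError("a consensus model needs at least 2 members")
        specs = [m.spec for m in self.members]
        if len(set(specs)) != len(specs):
            raise ConsensusError("consensus members must have distinct specs")
        checksums = {m.manifest.get("dataset_checksum") for m in self.members}
        if len(checksums) > 1:
            raise ConsensusError("members must be trained on the same dataset")

    @property
    def kinds(self) -> set[str]:
        return {m.spec.representation for m in self.members}

    @property
    def name(self) -> str:
        return " + ".join(m.spec.name for m in self.members)

    def member_ps(self, features: dict[str, np.ndarray] | np.ndarray) -> np.ndarray:
        """PS of every member; rows = compounds, columns = members.

        ``features`` maps representation kind -> feature matrix; a single
        array is accepted when all members share one representation.
        """
        if not isinstance(features, dict):
            if len(self.kinds) != 1:
                raise ConsensusError(
                    "members use several representations; pass a kind->matrix dict"
                )
            features = {next(iter(self.kinds)): features}
        missing = self.kinds - set(features)
        if missing:
            raise ConsensusError(f"missing feature matrices for kinds {sorted(missing)}")
        cols = [m.predict_ps(features[m.spec.representation]) for m in self.members]
        return np.column_stack(cols)

    def predict_cs(self, features) -> np.ndarray:
        """Consensus score per compound."""
        return self.member_ps(features).mean(axis=1)

    def predict(self, features, ids: Sequence[str] | None = None) -> list[ConsensusPrediction]:
        ps = self.member_ps(features)
        if ids is None:
            ids = [f"cpd{i}" for i in range(ps.shape[0])]
        return [ConsensusPrediction.from_ps(cid, row) for cid, row in zip(ids, ps)]


def enumerate_combinations(models: Sequence[TrainedClassifier]) -> list[ConsensusModel]:
    """All consensus combinations: subsets of size >= 2, deterministic order
    (increasing size, then input order).  n models yield 2^n - n - 1 subsets.
    """
    models = list(models)
    if len(models) < 2:
        raise ConsensusError("need at least 2 models to enumerate combinations")
    out = []
    for k in range(2, len(models) + 1):
        for combo in combinations(range(len(models)), k):
            out.append(ConsensusModel(members=[models[i] for i in combo]))
    return out


DEFAULT_THRESHOLDS = (0.5, 0.6, 0.7, 0.8, 0.9)


def threshold_sweep(
    predictions: Sequence[ConsensusPrediction] | np.ndarray,
    true_labels: Sequence,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
):
    """Precision/recall of "active iff CS >= t" over ascending thresholds.

    Returns a DataFrame with columns (threshold, precision, recall,
    n_predicted_active).  At t = 0.5 this reproduces the default consensus
    labels.
    """
    import pandas as pd

    thresholds = list(thresholds)
    if any(t < 0 or t > 1 for t in thresholds):
        raise ConsensusError("thresholds must lie in [0, 1]")
    if thresholds != sorted(thresholds):
        raise ConsensusError("thresholds must be sorted ascending")
    if len(predictions) and isinstance(predictions[0], ConsensusPrediction):
        cs = np.array([p.cs for p in predictions])
    else:
        cs = np.asarray(predictions, dtype=float)
    if len(cs) != len(true_labels):
        raise ConsensusError("prediction and label lengths differ")
    rows = []
    import warnings

    for t in thresholds:
        pred = (cs >= t).astype(int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            rep = evaluate(pred, true_labels)
        rows.append(
            {
                "threshold": t,
                "precision": rep.precision,
                "recall": rep.recall,
                "n_predicted_active": int(pred.sum()),
            }
        )
    return pd.DataFrame(rows)


def rank_combinations(
    combos: Sequence[ConsensusModel],
    features,
    true_labels: Sequence,
) -> list[tuple[ConsensusModel, EvaluationReport]]:
    """Score each combination on a labeled set; rank by accuracy, ties by
    precision, then by enumeration order (stable)."""
    import warnings

    scored = []
    for cm in combos:
        cs = cm.predict_cs(features)
        pred = (cs >= 0.5).astype(int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            scored.append((cm, evaluate(pred, true_labels)))
    scored.sort(key=lambda t: (-t[1].accuracy, -t[1].precision))
    return scored
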