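"""Composition-aware score calibration and FDR estimation.

Raw classifier scores are not probabilities: how often a score of 0.9
corresponds to a true virus depends on how many viruses are in the sample.
Calibration therefore conditions on the empirical sample composition
(the class proportions of the batch's own predictions). Training data are
artificial communities with Dirichlet-distributed class proportions; each
community's scores are calibrated by isotonic regression, and a regression
network learns to map (composition, raw score) to the isotonic target so
that new samples can be calibrated without refitting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.isotonic import IsotonicRegression

from . import nn
from .records import CLASSES

_EPS = 1e-4


@dataclass
class CommunitySample:
    """A sampled community: raw scores, true labels, empirical composition."""

    scores: np.ndarray  # (n, 3) simplex rows
    labels: np.ndarray  # (n,) ints, training only
    composition: np.ndarray  # (3,) predicted-class proportions

    @staticmethod
    def composition_of(scores: np.ndarray) -> np.ndarray:
        pred = np.argmax(scores, axis=1)
        return np.bincount(pred, minlength=3) / len(pred)


def sample_communities(
    pool_scores: np.ndarray,
    pool_labels: Sequence[int],
    n_communities: int,
    size_range: tuple[int, int] = (100, 1000),
    seed: int = 0,
) -> list[CommunitySample]:
    """Sample communities with flat-Dirichlet class proportions.

    Members are drawn with replacement from the labeled pool, class by
    class, so each community's true composition follows Dirichlet(1,1,1).
    """
    if size_range[0] < 10:
        raise ValueError("minimum community size must be >= 10")
    pool_labels = np.asarray(pool_labels)
    by_class = [np.flatnonzero(pool_labels == c) for c in range(3)]
    if any(len(idx) == 0 for idx in by_class):
        raise ValueError("pool must contain all three classes")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_communities):
        props = rng.dirichlet([1.0, 1.0, 1.0])
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        classes = rng.choice(3, size=size, p=props)
        members = np.concatenate(
            [
                rng.choice(by_class[c], size=int((classes == c).sum()), replace=True)
                for c in range(3)
                if (classes == c).any()
            ]
        )
        scores = pool_scores[members]
        out.append(
            CommunitySample(
                scores=scores,
                labels=pool_labels[members],
                composition=CommunitySample.composition_of(scores),
            )
        )
    return out


def isotonic_calibrate(scores: Sequence[float], truth: Sequence[int]) -> np.ndarray:
    """Non-decreasing isotonic fit of binary truth on scores."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    if len(np.unique(scores)) < 2:
        raise ValueError("need at least two distinct scores")
    if len(np.unique(truth)) < 2:
        warnings.warn("single-class truth: isotonic calibration is the identity")
        return scores.copy()
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
    iso.fit(scores, truth)
    return iso.predict(scores)


def isotonic_calibrate_multiclass(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-class one-vs-rest isotonic calibration, renormalized to the simplex."""
    out = np.column_stack(
        [isotonic_calibrate(scores[:, c], (labels == c).astype(int)) for c in range(3)]
    )
    out = np.clip(out, _EPS, None)
    return out / out.sum(axis=1, keepdims=True)


class CalibratorModel:
    """Composition-conditional monotone recalibration network.

    An MLP maps the composition 3-vector to per-class intercepts and
    non-negative slopes; the calibrated scores are the softmax of
    ``intercept_c + slope_c * logit(raw_c)``. Because each slope is
    non-negative (softplus) the calibrated score of a class is monotone
    non-decreasing in that class's raw score for any fixed composition.
    """

    def __init__(self, hidden: tuple[int, int] = (32, 32), seed: int = 0):
        self.hidden = hidden
        rng = np.random.default_rng(seed)
        self.net = nn.MLP([3, hidden[0], hidden[1], 6], rng, name="cal")

    @property
    def params(self) -> list[nn.Param]:
        return self.net.params

    @staticmethod
    def _logit(s: np.ndarray) -> np.ndarray:
        s = np.clip(s, _EPS, 1 - _EPS)
        return np.log(s / (1 - s))

    def _transform(self, head: np.ndarray, raw: np.ndarray) -> np.ndarray:
        alpha, beta_raw = head[:, :3], head[:, 3:]
        beta = np.logaddexp(0.0, beta_raw)  # softplus >= 0
        u = alpha + beta * self._logit(raw)
        return nn.softmax(u)

    def predict(self, composition: np.ndarray, raw: np.ndarray) -> np.ndarray:
        comp = np.broadcast_to(composition, raw.shape)
        head = self.net.forward(np.asarray(comp, dtype=float))
        return self._transform(head, raw)

    def save(self, path: str | Path) -> None:
        payload = {
            "kind": "calibrator",
            "hidden": list(self.hidden),
            "state": nn.params_to_state(self.params),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "CalibratorModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("kind") != "calibrator":
            raise ValueError(f"{path} is not a calibrator model file")
        model = cls(hidden=tuple(payload["hidden"]))
        nn.state_to_params(model.params, payload["state"])
        return model


def train_calibrator(
    communities: list[CommunitySample],
    seed: int = 0,
    epochs: int = 30,
    batch_size: int = 512,
    lr: float = 3e-3,
    max_pairs: int = 200_000,
) -> CalibratorModel:
    """Regress isotonic-calibrated targets from (composition, raw scores).

    Each community contributes (composition, raw, isotonic target) triples;
    the network is trained with Adam on mean squared error. Seeded and
    deterministic.
    """
    if len(communities) < 100:
        raise ValueError("need at least 100 communities to fit the calibrator")
    comps, raws, targets = [], [], []
    for comm in communities:
        target = isotonic_calibrate_multiclass(comm.scores, comm.labels)
        comps.append(np.broadcast_to(comm.composition, comm.scores.shape).copy())
        raws.append(comm.scores)
        targets.append(target)
    X_comp = np.concatenate(comps)
    X_raw = np.concatenate(raws)
    Y = np.concatenate(targets)

    rng = np.random.default_rng(seed)
    if len(Y) > max_pairs:
        keep = rng.choice(len(Y), size=max_pairs, replace=False)
        X_comp, X_raw, Y = X_comp[keep], X_raw[keep], Y[keep]

    model = CalibratorModel(seed=seed)
    opt = nn.Adam(model.params, lr=lr)
    n = len(Y)
    L = model._logit(X_raw)
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            head = model.net.forward(X_comp[idx])
            alpha, beta_raw = head[:, :3], head[:, 3:]
            beta = np.logaddexp(0.0, beta_raw)
            u = alpha + beta * L[idx]
            yhat = nn.softmax(u)
            diff = 2.0 * (yhat - Y[idx]) / (len(idx) * 3)
            du = yhat * (diff - np.sum(yhat * diff, axis=1, keepdims=True))
            dhead = np.concatenate(
                [du, du * L[idx] / (1.0 + np.exp(-beta_raw))], axis=1
            )
            opt.zero_grad()
            model.net.backward(dhead)
            opt.step()
    return model


def calibrate_scores(model: CalibratorModel, raw: np.ndarray) -> np.ndarray:
    """Calibrate a batch: composition from the batch's own argmax labels.

    Batches smaller than 10 sequences pass through unchanged (the
    composition estimate would be too noisy to condition on).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.shape[0] < 10:
        warnings.warn("batch too small for composition estimation; scores not calibrated")
        return raw.copy()
    composition = CommunitySample.composition_of(raw)
    return model.predict(composition, raw)


def fdr_from_scores(scores: Sequence[float], threshold: float) -> float | None:
    """Estimated FDR of the acceptance set {score >= t}: mean of (1 − score).

    Returns None when no score clears the threshold.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    scores = np.asarray(scores, dtype=float)
    accepted = scores[scores >= threshold]
    if accepted.size == 0:
        return None
    return float(np.mean(1.0 - accepted))
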