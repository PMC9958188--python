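"""Decoy labeling, gradient-descent training, and checkpointed scoring.

Decoys are labeled either by their interface RMSD to the native
(regression, native = 0 Å) or by the ≤ 4.0 Å native-likeness criterion
(binary). Training minimizes mean-squared error with seeded SGD at the
stated initial learning rate, batch size 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import DivergenceError, EmptyInputError, ScoringShapeError
from .evaluate import SUCCESS_THRESHOLD, interface_rmsd
from .featurize import ComplexTensor
from .network.layers import mse_loss
from .network.models import ScoringModel
from .structures import ComplexStructure

logger = logging.getLogger(__name__)


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-4
    max_steps: int = 20000
    batch_size: int = 1
    label_scheme: Literal["irmsd_regression", "native_binary"] = "irmsd_regression"
    seed: int = 0
    checkpoint_every: int = 0  # 0 = only the final checkpoint
    momentum: float = 0.0
    plateau_window: int = 0  # 0 = no plateau stopping
    plateau_tol: float = 1e-4
    oversample_native: bool = False

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")


@dataclass
class LabeledDecoy:
    tensor: ComplexTensor
    label: float
    decoy_id: str
    irmsd: float
    is_native: bool = False

    def __post_init__(self):
        if self.irmsd < 0:
            raise ValueError("irmsd must be non-negative")


def label_for(irmsd: float, scheme: str) -> float:
    if scheme == "irmsd_regression":
        return float(irmsd)
    if scheme == "native_binary":
        return 1.0 if irmsd <= SUCCESS_THRESHOLD else 0.0
    raise ValueError(f"unknown label scheme {scheme!r}")


def make_labels(
    decoys: Sequence[tuple[str, ComplexStructure, ComplexTensor]],
    native: ComplexStructure | None,
    scheme: str = "irmsd_regression",
    include_native: bool = False,
    native_tensor: ComplexTensor | None = None,
) -> list[LabeledDecoy]:
    """Label (decoy_id, structure, tensor) triples against the native.

    irmsd_regression labels with interface RMSD in Å (native = 0);
    native_binary labels 1 iff interface RMSD ≤ 4.0 Å.
    """
    if native is None:
        raise EmptyInputError("labeling requires the native structure")
    labeled = []
    if include_native:
        if native_tensor is None:
            raise EmptyInputError("include_native requires native_tensor")
        labeled.append(
            LabeledDecoy(
                tensor=native_tensor,
                label=label_for(0.0, scheme),
                decoy_id="native",
                irmsd=0.0,
                is_native=True,
            )
        )
    for decoy_id, structure, tensor in decoys:
        irmsd = interface_rmsd(native, structure)
        labeled.append(
            LabeledDecoy(
                tensor=tensor,
                label=label_for(irmsd, scheme),
                decoy_id=decoy_id,
                irmsd=irmsd,
            )
        )
    return labeled


@dataclass
class TrainResult:
    final_state: dict[str, np.ndarray]
    loss_trace: list[float]
    checkpoints: list[tuple[int, dict[str, np.ndarray]]] = field(default_factory=list)
    stopped_early: bool = False


def _plateaued(trace: list[float], window: int, tol: float) -> bool:
    if window <= 0 or len(trace) < 2 * window:
        return False
    recent = np.mean(trace[-window:])
    previous = np.mean(trace[-2 * window : -window])
    denom = max(abs(previous), 1e-12)
    return abs(previous - recent) / denom < tol


def train(
    model: ScoringModel,
    dataset: Sequence[LabeledDecoy],
    config: TrainingConfig,
) -> TrainResult:
    """Seeded SGD on mean-squared error, one decoy per step.

    Samples uniformly (optionally oversampling the native 50/50); halts at
    ``max_steps`` or when the windowed loss plateaus; raises
    DivergenceError (carrying the last good state) on non-finite loss.
    """
    if not dataset:
        raise EmptyInputError("training dataset is empty")
    rng = np.random.default_rng(config.seed)
    params = model.parameters()
    velocity = [np.zeros_like(p.value) for p in params]
    native_idx = [i for i, d in enumerate(dataset) if d.is_native]

    trace: list[float] = []
    checkpoints: list[tuple[int, dict[str, np.ndarray]]] = []
    last_good = model.state_dict()
    stopped_early = False
    for step in range(1, config.max_steps + 1):
        if config.oversample_native and native_idx and rng.random() < 0.5:
            idx = native_idx[rng.integers(len(native_idx))]
        else:
            idx = int(rng.integers(len(dataset)))
        sample = dataset[idx]
        for p in params:
            p.grad.fill(0.0)
        pred = model.forward(
            sample.tensor.data, mask=sample.tensor.mask, training=True
        )
        loss, dpred = mse_loss(np.array([pred]), sample.label)
        if not np.isfinite(loss):
            raise DivergenceError(
                f"non-finite loss at step {step}", last_checkpoint=last_good
            )
        model.backward(float(dpred[0]))
        if config.learning_rate > 0:
            for p, v in zip(params, velocity):
                if config.momentum:
                    v *= config.momentum
                    v -= config.learning_rate * p.grad
                    p.value += v
                else:
                    p.value -= config.learning_rate * p.grad
        trace.append(loss)
        if config.checkpoint_every and step % config.checkpoint_every == 0:
            last_good = model.state_dict()
            checkpoints.append((step, last_good))
        if _plateaued(trace, config.plateau_window, config.plateau_tol):
            logger.info("loss plateaued at step %d; stopping", step)
            stopped_early = True
            break
    return TrainResult(
        final_state=model.state_dict(),
        loss_trace=trace,
        checkpoints=checkpoints,
        stopped_early=stopped_early,
    )


def select_checkpoint(
    model: ScoringModel,
    result: TrainResult,
    heldout: Sequence[LabeledDecoy],
) -> tuple[int, dict[str, np.ndarray]]:
    """Tag the checkpoint with the lowest held-out MSE as 'selected'."""
    candidates = result.checkpoints or [(len(result.loss_trace), result.final_state)]
    best = None
    for step, state in candidates:
        model.load_state_dict(state)
        losses = [
            mse_loss(np.array([model.score(d.tensor)]), d.label)[0] for d in heldout
        ]
        mean_loss = float(np.mean(losses))
        if best is None or mean_loss < best[0]:
            best = (mean_loss, step, state)
    model.load_state_dict(best[2])
    return best[1], best[2]


def score_decoys(
    model: ScoringModel,
    decoys: Sequence[tuple[str, ComplexTensor]],
    scheme: str = "irmsd_regression",
) -> list[tuple[str, float]]:
    """Score and rank decoys: ascending for irmsd_regression (lower
    predicted interface RMSD is better), descending for native_binary;
    ties broken by decoy_id."""
    if scheme not in ("irmsd_regression", "native_binary"):
        raise ValueError(f"unknown label scheme {scheme!r}")
    rows = []
    for decoy_id, tensor in decoys:
        if tuple(tensor.data.shape) != model.config.input_shape:
            raise ScoringShapeError(
                f"decoy {decoy_id}: expected tensor shape "
                f"{model.config.input_shape}, got {tuple(tensor.data.shape)}"
            )
        score = model.score(tensor)
        if not np.isfinite(score):
            raise DivergenceError(f"non-finite score for decoy {decoy_id}")
        rows.append((decoy_id, float(score)))
    ascending = scheme == "irmsd_regression"
    rows.sort(key=lambda r: (r[1] if ascending else -r[1], r[0]))
    return rows
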