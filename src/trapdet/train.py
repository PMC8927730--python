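"""Per-image SGD training loop with the step learning-rate schedule."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .detector import Detector
from .nn import SGD

__all__ = ["TrainConfig", "train_detector"]


@dataclass(frozen=True)
class TrainConfig:
    """SGD protocol: momentum 0.9, 12 epochs, base lr 0.0025 dropped
    tenfold after epoch 8.  ``iterations`` switches to a fixed-iteration
    desk profile (images cycled in order, constant ``lr``)."""

    epochs: int = 12
    lr: float = 0.0025
    lr_drop_epoch: int = 8  # epochs after which lr is divided by 10
    lr_drop_factor: float = 10.0
    momentum: float = 0.9
    iterations: Optional[int] = None


def train_detector(
    model: Detector,
    images: Sequence[np.ndarray],
    targets: Sequence[tuple[np.ndarray, np.ndarray]],
    config: TrainConfig = TrainConfig(),
    seed: int = 0,
    log_fn: Optional[Callable[[int, dict], None]] = None,
) -> list[dict]:
    """Train in place; ``targets[i]`` is ``(gt_boxes [M,4], gt_labels [M])``.

    Every random choice (sampling, shuffling) derives from ``seed``.
    Returns the per-iteration loss history.
    """
    if len(images) != len(targets) or len(images) == 0:
        raise ValueError("need equally many images and targets, at least one")
    rng = np.random.default_rng(seed)
    opt = SGD(model.parameters(), lr=config.lr, momentum=config.momentum)
    history: list[dict] = []

    def step(idx: int, it: int) -> None:
        opt.zero_grad()
        losses = model.compute_losses(images[idx], *targets[idx], rng)
        total = losses["rpn_cls"] + losses["rpn_reg"] + losses["rcnn_cls"] + losses["rcnn_reg"]
        total.backward()
        opt.step()
        rec = {k: float(v.data) for k, v in losses.items()}
        rec["total"] = float(total.data)
        rec["lr"] = opt.lr
        history.append(rec)
        if log_fn is not None:
            log_fn(it, rec)

    if config.iterations is not None:
        for it in range(config.iterations):
            step(it % len(images), it)
        return history

    it = 0
    for epoch in range(config.epochs):
        if epoch == config.lr_drop_epoch:
            opt.lr = config.lr / config.lr_drop_factor
        order = rng.permutation(len(images))
        for idx in order:
            step(int(idx), it)
            it += 1
    return history
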