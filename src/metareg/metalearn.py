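"""Reptile meta-training over per-subject registration tasks and
few-shot test-time adaptation.

One *episode* samples a task (a subject), runs ``k`` inner gradient
steps on freshly sampled interactions of that task, and then moves the
meta-initialization toward the inner-loop weights:

    phi <- phi - beta_meta * mean_m (phi - phi*_m)

where the mean runs over all ``k`` intermediate snapshots (a
``final_only`` switch restricts it to the last snapshot, the common
Reptile variant).  The meta step size decays linearly from its initial
to its final value over the training episodes.

During meta-training the loss is computed against *complete* target
labels while the network input stays sparse, so the initialization is
learned from full supervision.  At meta-test, adaptation sees only the
sparse gland label on the acquired frames (partial similarity), one
gradient update per sweep step.

The inner loop is written against a small problem protocol
(``init_weights`` / ``sample_interaction`` / ``loss_and_grad``) so that
toy models can exercise the meta-update machinery exactly;
``RegistrationMetaProblem`` binds it to the registration network and
weakly-supervised loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Protocol

import numpy as np

from .core_spatial import Volume
from .interaction import (InteractionSample, SweepSchedule, apply_mask,
                          sample_training_interaction)
from .losses import LossWeights, registration_loss_t
from .network import (NetworkWeights, RegistrationNetwork, stack_inputs,
                      weights_axpy, weights_mean)

__all__ = [
    "MetaTrainConfig",
    "EpisodeTrace",
    "MetaProblem",
    "RegistrationMetaProblem",
    "SGDOptimizer",
    "AdamOptimizer",
    "make_optimizer",
    "inner_update",
    "reptile_update",
    "beta_meta_schedule",
    "meta_train",
    "few_shot_adapt",
]


@dataclass(frozen=True)
class MetaTrainConfig:
    """Outer/inner loop hyper-parameters (defaults mirror the baseline
    protocol: k=10 inner Adam steps at 1e-5, minibatch 4, meta step
    0.5 decaying linearly to 1e-5)."""

    k: int = 10
    beta_task: float = 1e-5
    beta_meta_init: float = 0.5
    beta_meta_final: float = 1e-5
    episodes: int = 25000
    minibatch: int = 4
    inner_optimizer: str = "adam"
    seed: int = 0
    final_only: bool = False

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.beta_task <= 0 or self.beta_meta_init <= 0 or self.beta_meta_final <= 0:
            raise ValueError("learning rates must be positive")
        if self.minibatch < 1:
            raise ValueError("minibatch must be >= 1")
        if self.inner_optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown inner optimizer {self.inner_optimizer!r}")


@dataclass
class EpisodeTrace:
    episode: int
    task_id: int
    inner_losses: list[float]
    beta_meta: float

    def to_json(self) -> str:
        return json.dumps({"episode": self.episode, "task_id": self.task_id,
                           "inner_losses": self.inner_losses,
                           "beta_meta": self.beta_meta})


class MetaProblem(Protocol):
    """What the meta-loops need from a learning problem."""

    def sample_interaction(self, task, rng: np.random.Generator): ...

    def loss_and_grad(self, w: NetworkWeights, task, samples,
                      sparse: bool = False) -> tuple[float, dict]: ...


# ---------------------------------------------------------------------------
# inner optimizers
# ---------------------------------------------------------------------------

class SGDOptimizer:
    def step(self, w: NetworkWeights, grads: dict, lr: float) -> NetworkWeights:
        return {name: a - lr * grads[name] for name, a in w.items()}


class AdamOptimizer:
    """Standard Adam; state is reset wherever a fresh optimizer is built
    (each episode and at meta-test start), so snapshots stay weight-space
    objects."""

    def __init__(self, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, w: NetworkWeights, grads: dict, lr: float) -> NetworkWeights:
        self.t += 1
        out = {}
        for name, a in w.items():
            g = grads[name]
            m = self.m.get(name, 0.0) * self.beta1 + (1 - self.beta1) * g
            v = self.v.get(name, 0.0) * self.beta2 + (1 - self.beta2) * g * g
            self.m[name], self.v[name] = m, v
            mhat = m / (1 - self.beta1 ** self.t)
            vhat = v / (1 - self.beta2 ** self.t)
            out[name] = a - lr * mhat / (np.sqrt(vhat) + self.eps)
        return out


def make_optimizer(name: str):
    return AdamOptimizer() if name == "adam" else SGDOptimizer()


# ---------------------------------------------------------------------------
# meta-update primitives
# ---------------------------------------------------------------------------

def inner_update(problem: MetaProblem, w: NetworkWeights, task, samples,
                 beta_task: float, optimizer=None) -> tuple[NetworkWeights, float]:
    """One descent step on the task loss; returns (new weights, loss).

    The input weights are not modified.  A non-finite loss or gradient
    raises, which aborts the surrounding episode.
    """
    optimizer = optimizer or SGDOptimizer()
    loss, grads = problem.loss_and_grad(w, task, samples)
    if not np.isfinite(loss):
        raise FloatingPointError(f"non-finite inner loss {loss}")
    for name, g in grads.items():
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient in {name}")
    return optimizer.step(w, grads, beta_task), float(loss)


def reptile_update(w: NetworkWeights, snapshots: list[NetworkWeights],
                   beta_meta: float) -> NetworkWeights:
    """phi - beta_meta * mean_m(phi - phi*_m), elementwise."""
    if not snapshots:
        raise ValueError("need at least one snapshot")
    return weights_axpy(w, weights_mean(list(snapshots)), beta_meta)


def beta_meta_schedule(episode_index: int, cfg: MetaTrainConfig) -> float:
    """Linear decay from beta_meta_init (episode 0) to beta_meta_final."""
    if not (0 <= episode_index < cfg.episodes):
        raise ValueError(
            f"episode index {episode_index} outside [0, {cfg.episodes})")
    if cfg.episodes == 1:
        return cfg.beta_meta_init
    frac = episode_index / (cfg.episodes - 1)
    return cfg.beta_meta_init + frac * (cfg.beta_meta_final - cfg.beta_meta_init)


# ---------------------------------------------------------------------------
# meta-training and few-shot adaptation
# ---------------------------------------------------------------------------

def meta_train(problem: MetaProblem, tasks: list, cfg: MetaTrainConfig,
               w0: NetworkWeights, trace: list | None = None) -> NetworkWeights:
    """Reptile meta-training; fully reproducible under ``cfg.seed``.

    Episodes whose inner loop produces non-finite values are logged and
    skipped; the outer loop continues from the pre-episode weights.
    """
    if len(tasks) < 2:
        raise ValueError("meta-training needs at least two tasks")
    rng = np.random.default_rng(cfg.seed)
    w = dict(w0)
    for e in range(cfg.episodes):
        beta_meta = beta_meta_schedule(e, cfg)
        t_idx = int(rng.integers(len(tasks)))
        task = tasks[t_idx]
        opt = make_optimizer(cfg.inner_optimizer)
        wi = w
        snapshots: list[NetworkWeights] = []
        losses: list[float] = []
        try:
            for _ in range(cfg.k):
                samples = [problem.sample_interaction(task, rng)
                           for _ in range(cfg.minibatch)]
                wi, loss = inner_update(problem, wi, task, samples,
                                        cfg.beta_task, opt)
                snapshots.append(wi)
                losses.append(loss)
        except FloatingPointError:
            if trace is not None:
                trace.append(EpisodeTrace(e, t_idx, losses, float("nan")))
            continue
        used = [snapshots[-1]] if cfg.final_only else snapshots
        w = reptile_update(w, used, beta_meta)
        if trace is not None:
            trace.append(EpisodeTrace(e, t_idx, losses, beta_meta))
    return w


def few_shot_adapt(problem: MetaProblem, w: NetworkWeights, task,
                   schedule: SweepSchedule, beta_task: float,
                   inner_optimizer: str = "adam") -> NetworkWeights:
    """Sequential few-shot adaptation along a sweep schedule.

    One gradient update per schedule step, supervised only by the sparse
    gland label on the acquired frames; applies exactly
    ``schedule.num_updates`` = F_max - F_min updates.
    """
    opt = make_optimizer(inner_optimizer)
    for frames in schedule.steps:
        sample = problem.interaction_at(task, frames)
        w, _ = _sparse_update(problem, w, task, sample, beta_task, opt)
    return w


def _sparse_update(problem, w, task, sample, beta_task, opt):
    loss, grads = problem.loss_and_grad(w, task, [sample], sparse=True)
    if not np.isfinite(loss):
        raise FloatingPointError(f"non-finite adaptation loss {loss}")
    return opt.step(w, grads, beta_task), float(loss)


# ---------------------------------------------------------------------------
# the registration meta-problem
# ---------------------------------------------------------------------------

class RegistrationMetaProblem:
    """Binds the network, loss and interaction simulator into the problem
    protocol used by the meta-loops.

    Meta-training supervision uses the complete gland label (optionally
    plus landmark-structure labels, averaged); sparse mode masks both
    the warped source label and the target label to the acquired frames.
    """

    def __init__(self, net: RegistrationNetwork, loss_weights: LossWeights,
                 f_min: int = 2, f_max: int = 10,
                 use_landmark_labels: bool = False):
        self.net = net
        self.loss_weights = loss_weights
        self.f_min = f_min
        self.f_max = f_max
        self.use_landmark_labels = use_landmark_labels

    def init_weights(self) -> NetworkWeights:
        return self.net.init_weights()

    def sample_interaction(self, task, rng: np.random.Generator) -> InteractionSample:
        return sample_training_interaction(
            task.target_img, task.target_gland, self.f_min, self.f_max, rng)

    def interaction_at(self, task, frames) -> InteractionSample:
        return apply_mask(task.target_img, task.target_gland, frames)

    def _labels(self, task, sparse: bool):
        if sparse:
            return None  # replaced per-sample by the masked gland label
        srcs = [task.source_gland.values]
        tgts = [task.target_gland.values]
        if self.use_landmark_labels:
            for ls, lt in task.landmark_labels:
                srcs.append(ls.values)
                tgts.append(lt.values)
        return srcs, tgts

    def loss_and_grad(self, w: NetworkWeights, task, samples,
                      sparse: bool = False) -> tuple[float, dict]:
        params = self.net.as_params(w)
        total = None
        labels = self._labels(task, sparse)
        for sample in samples:
            x = stack_inputs(self.net.cfg, task.source_img,
                             sample.target_image_masked, sample.mask)
            ddf_t = self.net.forward_t(params, x)
            if sparse:
                loss_t = registration_loss_t(
                    [task.source_gland.values], [sample.target_label_masked.values],
                    ddf_t, self.loss_weights, task.source_img.spacing_mm,
                    mask=sample.mask.values)
            else:
                srcs, tgts = labels
                loss_t = registration_loss_t(
                    srcs, tgts, ddf_t, self.loss_weights,
                    task.source_img.spacing_mm)
            total = loss_t if total is None else total + loss_t
        total = total * (1.0 / len(samples))
        total.backward()
        grads = {name: p.grad if p.grad is not None else np.zeros_like(p.value)
                 for name, p in params.items()}
        return float(total.value), grads

    def predict(self, w: NetworkWeights, task, frames) -> "Volume":
        """Predict the field for a task at a given interaction state."""
        sample = self.interaction_at(task, frames)
        return self.net.predict_ddf(w, task.source_img,
                                    sample.target_image_masked, sample.mask)
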