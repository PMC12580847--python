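"""Conditional flow matching with optimal-transport pairing.

Training pairs a base sample x0 with the ground-truth transition-state
coordinates x1 through the linear (optimal transport) interpolant
x_t = (1−t)·x0 + t·x1, whose conditional velocity is the constant x1 − x0.
Before pairing, both endpoints are moved to the zero-centroid subspace and x0
is rotationally aligned onto x1 with the Kabsch algorithm (proper rotations
only), which straightens the transport paths the network has to learn.
The network u_θ(x_t, t | CGR) is regressed onto x1 − x0 with a mean squared
error over atoms.

Two base distributions are supported: per-coordinate standard normal noise,
and the reactant geometry perturbed by isotropic Gaussian noise with
σ² = 0.25 Å² (μ = 0), both centered after sampling.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .cgr import CGRGraph, build_cgr
from .errors import ConfigError, InputError, TrainingError
from .field import FieldNet, save_checkpoint
from .geom import align
from .nn import Adam, Tensor
from .reaction_io import Reaction

__all__ = ["FlowPair", "TrainConfig", "sample_base", "make_flow_pair",
           "cfm_loss", "train"]

#: variance of the reactant-noise base distribution (Å²)
REACTANT_NOISE_SIGMA2 = 0.25


@dataclass
class FlowPair:
    """One OT training pair; x_t = (1−t)·x0 + t·x1 holds exactly."""

    x0: np.ndarray        # aligned, centered base sample
    x1: np.ndarray        # centered ground-truth TS coordinates
    t: float
    x_t: np.ndarray
    v_target: np.ndarray  # x1 − x0


@dataclass
class TrainConfig:
    batch_size: int = 128
    lr: float = 5e-4
    epochs: int = 100
    seed: int = 0
    base: str = "gaussian"            # "gaussian" | "reactant_noise"
    sigma2: float = REACTANT_NOISE_SIGMA2
    draws_per_reaction: int = 1       # (t, x0) draws per reaction per epoch
    align: bool = True                # Kabsch-align x0 onto x1 (OT pairing)
    lr_schedule: str = "cosine"       # "cosine" | "constant"
    grad_clip: float = 10.0           # global gradient-norm clip (0 disables)


def sample_base(reaction: Reaction, mode: str, rng: np.random.Generator,
                sigma2: float = REACTANT_NOISE_SIGMA2) -> np.ndarray:
    """Draw x0 from the base distribution, centered at zero centroid."""
    n = reaction.n_atoms
    if mode == "gaussian":
        x0 = rng.standard_normal((n, 3))
    elif mode == "reactant_noise":
        if reaction.reactant_geometry is None:
            raise ConfigError(
                f"{reaction.rxn_id}: reactant_noise initialization requires a "
                "reactant geometry")
        x0 = reaction.reactant_geometry.coords + rng.normal(0.0, np.sqrt(sigma2), (n, 3))
    else:
        raise ConfigError(f"unknown base-distribution mode {mode!r}")
    return x0 - x0.mean(axis=0)


def make_flow_pair(x0_raw: np.ndarray, x1: np.ndarray, t: float,
                   use_align: bool = True) -> FlowPair:
    """Center both endpoints, align x0 onto x1, and form the interpolant."""
    x1c = np.asarray(x1, dtype=np.float64)
    x1c = x1c - x1c.mean(axis=0)
    if use_align:
        x0c = align(x0_raw, x1c)
    else:
        x0c = np.asarray(x0_raw, dtype=np.float64)
        x0c = x0c - x0c.mean(axis=0)
    x_t = (1.0 - t) * x0c + t * x1c
    return FlowPair(x0=x0c, x1=x1c, t=float(t), x_t=x_t, v_target=x1c - x0c)


def cfm_loss(field_net: FieldNet, pairs: list[FlowPair],
             cgrs: list[CGRGraph]) -> Tensor:
    """Mean over atoms of ‖u_θ(x_t, t) − (x1 − x0)‖² (sum over the 3 components).

    Differentiable w.r.t. the network parameters; call .backward() on the
    returned scalar Tensor.
    """
    if len(pairs) != len(cgrs) or not pairs:
        raise InputError("pairs and cgrs must be equal-length, non-empty lists")
    vel, _ = field_net.forward_batch([p.x_t for p in pairs], [p.t for p in pairs], cgrs)
    target = np.concatenate([p.v_target for p in pairs])
    diff = vel - Tensor(target)
    return (diff * diff).sum(axis=1).mean()


def train(dataset: list[Reaction], field_net: FieldNet, config: TrainConfig,
          out_dir: str | Path | None = None,
          ) -> tuple[FieldNet, list[dict]]:
    """Optimize the field network with the OT-CFM objective.

    Per epoch, every reaction contributes `draws_per_reaction` independent
    (t, x0) draws with t ~ Uniform(0, 1); pairs are built with Align and the
    loss gradient is applied per batch with Adam. Deterministic given
    config.seed. Returns the trained network and the per-epoch loss history;
    when `out_dir` is given, a checkpoint and a JSON-lines loss log are
    written there.
    """
    if not dataset:
        raise ConfigError("cannot train on an empty dataset")
    for rxn in dataset:
        if rxn.ts_geometry is None:
            raise ConfigError(f"{rxn.rxn_id}: training requires a TS geometry")
    rng = np.random.default_rng(config.seed)
    cgrs = [build_cgr(r, field_net.config.elements) for r in dataset]
    x1s = [r.ts_geometry.coords for r in dataset]

    params = field_net.parameters()
    opt = Adam(params, lr=config.lr)
    history: list[dict] = []
    n = len(dataset)
    for epoch in range(config.epochs):
        if config.lr_schedule == "cosine":
            opt.lr = config.lr * 0.5 * (1.0 + np.cos(np.pi * epoch / config.epochs))
        # one (t, x0) draw per reaction per pass, draws_per_reaction passes,
        # shuffled together and chunked into batch_size gradient steps
        order = np.concatenate([rng.permutation(n)
                                for _ in range(config.draws_per_reaction)])
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, order.size, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch_pairs, batch_cgrs = [], []
            for i in idx:
                t = float(rng.uniform())
                x0 = sample_base(dataset[i], config.base, rng, config.sigma2)
                batch_pairs.append(make_flow_pair(x0, x1s[i], t, config.align))
                batch_cgrs.append(cgrs[i])
            loss = cfm_loss(field_net, batch_pairs, batch_cgrs)
            if not np.isfinite(loss.data):
                raise TrainingError(f"non-finite loss at epoch {epoch}", epoch=epoch)
            opt.zero_grad()
            loss.backward()
            if config.grad_clip > 0:
                gnorm = np.sqrt(sum(float(np.sum(p.grad ** 2)) for p in params
                                    if p.grad is not None))
                if gnorm > config.grad_clip:
                    scale = config.grad_clip / gnorm
                    for p in params:
                        if p.grad is not None:
                            p.grad *= scale
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        history.append({"epoch": epoch, "loss": epoch_loss / n_batches,
                        "lr": config.lr, "time": time.time()})

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(field_net, out_dir / "checkpoint.npz")
        with open(out_dir / "loss_log.jsonl", "w") as fh:
            for rec in history:
                fh.write(json.dumps(rec) + "\n")
    return field_net, history
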