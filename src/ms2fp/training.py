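"""Training loop: label-smoothed cross-entropy, Adam, best-loss checkpointing.

Training is teacher-forced: the decoder input is the target sequence shifted
right, and the loss compares each position's predicted distribution with the
next true token. Padding positions are excluded from both attention and loss.
After every epoch whose mean loss improves on the best seen so far, the model
weights are written to the configured output directory, so the checkpoint on
disk always corresponds to the minimal training loss.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ms2fp import nn
from ms2fp.errors import Ms2fpError
from ms2fp.fingerprints import FingerprintSpec
from ms2fp.model import MintModel, positional_encoding, save_checkpoint
from ms2fp.tokenizer import FingerprintTarget, TokenizedSpectrum, TokenVocabulary, PAD_ID

CHECKPOINT_FILENAME = "checkpoint.npz"


@dataclass
class TrainConfig:
    epochs: int = 10
    batch_size: int = 8
    label_smoothing: float = 0.1
    learning_rate: float = 1e-4
    adam_betas: tuple[float, float] = (0.9, 0.98)
    weight_decay: float = 0.0
    seed: int = 42
    device: str = "cpu"
    output_directory: str | None = None
    checkpoint_policy: str = "minimal-loss"

    def __post_init__(self):
        if not 0 <= self.label_smoothing < 1:
            raise ValueError("label_smoothing must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.device not in ("cpu", "gpu"):
            raise ValueError("device must be 'cpu' or 'gpu'")


@dataclass
class TrainLog:
    epoch_losses: list[float] = field(default_factory=list)
    best_loss: float | None = None
    best_epoch: int | None = None
    wall_seconds: float = 0.0


def smoothed_cross_entropy(
    logits: np.ndarray,
    targets: np.ndarray,
    smoothing: float = 0.0,
    ignore_pad: bool = True,
    pad_id: int = PAD_ID,
) -> float:
    """Mean label-smoothed cross-entropy over non-pad positions.

    The smoothed target distribution places 1-eps on the true token and spreads
    eps uniformly over the remaining K-1 tokens.
    """
    loss, _, _ = _ce_loss_and_grad(logits, targets, smoothing, ignore_pad, pad_id)
    return loss


def _ce_loss_and_grad(
    logits: np.ndarray,
    targets: np.ndarray,
    smoothing: float,
    ignore_pad: bool,
    pad_id: int = PAD_ID,
) -> tuple[float, np.ndarray, int]:
    """Loss, gradient w.r.t. logits, and the number of scored positions."""
    logits = np.asarray(logits, dtype=np.float64)
    targets = np.asarray(targets)
    flat_logits = logits.reshape(-1, logits.shape[-1])
    flat_targets = targets.reshape(-1)
    n, k = flat_logits.shape
    if k < 2:
        raise ValueError("need at least two classes")

    keep = np.ones(n, dtype=bool)
    if ignore_pad:
        keep = flat_targets != pad_id
    n_keep = int(keep.sum())
    if n_keep == 0:
        raise Ms2fpError("loss undefined: every position is padding")

    shifted = flat_logits - flat_logits.max(axis=1, keepdims=True)
    log_z = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    log_p = shifted - log_z
    probs = np.exp(log_p)

    rows = np.arange(n)
    eps = smoothing
    q_other = eps / (k - 1)
    # -sum_j q_j log p_j = -(1-eps) log p_true - q_other * (sum_j log p_j - log p_true)
    per_position = -(1 - eps) * log_p[rows, flat_targets] - q_other * (
        log_p.sum(axis=1) - log_p[rows, flat_targets]
    )
    loss = float(per_position[keep].mean())

    q = np.full_like(flat_logits, q_other)
    q[rows, flat_targets] = 1 - eps
    dflat = (probs - q) / n_keep
    dflat[~keep] = 0.0
    return loss, dflat.reshape(logits.shape), n_keep


def collate(
    batch: Sequence[tuple[TokenizedSpectrum, FingerprintTarget]],
    d_model: int,
    classic_pe: bool,
) -> dict[str, np.ndarray]:
    """Pad a batch to rectangular arrays with aligned boolean pad masks."""
    enc_len = max(item[0].length for item in batch)
    dec_len = max(item[1].length for item in batch) - 1  # shifted by one
    b = len(batch)
    enc_ids = np.zeros((b, enc_len), dtype=np.int64)
    ranks = np.zeros((b, enc_len))
    intensities = np.zeros((b, enc_len))
    enc_pad = np.ones((b, enc_len), dtype=bool)
    dec_in = np.full((b, dec_len), PAD_ID, dtype=np.int64)
    dec_out = np.full((b, dec_len), PAD_ID, dtype=np.int64)
    dec_pad = np.ones((b, dec_len), dtype=bool)
    for i, (tok, tgt) in enumerate(batch):
        le = tok.length
        enc_ids[i, :le] = tok.token_ids
        ranks[i, :le] = tok.ranks
        intensities[i, :le] = tok.pseudo_intensities
        enc_pad[i, :le] = False
        seq = tgt.token_ids
        ld = len(seq) - 1
        dec_in[i, :ld] = seq[:-1]
        dec_out[i, :ld] = seq[1:]
        dec_pad[i, :ld] = False
    pe = positional_encoding(ranks, intensities, d_model, classic_pe)
    pe[enc_pad] = 0.0
    return {
        "enc_ids": enc_ids,
        "enc_pe": pe,
        "enc_pad": enc_pad,
        "dec_in": dec_in,
        "dec_out": dec_out,
        "dec_pad": dec_pad,
    }


def train(
    dataset: Sequence[tuple[TokenizedSpectrum, FingerprintTarget]],
    model: MintModel,
    cfg: TrainConfig,
    vocab: TokenVocabulary | None = None,
    fingerprint_spec: FingerprintSpec | None = None,
) -> tuple[MintModel, TrainLog]:
    """Train in place; returns the model restored to its best-loss weights.

    A checkpoint is (over)written in ``cfg.output_directory`` every time the
    epoch mean loss improves. With ``epochs=0`` the model is returned untouched
    with an empty log.
    """
    if not dataset:
        raise ValueError("dataset must be non-empty")
    log = TrainLog()
    if cfg.epochs == 0:
        return model, log

    rng = np.random.default_rng(cfg.seed)
    optimizer = nn.Adam(
        lr=cfg.learning_rate,
        betas=tuple(cfg.adam_betas),
        weight_decay=cfg.weight_decay,
    )
    out_dir = Path(cfg.output_directory) if cfg.output_directory else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    best_state = None
    started = time.monotonic()
    indices = np.arange(len(dataset))
    for epoch in range(cfg.epochs):
        rng.shuffle(indices)
        total_loss = 0.0
        total_positions = 0
        for start in range(0, len(indices), cfg.batch_size):
            batch = [dataset[i] for i in indices[start : start + cfg.batch_size]]
            arrays = collate(batch, model.config.d_model, model.config.classic_pe)
            model.zero_grad()
            logits = model.forward(
                arrays["enc_ids"],
                arrays["enc_pe"],
                arrays["enc_pad"],
                arrays["dec_in"],
                arrays["dec_pad"],
                rng=rng,
                train=True,
            )
            loss, dlogits, n_positions = _ce_loss_and_grad(
                logits, arrays["dec_out"], cfg.label_smoothing, ignore_pad=True
            )
            if math.isnan(loss) or math.isinf(loss):
                raise Ms2fpError(
                    f"training diverged at epoch {epoch}: loss={loss} "
                    f"(lr={cfg.learning_rate}, batch={start // cfg.batch_size})"
                )
            model.backward(dlogits)
            optimizer.step(model.named_parameters())
            total_loss += loss * n_positions
            total_positions += n_positions
        epoch_loss = total_loss / total_positions
        log.epoch_losses.append(epoch_loss)
        if log.best_loss is None or epoch_loss < log.best_loss:
            log.best_loss = epoch_loss
            log.best_epoch = epoch
            best_state = model.state_dict()
            if out_dir is not None:
                save_checkpoint(
                    out_dir / CHECKPOINT_FILENAME,
                    model,
                    vocab or TokenVocabulary(),
                    fingerprint_spec,
                    metadata={"best_loss": epoch_loss, "best_epoch": epoch},
                )
    log.wall_seconds = time.monotonic() - started
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, log
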