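"""Training loop, evaluation pipeline and ablation harness.

Defaults follow the reference recipe for fundus training: batch size 2,
Adam at learning rate 1e-3, 200 epochs with x0.1 decay at epochs 150 and
190, online augmentation, deep supervision with auxiliary-loss weight 1.0,
and the best epoch (by pooled test AUC) kept for testing.  Runs are fully
seeded and deterministic on CPU.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .errors import ConfigurationError
from .metrics import MetricsReport, confusion_metrics, pooled_metrics
from .network import CascadeNet, NetworkConfig
from .pib import PIBWeightParams, compute_pib_weights, total_supervised_loss
from .preproc import AugmentSpec, PadSpec, augment, crop_back, pad_to
from .synthetic import FundusSample

__all__ = [
    "TrainConfig",
    "TrainState",
    "train",
    "predict",
    "evaluate",
    "run_ablation",
    "save_checkpoint",
    "load_checkpoint",
    "ABLATION_VARIANTS",
]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 2
    lr: float = 1e-3
    optimizer: str = "adam"
    epochs: int = 200
    lr_decay_epochs: tuple[int, ...] = (150, 190)
    lr_decay_factor: float = 0.1
    lambda_aux: float = 1.0
    use_pib_loss: bool = True
    pib_params: PIBWeightParams = field(default_factory=PIBWeightParams)
    augment: AugmentSpec | None = field(default_factory=AugmentSpec)
    select_by: str = "auc"  # "auc" or "last"
    seed: int = 0
    device: str = "cpu"

    def __post_init__(self):
        if self.lr <= 0:
            raise ConfigurationError("learning rate must be positive")
        if any(e >= self.epochs for e in self.lr_decay_epochs):
            raise ConfigurationError("decay epochs must be < total epochs")
        if self.optimizer != "adam":
            raise ConfigurationError("only the adam optimizer is supported")
        if self.select_by not in ("auc", "last"):
            raise ConfigurationError("select_by must be 'auc' or 'last'")


@dataclass
class TrainState:
    epoch: int = 0
    train_loss: float = float("nan")
    test_loss: float = float("nan")
    best_metric: float = -np.inf
    best_epoch: int = -1
    history: list[dict] = field(default_factory=list)


def _to_input(sample: FundusSample, pad: PadSpec) -> np.ndarray:
    """HWC image -> padded CHW float32."""
    img = pad_to(sample.image, pad)
    return np.ascontiguousarray(img.transpose(2, 0, 1)).astype(np.float32)


def _pad_spec_for(sample: FundusSample) -> PadSpec:
    h, w = sample.mask.shape
    if h % 4 == 0 and w % 4 == 0:
        return PadSpec.centered((h, w), (h, w))
    return PadSpec.square16((h, w))


def _batch_arrays(samples: list[FundusSample]):
    pads = [_pad_spec_for(s) for s in samples]
    th = max(p.target_height for p in pads)
    tw = max(p.target_width for p in pads)
    pads = [PadSpec.centered((s.mask.shape[0], s.mask.shape[1]), (th, tw)) for s in samples]
    x = np.stack([_to_input(s, p) for s, p in zip(samples, pads)])
    y = np.stack([pad_to(s.mask, p) for s, p in zip(samples, pads)])[:, None].astype(np.float32)
    return x, y, pads


def _effective_lambda(model_cfg: NetworkConfig, train_cfg: TrainConfig) -> float:
    if not model_cfg.use_cascade or not model_cfg.use_aux_supervision:
        return 0.0
    return train_cfg.lambda_aux


def _batch_loss(model: CascadeNet, x, y, train_cfg: TrainConfig, lam: float):
    out = model(nn.Tensor(x))
    if train_cfg.use_pib_loss:
        weights = compute_pib_weights(y, train_cfg.pib_params)
    else:
        weights = np.ones_like(y, dtype=np.float64)
    return total_supervised_loss(out.fine, out.coarse, y, lambda_aux=lam, weights=weights), out


def _test_pass(model, samples, train_cfg, lam):
    """Mean test loss and pooled test AUC of the fine-stage output."""
    from sklearn.metrics import roc_auc_score

    model.eval()
    losses, preds, ys = [], [], []
    with nn.no_grad():
        for s in samples:
            x, y, pads = _batch_arrays([s])
            sup, out = _batch_loss(model, x, y, train_cfg, lam)
            losses.append(sup.item())
            prob = crop_back(out.fine.data[0, 0], pads[0])
            fov = s.fov.astype(bool) if s.fov is not None else np.ones_like(s.mask, bool)
            preds.append(prob[fov])
            ys.append(s.mask[fov])
    model.train()
    y_all = np.concatenate(ys)
    auc = float("nan")
    if y_all.min() != y_all.max():
        auc = float(roc_auc_score(y_all, np.concatenate(preds)))
    return float(np.mean(losses)), auc


def train(
    model_cfg: NetworkConfig,
    train_cfg: TrainConfig,
    train_samples: list[FundusSample],
    test_samples: list[FundusSample] | None = None,
    out_dir: str | Path | None = None,
    verbose: bool = False,
    initial_model: CascadeNet | None = None,
) -> tuple[CascadeNet, TrainState]:
    """Train a cascade model; returns the model at its best epoch.

    The best epoch is selected by pooled test AUC (``select_by='auc'``,
    the default) or the final epoch (``'last'``).  Without test samples
    the final epoch is kept.  Pass ``initial_model`` to resume training
    from existing weights instead of a fresh initialisation.
    """
    if not train_samples:
        raise ConfigurationError("training set is empty")
    model = CascadeNet(model_cfg) if initial_model is None else initial_model
    opt = nn.Adam(model.parameters(), lr=train_cfg.lr)
    sched = nn.MultiStepLR(opt, train_cfg.lr_decay_epochs, train_cfg.lr_decay_factor)
    order_rng = np.random.default_rng(np.random.SeedSequence((train_cfg.seed, 11)))
    aug_rng = np.random.default_rng(np.random.SeedSequence((train_cfg.seed, 12)))
    lam = _effective_lambda(model_cfg, train_cfg)
    state = TrainState()
    best_state_dict = None

    for epoch in range(train_cfg.epochs):
        sched.step(epoch)
        idx = order_rng.permutation(len(train_samples))
        epoch_losses = []
        for start in range(0, len(idx), train_cfg.batch_size):
            batch = [train_samples[i] for i in idx[start : start + train_cfg.batch_size]]
            if train_cfg.augment is not None:
                batch = [augment(s, train_cfg.augment, rng=aug_rng) for s in batch]
            x, y, _ = _batch_arrays(batch)
            sup, _ = _batch_loss(model, x, y, train_cfg, lam)
            loss_value = sup.item()
            if not np.isfinite(loss_value):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"step {start // train_cfg.batch_size}"
                )
            opt.zero_grad()
            sup.total.backward()
            opt.step()
            epoch_losses.append(
                {
                    "total": loss_value,
                    "main": sup.loss_main.item(),
                    "aux": sup.loss_aux.item(),
                }
            )
        state.epoch = epoch
        state.train_loss = float(np.mean([e["total"] for e in epoch_losses]))

        test_loss, test_auc = float("nan"), float("nan")
        if test_samples:
            test_loss, test_auc = _test_pass(model, test_samples, train_cfg, lam)
        state.test_loss = test_loss
        record = {
            "epoch": epoch,
            "lr": opt.lr,
            "train_loss": state.train_loss,
            "train_loss_main": float(np.mean([e["main"] for e in epoch_losses])),
            "train_loss_aux": float(np.mean([e["aux"] for e in epoch_losses])),
            "test_loss": test_loss,
            "test_auc": test_auc,
        }
        state.history.append(record)
        if verbose:
            print(
                f"epoch {epoch:3d}  lr {opt.lr:.1e}  train {state.train_loss:.4f}"
                f"  test {test_loss:.4f}  auc {test_auc:.4f}"
            )

        select_metric = test_auc if train_cfg.select_by == "auc" else epoch
        if test_samples and np.isfinite(select_metric) and select_metric > state.best_metric:
            state.best_metric = float(select_metric)
            state.best_epoch = epoch
            best_state_dict = model.state_dict()

    if best_state_dict is not None:
        model.load_state_dict(best_state_dict)
    else:
        state.best_epoch = train_cfg.epochs - 1

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_history(state.history, out_dir)
        save_checkpoint(model, out_dir / "checkpoint.npz")
        manifest = {
            "network": asdict(model_cfg),
            "training": _config_dict(train_cfg),
            "best_epoch": state.best_epoch,
            "best_metric": state.best_metric,
        }
        (out_dir / "run.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return model, state


def _config_dict(train_cfg: TrainConfig) -> dict:
    d = asdict(train_cfg)
    d["pib_params"] = asdict(train_cfg.pib_params)
    if train_cfg.augment is not None:
        d["augment"] = asdict(train_cfg.augment)
    return d


def _write_history(history: list[dict], out_dir: Path) -> None:
    import csv

    with open(out_dir / "history.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(history[0].keys()))
        writer.writeheader()
        writer.writerows(history)
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.5))
        epochs = [h["epoch"] for h in history]
        ax.plot(epochs, [h["train_loss"] for h in history], label="train")
        if np.isfinite([h["test_loss"] for h in history]).any():
            ax.plot(epochs, [h["test_loss"] for h in history], label="test")
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out_dir / "loss_curve.png", dpi=120)
        plt.close(fig)
    except Exception as exc:  # pragma: no cover - plotting is best-effort
        warnings.warn(f"could not write loss curve: {exc}")


def predict(model: CascadeNet, sample: FundusSample) -> np.ndarray:
    """Fine-stage probability map at the sample's original resolution."""
    model.eval()
    x, _, pads = _batch_arrays([sample])
    with nn.no_grad():
        out = model(nn.Tensor(x))
    return crop_back(out.fine.data[0, 0], pads[0])


def evaluate(
    model_or_checkpoint,
    samples: list[FundusSample],
    threshold: float = 0.5,
    use_fov: bool = True,
) -> tuple[MetricsReport, list[MetricsReport]]:
    """Score a model on a dataset.

    Images are padded, run through the cascade, and the fine-stage map is
    cropped back to the original size before scoring.  Returns the pooled
    (all pixels of all images) report and the per-image reports.
    """
    if isinstance(model_or_checkpoint, (str, Path)):
        model = load_checkpoint(model_or_checkpoint)
    else:
        model = model_or_checkpoint
    preds = [predict(model, s) for s in samples]
    masks = [s.mask for s in samples]
    fovs = [s.fov if use_fov else None for s in samples]
    per_image = [
        confusion_metrics(p, m, threshold=threshold, fov=f)
        for p, m, f in zip(preds, masks, fovs)
    ]
    pooled = pooled_metrics(preds, masks, threshold=threshold, fovs=fovs)
    return pooled, per_image


def save_checkpoint(model: CascadeNet, path: str | Path) -> None:
    state = model.state_dict()
    cfg = asdict(model.config)
    np.savez(path, __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str | Path) -> CascadeNet:
    with np.load(path) as data:
        cfg = json.loads(bytes(data["__config__"]).decode())
        for key in ("channel_schedule", "dilation_rates", "lr_decay_epochs"):
            if key in cfg and isinstance(cfg[key], list):
                cfg[key] = tuple(cfg[key])
        model = CascadeNet(NetworkConfig(**cfg))
        model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return model


def _variant(use_cascade, use_aux, use_isam, use_pib):
    return {
        "use_cascade": use_cascade,
        "use_aux_supervision": use_aux,
        "use_isam": use_isam,
        "use_pib_loss": use_pib,
    }


#: The component-ablation lattice: residual-U-Net baseline, then cascade
#: design (CD), auxiliary supervision (AS), inter-stage attention (ISAM)
#: and the pixel-importance-balanced loss (PIBL) added stepwise.
ABLATION_VARIANTS: dict[str, dict] = {
    "baseline": _variant(False, False, False, False),
    "cd": _variant(True, False, False, False),
    "cd_as": _variant(True, True, False, False),
    "cd_as_isam": _variant(True, True, True, False),
    "cd_as_pibl": _variant(True, True, False, True),
    "full": _variant(True, True, True, True),
}


def run_ablation(
    variants: dict[str, dict] | list[str],
    model_cfg: NetworkConfig,
    train_cfg: TrainConfig,
    train_samples: list[FundusSample],
    test_samples: list[FundusSample],
    threshold: float = 0.5,
):
    """Train/evaluate each network-configuration variant; return a DataFrame.

    ``variants`` maps a row name to flag overrides (see
    :data:`ABLATION_VARIANTS`), or is a list of preset names.
    """
    import dataclasses

    import pandas as pd

    if isinstance(variants, list):
        variants = {name: ABLATION_VARIANTS[name] for name in variants}
    rows = []
    for name, flags in variants.items():
        net_flags = {k: v for k, v in flags.items() if k != "use_pib_loss"}
        cfg = dataclasses.replace(model_cfg, **net_flags)
        tcfg = dataclasses.replace(train_cfg, use_pib_loss=flags.get("use_pib_loss", True))
        model, state = train(cfg, tcfg, train_samples, test_samples)
        pooled, _ = evaluate(model, test_samples, threshold=threshold)
        rows.append(
            {
                "variant": name,
                "se": pooled.se,
                "sp": pooled.sp,
                "acc": pooled.acc,
                "f1": pooled.f1,
                "auc": pooled.auc,
                "best_epoch": state.best_epoch,
            }
        )
    return pd.DataFrame(rows)
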