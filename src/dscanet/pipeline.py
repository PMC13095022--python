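"""Model assembly, training/evaluation loops, complexity accounting, ablation.

The full network wires the two encoder branches stage-by-stage:

    image ─┬─ edge encoder (PDC) ──► E1..E4 ──► deep-supervised edge maps
           └─ body encoder (Swin) ─► B1..B4
    fuse:   F_i = ConvBNReLU([E_i ∥ B_i])            (per-stage fusion)
    SCA:    refined edge tokens ──► maps added to the decoder skips
    BF:     (F1, F4) class-token exchange ──► replaces skips 1 and 4
    decode: U-shaped decoder with gated axial attention ──► logit map

Ablation switches disable SCA / BF / FAA independently; with all three
off the model is the two-branch baseline (M1).  Parameter and FLOP
accounting is analytic: parameters are summed over trainable elements,
FLOPs are counted per matmul/convolution during a single shape-accurate
forward pass and reported as 2·MACs (one multiply + one add).
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import yaml

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .bf import BFConfig, BipolarFusion
from .body_encoder import BodyConfig, BodyEncoder
from .data import ImageSample
from .decoder_faa import Decoder, DecoderConfig
from .edge_encoder import EdgeEncoder
from .losses import LossWeights, total_loss
from .metrics import MetricsReport, compute_metrics, confusion
from .sca import SCAConfig, SCAProjectBack, SpatialCrossAttention

__all__ = [
    "ModelConfig", "TrainConfig", "ComplexityReport", "DSCANet",
    "build_model", "count_params", "count_flops", "complexity_report",
    "train", "evaluate", "ablate", "ablation_grid",
    "save_checkpoint", "load_checkpoint", "config_to_yaml", "config_from_yaml",
    "tiny_config",
]


@dataclasses.dataclass
class ModelConfig:
    body: BodyConfig = dataclasses.field(default_factory=BodyConfig)
    edge_width: int = 32
    pdc_variant: str = "central"
    sca_enabled: bool = True
    sca: SCAConfig = dataclasses.field(default_factory=SCAConfig)
    bf_enabled: bool = True
    bf: BFConfig = dataclasses.field(default_factory=BFConfig)
    bf_dim: int = 112            # width of the reduced deep level inside BF
    faa_enabled: bool = True
    decoder: DecoderConfig = dataclasses.field(default_factory=DecoderConfig)
    skip_widths: tuple | None = (96, 192, 320, 384)  # fused widths; None → body widths
    input_size: int = 224
    seed: int = 0

    def validate(self):
        self.body.validate()
        self.sca.validate()
        self.bf.validate()
        self.decoder.validate()
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")

    def ablation(self, sca: bool, bf: bool, faa: bool) -> "ModelConfig":
        cfg = dataclasses.replace(self, sca_enabled=sca, bf_enabled=bf,
                                  faa_enabled=faa)
        return cfg


@dataclasses.dataclass
class TrainConfig:
    optimizer: str = "adam"
    lr: float = 0.01
    weight_decay: float = 0.01
    patience: int = 5
    factor: float = 0.5
    min_lr: float = 1e-6
    batch_size: int = 16
    epochs: int = 200
    input_size: int = 224
    grad_clip: float = 0.0     # global-norm clip; 0 disables
    seed: int = 0
    device: str = "cpu"

    def validate(self):
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.device != "cpu":
            raise ValueError("only cpu execution is supported")


@dataclasses.dataclass
class ComplexityReport:
    params_m: float        # trainable parameters, millions
    flops_g: float         # 2·MACs for one forward pass, giga
    input_size: int
    macs_by_section: dict


class DSCANet(nn.Module):
    """Dual-branch polyp segmentation network with ablation switches."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        rng = nn.seeded_rng(cfg.seed)
        size = cfg.input_size

        self.edge = EdgeEncoder(rng, base_width=cfg.edge_width,
                                variant=cfg.pdc_variant)
        self.body = BodyEncoder(cfg.body, rng)
        # materialize the positional term for the configured input size so
        # checkpoints are complete before any forward pass
        self.body.patch_embed._pos_embed((size // cfg.body.patch_size) ** 2,
                                         cfg.body.embed_dim)
        e_w, b_w = self.edge.widths, self.body.widths
        s_w = list(cfg.skip_widths) if cfg.skip_widths else list(b_w)
        self.fuse = [nn.ConvBNReLU(e + b, s, 1, rng)
                     for e, b, s in zip(e_w, b_w, s_w)]
        self.skip_widths = s_w

        if cfg.sca_enabled:
            self.sca = SpatialCrossAttention(e_w, cfg.sca, rng)
            back_w = b_w if cfg.sca.target == "body" else s_w
            self.sca_back = [SCAProjectBack(e, t, rng) for e, t in zip(e_w, back_w)]

        if cfg.bf_enabled:
            n_small = (size // 4) ** 2
            n_large = (size // 32) ** 2
            self.bf_reduce = nn.ConvBNReLU(s_w[3], cfg.bf_dim, 1, rng)
            self.bf_expand = nn.ConvBNReLU(cfg.bf_dim, s_w[3], 1, rng)
            self.bf = BipolarFusion(s_w[0], cfg.bf_dim, n_small, n_large,
                                    cfg.bf, rng)

        self.decoder = Decoder(self.skip_widths, cfg.decoder, rng,
                               use_faa=cfg.faa_enabled)

    def forward(self, image) -> tuple:
        """Returns (logits (B,1,H,W), [4 edge probability maps at H×W])."""
        image = ad.tensor(image)
        out_size = (image.shape[-2], image.shape[-1])
        with ad.mac_scope("edge_encoder"):
            edge_pyr = self.edge(image)
        with ad.mac_scope("body_encoder"):
            body_feats = self.body(image)
        refined = None
        if self.cfg.sca_enabled:
            with ad.mac_scope("sca"):
                refined = self.sca(edge_pyr.features)
                if self.cfg.sca.target == "body":
                    body_feats = [b + back(r, (b.shape[-2], b.shape[-1]))
                                  for b, back, r in zip(body_feats, self.sca_back, refined)]
        with ad.mac_scope("fusion"):
            fused = [f(ad.concatenate([e, b], axis=1))
                     for f, e, b in zip(self.fuse, edge_pyr.features, body_feats)]
        if refined is not None and self.cfg.sca.target == "decoder":
            with ad.mac_scope("sca"):
                fused = [f + back(r, (f.shape[-2], f.shape[-1]))
                         for f, back, r in zip(fused, self.sca_back, refined)]
        if self.cfg.bf_enabled:
            with ad.mac_scope("bf"):
                deep = self.bf_reduce(fused[3])
                f1, f4 = self.bf(fused[0], deep)
                fused[0] = f1
                fused[3] = self.bf_expand(f4)
        with ad.mac_scope("decoder"):
            logits = self.decoder(fused, out_size)
        return logits, edge_pyr.edge_maps


def build_model(cfg: ModelConfig | None = None) -> DSCANet:
    return DSCANet(cfg or ModelConfig())


def tiny_config(input_size: int = 64, seed: int = 0) -> ModelConfig:
    """Reduced-width configuration for desk-scale experiments: C=24,
    depths (1,1,2,1), 64×64 inputs."""
    return ModelConfig(
        body=BodyConfig(embed_dim=24, depths=(1, 1, 2, 1), heads=(3, 6, 12, 24),
                        window_size=4),
        edge_width=16,
        bf_dim=96,
        decoder=DecoderConfig(widths=(96, 48, 32, 24), refine_widths=(16, 16),
                              heads=4),
        input_size=input_size,
        seed=seed,
    )


# -- complexity ----------------------------------------------------------------

def count_params(model: nn.Module) -> float:
    """Trainable parameter count in millions."""
    return model.n_parameters() / 1e6


def count_flops(model: DSCANet, input_size: int | None = None) -> tuple:
    """Analytic FLOPs (2·MACs, in G) of one forward pass.

    MACs are recorded by every matmul and convolution during a single
    real forward on a zero image, so each layer is counted exactly once
    with its true shapes; elementwise work is excluded by convention.
    Returns (flops_g, macs_by_section).
    """
    size = input_size or model.cfg.input_size
    x = np.zeros((1, 3, size, size), dtype=np.float32)
    was_training = model.training
    model.eval()
    with ad.no_grad(), ad.count_macs({}) as macs:
        model(x)
    model.train(was_training)
    flops_g = 2.0 * macs["total"] / 1e9
    return flops_g, {k: v for k, v in macs.items() if k != "total"}


def complexity_report(cfg: ModelConfig | None = None) -> ComplexityReport:
    model = build_model(cfg)
    params = count_params(model)
    flops, sections = count_flops(model)
    return ComplexityReport(params_m=params, flops_g=flops,
                            input_size=model.cfg.input_size,
                            macs_by_section=sections)


# -- batching ------------------------------------------------------------------

def _to_batch(samples: list) -> tuple:
    imgs = np.stack([s.image.transpose(2, 0, 1) for s in samples]).astype(np.float32)
    masks = np.stack([s.mask[None] for s in samples]).astype(np.float32)
    edges = np.stack([s.edge[None] for s in samples]).astype(np.float32)
    return imgs, masks, edges


# -- training ------------------------------------------------------------------

def train(model: DSCANet, train_samples: list, tcfg: TrainConfig,
          val_samples: list | None = None, loss_weights: LossWeights | None = None,
          out_dir=None, callback=None) -> dict:
    """Train the model; returns {"history": [...], "best": state_dict, ...}.

    Per epoch the history records the full loss report, learning rate
    and validation metrics; the best-by-validation-DSC parameters are
    kept (training metrics stand in when no validation set is given).
    A non-finite loss aborts with the last finite-loss parameters.
    """
    tcfg.validate()
    w = loss_weights or LossWeights()
    rng = nn.seeded_rng(tcfg.seed)
    opt_cls = nn.Adam if tcfg.optimizer == "adam" else nn.SGD
    opt = opt_cls(model.parameters(), lr=tcfg.lr, weight_decay=tcfg.weight_decay)
    sched = nn.ReduceLROnPlateau(opt, patience=tcfg.patience, factor=tcfg.factor,
                                 min_lr=tcfg.min_lr)
    history, best_state, best_dsc = [], model.state_dict(), -1.0
    last_good = model.state_dict()
    out_dir = Path(out_dir) if out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    n = len(train_samples)
    for epoch in range(tcfg.epochs):
        model.train()
        order = rng.permutation(n)
        epoch_losses = []
        for lo in range(0, n, tcfg.batch_size):
            batch = [train_samples[i] for i in order[lo:lo + tcfg.batch_size]]
            imgs, masks, edges = _to_batch(batch)
            logits, edge_maps = model(imgs)
            pred = ad.sigmoid(logits)
            loss, report = total_loss(pred, masks, edge_maps, edges, w)
            if not math.isfinite(report.total):
                model.load_state_dict(last_good)
                entry = {"epoch": epoch, "event": "non_finite_loss_abort"}
                history.append(entry)
                return {"history": history, "best": best_state, "best_dsc": best_dsc,
                        "aborted": True}
            model.zero_grad()
            loss.backward()
            if tcfg.grad_clip > 0:
                _clip_grad_norm(model.parameters(), tcfg.grad_clip)
            opt.step()
            epoch_losses.append(report)
        last_good = model.state_dict()

        mean_report = {k: float(np.mean([getattr(r, k) for r in epoch_losses]))
                       for k in ("edge", "bce", "dice", "body", "total")}
        eval_on = val_samples if val_samples else train_samples
        ev = evaluate(model, eval_on)
        monitored = _validation_loss(model, eval_on, w)
        entry = {"epoch": epoch, "loss": mean_report, "lr": opt.lr,
                 "val_metrics": ev.as_dict(), "val_loss": monitored}
        history.append(entry)
        if out_dir:
            with open(out_dir / "history.jsonl", "a") as fh:
                fh.write(json.dumps(entry) + "\n")
        if ev.dsc > best_dsc:
            best_dsc, best_state = ev.dsc, model.state_dict()
        sched.step(monitored)
        if callback:
            callback(entry)

    return {"history": history, "best": best_state, "best_dsc": best_dsc,
            "aborted": False}


def _clip_grad_norm(params, max_norm: float):
    total = math.sqrt(sum(float((p.grad ** 2).sum())
                          for p in params if p.grad is not None))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale


def _validation_loss(model: DSCANet, samples: list, w: LossWeights,
                     batch_size: int = 8) -> float:
    model.eval()
    tot, count = 0.0, 0
    with ad.no_grad():
        for lo in range(0, len(samples), batch_size):
            imgs, masks, edges = _to_batch(samples[lo:lo + batch_size])
            logits, edge_maps = model(imgs)
            _, report = total_loss(ad.sigmoid(logits), masks, edge_maps, edges, w)
            tot += report.total * len(samples[lo:lo + batch_size])
            count += len(samples[lo:lo + batch_size])
    return tot / max(count, 1)


def evaluate(model: DSCANet, samples: list, threshold: float = 0.5,
             aggregation: str = "per_image_mean", batch_size: int = 8,
             return_predictions: bool = False):
    """Evaluate on a sample list; returns a MetricsReport (or a tuple with
    per-sample predicted masks when requested)."""
    model.eval()
    counts, preds = [], []
    with ad.no_grad():
        for lo in range(0, len(samples), batch_size):
            batch = samples[lo:lo + batch_size]
            imgs, masks, _ = _to_batch(batch)
            logits, _ = model(imgs)
            prob = ad.sigmoid(logits).data
            for b, s in enumerate(batch):
                counts.append(confusion(prob[b, 0], s.mask, threshold))
                if return_predictions:
                    preds.append((prob[b, 0] >= threshold).astype(np.uint8))
    report = compute_metrics(counts, aggregation=aggregation)
    return (report, preds) if return_predictions else report


# -- ablation ------------------------------------------------------------------

ABLATION_GRID = {
    "M1": dict(sca=False, bf=False, faa=False),
    "M2": dict(sca=True, bf=False, faa=False),
    "M3": dict(sca=False, bf=True, faa=False),
    "M4": dict(sca=False, bf=False, faa=True),
    "M5": dict(sca=True, bf=True, faa=False),
    "M6": dict(sca=True, bf=False, faa=True),
    "M7": dict(sca=False, bf=True, faa=True),
    "DSCANet": dict(sca=True, bf=True, faa=True),
}


def ablation_grid(base: ModelConfig) -> dict:
    """The eight module-ablation configurations (baseline M1 … full)."""
    return {name: base.ablation(**flags) for name, flags in ABLATION_GRID.items()}


def ablate(base: ModelConfig, train_samples: list, test_samples: list,
           tcfg: TrainConfig, loss_weights: LossWeights | None = None,
           names: list | None = None, callback=None) -> dict:
    """Train/evaluate every ablation setting on identical data and seeds.

    Returns {name: {"metrics": MetricsReport-dict, "train_dsc": float}}.
    """
    rows = {}
    for name, cfg in ablation_grid(base).items():
        if names and name not in names:
            continue
        model = build_model(cfg)
        result = train(model, train_samples, tcfg, loss_weights=loss_weights)
        model.load_state_dict(result["best"])
        ev = evaluate(model, test_samples)
        tr = evaluate(model, train_samples)
        rows[name] = {"metrics": ev.as_dict(), "train_dsc": tr.dsc,
                      "aborted": result["aborted"]}
        if callback:
            callback(name, rows[name])
    return rows


# -- config / checkpoint serialization -----------------------------------------

def _cfg_to_dict(cfg) -> dict:
    if dataclasses.is_dataclass(cfg):
        return {f.name: _cfg_to_dict(getattr(cfg, f.name))
                for f in dataclasses.fields(cfg)}
    if isinstance(cfg, tuple):
        return list(cfg)
    return cfg


def config_to_yaml(cfg: ModelConfig) -> str:
    return yaml.safe_dump(_cfg_to_dict(cfg), sort_keys=True)


def config_from_yaml(text: str) -> ModelConfig:
    raw = yaml.safe_load(text)

    def tup(d, key):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])

    body = raw.pop("body", {})
    for k in ("depths", "heads"):
        tup(body, k)
    tup(raw, "skip_widths")
    sca = raw.pop("sca", {})
    bf = raw.pop("bf", {})
    dec = raw.pop("decoder", {})
    for k in ("widths", "refine_widths", "faa_stages"):
        tup(dec, k)
    return ModelConfig(body=BodyConfig(**body), sca=SCAConfig(**sca),
                       bf=BFConfig(**bf), decoder=DecoderConfig(**dec), **raw)


def save_checkpoint(model: DSCANet, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:
        np.savez(fh, __config__=config_to_yaml(model.cfg), **model.state_dict())


def load_checkpoint(path) -> DSCANet:
    with np.load(Path(path), allow_pickle=False) as zf:
        cfg = config_from_yaml(str(zf["__config__"]))
        state = {k: zf[k] for k in zf.files if k != "__config__"}
    model = build_model(cfg)
    model.load_state_dict(state)
    return model
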