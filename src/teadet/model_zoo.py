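"""Declarative construction of every detector variant, with exact
parameter counts and FLOP totals.

A :class:`ModelConfig` is the full architectural genotype: stem type,
nominal backbone stage repeats, depth/width multiples, neck family,
neck CSP flavour, input channels and class count.  ``build_detector``
realises it as a runnable model; ``summarize`` reports the deployment
(BN-fused) parameter count and the 2x multiply-accumulate GFLOPs at a
stated image size — the conventions under which this detector family's
variant tables are published.
"""
from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

from .autograd import Tensor, concat
from .blocks import count_flops_traced, count_parameters
from .nn import C3, SPPF, SPP, ConvBnAct, Detect, Focus, Module

__all__ = [
    "ModelConfig", "ModelSummary", "Detector", "effective_depth",
    "build_detector", "summarize", "PRESETS", "preset_config",
]

DEFAULT_ANCHORS = [
    [10, 13, 16, 30, 33, 23],        # P3 / stride 8
    [30, 61, 62, 45, 59, 119],       # P4 / stride 16
    [116, 90, 156, 198, 373, 326],   # P5 / stride 32
]


def make_divisible(x, div=8):
    return int(math.ceil(x / div) * div)


def effective_depth(n_nominal, depth_multiple):
    """Realised repeat count: round-half-up of n*depth, at least 1."""
    if n_nominal < 1:
        raise ValueError("nominal repeat count must be >= 1")
    if not 0 < depth_multiple <= 1:
        raise ValueError("depth multiple must be in (0, 1]")
    return max(int(n_nominal * depth_multiple + 0.5), 1)


@dataclass
class ModelConfig:
    stem: str = "focus"                  # focus | conv6
    stage_repeats: tuple = (3, 6, 9, 3)  # nominal CSP1_n counts
    depth_multiple: float = 0.33
    width_multiple: float = 0.50
    neck: str = "panet"                  # panet | fpn
    neck_csp: str = "csp2"               # csp2 | c3_dsconv
    in_channels: int = 3
    num_classes: int = 1
    anchors: list = field(default_factory=lambda: [list(a) for a in DEFAULT_ANCHORS])
    img_size: int = 640
    spp: str = "sppf"                    # sppf | spp (parameter-identical)

    def __post_init__(self):
        if self.stem not in ("focus", "conv6"):
            raise ValueError(f"unknown stem {self.stem!r}")
        if len(self.stage_repeats) != 4 or any(r < 1 for r in self.stage_repeats):
            raise ValueError("stage_repeats must be 4 counts, each >= 1")
        if self.neck not in ("panet", "fpn"):
            raise ValueError(f"unknown neck {self.neck!r}")
        if self.neck_csp not in ("csp2", "c3_dsconv"):
            raise ValueError(f"unknown neck_csp {self.neck_csp!r}")
        if self.in_channels not in (3, 4):
            raise ValueError("in_channels must be 3 or 4")
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")
        if len(self.anchors) != 3 or any(len(a) != 6 for a in self.anchors):
            raise ValueError("anchors: 3 levels of 3 (w, h) pairs")
        self.stage_repeats = tuple(self.stage_repeats)

    # ------------------------------------------------------------------
    def width(self, c):
        return make_divisible(c * self.width_multiple)

    def depth(self, n):
        return effective_depth(n, self.depth_multiple)

    def to_yaml(self):
        d = asdict(self)
        d["stage_repeats"] = list(d["stage_repeats"])
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text):
        return cls(**yaml.safe_load(text))


@dataclass
class ModelSummary:
    parameter_count: int          # fused (deployment) convention
    parameter_count_train: int    # all learnable arrays incl. BN affine
    gflops: float                 # 2x multiply-accumulate convention
    gflops_ma: float              # (2*Cin*K^2 - 1) per-layer form
    img_size: int
    per_stage: list               # (layer name, fused parameter count)

    def __post_init__(self):
        assert self.parameter_count == sum(p for _, p in self.per_stage)


class Detector(Module):
    """Single-stream one-stage detector realised from a ModelConfig.

    ``forward`` maps an (in_channels, H, W) image batch to three raw
    detection maps at strides 8/16/32 with 3*(num_classes+5) channels.
    """

    def __init__(self, config, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.config = config
        cfg = config
        w = cfg.width
        c256, c512, c1024 = w(256), w(512), w(1024)
        self.backbone = build_backbone(cfg, rng)
        self.neck = _Neck(_build_neck(cfg, rng))
        self.detect = Detect(cfg.num_classes, cfg.anchors,
                             [c256, c512, c1024], rng=rng)

    # ------------------------------------------------------------------
    def backbone_forward(self, x):
        taps = {}
        for i, layer in enumerate(self.backbone):
            x = layer(x)
            if i == 4:
                taps["p3"] = x
            elif i == 6:
                taps["p4"] = x
        taps["p5"] = x
        return taps

    def forward(self, x):
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected (N, {self.config.in_channels}, H, W) input, got {x.shape}")
        taps = self.backbone_forward(x)
        feats = _neck_forward(self.neck, taps)
        return self.detect(feats)


def build_backbone(cfg, rng=None):
    """The ten-layer CSP backbone as an ordered module list.

    Pyramid taps: index 4 (stride 8, P3), index 6 (stride 16, P4) and
    index 9, the SPP output (stride 32, P5).
    """
    rng = rng or np.random.default_rng(0)
    w = cfg.width
    c64, c128, c256, c512, c1024 = (w(64), w(128), w(256), w(512), w(1024))
    n1, n2, n3, n4 = [cfg.depth(r) for r in cfg.stage_repeats]
    spp_cls = SPPF if cfg.spp == "sppf" else SPP
    if cfg.stem == "focus":
        stem = Focus(cfg.in_channels, c64, 3, rng=rng)
    else:
        stem = ConvBnAct(cfg.in_channels, c64, 6, 2, p=2, rng=rng)
    return [
        stem,
        ConvBnAct(c64, c128, 3, 2, rng=rng),
        C3(c128, c128, n1, rng=rng),
        ConvBnAct(c128, c256, 3, 2, rng=rng),
        C3(c256, c256, n2, rng=rng),            # -> P3 tap (idx 4)
        ConvBnAct(c256, c512, 3, 2, rng=rng),
        C3(c512, c512, n3, rng=rng),            # -> P4 tap (idx 6)
        ConvBnAct(c512, c1024, 3, 2, rng=rng),
        C3(c1024, c1024, n4, rng=rng),
        spp_cls(c1024, c1024, rng=rng),         # -> P5 tap (idx 9)
    ]


def _build_neck(cfg, rng):
    """Neck modules keyed by name.  'panet' is the top-down + bottom-up
    path-aggregation head; 'fpn' keeps only the top-down pathway plus a
    CSP block on the P5 branch, heads reading (P3', P4', P5') at
    unchanged channel widths."""
    w = cfg.width
    c256, c512, c1024 = w(256), w(512), w(1024)
    nh = cfg.depth(3)
    ds = cfg.neck_csp == "c3_dsconv"
    m = {
        "reduce5": ConvBnAct(c1024, c512, 1, 1, rng=rng),
        "c3_p4": C3(c1024, c512, nh, shortcut=False, dsconv=ds, rng=rng),
        "reduce4": ConvBnAct(c512, c256, 1, 1, rng=rng),
        "c3_p3": C3(c512, c256, nh, shortcut=False, dsconv=ds, rng=rng),
    }
    if cfg.neck == "panet":
        m.update({
            "down3": ConvBnAct(c256, c256, 3, 2, rng=rng),
            "c3_n4": C3(c512, c512, nh, shortcut=False, dsconv=ds, rng=rng),
            "down4": ConvBnAct(c512, c512, 3, 2, rng=rng),
            "c3_n5": C3(c1024, c1024, nh, shortcut=False, dsconv=ds, rng=rng),
        })
    else:
        m["c3_p5"] = C3(c1024, c1024, nh, shortcut=False, dsconv=ds, rng=rng)
    return m


class _Neck(Module):
    def __init__(self, modules):
        super().__init__()
        for k, v in modules.items():
            setattr(self, k, v)
        self.names = list(modules)


def _neck_forward(neck, taps):
    p3, p4, p5 = taps["p3"], taps["p4"], taps["p5"]
    x10 = neck.reduce5(p5)
    t4 = neck.c3_p4(concat([x10.upsample2x(), p4], axis=1))
    x14 = neck.reduce4(t4)
    t3 = neck.c3_p3(concat([x14.upsample2x(), p3], axis=1))
    if hasattr(neck, "c3_p5"):  # fpn
        return [t3, t4, neck.c3_p5(p5)]
    n4 = neck.c3_n4(concat([neck.down3(t3), x14], axis=1))
    n5 = neck.c3_n5(concat([neck.down4(n4), x10], axis=1))
    return [t3, n4, n5]


def build_detector(config, rng=None):
    """Realise a ModelConfig as a runnable Detector."""
    if isinstance(config, str):
        config = preset_config(config)
    return Detector(config, rng=rng)


# ----------------------------------------------------------------------
PRESETS = {
    "baseline": ModelConfig(),
    "nofocus": ModelConfig(stem="conv6"),
    "stage_surgery": ModelConfig(stage_repeats=(8, 8, 3, 3)),
    "fpn_only": ModelConfig(neck="fpn"),
    "c3_dsconv": ModelConfig(neck_csp="c3_dsconv"),
    "improved": ModelConfig(stem="conv6", stage_repeats=(8, 8, 3, 3),
                            neck="fpn", neck_csp="c3_dsconv"),
    "baseline_4ch": ModelConfig(in_channels=4),
    "improved_4ch": ModelConfig(stem="conv6", stage_repeats=(8, 8, 3, 3),
                                neck="fpn", neck_csp="c3_dsconv",
                                in_channels=4),
}


def preset_config(name, **overrides):
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    cfg = PRESETS[name]
    return replace(cfg, **overrides) if overrides else replace(cfg)


def summarize(model, img_size=640):
    """Parameter counts and GFLOPs of a built model at ``img_size``.

    FLOPs are traced once at a 64-px input and scaled by the exact
    quadratic factor (every layer's spatial area scales with the input
    area, so the scaling is lossless).  Parameter counts are independent
    of image size.
    """
    if img_size % 32:
        raise ValueError("img_size must be divisible by 32")
    trace_size = 64
    x = np.zeros((1, model.config.in_channels, trace_size, trace_size),
                 dtype=np.float32)
    was_training = model.training
    model.eval()
    try:
        from .autograd import no_grad
        with no_grad():
            model(x)
    finally:
        model.train(was_training)
    scale = (img_size / trace_size) ** 2
    g2 = count_flops_traced(model, "2mac") * scale / 1e9
    g1 = count_flops_traced(model, "eq") * scale / 1e9
    stages = []
    for i, layer in enumerate(model.backbone):
        stages.append((f"backbone.{i}", count_parameters(layer, "fused")))
    for name in model.neck.names:
        stages.append((f"neck.{name}",
                       count_parameters(getattr(model.neck, name), "fused")))
    stages.append(("detect", count_parameters(model.detect, "fused")))
    return ModelSummary(
        parameter_count=count_parameters(model, "fused"),
        parameter_count_train=count_parameters(model, "train"),
        gflops=g2,
        gflops_ma=g1,
        img_size=img_size,
        per_stage=stages,
    )
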