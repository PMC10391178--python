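"""Constructors and exact parameter/FLOP accounting for detector blocks.

Two parameter-counting conventions are exposed, because both are in
common use for this detector family:

``train``
    Every learnable array: convolution kernels and biases, normalisation
    affine pairs (gamma, beta), quantisation scales.  Running statistics
    are not learnable and are never counted.

``fused``
    The deployment form: batch normalisation folded into the preceding
    convolution, so each convolution contributes C_in*C_out*K*K kernel
    weights plus C_out bias terms and nothing else.  This is the
    convention under which the published variant tables are reported,
    and is the headline count in :func:`teadet.model_zoo.summarize`.

FLOP counting follows the per-layer product (2*C_in*K^2) * H_out * W_out
* C_out ("2mac", one multiply-accumulate = 2 ops, the headline
convention) or (2*C_in*K^2 - 1) * H_out * W_out * C_out ("eq" — the
fused multiply-add form that subtracts the missing first addition).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor
from .nn import (C3, SPP, SPPF, Conv2d, ConvBnAct, Detect, DSConv2d, Focus,
                 Module)

__all__ = [
    "LayerSpec", "Block", "make_block", "block_parameters", "block_flops",
    "count_parameters", "count_flops_traced", "layer_specs",
]

BLOCK_KINDS = ("ConvBNAct", "Focus", "CSP1_n", "CSP2", "C3_DSConv", "SPP",
               "SPPF", "Detect")


@dataclass(frozen=True)
class LayerSpec:
    """Shape record for one convolution layer."""

    c_in: int
    c_out: int
    k: int
    s: int
    h_out: int
    w_out: int

    def __post_init__(self):
        for f in ("c_in", "c_out", "k", "s", "h_out", "w_out"):
            if getattr(self, f) <= 0:
                raise ValueError(f"LayerSpec.{f} must be positive")

    @property
    def weight_count(self):
        return self.c_in * self.c_out * self.k * self.k

    def flops(self, convention="2mac"):
        area = self.h_out * self.w_out
        if convention == "2mac":
            return 2 * self.c_in * self.k * self.k * area * self.c_out
        if convention == "eq":
            return (2 * self.c_in * self.k * self.k - 1) * area * self.c_out
        raise ValueError(f"unknown FLOP convention {convention!r}")


@dataclass
class Block:
    kind: str
    module: Module
    c_in: int
    c_out: int
    n: int = 1
    layers: list = field(default_factory=list)  # filled by layer_specs


def make_block(kind, c_in, c_out, k=None, s=1, n=1, rng=None):
    """Build one named detector block.

    CSP kinds require ``n >= 1`` internal bottlenecks; ``Detect``
    interprets ``n`` as the class count and builds one prediction conv.
    """
    if kind not in BLOCK_KINDS:
        raise ValueError(f"unsupported block kind {kind!r}; choose from {BLOCK_KINDS}")
    if c_in <= 0 or c_out <= 0:
        raise ValueError("channel counts must be positive")
    if kind in ("CSP1_n", "CSP2", "C3_DSConv") and n < 1:
        raise ValueError("CSP blocks need n >= 1")
    if kind == "ConvBNAct":
        mod = ConvBnAct(c_in, c_out, k or 1, s, rng=rng)
    elif kind == "Focus":
        mod = Focus(c_in, c_out, k or 3, s, rng=rng)
    elif kind == "CSP1_n":
        mod = C3(c_in, c_out, n, shortcut=True, rng=rng)
    elif kind == "CSP2":
        mod = C3(c_in, c_out, n, shortcut=False, rng=rng)
    elif kind == "C3_DSConv":
        mod = C3(c_in, c_out, n, shortcut=False, dsconv=True, rng=rng)
    elif kind == "SPP":
        mod = SPP(c_in, c_out, rng=rng)
    elif kind == "SPPF":
        mod = SPPF(c_in, c_out, rng=rng)
    else:  # Detect
        mod = Detect(n, [[10, 13, 16, 30, 33, 23]], [c_in], rng=rng)
    return Block(kind=kind, module=mod, c_in=c_in, c_out=c_out, n=n)


# ----------------------------------------------------------------------
def _iter_convs(module):
    for m in module.modules():
        if isinstance(m, (Conv2d, DSConv2d)):
            yield m


def count_parameters(module, convention="train"):
    """Learnable-parameter count of a module tree under a convention."""
    if convention == "train":
        return int(sum(p.data.size for _, p in module.named_parameters()))
    if convention == "fused":
        total = 0
        for m in _iter_convs(module):
            total += m.weight.data.size + m.c2  # kernel + (folded) bias
            if isinstance(m, DSConv2d):
                total += m.row_scale.data.size + m.row_shift.data.size
        return int(total)
    raise ValueError(f"unknown parameter convention {convention!r}")


def count_flops_traced(module, convention="2mac"):
    """Sum per-convolution FLOPs using the spatial sizes recorded by the
    most recent forward pass (see ``Conv2d.last_hw``)."""
    total = 0
    for m in _iter_convs(module):
        if m.last_hw is None:
            raise RuntimeError("no traced shapes: run a forward pass first")
        h, w = m.last_hw
        total += LayerSpec(m.c1, m.c2, m.k, m.s, h, w).flops(convention)
    return int(total)


def _trace(block, input_hw):
    h, w = input_hw
    mod = block.module
    x = Tensor(np.zeros((1, block.c_in, h, w), dtype=np.float32))
    was_training = mod.training
    mod.eval()
    try:
        if isinstance(mod, Detect):
            mod([x])
        else:
            mod(x)
    finally:
        mod.train(was_training)


def layer_specs(block, input_hw):
    """Enumerate LayerSpec records for every convolution in the block."""
    _trace(block, input_hw)
    specs = [LayerSpec(m.c1, m.c2, m.k, m.s, *m.last_hw)
             for m in _iter_convs(block.module)]
    block.layers = specs
    return specs


def block_parameters(block, convention="train"):
    """Total learnable parameters of a block (see module docstring for
    the two conventions)."""
    if block is None:
        return 0
    return count_parameters(block.module, convention)


def block_flops(block, input_hw, convention="2mac"):
    """Floating-point operations of one block at the given input size."""
    if input_hw[0] <= 0 or input_hw[1] <= 0:
        raise ValueError("input size must be positive")
    _trace(block, input_hw)
    return count_flops_traced(block.module, convention)
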