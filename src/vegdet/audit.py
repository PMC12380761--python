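"""Structural audit: trainable-parameter and FLOPs accounting.

Parameters are the sum of every trainable weight array's element count.
FLOPs are counted analytically by running the model's own forward code
on a shape probe: convolutions contribute 2 FLOPs per multiply-
accumulate (k*k * Cin/g * Cout * H_out * W_out MACs), batch 1;
normalization, activation, pooling and resampling are excluded, the
convention under which compact single-stage detectors are usually
quoted.
"""

from __future__ import annotations

import numpy as np

from .nn import tensor as T
from .model import Detector, ModelConfig, build_model


def count_parameters(model) -> float:
    """Trainable parameters in millions (not rounded)."""
    return model.num_parameters() / 1e6


def count_parameters_exact(model) -> int:
    return model.num_parameters()


def count_flops(model: Detector, input_size: int | None = None) -> float:
    """Analytic GFLOPs at batch 1 for the given input size."""
    if input_size is None:
        input_size = model.cfg.input_size
    with T.profile() as p:
        model(T.ShapeProbe((1, 3, input_size, input_size)))
    return p.flops / 1e9


VARIANTS = [
    ("baseline", False, False, False),
    ("+ADEConv", True, False, False),
    ("+MFLayer", False, True, False),
    ("+IDFNet", False, False, True),
    ("+ADEConv+MFLayer", True, True, False),
    ("+ADEConv+IDFNet", True, False, True),
    ("+MFLayer+IDFNet", False, True, True),
    ("full", True, True, True),
]


def audit_variant(use_adeconv: bool, use_mflayer: bool, use_idfnet: bool,
                  num_classes: int = 15, input_size: int = 640
                  ) -> tuple[float, float]:
    """(params in M, GFLOPs), both rounded to 0.1, for one flag combination."""
    cfg = ModelConfig(num_classes=num_classes, input_size=input_size,
                      use_adeconv=use_adeconv, use_mflayer=use_mflayer,
                      use_idfnet=use_idfnet)
    model = build_model(cfg)
    params = round(count_parameters(model), 1)
    flops = round(count_flops(model), 1)
    return params, flops


def audit_table(num_classes: int = 15, input_size: int = 640) -> list[dict]:
    rows = []
    for name, a, m, i in VARIANTS:
        params, flops = audit_variant(a, m, i, num_classes, input_size)
        rows.append({"variant": name, "adeconv": a, "mflayer": m,
                     "idfnet": i, "params_m": params, "gflops": flops})
    return rows


def format_audit_table(rows: list[dict]) -> str:
    lines = [f"{'variant':<22}{'params (M)':>12}{'FLOPs (G)':>12}"]
    for r in rows:
        lines.append(f"{r['variant']:<22}{r['params_m']:>12.1f}"
                     f"{r['gflops']:>12.1f}")
    return "\n".join(lines)


def brute_force_param_count(model) -> int:
    """Independent oracle: walk every module's registered parameter
    arrays and sum raw element counts with numpy, bypassing
    Module.num_parameters."""
    total = 0
    seen = set()
    for m in model.modules():
        for p in m._params.values():
            if id(p) in seen:
                continue
            seen.add(id(p))
            total += int(np.prod(p.data.shape))
    return total
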