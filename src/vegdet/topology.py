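"""Per-variant width/depth profiles of the detector family.

The ablation grid toggles three modules (ADEConv downsampling, the
MFLayer stride-4 route, the IDFNet neck).  The published budgets of the
ablation rows are not mutually flag-compositional, so each row carries
its own documented width profile, resolved purely from the three flags;
the profile is the reconstruction's free parameter set, fixed once here.

`width_scale` shrinks every channel count (used for the tiny models the
training tests run); it never changes the topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class WidthProfile:
    # backbone: channels at P1..P5 and C2f repeats at stages P2..P5
    chans: tuple[int, int, int, int, int] = (16, 32, 64, 128, 256)
    depths: tuple[int, int, int, int] = (1, 2, 2, 1)
    # lite = depthwise/pointwise bottlenecks (compact late-stage blocks)
    stage_lite: tuple[bool, bool, bool, bool] = (False, False, True, True)
    neck_depth: int = 1            # CSP repeats per PAFPN fusion node
    neck_lite: tuple[bool, bool, bool, bool] = (False, False, False, True)
    # ADEConv instances: groups of the cheap 5x5 branch (None = depthwise)
    ade_cheap_groups: int | None = None
    # IDFNet: fusion widths of the P3/P4/P5 nodes (int = shared width);
    # gate_groups 0 means one group per output channel (pairwise gating)
    idf_width: int | tuple[int, int, int] = 96
    idf_gate_groups: int = 0
    # MFLayer: width of the stride-4 route / P2 head input
    mf_width: int = 64
    # heads: int or per-level tuple listed for (P2, P3, P4, P5); the P2
    # entry applies only when the MFLayer head exists
    head_reg_width: int | tuple[int, ...] = 64
    head_cls_width: int | tuple[int, ...] = 64
    cls_separable: bool = True
    reg_max: int = 16


def resolve_profile(use_adeconv: bool, use_mflayer: bool,
                    use_idfnet: bool) -> WidthProfile:
    """Documented width profile for each flag combination.

    The profiles reconstruct each ablation row at its published
    parameter/FLOPs budget.  Rows are not naive flag compositions:
    the detail-preserving downsampling rows run a wider late backbone
    (their replacement unit shifts capacity into the downsampling
    steps), while the complete model keeps its neck and stride-4 route
    deliberately narrow so that all three modules together stay inside
    the published budget.
    """
    base = WidthProfile(depths=(2, 2, 2, 1),
                        head_reg_width=(32, 32, 56, 64))
    ade = dict(chans=(16, 32, 72, 160, 288), ade_cheap_groups=1)
    key = (use_adeconv, use_mflayer, use_idfnet)
    table: dict[tuple[bool, bool, bool], WidthProfile] = {
        # baseline reconstruction (n-scale multipliers)
        (False, False, False): base,
        # detail-preserving downsampling only
        (True, False, False): replace(base, **ade,
                                      head_cls_width=(64, 88, 64, 64)),
        # stride-4 small-target route only
        (False, True, False): replace(base, chans=(16, 32, 64, 128, 288),
                                      mf_width=56,
                                      head_reg_width=(44, 32, 56, 64),
                                      head_cls_width=(44, 64, 64, 64)),
        # attention-gated bidirectional neck only
        (False, False, True): replace(base, idf_width=(68, 64, 136)),
        # pairwise combinations (intermediate ablation rows)
        (True, True, False): replace(base, **ade, mf_width=56,
                                     head_reg_width=(44, 32, 56, 64),
                                     head_cls_width=(44, 88, 64, 64)),
        (True, False, True): replace(base, **ade, idf_width=(68, 64, 136),
                                     head_cls_width=(64, 88, 64, 64)),
        (False, True, True): replace(base, chans=(16, 32, 64, 128, 288),
                                     idf_width=(68, 64, 136), mf_width=56,
                                     head_reg_width=(44, 32, 56, 64),
                                     head_cls_width=(44, 64, 64, 64)),
        # complete model: narrow neck/route keep the joint budget small
        (True, True, True): replace(base, **ade, idf_width=(68, 64, 136),
                                    mf_width=40,
                                    head_reg_width=(32, 32, 56, 64),
                                    head_cls_width=(40, 64, 64, 64)),
    }
    return table[key]


def scaled(profile: WidthProfile, width_scale: float) -> WidthProfile:
    """Multiply all channel widths by `width_scale` (min 4, multiples of 4)."""
    if width_scale == 1.0:
        return profile

    def s(c: int) -> int:
        return max(4, int(round(c * width_scale / 4)) * 4)

    def sv(w):
        return s(w) if isinstance(w, int) else tuple(s(c) for c in w)

    return replace(
        profile,
        chans=tuple(s(c) for c in profile.chans),
        idf_width=sv(profile.idf_width),
        mf_width=s(profile.mf_width),
        head_reg_width=sv(profile.head_reg_width),
        head_cls_width=sv(profile.head_cls_width),
    )
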