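"""Non-salient target segmentation model (NTSM).

Assembles the difference-association (DA) module, a pinned 2-D
encoder–decoder backbone with skip connections, FHPA blocks substituted for
the second convolution of selected stages, and deep-supervision heads.

Backbone layout (pinned for reproducibility):

* encoder stage i holds two 3×3 conv blocks (instance norm + LeakyReLU);
  stages 2..n downsample ×2 with a stride-2 convolution as their first block;
* the DA module processes the raw RGB image at full resolution, and its
  output is concatenated with the stem features and reduced by a 1×1 conv;
* the decoder mirrors the encoder with kernel-2 stride-2 transposed
  convolutions and skip concatenation;
* FHPA replaces the *second* conv block of each configured stage (the first
  conv still performs the channel change, FHPA is channel-preserving);
  encoder stages are indexed 1-based from the shallowest, decoder stages
  1-based from the deepest;
* deep-supervision heads are 1×1 convolutions to ``num_classes`` on the
  finest ``deep_supervision_levels`` decoder outputs, finest first.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import autodiff as ad
from .autodiff import Tensor
from . import nn
from .attention_primitives import HPAParams
from .da_module import DAConfig, DAModule
from .fhpa_module import FHPABlock, FHPABlockConfig


@dataclass(frozen=True)
class NTSMConfig:
    stage_channels: tuple[int, ...] = (32, 64, 128, 256, 512)
    fhpa_encoder_stages: frozenset = frozenset({3, 4, 5})
    fhpa_decoder_stages: frozenset = frozenset({1})
    use_da: bool = True
    da: DAConfig | None = None
    hpa: HPAParams = field(default_factory=HPAParams)
    gn_groups: int = 4
    deep_supervision_levels: int = 3
    num_classes: int = 2
    in_channels: int = 3
    seed: int = 0

    def __post_init__(self):
        n = len(self.stage_channels)
        object.__setattr__(self, "fhpa_encoder_stages", frozenset(self.fhpa_encoder_stages))
        object.__setattr__(self, "fhpa_decoder_stages", frozenset(self.fhpa_decoder_stages))
        bad = [s for s in self.fhpa_encoder_stages if not 1 <= s <= n]
        bad += [s for s in self.fhpa_decoder_stages if not 1 <= s <= n - 1]
        if bad:
            raise ValueError(f"FHPA stage indices out of range: {sorted(bad)}")
        for s in sorted(self.fhpa_encoder_stages):
            if self.stage_channels[s - 1] % 4:
                raise ValueError(
                    f"encoder stage {s} width {self.stage_channels[s - 1]} not divisible by 4"
                )
        for s in sorted(self.fhpa_decoder_stages):
            # decoder stage s (1-based from deepest) works at encoder level n-s
            if self.stage_channels[n - 1 - s] % 4:
                raise ValueError(
                    f"decoder stage {s} width {self.stage_channels[n - 1 - s]} not divisible by 4"
                )
        if not 1 <= self.deep_supervision_levels <= n - 1:
            raise ValueError(
                f"deep_supervision_levels must be in [1, {n - 1}], got {self.deep_supervision_levels}"
            )

    @property
    def divisor(self) -> int:
        return 2 ** (len(self.stage_channels) - 1)

    def resolved_da(self) -> DAConfig:
        if self.da is not None:
            return self.da
        return DAConfig(out_channels=self.stage_channels[0])


@dataclass
class SegmentationOutput:
    """Per-supervision-level logits, finest first."""

    logits: list[Tensor]


class _ConvBlock(nn.Module):
    def __init__(self, in_c: int, out_c: int, rng, stride: int = 1):
        super().__init__()
        self.conv = nn.Conv2d(in_c, out_c, 3, rng, stride=stride, padding=1)
        self.norm = nn.InstanceNorm2d(out_c, affine=True)
        self.act = nn.LeakyReLU(0.01)

    def forward(self, x):
        return self.act(self.norm(self.conv(x)))


class NTSM(nn.Module):
    def __init__(self, config: NTSMConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        chans = config.stage_channels
        n = len(chans)
        c0 = chans[0]

        self.stem = _ConvBlock(config.in_channels, c0, rng)
        if config.use_da:
            da_cfg = config.resolved_da()
            if da_cfg.out_channels != c0:
                raise ValueError(
                    f"DA out_channels {da_cfg.out_channels} must equal stage 1 width {c0}"
                )
            self.da = DAModule(config.in_channels, da_cfg, rng)
            self.da_fuse = nn.Conv2d(2 * c0, c0, 1, rng)
        else:
            self.da = None

        def second_block(stage_1based: int, width: int, encoder: bool) -> nn.Module:
            stages = config.fhpa_encoder_stages if encoder else config.fhpa_decoder_stages
            if stage_1based in stages:
                return FHPABlock(
                    FHPABlockConfig(channels=width, hpa=config.hpa, gn_groups=config.gn_groups),
                    rng,
                )
            return _ConvBlock(width, width, rng)

        # encoder: stage 1 second block; stages 2..n as (downsample block, second block)
        self.enc_blocks2 = []
        self.enc_down = []
        self._modules["enc2_1"] = second_block(1, c0, True)
        self.enc_blocks2.append(self._modules["enc2_1"])
        for i in range(2, n + 1):
            down = _ConvBlock(chans[i - 2], chans[i - 1], rng, stride=2)
            blk2 = second_block(i, chans[i - 1], True)
            self._modules[f"down_{i}"] = down
            self._modules[f"enc2_{i}"] = blk2
            self.enc_down.append(down)
            self.enc_blocks2.append(blk2)

        # decoder: stage j (1-based from deepest), j = 1..n-1, target width chans[n-1-j]
        self.dec_up = []
        self.dec_blocks1 = []
        self.dec_blocks2 = []
        for j in range(1, n):
            w_in = chans[n - j]
            w_out = chans[n - 1 - j]
            up = nn.ConvTranspose2x(w_in, w_out, rng)
            blk1 = _ConvBlock(2 * w_out, w_out, rng)
            blk2 = second_block(j, w_out, False)
            self._modules[f"up_{j}"] = up
            self._modules[f"dec1_{j}"] = blk1
            self._modules[f"dec2_{j}"] = blk2
            self.dec_up.append(up)
            self.dec_blocks1.append(blk1)
            self.dec_blocks2.append(blk2)

        # deep-supervision heads on the finest `levels` decoder outputs
        self.heads = []
        for lvl in range(config.deep_supervision_levels):
            head = nn.Conv2d(chans[lvl], config.num_classes, 1, rng)
            self._modules[f"head_{lvl}"] = head
            self.heads.append(head)

    def forward(self, image: Tensor) -> SegmentationOutput:
        cfg = self.config
        if image.ndim != 4 or image.shape[1] != cfg.in_channels:
            raise ValueError(
                f"expected (b, {cfg.in_channels}, h, w) input, got shape {image.shape}"
            )
        h, w = image.shape[2], image.shape[3]
        d = cfg.divisor
        if h % d or w % d:
            raise ValueError(f"spatial extents {(h, w)} must be divisible by {d}")

        x = self.stem(image)
        if self.da is not None:
            x = self.da_fuse(ad.concat([x, self.da(image)], axis=1))
        x = self.enc_blocks2[0](x)
        skips = [x]
        for down, blk2 in zip(self.enc_down, self.enc_blocks2[1:]):
            x = blk2(down(x))
            skips.append(x)

        dec_outputs = []  # deepest first
        for j, (up, blk1, blk2) in enumerate(
            zip(self.dec_up, self.dec_blocks1, self.dec_blocks2), start=1
        ):
            skip = skips[len(skips) - 1 - j]
            x = blk2(blk1(ad.concat([up(x), skip], axis=1)))
            dec_outputs.append(x)

        logits = []
        for lvl, head in enumerate(self.heads):
            logits.append(head(dec_outputs[len(dec_outputs) - 1 - lvl]))
        return SegmentationOutput(logits=logits)

    def predict_proba(self, image: Tensor) -> np.ndarray:
        """Softmax class probabilities at full resolution (eval mode)."""
        was_training = self.training
        self.eval()
        try:
            with ad.no_grad():
                out = self.forward(image)
                probs = ad.softmax(out.logits[0], axis=1).data
        finally:
            self.train(was_training)
        return probs

    def predict_mask(self, image: Tensor) -> np.ndarray:
        """Argmax foreground mask {0,1}, shape (b, h, w)."""
        return self.predict_proba(image).argmax(axis=1).astype(np.uint8)


def build_ntsm(config: NTSMConfig) -> NTSM:
    """Build an NTSM; deterministic given ``config.seed``."""
    return NTSM(config)


# ---- configuration / checkpoint serialization ------------------------------


def config_to_dict(config: NTSMConfig) -> dict:
    d = asdict(config)
    d["stage_channels"] = list(config.stage_channels)
    d["fhpa_encoder_stages"] = sorted(config.fhpa_encoder_stages)
    d["fhpa_decoder_stages"] = sorted(config.fhpa_decoder_stages)
    d["hpa"] = {"nominal_grid": list(config.hpa.nominal_grid), "init_std": config.hpa.init_std}
    if config.da is not None:
        d["da"]["lcd_context_dilations"] = list(config.da.lcd_context_dilations)
    return d


def config_from_dict(d: dict) -> NTSMConfig:
    d = dict(d)
    d["stage_channels"] = tuple(d["stage_channels"])
    d["fhpa_encoder_stages"] = frozenset(d["fhpa_encoder_stages"])
    d["fhpa_decoder_stages"] = frozenset(d["fhpa_decoder_stages"])
    hpa = d.get("hpa") or {}
    d["hpa"] = HPAParams(
        nominal_grid=tuple(hpa.get("nominal_grid", (16, 16))),
        init_std=hpa.get("init_std", 0.02),
    )
    if d.get("da") is not None:
        da = dict(d["da"])
        da["lcd_context_dilations"] = tuple(da["lcd_context_dilations"])
        d["da"] = DAConfig(**da)
    return NTSMConfig(**d)


def save_checkpoint(model: NTSM, path) -> None:
    """Serialize weights (npz) plus the config as YAML alongside."""
    path = Path(path)
    sd = model.state_dict()
    np.savez(path, **sd)
    saved = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    if saved != path:
        saved.replace(path)
    path.with_suffix(".yaml").write_text(yaml.safe_dump(config_to_dict(model.config)))


def load_checkpoint(path) -> NTSM:
    path = Path(path)
    cfg = config_from_dict(yaml.safe_load(path.with_suffix(".yaml").read_text()))
    model = build_ntsm(cfg)
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model


def checkpoint_bytes(model: NTSM) -> int:
    """Size in bytes of the serialized weight file."""
    buf = io.BytesIO()
    np.savez(buf, **model.state_dict())
    return buf.getbuffer().nbytes
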