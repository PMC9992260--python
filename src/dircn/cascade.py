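"""Unrolled cascade reconstruction models with soft data consistency.

Each cascade performs the five-step procedure: estimate (shared) coil
sensitivities, fold the current k-space to a single complex image, refine
it with a CNN sub-network, expand back to coils, transform to k-space and
enforce data consistency against the measured lines:

    f_dc(k_p) = (k_u + λ k_p) / (1 + λ)   on sampled lines,
    f_dc(k_p) = k_p                        elsewhere,

with λ a learnable scalar per cascade, initialised to 0.01.

Three optional architectural extensions, strictly additive on top of the
reference composition:

* **dense connections** — every cascade's CNN sees the concatenation of its
  own coil-reduced input with those of all prior cascades (newest first);
* **resxunet** — the aggregated-residual SE sub-network replaces the plain
  U-Net;
* **interconnections** — each sub-network's per-resolution final feature
  maps are concatenated onto the next sub-network's encoder.

The DIRCN variant enables all three.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .kspace import complex_to_channels
from .masks import UndersamplingMask
from .nn import Tensor
from .subnetworks import SensitivityModel, SubnetConfig, build_subnet

__all__ = [
    "ModelConfig",
    "ReconstructionModel",
    "data_consistency",
    "build_model",
    "reconstruct",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
    "PRESETS",
]

# the five ablation variants: (subnet kind, dense connections, interconnections)
PRESETS = {
    "reference": ("unet", False, False),
    "dense": ("unet", True, False),
    "resxunet": ("resxunet", False, False),
    "interconnections": ("unet", False, True),
    "dircn": ("resxunet", True, True),
}


@dataclass(frozen=True)
class ModelConfig:
    """Cascade count, variant flags, and sub-network widths.

    The default cascade count is 12; ``lambda_init`` seeds every cascade's
    data-consistency weight.  The sensitivity network shares the cascade
    sub-network architecture at half the base width.
    """

    m: int = 12
    subnet: str = "unet"
    dense_connections: bool = False
    interconnections: bool = False
    lambda_init: float = 0.01
    subnet_config: SubnetConfig = field(default_factory=SubnetConfig)
    sensitivity_config: SubnetConfig | None = None

    def __post_init__(self):
        if self.m < 1:
            raise ValueError(f"need at least one cascade, got m={self.m}")
        if self.lambda_init <= 0:
            raise ValueError(f"lambda_init must be > 0, got {self.lambda_init}")
        if self.subnet not in ("unet", "resxunet"):
            raise ValueError(f"unknown sub-network {self.subnet!r}")

    def resolved_sensitivity_config(self) -> SubnetConfig:
        return (self.sensitivity_config if self.sensitivity_config is not None
                else self.subnet_config.scaled(0.5))

    @staticmethod
    def from_preset(name: str, tiny: bool = False, m: int | None = None) -> "ModelConfig":
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        kind, dense, inter = PRESETS[name]
        if tiny:
            sub = SubnetConfig(base_channels=8, depth=3, cardinality=4, se_reduction=4)
            mm = 2 if m is None else m
        else:
            # full-scale widths chosen per architecture so every variant lands
            # near the same total budget of roughly 45M learnable parameters
            # (grouped convolutions make the ResXUNet lighter per channel)
            base = 52 if kind == "resxunet" else 34
            sub = SubnetConfig(base_channels=base, depth=4, cardinality=32,
                               se_reduction=16)
            mm = 12 if m is None else m
        return ModelConfig(m=mm, subnet=kind, dense_connections=dense,
                           interconnections=inter, subnet_config=sub)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sensitivity_config"] = (asdict(self.sensitivity_config)
                                   if self.sensitivity_config else None)
        return d

    @staticmethod
    def from_dict(d: dict) -> "ModelConfig":
        d = dict(d)
        d["subnet_config"] = SubnetConfig(**d["subnet_config"])
        if d.get("sensitivity_config"):
            d["sensitivity_config"] = SubnetConfig(**d["sensitivity_config"])
        return ModelConfig(**d)


def data_consistency(kp: np.ndarray, ku: np.ndarray, mask: UndersamplingMask,
                     lam: float) -> np.ndarray:
    """Soft data-consistency blend on sampled lines (numpy front-end)."""
    if kp.shape != ku.shape:
        raise ValueError(f"shape mismatch: kp {kp.shape} vs ku {ku.shape}")
    sampled = mask.lines.astype(bool)
    blend = (ku + lam * kp) / (1.0 + lam)
    return np.where(sampled, blend, kp)


def _dc_tensor(kp: Tensor, ku: Tensor, lines: np.ndarray, lam: Tensor) -> Tensor:
    """Differentiable data consistency on (re, im) pair tensors."""
    inv = (1.0 + lam) ** -1.0
    blend = (ku + kp * lam) * inv
    m = lines.astype(kp.dtype)
    return blend * m + kp * (1.0 - m)


def _coil_reduce_t(k: Tensor, sens: Tensor) -> Tensor:
    """Tensor coil reduction: sum_i ifft2c(k_i) * conj(S_i) → [1, 2, h, w]."""
    imgs = nn.ifft2c_pair(k)                      # [c, 2, h, w]
    ar, ai = imgs[:, 0], imgs[:, 1]
    br, bi = sens[:, 0], sens[:, 1]
    # (ar + i ai)(br - i bi) = (ar br + ai bi) + i(ai br - ar bi)
    re = (ar * br + ai * bi).sum(axis=0, keepdims=True)
    im = (ai * br - ar * bi).sum(axis=0, keepdims=True)
    return nn.stack_pair(re, im, axis=1)          # [1, 2, h, w]


def _coil_expand_t(img: Tensor, sens: Tensor) -> Tensor:
    """Tensor coil expansion: coil i gets img * S_i → [c, 2, h, w]."""
    ar, ai = img[:, 0], img[:, 1]                 # [1, h, w]
    br, bi = sens[:, 0], sens[:, 1]               # [c, h, w]
    re = ar * br - ai * bi
    im = ar * bi + ai * br
    return nn.stack_pair(re, im, axis=1)


def _rss_t(coil_imgs: Tensor) -> Tensor:
    """Tensor RSS magnitude over coils of a [c, 2, h, w] pair array."""
    return ((coil_imgs * coil_imgs).sum(axis=(0, 1)) + 1e-12) ** 0.5


class _Cascade(nn.Module):
    def __init__(self, subnet, lambda_init: float):
        self.subnet = subnet
        self.lam = Tensor(np.asarray(lambda_init, np.float32), requires_grad=True)


class ReconstructionModel(nn.Module):
    """m cascades plus one sensitivity estimator; coil-count agnostic."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.sens_net = SensitivityModel(config.subnet,
                                         config.resolved_sensitivity_config())
        self.cascades = nn.ModuleList()
        for k in range(config.m):
            in_ch = 2 * (k + 1) if config.dense_connections else 2
            subnet = build_subnet(
                config.subnet, in_ch, config.subnet_config,
                accept_interconnect=(config.interconnections and k > 0),
            )
            self.cascades.append(_Cascade(subnet, config.lambda_init))

    # -- forward ----------------------------------------------------------
    def forward(self, ku: np.ndarray, mask: UndersamplingMask,
                return_internals: bool = False):
        """Run the full unrolled reconstruction.

        Parameters
        ----------
        ku:
            Measured (masked) complex k-space ``[c, h, w]``.
        mask:
            The undersampling mask that produced ``ku``.

        Returns the RSS magnitude image as a Tensor ``[h, w]``; with
        ``return_internals=True`` also a dict holding the final k-space
        pair tensor, the sensitivity tensor and per-cascade pre-DC
        predictions.
        """
        if ku.ndim != 3:
            raise ValueError(f"expected [coils, h, w] k-space, got {ku.shape}")
        sens = self.sens_net(ku, mask)                       # [c, 2, h, w]
        ku_t = Tensor(complex_to_channels(ku))               # constant
        k = ku_t
        history: list[Tensor] = []
        carry = None
        pre_dc: list[Tensor] = []
        for idx, cascade in enumerate(self.cascades):
            i_red = _coil_reduce_t(k, sens)
            if self.config.dense_connections and history:
                cnn_in = nn.concat([i_red] + history[::-1], axis=1)
            else:
                cnn_in = i_red
            packets_in = carry if (self.config.interconnections and idx > 0) else None
            i_rec, packets_out = cascade.subnet(cnn_in, packets_in)
            if self.config.interconnections:
                carry = packets_out
            kp = nn.fft2c_pair(_coil_expand_t(i_rec, sens))
            if return_internals:
                pre_dc.append(kp)
            k = _dc_tensor(kp, ku_t, mask.lines, cascade.lam)
            history.append(i_red)
        out = _rss_t(nn.ifft2c_pair(k))
        if return_internals:
            return out, {"k_final": k, "sens": sens, "pre_dc": pre_dc}
        return out


def build_model(config: ModelConfig, seed: int = 0) -> ReconstructionModel:
    """Construct a model with reproducible parameter initialisation."""
    nn.seed_init(seed)
    return ReconstructionModel(config)


def reconstruct(model: ReconstructionModel, ku: np.ndarray,
                mask: UndersamplingMask) -> np.ndarray:
    """Inference: undersampled k-space → nonnegative magnitude image."""
    with nn.no_grad():
        out = model(ku, mask)
    return out.data


def count_parameters(model: nn.Module) -> int:
    """Total learnable scalar count, including the per-cascade λ's."""
    return model.num_parameters()


def save_checkpoint(path, model: ReconstructionModel,
                    extra: dict | None = None) -> None:
    """Single-archive checkpoint: parameters keyed by module path + config."""
    payload = {f"param/{k}": v for k, v in model.state_dict().items()}
    meta = {"config": model.config.to_dict(), "extra": extra or {}}
    payload["meta_json"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8
    ).copy()
    np.savez(path, **payload)


def load_checkpoint(path) -> tuple[ReconstructionModel, dict]:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["meta_json"]).decode())
        state = {k[len("param/"):]: archive[k] for k in archive.files
                 if k.startswith("param/")}
    config = ModelConfig.from_dict(meta["config"])
    model = ReconstructionModel(config)
    model.load_state_dict(state)
    return model, meta.get("extra", {})
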