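"""End-to-end segmentation models: backbone + CRF head variants.

``SegmentationModel`` composes the three phases -- feature extraction,
potential computation, unrolled mean-field -- into one differentiable
object.  The ``variant`` field selects the pairwise-potential family:

``ncrf``
    learned potentials: features (+ positional encoding) -> shared MLP f
    -> per-edge squared differences -> network g -> M = exp(g(d)).
    The ``positional_encoding`` / ``learnable_function`` switches give the
    four ablation configurations; with both off the model degenerates to
    the plain backbone.
``spatial`` / ``intensity`` / ``posterior``
    fixed Gaussian-kernel Potts potentials (end-to-end trained unary).
``postproc``
    plain backbone during training; an intensity-kernel CRF is applied
    only at prediction time.
``none``
    plain backbone + unary head, no CRF.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .backbone import BackboneConfig, UNetBackbone
from .graph import build_neighbor_graph
from .inference import InferenceConfig, mean_field_inference, meanfield_tensor
from .nn import MLP, Linear, Module
from .potentials import (baseline_potentials, binary_tables_tensor,
                         positional_encoding, potts_tables_tensor)

VARIANTS = ("ncrf", "spatial", "intensity", "posterior", "postproc", "none")


@dataclass
class ModelConfig:
    n_classes: int = 3
    variant: str = "ncrf"
    positional_encoding: bool = True
    learnable_function: bool = True
    iterations: int = 5
    difference: str = "squared"
    growing_frequency: bool = False
    theta_spatial: float = 1.0
    theta_feature: float = 0.1
    potts_weight: float = 1.0
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; "
                             f"choose one of {VARIANTS}")
        if isinstance(self.backbone, dict):
            self.backbone = BackboneConfig(**self.backbone)

    def to_dict(self) -> dict:
        return asdict(self)


class SegmentationModel(Module):
    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        self.dtype = np.dtype(config.dtype).type
        rng = np.random.default_rng(config.seed)
        self.backbone = self.add_module(
            "backbone", UNetBackbone(config.backbone, rng, dtype=self.dtype))
        c = self.backbone.out_features
        k = config.n_classes
        self.unary_head = self.add_module("unary_head", Linear(c, k, rng,
                                                               dtype=self.dtype))
        self.feat_mlp = None
        self.pairwise_net = None
        if config.variant == "ncrf":
            if config.positional_encoding or config.learnable_function:
                self.feat_mlp = self.add_module(
                    "feat_mlp", MLP([c, c, c], rng, dtype=self.dtype))
            if config.learnable_function:
                self.pairwise_net = self.add_module(
                    "pairwise_net", MLP([c, c, k * k], rng, dtype=self.dtype))
                # start near M = exp(0) = 1 (a constant matrix is a no-op
                # under the per-pixel softmax), so early training is driven
                # by the unary term and the pairwise term grows in smoothly
                self.pairwise_net.layers[-1].weight.data *= 0.01
        self._pe_cache: dict[tuple, np.ndarray] = {}

    # -- helpers -------------------------------------------------------
    def _pe_table(self, height: int, width: int) -> np.ndarray:
        key = (height, width)
        if key not in self._pe_cache:
            table = positional_encoding(
                height, width, self.backbone.out_features,
                growing_frequency=self.config.growing_frequency,
            ).astype(self.dtype)
            self._pe_cache[key] = table
            self.add_buffer(f"positional_encoding_{height}x{width}", table)
        return self._pe_cache[key]

    def _head_mode(self) -> str:
        cfg = self.config
        if cfg.variant == "ncrf":
            if cfg.learnable_function:
                return "learned"
            if cfg.positional_encoding:
                return "encoded_kernel"
            return "off"
        if cfg.variant in ("none", "postproc"):
            return "off"
        return cfg.variant

    # -- forward -------------------------------------------------------
    def forward(self, x: Tensor, n_iterations: int | None = None):
        """(B, H, W, Cin) -> (log Q, Q), both (B, H, W, K)."""
        cfg = self.config
        k = cfg.n_classes
        _, height, width, _ = x.shape
        feats = self.backbone(x)                    # (B, H, W, C)
        unary = self.unary_head(feats)              # costs psi_u
        mode = self._head_mode()
        iters = cfg.iterations if n_iterations is None else n_iterations
        if mode == "off" or iters == 0:
            return meanfield_tensor(unary, {}, 0)

        if mode in ("learned", "encoded_kernel"):
            phi_in = feats
            if cfg.positional_encoding:
                phi_in = feats + self._pe_table(height, width)
            phi = self.feat_mlp(phi_in)
            if mode == "learned":
                tables = binary_tables_tensor(phi, self.pairwise_net, k,
                                              difference=cfg.difference)
            else:
                tables = potts_tables_tensor(phi, height, width, k,
                                             theta_spatial=cfg.theta_spatial,
                                             theta_feature=cfg.theta_feature,
                                             weight=cfg.potts_weight)
        elif mode == "spatial":
            tables = potts_tables_tensor(None, height, width, k,
                                         theta_spatial=cfg.theta_spatial,
                                         weight=cfg.potts_weight)
        elif mode == "intensity":
            intensity = Tensor(x.data[..., :1])
            tables = potts_tables_tensor(intensity, height, width, k,
                                         theta_spatial=cfg.theta_spatial,
                                         theta_feature=cfg.theta_feature,
                                         weight=cfg.potts_weight)
        elif mode == "posterior":
            posterior = ad.softmax(unary * (-1.0), axis=-1)
            tables = potts_tables_tensor(posterior, height, width, k,
                                         theta_spatial=cfg.theta_spatial,
                                         theta_feature=cfg.theta_feature,
                                         weight=cfg.potts_weight)
        else:  # pragma: no cover
            raise RuntimeError(f"unhandled head mode {mode}")
        return meanfield_tensor(unary, tables, iters)

    # -- prediction ----------------------------------------------------
    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        """Single image (H, W) or (H, W, Cin) -> label distribution (H, W, K)."""
        image = np.asarray(image, dtype=self.dtype)
        if image.ndim == 2:
            image = image[:, :, None]
        batch = Tensor(image[None])
        _, q = self.forward(batch)
        probs = q.data[0]
        if self.config.variant == "postproc":
            graph = build_neighbor_graph(*probs.shape[:2])
            binary = baseline_potentials(
                "intensity", image[..., 0], graph, self.config.n_classes,
                theta_spatial=self.config.theta_spatial,
                theta_feature=self.config.theta_feature,
                weight=self.config.potts_weight)
            unary = -np.log(np.clip(probs, 1e-12, None))
            probs = mean_field_inference(
                unary, binary, graph,
                InferenceConfig(iterations=self.config.iterations))
        return probs

    def predict(self, image: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(image), axis=-1)

    def predict_volume(self, volume: np.ndarray) -> np.ndarray:
        """(S, H, W) or (S, H, W, Cin) -> label volume (S, H, W)."""
        volume = np.asarray(volume, dtype=self.dtype)
        x = volume[..., None] if volume.ndim == 3 else volume
        if self.config.variant == "postproc":
            return np.stack([self.predict(s) for s in x])
        _, q = self.forward(Tensor(x))
        return np.argmax(q.data, axis=-1)


# ---------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------

def save_checkpoint(model: SegmentationModel, path) -> None:
    """Single-file archive of parameters, buffers and the model config."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path) -> SegmentationModel:
    with np.load(path) as archive:
        state = {name: archive[name] for name in archive.files}
    cfg_bytes = state.pop("__config__").tobytes()
    config = ModelConfig(**json.loads(cfg_bytes.decode()))
    model = SegmentationModel(config)
    model.load_state_dict(state)
    for name, value in state.items():
        if name.startswith("buffer:positional_encoding_"):
            size = name.rsplit("_", 1)[1]
            h, w = (int(v) for v in size.split("x"))
            model._pe_cache[(h, w)] = value
            model.add_buffer(name[len("buffer:"):], value)
    return model


def parameter_inventory(checkpoint_path) -> list[str]:
    """Sorted parameter/buffer names stored in a checkpoint file."""
    with np.load(checkpoint_path) as archive:
        return sorted(n for n in archive.files if n != "__config__")
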