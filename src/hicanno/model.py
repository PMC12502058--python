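"""Hierarchical image classifier: backbone + base-type and subtype heads.

A pluggable convolutional backbone maps a rendered cell image to a feature
vector; two linear heads map the features to base-type logits and to a
single global vector of subtype logits over all lineages.  At inference,
*probability masking* zeroes the subtype probabilities outside the
predicted base lineage and renormalizes the survivors, so the emitted
subtype is always a child of the emitted base type; terminal-leaf bases
(no subtypes) end at the base-level call.

Backbones
---------
``tiny_cnn``
    Two 3x3 conv + ReLU + 2x2 pool blocks followed by a dense feature
    layer, implemented in numpy.  CPU-friendly; the backbone used by the
    test suite and for desk-scale experiments.
``efficientnet_b5``
    The full-scale backbone used for atlas-scale training; requires the
    optional ``torch``/``torchvision`` dependency and is constructed lazily.
"""

from __future__ import annotations

import io as _io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from ._utils import ValidationError, spawn_rng
from .hierarchy import CellTypeHierarchy, hierarchy_from_dict


@dataclass(frozen=True)
class HierarchicalClassifierConfig:
    backbone_name: str = "tiny_cnn"
    feature_dim: int = 64
    image_hw: tuple[int, int] = (32, 32)
    n_channels: int = 3
    conv_channels: tuple[int, int] = (8, 16)
    pretrained_backbone: bool = False

    def __post_init__(self):
        if self.backbone_name not in ("tiny_cnn", "efficientnet_b5"):
            raise ValidationError(f"unknown backbone {self.backbone_name!r}")
        if self.feature_dim < 1:
            raise ValidationError("feature_dim must be positive")


@dataclass
class HierarchicalPrediction:
    """Per-cell output of the two-level classifier."""

    cell_id: str
    base_probs: np.ndarray          # (K_base,)
    sub_probs_raw: np.ndarray       # (K_sub,)
    sub_probs_masked: np.ndarray    # (K_sub,) zero outside the winning lineage
    base_label: str
    sub_label: str | None           # None for terminal-leaf bases
    rare_score: float = 0.0

    @property
    def base_prob(self) -> float:
        return float(self.base_probs.max())

    @property
    def sub_prob(self) -> float:
        return float(self.sub_probs_masked.max()) if self.sub_probs_masked.size else 0.0


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


def mask_subtype_probs(
    base_probs: np.ndarray, sub_probs_raw: np.ndarray, hier: CellTypeHierarchy
) -> np.ndarray:
    """Zero subtype probabilities outside the argmax base lineage, then
    renormalize the survivors to a proper conditional distribution.

    Argmax ties break to the lowest class index.  If the winning base is a
    terminal leaf the masked vector is all zeros (no subtype decision
    exists).  Idempotent: masking an already-masked vector is a no-op.
    """
    base_probs = np.asarray(base_probs, dtype=np.float64)
    sub = np.asarray(sub_probs_raw, dtype=np.float64)
    single = base_probs.ndim == 1
    if single:
        base_probs, sub = base_probs[None], sub[None]
    out = np.zeros_like(sub)
    for i in range(base_probs.shape[0]):
        b_star = int(np.argmax(base_probs[i]))  # np.argmax -> first/lowest index
        kids = hier.children_indices(b_star)
        if kids.size:
            vals = sub[i, kids]
            total = vals.sum()
            out[i, kids] = vals / total if total > 0 else 1.0 / kids.size
    return out[0] if single else out


def build_backbone(
    cfg: HierarchicalClassifierConfig, seed: int
) -> tuple[nn.Sequential, int]:
    """Construct the backbone; returns (module, feature dimension)."""
    if cfg.backbone_name == "efficientnet_b5":
        raise ImportError(
            "the efficientnet_b5 backbone requires the optional 'torch' and "
            "'torchvision' dependencies; install them or use backbone_name="
            "'tiny_cnn'"
        )
    h, w = cfg.image_hw
    if h % 4 or w % 4:
        raise ValidationError("tiny_cnn needs image dimensions divisible by 4")
    rng = spawn_rng(seed, "init")
    c1, c2 = cfg.conv_channels
    layers = [
        nn.Conv2d(cfg.n_channels, c1, 3, rng),
        nn.ReLU(),
        nn.MaxPool2d(2),
        nn.Conv2d(c1, c2, 3, rng),
        nn.ReLU(),
        nn.MaxPool2d(2),
        nn.Flatten(),
        nn.Linear(c2 * (h // 4) * (w // 4), cfg.feature_dim, rng),
        nn.ReLU(),
    ]
    return nn.Sequential(layers), cfg.feature_dim


class HierarchicalClassifier:
    """Backbone + two heads with explicit numpy forward/backward."""

    def __init__(
        self,
        cfg: HierarchicalClassifierConfig,
        hier: CellTypeHierarchy,
        seed: int = 0,
        pixel_map_fingerprint: str = "",
    ):
        self.cfg = cfg
        self.hier = hier
        self.seed = seed
        self.pixel_map_fingerprint = pixel_map_fingerprint
        self.backbone, feat = build_backbone(cfg, seed)
        rng = spawn_rng(seed, "heads")
        self.head_base = nn.Sequential([nn.Linear(feat, hier.K_base, rng)])
        self.head_sub = (
            nn.Sequential([nn.Linear(feat, hier.K_sub, rng)]) if hier.K_sub else None
        )

    # -- forward / backward -------------------------------------------------

    def forward(self, images: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
        """(N, C, H, W) images -> (base logits (N, K_base), sub logits or None)."""
        images = np.asarray(images, dtype=np.float64)
        expect = (self.cfg.n_channels, *self.cfg.image_hw)
        if images.ndim != 4 or images.shape[1:] != expect:
            raise ValidationError(
                f"expected images of shape (N, {expect[0]}, {expect[1]}, "
                f"{expect[2]}), got {images.shape}"
            )
        feats = self.backbone.forward(images)
        base_logits = self.head_base.forward(feats)
        sub_logits = self.head_sub.forward(feats) if self.head_sub else None
        return base_logits, sub_logits

    def backward(
        self, dbase: np.ndarray, dsub: np.ndarray | None
    ) -> np.ndarray:
        """Joint backprop through both heads; returns gradient w.r.t. input."""
        dfeat = self.head_base.backward(dbase)
        if self.head_sub is not None and dsub is not None:
            dfeat = dfeat + self.head_sub.backward(dsub)
        return self.backbone.backward(dfeat)

    def predict_proba(
        self, images: np.ndarray, batch_size: int = 256
    ) -> tuple[np.ndarray, np.ndarray]:
        """Softmax probabilities at both levels (raw, unmasked)."""
        bases, subs = [], []
        for start in range(0, images.shape[0], batch_size):
            bl, sl = self.forward(images[start:start + batch_size])
            bases.append(softmax(bl))
            subs.append(softmax(sl) if sl is not None
                        else np.zeros((bl.shape[0], 0)))
        return np.concatenate(bases), np.concatenate(subs)

    def class_score(self, images: np.ndarray, level: str, class_index: int) -> np.ndarray:
        """Pre-softmax score of one class; the quantity attributions explain."""
        base_logits, sub_logits = self.forward(images)
        if level == "base":
            return base_logits[:, class_index]
        if level == "subtype":
            if sub_logits is None:
                raise ValidationError("hierarchy has no subtypes")
            return sub_logits[:, class_index]
        raise ValidationError(f"level must be 'base' or 'subtype', got {level!r}")

    def class_score_input_grad(
        self, images: np.ndarray, level: str, class_index: int
    ) -> np.ndarray:
        """Gradient of the class score w.r.t. the input pixels."""
        base_logits, sub_logits = self.forward(images)
        dbase = np.zeros_like(base_logits)
        dsub = np.zeros_like(sub_logits) if sub_logits is not None else None
        if level == "base":
            dbase[:, class_index] = 1.0
        elif level == "subtype":
            if dsub is None:
                raise ValidationError("hierarchy has no subtypes")
            dsub[:, class_index] = 1.0
        else:
            raise ValidationError(f"level must be 'base' or 'subtype', got {level!r}")
        return self.backward(dbase, dsub)

    # -- checkpointing -------------------------------------------------------

    def _modules(self) -> dict[str, nn.Sequential]:
        mods = {"backbone": self.backbone, "head_base": self.head_base}
        if self.head_sub is not None:
            mods["head_sub"] = self.head_sub
        return mods

    def save(self, path: str | Path) -> None:
        """Checkpoint archive: weights + config + hierarchy + fingerprints.

        The hierarchy and pixel-map fingerprints are stored so a checkpoint
        refuses to run against a mismatched taxonomy or gene layout.
        """
        meta = {
            "config": {
                "backbone_name": self.cfg.backbone_name,
                "feature_dim": self.cfg.feature_dim,
                "image_hw": list(self.cfg.image_hw),
                "n_channels": self.cfg.n_channels,
                "conv_channels": list(self.cfg.conv_channels),
            },
            "seed": self.seed,
            "hierarchy": self.hier.to_dict(),
            "hierarchy_fingerprint": self.hier.fingerprint(),
            "pixel_map_fingerprint": self.pixel_map_fingerprint,
        }
        buf = _io.BytesIO()
        np.savez(buf, **nn.state_dict(self._modules()))
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            zf.writestr("meta.json", json.dumps(meta, indent=2))
            zf.writestr("weights.npz", buf.getvalue())

    @classmethod
    def load(cls, path: str | Path, pixel_map=None) -> "HierarchicalClassifier":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            with np.load(_io.BytesIO(zf.read("weights.npz"))) as npz:
                state = {k: npz[k] for k in npz.files}
        cfg = HierarchicalClassifierConfig(
            backbone_name=meta["config"]["backbone_name"],
            feature_dim=meta["config"]["feature_dim"],
            image_hw=tuple(meta["config"]["image_hw"]),
            n_channels=meta["config"]["n_channels"],
            conv_channels=tuple(meta["config"]["conv_channels"]),
        )
        hier = hierarchy_from_dict(meta["hierarchy"])
        clf = cls(cfg, hier, seed=meta["seed"],
                  pixel_map_fingerprint=meta["pixel_map_fingerprint"])
        nn.load_state_dict(clf._modules(), state)
        if pixel_map is not None:
            clf.check_pixel_map(pixel_map)
        return clf

    def check_pixel_map(self, pixel_map) -> None:
        if self.pixel_map_fingerprint and \
                pixel_map.fingerprint() != self.pixel_map_fingerprint:
            raise ValidationError(
                "pixel map does not match the one this checkpoint was trained "
                "with (fingerprint mismatch)"
            )
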