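"""Vessel segmentation: tiling, a vesselness baseline, and a small
trainable segmenter with two-stage transfer learning.

High-resolution ultra-widefield frames are processed as non-overlapping
576 x 576 tiles (zero-padded right/bottom) and recombined by exact
cropping, mirroring patch-based segmentation of 3,900 x 3,072 frames.
Two segmenters share that tiling front end:

* a deterministic multiscale Hessian-ridge (vesselness) baseline with
  quantile-based hysteresis thresholds;
* a compact trainable pixel classifier over multiscale Gaussian-derivative
  features, trained in two stages — pretraining on a regular-fundus-like
  corpus, then fine-tuning on ultra-widefield frames — the transfer-
  learning recipe that compensates for scarce annotated UWF data.

Segmentations are scored inside the field of view with the five standard
pixel metrics (accuracy, sensitivity, specificity, precision, F1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import filters as skfilters

from ._mlp import TinyMLP
from .core import FundusImage, as_bool_mask

DEFAULT_TILE_SIZE = 576


# ---------------------------------------------------------------------------
# Tiling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TileLayout:
    """Geometry of a non-overlapping tile cover of a padded frame."""

    tile_size: int
    n_rows: int
    n_cols: int
    orig_height: int
    orig_width: int

    @property
    def pad_bottom(self) -> int:
        return self.n_rows * self.tile_size - self.orig_height

    @property
    def pad_right(self) -> int:
        return self.n_cols * self.tile_size - self.orig_width

    @property
    def n_tiles(self) -> int:
        return self.n_rows * self.n_cols

    def origins(self) -> list[tuple[int, int]]:
        """Row-major top-left corners of each tile in the padded frame."""
        t = self.tile_size
        return [(r * t, c * t) for r in range(self.n_rows)
                for c in range(self.n_cols)]


def tile_image(image: np.ndarray, tile_size: int = DEFAULT_TILE_SIZE
               ) -> tuple[np.ndarray, TileLayout]:
    """Cut an image into non-overlapping row-major tiles.

    The frame is zero-padded on the right and bottom to the next multiple
    of ``tile_size``; returns ``(tiles, layout)`` with ``tiles`` shaped
    ``(n_tiles, tile_size, tile_size)``.
    """
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    image = np.asarray(image)
    if image.ndim != 2 or image.shape[0] < 1 or image.shape[1] < 1:
        raise ValueError("image must be 2-D and non-empty")
    h, w = image.shape
    n_rows = -(-h // tile_size)
    n_cols = -(-w // tile_size)
    padded = np.zeros((n_rows * tile_size, n_cols * tile_size), dtype=image.dtype)
    padded[:h, :w] = image
    tiles = (padded
             .reshape(n_rows, tile_size, n_cols, tile_size)
             .transpose(0, 2, 1, 3)
             .reshape(n_rows * n_cols, tile_size, tile_size))
    return tiles, TileLayout(tile_size, n_rows, n_cols, h, w)


def untile(tiles: np.ndarray, layout: TileLayout) -> np.ndarray:
    """Recombine tiles and crop the padding; exact inverse of tile_image."""
    tiles = np.asarray(tiles)
    if tiles.shape[0] != layout.n_tiles:
        raise ValueError(f"expected {layout.n_tiles} tiles, got {tiles.shape[0]}")
    t = layout.tile_size
    if tiles.shape[1:] != (t, t):
        raise ValueError("tile shape does not match layout tile_size")
    padded = (tiles
              .reshape(layout.n_rows, layout.n_cols, t, t)
              .transpose(0, 2, 1, 3)
              .reshape(layout.n_rows * t, layout.n_cols * t))
    return padded[: layout.orig_height, : layout.orig_width]


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionMetrics:
    """Pixel confusion counts and the five derived scores.

    Fractions lie in [0, 1]; ``f1_pct`` reports F1 x 100, the convention
    used in the vessel-segmentation literature.  When no positives are
    predicted, precision and F1 are defined as 0 and ``zero_division`` is
    flagged.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else 0.0

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return self.tn / denom if denom else 0.0

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else 0.0

    @property
    def zero_division(self) -> bool:
        return (self.tp + self.fp) == 0 or (self.tp + self.fn) == 0

    @property
    def f1(self) -> float:
        p, s = self.precision, self.sensitivity
        return 2.0 * p * s / (p + s) if (p + s) > 0 else 0.0

    @property
    def f1_pct(self) -> float:
        return 100.0 * self.f1

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
                "accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "precision": self.precision,
                "f1": self.f1, "f1_pct": self.f1_pct,
                "zero_division": self.zero_division}


def evaluate_segmentation(pred: np.ndarray, truth: np.ndarray,
                          fov: np.ndarray) -> ConfusionMetrics:
    """Pixelwise confusion metrics restricted to the field of view."""
    pred, truth, fov = map(as_bool_mask, (pred, truth, fov))
    if pred.shape != truth.shape or pred.shape != fov.shape:
        raise ValueError("pred, truth, and fov must share a shape")
    if not fov.any():
        raise ValueError("empty field of view")
    p, t = pred[fov], truth[fov]
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    m = ConfusionMetrics(tp, fp, fn, tn)
    if m.zero_division:
        warnings.warn("no positives predicted or present; precision/F1 set to 0",
                      stacklevel=2)
    return m


def evaluate_many(pairs: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray]]
                  ) -> dict:
    """Micro- and macro-averaged scores over (pred, truth, fov) triples.

    Micro scores pool the pixel counts; macro scores average the
    per-image metrics.  Both are reported because per-image averaging and
    pooled counting give slightly different F1 on heterogeneous sets.
    """
    per_image = [evaluate_segmentation(*triple) for triple in pairs]
    tp = sum(m.tp for m in per_image)
    fp = sum(m.fp for m in per_image)
    fn = sum(m.fn for m in per_image)
    tn = sum(m.tn for m in per_image)
    micro = ConfusionMetrics(tp, fp, fn, tn)
    macro = {key: float(np.mean([m.as_dict()[key] for m in per_image]))
             for key in ("accuracy", "sensitivity", "specificity",
                         "precision", "f1")}
    return {"per_image": per_image, "micro": micro, "macro": macro}


# ---------------------------------------------------------------------------
# Vesselness baseline
# ---------------------------------------------------------------------------


def _fov_from_image(image: np.ndarray) -> np.ndarray:
    """Estimate the field of view as the eroded nonzero region."""
    fov = np.asarray(image) > 0
    return ndimage.binary_erosion(fov, iterations=3)


def vesselness_baseline(image: np.ndarray | FundusImage,
                        scales: Sequence[float] = (1.0, 1.6, 2.6),
                        low_quantile: float = 0.966,
                        high_quantile: float = 0.972,
                        fov: Optional[np.ndarray] = None) -> np.ndarray:
    """Deterministic multiscale Hessian-ridge segmenter.

    The Sato tubularity response (dark ridges) is maximized over
    ``scales``, hysteresis-thresholded at the given response quantiles
    taken inside the field of view, and clipped to the field of view.
    Quantile thresholds make the output invariant to positive rescaling
    of the intensities.
    """
    if isinstance(image, FundusImage):
        if fov is None:
            fov = image.fov_mask()
        image = image.pixels
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    scales = list(scales)
    if not scales:
        raise ValueError("scales must be non-empty")
    if fov is None:
        fov = _fov_from_image(image)
    fov = as_bool_mask(fov)
    if not fov.any():
        return np.zeros_like(fov)

    resp = skfilters.sato(image, sigmas=scales, black_ridges=True, mode="reflect")
    # the FOV rim is a strong artificial ridge; keep a safety margin
    inner = ndimage.binary_erosion(fov, iterations=4)
    resp = np.where(inner, resp, 0.0)
    vals = resp[inner]
    if vals.size == 0 or np.ptp(vals) == 0:
        return np.zeros_like(fov)
    low, high = np.quantile(vals, [low_quantile, high_quantile])
    if high <= low:
        high = low + 1e-12
    mask = skfilters.apply_hysteresis_threshold(resp, low, high)
    return mask & inner


# ---------------------------------------------------------------------------
# Trainable segmenter
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainConfig:
    """Two-stage training configuration.

    ``stage`` selects which stages run: ``both`` (default) performs
    pretraining on the regular-fundus-like corpus then fine-tunes on
    ultra-widefield pairs; ``pretrain``/``finetune`` run a single stage.
    ``epochs`` applies per stage; 0 epochs returns the initialized model
    unchanged.  Counts default to the reference corpus sizes (380
    pretraining images, 50 labeled UWF frames) and are informational —
    the actual sets passed in govern.
    """

    stage: str = "both"
    n_pretrain_images: int = 380
    n_finetune_images: int = 50
    epochs: int = 2
    learning_rate: float = 3e-3
    batch_size: int = 512
    seed: int = 0
    binarization_threshold: float = 0.5
    tile_size: int = DEFAULT_TILE_SIZE
    feature_scales: tuple = (1.0, 2.0, 4.0)
    samples_per_tile: int = 400

    def __post_init__(self) -> None:
        if self.stage not in ("both", "pretrain", "finetune"):
            raise ValueError("stage must be 'both', 'pretrain' or 'finetune'")
        if not 0.0 < self.binarization_threshold < 1.0:
            raise ValueError("binarization_threshold must be in (0, 1)")
        if self.n_pretrain_images <= 0 or self.n_finetune_images <= 0:
            raise ValueError("image counts must be positive")


def pixel_features(image: np.ndarray, scales: Sequence[float] = (1.0, 2.0, 4.0)
                   ) -> np.ndarray:
    """Per-pixel feature stack: normalized intensity plus, per scale,
    Gaussian-smoothed intensity, gradient magnitude, and the two Hessian
    eigenvalues.  Shape (H, W, 1 + 4 * n_scales)."""
    img = np.asarray(image, dtype=np.float64)
    sd = img.std()
    img = (img - img.mean()) / (sd if sd > 0 else 1.0)
    feats = [img]
    for s in scales:
        g = ndimage.gaussian_filter(img, s)
        gr = ndimage.gaussian_filter(img, s, order=(1, 0))
        gc = ndimage.gaussian_filter(img, s, order=(0, 1))
        hrr = ndimage.gaussian_filter(img, s, order=(2, 0)) * s**2
        hcc = ndimage.gaussian_filter(img, s, order=(0, 2)) * s**2
        hrc = ndimage.gaussian_filter(img, s, order=(1, 1)) * s**2
        tr2 = 0.5 * (hrr + hcc)
        det = np.sqrt(np.maximum(0.25 * (hrr - hcc) ** 2 + hrc**2, 0.0))
        feats.extend([g, np.hypot(gr, gc), tr2 + det, tr2 - det])
    return np.stack(feats, axis=-1)


@dataclass
class SegmenterModel:
    """A trained pixel classifier plus its feature/tiling configuration."""

    mlp: TinyMLP
    config: TrainConfig
    stages_trained: tuple = ()

    def save(self, path) -> None:
        self.mlp.save(path)

    def predict_proba_image(self, image: np.ndarray) -> np.ndarray:
        tiles, layout = tile_image(np.asarray(image, dtype=np.float64),
                                   self.config.tile_size)
        out = np.empty_like(tiles, dtype=np.float64)
        for i in range(tiles.shape[0]):
            f = pixel_features(tiles[i], self.config.feature_scales)
            proba = self.mlp.predict_proba(f.reshape(-1, f.shape[-1]))
            out[i] = proba.reshape(tiles[i].shape)
        return untile(out, layout)


def _as_pixels(image) -> np.ndarray:
    return image.pixels if isinstance(image, FundusImage) else np.asarray(image)


def _stage_samples(pairs, config: TrainConfig, rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Balanced pixel samples from all tiles of all (image, mask) pairs."""
    xs, ys = [], []
    for image, mask in pairs:
        img = np.asarray(_as_pixels(image), dtype=np.float64)
        msk = as_bool_mask(mask)
        tiles, layout = tile_image(img, config.tile_size)
        mtiles, _ = tile_image(msk.astype(np.uint8), config.tile_size)
        for i in range(tiles.shape[0]):
            f = pixel_features(tiles[i], config.feature_scales)
            flat = f.reshape(-1, f.shape[-1])
            label = mtiles[i].astype(bool).ravel()
            pos = np.flatnonzero(label)
            neg = np.flatnonzero(~label)
            if pos.size == 0:
                continue
            n_half = config.samples_per_tile // 2
            pi = rng.choice(pos, size=min(n_half, pos.size), replace=False)
            ni = rng.choice(neg, size=min(n_half, neg.size), replace=False)
            idx = np.concatenate([pi, ni])
            xs.append(flat[idx])
            ys.append(label[idx].astype(np.float64))
    if not xs:
        raise ValueError("no usable training pixels (all masks empty?)")
    return np.concatenate(xs), np.concatenate(ys)


def train_segmenter(pretrain_set, finetune_set, config: TrainConfig = TrainConfig(),
                    model: Optional[SegmenterModel] = None) -> SegmenterModel:
    """Train the small segmenter with the two-stage transfer procedure.

    ``pretrain_set`` holds (image, mask) pairs from a regular-fundus-like
    distribution; ``finetune_set`` holds ultra-widefield pairs.  With
    ``stage='both'`` the model is pretrained then fine-tuned, each for
    ``config.epochs`` epochs.  Pass ``pretrain_set=None`` with
    ``stage='finetune'`` to train from scratch on UWF data alone (the
    no-transfer control).  Deterministic given ``config.seed``.
    """
    stages = {"both": ("pretrain", "finetune"),
              "pretrain": ("pretrain",),
              "finetune": ("finetune",)}[config.stage]
    data = {"pretrain": pretrain_set, "finetune": finetune_set}
    for st in stages:
        if not data[st]:
            raise ValueError(f"{st} set is empty but stage {st!r} was requested")

    if model is None:
        n_feat = 1 + 4 * len(config.feature_scales)
        model = SegmenterModel(
            mlp=TinyMLP(n_features=n_feat, hidden=16, seed=config.seed,
                        learning_rate=config.learning_rate),
            config=config,
        )
    for si, st in enumerate(stages):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, si]))
        X, y = _stage_samples(data[st], config, rng)
        model.mlp.fit_epochs(X, y, epochs=config.epochs,
                             batch_size=config.batch_size,
                             shuffle_seed=config.seed + 101 * si)
        model = replace(model, stages_trained=model.stages_trained + (st,))
    return model


def predict_mask(model, image, threshold: Optional[float] = None,
                 fov: Optional[np.ndarray] = None, **baseline_kwargs
                 ) -> np.ndarray:
    """Segment an image of arbitrary size (tiling handled internally).

    ``model`` is a :class:`SegmenterModel` or the string ``"baseline"``
    for the vesselness segmenter.  Probabilities are recombined with
    :func:`untile` and thresholded (default: the model's configured
    binarization threshold, 0.5).
    """
    if isinstance(image, FundusImage):
        if fov is None:
            fov = image.fov_mask()
        image = image.pixels
    if isinstance(model, str):
        if model != "baseline":
            raise ValueError("model must be a SegmenterModel or 'baseline'")
        return vesselness_baseline(image, fov=fov, **baseline_kwargs)
    thr = threshold if threshold is not None else model.config.binarization_threshold
    proba = model.predict_proba_image(image)
    mask = proba >= thr
    if fov is None:
        fov = _fov_from_image(image)
    return mask & as_bool_mask(fov)
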