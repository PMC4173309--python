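"""Four-layer HMAX feature hierarchy (image pyramid -> S1 -> C1 -> S2 -> C2).

Alternating template-matching ("simple cell", S) and max-pooling ("complex
cell", C) stages, CPU implementation:

* image layer: 10-scale pyramid, each level 2**(1/4) smaller than the last;
* S1: absolute normalized cross-correlation with a bank of Gabor filters
  (4 orientations, 11 x 11), contrast-polarity invariant, followed by 50 %
  lateral inhibition across orientations;
* C1: max pooling over 8 x 8 spatial neighbourhoods (stride 4) and over
  bands of 2 adjacent scales, followed by the same inhibition;
* S2: normalized dot product between local C1 patches (4/8/12/16 C1 units,
  all orientations) and a dictionary of prototypes sampled at random from
  training-image C1 responses;
* C2: per-prototype global maximum over all positions and scale bands,
  yielding a position- and scale-tolerant feature vector.

All responses lie in [0, 1].  The forward pass is deterministic given an
image and a dictionary; the only randomness is prototype sampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import fftconvolve
from skimage.transform import resize

__all__ = [
    "HMAXConfig",
    "PatchDictionary",
    "gabor_bank",
    "build_pyramid",
    "s1_filter",
    "lateral_inhibition",
    "c1_pool",
    "learn_dictionary",
    "s2_respond",
    "c2_pool",
    "HMAX",
    "LAYERS",
]

LAYERS = ("input", "s1", "c1", "s2", "c2")


@dataclass(frozen=True)
class HMAXConfig:
    """Architecture parameters.

    Defaults: 10 pyramid scales shrinking by 2**(1/4) per level from a
    256-px base; 4 Gabor orientations with an 11 x 11 support (wavelength
    5.6 px, envelope sigma 4.5 px, aspect ratio 0.3 -- standard V1-fit
    values for this filter size); C1 pools 8 x 8 with stride 4 over bands of
    2 adjacent scales; 50 % lateral inhibition in S1 and C1; 1000 S2
    prototypes with square patch sides of 4, 8, 12 or 16 C1 units.
    """

    base_size: int = 256
    n_scales: int = 10
    scale_factor: float = 2.0 ** 0.25
    orientations: tuple = (0.0, 45.0, 90.0, 135.0)
    filter_size: int = 11
    wavelength: float = 5.6
    sigma: float = 4.5
    aspect_ratio: float = 0.3
    pool_size: int = 8
    pool_stride: int = 4
    band_size: int = 2
    inhibition: float = 0.5
    n_prototypes: int = 1000
    patch_sizes: tuple = (4, 8, 12, 16)

    @property
    def n_bands(self) -> int:
        return self.n_scales // self.band_size

    def level_sides(self) -> list[int]:
        """Pyramid level side lengths, rounded half away from zero."""
        return [int(np.floor(self.base_size * self.scale_factor ** (-k) + 0.5))
                for k in range(self.n_scales)]


# ---------------------------------------------------------------------------
# image layer
# ---------------------------------------------------------------------------

def preprocess(raster: np.ndarray) -> np.ndarray:
    """Map a stimulus raster to the model's input: float in [0, 1], strokes = 1.

    Dark-on-light drawings are inverted so features respond to strokes
    rather than to the background; S1's polarity invariance makes this a
    convention, not a modelling choice.
    """
    img = np.asarray(raster, dtype=np.float32)
    if img.max() > 1.0:
        img = img / 255.0
    return 1.0 - img


def build_pyramid(image: np.ndarray, cfg: HMAXConfig = HMAXConfig()) -> list[np.ndarray]:
    """Multi-scale representation; level k has side round(base * factor**-k)."""
    img = np.asarray(image, dtype=np.float32)
    if img.ndim != 2 or img.shape[0] != img.shape[1] or img.shape[0] != cfg.base_size:
        raise ValueError(f"expected square {cfg.base_size}-px input, got {img.shape}")
    levels = [img]
    for side in cfg.level_sides()[1:]:
        levels.append(resize(img, (side, side), order=1, anti_aliasing=True,
                             preserve_range=True).astype(np.float32))
    return levels


# ---------------------------------------------------------------------------
# S1
# ---------------------------------------------------------------------------

def gabor_bank(cfg: HMAXConfig = HMAXConfig()) -> np.ndarray:
    """Mean-zero, unit-norm Gabor filters, one per orientation: (n_orient, k, k)."""
    k = cfg.filter_size
    half = (k - 1) / 2.0
    ys, xs = np.mgrid[-half:half + 1, -half:half + 1]
    filters = []
    for deg in cfg.orientations:
        th = np.deg2rad(deg)
        # coordinate along the preferred bar orientation and across it;
        # the carrier varies across the bar so the label is the bar angle
        along = xs * np.cos(th) + ys * np.sin(th)
        across = -xs * np.sin(th) + ys * np.cos(th)
        g = (np.exp(-(across ** 2 + (cfg.aspect_ratio * along) ** 2) / (2 * cfg.sigma ** 2))
             * np.cos(2 * np.pi * across / cfg.wavelength))
        g -= g.mean()
        g /= np.linalg.norm(g)
        filters.append(g)
    return np.asarray(filters, dtype=np.float32)


def s1_filter(pyramid: list[np.ndarray], bank: np.ndarray,
              dtype=np.float32) -> list[np.ndarray]:
    """Absolute normalized cross-correlation of each level with each filter.

    Response at a position = |sum(filter * patch)| / ||patch||, valid region
    only, clipped to [0, 1].  Returns one (n_orient, H, W) array per scale.
    Computation is double precision; ``dtype`` controls the stored maps.
    """
    k = bank.shape[-1]
    out = []
    for level in pyramid:
        if min(level.shape) < k:
            raise ValueError("pyramid level smaller than the filter support")
        sq = fftconvolve(level.astype(np.float64) ** 2, np.ones((k, k)), mode="valid")
        norms = np.sqrt(np.clip(sq, 0.0, None))
        maps = []
        for g in bank:
            num = fftconvolve(level.astype(np.float64), g[::-1, ::-1].astype(np.float64),
                              mode="valid")
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.abs(num) / norms
            r[norms < 1e-9] = 0.0
            maps.append(np.clip(r, 0.0, 1.0))
        out.append(np.asarray(maps, dtype=dtype))
    return out


def lateral_inhibition(maps, fraction: float = 0.5):
    """Zero responses below ``fraction`` x the strongest orientation response
    at each (scale, position); the winners are left unchanged."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if fraction == 0.0:
        return [m.copy() for m in maps]
    out = []
    for m in maps:
        peak = m.max(axis=0, keepdims=True)
        out.append(np.where(m < fraction * peak, 0.0, m).astype(m.dtype))
    return out


# ---------------------------------------------------------------------------
# C1
# ---------------------------------------------------------------------------

def _spatial_max_pool(m: np.ndarray, pool: int, stride: int) -> np.ndarray:
    """Max over pool x pool windows whose top-left corners sit on the stride
    grid 0, stride, 2*stride, ... (valid windows only)."""
    if m.shape[-1] < pool or m.shape[-2] < pool:
        raise ValueError("pool larger than map")
    win = sliding_window_view(m, (pool, pool), axis=(-2, -1))
    win = win[..., ::stride, ::stride, :, :]
    return win.max(axis=(-2, -1))


def c1_pool(s1_maps: list[np.ndarray], cfg: HMAXConfig = HMAXConfig()) -> list[np.ndarray]:
    """Complex-cell pooling: spatial max (pool_size, stride) per scale, then a
    max across the scales of each band of adjacent pyramid levels.

    The band's output grid is that of its finest (largest) member; coarser
    members are upsampled to it (nearest neighbour) before the cross-scale
    max.  Returns one (n_orient, h, w) array per band, with lateral
    inhibition applied across orientations.
    """
    pooled = [_spatial_max_pool(m, cfg.pool_size, cfg.pool_stride) for m in s1_maps]
    bands = []
    for b in range(cfg.n_bands):
        members = pooled[b * cfg.band_size:(b + 1) * cfg.band_size]
        ref = members[0]
        acc = ref.copy()
        for m in members[1:]:
            up = resize(m, ref.shape, order=0, preserve_range=True,
                        anti_aliasing=False).astype(ref.dtype)
            acc = np.maximum(acc, up)
        bands.append(acc)
    return lateral_inhibition(bands, cfg.inhibition)


# ---------------------------------------------------------------------------
# S2 / C2
# ---------------------------------------------------------------------------

@dataclass
class PatchDictionary:
    """S2 prototype set sampled from training-image C1 responses.

    ``patches[s]`` holds the unit-norm prototypes of side ``s`` as a
    (n_s, n_orient * s * s) matrix; ``meta`` records (source image index,
    band, row, col, size) per prototype, in global prototype order
    ``order`` (list of (size, row-in-group) pairs).
    """

    patches: dict
    meta: list
    order: list
    n_orientations: int

    @property
    def size(self) -> int:
        return len(self.order)

    def save(self, path) -> None:
        path = Path(path)
        arrays = {f"size_{s}": m for s, m in self.patches.items()}
        np.savez_compressed(path, **arrays)
        sidecar = {"meta": self.meta, "order": self.order,
                   "n_orientations": self.n_orientations}
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path) -> "PatchDictionary":
        path = Path(path)
        data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
        patches = {int(k.split("_")[1]): data[k] for k in data.files}
        sidecar = json.loads(path.with_suffix(".json").read_text())
        order = [tuple(o) for o in sidecar["order"]]
        return cls(patches, sidecar["meta"], order, sidecar["n_orientations"])


def learn_dictionary(c1_per_image: list[list[np.ndarray]], cfg: HMAXConfig,
                     rng: np.random.Generator) -> PatchDictionary:
    """Sample ``cfg.n_prototypes`` C1 patches uniformly at random over training
    image, band, patch size and position; unit-normalize and store.

    Patches that do not fit the chosen band, or whose response is all zero
    (blank image region), are redrawn.  Deterministic under a fixed rng.
    """
    if not c1_per_image:
        raise ValueError("need at least one training image")
    if cfg.n_prototypes < 1:
        raise ValueError("n_prototypes must be >= 1")
    n_orient = c1_per_image[0][0].shape[0]
    groups: dict[int, list[np.ndarray]] = {s: [] for s in cfg.patch_sizes}
    meta, order = [], []
    drawn = 0
    while drawn < cfg.n_prototypes:
        img = int(rng.integers(len(c1_per_image)))
        band = int(rng.integers(len(c1_per_image[img])))
        s = int(cfg.patch_sizes[rng.integers(len(cfg.patch_sizes))])
        m = c1_per_image[img][band]
        if m.shape[1] < s or m.shape[2] < s:
            continue
        r = int(rng.integers(m.shape[1] - s + 1))
        c = int(rng.integers(m.shape[2] - s + 1))
        patch = m[:, r:r + s, c:c + s].astype(np.float32).ravel()
        nrm = float(np.linalg.norm(patch))
        if nrm < 1e-9:
            continue
        groups[s].append(patch / nrm)
        order.append((s, len(groups[s]) - 1))
        meta.append({"image": img, "band": band, "row": r, "col": c, "size": s})
        drawn += 1
    patches = {s: (np.stack(v) if v else np.zeros((0, n_orient * s * s), np.float32))
               for s, v in groups.items()}
    return PatchDictionary(patches, meta, order, n_orient)


def s2_respond(c1_maps: list[np.ndarray], dictionary: PatchDictionary,
               dtype=np.float32) -> dict:
    """Normalized dot product of every prototype with every local C1 patch.

    Returns ``{band: {size: (n_prototypes_of_size, H', W') array}}`` over
    valid positions; a response of 1 occurs iff the local patch is a
    positive scalar multiple of the prototype.  Bands too small for a patch
    size are omitted for that size.  ``dtype`` sets the matrix-product
    precision (single by default; double for oracle-grade comparisons).
    """
    if dictionary.size == 0:
        raise ValueError("empty prototype dictionary")
    out: dict = {}
    for b, m in enumerate(c1_maps):
        n_orient, H, W = m.shape
        per_size = {}
        for s, protos in dictionary.patches.items():
            if len(protos) == 0 or H < s or W < s:
                continue
            win = sliding_window_view(m, (s, s), axis=(1, 2))  # (n_orient, H', W', s, s)
            win = np.moveaxis(win, 0, 2)  # (H', W', n_orient, s, s)
            hp, wp = win.shape[0], win.shape[1]
            flat = win.reshape(hp * wp, n_orient * s * s).astype(dtype)
            norms = np.linalg.norm(flat, axis=1)
            resp = flat @ protos.T.astype(dtype)
            with np.errstate(invalid="ignore", divide="ignore"):
                resp /= norms[:, None]
            resp[norms < 1e-9, :] = 0.0
            np.clip(resp, 0.0, 1.0, out=resp)
            per_size[s] = np.moveaxis(resp.reshape(hp, wp, -1), 2, 0)
        out[b] = per_size
    return out


def c2_pool(s2_maps: dict, dictionary: PatchDictionary) -> np.ndarray:
    """Global max per prototype over all positions and bands (length = dictionary size).

    Prototypes with no valid position anywhere respond 0.
    """
    if not s2_maps:
        raise ValueError("empty S2 maps")
    best: dict[int, np.ndarray] = {}
    for per_size in s2_maps.values():
        for s, arr in per_size.items():
            m = arr.reshape(arr.shape[0], -1).max(axis=1)
            best[s] = np.maximum(best[s], m) if s in best else m
    c2 = np.zeros(dictionary.size, dtype=np.float32)
    for i, (s, j) in enumerate(dictionary.order):
        if s in best and j < best[s].shape[0]:
            c2[i] = best[s][j]
    return c2


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

class HMAX:
    """Feature hierarchy with a tap after every layer."""

    def __init__(self, cfg: HMAXConfig = HMAXConfig()):
        self.cfg = cfg
        self.bank = gabor_bank(cfg)

    def forward(self, raster: np.ndarray, dictionary: PatchDictionary | None = None,
                upto: str = "c2") -> dict:
        """Run the hierarchy on one stimulus raster.

        Returns a dict with keys up to ``upto`` among ``input`` (normalized
        inverted image), ``s1`` (inhibited maps per scale), ``c1`` (band
        maps), ``s2``, ``c2``.  ``dictionary`` is required beyond C1.
        """
        if upto not in LAYERS:
            raise ValueError(f"unknown layer {upto!r}")
        img = preprocess(raster)
        out = {"input": img}
        if upto == "input":
            return out
        pyr = build_pyramid(img, self.cfg)
        s1 = lateral_inhibition(s1_filter(pyr, self.bank), self.cfg.inhibition)
        out["s1"] = s1
        if upto == "s1":
            return out
        c1 = c1_pool(s1, self.cfg)
        out["c1"] = c1
        if upto == "c1":
            return out
        if dictionary is None:
            raise ValueError("a PatchDictionary is required for S2/C2")
        s2 = s2_respond(c1, dictionary)
        out["s2"] = s2
        if upto == "s2":
            return out
        out["c2"] = c2_pool(s2, dictionary)
        return out

    def c1_features(self, raster: np.ndarray) -> list[np.ndarray]:
        """C1 band maps only (used for dictionary learning and caching)."""
        return self.forward(raster, upto="c1")["c1"]
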