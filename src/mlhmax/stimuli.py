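"""Synthetic Müller-Lyer / control / cross-fin line stimuli.

Every image is a 256 x 256 8-bit raster containing two horizontal 2-px-thick
"shafts" with oblique "fins" attached at the shaft ends, black strokes on a
white background.  Three families are produced:

* ``train_cross`` -- both lines carry X-shaped (cross) fins; non-illusory,
  used to train the feature hierarchy and the readout.
* ``ctl``         -- top line carries left-facing arrows, bottom line
  right-facing arrows (contraction and expansion cues cancel); used for
  parameterization.
* ``ml20`` / ``ml40`` -- the classical Müller-Lyer figure: arrow-tails on the
  top line, arrowheads on the bottom line, fin angle fixed at 20 or 40 deg.

The category of a stimulus is defined by the *top* line: ``"long"`` means the
top shaft is the longer of the two.  ``delta`` is the signed length
difference top - bottom in pixels.

Randomized quantities are independent uniform integers over closed ranges;
figures are jittered vertically, and horizontally only in ``"HV"`` mode
(``"V"`` mode centres each figure).  Sampled specs whose rendered strokes
would overlap between figures, self-intersect within a figure, or come
within 2 px of the image border are rejected and resampled.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from shapely.geometry import LineString, Point

__all__ = [
    "FigureSpec",
    "StimulusSpec",
    "StimulusSet",
    "IMAGE_SIZE",
    "SET_KINDS",
    "JITTER_MODES",
    "sample_stimulus_spec",
    "render_figure",
    "render_stimulus",
    "figure_segments",
    "figures_overlap",
    "stimulus_in_bounds",
    "generate_set",
]

IMAGE_SIZE = 256
STROKE = 2  # stroke thickness in pixels (2x2 stamps)
BORDER_MARGIN = 2

SET_KINDS = ("train_cross", "ctl", "ml20", "ml40")
JITTER_MODES = ("HV", "V")
CATEGORIES = ("long", "short")
FIN_STYLES = ("cross", "arrow_left", "arrow_right", "arrowhead", "arrowtail")

#: vertical bands for the shaft y-position (pixels from image top)
Y_BANDS = {
    "HV": {"top": (58, 88), "bottom": (168, 198)},
    "V": {"top": (48, 108), "bottom": (148, 208)},
}
X_OFFSET_RANGE = (-30, 30)  # HV mode only; V mode centres the figure
SHAFT_RANGE = (120, 240)  # longer line
FIN_LENGTH_RANGE = (15, 40)
TRAIN_DELTA_RANGE = (2, 62)  # |delta| for training / CTL parameterization
TEST_DELTAS = (10, 20, 30, 40, 50, 60)
FIN_ANGLE_RANGES = {"train_cross": (10, 90), "ctl": (10, 80)}
ML_ANGLES = {"ml20": 20, "ml40": 40}


@dataclass(frozen=True)
class FigureSpec:
    """Geometry of one line (shaft plus fins)."""

    role: str  # "top" | "bottom"
    shaft_length: int
    fin_style: str
    fin_angle: float  # degrees between each fin and the shaft axis
    fin_length: int
    y_position: int  # shaft row, pixels from image top
    x_offset: int  # shaft centre offset from the horizontal image centre


@dataclass(frozen=True)
class StimulusSpec:
    """Complete description of one two-line trial."""

    top: FigureSpec
    bottom: FigureSpec
    category: str  # "long" iff top shaft is the longer one
    delta: int  # signed, top - bottom, pixels
    set_kind: str
    jitter_mode: str
    seed: int | None = None

    def __post_init__(self):
        if (self.delta > 0) != (self.category == "long"):
            raise ValueError("category must be 'long' iff delta > 0")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def figure_segments(fig: FigureSpec) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """Continuum centre-line segments ((x0, y0), (x1, y1)) of one figure.

    The shaft spans ``shaft_length`` pixel columns; fins attach at the two
    shaft endpoints.  ``arrowhead`` fins converge toward the shaft interior,
    ``arrowtail`` fins diverge outward, ``arrow_left``/``arrow_right`` open
    toward one side at both ends, and ``cross`` draws all four diagonal
    directions at each end.
    """
    L = fig.shaft_length
    xc = (IMAGE_SIZE / 2) + fig.x_offset
    y = float(fig.y_position)
    x0 = xc - (L - 1) / 2.0
    x1 = xc + (L - 1) / 2.0
    segments = [((x0, y), (x1, y))]
    if fig.fin_length <= 0:
        return segments

    theta = math.radians(fig.fin_angle)
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    # x-direction multipliers for the fins at (left end, right end);
    # +1 points rightward (into the shaft at the left end, out of it at the right)
    style_dirs = {
        "cross": ((1, -1), (1, -1)),
        "arrowhead": ((1,), (-1,)),
        "arrowtail": ((-1,), (1,)),
        "arrow_left": ((-1,), (-1,)),
        "arrow_right": ((1,), (1,)),
    }
    if fig.fin_style not in style_dirs:
        raise ValueError(f"unknown fin_style {fig.fin_style!r}")
    left_dirs, right_dirs = style_dirs[fig.fin_style]
    for (ax, dirs) in (((x0, y), left_dirs), ((x1, y), right_dirs)):
        for dx in dirs:
            for dy in (1, -1):
                tip = (ax[0] + fig.fin_length * dx * cos_t,
                       ax[1] + fig.fin_length * dy * sin_t)
                segments.append((ax, tip))
    # drop duplicates (cross fins at 90 deg collapse pairwise)
    seen, unique = set(), []
    for (p, q) in segments:
        key = (round(p[0], 9), round(p[1], 9), round(q[0], 9), round(q[1], 9))
        if key not in seen:
            seen.add(key)
            unique.append((p, q))
    return unique


_EPS = 1e-9


def _segment_mask(p0, p1, shape=(IMAGE_SIZE, IMAGE_SIZE)) -> np.ndarray:
    """Boolean stroke mask of one 2-px-thick segment.

    A continuum point (u, v) stamps the 2x2 pixel block with upper-left
    corner (floor(u), floor(v)); pixel (row r, col c) is ON iff some point
    of the segment has u in [c-1, c+1) and v in [r-1, r+1).  Computed
    exactly by intersecting the per-axis parameter intervals.
    """
    h, w = shape
    (u0, v0), (u1, v1) = p0, p1
    mask = np.zeros(shape, dtype=bool)

    cmin = max(0, math.floor(min(u0, u1)) - 1)
    cmax = min(w - 1, math.floor(max(u0, u1)) + 1)
    rmin = max(0, math.floor(min(v0, v1)) - 1)
    rmax = min(h - 1, math.floor(max(v0, v1)) + 1)
    if cmin > cmax or rmin > rmax:
        return mask

    def axis_intervals(coords, a0, a1):
        d = a1 - a0
        lo_b = coords - 1.0
        hi_b = coords + 1.0 - _EPS
        if d == 0.0:
            ok = (lo_b <= a0) & (a0 <= hi_b)
            lo = np.where(ok, 0.0, np.inf)
            hi = np.where(ok, 1.0, -np.inf)
        else:
            t1 = (lo_b - a0) / d
            t2 = (hi_b - a0) / d
            lo = np.minimum(t1, t2)
            hi = np.maximum(t1, t2)
        return lo, hi

    cs = np.arange(cmin, cmax + 1, dtype=float)
    rs = np.arange(rmin, rmax + 1, dtype=float)
    lo_c, hi_c = axis_intervals(cs, u0, u1)
    lo_r, hi_r = axis_intervals(rs, v0, v1)
    lo = np.maximum(np.maximum(lo_r[:, None], lo_c[None, :]), 0.0)
    hi = np.minimum(np.minimum(hi_r[:, None], hi_c[None, :]), 1.0)
    mask[rmin:rmax + 1, cmin:cmax + 1] = lo <= hi
    return mask


def render_figure(fig: FigureSpec, shape=(IMAGE_SIZE, IMAGE_SIZE)) -> np.ndarray:
    """Boolean stroke mask of one figure (shaft plus fins)."""
    mask = np.zeros(shape, dtype=bool)
    for p0, p1 in figure_segments(fig):
        mask |= _segment_mask(p0, p1, shape)
    return mask


def render_stimulus(spec: StimulusSpec) -> np.ndarray:
    """Rasterize a trial: uint8 image, white (255) background, black (0) strokes."""
    strokes = render_figure(spec.top) | render_figure(spec.bottom)
    img = np.full((IMAGE_SIZE, IMAGE_SIZE), 255, dtype=np.uint8)
    img[strokes] = 0
    return img


def _self_intersects(fig: FigureSpec) -> bool:
    """True iff two centre-line strokes of one figure meet away from a shared endpoint."""
    segs = figure_segments(fig)
    lines = [LineString(s) for s in segs]
    for i in range(len(segs)):
        for j in range(i + 1, len(segs)):
            inter = lines[i].intersection(lines[j])
            if inter.is_empty:
                continue
            shared = [Point(p) for p in segs[i] for q in segs[j]
                      if abs(p[0] - q[0]) < 1e-9 and abs(p[1] - q[1]) < 1e-9]
            if (isinstance(inter, Point) and shared
                    and any(inter.distance(s) < 1e-9 for s in shared)):
                continue
            return True
    return False


def figures_overlap(spec: StimulusSpec) -> bool:
    """Exclusion rule: top/bottom strokes coincide or are 8-adjacent, or a
    figure's own strokes intersect away from their shared endpoint."""
    top = render_figure(spec.top)
    bottom = render_figure(spec.bottom)
    if np.any(ndimage.binary_dilation(top, structure=np.ones((3, 3), bool)) & bottom):
        return True
    return _self_intersects(spec.top) or _self_intersects(spec.bottom)


def stimulus_in_bounds(spec: StimulusSpec, margin: int = BORDER_MARGIN) -> bool:
    """True iff no stroke pixel of either figure falls within ``margin`` px of the border."""
    lo, hi = np.inf, -np.inf
    lo_v, hi_v = np.inf, -np.inf
    for fig in (spec.top, spec.bottom):
        for (p, q) in figure_segments(fig):
            lo = min(lo, p[0], q[0]); hi = max(hi, p[0], q[0])
            lo_v = min(lo_v, p[1], q[1]); hi_v = max(hi_v, p[1], q[1])
    # pixels extend one unit around the continuum coordinates (2x2 stamps)
    return (math.ceil(lo - 1) >= margin and math.floor(hi + 1) <= IMAGE_SIZE - 1 - margin
            and math.ceil(lo_v - 1) >= margin and math.floor(hi_v + 1) <= IMAGE_SIZE - 1 - margin)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _check_delta(set_kind: str, delta) -> None:
    if delta == "random":
        if set_kind in ("ml20", "ml40"):
            raise ValueError(f"{set_kind} requires an explicit test delta from {TEST_DELTAS}")
        return
    mag = abs(int(delta))
    if set_kind == "train_cross":
        if not (TRAIN_DELTA_RANGE[0] <= mag <= TRAIN_DELTA_RANGE[1]):
            raise ValueError(f"training |delta| must lie in {TRAIN_DELTA_RANGE}, got {delta}")
    elif set_kind == "ctl":
        if mag not in TEST_DELTAS and not (TRAIN_DELTA_RANGE[0] <= mag <= TRAIN_DELTA_RANGE[1]):
            raise ValueError(f"ctl |delta| must lie in {TRAIN_DELTA_RANGE} or {TEST_DELTAS}")
    else:
        if mag not in TEST_DELTAS:
            raise ValueError(f"{set_kind} |delta| must be one of {TEST_DELTAS}, got {delta}")


def sample_stimulus_spec(rng: np.random.Generator, set_kind: str, category: str,
                         delta="random", jitter_mode: str = "HV",
                         seed: int | None = None) -> StimulusSpec:
    """Draw one stimulus spec; all randomized fields are independent uniform integers.

    ``delta`` is either ``"random"`` (magnitude uniform over the training
    range) or a signed-magnitude test increment; its sign is forced to match
    ``category``.  No overlap/bounds rejection is applied here (see
    :func:`generate_set`).
    """
    if set_kind not in SET_KINDS:
        raise ValueError(f"unknown set_kind {set_kind!r}")
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    if jitter_mode not in JITTER_MODES:
        raise ValueError(f"unknown jitter_mode {jitter_mode!r}")
    _check_delta(set_kind, delta)

    if delta == "random":
        mag = int(rng.integers(TRAIN_DELTA_RANGE[0], TRAIN_DELTA_RANGE[1] + 1))
    else:
        mag = abs(int(delta))
    signed = mag if category == "long" else -mag

    longer = int(rng.integers(SHAFT_RANGE[0], SHAFT_RANGE[1] + 1))
    top_len = longer if category == "long" else longer - mag
    bot_len = longer - mag if category == "long" else longer

    if set_kind == "train_cross":
        a0, a1 = FIN_ANGLE_RANGES["train_cross"]
        angle_top = float(rng.integers(a0, a1 + 1))
        angle_bot = float(rng.integers(a0, a1 + 1))
        style_top = style_bot = "cross"
    elif set_kind == "ctl":
        a0, a1 = FIN_ANGLE_RANGES["ctl"]
        angle_top = angle_bot = float(rng.integers(a0, a1 + 1))  # shared angle
        style_top, style_bot = "arrow_left", "arrow_right"
    else:
        angle_top = angle_bot = float(ML_ANGLES[set_kind])
        style_top, style_bot = "arrowtail", "arrowhead"

    fl_top = int(rng.integers(FIN_LENGTH_RANGE[0], FIN_LENGTH_RANGE[1] + 1))
    fl_bot = int(rng.integers(FIN_LENGTH_RANGE[0], FIN_LENGTH_RANGE[1] + 1))

    bands = Y_BANDS[jitter_mode]
    y_top = int(rng.integers(bands["top"][0], bands["top"][1] + 1))
    y_bot = int(rng.integers(bands["bottom"][0], bands["bottom"][1] + 1))
    if jitter_mode == "HV":
        x_top = int(rng.integers(X_OFFSET_RANGE[0], X_OFFSET_RANGE[1] + 1))
        x_bot = int(rng.integers(X_OFFSET_RANGE[0], X_OFFSET_RANGE[1] + 1))
    else:
        x_top = x_bot = 0

    top = FigureSpec("top", top_len, style_top, angle_top, fl_top, y_top, x_top)
    bottom = FigureSpec("bottom", bot_len, style_bot, angle_bot, fl_bot, y_bot, x_bot)
    return StimulusSpec(top, bottom, category, signed, set_kind, jitter_mode, seed)


# ---------------------------------------------------------------------------
# set generation
# ---------------------------------------------------------------------------

@dataclass
class StimulusSet:
    """Generated stimulus set: manifest, in-memory rasters and the config used."""

    manifest: pd.DataFrame
    images: list  # uint8 rasters, row-aligned with the manifest
    specs: list  # StimulusSpec, row-aligned
    config: dict

    def write(self, out_dir) -> Path:
        """Write PNGs, manifest.csv and a JSON config snapshot to ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for fname, img in zip(self.manifest["filename"], self.images):
            Image.fromarray(img, mode="L").save(out / fname)
        self.manifest.to_csv(out / "manifest.csv", index=False)
        (out / "config.json").write_text(json.dumps(self.config, indent=2))
        return out


def _manifest_row(fname: str, spec: StimulusSpec) -> dict:
    row = {"filename": fname, "set_kind": spec.set_kind, "jitter_mode": spec.jitter_mode,
           "category": spec.category, "delta": spec.delta, "seed": spec.seed}
    for fig in (spec.top, spec.bottom):
        for k, v in asdict(fig).items():
            if k != "role":
                row[f"{fig.role}_{k}"] = v
    return row


def generate_set(set_kind: str, jitter_mode: str, seed: int, *,
                 n_per_category: int | None = None,
                 deltas=None, n_per_condition: int | None = None,
                 out_dir=None, max_attempts_factor: int = 100) -> StimulusSet:
    """Rejection-sample a full stimulus set.

    Either ``n_per_category`` (random deltas; training / CTL
    parameterization) or ``deltas`` plus ``n_per_condition`` (per-increment
    test sets) must be given.  Specs failing the overlap-exclusion rule or
    the 2-px border margin are discarded and redrawn.  Deterministic for a
    fixed seed.
    """
    if (n_per_category is None) == (deltas is None):
        raise ValueError("give exactly one of n_per_category or (deltas, n_per_condition)")
    if deltas is not None and not n_per_condition:
        raise ValueError("n_per_condition required with deltas")

    conditions: list[tuple[str, object, int]] = []
    if n_per_category is not None:
        if n_per_category <= 0:
            raise ValueError("n_per_category must be positive")
        conditions = [(cat, "random", n_per_category) for cat in CATEGORIES]
    else:
        for d in deltas:
            for cat in CATEGORIES:
                conditions.append((cat, int(d), n_per_condition))

    rng = np.random.default_rng(seed)
    rows, images, specs = [], [], []
    idx = 0
    for cat, d, n in conditions:
        _check_delta(set_kind, d)
        accepted, attempts = 0, 0
        limit = max(1000, max_attempts_factor * n)
        while accepted < n:
            attempts += 1
            if attempts > limit and accepted / attempts < 0.01:
                raise RuntimeError(
                    f"rejection rate above 99% for {set_kind}/{jitter_mode} "
                    f"category={cat} delta={d}; parameters leave almost no drawable specs")
            spec = sample_stimulus_spec(rng, set_kind, cat, d, jitter_mode, seed=seed)
            if not stimulus_in_bounds(spec) or figures_overlap(spec):
                continue
            fname = f"{set_kind}_{jitter_mode}_{idx:05d}.png"
            rows.append(_manifest_row(fname, spec))
            images.append(render_stimulus(spec))
            specs.append(spec)
            accepted += 1
            idx += 1

    manifest = pd.DataFrame(rows)
    config = {"set_kind": set_kind, "jitter_mode": jitter_mode, "seed": seed,
              "n_per_category": n_per_category,
              "deltas": list(map(int, deltas)) if deltas is not None else None,
              "n_per_condition": n_per_condition, "n_images": len(images)}
    sset = StimulusSet(manifest, images, specs, config)
    if out_dir is not None:
        sset.write(out_dir)
    return sset
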