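"""Seeded generators for synthetic benchmark data.

Three generators cover the inputs the evaluation harness needs:

* :func:`gen_digits` — 28x28 grayscale handwritten-digit-like images
  rendered from hand-coded stroke templates with random affine jitter
  and pixel noise. The images are flattened to 784-feature "expression"
  profiles whose pixels are highly correlated within strokes, which is
  the structural property (correlated features, simple class signal)
  that makes reference-based imputation work.
* :func:`gen_mvn` — correlated multivariate-normal data with
  block-diagonal correlation structure and optional class mean shifts,
  the controlled stand-in for inter-correlated expression panels.
* :func:`apply_missingness` — per-sample uniform-at-random masks with
  an exact per-sample count of missing dimensions.

All generators are bit-reproducible from their (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError, NoKnownValuesError
from .types import ExpressionMatrix, MaskedProfile

IMG_SIDE = 28
N_PIXELS = IMG_SIDE * IMG_SIDE


@dataclass
class MissingnessSpec:
    """Uniform missingness at a fixed per-sample fraction.

    Each sample independently receives a mask of exactly
    ``round(fraction * p)`` missing dimensions (round half away from
    zero), drawn uniformly without replacement.
    """

    fraction: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction < 1.0):
            raise InvalidInputError("fraction must lie in [0, 1)")

    def n_missing(self, p: int) -> int:
        # round half away from zero, documented for reproducibility
        return int(np.floor(self.fraction * p + 0.5))


# ---------------------------------------------------------------------------
# digit templates
# ---------------------------------------------------------------------------

def _ellipse(cx, cy, rx, ry, t0=0.0, t1=2 * np.pi, n=120):
    t = np.linspace(t0, t1, n)
    return np.column_stack([cx + rx * np.cos(t), cy + ry * np.sin(t)])


def _polyline(points, n_per_seg=40):
    pts = []
    for (x0, y0), (x1, y1) in zip(points[:-1], points[1:]):
        t = np.linspace(0.0, 1.0, n_per_seg)
        pts.append(np.column_stack([x0 + (x1 - x0) * t, y0 + (y1 - y0) * t]))
    return np.concatenate(pts)


#: glyphs are drawn on a nominal 20x20 box and scaled up about the image
#: centre so the strokes fill the 28x28 frame, as rendered digit sets do
_GLYPH_SCALE = 1.25


def _strokes(digit: int) -> np.ndarray:
    """Stroke sample points (x, y) for one digit, in 28x28 coordinates
    (x = column, y = row, y increasing downward)."""
    pts = _glyph(digit)
    return (pts - 13.5) * _GLYPH_SCALE + 13.5


def _glyph(digit: int) -> np.ndarray:
    if digit == 0:
        return _ellipse(14, 14, 6.5, 9)
    if digit == 1:
        # dominant near-vertical bar with a short head serif
        return np.concatenate([
            _polyline([(14, 4), (14, 23)], n_per_seg=120),
            _polyline([(11, 7), (14, 4)], n_per_seg=20),
        ])
    if digit == 2:
        return np.concatenate([
            _ellipse(13, 8, 6, 4.5, t0=np.pi, t1=2 * np.pi + 0.5),
            _polyline([(18.5, 11), (7, 22)]),
            _polyline([(7, 22), (21, 22)], n_per_seg=60),
        ])
    if digit == 3:
        return np.concatenate([
            _ellipse(14, 9, 5.5, 4.5, t0=-0.8 * np.pi, t1=0.55 * np.pi),
            _ellipse(14, 18.5, 6, 4.8, t0=-0.55 * np.pi, t1=0.8 * np.pi),
        ])
    if digit == 4:
        return np.concatenate([
            _polyline([(16, 4), (6, 16)]),
            _polyline([(6, 16), (22, 16)], n_per_seg=60),
            _polyline([(17, 4), (17, 24)], n_per_seg=100),
        ])
    if digit == 5:
        return np.concatenate([
            _polyline([(20, 4), (7, 4)], n_per_seg=60),
            _polyline([(7, 4), (7, 12)], n_per_seg=40),
            _polyline([(7, 12), (14, 12)], n_per_seg=30),
            _ellipse(14, 17.5, 5, 5.5, t0=-0.5 * np.pi, t1=0.6 * np.pi),
        ])
    if digit == 6:
        return np.concatenate([
            _ellipse(13.5, 18, 5.5, 5.5),
            _polyline([(9.5, 14), (15, 3)], n_per_seg=80),
        ])
    if digit == 7:
        return np.concatenate([
            _polyline([(7, 4), (21, 4)], n_per_seg=60),
            _polyline([(21, 4), (10, 24)], n_per_seg=100),
        ])
    if digit == 8:
        return np.concatenate([
            _ellipse(14, 8, 5.2, 4.2),
            _ellipse(14, 19, 5.8, 5),
        ])
    if digit == 9:
        return np.concatenate([
            _ellipse(13.5, 9.5, 5.5, 5),
            _polyline([(19, 9.5), (18, 24)], n_per_seg=80),
        ])
    raise InvalidInputError(f"invalid digit class {digit}; must be 0..9")


def _render(pts: np.ndarray, thickness: float) -> np.ndarray:
    """Rasterise stroke sample points onto the 28x28 grid.

    Pixel intensity falls off as a Gaussian of the distance to the
    nearest stroke point, giving anti-aliased strokes of roughly
    2*thickness pixel width.
    """
    yy, xx = np.mgrid[0:IMG_SIDE, 0:IMG_SIDE]
    img = np.zeros((IMG_SIDE, IMG_SIDE))
    # accumulate by max over stroke points; chunked for memory locality
    for start in range(0, len(pts), 64):
        chunk = pts[start : start + 64]
        d2 = (xx[..., None] - chunk[:, 0]) ** 2 + (yy[..., None] - chunk[:, 1]) ** 2
        img = np.maximum(img, np.exp(-d2 / (2.0 * thickness**2)).max(axis=-1))
    return img


def digit_template(digit: int, thickness: float = 2.4) -> np.ndarray:
    """Render the raw (undeformed) 28x28 template for one digit,
    pixel values in [0, 1]."""
    return _render(_strokes(digit), thickness)


def _jitter(img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random affine jitter: rotation <= 15 deg, translation <= 2 px,
    scale within +/-10%, about the image centre."""
    angle = np.deg2rad(rng.uniform(-15.0, 15.0))
    scale = rng.uniform(0.9, 1.1)
    tx, ty = rng.uniform(-2.0, 2.0, size=2)
    c, s = np.cos(angle), np.sin(angle)
    # inverse map (output -> input) for affine_transform
    M = np.array([[c, -s], [s, c]]) / scale
    centre = np.array([(IMG_SIDE - 1) / 2.0, (IMG_SIDE - 1) / 2.0])
    offset = centre - M @ (centre + np.array([ty, tx]))
    out = ndimage.affine_transform(img, M, offset=offset, order=1, mode="constant")
    # mild smoothing: bold anti-aliased strokes with spatially correlated
    # pixels, as in rendered printed-digit image sets
    return ndimage.gaussian_filter(out, 0.8)


def gen_digits(
    n_per_class: int,
    classes: list[int] | tuple[int, ...] = tuple(range(10)),
    noise_sd: float = 0.15,
    seed: int = 0,
    jitter: bool = True,
) -> ExpressionMatrix:
    """Generate stroke-rendered handwritten-digit-like images.

    Returns an :class:`ExpressionMatrix` of shape
    ``(n_per_class * len(classes), 784)`` with pixel values in [0, 1],
    labels set to the digit class, flattened row-major. Each sample is
    the class template under random affine jitter plus Gaussian pixel
    noise, clipped to [0, 1]. With ``jitter=False`` and ``noise_sd=0``
    each image is the raw class template.
    """
    classes = list(classes)
    if n_per_class < 1:
        raise InvalidInputError("n_per_class must be >= 1")
    for c in classes:
        if c not in range(10):
            raise InvalidInputError(f"invalid digit class {c}")
    rng = np.random.default_rng(seed)
    templates = {c: digit_template(c) for c in classes}
    rows, labels, ids = [], [], []
    for c in classes:
        for i in range(n_per_class):
            img = templates[c]
            if jitter:
                img = _jitter(img, rng)
            if noise_sd > 0:
                img = img + rng.normal(0.0, noise_sd, size=img.shape)
            rows.append(np.clip(img, 0.0, 1.0).ravel())
            labels.append(c)
            ids.append(f"digit{c}_{i}")
    feature_ids = [f"px_{r}_{col}" for r in range(IMG_SIDE) for col in range(IMG_SIDE)]
    return ExpressionMatrix(
        values=np.array(rows),
        sample_ids=ids,
        feature_ids=feature_ids,
        labels=np.array(labels),
    )


# ---------------------------------------------------------------------------
# correlated multivariate normal
# ---------------------------------------------------------------------------

def gen_mvn(
    n: int,
    p: int = 200,
    block_size: int = 20,
    within_block_corr: float = 0.8,
    seed: int = 0,
    n_classes: int = 2,
    class_shift: float = 1.0,
) -> ExpressionMatrix:
    """Correlated multivariate-normal "expression" data.

    Features have block-diagonal correlation: blocks of ``block_size``
    features with pairwise correlation ``within_block_corr``. Samples
    are split evenly over ``n_classes`` classes; class ``c`` receives a
    mean shift of ``class_shift`` on its own contiguous feature subset
    before columns are standardised to zero mean and unit variance over
    the generated sample.
    """
    if not (0.0 <= within_block_corr < 1.0):
        raise InvalidInputError("within_block_corr must lie in [0, 1)")
    if p % block_size != 0:
        raise InvalidInputError("block_size must divide p")
    rng = np.random.default_rng(seed)
    n_blocks = p // block_size
    rho = within_block_corr
    # equicorrelated block: x = sqrt(rho)*z_block + sqrt(1-rho)*eps
    z = rng.standard_normal((n, n_blocks))
    eps = rng.standard_normal((n, p))
    X = np.sqrt(rho) * np.repeat(z, block_size, axis=1) + np.sqrt(1.0 - rho) * eps

    labels = np.arange(n) % n_classes
    if n_classes > 1 and class_shift != 0.0:
        sub = max(1, p // n_classes)
        for c in range(n_classes):
            cols = slice(c * sub, min((c + 1) * sub, p))
            X[labels == c, cols] += class_shift

    sd = X.std(axis=0)
    sd[sd == 0.0] = 1.0  # degenerate at n = 1 or constant columns
    X = (X - X.mean(axis=0)) / sd
    return ExpressionMatrix(
        values=X,
        sample_ids=[f"s{i}" for i in range(n)],
        feature_ids=[f"f{j}" for j in range(p)],
        labels=labels,
    )


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

def apply_missingness(
    X: ExpressionMatrix, spec: MissingnessSpec
) -> tuple[list[MaskedProfile], ExpressionMatrix]:
    """Mask each sample of ``X`` independently and uniformly at random.

    Every sample receives exactly ``spec.n_missing(p)`` missing
    dimensions drawn without replacement. Returns the masked profiles
    and the untouched truth matrix for error computation.
    """
    p = X.n_features
    m = spec.n_missing(p)
    if m >= p:
        raise NoKnownValuesError("missing fraction leaves zero known entries")
    rng = np.random.default_rng(spec.seed)
    profiles = []
    for i in range(X.n_samples):
        mask = np.zeros(p, dtype=bool)
        if m > 0:
            mask[rng.choice(p, size=m, replace=False)] = True
        profiles.append(
            MaskedProfile(values=X.values[i].copy(), mask=mask, sample_id=X.sample_ids[i])
        )
    return profiles, X
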