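"""Synthetic phantoms with known ground truth, and overlap/SNR metrics.

The tissue phantom emulates simulator-style brain images: piecewise-constant
tissue classes (CSF-like, gray-matter-like, white-matter-like) arranged as
nested regions, corrupted by additive Gaussian noise (std expressed as a
percentage of the brightest class mean) and a smooth multiplicative bias
("migration"/offset) field whose peak-to-peak amplitude is a percentage:
a 40% field spans [0.8, 1.2].  Segmentations are scored with the average
overlap metric AOM = 2|Vm n Va| / (|Vm| + |Va|), identical to the Dice
coefficient, and filters with SNR = 10 log10(Ps/Pn) in dB.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .errors import InvalidParameterError, ShapeMismatchError

log = logging.getLogger(__name__)


@dataclass
class PhantomSpec:
    """Recipe for a synthetic image with known ground truth.

    ``noise_percent`` is the Gaussian noise std as a percentage of the
    brightest class mean; ``bias_percent`` the peak-to-peak amplitude of the
    multiplicative bias field (40 -> field in [0.8, 1.2]).
    """

    shape: tuple = (128, 128)
    class_means: tuple = (10.0, 50.0, 120.0, 200.0)  # background + 3 tissues
    noise_percent: float = 0.0
    bias_percent: float = 0.0
    seed: int = 0
    # nested-region geometry: fractional radii of the tissue boundaries,
    # outermost first (tissue k occupies radii (r_{k+1}, r_k])
    radii_frac: tuple = (0.42, 0.30, 0.19)

    def __post_init__(self):
        if self.noise_percent < 0 or self.bias_percent < 0:
            raise InvalidParameterError("noise and bias percentages must be >= 0")
        if len(set(self.class_means)) != len(self.class_means):
            raise InvalidParameterError("class means must be distinct")


# ---------------------------------------------------------------- metrics


def aom(truth, predicted):
    """Average overlap metric between two voxel sets on the same grid.

    ``2 |Vm n Va| / (|Vm| + |Va|)`` — the Dice coefficient.  Two empty sets
    agree vacuously and score 1.
    """
    t = np.asarray(truth, dtype=bool)
    p = np.asarray(predicted, dtype=bool)
    if t.shape != p.shape:
        raise ShapeMismatchError(f"grids differ: {t.shape} vs {p.shape}")
    denom = int(t.sum()) + int(p.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((t & p).sum()) / denom


def aom_overall(per_class) -> float:
    """Overall score: arithmetic mean of per-class AOMs, rounded half-up to 2 dp."""
    values = list(per_class)
    if not values:
        raise InvalidParameterError("aom_overall needs at least one per-class value")
    mean = sum(values) / len(values)
    return float(Decimal(repr(mean)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def snr(signal, noisy) -> float:
    """Signal-to-noise ratio in dB: 10 log10(Ps / Pn), P = mean of squares.

    ``noise = noisy - signal``; zero noise power returns +inf with a warning.
    """
    s = np.asarray(signal, dtype=float)
    n = np.asarray(noisy, dtype=float)
    if s.shape != n.shape:
        raise ShapeMismatchError(f"grids differ: {s.shape} vs {n.shape}")
    p_s = float(np.mean(s**2))
    p_n = float(np.mean((n - s) ** 2))
    if p_n == 0.0:
        log.warning("snr: zero noise power, returning +inf")
        return float("inf")
    return 10.0 * np.log10(p_s / p_n)


# ---------------------------------------------------------------- phantoms


def _bias_field(shape, bias_percent):
    """Smooth multiplicative field rescaled to span exactly 1 +/- p/200."""
    ny, nx = shape[-2], shape[-1]
    yy, xx = np.meshgrid(np.linspace(-1, 1, ny), np.linspace(-1, 1, nx), indexing="ij")
    # low-order polynomial: a tilted plane with a mild saddle
    raw = xx + 0.6 * yy + 0.35 * xx * yy
    lo, hi = raw.min(), raw.max()
    amp = bias_percent / 200.0
    return 1.0 - amp + (raw - lo) / (hi - lo) * 2 * amp


def make_disk_phantom(
    shape=(128, 128),
    radius=30.0,
    fg=200.0,
    bg=50.0,
    noise_percent=0.0,
    seed=0,
    center=None,
):
    """Disk on a uniform background, with optional Gaussian noise.

    Returns ``(image, mask)`` where mask is the exact ground-truth disk.
    """
    ny, nx = shape
    if center is None:
        center = ((ny - 1) / 2.0, (nx - 1) / 2.0)
    cy, cx = center
    if radius > min(ny, nx) / 2.0:
        raise InvalidParameterError("disk radius exceeds the image half-extent")
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    img = np.where(mask, float(fg), float(bg))
    if noise_percent > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_percent / 100.0 * max(fg, bg), size=img.shape)
    return img, mask.astype(np.uint8)


def make_tissue_phantom(spec: PhantomSpec):
    """Nested-region tissue phantom with noise and bias field.

    Geometry: concentric ellipses (slightly eccentric so the bias field is
    not aligned with any symmetry axis).  Labels: 0 background, then 1..k
    from the outermost (darkest) tissue inward to the brightest.  The clean
    image is ``means[label] * bias``; Gaussian noise with
    ``std = noise_percent/100 * max(means)`` is added on top.

    Returns ``(image, labels)``.
    """
    if len(spec.class_means) < 2:
        raise InvalidParameterError("need a background mean and at least one tissue class")
    if len(spec.radii_frac) != len(spec.class_means) - 1:
        raise InvalidParameterError("radii_frac must give one boundary per tissue class")
    ny, nx = spec.shape[-2], spec.shape[-1]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    # mild ellipticity: y-semiaxis 10% longer than x
    r = np.sqrt(((yy - cy) / 1.1) ** 2 + (xx - cx) ** 2) / min(ny, nx)
    labels = np.zeros((ny, nx), dtype=np.uint8)
    for k, rf in enumerate(spec.radii_frac, start=1):
        labels[r <= rf] = k
    means = np.asarray(spec.class_means, dtype=float)
    clean = means[labels]
    if spec.bias_percent > 0:
        clean = clean * _bias_field((ny, nx), spec.bias_percent)
    img = clean
    if spec.noise_percent > 0:
        rng = np.random.default_rng(spec.seed)
        std = spec.noise_percent / 100.0 * means.max()
        img = img + rng.normal(0.0, std, size=clean.shape)
    return img, labels


def make_volume_fixtures(name: str, n_interior: int = 0, seed: int = 0):
    """Point sets + boundary triangulations with known enclosed volume.

    ``name``: ``cube`` (unit cube, volume 1), ``Lprism`` (unit cube minus a
    1/2 x 1/2 x 1 corner prism, volume 0.75), or ``icosphere`` (subdivided
    icosahedron of radius 1; volume = its own polyhedral volume).  Optional
    interior points are drawn uniformly inside the solid.

    Returns ``(points, constraints, volume)`` where ``constraints`` is a
    :class:`~medsegmesh.tetmesh.ConstraintSet`.
    """
    from .tetmesh import ConstraintSet  # deferred: avoid import cycle

    rng = np.random.default_rng(seed)
    if name == "cube":
        pts = np.array(
            [[x, y, z] for z in (0.0, 1.0) for y in (0.0, 1.0) for x in (0.0, 1.0)]
        )
        quads = [
            (0, 1, 3, 2),  # z=0 (viewed from below)
            (4, 6, 7, 5),  # z=1
            (0, 4, 5, 1),  # y=0
            (2, 3, 7, 6),  # y=1
            (0, 2, 6, 4),  # x=0
            (1, 5, 7, 3),  # x=1
        ]
        faces = [t for q in quads for t in ((q[0], q[1], q[2]), (q[0], q[2], q[3]))]
        volume = 1.0
        inside = lambda p: True  # noqa: E731 - whole cube
    elif name == "Lprism":
        # L cross-section in (x, y): unit square minus the [1/2,1]x[1/2,1] corner
        poly = [(0, 0), (1, 0), (1, 0.5), (0.5, 0.5), (0.5, 1), (0, 1)]
        nv = len(poly)
        pts = np.array([[x, y, z] for z in (0.0, 1.0) for (x, y) in poly])
        faces = []
        # bottom (z=0, outward normal -z) and top (z=1, +z): fan-triangulate
        # the L by splitting into two rectangles [0,1]x[0,1/2] and [0,1/2]x[1/2,1]
        bot = [(0, 2, 1), (0, 3, 2), (0, 4, 3), (0, 5, 4)]
        faces += bot
        faces += [(a + nv, c + nv, b + nv) for (a, c, b) in bot]  # top, flipped
        for i in range(nv):  # side quads
            j = (i + 1) % nv
            faces += [(i, j, j + nv), (i, j + nv, i + nv)]
        volume = 0.75
        inside = lambda p: not (p[0] > 0.5 and p[1] > 0.5)  # noqa: E731
    elif name == "icosphere":
        import trimesh

        mesh = trimesh.creation.icosphere(subdivisions=2, radius=1.0)
        pts = np.asarray(mesh.vertices, dtype=float)
        faces = [tuple(int(i) for i in f) for f in mesh.faces]
        volume = float(mesh.volume)  # divergence-theorem volume of the polyhedron
        rad2 = 0.98  # stay safely inside the polyhedral surface
        inside = lambda p: np.dot(p - 0.0, p - 0.0) < rad2**2 * 0.9  # noqa: E731
    else:
        raise InvalidParameterError(f"unknown fixture {name!r}")

    interior = []
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    while len(interior) < n_interior:
        p = rng.uniform(lo + 0.1 * (hi - lo), hi - 0.1 * (hi - lo))
        if inside(p):
            interior.append(p)
    if interior:
        pts = np.vstack([pts, interior])
    edges = sorted({tuple(sorted((f[i], f[(i + 1) % 3]))) for f in faces for i in range(3)})
    return pts, ConstraintSet(edges=edges, faces=faces), volume


# ---------------------------------------------------------------- evaluation


def match_labels(truth, predicted):
    """Greedy best-overlap mapping from predicted labels to truth labels.

    Returns a dict ``{predicted_label: truth_label}`` covering the predicted
    foreground labels; pairs are claimed in decreasing overlap order, each
    label used at most once.
    """
    t = np.asarray(truth)
    p = np.asarray(predicted)
    if t.shape != p.shape:
        raise ShapeMismatchError(f"grids differ: {t.shape} vs {p.shape}")
    t_labels = [int(v) for v in np.unique(t)]
    p_labels = [int(v) for v in np.unique(p)]
    overlaps = []
    for pl in p_labels:
        pm = p == pl
        for tl in t_labels:
            overlaps.append((int((pm & (t == tl)).sum()), pl, tl))
    overlaps.sort(key=lambda o: (-o[0], o[1], o[2]))
    mapping, used_t = {}, set()
    for cnt, pl, tl in overlaps:
        if pl in mapping or tl in used_t:
            continue
        mapping[pl] = tl
        used_t.add(tl)
    return mapping


@dataclass
class EvaluationReport:
    """Per-class AOM table plus the rounded overall score."""

    per_class: dict = field(default_factory=dict)  # truth label -> AOM
    overall: float = 0.0

    def to_csv(self) -> str:
        lines = ["class,aom"]
        lines += [f"{k},{v:.6f}" for k, v in sorted(self.per_class.items())]
        lines.append(f"overall,{self.overall:.2f}")
        return "\n".join(lines) + "\n"


def evaluate_run(truth, predicted, include_background: bool = False) -> EvaluationReport:
    """Score a predicted label mask against ground truth.

    Predicted labels are matched to truth labels by greedy best overlap;
    each truth class (background excluded by default) is scored with
    :func:`aom` and the overall value is their :func:`aom_overall` mean.
    """
    t = np.asarray(truth)
    p = np.asarray(predicted)
    mapping = match_labels(t, p)
    inverse = {tl: pl for pl, tl in mapping.items()}
    per_class = {}
    for tl in (int(v) for v in np.unique(t)):
        if tl == 0 and not include_background:
            continue
        pl = inverse.get(tl)
        per_class[tl] = aom(t == tl, p == pl) if pl is not None else 0.0
    return EvaluationReport(per_class=per_class, overall=aom_overall(per_class.values()))
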