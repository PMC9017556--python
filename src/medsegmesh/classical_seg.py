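"""Non-level-set segmenters: ant-colony pixel clustering, seeded region
growing, and intensity-clustering baselines (k-means, FCM, KFCM).

The ant-colony (ACO) segmenter treats every pixel as an ant carrying a
3-component feature (gray value V, gradient magnitude G, 8-neighborhood
mean Ne).  Pixels are assigned to cluster centers with a pheromone/heuristic
transition rule; pheromone on the pixel->cluster links decays each cycle and
is reinforced by the assignments, weighted by a pixel pheromone field that
ants deposit while performing inertial random walks over the image.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError, OutOfRangeError, ShapeMismatchError

#: 8-neighborhood displacement table, indexed by direction id
DIRECTIONS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]

#: inertial weighting of the turn angle between successive moves
DEFAULT_DIRECTION_WEIGHTS = {0: 1.0, 45: 0.5, 90: 0.25, 135: 0.1, 180: 0.05}


@dataclass
class AntFeature:
    """Per-pixel ant feature vector (V, G, Ne) and component weights P_k."""

    gray: float
    gradient: float
    neigh: float
    weights: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any() or not (w > 0).any():
            raise InvalidParameterError("feature weights must be >= 0 and not all zero")

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.gray, self.gradient, self.neigh], dtype=float)


@dataclass
class AcoParams:
    """Parameters of the ant-colony segmenter.

    ``alpha``/``beta`` are the pheromone and heuristic exponents of the
    assignment rule, ``rho`` the pheromone persistence per cycle,
    ``b_radius`` the clustering radius, ``delta`` the pheromone-sensitivity
    parameter (1/delta is the ants' sensitivity), ``n0``/``p_gain`` the
    constant and similarity-driven parts of the walk deposit, and
    ``sim_weights`` (a, b, c), summing to 1, the mean/std/histogram mix of
    the window-similarity measure.
    """

    alpha: float = 1.0
    beta: float = 2.0
    rho: float = 0.9
    b_radius: float = 1.0
    delta: float = 0.2
    n0: float = 0.1
    p_gain: float = 1.0
    sim_weights: tuple = (0.4, 0.3, 0.3)
    window: int = 1  # comparison-window half-size (1 -> 3x3)
    n_ants: int = 50
    n_iter: int = 30
    seed: int = 0
    walk_steps: int = 100
    feature_weights: tuple = (1.0, 1.0, 1.0)
    direction_weights: dict = field(default_factory=lambda: dict(DEFAULT_DIRECTION_WEIGHTS))

    def __post_init__(self):
        if not (0 < self.rho <= 1):
            raise InvalidParameterError("rho must lie in (0, 1]")
        if abs(sum(self.sim_weights) - 1.0) > 1e-9:
            raise InvalidParameterError("sim_weights (a, b, c) must sum to 1")
        if self.b_radius <= 0:
            raise InvalidParameterError("clustering radius must be positive")
        if self.n_ants < 1 or self.n_iter < 1:
            raise InvalidParameterError("n_ants and n_iter must be >= 1")


class PheromoneField:
    """Non-negative pheromone intensity sigma(r) on the pixel grid."""

    def __init__(self, shape):
        self.tau = np.zeros(shape, dtype=float)

    def deposit(self, pos, amount):
        if amount < 0:
            raise InvalidParameterError("pheromone deposits must be non-negative")
        self.tau[pos] += amount

    def evaporate(self, rho):
        self.tau *= rho


# ------------------------------------------------------------------ pieces


def feature_distance(fi, fj, weights=(1.0, 1.0, 1.0)) -> float:
    """Weighted Euclidean distance between feature vectors:
    ``sqrt(sum_k P_k (X_ik - X_jk)^2)``."""
    vi = fi.vector if isinstance(fi, AntFeature) else np.asarray(fi, dtype=float)
    vj = fj.vector if isinstance(fj, AntFeature) else np.asarray(fj, dtype=float)
    w = np.asarray(weights, dtype=float)
    return float(np.sqrt(np.sum(w * (vi - vj) ** 2)))


def neighborhood_indicator(dist: float, b_radius: float) -> int:
    """1 if the feature distance is within the clustering radius, else 0."""
    if dist < 0:
        raise InvalidParameterError("distance must be >= 0")
    return 1 if dist <= b_radius else 0


def guiding_value(fi, center, b_radius: float, weights=(1.0, 1.0, 1.0)) -> float:
    """Heuristic eta = b / d(feature, center); capped at b / 1e-9 as d -> 0."""
    d = feature_distance(fi, center, weights)
    return b_radius / max(d, 1e-9)


def cluster_transition_probability(tau_row, eta_row, alpha: float, beta: float) -> np.ndarray:
    """Assignment probabilities P_j = tau_j^a eta_j^b / sum_s tau_s^a eta_s^b.

    ``tau_row``/``eta_row`` are the pheromone and heuristic values of one
    pixel against each candidate center.  All-zero numerators fall back to
    the uniform distribution.
    """
    tau = np.asarray(tau_row, dtype=float)
    eta = np.asarray(eta_row, dtype=float)
    if tau.size == 0:
        raise InvalidParameterError("candidate set must be non-empty")
    num = tau**alpha * eta**beta
    tot = num.sum()
    if tot <= 0:
        return np.full(tau.shape, 1.0 / tau.size)
    return num / tot


def pheromone_update(tau_ij, rho: float, delta_sum) -> np.ndarray:
    """Cycle update: tau <- rho * tau + sum of this cycle's ant deposits."""
    return rho * np.asarray(tau_ij, dtype=float) + np.asarray(delta_sum, dtype=float)


def pheromone_weight(sigma_r, beta: float, delta: float):
    """Two-parameter weighting W(sigma) = (1 + sigma / (1 + delta sigma))^beta."""
    s = np.asarray(sigma_r, dtype=float)
    if (s < 0).any():
        raise InvalidParameterError("pheromone intensity must be >= 0")
    return (1.0 + s / (1.0 + delta * s)) ** beta


def _turn_angle(d_prev: int, d_new: int) -> int:
    """Turn angle in degrees between two 8-neighborhood direction ids."""
    ang = lambda d: np.degrees(np.arctan2(DIRECTIONS[d][0], DIRECTIONS[d][1]))  # noqa: E731
    diff = abs(ang(d_new) - ang(d_prev)) % 360
    return int(round(min(diff, 360 - diff)))


def motion_transition(
    pos, shape, sigma_field, params: AcoParams, prev_dir: int | None = None
) -> tuple[list, np.ndarray]:
    """Walk probabilities from ``pos`` to its in-bounds 8-neighbors.

    ``P_i ~ W(sigma_i) * w(turn angle)``, normalized; without a previous
    direction the inertia factor is uniform.  Returns
    ``(candidate directions, probabilities)``.
    """
    y, x = pos
    cands, weights = [], []
    for d, (dy, dx) in enumerate(DIRECTIONS):
        ny_, nx_ = y + dy, x + dx
        if not (0 <= ny_ < shape[0] and 0 <= nx_ < shape[1]):
            continue
        w_dir = 1.0 if prev_dir is None else params.direction_weights[_turn_angle(prev_dir, d)]
        w_ph = float(pheromone_weight(sigma_field[ny_, nx_], params.beta, params.delta))
        cands.append(d)
        weights.append(w_ph * w_dir)
    if not cands:
        raise InvalidParameterError("pixel has no in-bounds neighbors")
    w = np.asarray(weights)
    tot = w.sum()
    return cands, (w / tot if tot > 0 else np.full(w.shape, 1.0 / w.size))


def deposit_amount(delta_h: float, n0: float, p_gain: float) -> float:
    """Pheromone released on a move: T = n0 + p_gain * delta_h."""
    if delta_h < 0:
        raise InvalidParameterError("delta_h must be >= 0")
    return n0 + p_gain * delta_h


def window_similarity(raw_terms, maxima, sim_weights) -> float:
    """Combine raw window differences into delta_h in [0, 1].

    ``raw_terms = (|m1-m2|, |s1-s2|, S)`` for one window pair and ``maxima``
    the per-term maxima over all pairs evaluated in the current iteration;
    any 0/0 term contributes 0.  Weights (a, b, c) must sum to 1.
    """
    a, b, c = sim_weights
    out = 0.0
    for w, t, mx in zip((a, b, c), raw_terms, maxima):
        out += w * (t / mx if mx > 0 else 0.0)
    return out


def window_raw_terms(win1, win2, bins=8, value_range=(0.0, 255.0)):
    """Raw (un-normalized) similarity terms between two equal-shape windows:
    |mean difference|, |std difference|, and the L1 histogram distance."""
    w1 = np.asarray(win1, dtype=float)
    w2 = np.asarray(win2, dtype=float)
    if w1.shape != w2.shape:
        raise ShapeMismatchError(f"windows differ in shape: {w1.shape} vs {w2.shape}")
    h1, _ = np.histogram(w1, bins=bins, range=value_range)
    h2, _ = np.histogram(w2, bins=bins, range=value_range)
    return (
        abs(float(w1.mean()) - float(w2.mean())),
        abs(float(w1.std()) - float(w2.std())),
        float(np.abs(h1 - h2).sum()),
    )


# ------------------------------------------------------------------ features


def build_features(img, feature_weights=(1.0, 1.0, 1.0)):
    """Per-pixel (V, G, Ne) feature array of shape (ny, nx, 3).

    G is the Sobel gradient magnitude, Ne the 3x3 neighborhood mean.
    """
    img = np.asarray(img, dtype=float)
    # Sobel responses divided by 4 so a unit step yields a unit-scale gradient
    gy = ndimage.sobel(img, axis=0, mode="reflect") / 4.0
    gx = ndimage.sobel(img, axis=1, mode="reflect") / 4.0
    grad = np.sqrt(gx**2 + gy**2)
    neigh = ndimage.uniform_filter(img, size=3, mode="reflect")
    return np.stack([img, grad, neigh], axis=-1)


# ------------------------------------------------------------------ segmenters


def aco_segment(img, k: int, params: AcoParams | None = None):
    """Ant-colony clustering segmentation into ``k`` clusters.

    Pipeline: build per-pixel features; seed initial centers with k-means++;
    each cycle, ants walk the image depositing a pixel pheromone field
    (inertial moves weighted by the two-parameter pheromone function,
    deposits driven by window similarity between consecutive positions),
    pixels are assigned to centers by the pheromone/heuristic transition
    rule, link pheromone decays and is reinforced by the assignments scaled
    by the walked field, and centers are recomputed as feature means.
    Deterministic given ``params.seed``.  Returns the per-pixel label mask
    (labels 0..k-1 ordered by increasing center gray value).
    """
    from sklearn.cluster import kmeans_plusplus

    params = params or AcoParams()
    img = np.asarray(img, dtype=float)
    ny, nx = img.shape
    feats = build_features(img, params.feature_weights)
    flat = feats.reshape(-1, 3)
    if k > np.unique(flat, axis=0).shape[0]:
        raise InvalidParameterError("more clusters than distinct pixel features")
    rng = np.random.default_rng(params.seed)
    centers, _ = kmeans_plusplus(flat, n_clusters=k, random_state=params.seed)
    w = np.asarray(params.feature_weights, dtype=float)

    tau = np.ones((ny * nx, k))
    sigma_field = PheromoneField((ny, nx))
    pad = params.window
    padded = np.pad(img, pad, mode="reflect")
    vr = (float(img.min()), float(img.max()) if img.max() > img.min() else float(img.min()) + 1)

    def window_at(y, x):
        return padded[y : y + 2 * pad + 1, x : x + 2 * pad + 1]

    labels = None
    for _cycle in range(params.n_iter):
        # --- spatial walks deposit the pixel pheromone field
        sigma_field.evaporate(params.rho)
        visits, raws = [], []
        for _ in range(params.n_ants):
            y, x = rng.integers(0, ny), rng.integers(0, nx)
            prev_dir = None
            for _step in range(params.walk_steps):
                cands, probs = motion_transition(
                    (y, x), (ny, nx), sigma_field.tau, params, prev_dir
                )
                d = cands[rng.choice(len(cands), p=probs)]
                dy, dx = DIRECTIONS[d]
                ny_, nx_ = y + dy, x + dx
                raws.append(window_raw_terms(window_at(y, x), window_at(ny_, nx_), value_range=vr))
                visits.append((ny_, nx_))
                y, x, prev_dir = ny_, nx_, d
        if raws:
            maxima = tuple(np.max([r[i] for r in raws]) for i in range(3))
            for (vy, vx), raw in zip(visits, raws):
                dh = window_similarity(raw, maxima, params.sim_weights)
                sigma_field.deposit((vy, vx), deposit_amount(dh, params.n0, params.p_gain))

        # --- cluster assignment biased by link pheromone and heuristic
        d2 = np.sum(w * (flat[:, None, :] - centers[None, :, :]) ** 2, axis=-1)
        dist = np.sqrt(d2)
        eta = params.b_radius / np.maximum(dist, 1e-9)
        num = tau**params.alpha * eta**params.beta
        tot = num.sum(axis=1, keepdims=True)
        probs = np.where(tot > 0, num / np.maximum(tot, 1e-300), 1.0 / k)

        # --- pheromone reinforcement: expected ant traffic on each link,
        #     weighted by the walked field
        w_sigma = pheromone_weight(sigma_field.tau, params.beta, params.delta).ravel()
        delta_tau = probs * (w_sigma / params.n_ants)[:, None]
        tau = pheromone_update(tau, params.rho, delta_tau)

        # --- recompute centers as responsibility-weighted feature means
        mass = probs.sum(axis=0)
        for j in range(k):
            if mass[j] > 0:
                centers[j] = (probs[:, j][:, None] * flat).sum(axis=0) / mass[j]

    # final deterministic labeling: most probable cluster
    d2 = np.sum(w * (flat[:, None, :] - centers[None, :, :]) ** 2, axis=-1)
    eta = params.b_radius / np.maximum(np.sqrt(d2), 1e-9)
    labels = np.argmax(tau**params.alpha * eta**params.beta, axis=1)
    order = np.argsort(centers[:, 0])  # relabel by increasing gray value
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap[labels].reshape(ny, nx).astype(np.uint8)


def region_grow(img, seeds, tol: float):
    """Seeded region growing over 8-neighborhoods.

    Regions grow in seed order by BFS, admitting a pixel when its intensity
    differs from the current region mean by at most ``tol``; the mean is
    updated as the region grows.  Unreached pixels are labeled 0.
    """
    img = np.asarray(img, dtype=float)
    ny, nx = img.shape
    labels = np.zeros((ny, nx), dtype=np.int32)
    for idx, (sy, sx) in enumerate(seeds, start=1):
        if not (0 <= sy < ny and 0 <= sx < nx):
            raise OutOfRangeError(f"seed {(sy, sx)} outside image of shape {(ny, nx)}")
        if labels[sy, sx] != 0:
            continue
        labels[sy, sx] = idx
        total, count = float(img[sy, sx]), 1
        queue = deque([(sy, sx)])
        while queue:
            y, x = queue.popleft()
            mean = total / count
            for dy, dx in DIRECTIONS:
                yy, xx = y + dy, x + dx
                if 0 <= yy < ny and 0 <= xx < nx and labels[yy, xx] == 0:
                    if abs(img[yy, xx] - mean) <= tol:
                        labels[yy, xx] = idx
                        total += float(img[yy, xx])
                        count += 1
                        queue.append((yy, xx))
    return labels


# ------------------------------------------------------------------ baselines


def _fcm(x, k, m=2.0, seed=0, max_iter=150, tol=1e-5, kernel_bw=None):
    """Fuzzy c-means on feature rows ``x``; Gaussian-kernel variant when
    ``kernel_bw`` is given (KFCM).  Returns hard labels."""
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    # initialize centers at spread quantiles (deterministic), jittered memberships
    qs = np.linspace(0.05, 0.95, k)
    centers = np.quantile(x, qs, axis=0)
    u = rng.random((n, k)) + 1e-3
    u /= u.sum(axis=1, keepdims=True)
    for _ in range(max_iter):
        if kernel_bw is None:
            d2 = np.sum((x[:, None, :] - centers[None, :, :]) ** 2, axis=-1)
        else:
            d2 = 2.0 * (
                1.0
                - np.exp(
                    -np.sum((x[:, None, :] - centers[None, :, :]) ** 2, axis=-1)
                    / (2 * kernel_bw**2)
                )
            )
        d2 = np.maximum(d2, 1e-12)
        inv = d2 ** (-1.0 / (m - 1.0))
        new_u = inv / inv.sum(axis=1, keepdims=True)
        um = new_u**m
        if kernel_bw is None:
            centers = (um.T @ x) / um.sum(axis=0)[:, None]
        else:
            kmat = np.exp(
                -np.sum((x[:, None, :] - centers[None, :, :]) ** 2, axis=-1) / (2 * kernel_bw**2)
            )
            wgt = um * kmat
            centers = (wgt.T @ x) / np.maximum(wgt.sum(axis=0)[:, None], 1e-12)
        if np.abs(new_u - u).max() < tol:
            u = new_u
            break
        u = new_u
    return np.argmax(u, axis=1), centers


def baseline_segment(img, method: str, k: int, seed: int = 0):
    """Intensity-feature clustering with a named standard algorithm.

    ``method`` is ``kmeans``, ``fcm`` (fuzziness m = 2), or ``kfcm``
    (Gaussian kernel, bandwidth = intensity std).  Labels are ordered by
    increasing cluster center so outputs are comparable across methods;
    deterministic given ``seed``.
    """
    if k < 2:
        raise InvalidParameterError("k must be >= 2")
    img = np.asarray(img, dtype=float)
    x = img.reshape(-1, 1)
    if method == "kmeans":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x)
        labels, centers = km.labels_, km.cluster_centers_
    elif method == "fcm":
        labels, centers = _fcm(x, k, seed=seed)
    elif method == "kfcm":
        labels, centers = _fcm(x, k, seed=seed, kernel_bw=float(x.std()) or 1.0)
    else:
        raise InvalidParameterError(f"unknown method {method!r}")
    order = np.argsort(np.asarray(centers).ravel())
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap[labels].reshape(img.shape).astype(np.uint8)
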