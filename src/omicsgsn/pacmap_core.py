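"""From-scratch PaCMAP: pair construction, losses, and phased optimization.

PaCMAP (Pairwise Controlled Manifold Approximation) embeds high-dimensional
points into 2-D by minimizing a sum of per-pair losses over three pair
classes:

* **neighbor pairs** — each point's nearest neighbors under a locally
  scaled squared distance ``d2_select(i, j) = ||Xi - Xj||^2 / (sigma_i *
  sigma_j)``, where ``sigma_i`` is the mean Euclidean distance from ``i``
  to its 4th–6th nearest neighbors.  The scaled distance is used only for
  neighbor selection, never during optimization.
* **mid-near pairs** — per anchor, sample 6 distinct other points and keep
  the second-closest; these carry global structure.
* **further pairs** — uniformly sampled non-neighbors, repelled.

With ``dt(a, b) = ||ya - yb||^2 + 1`` in the embedding, the losses are

    loss_nb = dt / (10 + dt)        (attractive, bounded)
    loss_mn = dt / (10000 + dt)     (weakly attractive)
    loss_fp = 1 / (1 + dt)          (repulsive)

combined as ``w_nb * sum(loss_nb) + w_mn * sum(loss_mn) + w_fp *
sum(loss_fp)``.  Optimization runs three phases with a scheduled w_mn:
heavily weighted at first (global structure), small but nonzero in the
middle, zero at the end (local structure), using Adam-style
adaptive-moment gradient updates from a scaled PCA initialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist
from sklearn.decomposition import PCA

from .io_preprocess import ValidationError

MIN_POINTS = 7  # sigma needs 4th-6th nearest neighbors to exist


@dataclass
class ScaledDistanceCache:
    """Per-point local scale sigma and the scaled squared distance matrix."""

    sigma: np.ndarray                # (n,) positive
    scaled_sq_dist: np.ndarray       # (n, n) symmetric, zero diagonal
    sq_dist: np.ndarray              # (n, n) unscaled squared distances

    @property
    def n_points(self) -> int:
        return self.sigma.shape[0]


@dataclass
class PairSet:
    """Index pairs driving the embedding loss, one array per pair class."""

    neighbor_pairs: np.ndarray   # (m, 2) int
    midnear_pairs: np.ndarray    # (m, 2) int
    further_pairs: np.ndarray    # (m, 2) int

    @staticmethod
    def empty() -> "PairSet":
        e = np.empty((0, 2), dtype=int)
        return PairSet(e.copy(), e.copy(), e.copy())


@dataclass
class LossWeights:
    w_nb: float = 2.0
    w_mn: float = 3.0
    w_fp: float = 1.0

    def __post_init__(self) -> None:
        w = (self.w_nb, self.w_mn, self.w_fp)
        if any(x < 0 or not np.isfinite(x) for x in w):
            raise ValidationError("loss weights must be finite and nonnegative")
        if all(x == 0 for x in w):
            raise ValidationError("at least one loss weight must be positive")


@dataclass
class PhaseSchedule:
    """Iteration counts and mid-near weight trajectory for the three phases.

    Phase 1 anneals w_mn linearly from ``w_mn_init`` to ``w_mn_mid``
    (global structure first), phase 2 holds it at ``w_mn_mid`` and phase 3
    sets it to zero; w_nb and w_fp are constant throughout.
    """

    t1: int = 100
    t2: int = 100
    t3: int = 250
    w_nb: float = 2.0
    w_fp: float = 1.0
    w_mn_init: float = 1000.0
    w_mn_mid: float = 3.0

    def __post_init__(self) -> None:
        if min(self.t1, self.t2, self.t3) < 0:
            raise ValidationError("phase iteration counts must be nonnegative")

    @property
    def total_iters(self) -> int:
        return self.t1 + self.t2 + self.t3

    def weights_at(self, t: int) -> LossWeights:
        """Loss weights in force at 0-based iteration ``t``."""
        if t < self.t1:
            frac = t / max(self.t1 - 1, 1)
            w_mn = self.w_mn_init + frac * (self.w_mn_mid - self.w_mn_init)
        elif t < self.t1 + self.t2:
            w_mn = self.w_mn_mid
        else:
            w_mn = 0.0
        return LossWeights(w_nb=self.w_nb, w_mn=w_mn, w_fp=self.w_fp)


@dataclass
class Embedding2D:
    """Per-point 2-D coordinates, in the order of ``point_ids``."""

    point_ids: list[str]
    coords: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.point_ids), 2):
            raise ValidationError("coords shape does not match point_ids")
        if not np.isfinite(self.coords).all():
            raise ValidationError("embedding coordinates must be finite")


@dataclass
class LossBreakdown:
    loss_nb_total: float
    loss_mn_total: float
    loss_fp_total: float
    total: float


@dataclass
class PacmapConfig:
    """Pair counts, schedule and seed for :func:`pacmap_embed`.

    Defaults: 10 neighbor pairs per anchor, mid-near pairs at half that,
    further pairs at twice that; PCA initialization scaled by ``init_scale``.
    """

    n_nb: int = 10
    n_mn: int = 5
    n_fp: int = 20
    schedule: PhaseSchedule = field(default_factory=PhaseSchedule)
    init_scale: float = 0.01
    learning_rate: float = 1.0
    seed: int = 0


def _as_points(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValidationError("points must be a 2-D array (n_points, n_dims)")
    if not np.isfinite(pts).all():
        raise ValidationError("points must be finite")
    return pts


def compute_sigmas(points: np.ndarray) -> ScaledDistanceCache:
    """Local scale sigma_i = mean distance to the 4th–6th nearest neighbors.

    Requires at least 7 points.  Ranking covers all other points (zero
    distances from duplicates included), ties broken by smaller index via
    a stable sort.
    """
    pts = _as_points(points)
    n = pts.shape[0]
    if n < MIN_POINTS:
        raise ValidationError(f"need at least {MIN_POINTS} points, got {n}")
    sq = squareform(pdist(pts, metric="sqeuclidean"))
    dist = np.sqrt(sq)
    order = np.argsort(dist, axis=1, kind="stable")
    # Drop the point itself from its sorted row; the 4th-6th closest OTHER
    # points then sit at positions 3..5.
    sigma = np.empty(n)
    for i in range(n):
        others = order[i][order[i] != i]
        sigma[i] = dist[i, others[3:6]].mean()
    if (sigma <= 0).any():
        # >=4 exact duplicates of a point collapse sigma to 0; fall back to
        # the smallest positive scale so scaled distances stay defined.
        positive = sigma[sigma > 0]
        floor = positive.min() if positive.size else 1.0
        sigma = np.where(sigma > 0, sigma, floor)
    scaled = sq / np.outer(sigma, sigma)
    np.fill_diagonal(scaled, 0.0)
    return ScaledDistanceCache(sigma=sigma, scaled_sq_dist=scaled, sq_dist=sq)


def select_neighbor_pairs(
    points: np.ndarray, cache: ScaledDistanceCache, n_nb: int, seed: int = 0
) -> np.ndarray:
    """Per anchor, the ``n_nb`` nearest other points under the scaled distance.

    Deterministic: ties resolve to the smaller index (stable argsort).  The
    seed parameter is accepted for interface symmetry; selection itself is
    deterministic.
    """
    n = cache.n_points
    if n_nb < 0 or n_nb >= n:
        raise ValidationError(f"n_nb must be in 0..{n - 1}")
    if n_nb == 0:
        return np.empty((0, 2), dtype=int)
    d = cache.scaled_sq_dist.copy()
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")[:, :n_nb]
    anchors = np.repeat(np.arange(n), n_nb)
    return np.column_stack([anchors, order.ravel()])


def select_midnear_pairs(
    points: np.ndarray, n_mn: int, seed: int = 0
) -> np.ndarray:
    """Sample mid-near pairs: 6 distinct non-anchor points, keep the 2nd closest.

    Euclidean (unscaled) distance ranks the 6 candidates.  Reproducible
    given ``seed``.
    """
    pts = _as_points(points)
    n = pts.shape[0]
    if n_mn < 0:
        raise ValidationError("n_mn must be >= 0")
    if n_mn == 0:
        return np.empty((0, 2), dtype=int)
    if n < 7:
        raise ValidationError("mid-near sampling needs at least 7 points")
    rng = np.random.default_rng(seed)
    pairs = np.empty((n * n_mn, 2), dtype=int)
    row = 0
    for i in range(n):
        candidates = np.delete(np.arange(n), i)
        for _ in range(n_mn):
            six = rng.choice(candidates, size=6, replace=False)
            d = np.sum((pts[six] - pts[i]) ** 2, axis=1)
            second = six[np.argsort(d, kind="stable")[1]]
            pairs[row] = (i, second)
            row += 1
    return pairs


def select_further_pairs(
    points: np.ndarray,
    neighbor_pairs: np.ndarray,
    n_fp: int,
    seed: int = 0,
) -> np.ndarray:
    """Uniformly sample ``n_fp`` non-anchor, non-neighbor points per anchor."""
    pts = _as_points(points)
    n = pts.shape[0]
    if n_fp < 0:
        raise ValidationError("n_fp must be >= 0")
    if n_fp == 0:
        return np.empty((0, 2), dtype=int)
    neighbors_of: dict[int, set[int]] = {}
    for a, b in np.asarray(neighbor_pairs, dtype=int).reshape(-1, 2):
        neighbors_of.setdefault(int(a), set()).add(int(b))
    rng = np.random.default_rng(seed)
    pairs = np.empty((n * n_fp, 2), dtype=int)
    row = 0
    for i in range(n):
        banned = neighbors_of.get(i, set()) | {i}
        allowed = np.array([j for j in range(n) if j not in banned])
        if allowed.size < n_fp:
            raise ValidationError(
                f"anchor {i}: only {allowed.size} candidates for {n_fp} further pairs"
            )
        chosen = rng.choice(allowed, size=n_fp, replace=False)
        pairs[row : row + n_fp, 0] = i
        pairs[row : row + n_fp, 1] = chosen
        row += n_fp
    return pairs


def build_pairs(points: np.ndarray, config: PacmapConfig) -> PairSet:
    """Construct all three pair classes for ``points`` under ``config``.

    On small point sets the configured pair counts are clamped to what is
    available: at most n - 1 neighbors per anchor, and at most
    n - 1 - n_nb further pairs (further pairs exclude the anchor's
    neighbors).  Clamping is logged.
    """
    import logging

    n = np.asarray(points).shape[0]
    n_nb = min(config.n_nb, n - 1)
    n_fp = min(config.n_fp, n - 1 - n_nb)
    if (n_nb, n_fp) != (config.n_nb, config.n_fp):
        logging.getLogger(__name__).info(
            "pair counts clamped for n=%d points: n_nb %d->%d, n_fp %d->%d",
            n, config.n_nb, n_nb, config.n_fp, n_fp,
        )
    cache = compute_sigmas(points)
    nb = select_neighbor_pairs(points, cache, n_nb, seed=config.seed)
    mn = select_midnear_pairs(points, config.n_mn, seed=config.seed + 1)
    fp = select_further_pairs(points, nb, n_fp, seed=config.seed + 2)
    return PairSet(neighbor_pairs=nb, midnear_pairs=mn, further_pairs=fp)


def _dt(coords: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    diff = coords[pairs[:, 0]] - coords[pairs[:, 1]]
    return np.sum(diff * diff, axis=1) + 1.0


def pair_losses(embedding: Embedding2D, pair: tuple[int, int], kind: str) -> float:
    """Loss of a single pair; ``kind`` in {"neighbor", "midnear", "further"}."""
    dt = float(_dt(embedding.coords, np.array([pair], dtype=int))[0])
    if kind == "neighbor":
        return dt / (10.0 + dt)
    if kind == "midnear":
        return dt / (10000.0 + dt)
    if kind == "further":
        return 1.0 / (1.0 + dt)
    raise ValidationError(f"unknown pair kind {kind!r}")


def total_loss(
    embedding: Embedding2D | np.ndarray, pairs: PairSet, weights: LossWeights
) -> LossBreakdown:
    """Sum each pair class's losses and combine with the weights."""
    coords = embedding.coords if isinstance(embedding, Embedding2D) else np.asarray(embedding, float)
    dt_nb = _dt(coords, pairs.neighbor_pairs)
    dt_mn = _dt(coords, pairs.midnear_pairs)
    dt_fp = _dt(coords, pairs.further_pairs)
    nb = float(np.sum(dt_nb / (10.0 + dt_nb)))
    mn = float(np.sum(dt_mn / (10000.0 + dt_mn)))
    fp = float(np.sum(1.0 / (1.0 + dt_fp)))
    return LossBreakdown(
        loss_nb_total=nb,
        loss_mn_total=mn,
        loss_fp_total=fp,
        total=weights.w_nb * nb + weights.w_mn * mn + weights.w_fp * fp,
    )


def loss_gradient(
    coords: np.ndarray, pairs: PairSet, weights: LossWeights
) -> np.ndarray:
    """Analytic gradient of the weighted total loss w.r.t. the coordinates.

    For an attractive pair with loss dt/(c + dt), d(loss)/d(dt) =
    c/(c + dt)^2; for the repulsive 1/(1 + dt), it is -1/(1 + dt)^2; and
    d(dt)/d(ya) = 2 (ya - yb).
    """
    grad = np.zeros_like(coords)

    def _accumulate(pair_arr: np.ndarray, dldt_fn, weight: float) -> None:
        if weight == 0.0 or pair_arr.shape[0] == 0:
            return
        a, b = pair_arr[:, 0], pair_arr[:, 1]
        diff = coords[a] - coords[b]
        dt = np.sum(diff * diff, axis=1) + 1.0
        coef = (weight * dldt_fn(dt))[:, None] * (2.0 * diff)
        np.add.at(grad, a, coef)
        np.add.at(grad, b, -coef)

    _accumulate(pairs.neighbor_pairs, lambda dt: 10.0 / (10.0 + dt) ** 2, weights.w_nb)
    _accumulate(pairs.midnear_pairs, lambda dt: 10000.0 / (10000.0 + dt) ** 2, weights.w_mn)
    _accumulate(pairs.further_pairs, lambda dt: -1.0 / (1.0 + dt) ** 2, weights.w_fp)
    return grad


def pca_initialize(
    points: np.ndarray, point_ids: list[str] | None = None, scale: float = 0.01
) -> Embedding2D:
    """Project mean-centered points onto the top-2 principal axes, scaled down.

    The small scale keeps the starting layout compact so early attractive
    gradients dominate.
    """
    pts = _as_points(points)
    n, d = pts.shape
    if n < 2 or d < 2:
        raise ValidationError("PCA initialization needs >= 2 points and >= 2 dims")
    if np.allclose(pts, pts[0]):
        raise ValidationError("all points identical; PCA initialization undefined")
    proj = PCA(n_components=2, svd_solver="full").fit_transform(pts)
    ids = point_ids if point_ids is not None else [str(i) for i in range(n)]
    return Embedding2D(point_ids=list(ids), coords=proj * scale)


def optimize_embedding(
    init: Embedding2D,
    pairs: PairSet,
    schedule: PhaseSchedule,
    learning_rate: float = 1.0,
    seed: int = 0,
) -> tuple[Embedding2D, list[LossBreakdown]]:
    """Run the three-phase adaptive-moment gradient descent.

    Returns the final embedding and the per-iteration loss trace.  Fully
    deterministic: pairs and schedule fix the trajectory (the seed is kept
    in the signature for interface stability).
    """
    coords = init.coords.copy()
    beta1, beta2, eps = 0.9, 0.999, 1e-7
    m = np.zeros_like(coords)
    v = np.zeros_like(coords)
    trace: list[LossBreakdown] = []
    for t in range(schedule.total_iters):
        w = schedule.weights_at(t)
        breakdown = total_loss(coords, pairs, w)
        if not np.isfinite(breakdown.total):
            raise RuntimeError(f"non-finite loss at iteration {t}")
        trace.append(breakdown)
        g = loss_gradient(coords, pairs, w)
        m = beta1 * m + (1 - beta1) * g
        v = beta2 * v + (1 - beta2) * g * g
        mhat = m / (1 - beta1 ** (t + 1))
        vhat = v / (1 - beta2 ** (t + 1))
        coords = coords - learning_rate * mhat / (np.sqrt(vhat) + eps)
    return Embedding2D(point_ids=list(init.point_ids), coords=coords), trace


def pacmap_embed(
    points: np.ndarray,
    config: PacmapConfig | None = None,
    point_ids: list[str] | None = None,
) -> Embedding2D:
    """Full PaCMAP: pair construction, PCA initialization, phased optimization."""
    config = config or PacmapConfig()
    pts = _as_points(points)
    pairs = build_pairs(pts, config)
    init = pca_initialize(pts, point_ids=point_ids, scale=config.init_scale)
    final, _ = optimize_embedding(
        init, pairs, config.schedule, learning_rate=config.learning_rate,
        seed=config.seed,
    )
    return final


def write_embedding_tsv(embedding: Embedding2D, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tx\ty\n")
        for pid, (x, y) in zip(embedding.point_ids, embedding.coords):
            fh.write(f"{pid}\t{float(x)!r}\t{float(y)!r}\n")


def read_embedding_tsv(path) -> Embedding2D:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"gene": str}, float_precision="round_trip")
    return Embedding2D(
        point_ids=[str(g) for g in df["gene"]],
        coords=df[["x", "y"]].to_numpy(dtype=float),
    )
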