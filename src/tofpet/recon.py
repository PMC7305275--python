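"""2-D TOF list-mode MLEM reconstruction.

The forward model factorises each event's detection probability into a
geometric part — exact voxel intersection lengths of the line of response
(Siddon-style ray tracing) — and a TOF part: the timing-kernel mass falling
into the event's TOF bin, evaluated per voxel as

    K = cdf(k_{t+1} - v') - cdf(k_t - v'),

where ``v'`` is the signed projection of the voxel centre onto the TOF axis
in picoseconds (``v' = 2 s / c`` for a displacement ``s`` mm from the LOR
midpoint towards detector ``b``; the sign matches ``delta_t = t_a - t_b``).

Because the per-event weights do not change across iterations, they are
assembled once into a sparse system matrix; the multiplicative MLEM update
is then two sparse mat-vecs per iteration.  The sensitivity (denominator)
image is the non-TOF backprojection of all admissible detector pairs — the
TOF weights of a full coincidence window sum to one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse

from tofpet.kernels import TimingKernel, SPEED_OF_LIGHT_MM_PER_PS
from tofpet.scan_sim import ListmodeEvents, RingGeometry, effective_lor_endpoints

__all__ = [
    "ImageGrid2D",
    "TOFBinning",
    "ray_trace_lor",
    "lor_tof_projection",
    "tof_weights",
    "sensitivity_image",
    "lm_mlem",
    "log_likelihood",
    "ReconResult",
]

logger = logging.getLogger("tofpet.recon")


@dataclass(frozen=True)
class TOFBinning:
    """Uniform, zero-centred TOF bins (the central bin straddles zero)."""

    bin_width: float = 1.0
    n_bins: int = 4101

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.n_bins < 1 or self.n_bins % 2 == 0:
            raise ValueError("n_bins must be a positive odd count (zero-centred)")

    @classmethod
    def from_window(cls, coincidence_window: float, bin_width: float = 1.0) -> "TOFBinning":
        """Binning whose bins cover the +-window/2 range at the given width."""
        half_bins = int(math.floor(0.5 * coincidence_window / bin_width))
        return cls(bin_width=bin_width, n_bins=2 * half_bins + 1)

    @property
    def edges(self) -> np.ndarray:
        return (np.arange(self.n_bins + 1) - self.n_bins / 2.0) * self.bin_width

    def index_for(self, delta_t) -> np.ndarray:
        return np.rint(np.asarray(delta_t) / self.bin_width).astype(np.int64) + (self.n_bins - 1) // 2


@dataclass
class ImageGrid2D:
    """Square-voxel 2-D activity image centred on the scanner axis.

    Voxel ``(ix, iy)`` has centre ``((ix - (nx-1)/2) * voxel,
    (iy - (ny-1)/2) * voxel)``; values are stored flat, C-order over
    ``(iy, ix)``.
    """

    nx: int
    ny: int
    voxel: float = 1.0
    values: np.ndarray | None = None

    def __post_init__(self):
        if self.nx < 1 or self.ny < 1 or self.voxel <= 0:
            raise ValueError("grid must have positive shape and voxel size")
        if self.values is None:
            self.values = np.zeros(self.nx * self.ny)
        else:
            self.values = np.asarray(self.values, dtype=float).reshape(self.nx * self.ny)
            if np.any(self.values < 0):
                raise ValueError("activity values must be non-negative")

    @property
    def n_voxels(self) -> int:
        return self.nx * self.ny

    @property
    def x_min(self) -> float:
        return -0.5 * self.nx * self.voxel

    @property
    def y_min(self) -> float:
        return -0.5 * self.ny * self.voxel

    def as_array(self) -> np.ndarray:
        """Image as an ``(ny, nx)`` array (row = y)."""
        return self.values.reshape(self.ny, self.nx)

    def voxel_centres(self) -> tuple[np.ndarray, np.ndarray]:
        xs = (np.arange(self.nx) - (self.nx - 1) / 2.0) * self.voxel
        ys = (np.arange(self.ny) - (self.ny - 1) / 2.0) * self.voxel
        return xs, ys

    def flat_index(self, ix, iy) -> np.ndarray:
        return np.asarray(iy) * self.nx + np.asarray(ix)

    def nearest_voxel(self, x: float, y: float) -> tuple[int, int]:
        ix = int(np.clip(round(x / self.voxel + (self.nx - 1) / 2.0), 0, self.nx - 1))
        iy = int(np.clip(round(y / self.voxel + (self.ny - 1) / 2.0), 0, self.ny - 1))
        return ix, iy

    def value_at(self, x: float, y: float) -> float:
        ix, iy = self.nearest_voxel(x, y)
        return float(self.values[iy * self.nx + ix])

    def copy_with(self, values: np.ndarray) -> "ImageGrid2D":
        return ImageGrid2D(nx=self.nx, ny=self.ny, voxel=self.voxel, values=np.array(values))

    # -- flat float32 raster + sidecar ------------------------------------------

    def to_files(self, raster_path, sidecar: dict | None = None) -> None:
        raster_path = Path(raster_path)
        self.values.astype("<f4").tofile(raster_path)
        side = {"nx": self.nx, "ny": self.ny, "voxel_mm": self.voxel, "dtype": "<f4", "order": "iy,ix"}
        side.update(sidecar or {})
        with raster_path.with_suffix(raster_path.suffix + ".hdr").open("w") as fh:
            for key, val in side.items():
                fh.write(f"{key} = {val}\n")


# ---------------------------------------------------------------------------
# Ray tracing
# ---------------------------------------------------------------------------


def ray_trace_lor(p0, p1, grid: ImageGrid2D) -> tuple[np.ndarray, np.ndarray]:
    """Exact voxel intersection lengths of segment ``p0 -> p1`` through the grid.

    Returns ``(flat_indices, lengths_mm)`` ordered along the segment.
    Incremental Siddon-style traversal via the sorted union of x- and
    y-plane crossings.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    seg_len = float(np.hypot(d[0], d[1]))
    if seg_len == 0:
        raise ValueError("LOR endpoints coincide")
    x_planes = grid.x_min + grid.voxel * np.arange(grid.nx + 1)
    y_planes = grid.y_min + grid.voxel * np.arange(grid.ny + 1)

    t_lo, t_hi = 0.0, 1.0
    for comp, planes in ((0, x_planes), (1, y_planes)):
        if d[comp] == 0.0:
            if not (planes[0] <= p0[comp] <= planes[-1]):
                return np.empty(0, dtype=np.int64), np.empty(0)
        else:
            ta = (planes[0] - p0[comp]) / d[comp]
            tb = (planes[-1] - p0[comp]) / d[comp]
            t_lo = max(t_lo, min(ta, tb))
            t_hi = min(t_hi, max(ta, tb))
    if t_hi <= t_lo:
        return np.empty(0, dtype=np.int64), np.empty(0)

    ts = [np.array([t_lo, t_hi])]
    for comp, planes in ((0, x_planes), (1, y_planes)):
        if d[comp] != 0.0:
            tc = (planes - p0[comp]) / d[comp]
            ts.append(tc[(tc > t_lo) & (tc < t_hi)])
    t = np.unique(np.concatenate(ts))
    if t.size < 2:
        return np.empty(0, dtype=np.int64), np.empty(0)
    tm = 0.5 * (t[:-1] + t[1:])
    mx = p0[0] + tm * d[0]
    my = p0[1] + tm * d[1]
    ix = np.floor((mx - grid.x_min) / grid.voxel).astype(np.int64)
    iy = np.floor((my - grid.y_min) / grid.voxel).astype(np.int64)
    ok = (ix >= 0) & (ix < grid.nx) & (iy >= 0) & (iy < grid.ny)
    lengths = np.diff(t) * seg_len
    return (iy[ok] * grid.nx + ix[ok]), lengths[ok]


def lor_tof_projection(p0, p1, points, c: float = SPEED_OF_LIGHT_MM_PER_PS) -> np.ndarray:
    """Signed TOF coordinate ``v'`` (ps) of points, relative to LOR ``p0 -> p1``.

    Positive towards ``p1`` (detector b): an annihilation displaced by ``s``
    mm towards b yields ``delta_t = t_a - t_b = 2 s / c``.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    points = np.asarray(points, dtype=float)
    u = p1 - p0
    u = u / np.hypot(u[0], u[1])
    mid = 0.5 * (p0 + p1)
    s = (points - mid) @ u
    return 2.0 * s / c


def tof_weights(kernel: TimingKernel, binning: TOFBinning, t: int, vprime) -> np.ndarray:
    """TOF projection weights for bin ``t``: CDF increment at each voxel.

    ``weights[j] = cdf(k_{t+1} - v'_j) - cdf(k_t - v'_j)``; summing over all
    bins of a full window telescopes to ~1 for every voxel.
    """
    if not 0 <= t < binning.n_bins:
        raise IndexError(f"TOF bin {t} out of range [0, {binning.n_bins})")
    vprime = np.asarray(vprime, dtype=float)
    edges = binning.edges
    w = np.asarray(kernel.cdf(edges[t + 1] - vprime)) - np.asarray(kernel.cdf(edges[t] - vprime))
    return np.maximum(w, 0.0)


# ---------------------------------------------------------------------------
# System matrix and sensitivity
# ---------------------------------------------------------------------------


def _admissible_pairs(geom: RingGeometry) -> np.ndarray:
    idx = np.arange(geom.n_detectors)
    a, b = np.meshgrid(idx, idx, indexing="ij")
    keep = (a < b) & (geom.circular_difference(a, b) >= geom.min_detector_difference)
    return np.stack([a[keep], b[keep]], axis=1)


def sensitivity_image(geom: RingGeometry, grid: ImageGrid2D, kernel: TimingKernel | None = None) -> ImageGrid2D:
    """Voxel-wise total detection weight over all admissible detector pairs.

    The TOF weights of any normalised kernel sum to one over a full
    coincidence window, so the sensitivity reduces to the non-TOF
    backprojection of the intersection lengths (``kernel`` is accepted for
    interface symmetry and does not alter the result).
    """
    sens = np.zeros(grid.n_voxels)
    pairs = _admissible_pairs(geom)
    pa, pb = effective_lor_endpoints(pairs[:, 0], pairs[:, 1], geom)
    for k in range(pairs.shape[0]):
        idx, ln = ray_trace_lor(pa[k], pb[k], grid)
        np.add.at(sens, idx, ln)
    return grid.copy_with(sens)


def _build_event_matrix(
    events: ListmodeEvents,
    geom: RingGeometry,
    grid: ImageGrid2D,
    kernel: TimingKernel,
    binning: TOFBinning,
    weight_floor: float = 1e-14,
):
    """Sparse (n_events x n_voxels) matrix of ``p_ij * K_it;j`` weights.

    Events sharing a detector pair reuse one ray trace; weights below
    ``weight_floor`` times the row maximum are dropped.  Returns the matrix
    and the number of events whose LOR misses the grid entirely.
    """
    n_events = len(events)
    pair_key = events.det_a.astype(np.int64) * geom.n_detectors + events.det_b.astype(np.int64)
    order = np.argsort(pair_key, kind="stable")
    sorted_keys = pair_key[order]
    boundaries = np.flatnonzero(np.r_[True, sorted_keys[1:] != sorted_keys[:-1], True])
    edges_lo = binning.edges[:-1]
    edges_hi = binning.edges[1:]
    xs, ys = grid.voxel_centres()

    rows, cols, vals = [], [], []
    n_missed = 0
    for s0, s1 in zip(boundaries[:-1], boundaries[1:]):
        ev = order[s0:s1]
        da = int(events.det_a[ev[0]])
        db = int(events.det_b[ev[0]])
        pa, pb = effective_lor_endpoints(da, db, geom)
        idx, ln = ray_trace_lor(pa, pb, grid)
        if idx.size == 0:
            n_missed += ev.size
            continue
        pts = np.stack([xs[idx % grid.nx], ys[idx // grid.nx]], axis=1)
        vp = lor_tof_projection(pa, pb, pts)
        t = events.tof_bin[ev]
        lo = edges_lo[t][:, None] - vp[None, :]
        hi = edges_hi[t][:, None] - vp[None, :]
        K = np.asarray(kernel.cdf(hi)) - np.asarray(kernel.cdf(lo))
        w = np.maximum(K, 0.0) * ln[None, :]
        wmax = w.max(axis=1, keepdims=True)
        w[w < weight_floor * np.maximum(wmax, 1e-300)] = 0.0
        er, ec = np.nonzero(w)
        rows.append(ev[er])
        cols.append(idx[ec])
        vals.append(w[er, ec])
    if rows:
        mat = sparse.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_events, grid.n_voxels),
        )
    else:
        mat = sparse.csr_matrix((n_events, grid.n_voxels))
    return mat, n_missed


# ---------------------------------------------------------------------------
# LM-MLEM
# ---------------------------------------------------------------------------


@dataclass
class ReconResult:
    """Snapshots and audit trail of an LM-MLEM run."""

    snapshots: dict[int, ImageGrid2D]
    log_likelihood: list[float]
    n_events_used: int
    n_events_skipped: int

    @property
    def final(self) -> ImageGrid2D:
        return self.snapshots[max(self.snapshots)]


def lm_mlem(
    events: ListmodeEvents,
    geom: RingGeometry,
    grid: ImageGrid2D,
    kernel: TimingKernel,
    n_iter: int = 60,
    binning: TOFBinning | None = None,
    snapshots: tuple[int, ...] | None = None,
    sens: ImageGrid2D | None = None,
) -> ReconResult:
    """TOF list-mode MLEM: ``x <- x/s * A^T (1 / (A x))`` with snapshots.

    ``A`` holds the per-event ``p_ij K_it;j`` weights; ``s`` is the
    sensitivity image.  The update preserves non-negativity, never decreases
    the list-mode Poisson log-likelihood, and drives ``sum_j s_j x_j`` to the
    number of used events.  Events whose LOR misses the grid or whose
    forward projection is empty are skipped and counted.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if binning is None:
        binning = TOFBinning.from_window(geom.coincidence_window, geom.tof_bin)
    if snapshots is None:
        snapshots = (n_iter,)
    snapshots = tuple(sorted(set(int(s) for s in snapshots)))
    if any(s < 1 or s > n_iter for s in snapshots):
        raise ValueError("snapshot iterations must lie in [1, n_iter]")

    A, n_missed = _build_event_matrix(events, geom, grid, kernel, binning)
    row_mass = np.asarray(A.sum(axis=1)).ravel()
    dead = row_mass <= 0  # subsumes the events whose LOR missed the grid
    n_dead = int(dead.sum())
    if n_dead:
        keep = ~dead
        A = A[keep]
        logger.info(
            "skipping %d events with empty forward projection (%d missed the grid)",
            n_dead,
            n_missed,
        )
    n_used = A.shape[0]
    if n_used == 0:
        raise ValueError("no usable events on this grid")

    if sens is None:
        sens = sensitivity_image(geom, grid)
    s = sens.values
    mask = s > 0
    x = np.where(mask, 1.0, 0.0)

    out: dict[int, ImageGrid2D] = {}
    loglik: list[float] = []
    s_masked = np.where(mask, s, 1.0)
    for it in range(1, n_iter + 1):
        y = A @ x
        if np.any(y <= 0):
            raise ZeroDivisionError("zero forward projection during MLEM update")
        loglik.append(float(np.sum(np.log(y)) - s @ x))
        back = A.T @ (1.0 / y)
        x = np.where(mask, x / s_masked * back, 0.0)
        if it in snapshots:
            out[it] = grid.copy_with(x)
    return ReconResult(
        snapshots=out,
        log_likelihood=loglik,
        n_events_used=n_used,
        n_events_skipped=n_dead,
    )


def log_likelihood(
    events: ListmodeEvents,
    image: ImageGrid2D,
    geom: RingGeometry,
    kernel: TimingKernel,
    binning: TOFBinning | None = None,
    sens: ImageGrid2D | None = None,
) -> float:
    """List-mode Poisson log-likelihood ``sum_e ln(A x)_e - sum_j s_j x_j``.

    Returns ``-inf`` when any event has zero forward projection through the
    image.
    """
    if np.any(image.values < 0):
        raise ValueError("image must be non-negative")
    if binning is None:
        binning = TOFBinning.from_window(geom.coincidence_window, geom.tof_bin)
    A, _ = _build_event_matrix(events, geom, image, kernel, binning)
    if sens is None:
        sens = sensitivity_image(geom, image)
    y = A @ image.values
    if np.any(y <= 0):
        return -math.inf
    return float(np.sum(np.log(y)) - sens.values @ image.values)
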