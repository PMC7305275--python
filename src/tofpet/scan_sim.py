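"""Desk-scale 2-D ring-scanner coincidence simulator.

A single detector ring (transaxial reduction of a cylindrical scanner) is
modelled as ``n_detectors`` angular sectors on a circle.  Annihilation
events are drawn from a piecewise-constant 2-D activity phantom, emitted
along uniformly random directions, and detected at the two ring
intersections.  Detection times combine the geometric path length, a
truncated-exponential photon-travel delay in the crystal and optional
per-detector Gaussian jitter; the signed difference ``delta_t = t_a - t_b``
feeds TOF reconstruction.  Only true coincidences are produced — no
attenuation, scatter or randoms — matching the reconstruction contract,
which corrects for none of them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from tofpet.timing_sim import TimingSimConfig, truncated_exp_mean, sample_absorption_depths

__all__ = [
    "DEFAULT_AVERAGE_DOI_MM",
    "RingGeometry",
    "PhantomRegion",
    "PhantomSpec",
    "ListmodeEvents",
    "build_nema_iq_2d",
    "build_derenzo_2d",
    "generate_listmode",
    "effective_lor_endpoints",
]

#: Average depth-of-interaction constants (mm) per crystal length (mm), used
#: as configuration defaults for the effective line-of-response radius.
DEFAULT_AVERAGE_DOI_MM = {10.0: 3.6, 20.0: 5.8, 40.0: 7.4}


@dataclass(frozen=True)
class RingGeometry:
    """Geometry and timing constants of the 2-D detector ring."""

    crystal_length: float
    ring_radius: float = 424.5
    n_detectors: int = 666
    crystal_face: float = 4.0
    crystal_gap: float = 0.2
    average_doi: float | None = None
    min_detector_difference: int | None = None
    coincidence_window: float = 4100.0  # ps, full width
    tof_bin: float = 1.0  # ps
    reject_gaps: bool = False

    def __post_init__(self):
        if self.crystal_length <= 0 or self.ring_radius <= 0:
            raise ValueError("crystal_length and ring_radius must be positive")
        if self.n_detectors < 8:
            raise ValueError("need at least 8 detectors")
        if self.average_doi is None:
            doi = DEFAULT_AVERAGE_DOI_MM.get(float(self.crystal_length))
            if doi is None:
                doi = truncated_exp_mean(self.crystal_length, 0.087)
            object.__setattr__(self, "average_doi", doi)
        if not 0 <= self.average_doi <= self.crystal_length:
            raise ValueError("average_doi must lie within the crystal")
        if self.min_detector_difference is None:
            # the full-size ring uses 83 of 666; scale proportionally
            object.__setattr__(
                self, "min_detector_difference", int(round(83 * self.n_detectors / 666))
            )
        if not 0 < self.min_detector_difference < self.n_detectors / 2:
            raise ValueError("min_detector_difference must be in (0, n_detectors/2)")

    @property
    def fov_radius(self) -> float:
        """Usable transaxial field-of-view radius, mm (0.7 x ring radius)."""
        return 0.7 * self.ring_radius

    @property
    def detector_pitch(self) -> float:
        """Arc length per detector sector at the inner radius, mm."""
        return 2.0 * math.pi * self.ring_radius / self.n_detectors

    def detector_angles(self) -> np.ndarray:
        return 2.0 * math.pi * np.arange(self.n_detectors) / self.n_detectors

    def circular_difference(self, det_a, det_b) -> np.ndarray:
        diff = np.abs(np.asarray(det_a) - np.asarray(det_b))
        return np.minimum(diff, self.n_detectors - diff)

    def metadata(self) -> dict:
        return {
            "ring_radius_mm": self.ring_radius,
            "n_detectors": self.n_detectors,
            "crystal_face_mm": self.crystal_face,
            "crystal_gap_mm": self.crystal_gap,
            "crystal_length_mm": self.crystal_length,
            "average_doi_mm": self.average_doi,
            "min_detector_difference": self.min_detector_difference,
            "coincidence_window_ps": self.coincidence_window,
            "tof_bin_ps": self.tof_bin,
            "reject_gaps": self.reject_gaps,
        }


# ---------------------------------------------------------------------------
# Phantoms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomRegion:
    """Disc of uniform relative activity.  Later regions override earlier ones."""

    centre: tuple[float, float]
    radius: float
    activity: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.activity < 0:
            raise ValueError("activity must be >= 0")

    def contains(self, x, y):
        return (np.asarray(x) - self.centre[0]) ** 2 + (np.asarray(y) - self.centre[1]) ** 2 <= self.radius**2


@dataclass(frozen=True)
class PhantomSpec:
    """Piecewise-constant 2-D activity distribution built from discs."""

    regions: tuple[PhantomRegion, ...]
    name: str = "phantom"
    sections: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "regions", tuple(self.regions))
        if not any(r.activity > 0 for r in self.regions):
            raise ValueError("phantom needs at least one region with positive activity")

    @property
    def extent(self) -> float:
        """Radius of the smallest origin-centred disc containing every region."""
        return max(math.hypot(*r.centre) + r.radius for r in self.regions)

    @property
    def bounding_box(self) -> tuple[float, float, float, float]:
        """``(xmin, xmax, ymin, ymax)`` of the active regions, mm."""
        active = [r for r in self.regions if r.activity > 0]
        return (
            min(r.centre[0] - r.radius for r in active),
            max(r.centre[0] + r.radius for r in active),
            min(r.centre[1] - r.radius for r in active),
            max(r.centre[1] + r.radius for r in active),
        )

    @property
    def max_activity(self) -> float:
        return max(r.activity for r in self.regions)

    def activity_at(self, x, y) -> np.ndarray:
        """Relative activity at points; the last enclosing region wins."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        val = np.zeros(np.broadcast(x, y).shape)
        for region in self.regions:
            inside = region.contains(x, y)
            val = np.where(inside, region.activity, val)
        return val


def build_nema_iq_2d(
    contrast: float = 4.5,
    background_radius: float = 60.0,
    placement_radius: float = 25.0,
) -> PhantomSpec:
    """2-D NEMA-IQ-like section: warm background disc with four hot discs.

    Hot-disc diameters are 10, 13, 17 and 22 mm at ``contrast`` times the
    background activity, placed every 90 degrees on a ring of
    ``placement_radius``.
    """
    if not contrast >= 1:
        raise ValueError("contrast must be >= 1")
    diameters = (10.0, 13.0, 17.0, 22.0)
    angles = (0.0, 0.5 * math.pi, math.pi, 1.5 * math.pi)
    regions = [PhantomRegion(centre=(0.0, 0.0), radius=background_radius, activity=1.0)]
    centres = []
    for d, a in zip(diameters, angles):
        centre = (placement_radius * math.cos(a), placement_radius * math.sin(a))
        if placement_radius + d / 2 > background_radius:
            raise ValueError("hot disc extends beyond the background")
        regions.append(PhantomRegion(centre=centre, radius=d / 2, activity=contrast))
        centres.append((centre, d))
    # pairwise overlap check
    for i in range(1, len(regions)):
        for j in range(i + 1, len(regions)):
            ri, rj = regions[i], regions[j]
            gap = math.dist(ri.centre, rj.centre) - ri.radius - rj.radius
            if gap <= 0:
                raise ValueError("hot discs overlap at the requested placement")
    return PhantomSpec(
        regions=tuple(regions),
        name="nema_iq_2d",
        sections={"hot": centres, "placement_radius": placement_radius},
    )


def build_derenzo_2d(
    phantom_radius: float = 50.0,
    rod_activity: float = 4.0,
    background_activity: float = 1.0,
    inner_margin: float = 9.0,
    edge_margin: float = 3.0,
) -> PhantomSpec:
    """Derenzo-style resolution phantom: six wedges of hot rods.

    Sections A-F have rod diameters 7.0, 5.0, 4.0, 3.5, 3.0 and 2.5 mm;
    centre-to-centre spacing is twice the diameter; rods sit on a triangular
    lattice inside a 60-degree wedge, over a warm background disc.
    """
    diameters = {"A": 7.0, "B": 5.0, "C": 4.0, "D": 3.5, "E": 3.0, "F": 2.5}
    regions = [PhantomRegion(centre=(0.0, 0.0), radius=phantom_radius, activity=background_activity)]
    sections: dict = {}
    for k, (label, d) in enumerate(diameters.items()):
        spacing = 2.0 * d
        bisector = (2 * k + 1) * math.pi / 6.0  # wedge centre angles 30, 90, ... degrees
        ux, uy = math.cos(bisector), math.sin(bisector)  # radial unit vector
        vx, vy = -uy, ux  # transverse unit vector
        rods = []
        for row in range(0, 16):
            r_row = inner_margin + d / 2 + row * spacing * math.sqrt(3.0) / 2.0
            if r_row + d / 2 + edge_margin > phantom_radius:
                break
            for col in range(row + 1):
                t_off = (col - row / 2.0) * spacing
                cx = r_row * ux + t_off * vx
                cy = r_row * uy + t_off * vy
                # stay clear of both wedge boundary half-planes
                ang = math.atan2(cy, cx) - bisector
                ang = (ang + math.pi) % (2 * math.pi) - math.pi
                rr = math.hypot(cx, cy)
                dist_to_edge = rr * math.sin(math.pi / 6.0 - abs(ang))
                if dist_to_edge < d / 2 + 1.0:
                    continue
                if rr + d / 2 + edge_margin > phantom_radius:
                    continue
                rods.append(((cx, cy), d))
                regions.append(PhantomRegion(centre=(cx, cy), radius=d / 2, activity=rod_activity))
        sections[label] = rods
    spec = PhantomSpec(regions=tuple(regions), name="derenzo_2d", sections=sections)
    # construction sanity: rods pairwise disjoint and inside the disc
    rods_flat = [r for r in spec.regions[1:]]
    for i in range(len(rods_flat)):
        if math.hypot(*rods_flat[i].centre) + rods_flat[i].radius > phantom_radius:
            raise AssertionError("rod outside phantom disc")
        for j in range(i + 1, len(rods_flat)):
            if (
                math.dist(rods_flat[i].centre, rods_flat[j].centre)
                <= rods_flat[i].radius + rods_flat[j].radius
            ):
                raise AssertionError("overlapping rods")
    return spec


# ---------------------------------------------------------------------------
# List-mode events
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ListmodeEvents:
    """TOF coincidence records: detector pair and signed ``delta_t = t_a - t_b``."""

    det_a: np.ndarray
    det_b: np.ndarray
    delta_t: np.ndarray
    tof_bin: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "det_a", np.asarray(self.det_a, dtype=np.int32))
        object.__setattr__(self, "det_b", np.asarray(self.det_b, dtype=np.int32))
        object.__setattr__(self, "delta_t", np.asarray(self.delta_t, dtype=float))
        object.__setattr__(self, "tof_bin", np.asarray(self.tof_bin, dtype=np.int32))
        n = self.det_a.size
        if not (self.det_b.size == n and self.delta_t.size == n and self.tof_bin.size == n):
            raise ValueError("event arrays must have equal length")

    def __len__(self) -> int:
        return self.det_a.size

    def to_file(self, path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write("# format = tofpet-listmode-v1\n")
            for key, val in self.metadata.items():
                fh.write(f"# {key} = {val}\n")
            fh.write("det_a\tdet_b\tdelta_t_ps\ttof_bin\n")
            for a, b, dt, tb in zip(self.det_a, self.det_b, self.delta_t, self.tof_bin):
                fh.write(f"{a}\t{b}\t{dt:.6f}\t{tb}\n")

    @classmethod
    def from_file(cls, path) -> "ListmodeEvents":
        path = Path(path)
        meta: dict = {}
        rows_a, rows_b, rows_dt, rows_tb = [], [], [], []
        header_seen = False
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    body = line.lstrip("#").strip()
                    if "=" in body:
                        key, _, val = body.partition("=")
                        meta[key.strip()] = val.strip()
                    continue
                if not header_seen:
                    if line.split("\t") != ["det_a", "det_b", "delta_t_ps", "tof_bin"]:
                        raise ValueError(f"{path}:{lineno}: unexpected header {line!r}")
                    header_seen = True
                    continue
                parts = line.split("\t")
                if len(parts) != 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 columns")
                rows_a.append(int(parts[0]))
                rows_b.append(int(parts[1]))
                rows_dt.append(float(parts[2]))
                rows_tb.append(int(parts[3]))
        if not header_seen:
            raise ValueError(f"{path}: missing list-mode header")
        return cls(
            det_a=np.asarray(rows_a),
            det_b=np.asarray(rows_b),
            delta_t=np.asarray(rows_dt),
            tof_bin=np.asarray(rows_tb),
            metadata=meta,
        )


def effective_lor_endpoints(det_a, det_b, geom: RingGeometry):
    """Effective LOR endpoints at radius ``ring_radius + average_doi``, mm.

    Returns two ``(..., 2)`` arrays of 2-D points at the detector-centre
    directions; the average depth-of-interaction pushes the endpoints into
    the crystal.
    """
    det_a = np.asarray(det_a)
    det_b = np.asarray(det_b)
    if np.any(det_a == det_b):
        raise ValueError("a line of response needs two distinct detectors")
    r = geom.ring_radius + geom.average_doi
    step = 2.0 * math.pi / geom.n_detectors
    aa, ab = det_a * step, det_b * step
    pa = np.stack([r * np.cos(aa), r * np.sin(aa)], axis=-1)
    pb = np.stack([r * np.cos(ab), r * np.sin(ab)], axis=-1)
    return pa, pb


def _tof_bin_index(delta_t, tof_bin: float, coincidence_window: float) -> np.ndarray:
    half_bins = int(math.floor(0.5 * coincidence_window / tof_bin))
    return np.rint(np.asarray(delta_t) / tof_bin).astype(np.int32) + half_bins


def generate_listmode(
    phantom: PhantomSpec,
    geom: RingGeometry,
    timing: TimingSimConfig,
    n_true: int,
    seed: int,
) -> ListmodeEvents:
    """Simulate ``n_true`` accepted true coincidences from a 2-D phantom.

    Emission points follow the phantom activity (rejection sampling on the
    last-region-wins field); directions are uniform; each photon's detection
    time is geometric path length plus a truncated-exponential crystal delay
    plus optional per-detector Gaussian jitter.  Pairs closer than the
    minimum detector difference (and, optionally, photons landing in
    inter-crystal gaps) are rejected.
    """
    if n_true < 1:
        raise ValueError("n_true must be >= 1")
    if phantom.extent > geom.fov_radius:
        raise ValueError(
            f"phantom extent {phantom.extent:.1f} mm exceeds the FOV radius {geom.fov_radius:.1f} mm"
        )
    rng = np.random.default_rng(seed)
    c = timing.crystal.c
    sigma = timing.sigma_per_detector
    R = geom.ring_radius
    xmin, xmax, ymin, ymax = phantom.bounding_box
    amax = phantom.max_activity
    step = 2.0 * math.pi / geom.n_detectors

    out_a, out_b, out_dt = [], [], []
    n_have = 0
    while n_have < n_true:
        m = max(int((n_true - n_have) * 2.5), 4096)
        # activity-weighted emission points by rejection in the bounding box
        x = rng.uniform(xmin, xmax, m)
        y = rng.uniform(ymin, ymax, m)
        keep = rng.random(m) * amax < phantom.activity_at(x, y)
        x, y = x[keep], y[keep]
        m = x.size
        if m == 0:
            continue
        phi = rng.uniform(0.0, math.pi, m)
        ex, ey = np.cos(phi), np.sin(phi)
        pe = x * ex + y * ey
        disc = pe * pe - (x * x + y * y) + R * R
        root = np.sqrt(disc)
        t_plus = -pe + root  # photon towards +e
        t_minus = -pe - root  # photon towards -e (negative)
        ax_, ay_ = x + t_plus * ex, y + t_plus * ey
        bx_, by_ = x + t_minus * ex, y + t_minus * ey
        ang_a = np.arctan2(ay_, ax_) % (2.0 * math.pi)
        ang_b = np.arctan2(by_, bx_) % (2.0 * math.pi)
        det_a = np.rint(ang_a / step).astype(np.int64) % geom.n_detectors
        det_b = np.rint(ang_b / step).astype(np.int64) % geom.n_detectors
        ok = geom.circular_difference(det_a, det_b) >= geom.min_detector_difference
        if geom.reject_gaps:
            half_accept = 0.5 * min(geom.crystal_face, geom.detector_pitch - geom.crystal_gap)
            off_a = (ang_a - det_a * step + math.pi) % (2.0 * math.pi) - math.pi
            off_b = (ang_b - det_b * step + math.pi) % (2.0 * math.pi) - math.pi
            ok &= (np.abs(off_a) * R <= half_accept) & (np.abs(off_b) * R <= half_accept)
        m_ok = int(ok.sum())
        if m_ok == 0:
            continue
        det_a, det_b = det_a[ok], det_b[ok]
        path_a = t_plus[ok]
        path_b = -t_minus[ok]
        depth_a = sample_absorption_depths(m_ok, timing.crystal, rng)
        depth_b = sample_absorption_depths(m_ok, timing.crystal, rng)
        t_a = (path_a + depth_a) / c
        t_b = (path_b + depth_b) / c
        if sigma > 0:
            t_a = t_a + rng.normal(0.0, sigma, m_ok)
            t_b = t_b + rng.normal(0.0, sigma, m_ok)
        dt = t_a - t_b
        inside = np.abs(dt) <= 0.5 * geom.coincidence_window
        out_a.append(det_a[inside])
        out_b.append(det_b[inside])
        out_dt.append(dt[inside])
        n_have += int(inside.sum())

    det_a = np.concatenate(out_a)[:n_true]
    det_b = np.concatenate(out_b)[:n_true]
    delta_t = np.concatenate(out_dt)[:n_true]
    meta = {
        "phantom": phantom.name,
        "seed": seed,
        "n_true": n_true,
        **geom.metadata(),
        **{f"timing_{k}": v for k, v in timing.metadata().items()},
    }
    return ListmodeEvents(
        det_a=det_a,
        det_b=det_b,
        delta_t=delta_t,
        tof_bin=_tof_bin_index(delta_t, geom.tof_bin, geom.coincidence_window),
        metadata=meta,
    )
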