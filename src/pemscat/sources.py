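"""Phantom emission models.

Three air-filled phantoms emit back-to-back pairs of 511 keV photons:

* a 15 x 10 x 6 cm^3 uniform cuboid centered in the FOV (breast surrogate,
  3.7 kBq/ml),
* a 50 mm diameter x 20 mm miniDerenzo with hot rods of 1/1.5/2/3/4/5 mm
  diameter in six 60-degree sectors (rods only, 3 kBq/ml),
* a zero-thickness planar square at z = 0 covering the FOV, used for the
  normalization acquisition.

Emission origins are uniform in the active volume, directions isotropic,
and event times accumulate exponential inter-arrivals at the total decay
rate implied by the activity concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CUBOID_HALF = np.array([75.0, 50.0, 30.0])       # mm
CUBOID_ACTIVITY_KBQ_ML = 3.7
DERENZO_RADIUS = 25.0                             # mm
DERENZO_HEIGHT = 20.0                             # mm
DERENZO_DIAMETERS = (1.0, 1.5, 2.0, 3.0, 4.0, 5.0)
DERENZO_ACTIVITY_KBQ_ML = 3.0
DERENZO_MARGIN = 2.0                              # mm, rim clearance
PLANAR_HALF = 86.1                                # mm, FOV half-span


class ConfigurationError(ValueError):
    pass


@dataclass
class EmissionBatch:
    """Back-to-back pair emissions: photon 0 along +direction, 1 along -."""

    origins: np.ndarray     # (n, 3) mm
    directions: np.ndarray  # (n, 3) unit vectors
    times: np.ndarray       # (n,) ns, strictly increasing

    def __len__(self):
        return len(self.times)


@dataclass(frozen=True)
class Rod:
    center: tuple[float, float]
    diameter: float
    sector: int


@dataclass
class PhantomSpec:
    kind: str  # cuboid | derenzo | planar
    activity_kbq_ml: float = CUBOID_ACTIVITY_KBQ_ML
    rods: list = field(default_factory=list)

    @property
    def active_volume_ml(self) -> float:
        if self.kind == "cuboid":
            return float(np.prod(2 * CUBOID_HALF)) / 1000.0
        if self.kind == "derenzo":
            return sum(np.pi * (r.diameter / 2) ** 2 * DERENZO_HEIGHT
                       for r in self.rods) / 1000.0
        if self.kind == "planar":
            # zero thickness; rate defined per area with a nominal 1 mm slab
            return (2 * PLANAR_HALF) ** 2 * 1.0 / 1000.0
        raise ConfigurationError(f"unknown phantom kind {self.kind!r}")


def _isotropic_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    ct = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    st = np.sqrt(1.0 - ct * ct)
    return np.column_stack([st * np.cos(phi), st * np.sin(phi), ct])


def _event_times(n: int, rate_per_s: float, rng: np.random.Generator):
    dt_ns = rng.exponential(1e9 / rate_per_s, n)
    return np.cumsum(dt_ns)


def build_derenzo_layout(diameters=DERENZO_DIAMETERS,
                         cylinder_radius: float = DERENZO_RADIUS,
                         margin: float = DERENZO_MARGIN) -> list[Rod]:
    """Place hot rods on per-sector triangular lattices.

    Sector s spans azimuth [60 s, 60 (s+1)) degrees.  Within a sector the
    lattice of constant 2d grows outward from the center along the sector
    bisector (rows of 1, 2, 3, ... rods).  A rod is kept iff its circle
    stays inside radius (cylinder_radius - margin) and its center keeps a
    clearance >= d from both sector boundary rays.
    """
    rods: list[Rod] = []
    r_use = cylinder_radius - margin
    for s, d in enumerate(diameters):
        theta = np.deg2rad(60.0 * s + 30.0)  # bisector azimuth
        bu = np.array([np.cos(theta), np.sin(theta)])
        bv = np.array([-np.sin(theta), np.cos(theta)])
        u0 = 2.0 * d
        row = 0
        while True:
            u = u0 + row * np.sqrt(3.0) * d
            if u - d / 2 > r_use:
                break
            for i in range(row + 1):
                v = (i - row / 2.0) * 2.0 * d
                c = u * bu + v * bv
                # clearance from the two boundary rays of the 60 deg wedge
                clear = u * np.sin(np.pi / 6) - abs(v) * np.cos(np.pi / 6)
                if clear < d - 1e-9:
                    continue
                if np.hypot(*c) + d / 2 > r_use + 1e-9:
                    continue
                rods.append(Rod(center=(float(c[0]), float(c[1])),
                                diameter=d, sector=s))
            row += 1
    return rods


def make_phantom(kind: str, activity_kbq_ml: float | None = None) -> PhantomSpec:
    if kind == "cuboid":
        return PhantomSpec("cuboid", activity_kbq_ml or CUBOID_ACTIVITY_KBQ_ML)
    if kind == "derenzo":
        return PhantomSpec("derenzo",
                           activity_kbq_ml or DERENZO_ACTIVITY_KBQ_ML,
                           rods=build_derenzo_layout())
    if kind == "planar":
        return PhantomSpec("planar", activity_kbq_ml or CUBOID_ACTIVITY_KBQ_ML)
    raise ConfigurationError(f"unknown phantom kind {kind!r}")


def sample_emissions(spec: PhantomSpec, n: int,
                     rng: np.random.Generator) -> EmissionBatch:
    """Draw n back-to-back pair emissions from a phantom."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if spec.kind == "cuboid":
        origins = rng.uniform(-CUBOID_HALF, CUBOID_HALF, (n, 3))
    elif spec.kind == "planar":
        xy = rng.uniform(-PLANAR_HALF, PLANAR_HALF, (n, 2))
        origins = np.column_stack([xy, np.zeros(n)])
    elif spec.kind == "derenzo":
        if not spec.rods:
            raise ConfigurationError("derenzo spec has no rods")
        vols = np.array([r.diameter ** 2 for r in spec.rods], float)
        idx = rng.choice(len(spec.rods), n, p=vols / vols.sum())
        radii = np.array([r.diameter / 2 for r in spec.rods])[idx]
        centers = np.array([r.center for r in spec.rods])[idx]
        rr = radii * np.sqrt(rng.uniform(0.0, 1.0, n))
        ang = rng.uniform(0.0, 2.0 * np.pi, n)
        origins = np.column_stack([
            centers[:, 0] + rr * np.cos(ang),
            centers[:, 1] + rr * np.sin(ang),
            rng.uniform(-DERENZO_HEIGHT / 2, DERENZO_HEIGHT / 2, n)])
    else:
        raise ConfigurationError(f"unknown phantom kind {spec.kind!r}")

    rate = spec.activity_kbq_ml * 1e3 * spec.active_volume_ml  # decays / s
    return EmissionBatch(origins=origins.astype(np.float32),
                         directions=_isotropic_directions(n, rng).astype(np.float32),
                         times=_event_times(n, rate, rng))
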