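"""Spatial model of the dual-panel PEM scanner.

Two parallel detector panels, each a 3x3 array of LYSO blocks, face each
other across a 60 mm gap along the z axis.  Inner crystal faces sit at
z = +/-30 mm and the crystals occupy 30 <= |z| <= 40 mm.  Each block is
either one monolithic 57.4 x 57.4 x 10 mm^3 crystal or a 40 x 40 array of
1.35 x 1.35 x 10 mm^3 crystals at 1.44 mm pitch separated by specular
reflector (modeled as vacuum for 511 keV transport).

Element ids are flat integers encoding (panel, block, pixel); -1 means
"not inside any crystal".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

MONOLITHIC = "monolithic"
PIXELATED = "pixelated"

BLOCK_SIZE_MONO = 57.4      # mm, monolithic crystal side
PIXELS_PER_SIDE = 40
PIXEL_SIZE = 1.35           # mm
PIXEL_PITCH = 1.44          # mm
# 40 pixels at 1.44 mm pitch span 57.6 mm; the pitch-derived footprint is
# the authoritative block size for the pixelated configuration.
BLOCK_SIZE_PIX = PIXELS_PER_SIDE * PIXEL_PITCH
CRYSTAL_THICKNESS = 10.0    # mm
BLOCKS_PER_SIDE = 3
DEFAULT_PANEL_GAP = 60.0    # mm, inner face to inner face


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ScannerGeometry:
    """Dual-panel scanner spatial model; distances in mm."""

    crystal_mode: str
    panel_gap: float = DEFAULT_PANEL_GAP
    crystal_thickness: float = CRYSTAL_THICKNESS
    blocks_per_panel: tuple[int, int] = (BLOCKS_PER_SIDE, BLOCKS_PER_SIDE)
    block_size: float = field(init=False, default=0.0)
    pixel_size: float = field(init=False, default=0.0)
    pixel_pitch: float = field(init=False, default=0.0)
    pixels_per_block: tuple[int, int] = field(init=False, default=(1, 1))
    reflector_gap: float = field(init=False, default=0.0)

    def __post_init__(self):
        if self.crystal_mode not in (MONOLITHIC, PIXELATED):
            raise ConfigurationError(
                f"unknown crystal mode {self.crystal_mode!r}")
        if self.panel_gap <= 0:
            raise ConfigurationError("panel_gap must be positive")
        if self.crystal_mode == MONOLITHIC:
            object.__setattr__(self, "block_size", BLOCK_SIZE_MONO)
            object.__setattr__(self, "pixel_size", BLOCK_SIZE_MONO)
            object.__setattr__(self, "pixel_pitch", BLOCK_SIZE_MONO)
            object.__setattr__(self, "pixels_per_block", (1, 1))
            object.__setattr__(self, "reflector_gap", 0.0)
        else:
            object.__setattr__(self, "block_size", BLOCK_SIZE_PIX)
            object.__setattr__(self, "pixel_size", PIXEL_SIZE)
            object.__setattr__(self, "pixel_pitch", PIXEL_PITCH)
            object.__setattr__(self, "pixels_per_block",
                               (PIXELS_PER_SIDE, PIXELS_PER_SIDE))
            object.__setattr__(self, "reflector_gap",
                               PIXEL_PITCH - PIXEL_SIZE)

    # -- derived quantities -------------------------------------------------

    @property
    def panel_span(self) -> float:
        """Sensitive extent of a panel in x and y (mm)."""
        return self.blocks_per_panel[0] * self.block_size

    @property
    def z_inner(self) -> float:
        return self.panel_gap / 2.0

    @property
    def z_outer(self) -> float:
        return self.panel_gap / 2.0 + self.crystal_thickness

    @property
    def n_blocks(self) -> int:
        return 2 * self.blocks_per_panel[0] * self.blocks_per_panel[1]

    @property
    def pixels_in_block(self) -> int:
        return self.pixels_per_block[0] * self.pixels_per_block[1]

    @property
    def n_crystals(self) -> int:
        """Total crystal element count over both panels."""
        return self.n_blocks * self.pixels_in_block

    @property
    def lyso_volume_per_panel(self) -> float:
        """Sensitive LYSO volume of one panel (mm^3)."""
        n_blocks = self.blocks_per_panel[0] * self.blocks_per_panel[1]
        return (n_blocks * self.pixels_in_block
                * self.pixel_size ** 2 * self.crystal_thickness)

    # -- element id plumbing ------------------------------------------------

    def element_id(self, panel: int, block: int, pixel: int) -> int:
        nb = self.blocks_per_panel[0] * self.blocks_per_panel[1]
        return (panel * nb + block) * self.pixels_in_block + pixel

    def block_of(self, element_id) -> np.ndarray:
        """Global block index (0..17) of an element id; panel = block // 9."""
        return np.asarray(element_id) // self.pixels_in_block

    # -- queries ------------------------------------------------------------

    def locate(self, points) -> np.ndarray:
        """Element id containing each point, or -1.

        Boundaries are half-open, lower-edge inclusive, on every axis.
        Accepts a single (3,) point or an (n, 3) array.
        """
        pts = np.atleast_2d(np.asarray(points, float))
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        out = np.full(len(pts), -1, dtype=np.int64)

        panel = np.where(z >= 0, 1, 0)
        az = np.abs(z)
        # lower-inclusive in the panel's outward direction
        in_z = np.where(z >= 0,
                        (z >= self.z_inner) & (z < self.z_outer),
                        (z > -self.z_outer) & (z <= -self.z_inner))

        half = self.panel_span / 2.0
        u, v = x + half, y + half
        in_plane = (u >= 0) & (u < self.panel_span) & (v >= 0) & (v < self.panel_span)
        ok = in_z & in_plane
        if not ok.any():
            return out if np.ndim(points) > 1 else out[:1]

        bs = self.block_size
        bx = np.floor_divide(u, bs).astype(np.int64)
        by = np.floor_divide(v, bs).astype(np.int64)
        block = by * self.blocks_per_panel[0] + bx

        if self.crystal_mode == MONOLITHIC:
            pixel = np.zeros(len(pts), dtype=np.int64)
            in_crystal = ok
        else:
            lu = u - bx * bs
            lv = v - by * bs
            px = np.floor_divide(lu, self.pixel_pitch).astype(np.int64)
            py = np.floor_divide(lv, self.pixel_pitch).astype(np.int64)
            margin = self.reflector_gap / 2.0
            fu = lu - px * self.pixel_pitch
            fv = lv - py * self.pixel_pitch
            in_pix = ((fu >= margin) & (fu < margin + self.pixel_size)
                      & (fv >= margin) & (fv < margin + self.pixel_size))
            pixel = py * self.pixels_per_block[0] + px
            in_crystal = ok & in_pix

        nb = self.blocks_per_panel[0] * self.blocks_per_panel[1]
        ids = ((panel * nb + block) * self.pixels_in_block + pixel)
        out[in_crystal] = ids[in_crystal]
        return out if np.ndim(points) > 1 else out[0]

    def ray_crystal_intersections(self, origin, direction, n_steps: int = 4096):
        """Ordered (element_id, entry_length, exit_length) crystal segments.

        Computed by uniform fine sampling of `locate` along the ray between
        the slab bounds — adequate as reference plumbing (transport uses
        Woodcock delta-tracking, which needs no explicit segments).
        """
        origin = np.asarray(origin, float)
        direction = np.asarray(direction, float)
        if not np.isclose(np.linalg.norm(direction), 1.0, atol=1e-9):
            raise ValueError("direction must be a unit vector")

        # restrict sampling to path lengths where |z| can be inside a slab
        tmax_candidates = []
        if abs(direction[2]) > 1e-12:
            for zb in (-self.z_outer, -self.z_inner, self.z_inner, self.z_outer):
                t = (zb - origin[2]) / direction[2]
                if t > 0:
                    tmax_candidates.append(t)
        span = 2 * (self.z_outer + self.panel_span)
        tmax = min(max(tmax_candidates), span) if tmax_candidates else span

        ts = np.linspace(0.0, tmax, n_steps)
        pts = origin[None, :] + ts[:, None] * direction[None, :]
        ids = self.locate(pts)

        segments = []
        dt = ts[1] - ts[0] if n_steps > 1 else 0.0
        cur_id, t_start = -1, 0.0
        for i, eid in enumerate(ids):
            if eid != cur_id:
                if cur_id >= 0:
                    segments.append((int(cur_id), t_start, ts[i] - dt / 2))
                cur_id = eid
                t_start = ts[i] - dt / 2 if i > 0 else 0.0
        if cur_id >= 0:
            segments.append((int(cur_id), t_start, ts[-1]))
        return segments

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps({"crystal_mode": d["crystal_mode"],
                           "panel_gap": d["panel_gap"]}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ScannerGeometry":
        d = json.loads(text)
        return build_geometry(d["crystal_mode"], d.get("panel_gap", DEFAULT_PANEL_GAP))


def build_geometry(mode: str, panel_gap: float = DEFAULT_PANEL_GAP) -> ScannerGeometry:
    """Construct the scanner model for a crystal configuration."""
    return ScannerGeometry(crystal_mode=mode, panel_gap=panel_gap)
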