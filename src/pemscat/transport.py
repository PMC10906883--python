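"""Monte Carlo transport of annihilation photons through the LYSO panels.

Each 511 keV photon is tracked by Woodcock delta-tracking inside the panel
slab its initial direction points to, with the LYSO total attenuation
coefficient as majorant: tentative collision points falling in reflector
gaps, inter-block spaces or outside the sensitive span are virtual, so the
photon statistics are exactly those of segment-by-segment exponential
attenuation in the crystals.  At a real collision the process is chosen
with probability mu_pe/mu_tot vs mu_cs/mu_tot; photoelectric absorption
deposits the remaining energy and ends the chain, Compton scattering
deposits E - E' locally (no secondary-electron transport) and continues
with a Klein-Nishina sampled direction.  A chain ends on photoelectric
absorption or when the photon leaves the slab in which it interacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .geometry import ScannerGeometry, PIXELATED
from .physics import CrossSectionTable, MEC2_KEV

C_MM_PER_NS = 299.792458
MAX_CHAIN = 64

INTERACTION_CS = 0
INTERACTION_PE = 1


@dataclass
class HitTable:
    """Columnar record of photon interactions (one row per hit)."""

    event_id: np.ndarray      # int64
    photon_index: np.ndarray  # int8, 0 or 1
    hit_order: np.ndarray     # int16, 1-based along the chain
    position: np.ndarray      # (n, 3) float32, mm
    energy_deposited: np.ndarray  # float32, keV
    interaction: np.ndarray   # int8: 0 = Compton, 1 = photoelectric
    element_id: np.ndarray    # int64
    time: np.ndarray          # float64, ns
    terminal_pe: np.ndarray   # bool, chain-terminating flag per hit

    def __len__(self):
        return len(self.event_id)


@njit(cache=True, inline="always")
def _locate(x, y, z, mode_pix, z_inner, z_outer, half_span, block_size,
            pitch, pix_lo, pix_hi):
    """Return (in_crystal, element_id) for a point; -1 if not in crystal."""
    if z >= 0.0:
        if z < z_inner or z >= z_outer:
            return False, np.int64(-1)
        panel = 1
    else:
        if z <= -z_outer or z > -z_inner:
            return False, np.int64(-1)
        panel = 0
    u = x + half_span
    v = y + half_span
    span = 2.0 * half_span
    if u < 0.0 or u >= span or v < 0.0 or v >= span:
        return False, np.int64(-1)
    bx = int(u // block_size)
    by = int(v // block_size)
    block = by * 3 + bx
    if mode_pix:
        lu = u - bx * block_size
        lv = v - by * block_size
        px = int(lu // pitch)
        py = int(lv // pitch)
        fu = lu - px * pitch
        fv = lv - py * pitch
        if fu < pix_lo or fu >= pix_hi or fv < pix_lo or fv >= pix_hi:
            return False, np.int64(-1)
        pixel = py * 40 + px
        return True, np.int64((panel * 9 + block) * 1600 + pixel)
    return True, np.int64(panel * 9 + block)


@njit(cache=True, inline="always")
def _kn_sample_cos(E):
    """Klein-Nishina polar angle cosine by rejection (bound 2 at theta=0)."""
    k = E / MEC2_KEV
    while True:
        ct = 2.0 * np.random.random() - 1.0
        r = 1.0 / (1.0 + k * (1.0 - ct))
        f = r * r * (r + 1.0 / r - (1.0 - ct * ct))
        if 2.0 * np.random.random() <= f:
            return ct


@njit(cache=True, inline="always")
def _rotate(dx, dy, dz, ct, phi):
    """Rotate unit vector d by polar angle acos(ct) about itself."""
    st = np.sqrt(max(0.0, 1.0 - ct * ct))
    cp = np.cos(phi)
    sp = np.sin(phi)
    if abs(dz) < 0.99999:
        # u = d x z_hat (normalized), v = d x u; (u, v, d) orthonormal
        norm = np.sqrt(dx * dx + dy * dy)
        ux, uy, uz = dy / norm, -dx / norm, 0.0
        vx = dz * dx / norm
        vy = dz * dy / norm
        vz = -norm
    else:
        ux, uy, uz = 1.0, 0.0, 0.0
        vx, vy, vz = 0.0, dz, 0.0
    nx = ct * dx + st * (cp * ux + sp * vx)
    ny = ct * dy + st * (cp * uy + sp * vy)
    nz = ct * dz + st * (cp * uz + sp * vz)
    n = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / n, ny / n, nz / n


@njit(cache=True)
def _track_kernel(origins, dirs, times, seed,
                  mode_pix, z_inner, z_outer, half_span, block_size,
                  pitch, pix_lo, pix_hi,
                  E0, dE, mu_pe_grid, mu_tot_grid,
                  h_event, h_photon, h_order, h_pos, h_edep, h_type,
                  h_elem, h_time, h_term):
    np.random.seed(seed)
    n = origins.shape[0]
    ngrid = mu_tot_grid.shape[0]
    count = 0
    cap = h_event.shape[0]
    for i in range(n):
        for ph in range(2):
            sgn = 1.0 if ph == 0 else -1.0
            dx = sgn * dirs[i, 0]
            dy = sgn * dirs[i, 1]
            dz = sgn * dirs[i, 2]
            if abs(dz) < 1e-12:
                continue
            # advance to the inner face of the slab this photon points at
            if dz > 0.0:
                t_entry = (z_inner - origins[i, 2]) / dz
                zlo, zhi = z_inner, z_outer
            else:
                t_entry = (-z_inner - origins[i, 2]) / dz
                zlo, zhi = -z_outer, -z_inner
            if t_entry < 0.0:
                continue
            x = origins[i, 0] + t_entry * dx
            y = origins[i, 1] + t_entry * dy
            z = origins[i, 2] + t_entry * dz
            path = t_entry
            E = 511.0
            order = 0
            for _ in range(MAX_CHAIN * 64):
                idx = int((E - E0) / dE)
                if idx < 0:
                    idx = 0
                elif idx >= ngrid:
                    idx = ngrid - 1
                mu = mu_tot_grid[idx]  # cm^-1
                step = -np.log(1.0 - np.random.random()) * 10.0 / mu
                x += step * dx
                y += step * dy
                z += step * dz
                path += step
                if z < zlo or z >= zhi:
                    break  # escaped the slab
                ok, elem = _locate(x, y, z, mode_pix, z_inner, z_outer,
                                   half_span, block_size, pitch, pix_lo,
                                   pix_hi)
                if not ok:
                    continue  # virtual collision (gap / outside blocks)
                p_pe = mu_pe_grid[idx] / mu
                order += 1
                if order > MAX_CHAIN:
                    break
                if count >= cap:
                    return count
                t_hit = times[i] + path / C_MM_PER_NS
                if np.random.random() < p_pe:
                    h_event[count] = i
                    h_photon[count] = ph
                    h_order[count] = order
                    h_pos[count, 0] = x
                    h_pos[count, 1] = y
                    h_pos[count, 2] = z
                    h_edep[count] = E
                    h_type[count] = 1
                    h_elem[count] = elem
                    h_time[count] = t_hit
                    h_term[count] = True
                    count += 1
                    break
                ct = _kn_sample_cos(E)
                Ep = E / (1.0 + (E / MEC2_KEV) * (1.0 - ct))
                phi = 2.0 * np.pi * np.random.random()
                h_event[count] = i
                h_photon[count] = ph
                h_order[count] = order
                h_pos[count, 0] = x
                h_pos[count, 1] = y
                h_pos[count, 2] = z
                h_edep[count] = E - Ep
                h_type[count] = 0
                h_elem[count] = elem
                h_time[count] = t_hit
                h_term[count] = False
                count += 1
                dx, dy, dz = _rotate(dx, dy, dz, ct, phi)
                E = Ep
        # next emission
    return count


def run_transport(geometry: ScannerGeometry, xs: CrossSectionTable,
                  emissions, seed: int, hits_per_pair: float = 4.0,
                  chunk_pairs: int = 2_000_000) -> HitTable:
    """Track both photons of every emission; returns the hit table.

    `emissions` provides origins (n,3), directions (n,3) and times (n,) in
    mm / ns.  `seed` drives the kernel RNG (one stream per chunk; large
    runs are processed in chunks of `chunk_pairs` to bound memory).
    """
    n = len(emissions.times)
    if n > chunk_pairs:
        seeds = np.random.SeedSequence(seed).generate_state(
            (n + chunk_pairs - 1) // chunk_pairs) & 0x7FFFFFFF
        parts = []
        for k, lo in enumerate(range(0, n, chunk_pairs)):
            hi = min(lo + chunk_pairs, n)
            sub = type(emissions)(origins=emissions.origins[lo:hi],
                                  directions=emissions.directions[lo:hi],
                                  times=emissions.times[lo:hi])
            part = run_transport(geometry, xs, sub, int(seeds[k]),
                                 hits_per_pair, chunk_pairs)
            part.event_id += lo
            parts.append(part)
        return HitTable(**{f: np.concatenate([getattr(p, f) for p in parts])
                           for f in HitTable.__dataclass_fields__})

    origins = np.ascontiguousarray(emissions.origins, dtype=np.float64)
    dirs = np.ascontiguousarray(emissions.directions, dtype=np.float64)
    times = np.ascontiguousarray(emissions.times, dtype=np.float64)
    cap = max(1024, int(hits_per_pair * n))

    E0_grid, mu_pe_grid, mu_tot_grid = xs.fine_grid()
    dE = float(E0_grid[1] - E0_grid[0])

    h_event = np.empty(cap, np.int64)
    h_photon = np.empty(cap, np.int8)
    h_order = np.empty(cap, np.int16)
    h_pos = np.empty((cap, 3), np.float32)
    h_edep = np.empty(cap, np.float32)
    h_type = np.empty(cap, np.int8)
    h_elem = np.empty(cap, np.int64)
    h_time = np.empty(cap, np.float64)
    h_term = np.zeros(cap, np.bool_)

    mode_pix = geometry.crystal_mode == PIXELATED
    margin = geometry.reflector_gap / 2.0
    count = _track_kernel(
        origins, dirs, times, np.uint32(seed & 0x7FFFFFFF),
        mode_pix, geometry.z_inner, geometry.z_outer,
        geometry.panel_span / 2.0, geometry.block_size,
        geometry.pixel_pitch, margin, margin + geometry.pixel_size,
        float(E0_grid[0]), dE,
        np.ascontiguousarray(mu_pe_grid), np.ascontiguousarray(mu_tot_grid),
        h_event, h_photon, h_order, h_pos, h_edep, h_type, h_elem, h_time,
        h_term)
    if count >= cap:
        raise RuntimeError("hit buffer overflow; raise hits_per_pair")

    sl = slice(0, count)
    return HitTable(event_id=h_event[sl].copy(),
                    photon_index=h_photon[sl].copy(),
                    hit_order=h_order[sl].copy(),
                    position=h_pos[sl].copy(),
                    energy_deposited=h_edep[sl].copy(),
                    interaction=h_type[sl].copy(),
                    element_id=h_elem[sl].copy(),
                    time=h_time[sl].copy(),
                    terminal_pe=h_term[sl].copy())


def track_photon(emission_origin, direction, geometry: ScannerGeometry,
                 xs: CrossSectionTable, seed: int, time_ns: float = 0.0):
    """Track a single photon; convenience wrapper over the batch kernel."""
    from .sources import EmissionBatch
    d = np.asarray(direction, float)
    batch = EmissionBatch(origins=np.asarray(emission_origin, float)[None, :],
                          directions=d[None, :],
                          times=np.array([time_ns]))
    hits = run_transport(geometry, xs, batch, seed)
    keep = hits.photon_index == 0
    return HitTable(**{k: getattr(hits, k)[keep] for k in
                       ("event_id", "photon_index", "hit_order", "position",
                        "energy_deposited", "interaction", "element_id",
                        "time", "terminal_pe")})
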