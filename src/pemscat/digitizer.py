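"""Digitizer chain: hits -> singles -> coincidences.

Mirrors a conventional PET acquisition chain: per-photon hit merging
(energy-weighted centroid + first-hit position), Gaussian energy blurring
(13% FWHM at 511 keV, 1/sqrt(E) scaling), non-paralyzable per-block dead
time (6 us), a 350-750 keV energy window and a 6 ns coincidence window
between opposite panels.  Windows containing more than two qualifying
singles are discarded entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ScannerGeometry
from .transport import HitTable

ENERGY_RESOLUTION_511 = 0.13
DEAD_TIME_US = 6.0
COINC_WINDOW_NS = 6.0
ENERGY_WINDOW_KEV = (350.0, 750.0)
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

CLASS_SI_SI = 0
CLASS_MI_SI = 1
CLASS_MI_MI = 2
CLASS_NAMES = {CLASS_SI_SI: "SI-SI", CLASS_MI_SI: "MI-SI", CLASS_MI_MI: "MI-MI"}


class DataError(ValueError):
    pass


@dataclass
class SingleTable:
    """Per-photon detector responses, one row per single."""

    event_id: np.ndarray
    photon_index: np.ndarray
    ewp: np.ndarray            # (n, 3) energy-weighted centroid, mm
    fhp: np.ndarray            # (n, 3) first-hit position, mm
    energy_true: np.ndarray    # keV
    energy_blurred: np.ndarray  # keV (NaN until blurred)
    panel: np.ndarray          # 0 (-z) or 1 (+z)
    n_hits: np.ndarray
    n_compton: np.ndarray
    terminal_pe: np.ndarray    # chain ended in photoelectric absorption
    block: np.ndarray          # global block index 0..17 (first hit)
    time: np.ndarray           # ns

    def __len__(self):
        return len(self.time)

    def select(self, mask) -> "SingleTable":
        return SingleTable(**{k: getattr(self, k)[mask]
                              for k in self.__dataclass_fields__})


@dataclass
class CoincidenceTable:
    """Pairs of singles in opposite panels inside the timing window.

    idx_a / idx_b index into the SingleTable this was built from; a is the
    -z panel single, b the +z one.
    """

    idx_a: np.ndarray
    idx_b: np.ndarray
    coincidence_class: np.ndarray  # 0 SI-SI, 1 MI-SI, 2 MI-MI
    is_random: np.ndarray

    def __len__(self):
        return len(self.idx_a)


def make_singles(hits: HitTable, geometry: ScannerGeometry) -> SingleTable:
    """Merge each photon's hits into one single.

    Hits of one photon are contiguous in the table and ordered along the
    chain, so groups reduce to run boundaries.
    """
    n = len(hits)
    if n == 0:
        raise DataError("empty hit table")
    key = hits.event_id * 2 + hits.photon_index
    starts = np.concatenate([[0], np.flatnonzero(np.diff(key)) + 1])
    bounds = np.concatenate([starts, [n]])

    z_sign = hits.position[:, 2] >= 0
    if np.any(z_sign[starts] != z_sign[bounds[1:] - 1]):
        raise DataError("a photon's hits span both panels")

    edep = hits.energy_deposited.astype(np.float64)
    e_tot = np.add.reduceat(edep, starts)
    ewp = (np.add.reduceat(edep[:, None] * hits.position.astype(np.float64),
                           starts, axis=0) / e_tot[:, None])
    n_hits = np.diff(bounds)
    n_compton = np.add.reduceat((hits.interaction == 0).astype(np.int64), starts)

    singles = SingleTable(
        event_id=hits.event_id[starts],
        photon_index=hits.photon_index[starts],
        ewp=ewp.astype(np.float32),
        fhp=hits.position[starts].copy(),
        energy_true=e_tot.astype(np.float32),
        energy_blurred=np.full(len(starts), np.nan, np.float32),
        panel=z_sign[starts].astype(np.int8),
        n_hits=n_hits.astype(np.int32),
        n_compton=n_compton.astype(np.int16),
        terminal_pe=hits.terminal_pe[bounds[1:] - 1].copy(),
        block=geometry.block_of(hits.element_id[starts]).astype(np.int16),
        time=hits.time[starts].copy(),
    )
    order = np.argsort(singles.time, kind="stable")
    return singles.select(order)


def blur_energy(E, resolution_at_511: float, rng: np.random.Generator):
    """Gaussian energy blurring with FWHM(E) = R511 * sqrt(511 E)."""
    E = np.asarray(E, float)
    if np.any(E <= 0):
        raise ValueError("energies must be positive")
    sigma = resolution_at_511 * np.sqrt(511.0 * E) / FWHM_TO_SIGMA
    return E + sigma * rng.standard_normal(E.shape)


def apply_dead_time(singles: SingleTable, tau_us: float = DEAD_TIME_US,
                    n_blocks: int = 18) -> SingleTable:
    """Non-paralyzable per-block dead time on time-sorted singles."""
    t = singles.time
    if np.any(np.diff(t) < 0):
        raise DataError("singles must be time-sorted")
    if tau_us <= 0:
        return singles
    tau_ns = tau_us * 1e3
    last = np.full(n_blocks, -np.inf)
    keep = np.ones(len(singles), dtype=bool)
    blocks = singles.block
    for i in range(len(singles)):
        b = blocks[i]
        if t[i] - last[b] < tau_ns:
            keep[i] = False
        else:
            last[b] = t[i]
    return singles.select(keep)


def sort_coincidences(singles: SingleTable,
                      window_ns: float = COINC_WINDOW_NS,
                      energy_window=ENERGY_WINDOW_KEV):
    """Form coincidences from blurred, time-sorted singles.

    Returns (accepted_singles, CoincidenceTable): singles inside the energy
    window, and index pairs for clusters of exactly two singles in opposite
    panels whose times differ by <= window_ns.  Clusters of three or more
    qualifying singles are discarded.
    """
    if np.any(np.isnan(singles.energy_blurred)):
        raise DataError("singles must be energy-blurred first")
    if energy_window is not None:
        lo, hi = energy_window
        acc = singles.select((singles.energy_blurred >= lo)
                             & (singles.energy_blurred <= hi))
    else:
        acc = singles

    t = acc.time
    if len(t) < 2:
        return acc, CoincidenceTable(*[np.empty(0, np.int64)] * 2,
                                     coincidence_class=np.empty(0, np.int8),
                                     is_random=np.empty(0, bool))

    new_cluster = np.concatenate([[True], np.diff(t) > window_ns])
    cluster_id = np.cumsum(new_cluster) - 1
    counts = np.bincount(cluster_id)
    pair_clusters = np.flatnonzero(counts == 2)
    starts = np.concatenate([[0], np.cumsum(counts)])[:-1]

    ia = starts[pair_clusters]
    ib = ia + 1
    opposite = acc.panel[ia] != acc.panel[ib]
    ia, ib = ia[opposite], ib[opposite]
    # order: a in -z panel
    swap = acc.panel[ia] == 1
    ia2 = np.where(swap, ib, ia)
    ib2 = np.where(swap, ia, ib)

    mi_a = acc.n_hits[ia2] >= 2
    mi_b = acc.n_hits[ib2] >= 2
    cls = (mi_a.astype(np.int8) + mi_b.astype(np.int8))
    # 0 -> SI-SI, 1 -> MI-SI, 2 -> MI-MI matches the class constants
    is_random = acc.event_id[ia2] != acc.event_id[ib2]
    return acc, CoincidenceTable(idx_a=ia2.astype(np.int64),
                                 idx_b=ib2.astype(np.int64),
                                 coincidence_class=cls,
                                 is_random=is_random)


def digitize(hits: HitTable, geometry: ScannerGeometry,
             rng: np.random.Generator,
             resolution_at_511: float = ENERGY_RESOLUTION_511,
             tau_us: float = DEAD_TIME_US,
             window_ns: float = COINC_WINDOW_NS,
             energy_window=ENERGY_WINDOW_KEV):
    """Full digitizer chain; returns (accepted singles, coincidences)."""
    singles = make_singles(hits, geometry)
    if resolution_at_511 > 0:
        singles.energy_blurred = blur_energy(singles.energy_true,
                                             resolution_at_511, rng)
    else:
        singles.energy_blurred = singles.energy_true.copy()
    singles = apply_dead_time(singles, tau_us)
    return sort_coincidences(singles, window_ns, energy_window)
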