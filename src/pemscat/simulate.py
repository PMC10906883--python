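"""High-level study drivers: phantom -> transport -> digitizer -> recon.

These functions wire the modules together the way the study runs them and
are what the CLI and the acceptance analyses call.  All randomness flows
from a single integer seed per run via `numpy.random.SeedSequence`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ScannerGeometry, build_geometry
from .physics import build_lyso_table, CrossSectionTable
from .sources import make_phantom, sample_emissions, PhantomSpec
from .transport import run_transport, HitTable
from .digitizer import digitize, SingleTable, CoincidenceTable
from .recon import (ImageGrid, Image3D, to_virtual_lors, build_sensitivity,
                    lm_osem, gaussian_post_filter)


@dataclass
class StudyRun:
    geometry: ScannerGeometry
    phantom: PhantomSpec
    n_emissions: int
    hits: HitTable
    singles: SingleTable
    coincidences: CoincidenceTable


def _child_seeds(seed: int, n: int):
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(n)]


def run_study(mode: str, phantom_kind: str, n_emissions: int, seed: int,
              xs: CrossSectionTable | None = None,
              geometry: ScannerGeometry | None = None,
              activity_kbq_ml: float | None = None,
              keep_hits: bool = False) -> StudyRun:
    """Simulate one acquisition and run the full digitizer chain."""
    geometry = geometry or build_geometry(mode)
    xs = xs or build_lyso_table()
    s_src, s_tr, s_dig = _child_seeds(seed, 3)
    phantom = make_phantom(phantom_kind, activity_kbq_ml)
    emissions = sample_emissions(phantom, n_emissions,
                                 np.random.default_rng(s_src))
    hits = run_transport(geometry, xs, emissions, s_tr)
    singles, coincidences = digitize(hits, geometry,
                                     np.random.default_rng(s_dig))
    return StudyRun(geometry=geometry, phantom=phantom,
                    n_emissions=n_emissions,
                    hits=hits if keep_hits else None,
                    singles=singles, coincidences=coincidences)


def reconstruct(run: StudyRun, norm_run: StudyRun, position_mode: str,
                iterations: int = 2, subsets: int = 28,
                filter_fwhm_mm: float = 0.0,
                grid: ImageGrid | None = None) -> Image3D:
    """Reconstruct a study run against a normalization acquisition."""
    grid = grid or ImageGrid()
    na, nb = to_virtual_lors(norm_run.singles, norm_run.coincidences,
                             norm_run.geometry, position_mode)
    sens = build_sensitivity(na, nb, grid)
    la, lb = to_virtual_lors(run.singles, run.coincidences, run.geometry,
                             position_mode)
    img = lm_osem(la, lb, sens, iterations, subsets)
    if filter_fwhm_mm > 0:
        img = gaussian_post_filter(img, filter_fwhm_mm)
    return img


def derenzo_pipeline(mode: str, seed: int, n_derenzo: int = 13_600_000,
                     n_norm: int = 8_000_000, iterations: int = 2,
                     subsets: int = 28, filter_fwhm_mm: float = 0.0):
    """Derenzo study + planar normalization + FHP and EWP reconstructions.

    Returns (study run, {"fhp": Image3D, "ewp": Image3D}); both images come
    from the same coincidence set, differing only in LOR endpoints.
    """
    s_study, s_norm = _child_seeds(seed, 2)
    xs = build_lyso_table()
    run = run_study(mode, "derenzo", n_derenzo, s_study, xs=xs)
    norm = run_study(mode, "planar", n_norm, s_norm, xs=xs)
    images = {pm: reconstruct(run, norm, pm, iterations, subsets,
                              filter_fwhm_mm)
              for pm in ("fhp", "ewp")}
    return run, images


# ---------------------------------------------------------------------------
# columnar I/O


def save_coincidence_file(path, run: StudyRun, seed: int | None = None):
    """Write singles + coincidences (the list-mode file) to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["crystal_mode"] = run.geometry.crystal_mode
        f.attrs["panel_gap_mm"] = run.geometry.panel_gap
        f.attrs["phantom"] = run.phantom.kind
        f.attrs["n_emissions"] = run.n_emissions
        if seed is not None:
            f.attrs["seed"] = seed
        g = f.create_group("singles")
        for k in ("event_id", "photon_index", "ewp", "fhp", "energy_true",
                  "energy_blurred", "panel", "n_hits", "n_compton",
                  "terminal_pe", "block", "time"):
            g.create_dataset(k, data=getattr(run.singles, k))
        g = f.create_group("coincidences")
        for k in ("idx_a", "idx_b", "coincidence_class", "is_random"):
            g.create_dataset(k, data=getattr(run.coincidences, k))


def load_coincidence_file(path):
    """Read a list-mode file back into (geometry, singles, coincidences)."""
    import h5py

    with h5py.File(path, "r") as f:
        geometry = build_geometry(f.attrs["crystal_mode"],
                                  float(f.attrs["panel_gap_mm"]))
        s = {k: f["singles"][k][...] for k in f["singles"]}
        c = {k: f["coincidences"][k][...] for k in f["coincidences"]}
    return geometry, SingleTable(**s), CoincidenceTable(**c)
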