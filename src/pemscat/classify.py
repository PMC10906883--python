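"""Interaction-chain statistics and positioning-error analysis.

Coincidences are classed SI-SI / MI-SI / MI-MI by per-photon hit count
(single vs multiple interaction).  Per-photon chains are labeled by the
number of Compton scatterings and whether the chain terminated in
photoelectric absorption (PE, CS1->PE ... CS4+->PE) or escaped.  The
positioning error of a multiple-interaction photon is the in-plane
distance between its energy-weighted centroid and its first-hit position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .digitizer import (SingleTable, CoincidenceTable, CLASS_SI_SI,
                        CLASS_MI_SI, CLASS_MI_MI, CLASS_NAMES)

CHAIN_LABELS = ("PE", "CS1_escape", "CS1_PE", "CS2_PE", "CS3_PE",
                "CS4p_PE", "escape")


def chain_label(n_hits, n_compton, terminal_pe) -> np.ndarray:
    """Vectorized chain labels (indices into CHAIN_LABELS)."""
    n_hits = np.asarray(n_hits)
    n_compton = np.asarray(n_compton)
    terminal_pe = np.asarray(terminal_pe, bool)
    out = np.full(n_hits.shape, CHAIN_LABELS.index("escape"), np.int8)
    out[(n_compton == 0) & terminal_pe] = CHAIN_LABELS.index("PE")
    out[(n_compton == 1) & ~terminal_pe & (n_hits == 1)] = \
        CHAIN_LABELS.index("CS1_escape")
    for n, name in ((1, "CS1_PE"), (2, "CS2_PE"), (3, "CS3_PE")):
        out[(n_compton == n) & terminal_pe] = CHAIN_LABELS.index(name)
    out[(n_compton >= 4) & terminal_pe] = CHAIN_LABELS.index("CS4p_PE")
    return out


@dataclass
class ChainStats:
    n_coincidences: int
    class_fractions: dict      # {"SI-SI": f, "MI-SI": f, "MI-MI": f}
    chain_fractions: dict      # per accepted coincidence photon
    cs_pe_split: dict          # among CS...->PE chains, split by count
    mi_si_mi_chain_fractions: dict  # chains of the MI photon in MI-SI pairs
    random_fraction: float
    escape_coincidence_fraction: float


def classify_coincidences(singles: SingleTable,
                          coincidences: CoincidenceTable) -> ChainStats:
    """Chain statistics over registered coincidences."""
    nc = len(coincidences)
    cls = coincidences.coincidence_class
    class_fractions = {CLASS_NAMES[c]: float(np.mean(cls == c)) if nc else 0.0
                       for c in (CLASS_SI_SI, CLASS_MI_SI, CLASS_MI_MI)}

    idx = np.concatenate([coincidences.idx_a, coincidences.idx_b])
    labels = chain_label(singles.n_hits[idx], singles.n_compton[idx],
                         singles.terminal_pe[idx])
    nph = len(idx)
    chain_fractions = {name: float(np.mean(labels == i)) if nph else 0.0
                       for i, name in enumerate(CHAIN_LABELS)}

    # split of Compton-chains-ending-in-PE by number of scatterings
    cs_pe = {}
    cs_names = ("CS1_PE", "CS2_PE", "CS3_PE", "CS4p_PE")
    tot = sum(chain_fractions[n] for n in cs_names)
    for n in cs_names:
        cs_pe[n] = chain_fractions[n] / tot if tot > 0 else 0.0

    # chains of the multiple-interaction photon inside MI-SI coincidences
    mi_si = cls == CLASS_MI_SI
    ia, ib = coincidences.idx_a[mi_si], coincidences.idx_b[mi_si]
    mi_idx = np.where(singles.n_hits[ia] >= 2, ia, ib)
    mlab = chain_label(singles.n_hits[mi_idx], singles.n_compton[mi_idx],
                       singles.terminal_pe[mi_idx])
    mi_fr = {name: float(np.mean(mlab == i)) if len(mi_idx) else 0.0
             for i, name in enumerate(CHAIN_LABELS)}

    # coincidences where at least one photon's chain escaped
    esc = CHAIN_LABELS.index("escape")
    esc1 = CHAIN_LABELS.index("CS1_escape")
    esc_ph = np.isin(labels, (esc, esc1)).reshape(2, -1)
    escape_frac = float(np.mean(esc_ph.any(axis=0))) if nc else 0.0

    return ChainStats(
        n_coincidences=nc,
        class_fractions=class_fractions,
        chain_fractions=chain_fractions,
        cs_pe_split=cs_pe,
        mi_si_mi_chain_fractions=mi_fr,
        random_fraction=float(np.mean(coincidences.is_random)) if nc else 0.0,
        escape_coincidence_fraction=escape_frac,
    )


@dataclass
class PositioningErrors:
    delta_r_xy: np.ndarray  # per MI photon, mm
    delta_x: np.ndarray
    delta_y: np.ndarray
    mean: float = field(init=False)

    def __post_init__(self):
        self.mean = float(np.mean(self.delta_r_xy)) if len(self.delta_r_xy) else np.nan

    def percentile(self, q) -> float:
        return float(np.percentile(self.delta_r_xy, q))

    def cumulative_curve(self, bin_width_mm: float = 0.1,
                         max_mm: float = 25.0):
        edges = np.arange(0.0, max_mm + bin_width_mm, bin_width_mm)
        h, _ = np.histogram(self.delta_r_xy, bins=edges)
        cum = np.cumsum(h) / max(1, len(self.delta_r_xy))
        return edges[1:], cum


def positioning_errors(singles: SingleTable, coincidences: CoincidenceTable,
                       which=(CLASS_MI_SI, CLASS_MI_MI),
                       mi_only: bool = False) -> PositioningErrors:
    """In-plane EWP-FHP distances over photons of selected coincidences.

    By default both photons of every selected (multiple-interaction)
    coincidence contribute, so the SI partner of an MI-SI pair enters with
    its identically-zero error; SI-SI coincidences are excluded outright.
    Set mi_only=True to restrict to the MI photons themselves.
    """
    sel = np.isin(coincidences.coincidence_class, np.asarray(which))
    idx = np.concatenate([coincidences.idx_a[sel], coincidences.idx_b[sel]])
    if mi_only:
        idx = idx[singles.n_hits[idx] >= 2]
    d = singles.ewp[idx, :2] - singles.fhp[idx, :2]
    d[singles.n_hits[idx] == 1] = 0.0  # exact zero for SI photons
    return PositioningErrors(delta_r_xy=np.hypot(d[:, 0], d[:, 1]),
                             delta_x=d[:, 0], delta_y=d[:, 1])


def spectra(singles: SingleTable, coincidences: CoincidenceTable,
            bin_kev: float = 5.0, window=(350.0, 750.0)):
    """Blurred-energy histograms per coincidence class and chain label.

    Returns (bin_centers, {name: counts}) with classes "SI-SI"/"MI-SI"/
    "MI-MI" plus per-chain keys "CS1"/"CS2"/"CS3" for multiple-interaction
    photons.
    """
    edges = np.arange(window[0], window[1] + bin_kev, bin_kev)
    centers = 0.5 * (edges[:-1] + edges[1:])
    out = {}
    for c, name in CLASS_NAMES.items():
        sel = coincidences.coincidence_class == c
        idx = np.concatenate([coincidences.idx_a[sel],
                              coincidences.idx_b[sel]])
        out[name], _ = np.histogram(singles.energy_blurred[idx], bins=edges)
    idx = np.concatenate([coincidences.idx_a, coincidences.idx_b])
    lab = chain_label(singles.n_hits[idx], singles.n_compton[idx],
                      singles.terminal_pe[idx])
    for n, key in ((1, "CS1"), (2, "CS2"), (3, "CS3")):
        m = lab == CHAIN_LABELS.index(f"CS{n}_PE")
        out[key], _ = np.histogram(singles.energy_blurred[idx[m]], bins=edges)
    return centers, out


def photopeak_location(centers, counts) -> float:
    """Gaussian-fit photopeak position of one spectrum (keV)."""
    from scipy.optimize import curve_fit

    def g(x, a, mu, sig, b):
        return a * np.exp(-0.5 * ((x - mu) / sig) ** 2) + b

    p0 = (counts.max(), centers[np.argmax(counts)], 30.0, 0.0)
    popt, _ = curve_fit(g, centers, counts, p0=p0, maxfev=10000)
    return float(popt[1])
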