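"""Photon interaction physics for LYSO at PET energies.

Only the two processes relevant to 511 keV transport in the scintillator
are modeled: photoelectric absorption and (free-electron Klein-Nishina)
Compton scattering.  Rayleigh scattering, Doppler broadening, fluorescence
and secondary-electron transport are deliberately excluded; energy is
deposited at the interaction point.

Linear attenuation coefficients are built by the mixture rule from
elemental mass-attenuation tables shipped with the package, interpolated
log-log, and cached on a fine 1 keV grid for O(1) lookup inside the
transport kernel.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

MEC2_KEV = 510.99895

# GATE's conventional LYSO: Lu2(1-x)Y2xSiO5, x ~ 0.1, density 7.4 g/cm3
LYSO_DENSITY = 7.4  # g/cm^3
LYSO_MASS_FRACTIONS = {"lu": 0.714, "y": 0.040, "si": 0.064, "o": 0.181}

E_MIN_KEV = 10.0
E_MAX_KEV = 750.0


class CrossSectionDataError(ValueError):
    pass


def _load_element(name: str) -> np.ndarray:
    with resources.files("pemscat.data").joinpath(f"{name}.csv").open() as fh:
        return np.loadtxt(fh, delimiter=",", comments="#")


@dataclass(frozen=True)
class CrossSectionTable:
    """LYSO linear attenuation coefficients (cm^-1) on an energy grid (keV)."""

    energies: np.ndarray
    mu_pe: np.ndarray
    mu_cs: np.ndarray
    density: float = LYSO_DENSITY

    @property
    def mu_tot(self) -> np.ndarray:
        return self.mu_pe + self.mu_cs

    def _interp(self, coeff: np.ndarray, E) -> np.ndarray:
        E = np.asarray(E, float)
        if np.any(E < self.energies[0]) or np.any(E > self.energies[-1]):
            raise CrossSectionDataError(
                f"energy outside table range [{self.energies[0]}, "
                f"{self.energies[-1]}] keV")
        return np.exp(np.interp(np.log(E), np.log(self.energies),
                                np.log(coeff)))

    def mu_pe_at(self, E):
        return self._interp(self.mu_pe, E)

    def mu_cs_at(self, E):
        return self._interp(self.mu_cs, E)

    def mu_tot_at(self, E):
        return self.mu_pe_at(E) + self.mu_cs_at(E)

    def fine_grid(self, step_kev: float = 0.25):
        """(energies, mu_pe, mu_tot) on a uniform grid, for kernel lookup."""
        E = np.arange(self.energies[0], self.energies[-1] + step_kev, step_kev)
        E = np.minimum(E, self.energies[-1])
        pe = self.mu_pe_at(E)
        return E, pe, pe + self.mu_cs_at(E)


def build_lyso_table(mass_fractions: dict | None = None,
                     density: float = LYSO_DENSITY) -> CrossSectionTable:
    """Mixture-rule LYSO attenuation table from the elemental data files."""
    fractions = dict(mass_fractions or LYSO_MASS_FRACTIONS)
    grids = {}
    for el in fractions:
        try:
            grids[el] = _load_element(el)
        except FileNotFoundError as exc:
            raise CrossSectionDataError(f"no data table for element {el!r}") from exc
        cov = grids[el][:, 0]
        if cov[0] > E_MIN_KEV or cov[-1] < E_MAX_KEV:
            raise CrossSectionDataError(
                f"element {el!r} table does not cover [{E_MIN_KEV}, {E_MAX_KEV}] keV")

    energies = np.unique(np.concatenate([g[:, 0] for g in grids.values()]))
    energies = energies[(energies >= E_MIN_KEV) & (energies <= E_MAX_KEV)]
    mu_pe = np.zeros_like(energies)
    mu_cs = np.zeros_like(energies)
    for el, w in fractions.items():
        g = grids[el]
        lg = np.log(g[:, 0])
        pe = np.exp(np.interp(np.log(energies), lg, np.log(g[:, 1])))
        cs = np.exp(np.interp(np.log(energies), lg, np.log(g[:, 2])))
        mu_pe += density * w * pe
        mu_cs += density * w * cs
    return CrossSectionTable(energies=energies, mu_pe=mu_pe, mu_cs=mu_cs,
                             density=density)


# ---------------------------------------------------------------------------
# Klein-Nishina


def klein_nishina_dcs(E_kev: float, cos_theta) -> np.ndarray:
    """Unnormalized KN differential cross section d(sigma)/d(cos theta).

    In units of pi * r_e^2; the shape is what matters for sampling checks.
    """
    k = E_kev / MEC2_KEV
    ct = np.asarray(cos_theta, float)
    r = 1.0 / (1.0 + k * (1.0 - ct))  # E'/E
    return r * r * (r + 1.0 / r - (1.0 - ct * ct))


def compton_energy(E_kev, theta):
    """Scattered photon energy after a Compton event."""
    return E_kev / (1.0 + (E_kev / MEC2_KEV) * (1.0 - np.cos(theta)))


def sample_compton(E_kev: float, rng: np.random.Generator):
    """Sample one Compton scatter: returns (E_prime keV, theta, phi).

    Polar angle from the Klein-Nishina distribution by rejection against a
    uniform cos(theta) proposal (the forward-scatter value 2 bounds the
    unnormalized density for every energy); azimuth uniform.
    """
    if E_kev <= 0:
        raise ValueError("photon energy must be positive")
    while True:
        ct = rng.uniform(-1.0, 1.0)
        if rng.uniform(0.0, 2.0) <= klein_nishina_dcs(E_kev, ct):
            break
    theta = float(np.arccos(ct))
    phi = float(rng.uniform(0.0, 2.0 * np.pi))
    return float(compton_energy(E_kev, theta)), theta, phi


def sample_free_path(E_kev, xs: CrossSectionTable, rng: np.random.Generator,
                     size=None):
    """Exponential free path in LYSO at energy E, in mm."""
    mu = xs.mu_tot_at(E_kev)  # cm^-1
    return rng.exponential(10.0 / mu, size=size)  # mm
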