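"""Membrane electrostatics: Debye screening, Grahame surface potential, and
the screened probe-membrane repulsion model.

The anionic-lipid mole fraction n_PG sets a surface charge density
sigma = -e * n_PG / a_L (one elementary charge per PG headgroup, area per
lipid a_L = 0.70 nm^2).  The Grahame equation links sigma to the surface
potential phi_s in a symmetric 1:1 electrolyte; phi_s is linear in sigma in
the Debye-Huckel regime (|phi_s| < ~25 mV) and sublinear beyond.  A DNA
duplex probe of net charge -q_DNA*e held a distance d from the slipping
plane experiences a screened repulsion

    delta_eps = -q_DNA * e * delta_phi_s * exp(-kappa * d)      [Joules]

relative to the uncharged membrane, positive for the negative potentials of
anionic membranes.  At fixed d this is exactly linear in the potential, which
is why measured repulsion energies track the zeta potential of vesicles of
matching composition; fitting the single parameter d to (phi_z, delta_eps)
pairs locates the probe's charge centre relative to the slipping plane.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize_scalar

from .constants import (
    AREA_PER_LIPID_NM2,
    E_CHARGE,
    EPS0,
    EPS_R_WATER,
    IONIC_STRENGTH_MM,
    N_AVOGADRO,
    T_REF,
    kT_joules,
)

__all__ = [
    "ElectroModel",
    "debye_length",
    "sigma_from_n_pg",
    "grahame_potential",
    "eps_from_potential",
    "fit_probe_distance",
    "zeta_from_eps",
]


def debye_length(ionic_strength_mM: float, T: float = T_REF) -> float:
    """Debye screening length (nm) of a symmetric 1:1 electrolyte in water.

    lambda_D = sqrt(eps_r*eps0*kT / (2*N_A*e^2*I)) with I the ionic strength
    in mol/m^3; ~0.78 nm at physiological (150 mM) ionic strength, 298 K.
    """
    if ionic_strength_mM <= 0:
        raise ValueError("ionic strength must be positive")
    I_molar = ionic_strength_mM * 1e-3  # mol/L
    I_si = I_molar * 1e3 * N_AVOGADRO  # ions of each sign per m^3
    lam = np.sqrt(EPS_R_WATER * EPS0 * kT_joules(T) / (2.0 * I_si * E_CHARGE**2))
    return float(lam * 1e9)


@dataclass(frozen=True)
class ElectroModel:
    """Physical state of the screened probe-membrane interaction.

    Attributes
    ----------
    q_dna : probe charge magnitude in elementary charges (48-bp duplex: 24;
        the duplex is anionic, the sign is carried by the model).
    lambda_d_nm : Debye length; the default reproduces PBS-strength buffer.
    d_nm : separation of the probe charge centre from the potential plane.
    T : temperature, K.
    ionic_strength_mM : 1:1 electrolyte concentration (consistency with
        lambda_d_nm is the caller's concern; lambda_d_nm is authoritative).
    """

    q_dna: float = 24.0
    lambda_d_nm: float = 0.78
    d_nm: float = 0.0
    T: float = T_REF
    ionic_strength_mM: float = IONIC_STRENGTH_MM

    def __post_init__(self):
        if self.q_dna <= 0:
            raise ValueError("q_dna must be positive (magnitude of probe charge)")
        if self.lambda_d_nm <= 0:
            raise ValueError("Debye length must be positive")
        if self.d_nm < 0:
            raise ValueError("separation d must be non-negative")

    @property
    def kappa_per_nm(self) -> float:
        """Inverse Debye length, 1/nm."""
        return 1.0 / self.lambda_d_nm

    @classmethod
    def from_ionic_strength(cls, ionic_strength_mM: float, T: float = T_REF, **kw) -> "ElectroModel":
        return cls(
            lambda_d_nm=debye_length(ionic_strength_mM, T),
            T=T,
            ionic_strength_mM=ionic_strength_mM,
            **kw,
        )


def sigma_from_n_pg(n_pg, area_per_lipid_nm2: float = AREA_PER_LIPID_NM2):
    """Surface charge density (C/m^2) from the anionic lipid mole fraction.

    One -1e charge per PG headgroup spread over the area per lipid.
    """
    n_pg = np.asarray(n_pg, dtype=float)
    return -E_CHARGE * n_pg / (area_per_lipid_nm2 * 1e-18)


def grahame_potential(sigma, ionic_strength_mM: float = IONIC_STRENGTH_MM, T: float = T_REF):
    """Surface potential (mV) from charge density via the Grahame equation.

    Inverts sigma = sqrt(8*c0*eps*eps0*kT) * sinh(e*phi / 2kT) for a 1:1
    electrolyte of bulk number density c0.  Odd in sigma; linear for small
    charge (Debye-Huckel) and sublinear (asinh) at high charge, so doubling
    sigma less than doubles |phi| once |phi| exceeds ~25 mV.
    """
    sigma = np.asarray(sigma, dtype=float)
    c0 = ionic_strength_mM * 1e-3 * 1e3 * N_AVOGADRO  # ions/m^3
    kT = kT_joules(T)
    denom = np.sqrt(8.0 * c0 * EPS_R_WATER * EPS0 * kT)
    phi = (2.0 * kT / E_CHARGE) * np.arcsinh(sigma / denom)
    return phi * 1e3  # V -> mV


def eps_from_potential(delta_phi_s_mV, model: ElectroModel):
    """Screened repulsion-energy change (kT units) from a surface-potential change.

    delta_eps = -q_dna * e * delta_phi_s * exp(-kappa*d) / kT

    The probe carries charge -q_dna*e, so a negative (anionic-membrane)
    potential produces a positive repulsion energy.  Exactly linear in
    delta_phi_s at fixed d; each additional Debye length of separation
    attenuates the energy by a factor e.
    """
    phi_V = np.asarray(delta_phi_s_mV, dtype=float) * 1e-3
    screen = np.exp(-model.kappa_per_nm * model.d_nm)
    return -model.q_dna * E_CHARGE * phi_V * screen / kT_joules(model.T)


def zeta_from_eps(delta_eps_kT, model: ElectroModel):
    """Invert :func:`eps_from_potential`: potential (mV) from repulsion energy.

    Requires the probe separation d to be known (e.g. from
    :func:`fit_probe_distance`); exact inverse of the forward map.
    """
    eps = np.asarray(delta_eps_kT, dtype=float)
    screen = np.exp(-model.kappa_per_nm * model.d_nm)
    phi_V = -eps * kT_joules(model.T) / (model.q_dna * E_CHARGE * screen)
    return phi_V * 1e3


def fit_probe_distance(
    phi_z_mV,
    delta_eps_kT,
    model: ElectroModel,
    *,
    d_max_nm: float = 10.0,
    loss: str = "relative",
    n_bootstrap: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Fit the probe-to-slipping-plane separation d (nm) and its bootstrap SE.

    One-dimensional least squares: with q_dna and the Debye length fixed,
    d is the only free parameter of the screened-repulsion model; it sets
    the slope of the (phi_z, delta_eps) line.  Solved by bounded scalar
    minimisation on [0, d_max_nm]; the SE comes from a pairs bootstrap.

    ``loss`` selects the residual scale: "relative" (default) minimises
    fractional residuals — appropriate because repulsion energies derived
    from binding-constant ratios carry roughly constant *relative* error,
    and absolute residuals would let the largest-|phi_z| pairs dominate —
    while "absolute" minimises plain squared residuals.

    Raises ValueError with fewer than 3 pairs or when all zeta potentials
    are ~0 (the slope, hence d, is unidentifiable).
    """
    phi = np.asarray(phi_z_mV, dtype=float)
    eps = np.asarray(delta_eps_kT, dtype=float)
    if phi.size < 3:
        raise ValueError("need >= 3 (phi_z, delta_eps) pairs")
    if np.allclose(phi, 0.0, atol=1e-9):
        raise ValueError("all zeta potentials ~ 0: separation d is unidentifiable")
    if loss not in ("relative", "absolute"):
        raise ValueError(f"unknown loss {loss!r}")

    def _solve(p, e):
        if loss == "relative":
            # zero-energy pairs (the reference composition) carry no slope
            # information and would blow up fractional residuals: drop them
            keep = np.abs(e) > np.max(np.abs(e)) * 1e-9
            p, e = p[keep], e[keep]
            scale = np.abs(e)
        else:
            scale = 1.0

        def sse(d):
            pred = eps_from_potential(p, replace(model, d_nm=d))
            return float(np.sum(((pred - e) / scale) ** 2))

        res = minimize_scalar(sse, bounds=(0.0, d_max_nm), method="bounded",
                              options={"xatol": 1e-10})
        return float(res.x)

    d_hat = _solve(phi, eps)

    se = float("nan")
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        boot = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            idx = rng.integers(0, phi.size, size=phi.size)
            boot[b] = _solve(phi[idx], eps[idx])
        se = float(np.std(boot, ddof=1))
    return d_hat, se
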