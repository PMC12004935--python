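"""Langmuir-Boltzmann model of cholesterol-anchored DNA binding to vesicles.

A 48-bp single-cholesterol DNA duplex (the surface-charge probe) partitions
between solution and the membrane of a giant unilamellar vesicle.  Binding
follows a two-state Langmuir isotherm in the *Boltzmann-adjusted* free
concentration: electrostatic repulsion between the anionic duplex and an
anionic membrane depletes probe adjacent to the bilayer by a factor
exp(-eps_elec/kT), so the effective binding constant observed on a charged
membrane is

    K_B = K_B_int * exp(-delta_eps_elec / kT)

with K_B_int the intrinsic (zero-charge) constant.  Membrane-bound probe is
expressed as a molar percentage, 100 * (bound DNA) / (lipid), saturating at
DNA_max.  Empirically K_B decays mono-exponentially with the anionic-lipid
mole fraction n_PG:  K_B(n_PG) = K_B0 * exp(-B * n_PG).

This module provides the forward model, its per-vesicle inversion, the
population isotherm fit (nonlinear least squares on per-level means with a
vesicle-level bootstrap), the exponential charge law fit, and conversion of
binding-constant ratios to repulsion-energy changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .constants import T_REF, kT_joules

__all__ = [
    "IsothermFit",
    "ChargeLaw",
    "EnergyEstimate",
    "DNA_MAX_DEFAULT",
    "langmuir_bound",
    "boltzmann_adjust",
    "per_vesicle_kb",
    "fit_isotherm",
    "fit_charge_law",
    "delta_eps_from_kb",
]

#: saturation bound-DNA fraction used for per-vesicle K_B estimation, mol %
#: (composition-independent within error, hence fixed for the estimator)
DNA_MAX_DEFAULT: float = 0.4


@dataclass(frozen=True)
class IsothermFit:
    """Result of fitting the two-parameter Langmuir isotherm to a population.

    Attributes
    ----------
    k_b : effective binding constant, per µM of free DNA.
    dna_max : saturation bound fraction, mol % (DNA:lipid x 100).
    se_k_b, se_dna_max : bootstrap standard errors (vesicle-level resampling).
    n_vesicles : total vesicles entering the fit.
    n_levels : number of distinct free-DNA concentration levels.
    rss : residual sum of squares of the mean-curve fit.
    """

    k_b: float
    dna_max: float
    se_k_b: float
    se_dna_max: float
    n_vesicles: int
    n_levels: int
    rss: float
    n_bootstrap: int = 0
    seed: int | None = None

    @property
    def k_b_int(self) -> float:
        """Intrinsic constant equals the effective one when delta_eps = 0."""
        return self.k_b


@dataclass(frozen=True)
class ChargeLaw:
    """Exponential decay of K_B with anionic lipid fraction.

    K_B(n_PG) = k_b0 * exp(-b * n_PG); ``b`` is dimensionless, ``k_b0`` is
    the zero-charge binding constant in per-µM.
    """

    k_b0: float
    b: float
    se_b: float = float("nan")
    se_k_b0: float = float("nan")
    #: covariance of (ln k_b0, -b) from the log-linear fit, row-major
    cov_log: tuple[float, float, float, float] | None = None

    def predict(self, n_pg):
        return self.k_b0 * np.exp(-self.b * np.asarray(n_pg, dtype=float))

    def predict_se(self, n_pg):
        """Delta-method SE of the predicted K_B (nan without a fit covariance)."""
        x = np.asarray(n_pg, dtype=float)
        if self.cov_log is None:
            return np.full_like(x, np.nan, dtype=float)
        c00, c01, c10, c11 = self.cov_log
        var_log = c00 + x * (c01 + c10) + x**2 * c11
        return self.predict(x) * np.sqrt(np.clip(var_log, 0.0, None))


@dataclass(frozen=True)
class EnergyEstimate:
    """Electrostatic repulsion-energy change relative to a reference membrane."""

    delta_eps_kT: float
    delta_eps_J: float
    T: float = T_REF
    kT_ref_J: float = field(default_factory=kT_joules)


def langmuir_bound(dna_adj, k_b, dna_max):
    """Bound DNA fraction (mol %) from the Langmuir isotherm.

    dna_mem = dna_max * k_b * dna_adj / (1 + k_b * dna_adj)

    Parameters are the (Boltzmann-adjusted) free concentration in µM, the
    binding constant in per-µM and the saturation fraction in mol %.
    Monotone increasing in ``dna_adj``, saturating at ``dna_max``.
    """
    dna_adj = np.asarray(dna_adj, dtype=float)
    x = k_b * dna_adj
    return dna_max * x / (1.0 + x)


def boltzmann_adjust(dna_free, eps_elec_kT):
    """Free concentration adjacent to a charged membrane.

    The repulsion energy ``eps_elec_kT`` (in kT units) depletes probe near
    the bilayer: dna_adj = dna_free * exp(-eps_elec/kT).  Composed with
    :func:`langmuir_bound` this realises K_B = K_B_int * exp(-delta_eps/kT).
    """
    return np.asarray(dna_free, dtype=float) * np.exp(-np.asarray(eps_elec_kT, dtype=float))


def per_vesicle_kb(dna_mem, dna_free, dna_max: float = DNA_MAX_DEFAULT):
    """Per-vesicle binding constant by inverting the Langmuir isotherm.

    K_B_i = dna_mem / (dna_free * (dna_max - dna_mem)),   per µM,

    valid for 0 <= dna_mem < dna_max and dna_free > 0.  Saturated vesicles
    (dna_mem >= dna_max) and zero free concentration yield NaN; callers that
    need hard failures should pre-filter.  Scalar inputs raise instead, to
    surface the bad record.
    """
    dna_mem_a = np.asarray(dna_mem, dtype=float)
    dna_free_a = np.asarray(dna_free, dtype=float)
    scalar = dna_mem_a.ndim == 0 and dna_free_a.ndim == 0
    if scalar:
        if dna_mem_a >= dna_max:
            raise ValueError(
                f"dna_mem={float(dna_mem_a):g} >= dna_max={dna_max:g}: "
                "saturated vesicle, K_B undefined"
            )
        if dna_free_a <= 0:
            raise ValueError("dna_free must be positive")
        return float(dna_mem_a / (dna_free_a * (dna_max - dna_mem_a)))
    with np.errstate(divide="ignore", invalid="ignore"):
        kb = dna_mem_a / (dna_free_a * (dna_max - dna_mem_a))
    bad = (dna_mem_a >= dna_max) | (dna_free_a <= 0) | (dna_mem_a < 0)
    return np.where(bad, np.nan, kb)


def _init_params(dna_free_levels: np.ndarray, mean_mem: np.ndarray) -> tuple[float, float]:
    # dna_max from headroom over the largest observed mean; K_B from the
    # low-concentration secant dna_mem ~ dna_max*K_B*x
    m0 = 1.2 * float(np.max(mean_mem))
    order = np.argsort(dna_free_levels)
    x0, y0 = dna_free_levels[order[0]], mean_mem[order[0]]
    k0 = y0 / (m0 * x0) if x0 > 0 and y0 > 0 else 1.0
    return max(k0, 1e-6), max(m0, 1e-9)


def _fit_means(dna_free_levels, mean_mem, rng: np.random.Generator) -> tuple[float, float, float]:
    """Least-squares Langmuir fit to per-level means with jittered restarts."""
    k0, m0 = _init_params(dna_free_levels, mean_mem)
    best = None
    for i in range(5):
        jk = 1.0 if i == 0 else float(np.exp(rng.normal(0.0, 0.3)))
        jm = 1.0 if i == 0 else float(np.exp(rng.normal(0.0, 0.2)))
        try:
            popt, _ = curve_fit(
                langmuir_bound,
                dna_free_levels,
                mean_mem,
                p0=(k0 * jk, m0 * jm),
                bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        rss = float(np.sum((langmuir_bound(dna_free_levels, *popt) - mean_mem) ** 2))
        if best is None or rss < best[2]:
            best = (float(popt[0]), float(popt[1]), rss)
    if best is None:
        raise RuntimeError(
            "isotherm fit failed to converge from 5 restarts; "
            f"levels={dna_free_levels!r}, means={mean_mem!r}"
        )
    return best


def fit_isotherm(
    records: pd.DataFrame,
    *,
    mem_col: str = "dna_mem_molpct",
    free_col: str = "dna_free_uM",
    level_col: str = "dna_added_uM",
    n_bootstrap: int = 1000,
    seed: int | None = None,
) -> IsothermFit:
    """Fit the Langmuir isotherm to a single-vesicle population.

    The fit target is the per-concentration-level *mean* bound fraction
    against the per-level mean free concentration (the population mean of a
    saturating binding curve), with both K_B and dna_max free.  Uncertainty
    comes from a vesicle-level bootstrap: vesicles are resampled with
    replacement within each level and the two-parameter fit repeated.

    Parameters
    ----------
    records : table with one row per vesicle carrying bound fraction
        (mol %), free concentration (µM) and the added-DNA level label.
    n_bootstrap : bootstrap replicates for the standard errors (0 disables).
    seed : RNG seed for restart jitter and the bootstrap.

    Raises
    ------
    ValueError : fewer than 3 distinct levels.
    RuntimeError : optimiser failed from all restarts.
    """
    df = records[[level_col, mem_col, free_col]].dropna()
    levels = df[level_col].unique()
    if len(levels) < 3:
        raise ValueError(f"need >= 3 distinct {level_col} levels, got {len(levels)}")
    rng = np.random.default_rng(seed)

    grouped = df.groupby(level_col, sort=True)
    mean_mem = grouped[mem_col].mean().to_numpy()
    mean_free = grouped[free_col].mean().to_numpy()
    k_b, dna_max, rss = _fit_means(mean_free, mean_mem, rng)

    if 1.0 / k_b < mean_free.min() or 1.0 / k_b > mean_free.max():
        import warnings

        warnings.warn(
            "free-DNA levels do not bracket 1/K_B; parameter estimates may "
            "be weakly constrained",
            stacklevel=2,
        )

    se_k, se_m = float("nan"), float("nan")
    if n_bootstrap > 0:
        groups = [g[[mem_col, free_col]].to_numpy() for _, g in grouped]
        boot_k = np.empty(n_bootstrap)
        boot_m = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            bm = np.empty(len(groups))
            bf = np.empty(len(groups))
            for j, arr in enumerate(groups):
                idx = rng.integers(0, len(arr), size=len(arr))
                bm[j] = arr[idx, 0].mean()
                bf[j] = arr[idx, 1].mean()
            try:
                boot_k[b], boot_m[b], _ = _fit_means(bf, bm, rng)
            except RuntimeError:
                boot_k[b], boot_m[b] = np.nan, np.nan
        se_k = float(np.nanstd(boot_k, ddof=1))
        se_m = float(np.nanstd(boot_m, ddof=1))

    return IsothermFit(
        k_b=k_b,
        dna_max=dna_max,
        se_k_b=se_k,
        se_dna_max=se_m,
        n_vesicles=len(df),
        n_levels=len(levels),
        rss=rss,
        n_bootstrap=n_bootstrap,
        seed=seed,
    )


def fit_charge_law(
    n_pg,
    mean_kb,
    *,
    rel_se=None,
) -> ChargeLaw:
    """Fit K_B(n_PG) = K_B0 * exp(-B * n_PG) by weighted log-linear least squares.

    Linear regression of log K_B on n_PG; optional weights are inverse
    squared relative standard errors (the delta-method variance of log K_B).
    Requires >= 3 distinct anionic fractions spanning down to n_PG = 0 so the
    intercept K_B0 is anchored at the zero-charge reference.
    """
    n_pg = np.asarray(n_pg, dtype=float)
    mean_kb = np.asarray(mean_kb, dtype=float)
    if np.any(mean_kb <= 0):
        raise ValueError("all K_B values must be positive for the log-linear fit")
    if len(np.unique(n_pg)) < 3:
        raise ValueError("need >= 3 distinct n_PG values")
    if not np.any(np.isclose(n_pg, 0.0)):
        raise ValueError("charge-law fit requires an n_PG = 0 reference point")

    y = np.log(mean_kb)
    w = np.ones_like(y)
    if rel_se is not None:
        rel_se = np.asarray(rel_se, dtype=float)
        w = 1.0 / np.clip(rel_se, 1e-12, None) ** 2
    # weighted straight-line fit y = a + b*x  (b = -B)
    W = np.diag(w)
    X = np.column_stack([np.ones_like(n_pg), n_pg])
    beta, *_ = np.linalg.lstsq(np.sqrt(W) @ X, np.sqrt(w) * y, rcond=None)
    resid = y - X @ beta
    dof = max(len(y) - 2, 1)
    s2 = float(resid @ (w * resid)) / dof
    cov = s2 * np.linalg.inv(X.T @ W @ X)
    return ChargeLaw(
        k_b0=float(np.exp(beta[0])),
        b=float(-beta[1]),
        se_b=float(np.sqrt(cov[1, 1])),
        se_k_b0=float(np.exp(beta[0]) * np.sqrt(cov[0, 0])),
        cov_log=(float(cov[0, 0]), float(cov[0, 1]), float(cov[1, 0]), float(cov[1, 1])),
    )


def delta_eps_from_kb(k_b: float, k_b_ref: float, T: float = T_REF) -> EnergyEstimate:
    """Repulsion-energy change from the drop in effective binding constant.

    delta_eps = -kT * ln(K_B / K_B_ref), with the zero-anionic-fraction
    population as reference; positive when binding weakens (K_B < K_B_ref).
    Reported in kT units and Joules at the given temperature.
    """
    if k_b <= 0 or k_b_ref <= 0:
        raise ValueError("binding constants must be positive")
    d_kT = -float(np.log(k_b / k_b_ref))
    return EnergyEstimate(delta_eps_kT=d_kT, delta_eps_J=d_kT * kT_joules(T), T=T)
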