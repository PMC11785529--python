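"""Satellite net-primary-production algorithm skeletons.

Six algorithm structures are implemented: the two vertically generalised
production models (Eppley and Behrenfeld temperature functions), the two
carbon-based production models (surface-product and depth-resolved), an
absorption-based model, and an absorbed-energy/efficiency model.  The
structural skeletons — what multiplies what, which variable carries the
temperature, biomass or light dependence — are fixed; the inner
parameterizations (light-limitation term, backscatter-to-carbon
conversion, growth-rate mapping, the absorption model's inner function)
are pluggable strategy callables on :class:`AlgorithmParams`.

Defaults use the published constants where they are canonical (the VGPM
light term ``0.66125·PAR/(PAR+4.1)``, the Eppley exponential, the
7th-order Behrenfeld temperature polynomial with its clamps, the
``13000·(bbp443−0.00035)`` phytoplankton-carbon conversion).  The growth
profile and the absorption-model inner function default to documented
simplified forms; swap in alternatives via the params object for
faithful ports.

All algorithms return NPP in mg C m⁻² d⁻¹ and obey: zero biomass proxy
(chlorophyll, phytoplankton carbon, or phytoplankton absorption) gives
zero NPP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import xarray as xr

from .errors import ConfigurationError, ValidationError

__all__ = [
    "OceanColourInputs",
    "AlgorithmParams",
    "popt_vgpm",
    "npp_vgpm",
    "npp_cbpm",
    "npp_abpm",
    "npp_cafe",
    "compute_npp",
    "ALGORITHMS",
]

log = logging.getLogger(__name__)

# Behrenfeld & Falkowski (1997) optimal photosynthetic rate polynomial,
# lowest-order coefficient first, with the published range clamps.
_BF97_COEFFS = np.array(
    [1.2956, 2.749e-1, 6.17e-2, -2.05e-2, 2.462e-3, -1.348e-4, 3.4132e-6, -3.27e-8]
)
_BF97_COLD, _BF97_WARM = 1.13, 4.00  # mg C (mg Chl)-1 h-1 at T<-1 / T>28.5


@dataclass
class OceanColourInputs:
    """Bundle of per-pixel ocean-colour inputs (arrays broadcast together).

    Units: chl mg m⁻³, sst °C, par mol photons m⁻² d⁻¹, day_length h,
    zeu m, bbp443 / aph443 / kd490 m⁻¹, mld m, z_no3 m (nitracline).
    """

    chl: np.ndarray
    sst: np.ndarray
    par: np.ndarray
    day_length: np.ndarray
    zeu: np.ndarray
    bbp443: np.ndarray | None = None
    aph443: np.ndarray | None = None
    kd490: np.ndarray | None = None
    mld: np.ndarray | None = None
    z_no3: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("chl", "par", "day_length", "zeu", "bbp443", "aph443", "kd490", "mld"):
            v = getattr(self, name)
            if v is not None and np.any(np.asarray(v)[np.isfinite(v)] < 0):
                raise ValidationError(f"{name} must be non-negative")
        if np.any(np.asarray(self.zeu)[np.isfinite(self.zeu)] <= 0):
            raise ValidationError("zeu must be strictly positive")

    @classmethod
    def from_scene(cls, scene: xr.Dataset) -> "OceanColourInputs":
        return cls(
            chl=scene["CHL"].values,
            sst=scene["SST"].values,
            par=scene["PAR"].values,
            day_length=scene["day_length"].values,
            zeu=scene["Zeu"].values,
            bbp443=scene["bbp443"].values,
            aph443=scene["aph443"].values,
            kd490=scene["Kd490"].values,
            mld=scene["MLD"].values,
        )


def vgpm_light_limitation(par: np.ndarray) -> np.ndarray:
    """Canonical VGPM light term, 0.66125·PAR/(PAR+4.1), bounded in [0, 0.67)."""
    par = np.asarray(par, dtype=float)
    return 0.66125 * par / (par + 4.1)


def cphyto_from_bbp(bbp443: np.ndarray) -> np.ndarray:
    """Phytoplankton carbon (mg C m⁻³) from particulate backscatter,
    13000·(bbp443 − 0.00035); values below the offset clamp to zero."""
    c = 13000.0 * (np.asarray(bbp443, dtype=float) - 0.00035)
    n_clamped = int(np.sum(c[np.isfinite(c)] < 0))
    if n_clamped:
        log.info("cphyto_from_bbp: clamped %d negative carbon values to 0", n_clamped)
    return np.clip(c, 0.0, None)


def median_mixed_layer_irradiance(
    par: np.ndarray, day_length: np.ndarray, kd490: np.ndarray, mld: np.ndarray
) -> np.ndarray:
    """Growth irradiance I_g: hourly PAR attenuated to the mixed-layer midpoint
    (mol photons m⁻² h⁻¹)."""
    return np.asarray(par) / np.asarray(day_length) * np.exp(
        -np.asarray(kd490) * np.asarray(mld) / 2.0
    )


def default_growth_rate(
    chl: np.ndarray, cphyto: np.ndarray, ig: np.ndarray, mu_max: float
) -> np.ndarray:
    """Simplified carbon-based growth mapping (d⁻¹): growth scales with the
    chlorophyll-to-carbon ratio relative to its light-acclimated maximum
    Chl:C_max(I_g) = 0.022 + 0.023·exp(−3 I_g), times a saturating light
    response, capped at mu_max.  A documented simplification of the full
    carbon-based production model's physiology."""
    chl = np.asarray(chl, dtype=float)
    cphyto = np.asarray(cphyto, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        chlc = np.where(cphyto > 0, chl / np.maximum(cphyto, 1e-12), 0.0)
    chlc_max = 0.022 + 0.023 * np.exp(-3.0 * np.asarray(ig))
    mu = mu_max * np.clip(chlc / chlc_max, 0.0, 1.0) * (1.0 - np.exp(-5.0 * np.asarray(ig)))
    return np.minimum(mu, mu_max)


def simplified_abpm_inner(
    aph443: np.ndarray,
    kd490: np.ndarray,
    zeu: np.ndarray,
    par: np.ndarray,
    psi: float = 600.0,
) -> np.ndarray:
    """Simplified absorption-based inner function: photons absorbed by
    phytoplankton over the euphotic column, aph/Kd·PAR·(1−e^{−Kd·Zeu}),
    times a fixed carbon yield psi (mg C per mol photons)."""
    aph = np.asarray(aph443, dtype=float)
    kd = np.asarray(kd490, dtype=float)
    frac = np.where(kd > 0, (1.0 - np.exp(-kd * np.asarray(zeu))) / np.maximum(kd, 1e-12), np.asarray(zeu))
    return psi * aph * np.asarray(par) * frac


def default_qpar(inputs: OceanColourInputs, photons_to_carbon: float = 500.0) -> np.ndarray:
    """Absorbed-energy term for the efficiency model, expressed in
    carbon-equivalent units: photons absorbed by phytoplankton over the
    euphotic column times a fixed conversion (mg C per mol photons)."""
    kd = np.asarray(inputs.kd490, dtype=float)
    absorbed = (
        np.asarray(inputs.par)
        * np.where(kd > 0, np.asarray(inputs.aph443) / np.maximum(kd, 1e-12), 0.0)
        * (1.0 - np.exp(-kd * np.asarray(inputs.zeu)))
    )
    return photons_to_carbon * absorbed


@dataclass
class AlgorithmParams:
    """Tunable inner parameterizations for the NPP algorithm skeletons."""

    popt_variant: str = "eppley"  # {"eppley", "behrenfeld"}
    fpar: Callable[[np.ndarray], np.ndarray] = vgpm_light_limitation
    mu_max: float = 2.0  # d-1
    carbon_from_bbp: Callable[[np.ndarray], np.ndarray] = cphyto_from_bbp
    growth_rate: Callable[..., np.ndarray] = default_growth_rate
    abpm_inner: Callable[..., np.ndarray] | None = field(
        default_factory=lambda: simplified_abpm_inner
    )
    phi_mu_max: float = 0.35  # dimensionless efficiency, in (0, 1]
    e_k: float = 10.0  # light saturation, mol photons m-2 d-1
    q_par: np.ndarray | float | None = None  # override for the absorbed-energy term
    westberry_dz: float = 1.0  # m, trapezoid step for the depth-resolved variant

    def __post_init__(self) -> None:
        if not 0.0 < self.phi_mu_max <= 1.0:
            raise ValidationError("phi_mu_max must lie in (0, 1]")
        if self.mu_max <= 0:
            raise ValidationError("mu_max must be positive")


def popt_vgpm(sst: np.ndarray, variant: str = "eppley") -> np.ndarray:
    """Optimal chlorophyll-normalised photosynthetic rate P^B_opt
    (mg C (mg Chl)⁻¹ h⁻¹) as a function of temperature.

    ``eppley``: pure exponential, 1.54·10^(0.0275·T − 0.07), so the ratio
    over any fixed temperature increment is constant (Q10-like).
    ``behrenfeld``: the published 7th-order polynomial, clamped to 1.13
    below −1 °C and 4.00 above 28.5 °C; non-monotone with an interior
    maximum near 20 °C.
    """
    sst = np.asarray(sst, dtype=float)
    if variant == "eppley":
        return 1.54 * 10.0 ** (0.0275 * sst - 0.07)
    if variant == "behrenfeld":
        p = np.polynomial.polynomial.polyval(sst, _BF97_COEFFS)
        p = np.where(sst < -1.0, _BF97_COLD, p)
        p = np.where(sst > 28.5, _BF97_WARM, p)
        return p
    raise ConfigurationError(f"unknown popt variant {variant!r}")


def npp_vgpm(inputs: OceanColourInputs, params: AlgorithmParams) -> np.ndarray:
    """Vertically generalised production model:
    NPP = Chl × P^B_opt(SST) × DL × f(PAR) × Zeu.  Exactly linear in
    chlorophyll, day length and euphotic depth."""
    for name in ("chl", "par", "day_length", "zeu"):
        v = np.asarray(getattr(inputs, name))
        if np.any(v[np.isfinite(v)] < 0):
            raise ValidationError(f"{name} must be non-negative")
    popt = popt_vgpm(inputs.sst, params.popt_variant)
    return (
        np.asarray(inputs.chl, dtype=float)
        * popt
        * np.asarray(inputs.day_length, dtype=float)
        * params.fpar(inputs.par)
        * np.asarray(inputs.zeu, dtype=float)
    )


def _require(inputs: OceanColourInputs, *names: str) -> None:
    for name in names:
        if getattr(inputs, name) is None:
            raise ConfigurationError(f"input field {name!r} required but missing")


def npp_cbpm(
    inputs: OceanColourInputs,
    params: AlgorithmParams,
    variant: str = "behrenfeld",
) -> np.ndarray:
    """Carbon-based production model.

    ``behrenfeld``: surface product C_ph × μ × f(PAR) × Zeu.
    ``westberry``: trapezoidal depth integral of C_ph(z) × μ(z) over
    [0, Zeu] on a fixed ``westberry_dz`` grid, with light attenuated by
    Kd490 and carbon held at its surface value (attenuated below the
    nitracline when ``z_no3`` is given).
    """
    _require(inputs, "bbp443", "kd490", "mld")
    cph = params.carbon_from_bbp(inputs.bbp443)
    ig = median_mixed_layer_irradiance(
        inputs.par, inputs.day_length, inputs.kd490, inputs.mld
    )
    if variant == "behrenfeld":
        mu = params.growth_rate(inputs.chl, cph, ig, params.mu_max)
        return cph * mu * params.fpar(inputs.par) * np.asarray(inputs.zeu, dtype=float)
    if variant == "westberry":
        return _westberry_integral(inputs, params, cph)
    raise ConfigurationError(f"unknown CbPM variant {variant!r}")


def _westberry_integral(
    inputs: OceanColourInputs, params: AlgorithmParams, cph: np.ndarray
) -> np.ndarray:
    shape = np.broadcast(np.asarray(inputs.chl), np.asarray(inputs.zeu)).shape
    chl = np.broadcast_to(np.asarray(inputs.chl, dtype=float), shape).ravel()
    zeu = np.broadcast_to(np.asarray(inputs.zeu, dtype=float), shape).ravel()
    par = np.broadcast_to(np.asarray(inputs.par, dtype=float), shape).ravel()
    dl = np.broadcast_to(np.asarray(inputs.day_length, dtype=float), shape).ravel()
    kd = np.broadcast_to(np.asarray(inputs.kd490, dtype=float), shape).ravel()
    cphf = np.broadcast_to(np.asarray(cph, dtype=float), shape).ravel()
    zno3 = (
        np.broadcast_to(np.asarray(inputs.z_no3, dtype=float), shape).ravel()
        if inputs.z_no3 is not None
        else None
    )
    out = np.full(chl.shape, np.nan)
    dz = params.westberry_dz
    for i in range(chl.size):
        if not np.isfinite(zeu[i]) or not np.isfinite(cphf[i]):
            continue
        z = np.arange(0.0, zeu[i] + dz, dz)
        z[-1] = min(z[-1], zeu[i])
        iz = par[i] / dl[i] * np.exp(-kd[i] * z)  # hourly PAR at depth
        cz = np.full_like(z, cphf[i])
        if zno3 is not None and np.isfinite(zno3[i]):
            cz = np.where(z > zno3[i], cz * np.exp(-(z - zno3[i]) / 30.0), cz)
        mu_z = params.growth_rate(chl[i], cz, iz, params.mu_max)
        out[i] = np.trapezoid(cz * mu_z, z)
    return out.reshape(shape)


def npp_abpm(inputs: OceanColourInputs, params: AlgorithmParams) -> np.ndarray:
    """Absorption-based production model:
    NPP = f(aph443, Kd490-attenuated light, Zeu, PAR) with ``f`` the
    pluggable inner function.  Zero when aph443 = 0 or PAR = 0."""
    _require(inputs, "aph443", "kd490")
    if params.abpm_inner is None:
        raise ConfigurationError("no inner function configured for the absorption model")
    return params.abpm_inner(inputs.aph443, inputs.kd490, inputs.zeu, inputs.par)


def npp_cafe(inputs: OceanColourInputs, params: AlgorithmParams) -> np.ndarray:
    """Absorbed-energy/efficiency model, as the skeleton is printed:
    NPP = Q_PAR × Φ_μ^max × tanh(E_k / PAR); bounded above by
    Q_PAR × Φ_μ^max.  PAR = 0 is treated as the saturating tanh → 1
    limit (logged), so NPP remains Q_PAR × Φ there."""
    if params.q_par is not None:
        qpar = np.asarray(params.q_par, dtype=float)
    else:
        _require(inputs, "aph443", "kd490")
        qpar = default_qpar(inputs)
    par = np.asarray(inputs.par, dtype=float)
    zero_par = np.isfinite(par) & (par == 0)
    if np.any(zero_par):
        log.info("npp_cafe: %d cells with PAR=0 handled as saturating limit", int(zero_par.sum()))
    with np.errstate(divide="ignore"):
        light = np.where(par > 0, np.tanh(params.e_k / np.maximum(par, 1e-300)), 1.0)
    return qpar * params.phi_mu_max * light


def compute_npp(
    scene: xr.Dataset, algorithm: str, params: AlgorithmParams | None = None
) -> np.ndarray:
    """Run one named algorithm over a generated ocean-colour scene."""
    if algorithm not in ALGORITHMS:
        raise ConfigurationError(f"unknown algorithm {algorithm!r}; choose from {sorted(ALGORITHMS)}")
    inputs = OceanColourInputs.from_scene(scene)
    return ALGORITHMS[algorithm](inputs, params or AlgorithmParams())


ALGORITHMS: dict[str, Callable[[OceanColourInputs, AlgorithmParams], np.ndarray]] = {
    "eppley-vgpm": lambda i, p: npp_vgpm(i, AlgorithmParams(**{**p.__dict__, "popt_variant": "eppley"})),
    "behrenfeld-vgpm": lambda i, p: npp_vgpm(i, AlgorithmParams(**{**p.__dict__, "popt_variant": "behrenfeld"})),
    "behrenfeld-cbpm": lambda i, p: npp_cbpm(i, p, variant="behrenfeld"),
    "westberry-cbpm": lambda i, p: npp_cbpm(i, p, variant="westberry"),
    "lee-abpm": npp_abpm,
    "silsbe-cafe": npp_cafe,
}
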