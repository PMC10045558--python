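"""Mixed-field BNCT dose arithmetic.

A thermal-neutron irradiation of boron-loaded tissue deposits dose through
four channels: the 10B(n,alpha)7Li capture reaction (D_B), the
14N(n,p)14C capture reaction (D_N), proton recoil from 1H(n,n)1H (D_H),
and gamma rays (D_gamma).  The physical dose is their plain sum; the
photon-equivalent dose weights each channel by its biological
effectiveness relative to photons:

    D_eq = D_B * CBE + D_N * RBE_N + D_H * RBE_H + D_gamma

where the compound biological effectiveness (CBE) is specific to the
boron carrier and tissue, while RBE_N and RBE_H characterise the beam.

Kerma coefficients (Gy cm^2 per unit fluence, per ug 10B/g for the boron
channel) are treated as calibration inputs supplied through configuration,
never hard-coded: their effective values depend on the irradiation
geometry and in-tissue flux attenuation of a particular facility.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import ConfigurationError, InconsistentInputsError, InputValidationError, UnknownFactorError

__all__ = [
    "BeamSpec",
    "DoseComponents",
    "RadiobiologicalFactors",
    "CBELibrary",
    "ExposureSpec",
    "boron_dose",
    "total_physical_dose",
    "photon_equivalent_dose",
    "beam_component_split",
]

#: Reaction channels a beam configuration may carry kerma coefficients for.
CHANNELS = ("B10", "N14", "H1")


class BeamSpec(BaseModel):
    """A neutron beam: component fluxes, gamma dose rate and kerma coefficients.

    Parameters
    ----------
    thermal_flux : float
        Thermal neutron flux, n cm^-2 s^-1.
    epithermal_flux, fast_flux : float, optional
        Additional flux components; the fast flux drives the hydrogen
        recoil channel when present.
    gamma_dose_rate : float
        Gamma dose rate, Gy/s.
    kerma_coefficients : dict
        Per-channel coefficients. ``B10`` is Gy cm^2 per (ug 10B/g);
        ``N14`` and ``H1`` are Gy cm^2 at the reference tissue
        composition.
    """

    model_config = ConfigDict(frozen=True)

    thermal_flux: float = Field(ge=0)
    epithermal_flux: Optional[float] = Field(default=None, ge=0)
    fast_flux: Optional[float] = Field(default=None, ge=0)
    gamma_dose_rate: float = Field(default=0.0, ge=0)
    kerma_coefficients: Dict[str, float] = Field(default_factory=dict)

    @field_validator("kerma_coefficients")
    @classmethod
    def _check_kerma(cls, v: Dict[str, float]) -> Dict[str, float]:
        for channel, value in v.items():
            if channel not in CHANNELS:
                raise ValueError(f"unknown kerma channel {channel!r}; expected one of {CHANNELS}")
            if not value > 0:
                raise ValueError(f"kerma coefficient for {channel} must be > 0, got {value}")
        return dict(v)

    def kerma(self, channel: str) -> float:
        try:
            return self.kerma_coefficients[channel]
        except KeyError:
            raise ConfigurationError(
                f"beam configuration has no kerma coefficient for channel {channel!r}"
            ) from None


class DoseComponents(BaseModel):
    """The four physical dose terms of one tissue/exposure, in Gy."""

    model_config = ConfigDict(frozen=True)

    d_boron: float = Field(ge=0)
    d_nitrogen: float = Field(ge=0)
    d_hydrogen: float = Field(ge=0)
    d_gamma: float = Field(ge=0)

    @classmethod
    def from_lumped(
        cls, d_boron: float, d_nh: float, d_gamma: float, nitrogen_share: float = 0.5
    ) -> "DoseComponents":
        """Build components from a lumped nitrogen+hydrogen term.

        Report tables often give only the combined high-LET beam term
        because nitrogen and hydrogen share the same RBE; the split is
        then immaterial for every downstream quantity.
        """
        if not 0.0 <= nitrogen_share <= 1.0:
            raise InputValidationError("nitrogen_share must be in [0, 1]")
        return cls(
            d_boron=d_boron,
            d_nitrogen=d_nh * nitrogen_share,
            d_hydrogen=d_nh * (1.0 - nitrogen_share),
            d_gamma=d_gamma,
        )

    @property
    def d_nh(self) -> float:
        """Combined nitrogen + hydrogen dose (shared RBE)."""
        return self.d_nitrogen + self.d_hydrogen

    @property
    def total(self) -> float:
        return self.d_boron + self.d_nitrogen + self.d_hydrogen + self.d_gamma


class RadiobiologicalFactors(BaseModel):
    """Weighting factors converting physical dose to photon-equivalent dose.

    ``cbe`` may be None to represent a carrier/tissue pair whose compound
    biological effectiveness has never been measured; using such a factor
    set on a field with a non-zero boron dose raises
    :class:`~borondose.errors.UnknownFactorError` (report cells stay blank).
    """

    model_config = ConfigDict(frozen=True)

    cbe: Optional[float] = Field(default=None, gt=0)
    rbe_n: float = Field(default=3.0, gt=0)
    rbe_h: float = Field(default=3.0, gt=0)


class CBELibrary(BaseModel):
    """Known CBE factors keyed by carrier then tissue."""

    model_config = ConfigDict(frozen=True)

    factors: Dict[str, Dict[str, float]] = Field(default_factory=dict)

    def lookup(self, carrier: str, tissue: str) -> float:
        try:
            return self.factors[carrier][tissue]
        except KeyError:
            raise UnknownFactorError(
                f"no CBE factor known for carrier {carrier!r} in tissue {tissue!r}"
            ) from None

    def get(self, carrier: str, tissue: str) -> Optional[float]:
        return self.factors.get(carrier, {}).get(tissue)


class ExposureSpec(BaseModel):
    """One tissue's exposure: irradiation time and boron concentration."""

    model_config = ConfigDict(frozen=True)

    irradiation_time: float = Field(ge=0, description="s")
    boron_concentration: float = Field(ge=0, description="ug 10B per g tissue")
    tissue_label: str = ""


def boron_dose(beam: BeamSpec, exposure: ExposureSpec) -> float:
    """Physical boron capture dose, Gy.

    D_B = kerma_B10 * thermal fluence * boron concentration, strictly
    linear in the thermal fluence (flux x time) and in the concentration.
    """
    k = beam.kerma("B10")
    return k * beam.thermal_flux * exposure.irradiation_time * exposure.boron_concentration


def _channel_fluence(beam: BeamSpec, channel: str, time_s: float) -> float:
    # Capture channels ride on the thermal flux; proton recoil is driven by
    # the fast component when the beam declares one.
    if channel == "H1" and beam.fast_flux is not None:
        return beam.fast_flux * time_s
    return beam.thermal_flux * time_s


def beam_components(beam: BeamSpec, exposure: ExposureSpec) -> DoseComponents:
    """Full four-channel decomposition for one exposure."""
    d_b = boron_dose(beam, exposure)
    t = exposure.irradiation_time
    d_n = beam.kerma("N14") * _channel_fluence(beam, "N14", t) if "N14" in beam.kerma_coefficients else 0.0
    d_h = beam.kerma("H1") * _channel_fluence(beam, "H1", t) if "H1" in beam.kerma_coefficients else 0.0
    d_g = beam.gamma_dose_rate * t
    return DoseComponents(d_boron=d_b, d_nitrogen=d_n, d_hydrogen=d_h, d_gamma=d_g)


def total_physical_dose(components: DoseComponents) -> float:
    """Sum of the four physical dose terms, Gy."""
    return components.total


def photon_equivalent_dose(components: DoseComponents, factors: RadiobiologicalFactors) -> float:
    """CBE/RBE-weighted photon-equivalent dose, Gy-Eq.

    With all factors equal to 1 this reduces exactly to the physical dose.
    """
    if components.d_boron > 0 and factors.cbe is None:
        raise UnknownFactorError(
            "boron dose present but no CBE factor supplied; "
            "photon-equivalent dose is undefined for this carrier/tissue"
        )
    cbe = factors.cbe if factors.cbe is not None else 0.0
    return (
        components.d_boron * cbe
        + components.d_nitrogen * factors.rbe_n
        + components.d_hydrogen * factors.rbe_h
        + components.d_gamma
    )


def beam_component_split(
    physical_total: float, photon_equivalent_total: float, rbe_nh: float
) -> Tuple[float, float]:
    """Recover (D_N + D_H, D_gamma) from a boron-free dose pair.

    For a boron-free field the two reported totals determine the
    high-LET and gamma parts uniquely:

        (D_N + D_H) + D_gamma          = physical_total
        rbe_nh (D_N + D_H) + D_gamma   = photon_equivalent_total

    This lets a published beam-only row serve as a calibration input when
    the per-channel breakdown is not printed.
    """
    if physical_total < 0:
        raise InputValidationError("physical_total must be >= 0")
    if photon_equivalent_total < physical_total:
        raise InputValidationError(
            "photon-equivalent total below physical total is impossible for RBE >= 1"
        )
    if not rbe_nh > 1:
        raise InputValidationError("rbe_nh must be > 1 for the split to be identifiable")
    d_nh = (photon_equivalent_total - physical_total) / (rbe_nh - 1.0)
    d_gamma = physical_total - d_nh
    if d_nh < -1e-12 or d_gamma < -1e-12:
        raise InconsistentInputsError(
            f"inputs imply a negative component: d_nh={d_nh:.3g}, d_gamma={d_gamma:.3g}"
        )
    return max(d_nh, 0.0), max(d_gamma, 0.0)
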