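"""Clonogenic survival analysis: LQ model fitting, RBE and CBE estimation.

The linear-quadratic (LQ) model describes photon cell survival as

    SF(D) = exp(-alpha D - beta D^2)

Fitting is done on the log scale, -ln SF = alpha D + beta D^2, by
weighted least squares with non-negativity constraints on (alpha, beta).
The fitted curve is inverted to find the photon dose producing a chosen
survival endpoint (conventionally SF = 0.1), which anchors the relative
biological effectiveness (RBE) of a neutron beam and the compound
biological effectiveness (CBE) of each boron carrier:

    RBE  = D_photon(SF*) / D_beam(SF*)
    CBE  = (D_photon(SF*) - RBE_NH (D_N + D_H) - D_gamma) / D_B

i.e. the CBE is the inversion of the photon-equivalent dose equation at
the isoeffect endpoint, given a decomposition of the mixed field into
its boron and beam components.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from ._util import round_half_up
from .dose import DoseComponents
from .errors import (
    DegenerateFitError,
    InputValidationError,
    InsufficientDataError,
    UndefinedSFError,
)

__all__ = [
    "ColonyAssayRecord",
    "SurvivalFraction",
    "LQParameters",
    "LQModel",
    "LQResults",
    "MixedFieldModel",
    "survival_fraction",
    "lq_survival",
    "fit_lq",
    "dose_for_sf",
    "beam_rbe",
    "carrier_cbe",
]


@dataclass(frozen=True)
class ColonyAssayRecord:
    """One assay condition: replicate dishes seeded and counted.

    ``colonies`` holds one count per dish (three dishes per condition is
    the usual design); ``cells_seeded`` is the common seeding density or
    one value per dish.
    """

    label: str
    dose_gy: float
    cells_seeded: Sequence[float]
    colonies: Sequence[float]

    def __post_init__(self):
        seeded = np.atleast_1d(np.asarray(self.cells_seeded, dtype=float))
        counts = np.atleast_1d(np.asarray(self.colonies, dtype=float))
        if seeded.size == 1:
            seeded = np.full(counts.shape, seeded[0])
        if seeded.shape != counts.shape:
            raise InputValidationError("cells_seeded and colonies shapes differ")
        if counts.size < 1:
            raise InputValidationError("at least one dish is required")
        if np.any(counts < 0) or np.any(seeded <= 0):
            raise InputValidationError("counts must be >= 0 and seeded cells > 0")
        if np.any(counts > seeded):
            raise InputValidationError("colonies cannot exceed cells seeded")
        object.__setattr__(self, "cells_seeded", seeded)
        object.__setattr__(self, "colonies", counts)

    @property
    def plating_efficiencies(self) -> np.ndarray:
        return self.colonies / self.cells_seeded

    @property
    def plating_efficiency(self) -> float:
        """Mean of per-dish plating efficiencies."""
        return float(np.mean(self.plating_efficiencies))

    @property
    def plating_efficiency_se(self) -> float:
        pe = self.plating_efficiencies
        if pe.size < 2:
            return float("nan")
        return float(np.std(pe, ddof=1) / math.sqrt(pe.size))


@dataclass(frozen=True)
class SurvivalFraction:
    """A survival fraction with its propagated standard error."""

    sf: float
    se: float

    def __float__(self) -> float:
        return self.sf


def survival_fraction(treated: ColonyAssayRecord, control: ColonyAssayRecord) -> SurvivalFraction:
    """Survival fraction of a treated condition against its control.

    SF = mean plating efficiency (treated) / mean plating efficiency
    (control).  The standard error combines the replicate-dish spread of
    both conditions by first-order propagation of the ratio.
    """
    pe_c = control.plating_efficiency
    if pe_c <= 0:
        raise UndefinedSFError("control plating efficiency is zero; SF undefined")
    pe_t = treated.plating_efficiency
    if pe_t <= 0:
        raise UndefinedSFError(f"no colonies in treated condition {treated.label!r}; SF undefined")
    sf = pe_t / pe_c
    if sf > 1.0:
        warnings.warn(
            f"survival fraction {sf:.3f} > 1 for condition {treated.label!r}", stacklevel=2
        )
    rel = 0.0
    for rec, pe in ((treated, pe_t), (control, pe_c)):
        se = rec.plating_efficiency_se
        if np.isfinite(se):
            rel += (se / pe) ** 2
    return SurvivalFraction(sf=sf, se=sf * math.sqrt(rel))


@dataclass(frozen=True)
class LQParameters:
    """alpha (Gy^-1) and beta (Gy^-2) of the LQ photon survival model."""

    alpha: float
    beta: float

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise InputValidationError("alpha and beta must be >= 0")
        if self.alpha == 0 and self.beta == 0:
            raise InputValidationError("alpha and beta cannot both be zero")


def lq_survival(params: LQParameters, dose: float) -> float:
    """SF(D) = exp(-alpha D - beta D^2); equals 1 at D = 0."""
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise InputValidationError("dose must be >= 0")
    out = np.exp(-params.alpha * d - params.beta * d**2)
    return float(out) if np.isscalar(dose) or np.ndim(dose) == 0 else out


def dose_for_sf(params: LQParameters, sf_target: float) -> float:
    """Photon dose achieving a target survival fraction.

    The positive root of beta D^2 + alpha D - ln(1/sf) = 0; the beta -> 0
    limit ln(1/sf)/alpha is handled analytically.
    """
    if not 0 < sf_target <= 1:
        raise InputValidationError("sf_target must be in (0, 1]")
    if sf_target == 1.0:
        return 0.0
    ell = math.log(1.0 / sf_target)
    if params.beta == 0.0:
        return ell / params.alpha
    # stable form of the positive quadratic root: avoids cancellation
    # between alpha and the discriminant when beta*ell << alpha^2
    return 2.0 * ell / (params.alpha + math.sqrt(params.alpha**2 + 4.0 * params.beta * ell))


class LQModel:
    """Weighted least-squares LQ fit of clonogenic survival data.

    Built either from arrays of doses and survival fractions or, with
    :meth:`from_assay`, directly from replicate colony counts.  ``fit``
    returns an :class:`LQResults` carrying the estimates, diagnostics and
    a ``summary`` table, statsmodels-style.

    Parameters
    ----------
    doses : array-like, Gy
    sfs : sequence of float or SurvivalFraction
        Survival fractions in (0, 1]; SF = 1 points carry no information
        about the parameters but are accepted.
    weights : array-like, optional
        Weights on the -ln SF scale.  When SurvivalFraction objects with
        finite standard errors are supplied, defaults to 1/SE^2 of
        -ln SF (delta method: SE_lnSF = SE_SF / SF).
    """

    def __init__(self, doses, sfs, weights=None):
        doses = np.asarray(doses, dtype=float)
        sf_vals = np.array([float(s) for s in sfs], dtype=float)
        if doses.shape != sf_vals.shape:
            raise InputValidationError("doses and sfs must have the same length")
        if np.any(doses < 0):
            raise InputValidationError("doses must be >= 0")
        if np.any(sf_vals <= 0):
            raise InputValidationError("survival fractions must be > 0")
        # values slightly above 1 (sampling noise at low dose) are fitted
        # as-is; survival_fraction already flags them
        if np.unique(doses[doses > 0]).size < 3:
            raise InsufficientDataError("need >= 3 distinct positive doses to fit alpha and beta")
        if np.allclose(sf_vals, 1.0):
            raise DegenerateFitError("all survival fractions are 1; no dose response to fit")
        if weights is None:
            ses = np.array(
                [s.se if isinstance(s, SurvivalFraction) else np.nan for s in sfs], dtype=float
            )
            if np.all(np.isfinite(ses)) and np.all(ses > 0):
                weights = (sf_vals / ses) ** 2  # 1/SE^2 on the -ln SF scale
            else:
                weights = np.ones_like(sf_vals)
        self.doses = doses
        self.sfs = sf_vals
        self.weights = np.asarray(weights, dtype=float)
        self._records: Optional[Dict[float, ColonyAssayRecord]] = None
        self._control: Optional[ColonyAssayRecord] = None

    @classmethod
    def from_assay(
        cls, records: Sequence[ColonyAssayRecord], control: ColonyAssayRecord
    ) -> "LQModel":
        """Build the model from replicate colony counts.

        The control (0 Gy) condition normalises all survival fractions;
        keeping the raw records enables the parametric bootstrap in
        :meth:`LQResults.conf_int`.
        """
        sfs = [survival_fraction(r, control) for r in records]
        model = cls([r.dose_gy for r in records], sfs)
        model._records = {r.dose_gy: r for r in records}
        model._control = control
        return model

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, control_label: str = "control") -> "LQModel":
        """Build from a tidy colony-assay table.

        Expects columns ``group``, ``dose_gy``, ``cells_seeded``,
        ``colonies`` with one row per dish, and a 0 Gy control group.
        """
        records = []
        control = None
        for (group, dose), sub in df.groupby(["group", "dose_gy"], sort=True):
            rec = ColonyAssayRecord(
                label=str(group),
                dose_gy=float(dose),
                cells_seeded=sub["cells_seeded"].to_numpy(),
                colonies=sub["colonies"].to_numpy(),
            )
            if str(group) == control_label or (dose == 0 and control is None):
                control = rec
            else:
                records.append(rec)
        if control is None:
            raise InputValidationError("no control condition found (0 Gy or matching label)")
        return cls.from_assay(records, control)

    def fit(self) -> "LQResults":
        """Constrained weighted least squares on -ln SF = alpha D + beta D^2."""
        y = -np.log(self.sfs)
        X = np.column_stack([self.doses, self.doses**2])
        w = np.sqrt(self.weights)
        params, _ = optimize.nnls(X * w[:, None], y * w)
        unconstrained, *_ = np.linalg.lstsq(X * w[:, None], y * w, rcond=None)
        fitted = X @ params
        return LQResults(
            model=self,
            params=LQParameters(alpha=float(params[0]), beta=float(params[1])),
            unconstrained=tuple(float(v) for v in unconstrained),
            resid=y - fitted,
        )


@dataclass
class LQResults:
    """Fit results: parameter estimates, residuals and derived endpoints."""

    model: LQModel
    params: LQParameters
    unconstrained: tuple
    resid: np.ndarray
    _boot: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def alpha(self) -> float:
        return self.params.alpha

    @property
    def beta(self) -> float:
        return self.params.beta

    def predict(self, dose) -> np.ndarray:
        return lq_survival(self.params, dose)

    def dose_for_sf(self, sf_target: float = 0.1) -> float:
        return dose_for_sf(self.params, sf_target)

    def bootstrap(self, n_boot: int = 199, seed: Optional[int] = None) -> np.ndarray:
        """Parametric bootstrap replicates of (alpha, beta).

        Requires the model to have been built with :meth:`LQModel.from_assay`;
        dish counts are redrawn as Poisson around the fitted means and the
        constrained fit repeated.  Replicates are cached.
        """
        if self.model._records is None or self.model._control is None:
            raise InputValidationError("bootstrap requires replicate colony records")
        rng = np.random.default_rng(seed)
        control = self.model._control
        pe0 = control.plating_efficiency
        out = np.empty((n_boot, 2))
        records = list(self.model._records.values())
        for b in range(n_boot):
            ctrl_counts = rng.poisson(np.maximum(control.cells_seeded * pe0, 1e-9))
            ctrl_b = ColonyAssayRecord(
                label=control.label,
                dose_gy=control.dose_gy,
                cells_seeded=control.cells_seeded,
                colonies=np.minimum(ctrl_counts, control.cells_seeded),
            )
            sfs = []
            doses = []
            ok = True
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for rec in records:
                    mean = rec.cells_seeded * pe0 * lq_survival(self.params, rec.dose_gy)
                    counts = np.minimum(rng.poisson(np.maximum(mean, 1e-9)), rec.cells_seeded)
                    rec_b = ColonyAssayRecord(rec.label, rec.dose_gy, rec.cells_seeded, counts)
                    try:
                        sfs.append(survival_fraction(rec_b, ctrl_b))
                    except UndefinedSFError:
                        ok = False
                        break
                    doses.append(rec.dose_gy)
            if not ok:
                out[b] = out[b - 1] if b else (self.alpha, self.beta)
                continue
            try:
                res = LQModel(doses, sfs).fit()
                out[b] = (res.alpha, res.beta)
            except (InsufficientDataError, DegenerateFitError):
                out[b] = (self.alpha, self.beta)
        self._boot = out
        return out

    def conf_int(self, level: float = 0.95, n_boot: int = 199, seed: Optional[int] = None):
        """Percentile bootstrap confidence intervals for alpha and beta."""
        boot = self._boot if self._boot is not None and len(self._boot) >= n_boot else self.bootstrap(n_boot, seed)
        lo, hi = (1 - level) / 2 * 100, (1 + level) / 2 * 100
        ci = np.percentile(boot, [lo, hi], axis=0).T
        return pd.DataFrame(ci, index=["alpha", "beta"], columns=["lower", "upper"])

    def bse(self, n_boot: int = 199, seed: Optional[int] = None) -> pd.Series:
        boot = self._boot if self._boot is not None else self.bootstrap(n_boot, seed)
        return pd.Series(boot.std(axis=0, ddof=1), index=["alpha", "beta"])

    def summary(self) -> str:
        lines = [
            "Linear-quadratic survival fit (constrained WLS on -ln SF)",
            "=" * 57,
            f"n points:            {len(self.model.doses)}",
            f"alpha [Gy^-1]:       {self.alpha:.5f}",
            f"beta  [Gy^-2]:       {self.beta:.5f}",
            f"alpha/beta [Gy]:     {self.alpha / self.beta:.2f}" if self.beta > 0 else "alpha/beta [Gy]:     inf",
            f"D(SF=0.1) [Gy]:      {self.dose_for_sf(0.1):.3f}",
            f"resid SS (weighted): {float(np.sum(self.model.weights * self.resid**2)):.4g}",
            f"unconstrained (a,b): ({self.unconstrained[0]:.5f}, {self.unconstrained[1]:.5f})",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, max_dose: Optional[float] = None):
        """Survival-curve plot: data points and the fitted LQ curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        dmax = max_dose or float(self.model.doses.max()) * 1.1
        grid = np.linspace(0, dmax, 200)
        ax.semilogy(grid, self.predict(grid), "-", label="LQ fit")
        ax.semilogy(self.model.doses, self.model.sfs, "o", label="data")
        ax.set_xlabel("dose [Gy]")
        ax.set_ylabel("surviving fraction")
        ax.legend()
        return ax


def fit_lq(doses, sfs, weights=None) -> LQParameters:
    """Functional wrapper: fit the LQ model, return the parameters."""
    return LQModel(doses, sfs, weights=weights).fit().params


def beam_rbe(d_photon_ref: float, d_beam: float) -> float:
    """Relative biological effectiveness at a common survival endpoint."""
    if not d_beam > 0 or not d_photon_ref > 0:
        raise InputValidationError("both endpoint doses must be > 0")
    return d_photon_ref / d_beam


def carrier_cbe(
    d_photon_ref: float,
    components: DoseComponents,
    rbe_nh: float = 3.0,
) -> float:
    """Compound biological effectiveness of a boron carrier.

    Inverts the photon-equivalent equation at the isoeffect endpoint:

        CBE = (D_photon_ref - rbe_nh (D_N + D_H) - D_gamma) / D_B

    ``components`` is the decomposition of the carrier group's mixed
    field at the endpoint (see :class:`MixedFieldModel`).  CBE below 1 is
    a valid outcome (the carrier is less effective per Gy of boron dose
    than photons); a negative value indicates an inconsistent
    decomposition and is flagged with a warning.
    """
    if components.d_boron <= 0:
        raise InputValidationError("carrier contributes no boron dose; CBE undefined")
    cbe = (
        d_photon_ref - rbe_nh * (components.d_nitrogen + components.d_hydrogen) - components.d_gamma
    ) / components.d_boron
    if cbe < 0:
        warnings.warn(f"negative CBE ({cbe:.3f}): beam terms exceed the photon reference", stacklevel=2)
    return cbe


class MixedFieldModel:
    """Time-scaled decomposition of an in vitro mixed neutron field.

    The reactor run deposits a beam (non-boron) physical dose that is a
    fixed, tabulated function of irradiation time, plus a boron capture
    dose proportional to time and to the carrier's effective
    intracellular boron concentration:

        D_beam(t)  = ladder(t)                     (lookup, piecewise linear)
        D_B(t)     = kerma_B10 * flux * c_eff * t

    The beam dose is split into high-LET (N+H) and gamma parts by fixed
    fractions.  Given the beam dose at a carrier group's survival
    endpoint the model returns the full component decomposition needed
    by :func:`carrier_cbe`; conversely, :meth:`calibrate_concentration`
    solves for the effective concentration that reproduces a known CBE,
    which is how carriers whose absolute cellular concentrations were
    never published are pinned to their reported effectiveness.

    Parameters
    ----------
    ladder_times_s, ladder_doses_gy : arrays
        The irradiation-time -> beam-physical-dose lookup, extrapolated
        linearly beyond the last tabulated point.
    nh_fraction : float
        Fraction of the beam dose carried by the nitrogen + hydrogen
        channels (the remainder is gamma).
    boron_gy_per_s_per_conc : float
        kerma_B10 x thermal flux, Gy/s per (ug 10B/g).
    concentrations : dict, optional
        Effective intracellular boron concentration per carrier,
        ug 10B / 10^9 cells (numerically treated as ug/g).
    """

    def __init__(
        self,
        ladder_times_s,
        ladder_doses_gy,
        nh_fraction: float,
        boron_gy_per_s_per_conc: float,
        concentrations: Optional[Dict[str, float]] = None,
    ):
        t = np.asarray(ladder_times_s, dtype=float)
        d = np.asarray(ladder_doses_gy, dtype=float)
        if t.size < 2 or t.shape != d.shape:
            raise InputValidationError("ladder needs >= 2 matching time/dose points")
        if np.any(np.diff(t) <= 0) or np.any(np.diff(d) < 0):
            raise InputValidationError("ladder must be increasing in time, non-decreasing in dose")
        if not 0 <= nh_fraction <= 1:
            raise InputValidationError("nh_fraction must be in [0, 1]")
        if not boron_gy_per_s_per_conc > 0:
            raise InputValidationError("boron dose-rate coefficient must be > 0")
        self.ladder_t = t
        self.ladder_d = d
        self.nh_fraction = float(nh_fraction)
        self.boron_rate = float(boron_gy_per_s_per_conc)
        self.concentrations = dict(concentrations or {})

    def beam_dose(self, time_s: float) -> float:
        """Beam physical dose at an irradiation time (linear extrapolation)."""
        t = float(time_s)
        if t < 0:
            raise InputValidationError("time must be >= 0")
        if t <= self.ladder_t[-1]:
            return float(np.interp(t, self.ladder_t, self.ladder_d))
        slope = (self.ladder_d[-1] - self.ladder_d[-2]) / (self.ladder_t[-1] - self.ladder_t[-2])
        return float(self.ladder_d[-1] + slope * (t - self.ladder_t[-1]))

    def time_for_beam_dose(self, dose_gy: float) -> float:
        """Inverse of :meth:`beam_dose`."""
        d = float(dose_gy)
        if d < 0:
            raise InputValidationError("dose must be >= 0")
        if d <= self.ladder_d[-1]:
            return float(np.interp(d, self.ladder_d, self.ladder_t))
        slope = (self.ladder_d[-1] - self.ladder_d[-2]) / (self.ladder_t[-1] - self.ladder_t[-2])
        return float(self.ladder_t[-1] + (d - self.ladder_d[-1]) / slope)

    def decompose(self, carrier: str, beam_dose_gy: float) -> DoseComponents:
        """Component decomposition at a given beam dose for a carrier."""
        try:
            c_eff = self.concentrations[carrier]
        except KeyError:
            raise InputValidationError(f"no effective concentration for carrier {carrier!r}") from None
        t = self.time_for_beam_dose(beam_dose_gy)
        return DoseComponents.from_lumped(
            d_boron=self.boron_rate * c_eff * t,
            d_nh=beam_dose_gy * self.nh_fraction,
            d_gamma=beam_dose_gy * (1.0 - self.nh_fraction),
        )

    def derive_cbe(
        self, carrier: str, beam_dose_at_endpoint: float, d_photon_ref: float, rbe_nh: float = 3.0
    ) -> float:
        """CBE of a carrier from its endpoint beam dose."""
        return carrier_cbe(d_photon_ref, self.decompose(carrier, beam_dose_at_endpoint), rbe_nh)

    def calibrate_concentration(
        self,
        carrier: str,
        beam_dose_at_endpoint: float,
        target_cbe: float,
        d_photon_ref: float,
        rbe_nh: float = 3.0,
    ) -> float:
        """Solve for the effective concentration reproducing a known CBE.

        Stores and returns c_eff such that ``derive_cbe`` returns exactly
        ``target_cbe`` for this carrier.
        """
        if not target_cbe > 0:
            raise InputValidationError("target CBE must be > 0")
        b = float(beam_dose_at_endpoint)
        numerator = d_photon_ref - rbe_nh * b * self.nh_fraction - b * (1.0 - self.nh_fraction)
        if numerator <= 0:
            raise InputValidationError(
                "beam terms already exceed the photon reference; no positive boron dose fits"
            )
        d_b = numerator / target_cbe
        t = self.time_for_beam_dose(b)
        c_eff = d_b / (self.boron_rate * t)
        self.concentrations[carrier] = c_eff
        return c_eff

    def photon_equivalent_dose_rate_weight(self, rbe_nh: float = 3.0) -> float:
        """Photon-equivalent Gy-Eq per Gy of beam physical dose."""
        return rbe_nh * self.nh_fraction + (1.0 - self.nh_fraction)

    def group_survival(self, carrier: Optional[str], time_s: float, cbe: float,
                       lq: LQParameters, rbe_nh: float = 3.0) -> float:
        """Predicted mixed-field survival via the photon-isoeffect assumption.

        The photon-equivalent dose accumulated by time t is converted to a
        survival fraction through the photon LQ curve.
        """
        b = self.beam_dose(time_s)
        d_eq = b * self.photon_equivalent_dose_rate_weight(rbe_nh)
        if carrier is not None:
            c_eff = self.concentrations[carrier]
            d_eq += cbe * self.boron_rate * c_eff * time_s
        return lq_survival(lq, d_eq)


def cbe_table(model: MixedFieldModel, endpoints: Dict[str, float], d_photon_ref: float,
              rbe_nh: float = 3.0) -> pd.DataFrame:
    """Tabulate derived CBE factors for several carriers.

    ``endpoints`` maps carrier -> beam physical dose at the SF endpoint.
    """
    rows = []
    for carrier, b in endpoints.items():
        comp = model.decompose(carrier, b)
        cbe = carrier_cbe(d_photon_ref, comp, rbe_nh)
        rows.append(
            {
                "carrier": carrier,
                "beam_dose_gy": b,
                "d_boron_gy": comp.d_boron,
                "cbe": cbe,
                "cbe_rounded": round_half_up(cbe, 2),
            }
        )
    return pd.DataFrame(rows)
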