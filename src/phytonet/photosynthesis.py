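"""Standard leaf-physiology models: forward simulation and curve fitting.

Forward models
--------------
* C3 net assimilation follows the Farquhar–von Caemmerer–Berry (FvCB)
  construction: Rubisco-limited Ac = Vcmax (Ci - G*) / (Ci + Kc (1 + O/Ko)),
  RuBP-regeneration-limited Aj = J (Ci - G*) / (4 Ci + 8 G*), and
  A = min(Ac, Aj) - Rd with a hard minimum (no hyperbolic smoothing) by
  default.
* The C4 model is the simplified enzyme-limited form: net assimilation is
  the minimum of a Rubisco-limited plateau (Vcmax), a PEP-carboxylation
  supply rate Vpmax Ci / (Ci + Kp), and an optional light-limited rate J/6,
  minus Rd. It saturates at much lower Ci than the C3 form.
* The light response is the non-rectangular hyperbola in PPFD (Q):
  A = [phi Q + Amax - sqrt((phi Q + Amax)^2 - 4 theta phi Q Amax)] / (2 theta) - Rd,
  which reduces to the rectangular hyperbola as theta -> 0 and gives
  A(0) = -Rd exactly.

Kinetic constants default to the widely used 25 degC Rubisco values
(Kc = 404.9 umol/mol, Ko = 278.4 mmol/mol, G* = 42.75 umol/mol,
O = 210 mmol/mol); no temperature scaling is applied by default, since the
target use is a controlled-cuvette protocol at a single leaf temperature.

Fitting
-------
:func:`fit_aci` and :func:`fit_light` are nonlinear least-squares fits
(lmfit/Levenberg-Marquardt) with deterministic initialisation: the apparent
quantum yield from the slope of the lowest-light points, Amax from the
largest observed assimilation, Vcmax from the low-Ci region. Non-convergence
raises :class:`~phytonet.errors.FitError` with diagnostics, never silent
defaults.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .errors import DomainError, FitError, ValidationError

# ------------------------------------------------------------------- kinetics


@dataclass(frozen=True)
class C3Kinetics:
    """Rubisco kinetic constants at 25 degC (mole-fraction units)."""

    kc: float = 404.9       # Michaelis constant for CO2, umol mol-1
    ko: float = 278.4       # Michaelis constant for O2, mmol mol-1
    gamma_star: float = 42.75  # CO2 compensation point without Rd, umol mol-1
    o2: float = 210.0       # oxygen mole fraction, mmol mol-1

    @property
    def km(self) -> float:
        """Effective Michaelis constant Kc (1 + O/Ko), umol mol-1."""
        return self.kc * (1.0 + self.o2 / self.ko)


DEFAULT_KINETICS = C3Kinetics()

#: Default Michaelis constant of PEP carboxylase for CO2, umol mol-1.
DEFAULT_KP = 80.0

#: Photorespiration in C4 leaves is suppressed by the CO2-concentrating
#: mechanism; modelled as a fixed small fraction of Vcmax.
C4_PHOTORESP_FRACTION = 0.015


# -------------------------------------------------------------- forward models


def fvcb_c3_forward(ci, vcmax: float, j: float, rd: float,
                    kinetics: C3Kinetics = DEFAULT_KINETICS):
    """C3 net assimilation A(Ci); A = -Rd exactly at Ci = G*."""
    ci = np.asarray(ci, dtype=float)
    if np.any(ci <= 0):
        raise DomainError("Ci must be > 0")
    if min(vcmax, j) <= 0 or rd < 0:
        raise DomainError("Vcmax, J must be > 0 and Rd >= 0")
    g = kinetics.gamma_star
    ac = vcmax * (ci - g) / (ci + kinetics.km)
    aj = j * (ci - g) / (4.0 * ci + 8.0 * g)
    a = np.minimum(ac, aj) - rd
    return float(a) if a.ndim == 0 else a


def c4_forward(ci, vcmax: float, vpmax: float, rd: float,
               kp: float = DEFAULT_KP, j: float | None = None):
    """Simplified C4 net assimilation: min of enzyme-limited rates minus Rd."""
    ci = np.asarray(ci, dtype=float)
    if np.any(ci <= 0):
        raise DomainError("Ci must be > 0")
    if min(vcmax, vpmax) <= 0 or rd < 0 or kp <= 0:
        raise DomainError("Vcmax, Vpmax, Kp must be > 0 and Rd >= 0")
    rates = np.minimum(vcmax, vpmax * ci / (ci + kp))
    if j is not None:
        rates = np.minimum(rates, j / 6.0)
    a = rates - rd
    return float(a) if a.ndim == 0 else a


def photorespiration(vcmax: float, ci: float, pathway: str = "C3",
                     kinetics: C3Kinetics = DEFAULT_KINETICS) -> float:
    """Photorespiratory CO2 release, umol m-2 s-1.

    C3: half the oxygenation rate, 0.5 Vo = Vc G*/Ci with Vc at the
    operating Ci, i.e. Vcmax G* / (Ci + Km). C4: a fixed small fraction of
    Vcmax (bundle-sheath CO2 concentration suppresses oxygenation).
    """
    if vcmax <= 0 or ci <= 0:
        raise DomainError("Vcmax and Ci must be > 0")
    if pathway == "C3":
        return vcmax * kinetics.gamma_star / (ci + kinetics.km)
    if pathway == "C4":
        return C4_PHOTORESP_FRACTION * vcmax
    raise ValidationError(f"unknown pathway {pathway!r}")


def light_response(q, amax: float, phi: float, theta: float, rd: float):
    """Non-rectangular hyperbola A(Q); theta -> 0 gives the rectangular form."""
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise DomainError("PPFD must be >= 0")
    if amax <= 0 or phi <= 0 or rd < 0 or not 0 <= theta <= 1:
        raise DomainError("require Amax, phi > 0, Rd >= 0, theta in [0, 1]")
    s = phi * q + amax
    if theta < 1e-9:
        gross = np.where(s > 0, phi * q * amax / np.where(s > 0, s, 1.0), 0.0)
    else:
        gross = (s - np.sqrt(np.maximum(s * s - 4.0 * theta * phi * q * amax, 0.0))) \
            / (2.0 * theta)
    a = gross - rd
    return float(a) if a.ndim == 0 else a


def stomatal_limitation(a_operational: float, a_at_ca: float) -> float:
    """Relative stomatal limitation Ls = 100 (A(Ci=Ca) - A(Ci_op)) / A(Ci=Ca), %.

    A negative value (operational A above the Ca-evaluated A, a
    supersaturation artifact) is returned with a warning.
    """
    if a_at_ca <= 0:
        raise DomainError("A at Ci = Ca must be > 0")
    ls = 100.0 * (a_at_ca - a_operational) / a_at_ca
    if ls < 0:
        warnings.warn(
            "operational A exceeds A at Ci = Ca: negative stomatal limitation",
            RuntimeWarning, stacklevel=2,
        )
    return float(ls)


# ---------------------------------------------------------------- fluorescence


@dataclass(frozen=True)
class FluorRecord:
    """One set of raw chlorophyll-a fluorescence signals (arbitrary units).

    Fo/Fm are dark-adapted minimal/maximal fluorescence, Fs/Fm'/Fo' the
    light-adapted steady-state, maximal and minimal signals at PPFD.
    """

    fo: float
    fm: float
    fs: float
    fm_prime: float
    fo_prime: float
    ppfd: float
    absorptance: float = 0.84
    psii_fraction: float = 0.5

    def __post_init__(self):
        checks = [
            (self.fo > 0, "fo must be > 0"),
            (self.fm > self.fo, "fm must exceed fo"),
            (self.fs > 0, "fs must be > 0"),
            (self.fm_prime > self.fs, "fm_prime must exceed fs"),
            (self.fm >= self.fm_prime, "fm must be >= fm_prime"),
            (self.fo_prime > 0, "fo_prime must be > 0"),
            (self.ppfd >= 0, "ppfd must be >= 0"),
            (0 < self.absorptance <= 1, "absorptance must be in (0, 1]"),
            (0 < self.psii_fraction <= 1, "psii_fraction must be in (0, 1]"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValidationError(msg)


@dataclass(frozen=True)
class FluorParams:
    fvfm: float      # potential PSII quantum efficiency (Fm - Fo)/Fm
    df_fm: float     # effective PSII quantum efficiency (Fm' - Fs)/Fm'
    qp: float        # photochemical quenching (Fm' - Fs)/(Fm' - Fo')
    npq: float       # non-photochemical quenching Fm/Fm' - 1
    etr: float       # apparent electron transport, df_fm * PPFD * fPSII * abs


def fluorescence_params(rec: FluorRecord) -> FluorParams:
    """Standard PSII parameters from raw signals; scale-invariant in the signals."""
    fvfm = (rec.fm - rec.fo) / rec.fm
    df_fm = (rec.fm_prime - rec.fs) / rec.fm_prime
    qp = (rec.fm_prime - rec.fs) / (rec.fm_prime - rec.fo_prime)
    npq = rec.fm / rec.fm_prime - 1.0
    etr = df_fm * rec.ppfd * rec.psii_fraction * rec.absorptance
    return FluorParams(float(fvfm), float(df_fm), float(qp), float(npq), float(etr))


def alternative_electron_sink(etr: float, a: float, rd: float,
                              electrons_per_co2: float = 4.0) -> float:
    """AES: electron flow unexplained by net carbon metabolism.

    Default variant: (ETR / electrons_per_CO2) / (A + Rd). The divisor of 4
    is the minimal electron cost per CO2 fixed; species-specific variants
    can change ``electrons_per_co2``.
    """
    if a + rd <= 0:
        raise DomainError("A + Rd must be > 0")
    if electrons_per_co2 <= 0:
        raise DomainError("electrons_per_co2 must be > 0")
    return float((etr / electrons_per_co2) / (a + rd))


# --------------------------------------------------------------------- curves


@dataclass
class ACiCurve:
    """CO2-response curve: (Ci, A) points at fixed leaf temperature and light."""

    ci: np.ndarray
    a: np.ndarray
    leaf_temp: float = 30.0
    ppfd: float = 1200.0
    ca: float = 380.0

    def __post_init__(self):
        self.ci = np.asarray(self.ci, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.ci.shape != self.a.shape or self.ci.ndim != 1:
            raise ValidationError("ci and a must be 1-d arrays of equal length")
        if np.any(self.ci < 0):
            raise ValidationError("Ci must be >= 0")
        order = np.argsort(self.ci)
        self.ci, self.a = self.ci[order], self.a[order]
        if np.any(np.diff(self.ci) <= 0):
            raise ValidationError("Ci values must be distinct")
        if len(self.ci) < 5:
            raise ValidationError("need >= 5 points to fit an A/Ci curve")


@dataclass
class LightCurve:
    """Light-response curve: (PPFD, A) points."""

    q: np.ndarray
    a: np.ndarray
    leaf_temp: float = 30.0
    ca: float = 380.0

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.q.shape != self.a.shape or self.q.ndim != 1:
            raise ValidationError("q and a must be 1-d arrays of equal length")
        if np.any(self.q < 0):
            raise ValidationError("PPFD must be >= 0")
        order = np.argsort(self.q)
        self.q, self.a = self.q[order], self.a[order]
        if len(self.q) < 5:
            raise ValidationError("need >= 5 points to fit a light curve")
        if self.q[0] > 100:
            raise ValidationError("light curve needs low-light points (PPFD <= 100)")


@dataclass
class LeafParams:
    """Replicate-level derived leaf parameters."""

    amax_l: float
    amax_co2: float
    rd: float
    pr: float
    vcmax: float
    ls: float
    pathway: str = "C3"

    def __post_init__(self):
        if self.pathway not in ("C3", "C4"):
            raise ValidationError(f"pathway must be C3 or C4, got {self.pathway!r}")
        for name in ("amax_l", "amax_co2", "rd", "pr", "vcmax"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0 <= self.ls <= 100:
            raise ValidationError("ls must be within [0, 100]")


@dataclass
class FitResult:
    params: dict[str, float]
    success: bool
    rmse: float
    nfev: int
    message: str
    stderr: dict[str, float | None] = field(default_factory=dict)


def _finish_fit(result, data, model_at) -> FitResult:
    resid = model_at(result.params) - data
    rmse = float(np.sqrt(np.mean(resid**2)))
    out = FitResult(
        params={k: float(v.value) for k, v in result.params.items()},
        success=bool(result.success),
        rmse=rmse,
        nfev=int(result.nfev),
        message=str(result.message),
        stderr={k: (float(v.stderr) if v.stderr is not None else None)
                for k, v in result.params.items()},
    )
    if not out.success:
        raise FitError(f"fit did not converge: {out.message}",
                       diagnostics={"rmse": rmse, "nfev": out.nfev})
    return out


def fit_aci(curve: ACiCurve, pathway: str = "C3",
            kinetics: C3Kinetics = DEFAULT_KINETICS) -> FitResult:
    """Fit an A/Ci curve; returns Vcmax, J (or Vpmax), Rd and amax_co2.

    ``amax_co2`` is the model-predicted net assimilation at Ci = 2000
    umol/mol, the CO2-saturated plateau read-out.
    """
    ci, a = curve.ci, curve.a
    if np.ptp(a) < 1e-9:
        raise FitError("degenerate A/Ci curve: all assimilation values identical")
    rd0 = max(0.5, float(-a.min()) if a.min() < 0 else 1.0)
    params = lmfit.Parameters()
    if pathway == "C3":
        low = (ci > kinetics.gamma_star + 10) & (ci < 500)
        if low.sum() >= 1:
            vc0 = float(np.median(
                (a[low] + rd0) * (ci[low] + kinetics.km) / (ci[low] - kinetics.gamma_star)
            ))
        else:  # pragma: no cover - precondition requires sub-ambient points
            vc0 = 50.0
        j0 = max(4.0 * (float(a.max()) + rd0) * 1.1, 20.0)
        params.add("vcmax", value=max(vc0, 5.0), min=1e-3)
        params.add("j", value=j0, min=1e-3)
        params.add("rd", value=rd0, min=0.0)

        def model_at(p):
            return fvcb_c3_forward(ci, p["vcmax"].value, p["j"].value,
                                   p["rd"].value, kinetics)
    elif pathway == "C4":
        vc0 = float(a.max()) + rd0
        params.add("vcmax", value=max(vc0, 1.0), min=1e-3)
        params.add("vpmax", value=max(2.0 * vc0, 2.0), min=1e-3)
        params.add("rd", value=rd0, min=0.0)

        def model_at(p):
            return c4_forward(ci, p["vcmax"].value, p["vpmax"].value, p["rd"].value)
    else:
        raise ValidationError(f"unknown pathway {pathway!r}")

    result = lmfit.minimize(lambda p: model_at(p) - a, params, method="leastsq")
    fit = _finish_fit(result, a, model_at)
    p = fit.params
    if pathway == "C3":
        fit.params["amax_co2"] = float(
            fvcb_c3_forward(2000.0, p["vcmax"], p["j"], p["rd"], kinetics))
    else:
        fit.params["amax_co2"] = float(
            c4_forward(2000.0, p["vcmax"], p["vpmax"], p["rd"]))
    return fit


def fit_light(curve: LightCurve) -> FitResult:
    """Fit the non-rectangular hyperbola; returns amax, rd, phi, theta.

    ``amax`` is the light-saturated *gross* plateau; the light-saturated net
    assimilation is amax - rd.
    """
    q, a = curve.q, curve.a
    if np.ptp(a) < 1e-9:
        raise FitError("degenerate light curve: all assimilation values identical")
    # phi from the slope of the 3 lowest-light points; rd from the intercept
    coef = np.polyfit(q[:3], a[:3], 1)
    phi0 = float(np.clip(coef[0], 0.01, 0.12))
    rd0 = float(np.clip(-coef[1], 0.05, 10.0))
    amax0 = float(a.max()) + rd0
    params = lmfit.Parameters()
    params.add("amax", value=max(amax0, 1.0), min=1e-3)
    params.add("rd", value=rd0, min=0.0)
    params.add("phi", value=phi0, min=1e-4, max=0.5)
    params.add("theta", value=0.7, min=0.0, max=1.0 - 1e-9)

    def model_at(p):
        return light_response(q, p["amax"].value, p["phi"].value,
                              p["theta"].value, p["rd"].value)

    result = lmfit.minimize(lambda p: model_at(p) - a, params, method="leastsq")
    return _finish_fit(result, a, model_at)
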