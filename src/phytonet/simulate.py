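"""Synthetic replicate-level data with known statistical structure.

Two generator tiers:

1. :func:`simulate_correlated` — multivariate-normal draws with an exact
   target correlation matrix. This gives distributional ground truth for the
   connectance statistic (e.g. equicorrelated data with correlation rho has
   population module connectance atanh(rho)).
2. :func:`simulate_leaf_experiment` — a mechanistic leaf simulator. Each
   replicate plant draws its physiological parameters (Vcmax, J or Vpmax,
   Rd, gs, PSII yields, NPQ, biomass) from lognormal distributions tied
   together by a single latent "vigor" factor; the forward models of
   :mod:`phytonet.photosynthesis` then turn parameters into the measured
   variables at fixed cuvette conditions (leaf temperature 30 degC,
   Ca = 380 umol/mol, saturating PPFD 1200 umol m-2 s-1, VPD 1.5 kPa).
   The scenario's ``coupling`` in [0, 1] scales every latent-factor loading,
   so raising it monotonically raises all cross-variable correlations —
   including the ETR–AmaxL linking correlation.

:func:`preset_scenarios` encodes the two factorial study designs this
package is built around: 2 species (a C3 soybean-like and a C4
Brachiaria-like crop) x 3 day temperatures (20/30/40 degC) and the same
2 species x 2 water regimes (100% vs 30% replacement of transpired water),
both with 7 replicate plants per cell. Parameter means follow the published
treatment means; couplings rise with stress so that connectance increases
with temperature and with water deficit, the qualitative published pattern.

All generators are pure functions of (scenario, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .connectance import ReplicateTable
from .errors import DomainError, ValidationError
from .photosynthesis import (
    ACiCurve,
    FluorRecord,
    LightCurve,
    c4_forward,
    fit_aci,
    fit_light,
    fluorescence_params,
    fvcb_c3_forward,
    light_response,
    photorespiration,
    stomatal_limitation,
)

# Cuvette measurement conditions shared by every simulated replicate.
CA = 380.0          # ambient CO2, umol mol-1
PPFD_SAT = 1200.0   # saturating measurement light, umol m-2 s-1
VPD = 1.5           # leaf-air vapour pressure deficit, kPa
P_AIR = 101.3       # air pressure, kPa


# --------------------------------------------------- direct correlation tier


@dataclass
class CorrelationScenario:
    """Multivariate-normal scenario with an explicit target correlation matrix."""

    variables: list[str]
    target_corr: np.ndarray
    n_replicates: int
    seed: int = 0
    means: np.ndarray | None = None
    sds: np.ndarray | None = None
    species: str = "synthetic"
    treatment: str = "scenario"

    def __post_init__(self):
        k = len(self.variables)
        C = np.asarray(self.target_corr, dtype=float)
        if C.shape != (k, k):
            raise ValidationError(f"target_corr must be {k}x{k}")
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValidationError("target_corr must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-8):
            raise ValidationError("target_corr diagonal must be 1 (not repairable)")
        self.target_corr = C
        self.means = np.zeros(k) if self.means is None else np.asarray(self.means, float)
        self.sds = np.ones(k) if self.sds is None else np.asarray(self.sds, float)
        if np.any(self.sds <= 0):
            raise ValidationError("sds must be > 0")
        if self.n_replicates < 2:
            raise ValidationError("n_replicates must be >= 2")


def repair_psd(C: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Clip negative eigenvalues and rescale to unit diagonal (with warning)."""
    w, V = np.linalg.eigh(C)
    if w.min() >= -tol:
        return C
    warnings.warn(
        f"target correlation matrix has negative eigenvalue {w.min():.3g}; "
        "repairing to the nearest PSD matrix", RuntimeWarning, stacklevel=2,
    )
    w = np.clip(w, 0.0, None)
    R = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(R))
    return R / np.outer(d, d)


def simulate_correlated(scenario: CorrelationScenario) -> ReplicateTable:
    """Draws with the (repaired) target correlation; deterministic given seed."""
    C = repair_psd(scenario.target_corr)
    w, V = np.linalg.eigh(C)
    root = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    rng = np.random.default_rng(scenario.seed)
    Z = rng.standard_normal((scenario.n_replicates, len(scenario.variables)))
    X = scenario.means + scenario.sds * (Z @ root.T)
    return ReplicateTable(
        species=scenario.species, treatment=scenario.treatment,
        data=pd.DataFrame(X, columns=list(scenario.variables)),
    )


def equicorrelated_scenario(n_variables: int, rho: float, n_replicates: int,
                            seed: int = 0, variables=None) -> CorrelationScenario:
    """Convenience: all off-diagonal correlations equal to rho."""
    if not -1.0 / (n_variables - 1) <= rho < 1.0:
        raise ValidationError("rho outside the PSD range for this dimension")
    C = np.full((n_variables, n_variables), rho)
    np.fill_diagonal(C, 1.0)
    names = list(variables) if variables is not None else \
        [f"v{i}" for i in range(n_variables)]
    return CorrelationScenario(names, C, n_replicates, seed=seed)


# ------------------------------------------------------------ mechanistic tier

#: Relative latent-factor loading per parameter; the scenario's ``coupling``
#: multiplies these. NPQ loads negatively (stressed, low-vigor plants quench
#: more); sign is irrelevant to connectance, which uses |r|.
PARAM_LOADINGS = {
    "vcmax": 1.0, "j": 1.0, "vpmax": 1.0, "rd": 0.7, "gs": 0.9,
    "phi2": 1.0, "fvfm": 0.6, "npq": -0.8, "dmt": 0.8, "la": 0.6,
}

DEFAULT_CVS = {
    "vcmax": 0.12, "j": 0.12, "vpmax": 0.12, "rd": 0.12, "gs": 0.15,
    "phi2": 0.10, "fvfm": 0.02, "npq": 0.15, "dmt": 0.20, "la": 0.20,
}


@dataclass
class LeafScenario:
    """One species x treatment cell of a mechanistic simulation.

    ``means`` holds the population parameter means (vcmax, j or vpmax, rd,
    gs, phi2 = effective PSII yield at measurement light, fvfm, npq, dmt,
    la); ``cvs`` their coefficients of variation; ``coupling`` in [0, 1]
    scales all latent-factor loadings; ``noise_sd`` is the multiplicative
    measurement noise per reported variable.
    """

    species: str
    treatment: str
    pathway: str
    means: dict[str, float]
    cvs: dict[str, float] = field(default_factory=dict)
    coupling: float = 0.6
    noise_sd: float = 0.03
    n_replicates: int = 7
    seed: int | None = None

    def __post_init__(self):
        if self.pathway not in ("C3", "C4"):
            raise ValidationError(f"pathway must be C3 or C4, got {self.pathway!r}")
        if not -1.0 <= self.coupling <= 1.0:
            raise ValidationError("coupling must lie in [-1, 1]")
        if self.n_replicates < 3:
            raise ValidationError("n_replicates must be >= 3")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        required = {"vcmax", "rd", "gs", "phi2", "fvfm", "npq"}
        required.add("j" if self.pathway == "C3" else "vpmax")
        missing = sorted(required - set(self.means))
        if missing:
            raise ValidationError(f"scenario means missing parameters: {missing}")
        if any(v <= 0 for v in self.means.values()):
            raise ValidationError("parameter means must be > 0")
        self.cvs = {**DEFAULT_CVS, **self.cvs}
        if any(v < 0 for v in self.cvs.values()):
            raise ValidationError("CVs must be >= 0")


def _draw_params(scenario: LeafScenario, rng) -> dict[str, float]:
    """Lognormal parameter draws sharing one latent vigor factor."""
    f = rng.standard_normal()
    out = {}
    for name, mean in scenario.means.items():
        cv = scenario.cvs.get(name, 0.1)
        lam = float(np.clip(scenario.coupling * PARAM_LOADINGS.get(name, 0.5), -1, 1))
        u = lam * f + np.sqrt(max(1.0 - lam * lam, 0.0)) * rng.standard_normal()
        sigma = np.sqrt(np.log1p(cv * cv))
        out[name] = mean * np.exp(sigma * u - 0.5 * sigma * sigma)
    return out


def _forward(ci, p, pathway):
    if pathway == "C3":
        return fvcb_c3_forward(ci, p["vcmax"], p["j"], p["rd"])
    return c4_forward(ci, p["vcmax"], p["vpmax"], p["rd"])


def _operating_point(p, pathway):
    """Solve the A–Ci supply/demand intersection: Ci = Ca - 1.6 A / gs."""
    gs = p["gs"]

    def gap(ci):
        return CA - 1.6 * _forward(ci, p, pathway) / gs - ci

    lo = 43.0 if pathway == "C3" else 1.0  # just above the C3 compensation point
    if _forward(CA, p, pathway) <= 0:
        return CA, _forward(CA, p, pathway)
    ci = brentq(gap, lo, CA, xtol=1e-6)
    return ci, _forward(ci, p, pathway)


def _fluor_signals(fvfm, phi2, npq):
    """Raw fluorescence signals consistent with the target parameter values.

    Fo is an arbitrary scale; Fo' follows the standard reconstruction
    Fo' = Fo / (Fv/Fm + Fo/Fm').
    """
    fo = 500.0
    fm = fo / (1.0 - fvfm)
    fm_prime = fm / (1.0 + npq)
    fs = fm_prime * (1.0 - phi2)
    fo_prime = fo / (fvfm + fo / fm_prime)
    return fo, fm, fs, fm_prime, fo_prime


_Q_GRID = np.array([0, 25, 50, 75, 100, 150, 200, 300, 450, 600, 800,
                    1000, 1200, 1500, 2000], dtype=float)
_CI_GRID = np.array([50, 100, 150, 250, 400, 600, 800, 1100, 1500], dtype=float)
_PHI_Q = {"C3": 0.055, "C4": 0.065}  # apparent quantum yield on incident PPFD
_THETA = 0.75


def _simulate_replicate(scenario: LeafScenario, rng, refit: bool) -> dict[str, float]:
    p = _draw_params(scenario, rng)
    pathway = scenario.pathway
    ci_op, a_op = _operating_point(p, pathway)
    if a_op <= 0:
        raise DomainError("non-positive operational assimilation")

    amax_gross = _forward(ci_op, p, pathway) + p["rd"]  # light-saturated gross rate
    phi, theta = _PHI_Q[pathway], _THETA

    if refit:
        a_q = light_response(_Q_GRID, amax_gross, phi, theta, p["rd"])
        a_q = a_q + scenario.noise_sd * max(amax_gross, 1.0) * rng.standard_normal(len(_Q_GRID))
        lfit = fit_light(LightCurve(_Q_GRID, a_q))
        amax_l = lfit.params["amax"] - lfit.params["rd"]
        rd_v = lfit.params["rd"]
        a_ci = _forward(_CI_GRID, p, pathway)
        a_ci = a_ci + scenario.noise_sd * max(a_ci.max(), 1.0) * rng.standard_normal(len(_CI_GRID))
        afit = fit_aci(ACiCurve(_CI_GRID, a_ci), pathway=pathway)
        vcmax_v = afit.params["vcmax"]
        amax_co2 = afit.params["amax_co2"]
    else:
        amax_l = light_response(2000.0, amax_gross, phi, theta, p["rd"])
        rd_v = p["rd"]
        vcmax_v = p["vcmax"]
        amax_co2 = _forward(2000.0, p, pathway)

    pr = photorespiration(p["vcmax"], ci_op, pathway)
    ls = stomatal_limitation(a_op, _forward(CA, p, pathway))

    fvfm = float(np.clip(p["fvfm"], 0.4, 0.87))
    phi2 = float(np.clip(p["phi2"], 0.02, fvfm - 0.02))
    fo, fm, fs, fm_prime, fo_prime = _fluor_signals(fvfm, phi2, p["npq"])
    ppfd_i = PPFD_SAT * (1.0 + 0.02 * rng.standard_normal())
    fl = fluorescence_params(
        FluorRecord(fo=fo, fm=fm, fs=fs, fm_prime=fm_prime, fo_prime=fo_prime,
                    ppfd=ppfd_i))

    e = p["gs"] * VPD / P_AIR * 1000.0  # mmol H2O m-2 s-1

    row = {
        "AmaxL": amax_l, "gs": p["gs"], "E": e, "Rd": rd_v, "Pr": pr,
        "Ci": ci_op, "FvFm": fl.fvfm, "dF_Fm": fl.df_fm, "NPQ": fl.npq,
        "ETR": fl.etr, "AmaxCO2": amax_co2, "Vcmax": vcmax_v, "Ls": ls,
        "AES": (fl.etr / 4.0) / (a_op + p["rd"]),
        "DMt": p.get("dmt", np.nan), "LA": p.get("la", np.nan),
    }
    # independent multiplicative measurement noise per reported variable
    s = scenario.noise_sd
    if s > 0:
        for k in row:
            if np.isfinite(row[k]):
                row[k] = row[k] * (1.0 + s * rng.standard_normal())
    row["FvFm"] = float(np.clip(row["FvFm"], 0.01, 0.95))
    row["dF_Fm"] = float(np.clip(row["dF_Fm"], 0.005, 0.9))
    return row


def simulate_leaf_experiment(scenarios, seed: int | None = None,
                             refit: bool = False) -> list[ReplicateTable]:
    """Run the mechanistic simulator for each scenario cell.

    A replicate whose forward solution fails (for example a parameter draw
    with non-positive assimilation) is regenerated; the per-cell count is
    reported in ``table.meta['n_regenerated']``. With ``refit=True`` every
    replicate's light and A/Ci curves are refitted by nonlinear least
    squares instead of read off the generating model (slower, exercises the
    full estimation path).
    """
    tables = []
    base = np.random.default_rng(seed).integers(0, 2**31 - 1, size=len(scenarios)) \
        if seed is not None else [None] * len(scenarios)
    for i, scen in enumerate(scenarios):
        cell_seed = scen.seed if scen.seed is not None else base[i]
        rng = np.random.default_rng(cell_seed)
        rows, n_regen = [], 0
        while len(rows) < scen.n_replicates:
            try:
                rows.append(_simulate_replicate(scen, rng, refit))
            except Exception:
                n_regen += 1
                if n_regen > 50 * scen.n_replicates:
                    raise ValidationError(
                        f"cell ({scen.species}, {scen.treatment}): too many "
                        "failed replicate draws; scenario parameters are "
                        "physiologically inconsistent"
                    ) from None
        tables.append(ReplicateTable(
            species=scen.species, treatment=scen.treatment,
            data=pd.DataFrame(rows), meta={"n_regenerated": n_regen,
                                           "seed": cell_seed},
        ))
    return tables


# -------------------------------------------------------------------- presets

_GMAX, _BBRIZ = "G. max", "B. brizantha"


def _scen(species, treatment, pathway, coupling, seed, **means):
    if pathway == "C3":
        means.setdefault("j", 1.9 * means["vcmax"])
    else:
        means.setdefault("vpmax", 2.2 * means["vcmax"])
    return LeafScenario(species=species, treatment=treatment, pathway=pathway,
                        means=means, coupling=coupling, seed=seed)


def preset_scenarios(experiment: str, n_replicates: int = 7,
                     base_seed: int = 1000) -> list[LeafScenario]:
    """The two factorial study designs as ready-made scenario lists.

    ``temperature``: 2 species x 3 day temperatures (20/30/40 degC);
    ``water``: 2 species x 2 water regimes (100%/30% replacement). Parameter
    means follow the published treatment means; couplings rise with stress.
    """
    if experiment == "temperature":
        raw = [
            _scen(_GMAX, "20C", "C3", 0.70, 0, vcmax=61, rd=2.5, gs=0.30,
                  phi2=0.18, fvfm=0.73, npq=2.22, dmt=5.90, la=0.05),
            _scen(_GMAX, "30C", "C3", 0.82, 1, vcmax=68, rd=1.2, gs=0.35,
                  phi2=0.22, fvfm=0.74, npq=2.20, dmt=12.97, la=0.10),
            _scen(_GMAX, "40C", "C3", 0.92, 2, vcmax=78, rd=2.4, gs=0.40,
                  phi2=0.25, fvfm=0.79, npq=1.87, dmt=9.67, la=0.07),
            _scen(_BBRIZ, "20C", "C4", 0.65, 3, vcmax=18, rd=2.1, gs=0.18,
                  phi2=0.10, fvfm=0.75, npq=2.78, dmt=13.10, la=0.09),
            _scen(_BBRIZ, "30C", "C4", 0.58, 4, vcmax=24, rd=2.2, gs=0.25,
                  phi2=0.15, fvfm=0.78, npq=2.53, dmt=32.74, la=0.23),
            _scen(_BBRIZ, "40C", "C4", 0.90, 5, vcmax=27, rd=2.4, gs=0.30,
                  phi2=0.27, fvfm=0.79, npq=1.81, dmt=22.54, la=0.13),
        ]
    elif experiment == "water":
        raw = [
            _scen(_GMAX, "100%", "C3", 0.80, 10, vcmax=84, rd=2.28, gs=0.35,
                  phi2=0.273, fvfm=0.788, npq=2.07, dmt=72.3, la=0.43),
            _scen(_GMAX, "30%", "C3", 0.96, 11, vcmax=61, rd=2.07, gs=0.20,
                  phi2=0.404, fvfm=0.817, npq=1.70, dmt=19.7, la=0.41),
            _scen(_BBRIZ, "100%", "C4", 0.65, 12, vcmax=21, rd=1.23, gs=0.25,
                  phi2=0.196, fvfm=0.783, npq=3.15, dmt=147.7, la=0.53),
            _scen(_BBRIZ, "30%", "C4", 0.90, 13, vcmax=10, rd=0.86, gs=0.12,
                  phi2=0.208, fvfm=0.786, npq=3.10, dmt=48.3, la=0.49),
        ]
    else:
        raise ValidationError(f"unknown experiment {experiment!r}")
    return [replace(s, n_replicates=n_replicates, seed=base_seed + s.seed)
            for s in raw]
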