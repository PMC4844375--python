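"""Network connectance: Fisher-z correlation strength, module and global means.

The statistic follows Amzallag's global-connectance construction. For every
variable pair in the network the Pearson correlation r across replicate
plants is transformed to a non-negative strength

    z = 0.5 * ln((1 + |r|) / (1 - |r|)) = atanh(|r|),

a module's connectance Cg is the unweighted mean of z over its pairs, and
the global connectance Cg_total is the mean of the module connectances
(for the default network, (Cg_pho + Cg_ge) / 2 — not the pooled mean over
all pairs). The sign of r is deliberately discarded: connectance measures
the strength of coordination, not its direction.

All pairs enter the average regardless of significance; set
``significance_alpha`` to zero out pairs with p above the threshold (a
clearly non-default variant). Correlations use pairwise-complete deletion
and require at least 3 complete replicate pairs.

Resampling inference (:func:`bootstrap_cg`, :func:`permutation_test_cg`) is
provided because seven replicates per treatment cell make point estimates
of Cg extremely noisy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InsufficientDataError, ValidationError
from .network import NetworkSpec, VariablePair

_CLAMP = 1.0 - 1e-12


@dataclass
class ReplicateTable:
    """Replicate-level measurements for one species x treatment cell.

    ``data`` has one row per replicate plant and one numeric column per
    variable; missing cells are NaN.
    """

    species: str
    treatment: str
    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def n_replicates(self) -> int:
        return len(self.data)

    def require_variables(self, names) -> None:
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise ValidationError(
                f"cell ({self.species}, {self.treatment}): missing variable "
                f"columns {missing}"
            )

    def to_frame(self) -> pd.DataFrame:
        out = self.data.copy()
        out.insert(0, "treatment", self.treatment)
        out.insert(0, "species", self.species)
        out.insert(2, "replicate", np.arange(1, len(out) + 1))
        return out


def split_cells(df: pd.DataFrame, species_col: str = "species",
                treatment_col: str = "treatment") -> list[ReplicateTable]:
    """Split a tidy long table into one ReplicateTable per treatment cell."""
    drop = [c for c in (species_col, treatment_col, "replicate") if c in df.columns]
    cells = []
    for (sp, tr), sub in df.groupby([species_col, treatment_col], sort=True):
        cells.append(ReplicateTable(str(sp), str(tr),
                                    sub.drop(columns=drop).reset_index(drop=True)))
    return cells


@dataclass(frozen=True)
class PairResult:
    pair: VariablePair
    r: float
    n: int
    p: float
    z: float


@dataclass
class ConnectanceResult:
    species: str
    treatment: str
    module_cg: dict[str, float]
    linking_z: float | None
    pair_results: list[PairResult]

    @property
    def cg_ge(self) -> float | None:
        return self.module_cg.get("gas_exchange")

    @property
    def cg_pho(self) -> float | None:
        return self.module_cg.get("photochemical")

    @property
    def cg_total(self) -> float:
        return float(np.mean(list(self.module_cg.values())))

    def pairs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"species": self.species, "treatment": self.treatment,
                 "pair": pr.pair.label, "r": pr.r, "n": pr.n, "p": pr.p, "z": pr.z}
                for pr in self.pair_results
            ]
        )


# ---------------------------------------------------------------- pair level


def _complete_pairs(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-d vectors of equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    return x[mask], y[mask]


def pearson_r(x, y, *, method: str = "pearson") -> float:
    """Correlation across complete pairs; Pearson by default, Spearman optional.

    Raises InsufficientDataError for fewer than 3 complete pairs and
    DegenerateInputError for a constant vector (never a silent NaN).
    """
    x, y = _complete_pairs(x, y)
    if x.size < 3:
        raise InsufficientDataError(
            f"need >= 3 complete pairs for a correlation, got {x.size}"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("correlation undefined for a constant vector")
    if method == "pearson":
        r = float(np.corrcoef(x, y)[0, 1])
    elif method == "spearman":
        r = float(stats.spearmanr(x, y).statistic)
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    return float(np.clip(r, -1.0, 1.0))


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p-value of r from t = r*sqrt(n-2)/sqrt(1-r^2), df = n-2.

    |r| = 1 returns p = 0 by convention.
    """
    if n < 3:
        raise InsufficientDataError(f"need n >= 3 for a correlation p-value, got {n}")
    if not -1.0 <= r <= 1.0:
        raise ValidationError(f"r = {r} outside [-1, 1]")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def fisher_z(r: float) -> float:
    """Fisher strength z = atanh(|r|) >= 0; the sign of r is discarded.

    |r| = 1 is clamped to 1 - 1e-12 (z ~ 13.9) with a warning so degenerate
    small-sample cells stay finite but visible.
    """
    a = abs(float(r))
    if a > 1.0:
        raise ValidationError(f"|r| = {a} > 1")
    if a >= _CLAMP:
        warnings.warn(
            "|r| = 1: clamping to 1 - 1e-12 for a finite Fisher z",
            RuntimeWarning, stacklevel=2,
        )
        a = _CLAMP
    return float(np.arctanh(a))


def pair_strength(table: ReplicateTable, pair: VariablePair, *,
                  method: str = "pearson") -> PairResult:
    """r, n, p, z for one variable pair, pairwise-complete across replicates."""
    table.require_variables([pair.a, pair.b])
    x, y = _complete_pairs(table.data[pair.a], table.data[pair.b])
    try:
        r = pearson_r(x, y, method=method)
    except (DegenerateInputError, InsufficientDataError) as exc:
        raise type(exc)(f"pair {pair.label}: {exc}") from exc
    n = int(x.size)
    return PairResult(pair=pair, r=r, n=n, p=correlation_pvalue(r, n), z=fisher_z(r))


# -------------------------------------------------------------- module level


def module_connectance(table: ReplicateTable, pairs, *, method: str = "pearson",
                       significance_alpha: float | None = None) -> float:
    """Unweighted mean Fisher z over the given pairs.

    Every pair enters regardless of significance unless ``significance_alpha``
    is given, in which case pairs with p > alpha contribute z = 0 (non-default
    variant). Any failing pair aborts with an error listing all failures.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValidationError("module_connectance requires a non-empty pair list")
    zs, failures = [], []
    for pair in pairs:
        try:
            pr = pair_strength(table, pair, method=method)
        except (DegenerateInputError, InsufficientDataError) as exc:
            failures.append(str(exc))
            continue
        z = 0.0 if (significance_alpha is not None and pr.p > significance_alpha) else pr.z
        zs.append(z)
    if failures:
        raise DegenerateInputError(
            "module connectance failed for pairs: " + "; ".join(failures)
        )
    return float(np.mean(zs))


def global_connectance(cg_pho: float, cg_ge: float) -> float:
    """Cg_total: mean of the two module connectances (not the pooled pair mean)."""
    if cg_pho < 0 or cg_ge < 0:
        raise ValidationError("module connectances must be >= 0")
    return 0.5 * (cg_pho + cg_ge)


def analyze_cell(table: ReplicateTable, spec: NetworkSpec, *,
                 method: str = "pearson",
                 significance_alpha: float | None = None) -> ConnectanceResult:
    """Full connectance analysis of one treatment cell.

    Module connectances are the per-module z means; Cg_total is their mean;
    the linking pair(s) are reported separately and enter no average.
    """
    table.require_variables(spec.variable_names)
    pair_results: list[PairResult] = []
    module_cg: dict[str, float] = {}
    for name, pairs in spec.modules.items():
        zs = []
        for pair in pairs:
            pr = pair_strength(table, pair, method=method)
            pair_results.append(pr)
            z = 0.0 if (significance_alpha is not None and pr.p > significance_alpha) else pr.z
            zs.append(z)
        module_cg[name] = float(np.mean(zs))
    linking_z = None
    for pair in spec.linking_pairs:
        pr = pair_strength(table, pair, method=method)
        pair_results.append(pr)
        linking_z = pr.z  # default network has exactly one linking pair
    return ConnectanceResult(
        species=table.species, treatment=table.treatment,
        module_cg=module_cg, linking_z=linking_z, pair_results=pair_results,
    )


# ------------------------------------------------------- fast resampling core


def _spec_indices(spec: NetworkSpec):
    order = {name: i for i, name in enumerate(spec.variable_names)}
    mod_idx = {
        name: np.array([(order[p.a], order[p.b]) for p in pairs])
        for name, pairs in spec.modules.items()
    }
    link_idx = np.array([(order[p.a], order[p.b]) for p in spec.linking_pairs]) \
        if spec.linking_pairs else None
    return mod_idx, link_idx


def _cg_stats_matrix(X: np.ndarray, mod_idx, link_idx):
    """(module cg dict values..., cg_total, linking z) from a complete matrix.

    Returns None if any involved column is constant (caller decides whether
    to redraw or raise).
    """
    if np.any(np.ptp(X, axis=0) == 0):
        return None
    R = np.corrcoef(X, rowvar=False)
    Z = np.arctanh(np.minimum(np.abs(R), _CLAMP))
    cgs = {name: float(Z[idx[:, 0], idx[:, 1]].mean()) for name, idx in mod_idx.items()}
    total = float(np.mean(list(cgs.values())))
    link = float(Z[link_idx[:, 0], link_idx[:, 1]].mean()) if link_idx is not None else None
    return cgs, total, link


def _complete_matrix(table: ReplicateTable, spec: NetworkSpec) -> np.ndarray:
    table.require_variables(spec.variable_names)
    X = table.data[list(spec.variable_names)].to_numpy(dtype=float)
    X = X[np.all(np.isfinite(X), axis=1)]
    if len(X) < 3:
        raise InsufficientDataError(
            f"cell ({table.species}, {table.treatment}): fewer than 3 complete rows"
        )
    return X


@dataclass
class BootstrapResult:
    estimates: dict[str, float]
    intervals: dict[str, tuple[float, float]]
    n_boot: int
    n_redrawn: int
    level: float


def bootstrap_cg(table: ReplicateTable, spec: NetworkSpec, n_boot: int = 1000,
                 seed: int | None = 0, *, level: float = 0.95) -> BootstrapResult:
    """Percentile bootstrap CIs for module/global connectance and linking z.

    Replicate rows are resampled with replacement. A draw producing a
    constant column is redrawn and counted in ``n_redrawn``. Deterministic
    for a given seed.
    """
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100")
    X = _complete_matrix(table, spec)
    mod_idx, link_idx = _spec_indices(spec)
    point = _cg_stats_matrix(X, mod_idx, link_idx)
    if point is None:
        raise DegenerateInputError("constant column in the observed data")
    rng = np.random.default_rng(seed)
    n = len(X)
    stats_names = [f"cg_{m}" for m in mod_idx] + ["cg_total"] + (
        ["linking_z"] if link_idx is not None else [])
    draws = {name: np.empty(n_boot) for name in stats_names}
    n_redrawn = 0
    for b in range(n_boot):
        for _attempt in range(1000):
            res = _cg_stats_matrix(X[rng.integers(0, n, size=n)], mod_idx, link_idx)
            if res is not None:
                break
            n_redrawn += 1
        else:  # pragma: no cover - requires pathological data
            raise DegenerateInputError("bootstrap redraw limit exceeded")
        cgs, total, link = res
        for m, v in cgs.items():
            draws[f"cg_{m}"][b] = v
        draws["cg_total"][b] = total
        if link is not None:
            draws["linking_z"][b] = link
    lo, hi = (1 - level) / 2 * 100, (1 + level) / 2 * 100
    cgs, total, link = point
    estimates = {f"cg_{m}": v for m, v in cgs.items()}
    estimates["cg_total"] = total
    if link is not None:
        estimates["linking_z"] = link
    intervals = {
        name: (float(np.percentile(vals, lo)), float(np.percentile(vals, hi)))
        for name, vals in draws.items()
    }
    return BootstrapResult(estimates, intervals, n_boot, n_redrawn, level)


def permutation_test_cg(table_a: ReplicateTable, table_b: ReplicateTable,
                        spec: NetworkSpec, n_perm: int = 999,
                        seed: int | None = 0) -> float:
    """Permutation p-value for |Cg_total(a) - Cg_total(b)|.

    Replicates are pooled and randomly reassigned to two groups of the
    original sizes; the p-value is (1 + #{permuted >= observed}) / (n_perm + 1).
    Requires complete rows and at least 3 replicates per group.
    """
    if n_perm < 199:
        raise ValidationError("n_perm must be >= 199")
    Xa = _complete_matrix(table_a, spec)
    Xb = _complete_matrix(table_b, spec)
    mod_idx, link_idx = _spec_indices(spec)

    def total(X):
        res = _cg_stats_matrix(X, mod_idx, link_idx)
        return None if res is None else res[1]

    obs_a, obs_b = total(Xa), total(Xb)
    if obs_a is None or obs_b is None:
        raise DegenerateInputError("constant column in the observed data")
    observed = abs(obs_a - obs_b)
    pool = np.vstack([Xa, Xb])
    na, n = len(Xa), len(pool)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        for _attempt in range(1000):
            idx = rng.permutation(n)
            ta, tb = total(pool[idx[:na]]), total(pool[idx[na:]])
            if ta is not None and tb is not None:
                break
        else:  # pragma: no cover
            raise DegenerateInputError("permutation redraw limit exceeded")
        if abs(ta - tb) >= observed - 1e-12:
            count += 1
    return float((1 + count) / (n_perm + 1))
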