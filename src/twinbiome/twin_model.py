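"""Maximum-likelihood ACE variance-component models for twin pairs.

The classical twin design decomposes phenotypic variance into additive
genetic (A), common/shared environment (C) and unique environment (E,
which absorbs measurement error) components, exploiting the fact that
monozygotic (MZ) co-twins share all segregating genes while dizygotic
(DZ) co-twins share half on average.  A twin pair's phenotypes are
modelled as bivariate normal with a shared mean and the implied
covariance structure::

    var(y)        = a2 + c2 + e2
    cov(y1, y2)   = a2 + c2        (MZ)
    cov(y1, y2)   = a2/2 + c2      (DZ)

The full log-likelihood is the sum of bivariate normal log-densities
over independent pairs, maximized numerically.  Submodels (AE, CE, E)
drop components; nested fits are compared by likelihood-ratio
chi-square tests and AIC.  Narrow-sense heritability h2 is the
standardized A component.

Two parameterizations are offered.  The default ``direct``
parameterization leaves a2 and c2 unbounded (e2 stays positive via an
internal log transform), so a point estimate or confidence bound can be
negative — informative when the data's MZ/DZ covariance pattern is
incompatible with a nonnegative decomposition.  The ``path``
parameterization constrains a2, c2 >= 0 by optimizing path coefficients
whose squares are the variances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "PairedPhenotypes",
    "VarianceComponents",
    "FitResult",
    "ModelComparison",
    "DegenerateDataError",
    "MODELS",
    "implied_covariance",
    "loglik",
    "fit",
    "standardize",
    "compare",
    "confidence_intervals",
    "heritability_test",
]

LOG_2PI = math.log(2.0 * math.pi)

#: component letters estimated by each model (mean is always estimated)
MODELS = {
    "ACE": ("A", "C", "E"),
    "AE": ("A", "E"),
    "CE": ("C", "E"),
    "E": ("E",),
}

#: convergence tolerance on -2*loglik
FIT_TOL = 1e-8

N_STARTS = 5


class DegenerateDataError(ValueError):
    """The data cannot identify the requested model."""


@dataclass(frozen=True)
class PairedPhenotypes:
    """Transformed phenotype values for complete twin pairs, by zygosity."""

    mz: np.ndarray  # (n_mz, 2)
    dz: np.ndarray  # (n_dz, 2)

    def __post_init__(self):
        mz = np.atleast_2d(np.asarray(self.mz, dtype=float))
        dz = np.atleast_2d(np.asarray(self.dz, dtype=float))
        if mz.size == 0:
            mz = mz.reshape(0, 2)
        if dz.size == 0:
            dz = dz.reshape(0, 2)
        if mz.shape[1] != 2 or dz.shape[1] != 2:
            raise ValueError("pair arrays must have two columns (one per co-twin)")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "dz", dz)

    @property
    def n_mz(self) -> int:
        return self.mz.shape[0]

    @property
    def n_dz(self) -> int:
        return self.dz.shape[0]

    def all_values(self) -> np.ndarray:
        return np.concatenate([self.mz.ravel(), self.dz.ravel()])


@dataclass(frozen=True)
class VarianceComponents:
    """A/C/E variances and the grand mean, on the transformed scale."""

    a2: float
    c2: float
    e2: float
    mu: float

    def __post_init__(self):
        if self.e2 <= 0:
            raise ValueError("e2 must be positive (it contains measurement error)")

    def total(self) -> float:
        return self.a2 + self.c2 + self.e2


@dataclass(frozen=True)
class FitResult:
    model: str
    components: VarianceComponents
    standardized: dict  # component letter -> proportion of total variance
    loglik: float
    n_params: int
    aic: float
    converged: bool
    ci95: dict = field(default_factory=dict)  # letter -> (lower, upper)
    parameterization: str = "direct"

    def unstandardized(self) -> dict:
        vals = {"A": self.components.a2, "C": self.components.c2, "E": self.components.e2}
        return {k: vals[k] for k in MODELS[self.model]}


@dataclass(frozen=True)
class ModelComparison:
    full: str
    reduced: str
    lr_stat: float
    df: int
    p_value: float
    delta_aic: float


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def implied_covariance(components: VarianceComponents, zygosity: str) -> np.ndarray:
    """Model-implied 2x2 covariance matrix for a twin pair."""
    a2, c2, e2 = components.a2, components.c2, components.e2
    if zygosity == "MZ":
        off = a2 + c2
    elif zygosity == "DZ":
        off = 0.5 * a2 + c2
    else:
        raise ValueError(f"zygosity must be MZ or DZ, got {zygosity!r}")
    v = a2 + c2 + e2
    return np.array([[v, off], [off, v]])


def _suffstats(arr: np.ndarray) -> tuple:
    """(n, sum y1, sum y2, sum y1^2, sum y2^2, sum y1*y2) as floats."""
    if arr.shape[0] == 0:
        return (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    y1 = arr[:, 0]
    y2 = arr[:, 1]
    return (
        float(arr.shape[0]),
        float(y1.sum()),
        float(y2.sum()),
        float((y1 * y1).sum()),
        float((y2 * y2).sum()),
        float((y1 * y2).sum()),
    )


def _ll_group(stats_: tuple, mu: float, v: float, c: float) -> float:
    """Bivariate-normal log-likelihood of one zygosity group.

    Exchangeable covariance [[v, c], [c, v]]; O(1) in the number of
    pairs via sufficient statistics.
    """
    n, s1, s2, q11, q22, q12 = stats_
    if n == 0.0:
        return 0.0
    det = v * v - c * c
    if det <= 0.0 or v <= 0.0:
        return -math.inf
    nmu2 = n * mu * mu
    c11 = q11 - 2.0 * mu * s1 + nmu2
    c22 = q22 - 2.0 * mu * s2 + nmu2
    c12 = q12 - mu * (s1 + s2) + nmu2
    quad = (v * (c11 + c22) - 2.0 * c * c12) / det
    return -n * LOG_2PI - 0.5 * n * math.log(det) - 0.5 * quad


def loglik(components: VarianceComponents, data: PairedPhenotypes) -> float:
    """Joint log-likelihood over all pairs; -inf when the implied
    covariance is not positive-definite (optimizer-safe)."""
    v = components.total()
    mu = components.mu
    ll = _ll_group(_suffstats(data.mz), mu, v, components.a2 + components.c2)
    ll += _ll_group(_suffstats(data.dz), mu, v, 0.5 * components.a2 + components.c2)
    return ll


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _moment_summary(data: PairedPhenotypes) -> dict:
    allv = data.all_values()
    mu = float(allv.mean())
    v = float(allv.var())
    def _cov(arr):
        if arr.shape[0] < 2:
            return 0.0
        return float(np.cov(arr[:, 0], arr[:, 1])[0, 1])
    return {"mu": mu, "var": v, "cov_mz": _cov(data.mz), "cov_dz": _cov(data.dz)}


def _check_data(data: PairedPhenotypes, model: str) -> None:
    if "A" in MODELS[model] or "C" in MODELS[model]:
        # A and C are identified only through the MZ/DZ covariance contrast
        if data.n_mz < 2 or data.n_dz < 2:
            raise DegenerateDataError(
                f"model {model} needs >=2 MZ and >=2 DZ pairs, "
                f"got {data.n_mz} MZ / {data.n_dz} DZ"
            )
    elif data.n_mz + data.n_dz < 2:
        raise DegenerateDataError("need at least 2 pairs")
    if float(data.all_values().var()) <= 0.0:
        raise DegenerateDataError("zero phenotypic variance")


def _unpack(x, model: str, parameterization: str) -> tuple:
    """Internal optimizer vector -> (mu, a2, c2, e2)."""
    mu = x[0]
    a2 = c2 = 0.0
    i = 1
    if "A" in MODELS[model]:
        a2 = x[i] * x[i] if parameterization == "path" else x[i]
        i += 1
    if "C" in MODELS[model]:
        c2 = x[i] * x[i] if parameterization == "path" else x[i]
        i += 1
    e2 = math.exp(min(x[i], 60.0))
    return mu, a2, c2, e2


def _pack(mu, a2, c2, e2, model: str, parameterization: str) -> list:
    x = [mu]
    if "A" in MODELS[model]:
        x.append(math.sqrt(max(a2, 1e-8)) if parameterization == "path" else a2)
    if "C" in MODELS[model]:
        x.append(math.sqrt(max(c2, 1e-8)) if parameterization == "path" else c2)
    x.append(math.log(max(e2, 1e-10)))
    return x


def _neg_ll_factory(data: PairedPhenotypes, model: str, parameterization: str):
    smz = _suffstats(data.mz)
    sdz = _suffstats(data.dz)

    def neg_ll(x):
        mu, a2, c2, e2 = _unpack(x, model, parameterization)
        v = a2 + c2 + e2
        ll = _ll_group(smz, mu, v, a2 + c2)
        ll += _ll_group(sdz, mu, v, 0.5 * a2 + c2)
        return -ll

    return neg_ll


def _starts(data: PairedPhenotypes, model: str, parameterization: str) -> list:
    """Deterministic multi-start points: moment estimator plus spread-out
    perturbations guarding against local optima."""
    m = _moment_summary(data)
    mu, v = m["mu"], max(m["var"], 1e-8)
    cmz, cdz = m["cov_mz"], m["cov_dz"]
    a2 = 2.0 * (cmz - cdz)
    c2 = 2.0 * cdz - cmz
    if model == "AE":
        a2, c2 = cmz, 0.0
    elif model == "CE":
        a2, c2 = 0.0, cmz
    elif model == "E":
        a2 = c2 = 0.0
    e2 = max(v - a2 - c2, 0.05 * v)
    base = (mu, a2, c2, e2)
    alts = [
        (mu, 0.5 * v, 0.0, 0.5 * v),
        (mu, 0.0, 0.5 * v, 0.5 * v),
        (mu, 0.25 * v, 0.25 * v, 0.5 * v),
        (mu, 0.0, 0.0, v),
    ]
    pts = [base] + alts
    return [_pack(*p, model=model, parameterization=parameterization) for p in pts[:N_STARTS]]


def _fit_e_closed_form(data: PairedPhenotypes) -> tuple:
    """The E model is iid normal over all 2n values: closed-form ML."""
    allv = data.all_values()
    mu = float(allv.mean())
    e2 = float(np.mean((allv - mu) ** 2))
    ll = float(-0.5 * allv.size * (LOG_2PI + math.log(e2) + 1.0))
    return mu, e2, ll


def fit(
    data: PairedPhenotypes,
    model: str = "AE",
    parameterization: str = "direct",
) -> FitResult:
    """Maximum-likelihood fit of an ACE-family model.

    Optimizes the exact pair likelihood with Nelder-Mead from five
    deterministic starting points (a moment-based start plus fixed
    perturbations) and keeps the best converged solution.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(MODELS)}")
    if parameterization not in ("direct", "path"):
        raise ValueError(f"unknown parameterization {parameterization!r}")
    _check_data(data, model)

    if model == "E":
        mu, e2, ll = _fit_e_closed_form(data)
        comps = VarianceComponents(a2=0.0, c2=0.0, e2=e2, mu=mu)
        return FitResult(
            model="E",
            components=comps,
            standardized=standardize(comps, "E"),
            loglik=ll,
            n_params=2,
            aic=-2.0 * ll + 4.0,
            converged=True,
            parameterization=parameterization,
        )

    neg_ll = _neg_ll_factory(data, model, parameterization)
    best = None
    any_success = False
    for x0 in _starts(data, model, parameterization):
        res = optimize.minimize(
            neg_ll,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": FIT_TOL / 2.0, "maxiter": 5000, "maxfev": 5000},
        )
        if not math.isfinite(res.fun):
            continue
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise DegenerateDataError("likelihood not finite at any starting point")

    mu, a2, c2, e2 = _unpack(best.x, model, parameterization)
    comps = VarianceComponents(a2=a2, c2=c2, e2=e2, mu=mu)
    ll = -float(best.fun)
    n_params = 1 + len(MODELS[model])
    return FitResult(
        model=model,
        components=comps,
        standardized=standardize(comps, model),
        loglik=ll,
        n_params=n_params,
        aic=-2.0 * ll + 2.0 * n_params,
        converged=any_success,
        parameterization=parameterization,
    )


def standardize(components: VarianceComponents, model: str) -> dict:
    """Express each included variance component as a proportion of the
    total fitted variance.  Under the direct parameterization a signed
    proportion is possible; the proportions always sum to one."""
    vals = {"A": components.a2, "C": components.c2, "E": components.e2}
    included = MODELS[model]
    total = sum(vals[k] for k in included)
    if total <= 0:
        raise DegenerateDataError(f"nonpositive total variance {total}")
    return {k: vals[k] / total for k in included}


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------


def compare(full: FitResult, reduced: FitResult) -> ModelComparison:
    """Likelihood-ratio test of a nested submodel, plus the AIC change.

    The test statistic 2*(ll_full - ll_reduced) is referred to a central
    chi-square with df equal to the parameter difference.  With the
    direct parameterization the null value of a dropped component is
    interior to the parameter space, so no boundary mixture correction
    is applied.
    """
    if not set(MODELS[reduced.model]) < set(MODELS[full.model]):
        raise ValueError(
            f"{reduced.model} is not nested in {full.model}"
        )
    lr = 2.0 * (full.loglik - reduced.loglik)
    if lr < -1e-6:
        raise RuntimeError(
            f"reduced model {reduced.model} fits better than {full.model} "
            f"(lr={lr:.3g}); full-model optimization failed"
        )
    lr = max(lr, 0.0)
    df = full.n_params - reduced.n_params
    return ModelComparison(
        full=full.model,
        reduced=reduced.model,
        lr_stat=lr,
        df=df,
        p_value=float(stats.chi2.sf(lr, df)),
        delta_aic=reduced.aic - full.aic,
    )


# ---------------------------------------------------------------------------
# confidence intervals
# ---------------------------------------------------------------------------


def _profile_ll(data, model, parameterization, letter, value, warm):
    """Maximized log-likelihood with one variance component pinned."""
    smz = _suffstats(data.mz)
    sdz = _suffstats(data.dz)
    free = [k for k in MODELS[model] if k != letter]

    def neg_ll(x):
        mu = x[0]
        d = dict.fromkeys("ACE", 0.0)
        d[letter] = value
        for i, k in enumerate(free):
            if k == "E":
                d["E"] = math.exp(min(x[1 + i], 60.0))
            else:
                xi = x[1 + i]
                d[k] = xi * xi if parameterization == "path" else xi
        a2, c2, e2 = d["A"], d["C"], d["E"]
        if e2 <= 0.0:
            return math.inf
        v = a2 + c2 + e2
        ll = _ll_group(smz, mu, v, a2 + c2)
        ll += _ll_group(sdz, mu, v, 0.5 * a2 + c2)
        return -ll

    x0 = [warm["mu"]]
    for k in free:
        if k == "E":
            x0.append(math.log(max(warm["E"], 1e-10)))
        elif parameterization == "path":
            x0.append(math.sqrt(max(warm[k], 1e-8)))
        else:
            x0.append(warm[k])
    res = optimize.minimize(
        neg_ll,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": FIT_TOL / 2.0, "maxiter": 3000, "maxfev": 3000},
    )
    return -float(res.fun)


def confidence_intervals(
    fit_result: FitResult,
    data: PairedPhenotypes,
    level: float = 0.95,
    method: str = "profile",
) -> dict:
    """Likelihood-based confidence intervals for each variance component.

    The profile interval for a component is the set of pinned values at
    which twice the log-likelihood drop from the MLE stays below the
    chi-square(1) quantile for ``level`` (3.8415 at 95%).  Under the
    direct parameterization the lower bound of A or C may be negative;
    the E interval is always strictly positive.  A side whose bracket
    search fails is reported as NaN with a warning.

    ``method="wald"`` instead returns estimate +/- z * se from the
    numerical observed information (cheap, symmetric, less accurate in
    small samples).
    """
    if not fit_result.converged:
        raise RuntimeError("confidence intervals require a converged fit")
    if method == "wald":
        return _wald_intervals(fit_result, data, level)
    if method != "profile":
        raise ValueError(f"unknown CI method {method!r}")

    q = float(stats.chi2.ppf(level, 1))
    ll_hat = fit_result.loglik
    comps = fit_result.components
    est = {"A": comps.a2, "C": comps.c2, "E": comps.e2, "mu": comps.mu}
    scale = max(comps.total(), 1e-6)
    out = {}
    for letter in MODELS[fit_result.model]:
        theta = est[letter]

        def deficit(value):
            ll_p = _profile_ll(
                data, fit_result.model, fit_result.parameterization, letter, value, est
            )
            return 2.0 * (ll_hat - ll_p) - q

        lo = _find_bound(deficit, theta, -1, letter, fit_result.parameterization, scale)
        hi = _find_bound(deficit, theta, +1, letter, fit_result.parameterization, scale)
        out[letter] = (lo, hi)
    return out


def _find_bound(deficit, theta, direction, letter, parameterization, scale):
    """Bracket outward from the MLE, then solve deficit(x)=0 by brentq."""
    positive_only = letter == "E" or parameterization == "path"
    inner = theta
    if direction < 0 and positive_only:
        # approach zero geometrically; the likelihood blows up at e2=0,
        # so the bound always lies in (0, theta)
        cand = theta
        for _ in range(60):
            cand /= 2.0
            if deficit(cand) >= 0.0:
                return float(
                    optimize.brentq(deficit, cand, inner, xtol=1e-8 * scale, rtol=1e-10)
                )
            inner = cand
    else:
        step = 0.25 * scale
        for _ in range(60):
            cand = theta + direction * step
            if deficit(cand) >= 0.0:
                lo, hi = (cand, inner) if direction < 0 else (inner, cand)
                return float(
                    optimize.brentq(deficit, lo, hi, xtol=1e-8 * scale, rtol=1e-10)
                )
            inner = cand
            step *= 2.0
    warnings.warn(
        f"profile bound search failed for component {letter} "
        f"({'lower' if direction < 0 else 'upper'} side)"
    )
    return math.nan


def _wald_intervals(fit_result: FitResult, data: PairedPhenotypes, level: float) -> dict:
    comps = fit_result.components
    letters = list(MODELS[fit_result.model])
    theta = np.array(
        [comps.mu] + [{"A": comps.a2, "C": comps.c2, "E": comps.e2}[k] for k in letters]
    )

    def nll(v):
        d = dict.fromkeys("ACE", 0.0)
        for k, val in zip(letters, v[1:]):
            d[k] = float(val)
        if d["E"] <= 0:
            return math.inf
        c = VarianceComponents(a2=d["A"], c2=d["C"], e2=d["E"], mu=float(v[0]))
        return -loglik(c, data)

    h = _numerical_hessian(nll, theta)
    cov = np.linalg.inv(h)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    return {
        k: (float(theta[i + 1] - z * se[i + 1]), float(theta[i + 1] + z * se[i + 1]))
        for i, k in enumerate(letters)
    }


def _numerical_hessian(f, x, rel_step=1e-4):
    n = x.size
    h = np.maximum(np.abs(x) * rel_step, 1e-6)
    out = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            if i == j:
                val = (f(x + ei) - 2.0 * f0 + f(x - ei)) / (h[i] ** 2)
            else:
                val = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4.0 * h[i] * h[j])
            out[i, j] = out[j, i] = val
    return out


# ---------------------------------------------------------------------------
# headline analysis
# ---------------------------------------------------------------------------


def heritability_test(
    data: PairedPhenotypes,
    parameterization: str = "direct",
    compute_ci: bool = False,
    ci_level: float = 0.95,
) -> tuple:
    """Fit the full ACE/AE/CE/E model ladder and test heritability.

    Returns ``(h2, p_value, fits)`` where ``h2`` is the standardized A
    component of the AE model, ``p_value`` comes from the AE-vs-E
    likelihood-ratio test on one degree of freedom, and ``fits`` maps
    each model label to its :class:`FitResult` (the nested-model ladder
    kept for supplementary reporting).
    """
    fits = {}
    for model in ("ACE", "AE", "CE", "E"):
        fr = fit(data, model=model, parameterization=parameterization)
        if compute_ci and model == "AE":
            ci = confidence_intervals(fr, data, level=ci_level)
            fr = FitResult(
                model=fr.model,
                components=fr.components,
                standardized=fr.standardized,
                loglik=fr.loglik,
                n_params=fr.n_params,
                aic=fr.aic,
                converged=fr.converged,
                ci95=ci,
                parameterization=fr.parameterization,
            )
        fits[model] = fr
    cmp_ae_e = compare(fits["AE"], fits["E"])
    h2 = fits["AE"].standardized["A"]
    return h2, cmp_ae_e.p_value, fits
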