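"""Maximum-likelihood inference of gBGC strength from DAF spectra.

GC-biased gene conversion acts on GC-changing heterozygotes like directional
selection with population-scaled coefficient B = 4*Ne*b.  Under a
Poisson-random-field treatment, the expected density of derived alleles at
frequency x carries the classic fixation-flux weight, so the expected count
in frequency class i of n sampled haploid genomes is proportional to

    F_i(B) = Int_0^1 [(1 - e^{-B(1-x)}) / ((1 - e^{-B}) x (1-x))]
                 * C(n,i) x^i (1-x)^{n-i} dx,

which reduces to the neutral 1/i as B -> 0.  Four nested models are fitted
to the (N->N, S->W, W->S) spectra by maximizing independent Poisson
likelihoods per (category, frequency-class) cell:

* M0      : B = 0 (mutation bias lambda only)
* M1      : free B
* M0*, M1*: add one polarization-error parameter per mutation category

All models share demographic nuisance multipliers r_i per frequency class
(r_1 = 1 as the reference), the scaled diversities theta_N and theta_WS,
and treat the regional ancestral GC content as a fixed, known quantity.

The optimizer concentrates the likelihood: for any (lambda, B) the cell
means are linear in theta and, separately, linear in r, so those are
maximized by exact scaling updates and multiplicative (MM-style) updates,
leaving a 1-2 dimensional outer problem solved by Nelder-Mead from several
deterministic starts.  The star models' error rates trade off almost
flatly against the mirrored nuisance classes and are instead fitted
jointly by box-constrained quasi-Newton, warm-started from the non-star
optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import chi2

from .spectra import CategorySpectra, build_spectra

MODELS = ("M0", "M0star", "M1", "M1star")

#: switch to the series expansion of F_i(B) below this |B|
_B_SERIES_THRESHOLD = 1e-4
_GL_ORDER = 64

_gl_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gl_nodes(order: int = _GL_ORDER) -> tuple[np.ndarray, np.ndarray]:
    if order not in _gl_cache:
        x, w = leggauss(order)
        # map from (-1, 1) to (0, 1)
        _gl_cache[order] = (0.5 * (x + 1.0), 0.5 * w)
    return _gl_cache[order]


def sfs_weight(i, n: int, B: float, order: int = _GL_ORDER) -> np.ndarray:
    """Expected relative density F_i(B) of derived alleles in class i of n.

    Vectorized over ``i``.  F_i(0) = 1/i (neutral SFS); B > 0 shifts mass
    toward high frequencies.  ``B`` must be finite; |B| below the series
    threshold uses the expansion F_i(B) = 1/i + B/(2(n+1)) + O(B^2).
    """
    if not np.isfinite(B):
        raise ValueError("B must be finite")
    i = np.atleast_1d(np.asarray(i, dtype=int))
    if (i < 1).any() or (i > n - 1).any():
        raise ValueError("frequency class i must be in [1, n-1]")
    if abs(B) < _B_SERIES_THRESHOLD:
        return 1.0 / i + B / (2.0 * (n + 1.0))
    x, w = _gl_nodes(order)
    log_binom = gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)
    # binomial sampling kernel, one row per class
    logM = log_binom[:, None] + i[:, None] * np.log(x) + (n - i)[:, None] * np.log1p(-x)
    g = -np.expm1(-B * (1.0 - x)) / (-np.expm1(-B) * x * (1.0 - x))
    return np.exp(logM) @ (w * g)


def sfs_weight_n2_closed_form(B: float) -> float:
    """Closed form of F_1(B) at n=2: 2[1 - (1-e^-B)/B] / (1-e^-B)."""
    if abs(B) < 1e-12:
        return 1.0
    em = -np.expm1(-B)  # 1 - e^-B
    return float(2.0 * (1.0 - em / B) / em)


@dataclass
class GBGCModelSpec:
    """Model id plus the fixed quantities of one fit: ancestral GC and n."""

    model: str
    gc: float
    n: int

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if not 0.0 < self.gc < 1.0:
            raise ValueError("fixed gc must be in (0, 1): opportunity ratio undefined at 0 or 1")
        if self.n < 2:
            raise ValueError("need at least 2 haploid genomes")

    @property
    def with_gbgc(self) -> bool:
        return self.model in ("M1", "M1star")

    @property
    def with_errors(self) -> bool:
        return self.model in ("M0star", "M1star")

    @property
    def n_free_params(self) -> int:
        # lambda, theta_N, theta_WS, r_2..r_{n-1}
        k = 3 + (self.n - 2)
        if self.with_gbgc:
            k += 1
        if self.with_errors:
            k += 3
        return k


@dataclass
class GBGCFit:
    """One fitted model: point estimates, log-likelihood and diagnostics."""

    model: str
    n: int
    gc: float
    lam: float
    B: float
    theta_N: float
    theta_WS: float
    r: np.ndarray
    e_N: float = 0.0
    e_SW: float = 0.0
    e_WS: float = 0.0
    loglik: float = -np.inf
    converged: bool = False
    n_starts: int = 0
    message: str = ""

    def to_dict(self) -> dict:
        d = {
            "model": self.model, "n": self.n, "gc": self.gc,
            "lambda": self.lam, "B": self.B,
            "theta_N": self.theta_N, "theta_WS": self.theta_WS,
            "r": list(map(float, self.r)),
            "e_N": self.e_N, "e_SW": self.e_SW, "e_WS": self.e_WS,
            "loglik": self.loglik, "converged": self.converged,
            "n_starts": self.n_starts, "message": self.message,
        }
        return d


def _cell_means(lam, B, theta_N, theta_WS, r, e_N, e_SW, e_WS, gc, n,
                a=None, c=None):
    """Expected Poisson counts for the N->N, W->S and S->W spectra.

    a_i = F_i(B) and c_i = lambda * gc/(1-gc) * F_i(-B) may be passed in to
    avoid recomputing the quadrature.  Misorientation moves a fraction of a
    category's mass to the reverse category at the mirrored class n-i.
    """
    idx = np.arange(1, n)
    if a is None:
        a = sfs_weight(idx, n, B)
    if c is None:
        c = lam * gc / (1.0 - gc) * sfs_weight(idx, n, -B)
    inv_i = 1.0 / idx
    r = np.asarray(r, dtype=float)
    mu_nn = theta_N * ((1.0 - e_N) * r * inv_i + e_N * (r * inv_i)[::-1])
    mu_ws = theta_WS * ((1.0 - e_WS) * r * a + e_SW * (r * c)[::-1])
    mu_sw = theta_WS * ((1.0 - e_SW) * r * c + e_WS * (r * a)[::-1])
    return mu_nn, mu_ws, mu_sw


def expected_spectra(fit: GBGCFit, spec: GBGCModelSpec | None = None) -> dict[str, np.ndarray]:
    """Expected counts per category per frequency class for a parameter set."""
    gc = fit.gc if spec is None else spec.gc
    n = fit.n if spec is None else spec.n
    mu_nn, mu_ws, mu_sw = _cell_means(
        fit.lam, fit.B, fit.theta_N, fit.theta_WS, fit.r,
        fit.e_N, fit.e_SW, fit.e_WS, gc, n)
    return {"NN": mu_nn, "WS": mu_ws, "SW": mu_sw}


def _poisson_loglik(x_nn, x_ws, x_sw, mu_nn, mu_ws, mu_sw, lgamma_const):
    ll = 0.0
    for x, mu in ((x_nn, mu_nn), (x_ws, mu_ws), (x_sw, mu_sw)):
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(x > 0, x * np.log(mu), 0.0)
        ll += float(term.sum() - mu.sum())
    return ll - lgamma_const


def _profile_loglik(lam, B, x_nn, x_ws, x_sw, gc, n,
                    tol=1e-10, max_iter=5000, r0=None):
    """Maximize over theta_N, theta_WS and r_2..r_{n-1} at fixed (lam, B),
    with the error rates pinned at 0.

    theta updates are exact MLE scalings; r updates are multiplicative
    MM steps for the linear Poisson model, each monotone in the likelihood.
    ``r0`` warm-starts the nuisance vector.  Returns
    (loglik, theta_N, theta_WS, r).
    """
    idx = np.arange(1, n)
    inv_i = 1.0 / idx
    a = sfs_weight(idx, n, B)
    c = lam * gc / (1.0 - gc) * sfs_weight(idx, n, -B)
    lgamma_const = float(gammaln(x_nn + 1).sum() + gammaln(x_ws + 1).sum()
                         + gammaln(x_sw + 1).sum())
    r = np.ones(n - 1) if r0 is None else np.asarray(r0, dtype=float).copy()
    prev = -np.inf
    theta_N = theta_WS = 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        for _ in range(max_iter):
            theta_N = max(x_nn.sum() / (r * inv_i).sum(), 1e-300)
            theta_WS = max((x_ws.sum() + x_sw.sum()) / (r * (a + c)).sum(), 1e-300)
            mu_nn, mu_ws, mu_sw = _cell_means(
                lam, B, theta_N, theta_WS, r, 0.0, 0.0, 0.0, gc, n, a=a, c=c)
            ll = _poisson_loglik(x_nn, x_ws, x_sw, mu_nn, mu_ws, mu_sw, lgamma_const)
            if abs(ll - prev) < tol:
                break
            prev = ll
            ratio_nn = np.where(mu_nn > 0, x_nn / mu_nn, 0.0)
            ratio_ws = np.where(mu_ws > 0, x_ws / mu_ws, 0.0)
            ratio_sw = np.where(mu_sw > 0, x_sw / mu_sw, 0.0)
            num = (theta_N * inv_i * ratio_nn
                   + theta_WS * a * ratio_ws
                   + theta_WS * c * ratio_sw)
            den = theta_N * inv_i + theta_WS * (a + c)
            r = r * num / den
            r[0] = 1.0  # singleton class is the demographic reference
            np.clip(r, 1e-12, 1e12, out=r)
    return ll, theta_N, theta_WS, r


def _unpack(vec, spec: GBGCModelSpec):
    lam = float(np.exp(vec[0]))
    B = float(vec[1]) if spec.with_gbgc else 0.0
    return lam, B


def fit_model(spectra: CategorySpectra, spec: GBGCModelSpec,
              n_starts: int = 5, outer_tol: float = 1e-8,
              inner_tol: float = 1e-10, max_outer: int = 2000) -> GBGCFit:
    """Fit one of M0/M0*/M1/M1* to per-category spectra by maximum likelihood.

    Deterministic: multiple fixed starting points (a method-of-moments
    neutral start plus perturbations), best final likelihood wins, ties
    broken by the first start reaching it.  For the non-star models the
    nuisances are concentrated out and Nelder-Mead searches only (lambda)
    or (lambda, B).  The star models add the three error rates, which trade
    off almost flatly against the mirrored nuisance classes; they are
    fitted by box-constrained quasi-Newton over the full parameter vector,
    warm-started from the corresponding non-star fit (which also guarantees
    the nested log-likelihood ordering).
    """
    if spectra.n != spec.n:
        raise ValueError("spectra and model spec disagree on sample size n")
    x_nn = spectra.nn
    x_ws = spectra.counts["WS"]
    x_sw = spectra.counts["SW"]
    if x_nn.sum() + x_ws.sum() + x_sw.sum() == 0:
        raise ValueError("cannot fit a model to all-empty spectra")
    gc, n = spec.gc, spec.n

    if spec.with_errors:
        return _fit_star(spectra, spec, n_starts, outer_tol, inner_tol, max_outer)

    # neutral moment start for lambda: total SW/WS input corrected for opportunity
    lam0 = (x_sw.sum() / max(x_ws.sum(), 1.0)) * (1.0 - gc) / gc
    lam0 = float(np.clip(lam0, 0.05, 50.0))
    base_starts = [(1.0, 0.0), (1.0, 0.5), (1.0, -0.5), (1.6, 0.25), (0.625, -0.25),
                   (1.0, 1.0), (2.0, -1.0)]

    warm = {"r": None}

    def objective(vec):
        lam, B = _unpack(vec, spec)
        if not (1e-6 < lam < 1e6) or abs(B) > 50:
            return 1e12
        ll, _, _, r = _profile_loglik(lam, B, x_nn, x_ws, x_sw, gc, n,
                                      tol=inner_tol, r0=warm["r"])
        warm["r"] = r
        return -ll

    best = None
    n_ok = 0
    for mult, b0 in base_starts[:max(n_starts, 1)]:
        warm["r"] = None  # each start profiles its own nuisances from scratch
        vec0 = [np.log(lam0 * mult)]
        if spec.with_gbgc:
            vec0.append(b0)
        res = minimize(objective, np.asarray(vec0), method="Nelder-Mead",
                       options={"xatol": 1e-7, "fatol": outer_tol,
                                "maxiter": max_outer})
        if np.isfinite(res.fun):
            n_ok += int(res.success)
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        return GBGCFit(model=spec.model, n=n, gc=gc, lam=np.nan, B=np.nan,
                       theta_N=np.nan, theta_WS=np.nan, r=np.full(n - 1, np.nan),
                       converged=False, n_starts=n_starts,
                       message="all optimizer starts failed")
    lam, B = _unpack(best.x, spec)
    ll, theta_N, theta_WS, r = _profile_loglik(
        lam, B, x_nn, x_ws, x_sw, gc, n, tol=1e-12, max_iter=20000)
    return GBGCFit(model=spec.model, n=n, gc=gc, lam=lam, B=B,
                   theta_N=theta_N, theta_WS=theta_WS, r=r, loglik=ll,
                   converged=n_ok > 0, n_starts=n_starts,
                   message="" if n_ok > 0 else "no start reported formal convergence")


def _fit_star(spectra: CategorySpectra, spec: GBGCModelSpec,
              n_starts: int, outer_tol: float, inner_tol: float,
              max_outer: int) -> GBGCFit:
    """Star-model fit: L-BFGS-B on (log lam, [B], log theta, log r, e)."""
    x_nn = spectra.nn
    x_ws = spectra.counts["WS"]
    x_sw = spectra.counts["SW"]
    gc, n = spec.gc, spec.n
    base_spec = GBGCModelSpec("M1" if spec.with_gbgc else "M0", gc, n)
    base = fit_model(spectra, base_spec, n_starts=n_starts,
                     outer_tol=outer_tol, inner_tol=inner_tol, max_outer=max_outer)
    lgamma_const = float(gammaln(x_nn + 1).sum() + gammaln(x_ws + 1).sum()
                         + gammaln(x_sw + 1).sum())
    k_fixed = 3 + (1 if spec.with_gbgc else 0)  # log lam, [B], log thetas

    def unpack_full(vec):
        lam = np.exp(vec[0])
        j = 1
        B = 0.0
        if spec.with_gbgc:
            B = vec[j]
            j += 1
        theta_N, theta_WS = np.exp(vec[j]), np.exp(vec[j + 1])
        r = np.ones(n - 1)
        r[1:] = np.exp(vec[k_fixed:k_fixed + n - 2])
        e_N, e_SW, e_WS = vec[k_fixed + n - 2:]
        return lam, B, theta_N, theta_WS, r, e_N, e_SW, e_WS

    def objective(vec):
        lam, B, theta_N, theta_WS, r, e_N, e_SW, e_WS = unpack_full(vec)
        mus = _cell_means(lam, B, theta_N, theta_WS, r, e_N, e_SW, e_WS, gc, n)
        return -_poisson_loglik(x_nn, x_ws, x_sw, *mus, lgamma_const)

    bounds = ([(-14, 14)] + ([(-50, 50)] if spec.with_gbgc else [])
              + [(-40, 40)] * 2 + [(-25, 25)] * (n - 2) + [(0.0, 0.5)] * 3)

    def x0_from_base(e0):
        vec = [np.log(base.lam)]
        if spec.with_gbgc:
            vec.append(base.B)
        vec.extend([np.log(base.theta_N), np.log(base.theta_WS)])
        vec.extend(np.log(np.clip(base.r[1:], 1e-11, 1e11)))
        vec.extend([e0] * 3)
        return np.asarray(vec)

    e_starts = (1e-3, 0.02, 0.05, 0.1, 0.005)[:max(n_starts, 1)]
    best, n_ok = None, 0
    for e0 in e_starts:
        res = minimize(objective, x0_from_base(e0), method="L-BFGS-B",
                       bounds=bounds,
                       options={"maxiter": max_outer, "ftol": 1e-12, "gtol": 1e-8})
        if np.isfinite(res.fun):
            n_ok += int(res.success)
            if best is None or res.fun < best.fun:
                best = res
    # the e = 0 corner equals the base fit exactly; never report worse
    if best is None or -best.fun < base.loglik:
        return GBGCFit(model=spec.model, n=n, gc=gc, lam=base.lam, B=base.B,
                       theta_N=base.theta_N, theta_WS=base.theta_WS, r=base.r,
                       e_N=0.0, e_SW=0.0, e_WS=0.0, loglik=base.loglik,
                       converged=base.converged, n_starts=n_starts,
                       message="error rates at the zero boundary")
    lam, B, theta_N, theta_WS, r, e_N, e_SW, e_WS = unpack_full(best.x)
    return GBGCFit(model=spec.model, n=n, gc=gc, lam=float(lam), B=float(B),
                   theta_N=float(theta_N), theta_WS=float(theta_WS), r=r,
                   e_N=float(e_N), e_SW=float(e_SW), e_WS=float(e_WS),
                   loglik=float(-best.fun), converged=n_ok > 0, n_starts=n_starts,
                   message="" if n_ok > 0 else "no start reported formal convergence")


def likelihood_ratio_test(fit_reduced: GBGCFit, fit_full: GBGCFit,
                          df: int | None = None) -> dict:
    """Upper-tailed chi-square LRT between nested fits on the same spectra.

    df defaults to the free-parameter difference: 1 for M0 vs M1, 3 for
    M1 vs M1* (and M0 vs M0*).  A negative statistic (numerical artifact of
    nested optimizations) is clipped to 0 with a warning.
    """
    if df is None:
        spec_r = GBGCModelSpec(fit_reduced.model, fit_reduced.gc, fit_reduced.n)
        spec_f = GBGCModelSpec(fit_full.model, fit_full.gc, fit_full.n)
        df = spec_f.n_free_params - spec_r.n_free_params
    if df <= 0:
        raise ValueError("full model must have more free parameters than reduced")
    stat = 2.0 * (fit_full.loglik - fit_reduced.loglik)
    if stat < 0:
        warnings.warn("negative LRT statistic clipped to 0 "
                      f"(2*dlogL = {stat:.3g})", stacklevel=2)
        stat = 0.0
    return {"statistic": stat, "df": df, "p": float(chi2.sf(stat, df))}


@dataclass
class BootstrapResult:
    fits: "object"  # pandas DataFrame, one row per converged replicate
    n_failed: int
    summary: dict = field(default_factory=dict)


def bootstrap_fit(sites, spec: GBGCModelSpec, n_reps: int, seed: int,
                  L_W: float, L_S: float, n_starts: int = 3,
                  resample: bool = True) -> BootstrapResult:
    """Bootstrap over segregating sites: resample, rebuild spectra, refit.

    The resampling unit is the polarized site.  Returns per-replicate
    parameter draws plus mean and 2.5/97.5 percentile summaries; replicates
    whose fit does not converge are excluded and counted.  ``resample=False``
    keeps the original site set (every replicate then equals the point fit),
    which is useful for checking the wiring.
    """
    import pandas as pd

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    if not isinstance(sites, pd.DataFrame):
        sites = pd.DataFrame([{"category": s.category, "derived_count": s.derived_count}
                              for s in sites])
    rows, n_failed = [], 0
    for rep in range(n_reps):
        pick = (rng.integers(0, len(sites), size=len(sites)) if resample
                else np.arange(len(sites)))
        sp = build_spectra(sites.iloc[pick], spec.n, L_W, L_S)
        fit = fit_model(sp, spec, n_starts=n_starts)
        if not np.isfinite(fit.loglik):
            n_failed += 1
            continue
        rows.append({"rep": rep, "lambda": fit.lam, "B": fit.B,
                     "theta_N": fit.theta_N, "theta_WS": fit.theta_WS,
                     "loglik": fit.loglik, "converged": fit.converged})
    df = pd.DataFrame(rows)
    summary = {}
    for col in ("lambda", "B"):
        if len(df):
            summary[col] = {"mean": float(df[col].mean()),
                            "q2.5": float(df[col].quantile(0.025)),
                            "q97.5": float(df[col].quantile(0.975))}
    return BootstrapResult(fits=df, n_failed=n_failed, summary=summary)
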