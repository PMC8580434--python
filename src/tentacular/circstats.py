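"""Core circular statistics for directed tentacle-extension analysis.

This module implements the statistical primitives the behavioural pipelines
are built on:

* Moore's modified Rayleigh test — a nonparametric test of circular
  uniformity for vectors that carry both a heading and a magnitude.  The
  magnitudes enter only through their ranks, which makes the statistic
  robust to how far individual tentacles happen to be extended.
* Monte Carlo critical values for that test, valid for any sample size.
* Maximum-likelihood von Mises fits, optionally weighted (weights are
  relative tentacle lengths in the rotating-stimulus pipeline).
* Small-sample AICc model selection between a uniform circular null and a
  unimodal (von Mises) alternative.
* Fisher's homogeneity-of-concentration (equal kappa) test.
* A tie-corrected Friedman rank-sum test for repeated-measures counts.
* The directedness-versus-offset linear regression (OLS with F-test,
  coefficient confidence intervals and a Shapiro–Wilk residual check).

All public functions take angles in degrees; radians are used internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special, stats

from .errors import EmptySampleError, InsufficientSampleError

__all__ = [
    "VectorSample",
    "MooreResult",
    "VonMisesFit",
    "ModelSelectionResult",
    "EqualKappaResult",
    "FriedmanResult",
    "RegressionResult",
    "moore_rayleigh",
    "moore_critical_value",
    "moore_test",
    "vonmises_fit",
    "kappa_from_rbar",
    "uniform_loglik",
    "model_select",
    "equal_kappa_test",
    "friedman_test",
    "directedness_regression",
    "fisher_lee_correlation",
]

# Concentration parameters are capped here: the MLE diverges as the mean
# resultant length approaches 1 (all angles identical).
KAPPA_MAX = 500.0

# Two AICc units is the conventional cutoff for a model retaining
# "good support" relative to the best model.
GOOD_SUPPORT_DELTA = 2.0

_TWO_PI = 2.0 * math.pi


# ---------------------------------------------------------------------------
# Samples and results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VectorSample:
    """A population of (angle, magnitude) vectors for one trial or frame.

    Parameters
    ----------
    angles_deg:
        Vector headings in degrees.
    weights:
        Nonnegative magnitudes (tentacle lengths or relative lengths).
        ``None`` means unit weights.
    """

    angles_deg: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        angles = np.asarray(self.angles_deg, dtype=float)
        object.__setattr__(self, "angles_deg", angles)
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != angles.shape:
                raise ValueError("weights must match angles in shape")
            if np.any(w < 0):
                raise ValueError("weights must be nonnegative")
            object.__setattr__(self, "weights", w)

    @property
    def n(self) -> int:
        return int(self.angles_deg.size)


@dataclass(frozen=True)
class MooreResult:
    """Outcome of Moore's modified Rayleigh test for one vector population."""

    R_star: float
    phi_star_deg: float  # NaN when the resultant is exactly zero
    n: int
    R_crit: float
    alpha: float
    significant: bool
    trial_id: str | None = None


@dataclass(frozen=True)
class VonMisesFit:
    """Weighted ML fit of a von Mises distribution."""

    mu_deg: float
    kappa: float
    loglik: float
    n_effective: float
    rbar: float
    degenerate: bool = False  # kappa hit the cap (all mass at one angle)


@dataclass(frozen=True)
class ModelSelectionResult:
    """AICc comparison of uniform vs unimodal circular models."""

    loglik_uniform: float
    loglik_unimodal: float
    aicc_uniform: float
    aicc_unimodal: float
    delta_aicc: dict[str, float]
    aicc_weights: dict[str, float]
    best: str
    unimodal_fit: VonMisesFit
    n: int
    good_support_threshold: float = GOOD_SUPPORT_DELTA

    def good_support(self, model: str) -> bool:
        return self.delta_aicc[model] < self.good_support_threshold


@dataclass(frozen=True)
class EqualKappaResult:
    statistic: float
    df: int
    p_value: float
    kappas: tuple[float, ...]
    rbar_pooled: float
    regime: str  # which of Fisher's three approximations was used


@dataclass(frozen=True)
class FriedmanResult:
    chi2: float
    df: int
    p_value: float
    n_subjects: int
    n_treatments: int


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of directedness R* on chord distance z."""

    beta1: float  # intercept
    beta2: float  # slope on z
    f_stat: float
    f_df: tuple[int, int]
    p_value: float
    r_squared: float
    conf_int: dict[str, tuple[float, float]]
    shapiro_p: float
    n: int
    residuals: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Moore's modified Rayleigh test
# ---------------------------------------------------------------------------

def moore_rayleigh(sample: VectorSample) -> tuple[float, float]:
    """Moore's rank-weighted Rayleigh statistic.

    Magnitudes are converted to ascending ranks (ties get average ranks);
    the rank-weighted resultant is

        D = sum_i r_i * (cos theta_i, sin theta_i),
        R* = |D| / n^{3/2},  phi* = atan2(D_y, D_x).

    Returns ``(R_star, phi_star_deg)``; ``phi_star_deg`` is NaN when the
    resultant vanishes exactly (no defined mean direction).
    """
    if sample.n == 0:
        raise EmptySampleError("Moore's test requires at least one vector")
    theta = np.deg2rad(sample.angles_deg)
    if sample.weights is None:
        ranks = np.arange(1.0, sample.n + 1.0)
    else:
        ranks = stats.rankdata(sample.weights, method="average")
    dx = float(np.sum(ranks * np.cos(theta)))
    dy = float(np.sum(ranks * np.sin(theta)))
    resultant = math.hypot(dx, dy)
    # a resultant at rounding-noise level is an exactly balanced sample
    if resultant < 1e-12 * float(np.sum(ranks)):
        return 0.0, float("nan")
    r_star = resultant / sample.n ** 1.5
    phi = math.degrees(math.atan2(dy, dx)) % 360.0
    return r_star, phi


_CRIT_CACHE: dict[tuple[int, float, int, int], float] = {}


def _simulate_moore_null(n: int, reps: int, rng: np.random.Generator,
                         chunk: int = 200_000) -> np.ndarray:
    """R* under the null: n iid uniform headings with distinct magnitudes.

    Because headings are iid uniform and independent of the magnitudes, the
    rank labels can be taken as the fixed sequence 1..n without loss of
    generality.
    """
    ranks = np.arange(1.0, n + 1.0)
    out = np.empty(reps)
    done = 0
    max_rows = max(1, chunk // max(n, 1))
    while done < reps:
        m = min(max_rows, reps - done)
        theta = rng.uniform(0.0, _TWO_PI, size=(m, n))
        dx = np.cos(theta) @ ranks
        dy = np.sin(theta) @ ranks
        out[done:done + m] = np.hypot(dx, dy) / n ** 1.5
        done += m
    return out


def moore_critical_value(
    n: int,
    alpha: float = 0.05,
    reps: int = 100_000,
    seed: int = 19800101,
    cache_path: str | Path | None = None,
) -> float:
    """Monte Carlo (1 - alpha) critical value of R* for sample size n.

    Values are deterministic given ``(n, alpha, reps, seed)`` and memoised;
    ``cache_path`` optionally persists the cache as a TSV keyed the same way.
    """
    if n < 2:
        raise ValueError("critical values require n >= 2")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    if reps < 1000:
        raise ValueError("use at least 1000 Monte Carlo replicates")
    key = (int(n), float(alpha), int(reps), int(seed))
    if key in _CRIT_CACHE:
        return _CRIT_CACHE[key]
    if cache_path is not None:
        cached = _read_crit_cache(Path(cache_path)).get(key)
        if cached is not None:
            _CRIT_CACHE[key] = cached
            return cached
    rng = np.random.default_rng(seed + 1_000_003 * n)
    r = _simulate_moore_null(n, reps, rng)
    crit = float(np.quantile(r, 1.0 - alpha)) if alpha < 1.0 else 0.0
    _CRIT_CACHE[key] = crit
    if cache_path is not None:
        _append_crit_cache(Path(cache_path), key, crit)
    return crit


def _read_crit_cache(path: Path) -> dict[tuple[int, float, int, int], float]:
    if not path.exists():
        return {}
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return {
        (int(r.n), float(r.alpha), int(r.reps), int(r.seed)): float(r.R_crit)
        for r in df.itertuples()
    }

def _append_crit_cache(path: Path, key, crit: float) -> None:
    row = pd.DataFrame(
        [{"n": key[0], "alpha": key[1], "reps": key[2], "seed": key[3],
          "R_crit": crit}]
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    row.to_csv(path, sep="\t", index=False, mode="a",
               header=not path.exists())


def moore_test(
    sample: VectorSample,
    alpha: float = 0.05,
    reps: int = 100_000,
    seed: int = 19800101,
    cache_path: str | Path | None = None,
    trial_id: str | None = None,
) -> MooreResult:
    """Moore's modified Rayleigh test with a Monte Carlo significance call."""
    r_star, phi_star = moore_rayleigh(sample)
    crit = moore_critical_value(sample.n, alpha, reps, seed, cache_path)
    return MooreResult(
        R_star=r_star,
        phi_star_deg=phi_star,
        n=sample.n,
        R_crit=crit,
        alpha=alpha,
        significant=bool(r_star > crit),
        trial_id=trial_id,
    )


# ---------------------------------------------------------------------------
# von Mises fitting
# ---------------------------------------------------------------------------

def _bessel_ratio(kappa: float) -> float:
    """A1(kappa) = I1(kappa) / I0(kappa), computed with scaled Bessels."""
    if kappa == 0.0:
        return 0.0
    return float(special.i1e(kappa) / special.i0e(kappa))


def kappa_from_rbar(rbar: float, kappa_max: float = KAPPA_MAX,
                    tol: float = 1e-13, max_iter: int = 60) -> float:
    """Invert the Bessel ratio: solve A1(kappa) = rbar for kappa >= 0.

    Newton iteration from the standard piecewise closed-form approximation
    (Fisher 1993); A1'(kappa) = 1 - A1/kappa - A1^2.
    """
    if not 0.0 <= rbar <= 1.0:
        raise ValueError("mean resultant length must lie in [0, 1]")
    if rbar == 0.0:
        return 0.0
    if rbar >= _bessel_ratio(kappa_max):
        return kappa_max
    if rbar < 0.53:
        k = 2.0 * rbar + rbar ** 3 + 5.0 * rbar ** 5 / 6.0
    elif rbar < 0.85:
        k = -0.4 + 1.39 * rbar + 0.43 / (1.0 - rbar)
    else:
        k = 1.0 / (rbar ** 3 - 4.0 * rbar ** 2 + 3.0 * rbar)
    for _ in range(max_iter):
        a = _bessel_ratio(k)
        err = a - rbar
        if abs(err) < tol:
            break
        deriv = 1.0 - a / k - a * a
        if deriv <= 0.0:
            break
        step = err / deriv
        k = min(max(k - step, 1e-12), kappa_max)
    return float(min(k, kappa_max))


def _log_i0(kappa: float) -> float:
    # ln I0(k) = k + ln i0e(k), stable for large k
    return kappa + math.log(float(special.i0e(kappa)))


def vonmises_fit(sample: VectorSample, weighted: bool = True,
                 kappa_max: float = KAPPA_MAX) -> VonMisesFit:
    """Weighted maximum-likelihood von Mises fit.

    mu is the direction of the weighted resultant; kappa solves
    A1(kappa) = rbar where rbar is the weighted mean resultant length.
    The log-likelihood is the weighted sum of von Mises log-densities.
    """
    if sample.n == 0:
        raise EmptySampleError("cannot fit a von Mises to an empty sample")
    theta = np.deg2rad(sample.angles_deg)
    if weighted and sample.weights is not None:
        w = sample.weights
        if not np.any(w > 0):
            raise ValueError("weighted fit requires a positive total weight")
    else:
        w = np.ones(sample.n)
    w_sum = float(np.sum(w))
    cx = float(np.sum(w * np.cos(theta))) / w_sum
    sx = float(np.sum(w * np.sin(theta))) / w_sum
    rbar = math.hypot(cx, sx)
    mu = math.degrees(math.atan2(sx, cx)) % 360.0 if rbar > 0 else 0.0
    kappa = kappa_from_rbar(min(rbar, 1.0), kappa_max=kappa_max)
    degenerate = kappa >= kappa_max
    mu_rad = math.radians(mu)
    # ln f = kappa cos(theta - mu) - ln(2 pi I0(kappa))
    log_norm = math.log(_TWO_PI) + _log_i0(kappa)
    loglik = float(np.sum(w * (kappa * np.cos(theta - mu_rad) - log_norm)))
    n_eff = w_sum ** 2 / float(np.sum(w * w))
    return VonMisesFit(mu_deg=mu, kappa=kappa, loglik=loglik,
                       n_effective=n_eff, rbar=rbar, degenerate=degenerate)


def uniform_loglik(n: int) -> float:
    """Log-likelihood of n angles under the circular uniform density."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    return -n * math.log(_TWO_PI)


# ---------------------------------------------------------------------------
# AICc model selection (uniform vs unimodal)
# ---------------------------------------------------------------------------

def _aicc(loglik: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        raise InsufficientSampleError(
            f"AICc undefined for n={n} with k={k} parameters"
        )
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def model_select(angles_deg) -> ModelSelectionResult:
    """Rank uniform vs unimodal circular models of a set of angles by AICc.

    The uniform null has no free parameters; the unimodal alternative is a
    von Mises with two (mu, kappa).  Small-sample AICc is used throughout;
    a model retains "good support" when its delta-AICc is below 2.
    """
    angles = np.asarray(angles_deg, dtype=float)
    n = angles.size
    if n < 4:
        raise InsufficientSampleError(
            "model selection needs at least 4 angles (AICc with k=2)"
        )
    fit = vonmises_fit(VectorSample(angles), weighted=False)
    ll_u = uniform_loglik(n)
    aicc = {
        "uniform": _aicc(ll_u, 0, n),
        "unimodal": _aicc(fit.loglik, 2, n),
    }
    best = min(aicc, key=aicc.get)
    delta = {m: aicc[m] - aicc[best] for m in aicc}
    raw = {m: math.exp(-0.5 * delta[m]) for m in delta}
    total = sum(raw.values())
    weights = {m: raw[m] / total for m in raw}
    return ModelSelectionResult(
        loglik_uniform=ll_u,
        loglik_unimodal=fit.loglik,
        aicc_uniform=aicc["uniform"],
        aicc_unimodal=aicc["unimodal"],
        delta_aicc=delta,
        aicc_weights=weights,
        best=best,
        unimodal_fit=fit,
        n=n,
    )


# ---------------------------------------------------------------------------
# Homogeneity of concentration parameters (Fisher 1993, three regimes)
# ---------------------------------------------------------------------------

def equal_kappa_test(groups) -> EqualKappaResult:
    """Test whether several angle samples share a common concentration.

    Follows Fisher's (1993) procedure: the approximation regime is chosen
    by the mean resultant length of the pooled sample; the statistic is
    referred to a chi-square with (g - 1) degrees of freedom.
    """
    samples = [np.deg2rad(np.asarray(g, dtype=float)) for g in groups]
    g = len(samples)
    if g < 2:
        raise ValueError("need at least two groups")
    ns = np.array([s.size for s in samples], dtype=float)
    if np.any(ns < 2):
        raise ValueError("each group needs at least two angles")
    rbars = np.array([
        math.hypot(float(np.mean(np.cos(s))), float(np.mean(np.sin(s))))
        for s in samples
    ])
    pooled = np.concatenate(samples)
    rbar_all = math.hypot(float(np.mean(np.cos(pooled))),
                          float(np.mean(np.sin(pooled))))
    kappas = tuple(kappa_from_rbar(min(r, 1.0)) for r in rbars)
    n_total = float(np.sum(ns))

    if rbar_all < 0.45:
        g1 = np.arcsin(np.clip(2.0 * rbars * math.sqrt(3.0 / 8.0), -1.0, 1.0))
        w = 4.0 * (ns - 4.0) / 3.0
        stat = float(np.sum(w * g1 ** 2) - np.sum(w * g1) ** 2 / np.sum(w))
        regime = "low"
    elif rbar_all < 0.70:
        g2 = np.arcsinh((rbars - 1.089) / 0.258)
        w = (ns - 3.0) / 0.798
        stat = float(np.sum(w * g2 ** 2) - np.sum(w * g2) ** 2 / np.sum(w))
        regime = "medium"
    else:
        vs = ns - 1.0
        v = n_total - g
        ds = ns * (1.0 - rbars)  # circular dispersion n_i - R_i
        d = float(np.sum(ds))
        bartlett = 1.0 + (float(np.sum(1.0 / vs)) - 1.0 / v) / (3.0 * (g - 1.0))
        stat = float(
            (v * math.log(d / v) - np.sum(vs * np.log(ds / vs))) / bartlett
        )
        regime = "high"
    df = g - 1
    p = float(stats.chi2.sf(max(stat, 0.0), df))
    return EqualKappaResult(statistic=stat, df=df, p_value=p,
                            kappas=kappas, rbar_pooled=rbar_all,
                            regime=regime)


# ---------------------------------------------------------------------------
# Friedman rank-sum test
# ---------------------------------------------------------------------------

def friedman_test(table) -> FriedmanResult:
    """Tie-corrected Friedman test on a complete subjects x treatments table.

    ``table`` is a 2-D array or DataFrame with one row per subject and one
    column per treatment; every subject must be observed under every
    treatment (rows with missing cells should be dropped beforehand).
    """
    x = np.asarray(pd.DataFrame(table), dtype=float)
    if np.isnan(x).any():
        raise ValueError("table contains missing cells; drop incomplete "
                         "subjects before testing")
    n, k = x.shape
    if k < 2:
        raise ValueError("need at least two treatments")
    if n < 2:
        raise ValueError("need at least two complete subjects")
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    col_sums = ranks.sum(axis=0)
    mean_rank_sum = n * (k + 1) / 2.0
    numer = (k - 1) * float(np.sum((col_sums - mean_rank_sum) ** 2))
    denom = float(np.sum(ranks ** 2)) - n * k * (k + 1) ** 2 / 4.0
    if denom == 0.0:  # all values tied within every subject
        chi2 = 0.0
    else:
        chi2 = numer / denom
    df = k - 1
    p = float(stats.chi2.sf(chi2, df)) if denom != 0.0 else 1.0
    return FriedmanResult(chi2=chi2, df=df, p_value=p,
                          n_subjects=n, n_treatments=k)


# ---------------------------------------------------------------------------
# Directedness-vs-offset regression
# ---------------------------------------------------------------------------

def directedness_regression(r_star, z) -> RegressionResult:
    """OLS fit of R* on an intercept and the unit-circle chord distance z.

    Reports the slope/intercept, the model F-test, R^2, 95% confidence
    intervals for both coefficients and a Shapiro–Wilk p-value for the
    residuals.
    """
    r_star = np.asarray(r_star, dtype=float)
    z = np.asarray(z, dtype=float)
    if r_star.size != z.size:
        raise ValueError("R* and z must be paired")
    if r_star.size < 3:
        raise InsufficientSampleError("regression needs at least 3 trials")
    if np.ptp(z) == 0.0:
        raise ValueError("z is constant; the design matrix is singular")
    X = sm.add_constant(z)
    fit = sm.OLS(r_star, X).fit()
    ci = np.asarray(fit.conf_int(alpha=0.05))
    resid = np.asarray(fit.resid)
    shapiro_p = float(stats.shapiro(resid).pvalue)
    return RegressionResult(
        beta1=float(fit.params[0]),
        beta2=float(fit.params[1]),
        f_stat=float(fit.fvalue),
        f_df=(int(fit.df_model), int(fit.df_resid)),
        p_value=float(fit.f_pvalue),
        r_squared=float(fit.rsquared),
        conf_int={
            "beta1": (float(ci[0, 0]), float(ci[0, 1])),
            "beta2": (float(ci[1, 0]), float(ci[1, 1])),
        },
        shapiro_p=shapiro_p,
        n=int(r_star.size),
        residuals=resid,
    )


# ---------------------------------------------------------------------------
# Circular-circular association (used by the rotation pipeline)
# ---------------------------------------------------------------------------

def fisher_lee_correlation(a_deg, b_deg) -> float:
    """Fisher–Lee circular-circular correlation coefficient in [-1, 1].

    Positive when the two angle series rotate together in the same sense,
    negative when they rotate in opposite senses.  Returns NaN when either
    series is constant (no angular variation to correlate).
    """
    a = np.deg2rad(np.asarray(a_deg, dtype=float))
    b = np.deg2rad(np.asarray(b_deg, dtype=float))
    if a.size != b.size:
        raise ValueError("series must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 paired angles")
    da = np.sin(a[:, None] - a[None, :])
    db = np.sin(b[:, None] - b[None, :])
    iu = np.triu_indices(a.size, k=1)
    num = float(np.sum(da[iu] * db[iu]))
    den = math.sqrt(float(np.sum(da[iu] ** 2)) * float(np.sum(db[iu] ** 2)))
    if den == 0.0:
        return float("nan")
    return num / den
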