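"""Unimodal MLE fits of patch-area distributions and AIC model selection.

Four two-parameter candidate families are fitted by maximum likelihood:
gamma (shape, rate), Weibull (shape, scale), lognormal (meanlog, sdlog) and
normal (mean, MLE sd).  Families are ranked by AIC = 2k - 2 logL with k = 2
throughout (no small-sample correction); every family with dAIC < 2 counts
as a plausible candidate, and normalised Akaike weights
w_i = exp(-dAIC_i/2) / sum_j exp(-dAIC_j/2) quantify relative support.

Areas are conventionally pre-scaled (default factor 0.01, i.e. cm^2 to dm^2
magnitudes) to keep the optimiser in a well-behaved range; dAIC and the
weights are invariant to a common positive factor, so the ranking does not
depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "Family",
    "FamilyFitResult",
    "FamilyRanking",
    "FitError",
    "FAMILIES",
    "scale_areas",
    "fit_family",
    "akaike_weights",
    "rank_families",
    "fit_all_families",
    "sample_skewness",
]

#: canonical family order, also the deterministic tie-break order
FAMILIES = ("gamma", "weibull", "lognormal", "normal")
Family = str
_K_PARAMS = 2  # every candidate family has two free parameters


class FitError(RuntimeError):
    """Raised when a maximum-likelihood fit fails to converge."""


@dataclass(frozen=True)
class FamilyFitResult:
    family: Family
    params: dict[str, float]
    log_likelihood: float
    aic: float
    n: int
    scale_factor: float = 1.0


@dataclass(frozen=True)
class FamilyRanking:
    """AIC ranking of family fits on one dataset (best first)."""

    results: tuple[FamilyFitResult, ...]
    delta_aic: dict[Family, float]
    akaike_weights: dict[Family, float]
    #: families with dAIC < 2 — all are considered plausible fits
    candidates: tuple[Family, ...]

    @property
    def best(self) -> FamilyFitResult:
        return self.results[0]


def scale_areas(areas, factor: float) -> np.ndarray:
    """Multiply areas by a common positive factor (e.g. 0.01)."""
    areas = np.asarray(areas, dtype=float)
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    if np.any(areas <= 0):
        raise ValueError("areas must be strictly positive")
    return areas * factor


def _validate(areas: np.ndarray, family: Family) -> None:
    if areas.size < 3:
        raise ValueError(f"need n >= 3 observations, got {areas.size}")
    if np.ptp(areas) == 0:
        raise ValueError("degenerate data: zero variance")
    if family != "normal" and np.any(areas <= 0):
        raise ValueError(f"{family} requires strictly positive data")


def fit_family(areas, family: Family, scale_factor: float = 1.0) -> FamilyFitResult:
    """Maximum-likelihood fit of one candidate family.

    ``scale_factor`` is applied to the data before fitting and recorded in
    the result.  Normal and lognormal use their closed-form MLEs; gamma and
    Weibull are fitted numerically with the location pinned at zero.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    x = scale_areas(areas, scale_factor) if family != "normal" else (
        np.asarray(areas, dtype=float) * float(scale_factor)
    )
    _validate(x, family)
    n = x.size

    if family == "normal":
        mean, sd = float(np.mean(x)), float(np.std(x))  # MLE sd (1/n)
        ll = float(np.sum(stats.norm.logpdf(x, mean, sd)))
        params = {"mean": mean, "sd": sd}
    elif family == "lognormal":
        logs = np.log(x)
        mu, sigma = float(np.mean(logs)), float(np.std(logs))
        ll = float(np.sum(stats.lognorm.logpdf(x, sigma, scale=np.exp(mu))))
        params = {"meanlog": mu, "sdlog": sigma}
    elif family == "gamma":
        try:
            shape, _, scale = stats.gamma.fit(x, floc=0)
        except (ValueError, RuntimeError) as exc:
            raise FitError(f"gamma MLE did not converge: {exc}") from exc
        ll = float(np.sum(stats.gamma.logpdf(x, shape, scale=scale)))
        params = {"shape": float(shape), "rate": float(1.0 / scale)}
    else:  # weibull
        try:
            shape, _, scale = stats.weibull_min.fit(x, floc=0)
        except (ValueError, RuntimeError) as exc:
            raise FitError(f"Weibull MLE did not converge: {exc}") from exc
        ll = float(np.sum(stats.weibull_min.logpdf(x, shape, scale=scale)))
        params = {"shape": float(shape), "scale": float(scale)}

    if not np.isfinite(ll):
        raise FitError(f"{family} fit produced a non-finite log-likelihood")
    return FamilyFitResult(
        family=family,
        params=params,
        log_likelihood=ll,
        aic=2.0 * _K_PARAMS - 2.0 * ll,
        n=n,
        scale_factor=float(scale_factor),
    )


def akaike_weights(aics) -> np.ndarray:
    """Normalised Akaike weights from a vector of AIC values.

    Computed after subtracting the minimum AIC for numerical stability;
    invariant to adding any constant to all AICs.
    """
    aics = np.asarray(aics, dtype=float)
    if aics.size < 2:
        raise ValueError("need at least two AIC values")
    if not np.all(np.isfinite(aics)):
        raise ValueError("AIC values must be finite")
    rel = np.exp(-0.5 * (aics - aics.min()))
    return rel / rel.sum()


def rank_families(results) -> FamilyRanking:
    """Rank family fits by AIC; ties broken by the canonical family order."""
    results = list(results)
    if len(results) < 2:
        raise ValueError("need at least two fitted families to rank")
    ns = {r.n for r in results}
    if len(ns) != 1:
        raise ValueError(f"fits are not on identical data (n values {sorted(ns)})")
    order = {f: i for i, f in enumerate(FAMILIES)}
    results.sort(key=lambda r: (r.aic, order[r.family]))
    aics = np.array([r.aic for r in results])
    weights = akaike_weights(aics)
    delta = aics - aics.min()
    return FamilyRanking(
        results=tuple(results),
        delta_aic={r.family: float(d) for r, d in zip(results, delta)},
        akaike_weights={r.family: float(w) for r, w in zip(results, weights)},
        candidates=tuple(r.family for r, d in zip(results, delta) if d < 2.0),
    )


def fit_all_families(
    areas, scale_factor: float = 0.01, families=FAMILIES
) -> FamilyRanking:
    """Fit every candidate family on commonly-scaled data and rank them."""
    return rank_families(fit_family(areas, f, scale_factor) for f in families)


def sample_skewness(values) -> float:
    """Moment coefficient of skewness g1 = m3 / m2^(3/2) (1/n central moments)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    m2 = np.mean((x - x.mean()) ** 2)
    if m2 == 0:
        raise ValueError("degenerate data: zero variance")
    m3 = np.mean((x - x.mean()) ** 3)
    return float(m3 / m2**1.5)
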