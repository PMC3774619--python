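"""Per-quilt analysis orchestration and group comparison.

``analyze_quilt`` runs the full pipeline the published analysis applied per
quilt: crop to the patched bounding box, compute areas and skewness, fit
and rank the four unimodal families, fit a seeded Gaussian mixture and run
the sorted-area envelope test, then fit a Strauss process to the patch
centroids and run the L-function envelope test.  A Strauss fit with
``gamma > 1`` is a *refusal* (the model rejects the pattern), recorded in
the report rather than raised.

All stage seeds are derived deterministically from one master seed, so a
report is bit-identical under reruns with the same configuration.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import distributions as dist
from . import mixtures as mix
from . import pointprocess as pp
from . import stats as gstats
from .geometry import Quilt, QuiltClass, patched_bounding_box

__all__ = [
    "AnalysisConfig",
    "QuiltReport",
    "analyze_quilt",
    "category_seeds",
    "compare_quilt_groups",
]

#: metrics compared between quilt groups
GROUP_METRICS = ("n_patches", "patched_area", "bandwidth", "pct_deviations")


@dataclass(frozen=True)
class AnalysisConfig:
    """Pipeline defaults mirror the published analysis: areas scaled by
    0.01 before family fitting, 39-simulation envelopes, 0.01-cm radius
    profile steps, isotropic edge correction on."""

    seed: int = 0
    scale_factor: float = 0.01
    n_sim: int = 39
    r_step: float = 0.01
    correction: str = "isotropic"
    quad_factor: float = 4.0
    r_max: float | None = None
    proposals_per_point: int = 10_000
    burn_in_per_point: int = 1_000
    min_points_for_strauss: int = 10

    def stage_seed(self, stage: int) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        return int(
            np.random.SeedSequence(
                entropy=self.seed, spawn_key=(stage,)
            ).generate_state(1)[0]
            % 2**31
        )


@dataclass
class QuiltReport:
    name: str
    quilt_class: str
    n_patches: int
    patched_area: float
    window: tuple[float, float]
    skewness: float
    bandwidth: float
    family_ranking: dist.FamilyRanking
    mixture: mix.MixtureModel
    area_envelope: mix.AreaEnvelopeResult
    strauss: pp.StraussFit | None
    l_envelope: pp.LEnvelopeResult | None
    refusals: dict[str, str]
    config: AnalysisConfig

    def summary(self) -> dict[str, Any]:
        """Flat JSON-serialisable summary of the report."""
        out: dict[str, Any] = {
            "name": self.name,
            "class": self.quilt_class,
            "n_patches": self.n_patches,
            "patched_area": self.patched_area,
            "window": list(self.window),
            "skewness": self.skewness,
            "bandwidth": self.bandwidth,
            "best_family": self.family_ranking.best.family,
            "candidate_families": list(self.family_ranking.candidates),
            "delta_aic": self.family_ranking.delta_aic,
            "akaike_weights": self.family_ranking.akaike_weights,
            "mixture_components": [list(c) for c in self.mixture.components],
            "n_deviations": self.area_envelope.n_deviations,
            "pct_deviations": self.area_envelope.pct_deviations,
            "envelope_alpha": self.area_envelope.alpha,
            "refusals": self.refusals,
            "config": asdict(self.config),
        }
        if self.strauss is not None:
            out["strauss"] = {
                "beta": self.strauss.beta,
                "gamma": self.strauss.gamma,
                "r": self.strauss.r,
                "valid": self.strauss.valid,
                "log_pseudolikelihood": self.strauss.log_pseudolikelihood,
            }
        if self.l_envelope is not None:
            out["l_envelope"] = {
                "n_sim": self.l_envelope.n_sim,
                "any_outside": self.l_envelope.any_outside,
                "frac_outside": self.l_envelope.frac_outside,
            }
        return out


def category_seeds(quilt: Quilt) -> list[tuple[float, float, float]]:
    """Mixture seeds: per motif category for regular quilts (mean, sd,
    relative frequency), a single overall seed for crazy quilts.

    Categories whose area means are indistinguishable (closer than half a
    component sd — e.g. two motif shapes cut to the same size) are merged
    into one seed: separate Gaussian components on identical distributions
    make EM singular and are unidentifiable anyway.
    """
    areas = quilt.areas
    cats = quilt.categories
    if quilt.quilt_class is QuiltClass.REGULAR and any(c is not None for c in cats):
        seeds = []
        for cat in sorted({c for c in cats if c is not None}):
            sel = areas[[c == cat for c in cats]]
            sd = float(sel.std()) if sel.size > 1 else float(areas.std())
            seeds.append((float(sel.mean()), max(sd, 1e-9), sel.size / areas.size))
        merged: list[tuple[float, float, float]] = []
        for mu, sd, f in sorted(seeds):
            if merged and abs(mu - merged[-1][0]) < 0.5 * max(sd, merged[-1][1]):
                mu0, sd0, f0 = merged[-1]
                w0, w1 = f0 / (f0 + f), f / (f0 + f)
                mu_new = w0 * mu0 + w1 * mu
                var_new = (
                    w0 * (sd0**2 + (mu0 - mu_new) ** 2)
                    + w1 * (sd**2 + (mu - mu_new) ** 2)
                )
                merged[-1] = (mu_new, max(np.sqrt(var_new), 1e-9), f0 + f)
            else:
                merged.append((mu, sd, f))
        return merged
    return [(float(areas.mean()), max(float(areas.std()), 1e-9), 1.0)]


def analyze_quilt(quilt: Quilt, config: AnalysisConfig = AnalysisConfig()) -> QuiltReport:
    """Run the full per-quilt analysis; see the module docstring."""
    quilt = patched_bounding_box(quilt)
    areas = quilt.areas
    refusals: dict[str, str] = {}

    try:
        skew = dist.sample_skewness(areas)
        ranking = dist.fit_all_families(areas, scale_factor=config.scale_factor)
    except (ValueError, dist.FitError) as exc:
        raise RuntimeError(f"area-distribution stage failed: {exc}") from exc

    try:
        kde = mix.kde_with_bandwidth(areas)
        mixture = mix.fit_seeded_mixture(areas, category_seeds(quilt))
        envelope = mix.area_envelope_test(
            areas, mixture, n_sim=config.n_sim, seed=config.stage_seed(1)
        )
    except (ValueError, mix.ComponentCollapseError) as exc:
        raise RuntimeError(f"mixture-envelope stage failed: {exc}") from exc

    strauss: pp.StraussFit | None = None
    l_env: pp.LEnvelopeResult | None = None
    if quilt.patches and len(quilt.patches) >= config.min_points_for_strauss:
        pattern = pp.PointPattern(points=quilt.centroids, window=quilt.window)
        try:
            strauss = pp.fit_strauss(
                pattern,
                r_step=config.r_step,
                correction=config.correction,
                quad_factor=config.quad_factor,
                r_max=config.r_max,
            )
        except (ValueError, RuntimeError) as exc:
            raise RuntimeError(f"Strauss stage failed: {exc}") from exc
        if strauss.valid:
            l_env = pp.l_envelope_test(
                pattern,
                strauss,
                n_sim=config.n_sim,
                seed=config.stage_seed(2),
                proposals_per_point=config.proposals_per_point,
                burn_in_per_point=config.burn_in_per_point,
            )
        else:
            refusals["l_envelope"] = (
                f"gamma = {strauss.gamma:.3f} > 1: Strauss model rejected"
            )
    else:
        refusals["strauss"] = (
            f"only {len(quilt.patches)} patches "
            f"(< {config.min_points_for_strauss} required)"
        )

    return QuiltReport(
        name=quilt.name,
        quilt_class=quilt.quilt_class.value,
        n_patches=len(quilt.patches),
        patched_area=quilt.patched_area,
        window=quilt.window,
        skewness=skew,
        bandwidth=kde.bandwidth,
        family_ranking=ranking,
        mixture=mixture,
        area_envelope=envelope,
        strauss=strauss,
        l_envelope=l_env,
        refusals=refusals,
        config=config,
    )


def _metric(report: QuiltReport, metric: str) -> float:
    if metric == "n_patches":
        return float(report.n_patches)
    if metric == "patched_area":
        return float(report.patched_area)
    if metric == "bandwidth":
        return float(report.bandwidth)
    if metric == "pct_deviations":
        return float(report.area_envelope.pct_deviations)
    raise ValueError(f"unknown metric {metric!r}; choose from {GROUP_METRICS}")


def compare_quilt_groups(
    reports_a, reports_b, metrics=GROUP_METRICS
) -> pd.DataFrame:
    """Mann-Whitney U and Cohen's d per metric between two report groups.

    Returns a tidy DataFrame (one row per metric) with group means, U, z,
    two-sided p and d (sign: group A minus group B).
    """
    reports_a, reports_b = list(reports_a), list(reports_b)
    if len(reports_a) < 2 or len(reports_b) < 2:
        raise ValueError("need at least 2 reports per group")
    rows = []
    for metric in metrics:
        a = np.array([_metric(r, metric) for r in reports_a])
        b = np.array([_metric(r, metric) for r in reports_b])
        test = gstats.mann_whitney(a, b)
        try:
            d = gstats.cohens_d(a, b)
        except ValueError:
            d = float("nan")  # zero pooled variance (e.g. fixed-size designs)
        rows.append(
            {
                "metric": metric,
                "mean_a": a.mean(),
                "mean_b": b.mean(),
                "u": test.u,
                "z": test.z,
                "p_two_sided": test.p_two_sided,
                "cohens_d": d,
            }
        )
    return pd.DataFrame(rows)
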