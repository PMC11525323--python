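"""Posterior risk surfaces, exceedance hotspots, and the shared-variance fraction.

The joint model decomposes each area's log relative risk of outcome 1
into a shared part delta*theta_i, a specific spatially structured part
s_i1, and a specific unstructured part u_i1.  This module turns retained
MCMC draws into the quantities mapped in practice: posterior means of
exp(component), equal-tailed 95% credible intervals, exceedance
probabilities Pr(exp(component) > 1 | data), a four-class hotspot
labelling, and the fraction of outcome-1 risk variation attributable to
the shared component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mcmc import PosteriorSamples

__all__ = [
    "RiskSurface",
    "FractionSummary",
    "component_risk_summary",
    "exceedance_probability",
    "shared_variance_fraction",
    "hotspot_classes",
    "results_table",
    "HOTSPOT_LABELS",
]

log = logging.getLogger(__name__)

HOTSPOT_LABELS = ("minimal", "weak", "moderate", "strong")

_COMPONENTS = {
    "shared_theta": ("theta",),
    "specific_spatial_k1": ("s1",),
    "specific_spatial_k2": ("s2",),
    "specific_nonspatial_k1": ("u1",),
    "specific_nonspatial_k2": ("u2",),
    "specific_total_k1": ("s1", "u1"),
    "specific_total_k2": ("s2", "u2"),
}


@dataclass
class RiskSurface:
    """Per-area posterior summary of a relative-risk component exp(.).

    ``significant`` flags areas whose entire 95% interval lies above 1
    (the conventional "high risk at the 95% CI" criterion);
    ``hotspot_class`` bins the exceedance probability.
    """

    component: str
    mean: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    exceedance: np.ndarray
    significant: np.ndarray
    hotspot_class: np.ndarray


@dataclass
class FractionSummary:
    """Posterior mean and equal-tailed 95% CI of the shared-variance fraction."""

    mean: float
    lo95: float
    hi95: float
    n_excluded: int = 0


def _component_draws(samples: PosteriorSamples, component: str) -> np.ndarray:
    """Log-scale draws (m, n) of the requested component."""
    if component not in _COMPONENTS:
        raise ValueError(f"unknown component {component!r}; choose from {sorted(_COMPONENTS)}")
    parts = _COMPONENTS[component]
    missing = [p for p in parts if p not in samples.chains[0]]
    if missing:
        raise ValueError(
            f"component {component!r} needs draws of {missing} which the fitted "
            f"family ({samples.spec.family!r}) does not provide"
        )
    return sum(samples.stacked(p) for p in parts)


def component_risk_summary(
    samples: PosteriorSamples, component: str, cuts: tuple[float, ...] = (0.5, 0.8, 0.9)
) -> RiskSurface:
    """Posterior summary of exp(component) across retained draws.

    The 95% interval is the equal-tailed 2.5%/97.5% sample quantile
    bracket of exp(component).
    """
    logdraws = _component_draws(samples, component)
    rr = np.exp(logdraws)
    mean = rr.mean(axis=0)
    lo, hi = np.quantile(rr, [0.025, 0.975], axis=0)
    exc = np.mean(logdraws > 0.0, axis=0)
    return RiskSurface(
        component=component,
        mean=mean,
        lo95=lo,
        hi95=hi,
        exceedance=exc,
        significant=lo > 1.0,
        hotspot_class=hotspot_classes(exc, cuts),
    )


def exceedance_probability(
    samples: PosteriorSamples, component: str, threshold: float = 1.0
) -> np.ndarray:
    """Per-area fraction of draws with exp(component_i) > threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    logdraws = _component_draws(samples, component)
    return np.mean(logdraws > np.log(threshold), axis=0)


def shared_variance_fraction(samples: PosteriorSamples) -> FractionSummary:
    """Posterior of Var(delta*theta) / (Var(delta*theta) + Var(s1) + Var(u1)).

    Computed per retained draw from the across-area empirical variances,
    then summarised by the posterior mean and equal-tailed 95% CI.  Draws
    with zero total variance are excluded (with a logged count).
    """
    if samples.spec.family != "shared":
        raise ValueError("shared_variance_fraction requires a shared-family fit")
    theta = samples.stacked("theta")
    delta = samples.stacked("delta")
    s1 = samples.stacked("s1")
    u1 = samples.stacked("u1")
    v_shared = np.var(delta[:, None] * theta, axis=1)
    v_s = np.var(s1, axis=1)
    v_u = np.var(u1, axis=1)
    denom = v_shared + v_s + v_u
    ok = denom > 0
    n_excluded = int((~ok).sum())
    if n_excluded:
        log.warning("excluded %d draw(s) with zero total variance", n_excluded)
    if not np.any(ok):
        raise ValueError("all draws have zero total variance; fraction undefined")
    frac = v_shared[ok] / denom[ok]
    lo, hi = np.quantile(frac, [0.025, 0.975])
    return FractionSummary(float(frac.mean()), float(lo), float(hi), n_excluded)


def hotspot_classes(
    probs: np.ndarray, cuts: tuple[float, ...] = (0.5, 0.8, 0.9)
) -> np.ndarray:
    """Bin exceedance probabilities into hotspot classes.

    Left-closed, right-open bins except the top bin: with the default
    cuts, minimal < 0.5 <= weak < 0.8 <= moderate < 0.9 <= strong.
    """
    probs = np.asarray(probs, dtype=float)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if len(cuts) != 3 or not (cuts[0] < cuts[1] < cuts[2]):
        raise ValueError("cuts must be three strictly increasing values")
    idx = np.searchsorted(np.asarray(cuts), probs, side="right")
    return np.asarray(HOTSPOT_LABELS, dtype=object)[idx]


def results_table(samples: PosteriorSamples) -> pd.DataFrame:
    """Per-area results in the standard output layout.

    Shared-risk summaries (exp(theta)) plus the outcome-1 specific total
    risk exp(s1 + u1), matching the columns of the results CSV.
    """
    shared = component_risk_summary(samples, "shared_theta")
    specific = component_risk_summary(samples, "specific_total_k1")
    return pd.DataFrame(
        {
            "area_id": samples.area_ids,
            "rr_shared_mean": shared.mean,
            "rr_shared_lo95": shared.lo95,
            "rr_shared_hi95": shared.hi95,
            "pr_shared_gt1": shared.exceedance,
            "rr_specific_mean_k1": specific.mean,
            "pr_specific_gt1_k1": specific.exceedance,
            "hotspot_class": shared.hotspot_class,
        }
    )
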