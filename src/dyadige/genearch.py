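"""Derived genetic-architecture quantities and significance machinery.

Covers the quantities a dyadic indirect-genetic-effect analysis reports on
top of raw variance components:

* total heritable variance of a dyadic trait,
  ``V_TBV = V_Am + V_Af + 2 COV_Am,Af`` (dyads, group size n = 2);
* genetic correlations between effect channels;
* likelihood-ratio tests with the two boundary conventions — a 50:50
  mixture of chi-square(0) and chi-square(1) for variances tested on their
  zero boundary, and plain chi-square(1) for covariances/correlations;
* reverse scoring of latency traits (negation, so larger = more motivated
  or more attractive);
* the genetic-level responsiveness matrix ``Psi = C_ID G_D^{-1}`` relating
  indirect effects to the direct genetic basis of partner traits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .synth import Channel, GeneticCovariance

MIXTURE_HALF_CHI2 = "mixture_half_chi2"
CHI2_DF1 = "chi2_df1"

__all__ = [
    "MIXTURE_HALF_CHI2",
    "CHI2_DF1",
    "LRTResult",
    "CorrelationEstimate",
    "ZeroVarianceError",
    "total_heritable_variance",
    "genetic_correlation",
    "lrt",
    "reverse_score",
    "psi_matrix",
]


class ZeroVarianceError(ValueError):
    """A genetic correlation is undefined because a parent variance is zero
    (boundary case: the correlation cannot be estimated or tested)."""


@dataclass(frozen=True)
class LRTResult:
    """A likelihood-ratio test of one variance component or covariance."""

    statistic: float
    convention: str  # MIXTURE_HALF_CHI2 or CHI2_DF1
    p_value: float


@dataclass(frozen=True)
class CorrelationEstimate:
    """A genetic correlation between two effect channels."""

    channel_i: Channel
    channel_j: Channel
    r: float
    se: float | None = None
    test: LRTResult | None = None


def total_heritable_variance(v_am: float, v_af: float, cov_amaf: float) -> float:
    """Total heritable variance of a dyadic trait.

    With a male and a female genetic effect on the same interaction trait,
    the variance in total breeding value for a dyad (group size 2) is
    ``V_Am + V_Af + 2 COV_Am,Af``.  The (V_Am, V_Af, COV) triple must form
    an admissible 2x2 covariance block.
    """
    if v_am < 0 or v_af < 0:
        raise ValueError("variances must be non-negative")
    if abs(cov_amaf) > math.sqrt(v_am * v_af) + 1e-12:
        raise ValueError("inadmissible block: |COV_Am,Af| exceeds sqrt(V_Am * V_Af)")
    return v_am + v_af + 2.0 * cov_amaf


def genetic_correlation(g: GeneticCovariance, ci: Channel, cj: Channel) -> CorrelationEstimate:
    """Genetic correlation ``G_ij / sqrt(G_ii G_jj)`` between two channels.

    Raises :class:`ZeroVarianceError` if a parent variance is zero — the
    boundary case in which the correlation is undefined and untestable.
    """
    vi, vj = g.value(ci, ci), g.value(cj, cj)
    if vi <= 0 or vj <= 0:
        raise ZeroVarianceError(
            f"correlation between {ci.label} and {cj.label} undefined: "
            "a parent genetic variance is zero"
        )
    r = g.value(ci, cj) / math.sqrt(vi * vj)
    return CorrelationEstimate(ci, cj, float(np.clip(r, -1.0, 1.0)))


def lrt(logl_full: float, logl_reduced: float, component_kind: str) -> LRTResult:
    """Likelihood-ratio test: twice the log-likelihood difference.

    ``component_kind`` is ``"variance"`` (the null pins a variance at its
    zero boundary; reference distribution is the 50:50 mixture of a point
    mass at 0 and chi-square with 1 df, so ``p = 0.5 P(chi2_1 >= LRT)`` for
    a positive statistic and 0.5 at exactly 0) or
    ``"covariance_or_correlation"`` (interior null; plain chi-square, 1 df).

    A slightly negative statistic (optimizer noise, within 1e-3) is clipped
    to zero with a warning; anything more negative indicates the "full"
    model was misfit.
    """
    diff = 2.0 * (logl_full - logl_reduced)
    if diff < -1e-3:
        raise ValueError(
            f"reduced model log-likelihood exceeds the full model's by "
            f"{-diff / 2:.3g}: model/data mismatch"
        )
    if diff < 0:
        warnings.warn("negative LRT statistic within tolerance; clipped to 0")
        diff = 0.0
    if component_kind == "variance":
        convention = MIXTURE_HALF_CHI2
        p = 0.5 if diff == 0.0 else 0.5 * float(stats.chi2.sf(diff, df=1))
    elif component_kind == "covariance_or_correlation":
        convention = CHI2_DF1
        p = float(stats.chi2.sf(diff, df=1))
    else:
        raise ValueError(f"unknown component kind {component_kind!r}")
    return LRTResult(statistic=diff, convention=convention, p_value=max(p, 1e-300))


def reverse_score(values) -> np.ndarray:
    """Reverse-score a trait vector (elementwise negation).

    Applied to latency traits so that higher scores mean greater motivation
    to mate (own latency) or greater attractiveness (partner effect on the
    latency).  An involution: applying it twice restores the input.
    """
    return -np.asarray(values, dtype=float)


def psi_matrix(c_id: np.ndarray, g_d: np.ndarray) -> np.ndarray:
    """Genetic-level responsiveness matrix ``Psi = C_ID G_D^{-1}``.

    ``c_id`` holds covariances between indirect-effect channels (rows) and
    the direct genetic effects of the partner traits (columns); ``g_d`` is
    the direct-effect genetic covariance matrix of those partner traits.
    ``Psi[i, j]`` is the expected change in the focal individual's trait i
    per unit partner breeding value for trait j.
    """
    c_id = np.atleast_2d(np.asarray(c_id, dtype=float))
    g_d = np.atleast_2d(np.asarray(g_d, dtype=float))
    if g_d.shape[0] != g_d.shape[1]:
        raise ValueError("G_D must be square")
    if not np.allclose(g_d, g_d.T, atol=1e-10):
        raise ValueError("G_D must be symmetric")
    if c_id.shape[1] != g_d.shape[0]:
        raise ValueError("C_ID columns must match G_D dimension")
    if np.linalg.eigvalsh(g_d).min() <= 1e-12 * max(1.0, np.abs(g_d).max()):
        raise np.linalg.LinAlgError("G_D is singular: Psi is not identified")
    return np.linalg.solve(g_d.T, c_id.T).T
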