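"""Deleteriousness stratification by univariate Gaussian mixture EM.

Each precomputed score (CADD on its phred scale, VIPUR in [0, 1]) is clustered
independently into two Gaussian components with unequal variances, fitted by
expectation-maximization with deterministic quantile initialization (no RNG,
so cutpoints are reproducible). The "high-score" cluster defines a cutpoint —
the smallest observed score whose maximum-a-posteriori component is the high
one — and variants are tiered:

* high on both scores                      -> ``deleterious``
* high on exactly one (the other low or
  unavailable-but-CADD-high)               -> ``possibly_deleterious``
* otherwise                                -> ``benign``

A variant without a structural (VIPUR) score is classified on CADD alone:
high CADD -> possibly deleterious, low CADD -> benign. A missing CADD is an
error — CADD is computable for every variant in scope.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2

from .exact_tests import mann_whitney_exact

__all__ = [
    "MixtureFit",
    "TierCall",
    "EllipseSummary",
    "ScoreGroupComparison",
    "fit_gmm_em",
    "derive_cutpoint",
    "fit_score_model",
    "classify_tier",
    "classify_variants",
    "compare_score_groups",
    "confidence_ellipse",
    "TIERS",
]

TIERS = ("deleterious", "possibly_deleterious", "benign")

# Variances never fall below this multiple of the overall sample variance,
# preventing singular collapse onto a single observation.
VARIANCE_FLOOR_FACTOR = 1e-6


class DegenerateDataError(ValueError):
    """All observations identical — a two-component mixture is meaningless."""


class InsufficientDataError(ValueError):
    """Fewer than 4 finite observations."""


@dataclass
class MixtureFit:
    """A fitted two-component univariate Gaussian mixture (low, high order)."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_likelihood: float
    loglik_path: np.ndarray
    n_iterations: int
    converged: bool
    responsibilities: np.ndarray  # posterior of the HIGH component, per obs
    variance_floor_hit: bool = False
    cutpoint: Optional[float] = None

    def posterior_high(self, x: np.ndarray | float) -> np.ndarray:
        """Posterior probability that ``x`` came from the high component."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        log_h = _log_norm(x, self.means[1], self.variances[1]) + math.log(self.weights[1])
        log_l = _log_norm(x, self.means[0], self.variances[0]) + math.log(self.weights[0])
        m = np.maximum(log_h, log_l)
        return np.exp(log_h - m) / (np.exp(log_h - m) + np.exp(log_l - m))

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "log_likelihood": self.log_likelihood,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "variance_floor_hit": self.variance_floor_hit,
            "cutpoint": self.cutpoint,
        }


@dataclass(frozen=True)
class TierCall:
    variant_id: str
    cadd_flag: str  # high / low / missing
    vipur_flag: str
    tier: str


@dataclass
class EllipseSummary:
    """Normal-theory confidence ellipse of a (CADD, VIPUR) point cloud."""

    group_label: Optional[str]
    mean_vector: np.ndarray
    covariance: np.ndarray
    level: float
    semi_axes: np.ndarray
    orientation: float  # radians, major axis vs CADD axis
    distances: np.ndarray  # per-point Euclidean distance to the group mean
    degenerate: bool = False


@dataclass(frozen=True)
class ScoreGroupComparison:
    group_a: str
    group_b: str
    score_name: str
    p_value: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


def _log_norm(x: np.ndarray, mean: float, var: float) -> np.ndarray:
    return -0.5 * (np.log(2.0 * np.pi * var) + (x - mean) ** 2 / var)


def fit_gmm_em(
    scores: Sequence[float], tol: float = 1e-8, max_iter: int = 500
) -> MixtureFit:
    """Fit a two-component unequal-variance Gaussian mixture by EM.

    Deterministic: component means start at the 25th/75th percentiles of the
    data, both variances at the overall sample variance, weights at 0.5/0.5.
    Iterates until the relative log-likelihood change falls below ``tol``.
    The EM ascent property (non-decreasing log-likelihood) is recorded in
    ``loglik_path`` and is testable per fit.
    """
    x = np.asarray(list(scores), dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 4:
        raise InsufficientDataError(
            f"need >= 4 finite observations, got {x.size}"
        )
    if np.ptp(x) == 0.0:
        raise DegenerateDataError("all observations identical")

    overall_var = float(np.var(x, ddof=1))
    floor = VARIANCE_FLOOR_FACTOR * overall_var

    means = np.percentile(x, [25.0, 75.0]).astype(float)
    if means[0] == means[1]:  # heavy ties: fall back to the data range
        means = np.array([float(x.min()), float(x.max())])
    variances = np.array([overall_var, overall_var])
    weights = np.array([0.5, 0.5])

    loglik_path: list[float] = []
    prev_ll = -np.inf
    converged = False
    floor_hit = False
    n_iter = 0
    resp_high = np.full(x.size, 0.5)

    for n_iter in range(1, max_iter + 1):
        # E-step
        log_comp = np.stack([
            _log_norm(x, means[k], variances[k]) + math.log(weights[k])
            for k in (0, 1)
        ])
        m = log_comp.max(axis=0)
        log_total = m + np.log(np.exp(log_comp - m).sum(axis=0))
        ll = float(log_total.sum())
        loglik_path.append(ll)
        resp = np.exp(log_comp - log_total)  # (2, n)
        resp_high = resp[1]

        if prev_ll > -np.inf:
            rel = abs(ll - prev_ll) / max(1.0, abs(prev_ll))
            if rel < tol:
                converged = True
                break
        prev_ll = ll

        # M-step
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-300)
        weights = nk / x.size
        means = (resp @ x) / nk
        variances = np.array([
            float(resp[k] @ (x - means[k]) ** 2 / nk[k]) for k in (0, 1)
        ])
        if (variances < floor).any():
            floor_hit = True
            variances = np.maximum(variances, floor)

    # canonical (low, high) ordering
    if means[0] > means[1]:
        means = means[::-1].copy()
        variances = variances[::-1].copy()
        weights = weights[::-1].copy()
        resp_high = 1.0 - resp_high

    return MixtureFit(
        weights=weights,
        means=means,
        variances=variances,
        log_likelihood=loglik_path[-1],
        loglik_path=np.asarray(loglik_path),
        n_iterations=n_iter,
        converged=converged,
        responsibilities=resp_high,
        variance_floor_hit=floor_hit,
    )


def derive_cutpoint(fit: MixtureFit, scores: Sequence[float]) -> Optional[float]:
    """Smallest observed score whose MAP assignment is the high component.

    The threshold is anchored to the data ("24 or higher"-style), not to the
    analytic posterior crossing: among observed scores at or above the low
    component mean whose posterior for the high component exceeds 0.5, the
    minimum is returned. Warns if MAP assignment is non-monotone in the score
    over the observed range, or if no observation maps to the high component
    (then the cutpoint is undefined -> None).
    """
    if not fit.converged:
        raise ValueError("cutpoint requires a converged fit")
    x = np.asarray(list(scores), dtype=float)
    x = x[np.isfinite(x)]
    post = fit.posterior_high(x)
    is_high = post > 0.5

    order = np.argsort(x, kind="stable")
    seq = is_high[order]
    if seq.any() and not np.all(np.diff(seq.astype(int)) >= 0):
        warnings.warn(
            "MAP assignment is non-monotone in score over the observed range",
            stacklevel=2,
        )
    candidates = x[is_high & (x >= fit.means[0])]
    if candidates.size == 0:
        warnings.warn("no observation assigned to the high component; "
                      "cutpoint undefined", stacklevel=2)
        return None
    return float(candidates.min())


def fit_score_model(scores: Sequence[float], **kwargs) -> MixtureFit:
    """Convenience: fit the mixture and attach the derived cutpoint."""
    fit = fit_gmm_em(scores, **kwargs)
    fit.cutpoint = derive_cutpoint(fit, scores)
    return fit


def classify_tier(cadd_flag: str, vipur_flag: str) -> str:
    """Tier from per-score high/low/missing flags.

    high+high -> deleterious; a single high (including high CADD with
    missing VIPUR) -> possibly_deleterious; everything else -> benign.
    Missing CADD is an error: CADD is defined for all variants in scope,
    while VIPUR requires a structural model and may be unavailable.
    """
    if cadd_flag == "missing":
        raise ValueError("CADD flag may not be missing")
    if cadd_flag not in ("high", "low") or vipur_flag not in ("high", "low", "missing"):
        raise ValueError(f"bad flags ({cadd_flag!r}, {vipur_flag!r})")
    if cadd_flag == "high" and vipur_flag == "high":
        return "deleterious"
    if cadd_flag == "high" or vipur_flag == "high":
        return "possibly_deleterious"
    return "benign"


def _flag(score: Optional[float], cutpoint: Optional[float]) -> str:
    if score is None:
        return "missing"
    if cutpoint is None:
        return "low"  # no high cluster observed
    return "high" if score >= cutpoint else "low"


def classify_variants(variants, cadd_fit: MixtureFit, vipur_fit: MixtureFit) -> list[TierCall]:
    """Tier every variant from the two fitted score models.

    A score is flagged high iff it is at or above the model's cutpoint
    (boundary inclusive, "or higher").
    """
    for name, fit in (("CADD", cadd_fit), ("VIPUR", vipur_fit)):
        if not fit.converged:
            raise ValueError(f"{name} fit not converged")
        if fit.cutpoint is None:
            raise ValueError(f"{name} cutpoint undefined")
    calls = []
    for v in variants:
        cadd_flag = _flag(v.cadd, cadd_fit.cutpoint)
        vipur_flag = _flag(v.vipur, vipur_fit.cutpoint)
        calls.append(TierCall(
            variant_id=v.variant_id,
            cadd_flag=cadd_flag,
            vipur_flag=vipur_flag,
            tier=classify_tier(cadd_flag, vipur_flag),
        ))
    return calls


def tier_counts(calls: Sequence[TierCall]) -> dict[str, int]:
    counts = {t: 0 for t in TIERS}
    for c in calls:
        counts[c.tier] += 1
    return counts


def compare_score_groups(variants, score_name: str) -> list[ScoreGroupComparison]:
    """Pairwise exact Mann–Whitney comparison of a score across phenotype groups.

    Variants lacking the score are dropped (their count is recorded via the
    group sizes); pairs with an empty group after filtering are skipped with
    a warning.
    """
    attr = score_name.lower()
    if attr not in ("cadd", "vipur"):
        raise ValueError("score_name must be CADD or VIPUR")
    groups: dict[str, list[float]] = {}
    n_dropped = 0
    for v in variants:
        if v.phenotype_label is None:
            continue
        s = getattr(v, attr)
        if s is None:
            n_dropped += 1
            continue
        groups.setdefault(v.phenotype_label, []).append(float(s))
    if n_dropped:
        warnings.warn(
            f"{n_dropped} variants lacked a {score_name} score and were dropped",
            stacklevel=2,
        )
    if len(groups) < 2:
        raise ValueError("need >= 2 phenotype groups with scored variants")

    out = []
    for ga, gb in combinations(sorted(groups), 2):
        a, b = groups[ga], groups[gb]
        if not a or not b:
            warnings.warn(f"group pair ({ga}, {gb}) skipped: empty after filtering",
                          stacklevel=2)
            continue
        res = mann_whitney_exact(a, b)
        out.append(ScoreGroupComparison(
            group_a=ga, group_b=gb, score_name=score_name,
            p_value=res.p_value,
            mean_a=float(np.mean(a)), mean_b=float(np.mean(b)),
            n_a=len(a), n_b=len(b),
        ))
    return out


def confidence_ellipse(points, level: float = 0.95,
                       group_label: Optional[str] = None) -> EllipseSummary:
    """Normal-theory confidence ellipse of a bivariate score cloud.

    Sample mean and covariance (n-1 denominator); semi-axes are
    ``sqrt(eigenvalue * chi2.ppf(level, df=2))`` along the covariance
    eigenvectors. Rank-deficient covariance (e.g. collinear points) yields a
    degenerate ellipse with a zero semi-axis and a warning.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 bivariate points")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    mean = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    degenerate = bool(evals.min() <= 1e-12 * max(evals.max(), 1.0))
    if degenerate:
        warnings.warn("degenerate ellipse: rank-deficient covariance", stacklevel=2)
    q = chi2.ppf(level, df=2)
    semi = np.sqrt(evals[::-1] * q)  # major first
    major_vec = evecs[:, int(np.argmax(evals))]
    orientation = float(np.arctan2(major_vec[1], major_vec[0]))
    distances = np.linalg.norm(pts - mean, axis=1)
    return EllipseSummary(
        group_label=group_label, mean_vector=mean, covariance=cov, level=level,
        semi_axes=semi, orientation=orientation, distances=distances,
        degenerate=degenerate,
    )
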