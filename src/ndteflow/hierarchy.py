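"""Functional hierarchy from directed flow: G_in / G_out / G_tot and the FF hierarchy.

The hierarchy profile of a flow matrix is the per-region incoming flow
``G_in(i) = sum_j C[i, j]`` (row sums — rows are targets), the outgoing flow
``G_out(i) = sum_j C[j, i]`` (column sums), and their total.  The
feedforward (FF) hierarchy assigns each region a scalar ``H_i`` such that
the fraction of feedforward flow between two regions,
``C[i, j] / (C[i, j] + C[j, i])``, is the logistic function of ``H_i - H_j``
— a Bradley–Terry-style paired-comparison model fitted as a binomial GLM,
with one region pinned to zero as the reference.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import stats
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .ndte import FlowMatrix


@dataclass
class HierarchyProfile:
    """Per-region incoming/outgoing/total directed flow."""

    g_in: np.ndarray
    g_out: np.ndarray
    g_tot: np.ndarray
    region_labels: list[str]


@dataclass
class FFHierarchy:
    """Fitted feedforward hierarchy: values, model-implied fractions, deviance."""

    h: np.ndarray
    fitted_fractions: np.ndarray
    deviance: float
    region_labels: list[str]
    reference: int


def flow_profiles(flow: FlowMatrix) -> HierarchyProfile:
    """G_in (row sums), G_out (column sums) and G_tot of a flow matrix."""
    v = flow.values
    g_in = v.sum(axis=1)
    g_out = v.sum(axis=0)
    return HierarchyProfile(
        g_in=g_in, g_out=g_out, g_tot=g_in + g_out, region_labels=list(flow.region_labels)
    )


def correlate_with_structure(
    profile_component: np.ndarray, covariate: np.ndarray
) -> tuple[float, tuple[float, float], float]:
    """Pearson correlation of a hierarchy component with a structural covariate.

    Returns ``(r, (lo, hi), p)`` with a Fisher-z 95% confidence interval and a
    two-sided p-value.  Typical use: G_tot against a per-region myelination
    proxy (T1w/T2w ratio).
    """
    a = np.asarray(profile_component, dtype=float)
    b = np.asarray(covariate, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 4:
        raise ValueError("inputs must be equal-length 1-D arrays of length >= 4")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("inputs must be finite")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for a zero-variance input")
    res = stats.pearsonr(a, b)
    ci = res.confidence_interval(0.95)
    return float(res.statistic), (float(ci.low), float(ci.high)), float(res.pvalue)


class FFHierarchyGLM(BaseEstimator):
    """Feedforward-fraction hierarchy via a weighted binomial GLM.

    For every unordered pair ``(i, j)`` with positive total flow the response
    is the feedforward fraction ``C[i, j] / (C[i, j] + C[j, i])`` and the
    linear predictor is ``H_i - H_j`` through a logit link.  Pairs are
    weighted by their total bidirectional flow (binomial totals) so strong
    pairs dominate; set ``weighted=False`` for equal weights.  The reference
    region's value is fixed at 0 (the model is identified only up to an
    additive constant).

    Attributes (after ``fit``): ``h_``, ``fitted_fractions_``, ``deviance_``.
    """

    def __init__(self, reference: int | None = None, weighted: bool = True, weight_scale: float = 1000.0):
        self.reference = reference
        self.weighted = weighted
        self.weight_scale = weight_scale

    def fit(self, flow: FlowMatrix, y=None) -> "FFHierarchyGLM":
        v = flow.values
        n = v.shape[0]
        ref = (n - 1) if self.reference is None else int(self.reference)
        if not (0 <= ref < n):
            raise ValueError("reference region out of bounds")
        rows_i, rows_j, frac, tot = [], [], [], []
        dropped = 0
        for i in range(n):
            for j in range(i + 1, n):
                total = v[i, j] + v[j, i]
                if total <= 0:
                    dropped += 1
                    continue
                rows_i.append(i)
                rows_j.append(j)
                frac.append(v[i, j] / total)
                tot.append(total)
        if dropped:
            warnings.warn(f"dropped {dropped} zero-total pairs from the FF GLM", stacklevel=2)
        if not frac:
            raise ValueError("no pairs with positive total flow")
        # design: +1 on H_i, -1 on H_j; reference column removed (pinned at 0)
        design = np.zeros((len(frac), n))
        design[np.arange(len(frac)), rows_i] = 1.0
        design[np.arange(len(frac)), rows_j] = -1.0
        design = np.delete(design, ref, axis=1)
        weights = (
            np.asarray(tot) * self.weight_scale if self.weighted else np.ones(len(frac))
        )
        model = sm.GLM(
            np.asarray(frac),
            design,
            family=sm.families.Binomial(),
            freq_weights=weights,
        )
        with warnings.catch_warnings():
            # fractional responses make statsmodels warn about non-integer counts
            warnings.simplefilter("ignore")
            result = model.fit(maxiter=200)
        if not result.converged:
            raise RuntimeError(
                f"FF hierarchy GLM did not converge after {result.fit_history['iteration']} "
                "IRLS iterations"
            )
        h = np.insert(result.params, ref, 0.0)
        fitted = np.full((n, n), 0.5)
        diff = h[:, None] - h[None, :]
        fitted = 1.0 / (1.0 + np.exp(-diff))
        np.fill_diagonal(fitted, 0.0)
        self.h_ = h
        self.fitted_fractions_ = fitted
        self.deviance_ = float(result.deviance)
        self.reference_ = ref
        self.labels_ = list(flow.region_labels)
        return self


def ff_hierarchy(flow: FlowMatrix, reference: int | None = None, weighted: bool = True) -> FFHierarchy:
    """Functional wrapper over :class:`FFHierarchyGLM`."""
    est = FFHierarchyGLM(reference=reference, weighted=weighted).fit(flow)
    return FFHierarchy(
        h=est.h_,
        fitted_fractions=est.fitted_fractions_,
        deviance=est.deviance_,
        region_labels=est.labels_,
        reference=est.reference_,
    )
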