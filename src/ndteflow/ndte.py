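"""Normalized directed transfer entropy (NDTE) under the Gaussian approximation.

For a source series ``X`` and target ``Y``, transfer entropy is the
conditional mutual information ``I(Y_{i+1}; X^i | Y^i)`` — what the past
window of the source adds to the prediction of the target's next sample
beyond the target's own past.  Under the Gaussian approximation every
entropy is a covariance log-determinant, so the whole quantity reduces to
second-order statistics.  The normalized flow

    F_XY = I(Y_{i+1}; X^i | Y^i) / I(Y_{i+1}; X^i, Y^i)

divides by the total mutual information both pasts carry about the target's
future, yielding a unit-interval measure that can be summed and compared
across pairs.  The chain rule

    I(Y_{i+1}; X^i, Y^i) = I(Y_{i+1}; Y^i) + I(Y_{i+1}; X^i | Y^i)

is an exact algebraic identity of the entropy decomposition used here.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .signals import EmbeddingSpec, TimeSeriesPanel, embed_lags

_LN_2PI_E = float(np.log(2.0 * np.pi * np.e))


class SingularCovarianceError(ValueError):
    """A covariance block has a non-positive determinant even after ridging."""


class UndefinedFlowError(ValueError):
    """Total predictive information is ~0; the normalized flow is undefined."""


@dataclass(frozen=True)
class InfoDecomposition:
    """Mutual-information decomposition of one ordered pair (all in nats).

    ``i_joint = i_self + i_cond`` holds exactly (chain rule); ``i_cond`` is
    the (Gaussian) transfer entropy and ``i_cond / i_joint`` the NDTE flow.
    """

    i_cond: float
    i_self: float
    i_joint: float
    entropies: dict[str, float]


@dataclass
class FlowMatrix:
    """Pairwise NDTE flow: entry ``(i, j)`` is flow from source ``j`` to target ``i``.

    Rows are targets, columns are sources, diagonal is zero, all entries in
    ``[0, 1]``.
    """

    values: np.ndarray
    region_labels: list[str]
    embedding: EmbeddingSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("flow matrix must be square")
        if len(self.region_labels) != n:
            raise ValueError("label count does not match matrix size")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("flow matrix diagonal must be zero")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("flow values must lie in [0, 1]")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def _logdet(cov: np.ndarray, what: str) -> float:
    """Stable log-determinant of a covariance block; ridge once on failure."""
    sign, ld = np.linalg.slogdet(cov)
    if sign > 0 and np.isfinite(ld):
        return float(ld)
    d = cov.shape[0]
    eps = 1e-8 * np.trace(cov) / d
    warnings.warn(f"ridging near-singular covariance block {what}", stacklevel=3)
    sign, ld = np.linalg.slogdet(cov + eps * np.eye(d))
    if sign > 0 and np.isfinite(ld):
        return float(ld)
    raise SingularCovarianceError(f"covariance block {what} is singular")


def gaussian_entropy(cov: np.ndarray) -> float:
    """Differential entropy (nats) of a Gaussian with covariance ``cov``.

    ``H = (d/2) ln(2 pi e) + (1/2) ln det(cov)``.
    """
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    d = cov.shape[0]
    if cov.shape != (d, d):
        raise ValueError("covariance must be square")
    if not np.allclose(cov, cov.T, atol=1e-8):
        raise ValueError("covariance must be symmetric (tolerance 1e-8)")
    return 0.5 * d * _LN_2PI_E + 0.5 * _logdet(cov, "input")


def _pair_terms(x: np.ndarray, y: np.ndarray, T: int) -> tuple[float, float, float, dict[str, float]]:
    """Core Gaussian computation shared by the scalar and matrix paths.

    Assembles Z = [future_target | past_target (T cols) | past_source (T cols)]
    and reads every needed entropy off submatrices of one (2T+1) covariance.
    """
    n_rows = x.size - T
    z = np.empty((n_rows, 2 * T + 1))
    z[:, 0] = y[T:]
    z[:, 1 : T + 1] = embed_lags(y, T)
    z[:, T + 1 :] = embed_lags(x, T)
    zc = z - z.mean(axis=0)
    cov = (zc.T @ zc) / (n_rows - 1)

    h_ypast = 0.5 * T * _LN_2PI_E + 0.5 * _logdet(cov[1 : T + 1, 1 : T + 1], "Sigma(Y^i)")
    h_fy = 0.5 * (T + 1) * _LN_2PI_E + 0.5 * _logdet(cov[: T + 1, : T + 1], "Sigma(Y_{i+1},Y^i)")
    h_xy = 0.5 * 2 * T * _LN_2PI_E + 0.5 * _logdet(cov[1:, 1:], "Sigma(X^i,Y^i)")
    h_all = 0.5 * (2 * T + 1) * _LN_2PI_E + 0.5 * _logdet(cov, "Sigma(Y_{i+1},Y^i,X^i)")
    h_f = 0.5 * _LN_2PI_E + 0.5 * float(np.log(cov[0, 0]))

    i_cond = (h_fy - h_ypast) - (h_all - h_xy)
    i_self = h_f + h_ypast - h_fy
    i_joint = h_f + h_xy - h_all
    entropies = {
        "H(Y^i)": h_ypast,
        "H(Y_{i+1},Y^i)": h_fy,
        "H(X^i,Y^i)": h_xy,
        "H(Y_{i+1},Y^i,X^i)": h_all,
    }
    return i_cond, i_self, i_joint, entropies


def info_decomposition(x: np.ndarray, y: np.ndarray, spec: EmbeddingSpec) -> InfoDecomposition:
    """All mutual-information terms for the ordered pair source ``x`` -> target ``y``.

    Sample covariances use the 1/(rows-1) convention; series should be
    standardized (mutual information is scale-invariant, but conditioning of
    the determinants is not).  Warns when the number of embedded rows is
    small relative to the joint dimension.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n_rows = x.size - spec.T
    if n_rows < 2:
        raise ValueError("series too short for the embedding")
    if n_rows < 10 * (2 * spec.T + 1):
        warnings.warn(
            f"only {n_rows} embedded samples for a {2 * spec.T + 1}-dimensional "
            "covariance; estimates will be noisy",
            stacklevel=2,
        )
    i_cond, i_self, i_joint, entropies = _pair_terms(x, y, spec.T)
    assert abs(i_joint - i_self - i_cond) < 1e-10, "chain-rule identity violated"
    return InfoDecomposition(i_cond=i_cond, i_self=i_self, i_joint=i_joint, entropies=entropies)


def ndte_pair(x: np.ndarray, y: np.ndarray, spec: EmbeddingSpec, _tol: float = 1e-12) -> float:
    """NDTE flow F_XY from source ``x`` to target ``y`` (unit interval)."""
    dec = info_decomposition(x, y, spec)
    if dec.i_joint <= _tol:
        raise UndefinedFlowError(
            f"total predictive information {dec.i_joint:.3g} nats is not positive"
        )
    return float(np.clip(dec.i_cond / dec.i_joint, 0.0, 1.0))


def _ndte_pair_fast(x: np.ndarray, y: np.ndarray, T: int) -> float:
    """Unchecked fast path used by the matrix/surrogate loops."""
    i_cond, _, i_joint, _ = _pair_terms(x, y, T)
    if i_joint <= 1e-12:
        raise UndefinedFlowError("total predictive information is not positive")
    return float(np.clip(i_cond / i_joint, 0.0, 1.0))


def ndte_matrix(panel: TimeSeriesPanel, spec: EmbeddingSpec, standardize: bool = True) -> FlowMatrix:
    """Pairwise NDTE flow matrix over all ordered region pairs.

    Entry ``(i, j)`` is the flow from source region ``j`` to target region
    ``i``; the diagonal (self-flow) is defined as zero.
    """
    work = panel.standardized() if standardize else panel
    if work.n_timepoints <= spec.T + 1:
        raise ValueError("panel too short for the embedding window")
    n = work.n_regions
    values = np.zeros((n, n))
    for target in range(n):
        for source in range(n):
            if source == target:
                continue
            try:
                values[target, source] = _ndte_pair_fast(
                    work.data[source], work.data[target], spec.T
                )
            except (SingularCovarianceError, UndefinedFlowError) as exc:
                raise type(exc)(
                    f"pair source={work.region_labels[source]} "
                    f"target={work.region_labels[target]}: {exc}"
                ) from exc
    return FlowMatrix(values=values, region_labels=list(work.region_labels), embedding=spec)
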