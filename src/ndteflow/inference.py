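"""Significance of directed flow: circular-shift surrogates, Stouffer pooling, FDR.

Each ordered region pair is tested per subject against circular time-shifted
surrogates: both series are rotated by independent random offsets, which
preserves every marginal property (amplitude distribution, autocorrelation)
while destroying cross-dependence, exactly the null an NDTE value should be
compared against.  The per-subject p-value is the upper-tail area of a
Gaussian-kernel density fitted to the surrogate flows.  Subjects are pooled
per pair with Stouffer's method, S = sum_i Phi^{-1}(p_i), which is N(0, m)
under the null, and the resulting group p-values are corrected over all
ordered pairs with the Benjamini–Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .ndte import FlowMatrix, _ndte_pair_fast, ndte_matrix
from .signals import EmbeddingSpec, TimeSeriesPanel


@dataclass(frozen=True)
class SurrogateSpec:
    """Circular-shift surrogate settings.

    Shifts are drawn uniformly from ``[low * n, high * n]`` so a surrogate is
    never a near-identity rotation of the original series.
    """

    n_surrogates: int = 100
    shift_fraction_low: float = 0.05
    shift_fraction_high: float = 0.95
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_surrogates < 1:
            raise ValueError("need at least one surrogate")
        if not (0.0 < self.shift_fraction_low < self.shift_fraction_high < 1.0):
            raise ValueError("shift fractions must satisfy 0 < low < high < 1")


@dataclass
class GroupSignificance:
    """Group-level significance summary for every ordered region pair."""

    subject_pvalues: np.ndarray  # (N, N, m)
    stouffer: np.ndarray  # (N, N)
    group_pvalues: np.ndarray  # (N, N)
    mask: np.ndarray  # (N, N) binary
    q_level: float
    region_labels: list[str] = field(default_factory=list)


def circular_shift(series: np.ndarray, shift: int) -> np.ndarray:
    """Move the first ``shift`` values of ``series`` to its end."""
    series = np.asarray(series)
    if not (0 <= shift < series.size):
        raise IndexError(f"shift {shift} out of range [0, {series.size})")
    return np.concatenate([series[shift:], series[:shift]])


def _kde_tail_pvalue(observed: float, surrogates: np.ndarray, p_floor: float) -> float:
    """Upper-tail area of a Gaussian KDE over the surrogate flows.

    The KDE is a mixture of normals centred on the surrogate values with
    Silverman's bandwidth, so the tail area has the closed form
    ``mean_s Phi_bar((observed - F_s) / h)``.
    """
    m = surrogates.size
    sd = float(surrogates.std(ddof=1)) if m > 1 else 0.0
    if sd == 0.0:
        import warnings

        warnings.warn("degenerate surrogate distribution (zero variance)", stacklevel=3)
        return p_floor if observed > surrogates.max() else 1.0
    h = sd * (3.0 * m / 4.0) ** (-0.2)  # Silverman, univariate
    p = float(np.mean(stats.norm.sf((observed - surrogates) / h)))
    return float(np.clip(p, p_floor, 1.0))


def _pair_pvalue_seeded(
    x: np.ndarray,
    y: np.ndarray,
    T: int,
    surr: SurrogateSpec,
    rng: np.random.Generator,
    p_floor: float = 1e-6,
) -> tuple[float, float]:
    """(observed flow, surrogate p-value) for one ordered pair with a given RNG."""
    observed = _ndte_pair_fast(x, y, T)
    n = x.size
    lo = int(np.ceil(surr.shift_fraction_low * n))
    hi = int(np.floor(surr.shift_fraction_high * n))
    shifts = rng.integers(lo, hi + 1, size=(surr.n_surrogates, 2))
    vals = np.empty(surr.n_surrogates)
    for s, (c, d) in enumerate(shifts):
        vals[s] = _ndte_pair_fast(circular_shift(x, int(c)), circular_shift(y, int(d)), T)
    return observed, _kde_tail_pvalue(observed, vals, p_floor)


def pair_pvalue(
    x: np.ndarray,
    y: np.ndarray,
    spec: EmbeddingSpec,
    surr: SurrogateSpec,
    p_floor: float = 1e-6,
) -> float:
    """Surrogate p-value for the observed flow from source ``x`` to target ``y``."""
    rng = np.random.default_rng(surr.rng_seed)
    _, p = _pair_pvalue_seeded(
        np.asarray(x, float), np.asarray(y, float), spec.T, surr, rng, p_floor
    )
    return p


def stouffer_combine(pvalues: np.ndarray, clamp: float = 1e-15) -> tuple[float, float]:
    """Stouffer pooling of per-subject p-values.

    Returns ``(S, group_p)`` where ``S = sum_i Phi^{-1}(p_i)`` and the group
    p-value is the left tail ``Phi(S / sqrt(m))`` — small per-subject
    p-values drive ``S`` negative, so small group p means consistent
    significance.  (The common convention that transforms ``1 - p_i`` is the
    mirror image; only the tail side differs.)
    """
    p = np.clip(np.asarray(pvalues, dtype=float), clamp, 1.0 - clamp)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("pvalues must be a non-empty 1-D array")
    s = float(np.sum(stats.norm.ppf(p)))
    return s, float(stats.norm.cdf(s / np.sqrt(p.size)))


def bh_fdr(pvalues: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg mask over all off-diagonal entries of a p-value matrix.

    Returns a binary matrix with 1 where the pair is significant at FDR
    level ``q``; the diagonal is always 0.
    """
    p = np.asarray(pvalues, dtype=float)
    if not (0.0 < q < 1.0):
        raise ValueError("q must be in (0, 1)")
    n = p.shape[0]
    off = ~np.eye(n, dtype=bool)
    flat = p[off]
    if np.any((flat <= 0) | (flat > 1)):
        raise ValueError("off-diagonal p-values must lie in (0, 1]")
    reject, *_ = multipletests(flat, alpha=q, method="fdr_bh")
    mask = np.zeros((n, n), dtype=int)
    mask[off] = reject.astype(int)
    return mask


class GroupNDTE(BaseEstimator):
    """Group-level NDTE flow with surrogate-based edge significance.

    Fits per-subject flow matrices and surrogate p-values, pools subjects
    with Stouffer's method, corrects over all ordered pairs with BH-FDR, and
    averages subject flows into the group matrix ``C_All``.

    Parameters
    ----------
    T : past-window length (samples).
    n_surrogates : circular-shift surrogates per pair per subject.
    q : FDR level for the significance mask.
    mask_mean : zero non-significant entries of the group mean (the raw mean
        is always kept in ``raw_mean_``).
    seed : master seed; per-subject-per-pair streams are split from it.

    Attributes (after ``fit``)
    ----------
    flow_matrix_ : FlowMatrix, group mean (masked when ``mask_mean``).
    raw_mean_ : ndarray, unmasked mean of subject flows.
    subject_flows_ : ndarray (m, N, N).
    significance_ : GroupSignificance.
    """

    def __init__(
        self,
        T: int = 10,
        n_surrogates: int = 100,
        q: float = 0.05,
        shift_fraction_low: float = 0.05,
        shift_fraction_high: float = 0.95,
        mask_mean: bool = True,
        p_floor: float = 1e-6,
        seed: int = 0,
    ):
        self.T = T
        self.n_surrogates = n_surrogates
        self.q = q
        self.shift_fraction_low = shift_fraction_low
        self.shift_fraction_high = shift_fraction_high
        self.mask_mean = mask_mean
        self.p_floor = p_floor
        self.seed = seed

    def fit(self, panels: list[TimeSeriesPanel], y=None) -> "GroupNDTE":
        if not panels:
            raise ValueError("need at least one panel")
        labels = list(panels[0].region_labels)
        n = panels[0].n_regions
        for p in panels[1:]:
            if p.region_labels != labels:
                raise ValueError(
                    f"subject {p.subject_id!r} regions do not match the first subject"
                )
        m = len(panels)
        spec = EmbeddingSpec(T=self.T)
        surr = SurrogateSpec(
            n_surrogates=self.n_surrogates,
            shift_fraction_low=self.shift_fraction_low,
            shift_fraction_high=self.shift_fraction_high,
            rng_seed=self.seed,
        )
        flows = np.zeros((m, n, n))
        pvals = np.ones((n, n, m))
        # one independent child stream per (subject, ordered pair)
        streams = np.random.SeedSequence(self.seed).spawn(m)
        for s_idx, panel in enumerate(panels):
            work = panel.standardized()
            pair_streams = streams[s_idx].spawn(n * n)
            for target in range(n):
                for source in range(n):
                    if source == target:
                        continue
                    rng = np.random.default_rng(pair_streams[target * n + source])
                    obs, p = _pair_pvalue_seeded(
                        work.data[source], work.data[target], self.T, surr, rng, self.p_floor
                    )
                    flows[s_idx, target, source] = obs
                    pvals[target, source, s_idx] = p
        stouffer = np.zeros((n, n))
        group_p = np.ones((n, n))
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                stouffer[i, j], group_p[i, j] = stouffer_combine(pvals[i, j])
        mask = bh_fdr(group_p, self.q)
        raw_mean = flows.mean(axis=0)
        np.fill_diagonal(raw_mean, 0.0)
        mean = raw_mean * mask if self.mask_mean else raw_mean
        self.subject_flows_ = flows
        self.raw_mean_ = raw_mean
        self.flow_matrix_ = FlowMatrix(values=mean, region_labels=labels, embedding=spec)
        self.significance_ = GroupSignificance(
            subject_pvalues=pvals,
            stouffer=stouffer,
            group_pvalues=group_p,
            mask=mask,
            q_level=self.q,
            region_labels=labels,
        )
        return self


def group_ndte(
    panels: list[TimeSeriesPanel],
    spec: EmbeddingSpec,
    surr: SurrogateSpec,
    q: float = 0.05,
    mask_mean: bool = True,
) -> tuple[FlowMatrix, GroupSignificance]:
    """Functional wrapper over :class:`GroupNDTE`."""
    est = GroupNDTE(
        T=spec.T,
        n_surrogates=surr.n_surrogates,
        q=q,
        shift_fraction_low=surr.shift_fraction_low,
        shift_fraction_high=surr.shift_fraction_high,
        mask_mean=mask_mean,
        seed=surr.rng_seed,
    ).fit(panels)
    return est.flow_matrix_, est.significance_


def subject_flow(panel: TimeSeriesPanel, spec: EmbeddingSpec) -> FlowMatrix:
    """Single-subject flow matrix without significance testing."""
    return ndte_matrix(panel, spec)
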