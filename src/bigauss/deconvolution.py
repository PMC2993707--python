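"""EM-like deconvolution of partially overlapping peaks.

Overlapping peaks sharing an m/z value are resolved by fitting a bi-Gaussian
mixture.  Unlike textbook EM, the M-step re-uses the moment-based single-peak
estimators rather than maximum likelihood, and an extra pruning step removes
components that explain too small a share of the fitted signal — a guard
against noise-induced spurious components.

The algorithm:

1. Smooth the trace with a Gaussian kernel, split the points into groups at
   the smoother's valleys, and fit one component per group (summit seeded at
   the group's smoother peak).
2. Iterate until convergence:
   2.1  compute each component's fitted values z_ij at every time point;
   2.2  compute each component's share Q_j = sum_i z_ij / sum_jk z_ik and
        drop components below a share threshold;
   2.3  split each observation among the surviving components in proportion
        to their fitted values (responsibilities q_ij = z_ij / sum_k z_ik)
        and re-fit every component to its share (t_i, x_i * q_ij) with the
        full single-peak procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import BiGaussianPeak, evaluate_bigaussian
from .single_peak import (
    InsufficientDataError,
    IonTrace,
    OneSidedPeakError,
    UndefinedSplitError,
    fit_single_peak,
)

__all__ = [
    "SmootherResult",
    "MixtureFitState",
    "kernel_smooth",
    "initialize_components",
    "em_iterate",
]

# EM loop defaults; the threshold removes components explaining < 5% of the
# fitted mass ("smaller than a threshold" pruning).
DEFAULT_SHARE_THRESHOLD = 0.05
DEFAULT_MAX_ITER = 100
DEFAULT_TOL = 1e-4
_REL_EPS = 1e-10
_PATIENCE = 5  # iterations without RSS improvement before stopping


@dataclass(frozen=True)
class SmootherResult:
    """A kernel-smoothed trace with its interior extrema."""

    bandwidth: float
    smoothed_values: np.ndarray
    peak_indices: np.ndarray
    valley_indices: np.ndarray

    def peak_times(self, trace: IonTrace) -> np.ndarray:
        return trace.times[self.peak_indices]

    def valley_times(self, trace: IonTrace) -> np.ndarray:
        return trace.times[self.valley_indices]


@dataclass
class MixtureFitState:
    """Mixture parameters plus the bookkeeping matrices of one EM pass."""

    components: list[BiGaussianPeak]
    fitted_matrix: np.ndarray = field(default=None)  # z_ij, shape (n, J)
    responsibilities: np.ndarray = field(default=None)  # q_ij
    shares: np.ndarray = field(default=None)  # Q_j
    n_iter: int = 0
    converged: bool = False
    n_pruned: int = 0


def _run_extrema(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Peak and valley indices of a sequence, collapsing plateaus to their
    centre point.  Valleys are interior only; a boundary run higher than its
    single neighbour counts as a peak (a summit at the edge of the window)."""
    n = y.size
    # snap to 12 significant digits so float jitter cannot split a plateau
    scale = np.max(np.abs(y))
    if scale > 0:
        y = np.round(y / scale, 12)
    # run-length encode equal neighbours
    starts = np.flatnonzero(np.r_[True, y[1:] != y[:-1]])
    ends = np.r_[starts[1:], n]  # exclusive
    vals = y[starts]
    peaks, valleys = [], []
    for k in range(starts.size):
        centre = (starts[k] + ends[k] - 1) // 2
        left_higher = k > 0 and vals[k - 1] > vals[k]
        right_higher = k < starts.size - 1 and vals[k + 1] > vals[k]
        left_lower = k > 0 and vals[k - 1] < vals[k]
        right_lower = k < starts.size - 1 and vals[k + 1] < vals[k]
        if k == 0 and k == starts.size - 1:
            peaks.append(centre)  # constant trace: one peak, no valleys
        elif k == 0:
            if right_lower:
                peaks.append(centre)
        elif k == starts.size - 1:
            if left_lower:
                peaks.append(centre)
        else:
            if left_lower and right_lower:
                peaks.append(centre)
            elif left_higher and right_higher:
                valleys.append(centre)
    return np.asarray(peaks, dtype=int), np.asarray(valleys, dtype=int)


def kernel_smooth(trace: IonTrace, bandwidth: float) -> SmootherResult:
    """Nadaraya-Watson smoother with a Gaussian kernel of SD ``bandwidth``,
    evaluated at the observed time points, plus its peaks and valleys.

    Zero intensities mark missing observations (dropout) and are excluded
    from the kernel average: a hole in the trace would otherwise drag the
    smooth toward zero and manufacture spurious valleys.
    """
    if not bandwidth > 0:
        raise ValueError("bandwidth must be > 0")
    t, x = trace.times, trace.intensities
    support = x > 0 if np.any(x > 0) else np.ones(t.size, bool)
    d = (t[:, None] - t[None, support]) / bandwidth
    K = np.exp(-0.5 * d * d)
    smoothed = (K @ x[support]) / K.sum(axis=1)
    peaks, valleys = _run_extrema(smoothed)
    return SmootherResult(
        bandwidth=float(bandwidth),
        smoothed_values=smoothed,
        peak_indices=peaks,
        valley_indices=valleys,
    )


def initialize_components(
    trace: IonTrace, smoother: SmootherResult, symmetric: bool = False
) -> list[BiGaussianPeak]:
    """One initial component per valley-delimited group of points.

    Each group's summit is seeded at its smoother peak; sigmas and delta are
    then estimated from the group's points alone.  Groups with fewer than 3
    positive-intensity points cannot support a two-sided moment estimate and
    are merged into the neighbouring group across their higher valley.
    """
    if smoother.peak_indices.size == 0:
        raise InsufficientDataError("smoother found no peak")
    n = trace.n
    # groups as [start, stop) index pairs, split after each valley point
    bounds = [0] + [int(v) + 1 for v in smoother.valley_indices] + [n]
    groups = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
    groups = [g for g in groups if g[1] > g[0]]

    def npos(g):
        return int(np.count_nonzero(trace.intensities[g[0] : g[1]] > 0))

    # merge undersized groups into the neighbour across the higher valley
    while len(groups) > 1:
        sizes = [npos(g) for g in groups]
        k = int(np.argmin(sizes))
        if sizes[k] >= 3:
            break
        sm = smoother.smoothed_values
        left_valley = sm[groups[k][0] - 1] if k > 0 else -np.inf
        right_valley = sm[groups[k][1] - 1] if k < len(groups) - 1 else -np.inf
        if left_valley >= right_valley:
            groups[k - 1] = (groups[k - 1][0], groups[k][1])
        else:
            groups[k + 1] = (groups[k][0], groups[k + 1][1])
        del groups[k]

    components: list[BiGaussianPeak] = []
    for start, stop in groups:
        sub = IonTrace(trace.times[start:stop], trace.intensities[start:stop])
        in_group = (smoother.peak_indices >= start) & (smoother.peak_indices < stop)
        if in_group.any():
            pk = smoother.peak_indices[in_group]
            alpha0 = float(
                trace.times[pk[np.argmax(smoother.smoothed_values[pk])]]
            )
        else:
            seg = smoother.smoothed_values[start:stop]
            alpha0 = float(trace.times[start + int(np.argmax(seg))])
        components.append(fit_single_peak(sub, alpha_hat=alpha0, symmetric=symmetric))
    return components


def _fitted_matrix(trace: IonTrace, components: list[BiGaussianPeak]) -> np.ndarray:
    return np.column_stack(
        [evaluate_bigaussian(c, trace.times) for c in components]
    )


def _max_rel_change(old: list[BiGaussianPeak], new: list[BiGaussianPeak]) -> float:
    worst = 0.0
    for o, c in zip(old, new):
        for a, b in zip(
            (o.alpha, o.sigma1, o.sigma2, o.delta),
            (c.alpha, c.sigma1, c.sigma2, c.delta),
        ):
            worst = max(worst, abs(b - a) / (abs(a) + _REL_EPS))
    return worst


def em_iterate(
    trace: IonTrace,
    state: MixtureFitState,
    share_threshold: float = DEFAULT_SHARE_THRESHOLD,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    symmetric: bool = False,
) -> MixtureFitState:
    """Run the prune / redistribute / re-fit loop to convergence.

    Convergence is declared when the largest relative change of any parameter
    of any component falls below ``tol``.  A point where every component's
    fitted value underflows to zero is left unassigned for that iteration
    (its responsibilities are set to 0).  If pruning removes every component
    the fit falls back to a single peak on the full trace.
    """
    if not (0 <= share_threshold < 0.5):
        raise ValueError("share_threshold must lie in [0, 0.5)")
    if not tol > 0:
        raise ValueError("tol must be > 0")
    components = list(state.components)
    if not components:
        raise ValueError("state must hold at least one component")

    x = trace.intensities
    observed = x > 0
    n_pruned = 0
    n_iter = 0
    converged = False
    Z = _fitted_matrix(trace, components)
    # The moment-based M-step is not a likelihood ascent, so the loop can
    # oscillate on noisy traces; keep the best-fitting iterate (RSS over the
    # observed points) and stop when it stops improving.
    best_rss = np.inf
    best_components = components
    stall = 0
    for n_iter in range(1, max_iter + 1):
        # (2.2) shares and pruning
        col = Z.sum(axis=0)
        total = col.sum()
        if total <= 0:
            components = [fit_single_peak(trace, symmetric=symmetric)]
            Z = _fitted_matrix(trace, components)
            col = Z.sum(axis=0)
            total = col.sum()
        Q = col / total
        keep = Q >= share_threshold
        if not keep.all():
            n_pruned += int(np.count_nonzero(~keep))
            if not keep.any():
                components = [fit_single_peak(trace, symmetric=symmetric)]
                Z = _fitted_matrix(trace, components)
                Q = Z.sum(axis=0) / Z.sum()
            else:
                components = [c for c, k in zip(components, keep) if k]
                Z = Z[:, keep]
                Q = Q[keep] / Q[keep].sum()
        # (2.3) responsibilities from the survivors, then re-fit
        row = Z.sum(axis=1)
        q = np.divide(Z, row[:, None], out=np.zeros_like(Z), where=row[:, None] > 0)
        new_components = []
        for j, comp in enumerate(components):
            try:
                new_components.append(
                    fit_single_peak(
                        trace.with_intensities(x * q[:, j]), symmetric=symmetric
                    )
                )
            except (InsufficientDataError, UndefinedSplitError, OneSidedPeakError):
                new_components.append(comp)  # starved component; pruning decides
        change = _max_rel_change(components, new_components)
        components = new_components
        Z = _fitted_matrix(trace, components)
        rss = float(np.sum((x[observed] - Z.sum(axis=1)[observed]) ** 2))
        if rss < best_rss * (1.0 - 1e-9):
            best_rss = rss
            best_components = components
            stall = 0
        else:
            stall += 1
        if change < tol:
            converged = True
            break
        if stall >= _PATIENCE:
            break

    if not converged or float(
        np.sum((x[observed] - Z.sum(axis=1)[observed]) ** 2)
    ) > best_rss:
        components = best_components
        Z = _fitted_matrix(trace, components)
    row = Z.sum(axis=1)
    q = np.divide(Z, row[:, None], out=np.zeros_like(Z), where=row[:, None] > 0)
    Q = Z.sum(axis=0) / Z.sum()
    return MixtureFitState(
        components=components,
        fitted_matrix=Z,
        responsibilities=q,
        shares=Q,
        n_iter=n_iter,
        converged=converged,
        n_pruned=n_pruned,
    )
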