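"""Free energy estimators over non-equilibrium work samples.

Three routes from work values to ΔA:

``jarzynski``
    One-sided exponential work average,
    ΔA = −kT·ln⟨exp(−βW)⟩, evaluated through a log-sum-exp reduction so the
    exponential average never overflows.  Its bias grows with the work
    variance σ_W (Jensen), which is why σ_W is tracked as the convergence
    diagnostic throughout the package.

``two_sided``
    The Bennett maximum-likelihood estimator on forward and backward work
    samples — the statistically efficient estimator consistent with the
    Crooks fluctuation theorem P_F(W) = P_R(−W)·exp[β(W − ΔA)].  The
    histogram-crossing behaviour enters only through diagnostics (the fitted
    slope of ln[P_F(W)/P_R(−W)] vs W, which should equal β).

``staged_bar``
    Pairwise Bennett estimates between neighbouring states of a λ ladder,
    summed, with stage variances propagated in quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logsumexp

from .seeds import child_rng

__all__ = [
    "WorkSample",
    "FreeEnergyEstimate",
    "OverlapDiagnostics",
    "EstimationError",
    "jarzynski",
    "two_sided",
    "staged_bar",
    "work_sigma",
]


class EstimationError(ValueError):
    pass


@dataclass
class WorkSample:
    """A directed collection of work values (kcal/mol) at inverse temperature β."""

    values: np.ndarray
    beta: float
    direction: str = "forward"
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise EstimationError("work values must be finite")
        if self.beta <= 0:
            raise EstimationError("beta must be positive")
        if self.direction not in ("forward", "backward"):
            raise EstimationError("direction must be 'forward' or 'backward'")

    @classmethod
    def from_records(cls, records, beta: float, label: str = "") -> "WorkSample":
        if not records:
            raise EstimationError("no work records")
        return cls(
            values=np.array([r.final_work for r in records]),
            beta=beta,
            direction=records[0].direction,
            label=label,
        )

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class OverlapDiagnostics:
    sigma_w_forward: float
    sigma_w_backward: float | None = None
    histogram_overlap: float = 1.0
    crooks_slope: float | None = None


@dataclass
class FreeEnergyEstimate:
    delta_a: float  # kcal/mol
    stderr: float  # kcal/mol
    method: str
    n_forward: int = 0
    n_backward: int = 0
    diagnostics: OverlapDiagnostics | None = None
    warning: str | None = None

    def __post_init__(self) -> None:
        if self.stderr < 0:
            raise ValueError("stderr must be non-negative")


def work_sigma(sample: WorkSample) -> float:
    """Sample standard deviation of the work values (n−1 denominator)."""
    if sample.n < 2:
        raise EstimationError("work sigma needs at least 2 values")
    return float(sample.values.std(ddof=1))


def _sigma_or_nan(values: np.ndarray) -> float:
    return float(values.std(ddof=1)) if values.size >= 2 else float("nan")


def jarzynski(
    sample: WorkSample, n_bootstrap: int = 1000, seed: int = 0
) -> FreeEnergyEstimate:
    """Jarzynski estimate ΔA = −(1/β)·ln⟨e^(−βW)⟩ with bootstrap stderr."""
    if sample.n == 0:
        raise EstimationError("cannot estimate from an empty sample")
    if sample.direction != "forward":
        raise EstimationError("jarzynski requires a forward-direction sample")
    beta, w = sample.beta, sample.values

    def _jar(values: np.ndarray) -> float:
        return -(logsumexp(-beta * values) - np.log(values.size)) / beta

    delta_a = _jar(w)
    stderr = 0.0
    if sample.n > 1 and n_bootstrap > 0:
        rng = child_rng(seed, "jar-bootstrap")
        boots = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            boots[b] = _jar(w[rng.integers(0, sample.n, sample.n)])
        stderr = float(boots.std(ddof=1))
    return FreeEnergyEstimate(
        delta_a=float(delta_a),
        stderr=stderr,
        method="JAR",
        n_forward=sample.n,
        diagnostics=OverlapDiagnostics(sigma_w_forward=_sigma_or_nan(w)),
    )


# ---------------------------------------------------------------------------
# Bennett / Crooks two-sided estimator
# ---------------------------------------------------------------------------


def _bennett_solve(wf: np.ndarray, wr: np.ndarray, beta: float, tol: float) -> float:
    """Solve the Bennett self-consistency equation for ΔA.

    ``wf`` are forward works, ``wr`` backward works; the Crooks relation pairs
    P_F(W) with P_R(−W), so the reverse sample enters through −wr.
    """
    m = np.log(wf.size / wr.size)

    def g(da: float) -> float:
        lhs = expit(beta * (da - wf) - m).sum()
        rhs = expit(m - beta * (wr + da)).sum()
        return lhs - rhs

    span = np.concatenate([wf, -wr])
    lo = float(span.min()) - 100.0 / beta
    hi = float(span.max()) + 100.0 / beta
    return float(brentq(g, lo, hi, xtol=tol))


def _bennett_variance(
    wf: np.ndarray, wr: np.ndarray, beta: float, delta_a: float
) -> float:
    """Asymptotic variance of the Bennett estimate (clamped at zero)."""
    m = np.log(wf.size / wr.size)
    z = np.concatenate([m + beta * (wf - delta_a), m + beta * (-wr - delta_a)])
    p = expit(z)
    fisher = np.sum(p * (1.0 - p))
    if fisher <= 0:
        return float("inf")
    var = max(0.0, 1.0 / fisher - 1.0 / wf.size - 1.0 / wr.size) / beta**2
    return var


def _shared_histograms(wf: np.ndarray, neg_wr: np.ndarray):
    combined = np.concatenate([wf, neg_wr])
    # Freedman–Diaconis, capped: a tiny IQR against a wide range would
    # otherwise request an astronomical number of bins
    lo, hi = float(combined.min()), float(combined.max())
    width = 2.0 * np.subtract(*np.percentile(combined, [75, 25])) * combined.size ** (
        -1.0 / 3.0
    )
    if width > 0 and np.isfinite(width):
        n_bins = int(np.clip(np.ceil((hi - lo) / width), 1, 200))
    else:
        n_bins = 10
    edges = np.histogram_bin_edges(combined, bins=max(n_bins, 2))
    df, _ = np.histogram(wf, bins=edges, density=True)
    dr, _ = np.histogram(neg_wr, bins=edges, density=True)
    return df, dr, edges


def _histogram_overlap(wf: np.ndarray, neg_wr: np.ndarray) -> float:
    if wf.size < 2 or neg_wr.size < 2:
        return 0.0
    df, dr, edges = _shared_histograms(wf, neg_wr)
    width = np.diff(edges)
    return float(np.sum(np.minimum(df, dr) * width))


def crooks_slope(
    forward: "WorkSample",
    backward: "WorkSample",
    method: str = "mle",
    n_bins: int | None = None,
    min_count: int = 5,
) -> float | None:
    """Fitted slope of ln[P̂_F(W)/P̂_R(−W)] vs W; equals β under the Crooks
    relation.

    ``method="mle"`` (default) fits the log density ratio in its
    maximum-likelihood logistic form on the unbinned work values — the same
    slope, free of histogram noise.  ``method="histogram"`` regresses the
    binned log ratio over the overlap region, restricted to bins holding at
    least ``min_count`` samples from *each* direction (sparse tail bins carry
    a large Jensen bias that flattens the slope) and weighted by the
    delta-method variance 1/n_F + 1/n_R per bin.  Returns ``None`` when the
    samples do not overlap (or fewer than three bins qualify).
    """
    wf, neg_wr = forward.values, -backward.values
    if wf.min() > neg_wr.max() or neg_wr.min() > wf.max():
        return None  # perfect separation: slope undefined
    if method == "mle":
        return _mle_slope(wf, neg_wr)
    if method != "histogram":
        raise ValueError("method must be 'mle' or 'histogram'")
    if n_bins is not None:
        combined = np.concatenate([wf, neg_wr])
        edges = np.linspace(combined.min(), combined.max(), n_bins + 1)
    else:
        _, _, edges = _shared_histograms(wf, neg_wr)
    cf, _ = np.histogram(wf, bins=edges)
    cr, _ = np.histogram(neg_wr, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mask = (cf >= min_count) & (cr >= min_count)
    if mask.sum() < 3:
        return None
    # densities share bin widths and sample sizes up to constants, which only
    # shift the intercept; the slope needs raw counts only
    y = np.log(cf[mask] / cr[mask])
    w = 1.0 / (1.0 / cf[mask] + 1.0 / cr[mask])
    slope = np.polyfit(centers[mask], y, 1, w=np.sqrt(w))[0]
    return float(slope) if np.isfinite(slope) else None


def _mle_slope(wf: np.ndarray, neg_wr: np.ndarray) -> float | None:
    """Newton iteration for the logistic-regression slope of the log ratio."""
    x = np.concatenate([wf, neg_wr])
    y = np.concatenate([np.ones(wf.size), np.zeros(neg_wr.size)])
    design = np.column_stack([np.ones_like(x), x])
    ab = np.zeros(2)
    for _ in range(200):
        p = expit(design @ ab)
        grad = design.T @ (y - p)
        curv = p * (1.0 - p)
        hess = design.T @ (design * curv[:, None])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return None
        step = np.clip(step, -10.0, 10.0)
        ab = ab + step
        if np.abs(step).max() < 1e-10:
            break
    slope = float(ab[1])
    return slope if np.isfinite(slope) else None


def two_sided(
    forward: WorkSample,
    backward: WorkSample,
    tol: float = 1e-8,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> FreeEnergyEstimate:
    """Bennett maximum-likelihood ΔA from forward and backward work samples.

    The returned stderr is the Bennett asymptotic value; when the work
    histograms do not overlap a warning flag is set and the stderr is
    inflated to the larger of the asymptotic value and the full spread of
    the two sample means.
    """
    if forward.n == 0 or backward.n == 0:
        raise EstimationError("both work samples must be non-empty")
    if abs(forward.beta - backward.beta) > 1e-12 * forward.beta:
        raise EstimationError("forward and backward samples have different beta")
    beta = forward.beta
    wf, wr = forward.values, backward.values
    delta_a = _bennett_solve(wf, wr, beta, tol)
    stderr = float(np.sqrt(_bennett_variance(wf, wr, beta, delta_a)))
    overlap = _histogram_overlap(wf, -wr)
    slope = crooks_slope(forward, backward)
    warning = None
    if overlap == 0.0:
        warning = "no overlap between forward and reversed backward work histograms"
        spread = abs(float(wf.mean()) - float((-wr).mean()))
        stderr = max(stderr if np.isfinite(stderr) else 0.0, spread)
    diag = OverlapDiagnostics(
        sigma_w_forward=_sigma_or_nan(wf),
        sigma_w_backward=_sigma_or_nan(wr),
        histogram_overlap=overlap,
        crooks_slope=slope,
    )
    return FreeEnergyEstimate(
        delta_a=delta_a,
        stderr=stderr,
        method="CRO",
        n_forward=forward.n,
        n_backward=backward.n,
        diagnostics=diag,
        warning=warning,
    )


def bootstrap_two_sided(
    forward: WorkSample,
    backward: WorkSample,
    n_bootstrap: int = 200,
    seed: int = 0,
    tol: float = 1e-8,
) -> float:
    """Bootstrap stderr of the two-sided estimate (cross-check of the
    asymptotic value)."""
    rng = child_rng(seed, "bar-bootstrap")
    beta = forward.beta
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        wf = forward.values[rng.integers(0, forward.n, forward.n)]
        wr = backward.values[rng.integers(0, backward.n, backward.n)]
        boots[b] = _bennett_solve(wf, wr, beta, tol)
    return float(boots.std(ddof=1))


def staged_bar(
    energy_matrices: Sequence[np.ndarray],
    lambda_values: Sequence[float],
    beta: float = 1.0,
    tol: float = 1e-8,
) -> FreeEnergyEstimate:
    """Summed pairwise Bennett estimates along a λ ladder.

    ``energy_matrices[k]`` holds the *reduced* (×β) potential energies of the
    samples drawn at state k, re-evaluated at every state: shape
    ``(n_samples_k, K)``.  Neighbouring states k → k+1 contribute a Bennett
    stage on the reduced energy differences; stage results are summed and
    stage variances propagated in quadrature.  ``beta`` converts the reduced
    result back to kcal/mol.

    The default charge-perturbation ladder uses λ = (0, 0.25, 0.5, 0.75, 1).
    """
    K = len(lambda_values)
    if K < 2:
        raise EstimationError("staged BAR needs at least two states")
    if len(energy_matrices) != K:
        raise EstimationError("one energy matrix required per state")
    mats = [np.asarray(m, float) for m in energy_matrices]
    for k, m in enumerate(mats):
        if m.ndim != 2 or m.shape[1] != K:
            raise EstimationError(
                f"state {k}: energy matrix must have one column per state"
            )
    total, var = 0.0, 0.0
    min_overlap = 1.0
    for k in range(K - 1):
        wf = mats[k][:, k + 1] - mats[k][:, k]  # reduced forward works
        wr = mats[k + 1][:, k] - mats[k + 1][:, k + 1]  # reduced backward works
        est = two_sided(
            WorkSample(wf, beta=1.0, direction="forward"),
            WorkSample(wr, beta=1.0, direction="backward"),
            tol=tol,
            n_bootstrap=0,
        )
        total += est.delta_a
        var += est.stderr**2
        if est.diagnostics is not None:
            min_overlap = min(min_overlap, est.diagnostics.histogram_overlap)
    return FreeEnergyEstimate(
        delta_a=total / beta,
        stderr=float(np.sqrt(var)) / beta,
        method="BAR-staged",
        n_forward=sum(m.shape[0] for m in mats[:-1]),
        n_backward=sum(m.shape[0] for m in mats[1:]),
        diagnostics=OverlapDiagnostics(
            sigma_w_forward=float("nan"), histogram_overlap=min_overlap
        ),
    )
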