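"""Convergence diagnostics: charge-distribution metrics, solvation-shell
statistics, Stokes-shift relaxation, and δΔA/MAD reporting.

The guiding question is *why* one-sided switching estimates converge or fail:
how different are the charge distributions of the two levels (RMSD_q,
differential dipole, dipole angle), how does that difference restructure the
first solvation shell, and how long does the solvent need to reorient after
an instantaneous charge jump (mono-exponential fit to the unnormalized
Stokes-shift decay, with the fast initial process excluded from the fit).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .charges import ChargeSet
from .constants import EA_TO_DEBYE
from .model_systems import Configuration

__all__ = [
    "ChargeComparison",
    "StokesSeries",
    "ExpFit",
    "ProtocolSummary",
    "FitDegenerateError",
    "delta_delta_a",
    "rmsd_q",
    "differential_dipole",
    "dipole_angle",
    "compare_charge_sets",
    "count_first_shell",
    "delta_n_waters",
    "stokes_relaxation",
    "fit_mono_exponential",
    "evaluate_fit_at",
    "mad_and_spread",
]


class FitDegenerateError(RuntimeError):
    pass


@dataclass
class ChargeComparison:
    rmsd_q: float  # e
    delta_mu_vector: np.ndarray  # e·Å
    delta_mu: float  # Debye
    theta: float | None  # degrees
    method_label: str = ""
    reference_label: str = ""


@dataclass
class StokesSeries:
    """Ensemble-averaged energy-gap relaxation with its long-time baseline."""

    times: np.ndarray  # fs
    mean_gap: np.ndarray  # ΔU(t)‾, kcal/mol
    baseline: float  # ΔU(∞)‾, kcal/mol
    n_trajectories: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.mean_gap = np.asarray(self.mean_gap, float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times.shape != self.mean_gap.shape:
            raise ValueError("times and mean_gap must have equal length")

    @property
    def shifted(self) -> np.ndarray:
        """ΔΔU(t)‾ = ΔU(t)‾ − ΔU(∞)‾."""
        return self.mean_gap - self.baseline


@dataclass
class ExpFit:
    amplitude: float  # ΔU0, kcal/mol
    tau: float  # fs
    discard_window: float  # fs
    fit_rss: float  # kcal²/mol²

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclass
class ProtocolSummary:
    per_item_delta_delta_a: np.ndarray
    mad: float
    spread_min: float
    spread_max: float


def delta_delta_a(
    estimate: float, reference: float, correction: float | None = None
) -> float:
    """δΔA = estimate − reference, plus the low↔intermediate correction when
    the transformation runs through a hybrid charge intermediate."""
    base = estimate - reference
    return base if correction is None else correction + base


def rmsd_q(q_method: ChargeSet, q_ref: ChargeSet) -> float:
    """Root-mean-square per-atom charge deviation between two sets (e)."""
    if q_method.n_atoms != q_ref.n_atoms:
        raise ValueError("charge sets have different atom counts")
    d = q_method.charges - q_ref.charges
    return float(np.sqrt(np.mean(d**2)))


def differential_dipole(
    q_method: ChargeSet, q_ref: ChargeSet, coordinates: np.ndarray
) -> tuple[np.ndarray, float]:
    """Δμ→ = Σᵢ (qᵢ_method − qᵢ_ref)·rᵢ; returns (vector e·Å, magnitude Debye).

    For neutral charge differences (ΣΔq = 0) the vector is origin-independent.
    """
    coords = np.atleast_2d(np.asarray(coordinates, float))
    if q_method.n_atoms != q_ref.n_atoms or coords.shape[0] != q_method.n_atoms:
        raise ValueError("charge sets / coordinates size mismatch")
    dq = q_method.charges - q_ref.charges
    vec = dq @ coords
    return vec, float(np.linalg.norm(vec) * EA_TO_DEBYE)


def _dipole_vector(q: ChargeSet, coords: np.ndarray) -> np.ndarray:
    return q.charges @ np.atleast_2d(np.asarray(coords, float))


def dipole_angle(
    q_method: ChargeSet, q_ref: ChargeSet, coordinates: np.ndarray
) -> float:
    """Angle (degrees) between the full dipole vectors of two charge sets."""
    mu_m = _dipole_vector(q_method, coordinates)
    mu_r = _dipole_vector(q_ref, coordinates)
    nm, nr = np.linalg.norm(mu_m), np.linalg.norm(mu_r)
    if nm == 0.0 or nr == 0.0:
        raise ValueError("dipole angle undefined for a zero-magnitude dipole")
    cosang = np.clip(mu_m @ mu_r / (nm * nr), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def compare_charge_sets(
    q_method: ChargeSet, q_ref: ChargeSet, coordinates: np.ndarray
) -> ChargeComparison:
    """All three charge-distribution metrics in one record."""
    vec, mag = differential_dipole(q_method, q_ref, coordinates)
    try:
        theta = dipole_angle(q_method, q_ref, coordinates)
    except ValueError:
        theta = None
    return ChargeComparison(
        rmsd_q=rmsd_q(q_method, q_ref),
        delta_mu_vector=vec,
        delta_mu=mag,
        theta=theta,
        method_label=q_method.source,
        reference_label=q_ref.source,
    )


# ---------------------------------------------------------------------------
# first solvation shell
# ---------------------------------------------------------------------------


def count_first_shell(
    config: Configuration | np.ndarray,
    solute_coords: np.ndarray,
    cutoff: float = 3.0,
    heavy_mask: np.ndarray | None = None,
) -> int:
    """Number of solvent sites within ≤ cutoff (inclusive) of any heavy solute
    site.

    ``config`` may be a Configuration carrying ``solvent_positions`` or a raw
    (n_sites, 3) array of solvent positions.  ``heavy_mask`` restricts the
    solute sites considered (default: all sites are heavy).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if isinstance(config, Configuration):
        solvent = config.solvent_positions
        if solvent is None:
            raise ValueError("configuration carries no solvent positions")
    else:
        solvent = np.asarray(config, float)
    solvent = np.atleast_2d(solvent)
    coords = np.atleast_2d(np.asarray(solute_coords, float))
    if heavy_mask is not None:
        coords = coords[np.asarray(heavy_mask, bool)]
    d = np.linalg.norm(solvent[:, None, :] - coords[None, :, :], axis=2)
    return int(np.sum(d.min(axis=1) <= cutoff))


def delta_n_waters(
    traj_method, traj_ref, solute_coords: np.ndarray, cutoff: float = 3.0
) -> float:
    """Mean first-shell count over one trajectory minus that over a reference.

    Accepts RestartPools or plain sequences of Configurations/position arrays.
    """

    def _mean(traj) -> float:
        configs = getattr(traj, "configurations", traj)
        if len(configs) == 0:
            raise ValueError("empty trajectory")
        return float(
            np.mean([count_first_shell(c, solute_coords, cutoff) for c in configs])
        )

    return _mean(traj_method) - _mean(traj_ref)


# ---------------------------------------------------------------------------
# Stokes-shift relaxation
# ---------------------------------------------------------------------------


def stokes_relaxation(
    gap_series: np.ndarray | Sequence[np.ndarray],
    times: np.ndarray,
    baseline_window: tuple[float, float] | None = None,
) -> StokesSeries:
    """Average per-trajectory ΔU(t) series and subtract the long-time baseline.

    ``gap_series`` is (n_trajectories, n_times) on the common ``times`` grid.
    The baseline ΔU(∞)‾ is the time-average of the ensemble mean over
    ``baseline_window`` (default: the final 20 % of the series, which for a
    10 ps / 1 fs series averages the last 2000 entries).
    """
    series = np.atleast_2d(np.asarray(gap_series, float))
    times = np.asarray(times, float)
    if series.shape[1] != times.size:
        raise ValueError("gap series and time grid length mismatch")
    mean_gap = series.mean(axis=0)
    if baseline_window is None:
        t0 = times[0] + 0.8 * (times[-1] - times[0])
        baseline_window = (t0, times[-1])
    lo, hi = baseline_window
    mask = (times >= lo) & (times <= hi)
    if not mask.any():
        raise ValueError("baseline window lies outside the time grid")
    return StokesSeries(
        times=times,
        mean_gap=mean_gap,
        baseline=float(mean_gap[mask].mean()),
        n_trajectories=series.shape[0],
    )


def fit_mono_exponential(series: StokesSeries, discard: float = 500.0) -> ExpFit:
    """Least-squares fit of ΔU0·e^(−t/τ) to ΔΔU(t)‾ for t ≥ ``discard`` (fs).

    The discard window removes the fast initial relaxation so τ reflects the
    slower reorientation process.  Initial guesses come from a log-linear
    regression on the positive segment of the decay.
    """
    mask = series.times >= discard
    t = series.times[mask]
    y = series.shifted[mask]
    if t.size < 10:
        raise FitDegenerateError("fewer than 10 points after the discard window")
    pos = y > 0
    if pos.sum() < max(3, 0.2 * y.size) or abs(y.max()) == 0.0:
        raise FitDegenerateError(
            "shifted series is non-positive or sign-alternating over the fit window"
        )
    slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
    tau0 = -1.0 / slope if slope < 0 else (t[-1] - t[0])
    a0 = float(np.exp(intercept))

    def model(tt, a, tau):
        return a * np.exp(-tt / tau)

    popt, _ = curve_fit(
        model, t, y, p0=[a0, max(tau0, 1.0)], maxfev=20000,
        bounds=([-np.inf, 1e-9], [np.inf, np.inf]),
    )
    resid = y - model(t, *popt)
    return ExpFit(
        amplitude=float(popt[0]),
        tau=float(popt[1]),
        discard_window=discard,
        fit_rss=float(resid @ resid),
    )


def evaluate_fit_at(fit: ExpFit, t: float) -> float:
    """ΔU0·e^(−t/τ) at time t (fs)."""
    return fit.amplitude * float(np.exp(-t / fit.tau))


def mad_and_spread(values) -> ProtocolSummary:
    """Mean absolute deviation (from zero) and the min/max absolute values."""
    v = np.asarray(values, float).ravel()
    if v.size == 0:
        raise ValueError("mad_and_spread requires a non-empty list")
    a = np.abs(v)
    return ProtocolSummary(
        per_item_delta_delta_a=v,
        mad=float(a.mean()),
        spread_min=float(a.min()),
        spread_max=float(a.max()),
    )
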