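"""Folding kinetics: free-energy profiles, barriers, folding times, P_fold.

Two independent folding-time estimators are provided:

* Kramers' rate law, τ = A · exp(ΔG* / RT), from the free-energy barrier
  ΔG* along an order parameter and a friction-dependent pre-exponential
  factor A.  For a chain of n residues A scales linearly with length from
  the 40-residue reference value of 0.80 µs, giving 0.56 µs at n = 28.
* A trajectory-count estimator from M constant-temperature runs of
  duration t of which m folded: τ = M·t/m with a Poisson counting
  uncertainty τ/√m.  With m = 0 the result is a censored lower bound M·t.
  Folding times from low-friction simulations are rescaled by the
  friction ratio (τ ∝ γ in the overdamped regime).

A folding event in an RMSD trace is a first time t0 such that the trace
stays below the cutoff for the whole dwell window [t0, t0 + min_dwell].

The committor P_fold of a putative transition-state structure is the
fraction of trajectories started from it that fold; a structure belongs
to the transition-state ensemble when the Wilson 95% interval of P_fold
contains one half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import R_KCAL
from .io import TemperatureSeries


@dataclass
class FreeEnergyProfile:
    """Free energy vs an order parameter, min-shifted to zero.

    Empty bins hold NaN (no sample ever visited them), never zero.
    """

    bin_centers: np.ndarray
    free_energy: np.ndarray
    temperature: float
    bin_width: float
    counts: np.ndarray | None = None


@dataclass
class KineticsResult:
    """A folding-time estimate with provenance."""

    tau: float  # µs
    tau_err: float = float("nan")
    method: str = "kramers"  # "kramers" | "counting"
    barrier: float = float("nan")  # kcal/mol
    barrier_err: float = float("nan")
    prefactor: float = float("nan")  # µs
    lower_bound: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("folding time must be positive")


@dataclass
class PfoldResult:
    """Committor estimate from binary trajectory outcomes."""

    n_trajectories: int
    n_folded: int
    p_fold: float
    ci_low: float
    ci_high: float
    is_transition_state: bool


# ---------------------------------------------------------------------------
# Free-energy profiles and barriers
# ---------------------------------------------------------------------------

def free_energy_profile(
    values, bins, temperature: float
) -> FreeEnergyProfile:
    """F(q) = −RT ln(fraction of samples per bin), shifted so min F = 0.

    ``bins`` follows numpy.histogram (count or explicit edges).
    """
    if isinstance(values, TemperatureSeries):
        temperature = values.temperature
        values = values.values
    x = np.asarray(values, dtype=float)
    counts, edges = np.histogram(x, bins=bins)
    if counts.sum() == 0:
        raise ValueError("no samples fall inside the bins")
    centers = 0.5 * (edges[:-1] + edges[1:])
    frac = counts / counts.sum()
    F = np.full_like(frac, np.nan)
    occ = counts > 0
    F[occ] = -R_KCAL * temperature * np.log(frac[occ])
    F -= np.nanmin(F)
    return FreeEnergyProfile(
        bin_centers=centers,
        free_energy=F,
        temperature=float(temperature),
        bin_width=float(edges[1] - edges[0]),
        counts=counts,
    )


def barrier_height(
    profile: FreeEnergyProfile,
    folded_range: tuple[float, float],
    unfolded_range: tuple[float, float],
) -> tuple[float, float]:
    """Folding free-energy barrier ΔG* and its location.

    ΔG* = (max F between the two basin minima) − (F at the folded-basin
    minimum).  The interior maximum must exceed both basin minima; a
    monotone (V-shaped) stretch between the minima is an error.  A plateau
    at the top resolves to the first (lowest-q) maximum.
    """
    q, F = profile.bin_centers, profile.free_energy

    def basin_min(rng):
        lo, hi = sorted(rng)
        mask = (q >= lo) & (q <= hi) & np.isfinite(F)
        if not mask.any():
            raise ValueError(f"no occupied bins in basin range {rng}")
        idx = np.flatnonzero(mask)
        return idx[np.argmin(F[mask])]

    i_fold = basin_min(folded_range)
    i_unfold = basin_min(unfolded_range)
    lo, hi = sorted((i_fold, i_unfold))
    interior = np.arange(lo + 1, hi)
    interior = interior[np.isfinite(F[interior])]
    if interior.size == 0:
        raise ValueError("no occupied bins between the basin minima")
    k = interior[np.argmax(F[interior])]
    # np.argmax returns the first index on ties -> first maximum of a plateau
    if F[k] <= F[i_fold] or F[k] <= F[i_unfold]:
        raise ValueError("no interior maximum between the basin minima")
    return float(F[k] - F[i_fold]), float(q[k])


# ---------------------------------------------------------------------------
# Folding-time estimators
# ---------------------------------------------------------------------------

def kramers_time(barrier: float, temperature: float, prefactor: float) -> float:
    """τ = A · exp(ΔG*/RT) in µs."""
    if prefactor <= 0:
        raise ValueError("prefactor must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return float(prefactor * np.exp(barrier / (R_KCAL * temperature)))


def kramers_estimate(
    barrier: float,
    temperature: float,
    prefactor: float,
    barrier_err: float = float("nan"),
) -> KineticsResult:
    """Kramers folding time with first-order error propagation
    (δτ = τ · δΔG* / RT)."""
    tau = kramers_time(barrier, temperature, prefactor)
    tau_err = tau * barrier_err / (R_KCAL * temperature)
    return KineticsResult(
        tau=tau,
        tau_err=float(tau_err),
        method="kramers",
        barrier=float(barrier),
        barrier_err=float(barrier_err),
        prefactor=float(prefactor),
        meta={"temperature": temperature},
    )


def scale_prefactor(n_residues: int, reference_prefactor: float = 0.80,
                    reference_length: int = 40) -> float:
    """Linear length scaling of the Kramers prefactor: A(n) = 0.80·n/40 µs."""
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    return reference_prefactor * n_residues / reference_length


def cmd_folding_time(n_traj: int, duration: float, n_folded: int) -> KineticsResult:
    """Trajectory-count folding time τ = M·t/m (µs), uncertainty τ/√m.

    With no folding events the estimate is censored: the result carries
    ``lower_bound=True`` with value M·t.
    """
    if n_traj < 1:
        raise ValueError("need at least one trajectory")
    if not 0 <= n_folded <= n_traj:
        raise ValueError("n_folded must lie in [0, n_traj]")
    total = n_traj * duration
    if n_folded == 0:
        return KineticsResult(
            tau=total, method="counting", lower_bound=True,
            meta={"n_traj": n_traj, "duration": duration, "n_folded": 0},
        )
    tau = total / n_folded
    return KineticsResult(
        tau=tau,
        tau_err=tau / np.sqrt(n_folded),
        method="counting",
        meta={"n_traj": n_traj, "duration": duration, "n_folded": n_folded},
    )


def friction_correct(result: KineticsResult, friction_ratio: float) -> KineticsResult:
    """Rescale a folding time to a different friction (τ ∝ γ overdamped).

    A censored input stays flagged as a lower bound.
    """
    if friction_ratio <= 0:
        raise ValueError("friction ratio must be positive")
    return KineticsResult(
        tau=result.tau * friction_ratio,
        tau_err=result.tau_err * friction_ratio,
        method=result.method,
        barrier=result.barrier,
        barrier_err=result.barrier_err,
        prefactor=result.prefactor,
        lower_bound=result.lower_bound,
        meta={**result.meta, "friction_ratio": friction_ratio},
    )


# ---------------------------------------------------------------------------
# Event detection and committor
# ---------------------------------------------------------------------------

def detect_folding_event(
    series: TemperatureSeries, cutoff: float, min_dwell: float
) -> float | None:
    """First folding time in an RMSD trace, or None.

    The event time t0 is the earliest sample time such that every sample
    in [t0, t0 + min_dwell] lies strictly below ``cutoff``.  ``min_dwell``
    is in ns and must be at least one sample interval.
    """
    if min_dwell < series.dt:
        raise ValueError("min_dwell must be >= the sample interval")
    below = series.values < cutoff
    k = int(np.ceil(min_dwell / series.dt - 1e-9)) + 1  # samples spanning the dwell
    if k > below.size:
        return None
    window_ok = np.convolve(below.astype(int), np.ones(k, dtype=int), mode="valid") == k
    hits = np.flatnonzero(window_ok)
    if hits.size == 0:
        return None
    return float(hits[0] * series.dt)


def pfold_estimate(n_folded: int, n_unfolded: int) -> PfoldResult:
    """Committor estimate with a Wilson 95% interval.

    The structure is classified as a transition-state member when the
    interval contains 0.5.
    """
    from statsmodels.stats.proportion import proportion_confint

    total = n_folded + n_unfolded
    if total < 1:
        raise ValueError("need at least one trajectory outcome")
    p = n_folded / total
    lo, hi = proportion_confint(n_folded, total, alpha=0.05, method="wilson")
    return PfoldResult(
        n_trajectories=total,
        n_folded=n_folded,
        p_fold=p,
        ci_low=float(lo),
        ci_high=float(hi),
        is_transition_state=bool(lo <= 0.5 <= hi),
    )


def pearson_corr(series_a, series_b) -> float:
    """Pearson product-moment correlation of two equal-length series."""
    from scipy.stats import pearsonr

    a = series_a.values if isinstance(series_a, TemperatureSeries) else np.asarray(series_a, float)
    b = series_b.values if isinstance(series_b, TemperatureSeries) else np.asarray(series_b, float)
    if a.size != b.size:
        raise ValueError("series must have equal length")
    if a.size < 3:
        raise ValueError("need >= 3 samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant series")
    return float(pearsonr(a, b).statistic)
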