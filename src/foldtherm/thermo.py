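"""Two-state folding thermodynamics.

The stability curve of a two-state folder, in the folding→unfolding
direction with ΔH_m and ΔC_p constant in temperature, is

    ΔG_u(T) = ΔH_m (1 − T/T_m) + ΔC_p [(T − T_m) − T ln(T/T_m)]

so that ΔG_u(T_m) = 0 and ΔG_u > 0 below the midpoint.  The folded
fraction follows as f(T) = 1 / (1 + K_u) with the unfolding constant
K_u = exp(−ΔG_u / RT).  ΔS_m is derived as ΔH_m / T_m.

Heat capacity is estimated from potential-energy fluctuations,
C_p(T) = Var(E) / (R T²) with the unbiased (n−1) variance; the excess
profile subtracts the native-state baseline, taken as the absolute value
at the lowest sampled temperature.  The denaturation enthalpy of a
transition is the trapezoidal integral of the excess heat capacity over a
window bracketing the peak.

Units: kcal/mol, K; heat capacities kcal/mol/K.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .constants import R_KCAL
from .io import TemperatureSeries


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails to converge."""


@dataclass
class VantHoffParams:
    """Two-state van't Hoff parameters.

    t_m in K; dh_m in kcal/mol; dcp in kcal/mol/K; ds_m (derived,
    kcal/mol/K) = dh_m / t_m.  ``*_err`` are fit standard errors when the
    parameters come from a fit, else ``nan``.
    """

    t_m: float
    dh_m: float
    dcp: float = 0.0
    t_m_err: float = float("nan")
    dh_m_err: float = float("nan")
    dcp_err: float = float("nan")
    flags: list = field(default_factory=list)

    def __post_init__(self):
        if self.t_m <= 0:
            raise ValueError("t_m must be positive")

    @property
    def ds_m(self) -> float:
        return self.dh_m / self.t_m


@dataclass
class MeltingCurve:
    """Folded fraction vs temperature with block standard errors."""

    temperatures: np.ndarray
    folded_fraction: np.ndarray
    errors: np.ndarray | None = None

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.folded_fraction = np.asarray(self.folded_fraction, dtype=float)
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if np.any((self.folded_fraction < 0) | (self.folded_fraction > 1)):
            raise ValueError("folded fractions must lie in [0, 1]")
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=float)


@dataclass
class CpProfile:
    """Absolute (and optionally excess) heat capacity per temperature."""

    temperatures: np.ndarray
    cp: np.ndarray
    excess_cp: np.ndarray | None = None
    baseline: float | None = None
    cp_err: np.ndarray | None = None

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.cp = np.asarray(self.cp, dtype=float)


@dataclass
class PeakResult:
    """A transition located on the excess heat capacity profile."""

    peak_temperature: float
    dh_d: float
    window: tuple[float, float]
    peak_temperature_err: float = float("nan")


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

def stability_curve(T, p: VantHoffParams):
    """Unfolding free energy ΔG_u(T) in kcal/mol (zero at T_m)."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive")
    ratio = T / p.t_m
    return p.dh_m * (1.0 - ratio) + p.dcp * ((T - p.t_m) - T * np.log(ratio))


def folded_fraction_model(T, p: VantHoffParams):
    """Equilibrium folded fraction f(T) = 1 / (1 + exp(−ΔG_u/RT))."""
    dg = stability_curve(T, p)
    T = np.asarray(T, dtype=float)
    return 1.0 / (1.0 + np.exp(-dg / (R_KCAL * T)))


# ---------------------------------------------------------------------------
# Estimation from data
# ---------------------------------------------------------------------------

def block_errors(values, n_blocks: int = 2) -> tuple[float, float]:
    """Mean and block standard error of a series.

    The series is split into ``n_blocks`` contiguous equal blocks (any
    remainder samples are dropped); the error is the standard deviation of
    the block means divided by √n_blocks.
    """
    values = np.asarray(values, dtype=float)
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if values.size < n_blocks:
        raise ValueError("series shorter than the number of blocks")
    m = values.size // n_blocks
    block_means = values[: m * n_blocks].reshape(n_blocks, m).mean(axis=1)
    err = block_means.std(ddof=1) / np.sqrt(n_blocks)
    return float(block_means.mean()), float(err)


def melting_curve(
    indicator_series: Sequence[TemperatureSeries], n_blocks: int = 2
) -> MeltingCurve:
    """Folded fraction per temperature from folded-indicator series.

    Each input series holds 0/1 (or boolean) folded indicators at one
    temperature; fractions are block-averaged with ``n_blocks`` blocks.
    """
    if len(indicator_series) < 2:
        raise ValueError("need series at >= 2 temperatures")
    ordered = sorted(indicator_series, key=lambda s: s.temperature)
    temps, fracs, errs = [], [], []
    for s in ordered:
        if len(s) == 0:
            raise ValueError(f"empty series at T={s.temperature}")
        mean, err = block_errors(s.values, n_blocks)
        temps.append(s.temperature)
        fracs.append(min(max(mean, 0.0), 1.0))
        errs.append(err)
    return MeltingCurve(np.array(temps), np.array(fracs), np.array(errs))


def _initial_guess(curve: MeltingCurve) -> tuple[float, float, list]:
    """Midpoint/slope initialisation for the van't Hoff fit."""
    T, f = curve.temperatures, curve.folded_fraction
    flags: list = []
    crossing = None
    for i in range(T.size - 1):
        lo, hi = sorted((f[i], f[i + 1]))
        if lo <= 0.5 <= hi and f[i] != f[i + 1]:
            crossing = T[i] + (0.5 - f[i]) * (T[i + 1] - T[i]) / (f[i + 1] - f[i])
            slope = (f[i + 1] - f[i]) / (T[i + 1] - T[i])
            break
    if crossing is None:
        flags.append("extrapolated_tm")
        i = int(np.argmin(np.abs(f - 0.5)))
        crossing = T[i]
        j = min(i + 1, T.size - 1)
        slope = (f[j] - f[max(i - 1, 0)]) / (T[j] - T[max(i - 1, 0)] + 1e-12)
    # at the midpoint df/dT = -ΔHm / (4 R Tm^2)
    dh0 = max(-4.0 * R_KCAL * crossing**2 * slope, 1.0)
    return float(crossing), float(dh0), flags


def fit_vant_hoff(curve: MeltingCurve, error_floor: float = 0.01) -> VantHoffParams:
    """Weighted nonlinear least-squares fit of the two-state melting curve.

    Weights come from the curve's block errors, floored at ``error_floor``
    to avoid infinite weights on noiseless points.  Initial values: T_m
    from the interpolated 0.5 crossing, ΔH_m from the midpoint slope,
    ΔC_p = 0.  Standard errors are taken from the fit covariance.
    """
    T, f = curve.temperatures, curve.folded_fraction
    if T.size < 4:
        raise ValueError("need >= 4 temperatures to fit three parameters")
    if np.allclose(f, f[0]):
        raise ValueError("folded fractions are all equal; nothing to fit")

    tm0, dh0, flags = _initial_guess(curve)
    sigma = None
    if curve.errors is not None:
        sigma = np.maximum(curve.errors, error_floor)

    def model(T, tm, dh, dcp):
        return folded_fraction_model(T, VantHoffParams(t_m=tm, dh_m=dh, dcp=dcp))

    try:
        popt, pcov = curve_fit(
            model, T, f, p0=[tm0, dh0, 0.0], sigma=sigma, maxfev=20000
        )
    except RuntimeError as exc:
        resid = f - model(T, tm0, dh0, 0.0)
        raise FitError(
            f"van't Hoff fit did not converge (initial residual rms "
            f"{np.sqrt(np.mean(resid**2)):.3g})"
        ) from exc
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    return VantHoffParams(
        t_m=float(popt[0]),
        dh_m=float(popt[1]),
        dcp=float(popt[2]),
        t_m_err=float(perr[0]),
        dh_m_err=float(perr[1]),
        dcp_err=float(perr[2]),
        flags=flags,
    )


def heat_capacity_profile(
    energy_series: Sequence[TemperatureSeries], n_blocks: int = 2
) -> CpProfile:
    """Fluctuation heat capacity C_p(T) = Var(E)/(R T²) per temperature.

    Uses the unbiased (n−1) variance.  ``cp_err`` holds a block estimate of
    the statistical error (standard error of per-block C_p values).
    """
    ordered = sorted(energy_series, key=lambda s: s.temperature)
    temps, cps, errs = [], [], []
    for s in ordered:
        if len(s) < 2:
            raise ValueError(f"need >= 2 energy samples at T={s.temperature}")
        T = s.temperature
        cps.append(float(np.var(s.values, ddof=1)) / (R_KCAL * T**2))
        temps.append(T)
        if len(s) >= 2 * n_blocks:
            m = len(s) // n_blocks
            blocks = s.values[: m * n_blocks].reshape(n_blocks, m)
            block_cp = blocks.var(axis=1, ddof=1) / (R_KCAL * T**2)
            errs.append(float(block_cp.std(ddof=1) / np.sqrt(n_blocks)))
        else:
            errs.append(float("nan"))
    return CpProfile(np.array(temps), np.array(cps), cp_err=np.array(errs))


def excess_heat_capacity(profile: CpProfile) -> CpProfile:
    """Subtract the native baseline (C_p at the lowest temperature)."""
    if profile.temperatures.size == 0:
        raise ValueError("empty profile")
    baseline = float(profile.cp[np.argmin(profile.temperatures)])
    return CpProfile(
        temperatures=profile.temperatures,
        cp=profile.cp,
        excess_cp=profile.cp - baseline,
        baseline=baseline,
        cp_err=profile.cp_err,
    )


def peak_enthalpy(profile: CpProfile, window: tuple[float, float]) -> PeakResult:
    """Locate a transition peak and integrate its denaturation enthalpy.

    The peak temperature is the argmax of the excess heat capacity inside
    ``window``; it must be an interior point of the window.  ΔH_d is the
    trapezoidal integral of the excess heat capacity over the window.
    """
    if profile.excess_cp is None:
        raise ValueError("profile has no excess heat capacity; call excess_heat_capacity first")
    lo, hi = window
    T, ex = profile.temperatures, profile.excess_cp
    mask = (T >= lo) & (T <= hi)
    if mask.sum() < 3:
        raise ValueError("window must contain >= 3 profile points")
    Tw, exw = T[mask], ex[mask]
    k = int(np.argmax(exw))
    if k in (0, exw.size - 1):
        raise ValueError("no interior maximum inside the window")
    dh_d = float(np.trapezoid(exw, Tw))
    return PeakResult(peak_temperature=float(Tw[k]), dh_d=dh_d, window=(float(lo), float(hi)))


def find_peak_windows(profile: CpProfile, smooth: int = 5) -> list[tuple[float, float]]:
    """Default integration windows: flanking local minima of the smoothed
    excess profile around each interior local maximum."""
    if profile.excess_cp is None:
        raise ValueError("profile has no excess heat capacity")
    ex = profile.excess_cp
    if ex.size >= smooth:
        kernel = np.ones(smooth) / smooth
        sm = np.convolve(ex, kernel, mode="same")
    else:
        sm = ex.copy()
    T = profile.temperatures
    windows = []
    for k in range(1, sm.size - 1):
        if sm[k] >= sm[k - 1] and sm[k] > sm[k + 1]:
            left = k
            while left > 0 and sm[left - 1] < sm[left]:
                left -= 1
            right = k
            while right < sm.size - 1 and sm[right + 1] < sm[right]:
                right += 1
            if left < k < right:
                windows.append((float(T[left]), float(T[right])))
    return windows
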