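"""Synthetic two-state folding data with known ground truth.

Emulates the statistical structure of temperature replica-exchange and
constant-temperature folding simulation data for a two-state folder:

* equilibrium occupancies from a van't Hoff stability curve with
  prescribed T_m, ΔH_m, ΔC_p;
* per-temperature potential-energy samples from a two-component Gaussian
  mixture whose state gap μ_D(T) − μ_N(T) = ΔH_m + ΔC_p (T − T_m)
  reproduces the fluctuation heat-capacity peak at the transition
  (μ_N is held constant at its reference value — the minimal choice that
  places all temperature dependence of the gap in the denatured state);
* bimodal order-parameter emissions (folded ≈ 2 Å, unfolded ≈ 7 Å, the
  two basins of the folding free-energy surface);
* two-state Markov-chain kinetics obeying detailed balance, with folding
  rate k_f = exp(−ΔG*/RT)/A and unfolding rate k_u = k_f · K_u(T), so
  Kramers-based and trajectory-count folding-time estimators are mutually
  consistent by construction.

Default parameters are the CD-derived thermodynamics of FSD-1
(T_m = 315 K, ΔH_m = 10.4 kcal/mol, ΔC_p = 120.7 cal/mol/K) and its
simulation-derived kinetics (ΔG* = 0.9 kcal/mol, A = 0.56 µs).

Replica-exchange-like datasets draw the state i.i.d. per sample: exchange
decorrelates equilibrium sampling, so per-temperature REMD series mix
between the states far faster than the µs-scale dwell times of a single
constant-temperature trajectory.  Constant-temperature kinetics are
generated by :func:`simulate_order_series`, which keeps the full chain.

Seed policy: one master seed; per-series generators derive from a fixed
hash of (seed, temperature, series kind), so any series regenerates
byte-identically in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .constants import R_KCAL
from .io import Structure, TemperatureSeries, read_series_table, write_series_table
from .orderparams import superpose
from .thermo import VantHoffParams, folded_fraction_model, stability_curve


@dataclass(frozen=True)
class TwoStateParams:
    """Ground-truth parameters of the synthetic two-state folder.

    t_m (K), dh_m (kcal/mol), dcp (kcal/mol/K) parameterize the stability
    curve; sigma_n/sigma_d (kcal/mol) are intra-state energy standard
    deviations; mu_n_ref (kcal/mol) is the (constant) native-state mean
    energy; barrier_fold (kcal/mol) and prefactor (µs) set the folding
    rate k_f = exp(−barrier_fold/RT)/prefactor.
    """

    t_m: float = 315.0
    dh_m: float = 10.4
    dcp: float = 0.1207
    sigma_n: float = 3.0
    sigma_d: float = 3.0
    mu_n_ref: float = -100.0
    barrier_fold: float = 0.9
    prefactor: float = 0.56

    def __post_init__(self):
        if self.t_m <= 0 or self.dh_m <= 0:
            raise ValueError("t_m and dh_m must be positive")
        if self.sigma_n < 0 or self.sigma_d < 0:
            raise ValueError("state standard deviations must be non-negative")
        if self.prefactor <= 0:
            raise ValueError("prefactor must be positive")

    def vant_hoff(self) -> VantHoffParams:
        return VantHoffParams(t_m=self.t_m, dh_m=self.dh_m, dcp=self.dcp)

    def mu_native(self, T) -> float:
        return self.mu_n_ref

    def mu_denatured(self, T):
        return self.mu_n_ref + self.dh_m + self.dcp * (np.asarray(T, float) - self.t_m)


@dataclass(frozen=True)
class Emission:
    """Per-state order-parameter emission (mean, sd), in Å for rmsd/rg."""

    native_mean: float = 2.0
    native_sd: float = 0.5
    unfolded_mean: float = 7.0
    unfolded_sd: float = 1.5

    @property
    def overlapping(self) -> bool:
        gap = abs(self.unfolded_mean - self.native_mean)
        return gap < self.native_sd and gap < self.unfolded_sd


@dataclass
class SyntheticDataset:
    """Per-temperature energy and order-parameter series plus ground truth."""

    energy_series: list[TemperatureSeries]
    order_series: list[TemperatureSeries]
    truth: TwoStateParams
    seed: int

    @property
    def series(self) -> list[TemperatureSeries]:
        return list(self.energy_series) + list(self.order_series)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_series_table(self.energy_series, directory / "energy.tsv")
        write_series_table(self.order_series, directory / "order.tsv")
        payload = {"truth": dataclasses.asdict(self.truth), "seed": self.seed}
        (directory / "truth.json").write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, directory) -> "SyntheticDataset":
        directory = Path(directory)
        payload = json.loads((directory / "truth.json").read_text())
        return cls(
            energy_series=read_series_table(directory / "energy.tsv"),
            order_series=read_series_table(directory / "order.tsv"),
            truth=TwoStateParams(**payload["truth"]),
            seed=int(payload["seed"]),
        )


def _series_rng(seed: int, temperature: float, kind: str) -> np.random.Generator:
    """Deterministic per-series generator from (master seed, T, kind)."""
    ss = np.random.SeedSequence(
        [int(seed), int(round(temperature * 1000)), zlib.crc32(kind.encode())]
    )
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# Ground-truth functions
# ---------------------------------------------------------------------------

def occupancy_truth(T, p: TwoStateParams):
    """Equilibrium folded fraction f(T) = 1/(1 + K_u), K_u = e^(−ΔG_u/RT)."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive")
    return folded_fraction_model(T, p.vant_hoff())


def rates(T: float, p: TwoStateParams) -> tuple[float, float]:
    """Folding and unfolding rates (µs⁻¹) obeying detailed balance.

    k_f = exp(−ΔG*/RT)/A; k_u = k_f · K_u(T) so that the stationary native
    occupancy k_f/(k_f + k_u) equals :func:`occupancy_truth`.
    """
    k_f = float(np.exp(-p.barrier_fold / (R_KCAL * T)) / p.prefactor)
    k_u = k_f * float(np.exp(-stability_curve(T, p.vant_hoff()) / (R_KCAL * T)))
    return k_f, k_u


# ---------------------------------------------------------------------------
# Samplers
# ---------------------------------------------------------------------------

def sample_energy_series(
    T: float, n: int, p: TwoStateParams, seed: int = 0, dt: float = 0.002
) -> TemperatureSeries:
    """i.i.d. potential-energy samples at temperature T.

    Each sample: state ~ Bernoulli(occupancy), energy ~ N(μ_state, σ_state)
    with μ_D − μ_N = ΔH_m + ΔC_p (T − T_m).
    """
    if n < 1:
        raise ValueError("need n >= 1 samples")
    rng = _series_rng(seed, T, "energy")
    f = float(occupancy_truth(T, p))
    native = rng.random(n) < f
    values = np.where(
        native,
        rng.normal(p.mu_native(T), p.sigma_n, n),
        rng.normal(p.mu_denatured(T), p.sigma_d, n),
    )
    return TemperatureSeries(
        temperature=T, dt=dt, values=values, quantity="energy",
        meta={"seed": seed, "truth_occupancy": f},
    )


def sample_order_series(
    T: float,
    n: int,
    p: TwoStateParams,
    emission: Emission = Emission(),
    seed: int = 0,
    dt: float = 0.002,
    component: str = "whole",
) -> TemperatureSeries:
    """i.i.d. order-parameter samples at temperature T (exchange-mixed)."""
    if n < 1:
        raise ValueError("need n >= 1 samples")
    rng = _series_rng(seed, T, f"order:{component}")
    f = float(occupancy_truth(T, p))
    native = rng.random(n) < f
    values = np.where(
        native,
        rng.normal(emission.native_mean, emission.native_sd, n),
        rng.normal(emission.unfolded_mean, emission.unfolded_sd, n),
    )
    meta = {"seed": seed, "component": component, "truth_occupancy": f}
    if emission.overlapping:
        meta["overlapping_emissions"] = True
    return TemperatureSeries(
        temperature=T, dt=dt, values=np.abs(values), quantity="rmsd", meta=meta
    )


def simulate_order_series(
    T: float,
    duration: float,
    dt: float,
    p: TwoStateParams,
    emission: Emission = Emission(),
    seed: int = 0,
    start_state: int | None = None,
) -> TemperatureSeries:
    """Two-state Markov-chain order-parameter trajectory at temperature T.

    The chain switches state with per-step probability 1 − exp(−k·dt)
    (k = k_u in the native state, k_f otherwise; dt in ns, rates per µs),
    which makes dwell times geometric with mean ≈ 1/k for dt ≪ 1/k.  The
    emitted value is Normal(state mean, state sd).  ``start_state`` forces
    the initial state (1 native, 0 unfolded); default draws it from the
    stationary occupancy.  The hidden state path is kept in
    ``meta["state_path"]``.
    """
    if not duration >= dt > 0:
        raise ValueError("need duration >= dt > 0")
    rng = _series_rng(seed, T, "chain")
    n = int(round(duration / dt))
    k_f, k_u = rates(T, p)
    dt_us = dt * 1e-3
    p_fold = -np.expm1(-k_f * dt_us)  # unfolded -> native
    p_unfold = -np.expm1(-k_u * dt_us)  # native -> unfolded

    f = float(occupancy_truth(T, p))
    if start_state is None:
        state = 1 if rng.random() < f else 0
    else:
        state = int(start_state)

    # dwell-run generation: geometric run lengths, exact for the discrete chain
    states = np.empty(n, dtype=np.int8)
    pos = 0
    while pos < n:
        p_switch = p_unfold if state == 1 else p_fold
        run = n - pos if p_switch <= 0 else min(int(rng.geometric(p_switch)), n - pos)
        states[pos : pos + run] = state
        pos += run
        state = 1 - state

    native = states == 1
    values = np.where(
        native,
        rng.normal(emission.native_mean, emission.native_sd, n),
        rng.normal(emission.unfolded_mean, emission.unfolded_sd, n),
    )
    meta = {
        "seed": seed,
        "state_path": states,
        "k_f": k_f,
        "k_u": k_u,
        "truth_occupancy": f,
    }
    if emission.overlapping:
        meta["overlapping_emissions"] = True
    return TemperatureSeries(
        temperature=T, dt=dt, values=np.abs(values), quantity="rmsd", meta=meta
    )


def generate_conformations(
    reference: Structure, rmsd_targets, seed: int = 0, max_iter: int = 100
) -> list[Structure]:
    """Structures at prescribed post-superposition Cα-RMSDs from a reference.

    Each structure is the reference plus an isotropic Gaussian displacement,
    iteratively rescaled until its optimally superposed RMSD to the
    reference matches the target within 1e-6 Å.
    """
    if len(reference) < 3:
        raise ValueError("reference needs >= 3 residues")
    targets = [float(t) for t in np.atleast_1d(rmsd_targets)]
    if any(t < 0 for t in targets):
        raise ValueError("rmsd targets must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for k, target in enumerate(targets):
        if target == 0.0:
            out.append(
                Structure(reference.residue_numbers, reference.coords.copy(),
                          label=f"conf{k}_rmsd0")
            )
            continue
        noise = rng.standard_normal(reference.coords.shape)
        coords = reference.coords + noise * max(target, 1.0)
        for _ in range(max_iter):
            cand = Structure(reference.residue_numbers, coords, label=f"conf{k}")
            moved, _, rmsd = superpose(cand, reference)
            if abs(rmsd - target) < 1e-7:
                coords = moved.coords
                break
            coords = reference.coords + (moved.coords - reference.coords) * (target / rmsd)
        else:
            raise RuntimeError(f"rmsd target {target} did not converge")
        out.append(Structure(reference.residue_numbers, coords,
                             label=f"conf{k}_rmsd{target:g}"))
    return out


def generate_remd_dataset(
    ladder,
    p: TwoStateParams = TwoStateParams(),
    n_per_t: int = 10000,
    seed: int = 0,
    emission: Emission = Emission(),
    dt: float = 0.002,
) -> SyntheticDataset:
    """One energy series and one order-parameter series per ladder
    temperature, with the generating truth embedded."""
    ladder = np.asarray(ladder, dtype=float)
    if ladder.size == 0:
        raise ValueError("empty temperature ladder")
    if np.any(np.diff(ladder) <= 0):
        raise ValueError("ladder must be strictly increasing")
    energy = [sample_energy_series(T, n_per_t, p, seed=seed, dt=dt) for T in ladder]
    order = [
        sample_order_series(T, n_per_t, p, emission=emission, seed=seed, dt=dt)
        for T in ladder
    ]
    return SyntheticDataset(energy_series=energy, order_series=order, truth=p, seed=seed)
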