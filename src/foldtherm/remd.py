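"""Toy replica-exchange engine over analytic 1-D potentials.

A full temperature replica-exchange protocol — a geometric temperature
ladder, overdamped Langevin dynamics per replica, Metropolis swap attempts
between neighboring ladder temperatures on an alternating even/odd pair
schedule, and replica↔temperature bookkeeping — exercised on a double-well
potential V(x) = h (x² − 1)² whose barrier height h is known exactly.
Demultiplexing the output through :func:`foldtherm.io.demux_replicas` and
histogramming the 1-D coordinate lets every stage of the thermodynamic
pipeline be validated against an analytic landscape.

The coordinate is dimensionless; energies are kcal/mol, temperatures K.
The Langevin update is Euler–Maruyama:

    x ← x − V'(x) · dt / γ + sqrt(2 R T dt / γ) · ξ,   ξ ~ N(0, 1)

and a swap between the replicas at temperatures T_i, T_j with energies
E_i, E_j is accepted with probability min(1, exp[(β_i − β_j)(E_i − E_j)]),
β = 1/(RT).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import R_KCAL
from .io import ReplicaRecords, TemperatureSeries


class IntegrationError(RuntimeError):
    """The Langevin integration diverged (time step too large)."""


@dataclass(frozen=True)
class ToyPotential:
    """Symmetric double well V(x) = h (x² − 1)², minima at x = ±1."""

    barrier: float  # kcal/mol

    def __post_init__(self):
        if self.barrier <= 0:
            raise ValueError("barrier must be positive")

    def value(self, x):
        return self.barrier * (np.asarray(x) ** 2 - 1.0) ** 2

    def grad(self, x):
        x = np.asarray(x)
        return 4.0 * self.barrier * x * (x**2 - 1.0)


def geometric_ladder(t_min: float, t_max: float, n: int) -> np.ndarray:
    """Geometric (exponentially spaced) temperature ladder.

    T_k = t_min · (t_max/t_min)^(k/(n−1)); the endpoints are exact and the
    ratio of consecutive temperatures is constant.
    """
    if not 0 < t_min < t_max:
        raise ValueError("need 0 < t_min < t_max")
    if n < 2:
        raise ValueError("need n >= 2")
    ladder = np.geomspace(t_min, t_max, n)
    ladder[0], ladder[-1] = t_min, t_max
    return ladder


def exchange_probability(e_i: float, e_j: float, t_i: float, t_j: float) -> float:
    """Metropolis acceptance probability for swapping two replicas."""
    if t_i <= 0 or t_j <= 0:
        raise ValueError("temperatures must be positive")
    beta_i = 1.0 / (R_KCAL * t_i)
    beta_j = 1.0 / (R_KCAL * t_j)
    return float(min(1.0, np.exp((beta_i - beta_j) * (e_i - e_j))))


@dataclass
class ToyRemdResult:
    """Engine output: per-replica traces, bookkeeping and acceptance."""

    coordinate_series: dict[int, TemperatureSeries]
    energy_series: dict[int, TemperatureSeries]
    records: ReplicaRecords
    acceptance: dict[int, float]  # neighbor-pair index -> acceptance rate
    ladder: np.ndarray


def run_toy_remd(
    potential: ToyPotential,
    ladder,
    n_steps: int,
    exchange_interval: int,
    dt: float = 0.01,
    friction: float = 1.0,
    seed: int = 0,
    sample_interval: int = 10,
    x0: float = -1.0,
) -> ToyRemdResult:
    """Run the toy replica-exchange simulation.

    One replica per ladder temperature, all started at ``x0``.  Swap
    attempts run every ``exchange_interval`` steps over alternating
    even/odd neighbor pairs.  Samples (coordinate and potential energy)
    are recorded every ``sample_interval`` steps together with the
    replica↔temperature assignment, which is a bijection at every sample.
    """
    if n_steps < 1 or exchange_interval < 1 or dt <= 0 or friction <= 0:
        raise ValueError("steps, exchange interval, dt and friction must be positive")
    ladder = np.asarray(ladder, dtype=float)
    n_rep = ladder.size
    rng = np.random.default_rng(seed)

    x = np.full(n_rep, float(x0))  # indexed by replica id
    temp_of_replica = ladder.copy()  # replica k starts at ladder[k]
    replica_at_temp = np.arange(n_rep)  # ladder position -> replica id

    n_samples = n_steps // sample_interval
    coords = np.empty((n_rep, n_samples))
    energies = np.empty((n_rep, n_samples))
    rec_t, rec_r, rec_T = [], [], []

    attempts = dict.fromkeys(range(n_rep - 1), 0)
    accepts = dict.fromkeys(range(n_rep - 1), 0)
    attempt_counter = 0
    sample_idx = 0

    for step in range(1, n_steps + 1):
        noise = rng.standard_normal(n_rep)
        x = (
            x
            - potential.grad(x) * dt / friction
            + np.sqrt(2.0 * R_KCAL * temp_of_replica * dt / friction) * noise
        )
        if np.any(np.abs(x) > 1e3):
            raise IntegrationError(
                f"coordinate diverged at step {step}; reduce dt (currently {dt})"
            )

        if step % exchange_interval == 0 and n_rep > 1:
            start = attempt_counter % 2  # alternate even/odd neighbor pairs
            attempt_counter += 1
            energy = potential.value(x)
            for pair in range(start, n_rep - 1, 2):
                ri, rj = replica_at_temp[pair], replica_at_temp[pair + 1]
                p = exchange_probability(
                    energy[ri], energy[rj], ladder[pair], ladder[pair + 1]
                )
                attempts[pair] += 1
                if rng.random() < p:
                    accepts[pair] += 1
                    replica_at_temp[pair], replica_at_temp[pair + 1] = rj, ri
                    temp_of_replica[rj] = ladder[pair]
                    temp_of_replica[ri] = ladder[pair + 1]

        if step % sample_interval == 0:
            coords[:, sample_idx] = x
            energies[:, sample_idx] = potential.value(x)
            for r in range(n_rep):
                rec_t.append(sample_idx)
                rec_r.append(r)
                rec_T.append(temp_of_replica[r])
            sample_idx += 1

    dt_ns = dt * sample_interval  # nominal sample spacing
    coordinate_series = {
        r: TemperatureSeries(
            temperature=float(ladder[r]), dt=dt_ns, values=coords[r],
            quantity="coordinate", meta={"replica": r},
        )
        for r in range(n_rep)
    }
    energy_series = {
        r: TemperatureSeries(
            temperature=float(ladder[r]), dt=dt_ns, values=energies[r],
            quantity="energy", meta={"replica": r},
        )
        for r in range(n_rep)
    }
    acceptance = {
        k: (accepts[k] / attempts[k] if attempts[k] else float("nan"))
        for k in attempts
    }
    records = ReplicaRecords(
        time_index=np.array(rec_t), replica=np.array(rec_r), temperature=np.array(rec_T)
    )
    return ToyRemdResult(
        coordinate_series=coordinate_series,
        energy_series=energy_series,
        records=records,
        acceptance=acceptance,
        ladder=ladder,
    )
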