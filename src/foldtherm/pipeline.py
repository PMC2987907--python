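"""Orchestration of the two standard analyses.

``run_melt_analysis`` takes a replica-exchange-style dataset (per-
temperature energy and order-parameter series) and produces, per
structural component: the melting curve with block errors, the van't Hoff
fit, and the fluctuation heat-capacity / excess heat-capacity profiles
with transition peaks and denaturation enthalpies.

``run_kinetics_analysis`` takes constant-temperature RMSD trajectories
and produces the folding-event table, the trajectory-count folding time
with friction correction, optionally a free-energy profile / barrier /
Kramers estimate, and committor summaries when P_fold run outcomes are
supplied.

Reports are plain dicts (JSON-serializable) embedding the configuration
hash and package version; a rerun on the same inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

from . import __version__
from .io import TemperatureSeries
from .kinetics import (
    barrier_height,
    cmd_folding_time,
    detect_folding_event,
    free_energy_profile,
    friction_correct,
    kramers_estimate,
    pfold_estimate,
    scale_prefactor,
)
from .orderparams import DEFAULT_CUTOFFS, indicator_series
from .thermo import (
    excess_heat_capacity,
    find_peak_windows,
    fit_vant_hoff,
    heat_capacity_profile,
    melting_curve,
    peak_enthalpy,
)


@dataclass
class AnalysisConfig:
    """Defaults of the standard FSD-1 protocol.

    cutoffs: folded-state cutoffs per component (Å); reference_temperature:
    where bimodal cutoffs are derived (K); error/convergence block counts;
    folding-event rule (Å, ns); P_fold protocol size; friction ratio for
    rescaling low-friction folding times; Kramers prefactor from the
    28-residue linear length scaling.
    """

    cutoffs: dict = field(default_factory=lambda: dict(DEFAULT_CUTOFFS))
    reference_temperature: float = 323.0
    error_blocks: int = 2
    convergence_blocks: int = 5
    event_cutoff: float = 3.0
    event_min_dwell: float = 30.0
    pfold_runs: int = 40
    pfold_duration: float = 200.0
    friction_ratio: float = 60.0
    n_residues: int = 28

    def __post_init__(self):
        for name in ("reference_temperature", "event_cutoff", "event_min_dwell",
                     "pfold_duration", "friction_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for key, val in self.cutoffs.items():
            if val <= 0:
                raise ValueError(f"cutoff for {key!r} must be positive")

    @property
    def prefactor(self) -> float:
        return scale_prefactor(self.n_residues)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _group_by_component(order_series: Sequence[TemperatureSeries]) -> dict:
    groups: dict[str, list[TemperatureSeries]] = {}
    for s in order_series:
        key = s.meta.get("component", s.quantity)
        groups.setdefault(key, []).append(s)
    return groups


def run_melt_analysis(dataset, config: AnalysisConfig | None = None) -> dict:
    """Melting-curve, van't Hoff and heat-capacity analysis of a
    replica-exchange-style dataset.

    ``dataset`` needs ``energy_series`` and ``order_series`` attributes
    (e.g. :class:`foldtherm.synth.SyntheticDataset`), each a list of
    per-temperature series.
    """
    config = config or AnalysisConfig()
    energy = list(dataset.energy_series)
    order = list(dataset.order_series)
    if not order or len({s.temperature for s in order}) < 2:
        raise ValueError("melt analysis needs order-parameter series at >= 2 temperatures")

    report: dict = {
        "analysis": "melt",
        "config_hash": config.hash(),
        "version": __version__,
        "components": {},
    }

    for name, series in sorted(_group_by_component(order).items()):
        cutoff = config.cutoffs.get(name, config.event_cutoff)
        indicators = [indicator_series(s, cutoff) for s in series]
        curve = melting_curve(indicators, n_blocks=config.error_blocks)
        fit = fit_vant_hoff(curve)
        report["components"][name] = {
            "cutoff": cutoff,
            "n_samples": int(sum(len(s) for s in series)),
            "temperatures": curve.temperatures.tolist(),
            "folded_fraction": curve.folded_fraction.tolist(),
            "errors": curve.errors.tolist(),
            "fit": {
                "t_m": fit.t_m, "t_m_err": fit.t_m_err,
                "dh_m": fit.dh_m, "dh_m_err": fit.dh_m_err,
                "dcp": fit.dcp, "dcp_err": fit.dcp_err,
                "ds_m": fit.ds_m, "flags": fit.flags,
            },
        }

    if energy:
        profile = excess_heat_capacity(
            heat_capacity_profile(energy, n_blocks=config.error_blocks)
        )
        peaks = []
        for window in find_peak_windows(profile):
            try:
                pk = peak_enthalpy(profile, window)
            except ValueError:
                continue
            peaks.append(
                {"peak_temperature": pk.peak_temperature, "dh_d": pk.dh_d,
                 "window": list(pk.window)}
            )
        report["heat_capacity"] = {
            "temperatures": profile.temperatures.tolist(),
            "cp": profile.cp.tolist(),
            "excess_cp": profile.excess_cp.tolist(),
            "baseline": profile.baseline,
            "peaks": peaks,
        }
    return report


def run_kinetics_analysis(
    trajectories: Sequence[TemperatureSeries],
    config: AnalysisConfig | None = None,
    committor_outcomes: Sequence[tuple[int, int]] | None = None,
    profile_series: TemperatureSeries | None = None,
    folded_basin: tuple[float, float] = (0.0, 3.0),
    unfolded_basin: tuple[float, float] = (5.0, 10.0),
) -> dict:
    """Folding-time analysis of constant-temperature RMSD trajectories."""
    config = config or AnalysisConfig()
    if not trajectories:
        raise ValueError("need at least one trajectory")

    events = []
    for k, tr in enumerate(trajectories):
        t0 = detect_folding_event(tr, config.event_cutoff, config.event_min_dwell)
        events.append({"trajectory": k, "t_fold_ns": t0})
    n_folded = sum(1 for e in events if e["t_fold_ns"] is not None)
    duration_us = min(len(tr) * tr.dt for tr in trajectories) * 1e-3

    count = cmd_folding_time(len(trajectories), duration_us, n_folded)
    corrected = friction_correct(count, config.friction_ratio)

    report: dict = {
        "analysis": "kinetics",
        "config_hash": config.hash(),
        "version": __version__,
        "events": events,
        "counting": {
            "n_traj": len(trajectories),
            "duration_us": duration_us,
            "n_folded": n_folded,
            "tau_us": count.tau,
            "tau_err_us": count.tau_err,
            "lower_bound": count.lower_bound,
            "tau_friction_corrected_us": corrected.tau,
            "friction_ratio": config.friction_ratio,
        },
    }

    if profile_series is not None:
        profile = free_energy_profile(
            profile_series, bins=40, temperature=profile_series.temperature
        )
        dg, q_star = barrier_height(profile, folded_basin, unfolded_basin)
        kr = kramers_estimate(dg, profile_series.temperature, config.prefactor)
        report["barrier"] = {
            "dg_star": dg,
            "location": q_star,
            "temperature": profile_series.temperature,
            "prefactor_us": config.prefactor,
            "tau_kramers_us": kr.tau,
        }

    if committor_outcomes is not None:
        summaries = []
        for n_fold, n_unfold in committor_outcomes:
            pf = pfold_estimate(n_fold, n_unfold)
            summaries.append(
                {"n_trajectories": pf.n_trajectories, "n_folded": pf.n_folded,
                 "p_fold": pf.p_fold, "ci": [pf.ci_low, pf.ci_high],
                 "is_transition_state": pf.is_transition_state}
            )
        report["pfold"] = summaries
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
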