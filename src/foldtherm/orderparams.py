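"""Order parameters for folding: segment Cα-RMSD and core radius of gyration.

The four standard progress variables for the 28-residue ββα miniprotein
FSD-1 are the Cα-RMSD of the N-terminal β-hairpin (residues 3–13), of the
C-terminal α-helix (residues 14–26) and of the whole protein (residues
3–26) against a reference structure, plus the radius of gyration of the
hydrophobic core (residues 5, 7, 12, 18, 21, 22, 25).  Helpers to build
those specs against any reference are provided.

Folded/unfolded cutoffs are derived from the bimodal distribution of an
order parameter near the melting temperature: a two-component Gaussian
mixture is fit and the cutoff is the equal-posterior point between the
component means.  Frames classify as folded when the value is strictly
below the cutoff (small RMSD / small Rg = formed); a value exactly at the
cutoff counts as unfolded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .io import Structure, TemperatureSeries

#: Residue selections of the four standard structural components.
HAIRPIN_RESIDUES = tuple(range(3, 14))
HELIX_RESIDUES = tuple(range(14, 27))
WHOLE_RESIDUES = tuple(range(3, 27))
CORE_RESIDUES = (5, 7, 12, 18, 21, 22, 25)

#: Folded-state cutoffs (Å) for the four components.
DEFAULT_CUTOFFS = {
    "whole": 3.0,
    "hairpin": 3.0,
    "core": 7.7,
    "helix": 3.7,
}


class UnimodalError(ValueError):
    """The distribution does not separate into two populations; choose a
    cutoff manually."""


@dataclass
class OrderParamSpec:
    """Definition of one order parameter.

    kind: ``"rmsd"`` (needs a reference structure) or ``"rg"``.
    selection: 1-based residue numbers entering the calculation.
    cutoff: folded-state cutoff in Å, or None if not yet derived.
    """

    kind: str
    selection: tuple
    reference: Structure | None = None
    cutoff: float | None = None
    name: str = ""

    def __post_init__(self):
        if self.kind not in ("rmsd", "rg"):
            raise ValueError("kind must be 'rmsd' or 'rg'")
        if not self.selection:
            raise ValueError("selection must be non-empty")
        self.selection = tuple(int(r) for r in self.selection)
        if self.kind == "rmsd" and self.reference is None:
            raise ValueError("rmsd spec requires a reference structure")


def standard_specs(reference: Structure, cutoffs: dict | None = None) -> dict[str, OrderParamSpec]:
    """The four standard component specs against ``reference``."""
    c = dict(DEFAULT_CUTOFFS)
    if cutoffs:
        c.update(cutoffs)
    return {
        "hairpin": OrderParamSpec("rmsd", HAIRPIN_RESIDUES, reference, c["hairpin"], "hairpin"),
        "helix": OrderParamSpec("rmsd", HELIX_RESIDUES, reference, c["helix"], "helix"),
        "whole": OrderParamSpec("rmsd", WHOLE_RESIDUES, reference, c["whole"], "whole"),
        "core": OrderParamSpec("rg", CORE_RESIDUES, cutoff=c["core"], name="core"),
    }


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

@dataclass
class Transform:
    """Rigid transform y = R (x − mobile_center) + ref_center."""

    rotation: np.ndarray
    mobile_center: np.ndarray
    ref_center: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return (coords - self.mobile_center) @ self.rotation.T + self.ref_center


def superpose(
    mobile: Structure, reference: Structure, selection=None
) -> tuple[Structure, Transform, float]:
    """Optimal least-squares rigid superposition of ``mobile`` onto
    ``reference`` over ``selection`` (default: all shared residues).

    Returns the transformed structure, the transform, and the selection
    RMSD.  The rotation is proper (det +1); reflections are never used.
    """
    if selection is None:
        selection = tuple(int(r) for r in reference.residue_numbers)
    if len(selection) < 3:
        raise ValueError("need >= 3 residues to superpose")
    ref_xyz = reference.subset(selection)
    mob_xyz = mobile.subset(selection)

    ref_c = ref_xyz.mean(axis=0)
    mob_c = mob_xyz.mean(axis=0)
    rot, rssd = Rotation.align_vectors(ref_xyz - ref_c, mob_xyz - mob_c)
    tf = Transform(rotation=rot.as_matrix(), mobile_center=mob_c, ref_center=ref_c)
    moved = Structure(
        residue_numbers=mobile.residue_numbers,
        coords=tf.apply(mobile.coords),
        label=mobile.label,
    )
    rmsd = float(rssd / np.sqrt(len(selection)))
    return moved, tf, rmsd


def ca_rmsd(target: Structure, spec: OrderParamSpec, superpose_selection=None) -> float:
    """Cα-RMSD of ``target`` against the spec's reference after optimal
    superposition.

    By default the superposition uses the same selection as the RMSD
    (segment RMSDs are locally superposed).  Pass ``superpose_selection``
    to superpose globally and evaluate the RMSD locally instead.
    """
    if spec.kind != "rmsd":
        raise ValueError("spec.kind must be 'rmsd'")
    fit_sel = spec.selection if superpose_selection is None else tuple(superpose_selection)
    moved, _, _ = superpose(target, spec.reference, fit_sel)
    diff = moved.subset(spec.selection) - spec.reference.subset(spec.selection)
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def radius_of_gyration(target: Structure, spec: OrderParamSpec) -> float:
    """Unweighted radius of gyration of the spec's selection (Å)."""
    if spec.kind != "rg":
        raise ValueError("spec.kind must be 'rg'")
    xyz = target.subset(spec.selection)
    centroid = xyz.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((xyz - centroid) ** 2, axis=1))))


def evaluate(target: Structure, spec: OrderParamSpec, **kwargs) -> float:
    """Evaluate an order parameter of either kind."""
    if spec.kind == "rmsd":
        return ca_rmsd(target, spec, **kwargs)
    return radius_of_gyration(target, spec)


# ---------------------------------------------------------------------------
# Cutoff derivation and classification
# ---------------------------------------------------------------------------

def bimodal_cutoff(
    values, seed: int = 0, n_init: int = 50
) -> tuple[float, dict]:
    """Cutoff separating the two populations of a bimodal distribution.

    Fits a two-component Gaussian mixture (EM, ``n_init`` restarts, fixed
    seed) and returns the equal-posterior point between the component
    means, plus metadata with the fitted means, standard deviations and
    weights.  Raises :class:`UnimodalError` when the mixture degenerates
    (a weight below 0.02, means closer than a quarter of the pooled
    standard deviation, or no density valley between the components).
    """
    from sklearn.mixture import GaussianMixture

    if isinstance(values, TemperatureSeries):
        values = values.values
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    if x.size < 100:
        raise ValueError("need >= 100 samples to derive a cutoff")
    gm = GaussianMixture(n_components=2, n_init=n_init, random_state=seed)
    gm.fit(x)
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]

    pooled_sd = float(np.sqrt(np.mean(sds**2)))
    if weights.min() < 0.02 or (means[1] - means[0]) < pooled_sd / 4:
        raise UnimodalError(
            "distribution appears unimodal; set the cutoff manually "
            f"(means {means[0]:.3g}/{means[1]:.3g}, weights "
            f"{weights[0]:.3g}/{weights[1]:.3g})"
        )

    def log_posterior_diff(v):
        lo = np.log(weights) - 0.5 * ((v - means) / sds) ** 2 - np.log(sds)
        return lo[0] - lo[1]

    def mixture_pdf(v):
        return float(
            np.sum(
                weights / (sds * np.sqrt(2 * np.pi))
                * np.exp(-0.5 * ((v - means) / sds) ** 2)
            )
        )

    lo, hi = means[0], means[1]
    if log_posterior_diff(lo) <= 0 or log_posterior_diff(hi) >= 0:
        raise UnimodalError("no equal-posterior point between the component means")
    cutoff = float(brentq(log_posterior_diff, lo, hi))
    # the two populations must be separated by a genuine density valley:
    # on unimodal data the EM split puts the crossing near the mode instead
    if mixture_pdf(cutoff) >= min(mixture_pdf(means[0]), mixture_pdf(means[1])):
        raise UnimodalError(
            "no density valley between the fitted components; distribution "
            "appears unimodal — set the cutoff manually"
        )
    meta = {
        "means": means.tolist(),
        "sds": sds.tolist(),
        "weights": weights.tolist(),
    }
    return cutoff, meta


def classify_frames(values, cutoff: float) -> np.ndarray:
    """Folded indicator per frame: folded iff value < cutoff.

    Both RMSD and Rg order parameters are 'small = formed', so the same
    strict inequality applies; a value exactly at the cutoff is unfolded.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if isinstance(values, TemperatureSeries):
        values = values.values
    return np.asarray(values, dtype=float) < cutoff


def indicator_series(series: TemperatureSeries, cutoff: float) -> TemperatureSeries:
    """A 0/1 folded-indicator series from an order-parameter series."""
    return TemperatureSeries(
        temperature=series.temperature,
        dt=series.dt,
        values=classify_frames(series, cutoff).astype(float),
        quantity="indicator",
        meta={**series.meta, "cutoff": cutoff, "source_quantity": series.quantity},
    )
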