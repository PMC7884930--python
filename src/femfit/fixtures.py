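"""Synthetic specimen generators for the three calibration case studies.

Each case writes paired files to an output directory — one model-definition
file (``<name>.model``, YAML) plus one observation file (``<name>.dat``,
whitespace text) per specimen — and a ``manifest.yaml`` recording the true
parameters so recovery tests can check themselves.

The defaults reproduce the study conditions the calibration cases target:

* ``bone_greyscale``: 22 specimens, one apparent-stiffness scalar each,
  inter-specimen coefficient of variance 0.47 (high-variance bone data);
* ``osteodisc_goh``: 6 specimens, one nonlinear force-displacement curve
  each, CoV 0.05 (low-variance disc data);
* ``interface_slice``: 3 specimens, one 8-16-point radial-displacement
  list each, CoV 0.05.

Noise is one mean-preserving lognormal factor per specimen (observations
stay positive; the quoted CoV is between specimens).  Specimen-to-specimen
structural variation (element counts, greyscale fields, geometry, lamella
stiffness) is drawn from documented uniform ranges, so group calibration is
a genuine multi-model problem rather than n copies of one model.  Identical
(recipe, seed) pairs reproduce byte-identical files.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import forward_models as fm

__all__ = ["Case", "FixtureRecipe", "generate_case", "DEFAULT_TRUE_PARAMS"]


class Case(str, enum.Enum):
    BONE_GREYSCALE = "bone_greyscale"
    OSTEODISC_GOH = "osteodisc_goh"
    INTERFACE_SLICE = "interface_slice"


DEFAULT_N_SPECIMENS = {
    Case.BONE_GREYSCALE: 22,
    Case.OSTEODISC_GOH: 6,
    Case.INTERFACE_SLICE: 3,
}

DEFAULT_NOISE_COV = {
    Case.BONE_GREYSCALE: 0.47,
    Case.OSTEODISC_GOH: 0.05,
    Case.INTERFACE_SLICE: 0.05,
}

# true parameters used when a recipe does not override them
DEFAULT_TRUE_PARAMS = {
    Case.BONE_GREYSCALE: {"slope": 3000.0},  # MPa per unit normalised greyscale
    Case.OSTEODISC_GOH: {"k1": 1.0, "k2": 30.0},  # MPa, -
    Case.INTERFACE_SLICE: {"k_r": 2.0, "k_t": 1.0},  # N/mm
}


@dataclass(frozen=True)
class FixtureRecipe:
    """Recipe for one synthetic case: size, truth, noise, and seed."""

    case: Case
    n_specimens: int | None = None
    true_params: dict | None = None
    noise_cov: float | None = None
    seed: int = 0

    def resolved(self) -> "FixtureRecipe":
        case = Case(self.case)
        n = self.n_specimens if self.n_specimens is not None else DEFAULT_N_SPECIMENS[case]
        noise = self.noise_cov if self.noise_cov is not None else DEFAULT_NOISE_COV[case]
        truth = dict(DEFAULT_TRUE_PARAMS[case])
        if self.true_params:
            truth.update(self.true_params)
        if n < 1:
            raise ValueError("n_specimens must be >= 1")
        if noise < 0:
            raise ValueError("noise_cov must be >= 0")
        return FixtureRecipe(case, n, truth, noise, self.seed)


def _lognormal_factor(rng: np.random.Generator, cov: float) -> float:
    """Mean-1 multiplicative lognormal noise at the given CoV."""
    if cov == 0:
        return 1.0
    sigma = float(np.sqrt(np.log1p(cov**2)))
    return float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))


def _bone_specimen(rng: np.random.Generator) -> fm.GreyscaleLattice:
    # ranges keep structural CoV ~0.1 so the recipe's noise CoV dominates
    # the total inter-specimen variance of the observed stiffness
    n_el = int(rng.integers(8, 13))
    return fm.GreyscaleLattice(
        greyscales=rng.uniform(0.5, 0.9, n_el),
        lengths=rng.uniform(1.2, 1.8, n_el),
        areas=rng.uniform(90.0, 110.0, n_el),
        displacement=0.5,
    )


def _goh_specimen(rng: np.random.Generator):
    fixed = fm.GOHFixedParams(
        c10=0.1,
        kappa=0.1,
        theta_deg=30.0,
        d_comp=0.0,
        specimen_area=float(rng.uniform(500.0, 750.0)),
        specimen_height=float(rng.uniform(7.0, 9.0)),
    )
    displacements = np.linspace(0.0, 1.2, 13)
    return fixed, displacements


def _interface_specimen(rng: np.random.Generator) -> fm.InterfaceLattice:
    n_lam = int(rng.integers(4, 7))
    m = int(rng.integers(6, 9))
    n_tracked = int(rng.integers(8, 17))
    # observe free-lamella nodes only (lamella 0 is fixed, displacement 0)
    candidates = [(i, j) for i in range(1, n_lam) for j in range(m)]
    idx = rng.choice(len(candidates), size=min(n_tracked, len(candidates)), replace=False)
    tracked = tuple(candidates[k] for k in sorted(idx))
    # linearly graded radial pull excites shear so k_t is identifiable
    forces = 0.5 * np.linspace(0.5, 1.5, m) / m
    return fm.InterfaceLattice(
        n_lamellae=n_lam,
        nodes_per_lamella=m,
        lamella_stiffness=rng.uniform(4.0, 8.0, n_lam),
        tracked_points=tracked,
        applied_forces=forces,
        radial_gap=0.5,
        tangential_spacing=0.5,
    )


def _model_doc(case: Case, specimen) -> dict:
    if case is Case.BONE_GREYSCALE:
        lat = specimen
        return {
            "kind": case.value,
            "greyscales": lat.greyscales.tolist(),
            "lengths": lat.lengths.tolist(),
            "areas": lat.areas.tolist(),
            "displacement": lat.displacement,
        }
    if case is Case.OSTEODISC_GOH:
        fixed, disp = specimen
        return {
            "kind": case.value,
            "c10": fixed.c10,
            "kappa": fixed.kappa,
            "theta_deg": fixed.theta_deg,
            "d_comp": fixed.d_comp,
            "specimen_area": fixed.specimen_area,
            "specimen_height": fixed.specimen_height,
            "displacements": np.asarray(disp).tolist(),
        }
    lat = specimen
    return {
        "kind": case.value,
        "n_lamellae": lat.n_lamellae,
        "nodes_per_lamella": lat.nodes_per_lamella,
        "lamella_stiffness": lat.lamella_stiffness.tolist(),
        "tracked_points": [list(tp) for tp in lat.tracked_points],
        "applied_forces": lat.applied_forces.tolist(),
        "radial_gap": lat.radial_gap,
        "tangential_spacing": lat.tangential_spacing,
    }


def _write_dat(path: Path, payload) -> None:
    from .io import write_dat  # local import to avoid a cycle at import time

    write_dat(path, payload)


def generate_case(recipe: FixtureRecipe, out_dir) -> dict:
    """Write paired model/.dat files for one case; return the manifest.

    For each specimen the true-parameter forward model is run and its
    output perturbed by one lognormal factor at the recipe's CoV.  The
    manifest (also written as ``manifest.yaml``) records the truth, the
    noise level, and the per-specimen noise factors.
    """
    recipe = recipe.resolved()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(recipe.seed)
    case = Case(recipe.case)
    truth = recipe.true_params

    specimens = []
    for i in range(recipe.n_specimens):
        name = f"specimen_{i + 1:02d}"
        factor = 1.0
        if case is Case.BONE_GREYSCALE:
            lat = _bone_specimen(rng)
            outp = fm.greyscale_apparent_stiffness(
                lat, fm.GreyscaleMapping(truth["slope"])
            )
            factor = _lognormal_factor(rng, recipe.noise_cov)
            payload = float(outp.value) * factor
            doc = _model_doc(case, lat)
        elif case is Case.OSTEODISC_GOH:
            fixed, disp = _goh_specimen(rng)
            outp = fm.goh_force_displacement(
                fm.GOHParams(truth["k1"], truth["k2"]), fixed, disp
            )
            factor = _lognormal_factor(rng, recipe.noise_cov)
            curve = outp.value
            payload = fm.Curve(curve.x, curve.y * factor)
            doc = _model_doc(case, (fixed, disp))
        else:
            lat = _interface_specimen(rng)
            outp = fm.interface_displacements(
                lat, fm.InterfaceStiffness(truth["k_r"], truth["k_t"])
            )
            factor = _lognormal_factor(rng, recipe.noise_cov)
            payload = np.asarray(outp.value) * factor
            doc = _model_doc(case, lat)
        if outp.failed:
            raise RuntimeError(f"true-parameter forward model failed for {name}")

        with open(out / f"{name}.model", "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)
        _write_dat(out / f"{name}.dat", payload)
        specimens.append({"name": name, "noise_factor": factor})

    manifest = {
        "case": case.value,
        "n_specimens": recipe.n_specimens,
        "true_params": {k: float(v) for k, v in truth.items()},
        "noise_cov": float(recipe.noise_cov),
        "seed": int(recipe.seed),
        "specimens": specimens,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
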