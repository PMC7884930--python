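"""Readers/writers for observation, model-definition and config files, and
the end-to-end calibration driver.

Observation files (``.dat``) are whitespace-delimited plain text: a single
number is a scalar, one column is a list, two columns are a curve (x then
y, x strictly increasing).  Lines starting with ``#`` are comments.  Each
observation is paired with a model-definition file (``.model``, YAML) of
the same basename, mirroring the convention that experimental data carries
the model file's name with a .dat extension.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import forward_models as fm
from .forward_models import Curve, ForwardModel
from .objective import (
    Aggregation,
    Comparison,
    ErrorForm,
    NormalisationReference,
    Observation,
    ObjectiveSpec,
)
from .optimise import (
    ConfidenceReport,
    OptimisationResult,
    OptimiserOptions,
    ParameterSet,
    confidence_intervals,
    minimise,
    write_history,
)

__all__ = [
    "read_dat",
    "write_dat",
    "read_model",
    "CalibrationConfig",
    "load_config",
    "dump_config",
    "run_calibration",
]

log = logging.getLogger("femfit")


# ---------------------------------------------------------------------------
# .dat observation files
# ---------------------------------------------------------------------------


def read_dat(path) -> float | np.ndarray | Curve:
    """Read an observation file, auto-detecting scalar / list / curve."""
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            tokens = body.split()
            try:
                rows.append([float(t) for t in tokens])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric token ({exc})") from exc
    if not rows:
        raise ValueError(f"{path}: no data")
    widths = {len(r) for r in rows}
    if widths == {1}:
        values = np.array([r[0] for r in rows])
        return float(values[0]) if values.size == 1 else values
    if widths == {2}:
        x = np.array([r[0] for r in rows])
        y = np.array([r[1] for r in rows])
        if np.any(np.diff(x) <= 0):
            bad = int(np.flatnonzero(np.diff(x) <= 0)[0]) + 2
            raise ValueError(f"{path}: curve x not strictly increasing at row {bad}")
        return Curve(x, y)
    raise ValueError(f"{path}: inconsistent column counts {sorted(widths)}")


def write_dat(path, payload) -> None:
    """Write a scalar, list, or Curve in the .dat dialect."""
    path = Path(path)
    with open(path, "w") as fh:
        if isinstance(payload, Curve):
            for xv, yv in zip(payload.x, payload.y):
                fh.write(f"{xv:.17g} {yv:.17g}\n")
        elif np.ndim(payload) == 0:
            fh.write(f"{float(payload):.17g}\n")
        else:
            for v in np.asarray(payload, dtype=float):
                fh.write(f"{v:.17g}\n")


# ---------------------------------------------------------------------------
# model-definition files
# ---------------------------------------------------------------------------

MODEL_SUFFIX = ".model"


def read_model(path) -> ForwardModel:
    """Build a ForwardModel from a YAML model-definition file.

    The ``kind`` key names one of the built-in model families; the rest of
    the document is that family's construction data (see fixtures module
    for the schema written by the generators).
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "kind" not in doc:
        raise ValueError(f"{path}: not a model definition (missing 'kind')")
    kind = doc["kind"]
    name = path.stem
    if kind == "bone_greyscale":
        lattice = fm.GreyscaleLattice(
            greyscales=np.asarray(doc["greyscales"], dtype=float),
            lengths=np.asarray(doc["lengths"], dtype=float),
            areas=np.asarray(doc["areas"], dtype=float),
            displacement=float(doc["displacement"]),
        )
        return fm.make_greyscale_model(name, lattice)
    if kind == "osteodisc_goh":
        fixed = fm.GOHFixedParams(
            c10=float(doc["c10"]),
            kappa=float(doc["kappa"]),
            theta_deg=float(doc["theta_deg"]),
            d_comp=float(doc.get("d_comp", 0.0)),
            specimen_area=float(doc["specimen_area"]),
            specimen_height=float(doc["specimen_height"]),
        )
        return fm.make_goh_model(name, fixed, np.asarray(doc["displacements"], dtype=float))
    if kind == "interface_slice":
        lattice = fm.InterfaceLattice(
            n_lamellae=int(doc["n_lamellae"]),
            nodes_per_lamella=int(doc["nodes_per_lamella"]),
            lamella_stiffness=np.asarray(doc["lamella_stiffness"], dtype=float),
            tracked_points=tuple(tuple(tp) for tp in doc["tracked_points"]),
            applied_forces=np.asarray(doc["applied_forces"], dtype=float),
            radial_gap=float(doc.get("radial_gap", 0.5)),
            tangential_spacing=float(doc.get("tangential_spacing", 0.5)),
        )
        return fm.make_interface_model(name, lattice)
    raise ValueError(f"{path}: unknown model kind '{kind}'")


# ---------------------------------------------------------------------------
# calibration config
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationConfig:
    """One calibration run: where the files are, what to optimise, and how.

    Paths are resolved relative to the config file's directory when loaded
    from disk.
    """

    model_dir: Path
    data_dir: Path
    output_dir: Path
    parameters: ParameterSet
    objective: ObjectiveSpec = ObjectiveSpec()
    options: OptimiserOptions = OptimiserOptions()
    method: str | None = None

    def to_dict(self) -> dict:
        d = {
            "model_dir": str(self.model_dir),
            "data_dir": str(self.data_dir),
            "output_dir": str(self.output_dir),
            "parameters": {
                "names": list(self.parameters.names),
                "initial": None
                if self.parameters.initial is None
                else np.asarray(self.parameters.initial).tolist(),
                "bounds": None
                if self.parameters.bounds is None
                else [list(b) for b in self.parameters.bounds],
            },
            "objective": {
                "comparison": self.objective.comparison.value,
                "error_form": self.objective.error_form.value,
                "aggregation": self.objective.aggregation.value,
                "normalisation_reference": self.objective.normalisation_reference.value,
            },
            "options": dataclasses.asdict(self.options),
        }
        if self.method is not None:
            d["method"] = self.method
        return d


def _config_from_dict(doc: dict, base: Path) -> CalibrationConfig:
    pdoc = doc["parameters"]
    parameters = ParameterSet(
        names=tuple(pdoc["names"]),
        initial=None if pdoc.get("initial") is None else np.asarray(pdoc["initial"], dtype=float),
        bounds=None
        if pdoc.get("bounds") is None
        else tuple(tuple(b) for b in pdoc["bounds"]),
    )
    odoc = doc.get("objective", {})
    objective = ObjectiveSpec(
        comparison=Comparison(odoc.get("comparison", "least_squares")),
        error_form=ErrorForm(odoc.get("error_form", "relative")),
        aggregation=Aggregation(odoc.get("aggregation", "rms_over_models")),
        normalisation_reference=NormalisationReference(
            odoc.get("normalisation_reference", "experimental_value")
        ),
    )
    opts = doc.get("options", {})
    options = OptimiserOptions(**opts)
    return CalibrationConfig(
        model_dir=(base / doc["model_dir"]).resolve(),
        data_dir=(base / doc["data_dir"]).resolve(),
        output_dir=(base / doc["output_dir"]).resolve(),
        parameters=parameters,
        objective=objective,
        options=options,
        method=doc.get("method"),
    )


def load_config(path) -> CalibrationConfig:
    """Load a YAML calibration config; paths resolve relative to the file."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _config_from_dict(doc, path.parent)


def dump_config(config: CalibrationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# end-to-end driver
# ---------------------------------------------------------------------------


def _load_pairs(config: CalibrationConfig) -> list[tuple[ForwardModel, Observation]]:
    model_files = sorted(Path(config.model_dir).glob(f"*{MODEL_SUFFIX}"))
    dat_files = sorted(Path(config.data_dir).glob("*.dat"))
    model_names = {p.stem for p in model_files}
    dat_names = {p.stem for p in dat_files}
    if not model_files:
        raise ValueError(f"no model files in {config.model_dir}")
    orphans = sorted(model_names ^ dat_names)
    if orphans:
        raise ValueError(
            "unpaired model/data files (every model needs a same-basename "
            f".dat and vice versa): {', '.join(orphans)}"
        )
    pairs = []
    for mf in model_files:
        model = read_model(mf)
        payload = read_dat(Path(config.data_dir) / f"{mf.stem}.dat")
        obs = Observation(mf.stem, payload)
        if model.kind is not obs.kind:
            raise ValueError(
                f"specimen '{mf.stem}': model outputs {model.kind.value} but "
                f"observation is {obs.kind.value}"
            )
        pairs.append((model, obs))
    return pairs


def _run_one(
    pairs,
    config: CalibrationConfig,
    out_dir: Path,
) -> tuple[OptimisationResult, ConfidenceReport | None]:
    out_dir.mkdir(parents=True, exist_ok=True)
    result = minimise(
        pairs, config.objective, config.parameters, config.options, config.method
    )
    log.info(
        "calibration finished: %s, objective %.6g after %d iterations / %d evaluations",
        result.termination,
        result.objective_value,
        result.n_iterations,
        result.n_evaluations,
    )
    report = None
    if result.residuals is not None:
        n_obs = int(result.residuals.size)
        if n_obs > result.final_params.size:
            try:
                report = confidence_intervals(result, n_obs)
            except ValueError as exc:
                log.warning("confidence intervals unavailable: %s", exc)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(result.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    if report is not None:
        with open(out_dir / "confidence.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    if config.options.history:
        write_history(result, out_dir / "history.txt")
    return result, report


def run_calibration(
    config: CalibrationConfig, per_specimen: bool = False
):
    """Load pairs, dispatch, minimise, and write artefacts.

    Group mode (default) runs one optimisation over all specimens and
    writes ``summary.json`` / ``confidence.json`` / ``history.txt`` under
    ``output_dir``.  Per-specimen mode repeats the calibration once per
    file, writing into ``output_dir/<specimen>/``, and returns a dict of
    per-specimen (result, report) tuples.
    """
    pairs = _load_pairs(config)
    out_root = Path(config.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_root / "run.log", mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    )
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("loaded %d specimen pairs from %s", len(pairs), config.model_dir)
        if per_specimen:
            results = {}
            for model, obs in pairs:
                log.info("per-specimen calibration: %s", model.name)
                results[model.name] = _run_one(
                    [(model, obs)], config, out_root / model.name
                )
            return results
        return _run_one(pairs, config, out_root)
    finally:
        log.removeHandler(handler)
        handler.close()
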