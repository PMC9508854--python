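"""End-to-end experiment orchestration from a declarative TOML config.

One :func:`run_experiment` call runs, per pulling force: umbrella windows on
the toy simulator, WHAM reconstruction with three-block error bars, an
unbiased constant-force run for the clutch-ratio (alpha) profile and mean
extension, and representative-structure extraction — all with fixed,
derived seeds so a re-run of the same config is bit-identical.  A manifest
records the configuration, every seed, and SHA-256 hashes of all outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .clustering import select_representatives
from .colvars import ee_per_nuc
from .constants import kt
from .freeenergy import (FreeEnergyProfile, UmbrellaWindow, block_errors,
                         profile_from_samples, wham)
from .sampling import Bias, ToyEnergyModel, generate_fiber, run_mc
from .structures import (Trajectory, write_pdb, write_window_metadata,
                         write_xyz_trajectory)
from .surrogate import SurrogateModel, mc_most_probable

log = logging.getLogger("chromoclutch")

__all__ = ["ExperimentConfig", "run_experiment"]


@dataclass
class ExperimentConfig:
    """Declarative description of one umbrella-sampling experiment.

    The default window layout follows the published umbrella protocol:
    q_wrap centers 0.45-0.90 step 0.15 with spring 50 kcal/mol, d_stack
    centers 10-30 nm step 5 with spring 0.05 kcal/(mol nm^2).  Step counts
    default to desk scale; production-scale runs simply raise
    ``steps_per_window``.
    """

    n_nucleosomes: int = 12
    model: dict = field(default_factory=dict)
    cv: str = "d_stack"
    centers: list[float] = field(default_factory=lambda: [10.0, 15.0, 20.0, 25.0, 30.0])
    spring_k: float = 0.05
    forces_pN: list[float] = field(default_factory=lambda: [0.0, 4.0])
    steps_per_window: int = 4000
    steps_unbiased: int = 6000
    equilibration_frac: float = 0.25
    seed: int = 1
    init: str = "fiber"                 # "fiber", "uniform", or "surrogate"
    surrogate_model: str | None = None  # path to a trained model JSON
    compare_unwrap: bool = False        # paired alpha comparison at max force
    rep_tolerance: float = 1.0
    rep_cutoff: float = 3.0
    out_dir: str = "experiment_out"

    def __post_init__(self) -> None:
        if not self.centers:
            raise ValueError("window layout must be non-empty")
        if any(f < 0 for f in self.forces_pN):
            raise ValueError("forces must be >= 0")

    @classmethod
    def from_toml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def build_model(self, **overrides) -> ToyEnergyModel:
        kwargs = dict(self.model)
        if "sigma_ex" in kwargs:
            kwargs["sigma_ex"] = tuple(kwargs["sigma_ex"])
        kwargs.update(overrides)
        return ToyEnergyModel(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _initial_config(cfg: ExperimentConfig, bias: Bias | None, seed: int):
    if cfg.init == "fiber":
        return generate_fiber(cfg.n_nucleosomes)
    if cfg.init == "uniform":
        from .sampling import generate_uniform
        return generate_uniform(cfg.n_nucleosomes, spacing=8.0)
    if cfg.init == "surrogate":
        if cfg.surrogate_model is None:
            raise ValueError("init='surrogate' needs surrogate_model path")
        model = SurrogateModel.from_json(cfg.surrogate_model)
        biases = [bias] if bias is not None and bias.cv == "d_stack" else []
        return mc_most_probable(model, cfg.n_nucleosomes, biases,
                                steps=10000, seed=seed)
    raise ValueError(f"unknown init {cfg.init!r}")


def _burn(traj: Trajectory, frac: float):
    n = len(traj.cv_series)
    return traj.cv_series.iloc[int(frac * n):].reset_index(drop=True)


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full experiment; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "seeds": {},
        "per_force": {},
        "files": {},
    }
    window_seed = config.seed
    for force in config.forces_pN:
        tag = f"force_{force:g}"
        fdir = out / tag
        fdir.mkdir(exist_ok=True)
        stage = f"{tag}/umbrella"
        try:
            windows = []
            model = config.build_model()
            for wi, center in enumerate(config.centers):
                umb = Bias("umbrella", cv=config.cv, center=center,
                           spring_k=config.spring_k)
                biases = [umb]
                if force > 0:
                    biases.append(Bias("constant_force", force_pN=force))
                seed = window_seed + wi
                start = _initial_config(config, umb, seed)
                traj = run_mc(model, start, biases,
                              steps=config.steps_per_window, seed=seed)
                write_xyz_trajectory(traj, fdir / f"window_{wi}.xyz")
                write_window_metadata(
                    {"cv": config.cv, "center": center,
                     "spring_k": config.spring_k, "force_pN": force,
                     "seed": seed},
                    fdir / f"window_{wi}.json",
                )
                windows.append(UmbrellaWindow(
                    biases, _burn(traj, config.equilibration_frac)))
                report["seeds"][f"{tag}/window_{wi}"] = seed
            window_seed += len(config.centers)

            stage = f"{tag}/wham"
            grid = None
            prof = block_errors(
                windows,
                lambda ws: wham(ws, grid_spec=grid, temperature_K=300.0),
            )
            prof.write_tsv(fdir / f"F_{config.cv}.tsv")

            stage = f"{tag}/unbiased"
            seed = window_seed
            window_seed += 1
            report["seeds"][f"{tag}/unbiased"] = seed
            biases = ([Bias("constant_force", force_pN=force)]
                      if force > 0 else [])
            traj = run_mc(model, _initial_config(config, None, seed), biases,
                          steps=config.steps_unbiased, seed=seed)
            series = _burn(traj, config.equilibration_frac)
            alpha_prof = profile_from_samples(series["alpha"].to_numpy(),
                                              "alpha", bins=40)
            alpha_prof.write_tsv(fdir / "alpha_profile.tsv")
            mean_ee = float(series["ee_per_nuc"].mean())

            stage = f"{tag}/representatives"
            n_keep = min(len(traj.configs), 80)
            ensemble = traj.configs[-n_keep:]
            reps = select_representatives(
                ensemble, target_ee=mean_ee, tolerance=config.rep_tolerance,
                cutoff=config.rep_cutoff, n_structures=2)
            for ri, rep in enumerate(reps):
                write_pdb(rep, fdir / f"rep_{ri}.pdb")

            report["per_force"][tag] = {
                "mean_ee_per_nuc": mean_ee,
                "alpha_profile_min": alpha_prof.min_location(),
                "n_representatives": len(reps),
                "acceptance": traj.metadata["acceptance"],
            }
        except Exception as exc:  # annotate which stage failed, then abort
            raise RuntimeError(f"experiment stage {stage!r} failed: {exc}") from exc

    if config.compare_unwrap:
        fmax = max(config.forces_pN)
        pair = {}
        for allow in (True, False):
            seed = window_seed
            window_seed += 1
            model = config.build_model(allow_unwrap=allow)
            biases = ([Bias("constant_force", force_pN=fmax)] if fmax > 0 else [])
            traj = run_mc(model, _initial_config(config, None, seed), biases,
                          steps=config.steps_unbiased, seed=seed)
            series = _burn(traj, config.equilibration_frac)
            prof = profile_from_samples(series["alpha"].to_numpy(), "alpha",
                                        bins=40)
            pair["unwrap_allowed" if allow else "unwrap_prohibited"] = {
                "alpha_free_energy_min": prof.min_location(),
                "alpha_mean": float(series["alpha"].mean()),
                "seed": seed,
            }
        report["alpha_unwrap_comparison"] = pair

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            report["files"][str(path.relative_to(out))] = _sha256(path)
    with open(out / "manifest.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
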