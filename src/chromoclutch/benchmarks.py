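"""Self-contained validation experiments exercising the whole pipeline.

Each function generates its own inputs from a seed, runs one package
component end to end, and returns the measured quantities: the WHAM
estimator against an analytically known free energy, the linear
force-extension response of a harmonic profile, extension monotonicity,
force-matching parameter recovery, the clustering oracle, the
clutch-formation contrast between unwrapping-allowed and rigid-DNA
simulations, and the reweighting/direct-simulation consistency check.

These power both the acceptance test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .clustering import rmsd, single_linkage
from .colvars import alpha as alpha_cv
from .constants import KT_300K, PN_PER_KCAL_MOL_NM
from .freeenergy import (FreeEnergyProfile, UmbrellaWindow, block_errors,
                         mean_extension, profile_from_samples, wham)
from .sampling import (Bias, ToyEnergyModel, generate_clutch, generate_fiber,
                       quadratic_stacking_forces, run_mc,
                       sample_oligomer_configs)
from .structures import ChromatinConfig
from .surrogate import mc_most_probable, train_force_matching

__all__ = [
    "wham_oracle_rms",
    "linear_response_max_relative_error",
    "extension_monotonicity_fraction",
    "surrogate_recovery",
    "clustering_oracle",
    "clutch_alpha_contrast",
    "reweighting_consistency",
]


def wham_oracle_rms(seed: int, n_windows: int = 8, n_samples: int = 50_000,
                    k_true: float = 1.5, x0: float = 5.0,
                    spring_k: float = 2.0) -> float:
    """RMS error of WHAM against a known quadratic free energy.

    Window samples are drawn exactly from the biased Boltzmann densities
    (Gaussians), so any deviation is estimator error.  The RMS is taken
    over the central 80% of the sampled range (kcal/mol).
    """
    rng = np.random.default_rng(seed)
    windows = []
    for c in np.linspace(1.0, 9.0, n_windows):
        prec = (k_true + spring_k) / KT_300K
        mu = (k_true * x0 + spring_k * c) / (k_true + spring_k)
        x = rng.normal(mu, np.sqrt(1 / prec), n_samples)
        b = Bias("umbrella", cv="x", center=float(c), spring_k=spring_k)
        windows.append(UmbrellaWindow([b], pd.DataFrame({"x": x})))
    prof = wham(windows, grid_spec={"x": (0.0, 10.0, 100)})
    xs = prof.axes[0]
    allx = np.concatenate([w.samples["x"] for w in windows])
    lo, hi = np.quantile(allx, [0.1, 0.9])
    m = (xs >= lo) & (xs <= hi) & np.isfinite(prof.F)
    F_true = 0.5 * k_true * (xs - x0) ** 2
    F_true = F_true - F_true[m].min()
    return float(np.sqrt(np.mean((prof.F[m] - F_true[m]) ** 2)))


def linear_response_max_relative_error(
    k: float = 0.5, x0: float = 5.0,
    forces_pN: tuple[float, ...] = (1.0, 2.0, 3.0),
) -> float:
    """Max relative error of <x>(f) - <x>(0) vs the exact f/(6.948 k).

    For a harmonic extension profile the Boltzmann mean shifts linearly
    with force; deviations measure discretization error (dimensionless,
    e.g. 0.002 = 0.2%).
    """
    x = np.linspace(x0 - 55.0, x0 + 55.0, 4000)
    prof = FreeEnergyProfile(cvs=("x",), axes=(x,), F=0.5 * k * (x - x0) ** 2)
    base = mean_extension(prof, 0.0)
    errs = []
    for f in forces_pN:
        exact = f / (PN_PER_KCAL_MOL_NM * k)
        got = mean_extension(prof, f) - base
        errs.append(abs(got - exact) / exact)
    return float(max(errs))


def extension_monotonicity_fraction(seed: int, n_profiles: int = 100) -> float:
    """Fraction of random profiles with non-decreasing <x>(f) on f in [0, 6]."""
    rng = np.random.default_rng(seed)
    ok = 0
    for _ in range(n_profiles):
        nb = 80
        x = np.sort(rng.uniform(0, 20, nb))
        F = rng.uniform(0, 8, nb)
        prof = FreeEnergyProfile(cvs=("x",), axes=(x,), F=F)
        ext = [mean_extension(prof, f) for f in np.linspace(0, 6, 13)]
        ok += bool(np.all(np.diff(ext) >= -1e-9))
    return ok / n_profiles


def surrogate_recovery(seed: int, n_configs: int = 2000, epochs: int = 2000,
                       k_true: float = 2.0, d0: float = 6.0,
                       mc_steps: int = 20_000) -> dict:
    """Force-matching parameter recovery on the analytic stacking truth.

    Trains the surrogate on tetranucleosome ensembles with exact forces of
    ``F = sum over (i,i+2) of 0.5 k (d - d0)^2``, then asks surrogate Monte
    Carlo for the most probable structure.  Returns the held-out force RMSE
    as a fraction of the RMS force and the largest deviation of the
    recovered (i, i+2) distances from the known minimizer ``d0``.
    """
    centers = sample_oligomer_configs(n_configs, seed=seed)
    forces = [quadratic_stacking_forces(c, k=k_true, d0=d0) for c in centers]
    model = train_force_matching(list(centers), forces, epochs=epochs,
                                 seed=seed)
    tr = model.training
    rel = tr["holdout_force_rmse"] / tr["holdout_force_rms_ref"]
    cfg = mc_most_probable(model, 4, [], steps=mc_steps, seed=seed + 1)
    c = cfg.all_centers()
    dev = max(abs(float(np.linalg.norm(c[i] - c[i + 2])) - d0) for i in (0, 1))
    return {"holdout_rmse_frac": float(rel), "minimizer_max_dev_nm": dev}


def clustering_oracle(seed: int, trials: int = 1000) -> dict:
    """Single-linkage vs brute-force connected components; RMSD rigid check."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(trials):
        n = int(rng.integers(2, 9))
        D = rng.uniform(0, 1, (n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        cutoff = float(rng.uniform(0.2, 0.8))
        res = single_linkage(D, cutoff)
        seen = [-1] * n
        comp = 0
        for s in range(n):
            if seen[s] >= 0:
                continue
            stack = [s]
            while stack:
                u = stack.pop()
                if seen[u] >= 0:
                    continue
                seen[u] = comp
                stack.extend(v for v in range(n) if v != u and D[u, v] < cutoff)
            comp += 1
        same = all(
            (res.labels[i] == res.labels[j]) == (seen[i] == seen[j])
            for i in range(n) for j in range(n)
        )
        agree += same
    # rigid-motion RMSD: rotated+translated copy must score (numerically) zero
    from scipy.spatial.transform import Rotation

    cfg = generate_fiber(12)
    R = Rotation.from_euler("xyz", rng.uniform(0, 2 * np.pi, 3)).as_matrix()
    moved = cfg.transformed(R, rng.uniform(-20, 20, 3))
    return {"agreement_fraction": agree / trials,
            "rigid_motion_rmsd_nm": float(rmsd(cfg, moved))}


def clutch_alpha_contrast(seed: int, force_pN: float = 4.0,
                          steps: int = 30_000, burn: int = 10_000) -> dict:
    """Clutch-ratio free-energy minima with and without DNA unwrapping.

    Constant-force simulations from the fiber structure; the location of
    the free-energy minimum of alpha is compared between the default model
    and a control with the nucleosomal DNA fully rigid (wrap frozen at 1).
    Also reports the exact clutch-generator ratio for a 4x3 trimer layout.
    """
    start = generate_fiber(12)
    edges = np.linspace(1.0, 13.0, 49)
    out = {}
    for allow, key in ((True, "alpha_fmin_unwrap"), (False, "alpha_fmin_rigid")):
        model = ToyEnergyModel(allow_unwrap=allow)
        traj = run_mc(model, start, [Bias("constant_force", force_pN=force_pN)],
                      steps=steps, seed=seed)
        a = traj.cv_series["alpha"].to_numpy()[burn:]
        hist, _ = np.histogram(a, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        out[key] = float(centers[np.argmax(hist)])
    out["clutch_generator_alpha"] = float(
        alpha_cv(generate_clutch(12, [3, 3, 3, 3], intra=6.0, gap=24.0)))
    return out


def reweighting_consistency(
    seed: int,
    forces_pN: tuple[float, ...] = (1.0, 2.0, 3.0),
    window_steps: int = 6000,
    direct_steps: int = 8000,
    n_replicas: int = 3,
) -> list[dict]:
    """Tilted 0 pN profile vs direct constant-force toy simulations.

    Umbrella windows on the per-nucleosome z-extension at zero force are
    combined by WHAM; the profile is tilted to each pulling force and its
    Boltzmann mean extension compared against independent constant-force
    simulations.  Both sides use three equal-length independent replicas
    (full window campaigns / direct runs) as the error blocks: replica
    scatter honestly reflects the slow collective modes of the chain,
    which contiguous sub-blocks of a single trajectory underestimate.
    """
    model = ToyEnergyModel()
    start = generate_fiber(12)
    n = 12
    centers = np.arange(-4.0, 18.1, 2.0)
    grid = {"ee_z_per_nuc": (-6.0, 20.0, 80)}
    campaigns = []
    for rep in range(n_replicas):
        windows = []
        burn = window_steps // 4
        for wi, c in enumerate(centers):
            b = Bias("umbrella", cv="ee_z_per_nuc", center=float(c),
                     spring_k=0.6)
            traj = run_mc(model, start, [b], steps=window_steps,
                          seed=seed + 1000 * rep + wi)
            windows.append(UmbrellaWindow(
                [b], traj.cv_series.iloc[burn:][["ee_z_per_nuc"]]
                .reset_index(drop=True)))
        campaigns.append(windows)
    pooled = [
        UmbrellaWindow(
            [campaigns[0][i].biases[0]],
            pd.concat([c[i].samples for c in campaigns]).reset_index(drop=True))
        for i in range(len(centers))
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        prof = wham(pooled, grid_spec=grid)
        rep_profs = [wham(ws, grid_spec=grid) for ws in campaigns]
    out = []
    for fi, f in enumerate(forces_pN):
        rw = mean_extension(prof, f, n_scale=n)
        rw_err = float(np.std(
            [mean_extension(p, f, n_scale=n) for p in rep_profs], ddof=1))
        direct_reps = []
        for r in range(n_replicas):
            traj = run_mc(model, start,
                          [Bias("constant_force", force_pN=f)],
                          steps=direct_steps,
                          seed=seed + 5000 + 10 * fi + r)
            direct_reps.append(float(
                traj.cv_series["ee_z_per_nuc"].iloc[3 * direct_steps // 8:]
                .mean()))
        direct = float(np.mean(direct_reps))
        d_err = float(np.std(direct_reps, ddof=1))
        out.append({
            "force_pN": f,
            "reweighted": float(rw),
            "reweighted_err": rw_err,
            "direct": direct,
            "direct_err": d_err,
            "within_error_bars": bool(abs(rw - direct) <= rw_err + d_err),
        })
    return out
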