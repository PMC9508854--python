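"""Free-energy reconstruction from umbrella windows and force-extension.

Implements the self-consistent weighted-histogram (WHAM) estimator for 1D
and 2D collective-variable grids, three-block error bars, tilting of an
extension profile by a constant pulling force, Boltzmann-averaged
force-extension prediction, harmonic fits near the minimum, and the Debye
screening length.

Conventions: energies in kcal/mol, lengths in nm, forces in pN
(1 kcal/(mol nm) = 6.948 pN).  Profiles are referenced so the minimum over
defined bins is zero; bins never visited are NaN, not zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import constants as sc
from scipy.special import logsumexp

from .constants import PN_PER_KCAL_MOL_NM, kt
from .sampling import Bias

__all__ = [
    "UmbrellaWindow",
    "FreeEnergyProfile",
    "wham",
    "block_errors",
    "tilt",
    "mean_extension",
    "harmonic_fit",
    "HarmonicFit",
    "debye_length",
    "debye_cutoff",
    "marginalize",
    "profile_from_samples",
]


@dataclass
class UmbrellaWindow:
    """One biased trajectory: its umbrella bias(es) and the sampled CV series.

    ``samples`` holds one column per biased CV (one column for 1D, two for
    2D umbrella sampling).
    """

    biases: list[Bias]
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if isinstance(self.biases, Bias):
            self.biases = [self.biases]
        umb = [b for b in self.biases if b.kind == "umbrella"]
        if not umb:
            raise ValueError("an umbrella window needs at least one umbrella bias")
        for b in umb:
            if b.cv not in self.samples.columns:
                raise ValueError(f"samples missing biased CV column {b.cv!r}")
        if len(self.samples) < 3:
            raise ValueError("need >= 3 samples (three-block error analysis)")

    @property
    def umbrellas(self) -> list[Bias]:
        return [b for b in self.biases if b.kind == "umbrella"]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def block(self, i: int, n_blocks: int = 3) -> "UmbrellaWindow":
        """The i-th of ``n_blocks`` equal-length contiguous blocks."""
        size = len(self.samples) // n_blocks
        sub = self.samples.iloc[i * size:(i + 1) * size].reset_index(drop=True)
        return UmbrellaWindow(list(self.biases), sub)


@dataclass
class FreeEnergyProfile:
    """Free energies on a 1D or 2D grid of bin centers.

    ``F`` and ``err`` are kcal/mol; unvisited bins are NaN.  ``axes`` holds
    one bin-center array per CV dimension; for 2D, ``F[i, j]`` corresponds
    to ``(axes[0][i], axes[1][j])``.
    """

    cvs: tuple[str, ...]
    axes: tuple[np.ndarray, ...]
    F: np.ndarray
    err: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.axes = tuple(np.asarray(a, float) for a in self.axes)
        self.F = np.asarray(self.F, float)
        if self.err is not None:
            self.err = np.asarray(self.err, float)
        if np.any(np.isfinite(self.F)):
            self.F = self.F - np.nanmin(self.F)

    @property
    def ndim(self) -> int:
        return len(self.axes)

    def min_location(self) -> float | tuple[float, float]:
        idx = np.unravel_index(np.nanargmin(self.F), self.F.shape)
        if self.ndim == 1:
            return float(self.axes[0][idx[0]])
        return tuple(float(self.axes[d][idx[d]]) for d in range(self.ndim))

    def to_table(self) -> pd.DataFrame:
        if self.ndim == 1:
            df = pd.DataFrame({self.cvs[0]: self.axes[0], "F": self.F})
        else:
            g0, g1 = np.meshgrid(self.axes[0], self.axes[1], indexing="ij")
            df = pd.DataFrame({
                self.cvs[0]: g0.ravel(), self.cvs[1]: g1.ravel(),
                "F": self.F.ravel(),
            })
        if self.err is not None:
            df["err"] = self.err.ravel()
        return df

    def write_tsv(self, path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False, float_format="%.8g")


def _grid_edges(windows: Sequence[UmbrellaWindow], cvs: Sequence[str],
                grid_spec) -> list[np.ndarray]:
    """Bin edges per CV dimension from a spec or the sampled range."""
    edges = []
    for d, cv in enumerate(cvs):
        if grid_spec is not None and cv in grid_spec:
            spec = grid_spec[cv]
            lo, hi, nbins = spec
            edges.append(np.linspace(lo, hi, int(nbins) + 1))
        else:
            allv = np.concatenate([w.samples[cv].to_numpy() for w in windows])
            lo, hi = allv.min(), allv.max()
            if hi <= lo:
                raise ValueError(f"empty grid for CV {cv!r}")
            nbins = 100 if len(cvs) == 1 else 50
            edges.append(np.linspace(lo, hi, nbins + 1))
    return edges


def wham(
    windows: Sequence[UmbrellaWindow],
    grid_spec: dict | None = None,
    temperature_K: float = 300.0,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> FreeEnergyProfile:
    """Self-consistent WHAM estimate of the unbiased free-energy surface.

    All windows must bias the same CV set (1 or 2 CVs).  ``grid_spec`` maps
    CV name to ``(lo, hi, nbins)``; omitted CVs span the sampled range with
    100 (1D) or 50 (2D) bins.  Iterates the window free energies to
    ``max |delta f| < tol`` kcal/mol, then shifts the profile to min 0.

    Adjacent windows (sorted by bias center) sharing no occupied bin
    trigger a warning and flag the profile as ``"poor_overlap"``.
    """
    if not windows:
        raise ValueError("need at least one window")
    cvs = tuple(b.cv for b in windows[0].umbrellas)
    for w in windows:
        if tuple(b.cv for b in w.umbrellas) != cvs:
            raise ValueError("all windows must bias the same CV set")
    kT = kt(temperature_K)
    edges = _grid_edges(windows, cvs, grid_spec)
    centers = [0.5 * (e[:-1] + e[1:]) for e in edges]
    shape = tuple(len(c) for c in centers)
    B = int(np.prod(shape))
    W = len(windows)

    # histogram each window on the shared grid
    hist = np.zeros((W, B))
    for wi, w in enumerate(windows):
        pts = [w.samples[cv].to_numpy() for cv in cvs]
        h, _ = np.histogramdd(np.column_stack(pts), bins=edges)
        hist[wi] = h.ravel()
    n_tot = hist.sum(axis=1)  # samples landing on the grid, per window

    # bias energy of each window at each bin center
    mesh = np.meshgrid(*centers, indexing="ij")
    flat = [g.ravel() for g in mesh]
    U = np.zeros((W, B))
    for wi, w in enumerate(windows):
        for b in w.umbrellas:
            x = flat[cvs.index(b.cv)]
            U[wi] += 0.5 * b.spring_k * (x - b.center) ** 2 + b.offset

    # overlap diagnostics between center-adjacent windows
    flags: list[str] = []
    if W > 1:
        order = np.argsort([w.umbrellas[0].center for w in windows])
        occ = hist > 0
        for a, b in zip(order[:-1], order[1:]):
            if not np.any(occ[a] & occ[b]):
                warnings.warn(
                    "umbrella windows with no shared occupied bin: "
                    f"centers {windows[a].umbrellas[0].center} and "
                    f"{windows[b].umbrellas[0].center}",
                    stacklevel=2,
                )
                flags.append("poor_overlap")
                break

    # self-consistent iteration in log space
    log_c = -U / kT                      # log of bias Boltzmann factors
    log_hist_sum = np.log(np.where(hist.sum(axis=0) > 0,
                                   hist.sum(axis=0), 1.0))
    occupied = hist.sum(axis=0) > 0
    log_n = np.log(np.where(n_tot > 0, n_tot, 1.0))
    f = np.zeros(W)                      # window free energies / kT
    for _ in range(max_iter):
        # log denominator per bin: logsumexp_w [ log n_w + f_w + log_c[w,b] ]
        log_den = logsumexp(log_n[:, None] + f[:, None] + log_c, axis=0)
        log_p = np.where(occupied, log_hist_sum - log_den, -np.inf)
        f_new = -logsumexp(log_c + log_p[None, :], axis=1)
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f)) * kT
        f = f_new
        if delta < tol:
            break
    F = np.where(occupied, -kT * log_p, np.nan).reshape(shape)
    return FreeEnergyProfile(cvs=cvs, axes=tuple(centers), F=F, flags=flags)


def block_errors(
    windows: Sequence[UmbrellaWindow],
    estimator: Callable[[Sequence[UmbrellaWindow]], FreeEnergyProfile],
    n_blocks: int = 3,
) -> FreeEnergyProfile:
    """Attach block-averaged error bars to an estimator's profile.

    Each window's series is split into ``n_blocks`` equal-length,
    non-overlapping blocks; the estimator runs once per block (block i of
    every window together) and once on the full data.  The per-bin error is
    the sample standard deviation (ddof=1) of the block estimates; bins
    undefined in some blocks get the standard deviation of the defined
    subset (NaN if defined in fewer than two blocks).
    """
    full = estimator(list(windows))
    block_F = []
    for i in range(n_blocks):
        prof = estimator([w.block(i, n_blocks) for w in windows])
        block_F.append(_regrid(prof, full))
    stack = np.stack(block_F)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        counts = np.sum(np.isfinite(stack), axis=0)
        err = np.nanstd(stack, axis=0, ddof=1)
    err = np.where(counts >= 2, err, np.nan)
    return replace(full, err=err)


def _regrid(prof: FreeEnergyProfile, ref: FreeEnergyProfile) -> np.ndarray:
    """Block profiles share the reference grid when estimators fix it;
    otherwise interpolate (1D) / refuse (2D)."""
    if all(len(a) == len(b) and np.allclose(a, b)
           for a, b in zip(prof.axes, ref.axes)):
        return prof.F
    if prof.ndim == 1:
        return np.interp(ref.axes[0], prof.axes[0], prof.F,
                         left=np.nan, right=np.nan)
    raise ValueError("2D block profiles must share the reference grid; "
                     "pass an explicit grid_spec to the estimator")


def tilt(profile: FreeEnergyProfile, force_pN: float,
         n_scale: float = 1.0) -> FreeEnergyProfile:
    """Tilt an extension free-energy profile by a constant pulling force.

    ``F_f(x) = F_0(x) - (f / 6.948) * n_scale * x`` re-referenced to min 0.
    ``n_scale`` converts the profile's axis to total extension — e.g. the
    nucleosome count when the axis is end-to-end distance per nucleosome.
    """
    if profile.ndim != 1:
        raise ValueError("tilt expects a 1D extension profile")
    x = profile.axes[0]
    F = profile.F - (force_pN / PN_PER_KCAL_MOL_NM) * n_scale * x
    return replace(profile, F=F, err=profile.err)


def mean_extension(
    profile: FreeEnergyProfile,
    force_pN: float = 0.0,
    temperature_K: float = 300.0,
    n_scale: float = 1.0,
) -> float:
    """Boltzmann-averaged extension at a pulling force, from a 0-force profile.

    ``<x>(f) = sum_x x exp(-F_f(x)/kBT) / sum_x exp(-F_f(x)/kBT)`` over the
    defined bins of the tilted profile.
    """
    tilted = tilt(profile, force_pN, n_scale=n_scale)
    x = tilted.axes[0]
    F = tilted.F
    good = np.isfinite(F)
    if not np.any(good):
        raise ValueError("profile has no defined bins")
    kT = kt(temperature_K)
    logw = -F[good] / kT
    logw -= logw.max()
    w = np.exp(logw)
    return float(np.sum(x[good] * w) / np.sum(w))


@dataclass
class HarmonicFit:
    """Quadratic fit F ~ 0.5 * k * (x - x0)**2 near a profile minimum."""

    k: float            # curvature, kcal/(mol nm^2)
    x0: float           # minimum location, nm
    rms_residual: float  # kcal/mol over the fitted bins
    anharmonic: bool    # True when the residual exceeds the threshold


def harmonic_fit(
    profile: FreeEnergyProfile,
    window_kcal: float = 2.0,
    residual_threshold: float = 0.15,
) -> HarmonicFit:
    """Least-squares quadratic fit on bins within ``window_kcal`` of the minimum.

    A fit whose RMS residual exceeds ``residual_threshold`` kcal/mol is
    flagged ``anharmonic`` (e.g. flat-bottomed profiles under strong force).
    """
    if profile.ndim != 1:
        raise ValueError("harmonic_fit expects a 1D profile")
    x = profile.axes[0]
    F = profile.F
    good = np.isfinite(F) & (F <= np.nanmin(F) + window_kcal)
    if np.count_nonzero(good) < 3:
        raise ValueError("fewer than 3 bins within the fit window")
    coeffs = np.polyfit(x[good], F[good], 2)
    a, b, _ = coeffs
    if a <= 0:
        return HarmonicFit(k=2 * a, x0=float("nan"),
                           rms_residual=float("inf"), anharmonic=True)
    resid = np.polyval(coeffs, x[good]) - F[good]
    rms = float(np.sqrt(np.mean(resid**2)))
    return HarmonicFit(k=2 * a, x0=-b / (2 * a), rms_residual=rms,
                       anharmonic=rms > residual_threshold)


def debye_length(
    ionic_strength_M: float,
    temperature_K: float = 300.0,
    rel_permittivity: float = 78.4,
) -> float:
    """Debye screening length kappa^-1 in nm for a monovalent electrolyte.

    ``kappa^-1 = sqrt(eps0 epsr kB T / (2 NA e^2 I))`` with I in mol/L.
    At 150 mM, 300 K, water: ~0.787 nm.
    """
    if ionic_strength_M <= 0:
        raise ValueError("ionic strength must be positive")
    I_si = ionic_strength_M * 1000.0  # mol/m^3
    num = sc.epsilon_0 * rel_permittivity * sc.k * temperature_K
    den = 2 * sc.N_A * sc.e**2 * I_si
    return float(np.sqrt(num / den) * 1e9)


def debye_cutoff(
    ionic_strength_M: float = 0.15,
    temperature_K: float = 300.0,
    rel_permittivity: float = 78.4,
) -> float:
    """Electrostatics cutoff: four Debye lengths (3.14 nm at 150 mM, 300 K)."""
    return 4.0 * debye_length(ionic_strength_M, temperature_K, rel_permittivity)


def profile_from_samples(
    values: np.ndarray,
    cv: str,
    bins: int = 50,
    temperature_K: float = 300.0,
    range_: tuple[float, float] | None = None,
) -> FreeEnergyProfile:
    """Free-energy profile from unbiased samples: F = -kT ln p(x)."""
    values = np.asarray(values, float)
    if values.size == 0:
        raise ValueError("no samples")
    hist, edges = np.histogram(values, bins=bins, range=range_)
    centers = 0.5 * (edges[:-1] + edges[1:])
    kT = kt(temperature_K)
    with np.errstate(divide="ignore"):
        F = np.where(hist > 0, -kT * np.log(hist / hist.sum()), np.nan)
    return FreeEnergyProfile(cvs=(cv,), axes=(centers,), F=F)


def marginalize(profile: FreeEnergyProfile, keep_cv: str,
                temperature_K: float = 300.0) -> FreeEnergyProfile:
    """Integrate a 2D profile over the other CV: F1(x) = -kT ln sum_y e^{-F/kT}."""
    if profile.ndim != 2:
        raise ValueError("marginalize expects a 2D profile")
    if keep_cv not in profile.cvs:
        raise ValueError(f"profile has no CV {keep_cv!r}")
    keep = profile.cvs.index(keep_cv)
    other = 1 - keep
    kT = kt(temperature_K)
    logw = np.where(np.isfinite(profile.F), -profile.F / kT, -np.inf)
    log_marg = logsumexp(logw, axis=other)
    F1 = np.where(np.isfinite(log_marg), -kT * log_marg, np.nan)
    return FreeEnergyProfile(cvs=(keep_cv,), axes=(profile.axes[keep],), F=F1)
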