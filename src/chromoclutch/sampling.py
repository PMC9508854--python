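"""Toy nucleosome-resolution chromatin simulator and structure generators.

This module emulates, at nucleosome resolution, the statistical structure the
analysis modules assume: a 12-nucleosome chain (optionally two chains) that
can adopt two-start zigzag fibers, clutched configurations, and uniformly
extended states under constant z-axis pulling forces and umbrella biases.

The energy model is deliberately minimal.  Each nucleosome is a rigid
ellipsoidal disc (center + orthonormal frame) with a scalar outer-layer wrap
fraction in [0.5, 1]:

* a face-face stacking well (Gaussian in center distance, gated by the
  alignment of both disc normals with the separation vector) makes stacked
  contacts more favorable than side-side contacts;
* an anisotropic excluded-volume penalty (disc diameter ~10 nm in plane,
  ~5.5 nm along the normal);
* harmonic linker springs between consecutive nucleosomes whose rest length
  grows as either partner unwraps — unwrapping releases DNA contour into the
  adjacent linkers;
* a linear unwrapping penalty per unit (1 - wrap);
* optional constant pulling force along z acting on the DNA termini, and
  harmonic umbrella biases on collective variables.

With the defaults, unwrapping one nucleosome from wrap 1 to 0.5 costs
4 kcal/mol and releases 13.6 nm of contour, so unwrapping becomes the
economical route to extension above roughly 2 pN, while the 8 kcal/mol
stacking well keeps face-face contacts intact at those forces — the
mechanism by which clutches (stacked groups separated by unwrapped DNA)
appear under tension instead of uniform unstacking.
Setting ``allow_unwrap=False`` freezes wrap at 1, mirroring control
simulations in which the entire 147 bp of nucleosomal DNA is rigid.

Sampling uses single-nucleosome Metropolis Monte Carlo (rigid translation,
rigid rotation, wrap increment) at kB*T = 0.596 kcal/mol (300 K); forces are
converted with 1 kcal/(mol nm) = 6.948 pN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .constants import PN_PER_KCAL_MOL_NM, W_MIN, kt
from .structures import ChromatinConfig, NucleosomeFrame, Trajectory

__all__ = [
    "ToyEnergyModel",
    "Bias",
    "generate_fiber",
    "generate_clutch",
    "generate_uniform",
    "duplicate_chain",
    "run_mc",
    "total_energy",
    "sample_oligomer_configs",
    "quadratic_stacking_energy",
    "quadratic_stacking_forces",
]

#: Collective variables a harmonic umbrella may act on.
BIASABLE_CVS = ("d_stack", "q_wrap", "ee_z_per_nuc", "ee_per_nuc", "d_stack_2chain")

#: Extra per-sweep recorder channels (nucleosome-0 center coordinates).
_RECORD_EXTRAS = ("c0x", "c0y", "c0z")


@dataclass(frozen=True)
class ToyEnergyModel:
    """Parameters of the toy chromatin energy function (kcal/mol, nm)."""

    eps_stack: float = 8.0          # stacking well depth
    r_stack: float = 6.0            # stacking well minimum (center distance)
    w_stack: float = 1.5            # stacking well width
    sigma_ex: tuple[float, float] = (10.0, 5.5)  # excluded volume: in-plane, normal
    k_rep: float = 10.0             # excluded-volume penalty scale
    k_link: float = 1.0             # linker spring, kcal/(mol nm^2)
    L0: float = 9.0                 # linker rest length at wrap = 1
    lambda_release: float = 13.6    # nm added to each adjacent linker per unit (1-wrap)
    eps_unwrap: float = 8.0         # kcal/mol per unit (1-wrap)
    allow_unwrap: bool = True       # False freezes wrap at 1 (rigid nucleosomal DNA)

    def __post_init__(self) -> None:
        for name in ("eps_stack", "w_stack", "k_rep", "k_link", "eps_unwrap",
                     "lambda_release"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def linker_rest(self, w_i: float, w_j: float) -> float:
        return self.L0 + self.lambda_release * ((1 - w_i) + (1 - w_j))


@dataclass(frozen=True)
class Bias:
    """A bias acting on the simulated chain(s).

    * ``umbrella`` — 0.5 * spring_k * (cv - center)**2 on a named CV
      (spring units: kcal/mol for dimensionless CVs such as q_wrap,
      kcal/(mol nm^2) for length CVs such as d_stack);
    * ``constant_force`` — force ``force_pN`` pulling the DNA termini apart
      along ``axis`` (z by default);
    * ``tether`` — harmonic restraint of every nucleosome center to ``point``.
    """

    kind: str
    cv: str | None = None
    center: float = 0.0
    spring_k: float = 0.0
    force_pN: float = 0.0
    axis: str = "z"
    chain: int = 0
    point: tuple[float, float, float] = (0.0, 0.0, 0.0)
    offset: float = 0.0   # constant added to the bias energy (no physics)

    def __post_init__(self) -> None:
        if self.kind not in ("umbrella", "constant_force", "tether"):
            raise ValueError(f"unknown bias kind {self.kind!r}")
        if self.kind == "umbrella":
            if not self.cv:
                raise ValueError("umbrella bias needs a CV name")
            if self.spring_k <= 0:
                raise ValueError("umbrella spring_k must be > 0")
        if self.kind == "tether" and self.spring_k <= 0:
            raise ValueError("tether spring_k must be > 0")


# ---------------------------------------------------------------------------
# Structure generators

def _frames_from_arrays(centers, axis_a, axis_b, normals, wraps, chain_id=0):
    return [
        NucleosomeFrame(chain_id, i, centers[i], axis_a[i], axis_b[i],
                        normals[i], float(wraps[i]))
        for i in range(len(centers))
    ]


def generate_fiber(
    n: int, rise: float = 2.5, stack_dist: float = 6.0, twist_deg: float = 20.0
) -> ChromatinConfig:
    """Two-start zigzag fiber: nucleosome i stacks on i+2 at ``stack_dist``.

    Nucleosomes alternate between two interleaved helical stacks; all
    (i, i+2) center distances equal ``stack_dist`` by construction, so the
    clutch ratio alpha is exactly 1.  ``rise`` is the per-nucleosome rise
    along the fiber (z) axis; requires ``stack_dist >= 2 * rise``.
    """
    if n < 3:
        raise ValueError("a fiber needs >= 3 nucleosomes (d_stack undefined below)")
    if stack_dist < 2 * rise:
        raise ValueError("stack_dist must be >= 2 * rise")
    phi = math.radians(twist_deg)
    lat2 = stack_dist**2 - (2 * rise) ** 2
    rho = math.sqrt(lat2 / (2 * (1 - math.cos(phi)))) if lat2 > 0 else 0.0
    centers = np.empty((n, 3))
    axis_a = np.empty((n, 3))
    axis_b = np.empty((n, 3))
    normals = np.tile([0.0, 0.0, 1.0], (n, 1))
    for i in range(n):
        theta = (i // 2) * phi + (i % 2) * math.pi
        centers[i] = (rho * math.cos(theta), rho * math.sin(theta), i * rise)
        axis_a[i] = (math.cos(theta), math.sin(theta), 0.0)
        axis_b[i] = (-math.sin(theta), math.cos(theta), 0.0)
    return ChromatinConfig([_frames_from_arrays(centers, axis_a, axis_b,
                                                normals, np.ones(n))])


def generate_clutch(
    n: int,
    clutch_sizes: Sequence[int],
    intra: float = 6.0,
    gap: float = 24.0,
    boundary_wrap: float = 0.55,
) -> ChromatinConfig:
    """Clutched configuration: stacked groups separated by unwrapped DNA.

    Nucleosomes are stacked along z with spacing ``intra``/2 inside each
    clutch; consecutive clutches are placed so every clutch-bridging
    (i, i+2) distance equals ``gap`` exactly, hence
    ``alpha = gap / intra`` whenever there are >= 2 clutches.  Nucleosomes
    flanking a clutch boundary have their wrap lowered toward the minimum
    (DNA released into the long inter-clutch linker).
    """
    clutch_sizes = list(clutch_sizes)
    if sum(clutch_sizes) != n:
        raise ValueError("clutch sizes must sum to n")
    if any(s < 2 for s in clutch_sizes):
        raise ValueError("clutch sizes must be >= 2")
    if n < 3:
        raise ValueError("need >= 3 nucleosomes")
    if len(clutch_sizes) > 1 and not intra < gap:
        raise ValueError("intra must be smaller than gap")

    z = []
    z_cur = 0.0
    for c, size in enumerate(clutch_sizes):
        if c > 0:
            z_cur += gap - intra / 2  # boundary step; bridging (i,i+2) = gap
        for j in range(size):
            if j > 0:
                z_cur += intra / 2
            z.append(z_cur)
    centers = np.column_stack([np.zeros(n), np.zeros(n), z])
    wraps = np.ones(n)
    pos = 0
    for c, size in enumerate(clutch_sizes):
        if c > 0:
            wraps[pos] = boundary_wrap          # first of this clutch
        if c < len(clutch_sizes) - 1:
            wraps[pos + size - 1] = boundary_wrap  # last of this clutch
        pos += size
    axis_a = np.tile([1.0, 0.0, 0.0], (n, 1))
    axis_b = np.tile([0.0, 1.0, 0.0], (n, 1))
    normals = np.tile([0.0, 0.0, 1.0], (n, 1))
    return ChromatinConfig([_frames_from_arrays(centers, axis_a, axis_b,
                                                normals, wraps)])


def generate_uniform(n: int, spacing: float = 10.0) -> ChromatinConfig:
    """Uniformly extended chain: collinear centers along z, equal spacing."""
    if n < 1:
        raise ValueError("need >= 1 nucleosome")
    centers = np.column_stack([np.zeros(n), np.zeros(n), spacing * np.arange(n)])
    axis_a = np.tile([1.0, 0.0, 0.0], (n, 1))
    axis_b = np.tile([0.0, 1.0, 0.0], (n, 1))
    normals = np.tile([0.0, 0.0, 1.0], (n, 1))
    return ChromatinConfig([_frames_from_arrays(centers, axis_a, axis_b,
                                                normals, np.ones(n))])


def duplicate_chain(config: ChromatinConfig, offset: Sequence[float]) -> ChromatinConfig:
    """Two-chain configuration: the input chain plus a translated copy."""
    if config.n_chains != 1:
        raise ValueError("duplicate_chain expects a single-chain configuration")
    offset = np.asarray(offset, float).reshape(3)
    second = [
        NucleosomeFrame(1, fr.index, fr.center + offset, fr.axis_a, fr.axis_b,
                        fr.normal, fr.wrap)
        for fr in config.chains[0]
    ]
    return ChromatinConfig([[fr.copy() for fr in config.chains[0]], second])


def sample_oligomer_configs(
    n_configs: int,
    n_nucleosomes: int = 4,
    rise: float = 2.5,
    stack_dist: float = 6.0,
    noise: float = 1.5,
    seed: int = 0,
    min_separation: float = 4.0,
) -> np.ndarray:
    """Random oligonucleosome center sets: perturbed two-start zigzag fibers.

    Returns shape (n_configs, n_nucleosomes, 3).  Each configuration is the
    ideal fiber geometry plus per-coordinate displacements drawn uniformly
    in +-2*``noise`` nm: real nucleosome excursions are bounded by linker
    connectivity, and bounded uniform draws cover the whole accessible
    distance domain — including its edges — at usable density, which
    matters when the ensemble trains a regression model.  Configurations
    violating the excluded-volume floor (any pair closer than
    ``min_separation`` nm) are rejected and redrawn.
    """
    rng = np.random.default_rng(seed)
    base = generate_fiber(n_nucleosomes, rise=rise, stack_dist=stack_dist
                          ).centers()
    ii, jj = np.triu_indices(n_nucleosomes, 1)
    out = np.empty((n_configs, n_nucleosomes, 3))
    k = 0
    while k < n_configs:
        cand = base + rng.uniform(-2 * noise, 2 * noise, (n_nucleosomes, 3))
        if np.linalg.norm(cand[ii] - cand[jj], axis=1).min() >= min_separation:
            out[k] = cand
            k += 1
    return out


def quadratic_stacking_energy(centers: np.ndarray, k: float = 2.0,
                              d0: float = 6.0) -> float:
    """Analytic reference energy: sum over (i, i+2) pairs of 0.5*k*(d-d0)^2."""
    centers = np.asarray(centers, float)
    e = 0.0
    for i in range(len(centers) - 2):
        d = np.linalg.norm(centers[i] - centers[i + 2])
        e += 0.5 * k * (d - d0) ** 2
    return e


def quadratic_stacking_forces(centers: np.ndarray, k: float = 2.0,
                              d0: float = 6.0) -> np.ndarray:
    """Exact center forces of :func:`quadratic_stacking_energy` (closed form)."""
    centers = np.asarray(centers, float)
    F = np.zeros_like(centers)
    for i in range(len(centers) - 2):
        d = centers[i] - centers[i + 2]
        r = np.linalg.norm(d)
        g = k * (r - d0) * d / r
        F[i] -= g
        F[i + 2] += g
    return F


# ---------------------------------------------------------------------------
# Monte Carlo engine

class _MCState:
    """Flattened mutable state with incremental interaction-energy updates."""

    def __init__(self, config: ChromatinConfig, model: ToyEnergyModel,
                 biases: Sequence[Bias], temperature_K: float):
        self.model = model
        self.biases = list(biases)
        self.kT = kt(temperature_K)
        self.chain_slices: list[tuple[int, int]] = []
        centers, aa, bb, nn, ww = [], [], [], [], []
        start = 0
        for chain in config.chains:
            for fr in chain:
                centers.append(fr.center)
                aa.append(fr.axis_a)
                bb.append(fr.axis_b)
                nn.append(fr.normal)
                ww.append(fr.wrap)
            self.chain_slices.append((start, start + len(chain)))
            start += len(chain)
        self.centers = np.array(centers)
        self.axis_a = np.array(aa)
        self.axis_b = np.array(bb)
        self.normals = np.array(nn)
        self.wraps = np.array(ww)
        if not model.allow_unwrap:
            self.wraps[:] = 1.0
        self.N = len(self.centers)

    # -- interaction terms ---------------------------------------------------

    def _pair_energy_vs(self, k: int) -> float:
        """Sum of pair energies between nucleosome k and all others."""
        m = self.model
        return _kernels.pair_energy_vs(
            k, self.centers, self.normals, m.eps_stack, m.r_stack, m.w_stack,
            m.sigma_ex[0], m.sigma_ex[1], m.k_rep,
        )

    def _link_energy(self, i: int, j: int) -> float:
        m = self.model
        return _kernels.link_energy(self.centers[i], self.centers[j],
                                    self.wraps[i], self.wraps[j],
                                    m.k_link, m.L0, m.lambda_release)

    def _links_of(self, k: int) -> list[tuple[int, int]]:
        for start, stop in self.chain_slices:
            if start <= k < stop:
                out = []
                if k > start:
                    out.append((k - 1, k))
                if k < stop - 1:
                    out.append((k, k + 1))
                return out
        raise AssertionError

    def local_energy(self, k: int) -> float:
        e = self._pair_energy_vs(k)
        for i, j in self._links_of(k):
            e += self._link_energy(i, j)
        e += self.model.eps_unwrap * (1.0 - self.wraps[k])
        return e

    def interaction_energy(self) -> float:
        e = 0.5 * sum(self._pair_energy_vs(k) for k in range(self.N))
        for start, stop in self.chain_slices:
            for i in range(start, stop - 1):
                e += self._link_energy(i, i + 1)
        e += self.model.eps_unwrap * float(np.sum(1.0 - self.wraps))
        return e

    # -- collective variables on the flat state ------------------------------

    def _chain_arrays(self, chain: int):
        start, stop = self.chain_slices[chain]
        return self.centers[start:stop], self.wraps[start:stop]

    def _endpoints_z(self, chain: int) -> tuple[float, float]:
        m = self.model
        start, stop = self.chain_slices[chain]
        if stop - start == 1:
            c, w = self._chain_arrays(chain)
            l_end = m.L0 / 2 + m.lambda_release * (1 - w[0])
            nz = self.normals[start][2]
            return float(c[0, 2] - nz * l_end), float(c[0, 2] + nz * l_end)
        return _kernels.endpoints_z_of(self.centers, self.wraps, start, stop,
                                       m.L0, m.lambda_release)

    def _endpoints(self, chain: int) -> np.ndarray:
        m = self.model
        c, w = self._chain_arrays(chain)
        if len(c) == 1:
            n0 = self.normals[self.chain_slices[chain][0]]
            l_end = m.L0 / 2 + m.lambda_release * (1 - w[0])
            return np.array([c[0] - n0 * l_end, c[0] + n0 * l_end])
        out = np.empty((2, 3))
        for side, (t, nb) in enumerate(((0, 1), (-1, -2))):
            dvec = c[t] - c[nb]
            norm = np.linalg.norm(dvec)
            u = dvec / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
            l_end = m.L0 / 2 + m.lambda_release * (1 - w[t])
            out[side] = c[t] + u * l_end
        return out

    def cv_value(self, name: str, chain: int = 0) -> float:
        if name == "d_stack":
            start, stop = self.chain_slices[chain]
            return float(_kernels.d_stack_of(self.centers, start, stop))
        if name == "q_wrap":
            return float(self._chain_arrays(chain)[1].mean())
        if name == "alpha":
            start, stop = self.chain_slices[chain]
            return float(_kernels.alpha_of(self.centers, start, stop))
        if name == "ee_z_per_nuc":
            z0, z1 = self._endpoints_z(chain)
            return (z1 - z0) / (self.chain_slices[chain][1]
                                - self.chain_slices[chain][0])
        if name == "ee_per_nuc":
            e = self._endpoints(chain)
            n = self.chain_slices[chain][1] - self.chain_slices[chain][0]
            return float(np.linalg.norm(e[1] - e[0]) / n)
        if name == "d_stack_2chain":
            vals = [_kernels.d_stack_of(self.centers, s0, s1)
                    for s0, s1 in self.chain_slices]
            return float(np.mean(vals))
        if name == "c0x":
            return float(self.centers[0, 0])
        if name == "c0y":
            return float(self.centers[0, 1])
        if name == "c0z":
            return float(self.centers[0, 2])
        raise ValueError(f"unknown CV {name!r}")

    def bias_energy(self) -> float:
        e = 0.0
        for b in self.biases:
            if b.kind == "umbrella":
                x = self.cv_value(b.cv, b.chain)
                e += 0.5 * b.spring_k * (x - b.center) ** 2 + b.offset
            elif b.kind == "constant_force":
                ext = 0.0
                for c in range(len(self.chain_slices)):
                    z0, z1 = self._endpoints_z(c)
                    ext += z1 - z0
                e -= (b.force_pN / PN_PER_KCAL_MOL_NM) * ext
            elif b.kind == "tether":
                d = self.centers - np.asarray(b.point)
                e += 0.5 * b.spring_k * float(np.einsum("ij,ij->", d, d))
        return e

    def to_config(self) -> ChromatinConfig:
        chains = []
        for c, (start, stop) in enumerate(self.chain_slices):
            chains.append([
                NucleosomeFrame(c, i - start, self.centers[i].copy(),
                                self.axis_a[i].copy(), self.axis_b[i].copy(),
                                self.normals[i].copy(), float(self.wraps[i]))
                for i in range(start, stop)
            ])
        eps = np.stack([self._endpoints(c) for c in range(len(self.chain_slices))])
        return ChromatinConfig(chains, eps)


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


def total_energy(state_or_config, model: ToyEnergyModel | None = None,
                 biases: Sequence[Bias] = (), temperature_K: float = 300.0) -> float:
    """Total energy (interactions + biases) recomputed from scratch."""
    if isinstance(state_or_config, _MCState):
        st = state_or_config
    else:
        st = _MCState(state_or_config, model, biases, temperature_K)
    return st.interaction_energy() + st.bias_energy()


def run_mc(
    model: ToyEnergyModel,
    start: ChromatinConfig,
    biases: Sequence[Bias],
    steps: int,
    temperature_K: float = 300.0,
    seed: int = 0,
    config_stride: int | None = None,
    cv_record: Sequence[str] | None = None,
    cv_stride: int = 1,
    trans_sigma: float = 0.7,
    rot_sigma: float = 0.35,
    wrap_step: float = 0.05,
) -> Trajectory:
    """Metropolis Monte Carlo on the toy chromatin model.

    One ``step`` is a sweep of N single-nucleosome trial moves (N =
    nucleosome count), each a rigid translation, rigid rotation, or wrap
    increment (wrap moves only when the model allows unwrapping; increments
    are uniform in +-``wrap_step`` and reflected at the [0.5, 1] bounds).
    Interaction energies are updated incrementally; bias energies are
    recomputed per trial.  Deterministic for a given ``seed``.

    Returns a :class:`Trajectory` whose ``cv_series`` DataFrame holds the
    requested collective variables every ``cv_stride`` sweeps and whose
    metadata records acceptance statistics and the final total-energy
    bookkeeping (incremental vs from-scratch).
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    for b in biases:
        _ = b  # Bias validates itself on construction

    for b in biases:
        if b.kind == "umbrella" and b.cv not in BIASABLE_CVS:
            raise ValueError(
                f"the simulator cannot bias CV {b.cv!r}; choose one of "
                f"{BIASABLE_CVS}"
            )
    rng = np.random.default_rng(seed)
    st = _MCState(start, model, biases, temperature_K)
    kT = st.kT
    if config_stride is None:
        config_stride = max(1, steps // 200)
    if cv_record is None:
        names = {b.cv for b in biases if b.kind == "umbrella"}
        names.update({"d_stack", "q_wrap", "ee_z_per_nuc", "ee_per_nuc"})
        n_min = min(stop - s0 for s0, stop in st.chain_slices)
        if n_min >= 3:
            names.add("alpha")
        else:
            names -= {"d_stack", "alpha"}
        if len(st.chain_slices) == 2:
            names.add("d_stack_2chain")
        cv_record = sorted(names)

    move_kinds = ["trans", "rot"] + (["wrap"] if model.allow_unwrap else [])
    e_inter = st.interaction_energy()
    e_bias = st.bias_energy()
    accepted = 0
    attempted = 0
    configs: list[ChromatinConfig] = []
    snap_steps: list[int] = []
    records: list[list[float]] = []

    force_pN = sum(b.force_pN for b in biases if b.kind == "constant_force")

    for sweep in range(steps):
        for k in range(st.N):
            kind = move_kinds[rng.integers(len(move_kinds))]
            attempted += 1
            e_loc_old = st.local_energy(k)
            if kind == "trans":
                delta = rng.normal(0.0, trans_sigma, 3)
                st.centers[k] += delta
                undo = ("trans", delta)
            elif kind == "rot":
                axis = rng.normal(size=3)
                angle = rng.normal(0.0, rot_sigma)
                R = _rotation_matrix(axis, angle)
                old = (st.axis_a[k].copy(), st.axis_b[k].copy(), st.normals[k].copy())
                st.axis_a[k] = R @ st.axis_a[k]
                st.axis_b[k] = R @ st.axis_b[k]
                st.normals[k] = R @ st.normals[k]
                undo = ("rot", old)
            else:  # wrap
                dw = rng.uniform(-wrap_step, wrap_step)
                w_old = st.wraps[k]
                w_new = w_old + dw
                # reflect at the boundaries [W_MIN, 1]
                if w_new > 1.0:
                    w_new = 2.0 - w_new
                if w_new < W_MIN:
                    w_new = 2.0 * W_MIN - w_new
                w_new = min(1.0, max(W_MIN, w_new))
                st.wraps[k] = w_new
                undo = ("wrap", w_old)
            e_loc_new = st.local_energy(k)
            e_bias_new = st.bias_energy()
            dE = (e_loc_new - e_loc_old) + (e_bias_new - e_bias)
            if dE <= 0 or rng.random() < math.exp(-dE / kT):
                accepted += 1
                e_inter += e_loc_new - e_loc_old
                e_bias = e_bias_new
            else:
                what, payload = undo
                if what == "trans":
                    st.centers[k] -= payload
                elif what == "rot":
                    st.axis_a[k], st.axis_b[k], st.normals[k] = payload
                else:
                    st.wraps[k] = payload
        if (sweep + 1) % cv_stride == 0:
            records.append([st.cv_value(name) for name in cv_record])
        if (sweep + 1) % config_stride == 0:
            configs.append(st.to_config())
            snap_steps.append(sweep + 1)

    cv_df = pd.DataFrame(records, columns=list(cv_record))
    meta = {
        "force_pN": force_pN,
        "biases": [vars(b) | {} for b in biases],
        "seed": seed,
        "steps": snap_steps,
        "stride": config_stride,
        "cv_stride": cv_stride,
        "temperature_K": temperature_K,
        "acceptance": accepted / attempted if attempted else float("nan"),
        "energy_incremental": e_inter + e_bias,
        "energy_recomputed": st.interaction_energy() + st.bias_energy(),
    }
    return Trajectory(configs, metadata=meta, cv_series=cv_df)
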