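"""Collective variables and geometric statistics on chromatin configurations.

The two workhorse variables are ``d_stack`` — the mean center-to-center
distance between nucleosomes i and i+2, small in two-start zigzag fibers
where next-nearest nucleosomes stack — and ``q_wrap`` — the mean outer-layer
wrap fraction (1 = fully wrapped).  The clutch ratio ``alpha`` resolves how
non-uniform the (i, i+2) distances are: alpha ~ 1 for uniformly extended
chains, alpha >> 1 when the chain breaks into clutches (groups of stacked
nucleosomes separated by stretches of unwrapped/extended DNA).

All variables are invariant under global rotation and translation.
"""

from __future__ import annotations

import numpy as np

from .structures import ChromatinConfig, NucleosomeFrame, derive_endpoints

__all__ = [
    "d_stack",
    "q_wrap",
    "alpha",
    "shear_normal",
    "shear_normal_symmetric",
    "inter_chain_contacts",
    "d_stack_2chain",
    "ee_per_nuc",
    "ee_z_per_nuc",
    "i_i2_distances",
    "CV_NAMES",
]

CV_NAMES = (
    "d_stack",
    "q_wrap",
    "alpha",
    "d_stack_2chain",
    "inter_chain_contacts",
    "ee_per_nuc",
    "ee_z_per_nuc",
)


def i_i2_distances(config: ChromatinConfig, chain: int = 0) -> np.ndarray:
    """All |c_i - c_{i+2}| distances of one chain, i = 0 ... n-3."""
    centers = config.centers(chain)
    if len(centers) < 3:
        raise ValueError("chain needs >= 3 nucleosomes for (i, i+2) distances")
    return np.linalg.norm(centers[2:] - centers[:-2], axis=1)


def d_stack(config: ChromatinConfig, chain: int = 0) -> float:
    """Mean (i, i+2) center distance, nm."""
    return float(i_i2_distances(config, chain).mean())


def q_wrap(config: ChromatinConfig, chain: int = 0) -> float:
    """Mean wrap fraction over the chain (1 = fully wrapped)."""
    return float(config.wraps(chain).mean())


def alpha(config: ChromatinConfig, chain: int = 0) -> float:
    """Clutch ratio: max over (i, i+2) distances divided by the min."""
    d = i_i2_distances(config, chain)
    dmin = d.min()
    if dmin <= 0:
        raise ValueError("coincident nucleosome centers: alpha undefined")
    return float(d.max() / dmin)


def shear_normal(
    frame_i: NucleosomeFrame, frame_j: NucleosomeFrame
) -> tuple[float, float]:
    """Decompose the i->j center displacement against nucleosome i's plane.

    Returns ``(shear, normal)`` in nm: the in-plane and out-of-plane parts of
    ``r = c_j - c_i`` relative to ``frame_i.normal``.  By construction
    ``shear**2 + normal**2 == |r|**2``.  The decomposition uses nucleosome
    i's plane and is therefore asymmetric in (i, j); see
    :func:`shear_normal_symmetric`.
    """
    r = frame_j.center - frame_i.center
    z = float(np.dot(r, frame_i.normal))
    shear_vec = r - z * frame_i.normal
    return float(np.linalg.norm(shear_vec)), abs(z)


def shear_normal_symmetric(
    frame_i: NucleosomeFrame, frame_j: NucleosomeFrame
) -> tuple[float, float]:
    """Order-independent variant: mean of both orderings of :func:`shear_normal`."""
    s1, n1 = shear_normal(frame_i, frame_j)
    s2, n2 = shear_normal(frame_j, frame_i)
    return 0.5 * (s1 + s2), 0.5 * (n1 + n2)


def inter_chain_contacts(config: ChromatinConfig, cutoff: float = 15.0) -> int:
    """Number of nucleosome pairs, one per chain, closer than ``cutoff`` nm.

    Strict "<" at the cutoff; pairs at exactly the cutoff are excluded.
    """
    if config.n_chains != 2:
        raise ValueError("inter_chain_contacts requires a two-chain configuration")
    a = config.centers(0)
    b = config.centers(1)
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return int(np.count_nonzero(d < cutoff))


def d_stack_2chain(config: ChromatinConfig) -> float:
    """Mean of d_stack over the two chains (average unstacking, d̄_stack)."""
    if config.n_chains != 2:
        raise ValueError("d_stack_2chain requires a two-chain configuration")
    return 0.5 * (d_stack(config, 0) + d_stack(config, 1))


def ee_per_nuc(config: ChromatinConfig, chain: int = 0) -> float:
    """DNA end-to-end distance per nucleosome, nm."""
    e = derive_endpoints(config, chain)
    return float(np.linalg.norm(e[1] - e[0]) / config.n_nucleosomes(chain))


def ee_z_per_nuc(config: ChromatinConfig, chain: int = 0) -> float:
    """Signed z-projection of the DNA end-to-end vector per nucleosome, nm.

    This is the extension coordinate conjugate to a constant pulling force
    along the z-axis; it can be negative for compact configurations.
    """
    e = derive_endpoints(config, chain)
    return float((e[1, 2] - e[0, 2]) / config.n_nucleosomes(chain))


def evaluate_cv(name: str, config: ChromatinConfig, chain: int = 0) -> float:
    """Evaluate a named collective variable on a configuration."""
    if name == "d_stack":
        return d_stack(config, chain)
    if name == "q_wrap":
        return q_wrap(config, chain)
    if name == "alpha":
        return alpha(config, chain)
    if name == "d_stack_2chain":
        return d_stack_2chain(config)
    if name == "inter_chain_contacts":
        return float(inter_chain_contacts(config))
    if name == "ee_per_nuc":
        return ee_per_nuc(config, chain)
    if name == "ee_z_per_nuc":
        return ee_z_per_nuc(config, chain)
    raise ValueError(f"unknown collective variable: {name!r}")
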