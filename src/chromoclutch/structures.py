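"""Data model for nucleosome-level chromatin structures and all file I/O.

A chromatin chain is represented at nucleosome resolution: each nucleosome
carries a rigid-body pose (geometric center plus an orthonormal body frame
whose ``normal`` is the axis of the nucleosome disc) and a scalar ``wrap``
fraction describing how much of the outer DNA layer remains bound to the
histone core.  The inner layer never detaches, so ``wrap`` lives in
[0.5, 1].  Bead-level accounting (one bead per amino acid, three interaction
sites per nucleotide, 5'-terminal phosphates omitted) is provided for
bookkeeping against residue-level coarse-grained models.

File formats
------------
* frame-table CSV — canonical interchange format, one row per nucleosome;
* extended XYZ — trajectories, one pseudo-atom per nucleosome with the body
  frame and wrap carried as extra columns;
* JSON window metadata — bias specification of an umbrella window;
* PDB — pseudo-atom output for representative structures (B-factor = wrap);
* LAMMPS dump text (optional reader) — bead coordinates plus a bead→nucleosome
  map, converted immediately to frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import W_MIN, WRAPPED_BP

__all__ = [
    "NucleosomeFrame",
    "ChromatinConfig",
    "BeadTopology",
    "Trajectory",
    "build_topology",
    "read_frames",
    "write_frames",
    "frames_from_beads",
    "read_lammps_dump",
    "write_xyz_trajectory",
    "read_xyz_trajectory",
    "write_window_metadata",
    "read_window_metadata",
    "write_pdb",
    "DEFAULT_LINKER_REST_NM",
    "DEFAULT_RELEASE_NM_PER_UNWRAP",
    "derive_endpoints",
]

_ORTHO_TOL_STRICT = 1e-8
_ORTHO_TOL_REPAIR = 1e-6

#: Rest length of a fully wrapped linker between nucleosome centers, nm.
DEFAULT_LINKER_REST_NM = 9.0
#: Extra contour length added to each adjacent linker per unit (1 - wrap), nm.
DEFAULT_RELEASE_NM_PER_UNWRAP = 13.6


def _orthonormality_defect(R: np.ndarray) -> float:
    return float(np.max(np.abs(R @ R.T - np.eye(3))))


@dataclass
class NucleosomeFrame:
    """Rigid-body pose and wrap fraction of one nucleosome.

    ``axis_a``/``axis_b`` span the nucleosome disc plane; ``normal`` is the
    disc axis.  The three vectors form an orthonormal triad.
    """

    chain_id: int
    index: int
    center: np.ndarray
    axis_a: np.ndarray
    axis_b: np.ndarray
    normal: np.ndarray
    wrap: float = 1.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.axis_a = np.asarray(self.axis_a, dtype=float).reshape(3)
        self.axis_b = np.asarray(self.axis_b, dtype=float).reshape(3)
        self.normal = np.asarray(self.normal, dtype=float).reshape(3)
        self.validate()

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix with rows (axis_a, axis_b, normal)."""
        return np.vstack([self.axis_a, self.axis_b, self.normal])

    def validate(self) -> None:
        R = self.rotation
        defect = _orthonormality_defect(R)
        if defect > _ORTHO_TOL_STRICT:
            if defect > _ORTHO_TOL_REPAIR:
                raise ValueError(
                    f"nucleosome frame (chain {self.chain_id}, index {self.index}) "
                    f"is not orthonormal (defect {defect:.2e})"
                )
            # Small drift (e.g. accumulated rotations): re-orthonormalize via SVD.
            U, _, Vt = np.linalg.svd(R)
            R = U @ Vt
            self.axis_a, self.axis_b, self.normal = R[0], R[1], R[2]
        if not (W_MIN - 1e-12 <= self.wrap <= 1.0 + 1e-12):
            raise ValueError(
                f"wrap={self.wrap} outside [{W_MIN}, 1] "
                f"(chain {self.chain_id}, index {self.index})"
            )
        self.wrap = float(min(1.0, max(W_MIN, self.wrap)))

    def copy(self) -> "NucleosomeFrame":
        return NucleosomeFrame(
            self.chain_id,
            self.index,
            self.center.copy(),
            self.axis_a.copy(),
            self.axis_b.copy(),
            self.normal.copy(),
            self.wrap,
        )


@dataclass
class ChromatinConfig:
    """Ordered nucleosome frames of one or two chromatin chains.

    ``dna_endpoints``, when present, stores per chain the two DNA termini as
    an (n_chains, 2, 3) array; otherwise termini are derived from terminal
    nucleosome poses (see :func:`derive_endpoints`).
    """

    chains: list[list[NucleosomeFrame]]
    dna_endpoints: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.chains) <= 2:
            raise ValueError("ChromatinConfig supports 1 or 2 chains")
        for c, chain in enumerate(self.chains):
            if len(chain) < 1:
                raise ValueError("every chain needs at least one nucleosome")
            for k, fr in enumerate(chain):
                if fr.index != k:
                    raise ValueError(
                        f"chain {c}: indices must be consecutive from 0 "
                        f"(got {fr.index} at position {k})"
                    )
        if self.dna_endpoints is not None:
            self.dna_endpoints = np.asarray(self.dna_endpoints, dtype=float).reshape(
                len(self.chains), 2, 3
            )

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    def n_nucleosomes(self, chain: int = 0) -> int:
        return len(self.chains[chain])

    def centers(self, chain: int = 0) -> np.ndarray:
        return np.array([fr.center for fr in self.chains[chain]])

    def all_centers(self) -> np.ndarray:
        return np.vstack([self.centers(c) for c in range(self.n_chains)])

    def normals(self, chain: int = 0) -> np.ndarray:
        return np.array([fr.normal for fr in self.chains[chain]])

    def wraps(self, chain: int = 0) -> np.ndarray:
        return np.array([fr.wrap for fr in self.chains[chain]])

    def copy(self) -> "ChromatinConfig":
        return ChromatinConfig(
            [[fr.copy() for fr in chain] for chain in self.chains],
            None if self.dna_endpoints is None else self.dna_endpoints.copy(),
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ChromatinConfig":
        """Return a rigidly moved copy: x -> rotation @ x + translation."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float).reshape(3)
        chains = []
        for chain in self.chains:
            new = []
            for fr in chain:
                new.append(
                    NucleosomeFrame(
                        fr.chain_id,
                        fr.index,
                        rotation @ fr.center + translation,
                        rotation @ fr.axis_a,
                        rotation @ fr.axis_b,
                        rotation @ fr.normal,
                        fr.wrap,
                    )
                )
            chains.append(new)
        ep = None
        if self.dna_endpoints is not None:
            ep = self.dna_endpoints @ rotation.T + translation
        return ChromatinConfig(chains, ep)


def derive_endpoints(
    config: ChromatinConfig,
    chain: int = 0,
    linker_rest_nm: float = DEFAULT_LINKER_REST_NM,
    release_nm_per_unwrap: float = DEFAULT_RELEASE_NM_PER_UNWRAP,
) -> np.ndarray:
    """DNA termini of one chain, shape (2, 3).

    Stored endpoints take precedence.  Otherwise each terminus is
    extrapolated from the terminal nucleosome along the outgoing chain
    direction::

        e_first = c_0 + u * l_end,   u = (c_0 - c_1)/|c_0 - c_1|
        l_end   = linker_rest_nm / 2 + release_nm_per_unwrap * (1 - wrap_0)

    i.e. half a resting linker plus any DNA released by unwrapping the
    terminal nucleosome (and mirrored for the last nucleosome).  A
    single-nucleosome chain uses its ``normal`` as the direction.
    """
    if config.dna_endpoints is not None:
        return config.dna_endpoints[chain]
    frames = config.chains[chain]
    n = len(frames)
    if n == 1:
        u = frames[0].normal
        l_end = linker_rest_nm / 2 + release_nm_per_unwrap * (1 - frames[0].wrap)
        return np.array([frames[0].center - u * l_end, frames[0].center + u * l_end])
    out = np.empty((2, 3))
    for side, (t, nb) in enumerate(((0, 1), (n - 1, n - 2))):
        d = frames[t].center - frames[nb].center
        norm = np.linalg.norm(d)
        u = d / norm if norm > 0 else frames[t].normal
        l_end = linker_rest_nm / 2 + release_nm_per_unwrap * (1 - frames[t].wrap)
        out[side] = frames[t].center + u * l_end
    return out


@dataclass
class BeadTopology:
    """Bead counts of a residue-level coarse-grained nucleosome array."""

    n_nucleosomes: int
    linker_bp: int
    wrapped_bp: int
    octamer_residues: int
    protein_beads: int
    dna_beads: int
    total_beads: int


def build_topology(
    n_nucleosomes: int,
    linker_bp: int,
    octamer_residues: int = 974,
) -> BeadTopology:
    """Bead accounting for an array of nucleosomes joined by linker DNA.

    One bead per amino acid; three interaction sites per nucleotide with the
    5'-terminal nucleotide of each strand lacking its phosphate site, hence
    ``2 * (3 * total_bp - 1)`` DNA beads.  The default octamer size (974
    residues) corresponds to the histone construct of the 1KX5 crystal
    structure, 2 x (135 + 102 + 128 + 122).

    >>> build_topology(12, 20).total_beads
    23590
    """
    if n_nucleosomes < 1:
        raise ValueError("need at least one nucleosome")
    if linker_bp < 0:
        raise ValueError("linker_bp must be non-negative")
    if octamer_residues < 1:
        raise ValueError("octamer_residues must be positive")
    total_bp = n_nucleosomes * WRAPPED_BP + (n_nucleosomes - 1) * linker_bp
    dna_beads = 2 * (3 * total_bp - 1)
    protein_beads = n_nucleosomes * octamer_residues
    return BeadTopology(
        n_nucleosomes=n_nucleosomes,
        linker_bp=linker_bp,
        wrapped_bp=WRAPPED_BP,
        octamer_residues=octamer_residues,
        protein_beads=protein_beads,
        dna_beads=dna_beads,
        total_beads=protein_beads + dna_beads,
    )


@dataclass
class Trajectory:
    """Ordered configurations plus run metadata and recorded CV series."""

    configs: list[ChromatinConfig]
    metadata: dict = field(default_factory=dict)
    cv_series: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.configs:
            shape = [len(ch) for ch in self.configs[0].chains]
            for cfg in self.configs:
                if [len(ch) for ch in cfg.chains] != shape:
                    raise ValueError("all configs in a trajectory must share chain sizes")

    def __len__(self) -> int:
        return len(self.configs)


# ---------------------------------------------------------------------------
# Frame-table CSV

_CSV_COLUMNS = [
    "chain", "index", "cx", "cy", "cz",
    "ax", "ay", "az", "bx", "by", "bz",
    "nx", "ny", "nz", "wrap",
]


def config_to_table(config: ChromatinConfig) -> pd.DataFrame:
    rows = []
    for c, chain in enumerate(config.chains):
        for fr in chain:
            rows.append(
                [c, fr.index, *fr.center, *fr.axis_a, *fr.axis_b, *fr.normal, fr.wrap]
            )
    df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    df["chain"] = df["chain"].astype(int)
    df["index"] = df["index"].astype(int)
    return df


def config_from_table(df: pd.DataFrame) -> ChromatinConfig:
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"frame table missing columns: {sorted(missing)}")
    if df.duplicated(subset=["chain", "index"]).any():
        raise ValueError("duplicate (chain, index) rows in frame table")
    chains: list[list[NucleosomeFrame]] = []
    for c in sorted(df["chain"].unique()):
        sub = df[df["chain"] == c].sort_values("index")
        frames = [
            NucleosomeFrame(
                chain_id=int(c),
                index=int(r["index"]),
                center=[r["cx"], r["cy"], r["cz"]],
                axis_a=[r["ax"], r["ay"], r["az"]],
                axis_b=[r["bx"], r["by"], r["bz"]],
                normal=[r["nx"], r["ny"], r["nz"]],
                wrap=float(r["wrap"]),
            )
            for _, r in sub.iterrows()
        ]
        chains.append(frames)
    return ChromatinConfig(chains)


def read_frames(path: str | Path) -> ChromatinConfig:
    """Read a frame-table CSV into a :class:`ChromatinConfig`."""
    return config_from_table(pd.read_csv(path, float_precision="round_trip"))


def write_frames(config: ChromatinConfig, path: str | Path) -> None:
    """Write a frame-table CSV (17-digit floats: round-trips exactly)."""
    config_to_table(config).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Beads -> frames

def frames_from_beads(
    bead_coords: np.ndarray,
    bead_map: Sequence[tuple[int, int | None]],
) -> ChromatinConfig:
    """Reduce bead coordinates to nucleosome frames.

    ``bead_map[k] = (chain, nucleosome_index)`` assigns bead ``k``; linker
    beads are assigned ``(chain, None)`` and ignored.  The nucleosome center
    is the unweighted geometric mean of its beads; the body frame comes from
    principal components of the bead cloud, with ``normal`` the
    smallest-variance axis.  Normal signs are aligned so consecutive
    nucleosomes have non-negative normal dot products where possible.
    """
    bead_coords = np.asarray(bead_coords, dtype=float)
    groups: dict[tuple[int, int], list[int]] = {}
    for k, (chain, nuc) in enumerate(bead_map):
        if nuc is None:
            continue
        groups.setdefault((int(chain), int(nuc)), []).append(k)

    chains: dict[int, dict[int, NucleosomeFrame]] = {}
    for (chain, nuc), idx in sorted(groups.items()):
        pts = bead_coords[idx]
        if len(pts) < 3:
            raise ValueError(f"nucleosome (chain {chain}, {nuc}) has < 3 beads")
        center = pts.mean(axis=0)
        cov = np.cov((pts - center).T)
        evals, evecs = np.linalg.eigh(cov)  # ascending eigenvalues
        if evals[1] < 1e-12:
            raise ValueError(
                f"degenerate (collinear) bead set for nucleosome (chain {chain}, {nuc})"
            )
        normal = evecs[:, 0]
        axis_a = evecs[:, 2]
        axis_b = np.cross(normal, axis_a)
        chains.setdefault(chain, {})[nuc] = NucleosomeFrame(
            chain, nuc, center, axis_a, axis_b, normal
        )

    ordered: list[list[NucleosomeFrame]] = []
    for chain in sorted(chains):
        frames = [chains[chain][i] for i in sorted(chains[chain])]
        # sign-align consecutive normals (PCA sign is arbitrary)
        for i in range(1, len(frames)):
            if np.dot(frames[i].normal, frames[i - 1].normal) < 0:
                frames[i].normal = -frames[i].normal
                frames[i].axis_b = -frames[i].axis_b
        ordered.append(frames)
    return ChromatinConfig(ordered)


def read_lammps_dump(
    path: str | Path,
    bead_map: Sequence[tuple[int, int | None]],
    frame_index: int = -1,
) -> ChromatinConfig:
    """Read one snapshot of a LAMMPS text dump of bead coordinates.

    Parsing is delegated to MDAnalysis (``LAMMPSDUMP`` format); beads are
    then reduced to nucleosome frames via :func:`frames_from_beads`.
    """
    import MDAnalysis as mda

    u = mda.Universe(str(path), format="LAMMPSDUMP",
                     lammps_coordinate_convention="unscaled")
    u.trajectory[frame_index]
    coords = u.atoms.positions.astype(float)
    # MDAnalysis shifts dump coordinates into [0, L); restore the dump's own
    # frame by adding the box lower bounds of the selected snapshot back.
    lows = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    for i, line in enumerate(lines):
        if line.startswith("ITEM: BOX BOUNDS"):
            lows.append([float(lines[i + 1 + d].split()[0]) for d in range(3)])
    coords = coords + np.asarray(lows[frame_index if frame_index >= 0
                                      else len(lows) + frame_index])
    return frames_from_beads(coords, bead_map)


# ---------------------------------------------------------------------------
# Extended XYZ trajectories

_XYZ_PROPS = (
    "Properties=species:S:1:pos:R:3:axis_a:R:3:axis_b:R:3:normal:R:3:wrap:R:1:chain:I:1"
)


def write_xyz_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write an extended-XYZ trajectory, one pseudo-atom per nucleosome.

    The comment line carries the snapshot step and pulling force; extra
    columns carry the body frame and wrap so the file round-trips the full
    nucleosome-level state.
    """
    force = traj.metadata.get("force_pN", 0.0)
    steps = traj.metadata.get("steps", list(range(len(traj.configs))))
    with open(path, "w") as fh:
        for snap, cfg in enumerate(traj.configs):
            n_total = sum(len(ch) for ch in cfg.chains)
            fh.write(f"{n_total}\n")
            fh.write(f"step={steps[snap]} force_pN={force:.6g} {_XYZ_PROPS}\n")
            for c, chain in enumerate(cfg.chains):
                for fr in chain:
                    vals = np.concatenate(
                        [fr.center, fr.axis_a, fr.axis_b, fr.normal, [fr.wrap]]
                    )
                    fh.write(
                        "NUC " + " ".join(f"{v:.10g}" for v in vals) + f" {c}\n"
                    )


def read_xyz_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory written by :func:`write_xyz_trajectory`."""
    configs: list[ChromatinConfig] = []
    steps: list[int] = []
    force = 0.0
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        comment = lines[i + 1]
        step = 0
        for tok in comment.split():
            if tok.startswith("step="):
                step = int(tok[5:])
            elif tok.startswith("force_pN="):
                force = float(tok[9:])
        rows = []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            rows.append((np.array(parts[1:14], dtype=float), int(parts[14])))
        chains: dict[int, list[NucleosomeFrame]] = {}
        for vals, c in rows:
            chains.setdefault(c, []).append(vals)
        chain_list = []
        for c in sorted(chains):
            frames = [
                NucleosomeFrame(c, k, v[0:3], v[3:6], v[6:9], v[9:12], float(v[12]))
                for k, v in enumerate(chains[c])
            ]
            chain_list.append(frames)
        configs.append(ChromatinConfig(chain_list))
        steps.append(step)
        i += 2 + n
    return Trajectory(configs, metadata={"force_pN": force, "steps": steps})


# ---------------------------------------------------------------------------
# Window metadata + PDB

def write_window_metadata(meta: Mapping, path: str | Path) -> None:
    """Write umbrella-window metadata {cv, center, spring_k, force_pN, seed}."""
    with open(path, "w") as fh:
        json.dump(dict(meta), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_window_metadata(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_pdb(config: ChromatinConfig, path: str | Path) -> None:
    """Write a pseudo-atom PDB: one atom per nucleosome, B-factor = wrap."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n_total = sum(len(ch) for ch in config.chains)
    atoms = struc.AtomArray(n_total)
    k = 0
    chain_letters = "AB"
    for c, chain in enumerate(config.chains):
        for fr in chain:
            atoms.coord[k] = fr.center * 10.0  # nm -> Angstrom
            atoms.chain_id[k] = chain_letters[c]
            atoms.res_id[k] = fr.index + 1
            atoms.res_name[k] = "NUC"
            atoms.atom_name[k] = "NUC"
            atoms.element[k] = "C"
            atoms.hetero[k] = True
            k += 1
    atoms.set_annotation("b_factor", np.concatenate(
        [config.wraps(c) for c in range(config.n_chains)]
    ))
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))
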