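"""Data model, bead accounting, and file I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from chromoclutch.structures import (ChromatinConfig, NucleosomeFrame,
                                     Trajectory, build_topology,
                                     config_from_table, config_to_table,
                                     derive_endpoints, frames_from_beads,
                                     read_frames, read_lammps_dump,
                                     read_xyz_trajectory, write_frames,
                                     write_pdb, write_xyz_trajectory)
from conftest import random_config


class TestTopology:
    @pytest.mark.parametrize(
        "n,linker,octamer,total",
        [
            (12, 20, 974, 23590),          # the 12mer with 20 bp linkers
            (1, 0, 974, 974 + 2 * (3 * 147 - 1)),  # single nucleosome, no linker
        ],
    )
    def test_bead_counts(self, n, linker, octamer, total):
        topo = build_topology(n, linker, octamer)
        assert topo.total_beads == total
        assert topo.total_beads == topo.protein_beads + topo.dna_beads

    def test_empty_chain_rejected(self):
        with pytest.raises(ValueError):
            build_topology(0, 20, 974)

    @given(n=st.integers(1, 20), linker=st.integers(0, 60))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_closed_form_bead_formulas(self, n, linker):
        topo = build_topology(n, linker)
        total_bp = n * 147 + (n - 1) * linker
        assert topo.dna_beads == 2 * (3 * total_bp - 1)
        assert topo.protein_beads == n * 974
        assert topo.total_beads == topo.protein_beads + topo.dna_beads


class TestFrameValidation:
    def test_orthonormal_required(self):
        with pytest.raises(ValueError, match="orthonormal"):
            NucleosomeFrame(0, 0, [0, 0, 0], [1, 0, 0], [0.9, 0.5, 0], [0, 0, 1])

    def test_small_drift_repaired(self):
        eps = 5e-7
        fr = NucleosomeFrame(0, 0, [0, 0, 0], [1, eps, 0], [0, 1, 0], [0, 0, 1])
        R = fr.rotation
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)

    def test_wrap_range(self):
        with pytest.raises(ValueError, match="wrap"):
            NucleosomeFrame(0, 0, [0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                            wrap=1.2)
        with pytest.raises(ValueError, match="wrap"):
            NucleosomeFrame(0, 0, [0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                            wrap=0.4)

    def test_config_index_and_chain_constraints(self):
        fr = NucleosomeFrame(0, 1, [0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1])
        with pytest.raises(ValueError, match="consecutive"):
            ChromatinConfig([[fr]])
        with pytest.raises(ValueError, match="chains"):
            ChromatinConfig([])


class TestFrameTableCSV:
    def test_round_trip_identity(self, rng, tmp_path):
        cfg = random_config(rng, n=12)
        p = tmp_path / "frames.csv"
        write_frames(cfg, p)
        back = read_frames(p)
        p2 = tmp_path / "again.csv"
        write_frames(back, p2)
        assert p.read_text() == p2.read_text()
        for c in range(cfg.n_chains):
            assert np.allclose(back.centers(c), cfg.centers(c), atol=1e-9)
            assert np.allclose(back.wraps(c), cfg.wraps(c), atol=1e-9)

    def test_single_chain_twelve_rows(self, rng, tmp_path):
        cfg = random_config(rng, n=12)
        p = tmp_path / "frames.csv"
        write_frames(cfg, p)
        back = read_frames(p)
        assert back.n_chains == 1
        assert back.n_nucleosomes() == 12

    def test_wrap_out_of_range_rejected(self, rng, tmp_path):
        cfg = random_config(rng, n=3)
        df = config_to_table(cfg)
        df.loc[0, "wrap"] = 1.2
        with pytest.raises(ValueError, match="wrap"):
            config_from_table(df)

    def test_duplicate_rows_rejected(self, rng):
        df = config_to_table(random_config(rng, n=3))
        df.loc[1, "index"] = 0
        with pytest.raises(ValueError, match="duplicate"):
            config_from_table(df)

    def test_missing_column_rejected(self, rng):
        df = config_to_table(random_config(rng, n=3)).drop(columns=["wrap"])
        with pytest.raises(ValueError, match="missing"):
            config_from_table(df)


class TestFramesFromBeads:
    def _ring(self, center, normal, radius=4.0, n=24):
        normal = np.asarray(normal, float)
        normal = normal / np.linalg.norm(normal)
        # orthonormal basis of the plane
        a = np.array([1.0, 0, 0])
        if abs(normal @ a) > 0.9:
            a = np.array([0, 1.0, 0])
        u = np.cross(normal, a)
        u /= np.linalg.norm(u)
        v = np.cross(normal, u)
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return center + radius * (np.outer(np.cos(th), u) + np.outer(np.sin(th), v))

    def test_planar_ring_recovers_center_and_normal(self):
        pts = self._ring(np.array([1.0, 2.0, 3.0]), [0, 0, 1])
        cfg = frames_from_beads(pts, [(0, 0)] * len(pts))
        fr = cfg.chains[0][0]
        assert np.allclose(fr.center, [1, 2, 3], atol=1e-10)
        assert abs(abs(fr.normal[2]) - 1) < 1e-10

    def test_translation_equivariance(self, rng):
        pts = rng.normal(0, 3, (30, 3))
        t = np.array([5.0, -2.0, 7.0])
        c1 = frames_from_beads(pts, [(0, 0)] * 30)
        c2 = frames_from_beads(pts + t, [(0, 0)] * 30)
        assert np.allclose(c2.chains[0][0].center,
                           c1.chains[0][0].center + t, atol=1e-10)
        assert np.allclose(np.abs(c2.chains[0][0].normal),
                           np.abs(c1.chains[0][0].normal), atol=1e-10)

    def test_matches_independent_pca(self, rng):
        pts = rng.normal(0, 1, (50, 3)) * np.array([4.0, 2.0, 0.5])
        cfg = frames_from_beads(pts, [(0, 0)] * 50)
        # brute-force PCA oracle
        x = pts - pts.mean(axis=0)
        evals, evecs = np.linalg.eigh(x.T @ x / (len(x) - 1))
        oracle_normal = evecs[:, 0]
        got = cfg.chains[0][0].normal
        assert min(np.linalg.norm(got - oracle_normal),
                   np.linalg.norm(got + oracle_normal)) < 1e-8

    def test_rigid_motion_equivariance(self, rng):
        pts = rng.normal(0, 3, (40, 3))
        bead_map = [(0, 0)] * 20 + [(0, 1)] * 20
        R = Rotation.random(random_state=4).as_matrix()
        t = np.array([1.0, 2.0, 3.0])
        c1 = frames_from_beads(pts, bead_map)
        c2 = frames_from_beads(pts @ R.T + t, bead_map)
        for i in range(2):
            assert np.allclose(c2.chains[0][i].center,
                               R @ c1.chains[0][i].center + t, atol=1e-9)

    def test_collinear_beads_rejected(self):
        pts = np.outer(np.arange(10.0), [1.0, 0, 0])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            frames_from_beads(pts, [(0, 0)] * 10)


class TestTrajectoryIO:
    def test_xyz_round_trip(self, rng, tmp_path):
        configs = [random_config(rng, n=5) for _ in range(3)]
        traj = Trajectory(configs, metadata={"force_pN": 2.5,
                                             "steps": [10, 20, 30]})
        p = tmp_path / "traj.xyz"
        write_xyz_trajectory(traj, p)
        back = read_xyz_trajectory(p)
        assert len(back) == 3
        assert back.metadata["force_pN"] == pytest.approx(2.5)
        assert back.metadata["steps"] == [10, 20, 30]
        for a, b in zip(configs, back.configs):
            assert np.allclose(a.centers(), b.centers(), atol=1e-8)
            assert np.allclose(a.wraps(), b.wraps(), atol=1e-8)
            assert np.allclose(a.normals(), b.normals(), atol=1e-8)

    def test_two_chain_round_trip(self, rng, tmp_path):
        traj = Trajectory([random_config(rng, n=4, n_chains=2)])
        p = tmp_path / "t.xyz"
        write_xyz_trajectory(traj, p)
        back = read_xyz_trajectory(p)
        assert back.configs[0].n_chains == 2

    def test_pdb_writer(self, rng, tmp_path):
        import biotite.structure.io.pdb as pdb

        cfg = random_config(rng, n=12)
        p = tmp_path / "rep.pdb"
        write_pdb(cfg, p)
        atoms = pdb.PDBFile.read(str(p)).get_structure(model=1,
                                                       extra_fields=["b_factor"])
        assert len(atoms) == 12
        # coordinates are Angstrom in the file, nm in the model
        assert np.allclose(atoms.coord / 10.0, cfg.centers(), atol=1e-3)
        assert np.allclose(atoms.b_factor, cfg.wraps(), atol=1e-2)

    def test_lammps_dump_reader(self, tmp_path):
        # two nucleosomes of 4 coplanar beads each, centers (0,0,0) and (0,0,10)
        beads = []
        for zc in (0.0, 10.0):
            for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                beads.append((dx * 3.0, dy * 3.0, zc))
        lines = ["ITEM: TIMESTEP", "0", "ITEM: NUMBER OF ATOMS", str(len(beads)),
                 "ITEM: BOX BOUNDS pp pp pp", "-50 50", "-50 50", "-50 50",
                 "ITEM: ATOMS id type x y z"]
        for i, (x, y, z) in enumerate(beads, 1):
            lines.append(f"{i} 1 {x} {y} {z}")
        p = tmp_path / "dump.lammpstrj"
        p.write_text("\n".join(lines) + "\n")
        bead_map = [(0, 0)] * 4 + [(0, 1)] * 4
        cfg = read_lammps_dump(p, bead_map)
        assert np.allclose(cfg.chains[0][0].center, [0, 0, 0], atol=1e-5)
        assert np.allclose(cfg.chains[0][1].center, [0, 0, 10], atol=1e-5)


class TestEndpoints:
    def test_derived_endpoint_formula(self):
        from chromoclutch.sampling import generate_uniform

        cfg = generate_uniform(12, 5.0)
        e = derive_endpoints(cfg)  # wrap = 1 everywhere -> l_end = L0/2
        assert np.allclose(e[0], [0, 0, -4.5])
        assert np.allclose(e[1], [0, 0, 55 + 4.5])

    def test_stored_endpoints_take_precedence(self, rng):
        cfg = random_config(rng, n=4)
        cfg.dna_endpoints = np.array([[[0, 0, 0], [0, 0, 100.0]]])
        e = derive_endpoints(cfg)
        assert np.allclose(e[1], [0, 0, 100.0])
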