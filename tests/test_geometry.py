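"""Backbone construction, frames, duplex fixtures and superposition metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from scipy.spatial.transform import Rotation

from paircraft import (
    Frame,
    TorsionSet,
    build_backbone,
    coverage,
    extract_torsions,
    frame_from_atoms,
    ideal_duplex,
    kabsch_superpose,
    tm_score,
)
from paircraft import geometry as geo
from paircraft import ideal_geometry as ig
from paircraft.errors import GeometryError, ValidationError

from conftest import torsion_arrays


def random_rigid(seed):
    rng = np.random.default_rng(seed)
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.normal(scale=10.0, size=3)
    return R, t


def grid_min_rmsd(X, Y, final_step=0.1):
    """Brute-force oracle: minimize RMSD over rotations by scanning Euler
    angles on a 30-degree global grid, then refining the best candidate
    basins down to ``final_step`` degrees (translation is the closed-form
    centroid match)."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)

    def rmsd_of(a, b, c):
        R = Rotation.from_euler("zyz", (a, b, c), degrees=True).as_matrix()
        return np.sqrt(((Xc @ R.T - Yc) ** 2).sum() / len(X))

    coarse = 30.0
    cands = sorted(
        (rmsd_of(a, b, c), (a, b, c))
        for a in np.arange(-180, 180, coarse)
        for b in np.arange(0, 181, coarse)
        for c in np.arange(-180, 180, coarse)
    )
    best_val = cands[0][0]
    for _, center in cands[:8]:
        step, ctr = coarse / 5.0, np.array(center)
        while step >= final_step / 5.0:
            grid = np.arange(-6, 7) * step
            v, ctr = min(
                (rmsd_of(ctr[0] + a, ctr[1] + b, ctr[2] + c),
                 (ctr[0] + a, ctr[1] + b, ctr[2] + c))
                for a in grid for b in grid for c in grid
            )
            ctr = np.array(ctr)
            best_val = min(best_val, v)
            step /= 5.0
    return best_val


class TestFrame:
    def test_canonical_placement(self):
        f = frame_from_atoms((1, 0, 0), (0, 0, 0), (0, 1, 0))
        assert np.allclose(f.rotation, np.eye(3))
        assert np.allclose(f.origin, 0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equivariance(self, seed):
        R, t = random_rigid(seed)
        o4, c1, c2 = np.array([1.4, 0, 0]), np.zeros(3), np.array([-0.4, 1.5, 0])
        f0 = frame_from_atoms(o4, c1, c2)
        f1 = frame_from_atoms(R @ o4 + t, R @ c1 + t, R @ c2 + t)
        assert np.allclose(f1.rotation, R @ f0.rotation, atol=1e-8)
        assert np.allclose(f1.origin, R @ f0.origin + t, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_orthonormal_proper(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(3, 3))
        f = frame_from_atoms(*pts)
        assert np.allclose(f.rotation.T @ f.rotation, np.eye(3), atol=1e-10)
        assert np.linalg.det(f.rotation) > 0

    def test_collinear_rejected(self):
        with pytest.raises(GeometryError):
            frame_from_atoms((1, 0, 0), (0, 0, 0), (2, 0, 0))


class TestBuildExtract:
    def test_polymer_class_conditioning(self):
        ts = TorsionSet.uniform(1, ig.HELIX["RNA"]["torsions"])
        rna = build_backbone(ts, ["RNA"])
        dna = build_backbone(
            TorsionSet.uniform(1, ig.HELIX["DNA"]["torsions"], pucker="C2'-endo"),
            ["DNA"],
        )
        assert "O2'" in rna.residues[0]
        assert "O2'" not in dna.residues[0]

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(torsion_arrays())
    def test_roundtrip_random_torsions(self, cols):
        n = len(cols["alpha"])
        ts = TorsionSet(**cols)
        chain = build_backbone(ts, ["RNA"] * n)
        back = extract_torsions(chain)
        for nm in ("alpha", "beta", "gamma", "delta", "epsilon", "zeta"):
            a, b = getattr(ts, nm), getattr(back, nm)
            mask = np.isfinite(a)
            assert np.allclose(a[mask], b[mask], atol=1e-6)
            assert np.all(~np.isfinite(b[~mask]))

    def test_rigid_invariance_of_torsions(self):
        ts = TorsionSet.uniform(4, ig.HELIX["RNA"]["torsions"])
        chain = build_backbone(ts, ["RNA"] * 4)
        R, t = random_rigid(3)
        moved = chain.transformed(R, t)
        a, b = extract_torsions(chain), extract_torsions(moved)
        for nm in ("alpha", "beta", "gamma", "delta", "epsilon", "zeta"):
            x, y = getattr(a, nm), getattr(b, nm)
            mask = np.isfinite(x)
            assert np.allclose(x[mask], y[mask], atol=1e-8)

    def test_planar_cis_dihedral_is_zero(self):
        assert geo.dihedral((1, 1, 0), (1, 0, 0), (2, 0, 0), (2, 1, 0)) == pytest.approx(0.0)

    def test_phosphodiester_bond_reproduced(self):
        ts = TorsionSet.uniform(2, ig.HELIX["RNA"]["torsions"])
        chain = build_backbone(ts, ["RNA"] * 2)
        d = np.linalg.norm(chain.atom(1, "P") - chain.atom(0, "O3'"))
        assert d == pytest.approx(ig.BOND_LENGTHS["O3'-P"], abs=1e-6)

    def test_constructed_bond_lengths_match_table(self):
        ts = TorsionSet.uniform(3, ig.HELIX["RNA"]["torsions"])
        chain = build_backbone(ts, ["RNA"] * 3)
        checks = [
            (1, "P", 1, "O5'", "P-O5'"),
            (1, "O5'", 1, "C5'", "O5'-C5'"),
            (1, "C5'", 1, "C4'", "C5'-C4'"),
            (1, "C4'", 1, "C3'", "C4'-C3'"),
            (1, "C3'", 1, "O3'", "C3'-O3'"),
            (1, "C4'", 1, "O4'", "C4'-O4'"),
            (1, "O4'", 1, "C1'", "O4'-C1'"),
            (1, "C1'", 1, "C2'", "C1'-C2'"),
            (1, "C2'", 1, "O2'", "C2'-O2'"),
            (1, "P", 1, "OP1", "P-OP1"),
        ]
        for i, a, j, b, key in checks:
            d = np.linalg.norm(chain.atom(i, a) - chain.atom(j, b))
            assert d == pytest.approx(ig.BOND_LENGTHS[key], abs=1e-6), key
        # ring closure is implied, consistent with the pucker fit
        closure = np.linalg.norm(chain.atom(1, "C2'") - chain.atom(1, "C3'"))
        assert closure == pytest.approx(
            ig.PUCKER_TEMPLATES["C3'-endo"]["closure_C2C3"], abs=1e-6
        )

    def test_missing_atom_extraction_error(self):
        ts = TorsionSet.uniform(2, ig.HELIX["RNA"]["torsions"])
        chain = build_backbone(ts, ["RNA"] * 2)
        del chain.residues[1]["C5'"]
        with pytest.raises(GeometryError, match="residue 1.*C5'"):
            extract_torsions(chain)

    def test_unknown_pucker_rejected(self):
        with pytest.raises(GeometryError, match="pucker"):
            TorsionSet.uniform(2, ig.HELIX["RNA"]["torsions"], pucker="O4'-endo")

    def test_torsion_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            TorsionSet(
                alpha=[200.0], beta=[0.0], gamma=[0.0],
                delta=[0.0], epsilon=[0.0], zeta=[0.0],
            )


class TestIdealDuplex:
    def test_single_bp(self):
        d = ideal_duplex("RNA", 1)
        assert len(d.strand_a) == len(d.strand_b) == 1
        assert d.pairs == {(0, 0)}

    @pytest.mark.parametrize("pc", ["RNA", "DNA"])
    def test_rise_between_c1_projections(self, pc):
        d = ideal_duplex(pc, 6)
        z = [d.strand_a.atom(k, "C1'")[2] for k in range(6)]  # helix axis is z
        assert np.allclose(np.diff(z), ig.HELIX[pc]["rise"], atol=1e-6)

    @pytest.mark.parametrize("pc", ["RNA", "DNA"])
    def test_fixtures_validate(self, pc):
        d = ideal_duplex(pc, 5)
        d.strand_a.validate()
        d.strand_b.validate()

    def test_interior_torsions_constant(self):
        d = ideal_duplex("RNA", 6)
        for strand in (d.strand_a, d.strand_b):
            ts = extract_torsions(strand)
            for nm in ("alpha", "beta", "gamma", "delta", "epsilon", "zeta"):
                vals = getattr(ts, nm)
                interior = vals[np.isfinite(vals)]
                assert np.ptp(interior) < 1e-6

    def test_paired_c1_distance_matches_table(self):
        d = ideal_duplex("RNA", 4)
        for i, j in d.pairs:
            dist = np.linalg.norm(d.strand_a.atom(i, "C1'") - d.strand_b.atom(j, "C1'"))
            assert dist == pytest.approx(ig.HELIX["RNA"]["c1_c1_distance"], abs=1e-6)


class TestKabsch:
    def test_identity(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        R, t, r = kabsch_superpose(X, X)
        assert r == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(R, np.eye(3), atol=1e-8)

    @pytest.mark.parametrize("seed", range(3))
    def test_recovers_known_rigid(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(6, 3))
        R0, t0 = random_rigid(seed + 10)
        Y = X @ R0.T + t0
        R, t, r = kabsch_superpose(X, Y)
        assert r == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(R, R0, atol=1e-8)
        assert np.allclose(t, t0, atol=1e-7)

    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        X = rng.normal(size=(n, 3))
        Y = rng.normal(size=(n, 3))
        _, _, r = kabsch_superpose(X, Y)
        oracle = grid_min_rmsd(X, Y)
        assert r <= oracle + 1e-3  # analytic optimum can only beat the grid
        assert abs(r - oracle) < 1e-3

    def test_agrees_with_biotite(self):
        import biotite.structure as struc

        rng = np.random.default_rng(5)
        X, Y = rng.normal(size=(8, 3)), rng.normal(size=(8, 3))
        _, _, r = kabsch_superpose(X, Y)
        fitted, _ = struc.superimpose(Y, X)
        ref = np.sqrt(((fitted - Y) ** 2).sum() / len(X))
        assert r == pytest.approx(ref, abs=1e-5)  # biotite works in float32

    def test_invariant_to_prerotation(self):
        rng = np.random.default_rng(2)
        X, Y = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        R0, t0 = random_rigid(1)
        r1 = kabsch_superpose(X, Y)[2]
        r2 = kabsch_superpose(X @ R0.T + t0, Y)[2]
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


class TestTMScore:
    def test_identical_sets(self):
        X = np.random.default_rng(0).normal(size=(10, 3)) * 5
        assert tm_score(X, X) == pytest.approx(1.0, abs=1e-9)

    def test_far_limit(self):
        X = np.zeros((4, 3))
        Y = X + np.array([1e6, 0, 0]) * np.arange(1, 5)[:, None]
        assert tm_score(X, Y) < 1e-6

    def test_single_pair_at_d0(self):
        d0 = geo.d0_length_scale(1, "RNA")
        X = np.array([[0.0, 0.0, 0.0]])
        Y = np.array([[d0, 0.0, 0.0]])
        assert tm_score(X, Y, correspondence=[(0, 0)], L_norm=1) == pytest.approx(0.5)

    def test_at_most_one(self):
        rng = np.random.default_rng(1)
        for seed in range(5):
            X = rng.normal(size=(6, 3)) * 8
            Y = rng.normal(size=(6, 3)) * 8
            assert tm_score(X, Y) <= 1.0 + 1e-12

    def test_monotone_in_single_distance(self):
        # without superposition (2 points), growing one distance can only
        # lower the score
        X = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        scores = []
        for shift in (0.0, 1.0, 3.0, 10.0):
            Y = X.copy()
            Y[1, 1] += shift
            scores.append(tm_score(X, Y, L_norm=4))
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_l_norm_penalizes_short_alignment(self):
        X = np.random.default_rng(3).normal(size=(5, 3)) * 4
        full = tm_score(X, X, L_norm=5)
        padded = tm_score(X, X, L_norm=10)
        assert full == pytest.approx(1.0)
        assert padded == pytest.approx(0.5)

    def test_empty_correspondence(self):
        with pytest.raises(ValidationError, match="undefined"):
            tm_score(np.zeros((3, 3)), np.zeros((3, 3)), correspondence=[])


class TestCoverage:
    @pytest.mark.parametrize(
        "aligned, design, expect",
        [(133, 240, 0.55), (240, 240, 1.0), (0, 240, 0.0)],
    )
    def test_examples(self, aligned, design, expect):
        assert round(coverage(aligned, design), 2) == expect

    def test_zero_design_length(self):
        with pytest.raises(ValidationError):
            coverage(10, 0)


def test_pdb_roundtrip(tmp_path):
    d = ideal_duplex("RNA", 4)
    path = tmp_path / "duplex.pdb"
    geo.write_pdb(path, [d.strand_a, d.strand_b])
    chains = geo.read_pdb(path)
    assert len(chains) == 2
    assert chains[0].polymer_class == ["RNA"] * 4
    for i in range(4):
        assert np.allclose(
            chains[0].atom(i, "C1'"), d.strand_a.atom(i, "C1'"), atol=1e-3
        )
    chains[0].validate()


def test_torsion_table_roundtrip(tmp_path):
    ts = TorsionSet.uniform(4, ig.HELIX["RNA"]["torsions"])
    path = tmp_path / "torsions.tsv"
    ts.to_table(path)
    back = TorsionSet.from_table(path)
    for nm in ("alpha", "beta", "gamma", "delta", "epsilon", "zeta"):
        a, b = getattr(ts, nm), getattr(back, nm)
        mask = np.isfinite(a)
        assert np.allclose(a[mask], b[mask], atol=1e-5)
        assert list(np.isfinite(a)) == list(np.isfinite(b))
    assert back.pucker == ts.pucker
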