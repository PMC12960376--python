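"""Structure I/O, Kabsch superposition, TM-score, confidence metrics."""

import itertools

import numpy as np
import pytest

from ea2struct import (
    StructureModel,
    StructurePairSpec,
    kabsch_superpose,
    lcr_percent,
    make_structure_pair,
    mean_plddt,
    read_model,
    tm_score,
    write_model,
)
from ea2struct.structure_metrics import (
    InsufficientOverlapError,
    NoBackboneError,
    pair_residues,
    tm_d0,
)

# ---------------------------------------------------------------------------
# independent brute-force TM oracle: SVD Kabsch (hand-rolled), coarse SO(3)
# grid and dense contiguous seed windows, fixed-cutoff refinement
# ---------------------------------------------------------------------------


def _kabsch_svd(P, Q):
    pc, qc = P.mean(0), Q.mean(0)
    H = (Q - qc).T @ (P - pc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, pc - R @ qc


def _rot_z(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])


def _rot_y(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1.0, 0], [-s, 0, c]])


def brute_force_tm(P, Q, d0, l_norm):
    N = len(P)

    def score(R, t):
        d2 = ((Q @ R.T + t - P) ** 2).sum(1)
        return float((1.0 / (1.0 + d2 / d0**2)).sum() / l_norm)

    def polish(R, t, iters=10):
        best = score(R, t)
        for _ in range(iters):
            d2 = ((Q @ R.T + t - P) ** 2).sum(1)
            inl = np.flatnonzero(d2 < d0**2)
            if inl.size < 4:
                inl = np.argsort(d2)[:4]
            R, t = _kabsch_svd(P[inl], Q[inl])
            best = max(best, score(R, t))
        return best

    best = 0.0
    for L in sorted({N, max(4, N // 2), max(4, N // 4), 5}):
        for s in range(0, N - L + 1):
            R, t = _kabsch_svd(P[s:s + L], Q[s:s + L])
            best = max(best, polish(R, t))
    angles = np.linspace(0.0, 2 * np.pi, 5, endpoint=False)
    for a, b, c in itertools.product(angles, repeat=3):
        R = _rot_z(a) @ _rot_y(b) @ _rot_z(c)
        t = P.mean(0) - R @ Q.mean(0)
        best = max(best, polish(R, t, iters=6))
    return best


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def test_packaged_cif_fixture_round_trip():
    from importlib import resources

    path = resources.files("ea2struct").joinpath("data/synthetic_helix60_seed3.cif")
    m = read_model(str(path))
    assert len(m) == 60
    assert m.plddt is not None and (m.plddt >= 0).all() and (m.plddt <= 100).all()


def test_pdb_and_mmcif_readers_agree(tmp_path):
    wt, _, _ = make_structure_pair(StructurePairSpec(length=40, seed=1))
    p_cif = tmp_path / "m.cif"
    p_pdb = tmp_path / "m.pdb"
    write_model(wt, p_cif)
    write_model(wt, p_pdb)
    a, b = read_model(p_cif), read_model(p_pdb)
    assert a.sequence == b.sequence == wt.sequence
    assert np.allclose(a.coords, b.coords, atol=2e-3)
    assert np.allclose(a.plddt, b.plddt, atol=1e-2)


def test_altloc_duplicates_keep_first(tmp_path):
    pdb = tmp_path / "alt.pdb"
    pdb.write_text(
        "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.60 55.00           C\n"
        "ATOM      2  CA BALA A   1       9.000   9.000   9.000  0.40 99.00           C\n"
        "ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00 44.00           C\n"
        "END\n")
    m = read_model(pdb)
    assert len(m) == 2
    assert np.allclose(m.coords[0], [0, 0, 0])
    assert m.plddt[0] == pytest.approx(55.0)


def test_no_backbone_raises(tmp_path):
    pdb = tmp_path / "bad.pdb"
    pdb.write_text(
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 55.00           N\n"
        "END\n")
    with pytest.raises(NoBackboneError, match="no backbone"):
        read_model(pdb)


# ---------------------------------------------------------------------------
# Kabsch
# ---------------------------------------------------------------------------

def test_kabsch_identity():
    P = np.random.default_rng(0).normal(size=(10, 3))
    R, t, rmsd = kabsch_superpose(P, P)
    assert np.allclose(R, np.eye(3), atol=1e-10)
    assert np.allclose(t, 0, atol=1e-10)
    assert rmsd < 1e-10


def test_kabsch_recovers_known_rotation():
    rng = np.random.default_rng(5)
    from scipy.spatial.transform import Rotation

    P = rng.normal(size=(25, 3)) * 5
    R_true = Rotation.random(random_state=rng).as_matrix()
    t_true = rng.uniform(-10, 10, 3)
    Q = (P - t_true) @ R_true  # so that Q @ R_true.T + t_true == P
    R, t, rmsd = kabsch_superpose(P, Q)
    assert rmsd < 1e-8
    assert np.allclose(R, R_true.T, atol=1e-8) or np.allclose(Q @ R.T + t, P, atol=1e-8)


def test_kabsch_mirror_image_stays_proper():
    rng = np.random.default_rng(7)
    P = rng.normal(size=(12, 3))
    Q = P * np.array([1.0, 1.0, -1.0])  # reflection
    R, t, rmsd = kabsch_superpose(P, Q)
    assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
    assert rmsd > 0.1


def test_kabsch_errors():
    P = np.zeros((5, 3))
    P[:, 0] = np.arange(5)  # collinear
    with pytest.raises(ValueError, match="degenerate"):
        kabsch_superpose(P, P)
    with pytest.raises(ValueError, match="length mismatch"):
        kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


def test_kabsch_beats_grid_rotations():
    """Kabsch RMSD is a lower bound over a grid of candidate rotations."""
    rng = np.random.default_rng(9)
    P = rng.normal(size=(20, 3)) * 4
    Q = P + rng.normal(0, 1.0, size=(20, 3))
    _, _, rmsd = kabsch_superpose(P, Q)
    angles = np.linspace(0, 2 * np.pi, 6, endpoint=False)
    for a, b, c in itertools.product(angles, repeat=3):
        R = _rot_z(a) @ _rot_y(b) @ _rot_z(c)
        t = P.mean(0) - R @ Q.mean(0)
        grid_rmsd = np.sqrt((((Q @ R.T + t) - P) ** 2).sum(1).mean())
        assert rmsd <= grid_rmsd + 1e-9


# ---------------------------------------------------------------------------
# TM-score
# ---------------------------------------------------------------------------

def test_tm_identity_is_one():
    wt, var, _ = make_structure_pair(StructurePairSpec(length=100, seed=3))
    res = tm_score(wt, var)
    assert res.tm == pytest.approx(1.0, abs=1e-12)
    assert res.n_aligned == 100


def test_tm_truncation_equals_fraction_exactly():
    for frac in (0.25, 0.5, 0.8):
        wt, var, expected = make_structure_pair(
            StructurePairSpec(length=100, truncation_fraction=frac, seed=3))
        res = tm_score(wt, var)
        assert res.tm == pytest.approx(expected, abs=1e-12)


def test_tm_rigid_motion_invariance():
    for seed in (1, 2, 3):
        wt, var, _ = make_structure_pair(
            StructurePairSpec(length=80, rigid_motion=True, seed=seed))
        assert tm_score(wt, var).tm == pytest.approx(1.0, abs=1e-6)


def test_tm_noise_monotonicity():
    """Expected TM never increases with coordinate noise (seeded replicates)."""
    means = []
    for noise in (0.0, 1.0, 2.0, 4.0):
        tms = []
        for seed in range(10):
            wt, var, _ = make_structure_pair(
                StructurePairSpec(length=60, noise_sd=noise, seed=seed))
            tms.append(tm_score(wt, var).tm)
        means.append(np.mean(tms))
    assert all(a >= b for a, b in zip(means, means[1:]))
    assert means[1] < 1.0


def test_tm_agrees_with_brute_force_oracle():
    """Seed-and-refine search matches a dense window + SO(3) grid oracle
    within 0.01 on 40-residue decoys."""
    cases = [
        StructurePairSpec(length=40, noise_sd=1.0, rigid_motion=True, seed=21),
        StructurePairSpec(length=40, noise_sd=2.5, rigid_motion=True, seed=22),
        StructurePairSpec(length=40, truncation_fraction=0.6, noise_sd=1.5,
                          rigid_motion=True, seed=23),
    ]
    for spec in cases:
        wt, var, _ = make_structure_pair(spec)
        res = tm_score(wt, var)
        pairs = pair_residues(wt.sequence, var.sequence)
        P = wt.coords[[i for i, _ in pairs]]
        Q = var.coords[[j for _, j in pairs]]
        oracle = brute_force_tm(P, Q, res.d0, len(wt))
        assert res.tm == pytest.approx(oracle, abs=0.01), spec


def test_tm_insufficient_overlap():
    wt, _, _ = make_structure_pair(StructurePairSpec(length=20, seed=1))
    tiny = StructureModel((1, 2), wt.sequence[:2], wt.coords[:2], wt.plddt[:2])
    with pytest.raises(InsufficientOverlapError):
        tm_score(wt, tiny)


def test_d0_formula():
    assert tm_d0(10) == 0.5  # floored
    assert tm_d0(2261) == pytest.approx(1.24 * (2261 - 15) ** (1 / 3) - 1.8, rel=1e-12)


def test_pair_residues_inframe_deletion_uses_gapped_alignment():
    wt = "MKTAYWQRST"
    var = "MKTWQRST"  # AY deleted
    pairs = pair_residues(wt, var)
    assert (0, 0) in pairs and (9, 7) in pairs
    assert len(pairs) == 8


# ---------------------------------------------------------------------------
# confidence metrics
# ---------------------------------------------------------------------------

def test_mean_plddt_and_lcr():
    wt, _, _ = make_structure_pair(
        StructurePairSpec(length=20, seed=1,
                          plddt_profile=tuple([50.0] * 10 + [49.9] * 5 + [70.0] * 5)))
    assert mean_plddt(wt) == pytest.approx((50 * 10 + 49.9 * 5 + 70 * 5) / 20, abs=0.005)
    # strict inequality at the threshold: the 50.0 residues do not count
    assert lcr_percent(wt) == pytest.approx(25.0)


def test_lcr_boundary_values():
    wt, _, _ = make_structure_pair(
        StructurePairSpec(length=20, seed=1, plddt_profile=tuple([50.0] * 20)))
    assert lcr_percent(wt) == 0.0
    wt2, _, _ = make_structure_pair(
        StructurePairSpec(length=20, seed=1, plddt_profile=tuple([49.9] * 20)))
    assert lcr_percent(wt2) == 100.0


def test_confidence_requires_plddt():
    wt, _, _ = make_structure_pair(StructurePairSpec(length=20, seed=1))
    bare = StructureModel(wt.residue_index, wt.sequence, wt.coords, None)
    with pytest.raises(ValueError, match="no confidence data"):
        mean_plddt(bare)
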