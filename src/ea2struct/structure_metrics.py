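"""Structure models, Kabsch superposition, TM-score, and confidence metrics.

Models are read from mmCIF or PDB files (one Cα per residue; per-residue
pLDDT taken from the isotropic-B field, the AlphaFold convention).  The
TM-score between a wild-type and a variant model is

    TM = (1 / L_norm) * Σ_aligned 1 / (1 + (d_i / d0)^2),

normalized by the wild-type residue count L_norm with
d0 = max(0.5, 1.24 * (L_norm − 15)^(1/3) − 1.8) Å.  Residue correspondence
is by sequence (variant models derive from the wild-type sequence, so no
structural alignment search is needed): longest common prefix, gapped
prefix+suffix matching for in-frame indels, and no correspondence for
frameshift novel tails, which therefore contribute zero.  The superposition
maximizing TM is searched over seed fragments (sliding windows of lengths
L, L/2, L/4) each refined by iterating superposition on a shrinking-cutoff
inlier set — the standard TM-score protocol.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "StructureModel",
    "TmResult",
    "read_model",
    "write_model",
    "kabsch_superpose",
    "tm_score",
    "tm_d0",
    "mean_plddt",
    "lcr_percent",
    "pair_residues",
    "NoBackboneError",
    "InsufficientOverlapError",
]

LCR_PLDDT_THRESHOLD = 50.0  # residues below this count as low-confidence


class NoBackboneError(ValueError):
    """Structure file contains no Cα atoms."""


class InsufficientOverlapError(ValueError):
    """Fewer than 3 residues can be placed in correspondence."""


@dataclass(frozen=True)
class StructureModel:
    """Ordered Cα trace with optional per-residue pLDDT."""

    residue_index: tuple[int, ...]
    sequence: str  # one-letter codes, same order as coords
    coords: np.ndarray  # (n, 3) Å
    plddt: np.ndarray | None = None  # (n,) in [0, 100]
    model_id: str = ""
    chain_id: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        n = len(self.residue_index)
        if coords.shape != (n, 3) or len(self.sequence) != n:
            raise ValueError("inconsistent residue count")
        if not np.isfinite(coords).all():
            raise ValueError("non-finite coordinates")
        if any(b <= a for a, b in zip(self.residue_index, self.residue_index[1:])):
            raise ValueError("residue_index not strictly increasing")
        if self.plddt is not None:
            pl = np.asarray(self.plddt, dtype=float)
            object.__setattr__(self, "plddt", pl)
            if pl.shape != (n,):
                raise ValueError("pLDDT length mismatch")
            if ((pl < 0) | (pl > 100)).any():
                raise ValueError("pLDDT outside [0, 100]")

    def __len__(self) -> int:
        return len(self.residue_index)


@dataclass(frozen=True)
class TmResult:
    tm: float
    d0: float
    n_aligned: int
    rmsd_aligned: float
    rotation: np.ndarray  # (3, 3), det +1
    translation: np.ndarray  # (3,)
    normalization_length: int


# ---------------------------------------------------------------------------
# File I/O (gemmi)
# ---------------------------------------------------------------------------

_FORMAT_MAP = {".cif": "mmcif", ".mmcif": "mmcif", ".pdb": "pdb", ".ent": "pdb"}


def read_model(path, format: str | None = None, chain_id: str | None = None) -> StructureModel:
    """Read a Cα trace (+ pLDDT from B-iso) from an mmCIF or PDB file.

    The first model is used; the first chain unless ``chain_id`` is given.
    Only the first altloc of each residue's Cα is kept.
    """
    path = os.fspath(path)
    if format is None:
        format = _FORMAT_MAP.get(os.path.splitext(path)[1].lower(), "mmcif")
    st = gemmi.read_structure(path, format=gemmi.CoorFormat.Pdb
                              if format == "pdb" else gemmi.CoorFormat.Mmcif)
    st.setup_entities()
    if len(st) == 0:
        raise NoBackboneError("no backbone")
    model = st[0]
    chain = None
    for ch in model:
        if chain_id is None or ch.name == chain_id:
            chain = ch
            break
    if chain is None:
        raise NoBackboneError(f"chain {chain_id!r} not found")
    idx, seq, xyz, pl = [], [], [], []
    for res in chain:
        ca = None
        for atom in res:
            if atom.name == "CA":
                ca = atom  # first altloc wins
                break
        if ca is None:
            continue
        idx.append(res.seqid.num)
        info = gemmi.find_tabulated_residue(res.name)
        seq.append(info.one_letter_code.upper() if info else "X")
        xyz.append([ca.pos.x, ca.pos.y, ca.pos.z])
        pl.append(ca.b_iso)
    if not idx:
        raise NoBackboneError("no backbone")
    return StructureModel(
        residue_index=tuple(idx),
        sequence="".join(seq),
        coords=np.array(xyz, dtype=float),
        plddt=np.array(pl, dtype=float),
        model_id=st.name or os.path.basename(path),
        chain_id=chain.name,
    )


_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL", "X": "UNK",
}


def write_model(m: StructureModel, path, format: str | None = None) -> None:
    """Write a Cα-only model as mmCIF or PDB (pLDDT into the B-iso field)."""
    path = os.fspath(path)
    if format is None:
        format = _FORMAT_MAP.get(os.path.splitext(path)[1].lower(), "mmcif")
    st = gemmi.Structure()
    st.name = m.model_id or "model"
    model = gemmi.Model("1")
    chain = gemmi.Chain(m.chain_id or "A")
    for i, (num, aa, xyz) in enumerate(zip(m.residue_index, m.sequence, m.coords)):
        res = gemmi.Residue()
        res.name = _ONE_TO_THREE.get(aa, "UNK")
        res.seqid = gemmi.SeqId(num, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*xyz)
        atom.occ = 1.0
        atom.b_iso = float(m.plddt[i]) if m.plddt is not None else 0.0
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    if format == "pdb":
        st.write_pdb(path)
    else:
        st.make_mmcif_document().write_file(path)


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(P, Q) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of Q onto P (proper rotation).

    Returns ``(R, t, rmsd)`` with ``Q' = Q @ R.T + t`` minimizing the RMSD
    to P over all proper rotations (det R = +1) and translations.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError("length mismatch")
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise ValueError("length mismatch: need >= 3 paired 3-vectors")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    if np.linalg.matrix_rank(P0, tol=1e-9) < 2 or np.linalg.matrix_rank(Q0, tol=1e-9) < 2:
        raise ValueError("degenerate point set")
    rot, _ = Rotation.align_vectors(P0, Q0)
    R = rot.as_matrix()
    t = pc - R @ qc
    # recompute from residuals: scipy's rssd carries cancellation noise
    rmsd = math.sqrt(float(np.mean(np.sum((Q @ R.T + t - P) ** 2, axis=1))))
    return R, t, rmsd


def tm_d0(l_norm: int) -> float:
    """Length-dependent TM-score normalization distance, floored at 0.5 Å."""
    if l_norm <= 15:
        return 0.5
    return max(0.5, 1.24 * (l_norm - 15) ** (1.0 / 3.0) - 1.8)


def pair_residues(wt_seq: str, var_seq: str) -> list[tuple[int, int]]:
    """Sequence-derived residue correspondence (0-based index pairs).

    Equal lengths pair everything (substitutions keep correspondence); a
    clean prefix pairs the prefix; an in-frame indel pairs prefix + suffix;
    a truncation whose tail still matches in frame pairs the whole variant;
    a frameshift novel tail pairs only the common prefix.
    """
    n_wt, n_var = len(wt_seq), len(var_seq)
    if n_wt == n_var:
        return [(i, i) for i in range(n_wt)]
    p = 0
    while p < min(n_wt, n_var) and wt_seq[p] == var_seq[p]:
        p += 1
    short, long_ = (var_seq, wt_seq) if n_var < n_wt else (wt_seq, var_seq)
    s = 0
    limit = len(short) - p
    while s < limit and short[-1 - s] == long_[-1 - s]:
        s += 1
    if p + s >= len(short):  # in-frame indel: prefix + suffix correspond
        s = len(short) - p
        pairs = [(i, i) for i in range(p)]
        pairs += [(n_wt - s + k, n_var - s + k) for k in range(s)]
        return pairs
    if n_var < n_wt:
        tail = min(5, n_var - p - 1)
        if tail > 0 and var_seq[-tail:] == wt_seq[n_var - tail:n_var]:
            return [(i, i) for i in range(n_var)]  # stopgain with cis subs
    return [(i, i) for i in range(p)]


def _tm_from_distances(d2: np.ndarray, d0: float, l_norm: int) -> float:
    return float(np.sum(1.0 / (1.0 + d2 / (d0 * d0))) / l_norm)


def tm_score(wt: StructureModel, var: StructureModel) -> TmResult:
    """TM-score of ``var`` against ``wt``, normalized by the wild-type length.

    Invariant under rigid motion of either model; equals the retained
    fraction exactly for a noiseless truncation; 1.0 iff every wild-type
    residue is matched at zero distance.
    """
    if len(wt) == 0 or len(var) == 0:
        raise InsufficientOverlapError("insufficient overlap")
    pairs = pair_residues(wt.sequence, var.sequence)
    if len(pairs) < 3:
        raise InsufficientOverlapError("insufficient overlap")
    l_norm = len(wt)
    d0 = tm_d0(l_norm)
    P = wt.coords[[i for i, _ in pairs]]
    Q = var.coords[[j for _, j in pairs]]
    n = len(pairs)

    best = None  # (tm, n_aligned, -rmsd, R, t)
    seen_windows = set()
    for frag in (n, max(4, n // 2), max(4, n // 4)):
        if frag > n:
            continue
        step = max(1, frag // 2)
        starts = list(range(0, n - frag + 1, step))
        if starts[-1] != n - frag:
            starts.append(n - frag)
        for s0 in starts:
            if (s0, frag) in seen_windows:
                continue
            seen_windows.add((s0, frag))
            cand = _refine_from_seed(P, Q, s0, frag, d0, l_norm)
            if cand is not None and (best is None or cand[:3] > best[:3]):
                best = cand

    tm, n_aligned, neg_rmsd, R, t = best
    return TmResult(
        tm=tm,
        d0=d0,
        n_aligned=n_aligned,
        rmsd_aligned=-neg_rmsd,
        rotation=R,
        translation=t,
        normalization_length=l_norm,
    )


def _refine_from_seed(P, Q, s0, frag, d0, l_norm, n_iter=8):
    """Iterative inlier refinement from one seed window.

    The distance cutoff shrinks from d0 toward d0/2 across iterations
    (minimum inlier set 4); TM is always scored on all paired residues
    under the final superposition.
    """
    idx = np.arange(s0, s0 + frag)
    try:
        R, t, _ = kabsch_superpose(P[idx], Q[idx])
    except ValueError:
        return None
    cutoffs = np.linspace(d0, max(d0 / 2.0, 0.5), n_iter)
    prev = None
    result = None
    for c in cutoffs:
        d2 = np.sum((Q @ R.T + t - P) ** 2, axis=1)
        inliers = np.flatnonzero(d2 < c * c)
        if inliers.size < 4:
            inliers = np.argsort(d2)[:4]
        tm = _tm_from_distances(d2, d0, l_norm)
        n_close = int(np.sum(d2 < d0 * d0))
        rmsd_close = float(np.sqrt(d2[d2 < d0 * d0].mean())) if n_close else float("inf")
        cand = (tm, n_close, -rmsd_close, R, t)
        if result is None or cand[:3] > result[:3]:
            result = cand
        key = inliers.tobytes()
        if key == prev and c <= cutoffs[-1]:
            break
        prev = key
        try:
            R, t, _ = kabsch_superpose(P[inliers], Q[inliers])
        except ValueError:
            break
    # score once more with the last superposition
    d2 = np.sum((Q @ R.T + t - P) ** 2, axis=1)
    tm = _tm_from_distances(d2, d0, l_norm)
    n_close = int(np.sum(d2 < d0 * d0))
    rmsd_close = float(np.sqrt(d2[d2 < d0 * d0].mean())) if n_close else float("inf")
    cand = (tm, n_close, -rmsd_close, R, t)
    if result is None or cand[:3] > result[:3]:
        result = cand
    return result


# ---------------------------------------------------------------------------
# Confidence metrics
# ---------------------------------------------------------------------------

def mean_plddt(m: StructureModel) -> float:
    """Arithmetic mean pLDDT over residues, 2 decimals."""
    if m.plddt is None or len(m) == 0:
        raise ValueError("no confidence data")
    return round(float(np.mean(m.plddt)), 2)


def lcr_percent(m: StructureModel, threshold: float = LCR_PLDDT_THRESHOLD) -> float:
    """Low-confidence residue ratio: % of residues with pLDDT strictly < threshold."""
    if m.plddt is None or len(m) == 0:
        raise ValueError("no confidence data")
    return round(100.0 * float(np.mean(m.plddt < threshold)), 2)
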