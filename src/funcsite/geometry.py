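"""Computational-geometry primitives for structure analysis.

Contains the optimal rigid superposition (Kabsch), backbone dihedral
calculation, a deterministic Shrake-Rupley solvent-accessible surface
area, and an iterative sequence-independent superposition of two backbone
segments (used to demonstrate internal-repeat equivalence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .structure import Residue, Structure

__all__ = [
    "Transform",
    "DihedralRecord",
    "SegmentAlignment",
    "kabsch_superpose",
    "dihedral",
    "backbone_dihedrals",
    "shrake_rupley_sasa",
    "relative_sasa",
    "superpose_segments",
    "VDW_RADII",
    "MAX_SASA",
]

#: van der Waals radii (Angstrom) used for SASA and cavity detection.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "SE": 1.90,
             "P": 1.80, "H": 1.20, "D": 1.20}
DEFAULT_RADIUS = 1.70

#: Maximum accessible surface area per residue type (A^2), theoretical
#: Gly-X-Gly values of Tien et al. 2013 — denominators for relative SASA.
MAX_SASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
    "MSE": 224.0,
}

CHAIN_BREAK_CN = 2.5  # A; C(i)-N(i+1) beyond this breaks dihedral continuity


@dataclass
class Transform:
    """Proper rigid motion y = R (x - centroid_b) + centroid_a mapping a
    moving point set b onto a fixed set a, with the post-fit RMSD."""
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # 3-vector
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass
class DihedralRecord:
    chain: str
    residue: tuple[int, str]  # (author number, icode)
    phi: float | None  # degrees in (-180, 180], None at termini/breaks
    psi: float | None


@dataclass
class SegmentAlignment:
    pairs: list[tuple[tuple[int, str], tuple[int, str]]]
    rmsd: float
    n_matched: int
    transform: Transform


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> Transform:
    """Least-squares optimal proper rotation+translation mapping *coords_b*
    onto *coords_a* (paired points, N >= 3).  Reflections are disallowed."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("point sets must both be N x 3")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 paired points")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    # collinear (rank < 2) point sets leave the rotation underdetermined
    if min(np.linalg.matrix_rank(a0, tol=1e-8), np.linalg.matrix_rank(b0, tol=1e-8)) < 2:
        raise ValueError("degenerate (collinear) point set")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rot, rssd = Rotation.align_vectors(a0, b0)
    rmsd = float(rssd / np.sqrt(n))
    rmat = rot.as_matrix()
    return Transform(rotation=rmat, translation=ca - rmat @ cb, rmsd=rmsd)


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = np.subtract(p1, p0)
    b1 = np.subtract(p2, p1)
    b2 = np.subtract(p3, p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    ang = -np.degrees(np.arctan2(m1 @ n2, n1 @ n2))
    return float(ang if ang != -180.0 else 180.0)


def _backbone(res: Residue) -> dict[str, np.ndarray] | None:
    atoms = {}
    for name in ("N", "CA", "C"):
        a = res.atom(name)
        if a is None:
            return None
        atoms[name] = a.coords
    return atoms


def backbone_dihedrals(structure: Structure, chain: str) -> list[DihedralRecord]:
    """Phi/psi per polymer residue of a chain.  A dihedral is undefined
    (None) at termini, at missing backbone atoms, and across chain breaks
    (C(i)-N(i+1) distance > 2.5 A, e.g. at unmodelled loops)."""
    residues = [r for r in structure.chains[chain] if r.kind == "polymer"]
    backs = [_backbone(r) for r in residues]
    records = []
    for i, res in enumerate(residues):
        phi = psi = None
        here = backs[i]
        if here is not None:
            prev = backs[i - 1] if i > 0 else None
            if prev is not None and np.linalg.norm(here["N"] - prev["C"]) <= CHAIN_BREAK_CN:
                phi = dihedral(prev["C"], here["N"], here["CA"], here["C"])
            nxt = backs[i + 1] if i + 1 < len(residues) else None
            if nxt is not None and np.linalg.norm(nxt["N"] - here["C"]) <= CHAIN_BREAK_CN:
                psi = dihedral(here["N"], here["CA"], here["C"], nxt["N"])
        records.append(DihedralRecord(chain=chain, residue=res.key, phi=phi, psi=psi))
    return records


def _golden_spiral(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden-angle spiral)."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def atom_radius(element: str) -> float:
    r = VDW_RADII.get(element.upper())
    if r is None:
        warnings.warn(f"no vdW radius for element {element!r}; using {DEFAULT_RADIUS} A")
        r = DEFAULT_RADIUS
    return r


def shrake_rupley_sasa(structure: Structure, probe: float = 1.4,
                       n_points: int = 960, chain: str | None = None,
                       ) -> tuple[dict[int, float], dict[tuple[str, int, str], float]]:
    """Shrake-Rupley solvent-accessible surface area.

    Each heavy polymer atom is surrounded by a deterministic golden-spiral
    lattice of *n_points* points at radius vdW+probe; the accessible fraction
    is the fraction of lattice points outside every neighbouring sphere.

    Returns (per-atom areas keyed by flat atom index, per-residue areas keyed
    by (chain, resnum, icode)).
    """
    records = structure.atom_records(chain=chain, include_hydrogens=False,
                                     kinds=("polymer",))
    if not records:
        return {}, {}
    coords = np.array([a.coords for _, _, a in records])
    radii = np.array([atom_radius(a.element) for _, _, a in records]) + probe
    sphere = _golden_spiral(n_points)
    tree = cKDTree(coords)
    per_atom: dict[int, float] = {}
    per_res: dict[tuple[str, int, str], float] = {}
    rmax = radii.max()
    for i in range(len(records)):
        pts = coords[i] + radii[i] * sphere
        neigh = [j for j in tree.query_ball_point(coords[i], radii[i] + rmax) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neigh:
            accessible &= np.einsum("ij,ij->i", pts - coords[j], pts - coords[j]) > radii[j] ** 2
            if not accessible.any():
                break
        area = 4.0 * np.pi * radii[i] ** 2 * accessible.mean()
        per_atom[i] = area
        cid, res, _ = records[i]
        key = (cid, res.number, res.icode)
        per_res[key] = per_res.get(key, 0.0) + area
    return per_atom, per_res


def relative_sasa(structure: Structure, per_residue: dict[tuple[str, int, str], float],
                  ) -> dict[tuple[str, int, str], float]:
    """Residue SASA divided by the residue type's Gly-X-Gly maximum."""
    out = {}
    for cid, residues in structure.chains.items():
        for res in residues:
            key = (cid, res.number, res.icode)
            if key in per_residue and res.name in MAX_SASA:
                out[key] = per_residue[key] / MAX_SASA[res.name]
    return out


# ---------------------------------------------------------------------------
# Sequence-independent segment superposition


def _ca_coords(structure: Structure, chain: str, lo: int, hi: int,
               ) -> tuple[np.ndarray, list[tuple[int, str]]]:
    coords, keys = [], []
    for res in structure.chains[chain]:
        if res.kind == "polymer" and lo <= res.number <= hi:
            ca = res.atom("CA")
            if ca is not None:
                coords.append(ca.coords)
                keys.append(res.key)
    return np.array(coords), keys


def _dp_pairs(dist: np.ndarray, cutoff: float) -> list[tuple[int, int]]:
    """Order-preserving pairing maximising sum of max(0, cutoff - d)."""
    score = np.maximum(0.0, cutoff - dist)
    n, m = score.shape
    dp = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            dp[i, j] = max(dp[i - 1, j], dp[i, j - 1], dp[i - 1, j - 1] + score[i - 1, j - 1])
    pairs = []
    i, j = n, m
    while i > 0 and j > 0:
        if dp[i, j] == dp[i - 1, j - 1] + score[i - 1, j - 1] and score[i - 1, j - 1] > 0:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif dp[i, j] == dp[i - 1, j]:
            i -= 1
        else:
            j -= 1
    return pairs[::-1]


def superpose_segments(structure: Structure, chain: str,
                       seg_a: tuple[int, int], seg_b: tuple[int, int],
                       cutoff: float = 5.0, max_iter: int = 50,
                       structure_b: "Structure | None" = None,
                       chain_b: str | None = None) -> SegmentAlignment:
    """Iteratively superpose two backbone segments without using sequence.

    Starts from a gapless midpoint-anchored correspondence, then alternates
    Kabsch fitting with order-preserving dynamic-programming re-pairing on
    the inter-segment Ca distance matrix (score max(0, cutoff - d)) until the
    pair set is stable.
    """
    sb = structure_b or structure
    cb = chain_b or chain
    xa, keys_a = _ca_coords(structure, chain, *seg_a)
    xb, keys_b = _ca_coords(sb, cb, *seg_b)
    if len(xa) < 10 or len(xb) < 10:
        raise ValueError("segments must each have >= 10 residues with Ca")
    # midpoint-anchored gapless initial correspondence
    n = min(len(xa), len(xb))
    off_a = (len(xa) - n) // 2
    off_b = (len(xb) - n) // 2
    pairs = [(off_a + k, off_b + k) for k in range(n)]
    if len(pairs) < 3:
        raise ValueError("no initial correspondence with >= 3 pairs")
    transform = None
    for _ in range(max_iter):
        ia = [p[0] for p in pairs]
        ib = [p[1] for p in pairs]
        transform = kabsch_superpose(xa[ia], xb[ib])
        moved = transform.apply(xb)
        dist = np.linalg.norm(xa[:, None, :] - moved[None, :, :], axis=2)
        new_pairs = _dp_pairs(dist, cutoff)
        if len(new_pairs) < 3:
            break
        if new_pairs == pairs:
            pairs = new_pairs
            break
        pairs = new_pairs
    ia = [p[0] for p in pairs]
    ib = [p[1] for p in pairs]
    transform = kabsch_superpose(xa[ia], xb[ib])
    return SegmentAlignment(
        pairs=[(keys_a[i], keys_b[j]) for i, j in pairs],
        rmsd=transform.rmsd, n_matched=len(pairs), transform=transform)
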