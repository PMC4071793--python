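"""Ground-truth fixture generators.

Every detector in the package is testable offline against structures and
alignments built here with known, planted answers: backbones with
prescribed dihedrals, 3-residue acidic constellations placed at a known
rigid transform plus controlled noise, hollow atom shells enclosing a
cavity of analytic volume, and alignments evolved along a known tree under
the same Poisson model the distance correction assumes.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import dendropy
import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .conservation import AMINO_ACIDS, Alignment
from .geometry import Transform, _golden_spiral
from .site import FUNCTIONAL_ATOMS, SiteTemplate
from .structure import Atom, Residue, Structure

__all__ = [
    "PlantedGroundTruth",
    "build_helix",
    "plant_triad",
    "make_cavity_shell",
    "make_nest_backbone",
    "simulate_msa",
    "random_additive_tree",
    "tree_distance_matrix",
]

# ideal peptide geometry (bond lengths A, bond angles deg)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7


@dataclass
class PlantedGroundTruth:
    kind: str  # triad | cavity | nest | msa
    payload: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D given A-B-C and internal coordinates (natural-extension
    reference frame)."""
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * math.cos(ang),
                   bond * math.sin(ang) * math.cos(tor),
                   bond * math.sin(ang) * math.sin(tor)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_helix(n: int, phi: float | np.ndarray = -57.0,
                psi: float | np.ndarray = -47.0, omega: float = 180.0,
                chain: str = "A", res_name: str = "ALA",
                start_number: int = 1) -> Structure:
    """Backbone (N, CA, C) chain of *n* residues built by internal-coordinate
    extension at ideal peptide geometry; recovered dihedrals equal the
    inputs.  *phi*/*psi* may be scalars or per-residue arrays."""
    if n < 1:
        raise ValueError("need n >= 1 residues")
    phis = np.broadcast_to(np.asarray(phi, dtype=float), (n,))
    psis = np.broadcast_to(np.asarray(psi, dtype=float), (n,))
    coords: list[dict[str, np.ndarray]] = []
    n0 = np.zeros(3)
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n):
        prev = coords[i - 1]
        ni = _nerf(prev["N"], prev["CA"], prev["C"],
                   BOND_C_N, ANGLE_CA_C_N, psis[i - 1])
        cai = _nerf(prev["CA"], prev["C"], ni,
                    BOND_N_CA, ANGLE_C_N_CA, omega)
        ci = _nerf(prev["C"], ni, cai,
                   BOND_CA_C, ANGLE_N_CA_C, phis[i])
        coords.append({"N": ni, "CA": cai, "C": ci})
    struct = Structure(id=f"helix{n}")
    for i, atom_map in enumerate(coords):
        atoms = [Atom(name=nm, element=nm[0], coords=atom_map[nm])
                 for nm in ("N", "CA", "C")]
        struct.add_residue(chain, Residue(name=res_name, number=start_number + i,
                                          atoms=atoms))
    return struct


def plant_triad(base: Structure, template: SiteTemplate, noise_sigma: float,
                seed: int = 0, chain: str | None = None,
                center: np.ndarray | None = None,
                ) -> tuple[Structure, PlantedGroundTruth]:
    """Rebuild three residues of *base* so their functional atoms are a
    rigidly transformed copy of the template plus isotropic Gaussian noise.

    The constellation is centred at *center* (default: near the structure
    centroid).  The ground truth records the chosen residue keys, the exact
    transform, and the noisy coordinates (for oracle superposition)."""
    if noise_sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    rng = np.random.default_rng(seed)
    cid = chain or next(iter(base.chains))
    polymer = [r for r in base.chains[cid] if r.kind == "polymer"]
    m = len(template.members)
    if len(polymer) < m:
        raise ValueError("base structure too small to plant the template")
    picks = [polymer[round(k * (len(polymer) - 1) / (m - 1))] for k in range(m)]

    rotation = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
    if center is None:
        translation = base.coords().mean(axis=0) + rng.normal(scale=5.0, size=3)
    else:
        translation = np.asarray(center, dtype=float)
    tmpl_centroid = np.vstack([mem.coords for mem in template.members]).mean(axis=0)

    keys = []
    planted_coords = []
    for mem, res in zip(template.members, picks):
        new_name = sorted(c for c in mem.classes if c in FUNCTIONAL_ATOMS)[0]
        res.name = new_name
        res.kind = "polymer"
        atom_names = FUNCTIONAL_ATOMS[new_name]
        moved = (mem.coords - tmpl_centroid) @ rotation.T + translation
        noisy = moved + rng.normal(scale=noise_sigma, size=moved.shape)
        res.atoms = [a for a in res.atoms if a.name in ("N", "CA", "C", "O")]
        for nm, xyz in zip(atom_names, noisy):
            res.atoms.append(Atom(name=nm, element=nm[0], coords=xyz))
        keys.append((cid, res.number, res.icode))
        planted_coords.append(noisy)
    truth = PlantedGroundTruth(
        kind="triad", seed=seed,
        payload={"residues": keys,
                 "transform": Transform(rotation=rotation,
                                        translation=translation, rmsd=0.0),
                 "coords": np.vstack(planted_coords),
                 "template_coords": np.vstack(
                     [mem.coords for mem in template.members])})
    return base, truth


def make_cavity_shell(inner_radius: float, atom_radius: float = 1.7,
                      shell_layers: int = 2, spacing: float = 2.2,
                      probe: float = 1.4,
                      ) -> tuple[Structure, PlantedGroundTruth]:
    """Hollow sphere of pseudo-atoms enclosing a void of *inner_radius*.

    Atom centres sit on concentric golden-spiral lattices starting at
    inner_radius + atom_radius + probe, so that grid points farther than
    vdW+probe from every atom fill the intended interior sphere (plus a
    small positive bulge between lattice atoms, kept below ~5% of the void
    volume by the default lattice spacing).  Generation fails if the shell
    leaks (checked by flood fill).
    """
    if inner_radius < 4:
        raise ValueError("inner radius must be >= 4 A")
    layer_gap = atom_radius
    struct = Structure(id=f"shell{inner_radius:g}")
    num = 1
    for layer in range(shell_layers):
        radius = inner_radius + atom_radius + probe + layer * layer_gap
        n_atoms = int(math.ceil(4.0 * math.pi * radius ** 2 / spacing ** 2 * 1.3))
        pts = _golden_spiral(n_atoms) * radius
        if layer % 2 == 1:  # stagger alternate layers to seal gaps
            rot = Rotation.from_euler("z", 180.0 / n_atoms ** 0.5, degrees=True)
            pts = pts @ rot.as_matrix().T
        for xyz in pts:
            struct.add_residue("A", Residue(
                name="UNK", number=num, kind="polymer",
                atoms=[Atom(name="CA", element="C", coords=xyz)]))
            num += 1
    _check_sealed(struct, inner_radius, atom_radius, probe, spacing)
    truth = PlantedGroundTruth(
        kind="cavity",
        payload={"volume": 4.0 / 3.0 * math.pi * inner_radius ** 3,
                 "inner_radius": inner_radius,
                 "centroid": np.zeros(3)})
    return struct, truth


def _check_sealed(struct: Structure, inner_radius: float, atom_radius: float,
                  probe: float, spacing: float) -> None:
    """Flood-fill self check: interior free space must not reach the box
    boundary through the shell."""
    import scipy.ndimage as ndi

    coords = struct.coords()
    grid_spacing = 1.0
    lo = coords.min(axis=0) - 3.0
    hi = coords.max(axis=0) + 3.0
    shape = np.ceil((hi - lo) / grid_spacing).astype(int) + 1
    axes = [lo[d] + grid_spacing * np.arange(shape[d]) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    tree = cKDTree(coords)
    d, _ = tree.query(pts, k=1, workers=-1)
    free = (d > atom_radius + probe).reshape(tuple(shape))
    labels, _ = ndi.label(free)
    centre_idx = tuple(np.round((-lo) / grid_spacing).astype(int))
    interior_label = labels[centre_idx]
    boundary_labels = set(np.unique(labels[0])) | set(np.unique(labels[-1])) | \
        set(np.unique(labels[:, 0])) | set(np.unique(labels[:, -1])) | \
        set(np.unique(labels[:, :, 0])) | set(np.unique(labels[:, :, -1]))
    if interior_label == 0 or interior_label in boundary_labels:
        raise ValueError("shell parameters leak: interior connects to exterior "
                         "(reduce lattice spacing or add layers)")


def make_nest_backbone(pattern: str, chain: str = "A") -> Structure:
    """Backbone whose interior residues follow the given R/L conformation
    pattern (R: phi=-80, psi=-20; L: phi=+80, psi=+20), flanked by one
    extended residue on each side so all pattern dihedrals are defined."""
    if len(pattern) < 2:
        raise ValueError("pattern needs length >= 2")
    if set(pattern) - {"R", "L"}:
        raise ValueError(f"invalid pattern characters in {pattern!r}")
    phi_map = {"R": -80.0, "L": 80.0}
    psi_map = {"R": -20.0, "L": 20.0}
    phis = [-150.0] + [phi_map[c] for c in pattern] + [-150.0]
    psis = [150.0] + [psi_map[c] for c in pattern] + [150.0]
    return build_helix(len(pattern) + 2, phi=np.array(phis), psi=np.array(psis),
                       chain=chain)


# ---------------------------------------------------------------------------
# Sequence evolution


def simulate_msa(tree: dendropy.Tree, n_columns: int, rate: float = 1.0,
                 invariant_fraction: float = 0.0, seed: int = 0,
                 ) -> tuple[Alignment, PlantedGroundTruth]:
    """Evolve sequences along *tree* under a Poisson substitution model.

    The root sequence is uniform over the 20 amino acids; along each branch
    of length t every non-invariant site substitutes with probability
    1 - exp(-rate * t) to a uniformly chosen different residue — the model
    whose pairwise distances the Poisson correction inverts.  A fixed
    fraction of sites never changes (planted invariant columns).
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if not 0 <= invariant_fraction <= 1:
        raise ValueError("invariant_fraction must be in [0,1]")
    rng = np.random.default_rng(seed)
    invariant = rng.random(n_columns) < invariant_fraction
    root_seq = rng.integers(0, 20, size=n_columns)
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
    rows: dict[str, str] = {}
    ids: list[str] = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            seq = root_seq
        else:
            parent_seq = seqs[id(node.parent_node)]
            t = node.edge.length or 0.0
            p_sub = 1.0 - math.exp(-rate * t)
            seq = parent_seq.copy()
            hit = (rng.random(n_columns) < p_sub) & ~invariant
            if hit.any():
                shift = rng.integers(1, 20, size=int(hit.sum()))
                seq[hit] = (seq[hit] + shift) % 20
            seqs[id(node)] = seq
        if node.is_leaf():
            label = node.taxon.label
            ids.append(label)
            rows[label] = "".join(AMINO_ACIDS[k] for k in seq)
    truth = PlantedGroundTruth(
        kind="msa", seed=seed,
        payload={"tree": tree, "rate": rate,
                 "invariant_columns": np.where(invariant)[0]})
    return Alignment(ids=ids, rows=rows), truth


def random_additive_tree(n_taxa: int, seed: int = 0,
                         min_internal: float = 0.1,
                         max_branch: float = 1.0) -> dendropy.Tree:
    """Random unrooted binary topology with branch lengths drawn uniformly;
    internal branches are at least *min_internal* substitutions/site."""
    if n_taxa < 3:
        raise ValueError("need >= 3 taxa")
    rng = np.random.default_rng(seed)
    labels = [f"T{i}" for i in range(n_taxa)]
    ns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = False
    nodes = [dendropy.Node(taxon=t) for t in ns]
    root = dendropy.Node()
    for node in nodes[:3]:
        root.add_child(node)
    tree.seed_node = root
    edges = list(nodes[:3])
    for leaf in nodes[3:]:
        # split a random existing edge with a new internal node
        target = edges[int(rng.integers(0, len(edges)))]
        parent = target.parent_node
        mid = dendropy.Node()
        parent.remove_child(target)
        parent.add_child(mid)
        mid.add_child(target)
        mid.add_child(leaf)
        edges.extend([leaf, mid])
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        is_internal = not edge.head_node.is_leaf()
        low = min_internal if is_internal else 0.05
        edge.length = float(low + rng.uniform(0, max_branch - low))
    return tree


def tree_distance_matrix(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Additive leaf-to-leaf path-length distances (taxa sorted by label)."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return [t.label for t in taxa], d
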