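"""Structural evidence for functional-site prediction.

Four detectors and an integrator:

* 3-residue catalytic-template matching — finds constellations of acidic
  residues whose functional-atom geometry superposes onto a template
  (e.g. the Asp/Asp/Glu triad of a GH9 cellulase) below an RMSD cutoff,
  allowing Asp<->Glu class equivalence and carboxylate O1/O2 symmetry.
* Nest detection — short backbone stretches of alternating right/left
  (alpha-R/alpha-L) conformation whose main-chain NH groups form an
  anion-binding concavity.
* Cavity detection — a LIGSITE-style grid scan: free grid points enclosed
  by protein along most of 7 scan directions, clustered into cavities.
* Exposed-aromatic detection — surface Trp/Tyr/Phe/His residues, a
  signature of carbohydrate-binding surfaces.

`integrate_evidence` combines the detectors per cavity into a ranked
site report.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi
from scipy.spatial import cKDTree

from .conservation import ConservationProfile
from .geometry import Transform, atom_radius, backbone_dihedrals, kabsch_superpose
from .structure import Structure

__all__ = [
    "SiteTemplate", "TemplateHit", "Nest", "Cavity", "SiteReport",
    "FUNCTIONAL_ATOMS", "extract_template", "match_template",
    "detect_nests", "detect_cavities", "exposed_aromatics",
    "integrate_evidence",
]

#: Ordered functional-atom names per residue class; the first atom is the
#: anchor (carboxylate carbon) and the remaining pair may be swapped
#: (chemically symmetric oxygens).
FUNCTIONAL_ATOMS = {
    "ASP": ("CG", "OD1", "OD2"),
    "GLU": ("CD", "OE1", "OE2"),
}

#: Residue classes treated as interchangeable during matching.
DEFAULT_EQUIVALENCES = {"ASP": {"ASP", "GLU"}, "GLU": {"ASP", "GLU"}}

AROMATIC_TYPES = ("TRP", "TYR", "PHE", "HIS")


@dataclass
class TemplateMember:
    classes: list[str]  # acceptable residue names
    atoms: dict[str, list[str]]  # residue name -> ordered atom names
    coords: np.ndarray  # (k, 3) functional-atom coordinates

    def to_json(self) -> dict:
        return {"classes": sorted(self.classes),
                "atoms": {k: list(v) for k, v in self.atoms.items()},
                "coords": np.asarray(self.coords).round(4).tolist()}


@dataclass
class SiteTemplate:
    name: str
    members: list[TemplateMember]
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.members) < 3:
            raise ValueError("a site template needs >= 3 members")
        arity = {len(m.coords) for m in self.members}
        for m in self.members:
            for cls, names in m.atoms.items():
                if len(names) != len(m.coords):
                    raise ValueError(
                        f"member atom group for {cls} has wrong arity")
        del arity

    def to_json(self) -> dict:
        return {"name": self.name, "source": self.source,
                "members": [m.to_json() for m in self.members]}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1))

    @classmethod
    def from_json(cls, data: dict | str | Path) -> "SiteTemplate":
        if not isinstance(data, dict):
            data = json.loads(Path(data).read_text())
        members = [TemplateMember(classes=list(m["classes"]),
                                  atoms={k: list(v) for k, v in m["atoms"].items()},
                                  coords=np.asarray(m["coords"], dtype=float))
                   for m in data["members"]]
        return cls(name=data["name"], members=members, source=data.get("source", ""))


@dataclass
class TemplateHit:
    residues: list[tuple[str, int, str]]  # (chain, number, icode), template order
    correspondence: dict[int, tuple[str, int, str]]  # member index -> residue
    rmsd: float
    transform: Transform


@dataclass
class Nest:
    chain: str
    start: tuple[int, str]
    end: tuple[int, str]
    pattern: str  # over {R, L}, the classified run (excludes trailing residue)

    @property
    def n_residues(self) -> int:
        return len(self.pattern) + 1


@dataclass
class Cavity:
    grid_points: int
    volume: float
    centroid: np.ndarray
    lining_residues: list[tuple[str, int, str]]
    rank: int = 0
    spacing: float = 0.0


@dataclass
class SiteEvidence:
    cavity: Cavity
    mean_conservation: float
    template_hits: list[TemplateHit]
    nests: list[Nest]
    aromatics_nearby: list[tuple[str, int, str]]
    score: float


@dataclass
class SiteReport:
    sites: list[SiteEvidence]
    weights: tuple[float, ...]

    def to_json(self) -> dict:
        out = []
        for s in self.sites:
            out.append({
                "rank": s.cavity.rank,
                "volume": round(s.cavity.volume, 1),
                "centroid": np.asarray(s.cavity.centroid).round(2).tolist(),
                "lining_residues": [list(k) for k in s.cavity.lining_residues],
                "mean_conservation": round(s.mean_conservation, 4),
                "template_hits": [
                    {"residues": [list(k) for k in h.residues],
                     "rmsd": round(h.rmsd, 4)} for h in s.template_hits],
                "nests": [{"chain": n.chain, "start": list(n.start),
                           "end": list(n.end), "pattern": n.pattern}
                          for n in s.nests],
                "aromatics_nearby": [list(k) for k in s.aromatics_nearby],
                "score": round(s.score, 4),
            })
        return {"weights": list(self.weights), "sites": out}


# ---------------------------------------------------------------------------
# Template extraction and matching


def extract_template(structure: Structure, residue_keys: list[tuple[str, int, str]],
                     class_equivalences: dict[str, set[str]] | None = None,
                     name: str = "site") -> SiteTemplate:
    """Build a template from the functional atoms of the given residues.

    *residue_keys* are (chain, number, icode); every residue must carry the
    full functional-atom group of its type (e.g. CG/OD1/OD2 for Asp).
    """
    equiv = class_equivalences or DEFAULT_EQUIVALENCES
    members = []
    for cid, num, icode in residue_keys:
        res = structure.get_residue(cid, num, icode)
        if res.name not in FUNCTIONAL_ATOMS:
            raise ValueError(f"residue {res.name}{num}: no functional-atom definition")
        atom_names = FUNCTIONAL_ATOMS[res.name]
        coords = []
        for an in atom_names:
            atom = res.atom(an)
            if atom is None:
                raise ValueError(f"residue {res.name}{num} lacks functional atom {an}")
            coords.append(atom.coords)
        classes = sorted(equiv.get(res.name, {res.name}))
        members.append(TemplateMember(
            classes=classes,
            atoms={c: list(FUNCTIONAL_ATOMS[c]) for c in classes if c in FUNCTIONAL_ATOMS},
            coords=np.array(coords)))
    return SiteTemplate(name=name, members=members,
                        source=f"{structure.id} " + ";".join(
                            f"{c}{n}{i}" for c, n, i in residue_keys))


def _candidate_residues(structure: Structure, classes: set[str]):
    """All residues whose type is in *classes* and that carry the full
    functional-atom group: (key, anchor coords, (k,3) group coords)."""
    out = []
    for cid, residues in structure.chains.items():
        for res in residues:
            if res.kind != "polymer" or res.name not in classes:
                continue
            names = FUNCTIONAL_ATOMS.get(res.name)
            if names is None or not res.has_atoms(list(names)):
                continue
            coords = np.array([res.atom(n).coords for n in names])
            out.append(((cid, res.number, res.icode), coords))
    return out


def _oxygen_swaps(k: int):
    """Coordinate-row orderings allowed per member: identity and the swap of
    the two symmetric oxygens (rows 1 and 2 of a carboxylate group)."""
    if k != 3:
        return [tuple(range(k))]
    return [(0, 1, 2), (0, 2, 1)]


def match_template(structure: Structure, template: SiteTemplate,
                   rmsd_cutoff: float = 2.5, max_span: float = 15.0,
                   span_slack: float = 3.0) -> list[TemplateHit]:
    """Find residue constellations matching a site template.

    Enumerates assignments of distinct candidate residues to template
    members, pre-filtering on anchor-atom pairwise distances (within
    *span_slack* of the template's own and below *max_span*), then takes the
    minimum Kabsch RMSD over symmetric-oxygen swaps.  Hits with RMSD <=
    *rmsd_cutoff* are returned sorted by RMSD, one per residue set.
    """
    m = len(template.members)
    tmpl_anchor = np.array([mem.coords[0] for mem in template.members])
    tmpl_pair = np.linalg.norm(tmpl_anchor[:, None] - tmpl_anchor[None, :], axis=2)

    all_classes = set().union(*(set(mem.classes) for mem in template.members))
    cands = _candidate_residues(structure, all_classes)
    if not cands:
        return []
    keys = [c[0] for c in cands]
    groups = [c[1] for c in cands]
    anchors = np.array([g[0] for g in groups])
    names = {k: None for k in keys}
    del names
    res_class = {}
    for cid, residues in structure.chains.items():
        for res in residues:
            res_class[(cid, res.number, res.icode)] = res.name

    # candidate indices allowed per member
    allowed = [[i for i, k in enumerate(keys) if res_class[k] in mem.classes]
               for mem in template.members]
    pair_d = np.linalg.norm(anchors[:, None] - anchors[None, :], axis=2)

    best: dict[frozenset, TemplateHit] = {}
    for assign in itertools.product(*allowed):
        if len(set(assign)) != m:
            continue
        ok = True
        for i in range(m):
            for j in range(i + 1, m):
                d = pair_d[assign[i], assign[j]]
                if d > max_span or abs(d - tmpl_pair[i, j]) > span_slack:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        tmpl_coords_base = [np.asarray(mem.coords) for mem in template.members]
        query_coords = [groups[a] for a in assign]
        best_rmsd, best_tr = np.inf, None
        swap_sets = [_oxygen_swaps(len(c)) for c in tmpl_coords_base]
        for swaps in itertools.product(*swap_sets):
            tc = np.vstack([tmpl_coords_base[i][list(swaps[i])] for i in range(m)])
            qc = np.vstack(query_coords)
            tr = kabsch_superpose(qc, tc)  # map template onto query
            if tr.rmsd < best_rmsd:
                best_rmsd, best_tr = tr.rmsd, tr
        if best_rmsd <= rmsd_cutoff:
            key = frozenset(keys[a] for a in assign)
            hit = TemplateHit(residues=[keys[a] for a in assign],
                              correspondence={i: keys[a] for i, a in enumerate(assign)},
                              rmsd=best_rmsd, transform=best_tr)
            if key not in best or hit.rmsd < best[key].rmsd:
                best[key] = hit
    hits = sorted(best.values(), key=lambda h: (h.rmsd, h.residues))
    return hits


# ---------------------------------------------------------------------------
# Nest detection


def _classify_nest(phi: float | None, psi: float | None) -> str | None:
    if phi is None or psi is None or abs(psi) > 90:
        return None
    if -140 < phi < -20:
        return "R"
    if 20 < phi < 140:
        return "L"
    return None


def detect_nests(structure: Structure, chain: str) -> list[Nest]:
    """Detect backbone nests: maximal runs of >= 2 consecutive residues with
    alternating alpha-R/alpha-L conformation (phi in the R or L window,
    |psi| <= 90).  The nest spans the run plus the following residue, whose
    main-chain NH completes the anion-binding concavity."""
    records = backbone_dihedrals(structure, chain)
    labels = [_classify_nest(r.phi, r.psi) for r in records]
    keys = [r.residue for r in records]
    nests = []
    i = 0
    n = len(labels)
    while i < n:
        if labels[i] is None:
            i += 1
            continue
        j = i
        while (j + 1 < n and labels[j + 1] is not None
               and labels[j + 1] != labels[j]):
            j += 1
        run_len = j - i + 1
        if run_len >= 2 and j + 1 < n:
            nests.append(Nest(chain=chain, start=keys[i], end=keys[j + 1],
                              pattern="".join(labels[i:j + 1])))
        i = j + 1
    return nests


# ---------------------------------------------------------------------------
# Cavity detection (LIGSITE-style protein-solvent-protein grid scan)

SCAN_DIRECTIONS = np.array([
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
])


def _enclosed_along(mask: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """True where a voxel has protein both before and after it along the
    (signed) scan line through *direction*."""
    before = _occupied_towards(mask, -direction)
    after = _occupied_towards(mask, direction)
    return before & after


def _occupied_towards(mask: np.ndarray, step: np.ndarray) -> np.ndarray:
    """True where any voxel strictly beyond this one in direction *step*
    (unit grid steps) is protein.  Computed by plane-by-plane accumulation."""
    dx, dy, dz = (int(s) for s in step)
    nx = mask.shape[0]
    acc = np.zeros_like(mask)
    # accumulate along x planes; shift in (y, z) per plane step
    rng = range(nx - 2, -1, -1) if dx > 0 else range(1, nx) if dx < 0 else None
    if rng is None:
        # pure y/z direction: accumulate along that axis instead
        axis = 1 if dy != 0 else 2
        d = dy if axis == 1 else dz
        acc = np.zeros_like(mask)
        idx = [slice(None)] * 3
        n = mask.shape[axis]
        planes = range(n - 2, -1, -1) if d > 0 else range(1, n)
        for k in planes:
            src = k + (1 if d > 0 else -1)
            idx_k, idx_src = list(idx), list(idx)
            idx_k[axis], idx_src[axis] = k, src
            acc[tuple(idx_k)] = acc[tuple(idx_src)] | mask[tuple(idx_src)]
        return acc
    for x in rng:
        src = x + (1 if dx > 0 else -1)
        plane = acc[src] | mask[src]
        # voxel (x,y,z) looks at (src, y+dy, z+dz): shift the plane by (-dy,-dz)
        shifted = np.zeros_like(plane)
        sy, sz = dy, dz
        src_y = slice(max(0, sy), plane.shape[0] + min(0, sy))
        dst_y = slice(max(0, -sy), plane.shape[0] + min(0, -sy))
        src_z = slice(max(0, sz), plane.shape[1] + min(0, sz))
        dst_z = slice(max(0, -sz), plane.shape[1] + min(0, -sz))
        shifted[dst_y, dst_z] = plane[src_y, src_z]
        acc[x] = shifted
    return acc


def detect_cavities(structure: Structure, spacing: float = 0.9,
                    probe: float = 1.4, psp_min: int = 5,
                    min_volume: float = 50.0,
                    chain: str | None = None) -> list[Cavity]:
    """Grid-based cavity detection and ranking.

    A grid (bounding box + 2 A margin) is marked protein within vdW+probe of
    any heavy polymer atom; each free point is scanned along 7 fixed
    directions (3 axes + 4 body diagonals) and kept as a pocket point when
    protein encloses it along >= *psp_min* directions.  26-connected pocket
    clusters of at least *min_volume* become cavities, ranked by volume
    (ties by centroid lexicographic order).  Heteroatoms and waters are
    excluded so ligand-occupied cavities are still found.
    """
    records = structure.atom_records(chain=chain, include_hydrogens=False,
                                     kinds=("polymer",))
    if not records:
        raise ValueError("structure has no polymer atoms")
    coords = np.array([a.coords for _, _, a in records])
    radii = np.array([atom_radius(a.element) for _, _, a in records]) + probe

    margin = 2.0
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 2)
    axes = [lo[d] + spacing * np.arange(shape[d]) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    grid_pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    tree = cKDTree(coords)
    rmax = radii.max()
    neigh = tree.query_ball_point(grid_pts, rmax, workers=-1)
    protein = np.zeros(len(grid_pts), dtype=bool)
    for idx, nb in enumerate(neigh):
        if nb:
            d2 = np.einsum("ij,ij->i", coords[nb] - grid_pts[idx], coords[nb] - grid_pts[idx])
            if np.any(d2 <= radii[nb] ** 2):
                protein[idx] = True
    mask = protein.reshape(shape)

    enclosed_count = np.zeros(shape, dtype=np.int8)
    for direction in SCAN_DIRECTIONS:
        enclosed_count += _enclosed_along(mask, direction)
    pocket = (~mask) & (enclosed_count >= psp_min)

    labels, n_lab = ndi.label(pocket, structure=np.ones((3, 3, 3), dtype=int))
    cavities = []
    for lab in range(1, n_lab + 1):
        sel = labels == lab
        count = int(sel.sum())
        volume = count * spacing ** 3
        if volume < min_volume:
            continue
        pts = grid_pts.reshape(*shape, 3)[sel]
        centroid = pts.mean(axis=0)
        lin_tree = cKDTree(pts)
        lining: list[tuple[str, int, str]] = []
        seen = set()
        contact = radii + spacing  # vdW + probe + spacing per atom
        near = lin_tree.query_ball_point(coords, contact.max(), workers=-1)
        for ai, nb in enumerate(near):
            if not nb:
                continue
            d = np.linalg.norm(pts[nb] - coords[ai], axis=1)
            if np.any(d <= contact[ai]):
                cid, res, _ = records[ai]
                key = (cid, res.number, res.icode)
                if key not in seen:
                    seen.add(key)
                    lining.append(key)
        cavities.append(Cavity(grid_points=count, volume=volume,
                               centroid=centroid, lining_residues=sorted(lining),
                               spacing=spacing))
    cavities.sort(key=lambda c: (-c.volume, tuple(np.round(c.centroid, 6))))
    for i, c in enumerate(cavities, start=1):
        c.rank = i
    return cavities


# ---------------------------------------------------------------------------
# Exposed aromatics and evidence integration


def exposed_aromatics(structure: Structure,
                      rel_sasa: dict[tuple[str, int, str], float],
                      types: tuple[str, ...] = AROMATIC_TYPES,
                      threshold: float = 0.2) -> list[tuple[str, int, str]]:
    """Aromatic residues with relative SASA >= threshold, most exposed first."""
    hits = []
    for cid, residues in structure.chains.items():
        for res in residues:
            key = (cid, res.number, res.icode)
            if res.name in types and rel_sasa.get(key, 0.0) >= threshold:
                hits.append((rel_sasa[key], key))
    hits.sort(key=lambda t: (-t[0], t[1]))
    return [k for _, k in hits]


DEFAULT_WEIGHTS = (1.0, 1.0, 2.0, 0.5, 0.5)


def integrate_evidence(structure: Structure, cavities: list[Cavity],
                       profile: ConservationProfile | None = None,
                       hits: list[TemplateHit] | None = None,
                       nests: list[Nest] | None = None,
                       aromatics: list[tuple[str, int, str]] | None = None,
                       weights: tuple[float, ...] = DEFAULT_WEIGHTS,
                       rmsd_cutoff: float = 2.5) -> SiteReport:
    """Combine per-cavity evidence into a ranked site report.

    Per cavity: w1 * volume/max-volume + w2 * mean lining conservation +
    w3 * (cutoff - best lining hit RMSD)/cutoff + w4 * nest present +
    w5 * min(5, exposed aromatics within 10 A of centroid)/5.
    """
    if len(weights) != 5:
        raise ValueError("weights must have 5 components")
    hits = hits or []
    nests = nests or []
    aromatics = aromatics or []
    vmax = max((c.volume for c in cavities), default=1.0) or 1.0

    aro_coords = {}
    for key in aromatics:
        res = structure.get_residue(key[0], key[1], key[2])
        ca = res.atom("CA")
        if ca is not None:
            aro_coords[key] = ca.coords

    sites = []
    for cav in cavities:
        lining = set(cav.lining_residues)
        cons = [profile.residue_scores[k] for k in lining
                if profile is not None and k in profile.residue_scores]
        mean_cons = float(np.mean(cons)) if cons else 0.0
        cav_hits = [h for h in hits if lining.issuperset(h.residues)]
        best_hit = min((h.rmsd for h in cav_hits), default=None)
        hit_term = (rmsd_cutoff - best_hit) / rmsd_cutoff if best_hit is not None else 0.0
        cav_nests = [nst for nst in nests
                     if any((nst.chain, num, ic) in lining
                            for num, ic in _nest_keys(nst))]
        near_aro = [k for k, c in aro_coords.items()
                    if np.linalg.norm(c - cav.centroid) <= 10.0]
        score = (weights[0] * cav.volume / vmax
                 + weights[1] * mean_cons
                 + weights[2] * max(0.0, hit_term)
                 + weights[3] * (1.0 if cav_nests else 0.0)
                 + weights[4] * min(5, len(near_aro)) / 5.0)
        sites.append(SiteEvidence(cavity=cav, mean_conservation=mean_cons,
                                  template_hits=sorted(cav_hits, key=lambda h: h.rmsd),
                                  nests=cav_nests, aromatics_nearby=sorted(near_aro),
                                  score=score))
    sites.sort(key=lambda s: (-s.score, -s.cavity.volume,
                              tuple(np.round(s.cavity.centroid, 6))))
    return SiteReport(sites=sites, weights=tuple(weights))


def _nest_keys(nest: Nest):
    # nests span consecutive author numbers start..end (same icode convention)
    return [(num, nest.start[1]) for num in range(nest.start[0], nest.end[0] + 1)]
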