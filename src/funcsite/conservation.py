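"""Per-column conservation scoring, structure mapping, and surface-patch
detection.

Conservation is scored as Jensen-Shannon divergence between a column's
amino-acid frequency vector and a fixed background distribution
(BLOSUM62-derived), normalised to [0,1] by the largest possible divergence
of any single-residue column against that background.  This is a
deterministic stand-in for phylogeny-aware rate estimation: it does not
weight sequences by relatedness, but it separates conserved from variable
columns well enough to localise conserved surface patches.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO
from scipy.spatial import cKDTree

from .structure import Structure, extract_sequence

__all__ = [
    "Alignment",
    "ConservationProfile",
    "Patch",
    "read_msa",
    "column_conservation",
    "map_to_structure",
    "conserved_patch",
    "BACKGROUND_FREQS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: BLOSUM62 background amino-acid frequencies (Henikoff & Henikoff marginals).
BACKGROUND_FREQS = {
    "A": 0.074, "C": 0.025, "D": 0.054, "E": 0.054, "F": 0.047,
    "G": 0.074, "H": 0.026, "I": 0.068, "K": 0.058, "L": 0.099,
    "M": 0.025, "N": 0.045, "P": 0.039, "Q": 0.034, "R": 0.052,
    "S": 0.057, "T": 0.051, "V": 0.073, "W": 0.013, "Y": 0.032,
}

PSEUDOCOUNT = (1.0 / 20.0) * 0.05  # added per amino acid before normalising


@dataclass
class Alignment:
    """Ordered multiple sequence alignment over 20 aa + gap + X."""
    ids: list[str]
    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(self.rows[i]) for i in self.ids}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")

    @property
    def length(self) -> int:
        return len(self.rows[self.ids[0]]) if self.ids else 0

    @property
    def n_rows(self) -> int:
        return len(self.ids)

    def column(self, j: int) -> str:
        return "".join(self.rows[i][j] for i in self.ids)

    def ungapped(self, row_id: str) -> tuple[str, list[int]]:
        """Row sequence without gaps, plus the source column of each letter."""
        seq, cols = [], []
        for j, ch in enumerate(self.rows[row_id]):
            if ch != "-":
                seq.append(ch)
                cols.append(j)
        return "".join(seq), cols


@dataclass
class ConservationProfile:
    column_scores: np.ndarray
    gap_fraction: np.ndarray
    residue_scores: dict[tuple[str, int, str], float] = field(default_factory=dict)


def read_msa(source: str | Path) -> Alignment:
    """Read a FASTA or Stockholm alignment (auto-detected).  Sequences are
    upper-cased and both '.' and '-' are treated as gap characters."""
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and Path(source).is_file()):
        text = Path(source).read_text()
    else:
        text = str(source)
    fmt = "stockholm" if text.lstrip().startswith("# STOCKHOLM") else "fasta"
    if fmt == "fasta":
        _check_fasta_rows(text)
    msa = AlignIO.read(io.StringIO(text), fmt)
    ids = [rec.id for rec in msa]
    rows = {rec.id: str(rec.seq).upper().replace(".", "-") for rec in msa}
    return Alignment(ids=ids, rows=rows)


def _check_fasta_rows(text: str) -> None:
    lengths: dict[str, int] = {}
    name = None
    for line in text.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0] if line[1:].split() else ""
            lengths[name] = 0
        elif name is not None:
            lengths[name] += len(line.strip())
    if len(set(lengths.values())) > 1:
        ragged = min(lengths, key=lambda k: lengths[k])
        raise ValueError(f"ragged alignment: row {ragged!r} has a different length")


def _column_freqs(column: str) -> tuple[np.ndarray | None, float]:
    """Pseudo-counted amino-acid frequency vector of a column (X and gaps
    excluded from counts) and the column's gap fraction.  The pseudo-count
    is applied in frequency space (the frequency vector is mixed with a
    total uniform mass of 20 x 1/20 x 0.05), so scores do not depend on the
    absolute number of rows — duplicating every row changes nothing."""
    counts = np.zeros(20)
    gaps = 0
    for ch in column:
        if ch == "-":
            gaps += 1
        elif ch in AA_INDEX:
            counts[AA_INDEX[ch]] += 1
    gap_fraction = gaps / len(column)
    if counts.sum() == 0:
        return None, gap_fraction
    freqs = counts / counts.sum() + PSEUDOCOUNT
    return freqs / freqs.sum(), gap_fraction


_BG = np.array([BACKGROUND_FREQS[a] for a in AMINO_ACIDS])
_BG = _BG / _BG.sum()


def _jsd(p: np.ndarray, q: np.ndarray) -> float:
    m = 0.5 * (p + q)
    def kl(x, y):
        mask = x > 0
        return float(np.sum(x[mask] * np.log2(x[mask] / y[mask])))
    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


def _max_point_mass_jsd() -> float:
    """Largest divergence any single-residue column can reach against the
    background, after the same frequency-space pseudo-counting applied to
    observed columns.  Convexity of JSD in its first argument makes this an
    upper bound for every mixed column."""
    best = 0.0
    for i in range(20):
        delta = np.full(20, PSEUDOCOUNT)
        delta[i] += 1.0
        best = max(best, _jsd(delta / delta.sum(), _BG))
    return best


_JSD_NORM = _max_point_mass_jsd()


def column_conservation(msa: Alignment, gap_penalty: bool = True) -> np.ndarray:
    """Normalised Jensen-Shannon conservation score per column, in [0,1].

    Score = JSD(column frequencies, background) / JSD(point mass, background),
    where the normaliser is the maximum over single-residue columns (so an
    invariant column of the rarest background residue scores exactly 1);
    with *gap_penalty* the score is multiplied by (1 - gap fraction).
    All-gap columns score 0.
    """
    if msa.n_rows < 2:
        raise ValueError("need at least 2 sequences")
    scores = np.zeros(msa.length)
    for j in range(msa.length):
        p, gap_fraction = _column_freqs(msa.column(j))
        if p is None:
            continue
        s = _jsd(p, _BG) / _JSD_NORM
        if gap_penalty:
            s *= 1.0 - gap_fraction
        scores[j] = min(1.0, max(0.0, s))
    return scores


def map_to_structure(msa: Alignment, row_id: str, structure: Structure,
                     chain: str, column_scores: np.ndarray | None = None,
                     min_identity: float = 0.9) -> ConservationProfile:
    """Transfer per-column scores onto a structure's residues.

    The ungapped alignment row is globally aligned to the chain's observed
    sequence (match 1, mismatch -1, gap -2); every structure residue paired
    with a row letter inherits that letter's column score.  An identity below
    *min_identity* over the structure residues indicates the wrong row or
    chain and raises.
    """
    from Bio import Align

    if row_id not in msa.rows:
        raise KeyError(f"row {row_id!r} not in alignment")
    if column_scores is None:
        column_scores = column_conservation(msa)
    row_seq, row_cols = msa.ungapped(row_id)
    struct_seq, numbers = extract_sequence(structure, chain)
    icodes = [r.icode for r in structure.chains[chain] if r.kind == "polymer"]

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    aln = aligner.align(row_seq, struct_seq)[0]

    matched = identical = 0
    residue_scores: dict[tuple[str, int, str], float] = {}
    for (r0, r1), (s0, s1) in zip(*aln.aligned):
        for k in range(r1 - r0):
            i_row, i_str = r0 + k, s0 + k
            matched += 1
            if row_seq[i_row] == struct_seq[i_str]:
                identical += 1
            key = (chain, numbers[i_str], icodes[i_str])
            residue_scores[key] = float(column_scores[row_cols[i_row]])
    if matched == 0 or identical / max(1, len(struct_seq)) < min_identity:
        raise ValueError(
            f"alignment identity {identical}/{len(struct_seq)} below "
            f"{min_identity:.0%}: wrong alignment row or chain?")
    gap_fraction = np.array([msa.column(j).count("-") / msa.n_rows
                             for j in range(msa.length)])
    return ConservationProfile(column_scores=np.asarray(column_scores),
                               gap_fraction=gap_fraction,
                               residue_scores=residue_scores)


@dataclass
class Patch:
    residues: list[tuple[str, int, str]]
    mean_score: float
    size: int
    rank_score: float


def conserved_patch(structure: Structure, profile: ConservationProfile,
                    rel_sasa: dict[tuple[str, int, str], float],
                    radius: float = 8.0, exposure_min: float = 0.2,
                    percentile: float = 80.0) -> list[Patch]:
    """Rank connected clusters of conserved surface residues.

    Surface residues (relative SASA >= *exposure_min*) get a spatially
    smoothed score (mean over surface neighbours within *radius* of Ca);
    residues above the *percentile* of smoothed scores are clustered by
    Ca-distance connectivity and patches ranked by mean smoothed score x size.
    """
    keys, coords, scores = [], [], []
    for cid, residues in structure.chains.items():
        for res in residues:
            key = (cid, res.number, res.icode)
            if res.kind != "polymer" or rel_sasa.get(key, 0.0) < exposure_min:
                continue
            ca = res.atom("CA")
            if ca is None or key not in profile.residue_scores:
                continue
            keys.append(key)
            coords.append(ca.coords)
            scores.append(profile.residue_scores[key])
    if not keys:
        return []
    coords = np.array(coords)
    scores = np.array(scores)
    tree = cKDTree(coords)
    neighbours = tree.query_ball_tree(tree, radius)
    smoothed = np.array([scores[nb].mean() for nb in neighbours])
    thresh = np.percentile(smoothed, percentile)
    selected = np.where(smoothed >= thresh)[0]
    if selected.size == 0:
        return []
    # single-linkage clustering of selected residues at the same radius
    sel_tree = cKDTree(coords[selected])
    import scipy.sparse as sp
    import scipy.sparse.csgraph as csgraph
    adj = sel_tree.sparse_distance_matrix(sel_tree, radius, output_type="coo_matrix")
    n_comp, labels = csgraph.connected_components(
        sp.csr_matrix((np.ones_like(adj.data), (adj.row, adj.col)),
                      shape=(selected.size, selected.size)), directed=False)
    patches = []
    for c in range(n_comp):
        idx = selected[labels == c]
        mean_score = float(smoothed[idx].mean())
        patches.append(Patch(residues=[keys[i] for i in idx],
                             mean_score=mean_score, size=len(idx),
                             rank_score=mean_score * len(idx)))
    patches.sort(key=lambda p: -p.rank_score)
    return patches
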