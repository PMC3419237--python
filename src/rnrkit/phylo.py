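"""Protein-sequence analyses for the RNR subunit family.

CDS translation, pairwise percent identity from global alignments,
distance matrices under p/Poisson/Kimura protein models with pairwise gap
deletion, Saitou-Nei neighbor-joining, column-bootstrap support values
(the study's display convention flags nodes recovered in more than half
of 300 replicates), and scanning for the KEN-box degradation motif that
distinguishes the carp p53R2ii paralog.

Trees are Bio.Phylo objects, so Newick round trips (with supports as
internal node labels) come for free.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import MultipleSeqAlignment, substitution_matrices
from Bio.Phylo.BaseTree import Clade, Tree
from Bio.Seq import Seq

from .errors import DomainError, NumericalError

__all__ = [
    "DistanceMatrix",
    "translate_cds",
    "pairwise_identity",
    "protein_distance",
    "correct_distance",
    "neighbor_joining",
    "bootstrap_support",
    "bipartitions",
    "scan_ken_box",
    "DEFAULT_BOOTSTRAP_REPLICATES",
    "SUPPORT_DISPLAY_FRACTION",
]

#: replicate count used for the study's bootstrap trees
DEFAULT_BOOTSTRAP_REPLICATES = 300
#: nodes recovered in more than this fraction of replicates are flagged
SUPPORT_DISPLAY_FRACTION = 0.5

#: cap for distances whose correction formula diverges (saturated pairs)
SATURATION_CAP = 10.0

_AA = "ACDEFGHIKLMNPQRSTVWY"
_GAP = "-"


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def translate_cds(seq: str, strict: bool = True) -> str:
    """Translate a coding sequence with the standard genetic code.

    Translation stops before the first stop codon.  In strict mode an
    internal stop (any stop before the final codon) is an error, since a
    CDS should read through to its terminator.
    """
    seq = str(seq).upper().replace("U", "T")
    if len(seq) == 0 or len(seq) % 3 != 0:
        raise DomainError(f"CDS length {len(seq)} is not a positive multiple of 3")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise DomainError(f"invalid nucleotide characters: {sorted(bad)}")
    protein = str(Seq(seq).translate())
    stop = protein.find("*")
    if stop == -1:
        return protein
    if strict and stop != len(protein) - 1:
        raise DomainError(f"internal stop codon at codon {stop + 1}")
    return protein[:stop]


def pairwise_identity(a: str, b: str, open_gap: float = 10.0,
                      extend_gap: float = 0.5) -> float:
    """Percent identity from a global BLOSUM62 alignment.

    Identity is matches over alignment columns (a pairwise alignment has
    no dual-gap columns), x100.  Affine gap costs default to open 10 /
    extend 0.5, a standard protein-alignment setting.
    """
    a, b = str(a), str(b)
    if not a or not b:
        raise DomainError("sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -open_gap
    aligner.extend_gap_score = -extend_gap
    alignment = aligner.align(a, b)[0]
    counts = alignment.counts()
    columns = alignment.length
    return 100.0 * counts.identities / columns


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise distances in substitutions/site."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise DomainError("matrix shape must match the label count")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise DomainError("distance matrix must be symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise DomainError("diagonal must be zero")
        if np.any(self.matrix < 0) or not np.all(np.isfinite(self.matrix)):
            raise DomainError("distances must be finite and non-negative")

    def __getitem__(self, pair):
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.matrix[i, j])


def _alignment_array(aln: MultipleSeqAlignment) -> tuple[list[str], np.ndarray]:
    if len(aln) < 2:
        raise DomainError("alignment needs at least 2 rows")
    labels = [rec.id for rec in aln]
    arr = np.array([list(str(rec.seq).upper()) for rec in aln])
    return labels, arr


def _p_distance_pair(row_a, row_b) -> float:
    ok = (row_a != _GAP) & (row_b != _GAP)
    n = int(ok.sum())
    if n == 0:
        raise DomainError("all-gap sequence pair: no comparable columns")
    return float(np.sum(row_a[ok] != row_b[ok])) / n


def correct_distance(p: float, model: str) -> float:
    """Distance correction for one p-distance under the chosen model."""
    if model == "p":
        return p
    if model == "poisson":
        arg = 1.0 - p
    elif model == "kimura":
        arg = 1.0 - p - 0.2 * p * p
    else:
        raise DomainError(f"unknown model {model!r} (use p, poisson or kimura)")
    if arg <= 0:
        warnings.warn(
            f"saturated pair (p = {p:.3f}); distance capped at {SATURATION_CAP}",
            stacklevel=2,
        )
        return SATURATION_CAP
    return min(-np.log(arg), SATURATION_CAP)


def protein_distance(aln: MultipleSeqAlignment, model: str = "kimura") -> DistanceMatrix:
    """Pairwise protein distances with pairwise gap deletion.

    Models: ``p`` (raw proportion of differences), ``poisson``
    (d = -ln(1-p)) and ``kimura`` (d = -ln(1 - p - 0.2 p^2), the standard
    fast approximation to PAM distances and the default here).
    """
    labels, arr = _alignment_array(aln)
    n = len(labels)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        p = _p_distance_pair(arr[i], arr[j])
        mat[i, j] = mat[j, i] = correct_distance(p, model)
    return DistanceMatrix(labels, mat)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(d: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining.

    Standard Q-criterion agglomeration; ties are broken deterministically
    by taxon-label order of the joined pair.  Negative branch lengths are
    clamped to zero with the deficit moved to the sibling branch, the
    usual practical convention.  The result is an unrooted tree
    represented with a trifurcating root.
    """
    n = len(d.labels)
    if n < 3:
        raise DomainError("neighbor joining needs at least 3 taxa")
    dm = d.matrix.astype(float).copy()
    nodes = [Clade(name=lab) for lab in d.labels]
    # sort key: lexicographically smallest leaf label under each node
    keys = list(d.labels)
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = dm[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        # deterministic tie-break among minimal-Q pairs: label order
        cands = np.argwhere(q <= qmin + 1e-12)
        pick = min(
            ((min(keys[active[i]], keys[active[j]]),
              max(keys[active[i]], keys[active[j]]), i, j)
             for i, j in cands if i < j),
        )
        i, j = pick[2], pick[3]
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sibling branch
        if li < 0:
            lj, li = lj + li, 0.0
        if lj < 0:
            li, lj = li + lj, 0.0
        parent = Clade()
        child_i, child_j = nodes[ai], nodes[aj]
        child_i.branch_length = float(li)
        child_j.branch_length = float(lj)
        parent.clades = [child_i, child_j]
        new_d = 0.5 * (sub[i, :] + sub[j, :] - dij)
        nodes.append(parent)
        keys.append(min(keys[ai], keys[aj]))
        dm = np.pad(dm, ((0, 1), (0, 1)))
        new_idx = dm.shape[0] - 1
        for pos, a in enumerate(active):
            dm[new_idx, a] = dm[a, new_idx] = new_d[pos]
        dm[new_idx, new_idx] = 0.0
        active = [a for a in active if a not in (ai, aj)] + [new_idx]

    # connect the last three nodes through a central trifurcation
    a, b, c = active
    dab, dac, dbc = dm[a, b], dm[a, c], dm[b, c]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    lengths = [la, lb, lc]
    # pairwise clamping for the terminal trifurcation
    for k in range(3):
        if lengths[k] < 0:
            others = [o for o in range(3) if o != k]
            for o in others:
                lengths[o] += lengths[k] / 2
            lengths[k] = 0.0
    root = Clade()
    for node_idx, length in zip((a, b, c), lengths):
        nodes[node_idx].branch_length = float(max(length, 0.0))
        root.clades.append(nodes[node_idx])
    return Tree(root=root, rooted=False)


def bipartitions(tree: Tree, taxa=None) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree.

    Each internal edge splits the taxa in two; the side not containing
    the alphabetically first taxon is the canonical representative.
    Pendant edges (singleton splits) are omitted.
    """
    leaves = [t.name for t in tree.get_terminals()]
    if taxa is None:
        taxa = leaves
    full = frozenset(taxa)
    anchor = min(full)
    out = set()
    for clade in tree.get_nonterminals():
        if clade is tree.root:
            continue
        side = frozenset(t.name for t in clade.get_terminals())
        if anchor in side:
            side = full - side
        if 1 < len(side) < len(full) - 1:
            out.add(side)
    return out


def bootstrap_support(aln: MultipleSeqAlignment, model: str = "kimura",
                      n_reps: int = DEFAULT_BOOTSTRAP_REPLICATES,
                      seed: int = 0) -> Tree:
    """NJ tree with column-bootstrap support counts on internal nodes.

    Columns are resampled with replacement ``n_reps`` times; each
    replicate alignment is rebuilt into distances and an NJ tree, and
    each reference-tree bipartition's recovery is counted.  Supports are
    stored as ``confidence`` counts out of ``n_reps`` on the internal
    clades of the full-data tree; nodes with support above half the
    replicates additionally get ``comment = "supported"`` (the display
    rule used for the study's figures).
    """
    if n_reps < 1:
        raise DomainError("need at least one bootstrap replicate")
    labels, arr = _alignment_array(aln)
    n_cols = arr.shape[1]
    if n_cols < 10:
        warnings.warn("alignment shorter than 10 columns; supports are unstable",
                      stacklevel=2)
    reference = neighbor_joining(protein_distance(aln, model))
    ref_parts = {part: 0 for part in bipartitions(reference, labels)}

    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep_aln = MultipleSeqAlignment([
            rec.__class__(Seq("".join(arr[i, cols])), id=labels[i])
            for i, rec in enumerate(aln)
        ])
        rep_tree = neighbor_joining(protein_distance(rep_aln, model))
        for part in bipartitions(rep_tree, labels):
            if part in ref_parts:
                ref_parts[part] += 1

    full = frozenset(labels)
    anchor = min(full)
    for clade in reference.get_nonterminals():
        if clade is reference.root:
            continue
        side = frozenset(t.name for t in clade.get_terminals())
        if anchor in side:
            side = full - side
        if side in ref_parts:
            clade.confidence = ref_parts[side]
            if ref_parts[side] > SUPPORT_DISPLAY_FRACTION * n_reps:
                clade.comment = "supported"
    return reference


# ---------------------------------------------------------------------------
# motifs
# ---------------------------------------------------------------------------

def scan_ken_box(seq: str, extended: bool = False) -> list[tuple[int, int]]:
    """1-based spans of KEN-box degradation motifs.

    The minimal motif is the K-E-N tripeptide recognized by the anaphase
    promoting complex.  ``extended`` instead matches the broader consensus
    K-E-N-x-x-x-[DN] sometimes used to reduce spurious hits.
    """
    import re

    seq = str(seq).upper()
    pattern = r"KEN...[DN]" if extended else r"KEN"
    # overlapping matches via lookahead
    spans = []
    width = 7 if extended else 3
    for m in re.finditer(rf"(?=({pattern}))", seq):
        spans.append((m.start() + 1, m.start() + width))
    return spans
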