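"""Distance phylogenetics for receptor classification and pairwise dN/dS.

Mammalian olfactory receptors split into two deep subfamilies, class I and
class II; a query (including a truncated fragment) is classified by building a
neighbor-joining tree of Poisson-corrected protein distances over the labeled
references plus the query, rooting on the inter-class stem, and reading off
the smallest single-class clade containing the query (falling back to the
nearest labeled leaf by patristic distance).  Truncated fragments are placed
one by one so they never influence each other's assignment.

Selection on protein-coding genes is summarised by the Nei-Gojobori (1986)
pathway-counting dN/dS with Jukes-Cantor correction; omega << 1 indicates
purifying selection.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .seqcore import CODON_TABLE, NucSequence, ProtSequence

logger = logging.getLogger("chemomine")

MIN_SHARED_COLUMNS = 30
MAX_P_DISTANCE = 0.95


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple
    matrix: np.ndarray

    def __post_init__(self):
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match taxon count")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("diagonal must be zero")
        if not np.all(np.isfinite(m)) or np.any(m < 0):
            raise ValueError("distances must be finite and non-negative")


@dataclass(frozen=True)
class ClassAssignment:
    query_id: str
    assigned_class: str
    support: float  # patristic distance to the nearest labeled leaf
    method: str     # clade | nearest


def _pairwise_poisson(res_a: str, res_b: str, id_a: str, id_b: str) -> float:
    shared = [(a, b) for a, b in zip(res_a, res_b) if a != "-" and b != "-"]
    if len(shared) < MIN_SHARED_COLUMNS:
        raise ValueError(
            f"pair ({id_a}, {id_b}) shares only {len(shared)} aligned columns "
            f"(< {MIN_SHARED_COLUMNS})"
        )
    p = sum(1 for a, b in shared if a != b) / len(shared)
    if p >= MAX_P_DISTANCE:
        logger.warning("pair (%s, %s) p-distance %.3f capped at %.2f",
                       id_a, id_b, p, MAX_P_DISTANCE)
        p = MAX_P_DISTANCE
    return -math.log(1.0 - p)


def protein_distance(msa: list[ProtSequence]) -> DistanceMatrix:
    """Poisson-corrected distances d = -ln(1-p) over shared non-gap columns."""
    if len(msa) < 2:
        raise ValueError("need at least two sequences")
    n = len(msa)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = _pairwise_poisson(
                msa[i].residues, msa[j].residues, msa[i].id, msa[j].id
            )
    return DistanceMatrix(ids=tuple(s.id for s in msa), matrix=m)


# ---------------------------------------------------------------------------
# neighbor-joining


def build_nj(matrix: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor-joining; exact on additive matrices.

    Returns an unrooted dendropy tree with non-negative branch lengths
    (numerically negative estimates are clamped at 0).
    """
    n = len(matrix.ids)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    tns = dendropy.TaxonNamespace()
    nodes = []
    for tid in matrix.ids:
        taxon = tns.new_taxon(label=str(tid))
        node = dendropy.Node(taxon=taxon)
        nodes.append(node)
    d = matrix.matrix.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        k = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        ii, jj = np.unravel_index(np.argmin(q), q.shape)
        if ii > jj:
            ii, jj = jj, ii
        a, b = active[ii], active[jj]
        dij = d[a, b]
        la = 0.5 * dij + (r[ii] - r[jj]) / (2.0 * (k - 2))
        lb = dij - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        parent = dendropy.Node()
        na, nb = nodes[a], nodes[b]
        parent.add_child(na)
        parent.add_child(nb)
        na.edge.length = la
        nb.edge.length = lb
        # distances to the new node
        new_row = np.zeros(d.shape[0] + 1)
        for m_idx in active:
            if m_idx in (a, b):
                continue
            new_row[m_idx] = 0.5 * (d[a, m_idx] + d[b, m_idx] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [x for x in active if x not in (a, b)] + [d.shape[0] - 1]

    # star-join the last three
    a, b, c = active
    root = dendropy.Node()
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(ln, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def patristic_distances(tree: dendropy.Tree):
    pdm = tree.phylogenetic_distance_matrix()
    return pdm


# ---------------------------------------------------------------------------
# class I / class II assignment


def _midpoint_root_between_classes(tree: dendropy.Tree,
                                   reference_labels: dict) -> dendropy.Tree:
    """Reroot at the midpoint of the longest path between leaves of different
    classes (the inter-class stem for two deep clades)."""
    pdm = tree.phylogenetic_distance_matrix()
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    best = None
    for ta, tb in itertools.combinations(
        [l for l in leaves if l in reference_labels], 2
    ):
        if reference_labels[ta] == reference_labels[tb]:
            continue
        dist = pdm.patristic_distance(leaves[ta].taxon, leaves[tb].taxon)
        if best is None or dist > best[0]:
            best = (dist, ta, tb)
    if best is None:
        raise ValueError("references of both classes are required")
    dist, ta, tb = best
    # path between the two leaves through their deepest common ancestor;
    # each step is (node owning the edge, length, endpoint nearer to a)
    anc_a = [leaves[ta]]
    while anc_a[-1].parent_node is not None:
        anc_a.append(anc_a[-1].parent_node)
    in_a = {id(n): i for i, n in enumerate(anc_a)}
    anc_b = [leaves[tb]]
    while id(anc_b[-1]) not in in_a:
        anc_b.append(anc_b[-1].parent_node)
    apex = anc_b[-1]
    steps = []  # (edge_owner_node, length, True if walking up from a)
    for n in anc_a[: in_a[id(apex)]]:
        steps.append((n, n.edge.length or 0.0, True))
    for n in reversed(anc_b[:-1]):
        steps.append((n, n.edge.length or 0.0, False))

    target = dist / 2.0
    acc = 0.0
    eps = 1e-9
    for node, el, going_up in steps:
        if acc + el >= target - eps or (node, el, going_up) == steps[-1]:
            # distance consumed inside this edge, measured from its a-side end
            d1 = min(max(target - acc, 0.0), el)
            # distance from the edge's head (parent side)
            from_parent = el - d1 if going_up else d1
            near = node.parent_node if from_parent <= eps else (
                node if el - from_parent <= eps else None)
            if near is not None and not near.is_leaf():
                tree.reroot_at_node(near, update_bipartitions=False)
            else:
                tree.reroot_at_edge(node.edge, update_bipartitions=False,
                                    length1=max(from_parent, eps),
                                    length2=None)
                node.edge.length = max(el - from_parent, 0.0)
            break
        acc += el
    tree.is_rooted = True
    return tree


def classify_by_tree(tree: dendropy.Tree, reference_labels: dict,
                     query_id: str) -> ClassAssignment:
    """Assign the query to the class of the smallest single-class clade that
    contains it; fall back to the nearest labeled leaf (ties -> classII)."""
    classes = set(reference_labels.values())
    if len(classes) < 2:
        raise ValueError("references of at least two classes are required")
    tree = tree.clone(depth=1)
    tree = _midpoint_root_between_classes(tree, reference_labels)
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    if query_id not in leaves:
        raise ValueError(f"query {query_id!r} is not a leaf of the tree")

    node = leaves[query_id].parent_node
    while node is not None:
        labels = {
            reference_labels[lf.taxon.label]
            for lf in node.leaf_iter()
            if lf.taxon.label in reference_labels
        }
        if labels:
            if len(labels) == 1:
                cls = labels.pop()
                pdm = tree.phylogenetic_distance_matrix()
                support = min(
                    pdm.patristic_distance(leaves[query_id].taxon, leaves[r].taxon)
                    for r, lab in reference_labels.items()
                    if r in leaves and lab == cls
                )
                return ClassAssignment(query_id=query_id, assigned_class=cls,
                                       support=support, method="clade")
            break
        node = node.parent_node

    # nearest labeled leaf
    pdm = tree.phylogenetic_distance_matrix()
    dists: dict[str, float] = {}
    for rid, lab in reference_labels.items():
        if rid not in leaves:
            continue
        dd = pdm.patristic_distance(leaves[query_id].taxon, leaves[rid].taxon)
        if lab not in dists or dd < dists[lab]:
            dists[lab] = dd
    ranked = sorted(dists.items(), key=lambda kv: kv[1])
    cls, support = ranked[0]
    if len(ranked) > 1 and math.isclose(ranked[0][1], ranked[1][1]):
        logger.warning("query %s equidistant between classes; assigning classII",
                       query_id)
        cls = "classII" if "classII" in dists else cls
        support = dists[cls]
    return ClassAssignment(query_id=query_id, assigned_class=cls,
                           support=support, method="nearest")


def _align_query_to_msa(query: ProtSequence, reference_msa: list[ProtSequence]) -> str:
    """Project an unaligned query onto reference MSA columns via a pairwise
    local alignment to the profile consensus; returns the gapped query row."""
    from Bio.Align import PairwiseAligner, substitution_matrices

    ncol = len(reference_msa[0].residues)
    cons = []
    for c in range(ncol):
        col = [s.residues[c] for s in reference_msa if s.residues[c] != "-"]
        if col:
            vals, counts = np.unique(col, return_counts=True)
            cons.append(vals[np.argmax(counts)])
        else:
            cons.append("A")
    consensus = "".join(cons)
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    aligner.mode = "local"
    aln = aligner.align(query.residues.replace("*", "X").replace("-", ""),
                        consensus)[0]
    row = ["-"] * ncol
    qblocks, cblocks = aln.aligned
    for (qs, qe), (cs, ce) in zip(qblocks, cblocks):
        for off in range(qe - qs):
            row[cs + off] = query.residues[qs + off]
    return "".join(row)


def place_one_by_one(
    truncated_queries: list[ProtSequence],
    reference_msa: list[ProtSequence],
    reference_labels: dict,
) -> list[ClassAssignment | None]:
    """Classify each query independently: align it to the reference MSA,
    compute distances on its shared columns, add it to an NJ tree of the
    references, classify.  Queries never influence each other; a query with
    fewer than 30 aligned columns is returned as None and logged."""
    out: list[ClassAssignment | None] = []
    for q in truncated_queries:
        row = _align_query_to_msa(q, reference_msa)
        if sum(1 for c in row if c != "-") < MIN_SHARED_COLUMNS:
            logger.warning("query %s aligns fewer than %d columns; unassigned",
                           q.id, MIN_SHARED_COLUMNS)
            out.append(None)
            continue
        msa = list(reference_msa) + [ProtSequence(id=q.id, residues=row.replace("-", "X"))]
        # distances on shared columns only: rebuild with gaps preserved
        gapped = [s.residues for s in reference_msa] + [row]
        ids = [s.id for s in reference_msa] + [q.id]
        n = len(gapped)
        m = np.zeros((n, n))
        try:
            for i in range(n):
                for j in range(i + 1, n):
                    m[i, j] = m[j, i] = _pairwise_poisson(
                        gapped[i], gapped[j], ids[i], ids[j]
                    )
        except ValueError as exc:
            logger.warning("query %s unassigned: %s", q.id, exc)
            out.append(None)
            continue
        tree = build_nj(DistanceMatrix(ids=tuple(ids), matrix=m))
        out.append(classify_by_tree(tree, reference_labels, q.id))
    return out


# ---------------------------------------------------------------------------
# Nei-Gojobori dN/dS


@dataclass(frozen=True)
class DnDsResult:
    dn: float
    ds: float
    omega: float | None  # None when dS == 0
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    z_score: float | None  # approximate normal test on pN - pS

    def __iter__(self):
        return iter((self.dn, self.ds, self.omega))


_BASES = "ACGT"


def _syn_fraction(codon: str) -> float:
    """Number of synonymous sites in a codon (changes to stops count as
    nonsynonymous; stop codons themselves carry no sites)."""
    aa = CODON_TABLE[codon]
    if aa == "*":
        return 0.0
    s = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if CODON_TABLE[alt] == aa:
                s += 1.0 / 3.0
    return s


def _pathway_counts(ca: str, cb: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous difference counts over all
    single-step pathways between two codons, excluding pathways that pass
    through a stop codon (all pathways used if every one is blocked)."""
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = ca
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            steps.append((cur, nxt))
            if CODON_TABLE[nxt] == "*" and nxt != cb:
                blocked = True
            cur = nxt
        paths.append((blocked, steps))
    usable = [steps for blocked, steps in paths if not blocked]
    if not usable:
        usable = [steps for _, steps in paths]
    sd = nd = 0.0
    for steps in usable:
        for cur, nxt in steps:
            if CODON_TABLE[cur] == CODON_TABLE[nxt]:
                sd += 1.0
            else:
                nd += 1.0
    k = len(usable)
    return sd / k, nd / k


def _jc_correct(p: float) -> float:
    if p <= 0:
        return 0.0
    if p >= 0.75:
        logger.warning("proportion %.3f saturates the Jukes-Cantor correction", p)
        return math.inf
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def dnds_nei_gojobori(cds_a, cds_b) -> DnDsResult:
    """Pairwise dN/dS by Nei-Gojobori (1986) pathway counting with
    Jukes-Cantor correction; omega is None (undefined) when dS = 0."""
    a = cds_a.residues if isinstance(cds_a, NucSequence) else str(cds_a).upper()
    b = cds_b.residues if isinstance(cds_b, NucSequence) else str(cds_b).upper()
    if len(a) != len(b):
        raise ValueError("sequences must be the same length (codon-aligned)")
    if len(a) % 3 != 0:
        raise ValueError("length must be a multiple of 3")
    S = 0.0
    Sd = Nd = 0.0
    ncodons = len(a) // 3
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if CODON_TABLE.get(ca) == "*" or CODON_TABLE.get(cb) == "*":
            raise ValueError(f"internal stop codon at position {i + 1}")
        if "N" in ca or "N" in cb:
            raise ValueError("ambiguous bases are not supported")
        S += 0.5 * (_syn_fraction(ca) + _syn_fraction(cb))
        sd, nd = _pathway_counts(ca, cb)
        Sd += sd
        Nd += nd
    N = 3.0 * ncodons - S
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    ds = _jc_correct(ps)
    dn = _jc_correct(pn)
    omega = (dn / ds) if ds > 0 else None
    # approximate large-sample normal test on pN - pS
    var = (ps * (1 - ps) / S if S > 0 else 0.0) + (pn * (1 - pn) / N if N > 0 else 0.0)
    z = (pn - ps) / math.sqrt(var) if var > 0 else None
    return DnDsResult(dn=dn, ds=ds, omega=omega, syn_sites=S, nonsyn_sites=N,
                      syn_diffs=Sd, nonsyn_diffs=Nd, z_score=z)


# ---------------------------------------------------------------------------
# interchange


def write_phylip(matrix: DistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.ids)}\n")
        for tid, row in zip(matrix.ids, matrix.matrix):
            fh.write(f"{tid:<12s}" + " ".join(f"{v:.6f}" for v in row) + "\n")


def write_assignments_tsv(assignments, path) -> None:
    with open(path, "w") as fh:
        fh.write("query\tassigned_class\tsupport\tmethod\n")
        for a in assignments:
            if a is None:
                continue
            fh.write(f"{a.query_id}\t{a.assigned_class}\t{a.support:.4f}\t{a.method}\n")
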