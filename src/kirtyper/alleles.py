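"""Allele knowledge base: sequences, distances, trees and subgroup assignment.

The centromeric KIR typing method rests on a partition of the known
*KIR2DL1/L2/L3* alleles into phylogenetically defined subgroups, each
detectable by one "main" multiplex PCR reaction.  This module holds the
allele records, computes uncorrected (p-) distances between aligned protein
sequences, builds the neighbor-joining tree used to define the subgroups,
and assigns alleles to subgroups either from a curated table or — for new
or low-frequency alleles — by nearest-seed proximity on the tree.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Genes covered by the centromeric typing panel.
GENES = ("KIR2DL1", "KIR2DL2", "KIR2DL3", "KIR3DP1")

#: Row labels used for the KIR3DP1 framework pseudogene and its exon-2
#: variant in pattern matrices.  3DP1V on a haplotype marks the absence of
#: KIR2DL1 on that haplotype, which is what makes copy-number inference work.
DP1_ROW = "KIR3DP1"
DP1V_ROW = "KIR3DP1V"

_ALLELE_RE = re.compile(r"^(KIR(?:2DL[123]|3DP1))\*(\w+)$")
_IUPAC_NT = set("ACGTRYSWKMBDHVN-.")
_AA = set("ACDEFGHIKLMNPQRSTVWYX*-.")


def parse_allele_name(name: str) -> tuple[str, str]:
    """Split a KIR allele name like ``KIR2DL1*00303`` into (gene, designation)."""
    m = _ALLELE_RE.match(name)
    if m is None:
        raise ValueError(f"not a valid KIR allele name: {name!r}")
    return m.group(1), m.group(2)


@dataclass
class AlleleRecord:
    """One named KIR allele with its sequence(s) and subgroup label.

    Parameters
    ----------
    allele_name : str
        Full nomenclature string, e.g. ``"KIR2DL1*00303"``.  The special
        pseudogene markers ``"KIR3DP1"``/``"KIR3DP1V"`` are also accepted.
    genomic_sequence, protein_sequence : str, optional
        At least one must be present.  Validated against IUPAC symbols.
    group_label : str, optional
        Subgroup identifier such as ``"G*003"``; ``None`` = unassigned.
    tested : bool
        Whether the allele was validated by PCR (as opposed to predicted
        from sequence only).
    """

    allele_name: str
    genomic_sequence: str | None = None
    protein_sequence: str | None = None
    group_label: str | None = None
    tested: bool = False
    gene: str = field(default="", repr=False)

    def __post_init__(self) -> None:
        if self.allele_name in (DP1_ROW, DP1V_ROW):
            inferred = "KIR3DP1"
        else:
            inferred, _ = parse_allele_name(self.allele_name)
        if self.gene and self.gene != inferred:
            raise ValueError(
                f"allele {self.allele_name} belongs to {inferred}, not {self.gene}"
            )
        self.gene = inferred
        if self.genomic_sequence is None and self.protein_sequence is None:
            raise ValueError(f"{self.allele_name}: no sequence provided")
        if self.genomic_sequence is not None:
            self.genomic_sequence = self.genomic_sequence.upper()
            bad = set(self.genomic_sequence) - _IUPAC_NT
            if bad:
                raise ValueError(
                    f"{self.allele_name}: non-IUPAC nucleotide symbols {sorted(bad)}"
                )
        if self.protein_sequence is not None:
            self.protein_sequence = self.protein_sequence.upper()
            bad = set(self.protein_sequence) - _AA
            if bad:
                raise ValueError(
                    f"{self.allele_name}: invalid amino-acid symbols {sorted(bad)}"
                )


def read_allele_fasta(path, gene: str | None = None) -> list[AlleleRecord]:
    """Read allele records from a FASTA file in the IPD-KIR header dialect.

    Headers of the form ``>KIR:KIR00005 KIR2DL1*00303 14293 bp`` (accession
    first, allele name second) and plain ``>KIR2DL1*00303`` headers are both
    accepted.  If *gene* is given every record must belong to it.
    """
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        tokens = entry.description.split()
        name = None
        for tok in tokens:
            if _ALLELE_RE.match(tok):
                name = tok
                break
        if name is None:
            raise ValueError(
                f"malformed FASTA header (no KIR allele name): {entry.description!r}"
            )
        rec = AlleleRecord(allele_name=name, genomic_sequence=str(entry.seq))
        if gene is not None and rec.gene != gene:
            raise ValueError(
                f"allele {name} belongs to {rec.gene}, expected {gene}"
            )
        records.append(rec)
    if not records:
        logger.warning("no FASTA entries found in %s", path)
    return records


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

_GAPS = set("-.")


def p_distance(seq_a: str, seq_b: str) -> float:
    """Uncorrected proportional distance between two aligned sequences.

    Gap-containing columns are excluded; the result is the fraction of
    comparable columns at which the sequences differ.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"aligned sequences differ in length ({len(seq_a)} vs {len(seq_b)})"
        )
    if len(seq_a) == 0:
        raise ValueError("empty alignment")
    a = seq_a.upper()
    b = seq_b.upper()
    comparable = 0
    diffs = 0
    for x, y in zip(a, b):
        if x in _GAPS or y in _GAPS:
            continue
        comparable += 1
        if x != y:
            diffs += 1
    if comparable == 0:
        raise ValueError("no comparable (gap-free) columns")
    return diffs / comparable


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with ordered labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(self.values < 0):
            raise ValueError("negative distances")

    @classmethod
    def from_proteins(cls, records: list[AlleleRecord]) -> "DistanceMatrix":
        """p-distance matrix over aligned protein sequences of *records*."""
        labels = [r.allele_name for r in records]
        n = len(labels)
        vals = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            d = p_distance(records[i].protein_sequence, records[j].protein_sequence)
            vals[i, j] = vals[j, i] = d
        return cls(labels, vals)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


class PhyloTree:
    """Unrooted tree with branch lengths, backed by a networkx graph.

    Leaves are string labels; internal nodes are integers.  Supports path
    distances, split extraction (for Robinson–Foulds comparison) and newick
    export.
    """

    def __init__(self, graph: nx.Graph, leaves: list[str]):
        self.graph = graph
        self.leaves = list(leaves)

    def path_length(self, a: str, b: str) -> float:
        return nx.shortest_path_length(self.graph, a, b, weight="length")

    def splits(self) -> set[frozenset]:
        """Nontrivial bipartitions, each given as the leaf side not
        containing the lexicographically smallest leaf."""
        ref = min(self.leaves)
        out = set()
        for u, v in self.graph.edges:
            g = self.graph.copy()
            g.remove_edge(u, v)
            side = {n for n in nx.node_connected_component(g, u) if isinstance(n, str)}
            if ref in side:
                side = set(self.leaves) - side
            if 2 <= len(side) <= len(self.leaves) - 2:
                out.add(frozenset(side))
        return out

    def rf_distance(self, other: "PhyloTree") -> int:
        if set(self.leaves) != set(other.leaves):
            raise ValueError("trees have different leaf sets")
        return len(self.splits() ^ other.splits())

    def to_newick(self) -> str:
        internal = [n for n in self.graph.nodes if not isinstance(n, str)]
        root = internal[0] if internal else self.leaves[0]

        def fmt(node, parent):
            children = [n for n in self.graph.neighbors(node) if n != parent]
            if not children:
                return str(node)
            inner = ",".join(
                f"{fmt(c, node)}:{self.graph.edges[node, c]['length']:.6g}"
                for c in children
            )
            return f"({inner})"

        return fmt(root, None) + ";"


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining.

    Ties in the Q-criterion are broken by joining the pair whose
    (lexicographically smallest contained leaf, next) sort key is smallest,
    so the output is deterministic.  Negative branch lengths are clamped
    to zero.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    g = nx.Graph()
    # active nodes: graph node id -> sort key (smallest contained leaf name)
    active: dict = {lab: lab for lab in dm.labels}
    D = {
        (a, b): dm.values[i, j]
        for i, a in enumerate(dm.labels)
        for j, b in enumerate(dm.labels)
    }
    next_internal = itertools.count()

    def dist(a, b):
        return D[(a, b)]

    while len(active) > 3:
        nodes = list(active)
        m = len(nodes)
        r = {a: sum(dist(a, k) for k in nodes if k != a) for a in nodes}
        best = None
        best_pair = None
        for a, b in itertools.combinations(nodes, 2):
            q = (m - 2) * dist(a, b) - r[a] - r[b]
            key = tuple(sorted((active[a], active[b])))
            if best is None or q < best[0] - 1e-12 or (abs(q - best[0]) <= 1e-12 and key < best[1]):
                best = (q, key)
                best_pair = (a, b)
        a, b = best_pair
        u = next(next_internal)
        la = 0.5 * dist(a, b) + (r[a] - r[b]) / (2 * (m - 2))
        lb = dist(a, b) - la
        g.add_edge(a, u, length=max(la, 0.0))
        g.add_edge(b, u, length=max(lb, 0.0))
        for k in nodes:
            if k in (a, b):
                continue
            duk = 0.5 * (dist(a, k) + dist(b, k) - dist(a, b))
            D[(u, k)] = D[(k, u)] = max(duk, 0.0)
        D[(u, u)] = 0.0
        key = min(active[a], active[b])
        del active[a], active[b]
        active[u] = key

    # join the final three nodes on one internal node
    a, b, c = list(active)
    u = next(next_internal)
    la = 0.5 * (dist(a, b) + dist(a, c) - dist(b, c))
    lb = 0.5 * (dist(a, b) + dist(b, c) - dist(a, c))
    lc = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
    g.add_edge(a, u, length=max(la, 0.0))
    g.add_edge(b, u, length=max(lb, 0.0))
    g.add_edge(c, u, length=max(lc, 0.0))
    return PhyloTree(g, dm.labels)


# ---------------------------------------------------------------------------
# Subgroup assignment
# ---------------------------------------------------------------------------


@dataclass
class GroupAssignment:
    """Disjoint allele → subgroup mapping with per-group member lists."""

    assignment: dict[str, str]
    main_reaction: dict[str, str] = field(default_factory=dict)

    @property
    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for allele, grp in sorted(self.assignment.items()):
            out.setdefault(grp, []).append(allele)
        return out

    def __post_init__(self) -> None:
        for grp, members in self.groups.items():
            if not members:
                raise ValueError(f"empty group {grp}")


def assign_groups(
    alleles: list[AlleleRecord],
    tree: PhyloTree,
    seed_alleles: dict[str, str],
) -> GroupAssignment:
    """Assign every allele to the subgroup of its nearest seed allele.

    Distance is path length on *tree*; ties go to the lexicographically
    smallest group label.  Seeds must be tree leaves.  Alleles that already
    carry a curated ``group_label`` keep it — the nearest-seed rule is the
    fallback for new or low-frequency alleles.
    """
    if not seed_alleles:
        raise ValueError("at least one seed allele required")
    for grp, seed in seed_alleles.items():
        if seed not in tree.leaves:
            raise ValueError(f"seed allele {seed} (group {grp}) is not a tree leaf")
    assignment: dict[str, str] = {}
    for rec in alleles:
        if rec.group_label is not None:
            assignment[rec.allele_name] = rec.group_label
            continue
        if rec.allele_name not in tree.leaves:
            raise ValueError(f"allele {rec.allele_name} is not a tree leaf")
        best = min(
            sorted(seed_alleles.items()),
            key=lambda kv: (tree.path_length(rec.allele_name, kv[1]), kv[0]),
        )
        assignment[rec.allele_name] = best[0]
    return GroupAssignment(assignment)
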