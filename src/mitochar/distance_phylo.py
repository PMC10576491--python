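"""Uncorrected p-distances on aligned matrices, and neighbor-joining trees.

The p-distance between two aligned sequences is the proportion of compared
sites at which they differ.  Sites carrying gaps, N, or any other ambiguity
are treated as missing and excluded - either for all pairs at once (complete
deletion, the default of the tool the study used) or per pair (pairwise
deletion); with no missing data the two modes agree exactly.  Note the
p-distance need not satisfy the triangle inequality.

Neighbor joining follows the classic agglomeration with two determinism
rules: ties in the Q criterion are broken by the lexicographically smallest
pair of node labels, and a negative branch length is clamped to zero with
the deficit moved to its sister edge (preserving the pair's path length).
Output trees are unrooted, written as Newick with a trifurcating root and
branch lengths to 6 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import AlignIO, SeqIO

__all__ = [
    "AlignmentMatrix",
    "PDistanceMatrix",
    "UndefinedDistanceError",
    "read_alignment_fasta",
    "read_alignment_phylip",
    "p_distance",
    "neighbor_joining",
]

_VALID = frozenset("ACGT")


class UndefinedDistanceError(ValueError):
    """A pair of taxa shares no comparable (unambiguous) sites."""


@dataclass
class AlignmentMatrix:
    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows differ in length")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows of unequal length: {sorted(lengths)}")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass
class PDistanceMatrix:
    taxa: list[str]
    d: np.ndarray  # symmetric, zero diagonal
    deletion_mode: str

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.taxa.index(a), self.taxa.index(b)])

    def to_lower_triangle_tsv(self) -> str:
        """MEGA-style lower-triangle listing."""
        lines = ["\t".join([""] + self.taxa[:-1])]
        for i, t in enumerate(self.taxa):
            cells = [f"{self.d[i, j]:.4f}" for j in range(i)]
            lines.append("\t".join([t] + cells))
        return "\n".join(lines) + "\n"


def read_alignment_fasta(path: str | Path) -> AlignmentMatrix:
    records = list(SeqIO.parse(str(path), "fasta"))
    return AlignmentMatrix(
        taxa=[r.id for r in records], rows=[str(r.seq) for r in records]
    )


def read_alignment_phylip(path: str | Path) -> AlignmentMatrix:
    aln = AlignIO.read(str(path), "phylip-relaxed")
    return AlignmentMatrix(taxa=[r.id for r in aln], rows=[str(r.seq) for r in aln])


def p_distance(aln: AlignmentMatrix, mode: str = "complete") -> PDistanceMatrix:
    """Proportion of differing sites for every taxon pair.

    ``mode='complete'`` drops any column containing a gap/N/ambiguity for all
    pairs; ``mode='pairwise'`` excludes such sites per pair.
    """
    if mode not in ("complete", "pairwise"):
        raise ValueError(f"unknown deletion mode {mode!r}")
    n = len(aln.taxa)
    if n < 2:
        raise ValueError("need at least two taxa")
    mat = np.frombuffer(
        "".join(aln.rows).encode(), dtype="S1"
    ).reshape(n, aln.n_sites)
    valid = np.isin(mat, [b"A", b"C", b"G", b"T"])
    if mode == "complete":
        keep = valid.all(axis=0)
        mat = mat[:, keep]
        valid = valid[:, keep]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            compared = int(both.sum())
            if compared == 0:
                raise UndefinedDistanceError(
                    f"no comparable sites between {aln.taxa[i]} and {aln.taxa[j]}"
                )
            diffs = int((mat[i, both] != mat[j, both]).sum())
            d[i, j] = d[j, i] = diffs / compared
    return PDistanceMatrix(taxa=list(aln.taxa), d=d, deletion_mode=mode)


# ---------------------------------------------------------------------------
# neighbor joining


def _fmt(x: float) -> str:
    return f"{max(x, 0.0):.6f}"


def neighbor_joining(dm: PDistanceMatrix) -> str:
    """Neighbor-joining tree as a Newick string (unrooted, trifurcating root).

    Deterministic: Q-criterion ties resolved by the lexicographically smallest
    (label, label) pair; negative branch lengths clamped to zero with the
    deficit moved to the sister edge.
    """
    if not np.isfinite(dm.d).all():
        raise ValueError("non-finite distances")
    labels = list(dm.taxa)  # current node labels (sort keys for tie-break)
    newick = list(dm.taxa)  # newick fragment per active node
    D = dm.d.astype(float).copy()
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two taxa")
    if n == 2:
        h = D[0, 1] / 2
        return f"({newick[0]}:{_fmt(h)},{newick[1]}:{_fmt(h)});"
    while n > 3:
        r = D.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * D[i, j] - r[i] - r[j]
                key = (q, *sorted((labels[i], labels[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = D[i, j] / 2 + (r[i] - r[j]) / (2 * (n - 2))
        lj = D[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        frag = f"({newick[i]}:{_fmt(li)},{newick[j]}:{_fmt(lj)})"
        label = min(labels[i], labels[j])
        dnew = np.array(
            [(D[i, k] + D[j, k] - D[i, j]) / 2 for k in range(n) if k not in (i, j)]
        )
        keep = [k for k in range(n) if k not in (i, j)]
        D = D[np.ix_(keep, keep)]
        D = np.vstack([D, dnew])
        D = np.hstack([D, np.append(dnew, 0.0).reshape(-1, 1)])
        labels = [labels[k] for k in keep] + [label]
        newick = [newick[k] for k in keep] + [frag]
        n -= 1
    # final three nodes: closed-form branch lengths
    x = (D[0, 1] + D[0, 2] - D[1, 2]) / 2
    y = (D[0, 1] + D[1, 2] - D[0, 2]) / 2
    z = (D[0, 2] + D[1, 2] - D[0, 1]) / 2
    return (
        f"({newick[0]}:{_fmt(x)},{newick[1]}:{_fmt(y)},{newick[2]}:{_fmt(z)});"
    )
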