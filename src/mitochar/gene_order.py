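"""Circular gene orders: comparison, strand census, and TDRL explanation search.

A gene arrangement is an ordered, stranded list of canonical gene names on
the circle, read along the J strand.  Two arrangements are equal when some
rotation makes them elementwise equal; all comparisons here are
rotation-aware.  Rearrangements between two orders are explained (when
possible) by a single tandem duplication-random loss (TDRL) event: a
contiguous block is duplicated in tandem and, for every duplicated gene, one
of the two copies is lost - except for genes explicitly allowed to retain
both copies (the duplicated control region surviving as CR1 plus a remnant
CR2).  TDRL preserves gene orientation, so strands are compared but never
flipped by an event.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .mito_io import CONTROL_REGIONS, FTYPE_BY_NAME, PCGS, RRNAS, TRNAS, MitoRecord

__all__ = [
    "GeneArrangement",
    "TDRLSolution",
    "load_template",
    "available_templates",
    "extract_arrangement",
    "strand_census",
    "check_complete",
    "compare_orders",
    "tdrl_search",
    "apply_tdrl",
    "CompletenessError",
]


class CompletenessError(ValueError):
    """An arrangement is missing part of the standard 37-gene complement."""


def _canon_cr(name: str) -> str:
    return "CR" if name in CONTROL_REGIONS else name


@dataclass(frozen=True)
class GeneArrangement:
    """An ordered, stranded, circular list of genes."""

    genes: tuple[tuple[str, str], ...]
    anchor: str = "trnF"

    def __post_init__(self) -> None:
        names = [n for n, _ in self.genes if _canon_cr(n) != "CR"]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate non-CR gene names: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.genes)

    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.genes)

    def rotated_to_anchor(self) -> "GeneArrangement":
        """Rotate so the anchor gene comes first (lexicographic-minimal
        rotation when the anchor is absent)."""
        names = self.names()
        if self.anchor in names:
            i = names.index(self.anchor)
            rotations = [self.genes[i:] + self.genes[:i]]
        else:
            rotations = [
                self.genes[i:] + self.genes[:i] for i in range(len(self.genes))
            ]
            rotations.sort()
            rotations = rotations[:1]
        return GeneArrangement(genes=rotations[0], anchor=self.anchor)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneArrangement):
            return NotImplemented
        if len(self) != len(other):
            return False
        return self.rotated_to_anchor().genes == other.rotated_to_anchor().genes

    def __hash__(self) -> int:
        return hash(self.rotated_to_anchor().genes)

    def adjacencies(self) -> set[tuple[str, str]]:
        """Directed adjacent name pairs on the circle (CR1/CR2 canonicalized
        to CR so orders with one and two control regions are comparable)."""
        names = [_canon_cr(n) for n, _ in self.genes]
        return {
            (names[i], names[(i + 1) % len(names)]) for i in range(len(names))
        }


def available_templates() -> list[str]:
    return sorted(_load_all_templates())


def _load_all_templates() -> dict:
    text = resources.files("mitochar.data").joinpath("gene_orders.yaml").read_text()
    return yaml.safe_load(text)


def load_template(name: str) -> GeneArrangement:
    """Load a packaged gene-order template (``gallus_like``, ``phylloscopus``)."""
    templates = _load_all_templates()
    if name not in templates:
        raise KeyError(f"unknown template {name!r}; have {sorted(templates)}")
    t = templates[name]
    return GeneArrangement(
        genes=tuple((g, s) for g, s in t["genes"]), anchor=t.get("anchor", "trnF")
    )


def extract_arrangement(rec: MitoRecord, anchor: str = "trnF") -> GeneArrangement:
    """Read the circular gene order off a record's features."""
    if len(rec.features) < 2:
        raise ValueError("need at least two features to define an order")
    feats = sorted(rec.features, key=lambda f: f.start)
    arr = GeneArrangement(
        genes=tuple((f.name, f.strand) for f in feats), anchor=anchor
    )
    return arr.rotated_to_anchor()


def strand_census(arr: GeneArrangement) -> dict[str, int]:
    """Count J- and N-strand genes, control regions excluded."""
    counts = {"J": 0, "N": 0}
    for name, strand in arr.genes:
        if _canon_cr(name) == "CR":
            continue
        counts[strand] += 1
    return counts


_STANDARD_COMPLEMENT = frozenset(PCGS) | frozenset(TRNAS) | frozenset(RRNAS)


def check_complete(arr: GeneArrangement) -> None:
    """Raise :class:`CompletenessError` listing any of the 37 standard genes
    absent from the arrangement."""
    present = {n for n, _ in arr.genes}
    missing = sorted(_STANDARD_COMPLEMENT - present)
    if missing:
        raise CompletenessError(f"missing genes: {missing}")


def compare_orders(
    a: GeneArrangement, b: GeneArrangement
) -> list[tuple[str, str]]:
    """Breakpoints of ``a`` relative to ``b``: directed adjacent pairs present
    in ``a`` but not in ``b`` (rotation-aware; CR copies canonicalized).

    Empty iff the two arrangements are equal up to rotation (for same-universe
    inputs).
    """
    ua = {_canon_cr(n) for n, _ in a.genes}
    ub = {_canon_cr(n) for n, _ in b.genes}
    if ua != ub:
        raise ValueError(
            f"incomparable gene sets; only in a: {sorted(ua - ub)}, "
            f"only in b: {sorted(ub - ua)}"
        )
    adj_b = b.adjacencies()
    names = [_canon_cr(n) for n, _ in a.genes]
    out = []
    for i in range(len(names)):
        pair = (names[i], names[(i + 1) % len(names)])
        if pair not in adj_b:
            out.append(pair)
    return out


@dataclass(frozen=True)
class TDRLSolution:
    """One tandem duplication-random loss event.

    ``block`` is the duplicated contiguous gene interval (names in ancestral
    order); ``survivors`` records, for each duplicated gene, which copy is
    retained (``first``/``second``/``both``).  Genes marked ``both`` must be
    members of ``retained_both``.
    """

    block: tuple[str, ...]
    survivors: tuple[tuple[str, str], ...]  # (gene, first|second|both)
    retained_both: frozenset[str] = field(default_factory=frozenset)

    def survivor_map(self) -> dict[str, str]:
        return dict(self.survivors)


def _replay(
    genes: tuple[tuple[str, str], ...],
    start: int,
    k: int,
    pattern: tuple[str, ...],
    anchor: str,
) -> tuple[tuple[str, str], ...]:
    """Replay one TDRL event on a plain gene tuple (anchor-rotated output,
    surviving duplicate CRs relabeled CR1/CR2 in anchor order)."""
    n = len(genes)
    block_genes = [genes[(start + i) % n] for i in range(k)]
    copy1 = [g for g, p in zip(block_genes, pattern) if p in ("first", "both")]
    copy2 = [g for g, p in zip(block_genes, pattern) if p in ("second", "both")]
    block_idx = {(start + i) % n for i in range(k)}
    out: list[tuple[str, str]] = []
    for i in range(n):
        if i == start:
            out.extend(copy1)
            out.extend(copy2)
        elif i not in block_idx:
            out.append(genes[i])
    # rotate to anchor
    names = [nm for nm, _ in out]
    if anchor in names:
        j = names.index(anchor)
        out = out[j:] + out[:j]
    # relabel CR copies by order from the anchor
    if sum(1 for nm, _ in out if _canon_cr(nm) == "CR") == 2:
        counter = 0
        for j, (nm, st) in enumerate(out):
            if _canon_cr(nm) == "CR":
                counter += 1
                out[j] = (f"CR{counter}", st)
    return tuple(out)


def apply_tdrl(
    ancestral: GeneArrangement, solution: TDRLSolution
) -> GeneArrangement:
    """Replay a TDRL event: duplicate the block in tandem, delete non-surviving
    copies, and relabel surviving duplicate CRs as CR1/CR2 in anchor order."""
    genes = ancestral.rotated_to_anchor().genes
    names = [n for n, _ in genes]
    k = len(solution.block)
    n = len(names)
    start = None
    for s in range(n):
        if tuple(names[(s + i) % n] for i in range(k)) == solution.block:
            start = s
            break
    if start is None:
        raise ValueError(f"block {solution.block} not found in ancestral order")
    surv = solution.survivor_map()
    pattern = tuple(surv[g] for g in solution.block)
    out = _replay(genes, start, k, pattern, ancestral.anchor)
    return GeneArrangement(genes=out, anchor=ancestral.anchor)


def tdrl_search(
    ancestral: GeneArrangement,
    observed: GeneArrangement,
    retain_both: frozenset[str] | set[str] = frozenset(),
    max_block: int = 8,
) -> list[TDRLSolution]:
    """Exhaustively enumerate single TDRL events turning ``ancestral`` into
    ``observed``.

    Every contiguous block up to ``max_block`` genes is duplicated in tandem
    and every survivor pattern (``first``/``second`` per gene, plus ``both``
    for genes in ``retain_both``) is replayed; a solution is kept when the
    replayed order equals ``observed`` up to rotation.  No-op events (result
    identical to the ancestral order) are excluded, so identical inputs yield
    an empty list.  An empty result certifies that no single orientation-
    preserving event of that block size explains the rearrangement.
    """
    retain_both = frozenset(_canon_cr(g) for g in retain_both)
    anc = ancestral.rotated_to_anchor()
    names = [n for n, _ in anc.genes]
    n = len(names)
    anc_tuple = anc.genes
    obs_tuple = observed.rotated_to_anchor().genes
    extra = len(obs_tuple) - n  # surviving duplicate copies needed
    solutions: list[TDRLSolution] = []
    seen: set[tuple] = set()
    for start in range(n):
        for k in range(1, min(max_block, n - 1) + 1):
            block = tuple(names[(start + i) % n] for i in range(k))
            if len(set(block)) != k:
                continue
            choice_sets = [
                ("first", "second", "both")
                if _canon_cr(g) in retain_both
                else ("first", "second")
                for g in block
            ]
            for pattern in itertools.product(*choice_sets):
                if pattern.count("both") != extra:
                    continue
                key = (block, pattern)
                if key in seen:
                    continue
                seen.add(key)
                result = _replay(anc_tuple, start, k, pattern, anc.anchor)
                if result == anc_tuple:
                    continue  # no-op, not a proper event
                if result == obs_tuple:
                    solutions.append(
                        TDRLSolution(
                            block=block,
                            survivors=tuple(zip(block, pattern)),
                            retained_both=retain_both,
                        )
                    )
    return solutions
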