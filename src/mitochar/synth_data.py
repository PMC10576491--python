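"""Synthetic annotated mitogenomes and aligned matrices with known truth.

The generator lays out a complete avian-style circular mitogenome (13 PCGs,
22 tRNAs, 2 rRNAs and one or two control regions) along a gene-order
template, with every planted quantity recorded in a :class:`TruthRecord` so
each analysis stage can be exercised against ground truth:

* base composition follows configurable target frequencies (defaults match
  the leaf-warbler genome-wide averages);
* CDSs are in frame, start with ATG, avoid in-frame stops, end with
  configurable terminators including the incomplete T / TA stops completed
  by polyadenylation, and carry a codon-usage bias;
* tRNAs are built on generic cloverleaf layouts with fully complementary
  stems except for planted wobble/mismatch pairs; trnS(AGY) uses the
  DHU-less layout;
* CR1 carries a planted C-string and conserved boxes (optionally with a
  chosen number of substitutions) at recorded positions inside the ETAS /
  central / CSB domains; remnant CR2 carries a planted tandem repeat.

Intergenic spacers are short random fills; gene overlaps, indels and rate
heterogeneity are deliberately not simulated.  Everything is deterministic
under the configured seed.

For distance/tree work, :func:`simulate_alignment` evolves a root sequence
down a Newick tree with a constant per-branch, per-site substitution
probability (Jukes-Cantor-style: a substituted site picks one of the three
other bases uniformly), so expected p-distances have a closed form:
``E[p] = 3/4 * (1 - (1 - 4q/3)**k)`` over ``k`` branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .control_region import MotifDef, load_motif_library
from .gene_order import GeneArrangement, load_template
from .mito_io import GeneFeature, MitoRecord, reverse_complement
from .trna_structure import CloverleafSpec, load_generic_specs

__all__ = [
    "SynthConfig",
    "TruthRecord",
    "generate_mitogenome",
    "simulate_alignment",
    "random_sequence",
    "random_additive_tree",
    "expected_p_distance",
    "FUSCATUS_REPEAT_UNIT",
    "PROREGULUS_REPEAT_UNIT",
    "CSTRING",
]

#: Repeat units reported from the remnant CR2 of the two tandem-repeat
#: carriers (46 bp and 45 bp), used as generator defaults.
FUSCATUS_REPEAT_UNIT = "CATTTCATTAAACTCGCAAAGCCTACCAAACAACCGCATTCACACC"
PROREGULUS_REPEAT_UNIT = "AACCAAACCTATCCCAAACCCCCCTCCCACTAAAAAACAAACAAA"

#: The 18-nt interrupted poly-C run of CR1 domain I.
CSTRING = "CCCCCCCCCTCCCCCCCC"

_BASES = np.array(list("ACGT"))

# (codons including the ATG start, terminator string) per PCG; incomplete
# T / TA terminators follow the leaf-warbler annotations (nad4 / nad2), as
# do AGG (cox1, cox3) and AGA (nad5).
_PCG_LAYOUT: dict[str, tuple[int, str]] = {
    "nad1": (325, "TAA"),
    "nad2": (346, "TA"),
    "cox1": (516, "AGG"),
    "cox2": (227, "TAA"),
    "atp8": (55, "TAA"),
    "atp6": (227, "TAA"),
    "cox3": (261, "AGG"),
    "nad3": (116, "TAA"),
    "nad4L": (98, "TAA"),
    "nad4": (459, "T"),
    "nad5": (604, "AGA"),
    "cytb": (380, "TAA"),
    "nad6": (172, "TAA"),
}

_RRNA_LENGTHS = {"rrnS": 975, "rrnL": 1600}

#: default planted box layout inside CR1 (CR-local 1-based positions).
_DEFAULT_MOTIF_POSITIONS: dict[str, int] = {
    "C-string": 30,
    "F": 440,
    "E": 490,
    "D": 530,
    "C": 580,
    "bird-similarity": 700,
    "B": 760,
    "CSB1": 880,
}

#: default planted stem irregularities: (tRNA, arm, stem index, base5, base3).
_DEFAULT_PAIR_EDITS: tuple[tuple[str, str, int, str, str], ...] = (
    ("trnF", "AA", 0, "A", "C"),
    ("trnV", "AA", 1, "C", "C"),
    ("trnG", "AC", 2, "T", "C"),
    ("trnW", "AA", 3, "G", "T"),
    ("trnK", "TPSIC", 2, "G", "T"),
    ("trnD", "DHU", 1, "G", "T"),
    ("trnR", "AC", 0, "G", "T"),
)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _default_base_freqs() -> dict[str, float]:
    # genome-wide averages (A, C, G, T), normalized to sum to 1
    raw = {"A": 29.43, "C": 32.75, "G": 14.68, "T": 23.10}
    total = sum(raw.values())
    return {b: v / total for b, v in raw.items()}


def _default_codon_bias() -> dict[str, float]:
    # favour the most-used codons of the study system
    return {"CTA": 3.0, "CGA": 3.0, "TCC": 3.0, "GCC": 3.0}


@dataclass
class SynthConfig:
    """Ground-truth parameters for one synthetic mitogenome."""

    seed: int = 0
    genome_length: int = 16950
    arrangement: str = "phylloscopus"
    base_freqs: dict[str, float] = field(default_factory=_default_base_freqs)
    codon_bias: dict[str, float] = field(default_factory=_default_codon_bias)
    #: (box_name, CR1-local position, n_edits); None -> default layout, 0 edits
    planted_motifs: list[tuple[str, int, int]] | None = None
    plant_cstring: bool = True
    #: (unit, copies); copies may be fractional (>= 1.0)
    planted_repeat: tuple[str, float] = (FUSCATUS_REPEAT_UNIT, 2.0)
    pair_edits: tuple[tuple[str, str, int, str, str], ...] = _DEFAULT_PAIR_EDITS
    cr1_length: int = 1104
    cr2_length: int = 240
    species: str = "Synthetica mitogenomica"
    record_id: str = "SYN000001"

    def __post_init__(self) -> None:
        total = sum(self.base_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"base_freqs sum to {total}, not 1")
        if self.planted_repeat is not None and self.planted_repeat[1] < 1.0:
            raise ValueError("repeat copies must be >= 1.0")


@dataclass
class TruthRecord:
    """Everything the generator planted, for plant/recover testing."""

    config: SynthConfig
    arrangement: GeneArrangement
    cds: dict[str, str]  # gene -> coding-sense sequence incl. terminator
    stop_codons: dict[str, str]  # gene -> terminator string as planted
    feature_coords: dict[str, tuple[int, int, str]]
    cr1_motifs: list[tuple[str, int, int]]  # (box, CR1-local pos, edits)
    cstring_span: tuple[int, int] | None  # CR1-local, 1-based inclusive
    cr2_repeat: tuple[int, int, float, str] | None  # (start, period, copies, unit)
    trnas: dict[str, tuple[str, str]]  # name -> (layout, sequence)
    pair_edits: tuple[tuple[str, str, int, str, str], ...]


def random_sequence(rng: np.random.Generator, length: int,
                    freqs: dict[str, float]) -> str:
    p = np.array([freqs[b] for b in "ACGT"])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def _sample_codons(rng: np.random.Generator, n: int,
                   base_freqs: dict[str, float],
                   codon_bias: dict[str, float]) -> list[str]:
    from .codon_usage import MITO_CODE, MITO_STOPS

    sense = sorted(c for c in MITO_CODE if c not in MITO_STOPS)
    weights = np.array(
        [
            np.prod([base_freqs[b] for b in codon]) * codon_bias.get(codon, 1.0)
            for codon in sense
        ]
    )
    weights = weights / weights.sum()
    idx = rng.choice(len(sense), size=n, p=weights)
    return [sense[i] for i in idx]


def _generate_cds(rng: np.random.Generator, gene: str,
                  cfg: SynthConfig) -> tuple[str, str]:
    n_codons, stop = _PCG_LAYOUT[gene]
    body = _sample_codons(rng, n_codons - 1, cfg.base_freqs, cfg.codon_bias)
    return "ATG" + "".join(body) + stop, stop


def _generate_trna(rng: np.random.Generator, name: str, cfg: SynthConfig,
                   specs: dict[str, CloverleafSpec]) -> tuple[str, str]:
    layout = "no_dhu" if name == "trnS(AGY)" else "standard"
    spec = specs[layout]
    # the acceptor 3' strand ends at the tRNA's final base
    length = max(iv[1] for arms in spec.arms.values() for iv in arms)
    seq = list(random_sequence(rng, length, cfg.base_freqs))
    for arm, ((f0, f1), (t0, t1)) in spec.arms.items():
        stem_len = f1 - f0 + 1
        for i in range(stem_len):
            seq[t1 - 1 - i] = _COMPLEMENT[seq[f0 - 1 + i]]
    for trna, arm, idx, b5, b3 in cfg.pair_edits:
        if trna != name or arm not in spec.arms:
            continue
        (f0, f1), (t0, t1) = spec.arms[arm]
        seq[f0 - 1 + idx] = b5
        seq[t1 - 1 - idx] = b3
    return "".join(seq), layout


def _plant(seq: list[str], pos0: int, motif: str) -> None:
    seq[pos0 : pos0 + len(motif)] = list(motif)


def _edit(rng: np.random.Generator, seq: list[str], pos0: int,
          length: int, n_edits: int) -> None:
    sites = rng.choice(length, size=n_edits, replace=False)
    for s in sites:
        old = seq[pos0 + s]
        choices = [b for b in "ACGT" if b != old]
        seq[pos0 + s] = choices[rng.integers(0, 3)]


def _generate_cr1(rng: np.random.Generator, cfg: SynthConfig
                  ) -> tuple[str, list[tuple[str, int, int]],
                             tuple[int, int] | None]:
    seq = list(random_sequence(rng, cfg.cr1_length, cfg.base_freqs))
    library = {m.box_name: m for m in load_motif_library()}
    if cfg.planted_motifs is None:
        planted = [
            (name, pos, 0)
            for name, pos in _DEFAULT_MOTIF_POSITIONS.items()
            if cfg.plant_cstring or name != "C-string"
        ]
    else:
        planted = list(cfg.planted_motifs)
    cstring_span = None
    out: list[tuple[str, int, int]] = []
    for name, pos, n_edits in planted:
        pattern = CSTRING if name == "C-string" else library[name].pattern
        if pos + len(pattern) - 1 > cfg.cr1_length:
            raise ValueError(f"motif {name} at {pos} exceeds CR1 length")
        _plant(seq, pos - 1, pattern)
        if n_edits:
            _edit(rng, seq, pos - 1, len(pattern), n_edits)
        if name == "C-string":
            # keep the run's borders non-C so the planted span is maximal
            if pos >= 2:
                seq[pos - 2] = "A"
            if pos - 1 + len(pattern) < cfg.cr1_length:
                seq[pos - 1 + len(pattern)] = "A"
            cstring_span = (pos, pos + len(pattern) - 1)
        else:
            out.append((name, pos, n_edits))
    return "".join(seq), out, cstring_span


def _generate_cr2(rng: np.random.Generator, cfg: SynthConfig
                  ) -> tuple[str, tuple[int, int, float, str] | None]:
    if cfg.planted_repeat is None:
        return random_sequence(rng, cfg.cr2_length, cfg.base_freqs), None
    unit, copies = cfg.planted_repeat
    period = len(unit)
    rep_len = int(round(period * copies))
    reps = (unit * (rep_len // period + 1))[:rep_len]
    flank = max(cfg.cr2_length - rep_len, 20)
    left = flank // 2
    right = flank - left
    cr2 = (
        random_sequence(rng, left, cfg.base_freqs)
        + reps
        + random_sequence(rng, right, cfg.base_freqs)
    )
    return cr2, (left + 1, period, rep_len / period, unit)


def generate_mitogenome(cfg: SynthConfig) -> tuple[MitoRecord, TruthRecord]:
    """Build one annotated synthetic mitogenome plus its truth record."""
    rng = np.random.default_rng(cfg.seed)
    template = load_template(cfg.arrangement)
    specs = load_generic_specs()

    segments: list[str] = []
    features: list[GeneFeature] = []
    cds: dict[str, str] = {}
    stops: dict[str, str] = {}
    trnas: dict[str, tuple[str, str]] = {}
    coords: dict[str, tuple[int, int, str]] = {}
    cr1_motifs: list[tuple[str, int, int]] = []
    cstring_span = None
    cr2_repeat = None

    pos = 1  # next free 1-based position
    for name, strand in template.rotated_to_anchor().genes:
        if name in _PCG_LAYOUT:
            sense, stop = _generate_cds(rng, name, cfg)
            cds[name] = sense
            stops[name] = stop
            seg, ftype = sense, "PCG"
        elif name.startswith("trn"):
            sense, layout = _generate_trna(rng, name, cfg, specs)
            trnas[name] = (layout, sense)
            seg, ftype = sense, "tRNA"
        elif name in _RRNA_LENGTHS:
            seg = random_sequence(rng, _RRNA_LENGTHS[name], cfg.base_freqs)
            sense, ftype = seg, "rRNA"
        elif name in ("CR1", "CR"):
            seg, cr1_motifs, cstring_span = _generate_cr1(rng, cfg)
            sense, ftype = seg, "CR"
        elif name == "CR2":
            seg, cr2_repeat = _generate_cr2(rng, cfg)
            sense, ftype = seg, "CR"
        else:
            raise ValueError(f"template gene {name!r} not recognized")
        placed = reverse_complement(sense) if strand == "N" else sense
        start, end = pos, pos + len(placed) - 1
        features.append(
            GeneFeature(name=name, ftype=ftype, start=start, end=end,
                        strand=strand)
        )
        coords[name] = (start, end, strand)
        segments.append(placed)
        pos = end + 1
        spacer = int(rng.integers(0, 2))
        if spacer:
            segments.append(random_sequence(rng, spacer, cfg.base_freqs))
            pos += spacer

    used = pos - 1
    if used > cfg.genome_length:
        raise ValueError(
            f"layout needs {used} bp but genome_length is {cfg.genome_length}"
        )
    tail = cfg.genome_length - used
    if tail:
        segments.append(random_sequence(rng, tail, cfg.base_freqs))

    record = MitoRecord(
        record_id=cfg.record_id,
        species=cfg.species,
        sequence="".join(segments),
        is_circular=True,
        features=features,
    )
    truth = TruthRecord(
        config=cfg,
        arrangement=template,
        cds=cds,
        stop_codons=stops,
        feature_coords=coords,
        cr1_motifs=cr1_motifs,
        cstring_span=cstring_span,
        cr2_repeat=cr2_repeat,
        trnas=trnas,
        pair_edits=cfg.pair_edits,
    )
    return record, truth


# ---------------------------------------------------------------------------
# aligned-matrix simulation


def expected_p_distance(q: float, k_branches: int) -> float:
    """Closed-form expected p-distance across ``k`` branches with per-branch
    per-site substitution probability ``q`` (Jukes-Cantor-style moves)."""
    return 0.75 * (1.0 - (1.0 - 4.0 * q / 3.0) ** k_branches)


def _mutate(rng: np.random.Generator, seq: np.ndarray, q: float) -> np.ndarray:
    out = seq.copy()
    hit = rng.random(seq.size) < q
    shifts = rng.integers(1, 4, size=int(hit.sum()))
    out[hit] = (out[hit] + shifts) % 4
    return out


def simulate_alignment(
    tree: str, root_len: int, subst_prob_per_branch: float, seed: int
):
    """Evolve a root sequence down a Newick tree.

    Every branch applies an independent per-site substitution with
    probability ``subst_prob_per_branch`` (substituted sites pick one of the
    other three bases uniformly).  Returns ``(AlignmentMatrix, tree_newick)``.
    """
    from .distance_phylo import AlignmentMatrix

    if not 0 <= subst_prob_per_branch < 0.75:
        raise ValueError("need 0 <= subst_prob < 0.75")
    try:
        t = dendropy.Tree.get(data=tree, schema="newick")
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=root_len)
    seqs: dict[int, np.ndarray] = {id(t.seed_node): root_seq}
    taxa: list[str] = []
    rows: list[str] = []
    for node in t.preorder_node_iter():
        if node is t.seed_node:
            continue
        parent_seq = seqs[id(node.parent_node)]
        seqs[id(node)] = _mutate(rng, parent_seq, subst_prob_per_branch)
        if node.is_leaf():
            taxa.append(node.taxon.label.replace(" ", "_"))
            rows.append("".join(_BASES[seqs[id(node)]]))
    return AlignmentMatrix(taxa=taxa, rows=rows), tree


def random_additive_tree(
    n_taxa: int, rng: np.random.Generator,
    min_branch: float = 0.05, max_branch: float = 1.0,
):
    """Random unrooted binary tree with uniform branch lengths.

    Returns ``(newick, PDistanceMatrix-compatible matrix, taxa)`` where the
    matrix holds exact path-length (tree-additive) distances.
    """
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    taxa = [f"T{i + 1}" for i in range(n_taxa)]
    edges: dict[tuple[int, int], float] = {}
    adj: dict[int, set[int]] = {}
    next_id = [n_taxa]

    def add_edge(u: int, v: int, w: float) -> None:
        edges[(min(u, v), max(u, v))] = w
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)

    def drop_edge(u: int, v: int) -> float:
        w = edges.pop((min(u, v), max(u, v)))
        adj[u].discard(v)
        adj[v].discard(u)
        return w

    def blen() -> float:
        return float(rng.uniform(min_branch, max_branch))

    center = next_id[0]
    next_id[0] += 1
    for leaf in range(3):
        add_edge(leaf, center, blen())
    for leaf in range(3, n_taxa):
        u, v = list(edges)[rng.integers(0, len(edges))]
        w = drop_edge(u, v)
        mid = next_id[0]
        next_id[0] += 1
        split = float(rng.uniform(0.25, 0.75))
        add_edge(u, mid, w * split)
        add_edge(v, mid, w * (1 - split))
        add_edge(leaf, mid, blen())

    # all-pairs leaf distances by DFS from each leaf (trees have unique paths)
    D = np.zeros((n_taxa, n_taxa))
    for src in range(n_taxa):
        dist = {src: 0.0}
        stack = [src]
        seen = {src}
        while stack:
            u = stack.pop()
            for v in adj.get(u, ()):  # trees: simple DFS suffices
                if v in seen:
                    continue
                seen.add(v)
                dist[v] = dist[u] + edges[(min(u, v), max(u, v))]
                stack.append(v)
        for dst in range(n_taxa):
            D[src, dst] = dist[dst]

    def newick(u: int, parent: int | None) -> str:
        children = [v for v in adj[u] if v != parent]
        if not children:
            return taxa[u]
        inner = ",".join(
            f"{newick(v, u)}:{edges[(min(u, v), max(u, v))]:.6f}"
            for v in children
        )
        return f"({inner})"

    root = n_taxa  # the original center node
    return newick(root, None) + ";", D, taxa
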