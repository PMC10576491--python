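"""tRNA cloverleaf stem-pair classification and cross-species conservation.

Structures are inputs (tRNA-local arm intervals from an external folding
annotation or the packaged generic layouts), not predicted here.  Sequences
are handled as DNA (T, not U); reports may render U.  Stem pairs are
classified purely by the unordered base pair: A-T and G-C are Watson-Crick,
G-T is the wobble pair, anything else is a mismatch.  Conservation of an arm
across species is the percent of its columns identical in all species
(strict identity, computed on pre-aligned equal-length sequences).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "CloverleafSpec",
    "PairClass",
    "ARM_NAMES",
    "load_generic_specs",
    "load_cloverleaf_yaml",
    "classify_pairs",
    "pair_category",
    "stem_conservation",
]

ARM_NAMES = ("AA", "DHU", "AC", "TPSIC")

_WC = {frozenset("AT"), frozenset("GC")}
_WOBBLE = frozenset("GT")


@dataclass(frozen=True)
class CloverleafSpec:
    """Arm intervals of one tRNA cloverleaf, tRNA-local 1-based inclusive.

    ``arms`` maps arm name -> ((five_start, five_end), (three_start,
    three_end)); the DHU arm may be absent, as in mitochondrial trnS(AGY).
    """

    trna_name: str
    arms: dict[str, tuple[tuple[int, int], tuple[int, int]]]
    anticodon: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        for arm, (five, three) in self.arms.items():
            if arm not in ARM_NAMES:
                raise ValueError(f"unknown arm {arm!r}")
            if five[1] - five[0] != three[1] - three[0]:
                raise ValueError(f"{self.trna_name} {arm}: paired intervals differ in length")

    @property
    def has_dhu(self) -> bool:
        return "DHU" in self.arms

    def stem_length(self, arm: str) -> int:
        five, _ = self.arms[arm]
        return five[1] - five[0] + 1


@dataclass(frozen=True)
class PairClass:
    arm: str
    index: int  # 0-based position within the stem, 5' side
    base5: str
    base3: str
    category: str  # WatsonCrick | GU_wobble | mismatch


def pair_category(base5: str, base3: str) -> str:
    pair = frozenset((base5.upper(), base3.upper()))
    if pair in _WC:
        return "WatsonCrick"
    if pair == _WOBBLE:
        return "GU_wobble"
    return "mismatch"


def classify_pairs(seq: str, spec: CloverleafSpec) -> list[PairClass]:
    """Classify every stem base pair of a tRNA.

    Stems pair antiparallel: position i of the 5' strand pairs with position
    (length-1-i) of the 3' strand.
    """
    seq = seq.upper()
    out: list[PairClass] = []
    for arm in ARM_NAMES:
        if arm not in spec.arms:
            continue
        (f0, f1), (t0, t1) = spec.arms[arm]
        if f1 > len(seq) or t1 > len(seq):
            raise ValueError(
                f"{spec.trna_name} {arm}: interval beyond sequence of {len(seq)} nt"
            )
        stem_len = f1 - f0 + 1
        for i in range(stem_len):
            b5 = seq[f0 - 1 + i]
            b3 = seq[t1 - 1 - i]
            out.append(
                PairClass(
                    arm=arm, index=i, base5=b5, base3=b3,
                    category=pair_category(b5, b3),
                )
            )
    return out


def stem_conservation(
    aligned_trnas: dict[str, str], spec: CloverleafSpec
) -> dict[str, float | None]:
    """Percent of stem columns identical across all species, per arm.

    Input sequences must be pre-aligned and equal length.  Arms absent from
    the spec are reported as ``None``.
    """
    if len(aligned_trnas) < 2:
        raise ValueError("need at least two species")
    seqs = [s.upper() for s in aligned_trnas.values()]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
    out: dict[str, float | None] = {}
    for arm in ARM_NAMES:
        if arm not in spec.arms:
            out[arm] = None
            continue
        (f0, f1), (t0, t1) = spec.arms[arm]
        cols = list(range(f0 - 1, f1)) + list(range(t0 - 1, t1))
        identical = sum(
            1 for c in cols if len({s[c] for s in seqs}) == 1
        )
        out[arm] = 100.0 * identical / len(cols)
    return out


def _spec_from_dict(name: str, d: dict) -> CloverleafSpec:
    arms = {
        arm: (tuple(v["five"]), tuple(v["three"]))
        for arm, v in d["arms"].items()
    }
    anticodon = tuple(d["anticodon"]) if "anticodon" in d else None
    return CloverleafSpec(trna_name=name, arms=arms, anticodon=anticodon)


def load_cloverleaf_yaml(path: str | Path) -> dict[str, CloverleafSpec]:
    """Load cloverleaf specs from a YAML file (layout name -> spec)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return {name: _spec_from_dict(name, d) for name, d in data.items()}


def load_generic_specs() -> dict[str, CloverleafSpec]:
    """The packaged generic layouts: ``standard`` (4 arms, 72 nt) and
    ``no_dhu`` (66 nt, trnS(AGY)-style)."""
    text = resources.files("mitochar.data").joinpath("cloverleaf_generic.yaml").read_text()
    data = yaml.safe_load(text)
    return {name: _spec_from_dict(name, d) for name, d in data.items()}
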