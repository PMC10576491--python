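"""Base composition, A+T content and strand-skew statistics.

AT-skew = (A-T)/(A+T) and GC-skew = (G-C)/(G+C), computed on the J strand of
the region of interest.  Ambiguity codes (including N) are counted under
``other`` and excluded from percentage denominators and from both skews; a
skew whose denominator is zero is reported as ``None``.  All internal values
are kept at full precision - rounding (2 decimals for percentages, 4 for
skews) happens only when a report is serialized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .mito_io import MitoRecord

__all__ = [
    "CompositionSummary",
    "composition",
    "codon_position_composition",
    "per_region_report",
    "FrameError",
]


class FrameError(ValueError):
    """A coding sequence is not a whole number of codons."""


@dataclass
class CompositionSummary:
    region_label: str
    counts: dict[str, int]
    pct: dict[str, float]
    at_content: float
    at_skew: float | None
    gc_skew: float | None

    def base_order(self) -> str:
        """Bases sorted by decreasing percentage, e.g. ``'C>A>T>G'``."""
        ordered = sorted(self.pct, key=lambda b: (-self.pct[b], b))
        return ">".join(ordered)

    def rounded(self) -> dict:
        return {
            "region": self.region_label,
            "counts": dict(self.counts),
            "pct": {b: round(v, 2) for b, v in self.pct.items()},
            "at_content": round(self.at_content, 2),
            "at_skew": None if self.at_skew is None else round(self.at_skew, 4),
            "gc_skew": None if self.gc_skew is None else round(self.gc_skew, 4),
        }


def composition(seq: str, label: str = "") -> CompositionSummary:
    """Exact base counts, percentages over unambiguous bases, and skews."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    other = len(seq) - sum(counts.values())
    unamb = sum(counts.values())
    if unamb == 0:
        raise ValueError(f"{label or 'sequence'}: no unambiguous bases")
    pct = {b: 100.0 * counts[b] / unamb for b in "ACGT"}
    a, c, g, t = counts["A"], counts["C"], counts["G"], counts["T"]
    at_skew = (a - t) / (a + t) if (a + t) else None
    gc_skew = (g - c) / (g + c) if (g + c) else None
    return CompositionSummary(
        region_label=label,
        counts={**counts, "other": other},
        pct=pct,
        at_content=100.0 * (a + t) / unamb,
        at_skew=at_skew,
        gc_skew=gc_skew,
    )


def codon_position_composition(
    cds_set: list[str], gene_names: list[str] | None = None
) -> tuple[CompositionSummary, CompositionSummary, CompositionSummary]:
    """Composition at codon positions 1, 2 and 3 over a set of in-frame CDSs.

    Each CDS must be a whole number of codons (incomplete stops already padded);
    the final (termination) codon of each CDS is excluded before pooling.
    """
    parts = {1: [], 2: [], 3: []}
    for i, cds in enumerate(cds_set):
        if len(cds) % 3 != 0:
            name = gene_names[i] if gene_names else f"CDS #{i + 1}"
            raise FrameError(f"{name}: length {len(cds)} not divisible by 3")
        body = cds[:-3]  # drop the termination codon
        parts[1].append(body[0::3])
        parts[2].append(body[1::3])
        parts[3].append(body[2::3])
    return tuple(
        composition("".join(parts[p]), label=f"codon position {p}")
        for p in (1, 2, 3)
    )


#: Regions reported by :func:`per_region_report`, besides the whole genome.
_REPORT_REGIONS = ("rrnS", "rrnL", "CR1", "CR2")


def per_region_report(
    rec: MitoRecord, pcg_concatenate: str | None = None
) -> pd.DataFrame:
    """One composition row per region: whole genome, PCG concatenate (when
    supplied by the codon_usage stage), rrnS, rrnL, CR1, CR2.

    Missing regions are flagged with ``present=False`` rather than fabricated.
    """
    rows = []

    def add(label: str, seq: str | None) -> None:
        if seq:
            s = composition(seq, label).rounded()
            s["present"] = True
        else:
            s = {"region": label, "present": False}
        rows.append(s)

    add("whole_genome", rec.sequence)
    add("PCGs", pcg_concatenate)
    for region in _REPORT_REGIONS:
        add(region, rec.feature_sequence(region) if rec.has_feature(region) else None)
    df = pd.DataFrame(rows)
    return df.set_index("region")
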