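"""CDS assembly, start/stop classification and relative synonymous codon usage.

All computations use the vertebrate mitochondrial genetic code (NCBI
translation table 2): ATA codes Met, TGA codes Trp, and AGA/AGG act as
termination codons.  A CDS whose annotated length is 1 or 2 nt short of a
whole codon ends in an incomplete stop (T or TA) that is completed to TAA by
post-transcriptional polyadenylation; :func:`assemble_cds` applies that
padding and flags it.

RSCU for codon *i* of a synonymous family of size *n* with family total *X*
is ``X_i * n / X`` - the observed count relative to uniform usage within the
family.  Families are per amino acid (so the six Leu codons form one family
of size 6, as do the six Ser codons); the customary L1/L2/S1/S2 sub-family
labels (L1 = UUR, L2 = CUN, S1 = AGY, S2 = UCN) are carried for reporting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from .mito_io import MitoRecord, PCGS

__all__ = [
    "CodonProfile",
    "RSCUTable",
    "MITO_CODE",
    "MITO_STOPS",
    "FAMILY_LABEL",
    "assemble_cds",
    "rscu",
    "codon_inventory",
    "InternalStopError",
]


class InternalStopError(ValueError):
    """An in-frame termination codon occurs before the end of a CDS."""


# ---------------------------------------------------------------------------
# vertebrate mitochondrial code (translation table 2)

_STANDARD = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

#: codon -> amino acid under table 2 ('*' = stop)
MITO_CODE = dict(_STANDARD)
MITO_CODE["ATA"] = "M"
MITO_CODE["TGA"] = "W"
MITO_CODE["AGA"] = "*"
MITO_CODE["AGG"] = "*"

MITO_STOPS = frozenset(c for c, aa in MITO_CODE.items() if aa == "*")

#: codon -> report label with Leu/Ser sub-family disambiguation
FAMILY_LABEL = {}
for _codon, _aa in MITO_CODE.items():
    if _aa == "L":
        FAMILY_LABEL[_codon] = "L1" if _codon.startswith("TT") else "L2"
    elif _aa == "S":
        FAMILY_LABEL[_codon] = "S1" if _codon.startswith("AG") else "S2"
    else:
        FAMILY_LABEL[_codon] = _aa

#: amino acid -> synonymous family (sense codons only)
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(MITO_CODE.items()):
    if _aa != "*":
        FAMILIES.setdefault(_aa, ())
        FAMILIES[_aa] += (_codon,)


@dataclass
class CodonProfile:
    """Start/stop classification for one protein-coding gene."""

    gene: str
    start_codon: str
    stop_codon: str  # verbatim as annotated, possibly 'TA' or 'T'
    padded: bool


@dataclass
class RSCUEntry:
    codon: str
    family: str  # L1/L2/S1/S2 or one-letter amino acid
    amino_acid: str
    count: int
    rscu: float


@dataclass
class RSCUTable:
    entries: list[RSCUEntry]
    skipped_codons: int = 0
    code_table: str = "vertebrate mitochondrial"

    def by_codon(self) -> dict[str, RSCUEntry]:
        return {e.codon: e for e in self.entries}

    def to_frame(self, rna: bool = True) -> pd.DataFrame:
        """Tabular view; ``rna=True`` renders codons with U (report style)."""
        rows = [
            {
                "codon": e.codon.replace("T", "U") if rna else e.codon,
                "family": e.family,
                "amino_acid": e.amino_acid,
                "count": e.count,
                "rscu": round(e.rscu, 4),
            }
            for e in self.entries
        ]
        return pd.DataFrame(rows)


def assemble_cds(rec: MitoRecord, gene: str) -> tuple[str, CodonProfile]:
    """Extract the coding-sense, in-frame, stop-padded CDS of a PCG.

    N-strand genes are reverse-complemented; ``codon_start`` trims leading
    bases; a trailing 1-2 nt incomplete stop (T/TA) is padded with A to TAA.
    Returns the padded sequence and the gene's :class:`CodonProfile` (stop
    recorded verbatim, pre-padding).
    """
    feat = rec.feature_by_name(gene)
    if feat.ftype != "PCG":
        raise ValueError(f"{gene} is not a protein-coding gene")
    seq = rec.feature_sequence(gene)
    seq = seq[feat.codon_start - 1 :]
    if len(seq) < 6:
        raise ValueError(f"{gene}: CDS of {len(seq)} nt is too short")
    rem = len(seq) % 3
    if rem:
        stop = seq[-rem:]
        padded = True
        seq = seq + "A" * (3 - rem)
    else:
        stop = seq[-3:]
        padded = False
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for i, codon in enumerate(codons[:-1]):
        if codon in MITO_STOPS:
            raise InternalStopError(f"{gene}: in-frame stop {codon} at codon {i + 1}")
    profile = CodonProfile(
        gene=gene, start_codon=codons[0], stop_codon=stop, padded=padded
    )
    return seq, profile


def rscu(cds_set: list[str]) -> RSCUTable:
    """RSCU over a set of padded, in-frame CDS strings.

    The final (possibly padded) codon of every CDS is dropped, as are all
    termination codons; codons containing non-ACGT characters are skipped and
    tallied in ``skipped_codons``.  Families with zero total get RSCU 0 for
    all members.
    """
    counts: dict[str, int] = {c: 0 for c in MITO_CODE if MITO_CODE[c] != "*"}
    skipped = 0
    for cds in cds_set:
        if len(cds) % 3 != 0:
            raise ValueError(f"CDS length {len(cds)} not divisible by 3")
        for i in range(0, len(cds) - 3, 3):  # excludes the final codon
            codon = cds[i : i + 3]
            if codon not in MITO_CODE:
                skipped += 1
                continue
            if codon in MITO_STOPS:
                continue
            counts[codon] += 1
    entries = []
    for aa, family in sorted(FAMILIES.items()):
        total = sum(counts[c] for c in family)
        n = len(family)
        for codon in family:
            value = counts[codon] * n / total if total else 0.0
            entries.append(
                RSCUEntry(
                    codon=codon,
                    family=FAMILY_LABEL[codon],
                    amino_acid=aa,
                    count=counts[codon],
                    rscu=value,
                )
            )
    return RSCUTable(entries=entries, skipped_codons=skipped)


def codon_inventory(
    recs: list[MitoRecord],
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene start/stop codon table across records (verbatim, pre-padding).

    Returns the table plus completeness warnings for any missing PCG.
    """
    rows = []
    warnings: list[str] = []
    for rec in recs:
        for gene in PCGS:
            if not rec.has_feature(gene):
                warnings.append(f"{rec.record_id}: missing PCG {gene}")
                continue
            _, profile = assemble_cds(rec, gene)
            rows.append(
                {
                    "record": rec.record_id,
                    "gene": gene,
                    "start_codon": profile.start_codon,
                    "stop_codon": profile.stop_codon,
                    "padded": profile.padded,
                }
            )
    return pd.DataFrame(rows, columns=["record", "gene", "start_codon",
                                       "stop_codon", "padded"]), warnings
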