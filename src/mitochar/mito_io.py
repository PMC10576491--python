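"""Reading, writing and slicing annotated circular mitochondrial genomes.

Coordinates are 1-based inclusive throughout (GenBank convention); the only
conversions to Python 0-based half-open indices happen inside this module.
Strand labels follow the mitochondrial literature: ``J`` is the majority
(heavy) coding strand stored in the record sequence, ``N`` is the minority
strand, i.e. the gene is read on the reverse complement.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "MitoRecord",
    "GeneFeature",
    "MitoFormatError",
    "AnnotationError",
    "CoordinateError",
    "PCGS",
    "TRNAS",
    "RRNAS",
    "CONTROL_REGIONS",
    "FTYPE_BY_NAME",
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "extract_region",
    "reverse_complement",
    "load_synonyms",
    "resolve_gene_name",
]


class MitoFormatError(ValueError):
    """The input file could not be parsed in the expected format."""


class AnnotationError(ValueError):
    """The annotation content is unusable (e.g. no features at all)."""


class CoordinateError(ValueError):
    """A requested coordinate lies outside the record or wraps a linear record."""


#: Canonical gene symbols (controlled vocabulary).
PCGS = (
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
    "cox1", "cox2", "cox3", "atp6", "atp8", "cytb",
)
TRNAS = (
    "trnF", "trnV", "trnL(UUR)", "trnI", "trnQ", "trnM", "trnW", "trnA",
    "trnN", "trnC", "trnY", "trnS(UCN)", "trnD", "trnK", "trnG", "trnR",
    "trnH", "trnS(AGY)", "trnL(CUN)", "trnT", "trnP", "trnE",
)
RRNAS = ("rrnS", "rrnL")
CONTROL_REGIONS = ("CR", "CR1", "CR2")

FTYPE_BY_NAME: dict[str, str] = {}
FTYPE_BY_NAME.update({g: "PCG" for g in PCGS})
FTYPE_BY_NAME.update({g: "tRNA" for g in TRNAS})
FTYPE_BY_NAME.update({g: "rRNA" for g in RRNAS})
FTYPE_BY_NAME.update({g: "CR" for g in CONTROL_REGIONS})

_GB_TYPE_BY_FTYPE = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "CR": "misc_feature"}

_AA3_BY_TRNA = {
    "trnF": "Phe", "trnV": "Val", "trnL(UUR)": "Leu", "trnI": "Ile",
    "trnQ": "Gln", "trnM": "Met", "trnW": "Trp", "trnA": "Ala", "trnN": "Asn",
    "trnC": "Cys", "trnY": "Tyr", "trnS(UCN)": "Ser", "trnD": "Asp",
    "trnK": "Lys", "trnG": "Gly", "trnR": "Arg", "trnH": "His",
    "trnS(AGY)": "Ser", "trnL(CUN)": "Leu", "trnT": "Thr", "trnP": "Pro",
    "trnE": "Glu",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string, preserving IUPAC ambiguity codes."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class GeneFeature:
    """One annotated gene on the circle.

    ``start``/``end`` are 1-based inclusive; ``start > end`` denotes a feature
    wrapping the origin of a circular record.  ``strand`` is ``J`` or ``N``.
    """

    name: str
    ftype: str
    start: int
    end: int
    strand: str = "J"
    codon_start: int = 1

    def __post_init__(self) -> None:
        if self.strand not in ("J", "N"):
            raise ValueError(f"strand must be J or N, got {self.strand!r}")
        if self.name in FTYPE_BY_NAME and FTYPE_BY_NAME[self.name] != self.ftype:
            raise ValueError(
                f"{self.name!r} has canonical type {FTYPE_BY_NAME[self.name]}, "
                f"not {self.ftype}"
            )

    def length(self, genome_length: int) -> int:
        if self.start <= self.end:
            return self.end - self.start + 1
        return genome_length - self.start + 1 + self.end


@dataclass
class MitoRecord:
    """One annotated (usually circular) mitochondrial genome."""

    record_id: str
    species: str
    sequence: str
    is_circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        for f in self.features:
            self._check_feature(f)

    def _check_feature(self, f: GeneFeature) -> None:
        n = self.length_bp
        if not (1 <= f.start <= n and 1 <= f.end <= n):
            raise CoordinateError(
                f"feature {f.name}: [{f.start}, {f.end}] outside [1, {n}]"
            )
        if f.start > f.end and not self.is_circular:
            raise CoordinateError(
                f"feature {f.name} wraps the origin of a linear record"
            )

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    def feature_by_name(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def has_feature(self, name: str) -> bool:
        return any(f.name == name for f in self.features)

    def feature_sequence(self, name: str) -> str:
        """Sequence of a named feature in its reading orientation."""
        f = self.feature_by_name(name)
        return extract_region(self, f.start, f.end, f.strand)


def extract_region(rec: MitoRecord, start: int, end: int, strand: str = "J") -> str:
    """Extract ``[start, end]`` (1-based inclusive) from a record.

    ``start > end`` wraps through the origin (circular records only).
    ``strand='N'`` returns the reverse complement of the J-strand slice.
    """
    n = rec.length_bp
    if not (1 <= start <= n and 1 <= end <= n):
        raise CoordinateError(f"[{start}, {end}] outside [1, {n}]")
    if start <= end:
        seg = rec.sequence[start - 1 : end]
    else:
        if not rec.is_circular:
            raise CoordinateError("wrap through origin requested on linear record")
        seg = rec.sequence[start - 1 :] + rec.sequence[:end]
    if strand == "N":
        return reverse_complement(seg)
    if strand != "J":
        raise ValueError(f"strand must be J or N, got {strand!r}")
    return seg


# ---------------------------------------------------------------------------
# gene-name resolution


def _normalize(token: str) -> str:
    return re.sub(r"[\s_\-]+", "", token).upper()


def load_synonyms() -> dict[str, str]:
    """Load the packaged qualifier-spelling -> canonical-name table."""
    text = resources.files("mitochar.data").joinpath("synonyms.yaml").read_text()
    table = yaml.safe_load(text)["synonyms"]
    out = {_normalize(k): v for k, v in table.items()}
    out.update({_normalize(g): g for g in FTYPE_BY_NAME})
    return out


_ISOACCEPTOR_TAGS = ("UUR", "CUN", "UCN", "AGY")


def resolve_gene_name(
    qualifiers: dict[str, list[str]], synonyms: dict[str, str]
) -> str | None:
    """Map GenBank feature qualifiers to a canonical gene symbol.

    Tries ``gene``, then ``product``, then ``note``.  Ambiguous tRNA-Leu /
    tRNA-Ser spellings are resolved from a UUR/CUN/UCN/AGY tag appearing
    anywhere in the qualifier text; without one the name stays unresolved.
    """
    raw = " ".join(
        v for key in ("gene", "product", "note") for v in qualifiers.get(key, [])
    )
    tag = next((t for t in _ISOACCEPTOR_TAGS if t in raw.upper()), None)
    for key in ("gene", "product", "note"):
        for value in qualifiers.get(key, []):
            token = _normalize(value)
            if token in synonyms:
                return synonyms[token]
            # ambiguous Leu/Ser spellings such as "tRNA-Leu"
            if token in ("TRNL", "TRNALEU") and tag in ("UUR", "CUN"):
                return f"trnL({tag})"
            if token in ("TRNS", "TRNASER") and tag in ("UCN", "AGY"):
                return f"trnS({tag})"
    return None


# ---------------------------------------------------------------------------
# GenBank / FASTA I/O


def _feature_from_seqfeature(
    sf: SeqFeature, synonyms: dict[str, str], genome_length: int
) -> GeneFeature | None:
    if sf.type not in ("CDS", "tRNA", "rRNA", "misc_feature", "D-loop", "D_loop"):
        return None
    name = resolve_gene_name(dict(sf.qualifiers), synonyms)
    if sf.type in ("D-loop", "D_loop") and name is None:
        name = "CR"
    if name is None:
        return None
    ftype = FTYPE_BY_NAME[name]
    strand = "N" if sf.location.strand == -1 else "J"
    if isinstance(sf.location, CompoundLocation) and len(sf.location.parts) == 2:
        # origin-wrapping join(a..L, 1..b)
        p1, p2 = sf.location.parts
        start, end = int(p1.start) + 1, int(p2.end)
    else:
        start, end = int(sf.location.start) + 1, int(sf.location.end)
    codon_start = int(sf.qualifiers.get("codon_start", ["1"])[0])
    return GeneFeature(name=name, ftype=ftype, start=start, end=end,
                       strand=strand, codon_start=codon_start)


def _assign_cr_labels(features: list[GeneFeature], genome_length: int) -> None:
    """Relabel generic 'CR' features as CR1/CR2 in circular order from trnF.

    Using the anchor makes the labels independent of where the flat file
    happens to start on the circle.
    """
    crs = [f for f in features if f.name == "CR"]
    if len(crs) <= 1:
        return
    anchors = [f for f in features if f.name == "trnF"]
    origin = anchors[0].start if anchors else 1
    crs.sort(key=lambda f: (f.start - origin) % genome_length)
    for i, f in enumerate(crs, start=1):
        if i > 2:
            break
        f.name = f"CR{i}"


def read_genbank(path: str | Path) -> tuple[list[MitoRecord], list[str]]:
    """Read a GenBank flat file into :class:`MitoRecord` objects.

    Returns ``(records, warnings)``; features whose names cannot be resolved
    through the synonym table are reported in ``warnings``, never dropped
    silently into an exception.
    """
    synonyms = load_synonyms()
    warnings: list[str] = []
    records: list[MitoRecord] = []
    try:
        parsed = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises assorted ValueError subclasses
        raise MitoFormatError(f"cannot parse {path} as GenBank: {exc}") from exc
    if not parsed:
        raise MitoFormatError(f"{path}: no GenBank records found")
    for sr in parsed:
        feats: list[GeneFeature] = []
        seen_cds: set[tuple[str, int]] = set()
        for sf in sr.features:
            if sf.type == "gene":
                continue
            gf = _feature_from_seqfeature(sf, synonyms, len(sr.seq))
            if gf is None:
                if sf.type in ("CDS", "tRNA", "rRNA", "misc_feature", "D-loop", "D_loop"):
                    warnings.append(
                        f"{sr.id}: unmappable {sf.type} feature at {sf.location}"
                    )
                continue
            key = (gf.name, gf.start)
            if key in seen_cds:  # gene + CDS double annotation
                continue
            seen_cds.add(key)
            feats.append(gf)
        if not feats:
            raise AnnotationError(f"{sr.id}: no mappable features")
        _assign_cr_labels(feats, len(sr.seq))
        topology = sr.annotations.get("topology", "circular")
        records.append(
            MitoRecord(
                record_id=sr.id,
                species=sr.annotations.get("organism", ""),
                sequence=str(sr.seq),
                is_circular=(topology == "circular"),
                features=feats,
            )
        )
    return records, warnings


def _seqfeature_from_feature(gf: GeneFeature, genome_length: int) -> SeqFeature:
    strand = -1 if gf.strand == "N" else 1
    if gf.start <= gf.end:
        loc = SimpleLocation(gf.start - 1, gf.end, strand=strand)
    else:
        loc = CompoundLocation(
            [
                SimpleLocation(gf.start - 1, genome_length, strand=strand),
                SimpleLocation(0, gf.end, strand=strand),
            ]
        )
    qualifiers: dict[str, list[str]] = {"gene": [gf.name]}
    if gf.ftype == "PCG":
        qualifiers["codon_start"] = [str(gf.codon_start)]
    elif gf.ftype == "tRNA":
        qualifiers["product"] = [f"tRNA-{_AA3_BY_TRNA[gf.name]}"]
    elif gf.ftype == "rRNA":
        sub = "small" if gf.name == "rrnS" else "large"
        qualifiers["product"] = [f"{sub} subunit ribosomal RNA"]
    else:
        qualifiers["note"] = ["control region"]
    return SeqFeature(loc, type=_GB_TYPE_BY_FTYPE[gf.ftype], qualifiers=qualifiers)


def write_genbank(recs: Iterable[MitoRecord], path: str | Path) -> None:
    """Write records as a GenBank flat file re-readable by :func:`read_genbank`."""
    out = []
    for rec in recs:
        sr = SeqRecord(
            Seq(rec.sequence),
            id=rec.record_id,
            name=rec.record_id[:16].replace(" ", "_") or "mitogenome",
            description=f"{rec.species} mitochondrion".strip(),
            annotations={
                "molecule_type": "DNA",
                "topology": "circular" if rec.is_circular else "linear",
                "organism": rec.species,
            },
        )
        sr.features = [
            _seqfeature_from_feature(f, rec.length_bp) for f in rec.features
        ]
        out.append(sr)
    SeqIO.write(out, str(path), "genbank")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file as ``(identifier, sequence)`` pairs."""
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(entries: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
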