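"""Orchestration: run every characterization stage and emit a report bundle.

The reporter only collects and serializes module outputs - nothing is
recomputed here.  Cross-record averages are unweighted arithmetic means of
per-record percentages.  Rounding happens at serialization only: 2 decimals
for percentages, 4 for distances and RSCU, 1 for repeat copy numbers.
Report JSON is written with sorted keys so a rerun on the same inputs is
byte-identical.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np

from . import codon_usage, control_region, distance_phylo, seq_stats
from .gene_order import (
    CompletenessError,
    check_complete,
    extract_arrangement,
    strand_census,
)
from .mito_io import MitoRecord, read_genbank

__all__ = ["run_pipeline", "write_report", "validate_report", "load_report_schema"]


def _composition_section(rec: MitoRecord, pcg_concat: str | None) -> dict:
    df = seq_stats.per_region_report(rec, pcg_concatenate=pcg_concat)
    out = {}
    for region, row in df.iterrows():
        if not row["present"]:
            out[region] = {"present": False}
            continue
        out[region] = {
            "present": True,
            "pct": row["pct"],
            "at_content": row["at_content"],
            "at_skew": row["at_skew"],
            "gc_skew": row["gc_skew"],
            "base_order": ">".join(
                sorted(row["pct"], key=lambda b: (-row["pct"][b], b))
            ),
        }
    return out


def _cr_section(rec: MitoRecord, cr_name: str, config: dict) -> dict:
    if not rec.has_feature(cr_name):
        return {"present": False}
    seq = rec.feature_sequence(cr_name)
    section: dict = {"present": True, "length_bp": len(seq)}
    library = control_region.load_motif_library()
    spec = None
    boundaries = config.get("cr_domains")
    if boundaries:
        spec = control_region.CRDomainSpec(*[tuple(b) for b in boundaries])
    elif len(seq) >= control_region.DEFAULT_DOMAIN_SPEC.domain3[1]:
        spec = control_region.DEFAULT_DOMAIN_SPEC
    if cr_name == "CR1":
        hits = control_region.scan_motifs(seq, library, domain_spec=spec)
        present_boxes = {h.box_name for h in hits}
        section["boxes"] = {
            h.box_name: {
                "start": h.start,
                "mismatches": h.mismatches,
                "domain": h.domain,
            }
            for h in hits
        }
        section["absent_boxes"] = sorted(
            {m.box_name for m in library} - present_boxes
        )
        cstrings = control_region.find_cstring(seq)
        section["c_strings"] = [
            {"start": s, "end": e, "length": ln} for s, e, ln in cstrings
        ]
        if spec is not None:
            parts = control_region.partition_domains(seq, spec)
            section["domains"] = {k: len(v) for k, v in parts.items()}
    repeats = control_region.find_tandem_repeats(seq)
    section["tandem_repeats"] = [
        {
            "start": r.start,
            "end": r.end,
            "period": r.period,
            "copy_number": r.copy_number_1dp,
            "consensus": r.consensus,
            "pct_identity": round(r.pct_identity, 2),
        }
        for r in repeats
    ]
    return section


def _record_section(rec: MitoRecord, config: dict, warnings: list[str]) -> dict:
    section: dict = {
        "record_id": rec.record_id,
        "species": rec.species,
        "length_bp": rec.length_bp,
    }
    counts = {"PCG": 0, "tRNA": 0, "rRNA": 0, "CR": 0}
    for f in rec.features:
        counts[f.ftype] += 1
    section["gene_counts"] = counts
    section["n_genes"] = counts["PCG"] + counts["tRNA"] + counts["rRNA"]

    arr = extract_arrangement(rec)
    try:
        check_complete(arr)
    except CompletenessError as exc:
        warnings.append(f"{rec.record_id}: {exc}")
    section["strand_census"] = strand_census(arr)
    section["gene_order"] = [list(g) for g in arr.genes]

    cds_map: dict[str, str] = {}
    inventory = []
    for f in rec.features:
        if f.ftype != "PCG":
            continue
        try:
            padded, profile = codon_usage.assemble_cds(rec, f.name)
        except ValueError as exc:
            warnings.append(f"{rec.record_id}: {exc}")
            continue
        cds_map[f.name] = padded
        inventory.append(
            {
                "gene": profile.gene,
                "start_codon": profile.start_codon,
                "stop_codon": profile.stop_codon,
                "padded": profile.padded,
            }
        )
    section["codon_inventory"] = sorted(inventory, key=lambda r: r["gene"])

    # stop codons are excluded from the PCG concatenate
    pcg_concat = "".join(cds_map[g][:-3] for g in sorted(cds_map)) or None
    section["composition"] = _composition_section(rec, pcg_concat)

    if cds_map:
        table = codon_usage.rscu([cds_map[g] for g in sorted(cds_map)])
        section["rscu"] = {
            e.codon: {"family": e.family, "count": e.count, "rscu": round(e.rscu, 4)}
            for e in table.entries
        }
        top = max(table.entries, key=lambda e: (e.rscu, e.codon))
        section["rscu_top_codon"] = top.codon

    section["CR1"] = _cr_section(rec, "CR1", config)
    section["CR2"] = _cr_section(rec, "CR2", config)
    return section


def run_pipeline(
    inputs: list[str | Path],
    config: dict | None = None,
    alignment: str | Path | None = None,
) -> dict:
    """Run all characterization stages over a set of GenBank files.

    Per-record stage failures are isolated into the warnings list; an error
    is raised only when no record can be processed at all.
    """
    config = config or {}
    if not inputs:
        raise ValueError("no input files given")
    warnings: list[str] = []
    records: list[MitoRecord] = []
    for path in inputs:
        recs, w = read_genbank(path)
        warnings.extend(w)
        records.extend(recs)
    if not records:
        raise ValueError("no readable records")

    per_record = {}
    for rec in records:
        try:
            per_record[rec.record_id] = _record_section(rec, config, warnings)
        except Exception as exc:  # isolate per-record failures
            warnings.append(f"{rec.record_id}: stage failure: {exc}")

    if not per_record:
        raise ValueError("every record failed")

    report: dict = {"records": per_record, "warnings": warnings}

    # cross-record averaged whole-genome composition
    pcts = [
        s["composition"]["whole_genome"]["pct"]
        for s in per_record.values()
        if s["composition"]["whole_genome"].get("present")
    ]
    if pcts:
        report["average_composition"] = {
            b: round(float(np.mean([p[b] for p in pcts])), 2) for b in "ACGT"
        }

    if alignment is not None:
        aln = distance_phylo.read_alignment_fasta(alignment)
        mode = config.get("deletion_mode", "complete")
        dm = distance_phylo.p_distance(aln, mode=mode)
        report["p_distance"] = {
            "deletion_mode": mode,
            "taxa": dm.taxa,
            "matrix": [[round(float(x), 4) for x in row] for row in dm.d],
        }
        report["nj_tree"] = distance_phylo.neighbor_joining(dm)
    return report


def load_report_schema() -> dict:
    text = resources.files("mitochar.data").joinpath("report_schema.json").read_text()
    return json.loads(text)


def validate_report(report: dict) -> None:
    """Check a report against the shipped schema (required keys and types).

    Minimal structural validation: raises ``ValueError`` on the first
    violation.
    """
    schema = load_report_schema()

    def check(obj: dict, spec: dict, path: str) -> None:
        for key in spec.get("required", []):
            if key not in obj:
                raise ValueError(f"{path}: missing required key {key!r}")
        for key, sub in spec.get("properties", {}).items():
            if key not in obj:
                continue
            val = obj[key]
            expected = sub.get("type")
            pytypes = {
                "object": dict, "array": list, "string": str,
                "integer": int, "number": (int, float), "boolean": bool,
            }
            if expected and not isinstance(val, pytypes[expected]):
                raise ValueError(f"{path}.{key}: expected {expected}")
            if expected == "object" and (
                "required" in sub or "properties" in sub
            ):
                check(val, sub, f"{path}.{key}")
            if expected == "object" and "valueSchema" in sub:
                for k, v in val.items():
                    check(v, sub["valueSchema"], f"{path}.{key}.{k}")

    check(report, schema, "$")


def write_report(report: dict, outdir: str | Path) -> Path:
    """Serialize the report bundle (JSON + per-section TSVs).

    Returns the path of the JSON report.  Keys are sorted so reruns are
    byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    json_path = outdir / "report.json"
    json_path.write_text(
        json.dumps(report, indent=2, sort_keys=True, allow_nan=False) + "\n"
    )
    # flat TSVs for the most tabular sections
    lines = ["record\tgene\tstart_codon\tstop_codon\tpadded"]
    for rid, sec in sorted(report["records"].items()):
        for row in sec.get("codon_inventory", []):
            lines.append(
                f"{rid}\t{row['gene']}\t{row['start_codon']}"
                f"\t{row['stop_codon']}\t{row['padded']}"
            )
    (outdir / "codon_inventory.tsv").write_text("\n".join(lines) + "\n")
    lines = ["record\tcodon\tfamily\tcount\trscu"]
    for rid, sec in sorted(report["records"].items()):
        for codon, row in sorted(sec.get("rscu", {}).items()):
            lines.append(
                f"{rid}\t{codon}\t{row['family']}\t{row['count']}\t{row['rscu']}"
            )
    (outdir / "rscu.tsv").write_text("\n".join(lines) + "\n")
    return json_path
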