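"""CDS assembly, incomplete-stop padding, and RSCU under the mito code."""

from collections import Counter, defaultdict

import numpy as np
import pytest

from mitochar.codon_usage import (
    FAMILIES,
    InternalStopError,
    MITO_CODE,
    MITO_STOPS,
    assemble_cds,
    codon_inventory,
    rscu,
)
from mitochar.mito_io import GeneFeature, MitoRecord, reverse_complement


def make_record(cds: str, gene: str = "nad3", strand: str = "J",
                codon_start: int = 1) -> MitoRecord:
    placed = reverse_complement(cds) if strand == "N" else cds
    seq = "GGGG" + placed + "GGGG"
    return MitoRecord(
        "R1", "t", seq, True,
        [GeneFeature(gene, "PCG", 5, 4 + len(placed), strand,
                     codon_start=codon_start)],
    )


class TestAssembleCDS:
    def test_complete_stop_not_padded(self):
        seq, prof = assemble_cds(make_record("ATGAAATAA"), "nad3")
        assert (prof.start_codon, prof.stop_codon, prof.padded) == (
            "ATG", "TAA", False)
        assert seq == "ATGAAATAA"

    def test_single_t_stop_padded(self):
        seq, prof = assemble_cds(make_record("ATGGATGATT"), "nad3")
        assert prof.stop_codon == "T"
        assert prof.padded
        assert seq.endswith("TAA") and len(seq) % 3 == 0

    def test_ta_stop_padded(self):
        seq, prof = assemble_cds(make_record("ATGGATGATTA"), "nad3")
        assert prof.stop_codon == "TA"
        assert prof.padded
        assert seq.endswith("TAA")

    def test_n_strand_gene_returns_coding_sense(self, synth_genome):
        rec, truth = synth_genome
        seq, _ = assemble_cds(rec, "nad6")
        assert seq == truth.cds["nad6"]

    def test_codon_start_offset_honored(self):
        seq, prof = assemble_cds(
            make_record("GATGAAATAA", codon_start=2), "nad3")
        assert prof.start_codon == "ATG"

    def test_internal_stop_raises(self):
        with pytest.raises(InternalStopError):
            assemble_cds(make_record("ATGTAAGGGTAA"), "nad3")

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="short"):
            assemble_cds(make_record("ATGA"), "nad3")


class TestRSCU:
    def test_uniform_leu_family_all_ones(self):
        cds = "ATG" + "TTATTGCTTCTCCTACTG" + "TAA"
        table = rscu([cds])
        for codon in FAMILIES["L"]:
            assert table.by_codon()[codon].rscu == pytest.approx(1.0)

    def test_hand_computed_leu_family(self):
        # CTA x2, CTG x1, no other Leu: rscu(CTA) = 2*6/3 = 4.0
        cds = "ATG" + "CTACTACTG" + "TAA"
        table = rscu([cds])
        assert table.by_codon()["CTA"].rscu == pytest.approx(4.0)
        assert table.by_codon()["CTG"].rscu == pytest.approx(2.0)
        for codon in ("TTA", "TTG", "CTT", "CTC"):
            assert table.by_codon()[codon].rscu == 0.0

    def test_family_sums_equal_family_size(self, synth_genome):
        rec, truth = synth_genome
        table = rscu([assemble_cds(rec, g)[0] for g in truth.cds])
        sums = defaultdict(float)
        totals = defaultdict(int)
        for e in table.entries:
            sums[e.amino_acid] += e.rscu
            totals[e.amino_acid] += e.count
        for aa, family in FAMILIES.items():
            if totals[aa]:
                assert sums[aa] == pytest.approx(len(family), abs=1e-9)

    def test_mean_rscu_is_one_within_family(self, synth_genome):
        rec, truth = synth_genome
        table = rscu([assemble_cds(rec, g)[0] for g in truth.cds])
        by_aa = defaultdict(list)
        for e in table.entries:
            by_aa[e.amino_acid].append(e)
        for aa, entries in by_aa.items():
            if not sum(e.count for e in entries):
                continue
            assert sum(e.rscu for e in entries) / len(entries) == pytest.approx(1.0)

    def test_concatenation_order_invariance(self, synth_genome):
        rec, truth = synth_genome
        cds = [assemble_cds(rec, g)[0] for g in truth.cds]
        t1 = rscu(cds)
        t2 = rscu(list(reversed(cds)))
        assert [(e.codon, e.count, e.rscu) for e in t1.entries] == [
            (e.codon, e.count, e.rscu) for e in t2.entries
        ]

    def test_counts_match_naive_sliding_count(self, synth_genome):
        rec, truth = synth_genome
        cds = [assemble_cds(rec, g)[0] for g in truth.cds]
        table = rscu(cds)
        naive = Counter()
        for s in cds:
            for i in range(0, len(s) - 3, 3):
                codon = s[i : i + 3]
                if codon in MITO_CODE and codon not in MITO_STOPS:
                    naive[codon] += 1
        for e in table.entries:
            assert e.count == naive[e.codon]

    def test_planted_codon_bias_recovered(self, synth_genome):
        rec, truth = synth_genome
        table = rscu([assemble_cds(rec, g)[0] for g in truth.cds])
        leu = {c: table.by_codon()[c].rscu for c in FAMILIES["L"]}
        assert max(leu, key=leu.get) == "CTA"

    def test_met_trp_are_two_codon_families(self):
        assert set(FAMILIES["M"]) == {"ATA", "ATG"}
        assert set(FAMILIES["W"]) == {"TGA", "TGG"}
        assert MITO_STOPS == {"TAA", "TAG", "AGA", "AGG"}


class TestInventory:
    def test_inventory_on_synthetic_record(self, synth_genome):
        rec, truth = synth_genome
        table, warnings = codon_inventory([rec])
        assert warnings == []
        assert len(table) == 13
        assert set(table["start_codon"]) == {"ATG"}
        stops = dict(zip(table["gene"], table["stop_codon"]))
        assert stops["nad2"] == "TA"
        assert stops["nad4"] == "T"
        assert stops["cox1"] == "AGG"
        assert stops["nad5"] == "AGA"

    def test_gtg_start_reported_verbatim(self):
        rec = make_record("GTGAAATAG")
        table, warnings = codon_inventory([rec])
        row = table[table["gene"] == "nad3"].iloc[0]
        assert row["start_codon"] == "GTG"
        assert row["stop_codon"] == "TAG"

    def test_missing_pcgs_warn(self):
        rec = MitoRecord(
            "R2", "t", "A" * 100, True,
            [GeneFeature("trnF", "tRNA", 1, 70, "J"),
             GeneFeature("rrnS", "rRNA", 75, 95, "J")],
        )
        table, warnings = codon_inventory([rec])
        assert table.empty
        assert len(warnings) == 13
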