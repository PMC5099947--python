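"""Reference-set curation: reading, length partitioning, masking."""

import pandas as pd
import pytest

from aprphylo import refset
from aprphylo.refset import (
    MarkerRecord,
    ReferenceAlignment,
    alignment_from_records,
    concatenate_subunits,
    mask_incomplete_columns,
    masked_widths,
    partition_sequence_set,
    read_sequence_set,
)


def _write_fasta(path, entries):
    path.write_text("".join(f">{rid}\n{seq}\n" for rid, seq in entries))


def _metadata(ids):
    return pd.DataFrame(
        {
            "record_id": ids,
            "organism": [f"org {i}" for i in ids],
            "taxonomy": ["Bacteria;Proteobacteria"] * len(ids),
            "role": ["reductive"] * len(ids),
            "lineage": ["unknown"] * len(ids),
        }
    )


class TestReadSequenceSet:
    def test_empty_inputs_give_empty_list(self, tmp_path):
        fasta = tmp_path / "empty.fasta"
        fasta.write_text("")
        records = read_sequence_set({"B": fasta}, _metadata([]))
        assert records == []

    def test_subunits_paired_by_record_id(self, tmp_path):
        fasta_b = tmp_path / "b.fasta"
        fasta_a = tmp_path / "a.fasta"
        _write_fasta(fasta_b, [("X_aprB", "MKV")])
        _write_fasta(fasta_a, [("X_aprA", "MDE")])
        records = read_sequence_set({"B": fasta_b, "A": fasta_a}, _metadata(["X"]))
        assert len(records) == 1
        rec = records[0]
        assert rec.record_id == "X"
        assert rec.seq_B == "MKV" and rec.seq_A == "MDE"
        assert rec.role == "reductive"

    def test_missing_metadata_warns_and_defaults_unknown(self, tmp_path):
        fasta = tmp_path / "b.fasta"
        _write_fasta(fasta, [("Y_aprB", "MKV")])
        with pytest.warns(UserWarning, match="missing from metadata"):
            records = read_sequence_set({"B": fasta}, _metadata([]))
        assert records[0].role == "unknown"
        assert records[0].lineage == "unknown"

    def test_duplicate_record_id_is_hard_error(self, tmp_path):
        fasta = tmp_path / "b.fasta"
        _write_fasta(fasta, [("X_aprB", "MKV"), ("X_aprB", "MKL")])
        with pytest.raises(ValueError, match="duplicate"):
            read_sequence_set({"B": fasta}, _metadata(["X"]))


class TestPartition:
    def _record(self, rid, len_b, len_a):
        return MarkerRecord(
            record_id=rid,
            seq_B="A" * len_b if len_b else None,
            seq_A="A" * len_a if len_a else None,
        )

    def test_boundary_lengths_use_strict_inequality(self):
        # AprB of exactly 101 residues does not qualify ("more than 101")
        rec = self._record("x", 101, 600)
        part = partition_sequence_set([rec])
        assert part.shorter == ("x",)

    def test_apra_only_record_above_shorter_threshold(self):
        rec = self._record("y", 0, 119)
        part = partition_sequence_set([rec])
        assert part.shorter == ("y",)

    def test_partition_is_total_and_disjoint(self, rng):
        records = [
            self._record(f"r{i}", int(rng.integers(0, 200)), int(rng.integers(1, 700)))
            for i in range(50)
        ]
        part = partition_sequence_set(records)
        buckets = [set(part.core), set(part.shorter), set(part.rejected)]
        assert sum(len(b) for b in buckets) == 50
        assert set.union(*buckets) == {r.record_id for r in records}
        for rid in part.core:
            rec = next(r for r in records if r.record_id == rid)
            assert rec.subunit_length("B") > 101 and rec.subunit_length("A") > 554

    def test_gaps_ignored_in_lengths(self):
        rec = MarkerRecord(record_id="g", seq_B="A-" * 102, seq_A="A." * 600)
        part = partition_sequence_set([rec])
        assert part.core == ("g",)

    def test_nonpositive_thresholds_rejected(self):
        with pytest.raises(ValueError):
            partition_sequence_set([self._record("x", 10, 10)], (0, 5, 5))


class TestConcatenateAndMask:
    def test_lengths_add_and_boundary_recorded(self):
        b = ReferenceAlignment([("x", "A" * 10), ("y", "C" * 10)], 10, frozenset(range(10)), "B")
        a = ReferenceAlignment([("x", "D" * 20), ("y", "E" * 20)], 20, frozenset(range(20)), "A")
        cat = concatenate_subunits(b, a)
        assert cat.n_columns == 30
        assert cat.boundary == 10

    def test_record_missing_one_subunit_is_excluded(self):
        b = ReferenceAlignment([("x", "AAAA")], 4, frozenset(range(4)), "B")
        a = ReferenceAlignment([("x", "DDDD"), ("z", "EEEE")], 4, frozenset(range(4)), "A")
        cat = concatenate_subunits(b, a)
        assert cat.ids == ["x"]
        assert cat.excluded_ids == ("z",)

    def test_no_shared_ids_is_error(self):
        b = ReferenceAlignment([("x", "AAAA")], 4, frozenset(range(4)), "B")
        a = ReferenceAlignment([("z", "EEEE")], 4, frozenset(range(4)), "A")
        with pytest.raises(ValueError, match="shared"):
            concatenate_subunits(b, a)

    def test_single_gap_removes_single_column(self):
        aln = ReferenceAlignment(
            [("a", "ACDE"), ("b", "AC-E"), ("c", "ACDE")],
            4, frozenset(range(4)), "A",
        )
        masked = mask_incomplete_columns(aln)
        assert masked.mask == frozenset({0, 1, 3})

    def test_gapless_alignment_keeps_all_columns(self):
        aln = ReferenceAlignment([("a", "ACDE"), ("b", "ACDF")], 4, frozenset(range(4)), "A")
        assert mask_incomplete_columns(aln).mask == frozenset(range(4))

    def test_masking_is_idempotent(self):
        aln = ReferenceAlignment(
            [("a", "AC-EX"), ("b", "ACDE.")], 5, frozenset(range(5)), "A"
        )
        once = mask_incomplete_columns(aln)
        twice = mask_incomplete_columns(once)
        assert once.mask == twice.mask

    def test_x_is_missing_by_default_but_configurable(self):
        aln = ReferenceAlignment([("a", "AXDE"), ("b", "ACDE")], 4, frozenset(range(4)), "A")
        assert 1 not in mask_incomplete_columns(aln).mask
        assert 1 in mask_incomplete_columns(aln, treat_x_as_missing=False).mask

    def test_all_columns_gapped_is_error(self):
        aln = ReferenceAlignment([("a", "--"), ("b", "AA")], 2, frozenset(range(2)), "A")
        with pytest.raises(ValueError, match="comparable"):
            mask_incomplete_columns(aln)

    def test_concat_then_mask_equals_mask_then_concat(self, rng):
        from conftest import random_protein

        def noisy(seq):
            out = list(seq)
            for i in range(len(out)):
                if rng.random() < 0.1:
                    out[i] = "-"
            return "".join(out)

        ids = [f"r{i}" for i in range(6)]
        rows_b = [(i, noisy(random_protein(rng, 12))) for i in ids]
        rows_a = [(i, noisy(random_protein(rng, 20))) for i in ids]
        b = ReferenceAlignment(rows_b, 12, frozenset(range(12)), "B")
        a = ReferenceAlignment(rows_a, 20, frozenset(range(20)), "A")
        mask_after = mask_incomplete_columns(concatenate_subunits(b, a)).mask
        mb = mask_incomplete_columns(b).mask
        ma = mask_incomplete_columns(a).mask
        assert mask_after == mb | {c + 12 for c in ma}

    def test_masked_widths_reported_per_subunit(self):
        b = ReferenceAlignment([("x", "AA-A")], 4, frozenset(range(4)), "B")
        a = ReferenceAlignment([("x", "CC")], 2, frozenset(range(2)), "A")
        masked = mask_incomplete_columns(concatenate_subunits(b, a))
        assert masked_widths(masked) == (3, 2)

    def test_roundtrip_masked_fasta(self, tmp_path):
        aln = ReferenceAlignment(
            [("a", "AC-E"), ("b", "ACDE")], 4, frozenset(range(4)), "A"
        )
        masked = mask_incomplete_columns(aln)
        path = tmp_path / "masked.fasta"
        refset.write_masked_fasta(masked, path)
        back = refset.read_alignment_fasta(path, "A")
        assert dict(back.rows) == masked.masked_rows()


def test_alignment_from_records_requires_equal_lengths():
    recs = [
        MarkerRecord(record_id="a", seq_A="MKV"),
        MarkerRecord(record_id="b", seq_A="MKVV"),
    ]
    with pytest.raises(ValueError, match="not aligned"):
        alignment_from_records(recs, "A")
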