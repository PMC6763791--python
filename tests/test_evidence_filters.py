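"""Unique-peptide floor, frequency filter, and curated-table assembly."""

import copy

import pytest

from baitcall.enrichment import EnrichmentRecord
from baitcall.errors import DataError
from baitcall.evidence_filters import (
    filter_frequency,
    filter_min_peptides,
    finalize_calls,
    make_calls,
)


def record(acc, ratio=None, exclusive=False, peptides=3):
    return EnrichmentRecord(
        accession=acc,
        mean_bait=5000.0,
        mean_control=0.0 if exclusive else 5000.0 / (ratio or 1.0),
        ratio=None if exclusive else ratio,
        log2_ratio=None,
        exclusive=exclusive,
        passes_floor=True,
        unique_peptides=peptides,
    )


def seed_calls(spec):
    """spec: list of (acc, class, peptides, ratio, exclusive)."""
    classes = {acc: cls for acc, cls, *_ in spec}
    records = [
        record(acc, ratio=ratio, exclusive=excl, peptides=pep)
        for acc, _, pep, ratio, excl in spec
    ]
    return make_calls(classes, records), records


class TestPeptideFilter:
    def test_single_peptide_specific_rejected(self):
        calls, _ = seed_calls([("P1", "specific", 1, 10.0, False)])
        filter_min_peptides(calls)
        assert not calls[0].kept
        assert calls[0].reject_reason == "insufficient_peptides"

    def test_two_peptides_kept(self):
        calls, _ = seed_calls([("P1", "specific", 2, 10.0, False)])
        filter_min_peptides(calls)
        assert calls[0].kept

    def test_disabled_filter(self):
        calls, _ = seed_calls([("P1", "specific", 1, 10.0, False)])
        filter_min_peptides(calls, min_unique_peptides=0)
        assert calls[0].kept


class TestFrequencyFilter:
    def test_ubiquitous_contaminant_rejected(self):
        calls, _ = seed_calls([("P1", "specific", 5, 10.0, False)])
        filter_frequency(calls, {"P1": 1.0})
        assert not calls[0].kept and calls[0].reject_reason == "frequent_flyer"

    def test_absent_accession_retained(self):
        calls, _ = seed_calls([("P1", "specific", 5, 10.0, False)])
        filter_frequency(calls, {"OTHER": 1.0})
        assert calls[0].kept

    def test_no_library_is_noop(self):
        calls, _ = seed_calls([("P1", "specific", 5, 10.0, False)])
        filter_frequency(calls, None)
        assert calls[0].kept

    def test_invalid_frequency(self):
        calls, _ = seed_calls([("P1", "specific", 5, 10.0, False)])
        with pytest.raises(DataError):
            filter_frequency(calls, {"P1": 1.5})

    def test_kept_set_matches_comprehension_oracle(self):
        import numpy as np

        rng = np.random.default_rng(5)
        accs = [f"P{i}" for i in range(50)]
        lib = {a: float(rng.uniform(0, 1)) for a in accs}
        spec = [(a, "specific", 3, 10.0, False) for a in accs]
        calls, _ = seed_calls(spec)
        filter_frequency(calls, lib, max_frequency=0.5)
        kept = {c.accession for c in calls if c.kept}
        oracle = {a for a in accs if lib[a] <= 0.5}
        assert kept == oracle


class TestFilterComposition:
    def test_order_independence_of_kept_set(self):
        spec = [
            ("A", "specific", 1, 10.0, False),
            ("B", "specific", 5, 9.0, False),
            ("C", "exclusive", 2, None, True),
            ("D", "borderline", 4, 2.0, False),
            ("E", "unspecific", 8, 1.0, False),
        ]
        lib = {"B": 0.9, "C": 0.1}
        calls1, _ = seed_calls(spec)
        filter_min_peptides(calls1)
        filter_frequency(calls1, lib)
        calls2, _ = seed_calls(spec)
        filter_frequency(calls2, lib)
        filter_min_peptides(calls2)
        assert {c.accession: c.kept for c in calls1} == {
            c.accession: c.kept for c in calls2
        }

    def test_every_rejected_call_has_one_reason(self):
        spec = [
            ("A", "specific", 1, 10.0, False),
            ("B", "unspecific", 5, 1.0, False),
            ("C", "borderline", 1, 2.0, False),
        ]
        calls, _ = seed_calls(spec)
        filter_min_peptides(calls)
        filter_frequency(calls, {"A": 1.0})
        for c in calls:
            if not c.kept:
                assert isinstance(c.reject_reason, str)

    def test_borderline_keep_flag(self):
        spec = [("D", "borderline", 4, 2.0, False)]
        classes = {"D": "borderline"}
        records = [record("D", ratio=2.0, peptides=4)]
        rejected = make_calls(classes, records, keep_borderline=False)
        kept = make_calls(classes, records, keep_borderline=True)
        assert not rejected[0].kept and rejected[0].reject_reason == "borderline_excluded"
        assert kept[0].kept


class TestFinalize:
    def test_ordering_bait_exclusives_then_ratio(self):
        spec = [
            ("BAIT", "specific", 16, 845.0, False),
            ("EXC1", "exclusive", 2, None, True),
            ("EXC2", "exclusive", 4, None, True),
            ("LOW", "specific", 2, 3.6, False),
            ("HIGH", "specific", 19, 12388.6, False),
        ]
        calls, records = seed_calls(spec)
        filter_min_peptides(calls)
        rows = finalize_calls(calls, records, bait_accession="BAIT")
        assert [r["accession"] for r in rows] == ["BAIT", "EXC1", "EXC2", "HIGH", "LOW"]
        assert rows[1]["exclusive"] and not rows[3]["exclusive"]

    def test_empty_kept_set_bait_only(self):
        spec = [("BAIT", "specific", 16, 845.0, False), ("X", "unspecific", 5, 1.0, False)]
        calls, records = seed_calls(spec)
        rows = finalize_calls(calls, records, bait_accession="BAIT")
        assert [r["accession"] for r in rows] == ["BAIT"]

    def test_truth_recovery_on_spikein(self, spikein_dataset):
        from baitcall import analyze_quant_table

        _, table, truth = spikein_dataset
        result = analyze_quant_table(table)
        kept = result.kept_accessions
        expected = set(truth.of_label("interactor")) | set(truth.of_label("exclusive"))
        assert expected <= kept  # full sensitivity under separation assumptions
        n_exclusive_rows = sum(r["exclusive"] for r in result.rows)
        assert n_exclusive_rows == len(truth.of_label("exclusive"))
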