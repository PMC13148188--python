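"""Table-space enumeration, per-N classification and tallies."""

from collections import Counter
from math import comb

import pytest

from fragility.engine import Evaluability, Mechanism, Status
from fragility.enumeration import (
    MarginPCache,
    classify_range,
    classify_tables,
    enumerate_tables,
    mechanism_tally,
    min_cell_tally,
    read_records_csv,
    write_records_csv,
    write_summary_csv,
)
from fragility.fisher import two_sided_p
from fragility.tables import ContingencyTable

from .conftest import all_nondegenerate


class TestEnumerateTables:
    def test_n2_has_exactly_the_two_diagonal_tables(self):
        assert [t.cells() for t in enumerate_tables(2)] == [(0, 1, 1, 0), (1, 0, 0, 1)]

    @pytest.mark.parametrize("n_total", [3, 4, 5, 8])
    def test_matches_brute_force_filter(self, n_total):
        ours = [t.cells() for t in enumerate_tables(n_total)]
        brute = sorted(all_nondegenerate(n_total))
        assert ours == brute

    @pytest.mark.parametrize("n_total", [2, 5, 10])
    def test_degenerate_complement_of_stars_and_bars(self, n_total):
        # raw quadruple count is C(N+3, 3); enumeration must drop only the
        # degenerate ones
        raw = comb(n_total + 3, 3)
        degenerate = sum(
            1
            for a in range(n_total + 1)
            for b in range(n_total - a + 1)
            for c in range(n_total - a - b + 1)
            if not (
                a + b > 0
                and (n_total - a - b) > 0
                and a + c > 0
                and (n_total - a - c) > 0
            )
        )
        assert len(list(enumerate_tables(n_total))) == raw - degenerate

    def test_rejects_tiny_n(self):
        with pytest.raises(ValueError):
            list(enumerate_tables(1))


class TestClassify:
    def test_first_unattainable_cases_appear_at_n18(self):
        _, summaries = classify_range(2, 18)
        below = [s for s in summaries if s.n_total < 18]
        assert all(s.unattainable == 0 for s in below)
        last = summaries[-1]
        assert (last.total_significant, last.attainable, last.unattainable, last.ties_excluded) == (
            324,
            314,
            2,
            8,
        )

    def test_partition_of_the_table_space(self):
        """Every nondegenerate table lands in exactly one class."""
        n_total = 14
        records, row = classify_tables(n_total)
        n_tables = len(list(enumerate_tables(n_total)))
        not_significant = n_tables - row.total_significant
        assert (
            not_significant + row.ties_excluded + row.attainable + row.unattainable == n_tables
        )
        assert row.total_significant == row.attainable + row.unattainable + row.ties_excluded
        assert len(records) == row.total_significant

    def test_records_sorted_and_consistent(self):
        records, _ = classify_tables(12)
        cells = [r.table.cells() for r in records]
        assert cells == sorted(cells)
        for r in records:
            assert r.min_cell == min(r.table.cells())
            assert r.imbalance_ratio >= 1.0
            if r.evaluability is Evaluability.TIED_EVENTS:
                assert r.outcome is None
            else:
                assert r.outcome.status in (Status.ATTAINABLE, Status.NOT_ATTAINABLE)

    def test_counts_independent_of_cache_sharing(self):
        shared = MarginPCache()
        a = classify_tables(16, cache=shared)
        b = classify_tables(16)
        assert a[1] == b[1]
        assert [r.table for r in a[0]] == [r.table for r in b[0]]

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            classify_range(5, 4)
        with pytest.raises(ValueError):
            classify_range(1, 10)


class TestTallies:
    def test_no_legal_move_tables_have_zero_nonevents_in_selected_arm(self):
        records, _ = classify_range(18, 20)
        for r in records:
            if r.outcome is not None and r.outcome.mechanism is Mechanism.NO_LEGAL_MOVE:
                t = r.table
                selected_nonevents = t.b if t.a < t.c else t.d
                assert selected_nonevents == 0
                assert t.min_cell == 0

    def test_mechanisms_partition_the_unattainable(self):
        records, summaries = classify_range(18, 22)
        mech = mechanism_tally(records)
        assert sum(mech.values()) == sum(s.unattainable for s in summaries)

    def test_single_table_tally(self, counterexample_no_move):
        from fragility.engine import fragility_index
        from fragility.enumeration import TableRecord

        rec = TableRecord(
            table=counterexample_no_move,
            n_total=counterexample_no_move.n,
            p_baseline=two_sided_p(counterexample_no_move).p_two_sided,
            evaluability=Evaluability.EVALUABLE,
            outcome=fragility_index(counterexample_no_move),
            min_cell=0,
            imbalance_ratio=5.0,
        )
        mech = mechanism_tally([rec])
        assert mech[Mechanism.NO_LEGAL_MOVE] == 1
        assert mech.get(Mechanism.PATH_EXHAUSTED, 0) == 0

    def test_empty_input_gives_empty_tallies(self):
        assert min_cell_tally([]) == Counter()
        assert mechanism_tally([]) == Counter()


class TestCsvRoundTrip:
    def test_records_round_trip(self, tmp_path):
        records, _ = classify_range(16, 18)
        path = tmp_path / "records.csv"
        write_records_csv(records, path)
        back = read_records_csv(path)
        assert len(back) == len(records)
        for orig, re_read in zip(records, back):
            assert re_read.table == orig.table
            assert re_read.p_baseline == orig.p_baseline
            assert re_read.evaluability == orig.evaluability
            if orig.outcome is not None:
                assert re_read.outcome.status == orig.outcome.status
                assert re_read.outcome.mechanism == orig.outcome.mechanism
                assert re_read.outcome.fi == orig.outcome.fi

    def test_summary_and_records_are_byte_stable(self, tmp_path):
        records, summaries = classify_range(14, 16)
        paths = []
        for tag in ("first", "second"):
            s = tmp_path / f"summary-{tag}.csv"
            r = tmp_path / f"records-{tag}.csv"
            write_summary_csv(summaries, s)
            write_records_csv(records, r)
            paths.append((s.read_bytes(), r.read_bytes()))
        assert paths[0] == paths[1]
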