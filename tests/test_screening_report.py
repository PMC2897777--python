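"""Two-vector outcome aggregation: combined statuses, integer percentages, funnel."""

from decimal import ROUND_HALF_UP, Decimal

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isoclone.fixtures import FixtureSpec, random_cds
from isoclone.screening_report import (
    STATUS_PRECEDENCE,
    ScreeningRecord,
    combine_vectors,
    funnel,
    integer_percent,
    tabulate,
)

# Published per-domain/per-vector count cells of the 192-target campaign
# (columns: eukarya pFO4, eukarya pGEX, bacteria pFO4, bacteria pGEX,
# archaea pFO4, archaea pGEX, total pFO4, total pGEX, combined).
SOLUBLE_CELLS = [14, 13, 13, 25, 18, 26, 45, 64, 84]
INSOLUBLE_CELLS = [10, 19, 4, 5, 12, 24, 26, 48, 34]
SOLUBLE_PCT = [7, 7, 7, 13, 9, 14, 23, 33, 44]
SOL_INSOL_PCT = [13, 17, 9, 16, 16, 26, 37, 58, 61]


def _rec(tid, v, s):
    return ScreeningRecord(tid, v, s)


class TestCombineVectors:
    @pytest.mark.parametrize(
        "pair,expected",
        [(("soluble", "insoluble"), "soluble"),
         (("no_clone", "no_clone"), "no_clone"),
         (("insoluble", "no_expression"), "insoluble"),
         (("no_expression", "no_clone"), "no_expression"),
         (("not_screened", "soluble"), "soluble"),
         (("not_screened", "not_screened"), "no_clone")],
    )
    def test_precedence(self, pair, expected):
        records = [_rec("t", "pFO4", pair[0]), _rec("t", "pGEX-4T-1", pair[1])]
        assert combine_vectors(records) == expected

    def test_no_records_is_an_error(self):
        with pytest.raises(ValueError):
            combine_vectors([])

    @settings(max_examples=200, derandomize=True)
    @given(
        a=st.sampled_from(STATUS_PRECEDENCE),
        b=st.sampled_from(STATUS_PRECEDENCE),
    )
    def test_upgrading_one_record_never_lowers_combined(self, a, b):
        rank = {s: i for i, s in enumerate(STATUS_PRECEDENCE)}
        base = combine_vectors([_rec("t", "pFO4", a), _rec("t", "pGEX-4T-1", b)])
        for better in STATUS_PRECEDENCE[: rank[a]]:
            upgraded = combine_vectors([_rec("t", "pFO4", better), _rec("t", "pGEX-4T-1", b)])
            assert rank[upgraded] <= rank[base]


class TestIntegerPercent:
    @pytest.mark.parametrize(
        "count,total,pct",
        [(84, 192, 44), (24, 192, 13), (0, 192, 0), (192, 192, 100),
         (174, 183, 95), (118, 174, 68), (84, 118, 71)],
    )
    def test_campaign_cells(self, count, total, pct):
        assert integer_percent(count, total) == pct

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            integer_percent(1, 0)

    @settings(max_examples=300, derandomize=True)
    @given(count=st.integers(0, 1000), total=st.integers(1, 1000))
    def test_matches_decimal_half_up_oracle(self, count, total):
        oracle = int(
            (Decimal(100 * count) / Decimal(total)).quantize(Decimal(1), rounding=ROUND_HALF_UP)
        )
        assert integer_percent(count, total) == oracle


def _table2_marginal_fixture():
    """192 targets whose per-vector status counts equal the published cells.

    Domain sizes are 74/32/86; the archaea columns (which the published
    per-vector sums leave short of the domain size) are padded with
    not_screened.
    """
    per_vector = {
        ("eukarya", "pFO4"): (14, 10, 42, 8),
        ("eukarya", "pGEX-4T-1"): (13, 19, 37, 5),
        ("bacteria", "pFO4"): (13, 4, 11, 4),
        ("bacteria", "pGEX-4T-1"): (25, 5, 2, 0),
        ("archaea", "pFO4"): (18, 12, 31, 9),
        ("archaea", "pGEX-4T-1"): (26, 24, 11, 12),
    }
    sizes = {"eukarya": 74, "bacteria": 32, "archaea": 86}
    targets, records = [], []
    k = 0
    for domain, size in sizes.items():
        tids = []
        for _ in range(size):
            targets.append(
                random_cds(FixtureSpec(seed=500 + k, n_codons=60, domain_of_life=domain,
                                       id=f"m{k:03d}"))
            )
            tids.append(f"m{k:03d}")
            k += 1
        for vector in ("pFO4", "pGEX-4T-1"):
            counts = per_vector[(domain, vector)]
            statuses = (["soluble"] * counts[0] + ["insoluble"] * counts[1]
                        + ["no_expression"] * counts[2] + ["no_clone"] * counts[3])
            statuses += ["not_screened"] * (size - len(statuses))
            records.extend(_rec(tid, vector, s) for tid, s in zip(tids, statuses))
    return targets, records


@pytest.fixture(scope="module")
def table2():
    targets, records = _table2_marginal_fixture()
    return tabulate(records, targets)


class TestTabulate:
    def test_reproduces_published_soluble_percent_row(self, table2):
        cols = [("eukarya", "pFO4"), ("eukarya", "pGEX-4T-1"),
                ("bacteria", "pFO4"), ("bacteria", "pGEX-4T-1"),
                ("archaea", "pFO4"), ("archaea", "pGEX-4T-1"),
                ("Total", "pFO4"), ("Total", "pGEX-4T-1")]
        row = table2.percentages.loc["percentage of soluble proteins"]
        assert [int(row[c]) for c in cols] == SOLUBLE_PCT[:8]

    def test_reproduces_published_soluble_plus_insoluble_row(self, table2):
        cols = [("eukarya", "pFO4"), ("eukarya", "pGEX-4T-1"),
                ("bacteria", "pFO4"), ("bacteria", "pGEX-4T-1"),
                ("archaea", "pFO4"), ("archaea", "pGEX-4T-1"),
                ("Total", "pFO4"), ("Total", "pGEX-4T-1")]
        row = table2.percentages.loc["percentage of soluble + insoluble proteins"]
        assert [int(row[c]) for c in cols] == SOL_INSOL_PCT[:8]

    def test_per_vector_counts_conserve_total(self, table2):
        for vector in ("pFO4", "pGEX-4T-1"):
            assert table2.counts[("Total", vector)].sum() == 192
        assert table2.counts[("Total", "combined")].sum() == 192

    def test_all_soluble_gives_100_percent(self):
        targets = [random_cds(FixtureSpec(seed=700 + k, n_codons=60, id=f"s{k}"))
                   for k in range(4)]
        records = [_rec(t.id, v, "soluble") for t in targets for v in ("pFO4", "pGEX-4T-1")]
        table = tabulate(records, targets)
        assert int(table.percentages.loc["percentage of soluble proteins", ("Total", "pFO4")]) == 100

    def test_record_order_does_not_matter(self):
        targets, records = _table2_marginal_fixture()
        forward = tabulate(records, targets)
        backward = tabulate(records[::-1], targets)
        assert forward.counts.equals(backward.counts)

    def test_unknown_target_rejected(self):
        targets = [random_cds(FixtureSpec(seed=800, n_codons=60, id="known"))]
        with pytest.raises(ValueError, match="ghost"):
            tabulate([_rec("ghost", "pFO4", "soluble")], targets)


class TestFunnel:
    def test_published_stage_efficiencies(self):
        df = funnel({"selected": 192, "amplified": 183, "cloned": 174,
                     "expressed": 118, "soluble": 84})
        by_stage = df.set_index("stage")["percent_of_previous"]
        assert by_stage["amplified"] == 95  # 183/192
        assert by_stage["cloned"] == 95     # 174/183
        assert by_stage["expressed"] == 68  # 118/174
        assert by_stage["soluble"] == 71    # 84/118

    def test_increasing_stage_warns_not_fails(self):
        with pytest.warns(UserWarning, match="exceeds"):
            df = funnel({"cloned": 100, "recovered": 102})
        assert df["count"].tolist() == [100, 102]

    def test_empty_mapping_rejected(self):
        with pytest.raises(ValueError):
            funnel({})
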