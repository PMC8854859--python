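import numpy as np
import pandas as pd
import pytest

from rrsemen.qc import (QCConfig, QCError, RecordParseError, SchemaError,
                        apply_qc, derive_columns, parse_records)


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestParseRecords:
    def test_two_row_csv(self, tmp_path):
        p = write(tmp_path, "r.csv",
                  "boar,date,center,vol\nB1,2018-01-02,C1,250\nB1,2018-01-09,C1,260\n")
        rt = parse_records(p)
        assert len(rt) == 2
        assert rt["vol"].tolist() == [250.0, 260.0]

    def test_malformed_number_names_row_and_column(self, tmp_path):
        p = write(tmp_path, "r.csv",
                  "boar,date,center,vol\nB1,2018-01-02,C1,abc\n")
        with pytest.raises(RecordParseError, match=r"row 0.*vol.*abc"):
            parse_records(p)

    def test_unparseable_date_reported(self, tmp_path):
        p = write(tmp_path, "r.csv",
                  "boar,date,center,vol\nB1,not-a-date,C1,250\n")
        with pytest.raises(RecordParseError, match="date"):
            parse_records(p)

    def test_missing_required_column(self, tmp_path):
        p = write(tmp_path, "r.csv", "date,center,vol\n2018-01-02,C1,250\n")
        with pytest.raises(SchemaError, match="boar"):
            parse_records(p)

    def test_age_weeks_schema_leaves_intervals_undefined(self, tmp_path):
        p = write(tmp_path, "r.csv",
                  "boar,age_weeks,center,vol\n"
                  "B1,40,C1,250\nB1,41,C1,255\nB2,50,C1,260\n"
                  "B2,52,C1,240\nB2,53,C1,230\n")
        rt = derive_columns(parse_records(p))
        assert rt["interval_days"].isna().all()

    def test_both_date_and_age_rejected(self, tmp_path):
        p = write(tmp_path, "r.csv",
                  "boar,date,age_weeks,center,vol\nB1,2018-01-02,40,C1,250\n")
        with pytest.raises(SchemaError, match="exactly one"):
            parse_records(p)

    def test_schema_mapping(self, tmp_path):
        p = write(tmp_path, "r.tsv",
                  "id\twhen\tstation\tvolume\nB1\t2018-01-02\tC1\t250\n")
        rt = parse_records(p, {"boar": "id", "date": "when",
                               "center": "station", "vol": "volume"})
        assert rt.loc[0, "boar"] == "B1"


class TestDeriveColumns:
    def test_interval_sequence(self, tmp_path):
        p = write(tmp_path, "r.csv",
                  "boar,date,center,vol\n"
                  "B1,2018-01-01,C1,250\nB1,2018-01-08,C1,250\nB1,2018-01-17,C1,250\n")
        rt = derive_columns(parse_records(p))
        assert rt["interval_days"].tolist()[1:] == [7, 9]
        assert pd.isna(rt["interval_days"].iloc[0])

    def test_single_record_boar_interval_undefined(self, tmp_path):
        p = write(tmp_path, "r.csv",
                  "boar,date,center,vol\nB1,2018-01-01,C1,250\n")
        rt = derive_columns(parse_records(p))
        assert pd.isna(rt["interval_days"].iloc[0])

    def test_interleaved_boars_computed_within_boar(self, tmp_path):
        p = write(tmp_path, "r.csv", "boar,date,center,vol\n"
                  "B1,2018-01-01,C1,250\nB2,2018-01-03,C1,250\n"
                  "B1,2018-01-06,C1,250\nB2,2018-01-10,C1,250\n"
                  "B1,2018-01-16,C1,250\nB2,2018-01-13,C1,250\n")
        rt = derive_columns(parse_records(p))
        b1 = rt[rt["boar"] == "B1"]["interval_days"].tolist()
        b2 = rt[rt["boar"] == "B2"]["interval_days"].tolist()
        assert b1[1:] == [5, 10] and pd.isna(b1[0])
        assert b2[1:] == [7, 3] and pd.isna(b2[0])

    def test_aiys_from_date(self, tmp_path):
        p = write(tmp_path, "r.csv",
                  "boar,date,center,vol\nB1,2018-03-02,C7,250\n")
        rt = derive_columns(parse_records(p))
        assert rt.loc[0, "aiys"] == "C7|2018|3"

    def test_duplicate_boar_date_error(self, tmp_path):
        p = write(tmp_path, "r.csv", "boar,date,center,vol\n"
                  "B1,2018-01-01,C1,250\nB1,2018-01-01,C1,260\n")
        with pytest.raises(QCError, match="duplicate"):
            derive_columns(parse_records(p))

    def test_birthdates_give_age(self, tmp_path):
        p = write(tmp_path, "r.csv",
                  "boar,date,center,vol\nB1,2018-01-01,C1,250\n")
        rt = derive_columns(parse_records(p), {"B1": "2017-01-02"})
        assert rt.loc[0, "age_weeks"] == (pd.Timestamp("2018-01-01")
                                          - pd.Timestamp("2017-01-02")).days // 7


def derived_row(boar, age, vol=250.0, aiys="C1|2018|1", iclass=7,
                interval=7.0, **extra):
    row = dict(boar=boar, age_weeks=float(age), center="C1", aiys=aiys,
               interval_days=interval, interval_class=iclass, vol=vol)
    row.update(extra)
    return row


class TestApplyQC:
    def test_trait_range_removal(self):
        rows = [derived_row("B1", 50 + i, vol=250) for i in range(8)]
        rows.append(derived_row("B1", 60, vol=650.0))
        rt = pd.DataFrame(rows)
        out, rep = apply_qc(rt, QCConfig(min_records_per_fixed_level=1))
        assert rep.removed["trait_range_vol"] == 1
        assert len(out) == 8

    def test_trait_range_is_closed(self):
        rows = [derived_row("B1", 50 + i, vol=v)
                for i, v in enumerate([100.0, 600.0, 250, 250, 250, 250])]
        out, rep = apply_qc(pd.DataFrame(rows),
                            QCConfig(min_records_per_fixed_level=1))
        assert rep.removed["trait_range_vol"] == 0

    def test_boar_below_minimum_fully_removed(self):
        rows = ([derived_row("B1", 50 + i) for i in range(5)]
                + [derived_row("B2", 50 + i) for i in range(7)])
        out, rep = apply_qc(pd.DataFrame(rows),
                            QCConfig(min_records_per_fixed_level=1))
        assert set(out["boar"]) == {"B2"}
        assert rep.removed["min_ejaculates_per_boar"] == 5

    def test_undefined_or_out_of_range_interval_removed(self):
        rows = [derived_row("B1", 50, interval=np.nan, iclass=None)]
        rows += [derived_row("B1", 51 + i) for i in range(6)]
        rows += [derived_row("B1", 60, interval=45.0, iclass=45)]
        out, rep = apply_qc(pd.DataFrame(rows),
                            QCConfig(min_records_per_fixed_level=1))
        assert rep.removed["first_record_or_interval"] == 2
        assert len(out) == 6

    def test_cascade_fixture_reaches_fixed_point(self):
        # 40 rows: aiys level Y holds 9 records (below the 10 minimum).
        # Removing Y leaves B1 with 5 < 6 records, so a second pass drops
        # all of B1. Hand-computed survivors: B2 (10) + B3 (8) + B5 (8) = 26.
        rows = []
        rows += [derived_row("B1", 40 + i, aiys="X") for i in range(5)]
        rows += [derived_row("B1", 50 + i, aiys="Y") for i in range(2)]
        rows += [derived_row("B2", 40 + i, aiys="X") for i in range(10)]
        rows += [derived_row("B3", 40 + i, aiys="X") for i in range(8)]
        rows += [derived_row("B4", 40 + i, aiys="Y") for i in range(7)]
        rows += [derived_row("B5", 40 + i, aiys="X") for i in range(8)]
        rt = pd.DataFrame(rows)
        assert len(rt) == 40
        out, rep = apply_qc(rt, QCConfig())
        assert len(out) == 26
        assert set(out["boar"]) == {"B2", "B3", "B5"}
        assert rep.removed["fixed_level_count_aiys"] == 9
        assert rep.removed["min_ejaculates_per_boar"] == 5
        assert rep.passes >= 2

    def test_idempotence(self):
        rows = ([derived_row("B1", 40 + i) for i in range(12)]
                + [derived_row("B2", 40 + i) for i in range(12)])
        out1, _ = apply_qc(pd.DataFrame(rows), QCConfig())
        out2, rep2 = apply_qc(out1, QCConfig())
        assert len(out2) == len(out1)
        assert sum(rep2.removed.values()) == 0

    def test_attribution_sums_to_input(self):
        rng = np.random.default_rng(0)
        rows = [derived_row(f"B{rng.integers(6)}", rng.integers(20, 180),
                            vol=float(rng.normal(300, 150)),
                            aiys=f"L{rng.integers(3)}",
                            iclass=int(rng.integers(1, 40)),
                            interval=float(rng.integers(1, 40)))
                for _ in range(300)]
        rt = pd.DataFrame(rows)
        try:
            out, rep = apply_qc(rt, QCConfig(min_ejaculates_per_boar=3,
                                             min_records_per_fixed_level=4))
            n_out = len(out)
        except QCError:
            return
        assert sum(rep.removed.values()) + n_out == len(rt)

    @pytest.mark.parametrize("relax", [
        dict(age_min=20.0), dict(age_max=200.0), dict(interval_max=40),
        dict(min_ejaculates_per_boar=2), dict(min_records_per_fixed_level=1),
        dict(trait_ranges={"vol": (0.0, 1000.0), "mot": (10.0, 100.0),
                           "con": (0.1, 8.0), "abn": (0.01, 100.0)})])
    def test_relaxing_bounds_is_monotone(self, relax):
        rng = np.random.default_rng(3)
        rows = [derived_row(f"B{rng.integers(8)}", rng.integers(25, 170),
                            vol=float(rng.normal(300, 120)),
                            aiys=f"L{rng.integers(2)}",
                            iclass=int(rng.integers(1, 35)),
                            interval=float(rng.integers(1, 35)))
                for _ in range(400)]
        rt = pd.DataFrame(rows)
        base_cfg = QCConfig(min_ejaculates_per_boar=4,
                            min_records_per_fixed_level=5)
        out_base, _ = apply_qc(rt, base_cfg)
        relaxed = QCConfig(**{**dict(min_ejaculates_per_boar=4,
                                     min_records_per_fixed_level=5), **relax})
        out_relaxed, _ = apply_qc(rt, relaxed)
        assert len(out_relaxed) >= len(out_base)

    def test_per_trait_independence(self):
        rows = [derived_row("B1", 40 + i, mot=50.0) for i in range(8)]
        rt = pd.DataFrame(rows)
        rt.loc[0, "mot"] = 5.0  # fails MOT range only
        out_vol, _ = apply_qc(rt, QCConfig(min_records_per_fixed_level=1),
                              trait="vol")
        out_mot, _ = apply_qc(rt, QCConfig(min_records_per_fixed_level=1),
                              trait="mot")
        assert len(out_vol) == 8
        assert len(out_mot) == 7

    def test_all_filtered_raises(self):
        rows = [derived_row("B1", 40 + i) for i in range(3)]
        with pytest.raises(QCError, match="all records filtered"):
            apply_qc(pd.DataFrame(rows), QCConfig())
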