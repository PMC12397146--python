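"""Reading, writing and validating the CSV interchange formats."""

import datetime as dt
import textwrap

import numpy as np
import pytest

import limnotrends as lt
from limnotrends.io import validate_dataset, write_dataset, read_dataset


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(textwrap.dedent(text))
    return path


class TestReadProfiles:
    def test_single_date_three_depths(self, tmp_path):
        path = _write(
            tmp_path,
            "p.csv",
            """\
            date,depth_m,temp_c
            2001-05-01,0,15.2
            2001-05-01,12,7.1
            2001-05-01,24,4.4
            """,
        )
        profiles = lt.read_profiles(path)
        assert len(profiles) == 1
        assert profiles[0].date == dt.date(2001, 5, 1)
        np.testing.assert_allclose(profiles[0].depths, [0, 12, 24])
        np.testing.assert_allclose(profiles[0].analyte("temp_c"), [15.2, 7.1, 4.4])

    def test_interleaved_dates_are_grouped_and_depth_sorted(self, tmp_path):
        # asymmetric values guard against any depth/value reordering
        path = _write(
            tmp_path,
            "p.csv",
            """\
            date,depth_m,temp_c,o2_mg_l
            2001-05-01,24,4.0,1.5
            2001-06-01,0,18.0,9.9
            2001-05-01,0,15.0,9.0
            2001-06-01,24,4.5,0.5
            """,
        )
        profiles = lt.read_profiles(path)
        assert [p.date.month for p in profiles] == [5, 6]
        np.testing.assert_allclose(profiles[0].analyte("o2_mg_l"), [9.0, 1.5])
        np.testing.assert_allclose(profiles[1].analyte("o2_mg_l"), [9.9, 0.5])

    def test_duplicate_date_depth_pair_names_the_pair(self, tmp_path):
        path = _write(
            tmp_path,
            "p.csv",
            """\
            date,depth_m,temp_c
            2001-05-01,12,7.1
            2001-05-01,12,7.3
            """,
        )
        with pytest.raises(lt.ValidationError, match="2001-05-01.*12"):
            lt.read_profiles(path)

    def test_missing_mandatory_column(self, tmp_path):
        path = _write(tmp_path, "p.csv", "date,temp_c\n2001-05-01,15.0\n")
        with pytest.raises(lt.SchemaError, match="depth_m"):
            lt.read_profiles(path)

    def test_unparseable_rows_reported_not_silent(self, tmp_path):
        path = _write(
            tmp_path,
            "p.csv",
            """\
            date,depth_m,temp_c
            2001-05-01,0,15.0
            not-a-date,12,7.0
            2001-05-01,24,4.4
            """,
        )
        with pytest.warns(UserWarning, match="unparseable"):
            profiles = lt.read_profiles(path)
        assert profiles[0].depths.size == 2


class TestHypsographyIO:
    def test_cone_area_and_volume(self, tmp_path):
        path = _write(tmp_path, "h.csv", "depth_m,area_m2\n0,1000\n10,0\n")
        hyp = lt.read_hypsography(path)
        assert hyp.surface_area == 1000.0
        assert hyp.total_volume == pytest.approx(5000.0)

    def test_cylinder_volume(self, tmp_path):
        path = _write(tmp_path, "h.csv", "depth_m,area_m2\n0,1000\n10,1000\n")
        assert lt.read_hypsography(path).total_volume == pytest.approx(10_000.0)

    def test_increasing_area_rejected(self, tmp_path):
        path = _write(tmp_path, "h.csv", "depth_m,area_m2\n0,1000\n5,1200\n10,0\n")
        with pytest.raises(lt.ValidationError, match="non-monotone"):
            lt.read_hypsography(path)

    def test_missing_surface_row_rejected(self, tmp_path):
        path = _write(tmp_path, "h.csv", "depth_m,area_m2\n2,1000\n10,0\n")
        with pytest.raises(lt.ValidationError, match="surface"):
            lt.read_hypsography(path)


class TestDatasetRoundTrip:
    def test_write_then_read_reproduces_values(self, tmp_path):
        cfg = lt.GeneratorConfig(n_years=10)
        dataset, _ = lt.generate_dataset(cfg, seed=3)
        write_dataset(dataset, tmp_path)
        back = read_dataset(
            tmp_path / "profiles.csv",
            tmp_path / "hypsography.csv",
            tmp_path / "withdrawal.csv",
            tmp_path / "inflow.csv",
        )
        assert len(back.profiles) == len(dataset.profiles)
        for a, b in zip(dataset.profiles, back.profiles):
            assert a.date == b.date
            np.testing.assert_array_equal(a.depths, b.depths)
            for name in lt.ANALYTES:
                np.testing.assert_array_equal(a.analyte(name), b.analyte(name))
        np.testing.assert_array_equal(
            dataset.hypsography.areas, back.hypsography.areas
        )
        assert dataset.withdrawal == back.withdrawal
        assert dataset.inflow == back.inflow


class TestValidateDataset:
    def test_complete_dataset_has_no_issues(self):
        dataset, _ = lt.generate_dataset(lt.GeneratorConfig(n_years=10), seed=0)
        report = validate_dataset(dataset)
        assert report.ok
        assert all(not gaps for gaps in report.gap_years.values())

    def test_chlorophyll_gap_flagged_for_chla_only(self):
        dataset, _ = lt.generate_dataset(
            lt.GeneratorConfig(n_years=30, start_year=1975), seed=0
        )
        for p in dataset.profiles:
            if 1992 <= p.date.year <= 1997:
                p.values["chla_ug_l"][:] = np.nan
        report = validate_dataset(dataset)
        assert report.gap_years["chla_ug_l"] == [1992, 1993, 1994, 1995, 1996, 1997]
        for name in ("temp_c", "o2_mg_l", "tp_ug_l"):
            assert report.gap_years[name] == []

    def test_profile_deeper_than_basin_rejected(self):
        hyp = lt.Hypsography([0.0, 24.6], [1000.0, 0.0])
        profile = lt.DepthProfile(
            dt.date(2000, 6, 1), [0.0, 30.0], {"temp_c": [15.0, 4.0]}
        )
        with pytest.raises(lt.ValidationError, match="exceeds"):
            lt.LakeDataset(profiles=[profile], hypsography=hyp)
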