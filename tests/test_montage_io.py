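"""Montage integrity, impairment grouping, hemisphere remapping and I/O."""

import json

import numpy as np
import pytest

from nirswave.errors import DataQualityError, DomainError, FormatError, MontageError
from nirswave.montage_io import (
    REGIONS,
    Recording,
    StateInterval,
    SubjectMeta,
    assign_group,
    load_demographics,
    load_recording,
    remap_hemispheres,
    save_recording,
    validate_duration,
)
from nirswave.synthetic_data import SyntheticConfig, generate_subject

from conftest import quiet_config


class TestMontage:
    def test_fixture_counts(self, montage):
        layout, _ = montage
        assert layout.n_channels == 38
        assert len(layout.sources) == 18
        assert len(layout.detectors) == 16

    def test_every_region_on_both_hemispheres(self, montage):
        _, rmap = montage
        for hemi in ("left", "right"):
            regions = {r for h, r in rmap.assignments.values() if h == hemi}
            assert regions == set(REGIONS)

    def test_effective_labels_count(self, region_map_left):
        labels = set(region_map_left.effective_assignments.values())
        assert len(labels) == 14
        assert labels == set(region_map_left.effective_regions)


class TestAssignGroup:
    @pytest.mark.parametrize(
        "grade,expected",
        [(0, "severe"), (1, "severe"), (2, "moderate"), (3, "moderate"),
         (4, "mild"), (5, "mild")],
    )
    def test_grading_rule(self, grade, expected):
        assert assign_group(grade) == expected

    @pytest.mark.parametrize("grade", [-1, 6])
    def test_out_of_range(self, grade):
        with pytest.raises(DomainError):
            assign_group(grade)

    def test_cohort_table_grouping(self):
        """The packaged cohort table groups 10/15/8 under the stated rule."""
        df = load_demographics()
        counts = df["group"].value_counts()
        assert len(df) == 33
        assert counts["severe"] == 10
        assert counts["moderate"] == 15
        assert counts["mild"] == 8


class TestRemap:
    def test_lesion_left_motor(self, montage):
        _, rmap = montage
        left = remap_hemispheres(rmap, "left")
        ch = next(c for c, (h, r) in rmap.assignments.items()
                  if h == "left" and r == "M1")
        assert left.effective(ch) == "IM1"

    def test_lesion_right_sensory(self, montage):
        _, rmap = montage
        right = remap_hemispheres(rmap, "right")
        ch = next(c for c, (h, r) in rmap.assignments.items()
                  if h == "left" and r == "S1")
        assert right.effective(ch) == "CS1"

    def test_flip_is_involution(self, montage):
        """Remapping twice with flipped sides restores the partition."""
        _, rmap = montage
        left = remap_hemispheres(rmap, "left")
        right = remap_hemispheres(rmap, "right")
        for ch in rmap.channels:
            el, er = left.effective(ch), right.effective(ch)
            assert el[1:] == er[1:]  # region unchanged
            assert {el[0], er[0]} == {"I", "C"}  # prefixes swap
        # underlying anatomical assignment untouched
        assert left.assignments == rmap.assignments

    def test_partition_preserved(self, montage):
        _, rmap = montage
        left = remap_hemispheres(rmap, "left")
        n_by_region = {}
        for region in left.effective_regions:
            n_by_region[region] = len(left.channels_in(region))
        assert sum(n_by_region.values()) == 38


class TestValidateDuration:
    @pytest.mark.parametrize(
        "duration_s,expected",
        [(600.0, True), (400.0, False), (500.0, True)],
    )
    def test_five_cycle_rule(self, duration_s, expected):
        cfg = quiet_config(duration_s=duration_s, allow_short_states=True, seed=0)
        rec, _ = generate_subject(cfg, 0)
        report = validate_duration(rec, f_min_hz=0.01, min_cycles=5)
        assert report == {"rest": expected, "training": expected}

    def test_bad_f_min(self, default_subject):
        rec, _ = default_subject
        with pytest.raises(DomainError):
            validate_duration(rec, f_min_hz=0.0)


class TestRecordingIO:
    def test_tsv_round_trip(self, tmp_path, default_subject):
        rec, _ = default_subject
        path = save_recording(rec, tmp_path / "sub", format="tsv")
        back = load_recording(path, format="tsv")
        assert back.o2hb.shape == (38, rec.n_samples)
        np.testing.assert_allclose(back.o2hb, rec.o2hb, rtol=2e-5, atol=1e-5)
        np.testing.assert_allclose(back.hhb, rec.hhb, rtol=2e-5, atol=1e-5)
        assert back.meta == rec.meta
        assert back.state_intervals == rec.state_intervals

    def test_snirf_round_trip_exact(self, tmp_path, default_subject):
        rec, _ = default_subject
        path = save_recording(rec, tmp_path / "sub.snirf", format="snirf")
        back = load_recording(path, format="snirf")
        np.testing.assert_array_equal(back.o2hb, rec.o2hb)
        np.testing.assert_array_equal(back.hhb, rec.hhb)
        assert back.meta == rec.meta
        assert back.sample_rate_hz == rec.sample_rate_hz

    def test_missing_sidecar_field(self, tmp_path, default_subject):
        rec, _ = default_subject
        path = save_recording(rec, tmp_path / "sub", format="tsv")
        sidecar = path.with_suffix(".json")
        data = json.loads(sidecar.read_text())
        del data["state_intervals"]
        sidecar.write_text(json.dumps(data))
        with pytest.raises(FormatError):
            load_recording(path, format="tsv")

    def test_channel_mismatch(self, tmp_path, default_subject):
        rec, _ = default_subject
        path = save_recording(rec, tmp_path / "sub", format="tsv")
        sidecar = path.with_suffix(".json")
        data = json.loads(sidecar.read_text())
        data["channels"] = data["channels"][:-1]
        sidecar.write_text(json.dumps(data))
        with pytest.raises(MontageError):
            load_recording(path, format="tsv")

    def test_long_nan_run_rejected(self, tmp_path, default_subject):
        rec, _ = default_subject
        bad = Recording(
            sample_rate_hz=rec.sample_rate_hz,
            o2hb=rec.o2hb.copy(),
            hhb=rec.hhb.copy(),
            channel_names=rec.channel_names,
            state_intervals=rec.state_intervals,
            meta=rec.meta,
        )
        bad.o2hb[3, 1000:1030] = np.nan  # 3 s of dropout
        path = save_recording(bad, tmp_path / "bad", format="tsv")
        with pytest.raises(DataQualityError):
            load_recording(path, format="tsv", max_nan_run_s=1.0)


class TestRecordingValidation:
    def test_overlapping_states_rejected(self, default_subject):
        rec, _ = default_subject
        with pytest.raises(FormatError):
            Recording(
                sample_rate_hz=rec.sample_rate_hz,
                o2hb=rec.o2hb, hhb=rec.hhb,
                channel_names=rec.channel_names,
                state_intervals=(
                    StateInterval("rest", 0, 700),
                    StateInterval("training", 600, 1200),
                ),
                meta=rec.meta,
            )

    def test_meta_grade_range(self):
        with pytest.raises(DomainError):
            SubjectMeta("x", "left", "right", mmt_grade=7)
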