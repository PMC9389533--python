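"""Stream containers, dialects and the Vienna ground-truth mapping."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ttroi import (
    FrameRecord,
    FrameSeries,
    VideoMeta,
    collapse_frame,
    map_vienna_to_truth,
    read_detection_stream,
    read_metadata,
    write_detection_stream,
    write_metadata,
)
from ttroi.streams import LABELS, collapse_series

from conftest import series_of


class TestViennaMapping:
    @pytest.mark.parametrize(
        "category,expected",
        [("C1", "non_cancer"), ("C2", "non_cancer"), ("C3", "non_cancer"),
         ("C4", "cancer"), ("C5", "cancer")],
    )
    def test_partition(self, category, expected):
        assert map_vienna_to_truth(category) == expected

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="Vienna"):
            map_vienna_to_truth("C6")


class TestCollapse:
    @pytest.mark.parametrize(
        "labels,expected",
        [(["benign", "cancer"], "cancer"),
         (["background"], "background"),
         (["none", "benign"], "benign"),
         (["none", "background", "benign", "cancer"], "cancer")],
    )
    def test_priority_rule(self, labels, expected):
        assert collapse_frame(labels) == expected

    def test_empty_and_unknown(self):
        with pytest.raises(ValueError):
            collapse_frame([])
        with pytest.raises(ValueError, match="unknown label"):
            collapse_frame(["tumour"])

    def test_collapse_series_dedups_timestamps(self):
        s = FrameSeries("v", [1.0, 1.0, 2.0], ["benign", "cancer", "none"],
                        duration_s=5.0)
        c = collapse_series(s)
        assert list(c.t) == [1.0, 2.0]
        assert list(c.labels) == ["cancer", "none"]


class TestValidation:
    def test_record_rejects_bad_fields(self):
        with pytest.raises(ValueError):
            FrameRecord("v", -1.0, "cancer")
        with pytest.raises(ValueError):
            FrameRecord("v", 0.0, "cancer", confidence=1.5)
        with pytest.raises(ValueError, match="box"):
            FrameRecord("v", 0.0, "cancer", box=(0.8, 0.1, 0.5, 0.1))  # x+w>1

    def test_unsorted_input_sorted_with_warning(self):
        with pytest.warns(UserWarning, match="not sorted"):
            s = FrameSeries("v", [2.0, 1.0], ["cancer", "benign"], duration_s=3.0)
        assert list(s.t) == [1.0, 2.0]
        assert list(s.labels) == ["benign", "cancer"]

    def test_timestamps_beyond_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            FrameSeries("v", [0.0, 10.0], ["none", "none"], duration_s=5.0)

    def test_records_must_share_video_id(self):
        recs = [FrameRecord("a", 0.0, "none"), FrameRecord("b", 1.0, "none")]
        with pytest.raises(ValueError, match="several videos"):
            FrameSeries.from_records(recs)

    def test_meta_truth_consistency(self):
        with pytest.raises(ValueError, match="inconsistent"):
            VideoMeta("v", "inflammation", "C4")  # benign pathology, cancer Vienna
        with pytest.raises(ValueError, match="inconsistent"):
            VideoMeta("v", "EGC_diff", "C4", truth="non_cancer")
        meta = VideoMeta("v", "LGIN", "C3")
        assert meta.truth == "non_cancer"


# -- I/O --------------------------------------------------------------------

_series_strategy = st.builds(
    lambda n, seed: _random_series(n, seed),
    st.integers(min_value=1, max_value=40),
    st.integers(min_value=0, max_value=2**31 - 1),
)


def _random_series(n, seed):
    rng = np.random.default_rng(seed)
    t = np.sort(np.round(rng.uniform(0, 100, n), 3))
    labels = rng.choice(LABELS, n)
    conf = np.where(rng.random(n) < 0.5, np.round(rng.random(n), 4), np.nan)
    boxes = np.full((n, 4), np.nan)
    with_box = rng.random(n) < 0.5
    xy = rng.uniform(0, 0.5, (n, 2))
    wh = rng.uniform(0.05, 0.5, (n, 2))
    boxes[with_box] = np.hstack([xy, wh])[with_box]
    return FrameSeries("vid", t, labels, duration_s=101.0,
                       confidence=conf, boxes=boxes)


class TestStreamIO:
    @pytest.mark.parametrize("dialect,ext", [("jsonl", ".jsonl"), ("csv", ".csv")])
    @given(series=_series_strategy)
    def test_round_trip_identity(self, tmp_path_factory, dialect, ext, series):
        path = tmp_path_factory.mktemp("io") / f"s{ext}"
        write_detection_stream(series, path, dialect)
        back = read_detection_stream(path, dialect, duration_s=series.duration_s)
        assert back.equals(series)

    @given(series=_series_strategy)
    def test_dialect_equivalence(self, tmp_path_factory, series):
        d = tmp_path_factory.mktemp("io")
        write_detection_stream(series, d / "s.jsonl")
        write_detection_stream(series, d / "s.csv")
        a = read_detection_stream(d / "s.jsonl", duration_s=series.duration_s)
        b = read_detection_stream(d / "s.csv", duration_s=series.duration_s)
        assert a.equals(b)

    def test_jsonl_missing_field_names_line(self, tmp_path):
        path = tmp_path / "s.jsonl"
        path.write_text(
            '{"video_id": "v", "t": 0.0, "label": "none"}\n'
            '{"video_id": "v", "t": 0.033}\n'
        )
        with pytest.raises(ValueError, match="line 2.*label"):
            read_detection_stream(path)

    def test_unknown_label_rejected_with_line(self, tmp_path):
        path = tmp_path / "s.jsonl"
        path.write_text('{"video_id": "v", "t": 0.0, "label": "polyp"}\n')
        with pytest.raises(ValueError, match="line 1"):
            read_detection_stream(path)

    def test_empty_file_is_error(self, tmp_path):
        path = tmp_path / "s.jsonl"
        path.write_text("")
        with pytest.raises(ValueError, match="empty stream"):
            read_detection_stream(path)

    def test_refuse_to_write_empty(self, tmp_path):
        empty = FrameSeries("v", [], [], duration_s=0.0)
        with pytest.raises(ValueError, match="empty"):
            write_detection_stream(empty, tmp_path / "s.jsonl")

    def test_three_line_example(self, tmp_path):
        path = tmp_path / "s.jsonl"
        path.write_text(
            '{"video_id": "v", "t": 0.0, "label": "none"}\n'
            '{"video_id": "v", "t": 0.033, "label": "cancer"}\n'
            '{"video_id": "v", "t": 0.067, "label": "none"}\n'
        )
        s = read_detection_stream(path)
        assert len(s) == 3
        assert list(s.labels) == ["none", "cancer", "none"]


class TestMetadataIO:
    def test_round_trip_and_truth_derivation(self, tmp_path):
        metas = [
            VideoMeta("a", "EGC_diff", "C4", sex="male"),
            VideoMeta("b", "atrophy_IM", "C1", severity="mild", range="local"),
        ]
        path = tmp_path / "meta.csv"
        write_metadata(metas, path)
        back = read_metadata(path)
        assert back == metas

        # truth column omitted entirely → derived from Vienna
        no_truth = path.read_text().splitlines()
        header = no_truth[0].split(",")
        icol = header.index("truth")
        stripped = "\n".join(
            ",".join(v for i, v in enumerate(line.split(",")) if i != icol)
            for line in no_truth
        )
        path2 = tmp_path / "meta2.csv"
        path2.write_text(stripped + "\n")
        assert [m.truth for m in read_metadata(path2)] == ["cancer", "non_cancer"]
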