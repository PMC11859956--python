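"""AU table I/O, windowing, peak-segment selection and rating conversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from auaffect import (
    DataFormatError,
    DomainError,
    EmptyInputError,
    InsufficientCoverageError,
)
from auaffect.aucore import (
    AU_COLUMNS,
    AUFrame,
    AUWindow,
    ContinuousSession,
    MODEL_AUS,
    RatedEpisode,
    Rating,
    Scale,
    convert_rating,
    extract_window,
    invert_rating,
    read_au_table,
    select_peak_segment,
    write_au_table,
)
from conftest import make_frame, make_window


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

class TestTypes:
    def test_au_frame_requires_exactly_17_aus(self):
        with pytest.raises(DataFormatError, match="17 model AUs"):
            AUFrame(timestamp=0.0, intensities={1: 0.5})
        with pytest.raises(DataFormatError):
            bad = {a: 0.5 for a in MODEL_AUS}
            bad[16] = 0.1  # AU 16 is not in the model set
            AUFrame(timestamp=0.0, intensities=bad)

    @pytest.mark.parametrize("value", [-0.1, float("nan"), float("inf")])
    def test_au_frame_rejects_bad_intensities(self, value):
        intensities = {a: 0.5 for a in MODEL_AUS}
        intensities[12] = value
        with pytest.raises(DataFormatError):
            AUFrame(timestamp=0.0, intensities=intensities)

    def test_frame_vector_is_in_ascending_au_order(self):
        f = make_frame(0.0, value=0.0, au1=0.1, au45=0.9)
        v = f.vector()
        assert v[0] == 0.1 and v[-1] == 0.9 and v.shape == (17,)

    @pytest.mark.parametrize("shape", [(4, 17), (5, 16), (5,)])
    def test_window_shape_enforced(self, shape):
        with pytest.raises(DataFormatError):
            AUWindow(matrix=np.zeros(shape))

    def test_window_rejects_nonfinite(self):
        m = np.zeros((5, 17))
        m[2, 3] = np.nan
        with pytest.raises(DataFormatError):
            AUWindow(matrix=m)

    @pytest.mark.parametrize(
        "value,scale", [(0.5, Scale.FIVE), (5.5, Scale.FIVE), (9.5, Scale.NINE)]
    )
    def test_rating_bounds(self, value, scale):
        with pytest.raises(DomainError):
            Rating(value, scale)

    def test_episode_scales_must_match(self):
        with pytest.raises(DataFormatError, match="scale"):
            RatedEpisode(
                participant_id="p",
                window=make_window(fill=1.0),
                valence=Rating(3, Scale.FIVE),
                arousal=Rating(3, Scale.NINE),
            )

    def test_session_lengths_must_match(self):
        with pytest.raises(DataFormatError):
            ContinuousSession(
                participant_id="p",
                windows=[make_window(fill=1.0)],
                valence_series=[Rating(5, Scale.NINE), Rating(5, Scale.NINE)],
                arousal_series=[Rating(5, Scale.NINE)],
            )


# ---------------------------------------------------------------------------
# read_au_table
# ---------------------------------------------------------------------------

def _write_csv(path, rows, header=None):
    header = header or ["frame", "timestamp", "confidence", "success", *AU_COLUMNS]
    lines = [",".join(header)]
    lines += [",".join(str(x) for x in r) for r in rows]
    path.write_text("\n".join(lines) + "\n")


def _row(frame, ts, conf=0.95, success=1, au=0.5):
    return [frame, ts, conf, success] + [au] * 17


class TestReadAUTable:
    def test_pass_through_and_feature_count(self, tmp_path):
        p = tmp_path / "t.csv"
        _write_csv(p, [_row(i + 1, i / 30) for i in range(5)])
        frames = read_au_table(p)
        assert len(frames) == 5
        assert [f.timestamp for f in frames] == sorted(f.timestamp for f in frames)
        # each frame carries exactly the 17 model AU features
        assert all(len(f.intensities) == 17 for f in frames)
        assert set(frames[0].intensities) == set(MODEL_AUS)

    def test_success_filter(self, tmp_path):
        p = tmp_path / "t.csv"
        rows = [_row(i + 1, i / 30) for i in range(5)]
        rows[2][3] = 0
        _write_csv(p, rows)
        assert len(read_au_table(p, require_success=True)) == 4
        assert len(read_au_table(p, require_success=False)) == 5

    def test_confidence_filter(self, tmp_path):
        p = tmp_path / "t.csv"
        rows = [_row(1, 0.0, conf=0.2), _row(2, 0.1, conf=0.9)]
        _write_csv(p, rows)
        assert len(read_au_table(p, min_confidence=0.5)) == 1

    def test_missing_column_named_in_error(self, tmp_path):
        p = tmp_path / "t.csv"
        header = ["frame", "timestamp", "confidence", "success", *AU_COLUMNS[:-1]]
        _write_csv(p, [[1, 0.0, 0.9, 1] + [0.5] * 16], header=header)
        with pytest.raises(DataFormatError, match="AU45_r"):
            read_au_table(p)

    def test_empty_after_filter(self, tmp_path):
        p = tmp_path / "t.csv"
        _write_csv(p, [_row(1, 0.0, success=0)])
        with pytest.raises(EmptyInputError):
            read_au_table(p)

    def test_whitespace_and_extra_columns_tolerated(self, tmp_path):
        p = tmp_path / "t.csv"
        header = "frame, timestamp, confidence, success, extra, " + ", ".join(AU_COLUMNS)
        row = "1, 0.0, 0.9, 1, 99, " + ", ".join(["0.5"] * 17)
        p.write_text(header + "\n" + row + "\n")
        frames = read_au_table(p)
        assert len(frames) == 1 and frames[0].intensities[12] == 0.5

    def test_round_trip_is_lossless(self, tmp_path, rng):
        frames = [
            AUFrame(
                timestamp=i / 10,
                intensities={a: float(v) for a, v in zip(MODEL_AUS, rng.uniform(0, 5, 17))},
            )
            for i in range(8)
        ]
        path = tmp_path / "rt.csv"
        write_au_table(frames, path)
        back = read_au_table(path)
        assert len(back) == len(frames)
        for f, g in zip(frames, back):
            assert g.timestamp == pytest.approx(f.timestamp)
            for a in MODEL_AUS:
                assert g.intensities[a] == pytest.approx(f.intensities[a], abs=1e-12)


# ---------------------------------------------------------------------------
# extract_window
# ---------------------------------------------------------------------------

class TestExtractWindow:
    def test_30fps_nearest_targets(self):
        frames = [make_frame(i / 30, value=i / 200) for i in range(40)]
        w = extract_window(frames, 0.0)
        ts = np.array([f.timestamp for f in frames])
        for row, off in zip(w.matrix, (0.0, 0.25, 0.5, 0.75, 1.0)):
            nearest = frames[int(np.argmin(np.abs(ts - off)))]
            assert np.allclose(row, nearest.vector())

    def test_exact_frames_identity(self):
        frames = [make_frame(t, value=0.1 + t) for t in (0.0, 0.25, 0.5, 0.75, 1.0)]
        w = extract_window(frames, 0.0)
        assert np.allclose(w.matrix, np.stack([f.vector() for f in frames]))

    def test_low_fps_against_brute_force_nearest(self, rng):
        # 10 fps with jitter: each row must equal the globally nearest frame
        times = np.sort(np.arange(0, 2.0, 0.1) + rng.uniform(-0.02, 0.02, 20))
        frames = [make_frame(float(t), value=float(rng.uniform(0, 5))) for t in times]
        w = extract_window(frames, 0.4)
        for row, off in zip(w.matrix, (0.0, 0.25, 0.5, 0.75, 1.0)):
            dists = [abs(f.timestamp - (0.4 + off)) for f in frames]
            expected = frames[int(np.argmin(dists))]
            assert np.allclose(row, expected.vector())

    def test_samples_never_interpolates(self, rng):
        frames = [make_frame(i / 7, value=float(rng.uniform(0, 5))) for i in range(10)]
        w = extract_window(frames, 0.1)
        source_values = {f.vector()[0] for f in frames}
        assert all(v in source_values for v in w.matrix[:, 0])

    def test_coverage_gap_raises(self):
        frames = [make_frame(t) for t in (0.0, 0.1, 0.2, 1.0)]  # hole in (0.2, 1.0)
        with pytest.raises(InsufficientCoverageError):
            extract_window(frames, 0.0)

    def test_single_frame_raises(self):
        with pytest.raises(InsufficientCoverageError):
            extract_window([make_frame(0.0)], 0.0)


# ---------------------------------------------------------------------------
# select_peak_segment
# ---------------------------------------------------------------------------

class TestSelectPeakSegment:
    def test_plateau_dominates(self):
        frames = [
            make_frame(t, value=2.0 if 1.0 <= t <= 3.0 else 0.2)
            for t in np.arange(0, 4.01, 1 / 30)
        ]
        start = select_peak_segment(frames)
        assert 1.0 <= start <= 2.0

    def test_constant_series_ties_to_earliest(self):
        frames = [make_frame(t, value=1.0) for t in np.arange(0, 2.01, 0.1)]
        assert select_peak_segment(frames) == 0.0

    def test_matches_exhaustive_scan(self, rng):
        times = np.arange(0, 3.0, 1 / 15)
        values = rng.uniform(0, 3, len(times))
        frames = [make_frame(float(t), value=float(v)) for t, v in zip(times, values)]
        got = select_peak_segment(frames)
        # independent exhaustive scan at frame resolution
        totals = values * 17
        best, best_score = None, -np.inf
        for t0 in times:
            if t0 + 1.0 > times[-1] + 1e-12:
                break
            mask = (times >= t0 - 1e-12) & (times <= t0 + 1.0 + 1e-12)
            score = totals[mask].mean()
            if score > best_score + 1e-12:
                best, best_score = t0, score
        assert got == pytest.approx(best)

    def test_under_one_second_raises(self):
        frames = [make_frame(t) for t in np.arange(0, 0.9, 0.1)]
        with pytest.raises(InsufficientCoverageError):
            select_peak_segment(frames)


# ---------------------------------------------------------------------------
# Rating conversion
# ---------------------------------------------------------------------------

class TestConvertRating:
    @pytest.mark.parametrize("i,expected", [(1, 1), (3, 5), (5, 9), (2.5, 4)])
    def test_affine_map(self, i, expected):
        out = convert_rating(Rating(i, Scale.FIVE))
        assert out.value == expected and out.scale is Scale.NINE

    def test_wrong_scale_rejected(self):
        with pytest.raises(DomainError):
            convert_rating(Rating(5.0, Scale.NINE))
        with pytest.raises(DomainError):
            invert_rating(Rating(3.0, Scale.FIVE))

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=1.0, max_value=5.0))
    def test_round_trip_identity(self, i):
        assert invert_rating(convert_rating(Rating(i, Scale.FIVE))).value == pytest.approx(
            i, abs=1e-12
        )

    @settings(derandomize=True, max_examples=50)
    @given(
        st.floats(min_value=1.0, max_value=5.0),
        st.floats(min_value=1.0, max_value=5.0),
    )
    def test_strictly_increasing_affine(self, a, b):
        fa = convert_rating(Rating(a, Scale.FIVE)).value
        fb = convert_rating(Rating(b, Scale.FIVE)).value
        assert fb - fa == pytest.approx(2.0 * (b - a), abs=1e-9)
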