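import numpy as np
import pandas as pd
import pytest

from readobs.corpus import (
    ParseError,
    apply_exclusions,
    first_pass_measures,
    parse_fixation_report,
)
from readobs.lexicon import read_lexicon_tsv


def _frames(words, fixations):
    """Build canonical frames from terse tuples.

    words: (word_index, word, first_char); fixations: (order, x, dur[, blink[, line]])
    """
    w = pd.DataFrame(
        [
            {
                "participant": "p",
                "text_id": "t",
                "line_id": 0,
                "word_index": i,
                "word": word,
                "first_char": fc,
                "word_class": "noun",
            }
            for i, word, fc in words
        ]
    )
    f = pd.DataFrame(
        [
            {
                "participant": "p",
                "text_id": "t",
                "line_id": fx[4] if len(fx) > 4 else 0,
                "order": fx[0],
                "x_char": fx[1],
                "duration_ms": fx[2],
                "blink_adjacent": fx[3] if len(fx) > 3 else 0,
            }
            for fx in fixations
        ]
    )
    return f, w


FIVE_WORDS = [(0, "one", 0), (1, "two", 4), (2, "three", 8), (3, "four", 14), (4, "five", 19)]


class TestFirstPass:
    def test_skip_with_later_regression(self):
        # fixate w1, w3, w4, then regress to w2, then w5
        f, w = _frames(
            FIVE_WORDS,
            [(0, 1.0, 200), (1, 9.0, 210), (2, 15.0, 190), (3, 5.0, 180), (4, 20.0, 205)],
        )
        m = first_pass_measures(f, w).set_index("word_index")
        assert m.loc[1, "skipped_first_pass"] == 1.0
        assert m.loc[1, "later_regressive_fixation"] == 1.0
        # w5 keeps first-pass status despite the intervening regression
        assert m.loc[4, "status"] == "fixated"
        assert m.loc[4, "skipped_first_pass"] == 0.0

    def test_gaze_duration_sums_first_pass_run(self):
        f, w = _frames(
            FIVE_WORDS,
            [(0, 1.0, 150), (1, 9.0, 120), (2, 10.0, 80), (3, 15.0, 200)],
        )
        m = first_pass_measures(f, w).set_index("word_index")
        assert m.loc[2, "gaze_duration_ms"] == 200.0

    def test_refixation_after_leaving_not_added(self):
        f, w = _frames(
            FIVE_WORDS,
            [(0, 1.0, 150), (1, 9.0, 120), (2, 15.0, 200), (3, 9.5, 500), (4, 20.0, 100)],
        )
        m = first_pass_measures(f, w).set_index("word_index")
        assert m.loc[2, "gaze_duration_ms"] == 120.0  # second visit excluded

    def test_launch_distance(self):
        f, w = _frames(FIVE_WORDS, [(0, 1.0, 150), (1, 9.0, 100)])
        m = first_pass_measures(f, w).set_index("word_index")
        assert m.loc[2, "launch_distance"] == pytest.approx(8.0 - 1.0)
        assert m.loc[1, "launch_distance"] == pytest.approx(4.0 - 1.0)  # skipped w1

    def test_landing_offset_sign(self):
        # w2 spans [4,7), centre at 5; landing at 4.5 is left of centre
        f, w = _frames(FIVE_WORDS, [(0, 1.0, 150), (1, 4.5, 100)])
        m = first_pass_measures(f, w).set_index("word_index")
        assert m.loc[1, "landing_offset_chars"] == pytest.approx(-0.5)
        assert m.loc[1, "landing_offset_frac"] == pytest.approx(-0.5 / 3)

    def test_first_word_no_launch(self):
        f, w = _frames(FIVE_WORDS, [(0, 1.0, 150), (1, 9.0, 100)])
        m = first_pass_measures(f, w).set_index("word_index")
        assert m.loc[0, "status"] == "no_launch"

    def test_line_transition_not_scored(self):
        words = [
            (0, "one", 0),
            (1, "two", 4),
            (2, "three", 8),
        ]
        f, w = _frames(words, [(0, 1.0, 150, 0, 0), (1, 9.0, 100, 0, 1)])
        w.loc[w["word_index"] == 2, "line_id"] = 1
        m = first_pass_measures(f, w).set_index("word_index")
        assert m.loc[2, "status"] == "sweep"
        assert m.loc[1, "status"] == "sweep"  # crossed by the sweep saccade

    def test_never_crossed(self):
        f, w = _frames(FIVE_WORDS, [(0, 1.0, 150)])
        m = first_pass_measures(f, w).set_index("word_index")
        assert m.loc[4, "status"] == "not_crossed"

    def test_every_scored_token_classified_once(self):
        f, w = _frames(
            FIVE_WORDS,
            [(0, 1.0, 200), (1, 9.0, 210), (2, 15.0, 190), (3, 5.0, 180), (4, 20.0, 205)],
        )
        m = first_pass_measures(f, w)
        scored = m[m["status"].isin(["fixated", "skipped"])]
        assert scored["skipped_first_pass"].isin([0.0, 1.0]).all()
        assert ((scored["status"] == "skipped") == (scored["skipped_first_pass"] == 1.0)).all()

    def test_empty_fixations(self):
        f, w = _frames(FIVE_WORDS, [])
        m = first_pass_measures(f, w)
        assert (m["status"] == "not_crossed").all()


class TestExclusions:
    def _measures(self, **overrides):
        base = {
            "participant": ["p"] * 4,
            "text_id": ["t"] * 4,
            "word_index": [0, 1, 2, 3],
            "word": ["good", "fine", "okay", "last"],
            "status": ["fixated"] * 4,
            "skipped_first_pass": [0.0] * 4,
            "gaze_duration_ms": [200.0] * 4,
            "launch_distance": [3.0] * 4,
            "landing_offset_chars": [0.0] * 4,
            "landing_offset_frac": [0.0] * 4,
            "later_regressive_fixation": [np.nan] * 4,
            "blink": [False] * 4,
        }
        base.update(overrides)
        return pd.DataFrame(base)

    def test_short_gaze_dropped_from_duration_only(self):
        df, log = apply_exclusions(self._measures(gaze_duration_ms=[65.0, 200, 200, 200]))
        assert df["include_skip"].tolist() == [True] * 4
        assert df["include_duration"].tolist() == [False, True, True, True]
        assert log["gaze_out_of_range"] == 1

    def test_long_gaze_dropped(self):
        df, _ = apply_exclusions(self._measures(gaze_duration_ms=[901.0, 200, 200, 200]))
        assert df["include_duration"].tolist() == [False, True, True, True]

    def test_boundary_gazes_kept(self):
        df, _ = apply_exclusions(self._measures(gaze_duration_ms=[70.0, 900.0, 200, 200]))
        assert df["include_duration"].all()

    def test_far_launch_dropped_from_both(self):
        df, log = apply_exclusions(self._measures(launch_distance=[25.0, 3, 3, 3]))
        assert df["include_skip"].tolist() == [False, True, True, True]
        assert df["include_duration"].tolist() == [False, True, True, True]
        assert log["launch_gt_24"] == 1

    def test_launch_cap_is_magnitude(self):
        df, _ = apply_exclusions(self._measures(launch_distance=[-25.0, 24.0, -24.0, 3]))
        assert df["include_skip"].tolist() == [False, True, True, True]

    def test_non_alphabetic_dropped(self):
        df, log = apply_exclusions(self._measures(word=["don’t", "fine", "okay", "x2"]))
        assert df["include_skip"].tolist() == [False, True, True, False]
        assert log["non_alphabetic"] == 2

    def test_blink_adjacent_dropped(self):
        df, log = apply_exclusions(self._measures(blink=[True, False, False, False]))
        assert df["include_skip"].tolist() == [False, True, True, True]
        assert log["blink_adjacent"] == 1

    def test_out_of_lexicon_dropped(self, tmp_path):
        path = tmp_path / "lex.tsv"
        path.write_text("good\t5\nfine\t4\nokay\t3\n", encoding="utf-8")
        lexicon = read_lexicon_tsv(path)
        df, log = apply_exclusions(self._measures(), lexicon=lexicon)
        assert df["include_skip"].tolist() == [True, True, True, False]
        assert log["out_of_lexicon"] == 1

    def test_counts_order_independent(self):
        m = self._measures(gaze_duration_ms=[65.0, 901.0, 200, 200])
        _, log1 = apply_exclusions(m)
        _, log2 = apply_exclusions(m.iloc[::-1].reset_index(drop=True))
        assert log1 == log2


class TestParse:
    def test_roundtrip(self, tmp_path, small_study):
        outdir, _, _ = small_study
        words, fixations = parse_fixation_report(
            outdir / "words.tsv", outdir / "fixations.tsv"
        )
        wpath, fpath = tmp_path / "w.tsv", tmp_path / "f.tsv"
        words.to_csv(wpath, sep="\t", index=False)
        fixations.to_csv(fpath, sep="\t", index=False)
        w2, f2 = parse_fixation_report(wpath, fpath)
        pd.testing.assert_frame_equal(words, w2)
        pd.testing.assert_frame_equal(fixations, f2)

    def test_shuffled_order_rejected(self, tmp_path):
        f, w = _frames(FIVE_WORDS, [(1, 1.0, 150), (0, 9.0, 100)])
        wpath, fpath = tmp_path / "w.tsv", tmp_path / "f.tsv"
        w.to_csv(wpath, sep="\t", index=False)
        f.to_csv(fpath, sep="\t", index=False)
        with pytest.raises(ParseError, match="order"):
            parse_fixation_report(wpath, fpath)

    def test_overlapping_spans_rejected(self, tmp_path):
        f, w = _frames([(0, "one", 0), (1, "two", 2)], [(0, 1.0, 100)])
        wpath, fpath = tmp_path / "w.tsv", tmp_path / "f.tsv"
        w.to_csv(wpath, sep="\t", index=False)
        f.to_csv(fpath, sep="\t", index=False)
        with pytest.raises(ParseError, match="span"):
            parse_fixation_report(wpath, fpath)

    def test_missing_column_rejected(self, tmp_path):
        f, w = _frames(FIVE_WORDS, [(0, 1.0, 100)])
        wpath, fpath = tmp_path / "w.tsv", tmp_path / "f.tsv"
        w.drop(columns=["word_class"]).to_csv(wpath, sep="\t", index=False)
        f.to_csv(fpath, sep="\t", index=False)
        with pytest.raises(ParseError, match="word_class"):
            parse_fixation_report(wpath, fpath)

    def test_empty_tables(self, tmp_path):
        wpath, fpath = tmp_path / "w.tsv", tmp_path / "f.tsv"
        f, w = _frames([], [])
        cols_w = ["participant", "text_id", "line_id", "word_index", "word", "first_char", "word_class"]
        cols_f = ["participant", "text_id", "line_id", "order", "x_char", "duration_ms", "blink_adjacent"]
        wpath.write_text("\t".join(cols_w) + "\n", encoding="utf-8")
        fpath.write_text("\t".join(cols_f) + "\n", encoding="utf-8")
        words, fixations = parse_fixation_report(wpath, fpath)
        assert words.empty and fixations.empty
        assert first_pass_measures(fixations, words).empty


class TestGroundTruthRecovery:
    def test_generator_labels_recovered_exactly(self, small_study):
        outdir, _, _ = small_study
        words, fixations = parse_fixation_report(outdir / "words.tsv", outdir / "fixations.tsv")
        truth = pd.read_csv(outdir / "ground_truth.tsv", sep="\t")
        m = first_pass_measures(fixations, words)
        mm = m.merge(truth, on=["participant", "text_id", "word_index"], suffixes=("", "_t"))
        scored = mm[mm["status"].isin(["fixated", "skipped"]) & (mm["word"] != "#")]
        assert len(scored) > 1000
        assert (scored["skipped_first_pass"] == scored["skipped"]).all()
        assert np.allclose(scored["launch_distance"], scored["launch_distance_t"], atol=1e-9)
        fixated = scored[scored["skipped_first_pass"] == 0.0]
        assert np.allclose(fixated["gaze_duration_ms"], fixated["gaze_duration"], atol=1e-3)
        assert np.allclose(fixated["landing_offset_chars"], fixated["landing_offset"], atol=1e-9)
        sk = scored[scored["skipped_first_pass"] == 1.0]
        assert (sk["later_regressive_fixation"] == sk["refixated"]).all()
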