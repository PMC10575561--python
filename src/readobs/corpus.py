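"""Canonical fixation-report ingestion, first-pass measures, and exclusions.

Interchange format is a TSV pair:

``words.tsv``      participant, text_id, line_id, word_index, word, first_char, word_class
``fixations.tsv``  participant, text_id, line_id, order, x_char, duration_ms, blink_adjacent

Coordinates are 0-based character units, global within a line; a word of
length L spans ``[first_char, first_char + L)`` with assignment boundaries a
half character outside the span.

First-pass scoring walks fixations in order. A token is first-pass *skipped*
when the eyes first cross its span without fixating it while no later word
has been fixated before; it is first-pass *fixated* when the first crossing
lands on it, and its gaze duration sums the maximal initial run of fixations
on it. Tokens first crossed via a line transition (return sweep) or with no
prior fixation in the text are left unscored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WORD_COLUMNS = ["participant", "text_id", "line_id", "word_index", "word", "first_char", "word_class"]
FIXATION_COLUMNS = ["participant", "text_id", "line_id", "order", "x_char", "duration_ms", "blink_adjacent"]

#: classification outcomes for a token's first crossing
STATUS_FIXATED = "fixated"
STATUS_SKIPPED = "skipped"
STATUS_SWEEP = "sweep"  # first crossed by a saccade that changed lines
STATUS_NO_LAUNCH = "no_launch"  # no prior fixation in the text (text-initial)
STATUS_NOT_CROSSED = "not_crossed"  # eyes never moved past the token


@dataclass(frozen=True)
class ParseError(Exception):
    path: str
    line: int
    message: str

    def __str__(self) -> str:
        return f"{self.path}:{self.line}: {self.message}"


def parse_fixation_report(words_path, fixations_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate the canonical words/fixations TSV pair."""
    words = pd.read_csv(words_path, sep="\t", dtype={"participant": str, "text_id": str, "word": str})
    fixations = pd.read_csv(fixations_path, sep="\t", dtype={"participant": str, "text_id": str})
    for col in WORD_COLUMNS:
        if col not in words.columns:
            raise ParseError(str(words_path), 1, f"missing column {col!r}")
    for col in FIXATION_COLUMNS:
        if col not in fixations.columns:
            raise ParseError(str(fixations_path), 1, f"missing column {col!r}")
    if len(fixations) and (fixations["duration_ms"] <= 0).any():
        row = int(fixations.index[fixations["duration_ms"] <= 0][0])
        raise ParseError(str(fixations_path), row + 2, "non-positive fixation duration")
    for (_, _), grp in fixations.groupby(["participant", "text_id"], sort=False):
        order = grp["order"].to_numpy()
        if np.any(np.diff(order) <= 0):
            bad = int(grp.index[1:][np.diff(order) <= 0][0])
            raise ParseError(str(fixations_path), bad + 2, "fixation order not strictly increasing")
    for (_, _, _), grp in words.groupby(["participant", "text_id", "line_id"], sort=False):
        grp = grp.sort_values("word_index")
        first = grp["first_char"].to_numpy(dtype=float)
        last = first + grp["word"].str.len().to_numpy()
        if np.any(first[1:] < last[:-1]):
            bad = int(grp.index[1:][first[1:] < last[:-1]][0])
            raise ParseError(str(words_path), bad + 2, "overlapping or out-of-order word spans")
    return words, fixations


def _assign_word(x: float, first: np.ndarray, last: np.ndarray) -> int | None:
    """Index of the word whose span (plus half-character margin) contains x."""
    inside = np.flatnonzero((x >= first) & (x < last))
    if inside.size:
        return int(inside[0])
    dist = np.maximum(first - x, x - last)  # positive outside the span
    j = int(np.argmin(dist))
    return j if dist[j] <= 0.5 else None


def first_pass_measures(fixations: pd.DataFrame, words: pd.DataFrame) -> pd.DataFrame:
    """Per-token first-pass measures for one or many (participant, text) groups.

    Returns one row per word token with columns: status, skipped_first_pass,
    gaze_duration_ms, launch_distance, landing_offset_chars,
    landing_offset_frac, later_regressive_fixation, blink.
    """
    out_frames = []
    word_groups = (
        {} if words.empty else dict(tuple(words.groupby(["participant", "text_id"], sort=False)))
    )
    fix_groups = (
        {}
        if fixations.empty
        else dict(tuple(fixations.groupby(["participant", "text_id"], sort=False)))
    )
    for key, wgrp in word_groups.items():
        fgrp = fix_groups.get(key, pd.DataFrame(columns=FIXATION_COLUMNS))
        out_frames.append(_first_pass_one_text(fgrp, wgrp.sort_values("word_index")))
    if not out_frames:
        cols = WORD_COLUMNS + [
            "status", "skipped_first_pass", "gaze_duration_ms", "launch_distance",
            "landing_offset_chars", "landing_offset_frac", "later_regressive_fixation", "blink",
        ]
        return pd.DataFrame(columns=cols)
    return pd.concat(out_frames, ignore_index=True)


def _first_pass_one_text(fixations: pd.DataFrame, words: pd.DataFrame) -> pd.DataFrame:
    n = len(words)
    first = words["first_char"].to_numpy(dtype=float)
    lengths = words["word"].str.len().to_numpy(dtype=float)
    last = first + lengths
    line_of_word = words["line_id"].to_numpy()

    status = np.array([STATUS_NOT_CROSSED] * n, dtype=object)
    skipped = np.full(n, np.nan)
    gaze = np.full(n, np.nan)
    launch = np.full(n, np.nan)
    landing = np.full(n, np.nan)
    later_regress = np.full(n, np.nan)
    blink = np.zeros(n, dtype=bool)

    frontier = -1
    run_word: int | None = None  # open first-pass run
    prev_x: float | None = None
    prev_line = None
    prev_blink = False

    for f in fixations.itertuples(index=False):
        w = _assign_word(float(f.x_char), first, last)
        if w is None:
            logger.debug("fixation at x=%.2f outside all word spans; dropped", f.x_char)
            prev_x, prev_line, prev_blink = float(f.x_char), f.line_id, bool(f.blink_adjacent)
            run_word = None
            continue
        sweep = prev_line is not None and f.line_id != prev_line
        if w > frontier:
            # progressive crossing: words strictly between frontier and w are skipped
            for j in range(frontier + 1, w):
                if sweep:
                    status[j] = STATUS_SWEEP
                elif prev_x is None:
                    status[j] = STATUS_NO_LAUNCH
                else:
                    status[j] = STATUS_SKIPPED
                    skipped[j] = 1.0
                    later_regress[j] = 0.0
                    launch[j] = first[j] - prev_x
                    blink[j] |= prev_blink or bool(f.blink_adjacent)
            if sweep:
                status[w] = STATUS_SWEEP
            elif prev_x is None:
                status[w] = STATUS_NO_LAUNCH
            else:
                status[w] = STATUS_FIXATED
                skipped[w] = 0.0
                launch[w] = first[w] - prev_x
                centre = first[w] + (lengths[w] - 1) / 2.0
                landing[w] = float(f.x_char) - centre
                blink[w] |= prev_blink or bool(f.blink_adjacent)
            gaze[w] = float(f.duration_ms)
            run_word = w
            frontier = w
        elif w == run_word:
            gaze[w] += float(f.duration_ms)
            blink[w] |= bool(f.blink_adjacent)
        else:
            if skipped[w] == 1.0:
                later_regress[w] = 1.0
            run_word = None
        prev_x, prev_line, prev_blink = float(f.x_char), f.line_id, bool(f.blink_adjacent)

    # gaze durations only meaningful for scored fixated tokens
    gaze[np.array([s != STATUS_FIXATED for s in status])] = np.nan

    out = words.reset_index(drop=True).copy()
    out["length"] = lengths.astype(int)
    out["status"] = status
    out["skipped_first_pass"] = skipped
    out["gaze_duration_ms"] = gaze
    out["launch_distance"] = launch
    out["landing_offset_chars"] = landing
    out["landing_offset_frac"] = np.where(np.isnan(landing), np.nan, landing / lengths)
    out["later_regressive_fixation"] = later_regress
    out["blink"] = blink
    return out


def apply_exclusions(
    measures: pd.DataFrame,
    lexicon=None,
    max_launch: float = 24.0,
    min_gaze_ms: float = 70.0,
    max_gaze_ms: float = 900.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the data-selection filters; returns the table with boolean
    ``include_skip`` / ``include_duration`` columns plus per-rule counts.

    Rules (skipping and duration analyses unless noted): non-alphabetic
    token; blink-adjacent; |launch distance| > 24 characters; first crossed
    via a return sweep or with no launch fixation; out-of-lexicon (when a
    lexicon is supplied); gaze duration outside [70, 900] ms (duration
    analysis only).
    """
    df = measures.copy()
    log: dict[str, int] = {}

    scored = df["status"].isin([STATUS_FIXATED, STATUS_SKIPPED])
    log["not_first_pass_scored"] = int((~scored).sum())
    log["return_sweep"] = int((df["status"] == STATUS_SWEEP).sum())
    log["no_launch"] = int((df["status"] == STATUS_NO_LAUNCH).sum())

    word_lower = df["word"].str.lower()
    alpha = word_lower.str.fullmatch(r"[a-z]+").fillna(False)
    log["non_alphabetic"] = int((scored & ~alpha).sum())

    blink = df["blink"].astype(bool)
    log["blink_adjacent"] = int((scored & alpha & blink).sum())

    far = df["launch_distance"].abs() > max_launch
    log["launch_gt_24"] = int((scored & alpha & ~blink & far).sum())

    ok = scored & alpha & ~blink & ~far
    if lexicon is not None:
        in_lex = word_lower.map(lambda w: w in lexicon)
        log["out_of_lexicon"] = int((ok & ~in_lex).sum())
        ok &= in_lex

    df["include_skip"] = ok
    fixated = df["skipped_first_pass"] == 0.0
    gaze_ok = df["gaze_duration_ms"].between(min_gaze_ms, max_gaze_ms)
    log["gaze_out_of_range"] = int((ok & fixated & ~gaze_ok).sum())
    df["include_duration"] = ok & fixated & gaze_ok
    log["retained_skip_rows"] = int(df["include_skip"].sum())
    log["retained_duration_rows"] = int(df["include_duration"].sum())
    return df, log
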