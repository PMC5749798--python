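"""CSV input/output for trials, ratings and score tables.

Trial CSV: header ``rater,order,winner,loser[,draw]`` with ``draw`` in
{0,1} (absent column = all decisive).  Reading reconstructs the original
presentation sequence by sorting trials by rater first appearance, then by
the within-rater order column.  Rating CSV: either long format
``stimulus,rater,rating`` or a wide matrix whose first column is
``stimulus``; the header decides.  All files are UTF-8, comma-separated;
stimulus and rater identifiers are opaque strings.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .core import Trial, TrialSequence
from .melo import MeloResult

__all__ = [
    "read_trials",
    "write_trials",
    "read_ratings",
    "write_ratings",
    "write_melo",
]

TRIAL_COLUMNS = ["rater", "order", "winner", "loser"]


def read_trials(path) -> TrialSequence:
    """Read a trial CSV and reconstruct the original sequence."""
    df = pd.read_csv(path, dtype={"rater": str, "winner": str, "loser": str})
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    if "draw" not in df.columns:
        df["draw"] = 0
    bad = df.index[df["winner"] == df["loser"]]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 1-based
        raise ValueError(f"{path}: winner equals loser on line(s) {lines}")
    nan_rows = df.index[df[TRIAL_COLUMNS + ["draw"]].isna().any(axis=1)]
    if len(nan_rows):
        lines = ", ".join(str(i + 2) for i in nan_rows[:5])
        raise ValueError(f"{path}: malformed/missing fields on line(s) {lines}")
    # original sequence: raters in file first-appearance order, then trial order
    rater_rank = {r: i for i, r in enumerate(dict.fromkeys(df["rater"]))}
    df = df.assign(_rr=df["rater"].map(rater_rank)).sort_values(
        ["_rr", "order"], kind="stable"
    )
    trials = [
        Trial(
            rater=row.rater,
            order=int(row.order),
            winner=row.winner,
            loser=row.loser,
            draw=bool(int(row.draw)),
        )
        for row in df.itertuples()
    ]
    return TrialSequence(trials)


def write_trials(seq: TrialSequence, path) -> None:
    df = pd.DataFrame(
        {
            "rater": [t.rater for t in seq],
            "order": [t.order for t in seq],
            "winner": [t.winner for t in seq],
            "loser": [t.loser for t in seq],
            "draw": [int(t.draw) for t in seq],
        }
    )
    df.to_csv(path, index=False)


def read_ratings(path) -> pd.DataFrame:
    """Read a rating CSV (long or wide) into a stimuli x raters matrix."""
    df = pd.read_csv(path)
    if {"stimulus", "rater", "rating"}.issubset(df.columns):
        wide = df.pivot(index="stimulus", columns="rater", values="rating")
    elif "stimulus" in df.columns:
        wide = df.set_index("stimulus")
    else:
        raise ValueError(
            f"{path}: expected long columns (stimulus,rater,rating) or a wide "
            "matrix with a 'stimulus' column"
        )
    wide.index = wide.index.astype(str)
    wide.columns = wide.columns.astype(str)
    return wide


def write_ratings(ratings: pd.DataFrame, path) -> None:
    out = ratings.copy()
    out.index.name = "stimulus"
    out.to_csv(path)


def write_melo(result: MeloResult, path) -> None:
    """Write the mElo summary table, sorted by descending mElo."""
    result.to_frame().to_csv(path, float_format="%.6g")


def write_manifest(path, *, seed, config: dict, extra: dict | None = None) -> None:
    """Record package version, seed and a config hash next to any output."""
    import hashlib

    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "package": "pairelo",
        "version": __version__,
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
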