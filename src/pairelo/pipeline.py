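"""End-to-end analysis pipeline over one trial file (and optional ratings).

Runs the full battery on a data set: original-order Elo, mElo with
dispersion, mean consistency indices, Bradley-Terry worths, descriptive
summaries and the cross-method Pearson correlation table.  All outputs are
written to one directory together with a JSON manifest (package version,
seed, config hash) so a run can be reproduced exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .agreement import mean_likert, pearson, summarize
from .bradley_terry import bt_scores_from_trials
from .consistency import mean_consistency
from .core import EloConfig, run_sequence
from .io import read_ratings, read_trials, write_manifest, write_melo
from .melo import RandomizationPlan, melo_scores

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    trials_path: str
    out_dir: str
    ratings_path: str | None = None
    elo: EloConfig = field(default_factory=EloConfig)
    plan: RandomizationPlan = field(default_factory=RandomizationPlan)
    bt_pseudocount: float = 0.0
    verbose: bool = True


def _log(config: RunConfig, msg: str) -> None:
    if config.verbose:
        print(f"[pairelo] {msg}")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the result bundle; returns it in memory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    seq = read_trials(config.trials_path)
    _log(
        config,
        f"read {len(seq)} trials over {len(seq.roster)} stimuli "
        f"from {len(seq.raters)} raters",
    )

    elo = run_sequence(seq, config.elo)
    melo = melo_scores(seq, config.elo, config.plan)
    write_melo(melo, out / "melo.csv")

    cons = mean_consistency(seq, config.elo, config.plan)
    _log(
        config,
        f"consistency: mean R = {cons.mean_R}, mean R' = {cons.mean_R_weighted} "
        f"({cons.n_excluded} of {cons.n_sequences} sequences had no expectation)",
    )
    (out / "consistency.json").write_text(
        json.dumps(
            {
                "R": cons.mean_R,
                "R_weighted": cons.mean_R_weighted,
                "original_R": cons.original_R,
                "original_R_weighted": cons.original_R_weighted,
                "n_sequences": cons.n_sequences,
                "excluded": cons.n_excluded,
            },
            indent=2,
        )
        + "\n"
    )

    bt = bt_scores_from_trials(seq, pseudocount=config.bt_pseudocount)
    pd.DataFrame({"worth": bt.worth, "log_worth": bt.log_worth}).rename_axis(
        "stimulus"
    ).to_csv(out / "bradley_terry.csv", float_format="%.8g")

    measures: dict[str, pd.Series] = {
        "elo": elo,
        "melo": melo.melo,
        "log_bt": bt.log_worth,
    }
    if config.ratings_path is not None:
        ratings = read_ratings(config.ratings_path)
        measures = {"likert": mean_likert(ratings), **measures}

    idx = list(seq.roster)
    aligned = {name: s.reindex(idx).to_numpy() for name, s in measures.items()}
    names = list(aligned)
    corr = pd.DataFrame(
        [
            [pearson(aligned[a], aligned[b]) if a != b else 1.0 for b in names]
            for a in names
        ],
        index=names,
        columns=names,
    )
    corr.rename_axis("measure").to_csv(out / "correlations.csv", float_format="%.4f")

    summary = pd.DataFrame(
        {name: asdict(summarize(vec)) for name, vec in aligned.items()}
    ).T.rename_axis("measure")
    summary.to_csv(out / "summary.csv", float_format="%.6g")

    write_manifest(
        out / "manifest.json",
        seed=config.plan.seed,
        config={
            "trials_path": str(config.trials_path),
            "ratings_path": str(config.ratings_path),
            "elo": asdict(config.elo),
            "plan": asdict(config.plan),
            "bt_pseudocount": config.bt_pseudocount,
        },
        extra={
            "n_trials": len(seq),
            "n_stimuli": len(seq.roster),
            "n_raters": len(seq.raters),
            "excluded_sequences": cons.n_excluded,
        },
    )
    _log(config, f"wrote result bundle to {out}")
    return {
        "elo": elo,
        "melo": melo,
        "consistency": cons,
        "bt": bt,
        "correlations": corr,
        "summary": summary,
    }
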