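"""Result serialization: per-episode CSV, JSON summaries, SOM snapshots,
and basic learning-curve plots."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .experiments import RunRecord

__all__ = ["record_to_frame", "write_results"]


def record_to_frame(record: RunRecord) -> pd.DataFrame:
    rows = [
        {
            "episode": i,
            "reward": r.total_reward,
            "steps": r.steps,
            "reached_goal": r.reached_goal,
            "ideal": r.ideal,
            "epsilon": r.epsilon,
            "mean_eta": r.mean_eta,
            "mean_abs_td": r.mean_abs_td,
        }
        for i, r in enumerate(record.results)
    ]
    return pd.DataFrame(rows)


def write_results(record: RunRecord, out_dir: str | Path,
                  plots: bool = True) -> dict:
    """Write episodes.csv, summary.json, SOM snapshot JSONs, and PNG
    learning curves; returns the paths written. Deterministic records
    produce byte-identical CSV/JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    csv_path = out / "episodes.csv"
    record_to_frame(record).to_csv(csv_path, index=False)
    paths["episodes"] = csv_path

    summary = {
        "episodes": record.episodes,
        "seed": record.seed,
        "final_cumulative_reward": record.final_cumulative_reward,
        "final_cumulative_ideal": record.final_cumulative_ideal,
        "switch_episode": record.switch_episode,
        "config": record.config,
    }
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=1, sort_keys=True))
    paths["summary"] = summary_path

    snap_paths = []
    for episode, snap in record.snapshots:
        p = out / f"som_snapshot_{episode:05d}.json"
        p.write_text(json.dumps(snap))
        snap_paths.append(p)
    paths["snapshots"] = snap_paths

    if plots and record.episodes:
        paths["plot"] = _plot_curves(record, out / "curves.png")
    return paths


def _plot_curves(record: RunRecord, path: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    axes[0].plot(record.cumulative_reward)
    axes[0].set_xlabel("episode")
    axes[0].set_ylabel("cumulative reward")
    axes[1].plot(record.cumulative_ideal)
    axes[1].set_xlabel("episode")
    axes[1].set_ylabel("cumulative ideal episodes")
    if record.switch_episode is not None:
        for ax in axes:
            ax.axvline(record.switch_episode, ls="--", c="grey")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
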