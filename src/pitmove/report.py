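"""Tabular and graphical outputs of a pipeline run.

All numbers land in CSVs first; plots are drawn from the same frames, so a
re-run from the same manifest reproduces every CSV byte-identically even
where image encoders differ.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .diel import daily_activity, hourly_histogram
from .model import Diel, FilterLedger, MovementEvent
from .stats import DIEL_CLASSES, class_proportions, class_summary

__all__ = [
    "movements_to_frame",
    "write_movement_table",
    "write_ledger",
    "write_reports",
]

_TS_FMT = "%Y-%m-%d %H:%M:%S"


def movements_to_frame(movements: Sequence[MovementEvent]) -> pd.DataFrame:
    rows = []
    for mv in movements:
        rows.append(
            {
                "tag_id": mv.tag_id,
                "origin": mv.origin_antenna,
                "dest": mv.dest_antenna,
                "t_start": mv.t_start.strftime(_TS_FMT),
                "t_end": mv.t_end.strftime(_TS_FMT),
                "duration_s": mv.duration_s,
                "distance_m": mv.distance_m if mv.distance_m is not None else "",
                "rate_m_s": round(mv.rate_m_s, 6) if mv.rate_m_s is not None else "",
                "direction": mv.direction.value,
                "first_order": int(mv.first_order),
                "diel": mv.diel.value if mv.diel is not None else "",
                "diel_boundary": int(mv.diel_boundary),
            }
        )
    columns = [
        "tag_id", "origin", "dest", "t_start", "t_end", "duration_s",
        "distance_m", "rate_m_s", "direction", "first_order", "diel",
        "diel_boundary",
    ]
    return pd.DataFrame(rows, columns=columns)


def write_movement_table(movements: Sequence[MovementEvent], path: str | Path) -> Path:
    path = Path(path)
    movements_to_frame(movements).to_csv(path, index=False)
    return path


def write_ledger(ledger: FilterLedger, path: str | Path) -> Path:
    """One-row CSV of the stage counts plus the derived percentages."""
    path = Path(path)
    d = ledger.as_dict()
    if ledger.n_detection_events:
        d["overlap_removed_pct"] = round(100 * ledger.overlap_removed_frac, 1)
    if ledger.n_movement_events:
        d["detection_efficiency_pct"] = round(100 * ledger.detection_efficiency, 1)
        d["rate_removed_pct"] = round(100 * ledger.rate_removed_frac, 1)
        d["transit_removed_pct_of_all"] = round(
            100 * ledger.transit_removed_frac_of_all, 1
        )
        if ledger.n_movement_events > ledger.n_rate_removed:
            d["transit_removed_pct_post_rate"] = round(
                100 * ledger.transit_removed_frac_post_rate, 1
            )
    pd.DataFrame([d]).to_csv(path, index=False)
    return path


def write_reports(
    movements: Sequence[MovementEvent],
    ledger: FilterLedger,
    out_dir: str | Path,
    study_days: Sequence[dt.date] | None = None,
    make_plots: bool = True,
) -> dict[str, Path]:
    """Write the standard report set for final-filtered movements.

    Produces the movement table, filter ledger, per-tag class proportions,
    class summary, hourly histograms, daily-activity series, weekly
    day/night counts, and (optionally) the corresponding figures.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["movements"] = write_movement_table(movements, out_dir / "movements.csv")
    paths["ledger"] = write_ledger(ledger, out_dir / "ledger.csv")

    props = class_proportions(movements)
    paths["class_proportions"] = out_dir / "class_proportions.csv"
    props.to_csv(paths["class_proportions"])
    if len(props):
        summary = class_summary(props)
        paths["class_summary"] = out_dir / "class_summary.csv"
        summary.to_csv(paths["class_summary"])

    counts, modes = hourly_histogram(movements)
    hh = pd.DataFrame(
        {tag: arr for tag, arr in sorted(counts.items())},
        index=pd.RangeIndex(24, name="hour"),
    )
    paths["hourly_histogram"] = out_dir / "hourly_histogram.csv"
    hh.to_csv(paths["hourly_histogram"])
    pd.DataFrame(
        [(t, ";".join(map(str, m))) for t, m in sorted(modes.items())],
        columns=["tag_id", "mode_hours"],
    ).to_csv(out_dir / "mode_hours.csv", index=False)

    if study_days is None and movements:
        d0 = min(m.t_start for m in movements).date()
        d1 = max(m.t_start for m in movements).date()
        study_days = [d0 + dt.timedelta(days=i) for i in range((d1 - d0).days + 1)]
    study_days = study_days or []
    act = daily_activity(movements, study_days)
    daily = pd.DataFrame(
        [(d.isoformat(), n) for d, n in act["per_day"].items()],
        columns=["date", "n_active_tags"],
    )
    paths["daily_activity"] = out_dir / "daily_activity.csv"
    daily.to_csv(paths["daily_activity"], index=False)

    weekly = _weekly_diel_counts(movements)
    paths["weekly_diel"] = out_dir / "weekly_diel_counts.csv"
    weekly.to_csv(paths["weekly_diel"], index=False)

    if make_plots:
        _plot_class_proportions(props, out_dir / "class_proportions.png")
        _plot_daily_activity(daily, out_dir / "daily_activity.png")
        _plot_hourly(hh, out_dir / "hourly_histogram.png")
        _plot_weekly(weekly, out_dir / "weekly_diel_counts.png")
    return paths


def _weekly_diel_counts(movements: Sequence[MovementEvent]) -> pd.DataFrame:
    if not movements:
        return pd.DataFrame(columns=["week", "day", "night"])
    d0 = min(m.t_start for m in movements).date()
    rows: dict[int, dict[str, int]] = {}
    for mv in movements:
        week = (mv.t_start.date() - d0).days // 7 + 1
        row = rows.setdefault(week, {"day": 0, "night": 0})
        if mv.diel is Diel.DAY:
            row["day"] += 1
        elif mv.diel is Diel.NIGHT:
            row["night"] += 1
    return pd.DataFrame(
        [{"week": w, **rows[w]} for w in sorted(rows)],
        columns=["week", "day", "night"],
    )


def _plot_class_proportions(props: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    if len(props):
        data = [props[c].to_numpy() for c in DIEL_CLASSES]
        ax.boxplot(data, tick_labels=[c.replace("_", "\n") for c in DIEL_CLASSES])
    ax.set_ylabel("proportion of movements per fish")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_daily_activity(daily: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(8, 3))
    if len(daily):
        ax.bar(range(len(daily)), daily["n_active_tags"], color="0.3")
    ax.set_xlabel("study day")
    ax.set_ylabel("active fish")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_hourly(hh: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    if hh.shape[1]:
        ax.bar(hh.index, hh.sum(axis=1), color="0.3")
    ax.set_xlabel("hour of day")
    ax.set_ylabel("movement events")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_weekly(weekly: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    if len(weekly):
        x = np.arange(len(weekly))
        ax.bar(x - 0.2, weekly["day"], width=0.4, label="day", color="0.7")
        ax.bar(x + 0.2, weekly["night"], width=0.4, label="night", color="0.2")
        ax.set_xticks(x, weekly["week"])
        ax.legend()
    ax.set_xlabel("week of study")
    ax.set_ylabel("movement events")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
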