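"""Per-year recording, replicate averaging, scenario summaries and CSV I/O.

A year's record holds the censuses of the annual cycle: eggs deposited (count
and per m^2), May juvenile size, October parr density and size by freshwater
age, May smolt density and size by age, wild adult returns and size by sea
age, the mean scaled allelic value of the stage-appropriate gene set for each
censused stage, and the neutral-locus tracer frequency.  Counts of empty
classes are 0; their mean sizes are recorded as missing, never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: count-like columns (0 when a class is empty or the population is extinct)
COUNT_COLUMNS = (
    "egg_n",
    "egg_per_m2",
    "parr_n_0",
    "parr_n_1",
    "parr_n_2",
    "parr_n_3",
    "smolt_n_1",
    "smolt_n_2",
    "smolt_n_3",
    "ret_n_total",
    "ret_n_1",
    "ret_n_2",
    "ret_n_3",
    "escapees_in",
    "strayers_in",
)

#: mean-valued columns (missing when the class is empty)
MEAN_COLUMNS = (
    "juv_len_may",
    "parr_len_0",
    "parr_len_1",
    "parr_len_2",
    "parr_len_3",
    "smolt_len_1",
    "smolt_len_2",
    "smolt_len_3",
    "ret_len_1",
    "ret_len_2",
    "ret_len_3",
    "s_embryo",
    "s_parr",
    "s_smolt",
    "s_adult",
    "neutral_freq",
)

RECORD_COLUMNS = ("year",) + COUNT_COLUMNS + MEAN_COLUMNS

#: metric column -> (stage, age_class) labels used in the tidy CSV layout
_TIDY_KEYS = {}
for _c in COUNT_COLUMNS + MEAN_COLUMNS:
    parts = _c.split("_")
    if parts[-1].isdigit():
        _TIDY_KEYS[_c] = ("_".join(parts[:-1]), parts[-1])
    else:
        _TIDY_KEYS[_c] = (_c, "")


def empty_record(year: int) -> dict:
    """A zero-count, missing-mean record (extinct population or template)."""
    rec = {"year": year}
    rec.update({c: 0.0 for c in COUNT_COLUMNS})
    rec.update({c: np.nan for c in MEAN_COLUMNS})
    return rec


def series_to_frame(records: list[dict]) -> pd.DataFrame:
    """Stack per-year records into a wide DataFrame with the fixed schema."""
    df = pd.DataFrame.from_records(records, columns=RECORD_COLUMNS)
    return df.astype(float)


def average_replicates(frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Element-wise arithmetic mean of replicate series, aligned on year.

    Counts from extinct replicates are zeros and therefore pull the mean
    down; mean-valued columns are missing after extinction and are averaged
    over the replicates in which the class exists.
    """
    if not frames:
        raise ValueError("no replicate series to average")
    stacked = pd.concat(frames)
    return stacked.groupby("year", as_index=False).mean().astype(float)


# ---------------------------------------------------------------------------
# scenario summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SummaryWindows:
    """Year windows used to read scalar summaries off a 400-year series."""

    early: tuple = (1, 10)
    late: tuple = (190, 200)
    stabilization: tuple = (150, 200)


def _window_mean(df: pd.DataFrame, column: str, window: tuple) -> float:
    lo, hi = window
    if lo < df["year"].min() or hi > df["year"].max():
        raise ValueError(f"window {window} outside the recorded series")
    sel = df[(df["year"] >= lo) & (df["year"] <= hi)]
    return float(sel[column].mean())


def extinction_year(df: pd.DataFrame) -> float:
    """First year with zero fish at every stage and no eggs, else NaN."""
    alive = (
        df[["parr_n_0", "parr_n_1", "parr_n_2", "parr_n_3"]].sum(axis=1)
        + df[["smolt_n_1", "smolt_n_2", "smolt_n_3"]].sum(axis=1)
        + df["ret_n_total"]
        + df["egg_n"]
    )
    dead = df.loc[alive <= 0, "year"]
    return float(dead.iloc[0]) if len(dead) else float("nan")


def summarize_timeseries(df: pd.DataFrame, windows: SummaryWindows = SummaryWindows()) -> dict:
    """Scalar summary of one (averaged) scenario series.

    stabilization level: mean wild returners over the stabilization window;
    abundance ratio: late/early window means of wild returners, in %;
    size-at-age change: absolute relative change of each mean-length class
    between the early and late windows, in %;
    recovery delta: mean adult-gene-set S of the final 10 years minus that of
    the last 10 intrusion years (positive = genetic recovery).
    """
    size_change = {}
    for col in MEAN_COLUMNS:
        if "len" not in col:
            continue
        early = _window_mean(df, col, windows.early)
        late = _window_mean(df, col, windows.late)
        if np.isfinite(early) and early > 0 and np.isfinite(late):
            size_change[col] = abs(late - early) / early * 100.0
        else:
            size_change[col] = float("nan")

    last_year = int(df["year"].max())
    recovery = float("nan")
    if last_year > 200:
        s_end = _window_mean(df, "s_adult", (last_year - 9, last_year))
        s_mid = _window_mean(df, "s_adult", (191, 200))
        recovery = s_end - s_mid

    early_ret = _window_mean(df, "ret_n_total", windows.early)
    late_ret = _window_mean(df, "ret_n_total", windows.late)
    return {
        "stabilization_level": _window_mean(df, "ret_n_total", windows.stabilization),
        "abundance_ratio_pct": (late_ret / early_ret * 100.0) if early_ret > 0 else float("nan"),
        "size_change_pct": size_change,
        "extinction_year": extinction_year(df),
        "recovery_delta_s_adult": recovery,
        "windows": {
            "early": list(windows.early),
            "late": list(windows.late),
            "stabilization": list(windows.stabilization),
        },
    }


def detect_extinction_and_recovery(replicates: list[pd.DataFrame]) -> dict:
    """Per-replicate extinction years and genetic-recovery flags.

    A replicate shows recovery if the mean adult-gene-set S over the final
    10 years exceeds that over the last 10 intrusion years (191-200).
    """
    ext_years = [extinction_year(df) for df in replicates]
    recovery = []
    for df in replicates:
        if np.isfinite(extinction_year(df)):
            recovery.append(False)
            continue
        last = int(df["year"].max())
        s_end = _window_mean(df, "s_adult", (last - 9, last))
        s_mid = _window_mean(df, "s_adult", (191, 200))
        recovery.append(bool(s_end > s_mid))
    finite = [y for y in ext_years if np.isfinite(y)]
    return {
        "extinction_years": ext_years,
        "extinction_fraction": len(finite) / len(replicates),
        "recovery_flags": recovery,
    }


# ---------------------------------------------------------------------------
# CSV I/O (tidy layout)
# ---------------------------------------------------------------------------

def to_tidy(df: pd.DataFrame, scenario: str = "", replicate: str = "mean") -> pd.DataFrame:
    """Wide per-year frame -> tidy rows (year, stage, age_class, metric, value)."""
    rows = []
    for col in COUNT_COLUMNS + MEAN_COLUMNS:
        stage, age = _TIDY_KEYS[col]
        rows.append(
            pd.DataFrame(
                {
                    "year": df["year"].astype(int),
                    "stage": stage,
                    "age_class": age,
                    "metric": col,
                    "value": df[col],
                    "scenario": scenario,
                    "replicate": replicate,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_timeseries(df: pd.DataFrame, path, scenario: str = "", replicate: str = "mean") -> None:
    """Write one series as a tidy CSV; missing means become empty fields."""
    to_tidy(df, scenario, replicate).to_csv(path, index=False)


def read_timeseries(path) -> pd.DataFrame:
    """Read a tidy CSV written by :func:`write_timeseries` back to wide form."""
    tidy = pd.read_csv(path)
    if len(tidy) == 0:
        return pd.DataFrame(columns=RECORD_COLUMNS).astype(float)
    wide = tidy.pivot(index="year", columns="metric", values="value").reset_index()
    wide.columns.name = None
    return wide[list(RECORD_COLUMNS)].astype(float)


def quick_look_plot(df: pd.DataFrame, path) -> None:
    """Two-panel overview: genetic sums and wild adult returns vs year."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
    for col, label in [("s_embryo", "embryo"), ("s_parr", "parr"), ("s_smolt", "smolt"), ("s_adult", "adult")]:
        ax1.plot(df["year"], df[col], label=label)
    ax1.set_ylabel("mean scaled allelic value")
    ax1.set_ylim(0, 1)
    ax1.legend(loc="lower left", fontsize=8)
    ax2.plot(df["year"], df["ret_n_total"], color="k")
    ax2.set_ylabel("wild adult returns")
    ax2.set_xlabel("year")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
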