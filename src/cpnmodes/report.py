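"""Table and figure serialization, and standalone ratio-file input.

All tables are tab-separated (keeping the conventional ``.csv`` names
``outliers_cutoff.csv``, ``modes_basic_stats.csv``,
``modes_bootstrap.csv``).  Numeric cells serialize with full precision so
written values round-trip exactly.  Ratio files can also be read back so
the density stage runs standalone on precomputed o/e values.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .bootstrap import (
    DEFAULT_CI_LEVEL,
    DEFAULT_MASS_TOLERANCE,
    DEFAULT_REPS,
    BootstrapResult,
)
from .cleaning import CleaningReport
from .density import (
    DEFAULT_GRID_SIZE,
    DEFAULT_MIN_DISTANCE,
    DEFAULT_MIN_MASS,
    DEFAULT_THRESHOLD,
    ModeSet,
    summary_stats,
)
from .ratios import DEFAULT_MIN_LENGTH, Formula, RatioSample

__all__ = [
    "RunConfig",
    "read_ratio_file",
    "write_ratio_table",
    "write_cleaning_table",
    "write_stats_table",
    "write_bootstrap_table",
    "plot_cleaning",
    "plot_density",
    "write_all",
]

SEP = "\t"

CLEANING_TABLE = "outliers_cutoff.csv"
STATS_TABLE = "modes_basic_stats.csv"
BOOTSTRAP_TABLE = "modes_bootstrap.csv"
CLEANING_FIGURE = "data_cleaning.pdf"
DENSITY_FIGURE = "mode_detection.pdf"


@dataclass
class RunConfig:
    """All pipeline parameters with their defaults; ``name`` fills the
    "Name" column of every output table."""

    input_path: str = ""
    output_dir: str = "."
    name: str = "sample"
    dinucleotide: str = "CG"
    formula: Formula = Formula.F1
    min_length: int = DEFAULT_MIN_LENGTH
    min_distance: float = DEFAULT_MIN_DISTANCE
    min_mass: float = DEFAULT_MIN_MASS
    threshold: float = DEFAULT_THRESHOLD
    grid_size: int = DEFAULT_GRID_SIZE
    bootstrap: bool = False
    reps: int = DEFAULT_REPS
    ci_level: float = DEFAULT_CI_LEVEL
    mass_tolerance: float = DEFAULT_MASS_TOLERANCE
    seed: int = 0
    threads: int = 1
    figures: bool = True
    extra: dict = field(default_factory=dict)


def read_ratio_file(path: str | os.PathLike) -> RatioSample:
    """Read precomputed o/e ratios: one value per line, optionally
    preceded by an id column; a header line is auto-detected and
    skipped.  Raises on empty files and names the offending line for
    non-numeric input."""
    path = os.fspath(path)
    values: list[float] = []
    ids: list[str] = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    lines = [(i + 1, ln) for i, ln in enumerate(lines) if ln]
    if not lines:
        raise ValueError(f"ratio file {path} is empty")
    for pos, (lineno, ln) in enumerate(lines):
        parts = ln.split()
        token = parts[-1]
        try:
            val = float(token)
        except ValueError:
            if pos == 0:  # header line
                continue
            raise ValueError(
                f"{path}: non-numeric value {token!r} on line {lineno}"
            ) from None
        ids.append(parts[0] if len(parts) > 1 else f"seq_{len(values)}")
        values.append(val)
    if not values:
        raise ValueError(f"ratio file {path} contains no numeric values")
    return RatioSample(
        values=np.asarray(values), ids=ids, name=os.path.basename(path)
    )


def write_ratio_table(sample: RatioSample, path: str | os.PathLike) -> None:
    """Two-column (id, ratio) table with header; full float precision."""
    with open(path, "w") as fh:
        fh.write(f"id{SEP}ratio\n")
        for i, v in zip(sample.ids, sample.values):
            fh.write(f"{i}{SEP}{float(v)!r}\n")


def _write_row_table(row: dict, path: str | os.PathLike) -> None:
    df = pd.DataFrame([row])
    df.to_csv(path, sep=SEP, index=False)


def write_cleaning_table(report: CleaningReport, path: str | os.PathLike) -> None:
    _write_row_table(report.to_row(), path)


def write_stats_table(
    values: np.ndarray, ms: ModeSet, name: str, path: str | os.PathLike
) -> None:
    _write_row_table(summary_stats(values, ms, name), path)


def write_bootstrap_table(
    bs: BootstrapResult, name: str, path: str | os.PathLike
) -> None:
    _write_row_table(bs.to_row(name), path)


def plot_cleaning(
    raw: np.ndarray,
    nozero: np.ndarray,
    cleaned: np.ndarray,
    report: CleaningReport,
    path: str | os.PathLike,
) -> None:
    """Three-panel histogram: raw data, zero-free data with candidate
    outlier thresholds (chosen multiplier solid, others dotted, median
    in blue), and the cleaned data."""
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    for ax, data, title in zip(
        axes, (raw, nozero, cleaned), ("raw", "zeros removed", "cleaned")
    ):
        ax.hist(data, bins=60, color="0.7")
        ax.set_title(f"{report.name}: {title}")
        ax.set_xlabel("CpN o/e ratio")
    for ax in axes[1:]:
        ax.axvline(report.median, color="blue")
    for k in report.prop_out_k:
        style = "-" if k == report.used_k else ":"
        axes[1].axvline(report.q25 - k * report.iqr, color="red", ls=style)
        axes[1].axvline(report.q75 + k * report.iqr, color="red", ls=style)
    axes[2].axvline(report.q25 - report.used_k * report.iqr, color="red")
    axes[2].axvline(report.q75 + report.used_k * report.iqr, color="red")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_density(
    ms: ModeSet,
    path: str | os.PathLike,
    bs: BootstrapResult | None = None,
    name: str = "sample",
) -> None:
    """Fitted density (red) with mode lines (solid when mass >= 0.1,
    dashed otherwise; orange when close-flagged), local-minimum
    separators, and optional bootstrap CI shading."""
    de = ms.density
    fig, ax = plt.subplots(figsize=(7, 4))
    if de is not None:
        ax.plot(de.grid, de.density, color="red")
    for i, m in enumerate(ms.modes):
        color = "orange" if "close" in m.flags else "blue"
        ls = "-" if m.mass >= 0.1 else "--"
        ax.axvline(m.position, color=color, ls=ls)
        if i > 0:
            ax.axvline(m.left_bound, color="black", lw=0.8)
        if bs is not None and i < len(bs.ci_per_mode) and bs.ci_per_mode[i]:
            lo, hi = bs.ci_per_mode[i]
            ax.axvspan(lo, hi, color="blue", alpha=0.2)
    ax.set_title(name)
    ax.set_xlabel("CpN o/e ratio")
    ax.set_ylabel("density")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def write_all(
    outdir: str | os.PathLike,
    config: RunConfig,
    raw_sample: RatioSample,
    nozero_values: np.ndarray,
    cleaned: RatioSample,
    report: CleaningReport,
    ms: ModeSet,
    bs: BootstrapResult | None = None,
) -> dict[str, Path]:
    """Write every enabled table and figure into ``outdir``; returns the
    mapping of artifact kind to path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["cleaning_table"] = outdir / CLEANING_TABLE
    write_cleaning_table(report, paths["cleaning_table"])
    paths["stats_table"] = outdir / STATS_TABLE
    write_stats_table(cleaned.values, ms, config.name, paths["stats_table"])
    if bs is not None:
        paths["bootstrap_table"] = outdir / BOOTSTRAP_TABLE
        write_bootstrap_table(bs, config.name, paths["bootstrap_table"])
    if config.figures:
        paths["cleaning_figure"] = outdir / CLEANING_FIGURE
        plot_cleaning(
            raw_sample.values, nozero_values, cleaned.values, report,
            paths["cleaning_figure"],
        )
        paths["density_figure"] = outdir / DENSITY_FIGURE
        plot_density(ms, paths["density_figure"], bs=bs, name=config.name)
    return paths
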