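"""Batch retrieval of unit files, group summaries and hypothesis tests.

Unit files written by the detection stage are gathered by recursive
wildcard search ('?' matches exactly one character, case-insensitively,
against the file base name without extension; listed folder names are
pruned at any depth). Per-unit event counts, mean amplitudes and event
frequencies — for the total ([t]) and selected ([s]) events — feed group
descriptive statistics (mean, SD, SEM over units), cumulative relative
histograms of amplitude and inter-event interval, and three hypothesis
tests: the two-sample Kolmogorov-Smirnov test on pooled event-level
distributions, the pooled-variance independent two-sample t-test, and
one-way ANOVA on per-unit means.

Event frequency is defined as n_events divided by the time of the last
event, since the unit file stores only event times, not the recording
duration.
"""

from __future__ import annotations

import html
import os
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .signalio import SignalIOError, UnitRecord, read_unit_file

__all__ = [
    "Query",
    "HistogramSpec",
    "GroupSummary",
    "find_unit_files",
    "load_units",
    "summarize_group",
    "cumulative_relative_histogram",
    "ks_two_sample",
    "t_test_independent",
    "one_way_anova",
    "pooled_selected_values",
    "export_results",
]


@dataclass(frozen=True)
class Query:
    """Recursive wildcard search below ``root_path``.

    ``pattern`` matches the base file name without extension; ``?`` stands
    for exactly one character, everything else is literal, and matching is
    case-insensitive. Folders whose name (at any depth) appears in
    ``exclude_folders`` — also case-insensitively — are skipped.
    """

    root_path: str | os.PathLike
    pattern: str
    exclude_folders: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("search pattern must be nonempty")


def _pattern_regex(pattern: str) -> re.Pattern:
    return re.compile(
        "".join("." if ch == "?" else re.escape(ch) for ch in pattern),
        re.IGNORECASE,
    )


def find_unit_files(query: Query) -> list[Path]:
    """All files under the root whose stem matches the pattern, sorted."""
    root = Path(query.root_path)
    if not root.is_dir():
        raise FileNotFoundError(f"search root {root} does not exist")
    regex = _pattern_regex(query.pattern)
    excluded = {name.casefold() for name in query.exclude_folders}
    matches: list[Path] = []
    for dirpath, dirnames, filenames in os.walk(root):
        dirnames[:] = sorted(d for d in dirnames if d.casefold() not in excluded)
        for name in filenames:
            if regex.fullmatch(Path(name).stem):
                matches.append(Path(dirpath) / name)
    return sorted(matches, key=str)


def load_units(paths: Sequence[str | os.PathLike]) -> tuple[list[UnitRecord], dict[str, str]]:
    """Read and validate unit files, continuing past per-file failures.

    Returns the successfully loaded records (input order preserved) and a
    path -> message map of diagnostics. Raises if no path was given or if
    every file failed.
    """
    if not paths:
        raise ValueError("no unit files to load")
    records: list[UnitRecord] = []
    failures: dict[str, str] = {}
    for p in paths:
        try:
            records.append(read_unit_file(p))
        except (SignalIOError, OSError) as exc:
            failures[str(p)] = str(exc)
    if not records:
        raise SignalIOError(
            "all unit files failed to load: "
            + "; ".join(f"{k}: {v}" for k, v in failures.items())
        )
    return records, failures


def _unit_row(rec: UnitRecord) -> dict:
    sel = rec.selected.astype(bool)
    def block(times: np.ndarray, amps: np.ndarray) -> tuple[float, float]:
        if times.size == 0 or times[-1] <= 0:
            return np.nan, np.nan
        return float(np.mean(amps)), times.size / float(times[-1])
    amp_t, freq_t = block(rec.times_s, rec.amplitudes_pa)
    amp_s, freq_s = block(rec.times_s[sel], rec.amplitudes_pa[sel])
    return {
        "unit": rec.name,
        "n_total": int(rec.n_events),
        "n_selected": int(sel.sum()),
        "mean_amplitude_pa[t]": amp_t,
        "mean_amplitude_pa[s]": amp_s,
        "frequency_hz[t]": freq_t,
        "frequency_hz[s]": freq_s,
    }


@dataclass
class GroupSummary:
    """Per-unit table plus group-level mean/SD/SEM over units."""

    per_unit: pd.DataFrame
    group: pd.DataFrame


def summarize_group(records: Sequence[UnitRecord]) -> GroupSummary:
    """Descriptive statistics of one retrieved group of unit files.

    Per unit: event counts, mean amplitude and frequency for total ([t])
    and selected ([s]) events; units with no events in a block contribute
    missing values, excluded pairwise from the group statistics. Group SD
    uses the n-1 denominator and SEM = SD / sqrt(n_units).
    """
    if not records:
        raise ValueError("no unit records to summarize")
    per_unit = pd.DataFrame([_unit_row(r) for r in records])
    metrics = [
        "mean_amplitude_pa[t]",
        "mean_amplitude_pa[s]",
        "frequency_hz[t]",
        "frequency_hz[s]",
    ]
    rows = []
    for m in metrics:
        vals = per_unit[m].dropna().to_numpy()
        n = vals.size
        sd = float(np.std(vals, ddof=1)) if n > 1 else np.nan
        rows.append(
            {
                "metric": m,
                "n_units": n,
                "mean": float(np.mean(vals)) if n else np.nan,
                "sd": sd,
                "sem": sd / np.sqrt(n) if n > 1 else np.nan,
            }
        )
    return GroupSummary(per_unit=per_unit, group=pd.DataFrame(rows))


@dataclass(frozen=True)
class HistogramSpec:
    """Equal-width binning on [begin, end] with out-of-range values clipped."""

    n_bins: int
    begin: float
    end: float

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("need at least one bin")
        if not self.end > self.begin:
            raise ValueError("need end > begin")


def cumulative_relative_histogram(
    values: np.ndarray, spec: HistogramSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative relative frequency at the upper edge of each bin.

    Values below ``begin`` fall into the first bin and values above
    ``end`` into the last (clipping, not dropping), so the curve is
    non-decreasing and ends at exactly 1.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot histogram an empty value set")
    clipped = np.clip(values, spec.begin, spec.end)
    counts, edges = np.histogram(clipped, bins=spec.n_bins,
                                 range=(spec.begin, spec.end))
    cumulative = np.cumsum(counts) / counts.sum()
    return edges[1:], cumulative


def ks_two_sample(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum gap between the two empirical CDFs; the p value
    comes from the asymptotic Kolmogorov distribution evaluated at
    ``(sqrt(ne) + 0.12 + 0.11/sqrt(ne)) * D`` with the effective sample
    size ne = n*m/(n+m).
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    n, m = x.size, y.size
    if n < 2 or m < 2:
        raise ValueError("each sample needs at least 2 values")
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, grid, side="right") / n
    cdf_y = np.searchsorted(y, grid, side="right") / m
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    en = np.sqrt(n * m / (n + m))
    p = float(special.kolmogorov((en + 0.12 + 0.11 / en) * d))
    return d, min(max(p, 0.0), 1.0)


def t_test_independent(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """Pooled-variance (Student) independent two-sample t-test, two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    df = a.size + b.size - 2
    pooled = ((a.size - 1) * np.var(a, ddof=1) + (b.size - 1) * np.var(b, ddof=1)) / df
    if pooled == 0.0:
        if np.mean(a) == np.mean(b):
            return 0.0, df, 1.0
        return float(np.sign(np.mean(a) - np.mean(b)) * np.inf), df, 0.0
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), df, float(res.pvalue)


def one_way_anova(groups: Sequence[np.ndarray]) -> tuple[float, int, int, float]:
    """One-way ANOVA from the between/within sum-of-squares decomposition.

    For exactly two groups F equals the square of the pooled-variance t
    statistic and the p values coincide. Zero within-group variance is
    handled as in the t-test (F = 0, p = 1 when the means agree too).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(g.size < 2 for g in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    all_vals = np.concatenate(arrays)
    grand = np.mean(all_vals)
    ss_between = sum(g.size * (np.mean(g) - grand) ** 2 for g in arrays)
    ss_within = sum(float(np.sum((g - np.mean(g)) ** 2)) for g in arrays)
    df1 = len(arrays) - 1
    df2 = all_vals.size - len(arrays)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, df1, df2, 1.0
        return float("inf"), df1, df2, 0.0
    f = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), df1, df2, p


def pooled_selected_values(
    records: Sequence[UnitRecord], attribute: str = "amplitude"
) -> np.ndarray:
    """Pool selected-event amplitudes or IEIs across a group's units.

    IEIs are differences of consecutive selected-event times within each
    unit (never across units).
    """
    out: list[np.ndarray] = []
    for rec in records:
        sel = rec.selected.astype(bool)
        if attribute == "amplitude":
            out.append(rec.amplitudes_pa[sel])
        elif attribute == "iei":
            times = rec.times_s[sel]
            if times.size >= 2:
                out.append(np.diff(times))
        else:
            raise ValueError("attribute must be 'amplitude' or 'iei'")
    return np.concatenate(out) if out else np.empty(0)


# ---------------------------------------------------------------------------
# export

def _frame_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def export_results(
    summaries: Mapping[str, GroupSummary],
    histograms: Mapping[str, Mapping[str, tuple[np.ndarray, np.ndarray]]],
    tests: pd.DataFrame | Sequence[Mapping],
    out_dir: str | os.PathLike,
) -> dict[str, Path]:
    """Write summary, histogram (TSV + HTML) and test tables to a directory.

    ``histograms`` maps attribute name -> {group name -> (bin upper edges,
    cumulative relative frequency)}. The HTML page embeds the same numeric
    series as the TSV, as an inline SVG plot plus a table, so it is fully
    self-contained. Identical inputs produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rows = []
    for group, summ in summaries.items():
        per_unit = summ.per_unit.copy()
        per_unit.insert(0, "group", group)
        rows.append(per_unit)
    per_unit_all = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    group_rows = []
    for group, summ in summaries.items():
        g = summ.group.copy()
        g.insert(0, "group", group)
        group_rows.append(g)
    paths["summary"] = out / "summary.tsv"
    with open(paths["summary"], "w", newline="\n") as fh:
        per_unit_all.to_csv(fh, sep="\t", index=False, lineterminator="\n")
        fh.write("\n")
        if group_rows:
            pd.concat(group_rows, ignore_index=True).to_csv(
                fh, sep="\t", index=False, lineterminator="\n"
            )

    hist_rows = []
    for attribute, series in histograms.items():
        for group, (edges, cumulative) in series.items():
            for e, c in zip(edges, cumulative):
                hist_rows.append(
                    {
                        "attribute": attribute,
                        "group": group,
                        "bin_upper_edge": e,
                        "cumulative_relative_frequency": c,
                    }
                )
    hist_frame = pd.DataFrame(
        hist_rows,
        columns=["attribute", "group", "bin_upper_edge", "cumulative_relative_frequency"],
    )
    paths["histograms"] = out / "histograms.tsv"
    _frame_tsv(hist_frame, paths["histograms"])
    paths["histograms_html"] = out / "histograms.html"
    paths["histograms_html"].write_text(_histograms_html(histograms), newline="\n")

    tests_frame = tests if isinstance(tests, pd.DataFrame) else pd.DataFrame(list(tests))
    paths["tests"] = out / "tests.tsv"
    _frame_tsv(tests_frame, paths["tests"])
    return paths


def _svg_curve(edges: np.ndarray, cumulative: np.ndarray,
               x_range: tuple[float, float], color: str) -> str:
    x0, x1 = x_range
    span = (x1 - x0) or 1.0
    pts = " ".join(
        f"{40 + 540 * (e - x0) / span:.1f},{220 - 200 * c:.1f}"
        for e, c in zip(edges, cumulative)
    )
    return f'<polyline fill="none" stroke="{color}" points="{pts}"/>'


def _histograms_html(
    histograms: Mapping[str, Mapping[str, tuple[np.ndarray, np.ndarray]]]
) -> str:
    colors = ["#1f77b4", "#d62728", "#2ca02c", "#9467bd", "#8c564b", "#e377c2"]
    parts = [
        "<!DOCTYPE html>",
        "<html><head><meta charset='utf-8'>",
        "<title>Cumulative relative histograms</title></head><body>",
    ]
    for attribute, series in histograms.items():
        parts.append(f"<h2>{html.escape(attribute)}</h2>")
        all_edges = [e for e, _ in series.values() if len(e)]
        if all_edges:
            x0 = min(float(e[0]) for e in all_edges)
            x1 = max(float(e[-1]) for e in all_edges)
        else:
            x0, x1 = 0.0, 1.0
        parts.append('<svg width="600" height="240" xmlns="http://www.w3.org/2000/svg">')
        parts.append('<rect x="40" y="20" width="540" height="200" '
                     'fill="none" stroke="#888"/>')
        for k, (group, (edges, cumulative)) in enumerate(series.items()):
            parts.append(_svg_curve(np.asarray(edges), np.asarray(cumulative),
                                    (x0, x1), colors[k % len(colors)]))
        parts.append("</svg>")
        parts.append("<table border='1'><tr><th>group</th><th>bin upper edge</th>"
                     "<th>cumulative relative frequency</th></tr>")
        for group, (edges, cumulative) in series.items():
            for e, c in zip(edges, cumulative):
                parts.append(
                    f"<tr><td>{html.escape(str(group))}</td>"
                    f"<td>{float(e)!r}</td><td>{float(c)!r}</td></tr>"
                )
        parts.append("</table>")
    parts.append("</body></html>")
    return "\n".join(parts)
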