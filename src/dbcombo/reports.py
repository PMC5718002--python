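"""CSV report emission, mirroring the printed result-table layouts.

All internal numbers are full-precision fractions; this module is the
only place rounding happens.  Performance tables print percentages to
one decimal, practice tables to whole percents, both round-half-up, and
number needed to read to the nearest integer.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .combinations import AttainmentRow, CombinationPerformance, UniqueContributionSummary
from .model import combo_name

__all__ = [
    "format_percent",
    "unique_contributions_frame",
    "combination_performance_frame",
    "attainment_frame",
    "practice_frame",
    "write_reports",
]


def format_percent(fraction: float, decimals: int = 1) -> str:
    """Format a fraction as a percent string, round-half-up.

    >>> format_percent(0.98281)
    '98.3%'
    >>> format_percent(0.405, decimals=0)
    '41%'
    """
    quantum = Decimal(1).scaleb(-decimals)
    value = (Decimal(str(fraction)) * 100).quantize(quantum, rounding=ROUND_HALF_UP)
    return f"{value}%"


def _round_int(x: float) -> int:
    return int(Decimal(str(x)).quantize(Decimal(1), rounding=ROUND_HALF_UP))


def unique_contributions_frame(summary: UniqueContributionSummary) -> pd.DataFrame:
    rows = [
        {
            "database": c.database,
            "n_reviews_used": c.n_reviews_used,
            "n_reviews_with_unique": c.n_reviews_with_unique,
            "n_unique_refs": c.n_unique_refs,
        }
        for c in summary.per_database
    ]
    return pd.DataFrame(rows, columns=["database", "n_reviews_used", "n_reviews_with_unique", "n_unique_refs"])


def combination_performance_frame(
    performances: Sequence[CombinationPerformance],
) -> pd.DataFrame:
    """The combination performance table: 9 columns, one row per subset."""
    rows = [
        {
            "combination": p.name,
            "n_results": p.results_total_dedup,
            "n_includes": p.includes_retrieved,
            "overall_recall": format_percent(p.overall_recall),
            "median_recall": format_percent(p.median_recall),
            "min_recall": format_percent(p.min_recall),
            "pct_reviews_full_recall": format_percent(p.pct_reviews_full_recall),
            "precision": format_percent(p.precision),
            "nnr": _round_int(p.nnr),
        }
        for p in performances
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "combination",
            "n_results",
            "n_includes",
            "overall_recall",
            "median_recall",
            "min_recall",
            "pct_reviews_full_recall",
            "precision",
            "nnr",
        ],
    )


def attainment_frame(rows: Sequence[AttainmentRow]) -> pd.DataFrame:
    out = []
    for row in rows:
        rec: dict[str, object] = {"combination": combo_name(row.combo), "n_reviews": row.n_reviews}
        for t, pct in zip(row.thresholds, row.pct_reviews_at_or_above):
            rec[f"recall_{format_percent(t, 0)}"] = format_percent(pct)
        out.append(rec)
    return pd.DataFrame(out)


def practice_frame(rows: Sequence[Mapping[str, object]], thresholds: Sequence[float]) -> pd.DataFrame:
    """The practice table: whole-percent shares, probabilities and products.

    A ``Total`` row carries the headline probabilities (the sums of the
    weighted columns before rounding).
    """
    out = []
    sums = {f"weighted_{t:g}": 0.0 for t in thresholds}
    for row in rows:
        rec: dict[str, object] = {
            "combination": row["combination"],
            "frequency": row["frequency"],
            "frequency_pct": format_percent(float(row["frequency_share"]), 0),
        }
        for t in thresholds:
            rec[f"p_recall_{t:g}"] = format_percent(float(row[f"p_recall_{t:g}"]), 0)
            rec[f"weighted_{t:g}"] = format_percent(float(row[f"weighted_{t:g}"]), 0)
            sums[f"weighted_{t:g}"] += float(row[f"weighted_{t:g}"])
        out.append(rec)
    total: dict[str, object] = {
        "combination": "Total",
        "frequency": sum(int(r["frequency"]) for r in rows),
        "frequency_pct": "",
    }
    for t in thresholds:
        total[f"p_recall_{t:g}"] = ""
        total[f"weighted_{t:g}"] = format_percent(sums[f"weighted_{t:g}"], 0)
    out.append(total)
    return pd.DataFrame(out)


def write_reports(
    corpus_results: Mapping[str, object],
    out_dir: str | Path,
) -> list[Path]:
    """Emit every available analysis table as CSV under ``out_dir``.

    Recognised keys: ``unique_contributions``
    (:class:`UniqueContributionSummary`), ``combination_performance``
    (list of :class:`CombinationPerformance`), ``attainment`` (list of
    :class:`AttainmentRow`), ``stratified_attainment`` (group name ->
    AttainmentRow), ``practice_rows`` + ``practice_thresholds``,
    ``results_reduction`` / ``precision_improvement`` (combination name
    -> distribution summary).  Returns the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _emit(name: str, frame: pd.DataFrame) -> None:
        path = out / name
        try:
            frame.to_csv(path, index=False)
        except OSError as exc:
            raise OSError(f"could not write report {path}: {exc}") from exc
        written.append(path)

    if "unique_contributions" in corpus_results:
        _emit(
            "unique_contributions.csv",
            unique_contributions_frame(corpus_results["unique_contributions"]),  # type: ignore[arg-type]
        )
    if "combination_performance" in corpus_results:
        _emit(
            "combination_performance.csv",
            combination_performance_frame(corpus_results["combination_performance"]),  # type: ignore[arg-type]
        )
    if "attainment" in corpus_results:
        _emit("attainment.csv", attainment_frame(corpus_results["attainment"]))  # type: ignore[arg-type]
    if "stratified_attainment" in corpus_results:
        groups: Mapping[str, AttainmentRow] = corpus_results["stratified_attainment"]  # type: ignore[assignment]
        frames = []
        for group, row in groups.items():
            frame = attainment_frame([row])
            frame.insert(0, "group", group)
            frames.append(frame)
        if frames:
            _emit("stratified_attainment.csv", pd.concat(frames, ignore_index=True))
    if "practice_rows" in corpus_results:
        _emit(
            "practice.csv",
            practice_frame(
                corpus_results["practice_rows"],  # type: ignore[arg-type]
                corpus_results.get("practice_thresholds", (0.95, 1.0)),  # type: ignore[arg-type]
            ),
        )
    for key in ("results_reduction", "precision_improvement"):
        if key in corpus_results:
            dists: Mapping[str, Mapping[str, float]] = corpus_results[key]  # type: ignore[assignment]
            frame = pd.DataFrame(
                [{"combination": name, **summary} for name, summary in dists.items()]
            )
            _emit(f"{key}.csv", frame)
    return written
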