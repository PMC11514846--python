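"""Cross-genome analysis: composition matrices, regression panels, outliers.

The regression panels mirror the standard diagnostics for the three laws
on a cohort of genomes: T vs A and C vs G (law 1), purine excess and
purine content against GC content (law 2 / independence), and observed vs
estimated proportions for each base (law 3).  All fits are ordinary least
squares with vertical residuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from genolaws.composition import BaseCounts, CompositionProfile, profile_from_counts
from genolaws.laws import LawReport, evaluate_genome, evaluate_profile

__all__ = [
    "CohortRow",
    "CohortTable",
    "RegressionFit",
    "build_cohort",
    "fit_regression",
    "panel_regressions",
    "rank_outliers",
    "read_composition_table",
    "write_cohort_tsv",
    "write_panels_tsv",
    "write_outliers_tsv",
]


@dataclass(frozen=True)
class CohortRow:
    genome_id: str
    profile: CompositionProfile
    report: LawReport


@dataclass(frozen=True)
class CohortTable:
    """One row per genome, ids unique, order preserved."""

    rows: tuple[CohortRow, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.genome_id for r in self.rows]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate genome ids: {dupes}")

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self, decimals: int | None = None) -> pd.DataFrame:
        return pd.DataFrame([r.report.as_dict(decimals) for r in self.rows])


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of y on x.  ``r_squared`` is ``None`` (flagged undefined)
    when the response is constant, since SStot = 0 leaves it meaningless."""

    slope: float
    intercept: float
    r_squared: float | None
    n: int
    x_label: str = "x"
    y_label: str = "y"


def build_cohort(genomes: Iterable[tuple[str, BaseCounts]], provenance: str = "") -> CohortTable:
    """Profile and law-score every genome of a cohort.

    ``genomes`` yields ``(genome_id, BaseCounts)`` pairs; ids must be unique.
    """
    rows = []
    seen = set()
    for genome_id, counts in genomes:
        if genome_id in seen:
            raise ValueError(f"duplicate genome id: {genome_id!r}")
        seen.add(genome_id)
        try:
            report = evaluate_genome(genome_id, counts)
        except ValueError as exc:
            raise ValueError(f"genome {genome_id!r}: {exc}") from exc
        rows.append(CohortRow(genome_id, report.observed, report))
    if not rows:
        raise ValueError("cohort is empty")
    return CohortTable(tuple(rows), provenance=provenance)


def fit_regression(
    x: Sequence[float], y: Sequence[float], x_label: str = "x", y_label: str = "y"
) -> RegressionFit:
    """Ordinary least squares of y on x with vertical residuals.

    slope = Sxy/Sxx, intercept = ȳ − slope·x̄, R² = 1 − SSres/SStot.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d sequences of equal length")
    n = len(x)
    if n < 2:
        raise ValueError("regression requires at least 2 points")
    xbar = x.mean()
    ybar = y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    if sxx == 0.0:
        raise ValueError("x values are all identical; slope undefined")
    sxy = float(np.sum((x - xbar) * (y - ybar)))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    ss_res = float(np.sum((y - (intercept + slope * x)) ** 2))
    ss_tot = float(np.sum((y - ybar) ** 2))
    r_squared = None if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return RegressionFit(slope, intercept, r_squared, n, x_label, y_label)


def panel_regressions(cohort: CohortTable) -> list[RegressionFit]:
    """The eight diagnostic panels for a cohort.

    1. p_t vs p_a and 2. p_c vs p_g (law-1 pairing);
    3. purine excess p_r − p_y vs p_s and 4. p_r vs p_s (law-2 /
       independence of GC and purine content);
    5–8. observed vs estimated proportion for A, T, G, C (law 3).
    """
    if len(cohort) < 2:
        raise ValueError("panel regressions require at least 2 genomes")
    profiles = [row.profile for row in cohort.rows]
    reports = [row.report for row in cohort.rows]
    panels = [
        fit_regression([p.p_a for p in profiles], [p.p_t for p in profiles], "p_a", "p_t"),
        fit_regression([p.p_g for p in profiles], [p.p_c for p in profiles], "p_g", "p_c"),
        fit_regression(
            [p.p_s for p in profiles], [p.p_r - p.p_y for p in profiles], "p_s", "p_r - p_y"
        ),
        fit_regression([p.p_s for p in profiles], [p.p_r for p in profiles], "p_s", "p_r"),
    ]
    for base in "atgc":
        est = [getattr(r.estimated, f"p_{base}") for r in reports]
        obs = [getattr(r.observed, f"p_{base}") for r in reports]
        panels.append(fit_regression(est, obs, f"est_p_{base}", f"obs_p_{base}"))
    return panels


def rank_outliers(cohort: CohortTable, top_k: int = 10) -> list[tuple[str, float]]:
    """Genomes sorted by outlier score (largest pairing disparity) descending.

    Ties break lexicographically by genome id; at most ``top_k`` returned.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    ranked = sorted(
        ((row.genome_id, row.report.outlier_score) for row in cohort.rows),
        key=lambda item: (-item[1], item[0]),
    )
    return ranked[:top_k]


_COUNT_COLS = ["n_a", "n_t", "n_g", "n_c"]
_PROP_COLS = ["p_a", "p_t", "p_g", "p_c"]


def read_composition_table(path) -> CohortTable:
    """Load a cohort from a per-genome composition TSV.

    The table needs ``genome_id`` plus either the four base counts
    (``n_a n_t n_g n_c``, optional ``n_ambiguous``) or the four base
    proportions (``p_a p_t p_g p_c``).  Proportions may be percentages;
    values exceeding 1.5 trigger a /100 conversion for the whole table.
    With proportions only, the contingency-test fields of each report are
    unavailable (``None``).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "genome_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'genome_id'")
    has_counts = all(c in df.columns for c in _COUNT_COLS)
    has_props = all(c in df.columns for c in _PROP_COLS)
    if not has_counts and not has_props:
        missing = [c for c in _COUNT_COLS + _PROP_COLS if c not in df.columns]
        raise ValueError(
            f"{path}: need either count columns {_COUNT_COLS} or proportion "
            f"columns {_PROP_COLS}; missing {missing}"
        )

    rows = []
    if has_counts:
        for _, rec in df.iterrows():
            counts = BaseCounts(
                int(rec["n_a"]),
                int(rec["n_t"]),
                int(rec["n_g"]),
                int(rec["n_c"]),
                int(rec.get("n_ambiguous", 0)),
            )
            report = evaluate_genome(str(rec["genome_id"]), counts)
            rows.append(CohortRow(report.genome_id, report.observed, report))
    else:
        values = df[_PROP_COLS].to_numpy(dtype=float)
        # Percent vs fraction auto-detection on the whole table.
        if np.nanmax(values) > 1.5:
            values = values / 100.0
        for i, (_, rec) in enumerate(df.iterrows()):
            p = values[i]
            total = float(p.sum())
            if abs(total - 1.0) > 5e-3:
                raise ValueError(
                    f"{path}: row {rec['genome_id']!r} proportions sum to "
                    f"{total:.4f}, expected 1 within 0.005"
                )
            profile = CompositionProfile(
                p_a=float(p[0]),
                p_t=float(p[1]),
                p_g=float(p[2]),
                p_c=float(p[3]),
                n_counted=(
                    int(rec["n_counted"])
                    if "n_counted" in df.columns and pd.notna(rec["n_counted"])
                    else None
                ),
            )
            rows.append(
                CohortRow(str(rec["genome_id"]), profile, evaluate_profile(str(rec["genome_id"]), profile))
            )
    return CohortTable(tuple(rows), provenance=str(path))


def write_cohort_tsv(cohort: CohortTable, path, decimals: int = 4) -> None:
    cohort.to_frame(decimals).to_csv(path, sep="\t", index=False)


def write_panels_tsv(panels: Iterable[RegressionFit], path) -> None:
    frame = pd.DataFrame(
        [
            {
                "x_label": p.x_label,
                "y_label": p.y_label,
                "slope": p.slope,
                "intercept": p.intercept,
                "r_squared": p.r_squared,
                "n": p.n,
            }
            for p in panels
        ]
    )
    frame.to_csv(path, sep="\t", index=False)


def write_outliers_tsv(ranked: Iterable[tuple[str, float]], path, decimals: int = 4) -> None:
    frame = pd.DataFrame(ranked, columns=["genome_id", "outlier_score"])
    frame["outlier_score"] = frame["outlier_score"].round(decimals)
    frame.to_csv(path, sep="\t", index=False)
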