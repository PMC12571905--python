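"""Cohort-level event statistics: rates, incidence fractions, fold-changes.

Extrusion and shrink calls are aggregated into per-cohort summaries:
extrusion rate per 1,000 cells, the fraction of live-cell extrusions (LCE)
preceded by a detected shrink event, the analogous fraction for apoptotic
extrusions, overall shrink incidence, and counts of cells that shrink
without extruding.  Uncertainty is quantified by a seeded percentile
bootstrap over cells (default 2,000 resamples) instead of the original
ANOVA/t-test battery, since the quantity of interest here is parameter
recovery, not p-value replication.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["CohortSummary", "FoldChange", "build_cell_table", "summarize",
           "fold_change", "report"]

STATISTICS = ("extrusion_rate", "hes_fraction_lce", "hes_fraction_apoptotic",
              "shrink_incidence")


@dataclass
class CohortSummary:
    """Headline statistics for one condition cohort.

    ``extrusion_rate`` is per ``rate_per`` cells over the whole movie;
    fractions are percentages.  ``cell_table`` retains the per-cell calls so
    fold-changes can bootstrap over cells.
    """

    condition: str
    n_cells: int
    n_extrusions: int
    n_lce: int
    n_apoptotic: int
    extrusion_rate: float
    hes_fraction_lce: float | None
    hes_fraction_apoptotic: float | None
    shrink_incidence: float
    shrink_no_extrude_count: int
    dropout_count: int
    rate_per: int
    seed: int
    bootstrap_ci: dict[str, tuple[float, float]]
    cell_table: pd.DataFrame = field(repr=False)

    def as_row(self) -> dict:
        row = {k: getattr(self, k) for k in
               ("condition", "n_cells", "n_extrusions", "n_lce",
                "n_apoptotic", "extrusion_rate", "hes_fraction_lce",
                "hes_fraction_apoptotic", "shrink_incidence",
                "shrink_no_extrude_count", "dropout_count", "rate_per",
                "seed")}
        for stat, (lo, hi) in self.bootstrap_ci.items():
            row[f"{stat}_ci_low"] = lo
            row[f"{stat}_ci_high"] = hi
        return row


@dataclass
class FoldChange:
    statistic: str
    baseline_condition: str
    treated_condition: str
    ratio: float
    ci_low: float
    ci_high: float
    n_boot: int


def build_cell_table(results_df: pd.DataFrame, truth_df: pd.DataFrame,
                     n_cells: int | None = None) -> pd.DataFrame:
    """Join lightning calls with event labels into one row per cell.

    ``truth_df`` needs ``cell_id`` and ``event_class`` columns (ground truth
    or independently scored labels); cells absent from it are labelled
    ``none``.  ``results_df`` needs ``cell_id`` and ``called_hes``.
    """
    table = results_df[["cell_id", "called_hes"]].copy()
    labels = truth_df.set_index("cell_id")["event_class"] \
        if len(truth_df) else pd.Series(dtype=object)
    table["event_class"] = table["cell_id"].map(labels).fillna("none")
    if n_cells is not None and len(table) != n_cells:
        raise ValueError(f"expected {n_cells} cells, got {len(table)}")
    return table


def _stats(is_lce: np.ndarray, is_apo: np.ndarray, hes: np.ndarray,
           rate_per: int) -> dict[str, float]:
    n = len(is_lce)
    n_lce = int(is_lce.sum())
    n_apo = int(is_apo.sum())
    out = {
        "extrusion_rate": rate_per * (n_lce + n_apo) / n,
        "hes_fraction_lce":
            100.0 * (is_lce & hes).sum() / n_lce if n_lce else np.nan,
        "hes_fraction_apoptotic":
            100.0 * (is_apo & hes).sum() / n_apo if n_apo else np.nan,
        "shrink_incidence": 100.0 * hes.sum() / n,
    }
    return out


def summarize(cell_table: pd.DataFrame, condition: str = "control",
              seed: int = 0, n_boot: int = 2000, rate_per: int = 1000,
              min_presence: float = 0.5,
              presence_fraction: np.ndarray | None = None) -> CohortSummary:
    """Aggregate per-cell calls into a cohort summary with bootstrap CIs.

    ``cell_table`` has one row per cell with ``event_class`` and
    ``called_hes``.  Cells present in less than ``min_presence`` of frames
    without being extruded are excluded from denominators and counted as
    dropouts.
    """
    if len(cell_table) == 0:
        raise ValueError("empty cohort")
    table = cell_table.reset_index(drop=True)
    dropout = 0
    if presence_fraction is not None:
        extruded = table["event_class"].isin(["LCE", "apoptotic_extrusion"])
        keep = (presence_fraction >= min_presence) | extruded.to_numpy()
        dropout = int((~keep).sum())
        table = table[keep].reset_index(drop=True)
    is_lce = (table["event_class"] == "LCE").to_numpy()
    is_apo = (table["event_class"] == "apoptotic_extrusion").to_numpy()
    hes = table["called_hes"].to_numpy(dtype=bool)
    n = len(table)
    point = _stats(is_lce, is_apo, hes, rate_per)

    rng = np.random.default_rng(seed)
    boots = {k: [] for k in STATISTICS}
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        s = _stats(is_lce[idx], is_apo[idx], hes[idx], rate_per)
        for k in STATISTICS:
            boots[k].append(s[k])
    cis = {}
    for k in STATISTICS:
        vals = np.asarray(boots[k], dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals):
            cis[k] = (float(np.percentile(vals, 2.5)),
                      float(np.percentile(vals, 97.5)))
        else:
            cis[k] = (np.nan, np.nan)

    shrink_no_ext = int((hes & ~is_lce & ~is_apo).sum())
    return CohortSummary(
        condition=condition, n_cells=n,
        n_extrusions=int(is_lce.sum() + is_apo.sum()),
        n_lce=int(is_lce.sum()), n_apoptotic=int(is_apo.sum()),
        extrusion_rate=point["extrusion_rate"],
        hes_fraction_lce=None if np.isnan(point["hes_fraction_lce"])
            else point["hes_fraction_lce"],
        hes_fraction_apoptotic=None
            if np.isnan(point["hes_fraction_apoptotic"])
            else point["hes_fraction_apoptotic"],
        shrink_incidence=point["shrink_incidence"],
        shrink_no_extrude_count=shrink_no_ext, dropout_count=dropout,
        rate_per=rate_per, seed=seed, bootstrap_ci=cis,
        cell_table=table)


def _stat_from_table(table: pd.DataFrame, statistic: str,
                     rate_per: int) -> float:
    is_lce = (table["event_class"] == "LCE").to_numpy()
    is_apo = (table["event_class"] == "apoptotic_extrusion").to_numpy()
    hes = table["called_hes"].to_numpy(dtype=bool)
    return _stats(is_lce, is_apo, hes, rate_per)[statistic]


def fold_change(baseline: CohortSummary, treated: CohortSummary,
                statistic: str = "shrink_incidence", seed: int = 0,
                n_boot: int = 2000) -> FoldChange:
    """Ratio treated / baseline of a named statistic with a bootstrap CI.

    Both cohorts are resampled over cells.  A zero (or undefined) statistic
    in the baseline cohort is an error: report counts instead of a ratio.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    denom = _stat_from_table(baseline.cell_table, statistic, baseline.rate_per)
    numer = _stat_from_table(treated.cell_table, statistic, treated.rate_per)
    if not np.isfinite(denom) or denom == 0:
        raise ValueError(
            f"{statistic} is zero/undefined in the baseline cohort; "
            "report raw counts instead of a fold-change")
    rng = np.random.default_rng(seed)
    nb, nt = len(baseline.cell_table), len(treated.cell_table)
    ratios = []
    tb, tt = baseline.cell_table, treated.cell_table
    b_lce = (tb["event_class"] == "LCE").to_numpy()
    b_apo = (tb["event_class"] == "apoptotic_extrusion").to_numpy()
    b_hes = tb["called_hes"].to_numpy(dtype=bool)
    t_lce = (tt["event_class"] == "LCE").to_numpy()
    t_apo = (tt["event_class"] == "apoptotic_extrusion").to_numpy()
    t_hes = tt["called_hes"].to_numpy(dtype=bool)
    for _ in range(n_boot):
        bi = rng.integers(0, nb, nb)
        ti = rng.integers(0, nt, nt)
        d = _stats(b_lce[bi], b_apo[bi], b_hes[bi], baseline.rate_per)[statistic]
        u = _stats(t_lce[ti], t_apo[ti], t_hes[ti], treated.rate_per)[statistic]
        if np.isfinite(d) and d > 0 and np.isfinite(u):
            ratios.append(u / d)
    ratios = np.asarray(ratios)
    return FoldChange(statistic=statistic,
                      baseline_condition=baseline.condition,
                      treated_condition=treated.condition,
                      ratio=float(numer / denom),
                      ci_low=float(np.percentile(ratios, 2.5)),
                      ci_high=float(np.percentile(ratios, 97.5)),
                      n_boot=n_boot)


def report(cohorts: Sequence[CohortSummary],
           fold_changes: Sequence[FoldChange] = (),
           directory: str | Path | None = None,
           metadata: Mapping | None = None) -> str:
    """Machine-readable CSVs plus a human-readable text table.

    Output is a deterministic function of its inputs (the config hash and
    seed are embedded; no timestamps), so regenerating from the same inputs
    is byte-identical.
    """
    if not cohorts:
        raise ValueError("need at least one cohort")
    rows = [c.as_row() for c in cohorts]
    summary_df = pd.DataFrame(rows)
    fc_df = pd.DataFrame([vars(f) for f in fold_changes]) if fold_changes \
        else pd.DataFrame(columns=["statistic", "baseline_condition",
                                   "treated_condition", "ratio",
                                   "ci_low", "ci_high", "n_boot"])
    meta = dict(metadata or {})
    meta_json = json.dumps(meta, sort_keys=True, default=str)
    config_hash = hashlib.sha256(meta_json.encode()).hexdigest()[:16]

    lines = ["cohort summary", "=" * 70]
    for c in cohorts:
        lines.append(
            f"{c.condition}: n={c.n_cells} extrusions={c.n_extrusions} "
            f"(LCE {c.n_lce}, apoptotic {c.n_apoptotic}) "
            f"rate={c.extrusion_rate:.2f}/{c.rate_per} "
            f"HES|LCE={_fmt(c.hes_fraction_lce)}% "
            f"HES|apoptotic={_fmt(c.hes_fraction_apoptotic)}% "
            f"shrink incidence={c.shrink_incidence:.2f}% "
            f"(seed {c.seed})")
    for f in fold_changes:
        lines.append(f"fold change {f.treated_condition}/"
                     f"{f.baseline_condition} [{f.statistic}]: "
                     f"{f.ratio:.2f}x (95% CI {f.ci_low:.2f}-{f.ci_high:.2f})")
    lines.append(f"config hash: {config_hash}")
    text = "\n".join(lines) + "\n"

    if directory is not None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        summary_df.to_csv(directory / "cohort_summary.csv", index=False)
        fc_df.to_csv(directory / "fold_changes.csv", index=False)
        (directory / "summary.txt").write_text(text)
    return text


def _fmt(x: float | None) -> str:
    return "NA" if x is None else f"{x:.1f}"
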