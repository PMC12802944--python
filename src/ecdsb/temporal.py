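"""Clustered versus temporally isolated DSBs in surviving cells.

Two opposing temporal regimes shape the fate of cleaved ecDNA: many DSBs
packed into a short interval (clustered cleavage, linked to micronucleus
expulsion of damaged ecDNA) versus single DSBs with no other breaks nearby
in time (temporally isolated cleavage, linked to small-indel formation and
HDR knock-in). This module computes sliding-window DSB maxima, the fraction
of cells exceeding a clustering threshold, the optimization of that
threshold against micronucleus-positive fractions, the three-way per-copy
categorization (isolated single / non-isolated single / multiple), and
Pearson correlation with a Fisher-z confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dsb import CellDSBRecord

__all__ = [
    "ISOLATED_SINGLE",
    "NON_ISOLATED_SINGLE",
    "MULTIPLE",
    "windowed_max_dsb",
    "clustered_cell_fraction",
    "ThresholdChoice",
    "optimize_cluster_threshold",
    "classify_copy_isolation",
    "isolated_fraction_by_condition",
    "pearson_with_ci",
    "PearsonResult",
    "MICRONUCLEI_POSITIVE_0C",
    "MICRONUCLEI_POSITIVE_UNTREATED",
    "SMALL_INDEL_PER_ISOLATED",
]

# Per-copy temporal categories for copies cut inside the sampling window.
ISOLATED_SINGLE = "isolated_single"
NON_ISOLATED_SINGLE = "non_isolated_single"
MULTIPLE = "multiple"

#: Micronucleus-positive cell fractions reported for the standard guide and
#: for untreated cells; per-condition values beyond these two are
#: user-supplied input.
MICRONUCLEI_POSITIVE_0C = 0.707
MICRONUCLEI_POSITIVE_UNTREATED = 0.164

#: Empirical scaling between temporally isolated DSB copies and observed
#: small-indel fractions (~44% of isolated DSBs end up as small indels).
SMALL_INDEL_PER_ISOLATED = 0.44


def windowed_max_dsb(
    record: CellDSBRecord, window: int = 5, mode: str = "sliding"
) -> int:
    """Maximum DSB count over ``window``-frame windows in the sampling window.

    ``sliding`` (default) scans every stride-1 window of consecutive frames;
    ``disjoint`` partitions the sampling window into consecutive blocks.
    ``windowed_max_dsb(record, 1)`` equals ``record.max_dsb``.
    """
    if not 1 <= window <= record.sampling_window:
        raise ValueError("need 1 <= window <= sampling_window")
    counts = record.frame_counts
    if mode == "sliding":
        sums = np.convolve(counts, np.ones(window, dtype=np.int64), mode="valid")
    elif mode == "disjoint":
        n_full = counts.size // window
        trimmed = counts[: n_full * window].reshape(n_full, window)
        sums = trimmed.sum(axis=1)
        if counts.size % window:
            sums = np.append(sums, counts[n_full * window :].sum())
    else:
        raise ValueError(f"unknown window mode: {mode!r}")
    return int(sums.max()) if sums.size else 0


def clustered_cell_fraction(
    records: Sequence[CellDSBRecord],
    threshold: int,
    window: int = 5,
    mode: str = "sliding",
) -> float:
    """Fraction of cells whose windowed max DSB count reaches ``threshold``."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    if not records:
        raise ValueError("empty record list")
    hits = sum(windowed_max_dsb(r, window, mode) >= threshold for r in records)
    return hits / len(records)


@dataclass(frozen=True)
class ThresholdChoice:
    """Best clustering threshold with its correlation and SSR diagnostics."""

    threshold: int
    r: float
    ssr: float
    per_threshold: pd.DataFrame  # columns: threshold, r, ssr


def optimize_cluster_threshold(
    sim_fractions_by_condition: Mapping[int, Mapping[str, float]],
    micronuclei_fractions_by_condition: Mapping[str, float],
    candidate_thresholds: Sequence[int] | None = None,
) -> ThresholdChoice:
    """Pick the clustering threshold whose cell fractions best track micronuclei.

    ``sim_fractions_by_condition`` maps threshold -> {condition: clustered
    cell fraction}. For each candidate threshold the Pearson correlation and
    SSR against the micronucleus-positive fractions are computed over the
    shared conditions (>= 3 required); the threshold maximizing r wins, ties
    broken by the smaller SSR.
    """
    if candidate_thresholds is None:
        candidate_thresholds = sorted(sim_fractions_by_condition)
    conds = list(micronuclei_fractions_by_condition)
    if len(conds) < 3:
        raise ValueError("need at least 3 paired conditions")
    mn = np.array([micronuclei_fractions_by_condition[c] for c in conds])
    if np.allclose(mn, mn[0]):
        raise ValueError("micronuclei fractions are constant; correlation undefined")
    rows = []
    for t in candidate_thresholds:
        sim = np.array([sim_fractions_by_condition[t][c] for c in conds])
        if np.allclose(sim, sim[0]):
            raise ValueError(
                f"clustered fractions constant at threshold {t}; correlation undefined"
            )
        r = float(stats.pearsonr(sim, mn).statistic)
        ssr = float(np.sum((sim - mn) ** 2))
        rows.append((int(t), r, ssr))
    table = pd.DataFrame(rows, columns=["threshold", "r", "ssr"])
    best = table.sort_values(["r", "ssr"], ascending=[False, True]).iloc[0]
    return ThresholdChoice(
        threshold=int(best["threshold"]),
        r=float(best["r"]),
        ssr=float(best["ssr"]),
        per_threshold=table,
    )


def classify_copy_isolation(
    record: CellDSBRecord, neighborhood: int = 5
) -> list[str]:
    """Categorize every in-window cut copy of a cell by temporal context.

    For a copy cut at frame t (with ``h = neighborhood // 2``):

    - ``multiple``: another copy of the same cell was cut at exactly frame t;
    - ``non_isolated_single``: no same-frame co-cut, but another copy was cut
      within [t - h, t + h];
    - ``isolated_single``: no other copy cut anywhere in that neighborhood.

    Neighboring DSBs are looked up on the full time axis, so a DSB just
    outside the sampling window still de-isolates one inside it; categories
    are only assigned to in-window copies. Returns one category per
    in-window cut copy, in ``dsb_frames`` order.
    """
    if neighborhood < 1:
        raise ValueError("neighborhood must be >= 1")
    half = neighborhood // 2
    all_frames = record.dsb_frames[record.dsb_frames >= 1]
    window_frames = record.window_frames
    counts = np.bincount(all_frames) if all_frames.size else np.array([0])
    categories = []
    for t in window_frames:
        if counts[t] > 1:
            categories.append(MULTIPLE)
            continue
        lo, hi = max(1, t - half), min(counts.size - 1, t + half)
        neighbors = counts[lo : hi + 1].sum() - 1
        categories.append(NON_ISOLATED_SINGLE if neighbors > 0 else ISOLATED_SINGLE)
    return categories


def isolated_fraction_by_condition(
    records_by_condition: Mapping[str, Sequence[CellDSBRecord]],
    neighborhood: int = 5,
) -> pd.DataFrame:
    """Per-condition isolated-DSB fractions and the three-way split of cut copies.

    The headline quantity ``isolated_fraction`` is isolated-single copies
    over ALL ecDNA copies of the condition's (surviving) cells; the
    ``*_of_cut`` columns give the split among cut copies only (summing to 1).
    """
    rows = []
    for cond, records in records_by_condition.items():
        total_copies = sum(r.copy_number for r in records)
        tally = {ISOLATED_SINGLE: 0, NON_ISOLATED_SINGLE: 0, MULTIPLE: 0}
        for r in records:
            for cat in classify_copy_isolation(r, neighborhood):
                tally[cat] += 1
        n_cut = sum(tally.values())
        rows.append(
            {
                "condition": cond,
                "total_copies": total_copies,
                "cut_copies": n_cut,
                "isolated_fraction": tally[ISOLATED_SINGLE] / total_copies
                if total_copies
                else 0.0,
                "isolated_of_cut": tally[ISOLATED_SINGLE] / n_cut if n_cut else 0.0,
                "non_isolated_of_cut": tally[NON_ISOLATED_SINGLE] / n_cut
                if n_cut
                else 0.0,
                "multiple_of_cut": tally[MULTIPLE] / n_cut if n_cut else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("condition")


@dataclass(frozen=True)
class PearsonResult:
    r: float
    ci_low: float
    ci_high: float
    p: float


def pearson_with_ci(
    x: Sequence[float], y: Sequence[float], confidence: float = 0.95
) -> PearsonResult:
    """Pearson r with a Fisher-z confidence interval and two-sided p."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 points")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("constant input vector; correlation undefined")
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=confidence)
    return PearsonResult(
        r=float(res.statistic),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        p=float(res.pvalue),
    )
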