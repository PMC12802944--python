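"""Synthetic untreated ecDNA copy-number populations.

ecDNA-positive cancer cells carry oncogene amplicons on extrachromosomal
circles at highly heterogeneous copy number: a CORL23-like line shows a
right-skewed per-cell distribution with a median of ~86 MYC-ecDNA copies.
No numeric histogram of that distribution is published, so this module
generates one from a calibrated negative-binomial family and provides the
frequency-table plumbing (bin width 10, population scaling) that the
downstream survival fit operates on.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CopyNumberPopulation",
    "PopulationFrequencyTable",
    "PseudoExperiment",
    "generate_untreated_population",
    "make_frequency_table",
    "expand_table_to_cells",
    "generate_pseudo_experiment",
    "DEFAULT_MEDIAN",
    "DEFAULT_DISPERSION",
]

#: Median MYC-ecDNA copy number of the untreated CORL23-like population.
DEFAULT_MEDIAN = 86.0

#: Negative-binomial shape parameter (inverse over-dispersion). Calibrated so
#: the untreated distribution combines the 86-copy median with a low tail of
#: ~11% of cells below 33 copies; see docs/methods.md for the calibration.
DEFAULT_DISPERSION = 2.5


@dataclass(frozen=True)
class CopyNumberPopulation:
    """Per-cell ecDNA copy counts for one condition.

    Attributes
    ----------
    copy_numbers : ndarray of int
        Non-negative ecDNA copy count for every cell.
    label : str
        Free-text condition tag.
    seed : int or None
        RNG seed the population was generated with (None for derived
        populations such as table expansions without randomness).
    """

    copy_numbers: np.ndarray
    label: str = "untreated"
    seed: int | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.copy_numbers, dtype=np.int64)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("copy_numbers must be a non-empty 1-D array")
        if (arr < 0).any():
            raise ValueError("copy numbers must be non-negative")
        object.__setattr__(self, "copy_numbers", arr)

    @property
    def n_cells(self) -> int:
        return int(self.copy_numbers.size)

    @property
    def median(self) -> float:
        return float(np.median(self.copy_numbers))

    def to_csv(self, path_or_buf) -> None:
        """Write one row per cell: ``cell_id, copy_number``."""
        df = pd.DataFrame(
            {"cell_id": np.arange(self.n_cells), "copy_number": self.copy_numbers}
        )
        df.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf, label: str = "loaded") -> "CopyNumberPopulation":
        df = pd.read_csv(path_or_buf)
        return cls(df["copy_number"].to_numpy(dtype=np.int64), label=label)


@dataclass(frozen=True)
class PopulationFrequencyTable:
    """Binned copy-number histogram scaled to a cell population.

    Bins are half-open ``[lo, lo + bin_width)`` with the lowest edge at 0 and
    contiguous coverage of the observed range. ``counts`` hold the per-bin
    cell count times ``scale_factor``.
    """

    bin_width: int
    bin_edges: np.ndarray  # length n_bins + 1, increasing
    counts: np.ndarray  # length n_bins, non-negative
    scale_factor: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=np.int64)
        counts = np.asarray(self.counts, dtype=np.float64)
        if self.bin_width < 1:
            raise ValueError("bin_width must be >= 1")
        if edges.size != counts.size + 1:
            raise ValueError("need len(bin_edges) == len(counts) + 1")
        if (np.diff(edges) != self.bin_width).any():
            raise ValueError("bins must be contiguous with uniform width")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def midpoints(self) -> np.ndarray:
        """Integer midpoint of each half-open bin (``lo + bin_width // 2``)."""
        return self.bin_edges[:-1] + self.bin_width // 2

    def to_csv(self, path_or_buf) -> None:
        """Write one row per bin: ``bin_lo, bin_hi, count``."""
        df = pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "count": self.counts,
            }
        )
        df.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(
        cls, path_or_buf, scale_factor: int = 1, label: str = "loaded"
    ) -> "PopulationFrequencyTable":
        df = pd.read_csv(path_or_buf)
        lo = df["bin_lo"].to_numpy(dtype=np.int64)
        hi = df["bin_hi"].to_numpy(dtype=np.int64)
        width = int(hi[0] - lo[0])
        edges = np.concatenate([lo, hi[-1:]])
        return cls(
            bin_width=width,
            bin_edges=edges,
            counts=df["count"].to_numpy(dtype=np.float64),
            scale_factor=scale_factor,
            label=label,
        )


@dataclass(frozen=True)
class PseudoExperiment:
    """Synthetic observation set for parameter-recovery testing.

    Holds the untreated frequency table, per-condition post-selection tables
    with relative surviving cell fractions, and the (Mt, f) truth used to
    generate them, so that the grid fit can be validated against known
    parameters.
    """

    untreated: PopulationFrequencyTable
    observed_tables: Mapping[str, PopulationFrequencyTable]
    observed_fractions: Mapping[str, float]
    true_Mt: int
    true_f_by_condition: Mapping[str, int]

    def __post_init__(self) -> None:
        for cond, frac in self.observed_fractions.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"surviving fraction for {cond!r} outside [0, 1]")


def _calibrated_mean(median_target: float, dispersion: float) -> float:
    """Negative-binomial mean whose distribution median equals the target.

    Solved by bisection on the discrete quantile function; the median is a
    step function of the mean, so we return the smallest mean reaching it.
    """
    lo, hi = 1e-6, max(10.0 * median_target, 50.0)
    while stats.nbinom.ppf(0.5, dispersion, dispersion / (dispersion + hi)) < median_target:
        hi *= 2.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        p = dispersion / (dispersion + mid)
        if stats.nbinom.ppf(0.5, dispersion, p) < median_target:
            lo = mid
        else:
            hi = mid
    return hi


def generate_untreated_population(
    n_cells: int,
    median_target: float = DEFAULT_MEDIAN,
    dispersion: float = DEFAULT_DISPERSION,
    seed: int = 0,
    label: str = "untreated",
) -> CopyNumberPopulation:
    """Draw a CORL23-like untreated ecDNA copy-number population.

    Copy numbers are negative-binomial with shape ``dispersion`` and mean
    calibrated so the distribution median equals ``median_target``. Smaller
    ``dispersion`` means heavier heterogeneity and more low-copy cells; the
    default combination (86, 2.5) leaves ~11% of cells below 33 copies.

    Parameters
    ----------
    n_cells : int
        Number of cells to draw (>= 1).
    median_target : float
        Target median copy number (> 0); default 86.
    dispersion : float
        Negative-binomial shape (> 0); default 2.5.
    seed : int
        RNG seed; identical (parameters, seed) reproduce identical draws.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if median_target <= 0:
        raise ValueError("median_target must be positive")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    mu = _calibrated_mean(median_target, dispersion)
    p = dispersion / (dispersion + mu)
    rng = np.random.default_rng(seed)
    draws = rng.negative_binomial(dispersion, p, size=n_cells)
    return CopyNumberPopulation(draws.astype(np.int64), label=label, seed=seed)


def make_frequency_table(
    population: CopyNumberPopulation,
    bin_width: int = 10,
    scale_factor: int = 1000,
) -> PopulationFrequencyTable:
    """Bin a population into half-open bins and scale the counts.

    The default (bin width 10, scale 1000) mirrors how the untreated
    histogram is expanded into the "initial population" the survival model
    evolves: each observed cell stands for 1000 simulated cells.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    if scale_factor < 1:
        raise ValueError("scale_factor must be >= 1")
    values = population.copy_numbers
    n_bins = int(values.max()) // bin_width + 1
    edges = np.arange(0, (n_bins + 1) * bin_width, bin_width, dtype=np.int64)
    raw, _ = np.histogram(values, bins=edges)
    return PopulationFrequencyTable(
        bin_width=bin_width,
        bin_edges=edges,
        counts=raw.astype(np.float64) * scale_factor,
        scale_factor=scale_factor,
        label=population.label,
    )


def expand_table_to_cells(
    table: PopulationFrequencyTable,
    assignment: str = "midpoint",
    seed: int = 0,
    label: str | None = None,
) -> CopyNumberPopulation:
    """Materialize one cell per table count unit.

    ``midpoint`` (default) assigns every cell in a bin the integer bin
    midpoint — deterministic and reviewable. ``uniform_within_bin`` draws an
    integer uniformly from the half-open bin, seeded.
    """
    counts = np.round(table.counts).astype(np.int64)
    if (np.abs(table.counts - counts) > 1e-9).any():
        raise ValueError("table counts must be integral to expand into cells")
    if assignment == "midpoint":
        values = np.repeat(table.midpoints, counts)
    elif assignment == "uniform_within_bin":
        rng = np.random.default_rng(seed)
        lows = np.repeat(table.bin_edges[:-1], counts)
        values = lows + rng.integers(0, table.bin_width, size=lows.size)
    else:
        raise ValueError(f"unknown assignment rule: {assignment!r}")
    return CopyNumberPopulation(
        values, label=label if label is not None else table.label, seed=seed
    )


def generate_pseudo_experiment(
    untreated: CopyNumberPopulation,
    true_Mt: int,
    true_f_by_condition: Mapping[str, int],
    seed: int = 0,
    bin_width: int = 10,
    mode: str = "bernoulli",
) -> PseudoExperiment:
    """Run the full forward model and package the observations with the truth.

    For each condition the untreated population is pushed through the DSB
    simulation and the lethal-threshold survival filter (stochastic
    ``bernoulli`` survivors by default, deterministic ``expected_weight``
    optionally), producing a post-selection frequency table and a relative
    surviving cell fraction, together with the generating (Mt, f).
    """
    # local import: survival depends on dsb, which has no dependency back here
    from .dsb import SimulationConfig, simulate_population
    from .survival import apply_survival, expected_condition_summary, summarize_population

    if true_Mt < 1:
        raise ValueError("true_Mt must be >= 1")
    if any(f < 1 for f in true_f_by_condition.values()):
        raise ValueError("all binding frequencies must be >= 1")
    if mode not in ("bernoulli", "expected_weight", "analytic"):
        raise ValueError(f"unknown observation mode: {mode!r}")

    untreated_table = make_frequency_table(untreated, bin_width=bin_width, scale_factor=1)
    tables: dict[str, PopulationFrequencyTable] = {}
    fractions: dict[str, float] = {}
    for i, (cond, f) in enumerate(true_f_by_condition.items()):
        if mode == "analytic":
            summary = expected_condition_summary(
                untreated, int(f), true_Mt, bin_width=bin_width
            )
        else:
            derived = np.random.SeedSequence([seed, i]).generate_state(1)[0]
            config = SimulationConfig(
                binding_frequency=int(f), seed=int(derived % 2**31)
            )
            records = simulate_population(untreated, config)
            survivors = apply_survival(
                records,
                Mt=true_Mt,
                mode=mode,
                rng=np.random.default_rng([seed, 1000 + i]),
            )
            summary = summarize_population(
                survivors, bin_width=bin_width, initial_size=untreated.n_cells
            )
        tables[cond] = summary.table
        fractions[cond] = summary.surviving_fraction
    return PseudoExperiment(
        untreated=untreated_table,
        observed_tables=tables,
        observed_fractions=fractions,
        true_Mt=int(true_Mt),
        true_f_by_condition=dict(true_f_by_condition),
    )
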