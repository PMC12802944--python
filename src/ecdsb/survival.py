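"""Total-DSB-dependent cell survival and (Mt, f) grid fitting.

A cell's survival probability declines linearly with the number of DSBs it
accumulated inside the sampling window:

    P(cp1) = 1 - cp1 / Mt   for 0 <= cp1 <= Mt,   0 otherwise,

where cp1 is the total DSB count and Mt the lethal threshold (fitted
published value: 33). Applied to a heterogeneous ecDNA population this
preferentially eliminates high-copy cells, reshaping the copy-number
distribution; the lethal threshold and per-condition Cas9 binding
frequencies are recovered by a sum-of-squared-residuals grid search against
observed post-selection histograms, staged as in the original analysis:
first fix Mt on the highest-activity condition, then fit f per condition at
that Mt.

Because the total DSB count of a cell with n copies is exactly
Binomial(n, 1 - (1 - w/T)^f), the expected-weight forward model used for
fitting is evaluated in closed form (a finite binomial sum), which makes the
SSR surface fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dsb import CellDSBRecord, SimulationConfig, window_hit_probability
from .population import (
    CopyNumberPopulation,
    PopulationFrequencyTable,
    PseudoExperiment,
    expand_table_to_cells,
)

__all__ = [
    "survival_probability",
    "apply_survival",
    "summarize_population",
    "SurvivorPopulation",
    "PopulationSummary",
    "expected_survivor_weights",
    "CleavageSelectionModel",
    "CleavageFitResult",
    "fit_threshold_and_frequency",
    "PUBLISHED_MT",
    "PUBLISHED_F_MAP",
    "DEFAULT_F_GRID",
]

#: Published lethal threshold: ~33 total DSBs in the sampling window kill a cell.
PUBLISHED_MT = 33

#: Published Cas9 binding frequencies per sgRNA condition ([0C] is the
#: standard guide; [5C]..[20C] are safeguard guides with 5'-C extensions).
PUBLISHED_F_MAP: dict[str, int] = {
    "[0C]": 770,
    "[5C]": 170,
    "[10C]": 40,
    "[15C]": 30,
    "[20C]": 3,
}

#: Default log-ish frequency grid for the fit; includes the published values.
DEFAULT_F_GRID: tuple[int, ...] = (
    1, 2, 3, 5, 10, 20, 30, 40, 50, 70, 100, 170, 300, 500, 770,
    1000, 2000, 5000, 10000,
)


def survival_probability(cp1, Mt: int):
    """Linear-decline survival probability of a cell with ``cp1`` total DSBs.

    Returns ``1 - cp1/Mt`` for ``0 <= cp1 <= Mt`` and 0 beyond the lethal
    threshold. Accepts scalars or arrays; always in [0, 1].
    """
    if Mt < 1:
        raise ValueError("Mt must be >= 1")
    cp1_arr = np.asarray(cp1, dtype=np.float64)
    if (cp1_arr < 0).any():
        raise ValueError("total DSB count cannot be negative")
    p = np.where(cp1_arr <= Mt, 1.0 - cp1_arr / Mt, 0.0)
    return float(p) if np.isscalar(cp1) else p


@dataclass(frozen=True)
class SurvivorPopulation:
    """Outcome of the survival filter.

    ``bernoulli`` mode keeps a stochastic subset (weights all 1);
    ``expected_weight`` mode keeps every record with its survival
    probability attached as a weight.
    """

    records: list[CellDSBRecord]
    weights: np.ndarray
    mode: str
    Mt: int

    @property
    def copy_numbers(self) -> np.ndarray:
        return np.array([r.copy_number for r in self.records], dtype=np.int64)

    @property
    def effective_size(self) -> float:
        return float(self.weights.sum())


def apply_survival(
    records: Sequence[CellDSBRecord],
    Mt: int,
    mode: str = "bernoulli",
    rng: np.random.Generator | None = None,
) -> SurvivorPopulation:
    """Filter a simulated population through the lethal-threshold survival rule."""
    probs = survival_probability(
        np.array([r.total_dsb for r in records], dtype=np.float64), Mt
    )
    if mode == "bernoulli":
        if rng is None:
            raise ValueError("bernoulli mode needs an rng")
        keep = rng.random(len(records)) < probs
        kept = [r for r, k in zip(records, keep) if k]
        return SurvivorPopulation(kept, np.ones(len(kept)), mode, Mt)
    if mode == "expected_weight":
        return SurvivorPopulation(list(records), probs, mode, Mt)
    raise ValueError(f"unknown survival mode: {mode!r}")


@dataclass(frozen=True)
class PopulationSummary:
    """Binned survivor distribution with fraction and mean copy number."""

    table: PopulationFrequencyTable
    surviving_fraction: float
    mean_copy_number: float  # NaN flags an empty survivor set


def summarize_population(
    survivors: SurvivorPopulation,
    bin_width: int = 10,
    initial_size: int | None = None,
) -> PopulationSummary:
    """Summarize survivors: binned distribution, relative fraction, mean copies.

    ``initial_size`` is the pre-selection cell count the fraction is taken
    relative to; defaults to the number of records (which is only correct in
    expected_weight mode, where no record is dropped).
    """
    if initial_size is None:
        initial_size = len(survivors.records)
    cn = survivors.copy_numbers
    w = survivors.weights
    total_w = w.sum()
    if total_w > 0:
        n_bins = int(cn.max()) // bin_width + 1
        mean_cn = float(np.average(cn, weights=w))
    else:
        n_bins = 1
        mean_cn = float("nan")
    edges = np.arange(0, (n_bins + 1) * bin_width, bin_width, dtype=np.int64)
    counts, _ = np.histogram(cn, bins=edges, weights=w)
    table = PopulationFrequencyTable(
        bin_width=bin_width, bin_edges=edges, counts=counts, scale_factor=1
    )
    return PopulationSummary(
        table=table,
        surviving_fraction=float(total_w / initial_size),
        mean_copy_number=mean_cn,
    )


def expected_survivor_weights(
    copy_numbers: np.ndarray,
    f: int,
    Mt: int,
    config: SimulationConfig | None = None,
) -> np.ndarray:
    """Closed-form expected survival weight per cell.

    For a cell with n copies the window-total DSB count is
    D ~ Binomial(n, p) with p = 1 - (1 - w/T)^f, so the expected weight is
    sum_{d=0}^{Mt} P(D = d) (1 - d/Mt) — deterministic, no simulation.
    """
    if config is None:
        config = SimulationConfig(binding_frequency=f)
    p_hit = window_hit_probability(f, config.sampling_window, config.n_frames)
    cn = np.asarray(copy_numbers, dtype=np.int64)
    uniq, inv = np.unique(cn, return_inverse=True)
    d = np.arange(0, Mt + 1)
    pmf = stats.binom.pmf(d[None, :], uniq[:, None], p_hit)
    weights_uniq = pmf @ (1.0 - d / Mt)
    return weights_uniq[inv]


def _expected_binned(
    copy_numbers: np.ndarray,
    f: int,
    Mt: int,
    bin_width: int,
    n_bins: int,
    config: SimulationConfig | None,
) -> tuple[np.ndarray, float]:
    """Expected survivor bin counts (length ``n_bins``) and surviving fraction."""
    w = expected_survivor_weights(copy_numbers, f, Mt, config)
    edges = np.arange(0, (n_bins + 1) * bin_width, bin_width)
    counts, _ = np.histogram(copy_numbers, bins=edges, weights=w)
    return counts, float(w.sum() / copy_numbers.size)


def expected_condition_summary(
    population: CopyNumberPopulation,
    f: int,
    Mt: int,
    bin_width: int = 10,
    config: SimulationConfig | None = None,
) -> PopulationSummary:
    """Fully analytic forward summary of one condition (no simulation).

    Same quantity as simulate -> apply_survival(expected_weight) ->
    summarize, but with the binomial window-hit law evaluated in closed
    form, so the result carries no Monte-Carlo noise at all.
    """
    cn = population.copy_numbers
    n_bins = int(cn.max()) // bin_width + 1
    counts, frac = _expected_binned(cn, f, Mt, bin_width, n_bins, config)
    edges = np.arange(0, (n_bins + 1) * bin_width, bin_width, dtype=np.int64)
    w = expected_survivor_weights(cn, f, Mt, config)
    mean_cn = float(np.average(cn, weights=w)) if w.sum() > 0 else float("nan")
    table = PopulationFrequencyTable(
        bin_width=bin_width, bin_edges=edges, counts=counts, scale_factor=1
    )
    return PopulationSummary(table, frac, mean_cn)


class CleavageFitResult:
    """Results of the staged (Mt, f) grid fit.

    Attributes
    ----------
    ssr_surface : DataFrame
        Stage-1 SSR over the (Mt, f) grid for the reference condition
        (index: Mt, columns: f).
    best_Mt, best_f : int
        Joint argmin of the stage-1 surface (ties broken toward the
        smallest Mt, then the smallest f).
    f_by_condition : dict
        Stage-2 per-condition best frequency at the fixed ``best_Mt``.
    ssr_f_by_condition : DataFrame
        Stage-2 SSR curves (index: f, columns: condition).
    """

    def __init__(
        self,
        ssr_surface: pd.DataFrame,
        best_Mt: int,
        best_f: int,
        f_by_condition: dict[str, int],
        ssr_f_by_condition: pd.DataFrame,
        comparison_target: str,
        reference_condition: str,
    ) -> None:
        self.ssr_surface = ssr_surface
        self.best_Mt = best_Mt
        self.best_f = best_f
        self.f_by_condition = f_by_condition
        self.ssr_f_by_condition = ssr_f_by_condition
        self.comparison_target = comparison_target
        self.reference_condition = reference_condition

    def summary(self) -> str:
        lines = [
            "Cleavage-selection grid fit",
            "=" * 42,
            f"comparison target     : {self.comparison_target}",
            f"reference condition   : {self.reference_condition}",
            f"lethal threshold Mt   : {self.best_Mt}",
            f"reference frequency f : {self.best_f}",
            "-" * 42,
            f"{'condition':<14}{'fitted f':>10}{'min SSR':>14}",
        ]
        for cond, f in self.f_by_condition.items():
            ssr = self.ssr_f_by_condition.loc[f, cond]
            lines.append(f"{cond:<14}{f:>10}{ssr:>14.4g}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<CleavageFitResult Mt={self.best_Mt} "
            f"f={self.f_by_condition}>"
        )


class CleavageSelectionModel:
    """Grid-search model for the lethal threshold and binding frequencies.

    Built from per-condition observed post-selection histograms (and
    optionally relative surviving cell fractions) plus the untreated initial
    population; ``fit()`` runs the deterministic expected-weight forward
    model over the grid and returns a :class:`CleavageFitResult`.

    Parameters
    ----------
    observed_tables : mapping condition -> PopulationFrequencyTable
    untreated : CopyNumberPopulation or PopulationFrequencyTable
        Initial population the forward model evolves; a table is expanded
        one-cell-per-count at bin midpoints.
    observed_fractions : mapping condition -> float, optional
        Surviving cell fraction relative to the untreated population. When
        given, distributions are compared as survivors-per-initial-cell
        (shape x fraction); otherwise as conditional shapes.
    comparison_target : {"distribution", "fraction", "joint"}
    """

    def __init__(
        self,
        observed_tables: Mapping[str, PopulationFrequencyTable],
        untreated: CopyNumberPopulation | PopulationFrequencyTable,
        observed_fractions: Mapping[str, float] | None = None,
        comparison_target: str = "distribution",
        Mt_grid: Sequence[int] | None = None,
        f_grid: Sequence[int] | None = None,
        config: SimulationConfig | None = None,
    ) -> None:
        if not observed_tables:
            raise ValueError("need at least one observed condition")
        widths = {t.bin_width for t in observed_tables.values()}
        if len(widths) != 1:
            raise ValueError("observed tables must share a bin_width")
        if comparison_target not in ("distribution", "fraction", "joint"):
            raise ValueError(f"unknown comparison target: {comparison_target!r}")
        if comparison_target in ("fraction", "joint") and observed_fractions is None:
            raise ValueError("fraction-based targets need observed_fractions")
        if isinstance(untreated, PopulationFrequencyTable):
            if untreated.bin_width not in widths:
                raise ValueError("untreated table bin_width mismatch")
            untreated = expand_table_to_cells(untreated, assignment="midpoint")
        self.bin_width = widths.pop()
        self.observed_tables = dict(observed_tables)
        self.observed_fractions = (
            dict(observed_fractions) if observed_fractions is not None else None
        )
        self.untreated = untreated
        self.comparison_target = comparison_target
        self.Mt_grid = tuple(Mt_grid) if Mt_grid is not None else tuple(range(1, 101))
        self.f_grid = tuple(f_grid) if f_grid is not None else DEFAULT_F_GRID
        self.config = config
        max_obs = max(t.bin_edges[-1] for t in self.observed_tables.values())
        max_cn = int(self.untreated.copy_numbers.max()) + self.bin_width
        self.n_bins = int(max(max_obs, max_cn)) // self.bin_width + 1

    @classmethod
    def from_pseudo_experiment(
        cls, experiment: PseudoExperiment, **kwargs
    ) -> "CleavageSelectionModel":
        return cls(
            observed_tables=experiment.observed_tables,
            untreated=experiment.untreated,
            observed_fractions=experiment.observed_fractions,
            **kwargs,
        )

    # -- residual machinery ------------------------------------------------

    def _observed_vector(self, cond: str) -> tuple[np.ndarray, float | None]:
        table = self.observed_tables[cond]
        counts = np.zeros(self.n_bins)
        counts[: table.n_bins] = table.counts
        frac = (
            self.observed_fractions[cond]
            if self.observed_fractions is not None
            else None
        )
        total = counts.sum()
        shape = counts / total if total > 0 else counts
        return shape, frac

    def _ssr(self, cond: str, f: int, Mt: int) -> float:
        obs_shape, obs_frac = self._observed_vector(cond)
        sim_counts, sim_frac = _expected_binned(
            self.untreated.copy_numbers, f, Mt, self.bin_width, self.n_bins, self.config
        )
        sim_total = sim_counts.sum()
        sim_shape = sim_counts / sim_total if sim_total > 0 else sim_counts
        if self.comparison_target == "fraction":
            return float((obs_frac - sim_frac) ** 2)
        if obs_frac is not None:
            # survivors-per-initial-cell scale: shape x surviving fraction
            dist_resid = obs_shape * obs_frac - sim_shape * sim_frac
        else:
            dist_resid = obs_shape - sim_shape
        ssr = float(np.sum(dist_resid**2))
        if self.comparison_target == "joint":
            ssr += float((obs_frac - sim_frac) ** 2)
        return ssr

    # -- fitting -----------------------------------------------------------

    def fit(self, reference_condition: str | None = None) -> CleavageFitResult:
        """Two-stage grid fit.

        Stage 1 scans the joint (Mt, f) grid on the reference condition (by
        default the condition with the lowest observed surviving fraction,
        i.e. the most active guide) and fixes Mt at the argmin. Stage 2
        re-scans f alone for every condition at that Mt.
        """
        conds = list(self.observed_tables)
        if reference_condition is None:
            if self.observed_fractions is not None:
                reference_condition = min(conds, key=lambda c: self.observed_fractions[c])
            else:
                reference_condition = conds[0]
        elif reference_condition not in conds:
            raise ValueError(f"unknown reference condition {reference_condition!r}")

        surface = np.empty((len(self.Mt_grid), len(self.f_grid)))
        for i, Mt in enumerate(self.Mt_grid):
            for j, f in enumerate(self.f_grid):
                surface[i, j] = self._ssr(reference_condition, f, Mt)
        # first occurrence in (Mt asc, f asc) order = smallest-Mt-then-f tie-break
        i_best, j_best = np.unravel_index(np.argmin(surface), surface.shape)
        best_Mt = int(self.Mt_grid[i_best])
        best_f = int(self.f_grid[j_best])

        ssr_f = pd.DataFrame(index=list(self.f_grid), columns=conds, dtype=float)
        f_by_condition: dict[str, int] = {}
        for cond in conds:
            curve = np.array([self._ssr(cond, f, best_Mt) for f in self.f_grid])
            ssr_f[cond] = curve
            f_by_condition[cond] = int(self.f_grid[int(np.argmin(curve))])

        return CleavageFitResult(
            ssr_surface=pd.DataFrame(
                surface, index=list(self.Mt_grid), columns=list(self.f_grid)
            ),
            best_Mt=best_Mt,
            best_f=best_f,
            f_by_condition=f_by_condition,
            ssr_f_by_condition=ssr_f,
            comparison_target=self.comparison_target,
            reference_condition=reference_condition,
        )


def fit_threshold_and_frequency(
    observed: PseudoExperiment | Mapping[str, PopulationFrequencyTable],
    untreated: CopyNumberPopulation | PopulationFrequencyTable | None = None,
    Mt_grid: Sequence[int] | None = None,
    f_grid: Sequence[int] | None = None,
    comparison_target: str = "distribution",
    observed_fractions: Mapping[str, float] | None = None,
    config: SimulationConfig | None = None,
) -> CleavageFitResult:
    """Functional front door for :class:`CleavageSelectionModel`."""
    if isinstance(observed, PseudoExperiment):
        model = CleavageSelectionModel.from_pseudo_experiment(
            observed,
            Mt_grid=Mt_grid,
            f_grid=f_grid,
            comparison_target=comparison_target,
            config=config,
        )
    else:
        if untreated is None:
            raise ValueError("untreated population required with raw observed tables")
        model = CleavageSelectionModel(
            observed,
            untreated,
            observed_fractions=observed_fractions,
            Mt_grid=Mt_grid,
            f_grid=f_grid,
            comparison_target=comparison_target,
            config=config,
        )
    return model.fit()
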