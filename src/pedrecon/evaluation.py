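"""Experiment grids: estimator accuracy, spatial effort and density zones.

Three desk-scale experiments mirror the validation of the
pedigree-reconstruction estimator on the simulated moose population:

1. *Population-based sampling accuracy* -- sample 10-90% of previously
   unsampled animals each year for five years, estimate adult abundance
   per iteration, and score precision (CV), bias (scaled mean error),
   accuracy (scaled root mean squared error), growth-rate error and
   bootstrap-interval coverage against the true number of adults inside
   the study area.
2. *Spatial sampling effort* -- the same scoring for grid-cell surveys
   of 10-200 km^2 per year, plus the realized fraction of previously
   unsampled animals each effort captures.
3. *Local density* -- single-year grid surveys inside nine equal zones
   spanning the population's extent, relating local density to the
   effort needed for unbiased estimates.

All randomness flows from one root seed; each (experiment, treatment,
iteration) consumes an independent child stream, so estimator results
do not depend on replay order.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import box

from .demography import (
    PopulationState,
    VitalRateTable,
    initialize_population,
    step_year,
)
from .estimator import (
    BetaPrior,
    EstimationUndefinedError,
    PedigreeTable,
    bootstrap_interval,
    classify_adults,
    estimate_abundance,
)
from .sampling import SamplingRecord, population_sample, spatial_sample
from .spatial import (
    CellWeightMap,
    HomeRange,
    HomeRangeParams,
    StudyArea,
    cell_weights,
    utilization_map,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CensusSnapshot",
    "SimulatedStudy",
    "simulate_study",
    "compute_metrics",
    "summarize_results",
    "growth_table",
    "run_objective1",
    "run_objective2",
    "run_objective3",
    "make_zones",
    "density",
    "cost_summary",
]

DEFAULT_INTENSITIES = tuple(round(0.1 * k, 1) for k in range(1, 10))
GENOTYPING_COST_USD = 22.0


# ---------------------------------------------------------------------------
# simulated study container


@dataclass
class CensusSnapshot:
    """Frozen view of one December census during the sampling period."""

    year: int
    frame: pd.DataFrame  # id, sire, dam, sex, birth_year, age, alive, in_area
    winter_ranges: dict[int, HomeRange]
    annual_ranges: dict[int, HomeRange]
    true_adults_in_area: int
    true_adults_extant: int
    n_alive_in_area: int
    n_alive: int


class SimulatedStudy:
    """A burn-in trajectory plus census snapshots over the sampling years."""

    def __init__(
        self,
        area: StudyArea,
        rates: VitalRateTable,
        spatial_params: HomeRangeParams,
        snapshots: dict[int, CensusSnapshot],
        final_state: PopulationState,
        burn_in: int,
        years: int,
        seed: int,
    ) -> None:
        self.area = area
        self.rates = rates
        self.spatial_params = spatial_params
        self.snapshots = snapshots
        self.final_state = final_state
        self.burn_in = burn_in
        self.years = years
        self.seed = seed
        self._weights_cache: dict = {}
        self._util_cache: dict = {}

    @property
    def sampling_years(self) -> list[int]:
        return sorted(self.snapshots)

    def snapshot(self, year_index: int) -> CensusSnapshot:
        """Snapshot for 1-based sampling year index."""
        return self.snapshots[self.sampling_years[year_index - 1]]

    def truth(self, census_year: int, in_area: bool = True) -> int:
        snap = self.snapshots[census_year]
        return snap.true_adults_in_area if in_area else snap.true_adults_extant

    def weights_for(self, census_year: int, area: StudyArea | None = None) -> CellWeightMap:
        area = area or self.area
        key = (census_year, area.polygon.bounds, area.cell_size)
        if key not in self._weights_cache:
            snap = self.snapshots[census_year]
            self._weights_cache[key] = cell_weights(snap.annual_ranges.values(), area)
        return self._weights_cache[key]

    def utilization_for(
        self, census_year: int, area: StudyArea | None = None
    ) -> dict[int, dict[int, float]]:
        area = area or self.area
        key = (census_year, area.polygon.bounds, area.cell_size)
        if key not in self._util_cache:
            snap = self.snapshots[census_year]
            self._util_cache[key] = {
                ind_id: utilization_map(hr, area)
                for ind_id, hr in snap.winter_ranges.items()
            }
        return self._util_cache[key]


def _take_snapshot(state: PopulationState, area: StudyArea) -> CensusSnapshot:
    frame = state.census_frame(area)
    alive = state.alive()
    winter = {ind.id: ind.winter for ind in alive if ind.winter is not None}
    annual = {ind.id: ind.annual for ind in alive if ind.annual is not None}
    # independent truth bookkeeping straight from the individual objects
    in_area_adults = sum(
        1 for ind in alive
        if ind.age >= 2 and ind.annual is not None
        and ind.annual.mcp.intersects(area.polygon)
    )
    extant_adults = sum(1 for ind in alive if ind.age >= 2)
    n_alive_in_area = sum(
        1 for ind in alive
        if ind.annual is not None and ind.annual.mcp.intersects(area.polygon)
    )
    return CensusSnapshot(
        year=state.year,
        frame=frame,
        winter_ranges=winter,
        annual_ranges=annual,
        true_adults_in_area=in_area_adults,
        true_adults_extant=extant_adults,
        n_alive_in_area=n_alive_in_area,
        n_alive=len(alive),
    )


def simulate_study(
    rates: VitalRateTable | None = None,
    area: StudyArea | None = None,
    n0: int = 659,
    burn_in: int = 20,
    years: int = 5,
    seed: int = 0,
    spatial_params: HomeRangeParams | None = None,
) -> SimulatedStudy:
    """Run burn-in plus sampling-period censuses and snapshot each census.

    The pedigree accumulates over ``burn_in`` years before the first
    sampling census; censuses ``burn_in .. burn_in + years - 1`` are
    snapshot for the sampling experiments.
    """
    rates = rates or VitalRateTable.default()
    area = area or StudyArea.rectangle()
    spatial_params = spatial_params or HomeRangeParams()
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    state = initialize_population(rates, n0=n0, area=area, seed=rng,
                                  spatial_params=spatial_params)
    for _ in range(burn_in):
        step_year(state, rates, area=area, rng=rng, spatial_params=spatial_params)
    snapshots = {state.year: _take_snapshot(state, area)}
    for _ in range(years - 1):
        step_year(state, rates, area=area, rng=rng, spatial_params=spatial_params)
        snapshots[state.year] = _take_snapshot(state, area)
    return SimulatedStudy(area, rates, spatial_params, snapshots, state,
                          burn_in, years, seed)


# ---------------------------------------------------------------------------
# metrics


def compute_metrics(
    estimates: Sequence[float],
    truth: float,
    cis: Sequence[tuple[float, float]] | None = None,
) -> dict[str, float]:
    """Precision, bias, accuracy and coverage of replicate estimates.

    cv = sd/mean (sample sd); sme = mean scaled error; srmse = root mean
    squared scaled error; coverage = fraction of intervals containing
    the truth (NaN when no intervals are supplied).
    """
    values = np.asarray(estimates, dtype=float)
    if truth <= 0:
        raise ValueError("truth must be positive")
    if values.size < 2:
        raise ValueError("need at least two estimates")
    err = (values - truth) / truth
    out = {
        "cv": float(values.std(ddof=1) / values.mean()),
        "sme": float(err.mean()),
        "srmse": float(np.sqrt((err ** 2).mean())),
        "coverage": math.nan,
    }
    if cis is not None and len(cis):
        lo = np.asarray([c[0] for c in cis], dtype=float)
        hi = np.asarray([c[1] for c in cis], dtype=float)
        out["coverage"] = float(np.mean((lo <= truth) & (truth <= hi)))
    return out


def summarize_results(
    results: pd.DataFrame,
    group_cols: Sequence[str],
    truth_col: str = "truth",
) -> pd.DataFrame:
    """Per-group metric rows; undefined iterations become a failure rate."""
    rows = []
    for key, grp in results.groupby(list(group_cols)):
        ok = grp[~grp["failed"]]
        truth = float(grp[truth_col].iloc[0])
        row = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
        row["truth"] = truth
        row["n_iterations"] = len(grp)
        row["failure_rate"] = float(grp["failed"].mean())
        if len(ok) >= 2:
            cis = None
            if "ci_low" in ok.columns and ok["ci_low"].notna().any():
                with_ci = ok[ok["ci_low"].notna()]
                cis = list(zip(with_ci["ci_low"], with_ci["ci_high"]))
            row.update(compute_metrics(ok["n_hat"].to_numpy(), truth, cis))
        else:
            row.update({"cv": math.nan, "sme": math.nan,
                        "srmse": math.nan, "coverage": math.nan})
        rows.append(row)
    return pd.DataFrame(rows)


def growth_table(results: pd.DataFrame, group_cols: Sequence[str]) -> pd.DataFrame:
    """Estimated vs true annual growth rates between consecutive years."""
    rows = []
    for key, grp in results.groupby([*group_cols, "iteration"]):
        grp = grp.sort_values("year_index")
        ok = grp[~grp["failed"]]
        if len(ok) < 2:
            continue
        vals = ok["n_hat"].to_numpy()
        truths = ok[_truth_col_of(ok)].to_numpy()
        yi = ok["year_index"].to_numpy()
        for j in range(len(vals) - 1):
            if yi[j + 1] != yi[j] + 1:
                continue
            base = dict(zip(group_cols, key[:-1] if isinstance(key, tuple) else (key,)))
            base.update({
                "iteration": key[-1] if isinstance(key, tuple) else key,
                "transition": int(yi[j]),
                "lambda_hat": vals[j + 1] / vals[j],
                "lambda_true": truths[j + 1] / truths[j],
            })
            rows.append(base)
    frame = pd.DataFrame(rows)
    if frame.empty:
        return frame
    frame["lambda_error"] = frame["lambda_hat"] - frame["lambda_true"]
    return frame


def _truth_col_of(frame: pd.DataFrame) -> str:
    return "truth" if "truth" in frame.columns else "truth_in_area"


# ---------------------------------------------------------------------------
# estimator plumbing shared by the objectives


def _estimate_iteration_year(
    snap: CensusSnapshot,
    record: SamplingRecord,
    adult_age_threshold: int,
    n_boot: int,
    prior: BetaPrior,
    ci_level: float,
    rng: np.random.Generator,
    with_ci: bool,
) -> dict[str, float | bool]:
    """Classify segments for the cumulative sample and estimate abundance.

    ``known_dead`` is taken from the simulator's oracle alive state: the
    estimator counts adults alive at the census in every segment, so the
    residual bias of the experiments comes from live animals outside the
    study area, not from ghosts of dead ones.
    """
    frame = snap.frame
    sampled_ids = record.sampled_ids
    sampled = frame["id"].isin(sampled_ids)
    years = frame["id"].map(lambda i: record.year_of(i) if i in record else np.nan)
    ped = PedigreeTable(
        pd.DataFrame({
            "id": frame["id"],
            "sire": frame["sire"],
            "dam": frame["dam"],
            "sex": frame["sex"],
            "birth_year": frame["birth_year"],
            "sampled": sampled,
            "sample_year": years,
            "known_dead": ~frame["alive"].astype(bool),
        }),
        validate=False,
    )
    counts = classify_adults(ped, snap.year, adult_age_threshold)
    out: dict[str, float | bool] = {
        "n_linked": counts.n_linked,
        "n_unlinked": counts.n_unlinked,
        "n_inferred": counts.n_inferred,
        "n_hat": math.nan, "ci_low": math.nan, "ci_high": math.nan,
        "failed": False,
    }
    try:
        if with_ci and n_boot > 0:
            est = bootstrap_interval(counts, prior=prior, n_boot=n_boot,
                                     ci_level=ci_level, seed=rng)
            out["ci_low"], out["ci_high"] = est.ci_low, est.ci_high
        else:
            est = estimate_abundance(counts)
        out["n_hat"] = est.n_hat
    except EstimationUndefinedError as exc:
        logger.debug("estimation undefined at census %d: %s", snap.year, exc)
        out["failed"] = True
    return out


def _iteration_rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, *tags)))


# ---------------------------------------------------------------------------
# objective 1: population-based sampling


def run_objective1(
    study: SimulatedStudy,
    intensities: Sequence[float] = DEFAULT_INTENSITIES,
    iterations: int = 100,
    seed: int = 0,
    n_boot: int = 0,
    prior: BetaPrior = BetaPrior(),
    ci_level: float = 0.95,
    ci_years: set[int] | None = None,
    adult_age_threshold: int = 2,
) -> pd.DataFrame:
    """Population-based sampling grid: intensity x iteration x year.

    ``n_boot = 0`` skips interval construction; ``ci_years`` restricts
    it to selected 1-based year indices.
    """
    rows = []
    for ii, intensity in enumerate(intensities):
        for it in range(iterations):
            rng = _iteration_rng(seed, 1, ii, it)
            record = SamplingRecord()
            for yi, census_year in enumerate(study.sampling_years, start=1):
                snap = study.snapshots[census_year]
                new_ids = population_sample(snap.frame, intensity, record, rng, census_year)
                with_ci = ci_years is None or yi in ci_years
                est = _estimate_iteration_year(
                    snap, record, adult_age_threshold, n_boot, prior,
                    ci_level, rng, with_ci)
                rows.append({
                    "scheme": "population", "intensity": intensity,
                    "iteration": it, "year_index": yi, "census_year": census_year,
                    "n_new": len(new_ids), "n_cum": len(record),
                    "truth": snap.true_adults_in_area,
                    "truth_extant": snap.true_adults_extant,
                    **est,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# objective 2: spatially based sampling


def run_objective2(
    study: SimulatedStudy,
    efforts: Sequence[int] = (10, 50, 100, 150, 200),
    iterations: int = 100,
    seed: int = 0,
    n_boot: int = 0,
    prior: BetaPrior = BetaPrior(),
    ci_level: float = 0.95,
    ci_years: set[int] | None = None,
    adult_age_threshold: int = 2,
    fresh_cells: bool = True,
) -> pd.DataFrame:
    """Grid-cell surveys of ``efforts`` cells (km^2) per year.

    Cells are drawn proportionally to the number of animals using them;
    detection is Bernoulli at each animal's scaled winter utilization.
    With ``fresh_cells`` previously drawn cells are excluded within an
    iteration, so each year surveys new ground.  The realized capture
    fraction is the share of previously unsampled in-area animals that
    entered the record that year.
    """
    rows = []
    for ei, n_cells in enumerate(efforts):
        for it in range(iterations):
            rng = _iteration_rng(seed, 2, ei, it)
            record = SamplingRecord()
            excluded: set[int] = set()
            for yi, census_year in enumerate(study.sampling_years, start=1):
                snap = study.snapshots[census_year]
                weights = study.weights_for(census_year)
                umaps = study.utilization_for(census_year)
                pool = snap.frame
                pool_ids = set(pool.loc[pool["alive"] & pool["in_area"], "id"])
                unsampled_pool = len(pool_ids - record.sampled_ids)
                new_ids, drawn = spatial_sample(
                    snap.frame, n_cells, weights, umaps, record, rng,
                    census_year, excluded_cells=excluded if fresh_cells else None)
                if fresh_cells:
                    excluded.update(drawn)
                new_in_area = len(set(new_ids) & pool_ids)
                with_ci = ci_years is None or yi in ci_years
                est = _estimate_iteration_year(
                    snap, record, adult_age_threshold, n_boot, prior,
                    ci_level, rng, with_ci)
                rows.append({
                    "scheme": "spatial", "effort": n_cells,
                    "iteration": it, "year_index": yi, "census_year": census_year,
                    "n_new": len(new_ids), "n_cum": len(record),
                    "pool": unsampled_pool,
                    "realized_fraction": (new_in_area / unsampled_pool
                                          if unsampled_pool else math.nan),
                    "truth": snap.true_adults_in_area,
                    "truth_extant": snap.true_adults_extant,
                    **est,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# objective 3: local density zones


def make_zones(
    study: SimulatedStudy,
    n_rows: int = 3,
    n_cols: int = 3,
    extent: tuple[float, float, float, float] | None = None,
) -> list:
    """Equal rectangular zones partitioning the population's extent.

    The default extent is the bounding box of the final census's winter
    clouds united with the study area, so animals that dispersed out of
    the management unit still fall in a zone (nine zones over a moose
    population spanning ~2700 km^2 gives zones near 300 km^2 each).
    """
    if extent is None:
        final = study.snapshots[study.sampling_years[-1]]
        pts = np.vstack([hr.points for hr in final.winter_ranges.values()])
        minx, miny, maxx, maxy = study.area.polygon.bounds
        minx = min(minx, pts[:, 0].min())
        miny = min(miny, pts[:, 1].min())
        maxx = max(maxx, pts[:, 0].max())
        maxy = max(maxy, pts[:, 1].max())
    else:
        minx, miny, maxx, maxy = extent
    dx = (maxx - minx) / n_cols
    dy = (maxy - miny) / n_rows
    zones = []
    for r in range(n_rows):
        for c in range(n_cols):
            zones.append(box(minx + c * dx, miny + r * dy,
                             minx + (c + 1) * dx, miny + (r + 1) * dy))
    return zones


def run_objective3(
    study: SimulatedStudy,
    effort_fractions: Sequence[float] = (0.01, 0.05, 0.10, 0.20),
    iterations: int = 50,
    seed: int = 0,
    n_boot: int = 1000,
    prior: BetaPrior = BetaPrior(),
    ci_level: float = 0.95,
    adult_age_threshold: int = 2,
    zones=None,
) -> pd.DataFrame:
    """Single-year zone surveys at 1-20% of each zone's 1-km^2 cells.

    Zone truth is the number of alive adults whose winter range uses the
    zone at the final census; density counts animals of all ages.
    """
    final_year = study.sampling_years[-1]
    snap = study.snapshots[final_year]
    zones = zones if zones is not None else make_zones(study)
    rows = []
    for zi, zone in enumerate(zones):
        zone_area = StudyArea(zone, cell_size=study.area.cell_size)
        users = {ind_id for ind_id, hr in snap.winter_ranges.items()
                 if hr.mcp.intersects(zone)}
        frame = snap.frame
        alive_users = frame["alive"] & frame["id"].isin(users)
        truth = int((alive_users & (frame["age"] >= adult_age_threshold)).sum())
        zone_density = float(alive_users.sum()) / zone.area
        if not users or truth == 0:
            logger.info("zone %d holds no adults; skipped", zi)
            continue
        weights = study.weights_for(final_year, zone_area)
        umaps = study.utilization_for(final_year, zone_area)
        umaps = {i: m for i, m in umaps.items() if i in users and m}
        for frac in effort_fractions:
            n_cells = max(1, int(math.floor(frac * zone_area.n_cells + 0.5)))
            for it in range(iterations):
                rng = _iteration_rng(seed, 3, zi, int(frac * 1000), it)
                record = SamplingRecord()
                spatial_sample(snap.frame, n_cells, weights, umaps, record,
                               rng, final_year)
                est = _estimate_iteration_year(
                    snap, record, adult_age_threshold, n_boot, prior,
                    ci_level, rng, with_ci=n_boot > 0)
                rows.append({
                    "zone": zi, "density": zone_density, "effort_fraction": frac,
                    "n_cells": n_cells, "iteration": it,
                    "n_sampled": len(record), "truth": truth, **est,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# small arithmetic helpers


def density(count: float, area_km2: float = 1650.0) -> float:
    """Population density in animals per km^2."""
    if area_km2 <= 0:
        raise ValueError("area must be positive")
    return count / area_km2


def cost_summary(mean_sampled: float, unit_cost: float = GENOTYPING_COST_USD) -> float:
    """Total genotyping cost for an average number of samples."""
    return mean_sampled * unit_cost
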