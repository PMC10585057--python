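"""Close-kin abundance estimation from a reconstructed pedigree.

A population of adults is partitioned into four segments by what a
reconstructed pedigree reveals about each animal:

* **linked** -- genetically sampled and matched (as sire or dam) to at
  least one sampled offspring;
* **unlinked** -- sampled but matched to no sampled offspring;
* **inferred** -- never sampled, but its existence is certain because a
  mate and a shared offspring were both sampled (the missing parent's
  genotype is implied by the offspring's);
* **invisible** -- neither sampled nor matched; these animals leave no
  trace in the pedigree and must be estimated.

Writing ``p_sampled`` for the marginal probability that an adult is
sampled and ``p_matched`` for the probability that it is matched to an
offspring, and assuming the two events are independent, an adult is
*observed* (falls in one of the first three segments) with probability
``1 - (1 - p_sampled)(1 - p_matched)``.  The marginals are estimated
from conditional proportions inside the pedigree::

    p_sampled = n_linked / (n_linked + n_inferred)   # P(sampled | matched)
    p_matched = n_linked / (n_linked + n_unlinked)   # P(matched | sampled)

and the adult population estimate divides the observed count by the
joint observation probability, exactly as classical capture--recapture
divides a known sample by a capture probability::

    n_hat = (n_linked + n_unlinked + n_inferred)
            / (1 - (1 - p_sampled) * (1 - p_matched))

Uncertainty comes from the estimation of the two marginals.  Each is
given a (vague) beta prior which the segment counts update to a beta
posterior; a bootstrap draws both marginals from their posteriors,
recomputes the joint probability and the population estimate per trial,
and reports a percentile interval.

Only adults are counted in the segments; offspring of any age (calves
included) serve to match adults but never enter the counts themselves.
Adults flagged ``known_dead`` at the census are excluded from every
segment, so the estimate targets adults alive at the census that are
still traceable through the pedigree.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PedigreeError",
    "EstimationUndefinedError",
    "SegmentCounts",
    "BetaPrior",
    "AbundanceEstimate",
    "PedigreeTable",
    "classify_adults",
    "estimate_marginals",
    "estimate_abundance",
    "bootstrap_interval",
    "growth_rate",
]

DEFAULT_ADULT_AGE = 2  # years at the December census


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycles, duplicate ids, sex clash)."""


class EstimationUndefinedError(ValueError):
    """Raised when a marginal probability has an empty denominator."""


@dataclass(frozen=True)
class SegmentCounts:
    """Observed pedigree segments among live adults at one census.

    The sufficient statistic of the estimator: numbers of linked,
    unlinked and inferred adults (invisible adults are an output, not a
    count).
    """

    n_linked: int
    n_unlinked: int
    n_inferred: int
    census_year: int = 0

    def __post_init__(self) -> None:
        for name in ("n_linked", "n_unlinked", "n_inferred"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_observed(self) -> int:
        return self.n_linked + self.n_unlinked + self.n_inferred


@dataclass(frozen=True)
class BetaPrior:
    """Beta prior shared by both marginal probabilities (default uniform)."""

    alpha0: float = 1.0
    beta0: float = 1.0

    def __post_init__(self) -> None:
        if not (self.alpha0 > 0 and self.beta0 > 0):
            raise ValueError("beta prior parameters must be positive")


@dataclass
class AbundanceEstimate:
    """Point estimate of adult abundance with optional bootstrap interval."""

    n_hat: float
    p_sampled: float
    p_matched: float
    n_invisible_hat: float
    counts: SegmentCounts
    ci_low: float = math.nan
    ci_high: float = math.nan
    ci_level: float = math.nan
    n_boot: int = 0
    seed: int | None = None


_MISSING_TOKENS = {"0", "NA", "NAN", "NONE", ""}

_REQUIRED_COLUMNS = (
    "id",
    "sire",
    "dam",
    "sex",
    "birth_year",
    "sampled",
    "sample_year",
    "known_dead",
)


def _normalise_parent(col: pd.Series) -> pd.Series:
    """Map the missing-parent tokens (0, NA, ...) to NaN."""
    def conv(v: object) -> object:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return np.nan
        if isinstance(v, (int, np.integer)) and v == 0:
            return np.nan
        if isinstance(v, str) and v.strip().upper() in _MISSING_TOKENS:
            return np.nan
        return v

    return col.map(conv)


class PedigreeTable:
    """A pedigree plus per-individual attributes, one row per individual.

    Columns: ``id, sire, dam, sex, birth_year, sampled, sample_year,
    known_dead``.  Unknown parents are NaN (the text formats use ``0``
    or ``NA``).  ``validate=False`` skips the structural checks -- used
    by the experiment loops where the same simulator pedigree is reused
    across thousands of sampling iterations.
    """

    def __init__(self, frame: pd.DataFrame, validate: bool = True):
        missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise PedigreeError(f"pedigree frame lacks columns: {missing}")
        self.frame = frame.reset_index(drop=True)
        if validate:
            self.validate()

    @classmethod
    def from_components(
        cls,
        pedigree: pd.DataFrame,
        attributes: pd.DataFrame,
        validate: bool = True,
    ) -> "PedigreeTable":
        """Join a three-column pedigree (id, sire, dam) with attributes."""
        ped = pedigree.copy()
        ped["sire"] = _normalise_parent(ped["sire"])
        ped["dam"] = _normalise_parent(ped["dam"])
        merged = ped.merge(attributes, on="id", how="left", validate="one_to_one")
        if "known_dead" not in merged.columns:
            merged["known_dead"] = False
        if "sample_year" not in merged.columns:
            merged["sample_year"] = np.nan
        return cls(merged, validate=validate)

    def validate(self) -> None:
        df = self.frame
        if df["id"].duplicated().any():
            dupes = df.loc[df["id"].duplicated(), "id"].tolist()
            raise PedigreeError(f"duplicate individual ids: {dupes[:5]}")
        ids = set(df["id"])
        g = nx.DiGraph()
        g.add_nodes_from(df["id"])
        for parent_col in ("sire", "dam"):
            sub = df[["id", parent_col]].dropna()
            g.add_edges_from(zip(sub[parent_col], sub["id"]))
        if not nx.is_directed_acyclic_graph(g):
            raise PedigreeError("pedigree contains a cycle (individual is its own ancestor)")
        sex = dict(zip(df["id"], df["sex"]))
        bad_sires = [s for s in df["sire"].dropna() if s in ids and sex.get(s) == "F"]
        bad_dams = [d for d in df["dam"].dropna() if d in ids and sex.get(d) == "M"]
        if bad_sires or bad_dams:
            raise PedigreeError(
                f"impossible sex-of-parent assignment: sires {bad_sires[:3]}, dams {bad_dams[:3]}"
            )
        sampled = df["sampled"].astype(bool)
        has_year = df["sample_year"].notna()
        if (sampled != has_year).any():
            raise PedigreeError("sample_year must be present exactly for sampled individuals")


def classify_adults(
    pedigree: PedigreeTable,
    census_year: int,
    adult_age_threshold: int = DEFAULT_ADULT_AGE,
) -> SegmentCounts:
    """Partition adults at a census into linked / unlinked / inferred.

    An adult is any individual aged ``adult_age_threshold`` or more at
    ``census_year`` and not flagged ``known_dead``.  Offspring of any
    age establish matches, but only adults are counted.  Unsampled,
    unmatched adults are the invisible segment and appear in no count.
    """
    df = pedigree.frame
    if len(df) and census_year < df["birth_year"].min():
        raise ValueError("census_year precedes every birth year in the pedigree")

    age = census_year - df["birth_year"]
    adult = (age >= adult_age_threshold) & ~df["known_dead"].astype(bool)
    sampled = df["sampled"].astype(bool)

    offspring = df.loc[sampled, ["sire", "dam"]]
    matched_ids: set = set(offspring["sire"].dropna()) | set(offspring["dam"].dropna())

    sampled_ids = set(df.loc[sampled, "id"])
    sires_with_sampled_mate = offspring.loc[offspring["dam"].isin(sampled_ids), "sire"].dropna()
    dams_with_sampled_mate = offspring.loc[offspring["sire"].isin(sampled_ids), "dam"].dropna()
    inferred_ids = set(sires_with_sampled_mate) | set(dams_with_sampled_mate)

    ids = df["id"]
    matched = ids.isin(matched_ids)
    linked = adult & sampled & matched
    unlinked = adult & sampled & ~matched
    inferred = adult & ~sampled & ids.isin(inferred_ids)

    return SegmentCounts(
        n_linked=int(linked.sum()),
        n_unlinked=int(unlinked.sum()),
        n_inferred=int(inferred.sum()),
        census_year=census_year,
    )


def estimate_marginals(counts: SegmentCounts) -> tuple[float, float]:
    """Marginal sampling and matching probabilities from segment counts.

    ``p_sampled`` is the proportion sampled among matched adults
    (linked + inferred); ``p_matched`` the proportion matched among
    sampled adults (linked + unlinked).
    """
    L, U, I = counts.n_linked, counts.n_unlinked, counts.n_inferred
    if L + I == 0:
        raise EstimationUndefinedError(
            "no linked or inferred adults: p_sampled undefined (matched segment empty)"
        )
    if L + U == 0:
        raise EstimationUndefinedError(
            "no linked or unlinked adults: p_matched undefined (sampled segment empty)"
        )
    if L == 0:
        raise EstimationUndefinedError(
            "no linked adults: joint observation probability is zero"
        )
    return L / (L + I), L / (L + U)


def _n_hat(n_observed: float, p_sampled, p_matched):
    return n_observed / (1.0 - (1.0 - p_sampled) * (1.0 - p_matched))


def estimate_abundance(counts: SegmentCounts) -> AbundanceEstimate:
    """Point estimate of adult abundance from the joint observation probability."""
    p_s, p_m = estimate_marginals(counts)
    n_obs = counts.n_observed
    n_hat = _n_hat(n_obs, p_s, p_m)
    return AbundanceEstimate(
        n_hat=n_hat,
        p_sampled=p_s,
        p_matched=p_m,
        n_invisible_hat=n_hat - n_obs,
        counts=counts,
    )


def bootstrap_interval(
    counts: SegmentCounts,
    prior: BetaPrior = BetaPrior(),
    n_boot: int = 10_000,
    ci_level: float = 0.95,
    seed: int | np.random.Generator | None = None,
    resample_counts: bool = True,
) -> AbundanceEstimate:
    """Beta-posterior bootstrap percentile interval for the abundance estimate.

    Each trial draws the two marginals independently from their beta
    posteriors,

    ``p_sampled* ~ Beta(alpha0 + n_linked, beta0 + n_inferred)``
    ``p_matched* ~ Beta(alpha0 + n_linked, beta0 + n_unlinked)``,

    then (by default) redraws the four segments of a population of size
    ``round(n_hat)`` from the multinomial observation model implied by
    the drawn marginals and pushes the resampled counts back through the
    estimator.  The interval is the percentile interval of the bootstrap
    ``n_hat*`` sample at ``ci_level``.  Redrawing the counts propagates
    the binomial noise of the segment counts as well as the posterior
    uncertainty of the marginals; without it (``resample_counts=False``,
    the joint probabilities recomputed from the posterior draws alone)
    the interval is markedly anticonservative (see docs/methods.md).
    """
    if not isinstance(prior, BetaPrior):
        raise ValueError("prior must be a BetaPrior")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not 0.0 < ci_level < 1.0:
        raise ValueError("ci_level must be in (0, 1)")
    est = estimate_abundance(counts)  # also validates the marginals
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L, U, I = counts.n_linked, counts.n_unlinked, counts.n_inferred
    p_s = rng.beta(prior.alpha0 + L, prior.beta0 + I, size=n_boot)
    p_m = rng.beta(prior.alpha0 + L, prior.beta0 + U, size=n_boot)
    if resample_counts:
        n_pop = int(round(est.n_hat))
        probs = np.column_stack([
            p_s * p_m, p_s * (1.0 - p_m), (1.0 - p_s) * p_m,
            (1.0 - p_s) * (1.0 - p_m),
        ])
        seg = rng.multinomial(n_pop, probs).astype(float)
        L_s, U_s, I_s = seg[:, 0], seg[:, 1], seg[:, 2]
        valid = L_s > 0  # degenerate redraws carry no estimate
        if valid.sum() < max(10, n_boot // 100):
            raise EstimationUndefinedError(
                "bootstrap degenerate: almost no resampled trials have linked adults"
            )
        L_s, U_s, I_s = L_s[valid], U_s[valid], I_s[valid]
        n_star = _n_hat(L_s + U_s + I_s, L_s / (L_s + I_s), L_s / (L_s + U_s))
    else:
        n_star = _n_hat(counts.n_observed, p_s, p_m)
    lo, hi = np.quantile(n_star, [(1.0 - ci_level) / 2.0, (1.0 + ci_level) / 2.0])
    est.ci_low = float(lo)
    est.ci_high = float(hi)
    est.ci_level = ci_level
    est.n_boot = n_boot
    est.seed = seed if isinstance(seed, int) else None
    return est


def growth_rate(
    estimates: Sequence[AbundanceEstimate | float],
) -> np.ndarray:
    """Annual growth rates ``n_hat[t+1] / n_hat[t]`` from consecutive estimates."""
    values = np.asarray(
        [e.n_hat if isinstance(e, AbundanceEstimate) else float(e) for e in estimates],
        dtype=float,
    )
    if values.size < 2:
        raise ValueError("need at least two consecutive annual estimates")
    if np.any(values[:-1] == 0.0):
        raise ZeroDivisionError("zero abundance estimate in the denominator")
    return values[1:] / values[:-1]
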