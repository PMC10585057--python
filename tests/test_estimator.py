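"""Unit and property tests for the four-segment close-kin estimator."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pedrecon import (
    BetaPrior,
    EstimationUndefinedError,
    PedigreeError,
    PedigreeTable,
    SegmentCounts,
    bootstrap_interval,
    classify_adults,
    estimate_abundance,
    estimate_marginals,
    growth_rate,
)

CENSUS = 2020


def make_table(ped, attrs, validate=True):
    return PedigreeTable.from_components(ped, attrs, validate=validate)


# ---------------------------------------------------------------------------
# classification


def test_classifies_worked_pedigree_example(toy_pedigree_frames):
    table = make_table(*toy_pedigree_frames)
    counts = classify_adults(table, CENSUS)
    assert (counts.n_linked, counts.n_unlinked, counts.n_inferred) == (2, 1, 1)
    # the two unmatched, unsampled adults are invisible: present in the
    # pedigree but in no segment
    assert counts.n_observed == 4


def test_fully_sampled_population_is_all_linked(toy_pedigree_frames):
    ped, attrs = toy_pedigree_frames
    attrs = attrs.assign(sampled=True, sample_year=CENSUS)
    counts = classify_adults(make_table(ped, attrs), CENSUS)
    # every sampled parent of a sampled offspring is linked; adults
    # without offspring stay unlinked
    assert counts.n_inferred == 0
    assert counts.n_linked == 3  # P1, P2, U1
    assert counts.n_unlinked == 3  # S1, X1, X2


def test_empty_sample_yields_zero_counts(toy_pedigree_frames):
    ped, attrs = toy_pedigree_frames
    attrs = attrs.assign(sampled=False, sample_year=np.nan)
    counts = classify_adults(make_table(ped, attrs), CENSUS)
    assert (counts.n_linked, counts.n_unlinked, counts.n_inferred) == (0, 0, 0)


def test_known_dead_adults_enter_no_segment(toy_pedigree_frames):
    ped, attrs = toy_pedigree_frames
    attrs.loc[attrs["id"] == "P1", "known_dead"] = True
    counts = classify_adults(make_table(ped, attrs), CENSUS)
    assert counts.n_linked == 1


def test_calves_match_but_are_never_counted(toy_pedigree_frames):
    ped, attrs = toy_pedigree_frames
    counts = classify_adults(make_table(ped, attrs), CENSUS, adult_age_threshold=2)
    # K1, K2 are sampled age-0 calves: they create the links yet stay out
    assert counts.n_observed == 4


def test_cyclic_pedigree_rejected():
    ped = pd.DataFrame({"id": ["A", "B"], "sire": ["B", "A"], "dam": ["0", "0"]})
    attrs = pd.DataFrame({
        "id": ["A", "B"], "sex": ["M", "M"], "birth_year": [2000, 2001],
        "sampled": [False, False], "sample_year": [np.nan, np.nan],
        "known_dead": [False, False],
    })
    with pytest.raises(PedigreeError, match="cycle"):
        make_table(ped, attrs)


def test_impossible_parent_sex_rejected():
    ped = pd.DataFrame({"id": ["A", "K"], "sire": ["0", "A"], "dam": ["0", "0"]})
    attrs = pd.DataFrame({
        "id": ["A", "K"], "sex": ["F", "F"], "birth_year": [2000, 2010],
        "sampled": [False, False], "sample_year": [np.nan, np.nan],
        "known_dead": [False, False],
    })
    with pytest.raises(PedigreeError, match="sex"):
        make_table(ped, attrs)


def test_duplicate_ids_rejected():
    frame = pd.DataFrame({
        "id": ["A", "A"], "sire": [np.nan, np.nan], "dam": [np.nan, np.nan],
        "sex": ["F", "F"], "birth_year": [2000, 2000],
        "sampled": [False, False], "sample_year": [np.nan, np.nan],
        "known_dead": [False, False],
    })
    with pytest.raises(PedigreeError, match="duplicate"):
        PedigreeTable(frame)


def test_relabelling_ids_leaves_counts_unchanged(toy_pedigree_frames):
    ped, attrs = toy_pedigree_frames
    base = classify_adults(make_table(ped, attrs), CENSUS)
    rng = np.random.default_rng(42)
    ids = list(ped["id"])
    for _ in range(10):
        perm = rng.permutation(len(ids))
        mapping = {old: f"ind{perm[i]:03d}" for i, old in enumerate(ids)}
        mapping["0"] = "0"
        ped2 = ped.map(lambda v: mapping.get(v, v))
        attrs2 = attrs.assign(id=attrs["id"].map(mapping))
        got = classify_adults(make_table(ped2, attrs2), CENSUS)
        assert (got.n_linked, got.n_unlinked, got.n_inferred) == (
            base.n_linked, base.n_unlinked, base.n_inferred)


# ---------------------------------------------------------------------------
# brute-force oracle over every sampled/matched configuration


def _brute_force_segments(rows, census_year, threshold=2):
    """Literal restatement of the segment definitions, one animal at a time."""
    sampled_of = {r["id"]: r["sampled"] for r in rows}
    linked = unlinked = inferred = 0
    for r in rows:
        if census_year - r["birth_year"] < threshold or r["known_dead"]:
            continue
        sampled_offspring = [
            o for o in rows
            if o["sampled"] and (o.get("sire") == r["id"] or o.get("dam") == r["id"])
        ]
        if r["sampled"]:
            if sampled_offspring:
                linked += 1
            else:
                unlinked += 1
        else:
            for o in sampled_offspring:
                other = o.get("dam") if o.get("sire") == r["id"] else o.get("sire")
                if other is not None and sampled_of.get(other, False):
                    inferred += 1
                    break
    return linked, unlinked, inferred


def test_classification_matches_brute_force_on_all_configurations():
    """Enumerate every sampled subset of a 10-animal pedigree (7 adults)."""
    ped = pd.DataFrame({
        "id":   ["A", "B", "C", "D", "E", "F", "G", "k1", "k2", "k3"],
        "sire": ["0", "0", "0", "0", "0", "0", "0", "A",  "A",  "C"],
        "dam":  ["0", "0", "0", "0", "0", "0", "0", "B",  "D",  "D"],
    })
    sexes = {"A": "M", "B": "F", "C": "M", "D": "F", "E": "M", "F": "F", "G": "M",
             "k1": "F", "k2": "M", "k3": "F"}
    birth = {"A": 2010, "B": 2010, "C": 2011, "D": 2012, "E": 2010, "F": 2013,
             "G": 2014, "k1": 2019, "k2": 2020, "k3": 2020}
    ids = list(ped["id"])
    for config in itertools.product([False, True], repeat=len(ids)):
        sampled = dict(zip(ids, config))
        attrs = pd.DataFrame({
            "id": ids,
            "sex": [sexes[i] for i in ids],
            "birth_year": [birth[i] for i in ids],
            "sampled": [sampled[i] for i in ids],
            "sample_year": [CENSUS if sampled[i] else np.nan for i in ids],
            "known_dead": [False] * len(ids),
        })
        table = make_table(ped, attrs, validate=False)
        got = classify_adults(table, CENSUS)
        rows = [{"id": i, "sire": None if ped.loc[ped.id == i, "sire"].iloc[0] == "0"
                 else ped.loc[ped.id == i, "sire"].iloc[0],
                 "dam": None if ped.loc[ped.id == i, "dam"].iloc[0] == "0"
                 else ped.loc[ped.id == i, "dam"].iloc[0],
                 "birth_year": birth[i], "sampled": sampled[i], "known_dead": False}
                for i in ids]
        expected = _brute_force_segments(rows, CENSUS)
        assert (got.n_linked, got.n_unlinked, got.n_inferred) == expected, config


# ---------------------------------------------------------------------------
# marginals and abundance


@pytest.mark.parametrize("counts, expected", [
    ((60, 20, 20), (0.75, 0.75)),
    ((10, 0, 0), (1.0, 1.0)),
])
def test_marginal_probabilities(counts, expected):
    got = estimate_marginals(SegmentCounts(*counts))
    assert got == pytest.approx(expected)


def test_marginals_undefined_without_linked_adults():
    with pytest.raises(EstimationUndefinedError, match="linked"):
        estimate_marginals(SegmentCounts(0, 5, 5))
    with pytest.raises(EstimationUndefinedError):
        estimate_marginals(SegmentCounts(0, 0, 5))


def test_point_estimate_from_joint_probability():
    est = estimate_abundance(SegmentCounts(60, 20, 20))
    assert est.n_hat == pytest.approx(100 / 0.9375)
    assert est.n_invisible_hat == pytest.approx(100 / 0.9375 - 100)


def test_complete_observation_estimates_exactly_the_sample():
    est = estimate_abundance(SegmentCounts(500, 0, 0))
    assert est.n_hat == 500
    assert est.n_invisible_hat == 0


def test_estimate_never_below_observed_count():
    rng = np.random.default_rng(3)
    for _ in range(200):
        L = int(rng.integers(1, 100))
        U = int(rng.integers(0, 100))
        I = int(rng.integers(0, 100))
        est = estimate_abundance(SegmentCounts(L, U, I))
        assert est.n_hat >= L + U + I - 1e-9


def test_parameter_recovery_under_independence_model():
    """Mean estimate within 1% of N=500 with Bernoulli sampling/matching."""
    rng = np.random.default_rng(11)
    N, p_s, p_m = 500, 0.6, 0.5
    probs = [p_s * p_m, p_s * (1 - p_m), (1 - p_s) * p_m, (1 - p_s) * (1 - p_m)]
    draws = rng.multinomial(N, probs, size=2000)
    estimates = [
        estimate_abundance(SegmentCounts(int(L), int(U), int(I))).n_hat
        for L, U, I, _ in draws
    ]
    assert np.mean(estimates) == pytest.approx(N, rel=0.01)


# ---------------------------------------------------------------------------
# bootstrap interval


def test_bootstrap_is_deterministic_under_seed():
    counts = SegmentCounts(60, 20, 20)
    a = bootstrap_interval(counts, n_boot=2000, seed=7)
    b = bootstrap_interval(counts, n_boot=2000, seed=7)
    assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
    c = bootstrap_interval(counts, n_boot=2000, seed=8)
    assert (a.ci_low, a.ci_high) != (c.ci_low, c.ci_high)


def test_bootstrap_median_consistent_with_point_estimate():
    counts = SegmentCounts(60, 20, 20)
    est = bootstrap_interval(counts, n_boot=50_000, seed=1)
    assert est.ci_low < est.n_hat < est.ci_high
    # percentile interval medians sit within 1% of the analytic point
    mid = bootstrap_interval(counts, n_boot=50_000, ci_level=0.0001, seed=1)
    median = 0.5 * (mid.ci_low + mid.ci_high)
    assert median == pytest.approx(est.n_hat, rel=0.01)


def test_interval_width_shrinks_with_information():
    narrow = bootstrap_interval(SegmentCounts(500, 0, 0), n_boot=20_000, seed=2)
    wide = bootstrap_interval(SegmentCounts(50, 0, 0), n_boot=20_000, seed=2)
    rel_narrow = (narrow.ci_high - narrow.ci_low) / narrow.n_hat
    rel_wide = (wide.ci_high - wide.ci_low) / wide.n_hat
    assert rel_narrow < rel_wide


def test_bootstrap_interval_covers_truth_under_independence_model():
    """95% intervals cover N=500 in at least 93% of independent replicates."""
    rng = np.random.default_rng(5)
    N, p = 500, 0.6
    probs = [p * p, p * (1 - p), (1 - p) * p, (1 - p) * (1 - p)]
    covered = 0
    trials = 1000
    for L, U, I, _ in rng.multinomial(N, probs, size=trials):
        est = bootstrap_interval(SegmentCounts(int(L), int(U), int(I)),
                                 n_boot=1500, seed=rng)
        covered += est.ci_low <= N <= est.ci_high
    assert covered / trials >= 0.93


def test_invalid_prior_rejected():
    with pytest.raises(ValueError):
        BetaPrior(0.0, 1.0)
    with pytest.raises(ValueError):
        bootstrap_interval(SegmentCounts(5, 1, 1), prior=(1, 1))  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# growth rate


@pytest.mark.parametrize("series, expected", [
    ([100.0, 103.0], [1.03]),
    ([50.0, 50.0, 50.0], [1.0, 1.0]),
    ([320.0 / 3.0, 96.0, 105.6], [0.9, 1.1]),
])
def test_growth_rate_ratios(series, expected):
    assert growth_rate(series) == pytest.approx(expected)


def test_growth_rate_requires_two_estimates_and_nonzero_base():
    with pytest.raises(ValueError):
        growth_rate([100.0])
    with pytest.raises(ZeroDivisionError):
        growth_rate([0.0, 10.0])
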