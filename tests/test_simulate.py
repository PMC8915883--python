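"""Generative properties of the synthetic V(D)J cohort simulator."""

import numpy as np
import pandas as pd
import pytest

from tcrprof.composition import (
    AMINO_ACIDS,
    aa_occurrence,
    positional_occurrence,
    segment_usage,
)
from tcrprof.io import filter_functional
from tcrprof.simulate import (
    ConfigError,
    EnrichmentSpec,
    SimulationConfig,
    default_pools,
    simulate_cohort,
    simulate_repertoire,
    write_cohort,
)
from tcrprof.io import load_cohort, translate_cdr3


SMALL = dict(n_donors_case=2, n_donors_control=2, clonotypes_per_repertoire=300)


def test_same_seed_gives_identical_cohort():
    a = simulate_cohort(SimulationConfig(**SMALL, seed=5))
    b = simulate_cohort(SimulationConfig(**SMALL, seed=5))
    for ra, rb in zip(a, b):
        pd.testing.assert_frame_equal(ra.clonotypes, rb.clonotypes)
    c = simulate_cohort(SimulationConfig(**SMALL, seed=6))
    assert not a[0].clonotypes.equals(c[0].clonotypes)


def test_adding_donors_never_perturbs_existing_ones():
    small = simulate_cohort(SimulationConfig(**SMALL, seed=5))
    big = simulate_cohort(
        SimulationConfig(n_donors_case=4, n_donors_control=2,
                         clonotypes_per_repertoire=300, seed=5)
    )
    by_key = {rep.sample_key: rep for rep in big}
    for rep in small:
        pd.testing.assert_frame_equal(rep.clonotypes, by_key[rep.sample_key].clonotypes)


def test_cohort_counts_and_conditions():
    cohort = simulate_cohort(
        SimulationConfig(n_donors_case=3, n_donors_control=3,
                         clonotypes_per_repertoire=100, seed=0)
    )
    assert len(cohort) == 6
    conditions = [r.condition for r in cohort]
    assert conditions.count("case") == 3 and conditions.count("control") == 3
    assert len({r.donor_id for r in cohort}) == 6


def test_zero_nonfunctional_rate_means_nothing_filtered():
    rep = simulate_repertoire(
        SimulationConfig(clonotypes_per_repertoire=500, nonfunctional_rate=0.0,
                         seed=2), "d1", "case")
    assert filter_functional(rep).diversity == rep.diversity


def test_nonfunctional_rate_is_respected():
    # long insertions make collisions negligible, so the unique-clonotype
    # fraction reflects the rearrangement-level rate
    config = SimulationConfig(clonotypes_per_repertoire=4000, insertion_nt_mean=30,
                              nonfunctional_rate=0.2, seed=3)
    rep = simulate_repertoire(config, "d1", "control")
    bad = rep.clonotypes["cdr3_aa"].str.contains(r"\*|_", regex=True)
    assert bad.mean() == pytest.approx(0.2, abs=0.05)


def test_functional_cdr3s_are_anchored_and_consistent():
    rep = simulate_repertoire(
        SimulationConfig(clonotypes_per_repertoire=800, seed=4), "d1", "case")
    functional = filter_functional(rep)
    aa = functional.clonotypes["cdr3_aa"]
    assert aa.str.startswith("C").all()
    assert aa.str.endswith("F").all()
    prof = positional_occurrence(functional, max_position=1)
    assert prof.at(1, "C") == pytest.approx(100)
    # nucleotide/protein consistency
    for nt, expect in zip(functional.clonotypes["cdr3_nt"], aa):
        assert translate_cdr3(nt) == expect


def test_tra_chain_has_missing_d_segment():
    rep = simulate_repertoire(
        SimulationConfig(clonotypes_per_repertoire=50, chain="TRA", seed=1),
        "d1", "control")
    assert (rep.clonotypes["d_segment"] == ".").all()
    assert rep.clonotypes["v_segment"].str.startswith("TRAV").all()


def test_positional_enrichment_recovers_requested_effect_at_large_n():
    """+15 points of W at position 5: realized case-control gap within +/-1.5."""
    config = SimulationConfig(
        clonotypes_per_repertoire=50_000, seed=7,
        enrichments=(EnrichmentSpec("positional", "W", 15.0, position=5),),
    )
    case = filter_functional(simulate_repertoire(config, "d1", "case"))
    control = filter_functional(simulate_repertoire(config, "d2", "control"))
    gap = (positional_occurrence(case, max_position=5).at(5, "W")
           - positional_occurrence(control, max_position=5).at(5, "W"))
    assert gap == pytest.approx(15.0, abs=1.5)


def test_no_enrichment_composition_converges_between_arms():
    """Same generative law in both arms: per-residue gaps vanish at large n.

    Donor-usage jitter is a deliberate extra variance source that does not
    shrink with repertoire size, so it is switched off here to isolate the
    shared base law.
    """
    config = SimulationConfig(
        clonotypes_per_repertoire=50_000, donor_usage_noise=np.inf, seed=11)
    case = filter_functional(simulate_repertoire(config, "d1", "case"))
    control = filter_functional(simulate_repertoire(config, "d2", "control"))
    occ_case = aa_occurrence(case).occurrence
    occ_control = aa_occurrence(control).occurrence
    for aa in AMINO_ACIDS:
        assert abs(occ_case[aa] - occ_control[aa]) <= 1.0


def test_clone_sizes_independent_of_cdr3_content():
    """Count-weighted profiles sit inside the shuffled-count null band.

    The clone-size law is heavy-tailed (power-law exponent 2.5, infinite
    variance), so count-weighted occurrence keeps substantial scatter even
    in large repertoires; the sharp statement of independence is that the
    observed count-weighted profile is indistinguishable from one computed
    with clone sizes randomly reassigned.  The check runs on the raw
    rearrangement-level rows: collapsing merges independently re-created
    short-junction rearrangements (convergent recombination), which couples
    collapsed counts to content by construction.
    """
    config = SimulationConfig(clonotypes_per_repertoire=50_000, seed=13)
    rep = filter_functional(
        simulate_repertoire(config, "d1", "control", collapse=False))
    contains = np.column_stack([
        rep.clonotypes["cdr3_aa"].str.contains(aa, regex=False).to_numpy()
        for aa in AMINO_ACIDS
    ]).astype(float)
    counts = rep.clonotypes["count"].to_numpy(float)
    observed = 100.0 * counts @ contains / counts.sum()

    rng = np.random.default_rng(99)
    null = np.empty((300, len(AMINO_ACIDS)))
    for b in range(300):
        perm = rng.permutation(counts)
        null[b] = 100.0 * perm @ contains / perm.sum()
    lo, hi = np.percentile(null, [0.25, 99.75], axis=0)
    assert np.all(observed >= lo - 1e-9) and np.all(observed <= hi + 1e-9)


def test_infeasible_enrichment_raises():
    config = SimulationConfig(
        clonotypes_per_repertoire=200, seed=1,
        enrichments=(EnrichmentSpec("containment", "F", 50.0),),  # F already ~100%
    )
    with pytest.raises(ConfigError, match="infeasible"):
        simulate_repertoire(config, "d1", "case")


def test_enrichment_spec_validation():
    with pytest.raises(ConfigError):
        EnrichmentSpec("positional", "W", 10.0)  # missing position
    with pytest.raises(ConfigError):
        EnrichmentSpec("positional", "W", 10.0, position=1)  # anchor
    with pytest.raises(ConfigError):
        EnrichmentSpec("containment", "K", 150.0)  # effect out of range
    with pytest.raises(ConfigError):
        EnrichmentSpec("containment", "KK", 10.0)
    with pytest.raises(ConfigError):
        SimulationConfig(enrichments=(EnrichmentSpec("segment_usage", "TRBV99", 5.0),))


def test_cohort_needs_donors_on_both_arms():
    with pytest.raises(ConfigError):
        simulate_cohort(SimulationConfig(n_donors_case=0, seed=1))


def test_pool_anchor_validation():
    v_pool, j_pool = default_pools("TRB")
    broken = dict(v_pool)
    broken["TRBV1"] = (broken["TRBV1"][0], "GCTGCC")  # does not start with C
    with pytest.raises(ConfigError, match="start with C"):
        SimulationConfig(v_pool=broken, j_pool=j_pool)


def test_config_yaml_round_trip(tmp_path):
    config = SimulationConfig(
        **SMALL, seed=9,
        enrichments=(EnrichmentSpec("containment", "K", 10.0),),
    )
    path = tmp_path / "config.yaml"
    config.to_yaml(path)
    loaded = SimulationConfig.from_yaml(path)
    assert loaded == config


def test_write_cohort_round_trips_through_manifest(tmp_path):
    cohort = simulate_cohort(SimulationConfig(**SMALL, seed=5))
    manifest = write_cohort(cohort, tmp_path / "cohort")
    back = load_cohort(manifest)
    assert len(back) == len(cohort)
    by_key = {r.sample_key: r for r in back}
    for rep in cohort:
        again = by_key[rep.sample_key]
        assert again.clonotypes["cdr3_nt"].tolist() == rep.clonotypes["cdr3_nt"].tolist()
        assert again.clonotypes["count"].tolist() == rep.clonotypes["count"].tolist()
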