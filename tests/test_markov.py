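import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings
from hypothesis import strategies as st

from metachain import (
    TAXONOMY,
    StateVector,
    TransitionMatrix,
    conditional_next_distribution,
    default_config,
    estimate_transition_matrix,
    extract_pathways,
    initial_state,
    propagate,
    simulate_cohort,
    tally_transitions,
)

from conftest import pw, random_transition_matrix


def brute_force_tally(pathways, taxonomy):
    """Independent exhaustive tally of site-set transitions."""
    idx = {s: i for i, s in enumerate(taxonomy)}
    counts = np.zeros((len(taxonomy), len(taxonomy)))
    for p in pathways:
        for k in range(len(p.steps) - 1):
            prev, nxt = p.steps[k], p.steps[k + 1]
            for t in nxt:
                for s in prev:
                    counts[idx[s], idx[t]] += 1.0 / len(prev)
    return counts


class TestEstimation:
    def test_worked_example_100_patients_36_bone_first(self):
        """A 100-patient cohort with 36 bone-first metastases gives a
        breast-to-bone transition probability of exactly 0.36."""
        pathways = [pw("breast", "bone") for _ in range(36)]
        pathways += [pw("breast", "liver") for _ in range(40)]
        pathways += [pw("breast", "lung_pleura") for _ in range(24)]
        A = estimate_transition_matrix(pathways)
        assert A["breast", "bone"] == 0.36

    def test_deterministic_chain(self):
        pathways = [pw("breast", "bone", "deceased")] * 5
        A = estimate_transition_matrix(pathways)
        assert A["breast", "bone"] == 1.0
        assert A["bone", "deceased"] == 1.0
        assert A["deceased", "deceased"] == 1.0

    def test_manual_fractional_tally_fixture(self):
        """Six pathways, one with a co-occurring pair, against a
        hand-computed fractional tally."""
        pathways = [
            pw("breast", "bone", "liver", "deceased"),
            pw("breast", "bone", "deceased"),
            pw("breast", ("bone", "liver"), "lung_pleura"),
            pw("breast", "liver"),
            pw("breast", "bone", "bone"),
            pw("breast", "lung_pleura", "deceased"),
        ]
        A = estimate_transition_matrix(pathways)
        # breast exits: bone 4, liver 2, lung 1 (multi-site step adds one per site)
        assert A["breast", "bone"] == pytest.approx(4 / 7)
        assert A["breast", "liver"] == pytest.approx(2 / 7)
        assert A["breast", "lung_pleura"] == pytest.approx(1 / 7)
        # bone exits: liver 1 + lung 0.5 + deceased 1 + bone 1 = 3.5
        assert A["bone", "liver"] == pytest.approx(1 / 3.5)
        assert A["bone", "lung_pleura"] == pytest.approx(0.5 / 3.5)
        assert A["bone", "deceased"] == pytest.approx(1 / 3.5)
        assert A["bone", "bone"] == pytest.approx(1 / 3.5)
        # liver exits: deceased 1 + lung 0.5 = 1.5
        assert A["liver", "deceased"] == pytest.approx(1 / 1.5)
        assert A["liver", "lung_pleura"] == pytest.approx(0.5 / 1.5)
        assert A["lung_pleura", "deceased"] == 1.0

    def test_zero_exit_row_self_absorbing_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="metachain.markov"):
            A = estimate_transition_matrix([pw("breast", "bone")])
        assert A["bone", "bone"] == 1.0
        assert "no observed exits" in caplog.text

    def test_add_one_smoothing_spreads_mass_off_breast(self):
        A = estimate_transition_matrix([pw("breast", "bone")], smoothing="add_one")
        assert A["bone", "breast"] == 0.0
        row = A.row("bone")
        nonbreast = [v for s, v in row.items() if s != "breast"]
        assert all(v == pytest.approx(1 / 9) for v in nonbreast)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            estimate_transition_matrix([])
        with pytest.raises(ValueError):
            estimate_transition_matrix([pw("breast")])

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10**6))
    def test_counts_equal_brute_force_tally(self, seed):
        """Denumeration equals an independent exhaustive tally on random
        small pathway sets."""
        rng = np.random.default_rng(seed)
        mets = [s for s in TAXONOMY if s not in ("breast", "deceased")]
        pathways = []
        for _ in range(rng.integers(1, 10)):
            steps = ["breast"]
            for _ in range(rng.integers(1, 4)):
                size = rng.integers(1, 3)
                steps.append(tuple(rng.choice(mets, size=size, replace=False)))
            if rng.random() < 0.3:
                steps.append("deceased")
            pathways.append(pw(*steps))
        np.testing.assert_allclose(
            tally_transitions(pathways, TAXONOMY),
            brute_force_tally(pathways, TAXONOMY),
        )

    def test_rows_stochastic_on_estimates(self):
        cohort = simulate_cohort(default_config(n_patients=200, seed=4))
        A = estimate_transition_matrix(extract_pathways(cohort))
        np.testing.assert_allclose(A.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_parameter_recovery_at_n5000(self):
        """Estimating from 5000 simulated patients recovers the known
        matrix: max-entry error < 0.03 on rows with >= 200 observed exits."""
        cfg = default_config(n_patients=5000, seed=7)
        cfg = replace(
            cfg, multiplicity_weights={1: 1.0}, censoring_years=(80.0, 100.0)
        )
        cohort = simulate_cohort(cfg)
        A = estimate_transition_matrix(extract_pathways(cohort, window_years=100.0))
        truth = sum(
            cfg.subgroup_proportions[g] * cfg.transition_matrices[g].probs
            for g in cfg.subgroup_proportions
        )
        exits = A.counts.sum(axis=1)
        for i in range(len(TAXONOMY)):
            if exits[i] >= 200:
                assert np.abs(A.probs[i] - truth[i]).max() < 0.03


class TestPropagation:
    def test_identity_matrix_fixes_any_state(self):
        n = len(TAXONOMY)
        A = TransitionMatrix(sites=TAXONOMY, probs=np.eye(n))
        v = StateVector(sites=TAXONOMY, probs=np.full(n, 1 / n))
        for k in (0, 1, 5):
            np.testing.assert_allclose(propagate(v, A, k).probs, v.probs)

    def test_zero_steps_returns_initial_state(self):
        v0 = initial_state()
        out = propagate(v0, TransitionMatrix(sites=TAXONOMY, probs=np.eye(len(TAXONOMY))), 0)
        assert out["breast"] == 1.0
        np.testing.assert_allclose(out.probs, v0.probs)

    def test_two_step_deterministic_chain_absorbs(self):
        """breast -> bone -> deceased with certainty: after two steps all
        mass sits on deceased (hand matrix product)."""
        sites = ("breast", "bone", "deceased")
        probs = np.array([[0, 1, 0], [0, 0, 1], [0, 0, 1]], dtype=float)
        A = TransitionMatrix(sites=sites, probs=probs)
        v0 = StateVector(sites=sites, probs=np.array([1.0, 0, 0]))
        out = propagate(v0, A, 2)
        np.testing.assert_allclose(out.probs, [0, 0, 1])

    def test_taxonomy_mismatch_rejected(self):
        A = TransitionMatrix(sites=("breast", "deceased"), probs=np.array([[0, 1], [0, 1.0]]))
        v = initial_state()
        with pytest.raises(ValueError, match="taxonomy"):
            propagate(v, A, 1)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10**6), st.integers(0, 8))
    def test_propagation_preserves_stochasticity_and_absorption(self, seed, k):
        """Each step keeps the state a distribution, and deceased mass is
        non-decreasing in k."""
        A = random_transition_matrix(seed)
        v = initial_state(A.sites)
        masses = [propagate(v, A, i)["deceased"] for i in range(k + 1)]
        final = propagate(v, A, k)
        assert final.probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert all(b >= a - 1e-12 for a, b in zip(masses, masses[1:]))


class TestConditionalNextDistribution:
    def test_prefix_breast_matches_first_step_frequencies(self):
        pathways = [pw("breast", "bone"), pw("breast", "bone"), pw("breast", "liver")]
        d = conditional_next_distribution(pathways, ("breast",))
        assert d.n_matching == 3
        assert d.probs == {"bone": pytest.approx(2 / 3), "liver": pytest.approx(1 / 3)}

    def test_hand_count_after_breast_bone(self):
        pathways = [
            pw("breast", "bone", "lung_pleura"),
            pw("breast", "bone", "lung_pleura"),
            pw("breast", "bone", "liver"),
            pw("breast", "bone", "deceased"),
            pw("breast", "liver", "bone"),   # prefix mismatch
            pw("breast", "bone"),            # no next step
        ]
        d = conditional_next_distribution(pathways, ("breast", "bone"))
        assert d.n_matching == 4
        assert d.probs["lung_pleura"] == pytest.approx(0.5)
        assert d.probs["liver"] == pytest.approx(0.25)
        assert d.probs["deceased"] == pytest.approx(0.25)

    def test_no_match_yields_empty_distribution(self):
        d = conditional_next_distribution([pw("breast", "bone")], ("breast", "brain"))
        assert d.n_matching == 0 and d.probs == {}

    def test_prefix_must_start_at_breast(self):
        with pytest.raises(ValueError):
            conditional_next_distribution([], ("bone",))

    def test_synthetic_cohort_bone_lung_prefix_is_liver_dominated(self):
        """After breast -> bone -> lung/pleura the most likely next site is
        the liver and the deceased mass is small (calibrated flow
        structure: lung row sends 0.45 to liver, 0.03 to deceased)."""
        cfg = default_config(n_patients=4000, seed=13)
        cohort = simulate_cohort(cfg)
        pathways = extract_pathways(cohort)
        d = conditional_next_distribution(pathways, ("breast", "bone", "lung_pleura"))
        assert d.n_matching > 20
        top = max(d.probs, key=d.probs.get)
        assert top == "liver"
        assert d.probs.get("deceased", 0.0) < 0.15


class TestMatrixIO:
    def test_csv_and_json_round_trip(self, tmp_path):
        A = random_transition_matrix(3)
        A.to_csv(tmp_path / "A.csv")
        back = TransitionMatrix.from_csv(tmp_path / "A.csv")
        assert back.sites == A.sites
        np.testing.assert_allclose(back.probs, A.probs)
        A.to_json(tmp_path / "A.json")
        back = TransitionMatrix.from_json(tmp_path / "A.json")
        np.testing.assert_allclose(back.probs, A.probs)

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            TransitionMatrix(sites=("breast", "deceased"), probs=np.array([[0.5, 0.4], [0, 1.0]]))

    def test_non_absorbing_deceased_rejected(self):
        with pytest.raises(ValueError, match="absorbing"):
            TransitionMatrix(sites=("breast", "deceased"), probs=np.array([[0, 1.0], [0.5, 0.5]]))
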