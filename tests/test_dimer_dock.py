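import numpy as np
import pytest

from deerdock.deer_forward import DeerTrace, trace_from_pose
from deerdock.dimer_dock import (
    C2Pose,
    DistanceObjective,
    DockResult,
    GridSpec,
    RestraintSet,
    contact_sweep,
    grid_search,
    pose_equivalents,
    pose_parameter_error,
    refine,
    score_distance,
)
from deerdock.synthetic_data import ToySpec, find_touching_pose, make_toy_protomer

from conftest import RECOVERY_SITES


@pytest.fixture(scope="module")
def truth_pose(toy_protomer):
    return find_touching_pose(toy_protomer, alpha=250.0, beta=5.0, phi=200.0)


@pytest.fixture(scope="module")
def truth_restraints(toy_protomer, toy_ensembles, truth_pose):
    _, means = score_distance(
        truth_pose,
        toy_ensembles,
        RestraintSet({s: (1.0, 0.1) for s in RECOVERY_SITES}),
        center=toy_protomer.geometric_center,
    )
    return RestraintSet({s: (m, 0.1) for s, m in means.items()})


class TestScoreDistance:
    def test_self_restraints_zero(self, toy_protomer, toy_ensembles, truth_pose, truth_restraints):
        rmsd, _ = score_distance(
            truth_pose, toy_ensembles, truth_restraints, center=toy_protomer.geometric_center
        )
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_single_site_arithmetic(self):
        from deerdock.spin_labeling import SpinSiteEnsemble

        ens = {("A", 1): SpinSiteEnsemble(("A", 1), np.array([[1.0, 0, 0]]), np.array([1.0]))}
        # simulated inter-copy distance is 2.0; target 1.8 -> rmsd 0.2
        rmsd, means = score_distance(
            C2Pose(0, 0, 0, 0), ens, RestraintSet({("A", 1): (1.8, 0.1)})
        )
        assert means[("A", 1)] == pytest.approx(2.0, abs=1e-12)
        assert rmsd == pytest.approx(0.2, abs=1e-12)

    def test_order_invariant(self, toy_protomer, toy_ensembles, truth_restraints):
        pose = C2Pose(100, 10, 1.5, 0.5)
        center = toy_protomer.geometric_center
        r1, _ = score_distance(pose, toy_ensembles, truth_restraints, center=center)
        reordered = RestraintSet(dict(reversed(list(truth_restraints.entries.items()))))
        r2, _ = score_distance(pose, toy_ensembles, reordered, center=center)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_missing_ensemble_raises(self, toy_ensembles):
        with pytest.raises(ValueError, match="B.*99"):
            score_distance(
                C2Pose(0, 0, 1, 0), toy_ensembles, RestraintSet({("B", 99): (2.0, 0.1)})
            )


class TestGridSearch:
    def test_coarse_grid_containing_truth_ranks_first(
        self, toy_protomer, toy_ensembles, truth_pose
    ):
        # restraints generated with the same thinned ensembles the search uses
        thinned = {s: e.thinned(24) for s, e in toy_ensembles.items()}
        _, means = score_distance(
            truth_pose,
            thinned,
            RestraintSet({s: (1.0, 0.1) for s in RECOVERY_SITES}),
            center=toy_protomer.geometric_center,
        )
        restraints = RestraintSet({s: (m, 0.1) for s, m in means.items()})
        grid = GridSpec(
            alpha=np.array([truth_pose.alpha, (truth_pose.alpha + 90) % 360]),
            beta=np.array([truth_pose.beta, truth_pose.beta + 40.0]),
            x=np.array([truth_pose.x, truth_pose.x + 1.0]),
            y=np.array([truth_pose.y, truth_pose.y - 1.0]),
        )
        results = grid_search(toy_protomer, toy_ensembles, restraints, grid=grid)
        best = results[0]
        assert best.score == pytest.approx(0.0, abs=1e-9)
        assert pose_parameter_error(best.pose, truth_pose) == pytest.approx(
            (0, 0, 0, 0), abs=1e-9
        )

    def test_doubling_resolution_never_worse(self, toy_protomer, toy_ensembles, truth_restraints):
        base = GridSpec(
            alpha=np.arange(0.0, 360.0, 40.0),
            beta=np.arange(0.0, 30.1, 10.0),
            x=np.arange(-2.0, 2.01, 0.5),
            y=np.arange(-2.0, 2.01, 0.5),
        )
        fine = GridSpec(
            alpha=np.arange(0.0, 360.0, 20.0),
            beta=np.arange(0.0, 30.1, 5.0),
            x=np.arange(-2.0, 2.01, 0.25),
            y=np.arange(-2.0, 2.01, 0.25),
        )
        best_base = grid_search(toy_protomer, toy_ensembles, truth_restraints, grid=base)[0]
        best_fine = grid_search(toy_protomer, toy_ensembles, truth_restraints, grid=fine)[0]
        assert best_fine.score <= best_base.score + 1e-12

    def test_empty_feasible_set_raises(self, toy_protomer, toy_ensembles, truth_restraints):
        grid = GridSpec(
            alpha=np.array([0.0]),
            beta=np.array([0.0]),
            x=np.array([30.0]),
            y=np.array([0.0]),
        )
        with pytest.raises(ValueError, match="contact"):
            grid_search(toy_protomer, toy_ensembles, truth_restraints, grid=grid)

    def test_deterministic(self, toy_protomer, toy_ensembles, truth_restraints):
        grid = GridSpec(
            alpha=np.arange(0.0, 360.0, 60.0),
            beta=np.array([0.0, 10.0]),
            x=np.arange(-2.0, 2.01, 0.5),
            y=np.arange(-2.0, 2.01, 0.5),
        )
        r1 = grid_search(toy_protomer, toy_ensembles, truth_restraints, grid=grid)
        r2 = grid_search(toy_protomer, toy_ensembles, truth_restraints, grid=grid)
        assert [d.pose.as_tuple() for d in r1] == [d.pose.as_tuple() for d in r2]
        assert [d.score for d in r1] == [d.score for d in r2]


class TestRefine:
    def test_score_never_exceeds_start(self, toy_protomer, toy_ensembles, truth_restraints):
        objective = DistanceObjective(toy_protomer, toy_ensembles, truth_restraints)
        start = C2Pose(360.0, 5.0, 5.0, 1.0)  # grid-corner style start
        result = refine(start, objective)
        assert result.score <= objective(start) + 1e-12

    def test_start_at_optimum_stays(self, toy_protomer, toy_ensembles, truth_pose, truth_restraints):
        objective = DistanceObjective(toy_protomer, toy_ensembles, truth_restraints)
        result = refine(truth_pose, objective)
        assert result.score <= objective(truth_pose) + 1e-12
        err = pose_parameter_error(result.pose, truth_pose)
        assert max(err[:2]) <= 2.0 and max(err[2:]) <= 0.1

    def test_reaches_small_rmsd_from_grid_best(
        self, toy_protomer, toy_ensembles, truth_pose, truth_restraints
    ):
        grid = GridSpec(
            alpha=np.arange(0.0, 360.0, 10.0),
            beta=np.arange(0.0, 20.1, 5.0),
            x=np.arange(-2.5, 2.51, 0.25),
            y=np.arange(-2.5, 2.51, 0.25),
        )
        ranked = grid_search(toy_protomer, toy_ensembles, truth_restraints, grid=grid, top_k=5)
        objective = DistanceObjective(toy_protomer, toy_ensembles, truth_restraints)
        best = min((refine(r.pose, objective) for r in ranked), key=lambda d: d.score)
        assert best.score < 0.02
        assert best.clash_free

    def test_non_finite_score_raises(self):
        def bad(pose):
            return np.nan

        with pytest.raises(ValueError, match="non-finite"):
            refine(C2Pose(10, 10, 1, 1), bad)


@pytest.fixture(scope="module")
def sweep_setup(toy_protomer, toy_ensembles):
    t = 0.008 * np.arange(201)
    center = toy_protomer.geometric_center
    truth = find_touching_pose(toy_protomer, alpha=60.0, beta=0.0, phi=180.0, min_distance=0.5)
    thinned = {s: e.thinned(24) for s, e in toy_ensembles.items()}
    traces = {
        s: trace_from_pose(thinned[s], truth, t, 0.4, center=center).trace
        for s in RECOVERY_SITES
    }
    return truth, traces, t


class TestContactSweep:
    def test_recovers_touching_pose_invariants(self, toy_protomer, toy_ensembles, sweep_setup):
        truth, traces, _ = sweep_setup
        results = contact_sweep(
            toy_protomer, toy_ensembles, traces, depth=0.4, phi1_step=15.0, phi2_step=15.0,
        )
        best = results[0]
        # for beta = 0 a global z-rotation is a gauge freedom: compare the
        # rotation-minus-direction angle and the touching radius instead
        def invariant(pose):
            psi = (pose.alpha - np.rad2deg(np.arctan2(pose.y, pose.x))) % 360.0
            return psi, float(np.hypot(pose.x, pose.y))

        psi_t, rho_t = invariant(truth)
        psi_b, rho_b = invariant(best.pose)
        dpsi = min(abs(psi_b - psi_t) % 360.0, 360.0 - abs(psi_b - psi_t) % 360.0)
        assert dpsi <= 15.0 + 1e-9
        assert rho_b == pytest.approx(rho_t, abs=0.3)

    def test_chi2_of_trace_against_itself_is_zero(self, toy_protomer, toy_ensembles, sweep_setup):
        truth, traces, _ = sweep_setup
        results = contact_sweep(
            toy_protomer, toy_ensembles, traces, depth=0.4, phi1_step=15.0, phi2_step=15.0,
        )
        # the sweep's histogram-binned forward route differs from the exact
        # per-pair trace generator only by r-grid discretization
        assert results[0].score <= 1e-3

    def test_flat_traces_flat_objective(self, toy_protomer, toy_ensembles, sweep_setup):
        _, _, t = sweep_setup
        flat = {s: DeerTrace(t, np.ones_like(t), kind="form_factor") for s in RECOVERY_SITES}
        results = contact_sweep(
            toy_protomer, toy_ensembles, flat, depth=0.0, phi1_step=45.0, phi2_step=45.0, top_k=100,
        )
        scores = np.array([r.score for r in results])
        np.testing.assert_allclose(scores, 0.0, atol=1e-12)


class TestPoseEquivalence:
    def test_equivalent_pose_scores_identically(self, toy_protomer, toy_ensembles, truth_restraints):
        pose = C2Pose(130.0, 35.0, 1.4, -0.8)
        center = toy_protomer.geometric_center
        s1, _ = score_distance(pose, toy_ensembles, truth_restraints, center=center)
        s2, _ = score_distance(
            pose_equivalents(pose)[1], toy_ensembles, truth_restraints, center=center
        )
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_alpha_wraparound_gauge(self, toy_protomer, toy_ensembles, truth_restraints):
        center = toy_protomer.geometric_center
        s1, _ = score_distance(C2Pose(0.0, 12.0, 1.0, 0.4), toy_ensembles, truth_restraints, center=center)
        s2, _ = score_distance(C2Pose(360.0, 12.0, 1.0, 0.4), toy_ensembles, truth_restraints, center=center)
        assert s1 == pytest.approx(s2, abs=1e-12)


class TestDockResultInvariants:
    def test_negative_score_rejected(self):
        with pytest.raises(ValueError, match="score"):
            DockResult(C2Pose(0, 0, 0, 0), -1.0, "distance", True)

    def test_restraints_validate(self):
        with pytest.raises(ValueError, match="positive"):
            RestraintSet({("A", 1): (-2.0, 0.1)})
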