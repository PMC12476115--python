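"""Constrained ICA: recovery, constraints, windowing, alignment."""

import numpy as np
import pytest

from dynamap.constrained_ica import (IcaProblem, align_priors_to_frames,
                                     fit_constrained, n_windows,
                                     run_windowed)
from dynamap.synthetic import (PhantomSpec, export_references,
                               generate_subject)


def _phantom_problem(noise=0.1, seed=1, epsilon=0.3):
    spec = PhantomSpec(shape=(12, 12, 12), n_timepoints=60, n_networks=3,
                       drift_amplitude=0.0, noise_sigma=noise, seed=seed)
    vol, truth = generate_subject(spec)
    refs = np.stack([r.ravel() for r in export_references(truth)])
    X = vol.data.reshape(-1, spec.n_timepoints).T
    problem = IcaProblem(X=X, references=refs, epsilon_constraint=epsilon)
    return vol, truth, refs, problem


def test_recovers_well_separated_sources_against_truth():
    _, truth, _, problem = _phantom_problem()
    prior = fit_constrained(problem, seed=0)
    for k in range(3):
        r = np.corrcoef(prior.components[k],
                        truth.time_avg_maps[k].ravel())[0, 1]
        assert abs(r) >= 0.95
        assert prior.converged[k]
        assert prior.constraint_correlations[k] >= 0.3


def test_component_rows_have_unit_variance_and_positive_phi():
    _, _, _, problem = _phantom_problem()
    prior = fit_constrained(problem, seed=0)
    assert np.allclose(prior.components.std(axis=1), 1.0, atol=1e-6)
    assert np.all(prior.constraint_correlations >= 0)


def test_single_source_time_course_recovery():
    spec = PhantomSpec(shape=(10, 10, 10), n_timepoints=40, n_networks=1,
                       drift_amplitude=0.0, noise_sigma=0.01, seed=4)
    vol, truth = generate_subject(spec)
    refs = np.stack([r.ravel() for r in export_references(truth)])
    problem = IcaProblem(X=vol.data.reshape(-1, 40).T, references=refs)
    prior = fit_constrained(problem, seed=0)
    r = np.corrcoef(prior.time_courses[:, 0], truth.mixing[:, 0])[0, 1]
    assert abs(r) >= 0.95


def test_infeasible_references_are_flagged_not_raised(rng):
    """References orthogonal to the data cannot meet a 0.9 constraint."""
    _, _, _, problem = _phantom_problem(noise=0.05)
    orthogonal = rng.standard_normal(problem.references.shape)
    problem = IcaProblem(X=problem.X, references=orthogonal,
                         epsilon_constraint=0.9)
    prior = fit_constrained(problem, seed=0)
    assert not prior.converged.any()


def test_more_components_than_timepoints_is_an_error(rng):
    X = rng.standard_normal((2, 50))
    refs = rng.standard_normal((3, 50))
    with pytest.raises(ValueError, match="time points"):
        fit_constrained(IcaProblem(X=X, references=refs), seed=0)


def test_scale_invariance_of_components():
    _, _, _, problem = _phantom_problem()
    p1 = fit_constrained(problem, seed=0)
    scaled = IcaProblem(X=37.0 * problem.X, references=problem.references,
                        epsilon_constraint=0.3)
    p2 = fit_constrained(scaled, seed=0)
    assert np.allclose(p1.components, p2.components, atol=1e-6)


def test_permuting_references_permutes_components():
    _, _, refs, problem = _phantom_problem(noise=0.05)
    p1 = fit_constrained(problem, seed=0)
    perm = [2, 0, 1]
    permuted = IcaProblem(X=problem.X, references=refs[perm],
                          epsilon_constraint=0.3)
    p2 = fit_constrained(permuted, seed=0)
    for i, j in enumerate(perm):
        r = np.corrcoef(p2.components[i], p1.components[j])[0, 1]
        assert abs(r) > 0.98


def test_matches_brute_force_negentropy_search_on_two_source_toy(rng):
    """Grid search over unmixing angles is the oracle on a tiny problem."""
    n = 4000
    s1 = rng.laplace(size=n)
    s2 = rng.laplace(size=n)
    S = np.stack([s1, s2])
    S = (S - S.mean(axis=1, keepdims=True)) / S.std(axis=1, keepdims=True)
    A = np.array([[1.0, 0.4], [0.3, 1.0], [0.8, -0.5], [0.1, 0.9]])
    X = A @ S
    problem = IcaProblem(X=X, references=S, epsilon_constraint=0.3)
    prior = fit_constrained(problem, seed=0)

    # oracle: whiten to 2 PCs, exhaustively scan the unmixing angle for
    # the maximum of the negentropy surrogate
    Xc = X - X.mean(axis=1, keepdims=True)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    Z = Vt[:2] * np.sqrt(n)
    EG = 0.3745672
    best_angle, best_J = None, -np.inf
    for theta in np.linspace(0, np.pi, 3600, endpoint=False):
        c = np.cos(theta) * Z[0] + np.sin(theta) * Z[1]
        J = (np.mean(np.log(np.cosh(c))) - EG) ** 2
        if J > best_J:
            best_J, best_angle = J, theta
    oracle = np.cos(best_angle) * Z[0] + np.sin(best_angle) * Z[1]
    # the best-J direction must match one recovered component (sign-free)
    angles = []
    for k in range(2):
        c = prior.components[k]
        cosang = abs(np.dot(c, oracle) / (np.linalg.norm(c)
                                          * np.linalg.norm(oracle)))
        angles.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
    assert min(angles) < 5.0


@pytest.mark.parametrize("t,window,stride,expected", [
    (100, 30, 1, 71),
    (30, 30, 1, 1),
    (100, 30, 10, 8),
])
def test_window_count_formula(t, window, stride, expected):
    assert n_windows(t, window, stride) == expected


def test_run_windowed_counts_and_window_too_large(noisy_phantom):
    _, vol, truth = noisy_phantom
    refs = np.stack(export_references(truth))
    priors = run_windowed(vol, refs, window=30, stride=10)
    assert len(priors) == n_windows(60, 30, 10)
    assert [p.window_index for p in priors] == [0, 10, 20, 30]
    with pytest.raises(ValueError, match="window"):
        run_windowed(vol, refs, window=61)


def test_growing_amplitude_appears_in_window_time_courses():
    t = 60
    wave = np.linspace(0.2, 3.0, t)[None, :]
    spec = PhantomSpec(shape=(10, 10, 10), n_timepoints=t, n_networks=1,
                       amplitude_waveforms=wave, drift_amplitude=0.0,
                       noise_sigma=0.02, seed=6)
    vol, truth = generate_subject(spec)
    refs = np.stack(export_references(truth))
    priors = run_windowed(vol, refs, window=20, stride=5)
    amplitude = [np.abs(p.time_courses[:, 0]).mean() for p in priors]
    from scipy.stats import spearmanr
    rho, _ = spearmanr(np.arange(len(amplitude)), amplitude)
    assert rho >= 0.8


def test_alignment_selects_nearest_window_with_earlier_tie_break():
    class FakePrior:
        def __init__(self, idx, value):
            self.window_index = idx
            self.components = np.full((1, 8), value)

    mask = np.ones((2, 2, 2), dtype=bool)
    # windows of length 4 starting at 0, 2, 4 -> centers 1.5, 3.5, 5.5
    priors = [FakePrior(0, 0.0), FakePrior(2, 1.0), FakePrior(4, 2.0)]
    aligned = align_priors_to_frames(priors, [1, 4, 7], mask, window=4)
    assert aligned.shape == (1, 2, 2, 2, 3)
    # frame 1 -> center 1.5; frame 4 is nearer center 3.5 than 5.5;
    # frame 7 clamps to the last window
    assert np.all(aligned[0, ..., 0] == 0.0)
    assert np.all(aligned[0, ..., 1] == 1.0)
    assert np.all(aligned[0, ..., 2] == 2.0)
    # exact tie: frame 4.5 equidistant from centers 3.5 and 5.5 ->
    # earlier window wins
    tied = align_priors_to_frames(priors, [4.5], mask, window=4)
    assert np.all(tied[0, ..., 0] == 1.0)


def test_aligned_phantom_priors_match_true_frame_maps():
    spec = PhantomSpec(shape=(12, 12, 12), n_timepoints=60, n_networks=3,
                       drift_amplitude=0.0, noise_sigma=0.05, seed=9)
    vol, truth = generate_subject(spec)
    refs = np.stack(export_references(truth))
    priors = run_windowed(vol, refs, window=30, stride=10)
    frames = [0, 20, 40, 59]
    aligned = align_priors_to_frames(priors, frames, vol.mask_or_full(), 30)
    for j, tau in enumerate(frames):
        for k in range(3):
            r = np.corrcoef(aligned[k, ..., j].ravel(),
                            truth.source_maps[k, tau].ravel())[0, 1]
            assert r >= 0.8
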