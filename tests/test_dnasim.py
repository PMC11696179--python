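"""Reduced promoter-binding simulator: composition, contact rule,
conservation, determinism, and equilibrium sanity."""

import numpy as np
import pytest
from scipy.integrate import tplquad

import cophase.dnasim as ds
from cophase.dnasim import (
    ReducedSystem,
    bound_distribution,
    build_system,
    core_fragment_sequence,
    count_contacts,
    full_scale,
    metropolis_sample,
    random_contact_expectation,
    run_dynamics,
    unit_energy,
)


# ---------------------------------------------------------------------------
# composition


def test_full_scale_composition_matches_study_system():
    system = full_scale(1, seed=0)
    assert system.n_units == 60
    assert len(system.complexes) == 60
    assert system.n_dna == 15
    assert system.box_length == 120.0
    assert system.motif_indices.size == 4


@pytest.mark.parametrize("s, n_complexes, remainder", [(1, 60, 0), (3, 20, 0), (5, 12, 0)])
def test_oligomer_partition_of_sixty_units(s, n_complexes, remainder):
    system = build_system(s, units=60, n_dna=4, box_nm=60.0, seed=1)
    assert len(system.complexes) == n_complexes
    assert system.n_remainder_monomers == remainder
    assert sum(c.unit_indices.size for c in system.complexes) == 60


def test_remainder_units_enter_as_monomers():
    system = build_system(5, units=16, seed=2)
    sizes = sorted(c.unit_indices.size for c in system.complexes)
    assert sizes == [1, 5, 5, 5]
    assert system.n_remainder_monomers == 1


def test_core_fragment_sequence_packaged():
    seq = core_fragment_sequence()
    assert len(seq) == 169
    assert seq.startswith("TATTTCC")
    assert set(seq) <= set("ACGT")


def test_build_validation():
    with pytest.raises(ValueError):
        build_system(0)
    with pytest.raises(ValueError):
        build_system(6)
    with pytest.raises(RuntimeError):
        # impossible packing: many chains in a tiny box
        build_system(1, units=2, n_dna=40, box_nm=10.0, dna_beads=9, max_attempts=20)


# ---------------------------------------------------------------------------
# contact rule


def _single_bead_layout(unit_xyz, box=36.0):
    """One chain whose motif bead 0 sits exactly at the origin."""
    dna = np.zeros((1, 4, 3))
    dna[0, :, 0] = np.arange(4) * ds.DNA_BOND_NM
    units = np.asarray([unit_xyz], dtype=float)
    return units, dna


@pytest.mark.parametrize(
    "offset, bound", [(1.0, 1), (1.2, 1), (1.2000001, 0), (1.5, 0)]
)
def test_contact_cutoff_closed_boundary(offset, bound):
    units, dna = _single_bead_layout([0.0, offset, 0.0])
    counts = count_contacts(units, dna, motif_indices=np.array([0]), box_length=36.0, mode="motif")
    assert counts[0] == bound


def test_contact_counting_uses_minimum_image():
    box = 36.0
    units, dna = _single_bead_layout([box - 1.0, 0.0, 0.0], box)
    counts = count_contacts(units, dna, np.array([0]), box, mode="motif")
    assert counts[0] == 1
    # shifting the unit by whole boxes must not change the decision
    counts2 = count_contacts(units + 3 * box, dna, np.array([0]), box, mode="motif")
    assert counts2[0] == 1


def test_contact_counts_match_brute_force_recount():
    rng = np.random.default_rng(7)
    box = 20.0
    units = rng.uniform(0, box, (25, 3))
    dna = rng.uniform(0, box, (3, 9, 3))
    motifs = np.array([1, 3, 5, 7])
    for mode in ("dna", "motif"):
        fast = count_contacts(units, dna, motifs, box, mode=mode)
        beads = dna if mode == "dna" else dna[:, motifs, :]
        slow = np.zeros(3, dtype=int)
        for c in range(3):
            for u in range(25):
                best = np.inf
                for b in range(beads.shape[1]):
                    d = units[u] - beads[c, b]
                    d -= box * np.round(d / box)
                    best = min(best, float(np.linalg.norm(d)))
                slow[c] += best <= 1.2
        np.testing.assert_array_equal(fast, slow)


# ---------------------------------------------------------------------------
# dynamics invariants


@pytest.fixture(scope="module")
def short_run():
    system = build_system(3, seed=5)
    return system, run_dynamics(system, n_steps=20_000, seed=9)


def test_dynamics_deterministic_given_seed(short_run):
    system, traj = short_run
    again = run_dynamics(system, n_steps=20_000, seed=9)
    np.testing.assert_array_equal(traj.unit_frames, again.unit_frames)
    np.testing.assert_array_equal(traj.dna_frames, again.dna_frames)


def test_unit_count_conserved_every_frame(short_run):
    system, traj = short_run
    assert traj.unit_frames.shape[1] == system.n_units
    assert np.all(np.isfinite(traj.unit_frames))
    assert np.all((traj.unit_frames >= 0) & (traj.unit_frames < system.box_length))


def test_dna_bond_lengths_stay_near_rest(short_run):
    system, traj = short_run
    lengths = []
    for f in range(0, traj.dna_frames.shape[0], 10):
        dna = traj.dna_frames[f]
        d = dna[:, 1:] - dna[:, :-1]
        d -= system.box_length * np.round(d / system.box_length)
        lengths.append(np.linalg.norm(d, axis=-1).ravel())
    lengths = np.concatenate(lengths)
    # thermal spread well inside +/-10% of the rest length
    assert abs(lengths.mean() - ds.DNA_BOND_NM) < 0.02 * ds.DNA_BOND_NM
    assert lengths.std() < 0.05 * ds.DNA_BOND_NM
    assert np.quantile(np.abs(lengths - ds.DNA_BOND_NM), 0.95) < 0.1 * ds.DNA_BOND_NM


def test_bonded_units_stay_within_twice_rest_length(short_run):
    system, traj = short_run
    i, j = system.bond_pairs[:, 0], system.bond_pairs[:, 1]
    for f in range(0, traj.unit_frames.shape[0], 10):
        d = traj.unit_frames[f][i] - traj.unit_frames[f][j]
        d -= system.box_length * np.round(d / system.box_length)
        assert np.all(np.linalg.norm(d, axis=-1) < 2 * ds.UNIT_BOND_NM)


def test_kernel_forces_match_numpy_reference():
    system = build_system(2, seed=11)
    unit = system.unit_pos.copy()
    dna = system.dna_pos.reshape(-1, 3).copy()
    depths = ds._bead_depths(system)
    L = system.dna_pos.shape[1]
    idx = np.arange(system.n_dna * L).reshape(system.n_dna, L)
    slices = (idx[:, 1:].ravel(), idx[:, :-1].ravel())
    f_u, f_d = ds._forces(unit, dna, system, depths, slices)
    dang_a = idx[:, : L - 2].ravel().copy()
    u2, d2 = unit.copy(), dna.copy()
    ds._chunk_steps(
        u2, d2,
        system.bond_pairs[:, 0].copy(), system.bond_pairs[:, 1].copy(),
        system.angle_triples[:, 0].copy(), system.angle_triples[:, 1].copy(),
        system.angle_triples[:, 2].copy(),
        slices[0].copy(), slices[1].copy(),
        dang_a, dang_a + 1, dang_a + 2, depths,
        system.box_length, 0.004, 1.0,
        np.zeros((1, unit.shape[0], 3)), np.zeros((1, dna.shape[0], 3)),
    )
    np.testing.assert_allclose(u2, unit + 0.004 * f_u, atol=1e-12)
    np.testing.assert_allclose(d2, dna + 0.004 * f_d, atol=1e-12)


def test_timestep_stability_guard():
    system = build_system(1, seed=0)
    with pytest.raises(ValueError):
        run_dynamics(system, n_steps=10, dt=0.05)


# ---------------------------------------------------------------------------
# bound statistics


def test_bound_distribution_discards_equilibration_half(short_run):
    system, traj = short_run
    dist = bound_distribution(traj)
    n_frames = traj.unit_frames.shape[0]
    assert dist["counts"].shape == (n_frames - n_frames // 2, system.n_dna)
    assert dist["histogram"].sum() == dist["counts"].size
    assert np.all(dist["counts"] <= system.n_units)


def test_zero_affinity_matches_random_placement_expectation():
    """With the wells off, units are an ideal gas: the mean bound count per
    chain must match the analytic contact-volume expectation within 2 SE."""
    means = []
    for seed in (0, 1, 2):
        system = build_system(
            1, units=16, n_dna=4, box_nm=36.0,
            well_depth=0.0, nonspecific_depth=0.0, seed=seed,
        )
        traj = run_dynamics(system, n_steps=150_000, seed=seed + 50)
        means.append(bound_distribution(traj)["mean"])
    expect = random_contact_expectation(16, 9, 36.0)
    observed = np.mean(means)
    # SE from the per-chain binomial spread over sampled frames (correlated
    # frames: use a conservative effective sample of one per 10 frames)
    n_eff = (150_000 // 250 // 2) * 4 / 10 * 3
    se = expect["sd_per_chain"] / np.sqrt(n_eff)
    assert abs(observed - expect["mean_per_chain"]) < max(2 * se, 0.3 * expect["mean_per_chain"])


def test_ground_state_saturation_is_stable():
    """Deep wells at near-zero temperature keep every motif site occupied
    when units start on the sites (the zero-temperature limit)."""
    system = build_system(1, units=16, n_dna=4, box_nm=36.0,
                          well_depth=20.0, nonspecific_depth=0.0,
                          temperature=0.02, seed=3)
    # place the 16 units exactly on the 16 motif beads
    motif_xyz = system.dna_pos[:, system.motif_indices, :].reshape(-1, 3)
    system.unit_pos = motif_xyz.copy()
    traj = run_dynamics(system, n_steps=20_000, seed=1)
    dist = bound_distribution(traj, mode="motif")
    assert dist["mean"] == pytest.approx(4.0, abs=0.05)


def test_metropolis_two_state_occupancy_matches_boltzmann():
    """One unit, one attractive bead in a small box: Monte-Carlo occupancy of
    the well equals the Boltzmann ratio from direct quadrature."""
    box = 8.0
    eps = 2.0
    dna = np.zeros((1, 1, 3)) + box / 2
    system = ReducedSystem(
        box_length=box,
        dna_pos=dna,
        motif_indices=np.array([0]),
        unit_pos=np.array([[1.0, 1.0, 1.0]]),
        complexes=[],
        bond_pairs=np.empty((0, 2), dtype=int),
        angle_triples=np.empty((0, 3), dtype=int),
        oligomer_state=1,
        n_remainder_monomers=0,
        well_depth=eps,
        nonspecific_depth=0.0,
        seed=0,
    )
    frames = metropolis_sample(system, n_sweeps=120_000, max_step=1.2, seed=4, record_every=5)
    d = frames - box / 2
    d -= box * np.round(d / box)
    r = np.linalg.norm(d[:, 0, :], axis=1)
    occupancy = float(np.mean(r <= ds.CONTACT_CUTOFF_NM))

    rw = ds.WELL_RANGE_NM
    rc = ds.CONTACT_CUTOFF_NM
    from scipy.integrate import quad
    boltz = lambda r_: np.exp(eps * (1 - (r_ / rw) ** 2) ** 2 if r_ < rw else 0.0)
    num, _ = quad(lambda r_: 4 * np.pi * r_**2 * boltz(r_), 0, rc)
    den_in, _ = quad(lambda r_: 4 * np.pi * r_**2 * boltz(r_), 0, rw)
    den = den_in + (box**3 - 4 / 3 * np.pi * rw**3)
    expected = num / den
    assert occupancy == pytest.approx(expected, rel=0.25)


def test_bound_distribution_requires_sampling_frames():
    system = build_system(1, seed=0)
    traj = run_dynamics(system, n_steps=0, sample_stride=200, seed=0)
    with pytest.raises(ValueError):
        bound_distribution(traj)


def test_scan_requires_multiple_states():
    with pytest.raises(ValueError):
        ds.scan_oligomer_states(states=(1,), seeds=(0,), n_steps=1000)


def test_scan_single_seed_flagged():
    table, summary = ds.scan_oligomer_states(
        states=(1, 5), seeds=(0,), n_steps=4000,
    )
    assert summary["single_seed"]
    assert len(table) == 2
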