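"""DF matrices, RMSD series, stable contacts and H-bond occupancies."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import loopdyn as ld
from loopdyn import AtomRecord, LoopdynError, Selection, Structure, Trajectory
from loopdyn.dynamics import (
    canonical_pair,
    compare_contact_sets,
    compare_hbond_occupancy,
    contact_fractions,
    df_compare,
    df_matrix,
    df_matrix_bruteforce,
    hbond_occupancy,
    load_reference_contacts,
    rmsd_series,
    stable_contacts,
)
from loopdyn.synthetic import (
    make_harmonic_trajectory,
    make_rigid_trajectory,
    make_two_state_trajectory,
)


def _ca(chain, seq, xyz, name="GLY", atom="CA", element="C"):
    return AtomRecord(model_index=1, chain_id=chain, res_seq=seq,
                      insertion_code="", res_name=name, atom_name=atom,
                      alt_loc="", element=element,
                      coords=tuple(float(v) for v in xyz))


def _two_residue_trajectory(distances):
    """Two C-alphas on the x axis, one frame per requested distance."""
    top = Structure([_ca("A", 1, (0, 0, 0)), _ca("A", 2, (1, 0, 0))])
    frames = np.array([[[0, 0, 0], [d, 0, 0]] for d in distances], dtype=float)
    return Trajectory(top, frames)


def _random_trajectory(seed, n_res=20, n_frames=50):
    rng = np.random.default_rng(seed)
    atoms = [_ca("A", i + 1, rng.normal(scale=10, size=3))
             for i in range(n_res)]
    top = Structure(atoms)
    frames = top.coords[None] + rng.normal(scale=1.0,
                                           size=(n_frames, n_res, 3))
    return Trajectory(top, frames)


class TestDFMatrix:
    def test_two_frames_two_residues(self):
        """Distances 2 A and 4 A: population variance of {2, 4} is 1."""
        dfm = df_matrix(_two_residue_trajectory([2.0, 4.0]))
        assert dfm.values[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert dfm.values[0, 0] == 0.0 and dfm.values[1, 1] == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_double_loop(self, seed):
        traj = _random_trajectory(seed)
        fast = df_matrix(traj).values
        slow = df_matrix_bruteforce(traj).values
        assert np.abs(fast - slow).max() < 1e-10

    def test_rigid_motion_gives_zero(self, tiny_structure):
        traj = make_rigid_trajectory(tiny_structure, 60, seed=1)
        assert df_matrix(traj).values.max() < 1e-8

    @pytest.mark.parametrize("seed", range(3))
    def test_invariant_under_per_frame_rigid_transforms(self, seed):
        traj = _random_trajectory(seed, n_res=10, n_frames=30)
        before = df_matrix(traj).values
        rng = np.random.default_rng(seed + 100)
        frames = np.empty_like(traj.frames)
        for f in range(traj.n_frames):
            rot = Rotation.random(rng=rng).as_matrix()
            frames[f] = traj.frames[f] @ rot.T + rng.uniform(-30, 30, 3)
        after = df_matrix(Trajectory(traj.topology, frames)).values
        assert np.abs(after - before).max() < 1e-8

    def test_harmonic_limit_is_twice_sigma_squared(self, tiny_structure):
        """At separations >> sigma, DF of independent per-residue jitter
        tends to 2 sigma^2 (each end contributes sigma^2 along the axis)."""
        sigma, n = 0.3, 5000
        traj = make_harmonic_trajectory(tiny_structure, sigma, n, seed=2)
        dfm = df_matrix(traj)
        expected = 2 * sigma ** 2
        se = expected * np.sqrt(2.0 / n)
        # farthest-apart residue pair: separation ~40 A >> sigma
        assert dfm.values[0, -1] == pytest.approx(expected, abs=3 * se)

    def test_symmetry_and_nonnegativity(self):
        v = df_matrix(_random_trajectory(9)).values
        assert np.array_equal(v, v.T)
        assert v.min() >= 0.0
        assert np.all(np.diag(v) == 0.0)

    def test_single_frame_rejected(self):
        with pytest.raises(LoopdynError, match="2 frames"):
            df_matrix(_two_residue_trajectory([3.0]))

    def test_ambiguous_residue_selection_rejected(self, tiny_structure):
        traj = make_harmonic_trajectory(tiny_structure, 0.1, 3, seed=0)
        with pytest.raises(LoopdynError, match="exactly one"):
            df_matrix(traj, Selection.make(atom_names=["CA", "N"]))


class TestDFCompare:
    def test_identical_matrices_give_zero_delta(self):
        a = df_matrix(_random_trajectory(3))
        cmp_res = df_compare(a, a)
        assert np.all(cmp_res.delta == 0.0)

    def test_label_mismatch_rejected(self):
        a = df_matrix(_random_trajectory(3, n_res=5))
        b = df_matrix(_random_trajectory(3, n_res=6))
        with pytest.raises(LoopdynError, match="labels"):
            df_compare(a, b)

    def test_two_state_raises_loop_block_over_one_state(self, default_spec,
                                                        toy_structure):
        spec = default_spec
        mobile, _ = make_two_state_trajectory(
            toy_structure, spec.loop_range, spec.hinge_pair, 45.7, 0.5, 150,
            sigma=0.1, seed=7)
        still, _ = make_two_state_trajectory(
            toy_structure, spec.loop_range, spec.hinge_pair, 45.7, 0.0, 150,
            sigma=0.1, seed=8)
        lo, hi = spec.loop_range
        sel = Selection.make(chains=["A"], atom_names=["CA"])
        df_m, df_s = df_matrix(mobile, sel), df_matrix(still, sel)
        rows = [k for k, (_c, s, _n) in enumerate(df_m.labels) if lo <= s <= hi]
        cols = [k for k, (_c, s, _n) in enumerate(df_m.labels) if s > hi]
        assert np.median(df_m.values[np.ix_(rows, cols)]) > \
            np.median(df_s.values[np.ix_(rows, cols)])

    def test_chainwise_rigid_jitter_has_block_structure(self, toy_structure):
        """Chains moved as independent rigid bodies: intra-chain DF is ~0
        while inter-chain DF is not, giving the block character."""
        rng = np.random.default_rng(11)
        base = toy_structure.coords
        frames = np.empty((40, base.shape[0], 3))
        chain_masks = {c: np.array([a.chain_id == c
                                    for a in toy_structure.atoms])
                       for c in toy_structure.chain_ids}
        for f in range(40):
            frames[f] = base
            for mask in chain_masks.values():
                rot = Rotation.from_rotvec(
                    rng.normal(scale=0.05, size=3)).as_matrix()
                centre = base[mask].mean(axis=0)
                frames[f][mask] = (base[mask] - centre) @ rot.T + centre + \
                    rng.normal(scale=1.0, size=3)
        dfm = df_matrix(Trajectory(toy_structure, frames))
        cmp_res = df_compare(dfm, dfm)
        intra = [cmp_res.block_medians_a[(c, c)]
                 for c in toy_structure.chain_ids]
        inter = [v for (a, b), v in cmp_res.block_medians_a.items() if a != b]
        assert max(intra) < 1e-8
        assert min(inter) > 1e-3


class TestRMSDSeries:
    def test_repeated_reference_gives_zeros(self, tiny_structure):
        traj = Trajectory(tiny_structure,
                          np.stack([tiny_structure.coords] * 4))
        sel = Selection.make(atom_names=["CA"])
        series = rmsd_series(traj, tiny_structure, sel, sel)
        assert np.allclose(series.values, 0.0, atol=1e-10)

    def test_loop_exceeds_core_and_exclusion_lowers_rmsd(self, default_spec,
                                                         toy_structure):
        traj, _ = make_two_state_trajectory(
            toy_structure, default_spec.loop_range, default_spec.hinge_pair,
            45.7, 0.5, 100, sigma=0.1, seed=9)
        lo, hi = default_spec.loop_range
        core = Selection.make(residue_ranges=[(1, lo - 1), (hi + 1, 10 ** 6)],
                              atom_names=["CA"])
        loop = Selection.make(residue_ranges=[(lo, hi)], atom_names=["CA"])
        whole = Selection.make(atom_names=["CA"])
        loop_series = rmsd_series(traj, toy_structure, core, loop)
        core_series = rmsd_series(traj, toy_structure, core, core)
        all_series = rmsd_series(traj, toy_structure, whole, whole)
        assert loop_series.mean > core_series.mean
        assert core_series.mean < all_series.mean  # dropping the loop helps

    def test_empty_selection_rejected(self, tiny_structure):
        traj = Trajectory(tiny_structure,
                          np.stack([tiny_structure.coords] * 2))
        with pytest.raises(LoopdynError):
            rmsd_series(traj, tiny_structure,
                        Selection.make(chains=["Z"]),
                        Selection.make(atom_names=["CA"]))


def _pair_trajectory(distances):
    """Residues on different chains so no neighbor exclusion applies."""
    top = Structure([_ca("A", 1, (0, 0, 0)), _ca("B", 50, (1, 0, 0))])
    frames = np.array([[[0, 0, 0], [d, 0, 0]] for d in distances], dtype=float)
    return Trajectory(top, frames)


class TestStableContacts:
    def test_contact_in_forty_percent_of_frames(self):
        traj = _pair_trajectory([4.0] * 4 + [9.0] * 6)
        cs = stable_contacts(traj, Selection.make(chains=["A"]),
                             Selection.make(chains=["B"]))
        assert len(cs.records) == 1
        assert cs.records[0].fraction == pytest.approx(0.40)

    def test_exactly_thirty_percent_excluded(self):
        traj = _pair_trajectory([4.0] * 3 + [9.0] * 7)
        cs = stable_contacts(traj, Selection.make(chains=["A"]),
                             Selection.make(chains=["B"]))
        assert cs.records == []

    def test_distance_exactly_at_cutoff_is_no_contact(self):
        traj = _pair_trajectory([6.0] * 10)
        fr = contact_fractions(traj, Selection.make(chains=["A"]),
                               Selection.make(chains=["B"]))
        assert list(fr.values()) == [0.0]

    def test_sequence_neighbors_excluded(self):
        top = Structure([_ca("A", 1, (0, 0, 0)), _ca("A", 2, (3.8, 0, 0)),
                         _ca("A", 3, (7.6, 0, 0)), _ca("A", 5, (2.0, 3, 0))])
        traj = Trajectory(top, top.coords[None].repeat(2, axis=0))
        fr = contact_fractions(traj, Selection.make(), Selection.make())
        pairs = set(fr)
        assert canonical_pair(("A", 1, "GLY"), ("A", 2, "GLY")) not in pairs
        assert canonical_pair(("A", 1, "GLY"), ("A", 3, "GLY")) not in pairs
        assert canonical_pair(("A", 1, "GLY"), ("A", 5, "GLY")) in pairs

    def test_monotone_in_cutoffs(self):
        traj = _random_trajectory(13, n_res=8, n_frames=20)
        sel = Selection.make()
        loose = stable_contacts(traj, sel, sel, d_cut=8.0, f_cut=0.1)
        assert stable_contacts(traj, sel, sel, d_cut=6.0,
                               f_cut=0.1).pairs <= loose.pairs
        assert stable_contacts(traj, sel, sel, d_cut=8.0,
                               f_cut=0.5).pairs <= loose.pairs

    def test_no_cutoffs_returns_all_pairs(self):
        traj = _random_trajectory(14, n_res=8, n_frames=5)
        cs = stable_contacts(traj, Selection.make(), Selection.make(),
                             d_cut=np.inf, f_cut=0.0)
        # 8 residues on one chain, |i-j| > 2: 15 pairs
        assert len(cs.pairs) == 15
        assert all(r.fraction == 1.0 for r in cs.records)

    def test_planted_break_fraction_recovered(self, default_spec,
                                              toy_structure):
        p, n = 0.5, 2000
        traj, gt = make_two_state_trajectory(
            toy_structure, default_spec.loop_range, default_spec.hinge_pair,
            45.7, p, n, sigma=0.2, seed=15)
        fr = contact_fractions(
            traj,
            Selection.make(chains=["A"], residue_ranges=[(21, 21)],
                           atom_names=["CA"]),
            Selection.make(chains=["C"], residue_ranges=[(45, 45)],
                           atom_names=["CA"]))
        fraction = next(iter(fr.values()))
        se = np.sqrt(p * (1 - p) / n)
        assert abs(fraction - (1 - p)) < 3 * se
        assert fraction == pytest.approx(
            1 - gt.open_fraction_realized["A"], abs=1e-9)


class TestCompareContactSets:
    def test_self_comparison(self):
        pairs = {canonical_pair(("A", i, "GLY"), ("A", i + 5, "GLY"))
                 for i in range(4)}
        res = compare_contact_sets(pairs, pairs)
        assert res.n_conserved == 4 and res.n_lost == 0 and res.n_gained == 0

    def test_disjoint_sets(self):
        a = {canonical_pair(("A", 1, "X"), ("A", 9, "X"))}
        b = {canonical_pair(("A", 2, "X"), ("A", 9, "X"))}
        res = compare_contact_sets(a, b)
        assert res.n_conserved == 0
        assert res.n_lost == 1 and res.n_gained == 1

    @pytest.mark.parametrize("seed", range(4))
    def test_counts_partition_exactly(self, seed):
        rng = np.random.default_rng(seed)
        universe = [canonical_pair(("A", int(i), "G"), ("B", int(j), "G"))
                    for i in range(6) for j in range(6)]
        holo = {p for p in universe if rng.random() < 0.5}
        apo = {p for p in universe if rng.random() < 0.5}
        res = compare_contact_sets(holo, apo)
        assert res.n_conserved + res.n_lost == len(holo)
        assert res.n_conserved + res.n_gained == len(apo)
        assert not (res.conserved & res.lost) and not (res.conserved & res.gained)

    def test_reference_table_loads(self):
        ref = load_reference_contacts()
        assert set(ref) == {"HOLO", "APO"}
        assert all(len(p) == 2 for p in ref["HOLO"])


def _hbond_pair_structure(distance):
    return Structure([
        _ca("A", 1, (0, 0, 0), atom="N", element="N"),
        _ca("B", 9, (distance, 0, 0), atom="O", element="O"),
    ])


class TestHBonds:
    def test_static_pair_within_cutoff_has_full_occupancy(self):
        s = _hbond_pair_structure(2.9)
        traj = Trajectory(s, s.coords[None].repeat(5, axis=0))
        recs = hbond_occupancy(traj)
        assert len(recs) == 1
        assert recs[0].occupancy == 1.0
        assert recs[0].inter_protomer

    def test_static_pair_beyond_cutoff_absent(self):
        s = _hbond_pair_structure(4.0)
        traj = Trajectory(s, s.coords[None].repeat(5, axis=0))
        assert hbond_occupancy(traj) == []

    def test_intermittent_bond_counts_exactly(self):
        s = _hbond_pair_structure(2.9)
        frames = s.coords[None].repeat(10, axis=0)
        frames[6:, 1, 0] = 8.0  # bond broken in 4 of 10 frames
        recs = hbond_occupancy(Trajectory(s, frames))
        assert recs[0].occupancy == pytest.approx(0.6, abs=1e-12)

    def test_no_polar_atoms_rejected(self):
        s = Structure([_ca("A", 1, (0, 0, 0))])
        traj = Trajectory(s, s.coords[None].repeat(2, axis=0))
        with pytest.raises(LoopdynError, match="polar"):
            hbond_occupancy(traj)


class TestCompareHBonds:
    def _record(self, occ, donor=("A", 23, "SER", "N"),
                acceptor=("C", 120, "SER", "O")):
        return ld.HBondRecord(donor=donor, acceptor=acceptor, occupancy=occ,
                              inter_protomer=True)

    def test_identical_records_give_empty_list(self):
        recs = [self._record(0.5)]
        assert compare_hbond_occupancy(recs, recs) == []

    def test_loop_residue_stabilized_like_the_catalytic_serine(self):
        """A loop-residue bond rising 0.1 -> 0.8 on binding is reported."""
        out = compare_hbond_occupancy([self._record(0.1)],
                                      [self._record(0.8)])
        residues = {s.residue for s in out}
        assert ("A", 23, "SER") in residues
        assert all(s.domain == "N" for s in out
                   if s.residue == ("A", 23, "SER"))

    def test_rise_below_threshold_not_reported(self):
        out = compare_hbond_occupancy([self._record(0.1)],
                                      [self._record(0.3)], delta_cut=0.30)
        assert out == []

    def test_domain_annotation_uses_split(self):
        out = compare_hbond_occupancy(
            [self._record(0.0, acceptor=("C", 283, "GLU", "O"))],
            [self._record(0.9, acceptor=("C", 283, "GLU", "O"))],
            domain_split=190)
        domains = {s.residue: s.domain for s in out}
        assert domains[("C", 283, "GLU")] == "C"
        assert domains[("A", 23, "SER")] == "N"
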