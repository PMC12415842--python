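import numpy as np
import pytest

from condensekit.contacts import (
    ALL_TYPE_PAIRS,
    ContactParams,
    contact_correlation,
    contact_timeseries,
    domain_block_map,
    ensemble_contact_map,
    frame_contacts,
    pair_ratio_table,
    position_profile,
)
from condensekit.core.model import DomainMap
from condensekit.synthetic import SyntheticSpec, generate_chain, generate_slab
from condensekit.synthetic.spec import PlantedContact, SlabSpec

from conftest import brute_force_contacts, make_model


def two_residue_model(gap, n_res=12, res_types=None):
    """Chain of single-CA-like residues; residues 1 and n placed ``gap`` apart.

    Uses GLY (4 heavy atoms) collapsed onto per-residue points far apart,
    except the terminal pair.
    """
    res_types = res_types or ["GLY"] * n_res
    coords = []
    for i in range(n_res):
        base = np.array([100.0 * i, 0.0, 0.0])
        coords.append(np.tile(base, (4, 1)))
    # exactly one candidate heavy-atom pair: residue 0's first atom at the
    # origin and residue n-1's first atom at (gap, 0, 0); all other atoms
    # are parked far away
    coords = np.vstack(coords)
    coords[1:4] = [0.0, -300.0, 0.0]
    coords[-4:] = np.tile([500.0, 500.0, 500.0], (4, 1))
    coords[0] = [0.0, 0.0, 0.0]
    coords[-4] = [gap, 0.0, 0.0]
    return make_model(res_types, coords[None])


class TestFrameContacts:
    def test_pair_beyond_cutoff_is_zero(self):
        m = two_residue_model(5.0)
        intra, inter = frame_contacts(m, 0, ContactParams())
        assert intra[0, 11] == 0

    def test_single_pair_at_4p4(self):
        m = two_residue_model(4.4)
        intra, inter = frame_contacts(m, 0, ContactParams())
        assert intra[0, 11] == 1

    def test_tie_at_cutoff_excluded(self):
        m = two_residue_model(4.5)
        intra, inter = frame_contacts(m, 0, ContactParams())
        assert intra[0, 11] == 0

    def test_proximity_exclusion_window(self):
        # residues 1 and 5 (|i-j| = 4) in contact -> excluded;
        # residues 1 and 6 (|i-j| = 5) -> included
        coords = np.zeros((1, 24, 3))
        for i in range(6):
            coords[0, 4 * i : 4 * i + 4] = [30.0 * i, 0, 0]
        coords[0, 16:20] = [2.0, 0, 0]   # residue 5 near residue 1
        m = make_model(["GLY"] * 6, coords)
        intra, _ = frame_contacts(m, 0, ContactParams())
        assert intra[0, 4] == 0
        coords[0, 16:20] = [300.0, 0, 0]
        coords[0, 20:24] = [2.0, 0, 0]   # residue 6 near residue 1
        m = make_model(["GLY"] * 6, coords)
        intra, _ = frame_contacts(m, 0, ContactParams())
        assert intra[0, 5] == 16  # all 4x4 heavy-atom pairs within cutoff

    @pytest.mark.parametrize("seed", range(6))
    def test_brute_force_equivalence_random_frames(self, seed):
        spec = SyntheticSpec(seed=seed, chain_length=30, frames=2)
        m = generate_chain(spec)
        params = ContactParams()
        for f in range(2):
            fi, fe = frame_contacts(m, f, params)
            bi, be = brute_force_contacts(m, f, params)
            np.testing.assert_array_equal(fi, bi)
            np.testing.assert_array_equal(fe, be)

    def test_brute_force_equivalence_with_box(self):
        spec = SyntheticSpec(
            seed=5, chain_length=12, n_chains=2, frames=2,
            slab=SlabSpec(box=(40.0, 40.0, 60.0), dense_z_extent=40.0),
        )
        m = generate_slab(spec)
        params = ContactParams()
        for f in range(2):
            fi, fe = frame_contacts(m, f, params)
            bi, be = brute_force_contacts(m, f, params)
            np.testing.assert_array_equal(fi, bi)
            np.testing.assert_array_equal(fe, be)

    def test_cutoff_monotonicity(self):
        m = generate_chain(SyntheticSpec(seed=8, chain_length=25, frames=1))
        small = frame_contacts(m, 0, ContactParams(cutoff=4.0))
        large = frame_contacts(m, 0, ContactParams(cutoff=6.0))
        assert np.all(large[0] >= small[0])
        assert np.all(large[1] >= small[1])

    def test_atom_permutation_invariance(self, rng):
        m = generate_chain(SyntheticSpec(seed=2, chain_length=15, frames=1))
        intra1, _ = frame_contacts(m, 0, ContactParams())
        # permute atom coordinates within each residue
        coords = m.trajectory.coords.copy()
        top = m.topology
        for r in range(top.n_residues):
            atoms = top.residue_atoms(r)
            coords[0, atoms] = coords[0, rng.permutation(atoms)]
        m2 = m.with_trajectory(type(m.trajectory)(coords))
        intra2, _ = frame_contacts(m2, 0, ContactParams())
        np.testing.assert_array_equal(intra1, intra2)

    def test_inter_channel_independent_of_exclusion(self):
        spec = SyntheticSpec(
            seed=5, chain_length=12, n_chains=3, frames=1,
            slab=SlabSpec(box=(30.0, 30.0, 50.0), dense_z_extent=20.0),
        )
        m = generate_slab(spec)
        _, inter0 = frame_contacts(m, 0, ContactParams(proximity_exclusion=0))
        _, inter9 = frame_contacts(m, 0, ContactParams(proximity_exclusion=9))
        np.testing.assert_array_equal(inter0, inter9)


class TestEnsembleMap:
    def test_single_frame_equals_frame_map(self):
        m = generate_chain(SyntheticSpec(seed=3, chain_length=20, frames=1))
        cm = ensemble_contact_map(m)
        fi, fe = frame_contacts(m, 0, cm.params)
        np.testing.assert_array_equal(cm.intra, fi)
        np.testing.assert_array_equal(cm.inter, fe)

    def test_two_identical_frames_average_identity(self):
        m = generate_chain(SyntheticSpec(seed=3, chain_length=20, frames=1))
        coords = np.vstack([m.trajectory.coords, m.trajectory.coords])
        m2 = m.with_trajectory(type(m.trajectory)(coords))
        cm1 = ensemble_contact_map(m)
        cm2 = ensemble_contact_map(m2)
        np.testing.assert_allclose(cm1.total, cm2.total)

    def test_empty_frame_range_errors(self):
        m = generate_chain(SyntheticSpec(seed=3, chain_length=20, frames=2))
        with pytest.raises(ValueError, match="empty"):
            ensemble_contact_map(m, slice(5, 5))

    def test_planted_contact_ranks_top(self):
        # planted residues pinned to Trp (max heavy-atom count) so the
        # planted cell's per-frame count dominates transient coil contacts
        g = np.random.default_rng(21)
        seq = "".join(g.choice(list("ACDEFGHIKLMNPQRSTVY"), size=50))
        seq = seq[:4] + "W" + seq[5:39] + "W" + seq[40:]
        spec = SyntheticSpec(seed=21, chain_length=50, frames=10, sequence=seq,
                             planted_contacts=[PlantedContact(5, 40, 4.0)])
        m = generate_chain(spec)
        cm = ensemble_contact_map(m)
        planted = cm.total[4, 39]
        assert planted > 0
        # planted pair beats every sequence-distal pair (|i-j| >= 10)
        mask = np.zeros_like(cm.total, dtype=bool)
        iu = np.triu_indices_from(cm.total, k=10)
        mask[iu] = True
        mask[4, 39] = False
        assert planted > cm.total[mask].max()

    def test_intra_plus_inter_is_total(self):
        spec = SyntheticSpec(
            seed=5, chain_length=12, n_chains=2, frames=2,
            slab=SlabSpec(box=(30.0, 30.0, 50.0), dense_z_extent=25.0),
        )
        m = generate_slab(spec)
        cm = ensemble_contact_map(m)
        np.testing.assert_allclose(cm.intra + cm.inter, cm.total)

    def test_per_chain_average(self):
        spec = SyntheticSpec(
            seed=5, chain_length=12, n_chains=4, frames=1,
            slab=SlabSpec(box=(30.0, 30.0, 50.0), dense_z_extent=25.0),
        )
        m = generate_slab(spec)
        cm = ensemble_contact_map(m)
        np.testing.assert_allclose(cm.per_chain("total"), cm.total / 4)


class TestPositionProfile:
    def test_zero_matrix(self):
        m = generate_chain(SyntheticSpec(seed=3, chain_length=10, frames=1))
        cm = ensemble_contact_map(m)
        zero = np.zeros_like(cm.total)
        np.testing.assert_array_equal(position_profile(zero), np.zeros(10))

    def test_single_cell(self):
        mat = np.zeros((8, 8))
        mat[2, 6] = 3.0
        prof = position_profile(mat)
        assert prof[2] == 3.0 and prof[6] == 3.0
        assert prof.sum() == 6.0

    def test_random_matrix_oracle(self, rng):
        mat = np.triu(rng.uniform(size=(15, 15)), k=1)
        prof = position_profile(mat)
        manual = np.array(
            [mat[i, :].sum() + mat[:, i].sum() for i in range(15)]
        )
        np.testing.assert_allclose(prof, manual)
        assert prof.sum() == pytest.approx(2 * mat.sum())


class TestDomainBlocks:
    def test_identity_partition_returns_original(self):
        m = generate_chain(SyntheticSpec(seed=4, chain_length=12, frames=2))
        cm = ensemble_contact_map(m)
        dm = DomainMap([(f"D{i}", i, i) for i in range(1, 13)])
        blocks = domain_block_map(cm, dm)
        np.testing.assert_allclose(blocks.to_numpy(), np.triu(cm.total))

    def test_single_domain_scalar_total(self):
        m = generate_chain(SyntheticSpec(seed=4, chain_length=12, frames=2))
        cm = ensemble_contact_map(m)
        blocks = domain_block_map(cm, DomainMap([("ALL", 1, 12)]))
        assert blocks.loc["ALL", "ALL"] == pytest.approx(cm.total.sum())

    def test_block_sums_match_brute_force(self):
        dm = DomainMap([("N", 1, 10), ("M", 11, 25), ("C", 26, 40)])
        m = generate_chain(SyntheticSpec(seed=6, chain_length=40, frames=3,
                                         domain_map=dm))
        cm = ensemble_contact_map(m)
        blocks = domain_block_map(cm, dm)
        assert blocks.to_numpy().sum() == pytest.approx(cm.total.sum())
        manual = cm.total[0:10, 10:25].sum() + cm.total[10:25, 0:10].sum()
        assert blocks.loc["N", "M"] == pytest.approx(manual)

    def test_unassigned_positions_warn(self):
        m = generate_chain(SyntheticSpec(seed=4, chain_length=12, frames=1))
        cm = ensemble_contact_map(m)
        with pytest.warns(UserWarning, match="unassigned"):
            blocks = domain_block_map(cm, DomainMap([("HALF", 1, 6)]))
        assert "unassigned" in blocks.index


class TestPairRatios:
    def test_only_r_y_contact(self):
        m = generate_chain(SyntheticSpec(
            seed=1, chain_length=12,
            sequence="GRGGGGGGGGYG", frames=1,
        ))
        # place residues far apart, then move Y (idx 10) next to R (idx 1)
        top = m.topology
        c = m.trajectory.coords.copy()
        for r in range(12):
            c[0, top.residue_atoms(r)] += np.array([200.0 * r, 0, 0])
        y_atoms = top.residue_atoms(10)
        shift = c[0, top.find_atom(1, "CA")] + 1.0 - c[0, top.find_atom(10, "CA")]
        c[0, y_atoms] += shift
        m2 = m.with_trajectory(type(m.trajectory)(c))
        table = pair_ratio_table(ensemble_contact_map(m2))
        row = table.rows.iloc[0]
        assert row["pair"] == "RY"
        assert row["contact_ratio"] == pytest.approx(1.0)
        assert table.rows["contact_ratio"].iloc[1:].sum() == 0

    def test_all_glycine_only_gg(self):
        m = generate_chain(SyntheticSpec(seed=2, chain_length=30,
                                         sequence="G" * 30, frames=1))
        table = pair_ratio_table(ensemble_contact_map(m))
        nonzero = table.rows[table.rows["contact_ratio"] > 0]
        assert set(nonzero["pair"]) <= {"GG"}

    def test_ratios_sum_to_one(self):
        m = generate_chain(SyntheticSpec(seed=9, chain_length=40, frames=3))
        table = pair_ratio_table(ensemble_contact_map(m))
        if table.rows["contact_ratio"].sum() > 0:
            assert table.rows["contact_ratio"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_210_bins(self):
        assert len(ALL_TYPE_PAIRS) == 210

    def test_brute_force_tally(self):
        m = generate_chain(SyntheticSpec(seed=9, chain_length=25, frames=2))
        cm = ensemble_contact_map(m)
        table = pair_ratio_table(cm)
        one = [
            {"ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
             "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
             "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
             "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V"}[rt]
            for rt in cm.res_types
        ]
        tally: dict[str, float] = {}
        for i in range(25):
            for j in range(i, 25):
                if cm.total[i, j]:
                    key = "".join(sorted((one[i], one[j])))
                    tally[key] = tally.get(key, 0.0) + cm.total[i, j]
        total = sum(tally.values())
        for _, row in table.rows.iterrows():
            expected = tally.get(row["pair"], 0.0) / total
            assert row["contact_ratio"] == pytest.approx(expected)

    def test_normalized_by_aa_count(self):
        m = generate_chain(SyntheticSpec(seed=9, chain_length=25, frames=2))
        cm = ensemble_contact_map(m)
        table = pair_ratio_table(cm)
        for _, row in table.per_type.iterrows():
            if row["aa_count"]:
                assert row["normalized"] == pytest.approx(
                    row["mean_contacts"] / row["aa_count"]
                )

    def test_rank_invariant_under_scaling(self):
        m = generate_chain(SyntheticSpec(seed=9, chain_length=40, frames=2))
        cm = ensemble_contact_map(m)
        t1 = pair_ratio_table(cm)
        cm.intra = cm.intra * 7.5
        cm.inter = cm.inter * 7.5
        t2 = pair_ratio_table(cm)
        assert list(t1.rows["pair"]) == list(t2.rows["pair"])


class TestCorrelation:
    def test_self_correlation_is_one(self):
        m = generate_chain(SyntheticSpec(seed=9, chain_length=40, frames=2))
        table = pair_ratio_table(ensemble_contact_map(m))
        r, slope = contact_correlation(table, table)
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)

    def test_negation_gives_minus_one(self, rng):
        v = rng.uniform(0.1, 1.0, size=50)
        r, _ = contact_correlation(v, -v)
        assert r == pytest.approx(-1.0)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="3"):
            contact_correlation(np.zeros(10), np.zeros(10))

    def test_both_zero_bins_dropped(self, rng):
        a = np.concatenate([rng.uniform(size=5), np.zeros(100)])
        b = np.concatenate([rng.uniform(size=5), np.zeros(100)])
        r1, _ = contact_correlation(a, b)
        r2, _ = contact_correlation(a[:5], b[:5])
        assert r1 == pytest.approx(r2)

    def test_independent_tables_null(self):
        rs = []
        for seed in range(100):
            g = np.random.default_rng(seed)
            a = g.uniform(size=210)
            b = g.uniform(size=210)
            r, _ = contact_correlation(a, b)
            rs.append(abs(r))
        assert np.quantile(rs, 0.95) < 0.3


class TestTimeseries:
    def test_static_trajectory_constant(self):
        m = generate_chain(SyntheticSpec(seed=3, chain_length=20, frames=1))
        coords = np.repeat(m.trajectory.coords, 4, axis=0)
        m2 = m.with_trajectory(type(m.trajectory)(coords))
        ts = contact_timeseries(m2)
        assert ts["total_contacts"].nunique() == 1

    def test_alternating_frames(self):
        m = two_residue_model(4.0)
        apart = m.trajectory.coords.copy()
        apart[0, -4] = [50.0, 0, 0]
        coords = np.vstack([m.trajectory.coords, apart] * 2)
        m2 = m.with_trajectory(type(m.trajectory)(coords))
        ts = contact_timeseries(m2)
        assert list(ts["total_contacts"]) == [1.0, 0.0, 1.0, 0.0]

    def test_matches_frame_oracle(self):
        m = generate_chain(SyntheticSpec(seed=7, chain_length=25, frames=4))
        ts = contact_timeseries(m)
        params = ContactParams()
        for f in range(4):
            fi, fe = frame_contacts(m, f, params)
            assert ts["total_contacts"][f] == fi.sum() + fe.sum()
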