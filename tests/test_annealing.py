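"""Rigid-body annealing: moves, energies, ranking, recovery mechanics."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from interdom.annealing import (
    AnnealingSchedule,
    FlatWellRestraint,
    anneal_once,
    flat_well_energy,
    initialize_system,
    rank_ensemble,
    RigidConformation,
)
from interdom.structures import Structure

FAST = AnnealingSchedule(n_steps=12, moves_per_step=120)


def _conf(total_parts, run_index=0):
    r, c, l = total_parts
    st = Structure(chain=["A"], resnum=[1], resname=["GLY"], atomname=["CA"], element=["C"], xyz=[[0, 0, 0]])
    return RigidConformation(
        structure=st, energy_restraint=r, energy_clash=c, energy_linker=l, run_index=run_index
    )


class TestFlatWell:
    def test_zero_inside_well_quadratic_outside(self):
        d = np.array([0.0, 10.0, 27.0, 28.0, 30.0])
        e = flat_well_energy(d, np.zeros(5), np.full(5, 27.0), np.ones(5))
        assert np.allclose(e[:3], 0.0)
        assert e[3] == pytest.approx(1.0)  # (28-27)^2
        assert e[4] == pytest.approx(9.0)

    def test_continuous_at_boundary(self):
        eps = 1e-8
        e = flat_well_energy(np.array([27.0 + eps]), np.array([0.0]), np.array([27.0]), np.array([1.0]))
        assert e[0] < 1e-12

    def test_lower_bound_active(self):
        e = flat_well_energy(np.array([2.0]), np.array([5.0]), np.array([27.0]), np.array([1.0]))
        assert e[0] == pytest.approx(9.0)


class TestInitialization:
    def test_null_randomization_is_identity(self, toy_closed):
        sys0 = initialize_system(
            toy_closed.structure, toy_closed.partition, seed=0,
            max_translation=0.0, max_rotation_deg=0.0,
        )
        assert np.allclose(sys0.coords(), sys0.reference, atol=1e-9)

    def test_seed_determinism(self, toy_closed):
        a = initialize_system(toy_closed.structure, toy_closed.partition, seed=42)
        b = initialize_system(toy_closed.structure, toy_closed.partition, seed=42)
        assert np.array_equal(a.coords(), b.coords())

    def test_translation_bound_respected_and_approached(self, toy_closed):
        # empirical displacement distribution over many initializations
        disps = []
        for s in range(300):
            sys_s = initialize_system(
                toy_closed.structure, toy_closed.partition, seed=s, max_translation=20.0
            )
            for label in sys_s.mobile:
                disps.append(np.linalg.norm(sys_s.translations[label]))
        disps = np.array(disps)
        assert disps.max() <= 20.0 + 1e-9
        assert disps.max() > 18.0  # supremum approached

    def test_anchor_domain_fixed(self, toy_closed):
        sys0 = initialize_system(toy_closed.structure, toy_closed.partition, seed=3)
        idx = sys0.domain_idx[sys0.anchor]
        assert np.allclose(sys0.coords()[idx], sys0.reference[idx])

    def test_single_domain_partition_rejected(self, toy_closed):
        from interdom.partition import DomainPartition

        res = toy_closed.structure.residues()
        solo = DomainPartition({"all": [(int(res.min()), int(res.max()))]})
        with pytest.raises(ValueError, match="two domains"):
            initialize_system(toy_closed.structure, solo)


class TestAnnealing:
    def test_zero_restraints_keeps_zero_restraint_energy(self, toy_closed):
        from interdom.annealing import _Energy

        sys0 = initialize_system(toy_closed.structure, toy_closed.partition, seed=1,
                                 max_translation=0.0, max_rotation_deg=0.0)
        energy = _Energy(sys0, [])
        coords = sys0.coords()
        e_start = energy.clash(coords) + energy.linker_bonds(coords)
        conf = anneal_once(sys0, [], FAST, seed=1)
        assert conf.energy_restraint == 0.0
        # best-visited energy can never exceed the starting energy
        assert conf.total_energy <= e_start + 1e-9

    def test_within_domain_rigidity(self, toy_closed, toy_links):
        from interdom.xl import read_crosslink_table

        csv, _ = toy_links
        links = read_crosslink_table(csv)
        restraints = [
            FlatWellRestraint(int(r.residue_a), int(r.residue_b)) for r in links.itertuples()
        ]
        sys0 = initialize_system(toy_closed.structure, toy_closed.partition, seed=2)
        conf = anneal_once(sys0, restraints, FAST, seed=2)
        res_in, xyz_in = toy_closed.structure.ca_table()
        res_out, xyz_out = conf.structure.ca_table()
        for label, ranges in toy_closed.partition.segments.items():
            a, b = ranges[0]
            m_in = (res_in >= a) & (res_in <= b)
            m_out = (res_out >= a) & (res_out <= b)
            assert np.allclose(pdist(xyz_in[m_in]), pdist(xyz_out[m_out]), atol=1e-6)

    def test_determinism_given_seed(self, toy_closed):
        restraints = [FlatWellRestraint(5, 60)]
        sys0 = initialize_system(toy_closed.structure, toy_closed.partition, seed=4)
        c1 = anneal_once(sys0, restraints, FAST, seed=9)
        c2 = anneal_once(sys0, restraints, FAST, seed=9)
        assert np.array_equal(c1.structure.xyz, c2.structure.xyz)
        assert c1.total_energy == c2.total_energy

    def test_restraint_pulls_pair_together(self, toy_open):
        # a single tight restraint between far domains must shrink the distance
        st = toy_open.structure
        res = st.residues()
        a, b = int(res.min()) + 10, int(res.max()) - 10
        d0 = np.linalg.norm(st.ca_coord(a) - st.ca_coord(b))
        sys0 = initialize_system(st, toy_open.partition, seed=0,
                                 max_translation=0.0, max_rotation_deg=0.0)
        conf = anneal_once(sys0, [FlatWellRestraint(a, b, upper=20.0)], FAST, seed=0)
        d1 = np.linalg.norm(conf.structure.ca_coord(a) - conf.structure.ca_coord(b))
        assert d1 < d0
        assert d1 < 25.0


class TestRanking:
    def test_ascending_energy_order(self):
        confs = [_conf((5, 0, 0), 0), _conf((3, 0, 0), 1), _conf((9, 0, 0), 2)]
        ranked = rank_ensemble(confs, k=3)
        assert [c.total_energy for c in ranked] == [3, 5, 9]
        assert [c.rank for c in ranked] == [1, 2, 3]

    def test_tie_broken_by_restraint_energy(self):
        confs = [_conf((2, 2, 0), 0), _conf((1, 3, 0), 1)]
        ranked = rank_ensemble(confs, k=2)
        assert ranked[0].energy_restraint == 1

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            rank_ensemble([_conf((1, 0, 0))], k=0)


def test_unrestrained_control_does_not_converge(toy_closed, toy_links):
    """With negligible restraint weight the ensemble stays as scattered as the
    random initializations (negative control)."""
    from interdom.xl import read_crosslink_table

    csv, _ = toy_links
    links = read_crosslink_table(csv)
    restraints = [
        FlatWellRestraint(int(r.residue_a), int(r.residue_b)) for r in links.itertuples()
    ]
    schedule = AnnealingSchedule(n_steps=10, moves_per_step=100, w_xl_start=1e-9, w_xl_end=2e-9)
    pairs = [(r.res_a, r.res_b) for r in restraints]

    def euclid_satisfied(st):
        return sum(
            np.linalg.norm(st.ca_coord(a) - st.ca_coord(b)) <= 27.0 for a, b in pairs
        )

    final_counts, init_counts = [], []
    for s in range(6):
        sys0 = initialize_system(toy_closed.structure, toy_closed.partition, seed=s)
        init_counts.append(euclid_satisfied(sys0.template.__class__(
            chain=sys0.template.chain, resnum=sys0.template.resnum,
            resname=sys0.template.resname, atomname=sys0.template.atomname,
            element=sys0.template.element, xyz=sys0.coords(),
        )))
        conf = anneal_once(sys0, restraints, schedule, seed=s)
        final_counts.append(euclid_satisfied(conf.structure))
    # no systematic improvement without restraint force
    assert np.mean(final_counts) <= np.mean(init_counts) + 2.0
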