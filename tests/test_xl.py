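"""Cross-link tables, SLD/SASD computation and satisfaction classification."""

import numpy as np
import pytest

from interdom.partition import assign_domains
from interdom.xl import (
    CrossLinkError,
    SasdCalculator,
    classify_crosslinks,
    compute_sasd,
    compute_sld,
    read_crosslink_table,
)

HEADER = "protein_a,residue_a,protein_b,residue_b,chemistry\n"


class TestTableParsing:
    def test_residue_letter_prefix_parsed(self):
        df = read_crosslink_table(HEADER + "SurA,K105,SurA,K278,DSBU\n")
        assert len(df) == 1
        assert df.loc[0, "residue_a"] == 105 and df.loc[0, "residue_b"] == 278
        assert df.loc[0, "chemistry"] == "DSBU"

    def test_symmetric_duplicates_collapse(self):
        csv = HEADER + "P,K90,P,K134,DSBU\nP,K134,P,K90,DSBU\n"
        with pytest.warns(UserWarning, match="duplicate"):
            df = read_crosslink_table(csv)
        assert len(df) == 1

    def test_missing_column_is_schema_error(self):
        with pytest.raises(CrossLinkError, match="missing column"):
            read_crosslink_table("protein_a,residue_a\nP,1\n")

    def test_bad_residue_reports_row(self):
        with pytest.raises(CrossLinkError, match="row 2"):
            read_crosslink_table(HEADER + "P,1,P,2,DSBU\nP,xx9y,P,3,DSBU\n")


class TestSld:
    def test_axis_aligned_distance(self, make_ca_structure):
        st = make_ca_structure([[0, 0, 0], [0, 0, 10]])
        assert compute_sld(st, 1, 2) == pytest.approx(10.0)

    def test_self_distance_zero(self, make_ca_structure):
        st = make_ca_structure([[1, 2, 3]])
        assert compute_sld(st, 1, 1) == 0.0


class TestSasd:
    def test_free_space_approaches_sld(self, make_ca_structure):
        st = make_ca_structure([[0, 0, 0], [0, 0, 12]])
        sasd = compute_sasd(st, 1, 2, spacing=1.0)
        assert abs(sasd - 12.0) <= 1.0  # within one grid spacing

    def test_slab_forces_detour(self, make_ca_structure):
        # two Cα on opposite sides of a solid wall of dummy beads
        wall = [
            [x, y, 0.0]
            for x in np.arange(-10, 10.1, 1.5)
            for y in np.arange(-10, 10.1, 1.5)
        ]
        st = make_ca_structure([[0, 0, -6], [0, 0, 6]] + wall)
        calc = SasdCalculator(st, spacing=1.0)
        sasd = calc.sasd(1, 2)
        sld = compute_sld(st, 1, 2)
        assert np.isfinite(sasd) and sasd > 1.5 * sld

    def test_symmetry(self, toy_closed):
        calc = SasdCalculator(toy_closed.structure, spacing=1.5)
        assert calc.sasd(1, 60) == pytest.approx(calc.sasd(60, 1), abs=1e-9)

    def test_sasd_at_least_sld(self, toy_closed):
        st = toy_closed.structure
        calc = SasdCalculator(st, spacing=1.5)
        rng = np.random.default_rng(0)
        res = st.residues()
        pairs = [tuple(map(int, rng.choice(res, 2, replace=False))) for _ in range(12)]
        sasd = calc.sasd_many(pairs)
        for (a, b), s in zip(pairs, sasd):
            assert s >= compute_sld(st, a, b) - 1e-9

    def test_grid_refinement_converges_in_free_space(self, make_ca_structure):
        st = make_ca_structure([[0, 0, 0], [0, 0, 15]])
        coarse = compute_sasd(st, 1, 2, spacing=2.0)
        fine = compute_sasd(st, 1, 2, spacing=1.0)
        assert abs(coarse - fine) <= 2.0  # within one coarse spacing

    def test_degenerate_structure_rejected(self, make_ca_structure):
        st = make_ca_structure([[0, 0, 0], [0, 0, 0]])
        with pytest.raises(CrossLinkError, match="degenerate"):
            SasdCalculator(st)


class TestClassification:
    def _structure_with_pair(self, make_ca_structure, d):
        return make_ca_structure([[0, 0, 0], [0, 0, d]])

    @pytest.mark.parametrize(
        "chem,dist,expected",
        [
            ("tag-transfer", 15.0, True),  # boundary inclusive
            ("tag-transfer", 15.5, False),
            ("DSBU", 20.0, True),
            ("DSBU", 50.0, False),
        ],
    )
    def test_cutoff_boundaries(self, make_ca_structure, chem, dist, expected):
        st = self._structure_with_pair(make_ca_structure, dist)
        df = read_crosslink_table(HEADER + f"P,1,P,2,{chem}\n")
        table, summary = classify_crosslinks(df, st)
        assert bool(table.loc[0, "satisfied"]) is expected

    def test_dsbu_sasd_boundary_inclusive(self, make_ca_structure):
        # free space: SASD tracks SLD, so 35.0 Å separation stays satisfied
        # and 36.5 Å falls outside even with grid slack
        st = self._structure_with_pair(make_ca_structure, 34.0)
        df = read_crosslink_table(HEADER + "P,1,P,2,DSBU\n")
        table, _ = classify_crosslinks(df, st)
        assert bool(table.loc[0, "satisfied"])

    def test_missing_residue_unevaluable(self, make_ca_structure):
        st = self._structure_with_pair(make_ca_structure, 10.0)
        df = read_crosslink_table(HEADER + "P,1,P,99,DSBU\n")
        with pytest.warns(UserWarning, match="absent"):
            table, summary = classify_crosslinks(df, st)
        assert table.loc[0, "status"] == "unevaluable"
        assert summary["evaluable"] == 0

    def test_true_links_satisfied_on_ground_truth(self, toy_closed, toy_links):
        csv, truth = toy_links
        df = read_crosslink_table(csv)
        asg = assign_domains(toy_closed.structure, toy_closed.partition)
        table, summary = classify_crosslinks(
            df, toy_closed.structure, asg, spacing=1.5
        )
        merged = table.merge(truth, on=["residue_a", "residue_b"], suffixes=("", "_t"))
        true_rows = merged[merged["is_true"]]
        # links were sampled at Euclidean <= 25 Å on this conformation; all
        # must fall within the 35 Å SASD feasibility cutoff
        assert true_rows["satisfied"].all()
        assert (merged["relation"] == "inter-domain").all()

    def test_false_links_mostly_violated_on_decoy(self, toy_open, toy_links):
        csv, truth = toy_links
        df = read_crosslink_table(csv)
        table, summary = classify_crosslinks(df, toy_open.structure, spacing=1.5)
        merged = table.merge(truth, on=["residue_a", "residue_b"], suffixes=("", "_t"))
        true_rows = merged[merged["is_true"]]
        # on the open decoy most ground-truth contacts are broken
        assert (~true_rows["satisfied"]).mean() > 0.5


def test_crosslink_table_exports_flat_well_restraints():
    from interdom.xl import crosslinks_to_restraints

    df = read_crosslink_table(HEADER + "P,K10,P,K50,DSBU\nP,K5,P,K40,DSBU\n")
    restraints = crosslinks_to_restraints(df, upper=27.0)
    assert len(restraints) == 2
    assert {(r.res_a, r.res_b) for r in restraints} == {(10, 50), (5, 40)}
    assert all(r.lower == 0.0 and r.upper == 27.0 for r in restraints)
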