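"""Synthetic-data generators: determinism, constructed properties, schemas."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from interdom.synthetic import (
    HDX_TIMEPOINTS,
    HdxPeptideProfile,
    Population,
    StreamConfig,
    make_hdx_profiles,
    make_toy_multidomain,
    simulate_crosslinks,
    simulate_hdx,
    simulate_isotherm,
    simulate_photon_stream,
)


class TestToyStructures:
    def test_closed_conformation_contacts(self, toy_closed):
        cents = toy_closed.domain_centroids()
        labels = list(cents)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                assert np.linalg.norm(cents[a] - cents[b]) <= toy_closed.contact_bound + 1e-6

    def test_seed_determinism(self):
        a = make_toy_multidomain(seed=5)
        b = make_toy_multidomain(seed=5)
        assert np.array_equal(a.structure.xyz, b.structure.xyz)

    def test_open_and_closed_share_domain_geometry(self, toy_closed, toy_open):
        res_c, xyz_c = toy_closed.structure.ca_table()
        res_o, xyz_o = toy_open.structure.ca_table()
        for label, ranges in toy_closed.partition.segments.items():
            a, b = ranges[0]
            mc = (res_c >= a) & (res_c <= b)
            mo = (res_o >= a) & (res_o <= b)
            assert np.allclose(pdist(xyz_c[mc]), pdist(xyz_o[mo]), atol=1e-8)

    def test_chain_geometry_valid(self, toy_closed):
        _, xyz = toy_closed.structure.ca_table()
        steps = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
        assert steps.min() >= 3.4 and steps.max() <= 4.2
        # no non-bonded pair closer than 3.0 Å
        d = pdist(xyz)
        assert np.sort(d)[: len(xyz) - 1].min() >= 3.0

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            make_toy_multidomain(n_domains=1)
        with pytest.raises(ValueError):
            make_toy_multidomain(sizes=(10, 10, 10))


class TestCrosslinkSimulation:
    def test_true_links_within_cutoff_false_beyond(self, toy_closed):
        csv, truth = simulate_crosslinks(toy_closed, n_true=10, n_false=3, cutoff=25.0, seed=2)
        assert (truth.loc[truth["is_true"], "distance"] <= 25.0).all()
        assert (truth.loc[~truth["is_true"], "distance"] > 35.0).all()

    def test_schema_accepted_by_reader(self, toy_closed):
        from interdom.xl import read_crosslink_table

        csv, truth = simulate_crosslinks(toy_closed, n_true=8, n_false=2, seed=3)
        df = read_crosslink_table(csv)
        assert len(df) == 10
        assert set(df["chemistry"]) == {"DSBU"}

    def test_infeasible_request_reports_maximum(self, toy_closed):
        with pytest.raises(ValueError, match="site pairs"):
            simulate_crosslinks(toy_closed, n_true=10000, seed=0)


class TestPhotonSimulation:
    def test_pooled_acceptor_fraction_matches_e(self):
        cfg = StreamConfig(
            populations=[Population(E=0.5)],
            background={"dd": 0.0, "ad": 0.0, "aa": 0.0, "da": 0.0},
        )
        d, truth = simulate_photon_stream(cfg, duration=20.0, seed=0)
        from interdom.bursts import PhotonStream

        stream = PhotonStream.from_dict(d)
        labels = stream.stream_labels()
        n_ad = (labels == "ad").sum()
        n_dd = (labels == "dd").sum()
        frac = n_ad / (n_ad + n_dd)
        assert frac == pytest.approx(0.5, abs=0.01)

    def test_zero_efficiency_means_no_fret_photons(self):
        cfg = StreamConfig(
            populations=[Population(E=0.0)],
            background={"dd": 0.0, "ad": 0.0, "aa": 0.0, "da": 0.0},
        )
        d, _ = simulate_photon_stream(cfg, duration=10.0, seed=1)
        from interdom.bursts import PhotonStream

        labels = PhotonStream.from_dict(d).stream_labels()
        assert (labels == "ad").sum() == 0

    def test_weight_validation(self):
        cfg = StreamConfig(populations=[Population(E=0.5, weight=0.7)])
        with pytest.raises(ValueError, match="weights"):
            simulate_photon_stream(cfg, duration=10.0, seed=0)

    def test_determinism(self):
        cfg = StreamConfig(populations=[Population(E=0.3)])
        d1, t1 = simulate_photon_stream(cfg, duration=10.0, seed=9)
        d2, t2 = simulate_photon_stream(cfg, duration=10.0, seed=9)
        assert np.array_equal(d1["timestamps"], d2["timestamps"])
        assert t1.equals(t2)


class TestHdxSimulation:
    def test_unit_protection_factor_is_null(self):
        profiles = make_hdx_profiles(n_peptides=10, seed=0)
        table = simulate_hdx(profiles, noise_sd=0.0, seed=1)
        apo = table[table["state"] == "apo"].sort_values(["start", "exposure", "replicate"])
        bound = table[table["state"] == "bound"].sort_values(["start", "exposure", "replicate"])
        assert np.allclose(apo["uptake"].to_numpy(), bound["uptake"].to_numpy())

    def test_saturation_limit(self):
        p = HdxPeptideProfile(start=1, end=6, sequence="AAAAA", rates=np.full(5, 100.0))
        assert p.uptake(120.0, bound=False) == pytest.approx(0.82 * 5, rel=1e-6)

    def test_protection_reduces_uptake(self):
        p = HdxPeptideProfile(start=1, end=6, sequence="AAAAA", rates=np.full(5, 0.5), pf_bound=10.0)
        for t in HDX_TIMEPOINTS:
            assert p.uptake(t, bound=True) < p.uptake(t, bound=False)

    def test_invalid_pf_rejected(self):
        p = HdxPeptideProfile(start=1, end=6, sequence="AAAAA", rates=np.full(5, 0.5), pf_bound=-1.0)
        with pytest.raises(ValueError, match="protection factor"):
            p.uptake(1.0, bound=True)


class TestIsothermSimulation:
    def test_dilution_design_matches_study(self):
        iso = simulate_isotherm()
        assert len(iso) == 16
        assert iso["concentration"].max() == pytest.approx(1e-4)
        assert iso["concentration"].min() == pytest.approx(1e-4 / 2**15)  # ~3 nM

    def test_noise_validation(self):
        with pytest.raises(ValueError, match="noise"):
            simulate_isotherm(noise_sd=-0.1)

    def test_misspecified_hill_coefficient_leaves_residual_structure(self):
        from interdom.binding import fit_hill, hill_equation
        from scipy.optimize import curve_fit

        iso = simulate_isotherm(kd=8e-7, n=2.0, noise_sd=0.0)
        # best possible n = 1 description of n = 2 data has systematic residuals
        popt, _ = curve_fit(
            lambda x, s_u, s_b, kd: hill_equation(x, s_u, s_b, kd, 1.0),
            iso["concentration"], iso["signal"], p0=[0.0, 1.0, 8e-7], maxfev=20000,
        )
        resid = iso["signal"] - hill_equation(iso["concentration"], *popt, 1.0)
        assert np.abs(resid).max() > 0.01
        # whereas the free fit recovers the generating coefficient
        assert fit_hill(iso).n == pytest.approx(2.0, rel=1e-2)
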