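"""Macrostate models: sampling, enumeration, family clustering."""

import numpy as np
import pytest

import ensemblefit as ef
from ensemblefit import fixtures as fx
from ensemblefit.errors import InputError, ValidationError
from ensemblefit.model import (
    BondModel,
    DynamicModel,
    Macrostate,
    circular_mean,
    cluster_families,
    enumerate_macrostates,
    sample_ensemble,
)


def toy_model(pis=(0.62, 0.38), mus=(-103.0, 103.0), sigmas=(6.0, 10.0)):
    return DynamicModel(
        bonds={
            "tor": BondModel(
                "tor", [Macrostate(p, m, s) for p, m, s in zip(pis, mus, sigmas)]
            )
        }
    )


class TestValidation:
    def test_unnormalized_probabilities_rejected(self):
        m = toy_model(pis=(0.7, 0.38))
        with pytest.raises(ValidationError):
            m.validate()

    def test_sigma_negative_rejected(self):
        m = toy_model(sigmas=(-1.0, 10.0))
        with pytest.raises(ValidationError):
            m.validate()

    def test_coupled_members_must_share_mode_count(self):
        m = DynamicModel(
            bonds={
                "a": BondModel("a", [Macrostate(0.5, 0, 5), Macrostate(0.5, 100, 5)],
                               coupling_group="g"),
                "b": BondModel("b", [Macrostate(1.0, 50, 5)], coupling_group="g"),
            }
        )
        with pytest.raises(ValidationError):
            m.validate()

    def test_model_must_cover_template_bonds(self, strepto_template):
        m = toy_model()
        with pytest.raises(ValidationError):
            m.validate(strepto_template)


class TestSampling:
    def test_default_ensemble_size_is_300(self):
        t = fx.butane_template()
        m = DynamicModel(bonds={"tor": BondModel("tor", [Macrostate(1.0, 60, 10)])})
        ens = sample_ensemble(m, t, seed=0)
        assert ens.n == 300

    def test_sigma_zero_reproduces_means_exactly(self):
        t = fx.butane_template()
        m = DynamicModel(bonds={"tor": BondModel("tor", [Macrostate(1.0, 63.0, 0.0)])})
        ens = sample_ensemble(m, t, n=50, seed=1)
        assert np.allclose(ens.torsions["tor"], 63.0)

    def test_bimodal_mode_frequencies_match_binomial(self):
        t = fx.butane_template()
        pis = (0.62, 0.38)
        m = toy_model(pis=pis)
        n = 10000
        ens = sample_ensemble(m, t, n=n, seed=2)
        freq = np.mean(ens.mode_indices["tor"] == 0)
        se = np.sqrt(pis[0] * pis[1] / n)
        assert abs(freq - pis[0]) < 3 * se

    def test_wrapped_normal_near_branch_cut(self):
        t = fx.butane_template()
        m = DynamicModel(bonds={"tor": BondModel("tor", [Macrostate(1.0, 179.0, 10.0)])})
        ens = sample_ensemble(m, t, n=100000, seed=3)
        cm = circular_mean(ens.torsions["tor"])
        assert abs(ef.circular_distance(cm, 179.0)) < 1.0

    def test_deterministic_given_seed(self, strepto_template, truth_model):
        a = sample_ensemble(truth_model, strepto_template, n=40, seed=9)
        b = sample_ensemble(truth_model, strepto_template, n=40, seed=9)
        for k in a.torsions:
            assert np.array_equal(a.torsions[k], b.torsions[k])
        assert np.array_equal(a.coords, b.coords)

    def test_coupled_bonds_share_mode_index(self, strepto_template, truth_model):
        ens = sample_ensemble(truth_model, strepto_template, n=500, seed=4)
        k = ens.mode_indices["R2G3"]
        # all coupled members drew angles near the mu of their joint index
        phi = ens.torsions["phi23"]
        mus = truth_model.bonds["phi23"].mus[k]
        assert np.max(np.abs(ef.wrap_angle(phi - mus))) < 60

    def test_unnormalized_model_not_silently_renormalized(self, strepto_template):
        bad = fx.ground_truth_model()
        bad.bonds["phi12"].macrostates[0].pi = 0.9
        with pytest.raises(ValidationError):
            sample_ensemble(bad, strepto_template, n=10, seed=0)


class TestEnumeration:
    def test_final_model_has_12_macrostates(self, strepto_template, truth_model):
        ms = enumerate_macrostates(truth_model, strepto_template)
        assert len(ms) == 12
        assert sum(m.occupancy for m in ms) == pytest.approx(1.0, abs=1e-9)

    def test_all_unimodal_gives_single_state(self):
        t = fx.butane_template()
        m = DynamicModel(bonds={"tor": BondModel("tor", [Macrostate(1.0, 60, 5)])})
        ms = enumerate_macrostates(m)
        assert len(ms) == 1
        assert ms[0].occupancy == 1.0

    def test_two_independent_bimodal_bonds_product_rule(self):
        m = DynamicModel(
            bonds={
                "a": BondModel("a", [Macrostate(0.5, 0, 5), Macrostate(0.5, 120, 5)]),
                "b": BondModel("b", [Macrostate(0.5, 0, 5), Macrostate(0.5, 120, 5)]),
            }
        )
        ms = enumerate_macrostates(m)
        assert len(ms) == 4
        assert all(m_.occupancy == pytest.approx(0.25) for m_ in ms)


class TestFamilies:
    def test_paper_families_62_38(self, strepto_template, truth_model):
        ms = enumerate_macrostates(truth_model, strepto_template)
        fams = cluster_families(ms, fx.FAMILY_BONDS, model=truth_model)
        assert len(fams) == 2
        assert fams[0].population == pytest.approx(0.62, abs=1e-9)
        assert fams[1].population == pytest.approx(0.38, abs=1e-9)

    def test_single_family_degenerate(self):
        m = DynamicModel(bonds={"tor": BondModel("tor", [Macrostate(1.0, 60, 5)])})
        fams = cluster_families(enumerate_macrostates(m), ["tor"], model=m)
        assert len(fams) == 1
        assert fams[0].population == pytest.approx(1.0)

    def test_populations_equal_exhaustive_sum(self, strepto_template, truth_model):
        ms = enumerate_macrostates(truth_model, strepto_template)
        fams = cluster_families(ms, fx.FAMILY_BONDS, model=truth_model)
        # oracle: brute-force sum over the full product of unit indices
        units = truth_model.units()
        import itertools

        sizes = [len(p) for _, p, _ in units]
        r2g3_pos = [i for i, (uid, _, _) in enumerate(units) if uid == "R2G3"][0]
        pops = {}
        for combo in itertools.product(*(range(s) for s in sizes)):
            occ = 1.0
            for (uid, pis, _), k in zip(units, combo):
                occ *= pis[k]
            pops[combo[r2g3_pos]] = pops.get(combo[r2g3_pos], 0.0) + occ
        for f in fams:
            assert f.population == pytest.approx(pops[f.family_id[0]], abs=1e-12)

    def test_empty_defining_list_rejected(self, strepto_template, truth_model):
        ms = enumerate_macrostates(truth_model, strepto_template)
        with pytest.raises(InputError):
            cluster_families(ms, [], model=truth_model)


class TestModelIO:
    def test_json_round_trip_lossless(self, truth_model, tmp_path):
        p = tmp_path / "model.json"
        truth_model.save(p)
        back = DynamicModel.load(p)
        assert back.to_json() == truth_model.to_json()
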