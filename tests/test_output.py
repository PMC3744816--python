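"""Output ensembles, trimming, histograms and geometry measurements."""

import numpy as np
import pytest

import ensemblefit as ef
from ensemblefit import fixtures as fx
from ensemblefit.errors import InputError
from ensemblefit.geometry import clash_mask
from ensemblefit.model import BondModel, DynamicModel, Macrostate
from ensemblefit.output import (
    emit_macrostates,
    emit_microstates,
    measure_geometry,
    torsion_histogram,
    write_output_bundle,
)


class TestEmitMicrostates:
    def test_default_count_250_all_clash_free(self, strepto_template, truth_model):
        coords, sample, log = emit_microstates(
            truth_model, strepto_template, n=250, seed=1
        )
        assert coords.shape[0] == 250
        assert not clash_mask(strepto_template, coords).any()
        assert log["kept"] == 250

    def test_min_dist_zero_no_trimming(self, strepto_template, truth_model):
        coords, sample, log = emit_microstates(
            truth_model, strepto_template, n=100, min_dist=0, seed=2
        )
        assert log["rejected"] == 0
        assert coords.shape[0] == 100

    def test_emitted_conformers_pass_revalidation(self, strepto_template, truth_model):
        coords, sample, log = emit_microstates(
            truth_model, strepto_template, n=60, seed=3
        )
        for k in range(coords.shape[0]):
            c = ef.CartesianConformer(strepto_template, coords[k], {}, {})
            assert ef.detect_clashes(c) == []

    def test_trimming_unbiased_at_low_clash_rate(self):
        # toy with a rare steric conflict: torsion near 0 brings ends close
        t = fx.butane_template()
        model = DynamicModel(
            bonds={"tor": BondModel("tor", [Macrostate(1.0, 180.0, 25.0)])}
        )
        from scipy.stats import ks_2samp

        raw = ef.sample_ensemble(model, t, n=4000, seed=4).torsions["tor"]
        coords, sample, log = emit_microstates(model, t, n=4000, seed=4)
        rate = log["rejected"] / log["drawn"]
        assert rate < 0.05
        stat, p = ks_2samp(raw, sample["torsions"]["tor"])
        assert p > 0.01


class TestEmitMacrostates:
    def test_twelve_macrostates(self, strepto_template, truth_model):
        coords, occ, entries = emit_macrostates(truth_model, strepto_template)
        assert coords.shape[0] == 12
        assert occ.sum() == pytest.approx(1.0, abs=1e-9)

    def test_unimodal_model_single_state(self):
        t = fx.butane_template()
        m = DynamicModel(bonds={"tor": BondModel("tor", [Macrostate(1.0, 60, 5)])})
        coords, occ, entries = emit_macrostates(m, t)
        assert coords.shape[0] == 1 and occ[0] == 1.0

    def test_occupancies_match_enumeration(self, strepto_template, truth_model):
        from ensemblefit.model import enumerate_macrostates

        _, occ, entries = emit_macrostates(truth_model, strepto_template)
        want = [e.occupancy for e in enumerate_macrostates(truth_model, strepto_template)]
        assert np.allclose(occ, want)


class TestTorsionHistogram:
    def test_counts_conserved(self, rng):
        a = rng.uniform(-180, 180, size=100)
        counts = torsion_histogram(a)
        assert counts.sum() == 100
        assert len(counts) == 24

    def test_edge_angle_goes_to_higher_bin(self):
        counts = torsion_histogram([7.5])
        assert counts[1] == 1  # bin centered at 15 deg
        counts = torsion_histogram([-7.5])
        assert counts[0] == 1  # half-open: -7.5 belongs to the 0-deg bin

    def test_matches_direct_binning_oracle(self, rng):
        a = rng.normal(170, 30, size=5000)
        counts = torsion_histogram(a)
        oracle = np.zeros(24, dtype=int)
        for x in a:
            x = x % 360.0
            k = int(np.floor(x / 15.0 + 0.5)) % 24
            oracle[k] += 1
        assert np.array_equal(counts, oracle)

    def test_bad_width_rejected(self):
        with pytest.raises(InputError):
            torsion_histogram([0.0], bin_width=13.0)


class TestMeasureGeometry:
    def test_self_distance_zero(self, strepto_template, table_mean_torsions):
        c = ef.build_conformer(strepto_template, table_mean_torsions)
        df = measure_geometry(
            c.coordinates, strepto_template, [("distance", "S1_C1", "S1_C1")]
        )
        assert df.iloc[0]["mean"] == 0.0

    def test_collinear_angle_180(self):
        t = fx.butane_template()
        coords = np.zeros((1, 6, 3))
        coords[0, 1] = [1.5, 0, 0]
        coords[0, 2] = [3.0, 0, 0]
        coords[0, 3] = [4.5, 1, 0]
        coords[0, 4] = [0, 1, 0]
        coords[0, 5] = [5, 2, 0]
        df = measure_geometry(coords, t, [("angle", "C1", "C2", "C3")])
        assert df.iloc[0]["mean"] == pytest.approx(180.0)

    def test_vector_arithmetic_oracle(self, strepto_template, truth_model):
        ens = ef.sample_ensemble(truth_model, strepto_template, n=25, seed=6)
        df = measure_geometry(
            ens.coords, strepto_template,
            [("distance", "S1_O2", "R2_O4"), ("angle", "S1_C1", "S1_C2", "S1_C3")],
        )
        i, j = strepto_template.index("S1_O2"), strepto_template.index("R2_O4")
        want = np.linalg.norm(ens.coords[:, i] - ens.coords[:, j], axis=1)
        assert df.iloc[0]["mean"] == pytest.approx(want.mean())
        assert df.iloc[0]["min"] == pytest.approx(want.min())


class TestOutputBundle:
    def test_full_bundle_files_and_pdb_round_trip(
        self, strepto_template, truth_model, tmp_path
    ):
        bundle = write_output_bundle(
            truth_model, strepto_template, tmp_path,
            n_microstates=40, seed=7, family_bonds=fx.FAMILY_BONDS,
            measurement_queries=[("distance", "S1_O2", "R2_O4")],
        )
        assert (tmp_path / "microstates.pdb").exists()
        assert (tmp_path / "macrostates.pdb").exists()
        assert (tmp_path / "families.json").exists()
        assert (tmp_path / "torsion_histograms.tsv").exists()
        back = ef.read_pdb_coords(tmp_path / "microstates.pdb", strepto_template)
        assert np.abs(back - bundle.microstate_coords).max() < 1e-3
        pops = sorted(f["population"] for f in bundle.families)
        assert pops == pytest.approx([0.38, 0.62], abs=1e-9)
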