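"""Generators: determinism, statistical structure, agreement with closed forms."""

import numpy as np
import pandas as pd
import pytest

from bclscreen.bioeval import nca
from bclscreen.exceptions import InputError
from bclscreen.qsar import FeatureConfig, cross_validate, featurize_dataset
from bclscreen.sprkin import KineticParams, simulate_sensorgram
from bclscreen.synthdata import (
    BioSynthConfig,
    PKSynthConfig,
    SensorgramSynthConfig,
    bateman_concentration,
    bateman_tmax,
    dummy_smiles,
    generate_bioactivity_dataset,
    generate_docking_energies,
    generate_dose_response,
    generate_pk_profile,
    generate_screening_library,
    generate_sensorgram,
)


class TestBioactivity:
    def test_same_seed_gives_identical_tables(self):
        cfg = BioSynthConfig(n_compounds=200, seed=42)
        a = generate_bioactivity_dataset(cfg)
        b = generate_bioactivity_dataset(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_noiseless_separable_limit_reaches_perfect_cv(self):
        cfg = BioSynthConfig(
            n_compounds=400, noise_sd=0.0, signal_strength=5.0,
            n_informative=5, seed=1,
        )
        df = generate_bioactivity_dataset(cfg)
        X, kept, _ = featurize_dataset(df, FeatureConfig(mode="precomputed"))
        report = cross_validate(X, df["active"].to_numpy(), seed=1)
        assert report.mean_accuracy == 1.0
        assert report.mean_mcc == 1.0

    def test_active_share_tracks_requested_fraction(self):
        cfg = BioSynthConfig(n_compounds=2000, active_fraction=0.3, seed=5)
        df = generate_bioactivity_dataset(cfg)
        # within 3 binomial SD of 0.3: 3*sqrt(0.3*0.7/2000) ~ 0.0307
        assert abs(df["active"].mean() - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 2000)

    def test_record_schema_is_chembl_like(self):
        df = generate_bioactivity_dataset(BioSynthConfig(n_compounds=50))
        for col in ("compound_id", "smiles", "target_id", "assay_class",
                    "endpoint", "relation", "value", "units"):
            assert col in df.columns
        assert set(df["assay_class"]) <= {"FA", "BA"}
        assert (df["value"] > 0).all()
        # value (µM) round-trips with the stated pAffinity
        np.testing.assert_allclose(
            -np.log10(df["value"] * 1e-6), df["p_affinity"], rtol=1e-12
        )

    def test_nonpositive_size_rejected(self):
        with pytest.raises(InputError):
            BioSynthConfig(n_compounds=0)

    def test_dummy_smiles_are_deterministic_and_parsable(self):
        from rdkit import Chem

        ids = [f"SYN{i:05d}" for i in range(25)]
        for cid in ids:
            s = dummy_smiles(cid)
            assert s == dummy_smiles(cid)
            assert Chem.MolFromSmiles(s) is not None


class TestLibrary:
    def test_zero_rates_pass_all_filters(self):
        lib = generate_screening_library(40, 0.0, 0.0, seed=2)
        assert lib["available"].all() and lib["soluble_in_dmso"].all()

    def test_same_seed_identical(self):
        a = generate_screening_library(60, 0.1, 0.2, seed=3)
        b = generate_screening_library(60, 0.1, 0.2, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_forced_flags_reproduce_published_attrition(self):
        """60 candidates, 3 unavailable + 8 precipitating -> 49 testable."""
        ids = [f"LIB{i:06d}" for i in range(60)]
        lib = generate_screening_library(
            60, 0.0, 0.0, seed=0,
            force_unavailable=tuple(ids[:3]),
            force_insoluble=tuple(ids[3:11]),
        )
        passing = lib["available"] & lib["soluble_in_dmso"]
        assert passing.sum() == 49

    def test_rates_outside_unit_interval_rejected(self):
        with pytest.raises(InputError):
            generate_screening_library(10, -0.1, 0.0)
        with pytest.raises(InputError):
            generate_screening_library(10, 0.0, 1.5)


class TestSensorgram:
    def test_noiseless_generator_equals_forward_model(self, faststep, two_site_params):
        cfg = SensorgramSynthConfig(params=two_site_params, noise_sd=0.0)
        gen = generate_sensorgram(cfg, faststep)
        sim = simulate_sensorgram(two_site_params, faststep, cfg.sampling_interval)
        np.testing.assert_array_equal(gen.response, sim.response)

    def test_plateau_at_kd_is_half_capacity(self):
        from bclscreen.sprkin import build_schedule

        ka, kd, rmax = 1e5, 0.01, 50.0
        sched = build_schedule(
            "custom", segments=((0.0, 8000.0, kd / ka),), dissociation_s=0.0
        )
        cfg = SensorgramSynthConfig(
            params=KineticParams((ka,), (kd,), (rmax,)), noise_sd=0.0
        )
        sg = generate_sensorgram(cfg, sched)
        assert sg.response[-1] == pytest.approx(rmax / 2, rel=1e-6)

    def test_noise_is_seeded_and_additive(self, faststep, two_site_params):
        cfg = SensorgramSynthConfig(params=two_site_params, noise_sd=1.0, seed=7)
        a = generate_sensorgram(cfg, faststep)
        b = generate_sensorgram(cfg, faststep)
        np.testing.assert_array_equal(a.response, b.response)
        clean = generate_sensorgram(
            SensorgramSynthConfig(params=two_site_params, noise_sd=0.0), faststep
        )
        resid = a.response - clean.response
        assert 0.8 < resid.std() < 1.2


class TestPK:
    def test_bateman_peak_matches_closed_form(self):
        cfg = PKSynthConfig(sample_times=tuple(np.linspace(0.01, 48, 400)), cv=0.0)
        tmax = bateman_tmax(cfg)
        assert tmax == pytest.approx(
            np.log(cfg.ka_abs / cfg.ke) / (cfg.ka_abs - cfg.ke)
        )
        c = bateman_concentration(np.array([tmax - 0.01, tmax, tmax + 0.01]), cfg)
        assert c[1] >= c[0] and c[1] >= c[2]

    def test_concentration_zero_at_time_zero(self):
        cfg = PKSynthConfig()
        assert bateman_concentration(np.array([0.0]), cfg)[0] == 0.0

    def test_nca_half_life_recovers_ke_on_dense_samples(self):
        cfg = PKSynthConfig(
            ka_abs=1.7, ke=0.063,
            sample_times=tuple(np.linspace(0.0, 60.0, 121)), cv=0.0,
        )
        res = nca(generate_pk_profile(cfg), mw=cfg.mw)
        assert res.t_half == pytest.approx(np.log(2) / cfg.ke, rel=0.02)

    def test_degenerate_bateman_rejected(self):
        with pytest.raises(InputError):
            PKSynthConfig(ka_abs=0.5, ke=0.5)


class TestDoseResponse:
    def test_midpoint_and_asymptote(self):
        dr = generate_dose_response(
            ic50=20.0, hill=1.0, top=100.0, bottom=0.0,
            concs=(1e-6, 20.0), noise_sd=0.0,
        )
        assert dr.viability[1] == pytest.approx(50.0)
        assert dr.viability[0] == pytest.approx(100.0, abs=1e-3)

    def test_nonpositive_ic50_rejected(self):
        with pytest.raises(InputError):
            generate_dose_response(ic50=0.0)


class TestDockingEnergies:
    def test_exact_target_correlation(self):
        pkd = np.array([6.72, 6.49, 6.32, 6.28, 6.11, 5.47, 5.40, 5.34])
        e = generate_docking_energies(pkd, r_target=0.85, seed=0)
        r = np.corrcoef(e, pkd)[0, 1]
        assert r == pytest.approx(-0.85, abs=1e-12)
        assert np.all(e < 0)  # kcal/mol, binding-favourable convention
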