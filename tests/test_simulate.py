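"""The synthetic-data generator: design bookkeeping, determinism, exact
noiseless identities, and the statistical properties it plants."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

import yieldparts as yp
from yieldparts.io import check_ultrametric, records_to_frame
from yieldparts.pgls import phylo_covariance
from yieldparts.simulate import (ROSTER, SPECIES, SimConfig, _logit,
                                 _logit_location, make_tree,
                                 simulate_growth_series, simulate_trait_table)


class TestTree:
    def test_seventeen_ultrametric_tips(self, tree):
        assert len(list(tree.leaf_node_iter())) == 17
        depth = check_ultrametric(tree, tol=1e-9)
        assert depth == pytest.approx(1.0, abs=1e-9)

    def test_crop_closest_to_own_progenitor(self, tree):
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        pairs = {}
        for sp, status, fam, group, _, _ in ROSTER:
            pairs.setdefault(group, {}).setdefault(status, []).append(sp)
        for group, members in pairs.items():
            crop = members["crop"][0]
            own = min(pdm.patristic_distance(taxa[crop], taxa[p])
                      for p in members["progenitor"])
            others = [pdm.patristic_distance(taxa[crop], taxa[o])
                      for o in SPECIES if o != crop
                      and o not in members["progenitor"]]
            assert own < min(others)

    def test_round_trip_through_newick(self, tmp_path, tree):
        path = tmp_path / "t.nwk"
        yp.write_tree(tree, path)
        back = yp.read_tree(path, expected_taxa=list(SPECIES))
        C1, _ = phylo_covariance(tree, list(SPECIES))
        C2, _ = phylo_covariance(back, list(SPECIES))
        np.testing.assert_allclose(C1, C2, atol=1e-9)


class TestConfig:
    def test_invalid_chaff_effect_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(chaff_reduction_pct=100.0)
        with pytest.raises(ValueError):
            SimConfig(base_chaff=1.2)
        with pytest.raises(ValueError):
            SimConfig(mult_biomass=-1.0)

    def test_implied_yield_ratio(self):
        cfg = SimConfig()
        expected = 1.4 * (1 - 0.39 * 0.62) / (1 - 0.39)
        assert cfg.implied_yield_ratio() == pytest.approx(expected)

    def test_logit_location_compensates_smearing(self, rng):
        mu = _logit_location(0.39, 0.4)
        draws = 1 / (1 + np.exp(-(mu + rng.normal(0, 0.4, 200_000))))
        assert draws.mean() == pytest.approx(0.39, abs=0.002)
        assert _logit_location(0.39, 0.0) == pytest.approx(float(_logit(0.39)))


class TestTraitTable:
    def test_replicate_and_block_structure(self, noisy_dataset):
        records, _ = noisy_dataset
        df = records_to_frame(records)
        counts = df.groupby("species_id").size()
        for sp, status, fam, group, in_exp2, _ in ROSTER:
            assert counts[sp] == (30 if in_exp2 else 20)
        assert df[df["experiment_id"] == 1]["block_id"].nunique() == 20
        assert df[df["experiment_id"] == 2]["block_id"].nunique() == 10
        # Avena/Secale absent from experiment 2
        exp2 = df[df["experiment_id"] == 2]["species_id"].unique()
        assert not any(s.startswith(("Avena", "Secale")) for s in exp2)

    def test_same_seed_reproduces_byte_identical_csv(self, tmp_path):
        cfg = SimConfig(seed=123)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        for p in (p1, p2):
            records, _ = simulate_trait_table(cfg)
            yp.write_trait_table(records, p)
        assert p1.read_bytes() == p2.read_bytes()

    def test_pulses_have_no_packaging_counts(self, noisy_dataset):
        records, _ = noisy_dataset
        for r in records:
            if r.family == "legume":
                assert r.n_seeds_per_infructescence is None
                assert r.n_infructescences is None
            else:
                assert r.n_seeds_per_infructescence is not None

    def test_records_pass_table_validation(self, noisy_dataset):
        records, _ = noisy_dataset
        assert all(r.validation_errors() == [] for r in records)

    def test_truth_reconstructs_noiseless_traits(self, noiseless_records):
        records, truth = noiseless_records
        df = records_to_frame(records)
        for sp, sub in df.groupby("species_id"):
            row = truth.species.loc[sp]
            assert np.allclose(sub["biomass_total_g"], row["Md_g"], rtol=1e-12)
            assert np.allclose(sub["seed_mass_sown_mg"], row["Ms_mg"], rtol=1e-12)
            grain = row["Md_g"] * row["Ar"] * (1 - row["c"])
            assert np.allclose(sub["mass_grain_g"], grain, rtol=1e-10)

    def test_null_config_removes_status_differences(self):
        records, truth = simulate_trait_table(SimConfig(seed=5).null_effects().noiseless())
        sp = truth.species
        crop_ms = sp.loc[sp["status"] == "crop", "Ms_mg"]
        prog_ms = sp.loc[sp["status"] == "progenitor", "Ms_mg"]
        assert set(crop_ms.round(9)) <= set(prog_ms.round(9))

    def test_attenuated_secondary_domesticates(self):
        _, truth = simulate_trait_table(
            dataclasses.replace(SimConfig(seed=5), attenuate_secondary=True).noiseless())
        sp = truth.species
        assert sp.loc["Avena_sativa", "Ms_mg"] == pytest.approx(
            sp.loc["Avena_sterilis", "Ms_mg"])
        assert sp.loc["Hordeum_vulgare", "Ms_mg"] == pytest.approx(
            1.9 * sp.loc["Hordeum_spontaneum", "Ms_mg"])


class TestGrowthSeries:
    def test_harvest_days_within_window(self, default_config):
        series, _ = simulate_growth_series(default_config)
        for s in series.values():
            assert s.days.min() >= 8.0 and s.days.max() <= 28.0
            assert len(np.unique(s.days)) == 6
            assert len(s.observations) == 12

    def test_noiseless_series_refits_planted_parameters(self, default_config):
        series, truth = simulate_growth_series(default_config.noiseless())
        for sp in ("Hordeum_vulgare", "Pisum_elatius"):
            fit = yp.fit_fpl(series[sp])
            row = truth.growth_params.loc[sp]
            assert fit.A_ == pytest.approx(row["A"], abs=1e-6)
            assert fit.B_ == pytest.approx(row["B"], abs=1e-6)
            assert fit.t_mid_ == pytest.approx(row["t_mid"], abs=1e-6)
            assert fit.s_ == pytest.approx(row["s"], abs=1e-6)

    def test_no_planted_growth_rate_difference(self, default_config):
        _, truth = simulate_growth_series(default_config.noiseless())
        gp = truth.growth_params
        lam = gp["lambda_inflection"]
        crops = lam[gp["status"] == "crop"]
        progs = lam[gp["status"] == "progenitor"]
        assert crops.mean() == pytest.approx(progs.mean(), rel=0.02)
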