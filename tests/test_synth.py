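"""Synthetic generators: determinism, planted moments, config validation."""

import numpy as np
import pandas as pd
import pytest

from nichemapper.survival import hazard_ratio, median_split
from nichemapper.synth import (
    LRPair,
    PlantedDropout,
    PlantedLigand,
    PlantedReceptor,
    SurvivalSpec,
    SynthConfig,
    default_config,
    simulate_all,
    simulate_bulk,
    simulate_lr_table,
    simulate_niche,
    simulate_screen,
    simulate_survival,
)


def nb_loop_sampler(rng, mean, dispersion, n):
    """Independent straight-loop NB sampler, Var = mu + phi mu^2."""
    r = 1.0 / dispersion
    out = np.empty(n)
    for i in range(n):
        lam = rng.gamma(shape=r, scale=mean / r)
        out[i] = rng.poisson(lam)
    return out


class TestDeterminism:
    def test_identical_seed_identical_outputs(self):
        a = simulate_all(default_config(seed=7))
        b = simulate_all(default_config(seed=7))
        for disease in ("bcCML", "AML"):
            pd.testing.assert_frame_equal(a.bulk[disease][0], b.bulk[disease][0])
        pd.testing.assert_frame_equal(a.screen, b.screen)
        pd.testing.assert_frame_equal(a.niche_counts, b.niche_counts)
        pd.testing.assert_frame_equal(a.niche_meta, b.niche_meta)
        pd.testing.assert_frame_equal(a.lr_table, b.lr_table)
        pd.testing.assert_frame_equal(a.survival, b.survival)
        assert a.truth.to_json() == b.truth.to_json()

    def test_different_seeds_differ(self):
        a = simulate_all(default_config(seed=1))
        b = simulate_all(default_config(seed=2))
        assert not a.screen["log2fc"].equals(b.screen["log2fc"])


class TestBulk:
    def test_planted_mean_matches_independent_nb_sampler(self):
        """Effect +2 on baseline 100: disease mean ~400, checked against an
        independently coded gamma-Poisson loop sampler."""
        cfg = SynthConfig(
            seed=3,
            n_genes=50,
            n_samples_per_group=50,
            baseline_mean_range=(100.0, 100.0),
            planted_min_mean=0.0,
            planted_receptors=[PlantedReceptor("TGT", "bcCML", 2.0)],
        )
        counts, groups = simulate_bulk(cfg)["bcCML"]
        disease_vals = counts.loc["TGT", groups == "disease"].to_numpy()
        oracle = nb_loop_sampler(
            np.random.default_rng(99), 400.0, cfg.nb_dispersion, 4000
        )
        se = oracle.std(ddof=1) / np.sqrt(len(disease_vals))
        assert abs(disease_vals.mean() - oracle.mean()) < 3 * se

    def test_shared_baseline_across_diseases(self):
        cfg = default_config(seed=5)
        bulk = simulate_bulk(cfg)
        m_bc = bulk["bcCML"][0].iloc[:, :8].mean(axis=1)
        m_aml = bulk["AML"][0].iloc[:, :8].mean(axis=1)
        # same underlying baselines: control means correlate strongly
        assert np.corrcoef(np.log1p(m_bc), np.log1p(m_aml))[0, 1] > 0.98

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            simulate_bulk(SynthConfig(n_genes=0))

    def test_universe_too_small_for_planted_genes_rejected(self):
        bad = SynthConfig(
            n_genes=1,
            planted_receptors=[
                PlantedReceptor("X", "AML", 1.0),
                PlantedReceptor("Y", "AML", 1.0),
            ],
        )
        with pytest.raises(ValueError, match="cannot hold"):
            bad.validate()


class TestScreen:
    def test_zero_noise_guides_hit_effect_exactly(self):
        cfg = SynthConfig(
            n_genes=10,
            guide_sd=0.0,
            dropout_genes=[PlantedDropout("DROP", -1.5)],
        )
        screen = simulate_screen(cfg)
        vals = screen.loc[screen["gene"] == "DROP", "log2fc"]
        assert len(vals) == cfg.n_guides_per_gene
        assert (vals == -1.5).all()
        assert vals.median() == -1.5

    def test_dropout_effect_above_minus_one_rejected(self):
        cfg = SynthConfig(n_genes=10, dropout_genes=[PlantedDropout("D", -0.5)])
        with pytest.raises(ValueError, match="<= -1"):
            simulate_screen(cfg)


class TestNiche:
    def test_population_fractions_match_multinomial(self):
        cfg = SynthConfig(
            seed=11,
            n_genes=20,
            n_cells_per_stage=10_000,
            populations={"A": (0.1, 0.1, 0.1, 0.1), "B": (0.9, 0.9, 0.9, 0.9)},
        )
        _, meta = simulate_niche(cfg)
        for stage in cfg.stages:
            frac = (meta.loc[meta["stage"] == stage, "population"] == "A").mean()
            se = np.sqrt(0.1 * 0.9 / 10_000)
            assert abs(frac - 0.1) < 3 * se

    def test_lost_ligand_vanishes_at_end(self, default_cfg):
        counts, meta = simulate_niche(default_cfg)
        msc_end = (meta["population"] == "MSC") & (meta["stage"] == "end")
        msc_naive = (meta["population"] == "MSC") & (meta["stage"] == "naive")
        assert counts.loc[msc_naive.to_numpy(), "LIG_LOST1"].mean() > 1.0
        assert counts.loc[msc_end.to_numpy(), "LIG_LOST1"].mean() < 0.1

    def test_transient_ligand_peaks_interior(self, default_cfg):
        counts, meta = simulate_niche(default_cfg)
        means = []
        for stage in default_cfg.stages:
            sel = (meta["population"] == "osteo") & (meta["stage"] == stage)
            means.append(counts.loc[sel.to_numpy(), "LIG_TRANS1"].mean())
        assert np.argmax(means) in (1, 2)
        assert means[0] < 0.2 and means[3] < 0.2

    def test_unknown_temporal_class_rejected(self):
        cfg = SynthConfig(
            n_genes=10,
            populations={"A": (1.0, 1.0, 1.0, 1.0)},
            planted_ligands=[PlantedLigand("L", ("A",), "oscillating")],
            lr_pairs=[LRPair("L", "R", True)],
            planted_receptors=[PlantedReceptor("R", "both", 1.0)],
        )
        with pytest.raises(ValueError, match="temporal class"):
            simulate_niche(cfg)

    def test_proportions_must_sum_to_one(self):
        cfg = SynthConfig(
            n_genes=10, populations={"A": (0.5, 0.5, 0.5, 0.5)}
        )
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_niche(cfg)


class TestSurvivalGen:
    def test_positive_beta_gives_hr_above_one(self):
        """beta = 1, n = 400, effectively no censoring: the high-expression
        stratum shows excess hazard in nearly every replicate."""
        hits = 0
        n_reps = 200
        for seed in range(1, n_reps + 1):
            cfg = SynthConfig(
                seed=seed,
                n_genes=5,
                survival=SurvivalSpec(
                    genes=("X",),
                    betas={"X": 1.0},
                    n_patients=400,
                    censor_time=1e9,
                ),
            )
            surv = simulate_survival(cfg)
            _, low, high = median_split(surv["expression"].to_numpy())
            t = surv["time"].to_numpy()
            e = surv["event"].to_numpy()
            hr, _ = hazard_ratio(t[high], e[high], t[low], e[low])
            hits += hr > 1
        assert hits / n_reps >= 0.95

    def test_infinite_beta_rejected(self):
        cfg = SynthConfig(
            n_genes=5,
            survival=SurvivalSpec(genes=("X",), betas={"X": np.inf}),
        )
        with pytest.raises(ValueError, match="finite"):
            simulate_survival(cfg)


class TestLRTable:
    def test_ligandless_receptor_has_no_rows(self, default_cfg):
        lr = simulate_lr_table(default_cfg)
        assert (lr["receptor"] == "R_NOLIG1").sum() == 0
        assert (lr["receptor"] == "R_NOLIG2").sum() == 0

    def test_planted_pairs_present_once(self, default_cfg):
        lr = simulate_lr_table(default_cfg)
        for pair in default_cfg.lr_pairs:
            n = ((lr["ligand"] == pair.ligand) & (lr["receptor"] == pair.receptor)).sum()
            assert n == 1

    def test_decoy_count_as_configured(self, default_cfg):
        lr = simulate_lr_table(default_cfg)
        assert (lr["source"] == "decoy").sum() == default_cfg.n_decoy_pairs

    def test_ligandless_collision_rejected(self):
        cfg = default_config(seed=1)
        cfg.ligandless_receptors = list(cfg.ligandless_receptors) + ["R_BOTH1"]
        with pytest.raises(ValueError, match="ligandless"):
            simulate_lr_table(cfg)
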