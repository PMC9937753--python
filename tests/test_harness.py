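"""Training loop bookkeeping, determinism, grids, holdout and boosting."""

import numpy as np
import pytest

from conftest import TINY_DISC, TINY_GEN, TINY_L, tiny_train_config
from ecgan.errors import ConfigError, EmptyDatasetError, ShapeError
from ecgan.gan import GeneratorConfig, build_generator
from ecgan.harness import (OracleDenoiser, boost, denoise,
                           make_synthetic_dataset, run_grid, subject_holdout,
                           train)
from ecgan.preprocess import NoiseSpec, PairedDataset, SignalFragment


class TestTrain:
    def test_history_has_one_entry_per_epoch(self, tiny_dataset):
        _, hist = train(tiny_dataset, TINY_GEN, TINY_DISC, tiny_train_config(5))
        assert len(hist) == 5
        df = hist.to_frame()
        assert list(df.columns) == ["epoch", "generator_loss",
                                    "discriminator_loss", "train_rmse",
                                    "test_snr_imp_db"]
        assert np.isfinite(df.generator_loss).all()

    def test_same_seed_reproduces_final_rmse(self, tiny_dataset):
        cfg = tiny_train_config(2, seed=11)
        _, h1 = train(tiny_dataset, TINY_GEN, TINY_DISC, cfg)
        _, h2 = train(tiny_dataset, TINY_GEN, TINY_DISC, cfg)
        assert h1.per_epoch[-1]["train_rmse"] == h2.per_epoch[-1]["train_rmse"]

    def test_empty_train_split_rejected(self, tiny_dataset):
        empty = PairedDataset(clean=tiny_dataset.clean,
                              noisy=tiny_dataset.noisy,
                              noise_spec=tiny_dataset.noise_spec,
                              split=["test"] * len(tiny_dataset))
        with pytest.raises(EmptyDatasetError):
            train(empty, TINY_GEN, TINY_DISC, tiny_train_config(1))

    def test_training_never_mutates_test_fragments(self, tiny_dataset):
        test = tiny_dataset.subset("test")
        before = [f.samples.copy() for f in test.noisy + test.clean]
        train(tiny_dataset, TINY_GEN, TINY_DISC, tiny_train_config(2))
        after = [f.samples for f in test.noisy + test.clean]
        for a, b in zip(before, after):
            assert np.array_equal(a, b)

    def test_reconstruction_only_mode_trains_without_discriminator(
            self, tiny_dataset):
        cfg = tiny_train_config(3, adversarial_weight=0.0)
        _, hist = train(tiny_dataset, TINY_GEN, None, cfg)
        df = hist.to_frame()
        assert df.train_rmse.iloc[-1] < df.train_rmse.iloc[0]
        assert np.isnan(df.discriminator_loss).all()


class TestDenoise:
    def test_shapes_and_metadata_preserved(self, tiny_dataset):
        gen = build_generator(TINY_GEN, seed=0)
        out = denoise(gen, tiny_dataset.noisy[:7])
        assert len(out) == 7
        for inp, o in zip(tiny_dataset.noisy, out):
            assert len(o) == TINY_L
            assert o.source_id == inp.source_id
            assert o.fragment_index == inp.fragment_index

    def test_inference_is_deterministic(self, tiny_dataset):
        gen = build_generator(TINY_GEN, seed=0)
        a = denoise(gen, tiny_dataset.noisy[:3])
        b = denoise(gen, tiny_dataset.noisy[:3])
        for x, y in zip(a, b):
            assert np.array_equal(x.samples, y.samples)

    def test_untrained_generator_matches_golden_run(self):
        # frozen reference values from the seeded initial network
        gen = build_generator(TINY_GEN, seed=42)
        x = np.sin(np.arange(TINY_L) / 3.0)[None, :]
        y = gen.denoise_batch(x)[0]
        golden_mean = -0.00017867837844775912
        golden_first3 = [-1.0644095269781422e-05, -9.970989100584729e-06,
                         -2.449571083852767e-05]
        np.testing.assert_allclose(y.mean(), golden_mean, rtol=1e-9)
        np.testing.assert_allclose(y[:3], golden_first3, rtol=1e-9)

    def test_wrong_fragment_length_rejected(self):
        gen = build_generator(TINY_GEN, seed=0)
        with pytest.raises(ShapeError):
            gen.denoise_batch(np.zeros((2, TINY_L + 1)))


class TestRunGrid:
    def test_cell_count_is_product_of_axes(self, tiny_dataset):
        def oracle_fn(ds, gen_cfg, disc_cfg, cfg):
            return OracleDenoiser(ds)
        table = run_grid([("MA",), ("BW",), ("MA", "BW")], [-1.0, 7.0],
                         [TINY_GEN], tiny_train_config(1),
                         n_fragments=8, fragment_length=TINY_L,
                         test_fraction=0.25, train_fn=oracle_fn)
        assert len(table) == 3 * 2 * 1

    def test_oracle_denoiser_scores_zero_rmse_everywhere(self, tiny_dataset):
        table = run_grid([("MA", "BW", "EM")], [-1.0], [TINY_GEN],
                         tiny_train_config(1), n_fragments=8,
                         fragment_length=TINY_L, test_fraction=0.25,
                         train_fn=lambda ds, g, d, c: OracleDenoiser(ds))
        assert (table.rmse == 0).all()
        assert (table.prd == 0).all()

    def test_empty_architecture_list_rejected(self):
        with pytest.raises(ConfigError):
            run_grid([("MA",)], [-1.0], [], tiny_train_config(1))


def _subject(seed):
    return make_synthetic_dataset(10, NoiseSpec(("MA", "BW"), -1.0),
                                  seed=seed, fragment_length=TINY_L,
                                  test_fraction=0.2,
                                  source_id=f"subject-{seed}")


# Morphology-shift experiments need fragments long enough to hold whole
# beats: 256 samples (~0.7 s) with a matching reduced generator.
SHIFT_L = 256
SHIFT_GEN = GeneratorConfig(fragment_length=SHIFT_L, seed_length=8,
                            seed_channels=8, block_filters=(8, 8, 8, 8, 8))


def _subject_morph(seed, shifted=False):
    over = {}
    if shifted:  # inverted-polarity lead: R points down, broad slow waves
        over = {"wave_amplitudes": (0.1, 0.2, -1.0, 0.3, -0.25),
                "wave_widths_s": (0.05, 0.02, 0.03, 0.025, 0.09)}
    return make_synthetic_dataset(12, NoiseSpec(("MA", "BW"), -1.0),
                                  seed=seed, fragment_length=SHIFT_L,
                                  test_fraction=0.2,
                                  source_id=f"subject-{seed}",
                                  ecg_overrides=over)


class TestSubjectHoldout:
    def test_report_covers_only_held_out_subject(self):
        subjects = [_subject(s) for s in (1, 2, 3)]
        rep = subject_holdout(subjects, 1, TINY_GEN, TINY_DISC,
                              tiny_train_config(1))
        assert rep.n_fragments == len(subjects[1])

    def test_fewer_than_two_subjects_rejected(self):
        with pytest.raises(ConfigError):
            subject_holdout([_subject(1)], 0, TINY_GEN, TINY_DISC,
                            tiny_train_config(1))

    def test_out_of_range_index_rejected(self):
        with pytest.raises(ConfigError):
            subject_holdout([_subject(1), _subject(2)], 5, TINY_GEN,
                            TINY_DISC, tiny_train_config(1))

    def test_shifted_morphology_scores_below_matched_split(self):
        # distribution shift: a subject with a different beat shape denoises
        # worse than a same-distribution held-out subject, in every seed
        for seed in (0, 1, 2):
            subjects = [_subject_morph(10 + seed), _subject_morph(20 + seed),
                        _subject_morph(30 + seed, shifted=True)]
            cfg = tiny_train_config(15, seed=seed, adversarial_weight=0.0)
            shifted = subject_holdout(subjects, 2, SHIFT_GEN, None, cfg)
            matched = subject_holdout(
                subjects[:2] + [_subject_morph(40 + seed)], 2, SHIFT_GEN, None,
                cfg)
            assert (matched.aggregates["snr_imp_db"]
                    > shifted.aggregates["snr_imp_db"])


class TestBoost:
    def test_printed_fine_tune_and_test_counts(self):
        ds = _subject(99)
        # replicate fragments up to 542 to check the 20%/80% arithmetic
        reps = (542 // len(ds)) + 1
        clean = (ds.clean * reps)[:542]
        noisy = (ds.noisy * reps)[:542]
        big = PairedDataset(clean=clean, noisy=noisy, noise_spec=ds.noise_spec)
        gen = build_generator(TINY_GEN, seed=0)
        _, (before, after) = boost(gen, big, 0.2, tiny_train_config(1))
        assert before.n_fragments == 434
        assert after.n_fragments == 434

    def test_floor_arithmetic_on_small_sets(self):
        ds = _subject(98)
        gen = build_generator(TINY_GEN, seed=0)
        _, (before, _) = boost(gen, ds, 0.2, tiny_train_config(1))
        assert before.n_fragments == len(ds) - int(0.2 * len(ds))

    def test_invalid_fraction_rejected(self):
        gen = build_generator(TINY_GEN, seed=0)
        with pytest.raises(ConfigError):
            boost(gen, _subject(97), 1.2, tiny_train_config(1))

    def test_boosting_improves_on_shifted_subject(self):
        for seed in (0, 1, 2):
            base = _subject_morph(50 + seed)
            cfg = tiny_train_config(12, seed=seed, adversarial_weight=0.0)
            gen, _ = train(base, SHIFT_GEN, None, cfg)
            new_subject = _subject_morph(60 + seed, shifted=True)
            _, (before, after) = boost(
                gen, new_subject, 0.2,
                tiny_train_config(12, seed=seed, adversarial_weight=0.0))
            assert (after.aggregates["snr_imp_db"]
                    >= before.aggregates["snr_imp_db"])
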