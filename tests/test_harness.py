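"""Training/prediction/evaluation orchestration at micro scale."""

import numpy as np
import pytest

from mafcdn.errors import ValidationError
from mafcdn.harness import (
    AblationArm,
    LossSpec,
    PreprocessSpec,
    RunConfig,
    ablate,
    default_ablation_grid,
    evaluate,
    load_checkpoint,
    predict,
    train,
)
from mafcdn.image_core import read_mask
from mafcdn.network import ArchitectureConfig
from mafcdn.synth import SyntheticSceneConfig, generate_dataset

MICRO_ARCH = ArchitectureConfig(
    variant_name="micro",
    first_conv_channels=6,
    growth_rate=4,
    down_block_layers=(1,),
    bottleneck_layers=1,
    up_block_layers=(1,),
)

MICRO_CFG = RunConfig(model=MICRO_ARCH, epochs=2, batch_size=4, seed=7)


@pytest.fixture(scope="module")
def micro_data(tmp_path_factory):
    out = tmp_path_factory.mktemp("micro_data")
    cfg = SyntheticSceneConfig(
        height=32, width=32, n_vessels=2, n_mas=3, ma_radius_range=(1.0, 2.5),
        noise_sigma=3.0, seed=42,
    )
    generate_dataset(cfg, 8, 3, 3, out)
    return out


@pytest.fixture(scope="module")
def trained(micro_data, tmp_path_factory):
    out = tmp_path_factory.mktemp("micro_run")
    return train(MICRO_CFG, micro_data, out), out


class TestTrain:
    def test_artifacts_and_history(self, trained):
        result, out = trained
        assert result.best_checkpoint.exists()
        assert result.final_checkpoint.exists()
        assert result.log_path.exists()
        assert len(result.history) == 2
        header = result.log_path.read_text().splitlines()[0]
        assert header.startswith("epoch,lr,train_loss,val_miou")

    def test_zero_epochs_rejected(self, micro_data, tmp_path):
        with pytest.raises(ValidationError):
            train(RunConfig(model=MICRO_ARCH, epochs=0), micro_data, tmp_path)

    def test_empty_split_rejected(self, tmp_path):
        (tmp_path / "train").mkdir()
        (tmp_path / "val").mkdir()
        with pytest.raises(ValidationError):
            train(MICRO_CFG, tmp_path, tmp_path / "out")

    def test_rerun_reproduces_log_bit_for_bit(self, micro_data, trained, tmp_path):
        result, _ = trained
        cfg = RunConfig.from_file(result.config_path)
        rerun = train(cfg, micro_data, tmp_path)
        assert rerun.log_path.read_bytes() == result.log_path.read_bytes()

    def test_checkpoint_roundtrip_restores_val_miou(self, trained, micro_data):
        from mafcdn.harness import _load_split, _val_metrics

        result, _ = trained
        net, run_cfg = load_checkpoint(result.best_checkpoint)
        _, vx, vy = _load_split(micro_data / "val", run_cfg.preprocess)
        agg = _val_metrics(net, vx, vy, 4)
        assert agg.mean.MIoU == pytest.approx(result.best_val_miou, abs=1e-6)


class TestPredict:
    def test_output_contract(self, trained, micro_data, tmp_path):
        result, _ = trained
        written = predict(result.best_checkpoint, micro_data / "test", tmp_path)
        assert len(written) == 3
        for p in written:
            mask = read_mask(p)
            assert (mask.height, mask.width) == (32, 32)
            assert set(np.unique(mask.labels)) <= {0, 1}

    def test_predict_deterministic(self, trained, micro_data, tmp_path):
        result, _ = trained
        a = predict(result.best_checkpoint, micro_data / "test", tmp_path / "a")
        b = predict(result.best_checkpoint, micro_data / "test", tmp_path / "b")
        for pa, pb in zip(a, b):
            assert pa.read_bytes() == pb.read_bytes()

    def test_non_divisible_input_padded_and_cropped_back(self, trained, tmp_path):
        from mafcdn.image_core import GrayImage, write_gray_image

        result, _ = trained
        rng = np.random.default_rng(0)
        src = tmp_path / "odd"
        src.mkdir()
        write_gray_image(GrayImage(rng.integers(0, 256, (33, 35))), src / "odd_img.png")
        (out,) = predict(result.best_checkpoint, src, tmp_path / "pred")
        assert read_mask(out).labels.shape == (33, 35)

    def test_blank_input_passthrough_produces_valid_mask(self, trained, tmp_path):
        from mafcdn.image_core import GrayImage, write_gray_image

        result, _ = trained
        src = tmp_path / "blank"
        src.mkdir()
        write_gray_image(GrayImage(np.full((32, 32), 7)), src / "blank_img.png")
        (out,) = predict(result.best_checkpoint, src, tmp_path / "pred")
        assert set(np.unique(read_mask(out).labels)) <= {0, 1}


class TestEvaluate:
    def test_self_comparison_all_ones(self, micro_data, tmp_path):
        per_image, agg = evaluate(micro_data / "test", micro_data / "test", tmp_path)
        assert agg.n == 3
        assert agg.mean.MIoU == 1.0 and agg.mean.F1 == 1.0
        assert all(v.PA == 1.0 for v in per_image.values())
        assert (tmp_path / "metrics.json").exists()
        assert (tmp_path / "metrics.csv").exists()

    def test_single_pair_aggregate_equals_report(self, micro_data):
        single = micro_data / "val"
        per_image, agg = evaluate(single, single)
        first = next(iter(per_image.values()))
        if len(per_image) == 1:
            assert agg.mean == first

    def test_orphan_filenames_listed(self, micro_data, tmp_path):
        import shutil

        partial = tmp_path / "partial"
        partial.mkdir()
        masks = sorted((micro_data / "test").glob("*_mask.png"))
        shutil.copy(masks[0], partial / masks[0].name)
        with pytest.raises(ValidationError, match=masks[1].name):
            evaluate(partial, micro_data / "test")

    def test_hand_built_pair_matches_hand_computed_values(self, tmp_path):
        from mafcdn.image_core import MaskImage, write_mask

        truth = np.zeros((10, 10), dtype=np.uint8)
        truth.ravel()[:5] = 1  # 5 MA pixels
        pred = np.zeros((10, 10), dtype=np.uint8)
        pred.ravel()[:2] = 1  # 2 hits
        pred.ravel()[90:95] = 1  # 5 false alarms
        (tmp_path / "p").mkdir()
        (tmp_path / "t").mkdir()
        write_mask(MaskImage(pred), tmp_path / "p" / "0_mask.png")
        write_mask(MaskImage(truth), tmp_path / "t" / "0_mask.png")
        _, agg = evaluate(tmp_path / "p", tmp_path / "t")
        assert agg.mean.PA == pytest.approx(0.92)
        assert agg.mean.Pre == pytest.approx(2 / 7)
        assert agg.mean.Re == pytest.approx(0.4)


class TestAblate:
    def test_single_arm_equivalent_to_train_plus_evaluate(self, micro_data, tmp_path):
        grid = [AblationArm("solo", MICRO_CFG)]
        table = ablate(grid, micro_data, tmp_path / "grid")
        assert list(table["model"]) == ["solo"]
        result = train(MICRO_CFG, micro_data, tmp_path / "direct")
        predict(result.best_checkpoint, micro_data / "test", tmp_path / "direct_pred")
        _, agg = evaluate(tmp_path / "direct_pred", micro_data / "test")
        assert table.iloc[0]["MIoU"] == agg.format_row()["MIoU"]

    def test_default_grid_arms(self):
        grid = default_ablation_grid(MICRO_CFG)
        assert [a.name for a in grid] == ["preprocessing+net", "net+focal", "full"]
        assert grid[0].config.loss.name == "cross_entropy"
        assert grid[0].config.preprocess.enabled
        assert grid[1].config.loss.name == "focal"
        assert not grid[1].config.preprocess.enabled
        assert grid[2].config.loss.name == "focal"
        assert grid[2].config.preprocess.enabled
        # arms share seed; only the named deltas differ
        assert len({a.config.seed for a in grid}) == 1

    def test_failed_arm_marked_not_fatal(self, micro_data, tmp_path):
        bad = RunConfig(model=MICRO_ARCH, epochs=2, crop_size=31)  # not divisible
        table = ablate(
            [AblationArm("bad", bad), AblationArm("good", MICRO_CFG)],
            micro_data,
            tmp_path / "grid",
        )
        assert table.iloc[0]["MIoU"] == "failed"
        assert table.iloc[1]["MIoU"] != "failed"


class TestRunConfig:
    def test_yaml_and_json_round_trip(self, tmp_path):
        cfg = RunConfig(
            model="FC-DenseNet56",
            loss=LossSpec(name="focal", alpha_ma=0.3, gamma=1.5),
            preprocess=PreprocessSpec(enabled=False),
            epochs=3,
            seed=123,
        )
        cfg.save(tmp_path / "cfg.json")
        assert RunConfig.from_file(tmp_path / "cfg.json") == cfg

    def test_custom_architecture_round_trip(self, tmp_path):
        cfg = RunConfig(model=MICRO_ARCH)
        cfg.save(tmp_path / "cfg.json")
        assert RunConfig.from_file(tmp_path / "cfg.json").arch() == MICRO_ARCH

    def test_unknown_loss_rejected(self):
        with pytest.raises(ValidationError):
            LossSpec(name="dice")
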