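"""Domain types and file round-trips (EDF, hypnogram CSV, checkpoints)."""

from __future__ import annotations

import numpy as np
import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st

from stagernet import (
    CLASS_ORDER,
    EegRecording,
    Hypnogram,
    SleepStage,
    StagerConfig,
    TrainConfig,
    load_model,
    read_hypnogram,
    read_recording,
    save_model,
    write_hypnogram,
    write_recording,
)
from stagernet.architecture import StagerModel
from stagernet.config import load_stager_config, load_train_config, save_config
from stagernet.core import N_CLASSES, STAGE_TOKENS
from stagernet.io import ChannelNotFoundError, CheckpointError, FormatError
from stagernet.io import write_txt_recording


# ---------------------------------------------------------------------------
# SleepStage / Hypnogram
# ---------------------------------------------------------------------------


def test_stage_enum_has_six_codes_five_classes():
    assert len(SleepStage) == 6
    assert N_CLASSES == 5
    assert SleepStage.UNKNOWN not in CLASS_ORDER


def test_class_order_matches_documented_constant():
    assert CLASS_ORDER == (
        SleepStage.N3,
        SleepStage.N2,
        SleepStage.N1,
        SleepStage.REM,
        SleepStage.WAKE,
    )


def test_stage_integer_encoding_is_bijective():
    codes = {int(s) for s in SleepStage}
    assert codes == set(range(6))
    for s in SleepStage:
        assert SleepStage(int(s)) is s


def test_hypnogram_scored_mask_and_fractions():
    hyp = Hypnogram(stages=[SleepStage.WAKE, SleepStage.UNKNOWN, SleepStage.N2])
    assert hyp.scored_mask().tolist() == [True, False, True]
    frac = hyp.stage_fractions()
    assert frac[SleepStage.UNKNOWN] == pytest.approx(1 / 3)
    assert frac[SleepStage.N2] == pytest.approx(1 / 3)


def test_recording_validation():
    with pytest.raises(ValueError):
        EegRecording(samples=np.array([1.0, np.nan]), rate=100.0)
    with pytest.raises(ValueError):
        EegRecording(samples=np.zeros(10), rate=0.0)
    with pytest.raises(ValueError):
        EegRecording(samples=np.zeros(10), rate=100.0, gender=2)


# ---------------------------------------------------------------------------
# Hypnogram CSV
# ---------------------------------------------------------------------------


def test_read_hypnogram_direct_mapping(tmp_path):
    p = tmp_path / "h.csv"
    p.write_text("epoch,stage\n0,W\n1,N2\n")
    assert read_hypnogram(p).stages == [SleepStage.WAKE, SleepStage.N2]


def test_read_hypnogram_s3_s4_merge_to_n3(tmp_path):
    p = tmp_path / "h.csv"
    p.write_text("0,S3\n1,S4\n")
    assert read_hypnogram(p).stages == [SleepStage.N3, SleepStage.N3]


def test_read_hypnogram_gap_is_error(tmp_path):
    p = tmp_path / "h.csv"
    p.write_text("0,W\n2,N2\n")
    with pytest.raises(FormatError):
        read_hypnogram(p)


def test_read_hypnogram_unknown_token_is_error(tmp_path):
    p = tmp_path / "h.csv"
    p.write_text("0,W\n1,XX\n")
    with pytest.raises(FormatError):
        read_hypnogram(p)


def test_read_hypnogram_trim_unknown_edges(tmp_path):
    p = tmp_path / "h.csv"
    p.write_text("0,U\n1,U\n2,N2\n3,W\n4,U\n")
    hyp = read_hypnogram(p, trim_unknown_edges=True)
    assert hyp.stages == [SleepStage.N2, SleepStage.WAKE]


@settings(max_examples=25, deadline=None)
@given(st.lists(st.sampled_from(list(SleepStage)), min_size=1, max_size=200))
def test_hypnogram_write_read_identity(tmp_path_factory, stages):
    path = tmp_path_factory.mktemp("hyp") / "h.csv"
    hyp = Hypnogram(stages=stages)
    write_hypnogram(hyp, path)
    assert read_hypnogram(path) == hyp


def test_all_tokens_readable(tmp_path):
    p = tmp_path / "h.csv"
    rows = "\n".join(f"{i},{tok}" for i, tok in enumerate(STAGE_TOKENS))
    p.write_text(rows + "\n")
    hyp = read_hypnogram(p)
    assert [s for s in hyp] == [STAGE_TOKENS[t] for t in STAGE_TOKENS]


# ---------------------------------------------------------------------------
# EDF round trips
# ---------------------------------------------------------------------------


def test_edf_length_from_rate_and_duration(tmp_path):
    rec = EegRecording(samples=np.random.default_rng(0).normal(0, 20, 6000),
                       rate=100.0, subject_id="s1")
    path = tmp_path / "a.edf"
    write_recording(rec, path)
    back = read_recording(path)
    assert len(back) == 6000  # 100 Hz x 60 s
    assert back.rate == 100.0


def test_edf_round_trip_within_quantization(tmp_path):
    rng = np.random.default_rng(1)
    x = rng.normal(0.0, 30.0, 3000)
    rec = EegRecording(samples=x, rate=100.0)
    path = tmp_path / "a.edf"
    write_recording(rec, path)
    back = read_recording(path)
    # 16-bit quantization step of the written physical range
    quantum = 2 * np.max(np.abs(x)) * 1.000001 / 65535
    assert np.max(np.abs(back.samples - x)) <= quantum


def test_edf_round_trip_odd_length(tmp_path):
    x = np.sin(np.arange(2513) * 0.01) * 40
    rec = EegRecording(samples=x, rate=100.0)
    path = tmp_path / "odd.edf"
    write_recording(rec, path)
    back = read_recording(path)
    assert len(back) == 2513


def test_edf_missing_channel_error(tmp_path):
    rec = EegRecording(samples=np.zeros(100) + 1.0, rate=100.0,
                       channel_label="C3")
    path = tmp_path / "c3.edf"
    write_recording(rec, path)
    with pytest.raises(ChannelNotFoundError):
        read_recording(path, channel="FPz")


def test_unreadable_edf_is_format_error(tmp_path):
    path = tmp_path / "bad.edf"
    path.write_bytes(b"this is not an EDF file at all" * 10)
    with pytest.raises(FormatError):
        read_recording(path)


def test_txt_round_trip(tmp_path):
    x = np.linspace(-5, 5, 321)
    rec = EegRecording(samples=x, rate=100.0, subject_id="s9")
    path = tmp_path / "r.txt"
    write_txt_recording(rec, path)
    back = read_recording(path)
    assert back.subject_id == "s9"
    np.testing.assert_allclose(back.samples, x, atol=1e-6)


def test_demographics_sidecar(tmp_path):
    rec = EegRecording(samples=np.ones(200), rate=100.0, subject_id="s003")
    path = tmp_path / "r.edf"
    write_recording(rec, path)
    demo = tmp_path / "demographics.yaml"
    demo.write_text(yaml.safe_dump({"s003": {"age": 41.5, "gender": -1}}))
    back = read_recording(path, demographics=demo)
    assert back.age == 41.5
    assert back.gender == -1


# ---------------------------------------------------------------------------
# Config YAML
# ---------------------------------------------------------------------------


def test_config_yaml_round_trip(tmp_path):
    cfg = StagerConfig(units_per_layer=32, conv_activation="leaky_relu",
                       n_conv_layers=2, conv_filters=(4, 8))
    p = tmp_path / "cfg.yaml"
    save_config(cfg, p)
    assert load_stager_config(p) == cfg
    tcfg = TrainConfig(batch_size=4, n_epochs=2)
    save_config(tcfg, tmp_path / "t.yaml")
    assert load_train_config(tmp_path / "t.yaml") == tcfg


def test_default_config_reproduces_baseline():
    cfg = StagerConfig()
    assert cfg.conv_filters == (8, 16, 32)
    assert cfg.kernel_width == 8
    assert cfg.stride == 1
    assert cfg.pool_factor == 8
    assert cfg.conv_activation == "relu"
    assert cfg.recurrent_kind == "lstm"
    assert (cfg.n_recurrent_layers, cfg.units_per_layer) == (2, 64)
    assert cfg.output_classes == 5
    assert not cfg.use_age and not cfg.use_gender
    assert cfg.l1_conv == cfg.l2_conv == cfg.l1_rec == cfg.l2_rec == 0.0
    assert cfg.dropout_forward == cfg.dropout_recurrent == 0.0


def test_default_train_config_matches_protocol():
    t = TrainConfig()
    assert (t.learning_rate, t.beta1, t.beta2) == (0.001, 0.9, 0.999)
    assert (t.epsilon, t.decay) == (1e-8, 0.0)
    assert (t.batch_size, t.seq_len_windows) == (128, 128)
    assert (t.batches_per_epoch, t.n_epochs) == (16, 512)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def _small_config():
    return StagerConfig(n_conv_layers=2, conv_filters=(4, 8), units_per_layer=8)


def test_checkpoint_round_trip_identical_outputs(tmp_path):
    model = StagerModel(_small_config(), seed=3)
    path = tmp_path / "m.ckpt"
    save_model(model, path)
    back = load_model(path)
    rng = np.random.default_rng(0)
    X = rng.normal(0, 20, (2, 3, 3000))
    np.testing.assert_allclose(
        back.forward_sequence(X), model.forward_sequence(X), atol=1e-7
    )


def test_checkpoint_double_save_byte_identical(tmp_path):
    model = StagerModel(_small_config(), seed=3)
    p1, p2 = tmp_path / "a.ckpt", tmp_path / "b.ckpt"
    save_model(model, p1)
    back = load_model(p1)
    save_model(back, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_checkpoint_config_mismatch(tmp_path):
    model = StagerModel(_small_config(), seed=3)
    path = tmp_path / "m.ckpt"
    save_model(model, path)
    with pytest.raises(CheckpointError):
        load_model(path, expected_config=StagerConfig())


def test_checkpoint_bad_magic(tmp_path):
    path = tmp_path / "junk.ckpt"
    path.write_bytes(b"NOTACKPT" + b"\x00" * 32)
    with pytest.raises(CheckpointError):
        load_model(path)
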