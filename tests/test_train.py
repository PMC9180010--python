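"""Training protocol: poly schedule, pixel cross-entropy, determinism,
checkpoint resume, prediction and the latency harness."""

import numpy as np
import pytest

from mvdnet import (
    LabelSchema,
    MVDNetSpec,
    TrainConfig,
    build_mvdnet,
    evaluate,
    fps_benchmark,
    pixel_mean_cross_entropy,
    poly_lr,
    predict,
    read_mask,
    train,
)
from mvdnet.errors import InvalidInputError

TINY = MVDNetSpec(stage_channels=(4, 6, 8), depths=(1, 1, 1), dilations=(1, 2, 2))


def test_default_config_is_the_published_recipe():
    cfg = TrainConfig()
    assert (cfg.batch_size, cfg.momentum, cfg.weight_decay) == (8, 0.9, 1e-4)
    assert (cfg.base_lr, cfg.lr_power, cfg.epochs, cfg.crop) == (0.16, 0.9, 100, 512)


def test_poly_schedule_closed_form():
    cfg = TrainConfig()
    assert poly_lr(0, 1000, cfg) == pytest.approx(0.16)
    assert poly_lr(1000, 1000, cfg) == 0.0
    assert poly_lr(500, 1000, cfg) == pytest.approx(0.16 * 0.5 ** 0.9)


def test_poly_schedule_strictly_decreasing_and_bounded():
    cfg = TrainConfig()
    values = [poly_lr(s, 50, cfg) for s in range(51)]
    assert all(a > b for a, b in zip(values, values[1:]))
    with pytest.raises(InvalidInputError):
        poly_lr(51, 50, cfg)


def test_cross_entropy_uniform_scores():
    scores = np.zeros((10, 4, 4))
    targets = np.random.default_rng(0).integers(0, 10, size=(4, 4))
    assert pixel_mean_cross_entropy(scores, targets) == pytest.approx(np.log(10))


def test_cross_entropy_confident_correct_scores_vanish():
    targets = np.random.default_rng(1).integers(0, 3, size=(4, 4))
    scores = np.full((3, 4, 4), -100.0)
    for c in range(3):
        scores[c][targets == c] = 100.0
    assert pixel_mean_cross_entropy(scores, targets) == pytest.approx(0.0, abs=1e-12)


def test_cross_entropy_hand_computed_two_pixel_case():
    scores = np.array([[[2.0, 0.0]], [[0.0, 2.0]]])   # C=2, H=1, W=2
    targets = np.array([[0, 1]])
    expected = -np.log(np.exp(2) / (np.exp(2) + 1))
    assert pixel_mean_cross_entropy(scores, targets) == pytest.approx(expected)
    assert expected == pytest.approx(0.126928, abs=1e-6)


def test_cross_entropy_gradient_matches_finite_differences():
    rng = np.random.default_rng(2)
    scores = rng.normal(size=(1, 3, 2, 2))
    targets = rng.integers(0, 3, size=(1, 2, 2))
    _, grad = pixel_mean_cross_entropy(scores, targets, return_grad=True)
    eps = 1e-6
    for idx in [(0, 0, 0, 0), (0, 2, 1, 1), (0, 1, 0, 1)]:
        scores[idx] += eps
        lp = pixel_mean_cross_entropy(scores, targets)
        scores[idx] -= 2 * eps
        lm = pixel_mean_cross_entropy(scores, targets)
        scores[idx] += eps
        assert grad[idx] == pytest.approx((lp - lm) / (2 * eps), abs=1e-8)


def test_cross_entropy_rejects_out_of_range_labels():
    with pytest.raises(InvalidInputError):
        pixel_mean_cross_entropy(np.zeros((3, 2, 2)), np.full((2, 2), 5))


def _tiny_cfg(epochs):
    return TrainConfig(batch_size=4, epochs=epochs, crop=64, seed=3)


def test_two_epoch_loss_decreases_and_is_deterministic(tiny_corpus):
    net_a = build_mvdnet(TINY, seed=3)
    res_a = train(net_a, tiny_corpus, _tiny_cfg(2), validate_each_epoch=False)
    assert len(res_a.loss_log) == 2
    assert res_a.loss_log[1] < res_a.loss_log[0]
    net_b = build_mvdnet(TINY, seed=3)
    res_b = train(net_b, tiny_corpus, _tiny_cfg(2), validate_each_epoch=False)
    assert res_a.loss_log == res_b.loss_log


def test_resume_from_epoch_boundary_reproduces_full_run(tiny_corpus, tmp_path):
    cfg = _tiny_cfg(2)
    straight = build_mvdnet(TINY, seed=3)
    res = train(straight, tiny_corpus, cfg, validate_each_epoch=False)

    interrupted = build_mvdnet(TINY, seed=3)
    train(interrupted, tiny_corpus, cfg, out_dir=tmp_path,
          validate_each_epoch=False, stop_after=1)
    resumed = build_mvdnet(TINY, seed=999)   # weights come from the checkpoint
    res2 = train(resumed, tiny_corpus, cfg, resume=tmp_path / "checkpoint.npz",
                 validate_each_epoch=False)
    for (k, p), (k2, p2) in zip(straight.named_parameters(),
                                resumed.named_parameters()):
        np.testing.assert_array_equal(p.data, p2.data), k
    assert res.loss_log == res2.loss_log


def test_training_rejects_empty_split(tmp_path):
    from mvdnet.data import Corpus
    corpus = Corpus(root=tmp_path, schema=LabelSchema.default(),
                    manifest={"samples": [],
                              "normalization": {"mean": [0] * 3, "std": [1] * 3}})
    with pytest.raises(InvalidInputError):
        train(build_mvdnet(TINY), corpus, _tiny_cfg(1))


def test_predict_labels_and_overlay_roundtrip(tiny_corpus, tmp_path):
    net = build_mvdnet(TINY, seed=0)
    sample = tiny_corpus.load(tiny_corpus.ids("test")[0])
    overlay = tmp_path / "overlay.png"
    labels = predict(net, sample.image, tiny_corpus.normalization,
                     overlay_path=overlay)
    assert labels.shape == sample.mask.shape
    assert set(np.unique(labels)) <= set(range(10))
    np.testing.assert_array_equal(read_mask(overlay, LabelSchema.default()), labels)


def test_evaluate_reports_on_split(tiny_corpus):
    net = build_mvdnet(TINY, seed=0)
    report = evaluate(net, tiny_corpus.samples("val"), tiny_corpus.normalization,
                      schema=tiny_corpus.schema)
    assert 0.0 <= report.miou <= 1.0
    stratified = evaluate(net, tiny_corpus.samples("train"),
                          tiny_corpus.normalization, schema=tiny_corpus.schema,
                          group_key="gender")
    assert set(stratified.group_reports) <= {"male", "female"}


def test_fps_benchmark_reports_consistent_statistics():
    net = build_mvdnet(TINY, seed=0)
    stats = fps_benchmark(net, size=(32, 32), repeats=1, warmup=0)
    assert len(stats["samples_ms"]) == 1
    assert stats["fps"] == pytest.approx(1000.0 / stats["mean_ms"])
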