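"""Image-folder loading, stratified splitting, the Adam loop, evaluation."""

import numpy as np
import pytest
from PIL import Image

from rvit import models, synthetic, training


def write_folder(root, sizes, image_size=12):
    """Create a class-per-directory tree with the given class sizes."""
    rng = np.random.default_rng(0)
    for cls, n in sizes.items():
        d = root / cls
        d.mkdir(parents=True)
        for i in range(n):
            arr = (rng.random((image_size, image_size)) * 255).astype(np.uint8)
            Image.fromarray(arr).save(d / f"img_{i:03d}.png")
    return root


class TestLoadImageFolder:
    def test_sizes_and_labels(self, tmp_path):
        root = write_folder(tmp_path, {"a_neg": 3, "b_pos": 2})
        ds = training.load_image_folder(root, 8, channels=1)
        assert len(ds) == 5
        assert ds.class_names == ("a_neg", "b_pos")
        assert list(ds.labels) == [0, 0, 0, 1, 1]
        assert ds.images.shape == (5, 8, 8, 1)
        assert ds.images.min() >= 0 and ds.images.max() <= 1

    def test_reload_gives_identical_ordering(self, tmp_path):
        root = write_folder(tmp_path, {"x": 4, "y": 4})
        d1 = training.load_image_folder(root, 8, channels=1)
        d2 = training.load_image_folder(root, 8, channels=1)
        assert d1.files == d2.files
        assert np.array_equal(d1.images, d2.images)

    def test_non_square_source_resized_to_square(self, tmp_path):
        d = tmp_path / "only"
        d.mkdir()
        Image.fromarray(np.zeros((6, 20), dtype=np.uint8)).save(d / "a.png")
        Image.fromarray(np.zeros((6, 20), dtype=np.uint8)).save(d / "b.png")
        ds = training.load_image_folder(tmp_path, 10, channels=1)
        assert ds.images.shape[1:3] == (10, 10)

    def test_unreadable_file_skipped_with_warning(self, tmp_path):
        root = write_folder(tmp_path, {"c": 2})
        (root / "c" / "broken.png").write_bytes(b"not an image")
        with pytest.warns(UserWarning, match="skipping unreadable"):
            ds = training.load_image_folder(root, 8, channels=1)
        assert len(ds) == 2

    def test_empty_class_directory_rejected(self, tmp_path):
        root = write_folder(tmp_path, {"full": 2})
        (root / "empty").mkdir()
        with pytest.raises(ValueError, match="no images"):
            training.load_image_folder(root, 8, channels=1)

    def test_rgb_conversion(self, tmp_path):
        root = write_folder(tmp_path, {"g": 2})
        ds = training.load_image_folder(root, 8, channels=3)
        assert ds.images.shape[-1] == 3


class TestSplitTrainVal:
    def test_stratified_sizes(self):
        labels = np.array([0] * 5 + [1] * 5)
        tr, va = training.split_train_val(labels, 0.8, seed=0)
        assert len(tr) == 8 and len(va) == 2
        assert labels[tr].sum() == 4 and labels[va].sum() == 1

    def test_disjoint_and_exhaustive(self):
        labels = np.random.default_rng(1).integers(0, 2, size=37)
        tr, va = training.split_train_val(labels, 0.7, seed=3)
        combined = np.sort(np.concatenate([tr, va]))
        assert np.array_equal(combined, np.arange(37))

    def test_same_seed_reproduces_split(self):
        labels = np.array([0, 1] * 20)
        a = training.split_train_val(labels, 0.8, seed=9)
        b = training.split_train_val(labels, 0.8, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_different_seeds_permute_but_keep_sizes(self):
        labels = np.array([0, 1] * 20)
        a = training.split_train_val(labels, 0.8, seed=1)
        b = training.split_train_val(labels, 0.8, seed=2)
        assert len(a[0]) == len(b[0])
        assert not np.array_equal(a[0], b[0])

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            training.split_train_val(np.array([0, 0, 0, 1]), 0.8, seed=0)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            training.split_train_val(np.array([0, 1, 0, 1]), 1.5, seed=0)


class TestTrainLoop:
    def test_loss_decreases_on_separable_toy_data(self):
        spec = synthetic.PhantomSpec(image_size=32, n_images=60, seed=9,
                                     lesion_axes=(6.0, 9.0),
                                     lesion_intensity=0.5, noise_sd=0.01)
        data = synthetic.generate_dataset(spec)
        ds = training.LabelledImages(data.images, data.labels,
                                     synthetic.CLASS_NAMES)
        tr, va = training.split_train_val(ds.labels, 0.8, seed=0)
        cfg = models.ModelConfig(image_size=32, patch_size=8, in_channels=1,
                                 embed_dim=32, depth=2, heads=2, mlp_size=64,
                                 rotations=4, attention_dropout=0.0)
        model = models.build_model(cfg, seed=0)
        tconf = training.TrainConfig(epochs=5, seed=0)
        history = training.train(model, ds.subset(tr), ds.subset(va), tconf)
        assert len(history) == 5
        assert history.rows[-1]["train_loss"] < history.rows[0]["train_loss"]
        assert history.best_epoch >= 0
        assert history.best_state is not None

    def test_training_is_reproducible(self):
        spec = synthetic.PhantomSpec(image_size=32, n_images=24, seed=3,
                                     lesion_axes=(5.0, 8.0))
        data = synthetic.generate_dataset(spec)
        ds = training.LabelledImages(data.images, data.labels,
                                     synthetic.CLASS_NAMES)
        tr, va = training.split_train_val(ds.labels, 0.75, seed=0)
        cfg = models.ModelConfig(image_size=32, patch_size=8, in_channels=1,
                                 embed_dim=16, depth=1, heads=2, mlp_size=32,
                                 rotations=4)
        tconf = training.TrainConfig(epochs=2, seed=5)
        runs = []
        for _ in range(2):
            model = models.build_model(cfg, seed=5)
            history = training.train(model, ds.subset(tr), ds.subset(va), tconf)
            runs.append((history.rows, model.state_dict()))
        assert runs[0][0] == runs[1][0]
        for k in runs[0][1]:
            assert np.array_equal(runs[0][1][k], runs[1][1][k])

    def test_empty_sets_rejected(self, tiny_model):
        empty = training.LabelledImages(np.zeros((0, 16, 16, 1)),
                                        np.zeros(0, dtype=int), ("a", "b"))
        with pytest.raises(ValueError, match="non-empty"):
            training.train(tiny_model, empty, empty, training.TrainConfig())

    def test_history_csv_round_trip(self, tmp_path):
        history = training.History()
        history.append(epoch=0, train_loss=0.7, val_loss=0.6,
                       train_acc=0.5, val_acc=0.55)
        path = tmp_path / "history.csv"
        training.write_history_csv(history, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "epoch,train_loss,val_loss,train_acc,val_acc"
        assert len(lines) == 2


class _FixedModel:
    """Deterministic stub: predicts from a pre-set label vector."""

    def __init__(self, preds):
        self.preds = np.asarray(preds)
        self.used = 0

    def forward(self, images, training=False):
        n = len(images)
        out = np.zeros((n, 2))
        sel = self.preds[self.used:self.used + n]
        out[np.arange(n), sel] = 1.0
        self.used += n
        return out


class TestEvaluate:
    def test_counts_conserve_dataset_size(self, phantom_data):
        ds = training.LabelledImages(phantom_data.images, phantom_data.labels,
                                     synthetic.CLASS_NAMES)
        model = _FixedModel(np.zeros(len(ds), dtype=int))
        cm = training.evaluate(model, ds, batch_size=16)
        assert cm.total == len(ds)

    def test_perfect_predictions_have_no_errors(self, phantom_data):
        ds = training.LabelledImages(phantom_data.images, phantom_data.labels,
                                     synthetic.CLASS_NAMES)
        model = _FixedModel(ds.labels)
        cm = training.evaluate(model, ds)
        assert cm.fp == 0 and cm.fn == 0
        assert cm.tp == int(ds.labels.sum())

    def test_constant_model_zeroes_one_prediction_row(self, phantom_data):
        ds = training.LabelledImages(phantom_data.images, phantom_data.labels,
                                     synthetic.CLASS_NAMES)
        model = _FixedModel(np.zeros(len(ds), dtype=int))
        cm = training.evaluate(model, ds)
        assert cm.tp == 0 and cm.fp == 0  # nothing predicted positive
        assert cm.fn == int(ds.labels.sum())

    def test_trained_model_beats_chance(self, trained_small_model):
        model, data, ds, tr, va, history = trained_small_model
        cm = training.evaluate(model, ds.subset(va))
        from rvit.metrics import compute_metrics
        assert compute_metrics(cm).accuracy > 0.6

    def test_rotated_dataset_gives_identical_confusion_matrix(
            self, trained_small_model):
        """End-to-end invariance: evaluating the rotation-averaged model on
        a quarter-rotated copy of the data yields the same counts."""
        model, data, ds, tr, va, history = trained_small_model
        val = ds.subset(va)
        cm0 = training.evaluate(model, val)
        rot = training.LabelledImages(
            np.ascontiguousarray(np.rot90(val.images, 1, axes=(1, 2))),
            val.labels, val.class_names)
        cm1 = training.evaluate(model, rot)
        assert cm0 == cm1
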