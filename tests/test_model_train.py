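import numpy as np
import pytest

from subcdr.autodiff import Tensor
from subcdr.fixtures import generate_responses, generate_world
from subcdr.model_train import (CDRDataset, MLP, ModelConfig, SubCDRModel,
                                decode, evaluate, huber_loss, train)


@pytest.fixture(scope="module")
def tiny_dataset():
    world = generate_world(n_drugs=5, n_cells=6, n_genes=9, n_subsets=3,
                           seed=21)
    instances = generate_responses(world)
    from subcdr.data_io import binarize

    instances = binarize(instances, threshold=1.0)
    return CDRDataset(instances, world.drugs, world.expression,
                      world.catalog, world.tumour_type_of)


def _cfg(**kw):
    base = dict(hidden=8, epochs=2, batch_size=16, side_rank=2,
                side_width=4, side_iters=30, lr=1e-3, seed=0, dropout=0.0)
    base.update(kw)
    return ModelConfig(**base)


class TestHuberLoss:
    @pytest.mark.parametrize("e,expected", [(0.0, 0.0), (0.5, 0.125),
                                            (2.0, 1.5), (-2.0, 1.5)])
    def test_branch_values(self, e, expected):
        assert huber_loss(np.array([e]), np.array([0.0])) == \
            pytest.approx(expected)

    def test_continuity_at_delta(self):
        delta = 1.0
        quad = 0.5 * delta ** 2
        lin = delta * delta - 0.5 * delta ** 2
        assert quad == pytest.approx(lin) == pytest.approx(0.5)
        eps = 1e-9
        below = huber_loss(np.array([delta - eps]), np.array([0.0]))
        above = huber_loss(np.array([delta + eps]), np.array([0.0]))
        assert abs(below - above) < 1e-6

    def test_gradient_magnitude_capped_by_delta(self):
        for e in (-5.0, -1.2, -0.3, 0.4, 0.9, 3.0):
            pred = Tensor(np.array([e]), requires_grad=True)
            loss = huber_loss(pred, np.array([0.0]), delta=1.0)
            loss.backward()
            assert abs(pred.grad[0]) <= 1.0 + 1e-12

    def test_delta_validation(self):
        with pytest.raises(ValueError):
            huber_loss(np.array([1.0]), np.array([0.0]), delta=0.0)


class TestDecode:
    def test_zero_decoder_regression_zero(self):
        dec = MLP([3, 1], np.random.default_rng(0))
        dec.layers[0].W.data[...] = 0.0
        out = decode(np.ones((2, 3)), None, None, dec)
        assert np.allclose(out.data, 0.0)

    def test_zero_decoder_classification_half(self):
        dec = MLP([3, 1], np.random.default_rng(0))
        dec.layers[0].W.data[...] = 0.0
        out = decode(np.ones((2, 3)), None, None, dec, task="classification")
        assert np.allclose(out.data, 0.5)

    def test_hand_set_affine_decoder(self):
        dec = MLP([3, 1], np.random.default_rng(0))
        dec.layers[0].W.data[...] = [[1.0, -2.0, 0.5]]
        dec.layers[0].b.data[...] = 0.25
        h = np.array([[2.0, 1.0, 4.0]])
        out = decode(h, None, None, dec)
        assert out.data[0] == pytest.approx(2.0 - 2.0 + 2.0 + 0.25)

    def test_side_rows_concatenated(self):
        dec = MLP([4, 1], np.random.default_rng(0))
        dec.layers[0].W.data[...] = [[0.0, 0.0, 1.0, 1.0]]
        dec.layers[0].b.data[...] = 0.0
        out = decode(np.zeros((1, 2)), np.array([[3.0]]), np.array([[4.0]]),
                     dec)
        assert out.data[0] == pytest.approx(7.0)


class TestTraining:
    def test_zero_epochs_returns_initialized_model(self, tiny_dataset):
        model, history = train(tiny_dataset, _cfg(epochs=0))
        assert history == []
        assert np.isfinite(model.predict([0], [0])).all()

    def test_seeded_runs_identical(self, tiny_dataset):
        _, h1 = train(tiny_dataset, _cfg(epochs=3, seed=4))
        _, h2 = train(tiny_dataset, _cfg(epochs=3, seed=4))
        assert h1 == h2

    def test_loss_decreases_on_small_problem(self, tiny_dataset):
        _, history = train(tiny_dataset, _cfg(epochs=25, lr=3e-3))
        assert history[-1] < history[0]

    @pytest.mark.parametrize("ablation", [
        "no_side_info", "no_sequence_encoders", "no_graph", "gated_graph",
        "no_subcomponents"])
    def test_ablation_variants_train_and_predict(self, tiny_dataset,
                                                 ablation):
        model, history = train(tiny_dataset,
                               _cfg(ablation=frozenset({ablation})))
        pred = model.predict(tiny_dataset.di[:4], tiny_dataset.ci[:4])
        assert np.isfinite(pred).all() and len(history) == 2

    def test_classification_head_bounded(self, tiny_dataset):
        model, _ = train(tiny_dataset, _cfg(task="classification"))
        pred = model.predict(tiny_dataset.di[:6], tiny_dataset.ci[:6])
        assert np.all((pred > 0) & (pred < 1))

    def test_unknown_ablation_rejected(self):
        with pytest.raises(ValueError, match="no_magic"):
            _cfg(ablation=frozenset({"no_magic"}))

    def test_interaction_map_rows_are_unpadded_fragments(self, tiny_dataset):
        model, _ = train(tiny_dataset, _cfg())
        drug = tiny_dataset.drug_index[0]
        cell = tiny_dataset.cell_index[0]
        imap = model.interaction_map(drug, cell)
        assert imap.shape[0] == len(tiny_dataset.sequences[drug].fragments)
        assert imap.shape[1] == tiny_dataset.n_subsets
        assert np.all((imap.scores > 0) & (imap.scores < 1))

    def test_batched_graph_summary_matches_module_gcn(self, tiny_dataset):
        # the model's dense batched propagation must agree with the
        # graph-module implementation on the same parameters
        from subcdr.interaction import (GCNParams, build_graph,
                                        gcn_forward, pool, InteractionMap)

        model = SubCDRModel(tiny_dataset, _cfg())
        di = np.array([0])
        ci = np.array([0])
        omega, mask = model._interaction(di, ci)
        h_model = model._graph_summary(omega, mask).data[0]

        keep = mask[0] > 0
        scores = omega.data[0][keep]
        g = build_graph(InteractionMap(scores))
        t_d = tiny_dataset.t_d
        n = tiny_dataset.n_subsets
        m_eff = int(keep.sum())
        # rearrange theta columns: model's one-hot basis spans padded
        # node slots, the graph module's only the real ones
        cols = list(np.flatnonzero(keep)) + [t_d + j for j in range(n)]
        thetas = [model.thetas[0].data[:, cols]] + \
            [t.data for t in model.thetas[1:]]
        params = GCNParams(thetas)
        z = gcn_forward(g, params)
        assert np.allclose(pool(z), h_model, atol=1e-10)


class TestEvaluate:
    def test_perfect_predictions(self, tiny_dataset):
        model, _ = train(tiny_dataset, _cfg(epochs=0))
        idx = np.arange(8)
        model.predict = lambda di, ci: tiny_dataset.y[idx]
        rep = evaluate(model, idx)
        assert rep.rmse == pytest.approx(0.0)
        assert rep.pcc == pytest.approx(1.0)
        assert rep.r2 == pytest.approx(1.0)

    def test_sign_reversed_predictions_pcc_minus_one(self, tiny_dataset):
        model, _ = train(tiny_dataset, _cfg(epochs=0))
        idx = np.arange(8)
        centred = tiny_dataset.y[idx] - tiny_dataset.y[idx].mean()
        model.predict = lambda di, ci: -centred
        rep = evaluate(model, idx)
        assert rep.pcc == pytest.approx(-1.0)

    def test_toy_classification_metrics(self, tiny_dataset):
        model, _ = train(tiny_dataset, _cfg(epochs=0,
                                            task="classification"))
        model.predict = lambda di, ci: np.array([0.9, 0.8, 0.2, 0.1])
        tiny_dataset.labels[:4] = [1, 1, 0, 0]
        rep = evaluate(model, np.arange(4), task="classification")
        assert rep.auc == pytest.approx(1.0)
        assert rep.aupr == pytest.approx(1.0)

    def test_single_class_flagged_undefined(self, tiny_dataset):
        model, _ = train(tiny_dataset, _cfg(epochs=0,
                                            task="classification"))
        tiny_dataset.labels[:4] = [1, 1, 1, 1]
        rep = evaluate(model, np.arange(4), task="classification")
        assert rep.undefined

    def test_metrics_match_independent_formulas(self):
        # fixed toy vectors, metrics recomputed from first principles
        from scipy import stats
        from sklearn.metrics import r2_score

        truth = np.array([0.2, -1.3, 2.1, 0.7, -0.4])
        pred = np.array([0.1, -1.0, 1.8, 1.1, -0.2])
        rmse = np.sqrt(np.mean((pred - truth) ** 2))
        assert rmse == pytest.approx(
            float(np.sqrt(np.sum((pred - truth) ** 2) / 5)), abs=1e-10)
        assert np.corrcoef(pred, truth)[0, 1] == pytest.approx(
            stats.pearsonr(pred, truth).statistic, abs=1e-10)
        ss_res = np.sum((truth - pred) ** 2)
        ss_tot = np.sum((truth - truth.mean()) ** 2)
        assert r2_score(truth, pred) == pytest.approx(1 - ss_res / ss_tot,
                                                      abs=1e-10)


def test_config_yaml_round_trip(tmp_path):
    import yaml

    cfg = ModelConfig(hidden=12, ablation=frozenset({"no_graph"}),
                      decoder_hidden=(16, 8))
    p = tmp_path / "cfg.yaml"
    with open(p, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh)
    loaded = ModelConfig.from_yaml(p)
    assert loaded.hidden == 12
    assert loaded.ablation == frozenset({"no_graph"})
    assert loaded.decoder_hidden == (16, 8)
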