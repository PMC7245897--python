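"""Training loops, evaluation metrics, prediction."""

import numpy as np
import pytest
import yaml

from kbrelex.corpus import NONE_LABEL, RELATION_TYPES, RelationInstance
from kbrelex.estimation import (
    EntityTaggerModel,
    RelationExtractionModel,
    TrainConfig,
    emit_config,
    evaluate_prf,
    evaluate_prf_keys,
)
from kbrelex.model import ModelConfig
from kbrelex.synth import SynthConfig, generate


def rel(rtype, a, b, rid="R"):
    return RelationInstance(rid, rtype, a, b)


class TestEvaluatePrf:
    def test_perfect_agreement(self):
        gold = [rel(RELATION_TYPES[i % 3], f"T{i}", f"T{i+1}") for i in range(5)]
        report = evaluate_prf(gold, gold)
        assert report.precision == report.recall == report.f1 == 1.0

    def test_worked_counts(self):
        gold = [rel("Binds_To", "T1", "T2"), rel("Binds_To", "T3", "T4"),
                rel("Interacts_With", "T1", "T3"), rel("Interacts_With", "T2", "T4")]
        predicted = [gold[0], gold[2],  # 2 tp
                     rel("Binds_To", "T2", "T1")]  # 1 fp; 2 gold missed
        report = evaluate_prf(predicted, gold)
        m = report.micro
        assert (m.tp, m.fp, m.fn) == (2, 1, 2)
        assert round(report.precision, 4) == 0.6667
        assert round(report.recall, 4) == 0.5
        assert round(report.f1, 4) == 0.5714

    def test_no_predictions(self):
        report = evaluate_prf([], [rel("Binds_To", "T1", "T2")])
        assert report.precision == report.recall == report.f1 == 0.0

    def test_none_predictions_are_abstentions(self):
        gold = [rel("Binds_To", "T1", "T2")]
        predicted = [rel(NONE_LABEL, "T3", "T4"), gold[0]]
        report = evaluate_prf(predicted, gold)
        assert report.micro.fp == 0 and report.f1 == 1.0

    def test_direction_matters(self):
        gold = [rel("Binds_To", "T1", "T2")]
        predicted = [rel("Binds_To", "T2", "T1")]
        report = evaluate_prf(predicted, gold)
        assert report.micro.tp == 0 and report.micro.fp == 1

    def test_fuzz_against_counting_oracle(self, rng):
        labels = list(RELATION_TYPES[:4])
        for _ in range(300):
            universe = [
                (labels[int(rng.integers(4))], f"T{int(rng.integers(6))}",
                 f"U{int(rng.integers(6))}")
                for _ in range(int(rng.integers(0, 12)))
            ]
            pred = {k for k in universe if rng.random() < 0.5}
            gold = {k for k in universe if rng.random() < 0.5}
            report = evaluate_prf_keys(pred, gold)
            tp = len(pred & gold)
            fp = len(pred - gold)
            fn = len(gold - pred)
            m = report.micro
            assert (m.tp, m.fp, m.fn) == (tp, fp, fn)
            p = tp / (tp + fp) if tp + fp else 0.0
            r = tp / (tp + fn) if tp + fn else 0.0
            f = 2 * p * r / (p + r) if p + r else 0.0
            assert abs(report.f1 - f) < 1e-12


class TestTrainConfig:
    def test_lr_outside_allowed_range_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(lr=0.5)

    @pytest.mark.parametrize("lr", [0.8, 0.9, 1.0])
    def test_allowed_lrs(self, lr):
        assert TrainConfig(lr=lr).lr == lr

    def test_large_corpus_batch_size(self):
        cfg = TrainConfig()
        assert cfg.effective_batch_size(100) == 10
        assert cfg.effective_batch_size(100_000) == 20

    def test_emitted_defaults(self):
        data = yaml.safe_load(emit_config(ModelConfig(), TrainConfig()))
        assert data["train"]["lr"] == 1.0
        assert data["train"]["l2"] == 1e-5
        assert data["train"]["batch_size"] == 10
        assert data["train"]["batch_size_large"] == 20
        assert data["model"]["lstm_state"] == 200
        assert data["model"]["dropout"] == 0.3


@pytest.fixture(scope="module")
def trigger_synth():
    """Lexically separable corpus: trigger tokens fully determine labels."""
    return generate(
        SynthConfig(
            n_documents=10,
            sentences_per_doc=5,
            embed_dim=16,
            n_relation_labels=3,
            kb_signal=0.0,
            p_trigger=1.0,
            p_relation=1.0,
            seed=11,
        )
    )


MCFG = dict(embed_dim=16, lstm_state=12, num_relation_labels=4)


class TestRelationTraining:
    def test_loss_decreases_and_fits_separable_corpus(self, trigger_synth):
        data = trigger_synth
        model = RelationExtractionModel(
            data.documents, data.store, data.embeddings,
            ModelConfig(use_kb=False, seed=0, **MCFG),
        )
        results = model.fit(TrainConfig(max_epochs=25, seed=0))
        losses = results.epoch_log["loss"]
        assert losses.iloc[-1] < losses.iloc[0]
        assert results.evaluate(data.documents).f1 >= 0.95

    def test_empty_corpus_rejected(self, trigger_synth):
        with pytest.raises(ValueError):
            RelationExtractionModel(
                [], trigger_synth.store, trigger_synth.embeddings
            )

    def test_same_seed_reproducible(self, trigger_synth):
        data = trigger_synth
        docs = data.documents[:4]
        def final_loss(seed):
            model = RelationExtractionModel(
                docs, data.store, data.embeddings,
                ModelConfig(use_kb=True, seed=seed, **MCFG),
            )
            res = model.fit(TrainConfig(max_epochs=3, seed=seed))
            return res.epoch_log["loss"].iloc[-1], res.params
        l1, p1 = final_loss(0)
        l2, p2 = final_loss(0)
        assert l1 == l2
        assert all(np.array_equal(p1[k], p2[k]) for k in p1)

    def test_seed_change_changes_parameters(self, trigger_synth):
        data = trigger_synth
        docs = data.documents[:4]
        params = {}
        for seed in (0, 1):
            model = RelationExtractionModel(
                docs, data.store, data.embeddings,
                ModelConfig(use_kb=True, seed=seed, **MCFG),
            )
            params[seed] = model.fit(TrainConfig(max_epochs=1, seed=seed)).params
        assert any(
            not np.array_equal(params[0][k], params[1][k]) for k in params[0]
        )

    def test_predict_document_deterministic_and_none_suppressed(self, trigger_synth):
        data = trigger_synth
        model = RelationExtractionModel(
            data.documents[:5], data.store, data.embeddings,
            ModelConfig(use_kb=False, seed=0, **MCFG),
        )
        results = model.fit(TrainConfig(max_epochs=5, seed=0))
        doc = data.documents[5]
        p1 = results.predict_document(doc)
        p2 = results.predict_document(doc)
        assert [r.key for r in p1.relations] == [r.key for r in p2.relations]
        assert all(r.rtype != NONE_LABEL for r in p1.relations)

    def test_document_without_entities_yields_no_relations(self, trigger_synth):
        from kbrelex.corpus import Document, segment

        text = "Wrd1 Wrd2 Wrd3."
        doc = Document("bare", text, segment(text), [], [])
        data = trigger_synth
        model = RelationExtractionModel(
            data.documents[:2], data.store, data.embeddings,
            ModelConfig(use_kb=False, seed=0, **MCFG),
        )
        results = model.fit(TrainConfig(max_epochs=1, seed=0))
        assert results.predict_document(doc).relations == []

    def test_early_stopping_respects_patience(self, trigger_synth):
        data = trigger_synth
        model = RelationExtractionModel(
            data.documents[:6], data.store, data.embeddings,
            ModelConfig(use_kb=False, seed=0, **MCFG),
        )
        results = model.fit(
            TrainConfig(max_epochs=40, patience=2, seed=0),
            validation_documents=data.documents[6:8],
        )
        assert len(results.epoch_log) <= 40
        assert "val_f1" in results.epoch_log.columns

    def test_summary_mentions_key_settings(self, trigger_synth):
        data = trigger_synth
        model = RelationExtractionModel(
            data.documents[:2], data.store, data.embeddings,
            ModelConfig(use_kb=True, seed=0, **MCFG),
        )
        text = model.fit(TrainConfig(max_epochs=1, seed=0)).summary()
        assert "AdaDelta" in text and "KB attention" in text


class TestEntityTagging:
    @pytest.mark.parametrize("use_crf", [False, True])
    def test_recovers_planted_spans_after_training(self, use_crf):
        data = generate(
            SynthConfig(
                n_documents=12,
                sentences_per_doc=5,
                embed_dim=16,
                entity_pool=40,
                p_trigger=0.0,
                seed=5,
            )
        )
        model = EntityTaggerModel(
            data.documents, data.store, data.embeddings,
            ModelConfig(embed_dim=16, lstm_state=24, use_kb=False,
                        use_crf=use_crf, seed=0),
        )
        results = model.fit(TrainConfig(max_epochs=60, seed=0))
        report = results.evaluate(data.documents[:4])
        assert report.f1 >= 0.75

    def test_predicted_types_are_valid(self):
        data = generate(
            SynthConfig(n_documents=4, sentences_per_doc=3, embed_dim=16, seed=9)
        )
        model = EntityTaggerModel(
            data.documents, data.store, data.embeddings,
            ModelConfig(embed_dim=16, lstm_state=8, use_kb=True, seed=0),
        )
        results = model.fit(TrainConfig(max_epochs=2, seed=0))
        pred = results.predict_document(data.documents[0])
        assert all(e.etype in ("Gene", "Protein") for e in pred.entities)
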