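"""The self-training loop: confidence scoring, promotion rules, and the
conservation/termination invariants of the labeled/unlabeled pools."""

import numpy as np
import pandas as pd
import pytest

from sscnn import (
    SSLConfig,
    SSLState,
    TrainConfig,
    make_ssl_partition,
    ssl_step,
    train_sscnn,
    train_supervised,
)
from sscnn.selftrain import ConfidenceRecord, confidence_scores, select_promotions

FAST = TrainConfig(epochs=4, batch_size=16, seed=0)


# --------------------------------------------------------------------
# confidence scoring
# --------------------------------------------------------------------
def test_confidence_is_row_maximum():
    recs = confidence_scores(np.array([[0.7, 0.2, 0.1]]))
    assert recs[0].predicted_class == 0
    assert recs[0].confidence == pytest.approx(0.7)


def test_one_hot_row_gives_full_confidence():
    recs = confidence_scores(np.array([[0.0, 1.0, 0.0]]))
    assert recs[0].confidence == pytest.approx(1.0)
    assert recs[0].predicted_class == 1


def test_uniform_row_ties_to_lowest_class():
    recs = confidence_scores(np.array([[1 / 3, 1 / 3, 1 / 3]]))
    assert recs[0].predicted_class == 0
    assert recs[0].confidence == pytest.approx(1 / 3)


def test_non_stochastic_rows_rejected():
    with pytest.raises(ValueError):
        confidence_scores(np.array([[0.9, 0.5, 0.1]]))
    with pytest.raises(ValueError):
        confidence_scores(np.array([[1.2, -0.2, 0.0]]))


def test_alternative_scorers_available():
    probs = np.array([[0.5, 0.3, 0.2], [0.4, 0.35, 0.25]])
    margin = confidence_scores(probs, scorer="margin")
    assert margin[0].confidence == pytest.approx(0.2)
    entropy = confidence_scores(probs, scorer="neg_entropy")
    assert entropy[0].confidence > entropy[1].confidence  # sharper row wins


# --------------------------------------------------------------------
# promotion selection
# --------------------------------------------------------------------
def test_one_promotion_per_predicted_class():
    probs = np.array([
        [0.8, 0.1, 0.1], [0.6, 0.2, 0.2],
        [0.1, 0.7, 0.2], [0.2, 0.6, 0.2],
        [0.1, 0.1, 0.8],
    ])
    promoted = select_promotions(confidence_scores(probs))
    assert len(promoted) == 3
    assert sorted(r.predicted_class for r in promoted) == [0, 1, 2]
    assert {r.sample_id for r in promoted} == {0, 2, 4}  # class-wise maxima


def test_absent_class_contributes_nothing():
    probs = np.array([[0.9, 0.05, 0.05], [0.8, 0.1, 0.1]])
    promoted = select_promotions(confidence_scores(probs))
    assert len(promoted) == 1
    assert promoted[0].sample_id == 0


def test_within_class_tie_breaks_to_smaller_sample_id():
    records = [
        ConfidenceRecord(7, 1, 0.9),
        ConfidenceRecord(2, 1, 0.9),
    ]
    for order in (records, records[::-1]):
        assert select_promotions(order)[0].sample_id == 2


def test_per_class_promotion_budget():
    probs = np.tile([0.8, 0.1, 0.1], (6, 1))
    promoted = select_promotions(confidence_scores(probs), per_class=4)
    assert len(promoted) == 4


def test_empty_records_rejected():
    with pytest.raises(ValueError):
        select_promotions([])


# --------------------------------------------------------------------
# ssl_step on real state
# --------------------------------------------------------------------
@pytest.fixture(scope="module")
def warm_state_and_model(small_noisy_dataset):
    part = make_ssl_partition(small_noisy_dataset, 20, seed=0)
    state = SSLState.from_partition(part)
    model, _ = train_supervised(None, part.lds, None, FAST)
    return state, model


def test_ssl_step_conserves_samples(warm_state_and_model):
    state, model = warm_state_and_model
    new = ssl_step(state, model)
    assert new.total == state.total
    assert new.iteration == state.iteration + 1
    assert len(new.lds) > len(state.lds)
    assert len(new.lds) - len(state.lds) <= 3
    assert set(new.lds.sample_ids) | set(new.uds.sample_ids) == \
        set(state.lds.sample_ids) | set(state.uds.sample_ids)


def test_ssl_step_tags_promotions_with_provenance(warm_state_and_model):
    state, model = warm_state_and_model
    new = ssl_step(state, model)
    n_new = len(new.lds) - len(state.lds)
    assert new.provenance[-n_new:] == ["pseudo"] * n_new
    assert all(it == new.iteration for it in new.promotion_iteration[-n_new:])
    assert all(np.isfinite(c) for c in new.promotion_confidence[-n_new:])


def test_ssl_step_rejects_empty_uds(warm_state_and_model, small_noisy_dataset):
    _, model = warm_state_and_model
    part = make_ssl_partition(small_noisy_dataset, 100, seed=0)
    with pytest.raises(ValueError, match="empty"):
        ssl_step(SSLState.from_partition(part), model)


def test_small_remnant_promoted_wholesale(small_noisy_dataset, warm_state_and_model):
    _, model = warm_state_and_model
    part = make_ssl_partition(small_noisy_dataset, 97, seed=0)  # UDS of 3
    assert len(part.uds) <= 3
    new = ssl_step(SSLState.from_partition(part), model)
    assert len(new.uds) == 0


# --------------------------------------------------------------------
# the full loop
# --------------------------------------------------------------------
def test_loop_terminates_with_conservation_and_provenance(small_noisy_dataset):
    clf, history, ledger = train_sscnn(
        small_noisy_dataset, 20, FAST,
        SSLConfig(per_class=2, epochs_per_iteration=1, seed=0),
    )
    n = len(small_noisy_dataset)
    part = make_ssl_partition(small_noisy_dataset, 20, seed=0)
    assert history["uds_size"].iloc[-1] == 0
    # UDS strictly shrinks, LDS+UDS constant
    sizes = history[["lds_size", "uds_size"]].to_numpy()
    assert (sizes.sum(axis=1) == n).all()
    assert (np.diff(history["uds_size"]) < 0).all()
    assert (history["promotions"] >= 1).all()
    assert (history["promotions"] <= 2 * 3).all()
    # every promoted sample is accounted for exactly once
    assert len(ledger) == len(part.uds)
    assert ledger["sample_id"].is_unique
    assert set(ledger["sample_id"]) == set(part.uds.sample_ids)
    assert ledger["pseudo_label"].between(0, 2).all()
    assert ledger["confidence"].between(1 / 3 - 1e-9, 1 + 1e-9).all()


def test_m100_bit_matches_supervised_trainer(small_noisy_dataset):
    part = make_ssl_partition(small_noisy_dataset, 100, seed=5)
    sup, _ = train_supervised(None, part.lds, None, FAST)
    clf, history, ledger = train_sscnn(
        small_noisy_dataset, 100, FAST, SSLConfig(seed=5),
    )
    assert len(history) == 0 and len(ledger) == 0
    for a, b in zip(clf.model_.get_weights(), sup.get_weights()):
        assert np.array_equal(a, b)


def test_pseudo_labels_never_copy_hidden_truth(small_noisy_dataset):
    """Pseudo-labels come from the model: with a deliberately broken
    (untrained, 0-epoch) model they disagree with the hidden truth."""
    clf, history, ledger = train_sscnn(
        small_noisy_dataset, 20,
        TrainConfig(epochs=0, seed=0),
        SSLConfig(per_class=30, epochs_per_iteration=0, seed=0),
    )
    agree = (ledger["pseudo_label"] == ledger["true_label"]).mean()
    assert agree < 0.99  # an oracle-copying bug would give exactly 1.0


def test_loop_iteration_bound(small_noisy_dataset):
    part = make_ssl_partition(small_noisy_dataset, 20, seed=0)
    _, history, _ = train_sscnn(
        small_noisy_dataset, 20, FAST,
        SSLConfig(per_class=1, epochs_per_iteration=0, seed=0),
    )
    assert len(history) <= len(part.uds)
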