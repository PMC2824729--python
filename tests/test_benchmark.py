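"""Confusion matrices, rates, ROC/AUC, enrichment, method comparison."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from domprior.benchmark import (
    BenchmarkLabels,
    ConfusionMatrix,
    comparison_table,
    confusion,
    enrichment_ratio,
    evaluate,
    metrics,
    roc_curve,
)
from domprior.hrc import table3_check
from domprior.table3 import table3_fixture


def labels_of(n_pos, n_neg):
    return BenchmarkLabels(
        positives=frozenset(f"D{i}" for i in range(n_pos)),
        negatives=frozenset(f"C{i}" for i in range(n_neg)),
    )


def test_labels_must_be_disjoint_and_nonempty():
    with pytest.raises(ValueError):
        BenchmarkLabels(frozenset({"A"}), frozenset({"A", "B"}))
    with pytest.raises(ValueError):
        BenchmarkLabels(frozenset(), frozenset({"B"}))


def test_perfect_and_null_predictions():
    labels = labels_of(5, 10)
    perfect = confusion(labels.positives, labels)
    assert (perfect.tp, perfect.fp, perfect.tn, perfect.fn) == (5, 0, 10, 0)
    assert metrics(perfect) == (1.0, 1.0, 1.0)
    null = confusion(set(), labels)
    assert (null.tp, null.fp, null.fn) == (0, 0, 5)


def test_ids_outside_universe_dropped():
    labels = labels_of(3, 3)
    m = confusion({"D0", "ELSEWHERE"}, labels)
    assert (m.tp, m.fp) == (1, 0)


def test_confusion_matches_per_gene_tally():
    """Random prediction over a 372-gene universe vs an exhaustive tally."""
    rng = np.random.default_rng(8)
    labels = labels_of(19, 353)
    universe = sorted(labels.universe)
    predicted = {g for g in universe if rng.random() < 0.3}
    m = confusion(predicted, labels)
    tally = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
    for g in universe:
        pos = g in labels.positives
        pred = g in predicted
        tally["tp" if pos and pred else "fn" if pos else "fp" if pred else "tn"] += 1
    assert (m.tp, m.fp, m.tn, m.fn) == (
        tally["tp"], tally["fp"], tally["tn"], tally["fn"],
    )


def test_metrics_against_fraction_oracle():
    rng = np.random.default_rng(13)
    for _ in range(100):
        tp, fp, tn, fn = (int(x) for x in rng.integers(1, 50, size=4))
        sens, spec, acc = metrics(ConfusionMatrix(tp, fp, tn, fn))
        assert sens == pytest.approx(tp / (tp + fn))
        assert spec == pytest.approx(tn / (tn + fp))
        assert acc == pytest.approx((tp + tn) / (tp + fp + tn + fn))
        assert sens + fn / (tp + fn) == pytest.approx(1.0)
        assert spec + fp / (tn + fp) == pytest.approx(1.0)


def test_zero_denominator_reported_as_unavailable():
    sens, spec, acc = metrics(ConfusionMatrix(tp=0, fp=2, tn=3, fn=0))
    assert sens is None and spec is not None and acc is not None


def test_hrc_sensitivity_on_published_positives():
    """Applying the combined filter to the 19 published disease genes
    recovers 6, i.e. sensitivity 6/19 = 0.32 after rounding."""
    _, _, flags = table3_check(table3_fixture())
    positives = frozenset(r.gene for r in table3_fixture())
    labels = BenchmarkLabels(positives, frozenset({"CTRL"}))
    m = confusion({g for g, f in flags.items() if f}, labels)
    sens, _, _ = metrics(m)
    assert m.tp == 6
    assert sens == pytest.approx(6 / 19)
    assert round(sens, 2) == 0.32


def brute_force_auc(scores, labels):
    """P(random positive outscores random negative), ties half."""
    pos = [scores.get(g, 0.0) for g in labels.positives]
    neg = [scores.get(g, 0.0) for g in labels.negatives]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg
    )
    return wins / (len(pos) * len(neg))


def test_roc_perfect_separation_and_tied_scores():
    labels = labels_of(4, 4)
    scores = {f"D{i}": 1.0 for i in range(4)} | {f"C{i}": 0.0 for i in range(4)}
    points, auc = roc_curve(scores, labels)
    assert auc == pytest.approx(1.0)
    flat = {g: 0.5 for g in labels.universe}
    _, auc_flat = roc_curve(flat, labels)
    assert auc_flat == pytest.approx(0.5)


def test_roc_monotone_from_origin_to_one_one():
    rng = np.random.default_rng(3)
    labels = labels_of(20, 30)
    scores = {g: float(rng.random()) for g in labels.universe}
    points, _ = roc_curve(scores, labels)
    assert (points[0][1], points[0][2]) == (0.0, 0.0)
    assert (points[-1][1], points[-1][2]) == (1.0, 1.0)
    fprs = [p[1] for p in points]
    tprs = [p[2] for p in points]
    assert fprs == sorted(fprs) and tprs == sorted(tprs)


def test_auc_equals_pair_counting_and_sklearn():
    """Trapezoid AUC == brute-force concordant-pair probability on 50 seeded
    score/label sets (ties included), and == sklearn where defined."""
    rng = np.random.default_rng(17)
    for trial in range(50):
        n_pos = int(rng.integers(3, 15))
        n_neg = int(rng.integers(3, 25))
        labels = labels_of(n_pos, n_neg)
        # quantized scores force ties
        scores = {
            g: float(np.round(rng.random(), 1)) for g in sorted(labels.universe)
        }
        _, auc = roc_curve(scores, labels)
        assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
        y = [1 if g in labels.positives else 0 for g in sorted(labels.universe)]
        s = [scores[g] for g in sorted(labels.universe)]
        assert auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)


def test_auc_near_half_for_label_independent_scores():
    rng = np.random.default_rng(99)
    labels = labels_of(1000, 1000)
    scores = {g: float(rng.random()) for g in labels.universe}
    _, auc = roc_curve(scores, labels)
    assert auc == pytest.approx(0.5, abs=0.05)


def test_enrichment_trivial_cases():
    labels = labels_of(5, 15)
    all_genes = confusion(labels.universe, labels)
    assert enrichment_ratio(all_genes, labels) == pytest.approx(1.0)
    only_pos = confusion(labels.positives, labels)
    assert enrichment_ratio(only_pos, labels) == pytest.approx(20 / 5)
    none = confusion(set(), labels)
    assert enrichment_ratio(none, labels) is None


def test_enrichment_density_oracle_and_sensitivity_variant():
    rng = np.random.default_rng(31)
    labels = labels_of(19, 353)
    for _ in range(20):
        predicted = {g for g in labels.universe if rng.random() < 0.2}
        if not predicted:
            continue
        m = confusion(predicted, labels)
        dens = enrichment_ratio(m, labels, "density")
        assert dens == pytest.approx(
            (m.tp / len(predicted)) / (19 / 372)
        )
        assert enrichment_ratio(m, labels, "sensitivity") == pytest.approx(
            m.tp / 19
        )


def test_enrichment_near_one_for_label_blind_predictor():
    rng = np.random.default_rng(12)
    labels = labels_of(1000, 1000)
    predicted = {g for g in labels.universe if rng.random() < 0.5}
    m = confusion(predicted, labels)
    assert enrichment_ratio(m, labels) == pytest.approx(1.0, abs=0.1)


def test_comparison_table_layout_and_determinism():
    labels = labels_of(10, 30)
    rng = np.random.default_rng(4)
    random_method = {g for g in labels.universe if rng.random() < 0.5}
    table = comparison_table(
        {"ours": set(labels.positives), "random": random_method,
         "random-again": set(random_method)},
        labels,
    )
    assert list(table.index) == [
        "Accuracy (%)", "Sensitivity (%)", "Specificity (%)",
    ]
    assert table["ours"].tolist() == [100.0, 100.0, 100.0]
    assert table["random"].tolist() == table["random-again"].tolist()
    assert comparison_table({"empty": set()}, labels)["empty"].isna().all()


def test_comparison_table_preserves_planted_quality_ordering():
    """Three synthetic methods of decreasing constructed quality keep that
    order in every metric."""
    rng = np.random.default_rng(77)
    labels = labels_of(50, 150)
    def noisy(flip):
        out = set()
        for g in labels.universe:
            truth = g in labels.positives
            if rng.random() < flip:
                truth = not truth
            if truth:
                out.add(g)
        return out
    table = comparison_table(
        {"good": noisy(0.05), "mid": noisy(0.25), "bad": noisy(0.45)}, labels
    )
    for metric in table.index:
        row = table.loc[metric]
        assert row["good"] > row["mid"] > row["bad"]


def test_evaluate_bundles_all_quantities():
    labels = labels_of(8, 24)
    scores = {g: (1.0 if g in labels.positives else 0.1) for g in labels.universe}
    result = evaluate(set(labels.positives), labels, scores=scores)
    assert result.auc == pytest.approx(1.0)
    assert result.sensitivity == 1.0
    assert result.enrichment == pytest.approx(4.0)
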