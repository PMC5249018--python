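import numpy as np
import pytest

from protclass.align import local_align, selfalign
from protclass.classifier import (
    ConfusionMatrix,
    MLPModel,
    baseline_classifiers,
    build_training_set,
    evaluate,
    hidden_layer_size,
    mean_class_accuracy,
    per_class_accuracy,
    predict,
    round_percent,
    train_mlp,
    training_set_from_labels,
)
from protclass.io import ProteinRecord
from protclass.motif import has_domain, parse_pattern
from protclass.synthetic import FamilySpec, generate_family, random_protein


class TestEvaluateArithmetic:
    """Worked examples: confusion counts of a published method comparison."""

    @pytest.mark.parametrize(
        "tp,tn,fp,fn,sens,spec",
        [
            (229, 2704, 0, 67, 77.36, 100.0),   # identity/positive cutoff
            (231, 2704, 10, 55, 80.77, 99.63),  # conserved domain
            (219, 2704, 0, 77, 73.99, 100.0),   # domain with cutoff
            (289, 2704, 0, 7, 97.64, 100.0),    # learned classifier
        ],
    )
    def test_sensitivity_specificity_rows(self, tp, tn, fp, fn, sens, spec):
        cm = ConfusionMatrix(tp, tn, fp, fn)
        m = cm.metrics_percent()
        assert m["sensitivity"] == sens
        assert m["specificity"] == spec

    def test_all_correct_toy_labels(self):
        cm = evaluate([1, 1, 0, 0], [1, 1, 0, 0])
        m = cm.metrics_percent()
        assert m["sensitivity"] == m["specificity"] == m["accuracy"] == 100.0

    def test_counts_from_label_lists(self):
        cm = evaluate([1, 0, 1, 0, 1], [1, 1, 0, 0, 1])
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (2, 1, 1, 1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate([1, 0], [1])

    def test_rounding_is_half_up(self):
        assert round_percent(0.97635) == 97.64
        assert round_percent(0.773648) == 77.36
        assert round_percent(0.005) == 0.5
        assert round_percent(0.99605) == 99.61


class TestPerClassAccuracy:
    """Worked examples: per-family hit rates of a curated six-class panel."""

    def test_hits_over_curated(self):
        truth, pred = [], []
        # (class, curated, hits): build label lists realizing each row
        rows = [(1, 92, 91), (2, 23, 22), (3, 17, 16),
                (4, 14, 14), (5, 10, 10), (6, 13, 12)]
        for cls, curated, hits in rows:
            truth += [cls] * curated
            pred += [cls] * hits + [0] * (curated - hits)
        acc = per_class_accuracy(pred, truth)
        assert acc == {1: 98.91, 2: 95.65, 3: 94.12, 4: 100.0, 5: 100.0, 6: 92.31}
        assert mean_class_accuracy(acc) == 96.83


def graded_pool(consensus):
    """Candidate pool with controlled similarity: exact copies, mild and
    strong mutants of the consensus, plus unrelated decoys."""
    rng_seeds = iter(range(100, 200))
    pool = []
    for i, rate in enumerate((0.0, 0.02, 0.3, 0.35, 0.4, 0.45)):
        spec = FamilySpec(consensus, 1, rate, rng_seed=next(rng_seeds),
                          name=f"mut{i}")
        member = generate_family(spec)[0]
        pool.append(ProteinRecord(f"cand{i}_r{rate}", member.sequence))
    return pool


class TestBuildTrainingSet:
    CONSENSUS = random_protein(np.random.default_rng(7), 80)
    # conserved-domain proxy: the first 8 consensus residues
    PATTERN = parse_pattern("-".join(CONSENSUS[:8]))

    def test_balanced_classes_and_lowest_similarity_negatives(self):
        pool = graded_pool(self.CONSENSUS)
        matchers = [r for r in pool if has_domain(self.PATTERN, r.sequence)]
        non = [r for r in pool if not has_domain(self.PATTERN, r.sequence)]
        assert len(matchers) >= 2 and len(non) >= 2
        ts = build_training_set(pool, self.PATTERN, self.CONSENSUS)
        n_pos = int((ts.labels == 1).sum())
        n_neg = int((ts.labels == 0).sum())
        assert n_pos == len(matchers)
        assert n_neg == min(n_pos, len(non))
        # negatives are the lowest-selfalign non-matchers, ranked by hand
        ranked = sorted(non, key=lambda r: selfalign(r.sequence, self.CONSENSUS))
        expected_neg = {r.id for r in ranked[:n_neg]}
        neg_ids = {i for i, l in zip(ts.ids, ts.labels) if l == 0}
        assert neg_ids == expected_neg

    def test_candidate_identical_to_consensus_is_positive(self):
        pool = graded_pool(self.CONSENSUS)
        ts = build_training_set(pool, self.PATTERN, self.CONSENSUS)
        exact = pool[0].id
        assert dict(zip(ts.ids, ts.labels))[exact] == 1

    def test_low_similarity_candidate_excluded_despite_pattern_match(self):
        # a decoy carrying the pattern but with selfalign < 0.2 is gated out
        decoy_seq = self.CONSENSUS[:8] + random_protein(
            np.random.default_rng(3), 200
        )
        assert has_domain(self.PATTERN, decoy_seq)
        assert selfalign(decoy_seq, self.CONSENSUS) < 0.2
        pool = graded_pool(self.CONSENSUS) + [ProteinRecord("gated", decoy_seq)]
        ts = build_training_set(pool, self.PATTERN, self.CONSENSUS)
        assert "gated" not in ts.ids

    def test_no_positives_is_error(self):
        pool = graded_pool(self.CONSENSUS)
        never_matches = parse_pattern("W-W-W-W-W-W-W-W-W-W")
        with pytest.raises(ValueError, match="degenerate"):
            build_training_set(pool, never_matches, self.CONSENSUS)


@pytest.fixture(scope="module")
def separable_training_set():
    """Two well-separated synthetic families, features vs. family-1 consensus."""
    a_seed = random_protein(np.random.default_rng(41), 90)
    b_seed = random_protein(np.random.default_rng(42), 90)
    fam_a = generate_family(FamilySpec(a_seed, 30, 0.05, rng_seed=1, name="a"))
    fam_b = generate_family(FamilySpec(b_seed, 30, 0.05, rng_seed=2, name="b"))
    records = fam_a + fam_b
    truth = {r.id: (1 if r.id.startswith("a") else 0) for r in records}
    return training_set_from_labels(records, truth, a_seed,
                                    {0: "other", 1: "family"}), records, a_seed


class TestTrainPredict:
    def test_same_seed_identical_weights(self, separable_training_set):
        ts, _, _ = separable_training_set
        m1 = train_mlp(ts, seed=5)
        m2 = train_mlp(ts, seed=5)
        for w1, w2 in zip(m1.coefs, m2.coefs):
            np.testing.assert_array_equal(w1, w2)
        for b1, b2 in zip(m1.intercepts, m2.intercepts):
            np.testing.assert_array_equal(b1, b2)

    def test_hidden_layer_sizing_rule(self, separable_training_set):
        ts, _, _ = separable_training_set
        model = train_mlp(ts, seed=0)
        assert hidden_layer_size(39, 2) == 20
        assert model.layer_sizes == (39, 20, 1)

    def test_separable_data_trains_to_high_accuracy(self, separable_training_set):
        ts, _, _ = separable_training_set
        model = train_mlp(ts, seed=0)
        acc = (model.predict(ts.matrix) == ts.labels).mean()
        assert acc >= 0.99

    def test_training_positive_represented_scores_high(self, separable_training_set):
        ts, records, consensus = separable_training_set
        model = train_mlp(ts, seed=0)
        member = records[0]
        (pred,) = predict(model, [member], consensus)
        assert pred.status == "classified"
        assert pred.label == 1 and pred.score > 0.5

    def test_gated_record_reported_not_candidate(self, separable_training_set):
        ts, _, consensus = separable_training_set
        model = train_mlp(ts, seed=0)
        junk = ProteinRecord("junk", random_protein(np.random.default_rng(9), 90))
        (pred,) = predict(model, [junk], consensus)
        assert pred.status == "not-candidate"
        assert pred.label is None and pred.score is None

    def test_single_class_input_rejected(self, separable_training_set):
        ts, _, _ = separable_training_set
        bad = training_set_from_labels
        with pytest.raises(ValueError, match="2 classes"):
            train_mlp(
                type(ts)(ts.matrix, np.zeros_like(ts.labels), {0: "x"}), seed=0
            )

    def test_json_roundtrip_preserves_predictions(self, separable_training_set, tmp_path):
        ts, _, _ = separable_training_set
        model = train_mlp(ts, seed=0)
        path = tmp_path / "model.json"
        model.save(path)
        clone = MLPModel.load(path)
        np.testing.assert_allclose(
            clone.predict_proba(ts.matrix), model.predict_proba(ts.matrix)
        )
        assert clone.label_semantics == model.label_semantics


class TestMulticlass:
    def test_six_family_labels_map_to_names(self, nif_benchmark):
        bench = nif_benchmark
        assert sorted(bench.label_semantics) == [0, 1, 2, 3, 4, 5, 6]
        labels = set(bench.truth.values())
        assert labels == {0, 1, 2, 3, 4, 5, 6}


class TestBaselines:
    def test_consensus_itself_positive_under_all_methods(self, binary_pool):
        records, truth, consensus, pattern = binary_pool
        cand = ProteinRecord("exact", consensus)
        res = baseline_classifiers([cand], {"exact": 1}, pattern, consensus)
        for cm in res.values():
            assert (cm.tp, cm.fn) == (1, 0)

    def test_methods_match_hand_rule_application(self, binary_pool):
        records, truth, consensus, pattern = binary_pool
        subset = records[::8][:20]
        res = baseline_classifiers(subset, truth, pattern, consensus)
        # independent rule application, record by record
        expected = {"cutoff_score": [], "conserved_domain": [],
                    "domain_with_cutoff": []}
        t = []
        for rec in subset:
            l = local_align(rec.sequence, consensus)
            score_ok = l.identity > 0.30 and l.positive > 0.50
            dom = has_domain(pattern, rec.sequence)
            expected["cutoff_score"].append(int(score_ok))
            expected["conserved_domain"].append(int(dom))
            expected["domain_with_cutoff"].append(int(score_ok and dom))
            t.append(1 if truth[rec.id] == 1 else 0)
        for name, preds in expected.items():
            assert res[name] == evaluate(preds, t)

    def test_domain_only_method_ignores_score_cutoff(self):
        # a permissive pattern can match where alignment statistics are poor:
        # method 2 calls positive, methods 1 and 3 stay negative (every
        # candidate/consensus residue pair scores negative, so the local
        # alignment is empty)
        consensus = "WWWWWWWWWW"
        pattern = parse_pattern("[GD]-x(2)-[GD]")
        candidate = ProteinRecord("cand", "GDDGDDGDDG")
        l = local_align(candidate.sequence, consensus)
        assert not (l.identity > 0.30 and l.positive > 0.50)  # precondition
        res = baseline_classifiers([candidate], {"cand": 1}, pattern, consensus)
        assert res["conserved_domain"].tp == 1
        assert res["cutoff_score"].tp == 0
        assert res["domain_with_cutoff"].tp == 0
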