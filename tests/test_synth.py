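"""Generator determinism, ground-truth self-consistency, calibration targets."""

import numpy as np
import pytest

from mrim.features import extract_features_frame
from mrim.pipeline import tokenize_corpus
from mrim.svm import cross_validate
from mrim.synth import (
    GeneratorSpec,
    default_paper_profile,
    generate_corpus,
    generate_lexicons,
)


class TestLexiconFixture:
    def test_deterministic_per_seed(self):
        a = generate_lexicons(3)
        b = generate_lexicons(3)
        assert a == b
        assert generate_lexicons(4) != a

    def test_polarity_balance_and_sizes(self, lexicons):
        polarities = list(lexicons.sentiment.emotional_words.values())
        assert polarities.count(1) == polarities.count(-1)
        assert len(polarities) >= 20
        assert len(lexicons.sentiment.degree_adverbs) >= 5
        assert len(lexicons.sentiment.negation_words) >= 3
        assert len(lexicons.tokenizer.stop_words) >= 10
        assert len(lexicons.content_tokens) >= 500
        assert set(lexicons.signal_tokens) <= set(lexicons.content_tokens)

    def test_each_address_suffix_maps_to_one_level(self, lexicons):
        seen = {}
        for lvl, suffixes in lexicons.address.levels.items():
            assert len(suffixes) >= 4
            for s in suffixes:
                assert s not in seen
                seen[s] = lvl

    def test_lexicon_roundtrip_through_files(self, tmp_path, lexicons):
        from mrim.lexicons import load_lexicon_dir, write_lexicon_dir

        write_lexicon_dir(tmp_path, lexicons.sentiment, lexicons.address, lexicons.tokenizer)
        senti, addr, tok = load_lexicon_dir(tmp_path)
        assert senti == lexicons.sentiment
        assert dict(addr.levels) == {k: tuple(v) for k, v in lexicons.address.levels.items()}
        assert tok.dictionary == lexicons.tokenizer.dictionary


class TestGeneratorBasics:
    def test_byte_identical_under_same_seed(self, lexicons):
        spec = GeneratorSpec(n=150, seed=21)
        c1, t1 = generate_corpus(spec, lexicons)
        c2, t2 = generate_corpus(spec, lexicons)
        assert list(c1) == list(c2)
        assert t1.equals(t2)

    def test_useful_fraction_concentrates(self, lexicons):
        _, truth = generate_corpus(GeneratorSpec(n=1000, seed=13), lexicons)
        assert abs(truth["label"].mean() - 1936 / 7979) <= 0.03

    def test_default_profile_is_the_study_shape(self):
        spec = default_paper_profile()
        assert spec.n == 7979
        assert spec.useful_rate == pytest.approx(1936 / 7979)
        assert spec.quadrant_probs == pytest.approx(
            (5461 / 7979, 1202 / 7979, 331 / 7979, 985 / 7979)
        )
        assert spec.malformed_address_rate == 0.40
        assert spec.media_report_rate == 0.50

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError):
            GeneratorSpec(useful_rate=0.0)
        with pytest.raises(ValueError):
            GeneratorSpec(quadrant_probs=(0.5, 0.5, 0.5, 0.5))
        with pytest.raises(ValueError, match="infeasible"):
            # nearly all posts useful but the 'both' stratum too small to
            # absorb the strong-profile tilt
            generate_corpus(
                GeneratorSpec(
                    n=50,
                    useful_rate=0.9,
                    quadrant_probs=(0.1, 0.1, 0.1, 0.7),
                    feature_signal=1.0,
                )
            )


class TestSelfConsistency:
    def test_extraction_recovers_all_plants(self, small_corpus, resources):
        corpus, truth = small_corpus
        feats = extract_features_frame(corpus, resources)
        feats = feats.loc[truth.index]
        assert (feats["word_count"].to_numpy() == truth["word_count"].to_numpy()).all()
        assert np.allclose(feats["sentiment_value"], truth["sentiment_value"])
        assert (feats["has_contact"].to_numpy() == truth["has_contact"].to_numpy()).all()
        assert (
            feats["has_exact_address"].to_numpy()
            == truth["has_detectable_address"].to_numpy()
        ).all()

    def test_malformed_addresses_defeat_detection(self, lexicons, resources):
        # address-only stratum only, to make malformation frequent
        spec = GeneratorSpec(
            n=300,
            seed=17,
            quadrant_probs=(0.0, 0.0, 1.0, 0.0),
            feature_signal=0.0,
            malformed_address_rate=0.5,
        )
        corpus, truth = generate_corpus(spec, lexicons)
        feats = extract_features_frame(corpus, resources).loc[truth.index]
        malformed = truth["address_malformed"].to_numpy()
        assert malformed.any() and (~malformed).any()
        assert (feats.loc[malformed, "has_exact_address"] == 0).all()
        assert (feats.loc[~malformed, "has_exact_address"] == 1).all()


@pytest.fixture(scope="module")
def big(lexicons):
    return generate_corpus(GeneratorSpec(n=6000, seed=23), lexicons)


class TestCalibration:
    def test_quadrant_marginals_match_study_sizes(self, big):
        _, truth = big
        got = truth["quadrant"].value_counts(normalize=True)
        for name, target in zip(
            ("both", "contact_only", "address_only", "neither"),
            (5461 / 7979, 1202 / 7979, 331 / 7979, 985 / 7979),
        ):
            assert got.get(name, 0.0) == pytest.approx(target, abs=0.025)

    def test_nonzero_count_means_hit_targets(self, big):
        corpus, _ = big
        likes = np.array([p.likes for p in corpus], dtype=float)
        prior = np.array([p.prior_posts for p in corpus], dtype=float)
        assert np.mean(likes[likes > 0]) == pytest.approx(196.27, rel=0.15)
        assert np.mean(prior[prior > 0]) == pytest.approx(2299.05, rel=0.15)

    def test_nonzero_sentiment_mean_hits_target(self, big):
        _, truth = big
        nz = truth.loc[truth["sentiment_value"] != 0, "sentiment_value"].abs()
        assert nz.mean() == pytest.approx(5.97, rel=0.15)

    def test_word_count_decile_ladder(self, big):
        """Rank-decile means track the study ladder within +-20%."""
        _, truth = big
        # exclude the injected media reports, which deliberately distort
        # the upper tail (they are the attention-decile contamination)
        wc = np.sort(truth.loc[~truth["is_media_report"], "word_count"].to_numpy())
        ladder = [3.16, 8.38, 13.15, 18.18, 23.94, 30.44, 39.27, 51.07, 69.19, 97.73]
        means = [g.mean() for g in np.array_split(wc, 10)]
        for got, target in zip(means, ladder):
            assert got == pytest.approx(target, rel=0.20)


class TestSignalKnobs:
    def test_no_signal_leaves_svm_at_chance(self, lexicons):
        spec = GeneratorSpec(n=800, seed=31, token_signal=0.0, feature_signal=0.0)
        corpus, _ = generate_corpus(spec, lexicons)
        docs = tokenize_corpus(corpus, lexicons.extraction_resources())
        y = np.array([p.label for p in corpus])
        cv = cross_validate(docs, y, k=5, seed=0)
        r = y.mean()
        q = cv.oof_labels.mean()
        chance_f = 2 * r * q / (r + q) if r + q > 0 else 0.0
        assert abs(cv.f_measure - chance_f) <= 0.1

    def test_token_signal_monotonicity(self, lexicons):
        """More token signal never hurts SVM CV F (averaged over seeds)."""
        mean_f = []
        for strength in (0.0, 0.5, 1.0):
            fs = []
            for seed in (41, 42, 43):
                spec = GeneratorSpec(n=600, seed=seed, token_signal=strength)
                corpus, _ = generate_corpus(spec, lexicons)
                docs = tokenize_corpus(corpus, lexicons.extraction_resources())
                y = [p.label for p in corpus]
                fs.append(cross_validate(docs, y, k=4, seed=0).f_measure)
            mean_f.append(np.mean(fs))
        assert mean_f[0] <= mean_f[1] + 0.05 and mean_f[1] <= mean_f[2] + 0.05

    def test_feature_signal_monotonicity_for_rule_scorer(self, lexicons):
        """More feature signal raises the rule scorer's agreement with labels."""
        from mrim.rules import score_corpus

        mean_f = []
        for strength in (0.0, 1.0):
            fs = []
            for seed in (51, 52, 53):
                spec = GeneratorSpec(n=800, seed=seed, feature_signal=strength)
                corpus, _ = generate_corpus(spec, lexicons)
                feats = extract_features_frame(corpus, lexicons.extraction_resources())
                table = score_corpus(corpus, feats)
                from mrim.evaluate import confusion, precision_recall_f

                gold = [p.label for p in corpus]
                f = precision_recall_f(confusion(gold, table["rule_label"]))[2]
                fs.append(f)
            mean_f.append(np.mean(fs))
        assert mean_f[1] >= mean_f[0] - 0.02
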