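import math

import numpy as np
import pytest

from speechnet.errors import EmptyInputError, InsufficientInputError
from speechnet.features import (coherence_metrics, default_registry,
                                disfluency_ratios, extract_features,
                                mean_length_of_utterance, pos_tag_ratios,
                                syntax_metrics, type_token_ratio)
from speechnet.synthetic import SyntheticSpec, synth_transcript
from speechnet.transcripts import EmbeddingSequence, ParsedTranscript, Sentence, Token

from conftest import flat_sentence


def lemma_transcript(lemmas, upos="NOUN"):
    """One flat sentence per call; token 1 is the root."""
    return ParsedTranscript("s", [flat_sentence(lemmas, upos=upos)])


def tagged_transcript(tags):
    toks = [Token(f"w{i}", f"w{i}", tag, 0 if i == 0 else 1,
                  "root" if i == 0 else "dep")
            for i, tag in enumerate(tags)]
    return ParsedTranscript("s", [Sentence(toks)])


class TestTypeTokenRatio:
    @pytest.mark.parametrize(
        "lemmas, expected",
        [
            (["der", "hund", "der", "ball"], 0.75),
            (["x"] * 10, 0.1),
            (["a", "b", "c", "d", "e"], 1.0),
        ],
    )
    def test_examples(self, lemmas, expected):
        assert type_token_ratio(lemma_transcript(lemmas)) == pytest.approx(expected)

    def test_punctuation_not_counted(self):
        sent = Sentence([
            Token("Hund", "hund", "NOUN", 0, "root"),
            Token(".", ".", "PUNCT", 1, "punct"),
        ])
        assert type_token_ratio(ParsedTranscript("s", [sent])) == 1.0

    def test_case_folded(self):
        assert type_token_ratio(lemma_transcript(["Der", "der"])) == 0.5

    def test_empty_errors(self):
        t = ParsedTranscript("s", [], allow_empty=True)
        with pytest.raises(EmptyInputError):
            type_token_ratio(t)

    def test_type_accumulation_on_prefixes(self, rng):
        # the type count n*TTR(n) is non-decreasing and grows by at most
        # one per appended token; with a finite vocabulary TTR eventually
        # drops below 1
        vocab = [f"w{i}" for i in range(8)]
        words = [vocab[i] for i in rng.integers(0, 8, 60)]
        types = [round(n * type_token_ratio(lemma_transcript(words[:n])))
                 for n in range(1, 61)]
        diffs = np.diff(types)
        assert np.all((diffs == 0) | (diffs == 1))
        assert types[-1] == len(set(words))
        assert type_token_ratio(lemma_transcript(words)) < 1.0


class TestMeanLengthOfUtterance:
    @pytest.mark.parametrize(
        "lengths, expected",
        [([3, 5, 7], 5.0), ([7], 7.0), ([2, 2, 2, 10], 4.0)],
    )
    def test_examples(self, lengths, expected):
        sents = [flat_sentence([f"w{i}{j}" for j in range(n)])
                 for i, n in enumerate(lengths)]
        assert mean_length_of_utterance(ParsedTranscript("s", sents)) == expected


class TestPosTagRatios:
    TAGS = ["NOUN", "NOUN", "VERB", "ADJ", "DET", "PRON", "ADV", "AUX",
            "INTJ", "NOUN"]

    def test_counting_example(self):
        r = pos_tag_ratios(tagged_transcript(self.TAGS))
        assert r["noun_ratio"] == pytest.approx(0.3)
        assert r["verb_ratio"] == pytest.approx(0.1)
        assert r["noun_verb_ratio"] == pytest.approx(3.0)
        assert r["interjection_ratio"] == pytest.approx(0.1)

    def test_open_closed_example(self):
        r = pos_tag_ratios(tagged_transcript(self.TAGS))
        # open: 3 NOUN + VERB + ADJ + ADV = 6; closed: DET + PRON + AUX = 3
        assert r["open_closed_ratio"] == pytest.approx(2.0)

    def test_zero_verbs_gives_missing(self):
        r = pos_tag_ratios(tagged_transcript(["NOUN", "DET"]))
        assert math.isnan(r["noun_verb_ratio"])

    def test_zero_closed_gives_missing(self):
        r = pos_tag_ratios(tagged_transcript(["NOUN", "VERB"]))
        assert math.isnan(r["open_closed_ratio"])

    def test_propn_counts_as_noun_in_nvr(self):
        r = pos_tag_ratios(tagged_transcript(["PROPN", "VERB"]))
        assert r["noun_verb_ratio"] == 1.0


class TestDisfluencyRatios:
    def test_three_pauses_in_twenty(self):
        forms = ["äh"] * 3 + [f"w{i}" for i in range(17)]
        t = ParsedTranscript("s", [flat_sentence(forms)])
        assert disfluency_ratios(t)["filled_pause_ratio"] == pytest.approx(0.15)

    def test_no_matches(self):
        t = lemma_transcript(["wort", "satz"])
        assert disfluency_ratios(t)["filled_pause_ratio"] == 0.0

    def test_case_folded_match(self):
        t = ParsedTranscript("s", [flat_sentence(["Äh", "äh"])])
        assert disfluency_ratios(t, {"äh"})["filled_pause_ratio"] == 1.0


class TestSyntaxMetrics:
    def test_dependency_distance(self):
        sent = Sentence([
            Token("a", "a", "NOUN", 0, "root"),
            Token("b", "b", "NOUN", 1, "dep"),
            Token("c", "c", "NOUN", 1, "dep"),
        ])
        m = syntax_metrics(ParsedTranscript("s", [sent]))
        assert m["mean_dependency_distance"] == pytest.approx(1.5)

    def test_chain_depth(self):
        sent = Sentence([
            Token("a", "a", "NOUN", 0, "root"),
            Token("b", "b", "NOUN", 1, "dep"),
            Token("c", "c", "NOUN", 2, "dep"),
        ])
        m = syntax_metrics(ParsedTranscript("s", [sent]))
        assert m["syntactic_complexity"] == 2.0

    def test_simple_sentence_ratio(self):
        plain = flat_sentence(["a", "b"])
        clausal = Sentence([
            Token("a", "a", "VERB", 0, "root"),
            Token("b", "b", "VERB", 1, "ccomp"),
        ])
        t = ParsedTranscript("s", [plain, plain, plain, clausal])
        assert syntax_metrics(t)["simple_sentence_ratio"] == pytest.approx(0.75)

    def test_clausal_subtype_counts(self):
        sent = Sentence([
            Token("a", "a", "NOUN", 0, "root"),
            Token("b", "b", "VERB", 1, "acl:relcl"),
        ])
        t = ParsedTranscript("s", [sent])
        assert syntax_metrics(t)["simple_sentence_ratio"] == 0.0


class TestCoherenceMetrics:
    def test_identical_vectors(self):
        e = EmbeddingSequence("s", np.tile([1.0, 2.0], (3, 1)))
        m = coherence_metrics(e)
        assert m["coherence_mean"] == pytest.approx(1.0)
        assert m["coherence_min"] == pytest.approx(1.0)

    def test_orthogonal_pair(self):
        e = EmbeddingSequence("s", np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert coherence_metrics(e)["coherence_mean"] == pytest.approx(0.0)

    def test_cos45_path(self):
        r = math.sqrt(2) / 2
        e = EmbeddingSequence("s", np.array([[1, 0], [r, r], [0, 1.0]]))
        m = coherence_metrics(e)
        assert m["coherence_mean"] == pytest.approx(r, abs=1e-9)
        assert m["coherence_sd"] == pytest.approx(0.0, abs=1e-9)

    def test_single_vector_errors(self):
        with pytest.raises(InsufficientInputError):
            coherence_metrics(EmbeddingSequence("s", np.ones((1, 3))))

    def test_bounds(self, rng):
        e = EmbeddingSequence("s", rng.standard_normal((20, 5)))
        m = coherence_metrics(e)
        assert -1.0 <= m["coherence_min"] <= m["coherence_mean"] <= 1.0


class TestDuplicationInvariance:
    """Concatenating a transcript with itself changes only TTR."""

    def test_ratios_exactly_unchanged(self):
        spec = SyntheticSpec(n_utterances=15, seed=7, filled_pause_rate=0.08)
        t, emb, _ = synth_transcript(spec)
        doubled = ParsedTranscript(t.subject_id, t.sentences + t.sentences)
        for fn in (pos_tag_ratios, syntax_metrics, disfluency_ratios):
            assert fn(doubled) == fn(t)
        assert mean_length_of_utterance(doubled) == mean_length_of_utterance(t)
        assert type_token_ratio(doubled) <= type_token_ratio(t)


class TestExtractFeatures:
    def test_shape_and_order(self):
        reg = default_registry()
        t1, e1, _ = synth_transcript(SyntheticSpec(n_utterances=5, seed=1))
        t2, e2, _ = synth_transcript(SyntheticSpec(n_utterances=5, seed=2))
        fm = extract_features([t1, t2], reg,
                              {t1.subject_id: e1, t2.subject_id: e2})
        assert fm.values.shape == (2, len(reg))
        assert list(fm.values.columns) == reg.names
        assert all(d == "linguistic" for d in fm.domains.values())

    def test_missing_embeddings_marked(self):
        t1, _, _ = synth_transcript(SyntheticSpec(n_utterances=5, seed=1))
        fm = extract_features([t1])
        assert fm.values.loc[t1.subject_id, "coherence_mean"] != fm.values.loc[
            t1.subject_id, "coherence_mean"]  # NaN
        assert not math.isnan(fm.values.loc[t1.subject_id, "type_token_ratio"])
        assert fm.missing_counts["coherence_mean"] == 1

    def test_duplicate_subject_ids_rejected(self):
        t1, _, _ = synth_transcript(SyntheticSpec(n_utterances=5, seed=1))
        with pytest.raises(Exception, match="duplicate"):
            extract_features([t1, t1])

    def test_planted_pause_rate_recovered(self):
        spec = SyntheticSpec(n_utterances=250, utterance_length_mean=8.2,
                             filled_pause_rate=0.10, seed=42)
        t, _, truth = synth_transcript(spec)
        assert truth["n_tokens"] >= 2000
        fm = extract_features([t])
        got = fm.values.loc[t.subject_id, "filled_pause_ratio"]
        assert got == pytest.approx(0.10, abs=0.02)

    def test_deterministic(self, two_sentence_conllu):
        from speechnet.transcripts import parse_transcript

        t = parse_transcript(two_sentence_conllu, "s1")
        fm1 = extract_features([t])
        fm2 = extract_features([t])
        assert fm1.values.equals(fm2.values)
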