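"""Linguistic feature extraction from dependency-parsed speech.

Features span four linguistic levels commonly profiled in clinical speech:
lexical diversity (type-token ratio), productivity (mean length of
utterance), morphosyntactic distribution (POS ratios, open/closed ratio),
syntax (dependency distance, parse depth, simple-sentence ratio),
disfluency (filled pauses), and semantic coherence (consecutive-sentence
embedding cosine).

Counting conventions: a *countable* token is any token whose universal POS
tag is not PUNCT, SYM, or X; punctuation never contributes to ratios or
utterance lengths. Lexical types are case-folded lemmas, falling back to
the surface form when the lemma column is unannotated ("_").
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .errors import EmptyInputError, InsufficientInputError, SpeechNetError
from .transcripts import EmbeddingSequence, ParsedTranscript, Token

logger = logging.getLogger(__name__)

__all__ = [
    "MISSING",
    "NON_COUNTABLE_UPOS",
    "OPEN_CLASS",
    "CLOSED_CLASS",
    "CLAUSAL_DEPRELS",
    "DEFAULT_FILLED_PAUSES",
    "type_token_ratio",
    "mean_length_of_utterance",
    "pos_tag_ratios",
    "disfluency_ratios",
    "syntax_metrics",
    "coherence_metrics",
    "FeatureRegistry",
    "default_registry",
    "FeatureMatrix",
    "extract_features",
]

#: Missing-value marker used throughout the feature matrix.
MISSING = float("nan")

NON_COUNTABLE_UPOS = frozenset({"PUNCT", "SYM", "X"})
OPEN_CLASS = frozenset({"NOUN", "PROPN", "VERB", "ADJ", "ADV"})
CLOSED_CLASS = frozenset({"DET", "PRON", "AUX", "ADP", "CCONJ", "SCONJ", "NUM", "PART"})
#: Dependency relations marking clausal embedding (a non-simple sentence).
CLAUSAL_DEPRELS = frozenset({"csubj", "ccomp", "xcomp", "advcl", "acl", "parataxis"})
#: German filled-pause (hesitation) lexicon; case-folded surface match.
DEFAULT_FILLED_PAUSES = frozenset({"äh", "ähm", "öh", "öhm", "hm", "mh", "mhm"})


def _countable(tok: Token) -> bool:
    return tok.upos not in NON_COUNTABLE_UPOS


def _countable_tokens(t: ParsedTranscript) -> list[Token]:
    return [tok for sent in t.sentences for tok in sent.tokens if _countable(tok)]


def _lexical_type(tok: Token) -> str:
    base = tok.lemma if tok.lemma and tok.lemma != "_" else tok.form
    return base.casefold()


def type_token_ratio(t: ParsedTranscript) -> float:
    """Distinct case-folded lemmas over countable tokens (plain TTR)."""
    toks = _countable_tokens(t)
    if not toks:
        raise EmptyInputError("type_token_ratio: no countable tokens")
    return len({_lexical_type(tok) for tok in toks}) / len(toks)


def mean_length_of_utterance(t: ParsedTranscript) -> float:
    """Mean countable-token count per utterance."""
    utts = t.utterances()
    if not utts:
        raise EmptyInputError("mean_length_of_utterance: no utterances")
    return float(np.mean([sum(1 for tok in u if _countable(tok)) for u in utts]))


_SIMPLE_RATIO_TAGS = {
    "noun_ratio": ("NOUN",),
    "verb_ratio": ("VERB",),
    "adjective_ratio": ("ADJ",),
    "adverb_ratio": ("ADV",),
    "pronoun_ratio": ("PRON",),
    "auxiliary_ratio": ("AUX",),
    "interjection_ratio": ("INTJ",),
}


def pos_tag_ratios(t: ParsedTranscript) -> dict[str, float]:
    """Per-tag proportions plus noun/verb and open/closed class ratios.

    ``noun_verb_ratio`` counts NOUN and PROPN in the numerator; a transcript
    with no verbs yields the missing marker (not 0). Similarly
    ``open_closed_ratio`` is missing when no closed-class token occurs.
    """
    toks = _countable_tokens(t)
    if not toks:
        raise EmptyInputError("pos_tag_ratios: no countable tokens")
    n = len(toks)
    counts: dict[str, int] = {}
    for tok in toks:
        counts[tok.upos] = counts.get(tok.upos, 0) + 1

    out = {
        name: sum(counts.get(tag, 0) for tag in tags) / n
        for name, tags in _SIMPLE_RATIO_TAGS.items()
    }
    n_noun = counts.get("NOUN", 0) + counts.get("PROPN", 0)
    n_verb = counts.get("VERB", 0)
    out["noun_verb_ratio"] = n_noun / n_verb if n_verb else MISSING
    n_open = sum(counts.get(tag, 0) for tag in OPEN_CLASS)
    n_closed = sum(counts.get(tag, 0) for tag in CLOSED_CLASS)
    out["open_closed_ratio"] = n_open / n_closed if n_closed else MISSING
    return out


def disfluency_ratios(
    t: ParsedTranscript,
    filled_pause_lexicon: frozenset[str] | set[str] = DEFAULT_FILLED_PAUSES,
) -> dict[str, float]:
    """Filled-pause proportion by case-folded lexical match.

    Kept distinct from the interjection ratio: a filled pause is matched
    lexically against the hesitation lexicon, an interjection by POS tag.
    """
    if not filled_pause_lexicon:
        raise SpeechNetError("disfluency_ratios: filled-pause lexicon is empty")
    lexicon = {w.casefold() for w in filled_pause_lexicon}
    toks = _countable_tokens(t)
    if not toks:
        raise EmptyInputError("disfluency_ratios: no countable tokens")
    n_fp = sum(1 for tok in toks if tok.form.casefold() in lexicon)
    return {"filled_pause_ratio": n_fp / len(toks)}


def _sentence_depth(tokens: list[Token]) -> int:
    """Maximum root-to-leaf depth of one dependency tree (root depth 0)."""
    depths = [0] * len(tokens)

    def depth(i: int) -> int:  # i is 0-based
        if tokens[i].head == 0:
            return 0
        if depths[i]:
            return depths[i]
        depths[i] = 1 + depth(tokens[i].head - 1)
        return depths[i]

    return max(depth(i) for i in range(len(tokens))) if tokens else 0


def syntax_metrics(t: ParsedTranscript) -> dict[str, float]:
    """Dependency distance, parse depth, and simple-sentence proportion.

    - ``mean_dependency_distance``: mean |position - head position| over
      all non-root tokens (positions are 1-based within the sentence).
    - ``syntactic_complexity``: mean over sentences of the maximum
      root-to-leaf depth of the dependency tree.
    - ``simple_sentence_ratio``: fraction of sentences with no clausal
      dependency relation (see :data:`CLAUSAL_DEPRELS`; subtype suffixes
      such as ``acl:relcl`` count as their base relation).
    """
    if not t.sentences:
        raise EmptyInputError("syntax_metrics: no sentences")
    distances: list[int] = []
    depths: list[int] = []
    n_simple = 0
    for sent in t.sentences:
        for pos, tok in enumerate(sent.tokens, start=1):
            if tok.head != 0:
                distances.append(abs(pos - tok.head))
        depths.append(_sentence_depth(sent.tokens))
        has_clausal = any(
            tok.deprel.split(":")[0] in CLAUSAL_DEPRELS for tok in sent.tokens
        )
        if not has_clausal:
            n_simple += 1
    return {
        "mean_dependency_distance": float(np.mean(distances)) if distances else 0.0,
        "syntactic_complexity": float(np.mean(depths)),
        "simple_sentence_ratio": n_simple / len(t.sentences),
    }


def coherence_metrics(e: EmbeddingSequence) -> dict[str, float]:
    """Cosine similarity of consecutive sentence embeddings.

    Reports mean, sample standard deviation (ddof=1; zero when only one
    pair exists), and minimum over the consecutive-pair cosines.
    """
    if len(e) < 2:
        raise InsufficientInputError(
            "coherence_metrics: need at least 2 sentence vectors"
        )
    v = e.vectors
    norms = np.linalg.norm(v, axis=1)
    cos = np.sum(v[:-1] * v[1:], axis=1) / (norms[:-1] * norms[1:])
    cos = np.clip(cos, -1.0, 1.0)
    sd = float(np.std(cos, ddof=1)) if len(cos) > 1 else 0.0
    return {
        "coherence_mean": float(np.mean(cos)),
        "coherence_sd": sd,
        "coherence_min": float(np.min(cos)),
    }


# ---------------------------------------------------------------------------
# registry and matrix assembly
# ---------------------------------------------------------------------------

ExtractorFn = Callable[[ParsedTranscript, EmbeddingSequence | None], float]


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    extractor: ExtractorFn
    requires_embeddings: bool = False
    domain: str = "linguistic"


@dataclass
class FeatureRegistry:
    """Ordered collection of named linguistic feature extractors.

    Registry order fixes feature-matrix column order. Additional features
    (e.g. further lexicon- or embedding-based measures) are added with
    :meth:`register`; the pipeline is generic in the number of features.
    """

    specs: list[FeatureSpec] = field(default_factory=list)

    def register(self, spec: FeatureSpec) -> None:
        if spec.name in self.names:
            raise SpeechNetError(f"duplicate feature name {spec.name!r}")
        self.specs.append(spec)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def __len__(self) -> int:
        return len(self.specs)


def _scalar(fn: Callable[[ParsedTranscript], float]) -> ExtractorFn:
    return lambda t, e: fn(t)


def _from_map(fn: Callable[[ParsedTranscript], dict[str, float]], key: str) -> ExtractorFn:
    return lambda t, e: fn(t)[key]


def _coherence(key: str) -> ExtractorFn:
    def ex(t: ParsedTranscript, e: EmbeddingSequence | None) -> float:
        if e is None:
            return MISSING
        return coherence_metrics(e)[key]

    return ex


def default_registry(
    filled_pause_lexicon: frozenset[str] = DEFAULT_FILLED_PAUSES,
) -> FeatureRegistry:
    """The stock linguistic feature set (lexical, syntactic, disfluency,
    coherence levels)."""
    reg = FeatureRegistry()
    reg.register(FeatureSpec("type_token_ratio", _scalar(type_token_ratio)))
    reg.register(FeatureSpec("mean_length_of_utterance",
                             _scalar(mean_length_of_utterance)))
    for key in _SIMPLE_RATIO_TAGS:
        reg.register(FeatureSpec(key, _from_map(pos_tag_ratios, key)))
    reg.register(FeatureSpec("noun_verb_ratio",
                             _from_map(pos_tag_ratios, "noun_verb_ratio")))
    reg.register(FeatureSpec("open_closed_ratio",
                             _from_map(pos_tag_ratios, "open_closed_ratio")))
    reg.register(
        FeatureSpec(
            "filled_pause_ratio",
            lambda t, e: disfluency_ratios(t, filled_pause_lexicon)[
                "filled_pause_ratio"
            ],
        )
    )
    for key in ("mean_dependency_distance", "syntactic_complexity",
                "simple_sentence_ratio"):
        reg.register(FeatureSpec(key, _from_map(syntax_metrics, key)))
    for key in ("coherence_mean", "coherence_sd", "coherence_min"):
        reg.register(FeatureSpec(key, _coherence(key), requires_embeddings=True))
    return reg


DOMAINS = ("linguistic", "psychopathological", "cognitive")


@dataclass
class FeatureMatrix:
    """Subjects x named variables, with a domain label per column.

    ``values`` is a DataFrame indexed by subject id; missing cells carry
    NaN as the explicit missing marker (tracked in ``missing_counts``).
    ``groups``, when present, maps each subject to HC/MDD/BD/SSD.
    """

    values: pd.DataFrame
    domains: dict[str, str]
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        for col in self.values.columns:
            if col not in self.domains:
                raise SpeechNetError(f"column {col!r} has no domain label")
            if self.domains[col] not in DOMAINS:
                raise SpeechNetError(
                    f"column {col!r} has unknown domain {self.domains[col]!r}"
                )
        if self.groups is not None:
            self.groups = self.groups.reindex(self.values.index)

    @property
    def missing_counts(self) -> dict[str, int]:
        return {c: int(self.values[c].isna().sum()) for c in self.values.columns}

    def domain_counts(self) -> dict[str, int]:
        out = {d: 0 for d in DOMAINS}
        for col in self.values.columns:
            out[self.domains[col]] += 1
        return out

    def select(self, subjects=None, exclude_domains: tuple[str, ...] = ()) -> "FeatureMatrix":
        vals = self.values if subjects is None else self.values.loc[subjects]
        cols = [c for c in vals.columns if self.domains[c] not in exclude_domains]
        grp = None if self.groups is None else self.groups.reindex(vals.index)
        return FeatureMatrix(vals[cols].copy(),
                             {c: self.domains[c] for c in cols}, grp)

    def to_csv(self, path: str | os.PathLike) -> None:
        """Write values as CSV plus a sidecar JSON of domains and missingness."""
        df = self.values.copy()
        if self.groups is not None:
            df.insert(0, "group", self.groups)
        df.to_csv(path, index_label="subject_id")
        sidecar = {
            "domains": self.domains,
            "missing_counts": self.missing_counts,
        }
        with open(str(path) + ".meta.json", "w", encoding="utf-8") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def from_csv(cls, path: str | os.PathLike,
                 domains: dict[str, str] | None = None) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="subject_id")
        groups = None
        if "group" in df.columns:
            groups = df.pop("group")
        if domains is None:
            meta_path = str(path) + ".meta.json"
            with open(meta_path, encoding="utf-8") as fh:
                domains = json.load(fh)["domains"]
        return cls(df, domains, groups)


def extract_features(
    corpus: list[ParsedTranscript],
    registry: FeatureRegistry | None = None,
    embeddings: dict[str, EmbeddingSequence] | None = None,
) -> FeatureMatrix:
    """Apply every registered extractor to every subject.

    An extractor failure on one subject yields the missing marker for that
    cell (with a logged warning); it never aborts the whole corpus.
    """
    if registry is None:
        registry = default_registry()
    embeddings = embeddings or {}
    ids = [t.subject_id for t in corpus]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise SpeechNetError(f"duplicate subject ids: {dup}")

    rows = np.full((len(corpus), len(registry)), MISSING)
    for r, t in enumerate(corpus):
        emb = embeddings.get(t.subject_id)
        for c, spec in enumerate(registry.specs):
            if spec.requires_embeddings and emb is None:
                continue  # stays missing
            try:
                rows[r, c] = spec.extractor(t, emb)
            except SpeechNetError as exc:
                logger.warning(
                    "feature %s failed for subject %s: %s",
                    spec.name, t.subject_id, exc,
                )
    df = pd.DataFrame(rows, index=pd.Index(ids, name="subject_id"),
                      columns=registry.names)
    return FeatureMatrix(df, {s.name: s.domain for s in registry.specs})
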