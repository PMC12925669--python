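"""Dependency-parsed transcript containers and CoNLL-U input/output.

A transcript is one subject's utterance-segmented, POS-tagged,
dependency-parsed token stream, typically the concatenation of several
picture narrations. Only the columns the downstream linguistic features
need are retained: surface form, lemma, universal POS tag, head index,
and dependency relation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    ConlluParseError,
    EmptyInputError,
    TranscriptValidationError,
)

__all__ = [
    "Token",
    "Sentence",
    "ParsedTranscript",
    "EmbeddingSequence",
    "parse_transcript",
    "to_conllu",
    "read_conllu_dir",
    "read_embeddings_tsv",
]


@dataclass(frozen=True)
class Token:
    form: str
    lemma: str
    upos: str
    head: int  # 0 = sentence root, else 1-based index within the sentence
    deprel: str


@dataclass
class Sentence:
    tokens: list[Token]
    sent_id: str | None = None

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class ParsedTranscript:
    """One subject's parsed speech.

    ``utterance_ids[i]`` gives the utterance index of sentence ``i``; by
    default every sentence is its own utterance. Empty transcripts must be
    requested explicitly (``allow_empty=True``) and are rejected by every
    feature operation.
    """

    subject_id: str
    sentences: list[Sentence]
    utterance_ids: list[int] = field(default_factory=list)
    allow_empty: bool = False

    def __post_init__(self) -> None:
        if not self.sentences and not self.allow_empty:
            raise EmptyInputError(
                f"transcript {self.subject_id!r} has no sentences"
            )
        if not self.utterance_ids:
            self.utterance_ids = list(range(len(self.sentences)))
        if len(self.utterance_ids) != len(self.sentences):
            raise TranscriptValidationError(
                "utterance_ids length does not match sentence count"
            )
        for s_idx, sent in enumerate(self.sentences):
            _validate_sentence(sent, s_idx)

    @property
    def n_utterances(self) -> int:
        return len(set(self.utterance_ids))

    def utterances(self) -> list[list[Token]]:
        """Sentences grouped into utterances, preserving order."""
        groups: dict[int, list[Token]] = {}
        for uid, sent in zip(self.utterance_ids, self.sentences):
            groups.setdefault(uid, []).extend(sent.tokens)
        return [groups[k] for k in sorted(groups)]


def _validate_sentence(sent: Sentence, s_idx: int) -> None:
    n = len(sent.tokens)
    roots = [i for i, t in enumerate(sent.tokens) if t.head == 0]
    for i, tok in enumerate(sent.tokens):
        if tok.head < 0 or tok.head > n:
            raise TranscriptValidationError(
                f"sentence {s_idx}: token {i + 1} head {tok.head} out of range 1..{n}"
            )
        if tok.head == i + 1:
            raise TranscriptValidationError(
                f"sentence {s_idx}: token {i + 1} is its own head"
            )
    if len(roots) != 1:
        raise TranscriptValidationError(
            f"sentence {s_idx}: expected exactly one root token, found {len(roots)}"
        )
    # cycle check: follow head pointers from every token; must reach the root
    for start in range(n):
        seen = set()
        cur = start + 1
        while cur != 0:
            if cur in seen:
                raise TranscriptValidationError(
                    f"sentence {s_idx}: head cycle involving token {cur}"
                )
            seen.add(cur)
            cur = sent.tokens[cur - 1].head


@dataclass
class EmbeddingSequence:
    """Per-sentence dense embedding vectors for one subject."""

    subject_id: str
    vectors: np.ndarray  # (n_sentences, dim)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[1] < 1:
            raise TranscriptValidationError(
                "embedding vectors must form a 2-D array with dimension >= 1"
            )
        norms = np.linalg.norm(self.vectors, axis=1)
        if np.any(norms == 0):
            bad = int(np.flatnonzero(norms == 0)[0])
            raise TranscriptValidationError(
                f"embedding vector {bad} is the zero vector (cosine undefined)"
            )

    def __len__(self) -> int:
        return self.vectors.shape[0]


_N_COLUMNS = 10


def parse_transcript(conllu_text: str, subject_id: str = "") -> ParsedTranscript:
    """Parse a CoNLL-U document into a validated :class:`ParsedTranscript`.

    Honors ``# sent_id``, ``# newdoc`` and ``# newutt`` comments; ``# newutt``
    starts a new utterance group (default: one utterance per sentence).
    Multiword-token ranges (``3-4``) and empty nodes (``3.1``) are skipped in
    favor of their component rows.
    """
    sentences: list[Sentence] = []
    utterance_ids: list[int] = []
    explicit_utts = "# newutt" in conllu_text
    utt_counter = -1

    cur_tokens: list[Token] = []
    cur_sent_id: str | None = None
    saw_newutt = False

    def flush() -> None:
        nonlocal cur_tokens, cur_sent_id, utt_counter, saw_newutt
        if cur_tokens:
            if explicit_utts:
                if saw_newutt or utt_counter < 0:
                    utt_counter += 1
            else:
                utt_counter += 1
            sentences.append(Sentence(cur_tokens, cur_sent_id))
            utterance_ids.append(utt_counter)
        cur_tokens = []
        cur_sent_id = None
        saw_newutt = False

    for lineno, raw in enumerate(conllu_text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            flush()
            continue
        if line.startswith("#"):
            comment = line[1:].strip()
            if comment.startswith("sent_id"):
                cur_sent_id = comment.split("=", 1)[-1].strip()
            elif comment.startswith("newutt"):
                saw_newutt = True
            # `# newdoc` and other comments carry no token content
            continue
        cols = line.split("\t")
        if len(cols) != _N_COLUMNS:
            raise ConlluParseError(
                f"expected {_N_COLUMNS} tab-separated columns, found {len(cols)}",
                line=lineno,
            )
        tok_id = cols[0]
        if "-" in tok_id or "." in tok_id:
            continue  # multiword range or empty node: component rows follow
        try:
            int(tok_id)
        except ValueError:
            raise ConlluParseError(f"non-integer token id {tok_id!r}", line=lineno)
        try:
            head = int(cols[6])
        except ValueError:
            raise ConlluParseError(f"non-integer head {cols[6]!r}", line=lineno)
        cur_tokens.append(
            Token(form=cols[1], lemma=cols[2], upos=cols[3], head=head, deprel=cols[7])
        )
    flush()

    return ParsedTranscript(subject_id=subject_id, sentences=sentences,
                            utterance_ids=utterance_ids)


def to_conllu(t: ParsedTranscript) -> str:
    """Serialize a transcript back to 10-column CoNLL-U text."""
    out: list[str] = [f"# newdoc id = {t.subject_id}"]
    prev_utt: int | None = None
    for sent, uid in zip(t.sentences, t.utterance_ids):
        if uid != prev_utt:
            out.append("# newutt")
            prev_utt = uid
        if sent.sent_id is not None:
            out.append(f"# sent_id = {sent.sent_id}")
        for i, tok in enumerate(sent.tokens, start=1):
            out.append(
                "\t".join(
                    [str(i), tok.form, tok.lemma, tok.upos, "_", "_",
                     str(tok.head), tok.deprel, "_", "_"]
                )
            )
        out.append("")
    return "\n".join(out) + "\n"


def read_conllu_dir(directory: str | os.PathLike) -> list[ParsedTranscript]:
    """Read every ``*.conllu`` file in a directory; file stem = subject id."""
    directory = Path(directory)
    out = []
    for path in sorted(directory.glob("*.conllu")):
        out.append(parse_transcript(path.read_text(encoding="utf-8"),
                                    subject_id=path.stem))
    if not out:
        raise EmptyInputError(f"no .conllu files under {directory}")
    return out


def read_embeddings_tsv(path: str | os.PathLike) -> dict[str, EmbeddingSequence]:
    """Read sentence embeddings from TSV columns subject_id, sentence_index, v1..vd."""
    rows: dict[str, list[tuple[int, np.ndarray]]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["subject_id", "sentence_index"]:
            raise ConlluParseError(
                "embeddings TSV must start with columns subject_id, sentence_index",
                line=1,
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ConlluParseError(
                    f"expected {len(header)} columns, found {len(parts)}", line=lineno
                )
            sid, idx = parts[0], int(parts[1])
            vec = np.array([float(x) for x in parts[2:]], dtype=float)
            rows.setdefault(sid, []).append((idx, vec))
    out = {}
    for sid, pairs in rows.items():
        pairs.sort(key=lambda p: p[0])
        out[sid] = EmbeddingSequence(sid, np.vstack([v for _, v in pairs]))
    return out
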