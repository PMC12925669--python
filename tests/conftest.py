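import numpy as np
import pytest

from speechnet.transcripts import ParsedTranscript, Sentence, Token


def make_sentence(specs, sent_id=None):
    """Build a Sentence from (form, lemma, upos, head, deprel) tuples."""
    return Sentence([Token(*s) for s in specs], sent_id=sent_id)


def simple_token(form, upos="NOUN", head=0, deprel="root", lemma=None):
    return Token(form, lemma if lemma is not None else form, upos, head, deprel)


def flat_sentence(forms, upos="NOUN"):
    """A sentence where token 1 is the root and the rest attach to it."""
    toks = [Token(forms[0], forms[0], upos, 0, "root")]
    toks += [Token(f, f, upos, 1, "dep") for f in forms[1:]]
    return Sentence(toks)


@pytest.fixture
def transcript_factory():
    def make(sentences, subject_id="s1", **kw):
        return ParsedTranscript(subject_id=subject_id, sentences=sentences, **kw)

    return make


@pytest.fixture
def two_sentence_conllu():
    return """\
# newdoc id = subj1
# sent_id = 1
1\tDer\tder\tDET\t_\t_\t2\tdet\t_\t_
2\tHund\thund\tNOUN\t_\t_\t3\tnsubj\t_\t_
3\tbellt\tbellen\tVERB\t_\t_\t0\troot\t_\t_
4\t.\t.\tPUNCT\t_\t_\t3\tpunct\t_\t_

# sent_id = 2
1\tEr\ter\tPRON\t_\t_\t2\tnsubj\t_\t_
2\tschläft\tschlafen\tVERB\t_\t_\t0\troot\t_\t_
"""


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
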