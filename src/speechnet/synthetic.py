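"""Ground-truth generators for every pipeline input.

Two families:

1. Gaussian feature data with a *planted* sparse precision matrix (chain,
   hub, or random structure), so that edge-recovery, bootstrap, and
   network-comparison behaviour can be checked against a known truth.
   The default scale mirrors a typical clinical speech study: 44
   variables (28 linguistic, 10 psychopathological, 6 cognitive) over
   372 subjects in four groups (178 HC, 119 MDD, 27 BD, 48 SSD).

2. Synthetic parsed transcripts: Zipfian vocabulary partitioned by POS
   category, Poisson utterance lengths, i.i.d. filled-pause insertion,
   sequential-attachment dependency trees (acyclic, single root), and
   sentence embeddings rotating by a fixed drift angle so the expected
   consecutive-sentence coherence is exactly cos(angle).

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SpeechNetError
from .features import FeatureMatrix
from .ggm import precision_to_partial
from .transcripts import EmbeddingSequence, ParsedTranscript, Sentence, Token

__all__ = [
    "SyntheticSpec",
    "planted_precision",
    "sample_mvn_from_precision",
    "two_group_design",
    "synth_transcript",
    "study_shape_features",
    "STUDY_SHAPE_GROUPS",
    "STUDY_SHAPE_DOMAINS",
]

#: group sizes of the default study-scale preset
STUDY_SHAPE_GROUPS = {"HC": 178, "MDD": 119, "BD": 27, "SSD": 48}
#: variable counts per domain of the default study-scale preset
STUDY_SHAPE_DOMAINS = {"linguistic": 28, "psychopathological": 10, "cognitive": 6}

#: default POS category probabilities for synthetic German-like speech
DEFAULT_POS_PROBS = {
    "NOUN": 0.20, "VERB": 0.14, "DET": 0.12, "PRON": 0.11, "ADP": 0.09,
    "ADV": 0.08, "ADJ": 0.07, "AUX": 0.06, "CCONJ": 0.04, "SCONJ": 0.03,
    "PART": 0.03, "NUM": 0.02, "INTJ": 0.01,
}


@dataclass
class SyntheticSpec:
    """Parameters of the planted-truth generator."""

    p: int = 10
    structure: str = "chain"  # chain | hub | random
    rho: float = 0.3
    n: int = 2000
    edge_perturbation: tuple[int, float] | None = None  # (edge index, delta)
    # transcript parameters
    n_utterances: int = 40
    utterance_length_mean: float = 9.0  # Poisson mean (plus 1 to keep >= 1)
    vocabulary_size: int = 500
    zipf_exponent: float = 1.1
    pos_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_POS_PROBS))
    filled_pause_rate: float = 0.05
    embedding_dim: int = 16
    embedding_drift_deg: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.pos_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise SpeechNetError(f"POS probabilities sum to {total}, not 1")
        if not 0 <= self.filled_pause_rate < 1:
            raise SpeechNetError("filled_pause_rate must be in [0, 1)")
        if self.vocabulary_size < 1:
            raise SpeechNetError("vocabulary_size must be >= 1")


def planted_precision(
    p: int,
    structure: str = "chain",
    rho: float = 0.3,
    seed: int | None = None,
    edge_prob: float = 0.15,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Unit-diagonal sparse precision matrix with a known edge set.

    chain: theta_{i,i+1} = -rho, so adjacent partial correlations equal
    rho exactly (positive definite for |rho| < 0.5).
    hub: node 0 tied to all others with partial correlation rho
    (requires rho^2 (p-1) < 1).
    random: Erdos-Renyi edges of magnitude rho and random sign, repaired
    to positive definiteness by diagonal inflation when necessary (the
    repair shrinks the realized partial correlations; the edge set stays
    exact).
    """
    if p < 2:
        raise SpeechNetError("p must be >= 2")
    Theta = np.eye(p)
    edges: list[tuple[int, int]] = []
    if structure == "chain":
        if abs(rho) >= 0.5:
            raise SpeechNetError("chain structure requires |rho| < 0.5")
        for i in range(p - 1):
            Theta[i, i + 1] = Theta[i + 1, i] = -rho
            edges.append((i, i + 1))
    elif structure == "hub":
        if rho**2 * (p - 1) >= 1:
            raise SpeechNetError("hub structure requires rho^2 (p-1) < 1")
        for j in range(1, p):
            Theta[0, j] = Theta[j, 0] = -rho
            edges.append((0, j))
    elif structure == "random":
        rng = np.random.default_rng(seed)
        for i in range(p):
            for j in range(i + 1, p):
                if rng.random() < edge_prob:
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    Theta[i, j] = Theta[j, i] = -sign * rho
                    edges.append((i, j))
        min_eig = float(np.linalg.eigvalsh(Theta).min())
        if min_eig <= 1e-6:
            Theta += (abs(min_eig) + 0.05) * np.eye(p)
            d = np.sqrt(np.diag(Theta))
            Theta = Theta / np.outer(d, d)
    else:
        raise SpeechNetError(f"unknown structure {structure!r}")
    min_eig = float(np.linalg.eigvalsh(Theta).min())
    if min_eig <= 0:
        raise SpeechNetError(
            f"planted precision not positive definite (min eig {min_eig:.3e})"
        )
    return Theta, edges


def sample_mvn_from_precision(
    Theta: np.ndarray, n: int, seed: int | None = None
) -> np.ndarray:
    """n i.i.d. draws from N(0, Theta^{-1})."""
    Theta = np.asarray(Theta, dtype=float)
    try:
        np.linalg.cholesky(Theta)
    except np.linalg.LinAlgError as exc:
        raise SpeechNetError("precision matrix must be positive definite") from exc
    Sigma = np.linalg.inv(Theta)
    L = np.linalg.cholesky(Sigma)
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n, Theta.shape[0])) @ L.T


def two_group_design(
    spec: SyntheticSpec,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Group A from the base precision; group B with one edge perturbed.

    ``spec.edge_perturbation = (k, delta)`` shifts the k-th planted edge's
    precision entry by delta for group B (delta = 0, or no perturbation,
    gives the exact two-sample null). The truth record carries the
    perturbed edge and the implied partial-correlation difference.
    """
    Theta_a, edges = planted_precision(spec.p, spec.structure, spec.rho,
                                       seed=spec.seed)
    Theta_b = Theta_a.copy()
    truth: dict = {"edges": edges, "perturbed_edge": None,
                   "partial_diff": 0.0}
    if spec.edge_perturbation is not None:
        k, delta = spec.edge_perturbation
        if not 0 <= k < len(edges):
            raise SpeechNetError(f"edge index {k} out of range")
        i, j = edges[k]
        Theta_b[i, j] += delta
        Theta_b[j, i] += delta
        min_eig = float(np.linalg.eigvalsh(Theta_b).min())
        if min_eig <= 0:
            raise SpeechNetError(
                f"perturbation delta={delta} destroys positive definiteness"
            )
        rho_a = precision_to_partial(Theta_a)[i, j]
        rho_b = precision_to_partial(Theta_b)[i, j]
        truth["perturbed_edge"] = (i, j)
        truth["partial_diff"] = float(rho_b - rho_a)
    X_a = sample_mvn_from_precision(Theta_a, spec.n, seed=spec.seed)
    X_b = sample_mvn_from_precision(Theta_b, spec.n, seed=spec.seed + 1)
    return X_a, X_b, truth


# ---------------------------------------------------------------------------
# synthetic transcripts
# ---------------------------------------------------------------------------

_PAUSE_FORMS = ["äh", "ähm", "hm"]


def _zipf_probs(k: int, a: float) -> np.ndarray:
    w = 1.0 / np.arange(1, k + 1) ** a
    return w / w.sum()


def synth_transcript(
    spec: SyntheticSpec,
) -> tuple[ParsedTranscript, EmbeddingSequence, dict]:
    """Generate one subject's synthetic parsed transcript and embeddings.

    Token model: each position is a filled pause with probability
    ``filled_pause_rate`` (tagged INTJ, surface from the pause lexicon);
    otherwise a POS category is drawn from ``pos_probs`` and a word from
    that category's Zipf-distributed sub-vocabulary. Heads use sequential
    attachment (token 1 is the root; each later token attaches uniformly
    to an earlier token), guaranteeing acyclicity and a single root.
    Embeddings rotate by the drift angle per sentence step within a fixed
    plane, so every consecutive cosine equals cos(drift angle).
    """
    rng = np.random.default_rng(spec.seed)
    pos_names = list(spec.pos_probs)
    pos_p = np.array([spec.pos_probs[k] for k in pos_names])

    # partition the vocabulary across POS categories proportionally
    vocab: dict[str, list[str]] = {}
    sizes = np.maximum(1, np.round(pos_p * spec.vocabulary_size).astype(int))
    for tag, size in zip(pos_names, sizes):
        vocab[tag] = [f"{tag.lower()}{i}" for i in range(size)]

    sentences: list[Sentence] = []
    n_pauses = 0
    n_tokens = 0
    for _s in range(spec.n_utterances):
        length = 1 + rng.poisson(spec.utterance_length_mean)
        tokens: list[Token] = []
        for pos_idx in range(length):
            head = 0 if pos_idx == 0 else int(rng.integers(1, pos_idx + 1))
            deprel = "root" if pos_idx == 0 else "dep"
            if rng.random() < spec.filled_pause_rate:
                form = _PAUSE_FORMS[int(rng.integers(len(_PAUSE_FORMS)))]
                tokens.append(Token(form, form, "INTJ", head, deprel))
                n_pauses += 1
            else:
                tag = pos_names[int(rng.choice(len(pos_names), p=pos_p))]
                words = vocab[tag]
                zp = _zipf_probs(len(words), spec.zipf_exponent)
                form = words[int(rng.choice(len(words), p=zp))]
                tokens.append(Token(form, form, tag, head, deprel))
            n_tokens += 1
        sentences.append(Sentence(tokens))

    transcript = ParsedTranscript(subject_id=f"synth{spec.seed}",
                                  sentences=sentences)

    theta = np.deg2rad(spec.embedding_drift_deg)
    ks = np.arange(spec.n_utterances)
    vecs = np.zeros((spec.n_utterances, spec.embedding_dim))
    vecs[:, 0] = np.cos(ks * theta)
    vecs[:, 1] = np.sin(ks * theta)
    emb = EmbeddingSequence(transcript.subject_id, vecs)

    truth = {
        "expected_filled_pause_ratio": spec.filled_pause_rate,
        "observed_filled_pause_count": n_pauses,
        "n_tokens": n_tokens,
        "expected_coherence_mean": float(np.cos(theta)),
        "pos_probs": dict(spec.pos_probs),
        "expected_mlu": spec.utterance_length_mean + 1,
    }
    return transcript, emb, truth


# ---------------------------------------------------------------------------
# study-scale feature preset
# ---------------------------------------------------------------------------

_PSYCH_NAMES = ["SAPS_sum", "SANS_sum", "SAPS_FTD", "SANS_alogia", "HAMD",
                "HAMA", "YMRS", "GAF", "TLI_impoverished", "TLI_disorganization"]
_COG_NAMES = ["VF_semantic", "VF_lexical", "VF_alternating",
              "verbal_memory", "recognition", "executive_functioning"]


def study_shape_features(
    seed: int = 0,
    structure: str = "random",
    rho: float = 0.35,
    edge_prob: float = 0.15,
    group_sizes: dict[str, int] | None = None,
    domain_counts: dict[str, int] | None = None,
) -> tuple[FeatureMatrix, np.ndarray, list[tuple[int, int]]]:
    """A study-scale synthetic feature table with known network truth.

    Returns (feature matrix with domain labels and group assignments,
    planted precision matrix, true edge list). All groups share one
    distribution, mirroring the structural invariance the NCT probes.
    """
    group_sizes = dict(STUDY_SHAPE_GROUPS if group_sizes is None else group_sizes)
    domain_counts = dict(STUDY_SHAPE_DOMAINS if domain_counts is None
                         else domain_counts)
    p = sum(domain_counts.values())
    n = sum(group_sizes.values())
    Theta, edges = planted_precision(p, structure, rho, seed=seed,
                                     edge_prob=edge_prob)
    X = sample_mvn_from_precision(Theta, n, seed=seed)

    names: list[str] = []
    domains: dict[str, str] = {}
    n_ling = domain_counts.get("linguistic", 0)
    for i in range(n_ling):
        names.append(f"ling_{i + 1:02d}")
        domains[names[-1]] = "linguistic"
    n_psy = domain_counts.get("psychopathological", 0)
    for i in range(n_psy):
        nm = _PSYCH_NAMES[i] if i < len(_PSYCH_NAMES) else f"psy_{i + 1:02d}"
        names.append(nm)
        domains[nm] = "psychopathological"
    n_cog = domain_counts.get("cognitive", 0)
    for i in range(n_cog):
        nm = _COG_NAMES[i] if i < len(_COG_NAMES) else f"cog_{i + 1:02d}"
        names.append(nm)
        domains[nm] = "cognitive"

    subjects = []
    groups = []
    for g, size in group_sizes.items():
        for k in range(size):
            subjects.append(f"{g}_{k + 1:03d}")
            groups.append(g)
    df = pd.DataFrame(X, index=pd.Index(subjects, name="subject_id"),
                      columns=names)
    fm = FeatureMatrix(df, domains, pd.Series(groups, index=df.index))
    return fm, Theta, edges
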