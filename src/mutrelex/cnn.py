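"""Sentence-level relation classifier: a convolutional network over word,
entity-type and position embeddings, fused with scalar search-score features.

Architecture (single-sentence relation classification in the style of Kim's
convolutional sentence classifier, extended for a target entity pair):

* each token is the concatenation of a 300-d word embedding, a 10-d
  entity-type embedding (target mutation / target gene / target drug /
  non-target entity kinds / plain word), and two 10-d position embeddings
  indexed by the token's relative offset from the target mutation and from
  the target partner;
* convolution filters of widths 3/4/5, 100 feature maps each, ReLU,
  max-over-time pooling -> a 300-d sentence vector;
* the pooled vector is concatenated with standardized scalar features (the
  four search-engine scores, optionally more), dropout is applied, and an
  affine + softmax layer yields P(false), P(true).

Everything — forward pass, backpropagation, Adam — is implemented directly
in numpy: the model is small enough that a deep-learning framework would be
heavier than the computation it runs.  All randomness flows from the config
seed, so a fixed (seed, config, data) triple reproduces training exactly.

The module also provides skip-gram negative-sampling word-vector training
and readers/writers for the word2vec text and binary interchange formats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus import EntityMention
from .normalize import merge_entity_tokens

# ---------------------------------------------------------------------------
# Configuration and token/type alphabets

TYPE_ALPHABET = (
    "pad", "plain", "target_mutation", "target_gene", "target_drug",
    "other_mutation", "other_gene", "other_drug", "disease", "cell_line",
)
_TYPE_ID = {t: i for i, t in enumerate(TYPE_ALPHABET)}

PAD_ID = 0
UNK_ID = 1
_RESERVED = ("<pad>", "<unk>")


@dataclass(frozen=True)
class CnnConfig:
    """Hyper-parameters; defaults follow the Kim sentence-CNN conventions."""

    word_dim: int = 300
    type_dim: int = 10
    pos_dim: int = 10
    filter_widths: tuple[int, ...] = (3, 4, 5)
    maps_per_width: int = 100
    dropout_keep: float = 0.5
    batch_size: int = 50
    epochs: int = 5
    max_sentence_len: int = 30
    learning_algorithm: str = "adam"
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.dropout_keep <= 1.0):
            raise ValueError("dropout_keep must lie in (0, 1]")
        if min(self.word_dim, self.type_dim, self.pos_dim, self.maps_per_width,
               self.max_sentence_len, self.epochs, self.batch_size) <= 0:
            raise ValueError("all dimensions and counts must be positive")

    @property
    def token_dim(self) -> int:
        return self.word_dim + self.type_dim + 2 * self.pos_dim

    @property
    def n_positions(self) -> int:
        # offsets clipped to [-L, L] shifted by L+1; index 0 is the pad sentinel
        return 2 * self.max_sentence_len + 2


class Vocab:
    """Token -> id mapping with reserved pad/unk entries."""

    def __init__(self, tokens: Iterable[str]):
        self.itos: list[str] = list(_RESERVED)
        seen = set(_RESERVED)
        for t in tokens:
            if t not in seen:
                seen.add(t)
                self.itos.append(t)
        self.stoi = {t: i for i, t in enumerate(self.itos)}

    def __len__(self) -> int:
        return len(self.itos)

    def id(self, token: str) -> int:
        return self.stoi.get(token, UNK_ID)

    @staticmethod
    def build(token_sequences: Iterable[Sequence[str]], min_count: int = 1) -> "Vocab":
        counts: dict[str, int] = {}
        for seq in token_sequences:
            for t in seq:
                counts[t] = counts.get(t, 0) + 1
        kept = [t for t in sorted(counts) if counts[t] >= min_count]
        return Vocab(kept)


@dataclass
class EncodedSentence:
    """Index sequences plus scalar features: the network's input record."""

    token_ids: np.ndarray
    type_ids: np.ndarray
    rel_pos_mut: np.ndarray
    rel_pos_partner: np.ndarray
    scalar_features: np.ndarray
    label: bool | None = None


# ---------------------------------------------------------------------------
# Sentence encoding


def sentence_tokens(
    text: str,
    sentence_start: int,
    mentions: Sequence[EntityMention],
) -> tuple[list[str], list[EntityMention | None]]:
    """Tokenize a sentence, collapsing each entity mention to a single token.

    Returns parallel lists of tokens and the mention owning each token (None
    for plain words).  Entity tokens are the normalized form with spaces
    replaced by underscores; plain words are lower-cased.
    """
    spans = sorted(mentions, key=lambda m: m.start)
    tokens: list[str] = []
    owners: list[EntityMention | None] = []
    cursor = 0
    for m in spans:
        s, e = m.start - sentence_start, m.end - sentence_start
        for w in text[cursor:s].split():
            tokens.append(w.lower())
            owners.append(None)
        tokens.append(m.normalized.replace(" ", "_"))
        owners.append(m)
        cursor = e
    for w in text[cursor:].split():
        tokens.append(w.lower())
        owners.append(None)
    return tokens, owners


def _token_type(mention: EntityMention | None,
                target_mut: EntityMention, target_partner: EntityMention) -> str:
    if mention is None:
        return "plain"
    if mention == target_mut:
        return "target_mutation"
    if mention == target_partner:
        return f"target_{target_partner.kind}"
    if mention.kind in ("mutation", "gene", "drug"):
        return f"other_{mention.kind}"
    return mention.kind  # disease, cell_line


def encode_sentence(
    text: str,
    sentence_start: int,
    mentions: Sequence[EntityMention],
    target_mutation_mention: EntityMention,
    target_partner_mention: EntityMention,
    vocab: Vocab,
    config: CnnConfig,
    scalar_features: Sequence[float] = (),
    label: bool | None = None,
) -> EncodedSentence:
    """Encode one sentence for the network.

    Exactly one token carries the target-mutation type and one the target
    partner type; relative positions are 0 at the corresponding target token
    and clipped to +-max_sentence_len.  Over-long sentences are truncated to
    a window centred between the two targets (both must fit); short ones are
    right-padded with the reserved pad id/type and the sentinel position.
    """
    if target_mutation_mention not in mentions or target_partner_mention not in mentions:
        raise ValueError("target mentions must lie within the sentence")
    tokens, owners = sentence_tokens(text, sentence_start, mentions)
    mut_idx = owners.index(target_mutation_mention)
    par_idx = owners.index(target_partner_mention)

    L = config.max_sentence_len
    if len(tokens) > L:
        lo, hi = min(mut_idx, par_idx), max(mut_idx, par_idx)
        if hi - lo + 1 > L:
            raise ValueError(
                f"targets {hi - lo + 1} tokens apart exceed max_sentence_len={L}"
            )
        center = (lo + hi) // 2
        start = min(max(center - L // 2, 0), len(tokens) - L)
        start = min(start, lo)           # window must cover both targets
        start = max(start, hi - L + 1)
        tokens = tokens[start : start + L]
        owners = owners[start : start + L]
        mut_idx -= start
        par_idx -= start

    n = len(tokens)
    token_ids = np.full(L, PAD_ID, dtype=np.int64)
    type_ids = np.zeros(L, dtype=np.int64)          # 0 == pad type
    pos_mut = np.zeros(L, dtype=np.int64)           # 0 == sentinel
    pos_par = np.zeros(L, dtype=np.int64)
    for i, (tok, owner) in enumerate(zip(tokens, owners)):
        token_ids[i] = vocab.id(tok)
        type_ids[i] = _TYPE_ID[_token_type(owner, target_mutation_mention,
                                           target_partner_mention)]
        pos_mut[i] = int(np.clip(i - mut_idx, -L, L)) + L + 1
        pos_par[i] = int(np.clip(i - par_idx, -L, L)) + L + 1
    return EncodedSentence(token_ids, type_ids, pos_mut, pos_par,
                           np.asarray(scalar_features, dtype=np.float64), label)


# ---------------------------------------------------------------------------
# Word vectors: container, skip-gram training, word2vec I/O


@dataclass
class WordVectors:
    """A vocabulary of equal-dimension word vectors.

    ``oov_policy`` records how the downstream consumer initializes missing
    words ("random" here: unseen words get fresh random embeddings).
    """

    words: list[str]
    matrix: np.ndarray
    oov_policy: str = "random"

    def __post_init__(self) -> None:
        self._lookup = {w: i for i, w in enumerate(self.words)}
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.words):
            raise ValueError("matrix rows must match the vocabulary")

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def __contains__(self, word: str) -> bool:
        return word in self._lookup

    def __getitem__(self, word: str) -> np.ndarray:
        return self.matrix[self._lookup[word]]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def train_word_vectors(
    corpus,
    lexicon: Iterable[str],
    dim: int = 300,
    min_count: int = 5,
    seed: int = 0,
    window: int = 5,
    negative: int = 5,
    epochs: int = 5,
    learning_rate: float = 0.025,
) -> WordVectors:
    """Skip-gram with negative sampling over a corpus of annotated documents.

    Sentences are tokenized with multi-word lexicon phrases merged to single
    tokens; words with corpus frequency below ``min_count`` are dropped before
    training.  Negatives are drawn from the unigram^0.75 distribution; the
    learning rate decays linearly.  Deterministic per seed.
    """
    lexicon = list(lexicon)
    sentences: list[list[str]] = []
    for doc in corpus:
        for idx, _, _ in doc.sentences:
            sentences.append(merge_entity_tokens(doc.sentence_text(idx), lexicon))
    counts: dict[str, int] = {}
    for sent in sentences:
        for t in sent:
            counts[t] = counts.get(t, 0) + 1
    words = [w for w in sorted(counts) if counts[w] >= min_count]
    stoi = {w: i for i, w in enumerate(words)}
    V = len(words)
    if V == 0:
        return WordVectors([], np.zeros((0, dim)))

    rng = np.random.default_rng(seed)
    syn0 = (rng.random((V, dim)) - 0.5) / dim
    syn1 = np.zeros((V, dim))
    freq = np.array([counts[w] for w in words], dtype=np.float64) ** 0.75
    noise = freq / freq.sum()

    encoded = [[stoi[t] for t in sent if t in stoi] for sent in sentences]
    encoded = [s for s in encoded if len(s) > 1]
    total_steps = max(1, epochs * len(encoded))
    step = 0
    for _ in range(epochs):
        order = rng.permutation(len(encoded))
        for si in order:
            sent = encoded[si]
            lr = learning_rate * max(0.1, 1.0 - step / total_steps)
            step += 1
            for pos, center in enumerate(sent):
                span = int(rng.integers(1, window + 1))
                ctx = sent[max(0, pos - span) : pos] + sent[pos + 1 : pos + 1 + span]
                if not ctx:
                    continue
                for out in ctx:
                    rows = np.empty(negative + 1, dtype=np.int64)
                    rows[0] = out
                    rows[1:] = rng.choice(V, size=negative, p=noise)
                    labels = np.zeros(negative + 1)
                    labels[0] = 1.0
                    v = syn0[center]
                    f = _sigmoid(syn1[rows] @ v)
                    g = (labels - f) * lr
                    dv = g @ syn1[rows]
                    syn1[rows] += np.outer(g, v)
                    syn0[center] += dv
    return WordVectors(words, syn0)


def save_word_vectors(vectors: WordVectors, path, binary: bool = False) -> None:
    """Write vectors in the word2vec interchange format (text or binary)."""
    if binary:
        with open(path, "wb") as fh:
            fh.write(f"{len(vectors.words)} {vectors.dim}\n".encode())
            for w, row in zip(vectors.words, vectors.matrix):
                fh.write(w.encode() + b" ")
                fh.write(np.asarray(row, dtype=np.float32).tobytes())
                fh.write(b"\n")
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(vectors.words)} {vectors.dim}\n")
            for w, row in zip(vectors.words, vectors.matrix):
                fh.write(w + " " + " ".join(f"{x:.6f}" for x in row) + "\n")


def load_word_vectors(path, binary: bool = False) -> WordVectors:
    """Read word2vec text or binary vectors, validating the header counts."""
    words: list[str] = []
    if binary:
        with open(path, "rb") as fh:
            header = fh.readline().decode()
            try:
                n, dim = (int(x) for x in header.split())
            except ValueError as exc:
                raise ValueError(f"bad word2vec header {header!r}") from exc
            rows = np.empty((n, dim), dtype=np.float32)
            for i in range(n):
                chars = bytearray()
                while True:
                    c = fh.read(1)
                    if not c:
                        raise ValueError(f"truncated binary vector file at word {i}")
                    if c == b" ":
                        break
                    chars.extend(c)
                buf = fh.read(4 * dim)
                if len(buf) < 4 * dim:
                    raise ValueError(f"truncated binary vector file at word {i}")
                rows[i] = np.frombuffer(buf, dtype=np.float32)
                fh.read(1)  # trailing newline
                words.append(chars.decode())
    else:
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
            try:
                n, dim = (int(x) for x in header.split())
            except ValueError as exc:
                raise ValueError(f"bad word2vec header {header!r}") from exc
            rows = np.empty((n, dim), dtype=np.float32)
            for i in range(n):
                line = fh.readline()
                if not line:
                    raise ValueError(f"truncated vector file: {i} of {n} words")
                parts = line.rstrip("\n").split(" ")
                if len(parts) != dim + 1:
                    raise ValueError(f"vector line {i} has {len(parts) - 1} values, not {dim}")
                words.append(parts[0])
                rows[i] = [float(x) for x in parts[1:]]
    return WordVectors(words, rows.astype(np.float64))


# ---------------------------------------------------------------------------
# The network


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


class _SGD:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        for k, g in grads.items():
            params[k] -= self.lr * g


_OPTIMIZERS = {"adam": _Adam, "sgd": _SGD}


@dataclass
class TrainedModel:
    config: CnnConfig
    vocab: Vocab
    params: dict[str, np.ndarray]
    scalar_mean: np.ndarray
    scalar_std: np.ndarray
    history: list[dict] = field(default_factory=list)


def _init_params(config: CnnConfig, vocab_size: int, n_scalars: int,
                 initial_vectors: WordVectors | None, vocab: Vocab,
                 rng: np.random.Generator) -> dict[str, np.ndarray]:
    D = config.token_dim
    params: dict[str, np.ndarray] = {}
    W_word = rng.uniform(-0.25, 0.25, size=(vocab_size, config.word_dim))
    W_word[PAD_ID] = 0.0
    if initial_vectors is not None:
        if initial_vectors.dim != config.word_dim:
            raise ValueError(
                f"pre-trained vectors are {initial_vectors.dim}-d, "
                f"config.word_dim is {config.word_dim}"
            )
        for i, w in enumerate(vocab.itos):
            if w in initial_vectors:
                W_word[i] = initial_vectors[w]
    params["W_word"] = W_word
    params["W_type"] = rng.uniform(-0.25, 0.25, size=(len(TYPE_ALPHABET), config.type_dim))
    params["W_posm"] = rng.uniform(-0.25, 0.25, size=(config.n_positions, config.pos_dim))
    params["W_posp"] = rng.uniform(-0.25, 0.25, size=(config.n_positions, config.pos_dim))
    F = config.maps_per_width
    for w in config.filter_widths:
        bound = math.sqrt(6.0 / (w * D + F))
        params[f"K{w}"] = rng.uniform(-bound, bound, size=(w * D, F))
        params[f"b{w}"] = np.zeros(F)
    pooled = F * len(config.filter_widths)
    bound = math.sqrt(6.0 / (pooled + n_scalars + 2))
    params["W_out"] = rng.uniform(-bound, bound, size=(pooled + n_scalars, 2))
    params["b_out"] = np.zeros(2)
    return params


def _stack(batch: Sequence[EncodedSentence]) -> dict[str, np.ndarray]:
    return {
        "tok": np.stack([e.token_ids for e in batch]),
        "typ": np.stack([e.type_ids for e in batch]),
        "pm": np.stack([e.rel_pos_mut for e in batch]),
        "pp": np.stack([e.rel_pos_partner for e in batch]),
        "sc": np.stack([e.scalar_features for e in batch]),
    }


def _forward(params: Mapping[str, np.ndarray], config: CnnConfig,
             batch: dict[str, np.ndarray], scalar_mean: np.ndarray,
             scalar_std: np.ndarray, dropout_mask: np.ndarray | None):
    E = np.concatenate(
        [
            params["W_word"][batch["tok"]],
            params["W_type"][batch["typ"]],
            params["W_posm"][batch["pm"]],
            params["W_posp"][batch["pp"]],
        ],
        axis=2,
    )
    B, L, D = E.shape
    cache: dict = {"E_shape": (B, L, D)}
    pooled_parts = []
    for w in config.filter_widths:
        T = L - w + 1
        windows = np.lib.stride_tricks.sliding_window_view(E, w, axis=1)
        windows = np.ascontiguousarray(windows.transpose(0, 1, 3, 2)).reshape(B, T, w * D)
        Z = windows @ params[f"K{w}"] + params[f"b{w}"]
        A = np.maximum(Z, 0.0)
        arg = A.argmax(axis=1)
        pooled = np.take_along_axis(A, arg[:, None, :], axis=1)[:, 0, :]
        pooled_parts.append(pooled)
        cache[f"win{w}"] = windows
        cache[f"Z{w}"] = Z
        cache[f"arg{w}"] = arg
    h = np.concatenate(pooled_parts, axis=1)
    if batch["sc"].shape[1]:
        s = (batch["sc"] - scalar_mean) / scalar_std
        hh = np.concatenate([h, s], axis=1)
    else:
        hh = h
    if dropout_mask is not None:
        hh = hh * dropout_mask
    logits = hh @ params["W_out"] + params["b_out"]
    logits = logits - logits.max(axis=1, keepdims=True)
    expl = np.exp(logits)
    probs = expl / expl.sum(axis=1, keepdims=True)
    cache.update(hh=hh, probs=probs)
    return probs, cache


def _backward(params: Mapping[str, np.ndarray], config: CnnConfig,
              batch: dict[str, np.ndarray], cache: dict, labels: np.ndarray,
              dropout_mask: np.ndarray | None) -> dict[str, np.ndarray]:
    B, L, D = cache["E_shape"]
    probs = cache["probs"]
    dlogits = probs.copy()
    dlogits[np.arange(B), labels] -= 1.0
    dlogits /= B
    grads: dict[str, np.ndarray] = {
        "W_out": cache["hh"].T @ dlogits,
        "b_out": dlogits.sum(axis=0),
    }
    dhh = dlogits @ params["W_out"].T
    if dropout_mask is not None:
        dhh = dhh * dropout_mask
    F = config.maps_per_width
    dE = np.zeros((B, L, D))
    offset = 0
    for w in config.filter_widths:
        T = L - w + 1
        dpooled = dhh[:, offset : offset + F]
        offset += F
        dA = np.zeros((B, T, F))
        np.put_along_axis(dA, cache[f"arg{w}"][:, None, :], dpooled[:, None, :], axis=1)
        dZ = dA * (cache[f"Z{w}"] > 0)
        windows = cache[f"win{w}"]
        grads[f"K{w}"] = windows.reshape(B * T, w * D).T @ dZ.reshape(B * T, F)
        grads[f"b{w}"] = dZ.sum(axis=(0, 1))
        dwin = (dZ @ params[f"K{w}"].T).reshape(B, T, w, D)
        for j in range(w):
            dE[:, j : j + T, :] += dwin[:, :, j, :]
    wd, td, pd = config.word_dim, config.type_dim, config.pos_dim
    for key, ids, sl in (
        ("W_word", batch["tok"], slice(0, wd)),
        ("W_type", batch["typ"], slice(wd, wd + td)),
        ("W_posm", batch["pm"], slice(wd + td, wd + td + pd)),
        ("W_posp", batch["pp"], slice(wd + td + pd, wd + td + 2 * pd)),
    ):
        g = np.zeros_like(params[key])
        np.add.at(g, ids.ravel(), dE[:, :, sl].reshape(-1, sl.stop - sl.start))
        grads[key] = g
    return grads


def _evaluate(params, config, examples: Sequence[EncodedSentence],
              scalar_mean, scalar_std, batch_size: int = 200) -> tuple[float, np.ndarray]:
    """Return (F1 at threshold 0.5, probabilities of the true class)."""
    from .evaluation import prf_from_predictions

    probs = _predict_probs(params, config, examples, scalar_mean, scalar_std, batch_size)
    truth = np.array([bool(e.label) for e in examples])
    report = prf_from_predictions(truth, probs > 0.5)
    return report.f1, probs


def _predict_probs(params, config, examples, scalar_mean, scalar_std,
                   batch_size: int = 200) -> np.ndarray:
    out = []
    for i in range(0, len(examples), batch_size):
        batch = _stack(examples[i : i + batch_size])
        probs, _ = _forward(params, config, batch, scalar_mean, scalar_std, None)
        out.append(probs[:, 1])
    return np.concatenate(out) if out else np.zeros(0)


def build_and_train(
    config: CnnConfig,
    train: Sequence[EncodedSentence],
    dev: Sequence[EncodedSentence],
    initial_vectors: WordVectors | None = None,
    vocab: Vocab | None = None,
) -> TrainedModel:
    """Train the network; return the parameter state at the best dev F1 epoch.

    Scalar features are standardized with mean/variance estimated on the
    training split only.  Word embeddings start from ``initial_vectors``
    where the vocabulary overlaps (uniform random in [-0.25, 0.25]
    elsewhere); type and position embeddings start random; all embeddings
    are fine-tuned.
    """
    if not train:
        raise ValueError("empty training set")
    n_scalars = len(train[0].scalar_features)
    if any(len(e.scalar_features) != n_scalars for e in train):
        raise ValueError("inconsistent scalar feature dimensions")
    if vocab is None:
        vocab = Vocab([])  # encoding must then have used a shared vocab already
    vocab_size = max(len(vocab), int(max(e.token_ids.max() for e in train)) + 1)

    if n_scalars:
        sc = np.stack([e.scalar_features for e in train])
        scalar_mean = sc.mean(axis=0)
        scalar_std = sc.std(axis=0)
        scalar_std[scalar_std == 0] = 1.0
    else:
        scalar_mean = np.zeros(0)
        scalar_std = np.ones(0)

    rng = np.random.default_rng(config.seed)
    params = _init_params(config, vocab_size, n_scalars, initial_vectors, vocab, rng)
    try:
        opt_cls = _OPTIMIZERS[config.learning_algorithm]
    except KeyError:
        raise ValueError(f"unknown learning algorithm {config.learning_algorithm!r}")
    opt = opt_cls(params, config.learning_rate)

    labels = np.array([int(bool(e.label)) for e in train])
    history: list[dict] = []
    best_f1, best_params = -1.0, {k: v.copy() for k, v in params.items()}
    hh_dim = config.maps_per_width * len(config.filter_widths) + n_scalars
    for epoch in range(config.epochs):
        order = rng.permutation(len(train))
        losses = []
        for i in range(0, len(train), config.batch_size):
            idx = order[i : i + config.batch_size]
            batch = _stack([train[j] for j in idx])
            if config.dropout_keep < 1.0:
                mask = (rng.random((len(idx), hh_dim)) < config.dropout_keep)
                mask = mask / config.dropout_keep
            else:
                mask = None
            probs, cache = _forward(params, config, batch, scalar_mean, scalar_std, mask)
            y = labels[idx]
            losses.append(float(-np.log(probs[np.arange(len(idx)), y] + 1e-12).mean()))
            grads = _backward(params, config, batch, cache, y, mask)
            opt.step(params, grads)
        if dev:
            dev_f1, _ = _evaluate(params, config, dev, scalar_mean, scalar_std)
        else:
            dev_f1, _ = _evaluate(params, config, train, scalar_mean, scalar_std)
        history.append({"epoch": epoch, "loss": float(np.mean(losses)), "dev_f1": dev_f1})
        if dev_f1 > best_f1:
            best_f1 = dev_f1
            best_params = {k: v.copy() for k, v in params.items()}
    return TrainedModel(config, vocab, best_params, scalar_mean, scalar_std, history)


def predict(model: TrainedModel, examples: Sequence[EncodedSentence]) -> np.ndarray:
    """Probability of the true class per example (empty in, empty out)."""
    if not examples:
        return np.zeros(0)
    n_scalars = len(model.scalar_mean)
    if any(len(e.scalar_features) != n_scalars for e in examples):
        raise ValueError("examples were encoded with a different scalar feature set")
    if any(e.token_ids.max() >= model.params["W_word"].shape[0] for e in examples):
        raise ValueError("examples were encoded with a different vocabulary")
    return _predict_probs(model.params, model.config, examples,
                          model.scalar_mean, model.scalar_std)


# ---------------------------------------------------------------------------
# Glue: encoding SentenceExamples and a trainer for sub-sampling validation


def encode_examples(
    examples: Sequence,
    vocab: Vocab,
    config: CnnConfig,
    index=None,
    use_scores: bool = True,
) -> list[EncodedSentence]:
    """Encode SentenceExamples; search-score scalars come from ``index``.

    With ``use_scores`` false (or no index) the scalar block is empty, which
    is the "without search scores" ablation arm.
    """
    from .search import search_score_features

    encoded = []
    for ex in examples:
        if index is not None and use_scores:
            vec = search_score_features(
                index, ex.mutation, list(ex.mentions),
                ex.partner_mention.kind, ex.partner,
            )
            scalars: Sequence[float] = vec.as_tuple()
        else:
            scalars = ()
        encoded.append(
            encode_sentence(ex.text, ex.sentence_start, ex.mentions,
                            ex.mutation_mention, ex.partner_mention,
                            vocab, config, scalars, ex.label)
        )
    return encoded


def example_vocab(examples: Sequence, min_count: int = 1) -> Vocab:
    seqs = [sentence_tokens(ex.text, ex.sentence_start, ex.mentions)[0] for ex in examples]
    return Vocab.build(seqs, min_count)


def make_cnn_trainer(
    config: CnnConfig,
    initial_vectors: WordVectors | None = None,
    index=None,
    use_scores: bool = True,
    dev_fraction: float = 0.1,
):
    """Adapter fitting the ``subsampling_validation`` trainer contract.

    Per call: build the vocabulary from the training sentences, hold out a
    small stratified dev split for best-epoch selection, train, and return a
    predictor closure that encodes unseen examples with the same vocabulary.
    """

    def trainer(train_pos: Sequence, train_neg: Sequence, seed: int):
        cfg = replace(config, seed=int(seed) % (2**31))
        vocab = example_vocab(list(train_pos) + list(train_neg))
        rng = np.random.default_rng(cfg.seed)

        def split(examples):
            examples = list(examples)
            n_dev = max(1, int(len(examples) * dev_fraction))
            idx = rng.permutation(len(examples))
            dev = [examples[i] for i in idx[:n_dev]]
            tr = [examples[i] for i in idx[n_dev:]]
            return tr, dev

        tr_p, dev_p = split(train_pos)
        tr_n, dev_n = split(train_neg)
        train_enc = encode_examples(tr_p + tr_n, vocab, cfg, index, use_scores)
        dev_enc = encode_examples(dev_p + dev_n, vocab, cfg, index, use_scores)
        model = build_and_train(cfg, train_enc, dev_enc, initial_vectors, vocab)

        def predictor(examples: Sequence) -> np.ndarray:
            enc = encode_examples(examples, vocab, cfg, index, use_scores)
            return predict(model, enc) > 0.5

        predictor.model = model  # exposed for probability-level consumers
        predictor.vocab = vocab
        return predictor

    return trainer
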