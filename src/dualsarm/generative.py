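"""Staged fragment generators with log-likelihood scoring.

Three sequence-to-sequence generator roles mirror the staged design
pipeline: the key2 generator proposes new two-point scaffolds from known
scaffolds, the value2 generator proposes distinguishing substructures
from (generated) scaffolds, and the value1 generator proposes new
substituents from key1 cores.  Each generator is an LSTM encoder-decoder
(:mod:`dualsarm.nn`) trained on fragment SMILES: pre-trained on a pooled
corpus from both target classes, then fine-tuned on the fragments of
dual-target ligands.

Every emitted fragment carries a log-likelihood score — the sum of the
decoder's per-token log-probabilities — which is always <= 0 and is used
to filter and to score virtual analogs (the score of an analog is the sum
of its fragments' scores).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from rdkit import Chem

from .errors import ContractError, ParseError
from .fragmentation import attach_at, attachment_points, canonicalize
from .nn import BOS, EOS, PAD, Seq2Seq

logger = logging.getLogger(__name__)

ROLES = ("key2", "value2", "value1")
#: attachment points each role's output must carry
ROLE_POINTS = {"key2": 2, "value2": 1, "value1": 1}

_TOKEN_RE = re.compile(
    r"\[[^\]]*\]|Br|Cl|Si|Se|se|@@|%\d{2}|[A-Za-z]|\d|[()=#+\-/\\*.$:]"
)


def tokenize(smiles: str) -> list[str]:
    """Split a fragment SMILES into tokens.

    Bracket atoms and two-letter elements are single tokens; any character
    outside the token grammar raises with its position.
    """
    if not smiles:
        raise ParseError("cannot tokenize an empty SMILES")
    out = []
    pos = 0
    while pos < len(smiles):
        m = _TOKEN_RE.match(smiles, pos)
        if m is None:
            raise ParseError(
                f"character {smiles[pos]!r} at position {pos} of {smiles!r} "
                "does not match the SMILES token grammar"
            )
        out.append(m.group())
        pos = m.end()
    return out


def detokenize(tokens: list[str]) -> str:
    return "".join(tokens)


@dataclass(frozen=True)
class TokenVocabulary:
    """Ordered token set with reserved pad/start/end slots."""

    tokens: tuple[str, ...]  # positions 0..2 are <pad>, <bos>, <eos>
    index_of: dict[str, int] = field(hash=False, compare=False, default_factory=dict)

    SPECIALS = ("<pad>", "<bos>", "<eos>")

    @classmethod
    def from_corpus(cls, fragments: list[str]) -> "TokenVocabulary":
        seen: set[str] = set()
        for frag in fragments:
            seen.update(tokenize(frag))
        tokens = cls.SPECIALS + tuple(sorted(seen))
        return cls(tokens=tokens, index_of={t: i for i, t in enumerate(tokens)})

    def __len__(self) -> int:
        return len(self.tokens)

    def encode(self, smiles: str) -> list[int]:
        try:
            return [self.index_of[t] for t in tokenize(smiles)]
        except KeyError as exc:
            raise ParseError(f"token {exc.args[0]!r} of {smiles!r} not in vocabulary")

    def decode(self, ids: list[int]) -> str:
        return detokenize([self.tokens[i] for i in ids])

    def to_json(self) -> str:
        return json.dumps({"tokens": list(self.tokens)})

    @classmethod
    def from_json(cls, text: str) -> "TokenVocabulary":
        tokens = tuple(json.loads(text)["tokens"])
        return cls(tokens=tokens, index_of={t: i for i, t in enumerate(tokens)})


@dataclass
class TrainingConfig:
    """Desk-scale defaults: minutes of CPU on corpora of a few hundred lines."""

    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 5e-3
    embed_dim: int = 32
    hidden_size: int = 128
    holdout_fraction: float = 0.1
    seed: int = 0


@dataclass
class GeneratorState:
    """A trained generator: role + vocabulary + weights + training phase."""

    role: str
    vocabulary: TokenVocabulary
    model: Seq2Seq
    training_phase: str = "pretrained"  # or "finetuned"
    parent_phase: str | None = None  # phase of the state this descends from
    known_fragments: frozenset[str] = frozenset()  # canonical fine-tune set
    heldout_nll: float | None = None

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "role": self.role,
            "training_phase": self.training_phase,
            "parent_phase": self.parent_phase,
            "known_fragments": sorted(self.known_fragments),
            "heldout_nll": self.heldout_nll,
            "vocabulary": json.loads(self.vocabulary.to_json()),
        }
        (directory / "generator.json").write_text(json.dumps(meta, indent=1))
        np.savez(directory / "weights.npz", **self.model.state_arrays())

    @classmethod
    def load(cls, directory) -> "GeneratorState":
        directory = Path(directory)
        meta = json.loads((directory / "generator.json").read_text())
        vocab = TokenVocabulary.from_json(json.dumps(meta["vocabulary"]))
        arrays = dict(np.load(directory / "weights.npz"))
        return cls(
            role=meta["role"],
            vocabulary=vocab,
            model=Seq2Seq.from_arrays(arrays),
            training_phase=meta["training_phase"],
            parent_phase=meta["parent_phase"],
            known_fragments=frozenset(meta["known_fragments"]),
            heldout_nll=meta["heldout_nll"],
        )


@dataclass(frozen=True)
class ScoredFragment:
    smiles: str
    ll_score: float  # sum of decoder per-token log-probabilities; <= 0
    source_role: str
    novelty: bool = False  # absent from the generator's fine-tuning set


def _pad_batch(seqs: list[list[int]]) -> np.ndarray:
    T = max(len(s) for s in seqs)
    out = np.full((len(seqs), T), PAD, dtype=int)
    for r, s in enumerate(seqs):
        out[r, : len(s)] = s
    return out


def mean_nll(state: GeneratorState, fragments: list[str],
             sources: list[str] | None = None) -> float:
    """Mean per-token negative log-likelihood of fragments under the decoder.

    ``sources`` are the encoder inputs; by default each fragment conditions
    on itself (the key2-style identity convention).
    """
    sources = sources or fragments
    total_lp = 0.0
    total_tok = 0
    for src, frag in zip(sources, fragments):
        lps = state.model.sequence_log_probs(
            state.vocabulary.encode(src), state.vocabulary.encode(frag)
        )
        total_lp += float(lps.sum())
        total_tok += len(lps)
    return -total_lp / total_tok


def _train_epochs(model: Seq2Seq, src_ids: list[list[int]],
                  tgt_ids: list[list[int]], config: TrainingConfig,
                  rng: np.random.Generator) -> None:
    for _ in range(config.epochs):
        order = rng.permutation(len(tgt_ids))
        for start in range(0, len(order), config.batch_size):
            chunk = order[start : start + config.batch_size]
            src = _pad_batch([src_ids[k] for k in chunk])
            dec_in = _pad_batch([[BOS] + tgt_ids[k] for k in chunk])
            dec_tgt = _pad_batch([tgt_ids[k] + [EOS] for k in chunk])
            _, grads = model.loss_and_grads(src, dec_in, dec_tgt)
            model.adam_update(grads, lr=config.learning_rate)


def pretrain(corpus: list[str], role: str, config: TrainingConfig | None = None,
             sources: list[str] | None = None) -> GeneratorState:
    """Train a generator from scratch on a pooled fragment corpus.

    ``corpus`` holds the target fragments; ``sources`` the parallel
    encoder inputs (e.g. the key2 a value2 was observed with).  Without
    sources each fragment conditions on itself, the key2 convention.  A
    10% slice is held out and its mean per-token NLL recorded on the
    returned state.  Reproducible for a fixed config seed.
    """
    config = config or TrainingConfig()
    if role not in ROLES:
        raise ContractError(f"unknown generator role {role!r}; expected one of {ROLES}")
    if not corpus:
        raise ContractError("pretraining corpus is empty")
    if len(corpus) < config.batch_size:
        raise ContractError(
            f"corpus ({len(corpus)} fragments) is smaller than the batch size "
            f"({config.batch_size}); use a smaller batch_size"
        )
    sources = sources or list(corpus)
    if len(sources) != len(corpus):
        raise ContractError("sources and corpus must be parallel lists")
    vocab = TokenVocabulary.from_corpus(list(corpus) + list(sources))
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(corpus))
    n_hold = max(1, int(round(config.holdout_fraction * len(corpus))))
    hold = order[:n_hold]
    keep = order[n_hold:]
    model = Seq2Seq(
        len(vocab),
        embed_dim=config.embed_dim,
        hidden_size=config.hidden_size,
        seed=config.seed,
    )
    src_ids = [vocab.encode(sources[k]) for k in keep]
    tgt_ids = [vocab.encode(corpus[k]) for k in keep]
    _train_epochs(model, src_ids, tgt_ids, config, rng)
    state = GeneratorState(role=role, vocabulary=vocab, model=model)
    state.heldout_nll = mean_nll(
        state, [corpus[k] for k in hold], [sources[k] for k in hold]
    )
    return state


def finetune(state: GeneratorState, corpus: list[str],
             config: TrainingConfig | None = None,
             sources: list[str] | None = None) -> GeneratorState:
    """Adapt a pretrained generator to a focus corpus.

    The parameters with the lowest focus-corpus NLL seen during training
    (including the starting point) are kept, so the focus NLL of the
    returned state never exceeds that of the input state.
    """
    config = config or TrainingConfig()
    if state.training_phase != "pretrained":
        raise ContractError("finetune expects a pretrained state")
    if not corpus:
        raise ContractError("fine-tuning corpus is empty")
    sources = sources or list(corpus)
    for frag in list(corpus) + list(sources):
        state.vocabulary.encode(frag)  # role/vocabulary mismatch surfaces here
    rng = np.random.default_rng(config.seed)
    src_ids = [state.vocabulary.encode(f) for f in sources]
    tgt_ids = [state.vocabulary.encode(f) for f in corpus]
    model = state.model.copy()
    best_model = model.copy()
    best_nll = mean_nll(replace(state, model=model), corpus, sources)
    per_epoch = replace(config, epochs=1)
    for _ in range(config.epochs):
        _train_epochs(model, src_ids, tgt_ids, per_epoch, rng)
        nll = mean_nll(replace(state, model=model), corpus, sources)
        if nll < best_nll:
            best_nll = nll
            best_model = model.copy()
    return GeneratorState(
        role=state.role,
        vocabulary=state.vocabulary,
        model=best_model,
        training_phase="finetuned",
        parent_phase=state.training_phase,
        known_fragments=frozenset(canonicalize(f) for f in corpus),
        heldout_nll=state.heldout_nll,
    )


@dataclass
class GenerationReport:
    n_samples: int = 0
    n_valid: int = 0
    n_invalid: int = 0
    n_wrong_points: int = 0

    @property
    def validity_fraction(self) -> float:
        return self.n_valid / self.n_samples if self.n_samples else 0.0


def generate_fragments(
    state: GeneratorState,
    seeds: list[str],
    n_samples: int,
    temperature: float = 1.0,
    top_k: int = 0,
    seed: int = 0,
    report: GenerationReport | None = None,
) -> list[ScoredFragment]:
    """Sample fragments from a trained generator, round-robin over seeds.

    Only chemically valid, role-conforming fragments are returned,
    deduplicated on canonical SMILES (best score kept) and sorted by
    descending score.  Invalid decodes are counted in ``report`` and
    logged, never returned.
    """
    if state.model is None:
        raise ContractError("generator state is untrained")
    if not seeds:
        raise ContractError("at least one seed fragment is required")
    report = report if report is not None else GenerationReport()
    rng = np.random.default_rng(seed)
    want_points = ROLE_POINTS[state.role]
    best: dict[str, float] = {}
    seed_ids = [state.vocabulary.encode(canonicalize(s)) for s in seeds]
    for n in range(n_samples):
        src = seed_ids[n % len(seed_ids)]
        ids, ll = state.model.sample(
            src, rng, temperature=temperature, top_k=top_k
        )
        report.n_samples += 1
        smiles = state.vocabulary.decode(ids)
        try:
            can = canonicalize(smiles)
        except ParseError:
            report.n_invalid += 1
            continue
        mol = Chem.MolFromSmiles(can)
        n_heavy = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 0)
        if attachment_points(can) != want_points or n_heavy == 0:
            report.n_wrong_points += 1  # bare wildcards are not fragments
            continue
        report.n_valid += 1
        if can not in best or ll > best[can]:
            best[can] = ll
    logger.info(
        "generate[%s]: %d samples, %d valid (%.0f%%), %d invalid, %d wrong points",
        state.role,
        report.n_samples,
        report.n_valid,
        100 * report.validity_fraction,
        report.n_invalid,
        report.n_wrong_points,
    )
    frags = [
        ScoredFragment(
            smiles=smi,
            ll_score=ll,
            source_role=state.role,
            novelty=smi not in state.known_fragments,
        )
        for smi, ll in best.items()
    ]
    frags.sort(key=lambda f: (-f.ll_score, f.smiles))
    return frags


def score_fragment(state: GeneratorState, seed_smiles: str, fragment: str) -> float:
    """Independent teacher-forced recomputation of a fragment's score."""
    src = state.vocabulary.encode(canonicalize(seed_smiles))
    tgt = state.vocabulary.encode(fragment)
    return float(state.model.sequence_log_probs(src, tgt).sum())


def assemble_key1(key2: ScoredFragment, value2: ScoredFragment) -> list[ScoredFragment]:
    """Realize key1 cores by bonding a value2 onto either point of a key2.

    Both orientations are emitted (they collapse for symmetric scaffolds);
    the score is the sum of the fragment scores.  Valence violations are
    dropped with a log entry.
    """
    if attachment_points(key2.smiles) != 2:
        raise ContractError(f"key2 must have 2 attachment points: {key2.smiles!r}")
    if attachment_points(value2.smiles) != 1:
        raise ContractError(f"value2 must have 1 attachment point: {value2.smiles!r}")
    score = score_virtual_analog(key2.ll_score, value2.ll_score)
    out: list[ScoredFragment] = []
    seen: set[str] = set()
    for point in (0, 1):
        try:
            smi = attach_at(key2.smiles, value2.smiles, point)
        except Exception as exc:
            logger.info(
                "orientation %d of %s + %s dropped: %s",
                point, key2.smiles, value2.smiles, exc,
            )
            continue
        if smi not in seen:
            seen.add(smi)
            out.append(
                ScoredFragment(
                    smiles=smi,
                    ll_score=score,
                    source_role="key1",
                    novelty=key2.novelty or value2.novelty,
                )
            )
    return out


def score_virtual_analog(key_score: float, value_score: float) -> float:
    """Score of a virtual analog: the sum of its fragments' scores."""
    if key_score > 0 or value_score > 0:
        raise ContractError(
            f"log-likelihood scores must be <= 0, got ({key_score}, {value_score})"
        )
    return key_score + value_score


def filter_by_score(fragments: list[ScoredFragment], ll_min: float) -> list[ScoredFragment]:
    """Keep fragments with ll_score >= ll_min, preserving order."""
    kept = [f for f in fragments if f.ll_score >= ll_min]
    logger.info("score filter (>= %.3f): kept %d of %d", ll_min, len(kept), len(fragments))
    return kept


def staged_generation(
    states: dict[str, GeneratorState],
    key2_seeds: list[str],
    n_samples: int = 100,
    ll_min: float | None = None,
    max_per_stage: int | None = None,
    seed: int = 0,
) -> tuple[list[ScoredFragment], list[ScoredFragment]]:
    """Run the three-stage generation pipeline.

    The key2 generator proposes scaffolds from ``key2_seeds``; the value2
    generator is seeded with those scaffolds' single-point projections;
    assembled key2 + value2 pairs yield new key1 cores, which seed the
    value1 generator.  Between stages, fragments below ``ll_min`` are
    filtered out and at most ``max_per_stage`` best-scored are kept.
    Returns (new key1 fragments, new value1 fragments).
    """
    for role in ROLES:
        if role not in states:
            raise ContractError(f"missing generator for role {role!r}")

    def trim(frags: list[ScoredFragment]) -> list[ScoredFragment]:
        if ll_min is not None:
            frags = filter_by_score(frags, ll_min)
        return frags[:max_per_stage] if max_per_stage else frags

    key2s = trim(
        generate_fragments(states["key2"], key2_seeds, n_samples, seed=seed)
    )
    if not key2s:
        return [], []
    value2_seeds = [f.smiles for f in key2s]
    value2s = trim(
        generate_fragments(states["value2"], value2_seeds, n_samples, seed=seed + 1)
    )
    key1s: dict[str, ScoredFragment] = {}
    for k2 in key2s:
        for v2 in value2s:
            for cand in assemble_key1(k2, v2):
                if cand.smiles not in key1s or cand.ll_score > key1s[cand.smiles].ll_score:
                    key1s[cand.smiles] = cand
    new_keys = sorted(key1s.values(), key=lambda f: (-f.ll_score, f.smiles))
    new_keys = trim(new_keys)
    if not new_keys:
        return [], []
    value1_seeds = [f.smiles for f in new_keys]
    value1s = trim(
        generate_fragments(states["value1"], value1_seeds, n_samples, seed=seed + 2)
    )
    return new_keys, value1s


def default_ll_min(state: GeneratorState, reference_fragments: list[str],
                   percentile: float = 10.0) -> float:
    """Self-calibrating threshold: a low percentile of the scores the
    generator assigns to known-good (fine-tuning) fragments."""
    if not reference_fragments:
        raise ContractError("need reference fragments to calibrate ll_min")
    scores = [score_fragment(state, f, f) for f in reference_fragments]
    return float(np.percentile(scores, percentile))
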