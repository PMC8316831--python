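"""Synthetic dependency treebanks with controllable statistical structure.

Word forms are drawn from a Zipfian lexicon whose top ranks are flagged as
function words; trees are random recursive trees in which each new token
attaches to an earlier token, with an optional preference weight for
function-word governors (producing hub-dominated, heavy-tailed networks).
A level plan scales vocabulary size across proficiency levels so the
resulting network panels show the developmental trends the pipeline is
meant to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from synnet.errors import ValidationError
from synnet.treebank import CorpusMeta, Sentence, Token, Treebank

CONTENT_POS = "c"
FUNCTION_POS = "f"
GENERIC_RELATION = "DEP"


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs for one synthetic corpus."""

    vocab_size: int = 1000
    zipf_exponent: float = 1.0
    function_word_fraction: float = 0.05
    hub_bias: float = 5.0
    target_tokens: int = 5000
    sentence_length_mean: float = 12.0
    sentence_length_min: int = 2
    sentence_length_max: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vocab_size < 10:
            raise ValidationError("vocab_size must be >= 10")
        if self.zipf_exponent <= 0:
            raise ValidationError("zipf_exponent must be > 0")
        if not 0 <= self.function_word_fraction < 1:
            raise ValidationError("function_word_fraction must be in [0, 1)")
        if self.hub_bias < 0:
            raise ValidationError("hub_bias must be >= 0")
        if self.sentence_length_min < 2:
            raise ValidationError("sentence_length_min must be >= 2")
        if self.sentence_length_max < self.sentence_length_min:
            raise ValidationError("sentence_length_max < sentence_length_min")
        if self.target_tokens < self.sentence_length_min:
            raise ValidationError("target_tokens below minimum sentence length")


@dataclass(frozen=True)
class Lexicon:
    """Ranked word types with Zipfian probabilities."""

    forms: tuple[str, ...]
    probabilities: np.ndarray = field(repr=False)
    function_words: frozenset[str]

    def pos_of(self, form: str) -> str:
        return FUNCTION_POS if form in self.function_words else CONTENT_POS


def sample_lexicon(config: GeneratorConfig) -> Lexicon:
    """Zipfian lexicon: P(rank r) ∝ r^-s; top ranks are function words.

    Fully determined by the config (no sampling involved), so identical
    configs always yield identical lexica.
    """
    v = config.vocab_size
    n_func = int(np.ceil(config.function_word_fraction * v))
    if config.function_word_fraction > 0 and n_func >= v:
        raise ValidationError("function_word_fraction leaves no content words")
    forms = tuple(
        f"fw{r:05d}" if r <= n_func else f"cw{r:05d}" for r in range(1, v + 1)
    )
    ranks = np.arange(1, v + 1, dtype=float)
    probs = ranks**-config.zipf_exponent
    probs /= probs.sum()
    return Lexicon(
        forms=forms,
        probabilities=probs,
        function_words=frozenset(forms[:n_func]),
    )


def generate_sentence(
    length: int,
    lexicon: Lexicon,
    hub_bias: float,
    rng: np.random.Generator,
    sentence_id: str = "s1",
) -> Sentence:
    """One random dependency tree over ``length`` sampled word forms.

    Token 1 is the root; each later token chooses its governor among the
    tokens already placed, with weight 1 + hub_bias for function-word
    governors. The result always has exactly one root row and length-1
    dependencies.
    """
    if length < 2:
        raise ValidationError("sentence length must be >= 2")
    idx = rng.choice(len(lexicon.forms), size=length, p=lexicon.probabilities)
    forms = [lexicon.forms[i] for i in idx]
    is_func = np.array([f in lexicon.function_words for f in forms], dtype=float)
    tokens = [
        Token(
            order=1,
            form=forms[0],
            pos=lexicon.pos_of(forms[0]),
            governor_order=0,
            relation="HED",
        )
    ]
    for pos_i in range(2, length + 1):
        weights = 1.0 + hub_bias * is_func[: pos_i - 1]
        gov = int(rng.choice(pos_i - 1, p=weights / weights.sum())) + 1
        tokens.append(
            Token(
                order=pos_i,
                form=forms[pos_i - 1],
                pos=lexicon.pos_of(forms[pos_i - 1]),
                governor_order=gov,
                relation=GENERIC_RELATION,
            )
        )
    return Sentence(sentence_id=sentence_id, tokens=tuple(tokens))


def _sample_length(config: GeneratorConfig, rng: np.random.Generator) -> int:
    """Truncated geometric sentence length with the configured mean."""
    mean_excess = max(config.sentence_length_mean - config.sentence_length_min, 0.5)
    p = 1.0 / (1.0 + mean_excess)
    for _ in range(1000):
        length = config.sentence_length_min + int(rng.geometric(p)) - 1
        if length <= config.sentence_length_max:
            return length
    return config.sentence_length_max


def generate_treebank(
    config: GeneratorConfig, meta: CorpusMeta | None = None
) -> Treebank:
    """Emit sentences until the token target is reached (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    lexicon = sample_lexicon(config)
    sentences: list[Sentence] = []
    tokens = 0
    while tokens < config.target_tokens:
        length = _sample_length(config, rng)
        sent = generate_sentence(
            length, lexicon, config.hub_bias, rng, sentence_id=f"s{len(sentences) + 1}"
        )
        sentences.append(sent)
        tokens += length
    return Treebank(sentences=sentences, meta=meta or CorpusMeta())


@dataclass(frozen=True)
class LevelPlan:
    """Labeled generator configs covering both modalities and all levels."""

    entries: tuple[tuple[str, str, int | str, GeneratorConfig], ...]

    def __post_init__(self) -> None:
        for modality in ("written", "oral"):
            sizes = [
                cfg.vocab_size
                for _, mod, level, cfg in self.entries
                if mod == modality and level in (1, 2, 3, 4)
            ]
            if sizes != sorted(sizes) or len(set(sizes)) != len(sizes):
                raise ValidationError(
                    f"{modality}: vocabulary sizes must strictly increase "
                    f"with level, got {sizes}"
                )


#: learner vocabulary growth per level, loosely mirroring 500 -> 4,000
_WRITTEN_VOCAB = {1: 500, 2: 800, 3: 2000, 4: 4000, "native": 5000}
_ORAL_VOCAB = {1: 400, 2: 640, 3: 1600, 4: 3200, "native": 4000}


def default_level_plan(
    seed: int = 0, target_tokens: int = 5000, hub_bias: float = 5.0
) -> LevelPlan:
    """Ten-corpus plan: written/oral x levels 1-4 + native references."""
    entries = []
    offset = 0
    for modality, prefix, vocab in (
        ("written", "W", _WRITTEN_VOCAB),
        ("oral", "O", _ORAL_VOCAB),
    ):
        for level, size in vocab.items():
            label = f"{prefix}{'N' if level == 'native' else level}"
            entries.append(
                (
                    label,
                    modality,
                    level,
                    GeneratorConfig(
                        vocab_size=size,
                        target_tokens=target_tokens,
                        hub_bias=hub_bias,
                        seed=seed + offset,
                    ),
                )
            )
            offset += 1
    return LevelPlan(entries=tuple(entries))


def generate_level_series(plan: LevelPlan) -> list[Treebank]:
    """Generate one treebank per plan entry, meta filled from the plan."""
    out = []
    for label, modality, level, cfg in plan.entries:
        meta = CorpusMeta(modality=modality, level=level, label=label)
        out.append(generate_treebank(cfg, meta=meta))
    return out
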