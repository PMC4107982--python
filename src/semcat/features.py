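"""Sparse feature generation for span classification.

Four feature families, each in its own namespace so assembled vectors can
never collide:

* ``int:``  — features derived solely from the span text (lowercased text,
  tokens, token count, affixes, word shape, character flags and n-grams);
* ``gaz:``  — one binary feature per resource, fired by strict lookup;
* ``sim:``  — one binary feature per (resource, tau), fired by approximate
  character n-gram cosine lookup;
* ``np*:``  — text and lookup features for the heuristically found NP-head
  and Base-NP, useful when a compound noun phrase's head determines its
  semantic category ("Complex of fibrin and plasminogen" names a complex,
  not the proteins inside it).

Model variants combine families: INT, INT.GAZ, INT.SIM, INT.NP.GAZ,
INT.NP.SIM.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

from .lexicon import LexicalResource, SimilarityIndex, max_similarity, strict_lookup

__all__ = [
    "FeatureConfig",
    "FeatureExtractor",
    "internal_features",
    "gazetteer_features",
    "simstring_features",
    "np_head",
    "np_features",
    "assemble",
    "tokenize",
]

DEFAULT_TAUS = (0.6, 0.7, 0.8, 0.9, 1.0)

#: Post-modifier boundary prepositions for the NP-head heuristic.
PREPOSITIONS = frozenset({"of", "in", "on", "for", "with", "to", "by", "from", "at"})

_VARIANTS = {
    "INT": dict(use_internal=True, use_gazetteer=False, use_simstring=False, use_np=False),
    "INT.GAZ": dict(use_internal=True, use_gazetteer=True, use_simstring=False, use_np=False),
    "INT.SIM": dict(use_internal=True, use_gazetteer=False, use_simstring=True, use_np=False),
    "INT.NP.GAZ": dict(use_internal=True, use_gazetteer=True, use_simstring=False, use_np=True),
    "INT.NP.SIM": dict(use_internal=True, use_gazetteer=False, use_simstring=True, use_np=True),
}


@dataclass(frozen=True)
class FeatureConfig:
    """Which feature families are active and how lookups are parameterised."""

    use_internal: bool = True
    use_gazetteer: bool = False
    use_simstring: bool = False
    use_np: bool = False
    resources: tuple[str, ...] = ()
    taus: tuple[float, ...] = DEFAULT_TAUS
    n: int = 3

    def __post_init__(self) -> None:
        if not (self.use_internal or self.use_gazetteer or self.use_simstring or self.use_np):
            raise ValueError("at least one feature family must be enabled")
        if (self.use_gazetteer or self.use_simstring) and not self.resources:
            raise ValueError("gazetteer/simstring features require at least one resource")
        if any(not (0 < t <= 1) for t in self.taus):
            raise ValueError(f"similarity thresholds must be in (0, 1]: {self.taus}")

    @classmethod
    def from_variant(cls, variant: str, resources: tuple[str, ...] = (),
                     taus: tuple[float, ...] = DEFAULT_TAUS, n: int = 3) -> "FeatureConfig":
        """Build a config from a model-variant shorthand (e.g. ``INT.SIM``)."""
        key = variant.upper()
        if key not in _VARIANTS:
            raise ValueError(f"unknown model variant {variant!r}; "
                             f"choose from {sorted(_VARIANTS)}")
        return cls(resources=tuple(resources), taus=tuple(taus), n=n, **_VARIANTS[key])

    @property
    def variant(self) -> str:
        for name, flags in _VARIANTS.items():
            if all(getattr(self, k) == v for k, v in flags.items()):
                return name
        return "CUSTOM"


_TOKEN = re.compile(r"\w[\w\-']*|[^\w\s]")


def tokenize(s: str) -> list[str]:
    """Whitespace-and-punctuation tokenizer: words keep internal hyphens
    and apostrophes; punctuation marks become single-character tokens."""
    return _TOKEN.findall(s)


def _word_tokens(s: str) -> list[str]:
    return [t for t in tokenize(s) if any(c.isalnum() for c in t)]


def _shape(s: str) -> str:
    """Collapsed word-shape pattern: X/x/d classes with + for runs."""
    classes = []
    for ch in s:
        if ch.isupper():
            classes.append("X")
        elif ch.islower():
            classes.append("x")
        elif ch.isdigit():
            classes.append("d")
        else:
            classes.append(ch)
    out: list[str] = []
    i = 0
    while i < len(classes):
        j = i
        while j < len(classes) and classes[j] == classes[i]:
            j += 1
        out.append(classes[i] + ("+" if j - i > 1 else ""))
        i = j
    return "".join(out)


def internal_features(surface: str) -> dict[str, float]:
    """NER-inspired binary features derived solely from the span text."""
    if not surface:
        raise ValueError("cannot extract features from an empty surface")
    lower = surface.lower()
    feats: dict[str, float] = {f"int:text={lower}": 1.0}
    words = _word_tokens(surface)
    for tok in words:
        feats[f"int:tok={tok.lower()}"] = 1.0
    feats[f"int:ntok={len(words)}"] = 1.0
    for k in (2, 3, 4):
        if len(lower) >= k:
            feats[f"int:pre{k}={lower[:k]}"] = 1.0
            feats[f"int:suf{k}={lower[-k:]}"] = 1.0
    feats[f"int:shape={_shape(surface)}"] = 1.0
    if any(c.isdigit() for c in surface):
        feats["int:has_digit"] = 1.0
    if "-" in surface:
        feats["int:has_hyphen"] = 1.0
    if surface.isupper():
        feats["int:all_caps"] = 1.0
    for i in range(len(lower) - 1):
        feats[f"int:cb={lower[i:i+2]}"] = 1.0
    for i in range(len(lower) - 2):
        feats[f"int:ct={lower[i:i+3]}"] = 1.0
    return feats


def gazetteer_features(surface: str, resources: Mapping[str, LexicalResource],
                       config: FeatureConfig, prefix: str = "gaz") -> dict[str, float]:
    """One binary feature per resource whose strict lookup fires."""
    feats: dict[str, float] = {}
    for name in config.resources:
        if strict_lookup(resources[name], surface):
            feats[f"{prefix}:{name}"] = 1.0
    return feats


def simstring_features(surface: str, indexes: Mapping[str, SimilarityIndex],
                       config: FeatureConfig, prefix: str = "sim") -> dict[str, float]:
    """One binary feature per (resource, tau) whose approximate lookup fires.

    A single candidate scan per resource at the lowest grid threshold
    yields the maximum entry similarity, which answers every tau at once.
    """
    feats: dict[str, float] = {}
    tau_floor = min(config.taus)
    for name in config.resources:
        best = max_similarity(indexes[name], surface, tau_floor)
        for tau in config.taus:
            if best >= tau - 1e-12:
                feats[f"{prefix}:{name}@{tau:g}"] = 1.0
    return feats


def np_head(surface: str) -> tuple[str, str]:
    """Heuristic NP-head and Base-NP of a span.

    The head is the last word token strictly before the first post-modifier
    boundary — the first preposition among a small closed set, the first
    comma, or the first opening parenthesis — or the span's last word token
    when no boundary exists.  The Base-NP is the span text from its start
    through the head token inclusive.
    """
    if not surface:
        raise ValueError("cannot find the head of an empty span")
    matches = list(_TOKEN.finditer(surface))
    boundary = len(matches)
    for i, m in enumerate(matches):
        tok = m.group()
        if tok.lower() in PREPOSITIONS or tok in (",", "("):
            boundary = i
            break
    head_match = None
    for m in matches[:boundary]:
        if any(c.isalnum() for c in m.group()):
            head_match = m
    if head_match is None:
        # boundary opens the span (or no word tokens): fall back to the
        # last word token of the whole span, else the raw surface
        for m in matches:
            if any(c.isalnum() for c in m.group()):
                head_match = m
        if head_match is None:
            return surface, surface
    return head_match.group(), surface[: head_match.end()]


def np_features(surface: str, resources: Mapping[str, LexicalResource],
                indexes: Mapping[str, SimilarityIndex],
                config: FeatureConfig) -> dict[str, float]:
    """Text and lookup features for the NP-head and Base-NP subspans."""
    head, base = np_head(surface)
    feats: dict[str, float] = {
        f"np:h={head.lower()}": 1.0,
        f"np:b={base.lower()}": 1.0,
    }
    if config.use_gazetteer:
        feats.update(gazetteer_features(head, resources, config, prefix="npgaz:h"))
        feats.update(gazetteer_features(base, resources, config, prefix="npgaz:b"))
    if config.use_simstring:
        feats.update(simstring_features(head, indexes, config, prefix="npsim:h"))
        feats.update(simstring_features(base, indexes, config, prefix="npsim:b"))
    return feats


def assemble(surface: str, config: FeatureConfig,
             resources: Mapping[str, LexicalResource] | None = None,
             indexes: Mapping[str, SimilarityIndex] | None = None) -> dict[str, float]:
    """Union of the enabled families' feature vectors for one span surface."""
    feats: dict[str, float] = {}
    if config.use_internal:
        feats.update(internal_features(surface))
    if config.use_gazetteer:
        assert resources is not None
        feats.update(gazetteer_features(surface, resources, config))
    if config.use_simstring:
        assert indexes is not None
        feats.update(simstring_features(surface, indexes, config))
    if config.use_np:
        feats.update(np_features(surface, resources or {}, indexes or {}, config))
    return feats


class FeatureExtractor:
    """A configured extractor holding loaded resources and built indexes.

    Bundling the lookup state with the config makes trained models
    self-contained: predicting with a differently configured extractor is
    impossible by construction.
    """

    def __init__(self, config: FeatureConfig,
                 resources: Mapping[str, LexicalResource] | None = None) -> None:
        resources = dict(resources or {})
        missing = [r for r in config.resources if r not in resources]
        if missing:
            raise ValueError(f"config names resources not provided: {missing}")
        self.config = config
        self.resources = {name: resources[name] for name in config.resources}
        self.indexes: dict[str, SimilarityIndex] = {}
        if config.use_simstring:
            self.indexes = {
                name: SimilarityIndex(res, n=config.n)
                for name, res in self.resources.items()
            }

    def extract(self, surface: str) -> dict[str, float]:
        return assemble(surface, self.config, self.resources, self.indexes)
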