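"""Synthetic corpora and lexical resources for controlled experiments.

The generator reproduces the statistical structure that dictionary-driven
category disambiguation exploits, without any external data:

* per-category lexicons of pairwise-disjoint pronounceable strings, larger
  than any single corpus sample covers — as real gazetteers dwarf the
  vocabulary of any one annotated corpus;
* corpus spans drawn i.i.d. from a category's lexicon, with independent
  per-character edit noise (substitute/insert/delete) applied to the corpus
  surface only, so dictionaries hold canonical forms and the text holds
  variants — the regime where approximate matching beats strict matching;
* optionally, compound noun-phrase spans "X of Y" whose head X carries the
  gold category while Y comes from a different category's lexicon, the
  case NP-head features are designed for;
* resource sets at two granularities: fine (one resource per category) or
  merged (each resource is the union of >= 2 category lexicons, emulating
  coarse upper-level classes that do not distinguish the categories a task
  needs).

Filler text between spans comes from a closed token set disjoint from all
lexicons, so no accidental dictionary hits arise.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .annotation_io import AnnotatedSpan, Corpus, Document, write_standoff
from .lexicon import LexicalResource

__all__ = ["GeneratorSpec", "make_lexicons", "make_resources", "make_corpus",
           "write_fixture_tree"]

_CONSONANTS = list("bcdfghjklmnprstvwz")
_VOWELS = list("aeiou")
_ALPHABET = list("abcdefghijklmnopqrstuvwxyz")

# Closed filler vocabulary; deliberately English-like and disjoint by
# construction from the CV-syllable lexicon strings (generation rejects
# collisions).
_FILLERS = (
    "the a an and or but when while during under over after before some "
    "many few several results showed that was were been being study data "
    "analysis observed measured reported increased decreased levels values"
).split()


@dataclass(frozen=True)
class GeneratorSpec:
    """Conditions of one synthetic study."""

    n_categories: int = 5
    lexicon_size: int = 300
    n_spans: int = 700
    noise_rate: float = 0.05
    compound_fraction: float = 0.0
    resource_granularity: str = "fine"
    seed: int = 0
    spans_per_document: int = 20

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise ValueError("need >= 2 categories")
        if not (0 <= self.noise_rate < 1):
            raise ValueError("noise_rate must be in [0, 1)")
        if not (0 <= self.compound_fraction <= 1):
            raise ValueError("compound_fraction must be in [0, 1]")
        if self.resource_granularity not in ("fine", "merged"):
            raise ValueError("resource_granularity must be 'fine' or 'merged'")


def _pronounceable(rng: np.random.Generator) -> str:
    n_syll = int(rng.integers(3, 6))
    return "".join(
        rng.choice(_CONSONANTS) + rng.choice(_VOWELS) for _ in range(n_syll)
    )


def category_names(k: int) -> list[str]:
    return [f"CAT{i:02d}" for i in range(k)]


def make_lexicons(spec: GeneratorSpec) -> dict[str, LexicalResource]:
    """Pairwise-disjoint per-category lexicons, deterministic in the seed."""
    rng = np.random.default_rng(spec.seed)
    taken: set[str] = set(_FILLERS)
    lexicons: dict[str, LexicalResource] = {}
    for cat in category_names(spec.n_categories):
        entries: set[str] = set()
        while len(entries) < spec.lexicon_size:
            s = _pronounceable(rng)
            if s not in taken:
                taken.add(s)
                entries.add(s)
        lexicons[cat] = LexicalResource(name=cat, entries=frozenset(entries))
    return lexicons


def make_resources(spec: GeneratorSpec,
                   lexicons: dict[str, LexicalResource]) -> dict[str, LexicalResource]:
    """Resource set handed to the model, at the requested granularity.

    Fine granularity returns the per-category lexicons themselves.  Merged
    granularity partitions categories into consecutive groups of two (an
    odd remainder joins the last group) and returns one union resource per
    group, so category identity within a group is unrecoverable from
    lookups alone.
    """
    if spec.resource_granularity == "fine":
        return dict(lexicons)
    cats = list(lexicons)
    groups: list[list[str]] = [cats[i : i + 2] for i in range(0, len(cats) - 1, 2)]
    if len(cats) % 2:
        groups[-1].append(cats[-1])
    merged: dict[str, LexicalResource] = {}
    for group in groups:
        name = "MERGED_" + "_".join(group)
        entries = frozenset().union(*(lexicons[c].entries for c in group))
        merged[name] = LexicalResource(name=name, entries=entries)
    return merged


def _apply_noise(s: str, noise_rate: float, rng: np.random.Generator) -> str:
    """Independent per-character substitute/insert/delete edits."""
    if noise_rate == 0:
        return s
    out: list[str] = []
    for ch in s:
        if ch == " " or rng.random() >= noise_rate:
            out.append(ch)
            continue
        op = rng.integers(3)
        if op == 0:  # substitute
            out.append(str(rng.choice(_ALPHABET)))
        elif op == 1:  # insert before
            out.append(str(rng.choice(_ALPHABET)))
            out.append(ch)
        # op == 2: delete
    return "".join(out) if out else s


def make_corpus(spec: GeneratorSpec,
                lexicons: dict[str, LexicalResource]) -> Corpus:
    """Documents of filler tokens with embedded annotated spans.

    Each span's gold category is drawn uniformly; its surface is a lexicon
    entry of that category passed through the edit-noise channel.  With
    probability ``compound_fraction`` the span is instead the compound
    "X of Y" with X from the gold category and Y from a different one.
    """
    rng = np.random.default_rng(spec.seed + 1)
    cats = list(lexicons)
    entry_lists = {c: sorted(lexicons[c].entries) for c in cats}

    documents: dict[str, Document] = {}
    spans: list[AnnotatedSpan] = []
    n_docs = max(1, -(-spec.n_spans // spec.spans_per_document))
    span_budget = spec.n_spans
    for d in range(n_docs):
        doc_id = f"doc{d:04d}"
        pieces: list[str] = []
        pos = 0
        k = min(spec.spans_per_document, span_budget)
        span_budget -= k
        for _ in range(k):
            n_fill = int(rng.integers(2, 6))
            filler = " ".join(rng.choice(_FILLERS) for _ in range(n_fill))
            pieces.append(filler)
            pos += len(filler) + 1
            cat = cats[int(rng.integers(len(cats)))]
            entry = entry_lists[cat][int(rng.integers(len(entry_lists[cat])))]
            if rng.random() < spec.compound_fraction:
                other = cats[int(rng.integers(len(cats)))]
                while other == cat:
                    other = cats[int(rng.integers(len(cats)))]
                mod = entry_lists[other][int(rng.integers(len(entry_lists[other])))]
                surface = (_apply_noise(entry, spec.noise_rate, rng)
                           + " of "
                           + _apply_noise(mod, spec.noise_rate, rng))
            else:
                surface = _apply_noise(entry, spec.noise_rate, rng)
            pieces.append(surface)
            spans.append(AnnotatedSpan(doc_id=doc_id, start=pos,
                                       end=pos + len(surface), category=cat,
                                       surface=surface))
            pos += len(surface) + 1
        pieces.append("end")
        text = " ".join(pieces)
        documents[doc_id] = Document(doc_id=doc_id, text=text)

    return Corpus(documents=documents, spans=spans, categories=tuple(cats))


def write_fixture_tree(spec: GeneratorSpec, outdir: str | Path) -> Path:
    """Materialise a complete fixture: txt/ann corpus, dictionaries,
    resource manifest, and the generator spec echoed as config."""
    outdir = Path(outdir)
    lexicons = make_lexicons(spec)
    resources = make_resources(spec, lexicons)
    corpus = make_corpus(spec, lexicons)

    write_standoff(corpus, outdir / "corpus")
    dict_dir = outdir / "dicts"
    dict_dir.mkdir(parents=True, exist_ok=True)
    manifest_lines = []
    for name, res in resources.items():
        fname = f"{name}.dic"
        (dict_dir / fname).write_text(
            "\n".join(sorted(res.entries)) + "\n", encoding="utf-8"
        )
        manifest_lines.append(f"{name}\t{fname}")
    (dict_dir / "manifest.tsv").write_text(
        "\n".join(manifest_lines) + "\n", encoding="utf-8"
    )
    (outdir / "generator.json").write_text(
        json.dumps(asdict(spec), indent=2) + "\n", encoding="utf-8"
    )
    return outdir
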