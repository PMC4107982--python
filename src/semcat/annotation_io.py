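"""Standoff-annotated corpus I/O, pre-processing, and sampling.

Corpora are stored brat-style: a plain-text document ``doc.txt`` plus a
``doc.ann`` file of tab-separated textbound lines

    T<id>\\t<Category> <start> <end>\\t<surface>

with 0-based, half-open character offsets counted in Unicode code points.
Discontinuous textbounds (``<s1> <e1>;<s2> <e2>`` fragment lists) are
accepted and merged into their covering span.  A flat TSV span format
(``doc_id  start  end  category  surface``) is also supported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Document",
    "AnnotatedSpan",
    "Corpus",
    "read_standoff",
    "write_standoff",
    "read_tsv",
    "write_tsv",
    "merge_discontinuous",
    "collapse_categories",
    "split_corpus",
    "subsample",
]


@dataclass(frozen=True)
class Document:
    """A plain-text document identified by an opaque id."""

    doc_id: str
    text: str


@dataclass(frozen=True)
class AnnotatedSpan:
    """A contiguous character range in a document with its semantic category.

    Offsets are 0-based and half-open; ``surface`` must equal the document
    text slice ``[start, end)``.  Spans may overlap and nest freely.
    """

    doc_id: str
    start: int
    end: int
    category: str
    surface: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid span offsets [{self.start}, {self.end}) in {self.doc_id!r}"
            )


@dataclass
class Corpus:
    """Documents plus span annotations over a fixed category inventory.

    ``categories`` is an ordered inventory; every span's category must be a
    member, and every span's ``doc_id`` must resolve to a document.  Splits
    and subsamples keep the parent inventory so that ambiguity-reduction
    normalisation is computed against the full candidate set.
    """

    documents: dict[str, Document] = field(default_factory=dict)
    spans: list[AnnotatedSpan] = field(default_factory=list)
    categories: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        cats = set(self.categories)
        for sp in self.spans:
            if sp.doc_id not in self.documents:
                raise ValueError(f"span references unknown document {sp.doc_id!r}")
            doc = self.documents[sp.doc_id]
            if sp.end > len(doc.text):
                raise ValueError(
                    f"span [{sp.start}, {sp.end}) exceeds text of {sp.doc_id!r} "
                    f"(length {len(doc.text)})"
                )
            if doc.text[sp.start : sp.end] != sp.surface:
                raise ValueError(
                    f"surface mismatch in {sp.doc_id!r} at [{sp.start}, {sp.end}): "
                    f"annotation {sp.surface!r} vs text "
                    f"{doc.text[sp.start:sp.end]!r}"
                )
            if sp.category not in cats:
                raise ValueError(
                    f"span category {sp.category!r} not in inventory {self.categories}"
                )

    @property
    def n_spans(self) -> int:
        return len(self.spans)

    def with_spans(self, spans: Sequence[AnnotatedSpan]) -> "Corpus":
        """A corpus sharing this one's documents and inventory."""
        return Corpus(documents=self.documents, spans=list(spans), categories=self.categories)


def merge_discontinuous(fragments: Sequence[AnnotatedSpan]) -> AnnotatedSpan:
    """Merge fragments of one discontinuous annotation into a covering span.

    Returns a single span from ``min(start)`` to ``max(end)``; the caller is
    responsible for re-reading the surface from the text and for dropping
    any duplicate (doc, start, end, category) tuples created corpus-wide.
    """
    if not fragments:
        raise ValueError("no fragments to merge")
    doc_ids = {f.doc_id for f in fragments}
    if len(doc_ids) > 1:
        raise ValueError(f"fragments span multiple documents: {sorted(doc_ids)}")
    cats = {f.category for f in fragments}
    if len(cats) > 1:
        raise ValueError(f"fragments disagree on category: {sorted(cats)}")
    start = min(f.start for f in fragments)
    end = max(f.end for f in fragments)
    # surface is a placeholder here; read_standoff re-slices from the text
    return AnnotatedSpan(
        doc_id=fragments[0].doc_id,
        start=start,
        end=end,
        category=fragments[0].category,
        surface="".join(f.surface for f in sorted(fragments, key=lambda f: f.start)),
    )


def _parse_textbound(line: str, lineno: int, ann_path: Path):
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 2:
        raise ValueError(f"{ann_path}:{lineno}: malformed textbound line {line!r}")
    tid = parts[0]
    header = parts[1]
    given_text = parts[2] if len(parts) > 2 else None
    try:
        category, offs = header.split(" ", 1)
        frags = []
        for piece in offs.split(";"):
            s, e = piece.split()
            frags.append((int(s), int(e)))
    except ValueError as exc:
        raise ValueError(f"{ann_path}:{lineno}: cannot parse offsets in {line!r}") from exc
    return tid, category, frags, given_text


def read_standoff(ann_path: str | Path, txt_path: str | Path, doc_id: str | None = None) -> Corpus:
    """Read one brat document pair into a single-document corpus fragment.

    Only textbound (``T``) lines define spans; relation/event/attribute
    lines are skipped with a logged count.  Offsets out of range and
    surface-text mismatches are hard errors (corpus corruption).
    Discontinuous fragment lists are merged into covering spans and
    duplicates created by merging are dropped.
    """
    ann_path = Path(ann_path)
    txt_path = Path(txt_path)
    text = txt_path.read_text(encoding="utf-8")
    if doc_id is None:
        doc_id = txt_path.stem
    doc = Document(doc_id=doc_id, text=text)

    spans: list[AnnotatedSpan] = []
    seen: set[tuple[str, int, int, str]] = set()
    n_skipped = 0
    for lineno, line in enumerate(ann_path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        if not line.startswith("T"):
            n_skipped += 1
            continue
        _tid, category, frags, given_text = _parse_textbound(line, lineno, ann_path)
        for s, e in frags:
            if not (0 <= s < e <= len(text)):
                raise ValueError(
                    f"{ann_path}:{lineno}: offsets [{s}, {e}) out of range for "
                    f"text of length {len(text)}"
                )
        if given_text is not None:
            # brat joins discontinuous fragment texts with a single space
            expected = " ".join(text[s:e] for s, e in frags)
            if given_text != expected:
                raise ValueError(
                    f"{ann_path}:{lineno}: surface mismatch: annotation "
                    f"{given_text!r} vs text {expected!r}"
                )
        merged = merge_discontinuous(
            [
                AnnotatedSpan(doc_id=doc_id, start=s, end=e, category=category,
                              surface=text[s:e])
                for s, e in frags
            ]
        )
        start, end = merged.start, merged.end
        key = (doc_id, start, end, category)
        if key in seen:
            continue
        seen.add(key)
        spans.append(
            AnnotatedSpan(doc_id=doc_id, start=start, end=end, category=category,
                          surface=text[start:end])
        )
    if n_skipped:
        logger.info("%s: skipped %d non-textbound lines", ann_path, n_skipped)

    categories = tuple(dict.fromkeys(sp.category for sp in spans))
    return Corpus(documents={doc_id: doc}, spans=spans, categories=categories)


def read_standoff_dir(directory: str | Path) -> Corpus:
    """Read every ``*.txt``/``*.ann`` pair under a directory into one corpus."""
    directory = Path(directory)
    docs: dict[str, Document] = {}
    spans: list[AnnotatedSpan] = []
    cats: dict[str, None] = {}
    txts = sorted(directory.glob("*.txt"))
    if not txts:
        raise ValueError(f"no .txt documents under {directory}")
    for txt in txts:
        ann = txt.with_suffix(".ann")
        if not ann.exists():
            raise ValueError(f"missing annotation file {ann}")
        frag = read_standoff(ann, txt)
        docs.update(frag.documents)
        spans.extend(frag.spans)
        for c in frag.categories:
            cats[c] = None
    return Corpus(documents=docs, spans=spans, categories=tuple(cats))


def write_standoff(corpus: Corpus, directory: str | Path) -> None:
    """Write one ``.txt``/``.ann`` pair per document under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    by_doc: dict[str, list[AnnotatedSpan]] = {d: [] for d in corpus.documents}
    for sp in corpus.spans:
        by_doc[sp.doc_id].append(sp)
    for doc_id, doc in corpus.documents.items():
        (directory / f"{doc_id}.txt").write_text(doc.text, encoding="utf-8")
        lines = []
        for i, sp in enumerate(sorted(by_doc[doc_id], key=lambda s: (s.start, s.end)), 1):
            lines.append(f"T{i}\t{sp.category} {sp.start} {sp.end}\t{sp.surface}")
        (directory / f"{doc_id}.ann").write_text(
            "\n".join(lines) + ("\n" if lines else ""), encoding="utf-8"
        )


def read_tsv(path: str | Path, documents: Mapping[str, Document] | None = None) -> Corpus:
    """Read the flat TSV span format: doc_id, start, end, category, surface.

    Without a ``documents`` mapping, minimal documents are synthesised so
    that each surface matches its slice (padding with spaces); this supports
    span-only workflows where the original text is unavailable.
    """
    path = Path(path)
    rows: list[tuple[str, int, int, str, str]] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if lineno == 1 and parts[:2] == ["doc_id", "start"]:
            continue
        if len(parts) != 5:
            raise ValueError(f"{path}:{lineno}: expected 5 tab-separated fields")
        doc_id, start, end, category, surface = parts
        rows.append((doc_id, int(start), int(end), category, surface))

    if documents is None:
        texts: dict[str, list[str]] = {}
        for doc_id, start, end, _cat, surface in rows:
            buf = texts.setdefault(doc_id, [])
            if len(buf) < end:
                buf.extend(" " * (end - len(buf)))
            buf[start:end] = list(surface)
        documents = {d: Document(d, "".join(chars)) for d, chars in texts.items()}

    spans = [
        AnnotatedSpan(doc_id=d, start=s, end=e, category=c, surface=surf)
        for d, s, e, c, surf in rows
    ]
    categories = tuple(dict.fromkeys(sp.category for sp in spans))
    return Corpus(documents=dict(documents), spans=spans, categories=categories)


def write_tsv(corpus: Corpus, path: str | Path) -> None:
    path = Path(path)
    lines = ["doc_id\tstart\tend\tcategory\tsurface"]
    for sp in corpus.spans:
        lines.append(f"{sp.doc_id}\t{sp.start}\t{sp.end}\t{sp.category}\t{sp.surface}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def collapse_categories(corpus: Corpus, mapping: Mapping[str, str]) -> Corpus:
    """Rewrite categories through ``mapping``; unmapped categories pass through.

    Duplicate (doc, start, end, category) tuples created by the collapse are
    dropped.  The inventory is recomputed, keeping first-appearance order of
    the rewritten labels; producing an empty inventory is an error.
    """
    new_inventory: dict[str, None] = {}
    for c in corpus.categories:
        new_inventory[mapping.get(c, c)] = None
    if not new_inventory:
        raise ValueError("collapse produced an empty category inventory")

    seen: set[tuple[str, int, int, str]] = set()
    new_spans: list[AnnotatedSpan] = []
    for sp in corpus.spans:
        cat = mapping.get(sp.category, sp.category)
        key = (sp.doc_id, sp.start, sp.end, cat)
        if key in seen:
            continue
        seen.add(key)
        new_spans.append(replace(sp, category=cat))
    return Corpus(documents=corpus.documents, spans=new_spans,
                  categories=tuple(new_inventory))


def split_corpus(corpus: Corpus, seed: int) -> tuple[Corpus, Corpus, Corpus]:
    """Randomly partition spans into train/dev/test at ratios 1/2, 1/4, 1/4.

    The split is by annotation, not by document: spans of one document may
    land in different folds.  Rounding: train gets ceil(n/2) spans, dev gets
    ceil(remainder/2).  Deterministic in ``seed``; the inventory and the
    document store are shared by all three parts.
    """
    n = corpus.n_spans
    if n < 4:
        raise ValueError(f"corpus has only {n} spans; need >= 4 to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = math.ceil(n / 2)
    n_dev = math.ceil((n - n_train) / 2)
    idx_train = sorted(order[:n_train])
    idx_dev = sorted(order[n_train : n_train + n_dev])
    idx_test = sorted(order[n_train + n_dev :])
    pick = lambda idx: corpus.with_spans([corpus.spans[i] for i in idx])
    return pick(idx_train), pick(idx_dev), pick(idx_test)


def subsample(corpus: Corpus, fraction: float, seed: int) -> Corpus:
    """Uniform random subset of spans, without replacement.

    Size is ``floor(fraction * n + 0.5)``; ``fraction=1.0`` returns the
    span list unchanged.  An empty result is an error.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = corpus.n_spans
    if fraction == 1.0:
        return corpus.with_spans(list(corpus.spans))
    k = int(math.floor(fraction * n + 0.5))
    if k < 1:
        raise ValueError(f"fraction {fraction} of {n} spans yields an empty sample")
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(n, size=k, replace=False))
    return corpus.with_spans([corpus.spans[i] for i in idx])
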