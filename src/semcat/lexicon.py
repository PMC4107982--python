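"""Lexical resources with strict and approximate dictionary lookup.

A lexical resource is a named set of dictionary entries representing one
semantic class, read from a UTF-8 file with one entry per line.  Lookup
comes in two flavours:

* **strict** — exact set membership after text normalisation;
* **approximate** — cosine similarity over padded character n-gram
  multisets against an inverted index, thresholded at ``tau``.  Candidate
  generation exploits the bound that two profiles of sizes ``|p|`` and
  ``|q|`` can only reach cosine ``tau`` when
  ``ceil(tau^2 * |p|) <= |q| <= floor(|p| / tau^2)``, so the index buckets
  entries by profile size and scans only sizes inside that band.

``oracle_lookup`` is the exhaustive-scan reference with the identical
contract, kept as an independent check on the index.
"""

from __future__ import annotations

import math
import re
import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = [
    "LexicalResource",
    "NGramProfile",
    "SimilarityIndex",
    "normalize",
    "load_resource",
    "load_manifest",
    "ngram_profile",
    "cosine_similarity",
    "strict_lookup",
    "approx_lookup",
    "oracle_lookup",
    "max_similarity",
]

# Padding markers for n-gram profiles; control characters keep them outside
# any realistic entry alphabet.
BOS = "\x02"
EOS = "\x03"

_WS = re.compile(r"\s+")


def normalize(s: str) -> str:
    """Canonical text form used for all lookups.

    Unicode NFKC, case-folded, internal whitespace collapsed to single
    spaces, stripped.  Dictionary and corpus casing conventions differ, so
    matching is done in this normalised space on both sides.
    """
    return _WS.sub(" ", unicodedata.normalize("NFKC", s).casefold()).strip()


@dataclass(frozen=True)
class LexicalResource:
    """A named set of dictionary entries for one semantic class."""

    name: str
    entries: frozenset[str]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError(f"resource {self.name!r} has no entries")
        if "" in self.entries:
            raise ValueError(f"resource {self.name!r} contains an empty entry")

    @property
    def normalized(self) -> frozenset[str]:
        return frozenset(filter(None, (normalize(e) for e in self.entries)))


def load_resource(path: str | Path, name: str | None = None) -> LexicalResource:
    """Load a one-entry-per-line dictionary file.

    Blank lines are dropped and duplicates collapsed; an empty resource is
    an error.
    """
    path = Path(path)
    if name is None:
        name = path.stem
    entries = frozenset(
        line for line in path.read_text(encoding="utf-8").splitlines() if line.strip()
    )
    if not entries:
        raise ValueError(f"resource file {path} is empty")
    return LexicalResource(name=name, entries=entries)


def load_manifest(path: str | Path) -> dict[str, LexicalResource]:
    """Load a resource manifest mapping resource name -> dictionary path.

    The manifest is a two-column TSV (``name<TAB>path``); relative paths
    resolve against the manifest's directory.
    """
    path = Path(path)
    resources: dict[str, LexicalResource] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        try:
            name, rel = line.split("\t")
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: expected 'name<TAB>path'") from exc
        resources[name] = load_resource((path.parent / rel), name)
    if not resources:
        raise ValueError(f"manifest {path} lists no resources")
    return resources


@dataclass(frozen=True)
class NGramProfile:
    """Multiset of padded character n-grams of one string.

    For a string ``s`` padded with ``n-1`` begin and ``n-1`` end markers the
    profile holds exactly ``len(s) + n - 1`` grams.
    """

    grams: tuple[tuple[str, int], ...]  # sorted (gram, count) pairs
    n: int
    source_length: int

    def counter(self) -> Counter:
        return Counter(dict(self.grams))


def ngram_profile(s: str, n: int) -> NGramProfile:
    """Build the padded character n-gram multiset profile of ``s``."""
    if n < 1:
        raise ValueError(f"gram length must be >= 1, got {n}")
    if not s:
        raise ValueError("cannot profile an empty string")
    padded = BOS * (n - 1) + s + EOS * (n - 1)
    grams = Counter(padded[i : i + n] for i in range(len(padded) - n + 1))
    return NGramProfile(
        grams=tuple(sorted(grams.items())), n=n, source_length=sum(grams.values())
    )


def cosine_similarity(p: NGramProfile, q: NGramProfile) -> float:
    """Multiset cosine: |p ∩ q| / sqrt(|p| |q|), intersection by min counts."""
    if p.n != q.n:
        raise ValueError(f"profiles have different gram lengths: {p.n} vs {q.n}")
    cp, cq = dict(p.grams), dict(q.grams)
    if len(cp) > len(cq):
        cp, cq = cq, cp
    overlap = sum(min(c, cq[g]) for g, c in cp.items() if g in cq)
    return overlap / math.sqrt(p.source_length * q.source_length)


def strict_lookup(resource: LexicalResource, s: str) -> bool:
    """Exact membership of the normalised span text in the resource."""
    return normalize(s) in resource.normalized


class SimilarityIndex:
    """Inverted character n-gram index over one resource, bucketed by size.

    Entries are normalised once at build time.  Query evaluation is exact:
    candidates are generated from shared grams within the profile-size band
    and then verified with full multiset cosine, so results match the
    brute-force oracle identically.
    """

    def __init__(self, resource: LexicalResource, n: int = 3) -> None:
        self.resource = resource
        self.n = n
        self._profiles: list[NGramProfile] = []
        # size -> gram -> entry ids
        self._buckets: dict[int, dict[str, list[int]]] = {}
        for entry in sorted(resource.normalized):
            prof = ngram_profile(entry, n)
            eid = len(self._profiles)
            self._profiles.append(prof)
            bucket = self._buckets.setdefault(prof.source_length, {})
            for gram, _cnt in prof.grams:
                bucket.setdefault(gram, []).append(eid)

    def max_candidate_similarity(self, s: str, tau: float) -> float:
        """Highest cosine similarity to any entry reachable at threshold tau.

        Entries whose profile size lies outside
        ``[ceil(tau^2 |p|), floor(|p| / tau^2)]`` cannot reach ``tau`` and
        are never scanned, so the returned value is only guaranteed to be
        the true maximum when that maximum is >= tau.
        """
        q = normalize(s)
        if not q:
            return 0.0
        prof = ngram_profile(q, self.n)
        L = prof.source_length
        lo = math.ceil(tau * tau * L - 1e-12)
        hi = math.floor(L / (tau * tau) + 1e-12)
        best = 0.0
        for size, bucket in self._buckets.items():
            if not (lo <= size <= hi):
                continue
            cand: set[int] = set()
            for gram, _cnt in prof.grams:
                cand.update(bucket.get(gram, ()))
            for eid in cand:
                sim = cosine_similarity(prof, self._profiles[eid])
                if sim > best:
                    best = sim
        return best


def approx_lookup(index: SimilarityIndex, s: str, tau: float) -> bool:
    """True iff some entry's n-gram cosine similarity to ``s`` reaches tau."""
    if not (0 < tau <= 1):
        raise ValueError(f"tau must be in (0, 1], got {tau}")
    return index.max_candidate_similarity(s, tau) >= tau - 1e-12


def max_similarity(index: SimilarityIndex, s: str, tau_floor: float) -> float:
    """Max entry similarity, exact whenever it is >= ``tau_floor``.

    Feature generation queries a grid of thresholds; one scan at the grid's
    lowest threshold answers all of them.
    """
    return index.max_candidate_similarity(s, tau_floor)


def oracle_lookup(resource: LexicalResource, s: str, tau: float, n: int = 3) -> bool:
    """Exhaustive-scan reference implementation of ``approx_lookup``."""
    if not (0 < tau <= 1):
        raise ValueError(f"tau must be in (0, 1], got {tau}")
    q = normalize(s)
    if not q:
        return False
    prof = ngram_profile(q, n)
    for entry in resource.normalized:
        if cosine_similarity(prof, ngram_profile(entry, n)) >= tau - 1e-12:
            return True
    return False
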