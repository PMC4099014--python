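"""Lexical primitives behind the concept-name similarity measure.

Names are normalised (case-folded, hyphens/underscores removed, plural
nouns reduced to singular) before comparison.  Two normalised names score 1
when identical or listed as synonyms in the active lexicon; otherwise the
score is one minus the Levenshtein distance divided by the longer length.
"""

from __future__ import annotations

import re
from typing import Iterable, List, Set

import edlib

__all__ = [
    "SynonymLexicon",
    "normalize",
    "edit_distance",
    "name_similarity",
    "DegenerateNameError",
]


class DegenerateNameError(ValueError):
    """Both names normalise to the empty string; similarity is undefined."""


_SEPARATORS = re.compile(r"[-_]")


def _singularize(token: str) -> str:
    # Small deterministic suffix-rule list; no external morphology engine.
    if len(token) > 3 and token.endswith("ies"):
        return token[:-3] + "y"
    if token.endswith("ses"):
        return token[:-2]
    if token.endswith("ss") or token.endswith("us"):
        return token
    if token.endswith("s"):
        return token[:-1]
    return token


def normalize(name: str) -> str:
    """Canonical comparison form of a label.

    Lower-cases, deletes hyphens and underscores, reduces trailing plurals
    per whitespace token, and concatenates tokens.  Idempotent.
    """
    folded = _SEPARATORS.sub("", name.lower())
    return "".join(_singularize(tok) for tok in folded.split())


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance with unit-cost insert/delete/substitute."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b)["editDistance"]


class SynonymLexicon:
    """Sets of interchangeable labels, queried on normalised forms.

    The lexicon plays the role a general-purpose thesaurus plays in concept
    matching: names inside a common synset count as an exact match.  Members
    are normalised on construction so lookups are insensitive to case,
    separators and plurals.
    """

    def __init__(self, synsets: Iterable[Iterable[str]] = ()):
        self.synsets: List[Set[str]] = []
        for members in synsets:
            normed = {normalize(m) for m in members if normalize(m)}
            if normed:
                self.synsets.append(normed)

    def __len__(self) -> int:
        return len(self.synsets)

    def are_synonyms(self, a: str, b: str) -> bool:
        """True iff the normalised forms co-occur in some synset (or are equal)."""
        na, nb = normalize(a), normalize(b)
        if na == nb:
            return bool(na)
        return any(na in s and nb in s for s in self.synsets)


#: Empty lexicon used when no synonym resource is supplied.
EMPTY_LEXICON = SynonymLexicon()


def name_similarity(a: str, b: str, lexicon: SynonymLexicon | None = None) -> float:
    """Similarity of two labels in [0, 1].

    1.0 on exact normalised match or lexicon synonymy; otherwise
    ``1 - d / L`` where ``d`` is the Levenshtein distance between the
    normalised forms and ``L`` the longer normalised length, clamped at 0.
    """
    lex = lexicon if lexicon is not None else EMPTY_LEXICON
    na, nb = normalize(a), normalize(b)
    if not na and not nb:
        raise DegenerateNameError(
            f"both names normalise to empty strings: {a!r}, {b!r}"
        )
    if na == nb or lex.are_synonyms(na, nb):
        return 1.0
    longer = max(len(na), len(nb))
    return max(0.0, 1.0 - edit_distance(na, nb) / longer)
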