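"""Dictionary-constrained recovery of drug names from noisy OCR tokens.

OCR output over a printed drug bag is a stream of short text fragments:
drug names (possibly split across word boxes), dosage remnants, headers and
instructions.  Each fragment is resolved against the drug catalog by
normalized Levenshtein similarity

    sim(a, b) = 1 - lev(a, b) / max(|a|, |b|)

on NFC-normalized, case-folded text, and accepted when the best catalog
entry scores at or above a threshold (default 0.7, the operating point at
which dictionary-constrained extraction performs best).  A second pass
retries concatenations of adjacent unmatched tokens, because multi-word
names are frequently split across OCR word boxes.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

from .catalog import DrugCatalog, casefold_key, normalize_name

if TYPE_CHECKING:  # pragma: no cover
    from .ocr import OcrToken

__all__ = [
    "DEFAULT_THRESHOLD",
    "MatchResult",
    "edit_distance",
    "similarity",
    "match_token",
    "extract_drug_names",
    "accepted_names",
]

#: Minimal similarity for accepting a token as a catalog entry.
DEFAULT_THRESHOLD = 0.7


@dataclass(frozen=True)
class MatchResult:
    """Outcome of resolving one OCR fragment against the catalog."""

    token_text: str
    matched_name: str | None
    similarity: float
    accepted: bool
    merged: bool = False  # produced by the adjacent-token second pass

    def __post_init__(self) -> None:
        assert 0.0 <= self.similarity <= 1.0
        assert self.accepted == (self.matched_name is not None)


def _fold(text: str) -> str:
    return unicodedata.normalize("NFC", text).casefold()


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance with unit-cost insert/delete/substitute.

    Computed on NFC-normalized, case-folded text, so ``"ACER" == "acer"``
    and a decomposed Korean syllable equals its composed form.
    """
    a, b = _fold(a), _fold(b)
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    # Two-row DP; prev[j] = distance between a[:i] and b[:j].
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        curr = [i]
        for j, cb in enumerate(b, start=1):
            curr.append(min(
                prev[j] + 1,                       # delete from a
                curr[j - 1] + 1,                   # insert into a
                prev[j - 1] + (ca != cb),          # substitute / match
            ))
        prev = curr
    return prev[-1]


def similarity(a: str, b: str) -> float:
    """Normalized Levenshtein similarity in [0, 1]; 1.0 iff the case-folded
    NFC forms are equal (both-empty included), 0.0 at total mismatch."""
    longest = max(len(_fold(a)), len(_fold(b)))
    if longest == 0:
        return 1.0
    return 1.0 - edit_distance(a, b) / longest


def match_token(
    token: str, catalog: DrugCatalog, threshold: float = DEFAULT_THRESHOLD
) -> MatchResult:
    """Resolve one token to its most similar catalog entry.

    Ties on similarity break toward the longer entry, then lexicographically,
    so the result is deterministic for any catalog ordering.  An empty or
    whitespace-only token is never accepted.

    Raises
    ------
    ValueError
        If the catalog is empty or the threshold is outside [0, 1].
    """
    if not len(catalog):
        raise ValueError("cannot match against an empty catalog")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if not token.strip():
        return MatchResult(token, None, 0.0, False)

    best_name: str | None = None
    best_sim = -1.0
    for entry in catalog:
        s = similarity(token, entry)
        if best_name is None or s > best_sim:
            best_name, best_sim = entry, s
        elif s == best_sim and _prefer(entry, best_name):
            best_name = entry
    accepted = best_sim >= threshold
    return MatchResult(
        token_text=token,
        matched_name=best_name if accepted else None,
        similarity=max(best_sim, 0.0),
        accepted=accepted,
    )


def _prefer(candidate: str, incumbent: str) -> bool:
    """Tie-break at equal similarity: longer entry wins, then the
    lexicographically earlier one."""
    if len(candidate) != len(incumbent):
        return len(candidate) > len(incumbent)
    return candidate < incumbent


def _safe_normalize(text: str) -> str:
    """Token-level normalization; OCR junk that normalizes to nothing
    (e.g. a bare dosage fragment) becomes the empty string."""
    try:
        return normalize_name(text)
    except Exception:
        return ""


def extract_drug_names(
    tokens: Sequence["OcrToken | str"],
    catalog: DrugCatalog,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[MatchResult]:
    """Two-pass extraction of drug names from a token stream.

    Pass 1 matches each token (after per-token normalization) on its own.
    Pass 2 walks adjacent token pairs in reading order: where neither member
    matched alone, their space-joined concatenation is tried, recovering
    names split across OCR word boxes.  A successful merge consumes both
    tokens; the returned list is in reading order with merged results
    replacing their constituents.
    """
    texts = [t if isinstance(t, str) else t.text for t in tokens]
    if not texts:
        return []
    singles = [
        match_token(_safe_normalize(t), catalog, threshold) if t.strip()
        else MatchResult(t, None, 0.0, False)
        for t in texts
    ]
    results: list[MatchResult] = []
    i = 0
    while i < len(texts):
        if (
            not singles[i].accepted
            and i + 1 < len(texts)
            and not singles[i + 1].accepted
        ):
            joined = _safe_normalize(f"{texts[i]} {texts[i + 1]}")
            if joined:
                merged = match_token(joined, catalog, threshold)
                if merged.accepted:
                    results.append(MatchResult(
                        token_text=joined,
                        matched_name=merged.matched_name,
                        similarity=merged.similarity,
                        accepted=True,
                        merged=True,
                    ))
                    i += 2
                    continue
        results.append(
            MatchResult(texts[i], singles[i].matched_name,
                        singles[i].similarity, singles[i].accepted)
        )
        i += 1
    return results


def accepted_names(results: Sequence[MatchResult]) -> list[str]:
    """Accepted names in first-occurrence order, deduplicated
    case-insensitively."""
    seen: set[str] = set()
    out: list[str] = []
    for r in results:
        if r.accepted and r.matched_name is not None:
            key = casefold_key(r.matched_name)
            if key not in seen:
                seen.add(key)
                out.append(r.matched_name)
    return out
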