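"""OCR extraction quality metrics.

Three metrics quantify how well drug names are recovered from a bag:

* **package accuracy** — the fraction of a package's expected names exactly
  recovered; with the standard 8-name package each name contributes 0.125.
* **CER** — character error rate, ``(S + D + I) / N``: the minimal number of
  character substitutions, deletions and insertions turning the reference
  into the hypothesis, over the reference length ``N``.  Characters are NFC
  code points, so one Korean syllable block counts as one character.  Can
  exceed 1 when the hypothesis is much longer than the reference.
* **WER** — the same edit-error rate at word granularity, with ``N`` the
  number of reference words (drug names per bag).

Any minimal-cost alignment may split the edits differently among S/D/I, but
their sum is the Levenshtein distance and thus invariant; only the sum is
reported.  Corpus-level CER and WER pool edits over pooled reference length
(sum of edits / sum of lengths), not a mean of per-case rates, so every
reference character and word carries equal weight.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass
from typing import Hashable, Sequence

from .catalog import InvalidInputError, casefold_key
from .matching import edit_distance

__all__ = [
    "DEFAULT_PACKAGE_SIZE",
    "EvalSummary",
    "character_error_rate",
    "word_error_rate",
    "package_accuracy",
    "evaluate_corpus",
]

DEFAULT_PACKAGE_SIZE = 8


def _sequence_edit_distance(ref: Sequence[Hashable], hyp: Sequence[Hashable]) -> int:
    """Levenshtein distance over arbitrary item sequences (unit costs)."""
    if len(ref) < len(hyp):
        ref, hyp = hyp, ref
    prev = list(range(len(hyp) + 1))
    for i, r in enumerate(ref, start=1):
        curr = [i]
        for j, h in enumerate(hyp, start=1):
            curr.append(min(prev[j] + 1, curr[j - 1] + 1, prev[j - 1] + (r != h)))
        prev = curr
    return prev[-1]


def character_error_rate(reference: str, hypothesis: str) -> float:
    """``(S + D + I) / N`` at character level, N = reference length (NFC).

    Raises
    ------
    InvalidInputError
        If the reference is empty (the metric is undefined at N = 0).
    """
    ref = unicodedata.normalize("NFC", reference)
    if not ref:
        raise InvalidInputError("CER undefined for an empty reference")
    return edit_distance(reference, hypothesis) / len(ref)


def word_error_rate(
    reference_words: Sequence[str], hypothesis_words: Sequence[str]
) -> float:
    """``(S + D + I) / N`` at word level, N = number of reference words.

    Words are compared case-insensitively on NFC forms, consistent with
    name matching elsewhere in the pipeline.
    """
    if not reference_words:
        raise InvalidInputError("WER undefined for an empty reference")
    ref = [casefold_key(w) for w in reference_words]
    hyp = [casefold_key(w) for w in hypothesis_words]
    return _sequence_edit_distance(ref, hyp) / len(ref)


def package_accuracy(
    expected: Sequence[str],
    extracted: Sequence[str],
    package_size: int = DEFAULT_PACKAGE_SIZE,
) -> float:
    """Fraction of expected package names exactly recovered.

    Each of the ``package_size`` expected names contributes
    ``1 / package_size`` (0.125 for the standard 8-name package) when its
    normalized form appears in ``extracted``; 1.0 means all names were
    precisely extracted.

    Raises
    ------
    InvalidInputError
        If ``expected`` does not have exactly ``package_size`` names.
    """
    if len(expected) != package_size:
        raise InvalidInputError(
            f"expected {package_size} package names, got {len(expected)}"
        )
    extracted_keys = {casefold_key(name) for name in extracted}
    hits = sum(casefold_key(name) in extracted_keys for name in expected)
    return hits / package_size


@dataclass(frozen=True)
class EvalSummary:
    """Corpus-level aggregation over (expected, extracted) name-list cases."""

    total_words: int
    recognized_words: int
    correct_words: int
    accuracy: float
    wer: float
    cer: float

    def __post_init__(self) -> None:
        assert 0 <= self.correct_words <= self.total_words

    def to_dict(self) -> dict[str, float | int]:
        return {
            "total_words": self.total_words,
            "recognized_words": self.recognized_words,
            "correct_words": self.correct_words,
            "accuracy": self.accuracy,
            "wer": self.wer,
            "cer": self.cer,
        }


def evaluate_corpus(
    cases: Sequence[tuple[Sequence[str], Sequence[str]]],
) -> EvalSummary:
    """Aggregate extraction quality over many packages.

    Each case pairs the expected drug-name list of one package with the
    list the pipeline extracted.  Totals pool over all cases: ``accuracy``
    is correct words over total reference words, ``wer`` pools word-level
    edits over total reference words, and ``cer`` pools character edits of
    the space-joined name lists over pooled reference character length.
    """
    if not cases:
        raise InvalidInputError("cannot evaluate an empty corpus")
    total = recognized = correct = 0
    word_edits = 0
    char_edits = 0
    char_len = 0
    for expected, extracted in cases:
        expected = list(expected)
        extracted = list(extracted)
        if not expected:
            raise InvalidInputError("corpus case with empty expected name list")
        total += len(expected)
        recognized += len(extracted)
        extracted_keys = {casefold_key(n) for n in extracted}
        correct += sum(casefold_key(n) in extracted_keys for n in expected)
        word_edits += _sequence_edit_distance(
            [casefold_key(w) for w in expected],
            [casefold_key(w) for w in extracted],
        )
        ref_join = unicodedata.normalize("NFC", " ".join(expected))
        char_edits += edit_distance(ref_join, " ".join(extracted))
        char_len += len(ref_join)
    return EvalSummary(
        total_words=total,
        recognized_words=recognized,
        correct_words=correct,
        accuracy=correct / total,
        wer=word_edits / total,
        cer=char_edits / char_len,
    )
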