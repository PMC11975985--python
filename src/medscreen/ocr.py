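"""Pluggable OCR boundary.

The pipeline only ever consumes a :class:`BagReading` — an ordered list of
recognized text fragments for one drug bag.  The shipped backend reads a
plain JSON fixture (an array of ``{text, order_index, bbox?, confidence?}``
objects), so the whole system runs with no OCR engine installed; a real
engine backend need only produce the same structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

from .catalog import InvalidInputError

__all__ = ["OcrToken", "BagReading", "read_bag", "write_bag"]


@dataclass(frozen=True)
class OcrToken:
    """One recognized text fragment in reading order."""

    text: str
    order_index: int
    bbox: tuple[float, float, float, float] | None = None
    confidence: float | None = None

    def __post_init__(self) -> None:
        if self.order_index < 0:
            raise InvalidInputError("order_index must be non-negative")
        if self.bbox is not None:
            x0, y0, x1, y1 = self.bbox
            if x0 > x1 or y0 > y1:
                raise InvalidInputError(f"degenerate bbox: {self.bbox}")
        if self.confidence is not None and not 0.0 <= self.confidence <= 1.0:
            raise InvalidInputError(f"confidence outside [0, 1]: {self.confidence}")

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {"text": self.text, "order_index": self.order_index}
        if self.bbox is not None:
            d["bbox"] = list(self.bbox)
        if self.confidence is not None:
            d["confidence"] = self.confidence
        return d


@dataclass
class BagReading:
    """All OCR tokens for one drug bag, sorted by ``order_index``."""

    bag_id: str
    tokens: list[OcrToken] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.tokens = sorted(self.tokens, key=lambda t: t.order_index)
        indices = [t.order_index for t in self.tokens]
        if len(set(indices)) != len(indices):
            raise InvalidInputError(
                f"duplicate order_index in bag {self.bag_id!r}"
            )

    def texts(self) -> list[str]:
        return [t.text for t in self.tokens]


def _token_from_dict(obj: dict[str, Any]) -> OcrToken:
    bbox = obj.get("bbox")
    return OcrToken(
        text=str(obj["text"]),
        order_index=int(obj["order_index"]),
        bbox=tuple(float(v) for v in bbox) if bbox is not None else None,
        confidence=(
            float(obj["confidence"]) if obj.get("confidence") is not None else None
        ),
    )


def read_bag(source: str | Path, bag_id: str | None = None) -> BagReading:
    """Read a token-list fixture (JSON, UTF-8) into a :class:`BagReading`.

    Tokens are re-sorted by ``order_index`` regardless of file order.  The
    fixture may be a bare array of token objects or an object with
    ``bag_id`` and ``tokens`` keys.
    """
    path = Path(source)
    if not path.exists():
        raise InvalidInputError(f"OCR fixture not found: {path}")
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise InvalidInputError(f"invalid OCR fixture {path}: {exc}") from exc
    if isinstance(payload, dict):
        raw_tokens = payload.get("tokens", [])
        inferred = payload.get("bag_id")
    elif isinstance(payload, list):
        raw_tokens, inferred = payload, None
    else:
        raise InvalidInputError(f"OCR fixture {path} is neither array nor object")
    try:
        tokens = [_token_from_dict(obj) for obj in raw_tokens]
    except (KeyError, TypeError, ValueError) as exc:
        raise InvalidInputError(f"malformed token in {path}: {exc}") from exc
    return BagReading(bag_id=bag_id or inferred or path.stem, tokens=tokens)


def write_bag(reading: BagReading, path: str | Path) -> None:
    """Serialize a :class:`BagReading` to fixture JSON (round-trips with
    :func:`read_bag`)."""
    payload = {
        "bag_id": reading.bag_id,
        "tokens": [t.to_dict() for t in reading.tokens],
    }
    Path(path).write_text(
        json.dumps(payload, ensure_ascii=False, indent=1) + "\n", encoding="utf-8"
    )
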