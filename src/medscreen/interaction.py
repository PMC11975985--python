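"""Cross-bag pair enumeration and contraindication flagging.

Each drug bag comes from one prescribing institution, whose own dispensing
already screens within-bag combinations; the hazard this pipeline targets is
the combination *across* institutions.  Pairs are therefore formed only
between drugs from different bags — never A1×A2 from a single bag — and each
pair is looked up in the contraindication table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Sequence

from .catalog import ContraindicationTable, DrugCatalog, casefold_key
from .matching import DEFAULT_THRESHOLD, accepted_names, extract_drug_names
from .ocr import BagReading

__all__ = [
    "DrugPair",
    "ScreeningReport",
    "enumerate_cross_bag_pairs",
    "check_pair",
    "screen_bags",
    "render_message",
]

NO_DRUGS_MESSAGE = "No drugs recognized in either bag."
NO_CONTRAINDICATIONS_MESSAGE = "No contraindications exist."


@dataclass(frozen=True)
class DrugPair:
    """One cross-bag drug combination."""

    name_a: str
    name_b: str
    source_bags: tuple[str, str]

    def __post_init__(self) -> None:
        if self.source_bags[0] == self.source_bags[1]:
            raise ValueError(
                f"pair {self.name_a!r}/{self.name_b!r} drawn from a single bag "
                f"{self.source_bags[0]!r}; within-bag pairs are never formed"
            )

    def unordered_key(self) -> frozenset[str]:
        return frozenset((casefold_key(self.name_a), casefold_key(self.name_b)))


@dataclass
class ScreeningReport:
    """Full outcome of screening two bags against the contraindication table."""

    bag_a_id: str
    bag_b_id: str
    bag_a_drugs: list[str]
    bag_b_drugs: list[str]
    pairs_checked: list[DrugPair]
    contraindicated: list[DrugPair]
    unmatched_tokens: list[str] = field(default_factory=list)
    message: str = ""

    def to_dict(self) -> dict[str, Any]:
        def pair_dict(p: DrugPair) -> dict[str, Any]:
            return {"name_a": p.name_a, "name_b": p.name_b,
                    "source_bags": list(p.source_bags)}

        return {
            "bag_a_id": self.bag_a_id,
            "bag_b_id": self.bag_b_id,
            "bag_a_drugs": self.bag_a_drugs,
            "bag_b_drugs": self.bag_b_drugs,
            "pairs_checked": [pair_dict(p) for p in self.pairs_checked],
            "contraindicated": [pair_dict(p) for p in self.contraindicated],
            "unmatched_tokens": self.unmatched_tokens,
            "message": self.message,
        }

    def to_json(self, **kwargs: Any) -> str:
        kwargs.setdefault("ensure_ascii", False)
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)


def enumerate_cross_bag_pairs(
    bag_a: Sequence[str],
    bag_b: Sequence[str],
    bag_ids: tuple[str, str] = ("A", "B"),
) -> list[DrugPair]:
    """Cartesian product of the two bags' drug lists, bag-a order major.

    No within-bag pair is ever produced; either bag empty yields no pairs.
    """
    if bag_ids[0] == bag_ids[1]:
        raise ValueError("cross-bag enumeration requires two distinct bags")
    return [
        DrugPair(a, b, bag_ids) for a in bag_a for b in bag_b
    ]


def check_pair(pair: DrugPair, table: ContraindicationTable) -> bool:
    """True iff the pair's unordered, case-insensitive name pair is in the
    table.  Symmetric in the pair's members."""
    return table.contains(pair.name_a, pair.name_b)


def render_message(report: ScreeningReport) -> str:
    """Deterministic user-facing summary: one line per flagged pair, or a
    fixed sentence when nothing (or no drug at all) was found."""
    if not report.bag_a_drugs and not report.bag_b_drugs:
        return NO_DRUGS_MESSAGE
    if not report.contraindicated:
        return NO_CONTRAINDICATIONS_MESSAGE
    return "\n".join(
        f"{p.name_a} and {p.name_b} are contraindicated."
        for p in report.contraindicated
    )


def screen_bags(
    reading_a: BagReading,
    reading_b: BagReading,
    catalog: DrugCatalog,
    table: ContraindicationTable,
    threshold: float = DEFAULT_THRESHOLD,
) -> ScreeningReport:
    """Run the full screen: extract drugs from each bag, enumerate all
    cross-bag pairs, flag those present in the contraindication table.

    Deterministic for fixed inputs; pairs appear in bag-a-major order.  A
    drug recognized in both bags yields the self-pair {X, X}, which is
    flagged only if the table itself contains such a pair.
    """
    results_a = extract_drug_names(reading_a.tokens, catalog, threshold)
    results_b = extract_drug_names(reading_b.tokens, catalog, threshold)
    drugs_a = accepted_names(results_a)
    drugs_b = accepted_names(results_b)
    bag_ids = (reading_a.bag_id, reading_b.bag_id)
    if bag_ids[0] == bag_ids[1]:
        bag_ids = (f"{bag_ids[0]}#1", f"{bag_ids[1]}#2")

    pairs = enumerate_cross_bag_pairs(drugs_a, drugs_b, bag_ids)
    flagged = [p for p in pairs if check_pair(p, table)]
    unmatched = [
        r.token_text
        for r in (*results_a, *results_b)
        if not r.accepted and r.token_text.strip()
    ]
    report = ScreeningReport(
        bag_a_id=bag_ids[0],
        bag_b_id=bag_ids[1],
        bag_a_drugs=drugs_a,
        bag_b_drugs=drugs_b,
        pairs_checked=pairs,
        contraindicated=flagged,
        unmatched_tokens=unmatched,
    )
    report.message = render_message(report)
    return report
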