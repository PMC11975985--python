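"""Synthetic data for desk-scale testing of the whole pipeline.

Real drug-bag studies need a national product catalog, a contraindication
registry, printed bags in several fonts and an OCR engine.  This module
replaces each with a deterministic generator:

* product names are drawn from a synthetic lexicon with the same shape as
  real catalogs (multi-word base + form word + parenthesized dosage, with
  dosage variants that collapse under normalization);
* printing/scanning degradation is modeled as character-level noise —
  independent per-character substitution and deletion plus geometric
  insertions — and the study's five fonts become five noise conditions of
  increasing severity;
* the benchmark experiment builds three 8-drug packages: A holds 3 drugs
  with registered interactions plus 5 clean ones, B holds the 3 partners
  plus 5 clean ones, C holds 8 clean drugs.  Screening A×B must recover
  exactly the 3 planted pairs; A×C must flag nothing.

All generators are pure functions of (seed, parameters).
"""

from __future__ import annotations

import json
import random
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from string import ascii_letters
from typing import Any, Sequence

from .catalog import (
    ContraindicationTable,
    DrugCatalog,
    InvalidInputError,
    load_catalog,
)
from .ocr import BagReading, OcrToken, write_bag

__all__ = [
    "NoiseModel",
    "ExperimentDesign",
    "FONT_CONDITIONS",
    "generate_catalog",
    "corrupt_text",
    "generate_experiment",
    "write_experiment",
]

_SYLLABLES = [
    "ba", "ce", "da", "fe", "gi", "ho", "ka", "lu", "me", "ni",
    "po", "ra", "su", "te", "vo", "xa", "zo", "dol", "mab", "pril",
    "zid", "fen", "mol", "lor", "tan",
]
_FORMS = ["tab.", "cap.", "syr.", "inj.", "gran."]
_DOSES = ["0.1g", "0.2g", "2.5mg", "5mg", "10mg", "25mg", "50mg",
          "100mg", "250mg", "500mg", "5mL", "10mL"]

#: The five "font" difficulty conditions: (substitution, deletion,
#: insertion) rates applied per character of each printed token.
FONT_CONDITIONS: tuple[tuple[float, float, float], ...] = (
    (0.000, 0.000, 0.000),
    (0.015, 0.005, 0.005),
    (0.030, 0.010, 0.010),
    (0.045, 0.015, 0.015),
    (0.060, 0.020, 0.020),
)

# Non-drug text printed on every bag (pharmacy header, instructions).
_BAG_BOILERPLATE = ["Sunrise Pharmacy", "Prescription No. 77051",
                    "Take 1 tablet daily", "after meals"]


@dataclass(frozen=True)
class NoiseModel:
    """Character-level OCR corruption: independent substitution/deletion per
    character plus geometrically distributed insertions at each gap."""

    sub_rate: float = 0.0
    del_rate: float = 0.0
    ins_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "del_rate", "ins_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise InvalidInputError(f"{name} outside [0, 1]: {rate}")
        if self.sub_rate + self.del_rate > 1.0:
            raise InvalidInputError("sub_rate + del_rate must not exceed 1")
        if self.ins_rate >= 1.0 and self.ins_rate != 0.0:
            raise InvalidInputError("ins_rate must be < 1 for finite output")


def _base_name(rng: random.Random) -> str:
    n_syll = rng.randint(2, 4)
    word = "".join(rng.choice(_SYLLABLES) for _ in range(n_syll))
    return word.capitalize()


def generate_catalog(
    n: int, seed: int, dosage_variant_fraction: float = 0.2
) -> list[str]:
    """Generate ``n`` plausible raw product names, deterministically per seed.

    Roughly ``dosage_variant_fraction`` of the names are dosage variants of
    earlier names (same base + form, different parenthesized dose), so that
    normalization exercises the duplicate-collapsing path.
    """
    if n < 1:
        raise InvalidInputError(f"catalog size must be >= 1, got {n}")
    rng = random.Random(seed)
    names: list[str] = []
    bases: list[tuple[str, str]] = []
    seen_bases: set[str] = set()
    for _ in range(n):
        if bases and rng.random() < dosage_variant_fraction:
            base, form = rng.choice(bases)
        else:
            base = _base_name(rng)
            while base.casefold() in seen_bases:
                base = _base_name(rng)
            seen_bases.add(base.casefold())
            form = rng.choice(_FORMS)
            bases.append((base, form))
        dose = rng.choice(_DOSES)
        names.append(f"{base} {form}({dose})")
    return names


def _token_rng(model: NoiseModel, text: str) -> random.Random:
    # Mix the model seed with a CRC of the text so equal seeds on different
    # tokens decorrelate, yet (seed, text) fully determines the output.
    return random.Random(model.seed * 0x9E3779B1 + zlib.crc32(text.encode("utf-8")))


def corrupt_text(text: str, model: NoiseModel) -> str:
    """Apply the noise model to one string.

    Per character: substitute (with a different random letter) with
    probability ``sub_rate``, else delete with probability ``del_rate``,
    else keep.  At each of the ``len(text) + 1`` gaps, insert a geometric
    number of random letters with continuation probability ``ins_rate``.
    All-zero rates return the input unchanged.
    """
    rng = _token_rng(model, text)
    out: list[str] = []

    def _insert_run() -> None:
        while model.ins_rate > 0.0 and rng.random() < model.ins_rate:
            out.append(rng.choice(ascii_letters))

    for ch in text:
        _insert_run()
        u = rng.random()
        if u < model.sub_rate:
            repl = rng.choice(ascii_letters)
            while repl == ch:
                repl = rng.choice(ascii_letters)
            out.append(repl)
        elif u < model.sub_rate + model.del_rate:
            continue
        else:
            out.append(ch)
    _insert_run()
    return "".join(out)


@dataclass(frozen=True)
class ExperimentDesign:
    """The three-package benchmark layout."""

    package_a: tuple[str, ...]
    package_b: tuple[str, ...]
    package_c: tuple[str, ...]
    planted_pairs: tuple[tuple[str, str], ...]
    conditions: tuple[NoiseModel, ...]
    replicates: int

    def __post_init__(self) -> None:
        set_a, set_b = set(self.package_a), set(self.package_b)
        set_c = set(self.package_c)
        for a, b in self.planted_pairs:
            if a not in set_a or b not in set_b:
                raise InvalidInputError(
                    f"planted pair ({a!r}, {b!r}) not drawn from packages A x B"
                )
            if a in set_c or b in set_c:
                raise InvalidInputError("planted pair touches package C")

    def package(self, label: str) -> tuple[str, ...]:
        return {"A": self.package_a, "B": self.package_b,
                "C": self.package_c}[label]


@dataclass
class Experiment:
    """Everything :func:`generate_experiment` emits, plus the ground truth."""

    catalog: DrugCatalog
    table: ContraindicationTable
    design: ExperimentDesign
    bags: list[BagReading]
    manifest: dict[str, Any] = field(default_factory=dict)


def _tokens_for_bag(
    names: Sequence[str], model: NoiseModel
) -> list[OcrToken]:
    """Lay a package out as OCR word boxes: boilerplate lines, then each
    drug name split into per-word tokens (word-box OCR engines segment
    multi-word names), all passed through the noise model."""
    texts = list(_BAG_BOILERPLATE)
    for name in names:
        texts.extend(name.split(" "))
    tokens = []
    for idx, text in enumerate(texts):
        noisy = corrupt_text(text, replace(model, seed=model.seed + idx))
        tokens.append(OcrToken(text=noisy, order_index=idx))
    return tokens


def generate_experiment(
    seed: int,
    *,
    package_size: int = 8,
    n_planted: int = 3,
    n_distractors: int = 60,
    n_decoy_pairs: int = 10,
    conditions: Sequence[tuple[float, float, float]] = FONT_CONDITIONS,
    replicates: int = 10,
    noise_scale: float = 1.0,
) -> Experiment:
    """Build the full benchmark: catalog, contraindication table, and one
    bag fixture per (package, condition, replicate).

    Defaults produce ``3 × len(conditions) × replicates = 150`` fixtures
    with 3 planted contraindicated pairs between packages A and B, decoy
    pairs confined to distractor drugs, and a catalog holding all 24
    package names plus ``n_distractors`` distractors.  ``noise_scale``
    multiplies every condition's rates (0 → noise-free across the board).
    """
    if n_planted > package_size:
        raise InvalidInputError("cannot plant more pairs than package slots")
    rng = random.Random(seed)

    n_names = 3 * package_size + n_distractors
    raw_names = generate_catalog(n_names * 2, seed=rng.randrange(2**31),
                                 dosage_variant_fraction=0.25)
    catalog, _ = load_catalog(raw_names)
    unique = list(catalog.entries)
    if len(unique) < n_names:  # pragma: no cover - generous oversampling
        raise InvalidInputError("lexicon too small for requested experiment")
    rng.shuffle(unique)
    pkg_a = tuple(unique[:package_size])
    pkg_b = tuple(unique[package_size:2 * package_size])
    pkg_c = tuple(unique[2 * package_size:3 * package_size])
    distractors = unique[3 * package_size:n_names]

    planted = tuple((pkg_a[i], pkg_b[i]) for i in range(n_planted))
    table = ContraindicationTable()
    for a, b in planted:
        table.add(a, b)
    # Decoys keep the table from being trivially equal to the ground truth;
    # they only touch distractor drugs, never the packages.
    for _ in range(n_decoy_pairs):
        if len(distractors) < 2:
            break
        a, b = rng.sample(distractors, 2)
        table.add(a, b)

    models = tuple(
        NoiseModel(
            sub_rate=s * noise_scale,
            del_rate=d * noise_scale,
            ins_rate=i * noise_scale,
            seed=rng.randrange(2**31),
        )
        for s, d, i in conditions
    )
    design = ExperimentDesign(
        package_a=pkg_a, package_b=pkg_b, package_c=pkg_c,
        planted_pairs=planted, conditions=models, replicates=replicates,
    )

    bags: list[BagReading] = []
    manifest_bags: dict[str, Any] = {}
    for label in ("A", "B", "C"):
        names = design.package(label)
        for f_idx, model in enumerate(models, start=1):
            for rep in range(1, replicates + 1):
                bag_id = f"{label}_font{f_idx}_rep{rep:02d}"
                bag_model = replace(
                    model, seed=model.seed + 1_000_003 * rep + 7919 * f_idx
                )
                bags.append(
                    BagReading(bag_id, _tokens_for_bag(names, bag_model))
                )
                manifest_bags[bag_id] = {
                    "package": label,
                    "condition": f_idx,
                    "replicate": rep,
                    "expected_names": list(names),
                }
    manifest = {
        "seed": seed,
        "packages": {
            "A": list(pkg_a), "B": list(pkg_b), "C": list(pkg_c),
        },
        "planted_pairs": [list(p) for p in planted],
        "conditions": [
            {"sub_rate": m.sub_rate, "del_rate": m.del_rate,
             "ins_rate": m.ins_rate} for m in models
        ],
        "replicates": replicates,
        "bags": manifest_bags,
    }
    return Experiment(catalog=catalog, table=table, design=design,
                      bags=bags, manifest=manifest)


def write_experiment(experiment: Experiment, out_dir: str | Path) -> dict[str, Path]:
    """Write catalog CSV, contraindication CSV, bag fixture JSONs and the
    ground-truth manifest into ``out_dir``; returns the paths written."""
    out = Path(out_dir)
    bags_dir = out / "bags"
    bags_dir.mkdir(parents=True, exist_ok=True)

    catalog_path = out / "catalog.csv"
    with catalog_path.open("w", newline="", encoding="utf-8") as fh:
        fh.write("product_name\n")
        for entry in experiment.catalog.entries:
            for raw in experiment.catalog.provenance[entry]:
                fh.write(raw + "\n")

    contra_path = out / "contraindications.csv"
    with contra_path.open("w", newline="", encoding="utf-8") as fh:
        fh.write("product_name_a,product_name_b\n")
        for key in sorted(experiment.table.pairs,
                          key=lambda k: sorted(experiment.table.display[k])):
            a, b = experiment.table.display[key]
            fh.write(f"{a},{b}\n")

    for bag in experiment.bags:
        write_bag(bag, bags_dir / f"{bag.bag_id}.json")

    manifest_path = out / "manifest.json"
    manifest_path.write_text(
        json.dumps(experiment.manifest, ensure_ascii=False, indent=1,
                   sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return {"catalog": catalog_path, "contraindications": contra_path,
            "bags": bags_dir, "manifest": manifest_path}
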