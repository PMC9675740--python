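"""Synthetic registries and perturbed external-registry dumps.

Alignment and standardization cannot be exercised against the 23 live
external registries from a test suite, so this module generates the study
conditions instead: a ground-truth registry of fabricated identifier
resources, and external-registry dumps derived from it by exactly the kinds
of heterogeneity observed across real registries — capitalization variants
(``go`` vs ``GO``), punctuation variants (``ec-code`` vs ``eccode``),
synonym substitution (``flybase`` vs ``fb``, ``intenz`` vs ``eccode``),
novel out-of-vocabulary prefixes, and per-field metadata dropout mirroring
registries whose schemas carry a field only on some entries.

Because casing and punctuation perturbations are exactly the
transformations :func:`metaprefix.records.norm_key` inverts, and synonym
swaps draw only from curated synonyms, alignment must recover the planted
equivalence map perfectly on such dumps; novel rows must land in
new-records/curation/skip channels per policy group, never in wrong
mappings.  :func:`score_alignment` measures exactly that.

A single integer seed governs all randomness.  Draws happen in a documented
order (per record sorted by prefix: inclusion, synonym swap, punctuation,
casing, then field dropout in fixed field order; novel rows afterwards) so
generated counts are reproducible.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Optional

from pydantic import BaseModel, model_validator

from .align import AlignmentResult
from .records import ExternalRecord, Registry, ResourceRecord, norm_key

__all__ = [
    "GenerationError",
    "PerturbProfile",
    "TruthSet",
    "derive_dump",
    "generate_truth",
    "score_alignment",
]

#: Biologically flavored syllables composed into fabricated resource names.
_SYLLABLES = (
    "chem", "gen", "prot", "tax", "cell", "path", "enz", "bio", "reg",
    "ome", "lig", "seq", "var", "pheno", "meta", "micro", "neuro", "immuno",
    "glyco", "lipid", "trans", "cript", "zyme", "plasm", "vir", "bact",
    "fung", "flor", "faun", "terp",
)

_PUNCT = "-_."
_MAX_ATTEMPTS = 10_000


class GenerationError(RuntimeError):
    """The requested fixture cannot be generated (name space exhausted)."""


class PerturbProfile(BaseModel):
    """Perturbation rates for deriving an external dump from the truth.

    Rates are probabilities in [0, 1].  ``field_dropout`` maps metadata
    field names (name, homepage, example, pattern, uri_format) to the
    probability that the field is absent on a dump row, emulating an
    external registry whose schema carries the field only on some entries.
    """

    casing_rate: float = 0.0
    punctuation_rate: float = 0.0
    synonym_swap_rate: float = 0.0
    novel_rate: float = 0.0
    field_dropout: dict[str, float] = {}

    @model_validator(mode="after")
    def _check_rates(self) -> "PerturbProfile":
        for name in ("casing_rate", "punctuation_rate", "synonym_swap_rate", "novel_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for fname, value in self.field_dropout.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"field_dropout[{fname!r}] must be in [0, 1], got {value}")
        return self


@dataclass
class TruthSet:
    """A generated ground-truth registry plus the planted equivalences of
    every dump derived from it so far."""

    registry: Registry
    seed: int
    planted: dict[tuple[str, str], str] = field(default_factory=dict)


def _draw_word(rng: random.Random, taken: set[str]) -> str:
    """A fresh lowercase pseudo-resource name, unique under norm_key."""
    for _ in range(_MAX_ATTEMPTS):
        parts = rng.choices(_SYLLABLES, k=rng.randint(2, 3))
        word = "".join(parts)
        if rng.random() < 0.3:
            word += str(rng.randint(0, 99))
        if norm_key(word) not in taken:
            taken.add(norm_key(word))
            return word
    raise GenerationError(
        "could not draw a fresh prefix; synonym demand exceeds the name space"
    )


def generate_truth(n: int, synonyms_per_record: int = 2, seed: int = 0) -> TruthSet:
    """Generate a collision-free ground-truth registry of ``n`` records.

    Each record gets a unique canonical prefix, ``synonyms_per_record``
    synonyms (all globally unique under key normalization, so the lookup
    table is collision-free by construction), a numeric LUI pattern with a
    matching example, a homepage, and a URI format string unique to the
    record.  Deterministic for a fixed seed.

    Raises
    ------
    GenerationError
        When the syllable name space cannot supply the requested number of
        distinct prefixes and synonyms.
    """
    if n < 1:
        raise GenerationError("n must be at least 1")
    rng = random.Random(seed)
    taken: set[str] = set()
    records = []
    for _ in range(n):
        prefix = _draw_word(rng, taken)
        synonyms = [_draw_word(rng, taken) for _ in range(synonyms_per_record)]
        width = rng.randint(4, 8)
        example = "".join(str(rng.randint(0, 9)) for _ in range(width))
        records.append(
            ResourceRecord(
                prefix=prefix,
                name=prefix.capitalize(),
                homepage=f"https://{prefix}.example.org",
                description=f"Synthetic identifier resource {prefix!r} for testing.",
                synonyms=synonyms,
                pattern=rf"^\d{{{width}}}$",
                example=example,
                uri_format=f"https://{prefix}.example.org/entry/$1",
            )
        )
    return TruthSet(registry=Registry(records), seed=seed)


def _perturb_casing(rng: random.Random, s: str) -> str:
    style = rng.choice(("upper", "capitalize", "swapcase"))
    out = getattr(s, style)()
    return out if out != s else s.upper()


def _perturb_punctuation(rng: random.Random, s: str) -> str:
    count = rng.randint(1, 2)
    out = s
    for _ in range(count):
        pos = rng.randint(1, len(out) - 1)
        out = out[:pos] + rng.choice(_PUNCT) + out[pos:]
    return out


def derive_dump(
    truth: TruthSet,
    registry_key: str,
    profile: PerturbProfile,
    seed: int,
) -> tuple[list[ExternalRecord], dict[tuple[str, str], str]]:
    """Derive a perturbed external-registry dump with a planted answer key.

    Each truth record is emitted with probability ``1 − novel_rate`` under a
    prefix perturbed per the profile (synonym swap, then punctuation, then
    casing — the latter two preserve the normalization key by construction).
    Additionally ``⌈novel_rate · n⌉`` novel rows with no planted counterpart
    are appended, their prefixes rejection-sampled to be disjoint from every
    truth lookup key.  Metadata fields are dropped per ``field_dropout``.

    Returns the dump and the planted map (registry_key, external_prefix) →
    canonical prefix covering exactly the dump's mappable rows; the map is
    also accumulated onto ``truth.planted``.
    """
    rng = random.Random(seed)
    truth_keys = {
        norm_key(c)
        for record in truth.registry
        for c in [record.prefix, *record.synonyms]
    }
    dump: list[ExternalRecord] = []
    planted: dict[tuple[str, str], str] = {}

    def _metadata(record: ResourceRecord) -> dict[str, Optional[str]]:
        out: dict[str, Optional[str]] = {}
        for fname in ("name", "homepage", "example", "pattern", "uri_format"):
            value = getattr(record, fname)
            drop = rng.random() < profile.field_dropout.get(fname, 0.0)
            out[fname] = None if drop else value
        return out

    n = len(truth.registry)
    for prefix in sorted(truth.registry.records):
        record = truth.registry.records[prefix]
        if rng.random() < profile.novel_rate:
            continue
        base = record.prefix
        if record.synonyms and rng.random() < profile.synonym_swap_rate:
            base = rng.choice(record.synonyms)
        if rng.random() < profile.punctuation_rate:
            base = _perturb_punctuation(rng, base)
        if rng.random() < profile.casing_rate:
            base = _perturb_casing(rng, base)
        dump.append(
            ExternalRecord(registry_key=registry_key, external_prefix=base, **_metadata(record))
        )
        planted[(registry_key, base)] = record.prefix

    novel_count = math.ceil(profile.novel_rate * n)
    used_novel: set[str] = set()
    for _ in range(novel_count):
        for _ in range(_MAX_ATTEMPTS):
            word = "".join(rng.choices(_SYLLABLES, k=rng.randint(2, 3)))
            word += str(rng.randint(100, 999))
            if norm_key(word) not in truth_keys and norm_key(word) not in used_novel:
                used_novel.add(norm_key(word))
                break
        else:  # pragma: no cover - name space is far larger than any fixture
            raise GenerationError("could not draw a novel out-of-vocabulary prefix")
        dump.append(
            ExternalRecord(
                registry_key=registry_key,
                external_prefix=word,
                name=word.capitalize(),
                homepage=f"https://{word}.example.net",
            )
        )
    truth.planted.update(planted)
    return dump, planted


def score_alignment(
    result: AlignmentResult, planted: dict[tuple[str, str], str]
) -> dict[str, float]:
    """Precision and recall of recovered mappings against the planted truth.

    precision = correct emitted mappings / all emitted mappings (1.0 by
    convention when nothing was emitted); recall = correct emitted mappings
    / planted mappings (1.0 when nothing was planted).
    """
    correct = sum(
        1
        for m in result.new_mappings
        if planted.get((m.registry_key, m.external_prefix)) == m.prefix
    )
    emitted = len(result.new_mappings)
    precision = correct / emitted if emitted else 1.0
    recall = correct / len(planted) if planted else 1.0
    return {"precision": precision, "recall": recall}
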