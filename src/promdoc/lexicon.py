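"""The PROM catalog: instrument definitions and compiled matching patterns.

A :class:`PromDefinition` names one validated patient-reported outcome
measure together with its textual surface forms — multi-token aliases
("Oswestry Disability Index"), short abbreviations ("ODI"), and a flag
controlling whether typo-tolerant (fuzzy) matching applies.  A
:class:`PromCatalog` bundles the definitions with an exclusion list of
surface forms that must never match (unidimensional pain scales such as the
NRS and VAS are excluded by design).

:func:`compile_patterns` turns a definition into concrete matchers:

* case-insensitive, whitespace-collapsing regexes for aliases;
* word-boundary, case-sensitive regexes for abbreviations;
* tokenized alias forms for fuzzy scanning under a :class:`FuzzPolicy`
  (bounded Damerau-Levenshtein distance, long tokens only).
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path
from typing import Iterator

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "FuzzPolicy",
    "PromDefinition",
    "PromCatalog",
    "CompiledProm",
    "load_prom_catalog",
    "default_catalog",
    "compile_patterns",
]


def _norm_space(s: str) -> str:
    return " ".join(s.split())


#: word tokens for fuzzy comparison: internal hyphens/apostrophes kept,
#: surrounding punctuation stripped (must match the matcher's tokenizer)
WORD_RE = re.compile(r"[A-Za-z0-9][A-Za-z0-9'\-]*")


def tokenize_words(s: str) -> list[str]:
    return WORD_RE.findall(s)


class FuzzPolicy(BaseModel):
    """Typo tolerance for alias matching.

    ``max_edits`` Damerau-Levenshtein edits are allowed across an alias, but
    only tokens of at least ``min_token_len`` characters may absorb them;
    short tokens (and all abbreviations) must match exactly, which keeps
    three-letter false positives from exploding.
    """

    max_edits: int = 1
    min_token_len: int = 5

    model_config = {"frozen": True}


class PromDefinition(BaseModel):
    prom_id: str
    canonical_name: str
    aliases: list[str] = Field(default_factory=list)
    abbreviations: list[str] = Field(default_factory=list)
    allow_fuzzy: bool = False
    category: str = "uncategorized"

    model_config = {"frozen": True}

    @field_validator("canonical_name")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("canonical_name must be non-empty")
        return v

    @field_validator("abbreviations")
    @classmethod
    def _abbrev_norm(cls, v: list[str]) -> list[str]:
        out = []
        for a in v:
            a = a.strip().upper()
            if len(a) < 2:
                raise ValueError(f"abbreviation too short: {a!r}")
            out.append(a)
        return out

    def surface_forms(self) -> list[str]:
        """All alias surface forms, canonical name first, deduplicated."""
        seen: dict[str, None] = {}
        for s in [self.canonical_name, *self.aliases]:
            seen.setdefault(_norm_space(s), None)
        return list(seen)


class PromCatalog(BaseModel):
    definitions: list[PromDefinition]
    excluded_measures: list[str] = Field(default_factory=list)

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _unique_ids(self) -> "PromCatalog":
        if not self.definitions:
            raise ValueError("catalog has no definitions")
        ids = [d.prom_id for d in self.definitions]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate prom_id: {sorted(dupes)}")
        return self

    def __iter__(self) -> Iterator[PromDefinition]:  # type: ignore[override]
        return iter(self.definitions)

    def __len__(self) -> int:
        return len(self.definitions)

    def get(self, prom_id: str) -> PromDefinition:
        for d in self.definitions:
            if d.prom_id == prom_id:
                return d
        raise KeyError(prom_id)

    @property
    def prom_ids(self) -> list[str]:
        return [d.prom_id for d in self.definitions]

    def is_excluded_measure(self, name: str) -> bool:
        """True if ``name`` is a surface form of an excluded (never-matchable)
        measure, compared case-insensitively with whitespace collapsed."""
        key = _norm_space(name).casefold()
        if not key:
            return False
        return any(key == _norm_space(x).casefold() for x in self.excluded_measures)


def load_prom_catalog(config_path: str | Path) -> PromCatalog:
    """Load and validate a catalog from its YAML configuration."""
    with open(config_path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "definitions" not in raw:
        raise ValueError("lexicon config must define 'definitions'")
    return PromCatalog.model_validate(raw)


def default_catalog() -> PromCatalog:
    """The shipped 18-measure spine/pain catalog."""
    ref = resources.files("promdoc").joinpath("data/lexicon.yaml")
    with resources.as_file(ref) as path:
        return load_prom_catalog(path)


def is_excluded_measure(name: str, catalog: PromCatalog | None = None) -> bool:
    """Module-level convenience wrapper around
    :meth:`PromCatalog.is_excluded_measure` using the shipped catalog."""
    cat = catalog if catalog is not None else default_catalog()
    return cat.is_excluded_measure(name)


class CompiledProm(BaseModel):
    """Matchers compiled from one definition.

    ``alias_patterns`` / ``abbrev_patterns`` are regex sources (compiled lazily
    by the matcher); ``fuzzy_aliases`` holds tokenized, casefolded alias forms
    eligible for edit-distance scanning.
    """

    prom_id: str
    catalog_rank: int
    alias_regexes: list[re.Pattern] = Field(default_factory=list)
    abbrev_regexes: list[re.Pattern] = Field(default_factory=list)
    fuzzy_aliases: list[tuple[str, ...]] = Field(default_factory=list)
    fuzz: FuzzPolicy = Field(default_factory=FuzzPolicy)

    model_config = {"arbitrary_types_allowed": True, "frozen": True}


def _alias_regex(alias: str) -> re.Pattern:
    tokens = _norm_space(alias).split()
    body = r"[\s]+".join(re.escape(t) for t in tokens)
    return re.compile(rf"(?<!\w){body}(?!\w)", re.IGNORECASE)


def _abbrev_regex(abbrev: str) -> re.Pattern:
    # case-sensitive: "ODI" must not match inside "ODIN" or lower-case words
    return re.compile(rf"(?<![\w]){re.escape(abbrev)}(?![\w])")


def compile_patterns(
    definition: PromDefinition,
    fuzz: FuzzPolicy | None = None,
    excluded: list[str] | None = None,
    catalog_rank: int = 0,
) -> CompiledProm:
    """Compile one definition into its matcher set.

    Surface forms that appear on the exclusion list are dropped even when
    listed as aliases (exclusion dominates).  Fuzzy forms are emitted only
    when the definition opts in and contain at least one token long enough to
    absorb an edit under the policy.
    """
    fuzz = fuzz or FuzzPolicy()
    excl = {_norm_space(e).casefold() for e in (excluded or [])}

    def allowed(surface: str) -> bool:
        return _norm_space(surface).casefold() not in excl

    aliases = [s for s in definition.surface_forms() if allowed(s)]
    abbrevs = [a for a in definition.abbreviations if allowed(a)]

    fuzzy: list[tuple[str, ...]] = []
    if definition.allow_fuzzy and fuzz.max_edits > 0:
        for s in aliases:
            toks = tuple(t.casefold() for t in tokenize_words(s))
            if toks and any(len(t) >= fuzz.min_token_len for t in toks):
                fuzzy.append(toks)

    return CompiledProm(
        prom_id=definition.prom_id,
        catalog_rank=catalog_rank,
        alias_regexes=[_alias_regex(s) for s in aliases],
        abbrev_regexes=[_abbrev_regex(a) for a in abbrevs],
        fuzzy_aliases=fuzzy,
        fuzz=fuzz,
    )


def compile_catalog(
    catalog: PromCatalog, fuzz: FuzzPolicy | None = None
) -> list[CompiledProm]:
    """Compile every definition, threading the exclusion list through."""
    return [
        compile_patterns(d, fuzz, catalog.excluded_measures, rank)
        for rank, d in enumerate(catalog.definitions)
    ]
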