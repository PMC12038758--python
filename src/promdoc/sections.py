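"""Note sectionization: segment a clinic note into labeled sections.

Clinical notes carry structure as inline headers ("Subjective:",
"Medications:", "Goals of Care:").  The sectionizer matches a configurable
header lexicon and assigns every character of the note to exactly one
section; a default "preamble" section (disposition include) covers any text
before the first recognized header.  Each rule carries an include/exclude
disposition so the span filter can drop PROM mentions found in abbreviation
legends, medication lists, goals-of-care statements and similar boilerplate
where a lexicon term does not document actual PROM use.

The governing-section rule is positional: the nearest preceding header
governs, even mid-line.  This intentionally reproduces the known behaviour
on text like ``"Goals of Care: Improve outcome measures, reduce ODI by
20%"`` — the excluded Goals-of-Care section is re-opened by the inline
include header "outcome measures", so the trailing "ODI" span is kept.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import yaml
from pydantic import BaseModel, field_validator

__all__ = [
    "Section",
    "SectionRule",
    "load_section_rules",
    "default_section_rules",
    "detect_sections",
]

#: maximum header length, in whitespace tokens
MAX_HEADER_TOKENS = 6


class SectionRule(BaseModel):
    """One header pattern with its disposition.

    ``inline=False`` (default): matches only line-initially and requires a
    trailing colon.  ``inline=True``: matches anywhere, colon optional.
    """

    pattern: str
    disposition: Literal["include", "exclude"]
    inline: bool = False

    model_config = {"frozen": True}

    @field_validator("pattern")
    @classmethod
    def _short_phrase(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("empty header pattern")
        if len(v.split()) > MAX_HEADER_TOKENS:
            raise ValueError(f"header pattern longer than {MAX_HEADER_TOKENS} tokens: {v!r}")
        return v


@dataclass(frozen=True)
class Section:
    label: str
    header_start: int
    header_end: int
    body_start: int
    body_end: int
    disposition: str  # include | exclude

    def governs(self, offset: int) -> bool:
        return self.header_start <= offset < self.body_end


def load_section_rules(config_path: str | Path) -> list[SectionRule]:
    with open(config_path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    rules = raw.get("section_rules") if isinstance(raw, dict) else raw
    if not rules:
        raise ValueError("no section rules in config")
    return [SectionRule.model_validate(r) for r in rules]


def default_section_rules() -> list[SectionRule]:
    ref = resources.files("promdoc").joinpath("data/sections.yaml")
    with resources.as_file(ref) as path:
        return load_section_rules(path)


def _rule_regex(rule: SectionRule) -> re.Pattern:
    body = r"[ \t]+".join(re.escape(t) for t in rule.pattern.split())
    if rule.inline:
        return re.compile(rf"(?<!\w){body}(?!\w)(?:[ \t]*:)?", re.IGNORECASE)
    return re.compile(rf"^[ \t]*{body}[ \t]*:", re.IGNORECASE | re.MULTILINE)


def detect_sections(body: str, section_rules: Sequence[SectionRule]) -> list[Section]:
    """Segment ``body`` into sections covering every character exactly once.

    Headers are located by the rule lexicon; longer header matches win where
    two rules start at the same offset (so "Goals of Care:" is not shadowed
    by a shorter overlapping pattern).  The section opened by a header runs
    to the start of the next header or the end of the note.
    """
    if not section_rules:
        raise ValueError("section_rules must be non-empty")
    hits: list[tuple[int, int, str, str]] = []  # (start, end, label, disposition)
    for rule in section_rules:
        for m in _rule_regex(rule).finditer(body):
            hits.append((m.start(), m.end(), rule.pattern, rule.disposition))
    # earliest start first; longest match wins at equal starts
    hits.sort(key=lambda h: (h[0], -(h[1] - h[0])))
    chosen: list[tuple[int, int, str, str]] = []
    cursor = -1
    for h in hits:
        if h[0] > cursor:
            chosen.append(h)
            cursor = h[1] - 1

    sections: list[Section] = []
    first_start = chosen[0][0] if chosen else len(body)
    if first_start > 0 or not chosen:
        sections.append(
            Section("preamble", 0, 0, 0, first_start, "include")
        )
    for i, (hs, he, label, disp) in enumerate(chosen):
        nxt = chosen[i + 1][0] if i + 1 < len(chosen) else len(body)
        sections.append(Section(label, hs, he, he, nxt, disp))
    return sections


def governing_section(sections: Sequence[Section], offset: int) -> Section:
    """The section whose span (header plus body) contains ``offset``."""
    for sec in sections:
        if sec.governs(offset):
            return sec
    raise RuntimeError(f"offset {offset} not covered by any section (coverage invariant broken)")
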