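"""The rule-based PROM extraction pipeline.

Candidate spans are found by three pattern families compiled from the
catalog (exact aliases, word-boundary abbreviations, typo-tolerant fuzzy
aliases), overlaps are resolved longest-match-first, the sectionizer assigns
each span a governing section, spans in exclude-disposition sections are
dropped, and the surviving spans are cast to a note-level binary label
("documented PROM use: yes/no").

Only the clinical body of a note is ever scanned; the metadata header is
plumbing, not clinical text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from promdoc._edit import damerau_levenshtein
from promdoc.corpus_prep import ClinicNote
from promdoc.lexicon import (
    WORD_RE,
    CompiledProm,
    FuzzPolicy,
    PromCatalog,
    compile_catalog,
)
from promdoc.sections import Section, SectionRule, detect_sections, governing_section

__all__ = [
    "PromSpan",
    "NoteResult",
    "PrevalenceReport",
    "find_candidate_spans",
    "apply_section_filter",
    "annotate_note",
    "corpus_prevalence",
    "percent",
]

_KIND_PRIORITY = {"alias": 0, "abbreviation": 1, "fuzzy": 2}


@dataclass(frozen=True)
class PromSpan:
    """A character-offset span (0-based, half-open) tagged with its measure."""

    start: int
    end: int
    surface: str
    prom_id: str
    source: str = "model"  # human | model
    section_label: str | None = None
    match_kind: str = "alias"  # alias | abbreviation | fuzzy

    def overlaps(self, other: "PromSpan") -> bool:
        return self.start < other.end and other.start < self.end

    def overlap_len(self, other: "PromSpan") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class NoteResult:
    visit_id: str
    spans: tuple[PromSpan, ...]
    prom_positive: bool
    per_prom_flags: Mapping[str, bool]
    dropped_spans: tuple[PromSpan, ...] = ()


# same word tokenization as the lexicon's fuzzy alias forms, so
# token-to-token edit distances compare like with like
_TOKEN_RE = WORD_RE


def _fuzzy_hits(
    body: str,
    tokens: list[tuple[int, int, str]],
    compiled: CompiledProm,
) -> list[tuple[int, int, str, str, int]]:
    """Sliding token-window scan for aliases within the edit budget."""
    hits: list[tuple[int, int, str, str, int]] = []
    fuzz = compiled.fuzz
    for alias_toks in compiled.fuzzy_aliases:
        k = len(alias_toks)
        for i in range(len(tokens) - k + 1):
            edits = 0
            ok = True
            for j, at in enumerate(alias_toks):
                bt = tokens[i + j][2].casefold()
                if bt == at:
                    continue
                if len(at) >= fuzz.min_token_len:
                    budget = fuzz.max_edits - edits
                    d = damerau_levenshtein(bt, at, max_dist=budget)
                    if d <= budget:
                        edits += d
                        continue
                ok = False
                break
            if ok and edits > 0:  # exact hits are the alias regexes' job
                start, end = tokens[i][0], tokens[i + k - 1][1]
                hits.append((start, end, compiled.prom_id, "fuzzy", compiled.catalog_rank))
    return hits


def find_candidate_spans(
    body: str,
    catalog: PromCatalog | Sequence[CompiledProm],
    fuzz_policy: FuzzPolicy | None = None,
) -> list[PromSpan]:
    """All maximal non-overlapping PROM matches in ``body``.

    Overlapping candidates are resolved longest-match-first, ties by earliest
    start, then catalog order, then match kind (alias > abbreviation >
    fuzzy).  So "Bournemouth Questionnaire" beats the nested "Bournemouth".
    """
    compiled = (
        compile_catalog(catalog, fuzz_policy)
        if isinstance(catalog, PromCatalog)
        else list(catalog)
    )
    tokens = [(m.start(), m.end(), m.group()) for m in _TOKEN_RE.finditer(body)]

    cands: list[tuple[int, int, str, str, int]] = []
    for cp in compiled:
        for rx in cp.alias_regexes:
            for m in rx.finditer(body):
                cands.append((m.start(), m.end(), cp.prom_id, "alias", cp.catalog_rank))
        for rx in cp.abbrev_regexes:
            for m in rx.finditer(body):
                cands.append((m.start(), m.end(), cp.prom_id, "abbreviation", cp.catalog_rank))
        if cp.fuzzy_aliases:
            cands.extend(_fuzzy_hits(body, tokens, cp))

    cands.sort(key=lambda c: (-(c[1] - c[0]), c[0], c[4], _KIND_PRIORITY[c[3]]))
    chosen: list[tuple[int, int, str, str, int]] = []
    for c in cands:
        if all(c[1] <= o[0] or o[1] <= c[0] for o in chosen):
            chosen.append(c)
    chosen.sort(key=lambda c: c[0])
    return [
        PromSpan(start=s, end=e, surface=body[s:e], prom_id=pid, source="model", match_kind=kind)
        for s, e, pid, kind, _ in chosen
    ]


def apply_section_filter(
    spans: Sequence[PromSpan], sections: Sequence[Section]
) -> tuple[list[PromSpan], list[PromSpan]]:
    """Keep spans whose governing section has disposition include.

    Returns ``(kept, dropped)``; the dropped list is the audit trail.  Every
    span is annotated with its governing section label either way.
    """
    kept: list[PromSpan] = []
    dropped: list[PromSpan] = []
    for sp in spans:
        sec = governing_section(sections, sp.start)
        tagged = replace(sp, section_label=sec.label)
        (kept if sec.disposition == "include" else dropped).append(tagged)
    return kept, dropped


def annotate_note(
    note: ClinicNote | str,
    catalog: PromCatalog | Sequence[CompiledProm],
    section_rules: Sequence[SectionRule],
    fuzz_policy: FuzzPolicy | None = None,
    *,
    visit_id: str | None = None,
    section_filtering: bool = True,
) -> NoteResult:
    """Run the full pipeline on one note body and cast to a note label.

    ``section_filtering=False`` disables the exclusion step (the ablation
    configuration); candidate matching and sectionization still run so the
    audit fields stay comparable.
    """
    if isinstance(note, ClinicNote):
        body = note.body
        vid = note.visit_id
    else:
        body = note
        vid = visit_id or ""
    candidates = find_candidate_spans(body, catalog, fuzz_policy)
    sections = detect_sections(body, section_rules)
    if section_filtering:
        kept, dropped = apply_section_filter(candidates, sections)
    else:
        kept, _ = [replace(s, section_label=governing_section(sections, s.start).label)
                   for s in candidates], []
        dropped = []
    prom_ids = (
        catalog.prom_ids
        if isinstance(catalog, PromCatalog)
        else [c.prom_id for c in catalog]
    )
    flags = {pid: any(sp.prom_id == pid for sp in kept) for pid in prom_ids}
    return NoteResult(
        visit_id=vid,
        spans=tuple(kept),
        prom_positive=len(kept) > 0,
        per_prom_flags=flags,
        dropped_spans=tuple(dropped),
    )


def percent(numerator: float, denominator: float) -> float:
    """A share as a percentage rounded to one decimal (the reporting unit)."""
    if denominator == 0:
        raise ZeroDivisionError("empty denominator")
    return round(100.0 * numerator / denominator, 1)


@dataclass(frozen=True)
class PrevalenceReport:
    n_notes: int
    n_positive: int
    overall_pct: float
    per_stratum_pct: Mapping[str, float] = field(default_factory=dict)
    per_stratum_counts: Mapping[str, tuple[int, int]] = field(default_factory=dict)


def corpus_prevalence(
    results: Sequence[NoteResult],
    strata: Mapping[str, str] | None = None,
) -> PrevalenceReport:
    """Fraction of PROM-positive notes, overall and per stratum, as percents
    to one decimal."""
    if not results:
        raise ValueError("empty results")
    n = len(results)
    pos = sum(r.prom_positive for r in results)
    per_pct: dict[str, float] = {}
    per_counts: dict[str, tuple[int, int]] = {}
    if strata:
        groups: dict[str, list[NoteResult]] = {}
        for r in results:
            label = strata.get(r.visit_id)
            if label is not None:
                groups.setdefault(label, []).append(r)
        for label, rs in sorted(groups.items()):
            p = sum(x.prom_positive for x in rs)
            per_counts[label] = (p, len(rs))
            per_pct[label] = percent(p, len(rs))
    return PrevalenceReport(
        n_notes=n,
        n_positive=pos,
        overall_pct=percent(pos, n),
        per_stratum_pct=per_pct,
        per_stratum_counts=per_counts,
    )
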