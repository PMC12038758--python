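"""Synthetic sectioned clinic notes with gold-standard PROM annotations.

Real chiropractic clinic notes are protected health data, so every pipeline
stage here is exercised on generated corpora instead.  The generator
emulates the *structural* features the pipeline consumes — SOAP-style
sections with headers, abbreviation legends and medication lists, visit
sequences with care gaps, configurable PROM-mention prevalence, typos
aligned with the fuzzy-match policy, and longer first-consult notes — and
nothing more: the filler text makes no attempt at clinical plausibility.

Every planted mention records its exact character offsets as a gold span,
so span-level recall is checkable by construction.  "Decoy" mentions are
lexicon terms planted only inside excluded sections (an abbreviation
legend); they make a note lexically positive but gold-negative, which is
what the section filter exists to handle.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Callable, Sequence

import numpy as np
from pydantic import BaseModel, Field

from promdoc.corpus_prep import (
    ClinicNote,
    VisitCategory,
    VisitRecord,
    assign_visit_categories,
    build_metadata_header,
    build_visit_records,
)
from promdoc.lexicon import FuzzPolicy, PromCatalog, PromDefinition, default_catalog
from promdoc.matcher import PromSpan

__all__ = [
    "GeneratorConfig",
    "GoldNote",
    "GOALS_OF_CARE_EXAMPLE",
    "generate_patient_history",
    "generate_note",
    "generate_corpus",
    "make_high_probability_set",
]

#: The known hard case for the governing-section rule: an excluded
#: Goals-of-Care section re-opened mid-line by an inline include header,
#: so the trailing PROM abbreviation is (deliberately) kept.
GOALS_OF_CARE_EXAMPLE = "Goals of Care: Improve outcome measures, reduce ODI by 20%"


class GeneratorConfig(BaseModel):
    """Study-shaped corpus conditions.

    Defaults mirror the corpus the pipeline is designed for: ~17% of notes
    document a PROM, patients have a median of about 5 visits within the
    year after consultation, and about a quarter of patients have at least
    one >60-day care gap.
    """

    n_patients: int = Field(default=100, ge=1)
    n_notes: int | None = None  # stop once this many notes exist
    visit_geometric_p: float = 0.16  # median ~5 visits per patient
    max_visits: int = 30
    prom_prevalence: float = Field(default=0.17, ge=0.0, le=1.0)
    gap_probability: float = Field(default=0.25, ge=0.0, le=1.0)
    gap_threshold_days: int = 60
    typo_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    excluded_mention_rate: float = Field(default=0.10, ge=0.0, le=1.0)
    facility_count: int = Field(default=20, ge=1)
    consult_length_factor: float = 2.0  # first-consult notes ~2x longer
    seed: int = 0

    model_config = {"frozen": True}

    def content_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class GoldNote:
    note: ClinicNote
    visit: VisitRecord
    gold_spans: tuple[PromSpan, ...]
    gold_label: bool
    decoy_spans: tuple[PromSpan, ...] = ()


_FILLER = [
    "Veteran reports gradual improvement with the home exercise program.",
    "Tolerated treatment well without adverse reaction.",
    "Gait steady without an assistive device.",
    "Cervical and thoracic mobility within normal limits.",
    "Continue current plan of care with follow-up in two weeks.",
    "Discussed activity modification and ergonomic strategies.",
    "Palpation reveals mild paraspinal tenderness on the left.",
    "Range of motion improving since the prior visit.",
    "No new complaints reported today.",
    "Sleep quality reported as fair.",
    "Symptoms aggravated by prolonged sitting at work.",
    "Manual therapy applied to the lumbar region.",
]

_MED_FILLER = [
    "Ibuprofen 800 mg as needed.",
    "Cyclobenzaprine 5 mg nightly.",
    "Acetaminophen 500 mg twice daily.",
]

_LEGEND_FILLER = [
    "HEP - home exercise program.",
    "WNL - within normal limits.",
    "F/U - follow up.",
]

_EDU_FILLER = [
    "Provided handout on safe lifting mechanics.",
    "Reviewed posture recommendations for desk work.",
]

# (section header or None=preamble, sentence pool)
_TEMPLATES: list[list[tuple[str | None, list[str]]]] = [
    [
        ("Subjective", _FILLER),
        ("Objective", _FILLER),
        ("Assessment", _FILLER),
        ("Plan", _FILLER),
    ],
    [
        (None, _FILLER),
        ("History", _FILLER),
        ("Physical Exam", _FILLER),
        ("Assessment", _FILLER),
        ("Plan", _FILLER),
    ],
    [
        ("Chief Complaint", _FILLER),
        ("Subjective", _FILLER),
        ("Medications", _MED_FILLER),
        ("Objective", _FILLER),
        ("Plan", _FILLER),
    ],
    [
        ("Subjective", _FILLER),
        ("Objective", _FILLER),
        ("Patient Education", _EDU_FILLER),
        ("Plan", _FILLER),
    ],
]

_MENTION_PREFIXES = ["", "Completed ", "Reviewed ", "Administered "]
_MENTION_SUFFIXES = [
    " score 24/50 recorded today.",
    " completed at intake.",
    " reviewed with the patient.",
    " 31/70.",
]

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def _typo(token: str, rng: np.random.Generator) -> str:
    """One character-level edit: substitution, deletion, or transposition."""
    i = int(rng.integers(0, len(token)))
    op = int(rng.integers(0, 3))
    if op == 0:  # substitute
        repl = _LETTERS[int(rng.integers(0, 26))]
        while repl == token[i].lower():
            repl = _LETTERS[int(rng.integers(0, 26))]
        return token[:i] + repl + token[i + 1 :]
    if op == 1 and len(token) > 1:  # delete
        return token[:i] + token[i + 1 :]
    if len(token) > 1:  # transpose
        j = min(i, len(token) - 2)
        return token[:j] + token[j + 1] + token[j] + token[j + 2 :]
    return token


def generate_patient_history(
    config: GeneratorConfig, rng: np.random.Generator, patient_id: str = "P0"
) -> list[VisitRecord]:
    """One patient's categorized visit sequence within a year of consultation.

    With probability ``gap_probability`` the history is guaranteed to contain
    one inter-visit interval strictly exceeding the gap threshold; the gap is
    placed early enough that the 365-day window never truncates it away.
    """
    has_gap = bool(rng.random() < config.gap_probability)
    n = 1 + int(rng.geometric(config.visit_geometric_p))
    n = int(min(n, config.max_visits))
    if has_gap:
        n = max(n, 2)
    intervals = rng.integers(5, 21, size=max(n - 1, 0)).tolist()
    if has_gap:
        gap_at = int(rng.integers(0, min(len(intervals), 4)))
        intervals[gap_at] = int(rng.integers(config.gap_threshold_days + 1, 121))
    consult = date(2019, 1, 1) + timedelta(days=int(rng.integers(0, 200)))
    facility = f"F{int(rng.integers(0, config.facility_count)):03d}"
    dates = [consult]
    for iv in intervals:
        nxt = dates[-1] + timedelta(days=int(iv))
        if (nxt - consult).days > 365:
            break
        dates.append(nxt)
    visits = [(f"{patient_id}-v{i + 1}", d, facility) for i, d in enumerate(dates)]
    return assign_visit_categories(
        build_visit_records(patient_id, visits), config.gap_threshold_days
    )


def _pick_surface(
    definition: PromDefinition,
    rng: np.random.Generator,
    typo_rate: float,
    fuzz: FuzzPolicy,
) -> tuple[str, str]:
    """Choose a surface form and its match kind for one planted mention."""
    roll = rng.random()
    if roll < 0.35 and definition.abbreviations:
        return definition.abbreviations[int(rng.integers(0, len(definition.abbreviations)))], "abbreviation"
    alias = definition.surface_forms()[int(rng.integers(0, len(definition.surface_forms())))]
    if (
        definition.allow_fuzzy
        and rng.random() < typo_rate
        and any(len(t) >= fuzz.min_token_len for t in alias.split())
    ):
        toks = alias.split()
        eligible = [i for i, t in enumerate(toks) if len(t) >= fuzz.min_token_len]
        i = eligible[int(rng.integers(0, len(eligible)))]
        toks[i] = _typo(toks[i], rng)
        return " ".join(toks), "fuzzy"
    return alias, "alias"


class _BodyBuilder:
    """Accumulates body text while tracking exact character offsets."""

    def __init__(self) -> None:
        self.parts: list[str] = []
        self.cursor = 0

    def write(self, text: str) -> int:
        start = self.cursor
        self.parts.append(text)
        self.cursor += len(text)
        return start

    def text(self) -> str:
        return "".join(self.parts)


def generate_note(
    visit: VisitRecord,
    config: GeneratorConfig,
    rng: np.random.Generator,
    catalog: PromCatalog | None = None,
    fuzz: FuzzPolicy | None = None,
) -> GoldNote:
    """Assemble one sectioned note for a visit, with gold spans by construction.

    With probability ``prom_prevalence`` the note carries 1-3 PROM mentions
    planted inside include-disposition sections (gold positive); with
    probability ``excluded_mention_rate`` a lexicon term is planted *only*
    inside an appended abbreviation legend (gold negative decoy).
    First-consult notes draw proportionally more filler sentences.
    """
    catalog = catalog or default_catalog()
    fuzz = fuzz or FuzzPolicy()
    template = _TEMPLATES[int(rng.integers(0, len(_TEMPLATES)))]
    is_consult = visit.category is VisitCategory.FIRST_CONSULT
    length_factor = config.consult_length_factor if is_consult else 1.0

    positive = bool(rng.random() < config.prom_prevalence)
    n_mentions = int(rng.integers(1, 4)) if positive else 0
    include_slots = [i for i, (hdr, _) in enumerate(template) if hdr is None or hdr not in
                     ("Medications", "Patient Education")]
    mention_sections = (
        rng.choice(include_slots, size=n_mentions, replace=True).tolist()
        if n_mentions
        else []
    )
    decoy = bool(rng.random() < config.excluded_mention_rate)

    b = _BodyBuilder()
    gold: list[PromSpan] = []
    for si, (header, pool) in enumerate(template):
        if header is not None:
            b.write(f"{header}:\n")
        n_sent = max(1, int(round(length_factor * rng.integers(2, 6))))
        sentences = [pool[int(rng.integers(0, len(pool)))] for _ in range(n_sent)]
        for k in range(mention_sections.count(si)):
            definition = catalog.definitions[int(rng.integers(0, len(catalog)))]
            surface, kind = _pick_surface(definition, rng, config.typo_rate, fuzz)
            prefix = _MENTION_PREFIXES[int(rng.integers(0, len(_MENTION_PREFIXES)))]
            suffix = _MENTION_SUFFIXES[int(rng.integers(0, len(_MENTION_SUFFIXES)))]
            pos = int(rng.integers(0, len(sentences) + 1))
            sentences.insert(pos, (prefix, surface, suffix, definition.prom_id, kind))
        for s in sentences:
            if isinstance(s, tuple):
                prefix, surface, suffix, prom_id, kind = s
                b.write(prefix)
                start = b.write(surface)
                gold.append(
                    PromSpan(
                        start=start,
                        end=start + len(surface),
                        surface=surface,
                        prom_id=prom_id,
                        source="human",
                        match_kind=kind,
                    )
                )
                b.write(suffix + " ")
            else:
                b.write(s + " ")
        b.write("\n")

    decoys: list[PromSpan] = []
    if decoy:
        b.write("Abbreviations:\n")
        b.write(_LEGEND_FILLER[int(rng.integers(0, len(_LEGEND_FILLER)))] + " ")
        definition = catalog.definitions[int(rng.integers(0, len(catalog)))]
        abbrev = definition.abbreviations[0] if definition.abbreviations else ""
        if abbrev:
            start = b.write(abbrev)
            decoys.append(
                PromSpan(
                    start=start,
                    end=start + len(abbrev),
                    surface=abbrev,
                    prom_id=definition.prom_id,
                    source="human",
                    match_kind="abbreviation",
                )
            )
            b.write(" - ")
        start = b.write(definition.canonical_name)
        decoys.append(
            PromSpan(
                start=start,
                end=start + len(definition.canonical_name),
                surface=definition.canonical_name,
                prom_id=definition.prom_id,
                source="human",
                match_kind="alias",
            )
        )
        b.write(".\n")

    body = b.text()
    note = ClinicNote(
        visit_id=visit.visit_id,
        patient_id=visit.patient_id,
        service_date=visit.service_date,
        facility_id=visit.facility_id,
        header=build_metadata_header(visit),
        body=body,
        source_note_ids=(f"{visit.visit_id}-n1",),
    )
    for sp in gold + decoys:  # construction invariant
        assert body[sp.start : sp.end] == sp.surface
    return GoldNote(
        note=note,
        visit=visit,
        gold_spans=tuple(gold),
        gold_label=bool(gold),
        decoy_spans=tuple(decoys),
    )


def generate_corpus(
    config: GeneratorConfig,
    catalog: PromCatalog | None = None,
) -> tuple[list[GoldNote], dict]:
    """Generate a full corpus plus a manifest that makes it regenerable.

    Patients are drawn until ``n_patients`` (or ``n_notes``, when set) is
    reached.  The manifest records the seed, a config hash and per-stratum
    counts; the same config regenerates the corpus bit-identically.
    """
    catalog = catalog or default_catalog()
    rng = np.random.default_rng(config.seed)
    notes: list[GoldNote] = []
    pid = 0
    while pid < config.n_patients:
        history = generate_patient_history(config, rng, patient_id=f"P{pid:05d}")
        for visit in history:
            notes.append(generate_note(visit, config, rng, catalog))
            if config.n_notes is not None and len(notes) >= config.n_notes:
                break
        pid += 1
        if config.n_notes is not None and len(notes) >= config.n_notes:
            break
    if config.n_notes is not None:
        notes = notes[: config.n_notes]
    cat_counts: dict[str, int] = {}
    for gn in notes:
        key = gn.visit.category.value if gn.visit.category else "UNSET"
        cat_counts[key] = cat_counts.get(key, 0) + 1
    manifest = {
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "config": config.model_dump(),
        "n_notes": len(notes),
        "n_patients": pid,
        "n_positive": sum(gn.gold_label for gn in notes),
        "category_counts": cat_counts,
    }
    return notes, manifest


def make_high_probability_set(
    corpus: Sequence[GoldNote],
    matcher: Callable[[ClinicNote], bool],
    n: int = 200,
) -> list[GoldNote]:
    """Programmatic labeling: select ``n`` notes the matcher flags positive.

    Used to enrich positive prevalence in a training pool beyond a random
    sample's base rate.  Returns fewer than ``n`` (with a warning) when the
    matcher finds fewer positives.
    """
    positives = [gn for gn in corpus if matcher(gn.note)]
    if len(positives) < n:
        warnings.warn(
            f"only {len(positives)} matcher-positive notes available (requested {n})",
            stacklevel=2,
        )
        return positives
    return positives[:n]
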