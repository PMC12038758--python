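"""Corpus preparation: one merged note per visit, headers, categories, sampling.

Raw clinic notes arrive many-per-visit (e.g. a resident note and an attending
note for the same encounter).  This module concatenates them into a 1-to-1
visit<->note corpus, writes a machine-parseable metadata header for each note,
tags every visit with exactly one of five exclusive categories, and provides
the descriptive token-length statistics and the stratified sampling scheme
used to draw an annotation set.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

#: Delimiter separating individual source notes inside a merged note body.
#: An improbable character sigil so it can never collide with clinical text.
NOTE_DELIMITER = "\n@@@|||NOTE-BREAK|||@@@\n"

#: Delimiter separating the metadata header from the note body.
HEADER_DELIMITER = "\n###===END-OF-METADATA===###\n"


class VisitCategory(str, Enum):
    """The five exclusive visit categories within one year of consultation."""

    FIRST_CONSULT = "FIRST_CONSULT"
    FINAL_WITHIN_YEAR = "FINAL_WITHIN_YEAR"
    PRE_GAP = "PRE_GAP"
    POST_GAP = "POST_GAP"
    INTERMEDIATE = "INTERMEDIATE"


#: Precedence used when a visit qualifies for more than one category.
CATEGORY_PRECEDENCE = (
    VisitCategory.FIRST_CONSULT,
    VisitCategory.FINAL_WITHIN_YEAR,
    VisitCategory.PRE_GAP,
    VisitCategory.POST_GAP,
    VisitCategory.INTERMEDIATE,
)


@dataclass(frozen=True)
class RawNote:
    """A single authored note attached to one clinic visit."""

    note_id: str
    visit_id: str
    patient_id: str
    service_date: date
    facility_id: str
    author_role: str
    text: str

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError(f"note {self.note_id}: empty text")


@dataclass(frozen=True)
class ClinicNote:
    """One merged note per visit: metadata header plus concatenated body."""

    visit_id: str
    patient_id: str
    service_date: date
    facility_id: str
    header: str
    body: str
    source_note_ids: tuple[str, ...]


@dataclass
class VisitRecord:
    """Visit-level metadata: position in the care episode and gap distances."""

    visit_id: str
    patient_id: str
    service_date: date
    facility_id: str
    consult_date: date
    visit_index: int
    visit_total: int
    days_since_prev: int | None = None
    days_to_next: int | None = None
    category: VisitCategory | None = None


@dataclass(frozen=True)
class LengthStats:
    group_label: str
    n: int
    mean_tokens: float
    sd_tokens: float
    overflow_count: int

    #: histogram overflow threshold in tokens
    OVERFLOW: int = field(default=2000, repr=False)


def merge_visit_notes(notes: Sequence[RawNote], delimiter: str = NOTE_DELIMITER) -> ClinicNote:
    """Concatenate all notes for one visit into a single body.

    Notes are joined in service order (ties broken by note_id) regardless of
    author, separated by ``delimiter``.  The source order is recorded so the
    merge is auditable.
    """
    if not notes:
        raise ValueError("no notes for visit")
    visit_ids = {n.visit_id for n in notes}
    if len(visit_ids) != 1:
        raise ValueError(f"visit mismatch: {sorted(visit_ids)}")
    dates = {n.service_date for n in notes}
    if len(dates) != 1:
        raise ValueError(f"visit mismatch: multiple service dates {sorted(dates)}")
    ordered = sorted(notes, key=lambda n: (n.service_date, n.note_id))
    first = ordered[0]
    return ClinicNote(
        visit_id=first.visit_id,
        patient_id=first.patient_id,
        service_date=first.service_date,
        facility_id=first.facility_id,
        header="",
        body=delimiter.join(n.text for n in ordered),
        source_note_ids=tuple(n.note_id for n in ordered),
    )


_HDR_KEYS = ("patient", "visit", "date", "facility", "consult")


def build_metadata_header(visit: VisitRecord, delimiter: str = HEADER_DELIMITER) -> str:
    """Render the visit metadata header that prefixes each merged note.

    The header carries identifiers, dates, the ``visit {i} of {n}`` position
    phrase, and the day distances to the neighbouring visits when they exist.
    It is terminated by ``delimiter`` so downstream components can split it
    from the clinical body without ambiguity.
    """
    lines = [
        f"patient: {visit.patient_id}",
        f"visit: {visit.visit_id}",
        f"date: {visit.service_date.isoformat()}",
        f"facility: {visit.facility_id}",
        f"consult: {visit.consult_date.isoformat()}",
        f"visit {visit.visit_index} of {visit.visit_total}",
    ]
    if visit.days_since_prev is not None:
        lines.append(f"days since previous visit: {visit.days_since_prev}")
    if visit.days_to_next is not None:
        lines.append(f"days to next visit: {visit.days_to_next}")
    return "\n".join(lines) + delimiter


def parse_metadata_header(header: str, delimiter: str = HEADER_DELIMITER) -> VisitRecord:
    """Inverse of :func:`build_metadata_header` (lossless on metadata fields)."""
    text = header.split(delimiter)[0]
    kv: dict[str, str] = {}
    index = total = None
    since = to_next = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("visit ") and " of " in line and ":" not in line:
            left, right = line[len("visit "):].split(" of ")
            index, total = int(left), int(right)
        elif line.startswith("days since previous visit:"):
            since = int(line.split(":", 1)[1])
        elif line.startswith("days to next visit:"):
            to_next = int(line.split(":", 1)[1])
        elif ":" in line:
            key, val = line.split(":", 1)
            kv[key.strip()] = val.strip()
    missing = [k for k in _HDR_KEYS if k not in kv]
    if missing or index is None:
        raise ValueError(f"malformed header, missing {missing or ['visit position']}")
    return VisitRecord(
        visit_id=kv["visit"],
        patient_id=kv["patient"],
        service_date=date.fromisoformat(kv["date"]),
        facility_id=kv["facility"],
        consult_date=date.fromisoformat(kv["consult"]),
        visit_index=index,
        visit_total=total,
        days_since_prev=since,
        days_to_next=to_next,
    )


def build_visit_records(
    patient_id: str,
    visits: Sequence[tuple[str, date, str]],
) -> list[VisitRecord]:
    """Build :class:`VisitRecord` rows from ``(visit_id, service_date, facility_id)``
    tuples for a single patient, computing index, total and gap distances.

    The first visit anchors the consultation date; callers are expected to have
    already restricted visits to one year after it.
    """
    if not visits:
        raise ValueError("empty visit list")
    ordered = sorted(visits, key=lambda v: (v[1], v[0]))
    consult = ordered[0][1]
    total = len(ordered)
    records: list[VisitRecord] = []
    for i, (vid, d, fac) in enumerate(ordered):
        rec = VisitRecord(
            visit_id=vid,
            patient_id=patient_id,
            service_date=d,
            facility_id=fac,
            consult_date=consult,
            visit_index=i + 1,
            visit_total=total,
            days_since_prev=(d - ordered[i - 1][1]).days if i > 0 else None,
            days_to_next=(ordered[i + 1][1] - d).days if i + 1 < total else None,
        )
        records.append(rec)
    return records


def assign_visit_categories(
    visits: Sequence[VisitRecord], gap_threshold_days: int = 60
) -> list[VisitRecord]:
    """Tag each visit of one patient with exactly one of five categories.

    A care gap is an inter-visit interval strictly greater than
    ``gap_threshold_days``.  When a visit qualifies for several labels the
    fixed precedence FIRST_CONSULT > FINAL_WITHIN_YEAR > PRE_GAP > POST_GAP >
    INTERMEDIATE resolves the collision, keeping the categories exclusive.
    """
    if not visits:
        raise ValueError("empty visit list")
    dates = [v.service_date for v in visits]
    if dates != sorted(dates):
        raise ValueError("visits must be sorted ascending by service_date")
    consult = visits[0].consult_date
    for v in visits:
        if (v.service_date - consult).days > 365:
            raise ValueError(f"visit {v.visit_id} outside 1-year window")
    out: list[VisitRecord] = []
    n = len(visits)
    for i, v in enumerate(visits):
        if i == 0:
            cat = VisitCategory.FIRST_CONSULT
        elif i == n - 1:
            cat = VisitCategory.FINAL_WITHIN_YEAR
        elif v.days_to_next is not None and v.days_to_next > gap_threshold_days:
            cat = VisitCategory.PRE_GAP
        elif v.days_since_prev is not None and v.days_since_prev > gap_threshold_days:
            cat = VisitCategory.POST_GAP
        else:
            cat = VisitCategory.INTERMEDIATE
        out.append(replace(v, category=cat) if isinstance(v, VisitRecord) else v)
    return out


def whitespace_token_count(text: str) -> int:
    """Number of maximal non-whitespace runs (the corpus length measure)."""
    return len(text.split())


def length_stats(group_label: str, token_counts: Sequence[int], overflow: int = 2000) -> LengthStats:
    """Descriptive token-length summary for one group of notes."""
    arr = np.asarray(token_counts, dtype=float)
    n = arr.size
    return LengthStats(
        group_label=group_label,
        n=int(n),
        mean_tokens=float(arr.mean()) if n else 0.0,
        sd_tokens=float(arr.std(ddof=1)) if n > 1 else 0.0,
        overflow_count=int((arr > overflow).sum()),
        OVERFLOW=overflow,
    )


def stratified_annotation_sample(
    corpus: Sequence[tuple[ClinicNote, VisitRecord]],
    n: int = 300,
    seed: int = 0,
    n_draws: int = 25,
) -> list[str]:
    """Draw an annotation sample balanced across visit categories.

    Per-category quotas differ by at most one (subject to availability).  The
    draw is repeated ``n_draws`` times under the seeded generator and the
    candidate covering the largest number of distinct facilities is returned,
    mirroring a sampling scheme repeated until facility coverage is maximal.
    Deterministic given ``seed``.
    """
    if n <= 0:
        raise ValueError("sample size must be positive")
    if not corpus:
        raise ValueError("empty corpus")
    if len(corpus) <= n:
        warnings.warn(
            f"corpus ({len(corpus)}) smaller than requested sample ({n}); returning all",
            stacklevel=2,
        )
        return [note.visit_id for note, _ in corpus]

    by_cat: dict[VisitCategory, list[int]] = defaultdict(list)
    for idx, (_, rec) in enumerate(corpus):
        if rec.category is None:
            raise ValueError(f"visit {rec.visit_id} has no category")
        by_cat[rec.category].append(idx)
    cats = sorted(by_cat, key=lambda c: c.value)
    rng = np.random.default_rng(seed)

    best: list[str] | None = None
    best_fac = -1
    for _ in range(n_draws):
        chosen: list[int] = []
        # equal quotas, spreading the remainder; spill unmet quota to the pool
        base, extra = divmod(n, len(cats))
        quotas = {c: base + (1 if j < extra else 0) for j, c in enumerate(cats)}
        deficit = 0
        for c in cats:
            pool = by_cat[c]
            take = min(quotas[c], len(pool))
            deficit += quotas[c] - take
            chosen.extend(rng.choice(pool, size=take, replace=False).tolist())
        if deficit:
            remaining = [i for i in range(len(corpus)) if i not in set(chosen)]
            top_up = min(deficit, len(remaining))
            chosen.extend(rng.choice(remaining, size=top_up, replace=False).tolist())
        facs = {corpus[i][1].facility_id for i in chosen}
        if len(facs) > best_fac:
            best_fac = len(facs)
            best = [corpus[i][0].visit_id for i in chosen]
    assert best is not None
    return best


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    z: float
    p_raw: float
    p_adjusted: float
    reject: bool


@dataclass(frozen=True)
class GroupLengthComparison:
    kruskal_statistic: float
    omnibus_p: float
    alpha: float
    n_comparisons: int
    pairwise: tuple[PairwiseComparison, ...]


def _dunn_pairwise(
    groups: Mapping[str, Sequence[float]], alpha: float
) -> tuple[int, list[PairwiseComparison]]:
    """Dunn's rank-based post-hoc z tests with tie correction and Bonferroni."""
    labels = list(groups)
    all_vals = np.concatenate([np.asarray(groups[g], dtype=float) for g in labels])
    ranks = stats.rankdata(all_vals)
    sizes = [len(groups[g]) for g in labels]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = {
        g: ranks[bounds[i]:bounds[i + 1]].mean() for i, g in enumerate(labels)
    }
    big_n = all_vals.size
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (big_n - 1))
    k = len(labels)
    m = k * (k - 1) // 2
    out: list[PairwiseComparison] = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = labels[i], labels[j]
            se = np.sqrt(
                (big_n * (big_n + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j])
            )
            z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
            p_raw = float(2.0 * stats.norm.sf(abs(z)))
            p_adj = min(1.0, p_raw * m)
            out.append(
                PairwiseComparison(a, b, float(z), p_raw, p_adj, p_adj < alpha)
            )
    return m, out


def compare_group_lengths(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> GroupLengthComparison:
    """Kruskal-Wallis omnibus test plus Dunn pairwise tests (Bonferroni).

    Used to compare tokenized note lengths across visit categories or fiscal
    years; a rank-based design because length distributions are right-skewed.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    stat, p = stats.kruskal(*[np.asarray(v, dtype=float) for v in groups.values()])
    m, pairwise = _dunn_pairwise(groups, alpha)
    return GroupLengthComparison(
        kruskal_statistic=float(stat),
        omnibus_p=float(p),
        alpha=alpha,
        n_comparisons=m,
        pairwise=tuple(pairwise),
    )


def merge_corpus(
    raw_notes: Iterable[RawNote],
    gap_threshold_days: int = 60,
    delimiter: str = NOTE_DELIMITER,
) -> list[tuple[ClinicNote, VisitRecord]]:
    """Full corpus preparation: group raw notes by visit, merge, categorize,
    and prepend metadata headers.  Returns ``(note, visit_record)`` pairs.
    """
    by_visit: dict[str, list[RawNote]] = defaultdict(list)
    for note in raw_notes:
        by_visit[note.visit_id].append(note)
    merged = {vid: merge_visit_notes(notes, delimiter) for vid, notes in by_visit.items()}

    by_patient: dict[str, list[ClinicNote]] = defaultdict(list)
    for note in merged.values():
        by_patient[note.patient_id].append(note)

    out: list[tuple[ClinicNote, VisitRecord]] = []
    for pid, notes in sorted(by_patient.items()):
        tuples = [(nb.visit_id, nb.service_date, nb.facility_id) for nb in notes]
        records = assign_visit_categories(
            build_visit_records(pid, tuples), gap_threshold_days
        )
        rec_by_visit = {r.visit_id: r for r in records}
        for nb in sorted(notes, key=lambda x: (x.service_date, x.visit_id)):
            rec = rec_by_visit[nb.visit_id]
            header = build_metadata_header(rec)
            out.append((replace(nb, header=header), rec))
    return out
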