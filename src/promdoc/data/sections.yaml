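# Default note-section header lexicon with include/exclude dispositions.
# Non-inline patterns match as line-initial headers ending in a colon
# (e.g. "Subjective:"); inline patterns may open a section mid-line without
# a colon (e.g. "outcome measures" inside a goals-of-care sentence).
# Excluded sections are places where a PROM term does not document PROM use:
# abbreviation legends, medication lists, goals of care, patient education,
# and template boilerplate.
section_rules:
  - {pattern: Subjective, disposition: include}
  - {pattern: Objective, disposition: include}
  - {pattern: Assessment, disposition: include}
  - {pattern: Plan, disposition: include}
  - {pattern: History, disposition: include}
  - {pattern: History of Present Illness, disposition: include}
  - {pattern: Interval History, disposition: include}
  - {pattern: Chief Complaint, disposition: include}
  - {pattern: Physical Exam, disposition: include}
  - {pattern: Examination, disposition: include}
  - {pattern: Treatment, disposition: include}
  - {pattern: Progress, disposition: include}
  - {pattern: Outcome Measures, disposition: include, inline: true}
  - {pattern: Medications, disposition: exclude}
  - {pattern: Medication List, disposition: exclude}
  - {pattern: Current Medications, disposition: exclude}
  - {pattern: Allergies, disposition: exclude}
  - {pattern: Abbreviations, disposition: exclude}
  - {pattern: Abbreviation Legend, disposition: exclude}
  - {pattern: Goals of Care, disposition: exclude}
  - {pattern: Patient Education, disposition: exclude}
  - {pattern: Patient Instructions, disposition: exclude}
  - {pattern: Template, disposition: exclude}
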