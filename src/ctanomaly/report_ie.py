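"""Rule-based information extraction from free-text radiology reports.

The extraction schema has two stages: (1) tag *entities* — observations
(e.g. "nodule"), clinical findings (e.g. "metastasis") and modifiers
(location, certainty, change, characteristics, size) — then (2) link each
modifier to its nearest non-modifier entity within the same sentence.
Each observation/clinical-finding entity receives an ordinal certainty
grade from 0 (definite absence) to 4 (definite presence) via a cue table;
grade 0 maps to "no finding" and grades 1–4 to "abnormal finding".
Findings are finally routed to per-organ disease-category label vectors,
with kidney findings split left/right by the location modifier.

The engine is deterministic and lexicon-driven; a learned tagger can be
plugged in by implementing :class:`EntityTagger`.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from .schema import OTHER_CATEGORY, TARGET_ORGANS, categories_for

__all__ = [
    "Entity",
    "Relation",
    "FindingRecord",
    "OrganLabelVector",
    "Lexicon",
    "load_lexicon",
    "extract_entities",
    "extract_relations",
    "grade_certainty",
    "binarize_certainty",
    "map_to_organ_labels",
    "evaluate_ie",
    "ReportLabelExtractor",
]

MODIFIER_SUBTYPES = ("location", "certainty", "change", "characteristics", "size")


class ConfigurationError(ValueError):
    """Lexicon or cue-table misconfiguration."""


@dataclass(frozen=True)
class Entity:
    id: str
    start: int
    end: int
    text: str
    etype: str  # observation | clinical_finding | modifier
    modifier_subtype: str | None = None

    def __post_init__(self) -> None:
        if (self.etype == "modifier") != (self.modifier_subtype is not None):
            raise ValueError("modifier_subtype present iff etype == 'modifier'")


@dataclass(frozen=True)
class Relation:
    head_id: str  # modifier
    tail_id: str  # observation or clinical_finding
    rtype: str = "modifies"


@dataclass
class FindingRecord:
    organ: str | None
    category: str | None
    certainty: int
    source_entity_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.certainty not in (0, 1, 2, 3, 4):
            raise ValueError(f"certainty grade must be in 0..4, got {self.certainty}")


@dataclass
class OrganLabelVector:
    organ: str
    categories: dict[str, int]

    @property
    def abnormal(self) -> int:
        return int(any(self.categories.values()))


class Lexicon:
    """Compiled lexicon: entity surface forms, cue grades, category tables."""

    def __init__(self, raw: Mapping) -> None:
        self.raw = dict(raw)
        entities = raw.get("entities", {})
        if not entities:
            raise ConfigurationError("lexicon defines no entity surface forms")
        self.patterns: list[tuple[re.Pattern, str, str | None]] = []
        for etype in ("observation", "clinical_finding"):
            for form in entities.get(etype, []):
                self.patterns.append((self._compile(form), etype, None))
        for subtype in MODIFIER_SUBTYPES:
            for form in entities.get("modifier", {}).get(subtype, []):
                self.patterns.append((self._compile(form), "modifier", subtype))
        if not self.patterns:
            raise ConfigurationError("lexicon defines no entity surface forms")
        self.certainty_grades: dict[str, int] = {
            k.lower(): int(v) for k, v in raw.get("certainty_grades", {}).items()
        }
        self.locations: dict[str, str | None] = {
            k.lower(): v for k, v in raw.get("locations", {}).items()
        }
        self.categories: dict[str, dict[str, str]] = {
            organ: {w.lower(): c for w, c in table.items()}
            for organ, table in raw.get("categories", {}).items()
        }
        self.organ_phrases: dict[str, str] = dict(raw.get("organ_phrases", {}))
        self.finding_words: dict[str, str] = dict(raw.get("finding_words", {}))
        self.templates: dict[int, str] = {
            int(k): v for k, v in raw.get("templates", {}).items()
        }

    @staticmethod
    def _compile(form: str) -> re.Pattern:
        if form.startswith("re:"):
            return re.compile(form[3:], re.IGNORECASE)
        return re.compile(r"(?<!\w)" + re.escape(form) + r"(?!\w)", re.IGNORECASE)

    def category_table(self, organ: str) -> dict[str, str]:
        key = "kidney" if organ in ("kidney_L", "kidney_R") else organ
        return self.categories.get(key, {})


def load_lexicon(path: str | None = None) -> Lexicon:
    """Load the packaged default lexicon, or one from an explicit YAML path."""
    if path is None:
        ref = importlib.resources.files("ctanomaly") / "data" / "lexicon.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return Lexicon(raw)


_SENTENCE_RE = re.compile(r"[^.!?]*[.!?]?\s*")


def sentence_spans(text: str) -> list[tuple[int, int]]:
    spans, pos = [], 0
    while pos < len(text):
        m = _SENTENCE_RE.match(text, pos)
        if m is None or m.end() == pos:
            break
        spans.append((pos, m.end()))
        pos = m.end()
    return spans


def extract_entities(text: str, lexicon: Lexicon) -> list[Entity]:
    """Tag entities by longest-match, left-to-right, case-insensitive search.

    Candidate matches from all lexicon patterns are merged; at each position
    the longest match wins (ties broken by lexicon order) and the scan
    resumes after it, so returned spans never overlap.
    """
    if not lexicon.patterns:
        raise ConfigurationError("empty lexicon")
    candidates: list[tuple[int, int, int, str, str | None]] = []
    for prio, (pat, etype, subtype) in enumerate(lexicon.patterns):
        for m in pat.finditer(text):
            candidates.append((m.start(), -(m.end() - m.start()), prio, etype, subtype))
    candidates.sort()
    entities: list[Entity] = []
    cursor = 0
    for start, neglen, _prio, etype, subtype in candidates:
        end = start - neglen
        if start < cursor:
            continue
        entities.append(
            Entity(
                id=f"e{len(entities)}",
                start=start,
                end=end,
                text=text[start:end],
                etype=etype,
                modifier_subtype=subtype,
            )
        )
        cursor = end
    return entities


def _sentence_index(spans: Sequence[tuple[int, int]], pos: int) -> int:
    for i, (a, b) in enumerate(spans):
        if a <= pos < b:
            return i
    return len(spans) - 1


def extract_relations(text: str, entities: Sequence[Entity]) -> list[Relation]:
    """Link each modifier to the nearest non-modifier entity in its sentence.

    Distance is the character gap between spans; ties break to the earlier
    (leftward) entity. Modifiers with no same-sentence target stay unlinked.
    """
    spans = sentence_spans(text)
    sent_of = {e.id: _sentence_index(spans, e.start) for e in entities}
    targets = [e for e in entities if e.etype != "modifier"]
    relations: list[Relation] = []
    for mod in entities:
        if mod.etype != "modifier":
            continue
        best: tuple[int, int] | None = None
        best_target = None
        for t in targets:
            if sent_of[t.id] != sent_of[mod.id]:
                continue
            gap = max(t.start - mod.end, mod.start - t.end, 0)
            key = (gap, t.start)
            if best is None or key < best:
                best, best_target = key, t
        if best_target is not None:
            relations.append(Relation(head_id=mod.id, tail_id=best_target.id))
    return relations


def grade_certainty(
    finding_entity: Entity,
    linked_modifiers: Iterable[Entity],
    cue_table: Mapping[str, int],
) -> int:
    """Certainty grade of a finding from its linked certainty cues.

    A finding asserted with no certainty modifier is graded 4 (definite
    presence). When several cues link to one finding the lowest grade wins,
    so an explicit negation dominates.
    """
    grades = []
    for mod in linked_modifiers:
        if mod.etype == "modifier" and mod.modifier_subtype == "certainty":
            cue = mod.text.lower()
            if cue not in cue_table:
                raise ConfigurationError(f"certainty cue not in table: {cue!r}")
            grades.append(cue_table[cue])
    return min(grades) if grades else 4


def binarize_certainty(grade: int) -> str:
    """Map grade 0 to ``no_finding`` and grades 1-4 to ``abnormal_finding``."""
    if grade not in (0, 1, 2, 3, 4):
        raise ValueError(f"certainty grade must be in 0..4, got {grade}")
    return "no_finding" if grade == 0 else "abnormal_finding"


def extract_findings(text: str, lexicon: Lexicon) -> list[FindingRecord]:
    """Full single-document pass: entities -> relations -> graded findings."""
    entities = extract_entities(text, lexicon)
    relations = extract_relations(text, entities)
    by_id = {e.id: e for e in entities}
    mods_of: dict[str, list[Entity]] = {}
    for r in relations:
        mods_of.setdefault(r.tail_id, []).append(by_id[r.head_id])
    findings: list[FindingRecord] = []
    for ent in entities:
        if ent.etype == "modifier":
            continue
        linked = mods_of.get(ent.id, [])
        grade = grade_certainty(ent, linked, lexicon.certainty_grades)
        organs: list[str] = []
        for mod in linked:
            if mod.modifier_subtype == "location":
                organ = lexicon.locations.get(mod.text.lower())
                if organ is None and mod.text.lower() in lexicon.locations:
                    organs.extend(["kidney_L", "kidney_R"])  # no laterality
                elif organ is not None:
                    organs.append(organ)
        src = [ent.id] + [m.id for m in linked]
        if not organs:
            findings.append(FindingRecord(None, None, grade, src))
        for organ in organs:
            table = lexicon.category_table(organ)
            category = table.get(ent.text.lower())
            findings.append(FindingRecord(organ, category, grade, src))
    return findings


def map_to_organ_labels(
    findings: Sequence[FindingRecord],
    lexicon: Lexicon,
    organs: Sequence[str] = TARGET_ORGANS,
) -> dict[str, OrganLabelVector]:
    """Collapse graded findings into one binary category vector per organ.

    A category is set when any finding with certainty >= 1 maps to it; finding
    words absent from the organ's correspondence table fall into ``other`` so
    the organ is still flagged abnormal. Organs with no findings are all-zero.
    """
    vectors = {
        organ: OrganLabelVector(organ, {c: 0 for c in categories_for(organ)})
        for organ in organs
    }
    for f in findings:
        if f.organ is None or f.organ not in vectors:
            continue
        if binarize_certainty(f.certainty) != "abnormal_finding":
            continue
        category = f.category if f.category is not None else OTHER_CATEGORY
        if category not in vectors[f.organ].categories:
            category = OTHER_CATEGORY
        vectors[f.organ].categories[category] = 1
    return vectors


def extract_organ_labels(
    text: str, lexicon: Lexicon, organs: Sequence[str] = TARGET_ORGANS
) -> dict[str, OrganLabelVector]:
    return map_to_organ_labels(extract_findings(text, lexicon), lexicon, organs)


class EntityTagger(Protocol):
    """Contract for a pluggable (possibly learned) entity tagger."""

    def __call__(self, text: str) -> list[Entity]: ...


class ReportLabelExtractor(BaseEstimator, TransformerMixin):
    """Transformer turning report texts into per-organ binary label frames.

    Stateless apart from the lexicon; ``fit`` only validates the lexicon so
    the extractor composes with scikit-learn pipelines.

    Parameters
    ----------
    lexicon_path : str or None
        YAML lexicon to load; ``None`` uses the packaged default.
    organs : sequence of str
        Target organs for the label vectors.
    """

    def __init__(self, lexicon_path: str | None = None, organs=TARGET_ORGANS):
        self.lexicon_path = lexicon_path
        self.organs = organs

    def fit(self, X=None, y=None):
        self.lexicon_ = load_lexicon(self.lexicon_path)
        return self

    def transform(self, X: Sequence[str]):
        """Map an iterable of report texts to a list of organ-label dicts."""
        if not hasattr(self, "lexicon_"):
            self.fit()
        return [extract_organ_labels(text, self.lexicon_, self.organs) for text in X]


def evaluate_ie(
    pred: Mapping[str, Mapping[str, OrganLabelVector]],
    truth: Mapping[str, Mapping[str, OrganLabelVector]],
    organs: Sequence[str] = TARGET_ORGANS,
) -> dict[str, dict]:
    """Per-organ agreement between extracted and reference labels.

    Compares the binary abnormal flag per (exam, organ): confusion counts,
    accuracy/sensitivity/specificity/F1 and Cohen's kappa.
    """
    from . import metrics as M

    if set(pred) != set(truth):
        raise ValueError("exam-id mismatch between predictions and truth")
    exam_ids = sorted(pred)
    out: dict[str, dict] = {}
    for organ in organs:
        p = np.array([pred[e][organ].abnormal for e in exam_ids])
        t = np.array([truth[e][organ].abnormal for e in exam_ids])
        cm = M.confusion_counts(p, t)
        rep = M.confusion_metrics(p, t, threshold=0.5)
        rep["kappa"] = M.cohens_kappa(p, t)
        rep["confusion"] = cm
        out[organ] = rep
    return out
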