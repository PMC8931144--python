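"""Vocabularies and coded interview corpora.

The unit of analysis is a *coded segment*: a section of interview narrative
to which coders assigned a set of directed dependency mentions between
cultural-value codes and biophysical-element codes.  Direction encodes
dependency of the target on the source (e.g. ``PETRELS -> HAR``: customary
harvesting depends on petrels) and is supplied by the coder, never inferred
here.  Dependencies between two biophysical elements are excluded by the
coding framework and rejected on input.

Interchange formats
-------------------
Vocabulary CSV: columns ``code,label,class[,tier][,description]`` with
``class`` in ``{value, biophysical}``.

Corpus CSV (long format): columns ``interview_id,segment_id,source,target``,
one row per mention.  A row with empty ``source`` and ``target`` declares a
segment with no coded dependencies, so that empty segments survive a
round-trip.  JSON mirror: a list of
``{"interview_id": ..., "segment_id": ..., "mentions": [{"source","target"}]}``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

VALUE = "value"
BIOPHYSICAL = "biophysical"

NodeClass = Literal["value", "biophysical"]


@dataclass(frozen=True)
class ValueCode:
    """A cultural-value code (e.g. ``PTP`` = "people to people")."""

    code: str
    label: str
    description: str = ""
    tier: str = "secondary"

    def __post_init__(self) -> None:
        if not self.code:
            raise ValidationError("value code must be non-empty")
        if not self.label:
            raise ValidationError(f"value code {self.code!r}: label must be non-empty")
        if self.tier not in ("primary", "secondary"):
            raise FormatError(
                f"value code {self.code!r}: tier must be 'primary' or 'secondary', got {self.tier!r}"
            )


@dataclass(frozen=True)
class BiophysicalCode:
    """A biophysical-element code (a species, place or ecosystem feature)."""

    code: str
    label: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.code:
            raise ValidationError("biophysical code must be non-empty")
        if not self.label:
            raise ValidationError(
                f"biophysical code {self.code!r}: label must be non-empty"
            )


@dataclass(frozen=True)
class Vocabulary:
    """The closed code sets for values and biophysical elements.

    The two code namespaces must be disjoint and both non-empty.
    """

    values: tuple[ValueCode, ...]
    biophysical: tuple[BiophysicalCode, ...]

    def __post_init__(self) -> None:
        if not self.values or not self.biophysical:
            raise ValidationError(
                "vocabulary needs at least one value and one biophysical code"
            )
        seen: set[str] = set()
        for entry in (*self.values, *self.biophysical):
            if entry.code in seen:
                raise ValidationError(f"duplicate code {entry.code!r} in vocabulary")
            seen.add(entry.code)

    @property
    def value_codes(self) -> frozenset[str]:
        return frozenset(v.code for v in self.values)

    @property
    def biophysical_codes(self) -> frozenset[str]:
        return frozenset(b.code for b in self.biophysical)

    def __contains__(self, code: str) -> bool:
        return code in self.value_codes or code in self.biophysical_codes

    def class_of(self, code: str) -> NodeClass:
        if code in self.value_codes:
            return VALUE
        if code in self.biophysical_codes:
            return BIOPHYSICAL
        raise ValidationError(f"code {code!r} not in vocabulary")

    def label_of(self, code: str) -> str:
        for entry in (*self.values, *self.biophysical):
            if entry.code == code:
                return entry.label
        raise ValidationError(f"code {code!r} not in vocabulary")


@dataclass(frozen=True, order=True)
class DependencyMention:
    """A directed dependency mention: ``target`` depends on ``source``."""

    source: str
    target: str

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValidationError(f"self-dependency {self.source!r} -> itself")

    def classes(self, vocabulary: Vocabulary) -> tuple[NodeClass, NodeClass]:
        return vocabulary.class_of(self.source), vocabulary.class_of(self.target)

    def validate(self, vocabulary: Vocabulary) -> None:
        src_cls, tgt_cls = self.classes(vocabulary)
        if src_cls == BIOPHYSICAL and tgt_cls == BIOPHYSICAL:
            raise ValidationError(
                f"mention {self.source} -> {self.target}: connections between "
                "biophysical nodes are excluded by the coding framework"
            )


@dataclass(frozen=True)
class CodedSegment:
    """One narrative section with its set of dependency mentions.

    Mentions have set semantics: repeating a dependency within a segment
    does not strengthen it, co-occurrence is counted per segment.
    """

    interview_id: str
    segment_id: str
    mentions: frozenset[DependencyMention] = frozenset()

    @property
    def key(self) -> tuple[str, str]:
        return (self.interview_id, self.segment_id)

    def codes(self) -> set[str]:
        return {c for m in self.mentions for c in (m.source, m.target)}


@dataclass
class Corpus:
    """An ordered collection of coded segments under one vocabulary."""

    vocabulary: Vocabulary
    segments: list[CodedSegment]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        problems = self.violations()
        if problems:
            raise ValidationError(problems[0], violations=problems)

    def violations(self) -> list[str]:
        """Every invariant violation in the corpus, in segment order."""
        problems: list[str] = []
        seen_keys: set[tuple[str, str]] = set()
        for seg in self.segments:
            if seg.key in seen_keys:
                problems.append(
                    f"duplicate segment ({seg.interview_id}, {seg.segment_id})"
                )
            seen_keys.add(seg.key)
            for mention in sorted(seg.mentions):
                where = f"segment ({seg.interview_id}, {seg.segment_id})"
                for code in (mention.source, mention.target):
                    if code not in self.vocabulary:
                        problems.append(f"{where}: code {code!r} not in vocabulary")
                if (
                    mention.source in self.vocabulary
                    and mention.target in self.vocabulary
                ):
                    src_cls, tgt_cls = mention.classes(self.vocabulary)
                    if src_cls == BIOPHYSICAL and tgt_cls == BIOPHYSICAL:
                        problems.append(
                            f"{where}: biophysical->biophysical mention "
                            f"{mention.source} -> {mention.target} is excluded"
                        )
        return problems

    def __len__(self) -> int:
        return len(self.segments)

    def iter_mentions(self) -> Iterator[tuple[CodedSegment, DependencyMention]]:
        for seg in self.segments:
            for mention in sorted(seg.mentions):
                yield seg, mention

    @property
    def n_mentions(self) -> int:
        return sum(len(s.mentions) for s in self.segments)

    @property
    def interview_ids(self) -> list[str]:
        out: list[str] = []
        for seg in self.segments:
            if seg.interview_id not in out:
                out.append(seg.interview_id)
        return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_VOCAB_REQUIRED = ("code", "label", "class")


def _sniff_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    return "json" if path.suffix.lower() == ".json" else "csv"


def read_vocabulary(path: str | Path, format: str | None = None) -> Vocabulary:
    """Read a vocabulary table (CSV or JSON) and validate it.

    The ``class`` column partitions codes into values and biophysical
    elements; ``tier`` and ``description`` are optional.
    """
    path = Path(path)
    fmt = _sniff_format(path, format)
    if fmt == "json":
        records = json.loads(path.read_text())
        frame = pd.DataFrame.from_records(records)
    elif fmt == "csv":
        frame = pd.read_csv(path, dtype=str).fillna("")
    else:
        raise FormatError(f"unknown vocabulary format {fmt!r}")
    missing = [c for c in _VOCAB_REQUIRED if c not in frame.columns]
    if missing:
        raise FormatError(f"vocabulary {path}: missing columns {missing}")
    return vocabulary_from_frame(frame)


def vocabulary_from_frame(frame: pd.DataFrame) -> Vocabulary:
    values: list[ValueCode] = []
    biophysical: list[BiophysicalCode] = []
    seen: set[str] = set()
    for row in frame.to_dict("records"):
        code = str(row["code"]).strip()
        if code in seen:
            raise ValidationError(f"duplicate code {code!r} in vocabulary")
        seen.add(code)
        cls = str(row["class"]).strip().lower()
        label = str(row["label"]).strip()
        desc = str(row.get("description") or "")
        if cls == VALUE:
            tier = str(row.get("tier") or "secondary")
            values.append(ValueCode(code, label, desc, tier))
        elif cls == BIOPHYSICAL:
            biophysical.append(BiophysicalCode(code, label, desc))
        else:
            raise FormatError(
                f"code {code!r}: unknown class token {cls!r} "
                "(expected 'value' or 'biophysical')"
            )
    return Vocabulary(tuple(values), tuple(biophysical))


def vocabulary_to_frame(vocabulary: Vocabulary) -> pd.DataFrame:
    rows = [
        {"code": v.code, "label": v.label, "class": VALUE, "tier": v.tier,
         "description": v.description}
        for v in vocabulary.values
    ] + [
        {"code": b.code, "label": b.label, "class": BIOPHYSICAL, "tier": "",
         "description": b.description}
        for b in vocabulary.biophysical
    ]
    return pd.DataFrame(rows, columns=["code", "label", "class", "tier", "description"])


def write_vocabulary(vocabulary: Vocabulary, path: str | Path) -> None:
    vocabulary_to_frame(vocabulary).to_csv(path, index=False)


_CORPUS_REQUIRED = ("interview_id", "segment_id", "source", "target")


def read_corpus(
    path: str | Path, vocabulary: Vocabulary, format: str | None = None
) -> Corpus:
    """Read a long-format coded-segment table into a validated :class:`Corpus`.

    Duplicate (segment, source, target) rows collapse to a single mention;
    the number collapsed is logged and recorded under
    ``metadata["n_duplicate_rows"]``.  Value->biophysical mentions are
    accepted but counted under ``metadata["n_value_to_biophysical"]`` with a
    warning: the reported analyses only use biophysical->value and
    value->value edges.
    """
    path = Path(path)
    fmt = _sniff_format(path, format)
    if fmt == "json":
        return _corpus_from_json(path, vocabulary)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _CORPUS_REQUIRED if c not in frame.columns]
    if missing:
        raise FormatError(f"corpus {path}: missing columns {missing}")
    return corpus_from_frame(frame, vocabulary, origin=str(path))


def corpus_from_frame(
    frame: pd.DataFrame, vocabulary: Vocabulary, origin: str = "<frame>"
) -> Corpus:
    segments: dict[tuple[str, str], set[DependencyMention]] = {}
    order: list[tuple[str, str]] = []
    n_duplicates = 0
    n_value_to_bio = 0
    for i, row in enumerate(frame.itertuples(index=False)):
        rownum = i + 2  # 1-based, after the header row
        key = (str(row.interview_id), str(row.segment_id))
        if key not in segments:
            segments[key] = set()
            order.append(key)
        source, target = str(row.source).strip(), str(row.target).strip()
        if source == "" and target == "":
            continue  # segment manifest row: declares an empty segment
        for code in (source, target):
            if code not in vocabulary:
                raise ValidationError(
                    f"{origin} row {rownum}: code {code!r} not in vocabulary"
                )
        mention = DependencyMention(source, target)
        src_cls, tgt_cls = mention.classes(vocabulary)
        if src_cls == BIOPHYSICAL and tgt_cls == BIOPHYSICAL:
            raise ValidationError(
                f"{origin} row {rownum}: {source} -> {target} links two "
                "biophysical elements; connections between biophysical nodes "
                "are not included"
            )
        if src_cls == VALUE and tgt_cls == BIOPHYSICAL:
            n_value_to_bio += 1
        if mention in segments[key]:
            n_duplicates += 1
        segments[key].add(mention)
    if n_duplicates:
        logger.warning(
            "%s: %d duplicate mention rows collapsed (per-segment set semantics)",
            origin, n_duplicates,
        )
    if n_value_to_bio:
        logger.warning(
            "%s: %d value->biophysical mentions accepted but ignored by the "
            "support-direction analyses", origin, n_value_to_bio,
        )
    coded = [
        CodedSegment(iv, sg, frozenset(segments[(iv, sg)])) for iv, sg in order
    ]
    return Corpus(
        vocabulary,
        coded,
        metadata={
            "origin": origin,
            "n_duplicate_rows": n_duplicates,
            "n_value_to_biophysical": n_value_to_bio,
        },
    )


def _corpus_from_json(path: Path, vocabulary: Vocabulary) -> Corpus:
    records = json.loads(path.read_text())
    rows = []
    for rec in records:
        if not rec["mentions"]:
            rows.append(
                {"interview_id": rec["interview_id"], "segment_id": rec["segment_id"],
                 "source": "", "target": ""}
            )
        for m in rec["mentions"]:
            rows.append(
                {"interview_id": rec["interview_id"], "segment_id": rec["segment_id"],
                 "source": m["source"], "target": m["target"]}
            )
    frame = pd.DataFrame(rows, columns=list(_CORPUS_REQUIRED))
    return corpus_from_frame(frame, vocabulary, origin=str(path))


def corpus_to_frame(corpus: Corpus) -> pd.DataFrame:
    """Long-format table, deterministically sorted by
    (interview_id, segment_id, source, target).  Empty segments appear as a
    single manifest row with empty source/target."""
    rows = []
    for seg in corpus.segments:
        if not seg.mentions:
            rows.append((seg.interview_id, seg.segment_id, "", ""))
        for m in seg.mentions:
            rows.append((seg.interview_id, seg.segment_id, m.source, m.target))
    frame = pd.DataFrame(rows, columns=list(_CORPUS_REQUIRED))
    return frame.sort_values(list(_CORPUS_REQUIRED), kind="mergesort").reset_index(
        drop=True
    )


def write_corpus(corpus: Corpus, path: str | Path, format: str | None = None) -> None:
    """Write a corpus; ``read_corpus`` of the result reproduces its segments
    and mentions exactly."""
    path = Path(path)
    fmt = _sniff_format(path, format)
    if fmt == "json":
        records = [
            {
                "interview_id": seg.interview_id,
                "segment_id": seg.segment_id,
                "mentions": [
                    {"source": m.source, "target": m.target}
                    for m in sorted(seg.mentions)
                ],
            }
            for seg in sorted(corpus.segments, key=lambda s: s.key)
        ]
        path.write_text(json.dumps(records, indent=1) + "\n")
    else:
        corpus_to_frame(corpus).to_csv(path, index=False)


def corpus_from_segments(
    vocabulary: Vocabulary,
    segments: Iterable[tuple[str, str, Iterable[tuple[str, str]]]],
    metadata: dict | None = None,
) -> Corpus:
    """Convenience constructor from (interview_id, segment_id, pairs) triples."""
    coded = [
        CodedSegment(iv, sg, frozenset(DependencyMention(s, t) for s, t in pairs))
        for iv, sg, pairs in segments
    ]
    return Corpus(vocabulary, coded, metadata=metadata or {})
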