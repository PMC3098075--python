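"""Reading, cleaning and structuring prescription corpora.

The on-disk contract is a UTF-8 TSV with one prescription per row::

    symptom_name <TAB> role <TAB> remedy;remedy;...

where ``role`` is ``standard`` or ``clinical``.  Symptom and remedy names
are cleaned of format-control characters on read; repeated observations of
the same (name, role) pair are merged into a single record holding all of
its prescriptions.  A gold mapping is a two-column TSV mapping each clinical
name to its standard form, or to the sentinel ``NONE`` for names that have
no meaning in the standard vocabulary.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

#: Characters stripped from every name on read: the format-control
#: characters seen in raw clinical records plus ASCII whitespace.
DEFAULT_FILTER_CHARS = frozenset("-/=") | frozenset(" \t\r\n\x0b\x0c")

#: Literal marking a clinical name that cannot be normalized.
NONE_SENTINEL = "NONE"


class CorpusError(ValueError):
    """Malformed corpus or gold-mapping input."""


class Role(str, Enum):
    STANDARD = "standard"
    CLINICAL = "clinical"

    @classmethod
    def parse(cls, token: str) -> "Role":
        try:
            return cls(token.strip().lower())
        except ValueError:
            raise CorpusError(f"unknown role token: {token!r}") from None


#: A symptom identity: its spelling plus the side of the corpus it lives on.
#: Identical spellings may occur in both roles and are kept distinct.
NameRole = tuple[str, Role]


@dataclass
class SymptomRecord:
    """One symptom name, its role, and every prescription observed for it."""

    name: str
    role: Role
    prescriptions: list[list[str]] = field(default_factory=list)

    @property
    def key(self) -> NameRole:
        return (self.name, self.role)


@dataclass
class Corpus:
    """A collection of merged symptom records from both vocabularies."""

    records: list[SymptomRecord] = field(default_factory=list)

    @property
    def standard_names(self) -> set[str]:
        return {r.name for r in self.records if r.role is Role.STANDARD}

    @property
    def clinical_names(self) -> set[str]:
        return {r.name for r in self.records if r.role is Role.CLINICAL}

    def by_key(self) -> dict[NameRole, SymptomRecord]:
        return {r.key: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class RemedyBag:
    """Multiset of remedy occurrences across all prescriptions of one name.

    ``counts[r]`` is the occurrence frequency f of remedy ``r``; ``support``
    is the plain set of remedies used at least once.
    """

    owner: str
    counts: dict[str, int]

    @property
    def support(self) -> frozenset[str]:
        return frozenset(self.counts)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class GoldMapping:
    """Expert mapping clinical name -> standard name, or None if unmappable."""

    pairs: dict[str, str | None]

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def normalizable(self) -> set[str]:
        return {c for c, s in self.pairs.items() if s is not None}


def clean_text(raw: str, filter_chars: Iterable[str] = DEFAULT_FILTER_CHARS) -> str:
    """Remove every occurrence of each filter character, preserving order.

    Cleaning is idempotent; an empty result is permitted and left to the
    caller to drop.
    """
    drop = set(filter_chars)
    return "".join(ch for ch in raw if ch not in drop)


def read_prescriptions(
    path: str | Path,
    filter_chars: Iterable[str] = DEFAULT_FILTER_CHARS,
) -> Corpus:
    """Read a prescriptions TSV into a :class:`Corpus`.

    Names and remedies are cleaned; rows whose symptom name cleans to empty
    are dropped with a warning, as are prescriptions left with no remedies.
    Repeated (name, role) rows merge into one record.
    """
    path = Path(path)
    merged: dict[NameRole, SymptomRecord] = {}
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row:
                continue
            if len(row) != 3:
                raise CorpusError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(row)}"
                )
            raw_name, raw_role, raw_remedies = row
            name = clean_text(raw_name, filter_chars)
            if not name:
                logger.warning("%s:%d: symptom name empty after cleaning; row dropped", path, lineno)
                continue
            role = Role.parse(raw_role)
            remedies = [
                cleaned
                for tok in raw_remedies.split(";")
                if (cleaned := clean_text(tok, filter_chars))
            ]
            if not remedies:
                logger.warning("%s:%d: no remedies after cleaning; row dropped", path, lineno)
                continue
            record = merged.setdefault((name, role), SymptomRecord(name=name, role=role))
            record.prescriptions.append(remedies)
    return Corpus(records=list(merged.values()))


def write_prescriptions(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus back to the prescriptions TSV format (round-trippable)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for record in corpus.records:
            for prescription in record.prescriptions:
                writer.writerow([record.name, record.role.value, ";".join(prescription)])


def build_remedy_bags(corpus: Corpus) -> dict[NameRole, RemedyBag]:
    """One bag per record, counting remedy occurrences over its prescriptions."""
    bags: dict[NameRole, RemedyBag] = {}
    for record in corpus.records:
        counts: Counter[str] = Counter()
        for prescription in record.prescriptions:
            counts.update(prescription)
        bags[record.key] = RemedyBag(owner=record.name, counts=dict(counts))
    return bags


def read_gold_mapping(
    path: str | Path,
    corpus: Corpus | None = None,
    filter_chars: Iterable[str] = DEFAULT_FILTER_CHARS,
    none_sentinel: str = NONE_SENTINEL,
) -> GoldMapping:
    """Read a two-column gold TSV; duplicates collapse, conflicts raise.

    When ``corpus`` is supplied every non-NONE target must be one of its
    standard names.
    """
    path = Path(path)
    pairs: dict[str, str | None] = {}
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row:
                continue
            if len(row) != 2:
                raise CorpusError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(row)}"
                )
            clinical = clean_text(row[0], filter_chars)
            target_raw = row[1].strip()
            target = None if target_raw == none_sentinel else clean_text(target_raw, filter_chars)
            if not clinical:
                logger.warning("%s:%d: clinical name empty after cleaning; row dropped", path, lineno)
                continue
            if clinical in pairs and pairs[clinical] != target:
                raise CorpusError(
                    f"{path}:{lineno}: conflicting targets for {clinical!r}: "
                    f"{pairs[clinical]!r} vs {target!r}"
                )
            pairs[clinical] = target
    gold = GoldMapping(pairs=pairs)
    if corpus is not None:
        standards = corpus.standard_names
        bad = {s for s in gold.pairs.values() if s is not None and s not in standards}
        if bad:
            raise CorpusError(f"gold targets missing from standard vocabulary: {sorted(bad)[:5]}")
    return gold


def write_gold_mapping(
    gold: GoldMapping, path: str | Path, none_sentinel: str = NONE_SENTINEL
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for clinical, target in gold.pairs.items():
            writer.writerow([clinical, none_sentinel if target is None else target])
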