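"""Suite-customization operations: pure HGSuite → HGSuite transformations.

These are the building blocks for reshaping a track collection before cube
analysis: relabelling metadata, splitting a suite by a metadata column,
grouping tracks by title phrases, concatenating tracks that represent the
same biological event (e.g. a C>T call on the forward strand and the
equivalent G>A call on the reverse strand), combining metadata columns, and
adding new columns.

Operations that merge track contents (:func:`concatenate_by_metadata`,
:func:`collapse_complementary`) materialize the merged tracks as new BED
files in a workspace directory with deterministic names, so the resulting
suite is self-contained.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .hgsuite_format import MISSING, HGSuite, HGSuiteError, TrackEntry
from .track_store import IndexedTrack, union, write_bed

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PYRIMIDINE_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


@dataclass(frozen=True)
class MutationTypeLabel:
    """A single-base substitution class, e.g. C>T (accepted also as "CT")."""

    ref: str
    alt: str

    def __post_init__(self):
        if self.ref not in _COMPLEMENT or self.alt not in _COMPLEMENT:
            raise ValueError(f"bases must be A/C/G/T, got {self.ref!r}>{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ, got {self.ref!r}>{self.alt!r}")

    @classmethod
    def parse(cls, text: str) -> "MutationTypeLabel":
        m = re.fullmatch(r"([ACGTacgt])\s*>?\s*([ACGTacgt])", text.strip())
        if not m:
            raise ValueError(f"cannot parse mutation type {text!r} (expected 'C>T' or 'CT')")
        return cls(m.group(1).upper(), m.group(2).upper())

    def complement(self) -> "MutationTypeLabel":
        """The same substitution read on the reverse strand."""
        return MutationTypeLabel(_COMPLEMENT[self.ref], _COMPLEMENT[self.alt])

    def pyrimidine_class(self) -> "MutationTypeLabel":
        """The strand-collapsed representative with a C or T reference."""
        return self if self.ref in ("C", "T") else self.complement()

    def __str__(self) -> str:
        return f"{self.ref}>{self.alt}"


# -- metadata-only operations ---------------------------------------------

def _require_column(suite: HGSuite, column: str) -> None:
    if column not in suite.columns:
        raise HGSuiteError(
            f"column {column!r} not in suite columns {list(suite.columns)}")


def modify_metadata(suite: HGSuite, column: str,
                    mapping: dict[str, str]) -> HGSuite:
    """Replace values in ``column`` per ``mapping``; unmapped values are
    left untouched."""
    _require_column(suite, column)
    entries = []
    for e in suite.entries:
        old = e.get(column)
        if old in mapping:
            meta = dict(e.metadata)
            meta[column] = mapping[old]
            e = replace(e, metadata=meta)
        entries.append(e)
    return suite.with_entries(entries)


def filter_by_metadata(suite: HGSuite, column: str,
                       values: str | Iterable[str]) -> HGSuite:
    """Keep entries whose ``column`` value equals ``values`` (string) or is
    a member of it (collection). Order preserved; an empty result is valid."""
    _require_column(suite, column)
    accept = {values} if isinstance(values, str) else set(values)
    return suite.with_entries(e for e in suite.entries if e.get(column) in accept)


def partition_by_metadata(suite: HGSuite, column: str) -> list[HGSuite]:
    """Divide the suite into one sub-suite per distinct value of ``column``,
    ordered lexically by value."""
    _require_column(suite, column)
    values = sorted({e.get(column) for e in suite.entries})
    return [filter_by_metadata(suite, column, v) for v in values]


def filter_by_title(suite: HGSuite, phrases: Sequence[str],
                    mode: str = "keep",
                    group_column: str = "title_group") -> HGSuite:
    """Filter or group entries by substrings of their titles.

    ``mode="keep"`` retains entries whose title contains any phrase;
    ``mode="group"`` adds a metadata column holding the first matching
    phrase (``"."`` if none matches).
    """
    if not phrases:
        raise HGSuiteError("phrase list must be non-empty")
    if mode == "keep":
        return suite.with_entries(
            e for e in suite.entries if any(p in e.title for p in phrases))
    if mode == "group":
        values = {}
        for e in suite.entries:
            values[e.title] = next((p for p in phrases if p in e.title), MISSING)
        return add_column(suite, group_column, values)
    raise ValueError(f"mode must be 'keep' or 'group', got {mode!r}")


def combine_columns(suite: HGSuite, col_a: str, col_b: str, new_name: str,
                    separator: str = "_", drop: bool = False) -> HGSuite:
    """Merge two metadata columns into ``new_name`` = "a<sep>b".

    With ``drop=True`` the source columns are removed and any hierarchy
    reference to them is rewritten to the new column (first occurrence takes
    the new column's place)."""
    _require_column(suite, col_a)
    _require_column(suite, col_b)
    if new_name in suite.columns:
        raise HGSuiteError(f"column {new_name!r} already exists")
    entries = []
    for e in suite.entries:
        meta = dict(e.metadata)
        meta[new_name] = f"{e.get(col_a)}{separator}{e.get(col_b)}"
        if drop:
            meta.pop(col_a, None)
            meta.pop(col_b, None)
        entries.append(replace(e, metadata=meta))
    if drop:
        columns = tuple(c for c in suite.columns if c not in (col_a, col_b)) + (new_name,)
        hierarchy, replaced = [], False
        for c in suite.hierarchy:
            if c in (col_a, col_b):
                if not replaced:
                    hierarchy.append(new_name)
                    replaced = True
            else:
                hierarchy.append(c)
    else:
        columns = suite.columns + (new_name,)
        hierarchy = list(suite.hierarchy)
    header = replace(suite.header, hierarchy=tuple(hierarchy))
    return replace(suite, header=header, columns=columns, entries=tuple(entries))


def add_column(suite: HGSuite, name: str,
               values: str | dict[str, str]) -> HGSuite:
    """Append a metadata column: either a constant value or a
    title → value mapping (unmapped titles get ``"."``)."""
    if name in suite.columns:
        raise HGSuiteError(f"column {name!r} already exists")
    if isinstance(values, str):
        get = lambda title: values
    else:
        unknown = sorted(set(values) - set(suite.titles))
        if unknown:
            raise HGSuiteError(f"mapping names unknown title(s): {unknown}")
        get = lambda title: values.get(title, MISSING)
    entries = [replace(e, metadata={**e.metadata, name: get(e.title)})
               for e in suite.entries]
    return replace(suite, columns=suite.columns + (name,), entries=tuple(entries))


# -- track-merging operations ---------------------------------------------

def _sanitize(label: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.+-]", "", label.replace(">", ""))


def concatenate_by_metadata(suite: HGSuite, column: str,
                            phrase_groups: Sequence[Sequence[str]],
                            track_loader: Callable[[TrackEntry], IndexedTrack],
                            workspace: str | Path,
                            labels: Sequence[str] | None = None) -> HGSuite:
    """Concatenate tracks whose ``column`` values fall in the same group.

    Entries sharing a group *and* identical values in all hierarchy columns
    above ``column`` are replaced by one entry whose track is the
    interval-wise union (multiset union for point tracks). The group's new
    value is the joined label (``"CT+GA"``) unless ``labels`` overrides it.
    Entries whose value is in no group pass through unchanged. Merged BED
    files are written to ``workspace`` with deterministic names.
    """
    _require_column(suite, column)
    groups = [tuple(g) for g in phrase_groups]
    if any(not g for g in groups):
        raise HGSuiteError("each phrase group must be non-empty")
    seen: set[str] = set()
    for g in groups:
        overlap = seen & set(g)
        if overlap:
            raise HGSuiteError(f"value(s) {sorted(overlap)} appear in multiple groups")
        seen |= set(g)
    if labels is not None and len(labels) != len(groups):
        raise HGSuiteError("labels must match phrase_groups in length")
    group_label = {g: (labels[i] if labels is not None else "+".join(g))
                   for i, g in enumerate(groups)}
    value_to_group = {v: g for g in groups for v in g}

    if column in suite.hierarchy:
        above = suite.hierarchy[:suite.hierarchy.index(column)]
    else:
        above = suite.hierarchy

    workspace = Path(workspace)
    workspace.mkdir(parents=True, exist_ok=True)

    # bucket entries; preserve first-appearance order of buckets
    buckets: dict[tuple, list[TrackEntry]] = {}
    order: list[tuple[str, object]] = []  # ("entry", e) or ("bucket", key)
    for e in suite.entries:
        v = e.get(column)
        if v not in value_to_group:
            order.append(("entry", e))
            continue
        key = (tuple(e.get(c) for c in above), value_to_group[v])
        if key not in buckets:
            buckets[key] = []
            order.append(("bucket", key))
        buckets[key].append(e)

    entries: list[TrackEntry] = []
    for kind, item in order:
        if kind == "entry":
            entries.append(item)
            continue
        key = item
        members = buckets[key]
        above_vals, group = key
        label = group_label[group]
        merged = union([track_loader(m) for m in members])
        stem_parts = [_sanitize(v) for v in above_vals if v != MISSING]
        stem = "_".join(stem_parts + [_sanitize(label)]) or _sanitize(label)
        bed_path = workspace / f"{stem}.bed"
        write_bed(merged, bed_path)
        meta = {}
        for c in suite.columns:
            vals = {m.get(c) for m in members}
            meta[c] = vals.pop() if len(vals) == 1 else MISSING
        meta[column] = label
        entries.append(TrackEntry(uri=str(bed_path), title=stem, metadata=meta))
    return suite.with_entries(entries)


def collapse_complementary(suite: HGSuite, column: str,
                           track_loader: Callable[[TrackEntry], IndexedTrack],
                           workspace: str | Path) -> HGSuite:
    """Collapse reverse-strand-equivalent mutation types.

    Every value of ``column`` must parse as a base substitution; each
    purine-reference type (e.g. G>A) is concatenated into its
    pyrimidine-reference complement class (C>T), yielding at most the six
    classes C>A, C>G, C>T, T>A, T>C, T>G. Idempotent: an already-collapsed
    suite maps to itself (labels normalized to the "C>T" spelling).
    """
    _require_column(suite, column)
    by_class: dict[str, list[str]] = {}
    for e in suite.entries:
        raw = e.get(column)
        try:
            label = MutationTypeLabel.parse(raw)
        except ValueError as err:
            raise HGSuiteError(f"entry {e.title!r}: {err}") from None
        cls = str(label.pyrimidine_class())
        by_class.setdefault(cls, [])
        if raw not in by_class[cls]:
            by_class[cls].append(raw)
    groups = [tuple(v) for v in by_class.values()]
    labels = list(by_class.keys())
    return concatenate_by_metadata(suite, column, groups, track_loader,
                                   workspace, labels=labels)
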