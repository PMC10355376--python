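"""The GSuite/hGSuite tab-separated track-collection format.

A GSuite file lists genomic tracks with per-track metadata:

.. code-block:: text

    ##location: local
    ##file format: primary
    ##track type: points
    ##genome: toy1
    ##hierarchy: genotype,mutation_type
    ###uri	title	genotype	mutation_type
    WT_CT.bed	WT_CT	WT	C>T
    ...

``##``-prefixed pragma lines carry collection-level attributes; the
``###``-prefixed column line names the per-track fields (``uri`` and
``title`` are fixed, the rest are metadata columns); each data row is one
track. The hierarchy pragma is the hierarchical extension: an ordered,
comma-separated subset of the metadata columns that declares the data-cube
dimensions.

Missing metadata values use the sentinel ``"."``. Unknown pragmas are
preserved verbatim for round-trip. Metadata values are case-sensitive, with
leading/trailing whitespace stripped at parse time.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable

MISSING = "."

_KNOWN_PRAGMAS = ("location", "file format", "track type", "genome", "hierarchy")

LOCATIONS = ("local", "remote")
FILE_FORMATS = ("primary", "preprocessed")
TRACK_TYPES = ("points", "segments", "valued_points", "valued_segments", "unknown")


class HGSuiteError(ValueError):
    """Raised for malformed or invalid hGSuite content."""


@dataclass(frozen=True)
class GSuiteHeader:
    location: str = "local"
    file_format: str = "primary"
    track_type: str = "unknown"
    genome: str = "unknown"
    hierarchy: tuple[str, ...] = ()
    extra_pragmas: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if self.location not in LOCATIONS:
            raise HGSuiteError(f"invalid location {self.location!r}")
        if self.file_format not in FILE_FORMATS:
            raise HGSuiteError(f"invalid file format {self.file_format!r}")
        if self.track_type not in TRACK_TYPES:
            raise HGSuiteError(f"invalid track type {self.track_type!r}")
        object.__setattr__(self, "hierarchy", tuple(self.hierarchy))
        object.__setattr__(self, "extra_pragmas", tuple(tuple(p) for p in self.extra_pragmas))


@dataclass(frozen=True)
class TrackEntry:
    """One track: its file URI, unique title, and metadata row."""

    uri: str
    title: str
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.title:
            raise HGSuiteError("entry title must be non-empty")

    def get(self, column: str) -> str:
        return self.metadata.get(column, MISSING)


@dataclass(frozen=True)
class HGSuite:
    """An ordered track collection with metadata columns and an optional
    hierarchy declaration."""

    header: GSuiteHeader
    columns: tuple[str, ...]
    entries: tuple[TrackEntry, ...]

    def __post_init__(self):
        object.__setattr__(self, "columns", tuple(self.columns))
        object.__setattr__(self, "entries", tuple(self.entries))
        validate(self)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def hierarchy(self) -> tuple[str, ...]:
        return self.header.hierarchy

    @property
    def titles(self) -> tuple[str, ...]:
        return tuple(e.title for e in self.entries)

    def entry(self, title: str) -> TrackEntry:
        for e in self.entries:
            if e.title == title:
                return e
        raise KeyError(title)

    def with_entries(self, entries: Iterable[TrackEntry]) -> "HGSuite":
        return replace(self, entries=tuple(entries))

    def with_hierarchy(self, hierarchy: Iterable[str]) -> "HGSuite":
        return replace(self, header=replace(self.header, hierarchy=tuple(hierarchy)))


def validate(suite: HGSuite) -> None:
    """Check suite invariants; raise :class:`HGSuiteError` on violation."""
    seen: set[str] = set()
    for e in suite.entries:
        if e.title in seen:
            raise HGSuiteError(f"duplicate track title {e.title!r}")
        seen.add(e.title)
        unknown = set(e.metadata) - set(suite.columns)
        if unknown:
            raise HGSuiteError(
                f"entry {e.title!r} has values for undeclared column(s) {sorted(unknown)}")
    for col in suite.header.hierarchy:
        if col not in suite.columns:
            raise HGSuiteError(
                f"hierarchy names column {col!r} which is not a declared "
                f"metadata column {list(suite.columns)}")


# -- parsing ---------------------------------------------------------------

def parse_hgsuite(source: str | Path | IO[str]) -> HGSuite:
    """Parse a GSuite/hGSuite file, path, or open text stream.

    Rows with fewer fields than declared columns are padded with ``"."``;
    unknown pragmas are retained for round-trip.
    """
    if isinstance(source, Path):
        text = source.read_text()
    elif isinstance(source, str):
        if source and "\n" not in source and Path(source).exists():
            text = Path(source).read_text()
        else:
            text = source
    else:
        text = source.read()

    kwargs: dict = {}
    extra: list[tuple[str, str]] = []
    columns: list[str] | None = None
    entries: list[TrackEntry] = []

    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip():
            continue
        if line.startswith("###"):
            if columns is not None:
                raise HGSuiteError(f"line {lineno}: second column line")
            cols = [c.strip() for c in line[3:].split("\t")]
            if cols[:2] != ["uri", "title"]:
                raise HGSuiteError(
                    f"line {lineno}: column line must start with 'uri<TAB>title'")
            meta_cols = cols[2:]
            if len(set(meta_cols)) != len(meta_cols):
                raise HGSuiteError(f"line {lineno}: duplicate metadata column names")
            columns = meta_cols
        elif line.startswith("##"):
            if columns is not None:
                raise HGSuiteError(f"line {lineno}: pragma after column line")
            if ":" not in line:
                raise HGSuiteError(f"line {lineno}: malformed pragma {line!r}")
            key, _, value = line[2:].partition(":")
            key, value = key.strip(), value.strip()
            if key == "location":
                kwargs["location"] = value
            elif key == "file format":
                kwargs["file_format"] = value
            elif key == "track type":
                kwargs["track_type"] = value
            elif key == "genome":
                kwargs["genome"] = value
            elif key == "hierarchy":
                kwargs["hierarchy"] = tuple(
                    c.strip() for c in value.split(",") if c.strip())
            else:
                extra.append((key, value))
        else:
            if columns is None:
                raise HGSuiteError(f"line {lineno}: data row before column line")
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise HGSuiteError(f"line {lineno}: row needs non-empty uri and title")
            if len(fields) > 2 + len(columns):
                raise HGSuiteError(f"line {lineno}: more fields than declared columns")
            fields += [MISSING] * (2 + len(columns) - len(fields))
            meta = {c: (v if v else MISSING)
                    for c, v in zip(columns, fields[2:])}
            entries.append(TrackEntry(uri=fields[0], title=fields[1], metadata=meta))

    if columns is None:
        raise HGSuiteError("empty or headerless file: no '###' column line found")
    header = GSuiteHeader(extra_pragmas=tuple(extra), **kwargs)
    return HGSuite(header=header, columns=tuple(columns), entries=tuple(entries))


# -- writing ---------------------------------------------------------------

def write_hgsuite(suite: HGSuite, dest: str | Path | IO[str]) -> None:
    """Write a suite in canonical form (known pragmas first, fixed order)."""
    buf = io.StringIO()
    h = suite.header
    buf.write(f"##location: {h.location}\n")
    buf.write(f"##file format: {h.file_format}\n")
    buf.write(f"##track type: {h.track_type}\n")
    buf.write(f"##genome: {h.genome}\n")
    if h.hierarchy:
        buf.write(f"##hierarchy: {','.join(h.hierarchy)}\n")
    for key, value in h.extra_pragmas:
        buf.write(f"##{key}: {value}\n")
    buf.write("###" + "\t".join(("uri", "title") + suite.columns) + "\n")
    for e in suite.entries:
        fields = [e.uri, e.title] + [e.get(c) for c in suite.columns]
        for f in fields:
            if "\t" in f or "\n" in f:
                raise HGSuiteError(
                    f"entry {e.title!r}: value {f!r} contains a tab/newline; "
                    "the format cannot represent it")
        buf.write("\t".join(fields) + "\n")
    text = buf.getvalue()
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text)
    else:
        dest.write(text)


def dumps(suite: HGSuite) -> str:
    out = io.StringIO()
    write_hgsuite(suite, out)
    return out.getvalue()


# -- directory import ------------------------------------------------------

def build_from_directory(directory: str | Path,
                         metadata_source=None,
                         hierarchy: Iterable[str] = (),
                         genome: str = "unknown",
                         track_type: str = "unknown") -> HGSuite:
    """Create an hGSuite from a directory of BED files.

    ``metadata_source`` is a table mapping track titles to metadata values:
    a pandas DataFrame with a ``title`` column, a path to such a TSV, or
    ``None`` (no metadata). Every BED file stem must appear exactly once in
    the table and vice versa; titles are the file stems, URIs the relative
    file names.
    """
    import pandas as pd

    directory = Path(directory)
    beds = sorted(directory.glob("*.bed"))
    if not beds:
        raise HGSuiteError(f"no .bed files found in {directory}")
    stems = [p.stem for p in beds]
    if len(set(stems)) != len(stems):
        dupes = sorted({s for s in stems if stems.count(s) > 1})
        raise HGSuiteError(f"duplicate file stems: {dupes}")

    hierarchy = tuple(hierarchy)
    if metadata_source is None:
        if hierarchy:
            raise HGSuiteError("hierarchy requested but no metadata source given")
        columns: tuple[str, ...] = ()
        meta_by_title: dict[str, dict[str, str]] = {s: {} for s in stems}
    else:
        if isinstance(metadata_source, (str, Path)):
            table = pd.read_csv(metadata_source, sep="\t", dtype=str).fillna(MISSING)
        else:
            table = metadata_source.astype(str)
        if "title" not in table.columns:
            raise HGSuiteError("metadata source needs a 'title' column")
        columns = tuple(c for c in table.columns if c != "title")
        for col in hierarchy:
            if col not in columns:
                raise HGSuiteError(f"hierarchy column {col!r} absent from metadata source")
        titles = list(table["title"])
        unmatched = sorted(set(titles) - set(stems))
        if unmatched:
            raise HGSuiteError(
                f"metadata row(s) with no matching BED file: {unmatched}")
        missing = sorted(set(stems) - set(titles))
        if missing:
            raise HGSuiteError(f"BED file(s) with no metadata row: {missing}")
        meta_by_title = {
            row["title"]: {c: (row[c].strip() or MISSING) for c in columns}
            for _, row in table.iterrows()}

    header = GSuiteHeader(track_type=track_type, genome=genome, hierarchy=hierarchy)
    entries = tuple(TrackEntry(uri=p.name, title=p.stem,
                               metadata=meta_by_title[p.stem]) for p in beds)
    return HGSuite(header=header, columns=columns, entries=entries)
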