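"""Splice-event data model, canonical identifiers, and count-table IO.

A splice event is a local binary alternative in transcript structure with two
isoforms, each described by the junctions it uses.  Five event types are
supported: exon skipping (ES), intron retention (IR), alternative 3' splice
site (A3), alternative 5' splice site (A5), and mutually exclusive exons (MX).

Coordinates are 1-based inclusive genomic positions.  A junction is stored as
``(donor_base, acceptor_base)`` — the last exonic base of the upstream exon and
the first exonic base of the downstream exon in *genomic* order, regardless of
strand.  The implied intron is the closed interval
``[donor_base + 1, acceptor_base - 1]``.

The canonical event identifier (``event_jid``) is built from the contig,
strand, and both isoforms' junction coordinates::

    {contig}s{strand}:g.{iso1}>{iso2}[spl{TYPE}]

where each isoform renders its junctions as ``{donor}j{acceptor}`` joined by
``_``; the junction-free retained isoform of an IR event renders the retained
intron interval as ``{start}_{end}``.  As a regular expression::

    \\w+s[+-]:g\\.(\\d+(j|_)\\d+)(_\\d+j\\d+)*>(\\d+(j|_)\\d+)(_\\d+j\\d+)*\\[spl(ES|IR|A3|A5|MX)\\]
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

EVENT_TYPES = ("ES", "IR", "A3", "A5", "MX")

#: fixed leading columns of the count-table TSV dialect
TSV_FIXED_COLUMNS = (
    "event_id",
    "gene",
    "contig",
    "strand",
    "event_type",
    "iso1_junctions",
    "iso2_junctions",
)


class EventValidationError(ValueError):
    """A splice event violates a structural invariant."""


class CountTableParseError(ValueError):
    """A count-table TSV could not be parsed."""


def _normalize_strand(strand: str) -> str:
    # U+2212 (minus sign) shows up in typeset coordinates; treat as '-'
    strand = strand.replace("−", "-")
    if strand not in ("+", "-"):
        raise EventValidationError(f"strand must be '+' or '-', got {strand!r}")
    return strand


@dataclass(frozen=True, order=True)
class Junction:
    """One splice junction: (last exonic base upstream, first exonic base downstream)."""

    donor_base: int
    acceptor_base: int

    def __post_init__(self) -> None:
        if self.donor_base < 1 or self.acceptor_base < 1:
            raise EventValidationError("junction coordinates must be positive")
        if self.donor_base >= self.acceptor_base:
            raise EventValidationError(
                f"junction donor_base must precede acceptor_base: "
                f"({self.donor_base}, {self.acceptor_base})"
            )
        if self.acceptor_base - self.donor_base < 2:
            raise EventValidationError(
                f"implied intron [{self.donor_base + 1}, {self.acceptor_base - 1}] is empty"
            )

    @property
    def intron(self) -> tuple[int, int]:
        """Closed interval of intronic bases removed by this junction."""
        return (self.donor_base + 1, self.acceptor_base - 1)

    def render(self) -> str:
        return f"{self.donor_base}j{self.acceptor_base}"


@dataclass(frozen=True)
class SpliceEvent:
    """Genomic description of one splice event and its two isoforms."""

    event_id: str
    gene_id: str
    contig: str
    strand: str
    event_type: str
    iso1_junctions: tuple[Junction, ...]
    iso2_junctions: tuple[Junction, ...]
    ir_interval: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "strand", _normalize_strand(self.strand))
        object.__setattr__(self, "iso1_junctions", tuple(self.iso1_junctions))
        object.__setattr__(self, "iso2_junctions", tuple(self.iso2_junctions))
        self._validate()

    # -- structural invariants ---------------------------------------------
    def _validate(self) -> None:
        et = self.event_type
        if et not in EVENT_TYPES:
            raise EventValidationError(f"unknown event_type {et!r}")
        j1, j2 = self.iso1_junctions, self.iso2_junctions
        arity = {"ES": (2, 1), "IR": (1, 0), "A3": (1, 1), "A5": (1, 1), "MX": (2, 2)}[et]
        if (len(j1), len(j2)) != arity:
            raise EventValidationError(
                f"{et} event requires junction arity {arity}, got ({len(j1)}, {len(j2)})"
            )
        for iso in (j1, j2):
            for a, b in zip(iso, iso[1:]):
                if a.donor_base >= b.donor_base:
                    raise EventValidationError("junction lists must be sorted by donor_base")
                if a.acceptor_base > b.donor_base:
                    raise EventValidationError("junction introns within one isoform overlap")
        if j1 == j2:
            raise EventValidationError("iso1 and iso2 junction lists are identical")

        if et == "ES":
            if j2[0].donor_base != j1[0].donor_base or j2[0].acceptor_base != j1[1].acceptor_base:
                raise EventValidationError(
                    "ES skip junction must share iso1's outermost donor and acceptor"
                )
        elif et == "IR":
            if self.ir_interval is None:
                raise EventValidationError("IR event requires ir_interval")
            if tuple(self.ir_interval) != j1[0].intron:
                raise EventValidationError(
                    f"ir_interval {self.ir_interval} must equal iso1's intron {j1[0].intron}"
                )
        elif et in ("A3", "A5"):
            shared_donor = j1[0].donor_base == j2[0].donor_base
            shared_acceptor = j1[0].acceptor_base == j2[0].acceptor_base
            if shared_donor == shared_acceptor:
                raise EventValidationError(
                    f"{et} isoforms must share exactly one junction coordinate"
                )
            # A3 = alternative acceptor in transcript sense; A5 = alternative donor.
            # On '+' the sense acceptor is the genomic acceptor_base; on '-' it is
            # the genomic donor_base.
            varies_acceptor = shared_donor
            sense_varies_acceptor = varies_acceptor if self.strand == "+" else not varies_acceptor
            if et == "A3" and not sense_varies_acceptor:
                raise EventValidationError("A3 event varies the donor side in transcript sense")
            if et == "A5" and sense_varies_acceptor:
                raise EventValidationError("A5 event varies the acceptor side in transcript sense")
        elif et == "MX":
            if j1[0].donor_base != j2[0].donor_base or j1[1].acceptor_base != j2[1].acceptor_base:
                raise EventValidationError(
                    "MX isoforms must share the outermost donor and acceptor"
                )
        if et != "IR" and self.ir_interval is not None:
            raise EventValidationError("ir_interval is only valid for IR events")

    # -- rendering ----------------------------------------------------------
    def _render_iso(self, which: int) -> str:
        junctions = self.iso1_junctions if which == 1 else self.iso2_junctions
        if not junctions:  # IR retained isoform
            assert self.ir_interval is not None
            return f"{self.ir_interval[0]}_{self.ir_interval[1]}"
        return "_".join(j.render() for j in junctions)


def make_event_jid(event: SpliceEvent) -> str:
    """Canonical identifier from contig, strand and junction coordinates.

    Deterministic and injective over distinct (contig, strand, junction-set)
    triples; contains no whitespace.
    """
    return (
        f"{event.contig}s{event.strand}:g."
        f"{event._render_iso(1)}>{event._render_iso(2)}"
        f"[spl{event.event_type}]"
    )


def compute_psi(iso1_count: int, iso2_count: int) -> float:
    """PSI of isoform 1: iso1/(iso1+iso2); NaN (missing) at zero depth."""
    if iso1_count < 0 or iso2_count < 0:
        raise EventValidationError("counts must be non-negative")
    total = iso1_count + iso2_count
    if total == 0:
        return float("nan")
    return iso1_count / total


@dataclass
class EventCountTable:
    """Per-event, per-sample read counts supporting each of the two isoforms."""

    events: list[SpliceEvent]
    samples: list[str]
    iso1_counts: np.ndarray  # (n_events, n_samples) non-negative ints
    iso2_counts: np.ndarray
    psi_forced_missing: np.ndarray | None = None  # bool mask from depth filtering

    def __post_init__(self) -> None:
        self.iso1_counts = np.asarray(self.iso1_counts)
        self.iso2_counts = np.asarray(self.iso2_counts)
        shape = (len(self.events), len(self.samples))
        for name, arr in (("iso1_counts", self.iso1_counts), ("iso2_counts", self.iso2_counts)):
            if arr.shape != shape:
                raise EventValidationError(f"{name} has shape {arr.shape}, expected {shape}")
            if not np.issubdtype(arr.dtype, np.integer):
                raise EventValidationError(f"{name} must be integer-valued")
            if (arr < 0).any():
                raise EventValidationError(f"{name} contains negative counts")
        ids = [e.event_id for e in self.events]
        if len(set(ids)) != len(ids):
            raise EventValidationError("duplicate event_id in table")
        if len(set(self.samples)) != len(self.samples):
            raise EventValidationError("duplicate sample id in table")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.events), len(self.samples))

    @property
    def totals(self) -> np.ndarray:
        return self.iso1_counts + self.iso2_counts

    def psi(self, min_depth: int = 0) -> np.ndarray:
        """PSI of isoform 1 per event x sample; NaN where missing.

        Missing where the total depth is zero, below ``min_depth``, or where a
        depth mask set by :func:`mask_low_depth` applies.
        """
        totals = self.totals
        with np.errstate(divide="ignore", invalid="ignore"):
            psi = np.where(totals > 0, self.iso1_counts / np.maximum(totals, 1), np.nan)
        psi = np.where(totals >= max(min_depth, 1), psi, np.nan)
        if self.psi_forced_missing is not None:
            psi = np.where(self.psi_forced_missing, np.nan, psi)
        return psi

    def sample_index(self, sample_ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        idx = []
        for s in sample_ids:
            if s not in lookup:
                raise EventValidationError(f"unknown sample id {s!r}")
            idx.append(lookup[s])
        return np.asarray(idx, dtype=int)

    def event_jids(self) -> list[str]:
        return [make_event_jid(e) for e in self.events]


def mask_low_depth(table: EventCountTable, min_depth: int) -> EventCountTable:
    """Flag PSI as missing where total depth < ``min_depth``; counts unchanged."""
    if min_depth < 0:
        raise EventValidationError("min_depth must be >= 0")
    mask = table.totals < min_depth
    if table.psi_forced_missing is not None:
        mask = mask | table.psi_forced_missing
    return EventCountTable(
        events=list(table.events),
        samples=list(table.samples),
        iso1_counts=table.iso1_counts.copy(),
        iso2_counts=table.iso2_counts.copy(),
        psi_forced_missing=mask,
    )


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def _render_junction_field(event: SpliceEvent, which: int) -> str:
    return event._render_iso(which)


def _parse_junction_token(token: str, line_no: int) -> Junction:
    try:
        donor, acceptor = token.split("j")
        return Junction(int(donor), int(acceptor))
    except (ValueError, EventValidationError) as exc:
        raise CountTableParseError(f"line {line_no}: bad junction token {token!r}: {exc}") from exc


def _parse_iso_field(field_text: str, line_no: int) -> tuple[tuple[Junction, ...], tuple[int, int] | None]:
    """Parse an isoform column: junction list, or a retained interval (IR iso2)."""
    if field_text == "" or field_text == ".":
        raise CountTableParseError(f"line {line_no}: empty junction field")
    tokens = field_text.split("_")
    if all("j" in t for t in tokens):
        return tuple(_parse_junction_token(t, line_no) for t in tokens), None
    if len(tokens) == 2 and not any("j" in t for t in tokens):
        try:
            return (), (int(tokens[0]), int(tokens[1]))
        except ValueError as exc:
            raise CountTableParseError(f"line {line_no}: bad interval {field_text!r}") from exc
    raise CountTableParseError(f"line {line_no}: malformed junction field {field_text!r}")


def write_count_table(table: EventCountTable, path_or_handle) -> None:
    """Write the documented count-table TSV dialect (UTF-8, '#' comments)."""
    if hasattr(path_or_handle, "write"):
        _write_count_rows(table, path_or_handle)
    else:
        with open(path_or_handle, "w", encoding="utf-8") as fh:
            _write_count_rows(table, fh)


def _write_count_rows(table: EventCountTable, fh) -> None:
    cols = list(TSV_FIXED_COLUMNS)
    for s in table.samples:
        cols += [f"{s}.iso1", f"{s}.iso2"]
    fh.write("\t".join(cols) + "\n")
    for k, event in enumerate(table.events):
        row = [
            event.event_id,
            event.gene_id,
            event.contig,
            event.strand,
            event.event_type,
            _render_junction_field(event, 1),
            _render_junction_field(event, 2),
        ]
        for j in range(len(table.samples)):
            row += [str(int(table.iso1_counts[k, j])), str(int(table.iso2_counts[k, j]))]
        fh.write("\t".join(row) + "\n")


def read_count_table(path, schema_version: int = 1) -> EventCountTable:
    """Read the count-table TSV dialect; errors name the offending line."""
    if schema_version != 1:
        raise CountTableParseError(f"unsupported schema_version {schema_version}")
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    rows: list[tuple[int, list[str]]] = []
    for i, line in enumerate(lines, start=1):
        stripped = line.rstrip("\n")
        if not stripped or stripped.startswith("#"):
            continue
        rows.append((i, stripped.split("\t")))
    if not rows:
        raise CountTableParseError("no header line found")
    header_no, header = rows[0]
    if tuple(header[: len(TSV_FIXED_COLUMNS)]) != TSV_FIXED_COLUMNS:
        raise CountTableParseError(
            f"line {header_no}: fixed columns must be {list(TSV_FIXED_COLUMNS)}"
        )
    sample_cols = header[len(TSV_FIXED_COLUMNS):]
    if len(sample_cols) % 2 != 0:
        raise CountTableParseError(f"line {header_no}: unpaired sample columns")
    samples: list[str] = []
    for a, b in zip(sample_cols[::2], sample_cols[1::2]):
        if not a.endswith(".iso1"):
            raise CountTableParseError(f"line {header_no}: expected '<sample>.iso1', got {a!r}")
        name = a[: -len(".iso1")]
        if b != f"{name}.iso2":
            raise CountTableParseError(
                f"line {header_no}: sample {name!r} has column {a!r} but no matching {name}.iso2"
            )
        samples.append(name)

    events: list[SpliceEvent] = []
    seen_ids: set[str] = set()
    iso1_rows: list[list[int]] = []
    iso2_rows: list[list[int]] = []
    for line_no, fields in rows[1:]:
        if len(fields) != len(header):
            raise CountTableParseError(
                f"line {line_no}: expected {len(header)} fields, found {len(fields)}"
            )
        event_id, gene, contig, strand, event_type = fields[:5]
        if event_type not in EVENT_TYPES:
            raise CountTableParseError(f"line {line_no}: unknown event_type {event_type!r}")
        if event_id in seen_ids:
            raise CountTableParseError(f"line {line_no}: duplicate event_id {event_id!r}")
        seen_ids.add(event_id)
        j1, interval1 = _parse_iso_field(fields[5], line_no)
        j2, interval2 = _parse_iso_field(fields[6], line_no)
        if interval1 is not None:
            raise CountTableParseError(f"line {line_no}: iso1 must be a junction list")
        try:
            event = SpliceEvent(
                event_id=event_id,
                gene_id=gene,
                contig=contig,
                strand=strand,
                event_type=event_type,
                iso1_junctions=j1,
                iso2_junctions=j2,
                ir_interval=interval2,
            )
        except EventValidationError as exc:
            raise CountTableParseError(f"line {line_no}: {exc}") from exc
        counts = fields[len(TSV_FIXED_COLUMNS):]
        try:
            values = [int(c) for c in counts]
        except ValueError:
            bad = next(c for c in counts if not c.lstrip("-").isdigit())
            raise CountTableParseError(f"line {line_no}: non-integer count {bad!r}") from None
        if any(v < 0 for v in values):
            raise CountTableParseError(f"line {line_no}: negative count")
        events.append(event)
        iso1_rows.append(values[::2])
        iso2_rows.append(values[1::2])

    n = len(events)
    shape = (n, len(samples))
    return EventCountTable(
        events=events,
        samples=samples,
        iso1_counts=np.asarray(iso1_rows, dtype=np.int64).reshape(shape),
        iso2_counts=np.asarray(iso2_rows, dtype=np.int64).reshape(shape),
    )
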