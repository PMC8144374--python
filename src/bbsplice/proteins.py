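"""Protein-level effect prediction for splice events.

For each event, annotated protein-coding transcripts of the gene are
classified as matching isoform 1, isoform 2, or neither, by comparing the
event's junctions to the transcript's introns.  Each matching transcript is
then edited — the matched isoform's junctions are removed and replaced with
the other isoform's junctions — and both the original and edited structures
are translated.  The altered amino-acid run is localized by trimming the
longest common prefix and suffix (the two proteins are identical outside one
contiguous edit by construction, so trimming is exact), the effect is
classified from the reading-frame arithmetic, and one sequence pair per event
is selected by the prioritization rules:

    (1) pairs where both isoforms match known transcripts,
    (2) longest altered amino-acid sequence,
    (3) longest starting isoform sequence,

with a final lexicographic tie-break on transcript_id.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .annotation import Annotation, TranscriptModel, translate_transcript
from .events import SpliceEvent, make_event_jid

EVENT_CATEGORY = {"ES": "ExonSkip", "IR": "IntronRetention",
                  "A3": "Alt3", "A5": "Alt5", "MX": "MutExons"}

EFFECT_COLUMNS = ["event_jid", "event_cat", "effect_cat", "aa_change_type",
                  "group_increased_alt", "ref_seq_header", "alt_seq_header",
                  "refSeqPos", "altSeqPos", "refPept", "altPept"]


class SpliceEditError(ValueError):
    """The requested junction swap does not yield a valid exon structure."""


@dataclass(frozen=True)
class IsoformMatch:
    transcript_id: str
    matches: str  # iso1 | iso2 | neither


def _iso_introns(event: SpliceEvent, iso: int) -> tuple[tuple[int, int], ...]:
    """Intron boundary pairs used by one isoform (empty for IR retained)."""
    junctions = event.iso1_junctions if iso == 1 else event.iso2_junctions
    return tuple((j.donor_base, j.acceptor_base) for j in junctions)


def _matches_iso(transcript: TranscriptModel, event: SpliceEvent, iso: int) -> bool:
    if transcript.contig != event.contig or transcript.strand != event.strand:
        return False
    introns = set(transcript.introns)
    pairs = _iso_introns(event, iso)
    if event.event_type == "IR" and iso == 2:
        # retained isoform: the would-be intron must be fully exonic
        d, a = event.iso1_junctions[0].donor_base, event.iso1_junctions[0].acceptor_base
        return any(s <= d and a <= e for s, e in transcript.exons)
    return bool(pairs) and all(p in introns for p in pairs)


def match_transcripts(event: SpliceEvent, annotation: Annotation) -> list[IsoformMatch]:
    """Classify every protein-coding transcript of the event's gene."""
    out = []
    for t in annotation.coding_transcripts(event.gene_id):
        if _matches_iso(t, event, 1):
            m = "iso1"
        elif _matches_iso(t, event, 2):
            m = "iso2"
        else:
            m = "neither"
        out.append(IsoformMatch(t.transcript_id, m))
    return sorted(out, key=lambda m: m.transcript_id)


def apply_splice(transcript: TranscriptModel, event: SpliceEvent,
                 from_iso: int, to_iso: int) -> TranscriptModel:
    """Swap one isoform's junctions for the other's in a matching transcript.

    Exons are rebuilt as the complement of the edited intron set within the
    transcript span, so removed exons (ES) and newly exonic regions (IR, MX)
    fall out of the same bookkeeping.  Applying the inverse edit returns the
    original structure.
    """
    remove = set(_iso_introns(event, from_iso))
    add = set(_iso_introns(event, to_iso))
    introns = set(transcript.introns)
    if from_iso in (1, 2) and event.event_type == "IR" and from_iso == 2:
        pass  # retained isoform uses no junctions
    elif not remove <= introns:
        raise SpliceEditError(
            f"{transcript.transcript_id} does not contain the junctions of isoform {from_iso}"
        )
    new_introns = sorted((introns - remove) | add)
    span = transcript.span
    cur = span[0]
    exons: list[tuple[int, int]] = []
    for d, a in new_introns:
        if d < cur or a - d < 2:
            raise SpliceEditError("edited introns overlap or leave an empty exon")
        exons.append((cur, d))
        cur = a
    if cur > span[1]:
        raise SpliceEditError("edited intron extends past the transcript span")
    exons.append((cur, span[1]))
    if any(s > e for s, e in exons):
        raise SpliceEditError("edit produces an empty exon")
    return replace(transcript, exons=tuple(exons))


def localize_alteration(ref_protein: str, alt_protein: str):
    """Altered region of two proteins by common prefix/suffix trimming.

    Returns (refSeqPos, altSeqPos, refPept, altPept) with 1-based inclusive
    coordinates.  Identical proteins give empty peptides and positions None.
    A trailing stop mark is kept with the altered region when the divergence
    runs to the end of a sequence (a pure insertion point is rendered with
    start > end).
    """
    if ref_protein == alt_protein:
        return None, None, "", ""
    r = ref_protein[:-1] if ref_protein.endswith("*") else ref_protein
    a = alt_protein[:-1] if alt_protein.endswith("*") else alt_protein
    r_stop = ref_protein.endswith("*")
    a_stop = alt_protein.endswith("*")
    p = 0
    limit = min(len(r), len(a))
    while p < limit and r[p] == a[p]:
        p += 1
    s = 0
    limit_s = min(len(r), len(a)) - p
    while s < limit_s and r[len(r) - 1 - s] == a[len(a) - 1 - s]:
        s += 1
    ref_end, alt_end = len(r) - s, len(a) - s
    ref_pept, alt_pept = r[p:ref_end], a[p:alt_end]
    if s == 0:  # altered region reaches the end: keep the stop mark with it
        if r_stop:
            ref_pept += "*"
            ref_end += 1
        if a_stop:
            alt_pept += "*"
            alt_end += 1
    return (p + 1, ref_end), (p + 1, alt_end), ref_pept, alt_pept


def classify_effect(ref_protein: str, alt_protein: str, cds_nt_delta: int,
                    event_overlaps_cds: bool = True) -> str:
    """Effect category from the protein pair and coding-length arithmetic.

    ``cds_nt_delta`` is the signed change in spliced CDS length (alt - ref) in
    nucleotides.  Precedence: NonCoding (edit entirely outside the coding
    span) > Silent (identical proteins) > FrameDisruption (delta not a
    multiple of 3) > StopLoss (stop codon lost) > Truncation (in-frame edit
    introduces an early stop) > Insertion / Deletion by the sign of the
    length change.  An in-frame equal-length replacement is reported as
    Insertion (a novel run is inserted in place of the reference run).
    """
    if not event_overlaps_cds:
        return "NonCoding"
    if ref_protein == alt_protein:
        return "Silent"
    if cds_nt_delta % 3 != 0:
        return "FrameDisruption"
    if ref_protein.endswith("*") and not alt_protein.endswith("*"):
        return "StopLoss"
    if alt_protein.endswith("*"):
        expected_len = len(ref_protein) + cds_nt_delta // 3
        if len(alt_protein) < expected_len:
            return "Truncation"
    if cds_nt_delta > 0:
        return "Insertion"
    if cds_nt_delta < 0:
        return "Deletion"
    return "Insertion"


def _clip_exons(exons, interval):
    lo, hi = interval
    out = []
    for s, e in exons:
        s2, e2 = max(s, lo), min(e, hi)
        if s2 <= e2:
            out.append((s2, e2))
    return tuple(out)


def _spliced_length(exons) -> int:
    return sum(e - s + 1 for s, e in exons)


@dataclass
class PairCandidate:
    """One per-transcript sequence pair: a starting transcript and its edit."""

    transcript: TranscriptModel
    from_iso: int
    to_iso: int
    ref_protein: str
    alt_protein: str
    known_pair: bool
    cds_nt_delta: int
    event_overlaps_cds: bool
    ref_pos: tuple[int, int] | None
    alt_pos: tuple[int, int] | None
    ref_pept: str
    alt_pept: str
    effect_cat: str


def prioritize_pairs(candidates: list[PairCandidate]) -> PairCandidate | None:
    """Stable selection: known pair > longest altered run > longest start isoform."""
    if not candidates:
        return None
    return min(candidates, key=lambda c: (
        0 if c.known_pair else 1,
        -len(c.alt_pept),
        -len(c.ref_protein),
        c.transcript.transcript_id,
    ))


def _build_candidate(transcript: TranscriptModel, event: SpliceEvent,
                     from_iso: int, annotation: Annotation,
                     known_other: bool) -> PairCandidate | None:
    to_iso = 2 if from_iso == 1 else 1
    try:
        edited = apply_splice(transcript, event, from_iso, to_iso)
    except SpliceEditError:
        return None
    ref_protein = translate_transcript(transcript, annotation)
    alt_protein = translate_transcript(edited, annotation)
    if ref_protein is None or alt_protein is None:
        return None
    cds = transcript.cds_interval
    ref_cds = _clip_exons(transcript.exons, cds)
    alt_cds = _clip_exons(edited.exons, cds)
    delta = _spliced_length(alt_cds) - _spliced_length(ref_cds)
    overlaps = ref_cds != alt_cds
    ref_pos, alt_pos, ref_pept, alt_pept = localize_alteration(ref_protein, alt_protein)
    effect = classify_effect(ref_protein, alt_protein, delta, overlaps)
    return PairCandidate(transcript, from_iso, to_iso, ref_protein, alt_protein,
                         known_other, delta, overlaps, ref_pos, alt_pos,
                         ref_pept, alt_pept, effect)


def _render_pos(pos) -> str:
    return f"{pos[0]}-{pos[1]}" if pos is not None else ""


def increased_labels_from_diff(diff_df: pd.DataFrame) -> dict[str, dict[int, str]]:
    """Map event_jid -> {isoform: group label with increased PSI of that isoform}."""
    out: dict[str, dict[int, str]] = {}
    for _, row in diff_df.iterrows():
        if not row.get("group_increased_alt"):
            continue
        inc2 = row["group_increased_alt"]
        inc1 = row["group2"] if inc2 == row["group1"] else row["group1"]
        out[row["event_jid"]] = {1: inc1, 2: inc2}
    return out


def annotate_events(events, annotation: Annotation,
                    increased_alt_by_event: dict[str, dict[int, str]] | None = None):
    """Protein effect table plus reference/alternative FASTA records.

    Returns (effects DataFrame with the documented columns, known_records,
    novel_records) where records are (header, sequence) pairs.  Per-event
    failures downgrade to an Unknown row; they never abort the run.
    """
    rows = []
    known_records: dict[str, str] = {}
    novel_records: dict[str, str] = {}
    for event in events:
        jid = make_event_jid(event)
        row = dict.fromkeys(EFFECT_COLUMNS, "")
        row["event_jid"] = jid
        row["event_cat"] = EVENT_CATEGORY[event.event_type]
        matches = match_transcripts(event, annotation)
        matched = {1: [m.transcript_id for m in matches if m.matches == "iso1"],
                   2: [m.transcript_id for m in matches if m.matches == "iso2"]}
        candidates: list[PairCandidate] = []
        for iso in (1, 2):
            for tid in matched[iso]:
                other_known = bool(matched[2 if iso == 1 else 1])
                cand = _build_candidate(annotation.transcripts[tid], event, iso,
                                        annotation, other_known)
                if cand is not None:
                    candidates.append(cand)
        chosen = prioritize_pairs(candidates)
        if chosen is None:
            row["effect_cat"] = "Unknown"
            row["aa_change_type"] = "Unknown"
            rows.append(row)
            continue
        tid = chosen.transcript.transcript_id
        edit = f"g.{event._render_iso(chosen.from_iso)}>{event._render_iso(chosen.to_iso)}"
        row["effect_cat"] = chosen.effect_cat
        row["ref_seq_header"] = f"en|{tid}"
        row["alt_seq_header"] = f"en|{tid}:{edit}"
        row["refSeqPos"] = _render_pos(chosen.ref_pos)
        row["altSeqPos"] = _render_pos(chosen.alt_pos)
        row["refPept"] = chosen.ref_pept
        row["altPept"] = chosen.alt_pept
        core = chosen.alt_pept.rstrip("*")
        if core == "":
            row["aa_change_type"] = "Known"
        else:
            canon = annotation.gene_proteins(event.gene_id)
            row["aa_change_type"] = "Known" if any(core in p for p in canon) else "Novel"
        if increased_alt_by_event and jid in increased_alt_by_event:
            row["group_increased_alt"] = increased_alt_by_event[jid].get(chosen.to_iso, "")
        known_records.setdefault(row["ref_seq_header"], chosen.ref_protein.rstrip("*"))
        target = known_records if row["aa_change_type"] == "Known" else novel_records
        target.setdefault(row["alt_seq_header"], chosen.alt_protein.rstrip("*"))
        rows.append(row)
    effects = pd.DataFrame(rows, columns=EFFECT_COLUMNS)
    return effects, list(known_records.items()), list(novel_records.items())


def write_fasta(records, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def filter_novel_increased(effects: pd.DataFrame, group_label: str) -> pd.DataFrame:
    """Events predicted to generate novel sequence with the alternative isoform
    increased in the named group."""
    keep = (effects["aa_change_type"] == "Novel") & (effects["group_increased_alt"] == group_label)
    return effects[keep].reset_index(drop=True)
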