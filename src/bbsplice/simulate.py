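"""Synthetic data generation.

Two generators live here:

* :func:`simulate_counts` draws event count tables from the beta-binomial
  generative model the statistical tests assume: per sample, a PSI value
  p ~ Beta(omega*psi, omega*(1-psi)) captures biological variation, depth
  T ~ Poisson(lambda) captures library sampling, and the isoform-1 count is
  I ~ Binomial(T, p).  Group structure, concentration, depth and an optional
  outlier contingent are all controlled by a :class:`SimulationSpec`.

* :func:`make_toy_annotation` writes a small (< 100 kb) synthetic genome and
  GTF realizing a catalog of (event type, protein effect) combinations on
  both strands, together with the protein effects expected from each event.
  The expected proteins are computed here by direct string assembly of the
  constructed transcripts, independently of the effect-prediction pipeline,
  so the fixture doubles as an end-to-end oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from .events import EventCountTable, Junction, SpliceEvent, write_count_table

# ---------------------------------------------------------------------------
# beta-binomial count simulation
# ---------------------------------------------------------------------------


@dataclass
class GroupSpec:
    label: str
    n_samples: int
    psi: float


@dataclass
class SimulationSpec:
    n_events: int
    groups: list[GroupSpec]
    omega: float
    depth_mean: float = 100.0
    depth_model: str = "poisson"
    outlier_spec: tuple[int, float] | None = None  # (n_outlier_samples, outlier_psi)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if self.omega <= 2:
            raise ValueError("omega must exceed 2")
        if self.depth_mean < 0:
            raise ValueError("depth_mean must be >= 0")
        if self.depth_model not in ("poisson", "fixed"):
            raise ValueError(f"unknown depth_model {self.depth_model!r}")
        for g in self.groups:
            if not (0.0 < g.psi < 1.0):
                raise ValueError(f"group {g.label}: psi must be in (0, 1)")
            if g.n_samples < 1:
                raise ValueError(f"group {g.label}: n_samples must be >= 1")
        if self.outlier_spec is not None:
            n_out, psi_out = self.outlier_spec
            if not (0.0 < psi_out < 1.0):
                raise ValueError("outlier psi must be in (0, 1)")
            if n_out > sum(g.n_samples for g in self.groups):
                raise ValueError("more outlier samples than samples")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationSpec":
        groups = [GroupSpec(**g) for g in d["groups"]]
        out = d.get("outlier_spec")
        return cls(
            n_events=d["n_events"], groups=groups, omega=d["omega"],
            depth_mean=d.get("depth_mean", 100.0),
            depth_model=d.get("depth_model", "poisson"),
            outlier_spec=tuple(out) if out else None,
            seed=d.get("seed", 0),
        )


def _synthetic_event(k: int) -> SpliceEvent:
    base = 10_000 * (k + 1)
    return SpliceEvent(
        event_id=f"ev{k:05d}", gene_id=f"GENE{k:05d}", contig="chrS", strand="+",
        event_type="ES",
        iso1_junctions=(Junction(base + 100, base + 200), Junction(base + 300, base + 400)),
        iso2_junctions=(Junction(base + 100, base + 400),),
    )


def simulate_counts(spec: SimulationSpec) -> EventCountTable:
    """Draw an event count table from the beta-binomial generative model.

    Sample ids are ``{label}{i}``; if an outlier contingent is requested, the
    last ``n_outlier_samples`` samples of the table draw their PSI from the
    outlier value instead of their group's.  Identical seeds give identical
    tables.
    """
    rng = np.random.default_rng(spec.seed)
    samples: list[str] = []
    psis: list[float] = []
    for g in spec.groups:
        for i in range(g.n_samples):
            samples.append(f"{g.label}{i + 1}")
            psis.append(g.psi)
    if spec.outlier_spec is not None:
        n_out, psi_out = spec.outlier_spec
        for j in range(len(samples) - n_out, len(samples)):
            psis[j] = psi_out
    psis_arr = np.asarray(psis)
    n_s = len(samples)
    alpha = spec.omega * psis_arr
    beta = spec.omega * (1.0 - psis_arr)
    p = rng.beta(alpha[None, :].repeat(spec.n_events, axis=0),
                 beta[None, :].repeat(spec.n_events, axis=0))
    if spec.depth_model == "poisson":
        T = rng.poisson(spec.depth_mean, size=(spec.n_events, n_s))
    else:
        T = np.full((spec.n_events, n_s), int(round(spec.depth_mean)))
    I = rng.binomial(T, p)
    return EventCountTable(
        events=[_synthetic_event(k) for k in range(spec.n_events)],
        samples=samples,
        iso1_counts=I.astype(np.int64),
        iso2_counts=(T - I).astype(np.int64),
    )


# ---------------------------------------------------------------------------
# toy genome + annotation fixtures
# ---------------------------------------------------------------------------

_UTR5 = "CCTTCC" * 2          # no ATG, no stop
_UTR3 = "TAAG" * 9            # stop codons in all three frames
_E, _V, _H, _N = "GAA", "GTT", "CAC", "AAC"   # segment-colored codons

#: every (event_type, effect_cat) combination the fixture generator realizes
SUPPORTED_CATALOG: tuple[tuple[str, str], ...] = (
    ("ES", "Deletion"), ("ES", "FrameDisruption"), ("ES", "Truncation"),
    ("ES", "StopLoss"), ("ES", "NonCoding"),
    ("IR", "Insertion"), ("IR", "FrameDisruption"),
    ("A3", "Insertion"), ("A3", "Deletion"), ("A3", "FrameDisruption"),
    ("A5", "Insertion"), ("A5", "FrameDisruption"),
    ("MX", "Insertion"), ("MX", "Deletion"), ("MX", "FrameDisruption"),
)


@dataclass
class _LocalGene:
    """A gene laid out in local sense coordinates (1-based, 5'->3')."""

    seq: str
    ref_exons: list[tuple[int, int]]
    alt_exons: list[tuple[int, int]]
    cds_span: tuple[int, int]          # incl. stop codon
    event_type: str
    iso1_j: list[tuple[int, int]]
    iso2_j: list[tuple[int, int]]
    ir_interval: tuple[int, int] | None


def _generic_intron(n_repeats: int) -> str:
    return "GT" + "CCCT" * n_repeats + "AG"


def _layout(cds: str, cuts: list[tuple[int, str]], utr5: str = _UTR5,
            tail: str = _UTR3) -> tuple[str, list[tuple[int, int]], "callable", int]:
    """Insert introns into the mature sequence utr5+cds+tail after given positions.

    Returns (gene sequence, reference exons in local coords, the
    mRNA->gene coordinate map, mRNA length).
    """
    mrna = utr5 + cds + tail
    cuts = sorted(cuts)

    def g(p: int) -> int:
        return p + sum(len(iseq) for c, iseq in cuts if c < p)

    pieces, exons = [], []
    prev = 0
    for c, iseq in cuts:
        pieces.append(mrna[prev:c])
        exons.append((g(prev + 1), g(c)))
        pieces.append(iseq)
        prev = c
    pieces.append(mrna[prev:])
    exons.append((g(prev + 1), g(len(mrna))))
    return "".join(pieces), exons, g, len(mrna)


def _build_local(event_type: str, effect: str) -> _LocalGene:
    utr5, tail = _UTR5, _UTR3
    if event_type == "ES":
        if effect == "Deletion":
            # 102-nt cassette: in-frame skip removes 34 residues
            cds = "ATG" + _E * 8 + _H * 34 + _V * 8 + "TAA"
            c1, c2 = 39, 141
        elif effect == "FrameDisruption":
            # 103-nt cassette: skip shifts the reading frame
            cds = "ATG" + _E * 8 + _H * 34 + "C" + "AA" + _V * 6 + "TAA"
            c1, c2 = 39, 142
        elif effect == "Truncation":
            cds = "ATG" + _E * 8 + "TCA" + _H * 8 + "GAA" + _V * 6 + "TAA"
            c1, c2 = 40, 67
        elif effect == "StopLoss":
            cds = "ATG" + _E * 8 + _H * 6 + "TAA"
            tail = _V * 10  # no downstream stop: skipping the cassette loses it
            c1, c2 = 39, 60
        elif effect == "NonCoding":
            utr5 = "CCTTCC" * 6
            cds = "ATG" + _E * 8 + _V * 6 + "TAA"
            c1, c2 = 12, 24
        else:
            raise ValueError(f"unsupported (ES, {effect})")
        seq, exons, g, M = _layout(cds, [(c1, _generic_intron(18)), (c2, _generic_intron(18))],
                                   utr5, tail)
        iso1 = [(g(c1), g(c1 + 1)), (g(c2), g(c2 + 1))]
        iso2 = [(g(c1), g(c2 + 1))]
        alt_exons = [exons[0], exons[2]]
        ir = None
    elif event_type == "IR":
        cds = "ATG" + _E * 8 + _V * 8 + "TAA"
        c = 39
        if effect == "Insertion":
            intron = "GTA" + "GCT" * 8 + "GAG"          # 30 nt, stop-free in frame
        elif effect == "FrameDisruption":
            intron = "GTA" + "GCT" * 8 + "AGAG"         # 31 nt
        else:
            raise ValueError(f"unsupported (IR, {effect})")
        seq, exons, g, M = _layout(cds, [(c, intron)], utr5, tail)
        iso1 = [(g(c), g(c + 1))]
        iso2 = []
        ir = (g(c) + 1, g(c + 1) - 1)
        alt_exons = [(1, len(seq))]
    elif event_type in ("A3", "A5"):
        cds = "ATG" + _E * 8 + _V * 10 + "TAA"
        c = 39
        if event_type == "A3":
            shift = {"Insertion": -6, "Deletion": 9, "FrameDisruption": 14}.get(effect)
            if shift is None:
                raise ValueError(f"unsupported (A3, {effect})")
            intron = "GT" + "CCCT" * 16 + "GCTGAG" if shift < 0 else _generic_intron(17)
            seq, exons, g, M = _layout(cds, [(c, intron)], utr5, tail)
            iso1 = [(g(c), g(c + 1))]
            iso2 = [(g(c), g(c + 1) + shift)]
            alt_exons = [exons[0], (g(c + 1) + shift, len(seq))]
        else:
            k = {"Insertion": 6, "FrameDisruption": 7}.get(effect)
            if k is None:
                raise ValueError(f"unsupported (A5, {effect})")
            intron = ("GTAGAA" if k == 6 else "GTAGAAC") + "CCCT" * 16 + "AG"
            seq, exons, g, M = _layout(cds, [(c, intron)], utr5, tail)
            iso1 = [(g(c), g(c + 1))]
            iso2 = [(g(c) + k, g(c + 1))]
            alt_exons = [(1, g(c) + k), (g(c + 1), len(seq))]
        ir = None
    elif event_type == "MX":
        cds = "ATG" + _E * 8 + _H * 10 + _V * 6 + "TAA"
        c1, c2 = 39, 69
        m2 = {"Insertion": _N * 20, "Deletion": _N * 5,
              "FrameDisruption": _N * 10 + "A"}.get(effect)
        if m2 is None:
            raise ValueError(f"unsupported (MX, {effect})")
        i2, i3 = _generic_intron(5), _generic_intron(5)
        seq, exons, g, M = _layout(cds, [(c1, _generic_intron(10)), (c2, i2 + m2 + i3)],
                                   utr5, tail)
        m2s = g(c2) + len(i2) + 1
        m2e = m2s + len(m2) - 1
        iso1 = [(g(c1), g(c1 + 1)), (g(c2), g(c2 + 1))]
        iso2 = [(g(c1), m2s), (m2e, g(c2 + 1))]
        alt_exons = [exons[0], (m2s, m2e), exons[2]]
        ir = None
    else:
        raise ValueError(f"unsupported event_type {event_type!r}")

    cds_span = (g(len(utr5) + 1), g(len(utr5) + len(cds)))
    return _LocalGene(seq=seq, ref_exons=exons, alt_exons=alt_exons, cds_span=cds_span,
                      event_type=event_type, iso1_j=iso1, iso2_j=iso2, ir_interval=ir)


def _translate_local(gene_seq: str, exons, cds_start: int) -> str | None:
    """Translate a local-coordinate exon chain from a genomic start position."""
    spliced = "".join(gene_seq[s - 1:e] for s, e in exons)
    off = None
    pos = 0
    for s, e in exons:
        if s <= cds_start <= e:
            off = pos + cds_start - s
            break
        pos += e - s + 1
    if off is None:
        return None
    coding = spliced[off:]
    coding = coding[: len(coding) - len(coding) % 3]
    protein = str(Seq(coding).translate())
    stop = protein.find("*")
    return protein[: stop + 1] if stop >= 0 else protein


def _trim_pair(ref: str, alt: str):
    """Common prefix/suffix trimming (the generator's own copy of the rule)."""
    if ref == alt:
        return "", "", "", ""
    r = ref[:-1] if ref.endswith("*") else ref
    a = alt[:-1] if alt.endswith("*") else alt
    p = 0
    while p < min(len(r), len(a)) and r[p] == a[p]:
        p += 1
    s = 0
    while s < min(len(r), len(a)) - p and r[-1 - s] == a[-1 - s]:
        s += 1
    rp, ap = r[p:len(r) - s], a[p:len(a) - s]
    re_, ae = len(r) - s, len(a) - s
    if s == 0:
        if ref.endswith("*"):
            rp += "*"
            re_ += 1
        if alt.endswith("*"):
            ap += "*"
            ae += 1
    return f"{p + 1}-{re_}", f"{p + 1}-{ae}", rp, ap


def _flip_interval(iv, L, offset):
    s, e = iv
    return (offset + L - e + 1, offset + L - s + 1)


def make_toy_annotation(catalog, outdir, contig: str = "chrT",
                        spacer: int = 300):
    """Write a synthetic genome FASTA, GTF, count-table skeleton and expected
    protein-effect table realizing the requested catalog.

    ``catalog`` is an iterable of (event_type, effect_cat) pairs drawn from
    :data:`SUPPORTED_CATALOG`.  Genes alternate between the two strands.
    Returns a dict with the written paths, the constructed events and the
    expected effects table (as a list of per-event dicts).
    """
    import pandas as pd

    catalog = list(catalog)
    for entry in catalog:
        if tuple(entry) not in SUPPORTED_CATALOG:
            raise ValueError(f"unsupported catalog entry {entry!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome_parts: list[str] = []
    gtf_lines: list[str] = []
    events: list[SpliceEvent] = []
    expected_rows: list[dict] = []
    offset = 0

    for idx, (etype, effect) in enumerate(catalog):
        strand = "+" if idx % 2 == 0 else "-"
        local = _build_local(etype, effect)
        L = len(local.seq)
        gene_id, tid = f"G{idx:03d}", f"T{idx:03d}.1"

        genome_parts.append("T" * spacer)
        offset += spacer
        if strand == "+":
            genome_parts.append(local.seq)
            def to_g(iv, off=offset, LL=L):
                return (off + iv[0], off + iv[1])
            def j_to_g(j, off=offset, LL=L):
                return (off + j[0], off + j[1])
        else:
            genome_parts.append(str(Seq(local.seq).reverse_complement()))
            def to_g(iv, off=offset, LL=L):
                return _flip_interval(iv, LL, off)
            def j_to_g(j, off=offset, LL=L):
                return _flip_interval(j, LL, off)

        ref_exons_g = sorted(to_g(e) for e in local.ref_exons)
        cds_g = to_g(local.cds_span)
        # stop codon is the last 3 bases of the coding span in sense direction
        if strand == "+":
            stop_g = (cds_g[1] - 2, cds_g[1])
        else:
            stop_g = (cds_g[0], cds_g[0] + 2)
        cds_wo_stop = (cds_g[0], stop_g[0] - 1) if strand == "+" else (stop_g[1] + 1, cds_g[1])

        attrs = f'gene_id "{gene_id}"; transcript_id "{tid}"; transcript_biotype "protein_coding";'
        gtf_lines.append(f'{contig}\ttoy\tgene\t{min(s for s, _ in ref_exons_g)}\t'
                         f'{max(e for _, e in ref_exons_g)}\t.\t{strand}\t.\tgene_id "{gene_id}";')
        gtf_lines.append(f"{contig}\ttoy\ttranscript\t{ref_exons_g[0][0]}\t{ref_exons_g[-1][1]}"
                         f"\t.\t{strand}\t.\t{attrs}")
        for s, e in ref_exons_g:
            gtf_lines.append(f"{contig}\ttoy\texon\t{s}\t{e}\t.\t{strand}\t.\t{attrs}")
        for s, e in ref_exons_g:
            cs, ce = max(s, cds_wo_stop[0]), min(e, cds_wo_stop[1])
            if cs <= ce:
                gtf_lines.append(f"{contig}\ttoy\tCDS\t{cs}\t{ce}\t.\t{strand}\t0\t{attrs}")
        gtf_lines.append(f"{contig}\ttoy\tstop_codon\t{stop_g[0]}\t{stop_g[1]}\t.\t{strand}\t.\t{attrs}")

        iso1_g = sorted(j_to_g(j) for j in local.iso1_j)
        iso2_g = sorted(j_to_g(j) for j in local.iso2_j)
        ir_g = None
        if local.ir_interval is not None:
            ir_g = to_g(local.ir_interval)
        event = SpliceEvent(
            event_id=f"toy{idx:03d}", gene_id=gene_id, contig=contig, strand=strand,
            event_type=etype,
            iso1_junctions=tuple(Junction(*j) for j in iso1_g),
            iso2_junctions=tuple(Junction(*j) for j in iso2_g),
            ir_interval=ir_g,
        )
        events.append(event)

        # expected proteins by direct local-coordinate assembly
        cds_start_local = local.cds_span[0]
        ref_protein = _translate_local(local.seq, local.ref_exons, cds_start_local)
        alt_protein = _translate_local(local.seq, local.alt_exons, cds_start_local)
        ref_pos, alt_pos, ref_pept, alt_pept = _trim_pair(ref_protein, alt_protein)
        core = alt_pept.rstrip("*")
        aa_change = "Known" if core == "" or core in ref_protein.rstrip("*") else "Novel"
        from .events import make_event_jid
        from .proteins import EVENT_CATEGORY
        expected_rows.append({
            "event_jid": make_event_jid(event),
            "event_cat": EVENT_CATEGORY[etype],
            "effect_cat": effect,
            "aa_change_type": aa_change,
            "ref_seq_header": f"en|{tid}",
            "alt_seq_header": f"en|{tid}:g.{event._render_iso(1)}>{event._render_iso(2)}",
            "refSeqPos": ref_pos,
            "altSeqPos": alt_pos,
            "refPept": ref_pept,
            "altPept": alt_pept,
        })
        offset += L

    genome_parts.append("T" * spacer)
    genome = "".join(genome_parts)

    genome_path = outdir / "genome.fa"
    with open(genome_path, "w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, len(genome), 70):
            fh.write(genome[i:i + 70] + "\n")
    gtf_path = outdir / "annotation.gtf"
    with open(gtf_path, "w") as fh:
        fh.write("\n".join(gtf_lines) + "\n")

    samples = ["s1", "s2", "s3", "s4"]
    n = len(events)
    iso1 = np.tile(np.array([12, 10, 3, 2], dtype=np.int64), (n, 1))
    iso2 = np.tile(np.array([2, 3, 11, 9], dtype=np.int64), (n, 1))
    table = EventCountTable(events=events, samples=samples,
                            iso1_counts=iso1, iso2_counts=iso2)
    counts_path = outdir / "counts.tsv"
    write_count_table(table, counts_path)

    expected = pd.DataFrame(expected_rows)
    expected_path = outdir / "expected_effects.tsv"
    expected.to_csv(expected_path, sep="\t", index=False)

    return {
        "genome": genome_path,
        "gtf": gtf_path,
        "counts": counts_path,
        "expected": expected_path,
        "events": events,
        "expected_table": expected,
        "table": table,
    }
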