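"""Pseudogenization scan against a conserved reference ortholog.

Globally aligns a (reconstructed) CDS to its reference ortholog, then calls
sequence-evolution events: frameshift and in-frame INDELs, premature stop
codons, and retained introns (insertions that coincide with an annotated
exon-exon junction and match that intron's length).  Events roll up into a
per-gene status label.

Coordinate conventions: reference positions are 0-based CDS coordinates of
the base immediately preceding an event; alignment columns are reported
1-based, the idiom used in comparative-genomics reports.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional, Sequence

from .seqio import GeneModel, STOP_CODONS, SequenceRecord, revcomp, translate
from .reconstruction import _dna_aligner


@dataclass
class PairwiseAlignment:
    """A gapped global alignment of query vs reference CDS."""

    query_id: str
    reference_id: str
    aligned_query: str
    aligned_reference: str
    score: float
    identity: float  # percent, matches / columns (gap columns included)

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_reference):
            raise ValueError("aligned rows must have equal length")

    @property
    def query(self) -> str:
        return self.aligned_query.replace("-", "")

    @property
    def reference(self) -> str:
        return self.aligned_reference.replace("-", "")


@dataclass
class VariantEvent:
    """One detected difference vs the reference ortholog.

    kind: insertion | deletion | retained_intron | premature_stop
    position: 0-based reference CDS coordinate of the base preceding the
        event (-1 for an event before the first reference base)
    alignment_column: 1-based column of the event's first base
    frame_offset: length mod 3 (indels only)
    """

    kind: str
    position: int
    length: int
    alignment_column: int
    frame_offset: Optional[int] = None
    query_position: Optional[int] = None
    inserted_seq: str = ""
    deleted_seq: str = ""
    exon_index: Optional[int] = None
    intron_index: Optional[int] = None
    canonical_splice: Optional[bool] = None
    truncated_fraction: Optional[float] = None
    read_supported: Optional[bool] = None


@dataclass
class GeneStatus:
    """Per-gene roll-up of detected events."""

    label: str  # conserved | in_frame_variant | frameshift_pseudogene | retained_intron | truncated
    events: tuple[VariantEvent, ...]
    truncated_fraction: float = 0.0


class PrematureStopResult(NamedTuple):
    event: Optional[VariantEvent]
    no_stop: bool


# ---------------------------------------------------------------------------
# Alignment

def global_align(query: SequenceRecord, reference: SequenceRecord) -> PairwiseAlignment:
    """Global affine-gap DNA alignment.

    Scores: match +2, mismatch -3, gap cost 16 + 0.5(k-1) for a k-base run
    (high open, cheap extension, so intron-scale insertions align as one
    gap rather than scattering across the reference).  The first optimal
    traceback of the aligner is taken, which is deterministic for a fixed
    input pair.
    """
    q, r = query.residues, reference.residues
    if not q or not r:
        raise ValueError("empty sequence")
    if max(len(q), len(r)) > 5 * min(len(q), len(r)):
        raise ValueError("sequence lengths differ by more than 5x")
    aligner = _dna_aligner("global")
    aln = aligner.align(q, r)[0]
    aq, ar = str(aln[0]), str(aln[1])
    matches = sum(1 for a, b in zip(aq, ar) if a == b and a != "-")
    return PairwiseAlignment(
        query_id=query.id,
        reference_id=reference.id,
        aligned_query=aq,
        aligned_reference=ar,
        score=float(aln.score),
        identity=100.0 * matches / len(aq),
    )


# ---------------------------------------------------------------------------
# Event detection

def detect_indels(alignment: PairwiseAlignment) -> list[VariantEvent]:
    """Each maximal gap run becomes one event.

    A gap run in the reference row is an insertion (extra query bases); a
    gap run in the query row is a deletion.  frame_offset = length mod 3.
    """
    aq, ar = alignment.aligned_query, alignment.aligned_reference
    events: list[VariantEvent] = []
    rpos = qpos = 0
    col = 0
    n = len(aq)
    while col < n:
        if ar[col] == "-" and aq[col] != "-":
            start = col
            while col < n and ar[col] == "-" and aq[col] != "-":
                col += 1
            run = aq[start:col]
            events.append(
                VariantEvent(
                    kind="insertion",
                    position=rpos - 1,
                    length=len(run),
                    alignment_column=start + 1,
                    frame_offset=len(run) % 3,
                    query_position=qpos,
                    inserted_seq=run,
                )
            )
            qpos += len(run)
        elif aq[col] == "-" and ar[col] != "-":
            start = col
            r0 = rpos
            while col < n and aq[col] == "-" and ar[col] != "-":
                rpos += 1
                col += 1
            run = ar[start:col]
            events.append(
                VariantEvent(
                    kind="deletion",
                    position=r0 - 1,
                    length=len(run),
                    alignment_column=start + 1,
                    frame_offset=len(run) % 3,
                    query_position=qpos,
                    deleted_seq=run,
                )
            )
        else:
            if ar[col] != "-":
                rpos += 1
            if aq[col] != "-":
                qpos += 1
            col += 1
    return events


def merge_adjacent_indels(
    events: Sequence[VariantEvent], merge_window: int = 20
) -> list[VariantEvent]:
    """Merge same-kind gap runs separated by few aligned columns.

    Affine-gap alignment of diverged sequences occasionally splits one true
    indel into two nearby runs when the inserted bases spuriously match the
    reference ("gap attraction").  Runs of the same kind whose reference
    positions lie within merge_window bases are fused into one net event:
    length is the summed run length, frame_offset follows, the position is
    the first run's.  Other event kinds pass through untouched.
    """
    indels = sorted(
        (e for e in events if e.kind in ("insertion", "deletion")),
        key=lambda e: e.position,
    )
    others = [e for e in events if e.kind not in ("insertion", "deletion")]
    merged: list[VariantEvent] = []
    for ev in indels:
        if (
            merged
            and merged[-1].kind == ev.kind
            and ev.position - merged[-1].position <= merge_window
        ):
            prev = merged[-1]
            length = prev.length + ev.length
            merged[-1] = replace(
                prev,
                length=length,
                frame_offset=length % 3,
                inserted_seq=prev.inserted_seq + ev.inserted_seq,
                deleted_seq=prev.deleted_seq + ev.deleted_seq,
            )
        else:
            merged.append(ev)
    return sorted(merged + others, key=lambda e: (e.position, e.kind))


def detect_premature_stop(alignment: PairwiseAlignment) -> PrematureStopResult:
    """First in-frame query stop strictly before the reference terminal stop.

    The query frame is anchored at the query base aligned to the reference
    ATG.  A stop at or past the reference's terminal-stop column is not
    premature.  Returns (event or None, no_stop flag).
    """
    aq, ar = alignment.aligned_query, alignment.aligned_reference
    ref = alignment.reference
    query = alignment.query

    # column of each reference/query position
    ref_col = []
    q_col = []
    for col, (a, b) in enumerate(zip(aq, ar)):
        if b != "-":
            ref_col.append(col)
        if a != "-":
            q_col.append(col)
    ref_stop_col = ref_col[len(ref) - 3]  # first base of terminal stop codon

    # anchor: query position aligned at reference position 0
    q_anchor = None
    for col, (a, b) in enumerate(zip(aq, ar)):
        if b != "-":
            if a != "-":
                q_anchor = sum(1 for c in aq[:col] if c != "-")
            break
    if q_anchor is None:
        q_anchor = 0

    ref_pep_len = len(ref) // 3 - 1
    for qp in range(q_anchor, len(query) - 2, 3):
        codon = query[qp : qp + 3]
        if codon in STOP_CODONS:
            stop_col = q_col[qp]
            if stop_col >= ref_stop_col:
                return PrematureStopResult(None, False)
            codons_before = (qp - q_anchor) // 3
            trunc = 1.0 - codons_before / ref_pep_len if ref_pep_len else 0.0
            rpos = sum(1 for c in ar[:stop_col] if c != "-")
            return PrematureStopResult(
                VariantEvent(
                    kind="premature_stop",
                    position=rpos - 1,
                    length=3,
                    alignment_column=stop_col + 1,
                    query_position=qp,
                    truncated_fraction=trunc,
                ),
                False,
            )
    return PrematureStopResult(None, True)


def detect_retained_intron(
    events: Sequence[VariantEvent],
    gene_model: GeneModel,
    junction_tolerance_bp: int = 20,
    length_tolerance: float = 0.05,
) -> list[VariantEvent]:
    """Reclassify insertions at exon junctions as retained introns.

    An insertion becomes retained_intron when its reference position lies
    within +-junction_tolerance_bp of an annotated exon-exon junction AND
    its length is within +-length_tolerance of that intron's annotated
    length.  The junction tolerance absorbs affine-gap placement slip
    (a gap slides freely within locally similar sequence, typically a few
    bases).  GT..AG termini of the inserted run are recorded as
    corroborating evidence but are not required.
    """
    junctions = gene_model.cds_junctions
    intron_lens = gene_model.intron_lengths
    out = []
    for ev in events:
        if ev.kind != "insertion":
            out.append(ev)
            continue
        reclassified = ev
        for idx, (junc, ilen) in enumerate(zip(junctions, intron_lens), start=1):
            if (
                abs((ev.position + 1) - junc) <= junction_tolerance_bp
                and abs(ev.length - ilen) <= length_tolerance * ilen
            ):
                canonical = (
                    ev.inserted_seq[:2] == "GT" and ev.inserted_seq[-2:] == "AG"
                )
                reclassified = replace(
                    ev,
                    kind="retained_intron",
                    intron_index=idx,
                    canonical_splice=canonical,
                    frame_offset=None,
                )
                break
        out.append(reclassified)
    return out


def annotate_exon_indices(
    events: Sequence[VariantEvent], gene_model: GeneModel
) -> list[VariantEvent]:
    """Attach the 1-based reference exon index containing each indel."""
    bounds = [0]
    for ln in gene_model.exon_lengths:
        bounds.append(bounds[-1] + ln)
    out = []
    for ev in events:
        if ev.kind in ("insertion", "deletion") and ev.position >= 0:
            for i in range(len(bounds) - 1):
                if bounds[i] <= ev.position < bounds[i + 1]:
                    ev = replace(ev, exon_index=i + 1)
                    break
        out.append(ev)
    return out


def mark_read_support(
    events: Sequence[VariantEvent],
    query: str,
    reads: Sequence[str],
    min_read_support: int = 2,
    context: int = 15,
) -> list[VariantEvent]:
    """Mark an event supported when >= min_read_support reads span it with
    the variant allele.  Without reads the flag stays unset (None)."""
    pool = list(reads) + [revcomp(r) for r in reads]
    out = []
    for ev in events:
        if ev.query_position is None:
            out.append(ev)
            continue
        span = ev.length if ev.kind in ("insertion", "retained_intron") else 0
        lo = max(0, ev.query_position - context)
        hi = min(len(query), ev.query_position + span + context)
        window = query[lo:hi]
        n = sum(1 for r in pool if window in r)
        out.append(replace(ev, read_supported=n >= min_read_support))
    return out


# ---------------------------------------------------------------------------
# Classification

def classify(
    events: Sequence[VariantEvent],
    truncated_fraction_threshold: float = 0.05,
) -> GeneStatus:
    """Roll events up into one gene label.

    A frameshift indel with a downstream premature stop truncating at least
    the threshold fraction of the reference protein is a
    frameshift_pseudogene; a qualifying stop without a frameshift is
    truncated; otherwise retained_intron, in_frame_variant, or conserved.
    The result is a pure function of the event set (order never matters).
    """
    evs = sorted(events, key=lambda e: (e.position, e.kind, e.length))
    frameshifts = [
        e for e in evs
        if e.kind in ("insertion", "deletion") and e.frame_offset not in (0, None)
    ]
    stops = [e for e in evs if e.kind == "premature_stop"]
    retained = [e for e in evs if e.kind == "retained_intron"]
    indels = [e for e in evs if e.kind in ("insertion", "deletion")]

    trunc = max((e.truncated_fraction or 0.0) for e in stops) if stops else 0.0
    qualifying_stop = [
        e for e in stops if (e.truncated_fraction or 0.0) >= truncated_fraction_threshold
    ]
    if frameshifts and qualifying_stop:
        fs_min = min(e.position for e in frameshifts)
        downstream = [e for e in qualifying_stop if e.position >= fs_min]
        if downstream:
            return GeneStatus("frameshift_pseudogene", tuple(evs), trunc)
    if qualifying_stop:
        return GeneStatus("truncated", tuple(evs), trunc)
    if retained:
        return GeneStatus("retained_intron", tuple(evs), trunc)
    if indels:
        return GeneStatus("in_frame_variant", tuple(evs), trunc)
    return GeneStatus("conserved", tuple(evs), trunc)


# ---------------------------------------------------------------------------
# Orchestration

def scan_pair(
    query: SequenceRecord,
    reference: SequenceRecord,
    gene_model: Optional[GeneModel] = None,
    reads: Optional[Sequence[str]] = None,
    min_read_support: int = 2,
    merge_window: int = 20,
) -> tuple[GeneStatus, PairwiseAlignment]:
    """Align, detect all event kinds, optionally corroborate with reads."""
    aln = global_align(query, reference)
    events = merge_adjacent_indels(detect_indels(aln), merge_window)
    if gene_model is not None:
        events = detect_retained_intron(events, gene_model)
        events = annotate_exon_indices(events, gene_model)
    stop = detect_premature_stop(aln)
    if stop.event is not None:
        events = list(events) + [stop.event]
    if reads is not None:
        events = mark_read_support(events, aln.query, reads, min_read_support)
    return classify(events), aln


def apply_events(reference: str, events: Sequence[VariantEvent]) -> str:
    """Apply detected indel events back onto the reference.

    For a divergence-free query this reconstructs the query exactly (event
    completeness check).
    """
    seq = reference
    for ev in sorted(events, key=lambda e: -e.position):
        if ev.kind in ("insertion", "retained_intron"):
            p = ev.position + 1
            seq = seq[:p] + ev.inserted_seq + seq[p:]
        elif ev.kind == "deletion":
            p = ev.position + 1
            seq = seq[:p] + seq[p + ev.length :]
    return seq


def events_to_dict(ev: VariantEvent) -> dict:
    """JSON-stable event record."""
    return {
        "kind": ev.kind,
        "position": ev.position,
        "length": ev.length,
        "alignment_column": ev.alignment_column,
        "frame_offset": ev.frame_offset,
        "exon_index": ev.exon_index,
        "intron_index": ev.intron_index,
        "canonical_splice": ev.canonical_splice,
        "truncated_fraction": ev.truncated_fraction,
        "read_supported": ev.read_supported,
    }
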