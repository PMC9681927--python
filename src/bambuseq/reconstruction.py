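"""Ortholog-guided full-length CDS reconstruction.

Fragmented transcript contigs are mapped onto a conserved reference
ortholog CDS, stitched in reference order with explicit N gaps, remaining
gaps are filled by iterative exact-match seed-and-extend consensus over raw
reads, and genes absent from an annotation are recovered from genomic
scaffolds by translated search with GT..AG splice-boundary snapping.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import edlib
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import SequenceRecord, revcomp, translate

# DNA scores: BLAST-like match/mismatch (+2/-3) but a high-open, cheap-extend
# affine gap (cost 16 + 0.5(k-1) for a k-base gap).  The cheap extension is
# deliberate: a retained intron of several hundred bases must be cheaper as
# one long gap than as a mosaic of chance matches against the reference
# ("scatter"), which runs at roughly -0.7/base; the high open cost keeps
# 1-2 bp spurious gaps dearer than mismatches.
_DNA_MATCH, _DNA_MISMATCH = 2.0, -3.0
_DNA_OPEN, _DNA_EXTEND = -16.0, -0.5  # Biopython convention: first gap base -16


def _dna_aligner(mode: str) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = mode
    a.match_score = _DNA_MATCH
    a.mismatch_score = _DNA_MISMATCH
    a.open_gap_score = _DNA_OPEN
    a.extend_gap_score = _DNA_EXTEND
    return a


def _protein_aligner(mode: str = "local") -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = mode
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11.0
    a.extend_gap_score = -1.0
    return a


def _contig_infix_aligner() -> Align.PairwiseAligner:
    """Contig-global / reference-end-gap-free mapping aligner.

    Target = reference, query = contig.  Reference ends may be skipped for
    free (end gaps in the query row), while the contig aligns end-to-end,
    so diverged contig termini are still projected onto the reference.
    """
    a = _dna_aligner("global")
    # skipped reference letters are "deletions" in current Biopython naming
    if hasattr(a, "open_left_deletion_score"):
        a.open_left_deletion_score = 0.0
        a.extend_left_deletion_score = 0.0
        a.open_right_deletion_score = 0.0
        a.extend_right_deletion_score = 0.0
    else:  # older releases
        a.query_left_open_gap_score = 0.0
        a.query_left_extend_gap_score = 0.0
        a.query_right_open_gap_score = 0.0
        a.query_right_extend_gap_score = 0.0
    return a


# ---------------------------------------------------------------------------
# Types

@dataclass
class AlignmentBlock:
    """A contig mapped onto the reference CDS."""

    contig_id: str
    q_start: int
    q_end: int
    r_start: int
    r_end: int
    strand: str
    identity: float  # percent, over aligned columns
    score: float
    oriented_seq: str = ""
    # (r_start, r_end, q_start, q_end) runs where both sequences advance
    segments: tuple[tuple[int, int, int, int], ...] = ()
    # (ref position after which the run is inserted, q_start, q_end)
    insertions: tuple[tuple[int, int, int], ...] = ()
    deleted_ref: tuple[tuple[int, int], ...] = ()  # ref runs absent from contig


@dataclass(frozen=True)
class GapInfo:
    ref_start: int
    ref_end: int
    seq_start: int
    seq_end: int


@dataclass
class ScaffoldedTranscript:
    """Reference-ordered stitched sequence with per-base provenance.

    provenance[i] is 'contig:<id>', 'read_extended:<iteration>' or 'gap';
    gap records correspond exactly to N runs in the sequence.
    """

    reference_id: str
    sequence: str
    provenance: list[str]
    gaps: list[GapInfo]

    def __post_init__(self) -> None:
        if len(self.provenance) != len(self.sequence):
            raise ValueError("provenance must cover every base")


@dataclass(frozen=True)
class GapFillParams:
    seed_len: int = 25
    min_read_support: int = 2
    max_iterations: int = 10
    search_both_strands: bool = True
    extend_sides: str = "both"  # both | left | right
    flank_window: int = 200


@dataclass
class GapFillReport:
    ref_start: int
    ref_end: int
    closed: bool
    status: str  # closed | max_iterations | no_extension | unfillable
    iterations: int
    bases_added: int
    seeds_used: list[str] = field(default_factory=list)


@dataclass
class GenomicHit:
    scaffold: str
    start: int
    end: int
    strand: str
    frame: int
    exons: tuple[tuple[int, int], ...]  # genomic coords, transcription order
    score: float
    identity: float


@dataclass
class GenomeSearchResult:
    found: bool
    hit: Optional[GenomicHit]
    best_distance: Optional[int] = None
    reason: str = ""


@dataclass
class FinalizedCds:
    cds: str
    peptide: str
    frame: int
    identity_cds: float
    identity_peptide: float
    flags: tuple[str, ...] = ()


class StitchConflictError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Contig mapping

def _alignment_stats(aln, reference: str, contig: str) -> tuple[float, int]:
    """(percent identity, aligned columns) over the aligned region."""
    matches = cols = 0
    t_blocks, q_blocks = aln.aligned
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if prev_t is not None:
            cols += (ts - prev_t) + (qs - prev_q)
        for i in range(te - ts):
            cols += 1
            if reference[ts + i] == contig[qs + i]:
                matches += 1
        prev_t, prev_q = te, qe
    return (100.0 * matches / cols if cols else 0.0), cols


def map_contigs(
    contigs: Sequence[SequenceRecord],
    reference_cds: SequenceRecord,
    min_score: float = 20.0,
) -> list[AlignmentBlock]:
    """Map each contig onto the reference CDS (both strands), in reference order.

    The contig is aligned end-to-end while reference end gaps are free, so
    every contig base is projected; contigs scoring below min_score on both
    strands are dropped (empty list if nothing maps).  Because unrelated
    contigs are forced to align end-to-end they score hugely negative, so a
    small positive threshold separates them even from genuine contigs whose
    score is mostly consumed by a retained-intron gap.
    """
    aligner = _contig_infix_aligner()
    ref = reference_cds.residues
    blocks = []
    for contig in contigs:
        best = None
        for strand, seq in (("+", contig.residues), ("-", revcomp(contig.residues))):
            aln = aligner.align(ref, seq)[0]
            if best is None or aln.score > best[1].score:
                best = (strand, aln, seq)
        strand, aln, seq = best
        if aln.score < min_score:
            continue
        identity, _ = _alignment_stats(aln, ref, seq)
        t_blocks, q_blocks = aln.aligned
        segments, insertions, deleted = [], [], []
        prev_t = prev_q = None
        for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
            segments.append((int(ts), int(te), int(qs), int(qe)))
            if prev_t is not None:
                if qs > prev_q:  # contig bases absent from the reference
                    insertions.append((int(prev_t) - 1, int(prev_q), int(qs)))
                if ts > prev_t:  # reference bases absent from the contig
                    deleted.append((int(prev_t), int(ts)))
            prev_t, prev_q = te, qe
        blocks.append(
            AlignmentBlock(
                contig_id=contig.id,
                q_start=int(q_blocks[0][0]),
                q_end=int(q_blocks[-1][1]),
                r_start=int(t_blocks[0][0]),
                r_end=int(t_blocks[-1][1]),
                strand=strand,
                identity=identity,
                score=float(aln.score),
                oriented_seq=seq,
                segments=tuple(segments),
                insertions=tuple(insertions),
                deleted_ref=tuple(deleted),
            )
        )
    blocks.sort(key=lambda b: (b.r_start, b.contig_id))
    return blocks


# ---------------------------------------------------------------------------
# Stitching

def stitch(
    blocks: Sequence[AlignmentBlock],
    reference_cds: SequenceRecord,
    max_overlap_disagreement: float = 0.2,
) -> ScaffoldedTranscript:
    """Place contig bases at reference-projected positions; gaps become N runs.

    At overlapping positions where contigs disagree the base from the block
    with higher identity wins; exact identity ties emit N.  Two blocks
    disagreeing over more than `max_overlap_disagreement` of their overlap
    raise StitchConflictError.  Output is independent of block input order.
    """
    ref_len = len(reference_cds.residues)
    base: list[Optional[str]] = [None] * ref_len
    source: list[Optional[str]] = [None] * ref_len
    ident: list[float] = [-1.0] * ref_len
    covered = np.zeros(ref_len, bool)
    ins: dict[int, tuple[str, str, float]] = {}

    per_pos: dict[int, list[tuple[str, str]]] = {}
    ordered = sorted(blocks, key=lambda b: (-b.identity, b.contig_id))
    for b in ordered:
        for ts, te, qs, qe in b.segments:
            for i in range(te - ts):
                rp, ch = ts + i, b.oriented_seq[qs + i]
                per_pos.setdefault(rp, []).append((b.contig_id, ch))
                covered[rp] = True
                if base[rp] is None:
                    base[rp], source[rp], ident[rp] = ch, b.contig_id, b.identity
                elif base[rp] != ch:
                    if b.identity > ident[rp]:
                        base[rp], source[rp], ident[rp] = ch, b.contig_id, b.identity
                    elif b.identity == ident[rp]:
                        base[rp], source[rp] = "N", "conflict"
        for anchor, qs, qe in b.insertions:
            cur = ins.get(anchor)
            if cur is None or b.identity > cur[2]:
                ins[anchor] = (b.oriented_seq[qs:qe], b.contig_id, b.identity)
        for ds, de in b.deleted_ref:
            covered[ds:de] = True  # deleted in the contig: covered, emits nothing
            for rp in range(ds, de):
                if base[rp] is None:
                    base[rp], source[rp], ident[rp] = "", b.contig_id, b.identity

    _check_pairwise_conflicts(blocks, per_pos, max_overlap_disagreement)

    seq_parts: list[str] = []
    prov: list[str] = []
    gaps: list[GapInfo] = []
    pos_out = 0
    if -1 in ins:
        s, cid, _ = ins[-1]
        seq_parts.append(s)
        prov.extend([f"contig:{cid}"] * len(s))
        pos_out += len(s)
    rp = 0
    while rp < ref_len:
        if not covered[rp]:
            start = rp
            while rp < ref_len and not covered[rp]:
                rp += 1
            n = rp - start
            gaps.append(GapInfo(start, rp, pos_out, pos_out + n))
            seq_parts.append("N" * n)
            prov.extend(["gap"] * n)
            pos_out += n
            continue
        ch = base[rp] or ""
        if ch:
            seq_parts.append(ch)
            prov.append("conflict" if source[rp] == "conflict" else f"contig:{source[rp]}")
            pos_out += len(ch)
        if rp in ins:
            s, cid, _ = ins[rp]
            seq_parts.append(s)
            prov.extend([f"contig:{cid}"] * len(s))
            pos_out += len(s)
        rp += 1
    return ScaffoldedTranscript(
        reference_id=reference_cds.id,
        sequence="".join(seq_parts),
        provenance=prov,
        gaps=gaps,
    )


def _check_pairwise_conflicts(blocks, per_pos, max_frac) -> None:
    ids = sorted({b.contig_id for b in blocks})
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            overlap = disagree = 0
            positions = []
            for rp, entries in per_pos.items():
                chars = {cid: ch for cid, ch in entries}
                if a in chars and b in chars:
                    overlap += 1
                    if chars[a] != chars[b]:
                        disagree += 1
                        positions.append(rp)
            if overlap and disagree / overlap > max_frac:
                raise StitchConflictError(
                    f"contigs {a} and {b} disagree at {disagree}/{overlap} "
                    f"overlap positions: {sorted(positions)[:50]}"
                )


# ---------------------------------------------------------------------------
# Seed-and-extend gap filling

def _find_seed(context: str, seed_len: int) -> Optional[tuple[str, int]]:
    """Rightmost N-free window of seed_len in context; (seed, offset-from-end)."""
    if len(context) < seed_len:
        return None
    for back in range(len(context) - seed_len + 1):
        s = context[len(context) - seed_len - back : len(context) - back]
        if "N" not in s:
            return s, back
    return None


def _consensus_extend(tails: list[str], min_support: int) -> str:
    """Majority consensus column by column; a support tie halts extension."""
    out = []
    col = 0
    while True:
        counts: dict[str, int] = {}
        for t in tails:
            if len(t) > col:
                counts[t[col]] = counts.get(t[col], 0) + 1
        if not counts:
            break
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        best_ch, best_n = ranked[0]
        if best_n < min_support:
            break
        if len(ranked) > 1 and ranked[1][1] == best_n:
            break  # ambiguous column: report, don't guess
        out.append(best_ch)
        col += 1
    return "".join(out)


def _collect(pool: Sequence[str], seed: str, side: str, seed_back: int) -> list[str]:
    """Read suffixes (side=left) or prefixes (side=right) flanking the seed."""
    out = []
    for read in pool:
        start = 0
        while True:
            idx = read.find(seed, start)
            if idx < 0:
                break
            if side == "left":
                tail = read[idx + len(seed):]
                if seed_back:
                    tail = tail  # seed shifted into flank: tail begins after it
                if tail:
                    out.append(tail)
            else:
                head = read[:idx]
                if head:
                    out.append(head)
            start = idx + 1
    return out


def grep_extend(
    scaffold: ScaffoldedTranscript,
    reads: Sequence[str],
    params: GapFillParams = GapFillParams(),
) -> tuple[ScaffoldedTranscript, list[GapFillReport]]:
    """Fill N gaps by iterative exact-match seed extension over reads.

    Per gap and iteration, the terminal seed_len bases of the left (then
    right) flank are used as exact-match seeds into the read pool (both
    strands if configured); extension proceeds by majority consensus where
    at least min_read_support reads agree, halting on a support tie.  A gap
    closes when the converging extensions (or an extension and the opposite
    flank) overlap exactly over >= seed_len bases.  Non-gap bases are never
    modified.
    """
    pool = list(reads)
    if params.search_both_strands:
        pool += [revcomp(r) for r in reads]

    # split into alternating solid/gap parts
    parts: list[tuple[str, str, list[str]]] = []  # (type, seq, prov)
    last = 0
    for g in scaffold.gaps:
        parts.append(("solid", scaffold.sequence[last : g.seq_start],
                      scaffold.provenance[last : g.seq_start]))
        parts.append(("gap", scaffold.sequence[g.seq_start : g.seq_end],
                      scaffold.provenance[g.seq_start : g.seq_end]))
        last = g.seq_end
    parts.append(("solid", scaffold.sequence[last:], scaffold.provenance[last:]))

    reports: list[GapFillReport] = []
    new_parts: list[tuple[str, list[str], Optional[GapInfo]]] = []
    gap_iter = iter(scaffold.gaps)
    for pi, (kind, seq, prov) in enumerate(parts):
        if kind == "solid":
            new_parts.append((seq, list(prov), None))
            continue
        g = next(gap_iter)
        left_flank = parts[pi - 1][1][-params.flank_window :]
        right_flank = parts[pi + 1][1][: params.flank_window]
        fill, fill_prov, report = _fill_one_gap(
            g, left_flank, right_flank, pool, params
        )
        reports.append(report)
        if fill is None:
            new_parts.append((seq, list(prov), g))  # unchanged N run
        else:
            new_parts.append((fill, fill_prov, None))

    seq_out: list[str] = []
    prov_out: list[str] = []
    gaps_out: list[GapInfo] = []
    for seq, prov, g in new_parts:
        if g is not None:
            gaps_out.append(
                GapInfo(g.ref_start, g.ref_end, len("".join(seq_out)),
                        len("".join(seq_out)) + len(seq))
            )
        seq_out.append(seq)
        prov_out.extend(prov)
    return (
        ScaffoldedTranscript(scaffold.reference_id, "".join(seq_out), prov_out, gaps_out),
        reports,
    )


def _fill_one_gap(gap: GapInfo, left_flank: str, right_flank: str, pool, params):
    """Fill one N run.  A terminal gap (one flank empty) closes open-ended:
    the surviving side extends until read support runs out and the
    extension is accepted as the fill."""
    use_left = params.extend_sides in ("both", "left") and bool(left_flank)
    use_right = params.extend_sides in ("both", "right") and bool(right_flank)
    terminal = not left_flank or not right_flank
    left_ext: list[str] = []
    left_tag: list[str] = []
    right_ext: list[str] = []
    right_tag: list[str] = []
    seeds_used: list[str] = []
    status = "no_extension"
    closed = False
    fill = ""
    n_right_kept = 0
    it = 0

    def try_close():
        return _try_close(left_flank, "".join(left_ext), "".join(right_ext),
                          right_flank, params.seed_len)

    for it in range(1, params.max_iterations + 1):
        progressed = False
        if use_left:
            ctx = left_flank + "".join(left_ext)
            found = _find_seed(ctx[-params.flank_window :], params.seed_len)
            if found is None:
                use_left = False
            else:
                seed, _ = found
                seeds_used.append(seed)
                ext = _consensus_extend(
                    _collect(pool, seed, "left", 0), params.min_read_support
                )
                if ext:
                    left_ext.append(ext)
                    left_tag.extend([f"read_extended:{it}"] * len(ext))
                    progressed = True
            merged = try_close()
            if merged is not None:
                closed, status = True, "closed"
                fill, n_right_kept = merged
                break
        if use_right:
            ctx = "".join(right_ext) + right_flank
            found = _find_seed_left(ctx[: params.flank_window], params.seed_len)
            if found is None:
                use_right = False
            else:
                seed = found
                seeds_used.append(seed)
                ext = _consensus_extend_left(
                    _collect(pool, seed, "right", 0), params.min_read_support
                )
                if ext:
                    right_ext.insert(0, ext)
                    right_tag[:0] = [f"read_extended:{it}"] * len(ext)
                    progressed = True
            merged = try_close()
            if merged is not None:
                closed, status = True, "closed"
                fill, n_right_kept = merged
                break
        if not use_left and not use_right:
            status = "unfillable"
            break
        if not progressed:
            status = "no_extension"
            break
    else:
        status = "max_iterations"

    if not closed and terminal and (left_ext or right_ext):
        # open-ended closure at a transcript end
        closed, status = True, "closed"
        fill = "".join(left_ext) + "".join(right_ext)
        n_right_kept = len("".join(right_ext))

    if not closed:
        return None, None, GapFillReport(
            gap.ref_start, gap.ref_end, False, status, it,
            len("".join(left_ext)) + len("".join(right_ext)), seeds_used,
        )
    prov = left_tag[: len(fill)]
    if len(prov) < len(fill):
        # remaining bases came from the right-side extension
        take = len(fill) - len(prov)
        prov = prov + right_tag[len(right_tag) - n_right_kept :][:take]
        while len(prov) < len(fill):
            prov.append(f"read_extended:{it}")
    return fill, prov[: len(fill)], GapFillReport(
        gap.ref_start, gap.ref_end, True, "closed", it, len(fill), seeds_used
    )


def _find_seed_left(context: str, seed_len: int) -> Optional[str]:
    """Leftmost N-free window of seed_len in context."""
    if len(context) < seed_len:
        return None
    for fwd in range(len(context) - seed_len + 1):
        s = context[fwd : fwd + seed_len]
        if "N" not in s:
            return s
    return None


def _consensus_extend_left(heads: list[str], min_support: int) -> str:
    """Consensus growing leftward; heads are right-anchored."""
    out = []
    col = 0
    while True:
        counts: dict[str, int] = {}
        for h in heads:
            if len(h) > col:
                counts[h[len(h) - 1 - col]] = counts.get(h[len(h) - 1 - col], 0) + 1
        if not counts:
            break
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        best_ch, best_n = ranked[0]
        if best_n < min_support or (len(ranked) > 1 and ranked[1][1] == best_n):
            break
        out.append(best_ch)
        col += 1
    return "".join(reversed(out))


def _try_close(left_flank, left_ext, right_ext, right_flank, seed_len):
    """Exact >= seed_len overlap between the converging sides.

    Returns (fill string, bases of right_ext retained) or None.
    """
    A = left_flank + left_ext
    B = right_ext + right_flank
    if not left_ext and not right_ext:
        return None
    max_o = min(len(A), len(B))
    for o in range(max_o, seed_len - 1, -1):
        if A[-o:] == B[:o]:
            full = A + B[o:]
            fill_len = len(full) - len(left_flank) - len(right_flank)
            if fill_len < 0:
                return None
            fill = full[len(left_flank) : len(left_flank) + fill_len]
            n_right_kept = max(0, fill_len - len(left_ext))
            return fill, n_right_kept
    return None


# ---------------------------------------------------------------------------
# Genomic recovery (translated search)

def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def genome_recover(
    query: SequenceRecord,
    genome: Sequence[SequenceRecord],
    *,
    query_is_peptide: bool = False,
    min_intron: int = 30,
    snap_window: int = 10,
    max_norm_distance: float = 0.45,
) -> GenomeSearchResult:
    """Locate an unannotated gene on genomic scaffolds and infer its exons.

    DNA queries are located by infix edit-distance alignment on both
    strands; long deletion runs in the path become introns, whose
    boundaries are snapped to the nearest GT..AG pair within +-snap_window.
    The reading frame is the six-frame translation of the concatenated
    exons that best aligns to the query peptide.  Peptide queries are
    located via per-frame local protein alignments, chained in query order.
    """
    if query_is_peptide:
        return _recover_from_peptide(query, genome, min_intron, snap_window)
    # edlib (fast, unit costs) only locates the rough region; intron-aware
    # structure needs the high-open/cheap-extend affine aligner, since unit
    # costs price a long intron deletion like a run of mismatches
    best = None
    for scaf in genome:
        for strand, target in (("+", scaf.residues), ("-", revcomp(scaf.residues))):
            res = edlib.align(query.residues, target, mode="HW", task="locations")
            if best is None or res["editDistance"] < best[0]:
                best = (res["editDistance"], res, scaf, strand, target)
    dist, res, scaf, strand, target = best
    if dist > max_norm_distance * len(query.residues):
        return GenomeSearchResult(False, None, dist, "no hit above threshold")

    loc0, loc1 = res["locations"][0]
    pad = len(query.residues) + 5000
    w_start = max(0, loc0 - pad)
    w_end = min(len(target), loc1 + 1 + pad)
    window = target[w_start:w_end]
    aligner = _contig_infix_aligner()
    aln = aligner.align(window, query.residues)[0]
    if aln.score < 50:
        return GenomeSearchResult(False, None, dist, "no hit above threshold")
    t_blocks, _ = aln.aligned
    exons_t: list[tuple[int, int]] = []
    cur_start = int(t_blocks[0][0])
    prev_end = None
    for ts, te in ((int(a), int(b)) for a, b in t_blocks):
        if prev_end is not None and ts - prev_end >= min_intron:
            exons_t.append((cur_start, prev_end))
            cur_start = ts
        prev_end = te
    exons_t.append((cur_start, prev_end))
    exons_t = [(s + w_start, e + w_start) for s, e in exons_t]
    exons_t = _snap_splice_sites(exons_t, target, min_intron, snap_window)

    candidate = "".join(target[s:e] for s, e in exons_t)
    frame, fscore = _best_frame(candidate, query, query_is_peptide=False)
    identity = 100.0 * (1.0 - dist / max(len(query.residues), 1))
    L = len(scaf.residues)
    if strand == "+":
        exons_g = tuple(exons_t)
        start, end = exons_t[0][0], exons_t[-1][1]
    else:
        exons_g = tuple((L - e, L - s) for s, e in exons_t)
        start, end = L - exons_t[-1][1], L - exons_t[0][0]
    return GenomeSearchResult(
        True,
        GenomicHit(
            scaffold=scaf.id, start=start, end=end, strand=strand,
            frame=frame, exons=exons_g, score=float(fscore), identity=identity,
        ),
        dist,
    )


def _snap_splice_sites(exons, target, min_intron, window):
    """Shift donor/acceptor pairs (same shift preferred) onto GT..AG."""
    out = [list(exons[0])]
    for nxt in exons[1:]:
        donor = out[-1][1]       # intron start
        acceptor = nxt[0]        # intron end (exclusive of exon)
        best = None
        for d1 in range(-window, window + 1):
            for d2 in range(-window, window + 1):
                ds, ae = donor + d1, acceptor + d2
                if ae - ds < min_intron or ds < 2 or ae + 2 > len(target):
                    continue
                if target[ds : ds + 2] == "GT" and target[ae - 2 : ae] == "AG":
                    key = (abs(d1 - d2), abs(d1) + abs(d2), d1, d2)
                    if best is None or key < best[0]:
                        best = (key, d1, d2)
        if best is not None:
            _, d1, d2 = best
            out[-1][1] = donor + d1
            out.append([acceptor + d2, nxt[1]])
        else:
            out.append(list(nxt))
    return [tuple(e) for e in out]


def _best_frame(candidate: str, query: SequenceRecord, query_is_peptide: bool):
    """Six-frame translation of candidate maximizing protein alignment score."""
    if query_is_peptide:
        qpep = query.residues
    else:
        q = query.residues
        qpep = translate(q[: len(q) - len(q) % 3]).rstrip("*").replace("*", "X")
    aligner = _protein_aligner("local")
    best_frame, best_score = 1, -np.inf
    for strand_label, seq in ((1, candidate), (-1, revcomp(candidate))):
        for off in range(3):
            pep = translate(seq[off:]).replace("*", "X")
            if not pep:
                continue
            score = aligner.score(pep, qpep)
            if score > best_score:
                best_score = score
                best_frame = strand_label * (off + 1)
    return best_frame, best_score


def _recover_from_peptide(query, genome, min_intron, snap_window):
    """Chained per-frame local protein alignments (each chunk ~ one exon)."""
    aligner = _protein_aligner("local")
    best = None
    for scaf in genome:
        for strand, target in (("+", scaf.residues), ("-", revcomp(scaf.residues))):
            total = 0.0
            chunks = []  # (q_start, t_dna_start, t_dna_end)
            qpep = query.residues
            masked = qpep
            for _ in range(12):
                frame_best = None
                for off in range(3):
                    tpep = translate(target[off:]).replace("*", "X")
                    if len(masked.replace("X", "")) < 8:
                        break
                    alns = aligner.align(tpep, masked)
                    if alns.score <= 0:
                        continue
                    aln = alns[0]
                    if frame_best is None or aln.score > frame_best[0]:
                        frame_best = (aln.score, off, aln)
                if frame_best is None:
                    break
                score, off, aln = frame_best
                if score < 25:
                    break
                t_blocks, q_blocks = aln.aligned
                qs, qe = int(q_blocks[0][0]), int(q_blocks[-1][1])
                # a long gap in the target row inside one protein alignment
                # is an intron bridged by the affine gap: split there
                split_aa = max(8, min_intron // 3)
                seg_start = int(t_blocks[0][0])
                seg_q = int(q_blocks[0][0])
                prev_end = None
                for (ts, te), (bqs, bqe) in zip(t_blocks, q_blocks):
                    ts, te = int(ts), int(te)
                    if prev_end is not None and ts - prev_end >= split_aa:
                        chunks.append((seg_q, off + 3 * seg_start,
                                       off + 3 * prev_end))
                        seg_start, seg_q = ts, int(bqs)
                    prev_end = te
                chunks.append((seg_q, off + 3 * seg_start, off + 3 * prev_end))
                total += score
                masked = masked[:qs] + "X" * (qe - qs) + masked[qe:]
            if chunks and (best is None or total > best[0]):
                best = (total, chunks, scaf, strand, target)
    if best is None:
        return GenomeSearchResult(False, None, None, "no hit above threshold")
    total, chunks, scaf, strand, target = best
    chunks.sort(key=lambda c: c[0])
    exons_t = [(s, e) for _, s, e in chunks]
    exons_t = _snap_splice_sites(exons_t, target, min_intron, snap_window)
    candidate = "".join(target[s:e] for s, e in exons_t)
    frame, fscore = _best_frame(candidate, query, query_is_peptide=True)
    L = len(scaf.residues)
    if strand == "+":
        exons_g = tuple(exons_t)
        start, end = exons_t[0][0], exons_t[-1][1]
    else:
        exons_g = tuple((L - e, L - s) for s, e in exons_t)
        start, end = L - exons_t[-1][1], L - exons_t[0][0]
    return GenomeSearchResult(
        True,
        GenomicHit(scaf.id, start, end, strand, frame, exons_g, float(total), 0.0),
        None,
    )


# ---------------------------------------------------------------------------
# Finalization

def finalize(
    sequence: str,
    reference_cds: SequenceRecord,
    reference_peptide: Optional[SequenceRecord] = None,
) -> FinalizedCds:
    """Trim a reconstructed sequence to ATG..stop in the reference-selected frame.

    Global identity (matches / alignment columns, gap columns included) is
    reported against both the reference CDS and peptide.  A missing start
    or a premature stop is flagged, never silently trimmed away.
    """
    from .pseudoscan import global_align  # shared aligner, avoids duplication

    if not sequence:
        raise ValueError("empty sequence")
    flags: list[str] = []
    if "N" in sequence:
        flags.append("has_gaps")
    ref_pep = (
        reference_peptide.residues
        if reference_peptide is not None
        else translate(reference_cds.residues).rstrip("*")
    )
    paligner = _protein_aligner("local")
    best = None
    for off in range(3):
        pep = translate(sequence[off:]).replace("*", "X")
        if not pep:
            continue
        score = paligner.score(pep, ref_pep)
        if best is None or score > best[0]:
            best = (score, off)
    frame = best[1]
    inframe = sequence[frame:]
    inframe = inframe[: len(inframe) - len(inframe) % 3]
    pep_full = translate(inframe)

    start_codon = pep_full.find("M")
    if start_codon < 0:
        flags.append("no_start")
        cds = inframe
        pep = pep_full.rstrip("*")
    else:
        stop_rel = pep_full.find("*", start_codon)
        if stop_rel < 0:
            flags.append("no_stop")
            cds = inframe[3 * start_codon :]
            pep = pep_full[start_codon:]
        else:
            cds = inframe[3 * start_codon : 3 * (stop_rel + 1)]
            pep = pep_full[start_codon:stop_rel]
            if len(pep) < 0.95 * len(ref_pep):
                flags.append("premature_stop")

    aln = global_align(
        SequenceRecord("query", cds), reference_cds
    )
    id_cds = aln.identity
    pep_aln_id = _global_protein_identity(pep or "X", ref_pep)
    return FinalizedCds(
        cds=cds,
        peptide=pep,
        frame=frame + 1,
        identity_cds=id_cds,
        identity_peptide=pep_aln_id,
        flags=tuple(flags),
    )


def _global_protein_identity(a: str, b: str) -> float:
    aligner = _protein_aligner("global")
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(sa, sb) if x == y and x != "-")
    return 100.0 * matches / len(sa) if sa else 0.0
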