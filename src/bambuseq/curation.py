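"""Assembly curation: ORF filtering, representative selection, statistics.

Reduces a redundant de novo transcript assembly to one representative
contig per (assembly component, orthogroup) group and reports completeness
statistics: contig length summaries (N25/N50), and the capture rate of an
ultra-conserved ortholog (UCO) benchmark set.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .seqio import DNA_ALPHABET, STOP_CODONS, SequenceRecord, revcomp


@dataclass(frozen=True)
class OrfAnnotation:
    """Longest ATG..stop open reading frame of a contig.

    start/end are 0-based half-open coordinates on the *forward* contig;
    frame is +1/+2/+3 (forward offsets 0/1/2) or -1/-2/-3 (reverse
    complement offsets); length includes the stop codon.
    """

    start: int
    end: int
    frame: int
    length: int


@dataclass
class ContigRecord:
    """An assembled transcript contig with its grouping keys."""

    record: SequenceRecord
    component_id: str
    orthogroup_id: Optional[str] = None
    orf: Optional[OrfAnnotation] = None

    def __post_init__(self) -> None:
        if not self.component_id:
            raise ValueError(f"contig {self.record.id}: component_id must be nonempty")

    def __len__(self) -> int:
        return len(self.record.residues)


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    n_assigned: int
    n25: int
    n50: int
    mean_len: float
    min_len: int
    max_len: int


def find_longest_orf(record: SequenceRecord) -> Optional[OrfAnnotation]:
    """Longest ATG->stop ORF over all 6 frames (stop codon included).

    ORFs running off the contig end are not counted.  Ties are broken
    deterministically: frames are scanned in the order +1,+2,+3,-1,-2,-3
    and within a frame the 5'-most ORF wins; only a strictly longer ORF
    replaces the incumbent.
    """
    seq = record.residues
    if set(seq) - DNA_ALPHABET:
        raise ValueError(f"contig {record.id}: not a DNA sequence")
    L = len(seq)
    best: Optional[OrfAnnotation] = None
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for off in range(3):
            start = None
            for p in range(off, L - 2, 3):
                codon = s[p : p + 3]
                if start is None:
                    if codon == "ATG":
                        start = p
                elif codon in STOP_CODONS:
                    length = p + 3 - start
                    if best is None or length > best.length:
                        if strand == "+":
                            fs, fe = start, p + 3
                            frame = off + 1
                        else:
                            fs, fe = L - (p + 3), L - start
                            frame = -(off + 1)
                        best = OrfAnnotation(fs, fe, frame, length)
                    start = None
    return best


def annotate_orfs(contigs: Iterable[ContigRecord]) -> list[ContigRecord]:
    return [replace(c, orf=find_longest_orf(c.record)) for c in contigs]


def filter_orf(contigs: Sequence[ContigRecord], min_orf_bp: int = 200) -> list[ContigRecord]:
    """Keep contigs whose longest ORF is strictly greater than min_orf_bp."""
    return [c for c in contigs if c.orf is not None and c.orf.length > min_orf_bp]


def select_representatives(contigs: Sequence[ContigRecord]) -> list[ContigRecord]:
    """One longest contig per (component, orthogroup) group.

    Unassigned contigs (orthogroup None) group by component alone.  Ties on
    length keep the lexicographically smallest contig id.  Input order is
    preserved in the output.
    """
    best: dict[tuple[str, Optional[str]], ContigRecord] = {}
    for c in contigs:
        key = (c.component_id, c.orthogroup_id)
        cur = best.get(key)
        if (
            cur is None
            or len(c) > len(cur)
            or (len(c) == len(cur) and c.record.id < cur.record.id)
        ):
            best[key] = c
    chosen = {id(c) for c in best.values()}
    return [c for c in contigs if id(c) in chosen]


def _nxx(lengths: np.ndarray, fraction: float) -> int:
    """Length L such that contigs >= L sum to >= fraction of total bases."""
    desc = np.sort(lengths)[::-1]
    cum = np.cumsum(desc)
    idx = int(np.searchsorted(cum, fraction * cum[-1]))
    return int(desc[min(idx, len(desc) - 1)])


def assembly_stats(
    contigs: Sequence[ContigRecord], assigned_only: bool = False
) -> AssemblyStats:
    """Length summaries; assigned_only restricts to orthogroup-assigned contigs."""
    pool = [c for c in contigs if c.orthogroup_id] if assigned_only else list(contigs)
    if not pool:
        raise ValueError("no contigs to summarize")
    lengths = np.array([len(c) for c in pool])
    return AssemblyStats(
        n_contigs=len(pool),
        n_assigned=sum(1 for c in pool if c.orthogroup_id),
        n25=_nxx(lengths, 0.25),
        n50=_nxx(lengths, 0.50),
        mean_len=float(lengths.mean()),
        min_len=int(lengths.min()),
        max_len=int(lengths.max()),
    )


def uco_capture(
    orthogroups_present: Iterable[str], uco_orthogroup_ids: Sequence[str]
) -> tuple[int, int, float]:
    """UCO benchmark capture: (captured, total, rate as a 1-decimal percent).

    The percentage is truncated (not rounded) to one decimal, the
    convention completeness tables in this field typically use.
    """
    uco = set(uco_orthogroup_ids)
    if not uco:
        raise ValueError("UCO orthogroup list must be nonempty")
    captured = len(uco & set(orthogroups_present))
    rate = int(1000.0 * captured / len(uco)) / 10.0
    return captured, len(uco), rate
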