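"""Synthetic data generation with machine-readable ground truth.

Everything the pipeline consumes can be generated here: multi-exon gene
models on genomic scaffolds, diverged ortholog transcripts with planted
sequence-evolution events (frameshift indels, retained introns), fragmented
contig sets with an internal assembly gap, short error-prone reads, and
gene x library count matrices with cluster archetypes, negative-binomial
noise and injected outlier replicate libraries.

All generators are pure functions of (config, seed): the same inputs give
byte-identical artifacts.  Ground truth is returned alongside every
artifact so downstream stages can be scored without reaching back into
generator internals.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .seqio import (
    GeneModel,
    GenomicInterval,
    SequenceRecord,
    STOP_CODONS,
    revcomp,
    translate,
)

_BASES = "ACGT"
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in STOP_CODONS
)
_STOPS = ("TAA", "TAG", "TGA")


# ---------------------------------------------------------------------------
# Configuration

@dataclass(frozen=True)
class FragmentationSpec:
    """How an ortholog transcript is broken into contigs around one gap."""

    n_contigs: int = 3
    gap_len: int = 120
    gap_start: Optional[int] = None  # None: random interior placement
    min_contig_len: int = 50
    # breakpoints and the gap keep this distance from planted-event
    # footprints: affine-gap contig mapping needs a solid exonic anchor on
    # both sides of a long retained intron to place it as one gap
    event_margin: int = 150


@dataclass(frozen=True)
class EventSpec:
    """One planted sequence-evolution event.

    kind: insertion | deletion | retained_intron
    index: 1-based exon index (indels) or intron index (retained_intron)
    length: event length in bp (ignored for retained_intron: the intron's
        own length is used)
    offset: position within the exon (bp from exon start); None = random,
        at least 25 bp from either exon boundary where possible
    stop_free: insertions drawn from {A,C,G} so no stop codon can arise
        within the inserted run itself
    """

    kind: str
    index: int
    length: int = 0
    offset: Optional[int] = None
    stop_free: bool = False

    def __post_init__(self) -> None:
        if self.kind not in {"insertion", "deletion", "retained_intron"}:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class CountDesign:
    """Tissue x replicate layout and expression archetypes for counts.

    Defaults emulate the study layout: six developmental tissues (culm bud,
    underground/above-ground shoot, three flower stages) with three
    biological replicates, nine expression archetypes, and moderate
    negative-binomial overdispersion.
    """

    tissues: tuple[str, ...] = ("Cb", "ShU", "ShA", "Fl1", "Fl2", "Fl3")
    replicates: int = 3
    n_genes: int = 4500
    n_clusters: int = 9
    base_mean: float = 20.0
    fold: float = 32.0
    dispersion: float = 0.05
    outlier_libraries: tuple[str, ...] = ()

    def libraries(self) -> list[str]:
        return [f"{t}_R{r}" for t in self.tissues for r in range(1, self.replicates + 1)]


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for all generators.

    divergence is the per-base substitution probability of the simulated
    ortholog; the study's orthologs sit at roughly 73-85% CDS identity to
    rice, i.e. divergence 0.15-0.27.  Reads are 100 bp paired-end with a
    200-300 bp insert, matching the sequencing layout the generator
    emulates.
    """

    seed: int = 0
    n_genes: int = 20
    exon_count_range: tuple[int, int] = (4, 9)
    exon_len_range: tuple[int, int] = (90, 400)
    # fixed exon lengths (bp) override the two ranges when set, so a gene
    # with an exact CDS/peptide length can be constructed
    exon_lengths: Optional[tuple[int, ...]] = None
    intron_len_range: tuple[int, int] = (80, 800)
    flank_len: int = 300
    minus_strand_fraction: float = 0.5
    divergence: float = 0.2
    planted_events: tuple[EventSpec, ...] = ()
    fragmentation: FragmentationSpec = field(default_factory=FragmentationSpec)
    read_len: int = 100
    coverage: float = 20.0
    error_rate: float = 0.0
    insert_range: tuple[int, int] = (200, 300)
    count_design: CountDesign = field(default_factory=CountDesign)

    def __post_init__(self) -> None:
        for name in ("exon_count_range", "exon_len_range", "intron_len_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"{name} {lo, hi} is empty or invalid")
        if not (0 <= self.error_rate < 0.1):
            raise ValueError("error_rate must be in [0, 0.1)")
        if not (0 <= self.divergence < 1):
            raise ValueError("divergence must be in [0, 1)")
        lo, hi = self.exon_len_range
        if hi - lo < 2 and (lo * self.exon_count_range[0]) % 3 != 0:
            # with a fixed exon length the total may never be divisible by 3
            if (lo % 3) != 0 and self.exon_count_range[0] == self.exon_count_range[1] \
                    and (lo * self.exon_count_range[0]) % 3 != 0 and hi == lo:
                raise ValueError(
                    "exon length ranges cannot produce a CDS divisible by 3"
                )


# ---------------------------------------------------------------------------
# Ground truth containers

@dataclass(frozen=True)
class PlantedEvent:
    """Truth record for one applied event (reference CDS coordinates).

    position: 0-based coordinate of the reference base immediately
    preceding the event (matches the variant scanner's convention).
    """

    kind: str
    position: int
    length: int
    frame_offset: int
    exon_index: Optional[int] = None
    intron_index: Optional[int] = None
    inserted_seq: str = ""
    deleted_seq: str = ""


@dataclass
class GeneTruth:
    gene_id: str
    intron_seqs: tuple[str, ...]


@dataclass
class SimulatedGenes:
    genome: list[SequenceRecord]
    models: list[GeneModel]
    truth: dict[str, GeneTruth]


@dataclass
class OrthologSim:
    """A simulated diverged ortholog of one reference gene."""

    gene_id: str
    transcript: str                      # full mutant transcript (truth)
    substituted_reference: str           # reference CDS after substitutions only
    contigs: list[SequenceRecord]
    events: tuple[PlantedEvent, ...]
    contig_intervals: tuple[tuple[int, int], ...]  # on the mutant transcript
    gap_transcript: Optional[tuple[int, int]]      # gap on the mutant transcript
    gap_reference: Optional[tuple[int, int]]       # same gap in reference coords
    component_id: str = ""


@dataclass
class CountsTruth:
    cluster_labels: np.ndarray           # per-gene archetype index (0-based)
    outlier_libraries: tuple[str, ...]
    library_tissue: dict[str, str]


# ---------------------------------------------------------------------------
# Gene model simulation

def _random_dna(rng: np.random.Generator, n: int, alphabet: str = _BASES) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


def _draw_exon_lengths(rng, cfg: SimConfig, k: int) -> list[int]:
    lo, hi = cfg.exon_len_range
    lens = [int(v) for v in rng.integers(lo, hi + 1, k)]
    total = sum(lens)
    # retune the last exon so the CDS length is divisible by 3
    rem = total % 3
    if rem:
        last = lens[-1]
        candidates = [v for v in range(lo, hi + 1) if (total - last + v) % 3 == 0]
        if not candidates:
            raise ValueError("exon length range cannot produce a CDS divisible by 3")
        lens[-1] = min(candidates, key=lambda v: (abs(v - last), v))
        total = sum(lens)
    if total < 6:
        raise ValueError("CDS too short for a start and a stop codon")
    return lens


def _make_cds(rng, total: int) -> str:
    ncod = total // 3
    body = "".join(
        _NONSTOP_CODONS[i] for i in rng.integers(0, len(_NONSTOP_CODONS), ncod - 2)
    )
    stop = _STOPS[rng.integers(0, 3)]
    return "ATG" + body + stop


def _make_intron(rng, cfg: SimConfig) -> str:
    lo, hi = cfg.intron_len_range
    n = int(rng.integers(lo, hi + 1))
    n = max(n, 6)
    return "GT" + _random_dna(rng, n - 4) + "AG"


def simulate_gene_models(config: SimConfig) -> SimulatedGenes:
    """Generate scaffolds, gene models and ground truth.

    Each gene sits on its own scaffold with random flanks.  Introns begin
    GT and end AG; the CDS starts ATG, ends with a single stop codon, and
    its length is divisible by 3.
    """
    rng = np.random.default_rng(config.seed)
    genome, models, truth = [], [], {}
    lo_k, hi_k = config.exon_count_range
    for gi in range(config.n_genes):
        gene_id = f"gene{gi:03d}"
        scaffold_id = f"scaf{gi:03d}"
        if config.exon_lengths is not None:
            if sum(config.exon_lengths) % 3 != 0:
                raise ValueError("fixed exon lengths must sum to a multiple of 3")
            k = len(config.exon_lengths)
            exon_lens = list(config.exon_lengths)
        else:
            k = int(rng.integers(lo_k, hi_k + 1))
            exon_lens = _draw_exon_lengths(rng, config, k)
        cds = _make_cds(rng, sum(exon_lens))
        introns = tuple(_make_intron(rng, config) for _ in range(k - 1))
        minus = rng.random() < config.minus_strand_fraction

        parts, exon_plus, pos = [], [], 0
        left = _random_dna(rng, config.flank_len)
        parts.append(left)
        pos += len(left)
        off = 0
        for i, ln in enumerate(exon_lens):
            exon_plus.append((pos, pos + ln))
            parts.append(cds[off : off + ln])
            off += ln
            pos += ln
            if i < k - 1:
                parts.append(introns[i])
                pos += len(introns[i])
        parts.append(_random_dna(rng, config.flank_len))
        region = "".join(parts)

        if minus:
            scaffold_seq = revcomp(region)
            L = len(region)
            exons = tuple(
                GenomicInterval(scaffold_id, L - e, L - s, "-") for s, e in exon_plus
            )
            intron_seqs = introns  # transcript orientation, as planted
            strand = "-"
        else:
            scaffold_seq = region
            exons = tuple(
                GenomicInterval(scaffold_id, s, e, "+") for s, e in exon_plus
            )
            intron_seqs = introns
            strand = "+"

        pep = translate(cds)[:-1]
        model = GeneModel(
            gene_id=gene_id,
            scaffold=scaffold_id,
            strand=strand,
            exons=exons,
            cds=SequenceRecord(gene_id + ".cds", cds),
            peptide=SequenceRecord(gene_id + ".pep", pep),
        )
        model.validate()
        genome.append(SequenceRecord(scaffold_id, scaffold_seq))
        models.append(model)
        truth[gene_id] = GeneTruth(gene_id, intron_seqs)
    return SimulatedGenes(genome=genome, models=models, truth=truth)


# ---------------------------------------------------------------------------
# Ortholog simulation

def _substitute(
    rng, cds: str, divergence: float, protected: set[int], avoid_stops: bool
) -> str:
    """i.i.d. substitutions, uniform over the 3 alternative bases.

    Positions in `protected` (event footprints plus the start and terminal
    stop codons) are never touched.  With avoid_stops, a substitution that
    would create an in-frame stop in the reference frame is resampled among
    the remaining alternatives.
    """
    seq = list(cds)
    n = len(seq)
    hits = np.nonzero(rng.random(n) < divergence)[0]
    for p in hits:
        if p in protected:
            continue
        alts = [b for b in _BASES if b != seq[p]]
        rng.shuffle(alts)
        placed = False
        for b in alts:
            if avoid_stops:
                c0 = (p // 3) * 3
                codon = seq[c0] + seq[c0 + 1] + seq[c0 + 2] if c0 + 3 <= n else ""
                trial = list(codon)
                if codon:
                    trial[p - c0] = b
                    if "".join(trial) in STOP_CODONS:
                        continue
            seq[p] = b
            placed = True
            break
        if not placed:
            continue
    return "".join(seq)


def simulate_ortholog(
    model: GeneModel,
    intron_seqs: Sequence[str],
    *,
    divergence: float = 0.2,
    events: Sequence[EventSpec] = (),
    fragmentation: Optional[FragmentationSpec] = None,
    avoid_stops: bool = True,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> OrthologSim:
    """Diverge a reference gene into an ortholog transcript, then fragment it.

    Substitutions are applied only outside planted-event footprints; planted
    events are applied 3'->5' so earlier coordinates stay valid.  Expected
    global identity of the mutant vs the reference is 1 - divergence.
    """
    if rng is None:
        rng = np.random.default_rng(seed if seed is not None else 0)
    cds = model.cds.residues
    exon_lens = model.exon_lengths
    junctions = (0,) + tuple(np.cumsum(exon_lens))  # junction[i] = CDS start of exon i

    planned: list[tuple[int, EventSpec, str, int]] = []  # (ref_pos, spec, payload, length)
    for ev in events:
        if ev.kind == "retained_intron":
            if not (1 <= ev.index <= len(intron_seqs)):
                raise ValueError(f"no intron {ev.index} in gene {model.gene_id}")
            pos = int(junctions[ev.index])  # insert at start of exon index+1
            payload = intron_seqs[ev.index - 1]
            planned.append((pos, ev, payload, len(payload)))
        else:
            if not (1 <= ev.index <= len(exon_lens)):
                raise ValueError(f"no exon {ev.index} in gene {model.gene_id}")
            elen = exon_lens[ev.index - 1]
            if ev.offset is not None:
                off = ev.offset
            else:
                margin = 25 if elen > 60 + (ev.length if ev.kind == "deletion" else 0) else 3
                hi = elen - margin - (ev.length if ev.kind == "deletion" else 0)
                if hi <= margin:
                    off = elen // 2
                else:
                    off = int(rng.integers(margin, hi))
            pos = int(junctions[ev.index - 1]) + off
            if ev.kind == "insertion":
                alphabet = "ACG" if ev.stop_free else _BASES
                payload = _random_dna(rng, ev.length, alphabet)
                planned.append((pos, ev, payload, ev.length))
            else:
                if pos + ev.length > len(cds):
                    raise ValueError("deletion runs past CDS end")
                planned.append((pos, ev, cds[pos : pos + ev.length], ev.length))

    protected = {0, 1, 2, len(cds) - 3, len(cds) - 2, len(cds) - 1}
    for pos, ev, payload, ln in planned:
        if ev.kind == "deletion":
            protected.update(range(pos, pos + ln))
    sub = _substitute(rng, cds, divergence, protected, avoid_stops)

    # apply events 3'->5'
    mutant = sub
    truth_events = []
    for pos, ev, payload, ln in sorted(planned, key=lambda t: -t[0]):
        if ev.kind == "deletion":
            mutant = mutant[:pos] + mutant[pos + ln :]
        else:
            mutant = mutant[:pos] + payload + mutant[pos:]
        truth_events.append(
            PlantedEvent(
                kind=ev.kind,
                position=pos - 1,
                length=ln,
                frame_offset=ln % 3,
                exon_index=ev.index if ev.kind != "retained_intron" else None,
                intron_index=ev.index if ev.kind == "retained_intron" else None,
                inserted_seq=payload if ev.kind != "deletion" else "",
                deleted_seq=payload if ev.kind == "deletion" else "",
            )
        )
    truth_events = tuple(sorted(truth_events, key=lambda e: e.position))

    # query-space (mutant transcript) footprints of the planted events
    footprints = []
    shift = 0
    for e in truth_events:  # sorted by reference position
        q = e.position + 1 + shift
        ln = e.length if e.kind != "deletion" else 0
        footprints.append((q, q + ln))
        shift += e.length if e.kind != "deletion" else -e.length

    gap_t = gap_r = None
    contigs: list[SequenceRecord] = []
    contig_ivals: tuple[tuple[int, int], ...] = ()
    component = f"comp_{model.gene_id}"
    if fragmentation is not None:
        gap_t = _place_gap(rng, len(mutant), fragmentation, footprints)
        gs, ge = gap_t
        off = sum(
            e.length if e.kind != "deletion" else -e.length
            for e in truth_events
            if e.position < gs
        )
        gap_r = (gs - off, ge - off)
        contig_ivals = _split_contigs(
            rng, len(mutant), gap_t, fragmentation, footprints
        )
        contigs = [
            SequenceRecord(f"{model.gene_id}_c{i+1}", mutant[s:e])
            for i, (s, e) in enumerate(contig_ivals)
        ]
    return OrthologSim(
        gene_id=model.gene_id,
        transcript=mutant,
        substituted_reference=sub,
        contigs=contigs,
        events=truth_events,
        contig_intervals=contig_ivals,
        gap_transcript=gap_t,
        gap_reference=gap_r,
        component_id=component,
    )


def _place_gap(rng, L: int, frag: FragmentationSpec, footprints) -> tuple[int, int]:
    if frag.gap_len >= L:
        raise ValueError("gap longer than transcript")
    if frag.gap_start is not None:
        gs = frag.gap_start
        if gs + frag.gap_len > L:
            raise ValueError("gap runs past transcript end")
        return gs, gs + frag.gap_len
    lo = max(frag.min_contig_len, int(0.15 * L))
    hi = min(L - frag.gap_len - frag.min_contig_len, int(0.75 * L))
    if hi <= lo:
        raise ValueError("transcript too short for the configured gap")
    # keep the gap clear of planted events so event detection is
    # attributable to the scanner, not the gap filler; on cramped
    # transcripts the margin is relaxed progressively
    for m in (frag.event_margin, 100, 50, 25):
        if m > frag.event_margin:
            continue
        for _ in range(500):
            gs = int(rng.integers(lo, hi))
            ge = gs + frag.gap_len
            if all(ge + m <= s or e + m <= gs for s, e in footprints):
                if m < frag.event_margin:
                    warnings.warn(
                        f"gap placed only {m} bp from a planted event "
                        "(transcript too short for the configured margin)"
                    )
                return gs, ge
    raise ValueError("could not place gap away from planted events")


def _split_contigs(rng, L, gap, frag: FragmentationSpec, footprints=()):
    gs, ge = gap
    n = frag.n_contigs
    if n < 2:
        raise ValueError("fragmentation needs at least 2 contigs")
    left_len, right_len = gs, L - ge
    n_left = max(1, min(n - 1, round(n * left_len / (left_len + right_len))))
    n_right = n - n_left
    m = frag.event_margin
    ivals = _tile(rng, 0, gs, n_left, frag.min_contig_len, footprints, m) + _tile(
        rng, ge, L, n_right, frag.min_contig_len, footprints, m
    )
    return tuple(ivals)


def _tile(rng, start, end, n, min_len, footprints=(), margin=0):
    span = end - start
    if n * min_len > span:
        raise ValueError("contigs too short to tile the transcript side")
    if n == 1:
        return [(start, end)]

    def clear(c: int) -> bool:
        return all(c + margin <= s or e + margin <= c for s, e in footprints)

    for _ in range(500):
        cuts = sorted(int(c) for c in rng.integers(start + min_len, end - min_len, n - 1))
        bounds = [start] + cuts + [end]
        if all(b - a >= min_len for a, b in zip(bounds, bounds[1:])) and all(
            clear(c) for c in cuts
        ):
            return list(zip(bounds, bounds[1:]))
    # deterministic fallback: even tiling, cuts nudged off event footprints
    bounds = [start + round(i * span / n) for i in range(n + 1)]
    for i in range(1, n):
        for delta in range(0, span, 10):
            for c in (bounds[i] + delta, bounds[i] - delta):
                if start + min_len <= c <= end - min_len and clear(c):
                    bounds[i] = c
                    break
            else:
                continue
            break
    bounds = sorted(set(bounds))
    return list(zip(bounds, bounds[1:]))


# ---------------------------------------------------------------------------
# Reads

def simulate_reads(
    transcript: str,
    *,
    read_len: int = 100,
    coverage: float = 20.0,
    error_rate: float = 0.0,
    insert_range: tuple[int, int] = (200, 300),
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    prefix: str = "read",
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Paired-end reads at uniform positions; returns (R1, R2) records.

    With error_rate 0 every read is an exact substring of the transcript or
    its reverse complement.  The expected read count is coverage * L / read_len.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    L = len(transcript)
    if read_len >= L:
        raise ValueError("read_len must be shorter than the transcript")
    if rng is None:
        rng = np.random.default_rng(seed if seed is not None else 0)
    n_pairs = max(1, round(coverage * L / (2 * read_len)))
    lo = min(insert_range[0], L)
    hi = min(insert_range[1], L)
    r1, r2 = [], []
    for i in range(n_pairs):
        frag_len = int(rng.integers(max(read_len, lo), hi + 1)) if hi > lo else hi
        frag_len = max(frag_len, read_len)
        start = int(rng.integers(0, L - frag_len + 1))
        frag = transcript[start : start + frag_len]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        a = _with_errors(rng, frag[:read_len], error_rate)
        b = _with_errors(rng, revcomp(frag[-read_len:]), error_rate)
        r1.append(SequenceRecord(f"{prefix}{i}/1", a))
        r2.append(SequenceRecord(f"{prefix}{i}/2", b))
    return r1, r2


def _with_errors(rng, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    out = list(seq)
    for p in np.nonzero(rng.random(len(seq)) < error_rate)[0]:
        alts = [b for b in _BASES if b != out[p]]
        out[p] = alts[int(rng.integers(0, 3))]
    return "".join(out)


def tile_reads(transcript: str, read_len: int, stride: int = 1) -> list[str]:
    """Deterministic dense tiling reads (forward strand), for controlled
    gap-fill geometry experiments."""
    return [
        transcript[i : i + read_len]
        for i in range(0, len(transcript) - read_len + 1, stride)
    ]


# ---------------------------------------------------------------------------
# Counts

def _archetype_patterns(n_clusters: int, n_tissues: int) -> list[set[int]]:
    """Distinct 'on'-tissue subsets, one per archetype."""
    patterns: list[set[int]] = []
    for c in range(n_clusters):
        if c < n_tissues:
            patterns.append({c})
        else:
            j = c - n_tissues
            patterns.append({(2 * j) % n_tissues, (2 * j + 1) % n_tissues})
    return patterns


def simulate_counts(
    design: CountDesign,
    *,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
):
    """Counts ~ NB around archetype means; outliers are label permutations.

    Outlier libraries are produced by permuting a clean library's gene
    labels, which preserves the library's count distribution while
    destroying its correlation with the replicate group.
    """
    from .expression import CountMatrix

    if design.replicates < 2:
        raise ValueError("need >= 2 replicates per tissue")
    if design.n_clusters < 2:
        raise ValueError("need >= 2 archetypes")
    if design.dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed if seed is not None else 0)

    libs = design.libraries()
    for ol in design.outlier_libraries:
        if ol not in libs:
            raise ValueError(f"outlier library {ol!r} not in the design")
    T, G = len(design.tissues), design.n_genes
    labels = np.arange(G) % design.n_clusters
    patterns = _archetype_patterns(design.n_clusters, T)
    gene_factor = np.exp(rng.normal(0.0, 0.6, G))
    mean_tissue = np.empty((G, T))
    for t in range(T):
        on = np.array([t in patterns[c] for c in labels])
        mean_tissue[:, t] = design.base_mean * np.where(on, design.fold, 1.0)
    mean_tissue *= gene_factor[:, None]

    counts = np.empty((G, len(libs)), dtype=int)
    for j, lib in enumerate(libs):
        t = design.tissues.index(lib.rsplit("_R", 1)[0])
        mu = mean_tissue[:, t]
        if design.dispersion == 0:
            counts[:, j] = rng.poisson(mu)
        else:
            shape = 1.0 / design.dispersion
            lam = rng.gamma(shape, mu * design.dispersion)
            counts[:, j] = rng.poisson(lam)
    for ol in design.outlier_libraries:
        j = libs.index(ol)
        counts[:, j] = counts[rng.permutation(G), j]

    lengths = rng.integers(500, 3001, G)
    genes = [f"g{i:05d}" for i in range(G)]
    cm = CountMatrix(genes=genes, libraries=libs, counts=counts,
                     lengths=lengths.astype(float))
    truth = CountsTruth(
        cluster_labels=labels,
        outlier_libraries=tuple(design.outlier_libraries),
        library_tissue={lib: lib.rsplit("_R", 1)[0] for lib in libs},
    )
    return cm, truth


# ---------------------------------------------------------------------------
# Convenience: derive per-purpose child RNGs from one seed

def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Stable per-stage RNG derived from a global seed and a stage name."""
    import hashlib

    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return np.random.default_rng(int.from_bytes(h[:4], "big") % (2**31))
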