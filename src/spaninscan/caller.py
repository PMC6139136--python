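"""Spanin search orchestration: pair candidates, classify architecture, report.

The search protocol per genome is:

1. enumerate ORFs in all six frames (annotation is used for labelling only --
   the exhaustive scan is strictly more sensitive than an annotated-CDS pass,
   because embedded/overlapped o-spanin genes are usually not annotated);
2. refine start sites within each stop-sharing ORF group against the
   membrane-signal validator and Shine-Dalgarno evidence;
3. type each chosen candidate by membrane topology;
4. call u-spanins directly; pair i-candidates with o-candidates (nearest
   same-strand upstream i within ``max_gap``, greedy by gap);
5. classify the genetic architecture of each pair (embedded / overlapped /
   separated), its reading-frame offset (+1/-1), and the position of the
   o-gene relative to the i-gene in units of L (the i-gene length).

All base-pair arithmetic for minus-strand systems is done in
reading-direction coordinates after reflection.  Gene intervals here include
the stop codon, matching the GenBank convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .genome_io import (
    DEFAULT_START_CODONS,
    GenomeRecord,
    OrfCandidate,
    refine_start,
    scan_orfs,
)
from .topology import (
    I_CAND,
    NONE,
    O_CAND,
    U_CAND,
    TopologyCall,
    TopologyParams,
    classify_topology,
    find_lipobox,
    periplasmic_domain,
)

log = logging.getLogger(__name__)

EMBEDDED = "embedded"
OVERLAPPED = "overlapped"
SEPARATED = "separated"
UNIMOLECULAR = "unimolecular"

#: genome size above which the all-frame lipoprotein scan refuses to run
ALL_FRAME_SCAN_LIMIT = 50_000


class OrientationError(ValueError):
    """The o-gene lies entirely upstream of the i-gene."""


class SameFrameError(ValueError):
    """Overlapping genes share a reading frame (not a distinct overlapped gene)."""


@dataclass
class CallerConfig:
    """Search configuration; defaults encode the protocol's calibration.

    ``sep_threshold``: overlaps of at most this many bp still count as
    'separated' (an 8-bp terminal overlap is a start/stop idiom, not a shared
    coding region; a 70-bp overlap is genuinely 'overlapped').  ``max_gap``:
    the largest i-to-o separation searched, from the most extreme separated
    system known (~1 kb).
    """

    min_aa: int = 40
    start_codons: tuple[str, ...] = DEFAULT_START_CODONS
    sep_threshold: int = 10
    max_gap: int = 1000
    topology: TopologyParams = field(default_factory=TopologyParams)


@dataclass
class SpaninComponent:
    """One called spanin protein with its evidence."""

    role: str  # 'i', 'o', or 'u'
    orf: OrfCandidate
    topology: TopologyCall
    periplasmic_seq: str

    def __post_init__(self) -> None:
        expected = {"i": I_CAND, "o": O_CAND, "u": U_CAND}[self.role]
        if self.topology.type != expected:
            raise ValueError(
                f"role {self.role} inconsistent with topology {self.topology.type}"
            )

    @property
    def gene_interval(self) -> tuple[int, int]:
        return (self.orf.gene_start, self.orf.gene_end)


@dataclass
class SpaninSystem:
    """A called i+o pair or a u-spanin, with architecture metrics."""

    i: SpaninComponent | None = None
    o: SpaninComponent | None = None
    u: SpaninComponent | None = None
    architecture: str = ""
    overlap_bp: int = 0
    gap_bp: int = 0
    frame_offset: str = "n/a"  # '+1', '-1', or 'n/a'
    rel_start_frac: float | None = None
    rel_end_frac: float | None = None
    confidence: str = "high"

    def __post_init__(self) -> None:
        two = self.i is not None and self.o is not None
        uni = self.u is not None
        if two == uni:
            raise ValueError("exactly one of {(i and o), u} must be populated")


@dataclass
class SearchReport:
    """Per-genome search outcome, including the negative verdict."""

    genome_id: str
    systems: list[SpaninSystem] = field(default_factory=list)
    lipoproteins_without_partner: list[SpaninComponent] = field(default_factory=list)

    @property
    def verdict(self) -> str:
        return "spanins_found" if self.systems else "no_spanins"


def classify_architecture(
    i_interval: tuple[int, int],
    o_interval: tuple[int, int],
    sep_threshold: int = 10,
) -> tuple[str, int, int]:
    """Label the genetic architecture of an i/o gene pair.

    Intervals are bp half-open in reading-direction coordinates, i upstream.
    Returns ``(label, overlap_bp, gap_bp)``; ``gap_bp`` is 0 whenever the
    genes touch or overlap.
    """
    (i_s, i_e), (o_s, o_e) = i_interval, o_interval
    if o_e <= i_s:
        raise OrientationError("o-gene entirely upstream of i-gene")
    overlap = max(0, min(i_e, o_e) - max(i_s, o_s))
    if i_s <= o_s and o_e <= i_e:
        return EMBEDDED, o_e - o_s, 0
    if overlap > sep_threshold:
        return OVERLAPPED, overlap, 0
    gap = max(0, o_s - i_e)
    return SEPARATED, overlap, gap


def frame_offset(i_start: int, o_start: int) -> str:
    """Reading-frame of the o-gene relative to the i-gene: '+1' or '-1'."""
    d = (o_start - i_start) % 3
    if d == 1:
        return "+1"
    if d == 2:
        return "-1"
    raise SameFrameError(
        "overlapping genes share a frame; a same-frame nested start is not a "
        "distinct overlapping gene"
    )


def relative_position(
    i_interval: tuple[int, int], o_interval: tuple[int, int]
) -> tuple[float, float]:
    """Start/end of the o-gene in units of L (i-gene length in bp)."""
    (i_s, i_e), (o_s, o_e) = i_interval, o_interval
    L = i_e - i_s
    return (o_s - i_s) / L, (o_e - i_s) / L


def _reading_interval(comp: SpaninComponent, genome_len: int) -> tuple[int, int]:
    s, e = comp.gene_interval
    if comp.orf.strand == "+":
        return s, e
    return genome_len - e, genome_len - s


def pair_components(
    i_cands: Sequence[SpaninComponent],
    o_cands: Sequence[SpaninComponent],
    genome_len: int,
    max_gap: int = 1000,
) -> tuple[list[tuple[SpaninComponent, SpaninComponent, bool]], list[SpaninComponent]]:
    """Greedy nearest pairing of o-candidates with upstream i-candidates.

    Each o pairs with the nearest same-strand i for which the o-start is not
    upstream of the i-start and the gap is within ``max_gap`` (or the genes
    overlap).  Pairs are taken greedily by ascending gap, ties by ascending
    o-start; exact distance ties between two i's are flagged ambiguous.
    Returns ``(pairings, unpaired_o)``.
    """
    proposals = []  # (gap, o_start, i_idx, o_idx)
    for oi, o in enumerate(o_cands):
        o_iv = _reading_interval(o, genome_len)
        for ii, i in enumerate(i_cands):
            if i.orf.strand != o.orf.strand:
                continue
            i_iv = _reading_interval(i, genome_len)
            if o_iv[0] < i_iv[0]:
                continue
            overlap = max(0, min(i_iv[1], o_iv[1]) - max(i_iv[0], o_iv[0]))
            gap = 0 if overlap > 0 else o_iv[0] - i_iv[1]
            if gap > max_gap:
                continue
            proposals.append((gap, o_iv[0], ii, oi))
    proposals.sort()
    used_i: set[int] = set()
    used_o: set[int] = set()
    pairs: list[tuple[SpaninComponent, SpaninComponent, bool]] = []
    for gap, o_start, ii, oi in proposals:
        if oi in used_o or ii in used_i:
            continue
        ambiguous = any(
            g == gap and o2 == oi and i2 != ii and i2 not in used_i
            for g, _, i2, o2 in proposals
        )
        if ambiguous:
            # tie: keep the upstream-nearest i by reading-direction start
            tied = [
                i2
                for g, _, i2, o2 in proposals
                if g == gap and o2 == oi and i2 not in used_i
            ]
            ii = max(
                tied,
                key=lambda k: _reading_interval(i_cands[k], genome_len)[0],
            )
        used_i.add(ii)
        used_o.add(oi)
        pairs.append((i_cands[ii], o_cands[oi], ambiguous))
    unpaired = [o for oi, o in enumerate(o_cands) if oi not in used_o]
    return pairs, unpaired


def _select_candidates(
    genome: GenomeRecord, config: CallerConfig
) -> list[tuple[OrfCandidate, TopologyCall]]:
    """Scan, group by stop, refine starts, and type each retained candidate."""
    cands = scan_orfs(genome, min_aa=config.min_aa, start_codons=config.start_codons)
    groups: dict[tuple, list[OrfCandidate]] = {}
    for c in cands:
        # candidates share a stop iff they share strand, frame, and 3' end
        key = (c.strand, c.frame, c.end if c.strand == "+" else c.start)
        groups.setdefault(key, []).append(c)

    def validator(aa: str) -> bool:
        return classify_topology(aa, config.topology).type != NONE

    chosen: list[tuple[OrfCandidate, TopologyCall]] = []
    for group in groups.values():
        best = refine_start(group[0], group[1:], validator)
        call = classify_topology(best.aa_seq, config.topology)
        if call.type != NONE:
            chosen.append((best, call))
    return chosen


def call_spanins(genome: GenomeRecord, config: CallerConfig | None = None) -> SearchReport:
    """Run the full spanin search protocol on one genome."""
    config = config or CallerConfig()
    chosen = _select_candidates(genome, config)
    comps = {I_CAND: [], O_CAND: [], U_CAND: []}
    for orf, call in chosen:
        _, peri = periplasmic_domain(call, orf.aa_seq)
        role = {I_CAND: "i", O_CAND: "o", U_CAND: "u"}[call.type]
        comps[call.type].append(
            SpaninComponent(role=role, orf=orf, topology=call, periplasmic_seq=peri)
        )
    report = SearchReport(genome_id=genome.id)
    for u in comps[U_CAND]:
        report.systems.append(
            SpaninSystem(
                u=u,
                architecture=UNIMOLECULAR,
                confidence="low" if u.orf.low_confidence else "high",
            )
        )
    pairs, unpaired = pair_components(
        comps[I_CAND], comps[O_CAND], genome.length, config.max_gap
    )
    for i, o, ambiguous in pairs:
        i_iv = _reading_interval(i, genome.length)
        o_iv = _reading_interval(o, genome.length)
        label, overlap, gap = classify_architecture(i_iv, o_iv, config.sep_threshold)
        try:
            off = frame_offset(i_iv[0], o_iv[0]) if overlap > 0 else "n/a"
        except SameFrameError:
            log.warning(
                "%s: same-frame overlap between i@%s and o@%s; pair dropped",
                genome.id, i_iv, o_iv,
            )
            report.lipoproteins_without_partner.append(o)
            continue
        start_f, end_f = relative_position(i_iv, o_iv)
        low = ambiguous or i.orf.low_confidence or o.orf.low_confidence
        report.systems.append(
            SpaninSystem(
                i=i, o=o, architecture=label, overlap_bp=overlap, gap_bp=gap,
                frame_offset=off, rel_start_frac=start_f, rel_end_frac=end_f,
                confidence="low" if low else "high",
            )
        )
    report.lipoproteins_without_partner.extend(unpaired)
    # deterministic output order
    report.systems.sort(
        key=lambda s: (s.u or s.i).orf.start  # type: ignore[union-attr]
    )
    return report


def all_frame_lipoprotein_scan(
    genome: GenomeRecord,
    config: CallerConfig | None = None,
    force: bool = False,
) -> list[OrfCandidate]:
    """Find potential lipoproteins in every reading frame.

    Used to certify a 'no lipoprotein in any frame' verdict for spanin-less
    genomes.  Refuses genomes above 50 kb unless ``force`` is given, since
    exhaustive all-frame inspection is impractical above that size.
    """
    config = config or CallerConfig()
    if genome.length > ALL_FRAME_SCAN_LIMIT and not force:
        raise ValueError(
            f"genome {genome.id} is {genome.length} bp > {ALL_FRAME_SCAN_LIMIT} bp; "
            "pass force=True to scan anyway"
        )
    cands = scan_orfs(genome, min_aa=40, start_codons=config.start_codons)
    t = config.topology
    return [
        c
        for c in cands
        if find_lipobox(c.aa_seq, t.min_cys, t.max_cys, "relaxed") is not None
    ]


# ---------------------------------------------------------------------------
# SpaninDB-style tabular output

TABLE_COLUMNS = [
    "phage_name", "accession_version", "architecture", "host", "component_role",
    "gene_coordinates", "sd_sequence", "primary_structure", "periplasmic_sequence",
    "length_aa", "periplasmic_cys_count", "lipobox", "frame_offset", "overlap_bp",
    "rel_start_frac", "rel_end_frac", "confidence",
]


def _coord_string(comp: SpaninComponent) -> str:
    s, e = comp.gene_interval
    return f"{s + 1}..{e}({comp.orf.strand})"


def report_to_table(report: SearchReport, genome: GenomeRecord) -> pd.DataFrame:
    """One row per spanin component, SpaninDB column schema."""
    rows = []
    for sysno, system in enumerate(report.systems):
        for comp in (system.i, system.o, system.u):
            if comp is None:
                continue
            lipo = comp.topology.lipobox
            rows.append(
                {
                    "phage_name": genome.id,
                    "accession_version": genome.id,
                    "architecture": system.architecture,
                    "host": genome.host or "",
                    "component_role": comp.role,
                    "gene_coordinates": _coord_string(comp),
                    "sd_sequence": comp.orf.sd.motif if comp.orf.sd else "",
                    "primary_structure": comp.orf.aa_seq,
                    "periplasmic_sequence": comp.periplasmic_seq,
                    "length_aa": len(comp.orf.aa_seq),
                    "periplasmic_cys_count": comp.periplasmic_seq.count("C"),
                    "lipobox": lipo.motif if lipo and comp.role in "ou" else "",
                    "frame_offset": system.frame_offset,
                    "overlap_bp": system.overlap_bp,
                    "rel_start_frac": system.rel_start_frac,
                    "rel_end_frac": system.rel_end_frac,
                    "confidence": system.confidence,
                    "system_index": sysno,
                }
            )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS + ["system_index"])
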