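"""Genome input and exhaustive ORF enumeration.

Spanin genes are routinely mis-annotated: o-spanin genes of the embedded and
overlapped architectures sit in an alternate reading frame of the i-spanin
gene and are skipped by conventional gene callers, and many annotated CDSs
carry the wrong start codon.  Because the membrane-localization signals that
define spanins (N-terminal TMD, lipoprotein signal) are strictly N-terminal,
a wrong start is fatal to detection.  This module therefore does not trust
annotation: it reads genomes (GenBank, or FASTA with optional GFF3), then
enumerates every ORF in all six frames -- including ORFs nested inside
annotated genes -- and refines start sites against signal evidence and
Shine-Dalgarno support.

Internal coordinates are 0-based half-open on the forward strand; GenBank and
GFF3 conversions happen at the I/O boundary.  An ``OrfCandidate`` interval
covers the coding residues only (the stop codon is excluded), so translating
``sequence[start:end]`` on the candidate's strand reproduces ``aa_seq``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

DEFAULT_START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_IUPAC_AMBIGUOUS = set("RYSWKMBDHVN")
_SD_CONSENSUS = "AGGAGG"

# fraction of X residues above which an ORF is discarded (sequencing-error guard)
MAX_X_FRACTION = 0.10


class GenomeFormatError(ValueError):
    """Raised when an input file cannot be parsed in the declared format."""


@dataclass
class GeneFeature:
    """An annotated gene interval (0-based half-open, forward coordinates)."""

    start: int
    end: int
    strand: str  # '+' or '-'
    kind: str = "CDS"
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad feature interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.kind == "CDS" and (self.end - self.start) % 3 != 0:
            raise ValueError(
                f"CDS length not divisible by 3: [{self.start}, {self.end})"
            )


@dataclass
class GenomeRecord:
    """A nucleotide sequence plus annotated gene features; the search substrate."""

    id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    host: str | None = None

    def __post_init__(self) -> None:
        self.sequence = _clean_sequence(self.sequence, self.id)
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValueError(
                    f"feature [{f.start}, {f.end}) outside genome {self.id} "
                    f"of length {len(self.sequence)}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SdEvidence:
    """A Shine-Dalgarno match upstream of a start codon.

    ``spacer`` is the number of nucleotides between the 3' end of the matched
    motif and the first base of the start codon; ``score`` is the number of
    consecutive bases matched against the AGGAGG consensus.
    """

    motif: str
    spacer: int
    score: int

    def __post_init__(self) -> None:
        if not (4 <= self.spacer <= 14):
            raise ValueError(f"SD spacer {self.spacer} outside 4..14")
        if self.score < 4:
            raise ValueError(f"SD score {self.score} below minimum match length")


@dataclass(frozen=True)
class OrfCandidate:
    """A candidate coding interval in any frame/strand.

    ``start``/``end`` are forward-strand coordinates of the coding residues
    (stop codon excluded).  ``frame`` is 0-2 for the forward strand and 3-5
    for the reverse strand.  ``nested_in`` carries the label of an annotated
    CDS the candidate overlaps, if any.
    """

    start: int
    end: int
    strand: str
    frame: int
    aa_seq: str
    start_codon: str
    sd: SdEvidence | None = None
    nested_in: str | None = None
    low_confidence: bool = False

    @property
    def gene_start(self) -> int:
        """Forward-strand start of the gene including the stop codon."""
        return self.start - 3 if self.strand == "-" else self.start

    @property
    def gene_end(self) -> int:
        """Forward-strand end of the gene including the stop codon."""
        return self.end if self.strand == "-" else self.end + 3


def _clean_sequence(seq: str, record_id: str) -> str:
    out = []
    for i, ch in enumerate(seq.upper()):
        if ch in "ACGT":
            out.append(ch)
        elif ch in _IUPAC_AMBIGUOUS:
            out.append("N")
        else:
            raise GenomeFormatError(
                f"non-IUPAC character {ch!r} at position {i} in record {record_id}"
            )
    return "".join(out)


def read_genome(
    path: str | Path,
    format: str = "genbank",
    gff3: str | Path | None = None,
) -> GenomeRecord:
    """Read a genome (and annotation) into a :class:`GenomeRecord`.

    ``format`` is ``"genbank"`` or ``"fasta"``.  For FASTA an optional GFF3
    file supplies CDS features.  Spliced (``join``) CDSs are not expected in
    the phage genomes of interest and are skipped with a warning.
    """
    path = Path(path)
    if format == "genbank":
        return _read_genbank(path)
    if format == "fasta":
        rec = _read_fasta(path)
        if gff3 is not None:
            rec.features = _read_gff3(Path(gff3), rec)
        return rec
    raise GenomeFormatError(f"unknown format {format!r}")


def _read_genbank(path: Path) -> GenomeRecord:
    try:
        seqrec = next(SeqIO.parse(str(path), "genbank"))
    except (StopIteration, ValueError) as exc:
        raise GenomeFormatError(f"cannot parse {path} as GenBank: {exc}") from exc
    features: list[GeneFeature] = []
    host = None
    for feat in seqrec.features:
        if feat.type == "source":
            host = feat.qualifiers.get("host", [None])[0]
        if feat.type != "CDS":
            continue
        if len(feat.location.parts) > 1:
            warnings.warn(
                f"spliced (join) CDS at {feat.location} in {seqrec.id}: "
                "unsupported, skipped"
            )
            continue
        label = feat.qualifiers.get(
            "locus_tag", feat.qualifiers.get("gene", feat.qualifiers.get("product", [""]))
        )[0]
        try:
            features.append(
                GeneFeature(
                    start=int(feat.location.start),
                    end=int(feat.location.end),
                    strand="-" if feat.location.strand == -1 else "+",
                    kind="CDS",
                    label=label,
                )
            )
        except ValueError as exc:
            log.warning("skipping malformed CDS in %s: %s", seqrec.id, exc)
    return GenomeRecord(
        id=seqrec.id, sequence=str(seqrec.seq), features=features, host=host
    )


def _read_fasta(path: Path) -> GenomeRecord:
    try:
        seqrec = next(SeqIO.parse(str(path), "fasta"))
    except (StopIteration, ValueError) as exc:
        raise GenomeFormatError(f"cannot parse {path} as FASTA: {exc}") from exc
    return GenomeRecord(id=seqrec.id, sequence=str(seqrec.seq))


def _read_gff3(path: Path, genome: GenomeRecord) -> list[GeneFeature]:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises bare Exceptions on parse errors
        raise GenomeFormatError(f"cannot parse {path} as GFF3: {exc}") from exc
    features: list[GeneFeature] = []
    for f in db.features_of_type("CDS"):
        try:
            features.append(
                GeneFeature(
                    start=f.start - 1,  # GFF3 is 1-based inclusive
                    end=f.end,
                    strand="-" if f.strand == "-" else "+",
                    kind="CDS",
                    label=f.id or "",
                )
            )
        except ValueError as exc:
            log.warning("skipping malformed GFF3 CDS %s: %s", f.id, exc)
    return features


def _translate(nt: str) -> str:
    return str(Seq(nt).translate(table=11))


def scan_orfs(
    genome: GenomeRecord,
    min_aa: int = 40,
    start_codons: Sequence[str] = DEFAULT_START_CODONS,
    with_sd: bool = True,
) -> list[OrfCandidate]:
    """Enumerate ORF candidates in all six frames.

    Every maximal stop-to-stop frame segment on both strands yields one
    candidate per admissible start codon whose ORF is at least ``min_aa``
    codons.  Candidates overlapping annotated CDSs (in any frame) are kept
    and marked ``nested_in``.  ORFs with more than 10% unknown residues are
    dropped as likely sequencing artifacts.  Output is sorted by start.
    """
    if min_aa < 10:
        raise ValueError("min_aa must be >= 10")
    start_set = {c.upper() for c in start_codons}
    n = genome.length
    fwd = genome.sequence
    rev = str(Seq(fwd).reverse_complement())
    out: list[OrfCandidate] = []
    for strand, seq in (("+", fwd), ("-", rev)):
        for off in range(3):
            frame = off if strand == "+" else off + 3
            seg_starts: list[int] = []  # admissible start codon positions (seq coords)
            pos = off
            while pos + 3 <= n:
                codon = seq[pos : pos + 3]
                if codon in STOP_CODONS:
                    out.extend(
                        _emit(genome, strand, frame, seq, seg_starts, pos, min_aa)
                    )
                    seg_starts = []
                elif codon in start_set:
                    seg_starts.append(pos)
                pos += 3
            # trailing open segment has no stop codon: not a complete ORF
        # (candidates without a terminating stop are not emitted)
    out.sort(key=lambda c: (c.start, c.end, c.strand))
    if with_sd:
        out = [replace(c, sd=score_sd(genome, c)) for c in out]
    return out


def _emit(
    genome: GenomeRecord,
    strand: str,
    frame: int,
    seq: str,
    starts: Iterable[int],
    stop_pos: int,
    min_aa: int,
) -> list[OrfCandidate]:
    n = genome.length
    cands = []
    for s in starts:
        aa_len = (stop_pos - s) // 3
        if aa_len < min_aa:
            continue
        nt = seq[s:stop_pos]
        aa = _translate(nt)
        if aa.count("X") > MAX_X_FRACTION * len(aa):
            log.debug("dropping X-rich ORF at %d (%s)", s, genome.id)
            continue
        if strand == "+":
            start, end = s, stop_pos
        else:
            start, end = n - stop_pos, n - s
        gs, ge = (start, end + 3) if strand == "+" else (start - 3, end)
        cands.append(
            OrfCandidate(
                start=start,
                end=end,
                strand=strand,
                frame=frame,
                aa_seq=aa,
                start_codon=nt[:3],
                nested_in=_nested_label(genome, gs, ge),
            )
        )
    return cands


def _nested_label(genome: GenomeRecord, gs: int, ge: int) -> str | None:
    for f in genome.features:
        if f.kind != "CDS":
            continue
        if gs < f.end and f.start < ge and (gs, ge) != (f.start, f.end):
            return f.label or f"CDS:{f.start}-{f.end}"
    return None


def score_sd(genome: GenomeRecord, orf: OrfCandidate) -> SdEvidence | None:
    """Best ungapped >=4-base match to AGGAGG 4-14 nt upstream of the start.

    Ties break toward the longer match, then the smaller spacer.  Returns
    ``None`` when the ORF sits within 20 bp of the genome edge on its strand.
    """
    if orf.strand == "+":
        lead = orf.start
        coding = genome.sequence
        pos = orf.start  # start codon position in coding-strand coordinates
    else:
        lead = genome.length - orf.end
        coding = str(Seq(genome.sequence).reverse_complement())
        pos = genome.length - orf.end
    if lead < 20:
        return None
    best: SdEvidence | None = None
    for length in range(6, 3, -1):
        for spacer in range(4, 15):
            lo = pos - spacer - length
            if lo < 0:
                continue
            window = coding[lo : lo + length]
            for off in range(0, 7 - length):
                if window == _SD_CONSENSUS[off : off + length]:
                    cand = SdEvidence(motif=window, spacer=spacer, score=length)
                    if best is None:
                        best = cand
                    break
            if best is not None and best.score == length:
                break
        if best is not None:
            break
    return best


def refine_start(
    orf: OrfCandidate,
    siblings: Sequence[OrfCandidate],
    signal_validator: Callable[[str], bool],
) -> OrfCandidate:
    """Choose the best start among candidates sharing a stop codon.

    Among starts whose translation satisfies ``signal_validator`` (typically:
    places a membrane-localization signal at the N-terminus), the one with
    the strongest Shine-Dalgarno evidence wins, ties toward the longer ORF.
    If no start validates, the longest is returned flagged low-confidence.
    """
    group = [orf, *siblings]
    for sib in siblings:
        if (sib.strand, sib.frame) != (orf.strand, orf.frame):
            raise ValueError("siblings must share the ORF's frame segment")
    valid = [c for c in group if signal_validator(c.aa_seq)]
    if valid:
        return max(valid, key=lambda c: (c.sd.score if c.sd else -1, len(c.aa_seq)))
    longest = max(group, key=lambda c: len(c.aa_seq))
    return replace(longest, low_confidence=True)


def write_orfs_gff3(
    candidates: Sequence[OrfCandidate], genome_id: str, path: str | Path
) -> None:
    """Write ORF candidates as GFF3 CDS features with a nested_in attribute."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, c in enumerate(candidates):
            attrs = [f"ID=orf{i:05d}", f"start_codon={c.start_codon}"]
            if c.nested_in:
                attrs.append(f"nested_in={c.nested_in}")
            fh.write(
                "\t".join(
                    [
                        genome_id,
                        "spaninscan",
                        "CDS",
                        str(c.gene_start + 1),
                        str(c.gene_end),
                        ".",
                        c.strand,
                        "0",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
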