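"""Synthetic phage genomes with planted spanin systems and truth tables.

The generator emulates the gene-level anatomy the search protocol relies on:
i-spanin genes encode Met + a charged N-tail + a ~21-residue hydrophobic
block + a hydrophilic periplasmic tail with planted cysteines; o-spanin
genes encode a lipoprotein signal (charged tail, hydrophobic core, a chosen
lipobox) + a Pro/Ser-rich periplasmic tail; u-spanin genes add a C-terminal
hydrophobic block and carry no periplasmic cysteines.  Systems are planted
in all four architectures:

* *embedded* -- the o-gene is written inside the i-gene in the +1 or -1
  frame by searching synonymous-codon space so that both frames encode
  valid proteins (no i-frame stop across the shared region);
* *overlapped* -- the i-gene's stop codon is placed inside the 5' region of
  the o-gene (overlap 30-200 bp);
* *separated* -- the genes are disjoint (gap up to ~900 bp);
* *unimolecular* -- a single u-gene.

Cassettes are interleaved with decoy genes (soluble proteins, a non-spanin
membrane protein, a stray lipoprotein with no i-gene within pairing range)
and stop-rich spacers, annotation deliberately omits embedded o-genes, and
20% of annotated start codons are perturbed to exercise start refinement.
Builders re-randomize codon choices (bounded retries) until the planted
proteins classify to their intended topology type and the cassette contains
no unintended spanin-like ORF; this is construction QC, local to each
cassette -- the genome-level search is never consulted.  Output is
deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .genome_io import GeneFeature, GenomeRecord, scan_orfs, refine_start
from .caller import SearchReport, UNIMOLECULAR
from .topology import I_CAND, NONE, O_CAND, U_CAND, TopologyParams, classify_topology

log = logging.getLogger(__name__)

STOPS = ("TAA", "TAG", "TGA")

#: synonymous codons per residue (bacterial code, table 11)
CODONS: dict[str, tuple[str, ...]] = {}
_BASES = "TCAG"
_TABLE11 = {}
for _i, _b1 in enumerate(_BASES):
    for _b2 in _BASES:
        for _b3 in _BASES:
            _cod = _b1 + _b2 + _b3
            _TABLE11[_cod] = str(Seq(_cod).translate(table=11))
for _cod, _aa in _TABLE11.items():
    if _aa != "*":
        CODONS.setdefault(_aa, ())
        CODONS[_aa] += (_cod,)

_HYDRO = "LIVF"
_TAIL = "ADEGKNQRST"          # hydrophilic periplasmic alphabet (no C/P bias)
_O_TAIL = "PPSSADEGKNQRT"     # Pro/Ser-rich o-spanin tail alphabet
_SPACER_UNIT = "TTAATTAGTTAA"  # stops in all six frames together with its revcomp

DEFAULT_LIPOBOX_MIX = {"LSGC": 0.6, "LAGC": 0.2, "AWAC": 0.2}

# per-component planted-cysteine count distributions, approximating the
# observed census (most common combination: 0 in i, 2 in o; ~4% fully Cys-free)
_I_CYS_W = {0: 0.32, 1: 0.31, 2: 0.34, 3: 0.02, 4: 0.01}
_O_CYS_W = {0: 0.24, 1: 0.22, 2: 0.46, 3: 0.07, 4: 0.01}


@dataclass
class SimSpec:
    """How many systems of each architecture to plant, and with what signals."""

    n_embedded: int = 1
    n_overlapped: int = 1
    n_separated: int = 1
    n_unimolecular: int = 1
    n_decoys: int = 5
    frame_mix: float = 0.5          # fraction of +1 among overlapping systems
    lipobox_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LIPOBOX_MIX))
    minus_strand_frac: float = 0.3
    start_perturb_frac: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for n in (self.n_embedded, self.n_overlapped, self.n_separated,
                  self.n_unimolecular, self.n_decoys):
            if n < 0:
                raise ValueError("counts must be non-negative")
        total = sum(self.lipobox_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("lipobox_mix weights must sum to 1")
        for motif in self.lipobox_mix:
            if len(motif) != 4 or motif[3] != "C":
                raise ValueError(f"lipobox motif {motif!r} must be 4 residues ending in C")


@dataclass
class TruthRecord:
    """Ground truth for one planted system (forward coordinates, stop included)."""

    system_id: str
    architecture: str
    strand: str
    frame_offset: str  # '+1', '-1', or 'n/a'
    lipobox: str
    coords: dict[str, tuple[int, int]]   # role -> (start, end) forward bp
    proteins: dict[str, str]             # role -> translated protein
    cys_counts: dict[str, int]           # role -> realized periplasmic Cys count
    periplasmic_lengths: dict[str, int]


class SimulationError(RuntimeError):
    pass


def _enc(protein: str, rng: np.random.Generator) -> str:
    return "".join(
        CODONS[aa][rng.integers(len(CODONS[aa]))] for aa in protein
    )


def _weighted(rng: np.random.Generator, weights: dict) -> object:
    keys = list(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def _spacer(rng: np.random.Generator, n: int) -> str:
    parts = []
    while sum(len(p) for p in parts) < n:
        rand6 = "".join("ACGT"[rng.integers(4)] for _ in range(6))
        parts.append(rand6 + _SPACER_UNIT)
    return "".join(parts)[:n]


def _sd_leader(rng: np.random.Generator, spacer: int = 7) -> str:
    return "AGGAGG" + "".join("AC"[rng.integers(2)] for _ in range(spacer))


# ---------------------------------------------------------------------------
# protein designs


def _i_head(rng: np.random.Generator) -> str:
    charged = "KR"[rng.integers(2)] + "".join(
        "KRNST"[rng.integers(5)] for _ in range(2)
    )
    hydro = "".join(_HYDRO[rng.integers(len(_HYDRO))] for _ in range(21))
    return "M" + charged + hydro


def _hydrophilic_tail(rng: np.random.Generator, n: int, cys: int,
                      alphabet: str = _TAIL, first_cys_at: int = 2) -> str:
    tail = [alphabet[rng.integers(len(alphabet))] for _ in range(n)]
    if cys > n - first_cys_at - 2:
        raise SimulationError("infeasible cysteine plan: more Cys than tail length")
    positions = rng.choice(
        np.arange(first_cys_at, n - 1), size=cys, replace=False
    ) if cys else []
    for p in positions:
        tail[int(p)] = "C"
    return "".join(tail)


def _o_signal(rng: np.random.Generator, lipobox: str) -> str:
    # the charged residue is Arg: Lys at position 2 cannot be reconciled with
    # a -1-frame host gene (ATG + AA[AG] always completes a TGA in that frame)
    polar = "".join("KRNQST"[rng.integers(6)] for _ in range(2))
    hydro = "".join("LIVFA"[rng.integers(5)] for _ in range(9))
    return "M" + "R" + polar + hydro + lipobox


def make_spanin_gene(
    role: str,
    rng: np.random.Generator,
    lipobox: str = "LSGC",
    cys: int = 0,
    tail_len: int | None = None,
) -> tuple[str, dict]:
    """Build one standalone spanin gene (nt including stop) plus design info.

    Codons are drawn uniformly among synonyms.  The builder retries codon
    randomization until the translated protein classifies to the intended
    topology type.
    """
    for _ in range(60):
        if role == "i":
            n = int(tail_len if tail_len is not None else rng.integers(55, 100))
            protein = _i_head(rng) + _hydrophilic_tail(rng, n, cys, first_cys_at=18)
            want = I_CAND
        elif role == "o":
            n = int(tail_len if tail_len is not None else rng.integers(42, 68))
            if n < 3:
                raise SimulationError("o-spanin periplasmic tail too short")
            protein = _o_signal(rng, lipobox) + _hydrophilic_tail(rng, n, cys, _O_TAIL)
            want = O_CAND
        elif role == "u":
            n = int(tail_len if tail_len is not None else rng.integers(55, 90))
            tmd = "".join(_HYDRO[rng.integers(len(_HYDRO))] for _ in range(21))
            protein = _o_signal(rng, lipobox) + _hydrophilic_tail(rng, n, 0) + tmd
            want = U_CAND
        else:
            raise ValueError(f"unknown role {role!r}")
        call = classify_topology(protein)
        if call.type == want:
            nt = _enc(protein, rng) + STOPS[rng.integers(3)]
            return nt, {"protein": protein, "call": call}
    raise SimulationError(f"could not realize a valid {role} gene")


# ---------------------------------------------------------------------------
# dual-frame construction helpers

def _iframe_codons(prefix: str, nt: str) -> list[str]:
    """Complete i-frame codons of ``prefix + nt`` (prefix = carried-over bases)."""
    t = prefix + nt
    return [t[k : k + 3] for k in range(0, len(t) - len(t) % 3, 3)]


def _encode_no_iframe_stop(
    protein: str, pending: str, rng: np.random.Generator, with_stop: bool = True
) -> tuple[str, str] | None:
    """Encode ``protein`` choosing synonyms so the shifted i-frame has no stop.

    ``pending`` carries the 0-2 nt of the current (incomplete) i-frame codon.
    Returns ``(nt, new_pending)`` or ``None`` when stuck.
    """
    targets = list(protein) + (["*"] if with_stop else [])
    # depth-first search over synonymous-codon space with a node budget;
    # backtracking matters because e.g. a pending 'TG' blocks every Lys codon
    orders = []
    for aa in targets:
        options = list(STOPS) if aa == "*" else list(CODONS[aa])
        orders.append([options[int(i)] for i in rng.permutation(len(options))])
    parts: list[str] = []
    bufs = [pending]
    tried = [0]
    budget = 4000
    while len(parts) < len(targets):
        pos = len(parts)
        found = False
        while tried[pos] < len(orders[pos]):
            cod = orders[pos][tried[pos]]
            tried[pos] += 1
            budget -= 1
            if budget <= 0:
                return None
            t = bufs[pos] + cod
            cut = len(t) - len(t) % 3
            if any(c in STOPS for c in (t[k : k + 3] for k in range(0, cut, 3))):
                continue
            parts.append(cod)
            bufs.append(t[cut:])
            tried.append(0)
            found = True
            break
        if not found:
            if not parts:
                return None
            parts.pop()
            bufs.pop()
            tried.pop()
    return "".join(parts), bufs[-1]


def _pre_region(
    rng: np.random.Generator,
    d: int,
    n_fill: int,
    cys: int,
    next_nt: str,
) -> tuple[str, str] | None:
    """Build the i-gene tail segment preceding an alternate-frame o-start.

    The segment consists of hydrophilic filler codons (with the system's
    planted i-cysteines), an AGGAGG Shine-Dalgarno for the o-gene, and a
    spacer sized so that the o-start lands in frame offset ``d`` (1 or 2).
    Returns ``(nt, fill_protein)``; the caller re-tries on ``None``.
    """
    # planted Cys start at fill position 16 so they land past residue 40 of
    # the i-protein (outside the lipobox Cys window)
    fill = _hydrophilic_tail(rng, n_fill, cys, first_cys_at=16)
    fill_nt = _enc(fill, rng)
    spacer_opts = [s for s in range(4, 15) if (6 + s) % 3 == d]
    s = int(spacer_opts[rng.integers(len(spacer_opts))])
    for _ in range(20):
        spacer_nt = "".join("AC"[rng.integers(2)] for _ in range(s))
        nt = fill_nt + "AGGAGG" + spacer_nt
        # i-frame check across the whole segment plus the junction into the o-gene
        codons = _iframe_codons("", nt + next_nt[: 3 - d])
        if not any(c in STOPS for c in codons):
            return nt, fill
    return None


def _embedded_gene_pair(
    rng: np.random.Generator, d: int, lipobox: str, i_cys: int, o_cys: int
) -> tuple[str, int, int, dict] | None:
    """i-gene nt with an o-gene written inside it in frame offset ``d``.

    Returns ``(i_nt, o_off, o_len, info)`` with o coordinates relative to the
    i-gene start, or ``None`` when codon-space reconciliation failed.
    """
    head = _i_head(rng)
    head_nt = _enc(head, rng)
    o_tail_n = int(rng.integers(42, 60))
    o_prot = _o_signal(rng, lipobox) + _hydrophilic_tail(rng, o_tail_n, o_cys, _O_TAIL)
    n_fill = int(rng.integers(24, 34))
    pre = _pre_region(rng, d, n_fill, i_cys, "ATG")
    if pre is None:
        return None
    pre_nt, _ = pre
    enc = _encode_no_iframe_stop(o_prot, pre_nt[-d:], rng)
    if enc is None:
        return None
    o_nt, buf = enc
    if not o_nt.startswith("ATG"):  # M encodes uniquely; defensive
        return None
    # pad to complete the current i-frame codon, avoiding stops
    pad = ""
    if buf:
        for _ in range(12):
            cand = "".join("ACGT"[rng.integers(4)] for _ in range(3 - len(buf)))
            if (buf + cand) not in STOPS:
                pad = cand
                break
        else:
            return None
    tail_b = _hydrophilic_tail(rng, int(rng.integers(4, 10)), 0)
    i_nt = head_nt + pre_nt + o_nt + pad + _enc(tail_b, rng) + STOPS[rng.integers(3)]
    o_off = len(head_nt) + len(pre_nt)
    assert (o_off % 3) == d and len(i_nt) % 3 == 0
    return i_nt, o_off, len(o_nt), {"o_protein": o_prot}


def _overlapped_gene_pair(
    rng: np.random.Generator, d: int, lipobox: str, i_cys: int, o_cys: int
) -> tuple[str, str, int, dict] | None:
    """i-gene and o-gene sharing 30-200 bp: the i-stop sits inside the o-gene.

    Returns ``(i_nt, o_nt, overlap_bp, info)``; the o-gene begins at
    ``len(i_nt) - overlap_bp`` relative to the i start.
    """
    head = _i_head(rng)
    head_nt = _enc(head, rng)
    o_tail_n = int(rng.integers(42, 68))
    o_prot = _o_signal(rng, lipobox) + _hydrophilic_tail(rng, o_tail_n, o_cys, _O_TAIL)
    n_fill = int(rng.integers(24, 32))
    pre = _pre_region(rng, d, n_fill, i_cys, "ATG")
    if pre is None:
        return None
    pre_nt, _ = pre
    o_nt = _enc(o_prot, rng) + STOPS[rng.integers(3)]
    codons = _iframe_codons(pre_nt[-d:], o_nt)
    stop_at = next((k for k, c in enumerate(codons) if c in STOPS), None)
    if stop_at is None:
        return None
    ov = 3 * stop_at + 3 - d  # bp of o 5' region inside the i-gene
    if not (30 <= ov <= 200) or ov > len(o_nt) - 30:
        return None
    i_nt = head_nt + pre_nt + o_nt[:ov]
    assert len(i_nt) % 3 == 0
    return i_nt, o_nt, ov, {"o_protein": o_prot}


# ---------------------------------------------------------------------------
# cassette assembly

def _translate_fwd(nt: str) -> str:
    aa = str(Seq(nt).translate(table=11))
    return aa[:-1] if aa.endswith("*") else aa


def _cassette_clean(seq: str, planted: list[tuple[int, int]]) -> bool:
    """Every spanin-like ORF in the cassette is one of the planted genes.

    The cassette is scanned with stop-rich flanks so ORFs running off its
    edges are closed; a candidate is acceptable only when it reciprocally
    matches (>=90%) a planted plus-strand gene -- antisense shadows of
    planted genes count as contamination and trigger a rebuild.
    """
    pad = _SPACER_UNIT * 3
    genome = GenomeRecord(id="cassette", sequence=pad + seq + pad)
    off = len(pad)
    groups: dict[tuple, list] = {}
    for c in scan_orfs(genome, min_aa=40, with_sd=False):
        key = (c.strand, c.frame, c.end if c.strand == "+" else c.start)
        groups.setdefault(key, []).append(c)
    params = TopologyParams()
    for group in groups.values():
        best = refine_start(
            group[0], group[1:], lambda aa: classify_topology(aa, params).type != NONE
        )
        if classify_topology(best.aa_seq, params).type == NONE:
            continue
        iv = (best.gene_start - off, best.gene_end - off)
        if best.strand != "+" or not any(
            _reciprocal(iv, p) >= 0.9 for p in planted
        ):
            return False
    return True


def _build_cassette(
    kind: str, rng: np.random.Generator, spec: SimSpec, sysno: int
) -> tuple[str, dict[str, tuple[int, int]], dict[str, str], str, str]:
    """One plus-strand cassette: (seq, role->local coords, role->protein, frame, lipobox)."""
    lipobox = str(_weighted(rng, spec.lipobox_mix))
    i_cys = int(_weighted(rng, _I_CYS_W))
    o_cys = int(_weighted(rng, _O_CYS_W))
    d = 1 if rng.random() < spec.frame_mix else 2
    frame = {1: "+1", 2: "-1"}[d]
    lead = _sd_leader(rng)
    for _ in range(400):
        if kind == "embedded":
            built = _embedded_gene_pair(rng, d, lipobox, i_cys, o_cys)
            if built is None:
                continue
            i_nt, o_off, o_len, _info = built
            seq = lead + i_nt
            coords = {
                "i": (len(lead), len(lead) + len(i_nt)),
                "o": (len(lead) + o_off, len(lead) + o_off + o_len),
            }
        elif kind == "overlapped":
            built = _overlapped_gene_pair(rng, d, lipobox, i_cys, o_cys)
            if built is None:
                continue
            i_nt, o_nt, ov, _info = built
            seq = lead + i_nt + o_nt[ov:]
            coords = {
                "i": (len(lead), len(lead) + len(i_nt)),
                "o": (len(lead) + len(i_nt) - ov, len(lead) + len(i_nt) - ov + len(o_nt)),
            }
        elif kind == "separated":
            i_nt, _ = make_spanin_gene("i", rng, cys=i_cys)
            gap = int(rng.integers(17, 900))
            gap_nt = _spacer(rng, gap - 13) + _sd_leader(rng)
            o_nt, _ = make_spanin_gene("o", rng, lipobox=lipobox, cys=o_cys)
            seq = lead + i_nt + gap_nt + o_nt
            coords = {
                "i": (len(lead), len(lead) + len(i_nt)),
                "o": (len(lead) + len(i_nt) + len(gap_nt),
                      len(lead) + len(i_nt) + len(gap_nt) + len(o_nt)),
            }
            frame = "n/a"
        elif kind == "unimolecular":
            u_nt, _ = make_spanin_gene("u", rng, lipobox=lipobox)
            seq = lead + u_nt
            coords = {"u": (len(lead), len(lead) + len(u_nt))}
            frame = "n/a"
        else:
            raise ValueError(kind)
        proteins = {
            role: _translate_fwd(seq[s : e]) for role, (s, e) in coords.items()
        }
        calls = {role: classify_topology(p) for role, p in proteins.items()}
        want = {"i": I_CAND, "o": O_CAND, "u": U_CAND}
        if any(calls[r].type != want[r] for r in coords):
            continue
        if not _cassette_clean(seq, list(coords.values())):
            continue
        return seq, coords, proteins, frame, lipobox
    raise SimulationError(f"could not build a clean {kind} cassette (system {sysno})")


def _decoy(rng: np.random.Generator, kind: str) -> tuple[str, str]:
    """A decoy gene cassette: (seq, label)."""
    lead = _sd_leader(rng)
    for _ in range(60):
        if kind == "soluble":
            protein = "M" + _hydrophilic_tail(rng, int(rng.integers(80, 150)), 0)
            want = NONE
        elif kind == "membrane":
            protein = _i_head(rng) + _hydrophilic_tail(rng, int(rng.integers(55, 90)), 0)
            want = I_CAND
        elif kind == "lipoprotein":
            protein = _o_signal(rng, "LSGC") + _hydrophilic_tail(
                rng, int(rng.integers(42, 60)), 0, _O_TAIL
            )
            want = O_CAND
        else:
            raise ValueError(kind)
        if classify_topology(protein).type != want:
            continue
        seq = lead + _enc(protein, rng) + STOPS[rng.integers(3)]
        planted = [] if kind == "soluble" else [(len(lead), len(seq))]
        if _cassette_clean(seq, planted):
            return seq, kind
    raise SimulationError(f"could not realize decoy {kind}")


def _genome_clean(
    genome: GenomeRecord, allowed: list[tuple[int, int, str]]
) -> bool:
    """Whole-genome screen: every spanin-like candidate is a planted gene.

    Catches accidental signal-bearing ORFs that span cassette/spacer
    junctions and therefore escape the per-cassette checks.
    """
    groups: dict[tuple, list] = {}
    for c in scan_orfs(genome, min_aa=40, with_sd=False):
        key = (c.strand, c.frame, c.end if c.strand == "+" else c.start)
        groups.setdefault(key, []).append(c)
    params = TopologyParams()
    for group in groups.values():
        best = refine_start(
            group[0], group[1:], lambda aa: classify_topology(aa, params).type != NONE
        )
        if classify_topology(best.aa_seq, params).type == NONE:
            continue
        iv = (best.gene_start, best.gene_end)
        if not any(
            strand == best.strand and _reciprocal(iv, (s, e)) >= 0.9
            for s, e, strand in allowed
        ):
            return False
    return True


def simulate_genome(spec: SimSpec) -> tuple[GenomeRecord, list[TruthRecord]]:
    """Emit a genome with the requested planted systems and its truth table.

    Cassettes are separated by >=1050 bp stop-rich spacers so that no decoy
    or neighbouring system falls within pairing range (1 kb) of a planted
    o-gene.  After assembly the genome is screened as a whole: if any
    spanin-like ORF remains outside the planted genes (a junction artifact),
    the assembly is re-drawn (bounded retries).  Deterministic for a fixed
    seed.
    """
    for attempt in range(30):
        genome, truths, allowed = _assemble(spec, attempt)
        if _genome_clean(genome, allowed):
            return genome, truths
    raise SimulationError("could not assemble a junction-clean genome")


def _assemble(
    spec: SimSpec, attempt: int
) -> tuple[GenomeRecord, list[TruthRecord], list[tuple[int, int, str]]]:
    rng = np.random.default_rng([spec.seed, attempt])
    kinds = (
        ["embedded"] * spec.n_embedded
        + ["overlapped"] * spec.n_overlapped
        + ["separated"] * spec.n_separated
        + ["unimolecular"] * spec.n_unimolecular
    )
    rng.shuffle(kinds)
    decoy_kinds = ["soluble", "membrane", "lipoprotein"]
    decoys = [decoy_kinds[k % 3] for k in range(spec.n_decoys)]
    slots: list[tuple[str, str]] = [("system", k) for k in kinds] + [
        ("decoy", k) for k in decoys
    ]
    rng.shuffle(slots)

    parts: list[str] = [_spacer(rng, int(rng.integers(150, 300)))]
    pos = len(parts[0])
    truths: list[TruthRecord] = []
    features: list[GeneFeature] = []
    allowed: list[tuple[int, int, str]] = []
    sysno = 0
    for slot_kind, kind in slots:
        if slot_kind == "system":
            seq, coords, proteins, frame, lipobox = _build_cassette(
                kind, rng, spec, sysno
            )
            strand = "-" if rng.random() < spec.minus_strand_frac else "+"
            if strand == "-":
                L = len(seq)
                seq = str(Seq(seq).reverse_complement())
                coords = {r: (L - e, L - s) for r, (s, e) in coords.items()}
            abs_coords = {r: (pos + s, pos + e) for r, (s, e) in coords.items()}
            cys_counts, peri_lens = {}, {}
            for role, prot in proteins.items():
                call = classify_topology(prot)
                lo, hi = call.periplasmic
                peri = prot[lo:hi]
                cys_counts[role] = peri.count("C")
                peri_lens[role] = len(peri)
            truths.append(
                TruthRecord(
                    system_id=f"sys{sysno:03d}",
                    architecture=kind if kind != "unimolecular" else UNIMOLECULAR,
                    strand=strand,
                    frame_offset=frame,
                    lipobox=lipobox if set(proteins) != {"i"} else "",
                    coords=abs_coords,
                    proteins=proteins,
                    cys_counts=cys_counts,
                    periplasmic_lengths=peri_lens,
                )
            )
            for role, (s, e) in abs_coords.items():
                allowed.append((s, e, strand))
                if kind == "embedded" and role == "o":
                    continue  # annotation bias: embedded o-genes go unannotated
                features.append(
                    GeneFeature(start=s, end=e, strand=strand, kind="CDS",
                                label=f"sys{sysno:03d}_{role}")
                )
            sysno += 1
        else:
            seq, label = _decoy(rng, kind)
            allowed.append((pos + 13, pos + len(seq), "+"))
            features.append(
                GeneFeature(
                    start=pos + 13, end=pos + len(seq), strand="+", kind="CDS",
                    label=f"decoy_{label}_{pos}",
                )
            )
        parts.append(seq)
        pos += len(seq)
        spacer = _spacer(rng, int(rng.integers(1050, 1400)))
        parts.append(spacer)
        pos += len(spacer)
    genome_seq = "".join(parts)
    features = _perturb_starts(features, genome_seq, spec.start_perturb_frac, rng)
    genome = GenomeRecord(
        id=f"synthetic_phage_seed{spec.seed}", sequence=genome_seq, features=features
    )
    return genome, truths, allowed


def _perturb_starts(
    features: list[GeneFeature],
    seq: str,
    frac: float,
    rng: np.random.Generator,
) -> list[GeneFeature]:
    """Move ~frac of annotated starts to a downstream in-frame ATG (annotation only)."""
    out = []
    for f in features:
        if rng.random() >= frac:
            out.append(f)
            continue
        if f.strand == "+":
            body = seq[f.start : f.end]
        else:
            body = str(Seq(seq[f.start : f.end]).reverse_complement())
        shift = next(
            (k for k in range(3, min(len(body) - 60, 135), 3) if body[k : k + 3] == "ATG"),
            None,
        )
        if shift is None:
            out.append(f)
            continue
        if f.strand == "+":
            out.append(GeneFeature(f.start + shift, f.end, f.strand, f.kind, f.label))
        else:
            out.append(GeneFeature(f.start, f.end - shift, f.strand, f.kind, f.label))
    return out


# ---------------------------------------------------------------------------
# evaluation against truth

def _reciprocal(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0])) if inter else 0.0


def evaluate_calls(report: SearchReport, truth: list[TruthRecord]) -> dict[str, float]:
    """Recovery metrics of a search report against the planted truth.

    A called system matches a truth record when every shared role's gene
    interval overlaps the truth interval by >=90% reciprocally (same strand).
    """
    called = []
    for s in report.systems:
        comp = {r: c for r, c in (("i", s.i), ("o", s.o), ("u", s.u)) if c is not None}
        called.append(
            (
                s,
                {r: (c.orf.gene_start, c.orf.gene_end) for r, c in comp.items()},
                next(iter(comp.values())).orf.strand,
            )
        )
    matched_truth: set[int] = set()
    matched_pairs: list[tuple[SearchReport, TruthRecord]] = []
    n_called_matched = 0
    for s, ivs, strand in called:
        hit = None
        for ti, t in enumerate(truth):
            if ti in matched_truth or t.strand != strand:
                continue
            if set(ivs) != set(t.coords):
                continue
            if all(_reciprocal(ivs[r], t.coords[r]) >= 0.9 for r in ivs):
                hit = (ti, t)
                break
        if hit is not None:
            matched_truth.add(hit[0])
            matched_pairs.append((s, hit[1]))
            n_called_matched += 1
    recall = len(matched_truth) / len(truth) if truth else 1.0
    precision = n_called_matched / len(called) if called else 1.0
    arch_ok = [s.architecture == t.architecture for s, t in matched_pairs]
    frame_pairs = [
        (s, t) for s, t in matched_pairs if t.frame_offset in ("+1", "-1")
    ]
    frame_ok = [s.frame_offset == t.frame_offset for s, t in frame_pairs]
    return {
        "recall": recall,
        "precision": precision,
        "architecture_accuracy": (sum(arch_ok) / len(arch_ok)) if arch_ok else 1.0,
        "frame_accuracy": (sum(frame_ok) / len(frame_ok)) if frame_ok else 1.0,
    }


# ---------------------------------------------------------------------------
# serialization

def write_genbank(genome: GenomeRecord, path) -> None:
    """Write a simulated genome as a GenBank flat file with CDS features."""
    from Bio.SeqFeature import SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    rec = SeqRecord(Seq(genome.sequence), id=genome.id, name="synthetic",
                    description="synthetic phage genome with planted spanin systems")
    rec.annotations["molecule_type"] = "DNA"
    for f in genome.features:
        rec.features.append(
            SeqFeature(
                SimpleLocation(f.start, f.end, strand=-1 if f.strand == "-" else 1),
                type="CDS",
                qualifiers={"locus_tag": [f.label]},
            )
        )
    SeqIO.write(rec, str(path), "genbank")


def write_truth_tsv(truths: list[TruthRecord], path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            ["system_id", "architecture", "strand", "frame_offset", "lipobox",
             "role", "start", "end", "cys_count", "periplasmic_length"]
        )
        for t in truths:
            for role, (s, e) in sorted(t.coords.items()):
                w.writerow(
                    [t.system_id, t.architecture, t.strand, t.frame_offset,
                     t.lipobox, role, s + 1, e, t.cys_counts[role],
                     t.periplasmic_lengths[role]]
                )
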