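"""Membrane-topology typing of spanin candidates.

Spanins come in three topological flavours, each defined by N- or C-terminal
membrane-localization signals:

* **i-spanin** -- class II (N-in, C-out) inner-membrane protein: a single
  N-terminal transmembrane domain (TMD), everything downstream periplasmic.
* **o-spanin** -- outer-membrane lipoprotein: an N-terminal lipoprotein
  signal ending in a lipobox whose Cys is lipoylated and anchored in the OM;
  the mature periplasmic domain begins after the Cys.
* **u-spanin** -- unimolecular spanin: a lipoprotein signal *and* a
  C-terminal TMD, spanning the whole periplasm by itself.

TMDs are detected with a Kyte-Doolittle sliding-window hydropathy scan (a
self-contained stand-in for an HMM-based predictor; externally computed
intervals can be supplied through :func:`read_override_table`).  Lipoboxes
are matched against the consensus ``[LVI][ASTVI][GAS]C`` in strict mode; the
relaxed mode additionally admits the deviant motifs observed in real
o-/u-spanins (AWAC, LNGC, FVGC, ...), while still requiring the surrounding
signal-peptide anatomy (early K/R, a hydrophobic stretch before the lipobox).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

#: Kyte-Doolittle hydropathy index.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

STRICT_LIPOBOX_P1 = set("LVI")
STRICT_LIPOBOX_P2 = set("ASTVI")
STRICT_LIPOBOX_P3 = set("GAS")
# Relaxed per-position alphabet: the strict sets plus the residues seen in
# deviant but functional lipoboxes (AWAC, LNGC, FVGC ...).
RELAXED_LIPOBOX_SET = set("ALVIFGSTWMN")

# residues counted as hydrophobic when looking for the signal-peptide h-region
_H_REGION = set("ACFGILMVWST")

I_CAND = "I_CAND"
O_CAND = "O_CAND"
U_CAND = "U_CAND"
NONE = "NONE"


@dataclass(frozen=True)
class TmdInterval:
    """A transmembrane domain: 0-based half-open residue interval."""

    start: int
    end: int
    mean_hydropathy: float

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class LipoboxHit:
    """A lipobox match: ``cys_index`` is the 0-based index of the lipoylated Cys."""

    cys_index: int
    motif: str
    mode: str  # 'strict' or 'relaxed'


@dataclass
class TopologyParams:
    """Tunable knobs of the topology classifier.

    The eligibility gate is deliberately parameterised: the window/threshold
    pair controls TMD calling, the Cys window brackets plausible lipoprotein
    signal lengths, and the length gate brackets observed spanins (Rz1 at
    60 aa up to ~300-residue systems).
    """

    window: int = 19
    threshold: float = 1.6
    min_tmd: int = 15
    max_tmd: int = 30
    merge_gap: int = 3
    min_cys: int = 12   # 1-based residue bounds for the lipobox Cys
    max_cys: int = 40
    lipobox_mode: str = "relaxed"
    min_len: int = 40
    max_len: int = 350


@dataclass
class TopologyCall:
    """The typing verdict with its membrane-signal evidence."""

    type: str
    tmds: list[TmdInterval] = field(default_factory=list)
    lipobox: LipoboxHit | None = None
    periplasmic: tuple[int, int] | None = None
    evidence: str = ""


def hydropathy_profile(aa_seq: str, window: int = 19) -> np.ndarray:
    """Per-position mean Kyte-Doolittle index over a centred window.

    Termini are padded by truncated windows (the mean over the residues the
    window actually covers).  Unknown residues contribute 0.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    if len(aa_seq) < window:
        raise ValueError("sequence shorter than window")
    vals = np.empty(len(aa_seq))
    for i, ch in enumerate(aa_seq):
        if ch in KYTE_DOOLITTLE:
            vals[i] = KYTE_DOOLITTLE[ch]
        else:
            log.debug("unknown residue %r treated as hydropathy 0", ch)
            vals[i] = 0.0
    kernel = np.ones(window)
    sums = np.convolve(vals, kernel, mode="same")
    counts = np.convolve(np.ones_like(vals), kernel, mode="same")
    return sums / counts


def find_tmds(aa_seq: str, params: TopologyParams | None = None) -> list[TmdInterval]:
    """Maximal runs of window-mean hydropathy above threshold.

    Runs separated by fewer than ``merge_gap`` positions are merged; runs
    shorter than ``min_tmd`` are dropped; runs longer than ``max_tmd`` are
    trimmed to their best ``max_tmd``-residue stretch.
    """
    p = params or TopologyParams()
    if len(aa_seq) < p.window:
        return []
    prof = hydropathy_profile(aa_seq, p.window)
    above = prof >= p.threshold
    runs: list[list[int]] = []
    i = 0
    n = len(aa_seq)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < p.merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    out = []
    for s, e in merged:
        if e - s < p.min_tmd:
            continue
        if e - s > p.max_tmd:
            # keep the highest-scoring max_tmd-wide stretch of the run
            best_s = max(
                range(s, e - p.max_tmd + 1),
                key=lambda k: prof[k : k + p.max_tmd].mean(),
            )
            s, e = best_s, best_s + p.max_tmd
        raw = [KYTE_DOOLITTLE.get(c, 0.0) for c in aa_seq[s:e]]
        out.append(TmdInterval(start=s, end=e, mean_hydropathy=float(np.mean(raw))))
    return out


def _signal_anatomy_ok(aa_seq: str, cys_index: int) -> bool:
    """Lipoprotein signal sanity: early K/R and a hydrophobic stretch before the box."""
    if not any(c in "KR" for c in aa_seq[:7]):
        return False
    region = aa_seq[: cys_index - 3]
    run = 0
    for ch in region:
        run = run + 1 if ch in _H_REGION else 0
        if run >= 6:
            return True
    return False


def find_lipobox(
    aa_seq: str,
    min_cys: int = 12,
    max_cys: int = 40,
    mode: str = "strict",
) -> LipoboxHit | None:
    """First qualifying lipobox Cys within the signal window.

    Strict mode requires the consensus ``[LVI][ASTVI][GAS]C``; relaxed mode
    accepts any tripeptide drawn position-wise from the relaxed alphabet.
    Both modes require signal-peptide anatomy (see :func:`_signal_anatomy_ok`).
    The Cys bound is checked in 1-based residue numbering.
    """
    if mode not in ("strict", "relaxed"):
        raise ValueError(f"unknown lipobox mode {mode!r}")
    if len(aa_seq) <= max_cys:
        return None
    for i, ch in enumerate(aa_seq):
        if ch != "C":
            continue
        pos1 = i + 1
        if pos1 < min_cys or pos1 > max_cys or i < 3:
            continue
        tri = aa_seq[i - 3 : i]
        strict_ok = (
            tri[0] in STRICT_LIPOBOX_P1
            and tri[1] in STRICT_LIPOBOX_P2
            and tri[2] in STRICT_LIPOBOX_P3
        )
        relaxed_ok = all(c in RELAXED_LIPOBOX_SET for c in tri)
        if not (strict_ok or (mode == "relaxed" and relaxed_ok)):
            continue
        if not _signal_anatomy_ok(aa_seq, i):
            continue
        return LipoboxHit(
            cys_index=i, motif=tri + "C", mode="strict" if strict_ok else "relaxed"
        )
    return None


def classify_topology(aa_seq: str, params: TopologyParams | None = None) -> TopologyCall:
    """Type a protein as i-, o-, or u-spanin candidate (or NONE).

    The lipobox-bearing types are tested first (u, then o) so that
    lipoproteins with a C-terminal TMD are not mistyped as inner-membrane
    proteins; the plain N-terminal-TMD test comes last.
    """
    p = params or TopologyParams()
    n = len(aa_seq)
    if n < p.min_len or n > p.max_len:
        return TopologyCall(type=NONE, evidence="length")
    tmds = find_tmds(aa_seq, p)
    lipo = find_lipobox(aa_seq, p.min_cys, p.max_cys, p.lipobox_mode)
    if lipo is not None:
        downstream = [t for t in tmds if t.start > lipo.cys_index]
        cterm = [t for t in downstream if t.start >= n - 35]
        if cterm:
            call = TopologyCall(
                type=U_CAND, tmds=tmds, lipobox=lipo,
                evidence=f"lipobox {lipo.motif} + C-terminal TMD",
            )
            return _finalize(call, aa_seq)
        if not downstream:
            call = TopologyCall(
                type=O_CAND, tmds=tmds, lipobox=lipo,
                evidence=f"lipobox {lipo.motif}, no downstream TMD",
            )
            return _finalize(call, aa_seq)
        return TopologyCall(
            type=NONE, tmds=tmds, lipobox=lipo,
            evidence="lipobox with internal TMD",
        )
    if len(tmds) == 1 and tmds[0].start < 30:
        call = TopologyCall(
            type=I_CAND, tmds=tmds, evidence="single N-terminal TMD, no lipobox"
        )
        return _finalize(call, aa_seq)
    return TopologyCall(type=NONE, tmds=tmds, evidence="no admissible signal")


def _finalize(call: TopologyCall, aa_seq: str) -> TopologyCall:
    """Attach the periplasmic interval; demote degenerate calls to NONE."""
    try:
        call.periplasmic = periplasmic_domain(call, aa_seq)[0]
    except ValueError:
        return TopologyCall(
            type=NONE, tmds=call.tmds, lipobox=call.lipobox,
            evidence="degenerate periplasmic domain",
        )
    return call


def periplasmic_domain(call: TopologyCall, aa_seq: str) -> tuple[tuple[int, int], str]:
    """The periplasmic residue interval (0-based half-open) and its substring.

    i: downstream of the TMD; o: downstream of the lipoylated Cys (the Cys
    itself is membrane-anchored and excluded); u: between the Cys and the
    C-terminal TMD.
    """
    n = len(aa_seq)
    if call.type == I_CAND:
        iv = (call.tmds[0].end, n)
    elif call.type == O_CAND:
        iv = (call.lipobox.cys_index + 1, n)
    elif call.type == U_CAND:
        cterm = [t for t in call.tmds if t.start > call.lipobox.cys_index and t.start >= n - 35]
        iv = (call.lipobox.cys_index + 1, cterm[0].start)
    else:
        raise ValueError(f"no periplasmic domain for type {call.type}")
    if iv[0] >= iv[1]:
        raise ValueError(f"degenerate periplasmic interval {iv}")
    return iv, aa_seq[iv[0] : iv[1]]


def read_override_table(path) -> dict[str, dict[str, int]]:
    """Read externally computed TMD/lipobox coordinates.

    TSV columns: protein_id, tmd_start, tmd_end, cys_index (1-based inclusive
    in the file, converted to 0-based half-open / 0-based index on read).
    Empty fields mean 'no such signal'.
    """
    import csv

    out: dict[str, dict[str, int]] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            entry: dict[str, int] = {}
            if row.get("tmd_start"):
                entry["tmd_start"] = int(row["tmd_start"]) - 1
                entry["tmd_end"] = int(row["tmd_end"])
            if row.get("cys_index"):
                entry["cys_index"] = int(row["cys_index"]) - 1
            out[row["protein_id"]] = entry
    return out
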