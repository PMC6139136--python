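"""Database-level spanin analyses: cysteines, architectures, lipobox matrices.

Two-component spanin function depends on intermolecular disulfide bonds
between periplasmic cysteines, so the census of Cys counts and normalized
Cys positions is a first-class analysis here.  Positions are reported on two
scales: the *complex* coordinate (the i-spanin periplasmic domain, IM end
first, concatenated with the reversed o-spanin periplasmic domain so the OM
end comes last) and per-component coordinates (distance to the membrane
anchor and to the C-terminal interaction interface, as percent of that
component's periplasmic length).  The lipoylated Cys is anchored in the OM
and is never counted as periplasmic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .caller import SpaninComponent, SpaninSystem, UNIMOLECULAR

AA20 = list("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class CysteineProfile:
    """Cys counts and normalized positions for one two-component system."""

    i_count: int
    o_count: int
    total: int
    pos_closest_IM_pct: float | None = None
    pos_closest_OM_pct: float | None = None
    i_closest_IM_pct: float | None = None
    i_closest_interface_pct: float | None = None
    o_closest_OM_pct: float | None = None
    o_closest_interface_pct: float | None = None
    single_cys: bool = False


@dataclass
class LipoboxPFM:
    """Position-frequency matrix over the lipobox (3 pre-Cys residues + Cys)."""

    counts: pd.DataFrame  # 4 rows (-3, -2, -1, C) x 20 residue columns
    n: int


@dataclass
class DbSummary:
    architecture_counts: dict[str, int]
    frame_counts: dict[str, int]
    i_longer_than_o_count: int
    n_two_component: int
    periplasmic_length_min: tuple[str, int] | None
    periplasmic_length_max: tuple[str, int] | None
    cys_histogram_total: dict[int, int]
    cys_histogram_i: dict[int, int]
    cys_histogram_o: dict[int, int]
    rel_position_histogram: dict[float, int]


def _require_two_component(system: SpaninSystem) -> None:
    if system.architecture == UNIMOLECULAR or system.i is None or system.o is None:
        raise ValueError("two-component system required; use the u path")


def cysteine_counts(system: SpaninSystem) -> tuple[int, int, int]:
    """Periplasmic Cys counts (i, o, total); the lipoylated Cys is excluded
    because the periplasmic domain starts downstream of it."""
    _require_two_component(system)
    i_c = system.i.periplasmic_seq.count("C")
    o_c = system.o.periplasmic_seq.count("C")
    return i_c, o_c, i_c + o_c


def u_cysteine_count(system: SpaninSystem) -> int:
    if system.u is None:
        raise ValueError("unimolecular system required")
    return system.u.periplasmic_seq.count("C")


def cysteine_positions(system: SpaninSystem) -> CysteineProfile:
    """Normalized positions of the cysteines closest to each anchor.

    The complex coordinate runs IM -> OM: i periplasmic domain first, then
    the o periplasmic domain reversed (its first residue neighbours the
    lipoylated, OM-anchored Cys).  All distances are percent of the relevant
    length; a component without Cys reports absent percentages.
    """
    i_c, o_c, total = cysteine_counts(system)
    prof = CysteineProfile(i_count=i_c, o_count=o_c, total=total, single_cys=total == 1)
    if total == 0:
        return prof
    i_p = system.i.periplasmic_seq
    o_p = system.o.periplasmic_seq
    complex_seq = i_p + o_p[::-1]
    n = len(complex_seq)
    cys_idx = [k for k, ch in enumerate(complex_seq) if ch == "C"]
    prof.pos_closest_IM_pct = 100.0 * min(cys_idx) / n
    prof.pos_closest_OM_pct = 100.0 * (n - 1 - max(cys_idx)) / n
    if i_c:
        idx = [k for k, ch in enumerate(i_p) if ch == "C"]
        prof.i_closest_IM_pct = 100.0 * min(idx) / len(i_p)
        prof.i_closest_interface_pct = 100.0 * (len(i_p) - 1 - max(idx)) / len(i_p)
    if o_c:
        idx = [k for k, ch in enumerate(o_p) if ch == "C"]
        prof.o_closest_OM_pct = 100.0 * min(idx) / len(o_p)
        prof.o_closest_interface_pct = 100.0 * (len(o_p) - 1 - max(idx)) / len(o_p)
    return prof


def db_cysteine_tables(
    db: list[SpaninSystem],
) -> tuple[dict[int, int], dict[int, int], dict[int, int], pd.DataFrame]:
    """Total/i/o Cys count histograms and the joint (i, o) contingency table."""
    pairs = [cysteine_counts(s) for s in db if s.architecture != UNIMOLECULAR]
    total_h = Counter(t for _, _, t in pairs)
    i_h = Counter(i for i, _, _ in pairs)
    o_h = Counter(o for _, o, _ in pairs)
    if pairs:
        joint = pd.crosstab(
            pd.Series([i for i, _, _ in pairs], name="i_cys"),
            pd.Series([o for _, o, _ in pairs], name="o_cys"),
        )
    else:
        joint = pd.DataFrame()
    return dict(total_h), dict(i_h), dict(o_h), joint


def lipobox_pfm(components: list[SpaninComponent]) -> LipoboxPFM:
    """Residue counts at the 3 pre-Cys lipobox positions plus the Cys itself."""
    counts = pd.DataFrame(0, index=["-3", "-2", "-1", "C"], columns=AA20)
    n = 0
    for comp in components:
        hit = comp.topology.lipobox
        if hit is None:
            continue
        motif = hit.motif
        for row, ch in zip(counts.index, motif):
            if ch in counts.columns:
                counts.loc[row, ch] += 1
        n += 1
    return LipoboxPFM(counts=counts, n=n)


def db_summary(db: list[SpaninSystem], ids: list[str] | None = None) -> DbSummary:
    """Architecture/frame/length/cysteine aggregates over a spanin database.

    ``ids`` optionally labels each system (phage name) for the min/max
    periplasmic length report; defaults to the running index.
    """
    ids = ids or [str(k) for k in range(len(db))]
    arch = Counter(s.architecture for s in db)
    frames = Counter(
        s.frame_offset for s in db if s.frame_offset in ("+1", "-1")
    )
    two_cs = [(sid, s) for sid, s in zip(ids, db) if s.architecture != UNIMOLECULAR]
    longer = sum(
        1 for _, s in two_cs if len(s.i.orf.aa_seq) > len(s.o.orf.aa_seq)
    )
    peri_lengths = [
        (sid, len(s.i.periplasmic_seq) + len(s.o.periplasmic_seq)) for sid, s in two_cs
    ]
    total_h, i_h, o_h, _ = db_cysteine_tables([s for _, s in two_cs])
    rel_hist: Counter = Counter()
    for _, s in two_cs:
        if s.rel_start_frac is not None:
            rel_hist[round(int(s.rel_start_frac / 0.1) * 0.1, 1)] += 1
    return DbSummary(
        architecture_counts=dict(arch),
        frame_counts=dict(frames),
        i_longer_than_o_count=longer,
        n_two_component=len(two_cs),
        periplasmic_length_min=min(peri_lengths, key=lambda t: t[1]) if peri_lengths else None,
        periplasmic_length_max=max(peri_lengths, key=lambda t: t[1]) if peri_lengths else None,
        cys_histogram_total=total_h,
        cys_histogram_i=i_h,
        cys_histogram_o=o_h,
        rel_position_histogram=dict(rel_hist),
    )
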