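"""Single-linkage family clustering of spanin periplasmic domains.

Families are defined so that members are connected through pairwise local
alignments with >=40% identity over >=40% of the sequence length (BLOSUM62,
gap open 11 / extend 1 -- the classic BLASTCLUST regime).  Because a deep
scoring matrix needs long alignments, sequences shorter than 50 aa are held
out of the graph stage and attached afterwards by end-gap-free global
identity, where local alignment would over-score fragments.  Identical-set
detection (100% identity over 100% length, full-length sequences including
the signal) is done by exact hashing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWYBZX")


@dataclass(frozen=True)
class AlignmentResult:
    """Identity/coverage summary of the best local alignment of a pair."""

    identity_pct: float
    cov_a: float
    cov_b: float
    score: float

    @property
    def is_hit(self) -> bool:
        return self.score > 0


@dataclass
class ClusterParams:
    """Family thresholds: identity percent, length-coverage fraction.

    ``cov_rule`` names the sequence(s) that must meet the coverage cut:
    ``both`` (default, each sequence), ``either``, or ``shorter``.
    """

    id_threshold: float = 40.0
    cov_threshold: float = 0.4
    cov_rule: str = "both"
    short_len: int = 50

    def __post_init__(self) -> None:
        if not (0 <= self.id_threshold <= 100):
            raise ValueError("id_threshold must be a percentage")
        if not (0 <= self.cov_threshold <= 1):
            raise ValueError("cov_threshold must be a fraction")
        if self.cov_rule not in ("both", "either", "shorter"):
            raise ValueError(f"unknown cov_rule {self.cov_rule!r}")


@dataclass
class Family:
    """A cluster of sequence ids with a chosen representative."""

    members: list[str]
    representative: str
    singleton: bool

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError("representative must be a member")
        if self.singleton != (len(self.members) == 1):
            raise ValueError("singleton flag inconsistent with member count")


def _check_protein(seq: str, name: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in _VALID_AA:
            raise ValueError(f"non-amino-acid character {ch!r} at position {i} in {name}")


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _global_endfree_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    # end gaps are free: fragments may hang off either end without penalty
    try:
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    except AttributeError:  # older biopython naming
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0
    return aligner


def _summarise(alignment, a: str, b: str) -> AlignmentResult:
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = 100.0 * counts.identities / columns if columns else 0.0
    aligned_a = sum(e - s for s, e in alignment.aligned[0])
    aligned_b = sum(e - s for s, e in alignment.aligned[1])
    return AlignmentResult(
        identity_pct=identity,
        cov_a=aligned_a / len(a),
        cov_b=aligned_b / len(b),
        score=float(alignment.score),
    )


def pairwise_local_identity(a: str, b: str) -> AlignmentResult:
    """Best Smith-Waterman alignment under BLOSUM62 / gap 11,1.

    Identity is over aligned columns (gaps included, BLAST-style); coverage
    is the aligned fraction of each sequence.  A non-positive best score is
    the no-hit sentinel.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    _check_protein(a, "a")
    _check_protein(b, "b")
    aligner = _local_aligner()
    score = aligner.score(a, b)
    if score <= 0:
        return AlignmentResult(identity_pct=0.0, cov_a=0.0, cov_b=0.0, score=score)
    return _summarise(next(iter(aligner.align(a, b))), a, b)


def _edge_ok(res: AlignmentResult, len_a: int, len_b: int, params: ClusterParams) -> bool:
    if not res.is_hit or res.identity_pct < params.id_threshold:
        return False
    t = params.cov_threshold
    if params.cov_rule == "both":
        return res.cov_a >= t and res.cov_b >= t
    if params.cov_rule == "either":
        return res.cov_a >= t or res.cov_b >= t
    short_cov = res.cov_a if len_a <= len_b else res.cov_b
    return short_cov >= t


def family_clusters(
    seqs: Mapping[str, str], params: ClusterParams | None = None
) -> list[Family]:
    """Single-linkage families over the identity/coverage graph.

    All sequences must be at least ``short_len`` long; route shorter ones
    through :func:`assign_short_sequences` afterwards.
    """
    params = params or ClusterParams()
    for name, s in seqs.items():
        if len(s) < params.short_len:
            raise ValueError(
                f"{name} is shorter than {params.short_len} aa; "
                "use assign_short_sequences for short sequences"
            )
    g = nx.Graph()
    g.add_nodes_from(seqs)
    ids = sorted(seqs)
    for idx, a in enumerate(ids):
        for b in ids[idx + 1 :]:
            res = pairwise_local_identity(seqs[a], seqs[b])
            if _edge_ok(res, len(seqs[a]), len(seqs[b]), params):
                g.add_edge(a, b)
    fams = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        rep = choose_representative(members, {m: len(seqs[m]) for m in members})
        fams.append(Family(members=members, representative=rep, singleton=len(members) == 1))
    fams.sort(key=lambda f: f.representative)
    return fams


def identical_sets(full_seqs: Mapping[str, str]) -> list[Family]:
    """Group full-length sequences that are 100% identical over 100% length."""
    buckets: dict[str, list[str]] = {}
    for name in sorted(full_seqs):
        buckets.setdefault(full_seqs[name], []).append(name)
    fams = []
    for seq, members in buckets.items():
        rep = choose_representative(members, {m: len(seq) for m in members})
        fams.append(Family(members=members, representative=rep, singleton=len(members) == 1))
    fams.sort(key=lambda f: f.representative)
    return fams


def global_endfree_identity(a: str, b: str) -> AlignmentResult:
    """End-gap-free global alignment identity (for short-fragment assignment)."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    _check_protein(a, "a")
    _check_protein(b, "b")
    aligner = _global_endfree_aligner()
    alignment = next(iter(aligner.align(a, b)))
    # restrict columns to the aligned core (ignore overhanging end gaps)
    seg_a, seg_b = alignment.aligned
    if not len(seg_a):
        return AlignmentResult(0.0, 0.0, 0.0, float(alignment.score))
    counts = alignment.counts()
    aligned_a = sum(e - s for s, e in seg_a)
    aligned_b = sum(e - s for s, e in seg_b)
    # columns of the aligned core: matched/mismatched pairs plus internal gaps
    # (overhanging end-gap columns are excluded by construction)
    columns = counts.identities + counts.mismatches + _internal_gaps(seg_a, seg_b)
    identity = 100.0 * counts.identities / columns if columns else 0.0
    return AlignmentResult(
        identity_pct=identity,
        cov_a=aligned_a / len(a),
        cov_b=aligned_b / len(b),
        score=float(alignment.score),
    )


def _internal_gaps(seg_a, seg_b) -> int:
    gaps = 0
    for prev, nxt in zip(seg_a[:-1], seg_a[1:]):
        gaps += nxt[0] - prev[1]
    for prev, nxt in zip(seg_b[:-1], seg_b[1:]):
        gaps += nxt[0] - prev[1]
    return gaps


def assign_short_sequences(
    families: list[Family],
    shorts: Mapping[str, str],
    seqs: Mapping[str, str],
    params: ClusterParams | None = None,
) -> list[Family]:
    """Attach short sequences to existing families or spin off singletons.

    Each short sequence joins the family of its best-identity partner if the
    pairing satisfies the identity/coverage rule under end-gap-free global
    alignment; otherwise it becomes a new singleton.  Ties break toward
    higher identity, then the lexicographically smaller family representative.
    """
    params = params or ClusterParams()
    lengths = {m: len(seqs[m]) for fam in families for m in fam.members}
    out = [Family(list(f.members), f.representative, f.singleton) for f in families]
    for sid in sorted(shorts):
        best: tuple[float, str] | None = None  # (identity, family representative)
        for fam in out:
            for member in fam.members:
                if member not in seqs:
                    continue
                res = global_endfree_identity(shorts[sid], seqs[member])
                if not _edge_ok(res, len(shorts[sid]), len(seqs[member]), params):
                    continue
                key = (res.identity_pct, fam.representative)
                if best is None or key[0] > best[0] or (
                    key[0] == best[0] and key[1] < best[1]
                ):
                    best = key
        if best is None:
            out.append(Family(members=[sid], representative=sid, singleton=True))
        else:
            for fam in out:
                if fam.representative == best[1]:
                    fam.members = sorted(fam.members + [sid])
                    fam.singleton = False
                    lengths[sid] = len(shorts[sid])
                    fam.representative = choose_representative(
                        fam.members, {m: lengths.get(m, 0) for m in fam.members}
                    )
                    break
    out.sort(key=lambda f: f.representative)
    return out


def choose_representative(members: list[str], lengths: Mapping[str, int]) -> str:
    """Longest member; ties break lexicographically."""
    return min(members, key=lambda m: (-lengths[m], m))
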