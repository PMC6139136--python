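"""Pairwise alignment summaries and single-linkage family clustering."""

from __future__ import annotations

import random

import pytest
from Bio.Align import substitution_matrices

from spaninscan.clustering import (
    ClusterParams,
    assign_short_sequences,
    choose_representative,
    family_clusters,
    global_endfree_identity,
    identical_sets,
    pairwise_local_identity,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _gotoh_local_score(a: str, b: str, open_=-11, extend=-1) -> float:
    """Independent affine-gap Smith-Waterman score (first gap residue costs
    ``-open_``; each further residue ``-extend``), for cross-checking."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (insertion in b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + open_, E[i][j - 1] + extend)
            F[i][j] = max(H[i - 1][j] + open_, F[i - 1][j] + extend)
            s = BLOSUM62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def _random_protein(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(AA20) for _ in range(n))


def _mutate(rng: random.Random, seq: str, k: int) -> str:
    chars = list(seq)
    for pos in rng.sample(range(len(seq)), k):
        chars[pos] = rng.choice(AA20.replace(chars[pos], ""))
    return "".join(chars)


class TestPairwiseLocalIdentity:
    def test_self_alignment(self):
        res = pairwise_local_identity("MKTAYIAKQR", "MKTAYIAKQR")
        assert res.identity_pct == 100.0
        assert res.cov_a == res.cov_b == 1.0

    def test_single_substitution(self):
        """One mismatch in ten columns: 90% identity at full coverage, and the
        score equals the hand-summed BLOSUM62 diagonal (53) plus L-vs-V (1)."""
        res = pairwise_local_identity("ACDEFGHIKL", "ACDEFGHIKV")
        assert res.identity_pct == pytest.approx(90.0)
        assert res.cov_a == res.cov_b == 1.0
        assert res.score == 54.0

    def test_score_matches_affine_dp_oracle(self):
        rng = random.Random(17)
        for _ in range(10):
            a = _random_protein(rng, rng.randint(10, 25))
            b = _random_protein(rng, rng.randint(10, 25))
            res = pairwise_local_identity(a, b)
            assert max(res.score, 0.0) == pytest.approx(_gotoh_local_score(a, b))

    def test_symmetry(self):
        rng = random.Random(23)
        for _ in range(10):
            a = _random_protein(rng, 40)
            b = _mutate(rng, a, 20)[: rng.randint(25, 40)]
            r1 = pairwise_local_identity(a, b)
            r2 = pairwise_local_identity(b, a)
            assert r1.identity_pct == pytest.approx(r2.identity_pct)
            assert (r1.cov_a, r1.cov_b) == pytest.approx((r2.cov_b, r2.cov_a))

    def test_no_positive_alignment_is_no_hit(self):
        res = pairwise_local_identity("WWWWWWWW", "PPPPPPPP")
        assert not res.is_hit

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError, match="position 2"):
            pairwise_local_identity("MK1T", "MKTT")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_local_identity("", "MKT")


def _brute_components(seqs: dict[str, str], params: ClusterParams) -> set[frozenset]:
    """Brute-force single linkage: explicit adjacency + DFS."""
    ids = list(seqs)
    adj = {i: set() for i in ids}
    for x in range(len(ids)):
        for y in range(x + 1, len(ids)):
            a, b = ids[x], ids[y]
            res = pairwise_local_identity(seqs[a], seqs[b])
            if (
                res.is_hit
                and res.identity_pct >= params.id_threshold
                and res.cov_a >= params.cov_threshold
                and res.cov_b >= params.cov_threshold
            ):
                adj[a].add(b)
                adj[b].add(a)
    seen, comps = set(), []
    for start in ids:
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            node = stack.pop()
            if node in comp:
                continue
            comp.add(node)
            stack.extend(adj[node] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


def _random_instance(rng: random.Random, n_families: int = 2, copies: int = 3) -> dict[str, str]:
    seqs = {}
    for f in range(n_families):
        base = _random_protein(rng, rng.randint(55, 80))
        for c in range(copies):
            # up to ~45% mutations: some copies stay linked, some drop out
            k = rng.randint(0, int(0.45 * len(base)))
            seqs[f"f{f}c{c}"] = _mutate(rng, base, k)
    return seqs


class TestFamilyClusters:
    def test_transitive_chain_forms_one_family(self):
        """A-B and B-C pass the 40/40 rule, A-C fails: single linkage joins all."""
        rng = random.Random(7)
        a = _random_protein(rng, 60)
        c = _random_protein(rng, 60)
        b = a[:30] + c[30:]
        seqs = {"A": a, "B": b, "C": c}
        params = ClusterParams()
        ra = pairwise_local_identity(a, b)
        rb = pairwise_local_identity(b, c)
        rc = pairwise_local_identity(a, c)
        assert ra.identity_pct >= 40 and rb.identity_pct >= 40
        assert not (rc.is_hit and rc.identity_pct >= 40
                    and rc.cov_a >= 0.4 and rc.cov_b >= 0.4)
        fams = family_clusters(seqs, params)
        assert [f.members for f in fams] == [["A", "B", "C"]]

    def test_dissimilar_sequences_are_singletons(self):
        rng = random.Random(9)
        seqs = {f"s{k}": _random_protein(rng, 60) for k in range(3)}
        fams = family_clusters(seqs)
        assert all(f.singleton for f in fams) and len(fams) == 3

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_bruteforce_connected_components(self, seed):
        rng = random.Random(seed)
        seqs = _random_instance(rng)
        for id_thr in (30.0, 40.0, 60.0):
            params = ClusterParams(id_threshold=id_thr)
            got = {frozenset(f.members) for f in family_clusters(seqs, params)}
            assert got == _brute_components(seqs, params)

    def test_monotonicity_in_identity_threshold(self):
        """Lowering the identity threshold never increases the family count."""
        rng = random.Random(31)
        seqs = _random_instance(rng, n_families=3)
        counts = [
            len(family_clusters(seqs, ClusterParams(id_threshold=t)))
            for t in (20.0, 40.0, 60.0, 80.0, 100.0)
        ]
        assert counts == sorted(counts)

    def test_families_partition_the_input(self):
        rng = random.Random(13)
        seqs = _random_instance(rng, n_families=3)
        fams = family_clusters(seqs)
        members = [m for f in fams for m in f.members]
        assert sorted(members) == sorted(seqs)

    def test_short_sequences_rejected(self):
        with pytest.raises(ValueError, match="short"):
            family_clusters({"x": "MKT" * 10})


class TestIdenticalSets:
    def test_exact_duplicates_grouped(self):
        fams = identical_sets({"x": "MKTAYIAK", "y": "MKTAYIAK", "z": "MKTAYIAC"})
        groups = {frozenset(f.members) for f in fams}
        assert groups == {frozenset({"x", "y"}), frozenset({"z"})}

    def test_all_distinct_gives_singletons(self):
        fams = identical_sets({"a": "MK", "b": "MT", "c": "MR"})
        assert all(f.singleton for f in fams)

    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_clustering_at_100_over_100(self, seed):
        """Hash-based identical sets == single linkage at id=100, cov=1."""
        rng = random.Random(seed)
        base = _random_protein(rng, 60)
        seqs = {}
        for k in range(6):
            seqs[f"s{k}"] = base if k % 2 == 0 else _mutate(rng, base, rng.randint(1, 5))
        by_hash = {frozenset(f.members) for f in identical_sets(seqs)}
        by_graph = {
            frozenset(f.members)
            for f in family_clusters(
                seqs, ClusterParams(id_threshold=100.0, cov_threshold=1.0)
            )
        }
        assert by_hash == by_graph


class TestAssignShortSequences:
    def test_similar_fragment_joins_family(self):
        rng = random.Random(3)
        long_seq = _random_protein(rng, 70)
        frag = _mutate(rng, long_seq[:45], 10)  # ~78% identical over its length
        res = global_endfree_identity(frag, long_seq)
        assert res.identity_pct >= 40 and res.cov_a >= 0.4
        fams = family_clusters({"L": long_seq, "M": _mutate(rng, long_seq, 8)})
        out = assign_short_sequences(
            fams, {"frag": frag}, {"L": long_seq, "M": _mutate(rng, long_seq, 8)}
        )
        target = [f for f in out if "frag" in f.members]
        assert target and len(target[0].members) == 3

    def test_dissimilar_fragment_becomes_singleton(self):
        rng = random.Random(4)
        long_seq = _random_protein(rng, 70)
        frag = _random_protein(rng, 45)
        fams = family_clusters({"L": long_seq})
        out = assign_short_sequences(fams, {"frag": frag}, {"L": long_seq})
        target = [f for f in out if "frag" in f.members]
        assert target[0].singleton

    def test_fragment_coverage_rule_uses_global_identity(self):
        """A fragment must meet 40/40 under end-gap-free global alignment."""
        rng = random.Random(5)
        long_seq = _random_protein(rng, 70)
        res = global_endfree_identity(long_seq[:45], long_seq)
        assert res.identity_pct == pytest.approx(100.0)
        assert res.cov_a == 1.0 and res.cov_b == pytest.approx(45 / 70)


class TestChooseRepresentative:
    def test_longest_wins(self):
        assert choose_representative(["A", "B"], {"A": 100, "B": 90}) == "A"

    def test_length_tie_breaks_lexicographically(self):
        assert choose_representative(["B", "A"], {"A": 100, "B": 100}) == "A"

    def test_singleton(self):
        assert choose_representative(["only"], {"only": 10}) == "only"
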