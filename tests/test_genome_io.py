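"""Genome reading, six-frame ORF enumeration, SD scoring, start refinement."""

from __future__ import annotations

import random

import pytest
from Bio.Seq import Seq

from spaninscan.genome_io import (
    GenomeFormatError,
    GenomeRecord,
    GeneFeature,
    read_genome,
    refine_start,
    scan_orfs,
    score_sd,
    STOP_CODONS,
)

STARTS = ("ATG", "GTG", "TTG")


def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _orf_oracle(seq: str, min_aa: int) -> set[tuple[int, int, str]]:
    """Independent six-frame enumeration by direct codon-list segmentation."""
    n = len(seq)
    out: set[tuple[int, int, str]] = set()
    for strand in "+-":
        s = seq if strand == "+" else str(Seq(seq).reverse_complement())
        for off in range(3):
            codons = [s[k : k + 3] for k in range(off, n - 2, 3)]
            stop_idx = [k for k, c in enumerate(codons) if c in STOP_CODONS]
            prev = -1
            for st in stop_idx:
                for k in range(prev + 1, st):
                    if codons[k] in STARTS and st - k >= min_aa:
                        a, b = off + 3 * k, off + 3 * st
                        out.add((a, b, "+") if strand == "+" else (n - b, n - a, "-"))
                prev = st
    return out


def _genbank_text(seq: str) -> str:
    lines = [
        f"LOCUS       {'TEST00001':<17}{len(seq):>11} bp    DNA     linear   PHG 01-JAN-2000",
        "DEFINITION  synthetic test record.",
        "ACCESSION   TEST00001",
        "VERSION     TEST00001.1",
        "FEATURES             Location/Qualifiers",
        f"     source          1..{len(seq)}",
        '                     /host="Escherichia coli"',
        "     CDS             1..462",
        '                     /locus_tag="gp1"',
        f"     CDS             complement(475..{474 + 126})",
        '                     /locus_tag="gp2"',
        "     CDS             join(10..21,31..42)",
        '                     /locus_tag="spliced"',
        "ORIGIN",
    ]
    for i in range(0, len(seq), 60):
        chunk = seq[i : i + 60].lower()
        blocks = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {blocks}")
    lines.append("//")
    return "\n".join(lines) + "\n"


class TestReadGenome:
    def test_genbank_coordinates_converted(self, tmp_path):
        """1-based inclusive GenBank CDSs become 0-based half-open intervals."""
        seq = _random_seq(random.Random(0), 600)
        path = tmp_path / "t.gbk"
        path.write_text(_genbank_text(seq))
        with pytest.warns(UserWarning, match="join"):
            rec = read_genome(path, format="genbank")
        assert rec.length == 600
        assert rec.host == "Escherichia coli"
        plus = [f for f in rec.features if f.strand == "+"]
        minus = [f for f in rec.features if f.strand == "-"]
        assert (plus[0].start, plus[0].end) == (0, 462)
        assert (minus[0].start, minus[0].end) == (474, 600)
        # the spliced join() feature was skipped
        assert len(rec.features) == 2

    def test_fasta_without_annotation(self, tmp_path):
        path = tmp_path / "t.fa"
        path.write_text(">contig1 test\nACGTACGTACGT\n")
        rec = read_genome(path, format="fasta")
        assert rec.id == "contig1"
        assert rec.features == []

    def test_fasta_with_gff3(self, tmp_path):
        fa = tmp_path / "t.fa"
        fa.write_text(">chr1\n" + "ACGT" * 150 + "\n")
        gff = tmp_path / "t.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tCDS\t1\t462\t.\t+\t0\tID=gp1\n"
            "chr1\tsrc\tCDS\t475\t600\t.\t-\t0\tID=gp2\n"
        )
        rec = read_genome(fa, format="fasta", gff3=gff)
        assert [(f.start, f.end, f.strand) for f in rec.features] == [
            (0, 462, "+"),
            (474, 600, "-"),
        ]

    def test_non_iupac_characters_rejected_with_position(self):
        with pytest.raises(GenomeFormatError, match="position 4"):
            GenomeRecord(id="x", sequence="ACGT!ACGT")

    def test_ambiguity_codes_map_to_n(self):
        rec = GenomeRecord(id="x", sequence="ACGTRYSWKM")
        assert rec.sequence == "ACGT" + "N" * 6


class TestScanOrfs:
    @pytest.mark.parametrize("seed,length", [(1, 900), (2, 1500), (3, 3000), (4, 5000)])
    def test_matches_bruteforce_enumeration(self, seed, length):
        """Candidate set equals an independent six-frame enumeration oracle."""
        seq = _random_seq(random.Random(seed), length)
        genome = GenomeRecord(id="g", sequence=seq)
        got = {(c.start, c.end, c.strand) for c in scan_orfs(genome, min_aa=20, with_sd=False)}
        assert got == _orf_oracle(seq, min_aa=20)

    def test_strand_symmetry(self):
        """Reverse-complementing the genome reflects candidates bijectively."""
        seq = _random_seq(random.Random(5), 2000)
        fwd = GenomeRecord(id="f", sequence=seq)
        rev = GenomeRecord(id="r", sequence=str(Seq(seq).reverse_complement()))
        n = len(seq)
        fwd_set = {(c.start, c.end, c.strand) for c in scan_orfs(fwd, 20, with_sd=False)}
        rev_set = {(c.start, c.end, c.strand) for c in scan_orfs(rev, 20, with_sd=False)}
        reflected = {
            (n - e, n - s, "+" if strand == "-" else "-") for s, e, strand in rev_set
        }
        assert fwd_set == reflected

    def test_translation_roundtrip(self):
        """Translating each candidate's interval on its strand reproduces aa_seq."""
        seq = _random_seq(random.Random(6), 2500)
        genome = GenomeRecord(id="g", sequence=seq)
        cands = scan_orfs(genome, 20, with_sd=False)
        assert cands, "expected at least one ORF in 2.5 kb of random sequence"
        for c in cands:
            nt = seq[c.start : c.end]
            if c.strand == "-":
                nt = str(Seq(nt).reverse_complement())
            assert str(Seq(nt).translate(table=11)) == c.aa_seq
            assert "*" not in c.aa_seq
            assert (c.end - c.start) % 3 == 0

    def test_alternative_starts_share_one_stop(self):
        """ATG at codon 1 and GTG at codon 10 of one ORF give two candidates."""
        body = "GCTGAAGATAAAGCTGAAGAT" * 14  # 98 stop-free codons' worth
        seq = "TAA" + "ATG" + body[:24] + "GTG" + body[24 : 3 * 98] + "TAA"
        genome = GenomeRecord(id="g", sequence=seq + "TAGTAG")
        cands = [c for c in scan_orfs(genome, min_aa=50, with_sd=False) if c.strand == "+"]
        with_shared_stop = [c for c in cands if c.end == len("TAA") + 3 + len(body[: 3 * 98]) + 3]
        assert len(with_shared_stop) == 2
        assert len({c.end for c in with_shared_stop}) == 1
        assert {c.start_codon for c in with_shared_stop} == {"ATG", "GTG"}

    def test_all_stop_genome_yields_nothing(self):
        genome = GenomeRecord(id="g", sequence="TAATAGTGATAATAGTGA" * 20)
        assert scan_orfs(genome, 10, with_sd=False) == []

    def test_nested_orf_marked(self):
        """An ORF inside an annotated gene (alternate frame) is kept and labelled."""
        import numpy as np
        from spaninscan.simulate import _embedded_gene_pair

        rng = np.random.default_rng(3)
        built = None
        while built is None:
            built = _embedded_gene_pair(rng, 1, "LSGC", 1, 1)
        i_nt, o_off, o_len, _ = built
        pad = "TAATTAGTTAA"
        seq = pad + i_nt + pad
        genome = GenomeRecord(
            id="g",
            sequence=seq,
            features=[GeneFeature(len(pad), len(pad) + len(i_nt), "+", label="gene1")],
        )
        cands = scan_orfs(genome, min_aa=40, with_sd=False)
        annotated = [
            c for c in cands if (c.gene_start, c.gene_end) == (len(pad), len(pad) + len(i_nt))
        ]
        nested = [
            c for c in cands
            if c.gene_start == len(pad) + o_off and c.gene_end == len(pad) + o_off + o_len
        ]
        assert annotated and annotated[0].nested_in is None
        assert nested and nested[0].nested_in == "gene1"


class TestShineDalgarno:
    def _genome_with_upstream(self, upstream: str) -> tuple[GenomeRecord, object]:
        seq = "C" * (40 - len(upstream)) + upstream + "ATG" + "GCTGAAGAT" * 15 + "TAA"
        genome = GenomeRecord(id="g", sequence=seq)
        orf = [c for c in scan_orfs(genome, 10, with_sd=False) if c.start == 40][0]
        return genome, orf

    def test_perfect_site(self):
        genome, orf = self._genome_with_upstream("AGGAGG" + "C" * 7)
        sd = score_sd(genome, orf)
        assert (sd.motif, sd.spacer, sd.score) == ("AGGAGG", 7, 6)

    def test_partial_match_found_by_window_scan(self):
        genome, orf = self._genome_with_upstream("GGAG" + "C" * 9)
        sd = score_sd(genome, orf)
        # oracle: exhaustive scan over spacers 4-14 finds GGAG at spacer 9
        assert (sd.motif, sd.spacer, sd.score) == ("GGAG", 9, 4)

    def test_no_purine_context_gives_none(self):
        genome, orf = self._genome_with_upstream("T" * 13)
        assert score_sd(genome, orf) is None

    def test_too_close_to_genome_edge(self):
        seq = "ATG" + "GCTGAAGAT" * 15 + "TAA"
        genome = GenomeRecord(id="g", sequence=seq)
        orf = scan_orfs(genome, 10, with_sd=False)[0]
        assert score_sd(genome, orf) is None


class TestRefineStart:
    def _candidates(self):
        """Three starts sharing one stop, with distinct SD contexts."""
        seq = (
            "C" * 20
            + "AGGAGG" + "CCCCCCC"          # strong SD for the first start
            + "ATG" + "GCTGAAGAT" * 5        # 16 codons
            + "GTG" + "GCTGAAGAT" * 5
            + "TTG" + "GCTGAAGAT" * 10
            + "TAA"
        )
        genome = GenomeRecord(id="g", sequence=seq)
        cands = [c for c in scan_orfs(genome, min_aa=10) if c.strand == "+"]
        stop = max(c.end for c in cands)
        return [c for c in cands if c.end == stop]

    def test_signal_validator_picks_valid_start(self):
        group = self._candidates()
        shortest = min(group, key=lambda c: len(c.aa_seq))
        chosen = refine_start(group[0], group[1:], lambda aa: len(aa) == len(shortest.aa_seq))
        assert chosen.start == shortest.start
        assert not chosen.low_confidence

    def test_sd_breaks_ties_between_valid_starts(self):
        group = self._candidates()
        chosen = refine_start(group[0], group[1:], lambda aa: True)
        assert chosen.sd is not None and chosen.sd.score == 6
        assert chosen.start == min(c.start for c in group)

    def test_no_valid_start_falls_back_to_longest(self):
        group = self._candidates()
        chosen = refine_start(group[0], group[1:], lambda aa: False)
        assert chosen.start == min(c.start for c in group)
        assert chosen.low_confidence

    def test_empty_sibling_set_returns_orf(self):
        group = self._candidates()
        chosen = refine_start(group[0], [], lambda aa: True)
        assert (chosen.start, chosen.end) == (group[0].start, group[0].end)
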