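# spaninscan

Discovery and classification of **spanins** — the phage lysis proteins that
disrupt the Gram-negative outer membrane — directly from genome sequences.

Phage lysis of a Gram-negative host needs three steps: a holin permeabilizes
the inner membrane (IM), an endolysin degrades the peptidoglycan, and a
spanin system disrupts the outer membrane (OM), most likely by fusing it
with the IM. Spanins come in two flavours:

* a **two-component system (2CS)**: an **i-spanin** (class II, N-in/C-out IM
  protein with a single N-terminal transmembrane domain, prototype λ Rz)
  paired with an **o-spanin** (OM lipoprotein with an N-terminal lipobox,
  prototype λ Rz1), their periplasmic domains forming a membrane-to-membrane
  complex; or
* a **u-spanin**: one protein carrying both an N-terminal lipoprotein signal
  and a C-terminal TMD (prototype T1 gp11).

Spanin genes are a worst case for automated annotation: o-spanin genes of
the *embedded* architecture live entirely inside the i-spanin gene in the
+1 or −1 reading frame and are usually not annotated at all, and the
N-terminal membrane signals that define all three roles are destroyed by a
mis-called start codon. `spaninscan` therefore ignores annotated gene models
and searches exhaustively:

1. enumerate every ORF in all six frames (`genome_io`), including ORFs
   nested inside annotated genes, with Shine–Dalgarno scoring and
   signal-guided start refinement;
2. type each candidate by membrane topology (`topology`): Kyte–Doolittle
   hydropathy windows for TMDs, and lipobox matching — strict consensus
   `[LVI][ASTVI][GAS]C`, or a relaxed mode that also admits the deviant but
   experimentally validated motifs such as AWAC;
3. pair i- with o-candidates and classify the gene architecture
   (`caller`): *embedded* (o ⊆ i), *overlapped* (shared 3′/5′ region above a
   10-bp threshold), or *separated*; record the frame offset
   (`(o_start − i_start) mod 3` → +1/−1) and the o-gene position in units of
   L, the i-gene length;
4. cluster periplasmic domains into families (`clustering`): single linkage
   over the ≥40% identity / ≥40% coverage graph (Smith–Waterman, BLOSUM62,
   gap 11/1), short sequences attached by end-gap-free global identity,
   identical sets by exact full-length hashing;
5. compute database-level statistics (`stats`): periplasmic cysteine
   censuses and normalized positions (disulfide-bond geometry), lipobox
   position-frequency matrices, architecture/frame/length summaries;
6. simulate phage genomes with planted spanin systems of every architecture
   and a machine-readable truth table (`simulate`), so the entire pipeline
   is testable without downloads.

## Worked example

Simulate a 14-kb phage genome with one planted system of each architecture
plus decoy genes, then search it:

```sh
$ spaninscan simulate --seed 42 --out phage.gbk --truth truth.tsv
# wrote 14404 bp genome with 4 planted system(s) to phage.gbk
$ spaninscan find phage.gbk --out spanins.tsv
# verdict: spanins_found (4 system(s), 1 unpaired lipoprotein(s))
```

The output TSV (SpaninDB-style schema, one row per component) contains:

```text
architecture component_role gene_coordinates length_aa periplasmic_cys_count lipobox frame_offset overlap_bp
unimolecular              u    3194..3493(+)        99                     0    LSGC          n/a          0
    embedded              i    6263..6673(+)       136                     4                   +1        225
    embedded              o    6429..6653(+)        74                     1    LSGC           +1        225
  overlapped              i    9538..9768(+)        76                     2                   +1         56
  overlapped              o    9713..9955(+)        80                     2    LSGC           +1         56
   separated              i  12596..12838(+)        80                     2                  n/a          0
   separated              o  13070..13276(+)        68                     1    AWAC          n/a          0
```

Reading the table: the embedded o-gene (6429..6653) sits wholly inside its
i-gene in the +1 frame — it was absent from the simulated annotation and
recovered by the six-frame scan; the u-spanin has a cysteine-free
periplasmic domain; the separated o-spanin carries the non-consensus AWAC
lipobox, found only in relaxed mode; the one stray lipoprotein decoy,
placed outside pairing range (1 kb), is reported separately rather than
forced into a pair. Downstream:

```sh
spaninscan cluster spanins.tsv --type o --out families.tsv   # 40/40 families
spaninscan stats spanins.tsv --out-dir stats/                # Cys tables, lipobox PFMs
```

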