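# scaffoldmine

Genome mining for modular polyketide (PKS, type I) and nonribosomal peptide
(NRPS) biosynthetic gene clusters, prediction of the secondary-metabolite
scaffold they encode, and ranking of that scaffold against natural-compound
libraries.

**Who it is for.** Natural-product researchers who have a (meta)genome or an
annotated gene cluster and want to know *what molecule it probably makes*
and *whether that molecule — or a close relative — is already known*.

## The method

Modular PKS/NRPS megaenzymes follow (mostly) the co-linearity principle:
the order of modules along the genome maps onto the order of building
blocks in the product. The pipeline exploits this in seven stages:

1. **Domain detection** — profile-HMMs, one per biosynthetic domain type
   (KS, AT, A, C, KR, DH, ER, carrier domains, methyltransferases, TE/TD,
   …), each with a calibrated per-domain bit-score threshold `domT` set to
   the minimum score with which the profile detects its own training
   members (so calibration-set recall is 1 by construction). The shipped
   default threshold table covers 20 domain types (e.g. ACP 13.9, AT 47.4,
   KS 72.0); KSQ reuses the KS threshold.
2. **Module architecture** — ordered domain hits are segmented into modules
   (boundary after the carrier domain plus trailing E/TE/TD) and classified
   as normal / special / non-functional via a pattern table of known
   arrangements plus compositional fallback rules. The β-reduction state
   follows the reductive domain set ({} → ketone, KR → hydroxyl, DH+KR →
   enoyl, DH+ER+KR → alkyl, incomplete → ketone\*), and methyltransferase
   position decides α-, N- or O-methylation (a cMT between the reductive
   domains and the carrier additionally marks trans-AT chemistry).
3. **Module order** — strand-contiguous module runs form blocks; disjoint
   blocks are ordered by locally aligning hypothetical block-pair
   concatenations (Smith–Waterman over the domain-label alphabet; match +1,
   mismatch −1, gap open −2, gap extend −1) against a reference database of
   single-block clusters, merging the best admissible pair greedily.
4. **Substrate specificity** — AT- and A-domain substrates are predicted by
   random forests over one-hot encoded alignment columns (grid-searched
   hyperparameters; the full grid enumerates 2160 configurations).
5. **Scaffold assembly** — each functional module becomes a two-position
   building block (β/α for PK, peptide-N/α for NRP) with its substrate
   substituent, methylations, stereochemistry and reduction state; blocks
   condense head-to-tail into SMILES fragments, honoring the rule that
   reductive domains act on the carbonyl inherited from the previous block.
6. **Postsynthetic modifications (PSM)** — seven substructure classes
   (glycoside, Cl, spiroketal, disulfide, nitro, 6-ring, 5-ring) counted by
   SMARTS; per-PSM linear count models over curated Pfam-domain counts,
   retained only when cross-validated R² beats the predict-nothing baseline.
7. **Screening** — compound libraries (SMILES/SDF) are deduplicated and
   fingerprinted (Morgan, radius 3). Candidates are preselected by Tanimoto
   similarity, then scored by a multi-fragment MCS algorithm (fragments
   matched largest-first, each match deleted from the target before the
   next fragment is matched) and by a Bray–Curtis similarity between PSM
   count vectors, combined as
   `mixed = a·similarity + b·MCS + c·PSM` (default all-type weights
   a=0.3, b=0.4, c=0.1).

## Worked example

```bash
python examples/04_full_pipeline.py
```

prints (seed 0):

```
cluster fixshuf_c0: type=NRPS
genomic block order : [['C', 'A', 'PCP', 'TE'], ['C', 'A', 'PCP'], ['A', 'PCP']]
inferred biosynthesis order: [['A', 'PCP', 'C', 'A', 'PCP', 'C', 'A', 'PCP', 'TE']]
predicted scaffold  : CC(C)[C@H](NC(=O)[C@H](C)NC(=O)CN)C(=O)O
best library match  : true_product (rank 1)
```

The fixture genome carries a three-gene NRPS cluster whose genes appear in
scrambled genomic order (the thioesterase-bearing gene first). The block
ordering step reorders the three blocks into loading → extension →
termination, the substrate classifier assigns Gly/Ala/Val, assembly yields
the Gly-Ala-Val tripeptide acid, and screening retrieves the planted true
product at rank 1 out of a 32-compound library. The other examples
demonstrate each stage in isolation; the `scaffoldmine` console script
exposes the same stages as subcommands (`scan`, `modules`, `order`,
`predict-substrates`, `scaffold`, `psm`, `screen`, `run`, `train`,
`benchmark`, `fixtures`).

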