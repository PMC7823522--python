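"""Deterministic synthetic fixtures for every pipeline stage.

The generator plants a fully known ground truth at toy scale: motif-style
domain families (one distinct consensus per domain label), a small annotated
genome embedding an NRPS cluster with known module arrangements, substrates
and block order, a substrate training set whose specificity signal lives in
a signature region of the adenylation domain, a compound library containing
the cluster's true product among decoys, and Pfam-count/PSM tables with a
planted linear relation.  Everything derives from a single integer seed and
regenerates byte-identically.

The fixtures emulate the *shape* of real data (domain architecture, cluster
layout, file formats), not its statistics: real domain families are far more
diverse, real substrate signals are weaker, and real libraries are much
larger.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .domains import LabeledDomainSet, ProteinRecord

AAS = "ACDEFGHIKLMNPQRSTVWY"

#: one codon per amino acid for reverse translation of fixture CDS regions
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}

#: decoy natural-product-like molecules for the screening library
DECOY_SMILES = [
    "CC(=O)Oc1ccccc1C(=O)O",
    "CN1C=NC2=C1C(=O)N(C)C(=O)N2C",
    "C1CCCCC1",
    "c1ccc2[nH]ccc2c1",
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "OCC1OC(O)C(O)C(O)C1O",
    "CC1CCCC(C)O1",
    "O=C(O)c1ccccc1O",
    "NCCc1ccc(O)c(O)c1",
    "CC(=O)NC1C(O)OC(CO)C(O)C1O",
    "OC(=O)CC(O)(CC(=O)O)C(=O)O",
    "Clc1ccc(cc1)C(=O)O",
    "O=[N+]([O-])c1ccccc1",
    "C1CCOC1",
    "CCOC(=O)c1ccccc1",
    "CC(C)(C)c1ccc(O)cc1",
    "O=C1CCCCC1",
    "CC1CC(=O)NC(=O)C1",
    "OCC(O)C(O)C(O)C(O)CO",
    "CSCCC(N)C(=O)O",
    "SSCC(N)C(=O)O",
    "N[C@@H](Cc1ccccc1)C(=O)O",
    "N[C@@H](CO)C(=O)O",
    "CC(=O)CC(=O)O",
    "CCCCCCCC(=O)O",
    "Oc1ccc(cc1)C=CC(=O)O",
    "COc1cc(C=O)ccc1O",
    "CC(O)CC(=O)O",
]


def _consensus(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AAS), n))


def _mutate(rng: np.random.Generator, s: str, k: int, protect: range | None = None) -> str:
    out = list(s)
    eligible = [i for i in range(len(s)) if protect is None or i not in protect]
    for i in rng.choice(eligible, size=min(k, len(eligible)), replace=False):
        out[i] = rng.choice(list(AAS))
    return "".join(out)


@dataclass
class FixtureBundle:
    seed: int
    family_consensus: dict[str, str]
    labeled_domains: LabeledDomainSet
    substrate_sequences: list[str]
    substrate_labels: list[str]
    planted_substrates: list[str]
    genome: SeqRecord
    shuffled_genome: SeqRecord
    reference_domain_string: list[str]
    planted_arrangements: list[list[str]]
    library: list[tuple[str, str]]
    true_product_id: str
    true_product_smiles: str
    psm_domain_counts: dict[str, list[int]]
    psm_counts: dict[str, list[int]]
    psm_true_beta: dict[str, float] = field(default_factory=dict)

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Write the bundle as plain-text files; returns the path map."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}

        fasta = [
            f">dom{i}|{label}\n{seq}"
            for i, (seq, label) in enumerate(self.labeled_domains.entries)
        ]
        paths["domains_fasta"] = directory / "labeled_domains.fasta"
        paths["domains_fasta"].write_text("\n".join(fasta) + "\n")

        fasta = [
            f">sub{i}|{label}\n{seq}"
            for i, (seq, label) in enumerate(
                zip(self.substrate_sequences, self.substrate_labels)
            )
        ]
        paths["substrates_fasta"] = directory / "substrate_training.fasta"
        paths["substrates_fasta"].write_text("\n".join(fasta) + "\n")

        paths["genome"] = directory / "genome.gbk"
        SeqIO.write([self.genome], paths["genome"], "genbank")
        paths["shuffled_genome"] = directory / "genome_shuffled.gbk"
        SeqIO.write([self.shuffled_genome], paths["shuffled_genome"], "genbank")

        paths["library"] = directory / "library.smi"
        paths["library"].write_text(
            "".join(f"{smi}\t{ident}\n" for ident, smi in self.library)
        )

        paths["refdb"] = directory / "reference_blocks.tsv"
        paths["refdb"].write_text(
            "id\tdomains\nref0\t" + ",".join(self.reference_domain_string) + "\n"
        )

        lines = ["cluster_id\tdomain_id\tcount"]
        n = len(next(iter(self.psm_domain_counts.values())))
        for i in range(n):
            for d, counts in self.psm_domain_counts.items():
                lines.append(f"c{i}\t{d}\t{counts[i]}")
        paths["pfam_counts"] = directory / "pfam_counts.tsv"
        paths["pfam_counts"].write_text("\n".join(lines) + "\n")

        lines = ["cluster_id\tpsm\tcount"]
        for i in range(n):
            for p, counts in self.psm_counts.items():
                lines.append(f"c{i}\t{p}\t{counts[i]}")
        paths["psm_counts"] = directory / "psm_counts.tsv"
        paths["psm_counts"].write_text("\n".join(lines) + "\n")
        return paths


SIGNATURE = range(30, 45)  # substrate-determining region of the toy A domain


def _make_genome(
    name: str,
    gene_proteins: list[tuple[str, str]],
    spacing: int = 300,
    strands: list[int] | None = None,
) -> SeqRecord:
    """Assemble a GenBank record from (gene_id, protein) pairs separated by
    neutral spacers; minus-strand genes are stored reverse-complemented."""
    strands = strands or [1] * len(gene_proteins)
    spacer = "ACGT" * (spacing // 4)
    dna_parts = [spacer]
    features = []
    pos = len(spacer)
    for (gene_id, protein), strand in zip(gene_proteins, strands):
        cds = "".join(_CODON[aa] for aa in protein) + "TAA"
        stored = cds if strand == 1 else str(Seq(cds).reverse_complement())
        loc = FeatureLocation(pos, pos + len(cds), strand=strand)
        features.append(
            SeqFeature(
                loc,
                type="CDS",
                qualifiers={
                    "locus_tag": [gene_id],
                    "translation": [protein],
                    "transl_table": ["11"],
                },
            )
        )
        dna_parts.append(stored)
        dna_parts.append(spacer)
        pos += len(cds) + len(spacer)
    return SeqRecord(
        Seq("".join(dna_parts)),
        id=name,
        name=name,
        description="synthetic fixture genome",
        features=features,
        annotations={"molecule_type": "DNA"},
    )


def generate_fixtures(seed: int = 0, outdir: str | Path | None = None) -> FixtureBundle:
    """Build the deterministic fixture bundle for one seed."""
    rng = np.random.default_rng(seed)

    # --- domain families -------------------------------------------------
    labels = ["C", "A", "PCP", "TE", "KS", "AT", "KR", "ACP"]
    consensus = {lab: _consensus(rng, 60 if lab != "A" else 80) for lab in labels}

    substrate_names = ["G", "A", "V"]
    signatures = {s: _consensus(rng, len(SIGNATURE)) for s in substrate_names}

    def a_domain(substrate: str) -> str:
        base = list(consensus["A"])
        base[SIGNATURE.start:SIGNATURE.stop] = signatures[substrate]
        return "".join(base)

    labeled_entries: list[tuple[str, str]] = []
    for lab in labels:
        if lab == "A":
            # adenylation training members span all substrate signatures
            for sub in substrate_names:
                for _ in range(4):
                    seq = _mutate(rng, a_domain(sub), 4, protect=SIGNATURE)
                    labeled_entries.append((seq, "A"))
        else:
            for _ in range(6):
                seq = _mutate(rng, consensus[lab], 4)
                labeled_entries.append((seq, lab))
    labeled = LabeledDomainSet(labeled_entries)

    # --- substrate training set ------------------------------------------
    substrate_sequences, substrate_labels = [], []
    for sub in substrate_names:
        for _ in range(12):
            substrate_sequences.append(_mutate(rng, a_domain(sub), 2, protect=SIGNATURE))
            substrate_labels.append(sub)

    # --- toy genome: loading + extender + terminal NRPS genes ------------
    linker = "GSGSGS"
    planted_substrates = ["G", "A", "V"]
    gene_domains = [
        ["A", "PCP"],
        ["C", "A", "PCP"],
        ["C", "A", "PCP", "TE"],
    ]
    # embed the un-mutated family consensus: it outscores every (mutated)
    # calibration member by a wide margin, so planted domains clear the
    # calibrated thresholds by construction
    gene_proteins = []
    sub_iter = iter(planted_substrates)
    for gi, doms in enumerate(gene_domains):
        parts = [linker]
        for d in doms:
            parts.append(a_domain(next(sub_iter)) if d == "A" else consensus[d])
            parts.append(linker)
        gene_proteins.append((f"gene{gi}", "".join(parts)))
    genome = _make_genome("fixture", gene_proteins)
    # shuffled variant: terminal gene first, loading gene last, middle gene
    # on the opposite strand so each gene forms its own block
    shuffled = _make_genome(
        "fixshuf",
        [gene_proteins[2], gene_proteins[1], gene_proteins[0]],
        strands=[1, -1, 1],
    )
    reference_domain_string = [d for doms in gene_domains for d in doms]
    planted_arrangements = [list(d) for d in gene_domains]

    # --- compound library --------------------------------------------------
    # true product: Gly-Ala-Val tripeptide released as the free acid
    true_smiles = "NCC(=O)N[C@@H](C)C(=O)N[C@@H](C(C)C)C(=O)O"
    library = [("true_product", true_smiles)]
    library += [(f"decoy{i}", smi) for i, smi in enumerate(DECOY_SMILES)]
    library += [
        ("decoy_peptide0", "NCC(=O)N[C@@H](CO)C(=O)N[C@@H](C)C(=O)O"),
        ("decoy_peptide1", "N[C@@H](C)C(=O)N[C@@H](C(C)C)C(=O)O"),
        ("decoy_peptide2", "NCC(=O)N[C@@H](Cc1ccccc1)C(=O)O"),
    ]

    # --- PSM regression tables with planted linear relation ----------------
    n_clusters = 60
    betas = {"Glyco": 0.8, "Cl": 1.5}
    feature_of = {"Glyco": "PF00908.16", "Cl": "PF04820.13"}
    domain_counts: dict[str, list[int]] = {}
    psm_counts: dict[str, list[int]] = {}
    for psm_name, beta in betas.items():
        x = rng.poisson(3, n_clusters)
        noise = rng.normal(0, 0.3, n_clusters)
        y = np.clip(np.round(beta * x + noise), 0, None).astype(int)
        domain_counts[feature_of[psm_name]] = [int(v) for v in x]
        psm_counts[psm_name] = [int(v) for v in y]
    domain_counts["PF99999.1"] = [int(v) for v in rng.poisson(2, n_clusters)]

    bundle = FixtureBundle(
        seed=seed,
        family_consensus=consensus,
        labeled_domains=labeled,
        substrate_sequences=substrate_sequences,
        substrate_labels=substrate_labels,
        planted_substrates=planted_substrates,
        genome=genome,
        shuffled_genome=shuffled,
        reference_domain_string=reference_domain_string,
        planted_arrangements=planted_arrangements,
        library=library,
        true_product_id="true_product",
        true_product_smiles=true_smiles,
        psm_domain_counts=domain_counts,
        psm_counts=psm_counts,
        psm_true_beta=betas,
    )
    if outdir is not None:
        bundle.write(outdir)
    return bundle


def genome_proteins(record: SeqRecord) -> list[ProteinRecord]:
    """Extract CDS translations from an annotated record."""
    out = []
    for feat in record.features:
        if feat.type != "CDS":
            continue
        translation = feat.qualifiers.get("translation", [None])[0]
        if translation is None:
            translation = str(
                feat.extract(record.seq).translate(table=11, to_stop=True)
            )
        locus = feat.qualifiers.get("locus_tag", [f"cds{len(out)}"])[0]
        out.append(
            ProteinRecord(
                id=locus,
                sequence=translation,
                gene_locus=locus,
                genomic_start=int(feat.location.start),
                genomic_end=int(feat.location.end),
                strand="-" if feat.location.strand == -1 else "+",
            )
        )
    return out
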