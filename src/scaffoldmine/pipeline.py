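"""End-to-end orchestration: input → domains → modules → order → substrates
→ scaffold → PSMs → screening.

Input records may be annotated genomes (GenBank with CDS translations),
protein FASTA, or bare DNA FASTA — the latter requires an external gene
caller, invoked through a subprocess contract; pre-called proteins bypass it
entirely.  Clusters are formed from domain-bearing genes separated by at
most a configurable genomic window; the cluster type (PKS/NRPS/mixed) is
derived from the functional modules alone.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

from Bio import SeqIO

from . import scaffold as scaffold_mod
from .domains import CARRIER_LABELS, DomainHit, DomainProfile, ProteinRecord, scan_proteins
from .fixtures import genome_proteins
from .modules import (
    Module,
    ModulePatternTable,
    classify_all,
    merge_cross_gene,
    segment_into_modules,
)
from .ordering import AlignmentParams, ModuleBlock, ReferenceBlockDB, build_blocks, order_blocks
from .psm import PSMRegressor, predict_psms
from .scaffold import Scaffold, SubstrateChemistryTable
from .screening import RankedMatch, ScreeningDB, WeightConfig, default_weights, screen
from .substrates import SubstrateModel

GeneCaller = Callable[[Path], list[ProteinRecord]]


def prodigal_gene_caller(executable: str = "prodigal") -> GeneCaller:
    """Gene-calling contract backed by the prodigal executable."""

    def call(path: Path) -> list[ProteinRecord]:
        if shutil.which(executable) is None:
            raise RuntimeError(
                f"gene caller {executable!r} not found on PATH; provide protein or "
                "annotated GenBank input, or pass a custom gene_caller"
            )
        with tempfile.TemporaryDirectory() as tmp:
            faa = Path(tmp) / "genes.faa"
            subprocess.run(
                [executable, "-i", str(path), "-a", str(faa), "-p", "meta", "-q"],
                check=True,
                capture_output=True,
            )
            out = []
            for rec in SeqIO.parse(str(faa), "fasta"):
                # prodigal headers: id # start # end # strand # ...
                parts = rec.description.split("#")
                start = int(parts[1]) - 1 if len(parts) > 3 else 0
                end = int(parts[2]) if len(parts) > 3 else len(rec.seq) * 3
                strand = "-" if len(parts) > 3 and parts[3].strip() == "-1" else "+"
                out.append(
                    ProteinRecord(
                        id=rec.id,
                        sequence=str(rec.seq).rstrip("*"),
                        genomic_start=start,
                        genomic_end=end,
                        strand=strand,
                    )
                )
        return out

    return call


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; the seed reaches every stochastic part."""

    profiles: Mapping[str, DomainProfile]
    patterns: ModulePatternTable = field(default_factory=ModulePatternTable.default)
    chemistry: SubstrateChemistryTable = field(default_factory=SubstrateChemistryTable.default)
    refdb: ReferenceBlockDB = field(default_factory=ReferenceBlockDB)
    substrate_models: Mapping[str, SubstrateModel] = field(default_factory=dict)
    psm_regressors: Sequence[PSMRegressor] = field(default_factory=list)
    screening_db: ScreeningDB | None = None
    weights: Mapping[str, WeightConfig] = field(default_factory=default_weights)
    alignment_params: AlignmentParams = field(default_factory=AlignmentParams)
    window: int = 10_000
    top_n: int = 50
    seed: int = 0
    gene_caller: GeneCaller | None = None
    domain_counts: Mapping[str, Mapping[str, int]] = field(default_factory=dict)


@dataclass
class ClusterResult:
    cluster_id: str
    record_id: str
    genomic_start: int
    genomic_end: int
    cluster_type: str
    modules: list[Module]
    blocks: list[ModuleBlock]
    ordered_blocks: list[ModuleBlock]
    scaffold: Scaffold | None
    psm_vector: dict[str, int]
    ranked_matches: list[RankedMatch]
    log: list[str] = field(default_factory=list)


def _load_records(path: Path) -> list[tuple[str, list[ProteinRecord] | None, Path]]:
    """Parse input into per-record protein lists (None = DNA needing a caller)."""
    suffix = path.suffix.lower()
    out = []
    if suffix in {".gb", ".gbk", ".genbank"}:
        for rec in SeqIO.parse(str(path), "genbank"):
            out.append((rec.id, genome_proteins(rec), path))
    elif suffix in {".fa", ".fasta", ".faa", ".fna"}:
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no records parsed from {path}")
        alphabet = set("".join(str(r.seq)[:200].upper() for r in records))
        if alphabet <= set("ACGTNU"):
            for rec in records:
                out.append((rec.id, None, path))  # DNA: defer to gene caller
        else:
            proteins = [
                ProteinRecord(
                    id=r.id,
                    sequence=str(r.seq).rstrip("*"),
                    genomic_start=i * 10,
                    genomic_end=i * 10 + 1,
                )
                for i, r in enumerate(records)
            ]
            out.append((path.stem, proteins, path))
    else:
        raise ValueError(f"unsupported input format: {path}")
    if not out:
        raise ValueError(f"no records parsed from {path}")
    return out


def _cluster_proteins(
    proteins: Sequence[ProteinRecord], hits: Sequence[DomainHit], window: int
) -> list[list[ProteinRecord]]:
    """Group domain-bearing genes within ``window`` bp gaps into clusters."""
    with_hits = [p for p in proteins if any(h.protein_id == p.id for h in hits)]
    with_hits.sort(key=lambda p: p.genomic_start)
    clusters: list[list[ProteinRecord]] = []
    for p in with_hits:
        if clusters and p.genomic_start - clusters[-1][-1].genomic_end <= window:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    return clusters


def _translation_order(members: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Genomic order, with runs of minus-strand genes reversed so that the
    hit stream follows translation order."""
    ordered = sorted(members, key=lambda p: p.genomic_start)
    out: list[ProteinRecord] = []
    run: list[ProteinRecord] = []
    for p in ordered:
        if p.strand == "-":
            run.append(p)
        else:
            out.extend(reversed(run))
            run = []
            out.append(p)
    out.extend(reversed(run))
    return out


def _cluster_type(modules: Sequence[Module]) -> str:
    functional = [m for m in modules if m.functional_class in {"normal", "special"}]
    types = {m.type for m in functional}
    if types == {"PKS"}:
        return "PKS"
    if types == {"NRPS"}:
        return "NRPS"
    if not types:
        return "NRPS"
    return "Mixed"


def _predict_substrate(m: Module, proteins: Mapping[str, ProteinRecord],
                       models: Mapping[str, SubstrateModel]) -> str | None:
    model = models.get(m.substrate_domain)
    if model is None:
        return None
    hit = next((h for h in m.hits if h.domain == m.substrate_domain), None)
    if hit is None or hit.protein_id not in proteins:
        return None
    seq = proteins[hit.protein_id].sequence[hit.seq_start:hit.seq_end]
    label, _ = model.predict(seq, prealigned=False)
    return label


def run(input_path: str | Path, config: PipelineConfig) -> list[list[ClusterResult]]:
    """Run the full pipeline; one ClusterResult list per input record."""
    path = Path(input_path)
    results: list[list[ClusterResult]] = []
    for record_id, proteins, src in _load_records(path):
        if proteins is None:
            caller = config.gene_caller or prodigal_gene_caller()
            proteins = caller(src)
        results.append(_run_proteins(record_id, proteins, config))
    return results


def _run_proteins(
    record_id: str, proteins: Sequence[ProteinRecord], config: PipelineConfig
) -> list[ClusterResult]:
    hits = scan_proteins(proteins, config.profiles)
    protein_map = {p.id: p for p in proteins}
    clusters = _cluster_proteins(proteins, hits, config.window)
    out: list[ClusterResult] = []
    for ci, members in enumerate(clusters):
        log: list[str] = []
        ordered_members = _translation_order(members)
        member_ids = [p.id for p in ordered_members]
        cluster_hits: list[DomainHit] = []
        for pid in member_ids:
            cluster_hits.extend(
                sorted(
                    (h for h in hits if h.protein_id == pid),
                    key=lambda h: h.seq_start,
                )
            )
        # segment per gene, then merge complementary dangling modules
        modules: list[Module] = []
        for pid in member_ids:
            gene_hits = [h for h in cluster_hits if h.protein_id == pid]
            modules.extend(segment_into_modules(gene_hits, protein_map))
        modules = merge_cross_gene(modules, config.patterns)
        modules = classify_all(modules, config.patterns)
        log.append(f"{len(cluster_hits)} domain hits -> {len(modules)} modules")

        for m in modules:
            if m.functional_class == "normal" and m.substrate_domain in {"A", "AT"}:
                m.substrate = _predict_substrate(m, protein_map, config.substrate_models)

        blocks = build_blocks(modules, max_gap=config.window)
        ordered = order_blocks(blocks, config.refdb, config.alignment_params)
        ctype = _cluster_type(modules)

        scaffold_obj: Scaffold | None = None
        try:
            chains = []
            for block in ordered:
                chain = scaffold_mod.blocks_from_modules(block.modules, config.chemistry)
                if chain:
                    chains.append(chain)
            if chains:
                scaffold_obj = scaffold_mod.assemble(chains)
        except (ValueError, KeyError) as exc:
            log.append(f"scaffold assembly failed: {exc}")

        cluster_id = f"{record_id}_c{ci}"
        counts = config.domain_counts.get(cluster_id, {})
        psm_vector = (
            predict_psms(
                [r for r in config.psm_regressors if r.retained], counts
            )
            if config.psm_regressors
            else {}
        )
        if scaffold_obj is not None:
            scaffold_obj.psm_vector = psm_vector

        ranked: list[RankedMatch] = []
        if scaffold_obj is not None and config.screening_db is not None:
            weights = config.weights.get(ctype, config.weights.get("All"))
            ranked = screen(
                scaffold_obj.fragments,
                psm_vector,
                config.screening_db,
                weights=weights,
                top_n=config.top_n,
            )
        out.append(
            ClusterResult(
                cluster_id=cluster_id,
                record_id=record_id,
                genomic_start=min(p.genomic_start for p in members),
                genomic_end=max(p.genomic_end for p in members),
                cluster_type=ctype,
                modules=modules,
                blocks=blocks,
                ordered_blocks=ordered,
                scaffold=scaffold_obj,
                psm_vector=psm_vector,
                ranked_matches=ranked,
                log=log,
            )
        )
    return out
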