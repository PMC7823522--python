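"""Building-block generation and scaffold assembly.

Each functional module contributes one building block.  A polyketide (PK)
block is a two-carbon unit: a β-carbon whose oxidation state is set by the
module's reductive domains and an α-carbon carrying the substrate
substituent (plus any C-methylations).  A nonribosomal-peptide (NRP) block
is a peptide-bond nitrogen (the β-position, optionally N-methylated) and an
α-carbon with the amino-acid side chain (L by default, D after
epimerization).

Within a block the units are condensed head-to-tail into one linear
fragment; disconnected blocks yield separate fragments.  Because chain
extension forms the new C–C bond at the *previous* unit's thioester carbon,
the reductive domains of a module act on the carbonyl inherited from the
block before it: in the emitted chain that carbonyl is exactly the β-atom
written immediately upstream of the module's own α-carbon, so each module's
reduction profile is written to the β-position of its own two-carbon unit
while chemically modifying the previous building block's carbon.  Loading
modules contribute no β-carbon; terminal modules append a carboxyl (TE) or
hydroxyl (TD) cap.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from importlib.resources import files
from pathlib import Path
from typing import Sequence

from rdkit import Chem

from .modules import Module

BETA_STATES = {"ketone", "hydroxyl", "enoyl", "alkyl", "methoxy", "none"}


@dataclass(frozen=True)
class SubstrateChemistry:
    """Substrate label → α-substituent fragment (or a full unit template)."""

    label: str
    kind: str                 # PK | NRP
    side_chain: str = ""      # SMILES fragment attached to the α-carbon
    template: str = ""        # full β+α unit override (aryl acids, imino acids)


class SubstrateChemistryTable:
    def __init__(self, entries: Sequence[SubstrateChemistry]):
        self._by_label = {e.label: e for e in entries}

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    def __getitem__(self, label: str) -> SubstrateChemistry:
        if label not in self._by_label:
            raise KeyError(
                f"substrate {label!r} is not registered in the chemistry table"
            )
        return self._by_label[label]

    @classmethod
    def from_tsv(cls, text_or_path: str | Path) -> "SubstrateChemistryTable":
        text = (
            Path(text_or_path).read_text()
            if "\n" not in str(text_or_path)
            else str(text_or_path)
        )
        entries = []
        reader = csv.reader(io.StringIO(text), delimiter="\t")
        header = next(reader)
        for row in reader:
            if not row or not row[0].strip():
                continue
            row = row + [""] * (len(header) - len(row))
            entries.append(SubstrateChemistry(row[0], row[1], row[2], row[3]))
        # validate fragments parse
        for e in entries:
            probe = e.template or ("C" + (f"({e.side_chain})" if e.side_chain else ""))
            if Chem.MolFromSmiles(probe) is None:
                raise ValueError(f"chemistry table entry {e.label!r} does not parse")
        return cls(entries)

    @classmethod
    def default(cls) -> "SubstrateChemistryTable":
        return cls.from_tsv(
            files("scaffoldmine.data").joinpath("substrate_chemistry.tsv").read_text()
        )


@dataclass
class BuildingBlock:
    """One per-module molecular unit, prior to condensation."""

    kind: str                      # PK | NRP
    substrate: str = "malonyl"
    side_chain: str = ""
    template: str = ""
    alpha_methyls: int = 0
    beta_state: str = "none"       # PK β oxidation state; none for NRP/loading
    alpha_stereo: str = "unset"    # L | D | unset
    n_methylated: bool = False
    loading: bool = False
    terminal_cap: str = "none"     # none | carboxyl | hydroxyl

    def __post_init__(self):
        if self.beta_state not in BETA_STATES:
            raise ValueError(f"invalid beta state {self.beta_state!r}")
        if self.loading and self.kind == "PK" and self.beta_state != "none":
            raise ValueError("PK loading blocks have no β-carbon")
        if self.alpha_methyls == 2 and self.beta_state in {"enoyl", "alkyl"}:
            # gem-dimethyl α quenches the enolizable position: reduction to
            # the double bond or alkyl is chemically impossible
            raise ValueError("doubly α-methylated blocks allow only ketone/hydroxyl β")


@dataclass
class Scaffold:
    """Assembled scaffold: one SMILES fragment per connected block chain."""

    fragments: list[str]
    provenance: list[list[str]] = field(default_factory=list)
    psm_vector: dict[str, int] = field(default_factory=dict)

    @property
    def smiles(self) -> str:
        return ".".join(self.fragments)

    def as_mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)


GENERIC_PK_SUBSTRATE = "malonyl"  # trans-AT fallback: unsubstituted α


def module_to_building_block(
    m: Module,
    substrate: str | None = None,
    chemistry: SubstrateChemistryTable | None = None,
) -> BuildingBlock:
    """Translate a classified module (+ predicted substrate) into a block.

    Special modules without a substrate prediction (trans-AT in particular)
    fall back to an unsubstituted malonyl-like two-carbon unit.
    """
    if m.functional_class not in {"normal", "special"}:
        raise ValueError(
            f"module {m.arrangement} is {m.functional_class}; no building block"
        )
    chemistry = chemistry or SubstrateChemistryTable.default()
    label = substrate or m.substrate
    pk_like = m.type == "PKS" or (m.type == "mixed" and m.substrate_domain == "AT")
    if label is None:
        if pk_like:
            label = GENERIC_PK_SUBSTRATE
        else:
            raise ValueError(f"module {m.arrangement}: no substrate prediction")
    chem = chemistry[label]

    if chem.kind == "PK":
        beta = "none" if m.loading else m.reduction
        if beta == "ketone_star":
            beta = "ketone"  # reduction impossible without KR: stays a ketone
        methyls = 1 if label == "methylmalonyl" else 0
        if m.methylation == "alpha":
            methyls += 1
        if m.methylation == "O_methyl":
            beta = "methoxy"
        if methyls == 2 and beta in {"enoyl", "alkyl"}:
            beta = "ketone"
        return BuildingBlock(
            kind="PK",
            substrate=label,
            side_chain=chem.side_chain,
            template=chem.template,
            alpha_methyls=methyls,
            beta_state=beta,
            loading=m.loading,
            terminal_cap={"TE": "carboxyl", "TD": "hydroxyl", "none": "none"}[m.terminal],
        )
    # NRP
    stereo = "unset"
    if chem.side_chain and not chem.template:
        stereo = "D" if m.epimerized else "L"
    return BuildingBlock(
        kind="NRP",
        substrate=label,
        side_chain=chem.side_chain,
        template=chem.template,
        alpha_stereo=stereo,
        n_methylated=m.methylation == "N_methyl",
        loading=m.loading,
        terminal_cap={"TE": "carboxyl", "TD": "hydroxyl", "none": "none"}[m.terminal],
    )


def apply_previous_block_rule(
    blocks: list[BuildingBlock], modules: Sequence[Module]
) -> list[BuildingBlock]:
    """Place each module's β-modification on the chain position it acts on.

    Chain extension bonds the new α-carbon to the carbonyl inherited from
    the previous building block, so a module's reductive domains modify that
    inherited carbonyl.  In the emitted linear chain this carbonyl is the
    β-atom written directly upstream of the module's own α-carbon, i.e. the
    β-slot of the module's own unit; the first (loading) unit has no β and
    the terminal cap closes the final carboxyl.  This function re-derives
    every β-state from the module list so that externally constructed block
    lists obey the rule.
    """
    out = []
    for i, (blk, m) in enumerate(zip(blocks, modules)):
        if blk.kind != "PK":
            out.append(blk)
            continue
        if i == 0 and blk.loading:
            out.append(replace(blk, beta_state="none"))
            continue
        beta = m.reduction if m.reduction != "ketone_star" else "ketone"
        if m.methylation == "O_methyl":
            beta = "methoxy"
        if blk.alpha_methyls == 2 and beta in {"enoyl", "alkyl"}:
            beta = "ketone"
        out.append(replace(blk, beta_state=beta))
    return out


def _alpha_branches(blk: BuildingBlock) -> list[str]:
    branches = []
    if blk.side_chain:
        branches.append(blk.side_chain)
    branches.extend(["C"] * blk.alpha_methyls)
    return branches


def _emit_block(blk: BuildingBlock, first: bool, prev: BuildingBlock | None) -> str:
    """SMILES tokens for one block, upstream junction included."""
    parts = []
    if blk.kind == "NRP":
        if prev is not None:
            parts.append("C(=O)")  # amide carbonyl from the previous unit's carboxyl
        if blk.template:
            parts.append(blk.template)
            return "".join(parts)
        parts.append("N(C)" if blk.n_methylated else "N")
        alpha = {"L": "[C@@H]", "D": "[C@H]"}.get(blk.alpha_stereo, "C")
        branches = _alpha_branches(blk)
        parts.append(alpha + "".join(f"({b})" for b in branches))
        return "".join(parts)

    # PK block
    branches = _alpha_branches(blk)
    if first or blk.beta_state == "none":
        beta = ""
    elif blk.beta_state == "ketone":
        beta = "C(=O)"
    elif blk.beta_state == "hydroxyl":
        beta = "C(O)"
    elif blk.beta_state == "methoxy":
        beta = "C(OC)"
    elif blk.beta_state == "alkyl":
        beta = "C"
    elif blk.beta_state == "enoyl":
        # β=α double bond
        return "C=C" + "".join(f"({b})" for b in branches)
    else:
        raise ValueError(f"unhandled beta state {blk.beta_state}")
    if prev is not None and prev.kind == "NRP" and not beta:
        beta = "C(=O)" if blk.beta_state == "none" else beta
    return beta + "C" + "".join(f"({b})" for b in branches)


def assemble_chain(blocks: Sequence[BuildingBlock]) -> str:
    """Condense one ordered block chain into a canonical SMILES fragment."""
    if not blocks:
        raise ValueError("empty block chain")
    parts = []
    for i, blk in enumerate(blocks):
        parts.append(_emit_block(blk, first=(i == 0), prev=blocks[i - 1] if i else None))
    cap = blocks[-1].terminal_cap
    if cap == "carboxyl":
        parts.append("C(=O)O")
    elif cap == "hydroxyl":
        parts.append("CO")
    smiles = "".join(parts)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"assembled fragment does not parse: {smiles}")
    return Chem.MolToSmiles(mol)


def assemble(chains: Sequence[Sequence[BuildingBlock]],
             provenance: Sequence[Sequence[str]] | None = None) -> Scaffold:
    """Assemble every block chain; disconnected chains become separate
    fragments of the scaffold."""
    fragments = [assemble_chain(chain) for chain in chains if chain]
    prov = [list(p) for p in provenance] if provenance else [[] for _ in fragments]
    return Scaffold(fragments=fragments, provenance=prov)


def blocks_from_modules(
    modules: Sequence[Module],
    chemistry: SubstrateChemistryTable | None = None,
) -> list[BuildingBlock]:
    """Building blocks for the functional modules of one ordered chain."""
    chemistry = chemistry or SubstrateChemistryTable.default()
    usable = [m for m in modules if m.functional_class in {"normal", "special"}]
    blocks = [module_to_building_block(m, chemistry=chemistry) for m in usable]
    return apply_previous_block_rule(blocks, usable)
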