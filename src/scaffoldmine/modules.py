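"""Module architecture: parse ordered domain hits into biosynthetic modules.

A module is the set of domains that jointly incorporate and co-modify one
building block (e.g. ``KS-AT-KR-ACP`` or ``C-A-PCP``).  Segmentation closes a
module after the carrier domain (ACP/PCP/bACP) plus any immediately following
E/TE/TD domains — the boundary implied by how every common arrangement ends.
Classification assigns each module a functional class (normal / special /
non-functional), a chain type (PKS / NRPS / mixed), a β-reduction state, a
methylation flag, epimerization, trans-AT status, and loading/terminal roles.

Known arrangements are matched first against an editable pattern table
(first-match semantics); unseen arrangements fall back to compositional
rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib.resources import files
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .domains import CARRIER_LABELS, DomainHit, ProteinRecord

#: Domain labels the module grammar understands.
KNOWN_DOMAINS = {
    "ACP", "PCP", "bACP", "A", "AT", "C", "CAL", "cAL", "DH", "DH2", "DHt",
    "E", "ER", "KR", "KS", "KSQ", "TD", "TE", "cMT", "nMT", "oMT", "tAT_d",
}

PKS_CORE = {"KS", "KSQ", "AT", "tAT_d", "cAL", "CAL", "DH", "DH2", "DHt", "ER", "KR", "oMT"}
NRPS_CORE = {"C", "A", "E", "nMT"}
REDUCTIVE = {"KR", "DH", "DH2", "DHt", "ER"}
TRAILING = {"E", "TE", "TD"}

REDUCTION_STATES = {"ketone", "hydroxyl", "enoyl", "alkyl", "ketone_star", "none"}


@dataclass
class Module:
    """One biosynthetic module with its classification and modifications."""

    domains: list[str]
    type: str = "PKS"                      # PKS | NRPS | mixed
    functional_class: str = "non_functional"  # normal | special | non_functional
    substrate_domain: str = "none"         # AT | A | none
    reduction: str = "none"                # ketone|hydroxyl|enoyl|alkyl|ketone_star|none
    methylation: str = "none"              # none|alpha|O_methyl|N_methyl
    epimerized: bool = False
    trans_at: bool = False
    loading: bool = False
    terminal: str = "none"                 # none | TE | TD
    genomic_start: int = 0
    genomic_end: int = 0
    strand: str = "+"
    protein_ids: list[str] = field(default_factory=list)
    hits: list[DomainHit] = field(default_factory=list)
    substrate: str | None = None           # filled by substrate prediction

    @property
    def arrangement(self) -> str:
        return "-".join(self.domains)


@dataclass(frozen=True)
class PatternRule:
    domain_order: tuple[str, ...]
    functional: str      # N | S | NF
    type: str            # PKS | NRPS | Mixed
    modification: str    # Ketone|Hydroxyl|Enoyl|Alkyl|L|E|-


class ModulePatternTable:
    """Ordered arrangement → classification rules with first-match semantics."""

    def __init__(self, rules: Sequence[PatternRule]):
        self.rules = list(rules)

    @classmethod
    def from_tsv(cls, path_or_text: str | Path) -> "ModulePatternTable":
        text = (
            Path(path_or_text).read_text()
            if isinstance(path_or_text, Path) or "\n" not in str(path_or_text)
            else str(path_or_text)
        )
        rules = []
        for line in text.splitlines()[1:]:
            if not line.strip():
                continue
            parts = line.split("\t")
            rules.append(PatternRule(tuple(parts[0].split("-")), parts[1], parts[2], parts[3]))
        return cls(rules)

    @classmethod
    def default(cls) -> "ModulePatternTable":
        return cls.from_tsv(
            files("scaffoldmine.data").joinpath("module_patterns.tsv").read_text()
        )

    def match(self, domains: Sequence[str]) -> PatternRule | None:
        key = tuple(domains)
        for rule in self.rules:
            if rule.domain_order == key:
                return rule
        return None

    def arrangements(self) -> set[tuple[str, ...]]:
        return {r.domain_order for r in self.rules}


def segment_into_modules(
    hits: Sequence[DomainHit | str],
    proteins: Mapping[str, ProteinRecord] | None = None,
) -> list[Module]:
    """Partition an ordered hit list into modules.

    The boundary falls after a carrier domain plus any immediately following
    E/TE/TD; trailing domains with no carrier form a (non-functional) module
    of their own.  Input order is translation order; callers are responsible
    for presenting minus-strand genes already in translation order.
    """
    norm: list[DomainHit] = [
        h if isinstance(h, DomainHit) else DomainHit("_", h, 0, 1, 0.0) for h in hits
    ]
    modules: list[Module] = []
    current: list[DomainHit] = []
    i = 0
    while i < len(norm):
        current.append(norm[i])
        if norm[i].domain in CARRIER_LABELS:
            while i + 1 < len(norm) and norm[i + 1].domain in TRAILING:
                i += 1
                current.append(norm[i])
            modules.append(_module_from_hits(current, proteins))
            current = []
        i += 1
    if current:
        modules.append(_module_from_hits(current, proteins))
    return modules


def _module_from_hits(
    hits: list[DomainHit], proteins: Mapping[str, ProteinRecord] | None
) -> Module:
    pids = []
    for h in hits:
        if h.protein_id not in pids:
            pids.append(h.protein_id)
    start = end = 0
    strand = "+"
    if proteins:
        spans = [proteins[p] for p in pids if p in proteins]
        if spans:
            start = min(p.genomic_start for p in spans)
            end = max(p.genomic_end for p in spans)
            strand = spans[0].strand
    return Module(
        domains=[h.domain for h in hits],
        genomic_start=start,
        genomic_end=end,
        strand=strand,
        protein_ids=pids,
        hits=list(hits),
    )


def reduction_profile(domains: Sequence[str]) -> str:
    """β-reduction state from the reductive domain set.

    none → ketone; KR → hydroxyl; DH+KR → enoyl; DH+ER+KR → alkyl; any
    reductive domain present without KR (or an arrangement outside these
    combinations) cannot carry out the reduction → ketone_star.
    """
    present = {d for d in domains if d in REDUCTIVE}
    has_dh = bool(present & {"DH", "DH2", "DHt"})
    has_kr = "KR" in present
    has_er = "ER" in present
    if not present:
        return "ketone"
    if has_kr and not has_dh and not has_er:
        return "hydroxyl"
    if has_kr and has_dh and not has_er:
        return "enoyl"
    if has_kr and has_dh and has_er:
        return "alkyl"
    return "ketone_star"


def methylation_assignment(domains: Sequence[str], module_type: str) -> tuple[str, bool]:
    """Return (methylation flag, trans-AT inferred from cMT position).

    PKS carbon methyltransferases occupy three arrangements: between the
    reductive domains (cis), between AT and the carrier when no reduction
    domains are present (cis), and between the reductive domains and the
    carrier — the trans-AT signature, which flags the module as trans-AT
    even without a docking domain.  An O-methyltransferase acting after a
    lone KR converts the β-hydroxyl to methoxy; without reduction domains
    its role is too specialized to encode.  NRPS nitrogen methyltransferases
    (between A and the carrier) methylate the peptide-bond nitrogen; the
    rare NRPS cMT is ignored as too substrate-specific.
    """
    dlist = list(domains)
    reduction_present = any(d in REDUCTIVE for d in dlist)

    if "nMT" in dlist:
        i = dlist.index("nMT")
        before_a = "A" in dlist[:i]
        after_carrier = any(d in CARRIER_LABELS for d in dlist[i + 1:])
        if before_a and after_carrier:
            return "N_methyl", False

    if "oMT" in dlist and module_type in {"PKS", "mixed"}:
        present = {d for d in dlist if d in REDUCTIVE}
        if present == {"KR"}:
            return "O_methyl", False
        return "none", False

    if "cMT" in dlist:
        if module_type == "NRPS":
            return "none", False  # thiazostatin-like, too specific
        i = dlist.index("cMT")
        nxt = dlist[i + 1] if i + 1 < len(dlist) else None
        if not reduction_present:
            return "alpha", False  # between AT and carrier
        if nxt in CARRIER_LABELS:
            # between reductive domains and carrier: trans-AT arrangement
            return "alpha", True
        return "alpha", False  # between the reductive domains

    return "none", False


def classify_module(
    m: Module, patterns: ModulePatternTable | None = None
) -> Module:
    """Fill in class, type and modification fields of a segmented module."""
    unknown = [d for d in m.domains if d not in KNOWN_DOMAINS]
    if unknown:
        raise ValueError(f"unknown domain label(s): {unknown}")
    patterns = patterns or ModulePatternTable.default()
    dset = set(m.domains)

    # chain type
    has_pks = bool(dset & {"KS", "KSQ", "AT", "tAT_d"})
    has_nrps = bool(dset & {"C", "A"})
    carrier = next((d for d in m.domains if d in CARRIER_LABELS), None)
    if has_nrps and carrier in {"ACP", "bACP"} and not has_pks:
        mtype = "mixed"
    elif has_pks and carrier == "PCP" and not has_nrps:
        mtype = "mixed"
    elif has_pks and has_nrps:
        mtype = "mixed"
    elif has_nrps or (dset & NRPS_CORE and not dset & PKS_CORE):
        mtype = "NRPS"
    else:
        mtype = "PKS"

    substrate_domain = "AT" if "AT" in dset else ("A" if "A" in dset else "none")
    pk_like = mtype == "PKS" or (mtype == "mixed" and substrate_domain != "A")
    reduction = reduction_profile(m.domains) if pk_like else "none"
    methylation, trans_inferred = methylation_assignment(m.domains, mtype)
    trans_at = "tAT_d" in dset or trans_inferred

    rule = patterns.match(m.domains)
    if rule is not None:
        functional = {"N": "normal", "S": "special", "NF": "non_functional"}[rule.functional]
        mtype = {"PKS": "PKS", "NRPS": "NRPS", "Mixed": "mixed"}[rule.type]
        mod = rule.modification
        if mod in {"Ketone", "Hydroxyl", "Enoyl", "Alkyl"}:
            reduction = mod.lower()
        elif mod == "Ketone*":
            reduction = "ketone_star"
    else:
        if substrate_domain != "none":
            if carrier is None or reduction == "ketone_star":
                functional = "special"
            else:
                functional = "normal"
        elif "KS" in dset or "KSQ" in dset:
            # AT-less PKS extension: acts with a trans acyltransferase
            functional = "special"
            trans_at = True
        else:
            functional = "non_functional"

    if trans_at:
        mtype = "PKS"  # trans-AT is a PKS phenomenon
    epimerized = "E" in dset and mtype in {"NRPS", "mixed"}

    out = replace(
        m,
        type=mtype,
        functional_class=functional,
        substrate_domain=substrate_domain,
        reduction=reduction,
        methylation=methylation,
        epimerized=epimerized,
        trans_at=trans_at,
    )
    return loading_terminal_flags(out)


def loading_terminal_flags(m: Module) -> Module:
    """Set loading/terminal roles from domain content.

    PKS loading modules carry a KSQ domain or lack KS entirely; NRPS loading
    modules lack a condensation domain.  TE/TD mark terminal modules.
    """
    dset = set(m.domains)
    if m.type in {"PKS"} or (m.type == "mixed" and m.substrate_domain == "AT"):
        loading = "KSQ" in dset or "KS" not in dset
    else:
        loading = "C" not in dset
    terminal = "TE" if "TE" in dset else ("TD" if "TD" in dset else "none")
    return replace(m, loading=loading, terminal=terminal)


def classify_all(
    modules: Iterable[Module], patterns: ModulePatternTable | None = None
) -> list[Module]:
    patterns = patterns or ModulePatternTable.default()
    return [classify_module(m, patterns) for m in modules]


def merge_cross_gene(
    modules: list[Module], patterns: ModulePatternTable | None = None
) -> list[Module]:
    """Merge complementary dangling modules of adjacent same-strand genes.

    A gene ending mid-module (no carrier, e.g. ``…KS-AT``) followed by a gene
    whose leading module completes it (e.g. ``KR-ACP``) is merged only when
    the combined arrangement matches a known pattern.
    """
    patterns = patterns or ModulePatternTable.default()
    out: list[Module] = []
    i = 0
    while i < len(modules):
        cur = modules[i]
        nxt = modules[i + 1] if i + 1 < len(modules) else None
        if (
            nxt is not None
            and cur.strand == nxt.strand
            and not any(d in CARRIER_LABELS for d in cur.domains)
            and set(cur.protein_ids).isdisjoint(nxt.protein_ids)
            and patterns.match(cur.domains + nxt.domains) is not None
        ):
            merged = Module(
                domains=cur.domains + nxt.domains,
                genomic_start=min(cur.genomic_start, nxt.genomic_start),
                genomic_end=max(cur.genomic_end, nxt.genomic_end),
                strand=cur.strand,
                protein_ids=cur.protein_ids + nxt.protein_ids,
                hits=cur.hits + nxt.hits,
            )
            out.append(merged)
            i += 2
        else:
            out.append(cur)
            i += 1
    return out


def modules_to_tsv(modules: Iterable[Module]) -> str:
    cols = [
        "arrangement", "type", "functional_class", "substrate_domain", "reduction",
        "methylation", "epimerized", "trans_at", "loading", "terminal",
        "genomic_start", "genomic_end", "strand", "substrate",
    ]
    lines = ["\t".join(cols)]
    for m in modules:
        lines.append(
            "\t".join(
                str(v)
                for v in [
                    m.arrangement, m.type, m.functional_class, m.substrate_domain,
                    m.reduction, m.methylation, m.epimerized, m.trans_at, m.loading,
                    m.terminal, m.genomic_start, m.genomic_end, m.strand,
                    m.substrate or "",
                ]
            )
        )
    return "\n".join(lines) + "\n"
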