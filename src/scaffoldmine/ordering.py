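"""Module order inference for clusters that break co-linearity.

Modules are grouped into *blocks* — maximal runs of genomically adjacent,
same-strand modules, split after any internal terminal module.  The most
probable order of disjoint blocks is inferred by concatenating candidate
block pairs into hypothetical domain strings and locally aligning them
(Smith–Waterman, affine gaps, over the domain-label alphabet) against a
reference database of known single-block clusters: the highest-scoring
admissible pair is merged, the matrix is recomputed, and the process repeats
greedily.  Pairs that would put a loading block anywhere but first or a
terminal block anywhere but last are excluded, and two terminal blocks are
never merged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .modules import Module


@dataclass(frozen=True)
class AlignmentParams:
    """Integer local-alignment scores: match +1, mismatch −1, gap open −2
    (cost of the first gapped symbol), gap extend −1."""

    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1


@dataclass
class ModuleBlock:
    """A strand-contiguous run of modules; the unit of the ordering step."""

    modules: list[Module]
    block_id: str = ""
    genomic_order: int = 0

    @property
    def strand(self) -> str:
        return self.modules[0].strand

    @property
    def genomic_start(self) -> int:
        return min(m.genomic_start for m in self.modules)

    @property
    def genomic_end(self) -> int:
        return max(m.genomic_end for m in self.modules)

    @property
    def domain_string(self) -> list[str]:
        return [d for m in self.modules for d in m.domains]

    @property
    def has_start(self) -> bool:
        return self.modules[0].loading

    @property
    def has_end(self) -> bool:
        return self.modules[-1].terminal != "none"


@dataclass
class ReferenceBlockDB:
    """Known single-block clusters as flat ordered domain-label strings."""

    entries: list[tuple[str, list[str]]] = field(default_factory=list)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferenceBlockDB":
        entries = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("id\t"):
                continue
            ident, domstr = line.split("\t")
            entries.append((ident, domstr.split(",")))
        return cls(entries)

    def to_tsv(self) -> str:
        return "id\tdomains\n" + "\n".join(
            f"{i}\t{','.join(d)}" for i, d in self.entries
        ) + "\n"


def build_blocks(modules: Sequence[Module], max_gap: int | None = None) -> list[ModuleBlock]:
    """Group modules into maximal same-strand adjacent runs.

    A run is additionally split *after* a terminal module so that a terminal
    module can only ever sit at the end of its block.  ``max_gap`` optionally
    breaks runs whose consecutive modules are further apart genomically.
    """
    blocks: list[ModuleBlock] = []
    current: list[Module] = []

    def flush():
        if current:
            blocks.append(ModuleBlock(list(current)))
            current.clear()

    prev: Module | None = None
    for m in modules:
        split = (
            prev is not None
            and (
                m.strand != prev.strand
                or (max_gap is not None and m.genomic_start - prev.genomic_end > max_gap)
            )
        )
        if split:
            flush()
        current.append(m)
        if m.terminal != "none":
            flush()
        prev = m
    flush()
    for i, b in enumerate(blocks):
        b.block_id = f"B{i}"
        b.genomic_order = i
    return blocks


def sw_domain_score(
    a: Sequence[str], b: Sequence[str], params: AlignmentParams = AlignmentParams()
) -> int:
    """Best local-alignment score between two domain strings (affine gaps).

    Each domain label is one symbol.  Scores never drop below zero (local
    semantics), so disjoint strings score 0.
    """
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return 0
    neg = float("-inf")
    # M: a[i-1] aligned to b[j-1]; X: gap in b (a consumed); Y: gap in a.
    M = [[0] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]
    Y = [[neg] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = params.match if a[i - 1] == b[j - 1] else params.mismatch
            M[i][j] = max(0, M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + params.gap_open, X[i - 1][j] + params.gap_extend)
            Y[i][j] = max(M[i][j - 1] + params.gap_open, Y[i][j - 1] + params.gap_extend)
            if M[i][j] > best:
                best = M[i][j]
    return best


def _pair_admissible(first: ModuleBlock, second: ModuleBlock) -> bool:
    """Placement rules: loading blocks only at the front, terminal blocks only
    at the back, and two terminal blocks are never joined."""
    if first.has_end:
        return False
    if second.has_start:
        return False
    return True


def _best_ref_score(
    domains: list[str], refdb: ReferenceBlockDB, params: AlignmentParams
) -> int:
    return max((sw_domain_score(domains, ref, params) for _, ref in refdb.entries), default=0)


def order_blocks(
    blocks: Sequence[ModuleBlock],
    refdb: ReferenceBlockDB,
    params: AlignmentParams = AlignmentParams(),
    max_blocks: int = 10,
) -> list[ModuleBlock]:
    """Greedy iterative pairing of blocks guided by reference alignments.

    Every admissible ordered pair is scored as the best local alignment of
    the hypothetical concatenated domain string against the reference
    entries; the best pair is merged and the matrix recomputed with the
    merged block, until no admissible pair remains.  Unmergeable blocks stay
    disconnected.  Ties prefer the pair preserving genomic order, then the
    lexicographically smallest block-id pair.
    """
    work = list(blocks)
    if len(work) > max_blocks:
        warnings.warn(
            f"{len(work)} blocks exceed the ordering limit ({max_blocks}); "
            "returning genomic order"
        )
        return work
    if not refdb.entries:
        warnings.warn("empty reference database; returning blocks in genomic order")
        return work

    while len(work) > 1:
        candidates = []
        for i, bi in enumerate(work):
            for j, bj in enumerate(work):
                if i == j or not _pair_admissible(bi, bj):
                    continue
                concat = bi.domain_string + bj.domain_string
                score = _best_ref_score(concat, refdb, params)
                # among equal alignment scores, prefer the concatenation that
                # leaves fewer of its own domains unmatched (each unmatched
                # domain costs a point), then genomic order, then block ids
                wasted = len(concat) - score
                preserves_genomic = bi.genomic_order < bj.genomic_order
                candidates.append(
                    (-score, wasted, 0 if preserves_genomic else 1,
                     bi.block_id, bj.block_id, i, j)
                )
        if not candidates:
            break
        candidates.sort()
        *_, i, j = candidates[0]
        bi, bj = work[i], work[j]
        merged = ModuleBlock(
            bi.modules + bj.modules,
            block_id=min(bi.block_id, bj.block_id),
            genomic_order=min(bi.genomic_order, bj.genomic_order),
        )
        work = [b for idx, b in enumerate(work) if idx not in (i, j)] + [merged]
    return sorted(work, key=lambda b: (not b.has_start, b.genomic_order))
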