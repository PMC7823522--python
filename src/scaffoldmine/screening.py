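"""Compound-library screening of predicted scaffolds.

Candidates are preselected by Tanimoto similarity of circular Morgan
fingerprints (radius 3), then scored with a multi-fragment maximum-common-
substructure (MCS) algorithm that matches the scaffold's fragments into the
target one after another — each matched substructure is deleted from the
target before the next fragment is matched — and with a Bray–Curtis
similarity between predicted and observed postsynthetic-modification count
vectors.  The three components combine linearly into a mixed score with
per-cluster-type weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib.resources import files
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from rdkit import Chem, DataStructs
from rdkit.Chem import rdFMCS, rdFingerprintGenerator

from .psm import PSMPattern, count_psms

_FP_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=3, fpSize=2048)


def fingerprint(mol: Chem.Mol):
    return _FP_GEN.GetFingerprint(mol)


@dataclass
class CompoundRecord:
    id: str
    source: str
    smiles: str                      # canonical
    fp: object = field(repr=False, default=None)
    psm_vector: dict[str, int] = field(default_factory=dict)


@dataclass
class ScreeningDB:
    records: list[CompoundRecord]
    skipped: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def by_id(self, compound_id: str) -> CompoundRecord | None:
        return next((r for r in self.records if r.id == compound_id), None)


def _iter_library(path: Path) -> Iterable[tuple[str, str]]:
    """Yield (id, smiles) pairs from a SMILES or SDF file."""
    if path.suffix.lower() == ".sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                yield (f"{path.stem}_{i}", "")
            else:
                name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"{path.stem}_{i}"
                yield (name or f"{path.stem}_{i}", Chem.MolToSmiles(mol))
    else:
        for i, line in enumerate(path.read_text().splitlines()):
            if not line.strip():
                continue
            parts = line.split("\t")
            smiles = parts[0].strip()
            ident = parts[1].strip() if len(parts) > 1 else f"{path.stem}_{i}"
            yield (ident, smiles)


def ingest(
    libraries: Sequence[str | Path] | Mapping[str, Sequence[tuple[str, str]]],
    patterns: Sequence[PSMPattern] | None = None,
) -> ScreeningDB:
    """Build an in-memory screening database.

    ``libraries`` is either a list of SMILES/SDF file paths or a mapping of
    source name → (id, smiles) pairs.  Invalid molecules are skipped and
    counted; duplicates by canonical form are collapsed (first id wins);
    fingerprints and PSM count vectors are precomputed.
    """
    if isinstance(libraries, Mapping):
        sources = {name: list(pairs) for name, pairs in libraries.items()}
    else:
        sources = {str(p): list(_iter_library(Path(p))) for p in libraries}

    seen: dict[str, CompoundRecord] = {}
    skipped = 0
    for source, pairs in sources.items():
        for ident, smiles in pairs:
            mol = Chem.MolFromSmiles(smiles) if smiles else None
            if mol is None:
                skipped += 1
                continue
            canonical = Chem.MolToSmiles(mol)
            if canonical in seen:
                continue
            seen[canonical] = CompoundRecord(
                id=ident,
                source=source,
                smiles=canonical,
                fp=fingerprint(mol),
                psm_vector=count_psms(mol, patterns),
            )
    if not seen:
        raise ValueError("no valid molecules in the input libraries")
    if skipped:
        warnings.warn(f"skipped {skipped} invalid record(s) during ingestion")
    return ScreeningDB(records=list(seen.values()), skipped=skipped)


def tanimoto_topN(
    query_fragments: Sequence[str], db: ScreeningDB, n: int = 50
) -> list[tuple[CompoundRecord, float]]:
    """Descending Tanimoto over the fingerprint of the fragment union.

    Ties break by compound id, so the result is independent of insertion
    order.
    """
    query = Chem.MolFromSmiles(".".join(query_fragments))
    if query is None:
        raise ValueError("query fragments do not parse")
    qfp = fingerprint(query)
    scored = [(r, float(DataStructs.TanimotoSimilarity(qfp, r.fp))) for r in db.records]
    scored.sort(key=lambda t: (-t[1], t[0].id))
    return scored[:n]


# ---------------------------------------------------------------------------
# Extended multi-fragment MCS

def _mol_size(mol: Chem.Mol) -> int:
    return mol.GetNumAtoms() + mol.GetNumBonds()


def _delete_atoms(mol: Chem.Mol, atom_idx: Sequence[int]) -> Chem.Mol | None:
    from rdkit.rdBase import BlockLogs

    rw = Chem.RWMol(mol)
    for idx in sorted(atom_idx, reverse=True):
        rw.RemoveAtom(idx)
    out = rw.GetMol()
    with BlockLogs():
        try:
            Chem.SanitizeMol(out)
        except Exception:
            try:
                out.UpdatePropertyCache(strict=False)
                Chem.FastFindRings(out)
            except Exception:
                return None
    return out


def _mcs_matched(
    fragments: list[Chem.Mol], i: int, target: Chem.Mol, max_mcs_per_step: int
) -> int:
    """Best total matched atoms+bonds placing fragments[i:] into target."""
    if i >= len(fragments) or target.GetNumAtoms() == 0:
        return 0
    # branch: skip this fragment entirely
    best = _mcs_matched(fragments, i + 1, target, max_mcs_per_step)
    res = rdFMCS.FindMCS(
        [fragments[i], target],
        timeout=10,
        ringMatchesRingOnly=False,
        completeRingsOnly=False,
    )
    if res.canceled or res.numAtoms < 1 or not res.smartsString:
        return best
    query = Chem.MolFromSmarts(res.smartsString)
    if query is None:
        return best
    matches = target.GetSubstructMatches(query, uniquify=True)[:max_mcs_per_step]
    gained = res.numAtoms + res.numBonds
    for match in matches:
        remainder = _delete_atoms(target, match)
        if remainder is None:
            sub = 0
        else:
            sub = _mcs_matched(fragments, i + 1, remainder, max_mcs_per_step)
        best = max(best, gained + sub)
    return best


def extended_mcs_score(
    fragments: Sequence[str],
    target: str | Chem.Mol,
    max_mcs_per_step: int = 20,
    normalization: str = "mean",
) -> float:
    """Multi-fragment MCS score in [0, 1].

    Fragments are matched largest-first; after each match the matched
    substructure is removed from the target and the next fragment is matched
    against the remainder (up to ``max_mcs_per_step`` placements explored per
    step; best branch wins).  The matched atom+bond total is normalised by
    the query-side total and the target-side total — by default the
    arithmetic mean of the two fractions (``normalization="query"`` uses the
    query-side fraction alone).
    """
    if len(fragments) > 10:
        raise ValueError("at most 10 fragments are supported")
    frag_mols = []
    for smi in fragments:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"fragment does not parse: {smi!r}")
        frag_mols.append(mol)
    frag_mols.sort(key=_mol_size, reverse=True)
    target_mol = Chem.MolFromSmiles(target) if isinstance(target, str) else target
    if target_mol is None:
        raise ValueError("target does not parse")

    query_total = sum(_mol_size(m) for m in frag_mols)
    target_total = _mol_size(target_mol)
    if query_total == 0 or target_total == 0:
        return 0.0
    matched = _mcs_matched(frag_mols, 0, target_mol, max_mcs_per_step)
    q_frac = matched / query_total
    t_frac = matched / target_total
    if normalization == "query":
        return min(1.0, q_frac)
    return min(1.0, 0.5 * (q_frac + t_frac))


def bray_curtis_similarity(
    u: Mapping[str, int] | Sequence[int], v: Mapping[str, int] | Sequence[int]
) -> float:
    """1 − Bray–Curtis dissimilarity of two nonnegative count vectors.

    Identical vectors score 1; disjoint support scores 0.  Two all-zero
    vectors are identically empty and score 1.
    """
    if isinstance(u, Mapping) or isinstance(v, Mapping):
        keys = sorted(set(u) | set(v))
        uu = [u.get(k, 0) for k in keys]
        vv = [v.get(k, 0) for k in keys]
    else:
        if len(u) != len(v):
            raise ValueError("count vectors must have equal length")
        uu, vv = list(u), list(v)
    total = sum(abs(a) + abs(b) for a, b in zip(uu, vv))
    if total == 0:
        return 1.0
    diff = sum(abs(a - b) for a, b in zip(uu, vv))
    return 1.0 - diff / total


@dataclass(frozen=True)
class WeightConfig:
    """Mixed-score weights: mixed = a·similarity + b·MCS + c·PSM."""

    a: float
    b: float
    c: float

    def __post_init__(self):
        if min(self.a, self.b, self.c) < 0:
            raise ValueError("weights must be nonnegative")
        if self.a == self.b == self.c == 0:
            raise ValueError("at least one weight must be positive")


def default_weights() -> dict[str, WeightConfig]:
    text = files("scaffoldmine.data").joinpath("mixed_weights.tsv").read_text()
    out = {}
    for line in text.splitlines()[1:]:
        ctype, a, b, c = line.split("\t")
        out[ctype] = WeightConfig(float(a), float(b), float(c))
    return out


def mixed_score(sim: float, mcs: float, psm: float, w: WeightConfig) -> float:
    return w.a * sim + w.b * mcs + w.c * psm


@dataclass
class RankedMatch:
    compound_id: str
    source: str
    similarity_score: float
    mcs_score: float
    psm_score: float
    mixed_score: float
    rank: int = 0


def screen(
    query_fragments: Sequence[str],
    query_psms: Mapping[str, int],
    db: ScreeningDB,
    weights: WeightConfig | None = None,
    top_n: int = 50,
    max_mcs_per_step: int = 20,
) -> list[RankedMatch]:
    """Full screening: Tanimoto preselection of ``top_n`` compounds, MCS and
    PSM scoring of the preselection, mixed-score ranking."""
    weights = weights or default_weights()["All"]
    pre = tanimoto_topN(query_fragments, db, top_n)
    out = []
    for record, sim in pre:
        mcs = extended_mcs_score(query_fragments, record.smiles, max_mcs_per_step)
        psm = bray_curtis_similarity(query_psms, record.psm_vector)
        out.append(
            RankedMatch(
                record.id, record.source, sim, mcs, psm,
                mixed_score(sim, mcs, psm, weights),
            )
        )
    out.sort(key=lambda r: (-r.mixed_score, r.compound_id))
    for i, r in enumerate(out):
        r.rank = 1 + sum(1 for o in out if o.mixed_score > r.mixed_score)
    return out


def _competition_ranks(scores: Mapping[str, float]) -> dict[str, int]:
    values = sorted(scores.values(), reverse=True)
    return {cid: 1 + sum(1 for v in values if v > s) for cid, s in scores.items()}


@dataclass
class BenchmarkEntry:
    """One cluster prediction with its known true product."""

    query_fragments: list[str]
    query_psms: dict[str, int]
    true_compound_id: str
    cluster_type: str = "All"


@dataclass
class BenchmarkResult:
    #: entry index -> 1-based competition rank of the entry's true product
    ranks: dict[int, int]
    top10: float
    top50: float


def rank_benchmark(
    entries: Sequence[BenchmarkEntry],
    db: ScreeningDB,
    weights: WeightConfig | Mapping[str, WeightConfig] | None = None,
    max_mcs_per_step: int = 20,
) -> BenchmarkResult:
    """Rank every entry's true product in the full database.

    Ranks are 1-based competition ranks (ties share the best rank); Top-k
    fractions count entries whose true product ranks ≤ k.  Entries whose
    true product is absent from the database are excluded with a warning.
    """
    weight_map = weights if isinstance(weights, Mapping) else None
    single = weights if isinstance(weights, WeightConfig) else None
    components = _component_scores(entries, db, max_mcs_per_step)

    ranks: dict[int, int] = {}
    for idx, entry in enumerate(entries):
        if db.by_id(entry.true_compound_id) is None:
            warnings.warn(f"true product {entry.true_compound_id!r} not in db; excluded")
            continue
        w = single or (weight_map or default_weights()).get(
            entry.cluster_type, default_weights()["All"]
        )
        scores = {
            cid: mixed_score(sim, mcs, psm, w)
            for cid, (sim, mcs, psm) in components[idx].items()
        }
        ranks[idx] = _competition_ranks(scores)[entry.true_compound_id]
    n = len(ranks)
    if n == 0:
        raise ValueError("no benchmark entries with true product in the database")
    top10 = sum(1 for r in ranks.values() if r <= 10) / n
    top50 = sum(1 for r in ranks.values() if r <= 50) / n
    return BenchmarkResult(ranks, top10, top50)


def _component_scores(
    entries: Sequence[BenchmarkEntry], db: ScreeningDB, max_mcs_per_step: int
) -> list[dict[str, tuple[float, float, float]]]:
    out = []
    for entry in entries:
        query = Chem.MolFromSmiles(".".join(entry.query_fragments))
        qfp = fingerprint(query)
        comp = {}
        for record in db.records:
            sim = float(DataStructs.TanimotoSimilarity(qfp, record.fp))
            mcs = extended_mcs_score(entry.query_fragments, record.smiles, max_mcs_per_step)
            psm = bray_curtis_similarity(entry.query_psms, record.psm_vector)
            comp[record.id] = (sim, mcs, psm)
        out.append(comp)
    return out


def grid_search_weights(
    entries: Sequence[BenchmarkEntry],
    db: ScreeningDB,
    step: float = 0.1,
    max_mcs_per_step: int = 20,
) -> tuple[WeightConfig, list[tuple[WeightConfig, float]]]:
    """Exhaustive weight grid (each weight 0..1 in ``step`` increments).

    The criterion is the fraction of true products ranked in the Top 10;
    ties report the lexicographically smallest (a, b, c).  Returns the best
    config and the full (config, top10) list.
    """
    if not entries:
        raise ValueError("empty benchmark")
    components = _component_scores(entries, db, max_mcs_per_step)
    valid = [
        (i, e) for i, e in enumerate(entries) if db.by_id(e.true_compound_id) is not None
    ]
    if not valid:
        raise ValueError("no benchmark entries with true product in the database")

    n_steps = int(round(1.0 / step))
    levels = [round(i * step, 10) for i in range(n_steps + 1)]
    results = []
    for a in levels:
        for b in levels:
            for c in levels:
                if a == b == c == 0:
                    continue
                w = WeightConfig(a, b, c)
                hits = 0
                for idx, entry in valid:
                    scores = {
                        cid: mixed_score(s, m, p, w)
                        for cid, (s, m, p) in components[idx].items()
                    }
                    if _competition_ranks(scores)[entry.true_compound_id] <= 10:
                        hits += 1
                results.append((w, hits / len(valid)))
    best = max(results, key=lambda t: (t[1], (-t[0].a, -t[0].b, -t[0].c)))
    # lexicographically smallest among ties
    top = max(r[1] for r in results)
    best = min(
        (w for w, v in results if v == top), key=lambda w: (w.a, w.b, w.c)
    )
    return best, results


def results_to_tsv(matches: Iterable[RankedMatch]) -> str:
    lines = ["compound_id\tsource\tsimilarity\tmcs\tpsm\tmixed\trank"]
    for m in matches:
        lines.append(
            f"{m.compound_id}\t{m.source}\t{m.similarity_score:.4f}\t"
            f"{m.mcs_score:.4f}\t{m.psm_score:.4f}\t{m.mixed_score:.4f}\t{m.rank}"
        )
    return "\n".join(lines) + "\n"
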