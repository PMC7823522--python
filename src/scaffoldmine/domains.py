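"""Biosynthetic domain detection with profile-HMMs.

Profiles are built from labeled domain sequence sets (one profile per domain
label), per-profile bit-score reporting thresholds (``domT``) are calibrated
as the minimum score with which a profile detects its own training members,
and proteins are scanned against the calibrated profile set.  A 5-fold
cross-validation harness benchmarks profile separability the same way the
shipped threshold table was derived.

Scores are per-domain bit scores throughout (HMMER ``domT`` semantics), not
e-values: bit scores are independent of database size and therefore give
stable thresholds.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from importlib.resources import files
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pyhmmer
from pyhmmer.easel import Alphabet, DigitalSequenceBlock, TextMSA, TextSequence

from .aligners import AlignerContract, default_aligner

AMINO = Alphabet.amino()

#: Valid residue alphabet for protein records (20 canonical + X for unknown).
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

#: Carrier-domain label equivalence: ACP and bACP are frequently confused by
#: the profiles but play the identical chain-tethering role downstream, so
#: both (plus PCP for NRPS) map onto a single carrier role.
CARRIER_LABELS = {"ACP", "PCP", "bACP"}
LABEL_EQUIVALENCE = {"bACP": "ACP"}


@dataclass(frozen=True)
class ProteinRecord:
    """A (predicted) protein gene product with its genomic placement."""

    id: str
    sequence: str
    gene_locus: str = ""
    genomic_start: int = 0
    genomic_end: int = 0
    strand: str = "+"

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence.upper()) - AA_ALPHABET
        if bad:
            raise ValueError(f"protein {self.id!r}: invalid residues {sorted(bad)}")
        if self.genomic_start > self.genomic_end:
            raise ValueError(f"protein {self.id!r}: start > end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"protein {self.id!r}: strand must be '+' or '-'")


@dataclass
class DomainProfile:
    """A profile-HMM for one domain label plus its detection threshold."""

    name: str
    hmm: pyhmmer.plan7.HMM
    threshold: float = 0.0


@dataclass(frozen=True, order=True)
class DomainHit:
    """A retained domain detection on a protein (0-based half-open coords)."""

    protein_id: str
    domain: str
    seq_start: int
    seq_end: int
    bit_score: float

    def __post_init__(self):
        if self.seq_start >= self.seq_end:
            raise ValueError("hit start must be < end")

    @property
    def length(self) -> int:
        return self.seq_end - self.seq_start


@dataclass
class LabeledDomainSet:
    """Training sequences with their true domain labels."""

    entries: list[tuple[str, str]] = field(default_factory=list)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "LabeledDomainSet":
        """Read FASTA where the label follows a ``|`` in the header."""
        entries = []
        name, chunks = None, []
        for line in Path(path).read_text().splitlines():
            if line.startswith(">"):
                if name is not None:
                    entries.append(("".join(chunks), name.rsplit("|", 1)[1].strip()))
                name, chunks = line[1:].strip(), []
            elif line.strip():
                chunks.append(line.strip())
        if name is not None:
            entries.append(("".join(chunks), name.rsplit("|", 1)[1].strip()))
        return cls(entries)

    def by_label(self) -> dict[str, list[str]]:
        grouped: dict[str, list[str]] = defaultdict(list)
        for seq, label in self.entries:
            grouped[label].append(seq)
        return dict(grouped)


def _make_pipeline() -> pyhmmer.plan7.Pipeline:
    # Max-sensitivity settings: heuristic prefilters are disabled and hits are
    # reported by bit score so that short toy profiles behave like full-length
    # ones; thresholding is done by the caller against the calibrated domT.
    return pyhmmer.plan7.Pipeline(
        AMINO, bias_filter=False, F1=1.0, F2=1.0, F3=1.0, T=0.0, domT=0.0
    )


def _digital_block(sequences: Sequence[str]) -> DigitalSequenceBlock:
    texts = [
        TextSequence(name=str(i).encode(), sequence=s.upper())
        for i, s in enumerate(sequences)
    ]
    return DigitalSequenceBlock(AMINO, [t.digitize(AMINO) for t in texts])


def _search(hmm: pyhmmer.plan7.HMM, sequences: Sequence[str]) -> dict[int, list[tuple[int, int, float]]]:
    """Run one profile over sequences; return per-sequence domain envelopes.

    Keys are sequence indices; values are (start, end, bit_score) tuples in
    0-based half-open protein coordinates.
    """
    if not sequences:
        return {}
    hits = _make_pipeline().search_hmm(hmm, _digital_block(sequences))
    out: dict[int, list[tuple[int, int, float]]] = defaultdict(list)
    for hit in hits:
        name = hit.name
        idx = int(name.decode() if isinstance(name, bytes) else name)
        for dom in hit.domains:
            out[idx].append((dom.env_from - 1, dom.env_to, dom.score))
    return dict(out)


def build_profiles(
    labeled: LabeledDomainSet, aligner: AlignerContract | None = None
) -> dict[str, DomainProfile]:
    """Build one profile-HMM per domain label.

    Each label's sequences are multiply aligned (via the pluggable aligner)
    and turned into a profile; thresholds start at 0 (uncalibrated).
    """
    aligner = aligner or default_aligner()
    profiles: dict[str, DomainProfile] = {}
    for label, seqs in labeled.by_label().items():
        if len(seqs) < 2:
            raise ValueError(
                f"label {label!r} has {len(seqs)} sequence(s); at least 2 required"
            )
        aligned = aligner.align(seqs)
        msa = TextMSA(
            name=label.encode(),
            sequences=[
                TextSequence(name=f"{label}_{i}".encode(), sequence=a.upper())
                for i, a in enumerate(aligned)
            ],
        )
        builder = pyhmmer.plan7.Builder(AMINO)
        hmm, _, _ = builder.build_msa(msa.digitize(AMINO), pyhmmer.plan7.Background(AMINO))
        profiles[label] = DomainProfile(name=label, hmm=hmm)
    return profiles


def calibrate_thresholds(
    profiles: Mapping[str, DomainProfile], labeled: LabeledDomainSet
) -> dict[str, DomainProfile]:
    """Set each profile's domT to the minimum self-detection bit score.

    After calibration, rescanning the calibration set yields recall 1.0 for
    every label whose members were all detected by their own profile; a
    member not hit at all triggers a warning and is excluded from the
    minimum.
    """
    grouped = labeled.by_label()
    for label, profile in profiles.items():
        seqs = grouped.get(label, [])
        if not seqs:
            continue
        found = _search(profile.hmm, seqs)
        scores = []
        for i in range(len(seqs)):
            if i in found:
                scores.append(max(s for _, _, s in found[i]))
            else:
                warnings.warn(
                    f"profile {label!r}: training sequence {i} not detected; "
                    "threshold derived from remaining hits"
                )
        if scores:
            profile.threshold = float(min(scores))
        else:
            warnings.warn(f"profile {label!r}: no training sequence detected")
            profile.threshold = 0.0
    return dict(profiles)


def _resolve_overlaps(hits: list[DomainHit]) -> list[DomainHit]:
    """Drop hits overlapping a better hit by >50% of the shorter hit.

    Higher bit score wins; exact ties break alphabetically by domain label.
    """
    order = sorted(hits, key=lambda h: (-h.bit_score, h.domain, h.seq_start))
    kept: list[DomainHit] = []
    for cand in order:
        clash = False
        for k in kept:
            overlap = min(cand.seq_end, k.seq_end) - max(cand.seq_start, k.seq_start)
            if overlap > 0.5 * min(cand.length, k.length):
                clash = True
                break
        if not clash:
            kept.append(cand)
    return sorted(kept, key=lambda h: h.seq_start)


def scan_proteins(
    proteins: Sequence[ProteinRecord], profiles: Mapping[str, DomainProfile]
) -> list[DomainHit]:
    """Scan proteins with all calibrated profiles.

    Only hits at or above each profile's threshold are retained; overlapping
    hits are resolved in favour of the higher bit score; output is ordered by
    protein genomic position, then domain start within the protein.
    """
    if not proteins:
        return []
    seqs = [p.sequence for p in proteins]
    per_protein: dict[int, list[DomainHit]] = defaultdict(list)
    for label, profile in profiles.items():
        for idx, envs in _search(profile.hmm, seqs).items():
            for start, end, score in envs:
                if score >= profile.threshold:
                    per_protein[idx].append(
                        DomainHit(proteins[idx].id, label, start, end, score)
                    )
    ordered_idx = sorted(
        range(len(proteins)), key=lambda i: (proteins[i].genomic_start, i)
    )
    out: list[DomainHit] = []
    for idx in ordered_idx:
        out.extend(_resolve_overlaps(per_protein.get(idx, [])))
    return out


@dataclass
class CrossValidationResult:
    per_label: dict[str, dict[str, float]]
    macro: dict[str, float]
    micro: dict[str, float]
    weighted: dict[str, float]
    confusion: dict[tuple[str, str], int]


def crossvalidate_profiles(
    labeled: LabeledDomainSet,
    k: int = 5,
    seed: int = 0,
    aligner: AlignerContract | None = None,
) -> CrossValidationResult:
    """Stratified k-fold cross-validation of profile separability.

    Held-out sequences are classified by the profile with the highest bit
    score; labels with fewer than ``k`` members are skipped with a warning.
    Fold assignment is seeded and independent of label order.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    aligner = aligner or default_aligner()
    grouped = labeled.by_label()
    usable = {}
    for label in sorted(grouped):
        if len(grouped[label]) < k:
            warnings.warn(f"label {label!r} has < {k} sequences; skipped in CV")
        else:
            usable[label] = grouped[label]

    rng = np.random.default_rng(seed)
    folds: dict[str, np.ndarray] = {}
    for label, seqs in usable.items():
        assign = np.arange(len(seqs)) % k
        rng.shuffle(assign)
        folds[label] = assign

    y_true: list[str] = []
    y_pred: list[str] = []
    for fold in range(k):
        train = LabeledDomainSet(
            [
                (s, label)
                for label, seqs in usable.items()
                for i, s in enumerate(seqs)
                if folds[label][i] != fold
            ]
        )
        test = [
            (s, label)
            for label, seqs in usable.items()
            for i, s in enumerate(seqs)
            if folds[label][i] == fold
        ]
        profiles = build_profiles(train, aligner)
        test_seqs = [s for s, _ in test]
        best_scores = {i: (-np.inf, "none") for i in range(len(test_seqs))}
        for label, profile in profiles.items():
            for idx, envs in _search(profile.hmm, test_seqs).items():
                top = max(s for _, _, s in envs)
                if top > best_scores[idx][0]:
                    best_scores[idx] = (top, label)
        for i, (_, true_label) in enumerate(test):
            y_true.append(true_label)
            y_pred.append(best_scores[i][1])

    return _tabulate_cv(y_true, y_pred, sorted(usable))


def _tabulate_cv(y_true: list[str], y_pred: list[str], labels: list[str]) -> CrossValidationResult:
    from sklearn.metrics import precision_recall_fscore_support

    per_label = {}
    p, r, f, s = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    for i, label in enumerate(labels):
        per_label[label] = {
            "precision": float(p[i]),
            "recall": float(r[i]),
            "f1": float(f[i]),
            "support": int(s[i]),
        }
    averages = {}
    for avg in ("macro", "micro", "weighted"):
        pa, ra, fa, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=labels, average=avg, zero_division=0
        )
        averages[avg] = {"precision": float(pa), "recall": float(ra), "f1": float(fa)}
    confusion: dict[tuple[str, str], int] = defaultdict(int)
    for t, pr in zip(y_true, y_pred):
        confusion[(t, pr)] += 1
    return CrossValidationResult(
        per_label, averages["macro"], averages["micro"], averages["weighted"], dict(confusion)
    )


# ---------------------------------------------------------------------------
# Persistence: HMMER3 text profiles + a TSV threshold sidecar.

def save_profiles(profiles: Mapping[str, DomainProfile], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "profiles.hmm", "wb") as fh:
        for name in sorted(profiles):
            profiles[name].hmm.write(fh, binary=False)
    with open(directory / "thresholds.tsv", "w") as fh:
        fh.write("name\tdomT\n")
        for name in sorted(profiles):
            fh.write(f"{name}\t{profiles[name].threshold}\n")


def load_profiles(directory: str | Path) -> dict[str, DomainProfile]:
    directory = Path(directory)
    thresholds = {}
    for line in (directory / "thresholds.tsv").read_text().splitlines()[1:]:
        name, t = line.split("\t")
        thresholds[name] = float(t)
    profiles = {}
    with pyhmmer.plan7.HMMFile(directory / "profiles.hmm") as fh:
        for hmm in fh:
            name = hmm.name.decode() if isinstance(hmm.name, bytes) else hmm.name
            profiles[name] = DomainProfile(name, hmm, thresholds.get(name, 0.0))
    return profiles


def default_threshold_table() -> dict[str, float]:
    """The shipped per-domain domT defaults (bit scores).

    The KSQ entry reuses the KS threshold: KSQ profiles are user-supplied
    (the loading-module keto-synthase variant is not separately labeled in
    typical training annotations) and are thresholded like KS.
    """
    text = files("scaffoldmine.data").joinpath("domain_thresholds.tsv").read_text()
    out = {}
    for line in text.splitlines()[1:]:
        name, _, domt = line.split("\t")
        out[name] = float(domt)
    return out


def hits_to_tsv(hits: Iterable[DomainHit]) -> str:
    lines = ["protein_id\tdomain\tstart\tend\tbit_score"]
    for h in hits:
        lines.append(f"{h.protein_id}\t{h.domain}\t{h.seq_start}\t{h.seq_end}\t{h.bit_score:.2f}")
    return "\n".join(lines) + "\n"
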