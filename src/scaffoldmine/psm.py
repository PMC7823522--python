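"""Postsynthetic modification (PSM) counting and prediction.

Seven PSM classes (glycosylation, chlorination, spiroketal, disulfide,
nitro, 6-ring and 5-ring ether formation) are counted in molecules by SMARTS
substructure search with symmetry-deduplicated matches.  Per-cluster Pfam
domain counts are correlated with PSM counts (Pearson), positively
correlating domains intersected with a curated allow-list become regression
features, and per-PSM linear models are trained with 5-fold CV.  A model is
retained only when its pooled out-of-fold R² beats the zero-prediction
baseline (the R² of always predicting no PSM).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib.resources import files
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem
from scipy import stats
from sklearn.linear_model import LinearRegression
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold


@dataclass(frozen=True)
class PSMPattern:
    name: str
    smarts: str

    @property
    def query(self) -> Chem.Mol:
        q = Chem.MolFromSmarts(self.smarts)
        if q is None:
            raise ValueError(f"SMARTS for {self.name!r} does not parse: {self.smarts}")
        return q


def default_patterns() -> list[PSMPattern]:
    text = files("scaffoldmine.data").joinpath("psm_smarts.tsv").read_text()
    out = []
    for line in text.splitlines()[1:]:
        name, smarts = line.split("\t")
        out.append(PSMPattern(name, smarts))
    return out


def patterns_from_tsv(path: str | Path) -> list[PSMPattern]:
    out = []
    for line in Path(path).read_text().splitlines()[1:]:
        if line.strip():
            name, smarts = line.split("\t")
            out.append(PSMPattern(name, smarts))
    return out


def count_psms(
    molecule: str | Chem.Mol, patterns: Sequence[PSMPattern] | None = None
) -> dict[str, int]:
    """Count symmetry-deduplicated substructure matches per PSM pattern.

    Matches covering the same atom set (ring automorphisms in particular)
    count once.
    """
    mol = Chem.MolFromSmiles(molecule) if isinstance(molecule, str) else molecule
    if mol is None:
        raise ValueError(f"molecule does not parse: {molecule!r}")
    patterns = patterns if patterns is not None else default_patterns()
    counts = {}
    for pat in patterns:
        matches = mol.GetSubstructMatches(pat.query, uniquify=True)
        counts[pat.name] = len({frozenset(m) for m in matches})
    return counts


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Pearson correlation; None when undefined (short input, zero variance)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)


def default_domain_allowlist() -> dict[str, list[str]]:
    """The shipped per-PSM curated Pfam feature domains."""
    text = files("scaffoldmine.data").joinpath("psm_domains.tsv").read_text()
    out: dict[str, list[str]] = {}
    for line in text.splitlines()[1:]:
        psm, pfam, _desc, _r = line.split("\t")
        out.setdefault(psm, []).append(pfam)
    return out


def select_domains(
    corr_table: Mapping[str, Mapping[str, float | None]],
    curation_list: Mapping[str, Sequence[str]],
) -> dict[str, list[str]]:
    """Positively correlating domains intersected with the curated allow-list.

    ``corr_table``: psm name → {domain id → pearson r (None if undefined)}.
    """
    out: dict[str, list[str]] = {}
    for psm_name, domain_rs in corr_table.items():
        allowed = set(curation_list.get(psm_name, []))
        out[psm_name] = [
            d for d, r in sorted(domain_rs.items()) if r is not None and r > 0 and d in allowed
        ]
    return out


def correlate(
    domain_counts: Mapping[str, Sequence[float]],
    psm_counts: Mapping[str, Sequence[float]],
) -> dict[str, dict[str, float | None]]:
    """Pearson r of every (PSM, domain) count-vector pair across clusters."""
    out: dict[str, dict[str, float | None]] = {}
    for psm_name, y in psm_counts.items():
        out[psm_name] = {d: pearson_r(x, y) for d, x in domain_counts.items()}
    return out


def baseline_r2(y: Sequence[float]) -> float:
    """R² of the constant-zero predictor ("no PSM predicted at all")."""
    y = np.asarray(y, dtype=float)
    if np.all(y == y[0]):
        raise ValueError("baseline R² undefined for constant targets")
    return float(r2_score(y, np.zeros_like(y)))


@dataclass
class PSMRegressor:
    """A per-PSM linear count model with its CV and baseline scores."""

    psm_name: str
    feature_domains: list[str]
    coefficients: list[float]
    intercept: float
    cv_r2: float
    baseline_r2: float
    retained: bool = field(init=False)

    def __post_init__(self):
        self.retained = self.cv_r2 > self.baseline_r2

    def predict(self, domain_counts: Mapping[str, float]) -> int:
        """Rounded, zero-clipped count; missing feature domains count as 0."""
        val = self.intercept + sum(
            c * float(domain_counts.get(d, 0))
            for c, d in zip(self.coefficients, self.feature_domains)
        )
        return max(0, int(round(val)))

    def to_dict(self) -> dict:
        return {
            "psm_name": self.psm_name,
            "feature_domains": self.feature_domains,
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "cv_r2": self.cv_r2,
            "baseline_r2": self.baseline_r2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PSMRegressor":
        return cls(
            d["psm_name"], d["feature_domains"], d["coefficients"],
            d["intercept"], d["cv_r2"], d["baseline_r2"],
        )


def train_psm_regressor(
    psm_name: str,
    features: Mapping[str, Sequence[float]],
    psm_counts: Sequence[float],
    k: int = 5,
    seed: int = 0,
) -> PSMRegressor:
    """Fit a linear count model and score it against the zero baseline.

    ``cv_r2`` is the pooled out-of-fold R²; the baseline is the zero
    predictor evaluated on the identical folds.  The model is marked
    retained only when it beats the baseline.
    """
    domains = sorted(features)
    X = np.column_stack([np.asarray(features[d], dtype=float) for d in domains])
    y = np.asarray(psm_counts, dtype=float)
    if len(y) < 2 * k:
        raise ValueError(f"need at least {2 * k} samples for {k}-fold CV")
    if np.all(y == 0):
        raise ValueError("all-zero targets: baseline undefined, model rejected")

    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    pooled_pred = np.empty_like(y)
    for train_idx, test_idx in kf.split(X):
        reg = LinearRegression().fit(X[train_idx], y[train_idx])
        pooled_pred[test_idx] = reg.predict(X[test_idx])
    cv = float(r2_score(y, pooled_pred))
    base = float(r2_score(y, np.zeros_like(y)))

    final = LinearRegression().fit(X, y)
    return PSMRegressor(
        psm_name=psm_name,
        feature_domains=domains,
        coefficients=[float(c) for c in final.coef_],
        intercept=float(final.intercept_),
        cv_r2=cv,
        baseline_r2=base,
    )


def predict_psms(
    regressors: Sequence[PSMRegressor], domain_counts: Mapping[str, float]
) -> dict[str, int]:
    """Predicted PSM count vector from per-cluster domain counts.

    Non-retained regressors predict 0 (with a warning the first time).
    """
    out = {}
    for reg in regressors:
        if not reg.retained:
            warnings.warn(f"regressor {reg.psm_name!r} did not beat baseline; predicting 0")
            out[reg.psm_name] = 0
        else:
            out[reg.psm_name] = reg.predict(domain_counts)
    return out


def save_regressors(regressors: Sequence[PSMRegressor], path: str | Path) -> None:
    Path(path).write_text(json.dumps([r.to_dict() for r in regressors], indent=1))


def load_regressors(path: str | Path) -> list[PSMRegressor]:
    return [PSMRegressor.from_dict(d) for d in json.loads(Path(path).read_text())]


def read_domain_count_tsv(path: str | Path) -> dict[str, dict[str, int]]:
    """Pfam count input: TSV of (cluster_id, domain_id, count)."""
    out: dict[str, dict[str, int]] = {}
    for line in Path(path).read_text().splitlines()[1:]:
        if line.strip():
            cluster, domain, count = line.split("\t")
            out.setdefault(cluster, {})[domain] = int(count)
    return out
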