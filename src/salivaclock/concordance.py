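"""Replicate/twin/unrelated concordance, pair clustering, and drift-vs-age.

Monozygotic co-twins start life with near-identical methylomes; comparing
pairwise sample correlations within replicate, twin and unrelated classes
quantifies how much of the array signal is biological.  Epigenetic drift is
probed by asking whether intra-pair distance grows with the pair's age.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average as _average_linkage
from scipy.spatial.distance import squareform

from .io import BetaMatrix, SampleSheet, ValidationError
from .preprocess import collapse_replicates

__all__ = [
    "ConcordanceReport",
    "DriftResult",
    "concordance_report",
    "drift_vs_age",
    "pair_clustering_fraction",
]

DRIFT_METRICS = ("one_minus_pearson", "euclidean", "manhattan")


@dataclass
class ConcordanceReport:
    """Pairwise Pearson correlations split by relationship class."""

    groups: dict[str, list[float]]
    comparisons: dict[str, float]  # e.g. "replicate_vs_unrelated" -> two-sided p
    warnings: list[str] = field(default_factory=list)

    def median(self, group: str) -> float:
        return float(np.median(self.groups[group]))

    def range(self, group: str) -> tuple[float, float]:
        vals = self.groups[group]
        return float(min(vals)), float(max(vals))

    def to_dict(self) -> dict:
        out = {"comparisons": self.comparisons, "warnings": self.warnings}
        for g, vals in self.groups.items():
            out[g] = {
                "n": len(vals),
                "median_r": self.median(g) if vals else None,
                "range_r": list(self.range(g)) if vals else None,
            }
        return out


@dataclass
class DriftResult:
    metric: str
    pair_ids: list[str]
    distances: np.ndarray
    ages: np.ndarray
    r: float
    p: float
    estimable: bool

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "r": None if not self.estimable else self.r,
            "p": None if not self.estimable else self.p,
            "estimable": self.estimable,
            "n_pairs": len(self.pair_ids),
        }


def _relationships(sheet: SampleSheet, sample_ids: list[str]) -> tuple[dict, dict]:
    """Map each column to its individual and each individual to its pair."""
    meta = sheet.data.set_index("sample_id")
    individual = {}
    pair_of = {}
    for sid in sample_ids:
        row = meta.loc[sid]
        rep = row["replicate_of"]
        ind = sid if rep is None or (isinstance(rep, float) and np.isnan(rep)) or rep == "" else str(rep)
        individual[sid] = ind
        pid = meta.loc[ind, "pair_id"] if ind in meta.index else None
        pair_of[ind] = None if pid is None or (isinstance(pid, float) and np.isnan(pid)) else str(pid)
    return individual, pair_of


def concordance_report(bm: BetaMatrix, sheet: SampleSheet) -> ConcordanceReport:
    """All pairwise sample correlations, classed replicate / twin / unrelated.

    Replicate: two arrays of the same individual.  Twin: arrays of the two
    co-twins of a pair.  Unrelated: different individuals from different
    pairs.  Each class is compared against the unrelated class with a
    two-sided Wilcoxon rank-sum test (exact for small tie-free groups,
    normal approximation with tie correction otherwise).
    """
    ids = bm.sample_ids
    if len(ids) < 2:
        raise ValidationError("concordance needs >= 2 samples")
    individual, pair_of = _relationships(sheet, ids)
    C = np.corrcoef(bm.values.T)
    groups: dict[str, list[float]] = {"replicate": [], "twin": [], "unrelated": []}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            ia, ib = individual[a], individual[b]
            if ia == ib:
                cls = "replicate"
            elif pair_of[ia] is not None and pair_of[ia] == pair_of[ib]:
                cls = "twin"
            else:
                cls = "unrelated"
            groups[cls].append(float(C[i, j]))

    comparisons: dict[str, float] = {}
    warnings: list[str] = []
    for cls in ("replicate", "twin"):
        if not groups[cls]:
            warnings.append(f"no {cls} comparisons available; skipped")
            continue
        if not groups["unrelated"]:
            warnings.append("no unrelated comparisons available; skipped")
            continue
        stat = stats.mannwhitneyu(groups[cls], groups["unrelated"],
                                  alternative="two-sided", method="auto")
        comparisons[f"{cls}_vs_unrelated"] = float(stat.pvalue)
    return ConcordanceReport(groups=groups, comparisons=comparisons, warnings=warnings)


def _pair_columns(bm: BetaMatrix, sheet: SampleSheet) -> dict[str, tuple[str, str]]:
    meta = sheet.data.set_index("sample_id")
    twins = meta[(meta["cohort"] == "twin") & meta["replicate_of"].isna()]
    pairs: dict[str, list[str]] = {}
    for sid in bm.sample_ids:
        if sid in twins.index:
            pid = twins.loc[sid, "pair_id"]
            if pd.notna(pid):
                pairs.setdefault(str(pid), []).append(sid)
    return {p: (m[0], m[1]) for p, m in pairs.items() if len(m) == 2}


def drift_vs_age(bm: BetaMatrix, sheet: SampleSheet, metric: str = "euclidean") -> DriftResult:
    """Correlate intra-pair distance with pair age (epigenetic drift test)."""
    if metric not in DRIFT_METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {DRIFT_METRICS}")
    if sheet.data["replicate_of"].notna().any():
        bm, sheet = collapse_replicates(bm, sheet)
    pairs = _pair_columns(bm, sheet)
    if len(pairs) < 3:
        raise ValidationError("drift test needs >= 3 complete twin pairs")
    meta = sheet.data.set_index("sample_id")
    pair_ids, dists, ages = [], [], []
    for pid, (a, b) in sorted(pairs.items()):
        x = bm.data[a].to_numpy(float)
        y = bm.data[b].to_numpy(float)
        if metric == "euclidean":
            d = float(np.linalg.norm(x - y))
        elif metric == "manhattan":
            d = float(np.abs(x - y).sum())
        else:
            d = float(1.0 - np.corrcoef(x, y)[0, 1])
        pair_ids.append(pid)
        dists.append(d)
        ages.append(float(meta.loc[a, "age"]))
    dists = np.asarray(dists)
    ages = np.asarray(ages)
    if np.std(dists) == 0 or np.std(ages) == 0:
        return DriftResult(metric, pair_ids, dists, ages, np.nan, np.nan, estimable=False)
    r, p = stats.pearsonr(dists, ages)
    return DriftResult(metric, pair_ids, dists, ages, float(r), float(p), estimable=True)


def pair_clustering_fraction(
    bm: BetaMatrix, sheet: SampleSheet, linkage: str = "average"
) -> float:
    """Fraction of twin pairs that are mutual nearest neighbours.

    Samples are placed in the 1 − Pearson correlation space used for the
    sample dendrogram; a pair "clusters together" when each co-twin's nearest
    other sample is its twin.  Replicate arrays are collapsed first so they
    cannot shadow the co-twin.
    """
    if linkage != "average":
        raise ValueError("only average linkage is supported")
    if sheet.data["replicate_of"].notna().any():
        bm, sheet = collapse_replicates(bm, sheet)
    pairs = _pair_columns(bm, sheet)
    if len(pairs) < 2:
        raise ValidationError("need >= 2 twin pairs")
    ids = bm.sample_ids
    idx = {s: i for i, s in enumerate(ids)}
    D = 1.0 - np.corrcoef(bm.values.T)
    np.fill_diagonal(D, np.inf)
    nearest = np.argmin(D, axis=1)
    hits = 0
    for a, b in pairs.values():
        i, j = idx[a], idx[b]
        if nearest[i] == j and nearest[j] == i:
            hits += 1
    return hits / len(pairs)


def sample_dendrogram(bm: BetaMatrix) -> np.ndarray:
    """Average-linkage sample tree on 1 − Pearson distance (for export)."""
    D = 1.0 - np.corrcoef(bm.values.T)
    np.fill_diagonal(D, 0.0)
    return _average_linkage(squareform(D, checks=False))
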