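"""Per-probe age association, Storey q-values, and annotation enrichment.

Each probe's beta value is tested for Pearson correlation with age via the
Student t transform t = r·sqrt(n−2)/sqrt(1−r²).  The resulting p-values are
converted to q-values (the false-discovery-rate analogue of the p-value)
with Storey's π₀ estimate, and probes passing the q threshold are summarised
against the probe annotation: CpG-island enrichment by Fisher's exact test
and the median signed offset from the transcription start site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import BetaMatrix, ProbeAnnotation, ValidationError

__all__ = [
    "PearsonTest",
    "pearson_age_test",
    "probe_age_association",
    "storey_qvalues",
    "select_significant",
    "SelectionSummary",
    "island_enrichment",
    "tss_offset_summary",
    "overlap_with_probe_list",
]


class PearsonTest(NamedTuple):
    t: float
    p: float
    exact_fit: bool = False


def pearson_age_test(r: float, n: int) -> PearsonTest:
    """Two-sided test of a Pearson correlation via the Student t transform.

    t = r·sqrt(n−2)/sqrt(1−r²) with n−2 degrees of freedom.  |r| = 1 is an
    exact fit: p = 0 is returned with the flag set.
    """
    if n < 3:
        raise ValidationError("need n >= 3")
    if abs(r) > 1:
        raise ValidationError(f"|r| must be <= 1, got {r}")
    if abs(r) == 1:
        return PearsonTest(t=np.inf * np.sign(r), p=0.0, exact_fit=True)
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return PearsonTest(t=float(t), p=float(p), exact_fit=False)


def probe_age_association(bm: BetaMatrix, ages: Sequence[float]) -> pd.DataFrame:
    """Per-probe Pearson r, t and two-sided p against age.

    Returns a frame indexed by probe id with columns r, t, p, direction and
    exact_fit; q-values are attached separately by :func:`storey_qvalues`.
    """
    ages = np.asarray(ages, dtype=float)
    X = bm.values
    n = X.shape[1]
    if n != len(ages):
        raise ValidationError("ages length must match sample count")
    if n < 3:
        raise ValidationError("need >= 3 samples")
    sd = X.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = bm.probe_ids[int(np.argmax(sd == 0))]
        raise ValidationError(f"constant probe {bad!r}; filter first")
    if ages.std() == 0:
        raise ValidationError("ages are constant")
    xc = X - X.mean(axis=1, keepdims=True)
    yc = ages - ages.mean()
    r = (xc @ yc) / (np.sqrt((xc**2).sum(axis=1)) * np.sqrt((yc**2).sum()))
    r = np.clip(r, -1.0, 1.0)
    exact = np.abs(r) >= 1.0 - 1e-15
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    t[exact] = np.sign(r[exact]) * np.inf
    p = np.where(exact, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    return pd.DataFrame(
        {
            "r": r,
            "t": t,
            "p": p,
            "direction": np.where(r >= 0, "+", "-"),
            "exact_fit": exact,
        },
        index=pd.Index(bm.probe_ids, name="probe_id"),
    )


DEFAULT_LAMBDA_GRID = np.arange(0.05, 0.901, 0.05)


def estimate_pi0(
    pvals: np.ndarray,
    method: str = "smoother",
    lambda_grid: np.ndarray | None = None,
    fixed_lambda: float = 0.5,
) -> float:
    """Estimate the null proportion π₀ from the p-value distribution.

    "smoother": π₀(λ) = #{p > λ}/(m(1−λ)) over the λ grid, smoothed with a
    cubic polynomial and read off at the largest λ; clamped to (0, 1].
    Falls back to π₀ = 1 for m < 100, where the tail estimate is unstable.
    """
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    if method == "one":
        return 1.0
    if m < 100:
        return 1.0
    if method == "fixed_lambda":
        pi0 = np.mean(p > fixed_lambda) / (1.0 - fixed_lambda)
        return float(min(max(pi0, 1.0 / m), 1.0))
    if method != "smoother":
        raise ValueError(f"unknown pi0 method {method!r}")
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, float)
    pi0_lambda = np.array([np.mean(p > lam) / (1.0 - lam) for lam in grid])
    coefs = np.polyfit(grid, pi0_lambda, deg=3)
    pi0 = float(np.polyval(coefs, grid.max()))
    return float(min(max(pi0, 1.0 / m), 1.0))


def storey_qvalues(
    pvals: Sequence[float],
    pi0_method: str = "smoother",
    lambda_grid: np.ndarray | None = None,
    fixed_lambda: float = 0.5,
) -> np.ndarray:
    """Storey q-values: q_(i) = min_{j>=i} π₀·m·p_(j)/j, in input order.

    With π₀ forced to 1 (``pi0_method="one"``) this is exactly the
    Benjamini–Hochberg adjusted p-value.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValidationError("pvals must be a non-empty 1-d sequence")
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    pi0 = estimate_pi0(p, method=pi0_method, lambda_grid=lambda_grid,
                       fixed_lambda=fixed_lambda)
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


@dataclass
class SelectionSummary:
    probe_ids: list[str]
    n_selected: int
    min_abs_r: float
    n_positive: int
    n_negative: int
    q_cut: float

    def to_dict(self) -> dict:
        return self.__dict__ | {"probe_ids": list(self.probe_ids)}


def select_significant(table: pd.DataFrame, q_cut: float = 0.05) -> tuple[pd.DataFrame, SelectionSummary]:
    """Probes with q strictly below the cut, with direction counts and min |r|."""
    if "q" not in table.columns:
        raise ValidationError("q-values not computed; run storey_qvalues first")
    sel = table[table["q"] < q_cut]
    summary = SelectionSummary(
        probe_ids=list(sel.index),
        n_selected=len(sel),
        min_abs_r=float(np.abs(sel["r"]).min()) if len(sel) else float("nan"),
        n_positive=int((sel["r"] > 0).sum()),
        n_negative=int((sel["r"] < 0).sum()),
        q_cut=q_cut,
    )
    return sel, summary


def island_enrichment(
    selected: Iterable[str], ann: ProbeAnnotation, background: Iterable[str]
) -> tuple[np.ndarray, float, float]:
    """2×2 Fisher exact test of CpG-island membership, selected vs the rest.

    Returns (table, odds ratio, two-sided p); the table rows are
    [selected, background-minus-selected] × [in island, not in island].
    """
    selected = set(selected)
    background = set(background)
    if not selected:
        raise ValidationError("empty selection")
    if not selected <= background:
        raise ValidationError("selected probes must be a subset of the background")
    island = ann.data.set_index("probe_id")["in_cpg_island"]
    rest = background - selected
    sel_in = sum(bool(island.get(p, False)) for p in selected)
    rest_in = sum(bool(island.get(p, False)) for p in rest)
    table = np.array([[sel_in, len(selected) - sel_in],
                      [rest_in, len(rest) - rest_in]])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(odds), float(p)


def tss_offset_summary(selected: Iterable[str], ann: ProbeAnnotation) -> tuple[float, str]:
    """Median signed TSS offset of the selected probes, with a wording.

    Negative offsets are upstream (promoter side); the even-count median is
    the mean of the middle two values.
    """
    offsets = ann.data.set_index("probe_id")["tss_offset"]
    vals = offsets.reindex(list(selected)).dropna().to_numpy(float)
    if len(vals) == 0:
        raise ValidationError("no annotated probes among the selection")
    med = float(np.median(vals))
    if med < 0:
        wording = f"{abs(med):g} bp upstream of the TSS"
    elif med > 0:
        wording = f"{med:g} bp downstream of the TSS"
    else:
        wording = "at the TSS"
    return med, wording


def overlap_with_probe_list(
    selected: Iterable[str],
    external: Iterable[str],
    selected_directions: dict[str, str] | None = None,
    external_directions: dict[str, str] | None = None,
) -> tuple[int, list[str]]:
    """Intersection with an external probe list, optionally direction-matched."""
    shared = set(selected) & set(external)
    if selected_directions is not None and external_directions is not None:
        shared = {
            p for p in shared
            if selected_directions.get(p) == external_directions.get(p)
        }
    ids = sorted(shared)
    return len(ids), ids
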