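"""Probe filtering, batch adjustment, outlier flagging and twin-pair averaging.

The canonical preprocessing order is: drop incomplete probes -> mean/variance
probe filter -> ComBat batch adjustment -> outlier removal -> replicate
collapse -> twin-pair averaging.  Each step is also usable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import BetaMatrix, SampleSheet, ValidationError

__all__ = [
    "FilterReport",
    "ProbeFilter",
    "filter_probes",
    "combat_adjust",
    "flag_outliers",
    "collapse_replicates",
    "average_pairs",
]


@dataclass
class FilterReport:
    """Bookkeeping for the probe filter; a probe counts once (mean rule first)."""

    n_input: int
    n_kept: int
    n_removed_mean: int
    n_removed_var: int
    min_mean: float
    max_mean: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


class ProbeFilter(TransformerMixin, BaseEstimator):
    """Keep probes with min_mean < mean < max_mean and sample variance > 0.

    sklearn-style transformer over a samples × probes array; the mean rule is
    applied before the variance rule when attributing removals.
    """

    def __init__(self, min_mean: float = 0.05, max_mean: float = 0.95):
        self.min_mean = min_mean
        self.max_mean = max_mean

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            raise ValidationError("empty matrix")
        if np.isnan(X).any():
            raise ValidationError("matrix contains missing values; drop incomplete probes first")
        means = X.mean(axis=0)
        var = X.var(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
        mean_ok = (means > self.min_mean) & (means < self.max_mean)
        var_ok = var > 0
        self.support_ = mean_ok & var_ok
        self.report_ = FilterReport(
            n_input=X.shape[1],
            n_kept=int(self.support_.sum()),
            n_removed_mean=int((~mean_ok).sum()),
            n_removed_var=int((mean_ok & ~var_ok).sum()),
            min_mean=self.min_mean,
            max_mean=self.max_mean,
        )
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        return np.asarray(X, dtype=float)[:, self.support_]

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_


def filter_probes(
    bm: BetaMatrix, min_mean: float = 0.05, max_mean: float = 0.95
) -> tuple[BetaMatrix, FilterReport]:
    """Apply the mean/variance probe filter to a beta matrix (order preserved)."""
    f = ProbeFilter(min_mean=min_mean, max_mean=max_mean).fit(bm.values.T)
    kept = BetaMatrix(bm.data.loc[f.get_support()])
    return kept, f.report_


def combat_adjust(bm: BetaMatrix, sheet: SampleSheet) -> BetaMatrix:
    """Remove batch effects with parametric empirical-Bayes ComBat.

    Per-probe values are standardized, per-batch additive and multiplicative
    effects are shrunk toward pooled priors (normal / inverse-gamma with
    moments-matched hyperparameters), then back-transformed.  Output is
    clipped to [0, 1] so adjusted betas remain valid fractions.  With a
    single batch the input is returned unchanged.
    """
    batches = sheet.data.set_index("sample_id").loc[bm.sample_ids, "batch_id"]
    counts = batches.value_counts()
    if len(counts) <= 1:
        return bm.copy()
    singletons = counts[counts < 2]
    if len(singletons):
        raise ValidationError(
            f"each batch needs >= 2 samples; offending batches: {list(singletons.index)}"
        )
    import anndata

    import scanpy as sc

    ad = anndata.AnnData(
        X=bm.values.T.copy(),
        obs=pd.DataFrame({"batch": batches.astype(str).to_numpy()},
                         index=bm.sample_ids),
        var=pd.DataFrame(index=bm.probe_ids),
    )
    sc.pp.combat(ad, key="batch")
    adj = np.clip(np.asarray(ad.X, dtype=float).T, 0.0, 1.0)
    return BetaMatrix(pd.DataFrame(adj, index=bm.probe_ids, columns=bm.sample_ids))


def flag_outliers(bm: BetaMatrix, k: float = 3.0) -> list[str]:
    """Flag samples with unusually low mean inter-sample correlation.

    A sample is flagged when its mean Pearson correlation with all other
    samples falls below median − k·IQR of that statistic across samples.
    Degenerate case IQR = 0 (e.g. identical columns) flags nothing.
    """
    X = bm.values
    if X.shape[1] < 4:
        raise ValidationError("outlier flagging needs >= 4 samples")
    C = np.corrcoef(X.T)
    np.fill_diagonal(C, np.nan)
    mean_r = np.nanmean(C, axis=1)
    q75, q25 = np.percentile(mean_r, [75, 25])
    iqr = q75 - q25
    if iqr == 0:
        return []
    cut = np.median(mean_r) - k * iqr
    return [s for s, r in zip(bm.sample_ids, mean_r) if r < cut]


def collapse_replicates(bm: BetaMatrix, sheet: SampleSheet) -> tuple[BetaMatrix, SampleSheet]:
    """Average each sample with its technical replicates into one column."""
    meta = sheet.data.set_index("sample_id")
    rep_of = meta["replicate_of"]
    groups: dict[str, list[str]] = {}
    for sid in bm.sample_ids:
        parent = rep_of.get(sid)
        parent = sid if parent is None or (isinstance(parent, float) and np.isnan(parent)) or parent == "" else str(parent)
        groups.setdefault(parent, []).append(sid)
    cols = {parent: bm.data[members].mean(axis=1) for parent, members in groups.items()}
    order = [s for s in bm.sample_ids if s in cols]  # keep primary order
    new = pd.DataFrame(cols)[order]
    keep_rows = sheet.data[sheet.data["sample_id"].isin(order)].copy()
    keep_rows["replicate_of"] = None
    return BetaMatrix(new), SampleSheet(keep_rows)


def average_pairs(bm: BetaMatrix, sheet: SampleSheet) -> tuple[BetaMatrix, SampleSheet]:
    """Average co-twins into one column per pair; controls pass through.

    Twins share age by construction, so the pair column keeps that age and is
    treated downstream as one independent sample.  Replicate columns, if still
    present, are collapsed first.
    """
    if sheet.data["replicate_of"].notna().any():
        bm, sheet = collapse_replicates(bm, sheet)
    meta = sheet.data.set_index("sample_id")
    twins = meta[meta["cohort"] == "twin"]
    if twins["pair_id"].isna().any():
        missing = list(twins[twins["pair_id"].isna()].index)
        raise ValidationError(f"twin samples without pair_id: {missing}")

    cols: dict[str, pd.Series] = {}
    rows = []
    seen_pairs: set[str] = set()
    for sid in bm.sample_ids:
        row = meta.loc[sid]
        if row["cohort"] != "twin":
            cols[sid] = bm.data[sid]
            rows.append(dict(sample_id=sid, pair_id=None, age=row["age"], sex=row["sex"],
                             batch_id=row["batch_id"], replicate_of=None, cohort=row["cohort"]))
            continue
        pair = str(row["pair_id"])
        if pair in seen_pairs:
            continue
        members = list(twins.index[twins["pair_id"] == pair])
        if len(members) != 2:
            raise ValidationError(f"pair {pair!r} has {len(members)} members, expected 2")
        cols[pair] = bm.data[members].mean(axis=1)
        rows.append(dict(sample_id=pair, pair_id=None, age=row["age"], sex=row["sex"],
                         batch_id="pooled", replicate_of=None, cohort="twin"))
        seen_pairs.add(pair)
    new = pd.DataFrame(cols)
    return BetaMatrix(new), SampleSheet(pd.DataFrame(rows))
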