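"""Signed weighted co-methylation network, module detection, eigenloci.

The network follows the weighted correlation network analysis (WGCNA)
construction: probe–probe Pearson correlations are soft-thresholded into a
signed adjacency a_ij = ((1 + c_ij)/2)^beta, optionally converted to the
topological overlap measure (TOM), and 1 − TOM is clustered with average
linkage.  Branches of the tree cut at a fixed fraction of the maximum merge
height define modules; clusters below the minimum size are relabelled grey.
Each module is summarised by its eigenlocus — the first principal component
of the standardized module profiles, a weighted-average representative whose
correlation with age gives a module-level ageing statistic with only as many
multiple comparisons as there are modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average as _average_linkage
from scipy.cluster.hierarchy import fcluster
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .io import BetaMatrix, ValidationError
from .simulate import MODULE_COLORS

__all__ = [
    "NetworkConfig",
    "ModuleAssignment",
    "Eigenlocus",
    "signed_adjacency",
    "topological_overlap",
    "ModuleDetector",
    "detect_modules",
    "module_eigenloci",
    "module_age_stats",
    "linkage_to_text",
]


@dataclass
class NetworkConfig:
    beta_power: int = 12
    use_tom: bool = True
    linkage: str = "average"
    cut_height: float = 0.99
    min_module_size: int = 30

    def validate(self) -> None:
        if self.beta_power < 1:
            raise ValueError("beta_power must be >= 1")
        if not 0 < self.cut_height <= 1:
            raise ValueError("cut_height must be in (0, 1]")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if self.linkage != "average":
            raise ValueError("only average linkage is supported")


@dataclass
class ModuleAssignment:
    """Probe → module colour map; "grey" marks unassigned probes."""

    labels: pd.Series  # index = probe ids, values = colour strings

    @property
    def sizes(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()

    @property
    def module_names(self) -> list[str]:
        sizes = self.sizes
        return sorted((m for m in sizes if m != "grey"), key=lambda m: -sizes[m])

    def probes_in(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"probe_id": self.labels.index, "module": self.labels.values})


@dataclass
class Eigenlocus:
    """First principal component of a module's standardized profiles."""

    module: str
    sample_ids: list[str]
    scores: np.ndarray          # unit-norm, one entry per sample
    variance_explained: float

    def series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.sample_ids, name=self.module)


def _check_symmetric(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValidationError(f"{name} must be square")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValidationError(f"{name} must be symmetric")
    return M


def signed_adjacency(corr: np.ndarray, beta_power: int = 12) -> np.ndarray:
    """Soft-threshold correlations: a_ij = ((1 + c_ij)/2)^beta, diagonal 1.

    The signed transform maps c = −1 to adjacency 0 and c = +1 to 1, so
    anti-correlated probes end up unconnected rather than connected.
    """
    C = _check_symmetric(corr, "correlation matrix")
    if np.nanmax(np.abs(C)) > 1 + 1e-8:
        raise ValidationError("correlations must lie in [-1, 1]")
    A = ((1.0 + np.clip(C, -1.0, 1.0)) / 2.0) ** beta_power
    np.fill_diagonal(A, 1.0)
    return A


def topological_overlap(adj: np.ndarray) -> np.ndarray:
    """TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij) with unit diagonal.

    l_ij counts shared-neighbour connectivity Σ_{u≠i,j} a_iu a_uj and k_i is
    the node connectivity Σ_{u≠i} a_iu.
    """
    A = _check_symmetric(adj, "adjacency matrix")
    if A.min() < -1e-12 or A.max() > 1 + 1e-8:
        raise ValidationError("adjacency entries must lie in [0, 1]")
    A = np.clip(A, 0.0, 1.0)
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    L = A0 @ A0                      # u = i, j terms vanish with zero diagonal
    k = A0.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - A0
    with np.errstate(invalid="ignore", divide="ignore"):
        T = (L + A0) / denom
    T[~np.isfinite(T)] = 0.0
    np.fill_diagonal(T, 1.0)
    return T


class ModuleDetector(ClusterMixin, BaseEstimator):
    """Cluster probes into co-methylation modules (sklearn-style).

    ``fit`` takes a probes × samples array (each row one probe's profile);
    ``labels_`` holds module colour strings ordered by module size, with
    "grey" for probes left unassigned by the minimum-size rule.
    """

    def __init__(self, beta_power: int = 12, use_tom: bool = True,
                 linkage: str = "average", cut_height: float = 0.99,
                 min_module_size: int = 30):
        self.beta_power = beta_power
        self.use_tom = use_tom
        self.linkage = linkage
        self.cut_height = cut_height
        self.min_module_size = min_module_size

    def _config(self) -> NetworkConfig:
        cfg = NetworkConfig(self.beta_power, self.use_tom, self.linkage,
                            self.cut_height, self.min_module_size)
        cfg.validate()
        return cfg

    def fit(self, X, y=None):
        cfg = self._config()
        X = np.asarray(X, dtype=float)
        if X.shape[0] < cfg.min_module_size:
            raise ValidationError("fewer probes than min_module_size")
        if X.shape[1] < 3:
            raise ValidationError("module detection needs >= 3 samples")
        if (X.std(axis=1) == 0).any():
            bad = int(np.argmax(X.std(axis=1) == 0))
            raise ValidationError(
                f"constant probe at row {bad}; filter zero-variance probes first"
            )
        C = np.corrcoef(X)
        A = signed_adjacency(C, cfg.beta_power)
        S = topological_overlap(A) if cfg.use_tom else A
        D = 1.0 - S
        np.fill_diagonal(D, 0.0)
        Z = _average_linkage(squareform(D, checks=False))
        self.linkage_matrix_ = Z
        cut = cfg.cut_height * Z[:, 2].max()
        raw = fcluster(Z, t=cut, criterion="distance")
        self.labels_ = self._colorize(raw, cfg.min_module_size)
        return self

    @staticmethod
    def _colorize(raw: np.ndarray, min_size: int) -> np.ndarray:
        sizes = pd.Series(raw).value_counts()
        keep = [c for c in sizes.index if sizes[c] >= min_size]
        # rank by size desc; ties broken by lowest member index for determinism
        first_idx = {c: int(np.argmax(raw == c)) for c in keep}
        keep.sort(key=lambda c: (-sizes[c], first_idx[c]))
        color_of = {c: MODULE_COLORS[i % len(MODULE_COLORS)] if i < len(MODULE_COLORS)
                    else f"module{i}" for i, c in enumerate(keep)}
        return np.array([color_of.get(c, "grey") for c in raw], dtype=object)


def detect_modules(
    bm: BetaMatrix, cfg: NetworkConfig | None = None
) -> tuple[ModuleAssignment, np.ndarray]:
    """Detect modules on a beta matrix; returns the assignment and the linkage."""
    cfg = cfg or NetworkConfig()
    det = ModuleDetector(cfg.beta_power, cfg.use_tom, cfg.linkage,
                         cfg.cut_height, cfg.min_module_size).fit(bm.values)
    labels = pd.Series(det.labels_, index=bm.probe_ids, name="module")
    return ModuleAssignment(labels), det.linkage_matrix_


def module_eigenloci(bm: BetaMatrix, assignment: ModuleAssignment) -> list[Eigenlocus]:
    """Eigenlocus per non-grey module.

    Probes are standardized across samples; the first right singular vector
    gives the per-sample scores (unit norm), signed so its correlation with
    the module's mean standardized profile is positive.
    """
    out = []
    for module in assignment.module_names:
        probes = assignment.probes_in(module)
        X = bm.data.loc[probes].to_numpy(float)
        sd = X.std(axis=1, ddof=1)
        if (sd == 0).any():
            bad = probes[int(np.argmax(sd == 0))]
            raise ValidationError(f"zero-variance probe {bad!r} in module {module!r}")
        Zs = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
        U, S, Vt = np.linalg.svd(Zs, full_matrices=False)
        scores = Vt[0]
        mean_profile = Zs.mean(axis=0)
        if np.dot(scores, mean_profile) < 0:
            scores = -scores
        var_explained = float(S[0] ** 2 / np.sum(S**2))
        out.append(Eigenlocus(module, bm.sample_ids, scores, var_explained))
    return out


def module_age_stats(
    eigenloci: list[Eigenlocus],
    ages: np.ndarray,
    probe_t: pd.Series | None = None,
    assignment: ModuleAssignment | None = None,
) -> pd.DataFrame:
    """Per-module eigenlocus–age correlation with Bonferroni correction.

    Only as many comparisons as modules are made, so Bonferroni multiplies p
    by the module count.  When per-probe t-statistics are supplied, the mean
    t per module (the barplot height of the module-age display) is added.
    """
    ages = np.asarray(ages, dtype=float)
    if len(ages) < 3:
        raise ValidationError("need >= 3 samples")
    n_mod = len(eigenloci)
    rows = []
    for el in eigenloci:
        if np.std(el.scores) == 0 or np.std(ages) == 0:
            rows.append(dict(module=el.module, r=np.nan, p=np.nan,
                             p_bonferroni=np.nan, estimable=False))
            continue
        r, p = stats.pearsonr(el.scores, ages)
        rows.append(dict(module=el.module, r=float(r), p=float(p),
                         p_bonferroni=float(min(1.0, p * n_mod)), estimable=True))
    df = pd.DataFrame(rows).set_index("module")
    df["variance_explained"] = [el.variance_explained for el in eigenloci]
    if probe_t is not None and assignment is not None:
        df["mean_probe_t"] = [
            float(probe_t.loc[[p for p in assignment.probes_in(m) if p in probe_t.index]].mean())
            for m in df.index
        ]
    return df


def linkage_to_text(Z: np.ndarray, labels: list[str]) -> str:
    """Render a linkage matrix as nested-parenthesis (Newick-like) text."""
    n = len(labels)
    nodes: dict[int, str] = {i: labels[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        nodes[n + k] = f"({nodes[int(a)]},{nodes[int(b)]}):{h:.6g}"
    return nodes[n + len(Z) - 1] + ";"
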