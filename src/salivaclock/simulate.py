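"""Synthetic twin/control methylome generator with known ground truth.

The generator emulates the design of a saliva methylation ageing study:
monozygotic twin pairs plus unrelated male/female controls assayed on a
27k-style CpG array, with planted co-methylation modules, a subset of probes
whose methylation drifts linearly with age, twin-shared signal, batch
effects, and technical replicate arrays.

Each probe/sample cell is built on a latent Gaussian scale and mapped through
the logistic function, so beta values are bounded in (0, 1) without
truncation artifacts:

    x = baseline + slope * age + loading * module_factor + pair_effect
        + individual_effect + batch_shift + batch_scale * noise
    beta = 1 / (1 + exp(-x))

Age slopes are specified on the latent scale; :func:`calibrate_slope` converts
a target Pearson correlation with age into a latent slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .io import BetaMatrix, ProbeAnnotation, SampleSheet

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "calibrate_slope",
    "simulate_dataset",
    "simulate_validation_cohort",
    "default_config",
]

MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green",
    "red", "black", "pink", "magenta", "purple",
]


class ConfigError(ValueError):
    """Inconsistent simulation configuration."""


@dataclass
class SimulationConfig:
    """Knobs of the synthetic methylome; defaults mirror the study design.

    All standard deviations are on the latent (logit) scale; ages in years.
    """

    n_pairs: int = 34
    twin_age_range: tuple[float, float] = (21.0, 55.0)
    n_controls_m: int = 31
    n_controls_f: int = 29
    control_age_range: tuple[float, float] = (18.0, 70.0)
    n_probes: int = 5000
    module_sizes: tuple[int, ...] = (842, 600, 450, 300, 199)
    module_factor_sd: float = 0.5
    n_age_probes: int = 88
    age_slope_range: tuple[float, float] = (0.0223, 0.0396)
    frac_positive_slopes: float = 69 / 88
    pair_effect_sd: float = 0.2
    individual_effect_sd: float = 0.15
    n_batches: int = 4
    batch_shift_sd: float = 0.10
    batch_scale_sd: float = 0.05
    n_replicate_samples: int = 10
    noise_sd: float = 0.3
    island_rate_background: float = 0.73
    island_rate_age_probes: float = 0.83
    tss_offset_age_mean: float = -238.0
    seed: int = 0

    def validate(self) -> None:
        if sum(self.module_sizes) + self.n_age_probes > self.n_probes:
            raise ConfigError(
                "module sizes plus age probes exceed the probe count "
                f"({sum(self.module_sizes)} + {self.n_age_probes} > {self.n_probes})"
            )
        for sd in (self.module_factor_sd, self.pair_effect_sd,
                   self.individual_effect_sd, self.batch_shift_sd,
                   self.batch_scale_sd, self.noise_sd):
            if sd < 0:
                raise ConfigError("standard deviations must be >= 0")
        for lo, hi in (self.twin_age_range, self.control_age_range, self.age_slope_range):
            if lo > hi:
                raise ConfigError(f"range ({lo}, {hi}) not ordered")
        if self.n_batches < 1:
            raise ConfigError("need at least one batch")
        n_samples = 2 * self.n_pairs + self.n_controls_m + self.n_controls_f
        if n_samples == 0:
            raise ConfigError("no samples configured")
        if self.n_replicate_samples > n_samples:
            raise ConfigError("more replicate samples than samples")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulationTruth:
    """Ground truth: per-probe age/module membership, per-sample batch."""

    probes: pd.DataFrame   # probe_id, is_age_associated, true_slope, module_label
    samples: pd.DataFrame  # sample_id, batch_id, age

    @property
    def age_probe_ids(self) -> list[str]:
        m = self.probes["is_age_associated"]
        return list(self.probes.loc[m, "probe_id"])


def calibrate_slope(target_r: float, age_sd: float, noise_sd: float) -> float:
    """Latent slope giving corr(slope*age, slope*age + noise) = ``target_r``.

    Closed form: slope = (noise_sd / age_sd) * r / sqrt(1 - r^2).
    """
    if abs(target_r) >= 1:
        raise ValueError(f"|target_r| must be < 1, got {target_r}")
    if age_sd <= 0 or noise_sd <= 0:
        raise ValueError("age_sd and noise_sd must be > 0")
    return (noise_sd / age_sd) * target_r / np.sqrt(1.0 - target_r**2)


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default study-design configuration (34 twin pairs + 60 controls).

    The default age-slope range targets per-pair age correlations of
    roughly 0.6–0.8 on pair-averaged twin data: averaging the two co-twins
    halves the individual and measurement noise variances but keeps the
    pair-shared effect, so the residual latent sd is
    sqrt(pair_effect_sd² + (individual_effect_sd² + noise_sd²) / 2); the
    pair-age sd comes from a uniform draw over the twin age range.
    """
    cfg = SimulationConfig(seed=seed, **overrides)
    if "age_slope_range" not in overrides:
        lo, hi = cfg.twin_age_range
        age_sd = (hi - lo) / np.sqrt(12.0)
        resid_sd = float(np.sqrt(
            cfg.pair_effect_sd**2
            + (cfg.individual_effect_sd**2 + cfg.noise_sd**2) / 2.0
        ))
        cfg.age_slope_range = (
            calibrate_slope(0.6, age_sd, resid_sd),
            calibrate_slope(0.8, age_sd, resid_sd),
        )
    cfg.validate()
    return cfg


def _build_samples(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for p in range(cfg.n_pairs):
        age = rng.uniform(*cfg.twin_age_range)
        pair = f"P{p:03d}"
        for letter in "ab":
            rows.append(dict(sample_id=f"T{p:03d}{letter}", pair_id=pair, age=age,
                             sex="M", cohort="twin", unit=pair))
    for i in range(cfg.n_controls_m):
        rows.append(dict(sample_id=f"CM{i:03d}", pair_id=None,
                         age=rng.uniform(*cfg.control_age_range),
                         sex="M", cohort="control", unit=f"CM{i:03d}"))
    for i in range(cfg.n_controls_f):
        rows.append(dict(sample_id=f"CF{i:03d}", pair_id=None,
                         age=rng.uniform(*cfg.control_age_range),
                         sex="F", cohort="control", unit=f"CF{i:03d}"))
    df = pd.DataFrame(rows)
    batches = rng.permuted(np.arange(len(df)) % cfg.n_batches)
    df["batch_id"] = [f"B{b}" for b in batches]
    df["replicate_of"] = None
    return df


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[BetaMatrix, SampleSheet, ProbeAnnotation, SimulationTruth]:
    """Generate a full synthetic dataset plus its ground-truth table.

    Identical ``cfg`` (including seed) yields byte-identical output.  The
    module latent factor is drawn once per twin pair / per control, so with
    ``noise_sd``, ``individual_effect_sd`` and the batch sds all zero,
    co-twins are exact copies (and replicates always collapse onto their
    primary sample as soon as ``noise_sd = 0``).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    samples = _build_samples(cfg, rng)

    # replicate arrays for the first n_replicate_samples samples
    reps = []
    for _, row in samples.head(cfg.n_replicate_samples).iterrows():
        rep = row.copy()
        rep["sample_id"] = row["sample_id"] + "_r"
        rep["replicate_of"] = row["sample_id"]
        reps.append(rep)
    if reps:
        samples = pd.concat([samples, pd.DataFrame(reps)], ignore_index=True)

    n_s = len(samples)
    ages = samples["age"].to_numpy(float)
    units = samples["unit"].to_numpy()
    unit_ids, unit_idx = np.unique(units, return_inverse=True)
    batch_ids, batch_idx = np.unique(samples["batch_id"].to_numpy(), return_inverse=True)

    P = cfg.n_probes
    probe_ids = np.array([f"cg{i:06d}" for i in range(P)])

    # probe layout: [age probes | module blocks ... | null probes]
    is_age = np.zeros(P, bool)
    is_age[: cfg.n_age_probes] = True
    module_label = np.array(["grey"] * P, dtype=object)
    loading = np.zeros(P)
    start = cfg.n_age_probes
    order = np.argsort(cfg.module_sizes)[::-1]  # largest first -> color rank
    for rank, mi in enumerate(order):
        size = cfg.module_sizes[mi]
        color = MODULE_COLORS[rank % len(MODULE_COLORS)]
        module_label[start : start + size] = color
        loading[start : start + size] = rng.uniform(0.6, 1.4, size)
        start += size

    baseline = np.where(
        is_age | (module_label != "grey"),
        rng.uniform(-1.8, 1.8, P),
        rng.uniform(-3.0, 3.0, P),
    )

    slope = np.zeros(P)
    mags = rng.uniform(*cfg.age_slope_range, cfg.n_age_probes)
    signs = np.where(rng.random(cfg.n_age_probes) < cfg.frac_positive_slopes, 1.0, -1.0)
    slope[: cfg.n_age_probes] = mags * signs

    # latent components
    latent = baseline[:, None] + slope[:, None] * ages[None, :]

    module_names = [m for m in np.unique(module_label) if m != "grey"]
    factors = rng.normal(0.0, cfg.module_factor_sd, (len(module_names), len(unit_ids)))
    # modules are co-methylation structure, not age signal: project the age
    # direction out of each factor so probes labelled non-age-associated in
    # the truth table have exactly zero in-sample age correlation
    unit_age = np.array([ages[units == u][0] for u in unit_ids])
    ac = unit_age - unit_age.mean()
    if ac @ ac > 0:
        factors -= np.outer(factors @ ac / (ac @ ac), ac)
    for k, m in enumerate(module_names):
        sel = module_label == m
        latent[sel] += loading[sel, None] * factors[k][unit_idx][None, :]

    pair_mask = samples["cohort"].to_numpy() == "twin"
    pair_units = np.unique(units[pair_mask])
    pair_fx = rng.normal(0.0, cfg.pair_effect_sd, (P, len(pair_units)))
    pair_pos = {u: j for j, u in enumerate(pair_units)}
    for s in range(n_s):
        if pair_mask[s]:
            latent[:, s] += pair_fx[:, pair_pos[units[s]]]

    # individual-level environmental variation: shared by replicate arrays of
    # one person, but NOT by co-twins — this is what separates the replicate
    # and twin concordance classes
    ind_ids, ind_idx = np.unique(
        np.where(samples["replicate_of"].isna(), samples["sample_id"],
                 samples["replicate_of"]).astype(str),
        return_inverse=True,
    )
    ind_fx = rng.normal(0.0, cfg.individual_effect_sd, (P, len(ind_ids)))
    latent += ind_fx[:, ind_idx]

    batch_shift = rng.normal(0.0, cfg.batch_shift_sd, (P, len(batch_ids)))
    batch_scale = np.exp(rng.normal(0.0, cfg.batch_scale_sd, len(batch_ids)))
    latent += batch_shift[:, batch_idx]

    noise = rng.normal(0.0, 1.0, (P, n_s)) * cfg.noise_sd * batch_scale[batch_idx][None, :]
    latent += noise

    beta = expit(latent)

    bm = BetaMatrix(pd.DataFrame(beta, index=probe_ids,
                                 columns=samples["sample_id"].to_numpy()))
    sheet = SampleSheet(samples.drop(columns=["unit"]))

    island = np.where(
        is_age,
        rng.random(P) < cfg.island_rate_age_probes,
        rng.random(P) < cfg.island_rate_background,
    )
    tss = np.where(
        is_age,
        rng.normal(cfg.tss_offset_age_mean, 200.0, P),
        rng.normal(0.0, 600.0, P),
    ).round().astype(int)
    ann = ProbeAnnotation(pd.DataFrame({
        "probe_id": probe_ids,
        "chrom": rng.integers(1, 23, P).astype(str),
        "position": rng.integers(10_000, 100_000_000, P),
        "gene_symbol": [f"GENE{i:05d}" for i in range(P)],
        "tss_offset": tss,
        "in_cpg_island": island,
    }))

    truth = SimulationTruth(
        probes=pd.DataFrame({
            "probe_id": probe_ids,
            "is_age_associated": is_age,
            "true_slope": slope,
            "module_label": module_label,
        }),
        samples=samples[["sample_id", "batch_id", "age"]].copy(),
    )
    return bm, sheet, ann, truth


def simulate_validation_cohort(
    n: int = 66,
    target_r2: float = 0.73,
    n_markers: int = 2,
    age_mean: float = 38.0,
    age_sd: float = 13.0,
    age_range: tuple[float, float] = (18.0, 70.0),
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[BetaMatrix, SampleSheet, pd.DataFrame]:
    """Marker-panel cohort: a few CpG markers jointly explaining ``target_r2``
    of age variance in unrelated subjects.

    The joint population R² of age on ``k`` markers with independent latent
    noise decomposes over per-marker signal-to-noise ratios λ_j = r_j²/(1−r_j²)
    as R² = Σλ / (1 + Σλ); the target is split equally, so each marker is
    calibrated to r = sqrt(λ/(1+λ)) with λ = (R²/(1−R²))/k.  Ages are drawn
    truncated-normal; the truncated sd enters the calibration.
    """
    if not 0 < target_r2 < 1:
        raise ValueError("target_r2 must be in (0, 1)")
    rng = np.random.default_rng(seed)
    lo, hi = age_range
    a, b = (lo - age_mean) / age_sd, (hi - age_mean) / age_sd
    dist = truncnorm(a, b, loc=age_mean, scale=age_sd)
    ages = dist.rvs(size=n, random_state=rng)
    pop_age_sd = float(dist.std())

    lam = (target_r2 / (1.0 - target_r2)) / n_markers
    r_marker = np.sqrt(lam / (1.0 + lam))
    slope_mag = calibrate_slope(r_marker, pop_age_sd, noise_sd)

    probe_ids = [f"mk{j:02d}" for j in range(n_markers)]
    rows = []
    slopes = []
    for j in range(n_markers):
        sign = -1.0 if j % 2 == 0 else 1.0  # alternate hypo-/hyper-methylation
        s = sign * slope_mag
        slopes.append(s)
        latent = s * (ages - dist.mean()) + rng.normal(0.0, noise_sd, n)
        rows.append(expit(latent))
    beta = np.vstack(rows)

    sample_ids = [f"V{i:03d}" for i in range(n)]
    bm = BetaMatrix(pd.DataFrame(beta, index=probe_ids, columns=sample_ids))
    sheet = SampleSheet(pd.DataFrame({
        "sample_id": sample_ids,
        "pair_id": None,
        "age": ages,
        "sex": np.where(rng.random(n) < 0.5, "M", "F"),
        "batch_id": "B0",
        "replicate_of": None,
        "cohort": "control",
    }))
    truth = pd.DataFrame({"probe_id": probe_ids, "true_slope": slopes,
                          "target_marker_r": r_marker})
    return bm, sheet, truth
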