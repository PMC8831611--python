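"""Calibration-standard benchmarking and a synthetic calibration simulator.

Calibration standards are DNA samples engineered so that every CpG is
methylated at a known fraction — the benchmark variable
ProportionMethylated, with ordinal levels 0, 0.25, 0.5, 0.75 and 1.
A well-behaved probe's beta values track those levels almost linearly,
so the per-probe Pearson correlation with ProportionMethylated measures
probe fidelity.  The standard protocol runs human standards on 10
arrays (2 per level), mouse on 20 (4 per level) and rat on 15
(3 per level).

The simulator stands in for purchased standards at desk scale: each
non-failing probe's beta at level p is Binomial(d, clamp(p + bias)) / d
— a read-depth-like sampling model that reproduces the heteroscedastic
variance = c * mean * (1 - mean) relation observed on real arrays — and
a planted fraction of failing probes draw betas uniformly regardless of
level, emulating probes that do not work in the target species.

Normalization (noob / pOOBAH etc.) is out of scope: beta matrices are
consumed already normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

LEVELS = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass
class SimulatorConfig:
    """Synthetic calibration experiment parameters.

    depth is the effective number of molecules sampled per beta value;
    bias_scale the s.d. of an optional per-probe additive shift
    (probe-level technical bias; 0 means pure binomial sampling);
    f_fail the fraction of planted failing probes.  Defaults mirror the
    mouse calibration design (4 arrays per level).
    """

    seed: int
    n_probes: int = 2000
    replicates_per_level: int = 4
    depth: int = 100
    bias_scale: float = 0.0
    f_fail: float = 0.0
    levels: tuple[float, ...] = LEVELS
    species: str = "mouse"
    platform: str = "mammalian"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0 <= self.f_fail <= 1:
            raise ValueError("f_fail must be in [0, 1]")


@dataclass
class CalibrationDataset:
    """Beta matrix (probes x arrays) plus per-array benchmark levels."""

    betas: pd.DataFrame
    levels: pd.Series            # per array (column), ordinal benchmark
    species: str = ""
    platform: str = ""
    failing_probes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.betas.columns.equals(self.levels.index):
            raise ValueError("levels index must match beta columns")
        bad = set(np.unique(self.levels)) - set(LEVELS)
        if bad:
            raise ValueError(f"levels outside the ordinal scale: {sorted(bad)}")

    @property
    def n_probes(self) -> int:
        return len(self.betas)

    def write_csv(self, beta_path: str | Path, sheet_path: str | Path) -> None:
        self.betas.to_csv(beta_path, index_label="probe_id")
        sheet = pd.DataFrame({
            "sample_id": self.levels.index,
            "level": self.levels.values,
            "species": self.species,
            "platform": self.platform,
        })
        sheet.to_csv(sheet_path, index=False)

    @classmethod
    def read_csv(cls, beta_path: str | Path,
                 sheet_path: str | Path) -> "CalibrationDataset":
        betas = pd.read_csv(beta_path, index_col="probe_id")
        sheet = pd.read_csv(sheet_path)
        levels = pd.Series(sheet["level"].values,
                           index=sheet["sample_id"].values)
        species = sheet["species"].iloc[0] if "species" in sheet else ""
        platform = sheet["platform"].iloc[0] if "platform" in sheet else ""
        return cls(betas[levels.index.astype(str)], levels,
                   species=species, platform=platform)


def simulate_calibration(config: SimulatorConfig) -> CalibrationDataset:
    """Draw a reproducible synthetic calibration dataset."""
    rng = np.random.default_rng(config.seed)
    n = config.n_probes
    arrays = [(lvl, rep) for lvl in config.levels
              for rep in range(config.replicates_per_level)]
    cols = [f"{config.species}_L{int(lvl * 100):03d}_r{rep + 1}"
            for lvl, rep in arrays]
    bias = rng.normal(0.0, config.bias_scale, size=n)
    failing = rng.random(n) < config.f_fail
    betas = np.empty((n, len(arrays)))
    for j, (lvl, _) in enumerate(arrays):
        p = np.clip(lvl + bias, 0.0, 1.0)
        betas[:, j] = rng.binomial(config.depth, p) / config.depth
    betas[failing] = rng.uniform(0.0, 1.0, size=(int(failing.sum()),
                                                 len(arrays)))
    probe_ids = [f"cg{i + 1:08d}" for i in range(n)]
    df = pd.DataFrame(betas, index=probe_ids, columns=cols)
    levels = pd.Series([lvl for lvl, _ in arrays], index=cols)
    return CalibrationDataset(
        betas=df, levels=levels, species=config.species,
        platform=config.platform,
        failing_probes=frozenset(pid for pid, f in zip(probe_ids, failing) if f))


def correlate_with_benchmark(dataset: CalibrationDataset) -> pd.Series:
    """Per-probe Pearson r of betas against ProportionMethylated.

    Probes with zero variance across arrays get NaN (undefined, flagged
    for exclusion downstream).  Requires at least two distinct levels.
    """
    lv = dataset.levels.to_numpy(dtype=float)
    if len(np.unique(lv)) < 2:
        raise ValueError("need >= 2 distinct benchmark levels")
    X = dataset.betas.to_numpy(dtype=float)
    xc = X - X.mean(axis=1, keepdims=True)
    yc = lv - lv.mean()
    num = xc @ yc
    denom = np.sqrt((xc ** 2).sum(axis=1) * (yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / denom, np.nan)
    return pd.Series(r, index=dataset.betas.index, name="r")


def threshold_counts(r: pd.Series,
                     thresholds: tuple[float, ...] = (0.85, 0.90, 0.95),
                     ) -> dict[float, int]:
    """Probes whose correlation strictly exceeds each threshold;
    undefined (NaN) correlations are excluded."""
    vals = r.dropna().to_numpy()
    return {t: int((vals > t).sum()) for t in thresholds}


def filter_outliers(dataset: CalibrationDataset, r: pd.Series,
                    cutoff: float = 0.8,
                    ) -> tuple[CalibrationDataset, list[str]]:
    """Discard probes with benchmark correlation below the cutoff.

    Probes with r < cutoff or undefined r are removed (strictly below:
    r exactly at the cutoff is retained).  Returns the filtered dataset
    and the removal list.
    """
    r = r.reindex(dataset.betas.index)
    removed = r.index[(r < cutoff) | r.isna()].tolist()
    kept = dataset.betas.drop(index=removed)
    filtered = CalibrationDataset(
        betas=kept, levels=dataset.levels, species=dataset.species,
        platform=dataset.platform,
        failing_probes=frozenset(p for p in dataset.failing_probes
                                 if p in kept.index))
    return filtered, removed


@dataclass
class MeanVarianceFit:
    """Fit of variance = c * mean * (1 - mean) over per-level beta
    distributions."""

    c: float
    r: float
    n_cells: int

    def summary(self) -> str:
        r_txt = "undefined" if np.isnan(self.r) else f"{self.r:.3f}"
        return (
            "Mean-variance relation: variance = c * mean * (1 - mean)\n"
            f"  distribution cells:    {self.n_cells}\n"
            f"  fitted c:              {self.c:.5f}\n"
            f"  Pearson r(var, m(1-m)): {r_txt}\n")


def mean_variance_check(dataset: CalibrationDataset) -> MeanVarianceFit:
    """Test the binomial-like heteroscedasticity of beta values.

    At each benchmark level, the beta-value distribution (pooled over
    probes and replicate arrays) has a mean m and an unbiased variance
    v; distributions near m = 0.5 spread more than those near 0 or 1.
    c is the least-squares slope through the origin of v on m*(1-m),
    and r their Pearson correlation across levels.  Under pure binomial
    sampling at depth d, v = m*(1-m)/d exactly, so c = 1/d.

    Means and variances are taken within a level: pooling across levels
    would let the level spread dominate every variance and flatten all
    means to ~0.5, which measures the design of the experiment rather
    than the assay noise.
    """
    if dataset.n_probes < 3:
        raise ValueError("need >= 3 probes")
    means, variances = [], []
    lv = dataset.levels
    for level in sorted(lv.unique()):
        cols = lv.index[lv == level]
        vals = dataset.betas[cols].to_numpy(dtype=float).ravel()
        if len(vals) < 2:
            continue
        means.append(vals.mean())
        variances.append(vals.var(ddof=1))
    if len(means) < 2:
        raise ValueError("need >= 2 levels with >= 2 beta values each")
    m = np.asarray(means)
    v = np.asarray(variances)
    x = m * (1.0 - m)
    sxx = float((x ** 2).sum())
    c = float((x * v).sum() / sxx) if sxx > 0 else 0.0
    if v.std() == 0 or x.std() == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(v, x)[0])
    return MeanVarianceFit(c=c, r=r, n_cells=len(x))


def betas_from_counts(counts: pd.DataFrame,
                      min_depth: int | None = None) -> pd.Series:
    """Methylation fractions from sequencing counts.

    ``counts`` columns: chrom, position (1-based), methylated, total.
    Sites below ``min_depth`` total reads are dropped (the read-count
    filter used when comparing arrays with WGBS/RRBS).
    """
    df = counts.copy()
    if min_depth is not None:
        df = df[df["total"] >= min_depth]
    idx = df["chrom"].astype(str) + ":" + df["position"].astype(str)
    return pd.Series(df["methylated"].to_numpy(dtype=float)
                     / df["total"].to_numpy(dtype=float), index=idx)


def cross_platform_mean_correlation(matrix_a: pd.DataFrame,
                                    matrix_b: pd.DataFrame,
                                    shared_ids=None) -> tuple[float, int]:
    """Pearson r of per-probe mean methylation between two platforms.

    Means are taken within each platform across its samples, then
    correlated over the shared probe ids.  A platform given as a Series
    is treated as already-averaged per-site values (e.g. WGBS betas).
    """
    mean_a = matrix_a.mean(axis=1) if isinstance(matrix_a, pd.DataFrame) else matrix_a
    mean_b = matrix_b.mean(axis=1) if isinstance(matrix_b, pd.DataFrame) else matrix_b
    if shared_ids is None:
        shared_ids = mean_a.index.intersection(mean_b.index)
    shared_ids = pd.Index(shared_ids)
    if len(shared_ids) < 3:
        raise ValueError("need >= 3 shared probes")
    a = mean_a.reindex(shared_ids).to_numpy(dtype=float)
    b = mean_b.reindex(shared_ids).to_numpy(dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 3:
        raise ValueError("need >= 3 shared probes with values")
    r = float(stats.pearsonr(a[ok], b[ok])[0])
    return r, int(ok.sum())
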