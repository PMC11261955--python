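"""Seeded generators of synthetic GWAS inputs with known ground truth.

Three generators cover the statistical structure the pipeline assumes:

* :func:`simulate_effect_pairs` — two-trait effect pairs from a line-model
  mixture observed with per-variant Gaussian noise (the generative model
  behind the classifier);
* :func:`simulate_ld_block` — a block of Z-scores over correlated variants
  with one causal signal of given strength (the structure the clumping
  rule untangles);
* :func:`simulate_two_cohorts` — two noisy realisations of a base scan
  with unequal effective sample size and a population-private variant
  subset (the structure IVW meta-analysis combines).

Effects are in log-odds units throughout.  All generators are
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .linemodels import LineModelGroup, group_prior_cov
from .sumstats import LDMatrix, SummaryStatsTable, pval_from_chisq


def _config_hash(cfg) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class MixtureSimConfig:
    """Effect-pair mixture simulation settings.

    Defaults reproduce the study's classifier conditions: scale 0.6,
    correlation 0.99, a slope-0 trait-1-only group plus a shared group.
    """

    n: int = 400
    groups: list[LineModelGroup] = field(
        default_factory=lambda: [
            LineModelGroup(scale=0.6, slope=0.0, cor=0.99, slope_fixed=True),
            LineModelGroup(scale=0.6, slope=0.447, cor=0.99, slope_fixed=False),
        ]
    )
    proportions: tuple[float, ...] = (0.5, 0.5)
    se_low: float = 0.01
    se_high: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        if self.se_low <= 0 or self.se_high < self.se_low:
            raise ValueError("need 0 < se_low <= se_high")
        if len(self.proportions) != len(self.groups):
            raise ValueError("one proportion per group")


def simulate_effect_pairs(cfg: MixtureSimConfig) -> pd.DataFrame:
    """Draw effect pairs from the line-model mixture with observation noise.

    Returns a DataFrame with observed ``beta1 se1 beta2 se2``, plus ground
    truth: ``true_group`` (0-based), ``true_beta1``, ``true_beta2``.  The
    config hash is stored in ``df.attrs["config_hash"]``.
    """
    rng = np.random.default_rng(cfg.seed)
    z = rng.choice(len(cfg.groups), size=cfg.n, p=np.asarray(cfg.proportions))
    true = np.empty((cfg.n, 2))
    for k, g in enumerate(cfg.groups):
        sel = z == k
        if not sel.any():
            continue
        cov = group_prior_cov(g)
        # exact line prior (cor=1) makes cov singular; sample along the line
        if np.linalg.matrix_rank(cov, tol=1e-15) < 2:
            u = np.array([1.0, g.slope]) / np.hypot(1.0, g.slope)
            amp = rng.normal(0.0, g.scale, size=sel.sum())
            true[sel] = amp[:, None] * u[None, :]
        else:
            true[sel] = rng.multivariate_normal([0, 0], cov, size=sel.sum())
    se = rng.uniform(cfg.se_low, cfg.se_high, size=(cfg.n, 2))
    obs = true + rng.normal(0.0, se)
    df = pd.DataFrame(
        {
            "key": [f"v{i}" for i in range(cfg.n)],
            "beta1": obs[:, 0],
            "se1": se[:, 0],
            "beta2": obs[:, 1],
            "se2": se[:, 1],
            "true_group": z,
            "true_beta1": true[:, 0],
            "true_beta2": true[:, 1],
        }
    )
    df.attrs["config_hash"] = _config_hash(cfg)
    return df


@dataclass
class LDBlockSimConfig:
    """LD-block Z-score simulation settings.

    r between variants decays exponentially with distance
    (``r = exp(-decay * |dpos|)``, so r² is its square); the causal variant
    contributes noncentrality ``sqrt(causal_chisq)`` which propagates to
    its LD partners proportionally to r.
    """

    m: int = 10
    decay: float = 2e-6
    causal_idx: int = 0
    causal_chisq: float = 100.0
    positions: tuple[int, ...] | None = None
    chrom: str = "1"
    start_pos: int = 1_000_000
    spacing: int = 10_000
    se: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.causal_chisq < 0:
            raise ValueError("causal_chisq must be >= 0")
        if self.positions is not None and len(self.positions) != self.m:
            raise ValueError("positions length must equal m")
        if not 0 <= self.causal_idx < self.m:
            raise ValueError("causal_idx out of range")


def ld_block_correlation(cfg: LDBlockSimConfig) -> tuple[np.ndarray, np.ndarray]:
    """(positions, signed correlation matrix R) for a block; r2 = R**2."""
    if cfg.positions is not None:
        pos = np.asarray(cfg.positions, dtype=float)
    else:
        pos = cfg.start_pos + cfg.spacing * np.arange(cfg.m, dtype=float)
    d = np.abs(pos[:, None] - pos[None, :])
    r = np.exp(-cfg.decay * d)  # all-positive haplotype correlation
    return pos.astype(int), r


def simulate_ld_block(cfg: LDBlockSimConfig, n_draws: int = 1) -> tuple[SummaryStatsTable, LDMatrix, np.ndarray]:
    """Draw Z-score vectors over one LD block with a single causal signal.

    Z ~ N(mu, R) with mu_i = r(i, causal) * sqrt(causal_chisq).  Returns a
    summary-statistics table built from the first draw (beta = Z * se with
    fixed se), the LD matrix (r²), and the full (n_draws, m) Z array.
    """
    rng = np.random.default_rng(cfg.seed)
    pos, r = ld_block_correlation(cfg)
    mu = r[:, cfg.causal_idx] * np.sqrt(cfg.causal_chisq)
    # jitter for numerical PSD; signed R is a valid correlation matrix here
    eigmin = np.linalg.eigvalsh(r).min()
    jitter = 0.0 if eigmin > 1e-10 else (1e-10 - eigmin)
    cov = r + jitter * np.eye(cfg.m)
    if np.linalg.eigvalsh(cov).min() < -1e-8:
        raise ValueError("LD correlation matrix is not PSD")
    z = rng.multivariate_normal(mu, cov, size=n_draws)
    z0 = z[0]
    beta = z0 * cfg.se
    df = pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "pos": pos,
            "ref": "A",
            "alt": "G",
            "af": 0.3,
            "beta": beta,
            "se": cfg.se,
            "pval": pval_from_chisq(z0**2),
        }
    )
    table = SummaryStatsTable(df, cohort="sim")
    keys = [f"{cfg.chrom}:{p}:A:G" for p in pos]
    ld = LDMatrix(keys, r**2)
    return table, ld, z


def simulate_two_cohorts(
    base: SummaryStatsTable,
    n_eff_ratio: float = 1.0,
    finnish_only_fraction: float = 0.0,
    noise_scale: float = 1.0,
    seed: int = 0,
) -> tuple[SummaryStatsTable, SummaryStatsTable, list[str]]:
    """Derive two cohort scans from a base table.

    Cohort A resamples the base betas with their own SE noise; cohort B has
    SEs inflated by sqrt(1/n_eff_ratio) (smaller effective sample) and a
    seeded fraction of variants removed entirely — the population-private
    set, returned as the third element.  ``noise_scale=0`` gives noiseless
    copies for exact bookkeeping checks.
    """
    rng = np.random.default_rng(seed)
    df = base.df

    def _cohort(scale_se: float) -> pd.DataFrame:
        out = df.copy()
        out["se"] = df["se"] * scale_se
        out["beta"] = df["beta"] + noise_scale * rng.normal(0.0, out["se"])
        out["pval"] = pval_from_chisq((out["beta"] / out["se"]) ** 2)
        return out

    a = _cohort(1.0)
    b = _cohort(float(np.sqrt(1.0 / n_eff_ratio)))
    n_remove = int(round(finnish_only_fraction * len(df)))
    removed: list[str] = []
    if n_remove:
        drop_idx = rng.choice(len(df), size=n_remove, replace=False)
        removed = [
            f"{r.chrom}:{r.pos}:{r.ref}:{r.alt}"
            for r in df.iloc[drop_idx].itertuples(index=False)
        ]
        b = b.drop(b.index[drop_idx])
    return (
        SummaryStatsTable(a, cohort="cohort_a"),
        SummaryStatsTable(b, cohort="cohort_b"),
        removed,
    )
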