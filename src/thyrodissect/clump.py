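"""LD-independent index-variant selection with a dynamic residual-chi-square
threshold, and 1 Mb locus merging.

The admission rule, applied greedily from the most significant genome-wide
hit downwards:

* each admitted index carries a dynamic LD threshold
  ``T = min(t_cap, resid_chisq / chisq)`` — the r² at which a correlated
  variant would retain an expected residual chi-square of ``resid_chisq``
  given the index's own chi-square (noncentrality transfers as r²·chi²);
* a candidate is blocked if its r² to any already-admitted index within
  ``window_bp`` reaches that index's threshold;
* around exceptionally strong indexes whose threshold falls below
  ``t_floor`` (where small r² values are unreliable), no further signal is
  admitted within ``suppress_bp`` at all;
* at most ``max_per_mb`` indexes may fall inside any window of width
  ``suppress_bp``.

Admitted indexes within ``locus_merge_bp`` of each other are chained into
a single locus (single linkage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import LDMatrix, SumstatsError


@dataclass(frozen=True)
class ClumpConfig:
    """Clumping parameters; defaults follow the published procedure."""

    p_threshold: float = 5e-8
    t_cap: float = 0.1
    resid_chisq: float = 5.0
    t_floor: float = 0.02
    window_bp: int = 2_000_000
    suppress_bp: int = 1_000_000
    max_per_mb: int = 2
    locus_merge_bp: int = 1_000_000

    def __post_init__(self) -> None:
        if not (0 < self.t_floor < self.t_cap <= 1):
            raise ValueError("require 0 < t_floor < t_cap <= 1")
        for name in ("window_bp", "suppress_bp", "locus_merge_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def dynamic_threshold(chisq: float, cfg: ClumpConfig = ClumpConfig()) -> float:
    """Dynamic LD threshold ``T = min(t_cap, resid_chisq / chisq)``.

    ``resid_chisq / chisq`` is the r² at which the expected residual
    chi-square of a variant correlated with the lead equals ``resid_chisq``.
    """
    if chisq <= 0:
        raise SumstatsError("chisq must be > 0")
    return min(cfg.t_cap, cfg.resid_chisq / chisq)


@dataclass
class IndexVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    beta: float
    se: float
    pval: float
    chisq: float
    threshold_T: float
    rank: int
    key: str = field(init=False)

    def __post_init__(self) -> None:
        self.key = f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class Locus:
    locus_id: int
    chrom: str
    start: int
    end: int
    indexes: list[IndexVariant]


def _candidate_frame(stats: pd.DataFrame, cfg: ClumpConfig) -> pd.DataFrame:
    df = stats.copy()
    if "beta_meta" in df.columns:
        df = df.rename(
            columns={"beta_meta": "beta", "se_meta": "se", "pval_meta": "pval"}
        )
    df["chisq"] = (df["beta"] / df["se"]) ** 2
    df = df[df["pval"] <= cfg.p_threshold]
    # greedy order: significance first (chi-square breaks p underflow ties),
    # then position, then alleles — deterministic on any fixture
    return df.sort_values(
        ["pval", "chisq", "chrom", "pos", "ref", "alt"],
        ascending=[True, False, True, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)


def _cap_violated(positions: list[int], cfg: ClumpConfig) -> bool:
    """True if some window of width suppress_bp holds > max_per_mb positions."""
    pos = sorted(positions)
    k = cfg.max_per_mb
    for i in range(len(pos) - k):
        if pos[i + k] - pos[i] <= cfg.suppress_bp:
            return True
    return False


def select_index_variants(
    stats: pd.DataFrame,
    ld: LDMatrix,
    cfg: ClumpConfig = ClumpConfig(),
) -> list[IndexVariant]:
    """Greedy selection of LD-independent genome-wide-significant indexes.

    Parameters
    ----------
    stats
        Meta-analysis records (``beta_meta/se_meta/pval_meta`` or plain
        ``beta/se/pval`` columns) with variant keys.
    ld
        Pairwise r²; pairs it does not cover are treated as r²=0.
    """
    cands = _candidate_frame(stats, cfg)
    admitted: list[IndexVariant] = []
    for row in cands.itertuples(index=False):
        key = f"{row.chrom}:{row.pos}:{row.ref}:{row.alt}"
        blocked = False
        for idx in admitted:
            if idx.chrom != str(row.chrom):
                continue
            dist = abs(idx.pos - row.pos)
            if dist <= cfg.window_bp and ld.get(key, idx.key) >= idx.threshold_T:
                blocked = True
                break
            if idx.threshold_T < cfg.t_floor and dist <= cfg.suppress_bp:
                blocked = True
                break
        if not blocked:
            same_chrom = [a.pos for a in admitted if a.chrom == str(row.chrom)]
            blocked = _cap_violated(same_chrom + [row.pos], cfg)
        if blocked:
            continue
        admitted.append(
            IndexVariant(
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                beta=float(row.beta),
                se=float(row.se),
                pval=float(row.pval),
                chisq=float(row.chisq),
                threshold_T=dynamic_threshold(float(row.chisq), cfg),
                rank=len(admitted) + 1,
            )
        )
    return admitted


def merge_loci(
    indexes: list[IndexVariant], cfg: ClumpConfig = ClumpConfig()
) -> list[Locus]:
    """Single-linkage chaining of indexes within ``locus_merge_bp``."""
    ordered = sorted(indexes, key=lambda v: (v.chrom, v.pos))
    loci: list[Locus] = []
    for iv in ordered:
        last = loci[-1] if loci else None
        if (
            last is not None
            and last.chrom == iv.chrom
            and iv.pos - last.end <= cfg.locus_merge_bp
        ):
            last.indexes.append(iv)
            last.end = iv.pos
        else:
            loci.append(
                Locus(
                    locus_id=len(loci) + 1,
                    chrom=iv.chrom,
                    start=iv.pos,
                    end=iv.pos,
                    indexes=[iv],
                )
            )
    return loci


def index_variants_frame(indexes: list[IndexVariant], loci: list[Locus] | None = None) -> pd.DataFrame:
    """Tabular view: ``chrom pos ref alt beta se pval chisq threshold_T rank locus_id``."""
    locus_of: dict[str, int] = {}
    if loci:
        for loc in loci:
            for iv in loc.indexes:
                locus_of[iv.key] = loc.locus_id
    rows = [
        {
            "chrom": iv.chrom, "pos": iv.pos, "ref": iv.ref, "alt": iv.alt,
            "beta": iv.beta, "se": iv.se, "pval": iv.pval, "chisq": iv.chisq,
            "threshold_T": iv.threshold_T, "rank": iv.rank,
            "locus_id": locus_of.get(iv.key, pd.NA),
        }
        for iv in indexes
    ]
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "beta", "se", "pval",
                 "chisq", "threshold_T", "rank", "locus_id"],
    )
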