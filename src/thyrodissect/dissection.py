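"""Downstream dissection statistics over index variants and memberships.

Turns classifications and secondary-scan lookups into the headline
numbers of a cross-trait dissection: Bonferroni overlap counts with
direction concordance, sharing proportions over the strongest hits,
cross-membership Spearman correlation, and coding-category frequency
enrichment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats


def bonferroni_thresholds(
    n_tests: int, fwer: float = 0.05, per_expected: float = 1.0
) -> tuple[float, float]:
    """Strict and loose per-test p-value cutoffs for ``n_tests`` lookups.

    strict = fwer / n_tests (family-wise control); loose =
    per_expected / n_tests (the threshold at which ``per_expected`` hits
    are expected by chance).
    """
    if n_tests <= 0:
        raise ValueError("n_tests must be > 0")
    return fwer / n_tests, per_expected / n_tests


@dataclass
class OverlapReport:
    """Secondary-scan overlap counts at two Bonferroni thresholds."""

    n_index: int
    n_skipped: int
    threshold_strict: float
    threshold_loose: float
    n_strict: int
    n_loose: int
    n_concordant: int
    n_discordant: int
    expected_strict: float
    expected_loose: float

    def to_dict(self) -> dict:
        return asdict(self)


def overlap_report(
    pairs: pd.DataFrame,
    threshold_strict: float,
    threshold_loose: float,
) -> OverlapReport:
    """Count index variants replicating in a second scan.

    ``pairs`` needs columns ``beta1 beta2 pval2`` (effect alleles already
    harmonized across the scans).  Rows with missing ``pval2`` are skipped
    and counted — a secondary scan rarely covers every index variant.
    Concordance (sign(beta1)·sign(beta2) > 0; a zero beta counts as
    discordant) is assessed among the loose hits.
    """
    have = pairs["pval2"].notna()
    sub = pairs.loc[have]
    n_index = int(have.sum())
    p2 = sub["pval2"].to_numpy(dtype=float)
    strict = p2 < threshold_strict
    loose = p2 < threshold_loose
    prod = np.sign(sub["beta1"].to_numpy()) * np.sign(sub["beta2"].to_numpy())
    concordant = int(np.sum(loose & (prod > 0)))
    return OverlapReport(
        n_index=n_index,
        n_skipped=int((~have).sum()),
        threshold_strict=threshold_strict,
        threshold_loose=threshold_loose,
        n_strict=int(strict.sum()),
        n_loose=int(loose.sum()),
        n_concordant=concordant,
        n_discordant=int(loose.sum()) - concordant,
        expected_strict=n_index * threshold_strict,
        expected_loose=n_index * threshold_loose,
    )


def sharing_proportion(
    posteriors: pd.DataFrame,
    p1: pd.Series,
    top_cutoff: float = 1e-11,
    shared_col: str = "p_group2",
    hard: bool = False,
) -> float:
    """Estimated proportion of shared associations among the strongest hits.

    Restricts to variants with primary-scan p below ``top_cutoff`` (the
    confidently classifiable top of the distribution) and averages the
    shared-group posterior.  ``hard=True`` counts posteriors > 0.5
    instead of averaging (higher variance; provided for comparison).
    """
    merged = posteriors.merge(
        p1.rename("p1").rename_axis("key").reset_index(), on="key"
    )
    top = merged.loc[merged["p1"] < top_cutoff, shared_col]
    if len(top) == 0:
        raise ValueError("no variants pass the top cutoff")
    if hard:
        return float((top > 0.5).mean())
    return float(top.mean())


def membership_spearman(m1, m2) -> dict:
    """Spearman rank correlation between two membership-posterior vectors.

    Average ranks for ties; two-sided p from the t approximation, or by
    exact permutation when n < 10.  A constant vector leaves rho undefined
    and is flagged rather than raised.
    """
    x = np.asarray(m1, dtype=float)
    y = np.asarray(m2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("m1 and m2 must be 1-D and the same length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"rho": float("nan"), "p": float("nan"), "constant_input": True}
    if n < 10:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = _rank_corr(rx, ry)
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_rank_corr(rx, np.asarray(perm))) >= abs(obs) - 1e-12:
                count += 1
        return {"rho": float(obs), "p": count / total, "constant_input": False}
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p), "constant_input": False}


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


CODING_HI = "r2_gt_095"
CODING_MID = "r2_070_095"
CODING_OTHER = "other"


def categorize_coding(
    ld_to_coding: dict[str, float] | pd.Series,
    cut_hi: float = 0.95,
    cut_lo: float = 0.70,
) -> pd.DataFrame:
    """Assign each index variant a coding-association category from its best
    r² to any protein-coding variant.

    r² > cut_hi (a coding lead variant is encoded as r²=1) → the most
    likely coding-association category; cut_lo < r² ≤ cut_hi → the
    intermediate category; otherwise ``other``.
    """
    series = pd.Series(ld_to_coding, dtype=float)
    if ((series < 0) | (series > 1)).any():
        raise ValueError("r2 values must lie in [0, 1]")
    cat = np.where(
        series > cut_hi, CODING_HI,
        np.where(series > cut_lo, CODING_MID, CODING_OTHER),
    )
    return pd.DataFrame(
        {"key": series.index, "best_r2_to_coding": series.to_numpy(), "category": cat}
    ).reset_index(drop=True)


@dataclass
class EnrichmentTable:
    """2x2 counts: coding-association category x allele-frequency class."""

    a: int  # low-frequency, coding
    b: int  # low-frequency, non-coding
    c: int  # common, coding
    d: int  # common, non-coding

    @property
    def prop_low(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def prop_common(self) -> float:
        return self.c / (self.c + self.d)

    def to_dict(self) -> dict:
        return asdict(self)


def coding_enrichment(
    categories: pd.DataFrame,
    low_freq_keys: set[str],
    coding_category: str = CODING_HI,
) -> dict:
    """Test whether low-frequency index variants are enriched for coding
    associations.

    Builds the 2x2 of coding-category membership against frequency class
    and computes the fold excess (low-frequency coding proportion over
    common coding proportion) with a two-sided Fisher's exact p.
    """
    is_low = categories["key"].isin(low_freq_keys).to_numpy()
    is_coding = (categories["category"] == coding_category).to_numpy()
    table = EnrichmentTable(
        a=int(np.sum(is_low & is_coding)),
        b=int(np.sum(is_low & ~is_coding)),
        c=int(np.sum(~is_low & is_coding)),
        d=int(np.sum(~is_low & ~is_coding)),
    )
    return enrichment_stats(table)


def enrichment_stats(table: EnrichmentTable) -> dict:
    """Fold excess and two-sided Fisher's exact p for a 2x2 table."""
    if table.a + table.b == 0 or table.c + table.d == 0:
        raise ValueError("empty margin in the 2x2 table")
    if table.prop_common == 0:
        fold = float("inf") if table.prop_low > 0 else float("nan")
        flagged = True
    else:
        fold = table.prop_low / table.prop_common
        flagged = False
    _, p = stats.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative="two-sided"
    )
    return {
        "table": table,
        "prop_low": table.prop_low,
        "prop_common": table.prop_common,
        "fold": fold,
        "p_fisher": float(p),
        "fold_undefined": flagged,
    }
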