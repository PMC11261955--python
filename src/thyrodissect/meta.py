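"""Fixed-effects inverse-variance-weighted (IVW) meta-analysis of two cohorts.

Two-cohort variants are combined with weights w_k = 1/se_k²:

    beta_meta = (w_a * beta_a + w_b * beta_b) / (w_a + w_b)
    se_meta   = (w_a + w_b) ** -0.5

Variants present in a single cohort pass through unchanged with
``n_cohorts = 1`` and a provenance label, so population-enriched hits seen
in only one biobank are retained.  A Cochran's Q column is emitted for
diagnostics only; no heterogeneity filtering is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sumstats import KEY_COLUMNS, HarmonizedPair, pval_from_chisq

META_COLUMNS = KEY_COLUMNS + [
    "af", "beta_meta", "se_meta", "pval_meta", "n_cohorts", "source", "cochran_q",
]


@dataclass(frozen=True)
class StudyCounts:
    """Per-cohort case/control bookkeeping for the meta-analysis report."""

    cases_a: int
    cases_b: int
    controls_a: int = 0
    controls_b: int = 0

    @property
    def total_cases(self) -> int:
        return self.cases_a + self.cases_b

    @property
    def total_controls(self) -> int:
        return self.controls_a + self.controls_b


def ivw_meta(
    pair: HarmonizedPair,
    label_a: str = "cohort_a",
    label_b: str = "cohort_b",
    drop_singletons: bool = False,
) -> pd.DataFrame:
    """Combine a harmonized two-cohort join into meta-analysis records.

    Parameters
    ----------
    pair
        Output of :func:`thyrodissect.sumstats.harmonize_pair`.
    drop_singletons
        If True, exclude variants seen in only one cohort.

    Returns
    -------
    DataFrame with columns ``chrom pos ref alt af beta_meta se_meta
    pval_meta n_cohorts source cochran_q``, sorted by significance rank of
    the combined chi-square.
    """
    parts = []
    j = pair.joined
    if len(j):
        w_a = 1.0 / j["se_a"] ** 2
        w_b = 1.0 / j["se_b"] ** 2
        wsum = w_a + w_b
        beta = (w_a * j["beta_a"] + w_b * j["beta_b"]) / wsum
        se = wsum**-0.5
        # Cochran's Q against the pooled estimate; diagnostics only
        q = w_a * (j["beta_a"] - beta) ** 2 + w_b * (j["beta_b"] - beta) ** 2
        af = (w_a * j["af_a"] + w_b * j["af_b"]) / wsum
        both = j[KEY_COLUMNS].copy()
        both["af"] = af
        both["beta_meta"] = beta
        both["se_meta"] = se
        both["pval_meta"] = pval_from_chisq((beta / se) ** 2)
        both["n_cohorts"] = 2
        both["source"] = f"{label_a}+{label_b}"
        both["cochran_q"] = q
        parts.append(both)

    if not drop_singletons:
        for single, label in ((pair.only_a, label_a), (pair.only_b, label_b)):
            if not len(single):
                continue
            s = single[KEY_COLUMNS + ["af"]].copy()
            s["beta_meta"] = single["beta"].to_numpy()
            s["se_meta"] = single["se"].to_numpy()
            s["pval_meta"] = pval_from_chisq(
                (single["beta"] / single["se"]) ** 2
            )
            s["n_cohorts"] = 1
            s["source"] = label
            s["cochran_q"] = np.nan
            parts.append(s)

    if not parts:
        return pd.DataFrame(columns=META_COLUMNS)
    out = pd.concat(parts, ignore_index=True)[META_COLUMNS]
    chisq = (out["beta_meta"] / out["se_meta"]) ** 2
    return (
        out.assign(_chisq=chisq)
        .sort_values("_chisq", ascending=False, kind="mergesort")
        .drop(columns="_chisq")
        .reset_index(drop=True)
    )
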