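"""GWAS summary-statistics containers, I/O and harmonization.

Conventions shared by every downstream stage:

* positions are 1-based inclusive, GRCh38;
* the variant key is ``(chrom, pos, ref, alt)`` with ``alt`` the effect allele;
* ``beta`` is the additive log-odds effect per effect allele, ``se`` its
  standard error, ``pval`` the two-sided p-value;
* association strength is always measured as the 1-df chi-square
  ``(beta/se)**2``, never inverted from the p-value, so that hits with
  p-values far below double underflow remain usable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: canonical column order of a summary-statistics table
CANONICAL_COLUMNS = ["chrom", "pos", "ref", "alt", "af", "beta", "se", "pval"]

KEY_COLUMNS = ["chrom", "pos", "ref", "alt"]

#: MHC interval on GRCh38, excluded from variant-level counting
MHC_REGION_GRCH38 = ("6", 28_510_120, 33_480_577)


class SumstatsError(ValueError):
    """Raised on malformed summary-statistics input."""


@dataclass(frozen=True)
class GenomicRegion:
    """Closed genomic interval, 1-based inclusive on both ends."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise SumstatsError(
                f"region start {self.start} exceeds end {self.end}"
            )

    def contains(self, chrom: str, pos: int) -> bool:
        return str(chrom) == self.chrom and self.start <= pos <= self.end


def mhc_region() -> GenomicRegion:
    """The GRCh38 MHC interval (chr6:28,510,120-33,480,577)."""
    chrom, start, end = MHC_REGION_GRCH38
    return GenomicRegion(chrom, start, end)


@dataclass
class SummaryStatsTable:
    """Sorted, key-unique table of per-variant association statistics.

    ``df`` holds the canonical columns; extra columns are carried along
    untouched.  ``n_cases`` / ``n_controls`` are optional cohort-level
    sample counts used only for bookkeeping in the meta-analysis report.
    """

    df: pd.DataFrame
    cohort: str = ""
    build: str = "GRCh38"
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise SumstatsError(f"missing required columns: {missing}")
        self.df = _canonicalize(self.df)
        dup = self.df.duplicated(subset=KEY_COLUMNS)
        if dup.any():
            key = self.df.loc[dup.idxmax(), KEY_COLUMNS].tolist()
            raise SumstatsError(f"duplicate variant key: {tuple(key)}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def keys(self) -> pd.Series:
        return variant_key_series(self.df)


def variant_key_series(df: pd.DataFrame) -> pd.Series:
    """``chrom:pos:ref:alt`` string key per row."""
    return (
        df["chrom"].astype(str)
        + ":" + df["pos"].astype(int).astype(str)
        + ":" + df["ref"].astype(str)
        + ":" + df["alt"].astype(str)
    )


def _chrom_sort_key(chrom: pd.Series) -> pd.Series:
    order = {str(i): i for i in range(1, 23)}
    order.update({"X": 23, "Y": 24, "MT": 25})
    return chrom.astype(str).map(lambda c: order.get(c, 99))


def _canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["chrom"] = df["chrom"].astype(str).str.removeprefix("chr")
    df["pos"] = df["pos"].astype(int)
    for col in ("af", "beta", "se", "pval"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = df.sort_values(
        ["pos", "ref", "alt"], kind="mergesort"
    ).sort_values("chrom", key=_chrom_sort_key, kind="mergesort")
    extra = [c for c in df.columns if c not in CANONICAL_COLUMNS]
    return df[CANONICAL_COLUMNS + extra].reset_index(drop=True)


def read_sumstats(
    path,
    column_map: dict[str, str] | None = None,
    cohort: str = "",
    sep: str = "\t",
) -> SummaryStatsTable:
    """Read a delimited summary-statistics file.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    column_map
        Mapping from canonical name (``chrom``, ``pos``, ...) to the column
        name used in the file; canonical names missing from the map are
        assumed to appear verbatim.
    cohort
        Free-text label attached to the table.

    Rows with missing ``beta`` or ``se``, or with ``se <= 0``, are dropped
    and the count logged.
    """
    raw = pd.read_csv(path, sep=sep)
    column_map = column_map or {}
    rename = {}
    for canon in CANONICAL_COLUMNS:
        src = column_map.get(canon, canon)
        if src not in raw.columns:
            raise SumstatsError(
                f"column {src!r} (for {canon!r}) not found in {path}"
            )
        rename[src] = canon
    df = raw.rename(columns=rename)
    for col in ("af", "beta", "se", "pval"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df["beta"].isna() | df["se"].isna() | (df["se"] <= 0)
    if bad.any():
        logger.info("dropping %d rows with missing beta/se or se<=0", bad.sum())
    return SummaryStatsTable(df.loc[~bad], cohort=cohort)


def write_sumstats(table: SummaryStatsTable, path, float_format: str = "%.8g") -> None:
    table.df.to_csv(path, sep="\t", index=False, float_format=float_format)


def exclude_region(table: SummaryStatsTable, region: GenomicRegion) -> SummaryStatsTable:
    """Drop every variant inside ``region`` (both boundaries inclusive)."""
    df = table.df
    inside = (df["chrom"] == region.chrom) & df["pos"].between(region.start, region.end)
    return SummaryStatsTable(
        df.loc[~inside],
        cohort=table.cohort,
        build=table.build,
        n_cases=table.n_cases,
        n_controls=table.n_controls,
    )


def chisq_from_stats(beta, se):
    """1-df association chi-square ``(beta/se)**2``.

    Computed from the effect and its standard error rather than by
    inverting the p-value, so the statistic does not saturate for the
    strongest associations.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise SumstatsError("se must be > 0")
    out = (beta / se) ** 2
    return float(out) if out.ndim == 0 else out


def pval_from_chisq(chisq):
    """Two-sided p-value from a 1-df chi-square statistic."""
    return stats.chi2.sf(chisq, df=1)


@dataclass
class HarmonizedPair:
    """Result of joining two cohorts' tables on the variant key.

    ``joined`` carries suffixed statistic columns (``beta_a`` ...); rows
    present in only one cohort land in ``only_a`` / ``only_b``;
    ``n_flipped`` counts rows of ``b`` matched with ref/alt swapped (their
    beta negated and af complemented before the join); ``n_incompatible``
    counts b-rows whose alleles matched neither orientation at a shared
    position.
    """

    joined: pd.DataFrame
    only_a: pd.DataFrame
    only_b: pd.DataFrame
    n_flipped: int = 0
    n_incompatible: int = 0


def harmonize_pair(a: SummaryStatsTable, b: SummaryStatsTable) -> HarmonizedPair:
    """Join two cohorts on ``(chrom,pos,ref,alt)``, allowing allele swaps.

    A ``b`` record whose ref/alt are swapped relative to ``a`` is flipped
    (beta negated, af complemented) before joining.  Strand flips are never
    attempted: both cohorts are assumed aligned to the same build.  Records
    at a shared position whose alleles are incompatible under swap are
    excluded from ``b`` and counted.
    """
    adf, bdf = a.df.copy(), b.df.copy()
    akeys = set(variant_key_series(adf))
    bkeys = variant_key_series(bdf)

    direct = bkeys.isin(akeys)
    swapped_key = (
        bdf["chrom"].astype(str)
        + ":" + bdf["pos"].astype(str)
        + ":" + bdf["alt"] + ":" + bdf["ref"]
    )
    flip = ~direct & swapped_key.isin(akeys)

    # positions shared with a but alleles matching neither orientation
    apos = set(zip(adf["chrom"], adf["pos"]))
    bpos = list(zip(bdf["chrom"], bdf["pos"]))
    shared_pos = pd.Series([p in apos for p in bpos], index=bdf.index)
    incompatible = shared_pos & ~direct & ~flip
    n_incompatible = int(incompatible.sum())
    if n_incompatible:
        logger.info("excluding %d allele-incompatible records", n_incompatible)

    if flip.any():
        bdf.loc[flip, ["ref", "alt"]] = bdf.loc[flip, ["alt", "ref"]].to_numpy()
        bdf.loc[flip, "beta"] = -bdf.loc[flip, "beta"]
        bdf.loc[flip, "af"] = 1.0 - bdf.loc[flip, "af"]
    bdf = bdf.loc[~incompatible]

    stat_cols = ["af", "beta", "se", "pval"]
    joined = adf.merge(bdf, on=KEY_COLUMNS, suffixes=("_a", "_b"), how="inner")
    joined = joined[KEY_COLUMNS + [f"{c}_a" for c in stat_cols] + [f"{c}_b" for c in stat_cols]]

    jkeys = set(variant_key_series(joined))
    only_a = adf.loc[~variant_key_series(adf).isin(jkeys)].reset_index(drop=True)
    only_b = bdf.loc[~variant_key_series(bdf).isin(jkeys)].reset_index(drop=True)
    return HarmonizedPair(
        joined=joined.reset_index(drop=True),
        only_a=only_a,
        only_b=only_b,
        n_flipped=int(flip.sum()),
        n_incompatible=n_incompatible,
    )


@dataclass
class LDMatrix:
    """Pairwise squared-correlation matrix for a set of variants.

    ``keys`` are ``chrom:pos:ref:alt`` strings; ``r2`` is symmetric with a
    unit diagonal and entries in [0, 1].  Pairs absent from a triplet input
    default to r²=0 — clumping then treats unknown LD as independence.
    """

    keys: list[str]
    r2: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        m = len(self.keys)
        if self.r2.shape != (m, m):
            raise SumstatsError(f"r2 shape {self.r2.shape} != ({m}, {m})")
        if not np.allclose(self.r2, self.r2.T, atol=1e-9):
            raise SumstatsError("r2 matrix not symmetric")
        if np.any((self.r2 < -1e-12) | (self.r2 > 1 + 1e-12)):
            raise SumstatsError("r2 entries outside [0, 1]")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-9):
            raise SumstatsError("r2 diagonal must be 1")
        self.r2 = np.clip(self.r2, 0.0, 1.0)
        np.fill_diagonal(self.r2, 1.0)
        self._index = {k: i for i, k in enumerate(self.keys)}

    def get(self, key_i: str, key_j: str) -> float:
        """r² between two variants; unknown pairs are 0 (independence)."""
        if key_i == key_j:
            return 1.0
        i = self._index.get(key_i)
        j = self._index.get(key_j)
        if i is None or j is None:
            return 0.0
        return float(self.r2[i, j])


def read_ld(path, sep: str = "\t") -> LDMatrix:
    """Read LD as either triplet (``key_i key_j r2``) or square-matrix text.

    A square matrix is recognised by its header naming the variant keys in
    every column.  Triplets are symmetrized; missing pairs default to 0.
    """
    df = pd.read_csv(path, sep=sep)
    if list(df.columns[:3]) == ["key_i", "key_j", "r2"] and df.shape[1] == 3:
        keys: list[str] = []
        seen = set()
        for k in pd.concat([df["key_i"], df["key_j"]]):
            if k not in seen:
                seen.add(k)
                keys.append(k)
        idx = {k: i for i, k in enumerate(keys)}
        m = len(keys)
        r2 = np.zeros((m, m))
        np.fill_diagonal(r2, 1.0)
        for ki, kj, v in df.itertuples(index=False):
            r2[idx[ki], idx[kj]] = v
            r2[idx[kj], idx[ki]] = v
        n_pairs = m * (m - 1) // 2
        if len(df) < n_pairs:
            logger.warning(
                "LD triplets cover %d of %d pairs; missing pairs set to r2=0",
                len(df), n_pairs,
            )
        return LDMatrix(keys, r2)
    # square-matrix dialect: first column holds row keys
    keys = df.iloc[:, 0].astype(str).tolist()
    mat = df.iloc[:, 1:].to_numpy(dtype=float)
    return LDMatrix(keys, mat)


def write_ld_triplets(ld: LDMatrix, path) -> None:
    rows = []
    m = len(ld.keys)
    for i in range(m):
        for j in range(i + 1, m):
            rows.append((ld.keys[i], ld.keys[j], ld.r2[i, j]))
    pd.DataFrame(rows, columns=["key_i", "key_j", "r2"]).to_csv(
        path, sep="\t", index=False, float_format="%.8g"
    )
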