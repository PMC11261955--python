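"""End-to-end orchestration: meta-analysis → MHC exclusion → clumping →
effect-pair construction → classification → dissection, driven by one YAML
config, with a machine-readable run report.

Every stage's outputs are written under ``out_dir`` and checksummed in the
report, so a rerun with the same config and seed can be verified
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clump as clump_mod
from . import dissection as diss
from .linemodels import LineModelGroup, LineModelMixture, lrt_groups
from .meta import ivw_meta
from .sumstats import (
    SummaryStatsTable,
    harmonize_pair,
    exclude_region,
    mhc_region,
    read_ld,
    read_sumstats,
    variant_key_series,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    cohort_a: str
    cohort_b: str
    ld: str
    out_dir: str
    seed: int
    secondary: dict[str, str] = field(default_factory=dict)
    coding_ld: str | None = None
    clump: dict = field(default_factory=dict)
    classifier: dict = field(default_factory=dict)
    dissection: dict = field(default_factory=dict)
    exclude_mhc: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        paths = [self.cohort_a, self.cohort_b, self.ld, *self.secondary.values()]
        if self.coding_ld:
            paths.append(self.coding_ld)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"config references missing paths: {missing}")
        if self.seed is None:
            raise ValueError("a seed is required (classification is stochastic)")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _parse_slopes(spec: list) -> list[LineModelGroup]:
    scale = 0.6
    cor = 0.99
    groups = []
    for item in spec:
        if isinstance(item, str) and item.startswith("free"):
            init = float(item.split(":", 1)[1]) if ":" in item else 0.5
            groups.append(LineModelGroup(scale, init, cor, slope_fixed=False))
        else:
            groups.append(LineModelGroup(scale, float(item), cor, slope_fixed=True))
    return groups


def build_effect_pairs(
    index_frame: pd.DataFrame, meta_table: SummaryStatsTable, secondary: SummaryStatsTable
) -> pd.DataFrame:
    """Pair each index variant's primary effect with the secondary scan's.

    Index variants absent from the secondary scan keep NaN secondary
    columns (they count as skipped in overlap reports).
    """
    keys = (
        index_frame["chrom"].astype(str) + ":" + index_frame["pos"].astype(str)
        + ":" + index_frame["ref"] + ":" + index_frame["alt"]
    )
    sub = meta_table.df.loc[variant_key_series(meta_table.df).isin(set(keys))]
    sub_table = SummaryStatsTable(sub, cohort=meta_table.cohort)
    harm = harmonize_pair(sub_table, secondary)
    j = harm.joined
    pairs = pd.DataFrame(
        {
            "key": variant_key_series(j),
            "beta1": j["beta_a"], "se1": j["se_a"], "pval1": j["pval_a"],
            "beta2": j["beta_b"], "se2": j["se_b"], "pval2": j["pval_b"],
            "af1": j["af_a"],
        }
    )
    only = harm.only_a
    if len(only):
        pairs = pd.concat(
            [
                pairs,
                pd.DataFrame(
                    {
                        "key": variant_key_series(only),
                        "beta1": only["beta"].to_numpy(),
                        "se1": only["se"].to_numpy(),
                        "pval1": only["pval"].to_numpy(),
                        "beta2": float("nan"), "se2": float("nan"),
                        "pval2": float("nan"),
                        "af1": only["af"].to_numpy(),
                    }
                ),
            ],
            ignore_index=True,
        )
    return pairs.sort_values("key", kind="mergesort").reset_index(drop=True)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full dissection pipeline; returns the run report."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "config": {
        "seed": cfg.seed, "clump": cfg.clump,
        "classifier": cfg.classifier, "dissection": cfg.dissection,
    }, "outputs": {}}

    def _stage(name):
        t0 = time.time()

        def done(**extra):
            report["stages"][name] = {"status": "ok",
                                      "seconds": round(time.time() - t0, 3), **extra}
            logger.info("stage %s ok (%.2fs)", name, time.time() - t0)

        return done

    def _write(name: str, df: pd.DataFrame) -> Path:
        path = out / name
        df.to_csv(path, sep="\t", index=False, float_format="%.8g")
        report["outputs"][name] = _sha256(path)
        return path

    try:
        # --- meta-analysis -------------------------------------------------
        done = _stage("meta")
        a = read_sumstats(cfg.cohort_a, cohort="cohort_a")
        b = read_sumstats(cfg.cohort_b, cohort="cohort_b")
        harm = harmonize_pair(a, b)
        meta_df = ivw_meta(harm, label_a=a.cohort or "a", label_b=b.cohort or "b")
        _write("meta.tsv", meta_df)
        done(n_joined=len(harm.joined), n_only_a=len(harm.only_a),
             n_only_b=len(harm.only_b), n_meta=len(meta_df))

        # --- MHC exclusion + clumping -------------------------------------
        done = _stage("clump")
        meta_table = SummaryStatsTable(
            meta_df.rename(columns={"beta_meta": "beta", "se_meta": "se",
                                    "pval_meta": "pval"})[
                ["chrom", "pos", "ref", "alt", "af", "beta", "se", "pval"]
            ],
            cohort="meta",
        )
        if cfg.exclude_mhc:
            meta_table = exclude_region(meta_table, mhc_region())
        ld = read_ld(cfg.ld)
        ccfg = clump_mod.ClumpConfig(**cfg.clump)
        indexes = clump_mod.select_index_variants(meta_table.df, ld, ccfg)
        loci = clump_mod.merge_loci(indexes, ccfg)
        index_frame = clump_mod.index_variants_frame(indexes, loci)
        _write("index_variants.tsv", index_frame)
        _write(
            "loci.tsv",
            pd.DataFrame(
                [
                    {"locus_id": l.locus_id, "chrom": l.chrom,
                     "start": l.start, "end": l.end, "n_index": len(l.indexes)}
                    for l in loci
                ]
            ),
        )
        done(n_index=len(indexes), n_loci=len(loci))

        # --- pairs + classification per secondary scan ---------------------
        memberships: dict[str, pd.DataFrame] = {}
        pairs_by_scan: dict[str, pd.DataFrame] = {}
        cls_cfg = cfg.classifier
        for scan, path in cfg.secondary.items():
            done = _stage(f"classify:{scan}")
            sec = read_sumstats(path, cohort=scan)
            pairs = build_effect_pairs(index_frame, meta_table, sec)
            pairs_by_scan[scan] = pairs
            _write(f"pairs_{scan}.tsv", pairs)
            fit_pairs = pairs.dropna(subset=["beta2", "se2"])
            groups = _parse_slopes(cls_cfg.get("slopes", [0, "free"]))
            model = LineModelMixture(fit_pairs, groups)
            res = model.fit(seed=cfg.seed,
                            restarts=cls_cfg.get("restarts", 5))
            null = LineModelMixture(
                fit_pairs, [LineModelGroup(0.6, 0.5, 0.99, slope_fixed=False)]
            ).fit(seed=cfg.seed)
            lrt = lrt_groups(null, res)
            member = res.gibbs(
                n_iter=cls_cfg.get("gibbs_iters", 2000),
                burn_in=cls_cfg.get("burn_in", 500),
                dirichlet_alpha=cls_cfg.get("alpha", 1.0),
                seed=cfg.seed,
            )
            memberships[scan] = member
            _write(f"membership_{scan}.tsv", member)
            fit_report = {
                "slopes": [g.slope for g in res.groups],
                "proportions": res.proportions.tolist(),
                "loglik": res.loglik,
                "loglik_trace": res.loglik_trace.tolist(),
                "converged": res.converged,
                "lrt": lrt,
            }
            (out / f"fit_{scan}.json").write_text(json.dumps(fit_report, indent=1))
            report["outputs"][f"fit_{scan}.json"] = _sha256(out / f"fit_{scan}.json")
            done(slopes=fit_report["slopes"], proportions=fit_report["proportions"])

        # --- dissection -----------------------------------------------------
        done = _stage("dissect")
        dcfg = cfg.dissection
        summary: dict = {}
        for scan, pairs in pairs_by_scan.items():
            strict, loose = diss.bonferroni_thresholds(
                int(pairs["pval2"].notna().sum()),
                fwer=dcfg.get("fwer", 0.05),
                per_expected=dcfg.get("per_expected", 1.0),
            )
            rep = diss.overlap_report(pairs, strict, loose)
            entry: dict = {"overlap": rep.to_dict()}
            member = memberships[scan]
            p1 = pairs.set_index("key")["pval1"]
            try:
                entry["sharing_proportion"] = diss.sharing_proportion(
                    member, p1, top_cutoff=dcfg.get("top_cutoff", 1e-11)
                )
            except ValueError:
                entry["sharing_proportion"] = None
            summary[scan] = entry
        scans = list(memberships)
        for i in range(len(scans)):
            for jdx in range(i + 1, len(scans)):
                mi = memberships[scans[i]].set_index("key")["p_group2"]
                mj = memberships[scans[jdx]].set_index("key")["p_group2"]
                common = mi.index.intersection(mj.index)
                if len(common) >= 3:
                    summary[f"spearman:{scans[i]}~{scans[jdx]}"] = diss.membership_spearman(
                        mi.loc[common], mj.loc[common]
                    )
        if cfg.coding_ld:
            coding = pd.read_csv(cfg.coding_ld, sep="\t")
            cats = diss.categorize_coding(
                coding.set_index("key")["best_r2"]
            )
            af_low = dcfg.get("af_low", 0.05)
            af = meta_table.df.assign(key=variant_key_series(meta_table.df)).set_index("key")["af"]
            index_keys = set(
                index_frame["chrom"].astype(str) + ":" + index_frame["pos"].astype(str)
                + ":" + index_frame["ref"] + ":" + index_frame["alt"]
            )
            idx_keys = set(cats["key"]) & set(af.index) & index_keys
            maf = af.loc[list(idx_keys)].map(lambda f: min(f, 1 - f))
            low_keys = set(maf[maf < af_low].index)
            try:
                enr = diss.coding_enrichment(
                    cats[cats["key"].isin(idx_keys)], low_keys
                )
                summary["coding_enrichment"] = {
                    "table": enr["table"].to_dict(), "fold": enr["fold"],
                    "p_fisher": enr["p_fisher"],
                    "prop_low": enr["prop_low"],
                    "prop_common": enr["prop_common"],
                }
            except ValueError as exc:  # e.g. no low-frequency index variants
                summary["coding_enrichment"] = {"skipped": str(exc)}
        report["dissection"] = summary
        done()
    except Exception as exc:  # record the failing stage, keep partial outputs
        report["error"] = {"stage": _last_pending(report), "message": str(exc)}
        (out / "run_report.json").write_text(json.dumps(report, indent=1, default=str))
        raise

    (out / "run_report.json").write_text(json.dumps(report, indent=1, default=str))
    return report


def _last_pending(report: dict) -> str:
    names = [k for k, v in report["stages"].items() if v.get("status") == "ok"]
    return f"after:{names[-1]}" if names else "meta"
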