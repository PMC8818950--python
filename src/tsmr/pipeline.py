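"""End-to-end orchestration: read → filter → clump → proxy → harmonize →
estimate → sensitivity, with full per-SNP provenance accounting."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .exceptions import DegenerateDataError, TsmrError
from .gwas_io import (
    ColumnMap,
    SummaryStatRecord,
    filter_genome_wide_significant,
    read_summary_stats,
)
from .harmonization import HarmonizedInstrument, harmonize, harmonize_all
from .instruments import ClumpConfig, LDMatrix, find_proxy, ld_clump
from .estimators import MREstimate
from .sensitivity import (
    SensitivityReport,
    _dispatch,
    bonferroni_threshold,
    build_sensitivity_report,
)

logger = logging.getLogger("tsmr")

__all__ = ["RunConfig", "RunReport", "run_mr", "run_mr_records", "format_table2"]

DEFAULT_METHODS = ("ivw", "egger", "weighted_median", "simple_mode", "weighted_mode")

#: Table-2-style display order and labels
METHOD_LABELS = {
    "egger": "MR Egger",
    "weighted_median": "Weighted median",
    "ivw": "Inverse variance weighted",
    "simple_mode": "Simple mode",
    "weighted_mode": "Weighted mode",
}
TABLE2_ORDER = ("egger", "weighted_median", "ivw", "simple_mode", "weighted_mode")


@dataclass
class RunConfig:
    """Everything one analysis run needs; defaults mirror the reference protocol."""

    exposure_path: Optional[str] = None
    outcome_path: Optional[str] = None
    seed: int = 0
    exposure_column_map: Optional[ColumnMap] = None
    outcome_column_map: Optional[ColumnMap] = None
    ld_path: Optional[str] = None
    pval_threshold: float = 5e-8
    clump_r2: float = 0.01
    clump_kb: float = 10_000.0
    proxy_min_r2: float = 0.8
    maf_limit: float = 0.42
    methods: tuple[str, ...] = DEFAULT_METHODS
    n_boot: int = 1000
    bonferroni_m: int = 5
    alpha: float = 0.05
    ivw_variant: str = "fixed"
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    out_dir: Optional[str] = None


@dataclass
class RunReport:
    """Run outcome: estimates, diagnostics, and per-SNP provenance.

    Every significant exposure SNP lands in exactly one provenance bin:
    ``analyzed``, ``proxied``, ``clumped_out``, ``missing_from_outcome``, or
    ``discarded:<reason>``.
    """

    exposure_name: str
    outcome_name: str
    estimates: dict[str, MREstimate]
    estimate_failures: dict[str, str]
    sensitivity: Optional[SensitivityReport]
    provenance: list[tuple[str, str]]
    n_significant: int
    config: dict
    seed: int
    version: str = __version__

    def provenance_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, bin_ in self.provenance:
            counts[bin_] = counts.get(bin_, 0) + 1
        return counts

    def estimates_frame(self) -> pd.DataFrame:
        return format_table2([self])

    def to_dict(self) -> dict:
        return {
            "exposure": self.exposure_name,
            "outcome": self.outcome_name,
            "estimates": {
                m: dataclasses.asdict(e) for m, e in sorted(self.estimates.items())
            },
            "estimate_failures": self.estimate_failures,
            "sensitivity": None if self.sensitivity is None else self.sensitivity.to_dict(),
            "provenance": [{"snp_id": s, "bin": b} for s, b in self.provenance],
            "n_significant": self.n_significant,
            "config": self.config,
            "seed": self.seed,
            "version": self.version,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def _config_echo(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["exposure_column_map"] = (
        dict(config.exposure_column_map.mapping) if config.exposure_column_map else None
    )
    d["outcome_column_map"] = (
        dict(config.outcome_column_map.mapping) if config.outcome_column_map else None
    )
    return d


def run_mr_records(
    exposure: Sequence[SummaryStatRecord],
    outcome: Sequence[SummaryStatRecord],
    config: RunConfig,
    ld: Optional[LDMatrix] = None,
) -> RunReport:
    """Run the pipeline on already-parsed records (the file-free core of run_mr)."""
    ld = ld if ld is not None else LDMatrix()

    significant = filter_genome_wide_significant(exposure, config.pval_threshold)
    logger.info("significance filter: %d of %d exposure SNPs pass p < %g",
                len(significant), len(exposure), config.pval_threshold)

    clumped = ld_clump(
        significant, ld, ClumpConfig(r2_threshold=config.clump_r2, window_kb=config.clump_kb)
    )
    clumped_ids = {r.snp_id for r in clumped}
    logger.info("clumping: %d index SNPs retained of %d", len(clumped), len(significant))

    provenance: dict[str, str] = {
        r.snp_id: "clumped_out" for r in significant if r.snp_id not in clumped_ids
    }

    # outcome lookup with proxy fallback for clumped index SNPs
    outcome_by_id = {o.snp_id: o for o in outcome}
    pairs: list[tuple[SummaryStatRecord, SummaryStatRecord, bool]] = []
    for rec in clumped:
        if rec.snp_id in outcome_by_id:
            pairs.append((rec, outcome_by_id[rec.snp_id], False))
            continue
        proxy = find_proxy(rec.snp_id, list(outcome), ld, min_r2=config.proxy_min_r2)
        if proxy is None:
            provenance[rec.snp_id] = "missing_from_outcome"
            logger.info("no outcome data or proxy for %s", rec.snp_id)
        else:
            pairs.append((rec, proxy, True))
            logger.info("proxy %s used for %s", proxy.snp_id, rec.snp_id)

    if not pairs:
        raise DegenerateDataError(
            "no shared instruments between exposure and outcome "
            f"(provenance: {dict(sorted(provenance.items()))})"
        )

    kept: list[HarmonizedInstrument] = []
    for exp_rec, out_rec, via_proxy in pairs:
        # a proxy's outcome row is treated as the target's: re-key it so
        # harmonize sees matching ids (alleles/eaf are the proxy's own)
        if via_proxy:
            out_rec = dataclasses.replace(out_rec, snp_id=exp_rec.snp_id)
        h = harmonize(exp_rec, out_rec, maf_limit=config.maf_limit)
        if h.kept:
            kept.append(h)
            provenance[exp_rec.snp_id] = "proxied" if via_proxy else "analyzed"
        else:
            provenance[exp_rec.snp_id] = f"discarded:{h.reason}"
            logger.info("discarded %s: %s", exp_rec.snp_id, h.reason)

    if len(kept) < 2:
        raise DegenerateDataError(
            "fewer than 2 kept instruments after harmonization "
            f"(provenance: {dict(sorted(provenance.items()))})"
        )

    estimates: dict[str, MREstimate] = {}
    failures: dict[str, str] = {}
    for i, method in enumerate(config.methods):
        try:
            estimates[method] = _dispatch(
                method, kept, n_boot=config.n_boot, seed=config.seed + i,
                ivw_variant=config.ivw_variant,
            )
        except TsmrError as exc:
            failures[method] = str(exc)
            logger.warning("method %s failed: %s", method, exc)

    sens = build_sensitivity_report(
        kept,
        alpha=config.alpha,
        m_tests=config.bonferroni_m,
        n_boot=config.n_boot,
        seed=config.seed,
        ivw_variant=config.ivw_variant,
    )

    prov_list = sorted(provenance.items())
    assert len(prov_list) == len(significant), "provenance must cover every significant SNP"
    return RunReport(
        exposure_name=config.exposure_name,
        outcome_name=config.outcome_name,
        estimates=estimates,
        estimate_failures=failures,
        sensitivity=sens,
        provenance=prov_list,
        n_significant=len(significant),
        config=_config_echo(config),
        seed=config.seed,
    )


def run_mr(config: RunConfig) -> RunReport:
    """Read the configured inputs, run the pipeline, and write outputs if requested."""
    exposure = read_summary_stats(config.exposure_path, config.exposure_column_map)
    outcome = read_summary_stats(config.outcome_path, config.outcome_column_map)
    ld = LDMatrix.from_pairs_tsv(config.ld_path) if config.ld_path else None
    report = run_mr_records(exposure.records, outcome.records, config, ld=ld)
    if config.out_dir:
        write_report(report, config.out_dir, bonferroni_m=config.bonferroni_m,
                     alpha=config.alpha)
    return report


def format_table2(reports: Sequence[RunReport], alpha: float = 0.05,
                  m_tests: int = 5) -> pd.DataFrame:
    """Long-format estimates table: one row per (exposure, outcome, method).

    Methods appear in the conventional display order; p-values below the
    Bonferroni threshold are starred.
    """
    if not reports:
        raise ValueError("format_table2 needs at least one report")
    threshold = bonferroni_threshold(alpha, m_tests)
    rows = []
    for rep in reports:
        for method in TABLE2_ORDER:
            est = rep.estimates.get(method)
            if est is None:
                continue
            rows.append(
                {
                    "exposure": rep.exposure_name,
                    "outcome": rep.outcome_name,
                    "method": METHOD_LABELS[method],
                    "nsnp": est.nsnp,
                    "beta": est.beta,
                    "se": est.se,
                    "pval": est.pval,
                    "or": est.or_value,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "significant": "*" if est.pval < threshold else "",
                }
            )
        for method, est in rep.estimates.items():
            if method not in TABLE2_ORDER:
                rows.append(
                    {
                        "exposure": rep.exposure_name,
                        "outcome": rep.outcome_name,
                        "method": method,
                        "nsnp": est.nsnp,
                        "beta": est.beta,
                        "se": est.se,
                        "pval": est.pval,
                        "or": est.or_value,
                        "ci_low": est.ci_low,
                        "ci_high": est.ci_high,
                        "significant": "*" if est.pval < threshold else "",
                    }
                )
    return pd.DataFrame(rows)


def write_report(report: RunReport, out_dir: str | Path, alpha: float = 0.05,
                 bonferroni_m: int = 5) -> None:
    """Emit estimates.tsv, sensitivity.json, provenance.tsv, and run.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    format_table2([report], alpha=alpha, m_tests=bonferroni_m).to_csv(
        out / "estimates.tsv", sep="\t", index=False
    )
    if report.sensitivity is not None:
        (out / "sensitivity.json").write_text(report.sensitivity.to_json(indent=2))
    pd.DataFrame(report.provenance, columns=["snp_id", "bin"]).to_csv(
        out / "provenance.tsv", sep="\t", index=False
    )
    (out / "run.json").write_text(report.to_json(indent=2))
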