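"""End-to-end pipelines: FASTQ -> hits, and variant table -> recovery report.

Both pipelines validate their inputs up front, write every intermediate
artifact as TSV/JSON, and log a human-readable summary (read totals,
unassigned rate, thresholds, hit count).  Reruns on identical inputs produce
identical output files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import demux as demux_mod
from . import recovery as recovery_mod
from . import scoring as scoring_mod
from .barcodes import load_manifest
from .panel import AmpliconPanel
from .platemap import load_plate_map

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class ScoringParams:
    k: float = scoring_mod.DEFAULT_K
    fixed_threshold: float | None = None
    min_depth: int = scoring_mod.DEFAULT_MIN_DEPTH
    qc_ratio: float = scoring_mod.DEFAULT_QC_RATIO
    exclude_failed_plates_from_null: bool = True

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ConfigError("k must be >= 0")
        if self.min_depth < 0:
            raise ConfigError("min_depth must be >= 0")
        if self.qc_ratio <= 0:
            raise ConfigError("qc_ratio must be > 0")


@dataclass
class RecoveryParams:
    min_depth: int = recovery_mod.DEFAULT_MIN_DEPTH
    fold_threshold: float = recovery_mod.DEFAULT_FOLD
    pseudocount: float = recovery_mod.DEFAULT_PSEUDOCOUNT
    continuity: bool = True
    denominator: str = "total"

    def __post_init__(self) -> None:
        if self.min_depth < 0:
            raise ConfigError("min_depth must be >= 0")
        if self.fold_threshold <= 0:
            raise ConfigError("fold_threshold must be > 0")
        if self.pseudocount <= 0:
            raise ConfigError("pseudocount must be > 0")
        if self.denominator not in ("total", "wildtype"):
            raise ConfigError(f"unknown denominator {self.denominator!r}")


def _params_from_dict(cls, payload: dict, where: str):
    fields = {f for f in cls.__dataclass_fields__}
    unknown = set(payload) - fields
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}")
    return cls(**payload)


def _require(path: str | Path, what: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"{what} not found: {p}")
    return p


def _file_hash(path: Path) -> str:
    h = hashlib.sha1()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:12]


def _fmt(x: float | None, sig: int = 6) -> float | None:
    """Serialize floats at 6 significant digits (full precision via sig=None)."""
    if x is None or pd.isna(x):
        return None
    return float(f"{x:.{sig}g}")


def run_screen_pipeline(
    fastq: str | Path,
    manifest_yaml: str | Path,
    panel_fasta: str | Path,
    windows_tsv: str | Path,
    platemap_csv: str | Path,
    pool_yaml: str | Path,
    outdir: str | Path,
    params: ScoringParams | None = None,
    min_mean_quality: float | None = None,
) -> dict:
    """Demultiplex -> count -> score -> QC -> hit call; returns the run summary.

    All configuration and metadata artifacts are validated before the FASTQ
    stream is opened, so configuration errors fail fast.
    """
    params = params or ScoringParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # fail fast on configuration before streaming reads
    manifest = load_manifest(_require(manifest_yaml, "barcode manifest"))
    panel = AmpliconPanel.from_files(
        _require(panel_fasta, "amplicon panel FASTA"),
        _require(windows_tsv, "diagnostic windows TSV"),
    )
    platemap = load_plate_map(_require(platemap_csv, "plate map"))
    design = scoring_mod.PoolDesign.from_yaml(_require(pool_yaml, "pool design"))
    fastq = _require(fastq, "FASTQ")
    for allele_id in design.mutant_allele_ids:
        if allele_id not in panel.alleles:
            raise ConfigError(f"pool design allele {allele_id!r} absent from panel")

    counts = demux_mod.count_pool(
        fastq, manifest, panel, platemap=platemap, min_mean_quality=min_mean_quality
    )
    counts.write_tsv(outdir / "counts.tsv")
    counts.write_summary(outdir / "demux_summary.json")

    maf = scoring_mod.score_counts(counts.to_frame(), design, panel, min_depth=params.min_depth)
    maf_out = maf.copy()
    for col in ("raw_maf", "corrected_maf"):
        maf_out[col] = maf_out[col].map(lambda v: _fmt(v))
    maf_out.to_csv(outdir / "maf.tsv", sep="\t", index=False)

    qc = scoring_mod.plate_qc(maf, platemap, q=params.qc_ratio)
    qc.to_csv(outdir / "plate_qc.tsv", sep="\t", index=False)

    exclude = (
        set(qc.loc[~qc["passed"], "plate_id"])
        if params.exclude_failed_plates_from_null
        else None
    )
    controls = scoring_mod.control_values(maf, platemap, exclude_plates=exclude)
    null = scoring_mod.fit_null(controls, k=params.k, fixed_threshold=params.fixed_threshold)
    null.to_json(outdir / "null_model.json")

    hits = scoring_mod.call_hits(maf, null, platemap, design, qc=qc)
    hits.to_csv(outdir / "hits.tsv", sep="\t", index=False)

    summary = {
        "inputs": {
            "fastq": str(fastq),
            "fastq_sha1": _file_hash(Path(fastq)),
        },
        "params": {
            "k": params.k,
            "fixed_threshold": params.fixed_threshold,
            "min_depth": params.min_depth,
            "qc_ratio": params.qc_ratio,
        },
        "demux": counts.summary(),
        "thresholds": {a: _fmt(null.threshold(a)) for a in design.mutant_allele_ids},
        "plates_passed": int(qc["passed"].sum()),
        "plates_failed": int((~qc["passed"]).sum()),
        "n_library_wells": int(len(hits)),
        "n_hits": int(hits["is_hit"].sum()),
        "hit_compounds": sorted(hits.loc[hits["is_hit"], "compound_id"]),
    }
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    logger.info(
        "screen pipeline: %d reads, unassigned rate %.3f%%, %d/%d plates passed QC, %d hits",
        summary["demux"]["totals"]["reads_seen"],
        100 * summary["demux"]["unassigned_rate"],
        summary["plates_passed"],
        summary["plates_passed"] + summary["plates_failed"],
        summary["n_hits"],
    )
    return summary


def run_recovery_pipeline(
    variants: str | Path,
    outdir: str | Path,
    params: RecoveryParams | None = None,
) -> dict:
    """Filter -> fold change -> class stratification -> chi-squared test."""
    params = params or RecoveryParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = recovery_mod.load_variant_table(_require(variants, "variant table"))
    if not records:
        logger.warning("variant table %s is empty; writing empty outputs", variants)
    recovery = recovery_mod.analyze_recovery(
        records,
        r=params.fold_threshold,
        pseudocount=params.pseudocount,
        min_depth=params.min_depth,
        denominator=params.denominator,
    )
    recovery.to_csv(outdir / "recovery.tsv", sep="\t", index=False)
    summary_df = recovery_mod.stratify_recovery(recovery) if len(recovery) else pd.DataFrame(
        columns=["mutation_class", "n_variants", "n_pass", "n_recovered", "recovery_rate"]
    )
    summary_df.to_csv(outdir / "class_summary.tsv", sep="\t", index=False)
    test = recovery_mod.nmd_recovery_test(recovery, continuity=params.continuity) if len(recovery) else None
    recovery_mod.write_test_json(test, outdir / "test_result.json")
    summary = {
        "n_variants": int(len(recovery)),
        "n_pass": int(recovery["pass_filter"].sum()) if len(recovery) else 0,
        "n_recovered": int(recovery["recovered"].sum()) if len(recovery) else 0,
        "class_summary": summary_df.to_dict(orient="records"),
        "nmd_recovery_test": test,
        "params": {
            "min_depth": params.min_depth,
            "fold_threshold": params.fold_threshold,
            "pseudocount": params.pseudocount,
            "continuity": params.continuity,
            "denominator": params.denominator,
        },
    }
    with open(outdir / "recovery_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    logger.info(
        "recovery pipeline: %d variants, %d pass filter, %d recovered",
        summary["n_variants"],
        summary["n_pass"],
        summary["n_recovered"],
    )
    return summary


@dataclass
class RunConfig:
    """Validated YAML-driven configuration for the combined pipelines."""

    screen: dict | None = None
    recovery: dict | None = None
    scoring_params: ScoringParams = field(default_factory=ScoringParams)
    recovery_params: RecoveryParams = field(default_factory=RecoveryParams)
    log_level: str = "INFO"

    SCREEN_KEYS = {"fastq", "manifest_yaml", "panel_fasta", "windows_tsv", "platemap_csv", "pool_yaml", "outdir"}
    RECOVERY_KEYS = {"variants", "outdir"}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        known = {"screen", "recovery", "scoring_params", "recovery_params", "log_level"}
        unknown = set(cfg) - known
        if unknown:
            raise ConfigError(f"{path}: unknown top-level keys {sorted(unknown)}")
        screen = cfg.get("screen")
        if screen is not None:
            missing = cls.SCREEN_KEYS - set(screen)
            extra = set(screen) - cls.SCREEN_KEYS
            if missing or extra:
                raise ConfigError(
                    f"{path}: screen block missing {sorted(missing)}, unknown {sorted(extra)}"
                )
        recovery = cfg.get("recovery")
        if recovery is not None:
            missing = cls.RECOVERY_KEYS - set(recovery)
            extra = set(recovery) - cls.RECOVERY_KEYS
            if missing or extra:
                raise ConfigError(
                    f"{path}: recovery block missing {sorted(missing)}, unknown {sorted(extra)}"
                )
        return cls(
            screen=screen,
            recovery=recovery,
            scoring_params=_params_from_dict(
                ScoringParams, cfg.get("scoring_params", {}), f"{path}: scoring_params"
            ),
            recovery_params=_params_from_dict(
                RecoveryParams, cfg.get("recovery_params", {}), f"{path}: recovery_params"
            ),
            log_level=str(cfg.get("log_level", "INFO")),
        )

    def run(self) -> dict:
        logging.basicConfig(level=self.log_level)
        out: dict = {}
        if self.screen is not None:
            out["screen"] = run_screen_pipeline(
                fastq=self.screen["fastq"],
                manifest_yaml=self.screen["manifest_yaml"],
                panel_fasta=self.screen["panel_fasta"],
                windows_tsv=self.screen["windows_tsv"],
                platemap_csv=self.screen["platemap_csv"],
                pool_yaml=self.screen["pool_yaml"],
                outdir=self.screen["outdir"],
                params=self.scoring_params,
            )
        if self.recovery is not None:
            out["recovery"] = run_recovery_pipeline(
                variants=self.recovery["variants"],
                outdir=self.recovery["outdir"],
                params=self.recovery_params,
            )
        return out
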