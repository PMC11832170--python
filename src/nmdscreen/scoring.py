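"""Screen scoring: pool-corrected mutant allele fractions and hit calling.

The screen pools N isogenic lines in equal ratio; each clone-specific mutant
allele a is carried by n_a lines at zygosity dosage delta_a (0.5 heterozygous,
1.0 homozygous/hemizygous).  Its pool-expected maximum fraction is

    e_a = n_a * delta_a / N

and the corrected MAF of a well is raw MAF (mutant / (mutant + wild-type))
divided by e_a, so that complete NMD blockade with equal per-cell expression
scores approximately 1.  The null model pools vehicle (DMSO) control wells
across all passing plates; the per-allele hit threshold is mean + k * SD
(sample SD, n-1), k = 5 by default, optionally overridden by a single fixed
threshold.  A compound is a hit only when the corrected MAF of *every* mutant
allele strictly exceeds its threshold and no QC flag disqualifies the well.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .panel import AmpliconPanel

DEFAULT_MIN_DEPTH = 200
DEFAULT_K = 5.0
DEFAULT_QC_RATIO = 2.0

MAF_COLUMNS = [
    "plate_id",
    "well_id",
    "allele_id",
    "mutant_reads",
    "wildtype_reads",
    "depth",
    "raw_maf",
    "corrected_maf",
    "low_coverage",
]


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class Carrier:
    """One mutant allele's representation in the pool."""

    gene: str
    n_carrier_lines: int
    dosage: float  # 0.5 heterozygous, 1.0 homozygous/hemizygous

    def __post_init__(self) -> None:
        if self.n_carrier_lines < 1:
            raise ScoringError("n_carrier_lines must be >= 1")
        if not (0.0 < self.dosage <= 1.0):
            raise ScoringError("dosage must be in (0, 1]")


@dataclass
class PoolDesign:
    """Composition of the equally mixed cell-line pool."""

    n_lines: int
    carriers: dict[str, Carrier]

    def __post_init__(self) -> None:
        if self.n_lines < 1:
            raise ScoringError("n_lines must be >= 1")
        for allele_id, c in self.carriers.items():
            if c.n_carrier_lines > self.n_lines:
                raise ScoringError(f"{allele_id}: more carrier lines than lines in pool")
        for gene in {c.gene for c in self.carriers.values()}:
            if self.mutant_dosage(gene) > self.n_lines:
                raise ScoringError(f"gene {gene}: total mutant dosage exceeds pool size")

    def expected_max_fraction(self, allele_id: str) -> float:
        """e_a = n_a * delta_a / N."""
        c = self._carrier(allele_id)
        return c.n_carrier_lines * c.dosage / self.n_lines

    def mutant_dosage(self, gene: str) -> float:
        """Total mutant dosage M_g of a gene across the pool."""
        return sum(
            c.n_carrier_lines * c.dosage for c in self.carriers.values() if c.gene == gene
        )

    def wildtype_dosage(self, gene: str) -> float:
        """Total wild-type dosage W_g = N - M_g for a gene."""
        return self.n_lines - self.mutant_dosage(gene)

    def _carrier(self, allele_id: str) -> Carrier:
        try:
            return self.carriers[allele_id]
        except KeyError:
            raise ScoringError(f"unknown mutant allele {allele_id!r}") from None

    @property
    def mutant_allele_ids(self) -> list[str]:
        return list(self.carriers)

    # -- i/o ----------------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "n_lines": self.n_lines,
            "carriers": {
                a: {"gene": c.gene, "n_carrier_lines": c.n_carrier_lines, "dosage": c.dosage}
                for a, c in self.carriers.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PoolDesign":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        try:
            carriers = {
                a: Carrier(gene=c["gene"], n_carrier_lines=int(c["n_carrier_lines"]), dosage=float(c["dosage"]))
                for a, c in cfg["carriers"].items()
            }
            return cls(n_lines=int(cfg["n_lines"]), carriers=carriers)
        except (KeyError, TypeError) as exc:
            raise ScoringError(f"{path}: malformed pool design ({exc})") from None


@dataclass
class MafRecord:
    """Per-well, per-mutant-allele MAF statistics.

    ``raw_maf``/``corrected_maf`` are ``None`` (missing, never 0) when depth
    is zero; zero depth always implies ``low_coverage``.
    """

    plate_id: str
    well_id: str
    allele_id: str
    mutant_reads: int
    wildtype_reads: int
    raw_maf: float | None
    corrected_maf: float | None
    depth: int
    low_coverage: bool


def corrected_maf(
    m: int,
    w: int,
    design: PoolDesign,
    allele_id: str,
    plate_id: str = "",
    well_id: str = "",
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> MafRecord:
    """Raw and pool-corrected MAF for one (well, mutant allele).

    raw = m / (m + w); corrected = raw / e_a, exactly.  Wells with depth
    below ``min_depth`` are flagged low-coverage; depth 0 propagates as
    missing, not 0.
    """
    if m < 0 or w < 0:
        raise ScoringError("read counts must be non-negative")
    e_a = design.expected_max_fraction(allele_id)
    depth = m + w
    if depth == 0:
        return MafRecord(plate_id, well_id, allele_id, m, w, None, None, 0, True)
    raw = m / depth
    return MafRecord(
        plate_id=plate_id,
        well_id=well_id,
        allele_id=allele_id,
        mutant_reads=m,
        wildtype_reads=w,
        raw_maf=raw,
        corrected_maf=raw / e_a,
        depth=depth,
        low_coverage=depth < min_depth,
    )


def score_counts(
    counts: pd.DataFrame,
    design: PoolDesign,
    panel: AmpliconPanel,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> pd.DataFrame:
    """Turn an allele count table into a per-well MAF table.

    ``counts`` has columns plate_id, well_id, gene, allele_id, count (the
    demultiplexer's output).  For every well with any counted read and every
    mutant allele of the design, m is that allele's count and w the count of
    its gene's wild-type allele; alleles with no reads in a well get a
    zero-depth (missing) record so downstream hit calling can flag them.
    """
    lookup = {
        (r.plate_id, r.well_id, r.allele_id): int(r.count)
        for r in counts.itertuples(index=False)
    }
    wells = sorted({(r.plate_id, r.well_id) for r in counts.itertuples(index=False)})
    rows = []
    for plate_id, well_id in wells:
        for allele_id in design.mutant_allele_ids:
            gene = panel.gene_of(allele_id)
            wt_id = panel.wildtype_of(gene)
            m = lookup.get((plate_id, well_id, allele_id), 0)
            w = lookup.get((plate_id, well_id, wt_id), 0)
            rec = corrected_maf(m, w, design, allele_id, plate_id, well_id, min_depth)
            rows.append(rec.__dict__)
    return pd.DataFrame(rows, columns=MAF_COLUMNS)


# ---------------------------------------------------------------------------
# null model


@dataclass
class AlleleNull:
    mean: float
    sd: float
    n_controls: int
    threshold: float


@dataclass
class NullModel:
    """Pooled-control null: per-allele mean, SD and threshold T = mean + k*SD."""

    per_allele: dict[str, AlleleNull]
    k: float = DEFAULT_K
    fixed_threshold: float | None = None

    def threshold(self, allele_id: str) -> float:
        if self.fixed_threshold is not None:
            return self.fixed_threshold
        try:
            return self.per_allele[allele_id].threshold
        except KeyError:
            raise ScoringError(f"no null model for allele {allele_id!r}") from None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "fixed_threshold": self.fixed_threshold,
            "per_allele": {
                a: {"mean": s.mean, "sd": s.sd, "n_controls": s.n_controls, "threshold": s.threshold}
                for a, s in self.per_allele.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "NullModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            per_allele={
                a: AlleleNull(s["mean"], s["sd"], s["n_controls"], s["threshold"])
                for a, s in payload["per_allele"].items()
            },
            k=payload["k"],
            fixed_threshold=payload["fixed_threshold"],
        )


def fit_null(
    control_mafs: Mapping[str, Sequence[float]],
    k: float = DEFAULT_K,
    fixed_threshold: float | None = None,
) -> NullModel:
    """Fit the pooled-DMSO null per allele: mean, sample SD (n-1), T = mean + k*SD.

    ``control_mafs`` maps allele_id to the corrected MAFs of all usable
    negative-control wells pooled across plates.  Fewer than two usable
    values for any allele is an error unless a fixed threshold is configured.
    """
    per_allele: dict[str, AlleleNull] = {}
    for allele_id, values in control_mafs.items():
        vals = [v for v in values if v is not None and not math.isnan(v)]
        if len(vals) < 2:
            if fixed_threshold is not None:
                per_allele[allele_id] = AlleleNull(
                    mean=float(np.mean(vals)) if vals else math.nan,
                    sd=math.nan,
                    n_controls=len(vals),
                    threshold=fixed_threshold,
                )
                continue
            raise ScoringError(
                f"allele {allele_id!r}: {len(vals)} usable control wells (< 2) "
                "and no fixed threshold configured"
            )
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1))
        per_allele[allele_id] = AlleleNull(
            mean=mean, sd=sd, n_controls=len(vals), threshold=mean + k * sd
        )
    return NullModel(per_allele=per_allele, k=k, fixed_threshold=fixed_threshold)


def control_values(
    maf: pd.DataFrame,
    platemap: pd.DataFrame,
    role: str = "negative_control",
    exclude_plates: set[str] | None = None,
) -> dict[str, list[float]]:
    """Collect usable (non-missing, non-low-coverage) corrected MAFs of
    control wells, pooled across plates, keyed by allele."""
    roles = {
        (r.plate_id, r.well_id): r.role for r in platemap.itertuples(index=False)
    }
    out: dict[str, list[float]] = {}
    for r in maf.itertuples(index=False):
        if roles.get((r.plate_id, r.well_id)) != role:
            continue
        if exclude_plates and r.plate_id in exclude_plates:
            continue
        if r.low_coverage or r.corrected_maf is None or pd.isna(r.corrected_maf):
            continue
        out.setdefault(r.allele_id, []).append(float(r.corrected_maf))
    return out


# ---------------------------------------------------------------------------
# plate QC


def plate_qc(
    maf: pd.DataFrame,
    platemap: pd.DataFrame,
    q: float = DEFAULT_QC_RATIO,
) -> pd.DataFrame:
    """Per-plate QC on the sequencing readout: mean positive-control corrected
    MAF must be at least ``q`` times the mean negative-control value.

    A plate without usable controls on either side fails with a reason.  A
    zero negative mean with a positive signal yields ratio +inf (passes).
    """
    roles = {(r.plate_id, r.well_id): r.role for r in platemap.itertuples(index=False)}
    plates = sorted({r.plate_id for r in platemap.itertuples(index=False)})
    usable = maf[~maf["low_coverage"] & maf["corrected_maf"].notna()]
    rows = []
    for plate in plates:
        sub = usable[usable["plate_id"] == plate]
        pos = [
            float(r.corrected_maf)
            for r in sub.itertuples(index=False)
            if roles.get((r.plate_id, r.well_id)) == "positive_control"
        ]
        neg = [
            float(r.corrected_maf)
            for r in sub.itertuples(index=False)
            if roles.get((r.plate_id, r.well_id)) == "negative_control"
        ]
        if not pos or not neg:
            rows.append(
                {
                    "plate_id": plate,
                    "pos_control_mean": float(np.mean(pos)) if pos else math.nan,
                    "neg_control_mean": float(np.mean(neg)) if neg else math.nan,
                    "pos_neg_ratio": math.nan,
                    "passed": False,
                    "reason": "missing usable controls",
                }
            )
            continue
        pos_mean = float(np.mean(pos))
        neg_mean = float(np.mean(neg))
        if neg_mean == 0.0:
            ratio = math.inf if pos_mean > 0 else math.nan
        else:
            ratio = pos_mean / neg_mean
        passed = bool(ratio >= q) if not math.isnan(ratio) else False
        rows.append(
            {
                "plate_id": plate,
                "pos_control_mean": pos_mean,
                "neg_control_mean": neg_mean,
                "pos_neg_ratio": ratio,
                "passed": passed,
                "reason": "" if passed else "pos/neg ratio below threshold",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["plate_id", "pos_control_mean", "neg_control_mean", "pos_neg_ratio", "passed", "reason"],
    )


# ---------------------------------------------------------------------------
# hit calling


def call_hits(
    maf: pd.DataFrame,
    null: NullModel,
    platemap: pd.DataFrame,
    design: PoolDesign,
    qc: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Call compound hits over library wells.

    A well is a hit iff the corrected MAF of *every* mutant allele in the
    design strictly exceeds that allele's threshold, no allele is missing or
    low-coverage, and the plate passed QC.  Output is one row per library
    well, wide per-allele columns ``maf_<allele>`` / ``thr_<allele>``, sorted
    by the minimum per-allele exceedance margin, descending.
    """
    alleles = design.mutant_allele_ids
    failed_plates = (
        set(qc.loc[~qc["passed"], "plate_id"]) if qc is not None else set()
    )
    by_well: dict[tuple[str, str], dict[str, object]] = {}
    for r in maf.itertuples(index=False):
        by_well.setdefault((r.plate_id, r.well_id), {})[r.allele_id] = r
    rows = []
    for pm in platemap.itertuples(index=False):
        if pm.role != "library":
            continue
        key = (pm.plate_id, pm.well_id)
        recs = by_well.get(key, {})
        flags = []
        if pm.plate_id in failed_plates:
            flags.append("failed_plate")
        margins = []
        row: dict[str, object] = {
            "plate_id": pm.plate_id,
            "well_id": pm.well_id,
            "compound_id": pm.compound_id,
        }
        all_exceed = True
        for allele_id in alleles:
            rec = recs.get(allele_id)
            thr = null.threshold(allele_id)
            row[f"thr_{allele_id}"] = thr
            if rec is None or rec.corrected_maf is None or pd.isna(rec.corrected_maf):
                row[f"maf_{allele_id}"] = math.nan
                if "missing_allele" not in flags:
                    flags.append("missing_allele")
                all_exceed = False
                continue
            value = float(rec.corrected_maf)
            row[f"maf_{allele_id}"] = value
            margins.append(value - thr)
            if rec.low_coverage and "low_coverage" not in flags:
                flags.append("low_coverage")
            if not (value > thr):  # strict inequality
                all_exceed = False
        row["min_margin"] = min(margins) if len(margins) == len(alleles) else -math.inf
        row["is_hit"] = bool(all_exceed and not flags)
        row["qc_flags"] = ";".join(flags)
        rows.append(row)
    columns = (
        ["plate_id", "well_id", "compound_id"]
        + [f"maf_{a}" for a in alleles]
        + [f"thr_{a}" for a in alleles]
        + ["min_margin", "is_hit", "qc_flags"]
    )
    df = pd.DataFrame(rows, columns=columns)
    return df.sort_values("min_margin", ascending=False, kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# dose response


def dose_response(records: pd.DataFrame, design: PoolDesign) -> pd.DataFrame:
    """Per-concentration corrected MAF for one compound (reporting only).

    ``records`` needs columns concentration, allele_id, mutant_reads,
    wildtype_reads.  Requires at least two distinct concentrations; duplicate
    (concentration, allele) rows are an error.  No curve fitting is done.
    """
    required = {"concentration", "allele_id", "mutant_reads", "wildtype_reads"}
    missing = required - set(records.columns)
    if missing:
        raise ScoringError(f"dose_response: missing columns {sorted(missing)}")
    if records["concentration"].nunique() < 2:
        raise ScoringError("dose_response requires at least 2 concentrations")
    dup = records.duplicated(subset=["concentration", "allele_id"])
    if dup.any():
        pair = records.loc[dup, ["concentration", "allele_id"]].iloc[0]
        raise ScoringError(
            f"duplicate (concentration, allele) row: {pair.concentration}, {pair.allele_id}"
        )
    rows = []
    for r in records.itertuples(index=False):
        rec = corrected_maf(int(r.mutant_reads), int(r.wildtype_reads), design, r.allele_id)
        rows.append(
            {
                "concentration": r.concentration,
                "allele_id": r.allele_id,
                "raw_maf": rec.raw_maf if rec.raw_maf is not None else math.nan,
                "corrected_maf": rec.corrected_maf if rec.corrected_maf is not None else math.nan,
                "depth": rec.depth,
            }
        )
    return (
        pd.DataFrame(rows, columns=["concentration", "allele_id", "raw_maf", "corrected_maf", "depth"])
        .sort_values(["concentration", "allele_id"], kind="mergesort")
        .reset_index(drop=True)
    )
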