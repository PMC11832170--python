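"""Mutant-transcript recovery analysis on treated vs control duplicates.

Input is a per-variant table of mutant/wild-type read counts at the variant
site for four samples (biological duplicates of drug-treated and vehicle
control).  A variant enters the analysis only if it is heterozygous and has
at least ``d_min`` (default 5) reads in all four samples.  Per-sample MAF is
m / (m + w) (a config switch selects the mutant/wild-type ratio variant);
replicate MAFs are averaged arithmetically, and the fold change is

    FC = mean treated MAF / mean control MAF

with a pseudocount rescue when the control mean is exactly zero.  A variant
is "recovered" when FC >= r (default 2, inclusive).  Recovery rates are
stratified by mutation class, and two groups of variants are compared with a
two-proportion chi-squared test (Yates continuity correction by default,
matching R's prop.test).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

SAMPLES = ("treated_1", "treated_2", "control_1", "control_2")
TREATED = ("treated_1", "treated_2")
CONTROLS = ("control_1", "control_2")
MUTATION_CLASSES = ("frameshift_indel", "nonsense", "other_snv", "control_snp")
ZYGOSITIES = ("heterozygous", "homozygous")

DEFAULT_MIN_DEPTH = 5
DEFAULT_FOLD = 2.0
DEFAULT_PSEUDOCOUNT = 0.5

COUNT_COLUMNS = [f"{p}_{s}" for s in SAMPLES for p in ("m", "w")]
TABLE_COLUMNS = ["variant_id", "gene", "mutation_class", "zygosity"] + COUNT_COLUMNS


class VariantTableError(ValueError):
    pass


@dataclass
class VariantRecord:
    """Per-variant read counts across the four compared samples."""

    variant_id: str
    gene: str
    mutation_class: str
    zygosity: str
    counts: dict[str, tuple[int, int]]  # sample -> (mutant_reads, wildtype_reads)
    nmd_predicted: bool | None = None

    def __post_init__(self) -> None:
        if self.mutation_class not in MUTATION_CLASSES:
            raise VariantTableError(
                f"variant {self.variant_id!r}: unknown mutation_class {self.mutation_class!r}"
            )
        if self.zygosity not in ZYGOSITIES:
            raise VariantTableError(
                f"variant {self.variant_id!r}: unknown zygosity {self.zygosity!r}"
            )
        if set(self.counts) != set(SAMPLES):
            raise VariantTableError(
                f"variant {self.variant_id!r}: expected samples {SAMPLES}, got {sorted(self.counts)}"
            )
        for s, (m, w) in self.counts.items():
            if m < 0 or w < 0:
                raise VariantTableError(f"variant {self.variant_id!r}: negative count in {s}")

    def depth(self, sample: str) -> int:
        m, w = self.counts[sample]
        return m + w


@dataclass
class RecoveryRecord:
    variant_id: str
    gene: str
    mutation_class: str
    zygosity: str
    pass_filter: bool
    maf_by_sample: dict[str, float | None]
    maf_treated: float | None
    maf_control: float | None
    fold_change: float | None
    recovered: bool
    pseudocount_applied: bool
    nmd_predicted: bool | None = None

    def as_row(self) -> dict:
        row = {
            "variant_id": self.variant_id,
            "gene": self.gene,
            "mutation_class": self.mutation_class,
            "zygosity": self.zygosity,
            "pass_filter": self.pass_filter,
        }
        for s in SAMPLES:
            v = self.maf_by_sample.get(s)
            row[f"maf_{s}"] = math.nan if v is None else v
        row["maf_treated"] = math.nan if self.maf_treated is None else self.maf_treated
        row["maf_control"] = math.nan if self.maf_control is None else self.maf_control
        row["fold_change"] = math.nan if self.fold_change is None else self.fold_change
        row["recovered"] = self.recovered
        row["pseudocount_applied"] = self.pseudocount_applied
        row["nmd_predicted"] = self.nmd_predicted
        return row


# ---------------------------------------------------------------------------
# loading


def load_variant_table(path: str | Path) -> list[VariantRecord]:
    """Load a variant count table (TSV, or VCF if the suffix says so)."""
    path = Path(path)
    if path.suffix.lower() in (".vcf",) or path.name.endswith(".vcf.gz"):
        return load_variant_vcf(path)
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise VariantTableError(f"{path}: missing columns {missing}")
    has_pred = "nmd_predicted" in df.columns
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # data starts at line 2
        try:
            counts = {
                s: (int(getattr(row, f"m_{s}")), int(getattr(row, f"w_{s}")))
                for s in SAMPLES
            }
            rec = VariantRecord(
                variant_id=str(row.variant_id),
                gene=str(row.gene),
                mutation_class=str(row.mutation_class),
                zygosity=str(row.zygosity),
                counts=counts,
                nmd_predicted=_parse_bool(getattr(row, "nmd_predicted")) if has_pred else None,
            )
        except (ValueError, VariantTableError) as exc:
            raise VariantTableError(f"{path}: line {i}: {exc}") from None
        records.append(rec)
    return records


def _parse_bool(value) -> bool | None:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    if text in ("", "na", "nan", "none"):
        return None
    raise ValueError(f"cannot parse boolean {value!r}")


def load_variant_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a 4-sample VCF with per-sample AD (ref, alt) = (w, m) depths.

    Samples must be named treated_1, treated_2, control_1, control_2.
    Per-variant annotations come from INFO keys GENE, MCLASS, ZYG and
    optional NMD (0/1).  Variant ids keep 1-based VCF coordinates.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_idx = {s: i for i, s in enumerate(vcf.samples)}
    missing = [s for s in SAMPLES if s not in sample_idx]
    if missing:
        raise VariantTableError(f"{path}: VCF lacks samples {missing}")
    records = []
    for v in vcf:
        ad = v.format("AD")
        if ad is None:
            raise VariantTableError(f"{path}: {v.CHROM}:{v.POS}: missing AD field")
        counts = {}
        for s in SAMPLES:
            ref_d, alt_d = (int(x) for x in ad[sample_idx[s]][:2])
            counts[s] = (alt_d, ref_d)  # (m, w)
        info = dict(v.INFO)
        try:
            gene = str(info["GENE"])
            mclass = str(info["MCLASS"])
            zyg = str(info["ZYG"])
        except KeyError as exc:
            raise VariantTableError(
                f"{path}: {v.CHROM}:{v.POS}: missing INFO key {exc}"
            ) from None
        nmd = info.get("NMD")
        records.append(
            VariantRecord(
                variant_id=f"{v.CHROM}:{v.POS}:{v.REF}>{','.join(v.ALT)}",
                gene=gene,
                mutation_class=mclass,
                zygosity=zyg,
                counts=counts,
                nmd_predicted=None if nmd is None else bool(int(nmd)),
            )
        )
    return records


def records_to_frame(records: Iterable[VariantRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "variant_id": r.variant_id,
            "gene": r.gene,
            "mutation_class": r.mutation_class,
            "zygosity": r.zygosity,
        }
        for s in SAMPLES:
            row[f"m_{s}"], row[f"w_{s}"] = r.counts[s]
        if r.nmd_predicted is not None:
            row["nmd_predicted"] = r.nmd_predicted
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# filtering and fold change


def passes_filter(record: VariantRecord, min_depth: int = DEFAULT_MIN_DEPTH) -> bool:
    """Inclusion rule: heterozygous, and depth >= min_depth in all 4 samples
    (boundary inclusive)."""
    return record.zygosity == "heterozygous" and all(
        record.depth(s) >= min_depth for s in SAMPLES
    )


def filter_variants(
    records: Sequence[VariantRecord], min_depth: int = DEFAULT_MIN_DEPTH
) -> list[tuple[VariantRecord, bool]]:
    return [(r, passes_filter(r, min_depth)) for r in records]


def recovery_fold(
    record: VariantRecord,
    r: float = DEFAULT_FOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_depth: int = DEFAULT_MIN_DEPTH,
    denominator: str = "total",
) -> RecoveryRecord:
    """Fold change and recovery call for one variant.

    Per-sample MAF is m/(m+w) (``denominator="total"``) or m/w
    (``denominator="wildtype"``); replicate means are arithmetic.  If the
    control mean is exactly zero, ``pseudocount`` is added to the mutant and
    wild-type counts of *all four* samples and the MAFs recomputed, keeping
    FC finite while preserving ordering.  Recovered iff the variant passes
    the inclusion filter and FC >= r (inclusive).
    """
    if denominator not in ("total", "wildtype"):
        raise VariantTableError(f"unknown MAF denominator {denominator!r}")
    ok = passes_filter(record, min_depth)
    if not ok:
        return RecoveryRecord(
            variant_id=record.variant_id,
            gene=record.gene,
            mutation_class=record.mutation_class,
            zygosity=record.zygosity,
            pass_filter=False,
            maf_by_sample={s: None for s in SAMPLES},
            maf_treated=None,
            maf_control=None,
            fold_change=None,
            recovered=False,
            pseudocount_applied=False,
            nmd_predicted=record.nmd_predicted,
        )

    def mafs(pc: float) -> dict[str, float]:
        out = {}
        for s in SAMPLES:
            m, w = record.counts[s]
            m, w = m + pc, w + pc
            out[s] = (m / (m + w)) if denominator == "total" else (m / w)
        return out

    maf = mafs(0.0)
    control_mean = float(np.mean([maf[s] for s in CONTROLS]))
    used_pc = False
    if control_mean == 0.0:
        maf = mafs(pseudocount)
        control_mean = float(np.mean([maf[s] for s in CONTROLS]))
        used_pc = True
    treated_mean = float(np.mean([maf[s] for s in TREATED]))
    fc = treated_mean / control_mean
    return RecoveryRecord(
        variant_id=record.variant_id,
        gene=record.gene,
        mutation_class=record.mutation_class,
        zygosity=record.zygosity,
        pass_filter=True,
        maf_by_sample=dict(maf),
        maf_treated=treated_mean,
        maf_control=control_mean,
        fold_change=fc,
        recovered=fc >= r,
        pseudocount_applied=used_pc,
        nmd_predicted=record.nmd_predicted,
    )


def analyze_recovery(
    records: Sequence[VariantRecord],
    r: float = DEFAULT_FOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_depth: int = DEFAULT_MIN_DEPTH,
    denominator: str = "total",
) -> pd.DataFrame:
    """Filter + fold change for a whole table; one row per variant."""
    rows = [
        recovery_fold(rec, r=r, pseudocount=pseudocount, min_depth=min_depth, denominator=denominator).as_row()
        for rec in records
    ]
    columns = (
        ["variant_id", "gene", "mutation_class", "zygosity", "pass_filter"]
        + [f"maf_{s}" for s in SAMPLES]
        + ["maf_treated", "maf_control", "fold_change", "recovered", "pseudocount_applied", "nmd_predicted"]
    )
    return pd.DataFrame(rows, columns=columns)


def stratify_recovery(recovery: pd.DataFrame) -> pd.DataFrame:
    """Per-mutation-class recovery rates over filter-passing variants.

    A class with zero passing variants reports a missing (NaN) rate, not 0.
    """
    unknown = sorted(set(recovery["mutation_class"]) - set(MUTATION_CLASSES))
    if unknown:
        raise VariantTableError(f"unknown mutation classes {unknown}")
    rows = []
    for mclass in MUTATION_CLASSES:
        sub = recovery[(recovery["mutation_class"] == mclass)]
        if sub.empty:
            continue
        passing = sub[sub["pass_filter"]]
        n_pass = int(len(passing))
        n_rec = int(passing["recovered"].sum())
        rows.append(
            {
                "mutation_class": mclass,
                "n_variants": int(len(sub)),
                "n_pass": n_pass,
                "n_recovered": n_rec,
                "recovery_rate": (n_rec / n_pass) if n_pass else math.nan,
            }
        )
    return pd.DataFrame(
        rows, columns=["mutation_class", "n_variants", "n_pass", "n_recovered", "recovery_rate"]
    )


# ---------------------------------------------------------------------------
# two-proportion chi-squared test


@dataclass(frozen=True)
class TwoProportionResult:
    chi2: float
    p_value: float
    proportion1: float
    proportion2: float
    continuity: bool

    def to_dict(self) -> dict:
        return {
            "chi2": self.chi2,
            "p_value": self.p_value,
            "proportion1": self.proportion1,
            "proportion2": self.proportion2,
            "continuity": self.continuity,
        }


def two_proportion_test(
    a1: int, n1: int, a2: int, n2: int, continuity: bool = True
) -> TwoProportionResult:
    """2x2 chi-squared test of equal proportions (a1/n1 vs a2/n2).

    Closed-form Pearson statistic on the table [[a1, n1-a1], [a2, n2-a2]];
    the Yates continuity correction (default, matching R's prop.test) shrinks
    |ad - bc| by N/2, capped so the corrected statistic is never negative.
    p-value from the chi-squared distribution with 1 df.  A degenerate table
    (any zero row/column margin) is an error.
    """
    if not (0 <= a1 <= n1 and 0 <= a2 <= n2):
        raise ValueError("need 0 <= successes <= trials in both groups")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("trial counts must be positive")
    a, b = a1, n1 - a1
    c, d = a2, n2 - a2
    n = a + b + c + d
    margins = [a + b, c + d, a + c, b + d]
    if any(m == 0 for m in margins):
        raise ValueError("degenerate 2x2 table: a row or column margin is zero")
    cross = abs(a * d - b * c)
    if continuity:
        cross = max(0.0, cross - n / 2.0)
    chi2 = n * cross**2 / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(stats.chi2.sf(chi2, df=1))
    return TwoProportionResult(
        chi2=float(chi2),
        p_value=p,
        proportion1=a1 / n1,
        proportion2=a2 / n2,
        continuity=continuity,
    )


def nmd_recovery_test(recovery: pd.DataFrame, continuity: bool = True) -> dict | None:
    """Compare recovery proportions between NMD-predicted and other variants.

    Uses filter-passing variants with a non-null ``nmd_predicted`` annotation;
    returns None when either group is absent or the table is degenerate.
    """
    passing = recovery[recovery["pass_filter"] & recovery["nmd_predicted"].notna()]
    if passing.empty:
        return None
    pred = passing[passing["nmd_predicted"] == True]  # noqa: E712
    other = passing[passing["nmd_predicted"] == False]  # noqa: E712
    if pred.empty or other.empty:
        return None
    try:
        res = two_proportion_test(
            int(pred["recovered"].sum()),
            len(pred),
            int(other["recovered"].sum()),
            len(other),
            continuity=continuity,
        )
    except ValueError:
        return None
    out = res.to_dict()
    out.update(
        {
            "n_nmd_predicted": int(len(pred)),
            "n_recovered_nmd_predicted": int(pred["recovered"].sum()),
            "n_other": int(len(other)),
            "n_recovered_other": int(other["recovered"].sum()),
        }
    )
    return out


def write_test_json(result: dict | None, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(result if result is not None else {"note": "test not applicable"}, fh, indent=2)
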