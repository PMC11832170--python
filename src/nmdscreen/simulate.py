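"""Synthetic screens and variant tables with known ground truth.

The screen generator emulates the pooled three-line reporter assay: an
equal-ratio pool of isogenic knockout clones (two STAG2 frameshift clones,
one TP53 frameshift clone by default), per-gene baseline NMD escape ratios
theta0 (1/20 for STAG2, 1/6 for TP53 — i.e. 20-fold and 6-fold suppression
of the mutant transcript), a positive-control (translation-inhibitor) effect
multiplier of 3.5, per-well sequencing depth drawn from a negative binomial
around 56,753 reads, and i.i.d. per-base substitution errors.  Every output
(FASTQ, barcode manifest, amplicon panel, plate map, pool design) is exactly
what the analysis pipeline consumes, plus a truth manifest sufficient to
recompute every expectation analytically.

The variant-table generator emulates treated/control duplicate count tables
with known per-variant fold changes for the recovery stage.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import string
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .barcodes import BarcodeManifest, hamming_distance, write_manifest
from .panel import AlleleDef, AmpliconPanel, PanelError
from .scoring import Carrier, PoolDesign, corrected_maf, DEFAULT_MIN_DEPTH
from .recovery import MUTATION_CLASSES

#: baseline NMD escape ratios: mutant transcript output relative to an
#: unsuppressed allele (reciprocal of the fold-suppression)
DEFAULT_THETA0 = {"STAG2": 1.0 / 20.0, "TP53": 1.0 / 6.0}
DEFAULT_DEPTH_MEAN = 56753.0
DEFAULT_POSITIVE_EFFECT = 3.5

_BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)
_LUT = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i


class SimulationError(ValueError):
    pass


def default_pool_design() -> PoolDesign:
    """Three lines in equal ratio: two STAG2 clones and one TP53 clone, each
    carrying its own homozygous/hemizygous frameshift allele."""
    return PoolDesign(
        n_lines=3,
        carriers={
            "STAG2_clone2_mut": Carrier("STAG2", 1, 1.0),
            "STAG2_clone8_mut": Carrier("STAG2", 1, 1.0),
            "TP53_clone221_mut": Carrier("TP53", 1, 1.0),
        },
    )


def expected_mutant_fraction(design: PoolDesign, allele_id: str, theta: float) -> float:
    """Analytic expected fraction of a mutant allele among its gene's reads.

    With equal per-cell expression, each carrier line emits the mutant allele
    at rate theta relative to an unsuppressed allele, so

        frac_a = n_a * delta_a * theta / (theta * M_g + W_g)

    where M_g is the total mutant dosage of the gene across the pool and
    W_g = N - M_g the total wild-type dosage (all mutant alleles of a gene
    share the well's theta).  At theta = 1 this reduces to e_a = n_a*delta_a/N.
    """
    if theta < 0:
        raise SimulationError("theta must be >= 0")
    c = design.carriers.get(allele_id)
    if c is None:
        raise SimulationError(f"allele {allele_id!r} absent from pool design")
    m_g = design.mutant_dosage(c.gene)
    w_g = design.wildtype_dosage(c.gene)
    denom = theta * m_g + w_g
    if denom == 0:
        return 0.0
    return c.n_carrier_lines * c.dosage * theta / denom


# ---------------------------------------------------------------------------
# deterministic screen scaffolding


def well_ids(n: int = 96) -> list[str]:
    """Standard 96-well ids A1..H12 in row-major order (first n)."""
    if not (1 <= n <= 96):
        raise SimulationError("wells_per_plate must be in 1..96")
    ids = [f"{r}{c}" for r in string.ascii_uppercase[:8] for c in range(1, 13)]
    return ids[:n]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _random_barcodes(
    rng: np.random.Generator, n: int, length: int, min_distance: int
) -> list[str]:
    """Greedy rejection sampling of barcodes with pairwise distance >= min_distance."""
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 100000:
            raise SimulationError("could not generate separated barcodes")
        cand = _random_seq(rng, length)
        if all(hamming_distance(cand, b) >= min_distance for b in out):
            out.append(cand)
    return out


def build_barcode_manifest(
    rng: np.random.Generator,
    n_plates: int,
    wells_per_plate: int = 96,
    plate_length: int = 8,
    well_length: int = 10,
    max_mismatches: int = 1,
    read_length: int = 150,
) -> BarcodeManifest:
    """Random barcode sets respecting the separation invariant; plate barcode
    at the start of the read, well barcode at its far (reverse-primer) end."""
    min_dist = 2 * max_mismatches + 1
    plates = _random_barcodes(rng, n_plates, plate_length, min_dist)
    wells = _random_barcodes(rng, wells_per_plate, well_length, min_dist)
    manifest = BarcodeManifest(
        plate_barcodes={f"P{i + 1:02d}": bc for i, bc in enumerate(plates)},
        well_barcodes=dict(zip(well_ids(wells_per_plate), wells)),
        plate_barcode_offset=0,
        well_barcode_offset=read_length - well_length,
        max_mismatches=max_mismatches,
    )
    manifest.validate_separation()
    return manifest


#: per-gene clone edits: (clone label, deletion length) at a shared cut site;
#: deletion lengths are non-multiples of 3 (frameshifts)
_DEFAULT_CLONES = {
    "STAG2": [("clone2", 4), ("clone8", 1)],
    "TP53": [("clone221", 2)],
}


def build_panel(
    rng: np.random.Generator,
    amplicon_length: int = 132,
    window_flank: int = 10,
    clones: dict[str, list[tuple[str, int]]] | None = None,
) -> AmpliconPanel:
    """Random amplicon panel: per gene one wild-type allele plus clone-specific
    frameshift deletions at a shared cut site, each with a diagnostic window
    of ``window_flank`` nt around the edit.  Retries on the (rare) random
    coincidence that makes windows non-discriminating.
    """
    clones = clones if clones is not None else _DEFAULT_CLONES
    cut = amplicon_length // 2
    for _ in range(20):
        alleles = []
        for gene, clone_list in clones.items():
            max_del = max(d for _, d in clone_list)
            locus = _random_seq(rng, amplicon_length + max_del)
            wt_seq = locus[:amplicon_length]
            alleles.append(
                AlleleDef(
                    gene=gene,
                    allele_id=f"{gene}_wt",
                    sequence=wt_seq,
                    diagnostic_window=(cut - window_flank, cut + window_flank + 1),
                    is_mutant=False,
                )
            )
            for clone, del_len in clone_list:
                mut_seq = (locus[:cut] + locus[cut + del_len :])[:amplicon_length]
                alleles.append(
                    AlleleDef(
                        gene=gene,
                        allele_id=f"{gene}_{clone}_mut",
                        sequence=mut_seq,
                        diagnostic_window=(cut - window_flank, cut + window_flank),
                        is_mutant=True,
                        clone_line=f"RPE1_{gene}_{clone.removeprefix('clone')}",
                    )
                )
        try:
            return AmpliconPanel(alleles)
        except PanelError:
            continue
    raise SimulationError("failed to build a discriminating panel after 20 attempts")


# ---------------------------------------------------------------------------
# screen simulation


@dataclass
class ScreenSimConfig:
    """Study conditions of the simulated screen.

    Defaults mirror the assay being emulated: 96-well plates with two
    positive (translation-inhibitor) and six negative (DMSO) control wells,
    a 3-line pool, 20-fold STAG2 / 6-fold TP53 baseline suppression, a 3.5x
    positive-control effect, negative-binomially dispersed depth around
    56,753 reads per well, and 0.001 per-base substitution error.
    """

    n_plates: int = 1
    wells_per_plate: int = 96
    n_positive: int = 2
    n_negative: int = 6
    theta0: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_THETA0))
    f_pos: float = DEFAULT_POSITIVE_EFFECT
    spiked: dict[str, float] = field(default_factory=dict)
    epsilon: float = 0.001
    depth_mean: float = DEFAULT_DEPTH_MEAN
    depth_dispersion: float = 20.0
    well_cv: float = 0.02
    read_length: int = 150
    amplicon_length: int = 132
    window_flank: int = 10
    gzip_fastq: bool = True

    def __post_init__(self) -> None:
        if self.n_plates < 1:
            raise SimulationError("n_plates must be >= 1")
        if self.n_positive + self.n_negative >= self.wells_per_plate:
            raise SimulationError("control wells leave no library wells")
        if not (0.0 <= self.epsilon < 0.25):
            raise SimulationError("epsilon must be in [0, 0.25)")
        for gene, t in self.theta0.items():
            if t <= 0:
                raise SimulationError(f"theta0[{gene}] must be > 0")
        for cpd, f in self.spiked.items():
            if f < 1.0:
                raise SimulationError(f"spiked inhibitor {cpd!r} must have effect >= 1")
        if self.depth_mean <= 0:
            raise SimulationError("depth_mean must be positive")
        if self.amplicon_length + 18 > self.read_length:
            raise SimulationError("amplicon does not fit in the read")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def plate_layout(config: ScreenSimConfig, plate_id: str) -> list[tuple[str, str, str]]:
    """Deterministic (well_id, compound_id, role) layout for one plate:
    positives then negatives occupy the leading wells, the rest are library
    compounds named cpd_<plate>_<well>."""
    rows = []
    for i, well in enumerate(well_ids(config.wells_per_plate)):
        if i < config.n_positive:
            rows.append((well, "emetine", "positive_control"))
        elif i < config.n_positive + config.n_negative:
            rows.append((well, "DMSO", "negative_control"))
        else:
            rows.append((well, f"cpd_{plate_id}_{well}", "library"))
    return rows


def library_compound_ids(config: ScreenSimConfig) -> list[str]:
    """All library compound ids of a configured screen, in layout order."""
    out = []
    for p in range(config.n_plates):
        plate_id = f"P{p + 1:02d}"
        out.extend(c for _, c, role in plate_layout(config, plate_id) if role == "library")
    return out


def _well_effect(config: ScreenSimConfig, compound_id: str, role: str) -> float:
    if role == "positive_control":
        return config.f_pos
    if role == "library":
        return config.spiked.get(compound_id, 1.0)
    return 1.0


def draw_well_counts(
    rng: np.random.Generator,
    design: PoolDesign,
    theta_by_gene: dict[str, float],
    depth: int,
) -> tuple[dict[str, int], dict[str, int]]:
    """Multinomial allele counts for one well.

    Reads split equally between genes (amplicons are separately amplified),
    then among each gene's mutant alleles and its wild-type allele according
    to :func:`expected_mutant_fraction`.  Returns (mutant counts by allele,
    wild-type counts by gene).
    """
    genes = sorted(theta_by_gene)
    gene_depths = rng.multinomial(depth, [1.0 / len(genes)] * len(genes)) if depth else [0] * len(genes)
    mut_counts: dict[str, int] = {}
    wt_counts: dict[str, int] = {}
    for gene, n_g in zip(genes, gene_depths):
        alleles = sorted(a for a, c in design.carriers.items() if c.gene == gene)
        fracs = [expected_mutant_fraction(design, a, theta_by_gene[gene]) for a in alleles]
        p_wt = max(0.0, 1.0 - sum(fracs))
        draw = rng.multinomial(n_g, fracs + [p_wt]) if n_g else np.zeros(len(fracs) + 1, dtype=int)
        for a, cnt in zip(alleles, draw[:-1]):
            mut_counts[a] = int(cnt)
        wt_counts[gene] = int(draw[-1])
    return mut_counts, wt_counts


def _draw_depth(rng: np.random.Generator, mean: float, dispersion: float | None) -> int:
    if dispersion is None:
        return int(round(mean))
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


@dataclass
class ScreenSimResult:
    outdir: Path
    fastq: Path
    manifest_yaml: Path
    panel_fasta: Path
    windows_tsv: Path
    platemap_csv: Path
    pool_yaml: Path
    truth_json: Path
    truth: dict


def simulate_screen(config: ScreenSimConfig, outdir: str | Path, seed: int) -> ScreenSimResult:
    """Generate a full synthetic screen: FASTQ + manifests + truth.

    Byte-reproducible for a fixed (config, seed): a single RNG drives barcode
    and amplicon generation, depths, allele draws, within-well read order and
    substitution errors, and the gzip stream carries no timestamp.
    Read ids are ``r<n>|<plate>|<well>|<true allele>`` so per-read truth
    travels with the data without the pipeline using it.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    design = default_pool_design()
    genes = sorted({c.gene for c in design.carriers.values()})
    if set(config.theta0) != set(genes):
        raise SimulationError(f"theta0 must cover genes {genes}")

    manifest = build_barcode_manifest(
        rng,
        config.n_plates,
        config.wells_per_plate,
        max_mismatches=1,
        read_length=config.read_length,
    )
    panel = build_panel(rng, config.amplicon_length, config.window_flank)

    plate_ids = sorted(manifest.plate_barcodes)
    layout: list[tuple[str, str, str, str]] = []  # plate, well, compound, role
    known_compounds = set()
    for plate_id in plate_ids:
        for well, compound, role in plate_layout(config, plate_id):
            layout.append((plate_id, well, compound, role))
            known_compounds.add(compound)
    for cpd in config.spiked:
        if cpd in ("DMSO", "emetine"):
            raise SimulationError(f"cannot spike an effect onto control compound {cpd!r}")
        if cpd not in known_compounds:
            raise SimulationError(f"spiked compound {cpd!r} is not on any plate")

    # per-allele read templates per (plate, well) barcode pair, as uint8 rows
    allele_ids = sorted(panel.alleles)
    pad = "T" * (config.read_length - 18 - config.amplicon_length)  # downstream context
    bodies = {
        a: panel.alleles[a].sequence + pad for a in allele_ids
    }

    fastq_path = outdir / ("reads.fastq.gz" if config.gzip_fastq else "reads.fastq")
    qual = "I" * config.read_length
    truth_wells = []
    read_counter = 0
    if config.gzip_fastq:
        fh = gzip.GzipFile(fastq_path, "wb", compresslevel=1, mtime=0)
    else:
        fh = open(fastq_path, "wb")
    try:
        for plate_id, well, compound, role in layout:
            depth = _draw_depth(rng, config.depth_mean, config.depth_dispersion)
            effect = _well_effect(config, compound, role)
            noise = max(0.0, 1.0 + rng.normal(0.0, config.well_cv)) if config.well_cv else 1.0
            theta = {g: config.theta0[g] * effect * noise for g in genes}
            mut_counts, wt_counts = draw_well_counts(rng, design, theta, depth)
            per_allele = []
            for a in allele_ids:
                ad = panel.alleles[a]
                n = mut_counts.get(a) if ad.is_mutant else wt_counts.get(ad.gene)
                per_allele.append(int(n or 0))
            total = sum(per_allele)
            if total:
                prefix = manifest.plate_barcodes[plate_id]
                suffix = manifest.well_barcodes[well]
                rows = np.stack(
                    [
                        np.frombuffer((prefix + bodies[a] + suffix).encode(), dtype=np.uint8)
                        for a in allele_ids
                    ]
                )
                reads = np.repeat(rows, per_allele, axis=0)
                labels = np.repeat(np.arange(len(allele_ids)), per_allele)
                perm = rng.permutation(total)
                reads = reads[perm]
                labels = labels[perm]
                if config.epsilon > 0:
                    mask = rng.random(reads.shape) < config.epsilon
                    idx = np.nonzero(mask)
                    if idx[0].size:
                        codes = _LUT[reads[idx]]
                        shift = rng.integers(1, 4, size=idx[0].size)
                        reads[idx] = _BASE_ARR[(codes + shift) % 4]
                chunk = []
                for i in range(total):
                    read_counter += 1
                    chunk.append(
                        f"@r{read_counter}|{plate_id}|{well}|{allele_ids[labels[i]]}\n"
                        f"{reads[i].tobytes().decode()}\n+\n{qual}\n"
                    )
                fh.write("".join(chunk).encode())
            truth_wells.append(
                {
                    "plate_id": plate_id,
                    "well_id": well,
                    "compound_id": compound,
                    "role": role,
                    "effect": effect,
                    "noise_multiplier": noise,
                    "depth": depth,
                    "theta": theta,
                    "expected_fraction": {
                        a: expected_mutant_fraction(design, a, theta[design.carriers[a].gene])
                        for a in design.mutant_allele_ids
                    },
                    "true_counts": {
                        **{a: mut_counts[a] for a in design.mutant_allele_ids},
                        **{f"{g}_wt": wt_counts[g] for g in genes},
                    },
                }
            )
    finally:
        fh.close()

    manifest_yaml = outdir / "manifest.yaml"
    write_manifest(manifest, manifest_yaml)
    panel_fasta = outdir / "panel.fasta"
    windows_tsv = outdir / "windows.tsv"
    panel.to_files(panel_fasta, windows_tsv)
    platemap_csv = outdir / "platemap.csv"
    pd.DataFrame(
        layout, columns=["plate_id", "well_id", "compound_id", "role"]
    ).to_csv(platemap_csv, index=False)
    pool_yaml = outdir / "pool.yaml"
    design.to_yaml(pool_yaml)

    truth = {
        "seed": seed,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "n_reads": read_counter,
        "spiked_hits": sorted(config.spiked),
        "wells": truth_wells,
    }
    truth_json = outdir / "truth.json"
    with open(truth_json, "w") as jf:
        json.dump(truth, jf, indent=1)
    return ScreenSimResult(
        outdir=outdir,
        fastq=fastq_path,
        manifest_yaml=manifest_yaml,
        panel_fasta=panel_fasta,
        windows_tsv=windows_tsv,
        platemap_csv=platemap_csv,
        pool_yaml=pool_yaml,
        truth_json=truth_json,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# count-level null simulation (for threshold calibration studies)


def simulate_null_mafs(
    n_library: int,
    n_controls: int,
    seed: int,
    design: PoolDesign | None = None,
    theta0: dict[str, float] | None = None,
    depth_mean: float = DEFAULT_DEPTH_MEAN,
    depth_dispersion: float | None = 20.0,
    well_cv: float = 0.02,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> tuple[dict[str, list[float]], pd.DataFrame]:
    """Simulate corrected MAFs of untreated wells directly at the count level.

    All wells (controls and library alike) are drawn from the identical null:
    binomial allele counts at negative-binomial depth around the baseline
    escape ratios, with a shared per-well Gaussian noise multiplier on theta.
    Returns (control corrected MAFs keyed by allele — null-model input — and
    a library-well MAF table for hit calling).
    """
    design = design if design is not None else default_pool_design()
    theta0 = dict(theta0 if theta0 is not None else DEFAULT_THETA0)
    rng = np.random.default_rng(seed)
    genes = sorted({c.gene for c in design.carriers.values()})

    def draw_maf_rows(n: int, tag: str) -> pd.DataFrame:
        rows = []
        for i in range(n):
            depth = _draw_depth(rng, depth_mean, depth_dispersion)
            noise = max(0.0, 1.0 + rng.normal(0.0, well_cv)) if well_cv else 1.0
            theta = {g: theta0[g] * noise for g in genes}
            mut_counts, wt_counts = draw_well_counts(rng, design, theta, depth)
            for a in design.mutant_allele_ids:
                gene = design.carriers[a].gene
                rec = corrected_maf(
                    mut_counts[a], wt_counts[gene], design, a,
                    plate_id="SIM", well_id=f"{tag}{i}", min_depth=min_depth,
                )
                rows.append(rec.__dict__)
        return pd.DataFrame(rows)

    control_df = draw_maf_rows(n_controls, "c")
    library_df = draw_maf_rows(n_library, "w")
    control_mafs: dict[str, list[float]] = {}
    usable = control_df[~control_df["low_coverage"] & control_df["corrected_maf"].notna()]
    for a in design.mutant_allele_ids:
        control_mafs[a] = [
            float(v) for v in usable.loc[usable["allele_id"] == a, "corrected_maf"]
        ]
    return control_mafs, library_df


# ---------------------------------------------------------------------------
# variant-table simulation


@dataclass
class VariantSimConfig:
    """Study conditions of the simulated variant count tables.

    Control MAFs of somatic classes follow Beta(4, 16) (moderate genome-wide
    NMD suppression); common heterozygous SNPs follow Beta(50, 50) (balanced
    allelic expression).  True folds default to 3 for truncating classes
    (frameshift indels, nonsense), 1 for non-truncating SNVs and control
    SNPs.  Per-sample site depth is negative binomial (mean 200, size 8);
    a ``None`` dispersion fixes depth at the mean.
    """

    n_variants: dict[str, int] = field(
        default_factory=lambda: {
            "frameshift_indel": 150,
            "nonsense": 100,
            "other_snv": 150,
            "control_snp": 100,
        }
    )
    true_fold: dict[str, float] = field(
        default_factory=lambda: {
            "frameshift_indel": 3.0,
            "nonsense": 3.0,
            "other_snv": 1.0,
            "control_snp": 1.0,
        }
    )
    baseline_beta: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "frameshift_indel": (4.0, 16.0),
            "nonsense": (4.0, 16.0),
            "other_snv": (4.0, 16.0),
            "control_snp": (50.0, 50.0),
        }
    )
    depth_mean: float = 200.0
    depth_dispersion: float | None = 8.0
    fraction_homozygous: float = 0.0

    def __post_init__(self) -> None:
        unknown = set(self.n_variants) - set(MUTATION_CLASSES)
        if unknown:
            raise SimulationError(f"unknown mutation classes {sorted(unknown)}")
        for mclass, f in self.true_fold.items():
            if f < 0:
                raise SimulationError(f"true fold for {mclass} must be >= 0")
        if self.true_fold.get("control_snp", 1.0) != 1.0:
            raise SimulationError("control_snp variants have fixed true fold 1.0")
        if not (0.0 <= self.fraction_homozygous <= 1.0):
            raise SimulationError("fraction_homozygous must be in [0, 1]")
        if self.depth_mean <= 0:
            raise SimulationError("depth_mean must be positive")


def simulate_variant_table(
    config: VariantSimConfig, seed: int
) -> tuple[pd.DataFrame, dict]:
    """Simulate a 4-sample variant count table with known fold-change truth.

    Per variant: control MAF q ~ Beta(class); per-sample depth drawn
    independently; control mutant counts ~ Binomial(depth, q) and treated
    counts ~ Binomial(depth, min(1, q*f)).  Saturated variants (q*f clipped
    at 1) are recorded in the truth manifest.
    """
    rng = np.random.default_rng(seed)
    rows = []
    truth_variants = []
    idx = 0
    n_saturated = 0
    for mclass in MUTATION_CLASSES:
        n = config.n_variants.get(mclass, 0)
        if n == 0:
            continue
        a, b = config.baseline_beta[mclass]
        f = config.true_fold.get(mclass, 1.0)
        for _ in range(n):
            idx += 1
            q = float(rng.beta(a, b))
            p_treated = min(1.0, q * f)
            saturated = q * f > 1.0
            n_saturated += saturated
            zyg = (
                "homozygous"
                if (config.fraction_homozygous and rng.random() < config.fraction_homozygous)
                else "heterozygous"
            )
            row = {
                "variant_id": f"var_{idx:05d}",
                "gene": f"GENE{idx:04d}",
                "mutation_class": mclass,
                "zygosity": zyg,
            }
            for sample, p in (
                ("treated_1", p_treated),
                ("treated_2", p_treated),
                ("control_1", q),
                ("control_2", q),
            ):
                d = _draw_depth(rng, config.depth_mean, config.depth_dispersion)
                m = int(rng.binomial(d, p)) if d else 0
                row[f"m_{sample}"] = m
                row[f"w_{sample}"] = d - m
            row["nmd_predicted"] = mclass in ("frameshift_indel", "nonsense")
            rows.append(row)
            truth_variants.append(
                {
                    "variant_id": row["variant_id"],
                    "mutation_class": mclass,
                    "true_fold": f,
                    "control_maf": q,
                    "zygosity": zyg,
                    "saturated": bool(saturated),
                }
            )
    columns = (
        ["variant_id", "gene", "mutation_class", "zygosity"]
        + [f"{p}_{s}" for s in ("treated_1", "treated_2", "control_1", "control_2") for p in ("m", "w")]
        + ["nmd_predicted"]
    )
    df = pd.DataFrame(rows, columns=columns)
    truth = {
        "seed": seed,
        "n_saturated": int(n_saturated),
        "variants": truth_variants,
    }
    return df, truth
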