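"""Dual-barcode demultiplexing for pooled amplicon screens.

Each sequencing read carries a plate barcode (embedded in the forward-primer
region) and a well barcode (reverse-primer region) at fixed, manifest-declared
offsets.  A read is assigned to a (plate, well) only when, on each axis,
exactly one manifest barcode lies within ``max_mismatches`` Hamming distance
of the observed k-mer; ties and no-matches leave that axis unassigned.

With barcode sets whose pairwise Hamming distance exceeds ``2 * max_mismatches``
(enforced on load), any read whose true barcode acquired at most
``max_mismatches`` substitutions is provably assigned to its true well.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import yaml

#: sentinel returned for an axis that could not be resolved
UNASSIGNED = "UNASSIGNED"

_ALPHABET = "ACGT"


class ManifestError(ValueError):
    """Raised when a barcode manifest violates its invariants."""


def hamming_distance(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def _check_set(name: str, barcodes: Mapping[str, str]) -> int:
    """Structural checks for one barcode set; returns the common length."""
    if not barcodes:
        raise ManifestError(f"{name} barcode set is empty")
    lengths = {len(s) for s in barcodes.values()}
    if len(lengths) != 1:
        raise ManifestError(f"{name} barcodes have mixed lengths: {sorted(lengths)}")
    seen: dict[str, str] = {}
    for bc_id, seq in barcodes.items():
        if set(seq) - set(_ALPHABET):
            raise ManifestError(f"{name} barcode {bc_id!r} has non-ACGT characters: {seq}")
        if seq in seen:
            raise ManifestError(
                f"duplicate {name} barcode {seq}: ids {seen[seq]!r} and {bc_id!r}"
            )
        seen[seq] = bc_id
    return lengths.pop()


@dataclass
class BarcodeManifest:
    """Barcode sets plus the fixed read offsets where they are found.

    Construction performs structural validation (uniform lengths, ACGT
    alphabet, pairwise-distinct sequences).  The Hamming-separation invariant
    (pairwise distance > ``2 * max_mismatches`` within each set) is enforced by
    :func:`load_manifest` / :meth:`validate_separation`, so that the
    tie-breaking semantics of :func:`demultiplex_read` remain testable on
    deliberately under-separated sets.
    """

    plate_barcodes: dict[str, str]
    well_barcodes: dict[str, str]
    plate_barcode_offset: int
    well_barcode_offset: int
    max_mismatches: int = 1

    plate_barcode_length: int = field(init=False)
    well_barcode_length: int = field(init=False)

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ManifestError("max_mismatches must be non-negative")
        if self.plate_barcode_offset < 0 or self.well_barcode_offset < 0:
            raise ManifestError("barcode offsets must be non-negative")
        self.plate_barcode_length = _check_set("plate", self.plate_barcodes)
        self.well_barcode_length = _check_set("well", self.well_barcodes)

    # -- invariants ---------------------------------------------------------

    def validate_separation(self) -> None:
        """Enforce pairwise Hamming distance > 2 * max_mismatches per set."""
        floor = 2 * self.max_mismatches
        for name, barcodes in (("plate", self.plate_barcodes), ("well", self.well_barcodes)):
            items = list(barcodes.items())
            for (id_a, a), (id_b, b) in itertools.combinations(items, 2):
                d = hamming_distance(a, b)
                if d <= floor:
                    raise ManifestError(
                        f"{name} barcodes {id_a!r} and {id_b!r} are at Hamming "
                        f"distance {d} <= 2*max_mismatches={floor}"
                    )

    @property
    def min_read_length(self) -> int:
        return max(
            self.plate_barcode_offset + self.plate_barcode_length,
            self.well_barcode_offset + self.well_barcode_length,
        )


# ---------------------------------------------------------------------------
# matching


def _match_axis(observed: str, barcodes: Mapping[str, str], max_mismatches: int) -> str:
    """Reference semantics: assigned iff exactly one barcode within tolerance."""
    hits = [
        bc_id
        for bc_id, bc in barcodes.items()
        if hamming_distance(observed, bc) <= max_mismatches
    ]
    return hits[0] if len(hits) == 1 else UNASSIGNED


def demultiplex_read(
    seq: str, manifest: BarcodeManifest
) -> tuple[str, str]:
    """Resolve (plate_id, well_id) for one read sequence.

    Either axis is ``UNASSIGNED`` when the read is too short for its window,
    no barcode lies within ``max_mismatches``, or more than one does.
    """
    seq = seq.upper()
    plate = well = UNASSIGNED
    po, pl = manifest.plate_barcode_offset, manifest.plate_barcode_length
    if len(seq) >= po + pl:
        plate = _match_axis(seq[po : po + pl], manifest.plate_barcodes, manifest.max_mismatches)
    wo, wl = manifest.well_barcode_offset, manifest.well_barcode_length
    if len(seq) >= wo + wl:
        well = _match_axis(seq[wo : wo + wl], manifest.well_barcodes, manifest.max_mismatches)
    return plate, well


def _neighborhood(seq: str, max_mismatches: int) -> Iterator[str]:
    """All sequences within Hamming distance ``max_mismatches`` of ``seq``."""
    yield seq
    for k in range(1, max_mismatches + 1):
        for positions in itertools.combinations(range(len(seq)), k):
            alternatives = [
                [b for b in _ALPHABET if b != seq[p]] for p in positions
            ]
            for subs in itertools.product(*alternatives):
                chars = list(seq)
                for p, b in zip(positions, subs):
                    chars[p] = b
                yield "".join(chars)


def _build_lookup(barcodes: Mapping[str, str], max_mismatches: int) -> dict[str, str | None]:
    """Exact-lookup table over the <=m-substitution neighborhood of each barcode.

    A k-mer claimed by more than one barcode maps to ``None`` (a tie), which
    reproduces the "exactly one within tolerance" rule of :func:`_match_axis`
    by construction.
    """
    table: dict[str, str | None] = {}
    for bc_id, bc in barcodes.items():
        for variant in _neighborhood(bc, max_mismatches):
            prior = table.get(variant, bc_id)
            table[variant] = bc_id if prior == bc_id else None
    return table


class BarcodeIndex:
    """Constant-time demultiplexer equivalent to :func:`demultiplex_read`."""

    def __init__(self, manifest: BarcodeManifest):
        self.manifest = manifest
        self._plate = _build_lookup(manifest.plate_barcodes, manifest.max_mismatches)
        self._well = _build_lookup(manifest.well_barcodes, manifest.max_mismatches)
        self._po = manifest.plate_barcode_offset
        self._pe = self._po + manifest.plate_barcode_length
        self._wo = manifest.well_barcode_offset
        self._we = self._wo + manifest.well_barcode_length

    def assign(self, seq: str) -> tuple[str, str]:
        n = len(seq)
        plate = well = UNASSIGNED
        if n >= self._pe:
            plate = self._plate.get(seq[self._po : self._pe]) or UNASSIGNED
        if n >= self._we:
            well = self._well.get(seq[self._wo : self._we]) or UNASSIGNED
        return plate, well


# ---------------------------------------------------------------------------
# i/o


def _read_barcode_tsv(path: Path) -> tuple[dict[str, str], dict[str, str]]:
    plates: dict[str, str] = {}
    wells: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["kind", "id", "sequence"]
        if header != expected:
            raise ManifestError(
                f"{path}: expected header {expected}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ManifestError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
            kind, bc_id, seq = fields
            target = {"plate": plates, "well": wells}.get(kind)
            if target is None:
                raise ManifestError(f"{path}:{lineno}: unknown kind {kind!r}")
            if bc_id in target:
                raise ManifestError(f"{path}:{lineno}: duplicate {kind} id {bc_id!r}")
            target[bc_id] = seq.upper()
    return plates, wells


def load_manifest(path: str | Path) -> BarcodeManifest:
    """Load and fully validate a barcode manifest.

    ``path`` is a YAML file with keys ``plate_barcode_offset``,
    ``well_barcode_offset``, ``max_mismatches`` and either ``barcode_tsv``
    (a sidecar TSV with columns kind/id/sequence, resolved relative to the
    YAML file) or inline ``plate_barcodes`` / ``well_barcodes`` mappings.
    """
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ManifestError(f"{path}: manifest YAML must be a mapping")
    known = {
        "plate_barcode_offset",
        "well_barcode_offset",
        "max_mismatches",
        "barcode_tsv",
        "plate_barcodes",
        "well_barcodes",
    }
    unknown = set(cfg) - known
    if unknown:
        raise ManifestError(f"{path}: unknown manifest keys {sorted(unknown)}")
    if "barcode_tsv" in cfg:
        plates, wells = _read_barcode_tsv(path.parent / cfg["barcode_tsv"])
    else:
        try:
            plates = {k: str(v).upper() for k, v in cfg["plate_barcodes"].items()}
            wells = {k: str(v).upper() for k, v in cfg["well_barcodes"].items()}
        except KeyError as exc:
            raise ManifestError(f"{path}: missing barcode source {exc}") from None
    try:
        manifest = BarcodeManifest(
            plate_barcodes=plates,
            well_barcodes=wells,
            plate_barcode_offset=int(cfg["plate_barcode_offset"]),
            well_barcode_offset=int(cfg["well_barcode_offset"]),
            max_mismatches=int(cfg.get("max_mismatches", 1)),
        )
    except KeyError as exc:
        raise ManifestError(f"{path}: missing required key {exc}") from None
    manifest.validate_separation()
    return manifest


def write_manifest(manifest: BarcodeManifest, yaml_path: str | Path, tsv_name: str = "barcodes.tsv") -> None:
    """Serialize a manifest as YAML config plus a sidecar barcode TSV."""
    yaml_path = Path(yaml_path)
    tsv_path = yaml_path.parent / tsv_name
    with open(tsv_path, "w") as fh:
        fh.write("kind\tid\tsequence\n")
        for bc_id, seq in manifest.plate_barcodes.items():
            fh.write(f"plate\t{bc_id}\t{seq}\n")
        for bc_id, seq in manifest.well_barcodes.items():
            fh.write(f"well\t{bc_id}\t{seq}\n")
    with open(yaml_path, "w") as fh:
        yaml.safe_dump(
            {
                "plate_barcode_offset": manifest.plate_barcode_offset,
                "well_barcode_offset": manifest.well_barcode_offset,
                "max_mismatches": manifest.max_mismatches,
                "barcode_tsv": tsv_name,
            },
            fh,
            sort_keys=False,
        )
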