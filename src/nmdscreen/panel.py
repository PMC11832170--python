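"""Amplicon allele panel and per-read allele classification.

The panel is a pseudo-reference holding, for each targeted gene, the
wild-type amplicon and one or more clone-specific mutant amplicons (as
sequenced, post-primer).  Each allele carries a *diagnostic window* — a short
subsequence spanning its distinguishing edit (for the wild-type allele, the
unedited site) — and a read is classified by exact containment of these
windows, searching both the read and its reverse complement.

Classification outcomes: exactly one allele window found -> that allele;
more than one -> AMBIGUOUS; none -> UNCLASSIFIED.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq, reverse_complement
from Bio.SeqRecord import SeqRecord

AMBIGUOUS = "AMBIGUOUS"
UNCLASSIFIED = "UNCLASSIFIED"


class PanelError(ValueError):
    """Raised when an amplicon panel violates its invariants."""


@dataclass
class AlleleDef:
    """One amplicon allele (wild-type or clone-specific mutant)."""

    gene: str
    allele_id: str
    sequence: str
    diagnostic_window: tuple[int, int]  # 0-based, half-open
    is_mutant: bool
    clone_line: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        start, end = self.diagnostic_window
        if not (0 <= start < end <= len(self.sequence)):
            raise PanelError(
                f"allele {self.allele_id!r}: diagnostic window {self.diagnostic_window} "
                f"outside sequence bounds [0, {len(self.sequence)})"
            )
        if self.is_mutant and not self.clone_line:
            raise PanelError(f"mutant allele {self.allele_id!r} must name its clone_line")
        if not self.is_mutant and self.clone_line:
            raise PanelError(f"wild-type allele {self.allele_id!r} must not name a clone_line")

    @property
    def window_seq(self) -> str:
        start, end = self.diagnostic_window
        return self.sequence[start:end]


class AmpliconPanel:
    """Validated collection of :class:`AlleleDef` covering one or more genes.

    Invariants enforced at construction:

    * every gene has exactly one wild-type allele and at least one mutant;
    * within a gene, diagnostic-window substrings are pairwise distinct;
    * no allele's window (in either orientation) occurs in any *other*
      allele's full sequence — the stronger form that guarantees error-free
      reads classify unambiguously.
    """

    def __init__(self, alleles: list[AlleleDef]):
        ids = [a.allele_id for a in alleles]
        if len(set(ids)) != len(ids):
            raise PanelError("allele_id values must be unique")
        self.alleles: dict[str, AlleleDef] = {a.allele_id: a for a in alleles}
        self.genes: set[str] = {a.gene for a in alleles}
        self._wildtype_of: dict[str, str] = {}
        for gene in sorted(self.genes):
            members = [a for a in alleles if a.gene == gene]
            wt = [a for a in members if not a.is_mutant]
            mut = [a for a in members if a.is_mutant]
            if len(wt) != 1:
                raise PanelError(f"gene {gene!r} must have exactly one wild-type allele, found {len(wt)}")
            if not mut:
                raise PanelError(f"gene {gene!r} has no mutant allele")
            windows = [a.window_seq for a in members]
            if len(set(windows)) != len(windows):
                raise PanelError(f"gene {gene!r}: diagnostic windows are not pairwise distinct")
            self._wildtype_of[gene] = wt[0].allele_id
        for a in alleles:
            win_rc = reverse_complement(a.window_seq)
            for b in alleles:
                if b.allele_id == a.allele_id:
                    continue
                if a.window_seq in b.sequence or win_rc in b.sequence:
                    raise PanelError(
                        f"diagnostic window of {a.allele_id!r} occurs in sequence of "
                        f"{b.allele_id!r}; windows would not be discriminating"
                    )
        # search strings precomputed once: (allele_id, gene, fwd window, rc window)
        self._search = [
            (a.allele_id, a.gene, a.window_seq, reverse_complement(a.window_seq))
            for a in alleles
        ]

    def wildtype_of(self, gene: str) -> str:
        return self._wildtype_of[gene]

    def mutant_alleles(self, gene: str | None = None) -> list[str]:
        return [
            a.allele_id
            for a in self.alleles.values()
            if a.is_mutant and (gene is None or a.gene == gene)
        ]

    def gene_of(self, allele_id: str) -> str:
        return self.alleles[allele_id].gene

    def __len__(self) -> int:
        return len(self.alleles)

    # -- i/o ----------------------------------------------------------------

    def to_files(self, fasta_path: str | Path, windows_path: str | Path) -> None:
        """Write the panel as FASTA (headers gene|allele_id|mut/wt|clone) plus
        a sidecar TSV of 0-based half-open diagnostic windows."""
        records = []
        for a in self.alleles.values():
            kind = "mut" if a.is_mutant else "wt"
            clone = a.clone_line if a.clone_line else "."
            records.append(
                SeqRecord(Seq(a.sequence), id=f"{a.gene}|{a.allele_id}|{kind}|{clone}", description="")
            )
        SeqIO.write(records, str(fasta_path), "fasta")
        with open(windows_path, "w") as fh:
            fh.write("allele_id\twindow_start\twindow_end\n")
            for a in self.alleles.values():
                s, e = a.diagnostic_window
                fh.write(f"{a.allele_id}\t{s}\t{e}\n")

    @classmethod
    def from_files(cls, fasta_path: str | Path, windows_path: str | Path) -> "AmpliconPanel":
        windows: dict[str, tuple[int, int]] = {}
        with open(windows_path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["allele_id", "window_start", "window_end"]:
                raise PanelError(f"{windows_path}: unexpected header {header}")
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) != 3:
                    raise PanelError(f"{windows_path}:{lineno}: expected 3 columns")
                windows[fields[0]] = (int(fields[1]), int(fields[2]))
        alleles = []
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            parts = rec.id.split("|")
            if len(parts) != 4:
                raise PanelError(
                    f"{fasta_path}: header {rec.id!r} is not gene|allele_id|mut/wt|clone"
                )
            gene, allele_id, kind, clone = parts
            if kind not in ("mut", "wt"):
                raise PanelError(f"{fasta_path}: {rec.id!r} has kind {kind!r}")
            if allele_id not in windows:
                raise PanelError(f"no diagnostic window for allele {allele_id!r}")
            alleles.append(
                AlleleDef(
                    gene=gene,
                    allele_id=allele_id,
                    sequence=str(rec.seq),
                    diagnostic_window=windows[allele_id],
                    is_mutant=(kind == "mut"),
                    clone_line="" if clone == "." else clone,
                )
            )
        return cls(alleles)


def classify_allele(seq: str, panel: AmpliconPanel) -> tuple[str | None, str]:
    """Classify one read against the panel's diagnostic windows.

    Returns ``(gene, allele_id)`` for a unique window hit, ``(gene, AMBIGUOUS)``
    when several alleles of one gene match, ``(None, AMBIGUOUS)`` when matches
    span genes, and ``(None, UNCLASSIFIED)`` for no match.  Degenerate input
    (empty/short reads) falls through to UNCLASSIFIED.
    """
    seq = seq.upper()
    hits = [
        (allele_id, gene)
        for allele_id, gene, fwd, rc in panel._search
        if fwd in seq or rc in seq
    ]
    if not hits:
        return None, UNCLASSIFIED
    if len(hits) == 1:
        allele_id, gene = hits[0]
        return gene, allele_id
    genes = {gene for _, gene in hits}
    return (genes.pop() if len(genes) == 1 else None), AMBIGUOUS
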