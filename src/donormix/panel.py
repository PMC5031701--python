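"""SNP panel I/O.

A *panel* is the set of biallelic SNPs interrogated by the assay (e.g. a
forensic identity panel). Panels are read from VCF (1-based) or a BED
dialect (0-based half-open, width-1 intervals, name and "A/G" allele
columns) and held as :class:`PanelLocus` records with 1-based positions.

The order of ``allele_a``/``allele_b`` carries no reference/alternate
meaning downstream: the recipient allele at each locus is determined from
the sequencing data itself, never from the panel — the method is
genotyping-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pysam

from .exceptions import EmptyPanelError, PanelFormatError

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")
_AUTOSOMES = frozenset(str(i) for i in range(1, 23))


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix so ``chr1`` and ``1`` compare equal."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def is_autosomal_chrom(chrom: str) -> bool:
    return normalize_chrom(chrom) in _AUTOSOMES


@dataclass(frozen=True)
class PanelLocus:
    """One biallelic SNP of the panel.

    Attributes
    ----------
    locus_id : str
        Unique identifier, typically an rsID.
    chrom : str
        Chromosome name, normalized (no ``chr`` prefix).
    pos : int
        1-based reference position.
    allele_a, allele_b : str
        The two panel alleles (distinct single nucleotides, no
        reference/alternate semantics).
    is_autosomal : bool
        True for chromosomes 1-22; only autosomal loci enter the model.
    """

    locus_id: str
    chrom: str
    pos: int
    allele_a: str
    allele_b: str
    is_autosomal: bool

    def __post_init__(self):
        if self.allele_a not in NUCLEOTIDES or self.allele_b not in NUCLEOTIDES:
            raise PanelFormatError(
                f"{self.locus_id}: alleles must be single nucleotides, "
                f"got {self.allele_a!r}/{self.allele_b!r}"
            )
        if self.allele_a == self.allele_b:
            raise PanelFormatError(f"{self.locus_id}: alleles must differ")
        if self.pos < 1:
            raise PanelFormatError(f"{self.locus_id}: position must be >= 1")

    @property
    def alleles(self) -> frozenset:
        return frozenset((self.allele_a, self.allele_b))


def _check_unique_ids(loci: list[PanelLocus]) -> list[PanelLocus]:
    seen: set[str] = set()
    for locus in loci:
        if locus.locus_id in seen:
            raise PanelFormatError(f"duplicate locus_id {locus.locus_id!r} in panel")
        seen.add(locus.locus_id)
    return loci


def read_panel_vcf(path: str | Path) -> list[PanelLocus]:
    """Read a panel from a VCF; keep biallelic SNP records only.

    Multi-allelic or indel records are skipped with a warning. Records
    with a missing ID get a synthesized ``chrom:pos`` identifier.

    Raises
    ------
    PanelFormatError
        Unreadable file or malformed header.
    EmptyPanelError
        No usable records.
    """
    path = Path(path)
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise PanelFormatError(f"cannot read VCF {path}: {exc}") from exc

    loci: list[PanelLocus] = []
    with vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1:
                logger.warning(
                    "skipping %s:%d: not biallelic (ALT=%s)", rec.chrom, rec.pos, ",".join(alts) or "."
                )
                continue
            ref, alt = rec.ref.upper(), alts[0].upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
                logger.warning("skipping %s:%d: not a SNP (%s>%s)", rec.chrom, rec.pos, ref, alt)
                continue
            locus_id = rec.id if rec.id not in (None, ".") else f"{normalize_chrom(rec.chrom)}:{rec.pos}"
            loci.append(
                PanelLocus(
                    locus_id=locus_id,
                    chrom=normalize_chrom(rec.chrom),
                    pos=rec.pos,
                    allele_a=ref,
                    allele_b=alt,
                    is_autosomal=is_autosomal_chrom(rec.chrom),
                )
            )
    if not loci:
        raise EmptyPanelError(f"no usable biallelic SNP records in {path}")
    return _check_unique_ids(loci)


def read_panel_bed(path: str | Path) -> list[PanelLocus]:
    """Read a panel from the BED5 dialect.

    Columns: chrom, start (0-based), end, locus_id, alleles as ``A/G``.
    Intervals must have width 1; positions are converted to 1-based.
    """
    path = Path(path)
    loci: list[PanelLocus] = []
    try:
        text = path.read_text()
    except OSError as exc:
        raise PanelFormatError(f"cannot read BED {path}: {exc}") from exc

    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 5:
            raise PanelFormatError(f"{path}:{lineno}: expected >=5 columns, got {len(fields)}")
        chrom, start_s, end_s, locus_id, allele_field = fields[:5]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise PanelFormatError(f"{path}:{lineno}: non-integer coordinates") from exc
        if end - start != 1:
            raise PanelFormatError(
                f"{path}:{lineno}: SNP interval must have width 1, got {end - start}"
            )
        parts = allele_field.upper().split("/")
        if len(parts) != 2 or any(p not in NUCLEOTIDES for p in parts) or parts[0] == parts[1]:
            raise PanelFormatError(
                f"{path}:{lineno}: allele field must be 'X/Y' with distinct nucleotides, "
                f"got {allele_field!r}"
            )
        loci.append(
            PanelLocus(
                locus_id=locus_id,
                chrom=normalize_chrom(chrom),
                pos=start + 1,
                allele_a=parts[0],
                allele_b=parts[1],
                is_autosomal=is_autosomal_chrom(chrom),
            )
        )
    if not loci:
        raise EmptyPanelError(f"no records in {path}")
    return _check_unique_ids(loci)


def write_panel_bed(loci: Iterable[PanelLocus], path: str | Path) -> None:
    """Write a panel to the BED5 dialect (inverse of :func:`read_panel_bed`)."""
    with open(path, "w") as fh:
        for locus in loci:
            fh.write(
                f"{locus.chrom}\t{locus.pos - 1}\t{locus.pos}\t"
                f"{locus.locus_id}\t{locus.allele_a}/{locus.allele_b}\n"
            )


def panel_by_id(loci: Iterable[PanelLocus]) -> dict[str, PanelLocus]:
    return {locus.locus_id: locus for locus in loci}


def panel_by_position(loci: Iterable[PanelLocus]) -> dict[tuple[str, int], PanelLocus]:
    return {(locus.chrom, locus.pos): locus for locus in loci}
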