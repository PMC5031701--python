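"""Quality-filtered per-base read counts at panel loci.

Counts come either from a samtools-mpileup text pileup (6 columns: chrom,
1-based pos, ref, depth, read bases, base qualities) or from a TSV counts
table. Only calls with Phred base quality >= the cutoff (default Q30)
are counted.

Convention: the per-base fields ``n_A..n_T`` are populated only for a
locus's two panel alleles; a quality-passing call of N or of either other
base is *ambiguous* — at a biallelic SNP a third allele is uninformative
for a two-contributor mixture and most plausibly sequencing error. Thus
``depth_qualified = n_A + n_C + n_G + n_T + n_ambiguous`` always holds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import CountsValidationError, PileupFormatError
from .panel import NUCLEOTIDES, PanelLocus, normalize_chrom, panel_by_position

logger = logging.getLogger(__name__)

COUNTS_COLUMNS = ["locus_id", "n_A", "n_C", "n_G", "n_T", "n_ambiguous"]

#: Phred+33 offset used by samtools pileup quality strings.
PHRED_OFFSET = 33


def phred_to_error_prob(q: float) -> float:
    """Base-call error probability for a Phred quality: ``10**(-q/10)``.

    Q30 corresponds to an error probability of exactly 0.001, the
    theoretical noise floor of the assay at the default quality cutoff.
    """
    return 10.0 ** (-q / 10.0)


@dataclass(frozen=True)
class LocusBaseCounts:
    """Quality-passing base-call counts at one panel locus.

    ``n_ambiguous`` counts calls of N or of a base that is neither panel
    allele. ``absent`` flags a panel locus with no pileup coverage.
    """

    locus_id: str
    n_A: int = 0
    n_C: int = 0
    n_G: int = 0
    n_T: int = 0
    n_ambiguous: int = 0
    absent: bool = False

    def __post_init__(self):
        for name in ("n_A", "n_C", "n_G", "n_T", "n_ambiguous"):
            if getattr(self, name) < 0:
                raise CountsValidationError(f"{self.locus_id}: {name} is negative")

    @property
    def depth_qualified(self) -> int:
        return self.n_A + self.n_C + self.n_G + self.n_T + self.n_ambiguous

    def count(self, base: str) -> int:
        return getattr(self, f"n_{base.upper()}")


def make_counts(
    locus: PanelLocus, base_calls: Mapping[str, int], n_other: int = 0
) -> LocusBaseCounts:
    """Build :class:`LocusBaseCounts` from raw per-base tallies.

    Calls of bases that are not panel alleles at ``locus``, plus
    ``n_other`` (e.g. N calls), are folded into ``n_ambiguous``.
    """
    fields = {"n_A": 0, "n_C": 0, "n_G": 0, "n_T": 0}
    ambiguous = int(n_other)
    for base, n in base_calls.items():
        base = base.upper()
        if base in locus.alleles:
            fields[f"n_{base}"] += int(n)
        else:
            ambiguous += int(n)
    return LocusBaseCounts(locus_id=locus.locus_id, n_ambiguous=ambiguous, **fields)


def _parse_read_bases(bases: str, ref: str, lineno: int) -> list[str]:
    """Expand a pileup read-base string into one symbol per quality char.

    Returns upper-case base calls ('A'..'T', 'N') for quality-consuming
    columns; deletion/skip placeholders ('*', '<', '>') are returned as-is
    so the caller can pair qualities, then drop them. Indel sequences and
    read start/end markup consume no quality and are skipped.
    """
    out: list[str] = []
    ref = ref.upper()
    i, n = 0, len(bases)
    while i < n:
        ch = bases[i]
        if ch == "^":  # read start; next char is mapping quality
            if i + 1 >= n:
                raise PileupFormatError("dangling '^' at end of read bases", lineno)
            i += 2
            continue
        if ch == "$":  # read end marker
            i += 1
            continue
        if ch in "+-":  # indel: [+-]N followed by N sequence chars
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupFormatError(f"indel marker {ch!r} without length", lineno)
            length = int(bases[i + 1 : j])
            i = j + length
            if i > n:
                raise PileupFormatError("indel sequence overruns read bases", lineno)
            continue
        if ch in ".,":
            out.append(ref)
        elif ch.upper() in "ACGTN":
            out.append(ch.upper())
        elif ch in "*<>":
            out.append(ch)
        else:
            raise PileupFormatError(f"unexpected pileup symbol {ch!r}", lineno)
        i += 1
    return out


def count_from_pileup(
    pileup: str | Path,
    panel: Sequence[PanelLocus],
    min_base_quality: int = 30,
) -> list[LocusBaseCounts]:
    """Count quality-passing base calls at each panel locus in a text pileup.

    Bases are counted only when their Phred quality is >= ``min_base_quality``
    (strict >= threshold: a Q29 call at cutoff 30 is excluded from every
    count, including ``depth_qualified``). Pileup markup (indels, read
    start/end, deletion placeholders) never contributes to counts, and
    upper/lower case (strand) is merged. Panel loci absent from the pileup
    are returned with zero counts and ``absent=True``.
    """
    pileup = Path(pileup)
    by_pos = panel_by_position(panel)
    if not by_pos:
        raise CountsValidationError("panel is empty")
    tallies: dict[str, dict[str, int]] = {}

    with open(pileup) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise PileupFormatError(
                    f"expected >=6 tab-separated columns, got {len(fields)}", lineno
                )
            chrom, pos_s, ref, _depth, bases, quals = fields[:6]
            try:
                pos = int(pos_s)
            except ValueError:
                raise PileupFormatError(f"non-integer position {pos_s!r}", lineno) from None
            locus = by_pos.get((normalize_chrom(chrom), pos))
            if locus is None:
                continue
            calls = _parse_read_bases(bases, ref, lineno)
            if len(calls) != len(quals):
                raise PileupFormatError(
                    f"{len(calls)} base calls but {len(quals)} quality characters", lineno
                )
            tally = tallies.setdefault(locus.locus_id, {})
            for call, qch in zip(calls, quals):
                if call in "*<>":  # not base calls
                    continue
                if ord(qch) - PHRED_OFFSET < min_base_quality:
                    continue
                tally[call] = tally.get(call, 0) + 1

    results: list[LocusBaseCounts] = []
    for locus in panel:
        tally = tallies.get(locus.locus_id)
        if tally is None:
            logger.warning("panel locus %s absent from pileup", locus.locus_id)
            results.append(LocusBaseCounts(locus_id=locus.locus_id, absent=True))
            continue
        n_other = tally.pop("N", 0)
        results.append(make_counts(locus, tally, n_other=n_other))
    return results


def load_counts_table(path: str | Path, panel: Sequence[PanelLocus]) -> list[LocusBaseCounts]:
    """Load a counts TSV (columns ``locus_id n_A n_C n_G n_T n_ambiguous``).

    Every row must reference a panel locus; unknown or duplicated
    locus_ids and negative counts raise :class:`CountsValidationError`.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except (OSError, pd.errors.ParserError) as exc:
        raise CountsValidationError(f"cannot read counts table {path}: {exc}") from exc
    missing = [c for c in COUNTS_COLUMNS if c not in df.columns]
    if missing:
        raise CountsValidationError(f"{path}: missing columns {missing}")
    known = {locus.locus_id for locus in panel}
    unknown = sorted(set(df["locus_id"]) - known)
    if unknown:
        raise CountsValidationError(f"{path}: locus_ids not in panel: {unknown}")
    dup = df["locus_id"][df["locus_id"].duplicated()].tolist()
    if dup:
        raise CountsValidationError(f"{path}: duplicated locus_ids: {sorted(set(dup))}")
    numeric = df[COUNTS_COLUMNS[1:]]
    if (numeric < 0).to_numpy().any():
        raise CountsValidationError(f"{path}: negative counts")
    return [
        LocusBaseCounts(
            locus_id=row.locus_id,
            n_A=int(row.n_A),
            n_C=int(row.n_C),
            n_G=int(row.n_G),
            n_T=int(row.n_T),
            n_ambiguous=int(row.n_ambiguous),
        )
        for row in df.itertuples(index=False)
    ]


def write_counts_table(counts: Iterable[LocusBaseCounts], path: str | Path) -> None:
    """Write counts in the fixed TSV column order (bit-exact round trips)."""
    df = pd.DataFrame(
        [
            {
                "locus_id": c.locus_id,
                "n_A": c.n_A,
                "n_C": c.n_C,
                "n_G": c.n_G,
                "n_T": c.n_T,
                "n_ambiguous": c.n_ambiguous,
            }
            for c in counts
        ],
        columns=COUNTS_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
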