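"""Selection of recipient-homozygous loci and their donor-signal fractions.

At a biallelic SNP where the major ("recipient") contributor is
homozygous, every read of the other panel allele comes from the minor
("donor") contributor or from sequencing error. Selection keeps loci that
are (i) autosomal, (ii) adequately covered, (iii) not ambiguity-ridden,
and (iv) called homozygous by a hard threshold: one panel allele must
account for strictly more than 86% of all quality-passing reads. The
per-locus donor signal is then the fraction of panel-allele reads
carrying the non-recipient allele.

The hard 86% call bounds the method's validity: at a no-shared-allele
locus the recipient allele is expected in a fraction ~(1 - x) of reads,
so the call fails in expectation once the donor fraction x reaches
1 - 0.86 = 0.14 — the method applies only below ~14% donor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .counts import LocusBaseCounts
from .exceptions import SelectionError
from .panel import PanelLocus, panel_by_id

logger = logging.getLogger(__name__)

DEFAULT_HOMOZYGOSITY_THRESHOLD = 0.86
DEFAULT_MAX_AMBIGUOUS_FRACTION = 0.05
DEFAULT_MIN_DEPTH = 100

#: Pipeline stages at which a locus can be dropped, in order of application.
DROP_STAGES = ("non_autosomal", "low_depth", "ambiguous", "not_homozygous")


@dataclass(frozen=True)
class SelectedLocus:
    """A recipient-homozygous locus with its per-locus donor signal.

    ``donor_signal_fraction`` is the minor (non-recipient) panel-allele
    fraction over the two panel alleles only; ``depth`` is the
    panel-allele read count it is computed over.
    """

    locus_id: str
    recipient_allele: str
    donor_signal_fraction: float
    depth: int


def _effective_ambiguous(counts: LocusBaseCounts, locus: PanelLocus) -> int:
    """Ambiguous calls including any non-panel per-base counts.

    Counts built by this package keep non-panel bases in ``n_ambiguous``
    already; externally supplied tables may carry them in the per-base
    fields, so both are folded in here.
    """
    other = sum(counts.count(b) for b in "ACGT" if b not in locus.alleles)
    return counts.n_ambiguous + other


def classify_homozygous(
    counts: LocusBaseCounts,
    locus: PanelLocus,
    homozygosity_threshold: float = DEFAULT_HOMOZYGOSITY_THRESHOLD,
) -> str | None:
    """Return the recipient (homozygous) panel allele, or None.

    A locus is homozygous for an allele when that allele's count strictly
    exceeds ``homozygosity_threshold`` times the total quality-passing
    depth. Exactly 86% of reads is *not* homozygous (strict inequality).
    Zero depth returns None with a logged skip.
    """
    depth = counts.depth_qualified
    if depth == 0:
        logger.info("locus %s has zero qualified depth; skipped", counts.locus_id)
        return None
    for allele in (locus.allele_a, locus.allele_b):
        if counts.count(allele) > homozygosity_threshold * depth:
            return allele
    return None


def passes_ambiguity_filter(
    counts: LocusBaseCounts,
    locus: PanelLocus | None = None,
    max_ambiguous_fraction: float = DEFAULT_MAX_AMBIGUOUS_FRACTION,
) -> bool:
    """True iff the ambiguous-call fraction is <= the cutoff.

    The denominator is the full quality-passing depth (ambiguous calls
    included). Exactly 5% ambiguous is retained; strictly more than 5%
    is excluded. Zero depth fails the filter.
    """
    depth = counts.depth_qualified
    if depth == 0:
        return False
    ambiguous = counts.n_ambiguous if locus is None else _effective_ambiguous(counts, locus)
    return ambiguous / depth <= max_ambiguous_fraction


def select_loci(
    all_counts: Sequence[LocusBaseCounts],
    panel: Sequence[PanelLocus],
    homozygosity_threshold: float = DEFAULT_HOMOZYGOSITY_THRESHOLD,
    max_ambiguous_fraction: float = DEFAULT_MAX_AMBIGUOUS_FRACTION,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> tuple[list[SelectedLocus], dict[str, int]]:
    """Apply the full selection cascade and compute donor-signal fractions.

    Returns the selected loci plus a per-stage drop-count report
    (keys: ``input``, the :data:`DROP_STAGES`, and ``selected``).

    Raises
    ------
    SelectionError
        No locus survives selection; the mixture model cannot be fit on
        an empty set.
    """
    by_id = panel_by_id(panel)
    report = {"input": len(all_counts), "selected": 0}
    report.update({stage: 0 for stage in DROP_STAGES})
    selected: list[SelectedLocus] = []
    stages: dict[str, str] = {}

    for counts in all_counts:
        locus = by_id.get(counts.locus_id)
        if locus is None:
            raise SelectionError(f"counts for unknown locus {counts.locus_id!r}")
        if not locus.is_autosomal:
            stage = "non_autosomal"
        elif counts.depth_qualified < min_depth:
            stage = "low_depth"
        elif not passes_ambiguity_filter(counts, locus, max_ambiguous_fraction):
            stage = "ambiguous"
        else:
            recipient = classify_homozygous(counts, locus, homozygosity_threshold)
            if recipient is None:
                stage = "not_homozygous"
            else:
                other = locus.allele_b if recipient == locus.allele_a else locus.allele_a
                n_rec, n_other = counts.count(recipient), counts.count(other)
                depth = n_rec + n_other
                selected.append(
                    SelectedLocus(
                        locus_id=counts.locus_id,
                        recipient_allele=recipient,
                        donor_signal_fraction=n_other / depth,
                        depth=depth,
                    )
                )
                stages[counts.locus_id] = "selected"
                report["selected"] += 1
                continue
        if counts.depth_qualified < min_depth and stage == "low_depth":
            logger.warning(
                "locus %s dropped: depth %d < %d", counts.locus_id, counts.depth_qualified, min_depth
            )
        stages[counts.locus_id] = stage
        report[stage] += 1

    if not selected:
        raise SelectionError(
            "no locus survived selection (autosomal, depth, ambiguity, homozygosity); "
            f"drop counts: { {k: report[k] for k in DROP_STAGES} }. "
            "Check coverage and the homozygosity threshold, or supply more loci."
        )
    return selected, report


def write_selection_report(
    all_counts: Sequence[LocusBaseCounts],
    panel: Sequence[PanelLocus],
    selected: Iterable[SelectedLocus],
    report_path: str | Path,
    homozygosity_threshold: float = DEFAULT_HOMOZYGOSITY_THRESHOLD,
    max_ambiguous_fraction: float = DEFAULT_MAX_AMBIGUOUS_FRACTION,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> pd.DataFrame:
    """Write the per-locus selection report TSV and return it as a frame."""
    by_id = panel_by_id(panel)
    sel_by_id = {s.locus_id: s for s in selected}
    rows = []
    for counts in all_counts:
        locus = by_id[counts.locus_id]
        sel = sel_by_id.get(counts.locus_id)
        if sel is not None:
            stage = "selected"
        elif not locus.is_autosomal:
            stage = "non_autosomal"
        elif counts.depth_qualified < min_depth:
            stage = "low_depth"
        elif not passes_ambiguity_filter(counts, locus, max_ambiguous_fraction):
            stage = "ambiguous"
        else:
            stage = "not_homozygous"
        rows.append(
            {
                "locus_id": counts.locus_id,
                "stage": stage,
                "recipient_allele": sel.recipient_allele if sel else ".",
                "donor_signal_fraction": f"{sel.donor_signal_fraction:.6g}" if sel else ".",
                "depth": sel.depth if sel else counts.depth_qualified,
            }
        )
    df = pd.DataFrame(rows, columns=["locus_id", "stage", "recipient_allele", "donor_signal_fraction", "depth"])
    df.to_csv(report_path, sep="\t", index=False)
    return df
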