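"""Negative-control (blank) contaminant removal and before/after accounting.

The removal rule is deliberately blunt: any OTU observed in *any* blank
sample is treated as a contaminant and removed from every sample.  It
operates on raw counts; percent-abundance normalisation happens after
removal.  The report mirrors the classic before/after accounting table:
sequences and OTUs per sample before and after removal, plus
dataset-level totals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Metadata, OtuTable

logger = logging.getLogger("blankgate")

__all__ = [
    "blank_otu_set", "remove_contaminants", "to_percent_abundance",
    "DecontamReport", "decontam_report",
]


def blank_otu_set(table: OtuTable, metadata: Metadata, min_count: int = 1) -> frozenset:
    """OTUs observed (count >= min_count) in at least one blank sample.

    ``min_count`` defaults to 1 — a single read in a blank marks the OTU
    as a contaminant; raise it to tolerate index-hopping-level noise.
    """
    if table.unit != "counts":
        raise ValueError("blank_otu_set requires a counts-unit table")
    blanks = [b for b in metadata.blank_ids if b in table.data.index]
    if not blanks:
        raise ValueError("no blank samples in the OTU table; the removal rule "
                         "requires submitted blanks")
    sub = table.data.loc[blanks]
    hit = (sub >= min_count).any(axis=0)
    return frozenset(sub.columns[hit])


def remove_contaminants(table: OtuTable, metadata: Metadata,
                        min_count: int = 1, drop_empty_otus: bool = False) -> OtuTable:
    """Drop blank samples and every blank-observed OTU from the table.

    Values of surviving cells are untouched.  OTU columns that end up
    all-zero across the remaining samples are retained (so OTU ids stay
    stable) unless ``drop_empty_otus``; they are logged either way, as
    are samples left with zero reads.
    """
    contaminants = blank_otu_set(table, metadata, min_count=min_count)
    keep_samples = [s for s in table.sample_ids
                    if not (s in metadata and metadata.is_blank(s))]
    keep_otus = [o for o in table.otu_ids if o not in contaminants]
    cleaned = table.data.loc[keep_samples, keep_otus]

    empty_otus = [o for o in keep_otus if cleaned[o].sum() == 0]
    if empty_otus:
        logger.info("remove_contaminants: %d surviving OTU column(s) are all-zero "
                    "across remaining samples", len(empty_otus))
        if drop_empty_otus:
            cleaned = cleaned.drop(columns=empty_otus)
    zero_samples = list(cleaned.index[cleaned.sum(axis=1) == 0])
    if zero_samples:
        warnings.warn(
            f"{len(zero_samples)} sample(s) retain zero reads after contaminant "
            f"removal: {', '.join(map(str, zero_samples))}", stacklevel=2)
    return OtuTable(cleaned, unit=table.unit)


def to_percent_abundance(table: OtuTable) -> OtuTable:
    """Scale each sample's counts so they sum to 100 (percent abundance)."""
    if table.unit == "percent":
        return table
    values = table.values()
    sums = values.sum(axis=1)
    if (sums == 0).any():
        sid = table.data.index[int(np.argmax(sums == 0))]
        raise ValueError(f"sample {sid!r} has zero total reads; cannot normalise")
    frame = pd.DataFrame(100.0 * values / sums[:, None],
                         index=table.data.index, columns=table.data.columns)
    return OtuTable(frame, unit="percent")


@dataclass
class DecontamReport:
    """Before/after accounting of contaminant removal.

    ``per_sample`` has, for every retained sample: sequences_before,
    sequences_after, otus_before, otus_after and the removed fractions
    1 - after/before (0 when before is 0).  ``totals`` carries
    dataset-level distinct-OTU counts and per-sample sequence extremes.
    """

    per_sample: pd.DataFrame
    totals: dict = field(default_factory=dict)


def _distinct_observed(table: OtuTable) -> int:
    return int((table.values().sum(axis=0) > 0).sum())


def decontam_report(before: OtuTable, after: OtuTable) -> DecontamReport:
    missing = [s for s in after.sample_ids if s not in before.data.index]
    if missing:
        raise ValueError(f"samples in 'after' but not 'before': {missing}")
    rows = []
    for sid in after.sample_ids:
        b = before.sample_row(sid)
        a = after.sample_row(sid)
        seq_b, seq_a = float(b.sum()), float(a.sum())
        otu_b, otu_a = int((b > 0).sum()), int((a > 0).sum())
        rows.append({
            "sample_id": sid,
            "sequences_before": seq_b, "sequences_after": seq_a,
            "otus_before": otu_b, "otus_after": otu_a,
            "contaminant_fraction_sequences": 0.0 if seq_b == 0 else 1.0 - seq_a / seq_b,
            "contaminant_fraction_otus": 0.0 if otu_b == 0 else 1.0 - otu_a / otu_b,
        })
    per_sample = pd.DataFrame(rows).set_index("sample_id")
    seqs_b = per_sample["sequences_before"]
    seqs_a = per_sample["sequences_after"]
    totals = {
        "distinct_otus_before": _distinct_observed(before),
        "distinct_otus_after": _distinct_observed(after),
        "min_sequences_before": float(seqs_b.min()),
        "max_sequences_before": float(seqs_b.max()),
        "min_sequences_after": float(seqs_a.min()),
        "max_sequences_after": float(seqs_a.max()),
        "n_samples": len(per_sample),
    }
    return DecontamReport(per_sample=per_sample, totals=totals)
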