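"""Group-level ASV detection and dataset filtering.

An ASV is *detected* in a sample group (one stage x DNA-type combination,
three replicate logs by default) when it is present in at least
``min_samples`` of the group's samples **and** its summed reads across the
group reach ``min_reads``.  The read floor is applied to the group sum,
not per sample: the rule is paired with a prevalence clause, which a
per-sample floor would render redundant at small counts.

Filtering retains every ASV detected in at least one group.  Counts of
retained ASVs are left untouched — detection is a separate boolean layer,
so an ASV can carry (sub-threshold) reads in groups outside its detected
set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_tables import AsvCountTable, SampleMetadata, logger, validate_inputs

DEFAULT_MIN_SAMPLES = 2
DEFAULT_MIN_READS = 5


@dataclass
class DetectionMatrix:
    """Boolean ASV x sample-group matrix under the detection rule."""

    detected: pd.DataFrame  # index asv_id, columns group_id, dtype bool

    @property
    def asv_ids(self) -> list[str]:
        return list(self.detected.index)

    @property
    def group_ids(self) -> list[str]:
        return list(self.detected.columns)

    def n_groups_detected(self) -> pd.Series:
        """Row sums: in how many of the groups each ASV is detected."""
        return self.detected.sum(axis=1)


def detect_in_group(
    counts_for_group,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    min_reads: int = DEFAULT_MIN_READS,
) -> bool:
    """Apply the two-clause detection rule to one ASV's counts in one group."""
    c = np.asarray(counts_for_group)
    return bool((c > 0).sum() >= min_samples and c.sum() >= min_reads)


def detection_matrix(
    table: AsvCountTable,
    meta: SampleMetadata,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    min_reads: int = DEFAULT_MIN_READS,
) -> DetectionMatrix:
    """Vectorised detection over all ASVs and groups."""
    cols = {}
    for gid, samples in meta.groups.items():
        sub = table.counts[samples]
        cols[gid] = ((sub > 0).sum(axis=1) >= min_samples) & (
            sub.sum(axis=1) >= min_reads
        )
    det = pd.DataFrame(cols, index=table.counts.index)
    det.columns.name = "group_id"
    return DetectionMatrix(det[meta.group_ids])


def filter_table(
    table: AsvCountTable,
    meta: SampleMetadata,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    min_reads: int = DEFAULT_MIN_READS,
) -> tuple[AsvCountTable, DetectionMatrix]:
    """Drop ASVs not detected in any group; keep counts of the rest intact.

    Returns the filtered table and the detection matrix restricted to the
    retained ASVs (all groups kept as columns).
    """
    validate_inputs(table, meta)
    det = detection_matrix(table, meta, min_samples=min_samples, min_reads=min_reads)
    keep = det.detected.any(axis=1)
    if not keep.any():
        logger.warning("filter removed every ASV (min_samples=%d, min_reads=%d)",
                       min_samples, min_reads)
    kept_ids = det.detected.index[keep]
    filtered = AsvCountTable(table.counts.loc[kept_ids])
    return filtered, DetectionMatrix(det.detected.loc[kept_ids])
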