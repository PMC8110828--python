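"""Extracellular-DNA persistence ("masking") detection across decay stages.

Decay stages cannot be followed through time on one log, so persistence is
inferred cross-sectionally: candidate ASVs are those detected in exactly
one adjacent pair of stages (earlier, later).  For each candidate, three
flags are computed from median per-sample read proportions and the
detection matrix:

``flag_intra_decline``
    the intracellular relative abundance is strictly lower in the later
    stage than in the earlier one (ties are not a decline);
``flag_intra_extinct_extra_present``
    the ASV is no longer detected in the later stage's intracellular group
    while still detected in its extracellular group — the signature of
    relic DNA outliving the population;
``flag_extra_exceeds_intra``
    in the later stage the extracellular relative abundance exceeds the
    intracellular one.

Relative abundance is the per-sample proportion over retained ASVs,
summarised as the median across the group's replicates (a pooled-group
mean is available via ``agg="mean"``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .filtering import DetectionMatrix
from .io_tables import AsvCountTable, SampleMetadata, group_id
from .set_analysis import VennAssignment


@dataclass
class PersistenceReport:
    """One row per candidate (ASV, earlier stage, later stage)."""

    report: pd.DataFrame

    def __len__(self) -> int:
        return len(self.report)


def candidate_asvs(
    venn: VennAssignment,
    stage_order,
    all_pairs: bool = False,
) -> list[tuple[str, str, str]]:
    """ASVs whose stage set is exactly one pair of stages.

    By default only adjacent pairs qualify (the conservative choice that
    keeps earlier/later unambiguous); ``all_pairs=True`` admits any
    two-stage set, ordered by ``stage_order``.
    """
    order = list(stage_order)
    pos = {s: i for i, s in enumerate(order)}
    out = []
    for asv, sset in venn.stage_set.items():
        if len(sset) != 2:
            continue
        a, b = sorted(sset, key=pos.get)
        if all_pairs or pos[b] - pos[a] == 1:
            out.append((asv, a, b))
    return out


def relative_abundance(
    table: AsvCountTable,
    meta: SampleMetadata,
    asv: str,
    gid: str,
    agg: str = "median",
) -> float:
    """Summary per-sample read proportion of one ASV in one sample group."""
    samples = meta.samples_of_group(gid)
    if not samples:
        raise ValueError(f"group {gid!r} has no samples")
    sub = table.counts[samples]
    props = sub.loc[asv] / sub.sum(axis=0)
    return float(props.median() if agg == "median" else props.mean())


def assess_persistence(
    candidates,
    table: AsvCountTable,
    det: DetectionMatrix,
    meta: SampleMetadata,
    agg: str = "median",
) -> PersistenceReport:
    """Compute the three persistence flags for every candidate.

    ``overall_rank`` is the ASV's position (1 = most reads) in the ranking
    of all retained ASVs by total reads across all samples; the report is
    sorted by it.
    """
    totals = table.asv_totals()
    rank = totals.rank(ascending=False, method="min").astype(int)
    rows = []
    for asv, earlier, later in candidates:
        ra = {
            key: relative_abundance(table, meta, asv, gid, agg=agg)
            for key, gid in {
                "rel_intra_earlier": group_id(earlier, "intra"),
                "rel_intra_later": group_id(later, "intra"),
                "rel_extra_later": group_id(later, "extra"),
            }.items()
        }
        det_intra_later = bool(det.detected.loc[asv, group_id(later, "intra")])
        det_extra_later = bool(det.detected.loc[asv, group_id(later, "extra")])
        rows.append(
            {
                "asv_id": asv,
                "earlier_stage": earlier,
                "later_stage": later,
                **ra,
                "flag_intra_decline": ra["rel_intra_later"] < ra["rel_intra_earlier"],
                "flag_intra_extinct_extra_present": (
                    not det_intra_later
                ) and det_extra_later,
                "flag_extra_exceeds_intra": ra["rel_extra_later"] > ra["rel_intra_later"],
                "overall_rank": int(rank[asv]),
            }
        )
    cols = [
        "asv_id", "earlier_stage", "later_stage",
        "rel_intra_earlier", "rel_intra_later", "rel_extra_later",
        "flag_intra_decline", "flag_intra_extinct_extra_present",
        "flag_extra_exceeds_intra", "overall_rank",
    ]
    df = pd.DataFrame(rows, columns=cols)
    df = df.sort_values(["overall_rank", "asv_id"]).set_index("asv_id")
    return PersistenceReport(df)


def masking_summary(
    report: PersistenceReport, det: DetectionMatrix, meta: SampleMetadata
) -> pd.DataFrame:
    """Headline counts plus per-stage richness inflation of the total pool.

    Richness inflation is the number of ASVs detected in a stage's total
    group minus those detected in its intracellular group — the net
    over-reporting attributable to extracellular carryover.
    """
    r = report.report
    rows = [
        ("n_candidates", len(r)),
        ("n_intra_decline", int(r["flag_intra_decline"].sum())),
        ("n_intra_extinct_extra_present",
         int(r["flag_intra_extinct_extra_present"].sum())),
        ("n_extra_exceeds_intra", int(r["flag_extra_exceeds_intra"].sum())),
    ]
    for stage in meta.stages:
        n_total = int(det.detected[group_id(stage, "total")].sum())
        n_intra = int(det.detected[group_id(stage, "intra")].sum())
        rows.append((f"richness_inflation_{stage}", n_total - n_intra))
    return pd.DataFrame(rows, columns=["quantity", "value"]).set_index("quantity")
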