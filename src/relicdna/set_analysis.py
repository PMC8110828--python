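"""Set algebra over detection patterns: stage Venn regions, DNA-type
labels, occurrence distributions and taxon-class frequency comparisons.

Stage-level detection is derived from group-level detection: an ASV is
considered present in a decay stage when it is detected in at least one of
that stage's DNA-type groups.  Within one stage, the three DNA-type groups
give eight boolean patterns which map onto seven Venn labels (plus
``absent``):

====== ====== ====== =========
intra  extra  total  label
====== ====== ====== =========
1      0      0      intra
0      1      0      extra
0      0      1      total
1      1      0      in/ex
1      0      1      in/tot
0      1      1      tot/ex
1      1      1      core
0      0      0      absent
====== ====== ====== =========
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .filtering import DetectionMatrix
from .io_tables import (
    DNA_TYPES,
    AsvCountTable,
    SampleMetadata,
    TaxonomyTable,
    group_id,
)

DNATYPE_LABELS = {
    (1, 0, 0): "intra",
    (0, 1, 0): "extra",
    (0, 0, 1): "total",
    (1, 1, 0): "in/ex",
    (1, 0, 1): "in/tot",
    (0, 1, 1): "tot/ex",
    (1, 1, 1): "core",
    (0, 0, 0): "absent",
}

# k = 2 co-occurrence categories (pairs of sample groups)
PAIR_CLASSES = (
    "intra+extra same stage",
    "total+extra same stage",
    "total+intra same stage",
    "cross-stage",
)


def _stage_detection(det: DetectionMatrix, stages) -> pd.DataFrame:
    """ASV x stage boolean: detected in >=1 DNA-type group of the stage."""
    cols = {}
    for s in stages:
        gids = [group_id(s, t) for t in DNA_TYPES if group_id(s, t) in det.detected.columns]
        cols[s] = det.detected[gids].any(axis=1)
    return pd.DataFrame(cols, index=det.detected.index)


def stage_sets(det: DetectionMatrix, meta: SampleMetadata) -> tuple[pd.Series, Counter]:
    """Per-ASV stage membership set and Venn region counts.

    Returns a Series of frozensets (empty for ASVs detected nowhere) and a
    Counter over the non-empty regions; region counts sum to the number of
    ASVs with a non-empty stage set.
    """
    sd = _stage_detection(det, meta.stages)
    sets = sd.apply(lambda row: frozenset(sd.columns[row.values]), axis=1)
    regions = Counter(s for s in sets if s)
    return sets, regions


def dnatype_label(det: DetectionMatrix, stage: str) -> pd.Series:
    """Per-ASV Venn label among the stage's three DNA-type groups."""
    gids = [group_id(stage, t) for t in DNA_TYPES]
    missing = [g for g in gids if g not in det.detected.columns]
    if missing:
        raise ValueError(f"stage {stage!r} lacks groups {missing}")
    patt = det.detected[gids].astype(int)
    return patt.apply(lambda row: DNATYPE_LABELS[tuple(row)], axis=1)


@dataclass
class VennAssignment:
    """Combined per-ASV set assignment across stages and DNA types."""

    stage_set: pd.Series  # asv -> frozenset of stages
    stage_regions: Counter  # region -> ASV count
    dnatype_labels: pd.DataFrame  # asv x stage -> label
    n_groups_detected: pd.Series
    total_reads: pd.Series

    def to_frame(self) -> pd.DataFrame:
        df = self.dnatype_labels.copy()
        df.columns = [f"label_{s}" for s in df.columns]
        df["stage_set"] = self.stage_set.map(
            lambda s: "+".join(sorted(s)) if s else ""
        )
        df["n_groups_detected"] = self.n_groups_detected
        df["total_reads"] = self.total_reads
        return df


def venn_assignment(
    det: DetectionMatrix, table: AsvCountTable, meta: SampleMetadata
) -> VennAssignment:
    sets, regions = stage_sets(det, meta)
    labels = pd.DataFrame(
        {s: dnatype_label(det, s) for s in meta.stages}, index=det.detected.index
    )
    return VennAssignment(
        stage_set=sets,
        stage_regions=regions,
        dnatype_labels=labels,
        n_groups_detected=det.n_groups_detected(),
        total_reads=table.asv_totals().reindex(det.detected.index),
    )


def group_occurrence_distribution(
    det: DetectionMatrix, table: AsvCountTable | None = None
) -> pd.DataFrame:
    """Histogram of the number of sample groups each ASV is detected in.

    Rows are k = 1..n_groups; ``n_asvs`` counts ASVs detected in exactly k
    groups, and, when a count table is supplied, ``read_proportion`` sums
    those ASVs' shares of the grand read total.
    """
    k = det.n_groups_detected()
    n_groups = det.detected.shape[1]
    idx = pd.RangeIndex(1, n_groups + 1, name="n_groups")
    hist = k[k > 0].value_counts().reindex(idx, fill_value=0).rename("n_asvs")
    out = hist.to_frame()
    if table is not None:
        totals = table.asv_totals().reindex(det.detected.index)
        share = totals / totals.sum()
        out["read_proportion"] = (
            share.groupby(k).sum().reindex(idx, fill_value=0.0)
        )
    return out


def pairwise_cooccurrence_breakdown(
    det: DetectionMatrix, meta: SampleMetadata
) -> dict[str, Counter]:
    """Classify ASVs detected in exactly two or exactly three groups.

    k = 2: whether the pair of groups is the intra+extra, total+extra or
    total+intra combination of a single stage, or spans stages.  k = 3:
    whether the triple is all three DNA types of one stage.
    """
    k = det.n_groups_detected()
    parse = {g: g.split(":") for g in det.detected.columns}
    out2: Counter = Counter({c: 0 for c in PAIR_CLASSES})
    out3: Counter = Counter({"all DNA types one stage": 0, "other": 0})
    for asv in det.detected.index[k == 2]:
        g1, g2 = det.detected.columns[det.detected.loc[asv].values]
        (s1, t1), (s2, t2) = parse[g1], parse[g2]
        if s1 != s2:
            out2["cross-stage"] += 1
        elif {t1, t2} == {"intra", "extra"}:
            out2["intra+extra same stage"] += 1
        elif {t1, t2} == {"total", "extra"}:
            out2["total+extra same stage"] += 1
        else:
            out2["total+intra same stage"] += 1
    for asv in det.detected.index[k == 3]:
        gids = det.detected.columns[det.detected.loc[asv].values]
        stages = {parse[g][0] for g in gids}
        types = {parse[g][1] for g in gids}
        if len(stages) == 1 and types == set(DNA_TYPES):
            out3["all DNA types one stage"] += 1
        else:
            out3["other"] += 1
    return {"k2": out2, "k3": out3}


@dataclass
class ClassFrequencyTable:
    """Per taxon-class detected-ASV counts, DNA-type fold changes and tests."""

    frequencies: pd.DataFrame  # class x group -> detected-ASV count
    comparisons: pd.DataFrame  # per (stage, class): folds, p, flags


def class_frequencies(
    det: DetectionMatrix,
    taxonomy: TaxonomyTable,
    meta: SampleMetadata,
    table: AsvCountTable,
    rank: str = "class",
    fold_intra: float = 1.5,
    fold_extra: float = 2.0,
    alpha: float = 0.05,
) -> ClassFrequencyTable:
    """Compare taxon-class richness among DNA types within each stage.

    For every (class, group) the number of detected ASVs annotated to the
    class is tallied; unknown annotations form an explicit ``unclassified``
    class so columns sum to the per-group detected totals.  Per stage and
    class, fold changes intra/total and extra/total are computed from these
    group counts, and a Kruskal-Wallis test across the three DNA types is
    run on per-sample class richness (number of the class's ASVs with >0
    reads in the sample).  A class is flagged enriched when its fold change
    reaches the threshold and p < alpha; folds with a zero denominator are
    reported as NaN, never as a division error.
    """
    tax = taxonomy.completed_for(det.asv_ids)
    classes = tax.rank(rank).replace("unknown", "unclassified")

    freq = (
        det.detected.groupby(classes).sum().astype(int).rename_axis(rank)
    )
    freq = freq[det.group_ids]

    rows = []
    counts = table.counts.reindex(det.asv_ids)
    class_groups = {c: counts.index[classes.values == c] for c in freq.index}
    for stage in meta.stages:
        gid_of = {t: group_id(stage, t) for t in DNA_TYPES}
        for cls in freq.index:
            n = {t: int(freq.loc[cls, gid_of[t]]) for t in DNA_TYPES}
            f_in = n["intra"] / n["total"] if n["total"] else np.nan
            f_ex = n["extra"] / n["total"] if n["total"] else np.nan
            # per-sample richness of this class, by DNA type
            member = counts.loc[class_groups[cls]]
            rich = {
                t: (member[meta.samples_of_group(gid_of[t])] > 0).sum(axis=0).values
                for t in DNA_TYPES
            }
            groups = list(rich.values())
            if np.ptp(np.concatenate(groups)) == 0:
                p = 1.0  # identical richness everywhere: no evidence
            else:
                p = float(stats.kruskal(*groups).pvalue)
            rows.append(
                {
                    "stage": stage,
                    rank: cls,
                    "n_intra": n["intra"],
                    "n_extra": n["extra"],
                    "n_total": n["total"],
                    "fold_intra_vs_total": f_in,
                    "fold_extra_vs_total": f_ex,
                    "p_kruskal": p,
                    "flag_intra_enriched": bool(
                        f_in >= fold_intra and p < alpha
                    ) if not np.isnan(f_in) else False,
                    "flag_extra_enriched": bool(
                        f_ex >= fold_extra and p < alpha
                    ) if not np.isnan(f_ex) else False,
                }
            )
    comparisons = pd.DataFrame(rows).set_index(["stage", rank])
    return ClassFrequencyTable(frequencies=freq, comparisons=comparisons)
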