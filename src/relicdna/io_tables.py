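"""Tabular input/output and validation.

The pipeline works on three tab-separated tables:

``counts.tsv``
    ASV x sample matrix of non-negative integer read counts; first column
    holds ASV identifiers, the header row holds sample identifiers.
``metadata.tsv``
    One row per sample with columns ``sample_id``, ``log_id`` (biological
    replicate, i.e. the deadwood log), ``stage`` (ordinal decay class) and
    ``dna_type`` (``intra``, ``extra`` or ``total``).
``taxonomy.tsv``
    One row per ASV with the six ranked lineage columns
    domain..genus; any rank may be ``unknown``.

All writers emit UTF-8 TSV with ``.`` as decimal separator so fixtures are
diff-able and round-trips are bit-exact on integers and labels.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("relicdna")
if not logger.handlers:  # default: level-tagged lines to stderr
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)

DNA_TYPES = ("intra", "extra", "total")
DEFAULT_STAGE_ORDER = ("I", "III", "V")
TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus")


class FormatError(ValueError):
    """A file does not conform to the expected tabular format."""


class ValidationError(ValueError):
    """Inputs are well-formed but violate a pipeline invariant."""


class ParameterError(ValueError):
    """A numeric parameter is outside its admissible range."""


def group_id(stage: str, dna_type: str) -> str:
    """Canonical sample-group identifier for a (stage, DNA type) pair."""
    return f"{stage}:{dna_type}"


@dataclass
class SampleMetadata:
    """Sample annotations defining the stage x DNA-type design.

    ``table`` is indexed by sample_id with columns ``log_id``, ``stage``,
    ``dna_type`` and the derived ``group_id``.  ``stage_order`` carries the
    total order of decay stages; it is configuration, never inferred from
    the labels, so non-Roman staging schemes work unchanged.
    """

    table: pd.DataFrame
    stage_order: tuple[str, ...] = DEFAULT_STAGE_ORDER

    def __post_init__(self) -> None:
        required = {"log_id", "stage", "dna_type"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"metadata missing columns: {sorted(missing)}")
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValidationError(f"duplicate sample_id {dup!r}")
        self.stage_order = tuple(str(s) for s in self.stage_order)
        bad_stage = set(self.table["stage"].astype(str)) - set(self.stage_order)
        if bad_stage:
            raise ValidationError(
                f"stage labels {sorted(bad_stage)} not in configured order "
                f"{list(self.stage_order)}"
            )
        bad_type = set(self.table["dna_type"]) - set(DNA_TYPES)
        if bad_type:
            raise ValidationError(
                f"unknown dna_type {sorted(bad_type)}; expected one of {list(DNA_TYPES)}"
            )
        self.table = self.table.copy()
        self.table["group_id"] = [
            group_id(s, t)
            for s, t in zip(self.table["stage"].astype(str), self.table["dna_type"])
        ]
        sizes = self.table.groupby("group_id").size()
        small = sizes[sizes < 2]
        if len(small):
            raise ValidationError(
                "each sample group needs >=2 samples (detection rule is undefined "
                f"otherwise); offending groups: {dict(small)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def stages(self) -> tuple[str, ...]:
        present = set(self.table["stage"].astype(str))
        return tuple(s for s in self.stage_order if s in present)

    @property
    def group_ids(self) -> list[str]:
        """Groups in stage-major, DNA-type-minor canonical order."""
        present = set(self.table["group_id"])
        return [
            group_id(s, t)
            for s in self.stages
            for t in DNA_TYPES
            if group_id(s, t) in present
        ]

    def samples_of_group(self, gid: str) -> list[str]:
        return list(self.table.index[self.table["group_id"] == gid])

    @property
    def groups(self) -> dict[str, list[str]]:
        return {g: self.samples_of_group(g) for g in self.group_ids}


@dataclass
class AsvCountTable:
    """ASV x sample matrix of sequencing read counts.

    ``counts`` is a pandas DataFrame indexed by ASV id with sample-id
    columns; cells are non-negative integers.  Input row and column order
    are preserved.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate ASV id {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        arr = self.counts.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.integer):
                # permit float input only if every cell is integral
                frac = arr != np.floor(arr)
                if frac.any():
                    i, j = map(int, next(zip(*frac.nonzero())))
                    raise FormatError(
                        f"non-integer count {arr[i, j]!r} at ASV "
                        f"{self.counts.index[i]!r}, sample {self.counts.columns[j]!r}"
                    )
                self.counts = self.counts.astype("int64")
                arr = self.counts.to_numpy()
            if (arr < 0).any():
                i, j = map(int, next(zip(*(arr < 0).nonzero())))
                raise FormatError(
                    f"negative count at ASV {self.counts.index[i]!r}, "
                    f"sample {self.counts.columns[j]!r}"
                )

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[0]

    def sample_depths(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def asv_totals(self) -> pd.Series:
        """Total reads per ASV across all samples ('ASV size')."""
        return self.counts.sum(axis=1)


@dataclass
class TaxonomyTable:
    """ASV -> ranked lineage (domain..genus); unknown ranks are 'unknown'."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(TAXONOMY_RANKS) - set(self.table.columns)
        if missing:
            raise FormatError(f"taxonomy missing rank columns: {sorted(missing)}")
        if self.table.index.duplicated().any():
            raise FormatError("duplicate ASV id in taxonomy")
        self.table = self.table[list(TAXONOMY_RANKS)].astype(str)

    def completed_for(self, asv_ids) -> "TaxonomyTable":
        """Return a taxonomy covering ``asv_ids``; absent ASVs are auto-filled
        as all-'unknown' with a warning (set analysis must not drop ASVs)."""
        missing = [a for a in asv_ids if a not in self.table.index]
        if not missing:
            return TaxonomyTable(self.table.loc[list(asv_ids)])
        logger.warning(
            "%d ASV(s) missing from taxonomy; filled as 'unknown'", len(missing)
        )
        fill = pd.DataFrame(
            "unknown", index=pd.Index(missing, name=self.table.index.name),
            columns=list(TAXONOMY_RANKS),
        )
        full = pd.concat([self.table, fill])
        return TaxonomyTable(full.loc[list(asv_ids)])

    def rank(self, rank: str) -> pd.Series:
        if rank not in TAXONOMY_RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        return self.table[rank]


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected tab-separated columns")
    return df


def read_count_table(path) -> AsvCountTable:
    """Read an ASV x sample TSV; first column ASV id, header row sample ids."""
    df = _read_tsv(path)
    df = df.set_index(df.columns[0])
    df.index.name = "asv_id"
    for col in df.columns:
        for asv, val in df[col].items():
            if not val.lstrip("-").isdigit():
                raise FormatError(
                    f"{path}: non-integer cell {val!r} at ASV {asv!r}, "
                    f"sample {col!r}"
                )
    return AsvCountTable(df.astype("int64"))


def read_metadata(path, stage_order=DEFAULT_STAGE_ORDER) -> SampleMetadata:
    df = _read_tsv(path)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing 'sample_id' column")
    return SampleMetadata(df.set_index("sample_id"), stage_order=tuple(stage_order))


def read_taxonomy(path) -> TaxonomyTable:
    df = _read_tsv(path)
    first = df.columns[0]
    return TaxonomyTable(df.set_index(first).rename_axis("asv_id"))


def write_table(result, path) -> None:
    """Write any tabular result as TSV so that re-reading returns the same
    values (exact on integers/labels, 12 decimal places on floats)."""
    df = result if isinstance(result, pd.DataFrame) else _as_frame(result)
    df.to_csv(path, sep="\t", float_format="%.12g")


def _as_frame(result) -> pd.DataFrame:
    for attr in ("counts", "table", "detected", "report"):
        obj = getattr(result, attr, None)
        if isinstance(obj, pd.DataFrame):
            return obj
    raise TypeError(f"cannot serialise {type(result).__name__} as a table")


def validate_inputs(table: AsvCountTable, meta: SampleMetadata) -> None:
    """Cross-check counts against metadata: identical sample sets, and every
    retained sample carries at least one read."""
    c, m = set(table.sample_ids), set(meta.sample_ids)
    if c - m:
        raise ValidationError(f"samples in counts but not metadata: {sorted(c - m)}")
    if m - c:
        raise ValidationError(f"samples in metadata but not counts: {sorted(m - c)}")
    depths = table.sample_depths()
    empty = depths[depths == 0]
    if len(empty):
        raise ValidationError(f"samples with zero total reads: {list(empty.index)}")
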