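"""Synthetic multi-fraction amplicon communities with known ground truth.

The generator emulates bacterial succession across ordered deadwood decay
stages, observed through three DNA fractions per sample:

* **intra** — the living community of the stage: per-ASV log-abundances
  follow a stage-to-stage AR(1) walk (correlation ``rho``) with absorbing
  extinction at rate ``tau``; each extinction is balanced by the arrival of
  a fresh colonising ASV so expected richness stays stable.
* **extra** — the extracellular (relic) DNA pool: a geometrically decaying
  superposition of all past intracellular communities with per-stage
  retention factor ``lam``; ``lam = 0`` reduces to the current community.
* **total** — a convex mixture of the two, with extracellular share ``mu``
  (default 0.5: the two fractions contribute comparable amounts of DNA).

Read counts are drawn Dirichlet-multinomial per sample: replicate-level
compositions come from a Dirichlet with concentration ``theta *
proportions`` (structural zeros are never resampled), then counts are
multinomial at a per-sample depth drawn uniformly from ``depth_range``.

Extinctions whose expected extracellular signal clears the pipeline's
5-read detection floor are recorded as *planted persistence events* — the
ground truth against which persistence detection is scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_tables import (
    DEFAULT_STAGE_ORDER,
    DNA_TYPES,
    TAXONOMY_RANKS,
    AsvCountTable,
    ParameterError,
    SampleMetadata,
    TaxonomyTable,
    write_table,
)


class GenerationError(RuntimeError):
    """The stochastic process reached a degenerate state."""


#: small pool of lineages typical of decaying-wood bacteriomes, used for
#: random taxonomy assignment (class is the rank the frequency analysis uses)
DEFAULT_TAXONOMY_POOL: tuple[tuple[str, ...], ...] = (
    ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Acetobacterales", "Acetobacteraceae", "Acidisoma"),
    ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Acetobacterales", "Acetobacteraceae", "Acidisphaera"),
    ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Rhizobiales", "Beijerinckiaceae", "Methylorosula"),
    ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Rhizobiales", "Beijerinckiaceae", "Roseiarcus"),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Burkholderiales", "Burkholderiaceae", "Burkholderia"),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Burkholderiales", "Burkholderiaceae", "Rhizobacter"),
    ("Bacteria", "Acidobacteriota", "Acidobacteriae", "Acidobacteriales", "Acidobacteriaceae", "Granulicella"),
    ("Bacteria", "Actinobacteriota", "Actinobacteria", "Mycobacteriales", "Mycobacteriaceae", "Mycobacterium"),
    ("Bacteria", "Bacteroidota", "Bacteroidia", "Chitinophagales", "Chitinophagaceae", "unknown"),
    ("Bacteria", "Verrucomicrobiota", "Verrucomicrobiae", "Opitutales", "Opitutaceae", "Opitutus"),
    ("Bacteria", "Desulfobacterota", "Desulfobulbia", "Desulfobulbales", "Desulfobulbaceae", "unknown"),
    ("Bacteria", "unknown", "unknown", "unknown", "unknown", "unknown"),
)


@dataclass
class GeneratorConfig:
    """Tunable parameters of the synthetic community generator.

    Defaults reflect a 3-stage x 3-DNA-type x 3-replicate design with
    per-sample depths in the 4,608-11,715 read range and an equal split of
    intra- and extracellular DNA in the total pool.
    """

    n_asvs: int = 300
    n_stages: int = 3
    n_logs: int = 3
    depth_range: tuple[int, int] = (4608, 11715)
    succession_rho: float = 0.5
    turnover_tau: float = 0.3
    retention_lambda: float = 0.5
    mix_mu: float = 0.5
    overdispersion_theta: float = 50.0
    taxonomy_pool: tuple[tuple[str, ...], ...] = DEFAULT_TAXONOMY_POOL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_asvs < 2:
            raise ParameterError("n_asvs must be >= 2")
        if self.n_stages < 2:
            raise ParameterError("n_stages must be >= 2")
        if self.n_logs < 2:
            raise ParameterError("n_logs must be >= 2 (detection rule needs it)")
        lo, hi = self.depth_range
        if not (1 <= lo <= hi):
            raise ParameterError("depth_range must satisfy 1 <= min <= max")
        if not 0.0 <= self.succession_rho < 1.0:
            raise ParameterError("succession_rho must be in [0, 1)")
        if not 0.0 <= self.turnover_tau <= 1.0:
            raise ParameterError("turnover_tau must be in [0, 1]")
        if not 0.0 <= self.retention_lambda <= 1.0:
            raise ParameterError("retention_lambda must be in [0, 1]")
        if not 0.0 <= self.mix_mu <= 1.0:
            raise ParameterError("mix_mu must be in [0, 1]")
        if self.overdispersion_theta <= 0:
            raise ParameterError("overdispersion_theta must be > 0")

    def stage_labels(self) -> tuple[str, ...]:
        if self.n_stages == len(DEFAULT_STAGE_ORDER):
            return DEFAULT_STAGE_ORDER
        return tuple(f"S{i + 1}" for i in range(self.n_stages))


@dataclass
class LatentCommunity:
    """Intracellular proportions plus the bookkeeping of births and deaths."""

    props: np.ndarray  # (n_stages, n_asvs_total), rows sum to 1
    alive: np.ndarray  # boolean, same shape
    extinction_events: list[tuple[int, int]]  # (asv index, stage index of death)


@dataclass
class SyntheticTruth:
    """Latent proportions and planted events emitted beside the count table."""

    asv_ids: list[str]
    stage_labels: tuple[str, ...]
    intra_props: pd.DataFrame  # stage x asv
    extra_props: pd.DataFrame
    total_props: pd.DataFrame
    extinction_events: set[tuple[str, str]] = field(default_factory=set)
    persistence_events: set[tuple[str, str]] = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for stage in self.stage_labels:
            for asv in self.asv_ids:
                rows.append(
                    {
                        "asv_id": asv,
                        "stage": stage,
                        "p_intra": self.intra_props.loc[stage, asv],
                        "p_extra": self.extra_props.loc[stage, asv],
                        "p_total": self.total_props.loc[stage, asv],
                        "extinction_event": int((asv, stage) in self.extinction_events),
                        "persistence_event": int((asv, stage) in self.persistence_events),
                    }
                )
        return pd.DataFrame(rows).set_index("asv_id")


def generate_latent(config: GeneratorConfig, rng: np.random.Generator | None = None) -> LatentCommunity:
    """Simulate the intracellular succession.

    Stage-1 log-abundances are standard normal; each later stage applies the
    AR(1) update ``x' = rho * x + sqrt(1 - rho^2) * eps``.  An extant ASV
    then goes extinct with probability ``tau`` (absorbing: it stays zero at
    all later stages) and every realised extinction is matched by a newly
    activated ASV with a fresh id, so richness is exactly stable and planted
    extinctions are unambiguous.  Proportions are a softmax over extant
    ASVs.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rho, tau = config.succession_rho, config.turnover_tau
    D, S = config.n_stages, config.n_asvs

    stage_states: list[tuple[np.ndarray, np.ndarray]] = []  # (ids, x)
    extinctions: list[tuple[int, int]] = []
    ids = np.arange(S)
    x = rng.standard_normal(S)
    next_id = S
    stage_states.append((ids, x))
    for d in range(1, D):
        x = rho * x + np.sqrt(1.0 - rho**2) * rng.standard_normal(len(x))
        dies = rng.random(len(x)) < tau
        n_dead = int(dies.sum())
        extinctions.extend((int(a), d) for a in ids[dies])
        ids, x = ids[~dies], x[~dies]
        if n_dead:  # colonisation: same number of fresh ASVs
            new_ids = np.arange(next_id, next_id + n_dead)
            next_id += n_dead
            ids = np.concatenate([ids, new_ids])
            x = np.concatenate([x, rng.standard_normal(n_dead)])
        if len(ids) == 0:
            raise GenerationError(
                f"all ASVs extinct at stage {d + 1}; lower turnover_tau"
            )
        stage_states.append((ids, x))

    n_total = next_id
    props = np.zeros((D, n_total))
    alive = np.zeros((D, n_total), dtype=bool)
    for d, (sids, sx) in enumerate(stage_states):
        w = np.exp(sx - sx.max())
        props[d, sids] = w / w.sum()
        alive[d, sids] = True
    return LatentCommunity(props=props, alive=alive, extinction_events=extinctions)


def derive_extracellular(intra_props: np.ndarray, lam: float) -> np.ndarray:
    """Extracellular pool as a geometric superposition of past communities.

    ``u[d] = sum_{k<=d} lam^(d-k) * p[k]``, normalised per stage.  With
    ``lam = 0`` only the current stage contributes, so ``e[d] == p[d]``
    exactly.
    """
    if not 0.0 <= lam <= 1.0:
        raise ParameterError("retention lambda must be in [0, 1]")
    p = np.atleast_2d(np.asarray(intra_props, dtype=float))
    if lam == 0.0:  # only the current stage contributes: exact identity
        return p.copy()
    D = p.shape[0]
    e = np.empty_like(p)
    u = np.zeros(p.shape[1])
    for d in range(D):
        u = lam * u + p[d]
        e[d] = u / u.sum()
    return e


def mix_total(intra: np.ndarray, extra: np.ndarray, mu: float) -> np.ndarray:
    """Convex mixture of the two fractions: ``t = (1 - mu) * p + mu * e``."""
    if not 0.0 <= mu <= 1.0:
        raise ParameterError("mix mu must be in [0, 1]")
    p, e = np.asarray(intra, float), np.asarray(extra, float)
    if p.shape != e.shape:
        raise ValueError(f"shape mismatch: intra {p.shape} vs extra {e.shape}")
    return (1.0 - mu) * p + mu * e


def sample_reads(
    props: np.ndarray, theta: float, depth: int, rng: np.random.Generator
) -> np.ndarray:
    """Dirichlet-multinomial read counts for one sample.

    A replicate-level composition is drawn from Dirichlet(theta * props)
    restricted to the support of ``props`` — structural zeros are never
    resampled — then counts are multinomial at the given depth.
    """
    if theta <= 0:
        raise ParameterError("overdispersion theta must be > 0")
    if depth < 1:
        raise ParameterError("depth must be >= 1")
    p = np.asarray(props, dtype=float)
    comp = np.zeros_like(p)
    support = p > 0
    draws = rng.gamma(shape=theta * p[support])
    if draws.sum() == 0:  # numerically possible at tiny theta*p
        comp[support] = p[support] / p[support].sum()
    else:
        comp[support] = draws / draws.sum()
    return rng.multinomial(depth, comp)


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[AsvCountTable, SampleMetadata, TaxonomyTable, SyntheticTruth]:
    """Emit the full synthetic study: counts, metadata, taxonomy and truth.

    For every stage and log, three samples are produced (intra, extra,
    total) from the stage's respective proportion vector, at depths drawn
    uniformly from ``depth_range``.  A planted extinction counts as a
    *persistence event* when its expected extracellular signal at the stage
    of death, ``e[d, asv] * median depth``, reaches the 5-read detection
    floor.  Identical config and seed give byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    latent = generate_latent(config, rng)
    e = derive_extracellular(latent.props, config.retention_lambda)
    t = mix_total(latent.props, e, config.mix_mu)
    p = latent.props

    stages = config.stage_labels()
    n_total = p.shape[1]
    asv_ids = [f"ASV{i + 1:05d}" for i in range(n_total)]
    logs = [f"L{r + 1}" for r in range(config.n_logs)]

    frac_props = {"intra": p, "extra": e, "total": t}
    sample_ids, meta_rows, columns = [], [], []
    depths_drawn = []
    lo, hi = config.depth_range
    for d, stage in enumerate(stages):
        for dna in DNA_TYPES:
            for r, log in enumerate(logs):
                depth = int(rng.integers(lo, hi + 1))
                depths_drawn.append(depth)
                counts = sample_reads(
                    frac_props[dna][d], config.overdispersion_theta, depth, rng
                )
                sid = f"{stage}_{dna}_{log}"
                sample_ids.append(sid)
                meta_rows.append(
                    {"sample_id": sid, "log_id": log, "stage": stage, "dna_type": dna}
                )
                columns.append(counts)

    counts_df = pd.DataFrame(
        np.column_stack(columns), index=pd.Index(asv_ids, name="asv_id"),
        columns=sample_ids,
    )
    table = AsvCountTable(counts_df)
    meta = SampleMetadata(
        pd.DataFrame(meta_rows).set_index("sample_id"), stage_order=stages
    )

    pool_idx = rng.integers(0, len(config.taxonomy_pool), size=n_total)
    tax_df = pd.DataFrame(
        [config.taxonomy_pool[i] for i in pool_idx],
        index=pd.Index(asv_ids, name="asv_id"),
        columns=list(TAXONOMY_RANKS),
    )
    taxonomy = TaxonomyTable(tax_df)

    median_depth = float(np.median(depths_drawn))
    extinction_events = {
        (asv_ids[a], stages[d]) for a, d in latent.extinction_events
    }
    persistence_events = {
        (asv_ids[a], stages[d])
        for a, d in latent.extinction_events
        if e[d, a] * median_depth >= 5.0
    }

    def _frame(mat: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(mat, index=list(stages), columns=asv_ids)

    truth = SyntheticTruth(
        asv_ids=asv_ids,
        stage_labels=stages,
        intra_props=_frame(p),
        extra_props=_frame(e),
        total_props=_frame(t),
        extinction_events=extinction_events,
        persistence_events=persistence_events,
    )
    return table, meta, taxonomy, truth


def write_dataset(out_dir, table, meta, taxonomy, truth) -> dict[str, Path]:
    """Write counts.tsv, metadata.tsv, taxonomy.tsv and truth.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "metadata": out / "metadata.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "truth": out / "truth.tsv",
    }
    write_table(table.counts, paths["counts"])
    write_table(meta.table, paths["metadata"])
    write_table(taxonomy.table, paths["taxonomy"])
    write_table(truth.to_frame(), paths["truth"])
    return paths
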