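"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates one input of the ovary comparison: FASTQ read sets
with planted PCR-duplicate clusters, two-condition count tables with planted
fold changes around the FPKM > 5 and ratio > 2 thresholds, a small is_a GO
DAG with annotations planting known term enrichment between two gene sets,
histological sections with stage-structured follicle diameters, and qPCR Ct
tables with known ddCt. All randomness flows from a single top-level seed
that fans out to fixed per-generator substreams, so each generator is
deterministic and independently reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import dedup as _dedup
from .dedup import ReadRecord
from .enrichment import AnnotationSet, GoDag, parse_obo
from .errors import InvalidConfigError
from .morphometry import STAGE_DIAMETERS_UM, Follicle, classify_stage

_BASES = np.array(list("ACGT"))

# substream keys: fixed per generator so stages can be re-run independently
_STREAM_READS = 1
_STREAM_EXPRESSION = 2
_STREAM_GO = 3
_STREAM_FOLLICLES = 4
_STREAM_CT = 5


@dataclass
class SimulationConfig:
    """Knobs for every generator, validated as a whole.

    Defaults describe a desk-scale ovary comparison: 101-nt single-end
    reads, a 500-gene two-condition table with 4-fold planted changes, a
    ~60-term single-namespace GO world, and a wildtype-like section with
    stage-III counts matching the published section statistics.
    """

    seed: int = 0
    read_length: int = 101
    n_unique_reads: int = 200
    duplicate_rate: float = 0.3
    n_genes: int = 500
    n_up_mutant: int = 40
    n_up_wildtype: int = 40
    planted_fold: float = 4.0
    n_go_terms: int = 60
    dag_depth: int = 4
    planted_terms: dict[str, str] | None = None  # term id -> "up_in_A" | "up_in_B"
    n_follicles_per_stage: dict[str, int] = field(
        default_factory=lambda: {"I": 200, "II": 120, "III": 35}
    )
    section_area_mm2: float = 5.52
    diameter_cv: float = 0.05

    def validate(self) -> None:
        if self.read_length < 11:
            raise InvalidConfigError(
                "read_length must be >= 11 (the 10-base prefix rule would "
                "cover the whole read)"
            )
        if not 0 <= self.duplicate_rate <= 1:
            raise InvalidConfigError("duplicate_rate must lie in [0, 1]")
        if self.planted_fold <= 1:
            raise InvalidConfigError("planted_fold must exceed 1")
        if self.n_up_mutant + self.n_up_wildtype > self.n_genes:
            raise InvalidConfigError("planted up-gene counts exceed n_genes")
        if self.dag_depth < 3:
            raise InvalidConfigError("dag_depth must be >= 3")
        if self.section_area_mm2 <= 0:
            raise InvalidConfigError("section_area_mm2 must be positive")
        if self.diameter_cv < 0:
            raise InvalidConfigError("diameter_cv must be non-negative")
        for name in ("n_unique_reads", "n_genes", "n_up_mutant", "n_up_wildtype",
                     "n_go_terms"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be non-negative")
        if any(v < 0 for v in self.n_follicles_per_stage.values()):
            raise InvalidConfigError("follicle counts must be non-negative")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,))
        )


# -- read sets ---------------------------------------------------------------


def _random_read(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def generate_read_set(
    cfg: SimulationConfig,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Simulate a single-end read set with planted PCR-duplicate clusters.

    Each unique molecule yields a seed read with a prefix unique in the set.
    A fraction of molecules become multi-read clusters whose extra copies
    keep the 10-base prefix intact and stay strictly above 90% whole-read
    identity to the seed; the selection probability and the cluster-size
    distribution are set so the expected fraction of reads sitting in
    clusters of size >= 2 equals ``duplicate_rate``. Every multi-read
    cluster also gets one "near-miss" read violating exactly one of the two
    duplicate conditions (a mutated prefix base, or prefix intact but
    identity pushed to <= 0.90); near misses are their own singleton truth
    clusters. Mutation positions within a cluster are disjoint so no
    accidental pairwise link can form.

    Returns the reads plus a truth table (read_id, cluster, role) where
    ``role`` is seed / duplicate / near_miss_prefix / near_miss_similarity.
    """
    cfg.validate()
    rng = cfg.rng(_STREAM_READS)
    L = cfg.read_length
    r = cfg.duplicate_rate
    # a seed becomes a multi-read cluster with prob r^2 and then carries
    # 1 + Poisson(1/r - 1) extra copies: E[extras] = n*r and the expected
    # read fraction in multi clusters is (n r^2 + n r)/(n (1+r)) = r.
    p_multi = r * r
    seen_prefixes: set[str] = set()
    reads: list[ReadRecord] = []
    truth_rows: list[dict] = []
    qual = [36] * L

    def add(read_id: str, seq: str, cluster: str, role: str) -> None:
        reads.append(ReadRecord(read_id, seq, list(qual)))
        truth_rows.append({"read_id": read_id, "cluster": cluster, "role": role})

    near_miss_mm = int(np.ceil(0.10 * L))  # smallest count making identity <= 0.90
    max_dup_mm = near_miss_mm - 1

    for i in range(cfg.n_unique_reads):
        while True:
            seq = _random_read(rng, L)
            if seq[:10] not in seen_prefixes:
                seen_prefixes.add(seq[:10])
                break
        cluster = f"c{i:05d}"
        add(f"read{i:05d}", seq, cluster, "seed")
        if r > 0 and rng.random() < p_multi:
            n_extra = 1 + int(rng.poisson(1.0 / r - 1.0))
            # disjoint mutable positions outside the prefix for the whole cluster
            pool = list(rng.permutation(np.arange(10, L)))
            # near-miss first: it needs the most positions
            nm_type = rng.random() < 0.5
            if nm_type and len(pool) >= near_miss_mm:
                positions, pool = pool[:near_miss_mm], pool[near_miss_mm:]
                nm = _mutate(rng, seq, positions)
                add(f"read{i:05d}nm", nm, f"{cluster}nm", "near_miss_similarity")
            else:
                pos = int(rng.integers(0, 10))
                nm = _mutate(rng, seq, [pos])
                add(f"read{i:05d}nm", nm, f"{cluster}nm", "near_miss_prefix")
            for j in range(n_extra):
                n_mut = int(rng.integers(0, max_dup_mm + 1))
                n_mut = min(n_mut, len(pool))
                positions, pool = pool[:n_mut], pool[n_mut:]
                dup = _mutate(rng, seq, positions)
                add(f"read{i:05d}d{j}", dup, cluster, "duplicate")
    truth = pd.DataFrame(truth_rows)
    return reads, truth


def _mutate(rng: np.random.Generator, seq: str, positions: Sequence[int]) -> str:
    out = list(seq)
    for p in positions:
        p = int(p)
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[int(rng.integers(0, 3))]
    return "".join(out)


# -- expression tables -------------------------------------------------------


def generate_expression_pair(
    cfg: SimulationConfig,
    library_size: int = 20_000_000,
    nb_dispersion: float = 50.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a two-condition count table with planted fold changes.

    True per-gene FPKM values are drawn log-normally around the expression
    threshold so the FPKM > 5 call is exercised on both sides. Planted
    up-in-mutant genes get a wildtype FPKM comfortably above the threshold
    and a mutant FPKM of ``planted_fold`` times that (and symmetrically for
    up-in-wildtype); all other genes share one true FPKM in both conditions.
    Observed fragment counts are negative-binomial around the expected
    count implied by the true FPKM, transcript length and library size
    (variance mu + mu^2/theta, theta = ``nb_dispersion``) — RNA-seq counts
    are overdispersed relative to Poisson.

    Returns (counts table, truth table). Truth labels: ``up_in_mutant`` /
    ``up_in_wildtype`` for planted genes, ``not_expressed`` when both true
    FPKMs are <= 5, else ``unchanged``.
    """
    cfg.validate()
    rng = cfg.rng(_STREAM_EXPRESSION)
    n = cfg.n_genes
    lengths = rng.integers(500, 3001, size=n)
    labels = np.array(["unchanged"] * n, dtype=object)
    idx = rng.permutation(n)
    up_mut = idx[: cfg.n_up_mutant]
    up_wt = idx[cfg.n_up_mutant : cfg.n_up_mutant + cfg.n_up_wildtype]

    # baseline true FPKM: log-normal centred just above the threshold
    base = rng.lognormal(mean=np.log(6.0), sigma=1.2, size=n)
    fpkm_mut = base.copy()
    fpkm_wt = base.copy()
    # planted genes: low side clearly expressed, high side = fold * low
    low = rng.uniform(8.0, 60.0, size=n)
    fpkm_wt[up_mut] = low[up_mut]
    fpkm_mut[up_mut] = low[up_mut] * cfg.planted_fold
    labels[up_mut] = "up_in_mutant"
    fpkm_mut[up_wt] = low[up_wt]
    fpkm_wt[up_wt] = low[up_wt] * cfg.planted_fold
    labels[up_wt] = "up_in_wildtype"
    labels[(fpkm_mut <= 5.0) & (fpkm_wt <= 5.0)] = "not_expressed"

    def draw_counts(fpkm: np.ndarray) -> np.ndarray:
        mu = fpkm * (lengths / 1e3) * (library_size / 1e6)
        # NB as gamma-Poisson with shape theta
        lam = rng.gamma(shape=nb_dispersion, scale=mu / nb_dispersion)
        return rng.poisson(lam)

    counts = pd.DataFrame(
        {
            "gene_id": [f"g{i:05d}" for i in range(n)],
            "length_nt": lengths,
            "count_mut": draw_counts(fpkm_mut),
            "count_wt": draw_counts(fpkm_wt),
        }
    )
    truth = pd.DataFrame(
        {
            "gene_id": counts["gene_id"],
            "true_fpkm_mut": fpkm_mut,
            "true_fpkm_wt": fpkm_wt,
            "label": labels,
        }
    )
    return counts, truth


# -- GO world ----------------------------------------------------------------


def generate_go_world(
    cfg: SimulationConfig,
    n_genes_per_set: int = 100,
    planted_freq_high: float = 0.30,
    planted_freq_low: float = 0.05,
    background_rate: float = 0.03,
    namespace: str = "biological_process",
) -> tuple[GoDag, AnnotationSet, list[str], list[str], dict[str, str]]:
    """Build a small single-namespace is_a DAG with planted term enrichment.

    The DAG has ``dag_depth`` levels below one root; each term at level k
    gets one or two parents among the level k-1 terms, which keeps the graph
    acyclic and single-rooted. Two disjoint gene sets A (mutant-specific)
    and B (wildtype-specific) are annotated with a uniform background rate
    per (gene, term). Planted terms sit at level >= 2 and annotate
    ``planted_freq_high`` of their favoured set against ``planted_freq_low``
    of the other, a margin that clears the |score| >= 1.2 display threshold
    at the default pseudo-count.

    Returns (dag, direct annotations, set_A, set_B, truth directions).
    """
    cfg.validate()
    rng = cfg.rng(_STREAM_GO)
    depth = cfg.dag_depth
    n_terms = max(cfg.n_go_terms, depth + 1)

    term_ids = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    levels: dict[str, int] = {term_ids[0]: 0}
    parents: dict[str, list[str]] = {term_ids[0]: []}
    by_level: dict[int, list[str]] = {0: [term_ids[0]]}
    # guarantee one chain covering every level
    for lvl in range(1, depth + 1):
        t = term_ids[lvl]
        parent = by_level[lvl - 1][0]
        levels[t], parents[t] = lvl, [parent]
        by_level.setdefault(lvl, []).append(t)
    for t in term_ids[depth + 1 :]:
        lvl = int(rng.integers(1, depth + 1))
        cand = by_level[lvl - 1]
        k = 1 if len(cand) == 1 or rng.random() < 0.7 else 2
        ps = list(rng.choice(cand, size=k, replace=False))
        levels[t], parents[t] = lvl, ps
        by_level.setdefault(lvl, []).append(t)

    import networkx as nx

    graph = nx.DiGraph()
    for t in term_ids:
        graph.add_node(t, name=f"synthetic term {t}", namespace=namespace)
    for t, ps in parents.items():
        for p in ps:
            graph.add_edge(t, p)
    dag = GoDag(graph=graph)

    planted = cfg.planted_terms
    if planted is None:
        # plant on leaf terms: closure adds nothing below a leaf, so the
        # planted frequency margin survives ancestor propagation intact
        has_child = {p for ps in parents.values() for p in ps}
        eligible = [t for t in term_ids if levels[t] >= 2 and t not in has_child]
        picks = list(rng.choice(eligible, size=min(4, len(eligible)), replace=False))
        planted = {
            t: ("up_in_A" if i % 2 == 0 else "up_in_B") for i, t in enumerate(picks)
        }
    for t in planted:
        if t not in levels:
            raise InvalidConfigError(f"planted term {t} not in generated DAG")
        if levels[t] < 2:
            raise InvalidConfigError(
                f"planted term {t} sits at level {levels[t]} < 2 and would be "
                "masked by the display filter"
            )

    set_a = [f"mutA_{i:04d}" for i in range(n_genes_per_set)]
    set_b = [f"wtB_{i:04d}" for i in range(n_genes_per_set)]
    mapping: dict[str, set[str]] = {g: set() for g in set_a + set_b}
    plain_terms = [t for t in term_ids if t not in planted]
    for g in set_a + set_b:
        hit = rng.random(len(plain_terms)) < background_rate
        mapping[g].update(t for t, h in zip(plain_terms, hit) if h)
    for t, direction in planted.items():
        favoured, other = (set_a, set_b) if direction == "up_in_A" else (set_b, set_a)
        n_f = int(round(planted_freq_high * len(favoured)))
        n_o = int(round(planted_freq_low * len(other)))
        for g in rng.choice(favoured, size=n_f, replace=False):
            mapping[g].add(t)
        for g in rng.choice(other, size=n_o, replace=False):
            mapping[g].add(t)
    ann = AnnotationSet(mapping=mapping, closed=False)
    return dag, ann, set_a, set_b, dict(planted)


def write_obo(dag: GoDag, path) -> None:
    """Serialize a GoDag as a minimal OBO 1.2 document (is_a only)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-go\n")
        for term in sorted(dag.terms):
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {dag.name(term)}\n")
            fh.write(f"namespace: {dag.namespace(term)}\n")
            for parent in sorted(dag.parents(term)):
                fh.write(f"is_a: {parent} ! {dag.name(parent)}\n")


# -- ovary sections ----------------------------------------------------------


def generate_ovary_section(
    cfg: SimulationConfig,
) -> tuple[list[Follicle], pd.DataFrame]:
    """Simulate one section: diameters normal around the stage means.

    Stage means are the nominal 50/70/100 um diameters with coefficient of
    variation ``diameter_cv``. If the configured spread makes diameter-based
    classification misassign more than 20% of follicles, a warning (not an
    error) is emitted. Returns the follicles (diameters only, as measured)
    and a truth table with the generating stage per follicle.
    """
    cfg.validate()
    rng = cfg.rng(_STREAM_FOLLICLES)
    follicles: list[Follicle] = []
    rows: list[dict] = []
    i = 0
    for stage in ("I", "II", "III"):
        mean = STAGE_DIAMETERS_UM[stage]
        for _ in range(cfg.n_follicles_per_stage.get(stage, 0)):
            d = float(rng.normal(mean, cfg.diameter_cv * mean)) if cfg.diameter_cv else mean
            d = max(d, 1.0)
            fid = f"f{i:05d}"
            follicles.append(Follicle(follicle_id=fid, diameter_um=d))
            rows.append({"follicle_id": fid, "true_stage": stage, "diameter_um": d})
            i += 1
    truth = pd.DataFrame(rows, columns=["follicle_id", "true_stage", "diameter_um"])
    if not truth.empty:
        recovered = np.mean(
            [classify_stage(r.diameter_um) == r.true_stage for r in truth.itertuples()]
        )
        if recovered < 0.8:
            warnings.warn(
                f"stage distributions overlap: only {recovered:.0%} of follicles "
                "classify back to their generating stage",
                stacklevel=2,
            )
    return follicles, truth


# -- Ct tables ---------------------------------------------------------------


def generate_ct_table(
    cfg: SimulationConfig,
    true_ddct: Mapping[str, float] | None = None,
    reference: str = "Ci-GAPDH",
    calibrator: str = "wildtype",
    test: str = "mutant",
    n_replicates: int = 3,
    noise_sd: float = 0.2,
    base_ct: float = 24.0,
    reference_ct: float = 20.0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Simulate a replicate Ct table with known ddCt ground truth.

    The reference gene sits at ``reference_ct`` cycles in both samples; each
    target gene sits at ``base_ct`` in the calibrator and ``base_ct +
    true_ddct`` in the test sample. Replicates get independent Gaussian
    noise of ``noise_sd`` cycles (a typical technical-replicate spread).
    """
    cfg.validate()
    if true_ddct is None:
        true_ddct = {"ceramide-synthase": 0.585, "PKCbeta": 0.5, "MLH3": -1.07}
    rng = cfg.rng(_STREAM_CT)
    rows = []

    def emit(sample: str, gene: str, centre: float) -> None:
        for ct in centre + rng.normal(0.0, noise_sd, size=n_replicates):
            rows.append({"sample": sample, "gene": gene, "ct": float(ct)})

    emit(calibrator, reference, reference_ct)
    emit(test, reference, reference_ct)
    for gene, ddct in true_ddct.items():
        emit(calibrator, gene, base_ct)
        emit(test, gene, base_ct + ddct)
    return pd.DataFrame(rows), dict(true_ddct)
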