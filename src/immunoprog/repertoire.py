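"""Clonotype tables and per-sample immune-repertoire diversity metrics.

Clones are rows of a MiXCR-style export: a CDR3 nucleotide sequence, a read
count, and V/D/J/C gene-hit lists. Each clone is assigned to a receptor class
(BCR or TCR) and, when the gene evidence allows it, to a single chain
(IGH/IGK/IGL for BCR, TRA/TRB/TRG/TRD for TCR); IGH clones additionally get
an isotype from the constant-region hit. Diversity metrics (normalized read
count, clone count, mean CDR3 length, top/second clone proportions, Gini,
Gini-Simpson, evenness) are computed per scope: globally over all BCR or all
TCR clones, per chain, and per IGH isotype.
"""

from __future__ import annotations

import enum
import logging
import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("immunoprog")

__all__ = [
    "Receptor",
    "Chain",
    "Isotype",
    "CloneRecord",
    "CloneTable",
    "MetricScope",
    "RepertoireMetrics",
    "CloneTableFormatError",
    "DEFAULT_COLUMNS",
    "read_clone_table",
    "assign_chain",
    "assign_isotype",
    "merge_duplicate_clones",
    "process_clone_table",
    "compute_metrics",
    "compute_all_scopes",
    "all_scopes",
    "metrics_long_frame",
    "metrics_wide_frame",
    "METRIC_NAMES",
]


class Receptor(str, enum.Enum):
    BCR = "BCR"
    TCR = "TCR"
    UNDETERMINED = "undetermined"


class Chain(str, enum.Enum):
    IGH = "IGH"
    IGK = "IGK"
    IGL = "IGL"
    TRA = "TRA"
    TRB = "TRB"
    TRG = "TRG"
    TRD = "TRD"
    MISSING = "missing"


class Isotype(str, enum.Enum):
    IGG = "IgG"
    IGA = "IgA"
    IGM = "IgM"
    IGD = "IgD"
    IGE = "IgE"
    UNDETERMINED = "undetermined"
    NOT_APPLICABLE = "not_applicable"


BCR_CHAINS = (Chain.IGH, Chain.IGK, Chain.IGL)
TCR_CHAINS = (Chain.TRA, Chain.TRB, Chain.TRG, Chain.TRD)
ISOTYPES = (Isotype.IGG, Isotype.IGA, Isotype.IGM, Isotype.IGD, Isotype.IGE)

_CHAIN_FOR_RECEPTOR = {
    Receptor.BCR: set(BCR_CHAINS),
    Receptor.TCR: set(TCR_CHAINS),
}

# constant-gene prefix -> isotype; order matters (IGHD before a bare IGH match)
_ISOTYPE_PREFIX = (
    ("IGHG", Isotype.IGG),
    ("IGHA", Isotype.IGA),
    ("IGHM", Isotype.IGM),
    ("IGHD", Isotype.IGD),
    ("IGHE", Isotype.IGE),
)

_CDR3_RE = re.compile(r"^[ACGTN]+$")


class CloneTableFormatError(ValueError):
    """Raised when a clonotype table cannot be parsed."""


@dataclass
class CloneRecord:
    """One clonotype: a CDR3 nucleotide sequence with its read support."""

    cdr3_nt: str
    read_count: int
    v_hits: list[str] = field(default_factory=list)
    d_hits: list[str] = field(default_factory=list)
    j_hits: list[str] = field(default_factory=list)
    c_hits: list[str] = field(default_factory=list)
    receptor: Receptor = Receptor.UNDETERMINED
    chain: Chain = Chain.MISSING
    isotype: Isotype = Isotype.NOT_APPLICABLE

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError(f"read_count must be >= 1, got {self.read_count}")
        if not self.cdr3_nt or not _CDR3_RE.match(self.cdr3_nt):
            raise ValueError(f"invalid CDR3 nucleotide sequence: {self.cdr3_nt!r}")


@dataclass
class CloneTable:
    """Per-sample clonotype list plus the sample's transcriptome-mapped total."""

    sample_id: str
    clones: list[CloneRecord]
    total_mapped_reads: int

    def __post_init__(self) -> None:
        if self.total_mapped_reads < 1:
            raise ValueError("total_mapped_reads must be >= 1")


@dataclass(frozen=True)
class MetricScope:
    """A metric scope: global per receptor, one chain, or one IGH isotype."""

    scope_kind: str  # global_BCR | global_TCR | chain | isotype
    selector: str | None = None

    def __post_init__(self) -> None:
        if self.scope_kind in ("chain", "isotype"):
            if self.selector is None:
                raise ValueError(f"{self.scope_kind} scope requires a selector")
        elif self.scope_kind in ("global_BCR", "global_TCR"):
            if self.selector is not None:
                raise ValueError("global scopes take no selector")
        else:
            raise ValueError(f"unknown scope_kind: {self.scope_kind}")

    @property
    def label(self) -> str:
        return self.selector if self.selector else self.scope_kind.split("_")[1]


@dataclass(frozen=True)
class RepertoireMetrics:
    """Diversity metrics for one sample at one scope.

    Undefined metrics (empty scope, or single-clone edge cases for evenness
    and the second-clone proportion) are represented as None.
    """

    n_reads_normalized: float
    n_clones: int
    cdr3_length_mean: float | None
    top_clone_prop: float | None
    second_clone_prop: float | None
    gini: float | None
    gini_simpson: float | None
    evenness: float | None


METRIC_NAMES = (
    "n_reads_normalized",
    "n_clones",
    "cdr3_length_mean",
    "top_clone_prop",
    "second_clone_prop",
    "gini",
    "gini_simpson",
    "evenness",
)

DEFAULT_COLUMNS: Mapping[str, str] = {
    "count": "cloneCount",
    "cdr3": "nSeqCDR3",
    "v": "allVHitsWithScore",
    "d": "allDHitsWithScore",
    "j": "allJHitsWithScore",
    "c": "allCHitsWithScore",
}

# ---------------------------------------------------------------------------
# Parsing


def _clean_gene(raw: str) -> str:
    """Strip allele suffix and alignment score: 'TRAV17*00(123.4)' -> 'TRAV17'."""
    name = raw.strip()
    name = re.sub(r"\(.*?\)", "", name)
    name = name.split("*")[0]
    return name.strip()


def _parse_hits(cell: object) -> list[str]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return []
    text = str(cell).strip()
    if not text:
        return []
    return [g for g in (_clean_gene(part) for part in text.split(",")) if g]


def read_clone_table(
    path,
    total_mapped_reads: int,
    sample_id: str | None = None,
    columns: Mapping[str, str] | None = None,
) -> CloneTable:
    """Read a MiXCR-export-like TSV into a :class:`CloneTable`.

    Rows with a read count below 1 or an empty/invalid CDR3 are dropped with
    a logged count. Receptor/chain/isotype are left unassigned; call
    :func:`assign_chain` and :func:`assign_isotype` (or
    :func:`process_clone_table`) afterwards.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for key in ("count", "cdr3", "v", "j"):
        if colmap[key] not in df.columns:
            raise CloneTableFormatError(
                f"{path}: required column {colmap[key]!r} (for {key}) not found"
            )
    clones: list[CloneRecord] = []
    n_dropped = 0
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        rec = dict(zip(df.columns, row))
        raw_count = rec[colmap["count"]]
        try:
            count = float(raw_count)
        except (TypeError, ValueError):
            raise CloneTableFormatError(
                f"{path}: unparseable clone count {raw_count!r} on line {idx}"
            )
        cdr3 = str(rec[colmap["cdr3"]]).strip() if pd.notna(rec[colmap["cdr3"]]) else ""
        if count < 1 or not cdr3 or not _CDR3_RE.match(cdr3):
            n_dropped += 1
            continue
        clones.append(
            CloneRecord(
                cdr3_nt=cdr3,
                read_count=int(round(count)),
                v_hits=_parse_hits(rec.get(colmap["v"])),
                d_hits=_parse_hits(rec.get(colmap["d"])) if colmap["d"] in df.columns else [],
                j_hits=_parse_hits(rec.get(colmap["j"])),
                c_hits=_parse_hits(rec.get(colmap["c"])) if colmap["c"] in df.columns else [],
            )
        )
    if n_dropped:
        logger.warning("%s: dropped %d rows (count < 1 or invalid CDR3)", path, n_dropped)
    if sample_id is None:
        sample_id = str(getattr(path, "stem", path))
    return CloneTable(sample_id=sample_id, clones=clones, total_mapped_reads=total_mapped_reads)


# ---------------------------------------------------------------------------
# Chain / isotype assignment


def _gene_chain(gene: str) -> Chain | None:
    prefix = gene[:3].upper()
    try:
        return Chain(prefix)
    except ValueError:
        return None


def _slot_chain_sets(clone: CloneRecord) -> list[set[Chain]]:
    """Per gene slot (V, D, J, C), the set of chains its hits point to."""
    sets = []
    for hits in (clone.v_hits, clone.d_hits, clone.j_hits, clone.c_hits):
        chains = {c for c in (_gene_chain(g) for g in hits) if c is not None}
        if chains:
            sets.append(chains)
    return sets


def assign_chain(clone: CloneRecord) -> CloneRecord:
    """Resolve the clone's chain and receptor class from its gene hits.

    The chain is assigned when all gene slots agree, or when an ambiguous
    slot (multiple hits on different chains) is resolved by another slot
    whose univocal chain is compatible with one of the ambiguous options.
    Irreconcilable slots leave the chain missing; the receptor class is
    still set whenever the locus family (IG* vs TR*) is unambiguous, so the
    clone keeps contributing to its global repertoire.
    """
    slot_sets = _slot_chain_sets(clone)
    if not slot_sets:
        clone.receptor = Receptor.UNDETERMINED
        clone.chain = Chain.MISSING
        logger.debug("clone %s: no recognizable gene hits, excluded from all scopes", clone.cdr3_nt)
        return clone

    families = {("BCR" if c.value.startswith("IG") else "TCR") for s in slot_sets for c in s}
    if families == {"BCR"}:
        clone.receptor = Receptor.BCR
    elif families == {"TCR"}:
        clone.receptor = Receptor.TCR
    else:
        clone.receptor = Receptor.UNDETERMINED

    common = set.intersection(*slot_sets)
    if len(common) == 1:
        clone.chain = next(iter(common))
        # a resolved chain pins the receptor class even if other slots strayed
        clone.receptor = Receptor.BCR if clone.chain in BCR_CHAINS else Receptor.TCR
    else:
        clone.chain = Chain.MISSING
        logger.debug(
            "clone %s: chain left missing (slot chain sets %s)", clone.cdr3_nt, slot_sets
        )
    return clone


def assign_isotype(clone: CloneRecord) -> CloneRecord:
    """Set the heavy-chain isotype from the constant-region gene hits."""
    if clone.chain is not Chain.IGH:
        clone.isotype = Isotype.NOT_APPLICABLE
        return clone
    classes = set()
    for gene in clone.c_hits:
        g = gene.upper()
        for prefix, iso in _ISOTYPE_PREFIX:
            if g.startswith(prefix) or (prefix in ("IGHM", "IGHD", "IGHE") and g == prefix):
                classes.add(iso)
                break
    clone.isotype = classes.pop() if len(classes) == 1 else Isotype.UNDETERMINED
    return clone


def merge_duplicate_clones(table: CloneTable) -> CloneTable:
    """Merge rows sharing the same CDR3 sequence on the same chain.

    Clone identity is the CDR3 nucleotide sequence within a chain, so
    duplicate rows (e.g. alternative V calls) are summed; identical CDR3s on
    different chains remain distinct clones. Gene hits are unioned and the
    isotype re-derived from the merged constant-region evidence.
    """
    groups: dict[tuple, CloneRecord] = {}
    order: list[tuple] = []
    for clone in table.clones:
        key = (clone.cdr3_nt, clone.chain, clone.receptor)
        if key not in groups:
            groups[key] = replace(
                clone,
                v_hits=list(clone.v_hits),
                d_hits=list(clone.d_hits),
                j_hits=list(clone.j_hits),
                c_hits=list(clone.c_hits),
            )
            order.append(key)
        else:
            tgt = groups[key]
            tgt.read_count += clone.read_count
            for attr in ("v_hits", "d_hits", "j_hits", "c_hits"):
                seen = getattr(tgt, attr)
                for g in getattr(clone, attr):
                    if g not in seen:
                        seen.append(g)
    merged = [assign_isotype(groups[k]) if groups[k].chain is Chain.IGH else groups[k] for k in order]
    return CloneTable(table.sample_id, merged, table.total_mapped_reads)


def process_clone_table(
    path,
    total_mapped_reads: int,
    sample_id: str | None = None,
    columns: Mapping[str, str] | None = None,
) -> CloneTable:
    """Read, assign chains/isotypes, and merge duplicate clones in one call."""
    table = read_clone_table(path, total_mapped_reads, sample_id=sample_id, columns=columns)
    for clone in table.clones:
        assign_chain(clone)
        assign_isotype(clone)
    return merge_duplicate_clones(table)


# ---------------------------------------------------------------------------
# Diversity metrics


def _gini_index(counts: np.ndarray) -> float:
    """Sample Gini index: relative mean absolute difference / 2.

    G = sum_ij |x_i - x_j| / (2 n^2 mean(x)), computed from sorted values;
    no small-sample (n/(n-1)) correction.
    """
    x = np.sort(np.asarray(counts, dtype=float))
    n = x.size
    ranks = np.arange(1, n + 1)
    return float(2.0 * np.sum(ranks * x) / (n * np.sum(x)) - (n + 1) / n)


def _select(table: CloneTable, scope: MetricScope) -> list[CloneRecord]:
    if scope.scope_kind == "global_BCR":
        return [c for c in table.clones if c.receptor is Receptor.BCR]
    if scope.scope_kind == "global_TCR":
        return [c for c in table.clones if c.receptor is Receptor.TCR]
    if scope.scope_kind == "chain":
        want = Chain(scope.selector)
        return [c for c in table.clones if c.chain is want]
    want_iso = Isotype(scope.selector)
    return [c for c in table.clones if c.chain is Chain.IGH and c.isotype is want_iso]


def compute_metrics(table: CloneTable, scope: MetricScope) -> RepertoireMetrics:
    """Compute all diversity metrics for the clones selected by ``scope``.

    Clone fractions p_i are read counts over the scope's read total.
    Normalized reads are scope reads / total transcriptome-mapped reads,
    times 1000. Edge rules: an empty scope leaves every count-distribution
    metric undefined; a single clone fixes Gini and Gini-Simpson at 0 while
    evenness and the second-clone proportion stay undefined.
    """
    selected = _select(table, scope)
    n = len(selected)
    if n == 0:
        return RepertoireMetrics(0.0, 0, None, None, None, None, None, None)

    counts = np.array([c.read_count for c in selected], dtype=float)
    total = counts.sum()
    p = counts / total
    n_reads_norm = float(total / table.total_mapped_reads * 1000.0)
    cdr3_mean = float(np.mean([len(c.cdr3_nt) for c in selected]))
    p_sorted = np.sort(p)[::-1]
    top = float(p_sorted[0])

    if n == 1:
        return RepertoireMetrics(n_reads_norm, 1, cdr3_mean, top, None, 0.0, 0.0, None)

    second = float(p_sorted[1])
    gini = _gini_index(counts)
    gini_simpson = float(1.0 - np.sum(p**2))
    evenness = float(-np.sum(p * np.log(p)) / math.log(n))
    return RepertoireMetrics(
        n_reads_norm, n, cdr3_mean, top, second, gini, gini_simpson, evenness
    )


def all_scopes() -> list[MetricScope]:
    """Every scope, in deterministic order: globals, 7 chains, 5 isotypes."""
    scopes = [MetricScope("global_BCR"), MetricScope("global_TCR")]
    scopes += [MetricScope("chain", c.value) for c in BCR_CHAINS + TCR_CHAINS]
    scopes += [MetricScope("isotype", iso.value) for iso in ISOTYPES]
    return scopes


def compute_all_scopes(table: CloneTable) -> dict[MetricScope, RepertoireMetrics]:
    return {scope: compute_metrics(table, scope) for scope in all_scopes()}


# ---------------------------------------------------------------------------
# Tabular output


def metrics_long_frame(results: Mapping[str, Mapping[MetricScope, RepertoireMetrics]]) -> pd.DataFrame:
    """Tidy long table: sample_id, scope, metric, value (NaN when undefined)."""
    rows = []
    for sample_id, per_scope in results.items():
        for scope, m in per_scope.items():
            for name in METRIC_NAMES:
                value = getattr(m, name)
                rows.append(
                    {
                        "sample_id": sample_id,
                        "scope": scope.label,
                        "metric": name,
                        "value": np.nan if value is None else value,
                    }
                )
    return pd.DataFrame(rows)


def metrics_wide_frame(results: Mapping[str, Mapping[MetricScope, RepertoireMetrics]]) -> pd.DataFrame:
    """Wide per-sample matrix with columns like 'BCR_evenness', 'IGH_gini'."""
    long = metrics_long_frame(results)
    long["column"] = long["scope"] + "_" + long["metric"]
    wide = long.pivot(index="sample_id", columns="column", values="value")
    wide.columns.name = None
    return wide
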