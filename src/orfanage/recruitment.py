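"""Metagenomic ORFan recruitment: hit-table parsing, identity/coverage
filtering, best-reciprocal-hit (BRBH) validation, relative gene abundance
(RGA), per-ORF-per-library abundance matrices, read-level synteny graphs and
mate-pair taxonomy.

Hit tables use the 12-column BLAST tabular dialect (qseqid, sseqid, pident,
length, mismatch, gapopen, qstart, qend, sstart, send, evalue, bitscore)
with an optional 13th ``qlen`` column; ``sstart > send`` encodes a
minus-strand hit on the read.  Subject read ids carry their library as a
``LIBRARY|read`` prefix.

RGA normalises a hit count N by the query protein length Q_L (residues) and
the database size DB_S (nucleotides):

    RGA = (N / Q_L / DB_S) * 1e12

so abundances are comparable across queries and across databases of very
different size.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

SALINITY_CLASSES = ("marine", "freshwater", "brackish")


class ConfigurationError(ValueError):
    """Missing configuration such as unknown query lengths or libraries."""


@dataclass(frozen=True)
class FilterThresholds:
    """Inclusive hit-retention thresholds: alignment percent identity and
    query coverage ``(qend - qstart + 1) / Q_L``."""

    min_identity: float = 40.0
    min_query_coverage: float = 0.50

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_identity <= 100.0:
            raise ValueError("min_identity must be in [0, 100]")
        if not 0.0 <= self.min_query_coverage <= 1.0:
            raise ValueError("min_query_coverage must be in [0, 1]")


@dataclass(frozen=True)
class RejectedRow:
    lineno: int
    reason: str
    text: str


def library_of(read_id: str) -> str:
    """Library id encoded as the ``LIBRARY|read`` prefix of a subject id."""
    return read_id.split("|", 1)[0] if "|" in read_id else ""


def region_key(read_id: str, sstart: int, send: int) -> str:
    """Canonical id of a hit's region on its read (strand-agnostic)."""
    lo, hi = (sstart, send) if sstart <= send else (send, sstart)
    return f"{read_id}:{lo}-{hi}"


# ---------------------------------------------------------------------------
# Parsing

def parse_hit_table(
    path: str | Path,
    query_lengths: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, list[RejectedRow]]:
    """Parse a 12/13-column tab-separated hit table into typed records.

    Returns ``(hits, rejected)`` where ``hits`` has the 12 standard columns
    plus ``qlen``, ``strand``, ``query_orf_id``, ``read_id`` and
    ``library_id``, and ``rejected`` lists malformed rows with line numbers.
    Queries whose length is available neither as a 13th column nor in
    ``query_lengths`` raise :class:`ConfigurationError`.
    """
    rows: list[list] = []
    rejected: list[RejectedRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) not in (12, 13):
                rejected.append(RejectedRow(lineno, f"expected 12 or 13 columns, got {len(cols)}", line))
                continue
            try:
                rec = [
                    cols[0], cols[1], float(cols[2]), int(cols[3]), int(cols[4]), int(cols[5]),
                    int(cols[6]), int(cols[7]), int(cols[8]), int(cols[9]),
                    float(cols[10]), float(cols[11]),
                ]
            except ValueError as exc:
                rejected.append(RejectedRow(lineno, f"unparsable field: {exc}", line))
                continue
            qlen = None
            if len(cols) == 13:
                try:
                    qlen = int(cols[12])
                except ValueError:
                    rejected.append(RejectedRow(lineno, "unparsable qlen column", line))
                    continue
            elif query_lengths is not None and rec[0] in query_lengths:
                qlen = int(query_lengths[rec[0]])
            if qlen is None:
                raise ConfigurationError(
                    f"{path}:{lineno}: no query length for {rec[0]!r} "
                    "(no 13th column and not in query_lengths)"
                )
            qstart, qend = rec[6], rec[7]
            pident = rec[2]
            if not (1 <= qstart <= qend <= qlen):
                rejected.append(
                    RejectedRow(lineno, f"invalid query interval [{qstart}, {qend}] for qlen {qlen}", line)
                )
                continue
            if not 0.0 <= pident <= 100.0:
                rejected.append(RejectedRow(lineno, f"percent identity {pident} out of [0, 100]", line))
                continue
            rows.append(rec + [qlen])
    df = pd.DataFrame(rows, columns=HIT_COLUMNS + ["qlen"])
    df["strand"] = np.where(df["sstart"] <= df["send"], "+", "-")
    df["query_orf_id"] = df["qseqid"]
    df["read_id"] = df["sseqid"]
    df["library_id"] = df["sseqid"].map(library_of)
    return df, rejected


def write_hit_table(df: pd.DataFrame, path: str | Path, include_qlen: bool = True) -> None:
    cols = HIT_COLUMNS + (["qlen"] if include_qlen else [])
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def read_library_meta(path: str | Path) -> pd.DataFrame:
    """Read library metadata TSV: library_id, db_size_nt, salinity_class."""
    meta = pd.read_csv(path, sep="\t", dtype={"library_id": str})
    required = {"library_id", "db_size_nt", "salinity_class"}
    if not required <= set(meta.columns):
        raise ValueError(f"library metadata must have columns {sorted(required)}")
    if (meta["db_size_nt"] <= 0).any():
        raise ValueError("db_size_nt must be positive")
    bad = set(meta["salinity_class"]) - set(SALINITY_CLASSES)
    if bad:
        raise ValueError(f"unknown salinity classes: {sorted(bad)}")
    return meta


def read_reciprocal_table(path: str | Path) -> pd.DataFrame:
    """Read a reciprocal-search table: region_id, subject_id, bitscore, evalue."""
    df = pd.read_csv(path, sep="\t", dtype={"region_id": str, "subject_id": str})
    required = {"region_id", "subject_id", "bitscore", "evalue"}
    if not required <= set(df.columns):
        raise ValueError(f"reciprocal table must have columns {sorted(required)}")
    return df


def read_taxonomy_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"subject_id", "group"} <= set(df.columns):
        raise ValueError("taxonomy map must have columns subject_id, group")
    return dict(zip(df["subject_id"], df["group"]))


# ---------------------------------------------------------------------------
# Filtering and BRBH validation

def filter_hits(hits: pd.DataFrame, thresholds: FilterThresholds = FilterThresholds()) -> pd.DataFrame:
    """Retain hits with identity and query coverage at or above the
    thresholds (both inclusive, matching the 40% / 50% convention)."""
    qcov = (hits["qend"] - hits["qstart"] + 1) / hits["qlen"]
    keep = (hits["pident"] >= thresholds.min_identity) & (qcov >= thresholds.min_query_coverage)
    return hits.loc[keep].copy()


@dataclass
class BrbhReport:
    n_input: int = 0
    n_retained: int = 0
    n_failed_best: int = 0
    n_missing_region: int = 0


def brbh_validate(hits: pd.DataFrame, reciprocal: pd.DataFrame) -> tuple[pd.DataFrame, BrbhReport]:
    """Keep hits whose read region's best reciprocal hit is their own query.

    ``reciprocal`` holds, per read region (``region_id`` as produced by
    :func:`region_key`), hits of that region against the full protein
    reference set, with columns ``region_id, subject_id, bitscore, evalue``.
    The top reciprocal hit is chosen by max bitscore, then min evalue, then
    lexicographic subject id.  Regions absent from the table fail
    validation and are counted separately.
    """
    report = BrbhReport(n_input=len(hits))
    if len(hits) == 0:
        return hits.copy(), report
    best = (
        reciprocal.sort_values(
            ["region_id", "bitscore", "evalue", "subject_id"],
            ascending=[True, False, True, True],
        )
        .drop_duplicates("region_id", keep="first")
        .set_index("region_id")["subject_id"]
    )
    regions = [
        region_key(r, s1, s2)
        for r, s1, s2 in zip(hits["read_id"], hits["sstart"], hits["send"])
    ]
    best_for_hit = pd.Series(regions, index=hits.index).map(best)
    missing = best_for_hit.isna()
    ok = best_for_hit == hits["query_orf_id"]
    report.n_missing_region = int(missing.sum())
    report.n_failed_best = int((~ok & ~missing).sum())
    report.n_retained = int(ok.sum())
    return hits.loc[ok].copy(), report


# ---------------------------------------------------------------------------
# RGA and the abundance matrix

def compute_rga(n: float, query_length: float, db_size_nt: float) -> float:
    """Relative gene abundance: ``(N / Q_L / DB_S) * 1e12``.

    Linear (additive) in N, inversely proportional to query length and to
    database size; zero iff N is zero.
    """
    if query_length <= 0:
        raise ValueError("query_length must be positive")
    if db_size_nt <= 0:
        raise ValueError("db_size_nt must be positive")
    return (n / query_length / db_size_nt) * 1e12


@dataclass
class RgaMatrix:
    """Per-(ORF, library) hit counts and RGA values.

    ``counts_per_read`` counts each read once per ORF (default abundance
    measure); ``counts_per_hit`` counts every retained hit.  ``rga`` is
    computed from the counts selected by ``count_mode``.
    """

    counts_per_read: pd.DataFrame
    counts_per_hit: pd.DataFrame
    rga: pd.DataFrame
    count_mode: str = "per_read"

    @property
    def counts(self) -> pd.DataFrame:
        return self.counts_per_read if self.count_mode == "per_read" else self.counts_per_hit

    def to_tsv(self, path: str | Path) -> None:
        self.rga.to_csv(path, sep="\t", index_label="query_orf_id")


def build_abundance_matrix(
    hits: pd.DataFrame,
    meta: pd.DataFrame,
    orf_ids: list[str] | None = None,
    query_lengths: Mapping[str, int] | None = None,
    count_mode: str = "per_read",
) -> RgaMatrix:
    """Aggregate validated hits into an ORF x library abundance matrix.

    Every library occurring in ``hits`` must appear in ``meta``; the output
    grid covers all of ``meta``'s libraries and ``orf_ids`` (defaulting to
    the ORFs seen in ``hits``), with zero-filled empty cells.
    """
    if count_mode not in ("per_read", "per_hit"):
        raise ValueError("count_mode must be 'per_read' or 'per_hit'")
    libraries = list(meta["library_id"])
    unknown = sorted(set(hits["library_id"]) - set(libraries))
    if unknown:
        raise ConfigurationError(f"libraries absent from metadata: {unknown}")
    if orf_ids is None:
        orf_ids = sorted(hits["query_orf_id"].unique())
    qlen: dict[str, int] = dict(query_lengths or {})
    for orf, ql in zip(hits["query_orf_id"], hits["qlen"]):
        qlen.setdefault(orf, int(ql))
    per_hit = (
        hits.groupby(["query_orf_id", "library_id"]).size()
        .unstack(fill_value=0)
        .reindex(index=orf_ids, columns=libraries, fill_value=0)
    )
    per_read = (
        hits.drop_duplicates(["query_orf_id", "library_id", "read_id"])
        .groupby(["query_orf_id", "library_id"]).size()
        .unstack(fill_value=0)
        .reindex(index=orf_ids, columns=libraries, fill_value=0)
    )
    counts = per_read if count_mode == "per_read" else per_hit
    db = meta.set_index("library_id")["db_size_nt"]
    rga = pd.DataFrame(0.0, index=counts.index, columns=counts.columns)
    for orf in counts.index:
        ql = qlen.get(orf)
        if ql is None:
            continue  # no hits anywhere: RGA stays 0 regardless of Q_L
        for lib in counts.columns:
            n = int(counts.at[orf, lib])
            rga.at[orf, lib] = compute_rga(n, ql, float(db[lib])) if n else 0.0
    return RgaMatrix(
        counts_per_read=per_read, counts_per_hit=per_hit, rga=rga, count_mode=count_mode
    )


# ---------------------------------------------------------------------------
# Synteny graph

@dataclass
class SyntenyGraph:
    """Weighted directed adjacency of co-localised ORF hits on reads.

    Edge weight counts ordered adjacent co-localisations (left-to-right in
    read coordinates); ``same_polarity`` counts those where both hits share
    strand.
    """

    graph: nx.DiGraph

    @property
    def total_weight(self) -> int:
        return sum(d["weight"] for _, _, d in self.graph.edges(data=True))

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (a, b, d["weight"], d["same_polarity"])
            for a, b, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["orf_a", "orf_b", "weight", "same_polarity_count"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def to_dot(self) -> str:
        lines = ["digraph synteny {"]
        for a, b, d in sorted(self.graph.edges(data=True)):
            lines.append(f'  "{a}" -> "{b}" [weight={d["weight"]}, label="{d["weight"]}"];')
        lines.append("}")
        return "\n".join(lines)


def _collapse_overlaps(group: pd.DataFrame) -> pd.DataFrame:
    """Collapse hits sharing >50% mutual overlap on the read, keeping the
    higher bitscore."""
    g = group.assign(
        smin=group[["sstart", "send"]].min(axis=1),
        smax=group[["sstart", "send"]].max(axis=1),
    ).sort_values(["smin", "smax"])
    kept: list[pd.Series] = []
    for _, row in g.iterrows():
        merged = False
        for i, prev in enumerate(kept):
            ov = min(row.smax, prev.smax) - max(row.smin, prev.smin) + 1
            if ov <= 0:
                continue
            len_a = row.smax - row.smin + 1
            len_b = prev.smax - prev.smin + 1
            if ov > 0.5 * len_a and ov > 0.5 * len_b:
                if row.bitscore > prev.bitscore:
                    kept[i] = row
                merged = True
                break
        if not merged:
            kept.append(row)
    return pd.DataFrame(kept).sort_values("smin")


def synteny_edges(hits: pd.DataFrame) -> SyntenyGraph:
    """Build the gene-neighbourhood graph from validated hits.

    For each read carrying >= 2 hits (after collapsing >50% mutual overlaps
    to the higher bitscore), hits are ordered by their leftmost read
    coordinate and each ordered adjacent pair contributes weight 1 to the
    edge ``orf_a -> orf_b``; pairs on the same strand increment the edge's
    ``same_polarity`` count.  The total edge weight equals
    ``sum(max(0, hits_on_read - 1))`` over reads.
    """
    g = nx.DiGraph()
    if len(hits) == 0:
        return SyntenyGraph(graph=g)
    for _, group in hits.groupby("read_id", sort=True):
        if len(group) < 2:
            continue
        ordered = _collapse_overlaps(group)
        rows = list(ordered.itertuples())
        for left, right in zip(rows, rows[1:]):
            a, b = left.query_orf_id, right.query_orf_id
            same = int(left.strand == right.strand)
            if g.has_edge(a, b):
                g[a][b]["weight"] += 1
                g[a][b]["same_polarity"] += same
            else:
                g.add_edge(a, b, weight=1, same_polarity=same)
    return SyntenyGraph(graph=g)


# ---------------------------------------------------------------------------
# Mate-pair taxonomy

MATE_LABELS = ("cyanophage", "non_cyanophage", "no_hit", "mixed")


def classify_mate_taxonomy(
    mate_hits: pd.DataFrame,
    taxon_map: Mapping[str, str],
    all_read_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Label each read by the taxonomy of its mate's best hits.

    ``mate_hits`` columns: ``read_id`` (the mate), ``subject_id``,
    ``bitscore``, ``sstart``, ``send``.  Per mate, overlapping hit regions
    are collapsed; each region is labelled by its best hit's (max bitscore)
    group under ``taxon_map``.  A single group labels the read with that
    group; distinct groups across regions give ``mixed``; mates listed in
    ``all_read_ids`` but without hits get ``no_hit``.  Subjects missing from
    ``taxon_map`` raise.
    """
    missing = sorted(set(mate_hits["subject_id"]) - set(taxon_map))
    if missing:
        raise ConfigurationError(f"subjects absent from taxonomy map: {missing}")
    labels: dict[str, str] = {}
    for read_id, group in mate_hits.groupby("read_id", sort=True):
        regions = _collapse_regions_best(group)
        groups = {taxon_map[s] for s in regions}
        labels[str(read_id)] = groups.pop() if len(groups) == 1 else "mixed"
    if all_read_ids is not None:
        for rid in all_read_ids:
            labels.setdefault(rid, "no_hit")
    df = pd.DataFrame(sorted(labels.items()), columns=["read_id", "label"])
    df["library_id"] = df["read_id"].map(library_of)
    return df


def _collapse_regions_best(group: pd.DataFrame) -> list[str]:
    """Best subject per collapsed region of one mate read."""
    g = group.assign(
        smin=group[["sstart", "send"]].min(axis=1),
        smax=group[["sstart", "send"]].max(axis=1),
    ).sort_values(["smin", "smax"])
    regions: list[dict] = []
    for _, row in g.iterrows():
        placed = False
        for reg in regions:
            ov = min(row.smax, reg["smax"]) - max(row.smin, reg["smin"]) + 1
            len_a = row.smax - row.smin + 1
            len_b = reg["smax"] - reg["smin"] + 1
            if ov > 0 and ov > 0.5 * len_a and ov > 0.5 * len_b:
                if row.bitscore > reg["bitscore"]:
                    reg.update(subject=row.subject_id, bitscore=row.bitscore)
                placed = True
                break
        if not placed:
            regions.append(
                {"smin": row.smin, "smax": row.smax, "subject": row.subject_id, "bitscore": row.bitscore}
            )
    return [r["subject"] for r in regions]


def summarize_mate_labels(labels: pd.DataFrame) -> pd.DataFrame:
    """Per-library counts of each mate-taxonomy label."""
    return (
        labels.groupby(["library_id", "label"]).size()
        .unstack(fill_value=0)
        .reindex(columns=list(MATE_LABELS), fill_value=0)
    )
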