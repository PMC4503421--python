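"""Generators for every input the pipeline consumes, each with a
machine-readable truth record: a fixture genome + annotation emulating a
~196-kb cyanophage with a 9,540-nt dispensable ORFan locus, metagenomic hit
tables with planted enrichment/decoy/synteny/mate structure, and two-group
plaque-radius samples.

The defaults encode the study conditions: a 196,000-nt genome with 244
ORFs; deletion breakpoints (5,799; 15,339) removing 9,540 nt that fully
contain 33 ORFan ORFs while truncating the non-ORFan ORF017 straddling the
left breakpoint; hit-count intensities that grow linearly with database
size in freshwater (and weakly in brackish/hypersaline) libraries but not
marine ones; and 34 plaque radii per strain with a 6-fold mean difference.

Junction identifiability: the fixture guarantees the deletion junction has
no micro-homology (the first deleted base differs from the first base after
the deleted interval, and the last deleted base differs from the last
retained base).  With micro-homology the breakpoint coordinates of a
deletion are mathematically ambiguous, so exact-recovery checks would be
ill-posed; the two bases adjusted to guarantee this lie inside the deleted
interval.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as _io
from .genome_model import (
    DeletionEvent,
    Genome,
    OrfRecord,
    apply_deletion,
    classify_orfs,
)
from .recruitment import HIT_COLUMNS, region_key

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Fixture genome + annotation

@dataclass(frozen=True)
class FixtureSpec:
    """Geometry of the fixture genome; defaults reproduce the study genome's
    published dimensions."""

    genome_length: int = 196_000
    n_orfs: int = 244
    left_retained: int = 5_799
    right_deleted: int = 15_339
    n_orfan: int = 33
    pac_position: int = 20_000
    gc_fraction: float = 0.38
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.left_retained < self.right_deleted <= self.genome_length:
            raise ValueError("breakpoints must satisfy 1 <= L < R <= genome_length")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must be in (0, 1)")


@dataclass
class Fixture:
    wt: Genome
    variant: Genome
    orfs: list[OrfRecord]
    event: DeletionEvent
    truth: dict


def _random_sequence(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _tile(start: int, end: int, n: int, max_orf_len: int) -> list[tuple[int, int]]:
    """Place n non-overlapping [s, e] intervals evenly in [start, end].

    ORF lengths are ``max_orf_len`` capped to ~85% of the pitch (multiple of
    3), so smaller fixtures tile with proportionally shorter ORFs."""
    span = end - start + 1
    if n <= 0:
        return []
    pitch = span / n
    orf_len = min(max_orf_len, int(pitch * 0.85) // 3 * 3)
    if orf_len < 60 or pitch < orf_len + 2:
        raise ValueError(
            f"infeasible tiling: {n} ORFs in {span} nt; use fewer or shorter ORFs"
        )
    out = []
    for i in range(n):
        s = start + int(round(i * pitch))
        out.append((s, s + orf_len - 1))
    return out


def gen_fixture(spec: FixtureSpec = FixtureSpec()) -> Fixture:
    """Generate the wild-type fixture genome, its ORF annotation, the
    deletion event and the deleted variant, plus a truth record.

    Layout (defaults): ORF001-016 upstream of the locus; ORF017 (not an
    ORFan) straddling the left breakpoint, hence truncated by the deletion;
    ORF018-050, 33 ORFans, fully inside the deleted interval; the remaining
    ORFs downstream.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(spec.seed)
    G, L, R = spec.genome_length, spec.left_retained, spec.right_deleted
    seq = _random_sequence(rng, G, spec.gc_fraction)

    # no junction micro-homology: edit bases *inside* the deleted interval
    while seq[L] == seq[R]:  # first deleted base vs first base after the gap
        seq[L] = rng.choice(_BASES)
    while seq[R - 1] == seq[L - 1]:  # last deleted base vs last retained base
        seq[R - 1] = rng.choice(_BASES)

    # straddler: ends beyond L, starts at or before it, stays within the gap
    straddler = (L - 199, L + 100)
    n_left = min(16, (straddler[0] - 60) // 340)
    n_right = spec.n_orfs - n_left - 1 - spec.n_orfan
    if n_right < 1:
        raise ValueError("infeasible tiling: too few ORFs for the layout")
    intervals: list[tuple[int, int, bool]] = []
    for s, e in _tile(1, straddler[0] - 60, n_left, 300):
        intervals.append((s, e, False))
    intervals.append((*straddler, False))
    for s, e in _tile(straddler[1] + 11, R, spec.n_orfan, 240):
        intervals.append((s, e, True))
    for s, e in _tile(R + 61, G - 50, n_right, 750):
        intervals.append((s, e, False))

    orfs = []
    for i, (s, e, is_orfan) in enumerate(intervals, start=1):
        orfs.append(
            OrfRecord(
                orf_id=f"ORF{i:03d}",
                start=s,
                end=e,
                strand=str(rng.choice(["+", "-"])),
                is_orfan=is_orfan,
            )
        )
    for prev, nxt in zip(orfs, orfs[1:]):
        if nxt.start <= prev.end:
            raise ValueError("infeasible tiling: overlapping ORFs; use fewer or shorter ORFs")

    wt = Genome(id="fixture_WT", sequence="".join(seq), circular=True)
    event = DeletionEvent(left_retained=L, right_deleted=R)
    variant = apply_deletion(wt, event)
    cls = classify_orfs(orfs, event)
    orfan_ids = [o.orf_id for o in orfs if o.is_orfan]
    truth = {
        "genome_length": G,
        "n_orfs": len(orfs),
        "left_retained": L,
        "right_deleted": R,
        "deletion_length": event.length,
        "n_fully_deleted": cls.n_fully_deleted,
        "n_truncated": cls.n_truncated,
        "truncated_orf": next(o for o, s in cls.status.items() if s == "truncated"),
        "orfan_ids": orfan_ids,
        "pac_position": spec.pac_position,
        "variant_length": len(variant),
        "seed": spec.seed,
    }
    return Fixture(wt=wt, variant=variant, orfs=orfs, event=event, truth=truth)


def write_fixture(fx: Fixture, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _io.write_fasta([fx.wt], out / "wt.fasta")
    _io.write_fasta([fx.variant], out / "variant.fasta")
    _io.write_gff3(fx.orfs, fx.wt.id, out / "annotation.gff3")
    (out / "truth.json").write_text(json.dumps(fx.truth, indent=1))


def orfan_protein_lengths(fx: Fixture) -> dict[str, int]:
    """Amino-acid query lengths of the fixture's ORFan proteins (nt/3)."""
    return {o.orf_id: o.length // 3 for o in fx.orfs if o.is_orfan}


# ---------------------------------------------------------------------------
# Metagenomic hit tables

@dataclass(frozen=True)
class ClassSpec:
    """Per-salinity-class library configuration."""

    n_libraries: int
    db_size_range: tuple[float, float] = (1e8, 1e9)
    beta: float = 0.0  # expected hits per ORF per database nt
    read_length: int = 250
    paired_fraction: float = 1.0


@dataclass(frozen=True)
class MetagenomeSpec:
    """Planted structure of the synthetic metagenomic screen.

    True recruitment counts per (ORF, library) are Poisson with mean
    ``baseline_rate + beta_class * DB_S`` -- linear through the origin in
    database size by default, the simplest model consistent with a
    database-size-vs-hits correlation.  ``baseline_rate`` (default 0) exists
    for null-model studies where counts must vary without depending on
    DB_S.  True orthologs get identities uniform on (40, 95] and query
    coverages on (0.5, 1]; a ``boundary_fraction`` of them sit exactly at
    40.0% / 0.50 to pin the inclusive-threshold convention.  Decoys are
    planted below threshold, and with ``decoy_outscore_prob`` a true hit's
    reciprocal search is outscored by a decoy protein (failing BRBH).
    Long-read libraries carry multi-ORF reads to exercise synteny.
    """

    classes: tuple[tuple[str, ClassSpec], ...] = (
        ("marine", ClassSpec(n_libraries=8, beta=0.0, read_length=250, paired_fraction=0.5)),
        ("freshwater", ClassSpec(n_libraries=5, beta=1.5e-8, read_length=900, paired_fraction=1.0)),
        ("brackish", ClassSpec(n_libraries=3, beta=5e-9, read_length=900, paired_fraction=1.0)),
    )
    baseline_rate: float = 0.0
    boundary_fraction: float = 0.05
    decoy_outscore_prob: float = 0.10
    missing_reciprocal_prob: float = 0.02
    decoy_rate: float = 3.0
    multi_hit_fraction: float = 0.15
    mate_hit_prob: float = 0.70
    mate_noncyano_prob: float = 0.10
    mate_mixed_prob: float = 0.05
    identity_true: tuple[float, float] = (40.0, 95.0)
    identity_decoy: tuple[float, float] = (20.0, 39.5)
    seed: int = 0


@dataclass
class Metagenome:
    hits: pd.DataFrame
    reciprocal: pd.DataFrame
    meta: pd.DataFrame
    taxonomy: pd.DataFrame
    mate_hits: pd.DataFrame
    truth: dict


_CYANO_POOL = [f"cyanophage_p{i:02d}" for i in range(20)]
_BACT_POOL = [f"bact_p{i:02d}" for i in range(10)]


def _default_query_lengths(n: int = 33, rng: np.random.Generator | None = None) -> dict[str, int]:
    rng = rng or np.random.default_rng(0)
    # even aa lengths so an exact 0.50 coverage boundary is representable
    return {f"ORF{18 + i:03d}": int(rng.integers(30, 76)) * 2 for i in range(n)}


class _HitFactory:
    """Builds hit-table rows plus per-hit truth flags for one library."""

    def __init__(self, spec: MetagenomeSpec, rng: np.random.Generator, lib: str, cspec: ClassSpec):
        self.spec, self.rng, self.lib, self.cspec = spec, rng, lib, cspec
        self.rows: list[list] = []
        self.flags: list[dict] = []
        self.reciprocal: list[list] = []
        self.counter = 0
        self.decoy_counter = 0

    def new_read(self) -> str:
        rid = f"{self.lib}|r{self.counter:06d}"
        self.counter += 1
        if self.rng.random() < self.cspec.paired_fraction:
            rid += "/1"
        return rid

    def add_true_hit(self, orf: str, qlen: int, read_id: str, block: int, n_blocks: int) -> None:
        rng, spec = self.rng, self.spec
        rl = self.cspec.read_length
        max_qspan = min(qlen, (rl // n_blocks - 10) // 3)
        boundary = rng.random() < spec.boundary_fraction and qlen % 2 == 0 and qlen // 2 <= max_qspan
        if boundary:
            pident = 40.0
            qspan = qlen // 2  # coverage exactly 0.50
        else:
            lo, hi = spec.identity_true
            pident = round(float(rng.uniform(lo + 0.05, hi)), 1)
            min_qspan = int(np.ceil(0.505 * qlen))
            if min_qspan > max_qspan:
                min_qspan = max_qspan
            qspan = int(rng.integers(min_qspan, max_qspan + 1))
        qstart = int(rng.integers(1, qlen - qspan + 2))
        nt_span = 3 * qspan
        block_width = rl // n_blocks
        s0 = block * block_width + int(rng.integers(0, max(1, block_width - nt_span)))
        strand_plus = bool(rng.random() < 0.5)
        sstart, send = (s0 + 1, s0 + nt_span) if strand_plus else (s0 + nt_span, s0 + 1)
        mismatch = int(round(qspan * (1 - pident / 100)))
        evalue = 10.0 ** -float(rng.uniform(6, 30))
        bitscore = round(2.0 * qspan * pident / 100 + float(rng.uniform(0, 10)), 1)
        self.rows.append(
            [orf, read_id, pident, qspan, mismatch, 0, qstart, qstart + qspan - 1,
             sstart, send, evalue, bitscore, qlen]
        )
        reg = region_key(read_id, sstart, send)
        missing = rng.random() < spec.missing_reciprocal_prob
        outscored = (not missing) and rng.random() < spec.decoy_outscore_prob
        if not missing:
            rbit = bitscore + float(rng.uniform(5, 20))
            self.reciprocal.append([reg, orf, round(rbit, 1), evalue])
            if outscored:
                decoy = f"DECOY{self.decoy_counter:04d}"
                self.decoy_counter += 1
                self.reciprocal.append([reg, decoy, round(rbit + float(rng.uniform(1, 10)), 1), evalue])
        self.flags.append(
            {
                "read_id": read_id, "orf": orf, "library_id": self.lib,
                "passes_filter": True, "reciprocal_missing": missing,
                "brbh_valid": (not missing) and (not outscored),
                "strand": "+" if strand_plus else "-", "smin": min(sstart, send),
            }
        )

    def add_decoy_hit(self, orf: str, qlen: int) -> None:
        rng, spec = self.rng, self.spec
        rl = self.cspec.read_length
        read_id = self.new_read()
        if rng.random() < 0.5:  # sub-threshold identity, good coverage
            pident = round(float(rng.uniform(*spec.identity_decoy)), 1)
            cov = float(rng.uniform(0.5, 1.0))
        else:  # good identity, sub-threshold coverage
            pident = round(float(rng.uniform(40.05, 95.0)), 1)
            cov = float(rng.uniform(0.2, 0.49))
        qspan = max(5, min(int(cov * qlen), (rl - 10) // 3))
        if qspan / qlen >= 0.5 and pident >= 40.0:
            pident = round(float(rng.uniform(*spec.identity_decoy)), 1)
        qstart = int(rng.integers(1, qlen - qspan + 2))
        nt_span = 3 * qspan
        s0 = int(rng.integers(0, max(1, rl - nt_span)))
        strand_plus = bool(rng.random() < 0.5)
        sstart, send = (s0 + 1, s0 + nt_span) if strand_plus else (s0 + nt_span, s0 + 1)
        mismatch = int(round(qspan * (1 - pident / 100)))
        self.rows.append(
            [orf, read_id, pident, qspan, mismatch, 0, qstart, qstart + qspan - 1,
             sstart, send, 10.0 ** -float(rng.uniform(3, 6)), round(float(rng.uniform(30, 60)), 1), qlen]
        )
        self.flags.append(
            {
                "read_id": read_id, "orf": orf, "library_id": self.lib,
                "passes_filter": False, "reciprocal_missing": False,
                "brbh_valid": False, "strand": "+" if strand_plus else "-",
                "smin": min(sstart, send),
            }
        )


def gen_metagenome(
    spec: MetagenomeSpec = MetagenomeSpec(),
    query_lengths: Mapping[str, int] | None = None,
) -> Metagenome:
    """Generate hit tables, reciprocal tables, library metadata, a taxonomy
    map, mate-read hits and an exact truth record.

    ``query_lengths`` maps ORFan protein ids to amino-acid lengths; by
    default a 33-protein set with even lengths of 60-150 aa is synthesised
    (random ORF translations; the pipeline's logic is composition-agnostic).
    Deterministic for a given spec (single seeded stream).
    """
    rng = np.random.default_rng(spec.seed)
    qlens = dict(query_lengths) if query_lengths else _default_query_lengths(rng=rng)
    orf_ids = sorted(qlens)
    if not any(c.n_libraries >= 3 for _, c in spec.classes):
        raise ValueError("at least one salinity class needs >= 3 libraries")

    meta_rows = []
    factories: list[_HitFactory] = []
    mate_rows: list[list] = []
    mate_labels: dict[str, str] = {}
    multi_reads: dict[str, list[tuple[str, str]]] = {}  # read -> ordered (orf, strand)

    for cls, cspec in spec.classes:
        lo, hi = cspec.db_size_range
        if not (hi > lo > 0):
            raise ValueError(f"empty db_size_range for class {cls}")
        for i in range(cspec.n_libraries):
            lib = f"{cls[:2].upper()}{i:02d}"
            db_s = float(rng.uniform(lo, hi))
            meta_rows.append([lib, int(db_s), cls])
            fac = _HitFactory(spec, rng, lib, cspec)

            lam = spec.baseline_rate + cspec.beta * db_s
            counts = rng.poisson(lam, size=len(orf_ids))
            # single-ORF reads
            for orf, n in zip(orf_ids, counts):
                for _ in range(int(n)):
                    rid = fac.new_read()
                    fac.add_true_hit(orf, qlens[orf], rid, block=0, n_blocks=1)
                    _maybe_mate(spec, rng, rid, mate_rows, mate_labels)
            # multi-ORF (synteny) reads on long-read libraries
            if cspec.read_length >= 600 and spec.multi_hit_fraction > 0:
                n_multi = int(rng.poisson(spec.multi_hit_fraction * counts.sum() / 2.0))
                for _ in range(n_multi):
                    m = int(rng.integers(2, 4))
                    anchor = int(rng.integers(0, max(1, len(orf_ids) - m + 1)))
                    chosen = orf_ids[anchor : anchor + m]
                    order = rng.permutation(len(chosen))
                    rid = fac.new_read()
                    for block, j in enumerate(order):
                        fac.add_true_hit(chosen[j], qlens[chosen[j]], rid, block=block, n_blocks=len(chosen))
                    _maybe_mate(spec, rng, rid, mate_rows, mate_labels)
            # sub-threshold decoys
            for _ in range(int(rng.poisson(spec.decoy_rate))):
                orf = orf_ids[int(rng.integers(0, len(orf_ids)))]
                fac.add_decoy_hit(orf, qlens[orf])
            factories.append(fac)

    hits = pd.DataFrame(
        [r for f in factories for r in f.rows], columns=HIT_COLUMNS + ["qlen"]
    )
    hits["strand"] = np.where(hits["sstart"] <= hits["send"], "+", "-")
    hits["query_orf_id"] = hits["qseqid"]
    hits["read_id"] = hits["sseqid"]
    hits["library_id"] = [r.split("|", 1)[0] for r in hits["sseqid"]]
    reciprocal = pd.DataFrame(
        [r for f in factories for r in f.reciprocal],
        columns=["region_id", "subject_id", "bitscore", "evalue"],
    )
    meta = pd.DataFrame(meta_rows, columns=["library_id", "db_size_nt", "salinity_class"])
    taxonomy = pd.DataFrame(
        [(s, "cyanophage") for s in _CYANO_POOL] + [(s, "non_cyanophage") for s in _BACT_POOL],
        columns=["subject_id", "group"],
    )
    mate_hits = pd.DataFrame(mate_rows, columns=["read_id", "subject_id", "bitscore", "sstart", "send"])

    flags = pd.DataFrame([fl for f in factories for fl in f.flags])
    valid = flags[flags["passes_filter"] & flags["brbh_valid"]]
    n_per_read = (
        valid.drop_duplicates(["orf", "library_id", "read_id"])
        .groupby(["orf", "library_id"]).size()
    )
    n_per_hit = valid.groupby(["orf", "library_id"]).size()
    # ordered valid ORFs per multi-hit read, by read coordinate
    synteny_pairs: dict[str, int] = {}
    for rid, grp in valid.groupby("read_id"):
        if len(grp) < 2:
            continue
        ordered = grp.sort_values("smin")["orf"].tolist()
        for a, b in zip(ordered, ordered[1:]):
            synteny_pairs[f"{a}->{b}"] = synteny_pairs.get(f"{a}->{b}", 0) + 1

    truth = {
        "seed": spec.seed,
        "query_lengths": qlens,
        "n_hits_total": len(hits),
        "n_valid_hits": int(len(valid)),
        "counts_per_read": {f"{o}|{l}": int(v) for (o, l), v in n_per_read.items()},
        "counts_per_hit": {f"{o}|{l}": int(v) for (o, l), v in n_per_hit.items()},
        "synteny_edge_weights": synteny_pairs,
        "synteny_total_weight": int(sum(synteny_pairs.values())),
        "mate_labels": mate_labels,
        "per_hit_flags": flags.to_dict(orient="list"),
    }
    return Metagenome(
        hits=hits, reciprocal=reciprocal, meta=meta, taxonomy=taxonomy,
        mate_hits=mate_hits, truth=truth,
    )


def _maybe_mate(spec, rng, read_id, mate_rows, mate_labels) -> None:
    if not read_id.endswith("/1"):
        return
    mate_id = read_id[:-2] + "/2"
    u = rng.random()
    if u > spec.mate_hit_prob:
        mate_labels[mate_id] = "no_hit"
        return
    v = rng.random()
    if v < spec.mate_mixed_prob:
        # two well-separated regions with best hits in different groups
        _mate_region(rng, mate_rows, mate_id, 1, 300, _CYANO_POOL)
        _mate_region(rng, mate_rows, mate_id, 401, 700, _BACT_POOL)
        mate_labels[mate_id] = "mixed"
    elif v < spec.mate_mixed_prob + spec.mate_noncyano_prob:
        _mate_region(rng, mate_rows, mate_id, 1, 500, _BACT_POOL)
        mate_labels[mate_id] = "non_cyanophage"
    else:
        _mate_region(rng, mate_rows, mate_id, 1, 500, _CYANO_POOL)
        mate_labels[mate_id] = "cyanophage"


def _mate_region(rng, mate_rows, mate_id, lo, hi, pool) -> None:
    subject = pool[int(rng.integers(0, len(pool)))]
    s = int(rng.integers(lo, max(lo + 1, hi - 120)))
    e = s + int(rng.integers(90, 120))
    best = round(float(rng.uniform(60, 120)), 1)
    mate_rows.append([mate_id, subject, best, s, e])
    if rng.random() < 0.3:  # weaker secondary hit on the same region
        other = pool[int(rng.integers(0, len(pool)))]
        mate_rows.append([mate_id, other, round(best - float(rng.uniform(5, 30)), 1), s + 5, e - 5])


def write_metagenome(mg: Metagenome, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mg.hits.to_csv(out / "hits.tsv", sep="\t", header=False, index=False,
                   columns=HIT_COLUMNS + ["qlen"])
    mg.reciprocal.to_csv(out / "reciprocal.tsv", sep="\t", index=False)
    mg.meta.to_csv(out / "libraries.tsv", sep="\t", index=False)
    mg.taxonomy.to_csv(out / "taxonomy.tsv", sep="\t", index=False)
    mg.mate_hits.to_csv(out / "mate_hits.tsv", sep="\t", index=False)
    truth = {k: v for k, v in mg.truth.items() if k != "per_hit_flags"}
    (out / "truth.json").write_text(json.dumps(truth, indent=1))


# ---------------------------------------------------------------------------
# Canonical simulation scenarios

def gen_redundancy_scenario(
    genome_length: int = 50_000, pac_position: int = 20_000, seed: int = 0
):
    """Genome + packaging config for the terminal-redundancy fold study.

    Single-headful series (k=1) at 3% redundancy on a 50-kb genome,
    ~100x total depth of 100-nt reads from a minimal-insert
    (overlapping-pair) library, insert 102 +/- 2 nt.  The short insert is
    deliberate: inserts cannot extend past headful fragment ends, so the
    plain in/out depth-ratio estimate of the redundancy fold is biased low
    by about insert_length / window_width; with the insert pinned near the
    read length the expectation stays within a few percent of the ideal
    (k+1)/k = 2 (see the methods note for the derivation).
    """
    from .packaging_sim import PackagingConfig

    rng = np.random.default_rng(seed)
    genome = Genome(
        id="redundancy_fixture",
        sequence="".join(_random_sequence(rng, genome_length, 0.5)),
        circular=True,
    )
    config = PackagingConfig(
        genotype_mix=((genome, 1.0),),
        pac_position=pac_position,
        redundancy_fraction=0.03,
        headfuls_per_series=1,
        n_series=200,
        read_length=100,
        insert_mean=102.0,
        insert_sd=2.0,
        error_rate=0.0,
        depth=100.0,
        seed=seed + 1,
    )
    return genome, config


def gen_deletion_scenario(fixture: Fixture, depth: float = 160.0, seed: int = 0):
    """Packaging config for re-sequencing the deletion genotype only:
    error-free 2 x 250 nt pairs at >= 150x from the deleted variant, to be
    mapped back against the wild-type fixture."""
    from .packaging_sim import PackagingConfig

    return PackagingConfig(
        genotype_mix=((fixture.variant, 1.0),),
        pac_position=fixture.truth["pac_position"],
        redundancy_fraction=0.03,
        headfuls_per_series=1,
        n_series=200,
        read_length=250,
        insert_mean=450.0,
        insert_sd=50.0,
        error_rate=0.0,
        depth=depth,
        seed=seed + 1,
    )


# ---------------------------------------------------------------------------
# Plaque radii

def gen_plaque_radii(
    n_per_group: int = 34,
    mean_ratio: float = 6.0,
    cv: float = 0.15,
    mean_small_mm: float = 0.25,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Two lognormal plaque-radius samples with a planted mean ratio.

    The wild-type strain gets the smaller plaques (mean ``mean_small_mm``),
    the deletion strain ``mean_ratio`` times larger; both share coefficient
    of variation ``cv``.  Returns a (group, radius_mm) frame and a truth
    record with the true means.
    """
    if mean_ratio <= 0 or cv <= 0 or mean_small_mm <= 0:
        raise ValueError("mean_ratio, cv and mean_small_mm must be positive")
    rng = np.random.default_rng(seed)
    sigma2 = np.log1p(cv * cv)
    sigma = float(np.sqrt(sigma2))
    rows = []
    means = {"WT": mean_small_mm, "deletion": mean_small_mm * mean_ratio}
    for group in ("WT", "deletion"):
        mu = np.log(means[group]) - sigma2 / 2
        for r in rng.lognormal(mu, sigma, size=n_per_group):
            rows.append([group, round(float(r), 4)])
    df = pd.DataFrame(rows, columns=["group", "radius_mm"])
    truth = {
        "n_per_group": n_per_group,
        "true_mean_wt_mm": means["WT"],
        "true_mean_deletion_mm": means["deletion"],
        "true_ratio": mean_ratio,
        "cv": cv,
        "seed": seed,
    }
    return df, truth


def write_plaque_radii(df: pd.DataFrame, truth: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "radii.csv", index=False)
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
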