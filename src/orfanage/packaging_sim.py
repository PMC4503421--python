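"""Headful-packaging simulator with an analytic expected-coverage oracle.

Model
-----
T4-like phages package DNA by a headful mechanism: a terminase makes a first
cut at a *pac* site on a genome concatemer and then fills capsids
sequentially, cutting whenever the head is full.  Each headful holds
slightly more than one genome length -- a redundancy fraction ``r`` (about
3% in T4-like phages) -- so consecutive headfuls start at positions that
drift by ``r * G`` around the circular genome map (circular permutation) and
every packaged molecule carries terminally redundant ends.

Consequences modelled here:

* a *series* of ``k`` headfuls cut from one concatemer yields fragments
  starting at ``pac + m * L_h (mod G)`` with headful length
  ``L_h = round((1 + r) * G)``;
* positions in the arc ``[pac, pac + k*r*G)`` occur ``k + 1`` times among
  the fragments of a series while all other positions occur ``k`` times, so
  the expected read depth just downstream of the pac site is elevated by a
  factor ``(k + 1) / k`` -- a factor of 2 for single-headful series;
* paired-end reads are drawn uniformly from within fragments, which also
  produces coverage ramps of roughly one insert length at fragment ends
  (see :func:`expected_coverage`).

Genotype mixtures (e.g. wild type plus a deletion variant) are supported:
each series draws its genotype by weight, so relative depth inside a region
deleted in one genotype estimates the mixture frequency.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_model import Genome, reverse_complement

PHRED40 = "I"  # constant placeholder quality; the pipeline never uses qualities


@dataclass(frozen=True)
class PackagingConfig:
    """Parameters of a packaging-plus-sequencing simulation.

    Parameters
    ----------
    genotype_mix
        Tuple of ``(Genome, weight)`` pairs; weights must sum to 1.
    pac_position
        1-based position of the first terminase cut.  For genotypes shorter
        than the position it is interpreted modulo the genotype length.
    redundancy_fraction
        Extra DNA packaged per headful, as a fraction of genome length
        (default 0.03).
    headfuls_per_series
        Number of headfuls cut from each concatemer (``k``); ``k * r`` must
        be < 1.
    n_series
        Number of independent packaging series.
    read_length, insert_mean, insert_sd
        Paired-end read geometry in nt.
    error_rate
        Per-base substitution probability.
    depth
        Target mean read depth (read bases per genome base) used to choose
        the number of inserts per fragment.
    seed
        Seed for the single pseudo-random stream driving all draws.
    """

    genotype_mix: tuple[tuple[Genome, float], ...]
    pac_position: int
    redundancy_fraction: float = 0.03
    headfuls_per_series: int = 1
    n_series: int = 200
    read_length: int = 250
    insert_mean: float = 450.0
    insert_sd: float = 50.0
    error_rate: float = 0.0
    depth: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.genotype_mix:
            raise ValueError("genotype_mix must contain at least one genotype")
        w = sum(weight for _, weight in self.genotype_mix)
        if any(weight < 0 for _, weight in self.genotype_mix):
            raise ValueError("genotype weights must be non-negative")
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"genotype weights must sum to 1 (got {w})")
        if self.redundancy_fraction < 0:
            raise ValueError("redundancy_fraction must be >= 0")
        if self.headfuls_per_series < 1:
            raise ValueError("headfuls_per_series must be >= 1")
        if self.headfuls_per_series * self.redundancy_fraction >= 1:
            raise ValueError(
                "unsupported overlap: headfuls_per_series * redundancy_fraction must be < 1"
            )
        if self.pac_position < 1:
            raise ValueError("pac_position must be >= 1")
        if self.n_series < 1:
            raise ValueError("n_series must be >= 1")

    def genome(self, genotype_id: str) -> Genome:
        for g, _ in self.genotype_mix:
            if g.id == genotype_id:
                return g
        raise KeyError(genotype_id)


@dataclass(frozen=True)
class PackagedFragment:
    """One headful: a linear molecule cut from a genotype's concatemer."""

    genotype_id: str
    start: int  # 1-based position on the circular genotype genome
    length: int


@dataclass
class ReadSet:
    """Simulated paired reads plus a machine-readable truth table."""

    pairs: list[tuple[str, str, str]]  # (read_id, R1 sequence, R2 sequence)
    truth: pd.DataFrame  # read_id, genotype, fragment_start, insert_start, insert_end, strand
    config: PackagingConfig = field(repr=False, default=None)

    def reads(self) -> list[tuple[str, str]]:
        """Flatten pairs into (read_id/1, seq), (read_id/2, seq) records."""
        out = []
        for rid, r1, r2 in self.pairs:
            out.append((f"{rid}/1", r1))
            out.append((f"{rid}/2", r2))
        return out

    def fastq_records(self) -> list[tuple[str, str, str]]:
        return [(rid, seq, PHRED40 * len(seq)) for rid, seq in self.reads()]


def headful_length(genome_length: int, redundancy_fraction: float) -> int:
    """Headful length ``round((1 + r) * G)``, rounding half up."""
    return int(math.floor(genome_length * (1.0 + redundancy_fraction) + 0.5))


def simulate_packaging(config: PackagingConfig) -> list[PackagedFragment]:
    """Cut ``n_series`` packaging series into headful fragments.

    Each series draws one genotype by weight (seeded) and emits
    ``headfuls_per_series`` fragments following the modular-start rule.
    Deterministic for a given config (including seed).
    """
    rng = np.random.default_rng(config.seed)
    genomes = [g for g, _ in config.genotype_mix]
    weights = np.array([w for _, w in config.genotype_mix])
    k = config.headfuls_per_series
    choices = rng.choice(len(genomes), size=config.n_series, p=weights)
    fragments: list[PackagedFragment] = []
    for gi in choices:
        g = genomes[gi]
        G = len(g)
        L_h = headful_length(G, config.redundancy_fraction)
        pac0 = (config.pac_position - 1) % G
        for m in range(k):
            start = (pac0 + m * L_h) % G + 1
            fragments.append(PackagedFragment(genotype_id=g.id, start=start, length=L_h))
    return fragments


def _circular_substring(doubled: str, G: int, start0: int, length: int) -> str:
    # doubled = seq + seq; start0 is 0-based < G; length <= G assumed
    return doubled[start0 : start0 + length]


def simulate_reads(fragments: list[PackagedFragment], config: PackagingConfig) -> ReadSet:
    """Sample paired-end reads uniformly from within each fragment.

    The number of inserts is the same for every fragment and is chosen so
    total read bases approximate ``config.depth`` per genome base.  R1 is the
    forward strand of the insert, R2 the reverse complement of its other
    end.  Per-base substitution errors are applied at ``error_rate``.
    Deterministic for a given config.
    """
    if not fragments:
        return ReadSet(pairs=[], truth=_empty_truth(), config=config)
    rng = np.random.default_rng(config.seed + 1)
    rl = config.read_length
    mean_G = sum(len(g) * w for g, w in config.genotype_mix)
    total_inserts = config.depth * mean_G / (2 * rl)
    per_fragment = max(1, int(round(total_inserts / len(fragments))))

    doubled = {g.id: g.sequence * 2 for g, _ in config.genotype_mix}
    lengths = {g.id: len(g) for g, _ in config.genotype_mix}
    for g, _ in config.genotype_mix:
        _check_n_runs(g, rl)

    pairs: list[tuple[str, str, str]] = []
    truth_rows: list[tuple] = []
    counter = 0
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for frag in fragments:
        if config.insert_mean > frag.length:
            raise ValueError("insert_mean exceeds fragment length")
        for _ in range(per_fragment):
            ins = _draw_insert_length(rng, config, frag.length)
            offset = int(rng.integers(0, frag.length - ins + 1))
            G = lengths[frag.genotype_id]
            start0 = ((frag.start - 1) + offset) % G
            insert_seq = _circular_substring(doubled[frag.genotype_id], G, start0, ins)
            r1 = insert_seq[:rl]
            r2 = reverse_complement(insert_seq[-rl:])
            if config.error_rate > 0:
                r1 = _mutate(r1, config.error_rate, rng, bases)
                r2 = _mutate(r2, config.error_rate, rng, bases)
            rid = f"r{counter:08d}"
            counter += 1
            pairs.append((rid, r1, r2))
            truth_rows.append(
                (rid, frag.genotype_id, frag.start, start0 + 1, start0 + ins, "+")
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "genotype", "fragment_start", "insert_start", "insert_end", "strand"],
    )
    return ReadSet(pairs=pairs, truth=truth, config=config)


def _empty_truth() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["read_id", "genotype", "fragment_start", "insert_start", "insert_end", "strand"]
    )


def _draw_insert_length(rng: np.random.Generator, config: PackagingConfig, frag_len: int, max_retries: int = 100) -> int:
    rl = config.read_length
    for _ in range(max_retries):
        ins = int(round(rng.normal(config.insert_mean, config.insert_sd)))
        if rl <= ins <= frag_len:
            return ins
    raise RuntimeError(
        f"could not draw an insert length in [{rl}, {frag_len}] after {max_retries} tries"
    )


def _mutate(seq: str, error_rate: float, rng: np.random.Generator, bases: np.ndarray) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    for i in hits:
        alternatives = bases[bases != arr[i]]
        arr[i] = alternatives[rng.integers(0, len(alternatives))]
    return arr.tobytes().decode()


def _check_n_runs(genome: Genome, read_length: int) -> None:
    run = 0
    for ch in genome.sequence:
        run = run + 1 if ch == "N" else 0
        if run >= read_length:
            raise ValueError(
                f"genome {genome.id} contains an N-run of >= read length; refusing to place reads"
            )


def expected_fold_change(redundancy_fraction: float, headfuls_per_series: int) -> float:
    """Expected depth inside ``[pac, pac + k*r*G)`` relative to outside.

    Positions in that window occur ``k + 1`` times per series versus ``k``
    elsewhere, giving ``(k + 1) / k``; with no redundancy the profile is
    flat (1.0).  For single-headful packaging this is the "two copies
    downstream of the cut site" factor of 2.
    """
    r, k = redundancy_fraction, headfuls_per_series
    if k < 1:
        raise ValueError("headfuls_per_series must be >= 1")
    if r < 0:
        raise ValueError("redundancy_fraction must be >= 0")
    if k * r >= 1:
        raise ValueError("headfuls_per_series * redundancy_fraction must be < 1")
    if r == 0:
        return 1.0
    return (k + 1) / k


def redundant_window(config: PackagingConfig, genotype_id: str | None = None) -> tuple[int, int]:
    """The terminally redundant arc ``[pac, pac + k*(L_h - G))`` as 1-based
    inclusive positions (start, end) on the genotype's circular genome."""
    g = config.genotype_mix[0][0] if genotype_id is None else config.genome(genotype_id)
    G = len(g)
    L_h = headful_length(G, config.redundancy_fraction)
    width = config.headfuls_per_series * (L_h - G)
    pac0 = (config.pac_position - 1) % G
    start = pac0 + 1
    end = (pac0 + width - 1) % G + 1
    return start, end


def _fragment_end_ramp(L_h: int, rl: int, ins: int) -> np.ndarray:
    """Relative read coverage along one fragment (interior == 1).

    Inserts start uniformly in ``[0, L_h - ins]``; R1 covers the first
    ``rl`` bases of the insert and R2 the last ``rl``.  Coverage therefore
    ramps up over roughly one insert length at the left fragment end and
    symmetrically down at the right end.
    """
    t = np.arange(L_h, dtype=np.float64)
    s_max = L_h - ins  # largest valid insert start (0-based)
    # R1 covers t iff insert start s in [t - rl + 1, t] ∩ [0, s_max]
    lo = np.maximum(t - rl + 1, 0.0)
    hi = np.minimum(t, s_max)
    r1 = np.clip(hi - lo + 1.0, 0.0, rl)
    # R2 covers t iff s in [t - ins + 1, t - ins + rl] ∩ [0, s_max]
    lo2 = np.maximum(t - ins + 1, 0.0)
    hi2 = np.minimum(t - ins + rl, s_max)
    r2 = np.clip(hi2 - lo2 + 1.0, 0.0, rl)
    return (r1 + r2) / (2.0 * rl)


def expected_coverage(config: PackagingConfig) -> dict[str, np.ndarray]:
    """Analytic expected relative read depth per genotype (mean ~ 1 within a
    genotype's own reads).

    Accounts for both the ``k+1`` vs ``k`` copy number of the terminally
    redundant window and the insert-length coverage ramps at fragment ends
    (computed with ``insert_mean`` as the insert length).  Serves as the
    oracle for Monte-Carlo depth profiles.
    """
    out: dict[str, np.ndarray] = {}
    k = config.headfuls_per_series
    for g, _ in config.genotype_mix:
        G = len(g)
        L_h = headful_length(G, config.redundancy_fraction)
        ramp = _fragment_end_ramp(L_h, config.read_length, int(round(config.insert_mean)))
        profile = np.zeros(G, dtype=np.float64)
        pac0 = (config.pac_position - 1) % G
        for m in range(k):
            start = (pac0 + m * L_h) % G
            idx = (start + np.arange(L_h)) % G
            np.add.at(profile, idx, ramp)
        out[g.id] = profile / profile.mean()
    return out
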