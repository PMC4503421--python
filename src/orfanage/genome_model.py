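"""Reference genome and ORF annotation handling for a phage genome carrying a
large dispensable locus.

Coordinate convention
---------------------
All coordinates are 1-based and inclusive (GFF3 convention).  A deletion is
recorded as ``(left_retained, right_deleted)``: the last base kept before the
gap and the last base removed.  The deleted interval is therefore
``left_retained + 1 .. right_deleted`` and the deleted length is
``right_deleted - left_retained``.  With breakpoints (5799, 15339) this
convention yields a 9540-nt deletion, matching the arithmetic used for the
S-PM2 ORFanage locus.
"""
from __future__ import annotations

from dataclasses import dataclass, field

ALPHABET = frozenset("ACGTN")

ORF_RETAINED = "retained"
ORF_FULLY_DELETED = "fully_deleted"
ORF_TRUNCATED = "truncated"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Genome:
    """A single reference nucleotide sequence.

    Parameters
    ----------
    id
        Text label, e.g. ``"S-PM2_WT"``.
    sequence
        Uppercase string over {A, C, G, T, N}.
    circular
        Whether the molecule is (effectively) circular.  Phage genomes that
        are circularly permuted by headful packaging behave as circular for
        read simulation and mapping even though each virion carries a linear
        molecule.
    """

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("genome sequence must be non-empty")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValueError(f"genome contains characters outside ACGTN: {sorted(bad)!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Base at 1-based position ``pos``."""
        if not 1 <= pos <= len(self.sequence):
            raise IndexError(f"position {pos} outside 1..{len(self.sequence)}")
        return self.sequence[pos - 1]


@dataclass(frozen=True)
class OrfRecord:
    """One annotated ORF with 1-based inclusive coordinates."""

    orf_id: str
    start: int
    end: int
    strand: str = "+"
    is_orfan: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"{self.orf_id}: require 1 <= start <= end, got [{self.start}, {self.end}]")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.orf_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def validate_against(self, genome_length: int) -> None:
        if self.end > genome_length:
            raise ValueError(f"{self.orf_id}: end {self.end} beyond genome length {genome_length}")


@dataclass(frozen=True)
class DeletionEvent:
    """A deletion stored as (last retained base, last deleted base).

    ``length == right_deleted - left_retained``; the removed bases are
    ``left_retained + 1 .. right_deleted``.
    """

    left_retained: int
    right_deleted: int

    def __post_init__(self) -> None:
        if self.left_retained < 1:
            raise ValueError("left_retained must be >= 1")
        if self.right_deleted <= self.left_retained:
            raise ValueError(
                f"right_deleted ({self.right_deleted}) must exceed left_retained ({self.left_retained})"
            )

    @property
    def length(self) -> int:
        return self.right_deleted - self.left_retained

    def validate_against(self, genome_length: int) -> None:
        if self.right_deleted > genome_length:
            raise ValueError(
                f"right_deleted {self.right_deleted} beyond genome length {genome_length}"
            )


@dataclass
class OrfClassification:
    """Per-ORF status against a deletion, plus summary counts."""

    status: dict[str, str] = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return sum(1 for s in self.status.values() if s == ORF_RETAINED)

    @property
    def n_fully_deleted(self) -> int:
        return sum(1 for s in self.status.values() if s == ORF_FULLY_DELETED)

    @property
    def n_truncated(self) -> int:
        return sum(1 for s in self.status.values() if s == ORF_TRUNCATED)

    @property
    def n_affected(self) -> int:
        """Count of ORFs fully deleted or truncated by the event."""
        return self.n_fully_deleted + self.n_truncated


def apply_deletion(genome: Genome, event: DeletionEvent, id_suffix: str = "d") -> Genome:
    """Remove the bases ``event.left_retained + 1 .. event.right_deleted``.

    Returns a new :class:`Genome` whose id is suffixed to mark the variant.
    The output length is ``len(genome) - event.length``.
    """
    event.validate_against(len(genome))
    seq = genome.sequence
    new_seq = seq[: event.left_retained] + seq[event.right_deleted :]
    return Genome(id=f"{genome.id}_{id_suffix}", sequence=new_seq, circular=genome.circular)


def classify_orfs(orfs: list[OrfRecord], event: DeletionEvent) -> OrfClassification:
    """Classify each ORF as retained, fully deleted or truncated.

    An ORF is *fully deleted* iff it lies entirely inside the removed
    interval (``start > left_retained and end <= right_deleted``), *retained*
    iff it does not overlap the removed interval at all, and *truncated*
    otherwise.  The three statuses partition the ORF set.
    """
    out = OrfClassification()
    L, R = event.left_retained, event.right_deleted
    for orf in orfs:
        if orf.start > L and orf.end <= R:
            out.status[orf.orf_id] = ORF_FULLY_DELETED
        elif orf.end <= L or orf.start > R:
            out.status[orf.orf_id] = ORF_RETAINED
        else:
            out.status[orf.orf_id] = ORF_TRUNCATED
    return out


def junction_sequence(genome: Genome, event: DeletionEvent, flank: int = 20) -> str:
    """Sequence created by the deletion: ``flank`` bases either side of the
    new junction, i.e. bases ``L-flank+1..L`` joined to ``R+1..R+flank``.

    The returned string has length ``2 * flank`` and occurs verbatim in the
    deleted-variant genome at position ``L - flank + 1``.
    """
    if flank < 1:
        raise ValueError("flank must be positive")
    event.validate_against(len(genome))
    L, R = event.left_retained, event.right_deleted
    if L < flank or R + flank > len(genome):
        raise ValueError(
            f"flank {flank} exceeds available sequence around breakpoints ({L}, {R})"
        )
    seq = genome.sequence
    return seq[L - flank : L] + seq[R : R + flank]
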