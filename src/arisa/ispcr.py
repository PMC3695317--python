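"""In-silico PCR with degenerate primers and spacer-length arithmetic.

The methanogen-specific primer pair anneals inside the 16S and 23S rRNA
genes, so every product carries 202 bp of 16S and 170 bp of 23S sequence
around the intergenic spacer: the spacer length is the amplicon length minus
372 bp, and only amplicons longer than 372 bp can contain a spacer at all.
This module predicts amplicons from rRNA-operon sequences by IUPAC-aware
primer matching, derives spacer lengths, and maps observed fragment bins
back to candidate source taxa — including the legitimate case of one
multi-operon organism claiming several bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .models import DEFAULT_FLANK_16S, DEFAULT_FLANK_23S
from .peaks import BinTable

__all__ = [
    "IUPAC_CODES",
    "Primer",
    "PAPER_PRIMERS",
    "AmpliconPrediction",
    "expand_degeneracies",
    "find_binding_sites",
    "predict_amplicons",
    "assign_bins_to_taxa",
    "read_operon_fasta",
]

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


@dataclass(frozen=True)
class Primer:
    """An oligonucleotide, possibly degenerate (IUPAC multi-base codes)."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.replace(" ", "").upper()
        if not seq:
            raise ValueError("empty primer sequence")
        bad = sorted(set(seq) - set(IUPAC_CODES))
        if bad:
            raise ValueError(f"primer {self.name!r}: invalid IUPAC characters {bad}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> str:
        return "".join(_COMPLEMENT[c] for c in reversed(self.sequence))


# The 16S/23S spacer-spanning methanogen primer pair (degenerate positions
# written as IUPAC codes: S = C/G, Y = C/T, V = A/C/G, N = any, R = A/G).
PAPER_PRIMERS: dict[str, Primer] = {
    "16S-RIS-M": Primer("16S-RIS-M", "TGAAGCTGGAATSCGTAGTAATCGC"),
    "23S-RIS-M": Primer("23S-RIS-M", "CTAAGATGTTTCAATYCVSNRSGTTCC"),
}


def expand_degeneracies(primer: Primer, enumeration_cap: int = 1024) -> tuple[int, list[str] | None]:
    """Number of non-degenerate variants, with the enumeration when small.

    The count is the product of per-position IUPAC code cardinalities; the
    explicit variant list is returned only when the count does not exceed
    ``enumeration_cap`` (None otherwise).
    """
    count = 1
    for c in primer.sequence:
        count *= len(IUPAC_CODES[c])
    if count > enumeration_cap:
        return count, None
    variants = ["".join(v) for v in product(*(sorted(IUPAC_CODES[c]) for c in primer.sequence))]
    return count, variants


def _mismatches(window: str, primer_seq: str, limit: int) -> int | None:
    """Mismatch count of a window vs a degenerate primer, or None past limit.

    An ambiguous base in the *target* (anything outside A/C/G/T, e.g. N in a
    draft sequence) counts as a mismatch against any primer position.
    """
    mm = 0
    for base, code in zip(window, primer_seq):
        if base not in IUPAC_CODES[code] or base not in "ACGT":
            mm += 1
            if mm > limit:
                return None
    return mm


@dataclass(frozen=True)
class BindingSite:
    position: int  # 0-based start of the site on the forward strand
    strand: str  # '+': primer extends rightward; '-': primer extends leftward
    mismatches: int

    @property
    def as_tuple(self) -> tuple[int, str, int]:
        return (self.position, self.strand, self.mismatches)


def find_binding_sites(sequence: str, primer: Primer, max_mismatches: int = 0) -> list[BindingSite]:
    """All primer binding sites on both strands of a sequence.

    Coordinates are 0-based half-open on the forward strand: a '+' site at
    position p occupies ``sequence[p : p + len(primer)]`` and the primer
    extends rightward; a '-' site means the primer anneals to the reverse
    strand over the same interval and extends leftward.
    """
    seq = sequence.upper()
    L = len(primer)
    if L > len(seq):
        raise ValueError("primer longer than target sequence")
    rc = primer.reverse_complement()
    sites: list[BindingSite] = []
    for p in range(len(seq) - L + 1):
        window = seq[p : p + L]
        mm = _mismatches(window, primer.sequence, max_mismatches)
        if mm is not None:
            sites.append(BindingSite(p, "+", mm))
        mm = _mismatches(window, rc, max_mismatches)
        if mm is not None:
            sites.append(BindingSite(p, "-", mm))
    return sites


@dataclass(frozen=True)
class AmpliconPrediction:
    """One predicted PCR product and its derived spacer length.

    ``ris_length`` is the amplicon length minus the 16S and 23S flanks and is
    None for products too short to contain a spacer (the 372 bp boundary
    case of the default flanks gives ris_length = 0, flagged by
    ``has_spacer``).
    """

    sequence_id: str
    fwd_position: int
    fwd_strand: str
    rev_position: int
    rev_strand: str
    amplicon_length: int
    ris_length: int | None
    fwd_mismatches: int = 0
    rev_mismatches: int = 0

    @property
    def has_spacer(self) -> bool:
        return self.ris_length is not None and self.ris_length > 0


def read_operon_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTA file of rRNA-operon sequences."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def predict_amplicons(
    sequences: Iterable[tuple[str, str]] | str | Path,
    forward: Primer,
    reverse: Primer,
    max_len: int = 3000,
    max_mismatches: int = 0,
    flank_16s: int = DEFAULT_FLANK_16S,
    flank_23s: int = DEFAULT_FLANK_23S,
) -> list[AmpliconPrediction]:
    """All convergent forward/reverse products up to ``max_len``.

    Both template orientations are scanned (forward primer on either
    strand, reverse primer on the other); every convergent, non-overlapping
    site pair is reported — nested alternative products are all kept, since
    multi-band patterns from one template are biologically meaningful.
    """
    if isinstance(sequences, (str, Path)):
        sequences = read_operon_fasta(sequences)

    predictions: list[AmpliconPrediction] = []
    min_len = len(forward) + len(reverse)
    for seq_id, seq in sequences:
        fwd_sites = find_binding_sites(seq, forward, max_mismatches)
        rev_sites = find_binding_sites(seq, reverse, max_mismatches)
        for f in fwd_sites:
            for r in rev_sites:
                if f.strand == r.strand:
                    continue  # divergent or tandem, not a convergent pair
                if f.strand == "+":
                    left, right = f, r
                    l_len, r_len = len(forward), len(reverse)
                else:
                    left, right = r, f
                    l_len, r_len = len(reverse), len(forward)
                if left.strand != "+" or right.strand != "-":
                    continue
                length = right.position + r_len - left.position
                if length < max(min_len, l_len, r_len) or length > max_len:
                    continue
                if right.position < left.position + l_len:
                    continue  # overlapping primer sites cannot extend
                ris = length - flank_16s - flank_23s
                predictions.append(
                    AmpliconPrediction(
                        sequence_id=seq_id,
                        fwd_position=f.position,
                        fwd_strand=f.strand,
                        rev_position=r.position,
                        rev_strand=r.strand,
                        amplicon_length=length,
                        ris_length=ris if ris >= 0 else None,
                        fwd_mismatches=f.mismatches,
                        rev_mismatches=r.mismatches,
                    )
                )
    predictions.sort(key=lambda p: (p.sequence_id, p.fwd_position, p.amplicon_length))
    return predictions


@dataclass(frozen=True)
class BinAssignment:
    bin_index: int
    bin_center: float
    candidates: tuple[tuple[str, int], ...]  # (taxon/sequence id, amplicon length)

    @property
    def assigned(self) -> bool:
        return len(self.candidates) > 0

    @property
    def ambiguous(self) -> bool:
        return len({t for t, _ in self.candidates}) > 1


def assign_bins_to_taxa(
    bin_table: BinTable,
    predictions: Sequence[AmpliconPrediction],
    tolerance: float = 0.05,
) -> list[BinAssignment]:
    """Match observed size bins to predicted amplicons within ±tolerance.

    Each bin lists every prediction whose amplicon length lies within the
    tolerance fraction (measured against the smaller of bin center and
    amplicon length, the conservative reading); a multi-operon taxon may
    claim several bins, and bins with no candidate are reported unassigned.
    """
    out: list[BinAssignment] = []
    for b, center in enumerate(bin_table.bin_centers):
        cands = []
        for p in predictions:
            lo, hi = sorted((float(p.amplicon_length), float(center)))
            if hi <= lo * (1.0 + tolerance):
                cands.append((p.sequence_id, p.amplicon_length))
        out.append(BinAssignment(bin_index=b, bin_center=float(center), candidates=tuple(sorted(set(cands)))))
    return out
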