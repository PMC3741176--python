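"""Sequence-level computations: FASTA I/O, mass, charge/pI, identity,
precursor parsing, codon arithmetic."""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .constants import (
    ACIDIC_GROUPS,
    AVERAGE_RESIDUE_MASS,
    BASIC_GROUPS,
    MONOISOTOPIC_RESIDUE_MASS,
    PKA_TABLES,
    STANDARD_AA,
    WATER_AVERAGE,
    WATER_MONOISOTOPIC,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_fasta",
    "write_fasta",
    "average_mass",
    "net_charge",
    "isoelectric_point",
    "IdentityResult",
    "pairwise_identity",
    "AnnotatedPrecursor",
    "parse_precursor",
    "codon_count",
]


def read_fasta(text: str) -> list[tuple[str, str]]:
    """Parse FASTA text into (id, sequence) pairs.

    Sequences are upper-cased; trailing '*' stop marks are stripped with a
    warning. Nonstandard residues like 'X' are accepted here and only rejected
    by the operations that cannot handle them (mass, pI).
    """
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not records:
        raise ValueError("empty or malformed FASTA input")
    out: list[tuple[str, str]] = []
    for rec in records:
        seq = str(rec.seq).upper()
        if "*" in seq:
            logger.warning("stripped stop mark(s) '*' from record %s", rec.id)
            seq = seq.replace("*", "")
        if not seq:
            raise ValueError(f"record {rec.id!r} has an empty sequence")
        illegal = {c for c in seq if not c.isalpha()}
        if illegal:
            raise ValueError(
                f"record {rec.id!r} contains illegal character(s): {sorted(illegal)}"
            )
        nonstandard = set(seq) - STANDARD_AA
        if nonstandard:
            logger.warning(
                "record %s contains nonstandard residue(s) %s; mass/pI will reject them",
                rec.id, sorted(nonstandard),
            )
        out.append((rec.id, seq))
    return out


def write_fasta(records: list[tuple[str, str]], width: int = 60) -> str:
    """Inverse of :func:`read_fasta` (up to line wrapping)."""
    buf = io.StringIO()
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records],
        buf,
        "fasta",
    )
    return buf.getvalue()


def _check_standard(sequence: str, what: str) -> None:
    if not sequence:
        raise ValueError(f"{what} undefined for an empty sequence")
    bad = set(sequence) - STANDARD_AA
    if bad:
        raise ValueError(f"{what} undefined: nonstandard residue(s) {sorted(bad)}")


def average_mass(
    sequence: str,
    tag_masses: list[float] | None = None,
    monoisotopic: bool = False,
) -> float:
    """Peptide mass in Da: residue masses + one water + any tag masses."""
    _check_standard(sequence, "mass")
    table = MONOISOTOPIC_RESIDUE_MASS if monoisotopic else AVERAGE_RESIDUE_MASS
    water = WATER_MONOISOTOPIC if monoisotopic else WATER_AVERAGE
    return sum(table[aa] for aa in sequence) + water + sum(tag_masses or [])


def net_charge(sequence: str, pH: float, pka_table: str | dict = "bjellqvist") -> float:
    """Henderson–Hasselbalch net charge at ``pH``, elementary charges.

    Positive groups (K, R, H side chains and the N-terminus) contribute
    1/(1+10^(pH-pKa)); negative groups (D, E, C, Y side chains and the
    C-terminus) contribute -1/(1+10^(pKa-pH)). Strictly decreasing in pH.
    """
    _check_standard(sequence, "charge")
    if not (0.0 <= pH <= 14.0):
        raise ValueError("invalid pH: must lie in [0, 14]")
    pka = PKA_TABLES[pka_table] if isinstance(pka_table, str) else pka_table
    charge = 1.0 / (1.0 + 10.0 ** (pH - pka["Nterm"]))
    charge -= 1.0 / (1.0 + 10.0 ** (pka["Cterm"] - pH))
    for aa in sequence:
        if aa in BASIC_GROUPS:
            charge += 1.0 / (1.0 + 10.0 ** (pH - pka[aa]))
        elif aa in ACIDIC_GROUPS:
            charge -= 1.0 / (1.0 + 10.0 ** (pka[aa] - pH))
    return charge


def isoelectric_point(
    sequence: str,
    pka_table: str | dict = "bjellqvist",
    tol: float = 1e-6,
) -> float:
    """pH of zero net charge, by bisection on the monotone charge curve."""
    lo, hi = 0.0, 14.0
    c_lo = net_charge(sequence, lo, pka_table)
    c_hi = net_charge(sequence, hi, pka_table)
    if c_lo < 0 or c_hi > 0:
        raise ValueError("no isoelectric point in range [0, 14]")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        c = net_charge(sequence, mid, pka_table)
        if abs(c) < tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class IdentityResult:
    """Pairwise identity as a rounded percent and as an exact fraction."""

    percent: int
    identities: int
    alignment_length: int

    @property
    def fraction(self) -> float:
        return self.identities / self.alignment_length


def pairwise_identity(a: str, b: str) -> IdentityResult:
    """Global-alignment percent identity.

    Needleman–Wunsch scoring: match +1, mismatch 0, linear gap -1. Identity
    is identical aligned positions over the alignment length (gaps included
    in the denominator).
    """
    if not a or not b:
        raise ValueError("empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    alignment = aligner.align(a, b)[0]
    counts = alignment.counts()
    length = alignment.length
    return IdentityResult(
        percent=round(100.0 * counts.identities / length),
        identities=int(counts.identities),
        alignment_length=int(length),
    )


@dataclass(frozen=True)
class AnnotatedPrecursor:
    """A zymogen precursor split into signal, activation and mature spans.

    Intervals are 1-based, closed. ``signal`` and ``activation_peptide`` cover
    a prefix; ``mature`` runs from the first occurrence of the start motif
    (IVGG for trypsins) to the C-terminus.
    """

    full_sequence: str
    signal: tuple[int, int]
    activation_peptide: tuple[int, int]
    mature: tuple[int, int]
    mature_start_motif: str = "IVGG"
    consistent: bool = True

    def _span(self, iv: tuple[int, int]) -> str:
        return self.full_sequence[iv[0] - 1 : iv[1]]

    @property
    def signal_sequence(self) -> str:
        return self._span(self.signal)

    @property
    def activation_sequence(self) -> str:
        return self._span(self.activation_peptide)

    @property
    def mature_sequence(self) -> str:
        return self._span(self.mature)


def parse_precursor(
    sequence: str,
    signal_length: int = 15,
    activation_length: int = 14,
    motif: str = "IVGG",
    expected_signal: str | None = None,
) -> AnnotatedPrecursor:
    """Split a trypsinogen precursor at its mature-start motif.

    The mature chain begins at the first ``motif`` occurrence; the signal
    peptide is the first ``signal_length`` residues and the activation
    peptide is whatever lies between. When signal + activation lengths do not
    meet the motif offset, the parse succeeds but is flagged inconsistent
    (with a warning) — the annotation lengths and the deposited sequence
    disagree and neither is silently adjusted.
    """
    idx = sequence.find(motif)
    if idx < 0:
        raise ValueError("mature start motif not found")
    consistent = signal_length + activation_length == idx
    if not consistent:
        logger.warning(
            "signal (%d) + activation (%d) = %d != mature-start offset %d; "
            "annotation lengths and sequence disagree",
            signal_length, activation_length, signal_length + activation_length, idx,
        )
    precursor = AnnotatedPrecursor(
        full_sequence=sequence,
        signal=(1, signal_length),
        activation_peptide=(signal_length + 1, idx),
        mature=(idx + 1, len(sequence)),
        mature_start_motif=motif,
        consistent=consistent,
    )
    if expected_signal is not None and precursor.signal_sequence != expected_signal:
        logger.warning("signal peptide differs from the annotated sequence")
    return precursor


def codon_count(orf_length_bp: int) -> int:
    """Amino acids encodable by an ORF of the given length: floor(bp/3)."""
    if orf_length_bp < 0:
        raise ValueError("invalid length")
    return orf_length_bp // 3
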