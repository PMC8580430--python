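"""Standard genetic code and anticodon->codon decoding relations.

Anticodons are handled in the DNA alphabet (T, not U), written 5'->3', so
string position 0 is tRNA base 34 — the wobble position that pairs with the
third codon base.  Decoding supports classical Watson–Crick pairing plus the
extended relations observed in metazoan translation: G:U wobble at the wobble
position (in both orientations, G34:U3 and U34:G3) and inosine pairing after
ADAT editing of A34 (I pairs with U, C or A).  Decoding never crosses
amino-acid families: an expansion whose codon encodes a different amino acid
than the Watson–Crick codon is discarded, and stop codons are never produced.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Iterable, Mapping, Set, Tuple

from Bio.Data import CodonTable
from Bio.Data.IUPACData import protein_letters_1to3

__all__ = [
    "STOP_CODONS",
    "SENSE_CODONS",
    "SENSE_ANTICODONS",
    "CODON_TO_AA",
    "AA_TO_CODONS",
    "FAMILY_SIZES",
    "AA1_TO_AA3",
    "AA3_TO_AA1",
    "PairingRule",
    "AllocationResult",
    "reverse_complement",
    "wc_codon",
    "wc_anticodon",
    "decode",
    "decoders_of",
    "pairing_type",
    "allocate_codon_counts",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ALPHABET = frozenset("ACGT")

_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: The three stop codons of the standard code.
STOP_CODONS: frozenset = frozenset(_TABLE.stop_codons)

#: Codon -> one-letter amino acid, for the 61 sense codons.
CODON_TO_AA: Dict[str, str] = dict(_TABLE.forward_table)

#: The 61 sense codons.
SENSE_CODONS: frozenset = frozenset(CODON_TO_AA)

#: Amino acid (one-letter) -> sorted tuple of synonymous codons.
AA_TO_CODONS: Dict[str, Tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] += (_codon,)

#: Synonymous-family sizes n_i; sums to 61 over the 20 amino acids.
FAMILY_SIZES: Dict[str, int] = {aa: len(c) for aa, c in AA_TO_CODONS.items()}

AA1_TO_AA3: Dict[str, str] = dict(protein_letters_1to3)
AA3_TO_AA1: Dict[str, str] = {v: k for k, v in AA1_TO_AA3.items()}

AMINO_ACIDS: Tuple[str, ...] = tuple(sorted(AA_TO_CODONS))


def _check_triplet(seq: str, what: str) -> str:
    if not isinstance(seq, str):
        raise TypeError(f"{what} must be a string, got {type(seq).__name__}")
    seq = seq.upper()
    if len(seq) != 3:
        raise ValueError(f"{what} {seq!r} must be exactly 3 bases")
    if not set(seq) <= _ALPHABET:
        raise ValueError(f"{what} {seq!r} contains non-ACGT characters")
    return seq


def reverse_complement(seq: str) -> str:
    """Reverse complement in the DNA alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def wc_codon(anticodon: str) -> str:
    """The codon read by *anticodon* under Watson–Crick pairing.

    Mutual inverse of :func:`wc_anticodon`.
    """
    return reverse_complement(_check_triplet(anticodon, "anticodon"))


def wc_anticodon(codon: str) -> str:
    """The anticodon that reads *codon* under Watson–Crick pairing."""
    return reverse_complement(_check_triplet(codon, "codon"))


#: The 61 anticodons whose Watson–Crick codon is a sense codon.
SENSE_ANTICODONS: frozenset = frozenset(wc_anticodon(c) for c in SENSE_CODONS)


@dataclass(frozen=True)
class PairingRule:
    """Which anticodon:codon pairings are allowed at the wobble position.

    ``watson_crick`` mode forces all extension flags off; ``extended`` mode
    defaults to all on (G:U wobble in both orientations plus inosine pairing
    from ADAT editing of A34).
    """

    mode: str = "extended"
    allow_g34_u3: bool = True
    allow_u34_g3: bool = True
    allow_adat: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("watson_crick", "extended"):
            raise ValueError(f"unknown pairing mode {self.mode!r}")
        if self.mode == "watson_crick" and (
            self.allow_g34_u3 or self.allow_u34_g3 or self.allow_adat
        ):
            raise ValueError("watson_crick mode forbids extension flags")

    @classmethod
    def watson_crick(cls) -> "PairingRule":
        return cls(mode="watson_crick", allow_g34_u3=False,
                   allow_u34_g3=False, allow_adat=False)

    @classmethod
    def extended(cls, allow_g34_u3: bool = True, allow_u34_g3: bool = True,
                 allow_adat: bool = True) -> "PairingRule":
        return cls(mode="extended", allow_g34_u3=allow_g34_u3,
                   allow_u34_g3=allow_u34_g3, allow_adat=allow_adat)


WATSON_CRICK = PairingRule.watson_crick()
EXTENDED = PairingRule.extended()


@lru_cache(maxsize=512)
def decode(anticodon: str, rule: PairingRule = EXTENDED) -> frozenset:
    """The set of sense codons *anticodon* can read under *rule*.

    The Watson–Crick codon is always included (unless it is a stop codon, in
    which case the anticodon reads nothing).  Wobble/ADAT expansions replace
    the codon's third base; any expansion that is a stop codon or encodes a
    different amino acid than the Watson–Crick codon is discarded.
    """
    anticodon = _check_triplet(anticodon, "anticodon")
    base34 = anticodon[0]
    wc = reverse_complement(anticodon)

    codons = set()
    if wc in SENSE_CODONS:
        codons.add(wc)

    third: Set[str] = set()
    if base34 == "G" and rule.allow_g34_u3:
        third.add("T")  # G34 : U3
    if base34 == "T" and rule.allow_u34_g3:
        third.add("G")  # U34 : G3
    if base34 == "A" and rule.allow_adat:
        third.update("TCA")  # I : U, I : C, I : A after A34 -> I editing

    wc_aa = CODON_TO_AA.get(wc)
    for b in third:
        cand = wc[:2] + b
        if cand in SENSE_CODONS and CODON_TO_AA[cand] == wc_aa:
            codons.add(cand)
    return frozenset(codons)


def decoders_of(codon: str, present_anticodons: Iterable[str],
                rule: PairingRule = EXTENDED) -> frozenset:
    """The subset of *present_anticodons* whose :func:`decode` covers *codon*.

    An empty result means *codon* is an orphan under this anticodon repertoire
    and pairing rule.
    """
    codon = _check_triplet(codon, "codon")
    if codon in STOP_CODONS:
        raise ValueError(f"{codon} is a stop codon")
    if codon not in SENSE_CODONS:  # pragma: no cover - exhaustive alphabet
        raise ValueError(f"{codon} is not a sense codon")
    return frozenset(a for a in present_anticodons if codon in decode(a, rule))


def pairing_type(anticodon: str, codon: str) -> str:
    """Classify the wobble-position pairing between *anticodon* and *codon*.

    Returns one of ``wc``, ``gu`` (G34:U3), ``ug`` (U34:G3), ``ic`` (I:C) or
    ``ia`` (I:A); I:U — an A34 anticodon on its Watson–Crick codon — counts as
    ``wc``.  Raises if the pair is not a valid decoding under extended rules.
    """
    codon = _check_triplet(codon, "codon")
    anticodon = _check_triplet(anticodon, "anticodon")
    if codon not in decode(anticodon, EXTENDED):
        raise ValueError(f"{anticodon} does not decode {codon}")
    if codon == reverse_complement(anticodon):
        return "wc"
    base34, third = anticodon[0], codon[2]
    if base34 == "G" and third == "T":
        return "gu"
    if base34 == "T" and third == "G":
        return "ug"
    if base34 == "A" and third == "C":
        return "ic"
    if base34 == "A" and third == "A":
        return "ia"
    raise AssertionError("unreachable")  # pragma: no cover


@dataclass(frozen=True)
class AllocationResult:
    """Codon counts split equally among the anticodons that decode them.

    ``allocated`` maps anticodon -> real-valued mass; ``orphans`` maps the
    codons no present anticodon decodes to their (undistributed) counts.
    Total allocated mass plus orphan mass equals the input mass.
    """

    allocated: Mapping[str, float]
    orphans: Mapping[str, float]

    @property
    def allocated_mass(self) -> float:
        return float(sum(self.allocated.values()))

    @property
    def orphan_mass(self) -> float:
        return float(sum(self.orphans.values()))


def allocate_codon_counts(codon_counts: Mapping[str, float],
                          present_anticodons: Iterable[str],
                          rule: PairingRule = EXTENDED) -> AllocationResult:
    """Split each codon's count 1/k among the k present anticodons decoding it.

    Orphan codons (no decoder) keep their full count in ``orphans`` rather
    than being silently dropped, so mass is conserved.
    """
    present = frozenset(present_anticodons)
    allocated: Dict[str, float] = {}
    orphans: Dict[str, float] = {}
    for codon, count in codon_counts.items():
        if count < 0:
            raise ValueError(f"negative count for codon {codon!r}")
        if count == 0:
            continue
        decoders = decoders_of(codon, present, rule)
        if not decoders:
            orphans[codon] = orphans.get(codon, 0.0) + float(count)
            continue
        share = float(count) / len(decoders)
        for a in decoders:
            allocated[a] = allocated.get(a, 0.0) + share
    return AllocationResult(allocated=allocated, orphans=orphans)


#: For each sense codon, every (anticodon, pairing type) that can decode it
#: under fully extended rules.  Static relation, precomputed once.
EXTENDED_DECODING_PAIRS: Dict[str, Tuple[Tuple[str, str], ...]] = {
    codon: tuple(sorted(
        (a, pairing_type(a, codon))
        for a in SENSE_ANTICODONS if codon in decode(a, EXTENDED)))
    for codon in sorted(SENSE_CODONS)
}


#: The 16 anticodons absent from the sea cucumber genome (isotype, anticodon),
#: used by the sea-cucumber synthetic preset and the decoding-coverage checks.
MISSING_ANTICODONS_AJAPONICUS: Tuple[str, ...] = (
    "CCG",  # Arg
    "ATC",  # Asp
    "ACA",  # Cys
    "ACC",  # Gly
    "ATG",  # His
    "GAT",  # Ile
    "GAG",  # Leu
    "AAA",  # Phe
    "GGG",  # Pro
    "GGA",  # Ser
    "ACT",  # Ser
    "GGT",  # Thr
    "ATA",  # Tyr
    "AAC",  # Val
    "TAC",  # Val
    "GAC",  # Val
)
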