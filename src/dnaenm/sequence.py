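"""DNA sequence container, random-sequence generation, and FASTA input.

Sequences are stored single-stranded; the complementary strand is implied
by Watson-Crick pairing (A-T, C-G) and never stored.  IUPAC ambiguity
codes other than A/C/G/T are kept but treated as a single "ambiguous"
class that must be resolved (enumerated) before a structure can be built.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: bases an ambiguity code may stand for, e.g. ``R -> "AG"``, ``N -> "ACGT"``
AMBIGUITY = {code.upper(): vals for code, vals in ambiguous_dna_values.items()}

CANONICAL = frozenset("ACGT")


@dataclass(frozen=True)
class DnaSequence:
    """An (implicitly double-stranded) DNA sequence.

    Parameters
    ----------
    bases : str
        Uppercase base symbols of the Watson strand, 5'->3'.
    id : str
        Free-form identifier (FASTA header, accession, ...).
    circular : bool
        Whether the molecule is circular.  Models are built on the linear
        (open) chain either way; the flag is metadata.
    """

    bases: str
    id: str = ""
    circular: bool = False
    variant: str = field(default="", compare=False)

    def __post_init__(self):
        up = self.bases.upper()
        if "U" in up:
            raise ValueError(
                "sequence contains U: RNA is not supported, supply a DNA sequence"
            )
        bad = set(up) - set(AMBIGUITY)
        if bad:
            raise ValueError(f"invalid base symbols: {sorted(bad)}")
        object.__setattr__(self, "bases", up)

    def __len__(self) -> int:
        return len(self.bases)

    def __getitem__(self, i):
        return self.bases[i]

    def __iter__(self):
        return iter(self.bases)

    @property
    def ambiguous_positions(self) -> list[int]:
        """0-based positions holding a non-ACGT symbol."""
        return [i for i, b in enumerate(self.bases) if b not in CANONICAL]

    @property
    def gc_content(self) -> float:
        n = sum(1 for b in self.bases if b in "GC")
        return n / len(self.bases)

    def reverse_complement(self) -> "DnaSequence":
        rc = self.bases.translate(COMPLEMENT)[::-1]
        return replace(self, bases=rc, id=self.id + "_rc" if self.id else "")

    def require_unambiguous(self) -> None:
        pos = self.ambiguous_positions
        if pos:
            raise ValueError(
                f"sequence has ambiguous bases at positions {pos[:10]}"
                f"{'...' if len(pos) > 10 else ''}; "
                "resolve them first (see resolve_ambiguous)"
            )


def random_sequence(
    length: int,
    rng: np.random.Generator,
    gc: float | None = None,
    id: str = "",
) -> DnaSequence:
    """Generate a random sequence, optionally at an exact GC content.

    With ``gc=None`` every base is drawn uniformly from {A,C,G,T}.  With a
    GC fraction given, exactly ``round(gc * length)`` positions carry G or C
    (each with probability 1/2), the rest A or T (each 1/2), with the G+C
    positions uniformly shuffled over the sequence.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if gc is None:
        bases = rng.choice(list("ACGT"), size=length)
        return DnaSequence("".join(bases), id=id)
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc must be in [0, 1], got {gc}")
    n_gc = int(round(gc * length))
    strong = rng.choice(list("GC"), size=n_gc)
    weak = rng.choice(list("AT"), size=length - n_gc)
    seq = np.concatenate([strong, weak])
    rng.shuffle(seq)
    return DnaSequence("".join(seq), id=id)


def read_fasta(path) -> list[DnaSequence]:
    """Read all records of a FASTA file as :class:`DnaSequence` objects.

    Bases are uppercased; IUPAC ambiguity codes are preserved (to be handled
    by :func:`resolve_ambiguous`).  ``U`` raises, pointing at RNA input.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    out = []
    for rec in records:
        if len(rec.seq) == 0:
            raise ValueError(f"empty sequence for record {rec.id!r} in {path}")
        out.append(DnaSequence(str(rec.seq), id=rec.id))
    return out


def resolve_ambiguous(seq: DnaSequence, max_ambiguous: int = 2) -> list[DnaSequence]:
    """Enumerate all concrete sequences compatible with the ambiguity codes.

    Each ambiguous position is expanded into the set of bases its IUPAC code
    stands for (``N`` -> A/C/G/T, ``R`` -> A/G, ...), and the Cartesian
    product over positions is returned.  Variant labels of the form
    ``pos<i>=<base>`` are recorded on each returned sequence.
    """
    pos = seq.ambiguous_positions
    if not pos:
        return [seq]
    if len(pos) > max_ambiguous:
        raise ValueError(
            f"{len(pos)} ambiguous positions exceed max_ambiguous="
            f"{max_ambiguous}; mask or split the sequence instead"
        )
    choices = [AMBIGUITY[seq.bases[i]] for i in pos]
    variants = []
    for combo in itertools.product(*choices):
        b = list(seq.bases)
        for i, base in zip(pos, combo):
            b[i] = base
        label = ",".join(f"pos{i}={x}" for i, x in zip(pos, combo))
        variants.append(
            DnaSequence("".join(b), id=seq.id, circular=seq.circular, variant=label)
        )
    return variants
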