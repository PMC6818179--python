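"""Reference-genome access and sequence primitives.

All genome text is uppercased at the access layer, so a softmasked FASTA
(repeats lowercased) behaves identically to a plain one.  Only the
{A, C, G, T, N} alphabet is accepted; other IUPAC ambiguity codes are
rejected at load because the downstream codon logic is defined only over
those five letters and silently accepting them would corrupt the filters.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Data import CodonTable

from .errors import AlphabetError, BoundsError, GenomeLookupError
from .models import TranscriptModel, derive_introns

log = logging.getLogger(__name__)

_VALID_RE = re.compile(r"[ACGTN]*\Z")
_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


def _validate(name: str, seq: str) -> str:
    seq = seq.upper()
    if not _VALID_RE.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise AlphabetError(
            f"sequence {name!r} contains unsupported characters {bad}; "
            "only A/C/G/T/N (any case) are accepted"
        )
    return seq


class GenomeIndex:
    """Random access to a reference genome, 1-based inclusive coordinates."""

    def __init__(self, sequences: Mapping[str, str], source: str = "<memory>"):
        self._seqs = {name: _validate(name, seq) for name, seq in sequences.items()}
        self.source = source

    # --- constructors -----------------------------------------------------

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeIndex":
        """Load a plain or gzip-compressed (multi-record) FASTA file."""
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            records = SeqIO.parse(fh, "fasta")
            seqs = {rec.id: str(rec.seq) for rec in records}
        return cls(seqs, source=str(path))

    @classmethod
    def from_text(cls, text: str) -> "GenomeIndex":
        records = SeqIO.parse(io.StringIO(text), "fasta")
        return cls({rec.id: str(rec.seq) for rec in records})

    # --- accessors ----------------------------------------------------------

    @property
    def names(self) -> list[str]:
        return list(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def length(self, name: str) -> int:
        if name not in self._seqs:
            raise GenomeLookupError(f"scaffold {name!r} not in genome {self.source}")
        return len(self._seqs[name])

    def slice(self, name: str, start: int, end: int) -> str:
        """Subsequence [start, end], 1-based inclusive, uppercased."""
        if name not in self._seqs:
            raise GenomeLookupError(f"scaffold {name!r} not in genome {self.source}")
        seq = self._seqs[name]
        if start < 1 or end > len(seq) or start > end:
            raise BoundsError(
                f"slice {name}:{start}-{end} outside scaffold of length {len(seq)}"
            )
        return seq[start - 1 : end]


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    seq = seq.upper()
    if not _VALID_RE.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise AlphabetError(f"cannot reverse-complement characters {bad}")
    return seq.translate(_RC_TABLE)[::-1]


# --------------------------------------------------------------------------
# Translation
# --------------------------------------------------------------------------

SUPPORTED_TRANSLATION_TABLES = (1, 11)


def _codon_map(table_id: int) -> dict[str, str]:
    if table_id not in SUPPORTED_TRANSLATION_TABLES:
        raise ValueError(
            f"translation table {table_id} unsupported; "
            f"choose from {SUPPORTED_TRANSLATION_TABLES}"
        )
    table = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


_CODON_MAPS = {tid: _codon_map(tid) for tid in SUPPORTED_TRANSLATION_TABLES}


def stop_codons(table_id: int = 1) -> frozenset:
    return frozenset(CodonTable.unambiguous_dna_by_id[table_id].stop_codons)


def start_codons(table_id: int = 1) -> frozenset:
    return frozenset(CodonTable.unambiguous_dna_by_id[table_id].start_codons)


def translate(cds: str, table_id: int = 1) -> str:
    """Translate a coding sequence read 5'→3' from position 1.

    Codons containing N translate to 'X', stop codons to '*'.  A trailing
    1-2 nt remainder is dropped with a logged warning rather than an error,
    since out-of-frame models are exactly what the filters exist to flag.
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise ValueError(f"CDS of length {len(cds)} is too short to translate")
    mapping = _CODON_MAPS[table_id] if table_id in _CODON_MAPS else _codon_map(table_id)
    remainder = len(cds) % 3
    if remainder:
        log.warning("CDS length %d not a multiple of 3; dropping %d trailing nt",
                    len(cds), remainder)
        cds = cds[: len(cds) - remainder]
    out = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if "N" in codon:
            out.append("X")
        else:
            try:
                out.append(mapping[codon])
            except KeyError:
                raise AlphabetError(f"untranslatable codon {codon!r}") from None
    return "".join(out)


# --------------------------------------------------------------------------
# Model-level sequence extraction
# --------------------------------------------------------------------------

def spliced_cds(genome: GenomeIndex, model: TranscriptModel) -> str:
    """Concatenated coding sequence of a model in 5'→3' orientation.

    Segments are sliced in ascending genomic order and joined; the result is
    reverse-complemented for minus-strand models.  Length always equals the
    summed segment lengths.
    """
    try:
        parts = [genome.slice(model.scaffold, s.start, s.end) for s in model.segments]
    except BoundsError as exc:
        raise BoundsError(f"model {model.transcript_id!r}: {exc}") from None
    seq = "".join(parts)
    return reverse_complement(seq) if model.strand == "-" else seq


def gene_region(genome: GenomeIndex, model: TranscriptModel) -> str:
    """Genomic slice from first to last segment (introns included), 5'→3'."""
    seq = genome.slice(model.scaffold, model.start, model.end)
    return reverse_complement(seq) if model.strand == "-" else seq


def intron_dinucleotides(
    genome: GenomeIndex, model: TranscriptModel
) -> list[tuple[str, str]]:
    """(donor, acceptor) dinucleotides per intron, in 5'→3' transcript order.

    A canonical spliceosomal intron reads GT...AG on the coding strand.  On
    the minus strand the donor is the reverse complement of the intron's last
    two genomic bases and the acceptor of its first two.  Monoexonic models
    yield an empty list.
    """
    introns = derive_introns(model)
    out = []
    if model.strand == "+":
        for i_start, i_end in introns:
            donor = genome.slice(model.scaffold, i_start, i_start + 1)
            acceptor = genome.slice(model.scaffold, i_end - 1, i_end)
            out.append((donor, acceptor))
    else:
        for i_start, i_end in reversed(introns):
            donor = reverse_complement(genome.slice(model.scaffold, i_end - 1, i_end))
            acceptor = reverse_complement(genome.slice(model.scaffold, i_start, i_start + 1))
            out.append((donor, acceptor))
    return out
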