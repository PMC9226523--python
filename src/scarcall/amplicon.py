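"""Reference amplicon model.

A run of the assay amplifies a single fixed amplicon bounded by the two PCR
primers, with a defined endonuclease cut site in between.  Everything
downstream (orientation, anchoring, alignment, classification) is expressed
in coordinates on this reference.  Coordinates are 0-based, half-open;
``cut_site`` is an inter-base offset (the break falls between
``sequence[cut_site - 1]`` and ``sequence[cut_site]``).

Adenine homopolymer tracts are annotated up front because polymerase
slippage in such tracts produces length-variation artifacts that must be
filtered before repair events are counted.  Tracts are detected on both
strands (A-runs and T-runs): a polyA stretch on the opposite strand reads
as polyT on the forward reference.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Seq import reverse_complement

_DNA_RE = re.compile(r"^[ACGT]+$")

DEFAULT_POLYA_MIN_LEN = 4


class ConfigurationError(ValueError):
    """Raised when an amplicon description is internally inconsistent."""


class InvalidAlphabetError(ValueError):
    """Raised on characters outside the uppercase {A, C, G, T} alphabet."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (delegates to Biopython)."""
    return reverse_complement(seq)


@dataclass(frozen=True)
class HomopolymerTract:
    """A maximal A or T homopolymer run, half-open on the reference."""

    start: int
    end: int
    base: str

    def __post_init__(self) -> None:
        if self.base not in ("A", "T"):
            raise ValueError(f"tract base must be A or T, got {self.base!r}")
        if self.end <= self.start:
            raise ValueError("tract end must exceed start")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        """True when ``pos`` lies inside the tract or on its boundary.

        Insertions are located at inter-base offsets, so both half-open
        boundaries count as "immediately adjacent" to the run.
        """
        return self.start <= pos <= self.end


def find_homopolymer_tracts(sequence: str, min_len: int = DEFAULT_POLYA_MIN_LEN) -> list[HomopolymerTract]:
    """Locate every maximal A-run and T-run of length >= ``min_len``.

    Parameters
    ----------
    sequence:
        Uppercase DNA over {A, C, G, T}.
    min_len:
        Minimum run length to report; must be >= 2 (a single base is not a
        tract and would flag every position).

    Returns
    -------
    Tracts sorted by start coordinate.  Runs are maximal by construction:
    the regex consumes each homopolymer in full, so no reported tract can
    be extended by its own base on either side.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    if not _DNA_RE.match(sequence):
        bad = sorted(set(sequence) - set("ACGT"))
        raise InvalidAlphabetError(f"sequence contains non-ACGT characters: {bad}")
    tracts = []
    for m in re.finditer(r"A+|T+", sequence):
        if m.end() - m.start() >= min_len:
            tracts.append(HomopolymerTract(m.start(), m.end(), m.group()[0]))
    return tracts


@dataclass(frozen=True)
class AmpliconReference:
    """The reference amplicon with its primer anchors and cut site.

    The sequence includes the primers: the amplicon begins with the forward
    primer and ends with the reverse complement of the reverse primer (both
    given 5'->3' as ordered for synthesis).  Adaptors are the 5' tails on
    the primers; they are not part of the reference but are stripped from
    reads when present.
    """

    name: str
    sequence: str
    cut_site: int
    primer_fwd: str
    primer_rev: str
    adaptor_fwd: str = ""
    adaptor_rev: str = ""
    tracts: tuple[HomopolymerTract, ...] = field(default=())
    polyA_min_len: int = DEFAULT_POLYA_MIN_LEN

    def __post_init__(self) -> None:
        for label, seq in (
            ("sequence", self.sequence),
            ("primer_fwd", self.primer_fwd),
            ("primer_rev", self.primer_rev),
        ):
            if not _DNA_RE.match(seq):
                raise InvalidAlphabetError(f"{label} must be uppercase ACGT, got {seq[:30]!r}")
        if len(self.sequence) < len(self.primer_fwd) + len(self.primer_rev) + 1:
            raise ConfigurationError("amplicon shorter than its two primers")
        if not self.sequence.startswith(self.primer_fwd):
            raise ConfigurationError("reference does not begin with the forward primer")
        if not self.sequence.endswith(revcomp(self.primer_rev)):
            raise ConfigurationError("reference does not end with revcomp(reverse primer)")
        if not 0 < self.cut_site < len(self.sequence):
            raise ConfigurationError(f"cut_site {self.cut_site} outside the amplicon interior")
        for t in self.tracts:
            if not (0 <= t.start < t.end <= len(self.sequence)):
                raise ConfigurationError(f"tract {t} outside the amplicon")
            if set(self.sequence[t.start:t.end]) != {t.base}:
                raise ConfigurationError(f"tract {t} does not match the sequence")

    def __len__(self) -> int:
        return len(self.sequence)


def build_reference(name: str, sequence: str, config: dict) -> AmpliconReference:
    """Assemble a validated :class:`AmpliconReference` from a config mapping.

    ``config`` supplies ``primer_fwd``, ``primer_rev``, ``cut_site`` and
    optionally ``adaptor_fwd``, ``adaptor_rev`` and ``polyA_min_len``.
    Homopolymer tracts are computed here so every downstream consumer sees
    the same annotation.
    """
    sequence = sequence.upper()
    try:
        primer_fwd = config["primer_fwd"].upper()
        primer_rev = config["primer_rev"].upper()
        cut_site = int(config["cut_site"])
    except KeyError as e:  # pragma: no cover - defensive
        raise ConfigurationError(f"missing config key: {e}") from e
    min_len = int(config.get("polyA_min_len", DEFAULT_POLYA_MIN_LEN))
    tracts = tuple(find_homopolymer_tracts(sequence, min_len))
    return AmpliconReference(
        name=name,
        sequence=sequence,
        cut_site=cut_site,
        primer_fwd=primer_fwd,
        primer_rev=primer_rev,
        adaptor_fwd=config.get("adaptor_fwd", "").upper(),
        adaptor_rev=config.get("adaptor_rev", "").upper(),
        tracts=tracts,
        polyA_min_len=min_len,
    )


def reference_from_fasta(fasta_path, config: dict) -> AmpliconReference:
    """Load the single amplicon record from a FASTA file."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ConfigurationError(f"expected exactly one FASTA record, found {len(records)}")
    rec = records[0]
    return build_reference(rec.id, str(rec.seq), config)
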