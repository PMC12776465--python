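"""Coding-sequence records, FASTA I/O, and codon/frame arithmetic.

Transcripts are stored as RNA (``U``) regardless of the input alphabet.
Coordinates are 1-based and inclusive throughout the package: nucleotide
``nt_pos`` lies in codon ``ceil(nt_pos / 3)`` with phase ``(nt_pos - 1) % 3``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_rna_by_id
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_STANDARD = unambiguous_rna_by_id[1]
#: codon -> amino acid for the standard genetic code (RNA alphabet)
CODON_TABLE: dict[str, str] = dict(_STANDARD.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

VALID_BASES = frozenset("ACGUN")

# Ensembl CDS headers look like
#   >ENST00000155840.12 cds chromosome:GRCh38:... gene:ENSG00000053918.17
#    gene_biotype:protein_coding ... gene_symbol:KCNQ1 ...
_GENE_RE = re.compile(r"\bgene:(\S+)")
_SYMBOL_RE = re.compile(r"\bgene_symbol:(\S+)")
_CANONICAL_RE = re.compile(r"\bEnsembl_canonical\b")


@dataclass
class TranscriptRecord:
    """One coding sequence with its gene/isoform identity.

    ``cds`` is RNA over {A,C,G,U,N}; ``in_frame`` is False when the length is
    not a multiple of three (such records are kept but excluded from motif
    search).
    """

    transcript_id: str
    gene_id: str
    gene_name: str
    isoform_class: str  # "canonical" | "alternative"
    cds: str
    in_frame: bool = field(init=False)

    def __post_init__(self) -> None:
        if not self.transcript_id or not self.gene_id:
            raise ValueError("transcript_id and gene_id must be non-empty")
        if self.isoform_class not in ("canonical", "alternative"):
            raise ValueError(f"bad isoform_class {self.isoform_class!r}")
        bad = set(self.cds) - VALID_BASES
        if bad:
            raise ValueError(f"invalid bases {sorted(bad)} in {self.transcript_id}")
        if len(self.cds) < 21:
            raise ValueError(
                f"{self.transcript_id}: CDS shorter than 21 nt ({len(self.cds)})"
            )
        self.in_frame = len(self.cds) % 3 == 0

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3

    @property
    def is_canonical(self) -> bool:
        return self.isoform_class == "canonical"


@dataclass(frozen=True)
class CodonCoordinate:
    nt_pos: int
    codon_index: int
    phase: int

    def __post_init__(self) -> None:
        if self.nt_pos < 1:
            raise ValueError("nt_pos is 1-based")
        if self.codon_index != (self.nt_pos + 2) // 3:
            raise ValueError("codon_index inconsistent with nt_pos")
        if self.phase != (self.nt_pos - 1) % 3:
            raise ValueError("phase inconsistent with nt_pos")


def codon_coordinate(nt_pos: int) -> CodonCoordinate:
    """Map a 1-based nucleotide position onto codon index and phase."""
    return CodonCoordinate(nt_pos, (nt_pos + 2) // 3, (nt_pos - 1) % 3)


def _parse_header(description: str) -> tuple[str, str, str, str]:
    tokens = description.split()
    transcript_id = tokens[0] if tokens else ""
    gene = _GENE_RE.search(description)
    symbol = _SYMBOL_RE.search(description)
    if not transcript_id or gene is None:
        logger.warning(
            "malformed FASTA header %r: assigning generic gene ids", description
        )
        transcript_id = transcript_id or "unknown_transcript"
        gene_id = gene.group(1) if gene else transcript_id
    else:
        gene_id = gene.group(1)
    gene_name = symbol.group(1) if symbol else gene_id
    isoform = "canonical" if _CANONICAL_RE.search(description) else "alternative"
    return transcript_id, gene_id, gene_name, isoform


def read_cds_fasta(
    path: str | Path,
    canonical_tsv: str | Path | None = None,
) -> list[TranscriptRecord]:
    """Read an Ensembl-style CDS FASTA into transcript records.

    ``T`` is normalized to ``U``.  The canonical/alternative flag is taken
    from an ``Ensembl_canonical`` header tag when present; a sidecar TSV
    (transcript_id <tab> 0/1) overrides it.  Records that fail validation
    (bad alphabet, too short) are skipped with a warning, never silently.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    canon_map: dict[str, bool] = {}
    if canonical_tsv is not None:
        for line in Path(canonical_tsv).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            tid, flag = line.split("\t")[:2]
            canon_map[tid] = flag.strip() in ("1", "true", "True", "canonical")

    records: list[TranscriptRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        tid, gid, name, isoform = _parse_header(entry.description)
        if tid in canon_map:
            isoform = "canonical" if canon_map[tid] else "alternative"
        cds = str(entry.seq).upper().replace("T", "U")
        try:
            rec = TranscriptRecord(tid, gid, name, isoform, cds)
        except ValueError as exc:
            logger.warning("skipping record %s: %s", tid, exc)
            continue
        if not rec.in_frame:
            logger.warning(
                "record %s: length %d not a multiple of 3; flagged and "
                "excluded from motif search",
                tid,
                len(cds),
            )
        records.append(rec)
    return records


def write_cds_fasta(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    """Write records back out with the same Ensembl-style header dialect."""
    out = []
    for rec in records:
        desc = f"cds gene:{rec.gene_id} gene_symbol:{rec.gene_name}"
        if rec.is_canonical:
            desc += " Ensembl_canonical"
        out.append(SeqRecord(Seq(rec.cds), id=rec.transcript_id, description=desc))
    with open(path, "w") as fh:
        SeqIO.write(out, fh, "fasta")


def translate(cds: str, start_nt: int = 1, frame_offset: int = 0) -> str:
    """Translate from ``start_nt + frame_offset`` with the standard code.

    Stops at (and excludes) the first stop codon; trailing sub-codon
    nucleotides are ignored; codons containing N become ``X``.  A start
    beyond the sequence end yields the empty string.
    """
    if frame_offset not in (0, -1, -2, 1):
        raise ValueError(f"frame_offset must be in {{0,-1,-2,+1}}, got {frame_offset}")
    begin = start_nt + frame_offset
    if begin < 1:
        raise ValueError("start_nt + frame_offset must be >= 1")
    aa, _ = _translate_with_stop(cds, begin)
    return aa


def _translate_with_stop(cds: str, begin: int) -> tuple[str, bool]:
    """Translate from 1-based ``begin``; also report whether a stop was hit."""
    out: list[str] = []
    for i in range(begin - 1, len(cds) - 2, 3):
        codon = cds[i : i + 3]
        if codon in STOP_CODONS:
            return "".join(out), True
        if "N" in codon:
            out.append("X")
        else:
            out.append(CODON_TABLE[codon])
    return "".join(out), False
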