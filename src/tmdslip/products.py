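"""Frameshift product prediction, in-silico digestion, peptide databases.

The transition model: the P-site residue of the slip site is the last
0-frame residue; after the tRNAs re-pair in the shifted frame, the next
decoded (A-site) codon is already in the alternative frame.  A product is
therefore ``prefix`` (0-frame translation through the P-site codon) plus
``extension`` (alternative-frame translation starting at the shifted A-site
codon, up to but excluding the first alternative-frame stop).  A direct
transition onto an alternative-frame stop codon yields an empty extension:
a premature-termination product.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from pyteomics import parser as _pyt_parser

from .motifs import TmdSlipMotif
from .transcriptome import TranscriptRecord, _translate_with_stop

logger = logging.getLogger(__name__)

FRAMES = (-1, -2, 1)
PEPTIDE_MIN_LEN = 7
PEPTIDE_MAX_LEN = 50

CALL_ZERO = "zero_frame"
CALL_TRANSITIONAL = "transitional"
CALL_FRAMESHIFT = "frameshift"
CALL_PREMATURE = "premature_termination"
CALL_AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class FrameshiftProduct:
    motif: TmdSlipMotif
    frame: int
    prefix: str  # 0-frame residues through the P-site residue
    extension: str  # alternative-frame residues, stop-free
    terminated: bool  # True when an alternative-frame stop was reached

    @property
    def extension_len(self) -> int:
        return len(self.extension)

    @property
    def full_sequence(self) -> str:
        return self.prefix + self.extension


@dataclass(frozen=True)
class PeptideCall:
    sequence: str
    call: str
    frame: Optional[int] = None
    source_transcript: str = ""
    n_loci: int = 0


def predict_frameshift_product(
    record: TranscriptRecord, motif: TmdSlipMotif, frame: int = -1
) -> FrameshiftProduct:
    """Predict the polypeptide produced by shifting frames at one motif."""
    if frame not in FRAMES:
        raise ValueError(f"frame must be one of {FRAMES}, got {frame}")
    if motif.transcript_id != record.transcript_id:
        raise ValueError("motif does not belong to this record")
    s = motif.heptamer_nt_start
    p_site_codon = s // 3 + 1
    prefix, stopped = _translate_with_stop(record.cds[: 3 * p_site_codon], 1)
    if len(prefix) != p_site_codon:
        logger.warning(
            "%s: 0-frame stop upstream of slip site (prefix %d < %d codons)",
            record.transcript_id,
            len(prefix),
            p_site_codon,
        )
    shifted_a_site = s + 4 + frame  # 0-frame A site starts at s + 4
    extension, terminated = _translate_with_stop(record.cds, shifted_a_site)
    return FrameshiftProduct(motif, frame, prefix, extension, terminated)


# --- proteolysis ---------------------------------------------------------

# cleavage rules as regexes whose match *end* marks the cut point
_EXPASY = dict(_pyt_parser.expasy_rules)
_RULE_REGEX = {
    "trypsin": _EXPASY["trypsin"],
    "lysC": _EXPASY["lysc"],
    "lysN": r"\w(?=K)",  # cleaves N-terminally to lysine
    "gluC": _EXPASY["glutamyl endopeptidase"],
    "aspN": _EXPASY["asp-n"],
    "chymotrypsin": _EXPASY["chymotrypsin high specificity"],
}


@dataclass(frozen=True)
class ProteaseRule:
    name: str
    regex: str
    max_missed_cleavages: int = 2

    def __post_init__(self) -> None:
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")

    @classmethod
    def named(cls, name: str, max_missed_cleavages: int = 2) -> "ProteaseRule":
        if name not in _RULE_REGEX:
            raise ValueError(f"unknown protease {name!r}; known: {sorted(_RULE_REGEX)}")
        return cls(name, _RULE_REGEX[name], max_missed_cleavages)


def standard_rules(max_missed_cleavages: int = 2) -> list[ProteaseRule]:
    """The six-protease panel used for frameshift-peptide databases."""
    return [ProteaseRule.named(n, max_missed_cleavages) for n in _RULE_REGEX]


@dataclass(frozen=True)
class Peptide:
    sequence: str
    start: int  # 1-based residue index in the parent protein
    missed: int

    @property
    def end(self) -> int:
        return self.start + len(self.sequence) - 1


def cleavage_sites(protein: str, rule: ProteaseRule) -> list[int]:
    """0-based cut offsets (cut occurs before this index), excluding ends."""
    return [
        m.end()
        for m in re.finditer(rule.regex, protein)
        if 0 < m.end() < len(protein)
    ]


def digest(protein: str, rule: ProteaseRule) -> list[Peptide]:
    """Ordered proteolytic fragments with 0..max missed cleavages."""
    if not protein:
        raise ValueError("protein must be non-empty")
    bounds = [0] + cleavage_sites(protein, rule) + [len(protein)]
    peptides = []
    for i in range(len(bounds) - 1):
        for missed in range(rule.max_missed_cleavages + 1):
            j = i + 1 + missed
            if j >= len(bounds):
                break
            seq = protein[bounds[i] : bounds[j]]
            peptides.append(Peptide(seq, bounds[i] + 1, missed))
    return peptides


# --- peptide databases and classification --------------------------------


def zero_frame_proteome(records: Iterable[TranscriptRecord]) -> dict[str, str]:
    """transcript_id -> 0-frame protein (to the first stop)."""
    out = {}
    for rec in records:
        aa, _ = _translate_with_stop(rec.cds, 1)
        out[rec.transcript_id] = aa
    return out


def zero_frame_peptides(
    proteome: dict[str, str],
    rules: Sequence[ProteaseRule],
    min_len: int = PEPTIDE_MIN_LEN,
    max_len: int = PEPTIDE_MAX_LEN,
) -> set[str]:
    out: set[str] = set()
    for protein in proteome.values():
        if not protein:
            continue
        for rule in rules:
            out.update(
                p.sequence
                for p in digest(protein, rule)
                if min_len <= len(p.sequence) <= max_len
            )
    return out


@dataclass(frozen=True)
class DbEntry:
    header: str
    sequence: str


def build_frameshift_peptide_db(
    records: Sequence[TranscriptRecord],
    motifs: Sequence[TmdSlipMotif],
    frames: Sequence[int] = (-1,),
    rules: Optional[Sequence[ProteaseRule]] = None,
    min_len: int = PEPTIDE_MIN_LEN,
    max_len: int = PEPTIDE_MAX_LEN,
) -> list[DbEntry]:
    """Second-pass search database of candidate frameshift peptides.

    Per motif and frame, digested peptides of the predicted product that
    overlap the transition point or the alternative-frame extension are
    emitted, plus the junction-truncated (semi-specific C-terminus) peptide
    for direct transitions onto an alternative-frame stop.  Any peptide
    identical to a first-pass (0-frame) digest peptide is excluded, so the
    second-pass database is disjoint from pass one by construction.
    """
    rules = list(rules) if rules is not None else standard_rules()
    by_tid = {r.transcript_id: r for r in records}
    pass1 = zero_frame_peptides(zero_frame_proteome(records), rules, min_len, max_len)
    entries: list[DbEntry] = []
    seen: set[tuple[str, str]] = set()
    for motif in motifs:
        rec = by_tid[motif.transcript_id]
        for frame in frames:
            product = predict_frameshift_product(rec, motif, frame)
            junction = len(product.prefix)  # residue index of last 0-frame aa
            full = product.full_sequence
            candidates: list[tuple[str, str]] = []
            for rule in rules:
                for pep in digest(full, rule):
                    if not (min_len <= len(pep.sequence) <= max_len):
                        continue
                    if pep.end <= junction:
                        continue  # fully 0-frame
                    cls = CALL_FRAMESHIFT if pep.start > junction else CALL_TRANSITIONAL
                    candidates.append((pep.sequence, cls))
                if product.terminated and product.extension_len == 0:
                    # premature termination: the C-terminal fragments of the
                    # truncated product (enzymatic N-terminus, junction
                    # C-terminus; usually semi-specific vs. the 0-frame protein)
                    for pep in digest(product.prefix, rule):
                        if pep.end == junction and min_len <= len(pep.sequence) <= max_len:
                            candidates.append((pep.sequence, CALL_PREMATURE))
            for seq, cls in candidates:
                if seq in pass1:
                    continue
                key = (seq, f"{motif.transcript_id}|{motif.heptamer_nt_start}|{frame}|{cls}")
                if key in seen:
                    continue
                seen.add(key)
                entries.append(
                    DbEntry(
                        f"{motif.transcript_id}|nt{motif.heptamer_nt_start}"
                        f"|frame{frame:+d}|{cls}",
                        seq,
                    )
                )
    return entries


def write_peptide_fasta(entries: Iterable[DbEntry], path) -> None:
    with open(path, "w") as fh:
        for e in entries:
            fh.write(f">{e.header}\n{e.sequence}\n")


class PeptideClassifier:
    """Exact-substring classification of observed peptides.

    A peptide is ``zero_frame`` when it occurs in a 0-frame protein,
    ``transitional`` when it crosses a slip-site junction into the
    alternative frame, ``frameshift`` when it lies wholly inside an
    alternative-frame extension, and ``premature_termination`` when its
    C-terminus is the P-site residue of a motif whose shifted A-site codon
    is a stop.  Conflicting classes (or one alternative-frame class at
    several motif loci) yield ``ambiguous``; a 0-frame match at several
    transcripts is ordinary isoform redundancy and stays ``zero_frame``.
    """

    def __init__(
        self,
        records: Sequence[TranscriptRecord],
        motifs: Sequence[TmdSlipMotif],
        frames: Sequence[int] = (-1, -2, 1),
        collapse_il: bool = False,
    ) -> None:
        self.collapse_il = collapse_il
        self._proteome = zero_frame_proteome(records)
        by_tid = {r.transcript_id: r for r in records}
        self._products: list[FrameshiftProduct] = []
        for motif in sorted(
            motifs, key=lambda m: (m.transcript_id, m.heptamer_nt_start)
        ):
            for frame in frames:
                self._products.append(
                    predict_frameshift_product(by_tid[motif.transcript_id], motif, frame)
                )

    def _norm(self, s: str) -> str:
        return s.replace("I", "L") if self.collapse_il else s

    def classify(self, peptide: str) -> PeptideCall:
        if len(peptide) < PEPTIDE_MIN_LEN:
            raise ValueError(f"peptide shorter than {PEPTIDE_MIN_LEN} residues")
        pep = self._norm(peptide)
        zero_loci = [
            tid for tid, prot in self._proteome.items() if pep in self._norm(prot)
        ]
        premature_loci: list[tuple[str, int]] = []
        transitional: list[tuple[str, int]] = []
        frameshift: list[tuple[str, int]] = []
        for product in self._products:
            junction = len(product.prefix)
            full = self._norm(product.full_sequence)
            start = 0
            while True:
                idx = full.find(pep, start)
                if idx < 0:
                    break
                start = idx + 1
                pep_start, pep_end = idx + 1, idx + len(pep)  # 1-based
                locus = (product.motif.transcript_id, product.frame)
                if pep_start > junction:
                    frameshift.append(locus)
                elif pep_end > junction:
                    transitional.append(locus)
                elif (
                    pep_end == junction
                    and product.terminated
                    and product.extension_len == 0
                ):
                    premature_loci.append(locus)

        classes = []
        if transitional:
            classes.append((CALL_TRANSITIONAL, transitional))
        if frameshift:
            classes.append((CALL_FRAMESHIFT, frameshift))
        if premature_loci:
            classes.append((CALL_PREMATURE, premature_loci))
        if zero_loci and not premature_loci:
            classes.append((CALL_ZERO, [(t, None) for t in zero_loci]))

        if not classes:
            return PeptideCall(peptide, CALL_AMBIGUOUS, None, "", 0)
        if len(classes) > 1:
            return PeptideCall(
                peptide, CALL_AMBIGUOUS, None, "", sum(len(c[1]) for c in classes)
            )
        call, loci = classes[0]
        if call in (CALL_TRANSITIONAL, CALL_FRAMESHIFT, CALL_PREMATURE):
            motif_loci = {t for t, _ in loci}
            if len(motif_loci) > 1:
                return PeptideCall(peptide, CALL_AMBIGUOUS, None, "", len(loci))
            tid, frame = loci[0]
            return PeptideCall(peptide, call, frame, tid, len(loci))
        return PeptideCall(peptide, CALL_ZERO, None, loci[0][0], len(loci))


def classify_peptide(
    peptide: str,
    records: Sequence[TranscriptRecord],
    motifs: Sequence[TmdSlipMotif],
    frames: Sequence[int] = (-1, -2, 1),
    collapse_il: bool = False,
) -> PeptideCall:
    """One-shot convenience wrapper around :class:`PeptideClassifier`."""
    return PeptideClassifier(records, motifs, frames, collapse_il).classify(peptide)
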