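"""Pairing slippery heptamers with refined TMD segments.

A TMD-slip motif is a slippery heptamer positioned so that decoding of the
heptamer coincides with translocon engagement of the TMD, nominally 45
codons downstream of the TMD's C-terminal residue (accepted range 35-55).
Only phase-aligned heptamers are scanned -- the classical X XXY YYZ register
in which heptamer nucleotides 2-4 and 5-7 are 0-frame codons -- so a
heptamer starting at 1-based CDS position s requires s % 3 == 0.

Assignment follows a nearest-to-ideal rule in both directions: each
slippery heptamer is attributed to the TMD minimizing |L - L_ideal|, and
where several heptamers land on one TMD only the one closest to the ideal
spacing is kept, avoiding double counting.  Ties break toward the smaller
distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

from .pairing import SlipperyTable
from .tmd import RefinedSegment
from .transcriptome import TranscriptRecord

logger = logging.getLogger(__name__)

L_RANGE_DEFAULT = (35, 55)
L_IDEAL_DEFAULT = 45

SPLICING_CANONICAL = "canonical"
SPLICING_DEPENDENT = "splicing_dependent"
SPLICING_NA = "not_applicable"


@dataclass(frozen=True)
class TmdSlipMotif:
    transcript_id: str
    tmd: RefinedSegment
    heptamer_nt_start: int  # 1-based CDS position, phase-aligned (s % 3 == 0)
    heptamer: str
    distance_L: int  # codons, TMD C-terminus -> heptamer P-site codon
    is_ideal: bool
    in_range: bool
    splicing_class: str = SPLICING_NA

    def __post_init__(self) -> None:
        if self.heptamer_nt_start % 3 != 0:
            raise ValueError("heptamer_nt_start must be phase-aligned (s % 3 == 0)")
        if self.distance_L <= 0:
            raise ValueError("heptamer must lie downstream of the TMD")
        if self.is_ideal and not self.in_range:
            raise ValueError("ideal spacing implies in-range spacing")


def scan_phase_aligned_heptamers(cds: str) -> list[tuple[int, str]]:
    """All (nt_start, heptamer) with the X XXY YYZ register, N-free.

    Heptamers overlapping the final (stop) codon are skipped, so the last
    admissible start satisfies s + 6 <= len(cds) - 3.
    """
    out = []
    for s in range(3, len(cds) - 8, 3):
        h = cds[s - 1 : s + 6]
        if "N" not in h:
            out.append((s, h))
    return out


def compute_distance(
    tmd: RefinedSegment,
    heptamer_nt_start: int,
    anchor: str = "c_term_to_p_site",
) -> Optional[int]:
    """Codon distance L from the TMD to the heptamer; None when upstream.

    The default anchor runs from the TMD C-terminal residue to the 0-frame
    P-site codon of the heptamer (its nucleotides 2-4).  The alternative
    ``c_term_to_heptamer_start`` anchor ends at the codon holding the
    heptamer's first nucleotide, one codon less.
    """
    p_site_codon = heptamer_nt_start // 3 + 1
    if anchor == "c_term_to_p_site":
        L = p_site_codon - tmd.aa_end
    elif anchor == "c_term_to_heptamer_start":
        L = p_site_codon - 1 - tmd.aa_end
    else:
        raise ValueError(f"unknown distance anchor {anchor!r}")
    return L if L > 0 else None


def assign_nearest_to_ideal(
    tmd_ends: Sequence[int],
    heptamer_codons: Sequence[int],
    l_ideal: int = L_IDEAL_DEFAULT,
) -> dict[int, tuple[int, int]]:
    """Nearest-to-ideal pairing on codon coordinates.

    ``tmd_ends`` are C-terminal residue indices, ``heptamer_codons`` the
    P-site codon indices of slippery heptamers.  Returns
    {tmd_index: (heptamer_index, L)} after both assignment passes; distances
    are unrestricted here (range filtering is the caller's concern).
    """
    best_for_hept: dict[int, tuple[int, int]] = {}  # hept idx -> (tmd idx, L)
    for hi, hc in enumerate(heptamer_codons):
        best: Optional[tuple[int, int, int]] = None  # (|L-ideal|, L, tmd idx)
        for ti, te in enumerate(tmd_ends):
            L = hc - te
            if L <= 0:
                continue
            key = (abs(L - l_ideal), L, ti)
            if best is None or key < best:
                best = key
        if best is not None:
            best_for_hept[hi] = (best[2], best[1])
    retained: dict[int, tuple[int, int]] = {}  # tmd idx -> (hept idx, L)
    for hi, (ti, L) in best_for_hept.items():
        key = (abs(L - l_ideal), L, hi)
        cur = retained.get(ti)
        if cur is None or key < (abs(cur[1] - l_ideal), cur[1], cur[0]):
            retained[ti] = (hi, L)
    return retained


def find_motifs(
    record: TranscriptRecord,
    tmds: Sequence[RefinedSegment],
    table: SlipperyTable,
    l_range: tuple[int, int] = L_RANGE_DEFAULT,
    l_ideal: int = L_IDEAL_DEFAULT,
    anchor: str = "c_term_to_p_site",
) -> list[TmdSlipMotif]:
    """TMD-slip motifs of one transcript, deduplicated and range-filtered."""
    if not record.in_frame:
        logger.warning(
            "transcript %s length not a multiple of 3; skipped", record.transcript_id
        )
        return []
    if not tmds:
        return []
    hepts = [
        (s, h) for s, h in scan_phase_aligned_heptamers(record.cds) if table.is_slippery(h)
    ]
    if not hepts:
        return []
    offset = 0 if anchor == "c_term_to_p_site" else 1
    tmd_ends = [t.aa_end + offset for t in tmds]
    hept_codons = [s // 3 + 1 for s, _ in hepts]
    retained = assign_nearest_to_ideal(tmd_ends, hept_codons, l_ideal)
    motifs = []
    for ti, (hi, L) in retained.items():
        if not (l_range[0] <= L <= l_range[1]):
            continue
        s, h = hepts[hi]
        motifs.append(
            TmdSlipMotif(
                transcript_id=record.transcript_id,
                tmd=tmds[ti],
                heptamer_nt_start=s,
                heptamer=h,
                distance_L=L,
                is_ideal=L == l_ideal,
                in_range=True,
            )
        )
    motifs.sort(key=lambda m: m.heptamer_nt_start)
    return motifs


def classify_splicing_dependence(
    records: Iterable[TranscriptRecord],
    motifs: Iterable[TmdSlipMotif],
) -> list[TmdSlipMotif]:
    """Mark alternative-isoform motifs absent from the canonical transcript.

    An alternative-isoform motif is splicing-dependent when the gene's
    canonical transcript has no in-range motif with the same heptamer
    sequence -- e.g. because the canonical spacing falls outside 35-55
    codons.  Genes lacking a canonical transcript yield ``not_applicable``;
    more than one canonical transcript per gene is a data error.
    """
    recs = list(records)
    by_tid = {r.transcript_id: r for r in recs}
    canon_by_gene: dict[str, str] = {}
    for r in recs:
        if r.is_canonical:
            if r.gene_id in canon_by_gene:
                raise ValueError(f"gene {r.gene_id} has multiple canonical transcripts")
            canon_by_gene[r.gene_id] = r.transcript_id

    canon_hepts: dict[str, set[str]] = {}  # gene -> heptamer sequences (in range)
    motif_list = list(motifs)
    for m in motif_list:
        rec = by_tid[m.transcript_id]
        if rec.is_canonical and m.in_range:
            canon_hepts.setdefault(rec.gene_id, set()).add(m.heptamer)

    out = []
    for m in motif_list:
        rec = by_tid[m.transcript_id]
        if rec.is_canonical:
            cls = SPLICING_CANONICAL
        elif rec.gene_id not in canon_by_gene:
            cls = SPLICING_NA
        elif m.heptamer in canon_hepts.get(rec.gene_id, set()):
            cls = SPLICING_CANONICAL  # same motif present in the canonical
        else:
            cls = SPLICING_DEPENDENT
        out.append(replace(m, splicing_class=cls))
    return out
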