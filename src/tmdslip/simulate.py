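"""Synthetic transcriptomes with known ground truth.

Each simulated gene encodes a membrane protein: a hydrophilic background, a
strongly hydrophobic TMD block (L/I/V/F-rich, codon-randomized), and -- when
a motif is planted -- a slippery heptamer inserted phase-aligned at a
configured codon distance L downstream of the TMD.  Splicing-dependent
motifs are realized by exon-block removal: the canonical transcript spaces
the heptamer outside the active range and the alternative isoform lacks a
spacer block, bringing the same heptamer into range of the same TMD.

At background slippery rate 0 the generator scrubs accidental phase-aligned
slippery heptamers from a guard zone [L_min - 5, L_max + 5] codons
downstream of the TMD (widened by the spacer length for splicing-dependent
genes so the isoform's guard zone is covered too): offending background
codons are re-drawn until the zone is clean, with a bounded number of
passes.  The 0-frame reading of every record is stop-free by construction
and verified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .motifs import L_RANGE_DEFAULT, scan_phase_aligned_heptamers
from .pairing import SlipperyTable, enumerate_slippery_heptamers
from .products import (
    CALL_FRAMESHIFT,
    CALL_PREMATURE,
    CALL_TRANSITIONAL,
    CALL_ZERO,
    ProteaseRule,
    digest,
    predict_frameshift_product,
)
from .stats import Upf1Record
from .transcriptome import (
    CODON_TABLE,
    STOP_CODONS,
    TranscriptRecord,
    _translate_with_stop,
)

logger = logging.getLogger(__name__)

HYDROPHILIC_AA = "STNQGDEKRH"
TMD_AA = "LIVF"
TMD_AA_WEIGHTS = (0.55, 0.20, 0.15, 0.10)

_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in sorted(CODON_TABLE.items()):
    _CODONS_FOR.setdefault(aa, []).append(codon)


def plantable_heptamers(table: SlipperyTable) -> list[str]:
    """Slippery heptamers whose 0-frame codons (nts 2-4, 5-7) are not stops."""
    return sorted(
        h
        for h in table.slippery
        if h[1:4] not in STOP_CODONS and h[4:7] not in STOP_CODONS
    )


@dataclass(frozen=True)
class PlantedMotif:
    """Specification of one planted TMD-slip motif."""

    L: int = 45
    heptamer: str = "UUUUUUA"
    tmd_len: int = 19
    isoform_only: bool = False
    canonical_L: int = 67  # spacing in the canonical when isoform_only

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("planted L must be positive")
        if self.heptamer[1:4] in STOP_CODONS or self.heptamer[4:7] in STOP_CODONS:
            raise ValueError(
                f"heptamer {self.heptamer} puts a stop codon in the 0-frame"
            )
        if self.isoform_only and L_RANGE_DEFAULT[0] <= self.canonical_L <= L_RANGE_DEFAULT[1]:
            raise ValueError("canonical_L must fall outside the active range")


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 100
    isoforms_per_gene: int = 1
    cds_length_range: tuple[int, int] = (250, 400)  # codons
    planted_motifs: Sequence[Optional[PlantedMotif]] = (PlantedMotif(),)
    background_slippery_rate: float = 0.0
    tmd_len: int = 19
    seed: int = 0
    max_scrub_passes: int = 50

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.isoforms_per_gene < 1:
            raise ValueError("n_genes and isoforms_per_gene must be >= 1")
        if not (0.0 <= self.background_slippery_rate <= 1.0):
            raise ValueError("background_slippery_rate in [0, 1]")


@dataclass
class TruthTable:
    """Ground truth for a generated transcriptome."""

    motifs: pd.DataFrame  # transcript_id, gene_id, tmd_aa_start, tmd_aa_end,
    #                       heptamer, heptamer_nt_start, L, splicing_dependent
    transcripts: pd.DataFrame  # transcript_id, gene_id, isoform_class, has_motif


def _random_codon(aa: str, rng: np.random.Generator) -> str:
    options = _CODONS_FOR[aa]
    return options[rng.integers(len(options))]


def _background_codon(rng: np.random.Generator) -> str:
    return _random_codon(HYDROPHILIC_AA[rng.integers(len(HYDROPHILIC_AA))], rng)


def _build_codons(
    n_codons: int,
    tmd_start: int,
    tmd_len: int,
    plants: Sequence[tuple[int, str]],  # (P-site codon index, heptamer)
    rng: np.random.Generator,
) -> list[str]:
    tmd_end = tmd_start + tmd_len - 1
    codons = ["AUG"]
    for i in range(2, n_codons + 1):
        if tmd_start <= i <= tmd_end:
            aa = rng.choice(list(TMD_AA), p=TMD_AA_WEIGHTS)
            codons.append(_random_codon(aa, rng))
        else:
            codons.append(_background_codon(rng))
    for p_site, heptamer in plants:
        k = p_site - 1  # codon carrying the heptamer's first nt (1-based)
        codons[k - 1] = codons[k - 1][:2] + heptamer[0]
        codons[k] = heptamer[1:4]
        codons[k + 1] = heptamer[4:7]
    return codons


def _scrub_guard_zone(
    codons: list[str],
    tmd_span: tuple[int, int],
    plants: Sequence[tuple[int, str]],
    table: SlipperyTable,
    guard: tuple[int, int],
    rng: np.random.Generator,
    max_passes: int,
) -> bool:
    """Re-draw background codons until the guard zone has no stray slippery
    heptamer.  Returns False if the zone cannot be cleaned."""
    protected: set[int] = set(range(tmd_span[0], tmd_span[1] + 1))
    semi: dict[int, str] = {}  # codon index -> fixed third nucleotide
    planted_at: dict[int, str] = {}
    for p, hep in plants:
        protected |= {p, p + 1}
        semi[p - 1] = hep[0]  # only the third nt of this codon is planted
        planted_at[3 * (p - 1)] = hep
    for _ in range(max_passes):
        cds = "".join(codons) + "UAA"
        offenders = []
        for s, h in scan_phase_aligned_heptamers(cds):
            if s in planted_at:
                continue
            if table.is_slippery(h):
                L = s // 3 + 1 - tmd_span[1]
                if guard[0] <= L <= guard[1]:
                    offenders.append(s)
        if not offenders:
            return True
        for s in offenders:
            k = s // 3  # heptamer spans codons k, k+1, k+2 (1-based)
            for ci in (k, k + 1, k + 2):
                if ci in protected or not 2 <= ci <= len(codons):
                    continue
                if ci in semi:
                    codons[ci - 1] = _background_codon(rng)[:2] + semi[ci]
                else:
                    codons[ci - 1] = _background_codon(rng)
    return False


def generate_transcriptome(
    cfg: SimConfig,
    table: Optional[SlipperyTable] = None,
) -> tuple[list[TranscriptRecord], TruthTable]:
    """Generate a transcriptome with planted motifs and its truth table.

    Genes cycle through ``cfg.planted_motifs`` (None entries give motif-free
    membrane-protein genes).  Deterministic under ``cfg.seed``.
    """
    table = table or enumerate_slippery_heptamers()
    root = np.random.SeedSequence(cfg.seed)
    gene_seeds = root.spawn(cfg.n_genes)
    extra_pool = plantable_heptamers(table)

    records: list[TranscriptRecord] = []
    motif_rows = []
    transcript_rows = []
    for g in range(cfg.n_genes):
        gid = f"SIMG{g:05d}"
        name = f"SYN{g:05d}"
        spec = (
            cfg.planted_motifs[g % len(cfg.planted_motifs)]
            if cfg.planted_motifs
            else None
        )
        if spec is not None and not table.is_slippery(spec.heptamer):
            raise ValueError(f"planted heptamer {spec.heptamer} is not slippery")
        tmd_len = spec.tmd_len if spec else cfg.tmd_len
        rng = np.random.default_rng(gene_seeds[g])

        # splicing-dependent genes get a wider guard so the isoform's guard
        # zone (shifted by the removed spacer) is scrubbed as well
        delta = (spec.canonical_L - spec.L) if spec and spec.isoform_only else 0
        guard = (L_RANGE_DEFAULT[0] - 5, L_RANGE_DEFAULT[1] + 5 + delta)
        plant_L = spec.canonical_L if spec and spec.isoform_only else (spec.L if spec else 0)
        span_after = max(plant_L + 3, 10)
        lo, hi = cfg.cds_length_range
        if tmd_len + span_after + 5 > hi:
            raise ValueError(
                f"cds_length_range {cfg.cds_length_range} cannot fit motif spec {spec}"
            )
        n_codons = int(rng.integers(max(lo, tmd_len + span_after + 5), hi + 1))
        tmd_start = int(rng.integers(5, n_codons - tmd_len - span_after + 1))
        tmd_end = tmd_start + tmd_len - 1
        plants: list[tuple[int, str]] = []
        if spec is not None:
            plants.append((tmd_end + plant_L, spec.heptamer))
        if cfg.background_slippery_rate > 0:
            for k in range(2, n_codons - 1):
                L = k - tmd_end
                in_plant = any(abs(k - p) <= 2 for p, _ in plants)
                if in_plant or tmd_start - 2 <= k <= tmd_end + 2:
                    continue
                if guard[0] <= L <= guard[1]:
                    continue  # keep the guard zone interpretable
                if rng.random() < cfg.background_slippery_rate:
                    plants.append((k, extra_pool[rng.integers(len(extra_pool))]))
        codons = _build_codons(n_codons, tmd_start, tmd_len, plants, rng)
        if not _scrub_guard_zone(
            codons, (tmd_start, tmd_end), plants, table, guard, rng,
            cfg.max_scrub_passes,
        ):
            raise RuntimeError(f"could not scrub guard zone for gene {gid}")
        cds = "".join(codons) + "UAA"
        rec = TranscriptRecord(f"SIMT{g:05d}.1", gid, name, "canonical", cds)
        aa, _ = _translate_with_stop(cds, 1)
        if len(aa) != n_codons:
            raise RuntimeError(f"internal stop in generated gene {gid}")
        records.append(rec)

        canonical_has_motif = bool(
            spec is not None
            and not spec.isoform_only
            and L_RANGE_DEFAULT[0] <= spec.L <= L_RANGE_DEFAULT[1]
        )
        transcript_rows.append(
            {
                "transcript_id": rec.transcript_id,
                "gene_id": gid,
                "isoform_class": "canonical",
                "has_motif": canonical_has_motif,
            }
        )
        if canonical_has_motif:
            motif_rows.append(
                {
                    "transcript_id": rec.transcript_id,
                    "gene_id": gid,
                    "tmd_aa_start": tmd_start,
                    "tmd_aa_end": tmd_end,
                    "heptamer": spec.heptamer,
                    "heptamer_nt_start": 3 * (tmd_end + spec.L - 1),
                    "L": spec.L,
                    "splicing_dependent": False,
                }
            )

        for iso in range(2, cfg.isoforms_per_gene + 1):
            iso_tid = f"SIMT{g:05d}.{iso}"
            if spec is not None and spec.isoform_only and iso == 2:
                # drop a spacer "exon" between TMD and heptamer so the same
                # heptamer comes into range of the same TMD
                cut_start_codon = tmd_end + 3  # short buffer after the TMD
                cut = cds[: 3 * (cut_start_codon - 1)] + cds[
                    3 * (cut_start_codon - 1 + delta):
                ]
                iso_rec = TranscriptRecord(iso_tid, gid, name, "alternative", cut)
                s_iso = 3 * (tmd_end + spec.L - 1)
                assert iso_rec.cds[s_iso - 1 : s_iso + 6] == spec.heptamer
                motif_rows.append(
                    {
                        "transcript_id": iso_tid,
                        "gene_id": gid,
                        "tmd_aa_start": tmd_start,
                        "tmd_aa_end": tmd_end,
                        "heptamer": spec.heptamer,
                        "heptamer_nt_start": s_iso,
                        "L": spec.L,
                        "splicing_dependent": True,
                    }
                )
                has = True
            else:
                # benign isoform: insert a hydrophilic codon block upstream
                # of the TMD (coordinates shift; spacing is unchanged)
                ins_len = 12
                ins = "".join(_background_codon(rng) for _ in range(ins_len))
                at = 3  # after codon 3
                cut = cds[: 3 * at] + ins + cds[3 * at :]
                iso_rec = TranscriptRecord(iso_tid, gid, name, "alternative", cut)
                has = canonical_has_motif
                if has:
                    motif_rows.append(
                        {
                            "transcript_id": iso_tid,
                            "gene_id": gid,
                            "tmd_aa_start": tmd_start + ins_len,
                            "tmd_aa_end": tmd_end + ins_len,
                            "heptamer": spec.heptamer,
                            "heptamer_nt_start": 3 * (tmd_end + ins_len + spec.L - 1),
                            "L": spec.L,
                            "splicing_dependent": False,
                        }
                    )
            records.append(iso_rec)
            transcript_rows.append(
                {
                    "transcript_id": iso_tid,
                    "gene_id": gid,
                    "isoform_class": "alternative",
                    "has_motif": has,
                }
            )

    truth = TruthTable(
        motifs=pd.DataFrame(
            motif_rows,
            columns=[
                "transcript_id", "gene_id", "tmd_aa_start", "tmd_aa_end",
                "heptamer", "heptamer_nt_start", "L", "splicing_dependent",
            ],
        ),
        transcripts=pd.DataFrame(transcript_rows),
    )
    return records, truth


def generate_upf1_table(
    n_with_motif: int,
    n_without: int,
    effect_log2fc: float,
    noise_sd: float,
    seed: int,
) -> list[Upf1Record]:
    """Fold-change table with a planted abundance shift for motif transcripts."""
    if n_with_motif <= 0 or n_without <= 0:
        raise ValueError("counts must be positive")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_with_motif):
        out.append(
            Upf1Record(f"M{i:05d}", float(rng.normal(effect_log2fc, noise_sd)), True)
        )
    for i in range(n_without):
        out.append(Upf1Record(f"N{i:05d}", float(rng.normal(0.0, noise_sd)), False))
    return out


def generate_peptide_fixtures(
    records: Sequence[TranscriptRecord],
    truth: TruthTable,
    classes: Sequence[str] = (CALL_ZERO, CALL_TRANSITIONAL, CALL_FRAMESHIFT),
    rule: Optional[ProteaseRule] = None,
) -> pd.DataFrame:
    """Labelled peptides of each requested class for classifier tests.

    Classes unrealizable for a motif (e.g. a frameshift peptide when the
    alternative-frame extension is too short) are skipped with a log line.
    Candidates that collide with the 0-frame proteome under another label
    are skipped too, so every emitted label is unambiguous by construction.
    """
    from .motifs import TmdSlipMotif
    from .products import zero_frame_proteome
    from .tmd import RefinedSegment

    rule = rule or ProteaseRule.named("trypsin", max_missed_cleavages=0)
    by_tid = {r.transcript_id: r for r in records}
    proteome = zero_frame_proteome(records)

    def in_zero_frame(seq: str) -> bool:
        return any(seq in prot for prot in proteome.values())

    rows = []
    for _, m in truth.motifs.iterrows():
        rec = by_tid[m.transcript_id]
        motif = TmdSlipMotif(
            transcript_id=m.transcript_id,
            tmd=RefinedSegment(
                int(m.tmd_aa_start), int(m.tmd_aa_end), 0.0, m.transcript_id
            ),
            heptamer_nt_start=int(m.heptamer_nt_start),
            heptamer=m.heptamer,
            distance_L=int(m.L),
            is_ideal=int(m.L) == 45,
            in_range=True,
        )
        product = predict_frameshift_product(rec, motif, -1)
        junction = len(product.prefix)
        if CALL_ZERO in classes:
            pep = next(
                (
                    p.sequence
                    for p in digest(proteome[rec.transcript_id], rule)
                    if 7 <= len(p.sequence) <= 50 and p.end < junction - 7
                ),
                None,
            )
            if pep is None:
                logger.info("no zero-frame fixture peptide for %s", rec.transcript_id)
            else:
                rows.append((pep, CALL_ZERO, None, rec.transcript_id))
        if CALL_TRANSITIONAL in classes:
            if product.extension_len < 1:
                logger.info(
                    "transitional unrealizable for %s (no extension)", rec.transcript_id
                )
            else:
                for n0 in (6, 8, 10, 12):
                    pep = product.prefix[-n0:] + product.extension[0]
                    if len(pep) == n0 + 1 and not in_zero_frame(pep):
                        rows.append((pep, CALL_TRANSITIONAL, -1, rec.transcript_id))
                        break
                else:
                    logger.info(
                        "transitional fixture collides with 0-frame for %s",
                        rec.transcript_id,
                    )
        if CALL_FRAMESHIFT in classes:
            if product.extension_len < 9:
                logger.info(
                    "frameshift unrealizable for %s (extension %d < 9)",
                    rec.transcript_id,
                    product.extension_len,
                )
            else:
                pep = product.extension[1:9]
                if in_zero_frame(pep):
                    logger.info(
                        "frameshift fixture collides with 0-frame for %s",
                        rec.transcript_id,
                    )
                else:
                    rows.append((pep, CALL_FRAMESHIFT, -1, rec.transcript_id))
        if CALL_PREMATURE in classes:
            if not (product.terminated and product.extension_len == 0):
                logger.info(
                    "premature termination unrealizable for %s", rec.transcript_id
                )
            else:
                pep = product.prefix[-10:]
                if len(pep) >= 7:
                    rows.append((pep, CALL_PREMATURE, -1, rec.transcript_id))
    return pd.DataFrame(rows, columns=["peptide", "label", "frame", "transcript_id"])
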