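"""Randomization null models and the tests used to assess motif context.

Two null ensembles probe whether slippery heptamers sit non-randomly
relative to TMDs: re-placing each transcript's TMD segments uniformly at
random (count- and length-preserving, non-overlapping) while heptamer
positions stay fixed, or re-drawing the slippery heptamer set itself
uniformly from the 16,384-heptamer space while TMDs stay fixed.  The
observed distance distribution is compared against the pooled null
distances with a two-tailed Mann-Whitney U test, and the count of
ideally-spaced (L = 45) motifs against the null mean with a Pearson
chi-square odds ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .motifs import L_IDEAL_DEFAULT, L_RANGE_DEFAULT, assign_nearest_to_ideal

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    odds_ratio: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("at least one margin must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    def sample_odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return math.inf if self.a * self.d > 0 else math.nan
        return (self.a * self.d) / (self.b * self.c)


@dataclass(frozen=True)
class NullEnsembleConfig:
    n_iterations: int = 16384
    seed: int = 0
    mode: str = "randomize_tmd_positions"

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.mode not in ("randomize_tmd_positions", "randomize_heptamer_sets"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class Upf1Record:
    transcript_id: str
    log2_fold_change: float
    has_motif: bool

    def __post_init__(self) -> None:
        if not math.isfinite(self.log2_fold_change):
            raise ValueError("log2_fold_change must be finite")


# --- rank / exact tests ---------------------------------------------------


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> TestResult:
    """Mann-Whitney U with tie correction.

    The exact null distribution is used for tie-free samples with
    n1*n2 <= 400; otherwise the normal approximation with tie correction
    (and no continuity correction, so identical samples give p = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and x.size * y.size <= 400:
        res = sps.mannwhitneyu(x, y, alternative=alternative, method="exact")
        return TestResult(float(res.statistic), float(res.pvalue))
    res = sps.mannwhitneyu(
        x, y, alternative=alternative, method="asymptotic", use_continuity=False
    )
    p = float(res.pvalue)
    if math.isnan(p):  # zero variance: every observation tied
        p = 1.0
    return TestResult(float(res.statistic), min(p, 1.0))


def fisher_exact(
    table: ContingencyTable2x2, alternative: str = "two-sided"
) -> TestResult:
    """Conditional hypergeometric test with the sample odds ratio ad/bc."""
    arr = table.as_array()
    if arr.sum(axis=1).min() == 0 or arr.sum(axis=0).min() == 0:
        return TestResult(math.nan, 1.0, None)
    res = sps.fisher_exact(arr, alternative=alternative)
    return TestResult(
        float(res[0]), float(res[1]), table.sample_odds_ratio()
    )


def chi2_association(table: ContingencyTable2x2) -> TestResult:
    """Pearson chi-square (df=1, no continuity correction) plus ad/bc."""
    arr = table.as_array().astype(float)
    row = arr.sum(axis=1)
    col = arr.sum(axis=0)
    n = arr.sum()
    expected = np.outer(row, col) / n
    if (expected == 0).any():
        raise ValueError("zero expected count; use fisher_exact instead")
    stat = float(((arr - expected) ** 2 / expected).sum())
    p = float(sps.chi2.sf(stat, df=1))
    return TestResult(stat, p, table.sample_odds_ratio())


# --- randomizations -------------------------------------------------------


def _random_starts(
    protein_len: int, lengths: Sequence[int], rng: np.random.Generator
) -> Optional[list[int]]:
    """Uniform non-overlapping placement of segments; 1-based starts.

    Segment order along the protein follows the order of ``lengths``.
    Returns None when the segments cannot fit.
    """
    k = len(lengths)
    free = protein_len - int(sum(lengths))
    if free < 0:
        return None
    if k == 0:
        return []
    # uniform over placements via the stars-and-bars bijection: a sorted
    # k-combination of {0..free+k-1} encodes the free space before each
    # segment as g_i = slots[i] - i, so start_i = g_i + 1 + sum(lengths[:i])
    slots = np.sort(rng.choice(free + k, size=k, replace=False))
    starts = []
    cum = 0
    for i, s in enumerate(slots):
        starts.append(int(s) - i + 1 + cum)
        cum += int(lengths[i])
    return starts


def randomize_tmd_positions(
    tmds_by_transcript: Mapping[str, tuple[int, Sequence[int]]],
    seed: int | np.random.Generator,
) -> dict[str, list[tuple[int, int]]]:
    """Length- and count-preserving uniform re-placement of TMD segments.

    ``tmds_by_transcript`` maps transcript_id -> (protein_length, [segment
    lengths, N- to C-terminal order]).  Returns transcript_id -> [(aa_start,
    aa_end), ...].  Transcripts whose segments cannot fit keep their input
    geometry unchanged (a warning is logged) -- callers should pass the
    original placement in that case.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: dict[str, list[tuple[int, int]]] = {}
    for tid, (plen, lengths) in tmds_by_transcript.items():
        starts = _random_starts(plen, lengths, rng)
        if starts is None:
            logger.warning("transcript %s too short to re-place TMDs; kept as-is", tid)
            out[tid] = []
            continue
        out[tid] = [(s, s + ln - 1) for s, ln in zip(starts, lengths)]
    return out


def sample_random_heptamer_sets(
    n_sets: int,
    set_size: int,
    seed: int | np.random.Generator,
    space_size: int = 4**7,
) -> list[frozenset[int]]:
    """Mutually distinct uniform subsets of the heptamer space (as indices)."""
    if set_size > space_size:
        raise ValueError("set_size exceeds the heptamer space")
    if set_size == space_size and n_sets > 1:
        raise ValueError("only one full-space set exists")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sets: list[frozenset[int]] = []
    seen: set[frozenset[int]] = set()
    attempts = 0
    while len(sets) < n_sets:
        s = frozenset(rng.choice(space_size, size=set_size, replace=False).tolist())
        attempts += 1
        if attempts > 50 * n_sets + 100:
            raise ValueError("cannot draw enough distinct heptamer sets")
        if s in seen:
            continue
        seen.add(s)
        sets.append(s)
    return sets


# --- positional null test -------------------------------------------------


@dataclass(frozen=True)
class TranscriptGeometry:
    """Minimal per-transcript geometry for the positional null.

    ``heptamer_codons`` are P-site codon indices of *all* phase-aligned
    heptamers, with ``heptamer_ids`` their integer encodings (base-4); the
    slippery subset is selected via the table or a randomized id set.
    """

    transcript_id: str
    protein_len: int
    tmd_spans: tuple[tuple[int, int], ...]
    heptamer_codons: np.ndarray
    heptamer_ids: np.ndarray


_BASE_INDEX = {b: i for i, b in enumerate("ACGU")}


def encode_heptamer(h: str) -> int:
    code = 0
    for b in h:
        code = code * 4 + _BASE_INDEX[b]
    return code


def transcript_geometry(record, tmds) -> TranscriptGeometry:
    """Build the null-test geometry for one transcript."""
    from .motifs import scan_phase_aligned_heptamers

    hepts = scan_phase_aligned_heptamers(record.cds)
    codons = np.array([s // 3 + 1 for s, _ in hepts], dtype=np.int64)
    ids = np.array([encode_heptamer(h) for _, h in hepts], dtype=np.int64)
    return TranscriptGeometry(
        record.transcript_id,
        record.n_codons - 1,  # exclude the stop codon
        tuple((t.aa_start, t.aa_end) for t in tmds),
        codons,
        ids,
    )


def _distances(
    tmd_ends: Sequence[int],
    hept_codons: Sequence[int],
    l_range: tuple[int, int],
    l_ideal: int,
) -> list[int]:
    retained = assign_nearest_to_ideal(tmd_ends, hept_codons, l_ideal)
    return [L for _, L in retained.values() if l_range[0] <= L <= l_range[1]]


def observed_distances(
    geometries: Sequence[TranscriptGeometry],
    slippery_ids: frozenset[int] | set[int],
    l_range: tuple[int, int] = L_RANGE_DEFAULT,
    l_ideal: int = L_IDEAL_DEFAULT,
) -> list[int]:
    out: list[int] = []
    for g in geometries:
        mask = np.isin(g.heptamer_ids, list(slippery_ids))
        ends = [b for _, b in g.tmd_spans]
        out.extend(_distances(ends, g.heptamer_codons[mask].tolist(), l_range, l_ideal))
    return out


@dataclass
class PositionalNullResult:
    observed: list[int]
    null_pooled: list[int]
    n_iterations: int
    mwu: TestResult
    chi2_l45: TestResult
    counts: pd.DataFrame = field(repr=False)


def positional_null_test(
    geometries: Sequence[TranscriptGeometry],
    slippery_ids: Iterable[int],
    cfg: NullEnsembleConfig,
    l_range: tuple[int, int] = L_RANGE_DEFAULT,
    l_ideal: int = L_IDEAL_DEFAULT,
) -> PositionalNullResult:
    """Compare observed motif distances against a randomized ensemble.

    Returns the pooled null distances, a two-tailed Mann-Whitney comparison,
    the per-distance count table (observed vs null mean), and a chi-square
    odds ratio contrasting ideal-spacing counts with the null expectation.
    """
    slippery_ids = frozenset(int(i) for i in slippery_ids)
    rng = np.random.default_rng(cfg.seed)
    observed = observed_distances(geometries, slippery_ids, l_range, l_ideal)

    # precompute, per transcript, the slippery heptamer codon positions
    # (fixed-heptamer mode) or the full position/id arrays
    slip_codons = []
    for g in geometries:
        mask = np.isin(g.heptamer_ids, list(slippery_ids))
        slip_codons.append(g.heptamer_codons[mask].tolist())

    set_size = len(slippery_ids)
    null_pooled: list[int] = []
    for _ in range(cfg.n_iterations):
        if cfg.mode == "randomize_tmd_positions":
            for g, codons in zip(geometries, slip_codons):
                lengths = [b - a + 1 for a, b in g.tmd_spans]
                starts = _random_starts(g.protein_len, lengths, rng)
                if starts is None:
                    ends = [b for _, b in g.tmd_spans]
                else:
                    ends = [s + ln - 1 for s, ln in zip(starts, lengths)]
                null_pooled.extend(_distances(ends, codons, l_range, l_ideal))
        else:  # randomize_heptamer_sets
            ids = frozenset(
                rng.choice(4**7, size=set_size, replace=False).tolist()
            )
            null_pooled.extend(observed_distances(geometries, ids, l_range, l_ideal))

    if observed and null_pooled:
        mwu = mann_whitney_u(observed, null_pooled)
    else:
        mwu = TestResult(math.nan, 1.0)

    ls = list(range(l_range[0], l_range[1] + 1))
    obs_counts = [observed.count(L) for L in ls]
    null_mean = [null_pooled.count(L) / cfg.n_iterations for L in ls]
    counts = pd.DataFrame({"L": ls, "observed": obs_counts, "null_mean": null_mean})

    obs45 = observed.count(l_ideal)
    null45 = null_pooled.count(l_ideal) / cfg.n_iterations
    tot_obs = len(observed)
    tot_null = len(null_pooled) / cfg.n_iterations
    try:
        chi2 = chi2_association(
            ContingencyTable2x2(
                obs45,
                tot_obs - obs45,
                int(round(null45)),
                int(round(tot_null - null45)),
            )
        )
    except ValueError:
        chi2 = TestResult(math.nan, 1.0, None)
    return PositionalNullResult(
        observed, null_pooled, cfg.n_iterations, mwu, chi2, counts
    )


# --- NMD association and term enrichment ----------------------------------


def nmd_association(
    records: Sequence[Upf1Record],
    up_threshold: float = 0.263,
    down_threshold: float = -0.263,
) -> dict[str, TestResult]:
    """Motif association with UPF1-sensitive abundance changes.

    Fisher tests of motif membership against up- and down-regulation plus a
    two-tailed Mann-Whitney on log2 fold-changes of motif-bearing vs
    motif-free transcripts.
    """
    if not records:
        raise ValueError("records must be non-empty")
    with_motif = [r.log2_fold_change for r in records if r.has_motif]
    without = [r.log2_fold_change for r in records if not r.has_motif]
    if not with_motif or not without:
        raise ValueError("both motif classes must be represented")

    def table(predicate) -> ContingencyTable2x2:
        a = sum(1 for r in records if r.has_motif and predicate(r.log2_fold_change))
        b = sum(1 for r in records if r.has_motif and not predicate(r.log2_fold_change))
        c = sum(1 for r in records if not r.has_motif and predicate(r.log2_fold_change))
        d = sum(
            1 for r in records if not r.has_motif and not predicate(r.log2_fold_change)
        )
        return ContingencyTable2x2(a, b, c, d)

    return {
        "fisher_up": fisher_exact(table(lambda v: v > up_threshold)),
        "fisher_down": fisher_exact(table(lambda v: v < down_threshold)),
        "mann_whitney": mann_whitney_u(with_motif, without),
    }


def term_enrichment(
    hit_genes: set[str],
    background_genes: set[str],
    annotation: pd.DataFrame,
    min_genes: int = 100,
    min_fold: float = 1.4,
    depth_range: tuple[int, int] = (3, 8),
) -> pd.DataFrame:
    """Per-term Fisher enrichment of hit genes against a background.

    ``annotation`` needs columns term, gene, depth.  Terms are retained when
    at least ``min_genes`` hit genes carry the term, the odds ratio exceeds
    ``min_fold`` and the term depth lies within ``depth_range``; adjusted
    p-values (Benjamini-Hochberg) are computed across all tested terms.
    """
    if not hit_genes <= background_genes:
        raise ValueError("hit genes must be a subset of the background")
    if annotation.empty:
        return pd.DataFrame(
            columns=["term", "depth", "n_hit", "n_background", "odds_ratio", "p", "p_adj"]
        )
    rows = []
    n_bg = len(background_genes)
    n_hit = len(hit_genes)
    for (term, depth), group in annotation.groupby(["term", "depth"]):
        genes = set(group["gene"]) & background_genes
        a = len(genes & hit_genes)
        b = n_hit - a
        c = len(genes) - a
        d = n_bg - n_hit - c
        res = fisher_exact(ContingencyTable2x2(a, b, c, d))
        rows.append(
            {
                "term": term,
                "depth": int(depth),
                "n_hit": a,
                "n_background": len(genes),
                "odds_ratio": res.odds_ratio,
                "p": res.p_value,
            }
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    keep = (
        (df["n_hit"] >= min_genes)
        & (df["odds_ratio"] > min_fold)
        & df["depth"].between(*depth_range)
    )
    return df[keep].sort_values("odds_ratio", ascending=False).reset_index(drop=True)
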