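"""Transmembrane-domain proposal and translocon-energetics refinement.

A candidate TMD region comes either from an external topology prediction
(one-letter i/o/M states per residue, as produced by consensus topology
predictors) or from a built-in hydrophobicity scan.  Each region is then
refined to the single 16-25 residue segment, inside a window extending 10
residues on either side of the region, that minimizes the apparent free
energy of translocon-mediated membrane insertion (dG_app): the segment the
translocon most readily integrates.  The C-terminal edge of that refined
segment anchors all downstream distance measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional

SEGMENT_MIN_LEN = 16
SEGMENT_MAX_LEN = 25
REFINE_FLANK = 10


@dataclass(frozen=True)
class DgScale:
    """Per-residue insertion free-energy coefficients (kcal/mol).

    ``center`` holds the contribution of each amino acid at the membrane
    center.  In the default ``center_only`` mode every residue of a segment
    contributes its center coefficient.  The ``positional`` mode attenuates
    contributions toward the segment edges with a Gaussian depth profile of
    width ``sigma`` (in residues) and adds a quadratic length correction
    around the optimal segment length -- a simplified stand-in for the full
    position-specific parameterization of the published predictor.
    """

    center: dict[str, float]
    mode: str = "center_only"  # "center_only" | "positional"
    sigma: float = 6.5
    length_coef: float = 0.0123
    length_opt: int = 19

    def __post_init__(self) -> None:
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.center)
        if missing:
            raise ValueError(f"scale missing residues {sorted(missing)}")
        if self.center["L"] >= self.center["A"]:
            raise ValueError("leucine must be more favorable than alanine")
        if self.mode not in ("center_only", "positional"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def default(cls, mode: str = "center_only") -> "DgScale":
        text = (
            resources.files("tmdslip.data").joinpath("dg_scale.tsv").read_text()
        )
        center: dict[str, float] = {}
        for line in text.splitlines():
            if not line.strip() or line.startswith("#") or line.startswith("aa"):
                continue
            aa, value = line.split("\t")
            center[aa] = float(value)
        return cls(center=center, mode=mode)


@dataclass(frozen=True)
class TmdRegion:
    """A proposed TMD region in protein (residue) coordinates, 1-based."""

    transcript_id: str
    aa_start: int
    aa_end: int
    source: str  # "topcons_file" | "builtin_scan"

    def __post_init__(self) -> None:
        if not (1 <= self.aa_start <= self.aa_end):
            raise ValueError("require 1 <= aa_start <= aa_end")
        if self.aa_end - self.aa_start + 1 < 10:
            raise ValueError("TMD region shorter than 10 residues")


@dataclass(frozen=True)
class RefinedSegment:
    """The minimum-dG_app 16-25 residue segment for one TMD region."""

    aa_start: int
    aa_end: int
    dg_app: float
    transcript_id: str = ""

    @property
    def length(self) -> int:
        return self.aa_end - self.aa_start + 1


def dg_app(segment: str, scale: Optional[DgScale] = None) -> float:
    """Apparent membrane-insertion free energy of a 16-25 residue segment.

    Lower values mean the translocon partitions the segment into the
    membrane more readily.
    """
    scale = scale or DgScale.default()
    n = len(segment)
    if not (SEGMENT_MIN_LEN <= n <= SEGMENT_MAX_LEN):
        raise ValueError(f"segment length {n} outside [{SEGMENT_MIN_LEN}, {SEGMENT_MAX_LEN}]")
    try:
        if scale.mode == "center_only":
            return sum(scale.center[aa] for aa in segment)
        mid = (n - 1) / 2.0
        total = sum(
            scale.center[aa] * math.exp(-(((i - mid) / scale.sigma) ** 2))
            for i, aa in enumerate(segment)
        )
        return total + scale.length_coef * (n - scale.length_opt) ** 2
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r} in segment") from exc


def parse_topology(transcript_id: str, protein: str, topology: str) -> list[TmdRegion]:
    """Extract M-state runs from a per-residue topology string."""
    if len(topology) != len(protein):
        raise ValueError(
            f"topology length {len(topology)} != protein length {len(protein)}"
        )
    regions: list[TmdRegion] = []
    start = None
    for i, state in enumerate(topology + "."):  # sentinel flushes final run
        if state == "M":
            if start is None:
                start = i
        elif start is not None:
            regions.append(TmdRegion(transcript_id, start + 1, i, "topcons_file"))
            start = None
    return regions


def propose_tmd_regions(
    protein: str,
    mode: str = "builtin_scan",
    topology: Optional[str] = None,
    transcript_id: str = "",
    scale: Optional[DgScale] = None,
    dg_cutoff: float = 1.0,
    window: int = 19,
    merge_gap: int = 5,
) -> list[TmdRegion]:
    """Propose candidate TMD regions for one protein.

    ``topcons_file`` mode parses an externally supplied topology string.
    ``builtin_scan`` marks maximal runs of residues covered by a sliding
    ``window``-residue segment whose dG_app falls below ``dg_cutoff``,
    merging runs separated by fewer than ``merge_gap`` residues.
    """
    if not protein:
        raise ValueError("protein must be non-empty")
    if mode == "topcons_file":
        if topology is None:
            raise ValueError("topcons_file mode requires a topology string")
        return parse_topology(transcript_id, protein, topology)
    if mode != "builtin_scan":
        raise ValueError(f"unknown mode {mode!r}")

    scale = scale or DgScale.default()
    n = len(protein)
    if n < window:
        return []
    hits: list[tuple[int, int]] = []  # covered residue spans, 0-based inclusive
    for s in range(n - window + 1):
        seg = protein[s : s + window]
        if any(aa not in scale.center for aa in seg):
            continue
        if dg_app(seg, scale) < dg_cutoff:
            hits.append((s, s + window - 1))
    if not hits:
        return []
    merged: list[list[int]] = [list(hits[0])]
    for a, b in hits[1:]:
        if a - merged[-1][1] < merge_gap:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [
        TmdRegion(transcript_id, a + 1, b + 1, "builtin_scan") for a, b in merged
    ]


def refine_tmd_segment(
    protein: str,
    region: TmdRegion,
    scale: Optional[DgScale] = None,
) -> RefinedSegment:
    """Exhaustively pick the minimum-dG_app 16-25 residue segment.

    All segments fully inside ``[aa_start - 10, aa_end + 10]`` (clipped to
    the protein) are enumerated; ties break toward the shorter segment, then
    the smaller start, so the result is deterministic.
    """
    scale = scale or DgScale.default()
    if region.aa_end > len(protein):
        raise ValueError(f"region {region} outside protein of length {len(protein)}")
    lo = max(1, region.aa_start - REFINE_FLANK)
    hi = min(len(protein), region.aa_end + REFINE_FLANK)
    if hi - lo + 1 < SEGMENT_MIN_LEN:
        raise ValueError(
            f"refinement window [{lo}, {hi}] for {region.transcript_id} "
            f"({region.aa_start}-{region.aa_end}) shorter than {SEGMENT_MIN_LEN}"
        )
    best: Optional[tuple[float, int, int]] = None  # (dg, length, start)
    for start in range(lo, hi + 1):
        for length in range(SEGMENT_MIN_LEN, SEGMENT_MAX_LEN + 1):
            end = start + length - 1
            if end > hi:
                break
            seg = protein[start - 1 : end]
            if any(aa not in scale.center for aa in seg):
                continue
            key = (dg_app(seg, scale), length, start)
            if best is None or key < best:
                best = key
    if best is None:
        raise ValueError(
            f"no scoreable segment in window [{lo}, {hi}] for {region.transcript_id}"
        )
    dg, length, start = best
    return RefinedSegment(start, start + length - 1, dg, region.transcript_id)
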