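"""Codon-anticodon pairing energetics and slippery-heptamer classification.

During a -1 frameshift the P- and A-site tRNAs detach from the 0-frame
codons of a heptamer N1..N7 (positions 2-4 and 5-7) and re-pair with the
-1-frame codons (positions 1-3 and 4-6).  The frameshift propensity score
dG_FS is the free-energy penalty of that re-pairing relative to cognate
pairing:

    dG_FS = [E(ac(N2N3N4) : N1N2N3) + E(ac(N5N6N7) : N4N5N6)]
          - [E(ac(N2N3N4) : N2N3N4) + E(ac(N5N6N7) : N5N6N7)]

where ac() is the perfect Watson-Crick anticodon and E scores a three-pair
minihelix with nearest-neighbor stacking.  Homopolymers re-pair onto
identical codons, so their dG_FS is exactly zero; small positive values mark
slippery sequences.

The minihelix energy sums the two stacking steps (Turner-style
nearest-neighbor values, uniformly scaled during calibration), treats G.U
as a pair with a per-pair wobble term, and replaces each mismatched
position by a flat penalty that also voids the adjacent stacking steps.
The bundled parameters are calibrated so the 24 classical X XXY YYZ motifs
span dG_FS in [0, 2.89] kcal/mol, below the +2.9 kcal/mol classification
cutoff.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional

BASES = "ACGU"
COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: published classification cutoff, kcal/mol
DEFAULT_THRESHOLD = 2.9
HEPTAMER_SPACE_SIZE = 4**7

_WOBBLE_STEPS = {("G", "A"), ("U", "C")}  # (-1 base, 0-frame base) giving G.U
# a G.U pair stacks approximately like its Watson-Crick analog
_GU_ANALOG = {("G", "U"): ("A", "U"), ("U", "G"): ("U", "A")}

Pair = tuple[str, str]
Step = tuple[Pair, Pair]


def _load_wc_stacks() -> dict[Step, float]:
    """Expand the bundled ten canonical Turner WC steps to all sixteen."""
    text = resources.files("tmdslip.data").joinpath("turner_wc_stacks.tsv").read_text()
    stacks: dict[Step, float] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("step"):
            continue
        step, value = line.split("\t")
        top, bottom = step.split("/")
        # X pairs Z, Y pairs W for step XY/WZ (second strand 5'->3')
        p1: Pair = (top[0], bottom[1])
        p2: Pair = (top[1], bottom[0])
        v = float(value)
        stacks[(p1, p2)] = v
        stacks[((p2[1], p2[0]), (p1[1], p1[0]))] = v  # duplex flip symmetry
    if len(stacks) != 16:
        raise ValueError(f"expected 16 WC steps after expansion, got {len(stacks)}")
    return stacks


@dataclass(frozen=True)
class PairingEnergyModel:
    """Knowledge-based codon-anticodon pairing model.

    ``wc_stacks`` carries the raw Turner Watson-Crick step values; ``scale``
    is a uniform multiplier applied to every stacking step;
    ``mismatch_penalty`` is the flat cost of a mismatched position (which
    also voids adjacent stacks) and ``wobble_pair_penalty`` the per-pair
    cost of a G.U wobble.  Defaults are the calibrated bundled parameters.
    """

    wc_stacks: Mapping[Step, float] = field(default_factory=_load_wc_stacks)
    scale: float = 0.425
    mismatch_penalty: float = 0.52
    wobble_pair_penalty: float = 0.50

    def __post_init__(self) -> None:
        if self.mismatch_penalty < 0:
            raise ValueError("mismatch_penalty must be >= 0")

    def stack(self, p1: Pair, p2: Pair) -> float:
        return self.scale * self.wc_stacks[(_GU_ANALOG.get(p1, p1), _GU_ANALOG.get(p2, p2))]


def _check_codon(codon: str) -> None:
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")


def anticodon_pairing_energy(
    anticodon_of: str, against: str, model: Optional[PairingEnergyModel] = None
) -> float:
    """Energy of the cognate anticodon of one codon paired against another.

    The anticodon is the perfect Watson-Crick complement of ``anticodon_of``.
    Each position of ``against`` is Watson-Crick, G.U wobble, or mismatched
    against it; stacking steps require both flanking positions paired.
    """
    model = model or PairingEnergyModel()
    _check_codon(anticodon_of)
    _check_codon(against)
    states = []
    pairs: list[Pair] = []
    for c, d in zip(anticodon_of, against):
        if d == c:
            states.append("WC")
        elif (d, c) in _WOBBLE_STEPS:
            states.append("GU")
        else:
            states.append("MM")
        pairs.append((d, COMPLEMENT[c]))
    energy = 0.0
    for j in (0, 1):
        if states[j] != "MM" and states[j + 1] != "MM":
            energy += model.stack(pairs[j], pairs[j + 1])
    energy += model.mismatch_penalty * states.count("MM")
    energy += model.wobble_pair_penalty * states.count("GU")
    return energy


def dg_fs(heptamer: str, model: Optional[PairingEnergyModel] = None) -> float:
    """Frameshift propensity score of a heptamer, kcal/mol, rounded to 0.01."""
    model = model or PairingEnergyModel()
    if len(heptamer) != 7 or any(b not in BASES for b in heptamer):
        raise ValueError(f"invalid heptamer {heptamer!r}")
    p0, a0 = heptamer[1:4], heptamer[4:7]
    pm1, am1 = heptamer[0:3], heptamer[3:6]
    shifted = anticodon_pairing_energy(p0, pm1, model) + anticodon_pairing_energy(
        a0, am1, model
    )
    cognate = anticodon_pairing_energy(p0, p0, model) + anticodon_pairing_energy(
        a0, a0, model
    )
    return round(shifted - cognate, 2)


def load_reference_motifs() -> list[str]:
    """The 24 classical X XXY YYZ slippery heptamers bundled with the package."""
    text = (
        resources.files("tmdslip.data")
        .joinpath("reference_slippery_heptamers.txt")
        .read_text()
    )
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


def calibrate_threshold(
    reference_motifs: Iterable[str], model: Optional[PairingEnergyModel] = None
) -> float:
    """Upper bound of the dG_FS range spanned by known slippery motifs."""
    scores = [dg_fs(h, model) for h in reference_motifs]
    if not scores:
        raise ValueError("reference motif list must be non-empty")
    return max(scores)


@dataclass(frozen=True)
class SlipScore:
    heptamer: str
    dg_fs: float
    is_slippery: bool


@dataclass(frozen=True)
class SlipperyTable:
    """Full heptamer census with the slippery subset at a given threshold."""

    threshold: float
    scores: Mapping[str, float]
    slippery: frozenset[str]

    def is_slippery(self, heptamer: str) -> bool:
        return heptamer in self.slippery

    def __len__(self) -> int:
        return len(self.slippery)

    def entries(self) -> list[SlipScore]:
        return [
            SlipScore(h, s, h in self.slippery) for h, s in sorted(self.scores.items())
        ]


def enumerate_slippery_heptamers(
    model: Optional[PairingEnergyModel] = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> SlipperyTable:
    """Score all 4^7 heptamers and collect those with dG_FS < threshold."""
    model = model or PairingEnergyModel()
    scores: dict[str, float] = {}
    for tup in itertools.product(BASES, repeat=7):
        h = "".join(tup)
        scores[h] = dg_fs(h, model)
    slippery = frozenset(h for h, s in scores.items() if s < threshold)
    return SlipperyTable(threshold, scores, slippery)
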