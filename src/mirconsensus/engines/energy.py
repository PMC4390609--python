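"""Nearest-neighbor duplex energy model.

Stack free energies (kcal/mol, 37 C) for adjacent base pairs ship as a
packaged TSV keyed ``XY/ZW``: strand 1 read 5'->3' gives ``XY``, strand 2
read 3'->5' gives ``ZW``, so X pairs Z and Y pairs W.  The table covers the
36 combinations of Watson-Crick and G.U wobble pairs; Watson-Crick entries
follow standard published nearest-neighbor values, wobble-containing
entries likewise, with the two symmetric double-wobble stacks clamped to
small negative values so that every complementary stack stabilizes the
duplex.  Loops and bulges carry a simple affine penalty rather than full
tabulated loop energies, and loops longer than ``max_loop`` unpaired
nucleotides per strand are forbidden — both are deliberate model choices,
not approximations of any specific folding package.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

BASES = "ACGU"
_ENC = {b: i for i, b in enumerate(BASES)}

#: canonical (Watson-Crick + wobble) pairs as (base, base) tuples
CANONICAL_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}

PAIR_OK = np.zeros((4, 4), dtype=bool)
for _a, _b in CANONICAL_PAIRS:
    PAIR_OK[_ENC[_a], _ENC[_b]] = True

WATSON_CRICK = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
WOBBLE = {("G", "U"), ("U", "G")}


def encode(seq: str) -> np.ndarray:
    """Encode an RNA string as int codes A=0 C=1 G=2 U=3."""
    try:
        return np.array([_ENC[b] for b in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-ACGU base {exc.args[0]!r} in sequence") from None


@dataclass(frozen=True)
class EnergyModel:
    """Duplex energy parameters: stacks, affine loop costs, initiation."""

    stacks: dict[str, float]
    loop_open: float = 2.0
    loop_extend: float = 0.5
    initiation: float = 4.09
    max_loop: int = 6
    #: stack energies as a [16, 16] array indexed by dinucleotide codes
    stack_array: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        for key, dg in self.stacks.items():
            if dg >= 0:
                raise ValueError(f"stack {key} has non-negative energy {dg}")
        if self.loop_open < 0 or self.loop_extend < 0:
            raise ValueError("loop penalties must be non-negative")
        arr = np.full((16, 16), np.inf)
        for key, dg in self.stacks.items():
            s1, s2 = key.split("/")
            c1 = 4 * _ENC[s1[0]] + _ENC[s1[1]]
            c2 = 4 * _ENC[s2[0]] + _ENC[s2[1]]
            arr[c1, c2] = dg
        object.__setattr__(self, "stack_array", arr)

    def stack_energy(self, s1: str, s2: str) -> float:
        """Energy of stacking pair (s1[1], s2[1]) on pair (s1[0], s2[0]).

        ``s1`` is the 5'->3' dinucleotide on strand 1, ``s2`` the 3'->5'
        dinucleotide on strand 2.
        """
        return self.stacks[f"{s1}/{s2}"]

    def loop_cost(self, unpaired1: int, unpaired2: int) -> float:
        """Affine cost of an internal loop/bulge with the given unpaired counts."""
        total = unpaired1 + unpaired2
        if total <= 0:
            raise ValueError("loop must have at least one unpaired base")
        if unpaired1 > self.max_loop or unpaired2 > self.max_loop:
            return float("inf")
        return self.loop_open + self.loop_extend * total


def default_model(**overrides) -> EnergyModel:
    """Load the packaged stack table into an :class:`EnergyModel`."""
    ref = resources.files("mirconsensus.engines").joinpath("data/stack_energies.tsv")
    stacks: dict[str, float] = {}
    with ref.open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            stacks[row["stack"]] = float(row["dg"])
    return EnergyModel(stacks=stacks, **overrides)
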