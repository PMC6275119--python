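"""First-order pentamer model of local DNA shape.

Four structural parameters are predicted from sequence with a sliding
pentamer lookup: minor groove width (MGW, Å) and propeller twist (ProT,
degrees) are base-pair-level quantities assigned to the central base of each
pentamer; roll and helix twist (HelT, degrees) are base-pair-*step*
quantities, each pentamer contributing values for its two central steps.
Overlapping step contributions from adjacent pentamers are averaged, and a
base-pair-level Roll/HelT value at position i is the mean of the defined
step values flanking i.

For a sequence of length L (1-based positions):

* MGW/ProT are defined at positions 3..L-2;
* step values exist at steps 2..L-2 (step j sits between bases j and j+1);
* base-pair-level Roll/HelT are defined wherever at least one adjacent step
  is defined (positions 2..L-1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._seq import BASES, is_acgt, revcomp
from .errors import CompletenessError, ContractError, ParseError

logger = logging.getLogger(__name__)

SHAPE_PARAMS = ("MGW", "ProT", "Roll", "HelT")
PENTAMER_COLUMNS = ("mgw", "prot", "roll_left", "roll_right", "helt_left", "helt_right")

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def pentamer_index(pentamer: str) -> int:
    """Base-4 integer code of a 5-mer (A=0, C=1, G=2, T=3)."""
    code = 0
    for c in pentamer:
        code = code * 4 + _BASE_INDEX[c]
    return code


def all_pentamers() -> list[str]:
    """The 1024 pentamers in lexicographic (= index) order."""
    out = []
    for i in range(1024):
        code, chars = i, []
        for _ in range(5):
            chars.append(BASES[code % 4])
            code //= 4
        out.append("".join(reversed(chars)))
    return out


@dataclass
class PentamerShapes:
    """Shape values of one pentamer (central base pair and central steps)."""

    mgw: float
    prot: float
    roll_left: float
    roll_right: float
    helt_left: float
    helt_right: float


@dataclass
class PentamerTable:
    """Complete 5-mer -> shape-value lookup.

    ``values`` holds one row per pentamer (lexicographic order) and one
    column per entry of :data:`PENTAMER_COLUMNS`.  When ``symmetric`` the
    table satisfies the reverse-complement identities
    mgw(s)=mgw(rc(s)), prot(s)=prot(rc(s)),
    roll_left(s)=roll_right(rc(s)), helt_left(s)=helt_right(rc(s)).
    """

    values: np.ndarray
    symmetric: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (1024, 6):
            raise ContractError(
                f"pentamer table must be 1024 x 6, got {self.values.shape}"
            )
        if not np.isfinite(self.values).all():
            raise ContractError("pentamer table contains non-finite values")
        if self.symmetric:
            self.check_symmetry()

    def __getitem__(self, pentamer: str) -> PentamerShapes:
        if len(pentamer) != 5 or not is_acgt(pentamer):
            raise ContractError(f"not a valid pentamer: {pentamer!r}")
        return PentamerShapes(*self.values[pentamer_index(pentamer)])

    def check_symmetry(self, atol: float = 1e-9) -> None:
        """Raise unless the reverse-complement identities hold."""
        for s in all_pentamers():
            a = self.values[pentamer_index(s)]
            b = self.values[pentamer_index(revcomp(s))]
            ok = (
                abs(a[0] - b[0]) <= atol  # mgw
                and abs(a[1] - b[1]) <= atol  # prot
                and abs(a[2] - b[3]) <= atol  # roll_left vs roll_right
                and abs(a[4] - b[5]) <= atol  # helt_left vs helt_right
            )
            if not ok:
                raise ContractError(
                    f"table not reverse-complement symmetric at {s}/{revcomp(s)}"
                )

    @classmethod
    def from_mapping(
        cls, mapping: Mapping[str, Iterable[float]], symmetric: bool = False
    ) -> "PentamerTable":
        missing = 1024 - len(set(mapping) & set(all_pentamers()))
        if missing:
            raise CompletenessError(f"pentamer table missing {missing} pentamers")
        values = np.empty((1024, 6))
        for pent, row in mapping.items():
            values[pentamer_index(pent)] = list(row)
        return cls(values, symmetric=symmetric)


def load_pentamer_table(path: str | Path, symmetric: bool = False) -> PentamerTable:
    """Load a tab-delimited pentamer table (7 columns, header optional).

    Duplicate pentamer rows: last wins, with a warning.  Missing pentamers
    raise :class:`CompletenessError`; non-numeric values :class:`ParseError`.
    """
    path = Path(path)
    rows: dict[str, list[float]] = {}
    duplicates = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            pent = parts[0].upper()
            if lineno == 1 and not (len(pent) == 5 and is_acgt(pent)):
                continue  # header row
            if len(pent) != 5 or not is_acgt(pent):
                raise ParseError(f"{path} line {lineno}: bad pentamer {parts[0]!r}")
            if len(parts) != 7:
                raise ParseError(f"{path} line {lineno}: expected 7 columns")
            try:
                vals = [float(x) for x in parts[1:]]
            except ValueError as exc:
                raise ParseError(f"{path} line {lineno}: non-numeric value") from exc
            if pent in rows:
                duplicates += 1
            rows[pent] = vals
    if duplicates:
        logger.warning(
            "load_pentamer_table(%s): %d duplicate pentamer rows (last wins)",
            path,
            duplicates,
        )
    return PentamerTable.from_mapping(rows, symmetric=symmetric)


def write_pentamer_table(table: PentamerTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pentamer\t" + "\t".join(PENTAMER_COLUMNS) + "\n")
        for pent in all_pentamers():
            row = table.values[pentamer_index(pent)]
            fh.write(pent + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


@dataclass
class ShapeProfile:
    """Per-position shape values with defined-position masks.

    Arrays are indexed 0-based (array index i <-> sequence position i+1);
    undefined entries are NaN with ``mask`` False.  ``roll_steps`` /
    ``helt_steps`` hold step-level values (index j <-> step j+1, the step
    between bases j+1 and j+2).
    """

    seq: str
    mgw: np.ndarray
    prot: np.ndarray
    roll: np.ndarray
    helt: np.ndarray
    roll_steps: np.ndarray
    helt_steps: np.ndarray
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def values(self, param: str) -> np.ndarray:
        return {"MGW": self.mgw, "ProT": self.prot, "Roll": self.roll, "HelT": self.helt}[
            param
        ]

    def to_frame(self) -> pd.DataFrame:
        """Per-position table (1-based ``position`` column, NA where undefined)."""
        return pd.DataFrame(
            {
                "position": np.arange(1, len(self.seq) + 1),
                "base": list(self.seq),
                "MGW": self.mgw,
                "ProT": self.prot,
                "Roll": self.roll,
                "HelT": self.helt,
            }
        )


def shape_profiles(seq: str, table: PentamerTable) -> ShapeProfile:
    """Compute MGW/ProT/Roll/HelT profiles of ``seq`` under the pentamer model."""
    if len(seq) < 5:
        raise ContractError(f"sequence length must be >= 5, got {len(seq)}")
    if not is_acgt(seq):
        raise ContractError("sequence contains bases outside ACGT")
    L = len(seq)
    mgw = np.full(L, np.nan)
    prot = np.full(L, np.nan)
    # pentamer centered at 1-based position i covers i-2..i+2
    codes = np.empty(L + 1, dtype=int)  # codes[i] = index of pentamer centered at i
    for i in range(3, L - 1):  # 1-based centers 3..L-2
        idx = pentamer_index(seq[i - 3 : i + 2])
        codes[i] = idx
        mgw[i - 1] = table.values[idx, 0]
        prot[i - 1] = table.values[idx, 1]

    # step j (1-based, between bases j and j+1) exists for j = 2..L-2
    roll_steps = np.full(L - 1, np.nan)
    helt_steps = np.full(L - 1, np.nan)
    for j in range(2, L - 1):  # 1-based steps 2..L-2
        contrib_roll: list[float] = []
        contrib_helt: list[float] = []
        if 3 <= j <= L - 2:  # right step of pentamer centered at j
            contrib_roll.append(table.values[codes[j], 3])
            contrib_helt.append(table.values[codes[j], 5])
        if 3 <= j + 1 <= L - 2:  # left step of pentamer centered at j+1
            contrib_roll.append(table.values[codes[j + 1], 2])
            contrib_helt.append(table.values[codes[j + 1], 4])
        roll_steps[j - 1] = float(np.mean(contrib_roll))
        helt_steps[j - 1] = float(np.mean(contrib_helt))

    # base-pair level Roll/HelT: mean of defined adjacent steps
    roll = np.full(L, np.nan)
    helt = np.full(L, np.nan)
    for i in range(2, L):  # 1-based positions 2..L-1
        adj_r = [roll_steps[k - 1] for k in (i - 1, i) if 2 <= k <= L - 2]
        adj_h = [helt_steps[k - 1] for k in (i - 1, i) if 2 <= k <= L - 2]
        if adj_r:
            roll[i - 1] = float(np.mean(adj_r))
            helt[i - 1] = float(np.mean(adj_h))

    masks = {
        "MGW": ~np.isnan(mgw),
        "ProT": ~np.isnan(prot),
        "Roll": ~np.isnan(roll),
        "HelT": ~np.isnan(helt),
    }
    return ShapeProfile(seq, mgw, prot, roll, helt, roll_steps, helt_steps, masks)


SHAPE_WINDOW_FLANK = 7  # 15-mer: minimal window defining all 11 central positions
_SHAPE_OFFSETS = tuple(range(-5, 6))


def shape_feature_names() -> list[str]:
    """The 88 shape feature names in canonical column order."""
    names = []
    for param in SHAPE_PARAMS:
        for off in _SHAPE_OFFSETS:
            names.append(f"shape_{param}_mut_{off:+d}")
        for off in _SHAPE_OFFSETS:
            names.append(f"shape_{param}_diff_{off:+d}")
    return names


def shape_feature_vector(
    ref_window: str, mut_window: str, table: PentamerTable
) -> np.ndarray:
    """The 88 shape features of one SNV.

    Inputs are 15-mers (flank 7 around the variant) differing only at the
    center.  For each parameter (MGW, ProT, Roll, HelT): the 11 mutated
    base-pair-level values at offsets -5..+5 from the variant, followed by
    the 11 differences (mutated - reference) at the same offsets.
    """
    if len(ref_window) != 15 or len(mut_window) != 15:
        raise ContractError("shape windows must be 15-mers (flank 7)")
    if ref_window[7] == mut_window[7]:
        raise ContractError("ref and mut windows share the center base")
    if ref_window[:7] != mut_window[:7] or ref_window[8:] != mut_window[8:]:
        raise ContractError("windows differ outside the center base")
    ref_prof = shape_profiles(ref_window, table)
    mut_prof = shape_profiles(mut_window, table)
    center = 8  # 1-based
    out = np.empty(88)
    k = 0
    for param in SHAPE_PARAMS:
        mut_vals = mut_prof.values(param)
        ref_vals = ref_prof.values(param)
        for off in _SHAPE_OFFSETS:
            out[k] = mut_vals[center + off - 1]
            k += 1
        for off in _SHAPE_OFFSETS:
            out[k] = mut_vals[center + off - 1] - ref_vals[center + off - 1]
            k += 1
    if not np.isfinite(out).all():
        raise ContractError("undefined shape value inside the 11-position grid")
    return out
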