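"""N-glycan composition arithmetic.

A released N-glycan is described here purely by its monosaccharide
composition: counts of hexose (Hex; mannose/galactose/glucose),
N-acetylhexosamine (HexNAc), deoxyhexose (dHex; fucose) and
N-acetylneuraminic acid (NeuAc; sialic acid).  In positive-mode MALDI
imaging of PNGaseF-released glycans the dominant species is the sodiated
adduct [M+Na]+, so observed m/z values are matched against theoretical
sodiated monoisotopic masses of enumerated candidate compositions.

Residue masses are the monoisotopic masses of the dehydrated residues
(the condensation product that appears inside a chain), derived from
standard atomic monoisotopic masses:

    Hex    C6H10O5  =  6*C + 10*H +     5*O             = 162.05282 Da
    HexNAc C8H13NO5 =  8*C + 13*H + N + 5*O             = 203.07937 Da
    dHex   C6H10O4  =  6*C + 10*H +     4*O             = 146.05791 Da
    NeuAc  C11H17NO8= 11*C + 17*H + N + 8*O             = 291.09542 Da

with C = 12 exactly, H = 1.00782503207, N = 14.0030740048,
O = 15.9949146196 and Na = 22.9897692809 (CODATA/IUPAC).  The neutral
molecule adds one water (the free reducing end); the sodium cation
adduct adds Na minus one electron mass (5.4857990e-4).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import pandas as pd

__all__ = [
    "GlycanComposition",
    "GlycanClass",
    "MatchConfig",
    "RESIDUE_MASSES",
    "WATER_MASS",
    "SODIUM_ADDUCT_MASS",
    "monoisotopic_mass",
    "sodiated_mz",
    "enumerate_compositions",
    "match_mz",
    "classify",
    "class_flags",
    "parse_composition",
    "annotate_peak_list",
    "read_peak_list",
    "write_peak_list",
]

# Atomic monoisotopic masses (Da)
_MASS_H = 1.00782503207
_MASS_C = 12.0
_MASS_N = 14.0030740048
_MASS_O = 15.9949146196
_MASS_NA = 22.9897692809
_MASS_ELECTRON = 0.00054857991

#: Monoisotopic residue masses (Da), >= 5 decimals; see module docstring.
RESIDUE_MASSES: dict[str, float] = {
    "Hex": 6 * _MASS_C + 10 * _MASS_H + 5 * _MASS_O,        # 162.05282
    "HexNAc": 8 * _MASS_C + 13 * _MASS_H + _MASS_N + 5 * _MASS_O,  # 203.07937
    "dHex": 6 * _MASS_C + 10 * _MASS_H + 4 * _MASS_O,       # 146.05791
    "NeuAc": 11 * _MASS_C + 17 * _MASS_H + _MASS_N + 8 * _MASS_O,  # 291.09542
}

#: Mass of water added to a residue chain to obtain the free glycan (Da).
WATER_MASS: float = 2 * _MASS_H + _MASS_O  # 18.01056

#: Sodium cation adduct: Na minus one electron (Da).
SODIUM_ADDUCT_MASS: float = _MASS_NA - _MASS_ELECTRON  # 22.98922


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Monosaccharide counts defining a candidate N-glycan.

    Ordering and lexicographic comparisons use the field order
    (n_hex, n_hexnac, n_dhex, n_neuac).
    """

    n_hex: int = 0
    n_hexnac: int = 0
    n_dhex: int = 0
    n_neuac: int = 0

    def __post_init__(self) -> None:
        for name in ("n_hex", "n_hexnac", "n_dhex", "n_neuac"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def is_valid_nglycan(self) -> bool:
        """True if the composition can carry the trimannosyl-chitobiose core
        (at least 2 HexNAc and 3 Hex)."""
        return self.n_hexnac >= 2 and self.n_hex >= 3

    def combine(self, other: "GlycanComposition") -> "GlycanComposition":
        """Residue-wise sum (glycosidic condensation of two glycans)."""
        return GlycanComposition(
            self.n_hex + other.n_hex,
            self.n_hexnac + other.n_hexnac,
            self.n_dhex + other.n_dhex,
            self.n_neuac + other.n_neuac,
        )

    def __str__(self) -> str:
        return format_composition(self)


class GlycanClass(str, Enum):
    """Structural grouping of N-glycans by composition.

    Exhaustive and mutually exclusive under the precedence
    high_mannose > fucosylated > sialylated > branched > other.
    """

    HIGH_MANNOSE = "high_mannose"
    FUCOSYLATED = "fucosylated"
    SIALYLATED = "sialylated"
    BRANCHED = "branched"
    OTHER_COMPLEX_HYBRID = "other_complex_hybrid"


@dataclass(frozen=True)
class MatchConfig:
    """Settings for composition enumeration and m/z matching.

    tolerance_da:  accept |theoretical - observed| <= tolerance (default
                   0.3 Da, the matching tolerance used for TOF data).
    mz_min/mz_max: acquisition window (default m/z 700-3000).
    bounds:        inclusive (lo, hi) count bounds per residue; defaults
                   cover single-charged N-glycans in the window without
                   combinatorial blowup.
    """

    tolerance_da: float = 0.3
    mz_min: float = 700.0
    mz_max: float = 3000.0
    hex_bounds: tuple[int, int] = (3, 12)
    hexnac_bounds: tuple[int, int] = (2, 8)
    dhex_bounds: tuple[int, int] = (0, 4)
    neuac_bounds: tuple[int, int] = (0, 4)

    def __post_init__(self) -> None:
        if self.tolerance_da < 0:
            raise ValueError("tolerance_da must be >= 0")
        if not self.mz_min < self.mz_max:
            raise ValueError("mz window lower bound must be below upper bound")
        for lo, hi in (self.hex_bounds, self.hexnac_bounds,
                       self.dhex_bounds, self.neuac_bounds):
            if lo < 0 or hi < lo:
                raise ValueError("count bounds must satisfy 0 <= lo <= hi")


def monoisotopic_mass(c: GlycanComposition) -> float:
    """Neutral monoisotopic mass (Da): sum of residue masses plus one water.

    Additive up to water: mass(a.combine(b)) == mass(a) + mass(b) - water.
    """
    return (
        c.n_hex * RESIDUE_MASSES["Hex"]
        + c.n_hexnac * RESIDUE_MASSES["HexNAc"]
        + c.n_dhex * RESIDUE_MASSES["dHex"]
        + c.n_neuac * RESIDUE_MASSES["NeuAc"]
        + WATER_MASS
    )


def sodiated_mz(c: GlycanComposition) -> float:
    """m/z of the singly charged sodiated adduct [M+Na]+ (Da)."""
    return monoisotopic_mass(c) + SODIUM_ADDUCT_MASS


def enumerate_compositions(cfg: MatchConfig | None = None) -> list[GlycanComposition]:
    """All valid N-glycan compositions within bounds whose sodiated m/z
    lies in the configured window, in lexicographic count order."""
    cfg = cfg or MatchConfig()
    out: list[GlycanComposition] = []
    for nh, nn, nd, ns in itertools.product(
        range(cfg.hex_bounds[0], cfg.hex_bounds[1] + 1),
        range(cfg.hexnac_bounds[0], cfg.hexnac_bounds[1] + 1),
        range(cfg.dhex_bounds[0], cfg.dhex_bounds[1] + 1),
        range(cfg.neuac_bounds[0], cfg.neuac_bounds[1] + 1),
    ):
        c = GlycanComposition(nh, nn, nd, ns)
        if not c.is_valid_nglycan:
            continue
        if cfg.mz_min <= sodiated_mz(c) <= cfg.mz_max:
            out.append(c)
    out.sort()
    return out


def match_mz(
    mz: float, cfg: MatchConfig | None = None
) -> list[tuple[GlycanComposition, float]]:
    """Candidate compositions for an observed m/z.

    Returns (composition, mass error) pairs with error = sodiated_mz - mz,
    restricted to |error| <= tolerance, sorted by |error| ascending.
    Raises ValueError for an m/z outside the configured window.
    """
    cfg = cfg or MatchConfig()
    if not cfg.mz_min <= mz <= cfg.mz_max:
        raise ValueError(
            f"observed m/z {mz} outside window [{cfg.mz_min}, {cfg.mz_max}]"
        )
    hits = []
    for c in enumerate_compositions(cfg):
        err = sodiated_mz(c) - mz
        if abs(err) <= cfg.tolerance_da:
            hits.append((c, err))
    hits.sort(key=lambda t: (abs(t[1]), t[0]))
    return hits


def classify(c: GlycanComposition) -> GlycanClass:
    """Assign a composition to exactly one structural class.

    Precedence: high-mannose (chitobiose core with only mannoses,
    HexNAc==2, Hex>=5, no fucose/sialic acid) > fucosylated (any dHex)
    > sialylated (any NeuAc) > tri-/tetra-antennary branched
    (HexNAc>=5) > other complex/hybrid.
    """
    if not c.is_valid_nglycan:
        raise ValueError(f"{c} is not a valid N-glycan composition")
    if c.n_hexnac == 2 and c.n_hex >= 5 and c.n_dhex == 0 and c.n_neuac == 0:
        return GlycanClass.HIGH_MANNOSE
    if c.n_dhex >= 1:
        return GlycanClass.FUCOSYLATED
    if c.n_neuac >= 1:
        return GlycanClass.SIALYLATED
    if c.n_hexnac >= 5:
        return GlycanClass.BRANCHED
    return GlycanClass.OTHER_COMPLEX_HYBRID


def class_flags(c: GlycanComposition) -> dict[str, bool]:
    """Non-exclusive structural feature flags (a glycan can be both
    fucosylated and sialylated; `classify` applies a precedence)."""
    if not c.is_valid_nglycan:
        raise ValueError(f"{c} is not a valid N-glycan composition")
    return {
        "high_mannose": c.n_hexnac == 2 and c.n_hex >= 5
        and c.n_dhex == 0 and c.n_neuac == 0,
        "fucosylated": c.n_dhex >= 1,
        "sialylated": c.n_neuac >= 1,
        "branched": c.n_hexnac >= 5,
    }


# --- composition string syntax -------------------------------------------

_RESIDUE_FIELD = {
    "Hex": "n_hex",
    "dHex": "n_dhex",
    "HexNAc": "n_hexnac",
    "NeuAc": "n_neuac",
}
# longest token first so "HexNAc" is not consumed as "Hex"
_TOKEN_RE = re.compile(r"(HexNAc|NeuAc|dHex|Hex)(\d+)")


def format_composition(c: GlycanComposition) -> str:
    """Canonical string, residues in Hex, dHex, HexNAc, NeuAc order with
    zero counts omitted (e.g. 'Hex5dHex1HexNAc4')."""
    parts = []
    for name in ("Hex", "dHex", "HexNAc", "NeuAc"):
        n = getattr(c, _RESIDUE_FIELD[name])
        if n:
            parts.append(f"{name}{n}")
    return "".join(parts) or "Free"


def parse_composition(s: str) -> GlycanComposition:
    """Inverse of :func:`format_composition`; accepts residues in any order."""
    if s == "Free":
        return GlycanComposition()
    counts = {f: 0 for f in _RESIDUE_FIELD.values()}
    pos = 0
    for m in _TOKEN_RE.finditer(s):
        if m.start() != pos:
            raise ValueError(f"cannot parse composition string {s!r}")
        field_name = _RESIDUE_FIELD[m.group(1)]
        if counts[field_name]:
            raise ValueError(f"duplicate residue token in {s!r}")
        counts[field_name] = int(m.group(2))
        pos = m.end()
    if pos != len(s):
        raise ValueError(f"cannot parse composition string {s!r}")
    return GlycanComposition(**counts)


# --- peak-list annotation I/O --------------------------------------------

def read_peak_list(path) -> pd.DataFrame:
    """Read a delimited peak list with columns mz, intensity."""
    df = pd.read_csv(path, sep="\t")
    if not {"mz", "intensity"}.issubset(df.columns):
        raise ValueError("peak list must have columns 'mz' and 'intensity'")
    return df


def write_peak_list(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def annotate_peak_list(
    mzs: Iterable[float], cfg: MatchConfig | None = None
) -> pd.DataFrame:
    """Annotate observed m/z values with their best composition match.

    Returns a table with columns mz, composition, mass_error_da,
    glycan_class; unmatched channels keep empty composition/class and are
    carried through (they remain usable, unannotated, downstream).
    """
    cfg = cfg or MatchConfig()
    rows = []
    for mz in mzs:
        try:
            hits = match_mz(float(mz), cfg)
        except ValueError:
            hits = []
        if hits:
            comp, err = hits[0]
            rows.append(
                {
                    "mz": float(mz),
                    "composition": format_composition(comp),
                    "mass_error_da": err,
                    "glycan_class": classify(comp).value,
                }
            )
        else:
            rows.append(
                {"mz": float(mz), "composition": "", "mass_error_da": float("nan"),
                 "glycan_class": ""}
            )
    return pd.DataFrame(rows)
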