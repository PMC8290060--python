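"""Elemental-formula prediction and exact-mass dereplication.

Ions observed in ESI-HRMS are matched to elemental compositions over
C/H/N/O/P/S by exhaustive, mass-pruned search, filtered by chemical
plausibility heuristics (RDBE range and integrality, element ratios), and to
library compounds by comparing theoretical adduct masses within a ppm/absolute
tolerance window.  An anomeric-configuration helper classifies sugar anomers
from their H-1/H-2 coupling constant.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidFormulaError

# Monoisotopic masses in Da (IUPAC/CODATA).  C is exactly 12 by definition.
ELEMENT_MASSES: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
}
ELECTRON_MASS = 0.00054857990907
PROTON_MASS = 1.007276466  # m(H) - m(e-); the charge carrier in [M+H]+/[M-H]-
SODIUM_MASS = 22.9897692809

ELEMENT_ORDER = ("C", "H", "N", "O", "P", "S")

#: m/z offset added to the neutral monoisotopic mass for each supported adduct,
#: electron mass included (even-electron ions).
ADDUCT_SHIFTS: dict[str, float] = {
    "[M+H]+": PROTON_MASS,
    "[M-H]-": -PROTON_MASS,
    "[M+Na]+": SODIUM_MASS - ELECTRON_MASS,
    "[M+HCOO]-": ELEMENT_MASSES["H"] + 12.0 + 2 * ELEMENT_MASSES["O"] + ELECTRON_MASS,
}
POSITIVE_ADDUCTS = ("[M+H]+", "[M+Na]+")
NEGATIVE_ADDUCTS = ("[M-H]-", "[M+HCOO]-")

#: Default per-element maximum counts for the formula search.  Chosen to cover
#: the largest ion of interest (m/z ~1441 for a proanthocyanidin pentamer)
#: without combinatorial blow-up.
DEFAULT_BOUNDS: dict[str, int] = {"C": 70, "H": 110, "N": 6, "O": 35, "P": 3, "S": 3}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation molecular formula into element counts.

    Only C, H, N, O, P, S are supported.
    """
    if not formula or not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", formula):
        raise InvalidFormulaError(f"cannot parse formula {formula!r}")
    counts: dict[str, int] = {}
    for elem, num in _FORMULA_RE.findall(formula):
        if not elem:
            continue
        if elem not in ELEMENT_MASSES:
            raise InvalidFormulaError(f"unsupported element {elem!r} in {formula!r}")
        counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
    return counts


def format_formula(counts: Mapping[str, int]) -> str:
    """Render element counts in Hill order (C, H, then alphabetical)."""
    parts = []
    for elem in ELEMENT_ORDER:
        n = counts.get(elem, 0)
        if n == 1:
            parts.append(elem)
        elif n > 1:
            parts.append(f"{elem}{n}")
    return "".join(parts)


def neutral_mass(counts: Mapping[str, int]) -> float:
    """Monoisotopic mass of the neutral molecule in Da."""
    try:
        return sum(ELEMENT_MASSES[e] * int(n) for e, n in counts.items() if n)
    except KeyError as exc:
        raise InvalidFormulaError(f"unsupported element {exc.args[0]!r}") from exc


def theoretical_mz(counts: Mapping[str, int] | str, adduct: str) -> float:
    """Theoretical m/z of the given adduct of a neutral formula.

    [M+H]+ = M + 1.007276 and [M-H]- = M - 1.007276 (proton mass, i.e. with
    the electron-mass correction folded in).
    """
    if isinstance(counts, str):
        counts = parse_formula(counts)
    if adduct not in ADDUCT_SHIFTS:
        raise ValueError(f"unknown adduct {adduct!r}")
    if any(n < 0 for n in counts.values()):
        raise InvalidFormulaError("negative element count")
    if adduct == "[M-H]-" and counts.get("H", 0) < 1:
        raise InvalidFormulaError("[M-H]- requires at least one hydrogen")
    return neutral_mass(counts) + ADDUCT_SHIFTS[adduct]


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed mass error in parts per million: (obs - theo)/theo * 1e6."""
    return (observed - theoretical) / theoretical * 1e6


def rdbe(counts: Mapping[str, int]) -> float:
    """Ring-and-double-bond equivalents: C + 1 + (N + P)/2 - H/2.

    Divalent O and S contribute zero.
    """
    c = counts.get("C", 0)
    h = counts.get("H", 0)
    n = counts.get("N", 0)
    p = counts.get("P", 0)
    return c + 1.0 + (n + p) / 2.0 - h / 2.0


@dataclass(frozen=True)
class FormulaCandidate:
    """One elemental composition compatible with an observed ion."""

    counts: tuple[int, ...]  # in ELEMENT_ORDER
    neutral_mass: float
    theoretical_mz: float
    ppm_error: float
    rdbe: float

    @property
    def formula(self) -> str:
        return format_formula(dict(zip(ELEMENT_ORDER, self.counts)))

    def as_dict(self) -> dict[str, int]:
        return {e: n for e, n in zip(ELEMENT_ORDER, self.counts) if n}


def _passes_heuristics(c: int, h: int, n: int, o: int, p: int, s: int,
                       rdbe_min: float, rdbe_max: float) -> bool:
    """Element-ratio and RDBE plausibility filters for a neutral molecule."""
    if c < 1:
        return False
    r = c + 1.0 + (n + p) / 2.0 - h / 2.0
    if not (rdbe_min <= r <= rdbe_max):
        return False
    if (h + n + p) % 2 != 0:  # RDBE must be integer for an even-electron neutral
        return False
    hc = h / c
    if not (0.1 <= hc <= 6.0):
        return False
    if n / c > 4.0 or o / c > 3.0 or p / c > 2.0 or s / c > 3.0:
        return False
    return True


def effective_tolerance(mz: float, tolerance_ppm: float, tolerance_mz: float,
                        combine: str = "larger") -> float:
    """Absolute tolerance window in Da for an ion at the given m/z.

    The ppm and absolute tolerances combine as the larger of the two by
    default (an "A or B" acceptance window); "smaller" is available for a
    stricter reading.
    """
    ppm_da = tolerance_ppm * 1e-6 * mz
    if combine == "larger":
        return max(ppm_da, tolerance_mz)
    if combine == "smaller":
        return min(ppm_da, tolerance_mz)
    raise ValueError(f"combine must be 'larger' or 'smaller', got {combine!r}")


def predict_formula(
    mz: float,
    adduct: str = "[M+H]+",
    tolerance_ppm: float = 5.0,
    tolerance_mz: float = 0.001,
    bounds: Mapping[str, int] | None = None,
    rdbe_range: tuple[float, float] = (0.0, 40.0),
    combine: str = "larger",
) -> list[FormulaCandidate]:
    """Exhaustively search CHNOPS compositions compatible with an observed ion.

    The search iterates over C, N, O, P, S counts with mass pruning and solves
    for the hydrogen count from the mass remainder (the tolerance window is far
    narrower than one hydrogen mass, so at most one H count can match per
    heteroatom combination).  Candidates must pass RDBE restrictions (range and
    integrality on the neutral molecule) and element-ratio heuristics, and are
    sorted by absolute ppm error, ties broken by fewer heteroatoms then
    lexicographic counts.

    Returns an empty list when nothing matches.
    """
    if mz <= 0:
        raise ValueError("mz must be positive")
    if adduct not in ADDUCT_SHIFTS:
        raise ValueError(f"unknown adduct {adduct!r}")
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)

    target = mz - ADDUCT_SHIFTS[adduct]  # neutral mass to explain
    tol = effective_tolerance(mz, tolerance_ppm, tolerance_mz, combine)
    if target <= 0:
        return []
    m = ELEMENT_MASSES
    # The [M-H]- adduct removes one H from the molecule, so require H >= 1.
    h_floor = 1 if adduct == "[M-H]-" else 0

    out: list[FormulaCandidate] = []
    hi = target + tol
    c_max = min(b["C"], int(hi // m["C"]))
    for c in range(1, c_max + 1):
        mc = c * m["C"]
        if mc > hi:
            break
        for n in range(min(b["N"], int((hi - mc) // m["N"])) + 1):
            mn = mc + n * m["N"]
            for p in range(min(b["P"], int((hi - mn) // m["P"])) + 1):
                mp = mn + p * m["P"]
                for s in range(min(b["S"], int((hi - mp) // m["S"])) + 1):
                    ms = mp + s * m["S"]
                    for o in range(min(b["O"], int((hi - ms) // m["O"])) + 1):
                        rem = target - ms - o * m["O"]
                        if rem < -tol:
                            break
                        h = round(rem / m["H"])
                        if h < h_floor or h > b["H"]:
                            continue
                        nm = ms + o * m["O"] + h * m["H"]
                        if abs(nm - target) > tol:
                            continue
                        if not _passes_heuristics(c, h, n, o, p, s, *rdbe_range):
                            continue
                        theo = nm + ADDUCT_SHIFTS[adduct]
                        out.append(FormulaCandidate(
                            counts=(c, h, n, o, p, s),
                            neutral_mass=nm,
                            theoretical_mz=theo,
                            ppm_error=ppm_error(mz, theo),
                            rdbe=rdbe({"C": c, "H": h, "N": n, "P": p}),
                        ))
    out.sort(key=lambda f: (abs(f.ppm_error),
                            f.counts[2] + f.counts[3] + f.counts[4] + f.counts[5],
                            f.counts))
    return out


def isotope_pattern_filter(candidates: Sequence[FormulaCandidate],
                           m1_relative_intensity: float | None = None,
                           tolerance: float = 0.25) -> list[FormulaCandidate]:
    """Optional isotope-pattern plausibility filter.

    Aligned feature tables carry no isotope envelope (deisotoping happens
    upstream), so this hook only acts when the relative intensity of the M+1
    isotopologue is supplied: candidates whose predicted M+1 intensity
    (dominated by 1.1% per carbon) deviates from the observation by more than
    ``tolerance`` (relative) are dropped.  With no observation the input is
    returned unchanged.
    """
    if m1_relative_intensity is None:
        return list(candidates)
    kept = []
    for cand in candidates:
        c = cand.counts[0]
        predicted = 0.0107 * c + 0.000115 * cand.counts[1] + 0.000364 * cand.counts[2]
        if abs(predicted - m1_relative_intensity) <= tolerance * max(m1_relative_intensity, predicted):
            kept.append(cand)
    return kept


def classify_anomeric(coupling_hz: float) -> str:
    """Assign sugar anomeric configuration from the 3J(H-1,H-2) coupling.

    Couplings above 5.0 Hz indicate a trans-diaxial arrangement (beta anomer
    for glucopyranosides); 0-5.0 Hz indicates alpha.
    """
    if coupling_hz < 0:
        raise ValueError("coupling constant must be nonnegative")
    return "beta" if coupling_hz > 5.0 else "alpha"


@dataclass(frozen=True)
class AnnotationHit:
    """A library compound whose adduct mass matches a feature within tolerance."""

    feature_id: str
    mz: float
    adduct: str
    name: str
    formula: str
    compound_class: str
    ppm_error: float


def dereplicate(
    matrix,
    library: pd.DataFrame,
    tolerance_ppm: float = 5.0,
    tolerance_mz: float = 0.001,
    adducts: Iterable[str] = ("[M+H]+", "[M-H]-"),
    combine: str = "larger",
) -> list[AnnotationHit]:
    """Match features to library compounds by exact adduct mass.

    ``matrix`` is a :class:`~seasonfuse.ms_features.FeatureMatrix`;
    ``library`` a DataFrame with columns name/formula/class.  Every
    polarity-compatible (feature, adduct, record) combination within tolerance
    yields a hit — exact mass cannot distinguish isomers, so one feature may
    receive several hits.
    """
    if library.empty:
        raise ValueError("compound library is empty")
    adducts = tuple(adducts)
    # Precompute theoretical masses per (record, adduct).
    theo: list[tuple[str, str, str, str, float]] = []
    for rec in library.to_dict("records"):
        counts = parse_formula(rec["formula"])
        for adduct in adducts:
            if adduct == "[M-H]-" and counts.get("H", 0) < 1:
                continue
            theo.append((rec["name"], rec["formula"], rec["class"], adduct,
                         theoretical_mz(counts, adduct)))
    hits: list[AnnotationHit] = []
    for feat in matrix.features.itertuples(index=False):
        compatible = POSITIVE_ADDUCTS if feat.polarity == "positive" else NEGATIVE_ADDUCTS
        tol = effective_tolerance(feat.mz, tolerance_ppm, tolerance_mz, combine)
        for name, formula, cls, adduct, t in theo:
            if adduct not in compatible:
                continue
            if abs(feat.mz - t) <= tol:
                hits.append(AnnotationHit(feat.feature_id, feat.mz, adduct,
                                          name, formula, cls, ppm_error(feat.mz, t)))
    return hits


def hits_to_frame(hits: Sequence[AnnotationHit]) -> pd.DataFrame:
    """Annotation hits as a flat table for CSV export."""
    return pd.DataFrame(
        [(h.feature_id, h.mz, h.adduct, h.name, h.formula, h.ppm_error, h.compound_class)
         for h in hits],
        columns=["feature_id", "mz", "adduct", "name", "formula", "ppm_error", "class"],
    )
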