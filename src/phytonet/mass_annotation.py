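"""Monoisotopic mass arithmetic and candidate-formula fitting for Q-TOF peaks.

ESI quasi-molecular ions ([M+H]+, [M-H]- and friends) are singly charged, so
an observed m/z maps back to a neutral monoisotopic mass by subtracting a
fixed charge-carrier delta.  Candidate elemental compositions for a peak are
enumerated exhaustively inside per-element count bounds, kept when the
relative mass deviation is within the instrument tolerance (5 ppm for a
modern Q-TOF) and when the ring-and-double-bond equivalent (RDBE) is
non-negative, and ranked by absolute ppm error.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ISOTOPE_MASS",
    "ELECTRON_MASS",
    "ADDUCTS",
    "DEFAULT_BOUNDS",
    "AdductSpec",
    "ElementalComposition",
    "MassPeak",
    "FormulaCandidate",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "rdbe",
    "fit_formulas",
    "assign_best_adduct",
    "read_peak_table",
    "candidates_to_frame",
    "load_reference_peaks",
]

# Most-abundant-isotope masses in Da (CODATA/AME).  12C defines the dalton.
ISOTOPE_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.99491461956,
    "Na": 22.9897692809,
    "Cl": 34.96885268,
    "S": 31.97207100,
    "P": 30.97376163,
}

ELECTRON_MASS = 0.00054857990907

# Valence-based RDBE contribution per atom: (valence - 2) / 2.
_RDBE_CONTRIB: dict[str, float] = {
    "C": 1.0,   # tetravalent
    "H": -0.5,  # monovalent
    "Cl": -0.5,
    "Na": -0.5,  # treated as H-like
    "N": 0.5,   # trivalent
    "P": 0.5,
    "O": 0.0,   # divalent
    "S": 0.0,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class AdductSpec:
    """A singly charged ESI charge carrier.

    ``mass_delta`` is added to the neutral monoisotopic mass to obtain the
    observed m/z; it is electron-corrected (a protonated cation is lighter
    than M + H by one electron, an anion heavier).
    """

    name: str
    polarity: str  # "positive" | "negative"
    mass_delta: float


ADDUCTS: dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", "positive", +1.00727646),
    "[M+Na]+": AdductSpec("[M+Na]+", "positive", +22.98922142),
    "[M-H]-": AdductSpec("[M-H]-", "negative", -1.00727646),
    "[M+Cl]-": AdductSpec("[M+Cl]-", "negative", +34.96940126),
    "[M+COOH]-": AdductSpec("[M+COOH]-", "negative", +44.99820285),
}


class ElementalComposition(Mapping[str, int]):
    """Immutable element -> count map over the supported element set.

    Supports addition (element-wise) and Hill-notation formatting
    (C first, H second, remaining elements alphabetical).
    """

    __slots__ = ("_counts", "_hash")

    def __init__(self, counts: Mapping[str, int]):
        clean: dict[str, int] = {}
        for sym, n in counts.items():
            if sym not in ISOTOPE_MASS:
                raise ValueError(f"unknown element symbol: {sym!r}")
            n = int(n)
            if n < 0:
                raise ValueError(f"negative count for element {sym}: {n}")
            if n != counts[sym]:
                raise ValueError(f"non-integer count for element {sym}")
            if n > 0:
                clean[sym] = n
        if not clean:
            raise ValueError("composition must contain at least one atom")
        object.__setattr__(self, "_counts", dict(sorted(clean.items())))
        object.__setattr__(self, "_hash", hash(tuple(self._counts.items())))

    def __setattr__(self, name, value):  # pragma: no cover - immutability guard
        raise AttributeError("ElementalComposition is immutable")

    def __getitem__(self, key: str) -> int:
        return self._counts.get(key, 0)

    def __iter__(self):
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __hash__(self) -> int:
        return self._hash

    def __eq__(self, other) -> bool:
        if isinstance(other, ElementalComposition):
            return self._counts == other._counts
        return NotImplemented

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self._counts)
        for sym, n in other.items():
            merged[sym] = merged.get(sym, 0) + n
        return ElementalComposition(merged)

    def hill_formula(self) -> str:
        parts: list[str] = []
        order = [s for s in ("C", "H") if s in self._counts]
        order += sorted(s for s in self._counts if s not in ("C", "H"))
        for sym in order:
            n = self._counts[sym]
            parts.append(sym if n == 1 else f"{sym}{n}")
        return "".join(parts)

    def heteroatoms(self) -> int:
        """Number of atoms other than carbon and hydrogen."""
        return sum(n for s, n in self._counts.items() if s not in ("C", "H"))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ElementalComposition({self.hill_formula()!r})"


@dataclass(frozen=True)
class MassPeak:
    """An observed quasi-molecular ion from the peak table."""

    peak_id: str
    rt_min: float
    observed_mz: float
    polarity: str

    def __post_init__(self):
        if self.observed_mz <= 0:
            raise ValueError(f"{self.peak_id}: observed_mz must be positive")
        if self.rt_min < 0:
            raise ValueError(f"{self.peak_id}: rt_min must be non-negative")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"{self.peak_id}: polarity must be positive|negative")


@dataclass(frozen=True)
class FormulaCandidate:
    """A scored formula hypothesis for a peak."""

    composition: ElementalComposition
    adduct: AdductSpec
    theoretical_mz: float
    ppm_error: float
    rdbe: float


def parse_formula(text: str) -> ElementalComposition:
    """Parse a Hill-notation molecular formula such as ``C9H16O4``.

    An omitted count means one atom.  Unknown element symbols and empty
    strings are rejected.
    """
    if not text:
        raise ValueError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise ValueError(f"unparseable formula {text!r} at position {pos}")
        sym, digits = match.groups()
        if sym not in ISOTOPE_MASS:
            raise ValueError(f"unknown element symbol {sym!r} in {text!r}")
        counts[sym] = counts.get(sym, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(text):
        raise ValueError(f"unparseable formula {text!r} at position {pos}")
    return ElementalComposition(counts)


def monoisotopic_mass(composition: ElementalComposition) -> float:
    """Sum of most-abundant-isotope masses, in Da."""
    return sum(ISOTOPE_MASS[sym] * n for sym, n in composition.items())


def adduct_mz(neutral_mass: float, adduct: AdductSpec | str) -> float:
    """m/z of the singly charged quasi-molecular ion for a neutral mass."""
    if isinstance(adduct, str):
        try:
            adduct = ADDUCTS[adduct]
        except KeyError:
            raise ValueError(f"unsupported adduct: {adduct!r}") from None
    if neutral_mass < 0:
        raise ValueError("neutral mass must be non-negative")
    return neutral_mass + adduct.mass_delta


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """Signed relative deviation, (observed - theoretical)/theoretical * 1e6."""
    if theoretical_mz <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed_mz - theoretical_mz) / theoretical_mz * 1e6


def rdbe(composition: ElementalComposition) -> float:
    """Ring-and-double-bond equivalents, 1 + sum of (valence-2)/2 per atom."""
    return 1.0 + sum(_RDBE_CONTRIB[sym] * n for sym, n in composition.items())


# Per-element (min, max) count bounds for enumeration; covers common
# phytochemistry (phenylpropanoids, flavonoids, alkaloids, organic acids).
DEFAULT_BOUNDS: dict[str, tuple[int, int]] = {
    "C": (0, 50),
    "H": (0, 100),
    "N": (0, 10),
    "O": (0, 20),
    "S": (0, 3),
    "P": (0, 3),
    "Na": (0, 1),
    "Cl": (0, 1),
}


def _enumerate_compositions(
    lo: float, hi: float, bounds: Mapping[str, tuple[int, int]]
) -> list[dict[str, int]]:
    """All compositions with monoisotopic mass inside [lo, hi].

    Depth-first over elements sorted by mass descending, with branch-and-bound
    on the remaining achievable mass.  Exact: no heuristics.
    """
    elements = sorted(
        (s for s in bounds if bounds[s][1] > 0),
        key=lambda s: ISOTOPE_MASS[s],
        reverse=True,
    )
    masses = [ISOTOPE_MASS[s] for s in elements]
    # max mass attainable from elements i..end
    max_rest = [0.0] * (len(elements) + 1)
    for i in range(len(elements) - 1, -1, -1):
        max_rest[i] = max_rest[i + 1] + masses[i] * bounds[elements[i]][1]

    out: list[dict[str, int]] = []
    current: dict[str, int] = {}

    def recurse(i: int, lo_rem: float, hi_rem: float) -> None:
        if i == len(elements):
            if lo_rem <= 0.0 <= hi_rem:
                out.append(dict(current))
            return
        sym, m = elements[i], masses[i]
        cmin, cmax = bounds[sym]
        # c*m must leave a gap fillable by the remaining elements:
        # need lo_rem - max_rest[i+1] <= c*m <= hi_rem
        c_lo = max(cmin, int(-((max_rest[i + 1] - lo_rem) // m)) if m else cmin)
        while c_lo * m < lo_rem - max_rest[i + 1] - 1e-12:
            c_lo += 1
        c_hi = min(cmax, int(hi_rem // m + 1e-12))
        for c in range(c_lo, c_hi + 1):
            if c:
                current[sym] = c
            recurse(i + 1, lo_rem - c * m, hi_rem - c * m)
            current.pop(sym, None)

    recurse(0, lo, hi)
    return out


def fit_formulas(
    peak: MassPeak,
    adducts: Sequence[AdductSpec | str] | None = None,
    bounds: Mapping[str, tuple[int, int]] | None = None,
    tolerance_ppm: float = 5.0,
) -> list[FormulaCandidate]:
    """Exhaustively enumerate formula candidates for an observed peak.

    Every composition within ``bounds`` whose adduct m/z deviates from the
    observed m/z by at most ``tolerance_ppm`` and has RDBE >= 0 is returned,
    sorted by absolute ppm error (ties: fewer heteroatoms, then Hill formula).
    An empty list is a valid result.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be positive")
    if adducts is None:
        specs = [a for a in ADDUCTS.values() if a.polarity == peak.polarity]
    else:
        specs = []
        for a in adducts:
            spec = ADDUCTS[a] if isinstance(a, str) else a
            if spec.name not in ADDUCTS:
                raise ValueError(f"unsupported adduct: {spec.name!r}")
            if spec.polarity != peak.polarity:
                raise ValueError(
                    f"adduct {spec.name} does not match peak polarity {peak.polarity}"
                )
            specs.append(spec)
    bounds = dict(DEFAULT_BOUNDS if bounds is None else bounds)
    for sym in bounds:
        if sym not in ISOTOPE_MASS:
            raise ValueError(f"unknown element in bounds: {sym!r}")

    tol = tolerance_ppm * 1e-6
    candidates: list[FormulaCandidate] = []
    seen: set[tuple[str, str]] = set()
    for spec in specs:
        # |obs - theo| / theo <= tol  <=>  theo in [obs/(1+tol), obs/(1-tol)]
        theo_lo = peak.observed_mz / (1.0 + tol)
        theo_hi = peak.observed_mz / (1.0 - tol)
        for counts in _enumerate_compositions(
            theo_lo - spec.mass_delta, theo_hi - spec.mass_delta, bounds
        ):
            comp = ElementalComposition(counts)
            r = rdbe(comp)
            if r < 0:
                continue
            key = (comp.hill_formula(), spec.name)
            if key in seen:
                continue
            seen.add(key)
            theo = adduct_mz(monoisotopic_mass(comp), spec)
            candidates.append(
                FormulaCandidate(comp, spec, theo, ppm_error(peak.observed_mz, theo), r)
            )
    candidates.sort(
        key=lambda c: (
            abs(c.ppm_error),
            c.composition.heteroatoms(),
            c.composition.hill_formula(),
        )
    )
    return candidates


def assign_best_adduct(
    observed_mz: float,
    composition: ElementalComposition,
    polarity: str | None = None,
) -> tuple[AdductSpec, float]:
    """Pick the supported adduct that best explains an observed m/z.

    Returns the adduct minimizing the absolute ppm error against the
    composition's theoretical quasi-molecular m/z, optionally restricted to
    one polarity.  Used when a peak table does not state the charge carrier.
    """
    neutral = monoisotopic_mass(composition)
    best: tuple[AdductSpec, float] | None = None
    for spec in ADDUCTS.values():
        if polarity is not None and spec.polarity != polarity:
            continue
        err = ppm_error(observed_mz, adduct_mz(neutral, spec))
        if best is None or abs(err) < abs(best[1]):
            best = (spec, err)
    if best is None:
        raise ValueError(f"no supported adduct with polarity {polarity!r}")
    return best


# ---------------------------------------------------------------------------
# Tabular I/O


def read_peak_table(path) -> pd.DataFrame:
    """Read a peak table (CSV/TSV: peak_id, rt_min, observed_mz, polarity,
    optional known_formula)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"peak_id", "rt_min", "observed_mz", "polarity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    return df


def candidates_to_frame(
    peak_id: str, candidates: Iterable[FormulaCandidate]
) -> pd.DataFrame:
    rows = [
        {
            "peak_id": peak_id,
            "rank": i + 1,
            "formula": c.composition.hill_formula(),
            "adduct": c.adduct.name,
            "theoretical_mz": c.theoretical_mz,
            "ppm_error": c.ppm_error,
            "rdbe": c.rdbe,
        }
        for i, c in enumerate(candidates)
    ]
    cols = ["peak_id", "rank", "formula", "adduct", "theoretical_mz", "ppm_error", "rdbe"]
    return pd.DataFrame(rows, columns=cols)


def load_reference_peaks() -> pd.DataFrame:
    """Bundled HPLC-Q-TOF peak table for the Sparganii rhizoma aqueous extract
    (41 identified compounds; printed m/z at 4 d.p. and reported ppm errors).

    ``consistent`` flags rows whose reported 1-d.p. ppm error is reproduced
    exactly from the printed m/z; the remainder were evidently computed from
    unrounded instrument values and are kept for context only.
    """
    with resources.files("phytonet").joinpath("data/sparganii_peaks.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
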