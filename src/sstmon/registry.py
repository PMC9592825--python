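"""Expected-peak registry for the QC mix.

The QC mixture contains nine chemically diverse analytes spanning the m/z
100-800 range in negative ionization mode. Each analyte contributes its
deprotonated monoisotopic ion plus M+1 and M+2 isotopologues; one analyte
forms a chloride adduct and each undergoes some in-source fragmentation,
giving 9 + 18 + 1 + 9 = 37 tracked QC peaks. Two continuously infused
reference compounds (homotaurine "HOT" and the hexakis-fluoropropoxy
phosphazine "HEX") serve as lock masses for intra-scan mass calibration.

The default compound list (apart from fluconazole, whose [M-H]- at
305.0968 Th anchors the in-source fragmentation indicator) and the
lock-mass species monitored are provisional choices of this package:
chemically plausible negative-mode ions with realistic isotopologue,
fragment and adduct abundances.
"""

from __future__ import annotations

from dataclasses import dataclass

MONOISOTOPIC = "monoisotopic"
ISOTOPOLOGUE = "isotopologue"
FRAGMENT = "fragment"
ADDUCT = "adduct"
LOCK_MASS = "lock_mass"

KINDS = (MONOISOTOPIC, ISOTOPOLOGUE, FRAGMENT, ADDUCT, LOCK_MASS)

_M1 = 1.0033548  # 13C - 12C mass difference, Th
_M2 = 2.0067096


@dataclass(frozen=True)
class ExpectedPeak:
    """One registry entry: a spectral peak the platform expects to see.

    ``theoretical_relative_abundance`` is the expected height as a fraction
    of the parent's monoisotopic peak (1.0 for monoisotopic ions and lock
    masses, which are their own parents).
    """

    peak_id: str
    theoretical_mz: float
    kind: str
    parent_id: str | None = None
    theoretical_relative_abundance: float = 1.0

    def __post_init__(self) -> None:
        if self.theoretical_mz <= 0:
            raise ValueError("theoretical_mz must be positive")
        if self.kind not in KINDS:
            raise ValueError(f"unknown peak kind {self.kind!r}")
        a = self.theoretical_relative_abundance
        if not 0 < a <= 1:
            raise ValueError("theoretical_relative_abundance must be in (0, 1]")
        if self.kind in (MONOISOTOPIC, LOCK_MASS):
            if self.parent_id not in (None, self.peak_id):
                raise ValueError(f"{self.kind} peak cannot reference a parent")
        elif self.parent_id is None:
            raise ValueError(f"{self.kind} peak must reference a parent")


# (compound, [M-H]- m/z, M+1 frac, M+2 frac, fragment m/z, fragment frac)
_COMPOUNDS = [
    ("taurine",       124.0074, 0.027, 0.046, 105.9968, 0.08),
    ("hippurate",     178.0510, 0.098, 0.006, 134.0612, 0.12),
    ("citrate",       191.0197, 0.065, 0.008, 173.0091, 0.15),
    ("estradiol",     271.1704, 0.197, 0.019, 245.1547, 0.05),
    ("fluconazole",   305.0968, 0.143, 0.010, 236.0641, 0.10),
    ("raffinose",     503.1618, 0.196, 0.028, 341.1089, 0.20),
    ("atp",           505.9885, 0.110, 0.014, 426.0222, 0.18),
    ("maltotetraose", 665.2145, 0.263, 0.044, 647.2039, 0.10),
    ("digoxin",       779.4217, 0.448, 0.105, 649.3587, 0.07),
]

LOCK_MASSES = [
    # homotaurine [M-H]-; HEX reported as its formate adduct (provisional)
    ExpectedPeak("HOT", 138.0230, LOCK_MASS),
    ExpectedPeak("HEX", 966.0007, LOCK_MASS),
]


def default_registry(include_lock_masses: bool = True) -> list[ExpectedPeak]:
    """The default 37-peak QC registry (+ 2 lock masses).

    Nine monoisotopic ions, eighteen isotopologues (M+1 and M+2 for each
    analyte), one chloride adduct (raffinose) and nine in-source fragments.
    """
    peaks: list[ExpectedPeak] = []
    for name, mz, a1, a2, frag_mz, frag_a in _COMPOUNDS:
        parent = f"{name}_M"
        peaks.append(ExpectedPeak(parent, mz, MONOISOTOPIC))
        peaks.append(ExpectedPeak(f"{name}_M1", mz + _M1, ISOTOPOLOGUE, parent, a1))
        peaks.append(ExpectedPeak(f"{name}_M2", mz + _M2, ISOTOPOLOGUE, parent, a2))
        peaks.append(ExpectedPeak(f"{name}_frag", frag_mz, FRAGMENT, parent, frag_a))
    peaks.append(ExpectedPeak("raffinose_Cl", 539.1379, ADDUCT, "raffinose_M", 0.05))
    peaks.sort(key=lambda p: p.theoretical_mz)
    if include_lock_masses:
        peaks = sorted(peaks + LOCK_MASSES, key=lambda p: p.theoretical_mz)
    return peaks


def qc_peaks(registry: list[ExpectedPeak]) -> list[ExpectedPeak]:
    """The QC-mix subset of a registry (everything except lock masses)."""
    return [p for p in registry if p.kind != LOCK_MASS]


def lock_mass_peaks(registry: list[ExpectedPeak]) -> list[ExpectedPeak]:
    return [p for p in registry if p.kind == LOCK_MASS]


def compounds(registry: list[ExpectedPeak]) -> list[str]:
    """Parent (monoisotopic) peak ids, ordered by m/z."""
    monos = [p for p in registry if p.kind == MONOISOTOPIC]
    return [p.peak_id for p in sorted(monos, key=lambda p: p.theoretical_mz)]


def by_id(registry: list[ExpectedPeak]) -> dict[str, ExpectedPeak]:
    index = {p.peak_id: p for p in registry}
    if len(index) != len(registry):
        raise ValueError("duplicate peak_id in registry")
    for p in registry:
        if p.parent_id is not None and p.parent_id not in index:
            raise ValueError(f"{p.peak_id} references unknown parent {p.parent_id}")
    return index
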