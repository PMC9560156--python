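"""Isotopologue assignment and internal-standard quantification.

Works on centroided peak tables (m/z, intensity): each expected
isotopologue of a target gets a ppm window around its theoretical m/z,
the most intense peak in the window is assigned, and the resulting
intensity vector yields the observed MID, the labeled fraction, and —
relative to a co-measured heavy internal standard spiked at known
amount — absolute picomoles per million cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .isotopes import AdductSpec, MIDistribution, POSITIVE, isotopologue_mz
from .masses import C13_SHIFT, N15_SHIFT, MolecularFormula, VALINE

__all__ = [
    "PeakTable",
    "IsotopologueAssignment",
    "InternalStandardSpec",
    "QuantResult",
    "assign_isotopologues",
    "assign_internal_standard",
    "fraction_labeled",
    "observed_mid",
    "quantify",
]


class PeakTable:
    """Centroided peaks: rows of (m/z, intensity[, retention time]).

    Rows are sorted by m/z on ingestion; intensities must be
    nonnegative and m/z positive.
    """

    def __init__(self, df: pd.DataFrame) -> None:
        if not {"mz", "intensity"} <= set(df.columns):
            raise ValueError("peak table needs columns 'mz' and 'intensity'")
        df = df.copy()
        if (df["mz"] <= 0).any():
            raise ValueError("m/z values must be positive")
        if (df["intensity"] < 0).any():
            raise ValueError("intensities must be nonnegative")
        self.df = df.sort_values("mz", kind="mergesort").reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "PeakTable":
        return cls(pd.read_csv(path))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def mz(self) -> np.ndarray:
        return self.df["mz"].to_numpy()

    @property
    def intensity(self) -> np.ndarray:
        return self.df["intensity"].to_numpy()


@dataclass(frozen=True)
class InternalStandardSpec:
    """A uniformly heavy standard spiked at a known amount per sample.

    The packaged use is 13C5/15N-valine: all five carbons and the single
    nitrogen heavy, so its m/z sits well clear of every analyte
    isotopologue.  ``spiked_pmol`` is the amount per sample, typically
    the spike concentration times the extraction volume.
    """

    formula: MolecularFormula = VALINE
    n_c13: int = 5
    n_n15: int = 1
    spiked_pmol: float = 500.0

    def __post_init__(self) -> None:
        if self.spiked_pmol <= 0:
            raise ValueError("spiked_pmol must be positive")
        if self.n_c13 > self.formula.n_carbon:
            raise ValueError("more 13C labels than carbons")
        if self.n_n15 > self.formula.counts.get("N", 0):
            raise ValueError("more 15N labels than nitrogens")

    def mz(self, adduct: AdductSpec = POSITIVE) -> float:
        base = isotopologue_mz(self.formula, self.n_c13, adduct)
        return base + self.n_n15 * N15_SHIFT / adduct.charge


@dataclass
class IsotopologueAssignment:
    """Matched intensities per label count for one target in one sample."""

    target: str
    theoretical_mz: dict[int, float]
    intensities: dict[int, float] = field(default_factory=dict)
    ppm_errors: dict[int, float] = field(default_factory=dict)

    def total_intensity(self) -> float:
        return float(sum(self.intensities.values()))

    def labeled_intensity(self) -> float:
        return float(sum(v for k, v in self.intensities.items() if k >= 1))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "n_labels": n,
                "theoretical_mz": self.theoretical_mz[n],
                "intensity": self.intensities.get(n, 0.0),
                "ppm_error": self.ppm_errors.get(n, np.nan),
            }
            for n in sorted(self.theoretical_mz)
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class QuantResult:
    """Absolute valine content of a sample, per million cells."""

    total_pmol_per_1e6_cells: float
    labeled_pmol_per_1e6_cells: float

    def __post_init__(self) -> None:
        if self.labeled_pmol_per_1e6_cells > self.total_pmol_per_1e6_cells + 1e-9:
            raise ValueError("labeled amount cannot exceed total")

    @property
    def labeled_fraction(self) -> float:
        if self.total_pmol_per_1e6_cells == 0:
            return 0.0
        return self.labeled_pmol_per_1e6_cells / self.total_pmol_per_1e6_cells


def assign_isotopologues(
    peaks: PeakTable,
    formula: MolecularFormula,
    adduct: AdductSpec = POSITIVE,
    max_labels: int | None = None,
    ppm_tolerance: float = 5.0,
    support: tuple[int, ...] | None = None,
) -> IsotopologueAssignment:
    """Match observed peaks to theoretical isotopologue m/z windows.

    For each label count the single most intense not-yet-used peak
    within ``ppm_tolerance`` is taken; counts with no peak in window get
    intensity 0.  ``support`` restricts the label counts considered
    (e.g. ``(0, 2, 3, 5)`` for the two-unit valine scheme).  Windows
    that would overlap — tolerance wider than half the isotopologue
    spacing — raise a configuration error rather than mis-assign.
    """
    if ppm_tolerance <= 0:
        raise ValueError("ppm_tolerance must be positive")
    if max_labels is None:
        max_labels = formula.n_carbon
    counts = tuple(support) if support is not None else tuple(range(max_labels + 1))
    theo = {n: isotopologue_mz(formula, n, adduct) for n in counts}
    ordered = sorted(theo.items(), key=lambda kv: kv[1])
    for (_, mz_a), (_, mz_b) in zip(ordered, ordered[1:]):
        if mz_a * ppm_tolerance * 1e-6 + mz_b * ppm_tolerance * 1e-6 >= mz_b - mz_a:
            raise ValueError(
                f"ppm_tolerance={ppm_tolerance} makes windows at {mz_a:.4f} and "
                f"{mz_b:.4f} overlap; narrow the tolerance"
            )
    assignment = IsotopologueAssignment(target=str(formula), theoretical_mz=theo)
    used: set[int] = set()
    mz = peaks.mz
    intensity = peaks.intensity
    for n, target_mz in ordered:
        half = target_mz * ppm_tolerance * 1e-6
        lo = np.searchsorted(mz, target_mz - half, side="left")
        hi = np.searchsorted(mz, target_mz + half, side="right")
        candidates = [i for i in range(lo, hi) if i not in used]
        if not candidates:
            assignment.intensities[n] = 0.0
            continue
        best = max(candidates, key=lambda i: intensity[i])
        used.add(best)
        assignment.intensities[n] = float(intensity[best])
        assignment.ppm_errors[n] = float((mz[best] - target_mz) / target_mz * 1e6)
    return assignment


def assign_internal_standard(
    peaks: PeakTable,
    is_spec: InternalStandardSpec,
    adduct: AdductSpec = POSITIVE,
    ppm_tolerance: float = 5.0,
) -> IsotopologueAssignment:
    """Match the single internal-standard peak (its label composition is
    fixed, so there is one window)."""
    target_mz = is_spec.mz(adduct)
    half = target_mz * ppm_tolerance * 1e-6
    mz = peaks.mz
    lo = np.searchsorted(mz, target_mz - half, side="left")
    hi = np.searchsorted(mz, target_mz + half, side="right")
    assignment = IsotopologueAssignment(
        target="internal_standard", theoretical_mz={0: target_mz}
    )
    if hi > lo:
        best = lo + int(np.argmax(peaks.intensity[lo:hi]))
        assignment.intensities[0] = float(peaks.intensity[best])
        assignment.ppm_errors[0] = float(
            (mz[best] - target_mz) / target_mz * 1e6
        )
    else:
        assignment.intensities[0] = 0.0
    return assignment


def fraction_labeled(assignment: IsotopologueAssignment) -> float:
    """Intensity share of isotopologues carrying at least one heavy label."""
    total = assignment.total_intensity()
    if total <= 0:
        raise ValueError("no matched intensity; labeled fraction undefined")
    return assignment.labeled_intensity() / total


def observed_mid(assignment: IsotopologueAssignment) -> MIDistribution:
    """Intensity-normalized MID over label counts 0..max."""
    total = assignment.total_intensity()
    if total <= 0:
        raise ValueError("no matched intensity; MID undefined")
    n_max = max(assignment.theoretical_mz)
    vec = np.zeros(n_max + 1)
    for n, v in assignment.intensities.items():
        vec[n] = v
    return MIDistribution(vec / total)


def quantify(
    assignment: IsotopologueAssignment,
    is_assignment: IsotopologueAssignment,
    is_spec: InternalStandardSpec,
    cell_count: float,
) -> QuantResult:
    """Absolute quantification against the internal standard.

    total pmol = (target intensity / standard intensity) x spiked pmol,
    normalized to one million cells; the labeled amount uses only
    intensities at one or more labels.  A missing standard peak is an
    error — there is no fallback that preserves the absolute scale.
    """
    if cell_count <= 0:
        raise ValueError("cell_count must be positive")
    is_intensity = is_assignment.total_intensity()
    if is_intensity <= 0:
        raise ValueError("internal-standard peak absent; cannot quantify")
    scale = is_spec.spiked_pmol / is_intensity * (1e6 / cell_count)
    return QuantResult(
        total_pmol_per_1e6_cells=assignment.total_intensity() * scale,
        labeled_pmol_per_1e6_cells=assignment.labeled_intensity() * scale,
    )
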