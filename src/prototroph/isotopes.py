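"""Mass-isotopomer distribution (MID) prediction for U-13C tracing.

The labeling design modeled here feeds cells uniformly labeled precursors
(e.g. 13C6-glucose yielding 13C3-pyruvate) so that each precursor unit
incorporated into a product carries either all of its carbons heavy or
none of them.  A product assembled from independent precursor units then
shows a characteristic sparse MID: valine, condensed from two pyruvate
units contributing 3 and 2 carbons, can only carry 0, 2, 3 or 5 heavy
carbons.  The MID is the convolution of the per-unit two-point
distributions, parameterized by each pool's labeled fraction ``p``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .masses import (
    C13_NATURAL_ABUNDANCE,
    C13_SHIFT,
    ELECTRON_MASS,
    PROTON_MASS,
    MolecularFormula,
)

__all__ = [
    "LabelingPool",
    "PrecursorScheme",
    "MIDistribution",
    "AdductSpec",
    "predict_mid",
    "isotopologue_mz",
    "predict_fragment_mz",
    "estimate_pool_fraction",
    "expected_labeled_fraction",
]


@dataclass(frozen=True)
class LabelingPool:
    """A well-mixed precursor pool that is all-or-none heavy labeled.

    Parameters
    ----------
    pool_id
        Name used by schemes to reference this pool.
    labeled_fraction
        Fraction ``p`` of pool molecules that are uniformly heavy.
    label_kind
        Heavy isotope identity; only ``"13C"`` is packaged.
    unit_carbon_count
        Carbons per pool molecule (3 for pyruvate).
    """

    pool_id: str
    labeled_fraction: float
    label_kind: str = "13C"
    unit_carbon_count: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.labeled_fraction <= 1.0:
            raise ValueError("labeled_fraction must lie in [0, 1]")
        if self.unit_carbon_count < 1:
            raise ValueError("unit_carbon_count must be >= 1")


@dataclass(frozen=True)
class PrecursorScheme:
    """How a product molecule is assembled from labeled precursor units.

    ``units`` lists ``(pool_id, carbons_contributed)`` pairs; units are
    drawn independently from their pools.  The carbon contributions must
    account for every label-eligible carbon of ``product_formula``.
    """

    product: str
    units: tuple[tuple[str, int], ...]
    product_formula: MolecularFormula

    def __post_init__(self) -> None:
        if not self.units:
            raise ValueError("scheme needs at least one precursor unit")
        total = sum(c for _, c in self.units)
        if any(c < 1 for _, c in self.units):
            raise ValueError("each unit must contribute >= 1 carbon")
        if total > self.product_formula.n_carbon:
            raise ValueError(
                f"units contribute {total} carbons but {self.product} has "
                f"only {self.product_formula.n_carbon}"
            )

    @property
    def max_labels(self) -> int:
        return sum(c for _, c in self.units)


class MIDistribution:
    """Probability vector over the number of heavy labels carried.

    Index ``k`` holds the probability that a product molecule carries
    exactly ``k`` heavy atoms.  Entries are nonnegative and sum to one.
    """

    __slots__ = ("probabilities",)

    def __init__(self, probabilities) -> None:
        p = np.asarray(probabilities, dtype=float)
        if p.ndim != 1 or p.size == 0:
            raise ValueError("MID must be a non-empty 1-D vector")
        if (p < -1e-12).any():
            raise ValueError("MID entries must be nonnegative")
        total = float(p.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"MID must sum to 1, got {total!r}")
        self.probabilities = np.clip(p, 0.0, None)

    def __len__(self) -> int:
        return self.probabilities.size

    def __getitem__(self, k: int) -> float:
        return float(self.probabilities[k])

    @property
    def support(self) -> tuple[int, ...]:
        return tuple(int(k) for k in np.nonzero(self.probabilities > 1e-12)[0])

    def __repr__(self) -> str:  # pragma: no cover
        body = ", ".join(f"{k}: {self[k]:.4g}" for k in self.support)
        return f"MIDistribution({{{body}}})"


@dataclass(frozen=True)
class AdductSpec:
    """Ionization adduct: protonated positive ([M+H]+) or deprotonated
    negative ([M-H]-); all packaged uses are singly charged."""

    kind: str = "protonated-positive"
    charge: int = 1

    _KINDS = ("protonated-positive", "deprotonated-negative")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}")
        if self.charge < 1:
            raise ValueError("charge must be a positive integer")

    @property
    def sign(self) -> int:
        return 1 if self.kind == "protonated-positive" else -1


POSITIVE = AdductSpec("protonated-positive", 1)
NEGATIVE = AdductSpec("deprotonated-negative", 1)


def predict_mid(
    scheme: PrecursorScheme,
    pools: list[LabelingPool] | dict[str, LabelingPool],
    natural_abundance: bool = False,
) -> MIDistribution:
    """Predict the product MID under independent all-or-none unit labeling.

    Each unit contributes 0 labels with probability ``1 - p`` or all of
    its carbons with probability ``p``; the product distribution is the
    convolution over units.  With ``natural_abundance=True`` the
    remaining light carbons are additionally allowed to be heavy at the
    terrestrial 13C abundance (binomial convolution), which fills in the
    +1 satellites a real spectrum shows.
    """
    pool_map = (
        pools if isinstance(pools, dict) else {pl.pool_id: pl for pl in pools}
    )
    dist = np.array([1.0])
    for pool_id, carbons in scheme.units:
        try:
            pool = pool_map[pool_id]
        except KeyError:
            raise KeyError(
                f"scheme references unknown pool {pool_id!r}"
            ) from None
        unit = np.zeros(carbons + 1)
        unit[0] = 1.0 - pool.labeled_fraction
        unit[carbons] = pool.labeled_fraction
        dist = np.convolve(dist, unit)
    if natural_abundance:
        n_c = scheme.product_formula.n_carbon
        out = np.zeros(n_c + 1)
        for k, q in enumerate(dist):
            if q == 0.0:
                continue
            spare = n_c - k
            for j in range(spare + 1):
                out[k + j] += q * (
                    math.comb(spare, j)
                    * C13_NATURAL_ABUNDANCE**j
                    * (1.0 - C13_NATURAL_ABUNDANCE) ** (spare - j)
                )
        dist = out
    return MIDistribution(dist)


def isotopologue_mz(
    formula: MolecularFormula, n_labels: int, adduct: AdductSpec = POSITIVE
) -> float:
    """Theoretical m/z of the isotopologue carrying ``n_labels`` 13C atoms.

    Monoisotopic neutral mass, plus the 13C-12C shift per label, plus or
    minus one proton per charge depending on adduct polarity.
    """
    if not 0 <= n_labels <= formula.n_carbon:
        raise ValueError(
            f"n_labels={n_labels} outside [0, {formula.n_carbon}] for {formula}"
        )
    mass = formula.monoisotopic_mass() + n_labels * C13_SHIFT
    mass += adduct.sign * adduct.charge * PROTON_MASS
    return mass / adduct.charge


def predict_fragment_mz(
    parent_formula: MolecularFormula,
    fragment_formula: MolecularFormula,
    labels_retained: int,
    adduct: AdductSpec = POSITIVE,
    ionization: str = "adduct",
) -> float:
    """Theoretical m/z of a product-ion fragment retaining some labels.

    ``ionization="adduct"`` applies the same protonation arithmetic as
    :func:`isotopologue_mz` (the fragment formula is a neutral).  With
    ``ionization="intrinsic"`` the written formula already includes the
    charge-carrying proton — the convention for immonium and acylium
    ions — so only the electron mass is adjusted.
    """
    if not parent_formula.contains(fragment_formula):
        raise ValueError(
            f"fragment {fragment_formula} is not a sub-formula of {parent_formula}"
        )
    if not 0 <= labels_retained <= fragment_formula.n_carbon:
        raise ValueError("labels_retained outside fragment carbon range")
    if ionization == "adduct":
        return isotopologue_mz(fragment_formula, labels_retained, adduct)
    if ionization == "intrinsic":
        mass = fragment_formula.monoisotopic_mass() + labels_retained * C13_SHIFT
        mass -= adduct.sign * adduct.charge * ELECTRON_MASS
        return mass / adduct.charge
    raise ValueError("ionization must be 'adduct' or 'intrinsic'")


def estimate_pool_fraction(
    observed: MIDistribution, scheme: PrecursorScheme
) -> float:
    """Invert a one-unit scheme: the pool's labeled fraction is one minus
    the unlabeled probability.  Multi-unit schemes are rejected because
    several ``p`` values can share an unlabeled fraction only through the
    full MID shape, making the single-number inversion ambiguous."""
    if len(scheme.units) != 1:
        raise ValueError(
            "pool-fraction estimation is defined only for one-unit schemes"
        )
    return 1.0 - observed[0]


def expected_labeled_fraction(mid: MIDistribution) -> float:
    """Fraction of molecules carrying at least one heavy label."""
    return 1.0 - mid[0]
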