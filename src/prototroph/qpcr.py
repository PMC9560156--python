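"""Efficiency-corrected ΔΔCq relative quantification.

Quantification cycles (Cq) are compared between a target and a
reference gene, and between a sample and a calibrator sample:

    ΔCq  = mean Cq(target) - mean Cq(reference)
    ΔΔCq = ΔCq(sample) - ΔCq(calibrator)
    RQ   = E ** (-ΔΔCq)

with amplification efficiency E (2.0 = perfect doubling per cycle).
On genomic DNA, RQ times the calibrator's known copy number gives the
sample's integrated copies per genome; on cDNA, RQ is the expression
level relative to the calibrator.  Technical-replicate scatter is
propagated in quadrature on the Cq scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CqTable",
    "CalibratorSpec",
    "RelativeQuantity",
    "delta_delta_cq",
    "copy_number",
    "expression_fold_change",
]

CQ_COLUMNS = ("sample_id", "gene", "template", "replicate", "cq")
TEMPLATES = ("gDNA", "cDNA")


class CqTable:
    """Long-format qPCR results: one row per technical replicate."""

    def __init__(self, df: pd.DataFrame) -> None:
        missing = set(CQ_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"Cq table missing columns {sorted(missing)}")
        bad = set(df["template"].unique()) - set(TEMPLATES)
        if bad:
            raise ValueError(f"unknown template values {sorted(bad)}")
        if not np.isfinite(df["cq"]).all() or (df["cq"] <= 0).any():
            raise ValueError("Cq values must be finite and positive")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "CqTable":
        return cls(pd.read_csv(path))

    def cq_stats(
        self, sample_id: str, gene: str, template: str
    ) -> tuple[float, float, int]:
        """Mean Cq, SD and replicate count for one well group."""
        sub = self.df[
            (self.df["sample_id"] == sample_id)
            & (self.df["gene"] == gene)
            & (self.df["template"] == template)
        ]
        if len(sub) == 0:
            raise ValueError(
                f"no Cq rows for sample {sample_id!r}, gene {gene!r}, "
                f"template {template!r}"
            )
        cq = sub["cq"].to_numpy()
        sd = float(cq.std(ddof=1)) if len(cq) > 1 else 0.0
        return float(cq.mean()), sd, len(cq)


@dataclass(frozen=True)
class CalibratorSpec:
    """The sample everything is relativized to.

    For gDNA the calibrator's copy number must be known; a single-copy
    landing-pad integration justifies ``known_copies=1``.  Efficiency E
    is the per-cycle amplification factor, in (1, 2].
    """

    sample_id: str
    known_copies: float = 1.0
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        if not 1.0 < self.efficiency <= 2.0:
            raise ValueError("efficiency must lie in (1, 2]")
        if self.known_copies <= 0:
            raise ValueError("known_copies must be positive")


@dataclass(frozen=True)
class RelativeQuantity:
    """RQ = E^-ΔΔCq with its Cq-scale standard deviation.

    ``sd_log`` is the SD of ΔΔCq; multiplicative error bounds are
    ``rq * efficiency ** (+-sd_log)``.
    """

    rq: float
    delta_delta_cq: float
    sd_log: float
    efficiency: float
    template: str

    @property
    def rq_low(self) -> float:
        return self.rq * self.efficiency ** (-self.sd_log)

    @property
    def rq_high(self) -> float:
        return self.rq * self.efficiency ** (self.sd_log)


def delta_delta_cq(
    table: CqTable,
    target_gene: str,
    reference_gene: str,
    calibrator: CalibratorSpec,
    sample_id: str,
    template: str = "gDNA",
) -> RelativeQuantity:
    """Relative quantity of the target gene in a sample vs the calibrator.

    Technical replicates are averaged per well group; their SDs combine
    in quadrature across the four groups entering ΔΔCq.
    """
    if template not in TEMPLATES:
        raise ValueError(f"template must be one of {TEMPLATES}")
    try:
        ref_s = table.cq_stats(sample_id, reference_gene, template)
        ref_c = table.cq_stats(calibrator.sample_id, reference_gene, template)
    except ValueError as exc:
        raise ValueError(f"reference gene unusable: {exc}") from None
    tgt_s = table.cq_stats(sample_id, target_gene, template)
    tgt_c = table.cq_stats(calibrator.sample_id, target_gene, template)
    dcq_sample = tgt_s[0] - ref_s[0]
    dcq_cal = tgt_c[0] - ref_c[0]
    ddcq = dcq_sample - dcq_cal
    sd_log = math.sqrt(sum(s[1] ** 2 for s in (tgt_s, ref_s, tgt_c, ref_c)))
    return RelativeQuantity(
        rq=calibrator.efficiency ** (-ddcq),
        delta_delta_cq=ddcq,
        sd_log=sd_log,
        efficiency=calibrator.efficiency,
        template=template,
    )


def copy_number(rq: RelativeQuantity, calibrator: CalibratorSpec) -> float:
    """Integrated copies per genome from a gDNA relative quantity."""
    if rq.template != "gDNA":
        raise ValueError("copy number requires a gDNA-basis relative quantity")
    return rq.rq * calibrator.known_copies


def expression_fold_change(
    rq: RelativeQuantity, convention: str = "increase"
) -> float:
    """Expression change of a cDNA relative quantity vs the calibrator.

    ``convention="increase"`` (default) reports RQ - 1, so "0.54-fold
    increase" means 1.54x the calibrator's expression; ``"ratio"``
    returns RQ itself for the alternative reading.
    """
    if rq.template != "cDNA":
        raise ValueError("fold change requires a cDNA-basis relative quantity")
    if convention == "increase":
        return rq.rq - 1.0
    if convention == "ratio":
        return rq.rq
    raise ValueError("convention must be 'increase' or 'ratio'")
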