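"""Synthetic fixtures with the statistical structure the analyses assume.

Every generator is deterministic under a fixed seed and emits its ground
truth alongside the data, so each downstream module can be tested by
round-trip recovery without any external download: EC annotation
profiles of complete / metazoan-like / CHO-like organisms, exponential
growth or decline passage series with multiplicative count noise,
isotopologue peak tables from the two-pyruvate labeling model with a
spiked internal standard, and Cq tables consistent with the ΔΔCq model.
"""

from __future__ import annotations

import math
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .isotopes import LabelingPool, PrecursorScheme, predict_mid, isotopologue_mz
from .masses import MolecularFormula
from .msquant import InternalStandardSpec, PeakTable
from .pathway import (
    ECNumber,
    ESSENTIAL_AMINO_ACIDS,
    OrganismAnnotation,
    PathwayCatalog,
)
from .qpcr import CqTable

__all__ = [
    "load_schemes",
    "make_scheme",
    "load_growth_scenarios",
    "gen_annotations",
    "gen_growth",
    "gen_growth_scenario",
    "gen_peaks",
    "gen_cq",
]

PROFILES = ("complete", "metazoan_like", "cho_like")

#: ECs of the branched-chain aminotransferase retained by metazoan hosts
#: (Bcat1/Bcat2) although it only occurs inside EAA pathway variants.
_BCAT_EC = ECNumber("2.6.1.42")
#: The two activities of the bifunctional metazoan P5CS enzyme; silenced
#: in the CHO-like profile, making it a proline auxotroph.
_P5CS_ECS = frozenset({ECNumber("2.7.2.11"), ECNumber("1.2.1.41")})


def _load_yaml(name: str) -> dict:
    ref = resources.files("prototroph.data") / name
    return yaml.safe_load(ref.read_text())


def load_schemes() -> dict:
    """Raw packaged scheme/pool definitions."""
    return _load_yaml("labeling_schemes.yaml")


def make_scheme(
    name: str, labeled_fraction: float
) -> tuple[PrecursorScheme, dict[str, LabelingPool]]:
    """Instantiate a packaged scheme with one effective pool fraction."""
    cfg = load_schemes()
    try:
        entry = cfg["schemes"][name]
    except KeyError:
        raise KeyError(
            f"unknown scheme {name!r}; packaged: {sorted(cfg['schemes'])}"
        ) from None
    pools = {
        pid: LabelingPool(
            pool_id=pid,
            labeled_fraction=labeled_fraction,
            unit_carbon_count=int(p["unit_carbon_count"]),
        )
        for pid, p in cfg["pools"].items()
    }
    scheme = PrecursorScheme(
        product=name,
        units=tuple((pid, int(c)) for pid, c in entry["units"]),
        product_formula=MolecularFormula.from_string(entry["formula"]),
    )
    return scheme, pools


def load_growth_scenarios() -> dict:
    """Packaged growth scenario parameter sets."""
    return _load_yaml("growth_scenarios.yaml")


def gen_annotations(
    catalog: PathwayCatalog, profile: str, seed: int = 0
) -> OrganismAnnotation:
    """An organism annotation with a prescribed completeness profile.

    ``complete``: the union of every catalog EC.  ``metazoan_like``:
    complete minus all ECs occurring exclusively in essential-amino-acid
    pathway variants — the annotation of a lineage that lost exactly
    those nine pathways.  ``cho_like``: metazoan-like with the
    branched-chain aminotransferase restored (hosts keep Bcat1/2) and
    the two P5CS activities removed (CHO cells silenced P5CS and are
    proline auxotrophs).  All three are deterministic; ``seed`` is
    accepted for interface uniformity.
    """
    del seed
    if profile not in PROFILES:
        raise ValueError(f"profile must be one of {PROFILES}")
    all_ecs = catalog.all_ecs()
    if profile == "complete":
        return OrganismAnnotation("complete", frozenset(all_ecs))
    eaa_ecs: set[ECNumber] = set()
    other_ecs: set[ECNumber] = set()
    for variant in catalog.variants:
        bucket = (
            eaa_ecs if variant.amino_acid in ESSENTIAL_AMINO_ACIDS else other_ecs
        )
        for step in variant.steps:
            bucket.update(step.ec_options)
    exclusive = eaa_ecs - other_ecs
    metazoan = frozenset(all_ecs - exclusive)
    if profile == "metazoan_like":
        return OrganismAnnotation("metazoan_like", metazoan)
    cho = (set(metazoan) | {_BCAT_EC}) - _P5CS_ECS
    return OrganismAnnotation("cho_like", frozenset(cho))


def gen_growth(
    doubling_days: float | None = None,
    decline_halflife: float | None = None,
    n_passages: int = 10,
    passage_interval_days: float = 3.9,
    seed_count: float = 1e5,
    noise_cv: float = 0.10,
    seed: int = 42,
    n_replicates: int = 3,
    condition: str = "synthetic",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a passage series with multiplicative count noise.

    Exactly one of ``doubling_days`` (growth) or ``decline_halflife``
    (exponential loss) must be given.  Each passage re-seeds
    ``seed_count`` cells and harvests after ``passage_interval_days``;
    the harvest is the deterministic exponential times a lognormal
    factor with coefficient of variation ``noise_cv``.  Returns the
    passage table and the matching seeded/counted records (day-0 rows
    are the seeded cells).
    """
    if (doubling_days is None) == (decline_halflife is None):
        raise ValueError(
            "give exactly one of doubling_days or decline_halflife"
        )
    if doubling_days is not None and doubling_days <= 0:
        raise ValueError("doubling_days must be positive")
    if decline_halflife is not None and decline_halflife <= 0:
        raise ValueError("decline_halflife must be positive")
    if n_passages < 1 or passage_interval_days <= 0 or seed_count <= 0:
        raise ValueError("n_passages, interval and seed_count must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    rate = (
        passage_interval_days / doubling_days
        if doubling_days is not None
        else -passage_interval_days / decline_halflife
    )
    growth_factor = 2.0**rate
    sigma = math.sqrt(math.log1p(noise_cv**2))
    rng = np.random.default_rng(seed)
    passages = []
    counts = []
    for rep in range(1, n_replicates + 1):
        counts.append(
            {
                "condition": condition,
                "replicate": rep,
                "day": 0.0,
                "cells": seed_count,
                "kind": "seeded",
            }
        )
        for i in range(n_passages):
            start = i * passage_interval_days
            end = start + passage_interval_days
            noise = (
                math.exp(rng.normal(-0.5 * sigma**2, sigma))
                if noise_cv > 0
                else 1.0
            )
            harvested = seed_count * growth_factor * noise
            passages.append(
                {
                    "condition": condition,
                    "replicate": rep,
                    "start_day": start,
                    "end_day": end,
                    "seeded": seed_count,
                    "harvested": harvested,
                }
            )
            counts.append(
                {
                    "condition": condition,
                    "replicate": rep,
                    "day": end,
                    "cells": harvested,
                    "kind": "counted",
                }
            )
    return pd.DataFrame(passages), pd.DataFrame(counts)


def gen_growth_scenario(
    name: str, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Run a packaged scenario; returns (passages, counts, truth).

    ``seed`` overrides the scenario's fixed seed.  The truth dict
    records the configured rate for parameter-recovery tests.
    """
    scenarios = load_growth_scenarios()
    try:
        params = dict(scenarios[name])
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; packaged: {sorted(scenarios)}"
        ) from None
    if seed is not None:
        params["seed"] = int(seed)
    truth = {"scenario": name, **params}
    passages, counts = gen_growth(condition=name, **params)
    return passages, counts, truth


def gen_peaks(
    scheme: PrecursorScheme | str,
    p: float,
    total_intensity: float = 1e6,
    is_spec: InternalStandardSpec | None = None,
    mz_jitter_ppm: float = 1.0,
    intensity_noise_cv: float = 0.05,
    n_background_peaks: int = 20,
    seed: int = 42,
    target_pmol_per_1e6_cells: float = 352.0,
    cell_count: float = 1e6,
    ppm_tolerance: float = 5.0,
) -> tuple[PeakTable, dict]:
    """Simulate a centroided peak table for one labeled sample.

    Isotopologue peaks sit at their theoretical m/z (plus uniform ppm
    jitter) with intensities ``total_intensity`` times the predicted MID
    times lognormal noise; the internal-standard peak is scaled so that
    quantification recovers ``target_pmol_per_1e6_cells`` (the default
    emulates the first-generation prototroph's mean valine content).
    Background peaks are placed at least three tolerance widths from
    every target so they exercise, but never corrupt, window matching.
    Returns the table and a ground-truth dict.
    """
    if isinstance(scheme, str):
        scheme, pools = make_scheme(scheme, p)
    else:
        pools = {
            pid: LabelingPool(pid, p, unit_carbon_count=c)
            for pid, c in scheme.units
        }
    if is_spec is None:
        is_spec = InternalStandardSpec()
    if mz_jitter_ppm > ppm_tolerance / 2:
        raise ValueError(
            f"mz_jitter_ppm={mz_jitter_ppm} exceeds half the assignment "
            f"tolerance ({ppm_tolerance} ppm); assignments would be unreliable"
        )
    rng = np.random.default_rng(seed)
    mid = predict_mid(scheme, pools)
    sigma = math.sqrt(math.log1p(intensity_noise_cv**2))

    def _noisy(base: float) -> float:
        if intensity_noise_cv == 0:
            return base
        return base * math.exp(rng.normal(-0.5 * sigma**2, sigma))

    rows = []
    truth_intensities = {}
    target_mzs = []
    for n in mid.support:
        theo = isotopologue_mz(scheme.product_formula, n)
        jitter = rng.uniform(-mz_jitter_ppm, mz_jitter_ppm) * 1e-6 * theo
        intensity = _noisy(total_intensity * mid[n])
        rows.append({"mz": theo + jitter, "intensity": intensity})
        truth_intensities[n] = intensity
        target_mzs.append(theo)
    is_mz = is_spec.mz()
    is_base = (
        total_intensity
        * is_spec.spiked_pmol
        * 1e6
        / (target_pmol_per_1e6_cells * cell_count)
    )
    is_intensity = _noisy(is_base)
    rows.append({"mz": is_mz, "intensity": is_intensity})
    target_mzs.append(is_mz)

    lo, hi = min(target_mzs) - 30.0, max(target_mzs) + 30.0
    placed = 0
    while placed < n_background_peaks:
        mz = rng.uniform(lo, hi)
        if all(
            abs(mz - t) >= 3.0 * t * ppm_tolerance * 1e-6 for t in target_mzs
        ):
            rows.append(
                {"mz": mz, "intensity": rng.uniform(0.001, 0.3) * total_intensity}
            )
            placed += 1
    truth = {
        "p": p,
        "mid": {int(n): mid[n] for n in mid.support},
        "target_intensities": truth_intensities,
        "is_intensity": is_intensity,
        "target_pmol_per_1e6_cells": target_pmol_per_1e6_cells,
        "labeled_pmol_per_1e6_cells": target_pmol_per_1e6_cells
        * (1.0 - mid[0]),
        "cell_count": cell_count,
        "spiked_pmol": is_spec.spiked_pmol,
    }
    return PeakTable(pd.DataFrame(rows)), truth


def gen_cq(
    copies: float = 7.1,
    expression_rq: float = 1.54,
    efficiency: float = 2.0,
    replicate_sd: float = 0.0,
    seed: int = 42,
    sample_id: str = "sample",
    calibrator_id: str = "calibrator",
    target_gene: str = "ilvD",
    reference_gene: str = "actb",
    n_replicates: int = 3,
) -> tuple[CqTable, dict]:
    """Simulate a Cq table consistent with the ΔΔCq model.

    The calibrator carries one target copy (gDNA) and expression 1.0
    (cDNA); the sample carries ``copies`` and ``expression_rq``.  Cq
    values follow the efficiency model exactly, plus Gaussian noise of
    SD ``replicate_sd`` per technical replicate.  Defaults emulate the
    boosted prototroph: 7.1 integrated copies, 1.54x expression.
    """
    if copies <= 0 or expression_rq <= 0:
        raise ValueError("copies and expression_rq must be positive")
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("efficiency must lie in (1, 2]")
    rng = np.random.default_rng(seed)
    base = {"gDNA": {reference_gene: 18.0, target_gene: 24.0},
            "cDNA": {reference_gene: 19.0, target_gene: 22.0}}
    shift = {
        ("gDNA", sample_id): math.log(copies, efficiency),
        ("gDNA", calibrator_id): 0.0,
        ("cDNA", sample_id): math.log(expression_rq, efficiency),
        ("cDNA", calibrator_id): 0.0,
    }
    rows = []
    for template in ("gDNA", "cDNA"):
        for sid in (calibrator_id, sample_id):
            for gene in (reference_gene, target_gene):
                cq = base[template][gene]
                if gene == target_gene:
                    cq -= shift[(template, sid)]
                for rep in range(1, n_replicates + 1):
                    noise = rng.normal(0.0, replicate_sd) if replicate_sd else 0.0
                    rows.append(
                        {
                            "sample_id": sid,
                            "gene": gene,
                            "template": template,
                            "replicate": rep,
                            "cq": cq + noise,
                        }
                    )
    truth = {
        "copies": copies,
        "expression_rq": expression_rq,
        "efficiency": efficiency,
        "replicate_sd": replicate_sd,
        "sample_id": sample_id,
        "calibrator_id": calibrator_id,
        "target_gene": target_gene,
        "reference_gene": reference_gene,
    }
    return CqTable(pd.DataFrame(rows)), truth
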